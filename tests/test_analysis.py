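import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import fieldmorph as fm
from fieldmorph.analysis import (
    cv_v,
    fixed_conductance_control,
    mann_whitney_u,
    mean_polarization,
    partial_corr,
    pearson_with_p,
    run_experiment,
    susceptibility,
    susceptibility_table,
)
from fieldmorph.cablesim import SimConfig, Trace
from fieldmorph.protocol import FieldProtocol


def _trace(values, dt=0.1):
    v = np.asarray(values, float)
    return Trace(t=np.arange(len(v)) * dt, voltages={"soma": v}, dt=dt)


def _responses(mean_v_by_e, neuron_id="n0", trials=1):
    rows = []
    for e, v in mean_v_by_e.items():
        for tr in range(trials):
            rows.append({"neuron_id": neuron_id, "class": "PC", "layer": "L23",
                         "orientation_deg": 0.0, "E": e, "trial": tr,
                         "target": "soma", "mean_V": v, "cv_V": 0.0,
                         "myelin_fraction": 0.0, "seed": 0})
    return pd.DataFrame(rows)


class TestTraceSummaries:
    def test_constant_trace_at_baseline(self):
        tr = _trace(np.full(200, -70.0))
        assert mean_polarization(tr, (5.0, 15.0), -70.0) == 0.0

    def test_offset_trace(self):
        tr = _trace(np.full(200, -68.0))
        assert mean_polarization(tr, (5.0, 15.0), -70.0) == pytest.approx(2.0)

    def test_exponential_tail(self):
        t = np.arange(0, 100, 0.1)
        v = -68.0 - 2.0 * np.exp(-t / 5.0)
        tr = _trace(v)
        # window deep in the tail: mean ≈ −68, polarization ≈ +2
        assert mean_polarization(tr, (60.0, 99.0), -70.0) == pytest.approx(2.0, abs=1e-4)

    def test_short_window_rejected(self):
        tr = _trace(np.full(200, -70.0))
        with pytest.raises(ValueError, match="10 samples"):
            mean_polarization(tr, (0.0, 0.5), -70.0)

    def test_cv_constant_is_zero(self):
        assert cv_v(_trace(np.full(100, -70.0)), (0.0, 9.0)) == 0.0

    def test_cv_alternating_hand_value(self):
        v = np.tile([-69.0, -71.0], 50)
        assert cv_v(_trace(v), (0.0, 9.9)) == pytest.approx(1.0 / 70.0, rel=1e-10)

    def test_cv_sign_invariant(self):
        v = -70.0 + np.sin(np.arange(100))
        assert cv_v(_trace(v), (0.0, 9.9)) == pytest.approx(
            cv_v(_trace(-v), (0.0, 9.9)), rel=1e-12)


class TestSusceptibility:
    def test_direct_evaluation(self):
        df = _responses({-50.0: -2.0, 50.0: 2.0})
        r = susceptibility(df)
        assert r.S == pytest.approx((-2.0 - 2.0) / -100.0)  # 0.04
        assert r.delta_E == -100.0

    def test_equal_endpoints_give_zero(self):
        r = susceptibility(_responses({-50.0: 1.5, 50.0: 1.5}))
        assert r.S == 0.0

    def test_matches_least_squares_slope_for_linear_response(self):
        levels = (-50.0, -30.0, -10.0, 0.0, 10.0, 30.0, 50.0)
        slope, icpt = -0.037, -70.0
        df = _responses({e: icpt + slope * e for e in levels})
        r = susceptibility(df)
        fit = sps.linregress(levels, [icpt + slope * e for e in levels])
        # with symmetric endpoints on a line the endpoint formula is the slope
        assert r.S == pytest.approx(fit.slope, rel=1e-12)

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValueError, match="field levels"):
            susceptibility(_responses({0.0: 0.0, 50.0: 1.0}))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_with_p(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.0, 3.5, 3.0, 5.5])
        r, p = pearson_with_p(x, y)
        r_ref = float(np.corrcoef(x, y)[0, 1])
        t_ref = r_ref * math.sqrt(3 / (1 - r_ref ** 2))
        p_ref = 2 * sps.t.sf(abs(t_ref), 3)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_cross_check_against_scipy(self, rng):
        x, y = rng.normal(size=(2, 30))
        r, p = pearson_with_p(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p(np.ones(5), np.arange(5.0))


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=(2, 20))
        assert partial_corr(x, y) == pytest.approx(pearson_with_p(x, y))

    def test_single_covariate_closed_form(self, rng):
        x, y, z = rng.normal(size=(3, 25))
        y = y + 0.8 * z
        x = x + 0.5 * z
        r, _ = partial_corr(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert r == pytest.approx(closed, abs=1e-10)

    def test_perfect_confound_removed(self, rng):
        z = rng.normal(size=30)
        r, p = partial_corr(z, z, z)
        assert abs(r) < 1e-8

    def test_cross_check_against_pingouin(self, rng):
        import pingouin as pg
        x, y, z1, z2 = rng.normal(size=(4, 40))
        y = y + 0.6 * z1 - 0.3 * z2
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        r, p = partial_corr(x, y, np.column_stack([z1, z2]))
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y, z = rng.normal(size=(3, 20))
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_corr(x, y, np.column_stack([z, 2 * z]))


class TestMannWhitney:
    def test_identical_samples_give_central_u(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        u, p = mann_whitney_u(a, a)
        assert u == 4 * 4 / 2
        assert p == pytest.approx(1.0)

    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u in (0.0, 9.0)

    def test_exact_p_matches_brute_force_enumeration(self):
        """Independent oracle: enumerate all C(8,4) labelings and count U
        statistics (computed by pairwise comparison, not ranks) at least as
        extreme as observed."""
        a = np.array([1.2, 3.4, 2.2, 5.0])
        b = np.array([2.9, 6.1, 4.4, 4.4])
        u_obs, p_obs = mann_whitney_u(a, b)

        pooled = np.concatenate([a, b])
        n1 = len(a)

        def u_of(sample_a, sample_b):
            # pairwise definition with half-credit for ties
            u = 0.0
            for x in sample_a:
                for y in sample_b:
                    u += 1.0 if x > y else (0.5 if x == y else 0.0)
            return u

        mu = n1 * (len(pooled) - n1) / 2.0
        assert u_of(a, b) == u_obs  # same statistic by both definitions
        count = total = 0
        for comb in itertools.combinations(range(len(pooled)), n1):
            sel = np.zeros(len(pooled), bool)
            sel[list(comb)] = True
            u = u_of(pooled[sel], pooled[~sel])
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        assert p_obs == pytest.approx(count / total, abs=1e-12)

    def test_cross_check_against_scipy_exact(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(loc=0.8, size=7)
        u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation_close_to_scipy(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(loc=0.4, size=30)
        u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=0.05)


@pytest.fixture(scope="module")
def small_pop():
    return fm.generate_population(
        [("PC", "L23", 3), ("PV", "L23", 3)], seed=21,
        biophys=fm.passive_biophysics())


@pytest.fixture(scope="module")
def proto():
    return FieldProtocol(e_levels=(-50.0, 0.0, 50.0), n_trials=2,
                         noise_sd=2.0, seed=6)


@pytest.fixture(scope="module")
def pc_pop():
    return fm.generate_population([("PC", "L23", 3)], seed=31)


class TestExperimentPipeline:
    CFG = SimConfig(duration=80.0, analysis_start=50.0)

    def test_full_pipeline_structure(self, small_pop, proto):
        res = run_experiment(small_pop, proto, self.CFG)
        assert len(res.traits) == 6
        assert len(res.susceptibility) == 6
        assert set(res.stats["traits"]) == set(fm.metrics.TRAIT_COLUMNS)
        for entry in res.stats["traits"].values():
            if not math.isnan(entry["p"]):
                assert 0.0 <= entry["p"] <= 1.0
        assert any(k.startswith("S:") for k in res.stats["group_tests"])

    def test_pipeline_deterministic(self, small_pop, proto):
        a = run_experiment(small_pop, proto, self.CFG)
        b = run_experiment(small_pop, proto, self.CFG)
        assert a.responses.to_csv() == b.responses.to_csv()
        assert a.susceptibility.to_csv() == b.susceptibility.to_csv()

    def test_whole_cell_partial_correlations_present(self, small_pop, proto):
        res = run_experiment(small_pop, proto, self.CFG)
        for t in ("vector_magnitude", "z_length", "ellipsoid_volume"):
            assert "r_partial" in res.stats["traits"][t]


class TestFixedConductanceControl:
    CFG = SimConfig(duration=60.0, analysis_start=40.0)

    def test_conductance_variance_zero_after_control(self, pc_pop):
        from fieldmorph.synthgen import average_conductances
        avg = average_conductances(pc_pop)
        assert avg.density_variability == 0.0
        cells = [avg.instantiate(n.model) for n in pc_pop]
        k = fm.cablesim.CHANNELS.index("NaT")
        vals = []
        for n, c in zip(pc_pop, cells):
            dmask = n.model.type_mask("basal_dendrite")
            vals.extend(np.unique(c.densities[k, dmask]).tolist())
        assert len(set(np.round(vals, 15))) == 1  # identical across subset

    def test_control_deterministic(self, pc_pop):
        proto = FieldProtocol(e_levels=(-50.0, 50.0), n_trials=1, noise_sd=0.0,
                              myelination_p={}, seed=8)
        a = fixed_conductance_control(pc_pop, proto, self.CFG)
        b = fixed_conductance_control(pc_pop, proto, self.CFG)
        assert a.to_csv() == b.to_csv()
        assert a["controlled"].all()

    def test_noop_on_already_uniform_subset(self):
        """Cells built with zero density variability: the averaging control
        must reproduce their susceptibilities exactly (σ_ξ = 0)."""
        pop = fm.generate_population([("PC", "L23", 2)], seed=41,
                                     biophys=fm.default_biophysics(0.0))
        proto = FieldProtocol(e_levels=(-50.0, 50.0), n_trials=1, noise_sd=0.0,
                              myelination_p={}, seed=8)
        from fieldmorph.protocol import run_population_protocol
        base = susceptibility_table(run_population_protocol(pop, proto, self.CFG))
        ctrl = fixed_conductance_control(pop, proto, self.CFG)
        np.testing.assert_allclose(ctrl["S"].to_numpy(), base["S"].to_numpy(),
                                   rtol=1e-9)


class TestStatsReportOnNull:
    def test_null_screen_small_smoke(self):
        df = fm.null_trait_screen(n_replicates=4, n_neurons=6, seed=5)
        assert set(df.columns) == {"replicate", "trait", "p"}
        assert df["p"].between(0, 1).all()

    def test_planted_screen_detects_length(self):
        df = fm.planted_length_screen(n_replicates=4, seed=5)
        assert (df["p_length"] < 0.05).all()
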