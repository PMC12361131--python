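import math

import numpy as np
import pytest
from scipy.linalg import expm

import fieldmorph as fm
from fieldmorph.cablesim import (
    CalciumSpec,
    SimConfig,
    Stimulus,
    assemble,
    ca_step,
    dense_passive_system,
    ionic_current,
    run,
)
from fieldmorph.morphology import Morphology, Section, discretize
from fieldmorph.protocol import field_offsets


def _soma_only(radius=10.0, g_pas=5e-5, e_pas=-70.0):
    m = Morphology([Section(0, "soma", np.zeros((1, 3)), np.array([2 * radius]), None)])
    model = discretize(m, 20.0)
    bio = fm.BiophysicsSpec(g_pas=g_pas, e_pas=e_pas,
                            channel_densities={}, density_variability=0.0)
    return model, bio.instantiate(model)


def _small_tree(n_child=2, seg_len=30.0):
    """Soma with a short stem that bifurcates: <10 compartments."""
    sections = [Section(0, "soma", np.zeros((1, 3)), np.array([12.0]), None),
                Section(1, "basal_dendrite",
                        np.array([[0, 0, 0], [0, 0, seg_len]]),
                        np.array([2.0, 2.0]), 0)]
    for k in range(n_child):
        x = (k + 1) * 10.0
        sections.append(Section(2 + k, "basal_dendrite",
                                np.array([[x, 0, seg_len], [x, 0, seg_len + 40.0]]),
                                np.array([1.5, 1.5]), 1))
    model = discretize(Morphology(sections), 25.0)
    bio = fm.passive_biophysics().instantiate(model)
    return model, bio


class TestAssemble:
    def test_axial_resistance_half_compartment_rule(self):
        # two identical 10 µm, 1 µm compartments, Ra = 100 Ω·cm:
        # R = Ra·Δx/(π (d/2)²) = 100·10e-4 cm / (π·(0.5e-4)² cm²) ≈ 12.73 MΩ
        pts = np.array([[0, 0, 0], [0, 0, 20.0]])
        m = Morphology([Section(0, "soma", np.zeros((1, 3)), np.array([1e-3]), None),
                        Section(1, "basal_dendrite", pts, np.array([1.0, 1.0]), 0)])
        model = discretize(m, 10.0)
        state = assemble(model, fm.passive_biophysics().instantiate(model))
        dend = np.flatnonzero(model.type_mask("basal_dendrite"))
        g = state.g_ax[dend[1]]  # coupling between the two dendritic comps
        expected_R = 100.0 * 10.0 / (math.pi * 0.25) * 1e-2  # MΩ
        assert 1.0 / g == pytest.approx(expected_R, rel=1e-12)

    def test_soma_only_is_pure_rc(self):
        model, bio = _soma_only()
        state = assemble(model, bio)
        assert state.n == 1 and np.all(state.g_ax == 0)

    def test_kirchhoff_row_sums(self):
        model, bio = _small_tree()
        state = assemble(model, bio)
        _, G = dense_passive_system(state)
        # off-diagonal sums cancel the coupling part of the diagonal exactly
        np.testing.assert_allclose(G.sum(axis=1), state.g_pas_u,
                                   rtol=1e-9, atol=1e-15)


class TestRun:
    def test_rc_step_response(self):
        model, bio = _soma_only()
        state = assemble(model, bio)
        R = state.input_resistance()  # MΩ
        tau = state.cap[0] * R  # nF·MΩ = ms
        I = 0.05  # nA
        cfg = SimConfig(duration=100.0, dt=0.025)
        tr = run(state, cfg, Stimulus(i_inj=np.array([I])))
        t = tr.t[1:]
        v = tr.voltages["soma"][1:] + 70.0
        pred = I * R * (1.0 - np.exp(-t / tau))
        mask = t > 1.0  # skip the first few steps of the first-order method
        err = np.abs(v[mask] - pred[mask]) / (I * R)
        assert err.max() < 0.005

    def test_rest_is_stable_without_stimulus(self):
        model, bio = _small_tree()
        state = assemble(model, bio)
        tr = run(state, SimConfig(duration=50.0))
        assert np.abs(tr.voltages["soma"] + 70.0).max() < 1e-6

    def test_gauge_invariance(self, passive_cable):
        state = assemble(passive_cable.model, passive_cable.biophys)
        cfg = SimConfig(duration=60.0)
        off = field_offsets(passive_cable.model, 10.0, mode="linear_potential")
        a = run(state, cfg, Stimulus(efield=off)).voltages["soma"]
        b = run(state, cfg, Stimulus(efield=off + 123.45)).voltages["soma"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_passive_linearity_and_antisymmetry(self, passive_cable):
        state = assemble(passive_cable.model, passive_cable.biophys)
        cfg = SimConfig(duration=80.0)
        off = field_offsets(passive_cable.model, 10.0, mode="linear_potential")
        v1 = run(state, cfg, Stimulus(efield=off)).voltages["soma"] + 70.0
        v3 = run(state, cfg, Stimulus(efield=3.0 * off)).voltages["soma"] + 70.0
        vm = run(state, cfg, Stimulus(efield=-off)).voltages["soma"] + 70.0
        scale = np.abs(v1).max()
        assert np.abs(v3 - 3.0 * v1).max() / (3 * scale) < 1e-6
        assert np.abs(vm + v1).max() / scale < 1e-6

    def test_dt_convergence_of_steady_state(self, passive_cable):
        state = assemble(passive_cable.model, passive_cable.biophys)
        off = field_offsets(passive_cable.model, 10.0, mode="linear_potential")
        ss = []
        for dt in (0.05, 0.025):
            cfg = SimConfig(duration=150.0, dt=dt)
            ss.append(run(state, cfg, Stimulus(efield=off)).voltages["soma"][-1] + 70.0)
        assert abs(ss[1] - ss[0]) / abs(ss[1]) < 1e-3

    def test_tree_solver_matches_dense_backward_euler(self):
        model, bio = _small_tree()
        state = assemble(model, bio)
        assert state.n <= 10
        dt, n_steps = 0.025, 400
        C, G = dense_passive_system(state)
        off = field_offsets(model, 30.0, mode="linear_potential")
        b_field = np.zeros(state.n)
        for i in range(1, state.n):
            p = model.parent[i]
            de = off[p] - off[i]
            b_field[i] += state.g_ax[i] * de
            b_field[p] -= state.g_ax[i] * de
        b = state.g_pas_u * (-70.0) + b_field
        v = np.full(state.n, -70.0)
        A = np.diag(C / dt) + G
        vs = [v[0]]
        for _ in range(n_steps):
            v = np.linalg.solve(A, C / dt * v + b)
            vs.append(v[0])
        cfg = SimConfig(duration=dt * n_steps, dt=dt)
        tr = run(state, cfg, Stimulus(efield=off))
        np.testing.assert_allclose(tr.voltages["soma"], vs, atol=1e-9)

    def test_steady_state_matches_dense_direct_solve(self):
        model, bio = _small_tree()
        state = assemble(model, bio)
        C, G = dense_passive_system(state)
        off = field_offsets(model, 30.0, mode="linear_potential")
        b_field = np.zeros(state.n)
        for i in range(1, state.n):
            p = model.parent[i]
            de = off[p] - off[i]
            b_field[i] += state.g_ax[i] * de
            b_field[p] -= state.g_ax[i] * de
        vss = np.linalg.solve(G, b_field + state.g_pas_u * (-70.0))
        tr = run(state, SimConfig(duration=400.0), Stimulus(efield=off))
        assert abs(tr.voltages["soma"][-1] - vss[0]) < 1e-6

    def test_trajectory_converges_to_matrix_exponential(self):
        """First-order convergence toward the exact expm trajectory."""
        model, bio = _small_tree()
        state = assemble(model, bio)
        C, G = dense_passive_system(state)
        off = field_offsets(model, 30.0, mode="linear_potential")
        b_field = np.zeros(state.n)
        for i in range(1, state.n):
            p = model.parent[i]
            de = off[p] - off[i]
            b_field[i] += state.g_ax[i] * de
            b_field[p] -= state.g_ax[i] * de
        b = b_field + state.g_pas_u * (-70.0)
        A = -np.diag(1.0 / C) @ G
        vss = np.linalg.solve(G, b)
        v0 = np.full(state.n, -70.0)
        T = 1.0  # sample inside the fast transient, on a common time grid
        t_grid = np.arange(0.0, T + 1e-9, 0.05)
        exact0 = np.array([(vss + expm(A * t) @ (v0 - vss))[0] for t in t_grid])
        errs = []
        for dt in (0.025, 0.0125):
            stride = int(round(0.05 / dt))
            tr = run(state, SimConfig(duration=T, dt=dt), Stimulus(efield=off))
            errs.append(np.abs(tr.voltages["soma"][::stride] - exact0).max())
        assert errs[0] < 0.15
        assert errs[1] < 0.65 * errs[0]  # ~first-order in dt

    def test_analytic_finite_cable_polarization(self, passive_cable):
        """Sealed-end cable in a linear extracellular gradient:
        |V_end| = E λ tanh(ℓ/2λ)."""
        state = assemble(passive_cable.model, passive_cable.biophys)
        cfg = SimConfig(duration=200.0, record_targets=("dendrite_end",))
        E = 10.0
        off = field_offsets(passive_cable.model, E, mode="linear_potential")
        tr = run(state, cfg, Stimulus(efield=off))
        lam = math.sqrt(1e-4 * (1.0 / 5e-5) / (4.0 * 100.0)) * 1e4  # µm
        m = passive_cable.model
        dend = np.flatnonzero(m.type_mask("basal_dendrite"))
        x_end = m.midpoints[dend, 2].max()
        pred = -E * 1e-3 * lam * math.sinh((x_end - 500.0) / lam) / math.cosh(500.0 / lam)
        got = tr.voltages["dendrite_end"][-1] + 70.0
        assert got == pytest.approx(pred, rel=0.01)

    def test_divergence_is_reported(self):
        model, bio = _soma_only()
        state = assemble(model, bio)
        bad = Stimulus(i_inj=np.array([np.nan]))  # poisoned stimulus
        with pytest.raises(FloatingPointError, match="diverged"):
            run(state, SimConfig(duration=5.0), bad)

    def test_active_model_quiescent_at_rest(self, pc_neuron):
        state = assemble(pc_neuron.model, pc_neuron.biophys)
        tr = run(state, SimConfig(duration=300.0))
        v = tr.voltages["soma"]
        assert v.max() < -40.0  # no spikes
        assert abs(v[-1] - v[-400]) < 0.05  # settled


class TestIonicCurrent:
    def test_zero_when_all_reversals_equal_v(self):
        model, _ = _soma_only()
        bio = fm.passive_biophysics().instantiate(model)
        state = assemble(model, bio)
        assert ionic_current(state, 0, v=-70.0) == pytest.approx(0.0, abs=1e-15)

    def test_passive_only_when_densities_zero(self):
        model, _ = _soma_only()
        bio = fm.passive_biophysics().instantiate(model)
        state = assemble(model, bio)
        assert ionic_current(state, 0, v=-60.0) == pytest.approx(5e-5 * 10.0, rel=1e-12)

    def test_current_linear_in_density(self, pc_neuron):
        state = assemble(pc_neuron.model, pc_neuron.biophys)
        base = ionic_current(state, 0, v=-55.0)
        doubled = assemble(pc_neuron.model, pc_neuron.biophys.copy())
        doubled.biophys.densities *= 2.0
        leak = pc_neuron.biophys.g_pas[0] * (-55.0 + 70.0)
        assert ionic_current(doubled, 0, v=-55.0) - leak == pytest.approx(
            2.0 * (base - leak), rel=1e-12)


class TestCalcium:
    SPEC = CalciumSpec(gamma=0.05, tau_d=80.0, d_shell=0.1, m_ca=1e-4)

    def test_fixed_point(self):
        assert ca_step(1e-4, 0.0, self.SPEC, 0.5) == pytest.approx(1e-4, rel=1e-14)

    def test_exponential_decay_closed_form(self):
        ca, dt, A = 1e-4 + 5e-4, 0.1, 5e-4
        t = 0.0
        for _ in range(2000):
            ca = ca_step(ca, 0.0, self.SPEC, dt)
            t += dt
        pred = 1e-4 + A * math.exp(-t / 80.0)
        assert ca == pytest.approx(pred, rel=1e-3)

    def test_steady_state_under_constant_current(self):
        i_ca = -2e-3  # inward Ca current, mA/cm²
        pred = 1e-4 - 10000.0 * i_ca * 0.05 * 80.0 / (2.0 * 96485.332 * 0.1)
        ca = 1e-4
        for _ in range(20000):
            ca = ca_step(ca, i_ca, self.SPEC, 0.5)
        assert ca == pytest.approx(pred, rel=1e-3)

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = ca_step(0.0, 1.0, self.SPEC, 1000.0)
        assert out == 0.0
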