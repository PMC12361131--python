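"""Compartmental cable-equation simulator.

Discretized membrane equation per compartment j:

    c_j dv_j/dt + i_ion,j = Σ_k ((v_k + e_k) − (v_j + e_j)) / r_jk + i_inj,j

with c_j the compartment capacitance, r_jk the axial resistance between
adjacent compartments, e_j an extracellular potential offset (how a uniform
field enters the model) and i_ion,j the sum of channel currents, each of the
form i = g (v − e_ion) with g = g_bar · (gating product).  The soma couples
to its children through its radius; neurite compartments couple through the
standard half-compartment series rule, which on a uniform unbranched chain
reduces to the textbook axial coefficient d/(4 R_a Δx²).

Integration is backward Euler with tree-ordered direct elimination
(unconditionally stable, O(N) per step); gating variables advance by
exponential Euler staggered with the voltage solve.  Units are NEURON
conventions: mV, ms, µm, S/cm², µF/cm², Ω·cm, mM, mA/cm².
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from .morphology import TYPE_CODE, CompartmentalModel

__all__ = [
    "CHANNELS",
    "CHANNEL_PLACEMENT",
    "CalciumSpec",
    "CellBiophysics",
    "SimConfig",
    "Stimulus",
    "SimState",
    "Trace",
    "assemble",
    "ionic_current",
    "ca_step",
    "run",
    "resolve_target",
    "dense_passive_system",
]

# fixed registry order; indices match _kernels
CHANNELS = ("Ih", "Im", "NaT", "Kd", "Kv2", "Kv3", "SK", "CaLVA", "CaHVA")

_DEND = ("basal_dendrite", "apical_dendrite")
#: compartment types each channel may occupy (dendrites = basal + apical)
CHANNEL_PLACEMENT = {
    "Ih": ("soma",) + _DEND,
    "Im": _DEND,
    "NaT": ("axon", "soma") + _DEND,
    "Kd": ("axon",),
    "Kv2": ("axon",),
    "Kv3": ("axon", "soma") + _DEND,
    "SK": ("axon", "soma"),
    "CaLVA": ("axon", "soma"),
    "CaHVA": ("axon", "soma"),
}

#: reversal potentials, mV
CHANNEL_REVERSAL = {
    "Ih": K.E_H,
    "Im": K.E_K,
    "NaT": K.E_NA,
    "Kd": K.E_K,
    "Kv2": K.E_K,
    "Kv3": K.E_K,
    "SK": K.E_K,
    "CaLVA": K.E_CA,
    "CaHVA": K.E_CA,
}

FARADAY = K.FARADAY


@dataclass(frozen=True)
class CalciumSpec:
    """Submembrane Ca²⁺ shell: dCa/dt = −10⁴ i_Ca γ / (2 F d) − (Ca − m)/τ_d.

    The 10⁴ factor is the unit conversion for i_Ca in mA/cm² and a shell
    depth in µm.  γ is the fraction of free (unbuffered) Ca²⁺, τ_d the
    removal time constant, m the resting concentration.
    """

    gamma: float = 0.05  # unitless, in (0, 1]
    tau_d: float = 80.0  # ms
    d_shell: float = 0.1  # µm
    m_ca: float = 1e-4  # mM

    def __post_init__(self) -> None:
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.tau_d <= 0 or self.d_shell <= 0:
            raise ValueError("tau_d and d_shell must be positive")


@dataclass
class CellBiophysics:
    """Per-compartment biophysics for one discretized cell.

    ``densities`` is (n_channels, N) in S/cm² in :data:`CHANNELS` order;
    passive parameters are per-compartment arrays (uniform after default
    instantiation, but myelination and controls may edit them).
    """

    cm: np.ndarray  # (N,) µF/cm²
    ra: float  # Ω·cm
    g_pas: np.ndarray  # (N,) S/cm²
    e_pas: np.ndarray  # (N,) mV
    densities: np.ndarray  # (9, N) S/cm²
    calcium: CalciumSpec = field(default_factory=CalciumSpec)
    ca_mask: Optional[np.ndarray] = None  # (N,) bool, where Ca dynamics run

    def copy(self) -> "CellBiophysics":
        return CellBiophysics(
            self.cm.copy(), self.ra, self.g_pas.copy(), self.e_pas.copy(),
            self.densities.copy(), self.calcium,
            None if self.ca_mask is None else self.ca_mask.copy(),
        )

    def mean_density(self, model: CompartmentalModel, neurite_type: str, channel: str) -> float:
        """Mean realized density of ``channel`` over compartments of a type."""
        mask = model.neurite_codes == TYPE_CODE[neurite_type]
        if not mask.any():
            return float("nan")
        return float(self.densities[CHANNELS.index(channel), mask].mean())


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.025  # ms
    duration: float = 500.0  # ms
    v_init: Optional[float] = None  # default: e_pas
    temperature: float = 34.0  # °C
    record_targets: Sequence[str] = ("soma",)
    analysis_start: Optional[float] = None  # default: duration / 2
    solver: str = "backward_euler"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.solver != "backward_euler":
            raise ValueError("only the backward_euler solver is implemented")

    @property
    def window(self) -> tuple[float, float]:
        start = self.duration / 2.0 if self.analysis_start is None else self.analysis_start
        return (start, self.duration)


@dataclass
class Stimulus:
    """Static extracellular offsets (mV), per-step Gaussian noise, and a
    constant injected current (nA) per compartment."""

    efield: Optional[np.ndarray] = None  # (N,) mV
    noise_sd: float = 0.0  # mV, redrawn i.i.d. per compartment per step
    noise_mean: float = 0.0  # mV
    i_inj: Optional[np.ndarray] = None  # (N,) nA
    rng: Optional[np.random.Generator] = None


@dataclass
class SimState:
    """Assembled electrical system: capacitances, axial conductances and
    channel conductances in solver units (nF, µS)."""

    model: CompartmentalModel
    biophys: CellBiophysics
    cap: np.ndarray  # (N,) nF
    g_ax: np.ndarray  # (N,) µS to parent; g_ax[0] = 0
    g_pas_u: np.ndarray  # (N,) µS
    gbar_u: np.ndarray  # (9, N) µS
    area_cm2: np.ndarray  # (N,)
    ca_mask: np.ndarray  # (N,) bool

    @property
    def n(self) -> int:
        return self.model.n

    def input_resistance(self) -> float:
        """Passive DC input resistance at the soma, MΩ (active g ignored)."""
        G = dense_passive_system(self)[1]
        b = np.zeros(self.n)
        b[0] = 1.0  # 1 nA at the soma
        return float(np.linalg.solve(G, b)[0])


def assemble(model: CompartmentalModel, biophys: CellBiophysics) -> SimState:
    """Build the electrical system from a discretized model and biophysics."""
    n = model.n
    for name, arr in (("cm", biophys.cm), ("g_pas", biophys.g_pas), ("e_pas", biophys.e_pas)):
        if len(arr) != n:
            raise ValueError(f"biophys.{name} length {len(arr)} != {n} compartments")
    if biophys.densities.shape != (len(CHANNELS), n):
        raise ValueError("densities must be (9, N)")
    if np.any(model.parent[1:] < 0):
        raise ValueError("disconnected compartment (parent < 0 beyond the root)")

    area_um2 = model.areas
    area_cm2 = area_um2 * 1e-8
    cap = biophys.cm * area_cm2 * 1e3  # µF → nF
    g_pas_u = biophys.g_pas * area_cm2 * 1e6  # S → µS
    gbar_u = biophys.densities * area_cm2 * 1e6

    # axial: half-compartment series resistances, MΩ; soma half-length = r
    half = biophys.ra * (model.lengths / 2.0) / (math.pi * (model.diameters / 2.0) ** 2) * 1e-2
    g_ax = np.zeros(n)
    for i in range(1, n):
        p = model.parent[i]
        g_ax[i] = 1.0 / (half[i] + half[p])

    if biophys.ca_mask is not None:
        ca_mask = biophys.ca_mask.astype(bool)
    else:
        ca_mask = model.type_mask("soma", "axon")
    return SimState(model, biophys, cap, g_ax, g_pas_u, gbar_u, area_cm2, ca_mask)


def dense_passive_system(state: SimState) -> tuple[np.ndarray, np.ndarray]:
    """(C, G): capacitance vector (nF) and dense passive conductance matrix
    (µS, symmetric M-matrix) such that C dv/dt = −G v + G·e-terms + I.

    Intended as an independent linear-algebra oracle for small trees.
    """
    n = state.n
    G = np.diag(state.g_pas_u.astype(float))
    for i in range(1, n):
        p = state.model.parent[i]
        G[i, i] += state.g_ax[i]
        G[p, p] += state.g_ax[i]
        G[i, p] -= state.g_ax[i]
        G[p, i] -= state.g_ax[i]
    return state.cap.copy(), G


@dataclass
class Trace:
    """Recorded voltages on a regular time grid, with metadata."""

    t: np.ndarray  # (S+1,) ms
    voltages: dict[str, np.ndarray]  # target name → (S+1,) mV
    dt: float
    meta: dict = field(default_factory=dict)

    def window_slice(self, window: tuple[float, float]) -> slice:
        i0 = int(round(window[0] / self.dt))
        i1 = int(round(window[1] / self.dt)) + 1
        return slice(i0, i1)

    def validate_finite(self) -> None:
        for name, v in self.voltages.items():
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(
                    f"simulation diverged (non-finite voltage at target {name!r}); "
                    f"meta={self.meta}"
                )


def resolve_target(model: CompartmentalModel, name: str) -> int:
    """Map a record-target selector to a compartment index.

    ``soma``: the soma compartment.  ``dendrite_terminal`` / ``axon_terminal``:
    the center compartment of the most distal terminal section of that class
    (responses are read at the center of a section).  ``dendrite_end`` /
    ``axon_end``: the most distal compartment itself (used for analytic
    end-polarization checks).
    """
    if name == "soma":
        return 0
    cls = name.split("_")[0]
    if cls in ("dendrite", "axon") and name.endswith(("_terminal", "_end")):
        if cls == "dendrite":
            mask = model.type_mask("basal_dendrite", "apical_dendrite")
        else:
            mask = model.type_mask("axon")
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"no compartments for target {name!r}")
        far = idx[np.argmax(np.linalg.norm(model.midpoints[idx], axis=1))]
        if name.endswith("_end"):
            return int(far)
        sec = model.section_compartments(int(model.section_ids[far]))
        return int(sec[len(sec) // 2])
    raise ValueError(f"unknown record target {name!r}")


def run(state: SimState, config: SimConfig, stimulus: Optional[Stimulus] = None) -> Trace:
    """Integrate the model and record at the configured targets."""
    stimulus = stimulus or Stimulus()
    n = state.n
    n_steps = int(round(config.duration / config.dt))
    v0 = float(config.v_init) if config.v_init is not None else float(state.biophys.e_pas[0])
    qt = 2.3 ** ((config.temperature - 21.0) / 10.0)

    efield = np.zeros(n) if stimulus.efield is None else np.asarray(stimulus.efield, float)
    i_inj = np.zeros(n) if stimulus.i_inj is None else np.asarray(stimulus.i_inj, float)
    if len(efield) != n or len(i_inj) != n:
        raise ValueError("stimulus arrays must have one entry per compartment")
    rng = stimulus.rng if stimulus.rng is not None else np.random.default_rng(0)

    rec_idx = np.array([resolve_target(state.model, t) for t in config.record_targets],
                       dtype=np.int64)
    cs = state.biophys.calcium
    vrec, _, _ = K.simulate(
        state.model.parent.astype(np.int64),
        state.cap, state.g_ax, state.g_pas_u, state.biophys.e_pas.astype(float),
        state.gbar_u, 1.0 / state.area_cm2, state.ca_mask,
        efield, float(stimulus.noise_sd), float(stimulus.noise_mean), i_inj,
        float(config.dt), n_steps, v0, qt,
        cs.gamma, cs.tau_d, cs.d_shell, cs.m_ca,
        rec_idx, rng,
    )
    t = np.arange(n_steps + 1) * config.dt
    voltages = {name: vrec[k] for k, name in enumerate(config.record_targets)}
    trace = Trace(t=t, voltages=voltages, dt=config.dt, meta={})
    trace.validate_finite()
    return trace


# ---------------------------------------------------------------------------
# single-compartment helpers exposed for direct use and testing


def ionic_current(state: SimState, j: int, v: float, ca: Optional[float] = None,
                  temperature: float = 34.0) -> float:
    """Total ionic current density of compartment j at voltage v, mA/cm².

    Gating variables are taken at their steady state for v (the relevant
    regime for subthreshold steady-state polarization); SK uses the resting
    Ca²⁺ concentration unless ``ca`` is given.
    """
    qt = 2.3 ** ((temperature - 21.0) / 10.0)
    dens = state.biophys.densities[:, j]
    ca_val = state.biophys.calcium.m_ca if ca is None else ca
    open_frac = {
        "Ih": K.rates_ih(v)[0],
        "Im": K.rates_im(v, qt)[0],
        "NaT": K.rates_nat_m(v, qt)[0] ** 3 * K.rates_nat_h(v, qt)[0],
        "Kd": K.rates_kd_m(v, qt)[0] ** 2 * K.rates_kd_h(v, qt)[0],
        "Kv2": K.rates_kv2_m(v, qt)[0] ** 4 * K.rates_kv2_h(v, qt)[0],
        "Kv3": K.rates_kv3_m(v)[0],
        "SK": K.sk_open(ca_val),
        "CaLVA": K.rates_calva_m(v, qt)[0] ** 2 * K.rates_calva_h(v, qt)[0],
        "CaHVA": K.rates_cahva_m(v)[0] ** 2 * K.rates_cahva_h(v)[0],
    }
    i = float(state.biophys.g_pas[j]) * (v - float(state.biophys.e_pas[j]))
    for k, name in enumerate(CHANNELS):
        i += dens[k] * open_frac[name] * (v - CHANNEL_REVERSAL[name])
    return i


def ca_step(ca: float, i_ca: float, spec: CalciumSpec, dt: float) -> float:
    """Advance the Ca²⁺ shell one step of dt (ms) under a frozen current
    density i_ca (mA/cm²); exact exponential update of the linear ODE."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    drive = -10000.0 * i_ca * spec.gamma / (2.0 * FARADAY * spec.d_shell)
    ca_ss = spec.m_ca + drive * spec.tau_d
    out = ca_ss + (ca - ca_ss) * math.exp(-dt / spec.tau_d)
    if out < 0.0:
        warnings.warn("Ca²⁺ went negative; clamped to 0")
        out = 0.0
    return out
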