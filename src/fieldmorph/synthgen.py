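"""Seeded synthetic neuron populations (morphology + biophysics).

Generates pyramidal (PC) and parvalbumin (PV) class morphologies for cortical
layers 2/3, 4 and 5 with the statistical structure the downstream analysis
assumes: PC cells are spatially extended with a dominant apical trunk toward
+z, PV cells are compact with densely branched axons, and dendritic diameters
taper with branch order.  Growth is a recursive stochastic branching process:
section lengths are log-normal, each section's direction blends its parent
direction with a signed z-bias plus Gaussian angular jitter, and a section
branches into two children with a fixed probability up to a maximum branch
order.

The default population layout is 27 cells — PC: 3/5/5 and PV: 5/4/5 across
L2/3, L4, L5.  All randomness flows from one root seed through per-neuron
child seeds, so populations are reproducible byte-for-byte.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .cablesim import CHANNEL_PLACEMENT, CHANNELS, CalciumSpec, CellBiophysics
from .morphology import (
    TYPE_CODE,
    CompartmentalModel,
    Morphology,
    Section,
    discretize,
    write_swc,
    read_swc,
)

__all__ = [
    "ClassSpec",
    "BiophysicsSpec",
    "Neuron",
    "DEFAULT_LAYOUT",
    "default_class_spec",
    "default_biophysics",
    "passive_biophysics",
    "generate_neuron",
    "generate_population",
    "straight_cable_neuron",
    "average_conductances",
    "save_population",
    "load_population",
]

DEFAULT_MAX_COMP_LEN = 20.0  # µm


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters for one (class, layer) morphology group."""

    class_label: str  # "PC" | "PV"
    layer_label: str  # "L23" | "L4" | "L5"
    n_dendritic_stems: int = 4
    apical: bool = False  # PC only: dominant +z trunk
    section_length_median: float = 100.0  # µm, log-normal median
    section_length_shape: float = 0.3  # log-sd
    branch_probability: float = 0.5
    max_branch_order: int = 3
    stem_diameter: float = 2.0  # µm
    taper_ratio: float = 0.8  # child/parent diameter, in (0, 1)
    axon_length_median: float = 120.0
    axon_length_shape: float = 0.3
    axon_branch_probability: float = 0.4
    axon_max_branch_order: int = 3
    axon_diameter: float = 1.0
    z_bias: float = 0.4  # fraction of growth direction pulled toward ±z
    angular_jitter: float = 0.35
    soma_radius: float = 8.0
    apical_length_median: float = 250.0  # trunk section length (PC only)

    def __post_init__(self) -> None:
        if not (0 < self.taper_ratio < 1):
            raise ValueError("taper_ratio must be in (0, 1)")
        for p in (self.branch_probability, self.axon_branch_probability, self.z_bias):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_dendritic_stems < 0:
            raise ValueError("n_dendritic_stems must be >= 0")


@dataclass(frozen=True)
class BiophysicsSpec:
    """Class-level biophysics: passive parameters plus per-compartment-type
    channel density targets, sampled per compartment with log-normal jitter
    of coefficient of variation ``density_variability``."""

    cm: float = 1.0  # µF/cm²
    ra: float = 100.0  # Ω·cm
    g_pas: float = 5e-5  # S/cm²
    e_pas: float = -70.0  # mV
    channel_densities: dict = field(default_factory=dict)  # type → {channel: S/cm²}
    calcium: CalciumSpec = field(default_factory=CalciumSpec)
    density_variability: float = 0.2  # CV of per-compartment jitter

    def __post_init__(self) -> None:
        if self.cm <= 0 or self.ra <= 0:
            raise ValueError("cm and ra must be positive")
        if self.g_pas < 0 or self.density_variability < 0:
            raise ValueError("g_pas and density_variability must be >= 0")
        for ntype, chans in self.channel_densities.items():
            for ch, g in chans.items():
                if ch not in CHANNELS:
                    raise ValueError(f"unknown channel {ch!r}")
                if g < 0:
                    raise ValueError(f"negative density for {ch}")
                allowed = CHANNEL_PLACEMENT[ch]
                ok = ntype in allowed or (
                    ntype in ("basal_dendrite", "apical_dendrite") and
                    any(t in allowed for t in ("basal_dendrite", "apical_dendrite"))
                )
                if g > 0 and not ok:
                    raise ValueError(f"channel {ch} not allowed on {ntype}")

    def instantiate(self, model: CompartmentalModel,
                    rng: Optional[np.random.Generator] = None) -> CellBiophysics:
        """Per-compartment realization on a discretized model.

        Passive parameters are uniform across compartments; channel densities
        get independent log-normal jitter with mean equal to the class target
        and CV = ``density_variability`` (0 disables jitter).
        """
        rng = rng or np.random.default_rng(0)
        n = model.n
        dens = np.zeros((len(CHANNELS), n))
        cv = self.density_variability
        sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
        # sorted iteration: the draw order (hence the realization) must not
        # depend on dict insertion order, or save/load round trips drift
        for ntype in sorted(self.channel_densities):
            chans = self.channel_densities[ntype]
            mask = model.neurite_codes == TYPE_CODE[ntype]
            if not mask.any():
                continue
            for ch in sorted(chans):
                g = chans[ch]
                k = CHANNELS.index(ch)
                if sigma > 0:
                    jitter = rng.lognormal(-0.5 * sigma * sigma, sigma, mask.sum())
                else:
                    jitter = np.ones(mask.sum())
                dens[k, mask] = g * jitter
        return CellBiophysics(
            cm=np.full(n, self.cm),
            ra=self.ra,
            g_pas=np.full(n, self.g_pas),
            e_pas=np.full(n, self.e_pas),
            densities=dens,
            calcium=self.calcium,
        )


@dataclass
class Neuron:
    """A generated cell: morphology, discretized model and biophysics."""

    id: str
    morphology: Morphology
    model: CompartmentalModel
    biophys: CellBiophysics
    class_label: str
    layer_label: str
    seed: int
    spec: Optional[ClassSpec] = None
    biophys_spec: Optional[BiophysicsSpec] = None


# ---------------------------------------------------------------------------
# default parameterization
#
# Calibrated so default-layout group means land in the qualitative ordering
# observed for real cortical populations: PV more compact (smaller z-length
# and vector magnitude) and with more axonal branching than same-layer PC;
# deeper-layer PCs taller than superficial ones.

_PC_BASE = dict(
    n_dendritic_stems=5, apical=True, section_length_median=110.0,
    branch_probability=0.5, max_branch_order=3, stem_diameter=2.4,
    taper_ratio=0.8, axon_length_median=150.0, axon_branch_probability=0.25,
    axon_max_branch_order=2, z_bias=0.35, soma_radius=9.0,
)
_PV_BASE = dict(
    n_dendritic_stems=6, apical=False, section_length_median=55.0,
    branch_probability=0.55, max_branch_order=3, stem_diameter=1.8,
    taper_ratio=0.75, axon_length_median=60.0, axon_branch_probability=0.65,
    axon_max_branch_order=4, z_bias=0.15, soma_radius=7.0,
)
_LAYER_TWEAK = {
    ("PC", "L23"): dict(apical_length_median=200.0),
    ("PC", "L4"): dict(apical_length_median=280.0),
    ("PC", "L5"): dict(apical_length_median=420.0, stem_diameter=2.8, soma_radius=10.0),
    ("PV", "L23"): dict(section_length_median=70.0),
    ("PV", "L4"): dict(),
    ("PV", "L5"): dict(section_length_median=60.0, axon_branch_probability=0.7),
}


def default_class_spec(class_label: str, layer_label: str) -> ClassSpec:
    base = dict(_PC_BASE) if class_label == "PC" else dict(_PV_BASE)
    base.update(_LAYER_TWEAK.get((class_label, layer_label), {}))
    return ClassSpec(class_label=class_label, layer_label=layer_label, **base)


#: Table-style default layout: (class, layer, count) summing to 27 cells.
DEFAULT_LAYOUT = (
    ("PC", "L23", 3), ("PC", "L4", 5), ("PC", "L5", 5),
    ("PV", "L23", 5), ("PV", "L4", 4), ("PV", "L5", 5),
)

# subthreshold-quiescent default densities (S/cm²) per compartment type
_DEFAULT_DENSITIES = {
    "soma": {"Ih": 1e-4, "NaT": 0.05, "Kv3": 0.1, "SK": 0.01,
             "CaLVA": 1e-4, "CaHVA": 5e-5},
    "axon": {"NaT": 0.1, "Kd": 0.05, "Kv2": 0.02, "Kv3": 0.2, "SK": 0.01,
             "CaLVA": 1e-4, "CaHVA": 5e-5},
    "basal_dendrite": {"Ih": 1e-4, "Im": 2e-4, "NaT": 0.01, "Kv3": 0.02},
    "apical_dendrite": {"Ih": 1e-4, "Im": 2e-4, "NaT": 0.01, "Kv3": 0.02},
}


def default_biophysics(density_variability: float = 0.2) -> BiophysicsSpec:
    return BiophysicsSpec(channel_densities={k: dict(v) for k, v in _DEFAULT_DENSITIES.items()},
                          density_variability=density_variability)


def passive_biophysics() -> BiophysicsSpec:
    """All active densities zero — the passive control used by calibration
    and oracle work."""
    return BiophysicsSpec(channel_densities={}, density_variability=0.0)


# ---------------------------------------------------------------------------
# growth model


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _grow_tree(sections: list[Section], rng: np.random.Generator, *,
               start: np.ndarray, direction: np.ndarray, parent_sid: int,
               neurite_type: str, order: int, spec: ClassSpec,
               length_median: float, length_shape: float,
               branch_p: float, max_order: int, base_diameter: float,
               z_sign: float, next_sid: list[int]) -> None:
    length = float(np.exp(rng.normal(math.log(length_median), length_shape)))
    n_seg = 5
    step = length / n_seg
    d = _unit(direction)
    pts = []
    cur = start.copy()
    for _ in range(n_seg):
        jitter = spec.angular_jitter * rng.standard_normal(3)
        d = _unit(d + jitter + spec.z_bias * np.array([0.0, 0.0, z_sign]))
        cur = cur + step * d
        pts.append(cur.copy())
    diameter = base_diameter * spec.taper_ratio ** order
    sid = next_sid[0]
    next_sid[0] += 1
    sections.append(Section(sid, neurite_type, np.array(pts),
                            np.full(n_seg, diameter), parent_sid))
    if order < max_order and rng.random() < branch_p:
        for sign in (1.0, -1.0):
            split = _unit(d + sign * 0.9 * _unit(np.cross(d, rng.standard_normal(3))))
            _grow_tree(sections, rng, start=cur, direction=split, parent_sid=sid,
                       neurite_type=neurite_type, order=order + 1, spec=spec,
                       length_median=length_median * 0.8, length_shape=length_shape,
                       branch_p=branch_p, max_order=max_order,
                       base_diameter=base_diameter, z_sign=z_sign, next_sid=next_sid)


def generate_neuron(spec: ClassSpec, biophys: BiophysicsSpec, seed: int,
                    neuron_id: Optional[str] = None,
                    max_compartment_length: float = DEFAULT_MAX_COMP_LEN) -> Neuron:
    """Grow one morphology and instantiate its biophysics; fully determined
    by (spec, biophys, seed)."""
    rng = np.random.default_rng(seed)
    soma = Section(0, "soma", np.zeros((1, 3)), np.array([2.0 * spec.soma_radius]), None)
    sections: list[Section] = [soma]
    next_sid = [1]

    # dendrites grow upward (+z); the apical trunk, when present, dominates
    n_stems = spec.n_dendritic_stems
    for k in range(n_stems):
        apical = spec.apical and k == 0
        ntype = "apical_dendrite" if apical else "basal_dendrite"
        if apical:
            direction = np.array([0.0, 0.0, 1.0])
            median = spec.apical_length_median
            diameter = spec.stem_diameter * 1.3
        else:
            az = rng.uniform(0, 2 * math.pi)
            el = rng.uniform(-0.2, 0.9)
            direction = np.array([math.cos(az) * math.cos(el),
                                  math.sin(az) * math.cos(el), math.sin(el)])
            median = spec.section_length_median
            diameter = spec.stem_diameter
        _grow_tree(sections, rng, start=np.zeros(3), direction=direction,
                   parent_sid=0, neurite_type=ntype, order=0, spec=spec,
                   length_median=median, length_shape=spec.section_length_shape,
                   branch_p=spec.branch_probability, max_order=spec.max_branch_order,
                   base_diameter=diameter, z_sign=1.0, next_sid=next_sid)

    # one axon initial stem growing downward (−z)
    _grow_tree(sections, rng, start=np.zeros(3), direction=np.array([0.0, 0.0, -1.0]),
               parent_sid=0, neurite_type="axon", order=0, spec=spec,
               length_median=spec.axon_length_median, length_shape=spec.axon_length_shape,
               branch_p=spec.axon_branch_probability, max_order=spec.axon_max_branch_order,
               base_diameter=spec.axon_diameter, z_sign=-1.0, next_sid=next_sid)

    if len(sections) <= 1:
        raise ValueError("spec produced zero neurite sections")
    morph = Morphology(sections, spec.class_label, spec.layer_label)
    morph.validate()
    model = discretize(morph, max_compartment_length)
    cell_biophys = biophys.instantiate(model, np.random.default_rng(
        np.random.SeedSequence([seed, 7]).generate_state(1)[0]))
    nid = neuron_id or f"{spec.class_label}-{spec.layer_label}-s{seed}"
    return Neuron(nid, morph, model, cell_biophys, spec.class_label,
                  spec.layer_label, seed, spec, biophys)


def _child_seed(root_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def generate_population(layout: Optional[Sequence] = None, seed: int = 0,
                        biophys: Optional[BiophysicsSpec] = None,
                        max_compartment_length: float = DEFAULT_MAX_COMP_LEN
                        ) -> list[Neuron]:
    """Generate a population from a layout of (ClassSpec | (class, layer), count).

    Default layout: the 27-cell population (PC 3/5/5, PV 5/4/5 over
    L2/3, L4, L5).  Per-neuron seeds are split from ``seed`` and recorded on
    each neuron.
    """
    if layout is None:
        layout = DEFAULT_LAYOUT
    if len(layout) == 0:
        raise ValueError("empty layout")
    biophys = biophys or default_biophysics()
    neurons: list[Neuron] = []
    idx = 0
    for entry in layout:
        if isinstance(entry[0], ClassSpec):
            spec, count = entry
        else:
            cls, layer, count = entry
            spec = default_class_spec(cls, layer)
        if count < 1:
            raise ValueError("counts must be >= 1")
        for k in range(count):
            s = _child_seed(seed, idx)
            nid = f"{spec.class_label}-{spec.layer_label}-{k:02d}"
            neurons.append(generate_neuron(spec, biophys, s, nid,
                                           max_compartment_length))
            idx += 1
    return neurons


def straight_cable_neuron(length: float, diameter: float, neuron_id: str = "cable",
                          biophys: Optional[BiophysicsSpec] = None,
                          soma_radius: float = 1.0, n_points: int = 21,
                          max_compartment_length: float = 25.0) -> Neuron:
    """A minimal cell: tiny soma at the origin with one straight vertical
    dendrite of the given length and uniform diameter.  The workhorse for
    analytic cable-theory checks and planted-effect screens."""
    biophys = biophys or passive_biophysics()
    z = np.linspace(0.0, length, n_points)
    pts = np.column_stack([np.zeros(n_points), np.zeros(n_points), z])
    sections = [
        Section(0, "soma", np.zeros((1, 3)), np.array([2.0 * soma_radius]), None),
        Section(1, "basal_dendrite", pts, np.full(n_points, diameter), 0),
    ]
    morph = Morphology(sections)
    model = discretize(morph, max_compartment_length)
    cell = biophys.instantiate(model, np.random.default_rng(0))
    return Neuron(neuron_id, morph, model, cell, "PC", "L23", 0, None, biophys)


# ---------------------------------------------------------------------------


def average_conductances(neurons: Sequence[Neuron]) -> BiophysicsSpec:
    """Average realized channel densities over a subset of cells.

    For each compartment type and channel, the arithmetic mean over neurons
    of that neuron's mean realized density; ``density_variability`` is forced
    to 0 so re-instantiation makes all compartments of a type identical.
    """
    if len(neurons) == 0:
        raise ValueError("need at least one neuron")
    specs = [n.biophys_spec for n in neurons]
    if any(s is None for s in specs):
        raise ValueError("neurons lack a BiophysicsSpec")
    keysets = [
        {(t, c) for t, chans in s.channel_densities.items() for c in chans}
        for s in specs
    ]
    if any(k != keysets[0] for k in keysets[1:]):
        raise ValueError("inconsistent channel sets across neurons")
    base = specs[0]
    avg: dict[str, dict[str, float]] = {}
    for ntype, chans in base.channel_densities.items():
        avg[ntype] = {}
        for ch in chans:
            vals = [n.biophys.mean_density(n.model, ntype, ch) for n in neurons]
            vals = [v for v in vals if not math.isnan(v)]
            avg[ntype][ch] = float(np.mean(vals)) if vals else 0.0
    return replace(base, channel_densities=avg, density_variability=0.0)


# ---------------------------------------------------------------------------
# population persistence: SWC directory + biophysics YAML + manifest CSV


def save_population(neurons: Sequence[Neuron], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["id,class,layer,seed,swc"]
    for n in neurons:
        fname = f"{n.id}.swc"
        write_swc(n.morphology, outdir / fname)
        rows.append(f"{n.id},{n.class_label},{n.layer_label},{n.seed},{fname}")
    (outdir / "manifest.csv").write_text("\n".join(rows) + "\n")
    spec = neurons[0].biophys_spec
    if spec is not None:
        cfg = {
            "cm": spec.cm, "ra": spec.ra, "g_pas": spec.g_pas, "e_pas": spec.e_pas,
            "density_variability": spec.density_variability,
            "channel_densities": {t: dict(c) for t, c in spec.channel_densities.items()},
            "calcium": {"gamma": spec.calcium.gamma, "tau_d": spec.calcium.tau_d,
                        "d_shell": spec.calcium.d_shell, "m_ca": spec.calcium.m_ca},
        }
        with open(outdir / "biophysics.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)


def load_population(indir, max_compartment_length: float = DEFAULT_MAX_COMP_LEN
                    ) -> list[Neuron]:
    """Rebuild a saved population; biophysics is re-instantiated from the
    stored spec and each neuron's recorded seed (so a save/load round trip
    reproduces the same cells)."""
    indir = Path(indir)
    bp_path = indir / "biophysics.yaml"
    if bp_path.exists():
        cfg = yaml.safe_load(bp_path.read_text())
        cal = cfg.pop("calcium", None)
        calcium = CalciumSpec(**cal) if cal else CalciumSpec()
        spec = BiophysicsSpec(calcium=calcium, **cfg)
    else:
        spec = passive_biophysics()
    neurons = []
    lines = (indir / "manifest.csv").read_text().strip().splitlines()[1:]
    for line in lines:
        nid, cls, layer, seed, fname = line.split(",")
        morph = read_swc(indir / fname)
        morph.class_label, morph.layer_label = cls, layer
        model = discretize(morph, max_compartment_length)
        model.class_label, model.layer_label = cls, layer
        cell = spec.instantiate(model, np.random.default_rng(
            np.random.SeedSequence([int(seed), 7]).generate_state(1)[0]))
        neurons.append(Neuron(nid, morph, model, cell, cls, layer, int(seed),
                              None, spec))
    return neurons
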