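"""Whole-cell and compartment-level morphometrics.

Whole-cell metrics (soma-centered coordinates, µm):

* vector magnitude  R = ⟨√(x² + y² + z²)⟩ over the N compartment midpoints —
  a spread measure;
* z-length  L = max z − min z over the raw morphology points;
* ellipsoid volume  V = (π/6)·(x-extent · y-extent · z-extent), the maximal
  ellipsoid the cell occupies.

Compartment-level metrics are reported separately for the dendritic (basal +
apical) and axonal memberships: mean compartment length, mean compartment
diameter, and the number of branches (bifurcation nodes: sections of the
class with ≥ 2 children).  Extents use raw morphology points rather than
midpoints so they do not depend on discretization granularity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import TYPE_CODE, CompartmentalModel

__all__ = [
    "vector_magnitude",
    "z_length",
    "ellipsoid_volume",
    "compartment_stats",
    "CompartmentClassStats",
    "build_trait_table",
    "TRAIT_COLUMNS",
]

_CLASS_TYPES = {
    "dendritic": ("basal_dendrite", "apical_dendrite"),
    "axonal": ("axon",),
}

TRAIT_COLUMNS = (
    "vector_magnitude", "z_length", "ellipsoid_volume",
    "dend_mean_length", "dend_mean_diameter", "dend_n_branches",
    "axon_mean_length", "axon_mean_diameter", "axon_n_branches",
)


def vector_magnitude(model: CompartmentalModel, include_soma: bool = False) -> float:
    """Mean Euclidean norm of compartment midpoints, µm.

    The soma midpoint is the origin and contributes zero; it is excluded
    from the average by default.
    """
    if model.n == 0:
        raise ValueError("empty model")
    mask = np.ones(model.n, dtype=bool)
    if not include_soma:
        mask &= model.neurite_codes != TYPE_CODE["soma"]
    if not mask.any():
        raise ValueError("no compartments to average")
    return float(np.linalg.norm(model.midpoints[mask], axis=1).mean())


def z_length(model: CompartmentalModel) -> float:
    """max z − min z over all raw morphology points, µm."""
    z = model.point_cloud[:, 2]
    return float(z.max() - z.min())


def ellipsoid_volume(model: CompartmentalModel) -> float:
    """V = (π/6)·Δx·Δy·Δz with per-axis point extents, µm³."""
    ext = model.point_cloud.max(axis=0) - model.point_cloud.min(axis=0)
    return float(math.pi / 6.0 * ext.prod())


@dataclass(frozen=True)
class CompartmentClassStats:
    mean_length: float
    mean_diameter: float
    n_branches: int
    present: bool = True


def compartment_stats(model: CompartmentalModel, neurite_class: str) -> CompartmentClassStats:
    """Mean compartment length/diameter and bifurcation count for a class.

    An absent class returns a flagged empty result (NaN means, 0 branches)
    rather than raising.
    """
    try:
        types = _CLASS_TYPES[neurite_class]
    except KeyError:
        raise ValueError(f"neurite_class must be one of {sorted(_CLASS_TYPES)}") from None
    mask = model.type_mask(*types)
    if not mask.any():
        return CompartmentClassStats(float("nan"), float("nan"), 0, present=False)
    n_branches = sum(
        1
        for sid, ntype in model.section_types.items()
        if ntype in types and len(model.section_children.get(sid, [])) >= 2
    )
    return CompartmentClassStats(
        mean_length=float(model.lengths[mask].mean()),
        mean_diameter=float(model.diameters[mask].mean()),
        n_branches=n_branches,
    )


def build_trait_table(population) -> pd.DataFrame:
    """One row of morphology metrics per neuron (deterministic)."""
    ids = [n.id for n in population]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated neuron ids")
    rows = []
    for n in population:
        dend = compartment_stats(n.model, "dendritic")
        axon = compartment_stats(n.model, "axonal")
        rows.append({
            "id": n.id,
            "class": n.class_label,
            "layer": n.layer_label,
            "vector_magnitude": vector_magnitude(n.model),
            "z_length": z_length(n.model),
            "ellipsoid_volume": ellipsoid_volume(n.model),
            "dend_mean_length": dend.mean_length,
            "dend_mean_diameter": dend.mean_diameter,
            "dend_n_branches": dend.n_branches,
            "axon_mean_length": axon.mean_length,
            "axon_mean_diameter": axon.mean_diameter,
            "axon_n_branches": axon.n_branches,
        })
    cols = ["id", "class", "layer", *TRAIT_COLUMNS]
    return pd.DataFrame(rows, columns=cols)
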