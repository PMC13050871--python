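"""Synaptic-engagement classification and per-cell count normalisation.

A ribbon is *synaptically engaged* when the shortest surface-to-surface
distance to any postsynaptic density (PSD) is strictly below 0.5 μm;
otherwise it is a cytoplasmically-floating ribbon.  Distances are
measured between boundary-voxel centers in physical units; intersecting
or 26-adjacent voxel sets are at distance 0.  This voxel-level
convention can differ from a sub-voxel mesh distance by at most one
voxel diagonal.

Ribbon counts are normalised to the number of inner hair cells (IHCs)
in the region of interest, which is an explicit input (cells are counted
manually in this preparation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .puncta3d import Punctum

__all__ = [
    "SynapseAssignment",
    "CountSummary",
    "ENGAGEMENT_CUTOFF_UM",
    "surface_distance",
    "classify",
    "summarize",
]

#: Engagement rule: shortest surface-to-surface distance < 0.5 μm.
ENGAGEMENT_CUTOFF_UM = 0.5


@dataclass(frozen=True)
class SynapseAssignment:
    """Nearest-PSD pairing of one ribbon."""

    ribbon_id: int
    nearest_psd_id: int | None
    surface_distance_um: float
    klass: str  # "synaptic" or "cytoplasmic"

    def __post_init__(self):
        if self.surface_distance_um < 0:
            raise ValueError("distance must be >= 0")
        if self.klass not in ("synaptic", "cytoplasmic"):
            raise ValueError("class must be 'synaptic' or 'cytoplasmic'")


@dataclass(frozen=True)
class CountSummary:
    """Ribbon counts and their per-IHC normalisation."""

    n_synaptic: int
    n_cytoplasmic: int
    n_ihc: int
    synaptic_per_ihc: float
    cytoplasmic_per_ihc: float


def _boundary_voxels(voxels: np.ndarray) -> np.ndarray:
    """Voxels of the set with at least one 26-neighbour outside the set."""
    voxels = np.asarray(voxels, dtype=np.int64)
    vset = set(map(tuple, voxels))
    out = []
    for v in voxels:
        z, y, x = v
        on_boundary = False
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    if (z + dz, y + dy, x + dx) not in vset:
                        on_boundary = True
                        break
                if on_boundary:
                    break
            if on_boundary:
                break
        if on_boundary:
            out.append(v)
    if not out:  # solid set with no exterior neighbour cannot occur for finite sets
        return voxels
    return np.array(out, dtype=np.int64)


def surface_distance(a: Punctum, b: Punctum, voxel_size_um) -> float:
    """Shortest surface-to-surface distance between two puncta, in μm.

    0 when the voxel sets intersect or are 26-adjacent; otherwise the
    minimum Euclidean distance between boundary-voxel centers, scaled by
    the physical voxel size ``(dz, dy, dx)``.
    """
    av, bv = np.asarray(a.voxels), np.asarray(b.voxels)
    if len(av) == 0 or len(bv) == 0:
        raise ValueError("puncta must be non-empty")
    # adjacency/overlap test: any index pair within Chebyshev distance 1
    tree_idx = cKDTree(av)
    d_cheb, _ = tree_idx.query(bv, k=1, p=np.inf)
    if float(d_cheb.min()) <= 1.0:
        return 0.0
    vs = np.asarray(voxel_size_um, dtype=float)
    ab = _boundary_voxels(av) * vs
    bb = _boundary_voxels(bv) * vs
    tree = cKDTree(ab)
    d, _ = tree.query(bb, k=1)
    return float(d.min())


def classify(
    ribbons: list[Punctum],
    psds: list[Punctum],
    voxel_size_um,
    cutoff_um: float = ENGAGEMENT_CUTOFF_UM,
) -> list[SynapseAssignment]:
    """Assign each ribbon its nearest PSD and an engagement class.

    Class is ``synaptic`` iff the shortest surface distance is strictly
    below ``cutoff_um``.  With no PSDs every ribbon is cytoplasmic.
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    out: list[SynapseAssignment] = []
    for r in ribbons:
        best_d, best_id = np.inf, None
        for p in psds:
            d = surface_distance(r, p, voxel_size_um)
            if d < best_d:
                best_d, best_id = d, p.label
            if best_d == 0.0:
                break
        if best_id is None:
            out.append(SynapseAssignment(r.label, None, np.inf, "cytoplasmic"))
        else:
            klass = "synaptic" if best_d < cutoff_um else "cytoplasmic"
            out.append(SynapseAssignment(r.label, best_id, best_d, klass))
    return out


def summarize(assignments: list[SynapseAssignment], n_ihc: int) -> CountSummary:
    """Count synaptic vs cytoplasmic ribbons and normalise per IHC."""
    if n_ihc < 1:
        raise ValueError("n_ihc must be >= 1")
    n_syn = sum(1 for a in assignments if a.klass == "synaptic")
    n_cyt = len(assignments) - n_syn
    return CountSummary(n_syn, n_cyt, n_ihc, n_syn / n_ihc, n_cyt / n_ihc)
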