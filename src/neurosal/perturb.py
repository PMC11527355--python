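"""Age-proportional ventricular dilation and surrogate ground truth.

The perturbation injects a known, age-dependent signal into each volume:
a subject's chronological age is mapped to a dilation coefficient in
[0, 1] (0 at/below the cohort's 5th age percentile, 1 at/above the 95th,
linear in age between), and that fraction of the white-matter voxels
face-adjacent to the lateral-ventricle boundary have their intensities
replaced by ventricle intensities — simulating ventricular dilation into
white matter. Averaging |perturbed − original| across the cohort yields a
surrogate ground-truth map whose support is known a priori, against which
attribution maps can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .phantom import IntensityVolume, LabelVolume

__all__ = [
    "dilation_coefficient",
    "find_edge_voxels",
    "split_adjacent",
    "dilate_ventricles",
    "build_ground_truth",
    "binarize_fixation",
    "PerturbationResult",
    "GroundTruthMap",
    "FixationMap",
]

Coord = Tuple[int, int, int]

# 6-connectivity (face adjacency) structuring element
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PerturbationResult:
    perturbed: IntensityVolume
    replaced_voxels: FrozenSet[Coord]
    peripheric_voxels: FrozenSet[Coord]
    coefficient: float


@dataclass
class GroundTruthMap:
    """Nonnegative map of injected signal, normalized to total mass 1."""

    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if (d < 0).any():
            raise ValueError("ground truth must be nonnegative")
        self.data = d

    @property
    def support(self) -> np.ndarray:
        return self.data > 0


@dataclass
class FixationMap:
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if not self.data.any():
            raise ValueError("fixation map must have nonempty support")


def dilation_coefficient(ca: float, cohort_cas: Sequence[float]) -> float:
    """Map chronological age to a dilation coefficient in [0, 1].

    0 at/below the 5th percentile of the cohort age distribution, 1
    at/above the 95th, linear in age between the two percentile ages.
    """
    cas = np.asarray(list(cohort_cas), dtype=float)
    if cas.size == 0:
        raise ValueError("cohort age list must be nonempty")
    if not np.isfinite(ca):
        raise ValueError("ca must be finite")
    p5, p95 = np.percentile(cas, [5.0, 95.0])
    if p95 <= p5:
        raise ValueError(
            f"degenerate cohort age distribution: 5th percentile {p5} == 95th {p95}")
    return float(np.clip((ca - p5) / (p95 - p5), 0.0, 1.0))


def _mask_of(labels: LabelVolume, structure) -> np.ndarray:
    if isinstance(structure, str):
        return labels.mask(structure)
    return labels.data == structure


def _coord_set(mask: np.ndarray) -> FrozenSet[Coord]:
    return frozenset(map(tuple, np.argwhere(mask)))


def find_edge_voxels(labels: LabelVolume, structure="LV") -> FrozenSet[Coord]:
    """Voxels of ``structure`` with a 6-neighbor of a different label
    (volume boundary counts as different)."""
    mask = _mask_of(labels, structure)
    if not mask.any():
        return frozenset()
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return _coord_set(mask & ~interior)


def _edge_and_adjacent_masks(labels: LabelVolume, lv_mask: np.ndarray):
    interior = ndimage.binary_erosion(lv_mask, structure=_FACE_STRUCT, border_value=0)
    edge = lv_mask & ~interior
    neigh = ndimage.binary_dilation(edge, structure=_FACE_STRUCT) & ~lv_mask
    bg = labels.mask("background")
    wm = labels.mask("WM")
    awm = neigh & wm
    anwm = neigh & ~wm & ~bg
    return edge, awm, anwm


def split_adjacent(labels: LabelVolume, edges: Iterable[Coord]
                   ) -> Tuple[FrozenSet[Coord], FrozenSet[Coord]]:
    """Split the non-ventricle face-neighbors of the ventricular edge into
    adjacent white matter (AWM) and adjacent non-white matter (ANWM;
    background excluded)."""
    edge_mask = np.zeros(labels.data.shape, dtype=bool)
    idx = np.array(list(edges), dtype=int).reshape(-1, 3)
    if idx.size:
        edge_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    lv = labels.mask("LV")
    neigh = ndimage.binary_dilation(edge_mask, structure=_FACE_STRUCT) & ~lv
    wm = labels.mask("WM")
    bg = labels.mask("background")
    return _coord_set(neigh & wm), _coord_set(neigh & ~wm & ~bg)


def _round_half_even(x: float) -> int:
    return int(round(x))


def dilate_ventricles(volume: IntensityVolume, labels: LabelVolume,
                      coeff: float, rng: np.random.Generator) -> PerturbationResult:
    """Replace ``round(coeff * |AWM|)`` randomly chosen AWM voxel
    intensities with the intensity of each voxel's nearest ventricular
    edge voxel (lexicographic tie-break), then reassign the new boundary
    voxels of the enlarged ventricle to the mean ANWM intensity.

    Selection is exact-count sampling without replacement, so a
    coefficient of 0.8 with 100 AWM voxels replaces exactly 80.
    """
    if not 0.0 <= coeff <= 1.0:
        raise ValueError(f"dilation coefficient must be in [0, 1], got {coeff}")
    lv = labels.mask("LV")
    if not lv.any():
        raise ValueError("label volume has no lateral-ventricle voxels")
    edge_mask, awm_mask, anwm_mask = _edge_and_adjacent_masks(labels, lv)

    awm = np.argwhere(awm_mask)          # C-order == lexicographic
    n_replace = _round_half_even(coeff * len(awm))
    out = volume.data.copy()
    if n_replace == 0:
        return PerturbationResult(IntensityVolume(out, volume.voxel_mm),
                                  frozenset(), frozenset(), coeff)

    sel_idx = rng.choice(len(awm), size=n_replace, replace=False)
    selected = awm[np.sort(sel_idx)]
    edges = np.argwhere(edge_mask)
    # nearest LV edge voxel per selected voxel; argmin over lexicographically
    # ordered edges makes ties resolve to the smallest coordinate
    d2 = ((selected[:, None, :] - edges[None, :, :]) ** 2).sum(axis=2)
    nearest = edges[np.argmin(d2, axis=1)]
    out[selected[:, 0], selected[:, 1], selected[:, 2]] = \
        volume.data[nearest[:, 0], nearest[:, 1], nearest[:, 2]]

    replaced_mask = np.zeros(out.shape, dtype=bool)
    replaced_mask[selected[:, 0], selected[:, 1], selected[:, 2]] = True

    # boundary voxels of the enlarged ventricular region that are newly
    # added take the mean intensity of the adjacent non-white-matter pool
    peripheric: FrozenSet[Coord] = frozenset()
    if anwm_mask.any():
        enlarged = lv | replaced_mask
        interior = ndimage.binary_erosion(enlarged, structure=_FACE_STRUCT,
                                          border_value=0)
        new_boundary = enlarged & ~interior & replaced_mask
        if new_boundary.any():
            anwm_mean = float(volume.data[anwm_mask].mean())
            out[new_boundary] = anwm_mean
            peripheric = _coord_set(new_boundary)

    return PerturbationResult(IntensityVolume(out, volume.voxel_mm),
                              _coord_set(replaced_mask), peripheric, coeff)


def build_ground_truth(pairs: Sequence[Tuple[IntensityVolume, IntensityVolume]]
                       ) -> GroundTruthMap:
    """Voxelwise mean of |perturbed − original| across subjects,
    normalized to total mass 1."""
    if len(pairs) == 0:
        raise ValueError("need at least one (original, perturbed) pair")
    shape = pairs[0][0].data.shape
    acc = np.zeros(shape)
    for orig, pert in pairs:
        if orig.data.shape != shape or pert.data.shape != shape:
            raise ValueError("all volumes must share one shape")
        acc += np.abs(pert.data - orig.data)
    acc /= len(pairs)
    total = acc.sum()
    if total == 0:
        raise ValueError("degenerate ground truth: no voxel differs in any pair")
    return GroundTruthMap(acc / total)


def binarize_fixation(gt: GroundTruthMap) -> FixationMap:
    """Indicator of the ground truth's nonzero support."""
    if not gt.support.any():
        raise ValueError("ground truth has empty support")
    return FixationMap(gt.support)
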