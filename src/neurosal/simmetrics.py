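"""Saliency normalization and similarity scoring against ground truth.

Raw attributions are converted to *saliency probability densities* —
absolute values normalized to unit total mass — and scored against the
surrogate ground truth with five measures:

* DC   — Sørensen–Dice coefficient on binarized maps, in [0, 1]
* NMI  — normalized mutual information ``(H(A)+H(B))/H(A,B)``, in [1, 2]
* NSS  — mean z-scored saliency over the fixation support (unbounded)
* CC   — Pearson correlation between maps, in [−1, 1]
* SIM  — histogram intersection ``Σ min(a, b)`` of two densities, in [0, 1]

Scores are reported per method together with the percent difference
relative to the masked-gradient (MG) baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .attribution import RawAttribution
from .perturb import FixationMap, GroundTruthMap

__all__ = [
    "SaliencyMap",
    "normalize_saliency",
    "cohort_mean_map",
    "dice",
    "binarize_saliency_for_dice",
    "nmi",
    "nss",
    "zscore_map",
    "cc",
    "sim",
    "score_method",
    "percent_diff_vs_baseline",
    "SimilarityReport",
]

_MASS_TOL = 1e-9


@dataclass
class SaliencyMap:
    """Nonnegative field of unit total mass ('saliency probability density')."""

    data: np.ndarray
    method: str = ""

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if (d < 0).any():
            raise ValueError("saliency density must be nonnegative")
        if abs(d.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"saliency density must sum to 1, got {d.sum():.12f}")
        self.data = d


def normalize_saliency(raw: RawAttribution) -> SaliencyMap:
    """|raw| / Σ|raw|; an all-zero field is a degeneracy (constant model,
    empty mask, …) and is rejected."""
    mag = np.abs(np.asarray(raw.data, dtype=float))
    total = mag.sum()
    if total == 0:
        raise ValueError(f"degenerate all-zero attribution for method {raw.method!r}")
    return SaliencyMap(mag / total, raw.method)


def cohort_mean_map(maps: Sequence[SaliencyMap]) -> SaliencyMap:
    """Voxelwise mean of per-subject densities, renormalized to mass 1."""
    if len(maps) == 0:
        raise ValueError("need at least one saliency map")
    acc = np.mean([m.data for m in maps], axis=0)
    return SaliencyMap(acc / acc.sum(), maps[0].method)


# ---------------------------------------------------------------------------
# image similarity
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen–Dice: 2|A∩B| / (|A|+|B|) on binary maps."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must share one shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Dice undefined: both maps are empty")
    return float(2.0 * (a & b).sum() / denom)


def binarize_saliency_for_dice(s: SaliencyMap, fixation: FixationMap) -> np.ndarray:
    """Top-N saliency voxels, N = |fixation support|; ties at the
    threshold broken by lexicographic (C-order) coordinate order."""
    n = int(np.asarray(fixation.data, dtype=bool).sum())
    flat = s.data.ravel()
    if n > flat.size:
        raise ValueError("fixation support exceeds the voxel count")
    # stable sort on descending saliency keeps C-order among ties
    order = np.argsort(-flat, kind="stable")[:n]
    out = np.zeros(flat.size, dtype=bool)
    out[order] = True
    return out.reshape(s.data.shape)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nmi(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) from a joint
    histogram over equal-width bins spanning each map's own range."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("maps must share one shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("NMI undefined for a constant map (zero entropy)")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    joint /= joint.sum()
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    hab = _entropy(joint.ravel())
    return float((ha + hb) / hab)


# ---------------------------------------------------------------------------
# saliency-benchmark measures
# ---------------------------------------------------------------------------

def zscore_map(data: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, (population) standard deviation 1."""
    data = np.asarray(data, dtype=float)
    sd = data.std()
    if sd == 0:
        raise ValueError("z-score undefined for a constant map")
    return (data - data.mean()) / sd


def nss(s: SaliencyMap, fixation: FixationMap) -> float:
    """Mean z-scored saliency over the fixation support."""
    fix = np.asarray(fixation.data, dtype=bool)
    if fix.shape != s.data.shape:
        raise ValueError("maps must share one shape")
    return float(zscore_map(s.data)[fix].mean())


def cc(a, b) -> float:
    """Pearson correlation of two maps over all voxels."""
    av = np.asarray(a.data if hasattr(a, "data") else a, dtype=float).ravel()
    bv = np.asarray(b.data if hasattr(b, "data") else b, dtype=float).ravel()
    if av.size != bv.size:
        raise ValueError("maps must share one shape")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("CC undefined for a constant map")
    return float(np.corrcoef(av, bv)[0, 1])


def sim(a, b) -> float:
    """Histogram intersection Σ_v min(a_v, b_v) of two unit-mass maps."""
    av = np.asarray(a.data if hasattr(a, "data") else a, dtype=float)
    bv = np.asarray(b.data if hasattr(b, "data") else b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("maps must share one shape")
    for name, v in (("first", av), ("second", bv)):
        if abs(v.sum() - 1.0) > 1e-6 or (v < 0).any():
            raise ValueError(f"SIM requires normalized densities; {name} map is not")
    return float(np.minimum(av, bv).sum())


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

METRICS = ("DC", "NMI", "NSS", "CC", "SIM")


def score_method(s: SaliencyMap, gt: GroundTruthMap, fixation: FixationMap,
                 nmi_bins: int = 64) -> Dict[str, float]:
    """All five scores of one saliency map against the ground truth.

    DC and NSS consume the binary fixation map; NMI, CC, and SIM the
    continuous normalized ground truth.
    """
    gt_norm = gt.data / gt.data.sum()
    return {
        "DC": dice(binarize_saliency_for_dice(s, fixation), fixation.data),
        "NMI": nmi(s.data, gt_norm, bins=nmi_bins),
        "NSS": nss(s, fixation),
        "CC": cc(s.data, gt_norm),
        "SIM": sim(s.data, gt_norm),
    }


@dataclass
class SimilarityReport:
    """Per-method metric scores plus percent differences vs the MG row."""

    scores: pd.DataFrame                 # rows = methods, cols = metrics
    percent_diff: pd.DataFrame           # same layout, vs the baseline row
    baseline_method: str = "MG"
    provenance: Dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        merged = self.scores.join(self.percent_diff.add_suffix("_pct_vs_" +
                                                               self.baseline_method))
        merged.to_csv(path, index_label="method")

    def to_json(self, path) -> None:
        import json
        payload = {"baseline": self.baseline_method,
                   "scores": self.scores.to_dict(orient="index"),
                   "percent_diff": self.percent_diff.to_dict(orient="index"),
                   "provenance": self.provenance}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def percent_diff_vs_baseline(scores: Dict[str, Dict[str, float]],
                             baseline_method: str = "MG") -> SimilarityReport:
    """100 · (score − score_baseline) / |score_baseline| per metric; a
    zero baseline score yields NaN for that cell (flagged, not inflated)."""
    if baseline_method not in scores:
        raise ValueError(f"baseline method {baseline_method!r} missing from scores")
    df = pd.DataFrame(scores).T
    base = df.loc[baseline_method]
    pct = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for metric in df.columns:
        if base[metric] == 0:
            pct[metric] = np.nan
        else:
            pct[metric] = 100.0 * (df[metric] - base[metric]) / abs(base[metric])
    return SimilarityReport(df, pct, baseline_method)
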