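"""Synthetic labeled brain phantoms whose ventricle size encodes age.

Each phantom is a cubic, skull-stripped-style volume built from nested
ellipsoids: a cortical shell of non-white-matter tissue (NWM) around a
white-matter (WM) core, with a bilateral pair of lateral-ventricle (LV)
ellipsoids embedded in the WM. The LV radius grows linearly with the
subject's chronological age, so ventricular size is the (only) learnable
age signal — a deliberately minimal stand-in for the ventricular
enlargement that dominates structural brain aging. Intensities are drawn
per tissue class from Gaussians (clipped at zero) on a unit scale, with
background exactly zero as in skull-stripped data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "LABELS",
    "PhantomParams",
    "SubjectRecord",
    "IntensityVolume",
    "LabelVolume",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

#: canonical label integers, FreeSurfer-like in spirit but self-contained
LABELS: Dict[str, int] = {"background": 0, "WM": 1, "NWM": 2, "LV": 3}

# fixed anatomical proportions of the phantom geometry (fractions of the
# brain semi-axes); these are shape constants, not tunable study conditions
_BRAIN_ANISOTROPY = (1.0, 0.92, 0.85)   # x (left-right), y, z
_WM_FRACTION = 0.78                      # WM ellipsoid relative to brain
_LV_CENTER_OFFSET_FRAC = 0.45            # lateral LV offset, fraction of WM x-semi-axis


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity, and age-encoding parameters of the phantom.

    ``base_ventricle_radius_vox`` is the LV radius (voxels) at
    ``age_min``; each year of age adds ``ventricle_growth_vox_per_year``
    voxels of radius. Tissue intensity means/SDs are on a unit scale.
    """

    grid_size: int = 32
    voxel_mm: float = 2.0
    brain_radius_frac: float = 0.88
    base_ventricle_radius_vox: float = 1.5
    ventricle_growth_vox_per_year: float = 0.05
    age_min: float = 40.0
    age_max: float = 90.0
    tissue_means: Dict[str, float] = field(
        default_factory=lambda: {"WM": 0.45, "NWM": 0.28, "LV": 0.10})
    tissue_sds: Dict[str, float] = field(
        default_factory=lambda: {"WM": 0.035, "NWM": 0.045, "LV": 0.025})
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.base_ventricle_radius_vox < 1:
            raise ValueError("base_ventricle_radius_vox must be >= 1")
        if any(sd < 0 for sd in self.tissue_sds.values()):
            raise ValueError("tissue_sds must be nonnegative")
        means = [self.tissue_means[k] for k in ("WM", "NWM", "LV")]
        if len(set(means)) != 3:
            raise ValueError("WM, NWM, LV intensity means must be pairwise distinct")
        # the oldest allowed subject's ventricles must fit inside the WM core;
        # checked exactly on the voxel grid
        if not _lv_fits(self, self.age_max):
            r_max = self.ventricle_radius(self.age_max)
            raise ValueError(
                f"ventricle radius {r_max:.2f} vox at age {self.age_max} does not fit "
                "inside the white-matter core")

    def ventricle_radius(self, ca: float) -> float:
        """LV radius (voxels) implied by chronological age ``ca``."""
        return self.base_ventricle_radius_vox + \
            self.ventricle_growth_vox_per_year * max(ca - self.age_min, 0.0)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    ca: float

    def __post_init__(self):
        if not np.isfinite(self.ca) or self.ca <= 0:
            raise ValueError(f"chronological age must be finite and positive, got {self.ca}")


@dataclass
class IntensityVolume:
    """Cubic scalar volume with isotropic voxel size in millimetres."""

    data: np.ndarray
    voxel_mm: float = 2.0

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or len(set(d.shape)) != 1:
            raise ValueError(f"intensity volume must be cubic 3D, got shape {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("intensity volume contains non-finite values")
        self.data = d


@dataclass
class LabelVolume:
    data: np.ndarray
    label_map: Dict[str, int] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self):
        d = np.asarray(self.data)
        if not np.issubdtype(d.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if d.ndim != 3 or len(set(d.shape)) != 1:
            raise ValueError(f"label volume must be cubic 3D, got shape {d.shape}")
        self.data = d

    def mask(self, name: str) -> np.ndarray:
        return self.data == self.label_map[name]


def _ellipsoid_mask(shape: Tuple[int, int, int], center: np.ndarray,
                    semi_axes: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _geometry(params: PhantomParams, ca: float):
    """Brain/WM/LV masks of a phantom at age ``ca`` (no intensities)."""
    n = params.grid_size
    shape = (n, n, n)
    center = np.array([n / 2.0 - 0.5] * 3)
    brain_semi = np.array([params.brain_radius_frac * (n / 2.0) * a
                           for a in _BRAIN_ANISOTROPY])
    wm_semi = brain_semi * _WM_FRACTION
    r = params.ventricle_radius(ca)
    offset = _LV_CENTER_OFFSET_FRAC * wm_semi[0]
    lv_semi = np.array([r, 1.3 * r, r])  # mildly elongated along y, like real LVs
    brain = _ellipsoid_mask(shape, center, brain_semi)
    wm = _ellipsoid_mask(shape, center, wm_semi)
    lv = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = center + np.array([side * offset, 0.0, 0.0])
        lv |= _ellipsoid_mask(shape, c, lv_semi)
    return brain, wm, lv


def _lv_fits(params: PhantomParams, ca: float) -> bool:
    _, wm, lv = _geometry(params, ca)
    return lv.any() and not (lv & ~wm).any()


def generate_phantom(record: SubjectRecord, params: PhantomParams,
                     rng: np.random.Generator) -> Tuple[IntensityVolume, LabelVolume]:
    """Build one age-encoded phantom.

    Deterministic given ``(record, params)`` and the generator state.
    Raises a geometry error when the age-implied ventricle would leave the
    white-matter core.
    """
    brain, wm, lv = _geometry(params, record.ca)
    if (lv & ~wm).any():
        raise ValueError(
            f"subject {record.subject_id}: ventricle at age {record.ca:.1f} "
            "exceeds the white-matter core")
    n = params.grid_size
    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[brain] = LABELS["NWM"]
    labels[wm] = LABELS["WM"]
    labels[lv] = LABELS["LV"]
    if not (labels == LABELS["LV"]).any():
        raise ValueError("degenerate geometry: empty ventricle region")

    intensity = np.zeros((n, n, n))
    for name in ("WM", "NWM", "LV"):
        m = labels == LABELS[name]
        intensity[m] = np.clip(
            rng.normal(params.tissue_means[name], params.tissue_sds[name], m.sum()),
            0.0, None)
    return (IntensityVolume(intensity, params.voxel_mm),
            LabelVolume(labels, dict(LABELS)))


def generate_cohort(n: int, age_low: float, age_high: float, params: PhantomParams,
                    rng: np.random.Generator
                    ) -> List[Tuple[SubjectRecord, IntensityVolume, LabelVolume]]:
    """Draw ``n`` subjects with ages uniform on [age_low, age_high] and
    build their phantoms. Reproducible under the generator's seed."""
    if n < 0:
        raise ValueError("cohort size must be nonnegative")
    if not age_low < age_high:
        raise ValueError("age_low must be < age_high")
    ages = rng.uniform(age_low, age_high, size=n)
    out = []
    for i, ca in enumerate(ages):
        rec = SubjectRecord(subject_id=f"sub-{i:04d}", ca=float(ca))
        vol, lab = generate_phantom(rec, params, rng)
        out.append((rec, vol, lab))
    return out


# ---------------------------------------------------------------------------
# disk interface (NIfTI-1 volumes + CSV manifest)
# ---------------------------------------------------------------------------

def save_cohort(cohort, out_dir: Path, params: PhantomParams) -> "Path":
    """Write intensity/label NIfTI pairs plus a CSV manifest; returns the
    manifest path."""
    import pandas as pd

    from .io import save_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, vol, lab in cohort:
        ipath = out_dir / f"{rec.subject_id}_T1.nii.gz"
        lpath = out_dir / f"{rec.subject_id}_labels.nii.gz"
        save_volume(vol.data, ipath, voxel_mm=vol.voxel_mm)
        save_volume(lab.data, lpath, voxel_mm=vol.voxel_mm, integer=True)
        rows.append({"subject_id": rec.subject_id, "ca": rec.ca,
                     "intensity_path": ipath.name, "label_path": lpath.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (out_dir / "phantom_params.json").write_text(_params_json(params))
    return manifest


def _params_json(params: PhantomParams) -> str:
    import json
    return json.dumps(dataclasses.asdict(params), indent=2)


def load_cohort(manifest_path: Path):
    """Read a cohort written by :func:`save_cohort`."""
    import pandas as pd

    from .io import load_volume

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    out = []
    for row in df.itertuples():
        data, voxel_mm = load_volume(base / row.intensity_path)
        ldata, _ = load_volume(base / row.label_path)
        out.append((SubjectRecord(str(row.subject_id), float(row.ca)),
                    IntensityVolume(data, voxel_mm),
                    LabelVolume(np.asarray(np.rint(ldata), dtype=np.int16))))
    return out
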