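"""End-to-end experiment stages (the library behind the CLI).

Stages communicate through a working directory::

    work/
      cohort/        phantom NIfTI volumes + manifest.csv (with split column)
      perturbed/     dilated volumes, per-subject JSON ledgers,
                     ground_truth.nii.gz, fixation.nii.gz
      models/        checkpoints (model_d.npz / model_nd.npz) + history CSV
      saliency/      per-method cohort-mean saliency maps (NIfTI + sidecar)
      reports/       similarity report CSV/JSON

Every stage derives its randomness from the master seed and a fixed
stage tag, so each stage — and each subject within a stage — is
reproducible independently of execution order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import attribution as attr
from . import bamodel, perturb, phantom, simmetrics
from .config import ExperimentConfig
from .io import load_volume, save_volume

__all__ = [
    "simulate",
    "perturb_cohort",
    "train_model",
    "attribute",
    "evaluate",
    "run_all",
]

# stage tags for seed fan-out
_STAGE = {"phantom": 1, "perturb": 2, "train": 3, "attribute": 4}


def _stage_rng(config: ExperimentConfig, stage: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _STAGE[stage], *extra]))


def assign_splits(n: int, fractions: Tuple[float, float, float],
                  rng: np.random.Generator) -> List[str]:
    """Random, disjoint train/val/test assignment covering all subjects."""
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    order = rng.permutation(n)
    out = [""] * n
    for pos, lab in zip(order, labels):
        out[pos] = lab
    return out


def simulate(config: ExperimentConfig, work_dir: Path, force: bool = False) -> Path:
    """Generate the phantom cohort with split assignment; returns the
    manifest path."""
    out_dir = Path(work_dir) / "cohort"
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force to overwrite)")
    rng = _stage_rng(config, "phantom")
    cohort = phantom.generate_cohort(config.n_subjects, config.age_low,
                                     config.age_high, config.phantom, rng)
    manifest = phantom.save_cohort(cohort, out_dir, config.phantom)
    df = pd.read_csv(manifest)
    df["split"] = assign_splits(len(df), config.split_fractions,
                                _stage_rng(config, "phantom", 99))
    df.to_csv(manifest, index=False)
    return manifest


def _load_cohort_frame(work_dir: Path) -> pd.DataFrame:
    manifest = Path(work_dir) / "cohort" / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest}; run simulate first")
    return pd.read_csv(manifest)


def _subject_volume(work_dir: Path, row, perturbed: bool) -> np.ndarray:
    base = Path(work_dir) / ("perturbed" if perturbed else "cohort")
    name = f"{row.subject_id}_T1_dilated.nii.gz" if perturbed else row.intensity_path
    data, _ = load_volume(base / name)
    return data


def perturb_cohort(config: ExperimentConfig, work_dir: Path) -> Path:
    """Dilate every subject's ventricles in proportion to age; write the
    perturbed volumes, per-subject ledgers, and the cohort ground-truth
    and fixation maps."""
    df = _load_cohort_frame(work_dir)
    cohort_dir = Path(work_dir) / "cohort"
    out_dir = Path(work_dir) / "perturbed"
    out_dir.mkdir(parents=True, exist_ok=True)
    cas = df["ca"].to_numpy()
    pairs = []
    for i, row in enumerate(df.itertuples()):
        vol_data, voxel_mm = load_volume(cohort_dir / row.intensity_path)
        lab_data, _ = load_volume(cohort_dir / row.label_path)
        vol = phantom.IntensityVolume(vol_data, voxel_mm)
        lab = phantom.LabelVolume(np.asarray(np.rint(lab_data), dtype=np.int16))
        coeff = perturb.dilation_coefficient(row.ca, cas)
        rng = _stage_rng(config, "perturb", i)
        result = perturb.dilate_ventricles(vol, lab, coeff, rng)
        save_volume(result.perturbed.data, out_dir / f"{row.subject_id}_T1_dilated.nii.gz",
                    voxel_mm=voxel_mm)
        ledger = {"subject_id": row.subject_id, "ca": float(row.ca),
                  "coefficient": coeff,
                  "n_replaced": len(result.replaced_voxels),
                  "n_peripheric": len(result.peripheric_voxels),
                  "seed": [config.seed, _STAGE["perturb"], i]}
        (out_dir / f"{row.subject_id}_ledger.json").write_text(json.dumps(ledger, indent=2))
        pairs.append((vol, result.perturbed))
    gt = perturb.build_ground_truth(pairs)
    fixation = perturb.binarize_fixation(gt)
    save_volume(gt.data, out_dir / "ground_truth.nii.gz", voxel_mm=config.phantom.voxel_mm)
    save_volume(fixation.data.astype(np.int16), out_dir / "fixation.nii.gz",
                voxel_mm=config.phantom.voxel_mm, integer=True)
    return out_dir


def _split_arrays(config: ExperimentConfig, work_dir: Path, split: str,
                  dilated: bool) -> Tuple[np.ndarray, np.ndarray]:
    df = _load_cohort_frame(work_dir)
    sub = df[df["split"] == split]
    if sub.empty:
        raise ValueError(f"no subjects in split {split!r}")
    X = np.stack([_subject_volume(work_dir, row, dilated) for row in sub.itertuples()])
    return X, sub["ca"].to_numpy(dtype=float)


def train_model(config: ExperimentConfig, work_dir: Path, dilated: bool
                ) -> Tuple[Path, bamodel.TrainingHistory]:
    """Train the age regressor on the dilated (M_D analogue) or original
    (M_ND analogue) volumes of the train/val splits."""
    Xtr, ytr = _split_arrays(config, work_dir, "train", dilated)
    Xva, yva = _split_arrays(config, work_dir, "val", dilated)
    model = bamodel.build_model(config.cnn)
    model, history = bamodel.train(model, (Xtr, ytr), (Xva, yva), config.cnn)
    tag = "d" if dilated else "nd"
    out_dir = Path(work_dir) / "models"
    ckpt = bamodel.save_checkpoint(model, config.cnn, out_dir / f"model_{tag}.npz")
    history.to_csv(out_dir / f"history_{tag}.csv")
    return ckpt, history


def attribute(config: ExperimentConfig, work_dir: Path, checkpoint: Path,
              methods: Sequence[str] = attr.METHODS, dilated: bool = True
              ) -> Dict[str, simmetrics.SaliencyMap]:
    """Per-method cohort-mean saliency densities over the test split."""
    for m in methods:
        if m not in attr.METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {attr.METHODS}")
    model, _ = bamodel.load_checkpoint(checkpoint)
    df = _load_cohort_frame(work_dir)
    test = df[df["split"] == "test"]
    if test.empty:
        raise ValueError("no subjects in the test split")
    train_rows = df[df["split"] == "train"].head(10)
    baseline_pool = [_subject_volume(work_dir, row, dilated)
                     for row in train_rows.itertuples()]
    out_dir = Path(work_dir) / "saliency"
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = config.attribution
    mean_maps: Dict[str, simmetrics.SaliencyMap] = {}
    for method in methods:
        per_subject = []
        for j, row in enumerate(test.itertuples()):
            x = _subject_volume(work_dir, row, dilated)
            local_opts = attr.AttributionOptions(
                ig_points=opts.ig_points, gshap_samples=opts.gshap_samples,
                gshap_sigma=opts.gshap_sigma,
                seed=int(np.random.default_rng(
                    np.random.SeedSequence([config.seed, _STAGE["attribute"], j])
                ).integers(2 ** 31)))
            raw = attr.compute_attribution(method, model, x, local_opts,
                                           baselines=baseline_pool or None)
            per_subject.append(simmetrics.normalize_saliency(raw))
        mean_map = simmetrics.cohort_mean_map(per_subject)
        mean_maps[method] = mean_map
        save_volume(mean_map.data, out_dir / f"saliency_{method}.nii.gz",
                    voxel_mm=config.phantom.voxel_mm)
        sidecar = {"method": method, "n_subjects": len(per_subject),
                   "options": {"ig_points": opts.ig_points,
                               "gshap_samples": opts.gshap_samples,
                               "gshap_sigma": opts.gshap_sigma},
                   "seed": config.seed, "dilated_inputs": dilated}
        (out_dir / f"saliency_{method}.json").write_text(json.dumps(sidecar, indent=2))
    return mean_maps


def evaluate(config: ExperimentConfig, work_dir: Path,
             maps: Optional[Dict[str, simmetrics.SaliencyMap]] = None
             ) -> simmetrics.SimilarityReport:
    """Score each method's cohort-mean map against the ground truth and
    report percent differences vs the MG baseline."""
    pert_dir = Path(work_dir) / "perturbed"
    gt_data, _ = load_volume(pert_dir / "ground_truth.nii.gz")
    gt = perturb.GroundTruthMap(np.clip(gt_data, 0, None))
    fixation = perturb.binarize_fixation(gt)
    if maps is None:
        sal_dir = Path(work_dir) / "saliency"
        maps = {}
        for path in sorted(sal_dir.glob("saliency_*.nii.gz")):
            method = path.name[len("saliency_"):-len(".nii.gz")]
            data, _ = load_volume(path)
            data = np.clip(data, 0, None)
            maps[method] = simmetrics.SaliencyMap(data / data.sum(), method)
    if not maps:
        raise ValueError("no saliency maps to evaluate")
    for method, smap in maps.items():
        if smap.data.shape != gt.data.shape:
            raise ValueError(f"{method}: map shape {smap.data.shape} != "
                             f"ground truth {gt.data.shape}")
    scores = {m: simmetrics.score_method(s, gt, fixation, nmi_bins=config.nmi_bins)
              for m, s in maps.items()}
    baseline = "MG" if "MG" in scores else next(iter(scores))
    report = simmetrics.percent_diff_vs_baseline(scores, baseline)
    report.provenance = {"seed": config.seed, "n_subjects": config.n_subjects,
                         "grid_size": config.phantom.grid_size}
    out_dir = Path(work_dir) / "reports"
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(out_dir / "similarity_report.csv")
    report.to_json(out_dir / "similarity_report.json")
    return report


def run_all(config: ExperimentConfig, work_dir: Path,
            methods: Sequence[str] = attr.METHODS, dilated: bool = True,
            force: bool = False) -> simmetrics.SimilarityReport:
    """simulate → perturb → train → attribute → evaluate in one call."""
    simulate(config, work_dir, force=force)
    perturb_cohort(config, work_dir)
    ckpt, _ = train_model(config, work_dir, dilated=dilated)
    maps = attribute(config, work_dir, ckpt, methods=methods, dilated=dilated)
    return evaluate(config, work_dir, maps)
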