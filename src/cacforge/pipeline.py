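"""End-to-end orchestration: phantoms -> ROI -> decomposition -> scores -> stats.

The package's full analysis chain, as one would run it on a cohort:

1. resample every volume to the standard analysis grid (1.0 mm in-plane,
   1.5 mm slices);
2. segment the heart and select CAC-containing axial slices;
3. decompose positive slices into calcium-free image + CAC-map;
4. score: threshold-free pseudomass from the map route on CTAC-like
   scans, clinical 130 HU Agatston scoring on the CSCT-like reference;
5. calibrate the continuous risk score on a held-out training subset and
   assign five-category risk;
6. compute the agreement statistics between CTAC and CSCT scores.

``demo()`` runs a small, fully seeded version of this chain and returns
a JSON-serializable report; with fixed seeds it is deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import decomposition as dec
from . import evalstats, phantom, roi, scoring
from .volume import CTVolume, STANDARD_SPACING, resample, resample_mask
from .volume import _resample_array  # linear resampling for additive truth fields

#: a slice counts as containing visible calcium when the (noise-free)
#: inserted-HU field on the analysis grid reaches this value...
VISIBLE_CAC_HU = 50.0
#: ...and as confidently calcium-free below this value; slices in between
#: are ambiguous and excluded from classifier/decomposition training
CLEAN_CAC_HU = 10.0


@dataclass
class PreparedCase:
    """A phantom case resampled to the standard analysis grid."""

    case_id: str
    csct: CTVolume
    ctac_rest: CTVolume
    ctac_stress: CTVolume
    heart_csct: np.ndarray
    heart_ctac: np.ndarray
    inserted_csct: np.ndarray  # float HU, truth calcium signal per voxel
    inserted_ctac: np.ndarray
    true_pseudomass: float
    true_agatston: float


def prepare_case(case: phantom.PhantomCase) -> PreparedCase:
    """Resample a phantom case and its truth fields to the analysis grid."""
    csct = resample(case.csct, STANDARD_SPACING)
    ctac_rest = resample(case.ctac_rest, STANDARD_SPACING)
    ctac_stress = resample(case.ctac_stress, STANDARD_SPACING)
    heart_csct = resample_mask(case.heart_mask_csct, case.csct.spacing, STANDARD_SPACING)
    heart_ctac = resample_mask(case.heart_mask_ctac, case.ctac_rest.spacing, STANDARD_SPACING)
    inserted_csct = _resample_array(
        case.inserted_hu_csct.astype(np.float32), case.csct.spacing, STANDARD_SPACING, order=1
    )
    inserted_ctac = _resample_array(
        case.inserted_hu_ctac.astype(np.float32), case.ctac_rest.spacing, STANDARD_SPACING, order=1
    )
    truth = phantom.true_scores(case)
    return PreparedCase(
        case_id=case.case_id,
        csct=csct,
        ctac_rest=ctac_rest,
        ctac_stress=ctac_stress,
        heart_csct=heart_csct,
        heart_ctac=heart_ctac,
        inserted_csct=inserted_csct,
        inserted_ctac=inserted_ctac,
        true_pseudomass=truth.pseudomass,
        true_agatston=truth.agatston,
    )


def truth_slice_labels(inserted: np.ndarray):
    """Per-slice truth: (positive, ambiguous) bool arrays from the inserted field."""
    peak = np.asarray(inserted).max(axis=(1, 2))
    positive = peak >= VISIBLE_CAC_HU
    ambiguous = (peak >= CLEAN_CAC_HU) & ~positive
    return positive, ambiguous


def ctac_volume(prep: PreparedCase, condition: str) -> CTVolume:
    if condition == "rest":
        return prep.ctac_rest
    if condition == "stress":
        return prep.ctac_stress
    raise ValueError(f"condition must be 'rest' or 'stress', got {condition!r}")


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------

def build_decomposition_domains(prepared, condition: str = "rest", crop: int = 64):
    """Heart-cropped normalized slices split into CAC / noCAC domains.

    Ambiguous slices (faint truth signal) belong to neither domain,
    mirroring how an annotator would only label confident slices.
    """
    cac, nocac = [], []
    for prep in prepared:
        vol = ctac_volume(prep, condition)
        crops, _ = roi.heart_crop_slices(vol, prep.heart_ctac, crop=crop, window=dec.DEC_HU_WINDOW)
        positive, ambiguous = truth_slice_labels(prep.inserted_ctac)
        in_heart = prep.heart_ctac.any(axis=(1, 2))
        for z in range(len(crops)):
            if not in_heart[z]:
                continue
            if positive[z]:
                cac.append(crops[z])
            elif not ambiguous[z]:
                nocac.append(crops[z])
    return np.array(cac, dtype=np.float32), np.array(nocac, dtype=np.float32)


def build_classifier_training(prepared, condition: str = "rest", crop: int = 64):
    """(slices, labels) for the slice classifier, ambiguous slices dropped."""
    xs, ys = [], []
    for prep in prepared:
        vol = ctac_volume(prep, condition)
        crops, _ = roi.heart_crop_slices(vol, prep.heart_ctac, crop=crop, window=roi.ROI_HU_WINDOW)
        positive, ambiguous = truth_slice_labels(prep.inserted_ctac)
        in_heart = prep.heart_ctac.any(axis=(1, 2))
        keep = in_heart & ~ambiguous
        xs.append(crops[keep])
        ys.append(positive[keep])
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# Quantification + evaluation
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved settings for a quantification run (all tunables explicit)."""

    seed: int = 0
    condition: str = "rest"
    map_floor_hu: float = 30.0
    min_area_mm2: float = 1.0
    slice_threshold: float = 0.5
    use_truth_heart: bool = False  # bypass the segmenter (ablation/debug)
    include_double_zero: bool = True

    def to_dict(self):
        return asdict(self)


@dataclass
class TrainedModels:
    heart: "roi.HeartSegmenter"
    slices: "roi.SliceClassifier"
    decomp: "dec.DecompositionModel"


def quantify_case(
    prep: PreparedCase,
    models: TrainedModels,
    config: RunConfig,
) -> scoring.CalciumScore:
    """Threshold-free calcium score of one CTAC-like volume."""
    vol = ctac_volume(prep, config.condition)
    if config.use_truth_heart:
        heart = prep.heart_ctac
    else:
        heart = roi.segment_heart(vol, models.heart)
    labels = roi.classify_slices(vol, heart, models.slices)
    labels.threshold = config.slice_threshold
    cac_map = dec.decompose_volume(vol, heart, labels, models.decomp)
    return scoring.score_volume(
        vol, heart, cac_map=cac_map,
        map_floor_hu=config.map_floor_hu, min_area_mm2=config.min_area_mm2,
    )


def score_reference(prep: PreparedCase, config: RunConfig) -> scoring.CalciumScore:
    """Clinical threshold scoring of the CSCT-like reference volume."""
    return scoring.score_volume(
        prep.csct, prep.heart_csct, cac_map=None, min_area_mm2=config.min_area_mm2
    )


def run_quantification(prepared, models: TrainedModels, config: RunConfig) -> pd.DataFrame:
    """Score a cohort; returns one row per case with CTAC and CSCT scores."""
    rows = []
    for prep in prepared:
        auto = quantify_case(prep, models, config)
        ref = score_reference(prep, config)
        rows.append(
            {
                "case_id": prep.case_id,
                "condition": config.condition,
                "ctac_pseudomass": auto.pseudomass,
                "ctac_volume": auto.volume,
                "csct_pseudomass": ref.pseudomass,
                "csct_agatston": ref.agatston,
                "true_pseudomass": prep.true_pseudomass,
                "true_agatston": prep.true_agatston,
            }
        )
    return pd.DataFrame(rows)


def run_evaluation(
    table: pd.DataFrame,
    params: scoring.CalibrationParams,
    config: RunConfig,
) -> evalstats.AgreementReport:
    """Agreement statistics of CTAC quantification against the CSCT reference."""
    pairs = [
        evalstats.ScorePair(
            patient_id=row.case_id,
            ctac_score=row.ctac_pseudomass,
            csct_score=row.csct_pseudomass,
            condition=config.condition,
        )
        for row in table.itertuples()
    ]
    cats_auto = [
        scoring.risk_category(row.ctac_pseudomass, params).category
        for row in table.itertuples()
    ]
    cats_ref = [
        scoring.categorize_agatston(row.csct_agatston).category for row in table.itertuples()
    ]
    return evalstats.agreement_report(
        pairs, cats_ctac=cats_auto, cats_csct=cats_ref, condition=config.condition
    )


# ---------------------------------------------------------------------------
# Held-out recovery measurements (phantom experiments)
# ---------------------------------------------------------------------------

def decomposition_recovery(
    model, prepared, condition: str = "rest", map_floor_hu: float = 30.0
) -> dict:
    """Per-slice CAC-map mass vs. true inserted mass on held-out cases.

    Uses truth heart masks and truth slice labels so that only the
    decomposition quality is measured. Map mass counts voxels at or
    above ``map_floor_hu`` — the same noise floor the scoring route uses
    to define the CAC area (sub-floor map values are diffuse background
    the pipeline never scores). Returns Pearson r over lesion slices,
    the clean/lesion mean-mass ratio, and the slice counts.
    """
    voxvol = float(np.prod(STANDARD_SPACING))
    map_mass, true_mass, clean_mass = [], [], []
    for prep in prepared:
        vol = ctac_volume(prep, condition)
        crops, _ = roi.heart_crop_slices(
            vol, prep.heart_ctac, crop=model.config.crop, window=dec.DEC_HU_WINDOW
        )
        positive, ambiguous = truth_slice_labels(prep.inserted_ctac)
        in_heart = prep.heart_ctac.any(axis=(1, 2))
        for z in range(len(crops)):
            if not in_heart[z]:
                continue
            _, cac_map = dec.remove_cac(crops[z], model)
            map_hu = cac_map * dec.MAP_SCALE_HU
            mass = float(map_hu[map_hu >= map_floor_hu].sum()) * voxvol
            if positive[z]:
                map_mass.append(mass)
                true_mass.append(float(prep.inserted_ctac[z].sum()) * voxvol)
            elif not ambiguous[z]:
                clean_mass.append(mass)
    map_mass = np.array(map_mass)
    true_mass = np.array(true_mass)
    r = float(np.corrcoef(map_mass, true_mass)[0, 1]) if len(map_mass) > 2 else float("nan")
    lesion_mean = float(map_mass.mean()) if len(map_mass) else float("nan")
    clean_mean = float(np.mean(clean_mass)) if clean_mass else 0.0
    return {
        "pearson_r": r,
        "clean_lesion_mass_ratio": clean_mean / lesion_mean if lesion_mean else float("nan"),
        "n_lesion_slices": int(len(map_mass)),
        "n_clean_slices": int(len(clean_mass)),
        "lesion_slice_mean_mass": lesion_mean,
        "clean_slice_mean_mass": clean_mean,
    }


def roi_recovery(heart_model, slice_model, prepared, condition: str = "rest") -> dict:
    """Held-out heart Dice and slice-classification accuracy/recall."""
    dices, correct, total, tp, pos_total = [], 0, 0, 0, 0
    for prep in prepared:
        vol = ctac_volume(prep, condition)
        mask = roi.segment_heart(vol, heart_model)
        truth = prep.heart_ctac
        dices.append(2 * np.sum(mask & truth) / (mask.sum() + truth.sum()))
        labels = roi.classify_slices(vol, truth, slice_model)
        positive, ambiguous = truth_slice_labels(prep.inserted_ctac)
        keep = truth.any(axis=(1, 2)) & ~ambiguous
        correct += int(np.sum(labels.positive[keep] == positive[keep]))
        total += int(keep.sum())
        tp += int(np.sum(labels.positive[keep] & positive[keep]))
        pos_total += int(positive[keep].sum())
    return {
        "mean_dice": float(np.mean(dices)),
        "min_dice": float(np.min(dices)),
        "slice_accuracy": correct / total if total else float("nan"),
        "slice_recall": tp / pos_total if pos_total else float("nan"),
        "n_slices": total,
    }


# ---------------------------------------------------------------------------
# Demo
# ---------------------------------------------------------------------------

@dataclass
class DemoConfig:
    seed: int = 20
    n_train: int = 6
    n_test: int = 6
    seg_steps: int = 120
    cls_steps: int = 300
    gan_iterations: int = 1000
    gan_lr: float = 3e-4
    gan_channels: int = 8
    condition: str = "rest"


def _limit_blas_threads():
    """Single-thread BLAS for bit-reproducible linear algebra."""
    try:
        from threadpoolctl import threadpool_limits

        return threadpool_limits(limits=1)
    except ImportError:  # pragma: no cover
        import contextlib

        return contextlib.nullcontext()


def demo(config: DemoConfig | None = None) -> dict:
    """Seeded end-to-end run on a small phantom cohort.

    Returns a flat JSON-serializable report with the demo's headline
    numbers (per-scan scores, reproducibility and agreement statistics).
    Identical configuration and seeds give an identical report.
    """
    cfg = config or DemoConfig()
    with _limit_blas_threads():
        return _demo_inner(cfg)


def _demo_inner(cfg: DemoConfig) -> dict:
    train_cases = phantom.generate_cohort(cfg.n_train, seed=cfg.seed, lesion_rate=(1, 4))
    test_cases = phantom.generate_cohort(cfg.n_test, seed=cfg.seed + 1, lesion_rate=(0, 4))
    train = [prepare_case(c) for c in train_cases]
    test = [prepare_case(c) for c in test_cases]

    # ROI networks
    seg_data = [(p.ctac_rest, p.heart_ctac) for p in train]
    seg = roi.train_heart_segmenter(
        seg_data, roi.SegConfig(steps=cfg.seg_steps, seed=cfg.seed)
    )
    cls_x, cls_y = build_classifier_training(train, cfg.condition)
    cls = roi.train_slice_classifier(
        cls_x, cls_y, roi.ClsConfig(steps=cfg.cls_steps, seed=cfg.seed)
    )

    # decomposition
    cac_sl, nocac_sl = build_decomposition_domains(train, cfg.condition)
    gan = dec.train_cyclegan(
        cac_sl,
        nocac_sl,
        dec.CycleGANConfig(
            iterations=cfg.gan_iterations, lr=cfg.gan_lr,
            channels=cfg.gan_channels, seed=cfg.seed,
        ),
    )
    models = TrainedModels(heart=seg, slices=cls, decomp=gan)

    run_cfg = RunConfig(seed=cfg.seed, condition=cfg.condition)
    train_table = run_quantification(train, models, run_cfg)

    # calibrate the risk formula on the training cohort (positive pairs only)
    mask = (train_table.ctac_pseudomass > 0) & (train_table.csct_agatston > 0)
    cal_masses = train_table.ctac_pseudomass[mask].to_numpy()
    cal_cats = [
        scoring.categorize_agatston(a).category
        for a in train_table.csct_agatston[mask]
    ]
    params, cal_rss = scoring.calibrate(cal_masses, cal_cats, condition=cfg.condition)

    test_table = run_quantification(test, models, run_cfg)
    report_stats = run_evaluation(test_table, params, run_cfg)

    report = {
        "demo_seed": cfg.seed,
        "n_train": cfg.n_train,
        "n_test": cfg.n_test,
        "condition": cfg.condition,
        "calibration_alpha": params.alpha,
        "calibration_delta": params.delta,
        "calibration_rss": cal_rss,
        "per_case_ctac_pseudomass": test_table.ctac_pseudomass.tolist(),
        "per_case_csct_pseudomass": test_table.csct_pseudomass.tolist(),
        "per_case_true_pseudomass": test_table.true_pseudomass.tolist(),
    }
    report.update({f"eval_{k}": v for k, v in report_stats.to_dict().items()})
    report["provenance_config_hash"] = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
    return report
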