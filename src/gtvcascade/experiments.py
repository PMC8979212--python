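"""Desk-scale reference experiments on seeded phantom cohorts.

These functions bundle the package's end-to-end study conditions so that the
test suite and reproduction scripts run exactly the same computation: a
preprocessing-recovery study (neck localization, bed exclusion, resampling,
normalization) and a scaled-down two-stage training/evaluation study with
the tiny network configuration (3 levels, base width 8, 64x64x32 / 48x32x16
patches).  Every function is deterministic in its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import (ROIBox, assemble, binarize_and_restore, locate_center,
                      sliding_window_infer, stage2_infer)
from .config import PipelineConfig
from .metrics import CaseReport, evaluate_case
from .phantom import PhantomSpec, generate_cohort
from .preprocessing import (compute_foreground_stats, extract_body_mask,
                            find_neck_index, normalize, preprocess_case)
from .training import train_cascade

__all__ = ["PreprocessingRecovery", "run_preprocessing_recovery",
           "DeskExperiment", "run_desk_experiment"]


@dataclass
class PreprocessingRecovery:
    neck_errors: list[int]
    bed_voxels_in_mask: int
    total_bed_voxels: int
    resampled_spacing: tuple[float, float, float]
    normalized_mean: float
    normalized_std: float
    n_cases: int


def run_preprocessing_recovery(seed: int, n: int = 20) -> PreprocessingRecovery:
    """Recover known phantom geometry through the preprocessing chain.

    Phantoms are rendered at a spacing away from the working target so the
    resampling step is exercised for real; neck localization error, bed-rail
    leakage into the body mask, the exactness of the target spacing and the
    pooled normalized foreground statistics are measured.
    """
    spec = PhantomSpec.desk(spacing=(1.1, 1.1, 2.7))
    target = (0.952, 0.952, 3.0)
    cohort = generate_cohort(spec, n, seed)

    neck_errors = []
    bed_in_mask = 0
    total_bed = 0
    vols, bodies = [], []
    spacing_seen = None
    for case in cohort:
        body = extract_body_mask(case.volume)
        bed_in_mask += int((body.data.astype(bool) & case.truth["bed"]).sum())
        total_bed += int(case.truth["bed"].sum())
        neck = find_neck_index(body)
        neck_errors.append(abs(neck - case.truth["neck_slice"]))
        vol, body_r, _ = preprocess_case(case.volume, target, gt=case.gt)
        spacing_seen = vol.spacing
        vols.append(vol)
        bodies.append(body_r)

    stats = compute_foreground_stats(vols, bodies)
    pooled = np.concatenate([
        v.first_channel[b.data.astype(bool)]
        for v, b in ((normalize(v, stats), b) for v, b in zip(vols, bodies))
    ]).astype(np.float64)
    return PreprocessingRecovery(
        neck_errors=neck_errors,
        bed_voxels_in_mask=bed_in_mask,
        total_bed_voxels=total_bed,
        resampled_spacing=spacing_seen,
        normalized_mean=float(pooled.mean()),
        normalized_std=float(pooled.std()),
        n_cases=n,
    )


@dataclass
class DeskExperiment:
    cascade_reports: list[CaseReport]
    stage1_reports: list[CaseReport]
    crop_containment: list[float]
    model_log: dict = field(default_factory=dict)
    n_train: int = 0
    config: PipelineConfig | None = None

    @property
    def cascade_median_dsc(self) -> float:
        return float(np.median([r.dsc for r in self.cascade_reports]))

    @property
    def stage1_median_dsc(self) -> float:
        return float(np.median([r.dsc for r in self.stage1_reports]))

    @property
    def containment_hits(self) -> int:
        return sum(c >= 0.95 for c in self.crop_containment)


def _split_predictions(model, case, cfg):
    """One test case: cascade mask, stage-1-only mask, ROI containment."""
    vol, _, gt_pre = preprocess_case(case.volume, cfg.target_spacing,
                                     cfg.hu_threshold, gt=case.gt)
    voln = normalize(vol, model.stats)
    s1 = sliding_window_infer(model.stage1, voln, cfg.stage1_patch, cfg.stage1_stride)
    stage1_mask = binarize_and_restore(s1, cfg.final_threshold, voln.meta)
    try:
        center = locate_center(s1)
    except ValueError:
        empty = np.zeros(tuple(voln.meta["original_shape"]), np.uint8)
        from .grids import BinaryMask
        return (BinaryMask(empty, case.volume.spacing), stage1_mask, 0.0)
    roi = ROIBox(center, cfg.stage2_patch)
    # fraction of (preprocessed-grid) gt voxels inside the fine-stage crop
    idx = np.argwhere(gt_pre.data)
    inside = np.ones(len(idx), dtype=bool)
    for ax in range(3):
        inside &= (idx[:, ax] >= roi.start[ax]) & (idx[:, ax] < roi.end[ax])
    containment = float(inside.mean()) if len(idx) else 0.0
    s2 = stage2_infer(model.stage2, voln, roi)
    s = assemble(s1, s2, roi, cfg.assembly_weight)
    cascade_mask = binarize_and_restore(s, cfg.final_threshold, voln.meta)
    return cascade_mask, stage1_mask, containment


def run_desk_experiment(seed: int, n_train: int = 30, n_test: int = 10,
                        epochs: int = 12, spec: PhantomSpec | None = None,
                        use_augment: bool = True) -> DeskExperiment:
    """Scaled-down end-to-end study: train the tiny two-stage cascade on
    phantoms and evaluate it on held-out phantoms.

    Training and test cohorts come from disjoint seed streams.  Evaluation
    reports, per test case, the assembled-cascade metrics, the stage-1-only
    metrics (the cascade ablation) and the fraction of tumor voxels captured
    by the fine-stage crop placed at the stage-1 centroid.
    """
    spec = spec or PhantomSpec.desk()
    cfg = PipelineConfig.tiny(seed=seed, epochs=epochs, patches_per_case=1)
    train_cohort = generate_cohort(spec, n_train, seed)
    test_cohort = generate_cohort(spec, n_test, seed + 10_000)

    model = train_cascade([(c.volume, c.gt) for c in train_cohort], cfg,
                          seed=seed, epochs=epochs, use_augment=use_augment)

    cascade_reports, stage1_reports, containment = [], [], []
    for case in test_cohort:
        cas_mask, s1_mask, frac = _split_predictions(model, case, cfg)
        cascade_reports.append(evaluate_case(case.gt, cas_mask, case.case_id))
        stage1_reports.append(evaluate_case(case.gt, s1_mask, case.case_id))
        containment.append(frac)
    return DeskExperiment(cascade_reports=cascade_reports,
                          stage1_reports=stage1_reports,
                          crop_containment=containment,
                          model_log=model.log, n_train=n_train, config=cfg)
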