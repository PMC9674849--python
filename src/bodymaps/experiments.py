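"""Canonical validation studies for the pipeline.

These are the package's built-in checks that the whole chain — from
painting events to group statistics and classification — behaves as a
measurement instrument should: topographies planted in a synthetic
cohort are recovered (parameter recovery), the FDR correction is
calibrated under a sign-flip null, and the classifier sits at chance
when the labels carry no information.  The same experiments back the
test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassificationReport, build_feature_matrix, lda_crossval
from .pipeline import PipelineConfig, stage_seed
from .preprocess import build_cohort_bsms, rasterize_clicks
from .simulate import (
    CohortConfig,
    TopographyComponent,
    TopographySpec,
    default_topography_specs,
    simulate_cohort,
)
from .stats import fdr_threshold, group_maps_for_cohort, pixelwise_ttest
from .template import build_default_template

__all__ = [
    "recovery_experiment",
    "classification_experiment",
    "fdr_null_calibration",
    "demo_pipeline_config",
]

RECOVERY_REGIONS = ("head", "chest", "abdomen", "arms", "hands", "legs")


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class RecoveryResult:
    """Per-stimulus overlap between recovered and planted activations."""

    jaccard_by_stimulus: dict[str, float]

    @property
    def minimum(self) -> float:
        return min(self.jaccard_by_stimulus.values())

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.jaccard_by_stimulus.values())))


def recovery_experiment(
    seed: int,
    n_subjects: int = 100,
    amplitude: float = 2.0,
    noise_sd: float = 1.0,
    brush_radius: int = 2,
    sigma: float = 1.0,
    alpha: float = 0.05,
) -> RecoveryResult:
    """Parameter recovery: plant one flat activation region per stimulus
    and measure how well the FDR-significant activation pixels recover it.

    Conditions: 60x120 template, amplitude-to-noise ratio 2, paint
    threshold at half the amplitude, fine brush (radius 2) and light
    smoothing (sigma 1) so topographies stay spatially resolved.  The
    recovery target is the noiseless painted set — the planted region
    dilated by the brush disk and clipped to the mask — since a click
    painting a disk is part of the forward measurement.  Overlap is the
    Jaccard index between that set and the significant activation set
    (sig pixels with t > 0).
    """
    template = build_default_template(60, 120)
    specs = [
        TopographySpec(region, (TopographyComponent(region, 1, amplitude),))
        for region in RECOVERY_REGIONS
    ]
    config = CohortConfig(
        n_subjects=n_subjects,
        stimuli=RECOVERY_REGIONS,
        subject_noise_sd=noise_sd,
        paint_threshold=amplitude / 2.0,
        brush_radius=brush_radius,
        completion_prob=1.0,
        anomaly_rate=0.0,
        seed=seed,
    )
    cohort = simulate_cohort(template, specs, config)
    bsms = build_cohort_bsms(cohort, template, brush_radius, sigma)
    maps = group_maps_for_cohort(bsms, template, alpha=alpha, stimuli=list(RECOVERY_REGIONS))

    scores = {}
    for gm in maps:
        truth = cohort.truths[gm.stimulus]
        centers = np.argwhere(template.mask & (truth > config.paint_threshold))
        target = (rasterize_clicks(centers, brush_radius, template) > 0) & template.mask
        recovered = gm.sig_mask & (gm.t > 0)
        scores[gm.stimulus] = jaccard(recovered, target)
    return RecoveryResult(jaccard_by_stimulus=scores)


def classification_experiment(
    seed: int,
    n_subjects: int = 30,
    iterations: int = 20,
    permute_labels: bool = False,
    n_components: int = 30,
    folds: int = 5,
) -> ClassificationReport:
    """Complete classification of the default 20-stimulus synthetic cohort.

    Uses the default study conditions (noise sd 0.5, paint threshold
    0.5, brush radius 6, smoothing sigma 5, completion probability
    0.95).  ``permute_labels=True`` shuffles the stimulus labels before
    training — the negative control whose accuracy must sit at chance.
    """
    template = build_default_template(60, 120)
    config = CohortConfig(
        n_subjects=n_subjects,
        completion_prob=0.95,
        anomaly_rate=0.0,
        seed=stage_seed(seed, "classification-cohort"),
    )
    cohort = simulate_cohort(template, default_topography_specs(), config)
    bsms = build_cohort_bsms(cohort, template, config.brush_radius, 5.0)
    features = build_feature_matrix(bsms, template)
    if permute_labels:
        rng = np.random.default_rng(stage_seed(seed, "label-permutation"))
        features.labels = rng.permutation(features.labels)
    return lda_crossval(
        features,
        n_components=n_components,
        folds=folds,
        iterations=iterations,
        seed=stage_seed(seed, "classification-cv"),
    )


@dataclass
class FdrCalibrationResult:
    """Realized FDR under a sign-flip null across replicates."""

    mean_fdp: float  # mean of V / max(R, 1); all rejections are false
    rejection_rate: float  # fraction of replicates with any rejection
    mean_sig_fraction: float  # mean fraction of in-mask pixels declared sig
    n_replicates: int
    mc_error: float  # binomial MC standard error of mean_fdp


def fdr_null_calibration(
    seed: int,
    n_subjects: int = 16,
    n_replicates: int = 200,
    alpha: float = 0.05,
) -> FdrCalibrationResult:
    """Calibration of the BH correction under a sign-flip null.

    A base stack of subject maps (realistic spatial structure from the
    painting model) is made null by flipping each subject's sign with
    probability 1/2, which symmetrizes every pixel's distribution about
    zero.  Every rejection is then a false positive, so the mean false
    discovery proportion V/max(R,1) over replicates estimates the
    realized FDR, which BH bounds by alpha.
    """
    template = build_default_template(40, 80)
    spec = TopographySpec("head", (TopographyComponent("head", 1, 1.0),))
    config = CohortConfig(
        n_subjects=n_subjects,
        stimuli=("head",),
        subject_noise_sd=0.5,
        paint_threshold=0.5,
        brush_radius=3,
        completion_prob=1.0,
        seed=stage_seed(seed, "fdr-null-cohort"),
    )
    cohort = simulate_cohort(template, [spec], config)
    bsms = build_cohort_bsms(cohort, template, config.brush_radius, sigma=2.0)
    base = np.stack([b.values for b in bsms])

    rng = np.random.default_rng(stage_seed(seed, "fdr-null-flips"))
    fdps = np.empty(n_replicates)
    sig_fracs = np.empty(n_replicates)
    m = template.n_in_mask
    for i in range(n_replicates):
        signs = rng.choice((-1.0, 1.0), size=n_subjects)
        gm = pixelwise_ttest(base * signs[:, None, None], template, alpha=alpha)
        _, sig = fdr_threshold(gm.p, alpha=alpha, template=template)
        R = int(sig.sum())
        fdps[i] = 1.0 if R > 0 else 0.0  # under the global null V = R
        sig_fracs[i] = R / m
    mean_fdp = float(fdps.mean())
    return FdrCalibrationResult(
        mean_fdp=mean_fdp,
        rejection_rate=float((fdps > 0).mean()),
        mean_sig_fraction=float(sig_fracs.mean()),
        n_replicates=n_replicates,
        mc_error=float(np.sqrt(max(mean_fdp * (1 - mean_fdp), 1e-12) / n_replicates)),
    )


def demo_pipeline_config(seed: int, n_subjects: int = 12, iterations: int = 5) -> PipelineConfig:
    """A desk-scale configuration for full end-to-end runs."""
    return PipelineConfig(
        n_subjects=n_subjects,
        iterations=iterations,
        completion_prob=1.0,
        anomaly_rate=0.0,
        seed=seed,
    )
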