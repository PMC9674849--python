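"""Subject-level BSM reconstruction and quality control.

A subject's bodily sensation map (BSM) is rebuilt from raw painting
events in four steps: rasterize click centers with a disk brush (a
single mouse click covers several hundred pixels), smooth each panel
with a Gaussian kernel to encode spatial dependency, merge the two
panels into one signed map (activation positive, deactivation
negative), and mask responses outside the body.  Masking comes after
smoothing so paint bleeding over the outline is zeroed rather than
reflected back in.

Quality control mirrors the study design: subjects who complete too few
of their maps (count below mean - k*SD of the cohort, k = 2.5 by
default) are flagged for exclusion, and heuristic detectors flag
anomalous responders (symbol drawing, heavy out-of-body painting).
Anomaly flags are advisory; exclusion requires an explicit decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .simulate import Cohort, PaintRecord
from .template import BodyTemplate

__all__ = [
    "SubjectBSM",
    "QCReport",
    "AnomalyThresholds",
    "rasterize_clicks",
    "smooth_map",
    "build_subject_bsm",
    "build_cohort_bsms",
    "completion_counts",
    "completion_threshold",
    "completion_screen",
    "anomaly_flags",
]


@dataclass
class SubjectBSM:
    """Signed, smoothed, masked map for one (subject, stimulus) pair."""

    subject_id: str
    stimulus: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("BSM values must be finite")


@dataclass
class QCReport:
    """Completion screening outcome for a cohort.

    ``excluded`` and ``kept`` partition the subjects; a subject is
    flagged ``insufficient_completion`` iff their completed-map count is
    strictly below ``mean - k*SD``.
    """

    counts: dict[str, int]
    mean: float
    sd: float
    k: float
    threshold: float
    excluded: list[str]
    kept: list[str]
    reasons: dict[str, str] = field(default_factory=dict)


def _disk_footprint(radius: int) -> np.ndarray:
    d = np.arange(-radius, radius + 1)
    return (d[:, None] ** 2 + d[None, :] ** 2) <= radius**2


def rasterize_clicks(
    events: np.ndarray, brush_radius: int, template: BodyTemplate
) -> np.ndarray:
    """Paint each click center with a discrete disk brush.

    The disk is ``{(dr, dc): dr^2 + dc^2 <= radius^2}``; overlapping
    clicks saturate at 1 (painting is set-valued, not additive) and
    disk parts outside the canvas are clipped.
    """
    if brush_radius < 0:
        raise ValueError("brush_radius must be nonnegative")
    events = np.asarray(events, dtype=int)
    if events.size == 0:
        return template.zeros()
    if events.ndim != 2 or events.shape[1] != 2:
        raise ValueError("events must be an (n, 2) array of (row, col)")
    if (
        events[:, 0].min() < 0
        or events[:, 0].max() >= template.height
        or events[:, 1].min() < 0
        or events[:, 1].max() >= template.width
    ):
        raise ValueError("click centers must lie within canvas bounds")
    centers = template.zeros(dtype=bool)
    centers[events[:, 0], events[:, 1]] = True
    if brush_radius == 0:
        return centers.astype(float)
    painted = ndimage.binary_dilation(centers, structure=_disk_footprint(brush_radius))
    return painted.astype(float)


def smooth_map(raw: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with a unit-sum kernel truncated at 3 sigma.

    ``sigma=0`` returns the input unchanged.  Zero-padded borders mean
    the total sum is conserved exactly only for maps whose support sits
    at least 3 sigma from the canvas edge.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    raw = np.asarray(raw, dtype=float)
    if sigma == 0:
        return raw.copy()
    return ndimage.gaussian_filter(raw, sigma=sigma, mode="constant", cval=0.0, truncate=3.0)


def build_subject_bsm(
    activation_events: np.ndarray,
    deactivation_events: np.ndarray,
    template: BodyTemplate,
    brush_radius: int = 6,
    sigma: float = 5.0,
    subject_id: str = "",
    stimulus: str = "",
) -> SubjectBSM:
    """Merge the two painted panels into one signed, masked map.

    ``values = smooth(rasterize(activation)) - smooth(rasterize(deactivation))``
    with out-of-mask cells set to exactly 0 afterwards.
    """
    act = smooth_map(rasterize_clicks(activation_events, brush_radius, template), sigma)
    deact = smooth_map(rasterize_clicks(deactivation_events, brush_radius, template), sigma)
    values = act - deact
    values[~template.mask] = 0.0
    return SubjectBSM(subject_id=subject_id, stimulus=stimulus, values=values)


def build_cohort_bsms(
    cohort: Cohort,
    template: BodyTemplate,
    brush_radius: int = 6,
    sigma: float = 5.0,
) -> list[SubjectBSM]:
    """Build one BSM per completed (subject, stimulus) pair."""
    bsms = []
    for sid, stim, act, deact in cohort.pairs():
        if not (act.completed or deact.completed):
            continue
        bsms.append(
            build_subject_bsm(
                act.events, deact.events, template, brush_radius, sigma,
                subject_id=sid, stimulus=stim,
            )
        )
    return bsms


def completion_counts(cohort: Cohort, template: BodyTemplate) -> dict[str, int]:
    """Completed-map count per subject.

    A map counts as completed iff at least one event rasterizes to an
    in-mask pixel in either panel (an isolated out-of-body scribble does
    not count as touching the body).
    """
    counts: dict[str, int] = {}
    for sid, stim, act, deact in cohort.pairs():
        counts.setdefault(sid, 0)
        touched = False
        for rec in (act, deact):
            if len(rec.events) and template.mask[rec.events[:, 0], rec.events[:, 1]].any():
                touched = True
                break
        if touched:
            counts[sid] += 1
    return counts


def completion_threshold(mean: float, sd: float, k: float = 2.5) -> float:
    """Exclusion cutoff ``mean - k*SD`` on completed-map counts."""
    return mean - k * sd


def completion_screen(
    cohort: Cohort, template: BodyTemplate, k: float = 2.5
) -> QCReport:
    """Flag subjects completing too few maps (count < mean - k*SD).

    Uses the sample SD (ddof=1), so at least two subjects are required.
    """
    counts = completion_counts(cohort, template)
    if len(counts) < 2:
        raise ValueError("completion screening needs at least 2 subjects")
    values = np.array(list(counts.values()), dtype=float)
    m = float(values.mean())
    s = float(values.std(ddof=1))
    threshold = completion_threshold(m, s, k)
    excluded, kept, reasons = [], [], {}
    for sid, c in counts.items():
        if c < threshold:
            excluded.append(sid)
            reasons[sid] = (
                f"insufficient_completion: {c} maps < threshold "
                f"{threshold:.2f} (mean {m:.2f} - {k}*SD {s:.2f})"
            )
        else:
            kept.append(sid)
    return QCReport(
        counts=counts, mean=m, sd=s, k=k, threshold=threshold,
        excluded=excluded, kept=kept, reasons=reasons,
    )


@dataclass(frozen=True)
class AnomalyThresholds:
    """Heuristic cutoffs for flagging anomalous responders.

    ``out_of_mask_fraction``: fraction of a subject's clicks landing
    outside the silhouette.  ``area_zscore``: |z| of the subject's total
    painted in-mask area relative to the cohort.  ``line_fraction``:
    fraction of a map's clicks concentrated in one 3-pixel row or
    column band (straight strokes, e.g. drawn symbols), applied to maps
    with at least ``line_min_events`` clicks.
    """

    out_of_mask_fraction: float = 0.25
    area_zscore: float = 3.5
    line_fraction: float = 0.55
    line_min_events: int = 30


def _line_score(events: np.ndarray) -> float:
    """Max fraction of clicks inside a single 3-wide row or column band."""
    best = 0.0
    n = len(events)
    for axis in (0, 1):
        vals = np.bincount(events[:, axis])
        if len(vals) >= 3:
            band = vals[:-2] + vals[1:-1] + vals[2:]
            best = max(best, band.max() / n)
        else:
            best = max(best, vals.sum() / n)
    return best


def anomaly_flags(
    cohort: Cohort,
    template: BodyTemplate,
    thresholds: AnomalyThresholds = AnomalyThresholds(),
) -> dict[str, list[str]]:
    """Advisory per-subject anomaly flags with human-readable reasons.

    Replaces the study's manual visual screening with three documented
    heuristics (out-of-body click fraction, painted-area z-score,
    straight-line stroke detector).  Returns only flagged subjects;
    exclusion remains an explicit caller decision.
    """
    per_subject: dict[str, dict] = {}
    for rec in cohort.records:
        st = per_subject.setdefault(
            rec.subject_id, {"clicks": 0, "out": 0, "area": 0, "line_maps": 0, "maps": 0}
        )
        n = len(rec.events)
        if n == 0:
            continue
        in_mask = template.mask[rec.events[:, 0], rec.events[:, 1]]
        st["clicks"] += n
        st["out"] += int((~in_mask).sum())
        st["area"] += int(in_mask.sum())
        st["maps"] += 1
        if n >= thresholds.line_min_events and _line_score(rec.events) > thresholds.line_fraction:
            st["line_maps"] += 1

    sids = list(per_subject)
    areas = np.array([per_subject[s]["area"] for s in sids], dtype=float)
    if len(areas) >= 2 and areas.std(ddof=1) > 0:
        z = (areas - areas.mean()) / areas.std(ddof=1)
    else:
        z = np.zeros(len(areas))

    flags: dict[str, list[str]] = {}
    for sid, zi in zip(sids, z):
        st = per_subject[sid]
        reasons = []
        if st["clicks"] > 0:
            frac_out = st["out"] / st["clicks"]
            if frac_out > thresholds.out_of_mask_fraction:
                reasons.append(f"out_of_mask_fraction {frac_out:.2f}")
        if abs(zi) > thresholds.area_zscore:
            reasons.append(f"painted_area_zscore {zi:.2f}")
        if st["maps"] > 0 and st["line_maps"] / st["maps"] > 0.25:
            reasons.append(f"straight_line_strokes in {st['line_maps']}/{st['maps']} maps")
        if reasons:
            flags[sid] = reasons
    return flags
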