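"""Group-level mass-univariate statistics on bodily sensation maps.

For each stimulus, a one-sample t-test against zero is run at every
in-body pixel across subjects, giving a statistical t-map; each map is
then thresholded with the Benjamini-Hochberg false-discovery-rate
correction (alpha = 0.05 by default) over its in-mask p-values.
Activations and deactivations are read from the sign of t (p-values are
two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import SubjectBSM
from .template import BodyTemplate, mask_vector_index

__all__ = ["GroupMap", "pixelwise_ttest", "fdr_threshold", "threshold_group_map", "group_maps_for_cohort"]


@dataclass
class GroupMap:
    """Per-stimulus group statistics: t-map, p-map and FDR threshold.

    ``t`` and ``p`` are full-canvas grids (t = 0 and p = 1 outside the
    mask); ``sig_mask`` marks in-mask pixels surviving FDR at ``alpha``;
    ``min_sig_abs_t`` is the smallest |t| among significant pixels (the
    display threshold), NaN if nothing survives.  Zero-variance pixels
    follow a documented convention: all-zero samples give t = 0, p = 1;
    constant nonzero samples give p = 0 with t = sign * inf as sentinel.
    """

    stimulus: str
    n_subjects: int
    t: np.ndarray
    p: np.ndarray
    alpha: float
    fdr_critical_p: float
    sig_mask: np.ndarray
    min_sig_abs_t: float

    @property
    def df(self) -> int:
        return self.n_subjects - 1


def pixelwise_ttest(
    stack: list[SubjectBSM] | np.ndarray,
    template: BodyTemplate,
    stimulus: str = "",
    alpha: float = 0.05,
) -> GroupMap:
    """Mass-univariate one-sample t-test against zero, one test per pixel.

    ``stack`` holds one completed map per subject (as ``SubjectBSM`` or
    an ``(n, height, width)`` array).  Returns an unthresholded
    ``GroupMap`` (``sig_mask`` empty, ``fdr_critical_p`` 0); apply
    ``fdr_threshold`` or use ``group_maps_for_cohort`` for thresholding.
    """
    if isinstance(stack, np.ndarray):
        arr = stack
    else:
        arr = np.stack([b.values for b in stack])
    n = arr.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 subjects for a t-test, got {n}")
    idx = mask_vector_index(template)
    X = arr[:, idx.rows, idx.cols]  # (n, m)

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var & (mean == 0)] = 0.0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    p = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df=n - 1))
    p[zero_var & (mean == 0)] = 1.0

    t_grid = idx.devectorize(t)
    p_grid = idx.devectorize(p, fill=1.0)
    return GroupMap(
        stimulus=stimulus, n_subjects=n, t=t_grid, p=p_grid, alpha=alpha,
        fdr_critical_p=0.0, sig_mask=template.zeros(bool), min_sig_abs_t=float("nan"),
    )


def fdr_threshold(
    p: np.ndarray,
    alpha: float = 0.05,
    template: BodyTemplate | None = None,
) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up threshold over the in-mask p-values.

    Finds the largest k with ``p_(k) <= k * alpha / m`` (m = number of
    in-mask pixels); the critical p is ``p_(k)`` (0 if no k qualifies)
    and the significance mask keeps pixels with ``p <= critical p``.

    ``p`` may be a vector, or a grid if ``template`` is given (only
    in-mask cells enter the correction).  Returns
    ``(critical_p, sig_mask)`` with ``sig_mask`` shaped like ``p``.
    """
    p = np.asarray(p, dtype=float)
    if template is not None:
        pv = p[template.mask]
    else:
        pv = p.ravel()
    if pv.size == 0:
        return 0.0, np.zeros_like(p, dtype=bool)
    if pv.min() < 0 or pv.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pv, alpha=alpha, method="fdr_bh")
    critical_p = float(pv[reject].max()) if reject.any() else 0.0
    sig = np.zeros_like(p, dtype=bool)
    if template is not None:
        sig[template.mask] = p[template.mask] <= critical_p if reject.any() else False
    else:
        sig = (p <= critical_p) if reject.any() else sig
    return critical_p, sig


def threshold_group_map(gm: GroupMap, template: BodyTemplate, alpha: float | None = None) -> GroupMap:
    """Apply per-map BH-FDR to a GroupMap in place; returns the map."""
    alpha = gm.alpha if alpha is None else alpha
    crit, sig = fdr_threshold(gm.p, alpha=alpha, template=template)
    gm.alpha = alpha
    gm.fdr_critical_p = crit
    gm.sig_mask = sig
    abs_t = np.abs(gm.t[sig])
    gm.min_sig_abs_t = float(abs_t.min()) if abs_t.size else float("nan")
    return gm


def group_maps_for_cohort(
    bsms: list[SubjectBSM],
    template: BodyTemplate,
    alpha: float = 0.05,
    stimuli: list[str] | None = None,
    pooled_fdr: bool = False,
) -> list[GroupMap]:
    """One FDR-thresholded GroupMap per stimulus.

    Subjects missing a stimulus are dropped listwise for that map only,
    so n may vary across maps.  By default the FDR correction is applied
    per map over its in-mask p-values; ``pooled_fdr=True`` instead pools
    the p-values of every map into a single correction, yielding one
    shared critical p (and hence a single display threshold on |t|).
    """
    by_stim: dict[str, list[SubjectBSM]] = {}
    for b in bsms:
        by_stim.setdefault(b.stimulus, []).append(b)
    order = stimuli if stimuli is not None else sorted(by_stim)
    maps = []
    for stim in order:
        stack = by_stim.get(stim, [])
        if len(stack) < 2:
            raise ValueError(f"stimulus {stim!r} has {len(stack)} completed maps; need >= 2")
        maps.append(pixelwise_ttest(stack, template, stimulus=stim, alpha=alpha))

    if pooled_fdr:
        pooled = np.concatenate([gm.p[template.mask] for gm in maps])
        crit, _ = fdr_threshold(pooled, alpha=alpha)
        for gm in maps:
            sig = template.zeros(bool)
            sig[template.mask] = gm.p[template.mask] <= crit if crit > 0 else False
            gm.fdr_critical_p = crit
            gm.sig_mask = sig
            abs_t = np.abs(gm.t[sig])
            gm.min_sig_abs_t = float(abs_t.min()) if abs_t.size else float("nan")
    else:
        for gm in maps:
            threshold_group_map(gm, template, alpha)
    return maps
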