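"""Spearman similarity between group-level bodily sensation maps.

Similarity between two maps is the Spearman rank correlation of their
in-mask pixel vectors, computed by default on the unthresholded t-maps
(thresholding would zero-inflate the ranks; a thresholded mode exists
for comparison).  An undefined correlation — either vector constant —
is reported as NaN, never silently as 0: a nearly empty map (e.g. the
neutral state) should be visible as undefined, not as dissimilar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .stats import GroupMap
from .template import BodyTemplate

__all__ = [
    "SimilarityMatrix",
    "spearman_similarity",
    "similarity_matrix",
    "cross_study_similarity",
]


@dataclass
class SimilarityMatrix:
    """Symmetric Spearman similarity matrix over an ordered stimulus list."""

    labels: list[str]
    r: np.ndarray
    n_pixels_used: int


def _masked_vectors(a: np.ndarray, b: np.ndarray, template: BodyTemplate) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    shape = template.mask.shape
    if a.shape != shape or b.shape != shape:
        raise ValueError(
            f"map shapes {a.shape}, {b.shape} do not match template {shape}"
        )
    return a[template.mask], b[template.mask]


def spearman_similarity(map_a: np.ndarray, map_b: np.ndarray, template: BodyTemplate) -> float:
    """Spearman rank correlation over the in-mask pixels of two maps.

    Ties get average ranks.  Returns NaN if either in-mask vector is
    constant (rank correlation undefined).
    """
    va, vb = _masked_vectors(map_a, map_b, template)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return float("nan")
    ra, rb = rankdata(va), rankdata(vb)
    return float(np.corrcoef(ra, rb)[0, 1])


def similarity_matrix(
    maps: list[GroupMap],
    template: BodyTemplate,
    thresholded: bool = False,
) -> SimilarityMatrix:
    """Pairwise Spearman similarity between group-level t-maps.

    Ranks each map's in-mask vector once and correlates the rank
    vectors, which is exactly pairwise Spearman with average-tie
    handling.  ``thresholded=True`` zeroes non-significant pixels first.
    Constant maps give NaN rows/columns (with a warning); the diagonal
    is 1 by convention.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    labels = [gm.stimulus for gm in maps]
    vecs = []
    for gm in maps:
        grid = gm.t.copy()
        if thresholded:
            grid[~gm.sig_mask] = 0.0
        vecs.append(grid[template.mask])
    V = np.stack(vecs)
    constant = np.ptp(V, axis=1) == 0
    if constant.any():
        bad = [labels[i] for i in np.nonzero(constant)[0]]
        warnings.warn(f"constant map(s) {bad}: similarity undefined (NaN)", stacklevel=2)
    ranks = np.stack([rankdata(v) for v in V])
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(ranks)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return SimilarityMatrix(labels=labels, r=r, n_pixels_used=template.n_in_mask)


def _resample_nearest(grid: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample of a grid to the template's shape."""
    if grid.shape == shape:
        return grid
    rows = np.floor((np.arange(shape[0]) + 0.5) * grid.shape[0] / shape[0]).astype(int)
    cols = np.floor((np.arange(shape[1]) + 0.5) * grid.shape[1] / shape[1]).astype(int)
    return grid[np.clip(rows, 0, grid.shape[0] - 1)][:, np.clip(cols, 0, grid.shape[1] - 1)]


def cross_study_similarity(
    current: list[GroupMap],
    reference: dict[str, np.ndarray],
    template: BodyTemplate,
) -> dict[str, float]:
    """Similarity of each shared stimulus against an external reference set.

    Labels are matched case-insensitively; reference grids on a
    different canvas are resampled to the template by nearest neighbor.
    Returns one Spearman coefficient per shared label (keyed by the
    current study's label).
    """
    ref_by_label = {k.lower(): np.asarray(v, float) for k, v in reference.items()}
    out: dict[str, float] = {}
    for gm in current:
        ref = ref_by_label.get(gm.stimulus.lower())
        if ref is None:
            continue
        ref = _resample_nearest(ref, template.mask.shape)
        out[gm.stimulus] = spearman_similarity(gm.t, ref, template)
    if not out:
        raise ValueError("no shared stimulus labels between current and reference maps")
    return out
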