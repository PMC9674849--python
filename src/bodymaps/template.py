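"""Body-template geometry: the canvas, the in-body mask and named regions.

Every downstream stage works on maps defined over a single silhouette
grid; the activation and deactivation panels share this template and
events carry a panel tag instead of doubling the canvas width.
Coordinates are 0-based with origin at the top-left, stored ``(row, col)``;
``col`` is the x coordinate in event files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "BodyTemplate",
    "MaskIndex",
    "EmptyMaskError",
    "REGION_NAMES",
    "build_default_template",
    "load_template",
    "save_template",
    "mask_vector_index",
]

REGION_NAMES = ("head", "cheeks", "chest", "abdomen", "arms", "hands", "legs")


class EmptyMaskError(ValueError):
    """Raised when a template mask contains no in-body pixels."""


@dataclass(frozen=True)
class BodyTemplate:
    """Silhouette mask grid defining in-body pixels and the map vector space.

    Parameters
    ----------
    width, height
        Canvas size of a single panel in pixels.
    mask
        Boolean ``(height, width)`` grid; ``True`` marks in-body cells.
    regions
        Named anatomical sub-grids (each a subset of ``mask``; regions
        may overlap, e.g. cheeks lie inside the head).
    """

    width: int
    height: int
    mask: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.height, self.width):
            raise ValueError(
                f"mask shape {mask.shape} does not match "
                f"(height, width)=({self.height}, {self.width})"
            )
        object.__setattr__(self, "mask", mask)
        if not mask.any():
            raise EmptyMaskError("template mask has no in-body pixels")
        for name, sub in self.regions.items():
            if np.asarray(sub).shape != mask.shape:
                raise ValueError(f"region {name!r} shape mismatch")
            if np.any(np.asarray(sub, dtype=bool) & ~mask):
                raise ValueError(f"region {name!r} is not a subset of the mask")

    @property
    def n_in_mask(self) -> int:
        """Number of in-body pixels (the BSM vector length)."""
        return int(self.mask.sum())

    def region(self, name: str) -> np.ndarray:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; available: {sorted(self.regions)}"
            ) from None

    def zeros(self, dtype=float) -> np.ndarray:
        return np.zeros((self.height, self.width), dtype=dtype)


@dataclass(frozen=True)
class MaskIndex:
    """Bijection between in-mask cells (row-major) and vector positions.

    ``vectorize`` / ``devectorize`` round-trip exactly on in-mask cells;
    out-of-mask cells devectorize to 0.
    """

    template: BodyTemplate
    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)

    def vectorize(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid)
        if grid.shape != self.template.mask.shape:
            raise ValueError("grid shape does not match template")
        return grid[self.rows, self.cols]

    def devectorize(self, vector: np.ndarray, fill=0.0) -> np.ndarray:
        vector = np.asarray(vector)
        if vector.shape != (len(self.rows),):
            raise ValueError(
                f"vector length {vector.shape} != n_in_mask {len(self.rows)}"
            )
        grid = np.full(self.template.mask.shape, fill, dtype=vector.dtype)
        grid[self.rows, self.cols] = vector
        return grid


def mask_vector_index(template: BodyTemplate) -> MaskIndex:
    """Row-major index map between in-mask cells and vector positions 0..n-1."""
    rows, cols = np.nonzero(template.mask)  # nonzero scans row-major
    return MaskIndex(template=template, rows=rows, cols=cols)


def _ellipse(height: int, width: int, cr: float, cc: float, rr: float, rc: float) -> np.ndarray:
    r = np.arange(height)[:, None]
    c = np.arange(width)[None, :]
    return ((r - cr) / rr) ** 2 + ((c - cc) / rc) ** 2 <= 1.0


def _band(height: int, width: int, r0: float, r1: float, cc: float, d0: float, d1: float) -> np.ndarray:
    """Cells with row in [r0, r1] and |col - cc| in [d0, d1]."""
    r = np.arange(height)[:, None]
    c = np.arange(width)[None, :]
    d = np.abs(c - cc)
    return (r >= r0) & (r <= r1) & (d >= d0) & (d <= d1)


def build_default_template(width: int = 60, height: int = 120) -> BodyTemplate:
    """Deterministic, left-right symmetric humanoid silhouette.

    A procedural stand-in for silhouette artwork: stacked ellipses and
    bands for head, neck, torso, arms, hands and legs, scaled to the
    requested canvas.  Symmetry holds cell-for-cell because every shape
    is defined through ``|col - (width-1)/2|``.

    Parameters
    ----------
    width, height
        Panel size in pixels; at least 40 x 80.
    """
    if width < 40 or height < 80:
        raise ValueError(f"canvas too small: need width>=40, height>=80, got {width}x{height}")

    H, W = height, width
    cx = (W - 1) / 2.0

    head = _ellipse(H, W, cr=0.09 * H, cc=cx, rr=0.07 * H, rc=0.11 * W)
    neck = _band(H, W, 0.14 * H, 0.18 * H, cx, 0.0, 0.05 * W)
    torso = _band(H, W, 0.18 * H, 0.52 * H, cx, 0.0, 0.18 * W)
    chest = _band(H, W, 0.18 * H, 0.35 * H, cx, 0.0, 0.18 * W)
    abdomen = _band(H, W, 0.35 * H, 0.52 * H, cx, 0.0, 0.18 * W)
    shoulders = _band(H, W, 0.20 * H, 0.24 * H, cx, 0.18 * W, 0.28 * W)
    arm_bars = _band(H, W, 0.20 * H, 0.46 * H, cx, 0.20 * W, 0.28 * W)
    arms = shoulders | arm_bars
    hands = _band(H, W, 0.46 * H, 0.52 * H, cx, 0.20 * W, 0.30 * W)
    legs = _band(H, W, 0.52 * H, 0.95 * H, cx, 0.03 * W, 0.17 * W)
    cheeks = _ellipse(H, W, 0.105 * H, cx - 0.055 * W, 0.022 * H, 0.035 * W) | _ellipse(
        H, W, 0.105 * H, cx + 0.055 * W, 0.022 * H, 0.035 * W
    )

    mask = head | neck | torso | arms | hands | legs
    # silhouette must not touch the canvas border
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False

    regions = {
        "head": head & mask,
        "cheeks": cheeks & head & mask,
        "chest": chest & mask,
        "abdomen": abdomen & mask,
        "arms": arms & mask,
        "hands": hands & mask,
        "legs": legs & mask,
    }
    return BodyTemplate(width=W, height=H, mask=mask, regions=regions)


def load_template(
    image_path: str | Path,
    threshold: float = 128,
    polarity: str = "dark-is-body",
) -> BodyTemplate:
    """Load a silhouette mask from a grayscale PNG.

    ``polarity="dark-is-body"`` marks pixels with intensity < ``threshold``
    as in-body; ``"light-is-body"`` marks intensity > ``threshold``.
    Regions are left empty; callers may attach their own.
    """
    if polarity not in ("dark-is-body", "light-is-body"):
        raise ValueError(f"unknown polarity {polarity!r}")
    arr = np.asarray(Image.open(image_path).convert("L"), dtype=float)
    mask = arr < threshold if polarity == "dark-is-body" else arr > threshold
    if not mask.any():
        raise EmptyMaskError(f"no in-body pixels in {image_path} at threshold {threshold}")
    return BodyTemplate(width=mask.shape[1], height=mask.shape[0], mask=mask, regions={})


def save_template(template: BodyTemplate, png_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write the mask as a grayscale PNG (body=black) plus a JSON sidecar."""
    import json

    img = Image.fromarray(np.where(template.mask, 0, 255).astype(np.uint8), mode="L")
    img.save(png_path)
    if json_path is not None:
        meta = {
            "width": template.width,
            "height": template.height,
            "n_in_mask": template.n_in_mask,
            "regions": {k: int(v.sum()) for k, v in template.regions.items()},
        }
        Path(json_path).write_text(json.dumps(meta, indent=2, sort_keys=True))
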