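"""Reading, validating and tracing binary dorsal masks.

A mask is a 2-D grid of {0, 1} where 1 marks the animal's dorsal region seen
from directly above.  Coordinates follow the raster convention: ``x`` is the
column index (increasing right), ``y`` the row index (increasing down),
origin at the top-left pixel center.  Foreground is 8-connected, background
4-connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, EmptyMaskError

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "Contour",
    "load_mask",
    "write_mask",
    "select_target_blob",
    "trace_contour",
    "touches_border",
]


@dataclass(frozen=True)
class BinaryMask:
    """A binary foreground/background image.

    grid holds exactly {0, 1} with dtype uint8; 1 is foreground.
    """

    grid: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("mask grid must be a non-empty 2-D array")
        vals = np.unique(g)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask grid must contain only 0 and 1")
        object.__setattr__(self, "grid", g.astype(np.uint8, copy=False))

    @property
    def height_px(self) -> int:
        return self.grid.shape[0]

    @property
    def width_px(self) -> int:
        return self.grid.shape[1]

    @property
    def area(self) -> int:
        """Foreground pixel count (interior holes do not add to it)."""
        return int(self.grid.sum())

    def is_degenerate(self) -> bool:
        """True for blobs too small or too thin for the geometric operators.

        Degenerate means fewer than 9 foreground pixels, or no pixel whose
        4-neighbourhood is entirely foreground (i.e. thinner than ~2 px
        everywhere).
        """
        if self.area < 9:
            return True
        interior = ndimage.binary_erosion(
            self.grid.astype(bool),
            structure=ndimage.generate_binary_structure(2, 1),
        )
        return not interior.any()


@dataclass
class Contour:
    """Ordered closed boundary of a blob, as pixel-center coordinates (x, y).

    Orientation is normalized counter-clockwise in the raster frame
    (y pointing down), which corresponds to a non-negative shoelace signed
    area computed on (x, y) as usual.
    """

    points: np.ndarray  # (N, 2) float, columns (x, y)
    closed: bool = True
    degenerate: bool = field(default=False)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("contour points must be (N, 2)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )


def load_mask(path: str | Path, threshold: int = 127) -> BinaryMask:
    """Read an image file and binarize it: luminance > threshold → foreground.

    Raises OSError if the file cannot be read, EmptyMaskError if no pixel
    exceeds the threshold.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    with Image.open(path) as im:
        gray = np.asarray(im.convert("L"))
    grid = (gray > threshold).astype(np.uint8)
    if grid.sum() == 0:
        raise EmptyMaskError(f"no foreground pixels in {path}")
    mask = BinaryMask(grid)
    _warn_on_holes(mask, str(path))
    return mask


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit grayscale PNG with values {0, 255}."""
    Image.fromarray(mask.grid * np.uint8(255), mode="L").save(path)


def _warn_on_holes(mask: BinaryMask, name: str = "<mask>") -> None:
    filled = ndimage.binary_fill_holes(mask.grid.astype(bool))
    if int(filled.sum()) != mask.area:
        logger.warning("mask %s contains interior holes (anomalous input)", name)


def select_target_blob(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 8-connected foreground component.

    Ties on area are broken by the smallest bounding-box top-left corner
    (row first, then column).  Raises EmptyMaskError on an empty mask.
    """
    if mask.area == 0:
        raise EmptyMaskError("cannot select a blob from an empty mask")
    labels, n = measure.label(mask.grid, connectivity=2, return_num=True)
    if n == 1:
        return mask
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    best = int(np.max(areas))
    candidates = [lab for lab in range(1, n + 1) if areas[lab - 1] == best]
    if len(candidates) > 1:
        corners = []
        for lab in candidates:
            rr, cc = np.nonzero(labels == lab)
            corners.append((rr.min(), cc.min(), lab))
        candidates = [min(corners)[2]]
    return BinaryMask((labels == candidates[0]).astype(np.uint8))


# Moore-neighbour offsets in clockwise order starting from north, as
# (drow, dcol).  Clockwise scanning of an outer boundary in a y-down raster
# yields the orientation normalized below.
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_contour(mask: BinaryMask) -> Contour:
    """Trace the closed outer boundary of a single blob (holes ignored).

    Returns pixel-center coordinates in counter-clockwise order (raster
    frame).  A single-pixel blob yields a degenerate one-point contour.
    Raises EmptyMaskError on an empty mask.
    """
    if mask.area == 0:
        raise EmptyMaskError("cannot trace contour of an empty mask")
    grid = np.pad(mask.grid.astype(bool), 1)
    rows, cols = np.nonzero(grid)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    if mask.area == 1:
        return Contour(
            np.array([[start[1] - 1, start[0] - 1]], float), degenerate=True
        )

    # Moore-neighbour tracing with Jacob's stopping criterion: stop when the
    # start pixel is re-entered from the same backtrack direction.
    points: list[tuple[int, int]] = [start]
    backtrack = (start[0], start[1] - 1)  # entered start from the west
    cur = start
    first_move: tuple | None = None
    while True:
        bi = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            d = _MOORE[(bi + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if grid[cand]:
                nxt = cand
                prev = _MOORE[(bi + k - 1) % 8]
                new_backtrack = (cur[0] + prev[0], cur[1] + prev[1])
                break
        if nxt is None:  # isolated pixel, handled above but keep safe
            break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            points.pop()  # the re-appended start of the second lap
            break
        points.append(nxt)
        backtrack = new_backtrack
        cur = nxt
        if len(points) > 4 * grid.size:
            raise RuntimeError("contour tracing failed to terminate")

    pts = np.array([(c - 1, r - 1) for r, c in points], dtype=float)
    # drop consecutive duplicates (can occur on 1-px-wide necks)
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    pts = pts[keep]
    contour = Contour(pts, degenerate=len(pts) < 4)
    if contour.signed_area < 0:
        contour.points = contour.points[::-1].copy()
    return contour


def touches_border(mask: BinaryMask, margin_px: int = 0) -> bool:
    """True iff any foreground pixel lies within margin_px of an image edge."""
    if margin_px < 0:
        raise ValueError("margin_px must be non-negative")
    rr, cc = np.nonzero(mask.grid)
    if rr.size == 0:
        return False
    h, w = mask.grid.shape
    dist = np.minimum.reduce([rr, cc, h - 1 - rr, w - 1 - cc])
    return bool(dist.min() <= margin_px)


def require_nondegenerate(mask: BinaryMask, what: str = "operation") -> None:
    if mask.area == 0:
        raise EmptyMaskError(f"{what}: empty mask")
    if mask.is_degenerate():
        raise DegenerateInputError(f"{what}: blob is degenerate (tiny or thin)")
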