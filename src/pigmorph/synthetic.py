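"""Synthetic masks with analytic ground truth, and a synthetic herd corpus.

Shapes are rasterized on a 960 × 540 canvas (the study resolution) by the
pixel-center rule: a pixel is foreground iff its center lies inside the
continuous shape.  The herd generator emulates the statistical structure of
a top-view pig-weighing study: elongated capsule silhouettes with a
per-image bend angle (posture), two discrete camera heights, pinhole scaling
(pixel size ∝ 1/height), several images per animal with fixed intrinsic
size, and an allometric weight law

    weight_kg = alpha · (L_cm · W_cm)^gamma_w · exp(ε),   ε ~ N(0, σ²),

clipped to the configured weight range.  Every sample carries its generating
parameters, so each morphometry operator can be checked against known
ground truth (longest ≈ body length in px, body_curve ≈ bend angle, …).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mask_io import BinaryMask, write_mask

__all__ = [
    "ShapeSpec",
    "HerdSample",
    "WeightModel",
    "make_shape",
    "simulate_herd",
    "write_herd",
    "CANVAS",
    "K_PX",
]

CANVAS: tuple[int, int] = (960, 540)  # (width, height), study resolution

#: Pinhole constant, px·m/cm: px_per_cm = K_PX / camera_height_m.  At 7.5 the
#: largest animal (160 cm) seen from 1.78 m spans ≈ 674 px of body length,
#: close to filling the 960-px width while always fitting the canvas under
#: rotation and bend jitter.
K_PX: float = 7.5

SHAPE_KINDS = ("disc", "ellipse", "rectangle", "capsule", "bent_capsule", "l_shape")


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of a synthetic silhouette.

    params by kind:
      disc: R; ellipse: a, b (semi-axes); rectangle: w, h (full sides);
      capsule / bent_capsule: length (tip-to-tip), width, bend_deg
      (interior angle at the midpoint, 180 = straight; capsule implies 180);
      l_shape: long, thick (two long×thick rectangles sharing a
      thick×thick corner).
    """

    kind: str
    params: dict = field(default_factory=dict)
    rotation_deg: float = 0.0
    center: tuple[float, float] | None = None  # (x, y); canvas center if None
    canvas: tuple[int, int] = CANVAS
    border_test: bool = False

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ValidationError(f"unknown shape kind {self.kind!r}")
        if any(v <= 0 for k, v in self.params.items() if k != "bend_deg"):
            raise ValidationError(f"shape parameters must be positive: {self.params}")
        bend = self.params.get("bend_deg", 180.0)
        if self.kind == "bent_capsule" and not 0.0 < bend <= 180.0:
            raise ValidationError("bend_deg must be in (0, 180]")


def _seg_dist(px, py, a, b):
    """Distance from points (px, py) to segment a→b (2-vectors)."""
    ab = np.subtract(b, a)
    ap_x = px - a[0]
    ap_y = py - a[1]
    denom = ab[0] ** 2 + ab[1] ** 2
    t = np.clip((ap_x * ab[0] + ap_y * ab[1]) / max(denom, 1e-12), 0.0, 1.0)
    return np.hypot(ap_x - t * ab[0], ap_y - t * ab[1])


def _capsule_vertices(length: float, width: float, bend_deg: float):
    """Medial polyline (V, E1, E2) of a (possibly bent) capsule, in the
    shape frame: chord along +u, arms bending toward +v."""
    seg = length - width
    if seg <= 0:
        raise ValidationError("capsule length must exceed its width")
    arm = seg / 2.0
    delta = np.deg2rad((180.0 - bend_deg) / 2.0)
    v = np.array([0.0, 0.0])
    e1 = arm * np.array([np.cos(delta), np.sin(delta)])
    e2 = arm * np.array([-np.cos(delta), np.sin(delta)])
    # vertical re-centering so the capsule straddles v = 0
    off = arm * np.sin(delta) / 2.0
    return v - [0, off], e1 - [0, off], e2 - [0, off]


def make_shape(spec: ShapeSpec) -> BinaryMask:
    """Rasterize a ShapeSpec: pixel center inside the continuous shape → 1.

    Raises ValidationError if the shape reaches the canvas border and
    ``border_test`` is not set, or if the rasterization is empty.
    """
    w, h = spec.canvas
    cx, cy = spec.center if spec.center is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    # shape-frame coordinates: translate then rotate by −rotation
    th = np.deg2rad(spec.rotation_deg)
    dx = xx - cx
    dy = yy - cy
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy

    p = spec.params
    if spec.kind == "disc":
        inside = u ** 2 + v ** 2 <= p["R"] ** 2
    elif spec.kind == "ellipse":
        inside = (u / p["a"]) ** 2 + (v / p["b"]) ** 2 <= 1.0
    elif spec.kind == "rectangle":
        inside = (
            (-p["w"] / 2.0 <= u) & (u < p["w"] / 2.0)
            & (-p["h"] / 2.0 <= v) & (v < p["h"] / 2.0)
        )
    elif spec.kind in ("capsule", "bent_capsule"):
        bend = p.get("bend_deg", 180.0) if spec.kind == "bent_capsule" else 180.0
        vert, e1, e2 = _capsule_vertices(p["length"], p["width"], bend)
        r = p["width"] / 2.0
        d = np.minimum(_seg_dist(u, v, vert, e1), _seg_dist(u, v, vert, e2))
        inside = d <= r
    elif spec.kind == "l_shape":
        long_, thick = p["long"], p["thick"]
        off = long_ / 2.0  # center the bounding square
        ua, va = u + off, v + off
        inside = (
            ((0 <= ua) & (ua < long_) & (0 <= va) & (va < thick))
            | ((0 <= ua) & (ua < thick) & (0 <= va) & (va < long_))
        )
    else:  # pragma: no cover - guarded in ShapeSpec
        raise ValidationError(spec.kind)

    grid = inside.astype(np.uint8)
    if grid.sum() == 0:
        raise ValidationError("shape rasterized to an empty mask")
    on_border = grid[0].any() or grid[-1].any() or grid[:, 0].any() or grid[:, -1].any()
    if on_border and not spec.border_test:
        raise ValidationError(
            "shape reaches the canvas border (set border_test=True if intended)"
        )
    return BinaryMask(grid)


# ---------------------------------------------------------------------------
# herd simulation


@dataclass(frozen=True)
class WeightModel:
    """Allometric law weight = alpha · (L_cm · W_cm)^gamma_w · exp(ε)."""

    alpha: float = 0.25
    gamma_w: float = 0.75
    sigma_noise: float = 0.05


@dataclass
class HerdSample:
    image_id: str
    animal_id: str
    camera_height_m: float
    weight_kg: float
    mask: BinaryMask | None
    true_shape: ShapeSpec | None
    length_cm: float
    width_cm: float
    length_px: float
    width_px: float
    bend_deg: float


def _fit_capsule_in_canvas(rng, length_px, width_px, canvas, max_tries=20):
    """Draw (bend, rotation, center) such that the capsule fits the canvas."""
    w, h = canvas
    for attempt in range(max_tries):
        bend = float(rng.uniform(90.0, 180.0))
        rot = float(rng.uniform(-25.0, 25.0)) if attempt < max_tries - 1 else 0.0
        verts = _capsule_vertices(length_px, width_px, bend)
        th = np.deg2rad(rot)
        rotm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = np.array([rotm @ p for p in verts])
        r = width_px / 2.0 + 2.0
        lo = pts.min(axis=0) - r
        hi = pts.max(axis=0) + r
        ext = hi - lo
        if ext[0] >= w - 4 or ext[1] >= h - 4:
            continue
        # admissible center positions keep the bbox ≥ 2 px off every border
        cx_lo, cx_hi = 2.0 - lo[0], (w - 3.0) - hi[0]
        cy_lo, cy_hi = 2.0 - lo[1], (h - 3.0) - hi[1]
        mid = ((cx_lo + cx_hi) / 2.0, (cy_lo + cy_hi) / 2.0)
        jx = min(40.0, (cx_hi - cx_lo) / 2.0)
        jy = min(25.0, (cy_hi - cy_lo) / 2.0)
        cx = float(np.clip(mid[0] + rng.uniform(-jx, jx), cx_lo, cx_hi))
        cy = float(np.clip(mid[1] + rng.uniform(-jy, jy), cy_lo, cy_hi))
        return bend, rot, (cx, cy)
    raise ValidationError(
        f"capsule of length {length_px:.0f} px cannot fit the canvas {canvas}"
    )


def simulate_herd(
    n_animals: int,
    images_per_animal: int,
    seed: int,
    weight_model: WeightModel | None = None,
    height_choices: tuple[float, ...] = (1.78, 1.88),
    weight_range_kg: tuple[float, float] = (33.1, 192.0),
    length_range_cm: tuple[float, float] = (50.0, 160.0),
    width_frac: float = 0.28,
    canvas: tuple[int, int] = CANVAS,
    render: bool = True,
) -> list[HerdSample]:
    """Generate a seeded synthetic herd of (mask, height, weight) samples.

    Per animal an intrinsic body length L_cm ~ U(length_range) and width
    W_cm = width_frac · L_cm · exp(N(0, 0.08²)) are drawn once; the weight
    follows the allometric law and is clipped to ``weight_range_kg``.  Per
    image the posture varies (bend ∈ [90°, 180°], rotation ∈ ±25°,
    translation jitter) and a camera height is drawn uniformly from
    ``height_choices``; the rendered pixel size scales as K_PX / height.

    With ``render=False`` no mask is rasterized (mask is None, true_shape is
    still recorded) — useful when just the (animal, image, weight) structure
    matters.  The random draws are identical either way.
    """
    if n_animals < 2 or images_per_animal < 1:
        raise ValidationError("need n_animals ≥ 2 and images_per_animal ≥ 1")
    wm = weight_model or WeightModel()
    if wm.alpha <= 0 or wm.gamma_w <= 0 or wm.sigma_noise < 0:
        raise ValidationError(f"invalid weight model {wm}")
    lo, hi = weight_range_kg
    if not 0 < lo < hi:
        raise ValidationError(f"invalid weight range {weight_range_kg}")
    rng = np.random.default_rng(seed)

    samples: list[HerdSample] = []
    for i in range(n_animals):
        animal_id = f"pig{i:03d}"
        L_cm = float(rng.uniform(*length_range_cm))
        W_cm = float(width_frac * L_cm * np.exp(rng.normal(0.0, 0.08)))
        eps = float(rng.normal(0.0, wm.sigma_noise)) if wm.sigma_noise > 0 else 0.0
        weight = float(np.clip(wm.alpha * (L_cm * W_cm) ** wm.gamma_w * np.exp(eps),
                               lo, hi))
        for j in range(images_per_animal):
            height = float(height_choices[rng.integers(len(height_choices))])
            px_per_cm = K_PX / height
            L_px = L_cm * px_per_cm
            W_px = W_cm * px_per_cm
            bend, rot, center = _fit_capsule_in_canvas(rng, L_px, W_px, canvas)
            spec = ShapeSpec(
                kind="bent_capsule",
                params={"length": L_px, "width": W_px, "bend_deg": bend},
                rotation_deg=rot,
                center=center,
                canvas=canvas,
            )
            mask = make_shape(spec) if render else None
            samples.append(
                HerdSample(
                    image_id=f"{animal_id}_{j:03d}",
                    animal_id=animal_id,
                    camera_height_m=height,
                    weight_kg=weight,
                    mask=mask,
                    true_shape=spec if render else replace(spec),
                    length_cm=L_cm,
                    width_cm=W_cm,
                    length_px=L_px,
                    width_px=W_px,
                    bend_deg=bend,
                )
            )
    return samples


def write_herd(samples: list[HerdSample], outdir: str | Path) -> Path:
    """Write PNG masks plus a meta.csv in the mask_io metadata schema."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        if s.mask is None:
            raise ValidationError("cannot write an unrendered herd (render=False)")
        write_mask(s.mask, outdir / f"{s.image_id}.png")
        rows.append(
            {"image_id": s.image_id, "animal_id": s.animal_id,
             "camera_height_m": s.camera_height_m, "weight_kg": s.weight_kg}
        )
    meta = outdir / "meta.csv"
    pd.DataFrame(rows).to_csv(meta, index=False)
    truth = [
        {"image_id": s.image_id, "length_px": s.length_px, "width_px": s.width_px,
         "bend_deg": s.bend_deg, "length_cm": s.length_cm, "width_cm": s.width_cm}
        for s in samples
    ]
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return meta
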