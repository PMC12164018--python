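"""Seeded synthetic initial-pressure phantoms.

Two families of 2-D initial-pressure maps stand in for experimental training
imagery: branching vessel trees (curvilinear absorbers like retinal or
subcutaneous vasculature) and smooth disk/tube cross-sections (agar-phantom
style targets).  Both are deterministic functions of an explicit seed, so a
phantom spec doubles as a reproducible dataset identifier.

Vessel trees are grown as biased random walks that branch with a fixed
probability and taper as they extend; each walk is rasterized as a tube with
a smooth (quadratic) radial profile of width 1–6 px.  Outside the tube
support the image is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PressureMap", "PhantomSpec", "generate_vessel_phantom", "generate_disk_phantom",
           "generate_phantom"]


@dataclass(frozen=True)
class PressureMap:
    """Ground-truth initial pressure on a square grid, normalized to [0, 1]."""

    values: np.ndarray
    pixel_size_mm: float = 0.1

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PressureMap requires a square 2-D array")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PressureMap values must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom; equal specs + seeds give bit-identical maps."""

    kind: str = "vessel_tree"  # or "disks"
    n_structures: int = 3
    intensity_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0
    # vessel-tree shape parameters
    branch_prob: float = 0.08
    step_px: float = 1.5
    width_decay: float = 0.985

    def __post_init__(self):
        if self.kind not in ("vessel_tree", "disks"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.n_structures < 0 or (self.kind == "vessel_tree" and self.n_structures < 1):
            raise ValueError("n_structures must be positive")
        lo, hi = self.intensity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("intensity_range must be a sub-interval of (0, 1]")


def _stamp_tube(img: np.ndarray, cx: float, cy: float, radius: float, value: float) -> None:
    """Max-composite a smooth tube cross-section centred at (cy, cx)."""
    n = img.shape[0]
    r_ext = radius + 1.0
    y0, y1 = max(0, int(cy - r_ext)), min(n, int(cy + r_ext) + 2)
    x0, x1 = max(0, int(cx - r_ext)), min(n, int(cx + r_ext) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    # smooth quadratic falloff over a 1-px rim; exactly 0 beyond the support
    prof = np.clip((radius + 1.0 - d), 0.0, 1.0)
    patch = value * np.where(d <= radius, 1.0, prof * prof)
    np.maximum(img[y0:y1, x0:x1], patch, out=img[y0:y1, x0:x1])


def generate_vessel_phantom(spec: PhantomSpec, size: int = 256) -> PressureMap:
    """Grow a branching vessel tree and rasterize it as smooth tubes.

    Walks start near the image centre region, step with angular jitter, and
    spawn child branches with probability ``spec.branch_prob`` per step.
    Tube half-width starts at 1–3 px and decays multiplicatively, with a
    floor of 0.5 px (1 px full width).  The foreground occupies roughly
    2–25 % of the image across seeds.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if spec.kind != "vessel_tree":
        raise ValueError("spec.kind must be 'vessel_tree'")
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((size, size))
    lo, hi = spec.intensity_range
    # draw until the tree covers a seeded target fraction of the image;
    # each step covers roughly step_px * (2*half_w + 2) px of fresh area
    target_frac = rng.uniform(0.05, 0.16)
    max_steps_total = max(12, int(target_frac * size * size / (spec.step_px * 7.0)))
    steps_done = 0
    margin = 0.12 * size
    queue: list[tuple[float, float, float, float, float]] = []

    def spawn():
        x = rng.uniform(margin, size - margin)
        y = rng.uniform(margin, size - margin)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        half_w = rng.uniform(1.0, 2.5)
        val = rng.uniform(lo, hi)
        queue.append((x, y, ang, half_w, val))

    for _ in range(spec.n_structures):
        spawn()
    while steps_done < max_steps_total:
        if not queue:
            spawn()  # a walk hit the boundary early; keep growing elsewhere
        x, y, ang, half_w, val = queue.pop(0)
        n_steps = int(rng.integers(size // 2, int(1.5 * size)))
        for _ in range(n_steps):
            if steps_done >= max_steps_total:
                break
            ang += rng.normal(0.0, 0.25)
            x += spec.step_px * np.cos(ang)
            y += spec.step_px * np.sin(ang)
            if not (1.0 <= x < size - 1 and 1.0 <= y < size - 1):
                break
            _stamp_tube(img, x, y, half_w, val)
            half_w = max(0.5, half_w * spec.width_decay)
            steps_done += 1
            if rng.random() < spec.branch_prob and len(queue) < 64:
                child_ang = ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.1)
                queue.append((x, y, child_ang, max(0.5, 0.75 * half_w),
                              float(np.clip(val * rng.uniform(0.85, 1.0), lo, hi))))
    return PressureMap(np.clip(img, 0.0, 1.0))


def generate_disk_phantom(spec: PhantomSpec, size: int = 256,
                          max_retries: int = 200) -> PressureMap:
    """Place ``n_structures`` anti-aliased disks with non-colliding centres."""
    if size < 32:
        raise ValueError("size must be >= 32")
    if spec.kind != "disks":
        raise ValueError("spec.kind must be 'disks'")
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((size, size))
    lo, hi = spec.intensity_range
    centers: list[tuple[float, float]] = []
    min_sep = 0.08 * size
    for _ in range(spec.n_structures):
        placed = False
        for _ in range(max_retries):
            cx = rng.uniform(0.15 * size, 0.85 * size)
            cy = rng.uniform(0.15 * size, 0.85 * size)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep**2 for px, py in centers):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.n_structures} disk centres without collision"
            )
        centers.append((cx, cy))
        radius = rng.uniform(0.03 * size, 0.12 * size)
        _stamp_tube(img, cx, cy, radius, rng.uniform(lo, hi))
    return PressureMap(np.clip(img, 0.0, 1.0))


def generate_phantom(spec: PhantomSpec, size: int = 256) -> PressureMap:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "vessel_tree":
        return generate_vessel_phantom(spec, size)
    return generate_disk_phantom(spec, size)
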