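"""Synthetic DSA-like angiogram generator.

Emulates the appearance of contrast-filled coronary arteries in digital
subtraction angiography at desk scale: a rooted branching tree of dark
tubular segments whose width tapers from a trunk of a few millimetres to
sub-millimetre terminal branches, drawn on a background containing a
smooth low-frequency intensity field, elliptical pseudo-bone blobs and
pixel noise.  Vessels are darker than the background, with a radial
cross-sectional gradient (darkest at the centerline, fading toward the
wall) so the vessel/background contrast is deliberately low near the
edge.  Independent branches may overlap; the mask is the union of all
stroked tubes, mimicking the projection superposition of 2-D DSA.

At the default scale of 0.08 mm/pixel a 2-3 mm trunk is 25-37 px wide and
0.2-0.3 mm terminals are 2-4 px, spanning the order-of-magnitude width
spread that multi-scale vessel segmentation must handle.

Geometry is sampled first (:func:`sample_tree`) as width-annotated
polylines — widths never increase from root to leaf — and rendered
separately (:func:`render`), so tests can assert on the tree structure
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import Sample, write_image, write_mask

__all__ = [
    "VesselTreeSpec",
    "RenderSpec",
    "Branch",
    "SyntheticSample",
    "sample_tree",
    "render",
    "generate_sample",
    "generate_dataset",
    "write_dataset",
]

MM_PER_PIXEL = 0.08


@dataclass(frozen=True)
class VesselTreeSpec:
    max_depth: int = 4
    branch_prob: float = 0.5
    trunk_width_mm: tuple[float, float] = (2.0, 3.0)
    terminal_width_mm: tuple[float, float] = (0.2, 0.3)
    mm_per_pixel: float = MM_PER_PIXEL
    taper_ratio: tuple[float, float] = (0.55, 0.85)
    tortuosity: float = 0.18          # std of per-step heading noise, radians
    segment_length: tuple[int, int] = (60, 140)  # pixels

    def __post_init__(self):
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must lie in [0, 1]")
        if not (0.0 < self.taper_ratio[0] <= self.taper_ratio[1] <= 1.0):
            raise ValueError("taper_ratio values must lie in (0, 1]")

    @property
    def trunk_width_px(self) -> tuple[float, float]:
        return tuple(w / self.mm_per_pixel for w in self.trunk_width_mm)

    @property
    def min_width_px(self) -> float:
        return max(self.terminal_width_mm[0] / self.mm_per_pixel, 1.0)


@dataclass(frozen=True)
class RenderSpec:
    size: int = 512
    background_level: float = 0.72
    vessel_contrast: float = 0.35     # center darkness below background
    edge_softness: float = 1.6        # px scale of the wall intensity gradient
    artifact_amplitude: float = 0.08  # low-frequency field amplitude
    blob_count: int = 3               # elliptical pseudo-bone blobs
    blob_depth: float = 0.10
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.size < 64:
            raise ValueError("size must be >= 64")


@dataclass
class Branch:
    points: np.ndarray                 # (n, 2) float (row, col)
    widths: np.ndarray                 # (n,) px, non-increasing
    depth: int
    children: list["Branch"] = field(default_factory=list)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def leaf_count(self) -> int:
        if not self.children:
            return 1
        return sum(ch.leaf_count() for ch in self.children)


@dataclass
class SyntheticSample:
    image: np.ndarray
    mask: np.ndarray
    tree: Branch
    seed: int

    def as_sample(self, sid: str | None = None) -> Sample:
        return Sample(image=self.image, mask=self.mask, id=sid or f"synthetic-{self.seed}")


def _grow_branch(
    spec: VesselTreeSpec,
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    width: float,
    depth: int,
    size: int,
) -> Branch:
    length = int(rng.integers(spec.segment_length[0], spec.segment_length[1] + 1))
    pts = [start.copy()]
    pos = start.copy()
    h = heading
    for _ in range(length):
        h += rng.normal(0.0, spec.tortuosity)
        pos = pos + np.array([np.sin(h), np.cos(h)])
        pts.append(pos.copy())
    points = np.asarray(pts, dtype=np.float32)
    # linear within-branch taper toward what a child would start at
    end_width = max(width * spec.taper_ratio[1], spec.min_width_px)
    end_width = min(end_width, width)
    widths = np.linspace(width, end_width, len(points)).astype(np.float32)
    branch = Branch(points=points, widths=widths, depth=depth)
    # growth stops at max_depth or the minimum width; branches leaving the
    # canvas keep growing and are clipped at render time
    can_branch = depth < spec.max_depth and end_width > spec.min_width_px
    if can_branch and rng.random() < spec.branch_prob:
        split = rng.uniform(0.3, 0.7)
        for sgn in (-1.0, 1.0):
            child_w = max(end_width * rng.uniform(*spec.taper_ratio), spec.min_width_px)
            child_h = h + sgn * rng.uniform(0.25, split)
            branch.children.append(
                _grow_branch(spec, rng, pos.copy(), child_h, child_w, depth + 1, size)
            )
    return branch


def sample_tree(spec: VesselTreeSpec, rng: np.random.Generator, size: int = 512) -> Branch:
    """Sample a rooted tree of width-annotated centerline polylines.

    The root enters from a random border point heading inward; headings
    evolve by bounded random turns; every child's width is its parent's
    end width scaled by a taper draw, so widths never increase from root
    to leaf; growth stops at ``max_depth`` or the minimum width.
    """
    side = int(rng.integers(0, 4))
    u = float(rng.uniform(0.2, 0.8)) * size
    # position update convention: pos += (sin h, cos h) in (row, col)
    start, heading = {
        0: (np.array([0.0, u]), np.pi / 2),        # top edge, heading down
        1: (np.array([size - 1.0, u]), -np.pi / 2),
        2: (np.array([u, 0.0]), 0.0),              # left edge, heading right
        3: (np.array([u, size - 1.0]), np.pi),
    }[side]
    trunk_w = float(rng.uniform(*spec.trunk_width_px))
    return _grow_branch(spec, rng, start, heading, trunk_w, 0, size)


def _stroke(mask: np.ndarray, branch: Branch) -> None:
    """Stamp every width-annotated centerline point as a disk."""
    H, W = mask.shape
    for br in branch.walk():
        for (r, c), w in zip(br.points, br.widths):
            # radius 0.5 floor keeps 1-px-wide branches contiguous
            rad = max((w - 1.0) / 2.0, 0.5)
            lo_r, hi_r = int(np.floor(r - rad)), int(np.ceil(r + rad))
            lo_c, hi_c = int(np.floor(c - rad)), int(np.ceil(c + rad))
            if hi_r < 0 or hi_c < 0 or lo_r >= H or lo_c >= W:
                continue
            lo_r, hi_r = max(lo_r, 0), min(hi_r, H - 1)
            lo_c, hi_c = max(lo_c, 0), min(hi_c, W - 1)
            rr = np.arange(lo_r, hi_r + 1)[:, None]
            cc = np.arange(lo_c, hi_c + 1)[None, :]
            disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2 + 1e-6
            mask[lo_r : hi_r + 1, lo_c : hi_c + 1] |= disk


def _lowfreq_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    coarse = rng.standard_normal((8, 8))
    field_ = ndimage.zoom(coarse, size / 8.0, order=3)
    field_ = field_[:size, :size]
    field_ /= max(np.abs(field_).max(), 1e-9)
    return amplitude * field_


def render(tree: Branch, spec: RenderSpec, rng: np.random.Generator, seed: int = 0) -> SyntheticSample:
    """Render a sampled tree into an image/mask pair.

    The mask is the exact union of the stroked tubes (computed before any
    noise); the image darkens the tube interior with a distance-based
    gradient, so intensity fades from the centerline to the wall.
    """
    size = spec.size
    mask = np.zeros((size, size), dtype=bool)
    _stroke(mask, tree)

    background = np.full((size, size), spec.background_level, dtype=np.float64)
    if spec.artifact_amplitude > 0:
        background += _lowfreq_field(size, spec.artifact_amplitude, rng)
    for _ in range(spec.blob_count):
        if spec.blob_depth <= 0:
            break
        cr, cc_ = rng.uniform(0, size, 2)
        a, b = rng.uniform(size / 8, size / 3, 2)
        theta = rng.uniform(0, np.pi)
        rr = np.arange(size)[:, None] - cr
        cc2 = np.arange(size)[None, :] - cc_
        u = rr * np.cos(theta) + cc2 * np.sin(theta)
        v = -rr * np.sin(theta) + cc2 * np.cos(theta)
        ellipse = (u / a) ** 2 + (v / b) ** 2
        background -= spec.blob_depth * np.exp(-ellipse * 2.0)

    image = background.copy()
    if mask.any():
        depth_in = ndimage.distance_transform_edt(mask)
        # radial gradient: darkest at the centerline, soft near the wall
        profile = np.tanh(depth_in / spec.edge_softness)
        image -= spec.vessel_contrast * profile
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, (size, size))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SyntheticSample(image=image, mask=mask.astype(np.uint8), tree=tree, seed=seed)


def scaled_specs(size: int) -> tuple[VesselTreeSpec, RenderSpec]:
    """Specs for a reduced canvas keeping the 512-px field of view.

    ``mm_per_pixel`` grows as the canvas shrinks, so trunk/terminal widths
    keep their anatomical proportions (a 2-3 mm trunk spans ~1/18 of the
    image side at any size); segment lengths scale likewise.
    """
    factor = 512 / size
    tree = VesselTreeSpec(
        mm_per_pixel=MM_PER_PIXEL * factor,
        segment_length=(max(int(60 / factor), 8), max(int(140 / factor), 16)),
    )
    return tree, RenderSpec(size=size)


def generate_sample(
    seed: int,
    tree_spec: VesselTreeSpec = VesselTreeSpec(),
    render_spec: RenderSpec = RenderSpec(),
) -> SyntheticSample:
    """Generate one fully seeded synthetic angiogram."""
    rng = np.random.default_rng(seed)
    tree = sample_tree(tree_spec, rng, size=render_spec.size)
    return render(tree, render_spec, rng, seed=seed)


def generate_dataset(
    n: int,
    seed: int,
    tree_spec: VesselTreeSpec = VesselTreeSpec(),
    render_spec: RenderSpec = RenderSpec(),
) -> list[SyntheticSample]:
    """Generate ``n`` samples; per-sample seeds derive from ``seed`` so any
    manifest of (seed, spec) pairs regenerates an identical dataset."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    return [generate_sample(int(s), tree_spec, render_spec) for s in child_seeds]


def write_dataset(samples: list[SyntheticSample], out_dir: str | Path) -> Path:
    """Write image/mask PNG pairs plus a JSON manifest of seeds."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = {"samples": []}
    for i, s in enumerate(samples):
        sid = f"sample_{i:04d}"
        write_image(out / "images" / f"{sid}.png", s.image)
        write_mask(out / "masks" / f"{sid}.png", s.mask)
        manifest["samples"].append({"id": sid, "seed": int(s.seed)})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
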