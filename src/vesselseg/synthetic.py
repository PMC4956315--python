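"""Synthetic fundus images with exact vessel ground truth.

The generator emulates the properties of DRIVE/STARE photographs that the
segmentation pipeline relies on: dark vessels of 1-8 px width on a bright
background, a circular field-of-view aperture, a smooth radial
illumination gradient, and additive sensor noise.  Vessel trees are grown
as bounded-curvature random walks from the FOV rim with monotone width
tapering and random branching; each centerline point is rendered as a
Gaussian cross-section dip (full width at half maximum equal to the local
vessel width) subtracted from the background.  The truth mask contains
every pixel within half the local width of a centerline, so sensitivity
and specificity on synthetic data are exactly defined.

Everything is driven by one integer seed through numpy's PCG64 generator;
a fixed spec reproduces the identical sample on every run.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "VesselPoint",
    "default_spec",
    "thin_spec",
    "wide_spec",
    "generate_vessel_tree",
    "render",
]


@dataclass(frozen=True)
class VesselPoint:
    """One centerline sample: position (row, col) and local full width, px."""

    row: float
    col: float
    width: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fundus sample.

    Intensities are on the [0,1] scale; widths in pixels.  The defaults
    describe a plausible small fundus frame: background 0.65 with a 0.1
    center-to-rim illumination drop, vessels 0.25 deeper than their
    surround, sensor noise sd 0.02, vessel widths spanning 1-8 px.
    """

    frame: tuple[int, int] = (256, 256)
    fov_radius: float = 118.0
    n_trees: int = 6
    width_range: tuple[float, float] = (1.0, 8.0)
    vessel_contrast: float = 0.25
    background_level: float = 0.65
    illumination_gradient: float = 0.1
    noise_sd: float = 0.02
    branching_prob: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        wmin, wmax = self.width_range
        if not (1.0 <= wmin <= wmax <= 8.0):
            raise ValueError(f"width_range must lie within [1, 8], got {self.width_range}")
        if self.fov_radius <= 0 or self.fov_radius > min(self.frame) / 2:
            raise ValueError("fov_radius must be positive and fit in the frame")
        if self.n_trees < 0 or self.noise_sd < 0:
            raise ValueError("n_trees and noise_sd must be nonnegative")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching_prob must be a probability")


@dataclass(frozen=True)
class SyntheticSample:
    """Rendered sample: (H, W, 3) color image, truth mask, FOV mask, spec."""

    image: np.ndarray
    truth: np.ndarray
    fov: np.ndarray
    spec: SyntheticSpec

    def spec_json(self) -> str:
        return json.dumps(asdict(self.spec), indent=2)


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Standard mixed-width sample (vessel widths 1-8 px)."""
    return SyntheticSpec(seed=seed, **overrides)


def thin_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Thin-only preset (widths 1-2 px) for scale-selection checks."""
    overrides.setdefault("width_range", (1.0, 2.0))
    return SyntheticSpec(seed=seed, **overrides)


def wide_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Wide-only preset (widths 6-8 px) for scale-selection checks."""
    overrides.setdefault("width_range", (6.0, 8.0))
    return SyntheticSpec(seed=seed, **overrides)


_STEP = 1.0          # centerline sampling step, px
_TURN_SD = 0.08      # random heading change per step, radians
_MAX_TURN = 0.25     # curvature bound per step, radians
_TAPER = 0.997       # per-step width decay factor
_BRANCH_RATIO = 0.65 # child width as a fraction of the parent's
_MAX_STEPS = 250     # per-branch length cap
_MAX_DEPTH = 2       # branching depth cap
_MAX_BRANCHES = 2    # child branches spawned per branch
_MAX_TREE_POINTS = 550  # total centerline samples per tree (bounds vessel area)


def _grow_branch(
    points: list[VesselPoint],
    rng: np.random.Generator,
    spec: SyntheticSpec,
    row: float,
    col: float,
    heading: float,
    width: float,
    depth: int,
) -> None:
    cy, cx = (spec.frame[0] - 1) / 2.0, (spec.frame[1] - 1) / 2.0
    wmin, wmax = spec.width_range
    n_children = 0
    for step in range(_MAX_STEPS):
        if len(points) >= _MAX_TREE_POINTS:
            break
        r = math.hypot(row - cy, col - cx)
        if r > spec.fov_radius - max(width, 2.0):
            break
        points.append(VesselPoint(row=row, col=col, width=width))
        turn = float(np.clip(rng.normal(0.0, _TURN_SD), -_MAX_TURN, _MAX_TURN))
        heading += turn
        row += _STEP * math.sin(heading)
        col += _STEP * math.cos(heading)
        width = max(width * _TAPER, wmin)
        if (
            depth < _MAX_DEPTH
            and n_children < _MAX_BRANCHES
            and step > 20
            and rng.random() < spec.branching_prob
        ):
            n_children += 1
            child_width = max(width * _BRANCH_RATIO, wmin)
            side = 1.0 if rng.random() < 0.5 else -1.0
            child_heading = heading + side * rng.uniform(0.35, 0.9)
            _grow_branch(
                points, rng, spec, row, col, child_heading, child_width, depth + 1
            )


def generate_vessel_tree(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[VesselPoint]:
    """Grow one vessel tree rooted on the FOV rim.

    The root starts just inside the aperture heading inward (with angular
    jitter); the trunk performs a bounded-curvature random walk, tapering
    monotonically, and spawns narrower children with probability
    ``branching_prob`` per step.  All recorded widths stay inside
    ``width_range`` and all points inside the FOV.
    """
    cy, cx = (spec.frame[0] - 1) / 2.0, (spec.frame[1] - 1) / 2.0
    wmin, wmax = spec.width_range
    phi = rng.uniform(0.0, 2.0 * math.pi)
    width = rng.uniform(0.5 * (wmin + wmax), wmax)    # trunks start wide
    # root just inside the walk's own stopping boundary, whatever the frame size
    r0 = min(spec.fov_radius * 0.92, spec.fov_radius - max(width, 2.0) - 1.0)
    row = cy + r0 * math.sin(phi)
    col = cx + r0 * math.cos(phi)
    heading = phi + math.pi + rng.uniform(-0.5, 0.5)  # inward, jittered
    points: list[VesselPoint] = []
    _grow_branch(points, rng, spec, row, col, heading, width, depth=0)
    return points


def _stamp(
    depth: np.ndarray, truth: np.ndarray, pts: list[VesselPoint], frame: tuple[int, int]
) -> None:
    """Accumulate Gaussian cross-section depth and the half-width truth mask."""
    h, w = frame
    for p in pts:
        s = p.width / 2.3548  # FWHM = width
        halfw = p.width / 2.0
        reach = int(math.ceil(max(2.5 * s, halfw))) + 1
        r0 = max(int(math.floor(p.row)) - reach, 0)
        r1 = min(int(math.ceil(p.row)) + reach + 1, h)
        c0 = max(int(math.floor(p.col)) - reach, 0)
        c1 = min(int(math.ceil(p.col)) + reach + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - p.row) ** 2 + (xx - p.col) ** 2
        np.maximum(
            depth[r0:r1, c0:c1],
            np.exp(-d2 / (2.0 * s * s)),
            out=depth[r0:r1, c0:c1],
        )
        truth[r0:r1, c0:c1] |= d2 <= halfw * halfw


def render(spec: SyntheticSpec) -> SyntheticSample:
    """Render a full synthetic sample from its spec, deterministically.

    The green plane carries the vessels at full contrast; the red plane is
    brighter with reduced vessel contrast and the blue plane darker with
    even less, mimicking the channel appearance of real fundus RGB.
    Outside the circular aperture all channels are black.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    fov = (r <= spec.fov_radius).astype(np.uint8)

    depth = np.zeros((h, w), dtype=np.float64)
    truth = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_trees):
        pts = generate_vessel_tree(spec, rng)
        _stamp(depth, truth, pts, spec.frame)
    truth &= fov.astype(bool)

    background = spec.background_level - spec.illumination_gradient * (
        np.clip(r / spec.fov_radius, 0.0, 1.0) ** 2
    )

    def _plane(level_shift: float, contrast_scale: float) -> np.ndarray:
        plane = (
            background
            + level_shift
            - contrast_scale * spec.vessel_contrast * depth
            + rng.normal(0.0, spec.noise_sd, size=(h, w))
        )
        return np.clip(plane, 0.0, 1.0) * fov

    red = _plane(0.15, 0.4)
    green = _plane(0.0, 1.0)
    blue = _plane(-0.25, 0.2)
    image = np.stack([red, green, blue], axis=2)
    return SyntheticSample(
        image=image, truth=truth.astype(np.uint8), fov=fov, spec=spec
    )
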