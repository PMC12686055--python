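"""Seeded synthetic fluorescence scenes with known ground truth.

Every downstream stage of the package (cluster analysis, PCC
colocalization, membrane/diffuse ratios, spine morphometry) can be
exercised without microscope data: the generators here plant puncta of
known count and area on controllable backgrounds, build channel pairs
with a chosen correlation, draw membrane-enriched dendrite
cross-sections, and sample protrusion tables strictly inside each spine
class's parameter region.  All generators take an explicit integer seed
and are bit-reproducible; there is no global RNG state.

Puncta are isotropic Gaussian spots truncated at 3σ whose "true area"
is the set of pixels above half-maximum; noise is additive Gaussian
clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log, sqrt

import numpy as np

from .calibration import Calibration
from .spines import ProtrusionMeasure, SpineRules

__all__ = [
    "SceneParams",
    "SceneTruth",
    "make_puncta_image",
    "make_coloc_pair",
    "make_membrane_scene",
    "make_protrusion_table",
    "make_protrusion_scene",
]

#: half-max radius r relates to the Gaussian σ by r = σ·sqrt(2 ln 2)
_HALF_MAX_FACTOR = sqrt(2.0 * log(2.0))


@dataclass
class SceneTruth:
    """Ground truth of one synthetic scene."""

    puncta_centers: list[tuple[int, int]] = field(default_factory=list)
    puncta_area_px: list[int] = field(default_factory=list)
    rho: float | None = None
    enrichment: float | None = None
    spine_classes: list[str] = field(default_factory=list)
    seed: int | None = None
    lines: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rho is not None and not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.enrichment is not None and not self.enrichment >= 0:
            raise ValueError("enrichment must be >= 0")


@dataclass
class SceneParams:
    """Parameters of a puncta scene."""

    image_shape: tuple[int, int] = (256, 256)
    n_puncta: int = 12
    punctum_radius_px: int = 4
    punctum_peak: float = 0.9
    background: str = "flat"  # {"flat", "linear-gradient", "low-frequency"}
    background_level: float = 0.1
    background_range: tuple[float, float] = (0.0, 0.5)
    noise_sd: float = 0.0
    min_center_distance_px: int | None = None
    calibration: Calibration = field(default_factory=lambda: Calibration(5.0 / 95.0))

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if not 0.0 <= self.punctum_peak <= 1.0:
            raise ValueError("punctum_peak must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background not in ("flat", "linear-gradient", "low-frequency"):
            raise ValueError(f"unknown background {self.background!r}")


def _background(params: SceneParams) -> np.ndarray:
    rows, cols = params.image_shape
    if params.background == "flat":
        return np.full((rows, cols), params.background_level, dtype=float)
    lo, hi = params.background_range
    if params.background == "linear-gradient":
        ramp = np.linspace(lo, hi, cols)
        return np.tile(ramp, (rows, 1))
    # low-frequency: one smooth 2D cosine mode spanning the range
    r = np.linspace(0, np.pi, rows)[:, None]
    c = np.linspace(0, 2 * np.pi, cols)[None, :]
    wave = 0.5 * (1.0 + np.cos(c) * np.sin(r))
    return lo + (hi - lo) * wave


def make_puncta_image(
    params: SceneParams,
    seed: int,
    centers: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a background plus disjoint Gaussian puncta.

    Puncta centers are drawn uniformly, rejecting draws closer than the
    minimum center distance (default 2·radius + 4 px, which keeps the
    half-maximum supports disjoint with more than 2 px of clearance) to
    any accepted center; an over-dense request fails after a bounded
    number of attempts.  Pass explicit ``centers`` to place puncta
    deterministically (they must satisfy the same separation).

    Returns the [0, 1]-clipped image and the scene truth (centers and
    per-punctum half-maximum support areas).
    """
    rng = np.random.default_rng(seed)
    rows, cols = params.image_shape
    radius = params.punctum_radius_px
    sigma = radius / _HALF_MAX_FACTOR if radius > 0 else 1.0
    support = ceil(3 * sigma)
    margin = support + 1
    min_sep = (
        params.min_center_distance_px
        if params.min_center_distance_px is not None
        else 2 * radius + 4
    )

    placed: list[tuple[int, int]] = []
    if centers is not None:
        if len(centers) != params.n_puncta:
            raise ValueError("explicit centers must match n_puncta")
        placed = [tuple(map(int, c)) for c in centers]
    else:
        max_attempts = 1000 * max(params.n_puncta, 1)
        attempts = 0
        while len(placed) < params.n_puncta:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {params.n_puncta} disjoint puncta in "
                    f"{params.image_shape} after {max_attempts} attempts "
                    "(request too dense)"
                )
            r = int(rng.integers(margin, rows - margin))
            c = int(rng.integers(margin, cols - margin))
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed):
                placed.append((r, c))

    image = _background(params)
    areas: list[int] = []
    for r, c in placed:
        r0, r1 = max(r - support, 0), min(r + support + 1, rows)
        c0, c1 = max(c - support, 0), min(c + support + 1, cols)
        dr = np.arange(r0, r1)[:, None] - r
        dc = np.arange(c0, c1)[None, :] - c
        d2 = dr**2 + dc**2
        spot = params.punctum_peak * np.exp(-d2 / (2.0 * sigma**2))
        spot[d2 > (3 * sigma) ** 2] = 0.0  # truncate at 3σ
        image[r0:r1, c0:c1] += spot
        areas.append(int(np.count_nonzero(spot >= params.punctum_peak / 2.0)))

    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    truth = SceneTruth(puncta_centers=placed, puncta_area_px=areas, seed=seed)
    return image, truth


def make_coloc_pair(n_pixels: int, rho: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw a channel pair whose expected Pearson correlation is ``rho``.

    Channel B is ``rho·S + sqrt(1 − rho²)·N`` where S is channel A's
    standardized signal and N independent standard-normal noise, so the
    limits ρ = ±1 give exact sample correlations of ±1.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    if n_pixels < 3:
        raise ValueError("need at least 3 pixels for a defined correlation")
    rng = np.random.default_rng(seed)
    chan_a = rng.normal(size=n_pixels)
    s = (chan_a - chan_a.mean()) / chan_a.std()
    noise = rng.normal(size=n_pixels)
    chan_b = rho * s + sqrt(1.0 - rho**2) * noise
    return chan_a, chan_b


def make_membrane_scene(
    enrichment: float,
    width_px: int,
    noise_sd: float,
    length_px: int = 200,
    center_level: float = 0.25,
    margin_px: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, SceneTruth]:
    """Cross-section of a dendrite with membrane-enriched edges.

    The dendrite is a horizontal band of ``width_px`` rows at
    ``center_level`` brightness whose two 1-px edge rows (the plasma
    membrane) have intensity ``enrichment × center_level`` before
    noise.  The truth carries the membrane and center line coordinates
    so the ratio can be recovered programmatically.
    """
    if not enrichment > 0:
        raise ValueError("enrichment must be > 0")
    if width_px < 5:
        raise ValueError("width_px must be >= 5")
    if enrichment * center_level > 1.0:
        raise ValueError("enrichment × center_level exceeds the brightness scale")
    rng = np.random.default_rng(seed)
    rows = width_px + 2 * margin_px
    plane = np.zeros((rows, length_px), dtype=float)
    top, bottom = margin_px, margin_px + width_px - 1
    plane[top : bottom + 1, :] = center_level
    plane[top, :] = enrichment * center_level
    plane[bottom, :] = enrichment * center_level
    if noise_sd > 0:
        plane = np.clip(plane + rng.normal(0.0, noise_sd, plane.shape), 0.0, 1.0)
    cols = np.arange(length_px)
    center_row = (top + bottom) // 2
    truth = SceneTruth(
        enrichment=enrichment,
        seed=seed,
        lines={
            "membrane1": np.column_stack([np.full(length_px, top), cols]),
            "membrane2": np.column_stack([np.full(length_px, bottom), cols]),
            "center": np.column_stack([np.full(length_px, center_row), cols]),
        },
    )
    return plane, truth


def _sample_in(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def make_protrusion_table(
    n_per_class: int,
    rules: SpineRules = SpineRules(),
    seed: int = 0,
    n_reject: int = 0,
) -> tuple[list[ProtrusionMeasure], list[str]]:
    """Sample protrusion measurements strictly inside each class region.

    Every sampled value stays ≥ 5% away from the classification and
    retention boundaries, so the intended label is unambiguous.
    Optional reject items violate one retention filter each (over-long,
    under-sized, or over-wide) and are labeled ``"reject"``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    lo_margin, hi_margin = 1.05, 0.95
    vol_floor = rules.min_volume_um3 * lo_margin
    vol_below_stubby = rules.stubby_min_volume_um3 * hi_margin
    head_below = rules.mushroom_min_head_um * hi_margin
    ratio_below = rules.mushroom_min_head_neck_ratio * hi_margin
    length_rng = (rules.min_length_um * 2, rules.max_length_um * 0.9)

    measures: list[ProtrusionMeasure] = []
    labels: list[str] = []
    idx = 0

    def add(measure: ProtrusionMeasure, label: str) -> None:
        nonlocal idx
        measure.id = idx
        idx += 1
        measures.append(measure)
        labels.append(label)

    for _ in range(n_per_class):
        head = _sample_in(rng, rules.mushroom_min_head_um * lo_margin, 0.8)
        ratio = _sample_in(rng, rules.mushroom_min_head_neck_ratio * lo_margin, 3.0)
        add(
            ProtrusionMeasure(
                length_um=_sample_in(rng, *length_rng),
                max_width_um=min(max(head, 0.5), rules.max_width_um * hi_margin),
                volume_um3=_sample_in(rng, vol_floor, 0.2),
                head_diameter_um=head,
                neck_diameter_um=head / ratio,
            ),
            "mushroom",
        )
    for _ in range(n_per_class):
        head = _sample_in(rng, 0.05, head_below)
        add(
            ProtrusionMeasure(
                length_um=_sample_in(rng, *length_rng),
                max_width_um=_sample_in(rng, 0.3, 1.0),
                volume_um3=_sample_in(rng, rules.stubby_min_volume_um3 * lo_margin, 0.2),
                head_diameter_um=head,
                neck_diameter_um=head,  # ratio 1: well below the mushroom cutoff
            ),
            "stubby",
        )
    for _ in range(n_per_class):
        head = _sample_in(rng, 0.05, head_below)
        add(
            ProtrusionMeasure(
                length_um=_sample_in(rng, *length_rng),
                max_width_um=_sample_in(rng, 0.1, 0.5),
                volume_um3=_sample_in(rng, vol_floor, vol_below_stubby),
                head_diameter_um=head,
                neck_diameter_um=head,
            ),
            "thin",
        )
    violations = ("length", "volume", "width")
    for k in range(n_reject):
        kind = violations[k % 3]
        add(
            ProtrusionMeasure(
                length_um=6.0 if kind == "length" else 1.0,
                max_width_um=3.5 if kind == "width" else 0.5,
                volume_um3=0.010 if kind == "volume" else 0.05,
                head_diameter_um=0.2,
                neck_diameter_um=0.2,
            ),
            "reject",
        )
    return measures, labels


def make_protrusion_scene(
    classes: list[str],
    seed: int = 0,
    pixel_size_um: float = 0.05,
    section_thickness_um: float = 0.4,
) -> tuple[np.ndarray, np.ndarray, SceneTruth, Calibration]:
    """Render class-labeled protrusions on a dendrite shaft.

    Builds a binary segmentation with a horizontal shaft band and one
    protrusion template per requested class, spaced so components never
    merge: *thin* is a 2-px-wide peg, *stubby* a 5-px-wide short peg,
    *mushroom* a 2-px neck carrying a radius-4 head.  Template heights
    are jittered by ±2 px from the seed.  Returns (segmentation,
    shaft_mask, truth, calibration); pass the first two to
    :func:`~dendroquant.spines.measure_protrusions`.
    """
    rng = np.random.default_rng(seed)
    spacing = 24
    height = 40
    width = spacing * (len(classes) + 1)
    seg = np.zeros((height, width), dtype=bool)
    shaft = np.zeros_like(seg)
    shaft_top = height - 6
    shaft[shaft_top : shaft_top + 4, :] = True
    seg |= shaft
    for i, cls in enumerate(classes):
        cx = spacing * (i + 1)
        jit = int(rng.integers(-2, 3))
        if cls == "thin":
            h = 15 + jit  # area 2·h ≈ 30 px → ~0.03 µm³ at defaults
            seg[shaft_top - h : shaft_top, cx : cx + 2] = True
        elif cls == "stubby":
            h = 10 + jit  # area 5·h ≈ 50 px → ~0.05 µm³
            seg[shaft_top - h : shaft_top, cx - 2 : cx + 3] = True
        elif cls == "mushroom":
            neck_h = 6 + jit
            seg[shaft_top - neck_h : shaft_top, cx : cx + 2] = True
            ball_r = 4
            ball_c_row = shaft_top - neck_h - ball_r
            rr = np.arange(height)[:, None] - ball_c_row
            cc = np.arange(width)[None, :] - (cx + 0.5)
            seg |= rr**2 + cc**2 <= ball_r**2 + 1
        else:
            raise ValueError(f"unknown spine class {cls!r}")
    truth = SceneTruth(spine_classes=list(classes), seed=seed)
    return seg, shaft, truth, Calibration(pixel_size_um, section_thickness_um)
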