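"""Synthetic data generation.

This module stands in for the optical bench and the tissue samples: it
produces Poisson-noisy coincidence-count tomography sets for Werner
states, labeled multi-replicate cohorts mimicking the animal study
layout (two transgenic strains with paired controls, two brain regions,
four replicates each, five spots per replicate, five repeated
tomographies per spot), and fluorescence-like plaque images with exact
ground truth.

The default study conditions are the source operating point
(7650 Hz coincidence rate, 80 kHz singles, 10 ns window, 1 s per
projection) and group Werner probabilities that reproduce the observed
qualitative ordering: transgenic tissue preserves entanglement better
(p near 0.95) than control tissue (p near 0.75), with a glass-slide
reference near 0.99.  The group p values are a fixture convention of
this generator, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .source import SourceParams
from .states import BellState, WernerParams, make_werner_state, projection_probability
from .tomography import (
    AnalyzerSetting,
    TomographyProjection,
    TomographySet,
    canonical_settings,
    design_matrix,
)

__all__ = [
    "GroupSpec",
    "SyntheticCohortConfig",
    "SpotMeasurement",
    "PlaqueGroundTruth",
    "expected_counts",
    "simulate_tomography_set",
    "simulate_cohort",
    "random_plaque_ground_truth",
    "simulate_plaque_image",
    "DEFAULT_GROUPS",
]


# ---------------------------------------------------------------------------
# coincidence-count simulation


def expected_counts(
    rho: np.ndarray,
    source: SourceParams,
    settings: list[AnalyzerSetting] | None = None,
    include_accidentals: bool = True,
) -> np.ndarray:
    """Noiseless expected coincidence counts for each projection.

    mean_k = R_cc · t · Tr(ρ P_k) + R_acc · t, with R_cc the total
    coincidence rate, t the integration time and R_acc the accidental
    rate of the source.
    """
    settings = settings if settings is not None else canonical_settings()
    probs = np.array([projection_probability(rho, s) for s in settings])
    mean = source.total_coincidence_rate * source.integration_time * probs
    if include_accidentals:
        mean = mean + source.accidental_rate * source.integration_time
    return mean


def simulate_tomography_set(
    rho: np.ndarray,
    source: SourceParams | None = None,
    settings: list[AnalyzerSetting] | None = None,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
    include_accidentals: bool = True,
    metadata: dict | None = None,
) -> TomographySet:
    """Simulate one 16-projection coincidence-count tomography set.

    Counts are Poisson draws around the Born-rule means (plus the
    accidental background); ``noise=False`` returns the exact means,
    which is useful for round-trip tests.  The same ``rng`` seed
    reproduces the counts bit-exactly.
    """
    source = source or SourceParams()
    settings = settings if settings is not None else canonical_settings()
    if np.linalg.matrix_rank(design_matrix(settings), tol=1e-8) != 16:
        raise ValueError("settings are not informationally complete")
    mean = expected_counts(rho, source, settings, include_accidentals)
    if noise:
        rng = np.random.default_rng(rng)
        counts = rng.poisson(mean).astype(float)
    else:
        counts = mean
    projections = [
        TomographyProjection(s, c, source.integration_time)
        for s, c in zip(settings, counts)
    ]
    return TomographySet(projections, metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class GroupSpec:
    """Werner-probability distribution of one (strain, region) group."""

    strain: str
    region: str
    label: str  # "transgenic" | "control"
    p_mean: float
    p_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mean <= 1.0:
            raise ValueError("group p mean must lie in [0, 1]")
        if self.p_sd < 0:
            raise ValueError("group p SD must be nonnegative")
        if self.label not in ("transgenic", "control"):
            raise ValueError("label must be 'transgenic' or 'control'")


def _default_groups() -> list[GroupSpec]:
    groups = []
    for region in ("cortex", "hippocampus"):
        groups += [
            GroupSpec("P301L", region, "transgenic", 0.95, 0.02),
            GroupSpec("NTL", region, "control", 0.75, 0.02),
            GroupSpec("5xFAD", region, "transgenic", 0.95, 0.02),
            GroupSpec("CD1", region, "control", 0.75, 0.02),
        ]
    return groups


DEFAULT_GROUPS = _default_groups()

#: conventional pairing of transgenic strains with their controls
STRAIN_PAIRS = {"P301L": "NTL", "5xFAD": "CD1"}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Layout and noise conditions of a synthetic cohort.

    Defaults mirror the animal study layout: 4 replicates (mice) per
    group, 5 spots per replicate, 5 repeated tomographies per spot, at
    the standard source operating point.
    """

    groups: tuple[GroupSpec, ...] = tuple(DEFAULT_GROUPS)
    replicates: int = 4
    spots_per_replicate: int = 5
    repeats_per_spot: int = 5
    source: SourceParams = field(default_factory=SourceParams)
    bell: BellState = field(default_factory=lambda: BellState("phi_plus"))
    include_accidentals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("at least one group must be specified")
        if min(self.replicates, self.spots_per_replicate, self.repeats_per_spot) < 1:
            raise ValueError("replicates, spots and repeats must all be >= 1")


@dataclass
class SpotMeasurement:
    """Repeated tomographies at one tissue spot, with cohort labels."""

    strain: str
    region: str
    label: str
    replicate_id: int
    spot_id: str
    true_p: float
    tomographies: list[TomographySet]


def _draw_truncated_p(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One Werner p from N(mean, sd²) truncated to [0, 1] (deterministic

    inverse-CDF draw so a fixed seed reproduces the value exactly)."""
    if sd == 0:
        return mean
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def simulate_cohort(config: SyntheticCohortConfig) -> list[SpotMeasurement]:
    """Simulate the full labeled cohort of spot measurements.

    Per spot, a Werner probability is drawn from the group's truncated
    normal; all repeats at that spot share the drawn p and differ only
    by counting noise.
    """
    rng = np.random.default_rng(config.seed)
    settings = canonical_settings()
    spots: list[SpotMeasurement] = []
    for group in config.groups:
        for rep in range(1, config.replicates + 1):
            for spot_idx in range(1, config.spots_per_replicate + 1):
                p = _draw_truncated_p(rng, group.p_mean, group.p_sd)
                rho = make_werner_state(WernerParams(p, config.bell))
                spot_id = f"{group.strain}-{group.region}-r{rep}-s{spot_idx}"
                tomos = [
                    simulate_tomography_set(
                        rho,
                        config.source,
                        settings,
                        rng=rng,
                        include_accidentals=config.include_accidentals,
                        metadata={
                            "spot_id": spot_id,
                            "repeat": repeat,
                            "strain": group.strain,
                            "region": group.region,
                            "replicate": rep,
                            "label": group.label,
                            "true_p": p,
                        },
                    )
                    for repeat in range(1, config.repeats_per_spot + 1)
                ]
                spots.append(
                    SpotMeasurement(
                        strain=group.strain,
                        region=group.region,
                        label=group.label,
                        replicate_id=rep,
                        spot_id=spot_id,
                        true_p=p,
                        tomographies=tomos,
                    )
                )
    return spots


# ---------------------------------------------------------------------------
# plaque image simulation


@dataclass
class PlaqueGroundTruth:
    """Exact ground truth for one synthetic plaque image."""

    shape: tuple[int, int]
    centers: list[tuple[float, float]]
    radii: list[float]
    mask: np.ndarray
    count: int
    area_fraction: float
    merged: bool  # True when overlapping disks merged into one component


def _rasterize(shape, centers, radii) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for (cy, cx), r in zip(centers, radii):
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _ground_truth(shape, centers, radii) -> PlaqueGroundTruth:
    from scipy import ndimage

    shape = tuple(int(v) for v in shape)
    for (cy, cx), r in zip(centers, radii):
        if cy - r < 0 or cx - r < 0 or cy + r >= shape[0] or cx + r >= shape[1]:
            raise ValueError("plaques must fit entirely inside the image")
    mask = _rasterize(shape, centers, radii)
    # 8-connectivity, matching the quantification stage
    _, count = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return PlaqueGroundTruth(
        shape=shape,
        centers=list(centers),
        radii=list(radii),
        mask=mask,
        count=int(count),
        area_fraction=float(mask.sum()) / (shape[0] * shape[1]),
        merged=count < len(centers),
    )


def random_plaque_ground_truth(
    n_plaques: int,
    shape: tuple[int, int] = (256, 256),
    radius_range: tuple[float, float] = (6.0, 14.0),
    rng: np.random.Generator | int | None = None,
    disjoint: bool = True,
    min_gap: float = 8.0,
    max_tries: int = 10_000,
) -> PlaqueGroundTruth:
    """Randomly place ``n_plaques`` disks inside an image, by default

    rejection-sampled to be pairwise disjoint with a gap wide enough
    (``min_gap`` px) that morphological closing cannot merge neighbors."""
    rng = np.random.default_rng(rng)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n_plaques:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place disjoint plaques; reduce n or radii")
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r + 1, shape[0] - r - 2)
        cx = rng.uniform(r + 1, shape[1] - r - 2)
        if disjoint and any(
            np.hypot(cy - y0, cx - x0) < r + r0 + min_gap
            for (y0, x0), r0 in zip(centers, radii)
        ):
            continue
        centers.append((cy, cx))
        radii.append(r)
    return _ground_truth(shape, centers, radii)


def simulate_plaque_image(
    ground_truth: PlaqueGroundTruth,
    background: float = 100.0,
    foreground: float = 600.0,
    noise_sd: float = 50.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, PlaqueGroundTruth]:
    """Render a fluorescence-like image: bright disks on a noisy background.

    SNR is (foreground − background) / noise_sd (defaults give SNR 10).
    The returned ground truth is exact for the rendered mask; the same
    seed reproduces the image bit-exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(rng)
    img = np.full(ground_truth.shape, background, dtype=float)
    img[ground_truth.mask] = foreground
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=ground_truth.shape)
    return img, ground_truth
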