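"""Cohort anthropometry and segment inertial parameters.

The body is modeled as nine rigid segments: two feet, two shanks, two
thighs, a pelvis, and a trunk segment with head and arms lumped in.  A
handheld object is an additional point mass at the hand point.  Segment
masses, lengths, center-of-mass positions and radii of gyration are
expressed as dimensionless fractions in the style of standard published
anthropometric proportion tables, scaled by each participant's body mass
and height.

Conventions used throughout the package: global X anterior, Y up, Z to the
participant's right; ``com_frac`` is measured from a segment's *lower*
(chain-distal) joint toward its upper joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: gravitational acceleration, m/s^2
G = 9.81

#: canonical segment names (bilateral segments listed per side)
SEGMENT_NAMES = (
    "pelvis",
    "trunk",
    "thigh_r",
    "thigh_l",
    "shank_r",
    "shank_l",
    "foot_r",
    "foot_l",
)


@dataclass(frozen=True)
class SegmentParams:
    """Dimensionless inertial parameters for one rigid segment.

    mass_frac
        fraction of total body mass
    length_frac
        segment length as a fraction of body height
    com_frac
        CoM position along the segment from its lower joint (0..1)
    rog_frac
        radius of gyration about the CoM, as a fraction of segment length
    """

    mass_frac: float
    length_frac: float
    com_frac: float
    rog_frac: float


# Winter-style proportions; trunk lumps head + both arms, pelvis spans the
# hip-joint midpoint to L5/S1.  Mass fractions sum to exactly 1.
DEFAULT_SEGMENT_TABLE: dict[str, SegmentParams] = {
    "pelvis": SegmentParams(0.142, 0.090, 0.50, 0.31),
    "trunk": SegmentParams(0.536, 0.330, 0.55, 0.42),
    "thigh_r": SegmentParams(0.100, 0.245, 0.567, 0.323),
    "thigh_l": SegmentParams(0.100, 0.245, 0.567, 0.323),
    "shank_r": SegmentParams(0.0465, 0.246, 0.567, 0.302),
    "shank_l": SegmentParams(0.0465, 0.246, 0.567, 0.302),
    "foot_r": SegmentParams(0.0145, 0.152, 0.50, 0.475),
    "foot_l": SegmentParams(0.0145, 0.152, 0.50, 0.475),
}

# Fixed skeletal geometry as fractions of body height.
ANKLE_HEIGHT_FRAC = 0.039
HEEL_X_FRAC = -0.045  # heel position relative to the ankle, anterior axis
HIP_HALF_WIDTH_FRAC = 0.0955
CHEST_FRAC = 0.18  # chest (hand-anchor) point above L5/S1 along the trunk


@dataclass(frozen=True)
class Anthropometry:
    """One participant's scaling parameters."""

    participant_id: str
    body_mass: float  # kg
    body_height: float  # m
    segment_params: dict[str, SegmentParams] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_TABLE)
    )
    sex: str = "na"

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.body_height <= 0:
            raise ValueError("body mass and height must be positive")
        total = sum(p.mass_frac for p in self.segment_params.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions sum to {total!r}, expected 1")

    @property
    def body_weight(self) -> float:
        """Body weight BW in newtons."""
        return self.body_mass * G

    @property
    def bwbh(self) -> float:
        """Moment normalization constant: body weight (N) x body height (m)."""
        return self.body_weight * self.body_height

    def segment_mass(self, name: str) -> float:
        return self.segment_params[name].mass_frac * self.body_mass

    def segment_length(self, name: str) -> float:
        return self.segment_params[name].length_frac * self.body_height


@dataclass(frozen=True)
class AnthroConfig:
    """Sampling distribution for the synthetic cohort.

    Heights and masses are drawn from independent truncated normals; the
    defaults reproduce the study cohort moments (1.8 +/- 0.1 m,
    79 +/- 14 kg) with truncation at +/- 2.5 sd.
    """

    height_mean: float = 1.8
    height_sd: float = 0.1
    mass_mean: float = 79.0
    mass_sd: float = 14.0
    truncation_sds: float = 2.5
    female_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.height_sd < 0 or self.mass_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.truncation_sds <= 0:
            raise ValueError("truncation bounds inverted")

    @property
    def height_bounds(self) -> tuple[float, float]:
        return (
            self.height_mean - self.truncation_sds * self.height_sd,
            self.height_mean + self.truncation_sds * self.height_sd,
        )

    @property
    def mass_bounds(self) -> tuple[float, float]:
        return (
            self.mass_mean - self.truncation_sds * self.mass_sd,
            self.mass_mean + self.truncation_sds * self.mass_sd,
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n_sds: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    return stats.truncnorm.rvs(-n_sds, n_sds, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(
    n: int,
    config: AnthroConfig | None = None,
    seed: int = 0,
    segment_table: dict[str, SegmentParams] | None = None,
) -> list[Anthropometry]:
    """Draw ``n`` participants from the cohort distribution.

    Deterministic given ``(config, seed)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or AnthroConfig()
    table = dict(segment_table or DEFAULT_SEGMENT_TABLE)
    rng = np.random.default_rng(seed)
    heights = _truncated_normal(rng, config.height_mean, config.height_sd, config.truncation_sds, n)
    masses = _truncated_normal(rng, config.mass_mean, config.mass_sd, config.truncation_sds, n)
    sexes = np.where(rng.random(n) < config.female_fraction, "f", "m")
    return [
        Anthropometry(
            participant_id=f"P{i + 1:02d}",
            body_mass=float(masses[i]),
            body_height=float(heights[i]),
            segment_params=table,
            sex=str(sexes[i]),
        )
        for i in range(n)
    ]


def cohort_mean_bwbh(cohort: list[Anthropometry]) -> float:
    """Mean body-weight x body-height normalization constant over a cohort."""
    return float(np.mean([a.bwbh for a in cohort]))
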