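"""Per-replicate structural configurations for the four heterogeneity cases.

Case (i)  : single distances, dynamically averaged kappa^2 = 2/3
Case (ii) : single distances, static kappa^2 sampled per pair
Case (iii): Gaussian distances, kappa^2 = 2/3
Case (iv) : Gaussian distances, static kappa^2 per pair

Two static-limit angle schemes are provided.  ``solid_angle`` draws
cos(theta) and cos(omega) uniformly on [-1, 1], which reproduces the
isotropic average <kappa^2> = 2/3 and is the default.  ``uniform_angle``
draws both angles uniformly on [0, 2*pi]; its kappa^2 mean is 5/4, and
it is retained for literal replication of the stated sampling recipe.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMode",
    "OrientationMode",
    "KappaScheme",
    "CaseSpec",
    "OrientationDraw",
    "Configuration",
    "sample_kappa2",
    "sample_distance",
    "sample_configuration",
    "sample_configurations",
]


class DistanceMode(str, enum.Enum):
    SINGLE = "single"
    GAUSSIAN = "gaussian"


class OrientationMode(str, enum.Enum):
    DYNAMIC = "dynamic"
    STATIC = "static"


class KappaScheme(str, enum.Enum):
    SOLID_ANGLE = "solid_angle"
    UNIFORM_ANGLE = "uniform_angle"


_CASE_TABLE = {
    "i": (DistanceMode.SINGLE, OrientationMode.DYNAMIC),
    "ii": (DistanceMode.SINGLE, OrientationMode.STATIC),
    "iii": (DistanceMode.GAUSSIAN, OrientationMode.DYNAMIC),
    "iv": (DistanceMode.GAUSSIAN, OrientationMode.STATIC),
}


@dataclass(frozen=True)
class CaseSpec:
    """How distances and orientation factors are drawn per replicate."""

    distance_mode: DistanceMode = DistanceMode.SINGLE
    orientation_mode: OrientationMode = OrientationMode.DYNAMIC
    relative_sd: float = 0.2
    kappa_scheme: KappaScheme = KappaScheme.SOLID_ANGLE

    def __post_init__(self):
        if self.distance_mode == DistanceMode.GAUSSIAN and self.relative_sd <= 0:
            raise ValueError("relative_sd must be > 0 in gaussian mode")

    @classmethod
    def from_case(
        cls,
        case: str,
        relative_sd: float = 0.2,
        kappa_scheme: KappaScheme | str = KappaScheme.SOLID_ANGLE,
    ) -> "CaseSpec":
        """Build the spec for case label 'i', 'ii', 'iii' or 'iv'."""
        key = case.lower().strip("()")
        if key not in _CASE_TABLE:
            raise ValueError(f"unknown case {case!r}; expected one of i-iv")
        dmode, omode = _CASE_TABLE[key]
        return cls(dmode, omode, relative_sd, KappaScheme(kappa_scheme))

    @property
    def case_label(self) -> str:
        for key, modes in _CASE_TABLE.items():
            if modes == (self.distance_mode, self.orientation_mode):
                return key
        raise AssertionError("unreachable")

    @property
    def is_deterministic(self) -> bool:
        """True iff a configuration draw consumes no randomness (case i)."""
        return (
            self.distance_mode == DistanceMode.SINGLE
            and self.orientation_mode == OrientationMode.DYNAMIC
        )

    def to_dict(self) -> dict:
        return {
            "case": self.case_label,
            "relative_sd": self.relative_sd,
            "kappa_scheme": self.kappa_scheme.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseSpec":
        return cls.from_case(
            d["case"],
            relative_sd=d.get("relative_sd", 0.2),
            kappa_scheme=d.get("kappa_scheme", KappaScheme.SOLID_ANGLE),
        )


@dataclass(frozen=True)
class OrientationDraw:
    """One orientation-factor draw: kappa2 = (1 + 3 cos^2 theta) cos^2 omega."""

    theta: float
    omega: float
    kappa2: float


@dataclass(frozen=True)
class Configuration:
    """One Monte Carlo realization of distances and orientation factors."""

    delta_da: np.ndarray = field(repr=False)   # (n,)
    delta_dd: np.ndarray = field(repr=False)   # (n, n), symmetric, 0 diag
    kappa2_da: np.ndarray = field(repr=False)  # (n,)
    kappa2_dd: np.ndarray = field(repr=False)  # (n, n), symmetric

    @property
    def n_donors(self) -> int:
        return self.delta_da.shape[0]


def _kappa2_from_angles(theta, omega):
    return (1.0 + 3.0 * np.cos(theta) ** 2) * np.cos(omega) ** 2


def _draw_kappa2_static(scheme: KappaScheme, rng: np.random.Generator, size):
    if scheme == KappaScheme.SOLID_ANGLE:
        theta = np.arccos(rng.uniform(-1.0, 1.0, size))
        omega = np.arccos(rng.uniform(-1.0, 1.0, size))
    else:
        theta = rng.uniform(0.0, 2.0 * np.pi, size)
        omega = rng.uniform(0.0, 2.0 * np.pi, size)
    return theta, omega, _kappa2_from_angles(theta, omega)


def sample_kappa2(spec: CaseSpec, rng: np.random.Generator) -> OrientationDraw:
    """Draw one orientation factor under the spec's orientation mode.

    Dynamic mode returns kappa2 = 2/3 without consuming randomness.
    """
    if spec.orientation_mode == OrientationMode.DYNAMIC:
        return OrientationDraw(theta=np.nan, omega=np.nan, kappa2=2.0 / 3.0)
    theta, omega, k2 = _draw_kappa2_static(spec.kappa_scheme, rng, None)
    return OrientationDraw(theta=float(theta), omega=float(omega), kappa2=float(k2))


def _draw_positive_normal(mean, sd, rng: np.random.Generator, size):
    """Normal(mean, sd) truncated to > 0 by rejection (no point mass at 0)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size), out)
        bad = out <= 0
    return out


def sample_distance(mean: float, spec: CaseSpec, rng: np.random.Generator) -> float:
    """Draw one normalized distance: the mean itself, or a positive Gaussian."""
    if mean <= 0:
        raise ValueError("mean distance must be > 0")
    if spec.distance_mode == DistanceMode.SINGLE:
        return float(mean)
    return float(_draw_positive_normal(mean, spec.relative_sd * mean, rng, None))


def sample_configurations(
    geometry,
    mean_delta_da: float,
    mean_delta_dd: float,
    spec: CaseSpec,
    rng: np.random.Generator,
    n_replicates: int,
) -> Configuration:
    """Draw a batch of configurations as stacked arrays.

    Returns a :class:`Configuration` whose arrays carry a leading
    replicate axis: ``delta_da`` has shape (R, n), ``delta_dd`` and the
    kappa2 tables (R, n, n) / (R, n).  Every unordered pair is drawn
    once and mirrored, so the D-D tables are exactly symmetric.

    The mean D-D distance for pair (i, j) is
    ``mean_delta_dd * pair_ratio[i, j]``: nearest neighbors sit at the
    nominal mean and farther shells scale with the geometry.
    """
    if mean_delta_da <= 0 or mean_delta_dd <= 0:
        raise ValueError("mean distances must be > 0")
    n = geometry.n_donors
    R = n_replicates
    iu, ju = np.triu_indices(n, k=1)
    mean_dd_pairs = mean_delta_dd * geometry.pair_ratio[iu, ju]

    if spec.distance_mode == DistanceMode.SINGLE:
        delta_da = np.full((R, n), float(mean_delta_da))
        dd_pairs = np.broadcast_to(mean_dd_pairs, (R, iu.size)).copy()
    else:
        sd = spec.relative_sd
        delta_da = _draw_positive_normal(
            mean_delta_da, sd * mean_delta_da, rng, (R, n)
        )
        dd_pairs = _draw_positive_normal(
            mean_dd_pairs, sd * mean_dd_pairs, rng, (R, iu.size)
        )

    if spec.orientation_mode == OrientationMode.DYNAMIC:
        kappa2_da = np.full((R, n), 2.0 / 3.0)
        k2_pairs = np.full((R, iu.size), 2.0 / 3.0)
    else:
        _, _, kappa2_da = _draw_kappa2_static(spec.kappa_scheme, rng, (R, n))
        _, _, k2_pairs = _draw_kappa2_static(spec.kappa_scheme, rng, (R, iu.size))

    delta_dd = np.zeros((R, n, n))
    kappa2_dd = np.zeros((R, n, n))
    delta_dd[:, iu, ju] = dd_pairs
    delta_dd[:, ju, iu] = dd_pairs
    kappa2_dd[:, iu, ju] = k2_pairs
    kappa2_dd[:, ju, iu] = k2_pairs
    return Configuration(
        delta_da=delta_da,
        delta_dd=delta_dd,
        kappa2_da=kappa2_da,
        kappa2_dd=kappa2_dd,
    )


def sample_configuration(
    geometry,
    mean_delta_da: float,
    mean_delta_dd: float,
    spec: CaseSpec,
    rng: np.random.Generator,
) -> Configuration:
    """Draw a single configuration (replicate axis squeezed away)."""
    batch = sample_configurations(
        geometry, mean_delta_da, mean_delta_dd, spec, rng, 1
    )
    return Configuration(
        delta_da=batch.delta_da[0],
        delta_dd=batch.delta_dd[0],
        kappa2_da=batch.kappa2_da[0],
        kappa2_dd=batch.kappa2_dd[0],
    )
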