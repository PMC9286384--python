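"""Discretized degree scales, degree priors, and the literal listener.

Gradable adjectives ("tall", "warm") are interpreted relative to a degree
scale. All scales are standardized so that the superordinate comparison
class (people, days of the year, ...) has a unit-normal degree
distribution; category-specific priors are Gaussians on the same scale.
Degrees live on a finite, evenly spaced grid and distributions are stored
as probability masses over the grid points.

The literal listener ``L0`` interprets an adjective with a *known*
comparison class by threshold semantics: the positive form is true of
degree ``x`` when ``x > theta``, the negative form when ``x < theta``,
where the threshold ``theta`` carries a uniform prior over the grid. The
joint over ``(x, theta)`` is proportional to
``[[u]](x, theta) * P(x | c) * P(theta)``, normalized once and then
marginalized over ``theta``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Polarity",
    "Utterance",
    "UtteranceSet",
    "DegreeGrid",
    "DegreeDistribution",
    "make_gaussian_prior",
    "literal_listener",
]

_NORM_TOL = 1e-9

#: default production costs (positive, negative, silence) for the
#: free-production speaker. Informative utterances carry a small effort
#: cost relative to staying silent; a strictly positive adjective cost
#: also anchors the degree scale of the fitted model (rescaling degree
#: priors can otherwise be traded off against the speaker optimality
#: almost exactly).
DEFAULT_COSTS = (0.5, 0.5, 0.0)

#: the endorsement speaker scores a truth judgment of a sentence the task
#: supplies: asserting carries no production cost, while declining to
#: assert (silence) is the dispreferred response in a forced judgment.
#: The cost asymmetry between the adjectives and silence is also what
#: anchors the degree scale in the joint fit (only relative costs enter
#: the soft-max), so the endorsement task keeps the same anchor strength
#: as the production task with the sign flipped.
DEFAULT_ENDORSE_COSTS = (0.0, 0.0, 0.5)


class GridError(ValueError):
    """A degree grid cannot support the requested distribution."""


class ZeroSupportError(ValueError):
    """An utterance is true at no (degree, threshold) pair with prior mass."""


class Polarity(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    SILENCE = "silence"


@dataclass(frozen=True)
class Utterance:
    """One of the speaker's alternatives: a positive-form adjective, its
    antonym, or staying silent (semantically vacuous)."""

    polarity: Polarity
    adjective_label: str = ""
    cost: float = 0.0

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"utterance cost must be nonnegative, got {self.cost}")


@dataclass(frozen=True)
class UtteranceSet:
    """The three-alternative set {positive, negative, silence}."""

    positive: Utterance
    negative: Utterance
    silence: Utterance

    def __post_init__(self) -> None:
        expected = (Polarity.POSITIVE, Polarity.NEGATIVE, Polarity.SILENCE)
        got = (self.positive.polarity, self.negative.polarity, self.silence.polarity)
        if got != expected:
            raise ValueError(f"utterance polarities must be {expected}, got {got}")

    @classmethod
    def default(
        cls,
        positive_label: str = "tall",
        negative_label: str = "short",
        costs: tuple[float, float, float] = DEFAULT_COSTS,
    ) -> "UtteranceSet":
        return cls(
            positive=Utterance(Polarity.POSITIVE, positive_label, costs[0]),
            negative=Utterance(Polarity.NEGATIVE, negative_label, costs[1]),
            silence=Utterance(Polarity.SILENCE, "", costs[2]),
        )

    def __iter__(self):
        return iter((self.positive, self.negative, self.silence))

    def costs(self) -> np.ndarray:
        return np.array([u.cost for u in self], dtype=float)


@dataclass(frozen=True)
class DegreeGrid:
    """Evenly spaced degree values on a standardized scale.

    The same grid serves as the support of both the degree ``x`` and the
    semantic threshold ``theta`` (uniform prior over the points).
    """

    points: np.ndarray
    mass_width: float = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 3:
            raise GridError("grid needs at least 3 points")
        diffs = np.diff(pts)
        if not np.all(diffs > 0):
            raise GridError("grid points must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-12):
            raise GridError("grid points must be evenly spaced")
        if not (pts[0] < 0 < pts[-1]):
            raise GridError("grid must straddle 0 (standardized scale)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "mass_width", float(diffs[0]))
        self.points.setflags(write=False)

    @classmethod
    def default(cls, lo: float = -5.0, hi: float = 5.0, n_points: int = 201) -> "DegreeGrid":
        return cls(np.linspace(lo, hi, n_points))

    @property
    def bounds(self) -> tuple[float, float]:
        return float(self.points[0]), float(self.points[-1])

    @property
    def n(self) -> int:
        return self.points.size

    def covers(self, mean: float, sd: float, n_sd: float = 4.0) -> bool:
        lo, hi = self.bounds
        return lo <= mean - n_sd * sd and mean + n_sd * sd <= hi

    def nearest_index(self, x: float) -> int:
        return int(np.argmin(np.abs(self.points - x)))

    def refine(self, factor: int = 2) -> "DegreeGrid":
        """Grid over the same bounds with spacing divided by ``factor``."""
        lo, hi = self.bounds
        return DegreeGrid(np.linspace(lo, hi, factor * (self.n - 1) + 1))


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability mass over a degree grid (one weight per grid point)."""

    grid: DegreeGrid
    mass: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.shape != self.grid.points.shape:
            raise ValueError("mass vector must match the grid")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("mass must be finite and nonnegative")
        total = m.sum()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"mass must sum to 1 (got {total!r})")
        object.__setattr__(self, "mass", m)
        self.mass.setflags(write=False)

    @property
    def mean(self) -> float:
        return float(self.grid.points @ self.mass)

    @property
    def sd(self) -> float:
        mu = self.mean
        return math.sqrt(float(((self.grid.points - mu) ** 2) @ self.mass))

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.mass)

    def reflect(self) -> "DegreeDistribution":
        """Distribution of ``-x`` (grid assumed symmetric about 0)."""
        return DegreeDistribution(self.grid, self.mass[::-1].copy(), self.label)


def gaussian_mass(mean: float, sd: float, points: np.ndarray) -> np.ndarray:
    """Gaussian density at ``points``, renormalized to a unit mass vector.

    Shifted by the minimum squared z-score before exponentiating so that
    distributions far off the grid degrade to an edge-concentrated
    truncated mass rather than underflowing to zero.
    """
    z2 = ((points - mean) / sd) ** 2
    w = np.exp(-0.5 * (z2 - z2.min()))
    return w / w.sum()


def make_gaussian_prior(
    mean: float,
    sd: float,
    grid: DegreeGrid,
    label: str = "",
    strict: bool = True,
) -> DegreeDistribution:
    """Gaussian degree prior discretized onto ``grid``.

    With ``strict=True`` (default) the grid must cover ``mean +/- 4*sd``;
    the model-fitting engine relaxes this and treats out-of-range Gaussians
    as truncated and renormalized.
    """
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    if strict and not grid.covers(mean, sd):
        raise GridError(
            f"grid {grid.bounds} does not cover mean±4sd for ({mean}, {sd})"
        )
    return DegreeDistribution(grid, gaussian_mass(mean, sd, grid.points), label)


def threshold_truth_weights(polarity: Polarity, n: int) -> np.ndarray:
    """P(utterance true at grid index j) under the uniform threshold prior.

    Positive form: true iff x > theta, so the weight at index j is the number
    of threshold points strictly below j, over n. Negative: x < theta. Silence
    is true everywhere. Strict inequalities throughout, so the grid point tied
    with the threshold never satisfies either polar form.
    """
    idx = np.arange(n, dtype=float)
    if polarity is Polarity.POSITIVE:
        return idx / n
    if polarity is Polarity.NEGATIVE:
        return (n - 1 - idx) / n
    return np.ones(n)


def literal_listener(u: Utterance, prior: DegreeDistribution) -> DegreeDistribution:
    """Literal interpretation L0(x | u, c) of ``u`` given the class prior.

    Joint over (x, theta) proportional to ``[[u]](x,theta) P(x|c) P(theta)``,
    normalized and then marginalized over theta. For silence the posterior
    equals the prior exactly.
    """
    if u.polarity is Polarity.SILENCE:
        return prior
    w = threshold_truth_weights(u.polarity, prior.grid.n)
    unnorm = prior.mass * w
    total = unnorm.sum()
    if total <= 0:
        raise ZeroSupportError(
            f"'{u.adjective_label or u.polarity.value}' is true at no degree "
            "with prior mass"
        )
    return DegreeDistribution(prior.grid, unnorm / total, prior.label)
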