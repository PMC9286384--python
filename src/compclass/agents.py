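"""Recursive Rational Speech Act agents for comparison-class inference.

The speaker ``S1`` chooses among {positive adjective, negative adjective,
silence} to convey a degree ``x`` to a literal listener, by soft-max
utility with rationality ``alpha``:

    S1(u | x, c) ∝ exp(alpha * (ln L0(x | u, c) − cost(u)))

The pragmatic listener ``L1`` hears an utterance with *no* explicit
comparison class and jointly infers the degree and the class, using the
degree prior of the referent's known category ``k`` and the class prior:

    L1(x, c | u, k) ∝ S1(u | x, c) * P(x | k) * P(c | k)

A rival non-pragmatic ("literal") class listener updates on the literal
threshold semantics only:

    L0(x, theta, c | u, k) ∝ [[u]](x, theta) * P(x | c) * P(theta) * P(c | k)

with theta marginalized out. It predicts the *opposite* interaction
between world knowledge and adjective polarity: it asks which class makes
a literally-true degree more probable, rather than which class a
cooperative speaker would have assumed.

The endorsement submodel predicts truth judgments for adjectives with an
*explicit* comparison class ("cold relative to other days of the year")
as the expected speaker production probability of the adjective under the
referent category's degree prior, with its own rationality ``alpha2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import (
    DegreeDistribution,
    Polarity,
    Utterance,
    UtteranceSet,
    threshold_truth_weights,
)

__all__ = [
    "SpeakerConfig",
    "ClassHypothesis",
    "ListenerPosterior",
    "speaker_matrix",
    "speaker",
    "pragmatic_listener",
    "literal_class_listener",
    "endorsement_prob",
]


class DegenerateStateError(ValueError):
    """No utterance/state combination carries probability mass."""


@dataclass(frozen=True)
class SpeakerConfig:
    """Speaker rationality and alternative set."""

    alpha: float = 1.0
    utterances: UtteranceSet = field(default_factory=UtteranceSet.default)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")


@dataclass(frozen=True)
class ClassHypothesis:
    """Two-class hypothesis space: (subordinate, superordinate) degree
    distributions sharing one grid, and the prior probability of the
    subordinate class."""

    subordinate: DegreeDistribution
    superordinate: DegreeDistribution
    prior: float  # P(c = subordinate | k)

    def __post_init__(self) -> None:
        if not (0.0 <= self.prior <= 1.0):
            raise ValueError(f"class prior must lie in [0, 1], got {self.prior}")
        if self.subordinate.grid is not self.superordinate.grid and not np.array_equal(
            self.subordinate.grid.points, self.superordinate.grid.points
        ):
            raise ValueError("both class distributions must share one grid")


@dataclass(frozen=True)
class ListenerPosterior:
    """Joint listener posterior over (degree, class).

    ``joint`` has shape (n_grid, 2); column 0 is the subordinate class.
    """

    joint: np.ndarray
    grid_points: np.ndarray

    @property
    def class_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    @property
    def p_subordinate(self) -> float:
        return float(self.joint[:, 0].sum())

    @property
    def degree_marginal_mass(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    def degree_marginal(self, grid) -> DegreeDistribution:
        return DegreeDistribution(grid, self.degree_marginal_mass)


def _log_l0_matrix(prior_mass: np.ndarray) -> np.ndarray:
    """ln L0(x | u, c) for the three alternatives; shape (3, n).

    Rows follow UtteranceSet order: positive, negative, silence. Uses the
    jointly normalized threshold semantics. Zero-mass cells are -inf.
    """
    n = prior_mass.size
    out = np.empty((3, n))
    with np.errstate(divide="ignore"):
        for i, pol in enumerate((Polarity.POSITIVE, Polarity.NEGATIVE)):
            w = prior_mass * threshold_truth_weights(pol, n)
            total = w.sum()
            if total <= 0:
                raise DegenerateStateError(f"{pol.value} utterance has zero support")
            out[i] = np.log(w) - np.log(total)
        out[2] = np.log(prior_mass)
    return out


def speaker_matrix(
    class_prior: DegreeDistribution, cfg: SpeakerConfig
) -> np.ndarray:
    """S1(u | x, c) for every grid point; shape (3, n_grid).

    Soft-max over utterances of alpha * (ln L0 − cost), computed in log
    space with max subtraction. Utterances with zero literal-listener mass
    at x get probability 0; if all three do (cannot happen while silence
    has the prior's support), the column is degenerate.
    """
    n = class_prior.grid.n
    if cfg.alpha == 0:
        # soft-max flattens completely; by convention every alternative is
        # produced uniformly, including ones with zero literal support
        return np.full((3, n), 1.0 / 3.0)
    logl0 = _log_l0_matrix(class_prior.mass)
    util = cfg.alpha * (logl0 - cfg.utterances.costs()[:, None])
    # columns where the prior itself is 0 are never visited by callers that
    # weight by a prior supported on the grid; normalize where possible
    colmax = util.max(axis=0)
    degenerate = ~np.isfinite(colmax)
    with np.errstate(invalid="ignore"):
        p = np.exp(util - colmax)
    p[:, degenerate] = np.nan
    denom = p.sum(axis=0)
    p = np.where(degenerate, np.nan, p / denom)
    return p


def speaker(
    x: float, class_prior: DegreeDistribution, cfg: SpeakerConfig
) -> dict[str, float]:
    """Speaker distribution over the three alternatives at degree ``x``.

    ``x`` must lie on (or is snapped to the nearest point of) the grid.
    """
    j = class_prior.grid.nearest_index(x)
    col = speaker_matrix(class_prior, cfg)[:, j]
    if not np.all(np.isfinite(col)):
        raise DegenerateStateError(
            f"all utterances assign zero literal-listener mass to x={x}"
        )
    return {
        "positive": float(col[0]),
        "negative": float(col[1]),
        "silence": float(col[2]),
    }


def _utterance_row(u: Utterance) -> int:
    return {Polarity.POSITIVE: 0, Polarity.NEGATIVE: 1, Polarity.SILENCE: 2}[u.polarity]


def pragmatic_listener(
    u: Utterance,
    k_prior: DegreeDistribution,
    hyp: ClassHypothesis,
    cfg: SpeakerConfig,
) -> ListenerPosterior:
    """L1 posterior over (degree, comparison class) after hearing ``u``.

    ``k_prior`` is the degree prior of the referent's known (subordinate)
    category; in the standard setup it equals ``hyp.subordinate``.
    """
    row = _utterance_row(u)
    s_sub = speaker_matrix(hyp.subordinate, cfg)[row]
    s_super = speaker_matrix(hyp.superordinate, cfg)[row]
    joint = np.empty((k_prior.grid.n, 2))
    joint[:, 0] = np.nan_to_num(s_sub) * k_prior.mass * hyp.prior
    joint[:, 1] = np.nan_to_num(s_super) * k_prior.mass * (1.0 - hyp.prior)
    total = joint.sum()
    if total <= 0:
        raise DegenerateStateError(
            "pragmatic listener: zero normalization constant"
        )
    return ListenerPosterior(joint / total, k_prior.grid.points)


def literal_class_listener(u: Utterance, hyp: ClassHypothesis) -> ListenerPosterior:
    """Non-pragmatic class inference via literal semantics only (rival model).

    Joint over (x, theta, c) ∝ [[u]](x, theta) P(x|c) P(theta) P(c|k),
    normalized once; theta marginalized out.
    """
    n = hyp.subordinate.grid.n
    w = threshold_truth_weights(u.polarity, n)
    joint = np.empty((n, 2))
    joint[:, 0] = hyp.subordinate.mass * w * hyp.prior
    joint[:, 1] = hyp.superordinate.mass * w * (1.0 - hyp.prior)
    total = joint.sum()
    if total <= 0:
        raise DegenerateStateError("literal class listener: zero support")
    return ListenerPosterior(joint / total, hyp.subordinate.grid.points)


def endorsement_prob(
    u: Utterance,
    k_prior: DegreeDistribution,
    explicit_class: DegreeDistribution,
    alpha2: float,
    utterances: UtteranceSet | None = None,
) -> float:
    """Probability of endorsing ``u`` with an explicit comparison class.

    Expected production probability of ``u`` by a speaker with rationality
    ``alpha2`` who knows the class, averaged over the referent category's
    degree prior: sum_x P(x|k) S1(u | x, explicit_class; alpha2). The
    judged sentence is given, so by default the alternatives are compared
    cost-free.
    """
    from .grids import DEFAULT_ENDORSE_COSTS

    cfg = SpeakerConfig(
        alpha=alpha2,
        utterances=utterances
        or UtteranceSet.default(
            u.adjective_label if u.polarity is Polarity.POSITIVE else "",
            u.adjective_label if u.polarity is Polarity.NEGATIVE else "",
            costs=DEFAULT_ENDORSE_COSTS,
        ),
    )
    s = speaker_matrix(explicit_class, cfg)[_utterance_row(u)]
    return float(np.nan_to_num(s) @ k_prior.mass)
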