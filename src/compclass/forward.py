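"""Vectorized forward model over a battery of items.

Maps a parameter vector (speaker optimalities, per-category Gaussian
degree-prior parameters, class-prior coefficients) to the two behavioral
probabilities the data analysis needs for every (category, polarity) cell:

* ``p_cc`` — the listener's posterior probability of the *subordinate*
  comparison class after hearing the bare adjective (comparison-class
  inference task);
* ``p_endorse`` — the probability of endorsing the adjective with an
  explicit (superordinate) comparison class (adjective endorsement task).

Everything is computed on a shared degree grid with the superordinate
degree prior fixed at the standard normal. The per-category math is the
same as in :mod:`compclass.agents` but batched across categories, which
is what makes desk-scale MCMC feasible; agreement between the two routes
is enforced by the test suite's brute-force oracle.

Gaussian degree priors proposed during fitting may extend past the grid;
they are treated as truncated to the grid and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .class_priors import ClassPriorParams, ItemMeta, class_prior_vector
from .grids import (
    DEFAULT_COSTS,
    DEFAULT_ENDORSE_COSTS,
    DegreeGrid,
    Polarity,
    threshold_truth_weights,
)

__all__ = ["ForwardEngine", "CellProbs"]

_POLS = (Polarity.POSITIVE, Polarity.NEGATIVE)


@dataclass(frozen=True)
class CellProbs:
    """Model probabilities per category, columns = (positive, negative)."""

    p_cc: np.ndarray  # (C, 2) P(c_sub | utterance, k)
    p_endorse: np.ndarray  # (C, 2) endorsement probability


def batch_gaussian_mass(points: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Row-normalized Gaussian masses, shape (len(mean), len(points)).

    The squared z-scores are shifted by their row minimum before
    exponentiating, so distributions centered far off the grid still yield
    a well-defined (edge-concentrated) truncated mass instead of 0/0.
    """
    z = (points[None, :] - np.asarray(mean, float)[:, None]) / np.asarray(sd, float)[:, None]
    z2 = z * z
    z2 -= z2.min(axis=1, keepdims=True)
    m = np.exp(-0.5 * z2)
    return m / m.sum(axis=1, keepdims=True)


def speaker_probs_batch(mass: np.ndarray, alpha: float, costs: np.ndarray) -> np.ndarray:
    """S1(u | x, c) for a batch of class masses; shape (3, C, G).

    Utterance order (positive, negative, silence). ``mass`` rows must be
    normalized. Zero-mass grid points yield zero speaker probability for
    every informative utterance and are only visited weighted by priors.
    """
    if alpha == 0:
        return np.full((3,) + mass.shape, 1.0 / 3.0)
    n = mass.shape[1]
    wpos = threshold_truth_weights(Polarity.POSITIVE, n)
    wneg = threshold_truth_weights(Polarity.NEGATIVE, n)
    a = mass * wpos
    b = mass * wneg
    with np.errstate(divide="ignore"):
        logl0 = np.stack(
            [
                np.log(a) - np.log(a.sum(axis=1, keepdims=True)),
                np.log(b) - np.log(b.sum(axis=1, keepdims=True)),
                np.log(mass),
            ]
        )
    util = alpha * (logl0 - costs[:, None, None])
    colmax = util.max(axis=0)
    dead = ~np.isfinite(colmax)  # grid points with zero mass under this class
    util -= np.where(dead, 0.0, colmax)
    np.exp(util, out=util)
    with np.errstate(invalid="ignore"):
        util /= util.sum(axis=0)
    if dead.any():
        util[:, dead] = 0.0
    return util


class ForwardEngine:
    """Batched predictions for a fixed item battery.

    Parameters
    ----------
    items
        One :class:`ItemMeta` per subordinate category, fixing the order of
        all per-category arrays.
    grid
        Shared degree grid (default [-5, 5] with 201 points).
    costs
        Utterance costs (positive, negative, silence).
    listener
        ``"pragmatic"`` for the full RSA listener or ``"literal"`` for the
        rival threshold-only class listener.
    """

    def __init__(
        self,
        items: Sequence[ItemMeta],
        grid: DegreeGrid | None = None,
        costs: tuple[float, float, float] = DEFAULT_COSTS,
        listener: str = "pragmatic",
        endorse_costs: tuple[float, float, float] = DEFAULT_ENDORSE_COSTS,
    ) -> None:
        if listener not in ("pragmatic", "literal"):
            raise ValueError(f"listener must be 'pragmatic' or 'literal', got {listener!r}")
        self.items = list(items)
        self.grid = grid or DegreeGrid.default()
        self.costs = np.asarray(costs, dtype=float)
        self.endorse_costs = np.asarray(endorse_costs, dtype=float)
        self.listener = listener
        self.n_categories = len(self.items)
        pts = self.grid.points
        self._super_mass = batch_gaussian_mass(pts, np.array([0.0]), np.array([1.0]))
        self._w = np.stack(
            [threshold_truth_weights(p, self.grid.n) for p in _POLS]
        )  # (2, G)

    # -- building blocks ---------------------------------------------------

    def sub_mass(self, sub_mean: np.ndarray, sub_sd: np.ndarray) -> np.ndarray:
        """Truncated-Gaussian degree priors for the subordinate categories."""
        return batch_gaussian_mass(self.grid.points, sub_mean, sub_sd)

    def super_speaker(self, alpha: float) -> np.ndarray:
        """Production-speaker probabilities for the superordinate class,
        rows (positive, negative); shape (2, G)."""
        return speaker_probs_batch(self._super_mass, alpha, self.costs)[:2, 0, :]

    def endorse_super_speaker(self, alpha2: float) -> np.ndarray:
        """Endorsement-speaker probabilities (cost-free alternatives) for
        the superordinate class; shape (2, G)."""
        return speaker_probs_batch(self._super_mass, alpha2, self.endorse_costs)[:2, 0, :]

    def informativity(self, mass: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """Evidence terms of the class inference, both shape (C, 2).

        ``own[j, p]`` integrates the production probability of polarity p
        assuming the subordinate class against the referent's degree prior
        (= that same subordinate prior); ``other[j, p]`` does the same
        assuming the superordinate class. For the literal listener these
        are the literal truth probabilities instead.
        """
        if self.listener == "literal":
            own = mass @ self._w.T
            other = np.broadcast_to(self._super_mass[0] @ self._w.T, own.shape)
            return own, other
        s_sub = speaker_probs_batch(mass, alpha, self.costs)  # (3, C, G)
        own = np.stack(
            [(s_sub[0] * mass).sum(axis=1), (s_sub[1] * mass).sum(axis=1)], axis=1
        )
        other = mass @ self.super_speaker(alpha).T
        return own, other

    @staticmethod
    def cc_prob(own: np.ndarray, other: np.ndarray, p_sub_prior: np.ndarray) -> np.ndarray:
        """Posterior P(c_sub | u, k) from evidence terms and the class prior."""
        p = np.asarray(p_sub_prior, float)[:, None]
        num = p * own
        den = num + (1.0 - p) * other
        with np.errstate(invalid="ignore"):
            out = num / den
        return np.where(den > 0, out, np.nan)

    def endorse_prob(self, mass: np.ndarray, alpha2: float) -> np.ndarray:
        """Endorsement probabilities with the explicit superordinate class,
        shape (C, 2)."""
        return mass @ self.endorse_super_speaker(alpha2).T

    # -- one-call surface --------------------------------------------------

    def predict(
        self,
        alpha1: float,
        alpha2: float,
        sub_mean: np.ndarray,
        sub_sd: np.ndarray,
        class_params: ClassPriorParams,
    ) -> CellProbs:
        mass = self.sub_mass(sub_mean, sub_sd)
        own, other = self.informativity(mass, alpha1)
        p_c = class_prior_vector(class_params, self.items)
        return CellProbs(
            p_cc=self.cc_prob(own, other, p_c),
            p_endorse=self.endorse_prob(mass, alpha2),
        )
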