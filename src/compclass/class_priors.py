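"""Parameterizations of the comparison-class prior P(c | k).

Four model variants differ in how the prior probability of the
subordinate comparison class is built from item metadata:

* ``flat`` — both classes equally likely (0.5 exactly).
* ``basic`` — intercept-only basic-level bias. Two intercepts: ``beta00``
  applies when the named (subordinate) category is itself subordinate-level
  (so the paired superordinate NP is a basic-level category); ``beta01``
  applies when the named category is basic-level (paired with a true
  superordinate).
* ``freq`` — slope ``beta1`` on the log corpus-frequency ratio of the
  subordinate NP to the superordinate NP.
* ``basic_freq`` — both intercepts and the frequency slope.

The link is logit-linear: P(c_sub | k) = logistic(b0 + b1 * log_freq_ratio).
The logistic form is this package's design choice, isolated here so it can
be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "VARIANTS",
    "ItemMeta",
    "ClassPriorParams",
    "class_prior",
    "imputed_level_probs",
]

#: pragmatic-listener variants; "literal" (rival listener) is handled in bda
VARIANTS = ("flat", "basic", "freq", "basic_freq")

EXPECTATION_LEVELS = ("low", "mid", "high")


class UnsupportedVariantError(ValueError):
    """Operation undefined for this class-prior variant."""


@dataclass(frozen=True)
class ItemMeta:
    """Design metadata for one subordinate category within an item set."""

    item_id: str
    subordinate_label: str
    superordinate_label: str
    expectation_level: str  # low / mid / high position on the degree scale
    log_freq_ratio: float  # ln(freq_sub / freq_super); typically negative
    sub_is_basic: bool  # named category is basic-level (superordinate is a
    # true superordinate) rather than subordinate-level

    def __post_init__(self) -> None:
        if self.expectation_level not in EXPECTATION_LEVELS:
            raise ValueError(
                f"expectation_level must be one of {EXPECTATION_LEVELS}, "
                f"got {self.expectation_level!r}"
            )
        if not np.isfinite(self.log_freq_ratio):
            raise ValueError("log_freq_ratio must be finite")


@dataclass(frozen=True)
class ClassPriorParams:
    """Intercepts and frequency slope of the comparison-class prior.

    Parameters unused by the variant are ignored (flat uses none, basic
    the intercepts only, freq the slope only).
    """

    variant: str = "basic_freq"
    beta00: float = 0.0
    beta01: float = 0.0
    beta1: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def has_intercepts(self) -> bool:
        return self.variant in ("basic", "basic_freq")

    @property
    def has_slope(self) -> bool:
        return self.variant in ("freq", "basic_freq")

    @property
    def free_names(self) -> tuple[str, ...]:
        names: tuple[str, ...] = ()
        if self.has_intercepts:
            names += ("beta00", "beta01")
        if self.has_slope:
            names += ("beta1",)
        return names


def class_prior(params: ClassPriorParams, item: ItemMeta) -> float:
    """Prior probability of the subordinate comparison class for ``item``."""
    if params.variant == "flat":
        return 0.5
    b0 = 0.0
    if params.has_intercepts:
        b0 = params.beta01 if item.sub_is_basic else params.beta00
    b1 = params.beta1 if params.has_slope else 0.0
    return float(expit(b0 + b1 * item.log_freq_ratio))


def class_prior_vector(params: ClassPriorParams, items) -> np.ndarray:
    """Vectorized :func:`class_prior` over a sequence of items."""
    if params.variant == "flat":
        return np.full(len(items), 0.5)
    basic = np.array([it.sub_is_basic for it in items], dtype=bool)
    ratio = np.array([it.log_freq_ratio for it in items], dtype=float)
    b0 = np.where(basic, params.beta01, params.beta00) if params.has_intercepts else 0.0
    b1 = params.beta1 if params.has_slope else 0.0
    return expit(b0 + b1 * ratio)


def imputed_level_probs(
    params: ClassPriorParams, reference_log_freq_ratio: float = 0.0
) -> dict[str, float]:
    """Impute a three-level class prior over {subordinate, basic, superordinate}.

    Chains the two pairwise intercepts by log-odds relative to the basic
    level (assuming a constant frequency effect at the reference ratio):
    ``beta00 + beta1*r`` is the log-odds of subordinate vs. basic and
    ``beta01 + beta1*r`` the log-odds of basic vs. superordinate, so

        w_sub = exp(beta00 + beta1*r),  w_basic = 1,
        w_super = exp(-(beta01 + beta1*r)),

    renormalized jointly. Zero intercepts at r = 0 give the uniform prior.
    """
    if not params.has_intercepts:
        raise UnsupportedVariantError(
            f"three-level imputation needs intercepts; variant={params.variant!r}"
        )
    r = reference_log_freq_ratio
    b1 = params.beta1 if params.has_slope else 0.0
    log_w = np.array([params.beta00 + b1 * r, 0.0, -(params.beta01 + b1 * r)])
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    return {"subordinate": float(w[0]), "basic": float(w[1]), "superordinate": float(w[2])}
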