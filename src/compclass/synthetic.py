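"""Synthetic item designs and behavioral datasets.

Emulates the structure of the free-production comparison-class study: item
sets of three subordinate categories at the low, middle and high end of a
degree scale, nested under one superordinate category, each paired with a
positive- and a negative-form adjective, with ~50 binary responses per
item per task. Counts are drawn from the package's own generative model
(pragmatic listener for class-inference responses, endorsement submodel
for truth judgments), so the full analysis pipeline can run with no
external download and with known ground-truth parameters.

Also implements the free-response coding rule used for the real task:
a paraphrase counts as *subordinate* iff it contains the subordinate NP as
a substring (case- and plural-insensitive), else *superordinate*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bda import BehavioralDataset, ParameterVector
from .class_priors import ClassPriorParams, ItemMeta
from .forward import ForwardEngine
from .grids import DegreeGrid

__all__ = [
    "ADJECTIVE_PAIRS",
    "ItemDesign",
    "make_item_design",
    "default_theta",
    "simulate_dataset",
    "simulate_responses",
    "code_response",
    "interaction_stat",
]

#: positive/negative adjective pairs for the physical-dimension scales the
#: study design draws on
ADJECTIVE_PAIRS = (
    ("big", "small"),
    ("tall", "short"),
    ("expensive", "cheap"),
    ("warm", "cold"),
    ("hot", "cold"),
    ("heavy", "light"),
    ("long", "short"),
    ("loud", "quiet"),
    ("noisy", "quiet"),
    ("light", "dark"),
    ("fast", "slow"),
    ("quick", "slow"),
    ("strong", "weak"),
    ("hard", "soft"),
    ("wide", "narrow"),
)

LEVELS = ("low", "mid", "high")

#: generating degree-prior means per expectation level (standardized scale)
DEFAULT_LEVEL_MEANS = {"low": -1.0, "mid": 0.0, "high": 1.0}
DEFAULT_SUB_SD = 0.5

#: generating global parameters, mimicking fitted values so the synthetic
#: regime is realistic: speaker optimalities, basic-level intercepts and
#: frequency slope
DEFAULT_GLOBALS = {
    "alpha1": 1.5,
    "alpha2": 5.0,
    "beta00": -0.1,
    "beta01": 1.6,
    "beta1": 0.2,
}


@dataclass(frozen=True)
class ItemDesign:
    """Item battery plus the generating degree-prior geometry."""

    items: list[ItemMeta]
    true_sub_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_MEANS)
    )
    true_sub_sd: float = DEFAULT_SUB_SD
    adjective_pairs: tuple[tuple[str, str], ...] = ADJECTIVE_PAIRS

    def __post_init__(self) -> None:
        if len(self.items) % 3:
            raise ValueError("items must come in sets of three")
        for s in range(len(self.items) // 3):
            levels = {it.expectation_level for it in self.items[3 * s : 3 * s + 3]}
            if levels != set(LEVELS):
                raise ValueError(
                    f"item set {s} must contain levels {LEVELS} exactly once"
                )

    @property
    def n_sets(self) -> int:
        return len(self.items) // 3

    def sub_mean_vector(self) -> np.ndarray:
        return np.array([self.true_sub_means[it.expectation_level] for it in self.items])

    def sub_sd_vector(self) -> np.ndarray:
        return np.full(len(self.items), self.true_sub_sd)


def make_item_design(n_sets: int, seed: int = 0) -> ItemDesign:
    """Deterministic-for-seed item battery of ``n_sets`` sets x 3 categories.

    Log corpus-frequency ratios are drawn Normal(-1.5, 1): superordinate
    NPs are typically more frequent, so the ratio of subordinate to
    superordinate frequency is usually negative. Whether the subordinate
    NPs of a set are themselves basic-level categories is Bernoulli(0.5)
    per set.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 101])))
    items: list[ItemMeta] = []
    for s in range(n_sets):
        sub_is_basic = bool(rng.uniform() < 0.5)
        super_label = f"group{s:03d}"
        for level in LEVELS:
            items.append(
                ItemMeta(
                    item_id=f"set{s:03d}_{level}",
                    subordinate_label=f"{level} member {s:03d}",
                    superordinate_label=super_label,
                    expectation_level=level,
                    log_freq_ratio=float(rng.normal(-1.5, 1.0)),
                    sub_is_basic=sub_is_basic,
                )
            )
    return ItemDesign(items=items)


def default_theta(
    design: ItemDesign,
    variant: str = "basic_freq",
    **overrides: float,
) -> ParameterVector:
    """Generating parameter vector for ``design`` at the default regime."""
    g = {**DEFAULT_GLOBALS, **overrides}
    cp = ClassPriorParams(
        variant=variant, beta00=g["beta00"], beta01=g["beta01"], beta1=g["beta1"]
    )
    return ParameterVector(
        alpha1=g["alpha1"],
        alpha2=g["alpha2"],
        sub_mean=design.sub_mean_vector(),
        sub_sd=design.sub_sd_vector(),
        class_params=cp,
    )


def simulate_dataset(
    design: ItemDesign,
    theta: ParameterVector,
    n_cc_per_cell: int = 50,
    n_endorse_per_cell: int = 50,
    seed: int = 0,
    grid: DegreeGrid | None = None,
    listener: str = "pragmatic",
) -> BehavioralDataset:
    """Binomial counts for both tasks from the generative model at ``theta``.

    Per (category, polarity) cell, subordinate-class responses are
    Binomial(n, p) with p the pragmatic listener's subordinate-class
    posterior, and endorsements Binomial(n, e) with e the endorsement
    probability for the explicit superordinate class.
    """
    engine = ForwardEngine(design.items, grid=grid, listener=listener)
    probs = engine.predict(
        theta.alpha1, theta.alpha2, theta.sub_mean, theta.sub_sd, theta.class_params
    )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 202])))
    cc_rows, en_rows = [], []
    for j, it in enumerate(design.items):
        for p, pol in enumerate(("positive", "negative")):
            cc_rows.append(
                {
                    "item_id": it.item_id,
                    "polarity": pol,
                    "n_sub": int(rng.binomial(n_cc_per_cell, probs.p_cc[j, p]))
                    if n_cc_per_cell
                    else 0,
                    "n_total": n_cc_per_cell,
                }
            )
            en_rows.append(
                {
                    "item_id": it.item_id,
                    "polarity": pol,
                    "explicit_class": "super",
                    "n_yes": int(rng.binomial(n_endorse_per_cell, probs.p_endorse[j, p]))
                    if n_endorse_per_cell
                    else 0,
                    "n_total": n_endorse_per_cell,
                }
            )
    return BehavioralDataset(
        items=list(design.items),
        cc_counts=pd.DataFrame(cc_rows),
        endorse_counts=pd.DataFrame(en_rows),
    )


# ---------------------------------------------------------------------------
# free-response coding
# ---------------------------------------------------------------------------


def _normalize(text: str, synonym_map: dict[str, str] | None) -> str:
    tokens = text.lower().split()
    if synonym_map:
        syn = {k.lower(): v.lower() for k, v in synonym_map.items()}
        tokens = [syn.get(t, t) for t in tokens]
    # plural-insensitive: strip one trailing "s" per token
    tokens = [t[:-1] if t.endswith("s") and len(t) > 1 else t for t in tokens]
    return " ".join(tokens)


def code_response(
    raw_text: str,
    subordinate_np: str,
    synonym_map: dict[str, str] | None = None,
) -> str:
    """Code a paraphrase completion as ``"subordinate"`` or ``"superordinate"``.

    Subordinate iff the normalized response contains the normalized
    subordinate NP as a substring. Normalization lowercases, collapses
    whitespace, applies the optional synonym map token-wise, and strips one
    trailing "s" per token so that plural forms match.
    """
    if not subordinate_np or not subordinate_np.strip():
        raise ValueError("subordinate_np must be a non-empty string")
    target = _normalize(subordinate_np, synonym_map)
    return "subordinate" if target in _normalize(raw_text, synonym_map) else "superordinate"


def _pluralize(label: str) -> str:
    return label if label.endswith("s") else label + "s"


def simulate_responses(
    design: ItemDesign, data: BehavioralDataset
) -> pd.DataFrame:
    """Templated raw-text responses consistent with the simulated counts.

    Purely to exercise the coding rule: each subordinate-coded response is
    rendered as "other <subordinate NP, pluralized>", superordinate ones
    with the superordinate NP. Columns: item_id, polarity, raw_text, coded.
    """
    by_id = {it.item_id: it for it in design.items}
    rows = []
    for _, r in data.cc_counts.iterrows():
        it = by_id[r["item_id"]]
        for i in range(int(r["n_total"])):
            label = it.subordinate_label if i < int(r["n_sub"]) else it.superordinate_label
            raw = f"other {_pluralize(label)}"
            rows.append(
                {
                    "item_id": it.item_id,
                    "polarity": r["polarity"],
                    "raw_text": raw,
                    "coded": code_response(raw, it.subordinate_label),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive interaction statistic
# ---------------------------------------------------------------------------


def interaction_stat(
    data: BehavioralDataset, level_pair: tuple[str, str] = ("high", "mid")
) -> float:
    """Difference-in-differences of subordinate-response proportions.

    ``[p_sub(negative) - p_sub(positive)]`` pooled over items at
    ``level_pair[0]`` minus the same contrast at ``level_pair[1]``. A
    positive value at ("high", "mid") is the signature of pragmatic
    class inference: a high-end category described with the *positive*
    adjective pushes the listener toward the superordinate class.
    """
    by_id = {it.item_id: it for it in data.items}
    totals: dict[tuple[str, str], list[float]] = {}
    for _, r in data.cc_counts.iterrows():
        lev = by_id[r["item_id"]].expectation_level
        key = (lev, r["polarity"])
        k, n = totals.setdefault(key, [0.0, 0.0])
        totals[key] = [k + r["n_sub"], n + r["n_total"]]

    def prop(level: str, pol: str) -> float:
        k, n = totals.get((level, pol), [0.0, 0.0])
        if n == 0:
            raise ValueError(f"no responses for level={level!r}, polarity={pol!r}")
        return k / n

    a, b = level_pair
    return (prop(a, "negative") - prop(a, "positive")) - (
        prop(b, "negative") - prop(b, "positive")
    )
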