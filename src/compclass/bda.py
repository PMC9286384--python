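"""Joint Bayesian data analysis of the two behavioral tasks.

One parameter vector — two speaker optimalities, a Gaussian degree prior
per subordinate category (the superordinate prior is fixed at the unit
normal), and the comparison-class-prior coefficients — is fitted jointly
to binomial counts from the comparison-class inference task and the
adjective endorsement task. The same world-knowledge parameters are
shared between the tasks; that sharing is what lets the endorsement task
act as an implicit prior-elicitation for the class-inference model.

Inference is by seeded adaptive block random-walk Metropolis. The
likelihood factorizes over subordinate categories given the global
parameters, so each iteration updates the globals (each against only the
data slice it touches) and then proposes all per-category blocks at once,
accepting them independently in one vectorized pass.

Model comparison uses annealed importance sampling (AIS) estimates of the
log marginal likelihood, with log Bayes factors reported against a
reference variant.

Public surface: :class:`ComparisonClassModel` / :class:`ComparisonClassResults`
(statsmodels-style), plus the functional pieces ``joint_log_likelihood``,
``log_prior``, ``run_mcmc``, ``posterior_predict``, ``fit_metrics``,
``log_marginal_likelihood`` and ``bayes_factor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, xlog1py, xlogy

from .class_priors import (
    VARIANTS,
    ClassPriorParams,
    ItemMeta,
    class_prior_vector,
)
from .forward import CellProbs, ForwardEngine
from .grids import DEFAULT_COSTS, DegreeGrid

__all__ = [
    "ALL_VARIANTS",
    "ParameterVector",
    "BehavioralDataset",
    "ParamSpace",
    "Chain",
    "FitSummary",
    "AISSettings",
    "joint_log_likelihood",
    "log_prior",
    "run_mcmc",
    "posterior_predict",
    "fit_metrics",
    "log_marginal_likelihood",
    "ais_log_evidence",
    "bayes_factor",
    "split_rhat",
    "ComparisonClassModel",
    "ComparisonClassResults",
    "compare_models",
]

#: the four pragmatic-listener variants plus the rival literal listener
ALL_VARIANTS = VARIANTS + ("literal",)

POLARITIES = ("positive", "negative")

# prior hyperparameters
ALPHA_MAX = 20.0
MEAN_PRIOR_SD = 2.0
SD_LO, SD_HI = 0.01, 2.0
BETA_PRIOR_SD = 3.0


class DataValidationError(ValueError):
    """A behavioral count table failed validation."""


# ---------------------------------------------------------------------------
# parameters and data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterVector:
    """Free parameters of the joint analysis.

    ``sub_mean`` / ``sub_sd`` are aligned with the dataset's item order.
    ``alpha1`` drives the comparison-class speaker, ``alpha2`` the
    endorsement speaker; for the rival ``literal`` listener ``alpha1`` is
    unused.
    """

    alpha1: float
    alpha2: float
    sub_mean: np.ndarray
    sub_sd: np.ndarray
    class_params: ClassPriorParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "sub_mean", np.atleast_1d(np.asarray(self.sub_mean, float)))
        object.__setattr__(self, "sub_sd", np.atleast_1d(np.asarray(self.sub_sd, float)))
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("speaker optimalities must be nonnegative")
        if np.any(self.sub_sd <= 0):
            raise ValueError("sub_sd must be positive")
        if self.sub_mean.shape != self.sub_sd.shape:
            raise ValueError("sub_mean and sub_sd must have equal length")


def _check_counts(df: pd.DataFrame, kcol: str, known_ids: set, table: str) -> pd.DataFrame:
    required = {"item_id", "polarity", kcol, "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{table}: missing columns {sorted(missing)}")
    df = df.reset_index(drop=True)
    for i, row in df.iterrows():
        if row["item_id"] not in known_ids:
            raise DataValidationError(f"{table} row {i}: unknown item_id {row['item_id']!r}")
        if row["polarity"] not in POLARITIES:
            raise DataValidationError(f"{table} row {i}: bad polarity {row['polarity']!r}")
        k, n = row[kcol], row["n_total"]
        if (float(k) != int(k)) or (float(n) != int(n)):
            raise DataValidationError(f"{table} row {i}: counts must be integers")
        if not (0 <= int(k) <= int(n)):
            raise DataValidationError(f"{table} row {i}: need 0 <= {kcol} <= n_total")
    df[kcol] = df[kcol].astype(int)
    df["n_total"] = df["n_total"].astype(int)
    return df


@dataclass
class BehavioralDataset:
    """Per-item binomial counts for both tasks plus item metadata.

    ``cc_counts`` columns: item_id, polarity, n_sub, n_total.
    ``endorse_counts`` columns: item_id, polarity, explicit_class, n_yes,
    n_total (the fitted pipeline uses the superordinate explicit class,
    matching the norming task's design).
    """

    items: list[ItemMeta]
    cc_counts: pd.DataFrame
    endorse_counts: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate item_id in item metadata")
        known = set(ids)
        self.cc_counts = _check_counts(pd.DataFrame(self.cc_counts), "n_sub", known, "cc_counts")
        edf = pd.DataFrame(self.endorse_counts)
        if "explicit_class" not in edf.columns:
            edf = edf.assign(explicit_class="super")
        bad = set(edf["explicit_class"].unique()) - {"super"} if len(edf) else set()
        if bad:
            raise DataValidationError(
                f"endorse_counts: unsupported explicit_class values {sorted(bad)}"
            )
        self.endorse_counts = _check_counts(edf, "n_yes", known, "endorse_counts")

    @property
    def n_categories(self) -> int:
        return len(self.items)

    def item_index(self) -> dict[str, int]:
        return {it.item_id: j for j, it in enumerate(self.items)}

    @classmethod
    def empty(cls, items: Sequence[ItemMeta] = ()) -> "BehavioralDataset":
        cols_cc = ["item_id", "polarity", "n_sub", "n_total"]
        cols_en = ["item_id", "polarity", "explicit_class", "n_yes", "n_total"]
        return cls(list(items), pd.DataFrame(columns=cols_cc), pd.DataFrame(columns=cols_en))

    def observed_proportions(self) -> pd.DataFrame:
        """Pooled observed proportions per (item, polarity) cell, both tasks."""
        out = []
        for task, df, kcol in (
            ("cc", self.cc_counts, "n_sub"),
            ("endorse", self.endorse_counts, "n_yes"),
        ):
            if len(df) == 0:
                continue
            g = df.groupby(["item_id", "polarity"], sort=False)[[kcol, "n_total"]].sum()
            g = g.reset_index()
            g["task"] = task
            g["observed"] = g[kcol] / g["n_total"]
            out.append(g[["task", "item_id", "polarity", "observed", "n_total"]])
        if not out:
            return pd.DataFrame(columns=["task", "item_id", "polarity", "observed", "n_total"])
        return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# parameter space: packing, priors
# ---------------------------------------------------------------------------


class ParamSpace:
    """Flat-vector view of :class:`ParameterVector` for a given variant."""

    def __init__(self, variant: str, n_categories: int):
        if variant not in ALL_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {ALL_VARIANTS}")
        self.variant = variant
        self.n_categories = n_categories
        self.prior_variant = "flat" if variant == "literal" else variant
        self.has_alpha1 = variant != "literal"
        self.beta_names = ClassPriorParams(variant=self.prior_variant).free_names
        names: list[str] = (["alpha1"] if self.has_alpha1 else []) + ["alpha2"]
        names += list(self.beta_names)
        names += [f"sub_mean[{j}]" for j in range(n_categories)]
        names += [f"sub_sd[{j}]" for j in range(n_categories)]
        self.names = names
        self.dim = len(names)
        self._n_beta = len(self.beta_names)
        self._i_mean = (1 if self.has_alpha1 else 0) + 1 + self._n_beta
        self._i_sd = self._i_mean + n_categories

    @property
    def global_names(self) -> list[str]:
        return (["alpha1"] if self.has_alpha1 else []) + ["alpha2"] + list(self.beta_names)

    def pack(self, theta: ParameterVector) -> np.ndarray:
        x = []
        if self.has_alpha1:
            x.append(theta.alpha1)
        x.append(theta.alpha2)
        x += [getattr(theta.class_params, b) for b in self.beta_names]
        return np.concatenate([np.asarray(x, float), theta.sub_mean, theta.sub_sd])

    def unpack(self, x: np.ndarray) -> ParameterVector:
        x = np.asarray(x, float)
        i = 0
        alpha1 = 0.0
        if self.has_alpha1:
            alpha1, i = x[0], 1
        alpha2 = x[i]
        i += 1
        betas = {b: float(x[i + j]) for j, b in enumerate(self.beta_names)}
        cp = ClassPriorParams(variant=self.prior_variant, **betas)
        return ParameterVector(
            alpha1=float(alpha1),
            alpha2=float(alpha2),
            sub_mean=x[self._i_mean : self._i_sd].copy(),
            sub_sd=x[self._i_sd :].copy(),
            class_params=cp,
        )

    # prior: alpha ~ U(0, 20); betas ~ N(0, 3); sub_mean ~ N(0, 2);
    # sub_sd ~ U(0.01, 2)
    def log_prior(self, x: np.ndarray) -> float:
        x = np.asarray(x, float)
        i = 0
        lp = 0.0
        n_alpha = 2 if self.has_alpha1 else 1
        alphas = x[:n_alpha]
        if np.any(alphas < 0) or np.any(alphas > ALPHA_MAX):
            return -np.inf
        lp += -n_alpha * math.log(ALPHA_MAX)
        i = n_alpha
        betas = x[i : i + self._n_beta]
        lp += float(np.sum(_norm_logpdf(betas, BETA_PRIOR_SD)))
        means = x[self._i_mean : self._i_sd]
        sds = x[self._i_sd :]
        if np.any(sds <= SD_LO) or np.any(sds >= SD_HI):
            return -np.inf
        lp += float(np.sum(_norm_logpdf(means, MEAN_PRIOR_SD)))
        lp += -len(sds) * math.log(SD_HI - SD_LO)
        return lp

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        n_alpha = 2 if self.has_alpha1 else 1
        parts = [
            rng.uniform(0, ALPHA_MAX, n_alpha),
            rng.normal(0, BETA_PRIOR_SD, self._n_beta),
            rng.normal(0, MEAN_PRIOR_SD, self.n_categories),
            rng.uniform(SD_LO, SD_HI, self.n_categories),
        ]
        return np.concatenate(parts)


def _norm_logpdf(x: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * (np.asarray(x, float) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def log_prior(theta: ParameterVector) -> float:
    """Log prior density of a parameter vector (variant taken from it)."""
    space = ParamSpace(theta.class_params.variant, theta.sub_mean.size)
    return space.log_prior(space.pack(theta))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class _CellData:
    """Counts aggregated to (category, polarity) cells for fast likelihood."""

    def __init__(self, data: BehavioralDataset):
        C = data.n_categories
        idx = data.item_index()
        self.C = C
        self.K_cc, self.N_cc, self.lc_cc = self._aggregate(data.cc_counts, "n_sub", idx, C)
        self.K_en, self.N_en, self.lc_en = self._aggregate(
            data.endorse_counts, "n_yes", idx, C
        )
        self.has_cc = self.N_cc.sum() > 0
        self.has_en = self.N_en.sum() > 0

    @staticmethod
    def _aggregate(df: pd.DataFrame, kcol: str, idx: dict, C: int):
        K = np.zeros((C, 2))
        N = np.zeros((C, 2))
        lc = 0.0
        for _, row in df.iterrows():
            j = idx[row["item_id"]]
            p = 0 if row["polarity"] == "positive" else 1
            k, n = int(row[kcol]), int(row["n_total"])
            K[j, p] += k
            N[j, p] += n
            lc += gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return K, N, float(lc)

    @staticmethod
    def _binom_by_cat(K: np.ndarray, N: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Per-category binomial log likelihood (no coefficient), (C,)."""
        psafe = np.where(N > 0, p, 0.5)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = xlogy(K, psafe) + xlog1py(N - K, -psafe)
        t = np.where(np.isnan(t) & (N > 0), -np.inf, np.nan_to_num(t, nan=0.0, neginf=-np.inf))
        return t.sum(axis=1)

    def cc_by_cat(self, p_cc: np.ndarray) -> np.ndarray:
        return self._binom_by_cat(self.K_cc, self.N_cc, p_cc)

    def en_by_cat(self, p_en: np.ndarray) -> np.ndarray:
        return self._binom_by_cat(self.K_en, self.N_en, p_en)

    def total(self, probs: CellProbs) -> float:
        return float(
            self.cc_by_cat(probs.p_cc).sum()
            + self.en_by_cat(probs.p_endorse).sum()
            + self.lc_cc
            + self.lc_en
        )


def _engine_for(data: BehavioralDataset, variant: str, grid=None, costs=DEFAULT_COSTS):
    listener = "literal" if variant == "literal" else "pragmatic"
    return ForwardEngine(data.items, grid=grid, costs=costs, listener=listener)


def joint_log_likelihood(
    theta: ParameterVector,
    data: BehavioralDataset,
    variant: str = "basic_freq",
    engine: ForwardEngine | None = None,
) -> float:
    """Joint binomial log likelihood of both tasks under ``theta``.

    Cells whose model probability is exactly 0 or 1 but whose counts
    contradict it contribute ``-inf`` rather than raising.
    """
    if data.n_categories == 0:
        return 0.0
    if variant not in ALL_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    eng = engine or _engine_for(data, variant)
    cp = replace(theta.class_params, variant="flat" if variant == "literal" else variant)
    probs = eng.predict(theta.alpha1, theta.alpha2, theta.sub_mean, theta.sub_sd, cp)
    return _CellData(data).total(probs)


# ---------------------------------------------------------------------------
# MCMC: adaptive block random-walk Metropolis
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    """Post-burn-in MCMC samples in packed-vector form."""

    samples: np.ndarray  # (n_kept, dim)
    log_posteriors: np.ndarray
    seed: int
    n_burned: int
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("chain must contain at least one post-burn-in sample")
        if not np.all(np.isfinite(self.log_posteriors)):
            raise ValueError("log posteriors must be finite")


class _BlockState:
    """Mutable sampler state with cached likelihood pieces."""

    __slots__ = (
        "alpha1", "alpha2", "betas", "mean", "sd",
        "M", "own", "other", "s2", "p_c", "e",
        "ll_cc", "ll_en", "lp_mean", "lp_sd_ok", "lp_beta",
    )


class _BlockSampler:
    """Blockwise Metropolis for the joint posterior, optionally tempered.

    Blocks: alpha1 (comparison-class slice only, pragmatic variants),
    alpha2 (endorsement slice only), the class-prior betas jointly, and all
    (sub_mean[j], sub_sd[j]) pairs proposed together but accepted
    independently (valid because likelihood and prior factorize over
    categories given the globals).
    """

    TARGET_SCALAR = 0.44
    TARGET_BLOCK = 0.30

    def __init__(self, space: ParamSpace, engine: ForwardEngine, cells: _CellData):
        self.space = space
        self.engine = engine
        self.cells = cells
        C = space.n_categories
        # proposal scales (log-adapted during burn-in)
        self.s_alpha1 = 0.4
        self.s_alpha2 = 0.4
        self.s_beta = 0.25
        self.s_mean = np.full(C, 0.25)
        self.s_sd = np.full(C, 0.15)

    # -- state construction -------------------------------------------------

    def init_state(self, x: np.ndarray) -> _BlockState:
        sp = self.space
        st = _BlockState()
        theta = sp.unpack(x)
        st.alpha1, st.alpha2 = theta.alpha1, theta.alpha2
        st.betas = np.array([getattr(theta.class_params, b) for b in sp.beta_names])
        st.mean, st.sd = theta.sub_mean.copy(), theta.sub_sd.copy()
        self._refresh(st)
        return st

    def _class_params(self, st: _BlockState) -> ClassPriorParams:
        kw = dict(zip(self.space.beta_names, map(float, st.betas)))
        return ClassPriorParams(variant=self.space.prior_variant, **kw)

    def _refresh(self, st: _BlockState) -> None:
        eng = self.engine
        st.M = eng.sub_mass(st.mean, st.sd)
        st.own, st.other = eng.informativity(st.M, st.alpha1)
        st.s2 = eng.endorse_super_speaker(st.alpha2)
        st.p_c = class_prior_vector(self._class_params(st), eng.items)
        st.e = st.M @ st.s2.T
        st.ll_cc = self.cells.cc_by_cat(eng.cc_prob(st.own, st.other, st.p_c))
        st.ll_en = self.cells.en_by_cat(st.e)
        st.lp_mean = _norm_logpdf(st.mean, MEAN_PRIOR_SD)
        st.lp_beta = float(np.sum(_norm_logpdf(st.betas, BETA_PRIOR_SD)))

    def log_posterior(self, st: _BlockState, beta_temp: float = 1.0) -> float:
        ll = st.ll_cc.sum() + st.ll_en.sum() + self.cells.lc_cc + self.cells.lc_en
        lp = st.lp_mean.sum() + st.lp_beta  # constant prior terms omitted
        return beta_temp * ll + lp

    def pack_state(self, st: _BlockState) -> np.ndarray:
        head = ([st.alpha1] if self.space.has_alpha1 else []) + [st.alpha2]
        return np.concatenate([np.asarray(head), st.betas, st.mean, st.sd])

    # -- block updates ------------------------------------------------------

    def sweep(self, st: _BlockState, rng: np.random.Generator, beta_temp: float = 1.0):
        # -inf/-inf likelihood differences yield NaN deltas, which the
        # acceptance comparisons below correctly treat as rejections
        with np.errstate(invalid="ignore"):
            acc = {}
            if self.space.has_alpha1:
                acc["alpha1"] = self._update_alpha1(st, rng, beta_temp)
            acc["alpha2"] = self._update_alpha2(st, rng, beta_temp)
            if len(self.space.beta_names):
                acc["beta"] = self._update_betas(st, rng, beta_temp)
            acc["cat"] = self._update_categories(st, rng, beta_temp)
            return acc

    def _update_alpha1(self, st, rng, bt) -> float:
        prop = st.alpha1 + self.s_alpha1 * rng.standard_normal()
        if not (0.0 <= prop <= ALPHA_MAX):
            return 0.0
        own, other = self.engine.informativity(st.M, prop)
        ll_cc = self.cells.cc_by_cat(self.engine.cc_prob(own, other, st.p_c))
        delta = bt * (ll_cc.sum() - st.ll_cc.sum())
        if math.log(rng.uniform()) < delta:
            st.alpha1, st.own, st.other, st.ll_cc = prop, own, other, ll_cc
            return 1.0
        return 0.0

    def _update_alpha2(self, st, rng, bt) -> float:
        prop = st.alpha2 + self.s_alpha2 * rng.standard_normal()
        if not (0.0 <= prop <= ALPHA_MAX):
            return 0.0
        s2 = self.engine.endorse_super_speaker(prop)
        e = st.M @ s2.T
        ll_en = self.cells.en_by_cat(e)
        delta = bt * (ll_en.sum() - st.ll_en.sum())
        if math.log(rng.uniform()) < delta:
            st.alpha2, st.s2, st.e, st.ll_en = prop, s2, e, ll_en
            return 1.0
        return 0.0

    def _update_betas(self, st, rng, bt) -> float:
        prop = st.betas + self.s_beta * rng.standard_normal(st.betas.size)
        kw = dict(zip(self.space.beta_names, map(float, prop)))
        cp = ClassPriorParams(variant=self.space.prior_variant, **kw)
        p_c = class_prior_vector(cp, self.engine.items)
        ll_cc = self.cells.cc_by_cat(self.engine.cc_prob(st.own, st.other, p_c))
        lp_beta = float(np.sum(_norm_logpdf(prop, BETA_PRIOR_SD)))
        delta = bt * (ll_cc.sum() - st.ll_cc.sum()) + (lp_beta - st.lp_beta)
        if math.log(rng.uniform()) < delta:
            st.betas, st.p_c, st.ll_cc, st.lp_beta = prop, p_c, ll_cc, lp_beta
            return 1.0
        return 0.0

    def _update_categories(self, st, rng, bt) -> np.ndarray:
        C = self.space.n_categories
        mean_p = st.mean + self.s_mean * rng.standard_normal(C)
        sd_p = st.sd + self.s_sd * rng.standard_normal(C)
        ok = (sd_p > SD_LO) & (sd_p < SD_HI)
        sd_safe = np.where(ok, sd_p, st.sd)
        M = self.engine.sub_mass(mean_p, sd_safe)
        own, other = self.engine.informativity(M, st.alpha1)
        e = M @ st.s2.T
        ll_cc = self.cells.cc_by_cat(self.engine.cc_prob(own, other, st.p_c))
        ll_en = self.cells.en_by_cat(e)
        lp_mean = _norm_logpdf(mean_p, MEAN_PRIOR_SD)
        delta = (
            bt * (ll_cc - st.ll_cc + ll_en - st.ll_en)
            + (lp_mean - st.lp_mean)
        )
        accept = ok & (np.log(rng.uniform(size=C)) < delta)
        if accept.any():
            st.mean[accept] = mean_p[accept]
            st.sd[accept] = sd_p[accept]
            st.M[accept] = M[accept]
            st.own[accept] = own[accept]
            if st.other.base is not None or not st.other.flags.writeable:
                st.other = st.other.copy()
            st.other[accept] = other[accept]
            st.e[accept] = e[accept]
            st.ll_cc[accept] = ll_cc[accept]
            st.ll_en[accept] = ll_en[accept]
            st.lp_mean[accept] = lp_mean[accept]
        return accept.astype(float)

    # -- adaptation ---------------------------------------------------------

    def adapt(self, acc: dict, t: int) -> None:
        g = 1.0 / (1.0 + 0.1 * t) ** 0.6
        if "alpha1" in acc:
            self.s_alpha1 *= math.exp(g * (acc["alpha1"] - self.TARGET_SCALAR))
        self.s_alpha2 *= math.exp(g * (acc["alpha2"] - self.TARGET_SCALAR))
        if "beta" in acc:
            self.s_beta *= math.exp(g * (acc["beta"] - self.TARGET_BLOCK))
        self.s_mean *= np.exp(g * (acc["cat"] - self.TARGET_BLOCK))
        self.s_sd *= np.exp(g * (acc["cat"] - self.TARGET_BLOCK))


def _draw_init(space: ParamSpace, rng: np.random.Generator) -> np.ndarray:
    """Moderately overdispersed initialization in the regime RSA fits live in."""
    n_alpha = 2 if space.has_alpha1 else 1
    parts = [
        rng.uniform(0.3, 6.0, n_alpha),
        rng.normal(0.0, 1.0, len(space.beta_names)),
        rng.normal(0.0, 1.0, space.n_categories),
        rng.uniform(0.3, 1.5, space.n_categories),
    ]
    return np.concatenate(parts)


def run_mcmc(
    data: BehavioralDataset,
    variant: str = "basic_freq",
    n_chains: int = 3,
    n_iter: int = 20_000,
    seed: int = 0,
    burn_frac: float = 0.5,
    grid: DegreeGrid | None = None,
    costs: tuple[float, float, float] = DEFAULT_COSTS,
    thin: int = 1,
) -> list[Chain]:
    """Sample the joint posterior; returns one post-burn-in Chain per seed.

    Deterministic for a fixed ``seed``: each chain uses an independent
    generator spawned from ``SeedSequence(seed, chain_index)``.
    """
    if variant not in ALL_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    space = ParamSpace(variant, data.n_categories)
    engine = _engine_for(data, variant, grid=grid, costs=costs)
    cells = _CellData(data)
    n_burn = int(burn_frac * n_iter)
    chains = []
    for c in range(n_chains):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, c])))
        sampler = _BlockSampler(space, engine, cells)
        st = None
        for _ in range(100):
            x0 = _draw_init(space, rng)
            cand = sampler.init_state(x0)
            if np.isfinite(sampler.log_posterior(cand)):
                st = cand
                break
        if st is None:
            raise RuntimeError("non-finite posterior at initialization after 100 retries")
        kept, lps = [], []
        for t in range(n_iter):
            acc = sampler.sweep(st, rng)
            if t < n_burn:
                sampler.adapt({k: np.mean(v) for k, v in acc.items()}, t)
            elif (t - n_burn) % thin == 0:
                kept.append(sampler.pack_state(st))
                lps.append(sampler.log_posterior(st))
        chains.append(
            Chain(
                samples=np.asarray(kept),
                log_posteriors=np.asarray(lps),
                seed=seed,
                n_burned=n_burn,
                names=list(space.names),
            )
        )
    return chains


def split_rhat(chains: Sequence[Chain]) -> pd.Series:
    """Split-R-hat per parameter across chains (Gelman–Rubin on half-chains)."""
    halves = []
    for ch in chains:
        n = len(ch.samples) // 2
        halves += [ch.samples[:n], ch.samples[n : 2 * n]]
    arr = np.stack(halves)  # (m, n, d)
    m, n, _ = arr.shape
    cmeans = arr.mean(axis=1)
    cvars = arr.var(axis=1, ddof=1)
    W = cvars.mean(axis=0)
    B = n * cmeans.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(W > 0, rhat, 1.0)
    return pd.Series(rhat, index=chains[0].names)


# ---------------------------------------------------------------------------
# posterior predictives and fit metrics
# ---------------------------------------------------------------------------


def _pooled(chains: Sequence[Chain]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.concatenate([ch.samples for ch in chains])
    lps = np.concatenate([ch.log_posteriors for ch in chains])
    return xs, lps


def posterior_predict(
    chains: Sequence[Chain],
    data: BehavioralDataset,
    variant: str = "basic_freq",
    n_draws: int = 200,
    grid: DegreeGrid | None = None,
    costs: tuple[float, float, float] = DEFAULT_COSTS,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-cell model predictions: MAP, posterior mean and credible interval.

    Returns one row per (task, item, polarity) cell present in the data,
    with the pooled observed proportion alongside.
    """
    if not chains:
        raise ValueError("posterior_predict needs at least one chain")
    space = ParamSpace(variant, data.n_categories)
    engine = _engine_for(data, variant, grid=grid, costs=costs)
    xs, lps = _pooled(chains)
    step = max(1, len(xs) // n_draws)
    draws = xs[::step]
    preds_cc, preds_en = [], []
    for x in draws:
        th = space.unpack(x)
        cp = engine.predict(th.alpha1, th.alpha2, th.sub_mean, th.sub_sd, th.class_params)
        preds_cc.append(cp.p_cc)
        preds_en.append(cp.p_endorse)
    preds = {"cc": np.stack(preds_cc), "endorse": np.stack(preds_en)}  # (S, C, 2)
    th_map = space.unpack(xs[int(np.argmax(lps))])
    cp_map = engine.predict(
        th_map.alpha1, th_map.alpha2, th_map.sub_mean, th_map.sub_sd, th_map.class_params
    )
    map_pred = {"cc": cp_map.p_cc, "endorse": cp_map.p_endorse}
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    obs = data.observed_proportions()
    idx = data.item_index()
    rows = []
    for _, r in obs.iterrows():
        j = idx[r["item_id"]]
        p = 0 if r["polarity"] == "positive" else 1
        samp = preds[r["task"]][:, j, p]
        rows.append(
            {
                "task": r["task"],
                "item_id": r["item_id"],
                "polarity": r["polarity"],
                "observed": r["observed"],
                "n_total": r["n_total"],
                "predicted_map": float(map_pred[r["task"]][j, p]),
                "predicted_mean": float(samp.mean()),
                "ci_low": float(np.quantile(samp, lo_q)),
                "ci_high": float(np.quantile(samp, hi_q)),
            }
        )
    return pd.DataFrame(rows)


def fit_metrics(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """(r2, mse): squared Pearson correlation and mean squared error.

    ``r2`` is 0 when the predictions have zero variance; zero observed
    variance is an error.
    """
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("predicted and observed must have equal length >= 2")
    if np.var(obs) == 0:
        raise ValueError("r2 undefined: observed values have zero variance")
    mse = float(np.mean((pred - obs) ** 2))
    if np.var(pred) == 0:
        return 0.0, mse
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r**2), mse


# ---------------------------------------------------------------------------
# marginal likelihood (AIS) and Bayes factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AISSettings:
    """Annealed-importance-sampling settings (geometric temperature ladder)."""

    n_temperatures: int = 30
    n_samples: int = 300
    n_transitions: int = 2
    beta_min: float = 1e-4


def _geometric_ladder(settings: AISSettings) -> np.ndarray:
    T = settings.n_temperatures
    return np.concatenate([[0.0], np.geomspace(settings.beta_min, 1.0, T - 1)])


def ais_log_evidence(
    sample_prior: Callable[[np.random.Generator], object],
    loglik: Callable[[object], float],
    transition: Callable[[object, float, float, np.random.Generator], tuple[object, float]],
    settings: AISSettings,
    rng: np.random.Generator,
) -> tuple[float, float, np.ndarray]:
    """Generic AIS estimate of ln ∫ L(θ) π(θ) dθ.

    ``transition(state, loglik_value, beta, rng)`` must leave
    π(θ)·L(θ)^beta invariant. Returns (log evidence, bootstrap SE, raw log
    weights).
    """
    betas = _geometric_ladder(settings)
    log_w = np.empty(settings.n_samples)
    for s in range(settings.n_samples):
        state = sample_prior(rng)
        ll = loglik(state)
        acc = 0.0
        for b_prev, b_next in zip(betas[:-1], betas[1:]):
            acc += (b_next - b_prev) * ll
            for _ in range(settings.n_transitions):
                state, ll = transition(state, ll, b_next, rng)
        log_w[s] = acc
    lml = float(logsumexp(log_w) - math.log(len(log_w)))
    boot = np.empty(200)
    for i in range(200):
        res = rng.choice(log_w, size=len(log_w), replace=True)
        boot[i] = logsumexp(res) - math.log(len(res))
    return lml, float(boot.std(ddof=1)), log_w


def log_marginal_likelihood(
    data: BehavioralDataset,
    variant: str = "basic_freq",
    settings: AISSettings | None = None,
    seed: int = 0,
    grid: DegreeGrid | None = None,
    costs: tuple[float, float, float] = DEFAULT_COSTS,
) -> tuple[float, float]:
    """AIS estimate of the log marginal likelihood of ``data`` under a variant.

    Transitions reuse the block Metropolis kernel at fixed proposal scales,
    targeting π(θ)·L(θ)^beta at each rung. Returns (estimate, bootstrap SE).
    """
    settings = settings or AISSettings()
    space = ParamSpace(variant, data.n_categories)
    engine = _engine_for(data, variant, grid=grid, costs=costs)
    cells = _CellData(data)
    sampler = _BlockSampler(space, engine, cells)
    const = cells.lc_cc + cells.lc_en

    def sample_prior(rng):
        return sampler.init_state(space.sample_prior(rng))

    def loglik(st):
        return float(st.ll_cc.sum() + st.ll_en.sum() + const)

    def transition(st, ll, beta, rng):
        sampler.sweep(st, rng, beta_temp=beta)
        return st, loglik(st)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 977])))
    lml, se, _ = ais_log_evidence(sample_prior, loglik, transition, settings, rng)
    return lml, se


def bayes_factor(lml_a: float, lml_b: float) -> float:
    """Log Bayes factor of model a over model b."""
    if not (np.isfinite(lml_a) and np.isfinite(lml_b)):
        raise ValueError("log marginal likelihoods must be finite")
    return float(lml_a - lml_b)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitSummary:
    """Headline fit metrics and posterior parameter summaries."""

    r2_cc: float
    mse_cc: float
    r2_endorse: float
    mse_endorse: float
    log_marginal: float | None
    posterior_summaries: pd.DataFrame


class ComparisonClassModel:
    """RSA comparison-class model bound to a behavioral dataset.

    Parameters
    ----------
    data
        Counts for the two tasks and item metadata.
    variant
        Class-prior parameterization: ``flat``, ``basic``, ``freq``,
        ``basic_freq``, or ``literal`` for the rival non-pragmatic
        listener (paired with a flat class prior).
    """

    def __init__(
        self,
        data: BehavioralDataset,
        variant: str = "basic_freq",
        grid: DegreeGrid | None = None,
        costs: tuple[float, float, float] = DEFAULT_COSTS,
    ) -> None:
        if variant not in ALL_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.data = data
        self.variant = variant
        self.grid = grid or DegreeGrid.default()
        self.costs = costs
        self.space = ParamSpace(variant, data.n_categories)
        self._engine = _engine_for(data, variant, grid=self.grid, costs=costs)

    @classmethod
    def from_csv(
        cls, counts_path, items_path, variant: str = "basic_freq", **kwargs
    ) -> "ComparisonClassModel":
        from .io import load_counts, load_items

        items = load_items(items_path)
        data = load_counts(counts_path, items)
        return cls(data, variant=variant, **kwargs)

    def loglike(self, theta: ParameterVector) -> float:
        return joint_log_likelihood(theta, self.data, self.variant, engine=self._engine)

    def logposterior(self, theta: ParameterVector) -> float:
        lp = self.space.log_prior(self.space.pack(theta))
        return lp + self.loglike(theta) if np.isfinite(lp) else -np.inf

    def fit(
        self,
        n_chains: int = 3,
        n_iter: int = 20_000,
        seed: int = 0,
        burn_frac: float = 0.5,
        thin: int = 1,
    ) -> "ComparisonClassResults":
        chains = run_mcmc(
            self.data,
            self.variant,
            n_chains=n_chains,
            n_iter=n_iter,
            seed=seed,
            burn_frac=burn_frac,
            grid=self.grid,
            costs=self.costs,
            thin=thin,
        )
        return ComparisonClassResults(self, chains)

    def log_evidence(
        self, settings: AISSettings | None = None, seed: int = 0
    ) -> tuple[float, float]:
        return log_marginal_likelihood(
            self.data, self.variant, settings=settings, seed=seed,
            grid=self.grid, costs=self.costs,
        )


class ComparisonClassResults:
    """Posterior samples plus diagnostics, predictions and summaries."""

    def __init__(self, model: ComparisonClassModel, chains: list[Chain]):
        self.model = model
        self.chains = chains
        self._xs, self._lps = _pooled(chains)

    @property
    def names(self) -> list[str]:
        return self.model.space.names

    def posterior_summaries(self, ci: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        return pd.DataFrame(
            {
                "parameter": self.names,
                "mean": self._xs.mean(axis=0),
                "ci_low": np.quantile(self._xs, lo, axis=0),
                "ci_high": np.quantile(self._xs, hi, axis=0),
            }
        )

    @property
    def params(self) -> ParameterVector:
        """Posterior-mean parameter vector."""
        return self.model.space.unpack(self._xs.mean(axis=0))

    @property
    def map_params(self) -> ParameterVector:
        return self.model.space.unpack(self._xs[int(np.argmax(self._lps))])

    def rhat(self) -> pd.Series:
        return split_rhat(self.chains)

    def posterior_predict(self, n_draws: int = 200) -> pd.DataFrame:
        return posterior_predict(
            self.chains,
            self.model.data,
            self.model.variant,
            n_draws=n_draws,
            grid=self.model.grid,
            costs=self.model.costs,
        )

    def fit_summary(
        self, log_marginal: float | None = None, predictions: pd.DataFrame | None = None
    ) -> FitSummary:
        pred = predictions if predictions is not None else self.posterior_predict()
        metrics = {}
        for task in ("cc", "endorse"):
            sub = pred[pred["task"] == task]
            if len(sub) >= 2:
                metrics[task] = fit_metrics(
                    sub["predicted_map"].to_numpy(), sub["observed"].to_numpy()
                )
            else:
                metrics[task] = (np.nan, np.nan)
        return FitSummary(
            r2_cc=metrics["cc"][0],
            mse_cc=metrics["cc"][1],
            r2_endorse=metrics["endorse"][0],
            mse_endorse=metrics["endorse"][1],
            log_marginal=log_marginal,
            posterior_summaries=self.posterior_summaries(),
        )

    def summary(self, globals_only: bool = True) -> str:
        """Readable fit report: globals (and optionally every parameter),
        posterior means, 95% credible intervals and split-R-hat."""
        tab = self.posterior_summaries()
        rh = self.rhat()
        tab["rhat"] = rh.to_numpy()
        if globals_only:
            tab = tab[tab["parameter"].isin(self.model.space.global_names)]
        lines = [
            "Comparison-class inference model",
            f"  variant: {self.model.variant}",
            f"  categories: {self.model.data.n_categories}",
            f"  chains: {len(self.chains)}  kept draws: {len(self._xs)}",
            "",
            tab.to_string(index=False, float_format=lambda v: f"{v: .3f}"),
        ]
        return "\n".join(lines)


def compare_models(
    data: BehavioralDataset,
    variants: Sequence[str] = ALL_VARIANTS,
    n_chains: int = 3,
    n_iter: int = 20_000,
    seed: int = 0,
    ais_settings: AISSettings | None = None,
    reference: str = "basic_freq",
    grid: DegreeGrid | None = None,
) -> pd.DataFrame:
    """Fit every variant and compare them, Table-2 style.

    Returns one row per variant with fit metrics, AIS log marginal
    likelihood and the log Bayes factor against ``reference``.
    """
    rows = {}
    for variant in variants:
        model = ComparisonClassModel(data, variant=variant, grid=grid)
        res = model.fit(n_chains=n_chains, n_iter=n_iter, seed=seed)
        lml, se = model.log_evidence(settings=ais_settings, seed=seed)
        fs = res.fit_summary(log_marginal=lml)
        rows[variant] = {
            "variant": variant,
            "r2_cc": fs.r2_cc,
            "mse_cc": fs.mse_cc,
            "r2_endorse": fs.r2_endorse,
            "mse_endorse": fs.mse_endorse,
            "log_marginal": lml,
            "log_marginal_se": se,
        }
    ref_lml = rows[reference]["log_marginal"] if reference in rows else np.nan
    for variant in rows:
        rows[variant]["log_bf_vs_full"] = rows[variant]["log_marginal"] - ref_lml
    return pd.DataFrame(rows.values())
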