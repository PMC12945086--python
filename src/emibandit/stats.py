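"""Statistical analyses: feasibility summaries, paired Wilcoxon tests, the
two-level mixed model with AIC selection, and a parameter-recovery harness.

The mixed model mirrors the longitudinal analysis of daily behavior counts:

    Level 1:  Y_ij   = Pi_0i + Pi_1i * Depression_ij + eps_ij
    Level 2:  Pi_0i  = gamma00 + zeta0_i
              Pi_1i  = gamma10 + gamma11 * Psych_i + zeta1_i

i.e. fixed effects gamma shared across participants, with a per-participant
random intercept and random depression slope.  Estimation is by maximum
likelihood (not REML) so AIC comparisons across fixed-effect structures are
valid; cross-level interactions appear as products of a level-1 and a level-2
column.  Fitting is delegated to statsmodels MixedLM behind this surface.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .events import EventLog, ReviewEvent, compute_use_rate

__all__ = [
    "LmmSpec",
    "LmmFit",
    "TestResult",
    "RecoveryReport",
    "FeasibilityReport",
    "SpecificationError",
    "wilcoxon_signed_rank",
    "fit_lmm",
    "select_model_aic",
    "recover_parameters",
    "summarize_feasibility",
]

LEVEL1_VOCAB = (
    "depression", "anxiety", "positive_affect",
    "delta_weight_baseline", "delta_weight_previous", "week",
)
LEVEL2_VOCAB = ("sex", "bmi_centered", "psych_comorbidity")
RANDOM_VOCAB = ("intercept", "depression_slope")


class SpecificationError(ValueError):
    """The requested model cannot be estimated from the given table."""


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


@dataclass(frozen=True)
class TestResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_effective: int  # pairs remaining after dropping zero differences
    method: str  # "exact", "approx", or "degenerate"


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic, conditional on the
    observed (mid)ranks.

    Enumerates the null distribution of W+ = sum of ranks with positive sign
    over all 2^n equiprobable sign assignments via a subset-sum convolution;
    midranks are handled by working on a doubled integer scale.  Equivalent
    to, but exponentially cheaper than, brute-force enumeration.
    """
    scaled = np.rint(2.0 * ranks).astype(np.int64)  # midranks -> integers
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _signed_rank_approx_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(min(1.0, 2.0 * scipy.stats.norm.sf(abs(z))))


def wilcoxon_signed_rank(
    pre: Sequence[float], post: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test of post vs pre.

    Zero differences are dropped before ranking and ``n_effective`` reports
    what remains; all-zero input yields a flagged degenerate result with
    p = 1 rather than an exception.  The exact null distribution (conditional
    on observed midranks) is used when ``mode="exact"``, or under ``"auto"``
    when n_effective <= 25 with no tied magnitudes; otherwise the normal
    approximation with continuity and tie corrections is used.
    """
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("pre and post must be equal-length 1-d, length >= 2")
    d = post - pre
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        return TestResult(0.0, 1.0, 0, "degenerate")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n_eff
    use_exact = mode == "exact" or (mode == "auto" and n_eff <= 25 and not has_ties)
    if use_exact:
        return TestResult(w_plus, _signed_rank_exact_p(w_plus, ranks), n_eff, "exact")
    return TestResult(w_plus, _signed_rank_approx_p(w_plus, ranks), n_eff, "approx")


# ---------------------------------------------------------------------------
# mixed model


@dataclass(frozen=True)
class LmmSpec:
    """Which fixed effects, cross-level interactions and random effects to fit.

    ``level1_fixed`` draws from per-observation covariates (mood subscales on
    [0, 1], weight deltas in kg, study week 1-4); ``level2_fixed`` from
    per-participant covariates (sex, BMI centered by subtracting 35,
    psychiatric comorbidity).  Interactions are (level1, level2) pairs whose
    main effects must both be included.  The intercept is always fixed;
    estimation is maximum likelihood.
    """

    level1_fixed: tuple[str, ...] = ("depression",)
    level2_fixed: tuple[str, ...] = ("psych_comorbidity",)
    cross_level_interactions: tuple[tuple[str, str], ...] = (
        ("depression", "psych_comorbidity"),
    )
    random_effects: tuple[str, ...] = ("intercept", "depression_slope")

    def __post_init__(self) -> None:
        for v in self.level1_fixed:
            if v not in LEVEL1_VOCAB:
                raise ValueError(f"unknown level-1 variable {v!r}")
        for v in self.level2_fixed:
            if v not in LEVEL2_VOCAB:
                raise ValueError(f"unknown level-2 variable {v!r}")
        for r in self.random_effects:
            if r not in RANDOM_VOCAB:
                raise ValueError(f"unknown random effect {r!r}")
        for l1, l2 in self.cross_level_interactions:
            if l1 not in self.level1_fixed or l2 not in self.level2_fixed:
                raise ValueError(
                    f"interaction {l1}:{l2} requires both main effects"
                )
        if "depression_slope" in self.random_effects and (
            "depression" not in self.level1_fixed
        ):
            raise ValueError("random depression slope requires depression fixed effect")

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return (
            ("intercept",)
            + self.level1_fixed
            + self.level2_fixed
            + tuple(f"{a}:{b}" for a, b in self.cross_level_interactions)
        )

    @property
    def n_parameters(self) -> int:
        q = len(self.random_effects)
        return len(self.fixed_terms) + q * (q + 1) // 2 + 1  # + residual var

    def canonical(self) -> str:
        return (
            "y ~ " + " + ".join(self.fixed_terms)
            + " | random: " + (" + ".join(self.random_effects) or "none")
        )


@dataclass(frozen=True)
class LmmFit:
    """Maximum-likelihood fit of one candidate two-level model."""

    spec: LmmSpec
    fixed_effects: pd.DataFrame  # index: term; estimate, se, ci_low, ci_high, p
    variance_components: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_groups: int
    n_dropped: int  # complete-case rows removed

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.fixed_effects.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _design(table: pd.DataFrame, spec: LmmSpec):
    cols = {"intercept": np.ones(len(table))}
    for v in spec.level1_fixed + spec.level2_fixed:
        cols[v] = table[v].to_numpy(dtype=float)
    for l1, l2 in spec.cross_level_interactions:
        cols[f"{l1}:{l2}"] = cols[l1] * cols[l2]
    X = pd.DataFrame(cols, index=table.index)[list(spec.fixed_terms)]
    return X


def fit_lmm(table: pd.DataFrame, spec: LmmSpec = LmmSpec()) -> LmmFit:
    """Fit one candidate model by maximum likelihood.

    Rows with a missing value in any used column are dropped (complete-case;
    ``n_dropped`` reports how many).  Wald 95% CIs on fixed effects.  AIC is
    -2 logL + 2k with k counting fixed effects, free (co)variance parameters
    of the random effects, and the residual variance.  Non-convergence or a
    boundary (singular) random-effects estimate is reported through
    ``converged``, never silently.
    """
    needed = ["y", "user_id"] + [
        v for v in spec.level1_fixed + spec.level2_fixed
    ]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise SpecificationError(f"table lacks columns {missing_cols}")
    # full-column sort makes the fit invariant to input row order
    data = table.dropna(subset=needed).sort_values(needed, kind="stable")
    n_dropped = len(table) - len(data)
    if len(data) == 0:
        raise SpecificationError("no complete-case rows remain")

    X = _design(data, spec)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise SpecificationError(f"rank-deficient design; collinear columns: {bad}")
    y = data["y"].to_numpy(dtype=float)
    groups = data["user_id"].to_numpy()
    n_groups = len(np.unique(groups))

    if not spec.random_effects:
        ols = sm.OLS(y, X.to_numpy()).fit()
        k = X.shape[1] + 1
        est, se = ols.params, ols.bse
        zcrit = scipy.stats.norm.ppf(0.975)
        fe = pd.DataFrame({
            "estimate": est, "se": se,
            "ci_low": est - zcrit * se, "ci_high": est + zcrit * se,
            "p": 2 * scipy.stats.norm.sf(np.abs(est / np.where(se > 0, se, np.inf))),
        }, index=list(X.columns))
        return LmmFit(spec, fe, {"var_residual": float(ols.scale)},
                      float(ols.llf), float(-2 * ols.llf + 2 * k), True,
                      len(data), n_groups, n_dropped)

    re_cols = []
    if "intercept" in spec.random_effects:
        re_cols.append(np.ones(len(data)))
    if "depression_slope" in spec.random_effects:
        re_cols.append(data["depression"].to_numpy(dtype=float))
    exog_re = np.column_stack(re_cols)

    converged = True
    res = None
    last_exc: Exception | None = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # fall back through optimizers: lbfgs is fast but brittle on small or
        # near-degenerate designs where powell/nm still find the optimum
        for method in ("lbfgs", "powell", "nm"):
            model = sm.MixedLM(y, X.to_numpy(), groups=groups, exog_re=exog_re)
            try:
                res = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if res.converged:
                break
        if res is None:
            raise SpecificationError(
                f"mixed-model fit failed: {last_exc}"
            ) from last_exc
    if not res.converged:
        converged = False
    for w in caught:
        msg = str(w.message).lower()
        # boundary / singular covariance warnings are legitimate ML fits with
        # a zero variance component, not optimization failures
        if "failed to converge" in msg or "optimization failed" in msg:
            converged = False
    if n_groups < 2:
        converged = False  # between-participant variance inestimable

    q = exog_re.shape[1]
    k = X.shape[1] + q * (q + 1) // 2 + 1
    est = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    zcrit = scipy.stats.norm.ppf(0.975)
    fe = pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - zcrit * se, "ci_high": est + zcrit * se,
        "p": 2 * scipy.stats.norm.sf(np.abs(est / np.where(se > 0, se, np.inf))),
    }, index=list(X.columns))

    cov_re = np.asarray(res.cov_re, dtype=float)
    vc: dict[str, float] = {"var_residual": float(res.scale)}
    re_names = [r for r in ("intercept", "depression_slope") if r in spec.random_effects]
    for i, name in enumerate(re_names):
        vc[f"var_{name}"] = float(cov_re[i, i])
    if len(re_names) == 2:
        vc["cov_intercept_slope"] = float(cov_re[0, 1])
    llf = float(res.llf)
    return LmmFit(spec, fe, vc, llf, float(-2 * llf + 2 * k), converged,
                  len(data), n_groups, n_dropped)


def select_model_aic(
    table: pd.DataFrame,
    candidate_level1: Sequence[str] = LEVEL1_VOCAB,
    candidate_level2: Sequence[str] = LEVEL2_VOCAB,
    candidate_random: Sequence[Sequence[str]] = (
        ("intercept",), ("intercept", "depression_slope"),
    ),
    candidate_interactions: Sequence[tuple[str, str]] = (
        ("depression", "psych_comorbidity"),
    ),
) -> tuple[LmmSpec, pd.DataFrame]:
    """Exhaustive AIC search over admissible model structures.

    Enumerates every subset of the level-1 and level-2 candidate sets, every
    subset of ``candidate_interactions`` whose main effects are included, and
    every candidate random-effect structure compatible with the fixed part.
    Returns the minimum-AIC converged model and a ranking table of all
    candidates.  Ties break toward fewer parameters, then lexicographically
    on the model formula.
    """
    specs: list[LmmSpec] = []
    for r1 in range(len(candidate_level1) + 1):
        for l1 in itertools.combinations(candidate_level1, r1):
            for r2 in range(len(candidate_level2) + 1):
                for l2 in itertools.combinations(candidate_level2, r2):
                    admissible = [
                        (a, b) for a, b in candidate_interactions
                        if a in l1 and b in l2
                    ]
                    inter_subsets = [
                        combo
                        for ri in range(len(admissible) + 1)
                        for combo in itertools.combinations(admissible, ri)
                    ]
                    for inter in inter_subsets:
                        for rand in candidate_random:
                            rand = tuple(rand)
                            if "depression_slope" in rand and "depression" not in l1:
                                continue
                            specs.append(LmmSpec(l1, l2, tuple(inter), rand))
    rows = []
    diagnostics = []
    for spec in specs:
        try:
            fit = fit_lmm(table, spec)
        except SpecificationError as exc:
            diagnostics.append((spec, str(exc)))
            continue
        rows.append({
            "model": spec.canonical(),
            "aic": fit.aic,
            "n_parameters": spec.n_parameters,
            "converged": fit.converged,
            "loglik": fit.loglik,
            "spec": spec,
        })
    ranking = pd.DataFrame(rows).sort_values(
        ["aic", "n_parameters", "model"], kind="stable"
    ).reset_index(drop=True)
    converged_ok = ranking[ranking["converged"]]
    if converged_ok.empty:
        raise SpecificationError(
            f"no candidate model converged; diagnostics: {diagnostics}"
        )
    best = converged_ok.iloc[0]["spec"]
    return best, ranking.drop(columns="spec")


# ---------------------------------------------------------------------------
# recovery harness


@dataclass(frozen=True)
class RecoveryReport:
    """Bias / RMSE / 95% CI coverage of the fixed effects over replicates."""

    per_coefficient: pd.DataFrame  # index: term; true, bias, rmse, coverage
    n_reps: int
    n_converged: int
    seed: int


#: generator coefficient -> fixed-effect term it identifies
_GEN_TERMS = {
    "gamma00": "intercept",
    "gamma10": "depression",
    "gamma11": "depression:psych_comorbidity",
}


def recover_parameters(
    gen, spec: LmmSpec, n_reps: int = 200, seed: int = 0
) -> RecoveryReport:
    """Generate ``n_reps`` datasets from the two-level equations, refit each
    with ``spec``, and summarise how well the generating fixed effects are
    recovered.

    Coverage is the fraction of converged replicates whose Wald 95% CI
    contains the generating value.  Non-converged replicates are excluded
    from the summaries and counted.
    """
    from .simulate import generate_lmm_dataset

    rng = np.random.default_rng(seed)
    truth = {
        term: getattr(gen, g) for g, term in _GEN_TERMS.items()
        if term in spec.fixed_terms
    }
    estimates: dict[str, list[float]] = {t: [] for t in truth}
    covered: dict[str, list[bool]] = {t: [] for t in truth}
    n_converged = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        data = generate_lmm_dataset(replace(gen, seed=rep_seed))
        try:
            fit = fit_lmm(data, spec)
        except SpecificationError:
            continue
        if not fit.converged:
            continue
        n_converged += 1
        for term, true_val in truth.items():
            est = fit.coef(term)
            lo, hi = fit.ci(term)
            estimates[term].append(est)
            covered[term].append(lo <= true_val <= hi)
    rows = {}
    for term, true_val in truth.items():
        e = np.asarray(estimates[term])
        rows[term] = {
            "true": true_val,
            "mean_estimate": float(e.mean()) if len(e) else np.nan,
            "bias": float(e.mean() - true_val) if len(e) else np.nan,
            "rmse": float(np.sqrt(np.mean((e - true_val) ** 2))) if len(e) else np.nan,
            "coverage": float(np.mean(covered[term])) if covered[term] else np.nan,
        }
    per_coef = pd.DataFrame(rows).T
    return RecoveryReport(per_coef, n_reps, n_converged, seed)


# ---------------------------------------------------------------------------
# feasibility


@dataclass(frozen=True)
class FeasibilityReport:
    use_rates: dict[str, float]  # per user, percent
    median: float
    min: float
    max: float
    mean: float
    sd: float | None  # None (flagged) for a single participant
    distinct_behaviors: dict[str, int]
    median_distinct: float
    range_distinct: tuple[int, int]

    def __str__(self) -> str:  # compact, report-style
        sd = f"{self.sd:.1f}" if self.sd is not None else "n/a"
        return (
            f"use rate: median {self.median:.1f}% "
            f"(range {self.min:.1f}%-{self.max:.1f}%), "
            f"mean {self.mean:.1f}% (SD {sd}%); "
            f"distinct behaviors performed: median {self.median_distinct:.1f} "
            f"(range {self.range_distinct[0]}-{self.range_distinct[1]})"
        )


def summarize_feasibility(
    log: EventLog, scheduled_days: int | Mapping[str, int] = 28
) -> FeasibilityReport:
    """Descriptive feasibility statistics of a study log.

    Per-user app use rates (percent of scheduled days with a review) with
    median / range / mean / SD, plus the number of distinct behaviors each
    user actually performed (preselected-and-done or logged as an extra).
    Medians use the midpoint convention for even-length samples.
    """
    rates = compute_use_rate(log, scheduled_days)
    if not rates:
        raise ValueError("empty log: no users to summarise")
    vals = np.array(sorted(rates.values()))
    distinct: dict[str, int] = {}
    for uid in sorted(rates):
        done: set[str] = set()
        for rev in log.events_of(ReviewEvent, uid):
            done.update(a for a, ok in rev.performed.items() if ok)
            done.update(rev.extras)
        distinct[uid] = len(done)
    dvals = np.array(sorted(distinct.values()))
    return FeasibilityReport(
        use_rates=rates,
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else None,
        distinct_behaviors=distinct,
        median_distinct=float(np.median(dvals)),
        range_distinct=(int(dvals.min()), int(dvals.max())),
    )
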