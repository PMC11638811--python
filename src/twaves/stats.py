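"""Bayes-factor inference layer.

Implements the default-prior Bayesian toolbox the analysis relies on:

* JZS (Jeffreys–Zellner–Siow) paired t-test Bayes factors — Cauchy prior
  with scale ``r`` on the standardized effect, marginal likelihood by
  numerical quadrature of the Rouder et al. (2009) integral.
* Repeated-measures ANOVA inclusion Bayes factors over the model space of
  main effects and interactions (marginality respected, participant
  blocking term in every model), with the matched-models inclusion rule.
  Per-model marginal likelihoods come from a deterministic BIC
  approximation by default, or from seeded Monte Carlo Zellner–Siow
  g-prior integration with a reported error estimate.
* JZS Bayesian linear regression (one covariate) for the capacity
  analysis, plus Cowan's K and per-participant slope extraction.
* Per-window-time t-test BF series for contra-vs-ipsi contrasts.

BF10 > 1 favors the effect; the conventional "substantial evidence"
threshold 3 is annotation only, never a gate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sstats

from .aggregate import validate_factorial

__all__ = [
    "BFResult",
    "k_capacity",
    "jzs_ttest_bf",
    "jzs_bf_from_t",
    "rm_anova_inclusion_bf",
    "posthoc_pairwise_bf",
    "bf_linear_regression",
    "extract_level_slopes",
    "timecourse_bf",
    "DEFAULT_T_RSCALE",
    "DEFAULT_REG_RSCALE",
]

#: Default Cauchy prior scale for t tests (the common "medium" default).
DEFAULT_T_RSCALE = 1.0 / np.sqrt(2.0)
#: Default prior scale for regression covariates.
DEFAULT_REG_RSCALE = np.sqrt(2.0) / 4.0
#: Conventional evidence threshold used for annotation.
EVIDENCE_THRESHOLD = 3.0


@dataclass(frozen=True)
class BFResult:
    """A Bayes factor with its provenance.

    ``bf`` is BF10 for pairwise kinds and BF_incl for ANOVA effects.
    ``error`` is the relative error estimate (percent) for stochastic
    methods, None for deterministic ones.
    """

    kind: str
    effect: str
    bf: float
    method: str
    error: float | None = None
    rng_seed: int | None = None
    extra: tuple = ()

    def __post_init__(self) -> None:
        if not self.bf > 0:
            raise ValueError("Bayes factor must be positive")
        if self.method in ("monte_carlo",) and self.error is None:
            raise ValueError("stochastic method must report an error estimate")


# ---------------------------------------------------------------------------
# capacity
# ---------------------------------------------------------------------------

def k_capacity(set_size: float, hit: float, false_alarm: float) -> float:
    """Cowan's K: ``set_size * (hit - false_alarm)``."""
    for name, rate in (("hit", hit), ("false_alarm", false_alarm)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} rate {rate} outside [0, 1]")
    return set_size * (hit - false_alarm)


# ---------------------------------------------------------------------------
# JZS t test
# ---------------------------------------------------------------------------

def jzs_bf_from_t(t: float, n: int, r_scale: float = DEFAULT_T_RSCALE) -> float:
    """BF10 for a one-sample/paired t statistic with ``n`` observations.

    The Cauchy(0, r) prior on the standardized effect is integrated as a
    normal mixture over g ~ InverseGamma(1/2, r^2/2):

        BF10 = int (1+Ng)^(-1/2) (1 + t^2/((1+Ng) nu))^(-(nu+1)/2) pi(g) dg
               / (1 + t^2/nu)^(-(nu+1)/2)
    """
    if n < 2:
        raise ValueError("need n >= 2 observations")
    if r_scale <= 0:
        raise ValueError("r_scale must be positive")
    nu = n - 1

    # substitute g = r^2/(2u): the InverseGamma(1/2, r^2/2) prior becomes
    # Gamma(1/2, 1) in u, giving a well-conditioned integrand on (0, inf)
    def integrand(u: float) -> float:
        g = r_scale**2 / (2.0 * u)
        return (
            (1 + n * g) ** -0.5
            * (1 + t * t / ((1 + n * g) * nu)) ** (-(nu + 1) / 2.0)
            * u**-0.5 * np.exp(-u) / special.gamma(0.5)
        )

    m1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    m0 = (1 + t * t / nu) ** (-(nu + 1) / 2.0)
    return m1 / m0


def jzs_ttest_bf(differences: np.ndarray, r_scale: float = DEFAULT_T_RSCALE,
                 effect: str = "paired difference") -> BFResult:
    """JZS BF10 for paired differences against zero (deterministic)."""
    d = np.asarray(differences, dtype=np.float64)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a 1-D array of >= 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences contain non-finite values")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in differences; t undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    bf = jzs_bf_from_t(t, d.size, r_scale)
    return BFResult("t_test", effect, bf, "quadrature",
                    extra=(("t", float(t)), ("n", int(d.size)),
                           ("mean_diff", float(d.mean()))))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA inclusion BF
# ---------------------------------------------------------------------------

def _model_space(factors: list[str]) -> list[frozenset]:
    """All effect sets respecting marginality (interaction implies mains)."""
    mains = list(factors)
    interactions = [frozenset(c) for k in range(2, len(factors) + 1)
                    for c in itertools.combinations(factors, k)]
    effects = [frozenset([m]) for m in mains] + interactions
    models = []
    for k in range(len(effects) + 1):
        for combo in itertools.combinations(effects, k):
            chosen = set(combo)
            ok = all(
                all(frozenset([f]) in chosen for f in eff)
                for eff in chosen if len(eff) > 1
            )
            if ok:
                models.append(frozenset(chosen))
    return models


def _effect_name(eff: frozenset) -> str:
    return " * ".join(sorted(eff))


def _design_columns(cells: pd.DataFrame, eff: frozenset) -> np.ndarray:
    """Full-dummy interaction design columns for one effect."""
    mats = []
    for f in sorted(eff):
        mats.append(pd.get_dummies(cells[f], drop_first=True, dtype=float).to_numpy())
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ni,nj->nij", out, m).reshape(len(cells), -1)
    return out


def _bic_log_bf(y: np.ndarray, common: np.ndarray, blocks: dict) -> dict:
    """log BF(model vs null) via the BIC approximation for each model key."""
    n = y.size

    def bic(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        k = np.linalg.matrix_rank(X)
        return n * np.log(rss / n) + k * np.log(n)

    bic_null = bic(common)
    out = {}
    for model, effs in blocks.items():
        X = np.hstack([common] + [effs[e] for e in sorted(model, key=_effect_name)]) \
            if model else common
        out[model] = (bic_null - bic(X)) / 2.0
    return out


def _mc_log_bf(y: np.ndarray, common: np.ndarray, blocks: dict,
               rng: np.random.Generator, n_samples: int,
               r_scale: float) -> tuple[dict, dict]:
    """log BF(model vs null) by MC Zellner–Siow g-prior integration.

    The common block (intercept + participant) is projected out; for each
    model the g-conditional BF has the closed g-prior form and g is
    integrated by sampling from its InverseGamma(1/2, n r^2 / 2) prior.
    """
    n = y.size
    Q, _ = np.linalg.qr(common)
    y_r = y - Q @ (Q.T @ y)
    c = np.linalg.matrix_rank(common)
    ssr_null = float(y_r @ y_r)
    g = sstats.invgamma.rvs(0.5, scale=n * r_scale**2 / 2.0,
                            size=n_samples, random_state=rng)
    log_bfs, errors = {}, {}
    for model, effs in blocks.items():
        if not model:
            log_bfs[model], errors[model] = 0.0, 0.0
            continue
        X = np.hstack([effs[e] for e in sorted(model, key=_effect_name)])
        X_r = X - Q @ (Q.T @ X)
        beta, *_ = np.linalg.lstsq(X_r, y_r, rcond=None)
        resid = y_r - X_r @ beta
        r2 = 1.0 - float(resid @ resid) / ssr_null
        p = np.linalg.matrix_rank(X_r)
        df = n - c
        log_terms = (0.5 * (df - p) * np.log1p(g)
                     - 0.5 * df * np.log1p(g * (1.0 - r2)))
        m = special.logsumexp(log_terms) - np.log(n_samples)
        log_bfs[model] = float(m)
        w = np.exp(log_terms - log_terms.max())
        rel_se = w.std() / (w.mean() * np.sqrt(n_samples))
        errors[model] = float(rel_se * 100.0)
    return log_bfs, errors


def rm_anova_inclusion_bf(
    cells: pd.DataFrame,
    factors: list[str],
    method: str = "bic_approx",
    value_col: str = "value",
    r_scale: float = 0.5,
    n_samples: int = 20000,
    rng_seed: int | None = 0,
) -> list[BFResult]:
    """Inclusion Bayes factor per effect of a repeated-measures ANOVA.

    ``cells`` holds one row per participant x factor-level combination
    (aggregate trials first); the layout must be a complete within-
    participant factorial.  Every candidate model contains a participant
    blocking term; models distribute equal prior mass; the inclusion BF for
    an effect compares the posterior mass of models containing it with the
    mass of the *matched* models without it (for a main effect, models with
    no interaction involving it).
    """
    if method not in ("bic_approx", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    cells = validate_factorial(cells, factors, value_col)
    y = cells[value_col].to_numpy(dtype=np.float64)
    common = np.hstack([
        np.ones((len(cells), 1)),
        pd.get_dummies(cells["participant"], drop_first=True, dtype=float).to_numpy(),
    ])
    models = _model_space(factors)
    all_effects = sorted({e for m in models for e in m}, key=_effect_name)
    eff_cols = {e: _design_columns(cells, e) for e in all_effects}
    blocks = {m: {e: eff_cols[e] for e in m} for m in models}

    errors: dict = {}
    if method == "bic_approx":
        log_bf = _bic_log_bf(y, common, blocks)
    else:
        rng = np.random.default_rng(rng_seed)
        log_bf, errors = _mc_log_bf(y, common, blocks, rng, n_samples, r_scale)

    # posterior model probabilities under equal priors
    vals = np.array([log_bf[m] for m in models])
    post = np.exp(vals - special.logsumexp(vals))
    post_by_model = dict(zip(models, post))

    results = []
    for eff in all_effects:
        if len(eff) == 1:
            with_eff = [m for m in models if eff in m
                        and not any(len(e) > 1 and eff <= e for e in m)]
        else:
            with_eff = [m for m in models if eff in m]
        without = [m - {eff} for m in with_eff]
        num = sum(post_by_model[m] for m in with_eff)
        den = sum(post_by_model[m] for m in without)
        if den == 0 or num == 0:
            # fall back to log-space ratio to avoid under/overflow
            lnum = special.logsumexp([log_bf[m] for m in with_eff])
            lden = special.logsumexp([log_bf[m] for m in without])
            bf_incl = float(np.exp(lnum - lden))
        else:
            bf_incl = num / den
        err = None
        if method == "monte_carlo":
            err = float(max(errors[m] for m in with_eff + without if m in errors))
        results.append(BFResult(
            "anova_inclusion", _effect_name(eff), bf_incl,
            method, error=err,
            rng_seed=rng_seed if method == "monte_carlo" else None,
        ))
    return results


def posthoc_pairwise_bf(cells: pd.DataFrame, factor: str,
                        levels: tuple, value_col: str = "value",
                        r_scale: float = DEFAULT_T_RSCALE) -> BFResult:
    """Uncorrected paired JZS t-test BF between two levels of a factor.

    Participant-wise level means are differenced (first minus second);
    flagged as post hoc in the result kind.
    """
    a, b = levels
    present = set(cells[factor].unique())
    for lv in (a, b):
        if lv not in present:
            raise ValueError(f"level {lv!r} not present in factor {factor!r}")
    by = cells.groupby(["participant", factor], observed=True)[value_col].mean().unstack()
    diffs = (by[a] - by[b]).dropna().to_numpy()
    res = jzs_ttest_bf(diffs, r_scale, effect=f"{factor}: {a} vs {b}")
    return BFResult("posthoc", res.effect, res.bf, res.method, extra=res.extra)


# ---------------------------------------------------------------------------
# JZS linear regression (capacity analysis)
# ---------------------------------------------------------------------------

def bf_linear_regression(x: np.ndarray, y: np.ndarray,
                         r_scale: float = DEFAULT_REG_RSCALE) -> BFResult:
    """BF10 for a single-covariate linear model against the intercept-only
    null, under a Zellner–Siow prior on the standardized coefficient:

        BF10 = int (1+g)^((n-2-1)/2) (1+g(1-R^2))^(-(n-1)/2) pi(g) dg,
        g ~ InverseGamma(1/2, n r^2 / 2).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need matching 1-D arrays with n >= 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant x or y; regression BF undefined")
    n = x.size
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    scale = n * r_scale**2 / 2.0

    # same Gamma(1/2, 1) substitution as the t test: g = scale/u
    def integrand(u: float) -> float:
        g = scale / u
        return (
            (1 + g) ** ((n - 2.0) / 2.0 - 0.5)
            * (1 + g * (1 - r2)) ** (-(n - 1.0) / 2.0)
            * u**-0.5 * np.exp(-u) / special.gamma(0.5)
        )

    import warnings

    with warnings.catch_warnings():
        # near-perfect fits (R^2 -> 1) trip quad's roundoff heuristic while
        # the value is already accurate to many digits
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        bf, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    slope = float(np.polyfit(x, y, 1)[0])
    return BFResult("regression", "slope", bf, "quadrature",
                    extra=(("r2", r2), ("n", n), ("slope", slope)))


def extract_level_slopes(cells: pd.DataFrame, level_col: str,
                         value_col: str = "value") -> pd.Series:
    """Per-participant least-squares slope of value against level."""
    def fit(df: pd.DataFrame) -> float:
        x = df[level_col].to_numpy(dtype=np.float64)
        yv = df[value_col].to_numpy(dtype=np.float64)
        return float(np.polyfit(x, yv, 1)[0])

    return cells.groupby("participant", observed=True)[[level_col, value_col]] \
        .apply(fit).rename("slope")


# ---------------------------------------------------------------------------
# per-timepoint contrast
# ---------------------------------------------------------------------------

def timecourse_bf(series: pd.DataFrame, value_col: str = "db",
                  roles: tuple[str, str] = ("contra", "ipsi"),
                  r_scale: float = DEFAULT_T_RSCALE) -> pd.DataFrame:
    """Paired JZS BF10 at every window time for a contra-vs-ipsi contrast.

    ``series`` is long with columns participant, window_time, axis_role and
    the value column (one value per participant x role x time; average
    trials first).  Returns per-time BF10, the role difference, and an
    ``exceeds_threshold`` annotation at the conventional BF10 > 3 level.
    """
    a, b = roles
    wide = series.pivot_table(index=["participant", "window_time"],
                              columns="axis_role", values=value_col,
                              observed=True)
    for role in roles:
        if role not in wide.columns:
            raise ValueError(f"role {role!r} missing from series")
    rows = []
    for t, df in wide.groupby(level="window_time"):
        diffs = (df[a] - df[b]).dropna().to_numpy()
        res = jzs_ttest_bf(diffs, r_scale, effect=f"{a} - {b} @ {t:.3f} s")
        rows.append({"window_time": t, "bf10": res.bf,
                     "mean_diff": float(diffs.mean()), "n": diffs.size,
                     "exceeds_threshold": res.bf > EVIDENCE_THRESHOLD})
    return pd.DataFrame(rows)
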