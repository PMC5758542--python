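"""Inferential layer: ANOVAs, the moderated gain regression, partial
correlations, and BCa bootstrap confidence intervals.

The headline model regresses executive-function gain on age, mean
framewise displacement, baseline EF, baseline modularity Q, and the
product of (mean-centered) baseline EF and Q:

    EF_gain ~ age + meanFD + EF_base + Q + EF_base_c * Q_c

fitted by OLS within each intervention group. The interaction tests
whether the modularity-gain slope is moderated by baseline ability.
Coefficient CIs are reported two ways: case-resampling bias-corrected
and accelerated (BCa) bootstrap intervals (default 5000 resamples), and
classical analytic OLS intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "BootstrapSpec",
    "BcaInterval",
    "RegressionResult",
    "bca_ci",
    "mixed_anova",
    "gain_anova",
    "fit_gain_model",
    "partial_correlation",
    "bonferroni",
    "GAIN_MODEL_TERMS",
]

GAIN_MODEL_TERMS = ("intercept", "age", "mean_fd", "ef_base", "modularity",
                    "ef_base_x_modularity")


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap settings: ``n_boot`` resamples, BCa 95% CIs by default."""

    n_boot: int = 5000
    ci_level: float = 0.95
    method: str = "bca"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.method != "bca":
            raise ValueError("only the BCa method is implemented")
        if self.n_boot < 1000:
            warnings.warn("n_boot < 1000: CIs are unstable for reporting",
                          stacklevel=2)


@dataclass(frozen=True)
class BcaInterval:
    lo: float
    hi: float
    estimate: float
    z0: float
    accel: float
    clamped: bool = False


def _bca_endpoints(estimate: float, boot: np.ndarray, jack: np.ndarray,
                   ci_level: float) -> BcaInterval:
    """BCa interval from precomputed bootstrap and jackknife statistics."""
    boot = np.asarray(boot, dtype=float)
    if np.ptp(boot) == 0:
        raise ValueError("degenerate bootstrap distribution: statistic constant")
    frac = np.mean(boot < estimate)
    clamped = False
    if frac == 0.0 or frac == 1.0:
        clamped = True
        warnings.warn("point estimate outside bootstrap range; z0 clamped",
                      stacklevel=3)
        eps = 1.0 / (boot.size + 1)
        frac = np.clip(frac, eps, 1 - eps)
    z0 = sps.norm.ppf(frac)
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    accel = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0
    alpha = 1.0 - ci_level
    out = []
    for a in (alpha / 2.0, 1.0 - alpha / 2.0):
        za = sps.norm.ppf(a)
        adj = sps.norm.cdf(z0 + (z0 + za) / (1.0 - accel * (z0 + za)))
        out.append(float(np.quantile(boot, adj)))
    return BcaInterval(lo=out[0], hi=out[1], estimate=float(estimate),
                       z0=float(z0), accel=accel, clamped=clamped)


def bca_ci(statistic: Callable[[np.ndarray], float], data: np.ndarray,
           spec: BootstrapSpec,
           vectorized_statistic: Callable[[np.ndarray], np.ndarray] | None = None,
           ) -> BcaInterval:
    """Case-resampling BCa bootstrap CI for a scalar statistic of data rows.

    ``statistic(rows) -> float`` is evaluated on the full sample, on
    ``spec.n_boot`` resamples drawn with replacement, and on all n
    leave-one-out jackknife subsamples (bias correction ``z0`` from the
    bootstrap distribution; acceleration from jackknife skewness).
    ``vectorized_statistic(resamples)`` taking a (B, n, ...) stack may be
    supplied to batch the bootstrap evaluations.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to bootstrap")
    rng = np.random.default_rng(spec.seed)
    estimate = float(statistic(data))
    idx = rng.integers(0, n, size=(spec.n_boot, n))
    if vectorized_statistic is not None:
        boot = np.asarray(vectorized_statistic(data[idx]), dtype=float)
    else:
        boot = np.array([statistic(data[row]) for row in idx])
    jack = np.array([
        statistic(np.delete(data, i, axis=0)) for i in range(n)
    ])
    return _bca_endpoints(estimate, boot, jack, spec.ci_level)


# -- ANOVA ------------------------------------------------------------------

def mixed_anova(pre: np.ndarray, post: np.ndarray,
                group: Sequence) -> pd.DataFrame:
    """Mixed two-way ANOVA: time (pre/post, within) x group (between).

    Complete pre/post pairs only; every group needs n >= 2. Returns a table
    indexed by effect (``group``, ``time``, ``interaction``) with columns
    F, df1, df2, p, np2 (partial eta squared).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    ok = ~(np.isnan(pre) | np.isnan(post))
    pre, post, group = pre[ok], post[ok], group[ok]
    counts = pd.Series(group).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"group(s) with n < 2: {small}")
    _heteroscedasticity_warning(post - pre, group)
    n = pre.size
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "time": np.repeat(["pre", "post"], n),
        "group": np.tile(group, 2),
        "value": np.concatenate([pre, post]),
    })
    res = pg.mixed_anova(data=long, dv="value", within="time",
                         subject="subject", between="group")
    res = res.rename(columns={"Source": "effect", "DF1": "df1", "DF2": "df2",
                              "ddof1": "df1", "ddof2": "df2",
                              "p-unc": "p", "p_unc": "p"})
    res["effect"] = res["effect"].str.lower()
    return res.set_index("effect")[["F", "df1", "df2", "p", "np2"]]


def _heteroscedasticity_warning(values: np.ndarray, group: np.ndarray) -> None:
    variances = pd.Series(values).groupby(pd.Series(group)).var(ddof=1)
    variances = variances[variances > 0]
    if len(variances) >= 2 and variances.max() / variances.min() > 4.0:
        warnings.warn("group variances differ more than 4-fold; classical "
                      "ANOVA assumptions are strained", stacklevel=3)


def gain_anova(gain: np.ndarray, group: Sequence,
               covariates: np.ndarray | None = None) -> dict:
    """One-way ANOVA (or ANCOVA) on a gain score across intervention groups.

    Covariates, if given (n x k), are partialled out by residualizing both
    the gain and the group indicators on them before the F test
    (equivalent to the covariate-adjusted group test). Also reports each
    group's one-sample t test of mean gain against zero and Bonferroni-
    corrected pairwise contrasts.
    """
    gain = np.asarray(gain, dtype=float)
    group = np.asarray(group)
    ok = ~np.isnan(gain)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != gain.size:
            covariates = covariates.T
        ok &= ~np.isnan(covariates).any(axis=1)
        covariates = covariates[ok]
    gain, group = gain[ok], group[ok]
    levels = sorted(pd.unique(group).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for lev in levels:
        g = gain[group == lev]
        if g.size >= 2 and g.var(ddof=1) == 0:
            raise ValueError(f"zero within-group variance in group {lev!r}")
    _heteroscedasticity_warning(gain, group)

    # design: intercept + group dummies (+ covariates)
    dummies = np.column_stack([(group == lev).astype(float) for lev in levels[1:]])
    n = gain.size
    intercept = np.ones((n, 1))
    if covariates is None:
        x_null = intercept
    else:
        x_null = np.hstack([intercept, covariates])
    x_full = np.hstack([x_null, dummies])
    rss_null = _rss(x_null, gain)
    rss_full = _rss(x_full, gain)
    df1 = dummies.shape[1]
    df2 = n - x_full.shape[1]
    ss_effect = rss_null - rss_full
    f_stat = (ss_effect / df1) / (rss_full / df2) if rss_full > 0 else np.inf
    p = float(sps.f.sf(f_stat, df1, df2))
    eta_p = float(ss_effect / (ss_effect + rss_full)) if (ss_effect + rss_full) else 0.0

    per_group = {}
    for lev in levels:
        g = gain[group == lev]
        t, pt = sps.ttest_1samp(g, 0.0)
        per_group[lev] = {"n": int(g.size), "mean": float(g.mean()),
                          "t": float(t), "p": float(pt)}
    pairs = {}
    combos = list(itertools.combinations(levels, 2))
    for a, b in combos:
        t, pt = sps.ttest_ind(gain[group == a], gain[group == b])
        pairs[(a, b)] = {"t": float(t), "p": float(pt),
                         "p_bonferroni": bonferroni(pt, len(combos))}
    return {"F": float(f_stat), "df1": df1, "df2": df2, "p": p,
            "partial_eta_sq": eta_p, "n": n, "per_group": per_group,
            "pairwise": pairs}


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


# -- the moderated gain regression -----------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """OLS fit with bootstrap and analytic CIs per coefficient."""

    table: pd.DataFrame  # index: term; columns: B, ci_lo, ci_hi, ci_lo_analytic, ci_hi_analytic, p
    r2: float
    r2_adj: float
    f_stat: float
    df_model: int
    df_resid: int
    f_p: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)


def _design_matrix(df: pd.DataFrame, reduced: bool, center: bool
                   ) -> tuple[np.ndarray, list[str]]:
    q = df["modularity"].to_numpy(dtype=float)
    n = len(df)
    if reduced:
        x = np.column_stack([np.ones(n), q])
        return x, ["intercept", "modularity"]
    age = df["age"].to_numpy(dtype=float)
    fd = df["mean_fd"].to_numpy(dtype=float)
    ef = df["ef_base"].to_numpy(dtype=float)
    if center:
        ef_c = ef - ef.mean()
        q_c = q - q.mean()
    else:
        ef_c, q_c = ef, q
    x = np.column_stack([np.ones(n), age, fd, ef_c, q_c, ef_c * q_c])
    return x, list(GAIN_MODEL_TERMS)


def fit_gain_model(cohort: pd.DataFrame,
                   spec: BootstrapSpec | None = None,
                   reduced: bool = False,
                   center: bool = True,
                   bootstrap_ci: bool = True) -> RegressionResult:
    """OLS of EF gain on age, mean FD, baseline EF, modularity and the
    centered EF x modularity interaction, with BCa bootstrap CIs.

    ``cohort`` needs columns ``ef_gain``, ``modularity`` and — unless
    ``reduced=True`` (modularity-only model) — ``age``, ``mean_fd``,
    ``ef_base``. Rows with any missing required field are dropped.
    ``center`` mean-centers baseline EF and modularity before forming the
    main-effect and product columns, so their coefficients are simple
    effects at the sample mean of the moderator (the fitted values are
    identical either way).
    """
    spec = spec or BootstrapSpec()
    cols = ["ef_gain", "modularity"] if reduced else [
        "ef_gain", "age", "mean_fd", "ef_base", "modularity"]
    data = cohort.dropna(subset=cols)
    n = len(data)
    y = data["ef_gain"].to_numpy(dtype=float)
    x, terms = _design_matrix(data, reduced, center)
    p = x.shape[1]
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for {p} parameters")
    cond = np.linalg.cond(x)
    if cond > 1e8:
        raise ValueError(
            f"collinear design (condition number {cond:.3g}) among terms {terms}")

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_model, df_resid = p - 1, n - p
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    if df_model > 0 and rss > 0:
        f_stat = (tss - rss) / df_model / (rss / df_resid)
        f_p = float(sps.f.sf(f_stat, df_model, df_resid))
    else:  # noise-free fit
        f_stat, f_p = np.inf, 0.0

    sigma2 = rss / df_resid if df_resid > 0 else 0.0
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)
    tcrit = sps.t.ppf(1 - (1 - spec.ci_level) / 2, df_resid)

    # case-resampling bootstrap of the whole coefficient vector
    if bootstrap_ci:
        rng = np.random.default_rng(spec.seed)
        idx = rng.integers(0, n, size=(spec.n_boot, n))
        boot = np.empty((spec.n_boot, p))
        for b, row in enumerate(idx):
            boot[b], *_ = np.linalg.lstsq(x[row], y[row], rcond=None)
        jack = np.empty((n, p))
        for i in range(n):
            keep = np.delete(np.arange(n), i)
            jack[i], *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
    rows = []
    for j, term in enumerate(terms):
        if not bootstrap_ci:
            lo, hi = np.nan, np.nan
        elif np.ptp(boot[:, j]) == 0:  # noise-free data: exact coefficients
            lo = hi = beta[j]
        else:
            ci = _bca_endpoints(beta[j], boot[:, j], jack[:, j], spec.ci_level)
            lo, hi = ci.lo, ci.hi
        rows.append({
            "term": term, "B": float(beta[j]),
            "ci_lo": float(lo), "ci_hi": float(hi),
            "ci_lo_analytic": float(beta[j] - tcrit * se[j]),
            "ci_hi_analytic": float(beta[j] + tcrit * se[j]),
            "se": float(se[j]), "p": float(pvals[j]),
        })
    table = pd.DataFrame(rows).set_index("term")
    return RegressionResult(table=table, r2=r2, r2_adj=r2_adj,
                            f_stat=float(f_stat), df_model=df_model,
                            df_resid=df_resid, f_p=f_p, n=n, residuals=resid)


# -- partial correlation ----------------------------------------------------

def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(c, v, rcond=None)
    return v - c @ beta


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None,
                        tail: str = "two-sided",
                        spec: BootstrapSpec | None = None) -> dict:
    """Partial correlation of x and y controlling for covariates.

    Computed as the Pearson correlation of the OLS residuals of x and y on
    the covariates (plus intercept); df = n - k - 2 for k covariates. The
    one-tailed p tests the observed sign. When ``spec`` is given, a BCa
    bootstrap CI over case resampling is included.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        c = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        c = np.hstack([np.ones((n, 1)), covariates])
        k = covariates.shape[1]
        if np.linalg.cond(c) > 1e8:
            raise ValueError("collinear covariates")
    if n <= k + 2:
        raise ValueError(f"n = {n} too small for {k} covariates")
    rx = _residualize(x, c)
    ry = _residualize(y, c)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    if tail == "two-sided":
        p = float(2.0 * sps.t.sf(abs(t), df))
    elif tail == "one-sided":
        p = float(sps.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'two-sided' or 'one-sided'")
    out = {"r": r, "df": df, "t": float(t), "p": p, "n": n}
    if spec is not None:
        rows = np.column_stack([x, y] + ([] if covariates is None else [covariates]))

        def stat(sub: np.ndarray) -> float:
            cc = np.hstack([np.ones((sub.shape[0], 1)), sub[:, 2:]])
            return float(np.corrcoef(_residualize(sub[:, 0], cc),
                                     _residualize(sub[:, 1], cc))[0, 1])

        ci = bca_ci(stat, rows, spec)
        out["ci"] = (ci.lo, ci.hi)
    return out


def bonferroni(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)`` for m comparisons."""
    p_arr = np.asarray(p, dtype=float)
    if m < 1 or (p_arr.ndim > 0 and m < p_arr.size):
        raise ValueError("m must cover the number of tests")
    adj = np.minimum(1.0, m * p_arr)
    return float(adj) if np.isscalar(p) or p_arr.ndim == 0 else adj
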