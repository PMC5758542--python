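"""Cognitive battery scoring: cleaning, composites, gains, PCA structure check.

The battery comprises 17 tests grouped into four constructs — vocabulary,
perceptual speed, episodic memory, and executive function (EF: the fluid
reasoning tests plus task switching and spatial working memory). Scoring
proceeds per test:

1. **Cleaning** (:func:`clean_scores`): values more than 3 SD from the
   sample mean are excluded; the mean/SD are recomputed on the survivors
   and remaining values beyond 3 SD are winsorized to the cut-off.
2. **Standardized gain** (:func:`standardized_gain`):
   ``(post - pre) / SD_pre`` with the pre-test SD pooled across groups; a
   direction flag makes positive gain always mean improvement (reaction-
   time costs are lower-is-better).
3. **Composites** (:func:`compute_composites`): per-construct means of
   member-test z-scores (baseline) and standardized gains.
4. **Structure check** (:func:`pca_check`): PCA of the baseline
   correlation matrix with an oblique (promax) rotation, verifying each
   test loads highest on its own construct's component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import promax as _promax
from statsmodels.multivariate.factor_rotation import rotate_factors as _rotate

__all__ = [
    "DEFAULT_CONSTRUCT_MAP",
    "DEFAULT_DIRECTIONS",
    "CleaningAudit",
    "clean_scores",
    "standardized_gain",
    "compute_composites",
    "pca_check",
    "task_switching_scores",
]

# test -> construct. EF groups the fluid reasoning tests with the task
# switching and spatial working memory measures.
DEFAULT_CONSTRUCT_MAP: dict[str, str] = {
    "word_vocabulary": "vocabulary",
    "picture_vocabulary": "vocabulary",
    "synonym_antonym": "vocabulary",
    "digit_symbol": "speed",
    "pattern_comparison": "speed",
    "letter_comparison": "speed",
    "word_recall": "memory",
    "logical_memory": "memory",
    "paired_associates": "memory",
    "shipley_abstraction": "ef",
    "form_boards": "ef",
    "letter_sets": "ef",
    "matrix_reasoning": "ef",
    "paper_folding": "ef",
    "spatial_relations": "ef",
    "spatial_working_memory": "ef",
    "switch_cost": "ef",
}

# +1: higher raw score is better; -1: lower is better (RT costs).
DEFAULT_DIRECTIONS: dict[str, int] = {t: 1 for t in DEFAULT_CONSTRUCT_MAP}
DEFAULT_DIRECTIONS["switch_cost"] = -1

CONSTRUCTS = ("vocabulary", "speed", "memory", "ef")


@dataclass
class CleaningAudit:
    """Per-value record of outlier handling for one test."""

    excluded: list[int] = field(default_factory=list)     # indices set to missing
    winsorized: list[int] = field(default_factory=list)   # indices clamped
    degenerate: bool = False                              # zero-SD short circuit


def clean_scores(raw: Sequence[float] | np.ndarray,
                 n_sd: float = 3.0) -> tuple[np.ndarray, CleaningAudit]:
    """Two-pass outlier handling for one test's scores across subjects.

    Pass 1 marks values strictly beyond ``n_sd`` sample SDs of the mean as
    missing (NaN). Pass 2 recomputes mean/SD on the survivors and clamps
    survivors strictly beyond ``n_sd`` SDs to the cut-off value. Exactly-at-
    boundary values are untouched in both passes. The two passes are
    iterated to a fixed point (clamping shrinks the SD, which can push an
    already-clamped value back outside the band), so cleaning is exactly
    idempotent; in practice the iteration converges in one or two rounds.
    Missing inputs pass through.
    """
    x = np.asarray(raw, dtype=float).copy()
    audit = CleaningAudit()
    if (~np.isnan(x)).sum() < 3:
        raise ValueError("need at least 3 non-missing values to clean")
    for _ in range(100):
        obs = ~np.isnan(x)
        mu, sd = x[obs].mean(), x[obs].std(ddof=1)
        if sd == 0:
            audit.degenerate = True
            warnings.warn("zero dispersion; scores returned unchanged",
                          stacklevel=2)
            return x, audit
        extreme = obs & (np.abs(x - mu) > n_sd * sd)
        audit.excluded.extend(np.nonzero(extreme)[0].tolist())
        x[extreme] = np.nan

        obs = ~np.isnan(x)
        mu, sd = x[obs].mean(), x[obs].std(ddof=1)
        if sd == 0:
            audit.degenerate = True
            warnings.warn("zero dispersion after exclusion; no winsorization",
                          stacklevel=2)
            return x, audit
        lo, hi = mu - n_sd * sd, mu + n_sd * sd
        below = obs & (x < lo)
        above = obs & (x > hi)
        if not (extreme.any() or below.any() or above.any()):
            break
        audit.winsorized.extend(np.nonzero(below | above)[0].tolist())
        x[below] = lo
        x[above] = hi
    audit.excluded = sorted(set(audit.excluded))
    audit.winsorized = sorted(set(audit.winsorized) - set(audit.excluded))
    return x, audit


def standardized_gain(pre: np.ndarray, post: np.ndarray,
                      direction: int = 1) -> np.ndarray:
    """Gain in pre-test-SD units: ``direction * (post - pre) / SD_pre``.

    ``SD_pre`` is the sample SD of the raw pre-test scores pooled across
    groups (computed over non-missing values). ``direction=-1`` flips
    lower-is-better measures so positive gain always means improvement.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must align")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    sd_pre = pre[~np.isnan(pre)].std(ddof=1)
    if not np.isfinite(sd_pre) or sd_pre == 0:
        raise ValueError("pooled pre-test SD is zero; gain undefined")
    return direction * (post - pre) / sd_pre


def _baseline_z(pre: np.ndarray, direction: int) -> np.ndarray:
    obs = ~np.isnan(pre)
    mu, sd = pre[obs].mean(), pre[obs].std(ddof=1)
    if sd == 0:
        raise ValueError("zero baseline SD; z-score undefined")
    return direction * (pre - mu) / sd


def compute_composites(battery: pd.DataFrame,
                       construct_map: Mapping[str, str] | None = None,
                       directions: Mapping[str, int] | None = None,
                       clean: bool = True,
                       ) -> tuple[pd.DataFrame, dict[str, CleaningAudit]]:
    """Construct-level baseline z-composites and standardized gain composites.

    ``battery`` has one row per subject with ``<test>_pre`` / ``<test>_post``
    columns for every test in ``construct_map``. Baseline z-scores are
    standardized against the analyzed sample. Composites average the
    available member tests; a ``completeness_<construct>`` column records
    the fraction of member tests present per subject.

    Returns the composites table (``baseline_<c>``, ``gain_<c>``,
    ``completeness_<c>`` per construct) and the per-column cleaning audit.
    """
    construct_map = dict(construct_map or DEFAULT_CONSTRUCT_MAP)
    directions = dict(directions or DEFAULT_DIRECTIONS)
    missing_dir = set(construct_map) - set(directions)
    if missing_dir:
        raise ValueError(f"no direction flag for test(s): {sorted(missing_dir)}")

    audits: dict[str, CleaningAudit] = {}
    z_cols: dict[str, np.ndarray] = {}
    gain_cols: dict[str, np.ndarray] = {}
    for test in construct_map:
        pre = battery[f"{test}_pre"].to_numpy(dtype=float)
        post = battery[f"{test}_post"].to_numpy(dtype=float)
        if clean:
            pre, audits[f"{test}_pre"] = clean_scores(pre)
            post, audits[f"{test}_post"] = clean_scores(post)
        d = directions[test]
        z_cols[test] = _baseline_z(pre, d)
        gain_cols[test] = standardized_gain(pre, post, direction=d)

    out = pd.DataFrame(index=battery.index)
    for construct in CONSTRUCTS:
        members = [t for t, c in construct_map.items() if c == construct]
        if not members:
            continue
        z = np.column_stack([z_cols[t] for t in members])
        g = np.column_stack([gain_cols[t] for t in members])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
            out[f"baseline_{construct}"] = np.nanmean(z, axis=1)
            out[f"gain_{construct}"] = np.nanmean(g, axis=1)
        out[f"completeness_{construct}"] = (~np.isnan(g)).mean(axis=1)
    return out, audits


def pca_check(baseline: pd.DataFrame, n_components: int = 4,
              rotation: str = "promax") -> pd.DataFrame:
    """PCA of the baseline correlation matrix with oblique rotation.

    Returns a tests x components table of rotated loadings (pattern
    matrix) plus a ``dominant`` column giving each test's top component by
    absolute loading. Rows with any missing value are dropped; a singular
    correlation matrix (e.g. duplicated tests) raises.
    """
    data = baseline.dropna(axis=0)
    n, p = data.shape
    if n < 4 * p:
        warnings.warn(
            f"only {n} subjects for {p} tests (<4x); loadings may be unstable",
            stacklevel=2,
        )
    corr = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix has undefined entries")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] < 1e-10:
        raise ValueError("singular correlation matrix (collinear tests?)")
    lead = evals[:n_components]
    loadings = evecs[:, :n_components] * np.sqrt(lead)
    if rotation == "promax":
        loadings, _ = _promax(loadings)
    elif rotation == "varimax":
        loadings, _ = _rotate(loadings, "varimax")
    elif rotation != "none":
        raise ValueError(f"unknown rotation {rotation!r}")
    cols = [f"PC{i + 1}" for i in range(n_components)]
    table = pd.DataFrame(loadings, index=data.columns, columns=cols)
    table["dominant"] = table[cols].abs().idxmax(axis=1)
    return table


def task_switching_scores(trials: pd.DataFrame,
                          n_bins: int = 10) -> pd.DataFrame:
    """Local switch cost and rank-binned composite from mixed-block trials.

    ``trials`` columns: ``subject``, ``trial_type`` ('switch'/'nonswitch'),
    ``rt_ms``, ``correct`` (0/1). Per subject:

    * ``switch_cost_ms`` — mean correct-trial switch RT minus mean correct
      nonswitch RT (the measure used for intervention analyses);
    * ``bin_score`` — a combined speed/accuracy rank score: subjects are
      ranked into ``n_bins`` quantile bins separately on RT switch cost
      and on accuracy cost (nonswitch minus switch accuracy) and the two
      bin numbers are summed; lower is better. Being rank-based it is
      invariant to monotone transforms of the underlying scores.
    """
    required = {"subject", "trial_type", "rt_ms", "correct"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table needs columns {sorted(required)}")
    rows = []
    for subj, sub in trials.groupby("subject", sort=True):
        sw = sub[(sub.trial_type == "switch") & (sub.correct == 1)]
        ns = sub[(sub.trial_type == "nonswitch") & (sub.correct == 1)]
        if sw.empty or ns.empty:
            raise ValueError(f"subject {subj!r} lacks correct switch/nonswitch trials")
        rt_cost = sw.rt_ms.mean() - ns.rt_ms.mean()
        acc_sw = sub[sub.trial_type == "switch"].correct.mean()
        acc_ns = sub[sub.trial_type == "nonswitch"].correct.mean()
        rows.append({"subject": subj, "switch_cost_ms": rt_cost,
                     "acc_cost": acc_ns - acc_sw})
    out = pd.DataFrame(rows).set_index("subject")
    for col, bin_col in (("switch_cost_ms", "rt_bin"), ("acc_cost", "acc_bin")):
        ranks = out[col].rank(method="average")
        out[bin_col] = np.ceil(ranks / len(out) * n_bins).astype(int).clip(1, n_bins)
    out["bin_score"] = out["rt_bin"] + out["acc_bin"]
    return out[["switch_cost_ms", "bin_score", "rt_bin", "acc_bin"]]
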