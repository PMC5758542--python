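"""End-to-end assembly: raw subject data -> analysis-ready cohort table.

Per subject: motion QC (mean FD, exclusion), connectivity (Pearson ->
Fisher z -> proportional threshold), modularity (spectral and/or
canonical partition), and battery scoring (EF baseline composite and
standardized EF gain). The resulting table feeds
:func:`modgain.stats.fit_gain_model`.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import behavior, motion, netmetrics, stats
from .connectome import (TimeSeriesMatrix, correlation_matrix, exclude_rois,
                         fisher_z, proportional_threshold)
from .netmetrics import Partition, canonical_partition, modularity_q, spectral_partition
from .simulate import Cohort

__all__ = ["subject_modularity", "measure_cohort", "fit_group_models",
           "DEFAULT_COSTS"]

DEFAULT_COSTS = (0.02, 0.04, 0.06, 0.08, 0.10)


def subject_modularity(ts: TimeSeriesMatrix, cost: float = 0.06,
                       drop: Iterable[str] = (),
                       canonical: Mapping[str, object] | None = None) -> dict:
    """Modularity of one subject's scan at one density threshold.

    Returns spectral Q (partition maximizing Q) and, when a canonical
    node-to-module table is supplied, the fixed-partition Q as well, plus
    the Fisher-z matrix and graph for downstream metrics.
    """
    if drop:
        ts = exclude_rois(ts, list(drop))
    zm = fisher_z(correlation_matrix(ts))
    g = proportional_threshold(zm, cost)
    spectral = spectral_partition(g)
    out = {"q_spectral": spectral.q, "partition_spectral": spectral,
           "graph": g, "z_matrix": zm}
    if canonical is not None:
        cp = canonical_partition(dict(canonical), g.roi_ids)
        out["q_canonical"] = modularity_q(g, cp).q
        out["partition_canonical"] = cp
    return out


def measure_cohort(cohort: Cohort, cost: float = 0.06,
                   use_canonical: bool = False,
                   clean: bool = True) -> pd.DataFrame:
    """Assemble the subjects x variables table the statistics layer consumes.

    Columns: subject_id, group, age, mean_fd, excluded (motion QC),
    ef_base (baseline EF z-composite), ef_gain (standardized EF gain
    composite), modularity (spectral Q at ``cost``; canonical Q in
    ``modularity_canonical`` when requested via the generator's planted
    labels).
    """
    table = cohort.table.set_index("subject_id")
    composites, _ = behavior.compute_composites(table, clean=clean)
    rows = []
    for sid in table.index:
        rec: dict = {"subject_id": sid, "group": table.loc[sid, "group"],
                     "age": float(table.loc[sid, "age"])}
        if sid in cohort.motion:
            ms = motion.motion_summary(cohort.motion[sid])
            rec.update(mean_fd=ms.mean_fd, excluded=ms.excluded,
                       qc_reason=ms.reason)
        else:
            rec.update(mean_fd=np.nan, excluded=False, qc_reason="no trace")
        if sid in cohort.timeseries:
            canonical = None
            if use_canonical:
                gt = cohort.ground_truth
                canonical = dict(zip(
                    cohort.timeseries[sid].roi_ids, gt.module_labels))
            res = subject_modularity(cohort.timeseries[sid], cost=cost,
                                     canonical=canonical)
            rec["modularity"] = res["q_spectral"]
            if use_canonical:
                rec["modularity_canonical"] = res["q_canonical"]
        else:
            rec["modularity"] = np.nan
        rec["ef_base"] = composites.loc[sid, "baseline_ef"]
        rec["ef_gain"] = composites.loc[sid, "gain_ef"]
        rows.append(rec)
    return pd.DataFrame(rows)


def fit_group_models(cohort_table: pd.DataFrame,
                     spec: stats.BootstrapSpec | None = None,
                     drop_excluded: bool = True) -> dict[str, stats.RegressionResult]:
    """Fit the moderated gain regression separately within each group."""
    df = cohort_table
    if drop_excluded and "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    out = {}
    for name, sub in df.groupby("group", sort=True):
        out[name] = stats.fit_gain_model(sub, spec=spec)
    return out
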