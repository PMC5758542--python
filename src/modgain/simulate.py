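"""Synthetic cohort generator with known ground truth.

Every downstream stage of the pipeline gets a parameter-recovery test
from this module. A simulated subject consists of:

* **ROI time series** — i.i.d. draws from a zero-mean multivariate
  normal with planted block (module) structure: correlation ``r_within``
  inside modules and ``r_between`` across modules. A subject's latent
  modularity target scales their within/between contrast, so the
  *measured* spectral Q carries the planted brain-behavior effect with
  realistic attenuation rather than by construction.
* **Motion traces** — low-amplitude random-walk drift on six rigid-body
  parameters plus sustained displacement spikes (> 0.5 mm framewise
  displacement) at a configurable per-volume rate.
* **A 17-test cognitive battery** — pre/post scores with a planted
  four-construct structure (vocabulary, speed, episodic memory, EF) and
  group-specific gains. EF gain follows the planted moderation model:

      gain_EF = group_mean + beta_modularity * (Q_latent - q_ref)
                + beta_ef_base * EF_base
                + beta_interaction * EF_base * (Q_latent - q_ref)
                + noise

:func:`simulate_regression_cohort` emits the analysis-ready cohort table
(gain, modularity, covariates) directly from the planted model — the
fast path for calibrating and validating the inference layer — while
:func:`simulate_cohort` generates the full raw-data cohort for
end-to-end pipeline runs.

Reproducibility: one master seed; each subject's streams are derived
from ``(seed, subject_index, stream)``, so any subject can be
regenerated independently and bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .connectome import TimeSeriesMatrix, write_timeseries
from .motion import MotionTrace, write_motion

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "DEFAULT_PARTITION_SPEC",
    "DEFAULT_GROUPS",
    "simulate_timeseries",
    "simulate_motion",
    "simulate_battery_row",
    "simulate_cohort",
    "simulate_regression_cohort",
    "write_cohort",
]

# 13 functional systems over 252 retained ROIs (sizes sum to 252).
DEFAULT_PARTITION_SPEC: dict[str, int] = {
    "dmn": 55, "vis": 30, "fp": 24, "co": 14, "sal": 18, "dan": 11,
    "van": 9, "aud": 13, "sm_hand": 28, "sm_mouth": 5, "mem": 5,
    "sub": 13, "unassigned": 27,
}

# per-group mean gains in pre-test-SD units: EF gains for the three
# fitness-improving arms, near-zero for dance; CRF gains largest for the
# walking arms.
DEFAULT_GROUPS: dict[str, dict[str, float]] = {
    "walk": {"ef": 0.16, "crf": 0.55},
    "walk_plus": {"ef": 0.17, "crf": 0.55},
    "sss": {"ef": 0.19, "crf": 0.22},
    "dance": {"ef": 0.03, "crf": 0.06},
}

# per-subject stream tags
_LATENT, _TS, _MOTION, _BATTERY = 0, 1, 2, 3

# test -> (offset, scale) of the raw score distribution
_TEST_SCALES: dict[str, tuple[float, float]] = {
    "digit_symbol": (70.0, 12.0),
    "pattern_comparison": (16.0, 3.0),
    "letter_comparison": (11.0, 2.5),
    "word_recall": (35.0, 7.0),
    "logical_memory": (44.0, 9.0),
    "paired_associates": (3.5, 1.3),
    "shipley_abstraction": (12.0, 3.5),
    "form_boards": (8.0, 3.0),
    "letter_sets": (10.0, 2.5),
    "matrix_reasoning": (8.0, 3.0),
    "paper_folding": (6.0, 2.5),
    "spatial_relations": (8.0, 4.0),
    "word_vocabulary": (45.0, 9.0),
    "picture_vocabulary": (20.0, 4.0),
    "synonym_antonym": (13.0, 4.0),
    "spatial_working_memory": (0.80, 0.08),
    "switch_cost": (250.0, 120.0),
}

_TEST_CONSTRUCT: dict[str, str] = {
    "word_vocabulary": "vocabulary", "picture_vocabulary": "vocabulary",
    "synonym_antonym": "vocabulary",
    "digit_symbol": "speed", "pattern_comparison": "speed",
    "letter_comparison": "speed",
    "word_recall": "memory", "logical_memory": "memory",
    "paired_associates": "memory",
    "shipley_abstraction": "ef", "form_boards": "ef", "letter_sets": "ef",
    "matrix_reasoning": "ef", "paper_folding": "ef", "spatial_relations": "ef",
    "spatial_working_memory": "ef", "switch_cost": "ef",
}

_TEST_DIRECTION: dict[str, int] = {t: 1 for t in _TEST_SCALES}
_TEST_DIRECTION["switch_cost"] = -1

_CONSTRUCT_ORDER = ("vocabulary", "speed", "memory", "ef")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the acquisition and design being emulated: 180
    volumes at TR = 2 s over 252 ROIs in 13 modules, four intervention
    arms, and a planted modularity -> EF-gain slope of the magnitude seen
    in moderated-regression analyses of this kind (~1.8 per unit Q, with
    a negative EF x Q interaction).
    """

    n_subjects: int = 0
    n_rois: int = 252
    n_volumes: int = 180
    tr_seconds: float = 2.0
    partition_spec: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PARTITION_SPEC))
    r_within: float = 0.25
    r_between: float = 0.10
    groups: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUPS.items()})
    beta_modularity: float = 1.8
    beta_interaction: float = -2.4
    beta_ef_base: float = -0.05
    noise_sd: float = 0.15
    motion_spike_prob: float = 0.05
    seed: int = 0
    # latent modularity target distribution and centering reference
    q_mean: float = 0.30
    q_sd: float = 0.06
    q_ref: float = 0.30
    # battery structure
    factor_corr: float = 0.30
    loading: float = 0.75
    # motion drift
    drift_sd_mm: float = 0.01
    drift_sd_rad: float = 1e-4
    spike_min_mm: float = 0.6
    spike_max_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_rois < 1 or self.n_volumes < 2:
            raise ValueError("invalid cohort dimensions")
        sizes = dict(self.partition_spec)
        if sum(sizes.values()) != self.n_rois:
            raise ValueError(
                f"module sizes sum to {sum(sizes.values())}, not n_rois = {self.n_rois}")
        if any(s < 1 for s in sizes.values()):
            raise ValueError("module sizes must be positive")
        if not (0.0 <= self.r_between <= self.r_within < 1.0):
            raise ValueError(
                "block covariance not positive semi-definite: need "
                f"0 <= r_between <= r_within < 1, got r_within={self.r_within}, "
                f"r_between={self.r_between}")
        if not self.groups:
            raise ValueError("at least one group required")
        for name, g in self.groups.items():
            if "ef" not in g or "crf" not in g:
                raise ValueError(f"group {name!r} needs 'ef' and 'crf' gain means")
        if not (0 <= self.motion_spike_prob <= 1):
            raise ValueError("motion_spike_prob must be a probability")
        if self.noise_sd < 0 or self.q_sd < 0:
            raise ValueError("negative SD")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.groups)

    @property
    def module_labels(self) -> np.ndarray:
        """Planted module label per ROI, in ROI order."""
        return np.repeat(list(self.partition_spec.keys()),
                         list(self.partition_spec.values()))

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(f"roi{i:03d}" for i in range(self.n_rois))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities; stored alongside a cohort, never fed to analyses."""

    q_latent: np.ndarray
    ef_base: np.ndarray
    group: np.ndarray
    beta_modularity: float
    beta_interaction: float
    beta_ef_base: float
    group_ef_means: dict
    group_crf_means: dict
    module_labels: np.ndarray
    q_ref: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "q_latent": self.q_latent.tolist(),
            "ef_base": self.ef_base.tolist(),
            "group": self.group.tolist(),
            "beta_modularity": self.beta_modularity,
            "beta_interaction": self.beta_interaction,
            "beta_ef_base": self.beta_ef_base,
            "group_ef_means": self.group_ef_means,
            "group_crf_means": self.group_crf_means,
            "module_labels": self.module_labels.tolist(),
            "q_ref": self.q_ref,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class Cohort:
    table: pd.DataFrame
    ground_truth: GroundTruth
    timeseries: dict[str, TimeSeriesMatrix] = field(default_factory=dict)
    motion: dict[str, MotionTrace] = field(default_factory=dict)


def _rng(config: SimulationConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, subject_index, stream])


def _latents(config: SimulationConfig, i: int) -> dict:
    """Per-subject latent draws, fixed order for reproducibility."""
    rng = _rng(config, i, _LATENT)
    q = config.q_mean + config.q_sd * rng.standard_normal()
    q = float(np.clip(q, 0.02, 0.65))
    age = float(rng.uniform(60.0, 78.0))
    # correlated construct factors (vocabulary, speed, memory, ef)
    rho = config.factor_corr
    corr = np.full((4, 4), rho) + (1 - rho) * np.eye(4)
    factors = np.linalg.cholesky(corr) @ rng.standard_normal(4)
    gain_noise = rng.standard_normal(4) * config.noise_sd
    vo2_pre = float(np.clip(20.0 + 4.5 * rng.standard_normal(), 6.0, 36.0))
    crf_noise = float(rng.standard_normal())
    group = config.group_names[i % len(config.group_names)]
    return {"q": q, "age": age, "factors": factors, "gain_noise": gain_noise,
            "vo2_pre": vo2_pre, "crf_noise": crf_noise, "group": group}


def _construct_gains(config: SimulationConfig, lat: dict) -> dict[str, float]:
    """Planted construct-level gains (pre-test-SD units) for one subject."""
    g = config.groups[lat["group"]]
    ef_base = float(lat["factors"][3])
    qc = lat["q"] - config.q_ref
    gains = {
        "vocabulary": 0.05 + lat["gain_noise"][0],
        "speed": 0.05 + lat["gain_noise"][1],
        "memory": 0.05 + lat["gain_noise"][2],
        "ef": (g["ef"] + config.beta_modularity * qc
               + config.beta_ef_base * ef_base
               + config.beta_interaction * ef_base * qc
               + lat["gain_noise"][3]),
    }
    return gains


def subject_within_correlation(config: SimulationConfig, q_latent: float) -> float:
    """Map a latent modularity target to the subject's within-module r."""
    contrast = (config.r_within - config.r_between) * q_latent / config.q_ref
    return float(np.clip(config.r_between + contrast, config.r_between, 0.97))


def simulate_timeseries(config: SimulationConfig, subject_index: int) -> TimeSeriesMatrix:
    """Block-covariance multivariate-normal ROI time series for one subject.

    Correlation is ``r_within_s`` inside planted modules and ``r_between``
    across them, where the subject's within-module correlation scales with
    their latent modularity target. Deterministic given (seed, index).
    """
    if subject_index >= config.n_subjects:
        raise IndexError("subject_index beyond configured cohort size")
    lat = _latents(config, subject_index)
    rw = subject_within_correlation(config, lat["q"])
    rb = config.r_between
    rng = _rng(config, subject_index, _TS)
    sizes = list(config.partition_spec.values())
    t, n = config.n_volumes, config.n_rois
    shared = np.sqrt(rb) * rng.standard_normal((t, 1))
    block_f = rng.standard_normal((t, len(sizes)))
    eps = rng.standard_normal((t, n))
    block_expanded = np.repeat(block_f, sizes, axis=1)
    values = shared + np.sqrt(rw - rb) * block_expanded + np.sqrt(1.0 - rw) * eps
    return TimeSeriesMatrix(values=values, roi_ids=config.roi_ids,
                            tr_seconds=config.tr_seconds)


def simulate_motion(config: SimulationConfig, subject_index: int) -> MotionTrace:
    """Drifting six-parameter motion trace with sustained displacement spikes.

    Drift is a low-amplitude random walk; each post-baseline volume
    independently hosts a spike with probability ``motion_spike_prob``, a
    sustained translation shift of 0.6-1.5 mm on a random axis (one
    framewise-displacement excursion > 0.5 mm per spike).
    """
    rng = _rng(config, subject_index, _MOTION)
    t = config.n_volumes
    trans = np.cumsum(rng.normal(0.0, config.drift_sd_mm, (t, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, config.drift_sd_rad, (t, 3)), axis=0)
    trans -= trans[0]
    rot -= rot[0]
    spikes = rng.random(t - 1) < config.motion_spike_prob
    for frame in np.nonzero(spikes)[0] + 1:
        axis = rng.integers(0, 3)
        mag = rng.uniform(config.spike_min_mm, config.spike_max_mm)
        # mean-reverting sign: the head drifts back toward the reference
        # position, so spikes raise FD without accumulating displacement
        offset = trans[frame - 1, axis]
        if abs(offset) > config.spike_max_mm:
            sign = -np.sign(offset)
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        trans[frame:, axis] += sign * mag
    return MotionTrace(translations=trans, rotations=rot)


def simulate_battery_row(config: SimulationConfig, subject_index: int) -> dict:
    """Pre/post raw scores on the 17-test battery for one subject."""
    lat = _latents(config, subject_index)
    gains = _construct_gains(config, lat)
    rng = _rng(config, subject_index, _BATTERY)
    lam = config.loading
    construct_idx = {c: k for k, c in enumerate(_CONSTRUCT_ORDER)}
    row: dict[str, float] = {}
    for test, (offset, scale) in _TEST_SCALES.items():
        c = _TEST_CONSTRUCT[test]
        d = _TEST_DIRECTION[test]
        s_true = lam * lat["factors"][construct_idx[c]] + np.sqrt(1 - lam**2) * rng.standard_normal()
        pre = offset + scale * d * s_true
        test_gain = gains[c] + 0.10 * rng.standard_normal()
        post = pre + d * scale * test_gain
        row[f"{test}_pre"] = float(pre)
        row[f"{test}_post"] = float(post)
    g = config.groups[lat["group"]]
    row["vo2peak_pre"] = lat["vo2_pre"]
    row["vo2peak_post"] = float(lat["vo2_pre"] + 4.5 * (g["crf"] + 0.3 * lat["crf_noise"]))
    return row


def _ground_truth(config: SimulationConfig, idx: range) -> GroundTruth:
    lats = [_latents(config, i) for i in idx]
    return GroundTruth(
        q_latent=np.array([l["q"] for l in lats]),
        ef_base=np.array([float(l["factors"][3]) for l in lats]),
        group=np.array([l["group"] for l in lats]),
        beta_modularity=config.beta_modularity,
        beta_interaction=config.beta_interaction,
        beta_ef_base=config.beta_ef_base,
        group_ef_means={k: v["ef"] for k, v in config.groups.items()},
        group_crf_means={k: v["crf"] for k, v in config.groups.items()},
        module_labels=config.module_labels,
        q_ref=config.q_ref,
    )


def simulate_cohort(config: SimulationConfig,
                    include_timeseries: bool = True,
                    include_motion: bool = True) -> Cohort:
    """Full raw-data cohort: demographics, battery, motion, ROI time series.

    The returned table holds one row per subject (id, group, age, battery
    pre/post, VO2peak pre/post); time series and motion traces are keyed by
    subject id. Derived columns (mean FD, modularity, composites) are the
    pipeline's job, not the generator's.
    """
    rows = []
    timeseries: dict[str, TimeSeriesMatrix] = {}
    motion: dict[str, MotionTrace] = {}
    for i in range(config.n_subjects):
        lat = _latents(config, i)
        sid = f"sub{i:04d}"
        row = {"subject_id": sid, "group": lat["group"], "age": lat["age"]}
        row.update(simulate_battery_row(config, i))
        rows.append(row)
        if include_motion:
            motion[sid] = simulate_motion(config, i)
        if include_timeseries:
            timeseries[sid] = simulate_timeseries(config, i)
    columns = ["subject_id", "group", "age"]
    table = pd.DataFrame(rows, columns=None if rows else columns)
    return Cohort(table=table, ground_truth=_ground_truth(config, range(config.n_subjects)),
                  timeseries=timeseries, motion=motion)


def simulate_regression_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Analysis-ready cohort table drawn directly from the planted gain model.

    Emits, per subject: group, age, mean FD, baseline EF, baseline
    modularity, and EF gain generated from the planted moderation model.
    Modularity here is the latent target itself, so inference on this
    table recovers the planted coefficients without measurement
    attenuation — the calibration path for the statistics layer.
    """
    rows = []
    for i in range(config.n_subjects):
        lat = _latents(config, i)
        gains = _construct_gains(config, lat)
        fd_rng = _rng(config, i, _MOTION)
        mean_fd = float(0.04 + np.abs(fd_rng.normal(0.04, 0.03)))
        rows.append({
            "subject_id": f"sub{i:04d}",
            "group": lat["group"],
            "age": lat["age"],
            "mean_fd": mean_fd,
            "ef_base": float(lat["factors"][3]),
            "modularity": lat["q"],
            "ef_gain": gains["ef"],
        })
    columns = ["subject_id", "group", "age", "mean_fd", "ef_base",
               "modularity", "ef_gain"]
    table = pd.DataFrame(rows, columns=columns if not rows else None)
    return table, _ground_truth(config, range(config.n_subjects))


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort as plain text: per-subject TSVs, cohort CSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(outdir / "cohort.csv", index=False)
    cohort.ground_truth.to_json(outdir / "ground_truth.json")
    for sid, ts in cohort.timeseries.items():
        write_timeseries(ts, outdir / f"{sid}_timeseries.tsv")
    for sid, mt in cohort.motion.items():
        write_motion(mt, outdir / f"{sid}_motion.tsv")
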