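"""Desk-scale end-to-end experiments on synthetic cohorts.

The central validation for the whole pipeline is a focal-electrode recovery
experiment: generate a cohort whose seizures are known to live on a specific
electrode subset, run the exhaustive configuration search, and check that
configurations covering the focal electrodes outperform configurations that
avoid them — both as a stochastic-dominance test on the median
percent-of-full values and as an electrode-participation contrast in the
top-ranked configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import classifier
from .pipeline import build_cohort_table
from .search import SplitData, prepare_split_data, run_exhaustive, summarize_top_configurations
from .splits import make_splits

logger = logging.getLogger(__name__)

#: Sub-montage used by the desk-scale recovery runs: the temporal-left focal
#: chain {F7, T3, T5} plus seven non-focal electrodes.
RECOVERY_CHANNELS: tuple[str, ...] = (
    "F7", "T3", "T5", "F3", "C3", "P3", "O1", "F4", "C4", "O2",
)
RECOVERY_FOCAL: tuple[str, ...] = ("F7", "T3", "T5")


@dataclass
class RecoveryResult:
    """Pooled outcome of the focal-recovery experiment."""

    focal_percents: np.ndarray  # median percent-of-full, configs ⊇ focal set
    nonfocal_percents: np.ndarray  # configs disjoint from the focal set
    mannwhitney_p: float
    focal_participation: float  # mean participation in top 5%, focal channels
    nonfocal_participation: float
    full_auc_pr_07: list[float]  # per (seed, split)
    full_auc_roc: list[float]
    summaries: list[pd.DataFrame]
    n_models: int


def prepare_cohort_splits(
    n_patients: int,
    hours_per_patient: float,
    channels,
    n_splits: int,
    seed: int,
    hyper_params=None,
    **cohort_kwargs,
) -> tuple[pd.DataFrame, list[SplitData]]:
    """Build a cohort feature table and its prepared per-split data."""
    table, manifest = build_cohort_table(
        n_patients, hours_per_patient, seed=seed, **cohort_kwargs
    )
    strata = {
        r.patient_id: (r.focus_zone, r.hemisphere) for r in manifest.itertuples()
    }
    splits = make_splits(strata, n_splits=n_splits, seed=seed)
    split_datas = [
        prepare_split_data(table, s, channels, hyper_params, base_seed=seed)
        for s in splits
    ]
    return table, split_datas


def focal_recovery_experiment(
    base_seed: int = 0,
    n_seeds: int = 5,
    n_patients: int = 24,
    hours_per_patient: float = 0.5,
    channels=RECOVERY_CHANNELS,
    focal=RECOVERY_FOCAL,
    k: int = 4,
    n_splits: int = 3,
    top_fraction: float = 0.05,
    hyper_params=None,
) -> RecoveryResult:
    """Run the exhaustive search over seeded replicate cohorts and pool.

    Each replicate generates a fixed-focus cohort (every patient
    temporal-left, so the cohort-level focal set is known), runs the
    exhaustive k-subset search over ``n_splits`` patient-level splits on a
    10-channel sub-montage, and splits the per-configuration median
    percent-of-full values into configurations containing all focal
    channels versus none.  The pooled one-sided Mann-Whitney U tests
    stochastic dominance of the focal-covering group.
    """
    focal = set(focal)
    hyper_params = dict(hyper_params or classifier.DEFAULT_HYPER_PARAMS)
    focal_vals: list[float] = []
    nonfocal_vals: list[float] = []
    part_focal: list[float] = []
    part_nonfocal: list[float] = []
    full_aucs: list[float] = []
    full_rocs: list[float] = []
    summaries: list[pd.DataFrame] = []
    n_models = 0

    for rep in range(n_seeds):
        seed = base_seed + 1000 * rep
        logger.info("recovery replicate %d/%d (seed %d)", rep + 1, n_seeds, seed)
        _, split_datas = prepare_cohort_splits(
            n_patients,
            hours_per_patient,
            channels,
            n_splits,
            seed,
            hyper_params,
            zone_distribution={"temporal": 1.0},
            hemisphere_distribution={"left": 1.0},
        )
        results, summary = run_exhaustive(
            split_datas, k=k, feature_mode="reduced", base_seed=seed
        )
        n_models += len(results)
        summaries.append(summary)
        full_aucs.extend(sd.full_auc_pr_07 for sd in split_datas)
        full_rocs.extend(sd.full_auc_roc for sd in split_datas)

        cfg_sets = summary["configuration"].map(lambda s: set(s.split("+")))
        covers = cfg_sets.map(focal.issubset)
        avoids = cfg_sets.map(lambda s: not (s & focal))
        focal_vals.extend(summary.loc[covers, "median_percent_of_full"])
        nonfocal_vals.extend(summary.loc[avoids, "median_percent_of_full"])

        report = summarize_top_configurations(
            summary, top_n=max(1, int(round(top_fraction * len(summary))))
        )
        freq = report.participation.reindex(list(channels)).fillna(0.0)
        part_focal.append(float(freq[list(focal)].mean()))
        part_nonfocal.append(float(freq[[c for c in channels if c not in focal]].mean()))

    stat = mannwhitneyu(focal_vals, nonfocal_vals, alternative="greater")
    return RecoveryResult(
        focal_percents=np.asarray(focal_vals),
        nonfocal_percents=np.asarray(nonfocal_vals),
        mannwhitney_p=float(stat.pvalue),
        focal_participation=float(np.mean(part_focal)),
        nonfocal_participation=float(np.mean(part_nonfocal)),
        full_auc_pr_07=full_aucs,
        full_auc_roc=full_rocs,
        summaries=summaries,
        n_models=n_models,
    )
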