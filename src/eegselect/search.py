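"""Two-stage electrode-configuration search.

Stage 1 (size sweep): on a single data split, sample up to 1000 random
electrode subsets of each size 1..17 (all subsets when fewer than 1000
exist), train a model per subset, and compare AUC-PR-0.7 against the full
18-electrode model to locate the smallest subset size that maintains
performance.

Stage 2 (exhaustive): for the chosen size k, evaluate every C(n, k) subset
on every data split (C(18, 8) = 43,758 subsets x 20 splits = 875,160 models
at full scale), normalize each result by the same split's full-montage,
full-feature model ("percent-of-full-AUC-PR-0.7"), and rank subsets by the
median across splits.  The exhaustive stage defaults to the reduced
5-feature mode for speed, while baselines always use all features.

Work items are independent (configuration, split) pairs; each derives its
model seed by hashing (labels, split_id, base_seed) so results are invariant
to execution order and to resume/restart.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier
from .features import feature_columns, fit_out_of_range_ranges, apply_out_of_range
from .metrics import auc_pr_07, median_across_splits, percent_of_full, roc_auc
from .montage import ANALYSIS_CHANNELS
from .splits import SplitSpec, assert_no_patient_leakage, balance_training_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElectrodeConfiguration:
    """An unordered subset of the analysis channels, canonically sorted."""

    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(sorted(self.labels))
        if not labels:
            raise ValueError("configuration must contain at least one channel")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channels in configuration")
        object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        return "+".join(self.labels)

    @classmethod
    def from_string(cls, s: str) -> "ElectrodeConfiguration":
        return cls(tuple(s.split("+")))


def enumerate_configurations(
    channels: Sequence[str] = ANALYSIS_CHANNELS,
    k: int = 8,
) -> list[ElectrodeConfiguration]:
    """All C(n, k) subsets of ``channels``, lexicographic, no repeats."""
    channels = sorted(set(channels))
    if not 1 <= k <= len(channels):
        raise ValueError(f"k={k} out of range for {len(channels)} channels")
    return [ElectrodeConfiguration(c) for c in itertools.combinations(channels, k)]


def sample_configurations(
    channels: Sequence[str] = ANALYSIS_CHANNELS,
    k: int = 8,
    max_samples: int = 1000,
    seed: int = 0,
) -> list[ElectrodeConfiguration]:
    """Up to ``max_samples`` distinct uniform subsets of size k.

    When C(n, k) <= max_samples the full enumeration is returned, matching
    the protocol for subset sizes with fewer than 1000 options.
    """
    channels = sorted(set(channels))
    n = len(channels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} channels")
    total = comb(n, k)
    if total <= max_samples:
        return enumerate_configurations(channels, k)
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, ...]] = set()
    while len(chosen) < max_samples:
        pick = tuple(sorted(rng.choice(n, size=k, replace=False)))
        chosen.add(tuple(channels[i] for i in pick))
    return [ElectrodeConfiguration(c) for c in sorted(chosen)]


def config_split_seed(config: ElectrodeConfiguration, split_id: int, base_seed: int) -> int:
    """Deterministic, order-independent per-(configuration, split) seed."""
    key = f"{config}|{split_id}|{base_seed}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# split preparation and single evaluations


@dataclass
class SplitData:
    """Everything one split needs: balanced train, unbalanced test, baseline."""

    split: SplitSpec
    train_rows: pd.DataFrame  # balanced, out_of_range applied
    test_rows: pd.DataFrame  # all data, out_of_range applied
    channels: tuple[str, ...]
    full_auc_pr_07: float
    full_auc_roc: float
    hyper_params: dict


@dataclass(frozen=True)
class EvalResult:
    configuration: ElectrodeConfiguration
    split_id: int
    auc_pr_07: float
    auc_roc: float
    percent_of_full: float
    feature_mode: str

    def as_row(self) -> dict:
        return {
            "configuration": str(self.configuration),
            "k": self.configuration.k,
            "split_id": self.split_id,
            "auc_pr_07": self.auc_pr_07,
            "auc_roc": self.auc_roc,
            "percent_of_full": self.percent_of_full,
            "feature_mode": self.feature_mode,
        }


def prepare_split_data(
    table: pd.DataFrame,
    split: SplitSpec,
    channels: Sequence[str],
    hyper_params: Mapping | None = None,
    base_seed: int = 0,
) -> SplitData:
    """Balance the split's training rows, fit out-of-range limits, and train
    the full-montage, full-feature baseline model.

    The out-of-range normal limits are fit on the split's non-ictal training
    rows only (leakage-free) and applied to both sides.
    """
    channels = tuple(channels)
    train_all = table[table["patient_id"].isin(split.train_patients)]
    test = table[table["patient_id"].isin(split.test_patients)]
    assert_no_patient_leakage(train_all, test)

    ranges = fit_out_of_range_ranges(train_all[train_all["label"] == 0])
    train_bal = balance_training_set(train_all, seed=split.seed)
    train_bal = apply_out_of_range(train_bal, ranges)
    test = apply_out_of_range(test, ranges)

    params = dict(hyper_params or classifier.DEFAULT_HYPER_PARAMS)
    full_cols = feature_columns(channels, "full")
    full_cfg = ElectrodeConfiguration(channels)
    model = classifier.train(
        train_bal[full_cols],
        train_bal["label"],
        params,
        seed=config_split_seed(full_cfg, split.split_id, base_seed),
        metadata={"split_id": split.split_id, "role": "full_baseline"},
    )
    scores = classifier.predict_scores(model, test[full_cols])
    return SplitData(
        split=split,
        train_rows=train_bal,
        test_rows=test,
        channels=channels,
        full_auc_pr_07=auc_pr_07(test["label"], scores),
        full_auc_roc=roc_auc(test["label"], scores),
        hyper_params=params,
    )


def evaluate_configuration(
    config: ElectrodeConfiguration,
    split_data: SplitData,
    feature_mode: str = "reduced",
    base_seed: int = 0,
) -> EvalResult:
    """Train on the configuration's columns only and score the full test set."""
    missing = set(config.labels) - set(split_data.channels)
    if missing:
        raise ValueError(f"configuration channels not in feature table: {sorted(missing)}")
    cols = feature_columns(config.labels, feature_mode)
    seed = config_split_seed(config, split_data.split.split_id, base_seed)
    model = classifier.train(
        split_data.train_rows[cols],
        split_data.train_rows["label"],
        split_data.hyper_params,
        seed=seed,
    )
    scores = classifier.predict_scores(model, split_data.test_rows[cols])
    auc = auc_pr_07(split_data.test_rows["label"], scores)
    return EvalResult(
        configuration=config,
        split_id=split_data.split.split_id,
        auc_pr_07=auc,
        auc_roc=roc_auc(split_data.test_rows["label"], scores),
        percent_of_full=percent_of_full(auc, split_data.full_auc_pr_07),
        feature_mode=feature_mode,
    )


# ---------------------------------------------------------------------------
# stage 1: size sweep


def run_size_sweep(
    split_data: SplitData,
    sizes: Sequence[int] | None = None,
    feature_mode: str = "full",
    max_samples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sampled subsets of each size on a single split, plus the full baseline.

    Returns one row per evaluated configuration (columns as in
    :meth:`EvalResult.as_row`) with the full-montage baseline appearing
    exactly once, supporting the AUC-vs-electrode-count scatter.
    """
    channels = split_data.channels
    sizes = list(sizes) if sizes is not None else list(range(1, len(channels)))
    rows = []
    for k in sizes:
        configs = sample_configurations(channels, k, max_samples=max_samples, seed=seed + k)
        logger.info("size sweep: k=%d, %d configurations", k, len(configs))
        for cfg in configs:
            rows.append(evaluate_configuration(cfg, split_data, feature_mode, seed).as_row())
    baseline = EvalResult(
        configuration=ElectrodeConfiguration(channels),
        split_id=split_data.split.split_id,
        auc_pr_07=split_data.full_auc_pr_07,
        auc_roc=split_data.full_auc_roc,
        percent_of_full=100.0,
        feature_mode="full",
    )
    rows.append(baseline.as_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 2: exhaustive fixed-size search


def run_exhaustive(
    split_datas: Sequence[SplitData],
    k: int = 8,
    feature_mode: str = "reduced",
    base_seed: int = 0,
    out_path: str | Path | None = None,
    resume: bool = False,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every size-k configuration on every split.

    Returns ``(results, summary)``: one result row per (configuration,
    split), and per-configuration summary rows holding the median
    percent-of-full across splits.  With ``out_path`` the result table is
    appended to disk in chunks; ``resume=True`` skips (configuration, split)
    pairs already present, never duplicating rows.
    """
    channels = split_datas[0].channels
    configs = enumerate_configurations(channels, k)
    done: set[tuple[str, int]] = set()
    existing: pd.DataFrame | None = None
    if resume and out_path is not None and Path(out_path).exists():
        existing = pd.read_csv(out_path)
        done = set(zip(existing["configuration"], existing["split_id"]))
        logger.info("resuming: %d of %d result rows present", len(done), len(configs) * len(split_datas))

    work = [
        (cfg, sd)
        for cfg in configs
        for sd in split_datas
        if (str(cfg), sd.split.split_id) not in done
    ]

    def _one(cfg, sd):
        return evaluate_configuration(cfg, sd, feature_mode, base_seed).as_row()

    new_rows: list[dict] = []
    if n_jobs != 1 and work:
        from joblib import Parallel, delayed

        new_rows = Parallel(n_jobs=n_jobs)(delayed(_one)(cfg, sd) for cfg, sd in work)
    else:
        chunk: list[dict] = []
        for cfg, sd in work:
            chunk.append(_one(cfg, sd))
            if out_path is not None and len(chunk) >= 500:
                _append_csv(pd.DataFrame(chunk), out_path)
                new_rows.extend(chunk)
                chunk = []
        new_rows.extend(chunk)
        if out_path is not None and chunk:
            _append_csv(pd.DataFrame(chunk), out_path)
    if n_jobs != 1 and out_path is not None and new_rows:
        _append_csv(pd.DataFrame(new_rows), out_path)

    results = pd.DataFrame(new_rows)
    if existing is not None and len(existing):
        results = pd.concat([existing, results], ignore_index=True)
    results = results.sort_values(["configuration", "split_id"], ignore_index=True)
    summary = summarize_results(results)
    return results, summary


def _append_csv(chunk: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    header = not path.exists()
    chunk.to_csv(path, mode="a", header=header, index=False)


def summarize_results(results: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration median percent-of-full (and AUCs) across splits."""
    summary = (
        results.groupby("configuration")
        .agg(
            k=("k", "first"),
            n_splits=("split_id", "nunique"),
            median_percent_of_full=("percent_of_full", median_across_splits),
            median_auc_pr_07=("auc_pr_07", median_across_splits),
            median_auc_roc=("auc_roc", median_across_splits),
        )
        .reset_index()
    )
    return summary.sort_values(
        ["median_percent_of_full", "configuration"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# reporting


@dataclass
class TopConfigReport:
    top: pd.DataFrame
    participation: pd.Series  # per-electrode frequency among the top_n
    best: str
    median_example: str
    worst: str

    def to_markdown(self) -> str:
        lines = [
            "# Electrode-configuration report",
            "",
            f"Configurations summarized: {len(self.top)} (top set)",
            "",
            "## Exemplar configurations (by median percent-of-full-AUC-PR-0.7)",
            f"- best: {self.best}",
            f"- intermediate: {self.median_example}",
            f"- worst: {self.worst}",
            "",
            "## Electrode participation in the top set",
        ]
        for ch, n in self.participation.items():
            lines.append(f"- {ch}: {int(n)}")
        lines += ["", "## Top configurations", "", self.top.to_string(index=False)]
        return "\n".join(lines)


def summarize_top_configurations(summary: pd.DataFrame, top_n: int = 1000) -> TopConfigReport:
    """Rank configurations and profile electrode participation in the top set.

    Ties in the median are broken lexicographically by configuration string
    (stable and documented).  ``top_n`` larger than the table is clamped with
    a warning.  Exemplars (best / intermediate / worst) are drawn from the
    full summary.
    """
    if summary.empty:
        raise ValueError("empty summary")
    if top_n > len(summary):
        logger.warning("top_n=%d clamped to %d configurations", top_n, len(summary))
        top_n = len(summary)
    ranked = summary.sort_values(
        ["median_percent_of_full", "configuration"], ascending=[False, True], ignore_index=True
    )
    top = ranked.head(top_n)
    counts: dict[str, int] = {}
    for cfg in top["configuration"]:
        for ch in cfg.split("+"):
            counts[ch] = counts.get(ch, 0) + 1
    participation = pd.Series(counts).sort_values(ascending=False)
    return TopConfigReport(
        top=top,
        participation=participation,
        best=ranked.iloc[0]["configuration"],
        median_example=ranked.iloc[len(ranked) // 2]["configuration"],
        worst=ranked.iloc[-1]["configuration"],
    )
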