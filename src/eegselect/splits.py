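"""Patient-level stratified train/test splitting with balanced training sets.

Splits are made at the level of whole patients, so test patients are never
seen during training (the cross-patient protocol).  Each split preserves the
cohort's frequency of (seizure onset zone, hemisphere) strata, the training
set is balanced by subsampling the majority class, and the test set is left
untouched (all data, unbalanced).  The default protocol repeats this for 20
distinct splits at a 75% train fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    split_id: int
    train_patients: frozenset[str]
    test_patients: frozenset[str]
    strata: Mapping[str, tuple[str, str]] = field(compare=False)
    seed: int = 0

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise ValueError("train and test patient sets overlap")


def _stratum_train_counts(
    strata_sizes: dict[tuple[str, str], int],
    train_fraction: float,
    forced_train: int,
) -> dict[tuple[str, str], int]:
    """Largest-remainder apportionment of the train quota across strata."""
    n_total = sum(strata_sizes.values()) + forced_train
    target = int(round(train_fraction * n_total)) - forced_train
    target = max(0, min(target, sum(strata_sizes.values())))
    keys = list(strata_sizes)
    ideal = np.array([train_fraction * strata_sizes[k] for k in keys])
    counts = np.floor(ideal).astype(int)
    counts = np.minimum(counts, [strata_sizes[k] for k in keys])
    remainder = ideal - counts
    deficit = target - counts.sum()
    order = np.argsort(-remainder)
    i = 0
    while deficit != 0 and i < 10 * len(keys):
        k = order[i % len(keys)]
        if deficit > 0 and counts[k] < strata_sizes[keys[k]]:
            counts[k] += 1
            deficit -= 1
        elif deficit < 0 and counts[k] > 0:
            counts[k] -= 1
            deficit += 1
        i += 1
    return dict(zip(keys, (int(c) for c in counts)))


def make_splits(
    strata: Mapping[str, tuple[str, str]],
    n_splits: int = 20,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> list[SplitSpec]:
    """Repeated stratified patient-level partitions.

    Within each (zone, hemisphere) stratum the train count follows
    largest-remainder rounding of ``train_fraction``, so the global train
    fraction is met to within one patient.  Split k draws from seed
    ``seed + k``; distinct partitions are enforced where combinatorially
    possible.  Strata with a single patient cannot be stratified and are
    assigned to the training set with a warning.
    """
    patients = sorted(strata)
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    by_stratum: dict[tuple[str, str], list[str]] = {}
    for p in patients:
        by_stratum.setdefault(tuple(strata[p]), []).append(p)

    singletons = [v[0] for v in by_stratum.values() if len(v) == 1]
    if singletons:
        logger.warning(
            "strata with a single patient assigned to train: %s", singletons
        )
    multi = {k: v for k, v in by_stratum.items() if len(v) > 1}
    counts = _stratum_train_counts(
        {k: len(v) for k, v in multi.items()}, train_fraction, len(singletons)
    )

    splits: list[SplitSpec] = []
    seen: set[frozenset] = set()
    attempt_offset = 0
    for k in range(n_splits):
        for _ in range(200):
            split_seed = seed + k + attempt_offset
            rng = np.random.default_rng(split_seed)
            train = set(singletons)
            for key, members in multi.items():
                perm = list(rng.permutation(members))
                train.update(perm[: counts[key]])
            train_f = frozenset(train)
            if train_f not in seen or len(seen) >= _max_distinct(multi, counts):
                seen.add(train_f)
                splits.append(
                    SplitSpec(
                        split_id=k,
                        train_patients=train_f,
                        test_patients=frozenset(patients) - train_f,
                        strata=dict(strata),
                        seed=split_seed,
                    )
                )
                break
            attempt_offset += 1000
        else:  # pragma: no cover - combinatorially exhausted
            raise RuntimeError("could not draw a distinct split")
    return splits


def _max_distinct(multi: dict, counts: dict) -> int:
    from math import comb

    total = 1
    for key, members in multi.items():
        total *= comb(len(members), counts[key])
        if total > 10**6:
            return 10**6
    return total


def balance_training_set(rows: pd.DataFrame, seed: int = 0, label_col: str = "label") -> pd.DataFrame:
    """Subsample the majority class to the minority count (without replacement).

    All minority rows are retained; row order follows the original table.
    Applies to training data only — test sets are evaluated unbalanced.
    """
    y = rows[label_col].to_numpy()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0:
        raise ValueError("no ictal rows in the training set; split unusable")
    if n_neg == 0:
        raise ValueError("no non-ictal rows in the training set; split unusable")
    if n_pos == n_neg:
        return rows
    rng = np.random.default_rng(seed)
    major = 1 if n_pos > n_neg else 0
    n_keep = min(n_pos, n_neg)
    major_idx = rows.index[y == major]
    keep = rng.choice(major_idx, size=n_keep, replace=False)
    mask = rows.index.isin(set(keep) | set(rows.index[y != major]))
    return rows.loc[mask]


def assert_no_patient_leakage(
    train_rows: pd.DataFrame,
    test_rows: pd.DataFrame,
    patient_col: str = "patient_id",
) -> None:
    """Raise if any patient contributes rows to both sides of a split."""
    overlap = set(train_rows[patient_col]) & set(test_rows[patient_col])
    if overlap:
        raise AssertionError(f"patient leakage across split: {sorted(overlap)}")
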