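"""Aggregation statistics for nuclease comparisons.

Per-target normalization of indel frequencies (each target's values divided
by its best spacer-length mean), spacer-length and PAM-subtype group
summaries, fold changes between nucleases, Pearson r-squared for replicate
agreement, and the paired/unpaired t and Wilcoxon matched-pairs tests used
for the comparisons. No multiple-testing correction is applied: results are
reported per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExperimentRecord",
    "NormalizedSummary",
    "records_to_frame",
    "normalize_per_target",
    "normalize_to_reference",
    "fold_change",
    "pearson_r2",
    "paired_tests",
]


@dataclass(frozen=True)
class ExperimentRecord:
    """One editing measurement: nuclease, target, cell type, spacer length,
    replicate id, and the indel frequency (fraction of edited reads)."""

    nuclease: str
    target_name: str
    cell_type: str
    spacer_length: int
    replicate: str
    indel_frequency: float
    pam_class: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.indel_frequency <= 1.0):
            raise ValueError("indel_frequency must be within [0, 1]")


def records_to_frame(records: Iterable[ExperimentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class NormalizedSummary:
    """Per-target-normalized view of an experiment table.

    ``per_record`` carries a ``relative`` column; ``target_length_means``
    one row per (grouping, target, spacer_length) with the relative mean;
    ``spacer_length_means`` / ``pam_class_means`` are group averages of the
    relative values. Targets whose every measurement is zero get relative 0
    and are listed in ``warnings``.
    """

    per_record: pd.DataFrame
    target_length_means: pd.DataFrame
    spacer_length_means: pd.DataFrame
    pam_class_means: Optional[pd.DataFrame] = None
    warnings: list[str] = field(default_factory=list)


def normalize_per_target(
    records: Sequence[ExperimentRecord], combine_cell_types: bool = True
) -> NormalizedSummary:
    """Divide each record's indel frequency by the highest spacer-length
    mean frequency of its target (per nuclease, and per cell type unless
    cell types are combined)."""
    if not records:
        raise ValueError("normalize_per_target requires at least one record")
    df = records_to_frame(records)
    keys = ["nuclease", "target_name"]
    if not combine_cell_types:
        keys = ["nuclease", "cell_type", "target_name"]
    warnings: list[str] = []

    means = (
        df.groupby(keys + ["spacer_length"], sort=True)["indel_frequency"]
        .mean()
        .rename("mean_frequency")
        .reset_index()
    )
    maxima = means.groupby(keys)["mean_frequency"].transform("max")
    means["relative_mean"] = np.where(maxima > 0, means["mean_frequency"] / maxima, 0.0)

    target_max = means.groupby(keys)["mean_frequency"].max().rename("max_mean")
    for idx, mx in target_max.items():
        if mx == 0:
            name = idx if isinstance(idx, str) else "/".join(map(str, idx))
            warnings.append(f"target {name}: all measurements zero; relative values set to 0")

    df = df.merge(target_max.reset_index(), on=keys, how="left")
    df["relative"] = np.where(
        df["max_mean"] > 0, df["indel_frequency"] / df["max_mean"], 0.0
    )
    df = df.drop(columns="max_mean")

    spacer_means = (
        df.groupby(["nuclease", "spacer_length"], sort=True)["relative"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    pam_means = None
    if df["pam_class"].notna().any():
        pam_means = (
            df[df["pam_class"].notna()]
            .groupby(["nuclease", "pam_class"], sort=True)["relative"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
    return NormalizedSummary(df, means, spacer_means, pam_means, warnings)


def normalize_to_reference(
    records: Sequence[ExperimentRecord],
    reference_nuclease: str = "SpCas9",
    per_target: bool = True,
) -> pd.DataFrame:
    """Express every indel frequency relative to the reference nuclease's
    average efficiency, either per target (default) or globally."""
    df = records_to_frame(records)
    ref = df[df["nuclease"] == reference_nuclease]
    if ref.empty:
        raise ValueError(f"no records for reference nuclease {reference_nuclease!r}")
    if per_target:
        denom = ref.groupby("target_name")["indel_frequency"].mean()
        df = df.merge(denom.rename("ref_mean"), on="target_name", how="left")
    else:
        df["ref_mean"] = ref["indel_frequency"].mean()
    if (df["ref_mean"] <= 0).any() or df["ref_mean"].isna().any():
        raise ValueError("reference mean is zero or missing for some target")
    df["relative"] = df["indel_frequency"] / df["ref_mean"]
    return df.drop(columns="ref_mean")


def fold_change(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Ratio of group means, mean(a) / mean(b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold_change requires two non-empty groups")
    mb = b.mean()
    if mb == 0:
        raise ValueError("fold_change denominator mean is zero")
    return float(a.mean() / mb)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r2 requires matched samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson_r2 undefined for zero-variance input")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def paired_tests(
    a: Sequence[float], b: Sequence[float], kind: str
) -> tuple[float, float]:
    """Two-sample significance test: ``t_paired``, ``t_unpaired`` or
    ``wilcoxon_matched``. Returns (statistic, two-tailed p).

    The Wilcoxon matched-pairs test uses exact enumeration below n = 10
    non-zero differences and the normal approximation from n = 10 on; an
    all-zero difference vector is undefined and raises.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if kind in ("t_paired", "wilcoxon_matched") and x.size != y.size:
        raise ValueError("paired tests require matched lengths")
    if min(x.size, y.size) < 2:
        raise ValueError("paired_tests requires n >= 2 per group")
    if kind == "t_paired":
        d = x - y
        if np.all(d == 0):
            # Zero variance of differences: no evidence of any difference.
            return 0.0, 1.0
        res = sps.ttest_rel(x, y)
    elif kind == "t_unpaired":
        res = sps.ttest_ind(x, y)
    elif kind == "wilcoxon_matched":
        d = x - y
        nz = d[d != 0]
        if nz.size == 0:
            raise ValueError("Wilcoxon undefined: all paired differences are zero")
        method = "exact" if nz.size < 10 else "approx"
        res = sps.wilcoxon(x, y, zero_method="wilcox", method=method)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return float(res.statistic), float(res.pvalue)
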