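"""Detection filtering, condition-wise feature loss, and raw-vs-normalized
discordance.

Degraded urine samples (e.g. stored at -20 degC instead of -80 degC) lose
low-abundance RNAs entirely and retain high-abundance RNAs at reduced raw
counts. Because library-size normalization rescales each sample to a common
total, surviving features in a collapsed library can *appear* upregulated in
normalized units while their raw counts dropped — an analysis artifact this
module detects explicitly by comparing raw and normalized directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .data_model import (
    CountMatrix,
    FeaturePanel,
    GroupingError,
    ParameterError,
)
from .normalization import NormalizationResult

__all__ = [
    "DetectionReport",
    "LossReport",
    "DiscordanceReport",
    "PanelCoverage",
    "detect_features",
    "lost_features",
    "panel_coverage",
    "percent_difference",
    "raw_norm_discordance",
]


@dataclass(frozen=True)
class DetectionReport:
    """Features passing a ">= min_count raw counts in at least min_fraction of
    samples" filter, with per-feature qualifying-sample counts."""

    min_count: int
    min_fraction: float
    detected_features: tuple[str, ...]
    per_feature_detected_sample_count: pd.Series

    @property
    def detected_set(self) -> frozenset[str]:
        return frozenset(self.detected_features)


@dataclass(frozen=True)
class LossReport:
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    lost_in_a: tuple[str, ...]  # zero in every sample of A, nonzero somewhere in B
    reduced_in_a: tuple[str, ...]  # present in both, lower mean in A
    summaries: pd.DataFrame  # per-feature mean raw count in each group


@dataclass(frozen=True)
class DiscordanceReport:
    """Per-feature raw group means, normalized log2 fold change, and the
    discordance flag (normalized and raw directions disagree beyond the
    configured magnitudes)."""

    table: pd.DataFrame  # columns: raw_mean_a, raw_mean_b, norm_lfc, discordant
    min_abs_lfc: float
    min_raw_ratio: float

    @property
    def discordant_features(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["discordant"]])


@dataclass(frozen=True)
class PanelCoverage:
    n_found: int
    n_panel: int
    found_ids: tuple[str, ...]
    missing_ids: tuple[str, ...]


def detect_features(counts: CountMatrix, min_count: int, min_fraction: float) -> DetectionReport:
    """Apply the detection filter; the sample-fraction threshold is inclusive.

    A feature with qualifying counts in exactly ``min_fraction`` of the
    samples (e.g. half of them at ``min_fraction=0.5``) is detected — the
    rule is "at least".
    """
    if not (0 < min_fraction <= 1):
        raise ParameterError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    if min_count < 0:
        raise ParameterError("min_count must be >= 0")
    qualifying = (counts.data >= min_count).sum(axis=1)
    threshold = min_fraction * counts.n_samples
    detected = qualifying[qualifying >= threshold].index
    return DetectionReport(
        min_count=min_count,
        min_fraction=min_fraction,
        detected_features=tuple(detected),
        per_feature_detected_sample_count=qualifying,
    )


def _validate_groups(counts: CountMatrix, group_a: Iterable[str], group_b: Iterable[str]):
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise GroupingError("both sample groups must be non-empty")
    overlap = set(a) & set(b)
    if overlap:
        raise GroupingError(f"groups overlap: {sorted(overlap)}")
    unknown = (set(a) | set(b)) - set(counts.sample_ids)
    if unknown:
        raise GroupingError(f"unknown samples: {sorted(unknown)}")
    return a, b


def lost_features(counts: CountMatrix, group_a: Iterable[str], group_b: Iterable[str]) -> LossReport:
    """Features absent from condition A (raw counts all zero) but present in B.

    "Lost" means zero in *every* sample of A — a stronger statement than
    failing the detection filter — while at least one B sample observed the
    feature. ``reduced_in_a`` lists features present in both conditions whose
    mean raw count is lower in A.
    """
    a, b = _validate_groups(counts, group_a, group_b)
    sum_a = counts.data[a].sum(axis=1)
    sum_b = counts.data[b].sum(axis=1)
    lost = counts.data.index[(sum_a == 0) & (sum_b > 0)]
    mean_a = counts.data[a].mean(axis=1)
    mean_b = counts.data[b].mean(axis=1)
    reduced = counts.data.index[(sum_a > 0) & (sum_b > 0) & (mean_a < mean_b)]
    summaries = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b})
    return LossReport(
        group_a=tuple(a),
        group_b=tuple(b),
        lost_in_a=tuple(lost),
        reduced_in_a=tuple(reduced),
        summaries=summaries,
    )


def panel_coverage(
    report: DetectionReport,
    panel: FeaturePanel,
    matcher: str | Callable[[str, str], bool] = "exact",
) -> PanelCoverage:
    """How many panel features the detection filter found.

    ``matcher`` is ``"exact"`` (identifier equality; genes), ``"mirna_stem"``
    (stem/arm-aware miRNA matching where a stem-only panel entry matches
    either mature arm), or any ``f(panel_id, feature_id) -> bool``.
    """
    if len(panel) == 0:
        raise ParameterError("empty panel")
    detected = list(report.detected_features)
    if matcher == "exact":
        detected_set = set(detected)
        found = [p for p in panel.feature_ids if p in detected_set]
    else:
        if matcher == "mirna_stem":
            from .mirna_match import ids_match, parse_mirna_id

            parsed_detected = []
            for d in detected:
                try:
                    parsed_detected.extend(parse_mirna_id(d))
                except Exception:
                    continue

            def matcher_fn(panel_id: str, _feature_id: str | None = None) -> bool:
                try:
                    panel_idents = parse_mirna_id(panel_id)
                except Exception:
                    return False
                return any(
                    ids_match(p, d, stem_policy="either_arm")
                    for p in panel_idents
                    for d in parsed_detected
                )

            found = [p for p in panel.feature_ids if matcher_fn(p)]
        else:
            found = [p for p in panel.feature_ids if any(matcher(p, d) for d in detected)]
    missing = [p for p in panel.feature_ids if p not in set(found)]
    return PanelCoverage(
        n_found=len(found),
        n_panel=len(panel),
        found_ids=tuple(found),
        missing_ids=tuple(missing),
    )


def percent_difference(
    normalized: pd.DataFrame,
    features: Iterable[str],
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> pd.Series:
    """Signed percent difference 100 x (mean_A - mean_B) / mean_A per feature.

    Computed on linear normalized counts with group A as the reference
    denominator (in the isolation-workflow comparison, A is the UC workflow).
    Features with mean_A = 0 are undefined and returned as NaN; range
    summaries should drop them.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise GroupingError("both sample groups must be non-empty")
    if set(a) & set(b):
        raise GroupingError("groups overlap")
    feats = list(features)
    sub = normalized.loc[feats]
    mean_a = sub[a].mean(axis=1)
    mean_b = sub[b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (mean_a - mean_b) / mean_a
    pct[mean_a == 0] = np.nan
    return pct


def raw_norm_discordance(
    counts: CountMatrix,
    norm: NormalizationResult,
    group_a: Iterable[str],
    group_b: Iterable[str],
    min_abs_lfc: float = 1.0,
    min_raw_ratio: float = 2.0,
) -> DiscordanceReport:
    """Flag features whose normalized and raw directions of change disagree.

    A feature is discordant when its normalized log2 fold change (the log2
    ratio of group-mean CPM, with the normalization prior guarding zeros) is
    at least ``min_abs_lfc`` in favor of A while its mean raw count is lower
    in A by a factor of at least ``min_raw_ratio`` — or the mirrored case.
    The fold change compares group means on the linear CPM scale, so with
    equal library sizes and no scaling the normalized and raw directions
    always agree; a disagreement is the signature of normalization against a
    collapsed library.
    """
    a, b = _validate_groups(counts, group_a, group_b)
    if min_abs_lfc < 0 or min_raw_ratio < 1:
        raise ParameterError("min_abs_lfc must be >= 0 and min_raw_ratio >= 1")
    raw_mean_a = counts.data[a].mean(axis=1)
    raw_mean_b = counts.data[b].mean(axis=1)
    lfc = np.log2(
        (norm.cpm[a].mean(axis=1) + norm.prior) / (norm.cpm[b].mean(axis=1) + norm.prior)
    )
    up_in_a = (lfc >= min_abs_lfc) & (raw_mean_b >= min_raw_ratio * raw_mean_a) & (raw_mean_b > 0)
    up_in_b = (lfc <= -min_abs_lfc) & (raw_mean_a >= min_raw_ratio * raw_mean_b) & (raw_mean_a > 0)
    table = pd.DataFrame(
        {
            "raw_mean_a": raw_mean_a,
            "raw_mean_b": raw_mean_b,
            "norm_lfc": lfc,
            "discordant": up_in_a | up_in_b,
        }
    )
    return DiscordanceReport(table=table, min_abs_lfc=min_abs_lfc, min_raw_ratio=min_raw_ratio)
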