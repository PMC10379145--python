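"""Staged reference-gene stability search across uEV datasets.

Candidate reference genes for qPCR normalization should be well expressed
and show little between-sample variability in every dataset. The search
proceeds per dataset: genes with CPM strictly above a threshold (default
200) in *all* samples are eligible; eligible genes are ranked by the
coefficient of variation (sample SD / mean) of their linear CPM; the k
(default 100) genes with the lowest CV form that dataset's candidate list.
Stages then intersect lists — each stage shrinks the running candidate set
by intersecting it with the top-k lists of that stage's datasets — and the
final intersection is the cross-dataset stable-gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ConfigurationError, CountMatrix, ParameterError
from .normalization import NormalizationResult

__all__ = [
    "StabilitySearchResult",
    "CandidateEvaluation",
    "coefficient_of_variation",
    "eligible_genes",
    "top_k_stable",
    "staged_search",
    "evaluate_candidates",
]


def coefficient_of_variation(values: Iterable[float]) -> float:
    """Sample standard deviation (n-1) divided by the mean.

    Requires at least two values and a positive mean; scale-invariant
    (cv(c*x) = cv(x) for c > 0).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ParameterError("CV needs at least 2 values")
    mean = arr.mean()
    if not mean > 0:
        raise ParameterError(f"CV needs a positive mean, got {mean}")
    return float(arr.std(ddof=1) / mean)


def eligible_genes(cpm: pd.DataFrame, threshold: float = 200.0) -> list[str]:
    """Genes with CPM strictly greater than ``threshold`` in every sample."""
    mask = (cpm > threshold).all(axis=1)
    return list(cpm.index[mask])


def cv_by_gene(cpm: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.Series:
    """Per-gene CV of linear CPM across samples."""
    sub = cpm if genes is None else cpm.loc[list(genes)]
    return sub.std(axis=1, ddof=1) / sub.mean(axis=1)


def top_k_stable(cv: Mapping[str, float] | pd.Series, k: int = 100) -> list[str]:
    """The k genes with the smallest CV, ascending; ties break lexicographically.

    If fewer than k genes are available all are returned and a warning is
    emitted.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    series = pd.Series(dict(cv) if not isinstance(cv, pd.Series) else cv)
    if series.empty:
        raise ParameterError("empty CV table")
    ordered = sorted(series.items(), key=lambda item: (item[1], item[0]))
    if len(ordered) < k:
        warnings.warn(
            f"only {len(ordered)} genes available for top-{k} selection", stacklevel=2
        )
    return [gene for gene, _ in ordered[:k]]


@dataclass(frozen=True)
class StabilitySearchResult:
    threshold: float
    k: int
    eligible: Mapping[str, tuple[str, ...]]  # dataset -> eligible genes
    cv_tables: Mapping[str, pd.Series]  # dataset -> CV of eligible genes
    top_k: Mapping[str, tuple[str, ...]]  # dataset -> top-k list
    stage_intersections: tuple[frozenset[str], ...]  # running set after each stage
    final_candidates: frozenset[str]


@dataclass(frozen=True)
class CandidateEvaluation:
    cv: pd.DataFrame  # genes x datasets; NaN where the gene is absent
    absent: Mapping[str, tuple[str, ...]]  # dataset -> genes absent there
    ineligible: Mapping[str, tuple[str, ...]]  # dataset -> genes failing CPM filter
    roles: Mapping[str, str]  # gene -> candidate / common_reference / high_cv_comparison
    sd_of_cpm: pd.DataFrame  # genes x datasets SD of CPM, for presentation order


Dataset = tuple[CountMatrix, NormalizationResult]


def staged_search(
    datasets: Mapping[str, Dataset],
    stages: Sequence[Sequence[str]],
    threshold: float = 200.0,
    k: int = 100,
) -> StabilitySearchResult:
    """Run the staged cross-dataset stability search.

    ``datasets`` maps dataset id to (counts, normalization); each dataset must
    have been normalized independently (datasets that belong together enter
    pre-merged as one). ``stages`` is an ordered grouping of dataset ids:
    stage 1 intersects the top-k lists of its datasets, and every later stage
    intersects the running set with its own datasets' top-k lists. All
    intermediate sets are retained.
    """
    if not stages or any(not stage for stage in stages):
        raise ConfigurationError("stages must be non-empty groups of dataset ids")
    known = set(datasets)
    for stage in stages:
        unknown = set(stage) - known
        if unknown:
            raise ConfigurationError(f"unknown dataset ids in stages: {sorted(unknown)}")

    eligible: dict[str, tuple[str, ...]] = {}
    cvs: dict[str, pd.Series] = {}
    tops: dict[str, tuple[str, ...]] = {}
    for ds_id, (counts, norm) in datasets.items():
        genes = eligible_genes(norm.cpm, threshold)
        eligible[ds_id] = tuple(genes)
        cv = cv_by_gene(norm.cpm, genes) if genes else pd.Series(dtype=float)
        cvs[ds_id] = cv
        tops[ds_id] = tuple(top_k_stable(cv, k)) if genes else tuple()

    running: frozenset[str] | None = None
    intersections: list[frozenset[str]] = []
    for stage in stages:
        stage_set: frozenset[str] | None = None
        for ds_id in stage:
            members = frozenset(tops[ds_id])
            stage_set = members if stage_set is None else stage_set & members
        running = stage_set if running is None else running & stage_set
        intersections.append(running)
    return StabilitySearchResult(
        threshold=threshold,
        k=k,
        eligible=eligible,
        cv_tables=cvs,
        top_k=tops,
        stage_intersections=tuple(intersections),
        final_candidates=intersections[-1],
    )


def evaluate_candidates(
    candidates: Iterable[str],
    datasets: Mapping[str, Dataset],
    comparison_genes: Mapping[str, str] | None = None,
    threshold: float = 200.0,
) -> CandidateEvaluation:
    """CV of each candidate (plus comparison genes) in every dataset.

    CVs are reported even where a gene failed the eligibility filter (flagged
    in ``ineligible``); genes absent from a dataset's features are flagged in
    ``absent`` and reported as NaN rather than raising. ``comparison_genes``
    maps extra genes to their role (e.g. GAPDH -> ``common_reference``,
    UPK1A -> ``high_cv_comparison``).
    """
    cand = list(dict.fromkeys(candidates))
    if not cand:
        raise ParameterError("no candidate genes supplied")
    comparison_genes = dict(comparison_genes or {})
    genes = cand + [g for g in comparison_genes if g not in cand]
    roles = {g: "candidate" for g in cand}
    roles.update(comparison_genes)

    cv = pd.DataFrame(index=genes, columns=list(datasets), dtype=float)
    sd = pd.DataFrame(index=genes, columns=list(datasets), dtype=float)
    absent: dict[str, tuple[str, ...]] = {}
    ineligible: dict[str, tuple[str, ...]] = {}
    for ds_id, (counts, norm) in datasets.items():
        present = [g for g in genes if g in norm.cpm.index]
        absent[ds_id] = tuple(g for g in genes if g not in norm.cpm.index)
        eligible = set(eligible_genes(norm.cpm.loc[present], threshold)) if present else set()
        ineligible[ds_id] = tuple(g for g in present if g not in eligible)
        if present:
            sub = norm.cpm.loc[present]
            cv.loc[present, ds_id] = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
            sd.loc[present, ds_id] = sub.std(axis=1, ddof=1)
    return CandidateEvaluation(cv=cv, absent=absent, ineligible=ineligible, roles=roles, sd_of_cpm=sd)
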