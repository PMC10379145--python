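"""Library-size normalization for small RNA-seq count matrices.

Implements, from first principles, the two scaling-factor methods standard in
bulk RNA-seq:

TMM (trimmed mean of M-values)
    A reference sample is chosen as the one whose 75th-percentile
    count-fraction is closest to the mean of those percentiles. For every
    other sample, per-feature log2 relative-abundance ratios against the
    reference (M-values) and average log2 abundances (A-values) are computed
    over features positive in both samples; the most extreme 30% of M and 5%
    of A (two-sided) are discarded, and the scaling factor is two raised to
    the inverse-variance-weighted mean of the surviving M-values. Factors are
    rescaled so their geometric mean is one, and the effective library size
    is library size x factor.

Median of ratios
    A pseudo-reference is the per-feature geometric mean across samples,
    computed over features positive in every sample; a sample's size factor
    is the median ratio of its counts to that pseudo-reference. To keep
    counts-per-million (CPM) in per-million units under this method, the
    effective library size is size factor x mean library size.

CPM is count / effective library size x 1e6; log2CPM adds a positive prior
count (default 1.0 on the CPM scale) before taking log2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import (
    CountMatrix,
    DegenerateSampleError,
    NormalizationError,
    ParameterError,
)

__all__ = [
    "NormalizationResult",
    "compute_cpm",
    "log2_cpm",
    "tmm_factors",
    "median_of_ratios_factors",
    "normalize",
]

METHODS = ("none", "tmm", "median_of_ratios")


@dataclass(frozen=True)
class NormalizationResult:
    """Scaling factors and normalized matrices for one dataset."""

    method: str
    library_sizes: pd.Series
    scaling_factors: pd.Series
    effective_library_sizes: pd.Series
    cpm: pd.DataFrame
    log2cpm: pd.DataFrame
    prior: float


def compute_cpm(
    counts: CountMatrix, effective_library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Counts per million: count / library size x 1e6, per sample.

    With plain library sizes (``effective_library_sizes=None``) each column
    sums to exactly 1e6 up to float tolerance. A zero-total sample without a
    supplied effective size raises :class:`DegenerateSampleError`.
    """
    if effective_library_sizes is None:
        sizes = counts.library_sizes().astype(float)
        zero = sizes[sizes == 0]
        if len(zero):
            raise DegenerateSampleError(
                f"samples with zero total counts: {list(zero.index)}; "
                "supply effective library sizes or drop them explicitly"
            )
    else:
        sizes = pd.Series(effective_library_sizes, index=counts.sample_ids).astype(float)
        if (sizes <= 0).any():
            bad = list(sizes[sizes <= 0].index)
            raise ParameterError(f"effective library sizes must be > 0; bad samples: {bad}")
    return counts.data.div(sizes, axis=1) * 1e6


def log2_cpm(cpm: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    """log2(CPM + prior); monotone in CPM. ``prior`` must be positive."""
    if not prior > 0:
        raise ParameterError(f"prior must be > 0, got {prior}")
    return np.log2(cpm + prior)


def _percentile75(counts: CountMatrix) -> np.ndarray:
    """Per-sample 75th percentile of the count fraction (count / library size)."""
    data = counts.data.to_numpy(dtype=float)
    lib = data.sum(axis=0)
    return np.percentile(data, 75, axis=0) / lib


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
    ref_sample: str | None = None,
) -> pd.Series:
    """TMM scaling factors per sample, geometric mean rescaled to 1.

    ``trim_m`` and ``trim_a`` are the two-sided trim fractions on M- and
    A-values; ``weighted`` applies inverse asymptotic-variance weights to the
    surviving M-values. ``ref_sample`` overrides the automatic reference
    choice (used e.g. to demonstrate order invariance).

    Raises :class:`NormalizationError` naming the sample when a sample shares
    no positive feature with the reference, and
    :class:`DegenerateSampleError` for all-zero samples.
    """
    if counts.n_samples < 2:
        raise ParameterError("TMM needs at least 2 samples")
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ParameterError("trim fractions must lie in [0, 0.5)")
    data = counts.data.to_numpy(dtype=float)
    lib = data.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l == 0]
        raise DegenerateSampleError(f"all-zero samples rejected: {bad}")

    if ref_sample is None:
        p75 = _percentile75(counts)
        ref_idx = int(np.argmin(np.abs(p75 - p75.mean())))  # ties -> lower index
    else:
        if ref_sample not in counts.sample_ids:
            raise ParameterError(f"unknown reference sample {ref_sample!r}")
        ref_idx = counts.sample_ids.index(ref_sample)

    ref = data[:, ref_idx]
    ref_lib = lib[ref_idx]
    log_factors = np.zeros(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            continue
        obs = data[:, j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise NormalizationError(
                f"sample {counts.sample_ids[j]!r} shares no positive feature with the reference"
            )
        p_obs = obs[both] / lib[j]
        p_ref = ref[both] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        if np.max(np.abs(m)) < 1e-6:
            # exact scalar multiples: all relative abundances identical
            continue
        n = m.size
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        if weighted:
            # delta-method asymptotic variance of an M-value
            var = (lib[j] - obs[both]) / (lib[j] * obs[both]) + (ref_lib - ref[both]) / (
                ref_lib * ref[both]
            )
            log_factors[j] = np.sum(m[keep] / var[keep]) / np.sum(1.0 / var[keep])
        else:
            log_factors[j] = np.mean(m[keep])
    factors = 2.0 ** log_factors
    # fsum keeps the rescaling constant independent of sample order
    factors /= np.exp(math.fsum(np.log(factors)) / len(factors))  # geometric mean 1
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def median_of_ratios_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Only features positive in every sample contribute; if none exists a
    :class:`NormalizationError` is raised.
    """
    data = counts.data.to_numpy(dtype=float)
    all_positive = (data > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError("no feature is positive in all samples")
    sub = data[all_positive]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize(
    counts: CountMatrix,
    method: str = "tmm",
    prior: float = 1.0,
    **method_kwargs,
) -> NormalizationResult:
    """Run a full normalization: factors, effective sizes, CPM and log2CPM."""
    if method not in METHODS:
        raise ParameterError(f"method must be one of {METHODS}, got {method!r}")
    lib = counts.library_sizes()
    if (lib == 0).any():
        raise DegenerateSampleError(
            f"all-zero samples rejected: {list(lib[lib == 0].index)}"
        )
    if method == "none":
        factors = pd.Series(1.0, index=counts.sample_ids, name="factor")
        effective = lib.astype(float)
    elif method == "tmm":
        factors = tmm_factors(counts, **method_kwargs)
        effective = lib * factors
    else:
        factors = median_of_ratios_factors(counts, **method_kwargs)
        # keep CPM in per-million units: size factors are library-size free
        effective = factors * float(lib.mean())
    cpm = compute_cpm(counts, effective_library_sizes=effective)
    return NormalizationResult(
        method=method,
        library_sizes=lib,
        scaling_factors=factors,
        effective_library_sizes=effective,
        cpm=cpm,
        log2cpm=log2_cpm(cpm, prior),
        prior=prior,
    )
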