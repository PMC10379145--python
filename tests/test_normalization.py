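"""CPM/log2CPM contracts and oracle equivalence for TMM and median-of-ratios.

The brute-force oracles below re-derive both scaling-factor methods from
their published definitions with plain loops and hand-coded quantiles/ranks,
independently of the implementation under test.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from uevrna import CountMatrix, compute_cpm, log2_cpm, median_of_ratios_factors, normalize, tmm_factors
from uevrna.data_model import DegenerateSampleError, NormalizationError, ParameterError

from conftest import make_counts, random_counts


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def _quantile_type7(values, q):
    """R's default (type 7) quantile, written out by hand."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def _average_ranks(values):
    """1-based average ranks: (#smaller) + (#equal + 1) / 2."""
    return [
        sum(1 for u in values if u < x) + (sum(1 for u in values if u == x) + 1) / 2.0
        for x in values
    ]


def oracle_tmm(frame: pd.DataFrame, trim_m=0.30, trim_a=0.05, weighted=True):
    """Step-by-step TMM from the published definition."""
    lib = {c: frame[c].sum() for c in frame.columns}
    p75 = {c: _quantile_type7(frame[c].tolist(), 0.75) / lib[c] for c in frame.columns}
    mean_p75 = sum(p75.values()) / len(p75)
    ref = min(frame.columns, key=lambda c: (abs(p75[c] - mean_p75), list(frame.columns).index(c)))
    log_factors = {}
    for col in frame.columns:
        if col == ref:
            log_factors[col] = 0.0
            continue
        ms, as_, ws = [], [], []
        for g in frame.index:
            x, r = frame.loc[g, col], frame.loc[g, ref]
            if x > 0 and r > 0:
                po, pr = x / lib[col], r / lib[ref]
                ms.append(np.log2(po / pr))
                as_.append(0.5 * np.log2(po * pr))
                ws.append((lib[col] - x) / (lib[col] * x) + (lib[ref] - r) / (lib[ref] * r))
        if max(abs(m) for m in ms) < 1e-6:
            log_factors[col] = 0.0
            continue
        n = len(ms)
        rank_m, rank_a = _average_ranks(ms), _average_ranks(as_)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        kept = [
            i for i in range(n)
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a
        ]
        if not kept:
            log_factors[col] = 0.0
        elif weighted:
            log_factors[col] = sum(ms[i] / ws[i] for i in kept) / sum(1 / ws[i] for i in kept)
        else:
            log_factors[col] = sum(ms[i] for i in kept) / len(kept)
    factors = {c: 2.0 ** f for c, f in log_factors.items()}
    geomean = np.exp(np.mean([np.log(f) for f in factors.values()]))
    return {c: f / geomean for c, f in factors.items()}


def oracle_median_of_ratios(frame: pd.DataFrame):
    usable = [g for g in frame.index if (frame.loc[g] > 0).all()]
    geomean = {g: np.exp(np.mean(np.log(frame.loc[g].to_numpy(dtype=float)))) for g in usable}
    return {
        c: float(np.median([frame.loc[g, c] / geomean[g] for g in usable]))
        for c in frame.columns
    }


# ---------------------------------------------------------------------------
# CPM / log2CPM
# ---------------------------------------------------------------------------

class TestCpm:
    def test_forced_by_definition(self):
        cm = make_counts([[1], [1], [2]])
        np.testing.assert_allclose(
            compute_cpm(cm).to_numpy().ravel(), [250000, 250000, 500000]
        )

    def test_identical_columns_give_identical_cpm(self):
        cm = make_counts([[3, 3], [7, 7], [1, 1]])
        cpm = compute_cpm(cm)
        np.testing.assert_allclose(cpm.iloc[:, 0], cpm.iloc[:, 1])

    def test_plain_columns_sum_to_one_million(self, rng):
        cm = random_counts(rng, 30, 5)
        np.testing.assert_allclose(compute_cpm(cm).sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_sample_is_degenerate(self):
        cm = make_counts([[0, 1], [0, 2]])
        with pytest.raises(DegenerateSampleError):
            compute_cpm(cm)

    def test_log2_cpm_examples_and_inverse(self, rng):
        cpm = pd.DataFrame([[0.0, 3.0]])
        np.testing.assert_allclose(log2_cpm(cpm, prior=1.0).to_numpy(), [[0.0, 2.0]])
        rand = pd.DataFrame(rng.uniform(0, 1e4, size=(10, 4)))
        back = 2.0 ** log2_cpm(rand, prior=1.0) - 1.0
        np.testing.assert_allclose(back.to_numpy(), rand.to_numpy(), rtol=1e-10)
        with pytest.raises(ParameterError):
            log2_cpm(cpm, prior=0.0)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTmm:
    def test_identical_columns_all_factors_one(self):
        cm = make_counts(np.tile([[5], [9], [2], [40]], (1, 4)))
        np.testing.assert_array_equal(tmm_factors(cm).to_numpy(), 1.0)

    def test_exact_scalar_multiple_gives_ones_exactly(self):
        cm = make_counts([[1, 3], [2, 6], [3, 9], [4, 12]])
        assert (tmm_factors(cm).to_numpy() == 1.0).all()

    def test_two_sample_hand_stepped_outlier(self):
        # 8 features, sample B doubles one high-abundance outlier; the
        # oracle walks the published steps independently.
        frame = pd.DataFrame(
            {"A": [100, 200, 300, 400, 500, 600, 700, 5000],
             "B": [100, 200, 300, 400, 500, 600, 700, 10000]},
            index=[f"g{i}" for i in range(8)],
        )
        got = tmm_factors(CountMatrix(frame))
        want = oracle_tmm(frame)
        for c in frame.columns:
            assert got[c] == pytest.approx(want[c], abs=1e-12)

    def test_oracle_equivalence_on_random_matrices(self, rng):
        for _ in range(50):
            n_feat = int(rng.integers(5, 21))
            n_samp = int(rng.integers(2, 7))
            cm = random_counts(rng, n_feat, n_samp, lam=rng.uniform(3, 40))
            got = tmm_factors(cm)
            want = oracle_tmm(cm.data)
            for c in cm.sample_ids:
                assert got[c] == pytest.approx(want[c], abs=1e-10)

    def test_matches_edger_reference_implementation(self, rng, tmp_path):
        """Independent cross-check against edgeR's calcNormFactors(method='TMM')."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; edgeR cross-check cannot run")
        cm = random_counts(rng, 40, 5, lam=30)
        path = tmp_path / "counts.tsv"
        cm.data.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(sprintf("%.12f\\n", calcNormFactors(x, method="TMM")))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = [float(v) for v in out.stdout.split()]
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), reference, atol=1e-9)

    def test_geometric_mean_is_one(self, rng):
        cm = random_counts(rng, 25, 6)
        factors = tmm_factors(cm)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_normalized_cpm(self, rng):
        # multiplying one sample's counts by c leaves its TMM-normalized CPM
        # column invariant: library size and factor compensate exactly for
        # the unweighted estimator (the inverse-variance weights of the
        # default estimator depend on sequencing depth by design, so the
        # weighted variant is only approximately invariant)
        cm = random_counts(rng, 40, 4)
        scaled = cm.data.copy()
        scaled["s1"] = scaled["s1"] * 3
        before = normalize(cm, method="tmm", weighted=False).cpm["s1"]
        after = normalize(CountMatrix(scaled), method="tmm", weighted=False).cpm["s1"]
        np.testing.assert_allclose(after, before, rtol=1e-6)
        before_w = normalize(cm, method="tmm").cpm["s1"]
        after_w = normalize(CountMatrix(scaled), method="tmm").cpm["s1"]
        np.testing.assert_allclose(after_w, before_w, rtol=0.05)

    def test_sample_permutation_permutes_factors(self, rng):
        cm = random_counts(rng, 30, 5)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        base = tmm_factors(cm, ref_sample="s0")
        shuffled = tmm_factors(CountMatrix(cm.data[perm]), ref_sample="s0")
        for s in perm:
            assert shuffled[s] == base[s]

    def test_disjoint_support_raises_naming_sample(self):
        cm = make_counts([[5, 0], [9, 0], [0, 3], [0, 8]])
        with pytest.raises(NormalizationError, match="s"):
            tmm_factors(cm)

    def test_all_zero_sample_rejected(self):
        cm = make_counts([[5, 0], [9, 0]])
        with pytest.raises(DegenerateSampleError):
            tmm_factors(cm)


# ---------------------------------------------------------------------------
# Median of ratios
# ---------------------------------------------------------------------------

class TestMedianOfRatios:
    def test_identical_columns(self):
        cm = make_counts([[4, 4], [9, 9]])
        np.testing.assert_allclose(median_of_ratios_factors(cm), 1.0)

    def test_doubled_sample_gives_sqrt2_pair(self):
        cm = make_counts([[1, 2], [2, 4], [3, 6]])
        factors = median_of_ratios_factors(cm)
        assert factors.iloc[0] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert factors.iloc[1] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_oracle_equivalence_on_random_matrix(self, rng):
        cm = random_counts(rng, 50, 4)
        got = median_of_ratios_factors(cm)
        want = oracle_median_of_ratios(cm.data)
        for c in cm.sample_ids:
            assert got[c] == pytest.approx(want[c], abs=1e-12)

    def test_no_universally_positive_feature_raises(self):
        cm = make_counts([[1, 0], [0, 1]])
        with pytest.raises(NormalizationError):
            median_of_ratios_factors(cm)


class TestNormalizeFacade:
    def test_none_method_cpm_columns_sum_to_million(self, rng):
        result = normalize(random_counts(rng, 20, 4), method="none")
        np.testing.assert_allclose(result.cpm.sum(axis=0), 1e6, rtol=1e-9)
        assert (result.scaling_factors == 1.0).all()

    def test_median_of_ratios_effective_sizes_stay_per_million(self, rng):
        cm = random_counts(rng, 30, 4)
        result = normalize(cm, method="median_of_ratios")
        # effective library size = size factor x mean library size keeps CPM
        # near the per-million scale
        assert result.effective_library_sizes.mean() == pytest.approx(
            cm.library_sizes().mean(), rel=0.5
        )

    def test_unknown_method(self, rng):
        with pytest.raises(ParameterError):
            normalize(random_counts(rng, 5, 2), method="quantile")
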