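"""Window binning, density outliers, and the Cook's-distance detector."""

from __future__ import annotations

import numpy as np
import pytest
from statsmodels.stats.outliers_influence import OLSInfluence
import statsmodels.api as sm

from macdiv import (
    GeneModelSet,
    OutlierResult,
    Transcript,
    WindowMatrix,
    bin_counts,
    cooks_distances,
    cooks_outliers,
    density_outliers,
    outlier_genes,
)


def loo_refit_cooks(y, x):
    """Cook's distance by its leave-one-out refit definition:
    D_i = ||fitted - fitted_without_i||^2 / (p * s^2)."""
    y = np.asarray(y, float)
    n = y.size
    X = np.column_stack([np.ones(n), np.asarray(x, float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    s2 = ((y - fitted) ** 2).sum() / (n - 2)
    out = np.zeros(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta_i, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        out[i] = ((fitted - X @ beta_i) ** 2).sum() / (2 * s2)
    return out


class TestBinCounts:
    def test_grid_and_partial_last_window(self):
        wms = bin_counts({"S": {"chr1": np.array([1, 50_000, 50_001, 119_999])}},
                         {"chr1": 120_000}, window_size=50_000)
        wm = wms["chr1"]
        assert wm.n_windows == 3 and wm.partial_last and wm.n_full == 2
        # 1-based 1..50000 fall in window 0
        assert wm.counts[:, 0].tolist() == [2, 1, 1]
        assert wm.effective_kb().tolist() == [50.0, 50.0, 20.0]

    def test_column_sums_conserve_variant_counts(self):
        rng = np.random.default_rng(0)
        pos = {s: {"chr1": rng.integers(1, 300_001, size=rng.integers(50, 200))}
               for s in "ABC"}
        wm = bin_counts(pos, {"chr1": 300_000})["chr1"]
        for j, s in enumerate("ABC"):
            assert wm.counts[:, j].sum() == len(pos[s]["chr1"])

    def test_position_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bin_counts({"S": {"chr1": np.array([150_001])}}, {"chr1": 150_000})


class TestDensityOutliers:
    def test_rate_threshold_with_effective_length(self):
        wm = bin_counts({"S": {"chr1": np.r_[np.repeat(10_000, 500),
                                             np.repeat(110_000, 100)]}},
                        {"chr1": 120_000})["chr1"]
        hits = density_outliers(wm, rate_per_kb=9.5)
        assert hits["window"].tolist() == [0]
        assert hits["rate_per_kb"].tolist() == [10.0]
        # partial 20-kb window: 100 variants = 5.0/kb, below threshold
        assert density_outliers(wm, 4.9)["window"].tolist() == [0, 2]

    def test_hotspot_recovered_at_three_times_mean_rate(self):
        """A 5x single-window hotspot is found in >=95% of replicates when
        thresholding at 3x the genome-wide mean rate."""
        rng = np.random.default_rng(42)
        found = 0
        for _ in range(50):
            counts = rng.poisson(40, size=60)
            counts[17] = rng.poisson(200)
            wm = WindowMatrix("chr1", 50_000, 3_000_000, ["S"],
                              counts[:, None].astype(np.int64))
            mean_rate = counts.mean() / 50.0
            hits = density_outliers(wm, 3 * mean_rate)
            found += 17 in set(hits["window"])
        assert found >= 48  # 95% of 50, rounded up


class TestCooksDistances:
    def test_hat_formula_matches_loo_refit_and_statsmodels(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = 2 + 0.5 * x + rng.normal(size=12)
        ours = cooks_distances(y, x)
        np.testing.assert_allclose(ours, loo_refit_cooks(y, x), rtol=1e-9)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(ours, OLSInfluence(sm_fit).cooks_distance[0],
                                   rtol=1e-9)

    def test_random_fits_agree_with_loo_refit(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            np.testing.assert_allclose(cooks_distances(y, x), loo_refit_cooks(y, x),
                                       rtol=1e-9, atol=1e-12)

    def test_degenerate_fit_returns_zeros(self):
        y = np.full(8, 5.0)
        x = np.full(8, 3.0)
        assert cooks_distances(y, x).tolist() == [0.0] * 8


class TestCooksOutliers:
    def test_identical_samples_give_no_outliers(self):
        counts = np.tile(np.array([4, 7, 5, 6, 8, 5])[:, None], (1, 3))
        wm = WindowMatrix("chr1", 50_000, 300_000, ["A", "B", "C"], counts)
        res = cooks_outliers(wm)
        assert res is not None and not res.flags.any()
        assert (res.distances == 0).all()

    def test_single_sample_spike_is_the_unique_flag(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(30, size=(40, 3)).astype(np.int64)
        counts[13, 1] += 150
        wm = WindowMatrix("chr1", 50_000, 2_000_000, ["A", "B", "C"], counts)
        res = cooks_outliers(wm, multiplier=30)
        assert res.flagged_windows().tolist() == [13]
        # the spiked fit's distance equals the leave-one-out refit value
        loo_mean = (counts.sum(axis=1) - counts[:, 1]) / 2.0
        np.testing.assert_allclose(
            res.distances[:, 1], loo_refit_cooks(counts[:, 1], loo_mean),
            rtol=1e-9)

    def test_infinite_multiplier_never_flags(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, size=(30, 4)).astype(np.int64)
        counts[5, 0] += 500
        wm = WindowMatrix("chr1", 50_000, 1_500_000, list("ABCD"), counts)
        res = cooks_outliers(wm, multiplier=float("inf"))
        assert not res.flags.any()

    def test_flags_invariant_under_window_relabeling(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(25, size=(36, 3)).astype(np.int64)
        counts[20, 2] += 120
        wm = WindowMatrix("chr1", 50_000, 1_800_000, list("ABC"), counts)
        res = cooks_outliers(wm)
        perm = rng.permutation(36)
        wm2 = WindowMatrix("chr1", 50_000, 1_800_000, list("ABC"), counts[perm])
        res2 = cooks_outliers(wm2)
        assert np.array_equal(res.flags[perm], res2.flags)

    def test_partial_window_excluded_from_fit(self):
        counts = np.vstack([np.tile([10, 11], (6, 1)), [[500, 0]]]).astype(np.int64)
        wm = WindowMatrix("chr1", 50_000, 320_000, ["A", "B"], counts)
        res = cooks_outliers(wm)
        assert wm.partial_last and res.windows.tolist() == list(range(6))

    def test_too_few_windows_skipped(self, caplog):
        wm = WindowMatrix("chr1", 50_000, 150_000, ["A", "B"],
                          np.ones((3, 2), dtype=np.int64))
        assert cooks_outliers(wm) is None


def test_outlier_genes_matches_naive_overlap_scan():
    rng = np.random.default_rng(6)
    W = 50_000
    for _ in range(10):
        n_genes = 25
        transcripts = {}
        spans = {}
        for g in range(n_genes):
            s = int(rng.integers(0, 900_000))
            e = s + int(rng.integers(1000, 60_000))
            tid, gid = f"T{g}", f"G{g}"
            transcripts[tid] = Transcript(tid, gid, "chr1", "+",
                                          exons=[(s, e)], cds=[])
            spans[gid] = (s, e)
        genes = GeneModelSet(transcripts=transcripts)
        flagged = sorted(rng.choice(20, size=3, replace=False))
        res = OutlierResult(
            chrom="chr1", window_size=W, multiplier=30.0,
            windows=np.arange(20), samples=["S"],
            distances=np.zeros((20, 1)), mean_d=np.zeros(1),
            thresholds=np.zeros(1),
            flags=np.isin(np.arange(20), flagged),
            max_d=np.zeros(20),
        )
        ns_pos = {"S": {"chr1": rng.integers(1, 1_000_001, size=60)}}
        got = set(outlier_genes({"chr1": res}, genes, ns_pos)["gene_id"])

        # naive O(n*m) scan
        expect = set()
        for gid, (s, e) in spans.items():
            has_ns = any(s < p <= e for p in ns_pos["S"]["chr1"])
            touches = any(s < (k + 1) * W and e > k * W for k in flagged)
            if has_ns and touches:
                expect.add(gid)
        assert got == expect
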