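import numpy as np
import pandas as pd
import pytest

from chipscan import triplets as tc
from chipscan import probe_stats as ps
from conftest import make_stats


# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate all windows, merge by probe sharing


def oracle_regions(stats, config=tc.CallerConfig()):
    chrom = stats["chrom"].to_numpy()
    start = stats["start"].to_numpy()
    end = stats["end"].to_numpy()
    p = stats["p_value"].to_numpy()
    n = len(stats)
    sig_windows = []
    for i in range(n - 2):
        if not (chrom[i] == chrom[i + 1] == chrom[i + 2]):
            continue
        if end[i + 2] - start[i] > config.max_span:
            continue
        ps3 = [p[i], p[i + 1], p[i + 2]]
        two = sum(v < config.p_probe for v in ps3) >= 2
        cen = ps3[1] < config.p_center and ps3[0] < config.p_flank and ps3[2] < config.p_flank
        if two or cen:
            sig_windows.append({i, i + 1, i + 2})
    # transitive merge by shared probe membership (union-find over windows)
    parent = list(range(len(sig_windows)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(sig_windows)):
        for b in range(a + 1, len(sig_windows)):
            if sig_windows[a] & sig_windows[b]:
                parent[find(a)] = find(b)
    groups = {}
    for w in range(len(sig_windows)):
        groups.setdefault(find(w), set()).update(sig_windows[w])
    regions = []
    for members in groups.values():
        idx = sorted(members)
        regions.append(
            (
                chrom[idx[0]],
                int(min(start[i] for i in idx)),
                int(max(end[i] for i in idx)),
                len(idx),
                sum(1 for w in sig_windows if w <= members),
                float(min(p[i] for i in idx)),
            )
        )
    regions.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_probes", "n_triplets", "best_p"]
    )


def random_instance(rng, max_probes=1000):
    n = int(rng.integers(3, max_probes))
    n_chrom = int(rng.integers(1, 4))
    chroms = np.sort(rng.integers(0, n_chrom, n))
    starts = np.zeros(n, dtype=int)
    pos = 0
    for i in range(n):
        if i and chroms[i] != chroms[i - 1]:
            pos = 0
        pos += int(rng.integers(100, 600))
        starts[i] = pos
    # heavy-tailed p-values so significant triplets actually occur
    p = rng.random(n) ** 3
    return make_stats(starts, p, chroms=[f"c{c}" for c in chroms])


class TestTripletRule:
    @pytest.mark.parametrize(
        "pvals, span_starts, expect_sig, expect_rule",
        [
            ((0.04, 0.20, 0.03), (0, 370, 740), True, tc.RULE_TWO_OF_THREE),
            ((0.09, 0.009, 0.09), (0, 370, 740), True, tc.RULE_CENTER),
            ((0.04, 0.20, 0.03), (0, 570, 1140), False, tc.RULE_TWO_OF_THREE),
            ((0.05, 0.05, 0.05), (0, 220, 440), False, tc.RULE_NONE),
        ],
        ids=["two_of_three", "center_rule", "window_too_wide", "thresholds_strict"],
    )
    def test_printed_rule_boundary_cases(self, pvals, span_starts, expect_sig, expect_rule):
        stats = make_stats(span_starts, pvals)
        trip = tc.scan_triplets(stats)
        assert len(trip) == 1
        assert bool(trip["significant"].iloc[0]) is expect_sig
        assert trip["rule"].iloc[0] == expect_rule

    def test_unsorted_input_rejected(self):
        stats = make_stats([500, 100, 900], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="sorted"):
            tc.scan_triplets(stats)

    def test_triplet_count_per_chromosome(self):
        rng = np.random.default_rng(5)
        stats = random_instance(rng, max_probes=200)
        trip = tc.scan_triplets(stats)
        for c, grp in stats.groupby("chrom"):
            assert (trip["chrom"] == c).sum() == max(0, len(grp) - 2)


class TestMerge:
    def test_overlapping_triplets_merge(self):
        stats = make_stats([0, 200, 400, 600], [0.01, 0.01, 0.3, 0.01])
        trip = tc.scan_triplets(stats)
        assert trip["significant"].tolist() == [True, True]
        regions = tc.merge_triplets(trip, stats)
        assert len(regions) == 1
        assert regions["n_probes"].iloc[0] == 4
        assert regions["n_triplets"].iloc[0] == 2
        assert regions["start"].iloc[0] == 0 and regions["end"].iloc[0] == 660

    def test_disjoint_triplets_stay_separate(self):
        starts = [0, 200, 400, 5000, 5200, 5400]
        p = [0.01, 0.01, 0.01, 0.01, 0.01, 0.01]
        stats = make_stats(starts, p)
        trip = tc.scan_triplets(stats)
        regions = tc.merge_triplets(trip, stats)
        assert len(regions) == 2
        assert regions["region_id"].tolist() == ["R000001", "R000002"]

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            stats = random_instance(rng, max_probes=200)
            trip = tc.scan_triplets(stats)
            got = tc.merge_triplets(trip, stats)[
                ["chrom", "start", "end", "n_probes", "n_triplets", "best_p"]
            ].reset_index(drop=True)
            want = oracle_regions(stats)
            pd.testing.assert_frame_equal(
                got.astype({"chrom": str}), want.astype({"chrom": str}), check_dtype=False
            )

    def test_invariant_to_distant_padding_probes(self):
        stats = make_stats([1000, 1200, 1400], [0.01, 0.01, 0.3])
        trip = tc.scan_triplets(stats)
        base = tc.merge_triplets(trip, stats)
        padded = make_stats(
            [0, 1000, 1200, 1400, 90000], [0.9, 0.01, 0.01, 0.3, 0.9]
        )
        trip2 = tc.scan_triplets(padded)
        got = tc.merge_triplets(trip2, padded)
        pd.testing.assert_frame_equal(
            base[["chrom", "start", "end", "n_probes", "best_p"]],
            got[["chrom", "start", "end", "n_probes", "best_p"]],
        )


class TestFdr:
    def test_reproducible_for_fixed_seed(self, small_array):
        _, probes, _, _ = small_array
        a = tc.estimate_fdr(probes, n_permutations=4, seed=9)
        b = tc.estimate_fdr(probes, n_permutations=4, seed=9)
        assert a == b

    def test_zero_permutations_rejected(self, small_array):
        _, probes, _, _ = small_array
        with pytest.raises(ValueError, match="n_permutations"):
            tc.estimate_fdr(probes, n_permutations=0)

    def test_pure_null_fdr_near_one(self, null_array):
        _, probes, _, _ = null_array
        est = tc.estimate_fdr(probes, n_permutations=8, seed=3)
        sd = np.std(est.null_region_counts, ddof=1)
        se = sd * np.sqrt(1 + 1 / est.n_permutations) / est.observed_regions
        assert abs(est.fdr - 1.0) <= 3 * se

    def test_spike_in_fdr_well_below_null(self, small_array):
        # enrichment pulls the FDR far below the pure-null value of ~1
        _, probes, _, _ = small_array
        est = tc.estimate_fdr(probes, n_permutations=5, seed=3)
        assert est.fdr < 0.95
        assert est.mean_null_regions < est.observed_regions

    def test_no_observed_regions_flags_warning(self, null_array):
        _, probes, _, _ = null_array
        strict = tc.CallerConfig(p_probe=1e-12, p_center=1e-12, p_flank=1e-12)
        est = tc.estimate_fdr(probes, strict, n_permutations=2, seed=0)
        assert est.observed_regions == 0
        assert est.fdr == 0.0
        assert est.zero_observed


def test_caller_recovers_spiked_regions(small_array):
    """End-to-end sensitivity and boundary accuracy on spiked truth."""
    from chipscan.evaluate import region_recovery

    cfg, probes, genes, truth = small_array
    stats = ps.compute_probe_stats(probes)
    _, regions = tc.call_regions(stats)
    rec = region_recovery(regions, truth.true_regions)
    assert rec.sensitivity >= 0.95
    assert rec.mean_boundary_error <= cfg.probe_spacing
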