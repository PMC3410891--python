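import numpy as np
import pandas as pd
import pytest

from vgwas import (
    ScanConfig,
    SimConfig,
    bonferroni_threshold,
    compare_scans,
    run_scan,
    simulate_dataset,
)
from vgwas.data import DataError
from vgwas.scan import REASON_LOW_MAF, REASON_TESTED, VarianceScan


@pytest.fixture(scope="module")
def causal_scan():
    """Scan of a simulated dataset with one strong variance-controlling
    locus (SD ratio 3, LAF 0.5, no mean effect) among null markers."""
    cfg = SimConfig(
        n_lines=200, n_markers=120, laf=0.5, sd_low=1.0, sd_high=3.0, seed=21
    )
    G, P, truth = simulate_dataset(cfg)
    return run_scan(G, P, "trait", ScanConfig()), truth


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(1, 0.05) == 0.05
        thr = bonferroni_threshold(216_130, 0.05)
        assert thr == pytest.approx(2.3133e-7, rel=1e-4)
        assert -np.log10(thr) == pytest.approx(6.636, abs=1e-3)

    def test_zero_tests(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)


class TestRunScan:
    def test_causal_marker_tops_variance_scan(self, causal_scan):
        res, truth = causal_scan
        t = res.table
        tested = t[t["reason_code"] == REASON_TESTED]
        best = tested.loc[tested["bf_p"].idxmin(), "marker_id"]
        assert best == truth["causal_marker"]
        assert res.significant("bf")["marker_id"].eq("causal").any()

    def test_decomposition_attached_to_all_tested(self, causal_scan):
        res, _ = causal_scan
        tested = res.table[res.table["reason_code"] == REASON_TESTED]
        assert tested[["laf", "h2_m", "h2_d"]].notna().all().all()
        causal = tested[tested["marker_id"] == "causal"].iloc[0]
        assert causal["h2_d"] > 0.1
        assert causal["d_sigma"] > 0

    def test_low_maf_markers_not_tested(self, causal_scan):
        res, _ = causal_scan
        low = res.table[res.table["maf"] < res.config.maf_min]
        assert (low["reason_code"] != REASON_TESTED).all()
        assert set(res.table["reason_code"]) <= {
            "tested",
            "monomorphic",
            "low_maf",
            "low_count",
        }

    def test_deterministic(self, causal_scan):
        res, _ = causal_scan
        cfg = SimConfig(
            n_lines=200, n_markers=120, laf=0.5, sd_low=1.0, sd_high=3.0, seed=21
        )
        G, P, _ = simulate_dataset(cfg)
        res2 = run_scan(G, P, "trait", ScanConfig())
        pd.testing.assert_frame_equal(res.table, res2.table)
        assert res.lambda_bf == res2.lambda_bf

    def test_gc_clamp_keeps_p_at_least_nominal(self, causal_scan):
        res, _ = causal_scan
        t = res.table[res.table["reason_code"] == REASON_TESTED]
        if res.lambda_bf > 1:
            assert (t["bf_p_gc"] >= t["bf_p"] - 1e-15).all()

    def test_bonferroni_uses_tested_count(self, causal_scan):
        res, _ = causal_scan
        assert res.bonferroni == pytest.approx(res.config.alpha / res.n_tested)

    def test_fixed_denominator_override(self, causal_scan):
        res, _ = causal_scan
        G, P, _ = simulate_dataset(
            SimConfig(n_lines=200, n_markers=120, laf=0.5, sd_low=1.0, sd_high=3.0, seed=21)
        )
        res2 = run_scan(G, P, "trait", ScanConfig(bonferroni_m=216_130))
        assert res2.bonferroni == pytest.approx(0.05 / 216_130)

    def test_null_genome_rarely_significant(self):
        # with no effects and no structure, Bonferroni should keep the
        # family-wise error low: most seeds yield zero significant markers
        hits = 0
        for seed in range(10):
            G, P, _ = simulate_dataset(
                SimConfig(n_lines=150, n_markers=150, laf=0.5, seed=100 + seed)
            )
            res = run_scan(G, P, "trait", ScanConfig())
            hits += int(len(res.significant("bf")) > 0)
        assert hits <= 1

    def test_marker_independence_of_filtering(self):
        # dropping a marker leaves other markers' statistics unchanged,
        # but changes lambda and the Bonferroni denominator
        G, P, _ = simulate_dataset(SimConfig(n_lines=120, n_markers=60, seed=5))
        full = run_scan(G, P, "trait", ScanConfig())
        keep = np.arange(1, G.n_markers)
        G2 = type(G)(
            marker_ids=G.marker_ids[keep],
            chrom=G.chrom[keep],
            pos=G.pos[keep],
            allele_a=G.allele_a[keep],
            allele_b=G.allele_b[keep],
            calls=G.calls[keep],
            accession_ids=G.accession_ids,
        )
        sub = run_scan(G2, P, "trait", ScanConfig())
        merged = full.table.set_index("marker_id").loc[sub.table["marker_id"]]
        np.testing.assert_allclose(
            merged["bf_F"].to_numpy(float),
            sub.table.set_index("marker_id")["bf_F"].to_numpy(float),
            equal_nan=True,
        )
        assert sub.bonferroni != full.bonferroni

    def test_unknown_trait_fails_fast(self, example_data):
        G, P, _ = example_data
        with pytest.raises(KeyError):
            VarianceScan(G, P, "nope")

    def test_all_filtered_raises_with_counts(self):
        G, P, _ = simulate_dataset(SimConfig(n_lines=50, n_markers=10, seed=3))
        with pytest.raises(DataError, match="reason counts"):
            run_scan(G, P, "trait", ScanConfig(maf_min=0.49999))


class TestTriageFlag:
    def test_structured_trait_flagged(self):
        cfg = SimConfig(
            n_lines=200, n_markers=250, n_subpops=3, fst=0.3, subpop_shift=2.0, seed=9
        )
        G, P, _ = simulate_dataset(cfg)
        res = run_scan(G, P, "trait", ScanConfig())
        assert res.lambda_bf > 1.5 and res.inflated

    def test_unstructured_trait_not_flagged(self):
        G, P, _ = simulate_dataset(SimConfig(n_lines=200, n_markers=250, seed=13))
        res = run_scan(G, P, "trait", ScanConfig())
        assert not res.inflated


class TestCompareScans:
    def test_identical_vectors(self):
        p = np.array([1e-9, 0.5, 1e-8, 0.9])
        s = compare_scans(p, p, 1e-6)
        assert s.joint_per_mille == 1000.0
        assert s.n_sig_both == 2

    def test_disjoint_sets(self):
        a = np.array([1e-9, 0.5, 0.5])
        b = np.array([0.5, 1e-9, 0.5])
        s = compare_scans(a, b, 1e-6)
        assert s.n_sig_both == 0 and s.joint_per_mille == 0.0

    def test_variance_architecture_favours_vgwas(self, causal_scan):
        res, _ = causal_scan
        t = res.table[res.table["reason_code"] == REASON_TESTED]
        s = compare_scans(
            t["wx_p_gc"].to_numpy(float),
            t["bf_p_gc"].to_numpy(float),
            res.bonferroni,
        )
        assert s.n_sig_vgwas > s.n_sig_gwas


class TestExports:
    def test_qq_and_manhattan_shapes(self, causal_scan, tmp_path):
        res, _ = causal_scan
        qq = res.qq_frame("bf")
        man = res.manhattan_frame("bf")
        assert len(qq) == len(man) == res.n_tested
        assert np.all(np.diff(qq["expected_neglog10_p"].to_numpy()) >= 0)
        paths = res.to_files(str(tmp_path / "out"))
        back = pd.read_csv(tmp_path / "out.scan.tsv", sep="\t", na_values=["NA"])
        assert len(back) == len(res.table)
        assert "bf_p_gc" in back.columns
        assert len(paths) == 6

    def test_summary_mentions_lambda_and_threshold(self, causal_scan):
        res, _ = causal_scan
        text = res.summary()
        assert "lambda" in text and "Bonferroni" in text
        assert f"{res.n_tested:>8d}" in text
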