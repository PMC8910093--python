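"""LOD, variant calling, germline concordance QC and copy number."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import liqrad as lq
from liqrad import variants as V


def brute_force_lod(depth, error_rate, alpha):
    """Scan m in steps of 1/depth with the exact binomial tail."""
    if error_rate == 0:
        return 1 / depth
    for c in range(1, depth + 1):
        if binom.sf(c - 1, depth, error_rate) <= alpha:
            return c / depth
    return 1.0


class TestComputeLod:
    def test_zero_error_gives_one_read(self):
        assert lq.compute_lod(100, 0.0) == pytest.approx(0.01)

    def test_monotone_nonincreasing_in_depth(self):
        for err in (1e-4, 1e-3, 1e-2):
            assert lq.compute_lod(10000, err) <= lq.compute_lod(1000, err)

    @pytest.mark.parametrize("depth", [50, 200, 1000, 10000])
    @pytest.mark.parametrize("error_rate", [1e-4, 1e-3, 5e-3, 2e-2])
    def test_matches_brute_force_oracle(self, depth, error_rate):
        for alpha in (0.01, 0.05):
            assert lq.compute_lod(depth, error_rate, alpha) == pytest.approx(
                brute_force_lod(depth, error_rate, alpha)
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lq.compute_lod(0, 0.001)
        with pytest.raises(ValueError):
            lq.compute_lod(100, 0.5)


def mini_table(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "analyte", "gene", "locus",
                 "ref_depth", "alt_depth"],
    )


class TestCallVariants:
    def test_analyte_floors(self):
        table = mini_table([
            ("s_cf", "p1", "cfDNA", "AR", "L1", 9995, 5),      # MAF 0.0005 < 0.1% floor
            ("s_cf", "p1", "cfDNA", "AR", "L2", 9800, 200),     # MAF 2% -> called
            ("s_ctc", "p1", "CTC", "AR", "L3", 750, 250),       # MAF 25% > 10% floor
            ("s_ctc", "p1", "CTC", "AR", "L4", 950, 50),        # MAF 5% < 10% floor
            ("s_ctc", "p1", "CTC", "AR", "L5", 1000, 0),        # no alt reads
        ])
        calls = lq.call_variants(table).set_index("locus")
        assert not calls.loc["L1", "called"]
        assert calls.loc["L2", "called"]
        assert calls.loc["L3", "called"]
        assert not calls.loc["L4", "called"]
        assert not calls.loc["L5", "called"]

    def test_zero_depth_rows_skipped(self):
        table = mini_table([
            ("s", "p1", "cfDNA", "AR", "L1", 0, 0),
            ("s", "p1", "cfDNA", "AR", "L2", 500, 250),
        ])
        calls = lq.call_variants(table)
        assert list(calls["locus"]) == ["L2"]

    def test_calling_monotone_in_alt_reads(self):
        """Raising alt (fixed total) never un-calls."""
        prev = False
        for alt in range(0, 200, 10):
            t = mini_table([("s", "p", "CTC", "AR", "L", 1000 - alt, alt)])
            called = bool(lq.call_variants(t)["called"].iloc[0])
            assert called >= prev
            prev = called


def germline_fixture(fn_counts, n_loci=20, depth=500):
    """WBC+buffy carry all loci; each CTC misses its first fn germline loci."""
    rows = []
    loci = [f"L{i}" for i in range(n_loci)]
    for locus in loci:
        rows.append(("wbc", "p1", "WBC", "G", locus, depth // 2, depth // 2))
        rows.append(("buffy", "p1", "buffy", "G", locus, depth // 2, depth // 2))
    for j, fn in enumerate(fn_counts):
        for i, locus in enumerate(loci):
            alt = 0 if i < fn else depth // 2
            rows.append((f"ctc{j}", "p1", "CTC", "G", locus, depth - alt, alt))
    return mini_table(rows)


class TestGermlineConcordance:
    def test_worked_arithmetic(self):
        summ = V.ConcordanceSummary("s", "cfDNA", tp=79, fp=1, fn=1)
        assert summ.sensitivity == pytest.approx(0.9875)
        assert summ.ppv == pytest.approx(79 / 80)

    def test_perfect_calls_score_one(self):
        calls = lq.call_variants(germline_fixture([0, 0]), error_rate=0.0)
        for s in lq.germline_concordance(calls):
            assert s.sensitivity == 1.0 and s.ppv == 1.0

    def test_designed_fn_counts_recovered(self):
        calls = lq.call_variants(germline_fixture([0, 3, 7]), error_rate=0.0)
        ctc = {s.sample_id: s for s in lq.germline_concordance(calls)
               if s.analyte == "CTC"}
        assert ctc["ctc0"].fn == 0 and ctc["ctc1"].fn == 3 and ctc["ctc2"].fn == 7

    def test_ado_sensitivity_matches_analytic_rate(self, small_cohort):
        """Mean per-cell germline sensitivity ~= 1 - ado/2 (alt dropped)."""
        spec = lq.VariantSpec(ado_rate=0.1, error_rate=0.0, het_fraction=1.0,
                              n_ctc_samples=5, seed=77)
        table, _ = lq.generate_amplicon_data(small_cohort, spec)
        calls = lq.call_variants(table, error_rate=0.0)
        cells = [s for s in lq.germline_concordance(calls) if s.analyte == "CTC"]
        per_site = np.array([[s.tp, s.fn] for s in cells]).sum(axis=0)
        n_sites = per_site.sum()
        rate = per_site[1] / n_sites
        se = np.sqrt(0.05 * 0.95 / n_sites)
        assert abs(rate - 0.05) < 3 * se


class TestFilterCells:
    def test_more_than_four_rule(self):
        summaries = [
            V.ConcordanceSummary(f"c{i}", "CTC", tp=20 - fn, fp=0, fn=fn)
            for i, fn in enumerate([0, 4, 5, 9])
        ]
        retained, excluded = lq.filter_cells(summaries)
        assert [s.sample_id for s in retained] == ["c0", "c1"]
        assert [s.sample_id for s in excluded] == ["c2", "c3"]

    def test_constructed_high_ado_cells_exactly_excluded(self):
        """Cells built with >4 germline dropouts are exactly the filtered set,
        mirroring an 11-of-35 poor-performer scenario."""
        fns = [6 if i < 11 else 1 for i in range(35)]
        calls = lq.call_variants(germline_fixture(fns), error_rate=0.0)
        cells = [s for s in lq.germline_concordance(calls) if s.analyte == "CTC"]
        retained, excluded = lq.filter_cells(cells)
        assert sorted(s.sample_id for s in excluded) == sorted(
            f"ctc{i}" for i in range(11)
        )
        assert len(retained) == 24


def cn_fixture(n_samples=6, n_genes=4, depth=400, amp=None):
    rows = []
    genes = [f"G{i}" for i in range(n_genes)]
    for s in range(n_samples):
        for g in genes:
            d = depth
            if amp and s == amp[0] and g == amp[1]:
                d = int(depth * amp[2] / 2)
            for j in range(2):
                rows.append((f"s{s}", f"p{s}", "cfDNA", g, f"{g}_a{j}", d, 0))
    return mini_table(rows)


class TestCopyNumber:
    def test_identical_samples_give_ploidy_everywhere(self):
        est = lq.estimate_copy_number(cn_fixture())
        assert np.allclose(est["ratio"], 1.0)
        assert np.allclose(est["copies"], 2.0)

    def test_fourfold_depth_reads_as_eight_copies(self):
        """One sample at 4x normalized depth for one gene -> ~8 copies, with
        the self-normalization shrinkage of that sample's total reads."""
        est = lq.estimate_copy_number(cn_fixture(n_genes=40, amp=(0, "G0", 8.0)))
        got = est.set_index(["sample_id", "gene"]).loc[("s0", "G0"), "copies"]
        # total-reads adjustment deflates by (G-1+4)/G with G=40
        expected = 8.0 / (43 / 40)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_median_sample_ratio_is_one_by_construction(self):
        rng = np.random.default_rng(0)
        table = cn_fixture(n_samples=7)
        table["ref_depth"] = rng.integers(200, 600, size=len(table))
        est = lq.estimate_copy_number(table)
        for _, grp in est.groupby("gene"):
            assert np.median(grp["ratio"]) == pytest.approx(1.0)

    def test_invariant_to_per_sample_depth_rescaling(self):
        table = cn_fixture(n_samples=5, amp=(1, "G1", 6.0))
        est1 = lq.estimate_copy_number(table)
        scaled = table.copy()
        mask = scaled["sample_id"] == "s2"
        scaled.loc[mask, ["ref_depth", "alt_depth"]] *= 17
        est2 = lq.estimate_copy_number(scaled)
        pd.testing.assert_frame_equal(est1, est2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lq.estimate_copy_number(cn_fixture(n_samples=2))


class TestCnConcordance:
    def test_worked_values(self):
        """cfDNA 7.5 vs CTC 5.5/6.0/7.6 copies for one gene."""
        est = pd.DataFrame(
            {
                "sample_id": ["cf", "c1", "c2", "c3"],
                "patient_id": ["p"] * 4,
                "analyte": ["cfDNA", "CTC", "CTC", "CTC"],
                "gene": ["AR"] * 4,
                "ratio": [1.0] * 4,
                "copies": [7.5, 5.5, 6.0, 7.6],
            }
        )
        out = lq.cn_concordance(est, "AR")
        vals = [7.5, 5.5, 6.0, 7.6]
        expected = max(
            abs(a - b) / ((a + b) / 2)
            for i, a in enumerate(vals)
            for b in vals[i + 1 :]
        )
        assert out["max_rel_diff"].iloc[0] == pytest.approx(expected)

    def test_identical_values_give_zero(self):
        est = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "patient_id": ["p", "p"],
                "analyte": ["cfDNA", "CTC"],
                "gene": ["AR", "AR"],
                "ratio": [1, 1],
                "copies": [4.0, 4.0],
            }
        )
        assert lq.cn_concordance(est, "AR")["max_rel_diff"].iloc[0] == 0.0


class TestVcfExport:
    def test_minimal_vcf_written(self, tmp_path):
        calls = lq.call_variants(germline_fixture([0]), error_rate=0.0)
        path = tmp_path / "calls.vcf"
        V.write_vcf(calls, path)
        text = path.read_text().splitlines()
        assert text[0] == "##fileformat=VCFv4.2"
        body = [l for l in text if not l.startswith("#")]
        assert len(body) == int(calls["called"].sum())
        assert "CLASS=germline" in body[0]
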