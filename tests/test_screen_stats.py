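"""Representation/depletion, PVE algebra, t-test power, ddCt, peak overlap."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cropmap import screen_stats as ss
from cropmap._util import ParseError
from cropmap.guide_design import SnpTarget


class TestRepresentationTable:
    def test_identical_proportions_zero_log_ratio(self):
        dna = pd.Series([100, 200, 300], index=list("abc"))
        rna = pd.Series([10, 20, 30], index=list("abc"))
        t = ss.representation_table(dna, rna)
        assert t["log2_ratio"].abs().max() == 0.0

    def test_double_share_gives_log2_of_two(self):
        # guide a holds 1/4 of the DNA pool but 1/2 of assigned cells
        dna = pd.Series([100, 100, 100, 100], index=list("abcd"))
        rna = pd.Series([90, 30, 30, 30], index=list("abcd"))
        t = ss.representation_table(dna, rna)
        assert t.loc["a", "log2_ratio"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_random(self, rng):
        dna = pd.Series(rng.integers(1, 1000, size=30), index=[f"g{i}" for i in range(30)])
        rna = pd.Series(rng.integers(1, 500, size=30), index=[f"g{i}" for i in range(30)])
        t = ss.representation_table(dna, rna)
        assert t["dna_frac"].sum() == pytest.approx(1.0)
        assert t["rna_frac"].sum() == pytest.approx(1.0)

    def test_zero_counts_flagged_not_inf(self):
        dna = pd.Series([0, 100], index=list("ab"))
        rna = pd.Series([10, 90], index=list("ab"))
        t = ss.representation_table(dna, rna)
        assert not np.isinf(t["log2_ratio"]).any()
        assert not t.loc["a", "ratio_defined"]

    def test_mismatched_guides_rejected(self):
        with pytest.raises(ValueError, match="different guide sets"):
            ss.representation_table(
                pd.Series([1], index=["a"]), pd.Series([1], index=["b"])
            )


class TestDepletionTest:
    def test_proportional_counts_no_calls(self):
        dna = pd.Series([1000] * 10, index=[f"g{i}" for i in range(10)])
        rna = pd.Series([50] * 10, index=[f"g{i}" for i in range(10)])
        out = ss.depletion_test(ss.representation_table(dna, rna))
        assert not out["called"].any()

    def test_planted_depletion_called_only_for_depleted_guides(self, rng):
        """Guides given a 5x death rate are the only depletion calls."""
        n = 20
        idx = [f"g{i}" for i in range(n)]
        dna = pd.Series(rng.poisson(10_000, size=n), index=idx, dtype=float)
        frac = dna / dna.sum()
        death = np.ones(n)
        death[:3] = 0.2  # essential-gene guides retain 1/5 of cells
        expected = frac * death
        rna = pd.Series(
            rng.multinomial(6000, expected / expected.sum()), index=idx, dtype=float
        )
        out = ss.depletion_test(ss.representation_table(dna, rna))
        assert set(out.index[out["depleted"]]) == {"g0", "g1", "g2"}

    def test_null_pvalues_uniform(self, rng):
        """Depletion-test p-values under the proportional null pass a KS test."""
        idx = [f"g{i}" for i in range(50)]
        dna = pd.Series([10_000] * 50, index=idx)
        pvals = []
        for _ in range(20):  # 20 null screens x 50 guides = 1000 p-values
            rna = pd.Series(rng.multinomial(5000, np.full(50, 1 / 50)), index=idx)
            out = ss.depletion_test(ss.representation_table(dna, rna))
            pvals.extend(out["p"].tolist())
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_anomalous_zero_dna_flagged(self):
        dna = pd.Series([0, 100], index=list("ab"))
        rna = pd.Series([10, 90], index=list("ab"))
        out = ss.depletion_test(ss.representation_table(dna, rna))
        assert bool(out.loc["a", "anomaly"])


class TestPveFromShift:
    def test_zero_shift_zero_pve(self):
        assert ss.pve_from_shift(0.0, 0.3, "biallelic") == 0.0

    def test_biallelic_at_half_frequency(self):
        assert ss.pve_from_shift(0.5, 0.5, "biallelic") == pytest.approx(0.03125)

    def test_monoallelic_solves_ten_percent(self):
        p = (1 - np.sqrt(1 - 0.8)) / 2  # 2p(1-p) * 0.25 == 0.10
        assert ss.pve_from_shift(0.5, p, "monoallelic") == pytest.approx(0.10)

    def test_maximized_at_half_frequency(self):
        grid = np.linspace(0.01, 0.99, 99)
        pves = [ss.pve_from_shift(0.5, p, "monoallelic") for p in grid]
        assert grid[int(np.argmax(pves))] == pytest.approx(0.5)

    def test_shift_of_half_sd_reaches_five_to_ten_percent(self):
        """Some allele frequency/mode maps a 0.5 SD shift into 5-10% PVE."""
        grid = np.linspace(0.01, 0.99, 199)
        pves = [
            ss.pve_from_shift(0.5, p, mode)
            for p in grid
            for mode in ("monoallelic", "biallelic")
        ]
        assert any(0.05 <= v <= 0.10 for v in pves)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ss.pve_from_shift(0.5, 0.0)
        with pytest.raises(ValueError):
            ss.pve_from_shift(-0.1, 0.5)
        with pytest.raises(ValueError):
            ss.pve_from_shift(0.5, 0.5, "triploid")


class TestPowerTwoGroup:
    def test_null_power_equals_alpha(self):
        for alpha in (0.05, 0.0025):
            assert ss.power_two_group(50, 50, 0.0, alpha) == pytest.approx(alpha, rel=1e-6)

    def test_monotone_in_n_delta_alpha(self):
        base = ss.power_two_group(100, 1000, 0.3, 0.0025)
        assert ss.power_two_group(200, 1000, 0.3, 0.0025) > base
        assert ss.power_two_group(100, 2000, 0.3, 0.0025) > base
        assert ss.power_two_group(100, 1000, 0.5, 0.0025) > base
        assert ss.power_two_group(100, 1000, 0.3, 0.05) > base

    def test_matches_monte_carlo(self, rng):
        """Noncentral-t power agrees with simulation via sufficient statistics."""
        n1, n0, delta, alpha = 100, 6000, 0.5, 0.0025
        reps = 20_000
        df = n1 + n0 - 2
        m1 = rng.normal(delta, 1 / np.sqrt(n1), size=reps)
        m0 = rng.normal(0.0, 1 / np.sqrt(n0), size=reps)
        s2 = rng.chisquare(df, size=reps) / df
        t = (m1 - m0) / np.sqrt(s2 * (1 / n1 + 1 / n0))
        crit = scipy.stats.t.ppf(1 - alpha / 2, df)
        emp = (np.abs(t) > crit).mean()
        ana = ss.power_two_group(n1, n0, delta, alpha)
        se = np.sqrt(ana * (1 - ana) / reps)
        assert abs(emp - ana) < 2 * se + 1e-4


class TestFoldChangeDdct:
    def test_zero_ddct_unity(self):
        x = ss.DdctInput(25.0, [22.0, 24.0], [2.0])
        assert ss.fold_change_ddct(x) == pytest.approx(1.0)

    def test_one_cycle_halves_expression(self):
        x = ss.DdctInput(26.0, [22.0, 24.0], [2.0])
        assert ss.fold_change_ddct(x) == pytest.approx(0.5)

    def test_hand_arithmetic_example(self):
        x = ss.DdctInput(25.0, [20.0, 22.0], [3.0, 5.0])
        assert ss.fold_change_ddct(x) == pytest.approx(1.0)

    def test_control_against_itself_is_unity(self):
        dct = 31.0 - np.mean([24.0, 26.0])
        x = ss.DdctInput(31.0, [24.0, 26.0], [dct])
        assert ss.fold_change_ddct(x) == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ss.DdctInput(25.0, [], [1.0])
        with pytest.raises(ValueError):
            ss.DdctInput(25.0, [20.0], [])


class TestPeakOverlap:
    def _snp(self, pos, chrom="chr1", snp_id="rs1"):
        return SnpTarget(snp_id, chrom, pos, "A" * 41, pos - 20, "G")

    def test_coordinate_conversion_inclusive(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [100]})
        out = ss.annotate_peak_overlap([self._snp(100)], peaks)
        assert bool(out["in_peak"].iloc[0])

    def test_position_past_interval_end_excluded(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [100]})
        out = ss.annotate_peak_overlap([self._snp(101)], peaks)
        assert not bool(out["in_peak"].iloc[0])

    def test_chromosome_mismatch_no_overlap(self):
        peaks = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [1000]})
        out = ss.annotate_peak_overlap([self._snp(100)], peaks)
        assert not bool(out["in_peak"].iloc[0])

    def test_agrees_with_naive_interval_scan(self, rng):
        peaks = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=40),
                "start": (starts := rng.integers(0, 5000, size=40)),
                "end": starts + rng.integers(1, 300, size=40),
            }
        )
        snps = [self._snp(int(p), chrom=c, snp_id=f"rs{i}")
                for i, (p, c) in enumerate(zip(rng.integers(25, 5300, size=60),
                                               rng.choice(["chr1", "chr2"], size=60)))]
        got = ss.annotate_peak_overlap(snps, peaks)
        for row, snp in zip(got.itertuples(index=False), snps):
            naive = any(
                (pk.chrom == snp.chrom) and (pk.start <= snp.pos - 1 < pk.end)
                for pk in peaks.itertuples(index=False)
            )
            assert row.in_peak == naive

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t10\t20\nchr1\tten\t20\n")
        with pytest.raises(ParseError, match="bad.bed:2"):
            ss.read_bed(str(bad))

    def test_bed_roundtrip_through_file(self, tmp_path):
        bed = tmp_path / "peaks.bed"
        bed.write_text("# comment\nchr1\t0\t100\tpeak1\nchr2\t500\t600\n")
        df = ss.read_bed(bed)
        assert len(df) == 2
        out = ss.annotate_peak_overlap([self._snp(50)], bed)
        assert bool(out["in_peak"].iloc[0])
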