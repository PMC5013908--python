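"""Summary-statistics loading and Z/p/effect scale conversions."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiqt.core import NoncentralityEstimates
from fiqt.sumstats import (
    ConfigurationError,
    InputError,
    adjusted_effect_from_z,
    pvalue_from_z,
    read_sumstats,
    write_adjusted,
    z_from_effect_se,
    z_from_pvalue_sign,
)


class TestScaleConversions:
    @pytest.mark.parametrize(
        "effect, se, expected",
        [(0.2, 0.1, 2.0), (0.0, 0.5, 0.0), (np.log(1.25), 0.05, 4.462871026284194)],
    )
    def test_z_from_effect_se(self, effect, se, expected):
        assert z_from_effect_se(effect, se) == pytest.approx(expected, rel=1e-9)

    def test_z_from_effect_se_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            z_from_effect_se(0.2, 0.0)

    @pytest.mark.parametrize(
        "p, sign, expected, tol",
        [
            (1.0, +1, 0.0, 1e-12),
            (0.0455, -1, -2.0000024438996036, 1e-9),  # frozen from scipy.stats.norm.isf(0.0455/2)
            (5e-8, +1, 5.451310437845478, 1e-9),  # the genome-wide significance quantile
        ],
    )
    def test_z_from_pvalue_sign(self, p, sign, expected, tol):
        assert z_from_pvalue_sign(p, sign) == pytest.approx(expected, abs=tol)

    def test_extreme_p_stays_finite(self):
        z = z_from_pvalue_sign(1e-308, 1)
        assert np.isfinite(z) and 37 < z < 39

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5, np.nan])
    def test_p_domain_errors(self, p):
        with pytest.raises(ValueError):
            z_from_pvalue_sign(p, 1)

    @given(st.floats(min_value=-37, max_value=37))
    @settings(max_examples=200, derandomize=True)
    def test_pz_round_trip(self, z):
        p = pvalue_from_z(z)
        sign = 1.0 if z >= 0 else -1.0
        assert z_from_pvalue_sign(p, sign) == pytest.approx(z, rel=1e-6, abs=1e-6)

    @given(st.floats(min_value=1e-300, max_value=0.5), st.floats(min_value=1e-4, max_value=0.99))
    @settings(max_examples=100, derandomize=True)
    def test_quantile_strictly_decreasing_in_p(self, p, frac):
        smaller = p * frac
        assert z_from_pvalue_sign(smaller, 1) > z_from_pvalue_sign(p, 1)


class TestAdjustedEffect:
    def test_se_scale(self):
        assert adjusted_effect_from_z(2.0, se=0.1) == pytest.approx(0.2)
        assert adjusted_effect_from_z(0.0, se=0.25) == 0.0

    def test_ratio_scale(self):
        got = adjusted_effect_from_z(1.5, mode="ratio_scale", z_raw=3.0, effect_raw=0.6)
        assert got == pytest.approx(0.3)

    def test_modes_agree_when_consistent(self):
        # ln(OR) = se * z makes the two conversions identical
        se, z_raw = 0.07, 3.2
        effect = se * z_raw
        a = adjusted_effect_from_z(1.1, se=se)
        b = adjusted_effect_from_z(1.1, mode="ratio_scale", z_raw=z_raw, effect_raw=effect)
        assert a == pytest.approx(b, rel=1e-12)

    def test_ratio_scale_zero_z_raw(self):
        with pytest.raises(ValueError):
            adjusted_effect_from_z(1.0, mode="ratio_scale", z_raw=0.0, effect_raw=0.5)

    @given(st.floats(min_value=-10, max_value=10), st.floats(min_value=-10, max_value=10))
    @settings(max_examples=50, derandomize=True)
    def test_se_scale_linear(self, z1, z2):
        f = lambda z: adjusted_effect_from_z(z, se=0.3)
        assert f(z1) + f(z2) == pytest.approx(f(z1 + z2), abs=1e-9)


class TestReadSumstats:
    def test_beta_se_table(self, tiny_sumstats):
        stats = read_sumstats(
            tiny_sumstats, {"snp": "SNP", "chrom": "CHR", "pos": "BP", "beta": "BETA", "se": "SE"}
        )
        assert len(stats) == 3
        np.testing.assert_allclose(stats.z, 2.0)
        np.testing.assert_allclose(stats.p, 2 * 0.022750131948, rtol=1e-6)
        # sorted by (chrom, pos): rs3 on chr2 comes last
        assert list(stats.variant_ids) == ["rs1", "rs2", "rs3"]

    def test_or_se_null_odds_ratio(self, tmp_path):
        path = tmp_path / "or.csv"
        path.write_text("SNP,CHR,BP,OR,SE\nrs1,1,100,1.0,0.1\n")
        stats = read_sumstats(path, {"snp": "SNP", "chrom": "CHR", "pos": "BP", "or": "OR", "se": "SE"})
        assert stats.z[0] == pytest.approx(0.0, abs=1e-12)

    def test_p_direction(self, tmp_path):
        path = tmp_path / "pd.tsv"
        path.write_text("SNP\tCHR\tBP\tP\tDIR\nrs1\t1\t100\t0.0455\t-\n")
        stats = read_sumstats(
            path, {"snp": "SNP", "chrom": "CHR", "pos": "BP", "p": "P", "direction": "DIR"}
        )
        assert stats.z[0] == pytest.approx(-2.000, abs=1e-2)

    def test_drops_out_of_domain_rows(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tBETA\tSE\tP\n"
            "rs1\t1\t100\t0.1\t0.1\t0.32\n"
            "rs2\t1\t200\t0.1\t0.0\t0.5\n"   # se <= 0
            "rs3\t1\t300\t0.1\t0.1\t1.5\n"   # p > 1
            "rs4\t1\t400\tx\ty\t0.5\n"       # unparseable
        )
        cmap = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "beta": "BETA", "se": "SE", "p": "P"}
        stats = read_sumstats(path, cmap)
        assert len(stats) == 1
        assert stats.report.n_dropped == 3
        assert sum(stats.report.drop_reasons.values()) == 3

    def test_inconsistent_pz_reported_not_fixed(self, tmp_path):
        path = tmp_path / "inc.tsv"
        path.write_text("SNP\tCHR\tBP\tZ\tP\nrs1\t1\t100\t2.0\t0.20\n")
        stats = read_sumstats(path, {"snp": "SNP", "chrom": "CHR", "pos": "BP", "z": "Z", "p": "P"})
        assert stats.report.inconsistent_pz == ["rs1"]
        assert stats.p[0] == 0.20  # kept as reported

    def test_missing_logical_column(self, tiny_sumstats):
        with pytest.raises(ConfigurationError, match="snp"):
            read_sumstats(tiny_sumstats, {"chrom": "CHR", "pos": "BP", "beta": "BETA", "se": "SE"})

    def test_no_statistic_combination(self, tiny_sumstats):
        with pytest.raises(ConfigurationError):
            read_sumstats(tiny_sumstats, {"snp": "SNP", "chrom": "CHR", "pos": "BP", "beta": "BETA"})

    def test_zero_usable_rows(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("SNP\tCHR\tBP\tP\tDIR\nrs1\t1\t100\t0.0\t+\n")
        with pytest.raises(InputError):
            read_sumstats(path, {"snp": "SNP", "chrom": "CHR", "pos": "BP", "p": "P", "direction": "DIR"})


class TestWriteAdjusted:
    def _load(self, tiny_sumstats):
        return read_sumstats(
            tiny_sumstats, {"snp": "SNP", "chrom": "CHR", "pos": "BP", "beta": "BETA", "se": "SE"}
        )

    def test_round_trip_and_shape(self, tiny_sumstats, tmp_path):
        stats = self._load(tiny_sumstats)
        ests = [
            NoncentralityEstimates("FIQT", np.array([1.5, 1.5, 1.5])),
            NoncentralityEstimates("MLE", stats.z),
        ]
        out = tmp_path / "adj.tsv"
        write_adjusted(stats, ests, out)
        again = read_sumstats(out, {"snp": "snp", "chrom": "chrom", "pos": "pos", "z": "z"})
        np.testing.assert_allclose(again.z, stats.z, rtol=1e-6)
        header = out.read_text().splitlines()[0].split("\t")
        assert header[-2:] == ["FIQT", "MLE"]

    def test_empty_estimates_copies_table(self, tiny_sumstats, tmp_path):
        stats = self._load(tiny_sumstats)
        out = tmp_path / "copy.tsv"
        write_adjusted(stats, [], out)
        assert len(out.read_text().splitlines()) == 4

    def test_length_mismatch(self, tiny_sumstats, tmp_path):
        stats = self._load(tiny_sumstats)
        with pytest.raises(InputError):
            write_adjusted(stats, [NoncentralityEstimates("FIQT", np.array([1.0]))], tmp_path / "x")
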