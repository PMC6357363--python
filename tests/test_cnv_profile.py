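import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from sarcnv.cnv_profile import (
    CNVQuantileDiscretizer,
    QuantileThresholds,
    band_frequencies,
    compare_cohorts,
    compute_thresholds,
    discretize,
    discretize_values,
    gene_frequencies,
    healthy_background_frequencies,
    tumor_vs_cellline_table,
)
from sarcnv.genomic_data import GeneModel, GenomicInterval, HealthyVariantRecord
from .conftest import make_discrete, make_genes, make_matrix


def type7_quantile(values, p):
    """Independent order-statistic interpolation oracle."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    if lo == len(v) - 1:
        return v[-1]
    return v[lo] + (h - lo) * (v[lo + 1] - v[lo])


class TestThresholds:
    def test_uniform_grid(self):
        m = make_matrix(np.arange(101.0).reshape(1, -1))
        assert compute_thresholds(m).as_tuple() == (5.0, 15.0, 85.0, 95.0)

    def test_constant_matrix_degenerates(self):
        m = make_matrix(np.full((3, 4), 0.3))
        assert compute_thresholds(m).as_tuple() == (0.3, 0.3, 0.3, 0.3)

    def test_two_values_interpolate(self):
        m = make_matrix(np.array([[0.0, 1.0]]))
        t = compute_thresholds(m)
        assert t.as_tuple() == pytest.approx((0.05, 0.15, 0.85, 0.95))

    def test_all_missing_errors(self):
        m = make_matrix(np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            compute_thresholds(m)

    def test_matches_order_statistic_oracle(self, rng):
        for _ in range(20):
            values = rng.normal(size=rng.integers(2, 40))
            t = compute_thresholds(values.reshape(1, -1))
            expected = tuple(type7_quantile(values, p) for p in (0.05, 0.15, 0.85, 0.95))
            assert t.as_tuple() == pytest.approx(expected, abs=1e-12)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            QuantileThresholds(1.0, 0.0, 2.0, 3.0)


class TestDiscretize:
    t = QuantileThresholds(-2.0, -1.0, 1.0, 2.0)

    @pytest.mark.parametrize(
        "value,code",
        [(2.5, 2), (1.5, 1), (0.0, 0), (-1.5, -1), (-2.5, -2),
         (2.0, 1), (1.0, 0), (-2.0, -1), (-1.0, 0)],  # boundary ties -> milder code
    )
    def test_five_level_rule(self, value, code):
        assert discretize_values(np.array([value]), self.t)[0] == code

    def test_degenerate_thresholds_code_zero(self):
        t = QuantileThresholds(0.3, 0.3, 0.3, 0.3)
        assert discretize_values(np.array([0.3]), t)[0] == 0

    def test_missing_stays_missing(self):
        out = discretize_values(np.array([np.nan, 0.0]), self.t)
        assert np.isnan(out[0]) and out[1] == 0

    def test_discretize_matrix_keeps_axes(self):
        m = make_matrix([[0.0, 3.0], [-3.0, 1.5]])
        d = discretize(m, self.t)
        assert list(d.values.index) == list(m.values.index)
        np.testing.assert_array_equal(d.values.to_numpy(), [[0, 2], [-2, 1]])

    def test_estimator_matches_functions(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 10)))
        est = CNVQuantileDiscretizer().fit(X)
        expected = discretize_values(X.to_numpy(), compute_thresholds(X))
        np.testing.assert_array_equal(est.transform(X).to_numpy(), expected)
        clone(est)  # sklearn-compatible construction

    def test_calibrated_proportions(self, rng):
        values = rng.normal(size=4000)
        codes = discretize_values(values, compute_thresholds(values))
        n = values.size
        tol = 2 / np.sqrt(n)
        for code, share in [(2, 0.05), (1, 0.10), (0, 0.70), (-1, 0.10), (-2, 0.05)]:
            assert np.mean(codes == code) == pytest.approx(share, abs=tol)


class TestGeneFrequencies:
    def test_direct_formula(self):
        d = make_discrete([[2, 1, 1, 0, 0, 0, 0, -1, 0, 0]])
        row = gene_frequencies(d).iloc[0]
        assert (row.amp_freq, row.del_freq, row.n_samples) == (0.3, 0.1, 10)

    def test_saturated_gene(self):
        d = make_discrete([[2] * 10])
        row = gene_frequencies(d).iloc[0]
        assert (row.amp_freq, row.del_freq) == (1.0, 0.0)

    def test_missing_excluded_from_denominator(self):
        d = make_discrete([[2, np.nan, 0, np.nan]])
        row = gene_frequencies(d).iloc[0]
        assert row.amp_freq == 0.5 and row.n_samples == 2

    def test_all_missing_gene_omitted(self):
        d = make_discrete([[np.nan, np.nan], [1, 0]])
        table = gene_frequencies(d)
        assert list(table.unit) == ["g1"]

    def test_matches_counting_oracle(self, rng):
        codes = rng.choice([-2, -1, 0, 1, 2], size=(6, 8)).astype(float)
        codes[rng.random(codes.shape) < 0.2] = np.nan
        d = make_discrete(codes)
        table = gene_frequencies(d).set_index("unit")
        for gi in range(6):
            row = codes[gi]
            obs = row[np.isfinite(row)]
            if obs.size == 0:
                assert f"g{gi}" not in table.index
                continue
            assert table.loc[f"g{gi}", "amp_freq"] == np.sum(obs >= 1) / obs.size
            assert table.loc[f"g{gi}", "del_freq"] == np.sum(obs <= -1) / obs.size

    def test_frequencies_bounded_and_exclusive(self, rng):
        codes = rng.choice([-2, -1, 0, 1, 2], size=(10, 12)).astype(float)
        table = gene_frequencies(make_discrete(codes))
        assert ((table.amp_freq >= 0) & (table.amp_freq <= 1)).all()
        assert ((table.amp_freq + table.del_freq) <= 1 + 1e-12).all()


class TestBandFrequencies:
    def test_two_gene_band(self):
        codes = np.zeros((2, 10))
        codes[0, :4] = 1   # gene A: 4 gains of 10
        codes[1, :2] = 2   # gene B: 2 gains of 10
        d = make_discrete(codes, bands=["1q11", "1q11"])
        row = band_frequencies(d).iloc[0]
        assert row.amp_freq == pytest.approx(6 / 20)
        assert row.n_genes_in_band == 2

    def test_single_gene_band_reduces_to_gene(self):
        codes = np.array([[1, 1, 0, 0, -1]])
        d = make_discrete(codes, bands=["2p11"])
        brow = band_frequencies(d).iloc[0]
        grow = gene_frequencies(d).iloc[0]
        assert brow.amp_freq == grow.amp_freq and brow.del_freq == grow.del_freq

    def test_complete_data_band_is_mean_of_genes(self, rng):
        codes = rng.choice([-2, -1, 0, 1, 2], size=(9, 7)).astype(float)
        bands = ["1p11"] * 4 + ["1q11"] * 5
        d = make_discrete(codes, bands=bands)
        gf = gene_frequencies(d)
        gf["band"] = bands
        bf = band_frequencies(d).set_index("unit")
        means = gf.groupby("band")[["amp_freq", "del_freq"]].mean()
        for band in means.index:
            assert bf.loc[band, "amp_freq"] == pytest.approx(
                means.loc[band, "amp_freq"], abs=1e-15)
            assert bf.loc[band, "del_freq"] == pytest.approx(
                means.loc[band, "del_freq"], abs=1e-15)

    def test_missing_data_counting_oracle(self, rng):
        codes = rng.choice([-2, -1, 0, 1, 2], size=(6, 8)).astype(float)
        codes[rng.random(codes.shape) < 0.3] = np.nan
        bands = ["1p11", "1p11", "1q11", "1q11", "1q11", "2p11"]
        d = make_discrete(codes, bands=bands)
        bf = band_frequencies(d).set_index("unit")
        for band in set(bands):
            idx = [i for i, b in enumerate(bands) if b == band]
            sub = codes[idx]
            obs = sub[np.isfinite(sub)]
            assert bf.loc[band, "amp_freq"] == np.sum(obs >= 1) / obs.size
            assert bf.loc[band, "del_freq"] == np.sum(obs <= -1) / obs.size

    def test_unlabeled_genes_skipped(self):
        d = make_discrete([[1, 1], [0, 0]], bands=["1q11", None])
        bf = band_frequencies(d)
        assert list(bf.unit) == ["1q11"]


class TestHealthyBackground:
    genes = [GeneModel("G", GenomicInterval("1", 100, 200))]

    def rec(self, ind, cls, start=50, end=250):
        return HealthyVariantRecord(ind, GenomicInterval("1", start, end), cls)

    def test_single_gain(self):
        table = healthy_background_frequencies([self.rec("I1", "gain")], self.genes, 4)
        assert table.iloc[0].amp_freq == 0.25 and table.iloc[0].cohort == "HEALTHY"

    def test_distinct_individual_counting(self):
        records = [self.rec("I1", "gain"), self.rec("I1", "gain", 60, 220)]
        table = healthy_background_frequencies(records, self.genes, 4)
        assert table.iloc[0].amp_freq == 0.25

    def test_nonpositive_population_errors(self):
        with pytest.raises(ValueError):
            healthy_background_frequencies([], self.genes, 0)

    def test_matches_overlap_oracle(self, rng):
        genes = make_genes(5, start=0, length=50, spacing=100)
        records = []
        for i in range(30):
            lo = int(rng.integers(0, 480))
            hi = lo + int(rng.integers(10, 120))
            cls = "gain" if rng.random() < 0.5 else "loss"
            records.append(HealthyVariantRecord(f"I{int(rng.integers(8))}",
                                                GenomicInterval("1", lo, hi), cls))
        table = healthy_background_frequencies(records, genes, 8).set_index("unit")
        for g in genes:
            for cls, col in (("gain", "amp_freq"), ("loss", "del_freq")):
                inds = {r.individual_id for r in records
                        if r.variant_class == cls
                        and g.interval.overlap_length(r.interval) > 0}
                assert table.loc[g.symbol, col] == len(inds) / 8


def freq_table(cohort, units, amps, dels):
    return pd.DataFrame({
        "unit": units, "unit_kind": "gene", "cohort": cohort,
        "amp_freq": amps, "del_freq": dels,
        "n_samples": 10, "n_genes_in_band": 1,
    })


class TestCompareCohorts:
    def test_floor_zero_gives_intersection(self):
        a = freq_table("A", ["g1", "g2", "g3"], [0.1, 0.2, 0.3], [0, 0, 0])
        b = freq_table("B", ["g2", "g3", "g4"], [0.5, 0.0, 0.9], [0, 0, 0])
        overlap = compare_cohorts([a, b], 0.0)
        assert overlap.overlap_genes == ["g2", "g3"]

    def test_floor_applied_in_all_cohorts(self):
        a = freq_table("A", ["g1", "g2"], [0.5, 0.5], [0, 0])
        b = freq_table("B", ["g1", "g2"], [0.6, 0.3], [0, 0])
        c = freq_table("C", ["g1", "g2"], [0.7, 0.9], [0, 0])
        overlap = compare_cohorts([a, b, c], 0.4)
        assert overlap.overlap_genes == ["g1"]

    def test_deletion_counts_as_alteration(self):
        a = freq_table("A", ["g1"], [0.0], [0.8])
        b = freq_table("B", ["g1"], [0.9], [0.0])
        assert compare_cohorts([a, b], 0.5).overlap_genes == ["g1"]

    def test_disjoint_universes_warn_empty(self):
        a = freq_table("A", ["g1"], [0.5], [0])
        b = freq_table("B", ["g2"], [0.5], [0])
        assert compare_cohorts([a, b], 0.0).overlap_genes == []

    def test_requires_two_cohorts(self):
        with pytest.raises(ValueError):
            compare_cohorts([freq_table("A", ["g1"], [0.5], [0])])


class TestTumorVsCellline:
    def test_panel_rows_and_missing_entries(self):
        d = make_discrete([[1, 1, 0, 0], [0, 0, 0, 0]])  # genes g0, g1
        tumor = freq_table("OS", ["g0", "g9"], [0.7, 0.2], [0.0, 0.1])
        table = tumor_vs_cellline_table([tumor], d, panel=["g0", "g1", "g9"])
        assert len(table) == 3
        row9 = table.set_index("unit").loc["g9"]
        assert np.isnan(row9.cellline_amp_freq)
        assert row9.OS_amp_freq == 0.2
        row0 = table.set_index("unit").loc["g0"]
        assert row0.cellline_amp_freq == 0.5 and row0.OS_amp_freq == 0.7
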