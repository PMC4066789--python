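"""Abundance-fluctuation statistics: spec'd examples, brute-force agreement,
and behaviour on planted synthetic classes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import conftest
from famflux import stats, synth


def _matrix(counts, fam_prefix="F", gen_prefix="g"):
    counts = np.asarray(counts)
    return pd.DataFrame(
        counts,
        index=[f"{fam_prefix}{i}" for i in range(counts.shape[0])],
        columns=[f"{gen_prefix}{j}" for j in range(counts.shape[1])],
    )


def _one_bin(n):
    return [stats.GenomeBin(b=0, lower=0.0, upper=1e9, members=np.arange(n), n_b=n)]


class TestGenomeSizes:
    def test_column_sums(self):
        m = _matrix([[1, 0], [2, 3]])
        assert list(stats.genome_sizes(m)) == [3, 3]

    def test_all_zero_column(self):
        m = _matrix([[0, 1], [0, 2]])
        assert list(stats.genome_sizes(m)) == [0, 3]

    def test_sizes_track_planted_size_factors(self, ensemble):
        sizes = stats.genome_sizes(ensemble["matrix"])
        s = ensemble["truth"].genomes["size_factor"]
        rho = pd.Series(sizes.to_numpy()).corr(
            pd.Series(s.to_numpy()), method="spearman"
        )
        assert rho > 0.9


class TestBuildBins:
    def test_equal_sizes_single_bin(self):
        bins = stats.build_bins(np.full(20, 1500.0))
        assert len(bins) == 1 and bins[0].n_b == 20

    def test_non_sliding_special_case_partitions(self):
        sizes = np.arange(1000, 2170, 10.0)
        bins = stats.build_bins(sizes, width=390, step=390, min_bin=1)
        members = np.concatenate([b.members for b in bins])
        assert len(members) == len(set(members)) == sizes.size

    def test_sliding_bins_overlap_four_deep(self):
        sizes = np.linspace(1000, 3000, 400) + 0.5  # keep off the bin edges
        bins = stats.build_bins(sizes, width=390, step=100, min_bin=1)
        depth = np.zeros(sizes.size, int)
        for b in bins:
            depth[b.members] += 1
        # a length-390 window holds 3 or 4 of the step-100 bin starts
        # depending on phase, with ceil(390/100) = 4 the typical depth
        interior = (sizes >= 1000 + 390) & (sizes <= 3000 - 390)
        assert set(depth[interior]) <= {3, 4}
        assert (depth[interior] == math.ceil(390 / 100)).mean() > 0.8

    def test_empty_sizes_rejected(self):
        with pytest.raises(ValueError):
            stats.build_bins(np.array([]))


class TestSamplingWeights:
    def test_full_presence_single_bin_gives_one(self):
        m = _matrix([[2, 3, 1, 4]])
        _, w = stats.sampling_weights(m, _one_bin(4))
        assert w.iloc[0] == pytest.approx(1.0)

    def test_absent_family_gets_zero(self):
        m = _matrix([[0, 0, 0]])
        _, w = stats.sampling_weights(m, _one_bin(3))
        assert w.iloc[0] == 0.0

    def test_two_bin_arithmetic(self):
        # bins (n=10, n+=5) and (n=20, n+=20): w = (50+400)/(100+400) = 0.9
        row = [1] * 5 + [0] * 5 + [1] * 20
        m = _matrix([row])
        bins = [
            stats.GenomeBin(0, 0, 1, np.arange(10), 10),
            stats.GenomeBin(1, 1, 2, np.arange(10, 30), 20),
        ]
        _, w = stats.sampling_weights(m, bins)
        assert w.iloc[0] == pytest.approx(0.9)

    @given(st.integers(0, 2**32 - 1))
    def test_weights_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.poisson(2.0, size=(5, 30)))
        bins = stats.build_bins(
            stats.genome_sizes(m), width=5, step=2, min_bin=2
        )
        if not bins:
            return
        w_fb, w = stats.sampling_weights(m, bins)
        assert (w_fb.to_numpy() >= 0).all()
        assert ((w >= 0) & (w <= 1 + 1e-12)).all()


class TestL1Statistic:
    def test_point_mass_versus_poisson(self):
        # constant abundance 30: L = 1 - Poiss(30; 30) ~= 0.9274
        m = _matrix([[30] * 50])
        _, L = stats.l1_statistic(m, _one_bin(50))
        expected = 1.0 - conftest.poisson_pmf_scalar(30, 30.0)
        assert L.iloc[0] == pytest.approx(expected, abs=1e-12)
        assert L.iloc[0] == pytest.approx(0.9274, abs=5e-5)

    def test_bounded_and_absent_family_nan(self):
        m = _matrix([[0, 0, 0, 0], [1, 2, 3, 4]])
        _, L = stats.l1_statistic(m, _one_bin(4))
        assert np.isnan(L.iloc[0])
        assert 0.0 <= L.iloc[1] <= 1.0


class TestQStatistic:
    def test_single_bin_arithmetic(self):
        # {2,4,4,6}: mean 4, population variance 2 -> ln 2
        m = _matrix([[2, 4, 4, 6]])
        _, Q, capped = stats.q_statistic(m, _one_bin(4))
        assert Q.iloc[0] == pytest.approx(math.log(2), abs=1e-12)
        assert not capped.iloc[0]

    def test_zero_variance_without_fallback_is_capped(self):
        m = _matrix([[7] * 12])
        _, Q, capped = stats.q_statistic(m, _one_bin(12))
        assert Q.iloc[0] == pytest.approx(stats.DEFAULT_Q_CAP)
        assert capped.iloc[0]

    def test_zero_variance_bin_inherits_family_maximum(self):
        # bin 0 constant (zero variance), bin 1 with variance
        row = [5, 5, 5, 5, 2, 4, 4, 6]
        m = _matrix([row])
        bins = [
            stats.GenomeBin(0, 0, 1, np.arange(4), 4),
            stats.GenomeBin(1, 1, 2, np.arange(4, 8), 4),
        ]
        q_fb, Q, capped = stats.q_statistic(m, bins)
        assert q_fb.iloc[0, 0] == pytest.approx(math.log(2))
        assert not capped.iloc[0]
        # both bins weighted 4*4/32 = 0.5; both contribute ln 2
        assert Q.iloc[0] == pytest.approx(math.log(2))

    def test_large_poisson_sample_is_near_zero(self, rng):
        m = _matrix([rng.poisson(20.0, size=2000)])
        _, Q, _ = stats.q_statistic(m, _one_bin(2000))
        assert abs(Q.iloc[0]) < 0.15


class TestOccurrenceAndTransferFraction:
    def test_occurrence_fractions(self):
        m = _matrix([[1, 2, 3, 4], [0, 0, 0, 0], [1, 0, 2, 0]])
        O_f, O_count = stats.occurrence(m)
        assert list(O_f) == [1.0, 0.0, 0.5]
        assert list(O_count) == [4, 0, 2]

    def test_h_index_arithmetic(self):
        m = _matrix([[2, 4], [3, 3], [5, 0]])
        h = _matrix([[1, 1], [0, 0], [5, 0]])
        H = stats.h_index(m, h)
        assert H.iloc[0] == pytest.approx(0.375)  # (1/2)(0.5 + 0.25)
        assert H.iloc[1] == 0.0
        assert H.iloc[2] == 1.0

    def test_h_index_never_present_is_missing(self):
        m = _matrix([[0, 0]])
        H = stats.h_index(m, _matrix([[0, 0]]))
        assert np.isnan(H.iloc[0])

    def test_excess_transfers_clipped_with_warning(self):
        m = _matrix([[2, 2]])
        h = _matrix([[5, 2]])
        with pytest.warns(UserWarning, match="clipped"):
            H = stats.h_index(m, h)
        assert H.iloc[0] == 1.0

    def test_misaligned_tables_rejected(self):
        m = _matrix([[1, 2]])
        h = _matrix([[1, 2]], gen_prefix="x")
        with pytest.raises(ValueError):
            stats.h_index(m, h)


class TestBinnedTrend:
    def test_constant_y(self):
        out = stats.binned_trend([0.1, 0.5, 0.9], [2.0, 2.0, 2.0], 3)
        assert (out["mean_y"].dropna() == 2.0).all()

    def test_identity_two_bins(self):
        out = stats.binned_trend([0.5, 1.5], [0.5, 1.5], 2)
        assert list(out["mean_y"]) == [0.5, 1.5]

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            stats.binned_trend([1.0], [1.0], 0)
        with pytest.raises(ValueError):
            stats.binned_trend([1.0, 2.0], [1.0], 2)


class TestBruteForceAgreement:
    def test_random_small_instances_match_exactly(self):
        # vectorised L1/Q/w against plain-loop recomputation from raw counts
        rng = np.random.default_rng(123)
        for _ in range(20):
            counts = rng.poisson(rng.uniform(0.5, 8.0), size=(6, 20))
            m = _matrix(counts)
            bins = stats.build_bins(
                stats.genome_sizes(m),
                width=rng.uniform(5, 40),
                step=rng.uniform(2, 10),
                min_bin=3,
            )
            if not bins:
                continue
            _, w = stats.sampling_weights(m, bins)
            _, L = stats.l1_statistic(m, bins)
            _, Q, _ = stats.q_statistic(m, bins)
            oracle = conftest.brute_force_family_stats(counts, bins)
            for f, (wf, lf, qf) in enumerate(oracle):
                assert w.iloc[f] == pytest.approx(wf, abs=1e-12)
                if math.isnan(lf):
                    assert np.isnan(L.iloc[f]) and np.isnan(Q.iloc[f])
                else:
                    assert L.iloc[f] == pytest.approx(lf, abs=1e-12)
                    assert Q.iloc[f] == pytest.approx(qf, abs=1e-12)


class TestPlantedClassBehaviour:
    def _flat_spec(self, fams, n_genomes, seed=5):
        return synth.EnsembleSpec(
            n_genomes=n_genomes,
            families=tuple(fams),
            n_clades=1,
            size_range=(1.0, 1.0),
            seed=seed,
        )

    def test_poisson_families_have_small_q_and_l(self):
        fams = [
            synth.FamilySpec(f"P{i}", "poisson", lam=lam)
            for i, lam in enumerate(np.linspace(5, 30, 15))
        ]
        m, _ = synth.generate_ensemble(self._flat_spec(fams, 1000))
        table, _ = stats.compute_family_stats(m, min_bin=200)
        assert (table["Q_f"].abs() < 0.15).all()
        assert (table["L_f"] < 0.1).all()

    def test_overdispersed_families_match_minus_log_dispersion(self):
        # var/mean = 1 + p_d/p_h = 10  =>  Q ~ -ln(10).  Lambda is kept high
        # enough that the NB mass at zero is negligible: natural absences
        # lower n_b^+ and hence shrink the weighted sum Q_f toward zero.
        fams = [
            synth.FamilySpec(f"O{i}", "overdispersed", lam=lam, dispersion=10.0)
            for i, lam in enumerate(np.linspace(20, 40, 10))
        ]
        m, _ = synth.generate_ensemble(self._flat_spec(fams, 1000))
        table, _ = stats.compute_family_stats(m, min_bin=200)
        assert (np.abs(table["Q_f"] + math.log(10)) < 0.15).all()

    def test_peaked_families_exceed_unit_q(self):
        fams = [
            synth.FamilySpec(f"K{i}", "peaked", k=k, eps=0.1)
            for i, k in enumerate(range(3, 9))
        ]
        m, _ = synth.generate_ensemble(self._flat_spec(fams, 1000))
        table, _ = stats.compute_family_stats(m, min_bin=200)
        assert (table["Q_f"] > 1.0).all()

    def test_weight_tracks_occurrence_but_q_does_not(self):
        # one dominant bin; classes and occurrence planted independently
        rng = np.random.default_rng(11)
        fams = [
            synth.FamilySpec(
                f"F{i}",
                ("poisson", "overdispersed")[i % 2],
                lam=10.0,
                dispersion=10.0,
                occurrence=float(rng.uniform(0.3, 1.0)),
            )
            for i in range(60)
        ]
        m, _ = synth.generate_ensemble(self._flat_spec(fams, 400))
        table, _ = stats.compute_family_stats(
            m, include_zeros=False, min_bin=50
        )
        O = table["O_f"]
        r_w = np.corrcoef(table["w_f"], O)[0, 1]
        assert r_w > 0.9
        ok = table["Q_f"].notna()
        r_q = np.corrcoef(table.loc[ok, "Q_f"], O[ok])[0, 1]
        assert abs(r_q) < 0.2
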