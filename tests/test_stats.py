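"""Summation-partition statistics against the brute-force oracle and by hand."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laspa import (
    CarrierStructure,
    LocalAncestry,
    NoRareVariantsError,
    build_carriers,
    compute_I1,
    compute_IA,
)

from _oracle import oracle_I1, oracle_IA, random_instance


def make_la(labels):
    labels = np.asarray(labels, dtype=int)
    J = int(labels.max())
    return LocalAncestry(
        labels=labels,
        n_clusters=J,
        cluster_sizes=np.bincount(labels, minlength=J + 1)[1:],
        pc_scores=np.zeros((len(labels), 0)),
    )


def carriers_from_sets(n, sets):
    K = len(sets)
    d = np.zeros((n, K), dtype=np.int8)
    for i, s in enumerate(sets):
        d[list(s), i] = 1
    return build_carriers(d)


class TestWorkedExamples:
    """Tiny regions small enough to evaluate the formulas by hand."""

    y = np.array([2.0, 0.0, -2.0, 4.0, -4.0])  # mean exactly 0

    def test_I1_two_variants(self):
        # variant A carried by subjects {0,1}: 2^2 * 1^2 = 4
        # variant B carried by subject {3}:   1^2 * 4^2 = 16
        c = carriers_from_sets(5, [{0, 1}, {3}])
        assert compute_I1(self.y, c) == pytest.approx(20.0, abs=1e-12)
        assert oracle_I1(self.y, [{0, 1}, {3}]) == pytest.approx(20.0, abs=1e-12)

    def test_partition_changes_the_statistic(self):
        # one variant carried by {0, 3}: marginal term 2^2 * 3^2 = 36,
        # but split across clusters {0,1,2} | {3,4}: 1*4 + 1*16 = 20
        c = carriers_from_sets(5, [{0, 3}])
        la = make_la([1, 1, 1, 2, 2])
        stats = compute_IA(self.y, c, la)
        assert stats.I1 == pytest.approx(36.0, abs=1e-12)
        assert stats.IA == pytest.approx(20.0, abs=1e-12)
        assert oracle_IA(self.y, [{0, 3}], [1, 1, 1, 2, 2], 2) == pytest.approx(20.0)
        assert stats.per_cluster == pytest.approx([4.0, 16.0])

    def test_every_carrier_mean_at_overall_mean_gives_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])  # mean 0
        c = carriers_from_sets(4, [{0, 1}, {2, 3}])
        assert compute_I1(y, c) == 0.0

    def test_variant_carried_by_everyone_contributes_zero(self):
        c = carriers_from_sets(5, [set(range(5))])
        assert compute_I1(self.y, c) == 0.0


class TestCarrierStructure:
    def test_homozygote_counts_once(self):
        c = build_carriers(np.array([[0], [1], [2], [0]], dtype=np.int8))
        assert c.n_i.tolist() == [2]
        assert c.carrier_sets()[0].tolist() == [1, 2]

    def test_zero_and_empty(self):
        c = build_carriers(np.zeros((4, 1), dtype=np.int8))
        assert c.n_i.tolist() == [0]
        empty = build_carriers(np.zeros((4, 0), dtype=np.int8))
        assert empty.K == 0
        with pytest.raises(NoRareVariantsError):
            compute_I1(np.zeros(4), empty)
        with pytest.raises(NoRareVariantsError):
            compute_IA(np.zeros(4), empty, make_la([1, 1, 1, 1]))

    def test_zero_carrier_variant_contributes_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        with_empty = carriers_from_sets(3, [{0}, set()])
        without = carriers_from_sets(3, [{0}])
        assert compute_I1(y, with_empty) == compute_I1(y, without)


class TestOracleAgreement:
    def test_thousand_random_instances(self):
        """Both statistics match the double-loop oracle to 1e-10 relative."""
        rng = np.random.default_rng(424242)
        for _ in range(1000):
            y, dosages, labels, J = random_instance(rng)
            c = build_carriers(dosages)
            la = LocalAncestry(
                labels=labels,
                n_clusters=J,
                cluster_sizes=np.bincount(labels, minlength=J + 1)[1:],
                pc_scores=np.zeros((len(labels), 0)),
            )
            sets = c.carrier_sets()
            assert compute_I1(y, c) == pytest.approx(
                oracle_I1(y, sets), rel=1e-10, abs=1e-12
            )
            assert compute_IA(y, c, la).IA == pytest.approx(
                oracle_IA(y, sets, labels, J), rel=1e-10, abs=1e-12
            )

    def test_allele_count_mode_matches_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            y, dosages, labels, J = random_instance(rng)
            c = build_carriers(dosages)
            la = LocalAncestry(
                labels, J, np.bincount(labels, minlength=J + 1)[1:], np.zeros((len(labels), 0))
            )
            sets = c.carrier_sets()
            w = dosages.sum(axis=0)
            assert compute_I1(y, c, mode="allele") == pytest.approx(
                oracle_I1(y, sets, weights=w), rel=1e-10, abs=1e-12
            )
            assert compute_IA(y, c, la, mode="allele").IA == pytest.approx(
                oracle_IA(y, sets, labels, J, dosages=dosages, mode="allele"),
                rel=1e-10,
                abs=1e-12,
            )


class TestInvariances:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_single_cluster_collapses_to_I1(self, seed):
        rng = np.random.default_rng(seed)
        y, dosages, _, _ = random_instance(rng)
        c = build_carriers(dosages)
        la = make_la(np.ones(len(y), dtype=int))
        assert compute_IA(y, c, la).IA == compute_I1(y, c)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_subject_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        y, dosages, labels, J = random_instance(rng)
        c = build_carriers(dosages)
        la = LocalAncestry(
            labels, J, np.bincount(labels, minlength=J + 1)[1:], np.zeros((len(labels), 0))
        )
        perm = rng.permutation(len(y))
        c2 = build_carriers(dosages[perm])
        la2 = LocalAncestry(
            labels[perm], J, np.bincount(labels, minlength=J + 1)[1:], np.zeros((len(y), 0))
        )
        s1 = compute_IA(y, c, la)
        s2 = compute_IA(y[perm], c2, la2)
        assert s2.I1 == pytest.approx(s1.I1, rel=1e-10)
        assert s2.IA == pytest.approx(s1.IA, rel=1e-10)

    def test_cluster_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        y, dosages, _, _ = random_instance(rng)
        n = len(y)
        labels = rng.integers(1, 3, size=n)
        c = build_carriers(dosages)
        swapped = np.where(labels == 1, 2, 1)
        ia1 = compute_IA(y, c, make_la(labels)).IA
        ia2 = compute_IA(y, c, make_la(swapped)).IA
        assert ia2 == pytest.approx(ia1, rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_phenotype_scaling_is_quadratic(self, seed, scale):
        rng = np.random.default_rng(seed)
        y, dosages, labels, J = random_instance(rng)
        c = build_carriers(dosages)
        la = LocalAncestry(
            labels, J, np.bincount(labels, minlength=J + 1)[1:], np.zeros((len(y), 0))
        )
        base = compute_IA(y, c, la)
        scaled = compute_IA(scale * y, c, la)
        assert scaled.I1 == pytest.approx(scale**2 * base.I1, rel=1e-9)
        assert scaled.IA == pytest.approx(scale**2 * base.IA, rel=1e-9)

    def test_carriers_confined_to_one_cluster(self):
        y = np.array([1.0, 2.0, -1.5, 0.5, 3.0, -5.0])
        c = carriers_from_sets(6, [{0, 1}])
        la = make_la([1, 1, 2, 2, 3, 3])
        stats = compute_IA(y, c, la)
        assert stats.per_cluster[1] == 0.0
        assert stats.per_cluster[2] == 0.0
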