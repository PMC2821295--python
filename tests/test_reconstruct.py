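"""Data-set building, distances, NJ/PNJ, bootstrap."""

import numpy as np
import pytest

import its2sim as it
from its2sim.models import transition_matrix
from its2sim.reconstruct import (
    CharacterAlignment,
    DistanceMatrix,
    ModelDistance,
    bootstrap_support,
    build_doubled_set,
    build_structure_set,
    distance_matrix,
    gtr_distance,
    model_distance,
    neighbor_joining,
    profile_neighbor_joining,
)
from its2sim.structures import AnnotatedSequence

from conftest import random_binary_tree


def _jc_pair(rng, t, n):
    """A pair of rows simulated under Jukes-Cantor at distance t."""
    a = rng.integers(0, 4, n)
    p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
    stay = rng.random(n) < p_same
    shift = rng.integers(1, 4, n)
    b = np.where(stay, a, (a + shift) % 4)
    return a, b


class TestDoubledSet:
    def test_column_count_doubles(self, ancestor, bundle):
        tree = it.generate_reference_tree(10, 0.1)
        s1 = it.simulate_set(tree, ancestor, bundle, seed=1)
        s2 = it.simulate_set(tree, ancestor, bundle, seed=2)
        aln = build_doubled_set(s1, s2)
        assert aln.n_columns == 2 * len(ancestor)
        assert aln.n_taxa == 10

    def test_self_concatenation_preserves_distance(self, ancestor, bundle):
        tree = it.generate_reference_tree(10, 0.1)
        s1 = it.simulate_set(tree, ancestor, bundle, seed=1)
        single = CharacterAlignment.from_sequences(s1)
        doubled = build_doubled_set(s1, s1)
        d1 = gtr_distance(single.data[0], single.data[1], k=4)
        d2 = gtr_distance(doubled.data[0], doubled.data[1], k=4)
        assert d2 == pytest.approx(d1, abs=1e-10)

    def test_taxon_mismatch_rejected(self, ancestor, bundle):
        tree = it.generate_reference_tree(10, 0.1)
        s1 = it.simulate_set(tree, ancestor, bundle, seed=1)
        bad = [AnnotatedSequence("x" + s.label, s.seq, s.structure) for s in s1]
        with pytest.raises(ValueError, match="labels"):
            build_doubled_set(s1, bad)


class TestGtrDistance:
    def test_identical_rows_zero(self):
        row = np.random.default_rng(0).integers(0, 4, 300)
        assert gtr_distance(row, row, k=4) == 0.0

    def test_jc_parameter_recovery(self):
        """100,000 sites at true distance 0.2: both the logdet estimator
        and the closed-form JC correction recover it within 0.01."""
        rng = np.random.default_rng(42)
        a, b = _jc_pair(rng, 0.2, 100000)
        d = gtr_distance(a, b, k=4)
        p = (a != b).mean()
        jc = -0.75 * np.log(1 - 4 * p / 3)
        assert abs(d - 0.2) < 0.01
        assert d == pytest.approx(jc, abs=2e-3)

    def test_unrelated_rows_saturate_at_cap(self):
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 4, 500), rng.integers(0, 4, 500)
        dm = distance_matrix(
            CharacterAlignment(("a", "b"), np.vstack([a, b]).astype(np.int8), it.NT_ALPHABET)
        )
        assert dm.saturated[0, 1]
        assert dm.values[0, 1] == 10.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            gtr_distance(np.array([], dtype=int), np.array([], dtype=int), k=4)

    def test_logdet_agrees_with_jc_across_grid(self, bundle):
        """Simulated under JC across the branch-length grid, the estimator
        tracks the analytic JC correction within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        for t in (0.05, 0.15, 0.3, 0.45):
            a, b = _jc_pair(rng, t, 20000)
            d = gtr_distance(a, b, k=4)
            p = (a != b).mean()
            jc = -0.75 * np.log(1 - 4 * p / 3)
            assert d == pytest.approx(jc, abs=5e-3)


class TestModelDistance:
    def test_equals_jc_closed_form(self, jc4):
        rng = np.random.default_rng(5)
        a, b = _jc_pair(rng, 0.25, 50000)
        d = model_distance(a, b, jc4)
        p = (a != b).mean()
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * p / 3), abs=1e-6)

    def test_identical_rows_zero(self, jc4):
        row = np.random.default_rng(0).integers(0, 4, 200)
        assert model_distance(row, row, jc4) == 0.0

    def test_saturated_at_cap(self, jc4):
        # data at stationarity (uniform pair counts): the likelihood keeps
        # increasing in t, so the estimate is capped and flagged
        counts = np.full((4, 4), 10.0)
        d, sat = ModelDistance(jc4).distances(counts)
        assert sat and d == 10.0

    def test_recovery_under_nonuniform_model(self):
        """ML under the true (non-JC) model recovers the branch length."""
        rng = np.random.default_rng(7)
        from conftest import random_gtr

        m = random_gtr(rng)
        t_true = 0.3
        P = transition_matrix(m, t_true)
        n = 60000
        a = rng.choice(4, size=n, p=m.frequencies)
        u = rng.random(n)
        b = (u[:, None] > np.cumsum(P[a], axis=1)[:, :-1]).sum(axis=1)
        assert model_distance(a, b, m) == pytest.approx(t_true, abs=0.02)


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        """Enumeration oracle: distances from a known quartet tree with
        internal edge 0.1 — NJ must recover topology and branch lengths."""
        # tree: (a:0.1, b:0.2)--0.15--(c:0.3, d:0.05)
        labels = ("a", "b", "c", "d")
        la, lb, lc, ld, lm = 0.1, 0.2, 0.3, 0.05, 0.15
        d = np.zeros((4, 4))
        d[0, 1] = la + lb
        d[0, 2] = la + lm + lc
        d[0, 3] = la + lm + ld
        d[1, 2] = lb + lm + lc
        d[1, 3] = lb + lm + ld
        d[2, 3] = lc + ld
        d = d + d.T
        tree = neighbor_joining(DistanceMatrix(labels, d, np.zeros((4, 4), bool)))
        assert tree.bipartitions() == {frozenset({"c", "d"})}
        pl = tree.path_lengths()
        for (x, y), expected in {
            ("a", "b"): la + lb,
            ("c", "d"): lc + ld,
            ("a", "c"): la + lm + lc,
        }.items():
            assert pl[(x, y)] == pytest.approx(expected, abs=1e-12)

    def test_recovers_random_additive_trees(self):
        """NJ consistency: 100 seeded random trees (n <= 10), additive
        input distances, RF must be 0 every time."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 11))
            true = random_binary_tree(rng, n)
            pl = true.path_lengths()
            labels = tuple(sorted(true.leaf_labels()))
            d = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pl[(a, labels[j])]
            rec = neighbor_joining(DistanceMatrix(labels, d, np.zeros((n, n), bool)))
            assert it.rf_distance(rec, true) == 0

    def test_tie_break_deterministic(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        labels = tuple("abcde")
        t1 = neighbor_joining(DistanceMatrix(labels, d, np.zeros((n, n), bool)))
        t2 = neighbor_joining(DistanceMatrix(labels, d, np.zeros((n, n), bool)))
        assert t1.to_newick() == t2.to_newick()

    def test_nonsymmetric_rejected(self):
        d = np.zeros((4, 4))
        d[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c", "d"), d, np.zeros((4, 4), bool))

    def test_agrees_with_dendropy_nj(self, ancestor, bundle):
        """Independent oracle: dendropy's NJ on the same matrix gives the
        same topology (away from ties)."""
        import dendropy

        tree = it.generate_reference_tree(10, 0.15)
        leaves = it.simulate_set(tree, ancestor, bundle, seed=21)
        aln = CharacterAlignment.from_sequences(leaves)
        dm = distance_matrix(aln, model=bundle.nucleotide)
        mine = neighbor_joining(dm)
        csv = "," + ",".join(dm.labels) + "\n"
        for i, lab in enumerate(dm.labels):
            csv += lab + "," + ",".join(str(x) for x in dm.values[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        theirs_str = pdm.nj_tree().as_string(schema="newick").replace("'", "")
        theirs = it.PhyloTree.from_newick(theirs_str)
        assert it.rf_distance(mine, theirs) == 0


class TestProfileNJ:
    def test_threshold_validation(self, ancestor, bundle):
        tree = it.generate_reference_tree(10, 0.1)
        aln = CharacterAlignment.from_sequences(
            it.simulate_set(tree, ancestor, bundle, seed=1)
        )
        with pytest.raises(ValueError):
            profile_neighbor_joining(aln, support_threshold=1.01)
        with pytest.raises(ValueError):
            profile_neighbor_joining(aln, support_threshold=0.5)

    def test_no_supported_clade_equals_plain_nj(self):
        """Random data with no phylogenetic signal: no clade reaches the
        threshold, so PNJ output matches plain NJ."""
        rng = np.random.default_rng(13)
        data = rng.integers(0, 4, size=(6, 120)).astype(np.int8)
        aln = CharacterAlignment(tuple("abcdef"), data, it.NT_ALPHABET)
        pnj = profile_neighbor_joining(aln, support_threshold=1.0, n_replicates=30, seed=1)
        nj = neighbor_joining(distance_matrix(aln))
        assert it.rf_distance(pnj, nj) == 0

    def test_strong_signal_matches_nj(self, ancestor, bundle):
        """Clean data from a tree with long internal edges: PNJ condenses
        clades but returns the same topology as NJ."""
        tree = it.generate_reference_tree(10, 0.08)
        leaves = it.simulate_set(tree, ancestor, bundle, seed=33)
        aln = CharacterAlignment.from_sequences(leaves)
        pnj = profile_neighbor_joining(aln, support_threshold=0.95, n_replicates=50, seed=2)
        nj = neighbor_joining(distance_matrix(aln))
        assert set(pnj.leaf_labels()) == set(nj.leaf_labels())
        assert it.rf_distance(pnj, nj) == 0


class TestBootstrap:
    def test_unanimous_signal_gives_full_support(self):
        """Columns that perfectly split the taxa: resampling cannot break
        the signal, all supports 100."""
        # two clades of 3 taxa, 60 columns each fixed within clades
        rng = np.random.default_rng(17)
        a = rng.integers(0, 2, 90)
        data = np.vstack([a, a, a, 3 - a, 3 - a, 3 - a]).astype(np.int8)
        # perturb single taxa slightly so distances differ but splits hold
        aln = CharacterAlignment(tuple("abcdef"), data, it.NT_ALPHABET)
        tree, sup = bootstrap_support(aln, n_replicates=50, seed=5)
        assert len(sup) == 6 - 3
        assert all(v == 100.0 for v in sup.values())

    def test_support_count_and_range(self, ancestor, bundle):
        tree0 = it.generate_reference_tree(10, 0.2)
        aln = CharacterAlignment.from_sequences(
            it.simulate_set(tree0, ancestor, bundle, seed=8)
        )
        tree, sup = bootstrap_support(aln, n_replicates=40, seed=9)
        assert len(sup) == 10 - 3
        assert all(0.0 <= v <= 100.0 for v in sup.values())

    def test_seed_reproducibility_and_stability(self, ancestor, bundle):
        tree0 = it.generate_reference_tree(10, 0.15)
        aln = CharacterAlignment.from_sequences(
            it.simulate_set(tree0, ancestor, bundle, seed=10)
        )
        _, s1 = bootstrap_support(aln, n_replicates=100, seed=11)
        _, s2 = bootstrap_support(aln, n_replicates=100, seed=11)
        assert s1 == s2
        _, s3 = bootstrap_support(aln, n_replicates=100, seed=12)
        for bp, v in s1.items():
            # binomial sampling error at n=100
            se = np.sqrt(max(v / 100 * (1 - v / 100), 0.0025) / 100) * 100
            assert abs(v - s3[bp]) <= 5 * se + 1e-9

    def test_structure_columns_resampled_as_units(self, ancestor, bundle):
        """12-state bootstrap keeps base and role together: encoding then
        resampling equals resampling then encoding."""
        tree0 = it.generate_reference_tree(6, 0.2)
        leaves = it.simulate_set(tree0, ancestor, bundle, seed=14)
        structured = build_structure_set(leaves, ancestor)
        aln = CharacterAlignment.from_pseudoproteins(structured)
        cols = np.random.default_rng(15).integers(0, aln.n_columns, aln.n_columns)
        sub = aln.data[:, cols]
        assert sub.shape == aln.data.shape  # both base and role travel
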