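"""Composition vectors, Euclidean composition distances, p-distances, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degenphy import (
    CodonAlignment,
    SimulationConfig,
    composition_distance,
    composition_distance_matrix,
    composition_vector,
    flag_heterogeneous_taxa,
    pdistance_matrix,
    sim_codon_alignment,
)
from degenphy.composition import (
    CompositionVector,
    composition_bootstrap,
    composition_bootstrap_splits,
    composition_tree,
)
from degenphy.consensus import edge_supports
from degenphy.distance_trees import tree_length


class TestCompositionVector:
    def test_uniform(self):
        assert composition_vector("ACGT").proportions == (0.25, 0.25, 0.25, 0.25)

    def test_exclude_rule(self):
        v = composition_vector("AAYG", "exclude")
        assert v.n_counted == 3
        assert v.proportions == pytest.approx((2 / 3, 0, 1 / 3, 0))

    def test_fractional_rule(self):
        v = composition_vector("AAYG", "fractional")
        assert v.n_counted == 4
        assert v.proportions == pytest.approx((0.5, 0.125, 0.25, 0.125))

    def test_gaps_never_counted(self):
        v = composition_vector("A-?T")
        assert v.n_counted == 2

    def test_empty(self):
        assert composition_vector("--??").n_counted == 0


class TestCompositionDistance:
    def test_identical_zero(self):
        v = composition_vector("ACGTACGT")
        assert composition_distance(v, v) == 0.0

    def test_max_sqrt2(self):
        a = CompositionVector((1, 0, 0, 0), 10)
        b = CompositionVector((0, 1, 0, 0), 10)
        assert composition_distance(a, b) == pytest.approx(math.sqrt(2))

    def test_hand_value(self):
        a = CompositionVector((0.3, 0.2, 0.2, 0.3), 10)
        b = CompositionVector((0.25, 0.25, 0.25, 0.25), 10)
        assert composition_distance(a, b) == pytest.approx(0.1)

    def test_empty_vector_rejected(self):
        empty = CompositionVector((0, 0, 0, 0), 0)
        with pytest.raises(ValueError):
            composition_distance(empty, empty)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=12, max_size=12))
    def test_metric_properties(self, raw):
        vs = []
        for i in range(3):
            p = np.array(raw[4 * i : 4 * i + 4])
            vs.append(CompositionVector(tuple(p / p.sum()), 1))
        a, b, c = vs
        dab = composition_distance(a, b)
        assert dab == pytest.approx(composition_distance(b, a))
        assert dab <= math.sqrt(2) + 1e-12
        assert dab <= composition_distance(a, c) + composition_distance(c, b) + 1e-12


class TestDistanceMatrices:
    def test_identical_sequences_zero_matrix(self):
        aln = CodonAlignment(("a", "b", "c"), ("ACGTAA",) * 3)
        D = composition_distance_matrix(aln)
        assert np.allclose(D.values, 0.0)

    def test_permutation_consistency(self):
        aln = sim_codon_alignment(SimulationConfig(n_taxa=5, n_codons=50, seed=11))
        D = composition_distance_matrix(aln)
        perm = list(aln.taxa[::-1])
        D2 = composition_distance_matrix(aln.subset(perm))
        for i, a in enumerate(perm):
            for j, b in enumerate(perm):
                assert D2.values[i, j] == pytest.approx(D[a, b])

    def test_matches_bruteforce_loop(self):
        aln = sim_codon_alignment(SimulationConfig(n_taxa=10, n_codons=60, seed=13))
        D = composition_distance_matrix(aln)
        for i, a in enumerate(aln.taxa):
            for j, b in enumerate(aln.taxa):
                va = composition_vector(aln.sequences[i])
                vb = composition_vector(aln.sequences[j])
                expected = math.sqrt(
                    sum((x - y) ** 2 for x, y in zip(va.proportions, vb.proportions))
                )
                assert D.values[i, j] == pytest.approx(expected)

    def test_pdistance_examples(self):
        aln = CodonAlignment(("a", "b", "c"), ("AAAA", "AATT", "AAAA"))
        D = pdistance_matrix(aln)
        assert D["a", "b"] == pytest.approx(0.5)
        assert D["a", "c"] == 0.0

    def test_pdistance_matches_bruteforce(self):
        aln = sim_codon_alignment(SimulationConfig(n_taxa=6, n_codons=40, seed=17))
        D = pdistance_matrix(aln)
        for i in range(6):
            for j in range(6):
                num = den = 0
                for x, y in zip(aln.sequences[i], aln.sequences[j]):
                    if x in "ACGT" and y in "ACGT":
                        den += 1
                        num += x != y
                assert D.values[i, j] == pytest.approx(num / den if den else 0.0)

    def test_zero_countable_sites_named(self):
        aln = CodonAlignment(("a", "b", "c"), ("AAA", "???", "AAA"))
        with pytest.raises(ValueError, match="'b'"):
            composition_distance_matrix(aln)


class TestCompositionBootstrap:
    def test_reproducible_and_order_invariant(self):
        aln = sim_codon_alignment(SimulationConfig(n_taxa=6, n_codons=80, seed=19))
        s1 = composition_bootstrap_splits(aln, 50, seed=4)
        s2 = composition_bootstrap_splits(aln, 50, seed=4)
        assert s1 == s2
        s3 = composition_bootstrap_splits(aln.subset(list(aln.taxa[::-1])), 50, seed=4)
        assert s3 == s1  # canonical taxon order inside

    def test_supports_in_range_and_mapped(self):
        aln = sim_codon_alignment(SimulationConfig(n_taxa=6, n_codons=80, seed=23))
        tree = composition_bootstrap(aln, 40, seed=1)
        supports = edge_supports(tree)
        assert supports and all(0 <= v <= 100 for v in supports.values())

    def test_two_composition_clusters_get_full_support(self):
        rng = np.random.default_rng(0)
        # two GC-rich, six AT-rich taxa; long sequences
        def seq(gc):
            return "".join(rng.choice(list("GC") if rng.random() < gc else list("AT"))
                           for _ in range(900))

        taxa = tuple(f"t{i}" for i in range(8))
        # keep the smallest label out of the pair: canonical splits are the
        # side away from it
        seqs = tuple(seq(0.8) if i in (1, 2) else seq(0.2) for i in range(8))
        aln = CodonAlignment(taxa, seqs)
        freqs = composition_bootstrap_splits(aln, 100, seed=2)
        assert freqs.get(frozenset({"t1", "t2"}), 0.0) >= 99.0


class TestFlagHeterogeneous:
    def test_identical_compositions_empty(self):
        aln = CodonAlignment(tuple("abcd"), ("ACGTACGTA",) * 4)
        assert flag_heterogeneous_taxa(aln) == []

    def test_planted_outlier_flagged_and_length_drops(self):
        rng = np.random.default_rng(1)
        # one extreme outlier among n taxa has z at most (n-1)/sqrt(n), so a
        # z>3 flag needs n >= 11; 16 gives comfortable headroom
        n = 16
        taxa = tuple(f"t{i:02d}" for i in range(n))
        base = [
            "".join(rng.choice(list("ACGT"), p=[0.25, 0.25, 0.25, 0.25]))
            for _ in range(600)
        ]
        seqs = []
        for i in range(n):
            if i == 0:  # GC outlier
                seqs.append("".join(rng.choice(list("GC")) if rng.random() < 0.5
                                    else c for c in "".join(base)))
            else:
                s = list("".join(base))
                for k in rng.integers(0, 600, size=30):
                    s[k] = rng.choice(list("ACGT"))
                seqs.append("".join(s))
        aln = CodonAlignment(taxa, tuple(seqs))
        flagged = flag_heterogeneous_taxa(aln, method="centroid_z", threshold=3.0)
        assert flagged == ["t00"]
        before = tree_length(composition_tree(aln))
        after = tree_length(composition_tree(aln.subset(list(taxa[1:]))))
        assert after < before

    def test_tree_tail_count(self):
        aln = sim_codon_alignment(SimulationConfig(n_taxa=8, n_codons=60, seed=29))
        flagged = flag_heterogeneous_taxa(aln, method="tree_tail", threshold=2)
        assert len(flagged) == 2

    def test_bad_threshold(self):
        aln = sim_codon_alignment(SimulationConfig(n_taxa=4, n_codons=20, seed=31))
        with pytest.raises(ValueError):
            flag_heterogeneous_taxa(aln, threshold=0)
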