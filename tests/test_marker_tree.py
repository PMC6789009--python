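import io
import itertools

import dendropy
import numpy as np
import pytest
from skbio import TreeNode

from strainrecov import (
    ConfigError,
    RecoveryCategory,
    RelatednessCall,
    SampleVariantProfile,
    SnvCall,
    ZERO_NOISE,
    build_alignment,
    extract_marker_sequences,
    make_marker_regions,
    nj_tree,
    pid_distance,
    tree_wss_concordance,
)
from strainrecov.marker_tree import MarkerAlignment, distance_matrix, simulate_additive_distances
from strainrecov.recovery_patterns import FOUR_POINT_LAYOUT
from strainrecov.synthetic_cohort import build_cohort, plan_from_counts


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson–Foulds via dendropy (the independent oracle)."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestMarkerExtraction:
    def test_no_snvs_equals_reference_slice(self, small_reference):
        prof = SampleVariantProfile("s1", "spTest", [], small_reference.genome_length)
        seq, masked = extract_marker_sequences(prof, small_reference, [(100, 600)])
        assert seq == small_reference.sequence[100:600] and masked == 0

    def test_single_snv_substituted(self, small_reference):
        ref_base = small_reference.sequence[250]
        alt = "A" if ref_base != "A" else "G"
        prof = SampleVariantProfile(
            "s1", "spTest", [SnvCall(250, ref_base, alt, 30, 1.0)], small_reference.genome_length
        )
        seq, _ = extract_marker_sequences(prof, small_reference, [(100, 600)])
        assert seq[150] == alt
        assert seq[:150] == small_reference.sequence[100:250]

    def test_low_depth_position_masked_to_reference(self, small_reference):
        ref_base = small_reference.sequence[250]
        alt = "A" if ref_base != "A" else "G"
        prof = SampleVariantProfile(
            "s1", "spTest", [SnvCall(250, ref_base, alt, 2, 1.0)], small_reference.genome_length
        )
        seq, masked = extract_marker_sequences(prof, small_reference, [(100, 600)], min_depth=5)
        assert seq[150] == ref_base and masked == 1

    def test_region_outside_genome_rejected(self, small_reference):
        prof = SampleVariantProfile("s1", "spTest", [], small_reference.genome_length)
        with pytest.raises(ConfigError, match="outside"):
            extract_marker_sequences(prof, small_reference, [(9800, 10_400)])

    def test_same_planted_strain_gives_identical_markers(self):
        cohort = build_cohort(
            plan_from_counts({RecoveryCategory.PERSISTENT: 1}),
            FOUR_POINT_LAYOUT,
            ZERO_NOISE,
            seed=8,
            genome_length=10_000,
            n_snv=80,
        )
        tl = cohort.timelines[0]
        ref = cohort.references[tl.species_id]
        aln = build_alignment([tl.samples[l][0] for l in FOUR_POINT_LAYOUT.labels], ref)
        seqs = list(aln.sequences.values())
        assert all(s == seqs[0] for s in seqs)


class TestPidDistance:
    def test_identical_sequences(self):
        assert pid_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_ten_percent_mismatch(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        assert pid_distance(a, b) == pytest.approx(0.10)

    def test_gap_columns_excluded(self):
        assert pid_distance("AC-T", "ACG-") == 0.0  # only 2 comparable columns, both match

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ConfigError, match="comparable"):
            pid_distance("--", "AA")

    def test_matches_brute_force_count(self, rng):
        alphabet = np.array(list("ACGT-"))
        for _ in range(20):
            a = "".join(rng.choice(alphabet, size=60))
            b = "".join(rng.choice(alphabet, size=60))
            cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not cols:
                continue
            expected = 1.0 - sum(x == y for x, y in cols) / len(cols)
            assert pid_distance(a, b) == pytest.approx(expected)
            assert pid_distance(b, a) == pid_distance(a, b)  # semimetric symmetry


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(d, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_five_taxon_topology_recovered(self, rng):
        for _ in range(10):
            ids, d, true_newick = simulate_additive_distances(5, rng)
            est = nj_tree(d, ids)
            assert rf_distance(est.to_newick(), true_newick) == 0

    def test_patristic_distances_reproduce_additive_input(self, rng):
        ids, d, _ = simulate_additive_distances(6, rng)
        tree = nj_tree(d, ids)
        tip_ids, dmat = tree.tip_distances()
        order = [tip_ids.index(i) for i in ids]
        assert np.allclose(dmat[np.ix_(order, order)], d, atol=1e-9)

    def test_equal_distances_tie_broken_deterministically(self):
        d = np.ones((4, 4)) - np.eye(4)
        ids = ["a", "b", "c", "d"]
        n1 = nj_tree(d, ids).to_newick()
        n2 = nj_tree(d.copy(), list(ids)).to_newick()
        assert n1 == n2

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ConfigError, match="symmetric"):
            nj_tree(d, ["a", "b", "c"])

    def test_newick_round_trip_stable(self, rng):
        ids, d, _ = simulate_additive_distances(5, rng)
        nwk = nj_tree(d, ids).to_newick()
        reparsed = str(TreeNode.read(io.StringIO(nwk))).strip()
        assert str(TreeNode.read(io.StringIO(reparsed))).strip() == reparsed


class TestConcordance:
    @staticmethod
    def two_strain_setup():
        # samples 0,1 one strain; 2,3 another — tight clades, long bridge
        seqs = {
            "a1": "A" * 50,
            "a2": "A" * 49 + "C",
            "b1": "G" * 25 + "A" * 25,
            "b2": "G" * 25 + "A" * 24 + "C",
        }
        aln = MarkerAlignment("sp", seqs)
        ids, d = distance_matrix(aln)
        tree = nj_tree(d, ids)
        R, U = RelatednessCall.RELATED, RelatednessCall.UNRELATED
        calls = np.full((4, 4), None, dtype=object)
        rel_pairs = {(0, 1): R, (2, 3): R}
        for i, j in itertools.combinations(range(4), 2):
            calls[i, j] = calls[j, i] = rel_pairs.get((i, j), U)
        return tree, calls, ids

    def test_two_strain_cohort_fully_concordant(self):
        tree, calls, ids = self.two_strain_setup()
        assert tree_wss_concordance(tree, calls, ids) == 1.0

    def test_single_strain_everywhere_concordant(self):
        seqs = {f"s{i}": "A" * 50 for i in range(4)}
        ids, d = distance_matrix(MarkerAlignment("sp", seqs))
        tree = nj_tree(d, ids)
        calls = np.full((4, 4), RelatednessCall.RELATED, dtype=object)
        assert tree_wss_concordance(tree, calls, ids) == 1.0

    def test_shuffled_calls_give_chance_concordance(self, rng):
        # random sequences give tie-free distances, so the permutation null
        # splits pairs 3/3 around the median and sits at concordance 0.5
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=200)) for i in range(4)}
        ids, d = distance_matrix(MarkerAlignment("sp", seqs))
        tree = nj_tree(d, ids)
        R, U = RelatednessCall.RELATED, RelatednessCall.UNRELATED
        base_calls = [R, R, U, U, U, U]
        pairs = list(itertools.combinations(range(4), 2))
        values = []
        for _ in range(200):
            perm = rng.permutation(base_calls)
            shuffled = np.full((4, 4), None, dtype=object)
            for (i, j), c in zip(pairs, perm):
                shuffled[i, j] = shuffled[j, i] = c
            values.append(tree_wss_concordance(tree, shuffled, ids))
        assert np.mean(values) == pytest.approx(0.5, abs=0.08)

    def test_disjoint_sample_sets_rejected(self):
        tree, calls, ids = self.two_strain_setup()
        with pytest.raises(ConfigError):
            tree_wss_concordance(tree, calls, ["x1", "x2", "x3", "x4"])


def test_marker_regions_fit_and_spacing():
    regions = make_marker_regions(10_000, n_regions=10, region_length=500)
    assert len(regions) == 10
    assert all(e - s == 500 for s, e in regions)
    flat = sorted(p for r in regions for p in r)
    assert flat == [p for r in regions for p in r]  # non-overlapping, ordered
    with pytest.raises(ConfigError):
        make_marker_regions(4000, n_regions=10, region_length=500)
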