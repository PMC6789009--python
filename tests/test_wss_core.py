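import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainrecov import (
    ConfigError,
    CoverageProfile,
    CutoffTable,
    RecoveryCategory,
    SampleVariantProfile,
    SnvCall,
    WindowSpec,
    ZERO_NOISE,
    all_pairs,
    filter_heterogeneous,
    window_depth_mask,
    window_similarity,
    wss_score,
)
from strainrecov.recovery_patterns import FOUR_POINT_LAYOUT
from strainrecov.synthetic_cohort import (
    NoiseModel,
    build_cohort,
    plan_from_counts,
)
from strainrecov.wss_core import RelatednessCall

GENOME = 10_000


def simple_profile(snvs, sample="s1", species="spA", genome=GENOME, depth=30):
    """snvs: iterable of (position, alt) or (position, alt, alt_fraction)."""
    calls = []
    for t in sorted(snvs):
        pos, alt = t[0], t[1]
        af = t[2] if len(t) > 2 else 1.0
        ref = "A" if alt != "A" else "C"
        calls.append(SnvCall(pos, ref, alt, depth, af))
    return SampleVariantProfile(sample, species, calls, genome)


def uniform_cov(depth=10.0, genome=GENOME, bin_size=1000, sample="s1", species="spA"):
    n = -(-genome // bin_size)
    return CoverageProfile(sample, species, bin_size, np.full(n, depth), genome)


class TestHeterogeneityFilter:
    def test_half_half_locus_excluded(self):
        prof = simple_profile([(10, "G", 0.5)])
        assert len(filter_heterogeneous(prof)) == 0

    def test_fixed_locus_retained(self):
        prof = simple_profile([(10, "G", 1.0)])
        assert len(filter_heterogeneous(prof)) == 1

    def test_boundary_minor_fraction_retained(self):
        # minor fraction exactly 0.2: the rule excludes only strictly above
        prof = simple_profile([(10, "G", 0.8), (20, "G", 0.2)])
        assert len(filter_heterogeneous(prof)) == 2

    def test_enumeration_oracle(self, rng):
        fracs = rng.choice([0.9, 0.6], size=1000)
        prof = simple_profile([(i, "G", f) for i, f in enumerate(fracs)])
        kept = filter_heterogeneous(prof)
        assert len(kept) == int(np.sum(fracs == 0.9))


class TestWindowDepthMask:
    def test_uniform_depth_all_retained(self):
        retained, ca, cb = window_depth_mask(uniform_cov(10), uniform_cov(10))
        assert retained.all() and ca == 1.0 and cb == 1.0

    def test_zero_depth_sample_blocks_everything(self):
        retained, ca, cb = window_depth_mask(uniform_cov(10), uniform_cov(0))
        assert not retained.any() and ca == 1.0 and cb == 0.0

    def test_exactly_half_low_depth_retained(self):
        # 500 of each 1000 bp window at depth 0: not *more than* 50%, so kept
        depths = np.tile([0.0, 10.0], GENOME // 1000)
        cov = CoverageProfile("s", "spA", 500, depths, GENOME)
        retained, ca, _ = window_depth_mask(cov, uniform_cov(10))
        assert retained.all() and ca == 1.0

    def test_mismatched_genomes_rejected(self):
        with pytest.raises(ConfigError):
            window_depth_mask(uniform_cov(10), uniform_cov(10, genome=5000))

    def test_lowering_threshold_is_monotone(self, rng):
        depths = rng.integers(0, 12, size=GENOME // 500).astype(float)
        cov = CoverageProfile("s", "spA", 500, depths, GENOME)
        counts = []
        for thr in (8, 5, 2):
            spec = WindowSpec(low_depth_threshold=thr)
            retained, _, _ = window_depth_mask(cov, cov, spec)
            counts.append(retained.sum())
        assert counts == sorted(counts)


class TestWindowSimilarity:
    def test_identical_profiles_all_ones(self):
        prof = simple_profile([(100, "G"), (1500, "T"), (2500, "G")])
        sims = window_similarity(prof, prof, np.ones(10, bool))
        defined = [s.similarity for s in sims if s.n_union]
        assert defined == [1.0, 1.0, 1.0]

    def test_disjoint_profiles_all_zero(self):
        a = simple_profile([(100, "G"), (1500, "T")])
        b = simple_profile([(200, "G"), (1600, "T")], sample="s2")
        defined = [s.similarity for s in window_similarity(a, b, np.ones(10, bool)) if s.n_union]
        assert defined == [0.0, 0.0]

    def test_same_position_different_alt_not_shared(self):
        a = simple_profile([(100, "G")])
        b = simple_profile([(100, "T")], sample="s2")
        sims = [s for s in window_similarity(a, b, np.ones(10, bool)) if s.n_union]
        assert sims[0].n_shared == 0 and sims[0].n_union == 2

    def test_three_window_case_against_brute_force(self):
        # window 0: share both of 2; window 1: 1 of union 2; window 2: 0 of 1
        a = simple_profile([(10, "G"), (20, "T"), (1010, "G"), (1020, "T"), (2010, "G")])
        b = simple_profile([(10, "G"), (20, "T"), (1010, "G")], sample="s2")
        sims = [s.similarity for s in window_similarity(a, b, np.ones(10, bool)) if s.n_union]
        assert sims == [1.0, 0.5, 0.0]
        # brute-force whole-genome set oracle per window
        sa = {(c.position, c.alt_allele) for c in a.calls}
        sb = {(c.position, c.alt_allele) for c in b.calls}
        for w, expected in zip((0, 1, 2), sims):
            in_w = lambda s: {x for x in s if x[0] // 1000 == w}
            wa, wb = in_w(sa), in_w(sb)
            assert expected == len(wa & wb) / len(wa | wb)


class TestWssScore:
    CUTOFFS = CutoffTable({"spA": 0.8})

    def test_identical_profiles_related(self):
        prof = simple_profile([(100, "G"), (5100, "T")])
        res = wss_score(prof, prof, uniform_cov(10), uniform_cov(10), cutoffs=self.CUTOFFS)
        assert res.score == 1.0 and res.call is RelatednessCall.RELATED

    def test_low_coverage_indeterminate_regardless_of_score(self):
        prof = simple_profile([(100, "G")])
        depths = np.array([10.0] * 2 + [0.0] * 8)  # 20% of windows pass
        cov = CoverageProfile("s", "spA", 1000, depths, GENOME)
        res = wss_score(prof, prof, cov, uniform_cov(10), cutoffs=self.CUTOFFS)
        assert res.call is RelatednessCall.INDETERMINATE and np.isnan(res.score)

    def test_exactly_30_percent_coverage_is_indeterminate(self):
        depths = np.array([10.0] * 3 + [0.0] * 7)
        cov = CoverageProfile("s", "spA", 1000, depths, GENOME)
        prof = simple_profile([(100, "G")])
        res = wss_score(prof, prof, cov, uniform_cov(10), cutoffs=self.CUTOFFS)
        assert res.coverage_a == pytest.approx(0.3)
        assert res.call is RelatednessCall.INDETERMINATE

    def test_score_equal_to_cutoff_is_unrelated(self):
        a = simple_profile([(100, "G"), (200, "T")])
        b = simple_profile([(100, "G"), (300, "T")], sample="s2")
        # one window: shared 1 of union 3
        res = wss_score(
            a, b, uniform_cov(10), uniform_cov(10), cutoffs=CutoffTable({"spA": 1 / 3})
        )
        assert res.score == pytest.approx(1 / 3)
        assert res.call is RelatednessCall.UNRELATED

    def test_missing_cutoff_is_config_error(self):
        prof = simple_profile([(100, "G")])
        with pytest.raises(ConfigError, match="cut-off"):
            wss_score(prof, prof, uniform_cov(10), uniform_cov(10), cutoffs=CutoffTable({"spB": 0.5}))

    def test_empty_windows_not_counted_as_similarity_one(self):
        # identical pair in window 0, nothing anywhere else: score stays 1.0
        # but the empty retained windows are reported, not averaged in
        prof = simple_profile([(100, "G")])
        res = wss_score(prof, prof, uniform_cov(10), uniform_cov(10), cutoffs=self.CUTOFFS)
        assert res.score == 1.0 and res.n_zero_union == 9


@st.composite
def snv_sets(draw):
    positions = draw(
        st.lists(st.integers(0, GENOME - 1), min_size=1, max_size=60, unique=True)
    )
    return [
        (p, draw(st.sampled_from("ACGT".replace("A", "G"))), draw(st.sampled_from([1.0, 0.9, 0.5])))
        for p in positions
    ]


class TestProperties:
    @given(snv_sets(), snv_sets())
    def test_symmetry_and_range(self, sa, sb):
        a, b = simple_profile(sa), simple_profile(sb, sample="s2")
        cov = uniform_cov(10)
        cutoffs = CutoffTable({"spA": 0.5})
        r1 = wss_score(a, b, cov, cov, cutoffs=cutoffs)
        r2 = wss_score(b, a, cov, cov, cutoffs=cutoffs)
        if not np.isnan(r1.score):
            assert 0.0 <= r1.score <= 1.0
            assert r1.score == r2.score
        assert r1.call == r2.call

    @given(snv_sets())
    def test_reflexivity(self, sa):
        a = simple_profile(sa)
        cov = uniform_cov(10)
        res = wss_score(a, a, cov, cov, cutoffs=CutoffTable({"spA": 0.5}))
        if res.call is not RelatednessCall.INDETERMINATE:
            assert res.score == 1.0

    def test_oracle_equivalence_whole_genome_window(self, rng):
        # one genome-spanning window reduces the score to the global Jaccard index
        spec = WindowSpec(window_length=GENOME)
        for _ in range(25):
            sa = simple_profile(
                [(int(p), "G", float(rng.choice([1.0, 0.6]))) for p in rng.choice(GENOME, 40, replace=False)]
            )
            sb = simple_profile(
                [(int(p), "G", float(rng.choice([1.0, 0.6]))) for p in rng.choice(GENOME, 40, replace=False)],
                sample="s2",
            )
            res = wss_score(sa, sb, uniform_cov(10), uniform_cov(10), spec, CutoffTable({"spA": 0.5}))
            fa = {(c.position, c.alt_allele) for c in sa.calls if c.minor_fraction <= 0.2}
            fb = {(c.position, c.alt_allele) for c in sb.calls if c.minor_fraction <= 0.2}
            if fa | fb:
                assert res.score == len(fa & fb) / len(fa | fb)

    def test_dropout_degrades_same_strain_score_monotonically(self):
        means = []
        for dropout in (0.0, 0.05, 0.15):
            noise = NoiseModel(snv_dropout_rate=dropout, false_snv_rate=0.0)
            scores = []
            for seed in range(15):
                cohort = build_cohort(
                    plan_from_counts({RecoveryCategory.PERSISTENT: 1}),
                    FOUR_POINT_LAYOUT,
                    noise,
                    seed=seed,
                    genome_length=20_000,
                    n_snv=150,
                )
                tl = cohort.timelines[0]
                samples = [tl.samples[l] for l in FOUR_POINT_LAYOUT.labels]
                pw = all_pairs(samples, WindowSpec(), cohort.cutoffs)
                scores += [r.score for r in pw.results.values()]
            means.append(np.mean(scores))
        assert means[0] >= means[1] >= means[2]


class TestAllPairs:
    def test_pair_count(self):
        prof = simple_profile([(100, "G")])
        cov = uniform_cov(10)
        samples = [(prof.with_calls(prof.calls), cov) for _ in range(4)]
        pw = all_pairs(samples, cutoffs=CutoffTable({"spA": 0.5}))
        assert len(pw.results) == 6

    def test_calls_matrix_symmetric_none_diagonal(self):
        prof = simple_profile([(100, "G")])
        cov = uniform_cov(10)
        pw = all_pairs([(prof, cov)] * 3, cutoffs=CutoffTable({"spA": 0.5}))
        m = pw.calls()
        assert all(m[i, i] is None for i in range(3))
        assert (m[0, 1], m[1, 0]) == (RelatednessCall.RELATED,) * 2

    def test_zero_noise_cohort_matches_implied_matrix(self):
        plan = plan_from_counts({c: 1 for c in RecoveryCategory})
        cohort = build_cohort(plan, FOUR_POINT_LAYOUT, ZERO_NOISE, seed=5, genome_length=20_000, n_snv=150)
        from strainrecov import implied_relatedness

        for tl in cohort.timelines:
            samples = [tl.samples[l] for l in FOUR_POINT_LAYOUT.labels]
            pw = all_pairs(samples, cutoffs=cohort.cutoffs)
            expected = implied_relatedness(tl.scenario)
            got = pw.calls()
            for i, j in itertools.combinations(range(len(FOUR_POINT_LAYOUT)), 2):
                assert got[i, j] == expected[i, j], (tl.category, i, j)
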