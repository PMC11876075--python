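import itertools

import numpy as np
import pandas as pd
import pytest

from ridgemotif import Pwm, score_threshold
from ridgemotif.motif_catalog import (
    MotifGroup,
    PeakMotifMatrix,
    enrichment_filter,
    filter_expressed,
    group_motifs,
    member_occurrence_fractions,
    pick_representative,
    prevalence_filter,
    reverse_complement,
    scan_matrix,
    sequence_has_hit,
)


def enumeration_threshold(threshold, bg):
    """Independent oracle: enumerate all 4^L words on the integer score
    lattice, accumulate their null mass, and find the smallest achievable
    score with upper-tail mass <= the target p-value."""
    ints = threshold.int_scores
    L = ints.shape[0]
    mass = {}
    for word in itertools.product(range(4), repeat=L):
        s = sum(ints[i, b] for i, b in enumerate(word))
        p = 1.0
        for b in word:
            p *= bg[b]
        mass[s] = mass.get(s, 0.0) + p
    scores = sorted(mass)
    best = np.inf
    tail = 0.0
    for s in reversed(scores):
        tail += mass[s]
        if tail <= threshold.pvalue + 1e-15:
            best = s
    return best


def random_pwm(rng, L, name="M"):
    mat = rng.dirichlet(np.full(4, 0.3), size=L)
    return Pwm(name=name, matrix=mat)


class TestScoreThreshold:
    def test_one_mer_cannot_reach_1e4(self):
        pwm = Pwm("one", np.array([[1.0, 0, 0, 0]]))
        th = score_threshold(pwm, pvalue=1e-4)
        assert th.min_score == np.inf

    def test_uniform_pwm_matches_nothing(self):
        pwm = Pwm("flat", np.full((6, 4), 0.25))
        th = score_threshold(pwm, pvalue=1e-4)
        assert th.min_score == np.inf

    def test_consensus_pwm_matches_enumeration(self, consensus_pwm):
        bg = np.full(4, 0.25)
        th = score_threshold(consensus_pwm, bg, pvalue=1e-4)
        assert np.isfinite(th.min_score_int)
        assert th.min_score_int == enumeration_threshold(th, bg)

    @pytest.mark.parametrize("L", [2, 4, 6])
    def test_random_pwms_match_enumeration(self, rng, L):
        for rep in range(5):
            bg = rng.dirichlet(np.full(4, 5.0))
            pwm = random_pwm(rng, L, f"M{L}_{rep}")
            th = score_threshold(pwm, bg, pvalue=10 ** rng.uniform(-4, -1))
            assert th.min_score_int == enumeration_threshold(th, bg)

    def test_tail_invariant(self, rng):
        """P(score >= cutoff) <= p and the next lower achievable score
        would exceed p."""
        bg = np.full(4, 0.25)
        pwm = random_pwm(rng, 5, "Minv")
        th = score_threshold(pwm, bg, pvalue=0.01)
        ints = th.int_scores
        mass = {}
        for word in itertools.product(range(4), repeat=5):
            s = sum(ints[i, b] for i, b in enumerate(word))
            mass[s] = mass.get(s, 0.0) + 0.25**5
        tail_at = lambda t: sum(m for s, m in mass.items() if s >= t)
        assert tail_at(th.min_score_int) <= 0.01 + 1e-12
        lower = [s for s in mass if s < th.min_score_int]
        if lower:
            assert tail_at(max(lower)) > 0.01

    def test_nonpositive_background_rejected(self, consensus_pwm):
        with pytest.raises(ValueError, match="background"):
            score_threshold(consensus_pwm, background=(0.5, 0.5, 0.0, 0.0))


class TestScan:
    def test_planted_consensus_found(self, consensus_pwm, rng):
        th = score_threshold(consensus_pwm)
        bgseq = "".join(rng.choice(list("ACGT"), size=60))
        seq = bgseq[:10] + consensus_pwm.consensus + bgseq[10:]
        assert sequence_has_hit(seq, th)

    def test_reverse_complement_found(self, consensus_pwm, rng):
        th = score_threshold(consensus_pwm)
        seq = "TT" + reverse_complement(consensus_pwm.consensus) + "GGCCAATT"
        assert sequence_has_hit(seq, th)

    def test_strand_symmetry(self, consensus_pwm, rng):
        th = score_threshold(consensus_pwm)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            assert sequence_has_hit(seq, th) == sequence_has_hit(reverse_complement(seq), th)

    def test_uniform_pwm_never_hits(self, rng):
        th = score_threshold(Pwm("flat", np.full((4, 4), 0.25)))
        assert not sequence_has_hit("ACGTACGTACGT", th)

    def test_windows_with_n_are_skipped(self, consensus_pwm):
        th = score_threshold(consensus_pwm)
        broken = consensus_pwm.consensus[:4] + "N" + consensus_pwm.consensus[5:]
        assert not sequence_has_hit("AA" + broken + "TT", th)

    def test_matrix_entries(self, consensus_pwm, rng):
        th = {consensus_pwm.name: score_threshold(consensus_pwm)}
        groups = [MotifGroup("G0", [consensus_pwm.name], ["TfTest"])]
        seqs = {
            "with": "AATT" + consensus_pwm.consensus + "CCGG",
            "without": "".join(rng.choice(list("ACGT"), size=30)),
        }
        X = scan_matrix(seqs, groups, th)
        assert X.values.loc["with", "G0"] == 1


class TestFilterExpressed:
    def _pwm(self, gene):
        return Pwm("M_" + gene, np.array([[1.0, 0, 0, 0]]), tf_gene=gene)

    def test_any_population_above_floor_kept(self, expr_three_pops):
        kept = filter_expressed([self._pwm("GeneHi")], expr_three_pops, floor=1.0)
        assert len(kept) == 1

    def test_boundary_is_strict(self, expr_three_pops):
        # GeneEdge has mean FPKM exactly 1.0 in every population
        assert filter_expressed([self._pwm("GeneEdge")], expr_three_pops, floor=1.0) == []

    def test_unresolvable_gene_dropped_and_empty_input(self, expr_three_pops):
        assert filter_expressed([self._pwm("NoSuchGene")], expr_three_pops) == []
        assert filter_expressed([], expr_three_pops) == []


class TestGroupMotifs:
    def _pwms(self, spec):
        return [Pwm(n, np.array([[1.0, 0, 0, 0]]), tf_gene=g, family=f)
                for n, g, f in spec]

    def test_single_edge_groups(self):
        pwms = self._pwms([("a", "gA", "F1"), ("b", "gB", "F1")])
        groups = group_motifs(pwms, {("a", "b"): 1e-6, ("b", "a"): 1e-6})
        assert len(groups) == 1

    def test_family_guard(self):
        pwms = self._pwms([("a", "gA", "F1"), ("b", "gB", "F2")])
        groups = group_motifs(pwms, {("a", "b"): 1e-6, ("b", "a"): 1e-6})
        assert len(groups) == 2

    def test_gene_uniqueness_merges_components(self):
        # m1,m2 share gene A but sit in different similarity components
        pwms = self._pwms([("m1", "gA", "F1"), ("m2", "gA", "F2"),
                           ("m3", "gB", "F1"), ("m4", "gC", "F2")])
        sim = {("m1", "m3"): 1e-7, ("m3", "m1"): 1e-7,
               ("m2", "m4"): 1e-7, ("m4", "m2"): 1e-7}
        groups = group_motifs(pwms, sim)
        assert len(groups) == 1  # all four merged through shared gene gA
        genes = [g for grp in groups for g in grp.genes]
        assert len(genes) == len(set(genes))

    def test_partition_and_order_independence(self, rng):
        spec = [(f"m{i}", f"g{i % 5}", f"F{i % 2}") for i in range(12)]
        pwms = self._pwms(spec)
        sim = {}
        for i in range(12):
            for j in range(i + 1, 12):
                e = 10.0 ** rng.uniform(-8, 0)
                sim[(f"m{i}", f"m{j}")] = e
                sim[(f"m{j}", f"m{i}")] = e
        ref = {frozenset(g.members) for g in group_motifs(pwms, sim)}
        for _ in range(20):
            order = list(pwms)
            rng.shuffle(order)
            got = {frozenset(g.members) for g in group_motifs(order, sim)}
            assert got == ref
        assert sorted(m for g in ref for m in g) == sorted(p.name for p in pwms)


def binary_matrix(cols):
    return PeakMotifMatrix(pd.DataFrame(cols))


class TestEnrichmentAndPrevalence:
    def test_strong_enrichment_kept(self):
        groups = [MotifGroup("G0", ["m"], ["g"])]
        atlas = binary_matrix({"G0": [1] * 500 + [0] * 500})
        bg = binary_matrix({"G0": [1] * 50 + [0] * 950})
        assert enrichment_filter(groups, atlas, bg) == groups

    def test_identical_occurrence_dropped(self):
        groups = [MotifGroup("G0", ["m"], ["g"])]
        atlas = binary_matrix({"G0": [1] * 100 + [0] * 900})
        assert enrichment_filter(groups, atlas, atlas) == []

    def test_absent_group_dropped(self):
        groups = [MotifGroup("G0", ["m"], ["g"])]
        zeros = binary_matrix({"G0": [0] * 100})
        assert enrichment_filter(groups, zeros, zeros) == []

    def test_prevalence_boundary(self):
        X = binary_matrix({"low": [1] * 19 + [0] * 981, "edge": [1] * 20 + [0] * 980})
        out = prevalence_filter(X, min_frac=0.02)
        assert out.groups == ["edge"]

    def test_prevalence_identity_when_all_pass(self):
        X = binary_matrix({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]})
        assert prevalence_filter(X).values.equals(X.values)

    def test_all_columns_dropped_is_an_error(self):
        X = binary_matrix({"a": [1] + [0] * 99})
        with pytest.raises(ValueError, match="threshold|cutoff"):
            prevalence_filter(X, min_frac=0.5)

    def test_filters_commute_on_retained_columns(self):
        atlas = binary_matrix({"keep": [1] * 400 + [0] * 600, "rare": [1] * 5 + [0] * 995})
        bg = binary_matrix({"keep": [1] * 40 + [0] * 960, "rare": [1] * 5 + [0] * 995})
        groups = [MotifGroup("keep", ["k"], ["gk"]), MotifGroup("rare", ["r"], ["gr"])]
        # enrichment then prevalence
        enriched = enrichment_filter(groups, atlas, bg)
        ab = prevalence_filter(PeakMotifMatrix(atlas.values[[g.group_id for g in enriched]]))
        # prevalence then enrichment (on surviving groups only)
        prev = prevalence_filter(atlas)
        surviving = [g for g in groups if g.group_id in prev.groups]
        ba = [g.group_id for g in enrichment_filter(surviving, prev, PeakMotifMatrix(bg.values[prev.groups]))]
        assert ab.groups == ba == ["keep"]


class TestRepresentative:
    def test_highest_fraction_wins(self):
        g = MotifGroup("G0", ["a", "b"], ["x"])
        assert pick_representative(g, {"a": 0.10, "b": 0.30}) == "b"

    def test_tie_breaks_lexicographically(self):
        g = MotifGroup("G0", ["b", "a"], ["x"])
        assert pick_representative(g, {"a": 0.2, "b": 0.2}) == "a"

    def test_singleton(self):
        g = MotifGroup("G0", ["only"], ["x"])
        assert pick_representative(g, {"only": 0.0}) == "only"

    def test_member_occurrence_fractions(self, consensus_pwm):
        th = {consensus_pwm.name: score_threshold(consensus_pwm)}
        seqs = {"a": "AA" + consensus_pwm.consensus + "TT", "b": "A" * 20}
        fracs = member_occurrence_fractions(seqs, th)
        assert fracs[consensus_pwm.name] == pytest.approx(0.5)
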