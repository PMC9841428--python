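"""Local alignment, E-values, reciprocal filtering and genome intersection."""

import math

import numpy as np
import pytest

from conftest import random_dna
from oracles import blosum_local, dna_local
from telotrace.motifs import TelomereMotif, revcomp
from telotrace.homology_filter import (
    align_to_genome,
    evalue,
    extend_search,
    intersect_genomes,
    local_align,
    protein_align,
    reciprocal_filter,
    template_correspondence,
)
from telotrace.template_scan import TemplateLocus, TemplateMatch, scan_templates

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestLocalAlign:
    def test_self_alignment_perfect(self, rng):
        s = random_dna(rng, 100)
        hit = local_align(s, s)
        assert hit.raw_score == 200
        assert hit.identity == 1.0
        assert (hit.query_start, hit.query_end) == (0, 100)

    def test_matches_brute_force_dp(self, rng):
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(5, 61)))
            b = random_dna(rng, int(rng.integers(5, 61)))
            assert local_align(a, b).raw_score == dna_local(a, b)

    def test_protein_matches_brute_force_dp(self, rng):
        for _ in range(30):
            a = "".join(np.array(list(AA))[rng.integers(0, 20, int(rng.integers(50, 61)))])
            b = "".join(np.array(list(AA))[rng.integers(0, 20, int(rng.integers(50, 61)))])
            assert protein_align(a, b).raw_score == blosum_local(a, b)

    def test_minus_strand_hit_coordinates(self, rng):
        a = random_dna(rng, 60)
        b = random_dna(rng, 30) + revcomp(a) + random_dna(rng, 30)
        hit = local_align(a, b)
        assert hit.strand == "-"
        assert hit.raw_score == 120
        assert (hit.subject_start, hit.subject_end) == (30, 90)

    def test_evalue_proportional_to_search_space(self):
        assert evalue(50, 100, 2000) == pytest.approx(2 * evalue(50, 100, 1000))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_align("", "ACGT")

    def test_masked_n_contributes_nothing(self):
        s = "ACGTACGTACGT"
        hit = local_align(s + "N" * 50, s + "N" * 50, both_strands=False)
        assert hit.raw_score == 2 * len(s)  # N vs N never matches


def _window_locus(genome_id, seq_id, seq, start, window=400):
    end = min(len(seq), start + window)
    return TemplateLocus(
        genome_id, seq_id, start, end,
        [TemplateMatch(seq_id, start + window // 2 - 6, start + window // 2 + 6, "-", "CCCCAACCTAAC")],
        sequence=seq[start:end],
    )


def _two_genome_sets(rng, shared):
    """Loci for two genomes: one shared window each plus private decoys."""
    sets = {}
    for g in ("gA", "gB"):
        seq = random_dna(rng, 20_000)
        seq = seq[:7000] + shared + seq[7000:]
        loci = [_window_locus(g, f"{g}_c", seq, 6900)]
        for i in range(5):
            loci.append(_window_locus(g, f"{g}_c", seq, 10_000 + 900 * i))
        sets[g] = loci
    return sets


class TestReciprocalFilter:
    def test_only_shared_window_pair_survives(self, rng):
        shared = random_dna(rng, 400)
        sets = _two_genome_sets(rng, shared)
        pairs = reciprocal_filter(sets["gA"], sets["gB"], prefilter_k=None)
        assert len(pairs) == 1
        a, b, hit = pairs[0]
        assert a.window_start == b.window_start == 6900
        assert hit.evalue < 1e-20

    def test_no_cross_hits_empty(self, rng):
        sets = {
            "gA": [_window_locus("gA", "c", random_dna(rng, 2000), 500)],
            "gB": [_window_locus("gB", "c", random_dna(rng, 2000), 500)],
        }
        assert reciprocal_filter(sets["gA"], sets["gB"], prefilter_k=None) == []

    def test_identical_decoy_in_both_genomes_also_survives(self, rng):
        """The filter is purely sequence-level; a conserved decoy passes and
        must be removed later by the template check."""
        shared_tr = random_dna(rng, 400)
        shared_decoy = random_dna(rng, 400)
        sets = _two_genome_sets(rng, shared_tr)
        for g in sets:
            seq = random_dna(rng, 1000) + shared_decoy + random_dna(rng, 1000)
            sets[g].append(_window_locus(g, f"{g}_d", seq, 1000))
        pairs = reciprocal_filter(sets["gA"], sets["gB"], prefilter_k=None)
        assert len(pairs) == 2

    def test_mirrored_in_arguments(self, rng):
        shared = random_dna(rng, 400)
        sets = _two_genome_sets(rng, shared)
        fwd = reciprocal_filter(sets["gA"], sets["gB"], prefilter_k=None)
        rev = reciprocal_filter(sets["gB"], sets["gA"], prefilter_k=None)
        assert {(a.locus_id, b.locus_id) for a, b, _ in fwd} == {
            (b.locus_id, a.locus_id) for a, b, _ in rev}

    def test_prefilter_equals_full_dp_on_significant_pairs(self, rng):
        shared = random_dna(rng, 400)
        sets = _two_genome_sets(rng, shared)
        full = reciprocal_filter(sets["gA"], sets["gB"], prefilter_k=None)
        seeded = reciprocal_filter(sets["gA"], sets["gB"], prefilter_k=13)
        key = lambda ps: {(a.locus_id, b.locus_id) for a, b, _ in ps}
        assert key(full) == key(seeded)


class TestIntersectGenomes:
    def test_planted_candidate_spans_all_genomes(self, rng):
        shared = random_dna(rng, 400)
        sets = {}
        for g in ("g0", "g1", "g2"):
            seq = random_dna(rng, 15_000)
            seq = seq[:5000] + shared + seq[5000:]
            loci = [_window_locus(g, f"{g}_c", seq, 4900)]
            for i in range(4):
                loci.append(_window_locus(g, f"{g}_c", seq, 8000 + 900 * i))
            sets[g] = loci
        cands = intersect_genomes(sets, prefilter_k=None)
        assert len(cands) == 1
        assert set(cands[0].homologs) == {"g0", "g1", "g2"}

    def test_genome_missing_the_locus_blocks_full_span(self, rng):
        shared = random_dna(rng, 400)
        sets = _two_genome_sets(rng, shared)
        sets["gC"] = [_window_locus("gC", "c", random_dna(rng, 2000), 500)]
        assert intersect_genomes(sets, prefilter_k=None) == []
        # pairwise mode still reports the 2-genome component
        pairs = reciprocal_filter(sets["gA"], sets["gB"], prefilter_k=None)
        assert len(pairs) == 1

    def test_single_genome_rejected(self, rng):
        with pytest.raises(ValueError, match="two genomes"):
            intersect_genomes({"g": []})


class TestTemplateCorrespondence:
    def test_motif_mutation_must_be_mirrored_in_template(self, rng):
        """A homolog window carrying the C-variant template verifies under
        the mutated motif but not under the unmutated one."""
        from telotrace.synthetic_data import template_of

        tmpl_c = template_of("TTAGGTTGGGC")  # GCCCAACCTAAG
        seq = random_dna(rng, 200) + tmpl_c + random_dna(rng, 188)
        locus = TemplateLocus("gS", "c", 0, 400, [], sequence=seq)
        from telotrace.homology_filter import CandidateTR

        cand = CandidateTR(locus=locus, homologs={"gS": locus})
        template_correspondence(cand, {"gS": TelomereMotif("TTAGGTTGGGC")})
        assert cand.template_ok["gS"] is True
        cand2 = CandidateTR(locus=locus, homologs={"gS": locus})
        template_correspondence(cand2, {"gS": TelomereMotif("TTAGGTTGGGG")})
        assert cand2.template_ok["gS"] is False

    def test_conserved_decoy_without_template_rejected(self, rng):
        from telotrace.homology_filter import CandidateTR

        good = TemplateLocus("g0", "c", 0, 400, [],
                             sequence=random_dna(rng, 194) + "CCCCAACCTAAC" + random_dna(rng, 194))
        bad = TemplateLocus("g1", "c", 0, 400, [], sequence=random_dna(rng, 400))
        cand = CandidateTR(locus=good, homologs={"g0": good, "g1": bad})
        motif = TelomereMotif("TTAGGTTGGGG")
        template_correspondence(cand, {"g0": motif, "g1": motif})
        assert cand.template_ok == {"g0": True, "g1": False}
        assert not cand.template_verified


class TestExtendSearch:
    def _candidate(self, rng, query):
        locus = TemplateLocus("g0", "c", 0, len(query), [], sequence=query)
        from telotrace.homology_filter import CandidateTR

        return CandidateTR(locus=locus, homologs={"g0": locus})

    def test_diverged_copy_found_at_relaxed_threshold_only(self, rng):
        """A relative retaining only a short conserved core of the query is
        significant at 1e-5 but not at the strict 1e-20 used within-genus:
        a 30-bp exact core scores 60, and E(60) over a 100-kb genome is
        ~1e-6 while E <= 1e-20 needs a score near 100."""
        query = random_dna(rng, 300)
        core = query[100:130]
        genome = {"chr": random_dna(rng, 50_000) + core + random_dna(rng, 50_000)}
        cand = self._candidate(rng, query)
        relaxed = extend_search(cand, {"rel": genome}, evalue_max=1e-5)
        assert relaxed["rel"]["hit"] is not None
        assert relaxed["rel"]["hit"].evalue > 1e-20
        strict = extend_search(cand, {"rel": genome}, evalue_max=1e-20)
        assert strict["rel"]["hit"] is None

    def test_absent_locus_no_hit(self, rng):
        cand = self._candidate(rng, random_dna(rng, 300))
        res = extend_search(cand, {"g": {"chr": random_dna(rng, 30_000)}})
        assert res["g"]["hit"] is None

    def test_hit_without_template_flagged(self, rng):
        query = random_dna(rng, 300)
        genome = {"chr": random_dna(rng, 10_000) + query + random_dna(rng, 10_000)}
        cand = self._candidate(rng, query)
        res = extend_search(cand, {"g": genome}, motifs={"g": TelomereMotif("TTAGGTTGGGG")})
        assert res["g"]["hit"] is not None
        assert res["g"]["template_ok"] is False
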