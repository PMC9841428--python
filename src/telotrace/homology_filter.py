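"""Pairwise local alignment, E-values and cross-genome candidate filtering.

Template-like loci are abundant within any one genome (hundreds per
*Bombus*-sized assembly) but almost never conserved between genomes unless
they are real genes. The filter aligns candidate windows across genomes
(Smith-Waterman, affine gaps, blastn-like nucleotide scores +2/-3 with gap
cost 5 + 2k), keeps reciprocal best pairs at a strict E-value threshold
(1e-20), intersects the surviving pairs across all genomes, and finally
demands template-telomere correspondence: the homolog in each genome must
carry a template pattern of *that genome's own* telomere motif, so a
single-base motif mutation in one species must be mirrored in its template.

E-values use the extreme-value formula E = K * m * n * exp(-lambda * S)
with (lambda, K) fitted once by simulation on random sequences at the
default scores (see scripts/fit_evalue_constants.py); the fitted values are
frozen in :mod:`telotrace._evalue_constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from . import _evalue_constants as _ev
from .motifs import revcomp
from .template_scan import TemplateLocus, template_patterns


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    raw_score: float
    evalue: float
    identity: float
    length: int = 0


@dataclass
class CandidateTR:
    """A template locus conserved across genomes, with verification state."""

    locus: TemplateLocus
    homologs: dict[str, TemplateLocus] = field(default_factory=dict)
    hits: dict[str, AlignmentHit] = field(default_factory=dict)
    template_ok: dict[str, bool] = field(default_factory=dict)
    promoter: object | None = None
    pol_class: str | None = None
    structure: object | None = None
    transcript_bounds: tuple[int, int] | None = None

    @property
    def template_verified(self) -> bool:
        return bool(self.template_ok) and all(self.template_ok.values())


def _dna_aligner() -> Align.PairwiseAligner:
    # open_gap_score covers the first gapped base, so a gap of length k
    # costs 7 + 2(k-1) = 5 + 2k, the stated affine cost. N never matches,
    # not even N vs N, so masked (low-complexity) stretches score nothing.
    a = Align.PairwiseAligner(mode="local")
    m = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            m[x, y] = 2.0 if (x == y and x != "N") else -3.0
    a.substitution_matrix = m
    a.open_gap_score = -7
    a.extend_gap_score = -2
    return a


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -12  # gap of length k costs 11 + 1*k
    a.extend_gap_score = -1
    return a


_DNA = _dna_aligner()
_PROT = _protein_aligner()


def evalue(score: float, m: int, n: int, lam: float | None = None, k: float | None = None) -> float:
    lam = _ev.DNA_LAMBDA if lam is None else lam
    k = _ev.DNA_K if k is None else k
    return k * m * n * math.exp(-lam * score)


def _hit_from_alignment(aln, score, strand, n_subject, query_id, subject_id, m, n,
                        lam, k) -> AlignmentHit:
    qa, sa = aln.aligned
    q0, q1 = int(qa[0][0]), int(qa[-1][1])
    s0, s1 = int(sa[0][0]), int(sa[-1][1])
    ident = 0
    length = 0
    qseq, sseq = aln.sequences
    for (qs, qe), (ss, se) in zip(qa, sa):
        for off in range(qe - qs):
            length += 1
            if qseq[qs + off] == sseq[ss + off]:
                ident += 1
    if strand == "-":
        s0, s1 = n_subject - s1, n_subject - s0
    return AlignmentHit(
        query_id, subject_id, q0, q1, s0, s1, strand,
        float(score), evalue(score, m, n, lam, k),
        ident / length if length else 0.0, length,
    )


def local_align(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    both_strands: bool = True,
    protein: bool = False,
) -> AlignmentHit:
    """Best local alignment of ``a`` against ``b`` (both strands of ``b``
    for DNA). Raw score is the exact affine-gap optimum at +2/-3 with gap
    cost 5 + 2k (BLOSUM62 with 11/1 for protein)."""
    if not a or not b:
        raise ValueError("empty sequence")
    if protein:
        a, b = a.upper(), b.upper()
        aligner, lam, k = _PROT, _ev.PROT_LAMBDA, _ev.PROT_K
        strands = [("+", b)]
    else:
        a, b = a.upper(), b.upper()
        aligner, lam, k = _DNA, _ev.DNA_LAMBDA, _ev.DNA_K
        strands = [("+", b)] + ([("-", revcomp(b))] if both_strands else [])
    best = None
    for strand, subject in strands:
        score = aligner.score(a, subject)
        if best is None or score > best[0]:
            best = (score, strand, subject)
    score, strand, subject = best
    if score <= 0:
        return AlignmentHit(query_id, subject_id, 0, 0, 0, 0, "+", 0.0,
                            evalue(0, len(a), len(b), lam, k), 0.0, 0)
    aln = aligner.align(a, subject)[0]
    return _hit_from_alignment(aln, score, strand, len(b), query_id, subject_id,
                               len(a), len(b), lam, k)


def protein_align(query: str, target: str, query_id: str = "query",
                  subject_id: str = "subject") -> AlignmentHit:
    """Affine local alignment under BLOSUM62 with gap cost 11 + k."""
    return local_align(query, target, query_id, subject_id, protein=True)


# ---------------------------------------------------------------------------
# k-mer seeding


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_seed(a: str, b_kmers: set[str], k: int) -> bool:
    return any(a[i : i + k] in b_kmers for i in range(len(a) - k + 1))


def align_to_genome(
    query: str,
    seqs: dict[str, str],
    k: int = 11,
    pad: int | None = None,
    query_id: str = "query",
) -> AlignmentHit | None:
    """Seed-and-extend search of a window-sized query in a genome.

    Exact ``k``-mer seeds (both strands) anchor full-DP alignment of the
    query against a padded genomic window around each seed; the best hit is
    reported with the E-value computed over the whole genome size.
    """
    pad = pad if pad is not None else 2 * len(query)
    qk = kmer_set(query, k) | kmer_set(revcomp(query), k)
    total_n = sum(len(s) for s in seqs.values())
    best: AlignmentHit | None = None
    for seq_id in sorted(seqs):
        seq = seqs[seq_id].upper()
        hit_regions: list[tuple[int, int]] = []
        i = 0
        n = len(seq)
        while i <= n - k:
            if seq[i : i + k] in qk:
                start, end = max(0, i - pad), min(n, i + k + pad)
                if hit_regions and start <= hit_regions[-1][1]:
                    hit_regions[-1] = (hit_regions[-1][0], end)
                else:
                    hit_regions.append((start, end))
                i += k  # seeds inside the merged region add nothing
            else:
                i += 1
        for start, end in hit_regions:
            hit = local_align(query, seq[start:end], query_id, seq_id)
            hit.subject_start += start
            hit.subject_end += start
            hit.evalue = evalue(hit.raw_score, len(query), total_n)
            if best is None or (hit.raw_score, -hit.evalue) > (best.raw_score, -best.evalue):
                best = hit
    return best


# ---------------------------------------------------------------------------
# reciprocal filtering and multi-genome intersection


def _seed_sequence(locus: TemplateLocus) -> str:
    """Window sequence with the template matches themselves masked out for
    seeding purposes: every locus contains a template pattern by
    construction, so pattern-derived words say nothing about homology, and
    a pattern-only alignment is far too short to reach the significance
    thresholds used here."""
    chars = list(locus.sequence)
    for m in locus.matches:
        for x in range(max(0, m.start - locus.window_start),
                       min(len(chars), m.end - locus.window_start)):
            chars[x] = "N"
    return "".join(chars)


def _score_matrix(
    loci_a: list[TemplateLocus],
    loci_b: list[TemplateLocus],
    prefilter_k: int | None,
) -> dict[tuple[int, int], float]:
    """Score-only Smith-Waterman over locus window pairs.

    With ``prefilter_k`` set, only pairs sharing an exact k-mer (either
    strand) are aligned; pairs without a shared word cannot reach
    window-scale significance at the strict thresholds used here.
    """
    candidate_pairs: set[tuple[int, int]]
    if prefilter_k:
        index: dict[str, list[int]] = {}
        for j, lb in enumerate(loci_b):
            for kmer in kmer_set(_seed_sequence(lb), prefilter_k):
                if "N" not in kmer:
                    index.setdefault(kmer, []).append(j)
        candidate_pairs = set()
        for i, la in enumerate(loci_a):
            seed_seq = _seed_sequence(la)
            for kmer in kmer_set(seed_seq, prefilter_k) | kmer_set(
                revcomp(seed_seq), prefilter_k
            ):
                if "N" in kmer:
                    continue
                for j in index.get(kmer, ()):
                    candidate_pairs.add((i, j))
    else:
        candidate_pairs = {(i, j) for i in range(len(loci_a)) for j in range(len(loci_b))}
    scores: dict[tuple[int, int], float] = {}
    for i, j in sorted(candidate_pairs):
        la, lb = loci_a[i], loci_b[j]
        s = max(
            _DNA.score(la.sequence, lb.sequence),
            _DNA.score(revcomp(la.sequence), lb.sequence),
        )
        if s > 0:
            scores[(i, j)] = float(s)
    return scores


def _best_of(
    loci_a: list[TemplateLocus],
    loci_b: list[TemplateLocus],
    scores: dict[tuple[int, int], float],
    i: int,
    evalue_max: float,
) -> tuple[int, float] | None:
    """Best subject index in B for query i, by (E-value, alignment length,
    lexicographic subject id); full alignments are computed only to break
    exact E-value ties."""
    la = loci_a[i]
    cands = []
    for (ii, j), s in scores.items():
        if ii != i:
            continue
        e = evalue(s, len(la.sequence), len(loci_b[j].sequence))
        if e <= evalue_max:
            cands.append((e, j))
    if not cands:
        return None
    cands.sort()
    best_e = cands[0][0]
    tied = [j for e, j in cands if e == best_e]
    if len(tied) == 1:
        return tied[0], best_e
    ranked = []
    for j in tied:
        hit = local_align(la.sequence, loci_b[j].sequence, la.locus_id, loci_b[j].locus_id)
        ranked.append((-hit.length, loci_b[j].locus_id, j))
    return min(ranked)[2], best_e


def reciprocal_filter(
    loci_a: list[TemplateLocus],
    loci_b: list[TemplateLocus],
    evalue_max: float = 1e-20,
    prefilter_k: int | None = 11,
) -> list[tuple[TemplateLocus, TemplateLocus, AlignmentHit]]:
    """Pairs (x, y) where each is the other's best hit at E <= evalue_max.

    Mirrored in its arguments: swapping A and B returns the mirrored pairs.
    """
    scores = _score_matrix(loci_a, loci_b, prefilter_k)
    rev_scores = {(j, i): s for (i, j), s in scores.items()}
    fwd = {}
    for i in range(len(loci_a)):
        got = _best_of(loci_a, loci_b, scores, i, evalue_max)
        if got is not None:
            fwd[i] = got[0]
    rev = {}
    for j in range(len(loci_b)):
        got = _best_of(loci_b, loci_a, rev_scores, j, evalue_max)
        if got is not None:
            rev[j] = got[0]
    pairs = []
    for i, j in sorted(fwd.items()):
        if rev.get(j) == i:
            hit = local_align(
                loci_a[i].sequence, loci_b[j].sequence,
                loci_a[i].locus_id, loci_b[j].locus_id,
            )
            pairs.append((loci_a[i], loci_b[j], hit))
    return pairs


def intersect_genomes(
    locus_sets: dict[str, list[TemplateLocus]],
    evalue_max: float = 1e-20,
    clique: bool = False,
    prefilter_k: int | None = 11,
) -> list[CandidateTR]:
    """Candidates conserved across *all* genomes.

    Reciprocal best pairs are computed for every genome pair; connected
    components of the resulting graph that span all genomes become
    candidates (``clique=True`` additionally demands a reciprocal pair for
    every genome pair within the component).
    """
    genomes = sorted(locus_sets)
    if len(genomes) < 2:
        raise ValueError("need at least two genomes to intersect")
    parent: dict[str, str] = {}
    loci_by_id: dict[str, TemplateLocus] = {}
    hits: dict[tuple[str, str], AlignmentHit] = {}
    edges: set[tuple[str, str]] = set()

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for g in genomes:
        for l in locus_sets[g]:
            parent[l.locus_id] = l.locus_id
            loci_by_id[l.locus_id] = l
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            for la, lb, hit in reciprocal_filter(
                locus_sets[ga], locus_sets[gb], evalue_max, prefilter_k
            ):
                union(la.locus_id, lb.locus_id)
                edges.add((la.locus_id, lb.locus_id))
                hits[(la.locus_id, lb.locus_id)] = hit

    components: dict[str, list[str]] = {}
    for lid in loci_by_id:
        components.setdefault(find(lid), []).append(lid)

    candidates = []
    for root in sorted(components):
        members = components[root]
        per_genome: dict[str, list[TemplateLocus]] = {}
        for lid in members:
            per_genome.setdefault(loci_by_id[lid].genome_id, []).append(loci_by_id[lid])
        if set(per_genome) != set(genomes):
            continue
        if clique:
            member_set = set(members)
            ok = all(
                any((a, b) in edges or (b, a) in edges
                    for a in member_set if loci_by_id[a].genome_id == ga
                    for b in member_set if loci_by_id[b].genome_id == gb)
                for i, ga in enumerate(genomes) for gb in genomes[i + 1 :]
            )
            if not ok:
                continue
        homologs = {g: sorted(ls, key=lambda l: l.locus_id)[0] for g, ls in per_genome.items()}
        rep = homologs[genomes[0]]
        cand = CandidateTR(locus=rep, homologs=homologs)
        for (a, b), hit in hits.items():
            ga, gb = loci_by_id[a].genome_id, loci_by_id[b].genome_id
            if a in members and loci_by_id[a] is homologs.get(ga) and loci_by_id[b] is homologs.get(gb):
                cand.hits.setdefault(gb if ga == genomes[0] else ga, hit)
        candidates.append(cand)
    return candidates


def template_correspondence(
    candidate: CandidateTR,
    motifs: dict[str, object],
    extension: int = 1,
) -> CandidateTR:
    """Check, per genome, that the homolog window carries a template pattern
    of that genome's own telomere motif (mutations must track the motif)."""
    for genome_id, locus in candidate.homologs.items():
        pats = template_patterns(motifs[genome_id], extension)
        seq = locus.sequence
        candidate.template_ok[genome_id] = any(p.pattern in seq for p in pats)
    return candidate


def extend_search(
    candidate: CandidateTR,
    genomes: dict[str, dict[str, str]],
    evalue_max: float = 1e-5,
    motifs: dict[str, object] | None = None,
    extension: int = 1,
) -> dict[str, dict]:
    """Relaxed-threshold search of further genomes with the candidate as
    query; one best hit per genome, template presence annotated."""
    query = candidate.locus.sequence
    results: dict[str, dict] = {}
    for genome_id in sorted(genomes):
        hit = align_to_genome(query, genomes[genome_id], query_id=candidate.locus.locus_id)
        if hit is None or hit.evalue > evalue_max:
            results[genome_id] = {"hit": None, "template_ok": None}
            continue
        entry: dict = {"hit": hit, "template_ok": None}
        if motifs and genome_id in motifs:
            seq = genomes[genome_id][hit.subject_id]
            lo = max(0, hit.subject_start - 50)
            hi = min(len(seq), hit.subject_end + 50)
            window = seq[lo:hi].upper()
            pats = template_patterns(motifs[genome_id], extension)
            entry["template_ok"] = any(
                p.pattern in window or p.pattern in revcomp(window) for p in pats
            )
        results[genome_id] = entry
    return results
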