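"""Screen genomes for TERT-like coding sequence.

The catalytic telomerase subunit TERT is detected tblastn-style: every
genome is translated in all six frames into stop-to-stop peptide segments,
each segment is locally aligned against protein queries split into the
telomerase-specific RNA-binding domain (TRBD) and the reverse-transcriptase
domain (RT), and the best E-value per genome and domain fills a
presence/absence matrix (reported on a log10 E-value scale). Stop-to-stop
segments rather than ATG-initiated ORFs keep the search sensitive to exon
fragments; introns are not modelled - a hit in any one segment suffices.
The two domains are scored independently: an RT-only retroelement never
rescues the TRBD column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .motifs import revcomp
from .homology_filter import protein_align

_CODON = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinQuery:
    id: str
    domain: str  # TRBD | RT
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not set(seq) <= AA_ALPHABET:
            raise ValueError(f"query {self.id}: non-amino-acid characters")
        if len(seq) < 50:
            raise ValueError(f"query {self.id}: shorter than 50 aa")
        if self.domain not in ("TRBD", "RT"):
            raise ValueError(f"query {self.id}: domain must be TRBD or RT")
        object.__setattr__(self, "sequence", seq)


@dataclass
class TranslatedSegment:
    seq_id: str
    frame: int  # 0..2
    strand: str
    start: int  # genomic, 0-based half-open, forward-strand coordinates
    end: int
    peptide: str


def _translate(codons_seq: str) -> str:
    out = []
    for i in range(0, len(codons_seq) - 2, 3):
        codon = codons_seq[i : i + 3]
        if codon in _STOPS:
            out.append("*")
        else:
            out.append(_CODON.get(codon, "X"))  # N-containing codons -> X
    return "".join(out)


def six_frame_translate(
    seqs: dict[str, str], min_len: int = 15
) -> list[TranslatedSegment]:
    """Stop-to-stop peptide segments of every frame and strand.

    Coordinates map each segment back to the forward genomic strand so the
    translation of the mapped interval reproduces the peptide exactly.
    """
    segments = []
    for seq_id in sorted(seqs):
        fwd = seqs[seq_id].upper()
        n = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            for frame in range(3):
                peptide = _translate(seq[frame:])
                start_aa = 0
                for chunk in peptide.split("*"):
                    if len(chunk) >= min_len:
                        s = frame + 3 * start_aa
                        e = s + 3 * len(chunk)
                        if strand == "+":
                            g0, g1 = s, e
                        else:
                            g0, g1 = n - e, n - s
                        segments.append(
                            TranslatedSegment(seq_id, frame, strand, g0, g1, chunk)
                        )
                    start_aa += len(chunk) + 1
    return segments


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass
class PresenceMatrix:
    """Best E-value per genome and (query, domain), with presence calls."""

    evalues: pd.DataFrame  # genomes x (query_id, domain); best E-value
    threshold: float

    @property
    def log10(self) -> pd.DataFrame:
        return np.log10(self.evalues)

    @property
    def presence(self) -> pd.DataFrame:
        return self.evalues <= self.threshold

    def domain_presence(self) -> pd.DataFrame:
        """Per-domain presence: any query of the domain below threshold."""
        pres = self.presence
        domains = sorted({d for _, d in pres.columns})
        return pd.DataFrame(
            {d: pres.loc[:, [c for c in pres.columns if c[1] == d]].any(axis=1)
             for d in domains}
        )


def tert_presence(
    genomes: dict[str, dict[str, str]],
    queries: list[ProteinQuery],
    evalue_max: float = 1e-5,
    prefilter_k: int = 4,
    min_segment_len: int = 15,
) -> PresenceMatrix:
    """Best TERT-domain E-value per genome, from six-frame translation plus
    protein-DNA local alignment.

    Only segments sharing an exact ``prefilter_k``-mer with the query are
    aligned (a diverged real domain always retains short exact words); the
    E-value search space is the total translated residue count of the
    genome.
    """
    if not queries:
        raise ValueError("need at least one protein query")
    cols = pd.MultiIndex.from_tuples(
        [(q.id, q.domain) for q in queries], names=["query", "domain"]
    )
    data = {}
    for genome_id in sorted(genomes):
        segments = six_frame_translate(genomes[genome_id], min_segment_len)
        total_residues = sum(len(s.peptide) for s in segments) or 1
        row = []
        for q in queries:
            q_kmers = _kmer_set(q.sequence, prefilter_k)
            best_score = 0.0
            for seg in segments:
                pep = seg.peptide
                if not any(pep[i : i + prefilter_k] in q_kmers
                           for i in range(len(pep) - prefilter_k + 1)):
                    continue
                hit = protein_align(q.sequence, pep, q.id, seg.seq_id)
                if hit.raw_score > best_score:
                    best_score = hit.raw_score
            from .homology_filter import evalue as _evalue
            from . import _evalue_constants as _ev

            row.append(
                _evalue(best_score, len(q.sequence), total_residues,
                        _ev.PROT_LAMBDA, _ev.PROT_K)
            )
        data[genome_id] = row
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    return PresenceMatrix(df, evalue_max)
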