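"""Scan genomes for TR template-like loci.

The only predictable feature of an unknown telomerase RNA is its template,
which must be complementary to the G-rich telomere strand. A template-like
pattern is therefore any circular permutation of the telomere repeat (on
either strand, or C-rich strand only in promoter-first mode) extended by at
least one further circular base as a minimal annealing portion. Each exact
genomic match seeds a 400 nt window centred on the match; matches lying
inside tandem arrays of three or more motif copies (telomeres and
interstitial telomeric repeats) are excluded, and overlapping windows are
merged into single candidate loci.

Matching is exact over ACGT; N never matches. Order of operations is fixed:
scan -> array exclusion -> windowing -> merge.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .motifs import TelomereMotif, as_motif, primitive_unit, revcomp, rotations


@dataclass(frozen=True)
class TemplatePattern:
    """One search pattern: a motif rotation plus its circular extension."""

    pattern: str
    source_rotation: int
    strand: str  # '+' = given (G-rich) strand, '-' = reverse complement


@dataclass(frozen=True)
class TemplateMatch:
    seq_id: str
    start: int
    end: int
    strand: str
    pattern: str


@dataclass
class TemplateLocus:
    """A candidate TR window: template-like match(es) centred in ~400 nt."""

    genome_id: str
    seq_id: str
    window_start: int
    window_end: int
    matches: list[TemplateMatch]
    merged: bool = False
    truncated: bool = False
    sequence: str = ""

    @property
    def locus_id(self) -> str:
        return f"{self.genome_id}:{self.seq_id}:{self.window_start}-{self.window_end}"


def template_patterns(
    motif: TelomereMotif | str, extension: int = 1, c_rich_only: bool = False
) -> list[TemplatePattern]:
    """Enumerate template-like patterns of a telomere motif.

    Both-strand mode yields at most ``2 L`` distinct patterns of length
    ``L + extension`` for a primitive motif of length ``L``; C-rich-only
    mode enumerates rotations of the C-rich strand alone (the
    promoter-first procedure). Duplicate strings are dropped.
    """
    if extension < 1:
        raise ValueError("extension must be >= 1 (minimal annealing portion)")
    if isinstance(motif, str):
        unit = motif.upper()
        prim = primitive_unit(unit)
        if prim != unit:
            warnings.warn(
                f"motif {unit!r} is a tandem of {prim!r}; reduced to its primitive unit"
            )
        unit = prim
        g_strand, c_strand = unit, revcomp(unit)
    else:
        g_strand, c_strand = motif.g_strand, motif.c_strand
    strands = [(c_strand, "+")] if c_rich_only else [(g_strand, "+"), (c_strand, "-")]
    seen: dict[str, TemplatePattern] = {}
    for unit, strand in strands:
        doubled = unit * (2 + extension // max(len(unit), 1))
        for i in range(len(unit)):
            pat = doubled[i : i + len(unit) + extension]
            if pat not in seen:
                seen[pat] = TemplatePattern(pat, i, strand)
    return list(seen.values())


def find_matches(
    seqs: dict[str, str], patterns: list[TemplatePattern]
) -> list[TemplateMatch]:
    """All exact (possibly overlapping) pattern occurrences, forward strand."""
    by_pattern = {p.pattern: p for p in patterns}
    # One alternation regex inside a lookahead reports overlapping matches.
    alts = sorted(by_pattern, key=len, reverse=True)
    rx = re.compile("(?=(" + "|".join(re.escape(a) for a in alts) + "))")
    matches = []
    for seq_id in sorted(seqs):
        seq = seqs[seq_id].upper()
        for m in rx.finditer(seq):
            pat = m.group(1)
            matches.append(
                TemplateMatch(seq_id, m.start(), m.start() + len(pat),
                              by_pattern[pat].strand, pat)
            )
    return matches


def _array_intervals(seq: str, motif: TelomereMotif, min_array_copies: int) -> list[tuple[int, int]]:
    """Maximal intervals covered by >= ``min_array_copies`` exact consecutive
    motif copies, any rotation phase, either strand."""
    L = motif.length
    rotset = set(rotations(motif.g_strand)) | set(rotations(motif.c_strand))
    n = len(seq)
    intervals: list[tuple[int, int]] = []
    min_run = (min_array_copies - 1) * L  # length of the period-L self-match run
    x = L
    while x < n:
        if seq[x] == seq[x - L] and seq[x] != "N":
            run_start = x
            while x < n and seq[x] == seq[x - L] and seq[x] != "N":
                x += 1
            if x - run_start >= min_run:
                a = run_start - L
                # Chance self-matches can extend the run beyond the array
                # proper, so probe every phase at the run head for a full
                # motif rotation before accepting the interval.
                if any(seq[a + off : a + off + L] in rotset for off in range(L + 1)):
                    intervals.append((a, x))
        else:
            x += 1
    return intervals


def exclude_tandem_arrays(
    matches: list[TemplateMatch],
    seqs: dict[str, str],
    motif: TelomereMotif | str,
    min_array_copies: int = 3,
    arrays: dict[str, list[tuple[int, int]]] | None = None,
) -> list[TemplateMatch]:
    """Drop matches lying within tandem arrays of >= ``min_array_copies``
    exact motif copies. Matches adjacent to, but not inside, an array are
    kept."""
    motif = as_motif(motif)
    if arrays is None:
        arrays = {}
    kept = []
    for m in matches:
        if m.seq_id not in arrays:
            arrays[m.seq_id] = _array_intervals(seqs[m.seq_id].upper(), motif, min_array_copies)
        inside = any(a <= m.start and m.end <= b for a, b in arrays[m.seq_id])
        if not inside:
            kept.append(m)
    return kept


def _window_for(match: TemplateMatch, seq_len: int, window: int) -> tuple[int, int, bool]:
    mid = (match.start + match.end) // 2
    start = mid - window // 2
    end = start + window
    truncated = start < 0 or end > seq_len
    return max(0, start), min(seq_len, end), truncated


def merge_overlaps(loci: list[TemplateLocus]) -> list[TemplateLocus]:
    """Union overlapping or bookended windows on the same sequence.

    Member matches are concatenated in coordinate order. Idempotent and
    independent of input order.
    """
    out: list[TemplateLocus] = []
    key = lambda l: (l.genome_id, l.seq_id, l.window_start, l.window_end)
    for locus in sorted(loci, key=key):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.genome_id == locus.genome_id
            and prev.seq_id == locus.seq_id
            and locus.window_start <= prev.window_end
        ):
            prev.window_end = max(prev.window_end, locus.window_end)
            prev.matches = sorted(
                prev.matches + locus.matches, key=lambda m: (m.start, m.end, m.pattern)
            )
            prev.merged = True
            prev.truncated = prev.truncated or locus.truncated
            prev.sequence = ""
        else:
            out.append(
                TemplateLocus(
                    locus.genome_id, locus.seq_id, locus.window_start, locus.window_end,
                    list(locus.matches), locus.merged, locus.truncated, locus.sequence,
                )
            )
    return out


def scan_templates(
    seqs: dict[str, str],
    motif: TelomereMotif | str,
    window: int = 400,
    extension: int = 1,
    c_rich_only: bool = False,
    min_array_copies: int = 3,
    genome_id: str = "genome",
) -> list[TemplateLocus]:
    """Full template-locus scan of one genome: match, exclude, window, merge."""
    motif = as_motif(motif)
    patterns = template_patterns(motif, extension, c_rich_only)
    if window < len(patterns[0].pattern):
        raise ValueError("window smaller than the template pattern")
    matches = find_matches(seqs, patterns)
    arrays: dict[str, list[tuple[int, int]]] = {}
    matches = exclude_tandem_arrays(matches, seqs, motif, min_array_copies, arrays)
    loci = []
    for m in matches:
        start, end, truncated = _window_for(m, len(seqs[m.seq_id]), window)
        loci.append(TemplateLocus(genome_id, m.seq_id, start, end, [m], truncated=truncated))
    loci = merge_overlaps(loci)
    for locus in loci:
        seq = seqs[locus.seq_id][locus.window_start : locus.window_end].upper()
        # Mask tandem-array stretches inside the window (the low-complexity
        # telomeric repeat itself must not drive downstream homology).
        chars = list(seq)
        for a, b in arrays.get(locus.seq_id, ()):
            lo = max(a, locus.window_start) - locus.window_start
            hi = min(b, locus.window_end) - locus.window_start
            for x in range(lo, hi):
                chars[x] = "N"
        locus.sequence = "".join(chars)
    return loci
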