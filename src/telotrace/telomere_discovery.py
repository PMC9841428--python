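"""Infer candidate telomere motifs from raw reads and from assembly ends.

Two prediction routes mirror field practice. (1) Read tallying: short
tandem repeats are detected in every read of a shotgun data set, mapped to
their rotation/strand canonical class and ranked by supporting read count -
terminal telomere arrays dominate the top of the table because every
chromosome end contributes reads of a single repeat class. (2) Assembly
ends: terminal windows of each scaffold are compared all-vs-all; ends that
share significant sequence (a candidate telomere substitute such as a
terminal satellite) form a connected component whose shared repeat unit is
then inferred by periodicity analysis.

The tandem detector is deliberately simple and fully specified: for each
period p it finds maximal runs of self-matching positions
(seq[i] == seq[i-p], N never matches), merges runs across mismatches while
the purity stays at or above ``min_purity``, and suppresses a hit whose
interval is equally explained by a proper divisor of its period (so a poly-A
run never reports period 3, and a 10-mer array never also reports 20).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import TelomereMotif, as_motif, canonical_form, display_form, primitive_unit, revcomp


@dataclass
class TandemRepeatHit:
    source_id: str
    start: int
    end: int
    period: int
    copies: float
    consensus: str
    purity: float


def _divisors(p: int) -> list[int]:
    return [q for q in range(1, p) if p % q == 0]


def _self_match_purity(seq: str, start: int, end: int, q: int) -> float:
    span = end - start - q
    if span <= 0:
        return 0.0
    matches = sum(
        1 for x in range(start + q, end) if seq[x] == seq[x - q] and seq[x] != "N"
    )
    return matches / span


def _consensus(seq: str, start: int, end: int, p: int) -> str:
    cols: list[dict[str, int]] = [{} for _ in range(p)]
    for x in range(start, end):
        c = seq[x]
        if c == "N":
            continue
        d = cols[(x - start) % p]
        d[c] = d.get(c, 0) + 1
    out = []
    for d in cols:
        if not d:
            out.append("N")
        else:
            best = max(sorted(d), key=lambda b: d[b])  # ties -> lexicographic least
            out.append(best)
    return "".join(out)


def _runs_for_period(
    match: np.ndarray, p: int, n: int, min_copies: float, min_purity: float
) -> list[tuple[int, int, float]]:
    """Greedy left-to-right merge of match blocks into runs.

    ``match[x]`` says whether position ``x`` (x >= p) self-matches at lag p.
    Returns (start, end, purity) sequence intervals; ``start`` backs up by
    one period to include the first copy.
    """
    if not match.any():
        return []
    idx = np.flatnonzero(match)
    # block boundaries: split where consecutive True indices are not adjacent
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    starts = np.concatenate(([0], splits))
    ends = np.concatenate((splits, [len(idx)]))
    blocks = [(int(idx[s]), int(idx[e - 1]) + 1) for s, e in zip(starts, ends)]
    runs = []
    cur_start, cur_end = blocks[0]
    cur_matches = cur_end - cur_start
    for bs, be in blocks[1:]:
        new_matches = cur_matches + (be - bs)
        if new_matches / (be - cur_start) >= min_purity:
            cur_end, cur_matches = be, new_matches
        else:
            runs.append((cur_start, cur_end, cur_matches))
            cur_start, cur_end, cur_matches = bs, be, be - bs
    runs.append((cur_start, cur_end, cur_matches))
    out = []
    for rs, re_, m in runs:
        start, end = rs - p, re_
        if (end - start) / p >= min_copies and end - start >= 2 * p:
            out.append((start, end, m / (re_ - rs)))
    return out


def _single_period_hits(
    seq: str,
    p: int,
    min_copies: float,
    min_purity: float,
    source_id: str,
) -> list[TandemRepeatHit]:
    """Exact detection at one period over one sequence (the normative rule)."""
    n = len(seq)
    if n < 2 * p:
        return []
    arr = np.frombuffer(seq.encode(), dtype="S1")
    valid = arr != b"N"
    full = np.zeros(n, dtype=bool)
    full[p:] = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
    hits = []
    for start, end, purity in _runs_for_period(full, p, n, min_copies, min_purity):
        if any(
            _self_match_purity(seq, start, end, q) >= min_purity for q in _divisors(p)
        ):
            continue
        hits.append(
            TandemRepeatHit(
                source_id, start, end, p, (end - start) / p,
                _consensus(seq, start, end, p), purity,
            )
        )
    return hits


def find_tandem_repeats(
    sequence: str,
    min_period: int = 3,
    max_period: int = 25,
    min_copies: float = 3,
    min_purity: float = 0.9,
    source_id: str = "seq",
) -> list[TandemRepeatHit]:
    """Detect tandem repeats of period ``min_period``..``max_period``.

    A hit is suppressed when its interval is explained equally well (purity
    >= ``min_purity``) by a proper divisor of its period, including periods
    below ``min_period``.
    """
    if min_period > max_period:
        raise ValueError("min_period must not exceed max_period")
    seq = sequence.upper()
    hits = []
    for p in range(min_period, max_period + 1):
        hits.extend(_single_period_hits(seq, p, min_copies, min_purity, source_id))
    hits.sort(key=lambda h: (h.start, h.period))
    return hits


def _seed_block_threshold(min_period: int, max_period: int,
                          min_copies: float, min_purity: float) -> int:
    """Shortest uninterrupted self-match block that any qualifying run must
    contain (pigeonhole over the allowed mismatch count)."""
    best = None
    for p in range(min_period, max_period + 1):
        span_min = int(np.ceil(max(min_copies * p, 2 * p))) - p  # matched region length
        for span in range(span_min, span_min + 256):
            k = int((1 - min_purity) * span)
            t = int(np.ceil((span - k) / (k + 1)))
            best = t if best is None else min(best, t)
    return max(2, best)


# ---------------------------------------------------------------------------
# read tallying


def _detect_in_concat(
    reads: list[str],
    min_period: int,
    max_period: int,
    min_copies: float,
    min_purity: float,
) -> list[tuple[int, TandemRepeatHit]]:
    """Detector over a whole read set, exactly equivalent to running
    :func:`find_tandem_repeats` per read.

    Reads are joined with N separators long enough that no self-match or
    purity-feasible merge can bridge them; per period, a vectorised pass
    finds long seed blocks (every qualifying run must contain one), and the
    exact single-period detector then runs on just the implicated reads.
    """
    sep = "N" * (2 * max_period)
    offsets = np.empty(len(reads), dtype=np.int64)
    pos = 0
    for i, r in enumerate(reads):
        offsets[i] = pos
        pos += len(r) + len(sep)
    big = sep.join(r.upper() for r in reads)
    arr = np.frombuffer(big.encode(), dtype="S1")
    valid = arr != b"N"
    threshold = _seed_block_threshold(min_period, max_period, min_copies, min_purity)

    candidates: set[tuple[int, int]] = set()  # (read_index, period)
    for p in range(min_period, max_period + 1):
        match = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        idx = np.flatnonzero(match)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        starts = idx[np.concatenate(([0], splits))]
        ends = idx[np.concatenate((splits - 1, [idx.size - 1]))] + 1
        long_enough = (ends - starts) >= threshold
        for s in starts[long_enough]:
            ri = int(np.searchsorted(offsets, s, side="right") - 1)
            candidates.add((ri, p))

    out = []
    for ri, p in sorted(candidates):
        for hit in _single_period_hits(
            reads[ri].upper(), p, min_copies, min_purity, f"read{ri}"
        ):
            out.append((ri, hit))
    return out


@dataclass
class MotifTally:
    """Ranked table of canonical tandem-repeat classes found in reads."""

    table: pd.DataFrame  # columns: motif (canonical), display, count, base_fraction
    total_bases: int = 0

    @property
    def empty(self) -> bool:
        return self.table.empty

    def top(self) -> str | None:
        return None if self.empty else str(self.table.iloc[0]["motif"])


def tally_read_motifs(
    reads: list[str] | list[tuple[str, str]],
    min_period: int = 3,
    max_period: int = 25,
    min_copies: float = 3,
    min_purity: float = 0.9,
    min_run_length: int = 25,
) -> MotifTally:
    """Aggregate tandem hits over a read set into a ranked motif tally.

    Accepts plain reads or (mate1, mate2) pairs; each hit consensus is
    reduced to its primitive unit and mapped to the rotation/strand
    canonical class. Rows sort by supporting hit count descending, ties
    lexicographically. Deterministic and independent of read order.

    ``min_run_length`` floors the tallied run length (default 25 nt,
    the equivalent of Tandem Repeats Finder's default minimum alignment
    score of 50 at +2 per matching base): without it, chance 9-nt
    microsatellite runs across hundreds of thousands of reads would
    drown the telomeric classes.
    """
    if reads and isinstance(reads[0], tuple):
        flat = [r for pair in reads for r in pair]
    else:
        flat = list(reads)
    if not flat:
        warnings.warn("empty read set: returning empty tally")
        return MotifTally(pd.DataFrame(columns=["motif", "display", "count", "base_fraction"]))
    total_bases = sum(len(r) for r in flat)
    counts: dict[str, int] = {}
    bases: dict[str, int] = {}
    for _, hit in _detect_in_concat(flat, min_period, max_period, min_copies, min_purity):
        if hit.end - hit.start < min_run_length:
            continue
        unit = primitive_unit(hit.consensus)
        if "N" in unit:
            continue
        canon = canonical_form(unit)
        counts[canon] = counts.get(canon, 0) + 1
        bases[canon] = bases.get(canon, 0) + (hit.end - hit.start)
    rows = [
        {
            "motif": canon,
            "display": display_form(canon),
            "count": counts[canon],
            "base_fraction": bases[canon] / total_bases,
        }
        for canon in counts
    ]
    df = pd.DataFrame(rows, columns=["motif", "display", "count", "base_fraction"])
    if not df.empty:
        df = df.sort_values(["count", "motif"], ascending=[False, True], ignore_index=True)
    return MotifTally(df, total_bases)


# ---------------------------------------------------------------------------
# assembly ends


@dataclass
class TerminalWindow:
    scaffold_id: str
    end: str  # '5p' | '3p'
    start: int
    stop: int
    sequence: str
    truncated: bool = False
    overlapping: bool = False

    @property
    def label(self) -> str:
        return f"{self.scaffold_id}:{self.end}"


def terminal_windows(assembly: dict[str, str], end_length: int) -> list[TerminalWindow]:
    """Two windows per scaffold (5' and 3'), truncated and flagged when the
    scaffold is shorter than twice the window."""
    if end_length < 1:
        raise ValueError("end_length must be >= 1")
    out = []
    for sid in sorted(assembly):
        seq = assembly[sid]
        n = len(seq)
        w = min(end_length, n)
        overlapping = n < 2 * end_length
        truncated = n < end_length
        out.append(TerminalWindow(sid, "5p", 0, w, seq[:w], truncated, overlapping))
        out.append(TerminalWindow(sid, "3p", n - w, n, seq[n - w :], truncated, overlapping))
    return out


@dataclass
class SharedEndRepeat:
    """A repeat shared by several scaffold ends (candidate telomere
    substitute). ``unit`` is None when the shared segment has no
    periodicity."""

    ends: list[str] = field(default_factory=list)
    unit: str | None = None
    unit_length: int | None = None
    canonical: str | None = None

    @property
    def empty(self) -> bool:
        return not self.ends


def shared_end_repeat(
    assembly: dict[str, str],
    end_length: int = 2000,
    min_shared_ends: int = 2,
    evalue_max: float = 1e-10,
    max_unit_period: int = 200,
    prefilter_k: int = 11,
) -> SharedEndRepeat:
    """Find the repeat shared by the largest set of scaffold ends.

    All-vs-all local alignment of terminal windows (k-mer-seeded), connected
    components over significant hits, then repeat-unit inference inside the
    winning component via the tandem detector with an extended period range.
    """
    from .homology_filter import kmer_set, local_align, shares_seed

    if len(assembly) < 2:
        raise ValueError("need at least two scaffolds")
    wins = terminal_windows(assembly, end_length)
    kmers = [kmer_set(w.sequence, prefilter_k) | kmer_set(revcomp(w.sequence), prefilter_k)
             for w in wins]
    parent = list(range(len(wins)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(wins)):
        for j in range(i + 1, len(wins)):
            if wins[i].scaffold_id == wins[j].scaffold_id:
                continue
            if not shares_seed(wins[i].sequence, kmers[j], prefilter_k):
                continue
            hit = local_align(wins[i].sequence, wins[j].sequence, wins[i].label, wins[j].label)
            if hit.evalue <= evalue_max:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, list[int]] = {}
    for i in range(len(wins)):
        comps.setdefault(find(i), []).append(i)
    big = max(comps.values(), key=len)
    if len(big) < min_shared_ends or len(big) < 2:
        return SharedEndRepeat()
    ends = sorted(wins[i].label for i in big)

    unit_votes: dict[str, int] = {}
    best_units: dict[str, str] = {}
    for i in big:
        hits = find_tandem_repeats(
            wins[i].sequence, min_period=3, max_period=max_unit_period, source_id=wins[i].label
        )
        if not hits:
            continue
        top = max(hits, key=lambda h: h.end - h.start)
        canon = canonical_form(primitive_unit(top.consensus))
        unit_votes[canon] = unit_votes.get(canon, 0) + (top.end - top.start)
        best_units.setdefault(canon, primitive_unit(top.consensus))
    if not unit_votes:
        return SharedEndRepeat(ends=ends)
    canon = max(sorted(unit_votes), key=lambda c: unit_votes[c])
    unit = best_units[canon]
    return SharedEndRepeat(ends=ends, unit=unit, unit_length=len(unit), canonical=canon)
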