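"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written as directly as possible from the definitions -
full-matrix dynamic programming, position-by-position scanning - and shares
no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def gotoh_local(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Affine-gap local alignment optimum, full O(mn) matrices.

    A gap of length k costs gap_open + k * gap_extend. ``score(x, y)`` gives
    the substitution score.
    """
    m, n = len(a), len(b)
    neg = -1e9
    M = np.zeros((m + 1, n + 1))
    X = np.full((m + 1, n + 1), neg)  # gap in b (consume a)
    Y = np.full((m + 1, n + 1), neg)  # gap in a (consume b)
    best = 0.0
    # cost(k) = open + k*extend: the first gapped position costs
    # open + extend, each further one extend.
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - gap_extend)
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + score(a[i - 1], b[j - 1]),
                X[i][j],
                Y[i][j],
            )
            if M[i][j] > best:
                best = M[i][j]
    return best


def dna_score(x: str, y: str) -> float:
    return 2.0 if (x == y and x != "N") else -3.0


def dna_local(a: str, b: str, both_strands: bool = True) -> float:
    s = gotoh_local(a, b, dna_score, 5.0, 2.0)
    if both_strands:
        s = max(s, gotoh_local(a, rc(b), dna_score, 5.0, 2.0))
    return s


def blosum_local(a: str, b: str) -> float:
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    return gotoh_local(a, b, lambda x, y: float(bl[x, y]), 11.0, 1.0)


# ---------------------------------------------------------------------------
# tandem repeat detection (naive transliteration of the normative rule)


def naive_tandem_hits(seq, min_period=3, max_period=25, min_copies=3, min_purity=0.9):
    """Position-by-position re-derivation of the tandem-run definition."""
    seq = seq.upper()
    n = len(seq)
    hits = []
    for p in range(min_period, max_period + 1):
        if n < 2 * p:
            continue
        good = [
            x >= p and seq[x] == seq[x - p] and seq[x] != "N" and seq[x - p] != "N"
            for x in range(n)
        ]
        # maximal blocks of consecutive good positions
        blocks = []
        x = 0
        while x < n:
            if good[x]:
                y = x
                while y < n and good[y]:
                    y += 1
                blocks.append((x, y))
                x = y
            else:
                x += 1
        # greedy merge while purity holds
        runs = []
        if blocks:
            cs, ce = blocks[0]
            cm = ce - cs
            for bs, be in blocks[1:]:
                nm = cm + (be - bs)
                if nm / (be - cs) >= min_purity:
                    ce, cm = be, nm
                else:
                    runs.append((cs, ce, cm))
                    cs, ce, cm = bs, be, be - bs
            runs.append((cs, ce, cm))
        for rs, re_, mt in runs:
            start, end = rs - p, re_
            if (end - start) / p < min_copies or end - start < 2 * p:
                continue
            # divisor suppression
            suppressed = False
            for q in range(1, p):
                if p % q:
                    continue
                span = end - start - q
                mq = sum(
                    1
                    for x in range(start + q, end)
                    if seq[x] == seq[x - q] and seq[x] != "N"
                )
                if span > 0 and mq / span >= min_purity:
                    suppressed = True
                    break
            if suppressed:
                continue
            cons = []
            for c in range(p):
                votes = {}
                for x in range(start + c, end, p):
                    if seq[x] != "N":
                        votes[seq[x]] = votes.get(seq[x], 0) + 1
                cons.append(max(sorted(votes), key=lambda b: votes[b]) if votes else "N")
            hits.append(
                dict(start=start, end=end, period=p, consensus="".join(cons),
                     purity=mt / (re_ - rs))
            )
    hits.sort(key=lambda h: (h["start"], h["period"]))
    return hits


# ---------------------------------------------------------------------------
# template scanning (string-method based, windows + exclusion + merging)


def _rotations(u: str) -> list[str]:
    return [(u + u)[i : i + len(u)] for i in range(len(u))]


def naive_patterns(motif: str, extension: int = 1, c_rich_only: bool = False):
    g = motif.upper()
    c = rc(g)
    units = [c] if c_rich_only else [g, c]
    pats = []
    for u in units:
        for i in range(len(u)):
            pat = (u * 3)[i : i + len(u) + extension]
            if pat not in pats:
                pats.append(pat)
    return pats


def naive_array_intervals(seq: str, motif: str, min_copies: int = 3):
    """Maximal period-L self-match runs whose head carries a motif rotation."""
    L = len(motif)
    rots = set(_rotations(motif.upper())) | set(_rotations(rc(motif.upper())))
    n = len(seq)
    out = []
    x = L
    while x < n:
        if seq[x] == seq[x - L] and seq[x] != "N" and seq[x - L] != "N":
            y = x
            while y < n and seq[y] == seq[y - L] and seq[y] != "N" and seq[y - L] != "N":
                y += 1
            if y - x >= (min_copies - 1) * L:
                a = x - L
                if any(seq[a + off : a + off + L] in rots for off in range(L + 1)):
                    out.append((a, y))
            x = y
        else:
            x += 1
    return out


def naive_scan(seqs: dict[str, str], motif: str, window=400, extension=1,
               min_array_copies=3):
    """Full naive re-derivation of the template-locus scan.

    Returns per-sequence lists of (window_start, window_end, matches,
    masked_window) where matches are (start, end, pattern) triples.
    """
    pats = naive_patterns(motif, extension)
    result = {}
    for sid in sorted(seqs):
        seq = seqs[sid].upper()
        matches = []
        for pat in pats:
            i = seq.find(pat)
            while i >= 0:
                matches.append((i, i + len(pat), pat))
                i = seq.find(pat, i + 1)
        matches = sorted(set(matches))
        arrays = naive_array_intervals(seq, motif, min_array_copies)
        matches = [
            m for m in matches
            if not any(a <= m[0] and m[1] <= b for a, b in arrays)
        ]
        wins = []
        for s, e, pat in matches:
            mid = (s + e) // 2
            ws, we = max(0, mid - window // 2), min(len(seq), mid - window // 2 + window)
            wins.append((ws, we, [(s, e, pat)]))
        wins.sort()
        merged = []
        for ws, we, ms in wins:
            if merged and ws <= merged[-1][1]:
                pw, pe, pm = merged[-1]
                merged[-1] = (pw, max(pe, we), pm + ms)
            else:
                merged.append((ws, we, list(ms)))
        final = []
        for ws, we, ms in merged:
            chars = list(seq[ws:we])
            for a, b in arrays:
                for x in range(max(a, ws), min(b, we)):
                    chars[x - ws] = "N"
            final.append((ws, we, sorted(ms), "".join(chars)))
        result[sid] = final
    return result
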