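"""Type 3 snRNA promoter discovery, annotation and RNAP classification.

Insect snRNA genes carry an external ("type 3") promoter built from a
conserved proximal sequence element A (PSEA) plus either a PSEB (RNA
polymerase II genes) or a TATA box (RNA polymerase III genes). A TR
candidate whose upstream region shows PSEA + TATA without PSEB is therefore
classified as a pol III transcript - the decisive biogenesis signature this
pipeline tests for.

Motif models are position probability matrices. PSEA (and optionally PSEB)
are learned from known snRNA upstream regions by one-occurrence-per-sequence
expectation-maximisation over start positions (best of ``n_starts`` seeded
restarts by log-likelihood); the TATA model defaults to a fixed
consensus-derived TATAWAWR matrix scanned in a window upstream of the
expected transcription start. Score thresholds default to the minimum
log-odds among training sites, mirroring the use of known snRNA promoters
as positive controls.

The promoter-first mode inverts the search: every genomic PSEA hit is
extended 400 nt downstream and kept only if a C-rich-strand template
pattern of the telomere motif occurs in the extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import revcomp
from .template_scan import template_patterns

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class MotifModel:
    """A position probability matrix with log-odds scoring."""

    label: str  # PSEA | PSEB | TATA
    matrix: np.ndarray  # shape (width, 4), rows sum to 1
    background: np.ndarray  # shape (4,)
    threshold: float  # minimum log2-odds score to call a hit

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (uniform background)."""
        m = self.matrix
        return 2 + (m * np.log2(np.where(m > 0, m, 1))).sum(axis=1)

    def scan(self, seq: str) -> np.ndarray:
        """Log2-odds score at every start position (NaN where N occurs)."""
        enc = _encode(seq)
        w = self.width
        n = len(enc) - w + 1
        if n <= 0:
            return np.empty(0)
        lo = self.log_odds
        scores = np.zeros(n)
        bad = np.zeros(n, dtype=bool)
        for j in range(w):
            col = enc[j : j + n]
            ok = col >= 0
            bad |= ~ok
            scores += np.where(ok, lo[j, np.clip(col, 0, 3)], 0.0)
        scores[bad] = -np.inf
        return scores

    def best_hit(self, seq: str) -> tuple[int, float] | None:
        scores = self.scan(seq)
        if scores.size == 0:
            return None
        i = int(scores.argmax())
        if scores[i] < self.threshold or not np.isfinite(scores[i]):
            return None
        return i, float(scores[i])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\tA\tC\tG\tT\n")
            for i, row in enumerate(self.matrix):
                fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def sequence_background(sequences: list[str]) -> np.ndarray:
    counts = np.ones(4)
    for s in sequences:
        enc = _encode(s)
        for i in range(4):
            counts[i] += (enc == i).sum()
    return counts / counts.sum()


def discover_motif(
    sequences: list[str],
    width: int,
    n_starts: int = 20,
    seed: int = 0,
    label: str = "PSEA",
    pseudocount: float = 0.5,
    n_iter: int = 60,
) -> tuple[MotifModel, list[tuple[int, float]]]:
    """One-occurrence-per-sequence EM motif discovery.

    Each sequence is assumed to contain exactly one motif site; EM iterates
    a posterior over start positions and a probability-matrix update. The
    best of ``n_starts`` seeded random initialisations by training
    log-likelihood is kept (ties by lower start index). Returns the model
    and the per-sequence best site (position, log-odds score); the model
    threshold is the minimum of those site scores.
    """
    if len(sequences) < 5:
        raise ValueError("need at least 5 training sequences for a stable motif model")
    if any(len(s) < width for s in sequences):
        raise ValueError("every training sequence must be at least motif width long")
    enc = [_encode(s) for s in sequences]
    bg = sequence_background(sequences)
    log_bg = np.log(bg)
    rng = np.random.default_rng(seed)

    # Per sequence: matrix of window base indices (n_windows x width), with
    # N recoded to a 5th "base" that scores zero and adds no counts.
    windows = []
    for e in enc:
        n = len(e) - width + 1
        W = np.lib.stride_tricks.sliding_window_view(e, width).copy()
        W[W < 0] = 4
        windows.append(W)
    jidx = np.arange(width)

    def site_matrix(positions: list[int]) -> np.ndarray:
        counts = np.full((width, 4), pseudocount)
        for e, p in zip(enc, positions):
            win = e[p : p + width]
            for j, c in enumerate(win):
                if c >= 0:
                    counts[j, c] += 1
        return counts / counts.sum(axis=1, keepdims=True)

    def em_from(start_positions: list[int]) -> tuple[float, np.ndarray]:
        mat = site_matrix(start_positions)
        ll_prev = -np.inf
        for _ in range(n_iter):
            lo5 = np.zeros((width, 5))
            lo5[:, :4] = np.log(mat) - log_bg[None, :]
            counts = np.full((width, 5), pseudocount)
            ll = 0.0
            for W in windows:
                scores = lo5[jidx[None, :], W].sum(axis=1)
                m = scores.max()
                w_post = np.exp(scores - m)
                z = w_post.sum()
                ll += m + np.log(z)
                w_post /= z
                np.add.at(counts, (jidx[None, :], W), w_post[:, None])
            mat = counts[:, :4] / counts[:, :4].sum(axis=1, keepdims=True)
            if abs(ll - ll_prev) < 1e-8:
                break
            ll_prev = ll
        return ll, mat

    best = None
    for s in range(n_starts):
        starts = [int(rng.integers(0, len(e) - width + 1)) for e in enc]
        ll, mat = em_from(starts)
        if best is None or ll > best[0] + 1e-9:
            best = (ll, mat)
    model = MotifModel(label, best[1], bg, threshold=-np.inf)
    sites = []
    for s in sequences:
        scores = model.scan(s)
        i = int(np.nanargmax(scores))
        sites.append((i, float(scores[i])))
    model.threshold = min(score for _, score in sites)
    return model, sites


def tata_default_model(threshold: float = 8.0) -> MotifModel:
    """Fixed consensus-derived TATAWAWR matrix (W = A/T, R = A/G)."""
    rows = []
    for sym in "TATAWAWR":
        p = np.full(4, 0.02)
        if sym in "ACGT":
            p["ACGT".index(sym)] = 0.94
        elif sym == "W":
            p[[0, 3]] = 0.47
        elif sym == "R":
            p[[0, 2]] = 0.47
        rows.append(p)
    return MotifModel("TATA", np.array(rows), np.full(4, 0.25), threshold)


# ---------------------------------------------------------------------------
# per-locus annotation


@dataclass
class PromoterAnnotation:
    """Promoter elements found upstream of one locus.

    Positions are relative to the locus 5' start on the transcribed strand
    (negative = upstream); each element is ``(position, score)`` or None.
    """

    psea: tuple[int, float] | None = None
    pseb: tuple[int, float] | None = None
    tata: tuple[int, float] | None = None
    psea_tata_spacing: int | None = None
    psea_pseb_spacing: int | None = None
    pol_class: str = "none"
    conflict: bool = False
    truncated: bool = False


@dataclass
class UpstreamRegion:
    sequence: str
    seq_id: str
    locus_start: int
    strand: str
    truncated: bool = False


def upstream_regions(
    loci: list[tuple[str, int, int, str]],
    seqs: dict[str, str],
    flank: int = 200,
) -> list[UpstreamRegion]:
    """5' flanking region of each (seq_id, start, end, strand) locus on the
    transcribed strand, truncated (and flagged) at contig edges."""
    out = []
    for seq_id, start, end, strand in loci:
        seq = seqs[seq_id]
        if strand == "+":
            lo = max(0, start - flank)
            region = seq[lo:start]
            truncated = start - flank < 0
        else:
            hi = min(len(seq), end + flank)
            region = revcomp(seq[end:hi])
            truncated = end + flank > len(seq)
        out.append(UpstreamRegion(region.upper(), seq_id, start, strand, truncated))
    return out


def annotate_promoter(
    sequence: str,
    models: dict[str, MotifModel],
    tss_offset: int = 50,
    tata_window: tuple[int, int] = (-45, -15),
    truncated: bool = False,
) -> PromoterAnnotation:
    """Annotate PSEA/PSEB/TATA on one upstream region.

    ``sequence`` is the upstream flank on the transcribed strand; reported
    positions are relative to the locus start (so always negative within
    the region). The TATA search is restricted to ``tata_window`` around
    the expected transcription start (PSEA 3' end + ``tss_offset``) when a
    PSEA hit anchors it; missing models simply yield absent elements.
    """
    ann = PromoterAnnotation(truncated=truncated)
    n = len(sequence)
    rel = lambda pos: pos - n

    psea_model = models.get("PSEA")
    if psea_model is not None and n >= psea_model.width:
        hit = psea_model.best_hit(sequence)
        if hit is not None:
            ann.psea = (rel(hit[0]), hit[1])

    pseb_model = models.get("PSEB")
    if pseb_model is not None and n >= pseb_model.width:
        if ann.psea is not None:
            # PSEB sits between PSEA and the TSS
            start = ann.psea[0] + n + psea_model.width
            sub = sequence[start:]
            hit = pseb_model.best_hit(sub) if len(sub) >= pseb_model.width else None
            if hit is not None:
                ann.pseb = (rel(start + hit[0]), hit[1])
        else:
            hit = pseb_model.best_hit(sequence)
            if hit is not None:
                ann.pseb = (rel(hit[0]), hit[1])

    tata_model = models.get("TATA")
    if tata_model is not None and n >= tata_model.width:
        if ann.psea is not None:
            tss = ann.psea[0] + n + psea_model.width + tss_offset
            lo = max(0, tss + tata_window[0])
            hi = min(n, tss + tata_window[1] + tata_model.width)
        else:
            lo, hi = 0, n
        sub = sequence[lo:hi]
        hit = tata_model.best_hit(sub) if len(sub) >= tata_model.width else None
        if hit is not None:
            ann.tata = (rel(lo + hit[0]), hit[1])

    if ann.psea is not None and ann.tata is not None:
        ann.psea_tata_spacing = ann.tata[0] - (ann.psea[0] + psea_model.width)
    if ann.psea is not None and ann.pseb is not None:
        ann.psea_pseb_spacing = ann.pseb[0] - (ann.psea[0] + psea_model.width)
    ann.pol_class = classify_polymerase(ann)
    return ann


def classify_polymerase(ann: PromoterAnnotation) -> str:
    """PSEA+PSEB -> pol2; PSEA+TATA (no PSEB) -> pol3; PSEA alone ->
    ambiguous; no PSEA -> none. PSEB takes precedence over TATA (the
    all-three case is pol2 with a conflict flag)."""
    if ann.psea is None:
        return "none"
    if ann.pseb is not None:
        ann.conflict = ann.tata is not None
        return "pol2"
    if ann.tata is not None:
        return "pol3"
    return "ambiguous"


# ---------------------------------------------------------------------------
# promoter-first TR prediction


@dataclass
class PromoterFirstCandidate:
    seq_id: str
    strand: str
    psea_pos: int  # forward-strand coordinate of the PSEA hit start
    psea_score: float
    window_start: int
    window_end: int
    template_pos: int  # offset of the template match within the window
    template_pattern: str
    tata: tuple[int, float] | None = None


def promoter_first_scan(
    seqs: dict[str, str],
    psea_model: MotifModel,
    telomere_motif,
    downstream: int = 400,
    tata_model: MotifModel | None = None,
    extension: int = 1,
    tss_offset: int = 50,
) -> list[PromoterFirstCandidate]:
    """Promoter-first TR prediction (telomere motif known, no homologs).

    Every genomic PSEA hit above threshold (both strands) is extended
    ``downstream`` nt on the hit strand; a candidate is emitted iff a
    C-rich-strand template pattern occurs within the extension. TATA
    presence in the expected window is annotated. Output is ordered by
    PSEA score, descending.
    """
    patterns = [p.pattern for p in template_patterns(telomere_motif, extension, c_rich_only=True)]
    cands = []
    for seq_id in sorted(seqs):
        fwd = seqs[seq_id].upper()
        n = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            scores = psea_model.scan(seq)
            for i in np.flatnonzero(scores >= psea_model.threshold):
                i = int(i)
                w_start = i + psea_model.width
                window = seq[w_start : w_start + downstream]
                t_hit = None
                for pat in patterns:
                    j = window.find(pat)
                    if j >= 0 and (t_hit is None or j < t_hit[0]):
                        t_hit = (j, pat)
                if t_hit is None:
                    continue
                tata = None
                if tata_model is not None:
                    tss = w_start + tss_offset
                    lo, hi = max(0, tss - 45), min(n, tss - 15 + tata_model.width)
                    sub = seq[lo:hi]
                    hit = tata_model.best_hit(sub) if len(sub) >= tata_model.width else None
                    if hit is not None:
                        tata = (lo + hit[0] - tss, hit[1])
                psea_fwd = i if strand == "+" else n - i - psea_model.width
                cands.append(
                    PromoterFirstCandidate(
                        seq_id, strand, psea_fwd, float(scores[i]),
                        w_start if strand == "+" else max(0, n - w_start - downstream),
                        min(w_start + downstream, n) if strand == "+" else n - w_start,
                        t_hit[0], t_hit[1], tata,
                    )
                )
    cands.sort(key=lambda c: (-c.psea_score, c.seq_id, c.psea_pos))
    return cands
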