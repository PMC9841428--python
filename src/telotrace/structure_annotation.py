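"""Comparative annotation of the TR core on a multiple sequence alignment.

A functional telomerase RNA core consists of the template, a template
boundary element (TBE / P1.1) immediately 5' of it, a pseudoknot formed by
two interleaved stems (P2 and P3) 3' of it, and a long-range stem (P1c)
closing the whole region. The joining loop between the P2 and P3 5' arms
(J2/3) carries invariant U residues essential for catalysis. Annotation
here is purely comparative - no thermodynamic folding: a column pair is a
stem pair when at least 90% of non-gap rows are Watson-Crick or G-U
complementary, and covariation (at least two distinct complementary pair
types at such a pair) is scored as independent evidence.

T and U are interchangeable; rows gapped at either column of a pair are
excluded from that pair's denominator, and columns with more than 50% gaps
are never paired. The pseudoknot constraint is the interleaving
P2 = (a, c), P3 = (b, d) with a < b < c < d on column indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _norm(base: str) -> str:
    b = base.upper()
    return "T" if b == "U" else b


@dataclass
class CoreMSA:
    """A gapped alignment of TR core sequences with a known template range."""

    ids: list[str]
    rows: list[str]
    template_columns: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows have unequal lengths")
        self.rows = ["".join(_norm(c) if c != "-" else "-" for c in r) for r in self.rows]
        t0, t1 = self.template_columns
        if not (0 <= t0 < t1 <= self.n_columns):
            raise ValueError("template_columns outside the alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]

    @classmethod
    def from_fasta(cls, path, template_columns: tuple[int, int]) -> "CoreMSA":
        ids, rows = [], []
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        ids.append(name)
                        rows.append("".join(chunks))
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if name is not None:
            ids.append(name)
            rows.append("".join(chunks))
        return cls(ids, rows, template_columns)


@dataclass
class Stem:
    pairs: list[tuple[int, int]]  # (5' column, 3' column), consecutive, antiparallel
    score: float = 0.0
    covariant: list[tuple[int, int]] = field(default_factory=list)

    @property
    def arm5(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0] + 1)

    @property
    def arm3(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1] + 1)


@dataclass
class StructureAnnotation:
    p1c: list[tuple[int, int]] = field(default_factory=list)
    p1_1: list[tuple[int, int]] = field(default_factory=list)
    p2: list[tuple[int, int]] = field(default_factory=list)
    p3: list[tuple[int, int]] = field(default_factory=list)
    j2_3: tuple[int, int] | None = None
    conservation: list[str] = field(default_factory=list)
    invariant_U_in_J23: bool = False
    diagnostics: dict = field(default_factory=dict)

    def stems(self) -> dict[str, list[tuple[int, int]]]:
        return {"p1c": self.p1c, "p1_1": self.p1_1, "p2": self.p2, "p3": self.p3}


def _pair_stats(msa: CoreMSA, i: int, j: int) -> tuple[float, int, int]:
    """(complementary fraction among rows non-gap at both columns,
    number of distinct complementary pair types, non-gap row count)."""
    types = set()
    comp = 0
    n = 0
    for r in msa.rows:
        a, b = r[i], r[j]
        if a == "-" or b == "-":
            continue
        n += 1
        if (a, b) in _PAIRS:
            comp += 1
            types.add((a, b))
    return (comp / n if n else 0.0, len(types), n)


def covariation_test(
    msa: CoreMSA,
    col_i: int,
    col_j: int,
    min_pair_fraction: float = 0.9,
    min_pair_types: int = 2,
) -> bool:
    """Covariation = complementarity maintained through sequence change:
    the pair must be complementary in >= ``min_pair_fraction`` of non-gap
    rows AND realised by >= ``min_pair_types`` distinct pair types."""
    if col_i >= col_j:
        raise ValueError("col_i must be 5' of col_j")
    frac, types, n = _pair_stats(msa, col_i, col_j)
    return n > 0 and frac >= min_pair_fraction and types >= min_pair_types


def _gap_fraction(msa: CoreMSA, i: int) -> float:
    col = msa.column(i)
    return col.count("-") / len(col)


def _pairable_matrix(msa: CoreMSA, min_pair_fraction: float = 0.9) -> np.ndarray:
    """Boolean matrix P[i, j]: columns i < j satisfy the pairing criterion."""
    n = msa.n_columns
    ok_col = np.array([_gap_fraction(msa, i) <= 0.5 for i in range(n)])
    P = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if not ok_col[i]:
            continue
        for j in range(i + 1, n):
            if not ok_col[j]:
                continue
            frac, _, nn = _pair_stats(msa, i, j)
            P[i, j] = nn > 0 and frac >= min_pair_fraction
    return P


def conservation_classes(
    msa: CoreMSA,
    stems: list[list[tuple[int, int]]] | None = None,
    max_gap_fraction: float = 0.1,
) -> list[str]:
    """Per-column class: invariant (one base in 100% of non-gap rows, gaps
    <= 10%), covariant (stem column whose pair passes the covariation
    test), conserved90 (modal base strictly > 90%), else variable."""
    covariant_cols = set()
    for stem in stems or []:
        for i, j in stem:
            if covariation_test(msa, i, j):
                covariant_cols.update((i, j))
    classes = []
    for i in range(msa.n_columns):
        col = [c for c in msa.column(i) if c != "-"]
        gap_frac = _gap_fraction(msa, i)
        if col and len(set(col)) == 1 and gap_frac <= max_gap_fraction:
            classes.append("invariant")
            continue
        if i in covariant_cols:
            classes.append("covariant")
            continue
        if col:
            modal = max(set(col), key=col.count)
            if col.count(modal) / len(col) > 0.9:
                classes.append("conserved90")
                continue
        classes.append("variable")
    return classes


def _blocks_between(
    P: np.ndarray,
    msa: CoreMSA,
    region5: tuple[int, int],
    region3: tuple[int, int],
    min_len: int,
) -> list[Stem]:
    """All maximal antiparallel blocks of consecutive pairable columns with
    the 5' column in region5 and the 3' column in region3."""
    a0, a1 = region5
    b0, b1 = region3
    blocks = []
    seen = set()
    for i in range(a0, a1):
        for j in range(b1 - 1, b0 - 1, -1):
            if j <= i or not P[i, j] or (i, j) in seen:
                continue
            pairs = []
            x, y = i, j
            while x < a1 and y >= b0 and x < y and P[x, y]:
                pairs.append((x, y))
                seen.add((x, y))
                x += 1
                y -= 1
            if len(pairs) >= min_len:
                cov = [p for p in pairs if covariation_test(msa, *p)]
                blocks.append(Stem(pairs, float(len(pairs) + len(cov)), cov))
    return blocks


def find_stem(
    msa: CoreMSA,
    region5: tuple[int, int],
    region3: tuple[int, int],
    min_len: int = 3,
    P: np.ndarray | None = None,
) -> Stem | None:
    """Best-scoring antiparallel block pairing region5 against region3.

    Score = pair count + 1 bonus per covariant pair; ties resolved in
    favour of the 5'-most (then outermost) block. Regions may coincide for
    hairpin search. Returns None when no block reaches ``min_len``.
    """
    if P is None:
        P = _pairable_matrix(msa)
    blocks = _blocks_between(P, msa, region5, region3, min_len)
    if not blocks:
        return None
    return min(blocks, key=lambda s: (-s.score, s.pairs[0][0], -s.pairs[0][1]))


def annotate_core(
    msa: CoreMSA,
    min_stem_len: int = 3,
    min_pair_fraction: float = 0.9,
) -> StructureAnnotation:
    """Annotate P1c, P1.1 (TBE), the P2/P3 pseudoknot and J2/3 on a core MSA.

    Search order: P1c pairs the extreme 5' flank against the extreme 3'
    flank; P1.1 is a short hairpin immediately 5' of the template (3'-most
    candidate on ties); P2 and P3 are the best-scoring interleaved stem
    pair (a < b < c < d) 3' of the template, inside P1c when present.
    Missing elements yield per-element diagnostics, never exceptions.
    """
    ann = StructureAnnotation()
    t0, t1 = msa.template_columns
    n = msa.n_columns
    P = _pairable_matrix(msa, min_pair_fraction)

    p1c = find_stem(msa, (0, t0), (t1, n), min_stem_len, P=P)
    if p1c is not None:
        ann.p1c = p1c.pairs
        inner5_end = t0
        inner5_start = p1c.arm5[1]
        inner3 = (t1, p1c.arm3[0])
    else:
        ann.diagnostics["p1c"] = "no long-range stem pairing the 5' and 3' flanks"
        inner5_start, inner5_end = 0, t0
        inner3 = (t1, n)

    p11 = None
    if inner5_end - inner5_start >= 2 * min_stem_len:
        blocks = _blocks_between(P, msa, (inner5_start, inner5_end),
                                 (inner5_start, inner5_end), min_stem_len)
        if blocks:
            # "immediately 5' of the template": prefer the 3'-most block
            p11 = min(blocks, key=lambda s: (-s.score, -s.pairs[0][0]))
    if p11 is not None:
        ann.p1_1 = p11.pairs
    else:
        ann.diagnostics["p1_1"] = "no hairpin 5' of the template"

    # Pseudoknot: two interleaved stems 3' of the template.
    r0, r1 = inner3
    blocks = _blocks_between(P, msa, (r0, r1), (r0, r1), min_stem_len)
    best_combo = None
    for s1 in blocks:
        for s2 in blocks:
            if s1 is s2:
                continue
            a0, a1 = s1.arm5
            c0, c1 = s1.arm3
            b0, b1 = s2.arm5
            d0, d1 = s2.arm3
            if not (a1 <= b0 and b1 <= c0 and c1 <= d0):
                continue  # interleaving a < b < c < d
            score = s1.score + s2.score
            key = (-score, a0, b0)
            if best_combo is None or key < best_combo[0]:
                best_combo = (key, s1, s2)
    if best_combo is not None:
        _, p2, p3 = best_combo
        ann.p2, ann.p3 = p2.pairs, p3.pairs
        ann.j2_3 = (p2.arm5[1], p3.arm5[0])
    else:
        ann.diagnostics["pseudoknot"] = "no interleaved stem pair 3' of the template"

    ann.conservation = conservation_classes(
        msa, [s for s in (ann.p1c, ann.p1_1, ann.p2, ann.p3) if s]
    )
    if ann.j2_3 is not None:
        for c in range(*ann.j2_3):
            col = [x for x in msa.column(c) if x != "-"]
            if ann.conservation[c] == "invariant" and col and col[0] == "T":
                ann.invariant_U_in_J23 = True
                break
    return ann


def dot_bracket(ann: StructureAnnotation, n_columns: int) -> str:
    """Consensus structure string: '()' for nested stems, '[]' for the
    pseudoknotted P3."""
    s = ["."] * n_columns
    for stem, op, cl in ((ann.p1c, "(", ")"), (ann.p1_1, "(", ")"),
                         (ann.p2, "(", ")"), (ann.p3, "[", "]")):
        for i, j in stem:
            s[i], s[j] = op, cl
    return "".join(s)


def classes_to_tsv(classes: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tclass\n")
        for i, c in enumerate(classes):
            fh.write(f"{i}\t{c}\n")


def stems_to_tsv(ann: StructureAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("element\tcol5\tcol3\n")
        for name, pairs in ann.stems().items():
            for i, j in pairs:
                fh.write(f"{name}\t{i}\t{j}\n")
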