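"""Synthetic genomes with planted, labelled telomere/TR/snRNA/TERT features.

Every downstream stage of the discovery pipeline is exercised on genomes
built here: chromosome-terminal telomere arrays (G-rich strand pointing at
the chromosome end), interstitial telomeric repeats, decoy template-like
loci in genome-specific random context, a planted TR gene whose template
region tracks each genome's telomere motif (including the single-base
G->C motif mutation logic seen between close relatives), pol II / pol III
style snRNA genes with PSEA+PSEB resp. PSEA+TATA promoters, an optional
TERT-like open reading frame, an optional terminal satellite, and shotgun
paired-end read sets.

Background sequence is i.i.d. at a configurable GC fraction: the simplest
null under which decoy loci are discoverable within one genome but not
conserved across genomes. All randomness flows from ``rng_seed``; a fixed
recipe and seed reproduce output byte for byte.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import DNA_ALPHABET, TelomereMotif, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Fixed promoter element consensi planted verbatim in every synthetic gene.
# PSEA is the long conserved proximal sequence element shared by all type 3
# promoters; PSEB marks pol II snRNA promoters; the TATA box marks pol III.
PSEA_CONSENSUS = "TCACCGTAACTGAA"
PSEB_CONSENSUS = "GCGTACAT"
TATA_CONSENSUS = "TATAAATA"

# Promoter geometry relative to the transcription start site (TSS at 0):
# PSEA occupies [-66,-52), PSEB (pol II genes) [-44,-36), TATA (pol III
# genes) [-30,-22).  The PSEA 3' end thus sits 52 nt upstream of the TSS.
PSEA_OFFSET = -66
PSEB_OFFSET = -44
TATA_OFFSET = -30
PROMOTER_SPAN = 66  # bases upstream of the TSS covered by the promoter


@dataclass
class SatelliteSpec:
    """A tandem satellite planted at a chosen set of scaffold ends.

    ``ends`` holds ``(scaffold_index, "5p" | "3p")`` pairs. ``unit=None``
    draws a random unit of ``unit_length`` from the recipe RNG.
    """

    ends: tuple = ()
    unit: str | None = None
    unit_length: int = 62
    copies: int = 30


@dataclass
class GenomeRecipe:
    """Parameters of one synthetic study: what to plant, where, how much."""

    n_genomes: int = 5
    scaffolds_per_genome: int = 1
    scaffold_length: int = 2_000_000
    gc_fraction: float = 0.38
    telomere_motif_per_genome: list[str] | None = None
    telomere_array_copies: tuple[int, int] = (100, 300)
    n_interstitial_arrays: int = 3
    interstitial_copies: tuple[int, int] = (3, 8)
    n_decoy_template_loci: int = 100
    plant_tr: bool = True
    plant_snrna_pol2: int = 6
    plant_snrna_pol3: int = 6
    plant_tert: bool = False
    plant_terminal_satellite: SatelliteSpec | None = None
    template_extension: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.telomere_motif_per_genome is None:
            # Default study condition: one genome carries a final-base G->C
            # point mutation of the long motif, the rest the unmutated form.
            motifs = ["TTAGGTTGGGG"] * self.n_genomes
            if self.n_genomes > 1:
                motifs[-1] = "TTAGGTTGGGC"
            self.telomere_motif_per_genome = motifs
        if len(self.telomere_motif_per_genome) != self.n_genomes:
            raise ValueError(
                f"{len(self.telomere_motif_per_genome)} motifs for {self.n_genomes} genomes"
            )
        for m in self.telomere_motif_per_genome:
            if not m or not set(m.upper()) <= DNA_ALPHABET:
                raise ValueError(f"telomere motif {m!r} contains non-ACGT characters")
        if self.scaffold_length < 4000:
            raise ValueError("scaffold_length must be at least 10x the 400 nt scan window")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie strictly between 0 and 1")

    def genome_ids(self) -> list[str]:
        return [f"genome{i}" for i in range(self.n_genomes)]


@dataclass
class TruthRecord:
    """One planted feature: kind, placement and feature-specific payload."""

    kind: str
    genome_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    payload: dict = field(default_factory=dict)


@dataclass
class TruthSet:
    """All planted features of one simulated study, JSON/BED serialisable."""

    records: list[TruthRecord] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def for_genome(self, genome_id: str) -> list[TruthRecord]:
        return [r for r in self.records if r.genome_id == genome_id]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([dataclasses.asdict(r) for r in self.records], indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        data = json.loads(Path(path).read_text())
        return cls([TruthRecord(**r) for r in data])

    def to_bed(self, path: str | Path) -> None:
        lines = []
        for r in self.records:
            name = f"{r.kind}:{r.genome_id}"
            lines.append(f"{r.scaffold_id}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    return _random_dna(rng, n, gc).tobytes().decode()


def template_of(motif: str, extension: int = 1, rotation: int = 0) -> str:
    """Genome-specific TR template: a rotation of the reverse complement of
    the telomere motif, extended circularly by ``extension`` bases (the
    minimal annealing portion)."""
    c = revcomp(motif.upper())
    doubled = c + c
    return doubled[rotation : rotation + len(c) + extension]


class _Placer:
    """Samples non-overlapping placement positions on one scaffold."""

    def __init__(self, rng: np.random.Generator, length: int, margin: int = 600):
        self.rng = rng
        self.length = length
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> None:
        self.taken.append((start - self.margin, end + self.margin))

    def place(self, size: int, tries: int = 200) -> int:
        for _ in range(tries):
            start = int(self.rng.integers(self.margin, self.length - size - self.margin))
            if all(e <= start or s >= start + size for s, e in self.taken):
                self.reserve(start, start + size)
                return start
        raise RuntimeError("could not place feature without overlap; scaffold too crowded")


def _design_tr_gene(
    rng: np.random.Generator, gc: float, flank: int = 150, tail: int = 30
) -> dict:
    """Design the shared TR gene block (one per recipe).

    Layout of the transcript (coordinates relative to the TSS):
    P1c 5' arm, spacer, P1.1 hairpin, spacer, template placeholder,
    spacer, P2 arm, J2/3 (invariant UUU), P3 arm, loop, P2' arm,
    spacer, P3' arm, spacer, P1c 3' arm, tail. The template placeholder is
    substituted per genome so the gene is sequence-identical across genomes
    except its template region.
    """
    p1c = random_dna(rng, 8, gc)
    p11 = random_dna(rng, 5, gc)
    p2 = random_dna(rng, 6, gc)
    p3 = random_dna(rng, 5, gc)
    parts = [
        ("p1c5", p1c),
        ("s1", random_dna(rng, 6, gc)),
        ("p11a", p11),
        ("l1", random_dna(rng, 4, gc)),
        ("p11b", revcomp(p11)),
        ("s2", random_dna(rng, 2, gc)),
        ("template", None),  # filled per genome
        ("s3", random_dna(rng, 2, gc)),
        ("p2a", p2),
        ("j23", "TTT"),  # invariant U residues of the pseudoknot loop
        ("p3a", p3),
        ("l2", random_dna(rng, 3, gc)),
        ("p2b", revcomp(p2)),
        ("s4", random_dna(rng, 3, gc)),
        ("p3b", revcomp(p3)),
        ("s5", random_dna(rng, 6, gc)),
        ("p1c3", revcomp(p1c)),
        ("tail", random_dna(rng, tail, gc)),
    ]
    promoter = bytearray(random_dna(rng, PROMOTER_SPAN, gc).encode())
    promoter[PSEA_OFFSET + PROMOTER_SPAN : PSEA_OFFSET + PROMOTER_SPAN + len(PSEA_CONSENSUS)] = (
        PSEA_CONSENSUS.encode()
    )
    promoter[TATA_OFFSET + PROMOTER_SPAN : TATA_OFFSET + PROMOTER_SPAN + len(TATA_CONSENSUS)] = (
        TATA_CONSENSUS.encode()
    )
    return {
        "flank5": random_dna(rng, flank, gc),
        "promoter": promoter.decode(),
        "parts": parts,
        "flank3": random_dna(rng, flank, gc),
    }


def _assemble_tr_gene(design: dict, template: str) -> tuple[str, dict]:
    """Concatenate the shared design with a genome-specific template.

    Returns the full planted block and a payload of block-relative
    coordinates (promoter elements, transcript, template, stems).
    """
    flank5 = design["flank5"]
    promoter = design["promoter"]
    tss = len(flank5) + len(promoter)
    coords: dict = {}
    pos = tss
    seq_parts = [flank5, promoter]
    for name, part in design["parts"]:
        s = template if part is None else part
        coords[name] = (pos, pos + len(s))
        seq_parts.append(s)
        pos += len(s)
    block = "".join(seq_parts)
    payload = {
        "tss": tss,
        "transcript": (tss, pos),
        "template": list(coords["template"]),
        "psea": [tss + PSEA_OFFSET, tss + PSEA_OFFSET + len(PSEA_CONSENSUS)],
        "tata": [tss + TATA_OFFSET, tss + TATA_OFFSET + len(TATA_CONSENSUS)],
        "stems": {
            "p1c": [list(coords["p1c5"]), list(coords["p1c3"])],
            "p1_1": [list(coords["p11a"]), list(coords["p11b"])],
            "p2": [list(coords["p2a"]), list(coords["p2b"])],
            "p3": [list(coords["p3a"]), list(coords["p3b"])],
        },
        "j23": list(coords["j23"]),
    }
    return block, payload


def _snrna_block(
    rng: np.random.Generator, gc: float, pol_class: str, body_len: int = 120
) -> tuple[str, dict]:
    promoter = bytearray(random_dna(rng, PROMOTER_SPAN, gc).encode())
    promoter[PSEA_OFFSET + PROMOTER_SPAN : PSEA_OFFSET + PROMOTER_SPAN + len(PSEA_CONSENSUS)] = (
        PSEA_CONSENSUS.encode()
    )
    if pol_class == "pol2":
        promoter[
            PSEB_OFFSET + PROMOTER_SPAN : PSEB_OFFSET + PROMOTER_SPAN + len(PSEB_CONSENSUS)
        ] = PSEB_CONSENSUS.encode()
    elif pol_class == "pol3":
        promoter[
            TATA_OFFSET + PROMOTER_SPAN : TATA_OFFSET + PROMOTER_SPAN + len(TATA_CONSENSUS)
        ] = TATA_CONSENSUS.encode()
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown pol_class {pol_class!r}")
    body = random_dna(rng, body_len, gc)
    block = promoter.decode() + body
    payload = {
        "pol_class": pol_class,
        "tss": PROMOTER_SPAN,
        "psea": [PSEA_OFFSET + PROMOTER_SPAN, PSEA_OFFSET + PROMOTER_SPAN + len(PSEA_CONSENSUS)],
    }
    if pol_class == "pol2":
        payload["pseb"] = [
            PSEB_OFFSET + PROMOTER_SPAN,
            PSEB_OFFSET + PROMOTER_SPAN + len(PSEB_CONSENSUS),
        ]
    else:
        payload["tata"] = [
            TATA_OFFSET + PROMOTER_SPAN,
            TATA_OFFSET + PROMOTER_SPAN + len(TATA_CONSENSUS),
        ]
    return block, payload


# 20 standard amino acids for the synthetic TERT-like peptides.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {
    "A": ["GCT", "GCC"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC"], "H": ["CAT", "CAC"], "I": ["ATT", "ATC"],
    "K": ["AAA", "AAG"], "L": ["CTT", "CTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC"], "S": ["TCT", "AGC"],
    "T": ["ACT", "ACC"], "V": ["GTT", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}


def random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def back_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(_CODON[aa][int(rng.integers(0, len(_CODON[aa])))] for aa in peptide)


def make_genomes(recipe: GenomeRecipe) -> tuple[dict[str, dict[str, str]], TruthSet]:
    """Build all genomes of a recipe and the matching ground-truth records.

    Returns ``(genomes, truth)`` where ``genomes[genome_id][scaffold_id]``
    is the scaffold sequence. Deterministic in ``recipe.rng_seed``.
    """
    master = np.random.default_rng(recipe.rng_seed)
    truth = TruthSet()
    motifs = [TelomereMotif(m) for m in recipe.telomere_motif_per_genome]

    tr_design = _design_tr_gene(master, recipe.gc_fraction) if recipe.plant_tr else None
    tert_trbd = tert_rt = None
    if recipe.plant_tert:
        tert_trbd = random_peptide(master, 250)
        tert_rt = random_peptide(master, 300)

    sat = recipe.plant_terminal_satellite
    sat_unit = None
    if sat is not None:
        sat_unit = sat.unit or random_dna(master, sat.unit_length, 0.5)

    genome_seeds = master.integers(0, 2**31 - 1, size=recipe.n_genomes)
    genomes: dict[str, dict[str, str]] = {}
    for gi, gid in enumerate(recipe.genome_ids()):
        rng = np.random.default_rng(genome_seeds[gi])
        motif = motifs[gi]
        g_unit = motif.g_strand
        scaffolds: dict[str, str] = {}
        for si in range(recipe.scaffolds_per_genome):
            sid = f"{gid}_scf{si}"
            seq = _random_dna(rng, recipe.scaffold_length, recipe.gc_fraction)
            placer = _Placer(rng, recipe.scaffold_length)

            def plant(start: int, block: str) -> None:
                seq[start : start + len(block)] = np.frombuffer(block.encode(), dtype="S1")

            # --- terminal telomere arrays (G-rich strand towards the end) ---
            lo, hi = recipe.telomere_array_copies
            for which in ("5p", "3p"):
                if sat is not None and (si, which) in set(sat.ends):
                    block = sat_unit * sat.copies
                    start = 0 if which == "5p" else recipe.scaffold_length - len(block)
                    plant(start, block)
                    placer.reserve(start, start + len(block))
                    truth.records.append(
                        TruthRecord(
                            "satellite", gid, sid, start, start + len(block),
                            "+", {"unit": sat_unit, "end": which, "copies": sat.copies},
                        )
                    )
                    continue
                copies = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                if copies <= 0:
                    continue
                if which == "5p":
                    block = revcomp(g_unit) * copies  # C-rich on + strand at the 5' end
                    start, strand = 0, "-"
                else:
                    block = g_unit * copies
                    start, strand = recipe.scaffold_length - len(block), "+"
                plant(start, block)
                placer.reserve(start, start + len(block))
                truth.records.append(
                    TruthRecord(
                        "telomere_array", gid, sid, start, start + len(block),
                        strand, {"motif": g_unit, "copies": copies, "end": which},
                    )
                )

            # --- interstitial telomeric repeats ---
            ilo, ihi = recipe.interstitial_copies
            for _ in range(recipe.n_interstitial_arrays):
                copies = int(rng.integers(ilo, ihi + 1))
                block = g_unit * copies
                start = placer.place(len(block))
                plant(start, block)
                truth.records.append(
                    TruthRecord(
                        "interstitial_array", gid, sid, start, start + len(block),
                        "+", {"motif": g_unit, "copies": copies},
                    )
                )

            # --- the planted TR gene (scaffold 0 only) ---
            if tr_design is not None and si == 0:
                template = template_of(g_unit, recipe.template_extension)
                block, payload = _assemble_tr_gene(tr_design, template)
                start = placer.place(len(block))
                plant(start, block)
                payload = json.loads(json.dumps(payload))  # deep copy
                payload["template_seq"] = template
                payload["motif"] = g_unit
                payload["block"] = [start, start + len(block)]
                truth.records.append(
                    TruthRecord(
                        "tr_gene", gid, sid,
                        start + payload["transcript"][0], start + payload["transcript"][1],
                        "+", payload,
                    )
                )

            # --- decoy template-like loci: one template pattern in random
            # genome-specific context, no promoter ---
            from .template_scan import template_patterns  # local import, no cycle at runtime

            patterns = [p.pattern for p in template_patterns(motif, recipe.template_extension)]
            for _ in range(recipe.n_decoy_template_loci):
                pat = patterns[int(rng.integers(0, len(patterns)))]
                start = placer.place(len(pat))
                plant(start, pat)
                truth.records.append(
                    TruthRecord(
                        "decoy_template", gid, sid, start, start + len(pat), "+",
                        {"pattern": pat},
                    )
                )

            # --- snRNA genes with pol II / pol III type 3 promoters ---
            if si == 0:
                for pol_class, count in (("pol2", recipe.plant_snrna_pol2),
                                         ("pol3", recipe.plant_snrna_pol3)):
                    for _ in range(count):
                        block, payload = _snrna_block(rng, recipe.gc_fraction, pol_class)
                        start = placer.place(len(block))
                        plant(start, block)
                        truth.records.append(
                            TruthRecord(
                                "snrna", gid, sid,
                                start + PROMOTER_SPAN, start + len(block), "+",
                                {**payload, "block": [start, start + len(block)]},
                            )
                        )

            # --- TERT-like ORF: TRBD then RT domain, one stop at the end ---
            if recipe.plant_tert and si == 0:
                peptide = tert_trbd + tert_rt
                orf = "ATG" + back_translate(rng, peptide) + "TAA"
                start = placer.place(len(orf))
                plant(start, orf)
                truth.records.append(
                    TruthRecord(
                        "tert_orf", gid, sid, start, start + len(orf), "+",
                        {"trbd": tert_trbd, "rt": tert_rt},
                    )
                )

            scaffolds[sid] = seq.tobytes().decode()
        genomes[gid] = scaffolds
    return genomes, truth


def extract(genomes: dict[str, dict[str, str]], rec: TruthRecord) -> str:
    """Sequence of a truth interval as written into the genome."""
    return genomes[rec.genome_id][rec.scaffold_id][rec.start : rec.end]


# ---------------------------------------------------------------------------
# paired-end read simulation


def make_reads(
    genome: dict[str, str],
    read_length: int = 100,
    n_pairs: int = 10_000,
    fragment_size: int = 350,
    rng_seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform shotgun paired-end reads from one genome.

    Mate 1 is the fragment 5' end on the sampled strand; mate 2 is the
    reverse complement of the fragment 3' end. No sequencing errors are
    simulated. Deterministic per ``rng_seed``.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    names = sorted(genome)
    lengths = np.array([len(genome[n]) for n in names])
    if read_length > fragment_size:
        raise ValueError("read_length must not exceed fragment_size")
    if fragment_size > lengths.max():
        raise ValueError("fragment_size exceeds every scaffold length")
    usable = lengths >= fragment_size
    weights = np.where(usable, lengths, 0).astype(float)
    weights /= weights.sum()
    rng = np.random.default_rng(rng_seed)
    scaffold_idx = rng.choice(len(names), size=n_pairs, p=weights)
    pairs = []
    for i in range(n_pairs):
        seq = genome[names[scaffold_idx[i]]]
        start = int(rng.integers(0, len(seq) - fragment_size + 1))
        frag = seq[start : start + fragment_size]
        pairs.append((frag[:read_length], revcomp(frag[-read_length:])))
    return pairs


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pair(
    pairs: list[tuple[str, str]], prefix: str | Path, quality: str = "I"
) -> tuple[Path, Path]:
    prefix = Path(prefix)
    p1, p2 = Path(f"{prefix}_R1.fastq"), Path(f"{prefix}_R2.fastq")
    for mate, path in ((0, p1), (1, p2)):
        with open(path, "w") as fh:
            for i, pair in enumerate(pairs):
                read = pair[mate]
                fh.write(f"@pair{i}/{mate + 1}\n{read}\n+\n{quality * len(read)}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# synthetic TR-core alignment families for the structure module


def make_tr_core_family(
    n_rows: int = 10,
    seed: int = 0,
    n_compensatory: int = 2,
    mutation_rate: float = 0.15,
    motif: str = "TTAGGTTGGGG",
):
    """A gapless TR-core alignment with planted stems and known truth.

    Each stem (P1c, P1.1, P2, P3) receives ``n_compensatory`` compensatory
    pair substitutions (a Watson-Crick pair replaced by a different
    Watson-Crick pair in a random subset of rows), producing genuine
    covariation. Unpaired, non-template columns outside J2/3 mutate
    independently at ``mutation_rate``. Rows are equal length, so the family
    is its own alignment.

    Returns ``(msa, truth)`` where ``truth`` maps stem names to lists of
    paired column index pairs plus the J2/3 column range.
    """
    from .structure_annotation import CoreMSA  # deferred to avoid import cycle

    rng = np.random.default_rng(seed)
    design = _design_tr_gene(rng, 0.5, flank=0, tail=12)
    template = template_of(motif)
    block, payload = _assemble_tr_gene(design, template)
    tss, t_end = payload["transcript"]
    core = block[tss:t_end]
    off = tss
    stems_truth = {}
    for name, (arm5, arm3) in payload["stems"].items():
        a0, a1 = arm5[0] - off, arm5[1] - off
        b0, b1 = arm3[0] - off, arm3[1] - off
        stems_truth[name] = [(a0 + k, b1 - 1 - k) for k in range(a1 - a0)]
    j23 = (payload["j23"][0] - off, payload["j23"][1] - off)
    template_cols = (payload["template"][0] - off, payload["template"][1] - off)

    paired_cols = {c for pairs in stems_truth.values() for p in pairs for c in p}
    frozen = set(range(*template_cols)) | set(range(*j23)) | paired_cols

    rows = [list(core) for _ in range(n_rows)]
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    wc = ["AT", "TA", "GC", "CG"]
    for pairs in stems_truth.values():
        chosen = rng.choice(len(pairs), size=min(n_compensatory, len(pairs)), replace=False)
        for idx in chosen:
            i, j = pairs[idx]
            current = core[i] + comp[core[i]]
            alt = [p for p in wc if p != current and p != current[::-1]]
            new = alt[int(rng.integers(0, len(alt)))]
            n_mut = int(rng.integers(2, max(3, n_rows // 2)))
            for r in rng.choice(n_rows, size=n_mut, replace=False):
                rows[r][i], rows[r][j] = new[0], new[1]
    for c in range(len(core)):
        if c in frozen:
            continue
        for r in range(n_rows):
            if rng.random() < mutation_rate:
                rows[r][c] = "ACGT"[int(rng.integers(0, 4))]
    # Boundary hygiene: a column adjacent to a planted stem must not extend
    # the stem (neither by Watson-Crick nor by G.U wobble pairing), or
    # recovery of the exact planted pairs would be ambiguous.
    pairable = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    non_pairing = {x: [y for y in "ACGT" if (x, y) not in pairable] for x in "ACGT"}
    for pairs in stems_truth.values():
        (i0, j0), (i1, j1) = pairs[0], pairs[-1]
        for a, b in ((i0 - 1, j0 + 1), (i1 + 1, j1 - 1)):
            if not (0 <= a < len(core) and 0 <= b < len(core)):
                continue
            if a in frozen and b in frozen:
                continue
            tgt, ref = (b, a) if b not in frozen else (a, b)
            bad = [r for r in range(n_rows) if (rows[r][a], rows[r][b]) in pairable]
            while len(bad) > 0.8 * n_rows:
                r = bad.pop()
                choices = non_pairing[rows[r][ref]]
                rows[r][tgt] = choices[int(rng.integers(0, len(choices)))]

    msa = CoreMSA(
        ids=[f"seq{r}" for r in range(n_rows)],
        rows=["".join(r) for r in rows],
        template_columns=template_cols,
    )
    truth = {"stems": stems_truth, "j2_3": j23, "template_columns": template_cols}
    return msa, truth


def simulate_to_dir(recipe: GenomeRecipe, outdir: str | Path,
                    reads: bool = False, read_params: dict | None = None) -> Path:
    """Write per-genome FASTA (optionally FASTQ pairs), truth.json, truth.bed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, truth = make_genomes(recipe)
    for gid, scaffolds in genomes.items():
        write_fasta(scaffolds, outdir / f"{gid}.fasta")
        if reads:
            params = dict(read_params or {})
            params.setdefault("rng_seed", recipe.rng_seed)
            write_fastq_pair(make_reads(scaffolds, **params), outdir / gid)
    truth.to_json(outdir / "truth.json")
    truth.to_bed(outdir / "truth.bed")
    return outdir
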