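"""End-to-end TR discovery: simulate/ingest -> telomere motifs -> template
scan -> cross-genome intersection -> template correspondence -> promoter
classification -> core structure annotation -> report.

The narrative the stage log mirrors: hundreds of template-like loci per
genome collapse to a handful of cross-genome reciprocal survivors, and
template-telomere correspondence under each genome's own motif leaves the
genuine TR. A candidate is reported "template-verified" only when every
genome's homolog carries a template pattern of that genome's motif, and its
polymerase class comes from the type 3 promoter elements found upstream of
the template region.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .homology_filter import CandidateTR, intersect_genomes, template_correspondence
from .motifs import TelomereMotif, revcomp
from .promoter_analysis import (
    MotifModel,
    annotate_promoter,
    discover_motif,
    tata_default_model,
    upstream_regions,
)
from .structure_annotation import CoreMSA, annotate_core
from .synthetic_data import GenomeRecipe, TruthSet, make_genomes
from .telomere_discovery import find_tandem_repeats, terminal_windows
from .template_scan import scan_templates

log = logging.getLogger("telotrace")


@dataclass
class PipelineConfig:
    recipe: GenomeRecipe | None = None
    genome_paths: dict[str, str] | None = None
    motifs: list[str] | str = "infer"
    window: int = 400
    extension: int = 1
    evalue_strict: float = 1e-20
    evalue_extended: float = 1e-5
    flank: int = 200
    psea_width: int = 14
    pseb_width: int = 8
    n_em_starts: int = 20
    end_length: int = 2000
    snrna_bed: str | None = None
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_strict <= 0 or self.evalue_extended <= 0:
            raise ValueError("E-value thresholds must be positive")
        if self.recipe is None and not self.genome_paths:
            raise ValueError("config needs either a synthetic recipe or genome FASTA paths")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("recipe"):
            sat = d["recipe"].get("plant_terminal_satellite")
            if sat:
                from .synthetic_data import SatelliteSpec

                sat["ends"] = tuple(tuple(e) for e in sat["ends"])
                d["recipe"]["plant_terminal_satellite"] = SatelliteSpec(**sat)
            for key in ("telomere_array_copies", "interstitial_copies"):
                if key in d["recipe"] and d["recipe"][key] is not None:
                    d["recipe"][key] = tuple(d["recipe"][key])
            d["recipe"] = GenomeRecipe(**d["recipe"])
        return cls(**d)


@dataclass
class PipelineReport:
    candidates: list[dict] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        cols = ["candidate", "genome", "seq_id", "start", "end", "template_ok",
                "pol_class", "template_verified", "stems_found"]
        lines = ["\t".join(cols)]
        for c in self.candidates:
            for g, h in sorted(c["homologs"].items()):
                lines.append("\t".join(str(x) for x in (
                    c["id"], g, h["seq_id"], h["start"], h["end"],
                    c["template_ok"].get(g), c["pol_class"],
                    c["template_verified"], ",".join(c["stems_found"]),
                )))
        Path(path).write_text("\n".join(lines) + "\n")


def _load_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def infer_motif_from_ends(seqs: dict[str, str], end_length: int = 2000) -> str | None:
    """Top canonical tandem class over all terminal windows, by base count."""
    votes: dict[str, int] = {}
    display: dict[str, str] = {}
    for win in terminal_windows(seqs, end_length):
        for hit in find_tandem_repeats(win.sequence, source_id=win.label):
            from .motifs import canonical_form, display_form, primitive_unit

            unit = primitive_unit(hit.consensus)
            if "N" in unit:
                continue
            canon = canonical_form(unit)
            votes[canon] = votes.get(canon, 0) + (hit.end - hit.start)
            display.setdefault(canon, display_form(unit))
    if not votes:
        return None
    best = max(sorted(votes), key=lambda c: votes[c])
    return display[best]


def _snrna_training_loci(config: PipelineConfig, truth: TruthSet | None):
    """(seq_id, start, end, strand, pol_class) tuples for promoter training."""
    loci = []
    if truth is not None:
        for rec in truth.by_kind("snrna"):
            loci.append((rec.genome_id, rec.scaffold_id, rec.start, rec.end,
                         rec.strand, rec.payload.get("pol_class")))
    elif config.snrna_bed:
        with open(config.snrna_bed) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 6:
                    continue
                pol = "pol2" if "pol2" in parts[3] else ("pol3" if "pol3" in parts[3] else None)
                loci.append((None, parts[0], int(parts[1]), int(parts[2]), parts[5], pol))
    return loci


def train_promoter_models(
    config: PipelineConfig,
    genomes: dict[str, dict[str, str]],
    truth: TruthSet | None,
) -> dict[str, MotifModel]:
    """Train PSEA on all snRNA upstream regions, PSEB on the pol II subset
    (downstream of each PSEA hit), and take the fixed TATA model."""
    loci = _snrna_training_loci(config, truth)
    if not loci:
        return {"TATA": tata_default_model()}
    all_seqs: dict[str, str] = {}
    for g in genomes.values():
        all_seqs.update(g)
    regions = upstream_regions(
        [(sid, start, end, strand) for _, sid, start, end, strand, _ in loci],
        all_seqs, config.flank,
    )
    seqs = [r.sequence for r in regions]
    psea, _ = discover_motif(seqs, config.psea_width, config.n_em_starts,
                             seed=config.seed, label="PSEA")
    models = {"PSEA": psea, "TATA": tata_default_model()}
    pol2_tails = []
    for region, (_, _, _, _, _, pol) in zip(regions, loci):
        if pol != "pol2":
            continue
        hit = psea.best_hit(region.sequence)
        if hit is None:
            continue
        tail = region.sequence[hit[0] + psea.width :]
        if len(tail) >= config.pseb_width:
            pol2_tails.append(tail)
    if len(pol2_tails) >= 5:
        pseb, _ = discover_motif(pol2_tails, config.pseb_width, config.n_em_starts,
                                 seed=config.seed + 1, label="PSEB")
        models["PSEB"] = pseb
    return models


def _transcript_strand(locus) -> str:
    """The TR transcript carries the C-rich template; template patterns are
    enumerated with '+' = G-rich strand, so a '-' pattern match means the
    transcript runs on the forward strand."""
    strands = {m.strand for m in locus.matches}
    return "+" if "-" in strands else "-"


def _candidate_promoter(cand: CandidateTR, models: dict[str, MotifModel],
                        flank: int) -> None:
    locus = cand.locus
    strand = _transcript_strand(locus)
    match = locus.matches[0]
    if strand == "+":
        region = locus.sequence[: match.start - locus.window_start]
        region = region[-flank:] if flank else region
    else:
        region = revcomp(locus.sequence[match.end - locus.window_start :])
        region = region[-flank:] if flank else region
    ann = annotate_promoter(region, models)
    cand.promoter = ann
    cand.pol_class = ann.pol_class


def _candidate_structure(cand: CandidateTR, pad: int = 100):
    """Stack homolog windows, trimmed around the template, as a gapless MSA.

    Homologous TR windows from close relatives align columnwise once
    anchored on the template match; rows that cannot be trimmed to equal
    length are dropped with a diagnostic.
    """
    rows, ids = [], []
    t_len = None
    for g in sorted(cand.homologs):
        locus = cand.homologs[g]
        if not locus.matches:
            continue
        m = locus.matches[0]
        strand = _transcript_strand(locus)
        s0 = m.start - locus.window_start
        s1 = m.end - locus.window_start
        lo, hi = max(0, s0 - pad), min(len(locus.sequence), s1 + pad)
        if s0 - pad < 0 or s1 + pad > len(locus.sequence):
            continue
        row = locus.sequence[lo:hi]
        if strand == "-":
            row = revcomp(row)
        rows.append(row)
        ids.append(g)
        t_len = s1 - s0
    if len(rows) < 2 or len({len(r) for r in rows}) != 1:
        return None
    msa = CoreMSA(ids, rows, (pad, pad + t_len))
    return annotate_core(msa)


def run_discovery(config: PipelineConfig) -> PipelineReport:
    """Run the full discovery pipeline; deterministic given config+seed."""
    t_start = time.time()
    report = PipelineReport()

    # --- stage: genomes ---
    truth = None
    if config.recipe is not None:
        recipe = dataclasses.replace(config.recipe, rng_seed=config.seed)
        genomes, truth = make_genomes(recipe)
    else:
        genomes = {gid: _load_fasta(p) for gid, p in sorted(config.genome_paths.items())}
    if len(genomes) < 2:
        raise ValueError("intersection mode needs at least 2 genomes")
    log.info("genomes: %d", len(genomes))

    # --- stage: telomere motifs ---
    if config.motifs == "infer":
        motifs = {}
        for gid in sorted(genomes):
            m = infer_motif_from_ends(genomes[gid], config.end_length)
            if m is None:
                raise RuntimeError(f"stage telomere-motif failed for {gid}: no terminal repeat")
            motifs[gid] = TelomereMotif(m)
    else:
        motifs = {gid: TelomereMotif(m) for gid, m in zip(sorted(genomes), config.motifs)}
    report.motifs = {g: m.display for g, m in motifs.items()}
    log.info("motifs: %s", report.motifs)

    # --- stage: template scan ---
    locus_sets = {}
    for gid in sorted(genomes):
        locus_sets[gid] = scan_templates(
            genomes[gid], motifs[gid], config.window, config.extension, genome_id=gid
        )
        log.info("template loci in %s: %d", gid, len(locus_sets[gid]))
    report.stage_counts["template_loci"] = {g: len(v) for g, v in locus_sets.items()}

    # --- stage: cross-genome intersection ---
    n_pairs = max(len(a) * len(b) for a in locus_sets.values() for b in locus_sets.values())
    prefilter = None if n_pairs <= 2000 else 13
    candidates = intersect_genomes(locus_sets, config.evalue_strict, prefilter_k=prefilter)
    report.stage_counts["reciprocal_candidates"] = len(candidates)
    log.info("cross-genome candidates: %d", len(candidates))

    # --- stage: template correspondence ---
    for cand in candidates:
        template_correspondence(cand, motifs, config.extension)
    n_verified = sum(c.template_verified for c in candidates)
    report.stage_counts["template_verified"] = n_verified
    log.info("template-verified candidates: %d", n_verified)

    # --- stage: promoter classification ---
    models = train_promoter_models(config, genomes, truth)
    for cand in candidates:
        _candidate_promoter(cand, models, config.flank)

    # --- stage: structure annotation ---
    for cand in candidates:
        cand.structure = _candidate_structure(cand)

    for i, cand in enumerate(candidates):
        stems_found = []
        if cand.structure is not None:
            stems_found = [k for k, v in cand.structure.stems().items() if v]
        report.candidates.append({
            "id": f"cand{i}",
            "homologs": {
                g: {"seq_id": l.seq_id, "start": l.window_start, "end": l.window_end}
                for g, l in cand.homologs.items()
            },
            "template_ok": dict(cand.template_ok),
            "template_verified": cand.template_verified,
            "pol_class": cand.pol_class,
            "stems_found": stems_found,
            "invariant_U_in_J23": bool(cand.structure and cand.structure.invariant_U_in_J23),
        })
    log.info("pipeline finished in %.1f s", time.time() - t_start)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.frozen.yaml")
        report.to_json(outdir / "report.json")
        report.to_tsv(outdir / "report.tsv")
        if truth is not None:
            truth.to_json(outdir / "truth.json")
    return report
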