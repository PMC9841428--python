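# telotrace

De novo discovery of telomerase RNA (TR) genes in insect genomes.

Telomerase adds telomere repeats using its own RNA subunit as the template.
In most animals that RNA is an H/ACA-box snoRNA transcribed by RNA
polymerase II - but TRs are so divergent in sequence and biogenesis that in
large clades (Hymenoptera among them) no TR was known at all, and ordinary
homology search cannot find one. The only predictable feature of an unknown
TR is its **template region**: a stretch complementary to the G-rich strand
of the telomere repeat, i.e. some circular permutation of the C-rich repeat
strand plus at least one extra "annealing" base.

`telotrace` implements that insight as a tested, reusable pipeline:

1. **Telomere motif inference** - tandem-repeat tallying over raw reads
   (rotation/strand canonical classes, ranked by read support) and
   terminal-window analysis of assemblies, including the search for a
   satellite shared among chromosome ends where telomeric arrays are
   absent.
2. **Template-locus scanning** - exact matching of all circular
   permutations of the motif (both strands) + 1 nt, a 400-nt window per
   match, exclusion of matches inside tandem arrays of >= 3 motif copies,
   and merging of overlapping windows.
3. **Cross-genome filtering** - Smith-Waterman reciprocal-best pairs at
   E <= 1e-20 (Karlin-Altschul E-values from simulation-fitted constants),
   intersected across all genomes, then **template correspondence**: each
   genome's homolog must carry a template of *its own* motif, so a
   single-base motif mutation in one species must appear in its template.
4. **Type 3 promoter analysis** - PSEA/PSEB/TATA models (EM-trained on
   known snRNA upstream regions), RNAP classification (PSEA+PSEB -> pol II,
   PSEA+TATA -> pol III), and a promoter-first mode that scans for PSEA
   hits with a downstream template.
5. **Core structure annotation** - comparative (covariation-guided)
   recovery of the template boundary element (P1.1), the P2/P3 pseudoknot
   with its invariant-U joining loop, and the closing P1c stem.
6. **TERT screening** - six-frame translation plus BLOSUM62 local
   alignment of TRBD/RT domain queries, yielding a presence matrix on a
   log10 E-value scale.

A synthetic-genome simulator with planted ground truth (telomere arrays,
interstitial repeats, decoy template loci, a motif-tracking TR gene, pol
II/pol III snRNAs, TERT ORFs, terminal satellites, shotgun read sets) makes
every stage testable without downloads. See `docs/methods.md` for the
model, parameter and design details.

## Worked example

Simulate three 500-kb genomes - the third carries a telomere motif mutated
at its final base (TTAGGTTGGGG -> TTAGGTTGGGC) - with 40 decoy template
loci each, then run the full discovery pipeline:

```python
import json
from telotrace import GenomeRecipe, PipelineConfig, run_discovery

recipe = GenomeRecipe(n_genomes=3, scaffold_length=500_000,
                      n_decoy_template_loci=40, rng_seed=7)
report = run_discovery(PipelineConfig(recipe=recipe, seed=7))
print(json.dumps(report.stage_counts, indent=1))
print(json.dumps(report.motifs, indent=1))
print(json.dumps(report.candidates[0], indent=1))
```

prints

```
{
 "template_loci": {"genome0": 42, "genome1": 41, "genome2": 41},
 "reciprocal_candidates": 1,
 "template_verified": 1
}
{
 "genome0": "TTAGGTTGGGG",
 "genome1": "TTAGGTTGGGG",
 "genome2": "TTAGGTTGGGC"
}
{
 "id": "cand0",
 "homologs": {
  "genome0": {"seq_id": "genome0_scf0", "start": 259670, "end": 260072},
  "genome1": {"seq_id": "genome1_scf0", "start": 205669, "end": 206071},
  "genome2": {"seq_id": "genome2_scf0", "start": 92184, "end": 92586}
 },
 "template_ok": {"genome0": true, "genome1": true, "genome2": true},
 "template_verified": true,
 "pol_class": "pol3",
 "stems_found": ["p1c", "p1_1", "p2", "p3"],
 "invariant_U_in_J23": false
}
```

Reading it: each genome yields ~40 template-like loci (the planted decoys
plus the TR); telomere motifs were inferred from the assembly ends,
recovering the G->C mutation in genome2; exactly one locus survives
reciprocal cross-genome filtering, its template tracks each genome's own
motif (`template_ok` everywhere, hence `template_verified`), its upstream
region shows PSEA + TATA without PSEB (`pol_class: pol3` - the RNAPIII
signature), and a closing stem, template-boundary hairpin and pseudoknot
are present in the homolog alignment. With only three near-identical
homolog rows the pseudoknot placement (and hence the invariant-U check) is
not always uniquely resolved; the dedicated structure analysis uses
10-sequence families, where recovery is exact (see `docs/methods.md`).

The same run is available from the shell:

```sh
telotrace run --config cfg.yaml        # full pipeline from a YAML config
telotrace simulate --out sim/          # genomes + truth.json + truth.bed
telotrace telomere-reads --fastq R1.fq --fastq R2.fq
telotrace telomere-ends --fasta genome.fa --end-length 2000
telotrace template-scan --fasta g.fa --motif TTAGGTTGGGG
telotrace promoter-scan --fasta g.fa --snrna-bed snrna.bed --motif TTAGG
telotrace tert --fasta g.fa --queries tert.faa
```

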