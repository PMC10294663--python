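# sporeamg

Phages that infect spore-forming bacteria sometimes carry host-derived
sporulation genes — up to and including truncated homologs of *spo0A*, the
master regulator of sporulation initiation — which they may use to
manipulate the host's dormancy program during infection. Finding such genes
in genomic and metagenomic data takes three steps, each of which is easy to
get wrong: deciding whether a gene is *statistically* associated with
spore-forming hosts, deciding whether the scaffold it sits on is *really*
viral rather than bacterial contamination, and deciding whether a regulator
homolog is *functionally* intact or truncated.

`sporeamg` implements that screen as a tested, reproducible pipeline for
microbiome bioinformaticians:

1. **Enrichment** — for each KEGG ortholog (KO), an exact hypergeometric
   upper-tail test of its detections among phages of spore-forming hosts:
   with `N` phages surveyed, `K` of them infecting spore-formers, and the
   gene detected in `n` phages, `k` of them spore-host,

   *P* = P(X ≥ k), X ~ Hypergeom(N, K, n),

   Benjamini–Hochberg adjusted across all tested genes. A gene is called
   enriched when adjusted *P* < 10⁻⁶ **and** n > 30.
2. **Curation** — a rule engine that codifies manual scaffold inspection:
   reject a focal gene at a scaffold edge; reject when its neighborhood has
   both dense non-viral annotation and frequent gene-direction switches
   (bacterial fragment); accept when it is nested between hallmark viral
   genes (capsid, terminase, tail, …). Per-gene verdict tallies become
   "likely viral" (≥ 5 scaffolds true), "possible viral" (1–4), or
   "unlikely viral" (0).
3. **Domain profiling** — per-source-group alignment coverage and
   per-sequence calls of response-regulator architecture: full-length
   (receiver + DNA-binding effector domain) vs effector-only (receiver
   lost), the signature of a constitutively active regulator.

A synthetic-data module generates every input with known ground truth —
phage populations with configurable enrichment odds, viral / bacterial /
chimeric scaffolds, and full-length vs truncated protein alignments — so
the whole pipeline is exercised end to end without any downloads.

## Worked example

```bash
spore-amg run --seed 1 --outdir results/demo
```

runs the packaged demo: 800 phages (30% with spore-forming hosts), eight
planted enriched genes — six placed in genuinely viral scaffold context,
two planted as bacterial contamination — and thirty null genes. It prints:

```
{"candidate_genes": ["K03091", "K03496", "K04769", "K06283", "K06412", "K07699"]}
```

All eight planted genes pass the enrichment threshold (the screen cannot
tell contamination from carriage), but curation rejects the two
bacterial-context genes (`K01356`, `K02343` → "unlikely viral"), so the
final candidate table is exactly the six genes that are both enriched and
viral — the planted ground truth. `results/demo/` holds the per-stage
tables (`enrichment.tsv`, `verdicts.tsv`, `gene_summary.tsv`,
`truncation_calls.tsv`, `candidates.tsv`), plots, and `report.json`.

The same stages are available piecewise as `spore-amg
simulate|enrich|curate|profile`, and as narrative analysis drivers:

```bash
python analysis/01_simulate_population.py   # 2,000 phages, 20 planted + 200 null genes
python analysis/02_enrichment_screen.py     # recovers 20/20 planted, 0 false positives
python analysis/03_curate_scaffolds.py      # 100% verdict accuracy on 110 scaffolds
python analysis/04_domain_truncation.py     # 57 full_length + 29 effector_only calls
python analysis/05_full_pipeline.py         # demo run + ground-truth join check
```

A gene catalog mirroring the screened sporulation KOs of *Bacillus
subtilis* and *Clostridioides difficile* (31 KOs, 9 regulatory) ships with
the package (`sporeamg/data/sporulation_catalog.tsv`).

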