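# Methods

## The screen

The package answers one question in three stages: which genes are carried
by phages *because* their hosts are spore-formers, on evidence that is
actually viral, and (for regulators) in what structural form?

**Units.** The unit of testing is the KEGG ortholog (KO), not the locus:
the screened catalog maps multiple loci (from *B. subtilis* and
*C. difficile*) to a single KO, and detection is collapsed per KO per
phage — two hits of the same KO on two scaffolds of one phage count once.
A phage's host label is the OR over its predicted hosts: a phage can
influence sporulation if *any* of its hosts sporulates. Phages with no
host prediction are excluded from the universe (the count is logged);
phages with a known host but zero detections still count in `N`, because
the test universe is all phages surveyed, not all phages with hits.

## Enrichment model

For each KO detected at least once, the upper-tail hypergeometric
probability P(X ≥ k) with population `N` (phages surveyed), successes `K`
(phages with a spore-forming host), and draws `n` (phages carrying the
gene). The tail is summed in exact integer arithmetic (`math.comb`) and
rounded once through `fractions.Fraction`, so the result is correct to the
last floating-point bit at any practical `N`; scipy's survival function is
used only as an independent cross-check in the tests.

Multiple testing is controlled with Benjamini–Hochberg (delegated to
`statsmodels.stats.multitest.multipletests`, verified in tests against a
naive double-loop step-up). The adjustment runs across exactly the tested
set (all KOs with n ≥ 1), *before* any threshold filtering.

The enrichment call is the dual threshold: adjusted p < `alpha_adj`
(default 10⁻⁶, exclusive) **and** n > `min_n` (default 30, exclusive).
"Sample size" here means n, the number of phages in which the gene is
detected — the x-axis of the volcano plot. The plotted −log₁₀ value uses
the raw hypergeometric p; both raw and adjusted p are reported so neither
interpretation is lost. A degenerate host partition (K = 0 or K = N)
produces a warning and all-p = 1 results rather than an error.

## Curation rule engine

Manual scaffold inspection is codified as explicit, configurable rules
over a window of `window` = 10 genes on each side of the focal gene:

- `is_edge`: focal gene is the first or last gene (`edge_margin` = 0).
  Edge hits are rejected outright — assembly chimeras break at contig
  ends.
- `nonviral_density`: fraction of window genes (focal excluded) whose
  annotation is neither hallmark-viral nor hypothetical.
- `strand_switch_frac`: fraction of adjacent gene pairs in the window on
  opposite strands. Phage gene blocks are operon-like; bacterial fragments
  flip direction often.
- `hallmark_flanked`: at least one hallmark-viral gene within
  `flank_reach` = 3 genes on *each* side. Hallmark means the annotation
  contains (case-insensitive substring) one of: virion, capsid, tail,
  terminase, baseplate, phage, virus, reverse transcriptase, head.

Verdict: **false** if edge, or if `nonviral_density` > 0.5 **and**
`strand_switch_frac` > 0.4 (the two bacterial signals must co-occur;
either alone is only suspicious → "maybe"); **true** if not rejected,
hallmark-flanked, and density ≤ 0.5; **maybe** otherwise. Every fired rule
is recorded in a `reasons` column.

The numeric cutoffs (0.5 density, 0.4 switch fraction, window 10, flank
reach 3) are this package's operationalization of qualitative inspection
criteria; they are configurable and echoed into all outputs. Edges are
defined by gene index, not base-pair distance, because inspection operates
on the gene map.

Per-gene categories from verdict tallies: `n_true` = 0 → "unlikely viral";
1 ≤ `n_true` < 5 → "possible viral"; `n_true` ≥ 5 → "likely viral"
(`possible_viral_max` = 5, exclusive).

## Domain-truncation profiling

Input is a pre-aligned protein set (computing alignments is out of scope)
with a source group per sequence. Per group and column, coverage is the
percentage of non-gap characters; `-`, `.` and the Unicode minus are all
accepted as gaps and normalized. Domain spans (receiver, effector) are
supplied in alignment-column coordinates rather than inferred from a
reference sequence, to avoid baking in one organism's numbering.

A sequence is `full_length` when both span coverages are ≥ 0.5,
`effector_only` when effector ≥ 0.5 and receiver ≤ 0.1, else `other`. The
0.5 / 0.1 presence/absence cutoffs are package choices — a binary call
needs explicit thresholds — and are configurable. They sit far from the
coverage values the generator produces (≈ 0.98 vs 0.0 at 2% gap noise),
so calls are insensitive to threshold choice within a wide band.

## Synthetic data: what it emulates and what it does not

The generator produces every input with known ground truth.

**Population.** One predicted host per phage (the ingest layer handles
multi-host tables; single hosts keep truth unambiguous). Exactly
`round(frac_spore_host × n_phages)` phages get a spore-forming host — the
fraction is rounding-exact by construction, not sampled. Gene presence is
an independent Bernoulli per (gene, phage) at the carriage probability for
the phage's host class; a gene's ground-truth label is "enriched" iff its
spore-host carriage probability is strictly higher. Defaults used
throughout the analyses: enriched carriage 0.2 (spore-host) vs 0.02
(other), null 0.05 everywhere — rates chosen so that a planted gene lands
at n ≈ 150 of N = 2,000, comfortably past the n > 30 gate, while null
genes stay orders of magnitude away from p < 10⁻⁶.

**Scaffolds.** Three kinds reproduce the situations curation must
separate: clean viral (focal interior, hallmark genes within 3 on each
side, remaining genes 80% hypothetical, switch fraction ≤ 0.1), bacterial
(80% housekeeping annotation from a fixed phrase list with no hallmark
terms, switch fraction ≥ 0.5), and chimeric (a bacterial block carrying
the focal gene, then a viral block). Strand switches are placed at evenly
spaced adjacent pairs (⌊rate·pairs⌋ for viral, ⌈rate·pairs⌉ for
bacterial), so the switch fraction in any local window tracks the global
rate and the kinds are separable by construction rather than merely in
expectation. Hallmark and housekeeping descriptions come from fixed
built-in phrase lists ("major capsid protein", "DNA gyrase subunit A", …)
so keyword matching is exercised on realistic text. Gene length is fixed
at 900 bp with 100 bp spacers — coordinates only need to order genes and
define edges.

**Alignments.** Full-length sequences carry residues at every column;
effector-only sequences carry residues only across the effector span
(default receiver 6–125, effector 146–255 of 260 columns, sketching a
spo0A-like receiver–linker–effector architecture). Gap noise flips
residues to gaps at `indel_rate` per column per sequence, but never
inside the receiver span of effector-only sequences, so truncation ground
truth survives the noise.

**Limits.** No sequence evolution (only gap structure), no read-level
data, no annotation scores, no realistic scaffold-length or gene-density
distributions — generator defaults are chosen for separability. Passing
tests therefore demonstrate that the statistics and rules are implemented
correctly and recover planted structure under the stated noise model; they
do not measure performance on real metagenome annotation text, real host
prediction error, or real assembly artifacts.

## Determinism and numerics

All randomness flows from one integer seed through
`numpy.random.Generator`; per-stage sub-seeds are derived arithmetically
(kept below 2³¹). Data outputs contain no timestamps or absolute paths,
SVG output pins matplotlib's `svg.hashsalt` and strips the creation date,
so a repeated run is byte-identical except `run.log`. Result ordering is
total (adjusted p, then KO id; scaffold verdicts in input order; summaries
by KO), so no output depends on dict or filesystem iteration order.

Problem sizes in the analyses and acceptance checks — 2,000 phages for
recovery, 500 for null calibration, 1,000 null genes, 110 scaffolds,
86 aligned sequences — were chosen so every check completes in seconds on
one CPU while leaving the statistical margins wide (a planted gene's tail
probability at these sizes is below 10⁻³⁰).

## Design choices that were genuinely open

- **Adjustment method**: only "adjusted P" is specified by the screen's
  convention; BH is the field default for gene-set screens and is recorded
  in output metadata.
- **Rejection conjunction**: bacterial-context rejection requires density
  AND switch frequency to be high, because each signal alone has innocent
  explanations (an integrated prophage region; a short window).
- **Candidate join**: final candidates = enriched ∧ category ≠ "unlikely
  viral". "Possible viral" genes are kept but flagged
  (`require_likely_viral` tightens this), since a handful of true viral
  scaffolds is evidence of carriage, not contamination.
- **Scaffold inspection scope**: all scaffolds of an enriched gene are
  inspected by default; the CLI exposes `--max-per-gene` for capped
  inspection.
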