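# Demo run: a synthetic phage population with eight planted spore-host-
# enriched genes (six in genuinely viral scaffold context, two planted as
# bacterial contamination), thirty null genes, and a 57+29 regulator
# alignment.  `spore-amg run --config <this file> --outdir <dir>`.
seed: 1
outdir: results/demo

population:
  n_phages: 800
  frac_spore_host: 0.3
  planted_genes:
    - {ko_id: K07699, p_carry_spore_host: 0.25, p_carry_other: 0.02, viral_context: true}   # spo0A
    - {ko_id: K03091, p_carry_spore_host: 0.25, p_carry_other: 0.02, viral_context: true}   # sigma factors
    - {ko_id: K06283, p_carry_spore_host: 0.20, p_carry_other: 0.02, viral_context: true}   # spoIIID
    - {ko_id: K04769, p_carry_spore_host: 0.20, p_carry_other: 0.02, viral_context: true}   # spoVT
    - {ko_id: K06412, p_carry_spore_host: 0.25, p_carry_other: 0.03, viral_context: true}   # spoVG
    - {ko_id: K03496, p_carry_spore_host: 0.20, p_carry_other: 0.02, viral_context: true}   # parA/soj
    - {ko_id: K01356, p_carry_spore_host: 0.25, p_carry_other: 0.02, viral_context: false}  # lexA, contamination
    - {ko_id: K02343, p_carry_spore_host: 0.20, p_carry_other: 0.02, viral_context: false}  # dnaX, contamination
  n_null_genes: 30
  null_carriage: 0.05

enrichment:
  alpha_adj: 1.0e-6
  min_n: 30
  adjust_method: BH

curation:
  n_scaffolds_per_gene: 8
  viral_n_genes: 24
  bacterial_n_genes: 20
  window: 10
  flank_reach: 3
  max_nonviral_density: 0.5
  max_strand_switch: 0.4
  edge_margin: 0
  possible_viral_max: 5

alignment:
  n_full_length: 57
  n_effector_only: 29
  receiver_span: [6, 125]
  effector_span: [146, 255]
  indel_rate: 0.02

truncation:
  present: 0.5
  absent: 0.1

require_likely_viral: false
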