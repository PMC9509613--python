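# Example pipeline configuration (small; runs in ~1 minute).
#
# Every stochastic stage derives its seed deterministically from the global
# `seed`, so re-running with the same file reproduces all outputs
# bit-for-bit.

seed: 1
simulation:
  genome:
    n_chromosomes: 2
    chromosome_length_bp: 5000000
    variants_per_chromosome: 1000      # 2,000 variants total
    recombination_rate: 1.0e-8         # Morgans per bp
    founder_ld_decay: 5000.0           # bp scale of founder LD decay
  lines:
    - name: A
      n_founders: 120
      n_generations: 2
      n_sires: 20
      n_dams: 50
      litter_size: 5
  chip:
    n_variants: 300                    # nested marker array
    maf_min: 0.01
  traits:
    - name: t1
      n_qtn: 30
      h2: 0.5
      qtn_panel: wgs_only              # causal variants kept off the chip
  write_vcf: false
analysis:
  use_phenotypes: true                 # bypass BLUP/deregression
  window_bp: 55000
  p_threshold: 1.0e-6
  variant_sets: [chip, top, chipplussign]
  min_family_size: 5
  rel_threshold: 0.5
  bayesr:
    n_iterations: 1000
    burn_in: 400
    thin: 5
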