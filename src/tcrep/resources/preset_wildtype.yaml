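# Polyclonal ("wild-type-like") cohort: 8 spleen samples, ~2e5 templates
# each over 1e5 background clones, CDR3 amino-acid lengths Gaussian around
# 14 aa, no planted dominant clones.
seed: 101
dialect: airr
groups:
  - name: wildtype
    n_subjects: 8
    paired: false
    config:
      n_templates: 200000
      n_clones_background: 100000
      cdr3_aa_length_mean: 14.0
      cdr3_aa_length_sd: 1.2
      productive_fraction_target: 0.85
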