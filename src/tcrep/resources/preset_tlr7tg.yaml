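# Oligoclonal ("TLR7tg-like") cohort: 8 subjects, each with a spleen sample
# (~2e5 templates) and a paired, smaller brain sample (~13k templates, about
# the cell yield of a lupus-prone brain).  Ten planted dominant clones: the
# top at 30.1% of productive templates and the ten together at 60.5%, with
# strong spleen-brain clone sharing (rho = 0.9).
seed: 202
dialect: airr
groups:
  - name: tlr7tg
    n_subjects: 8
    paired: true
    config:
      n_templates: 200000
      brain_n_templates: 13000
      n_clones_background: 20000
      cdr3_aa_length_mean: 14.0
      cdr3_aa_length_sd: 1.2
      planted_dominants: [0.301, 0.08, 0.06, 0.045, 0.035, 0.027, 0.022, 0.015, 0.012, 0.008]
      tissue_share_rho: 0.9
      productive_fraction_target: 0.85
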