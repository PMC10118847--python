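# tcrep — TCRβ repertoire clonal-dominance analysis

`tcrep` is a transparent, tested toolkit for analysing bulk TCRβ CDR3
repertoire sequencing of sorted T-cell populations — the kind of data used
to ask whether a CD8⁺ T-cell pool is polyclonal or dominated by a few
expanded clones (for example in murine lupus models, where the splenic and
brain-infiltrating CD8⁺ repertoire collapses onto a handful of clones, the
top one reaching ~30% of all productive templates, versus <0.4% in healthy
controls).

It is written for immunologists who receive rearrangement tables from a
sequencing provider (AIRR Rearrangement TSV or ImmunoSEQ-style export) and
want every downstream statistic to be reproducible and inspectable rather
than locked inside vendor software. A built-in synthetic V(D)J cohort
generator reproduces the statistical structure of polyclonal and
oligoclonal repertoires, so the entire pipeline can be exercised and
validated with no external data.

## What it computes

* **Clonality / diversity** — unique productive rearrangements, productive
  templates, productive fraction, top-clone and top-10 dominance, and the
  normalised-entropy clonality index

  clonality = 1 − H / ln R,  H = −Σᵢ fᵢ ln fᵢ,

  where fᵢ are clone frequencies over productive templates and R is the
  number of unique productive clones (0 = perfectly even, 1 = monoclonal;
  the ratio H/ln R is log-base invariant).
* **Spectratype** — CDR3 length histograms (nt or aa, template- or
  clone-weighted) with a least-squares Gaussian fit
  a·exp(−(x−μ)²/2σ²) and its R²; polyclonal repertoires are ~Gaussian
  around 14 aa, clonal expansions degrade the fit.
* **Gene usage** — per-sample V/D/J segment usage with dual IMGT / original
  Vβ nomenclature, gene-by-gene two-group comparison by two-tailed Welch
  t test with Benjamini–Hochberg FDR q values, and one-way ANOVA + Tukey
  HSD for 3+ groups.
* **Sharing and overlap** — exact CDR3-nucleotide sharing, 2/3-way Venn
  region counts, and the Morisita–Horn index
  MH = 2Σxᵢyᵢ / ((dₓ+d_y)·X·Y) over template counts keyed by CDR3 sequence.
* **Dominant clones** — per-sample top clone, pairwise CDR3 amino-acid
  percent identity (global alignment for unequal lengths), and convergent
  recombination groups (identical amino-acid CDR3 from distinct
  nucleotide rearrangements or V genes).
* **Simulation** — polyclonal or oligoclonal cohorts with planted dominant
  clones, a Gaussian CDR3-length junction model, a controllable productive
  fraction, and paired spleen/brain samples with tunable clone sharing.

## Worked example

Simulate a small mixed cohort (two polyclonal "wildtype" spleens plus three
oligoclonal "tlr7tg" subjects with paired spleen/brain samples), analyse it,
and print the digest:

```bash
cat > cohort.yaml <<'EOF'
seed: 7
dialect: immunoseq
groups:
  - name: wildtype
    n_subjects: 3
    paired: false
    config:
      n_templates: 5000
      n_clones_background: 2000
  - name: tlr7tg
    n_subjects: 3
    paired: true
    config:
      n_templates: 5000
      brain_n_templates: 1500
      n_clones_background: 1000
      planted_dominants: [0.301, 0.08, 0.06, 0.045, 0.035, 0.027, 0.022, 0.015, 0.012, 0.008]
      tissue_share_rho: 0.9
EOF
tcrep simulate --config cohort.yaml --out run
tcrep analyze --manifest run/manifest.tsv --out run/analysis --min-templates 1000
tcrep report --dir run/analysis
```

which prints:

```
tcrep report (tcrep 0.1.0)

samples: 9 listed, 9 passed QC (min templates 1000)

clonality and dominance by group:
  tlr7tg: mean clonality 0.3441, top-clone frequency 0.2837-0.3108, mean top-10 sum 0.6090
  wildtype: mean clonality 0.0387, top-clone frequency 0.0047-0.0056, mean top-10 sum 0.0374

spectratype Gaussian fits (group-average curves):
  tlr7tg: mean 13.8951 aa, R^2 0.8642
  wildtype: mean 13.9844 aa, R^2 0.9998

differential gene usage:
  V: 3 gene(s) at q <= 0.05: TRBV13-2, TRBV13-3, TRBV17
  D: 0 gene(s) at q <= 0.05: none
  J: 2 gene(s) at q <= 0.05: TRBJ1-5, TRBJ2-3

overlap (Morisita-Horn): mean off-diagonal 0.0830, max 0.9972

dominant clones:
  tlr7tg: top-clone frequency range 0.2837-0.3108
  wildtype: top-clone frequency range 0.0047-0.0056
```

Reading the digest: the oligoclonal arm has ~9-fold higher clonality, its
planted top clone is recovered near its 30.1% target while wild-type top
clones stay below 1%, the wild-type length spectrum is near-perfectly
Gaussian (R² 0.9998) while planted dominants distort the oligoclonal one,
and the only near-unit Morisita–Horn overlaps (max 0.997) are the
within-subject spleen–brain pairs. The V-gene hits reflect the template
mass the dominant clones concentrate on their particular V segments.

All analysis outputs are plain TSVs under `run/analysis/` (clonal summary,
spectratype histograms and fits, long-format usage with both nomenclatures,
comparison tables with p/q values, overlap matrix, dominant-clone report,
convergence groups) plus a JSON run manifest with QC status per sample.
Presets `wildtype-like` and `tlr7tg-like` (8 subjects each, study-scale
template counts) can be passed directly to `tcrep simulate --config`.

The same operations are available as a library:

```python
from tcrep import SyntheticConfig, generate_repertoire, summarize

cfg = SyntheticConfig(seed=1, n_templates=100_000, n_clones_background=20_000,
                      planted_dominants=(0.301,))
cs = summarize(generate_repertoire(cfg))
print(cs.top_clone_frequency)   # 0.30085...
print(cs.clonality)             # 0.25948...
```

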