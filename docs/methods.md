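# Methods

This note documents the statistical model behind `tcrep`, the synthetic
repertoire generator it ships, the numerical choices made where several
conventions exist, and the limits of what the test suite demonstrates.

## Data model and frame classification

A clonotype record carries a CDR3 junction nucleotide sequence, V/D/J gene
calls, and a template count (the number of input DNA molecules observed for
that rearrangement, a proxy for cell count). Frame status is always
recomputed from the sequence: *out-of-frame* when the nucleotide length is
not divisible by 3, *has-stop* when the in-frame translation (standard
codon table, stop rendered `*`) contains a stop codon, *productive*
otherwise. These three statuses partition every record. If an input file
carries its own `productive`/`frame_type` annotation it is compared against
the recomputed status and disagreements are logged, but the recomputed value
always wins — a single source of truth keeps productive-only statistics
consistent across input dialects.

Clone identity within a sample is the triple (CDR3 nt, V gene, J gene):
identical amino-acid CDR3s arising from different nucleotide rearrangements
or V genes are genuinely different clones (convergent recombination) and
must not be merged. Cross-sample *sharing*, by contrast, is keyed on the
CDR3 nucleotide sequence alone, because two repertoires share a clone when
the same junction was sequenced in both; the stricter key is available as
an option. Duplicate keys on ingest are merged by summing template counts,
which makes ingest permutation-invariant.

## Clonality

Clonality is the normalised-entropy complement `1 − H/ln R` with `H` the
Shannon entropy (natural log) of clone frequencies over productive
templates and `R` the number of unique productive clones. The ratio
`H/ln R` is identical in any log base, so the value does not depend on that
convention. The single-clone case (`R = 1`) is defined as 1 (maximal
dominance). An empty productive set raises an error rather than returning
zero: a silent zero would contaminate group means. Frequency ties are
broken lexicographically by CDR3 sequence so ranked lists are
deterministic.

Top-clone and top-10 frequencies are template-weighted fractions of
productive templates (the convention of repertoire-assay summary panels);
clone-weighted variants can be obtained by comparing unique counts
directly.

## Spectratype

The CDR3 length histogram is built on the productive subset, template-
weighted by default (relative abundance, not richness); zero bins inside
the observed length range are kept, lengths outside it are not padded. The
amino-acid unit is nt length / 3. A Gaussian `a·exp(−(x−μ)²/2σ²)` is fitted
by least squares (`scipy.optimize.curve_fit`) and summarised by
`R² = 1 − SS_res/SS_tot` over all bins. Initialisation is deterministic —
amplitude from the tallest bin, μ and σ from abundance-weighted moments —
plus a second deterministic start centred on the tallest bin, because the
moment start can sit on a symmetric saddle for strongly bimodal histograms
(the optimiser then "fits" a flat curve). The better of the two solutions
by residual sum of squares is reported. R² of a nonlinear fit can be
negative and is reported unclamped. Fits need at least three distinct
lengths. Both per-sample fits and a group-average-histogram fit are
provided; the group curve averages per-sample relative-abundance histograms
aligned on the union of their length ranges.

## Gene usage comparison

Usage of segment g in a sample is the fraction of productive templates
(default) or unique clones carrying g; unresolved D calls form an explicit
`unresolved` column so each row stays a probability vector. Two-group
comparison runs a per-gene two-tailed Welch (unequal-variance) t test with
Benjamini–Hochberg q values computed across the genes of one segment class
— BH being the standard choice where only "FDR-adjusted q values" is
specified. Genes with zero variance in both groups get p = 1 when the means
agree and p = 0 otherwise (the Welch statistic is undefined there);
all-zero genes are dropped before testing to avoid spurious degrees of
freedom. Three or more groups go through one-way ANOVA with Tukey HSD.
Dual IMGT/original Vβ labelling is presentation-only and never touches the
numbers; the bundled murine TRBV↔Vβ table is an editable TSV resource, and
unmapped names (e.g. pseudogenes) pass through unchanged with a flag.

## Overlap and homology

The repertoire "Morisita index" is implemented as the Morisita–Horn index
(bounded in [0, 1], abundance-weighted), computed over template counts
keyed by CDR3 nucleotide sequence; the classical Morisita variant is
available behind a flag but is not bounded by 1 on small samples. The
default read scope for sharing analyses is *in-frame* (productive plus
stop-containing in-frame reads), with productive-only as an option — both
are supported because "in-frame reads" is ambiguous about stop-containing
rearrangements.

Percent identity of two CDR3 amino-acid sequences is position-wise for
equal lengths. For unequal lengths a global alignment maximises the score
match = 1 / mismatch = 0 / gap = −1; among equal-score alignments the one
with the most matches is taken, and identity = matches / alignment length.
With that scoring the alignment length is determined by the optimum:
alen = (|a| + |b| + matches − score) / 2, which makes the value
deterministic without materialising an alignment. Convergence groups
partition clones by amino-acid CDR3 and flag groups of ≥ 2 members that
differ in nucleotide sequence or V gene.

## Synthetic repertoire generator

The generator emulates the statistics a bulk TCRβ assay sees, not the
biology that produces them:

* **Junction model** — V, D, J names drawn from configurable usage vectors
  (default: uniform over 18 murine TRBV, 2 TRBD, 11 TRBJ names). A clone's
  CDR3 is a fixed 9-nt V-derived prefix (translating to `CAS`, so junctions
  start with the canonical cysteine), uniform-random non-stop interior
  codons, and a fixed 6-nt suffix per J segment. CDR3 amino-acid length is
  a rounded Gaussian, default mean 14 aa and SD 1.2 aa, floored at 5 aa —
  the polyclonal length profile a healthy murine CD8⁺ repertoire shows.
* **Abundance model** — planted dominant frequencies are interpreted as
  fractions of *productive* templates, the scale on which dominance is
  reported. Template mass is split into a productive fraction f (default
  0.85, a typical productive-template fraction for genomic-DNA TCRβ
  libraries, applied identically to all groups) and a non-productive pool
  of mass 1 − f built from frameshifted (±1 nt) or stop-substituted
  variants of otherwise valid junctions, equiprobably. Within the
  productive mass, planted dominants take their target frequencies and the
  residual follows a symmetric Dirichlet (concentration 1, configurable)
  over `n_clones_background` clones. Template counts are a single
  multinomial draw, so planted frequencies are recovered to within
  multinomial error and the realised productive fraction is binomial around
  f. (A per-clone non-productive flip applied after fixing planted
  frequencies would bias the planted clones' productive-scale frequencies
  upward by ≈ 1/f; the mass-split construction avoids that. The standalone
  single-clone sampler keeps the per-clone flip, which is the natural
  clone-level contract.)
* **Paired tissues** — each brain template comes from the realised spleen
  composition with probability ρ (`tissue_share_rho`, default 0.9),
  otherwise from a brain-private pool that still contains the planted
  dominants. At ρ = 1 every brain clone exists in the spleen sample; at
  ρ = 0 sharing reduces to the planted dominants; the dominant clone is
  shared at any ρ. The default brain sample is ~13,000 templates against a
  200,000-template spleen, matching the cell-yield asymmetry of brain
  versus spleen sorts; the private pool size scales with that ratio unless
  overridden.
* **Cohorts** — per-subject RNG streams are spawned deterministically from
  the master seed, so subjects are independent (dominant clones differ
  across subjects with probability ≈ 1 in the large junction space) and
  identical config + seed reproduces a cohort byte-for-byte.

The bundled presets encode the two study conditions: `wildtype-like`
(8 subjects, 2×10⁵ templates over 10⁵ background clones, no dominants —
top clones land well below 0.4%) and `tlr7tg-like` (8 subjects, paired
tissues, ten planted dominants: top clone 30.1% and top-10 sum 60.5% of
productive templates).

What the generator does **not** model: thymic selection, real V(D)J
insertion/deletion statistics, nonuniform segment usage, sequencing error,
PCR amplification bias, or a power-law clone-size tail (the Dirichlet tail
is a deliberate minimal stand-in; its concentration is exposed for heavier
tails). Passing tests therefore demonstrate that the analysis stack
recovers planted structure under idealised sampling noise — not that it is
robust to assay artefacts.

## Pipeline and QC

`tcrep analyze` excludes samples below a minimum template count (default
1000, the practical minimum cell input for a reliable bulk TCRβ library;
configurable) with a logged warning and records per-sample QC status in a
JSON run manifest; it is a hard error when nothing passes. The reporter
derives every number in its digest from the analysis TSVs alone. Outputs
carry no timestamps, so simulate → analyze → report under a fixed seed is
byte-identical across runs.

## Problem sizes used in the tests

The acceptance-style tests run the dominance-recovery check at the full
study scale (8 subjects × 10⁵ templates oligoclonal; 8 × 2×10⁵ over 10⁵
background clones polyclonal). Spectratype recovery uses 8 samples of
3×10⁴ templates; the usage-test calibration uses 200 null cohorts and 100
planted-effect cohorts of 8-vs-8 samples at 2×10³ templates over 300
clones; tissue-sharing structure uses 20 cohorts of 4 paired subjects at
2×10⁴/1.5×10³ templates. Percent-identity is verified exhaustively against
an alignment-enumeration oracle for all string pairs of length ≤ 3 over a
4-letter alphabet, on random longer pairs against the same oracle, and
cross-checked against Biopython's co-optimal global alignments up to length
8 (full exhaustion at length 8 — ~10⁹ pairs — is not meaningful to run).

## Known limitations

* The Welch test on compositional usage frequencies ignores the negative
  correlation the simplex constraint induces between genes; the
  calibration test shows the per-gene type-I error is near nominal at the
  simulated depths, but q values across genes are not strictly independent.
* When one group has zero variance for a gene (e.g. a segment entirely
  absent), the Welch degrees of freedom collapse to n−1 of the other group,
  which bounds how small the p value can get for small cohorts.
* The percent-identity alignment convention (maximise matches, unit gap
  penalty) is one of several reasonable choices for unequal-length CDR3s;
  values for unequal lengths depend on it.
* The Gaussian spectratype fit treats bins as homoscedastic; no weighting
  by bin mass is applied.
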