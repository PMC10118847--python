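"""Synthetic TCRβ repertoire generator.

Emulates the statistical structure of murine CD8⁺ repertoires as seen by a
bulk TCRβ CDR3 assay: a large polyclonal background whose CDR3 amino-acid
lengths are Gaussian (default mean 14 aa), an optional set of planted
dominant clones with fixed frequencies (oligoclonal, lupus-prone-like
repertoires), a controllable productive-template fraction, and paired
spleen/brain samples per subject with tunable clone sharing.

Model outline
-------------
* V, D and J segment names are drawn from configurable usage vectors.
* A clone's CDR3 nucleotide sequence is assembled as a fixed 9-nt V-derived
  prefix (so translations start with ``CAS``), uniform-random non-stop
  interior codons, and a fixed 6-nt suffix per J segment.  CDR3 amino-acid
  length is a discretised Gaussian, floored at 5 aa.
* Clone abundances: planted dominant frequencies are interpreted as
  fractions of *productive* templates (the convention of repertoire-assay
  reports); the residual productive mass follows a symmetric Dirichlet over
  ``n_clones_background`` clones; non-productive mass
  ``1 − productive_fraction_target`` is carried by a separate pool of
  frameshifted or stop-containing variants.  Template counts are one
  multinomial draw of ``n_templates``.
* Paired tissues: each brain template comes from the realised spleen
  composition with probability ``tissue_share_rho``, otherwise from a
  brain-private pool that still contains the planted dominants, so the
  dominant clone is shared between tissues at any ρ.

Identical config + seed gives identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import Rearrangement, RepertoireSample

MIN_CDR3_AA = 5
V_PREFIX = "TGTGCAAGC"  # translates to C-A-S
_N_PREFIX_CODONS = 3
_N_SUFFIX_CODONS = 2

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOP_CODONS
)

DEFAULT_V_SEGMENTS = (
    "TRBV1", "TRBV2", "TRBV4", "TRBV5", "TRBV12-1", "TRBV12-2",
    "TRBV13-1", "TRBV13-2", "TRBV13-3", "TRBV14", "TRBV15", "TRBV16",
    "TRBV17", "TRBV19", "TRBV20", "TRBV26", "TRBV29", "TRBV31",
)
DEFAULT_D_SEGMENTS = ("TRBD1", "TRBD2")
DEFAULT_J_SEGMENTS = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-7",
)


def _j_suffix(j_name: str) -> str:
    """Fixed 6-nt (two non-stop codons) suffix, deterministic per J segment."""
    h = zlib.crc32(j_name.encode())
    c1 = NONSTOP_CODONS[h % len(NONSTOP_CODONS)]
    c2 = NONSTOP_CODONS[(h // len(NONSTOP_CODONS)) % len(NONSTOP_CODONS)]
    return c1 + c2


def _uniform_usage(names: Sequence[str]) -> dict[str, float]:
    p = 1.0 / len(names)
    return {n: p for n in names}


def _check_usage(name: str, usage: dict[str, float]) -> None:
    if not usage:
        raise ConfigError(f"{name}: usage vector is empty")
    total = sum(usage.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: usage probabilities sum to {total}, not 1")
    if any(p < 0 for p in usage.values()):
        raise ConfigError(f"{name}: negative probability")


@dataclass
class SyntheticConfig:
    """Full parameterisation of the repertoire generator.

    ``planted_dominants`` are target frequencies *among productive
    templates*; ``planted_lengths`` optionally pins each dominant's CDR3
    amino-acid length (otherwise sampled like any clone).
    """

    seed: int = 0
    n_templates: int = 200_000
    n_clones_background: int = 100_000
    v_usage: dict[str, float] | None = None
    d_usage: dict[str, float] | None = None
    j_usage: dict[str, float] | None = None
    cdr3_aa_length_mean: float = 14.0
    cdr3_aa_length_sd: float = 1.2
    planted_dominants: tuple[float, ...] = ()
    planted_lengths: tuple[int, ...] | None = None
    productive_fraction_target: float = 0.85
    tissue_share_rho: float = 0.9
    brain_n_templates: int = 13_000
    brain_private_clones: int | None = None
    dirichlet_concentration: float = 1.0
    n_subjects_per_group: int = 8

    def __post_init__(self) -> None:
        if self.v_usage is None:
            self.v_usage = _uniform_usage(DEFAULT_V_SEGMENTS)
        if self.d_usage is None:
            self.d_usage = _uniform_usage(DEFAULT_D_SEGMENTS)
        if self.j_usage is None:
            self.j_usage = _uniform_usage(DEFAULT_J_SEGMENTS)
        self.planted_dominants = tuple(float(f) for f in self.planted_dominants)
        if self.planted_lengths is not None:
            self.planted_lengths = tuple(int(x) for x in self.planted_lengths)
        self.validate()

    def validate(self) -> None:
        _check_usage("v_usage", self.v_usage)
        _check_usage("d_usage", self.d_usage)
        _check_usage("j_usage", self.j_usage)
        if self.cdr3_aa_length_sd <= 0:
            raise ConfigError("cdr3_aa_length_sd must be > 0")
        if not (0 < self.productive_fraction_target <= 1):
            raise ConfigError("productive_fraction_target must be in (0, 1]")
        if not (0 <= self.tissue_share_rho <= 1):
            raise ConfigError("tissue_share_rho must be in [0, 1]")
        if any(not (0 < f < 1) for f in self.planted_dominants):
            raise ConfigError("planted dominant frequencies must lie in (0, 1)")
        if sum(self.planted_dominants) >= 1:
            raise ConfigError("planted dominant frequencies must sum to < 1")
        if self.planted_lengths is not None and len(self.planted_lengths) != len(
            self.planted_dominants
        ):
            raise ConfigError("planted_lengths must match planted_dominants")
        if self.planted_lengths is not None and any(
            l < MIN_CDR3_AA for l in self.planted_lengths
        ):
            raise ConfigError(f"planted lengths must be >= {MIN_CDR3_AA} aa")
        if self.n_templates < max(1, len(self.planted_dominants)):
            raise ConfigError("n_templates smaller than the number of planted clones")
        if self.n_clones_background < 1:
            raise ConfigError("n_clones_background must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be > 0")


# ---------------------------------------------------------------------------
# sequence-level sampling


def _sample_sequences(
    config: SyntheticConfig,
    rng: np.random.Generator,
    n: int,
    lengths: np.ndarray | None = None,
) -> list[tuple[str, str, str, str]]:
    """Draw ``n`` productive junction sequences with V/D/J assignments."""
    v_names = list(config.v_usage)
    d_names = list(config.d_usage)
    j_names = list(config.j_usage)
    v_idx = rng.choice(len(v_names), size=n, p=list(config.v_usage.values()))
    d_idx = rng.choice(len(d_names), size=n, p=list(config.d_usage.values()))
    j_idx = rng.choice(len(j_names), size=n, p=list(config.j_usage.values()))
    if lengths is None:
        raw = rng.normal(config.cdr3_aa_length_mean, config.cdr3_aa_length_sd, n)
        lengths = np.maximum(np.rint(raw).astype(int), MIN_CDR3_AA)
    n_interior = lengths - (_N_PREFIX_CODONS + _N_SUFFIX_CODONS)
    flat = rng.integers(0, len(NONSTOP_CODONS), size=int(n_interior.sum()))
    bounds = np.concatenate([[0], np.cumsum(n_interior)])
    suffixes = {name: _j_suffix(name) for name in j_names}
    out = []
    for i in range(n):
        interior = "".join(
            NONSTOP_CODONS[k] for k in flat[bounds[i] : bounds[i + 1]]
        )
        j = j_names[j_idx[i]]
        out.append(
            (V_PREFIX + interior + suffixes[j], v_names[v_idx[i]],
             d_names[d_idx[i]], j)
        )
    return out


def _corrupt(cdr3_nt: str, rng: np.random.Generator) -> str:
    """Make a productive junction non-productive.

    Frameshift (±1 nt) or a forced in-frame stop codon, equiprobably; stop
    insertion needs at least one interior codon, otherwise frameshift.
    """
    n_codons = len(cdr3_nt) // 3
    can_stop = n_codons - (_N_PREFIX_CODONS + _N_SUFFIX_CODONS) >= 1
    if can_stop and rng.random() < 0.5:
        k = int(rng.integers(0, n_codons - _N_PREFIX_CODONS - _N_SUFFIX_CODONS))
        pos = 3 * (_N_PREFIX_CODONS + k)
        stop = _STOP_CODONS[int(rng.integers(0, len(_STOP_CODONS)))]
        return cdr3_nt[:pos] + stop + cdr3_nt[pos + 3 :]
    if rng.random() < 0.5:  # delete one nucleotide
        pos = int(rng.integers(0, len(cdr3_nt)))
        return cdr3_nt[:pos] + cdr3_nt[pos + 1 :]
    pos = int(rng.integers(0, len(cdr3_nt) + 1))
    base = _BASES[int(rng.integers(0, 4))]
    return cdr3_nt[:pos] + base + cdr3_nt[pos:]


def generate_clone(
    config: SyntheticConfig, rng: np.random.Generator
) -> Rearrangement:
    """Draw a single clone from the junction model.

    With probability ``1 − productive_fraction_target`` the clone is made
    non-productive (frameshift or forced stop).
    """
    nt, v, d, j = _sample_sequences(config, rng, 1)[0]
    if rng.random() > config.productive_fraction_target:
        nt = _corrupt(nt, rng)
    return Rearrangement.from_nt(nt, v_gene=v, j_gene=j, d_gene=d)


# ---------------------------------------------------------------------------
# repertoire-level sampling


def _build_pool(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, str, str, str]], np.ndarray, list[int]]:
    """Clone pool and its abundance vector.

    Returns (clone tuples, probabilities, indices of planted dominants).
    Probabilities sum to 1: planted + Dirichlet productive tail scaled to
    the productive mass, plus a non-productive pool carrying the rest.
    """
    f = config.productive_fraction_target
    planted_freqs = np.asarray(config.planted_dominants, dtype=float)
    planted_mass = float(planted_freqs.sum())

    lengths = None
    if config.planted_lengths is not None:
        lengths = np.asarray(config.planted_lengths, dtype=int)
    planted = (
        _sample_sequences(config, rng, len(planted_freqs), lengths=lengths)
        if len(planted_freqs)
        else []
    )

    n_bg = config.n_clones_background
    background = _sample_sequences(config, rng, n_bg)
    tail = rng.dirichlet([config.dirichlet_concentration] * n_bg)

    clones = list(planted) + background
    probs = np.concatenate([planted_freqs * f, tail * (1 - planted_mass) * f])

    if f < 1:
        n_np = max(1, int(round(n_bg * (1 - f))))
        np_seqs = _sample_sequences(config, rng, n_np)
        np_clones = [
            (_corrupt(nt, rng), v, d, j) for (nt, v, d, j) in np_seqs
        ]
        np_tail = rng.dirichlet([config.dirichlet_concentration] * n_np)
        clones += np_clones
        probs = np.concatenate([probs, np_tail * (1 - f)])

    probs = probs / probs.sum()
    return clones, probs, list(range(len(planted)))


def _sample_to_records(
    clones: list[tuple[str, str, str, str]], counts: np.ndarray
) -> list[Rearrangement]:
    recs = []
    for (nt, v, d, j), c in zip(clones, counts):
        if c > 0:
            recs.append(
                Rearrangement.from_nt(nt, v_gene=v, j_gene=j, d_gene=d,
                                      template_count=int(c))
            )
    return recs


def generate_repertoire(
    config: SyntheticConfig,
    sample_id: str = "synthetic",
    subject_id: str = "",
    tissue: str = "spleen",
    group: str = "",
    rng: np.random.Generator | None = None,
) -> RepertoireSample:
    """Generate one repertoire sample from the clone-abundance model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clones, probs, _ = _build_pool(config, rng)
    counts = rng.multinomial(config.n_templates, probs)
    return RepertoireSample.from_records(
        _sample_to_records(clones, counts),
        sample_id=sample_id,
        subject_id=subject_id,
        tissue=tissue,
        group=group,
    )


def generate_paired_tissues(
    config: SyntheticConfig,
    subject_id: str = "subject",
    group: str = "",
    rng: np.random.Generator | None = None,
) -> tuple[RepertoireSample, RepertoireSample]:
    """Generate a spleen sample and a paired, smaller brain sample.

    Each brain template is drawn from the realised spleen composition with
    probability ``tissue_share_rho``, otherwise from a brain-private pool
    that contains the planted dominants plus a private Dirichlet tail, so at
    ρ = 1 every brain clone is present in the spleen sample and at ρ = 0
    sharing is limited to the planted dominants.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clones, probs, planted_idx = _build_pool(config, rng)
    spleen_counts = rng.multinomial(config.n_templates, probs)
    spleen = RepertoireSample.from_records(
        _sample_to_records(clones, spleen_counts),
        sample_id=f"{subject_id}-spleen",
        subject_id=subject_id,
        tissue="spleen",
        group=group,
    )

    rho = config.tissue_share_rho
    f = config.productive_fraction_target
    planted_freqs = np.asarray(config.planted_dominants, dtype=float)
    planted_mass = float(planted_freqs.sum())

    # brain-private pool: planted dominants + private productive tail
    # (+ private non-productive pool when f < 1)
    n_private = config.brain_private_clones
    if n_private is None:
        n_private = max(
            1,
            int(round(config.n_clones_background
                      * config.brain_n_templates / config.n_templates)),
        )
    private = _sample_sequences(config, rng, n_private)
    private_tail = rng.dirichlet([config.dirichlet_concentration] * n_private)
    fresh_clones = [clones[i] for i in planted_idx] + private
    fresh_probs = np.concatenate(
        [planted_freqs * f, private_tail * (1 - planted_mass) * f]
    )
    if f < 1:
        n_np = max(1, int(round(n_private * (1 - f))))
        np_seqs = _sample_sequences(config, rng, n_np)
        np_clones = [(_corrupt(nt, rng), v, d, j) for (nt, v, d, j) in np_seqs]
        np_tail = rng.dirichlet([config.dirichlet_concentration] * n_np)
        fresh_clones += np_clones
        fresh_probs = np.concatenate([fresh_probs, np_tail * (1 - f)])

    # mixture over clone keys: rho * realised spleen + (1 - rho) * fresh
    total_spleen = spleen_counts.sum()
    mass: dict[tuple[str, str, str], float] = {}
    pool: dict[tuple[str, str, str], tuple[str, str, str, str]] = {}
    if rho > 0:
        for clone, c in zip(clones, spleen_counts):
            if c > 0:
                key = (clone[0], clone[1], clone[3])
                mass[key] = mass.get(key, 0.0) + rho * c / total_spleen
                pool.setdefault(key, clone)
    if rho < 1:
        for clone, p in zip(fresh_clones, fresh_probs):
            key = (clone[0], clone[1], clone[3])
            mass[key] = mass.get(key, 0.0) + (1 - rho) * p
            pool.setdefault(key, clone)

    keys = sorted(mass)
    brain_probs = np.array([mass[k] for k in keys])
    brain_probs = brain_probs / brain_probs.sum()
    brain_counts = rng.multinomial(config.brain_n_templates, brain_probs)
    brain = RepertoireSample.from_records(
        _sample_to_records([pool[k] for k in keys], brain_counts),
        sample_id=f"{subject_id}-brain",
        subject_id=subject_id,
        tissue="brain",
        group=group,
    )
    return spleen, brain


@dataclass
class GroupSpec:
    """One cohort arm: group label, subject count, pairing, generator config."""

    name: str
    n_subjects: int | None = None
    paired: bool = False
    config: SyntheticConfig | None = None


def generate_cohort(
    config: SyntheticConfig, groups: Sequence[GroupSpec]
) -> list[RepertoireSample]:
    """Generate a multi-group cohort with per-subject derived seeds.

    Subjects are independent: dominant clones are drawn separately per
    subject, so cross-subject nucleotide sharing is low.  The master seed
    lives in ``config``; group specs may override the generator config.
    """
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate group names in cohort: {names}")
    ss = np.random.SeedSequence(config.seed)
    total = sum(
        (g.n_subjects if g.n_subjects is not None else config.n_subjects_per_group)
        for g in groups
    )
    children = iter(ss.spawn(total))
    samples: list[RepertoireSample] = []
    for g in groups:
        gcfg = g.config if g.config is not None else config
        n_subj = g.n_subjects if g.n_subjects is not None else config.n_subjects_per_group
        for i in range(1, n_subj + 1):
            rng = np.random.default_rng(next(children))
            subject = f"{g.name}-s{i:02d}"
            if g.paired:
                spleen, brain = generate_paired_tissues(
                    gcfg, subject_id=subject, group=g.name, rng=rng
                )
                samples += [spleen, brain]
            else:
                samples.append(
                    generate_repertoire(
                        gcfg,
                        sample_id=f"{subject}-spleen",
                        subject_id=subject,
                        tissue="spleen",
                        group=g.name,
                        rng=rng,
                    )
                )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate sample_ids in generated cohort")
    return samples
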