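"""Cross-sample repertoire sharing and dominant-clone characterisation.

Sharing is keyed on the CDR3 nucleotide sequence alone (not V/J), because
two samples share a clone when the same junction was sequenced in both; a
stricter (cdr3_nt, v_gene, j_gene) key is available via ``key_mode``.
The default read scope is ``in_frame`` (productive plus stop-containing
in-frame reads); ``productive`` restricts to productive only.

The "Morisita index" of repertoire comparisons is implemented as the
Morisita–Horn index, the bounded abundance-weighted variant

    MH = 2 Σ xᵢyᵢ / ((dₓ + d_y) · X · Y),   dₓ = Σ xᵢ²/X²,  d_y = Σ yᵢ²/Y²

which is 1 for identical compositions, 0 for disjoint ones, and invariant
to proportional rescaling of either sample's counts.  The classical
Morisita index (unbiased for counts, not bounded by 1) is available with
``variant="classical"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import clone_frequencies
from .errors import EmptyRepertoireError, TcrepError
from .io import HAS_STOP, PRODUCTIVE, Rearrangement, RepertoireSample

IN_FRAME = "in_frame"
PRODUCTIVE_SCOPE = "productive"


def _scoped(sample: RepertoireSample, scope: str) -> list[Rearrangement]:
    if scope == IN_FRAME:
        keep = (PRODUCTIVE, HAS_STOP)
    elif scope == PRODUCTIVE_SCOPE:
        keep = (PRODUCTIVE,)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return [r for r in sample.rearrangements if r.frame_status in keep]


def _counts_by_key(
    sample: RepertoireSample, scope: str, key_mode: str = "cdr3_nt"
) -> dict:
    counts: dict = {}
    for r in _scoped(sample, scope):
        key = r.cdr3_nt if key_mode == "cdr3_nt" else r.key
        counts[key] = counts.get(key, 0) + r.template_count
    return counts


def shared_sequences(
    a: RepertoireSample, b: RepertoireSample, scope: str = IN_FRAME
) -> set[str]:
    """Exact-match intersection of CDR3 nucleotide sequences within scope."""
    sa = {r.cdr3_nt for r in _scoped(a, scope)}
    sb = {r.cdr3_nt for r in _scoped(b, scope)}
    return sa & sb


def venn_counts(
    samples: list[RepertoireSample], scope: str = IN_FRAME
) -> dict[tuple[str, ...], int]:
    """Cardinalities of the disjoint Venn regions of 2 or 3 samples.

    Keys are tuples of the sample_ids whose exclusive region the count
    belongs to; the regions partition the union of CDR3 sequences.
    """
    if len(samples) not in (2, 3):
        raise TcrepError(
            "venn_counts supports 2 or 3 samples; use overlap_matrix for more"
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise TcrepError(f"duplicate sample_ids in venn_counts: {ids}")
    sets = {s.sample_id: {r.cdr3_nt for r in _scoped(s, scope)} for s in samples}
    exclusive: dict[tuple[str, ...], int] = {}
    for k in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            inside = set.intersection(*(sets[i] for i in combo))
            for other in ids:
                if other not in combo:
                    inside = inside - sets[other]
            exclusive[combo] = len(inside)
    return exclusive


def morisita(
    a: RepertoireSample,
    b: RepertoireSample,
    scope: str = IN_FRAME,
    variant: str = "horn",
    key_mode: str = "cdr3_nt",
) -> float:
    """Morisita–Horn (default) or classical Morisita overlap of two samples."""
    xa = _counts_by_key(a, scope, key_mode)
    xb = _counts_by_key(b, scope, key_mode)
    if not xa or not xb:
        empty = a.sample_id if not xa else b.sample_id
        raise EmptyRepertoireError(f"no records in scope {scope!r} for {empty!r}")
    keys = set(xa) | set(xb)
    x = np.array([xa.get(k, 0) for k in keys], dtype=float)
    y = np.array([xb.get(k, 0) for k in keys], dtype=float)
    bigx, bigy = x.sum(), y.sum()
    cross = float((x * y).sum())
    if variant == "horn":
        dx = float((x**2).sum()) / bigx**2
        dy = float((y**2).sum()) / bigy**2
        return 2.0 * cross / ((dx + dy) * bigx * bigy)
    if variant == "classical":
        lx = float((x * (x - 1)).sum()) / (bigx * (bigx - 1))
        ly = float((y * (y - 1)).sum()) / (bigy * (bigy - 1))
        return 2.0 * cross / ((lx + ly) * bigx * bigy)
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class OverlapMatrix:
    scope: str
    key_mode: str
    values: pd.DataFrame  # symmetric, unit diagonal


def overlap_matrix(
    samples: list[RepertoireSample], scope: str = IN_FRAME
) -> OverlapMatrix:
    """All pairwise Morisita–Horn overlaps (symmetric, unit diagonal)."""
    if len(samples) < 2:
        raise TcrepError("overlap_matrix needs >= 2 samples")
    ids = [s.sample_id for s in samples]
    n = len(samples)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = morisita(samples[i], samples[j], scope=scope)
            except EmptyRepertoireError as exc:
                raise EmptyRepertoireError(
                    f"pair ({ids[i]}, {ids[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = v
    return OverlapMatrix(
        scope=scope,
        key_mode="cdr3_nt",
        values=pd.DataFrame(mat, index=ids, columns=ids),
    )


def dominant_clone(sample: RepertoireSample) -> tuple[Rearrangement, float]:
    """The most abundant productive clone and its frequency.

    Ties are broken lexicographically by (cdr3_nt, v_gene, j_gene).
    """
    ranked = clone_frequencies(sample)
    key, freq = ranked[0]
    by_key = {r.key: r for r in sample.rearrangements}
    return by_key[key], freq


def percent_identity(aa1: str, aa2: str) -> float:
    """Percent identity of two amino-acid strings.

    Equal lengths: position-wise matches / length × 100.  Unequal lengths:
    a global alignment scored match = 1, mismatch = 0, gap = −1 (maximising
    matches; among optimal-score alignments the one with the most matches),
    identity = matches / alignment length × 100.
    """
    if not aa1 or not aa2:
        raise TcrepError("percent_identity requires non-empty strings")
    la, lb = len(aa1), len(aa2)
    if la == lb:
        matches = sum(c1 == c2 for c1, c2 in zip(aa1, aa2))
        return 100.0 * matches / la
    neg = (-(10**9), -(10**9))
    prev = [(-j, 0) for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [neg] * (lb + 1)
        cur[0] = (-i, 0)
        ci = aa1[i - 1]
        for j in range(1, lb + 1):
            m = 1 if ci == aa2[j - 1] else 0
            sd, md = prev[j - 1]
            su, mu = prev[j]
            sl, ml = cur[j - 1]
            cur[j] = max((sd + m, md + m), (su - 1, mu), (sl - 1, ml))
        prev = cur
    score, matches = prev[lb]
    # alignment length = diagonal steps + gaps = (la + lb + matches - score)/2
    alen = (la + lb + matches - score) / 2.0
    return 100.0 * matches / alen


def identity_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """Pairwise percent-identity matrix over labelled aa sequences."""
    ids = list(sequences)
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = percent_identity(
                sequences[ids[i]], sequences[ids[j]]
            )
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class ConvergenceGroup:
    cdr3_aa: str
    members: list[Rearrangement]
    convergent: bool  # >= 2 members differing in cdr3_nt or v_gene


def convergence_groups(clones: list[Rearrangement]) -> list[ConvergenceGroup]:
    """Partition clones by CDR3 amino-acid sequence and flag convergent
    recombination: identical aa CDR3 from distinct nucleotide sequences or
    distinct V genes."""
    by_aa: dict[str, list[Rearrangement]] = {}
    for r in clones:
        if r.cdr3_aa:
            by_aa.setdefault(r.cdr3_aa, []).append(r)
    groups = []
    for aa in sorted(by_aa):
        members = by_aa[aa]
        nts = {m.cdr3_nt for m in members}
        vs = {m.v_gene for m in members}
        groups.append(
            ConvergenceGroup(
                cdr3_aa=aa,
                members=members,
                convergent=len(members) >= 2 and (len(nts) > 1 or len(vs) > 1),
            )
        )
    return groups
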