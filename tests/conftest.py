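"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

from tcrep.io import Rearrangement, RepertoireSample
from tcrep.simulate import NONSTOP_CODONS

# deterministic supply of distinct productive CDR3 nucleotide sequences:
# TGT + two non-stop codons -> 3721 distinct 9-nt productive junctions
_DISTINCT_NT = [
    "TGT" + a + b for a, b in itertools.product(NONSTOP_CODONS, repeat=2)
]


def sample_from_counts(
    counts, sample_id="s", v_gene="TRBV1", j_gene="TRBJ1-1", **meta
) -> RepertoireSample:
    """A sample of distinct productive clones with the given template counts."""
    recs = [
        Rearrangement.from_nt(
            _DISTINCT_NT[i], v_gene=v_gene, j_gene=j_gene, template_count=int(c)
        )
        for i, c in enumerate(counts)
    ]
    return RepertoireSample.from_records(recs, sample_id=sample_id, **meta)


def sample_from_keyed_counts(keyed_counts, sample_id="s", **meta):
    """A sample from {cdr3_nt: count} (or {(nt, v, j): count}) mappings."""
    recs = []
    for key, c in keyed_counts.items():
        if isinstance(key, tuple):
            nt, v, j = key
        else:
            nt, v, j = key, "TRBV1", "TRBJ1-1"
        recs.append(
            Rearrangement.from_nt(nt, v_gene=v, j_gene=j, template_count=int(c))
        )
    return RepertoireSample.from_records(recs, sample_id=sample_id, **meta)


@pytest.fixture
def nt_pool():
    return list(_DISTINCT_NT)


# ---------------------------------------------------------------------------
# independent alignment-enumeration oracle (used by overlap and acceptance
# tests): walks every global alignment of two short strings and returns the
# identity implied by the best (score, matches) pair under the scoring
# match = 1, mismatch = 0, gap = -1.


def enumerate_alignments(a: str, b: str):
    """Yield (score, matches) for every global alignment of a and b."""
    if not a and not b:
        yield (0, 0)
        return
    if a:
        for s, m in enumerate_alignments(a[1:], b):
            yield (s - 1, m)
    if b:
        for s, m in enumerate_alignments(a, b[1:]):
            yield (s - 1, m)
    if a and b:
        hit = 1 if a[0] == b[0] else 0
        for s, m in enumerate_alignments(a[1:], b[1:]):
            yield (s + hit, m + hit)


def oracle_percent_identity(a: str, b: str) -> float:
    if len(a) == len(b):  # equal lengths: position-wise by definition
        return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
    score, matches = max(enumerate_alignments(a, b))
    alen = (len(a) + len(b) + matches - score) / 2.0
    return 100.0 * matches / alen
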