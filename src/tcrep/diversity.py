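"""Clonality and dominance statistics for a repertoire sample.

The clonality index is the normalised-entropy complement

    clonality = 1 − H / ln(R)

where H is the Shannon entropy (natural log) of the clone frequency
distribution over productive templates and R is the number of unique
productive rearrangements.  Because H/ln(R) is a ratio of logarithms, the
value is identical for any log base.  clonality is 0 for a perfectly even
(polyclonal) repertoire, 1 for a single clone (by convention when R = 1),
and invariant to rescaling all template counts.

"Top clone" frequencies are template-weighted fractions of productive
templates, matching the convention of repertoire-assay summary panels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptyRepertoireError
from .io import PRODUCTIVE, RepertoireSample

CloneKey = tuple[str, str, str]


@dataclass
class ClonalSummary:
    sample_id: str
    unique_productive: int
    productive_templates: int
    total_templates: int
    productive_fraction: float
    clonality: float
    top_clone_frequency: float
    top10_frequency_sum: float
    ranked_frequencies: list[tuple[CloneKey, float]]


def productive_subset(sample: RepertoireSample) -> RepertoireSample:
    """Restrict a sample to productive rearrangements; metadata preserved."""
    return replace(
        sample,
        rearrangements=[
            r for r in sample.rearrangements if r.frame_status == PRODUCTIVE
        ],
    )


def clone_frequencies(sample: RepertoireSample) -> list[tuple[CloneKey, float]]:
    """Descending clone frequencies over productive templates.

    Ties are broken lexicographically by (cdr3_nt, v_gene, j_gene) for
    determinism.
    """
    prod = [r for r in sample.rearrangements if r.frame_status == PRODUCTIVE]
    if not prod:
        raise EmptyRepertoireError(
            f"sample {sample.sample_id!r} has no productive rearrangements"
        )
    total = sum(r.template_count for r in prod)
    return sorted(
        ((r.key, r.template_count / total) for r in prod),
        key=lambda kv: (-kv[1], kv[0]),
    )


def clonality(sample: RepertoireSample) -> float:
    """Normalised-entropy clonality in [0, 1]; 1 when a single clone."""
    freqs = np.array([f for _, f in clone_frequencies(sample)])
    r = len(freqs)
    if r == 1:
        return 1.0
    h = float(-(freqs * np.log(freqs)).sum())
    return 1.0 - h / np.log(r)


def summarize(sample: RepertoireSample) -> ClonalSummary:
    """All per-sample clonal statistics (diversity panel)."""
    ranked = clone_frequencies(sample)
    prod_templates = sum(
        r.template_count
        for r in sample.rearrangements
        if r.frame_status == PRODUCTIVE
    )
    total = sample.total_templates
    freqs = [f for _, f in ranked]
    return ClonalSummary(
        sample_id=sample.sample_id,
        unique_productive=len(ranked),
        productive_templates=prod_templates,
        total_templates=total,
        productive_fraction=prod_templates / total,
        clonality=clonality(sample),
        top_clone_frequency=freqs[0],
        top10_frequency_sum=float(sum(freqs[: min(10, len(freqs))])),
        ranked_frequencies=ranked,
    )


def summary_table(samples: list[RepertoireSample]) -> pd.DataFrame:
    """One row of scalar clonal statistics per sample."""
    rows = []
    for s in samples:
        cs = summarize(s)
        rows.append(
            {
                "sample_id": cs.sample_id,
                "subject_id": s.subject_id,
                "tissue": s.tissue,
                "group": s.group,
                "unique_productive": cs.unique_productive,
                "productive_templates": cs.productive_templates,
                "total_templates": cs.total_templates,
                "productive_fraction": cs.productive_fraction,
                "clonality": cs.clonality,
                "top_clone_frequency": cs.top_clone_frequency,
                "top10_frequency_sum": cs.top10_frequency_sum,
            }
        )
    return pd.DataFrame(rows)
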