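"""V/D/J gene-segment usage tables and group comparison.

Usage is the fraction of a sample's productive templates (or unique clones)
carrying each segment; unresolved calls are pooled into an explicit
``unresolved`` column so every row remains a probability vector.  Two-group
comparison is a per-gene two-tailed Welch (unequal-variance) t test with
Benjamini–Hochberg FDR-adjusted q values across the genes of one segment
class; three or more groups go through one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyRepertoireError, TcrepError
from .io import (
    IMGT_TO_ORIGINAL,
    PRODUCTIVE,
    UNRESOLVED,
    GeneNameMap,
    RepertoireSample,
)

SEGMENT_ATTR = {"V": "v_gene", "D": "d_gene", "J": "j_gene"}


@dataclass
class UsageTable:
    segment_class: str  # "V" | "D" | "J"
    weighting: str  # "templates" | "unique"
    frequencies: pd.DataFrame  # rows = sample_id, columns = genes


def usage_table(
    samples: Sequence[RepertoireSample],
    segment_class: str,
    weighting: str = "templates",
) -> UsageTable:
    """Per-sample segment usage frequencies over the productive subset.

    Columns are the union of genes seen in any sample; genes absent from a
    sample get an explicit 0.
    """
    if segment_class not in SEGMENT_ATTR:
        raise ValueError(f"segment_class must be one of {list(SEGMENT_ATTR)}")
    if weighting not in ("templates", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    attr = SEGMENT_ATTR[segment_class]
    rows: dict[str, dict[str, float]] = {}
    for s in samples:
        prod = [r for r in s.rearrangements if r.frame_status == PRODUCTIVE]
        if not prod:
            raise EmptyRepertoireError(
                f"sample {s.sample_id!r} has no productive rearrangements"
            )
        acc: dict[str, float] = {}
        for r in prod:
            gene = getattr(r, attr) or UNRESOLVED
            w = r.template_count if weighting == "templates" else 1
            acc[gene] = acc.get(gene, 0.0) + w
        total = sum(acc.values())
        rows[s.sample_id] = {g: v / total for g, v in acc.items()}
    genes = sorted({g for row in rows.values() for g in row})
    mat = pd.DataFrame(
        [[rows[sid].get(g, 0.0) for g in genes] for sid in rows],
        index=list(rows),
        columns=genes,
    )
    mat.index.name = "sample_id"
    return UsageTable(segment_class=segment_class, weighting=weighting,
                      frequencies=mat)


def usage_long_table(
    table: UsageTable, gene_map: GeneNameMap | None = None
) -> pd.DataFrame:
    """Long-format usage with dual gene nomenclature (presentation only)."""
    if gene_map is None:
        gene_map = GeneNameMap.default()
    records = []
    for sid, row in table.frequencies.iterrows():
        for gene, freq in row.items():
            orig, _ = gene_map.map(gene, IMGT_TO_ORIGINAL)
            records.append(
                {
                    "sample_id": sid,
                    "segment_class": table.segment_class,
                    "gene_imgt": gene,
                    "gene_original": orig,
                    "frequency": freq,
                }
            )
    return pd.DataFrame(records)


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-tailed p, with the degenerate zero-variance
    cases resolved deterministically."""
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_usage(
    table: UsageTable,
    group_labels: Mapping[str, str],
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Gene-by-gene Welch t test between exactly two groups, with BH FDR.

    Returns one row per gene: group means, t, p, q and a significance flag
    at ``q_cutoff``.  Genes with zero usage in every sample are dropped
    before testing.
    """
    freq = table.frequencies
    labels = pd.Series({sid: group_labels[sid] for sid in freq.index})
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise TcrepError(
            f"compare_usage needs exactly 2 groups, got {groups}; "
            "use anova_tukey for 3+"
        )
    idx_a = labels[labels == groups[0]].index
    idx_b = labels[labels == groups[1]].index
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise TcrepError("each group needs >= 2 samples for a t test")
    rows = []
    for gene in freq.columns:
        a = freq.loc[idx_a, gene].to_numpy(float)
        b = freq.loc[idx_b, gene].to_numpy(float)
        if (a == 0).all() and (b == 0).all():
            continue
        t, p = _welch(a, b)
        rows.append(
            {
                "gene": gene,
                f"mean_{groups[0]}": a.mean(),
                f"mean_{groups[1]}": b.mean(),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_qvalues(out["p"])
    out["significant"] = out["q"] <= q_cutoff
    return out


def anova_tukey(
    values: Sequence[float], group_labels: Sequence[str]
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F test plus Tukey HSD pairwise adjusted p values.

    Returns ``(F, p_anova, pairwise)`` where ``pairwise`` has columns
    group_a, group_b, p_adj.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    names = sorted(set(labels.tolist()))
    if len(names) < 3:
        raise TcrepError("anova_tukey needs >= 3 groups; use compare_usage for 2")
    arrays = [values[labels == g] for g in names]
    if any(len(a) < 2 for a in arrays):
        raise TcrepError("each group needs >= 2 samples")
    f_stat, p_anova = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return float(f_stat), float(p_anova), pd.DataFrame(rows)
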