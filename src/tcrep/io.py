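"""Reading, writing and normalising TCRβ rearrangement tables.

Two tab-separated dialects are supported:

* **airr** — AIRR Rearrangement-schema columns
  (``junction``, ``junction_aa``, ``v_call``, ``d_call``, ``j_call``,
  ``productive``, ``duplicate_count``).
* **immunoseq** — ImmunoSEQ-export-style columns
  (``rearrangement``, ``amino_acid``, ``v_gene``, ``d_gene``, ``j_gene``,
  ``frame_type``, ``templates``).

Frame status is always *recomputed* from the junction nucleotide sequence;
a ``productive``/``frame_type`` column in the file is only used to warn on
disagreement.  A rearrangement is *productive* when its CDR3 nucleotide
length is divisible by 3 and the translation contains no stop codon;
*out_of_frame* when the length is not divisible by 3; *has_stop* otherwise.

Clonotypes are keyed on ``(cdr3_nt, v_gene, j_gene)``: identical amino-acid
CDR3s produced from different nucleotide rearrangements or different V genes
are distinct clones (convergent recombination), while duplicate keys within
a file are merged by summing template counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import (
    EmptySampleError,
    FormatError,
    FrameError,
    RecordError,
)

logger = logging.getLogger(__name__)

STOP_SYMBOL = "*"
UNRESOLVED = "unresolved"

PRODUCTIVE = "productive"
OUT_OF_FRAME = "out_of_frame"
HAS_STOP = "has_stop"
FRAME_STATUSES = (PRODUCTIVE, OUT_OF_FRAME, HAS_STOP)

_STANDARD_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({codon: STOP_SYMBOL for codon in _STANDARD_TABLE.stop_codons})

_VALID_NT = frozenset("ACGT")


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate an in-frame CDR3 nucleotide sequence.

    Uses the standard codon table; stop codons are rendered as ``*``.
    Raises :class:`FrameError` when the length is not divisible by 3.
    """
    if len(cdr3_nt) % 3 != 0:
        raise FrameError(
            f"CDR3 length {len(cdr3_nt)} is not divisible by 3; cannot translate"
        )
    try:
        return "".join(
            CODON_TO_AA[cdr3_nt[i : i + 3]] for i in range(0, len(cdr3_nt), 3)
        )
    except KeyError as exc:
        raise RecordError(f"non-ACGT codon {exc.args[0]!r} in {cdr3_nt!r}") from exc


def classify_frame(cdr3_nt: str) -> tuple[str, str]:
    """Return ``(cdr3_aa, frame_status)`` for a junction sequence.

    ``cdr3_aa`` is empty for out-of-frame sequences.
    """
    if len(cdr3_nt) % 3 != 0:
        return "", OUT_OF_FRAME
    aa = translate_cdr3(cdr3_nt)
    return aa, (HAS_STOP if STOP_SYMBOL in aa else PRODUCTIVE)


@dataclass(frozen=True)
class Rearrangement:
    """One sequenced TCRβ clonotype record."""

    cdr3_nt: str
    v_gene: str
    d_gene: str
    j_gene: str
    template_count: int
    cdr3_aa: str
    frame_status: str

    @classmethod
    def from_nt(
        cls,
        cdr3_nt: str,
        v_gene: str,
        j_gene: str,
        d_gene: str = UNRESOLVED,
        template_count: int = 1,
    ) -> "Rearrangement":
        """Build a record, computing translation and frame status."""
        if len(cdr3_nt) < 3:
            raise RecordError(f"CDR3 nucleotide sequence too short: {cdr3_nt!r}")
        if not _VALID_NT.issuperset(cdr3_nt):
            bad = sorted(set(cdr3_nt) - _VALID_NT)
            raise RecordError(f"non-ACGT characters {bad} in junction {cdr3_nt!r}")
        if template_count < 1:
            raise RecordError(f"template_count must be >= 1, got {template_count}")
        aa, status = classify_frame(cdr3_nt)
        return cls(
            cdr3_nt=cdr3_nt,
            v_gene=v_gene,
            d_gene=d_gene or UNRESOLVED,
            j_gene=j_gene,
            template_count=int(template_count),
            cdr3_aa=aa,
            frame_status=status,
        )

    @property
    def key(self) -> tuple[str, str, str]:
        """Clone identity: (cdr3_nt, v_gene, j_gene)."""
        return (self.cdr3_nt, self.v_gene, self.j_gene)

    @property
    def in_frame(self) -> bool:
        return self.frame_status != OUT_OF_FRAME


@dataclass
class RepertoireSample:
    """A sample's full set of rearrangements plus metadata.

    Rearrangements are unique on ``(cdr3_nt, v_gene, j_gene)``; use
    :meth:`from_records` to merge duplicates by summing template counts.
    """

    sample_id: str
    rearrangements: list[Rearrangement] = field(default_factory=list)
    subject_id: str = ""
    tissue: str = "other"
    group: str = ""

    @classmethod
    def from_records(
        cls,
        records: Iterable[Rearrangement],
        sample_id: str,
        subject_id: str = "",
        tissue: str = "other",
        group: str = "",
    ) -> "RepertoireSample":
        merged: dict[tuple[str, str, str], Rearrangement] = {}
        for rec in records:
            prev = merged.get(rec.key)
            if prev is None:
                merged[rec.key] = rec
            else:
                merged[rec.key] = replace(
                    prev, template_count=prev.template_count + rec.template_count
                )
        # sorted for permutation invariance of the stored order
        recs = sorted(merged.values(), key=lambda r: r.key)
        return cls(
            sample_id=sample_id,
            rearrangements=recs,
            subject_id=subject_id,
            tissue=tissue,
            group=group,
        )

    @property
    def total_templates(self) -> int:
        return sum(r.template_count for r in self.rearrangements)

    def __len__(self) -> int:
        return len(self.rearrangements)


# ---------------------------------------------------------------------------
# dialects

AIRR = "airr"
IMMUNOSEQ = "immunoseq"

_AIRR_REQUIRED = ("junction", "v_call", "j_call", "duplicate_count")
_IMMUNOSEQ_REQUIRED = ("rearrangement", "v_gene", "j_gene", "templates")

_FILE_FRAME_COLUMN = {AIRR: "productive", IMMUNOSEQ: "frame_type"}


def detect_dialect(columns: Iterable[str]) -> str:
    cols = set(columns)
    if set(_AIRR_REQUIRED) <= cols:
        return AIRR
    if set(_IMMUNOSEQ_REQUIRED) <= cols:
        return IMMUNOSEQ
    raise FormatError(
        "could not detect dialect: need columns "
        f"{_AIRR_REQUIRED} (airr) or {_IMMUNOSEQ_REQUIRED} (immunoseq); "
        f"got {sorted(cols)}"
    )


def _require_columns(df: pd.DataFrame, required: Iterable[str], dialect: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing required column(s) {missing} for dialect {dialect!r}"
        )


def _file_says_productive(value: str, dialect: str) -> bool | None:
    """Interpret the file's own frame annotation, if any."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().lower()
    if dialect == AIRR:
        if text in ("t", "true", "1", "yes"):
            return True
        if text in ("f", "false", "0", "no"):
            return False
    else:  # immunoseq frame_type: In / Out / Stop
        if text == "in":
            return True
        if text in ("out", "stop"):
            return False
    return None


def read_rearrangements(
    path: str | Path,
    dialect: str = "auto",
    sample_id: str | None = None,
    subject_id: str = "",
    tissue: str = "other",
    group: str = "",
) -> RepertoireSample:
    """Read a rearrangement TSV into a :class:`RepertoireSample`.

    Frame status is recomputed from the junction sequence; rows whose file
    annotation disagrees are kept with the recomputed status and a warning
    is logged.  Duplicate clone keys are merged by summing template counts,
    so row order never affects the resulting sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptySampleError(f"{path}: file is empty") from None
    if df.empty:
        raise EmptySampleError(f"{path}: no data rows")

    if dialect == "auto":
        dialect = detect_dialect(df.columns)
    elif dialect == AIRR:
        _require_columns(df, _AIRR_REQUIRED, AIRR)
    elif dialect == IMMUNOSEQ:
        _require_columns(df, _IMMUNOSEQ_REQUIRED, IMMUNOSEQ)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if dialect == AIRR:
        nt_col, v_col, d_col, j_col, count_col = (
            "junction", "v_call", "d_call", "j_call", "duplicate_count",
        )
    else:
        nt_col, v_col, d_col, j_col, count_col = (
            "rearrangement", "v_gene", "d_gene", "j_gene", "templates",
        )
    frame_col = _FILE_FRAME_COLUMN[dialect]

    records: list[Rearrangement] = []
    bad_rows: list[str] = []
    n_disagree = 0
    for idx, row in enumerate(df.to_dict("records"), start=2):  # line 1 = header
        nt = row.get(nt_col)
        try:
            if nt is None or pd.isna(nt):
                raise RecordError("missing junction sequence")
            count_raw = row.get(count_col)
            count = 1 if count_raw is None or pd.isna(count_raw) else int(count_raw)
            d_raw = row.get(d_col)
            d_gene = UNRESOLVED if d_raw is None or pd.isna(d_raw) or not str(d_raw) else str(d_raw)
            rec = Rearrangement.from_nt(
                cdr3_nt=str(nt).upper(),
                v_gene=str(row[v_col]),
                j_gene=str(row[j_col]),
                d_gene=d_gene,
                template_count=count,
            )
        except (RecordError, ValueError) as exc:
            bad_rows.append(f"line {idx}: {exc}")
            continue
        claimed = _file_says_productive(row.get(frame_col), dialect)
        if claimed is not None and claimed != (rec.frame_status == PRODUCTIVE):
            n_disagree += 1
        records.append(rec)

    if bad_rows:
        raise RecordError(
            f"{path}: {len(bad_rows)} malformed row(s): " + "; ".join(bad_rows[:10])
        )
    if n_disagree:
        logger.warning(
            "%s: frame annotation disagreed with recomputed status on %d row(s); "
            "recomputed status used",
            path,
            n_disagree,
        )
    if not records:
        raise EmptySampleError(f"{path}: no usable rearrangement rows")

    return RepertoireSample.from_records(
        records,
        sample_id=sample_id if sample_id is not None else path.stem,
        subject_id=subject_id,
        tissue=tissue,
        group=group,
    )


def write_rearrangements(
    sample: RepertoireSample, path: str | Path, dialect: str = AIRR
) -> None:
    """Write a sample as a rearrangement TSV in the requested dialect.

    ``read_rearrangements(write_rearrangements(s))`` reproduces the sample's
    rearrangements field-by-field.
    """
    if not sample.rearrangements:
        raise EmptySampleError(f"sample {sample.sample_id!r} has no rearrangements")
    path = Path(path)
    rows = []
    for r in sample.rearrangements:
        if dialect == AIRR:
            rows.append(
                {
                    "junction": r.cdr3_nt,
                    "junction_aa": r.cdr3_aa,
                    "v_call": r.v_gene,
                    "d_call": r.d_gene,
                    "j_call": r.j_gene,
                    "productive": "T" if r.frame_status == PRODUCTIVE else "F",
                    "duplicate_count": r.template_count,
                }
            )
        elif dialect == IMMUNOSEQ:
            frame_type = {
                PRODUCTIVE: "In",
                OUT_OF_FRAME: "Out",
                HAS_STOP: "Stop",
            }[r.frame_status]
            rows.append(
                {
                    "rearrangement": r.cdr3_nt,
                    "amino_acid": r.cdr3_aa,
                    "v_gene": r.v_gene,
                    "d_gene": r.d_gene,
                    "j_gene": r.j_gene,
                    "frame_type": frame_type,
                    "templates": r.template_count,
                }
            )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Vβ nomenclature

IMGT_TO_ORIGINAL = "imgt_to_original"
ORIGINAL_TO_IMGT = "original_to_imgt"


class GeneNameMap:
    """Bidirectional map between IMGT TRBV names and original Vβ names.

    The mapping is a partial bijection: names absent from the table pass
    through unchanged (with a ``mapped`` flag of ``False``), and the
    round-trip IMGT → original → IMGT is the identity on mapped names.
    The bundled murine table is an editable resource, not a constant.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._imgt_to_orig: dict[str, str] = {}
        self._orig_to_imgt: dict[str, str] = {}
        for imgt, orig in pairs:
            if imgt in self._imgt_to_orig or orig in self._orig_to_imgt:
                raise ValueError(
                    f"duplicate entry ({imgt!r}, {orig!r}): map must be a bijection"
                )
            self._imgt_to_orig[imgt] = orig
            self._orig_to_imgt[orig] = imgt

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneNameMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"imgt", "original"} <= set(df.columns):
            raise FormatError("gene-name map needs columns 'imgt' and 'original'")
        return cls(zip(df["imgt"], df["original"]))

    @classmethod
    def default(cls) -> "GeneNameMap":
        """The bundled murine TRBV ↔ Vβ table."""
        with _ilres.as_file(
            _ilres.files("tcrep.resources") / "trbv_nomenclature.tsv"
        ) as p:
            return cls.from_tsv(p)

    def map(self, name: str, direction: str) -> tuple[str, bool]:
        if direction == IMGT_TO_ORIGINAL:
            table = self._imgt_to_orig
        elif direction == ORIGINAL_TO_IMGT:
            table = self._orig_to_imgt
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if name in table:
            return table[name], True
        return name, False

    def __len__(self) -> int:
        return len(self._imgt_to_orig)


def map_gene_name(
    name: str, direction: str, gene_map: GeneNameMap | None = None
) -> tuple[str, bool]:
    """Map a gene name between nomenclatures; unmapped names pass through."""
    if gene_map is None:
        gene_map = GeneNameMap.default()
    return gene_map.map(name, direction)
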