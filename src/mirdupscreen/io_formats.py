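"""Readers and writers for every external representation the pipeline touches.

All sequence data is normalized to the uppercase DNA alphabet on ingest
(``U`` -> ``T``) so that downstream pattern matching runs in a single
alphabet. Tables are plain TSV/CSV: tab- or comma-separated, UTF-8, header
row mandatory, no quoting, decimal points only. Writers emit a leading
``# mirdupscreen vX.Y`` comment line which every reader skips, and order
rows deterministically so repeated runs are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__

HEADER_COMMENT = f"# mirdupscreen v{__version__}"

#: the printed candidate table shipped with the package
TABLE1_PATH = Path(__file__).parent / "data" / "table1_candidates.tsv"

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line/row."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record, sequence uppercased and RNA->DNA normalized."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")


@dataclass
class CountMatrix:
    """Features x samples non-negative counts with tumor/normal labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_features, n_samples)
    group_of: dict[str, str]  # sample id -> "tumor" | "normal"

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples missing group annotation: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in ("tumor", "normal")}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class CandidateGene:
    """One candidate-table row: a down-regulated predicted target."""

    entrez_id: int | None
    symbol: str
    name: str
    log2fc: float
    total_sites: int
    arm: str  # "5p" | "3p"

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if not np.isfinite(self.log2fc):
            raise ValueError(f"{self.symbol}: non-finite log2FC")
        if self.total_sites < 1:
            raise ValueError(f"{self.symbol}: total_sites must be >= 1")


@dataclass
class CandidateTable:
    """Candidate genes partitioned by the targeting miRNA arm.

    A gene targeted by both arms appears once in each partition, as in the
    printed table (e.g. PRKAA2, FGF7, PRELP, SAMD12, HHIP).
    """

    rows: list[CandidateGene]

    def __post_init__(self) -> None:
        for arm in ("5p", "3p"):
            syms = [r.symbol for r in self.rows if r.arm == arm]
            if len(set(syms)) != len(syms):
                raise ValueError(f"duplicate gene symbols within arm {arm}")

    def partition(self, arm: str) -> list[CandidateGene]:
        return [r for r in self.rows if r.arm == arm]

    def symbols(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.symbol, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ClinicalTable:
    """Per-patient survival data plus expression columns.

    ``data`` holds one row per patient with columns ``patient_id``, ``time``
    (months, > 0), ``event`` (0 censored / 1 event), ``stage`` (ordinal 1-4),
    ``grade`` (ordinal 1-3), ``age`` (years) and one numeric column per gene
    listed in ``expression_columns``.
    """

    data: pd.DataFrame
    expression_columns: list[str] = field(default_factory=list)

    REQUIRED = ("patient_id", "time", "event", "stage", "grade", "age")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be > 0")
        ev = set(self.data["event"].unique())
        if not ev <= {0, 1}:
            raise ValueError(f"event column must be 0/1, found {sorted(ev)}")
        for col in self.expression_columns:
            if col not in self.data.columns:
                raise ValueError(f"expression column {col!r} absent")
            if not np.issubdtype(self.data[col].dtype, np.number):
                raise ValueError(f"expression column {col!r} is not numeric")

    def expression(self, gene: str) -> np.ndarray:
        if gene not in self.expression_columns:
            raise KeyError(f"no expression column for gene {gene!r}")
        return self.data[gene].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA to DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and U-normalized; record order is preserved;
    duplicate ids, headerless sequence and empty records are rejected with
    the offending line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header_line = 0
    rid = desc = None
    chunks: list[str] = []

    def flush() -> None:
        if rid is None:
            return
        seq = normalize_sequence("".join(chunks))
        if not seq:
            raise ParseError(f"line {header_line}: record {rid!r} has empty sequence")
        records.append(SequenceRecord(rid, desc or "", seq))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if not head:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                parts = head.split(None, 1)
                rid, desc = parts[0], parts[1] if len(parts) > 1 else ""
                if rid in seen:
                    raise ParseError(f"line {lineno}: duplicate record id {rid!r}")
                seen.add(rid)
                header_line = lineno
                chunks = []
            else:
                if rid is None:
                    raise ParseError(f"line {lineno}: sequence before any header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


def _read_table(path: str | os.PathLike, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str)


def read_count_matrix(path: str | os.PathLike, annotation: str | os.PathLike) -> CountMatrix:
    """Read a feature x sample count TSV plus a sample->group annotation TSV.

    The annotation file has columns ``sample`` and ``group``; every sample in
    the matrix must be annotated as ``tumor`` or ``normal``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    ann = _read_table(annotation, "\t")
    if not {"sample", "group"} <= set(ann.columns):
        raise ParseError("annotation needs 'sample' and 'group' columns")
    group_of = dict(zip(ann["sample"], ann["group"]))
    missing = [s for s in df.columns if s not in group_of]
    if missing:
        raise ParseError(f"samples missing from annotation: {missing}")
    counts = df.to_numpy(dtype=float)
    if (counts < 0).any():
        bad = df.index[(counts < 0).any(axis=1)].tolist()
        raise ParseError(f"negative counts for features: {bad}")
    return CountMatrix(
        feature_ids=df.index.astype(str).tolist(),
        sample_ids=df.columns.astype(str).tolist(),
        counts=counts,
        group_of={s: group_of[s] for s in df.columns},
    )


def write_count_matrix(m: CountMatrix, path: str | os.PathLike, annotation: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER_COMMENT + "\n")
        fh.write("feature\t" + "\t".join(m.sample_ids) + "\n")
        for i, fid in enumerate(m.feature_ids):
            vals = "\t".join(_fmt_number(v) for v in m.counts[i])
            fh.write(f"{fid}\t{vals}\n")
    with open(annotation, "w", encoding="utf-8") as fh:
        fh.write(HEADER_COMMENT + "\n")
        fh.write("sample\tgroup\n")
        for s in m.sample_ids:
            fh.write(f"{s}\t{m.group_of[s]}\n")


def _fmt_number(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# candidate table
# ---------------------------------------------------------------------------

_CAND_COLUMNS = ["EntrezID", "Symbol", "Name", "log2FC", "TotalSites", "Arm"]


def read_candidate_table(path: str | os.PathLike = TABLE1_PATH) -> CandidateTable:
    """Read a candidate-gene TSV (default: the packaged printed table).

    Numeric fields accept both ASCII ``-`` and the typographic minus U+2212
    that PDF extraction produces.
    """
    rows: list[CandidateGene] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return CandidateTable([])
    header = lines[0].split("\t")
    if header != _CAND_COLUMNS:
        raise ParseError(f"expected columns {_CAND_COLUMNS}, got {header}")
    for rowno, ln in enumerate(lines[1:], 2):
        f = ln.split("\t")
        if len(f) != 6:
            raise ParseError(f"row {rowno}: expected 6 fields, got {len(f)}")
        eid_s, symbol, name, fc_s, sites_s, arm = f
        fc_s = fc_s.replace("−", "-")
        try:
            log2fc = float(fc_s)
            total_sites = int(sites_s)
        except ValueError as exc:
            raise ParseError(f"row {rowno}: non-numeric value ({exc})") from None
        entrez = int(eid_s) if eid_s not in ("", "NA") else None
        rows.append(CandidateGene(entrez, symbol, name, log2fc, total_sites, arm))
    return CandidateTable(rows)


def write_candidate_table(table: CandidateTable, path: str | os.PathLike) -> int:
    """Write a candidate table sorted by (arm, symbol); returns row count."""
    rows = sorted(table.rows, key=lambda r: (r.arm, r.symbol))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER_COMMENT + "\n")
        fh.write("\t".join(_CAND_COLUMNS) + "\n")
        for r in rows:
            eid = "" if r.entrez_id is None else str(r.entrez_id)
            fh.write(f"{eid}\t{r.symbol}\t{r.name}\t{r.log2fc:.2f}\t{r.total_sites}\t{r.arm}\n")
    return len(rows)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------


def read_clinical_table(path: str | os.PathLike) -> ClinicalTable:
    df = pd.read_csv(path, comment="#")
    expr_cols = [c for c in df.columns if c not in ClinicalTable.REQUIRED]
    df = df.astype({c: float for c in expr_cols} | {"time": float, "event": int})
    return ClinicalTable(df, expression_columns=expr_cols)


def write_clinical_table(table: ClinicalTable, path: str | os.PathLike) -> None:
    cols = list(ClinicalTable.REQUIRED) + sorted(table.expression_columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER_COMMENT + "\n")
        table.data[cols].to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict[str, int]:
    """Write named result tables as TSVs with deterministic order.

    Rows are sorted by all columns left to right (arm then symbol where those
    exist, because writers place them first). Returns a manifest mapping file
    name to row count; the manifest itself is also written as
    ``manifest.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    for name in sorted(tables):
        df = tables[name].copy()
        sort_cols = [c for c in ("arm", "symbol", "gene") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort")
        fname = f"{name}.tsv"
        with open(out / fname, "w", encoding="utf-8") as fh:
            fh.write(HEADER_COMMENT + "\n")
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
        manifest[fname] = len(df)
    with open(out / "manifest.tsv", "w", encoding="utf-8") as fh:
        fh.write(HEADER_COMMENT + "\nfile\trows\n")
        for fname in sorted(manifest):
            fh.write(f"{fname}\t{manifest[fname]}\n")
    return manifest


def read_result_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
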