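"""Reading and writing the tabular and sequence formats of the pipeline.

Site tables are MaxQuant "Phospho (STY)Sites"-style TSV: one row per
phosphosite (per multiplicity), with identity columns, a localization
probability, a 13-residue sequence window, per-replicate inhibitor-screen
ratio columns (``ins_rep1`` ...), and per-replicate time-course columns
(``tc0.25_rep1`` ...).  All ratios are stored internally as log2; a
dialect flag declares whether input columns are linear ("Ratio H/L
normalized"-style) or already log2.  Missing quantification is encoded as
an empty cell, never 0 (0 is a meaningful log2 ratio).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from phosphodyn.temporal import TIMEPOINTS_MIN, TimeCourseProfile

WINDOW_PAD = "_"
RESIDUES = ("S", "T", "Y")


def _fmt_minutes(t: float) -> str:
    s = f"{t:g}"
    return s


TIME_LABELS = [_fmt_minutes(t) for t in TIMEPOINTS_MIN]

BASE_COLUMNS = [
    "site_id",
    "protein_id",
    "gene_name",
    "position",
    "residue",
    "localization_prob",
    "multiplicity",
    "sequence_window",
]


@dataclass
class TableDialect:
    """How to interpret a site table's ratio columns.

    ratio_scale "log2" stores values as-is; "linear" log2-transforms
    them on read.  ``flag_value`` marks reverse-database / contaminant
    rows (MaxQuant uses "+").
    """

    ratio_scale: str = "log2"
    reverse_col: str = "reverse"
    contaminant_col: str = "contaminant"
    flag_value: str = "+"

    def __post_init__(self) -> None:
        if self.ratio_scale not in ("log2", "linear"):
            raise ValueError(f"unknown ratio_scale {self.ratio_scale!r}")


@dataclass
class InhibitorScreenRecord:
    """Per-replicate log2(condition/basal) ratios from the inhibitor screens.

    Arms: insulin alone (ins), insulin + Akt inhibitor MK2206 (mk),
    insulin + PI3K/mTOR inhibitor LY294002 (ly).  Arrays are NaN-padded
    per replicate; an arm with no finite value is "not quantified".
    """

    ins_log2: np.ndarray
    mk_log2: np.ndarray
    ly_log2: np.ndarray

    def __post_init__(self) -> None:
        self.ins_log2 = np.atleast_1d(np.asarray(self.ins_log2, dtype=float))
        self.mk_log2 = np.atleast_1d(np.asarray(self.mk_log2, dtype=float))
        self.ly_log2 = np.atleast_1d(np.asarray(self.ly_log2, dtype=float))

    def _median(self, arr: np.ndarray) -> float:
        ok = np.isfinite(arr)
        return float(np.median(arr[ok])) if ok.any() else math.nan

    @property
    def ins_median(self) -> float:
        return self._median(self.ins_log2)

    @property
    def mk_median(self) -> float:
        return self._median(self.mk_log2)

    @property
    def ly_median(self) -> float:
        return self._median(self.ly_log2)

    def arm_quantified(self, arm: str) -> bool:
        return bool(np.isfinite(getattr(self, f"{arm}_log2")).any())


@dataclass
class PhosphoSiteRecord:
    """One quantified phosphosite (at one peptide multiplicity)."""

    site_id: str
    protein_id: str
    position: int
    residue: str
    localization_prob: float
    sequence_window: str
    gene_name: str = ""
    multiplicity: int = 1
    inhibitor_quant: InhibitorScreenRecord | None = None
    timecourse_quant: TimeCourseProfile | None = None

    def __post_init__(self) -> None:
        if self.residue not in RESIDUES:
            raise ValueError(f"residue must be one of {RESIDUES}, got {self.residue!r}")
        if len(self.sequence_window) != 13:
            raise ValueError(
                f"sequence_window must have length 13, got {len(self.sequence_window)}"
            )
        if self.sequence_window[6] != self.residue:
            raise ValueError(
                f"window center {self.sequence_window[6]!r} != residue {self.residue!r}"
            )
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError("localization_prob must lie in [0, 1]")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class SiteTable:
    """Parsed site table: records plus a read report."""

    records: list[PhosphoSiteRecord]
    n_excluded_decoy: int = 0
    n_bad_rows: int = 0
    n_bad_cells: int = 0
    messages: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def extract_window(protein_sequence: str, position: int, width: int = 13) -> str:
    """Sequence window of ``width`` residues centered on ``position`` (1-based).

    Flanks running past either terminus are padded with '_'.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError("width must be a positive odd integer")
    if not 1 <= position <= len(protein_sequence):
        raise ValueError(
            f"position {position} out of range for sequence of length "
            f"{len(protein_sequence)}"
        )
    half = width // 2
    i = position - 1
    left = protein_sequence[max(0, i - half) : i]
    right = protein_sequence[i + 1 : i + 1 + half]
    return (
        WINDOW_PAD * (half - len(left))
        + left
        + protein_sequence[i]
        + right
        + WINDOW_PAD * (half - len(right))
    )


def _replicate_columns(columns, prefix: str) -> list[str]:
    pat = re.compile(re.escape(prefix) + r"_rep(\d+)$")
    hits = [(int(m.group(1)), c) for c in columns if (m := pat.match(c))]
    return [c for _, c in sorted(hits)]


def _to_log2(values: np.ndarray, dialect: TableDialect) -> np.ndarray:
    if dialect.ratio_scale == "log2":
        return values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(values)
    out[~np.isfinite(out)] = np.nan
    return out


def read_site_table(path, dialect: TableDialect | None = None) -> SiteTable:
    """Read a phosphosite TSV into records.

    Reverse-database and contaminant-flagged rows are excluded (counted);
    rows failing type coercion on identity columns are reported, not
    silently dropped; unparseable numeric ratio cells become missing
    values and are counted in the report.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table is missing required column(s): {missing}")

    n_decoy = 0
    for flag_col in (dialect.reverse_col, dialect.contaminant_col):
        if flag_col in df.columns:
            mask = df[flag_col].str.strip() == dialect.flag_value
            n_decoy += int(mask.sum())
            df = df.loc[~mask]

    ins_cols = _replicate_columns(df.columns, "ins")
    mk_cols = _replicate_columns(df.columns, "mk")
    ly_cols = _replicate_columns(df.columns, "ly")
    tc_cols = {
        lab: _replicate_columns(df.columns, f"tc{lab}") for lab in TIME_LABELS
    }
    has_inhib = bool(ins_cols or mk_cols or ly_cols)
    has_tc = any(tc_cols.values())

    def numeric(cols, row) -> tuple[np.ndarray, int]:
        vals, bad = [], 0
        for c in cols:
            cell = row[c].strip()
            if cell == "":
                vals.append(math.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                vals.append(math.nan)
                bad += 1
        return np.array(vals, dtype=float), bad

    records: list[PhosphoSiteRecord] = []
    n_bad_rows = 0
    n_bad_cells = 0
    messages: list[str] = []
    for idx, row in df.iterrows():
        try:
            position = int(row["position"])
            loc_prob = float(row["localization_prob"])
            multiplicity = int(row["multiplicity"])
        except ValueError as exc:
            n_bad_rows += 1
            messages.append(f"row {idx}: type coercion failed ({exc})")
            continue
        inhib = None
        if has_inhib:
            ins, b1 = numeric(ins_cols, row)
            mk, b2 = numeric(mk_cols, row)
            ly, b3 = numeric(ly_cols, row)
            n_bad_cells += b1 + b2 + b3
            inhib = InhibitorScreenRecord(
                ins_log2=_to_log2(ins, dialect),
                mk_log2=_to_log2(mk, dialect),
                ly_log2=_to_log2(ly, dialect),
            )
        tc = None
        if has_tc:
            rows = []
            for lab in TIME_LABELS:
                vals, b = numeric(tc_cols[lab], row)
                n_bad_cells += b
                rows.append(_to_log2(vals, dialect))
            tc = TimeCourseProfile(replicate_log2=np.vstack(rows))
        try:
            records.append(
                PhosphoSiteRecord(
                    site_id=row["site_id"],
                    protein_id=row["protein_id"],
                    gene_name=row["gene_name"],
                    position=position,
                    residue=row["residue"],
                    localization_prob=loc_prob,
                    multiplicity=multiplicity,
                    sequence_window=row["sequence_window"],
                    inhibitor_quant=inhib,
                    timecourse_quant=tc,
                )
            )
        except ValueError as exc:
            n_bad_rows += 1
            messages.append(f"row {idx}: invalid record ({exc})")
    if n_bad_rows or n_bad_cells:
        warnings.warn(
            f"site table {path}: {n_bad_rows} row(s) rejected, "
            f"{n_bad_cells} unparseable numeric cell(s) treated as missing",
            stacklevel=2,
        )
    return SiteTable(
        records=records,
        n_excluded_decoy=n_decoy,
        n_bad_rows=n_bad_rows,
        n_bad_cells=n_bad_cells,
        messages=messages,
    )


def write_site_table(records, path, n_replicates: int = 3) -> None:
    """Write records as a log2-scale TSV readable by :func:`read_site_table`."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "site_id": r.site_id,
            "protein_id": r.protein_id,
            "gene_name": r.gene_name,
            "position": r.position,
            "residue": r.residue,
            "localization_prob": r.localization_prob,
            "multiplicity": r.multiplicity,
            "sequence_window": r.sequence_window,
            "reverse": "",
            "contaminant": "",
        }
        if r.inhibitor_quant is not None:
            for arm in ("ins", "mk", "ly"):
                vals = getattr(r.inhibitor_quant, f"{arm}_log2")
                for j in range(n_replicates):
                    v = vals[j] if j < len(vals) else math.nan
                    row[f"{arm}_rep{j + 1}"] = v if np.isfinite(v) else ""
        if r.timecourse_quant is not None:
            mat = r.timecourse_quant.replicate_log2
            for i, lab in enumerate(TIME_LABELS):
                for j in range(n_replicates):
                    v = mat[i, j] if j < mat.shape[1] else math.nan
                    row[f"tc{lab}_rep{j + 1}"] = v if np.isfinite(v) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fasta(path) -> dict[str, str]:
    """FASTA as a mapping protein_id -> sequence (id = first header token)."""
    mapping: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in mapping:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r}")
        mapping[rec.id] = seq
    return mapping


PREDICTION_COLUMNS = [
    "site_id",
    "kinase",
    "score",
    "delta",
    "pareto_front",
    "rank",
    "known_positive",
]


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write a kinase-prediction table (one row per site x kinase)."""
    missing = [c for c in PREDICTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"prediction table missing column(s): {missing}")
    table[PREDICTION_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing column(s): {missing}")
    return df
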