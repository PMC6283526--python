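"""Reading/writing protein quantification tables and experiment layout.

A quantification table is a delimited text export from MS search software:
one row per protein group per run with an accession, ten reporter-channel
abundances (TMT 10-plex), a PSM count and a unique-peptide count.  Column
names vary between search engines, so the mapping from column name to role
is configuration (`ColumnRoles`), with defaults matching the tables this
package's simulator writes.

`ChannelMap` assigns the ten channels their experimental meaning: a
temperature (melt, 37-64 degC in 3 degC steps), a concentration (ITDR) or a
time point (ITTR), plus the treatment/replicate labels and which channel is
the fold-change reference (always the lowest x: 37 degC, lowest dose, or
buffer-only).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

N_CHANNELS = 10

#: canonical TMT 10-plex reporter labels, used as default abundance columns
TMT10_LABELS = ("126", "127N", "127C", "128N", "128C",
                "129N", "129C", "130N", "130C", "131")

#: strings treated as missing abundance values on input
MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none", "#n/a"}


@dataclass(frozen=True)
class ColumnRoles:
    """Mapping from table column names to their roles."""

    protein_id: str = "accession"
    description: str = "description"
    psm: str = "psm_count"
    unique_peptides: str = "unique_peptides"
    abundances: Sequence[str] = TMT10_LABELS

    def mandatory(self) -> Dict[str, str]:
        cols = {"protein_id": self.protein_id, "psm": self.psm,
                "unique_peptides": self.unique_peptides}
        for i, name in enumerate(self.abundances):
            cols[f"abundance[{i}]"] = name
        return cols

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnRoles":
        kwargs = {}
        for key in ("protein_id", "description", "psm", "unique_peptides", "abundances"):
            if key in d:
                kwargs[key] = tuple(d[key]) if key == "abundances" else d[key]
        return cls(**kwargs)


@dataclass(frozen=True)
class ChannelMap:
    """Experimental meaning of the ten reporter channels of one run."""

    run_id: str
    treatment: str
    replicate: int
    channel_labels: Sequence[str]
    x_values: Sequence[float]
    x_kind: str  # temperature | concentration | time
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_labels) != N_CHANNELS or len(self.x_values) != N_CHANNELS:
            raise ConfigurationError("ChannelMap requires exactly 10 channels")
        if self.x_kind not in ("temperature", "concentration", "time"):
            raise ConfigurationError(f"unknown x_kind {self.x_kind!r}")
        if not (0 <= self.reference_index < N_CHANNELS):
            raise ConfigurationError("reference_index must lie in [0, 9]")
        if self.replicate < 1:
            raise ConfigurationError("replicate must be a positive integer")
        xs = np.asarray(self.x_values, dtype=float)
        order = np.argsort(xs, kind="stable")
        if not np.all(np.diff(xs[order]) >= 0):  # pragma: no cover
            raise ConfigurationError("x_values must be sortable")
        # the reference must sit at the lowest x (ties allowed for zero/vehicle)
        if xs[self.reference_index] > xs.min():
            raise ConfigurationError(
                "reference_index must point at the lowest x "
                "(37 degC / lowest dose / earliest time)")

    @property
    def x_array(self) -> np.ndarray:
        return np.asarray(self.x_values, dtype=float)


@dataclass
class ProteinQuant:
    """One protein's channel abundances and identification evidence in one run.

    ``abundances`` is a length-10 float array; NaN marks a missing channel.
    Note exports do not guarantee psm_count >= unique_peptides.
    """

    protein_id: str
    description: str
    abundances: np.ndarray
    psm_count: int
    unique_peptides: int
    run_id: str

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (N_CHANNELS,):
            raise DataError("abundances must have length 10")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.abundances)


@dataclass
class LoadReport:
    """Per-file accounting of loaded/skipped rows."""

    path: str
    n_rows: int = 0
    n_loaded: int = 0
    skipped: Counter = field(default_factory=Counter)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"path": self.path, "reason": "loaded", "count": self.n_loaded}]
        rows += [{"path": self.path, "reason": k, "count": v}
                 for k, v in sorted(self.skipped.items())]
        return pd.DataFrame(rows, columns=["path", "reason", "count"])


def _parse_abundance(value) -> float:
    """Float value, NaN for recognized missing tokens, ValueError otherwise."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s.lower() in MISSING_TOKENS:
        return np.nan
    v = float(s)  # may raise ValueError -> row skipped upstream
    if v < 0:
        raise ValueError("negative abundance")
    return v


def read_quant_table(
    path,
    fmt: str = "tsv",
    columns: ColumnRoles = ColumnRoles(),
    run_id: Optional[str] = None,
) -> tuple[List[ProteinQuant], LoadReport]:
    """Read a protein quantification table.

    Rows whose abundances cannot be parsed are skipped and counted in the
    returned LoadReport; recognized missing tokens (NA, empty, ...) become
    flagged missing channels instead.  A header lacking a mandatory column
    raises ConfigurationError naming the role.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"quantification table not found: {path}")
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise ConfigurationError(f"unknown table format {fmt!r}")
    run = run_id if run_id is not None else path.stem
    report = LoadReport(path=str(path))

    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("empty quantification table: %s", path)
        return [], report
    if df.empty and len(df.columns) <= 1:
        logger.warning("empty quantification table: %s", path)
        return [], report
    for role, col in columns.mandatory().items():
        if col not in df.columns:
            raise ConfigurationError(
                f"table {path} lacks mandatory column {col!r} (role: {role})")

    has_desc = columns.description in df.columns
    records: List[ProteinQuant] = []
    ab_cols = list(columns.abundances)
    for _, row in df.iterrows():
        report.n_rows += 1
        pid = str(row[columns.protein_id]).strip()
        if not pid:
            report.skipped["missing_protein_id"] += 1
            continue
        try:
            ab = np.array([_parse_abundance(row[c]) for c in ab_cols])
        except ValueError:
            report.skipped["unparseable_abundance"] += 1
            continue
        try:
            psm = int(float(row[columns.psm]))
            pep = int(float(row[columns.unique_peptides]))
        except ValueError:
            report.skipped["unparseable_evidence"] += 1
            continue
        records.append(ProteinQuant(
            protein_id=pid,
            description=str(row[columns.description]) if has_desc else "",
            abundances=ab,
            psm_count=psm,
            unique_peptides=pep,
            run_id=run,
        ))
        report.n_loaded += 1
    if not records:
        logger.warning("no usable rows in %s", path)
    return records, report


def write_quant_table(records: Iterable[ProteinQuant], path,
                      fmt: str = "tsv",
                      columns: ColumnRoles = ColumnRoles()) -> None:
    """Write records in the same delimited layout `read_quant_table` accepts."""
    sep = {"tsv": "\t", "csv": ","}[fmt]
    rows = []
    for q in records:
        row = {columns.protein_id: q.protein_id,
               columns.description: q.description,
               columns.psm: q.psm_count,
               columns.unique_peptides: q.unique_peptides}
        for name, v in zip(columns.abundances, q.abundances):
            row[name] = "NA" if not np.isfinite(v) else np.format_float_positional(
                v, trim="0", precision=None)
        rows.append(row)
    cols = [columns.protein_id, columns.description, columns.psm,
            columns.unique_peptides, *columns.abundances]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def join_runs(runs: Iterable[Iterable[ProteinQuant]]) -> "JoinedRuns":
    """Assemble a protein-indexed view across runs.

    Duplicate proteins within a run keep the row with the larger PSM count
    (first occurrence on ties); collisions are logged.
    """
    table: Dict[str, Dict[str, ProteinQuant]] = {}
    run_ids: List[str] = []
    for records in runs:
        seen_run = None
        for q in records:
            if seen_run is None:
                seen_run = q.run_id
                if q.run_id in run_ids:
                    raise DataError(f"duplicate run_id {q.run_id!r} in join_runs")
                run_ids.append(q.run_id)
            per = table.setdefault(q.protein_id, {})
            prev = per.get(q.run_id)
            if prev is None:
                per[q.run_id] = q
            else:
                logger.info("duplicate protein %s in run %s (psm %d vs %d)",
                            q.protein_id, q.run_id, prev.psm_count, q.psm_count)
                if q.psm_count > prev.psm_count:
                    per[q.run_id] = q
    return JoinedRuns(table=table, run_ids=sorted(run_ids))


@dataclass
class JoinedRuns:
    """Protein -> {run -> ProteinQuant} with presence bookkeeping."""

    table: Dict[str, Dict[str, ProteinQuant]]
    run_ids: List[str]

    def presence_count(self, protein_id: str) -> int:
        return len(self.table.get(protein_id, {}))

    def complete_subset(self) -> List[str]:
        """Proteins quantified in every run, in sorted order."""
        n = len(self.run_ids)
        return sorted(p for p, runs in self.table.items() if len(runs) == n)


# -- hit tables -------------------------------------------------------------

HIT_COLUMNS = ["protein_id", "treatment", "direction", "mdt", "r_squared",
               "max_effect_fc", "auc", "psm_count", "pass_baseline",
               "pass_30pct", "pass_r2", "pass_psm", "flags"]


def write_hit_table(hits, path) -> None:
    """Serialize HitCalls (or an equivalent DataFrame) to CSV.

    An absent MDT is written as an empty cell, never 0.
    """
    if isinstance(hits, pd.DataFrame):
        df = hits.copy()
    else:
        df = pd.DataFrame([h.as_record() for h in hits], columns=HIT_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=HIT_COLUMNS)
    try:
        df.to_csv(path, index=False, na_rep="")
    except OSError as exc:
        raise DataError(f"cannot write hit table {path}: {exc}") from exc


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df
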