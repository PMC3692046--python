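"""Reading, validating and writing TMA marker grids, survival tables and networks.

The expected grid layout is markers as columns and samples as rows, with the
first column holding the sample identifier.  Replicate marker columns share a
name; a column named ``*Batch`` carries batch labels and columns prefixed
``*cov`` carry per-sample covariates.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _nanreduce(reducer, a, axis):
    """nanmean/nanmedian without the all-NaN slice warning (all-NaN -> NaN)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return reducer(a, axis=axis)

from .errors import GridFormatError, ValidationError

MISSING_TOKENS = {"", "na", "nan"}

BATCH_COLUMN = "*Batch"
COVARIATE_PREFIX = "*cov"


def _parse_cell(text):
    """Parse one grid cell: missing token -> None, numeric -> float, else str."""
    if text is None:
        return None
    s = str(text).strip()
    if s.lower() in MISSING_TOKENS:
        return None
    try:
        return float(s)
    except ValueError:
        return s


@dataclass
class RawGrid:
    """A parsed score grid before annotation extraction.

    ``header`` keeps duplicate column names (replicates) exactly as found;
    ``cells`` holds parsed values (float, str for non-numeric, None for
    missing) row-major, excluding the identifier column.
    """

    header: list[str]
    sample_ids: list[str]
    cells: list[list[object]]
    source: str | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class MarkerTable:
    """Samples x marker-columns score matrix.

    ``columns`` may contain duplicate names (replicate columns); the
    ``replicate_map`` groups column indices by marker name.  After
    :func:`collapse_replicates` every marker owns exactly one column.
    Missing scores are NaN.
    """

    sample_ids: list[str]
    columns: list[str]
    values: np.ndarray
    replicate_map: dict[str, list[int]] = field(default_factory=dict)
    batch: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    score_kind: dict[str, str] = field(default_factory=dict)
    corrected: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.columns)} columns"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if self.batch is not None and len(self.batch) != len(self.sample_ids):
            raise ValidationError("batch labels must cover every sample")
        if not self.replicate_map:
            self.replicate_map = {}
            for j, name in enumerate(self.columns):
                self.replicate_map.setdefault(name, []).append(j)

    @property
    def marker_names(self) -> list[str]:
        return list(self.replicate_map)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def marker_values(self, name: str) -> np.ndarray:
        """Collapsed (mean over replicates) values for one marker."""
        idx = self.replicate_map[name]
        return _nanreduce(np.nanmean, self.values[:, idx], 1)

    def flag_report(self) -> dict:
        """Flag (never drop) all-missing rows and columns."""
        all_missing_rows = [
            self.sample_ids[i] for i in range(self.n_samples)
            if np.all(np.isnan(self.values[i]))
        ]
        all_missing_cols = [
            self.columns[j] for j in range(len(self.columns))
            if np.all(np.isnan(self.values[:, j]))
        ]
        return {"all_missing_samples": all_missing_rows,
                "all_missing_columns": all_missing_cols}


@dataclass
class SurvivalTable:
    """Right-censored follow-up per sample: time in months, event in {0, 1}."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample IDs in survival table: {dupes}")
        if np.any(self.time < 0):
            raise ValidationError("survival times must be non-negative")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValidationError("event indicator must be 0 (censored) or 1 (event)")


@dataclass
class LinkedDataset:
    """Marker table and survival table inner-joined on sample ID."""

    markers: MarkerTable
    survival: SurvivalTable
    report: dict


def _sniff_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return "xlsx"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    return "csv"


def parse_score_grid(source, dialect: str = "auto") -> RawGrid:
    """Parse a marker grid from CSV, TSV or XLSX.

    The first row is the header, the first column the sample identifier.
    Duplicate header names are preserved (replicates).  Empty cells and the
    tokens "NA"/"NaN" (case-insensitive) parse as missing.
    """
    path = Path(source)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect == "xlsx":
        rows = _read_xlsx_rows(path)
    elif dialect in ("csv", "tsv"):
        delim = "," if dialect == "csv" else "\t"
        try:
            with open(path, newline="", encoding="utf-8-sig") as fh:
                rows = list(csv.reader(fh, delimiter=delim))
        except OSError as exc:
            raise GridFormatError(f"cannot read {path}: {exc}") from exc
    else:
        raise GridFormatError(f"unknown dialect {dialect!r}")

    rows = [r for r in rows if any(str(c).strip() for c in r if c is not None)]
    if len(rows) < 2:
        raise GridFormatError(f"{path}: need a header row and at least one data row")
    header = [str(c).strip() for c in rows[0]]
    n_cols = len(header)
    sample_ids: list[str] = []
    cells: list[list[object]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise GridFormatError(
                f"{path}: row {i} has {len(row)} fields, expected {n_cols}"
            )
        sid = str(row[0]).strip()
        if not sid:
            raise GridFormatError(f"{path}: row {i} has an empty sample identifier")
        # integral numeric IDs from spreadsheets normalise to their integer form
        try:
            f = float(sid)
            if f == int(f):
                sid = str(int(f))
        except ValueError:
            pass
        sample_ids.append(sid)
        cells.append([_parse_cell(c) for c in row[1:]])
    dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dupes:
        raise ValidationError(f"duplicate sample IDs: {dupes}")
    return RawGrid(header=header, sample_ids=sample_ids, cells=cells, source=str(path))


def _read_xlsx_rows(path: Path) -> list[list[object]]:
    from openpyxl import load_workbook

    try:
        wb = load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:  # noqa: BLE001 - openpyxl raises many types
        raise GridFormatError(f"cannot read {path}: {exc}") from exc
    ws = wb.worksheets[0]
    out = []
    for row in ws.iter_rows(values_only=True):
        out.append(["" if c is None else c for c in row])
    wb.close()
    return out


_CATEGORICAL_MAX_LEVELS = 10


def _detect_score_kind(col: np.ndarray) -> str:
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return "continuous"
    levels = np.unique(obs)
    if levels.size <= _CATEGORICAL_MAX_LEVELS and np.all(levels == np.round(levels)):
        return "categorical"
    return "continuous"


def extract_annotations(raw: RawGrid, score_kind_override: dict[str, str] | None = None,
                        ) -> tuple[MarkerTable, dict]:
    """Split a raw grid into marker columns, batch labels and covariates.

    A column named exactly ``*Batch`` becomes the batch label; columns whose
    name starts with ``*cov`` become covariates (prefix stripped).  Everything
    else is a marker column.  Returns the table plus a report dict with
    warnings (e.g. batches with <3 samples) and all-missing flags.
    """
    n = raw.n_samples
    marker_cols: list[int] = []
    marker_names: list[str] = []
    batch_idx = None
    cov_cols: dict[str, int] = {}
    for j, name in enumerate(raw.header[1:]):
        if name == BATCH_COLUMN:
            batch_idx = j
        elif name.startswith(COVARIATE_PREFIX):
            cov_cols[name[len(COVARIATE_PREFIX):]] = j
        else:
            marker_cols.append(j)
            marker_names.append(name)

    values = np.full((n, len(marker_cols)), np.nan)
    for i in range(n):
        for out_j, j in enumerate(marker_cols):
            cell = raw.cells[i][j]
            if cell is None:
                continue
            if isinstance(cell, str):
                raise GridFormatError(
                    f"non-numeric score {cell!r} for marker "
                    f"{marker_names[out_j]!r} in row {i + 2}"
                )
            values[i, out_j] = cell

    batch = None
    warnings: list[str] = []
    if batch_idx is not None:
        labels = []
        for i in range(n):
            cell = raw.cells[i][batch_idx]
            if cell is None:
                raise ValidationError(
                    f"missing batch label for sample {raw.sample_ids[i]!r}"
                )
            if isinstance(cell, float) and cell == int(cell):
                cell = str(int(cell))
            labels.append(str(cell))
        batch = np.array(labels, dtype=object)
        counts = pd.Series(labels).value_counts()
        for b, c in counts.items():
            if c < 3:
                warnings.append(f"batch {b!r} has only {c} sample(s)")

    covariates = None
    if cov_cols:
        data = {}
        for cname, j in cov_cols.items():
            col = np.full(n, np.nan)
            for i in range(n):
                cell = raw.cells[i][j]
                if cell is None:
                    continue
                if isinstance(cell, str):
                    raise GridFormatError(
                        f"non-numeric covariate value {cell!r} for {cname!r} "
                        f"in row {i + 2}"
                    )
                col[i] = cell
            data[cname] = col
        covariates = pd.DataFrame(data, index=raw.sample_ids)

    replicate_map: dict[str, list[int]] = {}
    for j, name in enumerate(marker_names):
        replicate_map.setdefault(name, []).append(j)

    kinds = {}
    for name, idx in replicate_map.items():
        kinds[name] = _detect_score_kind(values[:, idx].ravel())
    if score_kind_override:
        kinds.update(score_kind_override)

    table = MarkerTable(
        sample_ids=list(raw.sample_ids),
        columns=marker_names,
        values=values,
        replicate_map=replicate_map,
        batch=batch,
        covariates=covariates,
        score_kind=kinds,
    )
    report = {"warnings": warnings, **table.flag_report()}
    return table, report


def collapse_replicates(table: MarkerTable, method: str = "mean") -> MarkerTable:
    """Collapse replicate columns to one column per marker.

    ``method`` is "mean" or "median", computed over non-missing replicate
    values; a sample with all replicates missing stays missing.  When batch
    correction is requested it runs before this step (batch effects are
    per-column phenomena).
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown collapse method {method!r}")
    reducer = np.nanmean if method == "mean" else np.nanmedian
    names = table.marker_names
    out = np.full((table.n_samples, len(names)), np.nan)
    for k, name in enumerate(names):
        out[:, k] = _nanreduce(reducer, table.values[:, table.replicate_map[name]], 1)
    return MarkerTable(
        sample_ids=list(table.sample_ids),
        columns=names,
        values=out,
        replicate_map={name: [k] for k, name in enumerate(names)},
        batch=None if table.batch is None else table.batch.copy(),
        covariates=None if table.covariates is None else table.covariates.copy(),
        score_kind=dict(table.score_kind),
        corrected=table.corrected,
    )


def parse_survival(source, dialect: str = "auto") -> SurvivalTable:
    """Parse a survival table with columns (id, time, event)."""
    raw = parse_score_grid(source, dialect=dialect)
    if len(raw.header) < 3:
        raise GridFormatError("survival table needs columns (id, time, event)")
    times = []
    events = []
    for i, row in enumerate(raw.cells, start=2):
        t, e = row[0], row[1]
        if t is None or e is None or isinstance(t, str) or isinstance(e, str):
            raise GridFormatError(f"non-numeric or missing time/event in row {i}")
        times.append(t)
        events.append(int(e))
    return SurvivalTable(sample_ids=list(raw.sample_ids), time=np.array(times),
                         event=np.array(events))


def attach_survival(table: MarkerTable, surv: SurvivalTable) -> LinkedDataset:
    """Inner-join marker and survival tables on sample ID.

    The report lists IDs present on only one side; zero overlap is an error.
    """
    marker_ids = set(table.sample_ids)
    surv_ids = set(surv.sample_ids)
    common = marker_ids & surv_ids
    if not common:
        raise ValidationError("no overlapping sample IDs between marker and survival data")
    keep = [i for i, s in enumerate(table.sample_ids) if s in common]
    ordered = [table.sample_ids[i] for i in keep]
    surv_pos = {s: i for i, s in enumerate(surv.sample_ids)}
    sidx = [surv_pos[s] for s in ordered]
    linked_markers = MarkerTable(
        sample_ids=ordered,
        columns=list(table.columns),
        values=table.values[keep],
        replicate_map={k: list(v) for k, v in table.replicate_map.items()},
        batch=None if table.batch is None else table.batch[keep],
        covariates=None if table.covariates is None else table.covariates.iloc[keep],
        score_kind=dict(table.score_kind),
        corrected=table.corrected,
    )
    linked_surv = SurvivalTable(
        sample_ids=ordered, time=surv.time[sidx], event=surv.event[sidx]
    )
    report = {
        "n_linked": len(ordered),
        "marker_only": sorted(marker_ids - surv_ids),
        "survival_only": sorted(surv_ids - marker_ids),
    }
    return LinkedDataset(markers=linked_markers, survival=linked_surv, report=report)


def write_grid(table: MarkerTable, path, dialect: str = "auto") -> None:
    """Serialize a MarkerTable back to a grid file (CSV/TSV)."""
    path = Path(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    delim = "\t" if dialect == "tsv" else ","
    header = ["id"] + list(table.columns)
    if table.batch is not None:
        header.append(BATCH_COLUMN)
    if table.covariates is not None:
        header += [COVARIATE_PREFIX + c for c in table.covariates.columns]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(header)
        for i, sid in enumerate(table.sample_ids):
            row: list[object] = [sid]
            for v in table.values[i]:
                row.append("" if np.isnan(v) else repr(float(v)))
            if table.batch is not None:
                row.append(table.batch[i])
            if table.covariates is not None:
                for c in table.covariates.columns:
                    v = table.covariates.iloc[i][c]
                    row.append("" if pd.isna(v) else repr(float(v)))
            w.writerow(row)


def write_survival(surv: SurvivalTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "time", "event"])
        for sid, t, e in zip(surv.sample_ids, surv.time, surv.event):
            w.writerow([sid, repr(float(t)), int(e)])


def export_graphml(network, sink) -> None:
    """Write a Network as GraphML.

    Nodes carry {name, degree}; edges carry {method, statistic, sign, p_raw,
    p_adj}.  The document re-parses to an isomorphic graph with identical
    attributes.
    """
    import networkx as nx

    g = nx.Graph()
    for node, degree in network.degrees.items():
        g.add_node(node, name=node, degree=int(degree))
    for e in network.edges:
        g.add_edge(
            e.marker_a, e.marker_b,
            method=e.method, statistic=float(e.statistic), sign=int(e.sign),
            p_raw=float(e.p_raw), p_adj=float(e.p_adj),
        )
    nx.write_graphml(g, sink)


def read_graphml(source):
    import networkx as nx

    return nx.read_graphml(source)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
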