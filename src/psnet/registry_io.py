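"""Reading, validation and writing of visit-level register tables and networks.

A register extract is a delimited text file with one row per primary-care
visit.  Rows that violate the field grammars (unparseable dates, malformed
diagnosis codes, empty mandatory identifiers) are collected into a rejects
table rather than silently dropped, so that every record can be accounted
for across processing phases.

Networks are written as canonical undirected edge lists (``node_a <
node_b``, sorted) and as GraphML with node attributes, both plain text.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import re
from pathlib import Path
from typing import Iterator, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import SchemaError

#: Canonical column order for visit tables.
VISIT_COLUMNS = (
    "visit_id",
    "patient_id",
    "professional_id",
    "date",
    "municipality",
    "occupation_title",
    "occupation_group",
    "service_type",
    "service_group",
    "icd10_codes",
    "icpc2_codes",
    "home_care",
    "patient_age_years",
)

#: Columns that must be present in an input file header.
MANDATORY_COLUMNS = (
    "visit_id",
    "patient_id",
    "professional_id",
    "date",
    "municipality",
    "occupation_group",
    "service_group",
    "patient_age_years",
)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}")
_ICPC2_RE = re.compile(r"^[A-Z][0-9]{2}$")
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f", ""}


@dataclasses.dataclass(frozen=True)
class Dialect:
    """Physical format of a register extract.

    The real register's dialect is not standardised, so everything is
    configurable; the defaults are UTF-8, comma-delimited, ISO-8601 dates,
    with multiple diagnosis codes per cell separated by ``;``.
    """

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    missing_token: str = ""
    code_separator: str = ";"
    encoding: str = "utf-8"


@dataclasses.dataclass(frozen=True)
class VisitRecord:
    """One register row: a single patient-professional contact."""

    visit_id: str
    patient_id: str
    professional_id: str  # empty string when missing
    date: _dt.date
    municipality: str
    occupation_title: str
    occupation_group: str  # empty string when missing
    service_type: str
    service_group: str
    icd10_codes: tuple[str, ...]
    icpc2_codes: tuple[str, ...]
    home_care: bool
    patient_age_years: int


class VisitTable:
    """Ordered collection of visit records with a provenance trail.

    Backed by a :class:`pandas.DataFrame` in the canonical column order;
    diagnosis-code cells are stored as separator-joined strings and only
    split into tuples when materialising :class:`VisitRecord` objects.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        provenance: Optional[Sequence[str]] = None,
        rejects: Optional[pd.DataFrame] = None,
        dialect: Dialect = Dialect(),
    ):
        missing = [c for c in VISIT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"visit table missing columns: {missing}")
        self.df = df.loc[:, list(VISIT_COLUMNS)].reset_index(drop=True)
        self.provenance: list[str] = list(provenance or [])
        self.rejects = (
            rejects
            if rejects is not None
            else pd.DataFrame(columns=["line", "visit_id", "reason"])
        )
        self.dialect = dialect

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    @property
    def n_professionals(self) -> int:
        pid = self.df["professional_id"]
        return pid[pid != ""].nunique()

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def records(self) -> Iterator[VisitRecord]:
        sep = self.dialect.code_separator
        for row in self.df.itertuples(index=False):
            yield VisitRecord(
                visit_id=row.visit_id,
                patient_id=row.patient_id,
                professional_id=row.professional_id,
                date=row.date.date() if hasattr(row.date, "date") else row.date,
                municipality=row.municipality,
                occupation_title=row.occupation_title,
                occupation_group=row.occupation_group,
                service_type=row.service_type,
                service_group=row.service_group,
                icd10_codes=_split_codes(row.icd10_codes, sep),
                icpc2_codes=_split_codes(row.icpc2_codes, sep),
                home_care=bool(row.home_care),
                patient_age_years=int(row.patient_age_years),
            )

    def equals(self, other: "VisitTable") -> bool:
        """Field-level equality of the records, ignoring provenance."""
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        return a.equals(b)

    def copy(self) -> "VisitTable":
        return VisitTable(
            self.df.copy(), list(self.provenance), self.rejects.copy(), self.dialect
        )


def _split_codes(cell: str, sep: str) -> tuple[str, ...]:
    if not cell:
        return ()
    return tuple(tok.strip() for tok in cell.split(sep) if tok.strip())


def _valid_codes(cell: str, sep: str, pattern: re.Pattern) -> bool:
    return all(pattern.match(tok) for tok in _split_codes(cell, sep))


def read_visits(path: str | Path, dialect: Dialect = Dialect()) -> VisitTable:
    """Read a visit table from delimited text.

    Rows violating the field grammars are routed to ``table.rejects`` with
    their 1-based file line number; a missing mandatory column raises
    :class:`SchemaError` naming the column.
    """
    path = Path(path)
    raw = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        keep_default_na=False,
        encoding=dialect.encoding,
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: header lacks mandatory column(s) {missing}")
    for col in VISIT_COLUMNS:
        if col not in raw.columns:
            raw[col] = "false" if col == "home_care" else ""

    sep = dialect.code_separator
    reject_rows: list[dict] = []
    keep_idx: list[int] = []
    parsed_dates: list[_dt.date] = []
    parsed_age: list[int] = []
    parsed_home: list[bool] = []
    seen_ids: set[str] = set()

    for pos, row in enumerate(raw.itertuples(index=False)):
        line = pos + 2  # header is line 1
        reason = None
        date_val: Optional[_dt.date] = None
        age_val = 0
        home_val = False
        vid = getattr(row, "visit_id").strip()
        if not vid:
            reason = "empty visit_id"
        elif vid in seen_ids:
            reason = "duplicate visit_id"
        elif not getattr(row, "patient_id").strip():
            reason = "empty patient_id"
        if reason is None:
            try:
                date_val = _dt.datetime.strptime(
                    getattr(row, "date").strip(), dialect.date_format
                ).date()
            except ValueError:
                reason = f"unparseable date {getattr(row, 'date')!r}"
        if reason is None:
            age_txt = getattr(row, "patient_age_years").strip()
            if not age_txt.isdigit():
                reason = f"invalid patient_age_years {age_txt!r}"
            else:
                age_val = int(age_txt)
        if reason is None and not _valid_codes(
            getattr(row, "icd10_codes"), sep, _ICD10_RE
        ):
            reason = f"malformed ICD-10 code(s) {getattr(row, 'icd10_codes')!r}"
        if reason is None and not _valid_codes(
            getattr(row, "icpc2_codes"), sep, _ICPC2_RE
        ):
            reason = f"malformed ICPC-2 code(s) {getattr(row, 'icpc2_codes')!r}"
        if reason is None:
            home_txt = getattr(row, "home_care").strip().lower()
            if home_txt in _TRUE_TOKENS:
                home_val = True
            elif home_txt in _FALSE_TOKENS:
                home_val = False
            else:
                reason = f"invalid home_care flag {getattr(row, 'home_care')!r}"

        if reason is not None:
            reject_rows.append({"line": line, "visit_id": vid, "reason": reason})
        else:
            seen_ids.add(vid)
            keep_idx.append(pos)
            parsed_dates.append(date_val)
            parsed_age.append(age_val)
            parsed_home.append(home_val)

    df = raw.iloc[keep_idx].reset_index(drop=True)
    df["date"] = pd.to_datetime(parsed_dates)
    df["patient_age_years"] = pd.array(parsed_age, dtype="int64")
    df["home_care"] = pd.array(parsed_home, dtype="bool")
    rejects = pd.DataFrame(reject_rows, columns=["line", "visit_id", "reason"])
    table = VisitTable(df, rejects=rejects, dialect=dialect)
    table.log(
        f"read_visits({path.name}): {len(table)} records accepted, "
        f"{len(rejects)} rejected"
    )
    return table


def write_visits(table: VisitTable, path: str | Path) -> Path:
    """Write a visit table as delimited text with stable column order."""
    path = Path(path)
    d = table.dialect
    out = table.df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime(d.date_format)
    out["home_care"] = out["home_care"].map({True: "true", False: "false"})
    out.to_csv(path, sep=d.delimiter, index=False, encoding=d.encoding)
    return path


def write_rejects(table: VisitTable, path: str | Path) -> Path:
    """Write the rejects sidecar (line number, visit id, reason)."""
    path = Path(path)
    table.rejects.to_csv(path, index=False)
    return path


def write_edge_list(net: nx.Graph, path: str | Path) -> Path:
    """Write a patient-sharing network as a canonical undirected edge list.

    One row per edge, ``node_a < node_b`` lexicographically, rows sorted;
    the output is therefore independent of in-memory insertion order.
    """
    path = Path(path)
    rows = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, int(data.get("shared_patients", 1))))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a,node_b,shared_patients\n")
        for a, b, w in rows:
            fh.write(f"{a},{b},{w}\n")
    return path


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an edge list written by :func:`write_edge_list`."""
    df = pd.read_csv(path, dtype={"node_a": str, "node_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, shared_patients=int(row.shared_patients))
    return g


def write_node_attrs(attrs: pd.DataFrame, path: str | Path) -> Path:
    """Write the professional attribute table (index = professional_id)."""
    path = Path(path)
    attrs.to_csv(path, index_label="professional_id")
    return path


def read_node_attrs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str).set_index("professional_id")


def write_graphml(net: nx.Graph, path: str | Path) -> Path:
    """Write the network as GraphML with stringified node attributes."""
    path = Path(path)
    g = nx.Graph()
    for n, data in net.nodes(data=True):
        g.add_node(str(n), **{k: str(v) for k, v in data.items()})
    for u, v, data in net.edges(data=True):
        g.add_edge(str(u), str(v), shared_patients=int(data.get("shared_patients", 1)))
    nx.write_graphml(g, path)
    return path
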