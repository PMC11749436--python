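"""Cohort selection cascade and majority-of-visits attribute assignment.

The cohort is adult primary-care patients with at least one visit related
to mental health or substance use (MH/SU) during the study year.  A visit
qualifies as MH/SU if any of three criteria holds:

(1) an ICD-10 psychiatric diagnosis (F-chapter), excluding dementia,
    intellectual disability and specific developmental/speech disorders;
(2) an ICPC-2 psychological symptom or diagnosis (P-chapter), excluding
    specific learning problems, dementia and intellectual disability;
(3) the visit's service type is a mental-health or substance-use service.

The cascade then removes home-care visits, visits under uninformative or
occupational-health service codes, visits without an identifiable
professional, and finally patients whose remaining visits cannot carry any
patient-sharing information (a single visit, or every visit to the same
professional).  Per-stage record counts are collected in a
:class:`FilterReport` so the whole cascade is auditable.

Because dropping visits in the middle stages can strip a patient of their
only qualifying visit or leave them with a single visit, the patient-level
stages are iterated to a fixed point; filtering is therefore idempotent.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .errors import ConfigError
from .registry_io import VisitRecord, VisitTable, _split_codes

#: Collapse of the register service groups to the 3-level nodal coding.
SERVICE_COLLAPSE = {
    "outpatient": "outpatient",
    "mental_health_substance_use": "mental_health_substance_use",
}


def collapse_service_group(value: str) -> str:
    """Map a register service group to the 3-level coding used for nodes."""
    return SERVICE_COLLAPSE.get(value, "other")


def _parse_range(spec: str) -> tuple[str, str]:
    if "-" in spec:
        lo, hi = spec.split("-", 1)
    else:
        lo = hi = spec
    lo, hi = lo.strip().upper(), hi.strip().upper()
    if len(lo) != 3 or len(hi) != 3 or lo > hi:
        raise ConfigError(f"malformed code range {spec!r} (expected like 'F00-F03')")
    return lo, hi


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Parameters of the cohort-selection cascade.

    Defaults encode the study conditions: calendar-year window, adult
    patients, ICD-10 F-codes excluding F00–F03 (dementia), F70–F79
    (intellectual disability) and F80–F83 (specific developmental/speech
    disorders), ICPC-2 P-codes excluding P24, P70 and P85.  The named
    exclusions are diagnostic categories; the code ranges realising them
    are configurable.
    """

    study_start: _dt.date = _dt.date(2021, 1, 1)
    study_end: _dt.date = _dt.date(2021, 12, 31)
    min_age_years: int = 18
    age_inclusive: bool = True  # age >= min counts as adult; False for strict >
    icd10_include_prefix: str = "F"
    icd10_exclusions: tuple[str, ...] = ("F00-F03", "F70-F79", "F80-F83")
    icpc2_include_prefix: str = "P"
    icpc2_exclusions: tuple[str, ...] = ("P24", "P70", "P85")
    mhsu_service_groups: frozenset[str] = frozenset({"mental_health_substance_use"})
    excluded_service_groups: frozenset[str] = frozenset(
        {"other_unspecified", "occupational_health"}
    )
    drop_home_care: bool = True
    patient_level_qualification: bool = True  # keep all visits of qualifying patients

    def __post_init__(self):
        for rng in self.icd10_exclusions:
            lo, hi = _parse_range(rng)
            if not (
                lo.startswith(self.icd10_include_prefix)
                and hi.startswith(self.icd10_include_prefix)
            ):
                raise ConfigError(
                    f"ICD-10 exclusion {rng!r} outside include family "
                    f"{self.icd10_include_prefix!r}"
                )
        for code in self.icpc2_exclusions:
            if not code.startswith(self.icpc2_include_prefix):
                raise ConfigError(
                    f"ICPC-2 exclusion {code!r} outside include family "
                    f"{self.icpc2_include_prefix!r}"
                )

    @property
    def icd10_exclusion_ranges(self) -> tuple[tuple[str, str], ...]:
        return tuple(_parse_range(r) for r in self.icd10_exclusions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for field in dataclasses.fields(cls):
            if field.name not in raw:
                continue
            val = raw[field.name]
            if field.name in ("study_start", "study_end") and isinstance(val, str):
                val = _dt.date.fromisoformat(val)
            if field.name in ("mhsu_service_groups", "excluded_service_groups"):
                val = frozenset(val)
            if field.name in ("icd10_exclusions", "icpc2_exclusions"):
                val = tuple(val)
            kwargs[field.name] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        raw = dataclasses.asdict(self)
        raw["study_start"] = self.study_start.isoformat()
        raw["study_end"] = self.study_end.isoformat()
        raw["mhsu_service_groups"] = sorted(self.mhsu_service_groups)
        raw["excluded_service_groups"] = sorted(self.excluded_service_groups)
        raw["icd10_exclusions"] = list(self.icd10_exclusions)
        raw["icpc2_exclusions"] = list(self.icpc2_exclusions)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)
        return path


class FilterReport:
    """Per-stage counts of visits, patients and professionals."""

    def __init__(self):
        self._rows: list[dict] = []
        self.empty_stages: list[str] = []

    def record(self, stage: str, description: str, df: pd.DataFrame) -> None:
        pid = df["professional_id"]
        self._rows.append(
            {
                "stage": stage,
                "description": description,
                "n_visits": len(df),
                "n_patients": df["patient_id"].nunique(),
                "n_professionals": int(pid[pid != ""].nunique()),
            }
        )
        if len(df) == 0:
            self.empty_stages.append(stage)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._rows,
            columns=["stage", "description", "n_visits", "n_patients", "n_professionals"],
        )

    def is_monotone(self) -> bool:
        f = self.frame
        for col in ("n_visits", "n_patients", "n_professionals"):
            if (f[col].diff().dropna() > 0).any():
                return False
        return True

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    def to_text(self) -> str:
        f = self.frame
        width = max(len(d) for d in f["description"])
        lines = [
            f"{'stage':<6} {'description':<{width}} {'visits':>9} {'patients':>9} "
            f"{'professionals':>13}"
        ]
        for row in f.itertuples(index=False):
            lines.append(
                f"{row.stage:<6} {row.description:<{width}} {row.n_visits:>9} "
                f"{row.n_patients:>9} {row.n_professionals:>13}"
            )
        if self.empty_stages:
            lines.append(f"WARNING: empty table after stage(s) {self.empty_stages}")
        return "\n".join(lines)


def _icd10_qualifies(code: str, cfg: FilterConfig) -> bool:
    c = code.strip().upper()
    if len(c) < 3 or not c.startswith(cfg.icd10_include_prefix):
        return False
    stem = c[:3]
    return not any(lo <= stem <= hi for lo, hi in cfg.icd10_exclusion_ranges)

def _icpc2_qualifies(code: str, cfg: FilterConfig) -> bool:
    c = code.strip().upper()
    if not c.startswith(cfg.icpc2_include_prefix):
        return False
    return c not in cfg.icpc2_exclusions


def is_mhsu_visit(visit: VisitRecord, cfg: FilterConfig) -> bool:
    """Whether one visit is related to mental health or substance use.

    True iff any of the three criteria (qualifying ICD-10 F-code,
    qualifying ICPC-2 P-code, MH/SU service type) holds.
    """
    if any(_icd10_qualifies(c, cfg) for c in visit.icd10_codes):
        return True
    if any(_icpc2_qualifies(c, cfg) for c in visit.icpc2_codes):
        return True
    return visit.service_group in cfg.mhsu_service_groups


def _mhsu_mask(df: pd.DataFrame, cfg: FilterConfig, sep: str) -> pd.Series:
    """Vectorised counterpart of :func:`is_mhsu_visit` over a table."""
    icd = [
        any(_icd10_qualifies(c, cfg) for c in _split_codes(cell, sep))
        for cell in df["icd10_codes"].to_numpy()
    ]
    icpc = [
        any(_icpc2_qualifies(c, cfg) for c in _split_codes(cell, sep))
        for cell in df["icpc2_codes"].to_numpy()
    ]
    svc = df["service_group"].isin(cfg.mhsu_service_groups).to_numpy()
    return pd.Series(
        [a or b or c for a, b, c in zip(icd, icpc, svc)], index=df.index
    )


def _drop_uninformative_patients(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the single-visit (S7) then single-professional (S8) patient drops."""
    counts = df.groupby("patient_id")["visit_id"].transform("count")
    after_s7 = df[counts >= 2]
    nprof = after_s7.groupby("patient_id")["professional_id"].transform("nunique")
    after_s8 = after_s7[nprof >= 2]
    return after_s7, after_s8


def apply_cohort_filters(
    table: VisitTable, cfg: Optional[FilterConfig] = None
) -> tuple[VisitTable, FilterReport]:
    """Run the full cohort-selection cascade S1–S8 and report stage counts.

    Stages: S1 study window; S2 adult age; S3 patients with at least one
    MH/SU visit (all their visits kept when patient-level qualification is
    on); S4 home-care visits dropped; S5 excluded service groups dropped;
    S6 visits without professional id or occupation group dropped; S7
    single-visit patients dropped; S8 single-professional patients dropped.
    S3/S7/S8 are iterated to a fixed point because the visit-level drops in
    S4–S6 can invalidate earlier patient-level decisions; extra passes are
    appended to the report.
    """
    cfg = cfg or FilterConfig()
    sep = table.dialect.code_separator
    report = FilterReport()
    df = table.df
    report.record("S0", "input", df)

    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    df = df[(df["date"] >= start) & (df["date"] <= end)]
    report.record("S1", "within study window", df)

    if cfg.age_inclusive:
        df = df[df["patient_age_years"] >= cfg.min_age_years]
    else:
        df = df[df["patient_age_years"] > cfg.min_age_years]
    report.record("S2", "adult patients", df)

    qual = _mhsu_mask(df, cfg, sep)
    if cfg.patient_level_qualification:
        mhsu_patients = set(df.loc[qual, "patient_id"])
        df = df[df["patient_id"].isin(mhsu_patients)]
    else:
        df = df[qual]
    report.record("S3", "patients with a MH/SU visit", df)

    if cfg.drop_home_care:
        df = df[~df["home_care"]]
    report.record("S4", "home-care visits dropped", df)

    df = df[~df["service_group"].isin(cfg.excluded_service_groups)]
    report.record("S5", "excluded service groups dropped", df)

    df = df[(df["professional_id"] != "") & (df["occupation_group"] != "")]
    report.record("S6", "missing professional/occupation dropped", df)

    after_s7, df = _drop_uninformative_patients(df)
    report.record("S7", "single-visit patients dropped", after_s7)
    report.record("S8", "single-professional patients dropped", df)

    # Fixed point: re-check MH/SU qualification and the S7/S8 drops until
    # stable, so that applying the cascade to its own output is a no-op.
    passes = 0
    while True:
        n_before = len(df)
        qual = _mhsu_mask(df, cfg, sep)
        if cfg.patient_level_qualification:
            keep = set(df.loc[qual, "patient_id"])
            df = df[df["patient_id"].isin(keep)]
        else:
            df = df[qual]
        _, df = _drop_uninformative_patients(df)
        if len(df) == n_before:
            break
        passes += 1
        report.record(f"S8+{passes}", f"fixed-point pass {passes}", df)

    out = VisitTable(df.reset_index(drop=True), list(table.provenance), dialect=table.dialect)
    out.log(
        f"apply_cohort_filters: {len(out)} visits, {out.n_patients} patients, "
        f"{out.n_professionals} professionals retained"
    )
    return out, report


def assign_primary_attributes(table: VisitTable) -> pd.DataFrame:
    """Assign each professional one municipality, occupation and service type.

    For each attribute independently, the value with the most visits wins;
    ties go to the value of the professional's chronologically first visit
    among the tied values, then lexicographically.  The service attribute
    is collapsed to the 3-level coding {outpatient, mental_health_
    substance_use, other} before counting.  Returns a DataFrame indexed by
    professional_id with columns municipality, occupation_group,
    service_group.
    """
    df = table.df
    if (df["professional_id"] == "").any() or (df["occupation_group"] == "").any():
        raise ConfigError(
            "assign_primary_attributes requires a filtered table without "
            "missing professional ids or occupation groups"
        )
    work = df.assign(service_3=df["service_group"].map(collapse_service_group))
    out = {}
    for col, attr in (
        ("municipality", "municipality"),
        ("occupation_group", "occupation_group"),
        ("service_3", "service_group"),
    ):
        g = (
            work.groupby(["professional_id", col])
            .agg(n=("visit_id", "count"), first_date=("date", "min"))
            .reset_index()
        )
        g = g.sort_values(
            ["professional_id", "n", "first_date", col],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        pick = g.drop_duplicates("professional_id").set_index("professional_id")[col]
        out[attr] = pick
    attrs = pd.DataFrame(out).sort_index()
    attrs.index.name = "professional_id"
    return attrs
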