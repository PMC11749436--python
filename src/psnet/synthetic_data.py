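"""Synthetic register generation and exact dyadic ERGM sampling.

The real register extract is not public, so two independent generators
provide test beds with known ground truth:

* :func:`simulate_register` — a mechanistic visit simulator producing a
  register-like table: seven municipalities of very unequal size, three
  occupation groups, three service-type groups, heavy-tailed visit counts
  per patient (zero-truncated negative binomial), a strong preference for
  care within the patient's home municipality, revisit persistence to
  previously seen professionals, and configurable fractions of rows that
  exercise every cohort-filter stage (minors, home care, uninformative
  service codes, missing professional ids, out-of-window dates).

* :func:`sample_ergm_network` — exact sampling from a dyad-independent
  ERGM: each dyad's tie is an independent Bernoulli draw with probability
  logistic(θᵀ·change statistics).  Used to test estimation in isolation;
  keeping the two generators separate prevents parameter-recovery checks
  from being circular.

All randomness flows through one ``numpy.random.Generator`` seeded from
the mandatory config seed, so outputs are fully reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ConfigError
from .ergm import TermSpec, build_design, dyad_covariates, fit_mple
from .registry_io import VisitTable

#: Register-like marginals: municipality codes with patient-count and
#: professional-count weights of very unequal size (one dominant centre).
DEFAULT_PATIENT_WEIGHTS = {
    "A": 576, "B": 1114, "C": 1241, "D": 570, "E": 253, "F": 6977, "G": 155,
}
DEFAULT_PROFESSIONAL_WEIGHTS = {
    "A": 103, "B": 220, "C": 180, "D": 66, "E": 40, "F": 1162, "G": 32,
}

OCCUPATION_GROUPS = ("physician", "nurse", "other")
SERVICE_GROUPS = ("outpatient", "mental_health_substance_use", "other")

#: Raw occupation titles per group (the title→group lookup is data).
_TITLES = {
    "physician": ("general_practitioner", "specialist", "dentist"),
    "nurse": ("registered_nurse", "public_health_nurse", "practical_nurse"),
    "other": ("physiotherapist", "psychologist", "social_worker"),
}
#: Register service codes per 3-level professional service group.
_SERVICE_CODES = {
    "outpatient": ("outpatient", "outpatient"),
    "mental_health_substance_use": ("mental_health_substance_use",),
    "other": ("other_services",),
}

_QUALIFYING_F = ("F32", "F41", "F10", "F43", "F60", "F90", "F84")
_EXCLUDED_F = ("F03", "F79", "F81")
_QUALIFYING_P = ("P01", "P02", "P74", "P76", "P29")
_SOMATIC_ICD = ("J06", "I10", "M54", "E11", "K21")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions.

    Scale mirrors the register extract after cohort selection: ~1566
    professionals, ~8500 patients, ~150 000 visits in one calendar year
    across 7 municipalities dominated by one large centre.
    """

    seed: int
    n_patients: int = 8500
    n_professionals: int = 1566
    patient_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PATIENT_WEIGHTS)
    )
    professional_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROFESSIONAL_WEIGHTS)
    )
    occupation_probs: tuple[float, float, float] = (0.258, 0.619, 0.123)
    service_probs: tuple[float, float, float] = (0.586, 0.053, 0.361)
    mean_visits: float = 16.0
    visit_dispersion: float = 0.8  # negative-binomial shape; smaller = heavier tail
    same_municipality_pref: float = 0.9
    revisit_persistence: float = 0.65
    mhsu_patient_fraction: float = 0.85
    mhsu_service_affinity: float = 0.12  # MH/SU patients steered to MH/SU services
    occupation_visit_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"physician": 1.6, "nurse": 1.0, "other": 0.75}
    )
    p_f_code: float = 0.35
    p_p_code: float = 0.15
    study_start: _dt.date = _dt.date(2021, 1, 1)
    study_days: int = 365
    # fractions of rows/patients exercising the cohort filters
    minor_patient_fraction: float = 0.02
    missing_professional_fraction: float = 0.01
    home_care_fraction: float = 0.01
    other_unspecified_fraction: float = 0.01
    occupational_health_fraction: float = 0.005
    out_of_window_fraction: float = 0.002
    cross_municipality_visit_prob: float = 0.03
    cross_service_visit_prob: float = 0.08

    def __post_init__(self):
        for name in (
            "same_municipality_pref", "revisit_persistence", "mhsu_patient_fraction",
            "mhsu_service_affinity", "p_f_code", "p_p_code",
            "minor_patient_fraction", "missing_professional_fraction",
            "home_care_fraction", "other_unspecified_fraction",
            "occupational_health_fraction", "out_of_window_fraction",
            "cross_municipality_visit_prob", "cross_service_visit_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.n_patients < 1 or self.n_professionals < 1:
            raise ConfigError("n_patients and n_professionals must be >= 1")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        active = [m for m, w in self.professional_weights.items() if w > 0]
        for m, w in self.patient_weights.items():
            if w > 0 and m not in active:
                raise ConfigError(
                    f"municipality {m!r} has patient weight but no professionals"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "study_start" in raw and isinstance(raw["study_start"], str):
            raw["study_start"] = _dt.date.fromisoformat(raw["study_start"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["patient_weights"] = dict(self.patient_weights)
        d["professional_weights"] = dict(self.professional_weights)
        return d


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually did, stored alongside every artefact."""

    config: dict
    professional_attrs: pd.DataFrame  # home municipality/occupation/service
    mhsu_patients: list[str]
    injected: dict  # counts of filter-exercising rows per category
    theta: Optional[dict] = None  # set by the dyadic sampler

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "professional_attrs": self.professional_attrs.to_dict(orient="index"),
            "mhsu_patients": self.mhsu_patients,
            "injected": self.injected,
            "theta": self.theta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        return path


def _allocate(total: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` items across categories."""
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ConfigError("weights must sum to a positive value")
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def _zt_negbinom(rng: np.random.Generator, n: int, mean: float, shape: float):
    """Zero-truncated negative binomial visit counts (resampled zeros)."""
    p = shape / (shape + mean)
    draws = rng.negative_binomial(shape, p, size=n)
    while (zero := draws == 0).any():
        draws[zero] = rng.negative_binomial(shape, p, size=int(zero.sum()))
    return draws


def simulate_register(cfg: SyntheticConfig) -> tuple[VisitTable, GroundTruth]:
    """Generate a seeded, reproducible register-like visit table."""
    rng = np.random.default_rng(cfg.seed)
    munis = sorted(m for m in cfg.professional_weights if cfg.professional_weights[m] > 0)

    # --- professionals ---------------------------------------------------
    alloc = _allocate(cfg.n_professionals, {m: cfg.professional_weights[m] for m in munis})
    prof_muni, prof_occ, prof_svc, prof_title = [], [], [], []
    for m in munis:
        for _ in range(alloc[m]):
            occ = OCCUPATION_GROUPS[rng.choice(3, p=np.array(cfg.occupation_probs))]
            svc = SERVICE_GROUPS[rng.choice(3, p=np.array(cfg.service_probs))]
            prof_muni.append(m)
            prof_occ.append(occ)
            prof_svc.append(svc)
            prof_title.append(_TITLES[occ][rng.integers(len(_TITLES[occ]))])
    n_prof = len(prof_muni)
    prof_ids = [f"H{i:05d}" for i in range(n_prof)]
    prof_attrs = pd.DataFrame(
        {
            "municipality": prof_muni,
            "occupation_group": prof_occ,
            "service_group": prof_svc,
        },
        index=pd.Index(prof_ids, name="professional_id"),
    )
    by_muni = {m: np.flatnonzero(np.array(prof_muni) == m) for m in munis}
    mhsu_by_muni = {
        m: np.array(
            [i for i in by_muni[m] if prof_svc[i] == "mental_health_substance_use"]
        )
        for m in munis
    }
    # physicians act as hubs: within-pool choice weighted by occupation
    occw = np.array(
        [cfg.occupation_visit_weights.get(o, 1.0) for o in prof_occ], dtype=float
    )

    def _pool_cum(pool: np.ndarray) -> np.ndarray:
        c = np.cumsum(occw[pool])
        return c / c[-1]

    cum_by_muni = {m: _pool_cum(by_muni[m]) for m in munis if len(by_muni[m])}
    cum_mhsu = {m: _pool_cum(mhsu_by_muni[m]) for m in munis if len(mhsu_by_muni[m])}
    muni_prof_weights = np.array([len(by_muni[m]) for m in munis], dtype=float)
    muni_prof_weights /= muni_prof_weights.sum()

    # --- patients ---------------------------------------------------------
    pat_ids = [f"P{i:05d}" for i in range(cfg.n_patients)]
    pat_w = np.array([cfg.patient_weights.get(m, 0.0) for m in munis], dtype=float)
    pat_w /= pat_w.sum()
    pat_muni = rng.choice(len(munis), size=cfg.n_patients, p=pat_w)
    minors = rng.random(cfg.n_patients) < cfg.minor_patient_fraction
    ages = 18 + np.minimum(np.floor(rng.gamma(2.0, 16.0, cfg.n_patients)), 80).astype(int)
    ages[minors] = rng.integers(8, 18, int(minors.sum()))
    is_mhsu = rng.random(cfg.n_patients) < cfg.mhsu_patient_fraction
    n_visits = _zt_negbinom(rng, cfg.n_patients, cfg.mean_visits, cfg.visit_dispersion)

    # --- visits -----------------------------------------------------------
    cols: dict[str, list] = {k: [] for k in (
        "visit_id", "patient_id", "professional_id", "date", "municipality",
        "occupation_title", "occupation_group", "service_type", "service_group",
        "icd10_codes", "icpc2_codes", "home_care", "patient_age_years",
    )}
    injected = {
        "minor_patients": int(minors.sum()),
        "missing_professional": 0,
        "home_care": 0,
        "other_unspecified": 0,
        "occupational_health": 0,
        "out_of_window": 0,
    }
    vid = 0
    start = pd.Timestamp(cfg.study_start)
    for pi in range(cfg.n_patients):
        nv = int(n_visits[pi])
        home = int(pat_muni[pi])
        visited: list[int] = []
        u = rng.random((nv, 4))
        day_offsets = np.sort(rng.integers(0, cfg.study_days, nv))
        qualified = False
        first_row = vid
        for v in range(nv):
            # professional choice: persistence, then municipality preference
            if visited and u[v, 0] < cfg.revisit_persistence:
                prof = visited[rng.integers(len(visited))]
            else:
                if u[v, 1] < cfg.same_municipality_pref:
                    mi = home
                else:
                    mi = int(rng.choice(len(munis), p=muni_prof_weights))
                mkey = munis[mi]
                if (
                    is_mhsu[pi]
                    and u[v, 2] < cfg.mhsu_service_affinity
                    and mkey in cum_mhsu
                ):
                    pool, cum = mhsu_by_muni[mkey], cum_mhsu[mkey]
                else:
                    pool, cum = by_muni[mkey], cum_by_muni[mkey]
                prof = int(pool[np.searchsorted(cum, rng.random())])
            if prof not in visited:
                visited.append(prof)

            date = start + pd.Timedelta(days=int(day_offsets[v]))
            muni = prof_muni[prof]
            if rng.random() < cfg.cross_municipality_visit_prob:
                muni = munis[home]
            svc3 = prof_svc[prof]
            if rng.random() < cfg.cross_service_visit_prob:
                svc3 = SERVICE_GROUPS[rng.choice(3, p=np.array(cfg.service_probs))]
            svc_codes = _SERVICE_CODES[svc3]
            service_group = svc_codes[rng.integers(len(svc_codes))]

            icd, icpc = [], []
            if is_mhsu[pi]:
                if u[v, 3] < cfg.p_f_code:
                    icd.append(_QUALIFYING_F[rng.integers(len(_QUALIFYING_F))])
                elif u[v, 3] < cfg.p_f_code + cfg.p_p_code:
                    icpc.append(_QUALIFYING_P[rng.integers(len(_QUALIFYING_P))])
                if icd or icpc or service_group == "mental_health_substance_use":
                    qualified = True
            else:
                r = rng.random()
                if r < 0.4:
                    icd.append(_SOMATIC_ICD[rng.integers(len(_SOMATIC_ICD))])
                elif r < 0.43:
                    icd.append(_EXCLUDED_F[rng.integers(len(_EXCLUDED_F))])

            cols["visit_id"].append(f"V{vid:07d}")
            cols["patient_id"].append(pat_ids[pi])
            cols["professional_id"].append(prof_ids[prof])
            cols["date"].append(date)
            cols["municipality"].append(muni)
            cols["occupation_title"].append(prof_title[prof])
            cols["occupation_group"].append(prof_occ[prof])
            cols["service_type"].append(service_group)
            cols["service_group"].append(service_group)
            cols["icd10_codes"].append(";".join(icd))
            cols["icpc2_codes"].append(";".join(icpc))
            cols["home_care"].append(False)
            cols["patient_age_years"].append(int(ages[pi]))
            vid += 1
        if is_mhsu[pi] and not qualified:
            cols["icd10_codes"][first_row] = _QUALIFYING_F[
                rng.integers(len(_QUALIFYING_F))
            ]

    df = pd.DataFrame(cols)
    df["date"] = pd.to_datetime(df["date"])

    # --- filter-exercising injections ------------------------------------
    n = len(df)
    def _mask(frac):
        return rng.random(n) < frac

    miss = _mask(cfg.missing_professional_fraction)
    df.loc[miss, "professional_id"] = ""
    df.loc[miss, "occupation_group"] = ""
    injected["missing_professional"] = int(miss.sum())

    hc = _mask(cfg.home_care_fraction) & ~miss
    df.loc[hc, "home_care"] = True
    injected["home_care"] = int(hc.sum())

    other = _mask(cfg.other_unspecified_fraction) & ~miss & ~hc
    df.loc[other, "service_group"] = "other_unspecified"
    injected["other_unspecified"] = int(other.sum())

    occh = _mask(cfg.occupational_health_fraction) & ~miss & ~hc & ~other
    df.loc[occh, "service_group"] = "occupational_health"
    injected["occupational_health"] = int(occh.sum())

    oow = _mask(cfg.out_of_window_fraction)
    df.loc[oow, "date"] = start - pd.Timedelta(days=30)
    injected["out_of_window"] = int(oow.sum())

    table = VisitTable(df)
    table.log(
        f"simulate_register(seed={cfg.seed}): {len(table)} visits, "
        f"{table.n_patients} patients, {table.n_professionals} professionals"
    )
    truth = GroundTruth(
        config=cfg.to_dict(),
        professional_attrs=prof_attrs,
        mhsu_patients=[pat_ids[i] for i in np.flatnonzero(is_mhsu)],
        injected=injected,
    )
    return table, truth


def sample_ergm_network(
    attrs: pd.DataFrame,
    theta: Sequence[float],
    terms: Sequence[TermSpec],
    seed: int,
) -> nx.Graph:
    """Draw one network exactly from a dyad-independent ERGM.

    Each dyad's tie is an independent Bernoulli with probability
    logistic(θᵀ·change statistics); -inf coefficients are honoured as
    hard zeros.
    """
    nodes = sorted(attrs.index)
    attr_map = {n: attrs.loc[n].to_dict() for n in nodes}
    X, labels, iu, ju = dyad_covariates(nodes, attr_map, terms)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(labels),):
        raise ConfigError(
            f"theta has {theta.shape[0] if theta.ndim else 0} entries but the "
            f"terms expand to {len(labels)} columns: {labels}"
        )
    with np.errstate(invalid="ignore"):
        eta = X @ theta
    p = expit(eta)
    p = np.where(np.isnan(p), 0.0, p)
    rng = np.random.default_rng(seed)
    draw = rng.random(p.size) < p
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, **attr_map[n])
    for i, j in zip(iu[draw], ju[draw]):
        g.add_edge(nodes[i], nodes[j], shared_patients=1)
    return g


def recovery_experiment(
    attrs: pd.DataFrame,
    theta_true: Sequence[float],
    terms: Sequence[TermSpec],
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Repeated sample-and-refit: per-term bias, RMSE and 95%-CI coverage.

    Returns a DataFrame indexed by term with columns true, mean_estimate,
    bias, rmse, coverage, n_ok, n_failed; ``low_precision`` flags runs
    with fewer than 30 successful replicates.
    """
    if replicates < 2:
        raise ConfigError("replicates must be >= 2")
    theta_true = np.asarray(theta_true, dtype=float)
    rng = np.random.default_rng(seed)
    estimates, covered = [], []
    n_failed = 0
    labels = None
    for _ in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        g = sample_ergm_network(attrs, theta_true, terms, rep_seed)
        try:
            fit = fit_mple(build_design(g, terms))
        except Exception:
            n_failed += 1
            continue
        labels = fit.labels
        estimates.append(fit.theta)
        covered.append(
            (fit.theta - 1.96 * fit.se <= theta_true)
            & (theta_true <= fit.theta + 1.96 * fit.se)
        )
    if not estimates:
        raise ConfigError("every replicate failed to fit")
    est = np.vstack(estimates)
    cov = np.vstack(covered)
    out = pd.DataFrame(
        {
            "true": theta_true,
            "mean_estimate": est.mean(axis=0),
            "bias": est.mean(axis=0) - theta_true,
            "rmse": np.sqrt(((est - theta_true) ** 2).mean(axis=0)),
            "coverage": cov.mean(axis=0),
            "n_ok": len(estimates),
            "n_failed": n_failed,
        },
        index=pd.Index(labels, name="term"),
    )
    out.attrs["low_precision"] = len(estimates) < 30
    return out
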