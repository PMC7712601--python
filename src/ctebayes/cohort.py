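"""Cohort data model: tabular I/O, KNN imputation, dichotomization, stratification.

The analysis operates on patient-level records with nine baseline covariates,
two binary treatment indicators (``rt``, ``chemo``), a follow-up time in
months and a death/censoring flag.  Each fully observed record maps to a
9-bit covariate vector whose packed integer (the *subgroup key*, 0-511)
indexes one of the 512 exhaustive strata.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CovariateVector",
    "CohortSchemaError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "cohort_to_dataframe",
    "impute_missing",
    "dichotomize",
    "subgroup_key",
    "key_to_vector",
    "stratify",
    "BIT_NAMES",
    "N_BITS",
    "N_SUBGROUPS",
    "REQUIRED_COLUMNS",
]

SEX_LEVELS = ("male", "female")
SITE_LEVELS = ("extremity", "axial")
HISTOLOGY_LEVELS = ("spindle", "biphasic", "NOS")
STAGE_LEVELS = (1, 2, 3)
TREATMENTS = ("rt", "chemo")

#: Fixed bit order of the covariate vector; bit i contributes 2**i to the key.
BIT_NAMES = (
    "age_over_20",
    "male",
    "size_over_5cm",
    "extremity",
    "stage_advanced",
    "surgery",
    "co_treatment",
    "spindle",
    "biphasic",
)
N_BITS = 9
N_SUBGROUPS = 2 ** N_BITS

REQUIRED_COLUMNS = (
    "id", "age", "sex", "size_cm", "site", "seer_stage", "surgery",
    "rt", "chemo", "histology", "time_months", "event",
)

#: Covariate fields that may be missing and are eligible for imputation.
IMPUTABLE_FIELDS = (
    "age", "sex", "tumor_size_cm", "site", "seer_stage", "surgery", "histology",
)


class CohortSchemaError(ValueError):
    """A required column is absent from the input table."""


class CohortParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""


class CovariateVector(NamedTuple):
    """Nine binary stratification covariates in the documented bit order."""

    age_over_20: int
    male: int
    size_over_5cm: int
    extremity: int
    stage_advanced: int
    surgery: int
    co_treatment: int
    spindle: int
    biphasic: int

    def validate(self) -> "CovariateVector":
        if any(b not in (0, 1) for b in self):
            raise ValueError(f"covariate bits must be 0/1, got {tuple(self)}")
        if self.spindle and self.biphasic:
            raise ValueError("spindle and biphasic histology are mutually exclusive")
        return self


@dataclass
class PatientRecord:
    """One subject: baseline covariates, treatments, follow-up and outcome.

    Covariate fields may be ``None`` (missing) prior to imputation; treatments
    and outcomes are never missing in a constructed record.
    """

    id: str
    age: Optional[float]
    sex: Optional[str]
    tumor_size_cm: Optional[float]
    site: Optional[str]
    seer_stage: Optional[int]
    surgery: Optional[int]
    rt: int
    chemo: int
    histology: Optional[str]
    time_months: float
    event: int

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError(f"record {self.id}: negative time_months")
        if self.event not in (0, 1):
            raise ValueError(f"record {self.id}: event must be 0/1")
        for t in TREATMENTS:
            if getattr(self, t) not in (0, 1):
                raise ValueError(f"record {self.id}: treatment {t} must be 0/1")
        if self.sex is not None and self.sex not in SEX_LEVELS:
            raise ValueError(f"record {self.id}: bad sex {self.sex!r}")
        if self.site is not None and self.site not in SITE_LEVELS:
            raise ValueError(f"record {self.id}: bad site {self.site!r}")
        if self.histology is not None and self.histology not in HISTOLOGY_LEVELS:
            raise ValueError(f"record {self.id}: bad histology {self.histology!r}")
        if self.seer_stage is not None and self.seer_stage not in STAGE_LEVELS:
            raise ValueError(f"record {self.id}: bad seer_stage {self.seer_stage!r}")

    def is_complete(self) -> bool:
        return all(getattr(self, f) is not None for f in IMPUTABLE_FIELDS)


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: List[PatientRecord]
    provenance: str = ""
    exclusions: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must be non-empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = Counter(ids).most_common(1)[0][0]
            raise ValueError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def exclusion_report(self) -> str:
        return json.dumps(self.exclusions, sort_keys=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "na", "nan", "none", "null"}


def _parse_cell(raw) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    return None if s.lower() in _MISSING_TOKENS else s


def _parse_float(s: Optional[str], row: int, col: str) -> Optional[float]:
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        raise CohortParseError(f"row {row}: cannot parse {col}={s!r} as a number") from None


def _parse_int(s: Optional[str], row: int, col: str) -> Optional[int]:
    v = _parse_float(s, row, col)
    if v is None:
        return None
    if v != int(v):
        raise CohortParseError(f"row {row}: {col}={s!r} is not an integer")
    return int(v)


def read_cohort(path, provenance: Optional[str] = None) -> Cohort:
    """Read a delimited cohort table (comma or tab, auto-detected).

    Rows with a missing treatment indicator or missing outcome are dropped and
    tallied in the returned cohort's ``exclusions`` mapping.

    Raises
    ------
    CohortSchemaError
        If a required column is absent.
    CohortParseError
        If a numeric cell cannot be parsed (message carries the row index).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CohortSchemaError(f"missing required column {col!r}")

    records: List[PatientRecord] = []
    exclusions: Counter = Counter()
    for i, row in enumerate(df.itertuples(index=False)):
        get = lambda col: _parse_cell(getattr(row, col))
        rt = _parse_int(get("rt"), i, "rt")
        chemo = _parse_int(get("chemo"), i, "chemo")
        if rt is None or chemo is None:
            exclusions["missing_treatment"] += 1
            continue
        time_months = _parse_float(get("time_months"), i, "time_months")
        event = _parse_int(get("event"), i, "event")
        if time_months is None or event is None:
            exclusions["missing_outcome"] += 1
            continue
        sex = get("sex")
        site = get("site")
        histology = get("histology")
        records.append(
            PatientRecord(
                id=get("id") or f"row{i}",
                age=_parse_float(get("age"), i, "age"),
                sex=sex.lower() if sex else None,
                tumor_size_cm=_parse_float(get("size_cm"), i, "size_cm"),
                site=site.lower() if site else None,
                seer_stage=_parse_int(get("seer_stage"), i, "seer_stage"),
                surgery=_parse_int(get("surgery"), i, "surgery"),
                rt=rt,
                chemo=chemo,
                histology=histology if histology is None else
                ("NOS" if histology.upper() == "NOS" else histology.lower()),
                time_months=time_months,
                event=event,
            )
        )
    if not records:
        raise ValueError(f"no usable records in {path}")
    return Cohort(records, provenance=provenance or str(path), exclusions=dict(exclusions))


def cohort_to_dataframe(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for r in cohort:
        rows.append({
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "size_cm": r.tumor_size_cm,
            "site": r.site,
            "seer_stage": r.seer_stage,
            "surgery": r.surgery,
            "rt": r.rt,
            "chemo": r.chemo,
            "histology": r.histology,
            "time_months": r.time_months,
            "event": r.event,
        })
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as CSV in the canonical column schema."""
    cohort_to_dataframe(cohort).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

_NUMERIC_FIELDS = ("age", "tumor_size_cm")
_CATEGORICAL_FIELDS = {
    "sex": SEX_LEVELS,
    "site": SITE_LEVELS,
    "seer_stage": STAGE_LEVELS,
    "surgery": (0, 1),
    "histology": HISTOLOGY_LEVELS,
}


def _feature_matrix(records: Sequence[PatientRecord]) -> np.ndarray:
    """Standardized-numeric + one-hot design matrix with NaN for missing."""
    n = len(records)
    cols: List[np.ndarray] = []
    for f in _NUMERIC_FIELDS:
        v = np.array([np.nan if getattr(r, f) is None else getattr(r, f) for r in records])
        obs = v[~np.isnan(v)]
        mu = obs.mean() if obs.size else 0.0
        sd = obs.std() if obs.size else 1.0
        cols.append((v - mu) / (sd if sd > 0 else 1.0))
    for f, levels in _CATEGORICAL_FIELDS.items():
        vals = [getattr(r, f) for r in records]
        for lev in levels:
            col = np.full(n, np.nan)
            for i, v in enumerate(vals):
                if v is not None:
                    col[i] = 1.0 if v == lev else 0.0
            cols.append(col)
    return np.column_stack(cols)


def _nan_distances(X: np.ndarray, i: int) -> np.ndarray:
    """NaN-aware Euclidean distance from row i to every row (inf if no overlap)."""
    diff = X - X[i]
    mask = ~np.isnan(diff)
    sq = np.where(mask, diff ** 2, 0.0)
    n_obs = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(sq.sum(axis=1) * X.shape[1] / n_obs)
    d[n_obs == 0] = np.inf
    return d


def impute_missing(cohort: Cohort, k: int = 5, seed: int = 0) -> Cohort:
    """Fill missing covariates by K-nearest-neighbour vote/average.

    Distances are NaN-aware Euclidean over standardized numeric covariates and
    one-hot categoricals.  Numeric fields take the mean of the k nearest
    donors; categorical fields the majority vote (ties broken by donor
    proximity, then record order).  Treatments and outcomes are never touched.
    The procedure is fully deterministic; ``seed`` is accepted for interface
    stability only.

    Raises
    ------
    ValueError
        If a field is missing in every record, or fewer than k donors exist.
    """
    del seed  # deterministic: ties broken by record order
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(r.is_complete() for r in cohort):
        return cohort

    records = list(cohort.records)
    X = _feature_matrix(records)
    out: List[PatientRecord] = []
    donors_cache: Dict[str, List[int]] = {}
    for f in IMPUTABLE_FIELDS:
        donors = [j for j, r in enumerate(records) if getattr(r, f) is not None]
        if not donors:
            raise ValueError(f"field {f!r} is missing in every record")
        if len(donors) < k:
            raise ValueError(f"fewer than k={k} records observe field {f!r}")
        donors_cache[f] = donors

    for i, r in enumerate(records):
        missing = [f for f in IMPUTABLE_FIELDS if getattr(r, f) is None]
        if not missing:
            out.append(r)
            continue
        d = _nan_distances(X, i)
        updates = {}
        for f in missing:
            donors = donors_cache[f]
            order = sorted(donors, key=lambda j: (d[j], j))
            nearest = order[:k]
            if f in _NUMERIC_FIELDS:
                updates[f] = float(np.mean([getattr(records[j], f) for j in nearest]))
            else:
                votes = Counter(getattr(records[j], f) for j in nearest)
                top = max(votes.values())
                tied = {v for v, c in votes.items() if c == top}
                updates[f] = next(getattr(records[j], f) for j in nearest
                                  if getattr(records[j], f) in tied)
        out.append(replace(r, **updates))
    return Cohort(out, provenance=cohort.provenance, exclusions=dict(cohort.exclusions))


# ---------------------------------------------------------------------------
# Dichotomization and stratification
# ---------------------------------------------------------------------------

def dichotomize(record: PatientRecord, treatment_of_interest: str) -> CovariateVector:
    """Map a fully imputed record to its 9-bit covariate vector.

    Cutoffs are strict: age bit requires age > 20 years, size bit requires
    longest diameter > 5 cm.  The stage bit marks distant disease (stage 3).
    The analyzed treatment is excluded from the vector; the *other* treatment
    enters as the co-treatment bit.
    """
    if treatment_of_interest not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}")
    if not record.is_complete():
        missing = [f for f in IMPUTABLE_FIELDS if getattr(record, f) is None]
        raise ValueError(
            f"record {record.id} has missing fields {missing}; impute first")
    co = record.chemo if treatment_of_interest == "rt" else record.rt
    return CovariateVector(
        age_over_20=int(record.age > 20),
        male=int(record.sex == "male"),
        size_over_5cm=int(record.tumor_size_cm > 5),
        extremity=int(record.site == "extremity"),
        stage_advanced=int(record.seer_stage == 3),
        surgery=int(record.surgery),
        co_treatment=int(co),
        spindle=int(record.histology == "spindle"),
        biphasic=int(record.histology == "biphasic"),
    ).validate()


def subgroup_key(vector: CovariateVector) -> int:
    """Pack a 9-bit covariate vector into its integer subgroup key."""
    if len(vector) != N_BITS:
        raise ValueError("covariate vector must have exactly 9 entries")
    return int(sum(int(b) << i for i, b in enumerate(vector)))


def key_to_vector(key: int) -> CovariateVector:
    """Inverse of :func:`subgroup_key`."""
    if not 0 <= key < N_SUBGROUPS:
        raise ValueError(f"subgroup key must be in [0, {N_SUBGROUPS - 1}]")
    return CovariateVector(*(int(key >> i & 1) for i in range(N_BITS)))


def describe_key(key: int) -> str:
    """Human-readable covariate profile for a subgroup key."""
    vec = key_to_vector(key)
    return ";".join(f"{name}={bit}" for name, bit in zip(BIT_NAMES, vec))


def stratify(
    cohort: Cohort, treatment: str
) -> Dict[int, Tuple[List[PatientRecord], List[PatientRecord]]]:
    """Partition a fully imputed cohort into (treated, untreated) lists per key.

    Every record lands in exactly one cell; empty cells are absent.
    """
    cells: Dict[int, Tuple[List[PatientRecord], List[PatientRecord]]] = {}
    for r in cohort:
        key = subgroup_key(dichotomize(r, treatment))
        treated, untreated = cells.setdefault(key, ([], []))
        (treated if getattr(r, treatment) == 1 else untreated).append(r)
    return cells
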