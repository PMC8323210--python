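"""Patient data model, cohort I/O, lab binarization, CART imputation, and the
numeric (Euclidean) patient representation.

A cohort is a plain ``list[Patient]``.  One :class:`Patient` corresponds to one
de-identified hospitalization: four demographic fields, a set of normalized
ICD-10 comorbidity codes, a dict of laboratory results (continuous or already
binarized to 0 normal / 1 abnormal), and a set of phrase tokens extracted from
the radiology report.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = [
    "Patient",
    "NormalRange",
    "CartLabImputer",
    "DEFAULT_OUTCOME_CODES",
    "normalize_icd",
    "read_cohort",
    "write_cohort",
    "binarize_labs",
    "impute_missing",
    "exclude_outcome_codes",
    "select_popular_comorbidities",
    "assemble_numeric",
    "lab_names",
]

_ICD_PATTERN = re.compile(r"^[A-Z]\d{1,3}$")

#: ICD-10 codes (normalized; matched as prefixes) that define the four liver
#: outcomes and are therefore stripped from comorbidity features before any
#: similarity or numeric assembly: liver cancer (C22*, C787), hemangioma
#: (D180), NAFLD (K760).
DEFAULT_OUTCOME_CODES = ("C22", "C787", "D180", "K760")


@dataclass
class Patient:
    """One de-identified hospitalization record."""

    id: str
    age: float
    sex: int
    drug_allergy: int
    admission_source: int  # 1 = outpatient admission, 0 = other
    comorbidities: set = field(default_factory=set)
    labs: dict = field(default_factory=dict)
    report_tokens: set = field(default_factory=set)

    def validate(self) -> None:
        if not self.id:
            raise ValueError("patient id must be a non-empty string")
        if not (self.age >= 0):
            raise ValueError(f"patient {self.id}: age must be >= 0, got {self.age}")
        for name in ("sex", "drug_allergy", "admission_source"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"patient {self.id}: {name} must be 0 or 1")
        for code in self.comorbidities:
            if not _ICD_PATTERN.match(code):
                raise ValueError(
                    f"patient {self.id}: comorbidity {code!r} is not a normalized "
                    "ICD-10 code (letter + 1-3 digits)"
                )


@dataclass(frozen=True)
class NormalRange:
    """Closed normal interval [low, high] for one laboratory test."""

    test: str
    low: float
    high: float

    def __post_init__(self):
        if not (self.low <= self.high):
            raise ValueError(f"{self.test}: low ({self.low}) > high ({self.high})")


def normalize_icd(code: str) -> str:
    """Normalize an ICD-10 code to its leading letter plus up to three digits.

    The dot is removed, the code upper-cased, and anything past the first four
    characters truncated: ``"C78.7" -> "C787"``, ``"K76.0" -> "K760"``.
    Idempotent on already-normalized codes.
    """
    if not isinstance(code, str) or not code:
        raise ValueError("ICD-10 code must be a non-empty string")
    c = code.strip().upper()
    if not c or not c[0].isalpha():
        raise ValueError(f"ICD-10 code must begin with a letter: {code!r}")
    c = c.replace(".", "")
    c = c[:4]
    if not _ICD_PATTERN.match(c):
        raise ValueError(f"cannot normalize ICD-10 code {code!r}")
    return c


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def lab_names(cohort) -> list:
    """Sorted union of laboratory test names over the cohort."""
    names = set()
    for p in cohort:
        names.update(p.labs)
    return sorted(names)


# ---------------------------------------------------------------------------
# I/O


_REQUIRED_FIELDS = ("id", "age", "sex", "drug_allergy", "admission_source",
                    "comorbidities", "labs", "report_tokens")


def _patient_to_record(p: Patient) -> dict:
    return {
        "id": p.id,
        "age": p.age,
        "sex": p.sex,
        "drug_allergy": p.drug_allergy,
        "admission_source": p.admission_source,
        "comorbidities": sorted(p.comorbidities),
        "labs": {k: (None if _is_missing(v) else v) for k, v in sorted(p.labs.items())},
        "report_tokens": sorted(p.report_tokens),
    }


def _record_to_patient(rec: dict, where: str) -> Patient:
    for f in _REQUIRED_FIELDS:
        if f not in rec:
            raise ValueError(f"{where}: missing field {f!r}")
    labs = {k: (math.nan if v is None else float(v)) for k, v in rec["labs"].items()}
    p = Patient(
        id=str(rec["id"]),
        age=float(rec["age"]),
        sex=int(rec["sex"]),
        drug_allergy=int(rec["drug_allergy"]),
        admission_source=int(rec["admission_source"]),
        comorbidities=set(rec["comorbidities"]),
        labs=labs,
        report_tokens=set(rec["report_tokens"]),
    )
    p.validate()
    return p


def write_cohort(cohort, path, format: str = "jsonl") -> None:
    """Write a cohort to ``path`` as JSON-lines (one patient per line) or CSV."""
    if format == "jsonl":
        with open(path, "w") as fh:
            for p in cohort:
                fh.write(json.dumps(_patient_to_record(p), sort_keys=True) + "\n")
    elif format == "csv":
        names = lab_names(cohort)
        rows = []
        for p in cohort:
            row = {
                "id": p.id, "age": p.age, "sex": p.sex,
                "drug_allergy": p.drug_allergy,
                "admission_source": p.admission_source,
                "comorbidities": "|".join(sorted(p.comorbidities)),
                "report_tokens": "|".join(sorted(p.report_tokens)),
            }
            for name in names:
                row[f"lab:{name}"] = p.labs.get(name, math.nan)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown cohort format {format!r}")


def read_cohort(path, format: str = "jsonl"):
    """Read a cohort written by :func:`write_cohort`.

    Raises a ``ValueError`` naming the offending line for malformed records and
    for duplicate patient ids.
    """
    if format == "jsonl":
        cohort = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: malformed JSON record: {exc}") from exc
                cohort.append(_record_to_patient(rec, where=f"line {lineno}"))
    elif format == "csv":
        df = pd.read_csv(path)
        lab_cols = [c for c in df.columns if c.startswith("lab:")]
        cohort = []
        for i, row in df.iterrows():
            rec = {
                "id": row["id"], "age": row["age"], "sex": row["sex"],
                "drug_allergy": row["drug_allergy"],
                "admission_source": row["admission_source"],
                "comorbidities": [c for c in str(row["comorbidities"]).split("|")
                                  if c and c != "nan"]
                                 if not pd.isna(row["comorbidities"]) else [],
                "labs": {c[4:]: (None if pd.isna(row[c]) else row[c]) for c in lab_cols},
                "report_tokens": [t for t in str(row["report_tokens"]).split("|")
                                  if t and t != "nan"]
                                 if not pd.isna(row["report_tokens"]) else [],
            }
            cohort.append(_record_to_patient(rec, where=f"row {i}"))
    else:
        raise ValueError(f"unknown cohort format {format!r}")

    ids = [p.id for p in cohort]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dup}")
    return cohort


# ---------------------------------------------------------------------------
# Laboratory tests: binarization and CART imputation


def binarize_labs(cohort, ranges):
    """Binarize laboratory values against their normal ranges.

    A value inside the closed interval [low, high] maps to 0 (normal), outside
    to 1 (abnormal).  Tests without a supplied range must already be binary and
    pass through unchanged.  Missing values are an error: impute first.
    """
    rng_map = {}
    for r in ranges:
        rng_map[r.test] = r
    out = []
    for p in cohort:
        labs = {}
        for name, value in p.labs.items():
            if _is_missing(value):
                raise ValueError(
                    f"patient {p.id}: lab {name!r} is missing; run impute_missing "
                    "before binarize_labs"
                )
            if name in rng_map:
                r = rng_map[name]
                labs[name] = 0 if r.low <= value <= r.high else 1
            elif value in (0, 1, 0.0, 1.0):
                labs[name] = int(value)
            else:
                raise ValueError(
                    f"patient {p.id}: lab {name!r} has value {value} but no "
                    "normal range was supplied"
                )
        out.append(replace(p, comorbidities=set(p.comorbidities), labs=labs,
                           report_tokens=set(p.report_tokens)))
    return out


class CartLabImputer:
    """Per-feature decision-tree imputer for laboratory values.

    For each lab feature with missing entries a single CART-family tree
    (classification for binary features, regression otherwise) is fitted on the
    complete cases, using every other lab feature plus the four demographics as
    predictors, and used to predict the missing entries.  Splits use the
    default Gini / squared-error criteria with ``min_samples_leaf`` of 5 and a
    fixed random state, so imputation is deterministic given cohort order.
    """

    def __init__(self, min_samples_leaf: int = 5, random_state: int = 0):
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit_transform(self, frame: pd.DataFrame, predictors: pd.DataFrame) -> pd.DataFrame:
        """Impute missing entries of ``frame`` (labs); ``predictors`` holds the
        extra always-complete columns (demographics)."""
        filled = frame.copy()
        full = pd.concat([frame, predictors], axis=1)
        self.trees_ = {}
        for col in frame.columns:
            mask = frame[col].isna()
            if not mask.any():
                continue
            complete = ~mask
            if not complete.any():
                raise ValueError(f"lab feature {col!r} is missing in all patients; cannot impute")
            X = full.drop(columns=[col])
            y = frame.loc[complete, col]
            binary = set(np.unique(y)) <= {0.0, 1.0}
            cls = DecisionTreeClassifier if binary else DecisionTreeRegressor
            tree = cls(min_samples_leaf=self.min_samples_leaf,
                       random_state=self.random_state)
            tree.fit(X.loc[complete].to_numpy(), y.to_numpy())
            pred = tree.predict(X.loc[mask].to_numpy())
            filled.loc[mask, col] = pred
            self.trees_[col] = tree
        return filled


def impute_missing(cohort, min_samples_leaf: int = 5, random_state: int = 0):
    """Return a cohort with every missing lab value imputed by a CART tree.

    Features are imputed independently, each from the original (pre-imputation)
    values of the other features, so the result does not depend on the order in
    which features are processed.
    """
    names = lab_names(cohort)
    if not names:
        return [replace(p, comorbidities=set(p.comorbidities), labs=dict(p.labs),
                        report_tokens=set(p.report_tokens)) for p in cohort]
    frame = pd.DataFrame(
        [[p.labs.get(n, math.nan) for n in names] for p in cohort],
        columns=names, dtype=float,
    )
    if not frame.isna().any().any():
        return [replace(p, comorbidities=set(p.comorbidities), labs=dict(p.labs),
                        report_tokens=set(p.report_tokens)) for p in cohort]
    demo = pd.DataFrame(
        [[p.age, p.sex, p.drug_allergy, p.admission_source] for p in cohort],
        columns=["age", "sex", "drug_allergy", "admission_source"], dtype=float,
    )
    filled = CartLabImputer(min_samples_leaf, random_state).fit_transform(frame, demo)
    out = []
    for i, p in enumerate(cohort):
        labs = {n: float(filled.iloc[i][n]) for n in names}
        out.append(replace(p, comorbidities=set(p.comorbidities), labs=labs,
                           report_tokens=set(p.report_tokens)))
    return out


# ---------------------------------------------------------------------------
# Comorbidity features


def exclude_outcome_codes(cohort, outcome_codes=DEFAULT_OUTCOME_CODES):
    """Strip the target-disease ICD-10 codes from every comorbidity list.

    A comorbidity is dropped when it equals an outcome code or extends one
    (e.g. ``C220`` is dropped for outcome code ``C22``).  Applied before any
    similarity computation or numeric assembly so the features cannot leak the
    prediction target.
    """
    oc = tuple(normalize_icd(c) for c in outcome_codes)
    out = []
    for p in cohort:
        keep = {c for c in p.comorbidities if not any(c == o or c.startswith(o) for o in oc)}
        out.append(replace(p, comorbidities=keep, labs=dict(p.labs),
                           report_tokens=set(p.report_tokens)))
    return out


def select_popular_comorbidities(cohort, threshold: float = 0.05):
    """Codes whose patient-level occurrence fraction is strictly greater than
    ``threshold``, sorted by descending frequency then lexicographically."""
    if not cohort:
        raise ValueError("empty cohort")
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    n = len(cohort)
    counts: dict = {}
    for p in cohort:
        for c in p.comorbidities:
            counts[c] = counts.get(c, 0) + 1
    kept = [c for c, k in counts.items() if k / n > threshold]
    return sorted(kept, key=lambda c: (-counts[c], c))


# ---------------------------------------------------------------------------
# Numeric (Euclidean) representation


def assemble_numeric(cohort, popular_comorbidities, text_schema):
    """Assemble the flat numeric patient representation used by the
    Euclidean-distance models.

    Column order is [text binaries | lab binaries | comorbidity binaries |
    age, sex, drug_allergy, admission_source]; with the default widths
    (44 text, 57 labs, 26 popular comorbidities, 4 demographics) the vector has
    131 features.  Age is min-max scaled to [0, 1] over the cohort so a single
    continuous column does not dominate Euclidean distances.

    Returns ``(frame, groups)``: a DataFrame indexed by patient id and a dict
    mapping group name -> list of its column names.
    """
    if not cohort:
        raise ValueError("empty cohort")
    universe = set()
    for p in cohort:
        universe.update(p.comorbidities)
    for code in popular_comorbidities:
        if not _ICD_PATTERN.match(code):
            raise ValueError(f"popular comorbidity {code!r} is not a normalized ICD-10 code")
        if code not in universe:
            raise ValueError(f"popular comorbidity {code!r} does not occur in the cohort")

    from .text import structure_reports  # local import to avoid a cycle

    indep, sets = structure_reports(cohort, text_schema)
    labs = lab_names(cohort)
    text_cols = [f"text:{t}" for t in text_schema.independent] + \
                [f"text:{t}" for t in text_schema.set_features]
    lab_cols = [f"lab:{n}" for n in labs]
    com_cols = [f"icd:{c}" for c in popular_comorbidities]
    demo_cols = ["age", "sex", "drug_allergy", "admission_source"]

    ages = np.array([p.age for p in cohort], dtype=float)
    lo, hi = ages.min(), ages.max()
    scaled = (ages - lo) / (hi - lo) if hi > lo else np.zeros_like(ages)

    rows = []
    for i, p in enumerate(cohort):
        for n in labs:
            v = p.labs.get(n, None)
            if _is_missing(v):
                raise ValueError(f"patient {p.id}: lab {n!r} missing; impute and binarize first")
            if v not in (0, 1):
                raise ValueError(f"patient {p.id}: lab {n!r} = {v} is not binarized")
        row = list(indep[i].astype(float))
        row += [1.0 if t in sets[i] else 0.0 for t in text_schema.set_features]
        row += [float(p.labs.get(n, 0)) for n in labs]
        row += [1.0 if c in p.comorbidities else 0.0 for c in popular_comorbidities]
        row += [scaled[i], float(p.sex), float(p.drug_allergy), float(p.admission_source)]
        rows.append(row)

    frame = pd.DataFrame(rows, index=[p.id for p in cohort],
                         columns=text_cols + lab_cols + com_cols + demo_cols)
    groups = {"text": text_cols, "lab": lab_cols, "comorbidity": com_cols,
              "demographic": demo_cols}
    return frame, groups
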