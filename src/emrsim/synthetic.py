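"""Synthetic EMR cohort generator with latent liver-condition classes and an
expert-score oracle.

The generator emulates a hospital cohort of de-identified hospitalizations
with four latent classes — liver cancer, hemangioma, NAFLD, and normal liver —
whose feature distributions differ by class: per-class prevalences for a pool
of ICD-10 comorbidity codes (1-11 codes per patient), per-class abnormality
rates for binary laboratory tests, per-class presence probabilities for report
phrases, and class-specific demographics.  Published per-class demographic and
comorbidity rates of the motivating liver cohort are used as defaults where
available; the remaining rates are fixed realistic choices (see
docs/methods.md).  Hidden class labels are returned alongside the patients and
are used only by the evaluation harness, never by the similarity pipeline.

The expert-score oracle stands in for the human scorer: the score of a pair is
a clipped noisy weighted sum of its 12 feature similarities,
``clip(Σ w_k v_k + ε, 0, 1)`` with ε ~ N(0, noise_sd).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import Patient
from .text import DEFAULT_INDEPENDENT_PHRASES

__all__ = ["CohortConfig", "OracleConfig", "generate_cohort",
           "expert_score_oracle", "inject_missingness", "CLASSES",
           "hierarchical_signal_config", "score_recovery_config"]

#: The four liver conditions, in canonical order.
CLASSES = ("cancer", "hemangioma", "nafld", "normal")

# Class proportions of the motivating cohort: 153 / 178 / 403 / 449 of 1183.
_DEFAULT_PROPORTIONS = (153 / 1183, 178 / 1183, 403 / 1183, 449 / 1183)

# Per-class demographics (age mean; male, drug-allergy, outpatient rates).
_AGE_MEAN = (66.6, 57.2, 51.4, 51.8)
_AGE_SD = 12.0
_MALE_RATE = (0.660, 0.478, 0.578, 0.508)
_ALLERGY_RATE = (0.085, 0.129, 0.199, 0.129)
_OUTPATIENT_RATE = (0.850, 0.921, 0.797, 0.906)


def _default_icd_pool() -> dict:
    """Default ICD-10 pool: six common comorbidities with published per-class
    prevalences, plus class-leaning disease families that give each class a
    hierarchical code signature."""
    pool = {
        # (cancer, hemangioma, nafld, normal) prevalences
        "I251": (0.085, 0.056, 0.067, 0.069),   # coronary heart disease
        "E119": (0.183, 0.101, 0.223, 0.127),   # diabetes without complication
        "E117": (0.046, 0.045, 0.109, 0.047),   # diabetes with complication
        "I10":  (0.399, 0.343, 0.419, 0.258),   # essential hypertension
        "E785": (0.020, 0.118, 0.335, 0.158),   # disorders of lipid metabolism
        "K590": (0.150, 0.174, 0.151, 0.149),   # other gastrointestinal disorders
    }
    # class-leaning families (higher prevalence in one class)
    families = {
        0: ["C240", "C241", "C250", "C260", "B180", "B181", "K703", "K746"],
        1: ["D170", "D171", "D175", "D360", "D377", "I780", "Q825", "L984"],
        2: ["E660", "E668", "K758", "K768", "E780", "E782", "R739", "E889"],
        3: ["Z000", "Z018", "M545", "J069", "H526", "N390", "R104", "K297"],
    }
    # in-class prevalence 0.30 keeps every family code above the 5% overall
    # popularity threshold even for the two smaller classes, so the cohort
    # yields a popular-comorbidity list of about the study's width (26)
    for cls_idx, codes in families.items():
        for code in codes:
            rates = [0.02, 0.02, 0.02, 0.02]
            rates[cls_idx] = 0.30
            pool[code] = tuple(rates)
    return pool


def _default_lab_rates(n_labs: int) -> np.ndarray:
    """Per-class abnormality rates: published rates for the six reported urine
    tests, a common background rate of 0.08 for the rest, with a handful of
    mildly class-leaning tests."""
    rates = np.full((4, n_labs), 0.08)
    published = [
        (0.085, 0.096, 0.092, 0.076),  # urine leukocytes
        (0.026, 0.011, 0.020, 0.020),  # urine bilirubin
        (0.059, 0.017, 0.030, 0.038),  # urobilinogen
        (0.059, 0.079, 0.139, 0.094),  # urine glucose
        (0.131, 0.101, 0.062, 0.082),  # urine occult blood
        (0.078, 0.090, 0.094, 0.069),  # ketone
    ]
    for j, row in enumerate(published[:n_labs]):
        rates[:, j] = row
    # a few liver-panel style tests lean toward the disease classes
    for j in range(6, min(12, n_labs)):
        cls = j % 4
        rates[cls, j] = 0.30
    return rates


def _default_text_rates(n_independent: int, n_set: int) -> tuple:
    """Per-class presence probabilities for report phrases."""
    indep = np.full((4, n_independent), 0.10)
    # each independent finding leans toward one class
    leans = [(0, 0.55), (0, 0.45), (3, 0.60), (3, 0.50), (1, 0.55)]
    for j in range(n_independent):
        cls, p = leans[j % len(leans)]
        indep[cls, j] = p
    sets = np.full((4, n_set), 0.12)
    for j in range(n_set):
        sets[j % 4, j] = 0.40
    return indep, sets


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the scale and class mix of the motivating liver cohort
    (1183 patients; 57 binary labs; 5 independent + 39 set text features).
    ``icd_pool`` maps each code to its per-class prevalence 4-tuple;
    ``lab_abnormal_rates`` is a (4, n_lab_features) matrix (or None for the
    defaults).
    """

    n_patients: int = 1183
    class_proportions: tuple = _DEFAULT_PROPORTIONS
    n_lab_features: int = 57
    n_text_set_features: int = 39
    n_independent_text_features: int = 5
    icd_pool: dict = field(default_factory=_default_icd_pool)
    lab_abnormal_rates: np.ndarray | None = None
    text_rates: tuple | None = None
    age_means: tuple = _AGE_MEAN
    age_sd: float = _AGE_SD
    male_rates: tuple = _MALE_RATE
    allergy_rates: tuple = _ALLERGY_RATE
    outpatient_rates: tuple = _OUTPATIENT_RATE
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError(f"n_patients must be >= 4, got {self.n_patients}")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (4,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("class_proportions must be 4 non-negative fractions summing to 1")
        if not self.icd_pool:
            raise ValueError("icd_pool must not be empty")
        for code, rates in self.icd_pool.items():
            r = np.asarray(rates, dtype=float)
            if r.shape != (4,) or (r < 0).any() or (r > 1).any():
                raise ValueError(f"icd_pool[{code!r}] prevalences must be 4 values in [0, 1]")
        if self.n_lab_features < 1 or self.n_text_set_features < 1:
            raise ValueError("feature counts must be positive")
        rates = self.resolved_lab_rates()
        if (rates < 0).any() or (rates > 1).any():
            raise ValueError("lab abnormality rates must lie in [0, 1]")

    def resolved_lab_rates(self) -> np.ndarray:
        if self.lab_abnormal_rates is None:
            return _default_lab_rates(self.n_lab_features)
        rates = np.asarray(self.lab_abnormal_rates, dtype=float)
        if rates.ndim == 1:  # one scalar rate per class, broadcast over labs
            rates = np.repeat(rates[:, None], self.n_lab_features, axis=1)
        if rates.shape != (4, self.n_lab_features):
            raise ValueError("lab_abnormal_rates must broadcast to (4, n_lab_features)")
        return rates

    def resolved_text_rates(self) -> tuple:
        if self.text_rates is None:
            return _default_text_rates(self.n_independent_text_features,
                                       self.n_text_set_features)
        indep, sets = self.text_rates
        return np.asarray(indep, dtype=float), np.asarray(sets, dtype=float)


def hierarchical_signal_config(n_patients: int, seed: int = 0) -> CohortConfig:
    """A cohort preset whose class signal lives in the ICD-10 hierarchy and
    set features rather than the flat numeric representation.

    Each class draws from its own family of eight codes sharing a rare
    two-character prefix; every individual family code stays below the 5%
    popularity threshold, so the numeric comorbidity binaries carry only the
    class-independent common codes.  Labs, text, and demographics are
    class-independent noise.
    """
    pool = {
        "I10": (0.30, 0.30, 0.30, 0.30),
        "E119": (0.15, 0.15, 0.15, 0.15),
        "K590": (0.15, 0.15, 0.15, 0.15),
    }
    families = {
        0: [f"C3{d}{d2}" for d, d2 in zip("00112233", "04826048")],
        1: [f"D4{d}{d2}" for d, d2 in zip("00112233", "15937159")],
        2: [f"E8{d}{d2}" for d, d2 in zip("00112233", "26048260")],
        3: [f"M2{d}{d2}" for d, d2 in zip("00112233", "37159371")],
    }
    for cls_idx, codes in families.items():
        for code in codes:
            rates = [0.01, 0.01, 0.01, 0.01]
            rates[cls_idx] = 0.16
            pool[code] = tuple(rates)
    flat_demo = dict(
        age_means=(55.0, 55.0, 55.0, 55.0), age_sd=10.0,
        male_rates=(0.5,) * 4, allergy_rates=(0.12,) * 4,
        outpatient_rates=(0.85,) * 4,
    )
    n_set = 39
    return CohortConfig(
        n_patients=n_patients,
        class_proportions=(0.25, 0.25, 0.25, 0.25),
        icd_pool=pool,
        lab_abnormal_rates=np.full((4, 57), 0.10),
        text_rates=(np.full((4, 5), 0.25), np.full((4, n_set), 0.15)),
        seed=seed,
        **flat_demo,
    )


def score_recovery_config(n_patients: int, seed: int = 0) -> CohortConfig:
    """A class-flat cohort preset for metric-recovery experiments.

    Every feature distribution is identical across the four classes, so no
    pair-similarity component correlates with the expert score except through
    the oracle's own weights — the standard identifiability design: if the
    learned metric concentrates on the oracle-weighted components here, it is
    recovering the scoring rule, not incidental class structure.  The code
    pool is class-independent with graded prevalences so the comorbidity IC
    component still varies across pairs.
    """
    pool = {}
    for i, code in enumerate(["A150", "A162", "B170", "B183", "C341", "D125",
                              "E149", "F410", "G409", "H251", "I109", "J189",
                              "K297", "L403", "M545", "N183", "I251", "E785",
                              "K590", "J069"]):
        p = 0.05 + 0.02 * i
        pool[code] = (p, p, p, p)
    return CohortConfig(
        n_patients=n_patients, class_proportions=(0.25,) * 4, icd_pool=pool,
        lab_abnormal_rates=np.full((4, 57), 0.10),
        text_rates=(np.full((4, 5), 0.25), np.full((4, 39), 0.15)),
        age_means=(55.0,) * 4, age_sd=12.0, male_rates=(0.5,) * 4,
        allergy_rates=(0.12,) * 4, outpatient_rates=(0.85,) * 4, seed=seed)


@dataclass
class OracleConfig:
    """The expert-score oracle: a noisy weighted sum of the 12 feature
    similarities, clipped to [0, 1].

    Default weights put 60% of the mass on the three set-valued components
    (comorbidity 0.30, labs 0.15, text set 0.15) and spread the rest evenly —
    the score is driven mainly by what the similarity learning must recover.
    """

    weights: np.ndarray = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.weights is None:
            w = np.full(12, 0.40 / 9)
            w[9], w[10], w[11] = 0.30, 0.15, 0.15
            self.weights = w
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (12,):
            raise ValueError(f"oracle weights must be a 12-vector, got shape {self.weights.shape}")
        if (self.weights < 0).any():
            raise ValueError("oracle weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"oracle weights must sum to 1, got {self.weights.sum()}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def expert_score_oracle(pair_vectors, oracle: OracleConfig):
    """Score one 12-vector or an (n, 12) stack of pair-similarity vectors.

    ``score = clip(Σ_k w_k v_k + ε, 0, 1)`` with ε drawn per pair from the
    oracle's seeded stream; deterministic given the seed.  The comorbidity
    component must already be normalized to [0, 1].
    """
    V = np.asarray(pair_vectors, dtype=float)
    single = V.ndim == 1
    if single:
        V = V[None, :]
    if V.ndim != 2 or V.shape[1] != 12:
        raise ValueError(f"pair vectors must have 12 components, got shape {V.shape}")
    if not np.isfinite(V).all():
        raise ValueError("pair vectors must be finite")
    rng = np.random.default_rng(oracle.seed)
    eps = rng.normal(0.0, oracle.noise_sd, size=V.shape[0]) if oracle.noise_sd > 0 \
        else np.zeros(V.shape[0])
    scores = np.clip(V @ oracle.weights + eps, 0.0, 1.0)
    return float(scores[0]) if single else scores


def generate_cohort(config: CohortConfig):
    """Draw a synthetic cohort; returns ``(patients, labels)`` with the hidden
    class labels in a separate list (used only for evaluation).

    Identical config + seed yields identical output.  Each patient carries 1-11
    comorbidity codes (per-class Bernoulli draws from the pool, padded with one
    class-weighted code when empty, truncated at 11), a binary lab vector, and
    a report-token set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    props = np.asarray(config.class_proportions, dtype=float)
    lab_rates = config.resolved_lab_rates()
    indep_rates, set_rates = config.resolved_text_rates()
    codes = sorted(config.icd_pool)
    prev = np.array([config.icd_pool[c] for c in codes])  # (n_codes, 4)

    if config.n_independent_text_features == 5:
        indep_phrases = list(DEFAULT_INDEPENDENT_PHRASES)
    else:
        indep_phrases = [f"indep finding {j:02d}"
                         for j in range(config.n_independent_text_features)]
    set_phrases = [f"finding {j:02d}" for j in range(config.n_text_set_features)]
    lab_names = [f"lab_{j:02d}" for j in range(config.n_lab_features)]
    width = len(str(config.n_patients - 1))

    patients, labels = [], []
    for i in range(config.n_patients):
        cls = int(rng.choice(4, p=props))
        age = float(np.clip(rng.normal(config.age_means[cls], config.age_sd), 18.0, 95.0))
        sex = int(rng.random() < config.male_rates[cls])
        allergy = int(rng.random() < config.allergy_rates[cls])
        outpatient = int(rng.random() < config.outpatient_rates[cls])

        draws = rng.random(len(codes)) < prev[:, cls]
        com = {codes[j] for j in np.flatnonzero(draws)}
        if not com:
            weights = prev[:, cls] + 1e-9
            com = {codes[int(rng.choice(len(codes), p=weights / weights.sum()))]}
        if len(com) > 11:
            com = set(rng.choice(sorted(com), size=11, replace=False).tolist())

        labs = {name: int(rng.random() < lab_rates[cls, j])
                for j, name in enumerate(lab_names)}
        tokens = {ph for j, ph in enumerate(indep_phrases)
                  if rng.random() < indep_rates[cls, j]}
        tokens |= {ph for j, ph in enumerate(set_phrases)
                   if rng.random() < set_rates[cls, j]}

        patients.append(Patient(
            id=f"p{i:0{width}d}", age=round(age, 1), sex=sex,
            drug_allergy=allergy, admission_source=outpatient,
            comorbidities=com, labs=labs, report_tokens=tokens,
        ))
        labels.append(CLASSES[cls])
    return patients, labels


def inject_missingness(cohort, rate: float, seed: int = 0):
    """Mask each lab value independently with probability ``rate`` (set to
    NaN), creating the input condition for CART imputation.  ``rate`` must lie
    in [0, 1); rate 0 returns an identical copy."""
    if not (0 <= rate < 1):
        raise ValueError(f"missingness rate must lie in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    out = []
    for p in cohort:
        labs = {}
        for name in sorted(p.labs):
            labs[name] = float("nan") if rng.random() < rate else p.labs[name]
        out.append(replace(p, comorbidities=set(p.comorbidities), labs=labs,
                           report_tokens=set(p.report_tokens)))
    return out
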