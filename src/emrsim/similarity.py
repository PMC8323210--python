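"""Feature-level similarity between patient pairs.

Every unordered pair of patients gets a 12-dimensional similarity vector

    [age, sex, drug_allergy, admission_source,
     text_1 ... text_5 (independent report binaries),
     comorbidity, labs, text_set]

whose components are each in [0, 1]: the age ratio min/max, exact-match
similarity for the binary features, an information-content (IC) similarity over
the ICD-10 code hierarchy for comorbidities (min-max normalized across the
cohort's pairs), and Jaccard similarity for the abnormal-lab and report-phrase
sets.

The comorbidity similarity is corpus-based: the fragment corpus collects, for
every ICD-10 code occurrence in the cohort, all its prefixes (leading letter
plus 0-3 digits).  The IC of two codes is -ln p(NCA) where the NCA (nearest
common ancestor) is their longest common prefix and p its corpus frequency;
codes with different leading letters share no information and get IC 0.  Rare
shared ancestors therefore score higher than common ones: two patients sharing
a rare diagnosis are more alike than two sharing a ubiquitous one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .text import TextSchema, structure_reports

__all__ = [
    "FragmentCorpus",
    "PAIR_COMPONENTS",
    "build_fragment_corpus",
    "ic_pair",
    "comorbidity_similarity",
    "binary_similarity",
    "jaccard_set_similarity",
    "age_similarity",
    "pair_similarity_vector",
    "pairwise_similarity_table",
    "count_pairs",
]

#: Fixed component order of the 12-dimensional pair-similarity vector.
PAIR_COMPONENTS = (
    "age", "sex", "drug_allergy", "admission_source",
    "text_1", "text_2", "text_3", "text_4", "text_5",
    "comorbidity", "labs", "text_set",
)


@dataclass(frozen=True)
class FragmentCorpus:
    """Multiset of ICD-10 code prefixes (lengths 1-4) with occurrence counts.

    ``total`` is the sum of all counts; p(fragment) = count / total.
    """

    counts: dict
    total: int

    def __post_init__(self):
        if self.total != sum(self.counts.values()):
            raise ValueError("corpus total does not equal the sum of fragment counts")
        for frag, c in self.counts.items():
            if c < 1:
                raise ValueError(f"fragment {frag!r} has count {c} < 1")

    def p(self, fragment: str) -> float:
        if fragment not in self.counts:
            raise KeyError(
                f"fragment {fragment!r} not in corpus; corpus and cohort disagree"
            )
        return self.counts[fragment] / self.total


def build_fragment_corpus(cohort) -> FragmentCorpus:
    """Build the fragment corpus from every code in every patient's
    comorbidity list: each occurrence contributes all its prefixes once."""
    if not cohort:
        raise ValueError("cannot build a fragment corpus from an empty cohort")
    counts: dict = {}
    total = 0
    for p in cohort:
        for code in p.comorbidities:
            for k in range(1, len(code) + 1):
                frag = code[:k]
                counts[frag] = counts.get(frag, 0) + 1
                total += 1
    if not counts:
        raise ValueError("no ICD-10 codes in cohort; fragment corpus would be empty")
    return FragmentCorpus(counts=counts, total=total)


def _longest_common_prefix(a: str, b: str) -> str:
    k = 0
    for x, y in zip(a, b):
        if x != y:
            break
        k += 1
    return a[:k]


def ic_pair(code1: str, code2: str, corpus: FragmentCorpus) -> float:
    """Information content of two ICD-10 codes' nearest common ancestor.

    ``-ln p(NCA)`` with the NCA the longest common prefix; 0 when the codes
    share no leading letter (no shared information).
    """
    nca = _longest_common_prefix(code1, code2)
    if not nca:
        return 0.0
    return -math.log(corpus.p(nca))


def comorbidity_similarity(X, Y, corpus: FragmentCorpus) -> float:
    """Mean IC over all m*n cross pairs of two comorbidity code sets.

    Unbounded and raw: min-max normalization to [0, 1] across the cohort's
    pairs happens in :func:`pairwise_similarity_table`.  Requires both sets
    non-empty (the empty-set conventions — both empty -> 1, one empty -> 0 —
    are applied after normalization and live in the table builder).
    """
    X, Y = list(X), list(Y)
    if not X or not Y:
        raise ValueError("comorbidity_similarity requires two non-empty code sets")
    return sum(ic_pair(a, b, corpus) for a in X for b in Y) / (len(X) * len(Y))


def binary_similarity(a, b) -> int:
    """1 iff the two binary values agree."""
    if a not in (0, 1) or b not in (0, 1):
        raise ValueError(f"binary_similarity requires values in {{0, 1}}, got ({a!r}, {b!r})")
    return 1 if a == b else 0


def jaccard_set_similarity(A, B) -> float:
    """|A∩B| / |A∪B|; both sets empty -> 1 (identical information), exactly
    one empty -> 0."""
    A, B = set(A), set(B)
    union = len(A | B)
    if union == 0:
        return 1.0
    return len(A & B) / union


def age_similarity(a1: float, a2: float) -> float:
    """min(age) / max(age); equal ages (including both zero) -> 1."""
    if a1 < 0 or a2 < 0:
        raise ValueError(f"ages must be non-negative, got ({a1}, {a2})")
    lo, hi = min(a1, a2), max(a1, a2)
    if hi == 0:
        return 1.0
    return lo / hi


def count_pairs(n: int) -> int:
    """Number of unordered patient pairs among n patients: n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def _comorbidity_component(raw: float, flag: str, lo: float, hi: float) -> float:
    """Map a raw IC average to [0, 1] given the cohort min/max of finite raws."""
    if flag == "both_empty":
        return 1.0
    if flag == "one_empty":
        return 0.0
    if hi > lo:
        return (raw - lo) / (hi - lo)
    # degenerate cohort: every pair has the same raw similarity
    return 1.0 if raw > 0 else 0.0


def pair_similarity_vector(p_i, p_j, corpus: FragmentCorpus, schema: TextSchema,
                           comorbidity_bounds=None) -> np.ndarray:
    """The 12-component similarity vector for one patient pair.

    ``comorbidity_bounds = (lo, hi)`` are the cohort-wide min/max of the raw IC
    averages used to normalize the comorbidity component; without them the raw
    (unbounded) value is returned in that slot.  Symmetric in the two patients.
    """
    if len(schema.independent) != 5:
        raise ValueError(
            f"the 12-component pair vector needs exactly 5 independent text "
            f"features, schema has {len(schema.independent)}"
        )
    indep, sets = structure_reports([p_i, p_j], schema)
    for p in (p_i, p_j):
        for name, v in p.labs.items():
            if v not in (0, 1):
                raise ValueError(
                    f"patient {p.id}: lab {name!r} = {v!r} is not binarized; "
                    "preprocess the cohort first"
                )
    v = np.empty(12)
    v[0] = age_similarity(p_i.age, p_j.age)
    v[1] = binary_similarity(p_i.sex, p_j.sex)
    v[2] = binary_similarity(p_i.drug_allergy, p_j.drug_allergy)
    v[3] = binary_similarity(p_i.admission_source, p_j.admission_source)
    for t in range(5):
        v[4 + t] = binary_similarity(int(indep[0, t]), int(indep[1, t]))
    X, Y = p_i.comorbidities, p_j.comorbidities
    if not X and not Y:
        raw, flag = math.nan, "both_empty"
    elif not X or not Y:
        raw, flag = math.nan, "one_empty"
    else:
        raw, flag = comorbidity_similarity(X, Y, corpus), "ok"
    if comorbidity_bounds is None:
        v[9] = 1.0 if flag == "both_empty" else (0.0 if flag == "one_empty" else raw)
    else:
        v[9] = _comorbidity_component(raw, flag, *comorbidity_bounds)
    abn_i = {n for n, val in p_i.labs.items() if val == 1}
    abn_j = {n for n, val in p_j.labs.items() if val == 1}
    v[10] = jaccard_set_similarity(abn_i, abn_j)
    v[11] = jaccard_set_similarity(sets[0], sets[1])
    return v


def _jaccard_matrix(B: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity between the rows of a boolean matrix, with
    the empty-set conventions (0/0 -> 1)."""
    Bf = B.astype(float)
    inter = Bf @ Bf.T
    sizes = Bf.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return sim


def pairwise_similarity_table(cohort, corpus: FragmentCorpus,
                              schema: TextSchema) -> pd.DataFrame:
    """Similarity vectors for all n(n-1)/2 unordered patient pairs.

    Pairs are canonical (``id_a < id_b`` lexicographically, enumerated in
    sorted-id order); columns are ``id_a, id_b, v1 .. v12`` in the
    :data:`PAIR_COMPONENTS` order.  The comorbidity component is min-max
    normalized over all pairs with both code sets non-empty; both-empty pairs
    map to 1 and one-empty pairs to 0.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 patients to enumerate pairs")
    if len(schema.independent) != 5:
        raise ValueError(
            f"the 12-component pair vector needs exactly 5 independent text "
            f"features, schema has {len(schema.independent)}"
        )
    patients = sorted(cohort, key=lambda p: p.id)
    n = len(patients)
    ids = [p.id for p in patients]
    iu, ju = np.triu_indices(n, 1)

    ages = np.array([p.age for p in patients], dtype=float)
    lo_a = np.minimum(ages[iu], ages[ju])
    hi_a = np.maximum(ages[iu], ages[ju])
    with np.errstate(invalid="ignore", divide="ignore"):
        age_sim = np.where(hi_a > 0, lo_a / np.maximum(hi_a, 1e-300), 1.0)

    demo = np.array([[p.sex, p.drug_allergy, p.admission_source] for p in patients])
    demo_sim = (demo[iu] == demo[ju]).astype(float)

    indep, sets = structure_reports(patients, schema)
    text_sim = (indep[iu] == indep[ju]).astype(float)

    names = sorted({n_ for p in patients for n_ in p.labs})
    lab_mat = np.zeros((n, len(names)), dtype=bool)
    for i, p in enumerate(patients):
        for j, name in enumerate(names):
            val = p.labs.get(name, 0)
            if val not in (0, 1):
                raise ValueError(
                    f"patient {p.id}: lab {name!r} = {val!r} is not binarized; "
                    "preprocess the cohort first"
                )
            lab_mat[i, j] = val == 1
    lab_sim = _jaccard_matrix(lab_mat)[iu, ju]

    set_vocab = list(schema.set_features)
    set_mat = np.zeros((n, len(set_vocab)), dtype=bool)
    for i, s in enumerate(sets):
        for j, phrase in enumerate(set_vocab):
            set_mat[i, j] = phrase in s
    set_sim = _jaccard_matrix(set_mat)[iu, ju]

    # raw comorbidity IC averages, cached per distinct code pair
    code_lists = [sorted(p.comorbidities) for p in patients]
    ic_cache: dict = {}

    def cached_ic(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        val = ic_cache.get(key)
        if val is None:
            val = ic_pair(a, b, corpus)
            ic_cache[key] = val
        return val

    raw = np.full(len(iu), np.nan)
    flags = np.empty(len(iu), dtype=object)
    for k in range(len(iu)):
        X, Y = code_lists[iu[k]], code_lists[ju[k]]
        if not X and not Y:
            flags[k] = "both_empty"
        elif not X or not Y:
            flags[k] = "one_empty"
        else:
            flags[k] = "ok"
            raw[k] = sum(cached_ic(a, b) for a in X for b in Y) / (len(X) * len(Y))

    finite = raw[np.isfinite(raw)]
    lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 0.0)
    com_sim = np.array([
        _comorbidity_component(raw[k], flags[k], lo, hi) for k in range(len(iu))
    ])

    table = pd.DataFrame({
        "id_a": [ids[i] for i in iu],
        "id_b": [ids[j] for j in ju],
    })
    V = np.column_stack([
        age_sim, demo_sim, text_sim[:, :5], com_sim, lab_sim, set_sim,
    ])
    for c in range(12):
        table[f"v{c + 1}"] = V[:, c]
    table.attrs["comorbidity_bounds"] = (float(lo), float(hi))
    return table
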