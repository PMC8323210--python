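"""TF-IDF phrase ranking and structuring of radiology-report tokens.

Reports arrive as pre-tokenized phrase multisets (segmentation of the source
free text happens upstream).  The top-``r`` phrases by corpus-level TF-IDF form
the text schema: a handful of clinically designated phrases become independent
binary features, the remainder a binary set feature.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["TextSchema", "tfidf_rank", "select_top_r", "structure_reports",
           "DEFAULT_INDEPENDENT_PHRASES"]

#: The five report findings treated as independent binary features (clinically
#: designated: most diagnostically important for the liver-condition task).
DEFAULT_INDEPENDENT_PHRASES = (
    "retroperitoneal lymph node enlargement",
    "lower density than spleen",
    "no abnormal density",
    "uniform liver parenchyma density",
    "arterial phase",
)


def tfidf_rank(documents):
    """Rank phrases by corpus-level TF-IDF.

    ``score(t) = sum_d tf(t, d) * ln(N / df(t))`` with raw term counts, the
    number of documents N, and document frequency df.  Ties are broken by
    lexicographic phrase order.  Needs at least two documents (otherwise every
    idf is ln(1) = 0 and the ranking is degenerate).
    """
    docs = [list(d) for d in documents]
    n = len(docs)
    if n < 2:
        raise ValueError("tfidf_rank needs at least 2 documents")
    tf_total: Counter = Counter()
    df: Counter = Counter()
    for d in docs:
        counts = Counter(d)
        for t, c in counts.items():
            if not isinstance(t, str) or not t:
                raise ValueError(f"tokens must be non-empty strings, got {t!r}")
            tf_total[t] += c
            df[t] += 1
    scored = [(t, tf_total[t] * math.log(n / df[t])) for t in tf_total]
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return scored


def select_top_r(ranked, r: int):
    """First ``r`` phrases of a :func:`tfidf_rank` ranking."""
    if r < 0 or r > len(ranked):
        raise ValueError(f"r = {r} out of range for a vocabulary of {len(ranked)} phrases")
    return [t for t, _ in ranked[:r]]


@dataclass(frozen=True)
class TextSchema:
    """Fixed text-feature schema: independent binary phrases plus the set-feature
    vocabulary (the remaining top-r phrases)."""

    independent: tuple
    set_features: tuple

    def __post_init__(self):
        overlap = set(self.independent) & set(self.set_features)
        if overlap:
            raise ValueError(f"phrases in both independent and set lists: {sorted(overlap)}")

    @property
    def size(self) -> int:
        return len(self.independent) + len(self.set_features)

    @classmethod
    def from_documents(cls, documents, r: int = 44, independent=None,
                       n_independent: int = 5) -> "TextSchema":
        """Build a schema from the report corpus: rank by TF-IDF, keep the top
        ``r`` phrases, and designate the independent binaries.

        ``independent`` names the designated phrases explicitly (they join the
        schema whether or not they rank in the top r, mirroring their expert
        designation); by default the ``n_independent`` highest-ranked phrases
        are used.
        """
        ranked = tfidf_rank(documents)
        top = select_top_r(ranked, min(r, len(ranked)))
        if independent is None:
            independent = tuple(top[:n_independent])
        else:
            independent = tuple(independent)
        set_feats = tuple(t for t in top if t not in independent)[: max(r - len(independent), 0)]
        return cls(independent=independent, set_features=set_feats)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"independent": list(self.independent),
                            "set": list(self.set_features)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "TextSchema":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(independent=tuple(data["independent"]),
                   set_features=tuple(data["set"]))


def structure_reports(cohort, schema: TextSchema):
    """Structure each patient's report tokens against a fixed schema.

    Returns ``(indep, sets)`` aligned with cohort order: ``indep`` is an
    ``(n, n_independent)`` 0/1 array (phrase present in the patient's tokens),
    ``sets`` a list of frozensets holding each patient's present set-feature
    phrases.  Presence semantics: token order and multiplicity are irrelevant.
    """
    if schema.size == 0:
        raise ValueError("empty text schema")
    set_vocab = set(schema.set_features)
    indep = np.zeros((len(cohort), len(schema.independent)), dtype=int)
    sets = []
    for i, p in enumerate(cohort):
        tokens = set(p.report_tokens)
        for j, phrase in enumerate(schema.independent):
            indep[i, j] = 1 if phrase in tokens else 0
        sets.append(frozenset(tokens & set_vocab))
    return indep, sets
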