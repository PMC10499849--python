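"""Data model for coded EHR visit sequences.

Patients are variable-length sequences of visits; each visit is a set of
diagnosis-code indices over a fixed vocabulary, encoded downstream as a
multi-hot binary vector.  Cohorts carry a pre/post environment tag marking
which side of a distribution-shift boundary each patient's records fall on,
and a train/valid/test split tag.

On-disk formats:

* cohort: JSON-Lines, one object per patient with keys ``patient_id``,
  ``visits`` (list of lists of code strings), ``label`` (0/1),
  ``environment`` (``"pre"``/``"post"``) and ``split``
  (``"train"``/``"valid"``/``"test"``);
* vocabulary: plain text, one code per line, line order defines the index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ENVIRONMENTS = ("pre", "post")
SPLITS = ("train", "valid", "test")


def truncate_code(code: str, k: int) -> str:
    """Keep the first ``k`` characters of a raw diagnosis code.

    ICD-style codes group into broader categories by prefix; keeping the
    first three characters collapses detailed codes into their category,
    shrinking the vocabulary while preserving clinical meaning.
    """
    if not code:
        raise ValueError("empty diagnosis code")
    if k < 1:
        raise ValueError(f"truncation length must be >= 1, got {k}")
    return code[:k]


@dataclass(frozen=True)
class CodeVocabulary:
    """Ordered diagnosis-code vocabulary with stable integer indices."""

    codes: tuple[str, ...]
    truncation_length: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("vocabulary codes must be unique")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.codes)})

    @property
    def size(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        if self.truncation_length is not None:
            code = truncate_code(code, self.truncation_length)
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"code {code!r} not in vocabulary") from None

    def __contains__(self, code: str) -> bool:
        if self.truncation_length is not None:
            code = truncate_code(code, self.truncation_length)
        return code in self._index

    @classmethod
    def from_codes(
        cls, codes: Iterable[str], truncation_length: int | None = None
    ) -> "CodeVocabulary":
        """Build a vocabulary from raw codes (deduplicated, sorted)."""
        if truncation_length is not None:
            codes = (truncate_code(c, truncation_length) for c in codes)
        return cls(tuple(sorted(set(codes))), truncation_length)

    @classmethod
    def load(cls, path: str | Path, truncation_length: int | None = None) -> "CodeVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(tuple(line.strip() for line in lines if line.strip()), truncation_length)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.codes) + "\n", encoding="utf-8")


@dataclass
class PatientRecord:
    """One patient: chronological visits of code-index sets, a binary
    outcome label, an environment tag and a split tag."""

    patient_id: str
    visits: list[frozenset[int]]
    label: int
    environment: str
    split: str
    period: int | None = None  # optional coarse time tag for drift audits

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"environment must be one of {ENVIRONMENTS}")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        if not self.visits or all(len(v) == 0 for v in self.visits):
            raise ValueError(f"patient {self.patient_id}: needs >=1 non-empty visit")
        self.visits = [frozenset(v) for v in self.visits]

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def code_counts(self, C: int) -> np.ndarray:
        """Occurrences of each code summed over visits (multi-hot per visit)."""
        counts = np.zeros(C, dtype=float)
        for visit in self.visits:
            for k in visit:
                counts[k] += 1.0
        return counts


@dataclass
class Cohort:
    """A collection of patient records sharing one vocabulary.

    ``max_visits`` (T) is the common padded length; by default the maximum
    visit count over all records, so pre- and post-shift batches share shape.
    """

    records: list[PatientRecord]
    vocabulary: CodeVocabulary
    max_visits: int = 0

    def __post_init__(self) -> None:
        C = self.vocabulary.size
        longest = 0
        for rec in self.records:
            longest = max(longest, rec.n_visits)
            for visit in rec.visits:
                bad = [k for k in visit if not 0 <= k < C]
                if bad:
                    raise ValueError(
                        f"patient {rec.patient_id}: code index {bad[0]} out of "
                        f"range for vocabulary of size {C}"
                    )
        if self.max_visits <= 0:
            self.max_visits = longest
        elif self.max_visits < longest:
            raise ValueError(
                f"max_visits={self.max_visits} < longest record ({longest} visits)"
            )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, environment: str | None = None, split: str | None = None) -> "Cohort":
        recs = [
            r
            for r in self.records
            if (environment is None or r.environment == environment)
            and (split is None or r.split == split)
        ]
        return Cohort(recs, self.vocabulary, self.max_visits)

    @property
    def pre(self) -> "Cohort":
        return self.subset("pre")

    @property
    def post(self) -> "Cohort":
        return self.subset("post")


@dataclass
class PaddedBatch:
    """Dense multi-hot tensor view of a record list.

    ``X`` has shape (n, T, C) with ``X[i, t, k] = 1`` iff code ``k`` was
    recorded at visit ``t`` of patient ``i``; ``visit_mask[i, t] = 1`` marks
    real (non-padding) visits.  Padded rows are all-zero and must never
    contribute to downstream sums.
    """

    X: np.ndarray
    visit_mask: np.ndarray
    labels: np.ndarray
    patient_ids: list[str] = field(default_factory=list)
    periods: np.ndarray | None = None

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]

    @property
    def C(self) -> int:
        return self.X.shape[2]

    def code_counts(self) -> np.ndarray:
        """Per-patient code occurrence counts, masked to real visits: (n, C)."""
        return (self.X * self.visit_mask[:, :, None]).sum(axis=1)


def to_padded_batch(
    records: Sequence[PatientRecord], T: int, C: int
) -> PaddedBatch:
    """Encode records as a zero-padded multi-hot batch of common length T."""
    n = len(records)
    X = np.zeros((n, T, C), dtype=np.float64)
    mask = np.zeros((n, T), dtype=np.float64)
    labels = np.zeros(n, dtype=np.int64)
    periods = np.full(n, -1, dtype=np.int64)
    for i, rec in enumerate(records):
        if rec.n_visits > T:
            raise ValueError(
                f"patient {rec.patient_id} has {rec.n_visits} visits > T={T}; "
                "refusing to truncate silently"
            )
        for t, visit in enumerate(rec.visits):
            for k in visit:
                X[i, t, k] = 1.0
            mask[i, t] = 1.0
        labels[i] = rec.label
        if rec.period is not None:
            periods[i] = rec.period
    has_periods = bool((periods >= 0).any())
    return PaddedBatch(
        X=X,
        visit_mask=mask,
        labels=labels,
        patient_ids=[r.patient_id for r in records],
        periods=periods if has_periods else None,
    )


def batch_from_cohort(cohort: Cohort, records: Sequence[PatientRecord] | None = None) -> PaddedBatch:
    recs = cohort.records if records is None else list(records)
    return to_padded_batch(recs, cohort.max_visits, cohort.vocabulary.size)


def _parse_record(obj: dict, vocabulary: CodeVocabulary) -> PatientRecord:
    visits = [frozenset(vocabulary.index(c) for c in visit) for visit in obj["visits"]]
    return PatientRecord(
        patient_id=str(obj["patient_id"]),
        visits=visits,
        label=int(obj["label"]),
        environment=obj["environment"],
        split=obj["split"],
        period=obj.get("period"),
    )


def load_cohort(
    path: str | Path,
    vocabulary: CodeVocabulary | None = None,
    truncation_length: int | None = None,
) -> Cohort:
    """Read a JSON-Lines cohort file.

    If no vocabulary is given, one is built from the codes present in the
    file (after optional prefix truncation).  Under a supplied vocabulary an
    unknown code is an error rather than being dropped.
    """
    path = Path(path)
    raw: list[dict] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
            for key in ("patient_id", "visits", "label", "environment", "split"):
                if key not in obj:
                    raise ValueError(f"{path}:{lineno}: missing field {key!r}")
            raw.append(obj)

    if vocabulary is None:
        all_codes = (c for obj in raw for visit in obj["visits"] for c in visit)
        vocabulary = CodeVocabulary.from_codes(all_codes, truncation_length)

    records = [_parse_record(obj, vocabulary) for obj in raw]
    return Cohort(records, vocabulary)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the JSON-Lines format ``load_cohort`` reads."""
    vocab = cohort.vocabulary
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in cohort.records:
            obj = {
                "patient_id": rec.patient_id,
                "visits": [sorted(vocab.codes[k] for k in visit) for visit in rec.visits],
                "label": int(rec.label),
                "environment": rec.environment,
                "split": rec.split,
            }
            if rec.period is not None:
                obj["period"] = int(rec.period)
            fh.write(json.dumps(obj) + "\n")
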