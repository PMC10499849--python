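import numpy as np
import pytest

from ehrshift.data import Cohort, CodeVocabulary, PatientRecord, to_padded_batch


def make_record(pid, visits, label=0, environment="pre", split="train", period=None):
    return PatientRecord(
        patient_id=pid,
        visits=[frozenset(v) for v in visits],
        label=label,
        environment=environment,
        split=split,
        period=period,
    )


def make_vocab(C):
    return CodeVocabulary(tuple(f"C{k:02d}" for k in range(C)))


@pytest.fixture
def tiny_cohort():
    """Two pre + one post patient over a 3-code vocabulary."""
    records = [
        make_record("p1", [{0, 1}, {1}], label=1, environment="pre"),
        make_record("p2", [{2}], label=0, environment="pre", split="valid"),
        make_record("q1", [{1}, {2}, {2}], label=1, environment="post"),
    ]
    return Cohort(records, make_vocab(3))


def random_batch(rng, n, T, C, min_visits=1):
    """Random padded multi-hot batch with varying sequence lengths."""
    records = []
    for i in range(n):
        n_visits = int(rng.integers(min_visits, T + 1))
        visits = []
        for _ in range(n_visits):
            k = int(rng.integers(1, min(4, C) + 1))
            visits.append(set(int(c) for c in rng.choice(C, size=k, replace=False)))
        records.append(make_record(f"p{i}", visits, label=int(rng.integers(2))))
    return to_padded_batch(records, T, C), records
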