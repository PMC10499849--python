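"""Seeded synthetic shifted-cohort generator.

Emulates the statistical structure of a case-control EHR cohort that
straddles a coding-system transition: every patient has at least ten
visits, each visit records a small set of diagnosis codes drawn from a
skewed (power-law) frequency spectrum, and the post-shift environment
changes the per-code occurrence rates (designated codes roughly double)
while the code->outcome relation stays fixed.  That makes the shift a pure
covariate shift, the setting sample reweighting addresses.

Two generators are provided:

* :func:`generate_cohort` — abrupt two-environment rate shift via
  per-code multipliers (renormalized), mimicking the jump in occurrence
  rates seen at a coding-system transition;
* :func:`generate_mixture_cohort` — a two-subpopulation construction with
  a closed-form importance-weight oracle (post-shift keeps only
  subpopulation A, so the optimal pre-shift weight is 1{A}/pi), used to
  test weight recovery against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import Cohort, CodeVocabulary, PatientRecord

__all__ = [
    "ShiftScenario",
    "MixtureScenario",
    "generate_cohort",
    "generate_mixture_cohort",
    "shifted_rates",
]


def _default_base_rates(C: int) -> np.ndarray:
    # Zipf-like spectrum: a few very common codes, a long tail — the shape of
    # real diagnosis-code frequency distributions.
    r = 1.0 / np.arange(1, C + 1)
    return r / r.sum()


def _default_multipliers(C: int) -> np.ndarray:
    # Roughly double the rate of a handful of moderately common codes,
    # halve a couple of others: an abrupt, asymmetric shift.
    m = np.ones(C)
    up = [k for k in (3, 5, 7, 9, 11) if k < C]
    down = [k for k in (4, 8) if k < C]
    m[up] = 2.0
    m[down] = 0.5
    return m


def _default_risk_coefficients(C: int) -> np.ndarray:
    # Sparse signal on common codes (including some of the shifted ones, so
    # the shift actually matters for prediction); alternating signs keep the
    # linear predictor roughly centred.
    beta = np.zeros(C)
    signal = [k for k in range(min(14, C))]
    for j, k in enumerate(signal):
        beta[k] = 6.0 if j % 2 == 0 else -6.0
    return beta


@dataclass
class ShiftScenario:
    """Parameters of an abrupt two-environment covariate shift.

    Defaults describe the study conditions used throughout: a 50-code
    vocabulary, 2,000 pre-shift patients against a tenfold-smaller
    post-shift training sample, 10–16 visits per patient and about 2.3
    codes per visit, with several codes shifted ~2x.
    """

    C: int = 50
    n_pre: int = 2000
    n_post_train: int = 200
    n_post_test: int = 500
    visits_min: int = 10
    visits_max: int = 16
    codes_per_visit: float = 2.3
    base_rates: np.ndarray | None = None
    shift_multipliers: np.ndarray | None = None
    risk_coefficients: np.ndarray | None = None
    intercept: float | None = None  # None -> auto-centred for ~50% prevalence
    pre_split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("need a vocabulary of at least 2 codes")
        if self.visits_min < 10:
            raise ValueError("cohort design requires >=10 visits per patient")
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max < visits_min")
        if self.codes_per_visit < 1 or self.codes_per_visit > self.C:
            raise ValueError("codes_per_visit must lie in [1, C]")
        if self.base_rates is None:
            self.base_rates = _default_base_rates(self.C)
        else:
            self.base_rates = np.asarray(self.base_rates, dtype=float)
            if self.base_rates.shape != (self.C,) or (self.base_rates < 0).any():
                raise ValueError("base_rates must be a non-negative length-C vector")
            s = self.base_rates.sum()
            if s <= 0:
                raise ValueError("base_rates has zero mass")
            self.base_rates = self.base_rates / s
        if self.shift_multipliers is None:
            self.shift_multipliers = _default_multipliers(self.C)
        else:
            self.shift_multipliers = np.asarray(self.shift_multipliers, dtype=float)
            if self.shift_multipliers.shape != (self.C,) or (
                self.shift_multipliers <= 0
            ).any():
                raise ValueError("shift_multipliers must be positive, length C")
        if self.risk_coefficients is None:
            self.risk_coefficients = _default_risk_coefficients(self.C)
        else:
            self.risk_coefficients = np.asarray(self.risk_coefficients, dtype=float)
            if self.risk_coefficients.shape != (self.C,):
                raise ValueError("risk_coefficients must have length C")

    @property
    def post_rates(self) -> np.ndarray:
        """Renormalized post-shift per-code sampling rates."""
        return shifted_rates(self.base_rates, self.shift_multipliers)


def shifted_rates(base_rates: np.ndarray, multipliers: np.ndarray) -> np.ndarray:
    r = np.asarray(base_rates, float) * np.asarray(multipliers, float)
    return r / r.sum()


@dataclass
class MixtureScenario:
    """Two-subpopulation construction with a known importance oracle.

    Pre-shift patients belong to subpopulation A with probability ``pi``
    (code rates ``rates_a``) and otherwise to B (``rates_b``); post-shift
    patients are all A.  The population importance ratio is therefore
    1/pi for A patients and 0 for B patients.
    """

    C: int = 50
    n_pre: int = 2000
    n_post_train: int = 200
    n_post_test: int = 500
    visits_min: int = 10
    visits_max: int = 16
    codes_per_visit: float = 2.3
    rates_a: np.ndarray | None = None
    rates_b: np.ndarray | None = None
    pi: float = 0.5
    risk_coefficients: np.ndarray | None = None
    intercept: float | None = None
    pre_split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("pi must lie in (0, 1]")
        C = self.C
        if self.rates_a is None:
            # A concentrates on the lower half of the vocabulary, B on the
            # upper half, with a small shared floor so supports overlap.
            a = np.full(C, 0.1 / C)
            a[: C // 2] += _default_base_rates(C - C // 2)[: C // 2] * 0.9
            self.rates_a = a / a.sum()
        else:
            self.rates_a = np.asarray(self.rates_a, float)
        if self.rates_b is None:
            b = np.full(C, 0.1 / C)
            b[C // 2 :] += _default_base_rates(C - C // 2) * 0.9
            self.rates_b = b / b.sum()
        else:
            self.rates_b = np.asarray(self.rates_b, float)
        for name, r in (("rates_a", self.rates_a), ("rates_b", self.rates_b)):
            if r.shape != (C,) or (r < 0).any() or r.sum() <= 0:
                raise ValueError(f"{name} must be a non-negative length-C vector with mass")
        self.rates_a = self.rates_a / self.rates_a.sum()
        self.rates_b = self.rates_b / self.rates_b.sum()
        if self.risk_coefficients is None:
            self.risk_coefficients = _default_risk_coefficients(C)
        else:
            self.risk_coefficients = np.asarray(self.risk_coefficients, float)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # Per-patient sub-streams: reproducible independently of generation order.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _draw_visits(
    rng: np.random.Generator,
    rates: np.ndarray,
    n_visits: int,
    codes_per_visit: float,
    C: int,
) -> list[frozenset[int]]:
    visits = []
    support = int((rates > 0).sum())
    for _ in range(n_visits):
        k = 1 + rng.poisson(codes_per_visit - 1.0)
        k = min(k, support)
        codes = rng.choice(C, size=k, replace=False, p=rates)
        visits.append(frozenset(int(c) for c in codes))
    return visits


def _mean_multihot(visits: Sequence[frozenset[int]], C: int) -> np.ndarray:
    x = np.zeros(C)
    for v in visits:
        for k in v:
            x[k] += 1.0
    return x / len(visits)


def _linear_predictor(visits, C, beta) -> float:
    return float(beta @ _mean_multihot(visits, C))


def _assign_pre_splits(n: int, fractions: tuple[float, float, float]) -> list[str]:
    n_train = int(round(n * fractions[0]))
    n_valid = int(round(n * fractions[1]))
    out = ["train"] * n_train + ["valid"] * n_valid + ["test"] * (n - n_train - n_valid)
    return out


def _generate(
    seed: int,
    C: int,
    n_pre: int,
    n_post_train: int,
    n_post_test: int,
    visits_range: tuple[int, int],
    codes_per_visit: float,
    pre_rates_for: "callable",
    post_rates: np.ndarray,
    beta: np.ndarray,
    intercept: float | None,
    pre_split_fractions: tuple[float, float, float],
) -> tuple[Cohort, np.ndarray]:
    """Shared two-environment generation; returns cohort and the per-pre-patient
    auxiliary tag produced by ``pre_rates_for`` (subpopulation membership)."""
    if n_pre <= 0:
        raise ValueError("n_pre must be positive")
    vocab = CodeVocabulary(tuple(f"C{k:03d}" for k in range(C)))
    vmin, vmax = visits_range

    pre_visits: list[list[frozenset[int]]] = []
    membership = np.zeros(n_pre, dtype=np.int64)
    for i in range(n_pre):
        rng = _patient_rng(seed, i)
        rates, tag = pre_rates_for(rng)
        membership[i] = tag
        n_visits = int(rng.integers(vmin, vmax + 1))
        pre_visits.append(_draw_visits(rng, rates, n_visits, codes_per_visit, C))

    post_visits: list[list[frozenset[int]]] = []
    n_post = n_post_train + n_post_test
    for j in range(n_post):
        rng = _patient_rng(seed, n_pre + j)
        n_visits = int(rng.integers(vmin, vmax + 1))
        post_visits.append(_draw_visits(rng, post_rates, n_visits, codes_per_visit, C))

    # Stable label mechanism: identical coefficients and intercept in both
    # environments.  The intercept, when unset, is centred on the pre-shift
    # linear predictors so prevalence lands near 50% (case-control balance).
    eta_pre = np.array([_linear_predictor(v, C, beta) for v in pre_visits])
    if intercept is None:
        intercept = -float(np.median(eta_pre))
    label_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(n_pre + n_post, 7))
    )

    def draw_label(eta: float) -> int:
        from scipy.special import expit

        return int(label_rng.random() < expit(intercept + eta))

    records: list[PatientRecord] = []
    pre_splits = _assign_pre_splits(n_pre, pre_split_fractions)
    for i, visits in enumerate(pre_visits):
        records.append(
            PatientRecord(
                patient_id=f"pre{i:06d}",
                visits=visits,
                label=draw_label(eta_pre[i]),
                environment="pre",
                split=pre_splits[i],
                period=0,
            )
        )
    for j, visits in enumerate(post_visits):
        records.append(
            PatientRecord(
                patient_id=f"post{j:06d}",
                visits=visits,
                label=draw_label(_linear_predictor(visits, C, beta)),
                environment="post",
                split="train" if j < n_post_train else "test",
                period=1,
            )
        )
    return Cohort(records, vocab, max_visits=vmax), membership


def generate_cohort(scenario: ShiftScenario) -> Cohort:
    """Generate an abrupt-shift two-environment cohort.

    Pre-shift visit codes follow ``base_rates``; post-shift codes follow the
    renormalized ``base_rates * shift_multipliers``.  Labels come from one
    logistic model shared by both environments (covariate shift only).
    Deterministic given ``scenario.seed``.
    """
    s = scenario
    cohort, _ = _generate(
        seed=s.seed,
        C=s.C,
        n_pre=s.n_pre,
        n_post_train=s.n_post_train,
        n_post_test=s.n_post_test,
        visits_range=(s.visits_min, s.visits_max),
        codes_per_visit=s.codes_per_visit,
        pre_rates_for=lambda rng: (s.base_rates, 1),
        post_rates=s.post_rates,
        beta=s.risk_coefficients,
        intercept=s.intercept,
        pre_split_fractions=s.pre_split_fractions,
    )
    return cohort


def generate_mixture_cohort(scenario: MixtureScenario) -> tuple[Cohort, np.ndarray]:
    """Generate a mixture cohort and the ground-truth membership vector.

    Returns ``(cohort, membership)`` where ``membership[i]`` is 1 if
    pre-shift patient ``i`` was drawn from subpopulation A (the one the
    post-shift environment retains) and 0 for B.  The closed-form optimal
    importance weight is ``membership / pi``.
    """
    s = scenario

    def pre_rates_for(rng: np.random.Generator):
        if rng.random() < s.pi:
            return s.rates_a, 1
        return s.rates_b, 0

    return _generate(
        seed=s.seed,
        C=s.C,
        n_pre=s.n_pre,
        n_post_train=s.n_post_train,
        n_post_test=s.n_post_test,
        visits_range=(s.visits_min, s.visits_max),
        codes_per_visit=s.codes_per_visit,
        pre_rates_for=pre_rates_for,
        post_rates=s.rates_a,
        beta=s.risk_coefficients,
        intercept=s.intercept,
        pre_split_fractions=s.pre_split_fractions,
    )


def no_shift_scenario(**kwargs) -> ShiftScenario:
    """A scenario whose pre and post environments share one distribution."""
    s = ShiftScenario(**kwargs)
    return replace(s, shift_multipliers=np.ones(s.C))
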