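"""Interrater agreement statistics for paired blinded judgements.

Each study visit is judged independently by two physicians (is the visit
suitable for subacute primary care: yes/no, plus a 1-5 confidence score).
After randomised assignment the two rating slots of a visit carry no stable
rater identity, so the default chance-corrected agreement coefficient uses a
single marginal pooled across both slots (the symmetric Scott/Byrt-style
treatment).  With ``po`` the observed proportion of concordant pairs and
``p`` the pooled probability of a "subacute" rating,

    pe    = p**2 + (1 - p)**2
    kappa = (po - pe) / (1 - pe)

This pooled estimator is invariant to swapping the two slots of any pair,
which classical two-rater Cohen's kappa is not; on data with attributed
raters and symmetric marginals the two coincide.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import EDACClass

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054


class KappaUndefinedError(ArithmeticError):
    """Chance agreement is 1 (all ratings identical): kappa has no value.

    Raised distinctly from computational failures so callers can treat
    degenerate subsets (e.g. bootstrap resamples) specially.
    """


@dataclass(frozen=True)
class JudgementPair:
    """The two blinded ratings of one visit.

    ``rating_a`` / ``rating_b`` are True when the rater judged the visit
    suitable for subacute primary care.  The a/b slots are unordered labels:
    no statistic in this module may depend on slot order.  Confidences are
    optional because reconstructed reference data carry none.
    """

    visit_id: str
    edac_class: EDACClass
    rating_a: bool
    rating_b: bool
    confidence_a: Optional[int] = None
    confidence_b: Optional[int] = None

    def __post_init__(self):
        for c in (self.confidence_a, self.confidence_b):
            if c is not None and c not in (1, 2, 3, 4, 5):
                raise ValueError(f"confidence must be in 1..5, got {c!r}")

    @property
    def concordant(self) -> bool:
        return self.rating_a == self.rating_b

    def swapped(self) -> "JudgementPair":
        return JudgementPair(
            self.visit_id,
            self.edac_class,
            self.rating_b,
            self.rating_a,
            self.confidence_b,
            self.confidence_a,
        )


@dataclass(frozen=True)
class AgreementResult:
    po: float
    pe: float
    kappa: float
    ci_low: float
    ci_high: float
    n_pairs: int
    method: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "po": self.po,
            "pe": self.pe,
            "kappa": self.kappa,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pairs": self.n_pairs,
            "method": self.method,
        }


def percent_agreement(pairs: Sequence[JudgementPair]) -> tuple[float, int]:
    """Observed agreement: (proportion concordant, count concordant)."""
    if not pairs:
        raise ValueError("no judgement pairs supplied")
    count = sum(p.concordant for p in pairs)
    return count / len(pairs), count


def pooled_kappa(pairs: Sequence[JudgementPair]) -> AgreementResult:
    """Chance-corrected agreement with the pooled two-slot marginal.

    The 95% CI is the large-sample Wald interval with
    ``SE = sqrt(po (1-po) / n) / (1 - pe)`` and the upper bound capped at 1
    (kappa cannot exceed 1).
    """
    if not pairs:
        raise ValueError("no judgement pairs supplied")
    n = len(pairs)
    po, _ = percent_agreement(pairs)
    n_subacute = sum(int(p.rating_a) + int(p.rating_b) for p in pairs)
    p = n_subacute / (2 * n)
    pe = p * p + (1 - p) * (1 - p)
    if pe >= 1.0 - 1e-15:
        raise KappaUndefinedError(
            "all ratings identical: chance agreement is 1, kappa undefined"
        )
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(max(po * (1 - po), 0.0) / n) / (1 - pe)
    return AgreementResult(
        po=po,
        pe=pe,
        kappa=kappa,
        ci_low=kappa - _Z975 * se,
        ci_high=min(kappa + _Z975 * se, 1.0),
        n_pairs=n,
        method="pooled",
    )


def per_class_kappa(
    pairs: Sequence[JudgementPair], edac_class: EDACClass
) -> AgreementResult:
    """Pooled kappa restricted to the pairs of one EDAC class."""
    subset = [p for p in pairs if p.edac_class == edac_class]
    if not subset:
        raise ValueError(f"no pairs in class {edac_class.name}")
    return pooled_kappa(subset)


def cohen_kappa_2x2(n11: int, n10: int, n01: int, n00: int) -> float:
    """Classical two-rater Cohen's kappa from an attributed 2x2 table.

    Cell ``nij``: rater 1 gave i, rater 2 gave j (1 = subacute).  Used as the
    small-case oracle for the pooled estimator and for attribution-robustness
    checks; not the default estimator because slot attribution is not
    recoverable from anonymised pairs.
    """
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise ValueError("empty table")
    po = (n11 + n00) / n
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    pe = p1 * p2 + (1 - p1) * (1 - p2)
    if pe >= 1.0 - 1e-15:
        raise KappaUndefinedError("degenerate marginals")
    return (po - pe) / (1 - pe)


#: Landis-Koch interpretation bands (upper bound inclusive).
_LANDIS_KOCH = [
    (0.00, "poor agreement"),
    (0.20, "slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.00, "almost perfect agreement"),
]


def kappa_interpretation(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa coefficient.

    Below 0 is "poor"; bands at 0-0.20, 0.21-0.40, 0.41-0.60, 0.61-0.80 and
    0.81-1.00.  Band edges belong to the lower band (0.20 is "slight").
    """
    if kappa > 1:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0:
        return "poor agreement"
    for upper, label in _LANDIS_KOCH[1:]:
        if kappa <= upper + 1e-12:
            return label
    return "almost perfect agreement"


def confidence_summary(
    pairs: Sequence[JudgementPair], by_class: bool = False
) -> dict:
    """Mean and sample SD of confidence scores, pooled over both slots.

    Returns ``{"mean":..., "sd":..., "n":...}`` or, with ``by_class``, a
    mapping from class label to that summary.  Pairs without confidence data
    are excluded; an input with no confidences at all is an error.
    """
    if not pairs:
        raise ValueError("no judgement pairs supplied")
    if by_class:
        out = {}
        for cls in EDACClass:
            subset = [p for p in pairs if p.edac_class == cls]
            if subset:
                out[cls.label] = confidence_summary(subset, by_class=False)
        return out
    scores = [
        c
        for p in pairs
        for c in (p.confidence_a, p.confidence_b)
        if c is not None
    ]
    if not scores:
        raise ValueError("no confidence scores present")
    arr = np.asarray(scores, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd, "n": int(arr.size)}


def bootstrap_ci(
    pairs: Sequence[JudgementPair],
    statistic: Callable[[Sequence[JudgementPair]], float],
    reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a visit-level statistic.

    Resamples whole pairs (the visit is the sampling unit).  Resamples on
    which the statistic is undefined (e.g. kappa with a degenerate marginal)
    are dropped with a logged count.
    """
    if reps < 200:
        raise ValueError("reps must be at least 200 for a percentile interval")
    if not pairs:
        raise ValueError("no judgement pairs supplied")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    values = []
    dropped = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        resample = [pairs[i] for i in idx]
        try:
            values.append(statistic(resample))
        except KappaUndefinedError:
            dropped += 1
    if dropped:
        logger.info("bootstrap_ci: dropped %d degenerate resamples", dropped)
    if not values:
        raise KappaUndefinedError("statistic undefined on every resample")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(values, [alpha, 1 - alpha])
    return float(lo), float(hi)
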