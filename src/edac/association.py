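"""EDAC-versus-judgement association analyses.

The two blinded binary judgements of a visit collapse to a three-level
ordinal concordance outcome: both judged ED-only (0) < discordant (1) < both
judged subacute-suitable (2).  Cross-classifying that outcome against the
three EDAC classes gives the study's central 3x3 concordance table, from
which this module computes

* a tie-corrected Spearman rank correlation between the two ordinal scales,
* a proportional-odds (cumulative-logit) regression of the concordance level
  on dummy-coded EDAC class (not-avoidable referent), fitted by damped
  Newton iteration on the multinomial likelihood,
* closed-form odds ratios with Wald CIs for the dichotomy "both judged
  subacute" vs rest (the published headline ORs are exactly these
  cross-product ratios), and
* Harrell's concordance index for per-class risk scores against the ordinal
  outcome.

Count tables are never expanded to observation lists; all statistics use
weighted closed forms.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .agreement import JudgementPair
from .core import EDACClass

_Z975 = 1.959963984540054


class ConcordanceLevel(enum.IntEnum):
    """Ordinal concordance of a visit's two judgements."""

    BOTH_ED = 0
    DISCORDANT = 1
    BOTH_SUBACUTE = 2


def ordinalize(pair: JudgementPair) -> ConcordanceLevel:
    """Map a judgement pair to its concordance level."""
    if pair.rating_a and pair.rating_b:
        return ConcordanceLevel.BOTH_SUBACUTE
    if not pair.rating_a and not pair.rating_b:
        return ConcordanceLevel.BOTH_ED
    return ConcordanceLevel.DISCORDANT


@dataclass(frozen=True)
class ConcordanceTable:
    """3x3 counts of EDAC class (rows) by concordance level (columns).

    Rows are indexed by :class:`EDACClass` (NOT < POT < AVOID) and columns by
    :class:`ConcordanceLevel` (BOTH_ED < DISCORDANT < BOTH_SUBACUTE).
    """

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (3, 3):
            raise ValueError(f"expected a 3x3 count table, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_pairs(cls, pairs: Sequence[JudgementPair]) -> "ConcordanceTable":
        if not pairs:
            raise ValueError("no judgement pairs supplied")
        arr = np.zeros((3, 3), dtype=int)
        for p in pairs:
            arr[int(p.edac_class), int(ordinalize(p))] += 1
        return cls(arr)

    @classmethod
    def from_class_rows(cls, rows: dict) -> "ConcordanceTable":
        """Build from ``{EDACClass: (both_ed, discordant, both_subacute)}``."""
        arr = np.zeros((3, 3), dtype=int)
        for c, row in rows.items():
            arr[int(EDACClass(c))] = row
        return cls(arr)

    def row(self, edac_class: EDACClass) -> np.ndarray:
        return self.counts[int(edac_class)]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_agreements(self) -> int:
        """Pairs whose two ratings agree (both-ED or both-subacute)."""
        return int(self.counts[:, [0, 2]].sum())

    def subset(self, classes: Sequence[EDACClass]) -> "ConcordanceTable":
        """Zero out the rows of all classes not listed."""
        arr = np.zeros_like(self.counts)
        for c in classes:
            arr[int(c)] = self.counts[int(c)]
        return ConcordanceTable(arr)

    def to_pairs(self) -> list[JudgementPair]:
        """Expand to anonymous judgement pairs (no confidences).

        Discordant pairs are emitted as (True, False); every statistic in
        this package is slot-swap invariant so the attribution is
        inconsequential.
        """
        pairs = []
        i = 0
        for c in EDACClass:
            for level, ratings in [
                (ConcordanceLevel.BOTH_ED, (False, False)),
                (ConcordanceLevel.DISCORDANT, (True, False)),
                (ConcordanceLevel.BOTH_SUBACUTE, (True, True)),
            ]:
                for _ in range(self.counts[int(c), int(level)]):
                    pairs.append(
                        JudgementPair(f"v{i:04d}", c, ratings[0], ratings[1])
                    )
                    i += 1
        return pairs


def concordance_table(pairs: Sequence[JudgementPair]) -> ConcordanceTable:
    """Cross-classify pairs by (EDAC class, concordance level)."""
    return ConcordanceTable.from_pairs(pairs)


def spearman_ordinal(table: ConcordanceTable) -> float:
    """Tie-corrected Spearman correlation between the two ordinal margins.

    Equivalent to the Pearson correlation of midranks over the expanded
    observations, computed here directly from the cell counts.  Undefined
    (raises ``ArithmeticError``) when either margin is degenerate.
    """
    n = table.total
    if n < 2:
        raise ValueError("need at least two observations")
    rmarg = table.row_margins.astype(float)
    cmarg = table.col_margins.astype(float)
    if (rmarg > 0).sum() < 2 or (cmarg > 0).sum() < 2:
        raise ArithmeticError("degenerate margin: correlation undefined")

    def midranks(margin: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(margin)])
        return cum[:-1] + (margin + 1) / 2.0

    rx = midranks(rmarg)  # rank of each EDAC class
    ry = midranks(cmarg)  # rank of each concordance level
    w = table.counts.astype(float)
    mean = (n + 1) / 2.0
    dx = rx - mean
    dy = ry - mean
    cov = float(dx @ w @ dy)
    vx = float((rmarg * dx**2).sum())
    vy = float((cmarg * dy**2).sum())
    return cov / math.sqrt(vx * vy)


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class OrdinalFit:
    """A fitted proportional-odds model on the concordance outcome.

    ``thresholds`` are the two cumulative-logit intercepts (theta1 < theta2);
    ``beta`` maps each non-referent class label to its coefficient; the
    referent (not avoidable) has OR 1 by construction.
    """

    thresholds: tuple[float, float]
    beta: dict[str, float]
    vcov: np.ndarray
    or_point: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    cindex: float
    loglik: float
    n_iter: int
    separation_warning: bool = False
    trace: list = field(default_factory=list, repr=False)


def _po_loglik_grad_hess(params: np.ndarray, X: np.ndarray, W: np.ndarray):
    """Log-likelihood, gradient and Hessian of the cumulative-logit model.

    ``params = (theta1, theta2, beta...)``; ``X`` is (patterns, p) and ``W``
    (patterns, 3) holds outcome counts per covariate pattern.  Model:
    P(Y <= j | x) = expit(theta_j - x beta).
    """
    theta = params[:2]
    beta = params[2:]
    eta = X @ beta  # (patterns,)

    def expit(z):
        return 1.0 / (1.0 + np.exp(-z))

    g1 = expit(theta[0] - eta)  # P(Y<=0)
    g2 = expit(theta[1] - eta)  # P(Y<=1)
    probs = np.stack([g1, g2 - g1, 1.0 - g2], axis=1)
    probs = np.clip(probs, 1e-300, None)
    ll = float((W * np.log(probs)).sum())

    npar = params.size
    grad = np.zeros(npar)
    hess = np.zeros((npar, npar))
    # derivative of g_j wrt theta_j is g_j(1-g_j); wrt beta is -g_j(1-g_j) x
    d1 = g1 * (1 - g1)
    d2 = g2 * (1 - g2)
    for i in range(X.shape[0]):
        x = X[i]
        w = W[i]
        p0, p1, p2 = probs[i]
        # score contributions per category wrt (theta1, theta2, beta)
        # d log p0 = d g1 / p0 ; d log p1 = (d g2 - d g1)/p1 ; d log p2 = -d g2 / p2
        dg1 = np.concatenate([[d1[i], 0.0], -d1[i] * x])
        dg2 = np.concatenate([[0.0, d2[i]], -d2[i] * x])
        s0 = dg1 / p0
        s1 = (dg2 - dg1) / p1
        s2 = -dg2 / p2
        grad += w[0] * s0 + w[1] * s1 + w[2] * s2
        # expected information for this pattern (Fisher scoring Hessian)
        ntot = w.sum()
        if ntot > 0:
            info = ntot * (
                np.outer(s0, s0) * p0 + np.outer(s1, s1) * p1 + np.outer(s2, s2) * p2
            )
            hess -= info
    return ll, grad, hess


def fit_cumulative_logit(table: ConcordanceTable) -> OrdinalFit:
    """Proportional-odds ML fit of concordance level on EDAC class dummies.

    Fisher-scoring Newton iteration with step-halving so the log-likelihood
    never decreases; converged when the gradient max-norm drops below 1e-8
    (at most 100 iterations, else :class:`ConvergenceError` with the trace).
    A class row concentrated entirely at one extreme outcome level is flagged
    with an inflated-variance warning (quasi-separation).
    """
    counts = table.counts
    present = counts.sum(axis=1) > 0
    if not present.all():
        raise ValueError("every EDAC class row must be non-empty")
    if (counts.sum(axis=0) > 0).sum() < 2:
        raise ValueError("outcome must have at least two observed levels")

    separated = False
    for r in range(3):
        row = counts[r]
        if row.sum() > 0 and (row[0] == row.sum() or row[2] == row.sum()):
            separated = True
            warnings.warn(
                "a class row lies entirely at one extreme concordance level; "
                "estimates near the boundary, variances inflated",
                RuntimeWarning,
                stacklevel=2,
            )

    # covariate patterns: one per class; dummies for POT and AVOID
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    W = counts.astype(float)

    # start: intercepts at marginal cumulative logits, beta 0
    cum = W.sum(axis=0).cumsum() / W.sum()
    eps = 1e-6
    c1 = min(max(cum[0], eps), 1 - eps)
    c2 = min(max(cum[1], eps), 1 - eps)
    params = np.array([math.log(c1 / (1 - c1)), math.log(c2 / (1 - c2)), 0.0, 0.0])

    ll, grad, hess = _po_loglik_grad_hess(params, X, W)
    trace = [(0, ll, float(np.abs(grad).max()))]
    n_iter = 0
    for n_iter in range(1, 101):
        if np.abs(grad).max() < 1e-8:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian: {exc}", trace) from exc
        # damped step: halve until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(40):
            cand = params + scale * step
            if cand[0] < cand[1]:
                ll_new, grad_new, hess_new = _po_loglik_grad_hess(cand, X, W)
                if ll_new >= ll - 1e-12:
                    break
            scale *= 0.5
        else:
            raise ConvergenceError("step-halving exhausted", trace)
        params, ll, grad, hess = cand, ll_new, grad_new, hess_new
        trace.append((n_iter, ll, float(np.abs(grad).max())))
    else:
        raise ConvergenceError("no convergence in 100 iterations", trace)
    if np.abs(grad).max() >= 1e-8:
        raise ConvergenceError("no convergence in 100 iterations", trace)

    vcov = np.linalg.inv(-hess)
    beta = {
        EDACClass.POTENTIALLY_AVOIDABLE.label: float(params[2]),
        EDACClass.AVOIDABLE.label: float(params[3]),
    }
    def safe_exp(z: float) -> float:
        # separation inflates SEs; an overflowing Wald bound is +inf
        return math.exp(z) if z < 700 else math.inf

    or_point, or_ci = {}, {}
    for k, idx in ((EDACClass.POTENTIALLY_AVOIDABLE.label, 2), (EDACClass.AVOIDABLE.label, 3)):
        se = math.sqrt(vcov[idx, idx])
        or_point[k] = safe_exp(params[idx])
        or_ci[k] = (
            safe_exp(params[idx] - _Z975 * se),
            safe_exp(params[idx] + _Z975 * se),
        )
    or_point[EDACClass.NOT_AVOIDABLE.label] = 1.0
    scores = {
        EDACClass.NOT_AVOIDABLE: 0.0,
        EDACClass.POTENTIALLY_AVOIDABLE: beta[EDACClass.POTENTIALLY_AVOIDABLE.label],
        EDACClass.AVOIDABLE: beta[EDACClass.AVOIDABLE.label],
    }
    return OrdinalFit(
        thresholds=(float(params[0]), float(params[1])),
        beta=beta,
        vcov=vcov,
        or_point=or_point,
        or_ci=or_ci,
        cindex=ordinal_cindex(table, scores),
        loglik=ll,
        n_iter=n_iter,
        separation_warning=separated,
        trace=trace,
    )


def intercept_only_cumulative_logits(table: ConcordanceTable) -> tuple[float, float]:
    """Closed-form thresholds of the intercept-only model: observed cumulative logits."""
    marg = table.col_margins.astype(float)
    cum = marg.cumsum() / marg.sum()
    if not (0 < cum[0] and cum[1] < 1):
        raise ArithmeticError("boundary cumulative proportion: logit undefined")
    return (
        math.log(cum[0] / (1 - cum[0])),
        math.log(cum[1] / (1 - cum[1])),
    )


def reported_or(
    table: ConcordanceTable,
    edac_class: EDACClass,
    continuity: bool = False,
) -> tuple[float, tuple[float, float]]:
    """Headline odds ratio for one class vs the not-avoidable referent.

    Dichotomises the outcome at "both judged subacute" vs rest and returns
    the cross-product ratio with the Wald CI
    ``exp(ln OR +/- 1.96 sqrt(sum 1/cell))``.  This closed form is the
    estimator behind the published per-class ORs.  Zero cells are an error
    unless ``continuity`` adds the 0.5 Haldane-Anscombe correction.
    """
    if edac_class == EDACClass.NOT_AVOIDABLE:
        return 1.0, (1.0, 1.0)
    row = table.row(edac_class).astype(float)
    ref = table.row(EDACClass.NOT_AVOIDABLE).astype(float)
    a = row[int(ConcordanceLevel.BOTH_SUBACUTE)]
    b = row.sum() - a
    c = ref[int(ConcordanceLevel.BOTH_SUBACUTE)]
    d = ref.sum() - c
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ZeroDivisionError(
                "zero cell in the dichotomised 2x2 table; "
                "set continuity=True for the 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orv = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(orv)
    return orv, (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))


def ordinal_cindex(table: ConcordanceTable, scores: dict | None = None) -> float:
    """Harrell's C of per-class scores against the ordinal concordance level.

    Over all observation pairs with different outcome levels: the fraction in
    which the higher outcome carries the higher class score, ties in score
    counted half.  Defaults to the EDAC ordinal ranks as scores.
    """
    if scores is None:
        scores = {c: float(int(c)) for c in EDACClass}
    counts = table.counts
    concordant = 0.0
    tied = 0.0
    total = 0.0
    cells = [
        (scores[EDACClass(r)], lvl, counts[r, lvl])
        for r in range(3)
        for lvl in range(3)
        if counts[r, lvl] > 0
    ]
    for i, (si, yi, ni) in enumerate(cells):
        for sj, yj, nj in cells[i + 1 :]:
            if yi == yj:
                continue
            w = ni * nj
            total += w
            if si == sj:
                tied += w
            elif (si > sj) == (yi > yj):
                concordant += w
    if total == 0:
        raise ArithmeticError("no informative pairs: c-index undefined")
    return (concordant + 0.5 * tied) / total
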