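"""Clustered sampling, blinded dual-rater assignment, and kappa power.

The validation design clusters the candidate visit pool by EDAC class,
samples the clusters evenly, and assigns each sampled visit to two distinct
physician raters.  Each rater receives a fixed-size batch whose cluster
composition is (near-)balanced — e.g. 20 visits split 7/7/6 across the three
clusters — with the cluster carrying the short count rotated across raters
so aggregate per-cluster rating totals stay balanced.  Rater-facing plan
output never carries the EDAC class (raters are blinded to it).

Sample-size planning for the agreement criterion is done by Monte-Carlo
simulation: paired binary judgements are generated from the
common-correlation model (joint probabilities fixed by the marginal
prevalence and kappa) and the pooled-kappa Wald z-test against the null
coefficient is applied to each replicate.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .core import EDACClass

_CLUSTER_ORDER = (
    EDACClass.AVOIDABLE,
    EDACClass.POTENTIALLY_AVOIDABLE,
    EDACClass.NOT_AVOIDABLE,
)


class InfeasibleDesignError(ValueError):
    """The requested design arithmetic cannot be satisfied."""


def stratified_sample(
    labeled_visits: Mapping[str, EDACClass], total_n: int, seed: int
) -> list[str]:
    """Sample ``total_n`` visits evenly across the three EDAC clusters.

    Per-cluster counts differ by at most one; when ``total_n`` is not
    divisible by 3 the remainder goes to clusters in the fixed order
    avoidable, potentially avoidable, not avoidable (so 160 realises
    54/53/53).  Sampling is uniform without replacement within cluster and
    reproducible under ``seed``.
    """
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    base, rem = divmod(total_n, 3)
    targets = {c: base for c in _CLUSTER_ORDER}
    for c in _CLUSTER_ORDER[:rem]:
        targets[c] += 1

    by_cluster: dict[EDACClass, list[str]] = {c: [] for c in _CLUSTER_ORDER}
    for vid, cls in labeled_visits.items():
        by_cluster[EDACClass(cls)].append(vid)

    rng = np.random.default_rng(seed)
    sample: list[str] = []
    for c in _CLUSTER_ORDER:
        pool = sorted(by_cluster[c])  # order-independent determinism
        if len(pool) < targets[c]:
            raise InfeasibleDesignError(
                f"cluster {c.label} has {len(pool)} candidates, "
                f"needs {targets[c]}"
            )
        chosen = rng.choice(len(pool), size=targets[c], replace=False)
        sample.extend(pool[i] for i in sorted(chosen))
    return sample


@dataclass(frozen=True)
class AssignmentPlan:
    """Visit-to-rater assignments satisfying the dual-rating design.

    ``assignments`` holds (rater_id, visit_id, round_index) triples;
    ``batch_composition`` maps (rater_id, round_index) to per-cluster visit
    counts in the order (avoidable, potentially avoidable, not avoidable).
    The plan rows are deliberately class-free: raters are blinded.
    """

    assignments: list[tuple[str, str, int]]
    batch_composition: dict[tuple[str, int], tuple[int, int, int]] = field(
        default_factory=dict
    )

    def raters_of(self, visit_id: str) -> list[str]:
        return [r for r, v, _ in self.assignments if v == visit_id]

    def to_rows(self) -> list[dict]:
        return [
            {"rater_id": r, "visit_id": v, "round": rd}
            for r, v, rd in self.assignments
        ]


def _rotation_quotas(
    n_units: int, composition: tuple[int, int, int], needed: tuple[int, int, int]
) -> list[tuple[int, int, int]]:
    """Assign a permutation of ``composition`` to each rater-round unit so
    column totals equal ``needed`` exactly (greedy largest-to-largest)."""
    remaining = list(needed)
    quotas = []
    comp_sorted = sorted(composition, reverse=True)
    for _ in range(n_units):
        order = sorted(range(3), key=lambda c: -remaining[c])
        q = [0, 0, 0]
        for val, c in zip(comp_sorted, order):
            q[c] = val
        quotas.append(tuple(q))
        for c in range(3):
            remaining[c] -= q[c]
    if any(r != 0 for r in remaining):
        raise InfeasibleDesignError(
            f"cannot tile composition {composition} into per-cluster totals "
            f"{needed}: residual {tuple(remaining)}"
        )
    return quotas


def build_assignment(
    sample: Sequence[tuple[str, EDACClass]],
    raters_round1: Sequence[str],
    raters_round2: Sequence[str],
    batch_size: int,
    composition: tuple[int, int, int],
    seed: int,
) -> AssignmentPlan:
    """Assign every sampled visit to two distinct raters.

    Each (rater, round) unit receives exactly ``batch_size`` visits whose
    cluster composition is a permutation of ``composition``; permutations
    rotate across units so aggregate per-cluster totals land exactly on
    twice the cluster sizes.  Within a cluster, the two copies of each visit
    go to the two rater identities with the largest remaining quota
    (random tie-break), which never pairs a visit with itself and succeeds
    whenever no single rater holds more than half the cluster's remaining
    rating slots.
    """
    if sum(composition) != batch_size:
        raise InfeasibleDesignError(
            f"composition {composition} does not sum to batch size {batch_size}"
        )
    n_units = len(raters_round1) + len(raters_round2)
    if n_units * batch_size != 2 * len(sample):
        raise InfeasibleDesignError(
            f"{n_units} rater batches of {batch_size} provide "
            f"{n_units * batch_size} ratings but {2 * len(sample)} are needed"
        )
    if len(set(raters_round1)) != len(raters_round1):
        raise InfeasibleDesignError("duplicate rater ids within round 1")
    if len(set(raters_round2)) != len(raters_round2):
        raise InfeasibleDesignError("duplicate rater ids within round 2")

    by_cluster: dict[EDACClass, list[str]] = {c: [] for c in _CLUSTER_ORDER}
    for vid, cls in sample:
        by_cluster[EDACClass(cls)].append(vid)
    needed = tuple(2 * len(by_cluster[c]) for c in _CLUSTER_ORDER)

    units = [(r, 1) for r in raters_round1] + [(r, 2) for r in raters_round2]
    rng = np.random.default_rng(seed)
    unit_order = list(rng.permutation(len(units)))
    quotas_seq = _rotation_quotas(len(units), composition, needed)
    quotas = {units[u]: list(quotas_seq[k]) for k, u in enumerate(unit_order)}

    assignments: list[tuple[str, str, int]] = []
    for ci, cluster in enumerate(_CLUSTER_ORDER):
        visits = list(by_cluster[cluster])
        rng.shuffle(visits)
        # remaining rating slots for this cluster, aggregated per rater id
        unit_rem = {u: quotas[u][ci] for u in units if quotas[u][ci] > 0}
        for vid in visits:
            picks = _pick_two_distinct(unit_rem, rng)
            if picks is None:
                raise InfeasibleDesignError(
                    f"cannot find two distinct raters for visit {vid!r} in "
                    f"cluster {cluster.label}"
                )
            for rater, rnd in picks:
                assignments.append((rater, vid, rnd))
                unit_rem[(rater, rnd)] -= 1
                if unit_rem[(rater, rnd)] == 0:
                    del unit_rem[(rater, rnd)]

    composition_map = {u: tuple(quotas[u]) for u in units}
    plan = AssignmentPlan(
        assignments=sorted(assignments), batch_composition=composition_map
    )
    _check_plan(plan, sample, composition_map, batch_size)
    return plan


def _pick_two_distinct(unit_rem: dict, rng: np.random.Generator):
    """Two (rater, round) units with distinct rater ids, largest remaining
    quota first (per rater id, summed over rounds), random tie-break."""
    by_rater: dict[str, int] = {}
    for (r, _), q in unit_rem.items():
        by_rater[r] = by_rater.get(r, 0) + q
    if len(by_rater) < 2:
        return None
    raters = list(by_rater)
    jitter = {r: rng.random() for r in raters}
    raters.sort(key=lambda r: (-by_rater[r], jitter[r]))
    picks = []
    for r in raters[:2]:
        cand = [(u, q) for u, q in unit_rem.items() if u[0] == r]
        cand.sort(key=lambda t: -t[1])
        picks.append(cand[0][0])
    return picks


def _check_plan(plan, sample, composition_map, batch_size):
    from collections import Counter

    per_visit = Counter(v for _, v, _ in plan.assignments)
    assert all(per_visit[v] == 2 for v, _ in sample), "each visit must be rated twice"
    for vid, _ in sample:
        rs = plan.raters_of(vid)
        assert len(set(rs)) == 2, f"visit {vid} needs two distinct raters"
    per_unit = Counter((r, rd) for r, _, rd in plan.assignments)
    assert all(n == batch_size for n in per_unit.values())
    assert all(sum(c) == batch_size for c in composition_map.values())


@dataclass(frozen=True)
class PowerSpec:
    """Design point for the kappa power simulation.

    ``kappa_null`` is the coefficient tested against (H0), ``kappa_alt`` the
    coefficient generating the data, ``marginal_prevalence`` the probability
    a single rating is "subacute-suitable".
    """

    kappa_null: float
    kappa_alt: float
    marginal_prevalence: float
    n_visits: int
    alpha: float = 0.05
    reps: int = 2000
    seed: int = 0

    def __post_init__(self):
        # kappa_alt == kappa_null is allowed: it is the null-calibration check
        if not (0 <= self.kappa_null <= self.kappa_alt <= 1):
            raise ValueError("need 0 <= kappa_null <= kappa_alt <= 1")
        if not (0 < self.marginal_prevalence < 1):
            raise ValueError("marginal_prevalence must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_visits < 2 or self.reps < 1:
            raise ValueError("n_visits >= 2 and reps >= 1 required")


def pair_probabilities(prevalence: float, kappa: float) -> np.ndarray:
    """Joint (both-ED, discordant-a, discordant-b, both-subacute) cell
    probabilities of the common-correlation binary pair model."""
    p, q = prevalence, 1 - prevalence
    pq = p * q
    probs = np.array(
        [q * q + kappa * pq, (1 - kappa) * pq, (1 - kappa) * pq, p * p + kappa * pq]
    )
    if (probs < -1e-12).any():
        raise ValueError("kappa incompatible with the marginal prevalence")
    return np.clip(probs, 0.0, 1.0)


def simulate_power(spec: PowerSpec) -> tuple[float, float]:
    """Monte-Carlo power of the two-sided pooled-kappa Wald z-test.

    Returns ``(power, monte_carlo_se)``.  Each replicate draws ``n_visits``
    rating pairs at ``kappa_alt``, computes the pooled kappa and its
    large-sample SE, and rejects when ``|kappa_hat - kappa_null| / SE``
    exceeds the two-sided normal critical value.  Replicates with a
    degenerate marginal (SE zero or chance agreement 1) never reject.
    """
    rng = np.random.default_rng(spec.seed)
    probs = pair_probabilities(spec.marginal_prevalence, spec.kappa_alt)
    zc = norm.ppf(1 - spec.alpha / 2)
    n = spec.n_visits
    counts = rng.multinomial(n, probs, size=spec.reps)
    n00, n01, n10, n11 = counts.T
    po = (n00 + n11) / n
    pm = (2 * n11 + n01 + n10) / (2 * n)
    pe = pm**2 + (1 - pm) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1 - pe)
        se = np.sqrt(po * (1 - po) / n) / (1 - pe)
        z = np.abs(kappa - spec.kappa_null) / se
    reject = np.where(np.isfinite(z) & (se > 0), z > zc, False)
    power = float(reject.mean())
    mc_se = math.sqrt(power * (1 - power) / spec.reps)
    return power, mc_se
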