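"""Precision of the EDAC against rating-level physician judgements.

The middle (potentially avoidable) class has no natural binary home, so the
classifier is evaluated under three regroupings: excluding the middle class,
merging it with the avoidable class, and merging it with the not-avoidable
class.  The unit of analysis is the individual physician rating (two per
visit, 320 over the full study), not the visit.

Orientation convention (fixed by the study design, where the classifier's
"positive" claim is subacute suitability):

* sensitivity — of ratings on visits in the EDAC *negative* (not-avoidable)
  group, the fraction judged ED-appropriate;
* specificity — of ratings on visits in the EDAC *positive*
  (avoidable-side) group, the fraction judged subacute-appropriate.

Because this labelling is a convention, :func:`precision_stats` also reports
the opposite orientation explicitly.
"""

from __future__ import annotations

import enum
from collections.abc import Sequence
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .agreement import JudgementPair
from .association import ConcordanceLevel, ConcordanceTable
from .core import EDACClass


class Scenario(enum.Enum):
    """Handling of the potentially-avoidable class."""

    EXCLUDE_POTENTIAL = "exclude_potential"
    POTENTIAL_AS_AVOIDABLE = "potential_as_avoidable"
    POTENTIAL_AS_NOT_AVOIDABLE = "potential_as_not_avoidable"


@dataclass(frozen=True)
class RatingTable:
    """Rating counts by EDAC grouping x judgement for one scenario.

    ``pos_*`` counts ratings of visits in the avoidable-side group,
    ``neg_*`` of visits in the not-avoidable-side group; the second part of
    each name is the physician judgement.
    """

    pos_subacute: int
    pos_ed: int
    neg_subacute: int
    neg_ed: int
    scenario: Scenario

    def __post_init__(self):
        if min(self.pos_subacute, self.pos_ed, self.neg_subacute, self.neg_ed) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.pos_subacute + self.pos_ed + self.neg_subacute + self.neg_ed


def _exact_ci(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return float(lo), float(hi)


@dataclass(frozen=True)
class PrecisionResult:
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    scenario: Scenario
    n_ratings: int

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario.value,
            "n_ratings": self.n_ratings,
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "sensitivity_negative_group_ed": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_positive_group_subacute": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            # opposite orientation, labelled, to avoid silent ambiguity
            "alt_sensitivity_positive_group_subacute": self.specificity,
            "alt_specificity_negative_group_ed": self.sensitivity,
        }
        return d


def _pair_rating_counts(pair: JudgementPair) -> tuple[int, int]:
    """(subacute ratings, ed ratings) contributed by one pair."""
    s = int(pair.rating_a) + int(pair.rating_b)
    return s, 2 - s


def _grouping(scenario: Scenario) -> dict[EDACClass, str | None]:
    g: dict[EDACClass, str | None] = {
        EDACClass.AVOIDABLE: "pos",
        EDACClass.NOT_AVOIDABLE: "neg",
    }
    if scenario is Scenario.EXCLUDE_POTENTIAL:
        g[EDACClass.POTENTIALLY_AVOIDABLE] = None
    elif scenario is Scenario.POTENTIAL_AS_AVOIDABLE:
        g[EDACClass.POTENTIALLY_AVOIDABLE] = "pos"
    else:
        g[EDACClass.POTENTIALLY_AVOIDABLE] = "neg"
    return g


def rating_table(pairs: Sequence[JudgementPair], scenario: Scenario) -> RatingTable:
    """Tabulate individual ratings by EDAC grouping under one scenario."""
    grouping = _grouping(scenario)
    counts = {"pos": [0, 0], "neg": [0, 0]}  # [subacute, ed]
    kept = 0
    for p in pairs:
        g = grouping[p.edac_class]
        if g is None:
            continue
        kept += 1
        s, e = _pair_rating_counts(p)
        counts[g][0] += s
        counts[g][1] += e
    if kept == 0:
        raise ValueError(f"no visits remain under scenario {scenario.value}")
    return RatingTable(
        pos_subacute=counts["pos"][0],
        pos_ed=counts["pos"][1],
        neg_subacute=counts["neg"][0],
        neg_ed=counts["neg"][1],
        scenario=scenario,
    )


def rating_table_from_concordance(
    table: ConcordanceTable, scenario: Scenario
) -> RatingTable:
    """Rating table from a concordance table (each pair -> two ratings).

    A both-subacute pair contributes two subacute ratings, a both-ED pair two
    ED ratings, a discordant pair one of each.
    """
    grouping = _grouping(scenario)
    counts = {"pos": [0, 0], "neg": [0, 0]}
    kept = 0
    for c in EDACClass:
        g = grouping[c]
        if g is None:
            continue
        row = table.row(c)
        kept += int(row.sum())
        be = int(row[int(ConcordanceLevel.BOTH_ED)])
        di = int(row[int(ConcordanceLevel.DISCORDANT)])
        bs = int(row[int(ConcordanceLevel.BOTH_SUBACUTE)])
        counts[g][0] += 2 * bs + di
        counts[g][1] += 2 * be + di
    if kept == 0:
        raise ValueError(f"no visits remain under scenario {scenario.value}")
    return RatingTable(
        pos_subacute=counts["pos"][0],
        pos_ed=counts["pos"][1],
        neg_subacute=counts["neg"][0],
        neg_ed=counts["neg"][1],
        scenario=scenario,
    )


def precision_stats(table: RatingTable) -> PrecisionResult:
    """Accuracy, sensitivity, specificity with exact (Clopper-Pearson) CIs.

    accuracy = (pos-group subacute + neg-group ed) / total;
    sensitivity = neg-group ed / neg-group total;
    specificity = pos-group subacute / pos-group total.
    """
    pos_total = table.pos_subacute + table.pos_ed
    neg_total = table.neg_subacute + table.neg_ed
    if table.total == 0:
        raise ZeroDivisionError("accuracy: empty rating table")
    if neg_total == 0:
        raise ZeroDivisionError("sensitivity: negative group is empty")
    if pos_total == 0:
        raise ZeroDivisionError("specificity: positive group is empty")
    acc_num = table.pos_subacute + table.neg_ed
    return PrecisionResult(
        accuracy=acc_num / table.total,
        accuracy_ci=_exact_ci(acc_num, table.total),
        sensitivity=table.neg_ed / neg_total,
        sensitivity_ci=_exact_ci(table.neg_ed, neg_total),
        specificity=table.pos_subacute / pos_total,
        specificity_ci=_exact_ci(table.pos_subacute, pos_total),
        scenario=table.scenario,
        n_ratings=table.total,
    )


def scenario_compare(
    source: Sequence[JudgementPair] | ConcordanceTable,
) -> dict:
    """The three scenario rows plus percentage-point deltas vs the baseline.

    Baseline is the exclude-the-middle-class scenario; deltas are (scenario -
    baseline) x 100 for each statistic.
    """
    if isinstance(source, ConcordanceTable):
        tables = {s: rating_table_from_concordance(source, s) for s in Scenario}
    else:
        tables = {s: rating_table(source, s) for s in Scenario}
    results = {s: precision_stats(t) for s, t in tables.items()}
    base = results[Scenario.EXCLUDE_POTENTIAL]
    deltas = {}
    for s, r in results.items():
        deltas[s.value] = {
            "accuracy_pp": 100 * (r.accuracy - base.accuracy),
            "sensitivity_pp": 100 * (r.sensitivity - base.sensitivity),
            "specificity_pp": 100 * (r.specificity - base.specificity),
        }
    return {
        "results": {s.value: r.to_dict() for s, r in results.items()},
        "deltas_vs_baseline": deltas,
    }
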