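"""Delimited-text readers/writers and the end-to-end study pipeline.

File conventions: comma-separated UTF-8 with a header row; header names are
canonicalised (trim, lowercase, internal whitespace to underscores);
booleans serialise as ``true``/``false``; judgement values as
``subacute``/``ed``.  Validation problems are collected with row numbers
and reported together rather than failing on the first bad row.

:func:`run_full_study` reproduces the complete validation report — cohort
descriptives, the agreement block (per-class kappas and interpretations),
the association block (Spearman, proportional-odds fit, headline ORs,
c-index) and the precision block (three regrouping scenarios, both
orientation labellings) — with provenance metadata for exact replay.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .agreement import (
    JudgementPair,
    KappaUndefinedError,
    confidence_summary,
    kappa_interpretation,
    per_class_kappa,
    percent_agreement,
    pooled_kappa,
)
from .association import (
    concordance_table,
    fit_cumulative_logit,
    ordinal_cindex,
    reported_or,
    spearman_ordinal,
)
from .core import EDACClass, EDVisit, ValidationError
from .precision import scenario_compare

logger = logging.getLogger(__name__)

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}

VISIT_REQUIRED = (
    "visit_id",
    "age",
    "ctas",
    "specialist_consult",
    "main_intervention",
    "outcome",
)
VISIT_OPTIONAL = (
    "sex",
    "arrival_mode",
    "day_of_week",
    "ed_minutes",
    "provider_service",
)
JUDGEMENT_COLUMNS = ("rater_id", "visit_id", "judgement", "confidence")


class TableValidationError(ValueError):
    """One or more rows failed validation; carries the itemised report."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        lines = "\n  ".join(problems)
        super().__init__(f"{path}: {len(problems)} validation problem(s):\n  {lines}")


def _canon_header(name: str) -> str:
    return "_".join(name.strip().lower().split())


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_visits(path: str | Path) -> list[EDVisit]:
    """Read a visit table, validating every row.

    Raises :class:`TableValidationError` listing each problem with its row
    number when any row is malformed.
    """
    path = Path(path)
    problems: list[str] = []
    visits: list[EDVisit] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableValidationError(path, ["empty file"])
        header = {_canon_header(h): h for h in reader.fieldnames}
        missing = [c for c in VISIT_REQUIRED if c not in header]
        if missing:
            raise TableValidationError(path, [f"missing column(s): {missing}"])
        for lineno, raw in enumerate(reader, start=2):
            row = {_canon_header(k): (v or "").strip() for k, v in raw.items() if k}
            try:
                vid = row["visit_id"]
                if vid in seen:
                    raise ValueError(f"duplicate visit_id {vid!r}")
                seen.add(vid)
                visit = EDVisit(
                    visit_id=vid,
                    age=int(row["age"]),
                    ctas=int(row["ctas"]),
                    specialist_consult=_parse_bool(row["specialist_consult"]),
                    main_intervention=row["main_intervention"],
                    outcome=row["outcome"].lower(),
                    sex=row.get("sex") or None,
                    arrival_mode=row.get("arrival_mode") or None,
                    day_of_week=row.get("day_of_week") or None,
                    ed_minutes=float(row["ed_minutes"]) if row.get("ed_minutes") else None,
                    provider_service=row.get("provider_service") or None,
                )
                visit.validate()
                visits.append(visit)
            except (ValueError, ValidationError, KeyError) as exc:
                problems.append(f"row {lineno}: {exc}")
    if problems:
        raise TableValidationError(path, problems)
    return visits


def write_visits(
    visits: Iterable[EDVisit],
    path: str | Path,
    classes: Mapping[str, EDACClass] | None = None,
) -> None:
    """Write a visit table; with ``classes``, append an ``edac_class`` column."""
    path = Path(path)
    cols = list(VISIT_REQUIRED + VISIT_OPTIONAL)
    if classes is not None:
        cols.append("edac_class")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for v in visits:
            row = [
                v.visit_id,
                v.age,
                v.ctas,
                "true" if v.specialist_consult else "false",
                v.main_intervention,
                v.outcome,
                v.sex or "",
                v.arrival_mode or "",
                v.day_of_week or "",
                "" if v.ed_minutes is None else v.ed_minutes,
                v.provider_service or "",
            ]
            if classes is not None:
                row.append(EDACClass(classes[v.visit_id]).label)
            writer.writerow(row)


def write_judgements(pairs: Iterable[JudgementPair], path: str | Path) -> None:
    """Write judgements in long form: one row per rating, two per visit."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(JUDGEMENT_COLUMNS)
        for p in pairs:
            for slot, rating, conf in (
                ("a", p.rating_a, p.confidence_a),
                ("b", p.rating_b, p.confidence_b),
            ):
                writer.writerow(
                    [
                        f"rater_{slot}",
                        p.visit_id,
                        "subacute" if rating else "ed",
                        "" if conf is None else conf,
                    ]
                )


def read_judgements(
    path: str | Path, classes: Mapping[str, EDACClass]
) -> list[JudgementPair]:
    """Read a long-form judgement table and pair ratings by visit.

    Every visit must appear exactly twice (with distinct rater ids) and have
    a known EDAC class in ``classes``; violations are itemised.
    """
    path = Path(path)
    rows: dict[str, list[tuple[str, bool, Optional[int]]]] = {}
    problems: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableValidationError(path, ["empty file"])
        header = {_canon_header(h): h for h in reader.fieldnames}
        missing = [c for c in JUDGEMENT_COLUMNS[:3] if c not in header]
        if missing:
            raise TableValidationError(path, [f"missing column(s): {missing}"])
        for lineno, raw in enumerate(reader, start=2):
            row = {_canon_header(k): (v or "").strip() for k, v in raw.items() if k}
            try:
                j = row["judgement"].lower()
                if j not in ("subacute", "ed"):
                    raise ValueError(f"judgement must be subacute|ed, got {j!r}")
                conf = int(row["confidence"]) if row.get("confidence") else None
                rows.setdefault(row["visit_id"], []).append(
                    (row["rater_id"], j == "subacute", conf)
                )
            except (ValueError, KeyError) as exc:
                problems.append(f"row {lineno}: {exc}")
    pairs: list[JudgementPair] = []
    for vid, ratings in rows.items():
        if len(ratings) != 2:
            problems.append(
                f"visit {vid!r}: expected exactly 2 ratings, found {len(ratings)}"
            )
            continue
        if ratings[0][0] == ratings[1][0]:
            problems.append(f"visit {vid!r}: both ratings from rater {ratings[0][0]!r}")
            continue
        if vid not in classes:
            problems.append(f"visit {vid!r}: no EDAC class available")
            continue
        pairs.append(
            JudgementPair(
                vid,
                EDACClass(classes[vid]),
                ratings[0][1],
                ratings[1][1],
                ratings[0][2],
                ratings[1][2],
            )
        )
    if problems:
        raise TableValidationError(path, problems)
    return pairs


def read_class_map(path: str | Path) -> dict[str, EDACClass]:
    """Read a keyed visit_id -> edac_class CSV (the unblinded key file)."""
    out: dict[str, EDACClass] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            row = {_canon_header(k): v.strip() for k, v in row.items() if k}
            out[row["visit_id"]] = EDACClass.from_label(row["edac_class"])
    return out


@dataclass
class RunConfig:
    """Paths, seeds and switches for one full-study run."""

    visits_path: Optional[str] = None
    judgements_path: Optional[str] = None
    registry_path: Optional[str] = None
    class_map_path: Optional[str] = None
    output_dir: str = "results"
    seed: int = 0
    ci_method: str = "wald"  # wald | bootstrap
    bootstrap_reps: int = 2000
    report_format: str = "json"  # json | markdown
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # output_dir is excluded: it locates the report, it does not affect
        # what is computed
        payload = json.dumps(
            {
                k: v
                for k, v in self.__dict__.items()
                if k not in ("extra", "output_dir")
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def cohort_descriptives(visits: Sequence[EDVisit], classes: Mapping[str, EDACClass]) -> dict:
    """Frequency tables of visit descriptors, overall and by EDAC class."""
    def summarise(subset: Sequence[EDVisit]) -> dict:
        out: dict = {"n": len(subset)}
        for attr in ("sex", "arrival_mode", "ctas", "day_of_week", "outcome", "provider_service"):
            counts = Counter(getattr(v, attr) for v in subset if getattr(v, attr) is not None)
            out[attr] = dict(sorted(counts.items(), key=lambda kv: str(kv[0])))
        minutes = [v.ed_minutes for v in subset if v.ed_minutes is not None]
        if minutes:
            import statistics

            out["ed_minutes_mean"] = statistics.fmean(minutes)
            out["ed_minutes_sd"] = statistics.stdev(minutes) if len(minutes) > 1 else 0.0
        return out

    report = {"all": summarise(visits)}
    for cls in EDACClass:
        subset = [v for v in visits if classes.get(v.visit_id) == cls]
        report[cls.label] = summarise(subset)
    return report


def study_report(
    pairs: Sequence[JudgementPair],
    visits: Sequence[EDVisit] | None = None,
    classes: Mapping[str, EDACClass] | None = None,
) -> dict:
    """The full validation report from paired judgements (and optional visits).

    Blocks appear in analysis order: descriptives, agreement, association,
    precision.  Confidence summaries are included only when the pairs carry
    confidence scores.
    """
    report: dict = {}
    if visits is not None and classes is not None:
        report["descriptives"] = cohort_descriptives(visits, classes)

    # agreement block
    po, n_agree = percent_agreement(pairs)
    agree: dict = {
        "n_pairs": len(pairs),
        "n_agreements": n_agree,
        "percent_agreement": po,
        "overall": _kappa_block(lambda: pooled_kappa(pairs)),
    }
    both_extremes = [
        p
        for p in pairs
        if p.edac_class in (EDACClass.AVOIDABLE, EDACClass.NOT_AVOIDABLE)
    ]
    if both_extremes:
        agree["avoidable_and_not_avoidable"] = _kappa_block(
            lambda: pooled_kappa(both_extremes)
        )
    for cls in EDACClass:
        if any(p.edac_class == cls for p in pairs):
            agree[cls.label] = _kappa_block(lambda c=cls: per_class_kappa(pairs, c))
    try:
        agree["confidence"] = confidence_summary(pairs, by_class=True)
        agree["confidence"]["all"] = confidence_summary(pairs, by_class=False)
    except ValueError:
        logger.info("no confidence scores present; confidence block omitted")
    report["agreement"] = agree

    # association block
    table = concordance_table(pairs)
    assoc: dict = {"concordance_table": table.counts.tolist()}
    assoc["spearman"] = spearman_ordinal(table)
    try:
        fit = fit_cumulative_logit(table)
        assoc["cumulative_logit"] = {
            "thresholds": list(fit.thresholds),
            "beta": fit.beta,
            "or_point": fit.or_point,
            "or_ci": {k: list(v) for k, v in fit.or_ci.items()},
            "loglik": fit.loglik,
            "n_iter": fit.n_iter,
        }
    except Exception as exc:  # pragma: no cover - degenerate tables only
        assoc["cumulative_logit"] = {"error": str(exc)}
    ors = {}
    for cls in (EDACClass.AVOIDABLE, EDACClass.POTENTIALLY_AVOIDABLE):
        point, ci = reported_or(table, cls, continuity=False)
        ors[cls.label] = {"or": point, "ci": list(ci)}
    ors[EDACClass.NOT_AVOIDABLE.label] = {"or": 1.0, "ci": [1.0, 1.0]}
    assoc["reported_or"] = ors
    assoc["cindex"] = ordinal_cindex(table)
    report["association"] = assoc

    # precision block
    report["precision"] = scenario_compare(table)
    return report


def _kappa_block(fn) -> dict:
    try:
        res = fn()
    except KappaUndefinedError as exc:
        return {"kappa": None, "undefined": str(exc)}
    block = res.to_dict()
    block["interpretation"] = kappa_interpretation(res.kappa)
    return block


def run_full_study(config: RunConfig) -> dict:
    """Read inputs per ``config``, run every analysis stage, write the report.

    Any stage error aborts with the stage name; blocks completed before the
    failure are preserved in ``partial_report.json`` under the output
    directory.
    """
    from .core import CodeRegistry, classify_cohort

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        }
    }
    try:
        stage = "read_visits"
        visits = read_visits(config.visits_path) if config.visits_path else None

        stage = "classify"
        if config.class_map_path:
            classes = read_class_map(config.class_map_path)
        elif visits is not None and config.registry_path:
            registry = CodeRegistry.from_file(config.registry_path)
            classes, _ = classify_cohort(visits, registry)
        else:
            raise ValueError(
                "need either class_map_path or (visits_path and registry_path)"
            )

        stage = "read_judgements"
        pairs = read_judgements(config.judgements_path, classes)

        stage = "analysis"
        report.update(study_report(pairs, visits, classes))
    except Exception as exc:
        partial = outdir / "partial_report.json"
        partial.write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "write_report"
    if config.report_format == "markdown":
        (outdir / "report.md").write_text(render_markdown(report))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def render_markdown(report: dict) -> str:
    """Minimal human-readable rendering of the JSON report."""
    lines = ["# EDAC validation report", ""]
    agree = report.get("agreement", {})
    if agree:
        lines += ["## Agreement", ""]
        lines.append(
            f"- {agree['n_agreements']}/{agree['n_pairs']} pairs agree "
            f"({100 * agree['percent_agreement']:.1f}%)"
        )
        for key in ("overall", "avoidable_and_not_avoidable") + tuple(
            c.label for c in EDACClass
        ):
            block = agree.get(key)
            if block and block.get("kappa") is not None:
                lines.append(
                    f"- {key}: kappa {block['kappa']:.2f} "
                    f"({block['ci_low']:.2f}-{block['ci_high']:.2f}), "
                    f"{block['interpretation']}"
                )
        lines.append("")
    assoc = report.get("association", {})
    if assoc:
        lines += ["## Association", ""]
        lines.append(f"- Spearman rank correlation: {assoc['spearman']:.2f}")
        for cls, d in assoc.get("reported_or", {}).items():
            lines.append(
                f"- OR {cls}: {d['or']:.1f} ({d['ci'][0]:.1f}-{d['ci'][1]:.1f})"
            )
        lines.append(f"- c-index: {assoc['cindex']:.2f}")
        lines.append("")
    prec = report.get("precision", {}).get("results", {})
    if prec:
        lines += ["## Precision (rating level)", ""]
        for scen, r in prec.items():
            lines.append(
                f"- {scen}: accuracy {100 * r['accuracy']:.1f}%, "
                f"sensitivity {100 * r['sensitivity_negative_group_ed']:.1f}%, "
                f"specificity {100 * r['specificity_positive_group_subacute']:.1f}%"
            )
        lines.append("")
    return "\n".join(lines)
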