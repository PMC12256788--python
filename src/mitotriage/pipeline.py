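"""End-to-end orchestration: QC -> variant filtering -> phenotype scoring -> triage.

The pipeline mirrors a diagnostic funnel: sample QC, haplogroup-marker
exclusion and the prioritization cascade on the genotype side; phenotype
similarity scoring against reference probands on the phenotype side; then
tier assignment (low/medium/high) and an action label per candidate.

Patients whose phenotype records are empty after validation are *kept* with
missing score and tier — sparse phenotyping is a known failure mode of
similarity scoring, and silently dropping such patients would hide exactly
the cases that need human follow-up.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as mio
from .evaluation import (
    GroupComparison,
    LabeledScore,
    classify_tier,
    kruskal_dunn,
    roc,
    sens_spec_at,
    youden_optimal,
)
from .ontology import (
    EmptyProfileError,
    Ontology,
    PhenotypeProfile,
    compute_ic,
    parse_obo,
    validate_profile,
)
from .similarity import PatientScore, ReferenceProfileTable, SimilarityScorer
from .variant_filter import FilterResult, PrioritizedCandidate, filter_cohort

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

_PATH_FIELDS = frozenset({
    "ontology", "references", "patients", "variants", "qc", "annotations",
    "markers", "out_report", "out_summary",
})

REPORT_COLUMNS = [
    "sample_id", "position", "ref", "alt", "heteroplasmy", "depth",
    "criterion", "haplogroup", "gene", "reportable", "score", "tier",
    "best_match_id", "n_hpo_terms", "mean_ic", "action", "flags",
]

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "score_cohort",
    "calibrate_thresholds",
    "SCHEMA_VERSION",
    "REPORT_COLUMNS",
]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and policy knobs for one pipeline run.

    Defaults are the calibrated screening values: QC >= 50% assembled /
    >= 5x depth, heteroplasmy floor 1%, allele-frequency ceiling 0.2%,
    tier boundaries 0.3 and 0.5.
    """

    # input paths
    ontology: str = ""
    references: str = ""
    patients: str = ""
    variants: str = ""
    qc: str = ""
    annotations: str = ""
    markers: str = ""
    # output paths (empty -> do not write)
    out_report: str = ""
    out_summary: str = ""
    # QC / filter thresholds
    min_fraction: float = 0.5
    min_depth: float = 5.0
    min_het: float = 0.01
    max_af: float = 0.002
    marker_het: float = 0.9
    # tier boundaries
    low_cut: float = 0.3
    high_cut: float = 0.5
    # similarity aggregation
    symmetric: bool = True
    aggregate: str = "max"
    ic_corpus: str = "cohort"  # or "references"
    # action policy
    action_low: str = "no_action"
    action_medium: str = "more_info"
    action_high: str = "review"
    action_missing: str = "more_info"
    action_reportable: str = "report_back"
    # misc
    root_id: str = ""
    seed: int = 0
    timestamp: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.low_cut < self.high_cut < 1.0:
            raise ValueError("tier boundaries must satisfy 0 < low_cut < high_cut < 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value TOML config; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**data)

    def action_for(self, tier: Optional[str], reportable: bool) -> str:
        if reportable:
            return self.action_reportable
        if tier is None:
            return self.action_missing
        return {"low": self.action_low, "medium": self.action_medium,
                "high": self.action_high}[tier]


@dataclass
class PipelineResult:
    candidates: list[PrioritizedCandidate]
    report: pd.DataFrame
    summary: dict
    scores: list[PatientScore]


def score_cohort(
    ont: Ontology,
    refs: ReferenceProfileTable,
    patients: Sequence[PhenotypeProfile],
    symmetric: bool = True,
    aggregate: str = "max",
    ic_corpus: str = "cohort",
) -> tuple[list[PatientScore], list[str]]:
    """Validate and score every patient; returns (scores, empty-profile ids).

    ``ic_corpus`` selects the annotation corpus behind IC: ``"cohort"``
    (default) pools the reference profiles with the validated patient
    profiles, so term specificity is resolved on realistic frequencies even
    when the reference table is small; ``"references"`` uses the reference
    table alone.
    """
    if ic_corpus not in ("cohort", "references"):
        raise ValueError(f"unknown ic_corpus {ic_corpus!r}")
    validated_refs = ReferenceProfileTable(
        profiles=[validate_profile(ont, p) for p in refs.profiles],
        labels=dict(refs.labels))
    validated: list[PhenotypeProfile] = []
    empty: list[str] = []
    for p in patients:
        try:
            validated.append(validate_profile(ont, p))
        except EmptyProfileError:
            empty.append(p.subject_id)
    corpus = list(validated_refs.profiles)
    if ic_corpus == "cohort":
        corpus += validated
    ic = compute_ic(ont, corpus)
    scorer = SimilarityScorer(ont, ic, symmetric=symmetric, aggregate=aggregate)
    scores = [scorer.score_patient(vp, validated_refs) for vp in validated]
    return scores, empty


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full funnel and (optionally) write report TSV + summary JSON."""
    ont = parse_obo(cfg.ontology, root=cfg.root_id or None)
    refs = mio.read_reference_table_tsv(cfg.references)
    patient_profiles = mio.read_profiles_tsv(cfg.patients)
    calls = mio.read_variants_tsv(cfg.variants)
    qc = mio.read_qc_tsv(cfg.qc)
    ann = mio.read_annotations_tsv(cfg.annotations)
    markers = mio.read_markers_tsv(cfg.markers)

    fr: FilterResult = filter_cohort(
        qc, calls, ann, markers,
        min_fraction=cfg.min_fraction, min_depth=cfg.min_depth,
        min_het=cfg.min_het, max_af=cfg.max_af, min_marker_het=cfg.marker_het)

    scores, empty_ids = score_cohort(
        ont, refs, patient_profiles,
        symmetric=cfg.symmetric, aggregate=cfg.aggregate,
        ic_corpus=cfg.ic_corpus)
    by_subject = {s.subject_id: s for s in scores}
    empty_set = set(empty_ids)

    rows = []
    for c in fr.candidates:
        ps = by_subject.get(c.sample_id)
        flags = []
        if ps is not None:
            c.score = ps.score
            c.tier = classify_tier(ps.score, cfg.low_cut, cfg.high_cut)
            c.best_match_id = ps.best_match_id
            c.n_hpo_terms = ps.n_terms
            c.mean_ic = ps.mean_ic
        else:
            flags.append("no_phenotype_data" if c.sample_id in empty_set
                         else "no_phenotype_record")
        c.action = cfg.action_for(c.tier, c.reportable)
        rows.append({
            "sample_id": c.sample_id, "position": c.position, "ref": c.ref,
            "alt": c.alt, "heteroplasmy": round(c.heteroplasmy, 6),
            "depth": c.depth, "criterion": c.criterion,
            "haplogroup": c.haplogroup, "gene": c.gene,
            "reportable": str(c.reportable).lower(),
            "score": "" if c.score is None else f"{c.score:.6f}",
            "tier": c.tier or "missing",
            "best_match_id": c.best_match_id or "",
            "n_hpo_terms": "" if c.n_hpo_terms is None else c.n_hpo_terms,
            "mean_ic": "" if c.mean_ic is None else f"{c.mean_ic:.6f}",
            "action": c.action, "flags": ";".join(flags),
        })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    tier_counts = report["tier"].value_counts().to_dict() if len(report) else {}
    action_counts = report["action"].value_counts().to_dict() if len(report) else {}
    summary = {
        "schema_version": SCHEMA_VERSION,
        "funnel": dict(fr.funnel),
        "patients_total": len(patient_profiles),
        "patients_scored": len(scores),
        "patients_empty_phenotype": sorted(empty_ids),
        "tier_counts": tier_counts,
        "action_counts": action_counts,
        # echo thresholds/policy only: paths vary per deployment and would
        # break byte-level reproducibility comparisons of the summary
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if k not in _PATH_FIELDS},
    }
    if cfg.timestamp:
        summary["generated_at"] = datetime.now(timezone.utc).isoformat()

    if cfg.out_report:
        Path(cfg.out_report).parent.mkdir(parents=True, exist_ok=True)
        report.to_csv(cfg.out_report, sep="\t", index=False)
    if cfg.out_summary:
        Path(cfg.out_summary).parent.mkdir(parents=True, exist_ok=True)
        Path(cfg.out_summary).write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    for stage, count in fr.funnel.items():
        logger.info("funnel %s = %d", stage, count)
    return PipelineResult(candidates=fr.candidates, report=report,
                          summary=summary, scores=scores)


def _comparison_dict(gc: GroupComparison) -> dict:
    return {
        "kruskal_h": gc.kw_h,
        "kruskal_p": gc.kw_p,
        "pairwise": [{"pair": list(pc.pair), "z": pc.z, "p_raw": pc.p_raw,
                      "p_adj": pc.p_adj} for pc in gc.pairwise],
    }


def calibrate_thresholds(
    scores: Sequence[LabeledScore] | pd.DataFrame,
    thresholds: Sequence[float] = (0.3, 0.48, 0.5),
) -> dict:
    """ROC/AUC + CI, Youden optimum, sens/spec at fixed cut-offs, group stats.

    Accepts either labeled scores or a DataFrame with columns
    subject_id/score/group.  The fixed cut-offs default to the screening
    (0.3), Youden-derived (0.48) and rounded (0.5) thresholds.
    """
    if isinstance(scores, pd.DataFrame):
        scores = [LabeledScore(str(r.subject_id), float(r.score), str(r.group))
                  for r in scores.itertuples()]
    scores = list(scores)
    r = roc(scores)
    y = youden_optimal(r)
    at = {}
    for t in thresholds:
        sens, spec = sens_spec_at(scores, t)
        at[f"{t:g}"] = {"sens": sens, "spec": spec}

    groups: dict[str, list[float]] = {}
    for s in scores:
        groups.setdefault(s.group, []).append(s.score)
    comparison = None
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        comparison = _comparison_dict(kruskal_dunn(groups))

    return {
        "schema_version": SCHEMA_VERSION,
        "n": {g: len(v) for g, v in sorted(groups.items())},
        "auc": r.auc,
        "auc_ci": list(r.auc_ci),
        "youden": {"threshold": y.threshold, "sens": y.sens,
                   "spec": y.spec, "j": y.j},
        "at_thresholds": at,
        "group_comparison": comparison,
    }
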