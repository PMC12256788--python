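"""Sample QC and mtDNA variant prioritization.

Implements the genotype side of the triage pipeline on per-sample variant
calls against the rCRS (16,569 bp, 1-based):

1. sample QC — at least half the mitochondrial genome assembled and mean
   depth >= 5x (off-capture exome coverage of chrM is shallow and variable,
   so the gates are deliberately permissive);
2. haplogroup-marker exclusion — variants defining the sample's own mtDNA
   lineage are benign population polymorphisms, not disease candidates;
3. a prioritization cascade: heteroplasmy >= 1% (mandatory) AND at least one
   disease-association criterion — "confirmed" status in the annotation
   database, presence in the phenotype reference database, or "reported"
   status with population allele frequency < 0.2%.

All thresholds are arguments with those defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

RCRS_LENGTH = 16_569

VariantKey = tuple[int, str, str]  # (position, ref, alt)

__all__ = [
    "RCRS_LENGTH",
    "VariantKey",
    "SampleQC",
    "MtVariantRecord",
    "VariantAnnotation",
    "HaplogroupMarkerTable",
    "PrioritizedCandidate",
    "QCResult",
    "PrioritizationResult",
    "FilterResult",
    "apply_sample_qc",
    "assign_haplogroup",
    "is_haplogroup_marker",
    "passes_prioritization",
    "filter_cohort",
]

_BASES = set("ACGT")


@dataclass(frozen=True)
class SampleQC:
    """Per-sample mtDNA assembly/coverage metrics."""

    sample_id: str
    assembled_fraction: float
    mean_depth: float
    assay: str = "ES"
    tissue: str = "blood"

    def __post_init__(self) -> None:
        if not 0.0 <= self.assembled_fraction <= 1.0:
            raise ValueError(
                f"{self.sample_id}: assembled_fraction {self.assembled_fraction} "
                "outside [0, 1]")
        if self.mean_depth < 0:
            raise ValueError(f"{self.sample_id}: negative mean_depth")


@dataclass(frozen=True)
class MtVariantRecord:
    """One mtDNA variant call in one sample (rCRS coordinates, 1-based)."""

    sample_id: str
    position: int
    ref: str
    alt: str
    heteroplasmy: float
    depth: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ValueError(f"position {self.position} outside rCRS [1, {RCRS_LENGTH}]")
        if not (set(self.ref) <= _BASES and set(self.alt) <= _BASES):
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at position {self.position}")
        if not 0.0 <= self.heteroplasmy <= 1.0:
            raise ValueError(f"heteroplasmy {self.heteroplasmy} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("negative depth")

    @property
    def key(self) -> VariantKey:
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Disease-association annotation for one (position, ref, alt) key.

    ``mitomap_status`` follows the curated-database convention: "confirmed"
    (established pathogenic association), "reported" (published but not
    confirmed), or "absent".  ``reportable`` flags variably penetrant alleles
    (LHON / aminoglycoside-related hearing-loss class) that warrant feedback
    regardless of phenotype-match tier.
    """

    position: int
    ref: str
    alt: str
    mitomap_status: str = "absent"
    mitomap_af: Optional[float] = None
    in_mitophen: bool = False
    gene: str = ""
    reportable: bool = False

    def __post_init__(self) -> None:
        if self.mitomap_status not in ("confirmed", "reported", "absent"):
            raise ValueError(f"bad mitomap_status {self.mitomap_status!r}")
        if self.mitomap_af is not None and not 0.0 <= self.mitomap_af <= 1.0:
            raise ValueError(f"mitomap_af {self.mitomap_af} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.position, self.ref, self.alt)


_UNANNOTATED = VariantAnnotation(position=1, ref="A", alt="C")


@dataclass
class HaplogroupMarkerTable:
    """Haplogroup -> defining marker variants (benign lineage polymorphisms)."""

    markers: dict[str, frozenset[VariantKey]]

    def __post_init__(self) -> None:
        self.markers = {hg: frozenset(ms) for hg, ms in self.markers.items()}

    @property
    def haplogroups(self) -> list[str]:
        return sorted(self.markers)


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class PrioritizationResult:
    passed: bool
    criterion: Optional[str] = None  # confirmed | mitophen | reported_rare


@dataclass
class PrioritizedCandidate:
    """A variant-sample pair that survived every genotype gate.

    Phenotype fields (score, tier, action, ...) are filled by the pipeline
    after similarity scoring; the filter stage leaves them unset.
    """

    sample_id: str
    position: int
    ref: str
    alt: str
    heteroplasmy: float
    depth: int
    criterion: str
    gene: str = ""
    reportable: bool = False
    haplogroup: str = ""
    score: Optional[float] = None
    tier: Optional[str] = None
    best_match_id: Optional[str] = None
    n_hpo_terms: Optional[int] = None
    mean_ic: Optional[float] = None
    action: Optional[str] = None

    @property
    def key(self) -> VariantKey:
        return (self.position, self.ref, self.alt)


def apply_sample_qc(qc: SampleQC, min_fraction: float = 0.5,
                    min_depth: float = 5.0) -> QCResult:
    """Inclusive thresholds: >= 50% assembled and >= 5x mean depth by default."""
    reasons = []
    if qc.assembled_fraction < min_fraction:
        reasons.append("assembly")
    if qc.mean_depth < min_depth:
        reasons.append("depth")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


def assign_haplogroup(
    variants: Sequence[MtVariantRecord],
    markers: HaplogroupMarkerTable,
    min_marker_het: float = 0.9,
) -> tuple[str, float]:
    """Best-marker-fraction haplogroup classifier.

    Returns the haplogroup maximizing the fraction of its defining markers
    carried by the sample at near-homoplasmic levels (heteroplasmy >=
    ``min_marker_het``); ties break lexicographically.  This is a simplified
    classifier for samples lacking an upstream haplogroup call.
    """
    if not markers.markers:
        raise ValueError("haplogroup marker table is empty")
    carried = {v.key for v in variants if v.heteroplasmy >= min_marker_het}
    best_hg, best_frac = "", -1.0
    for hg in markers.haplogroups:  # sorted -> lexicographic tie-break
        defining = markers.markers[hg]
        frac = len(carried & defining) / len(defining) if defining else 0.0
        if frac > best_frac:
            best_hg, best_frac = hg, frac
    return best_hg, max(best_frac, 0.0)


def is_haplogroup_marker(v: MtVariantRecord, hg: str,
                         markers: HaplogroupMarkerTable) -> bool:
    """True iff ``v`` is a defining marker of haplogroup ``hg``."""
    if hg not in markers.markers:
        raise KeyError(f"unknown haplogroup {hg!r}")
    return v.key in markers.markers[hg]


def passes_prioritization(
    v: MtVariantRecord,
    a: Optional[VariantAnnotation] = None,
    min_het: float = 0.01,
    max_af: float = 0.002,
) -> PrioritizationResult:
    """The prioritization cascade for one variant.

    Heteroplasmy >= ``min_het`` is mandatory (inclusive); the variant must
    additionally satisfy one disease-association clause, checked in order:
    confirmed status, phenotype-database membership, or reported status with
    allele frequency strictly below ``max_af``.  A "reported" annotation with
    no allele frequency cannot satisfy the frequency clause and is logged.
    """
    if a is None:
        a = _UNANNOTATED
    if v.heteroplasmy < min_het:
        return PrioritizationResult(False)
    if a.mitomap_status == "confirmed":
        return PrioritizationResult(True, "confirmed")
    if a.in_mitophen:
        return PrioritizationResult(True, "mitophen")
    if a.mitomap_status == "reported":
        if a.mitomap_af is None:
            logger.warning(
                "%s %d%s>%s: 'reported' status without allele frequency; "
                "frequency clause unevaluable, treated as failing",
                v.sample_id, v.position, v.ref, v.alt)
            return PrioritizationResult(False)
        if a.mitomap_af < max_af:
            return PrioritizationResult(True, "reported_rare")
    return PrioritizationResult(False)


@dataclass
class FilterResult:
    """Survivors plus a funnel of per-stage counts and per-sample haplogroups."""

    candidates: list[PrioritizedCandidate]
    funnel: dict[str, int]
    sample_haplogroups: dict[str, str]

    def __post_init__(self) -> None:
        f = self.funnel
        consumed = (f["dropped_qc"] + f["dropped_marker"] +
                    f["dropped_prioritization"] + f["candidates"])
        if consumed != f["variants_total"]:
            raise AssertionError("funnel counts do not conserve variants")


def filter_cohort(
    qc: Sequence[SampleQC],
    calls: Sequence[MtVariantRecord],
    ann: Mapping[VariantKey, VariantAnnotation] | Iterable[VariantAnnotation],
    markers: HaplogroupMarkerTable,
    min_fraction: float = 0.5,
    min_depth: float = 5.0,
    min_het: float = 0.01,
    max_af: float = 0.002,
    min_marker_het: float = 0.9,
    haplogroups: Optional[Mapping[str, str]] = None,
) -> FilterResult:
    """Run all genotype gates over a cohort of variant calls.

    QC-failing samples lose all their variants; each surviving sample is
    assigned a haplogroup (a precomputed ``haplogroups`` map takes precedence
    over the marker classifier) and its own lineage markers are excluded;
    the prioritization cascade decides the rest.  A call from a sample with
    no QC row is a hard error — silent inclusion of unvetted samples is
    exactly the failure mode QC exists to prevent.
    """
    if not isinstance(ann, Mapping):
        ann = {a.key: a for a in ann}
    qc_by_sample = {q.sample_id: q for q in qc}
    missing = sorted({v.sample_id for v in calls} - set(qc_by_sample))
    if missing:
        raise ValueError(f"samples missing from QC table: {missing}")

    by_sample: dict[str, list[MtVariantRecord]] = {}
    for v in calls:
        by_sample.setdefault(v.sample_id, []).append(v)

    funnel = {
        "samples_total": len(qc_by_sample),
        "samples_pass_qc": 0,
        "variants_total": len(calls),
        "dropped_qc": 0,
        "dropped_marker": 0,
        "dropped_prioritization": 0,
        "candidates": 0,
    }
    sample_hg: dict[str, str] = {}
    candidates: list[PrioritizedCandidate] = []

    for sid in sorted(qc_by_sample):
        sample_calls = by_sample.get(sid, [])
        if not apply_sample_qc(qc_by_sample[sid], min_fraction, min_depth).passed:
            funnel["dropped_qc"] += len(sample_calls)
            logger.debug("sample %s failed QC; %d variants dropped",
                         sid, len(sample_calls))
            continue
        funnel["samples_pass_qc"] += 1
        if haplogroups is not None and sid in haplogroups:
            hg = haplogroups[sid]
        else:
            hg, _ = assign_haplogroup(sample_calls, markers, min_marker_het)
        sample_hg[sid] = hg
        own_markers = markers.markers.get(hg, frozenset())
        for v in sample_calls:
            if v.key in own_markers:
                funnel["dropped_marker"] += 1
                continue
            pr = passes_prioritization(v, ann.get(v.key), min_het, max_af)
            if not pr.passed:
                funnel["dropped_prioritization"] += 1
                continue
            a = ann.get(v.key, _UNANNOTATED)
            candidates.append(PrioritizedCandidate(
                sample_id=sid, position=v.position, ref=v.ref, alt=v.alt,
                heteroplasmy=v.heteroplasmy, depth=v.depth,
                criterion=pr.criterion or "", gene=a.gene,
                reportable=a.reportable, haplogroup=hg,
            ))
    funnel["candidates"] = len(candidates)
    return FilterResult(candidates=candidates, funnel=funnel,
                        sample_haplogroups=sample_hg)
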