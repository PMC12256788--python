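"""Lin semantic similarity between phenotype terms and profiles.

Term-level similarity follows Lin: sim(t1, t2) = 2·IC(MICA) / (IC(t1) + IC(t2))
where the MICA is the common ancestor (reflexively including the terms
themselves) with maximal information content.  Profile-level similarity is the
symmetric best-match average, and a patient's phenotype similarity score is
the maximum profile similarity against a table of reference probands — the
"how close is this person to any previously reported mtDNA-disease case"
statistic that downstream triage thresholds act on.

Two implementations coexist deliberately: plain functions (:func:`lin_sim`,
:func:`profile_sim`, :func:`score_patient`) that enumerate common ancestors on
demand, and :class:`SimilarityScorer`, which precomputes the full term-pair
similarity matrix for fast cohort-scale scoring.  Tests assert the two agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ontology import (
    EmptyProfileError,
    ICTable,
    Ontology,
    OntologyError,
    PhenotypeProfile,
    reduce_nonredundant,
)

__all__ = [
    "ReferenceProfileTable",
    "PatientScore",
    "lin_sim",
    "profile_sim",
    "score_patient",
    "SimilarityScorer",
]


@dataclass
class ReferenceProfileTable:
    """Reference probands/diseases with known phenotype profiles.

    Stands in for a curated genotype-phenotype database (MitoPhen-style):
    one row per published proband, with the disease or variant as its label.
    """

    profiles: list[PhenotypeProfile]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        ids = [p.subject_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("reference subject_ids must be unique")
        for p in self.profiles:
            if not p.terms:
                raise ValueError(f"reference profile {p.subject_id!r} is empty")

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class PatientScore:
    """Per-patient phenotype similarity summary.

    ``n_terms`` and ``mean_ic`` are reported on the non-redundant reduction of
    the patient's term set (redundant ancestors removed), while ``score`` is
    computed on the full validated set.
    """

    subject_id: str
    score: float
    best_match_id: str
    n_terms: int
    mean_ic: float


def _mica_ic(ic: ICTable, ont: Ontology, t1: str, t2: str) -> float:
    common = ont.ancestors(t1) & ont.ancestors(t2)
    return max(ic[t] for t in common)


def lin_sim(ic: ICTable, ont: Ontology, t1: str, t2: str) -> float:
    """Lin similarity of two terms; 0 when both terms carry zero IC."""
    ic1, ic2 = ic[t1], ic[t2]
    denom = ic1 + ic2
    if denom <= 0.0:
        return 0.0
    return 2.0 * _mica_ic(ic, ont, t1, t2) / denom


def profile_sim(
    ic: ICTable,
    ont: Ontology,
    a: PhenotypeProfile,
    b: PhenotypeProfile,
    symmetric: bool = True,
) -> float:
    """Best-match-average similarity between two term sets, in [0, 1].

    Symmetric form (default) averages the two directional best-match means;
    the asymmetric form scores ``a`` against ``b`` only (each of a's terms
    matched to its best counterpart in b).
    """
    if not a.terms or not b.terms:
        raise EmptyProfileError("profile similarity is undefined on empty profiles")
    a_terms, b_terms = sorted(a.terms), sorted(b.terms)
    sims = [[lin_sim(ic, ont, x, y) for y in b_terms] for x in a_terms]
    forward = sum(max(row) for row in sims) / len(a_terms)
    if not symmetric:
        return forward
    backward = sum(max(sims[i][j] for i in range(len(a_terms)))
                   for j in range(len(b_terms))) / len(b_terms)
    return 0.5 * (forward + backward)


def score_patient(
    ic: ICTable,
    ont: Ontology,
    patient: PhenotypeProfile,
    refs: ReferenceProfileTable,
    symmetric: bool = True,
    aggregate: str = "max",
) -> PatientScore:
    """Score one patient against every reference profile.

    ``aggregate='max'`` (default) reports the best-matching reference —
    similarity to the closest previously reported case; ``'mean'`` averages
    over all references.  Ties go to the first reference in table order.
    """
    if not patient.terms:
        raise EmptyProfileError(f"patient {patient.subject_id!r} has no terms")
    if not refs.profiles:
        raise OntologyError("reference profile table is empty")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    sims = [profile_sim(ic, ont, patient, r, symmetric=symmetric)
            for r in refs.profiles]
    if aggregate == "max":
        best_idx = int(np.argmax(sims))  # first max wins on ties
        score = sims[best_idx]
    else:
        score = float(np.mean(sims))
        best_idx = int(np.argmax(sims))

    reduced = reduce_nonredundant(ont, patient.terms)
    return PatientScore(
        subject_id=patient.subject_id,
        score=float(score),
        best_match_id=refs.profiles[best_idx].subject_id,
        n_terms=len(reduced),
        mean_ic=ic.mean_ic(reduced),
    )


class SimilarityScorer:
    """Precomputed term-pair Lin similarity for cohort-scale scoring.

    Builds the dense n_terms x n_terms similarity matrix once (MICA IC via
    boolean ancestor masks), then profile comparisons are submatrix
    max/mean reductions.  Equivalent to the plain functions to within
    floating-point identity.
    """

    def __init__(self, ont: Ontology, ic: ICTable, symmetric: bool = True,
                 aggregate: str = "max") -> None:
        self.ont = ont
        self.ic = ic
        self.symmetric = symmetric
        self.aggregate = aggregate
        self._terms = ont.live_terms
        self._index = {t: i for i, t in enumerate(self._terms)}
        n = len(self._terms)
        anc = np.zeros((n, n), dtype=bool)
        for i, t in enumerate(self._terms):
            for a in ont.ancestors(t):
                anc[i, self._index[a]] = True
        ic_vec = np.array([ic[t] for t in self._terms])
        sim = np.zeros((n, n))
        for i in range(n):
            common = anc & anc[i]  # row j: common ancestors of (i, j)
            mica = np.where(common, ic_vec, -np.inf).max(axis=1)
            denom = ic_vec[i] + ic_vec
            with np.errstate(invalid="ignore", divide="ignore"):
                row = np.where(denom > 0, 2.0 * mica / denom, 0.0)
            sim[i] = row
        self._sim = sim
        self._ic_vec = ic_vec

    def _idx(self, profile: PhenotypeProfile) -> np.ndarray:
        if not profile.terms:
            raise EmptyProfileError(
                f"profile {profile.subject_id!r} has no terms")
        return np.array([self._index[t] for t in sorted(profile.terms)])

    def term_sim(self, t1: str, t2: str) -> float:
        return float(self._sim[self._index[t1], self._index[t2]])

    def profile_sim(self, a: PhenotypeProfile, b: PhenotypeProfile) -> float:
        sub = self._sim[np.ix_(self._idx(a), self._idx(b))]
        forward = float(sub.max(axis=1).mean())
        if not self.symmetric:
            return forward
        return 0.5 * (forward + float(sub.max(axis=0).mean()))

    def score_patient(self, patient: PhenotypeProfile,
                      refs: ReferenceProfileTable) -> PatientScore:
        if not refs.profiles:
            raise OntologyError("reference profile table is empty")
        sims = np.array([self.profile_sim(patient, r) for r in refs.profiles])
        best_idx = int(np.argmax(sims))
        score = float(sims[best_idx] if self.aggregate == "max" else sims.mean())
        reduced = reduce_nonredundant(self.ont, patient.terms)
        return PatientScore(
            subject_id=patient.subject_id,
            score=score,
            best_match_id=refs.profiles[best_idx].subject_id,
            n_terms=len(reduced),
            mean_ic=self.ic.mean_ic(reduced),
        )

    def score_cohort(self, patients: Sequence[PhenotypeProfile],
                     refs: ReferenceProfileTable) -> list[PatientScore]:
        return [self.score_patient(p, refs) for p in patients]
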