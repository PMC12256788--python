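"""Synthetic rare-disease cohorts with the statistical structure the pipeline assumes.

No patient-level data from the study this package emulates are public, so
every stage is exercised on simulated cohorts instead:

* **mtDNA-disease patients** are noisy copies of reference proband profiles —
  each reference term is independently *dropped* (incomplete phenotyping),
  surviving terms are *blurred* to a strict ancestor (clinicians recording a
  less specific term), and a few unrelated *noise* terms are appended.  Each
  such patient also carries one spiked causal mtDNA variant.
* **Nuclear-diagnosis patients** (mitochondrial-gene or other) draw fresh
  random term sets unrelated to the references and carry only background
  variants.
* Every sample gets a haplogroup with near-homoplasmic marker variants,
  benign background variants, and QC metrics; a configured fraction of
  samples fails QC.

The default cohort sizes mirror a phenotype test cohort of 47 mtDNA-disease
vs 1,460 nuclear-diagnosis patients (122 nuclear-mitochondrial, 1,338
nuclear-other).  The marker table and pathogenic-variant pool below are
synthetic stand-ins: the rCRS positions are real well-known alleles, but the
haplogroup assignments and annotation fields are invented for testing and
carry no clinical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ontology import Ontology, PhenotypeProfile
from .similarity import ReferenceProfileTable
from .variant_filter import (
    HaplogroupMarkerTable,
    MtVariantRecord,
    SampleQC,
    VariantAnnotation,
    VariantKey,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "DEFAULT_MARKER_TABLE",
    "PATHOGENIC_POOL",
    "BENIGN_POOL",
    "generate_random_ontology",
    "generate_reference_profiles",
    "sample_patient",
    "generate_cohort",
]

# Synthetic haplogroup marker table (haplogroup -> defining variants).
DEFAULT_MARKER_TABLE = HaplogroupMarkerTable(markers={
    "H": frozenset({(2706, "A", "G"), (7028, "C", "T"), (1438, "A", "G")}),
    "J": frozenset({(295, "C", "T"), (489, "T", "C"), (10398, "A", "G"),
                    (12612, "A", "G"), (13708, "G", "A")}),
    "K": frozenset({(1189, "T", "C"), (9055, "G", "A"), (11299, "T", "C")}),
    "T": frozenset({(709, "G", "A"), (1888, "G", "A"), (4917, "A", "G")}),
    "U": frozenset({(11467, "A", "G"), (12308, "A", "G"), (12372, "G", "A")}),
})

# Synthetic pathogenic pool: (position, ref, alt, status, in_mitophen, gene,
# reportable).  Positions are well-known disease alleles; fields are stand-ins.
PATHOGENIC_POOL: list[tuple[int, str, str, str, bool, str, bool]] = [
    (3243, "A", "G", "confirmed", True, "MT-TL1", False),
    (8344, "A", "G", "confirmed", True, "MT-TK", False),
    (8993, "T", "G", "confirmed", True, "MT-ATP6", False),
    (8993, "T", "C", "confirmed", True, "MT-ATP6", False),
    (13513, "G", "A", "confirmed", True, "MT-ND5", False),
    (9176, "T", "C", "confirmed", False, "MT-ATP6", False),
    (10191, "T", "C", "confirmed", False, "MT-ND3", False),
    (3460, "G", "A", "confirmed", True, "MT-ND1", True),
    (11778, "G", "A", "confirmed", True, "MT-ND4", True),
    (14484, "T", "C", "confirmed", True, "MT-ND6", True),
    (1555, "A", "G", "reported", True, "MT-RNR1", True),
    (1494, "C", "T", "reported", True, "MT-RNR1", True),
    (5698, "G", "A", "reported", False, "MT-TN", False),
    (9032, "T", "C", "reported", False, "MT-ATP6", False),
]

# Benign background pool: common polymorphisms (status absent or reported
# with a high population frequency, so the cascade rejects them).
BENIGN_POOL: list[tuple[int, str, str, str, Optional[float]]] = [
    (73, "A", "G", "absent", None),
    (263, "A", "G", "absent", None),
    (750, "A", "G", "reported", 0.05),
    (1438, "A", "G", "reported", 0.08),  # also an H marker
    (4769, "A", "G", "absent", None),
    (8860, "A", "G", "reported", 0.09),
    (15326, "A", "G", "absent", None),
    (16189, "T", "C", "reported", 0.02),
    (16519, "T", "C", "reported", 0.3),
    (5656, "A", "G", "reported", 0.01),
]


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; defaults are the simulated study conditions."""

    n_mtdna: int = 47
    n_nuclear_mito: int = 122
    n_nuclear_other: int = 1338
    dropout: float = 0.3
    imprecision: float = 0.2
    noise_terms: int = 2
    terms_per_reference: tuple[int, int] = (6, 10)
    seed: int = 0
    n_references: int = 8
    nuclear_terms_range: tuple[int, int] = (4, 10)
    qc_fail_fraction: float = 0.1
    causal_het_range: tuple[float, float] = (0.01, 1.0)
    background_rate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_mtdna", "n_nuclear_mito", "n_nuclear_other",
                     "noise_terms", "n_references"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dropout", "imprecision", "qc_fail_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """A complete simulated input set plus the ground truth behind it."""

    ontology: Ontology
    references: ReferenceProfileTable
    patients: list[tuple[PhenotypeProfile, str]]  # (profile, group label)
    variants: list[MtVariantRecord]
    annotations: dict[VariantKey, VariantAnnotation]
    qc: list[SampleQC]
    markers: HaplogroupMarkerTable
    truth: dict[str, dict]

    def to_dir(self, outdir: str | Path) -> None:
        """Materialize every table in the dialects the pipeline consumes."""
        from . import io as mio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_obo(self.ontology, outdir / "ontology.obo")
        mio.write_reference_table_tsv(self.references, outdir / "references.tsv")
        mio.write_profiles_tsv([p for p, _ in self.patients],
                               outdir / "patients.tsv")
        mio.write_variants_tsv(self.variants, outdir / "variants.tsv")
        mio.write_annotations_tsv(sorted(self.annotations.values(),
                                         key=lambda a: a.key),
                                  outdir / "annotations.tsv")
        mio.write_qc_tsv(self.qc, outdir / "qc.tsv")
        mio.write_markers_tsv(self.markers, outdir / "markers.tsv")
        truth_rows = []
        for sid in sorted(self.truth):
            t = self.truth[sid]
            cv = t.get("causal_variant")
            truth_rows.append({
                "sample_id": sid, "group": t["group"],
                "is_mtdna_case": str(t["is_mtdna_case"]).lower(),
                "causal_variant": ("" if cv is None
                                   else f"{cv[0]}:{cv[1]}>{cv[2]}"),
                "source_reference": t.get("source_reference", ""),
                "qc_fail": str(t["qc_fail"]).lower(),
            })
        pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t",
                                        index=False)


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_random_ontology(n_terms: int, max_parents: int = 2,
                             seed: int | np.random.Generator = 0,
                             prefix: str = "SYN") -> Ontology:
    """Random rooted DAG: each new term attaches to 1..max_parents earlier terms.

    Acyclic by construction (edges only point to earlier terms) and
    deterministic for a fixed seed.
    """
    if n_terms < 2:
        raise ValueError("a random ontology needs at least 2 terms (root + 1)")
    rng = _rng(seed)
    ids = [f"{prefix}:{i:07d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        chosen = rng.choice(i, size=min(k, i), replace=False)
        parents[ids[i]] = {ids[int(j)] for j in chosen}
    return Ontology.from_edges(parents, root=ids[0])


def generate_reference_profiles(
    ont: Ontology,
    n_profiles: int,
    terms_per_profile: tuple[int, int] = (6, 10),
    seed: int | np.random.Generator = 0,
    label_prefix: str = "REF",
) -> ReferenceProfileTable:
    """Depth-biased random reference profiles (disease annotations skew specific).

    Term sampling probability is proportional to DAG depth, so profiles
    favour leaves the way curated disease annotations do.  Profiles are
    mutually distinct and generation is deterministic per seed.
    """
    rng = _rng(seed)
    lo, hi = terms_per_profile
    candidates = [t for t in ont.live_terms if t != ont.root]
    if len(candidates) < 2 * hi:
        raise ValueError(
            f"ontology too small: {len(candidates)} non-root terms for "
            f"profiles of up to {hi} terms")
    depths = np.array([ont.depth(t) for t in candidates], dtype=float)
    weights = depths / depths.sum()

    profiles: list[PhenotypeProfile] = []
    seen: set[frozenset[str]] = set()
    for i in range(n_profiles):
        for _ in range(100):
            k = int(rng.integers(lo, hi + 1))
            terms = frozenset(rng.choice(candidates, size=k, replace=False,
                                         p=weights))
            if terms not in seen:
                break
        else:
            raise ValueError("could not draw a distinct reference profile; "
                             "ontology term budget infeasible")
        seen.add(terms)
        profiles.append(PhenotypeProfile(subject_id=f"{label_prefix}{i+1:04d}",
                                         terms=terms))
    labels = {p.subject_id: f"synthetic mtDNA disease {i+1}"
              for i, p in enumerate(profiles)}
    return ReferenceProfileTable(profiles=profiles, labels=labels)


def sample_patient(
    ref: PhenotypeProfile,
    ont: Ontology,
    dropout: float = 0.3,
    imprecision: float = 0.2,
    noise_terms: int = 2,
    seed: int | np.random.Generator = 0,
    subject_id: Optional[str] = None,
) -> PhenotypeProfile:
    """A noisy phenotype copy of a reference proband.

    Each reference term is dropped with probability ``dropout``; each
    survivor is replaced by a uniformly chosen strict ancestor (never the
    root) with probability ``imprecision``; ``noise_terms`` uniform random
    terms are appended.  If dropout removes everything, one reference term is
    retained — downstream scoring rejects empty profiles, so the generator
    never emits them.
    """
    if not ref.terms:
        raise ValueError("reference profile is empty")
    rng = _rng(seed)
    ref_terms = sorted(ref.terms)
    kept = [t for t in ref_terms if rng.random() >= dropout]
    if not kept:
        kept = [ref_terms[int(rng.integers(len(ref_terms)))]]
    out: set[str] = set()
    for t in kept:
        if rng.random() < imprecision:
            anc = sorted(set(ont.ancestors(t)) - {t, ont.root})
            if anc:
                t = anc[int(rng.integers(len(anc)))]
        out.add(t)
    non_root = [t for t in ont.live_terms if t != ont.root]
    for _ in range(noise_terms):
        out.add(non_root[int(rng.integers(len(non_root)))])
    return PhenotypeProfile(subject_id=subject_id or ref.subject_id,
                            terms=frozenset(out))


def _annotation_table() -> dict[VariantKey, VariantAnnotation]:
    ann: dict[VariantKey, VariantAnnotation] = {}
    for pos, ref, alt, status, in_mp, gene, reportable in PATHOGENIC_POOL:
        af = 0.001 if status == "reported" else None
        a = VariantAnnotation(position=pos, ref=ref, alt=alt,
                              mitomap_status=status, mitomap_af=af,
                              in_mitophen=in_mp, gene=gene,
                              reportable=reportable)
        ann[a.key] = a
    for pos, ref, alt, status, af in BENIGN_POOL:
        a = VariantAnnotation(position=pos, ref=ref, alt=alt,
                              mitomap_status=status, mitomap_af=af)
        ann[a.key] = a
    return ann


def generate_cohort(spec: CohortSpec,
                    ontology: Optional[Ontology] = None,
                    markers: Optional[HaplogroupMarkerTable] = None) -> SyntheticCohort:
    """End-to-end synthetic cohort: profiles, variants, annotations, QC, truth.

    Fully deterministic for a fixed ``spec`` (one RNG seeded from
    ``spec.seed`` drives every draw in fixed order).
    """
    from .io import load_fixture_ontology

    ont = ontology if ontology is not None else load_fixture_ontology()
    markers = markers if markers is not None else DEFAULT_MARKER_TABLE
    rng = np.random.default_rng(spec.seed)

    refs = generate_reference_profiles(
        ont, spec.n_references, spec.terms_per_reference,
        seed=np.random.default_rng(rng.integers(2**31)))

    group_plan = (["mtDNA"] * spec.n_mtdna +
                  ["nuclear_mito"] * spec.n_nuclear_mito +
                  ["nuclear_other"] * spec.n_nuclear_other)
    n_total = len(group_plan)
    non_root = [t for t in ont.live_terms if t != ont.root]
    lo_n, hi_n = spec.nuclear_terms_range

    patients: list[tuple[PhenotypeProfile, str]] = []
    variants: list[MtVariantRecord] = []
    qc: list[SampleQC] = []
    truth: dict[str, dict] = {}
    annotations = _annotation_table()
    hg_names = markers.haplogroups
    lo_het, hi_het = spec.causal_het_range

    qc_fail = rng.random(n_total) < spec.qc_fail_fraction

    for i, group in enumerate(group_plan):
        sid = f"P{i+1:05d}"
        source_ref = ""
        causal: Optional[VariantKey] = None

        if group == "mtDNA":
            ref = refs.profiles[int(rng.integers(len(refs.profiles)))]
            source_ref = ref.subject_id
            profile = sample_patient(ref, ont, spec.dropout, spec.imprecision,
                                     spec.noise_terms, seed=rng, subject_id=sid)
        else:
            k = int(rng.integers(lo_n, hi_n + 1))
            terms = frozenset(rng.choice(non_root, size=k, replace=False))
            profile = PhenotypeProfile(subject_id=sid, terms=terms)
        patients.append((profile, group))

        # QC metrics (assembly 62-100%, depth 7-165x for passing samples)
        if qc_fail[i]:
            if rng.random() < 0.5:
                qc.append(SampleQC(sid, float(rng.uniform(0.10, 0.49)),
                                   float(rng.uniform(7.0, 80.0))))
            else:
                qc.append(SampleQC(sid, float(rng.uniform(0.62, 1.0)),
                                   float(rng.uniform(0.5, 4.9))))
        else:
            assay = "GS" if rng.random() < 0.05 else "ES"
            qc.append(SampleQC(sid, float(rng.uniform(0.62, 1.0)),
                               float(rng.uniform(7.0, 165.0)), assay=assay))

        # haplogroup markers, near-homoplasmic
        hg = hg_names[int(rng.integers(len(hg_names)))]
        for key in sorted(markers.markers[hg]):
            if rng.random() < 0.9:
                variants.append(MtVariantRecord(
                    sid, key[0], key[1], key[2],
                    heteroplasmy=float(rng.uniform(0.95, 1.0)),
                    depth=int(rng.integers(10, 200))))

        # benign background variants
        for _ in range(int(rng.poisson(spec.background_rate))):
            pos, ref_a, alt_a, _, _ = BENIGN_POOL[int(rng.integers(len(BENIGN_POOL)))]
            variants.append(MtVariantRecord(
                sid, pos, ref_a, alt_a,
                heteroplasmy=float(rng.uniform(0.005, 1.0)),
                depth=int(rng.integers(10, 200))))

        # one spiked causal variant per mtDNA case
        if group == "mtDNA":
            pos, ref_a, alt_a, *_ = PATHOGENIC_POOL[
                int(rng.integers(len(PATHOGENIC_POOL)))]
            causal = (pos, ref_a, alt_a)
            variants.append(MtVariantRecord(
                sid, pos, ref_a, alt_a,
                heteroplasmy=float(rng.uniform(lo_het, hi_het)),
                depth=int(rng.integers(10, 200))))

        truth[sid] = {
            "group": group,
            "is_mtdna_case": group == "mtDNA",
            "causal_variant": causal,
            "source_reference": source_ref,
            "qc_fail": bool(qc_fail[i]),
            "haplogroup": hg,
        }

    # dedupe variant rows per (sample, key): a background draw may coincide
    # with a marker or causal allele; keep the last (causal wins).
    merged: dict[tuple[str, VariantKey], MtVariantRecord] = {}
    for v in variants:
        merged[(v.sample_id, v.key)] = v
    variants = sorted(merged.values(),
                      key=lambda v: (v.sample_id, v.position, v.ref, v.alt))

    return SyntheticCohort(ontology=ont, references=refs, patients=patients,
                           variants=variants, annotations=annotations,
                           qc=qc, markers=markers, truth=truth)
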