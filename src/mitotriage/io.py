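"""Readers and writers for the pipeline's tabular dialects.

All tables are headered TSV.  Phenotype term sets are serialized as
semicolon-separated id lists.  A minimal single-sample VCF reader (contig
chrM/MT) is provided for variant ingestion; everything else round-trips
through pandas.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ontology import Ontology, PhenotypeProfile, parse_obo
from .similarity import PatientScore, ReferenceProfileTable
from .variant_filter import (
    HaplogroupMarkerTable,
    MtVariantRecord,
    SampleQC,
    VariantAnnotation,
    VariantKey,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_fixture_ontology",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "read_reference_table_tsv",
    "write_reference_table_tsv",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
    "read_qc_tsv",
    "write_qc_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_markers_tsv",
    "write_markers_tsv",
    "write_scores_tsv",
    "read_scores_tsv",
    "write_obo",
]

_TERM_SEP = ";"


def load_fixture_ontology() -> Ontology:
    """The packaged ~58-term synthetic fixture ontology (stable term ids)."""
    ref = resources.files("mitotriage").joinpath("data/phenotype_fixture.obo")
    with resources.as_file(ref) as path:
        return parse_obo(path)


def _split_terms(cell: str) -> frozenset[str]:
    return frozenset(t.strip() for t in str(cell).split(_TERM_SEP) if t.strip())


def read_profiles_tsv(path: str | Path) -> list[PhenotypeProfile]:
    """2-column TSV: subject_id, semicolon-separated term ids (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require(df, ["subject_id", "hpo_terms"], path)
    return [PhenotypeProfile(subject_id=row.subject_id,
                             terms=_split_terms(row.hpo_terms))
            for row in df.itertuples()]


def write_profiles_tsv(profiles: Sequence[PhenotypeProfile],
                       path: str | Path) -> None:
    df = pd.DataFrame({
        "subject_id": [p.subject_id for p in profiles],
        "hpo_terms": [_TERM_SEP.join(sorted(p.terms)) for p in profiles],
    })
    df.to_csv(path, sep="\t", index=False)


def read_reference_table_tsv(path: str | Path) -> ReferenceProfileTable:
    """3-column TSV: subject_id, label, semicolon-separated term ids."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require(df, ["subject_id", "label", "hpo_terms"], path)
    profiles = [PhenotypeProfile(subject_id=row.subject_id,
                                 terms=_split_terms(row.hpo_terms))
                for row in df.itertuples()]
    labels = dict(zip(df["subject_id"], df["label"]))
    return ReferenceProfileTable(profiles=profiles, labels=labels)


def write_reference_table_tsv(refs: ReferenceProfileTable,
                              path: str | Path) -> None:
    df = pd.DataFrame({
        "subject_id": [p.subject_id for p in refs.profiles],
        "label": [refs.labels.get(p.subject_id, "") for p in refs.profiles],
        "hpo_terms": [_TERM_SEP.join(sorted(p.terms)) for p in refs.profiles],
    })
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[MtVariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require(df, ["sample_id", "position", "ref", "alt", "heteroplasmy", "depth"],
             path)
    return [MtVariantRecord(sample_id=str(r.sample_id), position=int(r.position),
                            ref=str(r.ref), alt=str(r.alt),
                            heteroplasmy=float(r.heteroplasmy), depth=int(r.depth))
            for r in df.itertuples()]


def write_variants_tsv(variants: Sequence[MtVariantRecord],
                       path: str | Path) -> None:
    df = pd.DataFrame([{
        "sample_id": v.sample_id, "position": v.position, "ref": v.ref,
        "alt": v.alt, "heteroplasmy": round(v.heteroplasmy, 6), "depth": v.depth,
    } for v in variants])
    df.to_csv(path, sep="\t", index=False)


_CHRM_NAMES = {"chrM", "MT", "chrMT", "M"}


def _normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # trim shared suffix, then shared prefix (left alignment for simple indels)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_variants_vcf(path: str | Path,
                      sample_id: Optional[str] = None) -> list[MtVariantRecord]:
    """Single-sample VCF restricted to the mitochondrial contig.

    Heteroplasmy is taken from the AF format/info field when present, else
    computed as AD[alt] / sum(AD).  Multiallelic rows are split into
    biallelic records; alleles are trimmed/left-aligned.
    """
    from cyvcf2 import VCF  # optional dependency, imported on use

    vcf = VCF(str(path))
    if sample_id is None:
        if len(vcf.samples) != 1:
            raise ValueError(
                f"{path}: expected a single-sample VCF, found {vcf.samples}")
        sample_id = vcf.samples[0]
    records: list[MtVariantRecord] = []
    for rec in vcf:
        if rec.CHROM not in _CHRM_NAMES:
            continue
        depth = int(rec.format("DP")[0][0]) if rec.format("DP") is not None else 0
        af = rec.format("AF")
        ad = rec.format("AD")
        for i, alt in enumerate(rec.ALT):
            if af is not None:
                het = float(af[0][i])
            elif ad is not None:
                counts = ad[0]
                total = counts.sum()
                het = float(counts[i + 1] / total) if total > 0 else 0.0
            else:
                raise ValueError(f"{path}: no AF or AD field at {rec.POS}")
            pos, ref, a = _normalize_allele(rec.POS, rec.REF, alt)
            records.append(MtVariantRecord(
                sample_id=sample_id, position=pos, ref=ref, alt=a,
                heteroplasmy=het, depth=depth))
    return records


def read_qc_tsv(path: str | Path) -> list[SampleQC]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require(df, ["sample_id", "assembled_fraction", "mean_depth"], path)
    has_assay = "assay" in df.columns
    has_tissue = "tissue" in df.columns
    return [SampleQC(sample_id=str(r.sample_id),
                     assembled_fraction=float(r.assembled_fraction),
                     mean_depth=float(r.mean_depth),
                     assay=str(r.assay) if has_assay else "ES",
                     tissue=str(r.tissue) if has_tissue else "blood")
            for r in df.itertuples()]


def write_qc_tsv(qc: Sequence[SampleQC], path: str | Path) -> None:
    df = pd.DataFrame([{
        "sample_id": q.sample_id, "assembled_fraction": round(q.assembled_fraction, 4),
        "mean_depth": round(q.mean_depth, 2), "assay": q.assay, "tissue": q.tissue,
    } for q in qc])
    df.to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: str | Path) -> dict[VariantKey, VariantAnnotation]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["position", "ref", "alt", "mitomap_status", "mitomap_af",
                  "in_mitophen"], path)
    out: dict[VariantKey, VariantAnnotation] = {}
    for r in df.itertuples():
        af = None if pd.isna(r.mitomap_af) else float(r.mitomap_af)
        a = VariantAnnotation(
            position=int(r.position), ref=str(r.ref), alt=str(r.alt),
            mitomap_status=str(r.mitomap_status), mitomap_af=af,
            in_mitophen=_as_bool(r.in_mitophen),
            gene=str(getattr(r, "gene", "") or ""),
            reportable=_as_bool(getattr(r, "reportable", False)))
        out[a.key] = a
    return out


def write_annotations_tsv(ann: Iterable[VariantAnnotation],
                          path: str | Path) -> None:
    df = pd.DataFrame([{
        "position": a.position, "ref": a.ref, "alt": a.alt,
        "mitomap_status": a.mitomap_status,
        "mitomap_af": "" if a.mitomap_af is None else a.mitomap_af,
        "in_mitophen": str(a.in_mitophen).lower(), "gene": a.gene,
        "reportable": str(a.reportable).lower(),
    } for a in ann])
    df.to_csv(path, sep="\t", index=False)


def read_markers_tsv(path: str | Path) -> HaplogroupMarkerTable:
    df = pd.read_csv(path, sep="\t", dtype={"haplogroup": str})
    _require(df, ["haplogroup", "position", "ref", "alt"], path)
    markers: dict[str, set[VariantKey]] = {}
    for r in df.itertuples():
        markers.setdefault(str(r.haplogroup), set()).add(
            (int(r.position), str(r.ref), str(r.alt)))
    return HaplogroupMarkerTable(markers={h: frozenset(m)
                                          for h, m in markers.items()})


def write_markers_tsv(markers: HaplogroupMarkerTable, path: str | Path) -> None:
    rows = [{"haplogroup": hg, "position": pos, "ref": ref, "alt": alt}
            for hg in markers.haplogroups
            for pos, ref, alt in sorted(markers.markers[hg])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_scores_tsv(scores: Sequence[PatientScore], path: str | Path) -> None:
    df = pd.DataFrame([{
        "subject_id": s.subject_id, "score": f"{s.score:.6f}",
        "best_match_id": s.best_match_id, "n_terms": s.n_terms,
        "mean_ic": f"{s.mean_ic:.6f}",
    } for s in scores])
    df.to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    """Labeled score table for calibration: subject_id, score, group."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    _require(df, ["subject_id", "score", "group"], path)
    return df


def write_obo(ont: Ontology, path: str | Path,
              ontology_name: str = "mitotriage-synthetic") -> None:
    """Serialize an ontology back to a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term_id in sorted(ont.terms):
        info = ont.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {info.name}")
        for p in sorted(info.parents):
            lines.append(f"is_a: {p}")
        if info.obsolete:
            lines.append("is_obsolete: true")
            if info.replaced_by:
                lines.append(f"replaced_by: {info.replaced_by}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def _require(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; "
                         f"found {list(df.columns)}")


def _as_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")
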