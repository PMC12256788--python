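"""Phenotype ontology handling.

Parses an OBO-format phenotype ontology (HPO or a compatible stand-in) into a
rooted DAG over ``is_a`` edges, answers ancestor queries, validates and
reduces phenotype term sets, and computes corpus-based information content
(IC).  IC is the building block of Lin semantic similarity: for a term *t*
annotated (directly or via a descendant) in *f* of *N* corpus profiles,

    IC(t) = -ln(f / N)    (nats)

so the root, implied by every profile, has IC 0, and IC never decreases when
walking from a parent to a child.  Terms never seen in the corpus receive the
add-one smoothed value -ln(1 / (N + 1)) so that similarity scores stay finite.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyError",
    "ParseError",
    "UnknownTermError",
    "EmptyProfileError",
    "TermInfo",
    "Ontology",
    "PhenotypeProfile",
    "ICTable",
    "parse_obo",
    "ancestors",
    "validate_profile",
    "reduce_nonredundant",
    "compute_ic",
]


class OntologyError(ValueError):
    """Structural problem with the ontology or a term-set operation."""


class ParseError(OntologyError):
    """Malformed OBO input."""


class UnknownTermError(KeyError):
    """A queried term id does not exist in the ontology."""


class EmptyProfileError(OntologyError):
    """A phenotype profile became empty after validation; scoring is undefined."""


@dataclass(frozen=True)
class TermInfo:
    """Static record for one ontology term."""

    name: str
    parents: frozenset[str]
    obsolete: bool = False
    replaced_by: Optional[str] = None


@dataclass
class Ontology:
    """A rooted DAG of phenotype terms connected by ``is_a`` edges.

    Only ``is_a`` edges are represented.  Obsolete terms are retained for
    ``replaced_by`` resolution but excluded from the DAG; they have no
    parents, no IC, and cannot be queried for ancestors.
    """

    terms: dict[str, TermInfo]
    root: str
    _ancestors: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _depth: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_edges(
        cls,
        parents: Mapping[str, Iterable[str]],
        names: Optional[Mapping[str, str]] = None,
        root: Optional[str] = None,
        obsolete: Optional[Mapping[str, Optional[str]]] = None,
    ) -> "Ontology":
        """Build and validate an ontology from a child -> parents mapping.

        ``obsolete`` maps obsolete term ids to their ``replaced_by`` target
        (or None).  Raises :class:`OntologyError` on cycles, on ambiguous or
        missing roots, and on terms disconnected from the root.
        """
        names = names or {}
        obsolete = obsolete or {}
        live = {t for t in parents if t not in obsolete}

        g = nx.DiGraph()
        g.add_nodes_from(live)
        for child, ps in parents.items():
            if child in obsolete:
                continue
            for p in ps:
                if p in obsolete:
                    raise OntologyError(
                        f"term {child!r} has obsolete parent {p!r}"
                    )
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"is_a graph contains a cycle: {cycle}")

        parentless = sorted(t for t in live if g.out_degree(t) == 0)
        if root is None:
            if len(parentless) != 1:
                raise OntologyError(
                    "cannot determine root: "
                    f"{len(parentless)} parentless terms {parentless[:5]} "
                    "(configure an explicit root id)"
                )
            root = parentless[0]
        elif root not in live:
            raise OntologyError(f"configured root {root!r} not in ontology")

        unreachable = sorted(
            t for t in live if t != root and root not in nx.descendants(g, t) | {t}
        )
        if unreachable:
            raise OntologyError(
                f"{len(unreachable)} terms have no is_a path to root "
                f"{root!r}: {unreachable[:5]}"
            )

        terms: dict[str, TermInfo] = {}
        for t in live:
            terms[t] = TermInfo(
                name=names.get(t, t),
                parents=frozenset(g.successors(t)),
            )
        for t, rep in obsolete.items():
            terms[t] = TermInfo(
                name=names.get(t, t),
                parents=frozenset(),
                obsolete=True,
                replaced_by=rep,
            )
        return cls(terms=terms, root=root)

    # -- queries ----------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def live_terms(self) -> list[str]:
        """All non-obsolete term ids, sorted."""
        return sorted(t for t, info in self.terms.items() if not info.obsolete)

    def _require_live(self, term: str) -> TermInfo:
        info = self.terms.get(term)
        if info is None:
            raise UnknownTermError(f"unknown term {term!r}")
        if info.obsolete:
            raise UnknownTermError(f"term {term!r} is obsolete")
        return info

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure over parent edges (includes ``term``)."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        info = self._require_live(term)
        closure = {term}
        for p in info.parents:
            closure |= self.ancestors(p)
        result = frozenset(closure)
        self._ancestors[term] = result
        return result

    def is_strict_ancestor(self, candidate: str, term: str) -> bool:
        """True iff ``candidate`` is an ancestor of ``term`` and not ``term`` itself."""
        return candidate != term and candidate in self.ancestors(term)

    def depth(self, term: str) -> int:
        """Longest is_a path length from the root down to ``term`` (root = 0)."""
        cached = self._depth.get(term)
        if cached is not None:
            return cached
        info = self._require_live(term)
        d = 0 if not info.parents else 1 + max(self.depth(p) for p in info.parents)
        self._depth[term] = d
        return d


@dataclass(frozen=True)
class PhenotypeProfile:
    """One subject's set of phenotype term ids (patient or reference proband)."""

    subject_id: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))


# Module-level functional aliases -----------------------------------------


def ancestors(ont: Ontology, term: str) -> frozenset[str]:
    """Reflexive ancestor closure of ``term`` (always contains the root)."""
    return ont.ancestors(term)


def validate_profile(ont: Ontology, profile: PhenotypeProfile) -> PhenotypeProfile:
    """Sanitize a profile against the ontology.

    Unknown ids are dropped with a warning; obsolete ids are mapped through
    ``replaced_by`` when available, else dropped.  Raises
    :class:`EmptyProfileError` if nothing survives, since similarity scoring
    is undefined on empty profiles.
    """
    kept: set[str] = set()
    for t in profile.terms:
        info = ont.terms.get(t)
        if info is None:
            logger.warning(
                "profile %s: dropping unknown term %s", profile.subject_id, t
            )
            continue
        if info.obsolete:
            if info.replaced_by is not None and info.replaced_by in ont.terms:
                rep = ont.terms[info.replaced_by]
                if not rep.obsolete:
                    logger.info(
                        "profile %s: obsolete term %s mapped to %s",
                        profile.subject_id, t, info.replaced_by,
                    )
                    kept.add(info.replaced_by)
                    continue
            logger.warning(
                "profile %s: dropping obsolete term %s (no replacement)",
                profile.subject_id, t,
            )
            continue
        kept.add(t)
    if not kept:
        raise EmptyProfileError(
            f"profile {profile.subject_id!r} has no valid terms after validation"
        )
    return PhenotypeProfile(subject_id=profile.subject_id, terms=frozenset(kept))


def reduce_nonredundant(ont: Ontology, terms: Iterable[str]) -> frozenset[str]:
    """Drop every term that is a strict ancestor of another retained term.

    The result is the maximal antichain-under-ancestry subset: leaves of the
    input are always kept, only redundant ancestors are removed.
    """
    term_set = set(terms)
    implied_ancestors: set[str] = set()
    for t in term_set:
        implied_ancestors |= set(ont.ancestors(t)) - {t}
    return frozenset(term_set - implied_ancestors)


@dataclass
class ICTable:
    """Per-term information content (nats) from an annotation corpus."""

    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise UnknownTermError(f"no IC for term {term!r}") from None

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def mean_ic(self, terms: Iterable[str]) -> float:
        vals = [self[t] for t in terms]
        return sum(vals) / len(vals) if vals else 0.0


def compute_ic(ont: Ontology, corpus: Sequence[PhenotypeProfile]) -> ICTable:
    """Information content of every live term from annotation frequencies.

    A profile annotates a term if it contains the term or any strict
    descendant, so frequencies propagate up the DAG and IC is anti-monotone
    along edges.  Terms absent from the corpus get the smoothed probability
    1/(N+1).
    """
    if not corpus:
        raise OntologyError("IC computation requires a non-empty corpus")
    n = len(corpus)
    counts: Counter[str] = Counter()
    for profile in corpus:
        implied: set[str] = set()
        for t in profile.terms:
            implied |= ont.ancestors(t)
        counts.update(implied)

    ic: dict[str, float] = {}
    for t in ont.live_terms:
        f = counts.get(t, 0)
        ic[t] = -math.log(f / n) if f > 0 else math.log(n + 1)
    return ICTable(ic=ic, corpus_size=n)


# OBO ingestion ------------------------------------------------------------

_TAG_LINE = re.compile(r"^[A-Za-z_][\w\-]*\s*:")


def _prescan_obo(path: Path) -> None:
    """Cheap structural scan so malformed stanzas fail with a line number."""
    in_stanza = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise ParseError(f"{path}:{lineno}: unterminated stanza header")
                in_stanza = True
                continue
            if in_stanza and not _TAG_LINE.match(line):
                raise ParseError(
                    f"{path}:{lineno}: expected 'tag: value' line, got {line!r}"
                )


def parse_obo(path: str | Path, root: Optional[str] = None) -> Ontology:
    """Read an OBO file into an :class:`Ontology`.

    Only ``[Term]`` stanzas and ``is_a`` edges are used; obsolete terms are
    retained with their ``replaced_by`` pointer.  ``root`` overrides automatic
    detection (the unique parentless term) for ontologies with several
    top-level terms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_obo(path)
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet raises varied types
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(graph) == 0:
        raise ParseError(f"{path}: no [Term] stanzas found")

    names: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    obsolete: dict[str, Optional[str]] = {}
    for node, data in graph.nodes(data=True):
        names[node] = data.get("name", node)
        if str(data.get("is_obsolete", "false")).lower() == "true":
            rep = data.get("replaced_by")
            obsolete[node] = rep[0] if rep else None
            continue
        parents[node] = set()
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        if child in parents and parent not in obsolete:
            parents[child].add(parent)

    return Ontology.from_edges(parents, names=names, root=root, obsolete=obsolete)
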