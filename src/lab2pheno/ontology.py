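"""HPO-style ontology loading and ancestor propagation.

A patient assigned a specific abnormality (say Eosinophilia) implicitly has
every more general ancestor abnormality (abnormal eosinophil count, abnormal
eosinophil morphology, ...).  Propagating observation counts up the is_a DAG
lets distinct tests with comparable interpretations aggregate under shared
parents — the machinery behind finding associations at terms no single test
maps to directly.

Supported formats: OBO 1.2 flat files (via :mod:`obonet`) and obographs-style
ontology JSON.  Obsolete terms are retained (with replacements resolved when
given) but excluded from closures; alt-ids resolve to primary ids.

Propagation uses union semantics over source-observation identity: one
observation contributes at most 1 to each ancestor, no matter how many paths
lead there (diamonds count once).  The closure stops below "Phenotypic
abnormality" (HP:0000118) and the root "All" (HP:0000001) by default — roots
that would otherwise be assigned to every patient are uninformative.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "DEFAULT_STOP_SET",
    "Ontology",
    "OntologyError",
    "load_ontology",
    "ancestors",
    "propagate_observations",
    "propagate_counts",
    "PropagationResult",
]

#: terms excluded (together with everything at-or-above them) from closures
DEFAULT_STOP_SET = frozenset({"HP:0000118", "HP:0000001"})


class OntologyError(ValueError):
    """Structural or usage error in an ontology file."""


@dataclass
class Ontology:
    """An is_a DAG over term ids, child -> parent edges."""

    graph: nx.DiGraph  # nodes: primary term ids; edges child -> parent
    labels: dict[str, str] = field(default_factory=dict)
    obsolete: dict[str, str | None] = field(default_factory=dict)  # id -> replacement
    alt_ids: dict[str, str] = field(default_factory=dict)  # alt -> primary

    @property
    def terms(self) -> set[str]:
        """All primary, non-obsolete term ids."""
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_ids or term in self.obsolete

    def primary_id(self, term: str) -> str:
        """Resolve alt-ids and obsolete replacements to a primary id."""
        term = self.alt_ids.get(term, term)
        seen = set()
        while term in self.obsolete and self.obsolete[term] and term not in seen:
            seen.add(term)
            term = self.obsolete[term]  # type: ignore[assignment]
            term = self.alt_ids.get(term, term)
        return term

    def label(self, term: str) -> str:
        return self.labels.get(term, term)

    def parents(self, term: str) -> set[str]:
        if term not in self.graph:
            return set()
        return set(self.graph.successors(term))

    def ancestors(self, term: str, stop_set: Iterable[str] | None = DEFAULT_STOP_SET) -> set[str]:
        return ancestors(self, term, stop_set)


def _validate(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyError(f"is_a cycle detected: {cycle}")


_OBO_ID = re.compile(r"^id:\s*(\S+)")
_OBO_REPLACED = re.compile(r"^replaced_by:\s*(\S+)")
_OBO_OBSOLETE = re.compile(r"^is_obsolete:\s*true")


def _scan_obo_obsolete(path: Path) -> dict[str, str | None]:
    """Collect obsolete stanzas (id -> replacement) that graph parsers drop."""
    obsolete: dict[str, str | None] = {}
    current: str | None = None
    is_obs = False
    replacement: str | None = None

    def flush() -> None:
        nonlocal current, is_obs, replacement
        if current is not None and is_obs:
            obsolete[current] = replacement
        current, is_obs, replacement = None, False, None

    in_term = False
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term:
                continue
            if m := _OBO_ID.match(line):
                current = m.group(1)
            elif _OBO_OBSOLETE.match(line):
                is_obs = True
            elif m := _OBO_REPLACED.match(line):
                replacement = m.group(1)
    flush()
    return obsolete


def _load_obo(path: Path) -> Ontology:
    multigraph = obonet.read_obo(str(path))
    graph = nx.DiGraph()
    labels: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        graph.add_node(node)
        if "name" in data:
            labels[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    return Ontology(
        graph=graph,
        labels=labels,
        obsolete=_scan_obo_obsolete(path),
        alt_ids=alt_ids,
    )


def _load_obographs(path: Path) -> Ontology:
    with path.open(encoding="utf-8") as fh:
        doc = json.load(fh)
    graphs = doc.get("graphs")
    if not graphs:
        raise OntologyError("no graphs in ontology JSON")
    g = graphs[0]

    def curie(uri: str) -> str:
        tail = uri.rsplit("/", 1)[-1]
        return tail.replace("_", ":", 1) if "_" in tail else tail

    graph = nx.DiGraph()
    labels: dict[str, str] = {}
    obsolete: dict[str, str | None] = {}
    alt_ids: dict[str, str] = {}
    for node in g.get("nodes", []):
        term = curie(node["id"])
        meta = node.get("meta") or {}
        if meta.get("deprecated"):
            replacement = None
            for prop in meta.get("basicPropertyValues", []) or []:
                if prop.get("pred", "").endswith(("term_replaced_by", "IAO_0100001")):
                    replacement = curie(prop["val"])
            obsolete[term] = replacement
            if node.get("lbl"):
                labels[term] = node["lbl"]
            continue
        graph.add_node(term)
        if node.get("lbl"):
            labels[term] = node["lbl"]
        for prop in meta.get("basicPropertyValues", []) or []:
            if prop.get("pred", "").endswith("hasAlternativeId"):
                alt_ids[curie(prop["val"])] = term
    for edge in g.get("edges", []):
        if edge.get("pred") == "is_a":
            child, parent = curie(edge["sub"]), curie(edge["obj"])
            if child in graph and parent in graph:
                graph.add_edge(child, parent)
    return Ontology(graph=graph, labels=labels, obsolete=obsolete, alt_ids=alt_ids)


def load_ontology(path: str | Path, fmt: str | None = None) -> Ontology:
    """Load an ontology from OBO or obographs JSON.

    ``fmt`` is "obo" or "json"; inferred from the suffix when omitted.
    Raises :class:`OntologyError` on is_a cycles or unknown formats.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "obo"
    if fmt == "obo":
        ont = _load_obo(path)
    elif fmt == "json":
        ont = _load_obographs(path)
    else:
        raise OntologyError(f"unknown ontology format {fmt!r}")
    _validate(ont.graph)
    return ont


def ancestors(
    ont: Ontology, term: str, stop_set: Iterable[str] | None = DEFAULT_STOP_SET
) -> set[str]:
    """Transitive is_a closure of ``term`` (excluding the term itself).

    Members of ``stop_set`` — and everything at-or-above them — are excluded.
    Obsolete terms never appear in closures.  Raises KeyError for terms
    unknown to the ontology.
    """
    primary = ont.primary_id(term)
    if primary not in ont.graph:
        raise KeyError(f"term {term!r} not in ontology")
    closure = nx.descendants(ont.graph, primary)  # edges point child -> parent
    stop = set(stop_set or ())
    excluded = set()
    for s in stop:
        if s in ont.graph:
            excluded |= {s} | nx.descendants(ont.graph, s)
        else:
            excluded.add(s)
    return {t for t in closure - excluded if t not in ont.obsolete}


@dataclass
class PropagationResult:
    """Augmented per-term contributions plus any unknown terms skipped."""

    contributions: dict[str, frozenset[str]]
    skipped: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {t: len(s) for t, s in self.contributions.items()}


def propagate_observations(
    profile: Mapping[str, Iterable[str]],
    ont: Ontology,
    stop_set: Iterable[str] | None = DEFAULT_STOP_SET,
) -> PropagationResult:
    """Propagate per-term source-observation sets up the is_a hierarchy.

    Each observation contributes at most once to each ancestor (set union),
    so diamonds never double count and the operation is idempotent.  Terms
    absent from the ontology are skipped (reported, not fatal).
    """
    out: dict[str, set[str]] = {}
    skipped: list[str] = []
    for term, obs_ids in profile.items():
        primary = ont.primary_id(term)
        if primary not in ont.graph:
            skipped.append(term)
            continue
        ids = set(obs_ids)
        out.setdefault(primary, set()).update(ids)
        for anc in ancestors(ont, primary, stop_set):
            out.setdefault(anc, set()).update(ids)
    return PropagationResult(
        contributions={t: frozenset(s) for t, s in out.items()},
        skipped=skipped,
    )


def propagate_counts(
    profile: Mapping[str, int],
    ont: Ontology,
    stop_set: Iterable[str] | None = DEFAULT_STOP_SET,
) -> tuple[dict[str, int], list[str]]:
    """Count view of :func:`propagate_observations` for plain term -> count
    profiles: each counted observation is given a synthetic identity, so an
    ancestor's count is the number of distinct source observations at or
    below it.  Asserted counts are unchanged (output >= input pointwise)."""
    with_ids = {
        term: [f"{term}#{i}" for i in range(int(n))] for term, n in profile.items()
    }
    result = propagate_observations(with_ids, ont, stop_set)
    return result.counts, result.skipped
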