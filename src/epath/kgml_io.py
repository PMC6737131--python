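"""KGML pathway I/O and the compound-by-compound reaction matrix.

KGML (KEGG Markup Language) encodes a metabolic map as ``entry`` elements
(compounds, genes, orthologs) plus ``reaction`` elements with substrate and
product children. Here each reaction becomes an undirected edge between its
substrate and product compounds, scored 5 when at least one of its genes is
experimentally essential and 1 when all are non-essential; absent reactions
score 0. The symmetric matrix S of these scores is the object the remapping
search traverses.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError, IntegrityError
from .ko_tables import ESSENTIAL

logger = logging.getLogger(__name__)

ESSENTIAL_SCORE = 5
NONESSENTIAL_SCORE = 1


@dataclass
class ReactionRecord:
    """One biochemical reaction: substrates, products, KOs and gene locus tags."""

    reaction_id: str
    substrates: list[str]
    products: list[str]
    ko_ids: set[str] = field(default_factory=set)
    locus_tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise IntegrityError(
                f"reaction {self.reaction_id}: substrates and products must be non-empty"
            )


@dataclass
class Edge:
    """Undirected edge between compound indices ``i`` and ``j``.

    Parallel edges between the same compound pair are kept distinct; the
    shared ReactionRecord carries the gene-level bookkeeping.
    """

    i: int
    j: int
    record: ReactionRecord
    score: int

    def endpoints(self) -> tuple[int, int]:
        return self.i, self.j


@dataclass
class PathwayGraph:
    """Compound nodes plus scored reaction edges of one metabolic map."""

    compounds: list[str]
    edges: list[Edge] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.compounds)

    def __post_init__(self) -> None:
        for e in self.edges:
            if not (0 <= e.i < self.n and 0 <= e.j < self.n):
                raise IntegrityError("edge endpoint outside compound index range")

    def compound_index(self) -> dict[str, int]:
        return {c: k for k, c in enumerate(self.compounds)}

    def to_json(self) -> str:
        payload = {
            "compounds": self.compounds,
            "edges": [
                {
                    "i": e.i,
                    "j": e.j,
                    "score": e.score,
                    "reaction_id": e.record.reaction_id,
                    "substrates": e.record.substrates,
                    "products": e.record.products,
                    "ko_ids": sorted(e.record.ko_ids),
                    "locus_tags": sorted(e.record.locus_tags),
                }
            for e in self.edges],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PathwayGraph":
        payload = json.loads(text)
        edges = [
            Edge(
                i=d["i"],
                j=d["j"],
                score=d["score"],
                record=ReactionRecord(
                    reaction_id=d["reaction_id"],
                    substrates=list(d["substrates"]),
                    products=list(d["products"]),
                    ko_ids=set(d["ko_ids"]),
                    locus_tags=set(d["locus_tags"]),
                ),
            )
            for d in payload["edges"]
        ]
        return cls(compounds=list(payload["compounds"]), edges=edges)


@dataclass
class ReactionMatrix:
    """Symmetric n x n integer matrix of reaction scores (S, or rescored S')."""

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (self.n, self.n):
            raise IntegrityError("matrix shape does not match declared dimension")
        if not np.array_equal(self.values, self.values.T):
            raise IntegrityError("reaction matrix must be symmetric")


def _strip_prefix(token: str) -> str:
    # KGML names carry namespace prefixes: cpd:C00022, rn:R00200, ko:K00001, eco:b0002
    return token.split(":", 1)[1] if ":" in token else token


def parse_kgml(xml_path) -> list[ReactionRecord]:
    """Parse a KGML file into one ReactionRecord per ``reaction`` element.

    Locus tags come only from entries with type="gene"; ortholog entries
    contribute KO identifiers but no locus tags, so reactions backed only by
    ortholog entries are retained with empty locus_tags (reference maps).
    Substrates/products must resolve to declared compound entries.
    """
    try:
        tree = ET.parse(xml_path)
    except ET.ParseError as exc:
        raise FormatError(f"{xml_path}: malformed KGML XML ({exc})") from exc
    root = tree.getroot()

    compounds_by_entry_id: dict[str, str] = {}
    declared_compounds: set[str] = set()
    genes_by_reaction: dict[str, set[str]] = {}
    kos_by_reaction: dict[str, set[str]] = {}

    for entry in root.iter("entry"):
        etype = entry.get("type", "")
        names = [_strip_prefix(t) for t in (entry.get("name") or "").split() if t]
        reactions = [
            _strip_prefix(t) for t in (entry.get("reaction") or "").split() if t
        ]
        if etype == "compound":
            if names:
                compounds_by_entry_id[entry.get("id", "")] = names[0]
                declared_compounds.update(names)
        elif etype == "gene":
            for rid in reactions:
                genes_by_reaction.setdefault(rid, set()).update(names)
            for rid in reactions:
                kos_by_reaction.setdefault(rid, set())
        elif etype == "ortholog":
            for rid in reactions:
                kos_by_reaction.setdefault(rid, set()).update(
                    n for n in names if n.startswith("K")
                )

    def _resolve(elem, rid) -> str:
        name = elem.get("name")
        if name:
            cid = _strip_prefix(name.split()[0])
        else:
            ref = elem.get("id", "")
            if ref not in compounds_by_entry_id:
                raise IntegrityError(
                    f"reaction {rid}: substrate/product references undeclared entry {ref!r}"
                )
            cid = compounds_by_entry_id[ref]
        if declared_compounds and cid not in declared_compounds:
            raise IntegrityError(
                f"reaction {rid}: compound {cid!r} is not declared as a compound entry"
            )
        return cid

    records: list[ReactionRecord] = []
    for reaction in root.iter("reaction"):
        rid = _strip_prefix(
            reaction.get("name") or reaction.get("id") or ""
        ).split()[0]
        substrates = [_resolve(s, rid) for s in reaction.findall("substrate")]
        products = [_resolve(p, rid) for p in reaction.findall("product")]
        records.append(
            ReactionRecord(
                reaction_id=rid,
                substrates=substrates,
                products=products,
                ko_ids=set(kos_by_reaction.get(rid, set())),
                locus_tags=set(genes_by_reaction.get(rid, set())),
            )
        )
    return records


def declared_compounds(xml_path) -> list[str]:
    """Compound ids declared as ``entry type="compound"`` elements, in file order."""
    try:
        tree = ET.parse(xml_path)
    except ET.ParseError as exc:
        raise FormatError(f"{xml_path}: malformed KGML XML ({exc})") from exc
    seen: list[str] = []
    for entry in tree.getroot().iter("entry"):
        if entry.get("type") == "compound":
            for token in (entry.get("name") or "").split():
                cid = _strip_prefix(token)
                if cid not in seen:
                    seen.append(cid)
    return seen


def build_pathway_graph(
    records: list[ReactionRecord],
    labels: dict[str, str],
    compounds: list[str] | None = None,
) -> PathwayGraph:
    """Score reactions from gene labels and expand them into compound edges.

    An edge scores 5 when at least one of the reaction's genes is
    experimentally essential and 1 otherwise. A reaction with several
    substrates/products expands into one edge per substrate x product pair,
    all sharing the same record and score. Locus tags absent from ``labels``
    are treated as non-essential with a warning.
    """
    if compounds is None:
        seen: list[str] = []
        for rec in records:
            for cid in rec.substrates + rec.products:
                if cid not in seen:
                    seen.append(cid)
        compounds = seen
    index = {c: k for k, c in enumerate(compounds)}

    edges: list[Edge] = []
    for rec in records:
        essential = False
        for tag in rec.locus_tags:
            if tag not in labels:
                logger.warning(
                    "locus tag %s has no label; treated as non-essential", tag
                )
            elif labels[tag] == ESSENTIAL:
                essential = True
        score = ESSENTIAL_SCORE if essential else NONESSENTIAL_SCORE
        for s in rec.substrates:
            for p in rec.products:
                try:
                    edges.append(Edge(i=index[s], j=index[p], record=rec, score=score))
                except KeyError as exc:
                    raise IntegrityError(
                        f"reaction {rec.reaction_id}: undeclared compound {exc.args[0]!r}"
                    ) from exc
    return PathwayGraph(compounds=list(compounds), edges=edges)


def to_reaction_matrix(graph: PathwayGraph) -> ReactionMatrix:
    """Collapse the edge list into the symmetric score matrix S.

    Parallel edges collapse by maximum score; the diagonal stays 0.
    """
    values = np.zeros((graph.n, graph.n), dtype=int)
    for e in graph.edges:
        if e.i == e.j:
            continue
        s = max(values[e.i, e.j], e.score)
        values[e.i, e.j] = s
        values[e.j, e.i] = s
    return ReactionMatrix(n=graph.n, values=values)


def write_kgml(graph: PathwayGraph, path) -> None:
    """Serialize a pathway graph to KGML parseable by :func:`parse_kgml`.

    Distinct ReactionRecords are written once each, so the substrate x product
    expansion regenerates the original edge set on re-parse (given the same
    label map for scores).
    """
    root = ET.Element("pathway", attrib={"name": "path:synthetic", "number": "01100"})
    next_id = 1
    for cid in graph.compounds:
        ET.SubElement(
            root,
            "entry",
            attrib={"id": str(next_id), "name": f"cpd:{cid}", "type": "compound"},
        )
        next_id += 1

    seen_records: list[ReactionRecord] = []
    for e in graph.edges:
        if not any(rec is e.record for rec in seen_records):
            seen_records.append(e.record)

    for rec in seen_records:
        if rec.locus_tags:
            ET.SubElement(
                root,
                "entry",
                attrib={
                    "id": str(next_id),
                    "name": " ".join(sorted(rec.locus_tags)),
                    "type": "gene",
                    "reaction": f"rn:{rec.reaction_id}",
                },
            )
            next_id += 1
        if rec.ko_ids:
            ET.SubElement(
                root,
                "entry",
                attrib={
                    "id": str(next_id),
                    "name": " ".join(f"ko:{k}" for k in sorted(rec.ko_ids)),
                    "type": "ortholog",
                    "reaction": f"rn:{rec.reaction_id}",
                },
            )
            next_id += 1
        relem = ET.SubElement(
            root,
            "reaction",
            attrib={
                "id": str(next_id),
                "name": f"rn:{rec.reaction_id}",
                "type": "reversible",
            },
        )
        next_id += 1
        for s in rec.substrates:
            ET.SubElement(relem, "substrate", attrib={"name": f"cpd:{s}"})
        for p in rec.products:
            ET.SubElement(relem, "product", attrib={"name": f"cpd:{p}"})

    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
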