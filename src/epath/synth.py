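"""Synthetic fixtures: pathway maps with planted gap genes, strain panels, annotation tables.

The pathway generator emulates the biological scenario behind gap genes: an
essential metabolic function carried by a paralog/isozyme pair, so that
single-gene knockouts label both copies non-essential although the reaction
they catalyze sits between experimentally essential neighbors. Each planted
pair becomes a score-1 edge flanked on both compound ends by score-5 edges
(guaranteed recoverable by the both-sides criterion), while connector and
distractor score-1 edges are laid out so that no other edge has essential
support on both sides:

* pair blocks  A --5-- B --1(gap)-- C --5-- D, attached to a hub J through a
  two-edge score-1 buffer (A -- m -- J), which blocks support from leaking
  across blocks;
* a score-1 chain hanging off the hub absorbs the remaining compound budget;
* extra essential edges are placed as pendant score-5 edges on chain nodes at
  least four positions apart (closer spacing would manufacture accidental
  gaps) or as parallel copies of existing score-5 edges;
* remaining reaction budget becomes parallel copies of score-5 edges, or of
  score-1 edges neither of whose endpoints touches a score-5 edge; either kind
  leaves every edge's two-sided support unchanged.

Locus tags and KOs are numbered in lockstep (g0007 carries K00007), so the
tag -> KO map is a pure function and strain tables can be derived from any
generated graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .kgml_io import (
    ESSENTIAL_SCORE,
    NONESSENTIAL_SCORE,
    Edge,
    PathwayGraph,
    ReactionRecord,
)
from .ko_tables import (
    ESSENTIAL,
    NONESSENTIAL,
    EssentialityCounts,
    KOAnnotation,
    StrainGeneRecord,
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic fixtures.

    Defaults emulate a small metabolic map (40 compounds, 48 reactions, a
    quarter of them essential) with three paralog-masked gap reactions, and
    the 31-strain experimental training panel.
    """

    n_compounds: int = 40
    n_reactions: int = 48
    n_strains: int = 31
    essential_fraction: float = 0.25
    n_paralog_pairs: int = 3
    n_kos: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2 or self.n_reactions < 1:
            raise ConfigError("need at least 2 compounds and 1 reaction")
        if self.n_strains < 1:
            raise ConfigError("n_strains must be >= 1")
        if not (0.0 < self.essential_fraction < 1.0):
            raise ConfigError("essential_fraction must be in (0, 1)")
        if self.n_paralog_pairs < 0:
            raise ConfigError("n_paralog_pairs must be >= 0")
        if self.n_paralog_pairs > self.n_reactions / 2:
            raise ConfigError("n_paralog_pairs must not exceed n_reactions/2")
        if self.n_reactions < self.n_compounds - 1:
            raise ConfigError("connected graph needs n_reactions >= n_compounds - 1")
        if self.n_kos < 1:
            raise ConfigError("n_kos must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for assertion against recovered results."""

    essential_kos: set[str] = field(default_factory=set)
    gap_edges: set[int] = field(default_factory=set)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)


def ko_for_tag(tag: str) -> str:
    """The KO paired with a synthetic locus tag (g0007 -> K00007)."""
    return f"K{int(tag[1:]):05d}"


def labels_from_graph(graph: PathwayGraph) -> dict[str, str]:
    """Experimental labels implied by edge scores: tags on a score-5 edge are essential."""
    labels: dict[str, str] = {}
    for e in graph.edges:
        for tag in e.record.locus_tags:
            labels.setdefault(tag, NONESSENTIAL)
    for e in graph.edges:
        if e.score == ESSENTIAL_SCORE:
            for tag in e.record.locus_tags:
                labels[tag] = ESSENTIAL
    return labels


def strain_table_from_graph(graph: PathwayGraph, strain_id: str) -> list[StrainGeneRecord]:
    """One DEG-style gene table listing every gene on the map with its label."""
    labels = labels_from_graph(graph)
    return [
        StrainGeneRecord(
            strain_id=strain_id, locus_tag=tag, ko_id=ko_for_tag(tag), label=label
        )
        for tag, label in sorted(labels.items())
    ]


class _Counter:
    def __init__(self) -> None:
        self.gene = 0
        self.reaction = 0
        self.compound = 0

    def next_gene(self) -> tuple[str, str]:
        self.gene += 1
        return f"g{self.gene:04d}", f"K{self.gene:05d}"

    def next_reaction(self) -> str:
        self.reaction += 1
        return f"R{self.reaction:05d}"

    def next_compound(self) -> str:
        self.compound += 1
        return f"C{self.compound:05d}"


def simulate_pathway(cfg: SynthConfig) -> tuple[PathwayGraph, GroundTruth]:
    """Generate a connected scored pathway with recoverable planted gap edges.

    Deterministic for a fixed seed. Raises ConfigError when the compound or
    reaction budget cannot host the requested paralog pairs.
    """
    rng = np.random.default_rng(cfg.seed)
    P = cfg.n_paralog_pairs
    blocks_compounds = 5 * P + 1  # A,B,C,D,buffer per block + hub
    if cfg.n_compounds < blocks_compounds:
        raise ConfigError(
            f"{cfg.n_compounds} compounds cannot host {P} paralog pairs "
            f"(need at least {blocks_compounds})"
        )
    n_parallel = cfg.n_reactions - (cfg.n_compounds - 1)
    target_ess = round(cfg.essential_fraction * cfg.n_reactions)
    extra_ess = max(0, target_ess - 2 * P)

    # split the free compound budget between the chain and pendant 5-edges
    free = cfg.n_compounds - blocks_compounds
    n_pendants = 0
    for cand in range(min(extra_ess, free), -1, -1):
        chain_len = free - cand
        capacity = 0 if chain_len < 2 else (chain_len - 2) // 4 + 1
        if cand <= capacity:
            n_pendants = cand
            break
    chain_len = free - n_pendants

    ctr = _Counter()
    truth = GroundTruth()
    compounds: list[str] = []
    edges: list[Edge] = []

    def new_node() -> str:
        cid = ctr.next_compound()
        compounds.append(cid)
        return cid

    index: dict[str, int] = {}

    def add_edge(u: str, v: str, score: int, n_genes: int = 1) -> int:
        rid = ctr.next_reaction()
        tags, kos = set(), set()
        for _ in range(n_genes):
            tag, ko = ctr.next_gene()
            tags.add(tag)
            kos.add(ko)
            if score == ESSENTIAL_SCORE:
                truth.essential_kos.add(ko)
        for c in (u, v):
            if c not in index:
                index[c] = compounds.index(c)
        rec = ReactionRecord(
            reaction_id=rid, substrates=[u], products=[v], ko_ids=kos, locus_tags=tags
        )
        edges.append(Edge(i=index[u], j=index[v], record=rec, score=score))
        return len(edges) - 1

    hub = new_node()
    essential_edge_idx: list[int] = []

    for _ in range(P):
        a, b, c, d, buf = (new_node() for _ in range(5))
        essential_edge_idx.append(add_edge(a, b, ESSENTIAL_SCORE))
        gap_idx = add_edge(b, c, NONESSENTIAL_SCORE, n_genes=2)
        truth.gap_edges.add(gap_idx)
        pair = tuple(sorted(edges[gap_idx].record.ko_ids))
        truth.paralog_pairs.append(pair)  # type: ignore[arg-type]
        essential_edge_idx.append(add_edge(c, d, ESSENTIAL_SCORE))
        add_edge(a, buf, NONESSENTIAL_SCORE)
        add_edge(buf, hub, NONESSENTIAL_SCORE)

    chain_nodes: list[str] = []
    prev = hub
    for _ in range(chain_len):
        node = new_node()
        add_edge(prev, node, NONESSENTIAL_SCORE)
        chain_nodes.append(node)
        prev = node

    # pendant essential edges on chain positions 2, 6, 10, ... (1-based),
    # randomly jittered while keeping >= 4 positions between pendants
    if n_pendants:
        positions: list[int] = []
        pos = 2
        for _ in range(n_pendants):
            limit = chain_len - 4 * (n_pendants - len(positions) - 1)
            pos = int(rng.integers(pos, limit + 1)) if limit > pos else pos
            positions.append(pos)
            pos += 4
        for t in positions:
            leaf = new_node()
            essential_edge_idx.append(
                add_edge(chain_nodes[t - 1], leaf, ESSENTIAL_SCORE)
            )

    # Parallel copies fill the remaining reaction budget. Essential duplicates
    # of score-5 edges come first (toward essential_fraction); the rest are
    # score-1 duplicates of edges with NEITHER endpoint touching a score-5
    # edge — a score-1 twin of an edge whose far endpoint is
    # essential-adjacent would hand the near side a second route to that
    # essential edge and manufacture an accidental gap.
    eg_adjacent = {e.i for e in edges if e.score == ESSENTIAL_SCORE} | {
        e.j for e in edges if e.score == ESSENTIAL_SCORE
    }
    n_essential_now = 2 * P + n_pendants
    for _ in range(n_parallel):
        safe_neutral = [
            e
            for e in edges
            if e.score == NONESSENTIAL_SCORE
            and e.i not in eg_adjacent
            and e.j not in eg_adjacent
        ]
        if (n_essential_now < target_ess or not safe_neutral) and essential_edge_idx:
            src = edges[int(rng.choice(essential_edge_idx))]
            score = ESSENTIAL_SCORE
            n_essential_now += 1
        else:
            src = safe_neutral[int(rng.integers(len(safe_neutral)))]
            score = NONESSENTIAL_SCORE
        add_edge(compounds[src.i], compounds[src.j], score, n_genes=1)
        if score == ESSENTIAL_SCORE:
            essential_edge_idx.append(len(edges) - 1)

    graph = PathwayGraph(compounds=compounds, edges=edges)
    assert graph.n == cfg.n_compounds and len(graph.edges) == cfg.n_reactions
    return graph, truth


def simulate_strain_panel(
    cfg: SynthConfig,
    essential_kos: set[str],
    presence_prob: float = 0.8,
) -> tuple[list[list[StrainGeneRecord]], dict[str, EssentialityCounts]]:
    """Generate DEG-style gene tables for ``cfg.n_strains`` training strains.

    The KO pool is ``essential_kos`` padded with non-essential KOs up to
    ``cfg.n_kos``. Each KO is present in each strain independently with
    probability ``presence_prob``; when present, a gene is emitted labeled
    essential_experimental iff its KO is in ``essential_kos``. The expected
    per-KO tallies are returned alongside, bookkept directly during
    generation.
    """
    if not (0.0 < presence_prob <= 1.0):
        raise ConfigError("presence_prob must be in (0, 1]")
    rng = np.random.default_rng([cfg.seed, 17])
    pool = sorted(essential_kos)
    k = 1
    while len(pool) < cfg.n_kos:
        ko = f"K{k:05d}"
        if ko not in essential_kos:
            pool.append(ko)
        k += 1
    pool = sorted(pool[: cfg.n_kos])

    tables: list[list[StrainGeneRecord]] = []
    tally: dict[str, list[int]] = {ko: [0, 0, 0] for ko in pool}
    for s in range(1, cfg.n_strains + 1):
        sid = f"s{s:02d}"
        table: list[StrainGeneRecord] = []
        for g, ko in enumerate(pool, start=1):
            if rng.random() > presence_prob:
                continue
            essential = ko in essential_kos
            table.append(
                StrainGeneRecord(
                    strain_id=sid,
                    locus_tag=f"{sid}_{g:04d}",
                    ko_id=ko,
                    label=ESSENTIAL if essential else NONESSENTIAL,
                )
            )
            tally[ko][0 if essential else 2] += 1
        tables.append(table)

    expected = {
        ko: EssentialityCounts(
            ko_id=ko, eg_e=c[0], eg_m=c[1], non_eg=c[2], n_strains=cfg.n_strains
        )
        for ko, c in tally.items()
        if sum(c) > 0
    }
    return tables, expected


def simulate_annotations(
    cfg: SynthConfig,
    kegg_group_sizes: list[int] | None = None,
    cog_group_sizes: list[int] | None = None,
    n_linked: int = 0,
) -> dict[str, KOAnnotation]:
    """Generate a KO annotation table with controllable group structure.

    KOs K00001..K{n_kos} are partitioned into pathway-annotation groups of the
    given sizes (leftover KOs get the empty string, forming the empty-string
    group); COG groups likewise. The last ``n_linked`` KOs carry no reaction
    of their own except one shared with a seed KO, so expanding the seed set
    by shared reactions attaches exactly ``n_linked`` extra KOs.
    """
    if n_linked >= cfg.n_kos:
        raise ConfigError("n_linked must be smaller than n_kos")
    kos = [f"K{i:05d}" for i in range(1, cfg.n_kos + 1)]
    n_seed = cfg.n_kos - n_linked

    def _group_strings(sizes: list[int] | None, stem: str) -> list[str]:
        if sizes is None:
            sizes = [max(2, cfg.n_kos // 10)] * 5
        strings: list[str] = []
        for g, size in enumerate(sizes, start=1):
            strings.extend([f"{stem} group {g:03d}//{stem} subgroup {g:03d}//"] * size)
        strings.extend([""] * (cfg.n_kos - len(strings)))
        return strings[: cfg.n_kos]

    kegg_strings = _group_strings(kegg_group_sizes, "pathway")
    cog_strings = _group_strings(cog_group_sizes, "COG")

    table: dict[str, KOAnnotation] = {}
    for idx, ko in enumerate(kos):
        if idx < n_seed:
            reactions = frozenset({f"R{idx + 1:05d}"})
        else:
            partner = (idx - n_seed) % n_seed
            reactions = frozenset({f"R{partner + 1:05d}"})
        table[ko] = KOAnnotation(
            ko_id=ko,
            kegg_pathway_annotation=kegg_strings[idx],
            cog_annotation=cog_strings[idx],
            reaction_ids=reactions,
            gene_name=f"gene{idx + 1}",
            description=f"synthetic ortholog {idx + 1}",
        )
    return table
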