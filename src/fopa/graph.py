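"""Pathway topologies: KGML parsing, normalization, decoys, and perturbations.

A pathway is a directed network of genes with typed interactions.  Every
interaction kind has a polarity: activating kinds (activation,
phosphorylation/dephosphorylation activation, indirect effect, expression)
promote the activation of the target, inhibiting kinds prevent it.  The
guarded-command model built downstream only distinguishes the two polarity
families, but the original kind is kept on each edge for provenance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from lxml import etree

__all__ = [
    "InteractionKind",
    "Edge",
    "PathwayGraph",
    "PathwayCollection",
    "parse_kgml",
    "normalize_graph",
    "final_effectors",
    "make_decoy",
    "perturb_graph",
    "read_edge_list",
    "write_edge_list",
]


class InteractionKind(str, enum.Enum):
    """Typed gene-gene interaction; each kind maps to one polarity."""

    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    PHOSPHORYLATION_ACTIVATION = "phosphorylation_activation"
    PHOSPHORYLATION_INHIBITION = "phosphorylation_inhibition"
    DEPHOSPHORYLATION_ACTIVATION = "dephosphorylation_activation"
    DEPHOSPHORYLATION_INHIBITION = "dephosphorylation_inhibition"
    INDIRECT_EFFECT = "indirect_effect"

    @property
    def is_activating(self) -> bool:
        return self in _ACTIVATING

    @property
    def polarity(self) -> int:
        """+1 for the activation family, -1 for the inhibition family."""
        return 1 if self.is_activating else -1


_ACTIVATING = {
    InteractionKind.ACTIVATION,
    InteractionKind.PHOSPHORYLATION_ACTIVATION,
    InteractionKind.DEPHOSPHORYLATION_ACTIVATION,
    InteractionKind.INDIRECT_EFFECT,
}


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    kind: InteractionKind

    @property
    def polarity(self) -> int:
        return self.kind.polarity


@dataclass
class PathwayGraph:
    """Directed gene-interaction network with typed edges.

    ``non_gene`` holds node identifiers flagged as compounds/maps by the
    parser; ``normalize_graph`` removes them while preserving connectivity.
    ``log`` records every normalization action.
    """

    id: str
    nodes: set[str] = field(default_factory=set)
    edges: list[Edge] = field(default_factory=list)
    non_gene: set[str] = field(default_factory=set)
    provenance: str = ""
    log: list[str] = field(default_factory=list)

    # -- basic views -------------------------------------------------------
    def gene_nodes(self) -> set[str]:
        return self.nodes - self.non_gene

    def out_degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.source == node)

    def in_degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.target == node)

    def sorted_genes(self) -> list[str]:
        return sorted(self.gene_nodes())

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges, key=lambda e: (e.source, e.target, e.kind.value))

    def edge_set(self) -> set[tuple[str, str, int]]:
        return {(e.source, e.target, e.polarity) for e in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        """Polarity-agnostic DiGraph view (for reachability/ancestor queries)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(
            id=self.id,
            nodes=set(self.nodes),
            edges=list(self.edges),
            non_gene=set(self.non_gene),
            provenance=self.provenance,
            log=list(self.log),
        )


@dataclass
class PathwayCollection:
    """A set of pathways plus the union of their genes.

    Interaction probabilities and gene-frequency weights are counted over
    this collection, so the pathway being scored must itself be a member.
    """

    pathways: list[PathwayGraph]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValueError("pathway ids must be unique")

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.gene_nodes()
        return out

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> PathwayGraph:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def replace_pathway(self, g: PathwayGraph) -> "PathwayCollection":
        """New collection with the member of the same id swapped for ``g``."""
        return PathwayCollection(
            [g if p.id == g.id else p for p in self.pathways]
        )


# ---------------------------------------------------------------------------
# KGML parsing
# ---------------------------------------------------------------------------

# KGML relation subtype names -> interaction kind.  Subtype combinations such
# as activation+phosphorylation refine the kind; the polarity-free subtypes
# (binding/association, missing, ...) are dropped by the parser and logged.
_POLARITY_SUBTYPES = {
    "activation": 1,
    "expression": 1,  # transcription-factor -> target; activation family
    "inhibition": -1,
    "repression": -1,
}


def _subtypes_to_kind(subtypes: list[str]) -> InteractionKind | None:
    pol = 0
    for s in subtypes:
        pol = _POLARITY_SUBTYPES.get(s, pol) or pol
    phos = "phosphorylation" in subtypes
    dephos = "dephosphorylation" in subtypes
    if "indirect effect" in subtypes and pol >= 0:
        return InteractionKind.INDIRECT_EFFECT
    # Lone (de)phosphorylation carries an implicit polarity by KEGG drawing
    # convention: +p arrows activate, -p arrows typically deactivate.
    if pol == 0 and phos:
        pol = 1
    if pol == 0 and dephos:
        pol = -1
    if pol == 0:
        return None
    if phos:
        return (
            InteractionKind.PHOSPHORYLATION_ACTIVATION
            if pol > 0
            else InteractionKind.PHOSPHORYLATION_INHIBITION
        )
    if dephos:
        return (
            InteractionKind.DEPHOSPHORYLATION_ACTIVATION
            if pol > 0
            else InteractionKind.DEPHOSPHORYLATION_INHIBITION
        )
    return InteractionKind.ACTIVATION if pol > 0 else InteractionKind.INHIBITION


class KGMLStructureError(ValueError):
    """A relation references an entry id that does not exist."""


def parse_kgml(document: str | bytes) -> PathwayGraph:
    """Parse a KGML (KEGG XML) document into a raw :class:`PathwayGraph`.

    Gene-type entries become candidate nodes; an entry naming several genes
    is expanded to one node per gene, each inheriting the entry's relations.
    Group entries are expanded to their component genes the same way.
    Compound/map entries are kept but flagged non-gene so that
    :func:`normalize_graph` can remove them while reconnecting their
    neighbours.  Relations without an activation/inhibition polarity are
    dropped and logged.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed KGML document: {exc}") from None

    pid = root.get("name") or root.get("title") or "pathway"
    g = PathwayGraph(id=pid, provenance="kgml")

    # entry id -> (list of node names, is_gene)
    entry_nodes: dict[str, tuple[list[str], bool]] = {}
    components: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "")
        name = entry.get("name", "")
        if etype == "group":
            components[eid] = [c.get("id") for c in entry.findall("component")]
            continue
        tokens = [t for t in name.split() if t and t != "undefined"]
        if etype in ("gene", "ortholog"):
            entry_nodes[eid] = (tokens, True)
        elif etype in ("compound", "map", "other", "enzyme"):
            # one placeholder node per entry, flagged non-gene
            label = tokens[0] if tokens else f"{etype}:{eid}"
            entry_nodes[eid] = ([f"__{label}#{eid}"], False)
        else:
            g.log.append(f"entry {eid}: unsupported type '{etype}' ignored")
            entry_nodes[eid] = ([], True)

    def resolve(eid: str, seen: frozenset = frozenset()) -> tuple[list[str], bool]:
        if eid in components:
            if eid in seen:
                return [], True
            names: list[str] = []
            for cid in components[eid]:
                sub, _ = resolve(cid, seen | {eid})
                names.extend(sub)
            return names, True
        if eid not in entry_nodes:
            raise KGMLStructureError(f"relation references unknown entry id '{eid}'")
        return entry_nodes[eid]

    for eid in entry_nodes:
        names, is_gene = entry_nodes[eid]
        for n in names:
            g.nodes.add(n)
            if not is_gene:
                g.non_gene.add(n)

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        src_names, _ = resolve(e1)
        tgt_names, _ = resolve(e2)
        subtypes = [s.get("name", "") for s in rel.findall("subtype")]
        kind = _subtypes_to_kind(subtypes)
        if kind is None:
            g.log.append(
                f"relation {e1}->{e2}: subtypes {subtypes or ['<none>']} carry no "
                "polarity; dropped"
            )
            continue
        for a in src_names:
            for b in tgt_names:
                g.edges.append(Edge(a, b, kind))
    return g


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_graph(g: PathwayGraph) -> PathwayGraph:
    """Merge duplicate gene nodes, remove non-gene nodes, drop self-edges.

    Removing a non-gene node reconnects every (parent -> node -> child) pair
    directly, with the composed polarity equal to the sign product of the two
    hops (composite kinds are recorded as plain activation/inhibition).
    Idempotent; every action is appended to the normalization log.
    """
    out = g.copy()

    # (i) duplicate gene merging is implicit in the name-keyed representation
    # produced by parse_kgml; collapse duplicate edges per (src, tgt, polarity).
    # (ii) remove non-gene nodes with sign-composed bypass edges.
    for node in sorted(out.non_gene):
        incoming = [e for e in out.edges if e.target == node and e.source != node]
        outgoing = [e for e in out.edges if e.source == node and e.target != node]
        for ein in incoming:
            for eout in outgoing:
                sign = ein.polarity * eout.polarity
                kind = (
                    InteractionKind.ACTIVATION if sign > 0 else InteractionKind.INHIBITION
                )
                out.edges.append(Edge(ein.source, eout.target, kind))
                out.log.append(
                    f"bypass {ein.source}->({node})->{eout.target} as {kind.value}"
                )
        out.edges = [e for e in out.edges if node not in (e.source, e.target)]
        out.nodes.discard(node)
        out.log.append(f"removed non-gene node {node}")
    out.non_gene = set()

    # (iii) drop self-edges
    kept: list[Edge] = []
    for e in out.edges:
        if e.source == e.target:
            out.log.append(f"dropped self-edge {e.source} ({e.kind.value})")
        else:
            kept.append(e)

    # de-duplicate: at most one edge per (source, target, polarity); the
    # first-listed kind within a polarity wins.
    seen: set[tuple[str, str, int]] = set()
    deduped: list[Edge] = []
    for e in kept:
        key = (e.source, e.target, e.polarity)
        if key in seen:
            out.log.append(f"collapsed duplicate edge {e.source}->{e.target}")
            continue
        seen.add(key)
        deduped.append(e)
    out.edges = deduped

    # drop edges whose endpoints vanished (defensive; should not occur)
    out.edges = [e for e in out.edges if e.source in out.nodes and e.target in out.nodes]
    return out


def final_effectors(g: PathwayGraph) -> list[str]:
    """Genes with no outgoing interaction, taken to trigger the cell response.

    Sorted by identifier.  A pure cycle has no such gene; an empty list is
    returned with a log entry.
    """
    sources = {e.source for e in g.edges}
    eff = sorted(n for n in g.gene_nodes() if n not in sources)
    if not eff:
        g.log.append(f"pathway {g.id}: no out-degree-0 gene (pure cycle)")
    return eff


# ---------------------------------------------------------------------------
# Decoys and perturbations
# ---------------------------------------------------------------------------


def make_decoy(g: PathwayGraph, universe: set[str], seed: int) -> PathwayGraph:
    """Decoy pathway: identical structure, node labels redrawn from ``universe``.

    Labels are sampled uniformly without replacement, so the decoy is
    isomorphic to ``g`` (same edge structure, kinds, and degree sequence).
    """
    nodes = g.sorted_genes()
    pool = sorted(universe)
    if len(pool) < len(nodes):
        raise ValueError(
            f"universe of {len(pool)} genes cannot relabel {len(nodes)} nodes"
        )
    rng = np.random.default_rng(seed)
    new_labels = [pool[i] for i in rng.choice(len(pool), size=len(nodes), replace=False)]
    mapping = dict(zip(nodes, new_labels))
    return PathwayGraph(
        id=f"{g.id}::decoy{seed}",
        nodes={mapping[n] for n in nodes},
        edges=[Edge(mapping[e.source], mapping[e.target], e.kind) for e in g.edges],
        provenance=f"decoy of {g.id}",
        log=[f"decoy relabeling of {g.id} (seed {seed})"],
    )


def perturb_graph(
    g: PathwayGraph, fraction: float, mode: str, seed: int
) -> PathwayGraph:
    """Emulate database incompleteness/noise by removing or rewiring edges.

    ``round(fraction * |edges|)`` edges are selected uniformly; ``remove``
    deletes them, ``rewire`` redraws each selected edge's target uniformly
    from the pathway's nodes (no self-edges, no duplicate of an existing
    edge).  The node set is unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    if mode not in ("remove", "rewire"):
        raise ValueError(f"mode must be 'remove' or 'rewire', got {mode!r}")
    out = g.copy()
    out.id = g.id  # same identity: stands in for the original topology
    rng = np.random.default_rng(seed)
    edges = out.sorted_edges()
    k = int(round(fraction * len(edges)))
    if k == 0:
        return out
    idx = set(rng.choice(len(edges), size=k, replace=False).tolist())
    if mode == "remove":
        out.edges = [e for i, e in enumerate(edges) if i not in idx]
        out.log.append(f"removed {k} edges (seed {seed})")
        return out
    nodes = sorted(out.nodes)
    present = {(e.source, e.target, e.polarity) for i, e in enumerate(edges) if i not in idx}
    new_edges: list[Edge] = [e for i, e in enumerate(edges) if i not in idx]
    for i in sorted(idx):
        e = edges[i]
        candidates = [
            n for n in nodes if n != e.source and (e.source, n, e.polarity) not in present
        ]
        if not candidates:
            new_edges.append(e)  # nowhere to rewire; keep as-is
            present.add((e.source, e.target, e.polarity))
            continue
        tgt = candidates[int(rng.integers(len(candidates)))]
        new_edges.append(Edge(e.source, tgt, e.kind))
        present.add((e.source, tgt, e.polarity))
    out.edges = new_edges
    out.log.append(f"rewired {k} edges (seed {seed})")
    return out


# ---------------------------------------------------------------------------
# Simple TSV edge-list dialect
# ---------------------------------------------------------------------------

_HEADER = "pathway_id\tsource\ttarget\tkind"


def write_edge_list(collection: PathwayCollection | list[PathwayGraph]) -> str:
    """Serialize pathways as ``pathway_id<TAB>source<TAB>target<TAB>kind``.

    Isolated nodes are written as rows with empty target and kind ``node``.
    """
    pathways = list(collection)
    lines = [_HEADER]
    for p in pathways:
        linked = {e.source for e in p.edges} | {e.target for e in p.edges}
        for n in sorted(p.gene_nodes() - linked):
            lines.append(f"{p.id}\t{n}\t\tnode")
        for e in p.sorted_edges():
            lines.append(f"{p.id}\t{e.source}\t{e.target}\t{e.kind.value}")
    return "\n".join(lines) + "\n"


def read_edge_list(text: str) -> PathwayCollection:
    """Parse the TSV edge-list dialect written by :func:`write_edge_list`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:2] != ["pathway_id", "source"]:
        raise ValueError("edge-list text must start with the header line")
    graphs: dict[str, PathwayGraph] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 tab-separated fields")
        pid, src, tgt, kind = parts
        g = graphs.setdefault(pid, PathwayGraph(id=pid, provenance="edge-list"))
        g.nodes.add(src)
        if kind == "node" and not tgt:
            continue
        try:
            ik = InteractionKind(kind)
        except ValueError:
            raise ValueError(f"line {lineno}: unknown interaction kind '{kind}'") from None
        g.nodes.add(tgt)
        g.edges.append(Edge(src, tgt, ik))
    return PathwayCollection(list(graphs.values()))
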