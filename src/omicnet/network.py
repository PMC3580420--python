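"""Gene networks and gene-set collections.

A :class:`GeneNetwork` is a simple undirected graph over gene symbols with
optional per-edge evidence tags and confidence scores.  Gene identity is the
bare symbol string, case-sensitive; no alias resolution is attempted.
:class:`GeneSet` and :class:`FgsCollection` hold altered and functional gene
sets, read from plain-text edge lists and GMT files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Evidence-tag vocabulary (advisory; unknown tags are kept as-is).
EVIDENCE_TAGS = frozenset(
    {
        "ppi",
        "mrna_coexpr",
        "protein_coexpr",
        "colocalization",
        "go_coherence",
        "kegg",
        "complex",
        "other",
    }
)

#: Allowed gene-set classes.
GENESET_CLASSES = ("SNV", "CNA", "AI", "FGS", "custom")


@dataclass
class GeneSet:
    """A named set of gene symbols.

    Parameters
    ----------
    name:
        Identifier of the set.
    genes:
        Member gene symbols (deduplicated).
    cls:
        One of ``SNV``, ``CNA``, ``AI``, ``FGS`` or ``custom``.

    Notes
    -----
    Empty sets are representable (filters may legitimately retain nothing);
    operations that cannot act on an empty set raise at the point of use.
    """

    name: str
    genes: frozenset[str]
    cls: str = "custom"

    def __post_init__(self) -> None:
        if self.cls not in GENESET_CLASSES:
            raise ValueError(f"unknown gene-set class {self.cls!r}")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class FgsCollection:
    """An ordered list of functional gene sets (multiple membership allowed)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sets:
            if s.cls != "FGS":
                raise ValueError(f"FgsCollection members must have cls='FGS', got {s.cls!r} for {s.name!r}")

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member symbols."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, i):
        return self.sets[i]


class GeneNetwork:
    """Simple undirected gene network.

    Backed by a :class:`networkx.Graph`; every edge carries an ``evidence``
    tag set and an optional ``score``.  Self-loops and duplicate edges are
    structurally impossible.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self._g = graph if graph is not None else nx.Graph()
        for u, v in self._g.edges():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")

    # -- construction -------------------------------------------------

    def add_node(self, gene: str) -> None:
        self._g.add_node(gene)

    def add_edge(
        self,
        u: str,
        v: str,
        evidence: Iterable[str] | None = None,
        score: float | None = None,
    ) -> None:
        """Add (or update) the edge ``u``-``v``.

        Evidence tags of duplicate additions are unioned; the score keeps
        the maximum of the values seen.
        """
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        tags = set(evidence) if evidence else set()
        if self._g.has_edge(u, v):
            data = self._g[u][v]
            data["evidence"] |= tags
            if score is not None:
                old = data.get("score")
                data["score"] = score if old is None else max(old, score)
        else:
            self._g.add_edge(u, v, evidence=tags, score=score)

    # -- inspection ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes())

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) tuples with u < v, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self._g.edges())

    def edge_evidence(self, u: str, v: str) -> set[str]:
        return set(self._g[u][v]["evidence"])

    def edge_score(self, u: str, v: str) -> float | None:
        return self._g[u][v].get("score")

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, gene: str) -> int:
        return self._g.degree(gene)

    def neighbors(self, gene: str) -> set[str]:
        return set(self._g.neighbors(gene))

    def graph(self) -> nx.Graph:
        """The underlying networkx graph (shared, not copied)."""
        return self._g

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self._g.copy())

    # -- array view (used by the randomization machinery) -------------

    def to_arrays(self):
        """Return ``(node_list, index, edge_array)``.

        ``node_list`` is sorted for determinism; ``edge_array`` is an
        ``(m, 2)`` integer array of node indices with ``u < v`` per row.
        """
        import numpy as np

        node_list = sorted(self._g.nodes())
        index = {g: i for i, g in enumerate(node_list)}
        if self.n_edges:
            edges = np.array(
                sorted((min(index[u], index[v]), max(index[u], index[v])) for u, v in self._g.edges()),
                dtype=np.int64,
            )
        else:
            edges = np.empty((0, 2), dtype=np.int64)
        return node_list, index, edges

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"GeneNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def load_edge_list(path, min_score: float | None = None) -> GeneNetwork:
    """Load a network from a TSV edge list.

    Expected columns: ``geneA  geneB  [evidence]  [score]``.  Lines starting
    with ``#`` and blank lines are skipped.  The evidence column holds
    comma-separated tags.  Rows with ``geneA == geneB`` are dropped;
    duplicate pairs are collapsed (evidence unioned, max score).  When
    ``min_score`` is given, rows whose score is present and below it are
    dropped; rows without a score are kept.

    Raises
    ------
    ValueError
        On malformed rows (with the line number) or when no edge survives.
    """
    net = GeneNetwork()
    n_kept = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            u, v = fields[0].strip(), fields[1].strip()
            evidence = None
            score = None
            if len(fields) >= 3 and fields[2].strip():
                evidence = [t.strip() for t in fields[2].split(",") if t.strip()]
            if len(fields) >= 4 and fields[3].strip():
                try:
                    score = float(fields[3])
                except ValueError as exc:
                    raise ValueError(f"{path}: bad score at line {lineno}: {fields[3]!r}") from exc
            if u == v:
                logger.debug("dropping self-loop at line %d: %s", lineno, u)
                continue
            if min_score is not None and score is not None and score < min_score:
                continue
            net.add_edge(u, v, evidence=evidence, score=score)
            n_kept += 1
    if net.n_edges == 0:
        raise ValueError(f"{path}: no edges loaded (all rows dropped or file empty)")
    return net


def write_edge_list(net: GeneNetwork, path) -> None:
    """Write a network as a TSV edge list (round-trips through load_edge_list)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#geneA\tgeneB\tevidence\tscore\n")
        for u, v in net.edges():
            ev = ",".join(sorted(net.edge_evidence(u, v)))
            sc = net.edge_score(u, v)
            fh.write(f"{u}\t{v}\t{ev}\t{'' if sc is None else repr(sc)}\n")


def load_gmt(path) -> FgsCollection:
    """Load gene sets from a GMT file (name, description, member genes).

    Duplicate genes within a line are collapsed.  Raises ``ValueError`` on
    lines with fewer than three fields, or on an empty file.
    """
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name = fields[0].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}: GMT line {lineno} has no member genes")
            sets.append(GeneSet(name=name, genes=genes, cls="FGS"))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return FgsCollection(sets)


def write_gmt(collection: FgsCollection | Sequence[GeneSet], path, description: str = "na") -> None:
    """Write gene sets in GMT format."""
    with open(path, "wt", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, description] + sorted(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def merge_networks(networks: Sequence[GeneNetwork]) -> GeneNetwork:
    """Union of networks: nodes and unique unordered edges, evidence unioned.

    Scores keep the per-edge maximum across sources.  Raises ``ValueError``
    on an empty input list.
    """
    if not networks:
        raise ValueError("merge_networks requires at least one network")
    out = GeneNetwork()
    for net in networks:
        for g in net.nodes:
            out.add_node(g)
        for u, v in net.edges():
            out.add_edge(u, v, evidence=net.edge_evidence(u, v), score=net.edge_score(u, v))
    return out


def restrict_to_network(s: GeneSet, net: GeneNetwork) -> GeneSet:
    """Intersect a gene set with the network's node set.

    Dropped symbols are logged.  Raises ``ValueError`` when nothing remains:
    a set with no network presence cannot be tested.
    """
    present = s.genes & net.nodes
    dropped = s.genes - present
    if dropped:
        logger.info(
            "restrict_to_network(%s): dropped %d/%d genes absent from network: %s",
            s.name,
            len(dropped),
            len(s.genes),
            ", ".join(sorted(dropped)[:20]),
        )
    if not present:
        raise ValueError(f"gene set {s.name!r} has no genes in the network")
    return GeneSet(name=s.name, genes=present, cls=s.cls)
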