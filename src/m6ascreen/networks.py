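"""Typed ortholog/paralog networks, GOI screening and presence/absence.

Ortholog pairs (cross-species) and paralog edges (within-species) are merged
into one undirected graph whose connected components are the gene-family
networks. Transcripts of interest — m6A writers (MTA, MTB, FIP37, VIRILIZER,
HAKAI) and erasers (ALKBH9B, ALKBH10B) — are assigned from query hit tables,
located inside the networks, and summarized as a GOI x species
presence/absence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .homology import DEFAULT_EVALUE_CEILING, HitTable, OrthologPair

#: The writer/eraser vocabulary screened for.
GOI_VOCABULARY = (
    "MTA", "MTB", "FIP37", "VIRILIZER", "HAKAI", "ALKBH9B", "ALKBH10B",
)

WRITERS = ("MTA", "MTB", "FIP37", "VIRILIZER", "HAKAI")
ERASERS = ("ALKBH9B", "ALKBH10B")


class NetworkError(ValueError):
    """Edge/species inconsistency or unresolvable GOI mapping."""


@dataclass
class HomologyNetwork:
    """Union graph of ortholog and paralog relations.

    Node attributes: ``species``, optional ``label``. Edge attribute
    ``type`` is ``ortholog`` or ``paralog``. ``component_of`` maps each gene
    to a deterministic component id (components sorted by smallest member).
    """

    graph: nx.Graph
    component_of: dict[str, int]

    def components(self) -> list[set[str]]:
        by_id: dict[int, set[str]] = {}
        for node, cid in self.component_of.items():
            by_id.setdefault(cid, set()).add(node)
        return [by_id[c] for c in sorted(by_id)]


def build_networks(
    ortholog_pairs: Sequence[OrthologPair],
    paralog_edges: Sequence[tuple[str, str, str]],
) -> HomologyNetwork:
    """Merge ortholog pairs and (gene_a, gene_b, species) paralog edges.

    Validates the type/species rule: ortholog edges must span two species,
    paralog edges must stay within one.
    """
    g = nx.Graph()
    for p in ortholog_pairs:
        if p.species_a == p.species_b:
            raise NetworkError(
                f"ortholog edge within one species: {p.gene_a}-{p.gene_b}"
            )
        g.add_node(p.gene_a, species=p.species_a)
        g.add_node(p.gene_b, species=p.species_b)
        g.add_edge(p.gene_a, p.gene_b, type="ortholog")
    for u, v, species in paralog_edges:
        for node in (u, v):
            if node in g.nodes and g.nodes[node]["species"] != species:
                raise NetworkError(
                    f"paralog edge species conflict at {node}: "
                    f"{g.nodes[node]['species']} vs {species}"
                )
        g.add_node(u, species=species)
        g.add_node(v, species=species)
        if g.has_edge(u, v) and g.edges[u, v]["type"] == "ortholog":
            raise NetworkError(f"edge {u}-{v} is both ortholog and paralog")
        g.add_edge(u, v, type="paralog")
    comps = sorted(nx.connected_components(g), key=min)
    component_of = {n: i for i, comp in enumerate(comps) for n in comp}
    return HomologyNetwork(graph=g, component_of=component_of)


def annotate_networks(
    net: HomologyNetwork, labels: Mapping[str, str]
) -> HomologyNetwork:
    """Attach functional-annotation strings to nodes where available."""
    for node, label in labels.items():
        if node in net.graph.nodes:
            net.graph.nodes[node]["label"] = label
    return net


@dataclass(frozen=True)
class GoiAssignment:
    """A transcript assigned to a writer/eraser by its best query hit."""

    transcript_id: str
    species: str
    goi_name: str
    best_query_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.goi_name not in GOI_VOCABULARY:
            raise NetworkError(f"unknown GOI name: {self.goi_name}")


def goi_from_query_id(query_id: str) -> str:
    """GOI name encoded in a query id, e.g. 'AT1G48980.1_ALKBH9B' -> ALKBH9B.

    The name is the last underscore-delimited token of the first
    whitespace-separated word of the id.
    """
    token = query_id.split()[0]
    name = token.rsplit("_", 1)[-1]
    if name not in GOI_VOCABULARY:
        raise NetworkError(f"query id encodes no known GOI: {query_id!r}")
    return name


def screen_goi(
    query_hits: HitTable,
    query_to_goi: Mapping[str, str] | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CEILING,
) -> list[GoiAssignment]:
    """Assign each transcript with a qualifying hit to exactly one GOI.

    Queries appear as ``query_id``; transcripts as ``subject_id``. When
    ``query_to_goi`` is omitted the GOI is parsed from the query id suffix.
    A transcript hit by several queries takes the GOI of the minimum-e-value
    query (ties: higher bitscore, then smaller query id).
    """
    if query_to_goi is None:
        qids = sorted(set(query_hits.df["query_id"]))
        unmapped = []
        query_to_goi = {}
        for q in qids:
            try:
                query_to_goi[q] = goi_from_query_id(q)
            except NetworkError:
                unmapped.append(q)
        if unmapped:
            raise NetworkError(f"query ids with no GOI mapping: {unmapped}")
    else:
        qids = sorted(set(query_hits.df["query_id"]))
        unmapped = [q for q in qids if q not in query_to_goi]
        if unmapped:
            raise NetworkError(f"query ids with no GOI mapping: {unmapped}")
    best: dict[str, tuple[float, float, str]] = {}
    for row in query_hits.df.itertuples(index=False):
        if row.evalue > evalue_cutoff:
            continue
        key = (row.evalue, -row.bitscore, row.query_id)
        t = row.subject_id
        if t not in best or key < best[t]:
            best[t] = key
    out = []
    for t in sorted(best):
        ev, neg_bs, q = best[t]
        out.append(
            GoiAssignment(
                transcript_id=t,
                species=query_hits.species_of[t],
                goi_name=query_to_goi[q],
                best_query_id=q,
                evalue=ev,
            )
        )
    return out


@dataclass
class GoiComponent:
    """A network component (or singleton) containing assigned transcripts."""

    component_id: int | None  # None for transcripts outside any network
    members: list[str]
    goi_names: list[str]


def goi_networks(
    net: HomologyNetwork, assignments: Sequence[GoiAssignment]
) -> list[GoiComponent]:
    """All components holding >= 1 assigned transcript, plus singletons for
    assigned transcripts absent from the network."""
    by_component: dict[int, set[str]] = {}
    singletons: list[GoiAssignment] = []
    for a in assignments:
        cid = net.component_of.get(a.transcript_id)
        if cid is None:
            singletons.append(a)
        else:
            by_component.setdefault(cid, set()).add(a.transcript_id)
    goi_of = {}
    for a in assignments:
        goi_of.setdefault(a.transcript_id, set()).add(a.goi_name)
    out = []
    comps = {i: c for i, c in enumerate(net.components())}
    for cid in sorted(by_component):
        members = sorted(comps[cid])
        names = sorted(set().union(*(goi_of.get(m, set()) for m in members)))
        out.append(GoiComponent(component_id=cid, members=members,
                                goi_names=names))
    for a in sorted(singletons, key=lambda a: a.transcript_id):
        out.append(
            GoiComponent(
                component_id=None,
                members=[a.transcript_id],
                goi_names=sorted(goi_of[a.transcript_id]),
            )
        )
    return out


@dataclass
class PresenceMatrix:
    """GOI x species transcriptome presence with transcript evidence."""

    entries: dict[tuple[str, str], bool]
    evidence: dict[tuple[str, str], list[str]]
    species: list[str]
    vocabulary: list[str]

    def present(self, goi: str, species: str) -> bool:
        return self.entries[(goi, species)]


def presence_matrix(
    assignments: Sequence[GoiAssignment],
    species_roster: Sequence[str],
    goi_vocabulary: Sequence[str] = GOI_VOCABULARY,
) -> PresenceMatrix:
    """Transcriptome-level presence: a cell is present iff >= 1 assignment.

    Every (GOI, species) cell is emitted, including all-absent rows.
    """
    if not species_roster:
        raise NetworkError("species roster must be non-empty")
    roster = sorted(set(species_roster))
    vocab = list(goi_vocabulary)
    entries = {(g, s): False for g in vocab for s in roster}
    evidence: dict[tuple[str, str], list[str]] = {
        (g, s): [] for g in vocab for s in roster
    }
    for a in assignments:
        key = (a.goi_name, a.species)
        if key not in entries:
            raise NetworkError(
                f"assignment outside roster/vocabulary: {key}"
            )
        entries[key] = True
        if a.transcript_id not in evidence[key]:
            evidence[key].append(a.transcript_id)
    for key in evidence:
        evidence[key].sort()
    return PresenceMatrix(
        entries=entries, evidence=evidence, species=roster, vocabulary=vocab
    )


# ---------------------------------------------------------------------------
# Exports


def write_edge_table(net: HomologyNetwork, path) -> None:
    """4-column edge TSV: u, v, type, component."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\ttype\tcomponent\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(
                f"{u}\t{v}\t{net.graph.edges[u, v]['type']}\t"
                f"{net.component_of[u]}\n"
            )


def write_graphml(net: HomologyNetwork, path) -> None:
    g = net.graph.copy()
    for n in g.nodes:
        g.nodes[n]["component"] = net.component_of[n]
    nx.write_graphml(g, str(path))


def read_graphml(path) -> HomologyNetwork:
    g = nx.read_graphml(str(path))
    component_of = {n: int(g.nodes[n].pop("component")) for n in g.nodes}
    return HomologyNetwork(graph=g, component_of=component_of)


def write_presence_matrix(matrix: PresenceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("goi\t" + "\t".join(matrix.species) + "\n")
        for g in matrix.vocabulary:
            cells = [
                "present" if matrix.entries[(g, s)] else "absent"
                for s in matrix.species
            ]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def write_goi_report(
    components: Sequence[GoiComponent], path
) -> None:
    with open(path, "w") as fh:
        fh.write("component\tgoi_names\tmembers\n")
        for c in components:
            cid = "singleton" if c.component_id is None else str(c.component_id)
            fh.write(f"{cid}\t{','.join(c.goi_names)}\t{','.join(c.members)}\n")
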