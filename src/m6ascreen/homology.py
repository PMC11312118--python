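"""Homology inference from similarity-search hit tables.

Orthologs are inferred by the Bidirectional Best Hit (BBH) rule: two genes in
different species that are each other's best hit. Paralogs are within-species
gene pairs whose hits pass an e-value cutoff; the cutoff itself is chosen by
scanning a grid and keeping the value that maximizes the number of
duplicated-gene networks (connected components of size >= 2 in the
within-species hit graph).

Hit tables follow the 12-column tabular convention of BLAST-family tools
(query, subject, %identity, alignment length, mismatches, gap opens,
q_start, q_end, s_start, s_end, e-value, bitscore).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

#: Column names of the 12-column tabular hit format.
OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "align_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]

#: Default e-value ceiling for best-hit / BBH searches.
DEFAULT_EVALUE_CEILING = 1e-5

#: Default cutoff grid for the paralogy threshold scan: 1e-5 .. 1e-180
#: in decade steps, most stringent first after sorting.
DEFAULT_SCAN_GRID = tuple(10.0 ** -k for k in range(5, 181))


class HitTableError(ValueError):
    """Malformed hit table or unresolvable gene identifiers."""


@dataclass(frozen=True)
class OrthologPair:
    """An unordered cross-species ortholog pair found by the BBH rule.

    ``gene_a < gene_b`` lexicographically so each pair is stored once.
    """

    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    evalue_ab: float
    evalue_ba: float

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValueError("ortholog pair must span two species")


@dataclass
class HitTable:
    """Parsed similarity hits plus a gene -> species resolution map."""

    df: pd.DataFrame
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in OUTFMT6_COLUMNS if c not in self.df.columns]
        if missing:
            raise HitTableError(f"hit table lacks columns: {missing}")

    def genes_of(self, species: str) -> list[str]:
        return sorted(g for g, sp in self.species_of.items() if sp == species)

    @property
    def species(self) -> list[str]:
        return sorted(set(self.species_of.values()))


def read_hit_table(
    path,
    species_map: Mapping[str, str] | None = None,
    species_prefix: Callable[[str], str] | None = None,
) -> HitTable:
    """Read a 12-column tabular hit file.

    Gene ids are resolved to species either through an explicit
    ``species_map`` or an id -> species ``species_prefix`` rule (e.g.
    splitting on the first ``|``). Raises :class:`HitTableError` with the
    offending line number on a malformed row, and lists every unmappable
    gene id if resolution fails.
    """
    if species_map is None and species_prefix is None:
        raise HitTableError("provide species_map or species_prefix")
    rows: list[list] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append(
                    [
                        fields[0],
                        fields[1],
                        float(fields[2]),
                        int(fields[3]),
                        int(fields[4]),
                        int(fields[5]),
                        int(fields[6]),
                        int(fields[7]),
                        int(fields[8]),
                        int(fields[9]),
                        float(fields[10]),
                        float(fields[11]),
                    ]
                )
            except ValueError as exc:
                raise HitTableError(f"line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    genes = sorted(set(df["query_id"]) | set(df["subject_id"]))
    if species_map is not None:
        unmapped = [g for g in genes if g not in species_map]
        if unmapped:
            raise HitTableError(f"gene ids with no species mapping: {unmapped}")
        species_of = {g: species_map[g] for g in genes}
    else:
        species_of = {g: species_prefix(g) for g in genes}
    return HitTable(df=df, species_of=species_of)


def write_hit_table(table: HitTable, path) -> None:
    """Write hits back out in the 12-column tabular format."""
    with open(path, "w") as fh:
        for row in table.df.itertuples(index=False):
            fh.write(
                f"{row.query_id}\t{row.subject_id}\t{row.pct_identity:.2f}\t"
                f"{row.align_len}\t{row.mismatches}\t{row.gap_opens}\t"
                f"{row.q_start}\t{row.q_end}\t{row.s_start}\t{row.s_end}\t"
                f"{row.evalue:.6g}\t{row.bitscore:.1f}\n"
            )


def best_hit(
    table: HitTable,
    gene: str,
    target_species: str,
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> str | None:
    """Best hit of ``gene`` into ``target_species``.

    The best subject minimizes the e-value; ties go to the higher bitscore,
    then to the lexicographically smallest subject id. Self-hits are ignored.
    Returns ``None`` when no hit passes the ceiling.
    """
    if gene not in table.species_of:
        raise HitTableError(f"unknown gene: {gene}")
    df = table.df
    sub = df[(df["query_id"] == gene) & (df["subject_id"] != gene)]
    best: tuple[float, float, str] | None = None
    for row in sub.itertuples(index=False):
        if table.species_of[row.subject_id] != target_species:
            continue
        if row.evalue > evalue_ceiling:
            continue
        key = (row.evalue, -row.bitscore, row.subject_id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def bbh_orthologs(
    table: HitTable,
    species_a: str,
    species_b: str,
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> list[OrthologPair]:
    """Bidirectional best hits between two species.

    A pair (a, b) is emitted iff b is the best hit of a in ``species_b``
    and a is the best hit of b in ``species_a``, both passing the ceiling.
    """
    if species_a == species_b:
        raise HitTableError("BBH requires two distinct species")
    # Precompute best hits per direction in one pass over the table.
    best_ab = _best_hits_directed(table, species_a, species_b, evalue_ceiling)
    best_ba = _best_hits_directed(table, species_b, species_a, evalue_ceiling)
    evalue_of = _min_evalue_lookup(table)
    pairs = []
    for a, b in sorted(best_ab.items()):
        if best_ba.get(b) == a:
            ga, gb = sorted((a, b))
            pairs.append(
                OrthologPair(
                    gene_a=ga,
                    gene_b=gb,
                    species_a=table.species_of[ga],
                    species_b=table.species_of[gb],
                    evalue_ab=evalue_of[(ga, gb)],
                    evalue_ba=evalue_of[(gb, ga)],
                )
            )
    return pairs


def _best_hits_directed(
    table: HitTable, src: str, dst: str, ceiling: float
) -> dict[str, str]:
    """query -> best subject for all hits from species src into dst."""
    sp = table.species_of
    best: dict[str, tuple[float, float, str]] = {}
    for row in table.df.itertuples(index=False):
        q, s = row.query_id, row.subject_id
        if q == s or sp[q] != src or sp[s] != dst or row.evalue > ceiling:
            continue
        key = (row.evalue, -row.bitscore, s)
        if q not in best or key < best[q]:
            best[q] = key
    return {q: k[2] for q, k in best.items()}


def _min_evalue_lookup(table: HitTable) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for row in table.df.itertuples(index=False):
        key = (row.query_id, row.subject_id)
        if key not in out or row.evalue < out[key]:
            out[key] = row.evalue
    return out


def _within_species_pair_evalues(
    table: HitTable, species: str
) -> dict[tuple[str, str], float]:
    """Min e-value over both directions for each within-species pair."""
    sp = table.species_of
    best: dict[tuple[str, str], float] = {}
    for row in table.df.itertuples(index=False):
        q, s = row.query_id, row.subject_id
        if q == s or sp[q] != species or sp[s] != species:
            continue
        key = (q, s) if q < s else (s, q)
        if key not in best or row.evalue < best[key]:
            best[key] = row.evalue
    return best


def paralog_edges(
    table: HitTable, species: str, cutoff: float
) -> list[tuple[str, str]]:
    """Within-species paralog edges at an e-value cutoff.

    An unordered pair qualifies when EITHER direction of the reciprocal
    search meets the cutoff (min over directions <= cutoff). Self-hits never
    form edges. Edges are returned sorted, each as (u, v) with u < v.
    """
    if species not in set(table.species_of.values()):
        raise HitTableError(f"species not present in table: {species}")
    best = _within_species_pair_evalues(table, species)
    return sorted(pair for pair, ev in best.items() if ev <= cutoff)


@dataclass
class ThresholdScanResult:
    """Outcome of the paralogy-threshold grid scan.

    ``count_at`` maps each cutoff to the number of duplicated-gene networks
    (within-species components of size >= 2, summed over the scanned
    species); ``chosen_cutoff`` attains the maximum, ties resolved toward
    the most stringent (smallest) cutoff.
    """

    grid: list[float]
    count_at: dict[float, int]
    chosen_cutoff: float
    species: list[str]
    pooled: bool = True

    def __post_init__(self) -> None:
        if self.count_at[self.chosen_cutoff] != max(self.count_at.values()):
            raise ValueError("chosen_cutoff does not attain the maximum count")

    @property
    def plateau(self) -> tuple[float, float]:
        """(smallest, largest) grid cutoff attaining the maximum count."""
        best = max(self.count_at.values())
        winners = [c for c, n in self.count_at.items() if n == best]
        return (min(winners), max(winners))


def count_duplicated_networks(
    table: HitTable, species: str, cutoff: float
) -> int:
    """Number of connected components of size >= 2 among paralog edges."""
    g = nx.Graph()
    g.add_edges_from(paralog_edges(table, species, cutoff))
    return sum(1 for c in nx.connected_components(g) if len(c) >= 2)


def paralog_threshold_scan(
    table: HitTable,
    species: str | Sequence[str],
    grid: Iterable[float] = DEFAULT_SCAN_GRID,
) -> ThresholdScanResult:
    """Scan cutoffs and keep the one maximizing duplicated-gene networks.

    ``species`` may be a single species (per-species threshold, the default
    pipeline mode) or a list (one pooled threshold: component counts are
    summed over species at each cutoff).
    """
    species_list = [species] if isinstance(species, str) else sorted(species)
    present = set(table.species_of.values())
    for sp in species_list:
        if sp not in present:
            raise HitTableError(f"species not present in table: {sp}")
    grid = sorted(set(float(c) for c in grid))
    if len(grid) < 2:
        raise HitTableError("scan grid needs at least 2 cutoffs")
    pair_evalues = {
        sp: _within_species_pair_evalues(table, sp) for sp in species_list
    }
    count_at: dict[float, int] = {}
    for cutoff in grid:
        total = 0
        for sp in species_list:
            g = nx.Graph()
            g.add_edges_from(
                pair for pair, ev in pair_evalues[sp].items() if ev <= cutoff
            )
            total += sum(1 for c in nx.connected_components(g) if len(c) >= 2)
        count_at[cutoff] = total
    best = max(count_at.values())
    chosen = min(c for c, n in count_at.items() if n == best)
    return ThresholdScanResult(
        grid=grid,
        count_at=count_at,
        chosen_cutoff=chosen,
        species=species_list,
        pooled=len(species_list) > 1,
    )


def write_ortholog_pairs(pairs: Sequence[OrthologPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tspecies_a\tspecies_b\tevalue_ab\tevalue_ba\n")
        for p in sorted(pairs, key=lambda p: (p.gene_a, p.gene_b)):
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.species_a}\t{p.species_b}\t"
                f"{p.evalue_ab:.6g}\t{p.evalue_ba:.6g}\n"
            )


def write_paralog_edges(
    edges: Sequence[tuple[str, str]], species: str, path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tspecies\n")
        for u, v in sorted(edges):
            fh.write(f"{u}\t{v}\t{species}\n")


def write_scan_table(result: ThresholdScanResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("cutoff\tduplicated_networks\tchosen\n")
        for cutoff in result.grid:
            chosen = "yes" if cutoff == result.chosen_cutoff else "no"
            fh.write(f"{cutoff:.6g}\t{result.count_at[cutoff]}\t{chosen}\n")
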