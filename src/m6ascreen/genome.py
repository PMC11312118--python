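"""Genome-presence filtering and transcriptome/genome reconciliation.

Transcript queries aligned to reference genomes (gmap-style spliced
alignment, consumed here as summarized tabular records) are filtered at a
percent-identity cutoff (40% by default, inclusive). Genome presence is then
reconciled with transcriptome presence into a three-way call per
(GOI, species): ``expressed`` (in the transcriptome), ``genomic_only``
(genome hit but no transcript — read as "not expressed under the sampled
conditions"), or ``absent``.

Some species lack a public genome; a close relative's genome may serve as a
surrogate (flagged in the provenance so downstream readers can see it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .networks import GOI_VOCABULARY, PresenceMatrix, goi_from_query_id

DEFAULT_MIN_IDENTITY = 40.0

STATUSES = ("expressed", "genomic_only", "absent")


class MappingError(ValueError):
    """Invalid mapping record or reconciliation mismatch."""


@dataclass(frozen=True)
class GenomeMappingRecord:
    query_id: str
    query_length: int
    genome_id: str
    pct_identity: float
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise MappingError(
                f"{self.query_id}: identity {self.pct_identity} outside [0, 100]"
            )
        if self.query_length <= 0:
            raise MappingError(f"{self.query_id}: non-positive query length")


def _parse_length(text: str) -> int:
    """Accept '1830' or '1830 bp'."""
    return int(text.strip().removesuffix("bp").strip())


def read_mappings(path) -> list[GenomeMappingRecord]:
    """Read a mapping-summary TSV.

    Dialect: header line, then tab-separated ``genome_id``, ``query_ID``,
    ``query_length`` (optionally suffixed ' bp'), ``identity%`` and an
    optional coverage column. Numeric validation names the offending row.
    """
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MappingError(
                    f"row {lineno}: expected >= 4 tab-separated columns"
                )
            try:
                rec = GenomeMappingRecord(
                    genome_id=fields[0],
                    query_id=fields[1],
                    query_length=_parse_length(fields[2]),
                    pct_identity=float(fields[3]),
                    coverage=float(fields[4]) if len(fields) > 4 else None,
                )
            except (ValueError, MappingError) as exc:
                raise MappingError(f"row {lineno}: {exc}") from exc
            records.append(rec)
    return records


def filter_mappings(
    records: Sequence[GenomeMappingRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[GenomeMappingRecord]:
    """Keep records with percent identity >= the cutoff (inclusive)."""
    if not 0.0 <= min_identity <= 100.0:
        raise MappingError("min_identity must be in [0, 100]")
    return [r for r in records if r.pct_identity >= min_identity]


def best_mapping_per_query(
    records: Sequence[GenomeMappingRecord],
) -> list[GenomeMappingRecord]:
    """Keep the max-identity record per (query, genome)."""
    best: dict[tuple[str, str], GenomeMappingRecord] = {}
    for r in records:
        key = (r.query_id, r.genome_id)
        if key not in best or r.pct_identity > best[key].pct_identity:
            best[key] = r
    return [best[k] for k in sorted(best)]


@dataclass
class GenomePresence:
    """(GOI, species) genome presence plus per-cell provenance."""

    entries: dict[tuple[str, str], bool]
    provenance: dict[tuple[str, str], dict]
    species: list[str]
    vocabulary: list[str]


def genome_presence(
    records: Sequence[GenomeMappingRecord],
    genome_to_species: Mapping[str, Sequence[tuple[str, bool]]],
    query_to_goi: Mapping[str, str] | None = None,
    goi_vocabulary: Sequence[str] = GOI_VOCABULARY,
) -> GenomePresence:
    """Presence of each GOI on each species' (possibly surrogate) genome.

    ``genome_to_species`` maps a genome id to the species it stands for, as
    (species, is_surrogate) tuples — one genome may serve several species.
    A cell is present iff >= 1 surviving record for any query of that GOI on
    a genome serving that species; surrogate use lands in the provenance.
    """
    species: list[str] = sorted(
        {sp for serves in genome_to_species.values() for sp, _ in serves}
    )
    vocab = list(goi_vocabulary)
    unmapped = sorted(
        {r.genome_id for r in records} - set(genome_to_species)
    )
    if unmapped:
        raise MappingError(f"genomes with no species mapping: {unmapped}")
    entries = {(g, s): False for g in vocab for s in species}
    prov: dict[tuple[str, str], dict] = {
        (g, s): {"queries": [], "genomes": [], "surrogate": False}
        for g in vocab for s in species
    }
    for r in records:
        goi = (
            query_to_goi[r.query_id]
            if query_to_goi is not None
            else goi_from_query_id(r.query_id)
        )
        if goi not in vocab:
            raise MappingError(f"query {r.query_id}: GOI {goi} not in vocabulary")
        for sp, surrogate in genome_to_species[r.genome_id]:
            key = (goi, sp)
            entries[key] = True
            cell = prov[key]
            if r.query_id not in cell["queries"]:
                cell["queries"].append(r.query_id)
            if r.genome_id not in cell["genomes"]:
                cell["genomes"].append(r.genome_id)
            cell["surrogate"] = cell["surrogate"] or surrogate
    for cell in prov.values():
        cell["queries"].sort()
        cell["genomes"].sort()
    return GenomePresence(
        entries=entries, provenance=prov, species=species, vocabulary=vocab
    )


@dataclass
class ReconciledMatrix:
    """Three-way (GOI, species) classification with provenance."""

    entries: dict[tuple[str, str], str]
    provenance: dict[tuple[str, str], dict]
    species: list[str]
    vocabulary: list[str]

    def status(self, goi: str, species: str) -> str:
        return self.entries[(goi, species)]


def reconcile(
    transcriptome: PresenceMatrix, genome: GenomePresence
) -> ReconciledMatrix:
    """Combine transcriptome and genome presence cell-wise.

    transcriptome-present -> ``expressed``; absent but genome-present ->
    ``genomic_only``; both absent -> ``absent``.
    """
    if sorted(transcriptome.species) != sorted(genome.species):
        raise MappingError(
            f"species rosters differ: {transcriptome.species} vs "
            f"{genome.species}"
        )
    if sorted(transcriptome.vocabulary) != sorted(genome.vocabulary):
        raise MappingError("GOI vocabularies differ")
    entries: dict[tuple[str, str], str] = {}
    prov: dict[tuple[str, str], dict] = {}
    for g in transcriptome.vocabulary:
        for s in transcriptome.species:
            key = (g, s)
            if transcriptome.entries[key]:
                entries[key] = "expressed"
            elif genome.entries[key]:
                entries[key] = "genomic_only"
            else:
                entries[key] = "absent"
            prov[key] = {
                "transcripts": list(transcriptome.evidence[key]),
                "genome": dict(genome.provenance[key]),
            }
    return ReconciledMatrix(
        entries=entries,
        provenance=prov,
        species=sorted(transcriptome.species),
        vocabulary=list(transcriptome.vocabulary),
    )


def write_reconciled_matrix(matrix: ReconciledMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("goi\t" + "\t".join(matrix.species) + "\n")
        for g in matrix.vocabulary:
            row = [matrix.entries[(g, s)] for s in matrix.species]
            fh.write(g + "\t" + "\t".join(row) + "\n")


def read_surrogate_map(path) -> dict[str, list[tuple[str, bool]]]:
    """Surrogate map TSV: genome_id, species, surrogate_flag (yes/no)."""
    out: dict[str, list[tuple[str, bool]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            genome_id, species, flag = line.split("\t")
            out.setdefault(genome_id, []).append(
                (species, flag.strip().lower() in {"yes", "true", "1"})
            )
    return out
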