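"""ORF prediction and isoform collapsing for assembled transcripts.

Coding regions are called with three rules: a minimum ORF length (100
residues by default, to limit false positives on de novo assemblies), removal
of candidate ORFs entirely contained within a longer candidate on the same
strand, and — because InterPro-style annotation is run on every surviving
protein — a final collapse keeping, per transcript, the isoform with the most
functional annotations. A single transcript may still report several ORFs
when they are not nested.

Coordinates are 0-based half-open on the reported strand; a protein id is
``transcript_id|start-end|strand`` so records round-trip unambiguously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}
VALID_CHARS = set("ACGTN")


class TranscriptError(ValueError):
    """Invalid transcript sequence or identifiers."""


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise TranscriptError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_CHARS
        if bad:
            raise TranscriptError(
                f"{self.transcript_id}: invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class OrfCandidate:
    """A called ORF on the reported strand (0-based half-open coordinates)."""

    transcript_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    aa_length: int
    has_stop: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a codon multiple")

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass
class ProteinRecord:
    protein_id: str
    transcript_id: str
    aa_sequence: str
    annotation_ids: list[str] = field(default_factory=list)

    @property
    def annotation_count(self) -> int:
        return len(self.annotation_ids)


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def _scan_strand(
    seq: str, transcript_id: str, strand: str, min_aa_len: int
) -> list[OrfCandidate]:
    """All ATG-initiated ORFs on one strand's sequence.

    Each ATG opens a candidate ending at the next in-frame stop (included in
    the span) or at the last complete codon of the transcript. Codons
    containing N translate to X and neither open nor close an ORF.
    """
    out = []
    n = len(seq)
    for frame in range(3):
        # in-frame stop position lookup: next stop at or after each codon
        starts = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon == "ATG":
                starts.append(pos)
            if codon in STOP_CODONS:
                for s in starts:
                    aa_len = (pos + 3 - s) // 3 - 1
                    if aa_len >= min_aa_len:
                        out.append(
                            OrfCandidate(
                                transcript_id=transcript_id,
                                start=s,
                                end=pos + 3,
                                strand=strand,
                                frame=frame,
                                aa_length=aa_len,
                                has_stop=True,
                            )
                        )
                starts = []
        # open ORFs running off the transcript end (no stop)
        last = frame + ((n - frame) // 3) * 3
        for s in starts:
            aa_len = (last - s) // 3
            if aa_len >= min_aa_len:
                out.append(
                    OrfCandidate(
                        transcript_id=transcript_id,
                        start=s,
                        end=last,
                        strand=strand,
                        frame=frame,
                        aa_length=aa_len,
                        has_stop=False,
                    )
                )
    return out


def find_orfs(
    transcript: TranscriptRecord,
    min_aa_len: int = 100,
    strands: Literal["forward_only", "both"] = "both",
) -> list[OrfCandidate]:
    """All qualifying ATG-initiated ORFs of one transcript.

    Returned in deterministic order: strand (+ before -), then start, then
    longest first.
    """
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    seq = transcript.sequence.upper()
    cands = _scan_strand(seq, transcript.transcript_id, "+", min_aa_len)
    if strands == "both":
        rc = str(Seq(seq).reverse_complement())
        cands += _scan_strand(rc, transcript.transcript_id, "-", min_aa_len)
    elif strands != "forward_only":
        raise ValueError(f"unknown strands mode: {strands}")
    cands.sort(key=lambda c: (c.strand, c.start, -(c.end - c.start)))
    return cands


def filter_contained(candidates: Sequence[OrfCandidate]) -> list[OrfCandidate]:
    """Drop ORFs entirely contained in a longer same-strand ORF.

    Identical duplicated intervals collapse to one survivor. Candidates must
    all come from one transcript.
    """
    tids = {c.transcript_id for c in candidates}
    if len(tids) > 1:
        raise ValueError("filter_contained expects one transcript's candidates")
    survivors: list[OrfCandidate] = []
    seen: set[tuple] = set()
    for c in sorted(
        candidates, key=lambda c: (c.strand, -(c.end - c.start), c.start)
    ):
        key = (c.strand, c.start, c.end)
        if key in seen:
            continue
        contained = any(
            s.strand == c.strand and s.start <= c.start and c.end <= s.end
            for s in survivors
        )
        if not contained:
            survivors.append(c)
            seen.add(key)
    survivors.sort(key=lambda c: (c.strand, c.start, -(c.end - c.start)))
    return survivors


def translate_orf(transcript: TranscriptRecord, orf: OrfCandidate) -> str:
    """Amino-acid sequence of an ORF; the terminal stop is not included."""
    seq = transcript.sequence.upper()
    if orf.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    span = seq[orf.start:orf.end]
    if orf.has_stop:
        span = span[:-3]
    return "".join(
        _translate_codon(span[i:i + 3]) for i in range(0, len(span), 3)
    )


def protein_id_for(orf: OrfCandidate) -> str:
    return f"{orf.transcript_id}|{orf.start}-{orf.end}|{orf.strand}"


def predict_proteome(
    transcripts: Iterable[TranscriptRecord],
    min_aa_len: int = 100,
    strands: Literal["forward_only", "both"] = "both",
) -> list[ProteinRecord]:
    """Call ORFs, drop contained candidates, translate the survivors.

    Multiple proteins per transcript are permitted when several non-nested
    ORFs reach the minimum length.
    """
    out = []
    for tr in transcripts:
        for orf in filter_contained(find_orfs(tr, min_aa_len, strands)):
            out.append(
                ProteinRecord(
                    protein_id=protein_id_for(orf),
                    transcript_id=tr.transcript_id,
                    aa_sequence=translate_orf(tr, orf),
                )
            )
    return out


def collapse_isoforms(
    proteome: Sequence[ProteinRecord],
    annotations: Mapping[str, Sequence[str]] | None = None,
    count_rows: bool = False,
) -> list[ProteinRecord]:
    """Keep exactly one protein per transcript: the most-annotated isoform.

    Annotation counts default to the number of distinct signature ids per
    protein (``count_rows=True`` counts raw rows instead). Ties break toward
    the longer protein, then the lexicographically smallest protein id.
    Annotation rows referencing unknown proteins raise a warning and are
    ignored.
    """
    annotations = annotations or {}
    known = {p.protein_id for p in proteome}
    unknown = sorted(set(annotations) - known)
    if unknown:
        warnings.warn(
            f"annotations reference unknown proteins (ignored): {unknown}",
            stacklevel=2,
        )
    enriched = []
    for p in proteome:
        sigs = list(annotations.get(p.protein_id, p.annotation_ids))
        if not count_rows:
            sigs = sorted(set(sigs))
        enriched.append(
            ProteinRecord(
                protein_id=p.protein_id,
                transcript_id=p.transcript_id,
                aa_sequence=p.aa_sequence,
                annotation_ids=sigs,
            )
        )
    best: dict[str, ProteinRecord] = {}
    for p in enriched:
        cur = best.get(p.transcript_id)
        if cur is None or _collapse_key(p) < _collapse_key(cur):
            best[p.transcript_id] = p
    return [best[t] for t in sorted(best)]


def _collapse_key(p: ProteinRecord) -> tuple:
    return (-p.annotation_count, -len(p.aa_sequence), p.protein_id)


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces


def read_transcripts_fasta(path, species: str) -> list[TranscriptRecord]:
    from Bio import SeqIO

    return [
        TranscriptRecord(
            transcript_id=rec.id, species=species, sequence=str(rec.seq)
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_proteins_fasta(proteome: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(proteome, key=lambda p: p.protein_id):
            fh.write(f">{p.protein_id}\n{p.aa_sequence}\n")


def write_orf_table(orfs: Sequence[OrfCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstart\tend\tstrand\tframe\taa_length\thas_stop\n")
        for o in orfs:
            fh.write(
                f"{o.transcript_id}\t{o.start}\t{o.end}\t{o.strand}\t"
                f"{o.frame}\t{o.aa_length}\t{'yes' if o.has_stop else 'no'}\n"
            )


def read_annotation_table(path) -> dict[str, list[str]]:
    """Two-plus-column TSV (protein_id, signature_id, ...) -> mapping."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError("annotation rows need >= 2 columns")
            out.setdefault(fields[0], []).append(fields[1])
    return out
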