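#!/usr/bin/env python
"""ORF prediction and isoform collapsing on demonstration transcripts.

Builds a small set of random transcripts with embedded coding regions, calls
ORFs (ATG-initiated, >= 100 aa by default — here 30 aa so the kb-scale demo
transcripts yield calls), removes nested candidates, and collapses isoforms
to one protein per transcript by annotation count.

Writes results/proteome/.
"""

from pathlib import Path

import numpy as np

from m6ascreen import orfs

OUT = Path(__file__).resolve().parent.parent / "results" / "proteome"
SEED = 1


def random_transcript_with_orf(rng, orf_aa=120, flank=150) -> str:
    bases = np.array(list("ACGT"))
    codons = ["ATG"]
    # avoid in-frame stops inside the planted coding region
    while len(codons) < orf_aa:
        c = "".join(rng.choice(bases, size=3))
        if c not in {"TAA", "TAG", "TGA"}:
            codons.append(c)
    codons.append("TAA")
    left = "".join(rng.choice(bases, size=flank))
    right = "".join(rng.choice(bases, size=flank))
    return left + "".join(codons) + right


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    transcripts = [
        orfs.TranscriptRecord(f"demo_t{i:03d}", "SP1",
                              random_transcript_with_orf(rng))
        for i in range(40)
    ]
    proteome = orfs.predict_proteome(transcripts, min_aa_len=30)
    orfs.write_proteins_fasta(proteome, OUT / "proteome_all_isoforms.fasta")
    print(f"{len(proteome)} proteins predicted from {len(transcripts)} "
          f"transcripts (multiple ORFs per transcript allowed)")

    # toy annotation table: every other protein gets 1-4 signatures
    annotations = {
        p.protein_id: [f"IPR{100 + j}" for j in range(1 + i % 4)]
        for i, p in enumerate(proteome)
        if i % 2 == 0
    }
    collapsed = orfs.collapse_isoforms(proteome, annotations)
    orfs.write_proteins_fasta(collapsed, OUT / "proteome_collapsed.fasta")
    assert len(collapsed) == len({p.transcript_id for p in proteome})
    print(f"collapsed to {len(collapsed)} proteins "
          f"(exactly one per transcript)")


if __name__ == "__main__":
    main()
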