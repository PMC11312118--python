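"""Packaged reference tables for the four-microalgae writer/eraser screen.

Two small TSVs ship with the package:

* ``goi_inventory.tsv`` — the published inventory of writer/eraser
  transcripts detected in the transcriptomes of the dinoflagellates
  *Alexandrium tamutum* and *Amphidinium carterae*, the diatom
  *Cylindrotheca closterium* and the green alga *Tetraselmis suecica*;
* ``genome_mapping_summary.tsv`` — the summarized genome-scan results:
  plant/seagrass query sequences aligned against the *A. carterae*,
  *C. fusiformis* and *T. striata* genomes with percent identity.

*C. fusiformis* and *T. striata* are surrogate genomes for *C. closterium*
and *T. suecica* (no public assemblies), and the *A. carterae* genome also
stands in for *A. tamutum*.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome import GenomeMappingRecord, read_mappings
from .networks import GoiAssignment

#: The four investigated species.
SPECIES_ROSTER = (
    "Alexandrium tamutum",
    "Amphidinium carterae",
    "Cylindrotheca closterium",
    "Tetraselmis suecica",
)

#: genome_id -> [(species served, is_surrogate)]
GENOME_TO_SPECIES: dict[str, list[tuple[str, bool]]] = {
    "Amphidinium carterae": [
        ("Amphidinium carterae", False),
        ("Alexandrium tamutum", True),
    ],
    "Cylindrotheca fusiformis": [("Cylindrotheca closterium", True)],
    "Tetraselmis striata": [("Tetraselmis suecica", True)],
}


def _data_path(name: str):
    return resources.files("m6ascreen.data").joinpath(name)


def load_goi_inventory() -> pd.DataFrame:
    """Published GOI inventory: transcript_id, species, goi."""
    with resources.as_file(_data_path("goi_inventory.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def goi_inventory_assignments(evalue: float = 1e-40) -> list[GoiAssignment]:
    """The inventory as GOI assignments (one per listed transcript).

    The inventory records which transcript belongs to which writer/eraser but
    not the underlying hit scores, so a nominal qualifying e-value is
    attached; presence/absence logic only needs the (transcript, species,
    GOI) triples.
    """
    df = load_goi_inventory()
    return [
        GoiAssignment(
            transcript_id=r.transcript_id,
            species=r.species,
            goi_name=r.goi,
            best_query_id="inventory",
            evalue=evalue,
        )
        for r in df.itertuples(index=False)
    ]


def load_genome_mapping_summary() -> list[GenomeMappingRecord]:
    """Summarized genome-scan records for the three reference genomes."""
    with resources.as_file(_data_path("genome_mapping_summary.tsv")) as p:
        return read_mappings(p)
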