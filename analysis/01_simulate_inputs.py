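#!/usr/bin/env python
"""Generate the ground-truthed synthetic inputs used by the later stages:
planted gene families with within-species duplications, their all-vs-all hit
table, GOI-query screening hits, a planted Cq table, and growth series.

Writes everything under results/synthetic/.
"""

from pathlib import Path

from m6ascreen import homology, qpcr, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = synth.SynthConfig(seed=SEED)
    families, roster = synth.simulate_families(config)
    synth.write_family_truth(families, OUT / "family_truth.tsv")
    n_dup = sum(synth.n_duplication_groups(families, sp) for sp in roster)
    print(f"planted {len(families)} families over {len(roster)} species, "
          f"{n_dup} duplication groups")

    table = synth.simulate_hit_table(families, config)
    homology.write_hit_table(table, OUT / "all_vs_all_hits.tsv")
    with open(OUT / "species_map.tsv", "w") as fh:
        for g in sorted(table.species_of):
            fh.write(f"{g}\t{table.species_of[g]}\n")
    print(f"hit table: {len(table.df)} rows, {len(table.species_of)} genes")

    goi_hits, family_to_goi = synth.simulate_goi_hits(families, config)
    homology.write_hit_table(goi_hits, OUT / "goi_query_hits.tsv")
    with open(OUT / "goi_truth.tsv", "w") as fh:
        fh.write("family_id\tgoi\n")
        for fam, goi in sorted(family_to_goi.items()):
            fh.write(f"{fam}\t{goi}\n")
    print(f"GOI queries planted on families: {sorted(family_to_goi.items())}")

    cq = synth.simulate_cq_table(synth.default_cq_truth(), 3, seed=SEED)
    qpcr.write_cq_table(cq, OUT / "cq_table.tsv", OUT / "cq_samples.tsv")
    print(f"Cq table: {len(cq.genes)} genes x {len(cq.samples)} samples "
          f"(triplicates, control vs treatment)")

    # batch-culture style growth series at the five observed condition rates
    for name, rate in [("control", 0.45), ("N_depletion", 0.43),
                       ("P_depletion", 0.39), ("Zn5", 0.44), ("Zn10", 0.22)]:
        series = synth.simulate_growth(rate, 5000.0, 7, 0.05, seed=SEED)
        synth.write_growth_series(series, OUT / f"growth_{name}.tsv")
    print("growth series written for 5 culture conditions")


if __name__ == "__main__":
    main()
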