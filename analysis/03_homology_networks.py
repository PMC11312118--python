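#!/usr/bin/env python
"""Homology inference on the simulated hit table: BBH orthologs for every
species pair, the paralogy e-value threshold scan, paralog edges at the
chosen cutoff, and the merged ortholog/paralog networks.

Reads results/synthetic/ (run 01 first); writes results/homology/.
"""

from pathlib import Path

from m6ascreen import homology, networks, synth

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = BASE / "homology"
    out.mkdir(parents=True, exist_ok=True)
    config = synth.SynthConfig(seed=SEED)
    families, roster = synth.simulate_families(config)
    table = synth.simulate_hit_table(families, config)

    all_pairs = []
    for i, sa in enumerate(roster):
        for sb in roster[i + 1:]:
            pairs = homology.bbh_orthologs(table, sa, sb)
            all_pairs += pairs
            print(f"BBH {sa} vs {sb}: {len(pairs)} ortholog pairs")
    homology.write_ortholog_pairs(all_pairs, out / "ortholog_pairs.tsv")

    scan = homology.paralog_threshold_scan(table, roster, synth.GAP_SCAN_GRID)
    homology.write_scan_table(scan, out / "threshold_scan.tsv")
    planted = sum(synth.n_duplication_groups(families, sp) for sp in roster)
    print(f"threshold scan: chosen cutoff {scan.chosen_cutoff:.3g}, "
          f"{scan.count_at[scan.chosen_cutoff]} duplicated-gene networks "
          f"(planted: {planted})")

    paralogs = []
    for sp in roster:
        edges = homology.paralog_edges(table, sp, scan.chosen_cutoff)
        paralogs += [(u, v, sp) for u, v in edges]
        print(f"paralog edges in {sp}: {len(edges)}")

    net = networks.build_networks(all_pairs, paralogs)
    networks.write_edge_table(net, out / "network_edges.tsv")
    networks.write_graphml(net, out / "networks.graphml")
    comps = net.components()
    print(f"merged networks: {net.graph.number_of_nodes()} genes in "
          f"{len(comps)} components "
          f"(largest: {max(len(c) for c in comps)})")


if __name__ == "__main__":
    main()
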