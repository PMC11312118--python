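"""Best hits, BBH orthology, paralog edges and the threshold scan, all
checked against independent brute-force oracles."""

import itertools

import pandas as pd
import pytest

from m6ascreen import synth
from m6ascreen.homology import (
    OUTFMT6_COLUMNS,
    HitTable,
    HitTableError,
    bbh_orthologs,
    best_hit,
    count_duplicated_networks,
    paralog_edges,
    paralog_threshold_scan,
    read_hit_table,
)


def make_table(hits, species_of):
    """hits: iterable of (query, subject, evalue[, bitscore])."""
    rows = []
    for h in hits:
        q, s, ev = h[0], h[1], h[2]
        bs = h[3] if len(h) > 3 else 50.0
        rows.append([q, s, 90.0, 100, 5, 0, 1, 100, 1, 100, ev, bs])
    return HitTable(
        df=pd.DataFrame(rows, columns=OUTFMT6_COLUMNS),
        species_of=dict(species_of),
    )


# ---------------------------------------------------------------------------
# parsing


def test_read_hit_table_parses_valid_line(tmp_path):
    path = tmp_path / "h.tsv"
    path.write_text("a1\tb1\t88.5\t120\t10\t1\t1\t120\t5\t124\t3e-50\t210\n")
    table = read_hit_table(path, species_map={"a1": "A", "b1": "B"})
    assert len(table.df) == 1
    assert table.df.evalue.iloc[0] == pytest.approx(3e-50)


def test_read_hit_table_rejects_wrong_column_count(tmp_path):
    path = tmp_path / "h.tsv"
    path.write_text("a1\tb1\t88.5\t120\t10\t1\t1\t120\t5\t124\t3e-50\n")
    with pytest.raises(HitTableError, match="line 1"):
        read_hit_table(path, species_map={"a1": "A", "b1": "B"})


def test_read_hit_table_lists_unmappable_genes(tmp_path):
    path = tmp_path / "h.tsv"
    path.write_text("a1\tb1\t88.5\t120\t10\t1\t1\t120\t5\t124\t3e-50\t210\n")
    with pytest.raises(HitTableError, match="b1"):
        read_hit_table(path, species_map={"a1": "A"})


# ---------------------------------------------------------------------------
# best hit


def test_best_hit_unique_minimum():
    t = make_table(
        [("a1", "b1", 1e-50), ("a1", "b2", 1e-10)],
        {"a1": "A", "b1": "B", "b2": "B"},
    )
    assert best_hit(t, "a1", "B") == "b1"


def test_best_hit_tie_broken_by_bitscore():
    t = make_table(
        [("a1", "b1", 1e-50, 210.0), ("a1", "b2", 1e-50, 180.0)],
        {"a1": "A", "b1": "B", "b2": "B"},
    )
    assert best_hit(t, "a1", "B") == "b1"


def test_best_hit_none_when_no_target_hits():
    t = make_table([("a1", "b1", 1e-50)], {"a1": "A", "b1": "B", "c1": "C"})
    assert best_hit(t, "a1", "C") is None


def test_best_hit_respects_ceiling():
    t = make_table([("a1", "b1", 1e-3)], {"a1": "A", "b1": "B"})
    assert best_hit(t, "a1", "B", evalue_ceiling=1e-5) is None
    assert best_hit(t, "a1", "B", evalue_ceiling=1e-2) == "b1"


# ---------------------------------------------------------------------------
# BBH


def test_bbh_asymmetric_best_hits_excluded():
    t = make_table(
        [("a1", "b1", 1e-50), ("b1", "a1", 1e-48), ("a2", "b1", 1e-10),
         ("b1", "a2", 1e-60)],
        {"a1": "A", "a2": "A", "b1": "B"},
    )
    # b1's best hit is a2, but a2's best hit is b1 while a1's is also b1:
    # only the mutual pair (a2, b1) qualifies
    pairs = bbh_orthologs(t, "A", "B")
    assert {(p.gene_a, p.gene_b) for p in pairs} == {("a2", "b1")}


def test_bbh_simple_reciprocal_pair():
    t = make_table(
        [("a1", "b1", 1e-50), ("b1", "a1", 1e-48)], {"a1": "A", "b1": "B"}
    )
    pairs = bbh_orthologs(t, "A", "B")
    assert len(pairs) == 1
    assert (pairs[0].gene_a, pairs[0].gene_b) == ("a1", "b1")


def test_bbh_one_side_above_ceiling_gives_nothing():
    t = make_table(
        [("a1", "b1", 1e-50), ("b1", "a1", 1e-3)], {"a1": "A", "b1": "B"}
    )
    assert bbh_orthologs(t, "A", "B", evalue_ceiling=1e-5) == []


def test_bbh_same_species_rejected(planted_tables):
    _, _, table = planted_tables
    with pytest.raises(HitTableError):
        bbh_orthologs(table, "SP1", "SP1")


def brute_force_bbh(table, sa, sb, ceiling):
    """O(n^2) oracle: recompute best hits per gene from raw rows."""
    def best(gene, target):
        cands = []
        for r in table.df.itertuples(index=False):
            if (
                r.query_id == gene
                and r.subject_id != gene
                and table.species_of[r.subject_id] == target
                and r.evalue <= ceiling
            ):
                cands.append((r.evalue, -r.bitscore, r.subject_id))
        return min(cands)[2] if cands else None

    pairs = set()
    for a in table.genes_of(sa):
        b = best(a, sb)
        if b is not None and best(b, sa) == a:
            pairs.add(tuple(sorted((a, b))))
    return pairs


def brute_force_paralog_edges(table, species, cutoff):
    genes = set(table.genes_of(species))
    pair_min = {}
    for r in table.df.itertuples(index=False):
        u, v = r.query_id, r.subject_id
        if u == v or u not in genes or v not in genes:
            continue
        key = tuple(sorted((u, v)))
        pair_min[key] = min(pair_min.get(key, float("inf")), r.evalue)
    return {pair for pair, ev in pair_min.items() if ev <= cutoff}


def test_bbh_matches_brute_force_on_planted_tables(planted_tables):
    _, roster, table = planted_tables
    for sa, sb in itertools.combinations(roster, 2):
        got = {(p.gene_a, p.gene_b) for p in bbh_orthologs(table, sa, sb)}
        assert got == brute_force_bbh(table, sa, sb, 1e-5)


def test_bbh_symmetry_and_uniqueness(planted_tables):
    _, _, table = planted_tables
    ab = {(p.gene_a, p.gene_b) for p in bbh_orthologs(table, "SP1", "SP2")}
    ba = {(p.gene_a, p.gene_b) for p in bbh_orthologs(table, "SP2", "SP1")}
    assert ab == ba
    flat = [g for pair in ab for g in pair]
    assert len(flat) == len(set(flat))


# ---------------------------------------------------------------------------
# paralog edges and threshold scan


def test_paralog_edge_requires_cutoff():
    t = make_table(
        [("a1", "a2", 1e-12)], {"a1": "A", "a2": "A"}
    )
    assert paralog_edges(t, "A", 1e-10) == [("a1", "a2")]
    assert paralog_edges(t, "A", 1e-13) == []


def test_paralog_edges_either_direction_qualifies():
    t = make_table(
        [("a1", "a2", 1e-3), ("a2", "a1", 1e-12)], {"a1": "A", "a2": "A"}
    )
    assert paralog_edges(t, "A", 1e-10) == [("a1", "a2")]


def test_self_hits_never_form_edges():
    t = make_table([("a1", "a1", 0.0)], {"a1": "A"})
    assert paralog_edges(t, "A", 1.0) == []


def test_paralog_edges_match_brute_force(planted_tables):
    _, roster, table = planted_tables
    for sp in roster:
        for cutoff in (1e-5, 1e-20, 1e-60, 1e-120):
            got = set(paralog_edges(table, sp, cutoff))
            assert got == brute_force_paralog_edges(table, sp, cutoff)


def test_scan_single_species_worked_example():
    # four genes of one species, two duplicated families a* and b*, plus a
    # weak spurious hit bridging them
    t = make_table(
        [("a1", "a2", 1e-50), ("b1", "b2", 1e-60), ("a2", "b1", 1e-8)],
        {"a1": "A", "a2": "A", "b1": "A", "b2": "A"},
    )
    res = paralog_threshold_scan(t, "A", [1e-5, 1e-10])
    assert res.count_at == {1e-10: 2, 1e-5: 1}
    assert res.chosen_cutoff == 1e-10


def test_scan_no_edges_ties_to_most_stringent():
    t = make_table([("a1", "a1", 0.0)], {"a1": "A"})
    res = paralog_threshold_scan(t, "A", [1e-5, 1e-10, 1e-20])
    assert set(res.count_at.values()) == {0}
    assert res.chosen_cutoff == 1e-20


def test_scan_rejects_missing_species(planted_tables):
    _, _, table = planted_tables
    with pytest.raises(HitTableError):
        paralog_threshold_scan(table, "NOPE", [1e-5, 1e-10])


def test_scan_counts_match_naive_component_recount(planted_tables):
    _, roster, table = planted_tables
    grid = [10.0 ** -k for k in range(5, 41, 5)]
    res = paralog_threshold_scan(table, roster, grid)
    for cutoff in grid:
        naive = sum(
            count_duplicated_networks(table, sp, cutoff) for sp in roster
        )
        assert res.count_at[cutoff] == naive


def test_edge_sets_monotone_in_cutoff(planted_tables):
    _, roster, table = planted_tables
    for sp in roster:
        strict = set(paralog_edges(table, sp, 1e-40))
        loose = set(paralog_edges(table, sp, 1e-10))
        assert strict <= loose


@pytest.mark.parametrize("seed", range(8))
def test_planted_gap_recovered(seed):
    """On planted-gap tables the scan lands inside the e-value gap and
    counts exactly the planted duplication groups; the maximizing plateau
    spans the whole gap interior."""
    cfg = synth.SynthConfig(seed=seed)
    families, roster = synth.simulate_families(cfg)
    table = synth.simulate_hit_table(families, cfg)
    planted = sum(synth.n_duplication_groups(families, sp) for sp in roster)
    res = paralog_threshold_scan(table, roster, synth.GAP_SCAN_GRID)
    gap_lo = 10.0 ** cfg.within_family_evalue_range[1]
    gap_hi = 10.0 ** cfg.background_evalue_range[0]
    assert gap_lo < res.chosen_cutoff <= gap_hi
    assert res.count_at[res.chosen_cutoff] == planted
    assert max(res.count_at.values()) == planted
    # every grid cutoff strictly inside the gap attains the maximum,
    # independent of the tie rule
    for c in res.grid:
        if gap_lo < c < gap_hi:
            assert res.count_at[c] == planted


def test_scan_per_species_counts_sum_to_pooled(planted_tables):
    _, roster, table = planted_tables
    grid = [1e-10, 1e-30]
    pooled = paralog_threshold_scan(table, roster, grid)
    per = [paralog_threshold_scan(table, sp, grid) for sp in roster]
    for cutoff in grid:
        assert pooled.count_at[cutoff] == sum(p.count_at[cutoff] for p in per)
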