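"""Closed-form and hand-computed checks of the qPCR analyses: relative
quantities, the three stability methods, efficiency-corrected expression
ratios, and growth-rate estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from m6ascreen import synth
from m6ascreen.qpcr import (
    CqTable,
    QpcrError,
    bestkeeper_stats,
    genorm,
    growth_rate,
    normfinder,
    read_cq_table,
    rel_expression,
    relative_quantities,
    select_reference_pair,
    stars,
    write_cq_table,
)


def make_cq(data, conditions=None, efficiency=None, role=None):
    """data: dict gene -> list of Cq values; samples named s1..sn."""
    genes = list(data)
    n = len(data[genes[0]])
    samples = [f"s{i + 1}" for i in range(n)]
    conditions = conditions or {s: "control" for s in samples}
    return CqTable(
        cq=pd.DataFrame(
            {s: [data[g][i] for g in genes] for i, s in enumerate(samples)},
            index=genes,
        ),
        condition=conditions,
        efficiency=efficiency or {},
        role=role or {},
    )


# ---------------------------------------------------------------------------
# relative quantities


def test_relative_quantity_closed_forms():
    t = make_cq({"g": [20.0, 21.0, 22.0]}, efficiency={"g": 2.0})
    q = relative_quantities(t).loc["g"]
    assert q.tolist() == pytest.approx([1.0, 0.5, 0.25])


def test_relative_quantity_non_doubling_efficiency():
    t = make_cq({"g": [20.0, 22.0]}, efficiency={"g": 1.9})
    q = relative_quantities(t).loc["g"]
    assert q.iloc[1] == pytest.approx(1.0 / 3.61, rel=1e-12)


# ---------------------------------------------------------------------------
# BestKeeper


def test_bestkeeper_constant_gene_is_most_stable():
    t = make_cq({"flat": [20.0] * 3, "wavy": [20.0, 21.0, 22.0]})
    rep = bestkeeper_stats(t)
    assert rep.statistic["flat"] == 0.0
    assert rep.statistic["wavy"] == pytest.approx(1.0)
    assert rep.ranking[0] == "flat"


def test_bestkeeper_mad_variant():
    t = make_cq({"g": [20.0, 21.0, 22.0], "h": [20.0] * 3})
    rep = bestkeeper_stats(t, variant="mad")
    assert rep.statistic["g"] == pytest.approx(2.0 / 3.0)


def test_bestkeeper_requires_two_samples():
    with pytest.raises(QpcrError):
        bestkeeper_stats(make_cq({"g": [20.0], "h": [21.0]}))


# ---------------------------------------------------------------------------
# geNorm


def test_genorm_hand_computed_three_gene_example():
    """g1 and g2 share a profile (V12 = 0); g3 is flat, so V13 = V23 =
    SD([0,1,2,3]) ~ 1.2910; g3 is excluded and the final pair M equals 0."""
    t = make_cq(
        {"g1": [3.0, 2.0, 1.0, 0.0],
         "g2": [13.0, 12.0, 11.0, 10.0],
         "g3": [20.0] * 4}
    )
    rep = genorm(t)
    sd = np.std([0.0, 1.0, 2.0, 3.0], ddof=1)
    assert rep.exclusion_trace == [("g3", pytest.approx(sd))]
    assert rep.best_pair == ("g1", "g2")
    assert rep.statistic["g1"] == pytest.approx(0.0)
    assert rep.statistic["g2"] == pytest.approx(0.0)
    assert rep.statistic["g3"] == pytest.approx(1.29099, abs=1e-4)


def test_genorm_final_pair_share_identical_m(planted_cq):
    rep = genorm(planted_cq)
    a, b = rep.best_pair
    assert rep.statistic[a] == pytest.approx(rep.statistic[b], abs=1e-12)


def test_genorm_invariant_to_per_gene_constant_shift(planted_cq):
    shifted = CqTable(
        cq=planted_cq.cq.add(
            pd.Series({g: 5.0 * i for i, g in enumerate(planted_cq.genes)}),
            axis=0,
        ),
        condition=dict(planted_cq.condition),
        efficiency=dict(planted_cq.efficiency),
        role=dict(planted_cq.role),
    )
    r1, r2 = genorm(planted_cq), genorm(shifted)
    assert r1.ranking == r2.ranking
    for g in r1.statistic:
        assert r1.statistic[g] == pytest.approx(r2.statistic[g], abs=1e-9)


def test_genorm_requires_three_genes():
    with pytest.raises(QpcrError):
        genorm(make_cq({"g1": [20.0, 21.0], "g2": [20.0, 21.0]}))


@pytest.fixture()
def planted_cq():
    table = synth.simulate_cq_table(synth.default_cq_truth(), 5, seed=42)
    return table.restrict(table.candidate_rgs())


# ---------------------------------------------------------------------------
# NormFinder


def test_normfinder_identical_profiles_all_zero():
    t = make_cq(
        {"g1": [20.0, 21.0, 19.5], "g2": [22.0, 23.0, 21.5],
         "g3": [25.0, 26.0, 24.5]}
    )
    rep = normfinder(t)
    for g in rep.statistic:
        assert rep.statistic[g] == pytest.approx(0.0, abs=1e-12)


def test_normfinder_loading_shift_absorbed():
    t1 = make_cq(
        {"g1": [20.0, 20.4, 19.7], "g2": [22.0, 22.6, 21.9],
         "g3": [24.0, 24.1, 23.8]}
    )
    shifted = t1.cq.copy()
    shifted["s2"] = shifted["s2"] + 3.0  # one sample loaded 3 cycles light
    t2 = CqTable(cq=shifted, condition=dict(t1.condition))
    r1, r2 = normfinder(t1), normfinder(t2)
    for g in r1.statistic:
        assert r1.statistic[g] == pytest.approx(r2.statistic[g], abs=1e-9)


def test_normfinder_noisy_gene_ranked_last(planted_cq):
    rep = normfinder(planted_cq)
    assert rep.ranking[-1].startswith("RG_noisy")
    # the planted stable genes always beat the worst noisy gene; full top-2
    # recovery is a Monte-Carlo property checked at the acceptance level
    worst = rep.statistic[rep.ranking[-1]]
    assert rep.statistic["RG_stable1"] < worst
    assert rep.statistic["RG_stable2"] < worst


def test_normfinder_single_group_falls_back_with_warning(planted_cq):
    groups = {s: "all" for s in planted_cq.samples}
    with pytest.warns(UserWarning, match="single group"):
        rep = normfinder(planted_cq, groups=groups)
    assert rep.ranking == normfinder(planted_cq).ranking


def test_normfinder_grouped_mode_ranks_planted_pair_top2():
    table = synth.simulate_cq_table(synth.default_cq_truth(), 6, seed=3)
    rgs = table.restrict(table.candidate_rgs())
    rep = normfinder(rgs, groups=dict(rgs.condition))
    assert set(rep.best_pair) == {"RG_stable1", "RG_stable2"}


# ---------------------------------------------------------------------------
# consensus pair


def _report(method, ranks):
    from m6ascreen.qpcr import StabilityReport

    ranking = sorted(ranks, key=lambda g: ranks[g])
    return StabilityReport(
        method=method,
        statistic={g: float(r) for g, r in ranks.items()},
        ranking=ranking,
        best_pair=tuple(sorted(ranking[:2])),
    )


def test_consensus_pair_unanimous():
    ranks = {"UB": 1, "CDK": 2, "ATUB": 3, "BTUB": 4, "GAPDH": 5}
    reports = [_report(m, ranks) for m in ("bestkeeper", "genorm", "normfinder")]
    assert select_reference_pair(reports) == ("CDK", "UB")


def test_consensus_pair_single_report():
    assert select_reference_pair(
        [_report("bestkeeper", {"a": 1, "b": 2, "c": 3})]
    ) == ("a", "b")


def test_consensus_pair_conflicting_reports_mean_rank():
    r1 = _report("bestkeeper", {"a": 1, "b": 2, "c": 3})
    r2 = _report("genorm", {"a": 3, "b": 1, "c": 2})
    r3 = _report("normfinder", {"a": 2, "b": 3, "c": 1})
    # mean ranks: a=2, b=2, c=2; top-2 votes: a=2, b=2, c=2; lexicographic
    assert select_reference_pair([r1, r2, r3]) == ("a", "b")
    r3b = _report("normfinder", {"a": 2, "b": 1, "c": 3})
    # mean ranks: a=2, b=4/3, c=8/3
    assert select_reference_pair([r1, r2, r3b]) == ("a", "b")


def test_consensus_requires_reports():
    with pytest.raises(QpcrError):
        select_reference_pair([])


# ---------------------------------------------------------------------------
# relative expression


def expression_table(target_shift, e_target=2.0, noise=None):
    """Two conditions x 3 replicates; refs flat, target shifted in treatment."""
    data = {
        "ref1": [20.0] * 6,
        "ref2": [18.0] * 6,
        "tg": [25.0] * 3 + [25.0 + target_shift] * 3,
    }
    if noise:
        rng = np.random.default_rng(0)
        data = {
            g: (np.asarray(v) + rng.normal(0, noise, 6)).tolist()
            for g, v in data.items()
        }
    conditions = {f"s{i + 1}": ("control" if i < 3 else "T") for i in range(6)}
    return make_cq(
        data,
        conditions=conditions,
        efficiency={"ref1": 2.0, "ref2": 2.0, "tg": e_target},
        role={"ref1": "candidate_RG", "ref2": "candidate_RG", "tg": "target"},
    )


def test_rel_expression_closed_form_doubling():
    t = expression_table(target_shift=-3.0)
    with pytest.warns(UserWarning, match="zero replicate variance"):
        (r,) = rel_expression(t, refs=["ref1", "ref2"])
    assert r.log2_ratio == pytest.approx(3.0, abs=1e-12)


def test_rel_expression_closed_form_efficiency_19():
    t = expression_table(target_shift=-3.0, e_target=1.9)
    with pytest.warns(UserWarning):
        (r,) = rel_expression(t, refs=["ref1", "ref2"])
    assert 2.0 ** r.log2_ratio == pytest.approx(1.9 ** 3, rel=1e-12)


def test_rel_expression_single_ref_equals_ddcq_closed_form():
    """With one reference and zero replicate variance the ratio equals
    E^ddCq to machine precision."""
    t = expression_table(target_shift=-2.0)
    with pytest.warns(UserWarning):
        (r,) = rel_expression(t, refs=["ref1"])
    assert r.log2_ratio == pytest.approx(2.0, abs=1e-12)


def test_rel_expression_identical_conditions_give_zero_ratio():
    t = expression_table(target_shift=0.0)
    with pytest.warns(UserWarning):
        (r,) = rel_expression(t, refs=["ref1", "ref2"])
    assert r.log2_ratio == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == 1.0 and r.significance == "ns"


def test_rel_expression_ttest_detects_planted_effect():
    t = expression_table(target_shift=-3.0, noise=0.1)
    (r,) = rel_expression(t, refs=["ref1", "ref2"])
    assert r.log2_ratio == pytest.approx(3.0, abs=0.5)
    assert r.p_value < 0.01


def test_rel_expression_permutation_p_bounded_and_small():
    t = expression_table(target_shift=-3.0, noise=0.1)
    (r,) = rel_expression(
        t, refs=["ref1", "ref2"], method="permutation",
        n_permutations=500, seed=1,
    )
    # with 3v3 replicates only C(6,3)=20 label splits exist; the smallest
    # attainable one-sided p with add-one correction is bounded below
    assert 0.0 < r.p_value < 0.2


def test_rel_expression_unknown_gene_or_condition_rejected():
    t = expression_table(target_shift=-1.0)
    with pytest.raises(QpcrError):
        rel_expression(t, refs=["ghost"])
    with pytest.raises(QpcrError):
        rel_expression(t, refs=["ref1"], control_condition="mock")


def test_significance_stars_consistent():
    assert stars(0.2) == "ns"
    assert stars(0.03) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"


# ---------------------------------------------------------------------------
# growth rate


def test_growth_rate_recovers_generating_rate_exactly():
    series = synth.simulate_growth(rate=0.45, n0=5000, days=7, noise_cv=0.0)
    fit = growth_rate(series)
    assert fit.rate == pytest.approx(0.45, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_growth_rate_constant_series_is_zero():
    series = synth.simulate_growth(rate=0.0, n0=5000, days=5)
    assert growth_rate(series).rate == pytest.approx(0.0, abs=1e-12)


def test_growth_rate_two_point_window_closed_form():
    series = synth.GrowthSeries(
        times=[0.0, 7.0], densities=[5000.0, 5000.0 * math.exp(3.15)]
    )
    fit = growth_rate(series)
    assert fit.n_points == 2
    assert fit.rate == pytest.approx(0.45, abs=1e-12)


def test_growth_rate_window_restricts_fit():
    series = synth.GrowthSeries(
        times=[0, 1, 2, 3, 4],
        densities=[100.0, 200.0, 400.0, 400.0, 400.0],  # growth then plateau
    )
    early = growth_rate(series, window=(0, 2))
    assert early.rate == pytest.approx(math.log(2), abs=1e-12)
    full = growth_rate(series)
    assert full.rate < early.rate


def test_growth_rate_needs_two_points():
    series = synth.simulate_growth(rate=0.4, n0=5000, days=7)
    with pytest.raises(QpcrError):
        growth_rate(series, window=(2.2, 2.8))


# ---------------------------------------------------------------------------
# IO round trip


def test_cq_table_round_trips(tmp_path):
    table = synth.simulate_cq_table(synth.default_cq_truth(), 3, seed=5)
    cq_path, samples_path = tmp_path / "cq.tsv", tmp_path / "samples.tsv"
    write_cq_table(table, cq_path, samples_path)
    back = read_cq_table(cq_path, samples_path)
    assert back.genes == table.genes
    assert back.condition == table.condition
    assert back.role == table.role
    assert np.allclose(back.cq.to_numpy(), table.cq.to_numpy(), atol=1e-6)
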