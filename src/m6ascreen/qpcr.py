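"""RT-qPCR analysis: reference-gene stability, relative expression, growth.

Implements the three standard reference-gene (RG) stability estimators —
BestKeeper-style Cq standard deviation, geNorm's pairwise-variation M with
stepwise exclusion, and a NormFinder-style model-based stability value — plus
efficiency-corrected relative expression ratios (REST-style
E_target^dCq / E_ref^dCq normalization against a reference-gene pair, with
Student's t-test or an optional label-permutation test) and net growth-rate
estimation as the slope of ln(cell density) over time.

Cq (quantification cycle) is the PCR cycle at which amplification crosses
threshold; one cycle difference corresponds to an E-fold change in starting
template, where E in (1, 2] is the amplification efficiency (2 = perfect
doubling, the default when assay efficiencies are not measured).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import GrowthSeries


class QpcrError(ValueError):
    """Invalid Cq table or analysis request."""


@dataclass
class CqTable:
    """Genes x samples Cq matrix with roles, conditions and efficiencies.

    ``cq`` is a DataFrame indexed by gene; ``condition`` maps sample ->
    condition label; ``efficiency`` maps gene -> fold per cycle; ``role``
    maps gene -> 'candidate_RG' or 'target'.
    """

    cq: pd.DataFrame
    condition: dict[str, str]
    efficiency: dict[str, float] = field(default_factory=dict)
    role: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.cq.to_numpy()).all():
            raise QpcrError("Cq values must be finite")
        missing = [s for s in self.cq.columns if s not in self.condition]
        if missing:
            raise QpcrError(f"samples without condition labels: {missing}")
        for g in self.cq.index:
            self.efficiency.setdefault(g, 2.0)
            self.role.setdefault(g, "candidate_RG")
        bad = {
            g: e for g, e in self.efficiency.items() if not 1.0 < e <= 2.0
        }
        if bad:
            raise QpcrError(f"efficiencies outside (1, 2]: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cq.columns)

    def candidate_rgs(self) -> list[str]:
        return [g for g in self.genes if self.role[g] == "candidate_RG"]

    def targets(self) -> list[str]:
        return [g for g in self.genes if self.role[g] == "target"]

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == condition]

    def restrict(self, genes: Sequence[str]) -> "CqTable":
        return CqTable(
            cq=self.cq.loc[list(genes)].copy(),
            condition=dict(self.condition),
            efficiency={g: self.efficiency[g] for g in genes},
            role={g: self.role[g] for g in genes},
        )


def relative_quantities(cq: CqTable) -> pd.DataFrame:
    """Relative quantity Q(g, s) = E_g^(minCq_g - Cq(g, s)).

    The best (lowest-Cq) sample of each gene gets Q = 1; every extra cycle
    divides the quantity by the gene's efficiency.
    """
    out = pd.DataFrame(index=cq.cq.index, columns=cq.cq.columns, dtype=float)
    for g in cq.genes:
        e = cq.efficiency[g]
        row = cq.cq.loc[g]
        out.loc[g] = np.power(e, row.min() - row)
    return out


@dataclass
class StabilityReport:
    """Per-gene stability statistics from one method (lower = more stable)."""

    method: str
    statistic: dict[str, float]
    ranking: list[str]
    best_pair: tuple[str, str]
    exclusion_trace: list[tuple[str, float]] | None = None

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.statistic):
            raise QpcrError("ranking must be a permutation of the genes")

    def rank_of(self, gene: str) -> int:
        return self.ranking.index(gene) + 1


def bestkeeper_stats(cq: CqTable, variant: str = "sd") -> StabilityReport:
    """Cq dispersion per candidate RG: sample SD (default) or the original
    tool's mean absolute deviation, ranked ascending."""
    genes = cq.candidate_rgs()
    if cq.cq.shape[1] < 2:
        raise QpcrError("BestKeeper needs >= 2 samples")
    stat = {}
    for g in genes:
        x = cq.cq.loc[g].to_numpy(dtype=float)
        if variant == "sd":
            stat[g] = float(np.std(x, ddof=1))
        elif variant == "mad":
            stat[g] = float(np.mean(np.abs(x - x.mean())))
        else:
            raise QpcrError(f"unknown BestKeeper variant: {variant}")
    ranking = sorted(genes, key=lambda g: (stat[g], g))
    return StabilityReport(
        method="bestkeeper",
        statistic=stat,
        ranking=ranking,
        best_pair=tuple(sorted(ranking[:2])),
    )


def _pairwise_variation(logq: pd.DataFrame, gj: str, gk: str) -> float:
    """SD over samples of log2(Q_j / Q_k)."""
    diff = logq.loc[gj] - logq.loc[gk]
    return float(np.std(diff.to_numpy(dtype=float), ddof=1))


def genorm(cq: CqTable) -> StabilityReport:
    """geNorm expression stability M with stepwise exclusion.

    M_j is the mean over all other candidates k of the SD of
    log2(Q_j / Q_k) across samples. The least stable (max M) gene is dropped
    each round until two remain; those two share the same final M by
    symmetry and form the best pair. The statistic reported per gene is its
    M in the round it was excluded (the final M for the surviving pair).
    """
    genes = cq.candidate_rgs()
    if len(genes) < 3:
        raise QpcrError("geNorm stepwise exclusion needs >= 3 candidate genes")
    if cq.cq.shape[1] < 2:
        raise QpcrError("geNorm needs >= 2 samples")
    logq = np.log2(relative_quantities(cq).loc[genes])
    remaining = list(genes)
    stat: dict[str, float] = {}
    trace: list[tuple[str, float]] = []
    order: list[str] = []
    while len(remaining) > 2:
        m = {
            j: float(
                np.mean(
                    [_pairwise_variation(logq, j, k) for k in remaining if k != j]
                )
            )
            for j in remaining
        }
        worst = max(remaining, key=lambda g: (m[g], g))
        stat[worst] = m[worst]
        trace.append((worst, m[worst]))
        order.append(worst)
        remaining.remove(worst)
    final_m = _pairwise_variation(logq, remaining[0], remaining[1])
    for g in remaining:
        stat[g] = final_m
    best_pair = tuple(sorted(remaining))
    ranking = sorted(remaining) + list(reversed(order))
    return StabilityReport(
        method="genorm",
        statistic=stat,
        ranking=ranking,
        best_pair=best_pair,
        exclusion_trace=trace,
    )


def normfinder(
    cq: CqTable, groups: Mapping[str, str] | None = None
) -> StabilityReport:
    """NormFinder-style model-based stability on log2 quantities.

    Ungrouped (default): fit the additive two-way model
    x(g, s) = gene effect + sample effect + residual by row/column means;
    the stability value is the bias-corrected SD of each gene's residuals,
    sqrt(G/(G-1) * sum_s r_gs^2 / (S-1)) — sample effects absorb loading
    shifts, so a gene is penalized only for variation the other genes do not
    share.

    Grouped mode (``groups``: sample -> group) combines the within-group
    residual SD with the magnitude of the gene's between-group effect
    (the full intra/inter-group variance decomposition of the original
    estimator is simplified to this sum; the ranking behaviour is the
    same for the planted scenarios exercised here). A single group falls
    back to ungrouped with a warning.
    """
    genes = cq.candidate_rgs()
    if len(genes) < 3:
        raise QpcrError("NormFinder needs >= 3 candidate genes")
    if cq.cq.shape[1] < 2:
        raise QpcrError("NormFinder needs >= 2 samples")
    logq = np.log2(relative_quantities(cq).loc[genes])
    x = logq.to_numpy(dtype=float)
    G, S = x.shape
    if groups is not None and len(set(groups.values())) < 2:
        warnings.warn(
            "grouped NormFinder with a single group; falling back to ungrouped",
            stacklevel=2,
        )
        groups = None
    if groups is None:
        stat = {
            g: s for g, s in zip(genes, _residual_sd(x))
        }
    else:
        labels = [groups[s] for s in logq.columns]
        uniq = sorted(set(labels))
        within = np.zeros(G)
        effect = np.zeros(G)
        grand_gene_mean = x.mean(axis=1)
        for grp in uniq:
            cols = [i for i, lab in enumerate(labels) if lab == grp]
            sub = x[:, cols]
            within += _residual_sd(sub) ** 2 / len(uniq)
            # gene-specific group effect, centred over genes
            d = sub.mean(axis=1) - grand_gene_mean
            effect += np.abs(d - d.mean()) / len(uniq)
        stat = {g: float(np.sqrt(w) + e) for g, w, e in zip(genes, within, effect)}
    ranking = sorted(genes, key=lambda g: (stat[g], g))
    return StabilityReport(
        method="normfinder",
        statistic={g: float(v) for g, v in stat.items()},
        ranking=ranking,
        best_pair=tuple(sorted(ranking[:2])),
    )


def _residual_sd(x: np.ndarray) -> np.ndarray:
    """Bias-corrected per-row residual SD of the additive two-way fit."""
    G, S = x.shape
    r = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    if S < 2 or G < 2:
        return np.zeros(G)
    var = (G / (G - 1)) * (r ** 2).sum(axis=1) / (S - 1)
    return np.sqrt(var)


def select_reference_pair(reports: Sequence[StabilityReport]) -> tuple[str, str]:
    """Consensus reference pair across stability methods.

    Genes are ordered by mean rank; ties resolve toward genes appearing in
    more methods' top-2, then lexicographically. Returns the two best genes
    sorted.
    """
    if not reports:
        raise QpcrError("no stability reports given")
    genes = reports[0].ranking
    for rep in reports[1:]:
        if sorted(rep.ranking) != sorted(genes):
            raise QpcrError("stability reports cover different gene sets")
    mean_rank = {
        g: float(np.mean([rep.rank_of(g) for rep in reports])) for g in genes
    }
    top2_votes = {
        g: sum(1 for rep in reports if g in rep.best_pair) for g in genes
    }
    ordered = sorted(genes, key=lambda g: (mean_rank[g], -top2_votes[g], g))
    return tuple(sorted(ordered[:2]))


@dataclass
class ExpressionResult:
    """Efficiency-corrected relative expression of one gene in one condition."""

    gene: str
    condition: str
    log2_ratio: float
    p_value: float
    significance: str
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_ratio):
            raise QpcrError("log2 ratio must be finite")
        if self.significance != stars(self.p_value):
            raise QpcrError("significance class inconsistent with p-value")


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _ref_normalized_log2(
    cq: CqTable, gene: str, refs: Sequence[str], samples: Sequence[str]
) -> np.ndarray:
    """Per-sample log2 expression of ``gene`` normalized to the reference
    genes: log2 E_g^(-Cq_g) - mean_r log2 E_r^(-Cq_r)."""
    eg = math.log2(cq.efficiency[gene])
    x = -cq.cq.loc[gene, list(samples)].to_numpy(dtype=float) * eg
    ref = np.zeros_like(x)
    for r in refs:
        er = math.log2(cq.efficiency[r])
        ref += -cq.cq.loc[r, list(samples)].to_numpy(dtype=float) * er
    return x - ref / len(refs)


def rel_expression(
    cq: CqTable,
    targets: Sequence[str] | None = None,
    refs: Sequence[str] = (),
    control_condition: str = "control",
    method: str = "ttest",
    n_permutations: int = 2000,
    seed: int = 0,
) -> list[ExpressionResult]:
    """Relative expression of target genes versus the control condition.

    The point estimate is the classical efficiency-corrected ratio
    ``E_target^dCq(target) / geomean_r E_r^dCq(r)`` with
    dCq = mean Cq(control) - mean Cq(treatment), reported as log2.
    Significance per (gene, condition) comes from a two-sided two-sample
    Student's t-test on per-replicate reference-normalized log2 expressions
    (default), or from a seeded REST-style permutation test of condition
    labels (``method='permutation'``, one-sided on |mean log effect|).
    """
    targets = list(targets) if targets is not None else cq.targets()
    refs = list(refs)
    if not refs:
        raise QpcrError("at least one reference gene required")
    for g in targets + refs:
        if g not in cq.genes:
            raise QpcrError(f"gene not in table: {g}")
    conditions = sorted(set(cq.condition.values()))
    if control_condition not in conditions:
        raise QpcrError(f"control condition not present: {control_condition}")
    ctrl_samples = cq.samples_in(control_condition)
    rng = np.random.default_rng(seed)
    results = []
    for cond in conditions:
        if cond == control_condition:
            continue
        cond_samples = cq.samples_in(cond)
        for g in targets:
            dcq_g = float(
                cq.cq.loc[g, ctrl_samples].mean() - cq.cq.loc[g, cond_samples].mean()
            )
            num = cq.efficiency[g] ** dcq_g
            ref_log = 0.0
            for r in refs:
                dcq_r = float(
                    cq.cq.loc[r, ctrl_samples].mean()
                    - cq.cq.loc[r, cond_samples].mean()
                )
                ref_log += math.log(cq.efficiency[r] ** dcq_r)
            denom = math.exp(ref_log / len(refs))
            log2_ratio = math.log2(num / denom)
            x_ctrl = _ref_normalized_log2(cq, g, refs, ctrl_samples)
            x_cond = _ref_normalized_log2(cq, g, refs, cond_samples)
            zero_var = bool(
                np.allclose(np.var(x_ctrl), 0.0) and np.allclose(np.var(x_cond), 0.0)
            )
            if zero_var:
                warnings.warn(
                    f"{g}/{cond}: zero replicate variance in both groups; "
                    "p-value degenerate",
                    stacklevel=2,
                )
                p = 0.0 if not np.isclose(x_ctrl.mean(), x_cond.mean()) else 1.0
            elif method == "ttest":
                p = float(stats.ttest_ind(x_cond, x_ctrl).pvalue)
            elif method == "permutation":
                p = _permutation_p(x_ctrl, x_cond, n_permutations, rng)
            else:
                raise QpcrError(f"unknown significance method: {method}")
            results.append(
                ExpressionResult(
                    gene=g,
                    condition=cond,
                    log2_ratio=log2_ratio,
                    p_value=p,
                    significance=stars(p),
                    zero_variance=zero_var,
                )
            )
    return results


def _permutation_p(
    x_ctrl: np.ndarray, x_cond: np.ndarray, n_perm: int, rng
) -> float:
    """REST-style randomization: reallocate condition labels and compare
    |mean difference|; add-one correction keeps p in (0, 1]."""
    obs = abs(x_cond.mean() - x_ctrl.mean())
    pooled = np.concatenate([x_ctrl, x_cond])
    n_c = len(x_ctrl)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[n_c:].mean() - perm[:n_c].mean())
        if d >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass
class GrowthRate:
    """Net growth rate (slope of ln density vs time) with fit diagnostics."""

    rate: float
    r_squared: float
    window: tuple[float, float]
    n_points: int


def growth_rate(
    series: GrowthSeries, window: tuple[float, float] | None = None
) -> GrowthRate:
    """Least-squares slope of ln(cell density) against time, per day.

    ``window`` restricts the fit to times in [t0, t1]; with exactly two
    points the estimator reduces to ln(N1/N0)/(t1-t0).
    """
    t = np.asarray(series.times, dtype=float)
    n = np.asarray(series.densities, dtype=float)
    if np.any(n <= 0):
        raise QpcrError("densities must be positive")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, n = t[mask], n[mask]
    if len(t) < 2:
        raise QpcrError("growth-rate fit needs >= 2 points in the window")
    y = np.log(n)
    if len(t) == 2:
        rate = float((y[1] - y[0]) / (t[1] - t[0]))
        return GrowthRate(
            rate=rate, r_squared=1.0,
            window=(float(t[0]), float(t[-1])), n_points=2,
        )
    fit = stats.linregress(t, y)
    return GrowthRate(
        rate=float(fit.slope),
        r_squared=float(fit.rvalue ** 2),
        window=(float(t[0]), float(t[-1])),
        n_points=len(t),
    )


# ---------------------------------------------------------------------------
# TSV interfaces


def read_cq_table(cq_path, samples_path, efficiency_path=None) -> CqTable:
    """Assemble a CqTable from its three TSV pieces.

    ``cq_path``: rows = genes with a ``role`` column, remaining columns =
    samples. ``samples_path``: sample, condition[, replicate].
    ``efficiency_path`` (optional): gene, efficiency.
    """
    df = pd.read_csv(cq_path, sep="\t", index_col=0)
    if "role" not in df.columns:
        raise QpcrError("Cq table needs a 'role' column")
    role = df["role"].to_dict()
    cq = df.drop(columns=["role"]).astype(float)
    meta = pd.read_csv(samples_path, sep="\t")
    condition = dict(zip(meta["sample"], meta["condition"]))
    efficiency = {}
    if efficiency_path is not None:
        eff = pd.read_csv(efficiency_path, sep="\t")
        efficiency = dict(zip(eff["gene"], eff["efficiency"].astype(float)))
    return CqTable(cq=cq, condition=condition, efficiency=efficiency, role=role)


def write_cq_table(table: CqTable, cq_path, samples_path) -> None:
    df = table.cq.copy()
    df.insert(0, "role", [table.role[g] for g in df.index])
    df.index.name = "gene"
    df.to_csv(cq_path, sep="\t", float_format="%.6f")
    with open(samples_path, "w") as fh:
        fh.write("sample\tcondition\n")
        for s in table.samples:
            fh.write(f"{s}\t{table.condition[s]}\n")


def write_stability_report(report: StabilityReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tstatistic\trank\tbest_pair\n")
        for g in report.ranking:
            inpair = "yes" if g in report.best_pair else "no"
            fh.write(
                f"{g}\t{report.statistic[g]:.6f}\t{report.rank_of(g)}\t{inpair}\n"
            )


def write_expression_results(results: Sequence[ExpressionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcondition\tlog2_ratio\tp_value\tsignificance\n")
        for r in sorted(results, key=lambda r: (r.gene, r.condition)):
            fh.write(
                f"{r.gene}\t{r.condition}\t{r.log2_ratio:.6f}\t"
                f"{r.p_value:.6g}\t{r.significance}\n"
            )
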