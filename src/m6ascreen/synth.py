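"""Ground-truthed synthetic inputs for every pipeline stage.

The generator plants what the downstream methods are supposed to recover:

* cross-species gene families with within-species duplications, whose
  reciprocal hits carry e-values log-uniform in a "within-family" range,
  separated by a gap from a "background" range used for spurious
  cross-family hits — so the paralogy threshold scan has a well-defined
  optimum inside the gap;
* quantification-cycle (Cq) tables built additively from gene baselines,
  per-sample loading shifts, planted treatment effects and per-gene
  Gaussian noise — so reference-gene stability methods and the
  efficiency-corrected expression ratios have known answers;
* exponential growth series with multiplicative noise.

Hits are simulated at the score level (e-values drawn directly rather than
mutating sequences and running an aligner): this keeps the generator free of
external tools while exercising all downstream logic. Bitscores are a
strictly decreasing function of e-value plus small jitter, preserving the
rank relation the best-hit logic relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .homology import OUTFMT6_COLUMNS, HitTable


class SynthConfigError(ValueError):
    """Invalid generator configuration."""


#: Cutoff grid used for threshold-recovery analyses on planted-gap tables:
#: decade steps spanning the background e-value range down to 1e-40, i.e.
#: bottoming out inside the planted separation gap. The tie rule of the scan
#: prefers the most stringent maximizer, so a grid reaching far below the gap
#: would tie its way past it; bounding the grid inside the gap keeps the
#: chosen cutoff interpretable while the scan still has to reject every
#: background-range cutoff on its own merits.
GAP_SCAN_GRID = tuple(10.0 ** -k for k in range(5, 41))


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the family/hit generator.

    E-value ranges are (low, high) exponents on the log10 scale, e.g.
    ``(-180, -50)`` means e-values drawn log-uniform in [1e-180, 1e-50].
    The within-family range must sit strictly below the background range:
    the gap between them is where the threshold scan should land.
    """

    n_species: int = 4
    n_families: int = 30
    dup_rate: float = 0.4
    within_family_evalue_range: tuple[float, float] = (-180.0, -50.0)
    background_evalue_range: tuple[float, float] = (-8.0, -1.0)
    background_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_families < 1:
            raise SynthConfigError("n_species and n_families must be >= 1")
        if not 0.0 <= self.dup_rate <= 1.0:
            raise SynthConfigError("dup_rate must be in [0, 1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise SynthConfigError("background_fraction must be in [0, 1]")
        for lo, hi in (
            self.within_family_evalue_range,
            self.background_evalue_range,
        ):
            if lo > hi:
                raise SynthConfigError("e-value range must be (low, high)")
        if self.within_family_evalue_range[1] >= self.background_evalue_range[0]:
            raise SynthConfigError(
                "within-family e-values must sit strictly below background "
                "e-values (planted separation gap)"
            )


@dataclass
class FamilyTruth:
    """Planted family: who belongs to it, and which members are duplicates.

    ``duplication_groups`` maps a species to the subset of its members that
    were copied from one ancestor (base gene plus its duplicates); only
    species where duplication actually occurred appear.
    """

    family_id: str
    members: list[tuple[str, str]]  # (species, gene_id)
    duplication_groups: dict[str, list[str]] = field(default_factory=dict)

    def genes_in(self, species: str) -> list[str]:
        return [g for sp, g in self.members if sp == species]


def species_roster(n_species: int) -> list[str]:
    return [f"SP{i + 1}" for i in range(n_species)]


def simulate_families(config: SynthConfig) -> tuple[list[FamilyTruth], list[str]]:
    """Plant gene families across a species roster.

    Every family has exactly one base gene per species; with probability
    ``dup_rate`` per (family, species) the base gene is duplicated (1-2
    extra copies), and the base plus its copies form a duplication group.
    Deterministic for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    roster = species_roster(config.n_species)
    families = []
    for i in range(config.n_families):
        fam_id = f"FAM{i + 1:04d}"
        members: list[tuple[str, str]] = []
        dup_groups: dict[str, list[str]] = {}
        for sp in roster:
            base = f"{sp}_F{i + 1:04d}_g1"
            group = [base]
            if rng.random() < config.dup_rate:
                n_extra = int(rng.integers(1, 3))
                group += [f"{sp}_F{i + 1:04d}_g{j + 2}" for j in range(n_extra)]
                dup_groups[sp] = list(group)
            members += [(sp, g) for g in group]
        families.append(
            FamilyTruth(family_id=fam_id, members=members,
                        duplication_groups=dup_groups)
        )
    return families, roster


def n_duplication_groups(families: list[FamilyTruth], species: str) -> int:
    """Planted number of duplicated-gene networks for one species."""
    return sum(1 for f in families if species in f.duplication_groups)


def _log_uniform_evalue(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(lo, hi))


def _hit_row(rng, q: str, s: str, evalue: float) -> list:
    """One 12-column row with plausible filler alignment statistics."""
    if evalue > 0:
        bitscore = round(2.0 * -np.log10(evalue) + rng.uniform(0.0, 0.4), 1)
    else:
        bitscore = round(500.0 + rng.uniform(0.0, 50.0), 1)
    align_len = int(rng.integers(80, 600))
    identity = round(float(rng.uniform(30.0, 95.0)), 2)
    mism = int(align_len * (100.0 - identity) / 100.0)
    return [q, s, identity, align_len, mism, int(rng.integers(0, 5)),
            1, align_len, 1, align_len, evalue, bitscore]


def simulate_hit_table(
    families: list[FamilyTruth], config: SynthConfig
) -> HitTable:
    """Emit an all-vs-all style hit table for planted families.

    Within-family pairs get e-values from the within-family range in both
    directions (independently drawn, as real reciprocal searches give);
    self-hits are included at e-value 0; a ``background_fraction`` of
    cross-family gene pairs get background-range e-values.
    """
    rng = np.random.default_rng(config.seed + 1)
    w_lo, w_hi = config.within_family_evalue_range
    b_lo, b_hi = config.background_evalue_range
    rows: list[list] = []
    all_genes: list[str] = []
    species_of: dict[str, str] = {}
    family_of: dict[str, str] = {}
    for fam in families:
        fam_genes = [g for _, g in fam.members]
        for sp, g in fam.members:
            species_of[g] = sp
            family_of[g] = fam.family_id
        all_genes += fam_genes
        for q in fam_genes:
            rows.append(_hit_row(rng, q, q, 0.0))
            for s in fam_genes:
                if q != s:
                    rows.append(
                        _hit_row(rng, q, s, _log_uniform_evalue(rng, w_lo, w_hi))
                    )
    if config.background_fraction > 0:
        cross = [
            (q, s)
            for q in all_genes
            for s in all_genes
            if family_of[q] != family_of[s]
        ]
        n_bg = int(round(config.background_fraction * len(cross)))
        if n_bg > 0:
            idx = rng.choice(len(cross), size=n_bg, replace=False)
            for i in sorted(idx):
                q, s = cross[i]
                rows.append(
                    _hit_row(rng, q, s, _log_uniform_evalue(rng, b_lo, b_hi))
                )
    df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    return HitTable(df=df, species_of=species_of)


def simulate_goi_hits(
    families: list[FamilyTruth],
    config: SynthConfig,
    goi_names: Sequence[str] = ("ALKBH9B", "ALKBH10B", "MTB", "FIP37"),
) -> tuple[HitTable, dict[str, str]]:
    """Screening-style hit table: one query per GOI hits every member of one
    planted family (within-family e-values); remaining families stay unhit.

    Returns the hit table (queries as ``query_id``, transcripts as
    ``subject_id``) and the planted family -> GOI assignment used as ground
    truth. Requires at least as many families as GOI names.
    """
    if len(families) < len(goi_names):
        raise SynthConfigError("need at least one family per GOI")
    rng = np.random.default_rng(config.seed + 2)
    w_lo, w_hi = config.within_family_evalue_range
    chosen = rng.choice(len(families), size=len(goi_names), replace=False)
    rows: list[list] = []
    species_of: dict[str, str] = {}
    family_to_goi: dict[str, str] = {}
    for fam_idx, goi in zip(sorted(chosen), sorted(goi_names)):
        fam = families[fam_idx]
        query = f"Q{fam.family_id}_{goi}"
        species_of[query] = "query"
        family_to_goi[fam.family_id] = goi
        for sp, gene in fam.members:
            species_of[gene] = sp
            rows.append(
                _hit_row(rng, query, gene, _log_uniform_evalue(rng, w_lo, w_hi))
            )
    df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    return HitTable(df=df, species_of=species_of), family_to_goi


# ---------------------------------------------------------------------------
# qPCR Cq tables


@dataclass
class CqTruth:
    """Ground truth behind a simulated Cq table.

    All quantities are in cycles. ``treatment_effects`` maps
    (gene, condition) to a Cq shift relative to the control condition
    (negative shift = higher expression). ``efficiencies`` are fold
    amplification per cycle in (1, 2].
    """

    gene_baselines: dict[str, float]
    noise_sd: dict[str, float]
    conditions: list[str]
    treatment_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    efficiencies: dict[str, float] = field(default_factory=dict)
    loading_shift_sd: float = 0.3
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise SynthConfigError("noise SDs must be >= 0")
        if any(not 1.0 < e <= 2.0 for e in self.efficiencies.values()):
            raise SynthConfigError("efficiencies must be in (1, 2]")
        if len(self.conditions) < 1:
            raise SynthConfigError("at least one condition required")


def default_cq_truth() -> CqTruth:
    """Five candidate reference genes (two stable, three noisy) plus two
    target genes with planted treatment effects — the recovery scenario the
    stability methods are tested against (sigma 0.15 vs 0.9 cycles)."""
    genes_sd = {
        "RG_stable1": 0.15,
        "RG_stable2": 0.15,
        "RG_noisy1": 0.9,
        "RG_noisy2": 0.9,
        "RG_noisy3": 0.9,
        "TG_up": 0.2,
        "TG_down": 0.2,
    }
    baselines = {g: 22.0 + 2.0 * i for i, g in enumerate(genes_sd)}
    roles = {
        g: ("candidate_RG" if g.startswith("RG_") else "target")
        for g in genes_sd
    }
    return CqTruth(
        gene_baselines=baselines,
        noise_sd=genes_sd,
        conditions=["control", "treatment"],
        treatment_effects={
            ("TG_up", "treatment"): -3.0,
            ("TG_down", "treatment"): 2.0,
        },
        efficiencies={g: 2.0 for g in genes_sd},
        roles=roles,
    )


def simulate_cq_table(
    truth: CqTruth, n_samples_per_condition: int, seed: int
):
    """Simulate a genes x samples Cq table from additive truth.

    Cq(g, s) = baseline(g) + loading_shift(s) + effect(g, condition(s))
    + Normal(0, sd(g)). Returns a :class:`~m6ascreen.qpcr.CqTable`.
    """
    from .qpcr import CqTable

    if n_samples_per_condition < 1:
        raise SynthConfigError("n_samples_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(truth.gene_baselines)
    samples: list[str] = []
    condition: dict[str, str] = {}
    shifts: dict[str, float] = {}
    for cond in truth.conditions:
        for r in range(n_samples_per_condition):
            name = f"{cond}_{r + 1}"
            samples.append(name)
            condition[name] = cond
            shifts[name] = (
                float(rng.normal(0.0, truth.loading_shift_sd))
                if truth.loading_shift_sd > 0
                else 0.0
            )
    data = np.empty((len(genes), len(samples)))
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            mu = (
                truth.gene_baselines[g]
                + shifts[s]
                + truth.treatment_effects.get((g, condition[s]), 0.0)
            )
            sd = truth.noise_sd[g]
            data[i, j] = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    cq = pd.DataFrame(data, index=genes, columns=samples)
    return CqTable(
        cq=cq,
        condition=condition,
        efficiency={g: truth.efficiencies.get(g, 2.0) for g in genes},
        role={g: truth.roles.get(g, "candidate_RG") for g in genes},
    )


# ---------------------------------------------------------------------------
# Growth series


@dataclass
class GrowthSeries:
    """Cell-density time series: times in days, densities in cells/mL."""

    times: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be positive")


def simulate_growth(
    rate: float,
    n0: float = 5000.0,
    days: int = 7,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> GrowthSeries:
    """Exponential growth N(t) = n0 * exp(rate*t) * (1 + eps),
    eps ~ Normal(0, noise_cv), sampled daily from t=0 to t=days.

    Defaults match a typical batch-culture setup: inoculation at 5000
    cells/mL, one count per day for a week.
    """
    if n0 <= 0:
        raise SynthConfigError("initial density must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0, days + 1, dtype=float)
    n = n0 * np.exp(rate * t)
    if noise_cv > 0:
        n = n * (1.0 + rng.normal(0.0, noise_cv, size=t.shape))
        n = np.clip(n, 1e-9, None)
    return GrowthSeries(times=t, densities=n)


# ---------------------------------------------------------------------------
# Writers (plain-text TSV, deterministic ordering)


def write_family_truth(families: list[FamilyTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tspecies\tgene_id\tin_duplication_group\n")
        for fam in families:
            for sp, g in fam.members:
                dup = "yes" if g in fam.duplication_groups.get(sp, []) else "no"
                fh.write(f"{fam.family_id}\t{sp}\t{g}\t{dup}\n")


def read_family_truth(path) -> list[FamilyTruth]:
    df = pd.read_csv(path, sep="\t")
    families = []
    for fam_id, grp in df.groupby("family_id", sort=True):
        members = [(r.species, r.gene_id) for r in grp.itertuples(index=False)]
        dup_groups: dict[str, list[str]] = {}
        for r in grp.itertuples(index=False):
            if r.in_duplication_group == "yes":
                dup_groups.setdefault(r.species, []).append(r.gene_id)
        families.append(
            FamilyTruth(family_id=fam_id, members=members,
                        duplication_groups=dup_groups)
        )
    return families


def write_growth_series(series: GrowthSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_days\tcells_per_ml\n")
        for t, n in zip(series.times, series.densities):
            fh.write(f"{t:.6g}\t{n:.6f}\n")


def read_growth_series(path) -> GrowthSeries:
    df = pd.read_csv(path, sep="\t")
    return GrowthSeries(
        times=df["time_days"].to_numpy(),
        densities=df["cells_per_ml"].to_numpy(),
    )
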