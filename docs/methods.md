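# Methods

`m6ascreen` implements a comparative-transcriptomics screen for
N6-methyladenosine (m6A) writer and eraser genes across microalgal species,
together with the RT-qPCR analyses used to follow their expression under
stress, and a ground-truthed synthetic-data generator that stands in for
study-scale sequencing and quantification-cycle data. This note records the
models, the defaults and why they were chosen, and what the synthetic checks
do and do not demonstrate.

## The screening pipeline

**ORF prediction (`orfs`).** Proteins are called from assembled transcripts
with three rules: (1) ATG-initiated open reading frames of at least
`min_aa_len` residues (default 100, the conventional de novo threshold that
keeps the false-positive rate down on kb-scale transcripts); (2) a candidate
entirely contained within a longer same-strand candidate is dropped; (3)
after external functional annotation, isoforms collapse to exactly one
protein per transcript — the one with the most distinct annotation
signatures, ties broken by protein length then id. Coding-potential scoring
(Markov/hexamer models as in TransDecoder) is deliberately not part of the
caller: the three stated rules fully determine the downstream inputs, and
annotation-count collapse already removes most spurious short calls. ORFs
are reported in 0-based half-open coordinates on the reported strand;
5'-partial ORFs (no ATG) are excluded by default since assembled transcripts
give no reliable start evidence. Both strands are scanned by default because
de novo assemblies are not consistently oriented. Ambiguous bases translate
to `X` and never open or close an ORF.

**Orthology (`homology.bbh_orthologs`).** Orthologs between two species are
bidirectional best hits (BBH) in the all-vs-all similarity search: gene *a*
and *b* pair iff each is the other's best hit, both within the working
e-value ceiling (default 1e-5). "Best" minimizes the e-value with
deterministic tie-breaks (higher bitscore, then lexicographic subject id).
BBH is the standard operational ortholog definition when synteny is
unavailable; its known limitation — one pair per species pair, so in-paralog
expansions attach via the paralog edges instead — is intended here.

**Paralogy threshold (`homology.paralog_threshold_scan`).** Within-species
paralog edges are gene pairs whose reciprocal hits pass an e-value cutoff
(either direction suffices; reciprocal searches are asymmetric and the union
is the deterministic permissive reading). The cutoff is not fixed a priori:
a grid of cutoffs is scanned and the one maximizing the number of
*duplicated-gene networks* — connected components of size >= 2 in the
within-species hit graph — is kept, ties resolved toward the most stringent
cutoff. The scan can run per species (default) or pooled across species
(component counts summed). Both modes ship because the choice is not
determined by the screening problem itself.

A subtlety of the tie rule: on data with a clean separation between
duplication-level and background e-values, *every* cutoff in the separation
gap attains the maximum, and so do most cutoffs below it (removing
within-duplication edges rarely splits a component into two countable
pieces). A grid extending far below the gap therefore ties its way down to
the grid floor. For the planted-gap analyses the grid is decades 1e-5 to
1e-40 (`synth.GAP_SCAN_GRID`): the floor sits inside the planted gap, the
scan still has to reject every background-range cutoff on its own merits,
and the result also exposes the full maximizing plateau
(`ThresholdScanResult.plateau`) so callers can assert the tie-rule-free
property directly. The general-purpose default grid remains 1e-5..1e-180.

**Networks (`networks`).** Ortholog pairs and paralog edges merge into one
undirected graph with typed edges; the type/species rule (ortholog edges
span species, paralog edges do not) is validated on construction. Connected
components are the gene-family networks; component numbering sorts by the
smallest member id so exports are reproducible byte-for-byte.

**GOI screening (`networks.screen_goi`).** Query sequences for the m6A
writers (MTA, MTB, FIP37, VIRILIZER, HAKAI) and erasers (ALKBH9B, ALKBH10B)
are searched against each transcript collection; the hit table is the input
here (the aligner itself is out of scope). Each transcript with a qualifying
hit (default cutoff 1e-5) is assigned to exactly one GOI — that of its
minimum-e-value query — since the screening question is presence/absence per
enzyme class, not multi-label homology. The GOI name is parsed from the
query-id suffix (`AT1G48980.1_ALKBH9B` -> ALKBH9B) or supplied explicitly.

**Presence and reconciliation (`networks.presence_matrix`, `genome`).**
Transcriptome presence is a GOI x species matrix (present iff >= 1 assigned
transcript, with transcript evidence per cell). Genome evidence comes from
spliced-alignment summaries of the query sequences against each species'
genome, filtered at a percent-identity cutoff, default 40 **inclusive** —
the cutoff is stated as "40%" without strictness and the published summary's
minimum retained value (40.4) cannot distinguish >= from >, so the inclusive
reading is fixed and explicit in config. Where a species has no public
genome a congeneric surrogate is used (*C. fusiformis* for *C. closterium*,
*T. striata* for *T. suecica*, and the *A. carterae* genome also answering
for the confamilial dinoflagellate *A. tamutum*); surrogate use is recorded
in per-cell provenance, since presence on a relative's genome is weaker
evidence. Reconciliation is cell-wise and total: transcriptome-present ->
`expressed`; transcriptome-absent but genome-present -> `genomic_only`
(read as "not expressed under the sampled culture conditions"); both absent
-> `absent`. One record per (query, genome) is kept (max identity), matching
how such summaries are reported.

The packaged tables (`m6ascreen/data/`) carry the published inventory of
writer/eraser transcripts in the four species and the published genome-scan
summary. Fed through the pipeline they reproduce the published pattern:
ALKBH9B expressed in all four species; ALKBH10B, MTB and FIP37 expressed
only in the two dinoflagellates and `genomic_only` in the diatom and green
alga; MTA, VIRILIZER and HAKAI `genomic_only` everywhere.

## The RT-qPCR arm (`qpcr`)

Quantities derive from Cq values via the efficiency model: one cycle
difference = E-fold template difference, E in (1, 2] per assay (default 2.0,
perfect doubling, used when assay efficiencies were not measured — reported
ratios then depend on that assumption). Relative quantities are
Q(g,s) = E_g^(minCq_g - Cq(g,s)), so each gene's best sample scores 1.

**Reference-gene stability.** Three standard estimators, each returning a
ranking (ascending = most stable) and a best pair:

* *BestKeeper-style*: sample SD of raw Cq per candidate (the reported
  statistic); the original tool's mean-absolute-deviation variant is
  available by flag. Simple, but blind to sample-wide loading shifts.
* *geNorm*: M_j = mean over partners k of SD_s[log2(Q_j/Q_k)], with
  stepwise exclusion of the max-M gene until two remain; the survivors share
  one M by symmetry and form the best pair. Invariant to per-gene constant
  shifts; requires >= 3 candidates.
* *NormFinder-style*: fit the additive model x(g,s) = gene effect + sample
  effect + residual on log2 quantities by row/column means; stability is the
  bias-corrected residual SD, sqrt(G/(G-1) * sum_s r^2 / (S-1)). Sample
  effects absorb loading shifts, so a gene is penalized only for variation
  the panel does not share. A grouped mode (conditions as groups) combines
  within-group residual SD with the centred between-group effect magnitude —
  a simplification of Andersen's full intra/inter-group decomposition that
  preserves the ranking behaviour in the regimes exercised here; note the
  full estimator's de-biasing is rank-invariant under a common contamination
  term, which is why the simpler form ranks identically.

The consensus pair is chosen by mean rank across methods (ties: most top-2
appearances, then lexicographic).

**Relative expression.** The point estimate is the classical
efficiency-corrected ratio E_t^dCq(t) / geomean_r E_r^dCq(r) with
dCq = mean Cq(control) - mean Cq(treatment), reported as log2. Significance
defaults to a two-sided two-sample Student's t-test on per-replicate
reference-normalized log2 expressions; a REST-style seeded permutation test
(condition labels reallocated, one-sided on |mean log effect|, add-one
corrected) is available by flag. With triplicates the permutation null has
only C(6,3) = 20 distinct splits, so its p-values are coarse by
construction — the t-test is the default for exactly this reason. If both
groups have zero replicate variance the p-value is degenerate (0 when the
means differ, 1 otherwise) and flagged with a warning. Stars follow the
usual 0.05 / 0.01 / 0.001 convention.

**Growth.** Net growth rate is the least-squares slope of ln(cell density)
against time (per day), with R²; a two-point window reduces to
ln(N1/N0)/dt. Densities must be positive; the fit window is caller-chosen.

## The synthetic-data generator (`synth`)

The generator plants exactly the structure each downstream method is
supposed to recover, at the score level rather than the sequence level:
e-values are drawn directly instead of mutating sequences and running an
aligner, which removes external-tool coupling while exercising every line of
the inference code. Bitscores are a strictly decreasing function of e-value
plus small jitter, preserving the rank relation best-hit logic uses.

Defaults (all surfaced in `SynthConfig`, chosen once as a plausible
four-species screen at desk scale): 4 species, 30 families, duplication
probability 0.4 per family per species (1-2 extra copies) — deliberately on
the high side, matching the heavy transcript redundancy of dinoflagellates;
within-family e-values log-uniform in [1e-180, 1e-50]; background (spurious
cross-family) e-values in [1e-8, 1e-1] on 5% of cross-family ordered pairs;
self-hits at e-value 0. The non-overlap of the two ranges is enforced: the
gap between them is the ground truth the threshold scan must find. At low
duplication rates (~0.3) a sparse background edge occasionally pairs two
singleton genes at a loose cutoff and beats the planted network count; at
0.4 merger events dominate and recovery was exact on 200/200 pilot seeds
before the test values were frozen.

Cq tables are additive: baseline(gene) + loading shift(sample, SD 0.3
cycles) + planted treatment effect(gene, condition) + Normal(0, SD(gene)).
The planted stability scenario is two stable candidates (SD 0.15 cycles)
against three unstable ones (SD 0.9), n = 9 — separations of this size are
what the stability literature treats as clearly distinguishable, and the
default expression scenario plants -3 and +2 cycle effects (8-fold up,
4-fold down at E = 2) on two target genes with triplicates. Growth series
are N(t) = n0 e^(rt) (1 + eps), eps ~ Normal(0, cv), daily for a week from
5000 cells/mL.

What the synthetic checks show: that the inference machinery recovers
planted structure exactly (orthologs, paralog networks, threshold, ORFs) or
at calibrated rates (stability rankings, effect sizes, growth rates, null
p-value uniformity). What they do not show: robustness to the things real
data add — assembly fragmentation and chimerism, alignment-score
idiosyncrasies, non-Gaussian Cq noise, inhibition-driven efficiency drift,
cross-hybridizing primers. Conclusions about real transcriptomes rest on the
published tables, which the pipeline reproduces cell-for-cell, not on the
simulations.

## Numerical and procedural choices

* All rankings, file outputs and component numberings are deterministically
  ordered (lexicographic or by statistic with explicit tie-breaks); fixed
  seeds give byte-identical outputs.
* Sample SDs use ddof=1 throughout.
* The e-value writer keeps 6 significant digits so hit tables round-trip
  losslessly at test tolerance.
* Degenerate inputs fail loudly (empty rosters, unmappable ids, identity
  outside [0,100], non-positive densities) rather than being coerced.
* Problem sizes in the test and acceptance layers (30-family tables, 50
  threshold seeds, 200 Monte-Carlo Cq simulations, 1000 null simulations)
  were chosen as the smallest sizes at which the stochastic criteria are
  stable, keeping the whole suite fast on one CPU.

## Known limitations

* BBH orthology ignores synteny and collapses many-to-many orthology onto
  best pairs; the paralog edges recover within-species expansions but
  out-paralogs across species appear only through shared components.
* The screening arm consumes similarity hit tables; nothing here validates
  the upstream aligner's sensitivity.
* The qPCR efficiencies default to 2.0; published fold changes produced with
  unstated efficiencies cannot be reproduced numerically, only structurally.
* The grouped NormFinder mode is a documented simplification, not the full
  Andersen estimator.
* Surrogate-genome presence (three of four species here) is suggestive, not
  conclusive, for the species of interest; the provenance flag exists so
  downstream readers never lose that caveat.
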