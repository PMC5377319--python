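# Methods

This note documents the statistical procedures implemented in
`refgenestab`, the modelling assumptions behind them, the defaults and why
they were chosen, and what the synthetic-data validation does and does not
establish.

## Data model

The unit of analysis is a *panel*: Cq measurements for G candidate
reference genes across N biological replicates of one (species, tissue),
each measured in R technical replicates. Technical replicates are combined
by the arithmetic mean of Cq — Cq is the log-domain quantity, so mean-of-Cq
corresponds to geometric-mean expression and matches the convention of the
established analysis tools. The technical SD (n−1 denominator) is kept per
cell; cells with technical SD above 0.5 cycles (configurable) are QC-flagged
but never dropped automatically. Non-detects are explicit missing values,
never Cq 40/45 sentinels: sentinel codes would masquerade as data in every
downstream SD. Valid Cq lies in (0, 45].

Downstream handling of missing cells is per-statistic: geNorm uses
pairwise-complete samples per gene pair and complete-case samples for
normalization factors; the BestKeeper Index uses only samples complete
across all candidates (and reports the excluded ones); NormFinder
mean-imputes per gene with the imputed fraction reported, because its
centering steps need a rectangular matrix.

## Relative quantification

Amplification efficiency comes from an ordinary least-squares fit of Cq on
log10 dilution; E = 10^(−1/slope) − 1, with R² the squared Pearson
correlation. Curves need ≥ 3 distinct dilutions; a non-negative slope marks
the curve invalid rather than producing a nonsense efficiency. Efficiency
is stored fractionally (e.g. 0.95), displayed as percent, and enters the
quantification as the amplification factor 1+E.

Relative quantities are rq_ij = (1+E_i)^(Cq_i,cal − Cq_ij). The default
calibrator is the per-gene minimum Cq (the maximum-expression sample), so
max rq = 1 per gene — the input convention of the geNorm tool family.
The choice is immaterial for geNorm (per-gene rescaling cancels in
log-ratios; asserted by a cross-module test) and shifts NormFinder input
only by per-gene constants, which its gene effect α_i absorbs. Per-gene
mean and named-sample calibrators are selectable. When no standard curve or
efficiency table is supplied the default is E = 1 (perfect doubling).
Efficiencies outside [0.6, 1.25] are flagged as implausible but used.

## geNorm

M_j is the arithmetic mean over all other candidates k of the sample SD of
log2(rq_j / rq_k). Log base 2 and the n−1 SD denominator are used for every
dispersion in the package; base and denominator rescale M and V jointly and
never change a ranking. Stepwise exclusion removes the largest-M gene until
two remain; those two are reported as a tied pair at rank 1–2, since the
pairwise criterion cannot separate them. Ties for exclusion (within 1e-12)
remove the gene latest in input order — an arbitrary but deterministic and
documented rule. Genes whose first-round M exceeds 1.5 carry an "unstable"
flag.

Normalization factors NF_n are per-sample geometric means of the n most
stable genes' rq; V_n/n+1 is the sample SD of log2(NF_n / NF_{n+1}) for
n = 2..G−1. The recommended gene count is the smallest n with V strictly
below the cutoff (default 0.15); a V exactly at the cutoff is not below it.
If no V clears the cutoff, the n at the minimum V is recommended and the
applied rule is recorded ("below cutoff" vs "lowest V fallback"; ties in
the fallback take the smallest n).

## NormFinder

The model is y_ij = α_i + β_j + ε_ij on y = log2 rq, with
Var(ε_ij) = σ_i². After per-sample centering z_ij = y_ij − mean_i(y_ij),
the per-gene variance s_i² over samples mixes all genes' variances:
E[s_i²] = σ_i²(G−2)/G + Σ_k σ_k²/G². Solving,

    Σσ² ≈ S = [G/(G−1)] Σ_i s_i²,      σ̂_i² = (s_i² − S/G²) · G/(G−2),

floored at zero (flagged when flooring occurs; possible at small N). The
stability value is σ̂_i, in log2-expression units. The unmixing requires
G ≥ 3 (division by G−2) and N ≥ 3. Consistency was checked on simulated
data: at N = 2000 the estimates sit within 10% of planted σ_i over the
0.1–0.8 log2-unit range.

The grouped variant estimates, per sample subgroup g, the within-group
σ̂_ig as above restricted to the group, and the interaction contrast
d̂_ig = (ȳ_ig· − ȳ_i··) − (ȳ_·g· − ȳ_···); stability is
mean_g(|d̂_ig| + σ̂_ig/√n_g). This additive combination omits the original
method's Bayesian shrinkage of d̂ — the shrinkage constants are a tuning
choice and the additive form preserves the ranking behaviour, which is what
is validated here; absolute grouped values are therefore not comparable to
the original add-in's, and with zero true group effect the grouped values
shrink toward 0 with group size (only the *ranking* converges on the
ungrouped one). Log base 2 is used (the original is ambivalent between
bases); rankings are base-invariant.

## BestKeeper

Works on untransformed Cq. Per gene: geometric and arithmetic mean, range,
dispersion and CV (= dispersion as a percent of the arithmetic mean).
The default dispersion dialect is the sample SD; the historical spreadsheet
computed a mean absolute deviation from the arithmetic mean, available as
the "mad" dialect. The BestKeeper Index is the per-sample geometric mean of
all candidates' Cq; each gene's Pearson r to the index (with a two-sided
t-test p on N−2 df, descriptive only — no multiplicity correction) measures
co-movement with the panel consensus. Ranking is by ascending dispersion,
ties broken by higher r then input order. Genes with dispersion above
1 cycle are flagged "inconsistent" (conventional heuristic, configurable),
never dropped.

## Consensus and overlap probabilities

Per tissue, each method's raw scores (M, σ̂, SD — all lower-is-stabler) are
z-standardised across genes with the sample SD (spreadsheet STDEV
convention; population-SD selectable). Standardisation makes the three
scales commensurable so their unweighted average is a meaningful composite;
a constant column yields all-zero z and a degeneracy flag. Genes are ranked
by ascending mean z with spreadsheet RANK semantics: tied values share the
minimum rank and the next rank is skipped. The per-gene geNorm score fed to
the consensus is the first-round M (every gene scored on the full panel);
the alternative, M at the exclusion step, is selectable — the tied final
pair shares its last-round M there. Top-k (default 3) lists include every
gene with rank ≤ k, so boundary ties spill over rather than being cut
arbitrarily.

The probability that k specified genes of G candidates all appear in a
uniformly random top-k′ subset is hypergeometric:
C(G−k, k′−k) / C(G, k′). For G = 9, k′ = 3 this gives 1/3, 1/12 and 1/84
for k = 1, 2, 3. Two experiments (e.g. the same tissue in two species) are
treated as independent selections, so the cross-experiment probability is
the square — 1/144 ≈ 0.0069 for two shared genes, 1/7056 ≈ 0.00014 for
three. No dependence correction is attempted; truly correlated biology
across experiments makes these p-values conservative statements of the
null, not of the alternative.

## Synthetic-data generator

Latent log2 expression y_ij = −base_i + δ_j + γ_{i,g(j)} + ε_ij with
δ_j ~ N(0, loading_sd²) (shared RNA-input/RT variation),
ε_ij ~ N(0, noise_sd_i²) (the planted per-gene instability) and optional
gene×group shifts γ. Observed Cq_ijr = −y_ij + η_ijr,
η ~ N(0, tech_sd²): one latent cycle is one two-fold change, i.e.
efficiency deviations are deliberately not simulated at the latent level —
they enter only through the quantification module, keeping recovery
analysis closed-form. Defaults: 9 genes with base Cq spread 16–30 cycles,
noise SDs spread 0.05–0.8 log2 units, loading_sd 0.5 log2 units, 10
biological replicates (8 for the pooled tissues: ovipositor, maxillary
palps, antennae), 3 technical replicates with tech_sd 0.15 cycles, and
per-gene efficiencies drawn uniformly in [0.901, 1.064] for the
quantification layer. All draws flow from one seed (study-level generation
spawns per-panel child streams), so panels regenerate bit-identically.

The generator emulates the additive structure all three algorithms assume,
which is precisely why it supports parameter-*recovery* testing — and why
passing those tests says nothing about model misspecification in real
data: no amplification inhibition, no non-detect mechanism, no
heavy-tailed or correlated biological noise, no primer-dimer artifacts.
Ranking-recovery results under technical noise remain interpretable
because the effective per-gene SD, sqrt(noise_sd² + tech_sd²/R), is a
monotone transform of the planted SD. Parameter-recovery runs for
NormFinder set tech_sd = 0 so that the planted ε SDs are exactly the
model's error SDs being estimated.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 200 random panels
(G ∈ 3–6, N ∈ 4–8) for brute-force geNorm equivalence at 1e-12 relative
tolerance; N = 2000 for NormFinder consistency (within 10%); 50 seeded
panels at N = 10 for ranking recovery (median Spearman against planted
order); exhaustive enumeration of all C(9,3) = 84 subsets for the overlap
probabilities. These sizes give stable medians and tight recovery bands
while keeping the whole suite's runtime in seconds.

## Known limitations

- The grouped NormFinder variant is ranking-faithful but not numerically
  identical to the original add-in (no shrinkage; see above).
- Which dispersion dialect a given historical BestKeeper analysis used can
  be ambiguous; both are provided, and mixed-dialect comparisons are the
  user's responsibility.
- p-values on BestKeeper correlations are descriptive; with nine candidate
  genes per panel, formal inference would need multiplicity handling.
- The cross-experiment overlap probability assumes independent selections;
  shared biology violates this in the direction of smaller true surprise.
- No vendor export parsing (RDML, thermal-cycler XML); input is plain
  CSV/TSV.
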