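# refgenestab

Reference-gene (housekeeping-gene) stability analysis for RT-qPCR.

Accurate relative quantification by RT-qPCR stands or falls with
normalisation: target-gene Cq values are divided by the expression of one
or more reference genes assumed stable across the samples. That assumption
routinely fails — a gene stable in one tissue or species drifts in another
— so candidate reference genes must be validated per experiment. This
package implements the three standard stability algorithms, a consensus
ranking that reconciles them, and the probability calculus for judging
whether two experiments agreeing on their top genes means anything. It is
aimed at molecular biologists running multi-tissue or multi-condition
RT-qPCR panels, and at anyone who wants these methods scriptable and
testable instead of locked in spreadsheet add-ins.

## What it computes

Given a long-format table of Cq values (one row per species / tissue /
gene / biological replicate / technical replicate):

- **Efficiency-corrected relative quantities.** From a dilution-series
  standard curve, amplification efficiency E = 10^(−1/slope) − 1; then
  rq = (1+E)^(Cq_cal − Cq), the efficiency-corrected 2^−ΔΔCt transform.
- **geNorm.** For gene *j*, M_j = mean over partners *k* of
  SD_samples[log2(rq_j/rq_k)]; stepwise exclusion of the largest-M gene
  ranks the candidates. Pairwise variation V_n/n+1 =
  SD[log2(NF_n/NF_{n+1})] between normalization factors (geometric means of
  the top n genes) picks how many genes to combine: the smallest n with
  V < 0.15, else the n with the lowest V.
- **NormFinder.** Under the additive model y_ij = α_i + β_j + ε_ij on log2
  expression with gene-specific Var(ε_ij) = σ_i², a method-of-moments
  unmixing of the per-sample-centered variances estimates each σ_i; the
  stability value is σ̂_i (a grouped variant adds inter-group differential
  expression).
- **BestKeeper.** Descriptive statistics on raw Cq: per-gene SD and CV, the
  BestKeeper Index (per-sample geometric mean of all candidates' Cq) and
  each gene's Pearson r to it; ranking by ascending SD.
- **Consensus.** The three raw scores (M, stability value, SD) are
  z-standardised across genes per tissue, averaged, and ranked
  (spreadsheet RANK tie semantics). Per-tissue top-3 lists across two
  species form a consensus key; the chance of k specific genes out of G
  candidates landing in a random top-k′ is hypergeometric,
  C(G−k, k′−k)/C(G, k′) — for 9 candidates and top-3: 1/3, 1/12, 1/84 for
  1, 2, 3 genes, squared for two independent experiments.
- **Synthetic panels.** A generator plants per-gene noise SDs, common
  loading shifts and technical noise under the same additive model, so
  every algorithm can be validated by parameter recovery against known
  ground truth.

## Worked example

Simulate a 9-gene, 10-replicate panel with planted instabilities and run
the full pipeline:

```sh
$ refgenestab simulate --seed 42 --out cq.tsv
wrote 270 rows to cq.tsv
$ refgenestab run cq.tsv --outdir out
analyzed 1 panel(s); artifacts under out
(sim_species, sim_tissue) top-3: tbp, GAPDH, RPL19
$ refgenestab genorm cq.tsv --outdir g_out
(sim_species, sim_tissue): combine 2 genes (below cutoff): RPL19, tbp
```

The generator's default planted noise SDs rise from 0.05 (RPL19) to 0.8
(actin3) log2 units, so the low-noise genes should — and do — surface at
the top. `out/sim_species__sim_tissue/consensus.tsv` holds the merged
ranking; its first rows:

```
gene    z_genorm  z_normfinder  z_bestkeeper  mean_z   final_rank
tbp     -1.073    -1.194        -0.768        -1.012   1
GAPDH   -1.028    -1.187        -0.739        -0.985   2
```

Negative z means more stable than the panel average on that method's
scale; `final_rank` orders genes by the mean of the three z-scores. The
geNorm recommendation ("combine 2 genes") comes from the first V_n/n+1
value under the 0.15 cutoff. Stage outputs (`genorm.tsv`, `genorm_v.tsv`,
`normfinder.tsv`, `bestkeeper.tsv`, `qc_report.txt`) land beside it; a
multi-panel input additionally produces the cross-tissue `key_table.tsv`
with shared-gene markings and `overlap.tsv` with the hypergeometric
probabilities.

The same operations are available as library functions
(`refgenestab.genorm.analyze`, `refgenestab.normfinder.ungrouped_stability`,
`refgenestab.bestkeeper.analyze`, `refgenestab.consensus.consensus_rank`,
...), which is what the CLI calls underneath.

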