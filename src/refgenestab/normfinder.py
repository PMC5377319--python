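"""NormFinder model-based stability analysis.

The method assumes an additive model on log expression,

    y_ij = alpha_i + beta_j + eps_ij,      Var(eps_ij) = sigma_i^2,

with gene effects alpha_i, sample (loading) effects beta_j and
gene-specific error variance sigma_i^2. A gene's stability value is the
estimated SD of its own error term: after per-sample centering
z_ij = y_ij - mean_over_genes(y_.j), the per-gene variance s_i^2 mixes
every gene's sigma^2; the method-of-moments unmixing is

    S_total     = G/(G-1) * sum_i s_i^2        (estimates sum_i sigma_i^2)
    sigma_i^2   = (s_i^2 - S_total/G^2) * G/(G-2)

floored at zero. The grouped variant adds, per sample subgroup g, the
estimated differential expression d_ig and combines |d_ig| with the
group-mean standard error. Log base 2 is used throughout; stability values
are therefore in log2-expression units (rankings are base-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .quantification import RQMatrix


def _log2_frame(rq) -> pd.DataFrame:
    frame = rq.rq if isinstance(rq, RQMatrix) else rq
    return np.log2(frame.astype(float))


@dataclass
class NormfinderResult:
    stability: dict[str, float]
    ranking: list[str]
    variant: str                                   # "ungrouped" | "grouped"
    floored: list[str] = field(default_factory=list)
    imputed_fraction: float = 0.0
    group_labels: list[str] | None = None
    intergroup: dict[tuple[str, str], float] | None = None


def _impute_gene_means(y: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Mean-impute missing log values per gene (centering needs a full grid)."""
    missing = y.isna()
    frac = float(missing.to_numpy().mean())
    if frac == 0.0:
        return y, 0.0
    filled = y.apply(lambda row: row.fillna(row.mean()), axis=1)
    if filled.isna().any().any():
        bad = list(filled.index[filled.isna().any(axis=1)])
        raise InsufficientDataError(f"gene(s) {bad} have no observed values")
    return filled, frac


def _residual_sds(y: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Unmix per-gene error SDs from per-sample-centered variances."""
    G = len(y.index)
    z = y - y.mean(axis=0)              # per-sample centering (beta_j removed)
    s2 = z.var(axis=1, ddof=1)          # per-gene variance over samples
    total = G / (G - 1) * s2.sum()
    sigma2 = (s2 - total / G**2) * G / (G - 2)
    floored = list(sigma2.index[sigma2 < 0])
    return np.sqrt(sigma2.clip(lower=0.0)), floored


def ungrouped_stability(rq) -> NormfinderResult:
    """Stability value per gene: estimated SD of its model error term.

    Needs >= 3 genes (the unmixing divides by G-2) and >= 3 samples.
    Missing values are mean-imputed per gene with the imputed fraction
    reported; stability is in log2 units, ranking sorts ascending.
    """
    y = _log2_frame(rq)
    G, N = y.shape
    if G < 3:
        raise ParameterError(f"NormFinder needs >= 3 genes (got {G})")
    if N < 3:
        raise InsufficientDataError(f"NormFinder needs >= 3 samples (got {N})")
    y, imputed = _impute_gene_means(y)
    sd, floored = _residual_sds(y)
    stability = {g: float(v) for g, v in sd.items()}
    ranking = sorted(stability, key=lambda g: (stability[g], list(y.index).index(g)))
    return NormfinderResult(stability, ranking, "ungrouped",
                            floored=floored, imputed_fraction=imputed)


def grouped_stability(rq, groups: list[str] | pd.Series) -> NormfinderResult:
    """Subgroup-aware stability combining intra- and inter-group variation.

    For each group g the per-gene residual SD sigma_ig is estimated as in
    the ungrouped model restricted to the group; the differential
    expression is the interaction contrast

        d_ig = (mean_ig. - mean_i..) - (mean_.g. - mean_...)

    and stability_i = mean over groups of |d_ig| + sigma_ig / sqrt(n_g).
    Small values mean the gene neither shifts between groups nor fluctuates
    within them.
    """
    y = _log2_frame(rq)
    G, N = y.shape
    if G < 3:
        raise ParameterError(f"NormFinder needs >= 3 genes (got {G})")
    labels = pd.Series(list(groups), index=y.columns, dtype=str)
    group_names = list(dict.fromkeys(labels))
    if len(group_names) < 2:
        raise ParameterError("grouped variant needs >= 2 groups")
    sizes = labels.value_counts()
    small = [g for g in group_names if sizes[g] < 2]
    if small:
        raise ParameterError(f"group(s) {small} have < 2 samples (need >= 2)")

    y, imputed = _impute_gene_means(y)
    grand = y.to_numpy().mean()
    gene_mean = y.mean(axis=1)
    floored: list[str] = []
    intergroup: dict[tuple[str, str], float] = {}
    per_group_terms = pd.DataFrame(index=y.index, columns=group_names, dtype=float)
    for g in group_names:
        cols = labels.index[labels == g]
        sub = y[cols]
        n_g = len(cols)
        if n_g >= 3:
            sigma, fl = _residual_sds(sub)
            floored.extend(f"{gene}:{g}" for gene in fl)
        else:
            sigma = pd.Series(0.0, index=y.index)
        group_mean = sub.to_numpy().mean()
        d = (sub.mean(axis=1) - gene_mean) - (group_mean - grand)
        for gene in y.index:
            intergroup[(gene, g)] = float(d[gene])
        per_group_terms[g] = d.abs() + sigma / np.sqrt(n_g)
    stability_series = per_group_terms.mean(axis=1)
    stability = {g: float(v) for g, v in stability_series.items()}
    order = {g: i for i, g in enumerate(y.index)}
    ranking = sorted(stability, key=lambda g: (stability[g], order[g]))
    return NormfinderResult(stability, ranking, "grouped", floored=floored,
                            imputed_fraction=imputed,
                            group_labels=list(labels), intergroup=intergroup)


def result_table(result: NormfinderResult) -> pd.DataFrame:
    rows = [{
        "gene": g,
        "stability_value": result.stability[g],
        "rank": i + 1,
        "variant": result.variant,
        "floored": g in result.floored,
        "imputed_fraction": result.imputed_fraction,
    } for i, g in enumerate(result.ranking)]
    return pd.DataFrame(rows).set_index("gene")
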