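"""BestKeeper descriptive statistics on raw Cq values.

Unlike geNorm and NormFinder, BestKeeper never leaves the Cq scale: each
candidate gene is summarised by the dispersion of its Cq values (sample SD
by default; the historical spreadsheet's mean-absolute-deviation dialect is
also available) and by its Pearson correlation to the BestKeeper Index —
the per-sample geometric mean of all candidates' Cq. Low dispersion and
high correlation mark a stable gene; ranking is by ascending dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cq_dataset import CqPanel
from .errors import InsufficientDataError, ParameterError

#: Genes with Cq dispersion above this many cycles are flagged inconsistent.
INCONSISTENT_SD_THRESHOLD = 1.0


@dataclass
class GeneStats:
    geo_mean_cq: float
    ar_mean_cq: float
    min_cq: float
    max_cq: float
    sd: float
    cv: float                       # percent of the arithmetic mean
    r_to_index: float | None = None
    p_value: float | None = None
    r_missing_reason: str | None = None


@dataclass
class BestkeeperResult:
    per_gene: dict[str, GeneStats]
    index: pd.Series                 # BestKeeper Index per complete sample
    ranking: list[str]
    dispersion_dialect: str
    excluded_samples: list[str] = field(default_factory=list)
    inconsistent: list[str] = field(default_factory=list)


def _dispersion(values: np.ndarray, dialect: str) -> float:
    if dialect == "sample_sd":
        return float(np.std(values, ddof=1))
    if dialect == "mad":
        return float(np.mean(np.abs(values - values.mean())))
    raise ParameterError(f"unknown dispersion dialect {dialect!r}")


def descriptive_stats(panel: CqPanel, dialect: str = "sample_sd") -> dict[str, GeneStats]:
    """Per-gene geometric/arithmetic mean, range, dispersion and CV on raw Cq."""
    out: dict[str, GeneStats] = {}
    for gene in panel.genes:
        values = panel.cq_mean.loc[gene].dropna().to_numpy(dtype=float)
        if len(values) < 2:
            raise InsufficientDataError(
                f"gene {gene}: {len(values)} sample(s), need >= 2")
        if (values <= 0).any():
            raise ParameterError(
                f"gene {gene}: non-positive Cq, geometric mean undefined")
        ar = float(values.mean())
        sd = _dispersion(values, dialect)
        out[gene] = GeneStats(
            geo_mean_cq=float(np.exp(np.mean(np.log(values)))),
            ar_mean_cq=ar,
            min_cq=float(values.min()),
            max_cq=float(values.max()),
            sd=sd,
            cv=100.0 * sd / ar,
        )
    return out


def bestkeeper_index(panel: CqPanel) -> tuple[pd.Series, list[str]]:
    """BI_j = geometric mean over candidate genes of Cq_ij.

    Only samples with Cq present for every gene contribute; the excluded
    sample labels are returned alongside.
    """
    cq = panel.cq_mean.astype(float)
    complete = cq.notna().all(axis=0)
    excluded = [s for s in panel.samples if not complete[s]]
    kept = cq.loc[:, complete]
    if kept.shape[1] == 0:
        raise InsufficientDataError("no sample has complete Cq across all genes")
    if (kept.to_numpy() <= 0).any():
        raise ParameterError("non-positive Cq, geometric mean undefined")
    bi = np.exp(np.log(kept).mean(axis=0))
    return bi, excluded


def correlation_to_index(panel: CqPanel, index: pd.Series) -> dict[str, tuple]:
    """Pearson r (and two-sided t-test p, N-2 df) of each gene's Cq vs BI."""
    out: dict[str, tuple] = {}
    for gene in panel.genes:
        paired = pd.concat(
            [panel.cq_mean.loc[gene], index], axis=1, join="inner").dropna()
        if len(paired) < 3:
            raise InsufficientDataError(
                f"gene {gene}: {len(paired)} complete sample(s), need >= 3")
        x = paired.iloc[:, 0].to_numpy(dtype=float)
        y = paired.iloc[:, 1].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[gene] = (None, None, "zero variance in gene Cq or index")
            continue
        r, p = stats.pearsonr(x, y)
        out[gene] = (float(r), float(p), None)
    return out


def rank_by_dispersion(per_gene: dict[str, GeneStats], gene_order: list[str]) -> list[str]:
    """Ascending dispersion; ties broken by higher r, then input order."""
    order = {g: i for i, g in enumerate(gene_order)}

    def key(gene: str):
        st = per_gene[gene]
        r = st.r_to_index if st.r_to_index is not None else -np.inf
        return (st.sd, -r, order[gene])

    return sorted(per_gene, key=key)


def analyze(panel: CqPanel, dialect: str = "sample_sd",
            inconsistent_sd: float = INCONSISTENT_SD_THRESHOLD) -> BestkeeperResult:
    """Full BestKeeper pass: stats, index, correlations, ranking, flags."""
    per_gene = descriptive_stats(panel, dialect)
    bi, excluded = bestkeeper_index(panel)
    correlations = correlation_to_index(panel, bi)
    for gene, (r, p, reason) in correlations.items():
        per_gene[gene].r_to_index = r
        per_gene[gene].p_value = p
        per_gene[gene].r_missing_reason = reason
    ranking = rank_by_dispersion(per_gene, panel.genes)
    inconsistent = [g for g, st in per_gene.items() if st.sd > inconsistent_sd]
    return BestkeeperResult(per_gene, bi, ranking, dialect,
                            excluded_samples=excluded, inconsistent=inconsistent)


def result_table(result: BestkeeperResult) -> pd.DataFrame:
    rows = []
    for rank, gene in enumerate(result.ranking, start=1):
        st = result.per_gene[gene]
        rows.append({
            "gene": gene,
            "geo_mean": st.geo_mean_cq,
            "ar_mean": st.ar_mean_cq,
            "min": st.min_cq,
            "max": st.max_cq,
            "sd": st.sd,
            "cv_percent": st.cv,
            "r": st.r_to_index,
            "p": st.p_value,
            "rank": rank,
            "inconsistent": gene in result.inconsistent,
        })
    return pd.DataFrame(rows).set_index("gene")
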