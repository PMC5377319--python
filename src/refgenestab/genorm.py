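"""geNorm stability analysis.

The method rests on one idea: the log-transformed expression ratio between
two stably expressed genes is constant across samples. For each gene j the
stability measure M_j is the mean, over all other candidates k, of the
sample SD of log2(rq_j / rq_k). Stepwise exclusion of the gene with the
largest M yields a ranking (the final two genes cannot be separated).
Pairwise variation V_n/n+1 between normalization factors built from the n
and n+1 most stable genes decides how many genes to combine: the smallest n
with V < 0.15, else the n at the lowest V.

All SDs use the n-1 denominator and log base 2; both choices rescale M and
V jointly and never change a ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .quantification import RQMatrix

#: Genes with first-round M above this are conventionally deemed unstable.
UNSTABLE_M_THRESHOLD = 1.5

#: Default pairwise-variation cutoff for the recommended gene count.
DEFAULT_V_CUTOFF = 0.15

_TIE_EPS = 1e-12


def _as_frame(rq) -> pd.DataFrame:
    if isinstance(rq, RQMatrix):
        return rq.rq
    return rq


@dataclass
class GenormResult:
    """Full output of the stepwise geNorm analysis."""

    ranking: list[str]                       # most to least stable
    final_pair: tuple[str, str]              # tied at rank 1-2
    m_trace: list[dict[str, float]]          # per exclusion round, remaining-gene M
    excluded: list[str]                      # exclusion order (least stable first)
    first_round_m: dict[str, float]
    m_at_exclusion: dict[str, float]
    unstable: list[str]                      # first-round M > threshold
    v_series: list[tuple[int, float]] = field(default_factory=list)
    recommended_n: int | None = None
    rule_applied: str | None = None
    cutoff_used: float = DEFAULT_V_CUTOFF

    @property
    def recommended_genes(self) -> list[str]:
        if self.recommended_n is None:
            return []
        return self.ranking[: self.recommended_n]


def pairwise_log_ratio_sd(rq, gene_a: str, gene_b: str) -> float:
    """Sample SD over samples of log2(rq_a / rq_b), pairwise-complete."""
    frame = _as_frame(rq)
    a = frame.loc[gene_a].astype(float)
    b = frame.loc[gene_b].astype(float)
    ratio = np.log2(a / b).dropna()
    if len(ratio) < 2:
        raise InsufficientDataError(
            f"pair ({gene_a}, {gene_b}): {len(ratio)} complete sample(s), need >= 2")
    return float(ratio.std(ddof=1))


def m_values(rq, gene_subset: list[str] | None = None) -> dict[str, float]:
    """M_j = mean over k != j of the pairwise log-ratio SD within the subset."""
    frame = _as_frame(rq)
    genes = list(gene_subset) if gene_subset is not None else list(frame.index)
    if len(genes) < 2:
        raise InsufficientDataError("M values need >= 2 genes")
    log = np.log2(frame.loc[genes].astype(float))
    out: dict[str, float] = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            diff = (log.loc[j] - log.loc[k]).dropna()
            if len(diff) < 2:
                raise InsufficientDataError(
                    f"pair ({j}, {k}): {len(diff)} complete sample(s), need >= 2")
            sds.append(diff.std(ddof=1))
        out[j] = float(np.mean(sds))
    return out


def stepwise_ranking(rq) -> GenormResult:
    """Iteratively drop the gene with the largest M until two remain.

    Ties for the largest M (within 1e-12) exclude the gene latest in input
    order; the rule is recorded implicitly by the trace. The surviving pair
    is reported tied at rank 1-2, ordered by input order.
    """
    frame = _as_frame(rq)
    genes = list(frame.index)
    if len(genes) < 3:
        raise InsufficientDataError("stepwise ranking needs >= 3 genes")
    input_pos = {g: i for i, g in enumerate(genes)}

    remaining = list(genes)
    m_trace: list[dict[str, float]] = []
    excluded: list[str] = []
    m_at_exclusion: dict[str, float] = {}
    first_round = m_values(frame, remaining)
    while len(remaining) > 2:
        ms = m_values(frame, remaining) if len(remaining) < len(genes) else dict(first_round)
        m_trace.append(ms)
        worst_m = max(ms.values())
        tied = [g for g, m in ms.items() if worst_m - m <= _TIE_EPS]
        drop = max(tied, key=lambda g: input_pos[g])
        m_at_exclusion[drop] = ms[drop]
        excluded.append(drop)
        remaining.remove(drop)
    final_ms = m_values(frame, remaining)
    m_trace.append(final_ms)
    pair = tuple(sorted(remaining, key=lambda g: input_pos[g]))
    for g in pair:
        m_at_exclusion[g] = final_ms[g]  # shared last-round M
    ranking = list(pair) + list(reversed(excluded))
    unstable = [g for g, m in first_round.items() if m > UNSTABLE_M_THRESHOLD]
    return GenormResult(
        ranking=ranking,
        final_pair=pair,
        m_trace=m_trace,
        excluded=excluded,
        first_round_m=first_round,
        m_at_exclusion=m_at_exclusion,
        unstable=unstable,
    )


def normalization_factor(rq, genes: list[str], n: int) -> pd.Series:
    """NF_n per sample: geometric mean of the n most stable genes' rq.

    Samples missing any contributing gene get a missing NF.
    """
    frame = _as_frame(rq)
    if not (2 <= n <= len(genes)):
        raise ParameterError(f"n = {n} outside [2, {len(genes)}]")
    sub = np.log2(frame.loc[genes[:n]].astype(float))
    nf_log = sub.mean(axis=0, skipna=False)  # complete-case across genes
    return np.exp2(nf_log)


def pairwise_variation_series(rq, ranking: list[str]) -> list[tuple[int, float]]:
    """V_n/n+1 = sample SD of log2(NF_n / NF_{n+1}) for n = 2 .. G-1."""
    frame = _as_frame(rq)
    G = len(ranking)
    series: list[tuple[int, float]] = []
    for n in range(2, G):
        nf_n = normalization_factor(frame, ranking, n)
        nf_n1 = normalization_factor(frame, ranking, n + 1)
        ratio = np.log2(nf_n / nf_n1).dropna()
        if len(ratio) < 2:
            raise InsufficientDataError(
                f"V_{n}/{n + 1}: {len(ratio)} complete sample(s), need >= 2")
        series.append((n, float(ratio.std(ddof=1))))
    return series


def recommend_gene_count(
    v_series: list[tuple[int, float]],
    cutoff: float = DEFAULT_V_CUTOFF,
) -> tuple[int, str]:
    """Smallest n with V_n/n+1 strictly below the cutoff; else lowest-V n.

    Returns (recommended_n, rule_applied) where rule_applied is
    "below cutoff" or "lowest V fallback". A V exactly at the cutoff is not
    below it.
    """
    if not v_series:
        raise InsufficientDataError("empty pairwise-variation series")
    for n, v in v_series:
        if v < cutoff:
            return n, "below cutoff"
    n_min = min(v_series, key=lambda item: (item[1], item[0]))[0]
    return n_min, "lowest V fallback"


def analyze(rq, cutoff: float = DEFAULT_V_CUTOFF) -> GenormResult:
    """Run the full geNorm pipeline: ranking, V series, recommendation."""
    result = stepwise_ranking(rq)
    result.v_series = pairwise_variation_series(rq, result.ranking)
    result.recommended_n, result.rule_applied = recommend_gene_count(
        result.v_series, cutoff)
    result.cutoff_used = cutoff
    return result


def result_table(result: GenormResult) -> pd.DataFrame:
    """Per-gene TSV-ready table: first-round M, exclusion step, rank."""
    rows = []
    step_of = {g: i + 1 for i, g in enumerate(result.excluded)}
    for rank_pos, gene in enumerate(result.ranking, start=1):
        rank = 1 if gene in result.final_pair else rank_pos
        rows.append({
            "gene": gene,
            "M_first_round": result.first_round_m[gene],
            "M_at_exclusion": result.m_at_exclusion[gene],
            "exclusion_step": step_of.get(gene, 0),
            "rank": rank,
            "unstable": gene in result.unstable,
        })
    return pd.DataFrame(rows).set_index("gene")
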