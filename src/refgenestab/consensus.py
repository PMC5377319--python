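"""Consensus ranking of stability scores and top-k overlap probabilities.

The three stability algorithms score on incommensurable scales (geNorm M,
NormFinder stability value, BestKeeper SD — all "lower is more stable").
Per tissue, each score column is standardised to a z-score across genes,
the three z-scores are averaged, and genes are ranked ascending by the mean
z with spreadsheet RANK tie semantics (ties share the minimum rank; the
following rank is skipped). The top-k genes per tissue form a consensus
key; whether the same genes surface in two independent experiments more
often than chance is assessed with hypergeometric probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

DEFAULT_TOP_K = 3


@dataclass
class ConsensusKey:
    """Per-tissue merged ranking (the per-row analogue of a consensus table)."""

    species: str
    tissue: str
    per_gene: pd.DataFrame     # z_genorm, z_normfinder, z_bestkeeper, mean_z, final_rank
    top_k: list[str]
    k: int
    degenerate_columns: list[str] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        return list(self.per_gene.sort_values(
            ["final_rank", "_input_order"]).index)


@dataclass
class OverlapAssessment:
    n_candidates: int
    k_top: int
    shared_genes: frozenset
    p_single_experiment: float
    p_cross_experiment: float


def zscore_column(values: dict[str, float], ddof: int = 1) -> tuple[dict[str, float], bool]:
    """Standardise one score column across genes; sample SD by default.

    Returns (z, degenerate): a constant column yields all-zero z with the
    degenerate flag set.
    """
    if len(values) < 2:
        raise ParameterError("z-scores need >= 2 genes")
    arr = np.array([float(v) for v in values.values()])
    if not np.isfinite(arr).all():
        bad = [g for g, v in values.items() if not np.isfinite(float(v))]
        raise ValidationError(f"non-finite score(s) for gene(s) {bad}")
    sd = arr.std(ddof=ddof)
    if sd == 0:
        return {g: 0.0 for g in values}, True
    mean = arr.mean()
    return {g: float((float(v) - mean) / sd) for g, v in values.items()}, False


def _rank_min(values: pd.Series) -> pd.Series:
    """Spreadsheet RANK semantics: ties share the minimum rank, next skipped."""
    return values.rank(method="min", ascending=True).astype(int)


def consensus_rank(
    genorm_m: dict[str, float],
    normfinder_stability: dict[str, float],
    bestkeeper_sd: dict[str, float],
    species: str = "",
    tissue: str = "",
    k: int = DEFAULT_TOP_K,
    ddof: int = 1,
) -> ConsensusKey:
    """Average the three per-gene z-scores and rank ascending.

    All three maps must score the identical gene set. ``top_k`` lists every
    gene with final rank <= k (ties at the boundary spill over), most
    stable first.
    """
    gene_sets = [set(genorm_m), set(normfinder_stability), set(bestkeeper_sd)]
    if not (gene_sets[0] == gene_sets[1] == gene_sets[2]):
        union = set.union(*gene_sets)
        inter = set.intersection(*gene_sets)
        raise ValidationError(
            f"gene sets differ between methods; symmetric difference {sorted(union - inter)}")
    genes = list(genorm_m)
    z_g, deg_g = zscore_column(genorm_m, ddof=ddof)
    z_n, deg_n = zscore_column(normfinder_stability, ddof=ddof)
    z_b, deg_b = zscore_column(bestkeeper_sd, ddof=ddof)
    frame = pd.DataFrame({
        "z_genorm": [z_g[g] for g in genes],
        "z_normfinder": [z_n[g] for g in genes],
        "z_bestkeeper": [z_b[g] for g in genes],
    }, index=pd.Index(genes, name="gene"))
    frame["mean_z"] = frame.mean(axis=1)
    frame["final_rank"] = _rank_min(frame["mean_z"])
    frame["_input_order"] = range(len(genes))
    top = list(frame[frame["final_rank"] <= k]
               .sort_values(["final_rank", "_input_order"]).index)
    degenerate = [name for name, deg in
                  (("z_genorm", deg_g), ("z_normfinder", deg_n), ("z_bestkeeper", deg_b))
                  if deg]
    return ConsensusKey(species, tissue, frame, top, k, degenerate)


def top_k_overlap_probability(n_candidates: int, k_top: int, k_specified: int) -> float:
    """P that ``k_specified`` given genes all land in a random top-``k_top``.

    Hypergeometric: C(n - k_spec, k_top - k_spec) / C(n, k_top). With 9
    candidates and a top-3, one specified gene appears with probability 1/3,
    two with 1/12 and three with 1/84.
    """
    if not (0 <= k_specified <= k_top <= n_candidates):
        raise ParameterError(
            f"need 0 <= k_specified ({k_specified}) <= k_top ({k_top}) "
            f"<= n_candidates ({n_candidates})")
    return math.comb(n_candidates - k_specified, k_top - k_specified) / math.comb(
        n_candidates, k_top)


def cross_experiment_overlap(
    n_candidates: int, k_top: int, shared: set[str] | frozenset
) -> OverlapAssessment:
    """Probability of one experiment's shared genes appearing in another's
    top-k, treating the two selections as independent (p_cross = p_single^2)."""
    shared = frozenset(shared)
    if len(shared) > k_top:
        raise ParameterError(f"|shared| = {len(shared)} exceeds k_top = {k_top}")
    p_single = top_k_overlap_probability(n_candidates, k_top, len(shared))
    return OverlapAssessment(n_candidates, k_top, shared, p_single, p_single**2)


@dataclass
class ConsensusTable:
    """Cross-tissue key: per tissue and species the top-k genes, with genes
    shared between both species in the same tissue marked."""

    frame: pd.DataFrame                    # rows tissue, columns species -> gene list
    shared: dict[str, set[str]]            # tissue -> genes shared across species
    frequency: pd.DataFrame                # gene x species counts in top-k
    k: int


def build_consensus_table(keys: list[ConsensusKey], k: int = DEFAULT_TOP_K) -> ConsensusTable:
    """Assemble per-tissue ConsensusKeys into the two-species key table."""
    seen = set()
    for key in keys:
        if (key.species, key.tissue) in seen:
            raise ValidationError(
                f"duplicate ConsensusKey for ({key.species}, {key.tissue})")
        seen.add((key.species, key.tissue))
    species = list(dict.fromkeys(key.species for key in keys))
    tissues = list(dict.fromkeys(key.tissue for key in keys))
    by_key = {(key.species, key.tissue): key for key in keys}

    cells: dict[str, dict[str, list[str]]] = {t: {} for t in tissues}
    shared: dict[str, set[str]] = {}
    for tissue in tissues:
        tops = {}
        for sp in species:
            key = by_key.get((sp, tissue))
            tops[sp] = key.top_k[:] if key is not None else []
            cells[tissue][sp] = tops[sp]
        present = [set(t) for t in tops.values() if t]
        shared[tissue] = set.intersection(*present) if len(present) >= 2 else set()

    frame = pd.DataFrame(
        {sp: {t: ", ".join(cells[t][sp]) for t in tissues} for sp in species})
    frame.index.name = "tissue"

    genes = sorted({g for key in keys for g in key.per_gene.index})
    freq = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=species)
    for key in keys:
        for g in key.top_k:
            freq.loc[g, key.species] += 1
    return ConsensusTable(frame, shared, freq, k)


def render_consensus_table(table: ConsensusTable) -> str:
    """Plain-text rendering; genes shared across species are starred."""
    lines = ["tissue\t" + "\t".join(table.frame.columns)]
    for tissue in table.frame.index:
        cells = []
        for sp in table.frame.columns:
            genes = [g.strip() for g in table.frame.loc[tissue, sp].split(",") if g.strip()]
            cells.append(", ".join(
                f"{g}*" if g in table.shared[tissue] else g for g in genes))
        lines.append(tissue + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def key_table(key: ConsensusKey) -> pd.DataFrame:
    """TSV-ready per-tissue consensus table sorted by final rank."""
    out = key.per_gene.sort_values(["final_rank", "_input_order"]).drop(
        columns="_input_order")
    return out
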