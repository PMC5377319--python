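"""Synthetic Cq panels with planted stability structure.

The generator mirrors the additive model the stability algorithms assume.
Latent log2 expression for gene i in biological sample j is

    y_ij = -base_cq_i + delta_j + gamma_{i, g(j)} + eps_ij

with a common per-sample loading shift delta_j ~ N(0, loading_sd^2)
(RNA input / RT-efficiency variation that good normalisation removes),
optional gene-by-group effects gamma, and gene-specific biological noise
eps_ij ~ N(0, noise_sd_i^2) — the planted instability. Observed technical
replicates are Cq_ijr = -y_ij + eta_ijr, eta ~ N(0, tech_sd^2): one latent
cycle equals one two-fold expression change. The true stability order
(genes sorted by noise SD) is returned for parameter-recovery tests.

Defaults emulate a 9-gene, 13-tissue, two-species RT-qPCR validation
design: 10 biological replicates per tissue (8 for pooled tissues:
ovipositor, maxillary palps, antennae), 3 technical replicates, base Cq
spread over 16-30 cycles, amplification efficiencies in the 90.1-106.4%
range for the quantification layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cq_dataset import CqPanel, PanelCollection, aggregate_technical_replicates
from .errors import ParameterError

DEFAULT_GENES = [
    "RPL19", "tbp", "ubx", "GAPDH", "a-TUB", "b-TUB",
    "14-3-3zeta", "RPE", "actin3",
]

#: Biological-replicate counts per tissue in the emulated design.
TISSUE_REPLICATES = {
    "egg": 10, "larva": 10, "pupa": 10,
    "head": 10, "thorax": 10, "abdomen": 10,
    "MAGs": 10, "testes": 10, "FAGs": 10, "ovaries": 10,
    "ovipositor": 8, "maxillary_palps": 8, "antennae": 8,
}

DEFAULT_EFFICIENCY_RANGE = (0.901, 1.064)


@dataclass
class SimConfig:
    """Parameters of one synthetic panel; all SDs in log2 units except
    ``tech_sd`` (cycles — numerically the same scale, one cycle = one
    two-fold change)."""

    n_genes: int = 9
    gene_labels: list[str] | None = None
    gene_base_cq: np.ndarray | None = None        # default spread 16-30 cycles
    gene_noise_sd: np.ndarray | None = None       # default spread 0.05-0.8
    loading_sd: float = 0.5
    n_bio: int = 10
    n_tech: int = 3
    tech_sd: float = 0.15
    group_labels: list[str] | None = None         # per biological sample
    group_effects: dict[tuple[str, str], float] | None = None
    efficiency_range: tuple[float, float] = DEFAULT_EFFICIENCY_RANGE
    seed: int = 0
    species: str = "sim_species"
    tissue: str = "sim_tissue"

    def resolved(self) -> "SimConfig":
        """Fill derived defaults and validate."""
        cfg = replace(self)
        if cfg.n_genes < 1 or cfg.n_bio < 1 or cfg.n_tech < 1:
            raise ParameterError("counts must be >= 1")
        if cfg.gene_labels is None:
            base = DEFAULT_GENES if cfg.n_genes <= len(DEFAULT_GENES) else [
                f"gene{i + 1}" for i in range(cfg.n_genes)]
            cfg.gene_labels = list(base[: cfg.n_genes])
        if len(cfg.gene_labels) != cfg.n_genes:
            raise ParameterError("gene_labels length != n_genes")
        if cfg.gene_base_cq is None:
            cfg.gene_base_cq = np.linspace(16.0, 30.0, cfg.n_genes)
        cfg.gene_base_cq = np.asarray(cfg.gene_base_cq, dtype=float)
        if cfg.gene_noise_sd is None:
            cfg.gene_noise_sd = np.linspace(0.05, 0.8, cfg.n_genes)
        cfg.gene_noise_sd = np.asarray(cfg.gene_noise_sd, dtype=float)
        if (cfg.gene_noise_sd < 0).any() or cfg.loading_sd < 0 or cfg.tech_sd < 0:
            raise ParameterError("SDs must be >= 0")
        lo, hi = cfg.efficiency_range
        if not (0 < lo <= hi < 2):
            raise ParameterError("efficiency interval must sit inside (0, 2)")
        if cfg.group_labels is not None and len(cfg.group_labels) != cfg.n_bio:
            raise ParameterError("group_labels length != n_bio")
        return cfg


@dataclass
class SimTruth:
    """Ground truth behind one generated panel."""

    config: SimConfig
    loading_shifts: np.ndarray                 # per sample (log2)
    noise: np.ndarray                          # genes x samples (log2)
    true_stability_order: list[str]            # noise SD ascending
    efficiencies: dict[str, float] = field(default_factory=dict)

    def noise_sd_of(self, gene: str) -> float:
        i = self.config.gene_labels.index(gene)
        return float(self.config.gene_noise_sd[i])


def generate_panel(config: SimConfig, rng: np.random.Generator | None = None
                   ) -> tuple[CqPanel, SimTruth]:
    """Simulate one tissue panel; fully reproducible from ``config.seed``.

    Technical replicates are drawn individually and aggregated through the
    same path real data takes (mean of tech Cq, technical SD recorded).
    """
    cfg = config.resolved()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    G, N, R = cfg.n_genes, cfg.n_bio, cfg.n_tech
    samples = [f"bio{j + 1}" for j in range(N)]

    delta = rng.normal(0.0, cfg.loading_sd, size=N)
    eps = rng.normal(0.0, 1.0, size=(G, N)) * cfg.gene_noise_sd[:, None]
    gamma = np.zeros((G, N))
    if cfg.group_effects and cfg.group_labels is not None:
        for i, gene in enumerate(cfg.gene_labels):
            for j, grp in enumerate(cfg.group_labels):
                gamma[i, j] = cfg.group_effects.get((gene, grp), 0.0)
    y = -cfg.gene_base_cq[:, None] + delta[None, :] + gamma + eps
    eta = rng.normal(0.0, cfg.tech_sd, size=(G, N, R))
    cq = -y[:, :, None] + eta

    rows = []
    for i, gene in enumerate(cfg.gene_labels):
        for j, sample in enumerate(samples):
            for r in range(R):
                rows.append({"gene": gene, "bio_replicate": sample,
                             "cq_value": cq[i, j, r]})
    long = pd.DataFrame(rows)
    panel = aggregate_technical_replicates(long, species=cfg.species,
                                           tissue=cfg.tissue)
    lo, hi = cfg.efficiency_range
    eff = {g: float(e) for g, e in
           zip(cfg.gene_labels, rng.uniform(lo, hi, size=G))}
    order = [cfg.gene_labels[i]
             for i in np.argsort(cfg.gene_noise_sd, kind="stable")]
    truth = SimTruth(cfg, delta, eps, order, eff)
    return panel, truth


def panel_to_raw_long(config: SimConfig) -> pd.DataFrame:
    """Long table with individual technical replicates, default dialect."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    G, N, R = cfg.n_genes, cfg.n_bio, cfg.n_tech
    delta = rng.normal(0.0, cfg.loading_sd, size=N)
    eps = rng.normal(0.0, 1.0, size=(G, N)) * cfg.gene_noise_sd[:, None]
    gamma = np.zeros((G, N))
    if cfg.group_effects and cfg.group_labels is not None:
        for i, gene in enumerate(cfg.gene_labels):
            for j, grp in enumerate(cfg.group_labels):
                gamma[i, j] = cfg.group_effects.get((gene, grp), 0.0)
    y = -cfg.gene_base_cq[:, None] + delta[None, :] + gamma + eps
    eta = rng.normal(0.0, cfg.tech_sd, size=(G, N, R))
    cq = -y[:, :, None] + eta
    rows = []
    for i, gene in enumerate(cfg.gene_labels):
        for j in range(N):
            for r in range(R):
                rows.append({
                    "species": cfg.species, "tissue": cfg.tissue, "gene": gene,
                    "bio_rep": f"bio{j + 1}", "tech_rep": f"tech{r + 1}",
                    "cq": repr(float(cq[i, j, r])),
                })
    return pd.DataFrame(rows)


def generate_study(
    base_config: SimConfig | None = None,
    species: tuple[str, str] = ("speciesA", "speciesB"),
    tissues: list[str] | None = None,
    shared_stable_genes: set[str] | frozenset = frozenset(),
    stable_sd: float = 0.05,
    noise_sd_range: tuple[float, float] = (0.1, 0.8),
    seed: int = 0,
) -> tuple[PanelCollection, dict[tuple[str, str], SimTruth]]:
    """Simulate a two-species, multi-tissue study with a shared gene set.

    Genes in ``shared_stable_genes`` get noise SD ``stable_sd`` in every
    panel of both species; the remaining genes draw iid noise SDs from
    ``noise_sd_range`` independently per panel, so with an empty shared set
    top-k membership is exchangeable across genes and panels.
    """
    base = (base_config or SimConfig()).resolved()
    if tissues is None:
        tissues = list(TISSUE_REPLICATES)
    unknown = shared_stable_genes - set(base.gene_labels)
    if unknown:
        raise ParameterError(f"shared stable gene(s) {sorted(unknown)} not in gene set")
    master = np.random.SeedSequence(seed)
    collection = PanelCollection()
    truths: dict[tuple[str, str], SimTruth] = {}
    children = master.spawn(len(species) * len(tissues))
    idx = 0
    for sp in species:
        for tissue in tissues:
            rng = np.random.default_rng(children[idx])
            idx += 1
            lo, hi = noise_sd_range
            noise_sd = rng.uniform(lo, hi, size=base.n_genes)
            for g in shared_stable_genes:
                noise_sd[base.gene_labels.index(g)] = stable_sd
            cfg = replace(
                base,
                gene_noise_sd=noise_sd,
                n_bio=TISSUE_REPLICATES.get(tissue, base.n_bio),
                species=sp,
                tissue=tissue,
            ).resolved()
            panel, truth = generate_panel(cfg, rng=rng)
            collection.add(panel)
            truths[(sp, tissue)] = truth
    return collection, truths
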