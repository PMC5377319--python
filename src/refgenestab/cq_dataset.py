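"""Data model and I/O for quantification-cycle (Cq) measurements.

A qPCR run produces one Cq value per well; wells are organised as genes x
biological replicates x technical replicates within one (species, tissue)
panel. This module reads long-format delimited text, validates it,
aggregates technical replicates and exposes the rectangular
:class:`CqPanel` that every stability algorithm consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputFormatError, ValidationError

#: Default column-name dialect for long-format Cq tables.
DEFAULT_DIALECT: dict[str, str] = {
    "species": "species",
    "tissue": "tissue",
    "gene": "gene",
    "bio_replicate": "bio_rep",
    "tech_replicate": "tech_rep",
    "cq": "cq",
}

#: Tokens accepted as explicit non-detects in the cq column.
MISSING_TOKENS = {"", "na", "nan", "nd", "none", "missing"}

#: Cq values must lie in (0, CQ_MAX] or be flagged missing.
CQ_MAX = 45.0

#: Technical replicates more dispersed than this (cycles) are QC-flagged.
DEFAULT_TECH_SD_THRESHOLD = 0.5


@dataclass(frozen=True)
class QCFlag:
    """One quality-control observation; flag-only, nothing is dropped."""

    species: str
    tissue: str
    gene: str
    sample: str
    code: str
    message: str


@dataclass
class CqPanel:
    """Rectangular Cq measurements for one (species, tissue).

    ``cq_mean``, ``tech_sd`` and ``n_tech`` are genes x samples DataFrames
    sharing index (gene labels) and columns (biological-replicate labels).
    Missing cells are NaN in ``cq_mean`` with ``n_tech`` = 0.
    """

    species: str
    tissue: str
    cq_mean: pd.DataFrame
    tech_sd: pd.DataFrame
    n_tech: pd.DataFrame
    qc_flags: list[QCFlag] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.cq_mean.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cq_mean.columns)

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.tissue)

    def __post_init__(self) -> None:
        if self.cq_mean.index.duplicated().any():
            dupes = self.cq_mean.index[self.cq_mean.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene labels: {dupes}")
        if self.cq_mean.columns.duplicated().any():
            dupes = self.cq_mean.columns[self.cq_mean.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample labels: {dupes}")


@dataclass
class PanelCollection:
    """Set of panels keyed by (species, tissue)."""

    panels: dict[tuple[str, str], CqPanel] = field(default_factory=dict)

    def add(self, panel: CqPanel) -> None:
        if panel.key in self.panels:
            raise ValidationError(f"duplicate panel key {panel.key}")
        self.panels[panel.key] = panel

    def __len__(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels.values())

    def __getitem__(self, key: tuple[str, str]) -> CqPanel:
        return self.panels[key]

    @property
    def species(self) -> list[str]:
        return sorted({s for s, _ in self.panels})

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for _, t in self.panels:
            if t not in seen:
                seen.append(t)
        return seen


def _parse_cq(raw, line_no: int) -> float:
    """Return a float Cq or NaN for an explicit non-detect."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return np.nan
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(
            f"line {line_no}: non-numeric Cq {raw!r} not flagged missing"
        ) from exc
    if not np.isfinite(value) or not (0.0 < value <= CQ_MAX):
        raise ValidationError(
            f"line {line_no}: Cq {value} outside (0, {CQ_MAX:g}]"
        )
    return value


def read_long_table(
    path,
    dialect: dict[str, str] | None = None,
    sep: str | None = None,
) -> PanelCollection:
    """Read a long-format Cq table (CSV/TSV) into a :class:`PanelCollection`.

    One row per (species, tissue, gene, bio_rep, tech_rep) with a Cq value;
    row order never affects the result. ``dialect`` maps the canonical field
    names (keys of :data:`DEFAULT_DIALECT`) to the file's column names.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    missing_cols = [c for c in dialect.values() if c not in df.columns]
    if missing_cols:
        raise InputFormatError(
            f"{path}: missing required column(s) {missing_cols}; found {list(df.columns)}"
        )
    renamed = df.rename(columns={v: k for k, v in dialect.items()})
    renamed["_line"] = np.arange(2, len(renamed) + 2)  # 1-based, after header
    renamed["cq_value"] = [
        _parse_cq(v, n) for v, n in zip(renamed["cq"], renamed["_line"])
    ]
    for col in ("species", "tissue", "gene", "bio_replicate", "tech_replicate"):
        renamed[col] = renamed[col].astype(str).str.strip()

    dup_mask = renamed.duplicated(
        subset=["species", "tissue", "gene", "bio_replicate", "tech_replicate"],
        keep=False,
    )
    if dup_mask.any():
        first = renamed[dup_mask].iloc[0]
        raise ValidationError(
            "duplicate (gene, bio_replicate, tech_replicate) key "
            f"({first['gene']}, {first['bio_replicate']}, {first['tech_replicate']}) "
            f"in panel ({first['species']}, {first['tissue']})"
        )

    collection = PanelCollection()
    for (species, tissue), grp in renamed.groupby(
        ["species", "tissue"], sort=True
    ):
        collection.add(aggregate_technical_replicates(grp, species=species, tissue=tissue))
    return collection


def aggregate_technical_replicates(
    measurements: pd.DataFrame,
    species: str = "",
    tissue: str = "",
    outlier_sd_threshold: float = DEFAULT_TECH_SD_THRESHOLD,
) -> CqPanel:
    """Collapse technical replicates to per-(gene, sample) mean Cq.

    ``measurements`` is a long DataFrame with at least columns ``gene``,
    ``bio_replicate`` and ``cq_value`` (float, NaN = non-detect). The mean is
    the arithmetic mean of non-missing technical Cq values (Cq is the
    log-domain quantity, so mean-of-Cq is geometric-mean expression); the
    technical SD uses the n-1 denominator. Cells whose technical SD exceeds
    ``outlier_sd_threshold`` cycles are QC-flagged but retained; cells with
    all replicates missing come out as NaN.
    """
    required = {"gene", "bio_replicate", "cq_value"}
    if not required.issubset(measurements.columns):
        raise InputFormatError(
            f"aggregate_technical_replicates needs columns {sorted(required)}"
        )
    gene_order = list(dict.fromkeys(measurements["gene"]))
    sample_order = list(dict.fromkeys(measurements["bio_replicate"]))

    grouped = measurements.groupby(["gene", "bio_replicate"], sort=False)["cq_value"]
    mean = grouped.mean().unstack().reindex(index=gene_order, columns=sample_order)
    sd = grouped.std(ddof=1).unstack().reindex(index=gene_order, columns=sample_order)
    n = grouped.count().unstack().reindex(index=gene_order, columns=sample_order)
    n = n.fillna(0).astype(int)

    flags: list[QCFlag] = []
    noisy = (sd > outlier_sd_threshold).fillna(False)
    for gene in gene_order:
        for sample in sample_order:
            if noisy.loc[gene, sample]:
                flags.append(
                    QCFlag(
                        species, tissue, gene, sample, "tech_sd",
                        f"technical SD {sd.loc[gene, sample]:.3f} cycles > "
                        f"{outlier_sd_threshold:g}",
                    )
                )
            if n.loc[gene, sample] == 0:
                flags.append(
                    QCFlag(species, tissue, gene, sample, "all_missing",
                           "all technical replicates missing; cell set missing")
                )
    return CqPanel(species, tissue, mean, sd, n, flags)


@dataclass(frozen=True)
class Violation:
    code: str
    message: str


def validate_panel(
    panel: CqPanel,
    min_genes: int = 3,
    min_samples: int = 2,
    missing_warn_fraction: float = 0.5,
) -> list[Violation]:
    """Report structural problems; never raises (reporting operation).

    A panel usable by all three stability algorithms needs >= 3 genes and
    >= 2 samples (NormFinder needs >= 3 samples, checked in that module).
    """
    violations: list[Violation] = []
    if len(panel.genes) < min_genes:
        violations.append(Violation(
            "min_genes", f"{len(panel.genes)} gene(s) < required {min_genes}"))
    if len(panel.samples) < min_samples:
        violations.append(Violation(
            "min_samples", f"{len(panel.samples)} sample(s) < required {min_samples}"))
    values = panel.cq_mean.to_numpy(dtype=float)
    finite = np.isfinite(values)
    bad = finite & ~((values > 0) & (values <= CQ_MAX))
    if bad.any():
        genes = [panel.genes[i] for i in sorted(set(np.where(bad)[0]))]
        violations.append(Violation(
            "cq_range", f"Cq outside (0, {CQ_MAX:g}] for gene(s) {genes}"))
    frac_missing = 1.0 - finite.mean(axis=1)
    for gene, frac in zip(panel.genes, frac_missing):
        if frac >= missing_warn_fraction:
            violations.append(Violation(
                "missingness",
                f"gene {gene} missing in {frac:.0%} of samples"))
    sd = panel.tech_sd.to_numpy(dtype=float)
    neg_sd = (panel.n_tech.to_numpy() >= 2) & np.isfinite(sd) & (sd < 0)
    if neg_sd.any():
        violations.append(Violation("tech_sd", "negative technical SD"))
    return violations


def panel_to_long(panel: CqPanel) -> pd.DataFrame:
    """Flatten aggregated means back to long format (one row per cell)."""
    rows = []
    for gene in panel.genes:
        for sample in panel.samples:
            value = panel.cq_mean.loc[gene, sample]
            rows.append({
                "species": panel.species,
                "tissue": panel.tissue,
                "gene": gene,
                "bio_rep": sample,
                "tech_rep": "agg",
                "cq": "" if pd.isna(value) else repr(float(value)),
            })
    return pd.DataFrame(rows)


def write_long_table(collection: PanelCollection, path, sep: str = "\t") -> None:
    """Write aggregated panels in the default long dialect (round-trips)."""
    frames = [panel_to_long(p) for p in collection]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def panel_summary(panel: CqPanel) -> pd.DataFrame:
    """Per-gene summary: sample count, mean Cq, technical-SD statistics."""
    out = pd.DataFrame(index=pd.Index(panel.genes, name="gene"))
    out["n_samples"] = panel.cq_mean.notna().sum(axis=1)
    out["mean_cq"] = panel.cq_mean.mean(axis=1)
    out["tech_sd_mean"] = panel.tech_sd.mean(axis=1)
    out["tech_sd_max"] = panel.tech_sd.max(axis=1)
    return out


def qc_report_text(panel: CqPanel) -> str:
    """Plain-text QC report listing every flag for one panel."""
    header = f"QC report for panel ({panel.species}, {panel.tissue})"
    if not panel.qc_flags:
        return header + "\nno flags\n"
    lines = [header]
    for f in panel.qc_flags:
        lines.append(f"[{f.code}] gene={f.gene} sample={f.sample}: {f.message}")
    return "\n".join(lines) + "\n"
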