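"""Amplification efficiency and efficiency-corrected relative quantities.

A dilution-series standard curve regresses Cq on log10 dilution; its slope
gives the per-cycle amplification efficiency E = 10^(-1/slope) - 1 (100%
means perfect doubling). Cq values are then converted to relative
quantities rq = (1+E)^(Cq_cal - Cq) — the efficiency-corrected form of the
2^-ddCt transform — which geNorm and NormFinder consume. BestKeeper works
on raw Cq and bypasses this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cq_dataset import CqPanel
from .errors import InsufficientDataError, ParameterError

#: Efficiencies outside this fractional range are flagged as implausible.
SANE_EFFICIENCY_RANGE = (0.6, 1.25)


@dataclass
class StandardCurve:
    """Least-squares fit of Cq against log10 template dilution."""

    gene: str
    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    valid: bool

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


@dataclass
class RQMatrix:
    """Relative quantities (genes x samples), all > 0, max 1 per gene under
    the default per-gene-minimum-Cq calibrator."""

    rq: pd.DataFrame
    calibration: str
    efficiencies: pd.Series
    flags: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.rq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rq.columns)


def fit_standard_curve(points, gene: str = "") -> StandardCurve:
    """Fit slope/intercept of Cq on log10 dilution by ordinary least squares.

    ``points`` is an iterable of (log10_dilution, cq). Requires >= 3 distinct
    dilutions; a non-negative slope yields ``valid=False`` (no meaningful
    efficiency). efficiency = 10^(-1/slope) - 1.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len({x for x, _ in pts}) < 3:
        raise InsufficientDataError(
            "standard curve needs >= 3 distinct dilution points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = stats.linregress(x, y)
    r_squared = float(fit.rvalue**2)
    if fit.slope >= 0:
        return StandardCurve(gene, pts, float(fit.slope), float(fit.intercept),
                             r_squared, float("nan"), valid=False)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(gene, pts, float(fit.slope), float(fit.intercept),
                         r_squared, float(efficiency), valid=True)


def read_standard_curves(path, sep: str = "\t") -> dict[str, StandardCurve]:
    """Read a TSV with columns gene, dilution (or log10_dilution), cq."""
    df = pd.read_csv(path, sep=sep, comment="#")
    if "log10_dilution" in df.columns:
        df["_x"] = df["log10_dilution"].astype(float)
    elif "dilution" in df.columns:
        df["_x"] = np.log10(df["dilution"].astype(float))
    else:
        raise ParameterError(f"{path}: need a dilution or log10_dilution column")
    curves = {}
    for gene, grp in df.groupby("gene"):
        curves[str(gene)] = fit_standard_curve(
            zip(grp["_x"], grp["cq"].astype(float)), gene=str(gene))
    return curves


def read_efficiency_table(path, sep: str = "\t") -> dict[str, float]:
    """Read per-gene fractional efficiencies from a gene/efficiency_percent TSV."""
    df = pd.read_csv(path, sep=sep, comment="#")
    if "efficiency_percent" not in df.columns:
        raise ParameterError(f"{path}: need an efficiency_percent column")
    return {str(g): float(e) / 100.0
            for g, e in zip(df["gene"], df["efficiency_percent"])}


def relative_quantities(
    panel: CqPanel,
    efficiencies: dict[str, float] | float | None = None,
    calibrator: str = "min",
) -> RQMatrix:
    """Convert a Cq panel into efficiency-corrected relative quantities.

    rq_ij = (1 + e_i)^(Cq_i,cal - Cq_ij), with the calibrator Cq per gene
    chosen by ``calibrator``: "min" (default; maximum-expression sample, so
    max rq = 1 per gene), "mean", or a sample label. With e = 1 this is
    exactly the 2^-dCq transform. Missing Cq propagates to missing rq.
    """
    cq = panel.cq_mean.astype(float)
    genes = panel.genes
    if efficiencies is None:
        eff = pd.Series(1.0, index=genes)
    elif isinstance(efficiencies, (int, float)):
        eff = pd.Series(float(efficiencies), index=genes)
    else:
        eff = pd.Series({g: float(efficiencies.get(g, 1.0)) for g in genes})
    if (eff <= -1).any():
        bad = list(eff.index[eff <= -1])
        raise ParameterError(f"efficiency <= -1 (amplification factor <= 0) for {bad}")
    flags = [
        f"efficiency for {g} ({e:.3f}) outside plausible range "
        f"{SANE_EFFICIENCY_RANGE}"
        for g, e in eff.items()
        if not (SANE_EFFICIENCY_RANGE[0] <= e <= SANE_EFFICIENCY_RANGE[1])
    ]

    if calibrator == "min":
        cal = cq.min(axis=1)
    elif calibrator == "mean":
        cal = cq.mean(axis=1)
    elif calibrator in panel.samples:
        cal = cq[calibrator]
    else:
        raise ParameterError(
            f"calibrator {calibrator!r} is neither 'min', 'mean' nor a sample label")

    factor = 1.0 + eff
    rq = pd.DataFrame(
        np.power(factor.to_numpy()[:, None], (cal.to_numpy()[:, None] - cq.to_numpy())),
        index=cq.index, columns=cq.columns)
    return RQMatrix(rq, calibration=str(calibrator), efficiencies=eff, flags=flags)
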