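from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refgenestab.cq_dataset import CqPanel
from refgenestab.quantification import RQMatrix


def make_rq(values: dict[str, list[float]]) -> RQMatrix:
    """Wrap a plain gene -> per-sample values dict into an RQMatrix."""
    frame = pd.DataFrame(values).T
    frame.columns = [f"s{i + 1}" for i in range(frame.shape[1])]
    genes = list(frame.index)
    return RQMatrix(frame, calibration="raw", efficiencies=pd.Series(1.0, index=genes),
                    flags=[])


def make_panel(cq: dict[str, list[float]], species: str = "sp",
               tissue: str = "tis") -> CqPanel:
    """Build an aggregated CqPanel from per-gene Cq lists (n_tech = 1)."""
    frame = pd.DataFrame(cq).T.astype(float)
    frame.columns = [f"s{i + 1}" for i in range(frame.shape[1])]
    zeros = frame * 0.0
    ones = (frame * 0 + 1).fillna(0).astype(int)
    return CqPanel(species, tissue, frame, zeros, ones)


def random_rq(rng: np.random.Generator, n_genes: int, n_samples: int) -> RQMatrix:
    """Log-normal random relative quantities, strictly positive."""
    log_vals = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    values = {f"g{i + 1}": list(np.exp2(log_vals[i])) for i in range(n_genes)}
    return make_rq(values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170403)


@pytest.fixture
def proportional_rq() -> RQMatrix:
    """Four genes that are exact positive multiples of one another."""
    base = [1.0, 2.0, 0.5, 4.0, 1.5]
    return make_rq({
        "g1": base,
        "g2": [3.0 * v for v in base],
        "g3": [0.25 * v for v in base],
        "g4": [10.0 * v for v in base],
    })
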