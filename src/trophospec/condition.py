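"""Predator-level derived covariates: scaled mass index and foraging intensity.

The scaled mass index (SMI) standardizes body mass to a common reference
body length through the allometric power law M = a L^b, with b estimated by
standardized major axis (SMA) regression on ln-transformed data:

    SMI_i = M_i * (L0 / L_i) ** b_SMA

where L0 is the arithmetic mean SVL of the analyzed sample.  Because
L0/L_i is dimensionless, SMI keeps the unit of mass and is invariant to
the length unit.  FORI, the foraging-intensity index, is simply the number
of prey items in an individual's stomach (diet-matrix row sum).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CovariateTable, DietMatrix


@dataclass
class ConditionResult:
    table: pd.DataFrame  # columns: id, svl, mass, smi, fori
    b_sma: float
    l0: float

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def sma_slope(ln_mass, ln_svl) -> float:
    """Standardized-major-axis slope of ln mass on ln length.

    b_SMA = b_OLS / |r|, which equals sign(r) * sd(ln mass)/sd(ln length).
    Undefined when the variables are uncorrelated (division by |r|).
    """
    y = np.asarray(ln_mass, dtype=float)
    x = np.asarray(ln_svl, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 individuals for the SMA slope")
    if np.var(x) == 0:
        raise ValueError("zero variance in length")
    if np.var(y) == 0:
        raise ValueError("zero variance in mass")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < 1e-10:
        raise ValueError("mass and length uncorrelated; SMA slope undefined")
    b_ols = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    return b_ols / abs(r)


def scaled_mass_index(
    covariates: CovariateTable, l0: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Per-individual SMI; returns (smi, b_sma, l0).

    L0 defaults to the mean SVL of the sample, so an individual of exactly
    reference length has SMI equal to its observed mass.
    """
    svl = covariates.table["svl"].to_numpy(dtype=float)
    mass = covariates.table["body_mass"].to_numpy(dtype=float)
    b = sma_slope(np.log(mass), np.log(svl))
    if l0 is None:
        l0 = float(svl.mean())
    smi = mass * (l0 / svl) ** b
    return smi, b, l0


def fori(diet: DietMatrix) -> np.ndarray:
    """Foraging-intensity index: prey items per individual (row sums)."""
    return diet.row_totals()


def condition_table(
    diet: DietMatrix, covariates: CovariateTable, l0: float | None = None
) -> ConditionResult:
    """Joined per-individual condition report (id, svl, mass, smi, fori)."""
    cov = covariates.aligned_to(diet)
    subset = CovariateTable(cov)
    smi, b, l0_used = scaled_mass_index(subset, l0=l0)
    table = pd.DataFrame(
        {
            "id": diet.individuals,
            "svl": cov["svl"].to_numpy(dtype=float),
            "mass": cov["body_mass"].to_numpy(dtype=float),
            "smi": smi,
            "fori": fori(diet),
        }
    )
    return ConditionResult(table=table, b_sma=b, l0=l0_used)
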