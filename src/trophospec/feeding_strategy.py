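"""Feeding-strategy metrics for the Amundsen-modified Costello plot.

For each prey category the plot uses two axes: frequency of occurrence
(FO, the fraction of predators whose stomach contained the prey) and
prey-specific abundance (Pi, the prey's share of all items found in just
those stomachs that contained it).  Specialist populations show points in
the upper-right (high FO, high Pi for one prey); generalists scatter low.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import DietMatrix, PreyTaxon

LABEL_CUTOFF = 0.30  # points with both FO and Pi below this are unlabelled


@dataclass
class StrategyPoint:
    taxon: PreyTaxon
    FO: float
    Pi: float

    @property
    def shown(self) -> bool:
        """Label-display flag: hidden when both coordinates are < 0.30."""
        return not (self.FO < LABEL_CUTOFF and self.Pi < LABEL_CUTOFF)


def frequency_of_occurrence(diet: DietMatrix) -> dict[PreyTaxon, float]:
    """FO_i = (# predators with the taxon in their stomach) / (# predators)."""
    if diet.n_individuals == 0:
        raise ValueError("empty diet matrix")
    present = (diet.counts > 0).sum(axis=0)
    return {
        t: present[j] / diet.n_individuals for j, t in enumerate(diet.taxa)
    }


def prey_specific_abundance(diet: DietMatrix) -> dict[PreyTaxon, float]:
    """Pi_i over stomachs containing taxon i: taxon items / those stomachs' items.

    Taxa absent from every stomach are omitted (Pi undefined).
    """
    row_tot = diet.row_totals().astype(float)
    out: dict[PreyTaxon, float] = {}
    for j, t in enumerate(diet.taxa):
        mask = diet.counts[:, j] > 0
        if not mask.any():
            continue
        out[t] = float(diet.counts[mask, j].sum() / row_tot[mask].sum())
    return out


def amundsen_table(diet: DietMatrix) -> list[StrategyPoint]:
    """Plot-ready (FO, Pi) points for every taxon occurring in >= 1 stomach."""
    fo = frequency_of_occurrence(diet)
    pi = prey_specific_abundance(diet)
    return [StrategyPoint(t, fo[t], pi[t]) for t in diet.taxa if t in pi]


def strategy_dataframe(points: list[StrategyPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": [p.taxon.name for p in points],
            "life_stage": [p.taxon.life_stage or "" for p in points],
            "FO": [p.FO for p in points],
            "Pi": [p.Pi for p in points],
            "shown_flag": [p.shown for p in points],
        }
    )


def export_strategy_csv(points: list[StrategyPoint], path: str | Path) -> None:
    strategy_dataframe(points).to_csv(path, index=False)
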