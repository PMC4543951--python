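"""Vanderploeg–Scavia relativized electivity E*.

E* compares a prey's relative abundance in the diet (r) with its relative
abundance in the environment (p) through the normalized forage ratio
W_i = (r_i/p_i) / sum_j (r_j/p_j), then relativizes against the random-
feeding expectation 1/n:

    E*_i = (W_i - 1/n) / (W_i + 1/n)

ranging from -1 (complete avoidance) through 0 (random feeding) to +1
(exclusive positive selection).  Prey categories too rare in the
environment (fewer than `min_avail` sampled individuals) are excluded
before r and p are renormalized over the retained set; diet-absent taxa
are retained with W = 0, E* = -1, so strong avoidance stays reportable.

The significance rule follows the source convention of thresholding at the
5th percentile of |E*|.  Note that, taken literally, this marks roughly
95% of categories as different from zero; the rule is applied as stated
and the threshold value is always reported alongside the flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import AvailabilityTable, PreyTaxon

DEFAULT_MIN_AVAIL = 5  # "more than four individuals sampled in the environment"


@dataclass
class ElectivityResult:
    taxon: PreyTaxon
    r: float          # relative abundance in the diet (over retained taxa)
    p: float          # relative abundance in the environment (retained taxa)
    W: float          # normalized forage ratio
    Estar: float
    significant: bool | None = None
    threshold: float | None = None
    n_categories: int = 0


def electivity_estar(
    diet_counts,
    availability: AvailabilityTable | None = None,
    *,
    taxa: list[PreyTaxon] | None = None,
    availability_counts=None,
    min_avail: int = DEFAULT_MIN_AVAIL,
) -> list[ElectivityResult]:
    """Relativized electivity for pooled diet counts against availability.

    `diet_counts` and the availability counts must be aligned on a shared
    taxon list (either an :class:`AvailabilityTable` whose taxa match, or a
    raw vector plus explicit `taxa`).  Results carry the significance flag
    from :func:`estar_threshold`.
    """
    diet_counts = np.asarray(diet_counts, dtype=float)
    if availability is not None:
        taxa = list(availability.taxa)
        avail = availability.counts.astype(float)
    else:
        if taxa is None or availability_counts is None:
            raise ValueError("need an AvailabilityTable or taxa + counts")
        avail = np.asarray(availability_counts, dtype=float)
    if len(diet_counts) != len(avail) or len(avail) != len(taxa):
        raise ValueError("diet, availability and taxa must be aligned")

    keep = avail >= min_avail
    if not keep.any():
        raise ValueError("no prey category passes the availability filter")
    kept_taxa = [t for t, k in zip(taxa, keep) if k]
    r = diet_counts[keep]
    p = avail[keep]
    r = r / r.sum() if r.sum() > 0 else r
    p = p / p.sum()
    n = int(keep.sum())

    ratio = np.where(r > 0, r / p, 0.0)
    w = ratio / ratio.sum()
    estar = (w - 1.0 / n) / (w + 1.0 / n)

    results = [
        ElectivityResult(taxon=t, r=float(ri), p=float(pi), W=float(wi),
                         Estar=float(ei), n_categories=n)
        for t, ri, pi, wi, ei in zip(kept_taxa, r, p, w, estar)
    ]
    thr = estar_threshold([res.Estar for res in results])
    for res in results:
        res.threshold = thr
        res.significant = abs(res.Estar) >= thr
    return results


def estar_threshold(estars) -> float:
    """5th percentile of |E*| (linear interpolation between order statistics)."""
    e = np.abs(np.asarray(estars, dtype=float))
    if e.size == 0:
        raise ValueError("need at least one electivity value")
    return float(np.percentile(e, 5.0))


def electivity_dataframe(results: list[ElectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": [x.taxon.name for x in results],
            "life_stage": [x.taxon.life_stage or "" for x in results],
            "r": [x.r for x in results],
            "p": [x.p for x in results],
            "W": [x.W for x in results],
            "Estar": [x.Estar for x in results],
            "significant": [x.significant for x in results],
            "threshold": [x.threshold for x in results],
        }
    )


def export_electivity_csv(results: list[ElectivityResult], path: str | Path) -> None:
    electivity_dataframe(results).to_csv(path, index=False)
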