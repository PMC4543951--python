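"""Niche-width decomposition, individual-specialization indices and
Monte Carlo null models.

The population's total niche width (TNW) is the Shannon diversity of the
pooled diet.  Writing q_j for the pooled diet proportions and p_ij for
individual i's diet proportions, TNW decomposes exactly (entropy chain
rule) into

    TNW  = -sum_j q_j ln q_j
    WIC  =  sum_i w_i * ( -sum_j p_ij ln p_ij )      (w_i = item share of i)
    BIC  =  TNW - WIC

WIC is the conditional entropy of prey category given individual, so
0 <= WIC <= TNW always.  The ratio WIC/TNW in [0, 1] measures
inter-individual diet variation: near 1 the population is a set of
identical generalists, near 0 every individual is a narrow specialist on a
different resource.

Individual overlap with the population is the proportional similarity
index PSi_i = 1 - 0.5 * sum_j |p_ij - q_j|  (equivalently
sum_j min(p_ij, q_j)); its population mean is the IS index.

Significance comes from a Monte Carlo "generalist null": each simulated
population keeps every individual's observed item count but draws the
items multinomially from the pooled distribution q.  The proportion of
null populations with an index value at or below the observed one, with
the add-one correction, is the non-parametric p-value (999 replicates can
therefore return exactly p = 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CovariateTable, DietMatrix
from .diversity import mann_whitney, shannon

__all__ = [
    "NicheDecomposition",
    "PSiResult",
    "niche_decomposition",
    "psi",
    "null_resample",
    "NullDistributions",
    "pvalue",
    "psi_threshold",
    "split_and_compare",
]


def _row_entropies(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


@dataclass
class NicheDecomposition:
    tnw: float
    wic: float
    bic: float
    ratio: float
    p_ratio: float | None = None
    reps: int | None = None
    seed: int | None = None
    null_ratios: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "tnw": self.tnw, "wic": self.wic, "bic": self.bic,
            "ratio": self.ratio, "p_ratio": self.p_ratio,
            "reps": self.reps, "seed": self.seed,
        }


def _decompose(counts: np.ndarray) -> NicheDecomposition:
    pooled = counts.sum(axis=0).astype(float)
    q = pooled / pooled.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        tnw = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
    w = counts.sum(axis=1) / counts.sum()
    wic = float(np.sum(w * _row_entropies(counts)))
    bic = tnw - wic
    ratio = wic / tnw if tnw > 0 else 1.0
    return NicheDecomposition(tnw=tnw, wic=wic, bic=bic, ratio=ratio)


def niche_decomposition(diet: DietMatrix) -> NicheDecomposition:
    """TNW/WIC/BIC decomposition of a per-individual diet matrix."""
    if diet.n_individuals < 2:
        raise ValueError("niche decomposition needs at least two individuals")
    return _decompose(diet.counts)


def psi(diet: DietMatrix) -> tuple[np.ndarray, float]:
    """Per-individual proportional similarity PSi and the IS index (mean PSi)."""
    p = diet.proportions()
    q = diet.pooled_proportions()
    values = 1.0 - 0.5 * np.abs(p - q).sum(axis=1)
    return values, float(values.mean())


@dataclass
class NullDistributions:
    """Null-model resampling output: one entry per replicate population."""

    ratios: np.ndarray          # WIC/TNW per replicate
    is_values: np.ndarray       # IS per replicate
    psi_pool: np.ndarray        # all PSi values, pooled over replicates
    reps: int
    seed: int


def null_resample(diet: DietMatrix, reps: int = 999, seed: int | None = None) -> NullDistributions:
    """Generalist-null Monte Carlo resampling.

    Each replicate population preserves every individual's observed item
    count and draws that many items multinomially from the pooled diet
    distribution q, then WIC/TNW, IS and all PSi values are recomputed.
    Deterministic for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed is None:
        raise ValueError("seed is required for Monte Carlo resampling")
    rng = np.random.default_rng(seed)
    q = diet.pooled_proportions()
    items = diet.row_totals()
    n, t = diet.n_individuals, diet.n_taxa

    # draw all replicates for each individual at once: (reps, n, t)
    sims = np.empty((reps, n, t), dtype=np.int64)
    for i, m in enumerate(items):
        sims[:, i, :] = rng.multinomial(int(m), q, size=reps)

    ratios = np.empty(reps)
    is_values = np.empty(reps)
    psi_pool = np.empty((reps, n))
    grand = float(items.sum())
    w = items / grand
    for r in range(reps):
        counts = sims[r]
        pooled = counts.sum(axis=0).astype(float)
        qr = pooled / pooled.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            tnw = -np.sum(np.where(qr > 0, qr * np.log(qr), 0.0))
        wic = float(np.sum(w * _row_entropies(counts)))
        ratios[r] = wic / tnw if tnw > 0 else 1.0
        props = counts / items[:, None].astype(float)
        psis = 1.0 - 0.5 * np.abs(props - qr).sum(axis=1)
        psi_pool[r] = psis
        is_values[r] = psis.mean()
    return NullDistributions(
        ratios=ratios, is_values=is_values, psi_pool=psi_pool.ravel(),
        reps=reps, seed=seed,
    )


def pvalue(observed: float, null_values, reps: int | None = None) -> float:
    """Non-parametric p = (1 + #{null <= observed}) / (reps + 1).

    The add-one correction bounds p below by 1/(reps+1), so 999 replicates
    can report at best p = 0.001.
    """
    null_values = np.asarray(null_values, dtype=float)
    if reps is None:
        reps = null_values.size
    if null_values.size != reps:
        raise ValueError("null_values length must equal reps")
    return float((1 + np.sum(null_values <= observed)) / (reps + 1))


def psi_threshold(null_psi, lower_quantile: float = 2.5) -> float:
    """Specialist cutoff: lower limit of the null PSi central 95% interval.

    By default the 2.5th percentile of the pooled null PSi distribution;
    individuals with observed PSi below it are classed "individual
    specialists" (low-PSi group).
    """
    null_psi = np.asarray(null_psi, dtype=float)
    if null_psi.size == 0:
        raise ValueError("empty null PSi pool")
    return float(np.percentile(null_psi, lower_quantile))


@dataclass
class PSiResult:
    psi: np.ndarray
    is_index: float
    p_is: float | None = None
    threshold: float | None = None
    groups: np.ndarray | None = None     # "low" / "high" per individual
    null_psi: np.ndarray | None = None

    def as_dict(self) -> dict:
        gs = None
        if self.groups is not None:
            gs = {g: int(np.sum(self.groups == g)) for g in ("low", "high")}
        return {
            "is": self.is_index, "p_is": self.p_is,
            "threshold": self.threshold, "group_sizes": gs,
        }


def specialization_analysis(
    diet: DietMatrix, reps: int = 999, seed: int | None = None
) -> tuple[NicheDecomposition, PSiResult, NullDistributions]:
    """Full specialization workflow: decomposition, PSi/IS, nulls, p-values,
    threshold and low/high group assignment."""
    dec = niche_decomposition(diet)
    psis, is_index = psi(diet)
    nulls = null_resample(diet, reps=reps, seed=seed)
    dec.p_ratio = pvalue(dec.ratio, nulls.ratios, reps)
    dec.reps, dec.seed, dec.null_ratios = reps, seed, nulls.ratios
    thr = psi_threshold(nulls.psi_pool)
    groups = np.where(psis < thr, "low", "high")
    res = PSiResult(
        psi=psis, is_index=is_index,
        p_is=pvalue(is_index, nulls.is_values, reps),
        threshold=thr, groups=groups, null_psi=nulls.psi_pool,
    )
    return dec, res, nulls


_CONTRAST_METRICS = ("smi", "svl", "shannon_H", "evenness_J", "fori",
                     "dominant_share")


def split_and_compare(
    diet: DietMatrix,
    covariates: CovariateTable,
    threshold: float,
    psi_values: np.ndarray | None = None,
    dominant_taxon_index: int | None = None,
) -> pd.DataFrame:
    """Low- vs high-PSi group contrasts (the published comparison table).

    Metrics per individual: SMI, SVL, Shannon H of the stomach, evenness J,
    FORI and the dominant prey's relative abundance in the stomach.  Each
    row reports group means, SDs, Mann-Whitney U and two-sided p.
    """
    from .condition import condition_table

    if psi_values is None:
        psi_values, _ = psi(diet)
    low = psi_values < threshold
    if low.all() or not low.any():
        raise ValueError(
            "PSi threshold does not split the population into two groups"
        )
    cond = condition_table(diet, covariates)
    if dominant_taxon_index is None:
        dominant_taxon_index = int(np.argmax(diet.pooled_counts()))
    props = diet.proportions()

    per_ind = {
        "smi": cond.table["smi"].to_numpy(),
        "svl": cond.table["svl"].to_numpy(),
        "shannon_H": np.array([shannon(row).H for row in diet.counts]),
        "evenness_J": np.array(
            [shannon(row).J if shannon(row).J is not None else 0.0
             for row in diet.counts]
        ),
        "fori": diet.row_totals().astype(float),
        "dominant_share": props[:, dominant_taxon_index],
    }
    rows = []
    for metric in _CONTRAST_METRICS:
        v = per_ind[metric]
        a, b = v[low], v[~low]
        u, p = mann_whitney(a, b)
        rows.append(
            {
                "metric": metric,
                "low_mean": float(a.mean()), "low_sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
                "high_mean": float(b.mean()), "high_sd": float(b.std(ddof=1)) if b.size > 1 else 0.0,
                "n_low": int(a.size), "n_high": int(b.size),
                "U": u, "p": p,
            }
        )
    return pd.DataFrame(rows)
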