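"""Diversity indices and community comparisons.

Shannon–Weaver diversity (natural log) with Hutcheson's analytic variance,
the Hutcheson two-sample t-test for comparing Shannon indices from count
data, Bray–Curtis dissimilarity, ANOSIM on ranked dissimilarities, and a
Mann–Whitney wrapper reporting the conventional (smaller) U.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .data_model import DietMatrix

__all__ = [
    "DiversityResult",
    "AnosimResult",
    "shannon",
    "hutcheson_t",
    "bray_curtis",
    "anosim",
    "mann_whitney",
]


@dataclass
class DiversityResult:
    """Shannon index H (nats), evenness J = H/ln S, richness S, Hutcheson
    variance of H, and total item count N."""

    H: float
    J: float | None
    S: int
    varH: float
    N: int

    def as_dict(self) -> dict:
        return {"H": self.H, "J": self.J, "S": self.S,
                "varH": self.varH, "N": self.N}


def shannon(counts) -> DiversityResult:
    """Shannon–Weaver diversity of a count vector.

    H = -sum p ln p over taxa with positive counts; evenness J = H / ln S
    (undefined, returned as None, for a single taxon); varH is Hutcheson's
    estimator  [sum p (ln p)^2 - (sum p ln p)^2]/N + (S-1)/(2 N^2).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector has no diversity")
    n = c.sum()
    p = c / n
    lnp = np.log(p)
    h = float(-np.sum(p * lnp))
    s = int(c.size)
    var = float(
        (np.sum(p * lnp**2) - np.sum(p * lnp) ** 2) / n + (s - 1) / (2 * n**2)
    )
    j = h / np.log(s) if s > 1 else None
    return DiversityResult(H=h, J=j, S=s, varH=var, N=int(round(n)))


def hutcheson_t(counts_a, counts_b) -> tuple[float, float, float]:
    """Hutcheson's t-test comparing two Shannon indices from count data.

    Returns (t, df, two-sided p) with
    t = (H_a - H_b) / sqrt(varH_a + varH_b)  and Welch-style df
    (varH_a + varH_b)^2 / (varH_a^2/N_a + varH_b^2/N_b).
    """
    a, b = shannon(counts_a), shannon(counts_b)
    pooled_var = a.varH + b.varH
    if pooled_var <= 0:
        raise ValueError(
            "zero pooled variance (both samples single-taxon); "
            "the Shannon indices cannot be compared"
        )
    t = (a.H - b.H) / np.sqrt(pooled_var)
    df = pooled_var**2 / (a.varH**2 / a.N + b.varH**2 / b.N)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / (x + y).sum())


@dataclass
class AnosimResult:
    """ANOSIM R statistic, permutation p-value and permutation count."""

    R: float
    p: float
    n_perm: int

    def as_dict(self) -> dict:
        return {"R": self.R, "p": self.p, "n_perm": self.n_perm}


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (n * (n - 1) / 4.0)


def anosim(
    diet: DietMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> AnosimResult:
    """ANOSIM on Bray–Curtis dissimilarities of per-individual diet proportions.

    Rows are converted to within-individual relative abundances before the
    dissimilarity, so item-count differences between predators do not masquerade
    as compositional structure.  R compares mean between- versus within-group
    dissimilarity ranks, scaled to [-1, 1]; the one-sided permutation p-value
    uses the add-one convention p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).

    With ``exhaustive=True`` (or automatically when all distinct label
    arrangements number at most n_perm) every permutation is enumerated and
    the p-value is exact.
    """
    groups = np.asarray(groups)
    if len(groups) != diet.n_individuals:
        raise ValueError("one group label per individual required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    if seed is None and not exhaustive:
        raise ValueError("seed is required for the permutation test")

    n = diet.n_individuals
    d = pdist(diet.proportions(), metric="braycurtis")
    ranks = stats.rankdata(d)
    iu, ju = np.triu_indices(n, k=1)

    codes = np.searchsorted(labels, groups)
    obs = _anosim_r(ranks, codes[iu] == codes[ju], n)

    import math

    n_distinct = math.factorial(n) // math.prod(
        math.factorial(int(c)) for c in counts
    )
    if exhaustive is None:
        exhaustive = n_distinct <= n_perm

    if exhaustive:
        seen = set()
        r_perm = []
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            pc = np.array(perm)
            r_perm.append(_anosim_r(ranks, pc[iu] == pc[ju], n))
        r_perm = np.array(r_perm)
        # observed arrangement is one of the enumerated ones
        p = float(np.sum(r_perm >= obs - 1e-12) / len(r_perm))
        return AnosimResult(R=float(obs), p=p, n_perm=len(r_perm))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        pc = rng.permutation(codes)
        if _anosim_r(ranks, pc[iu] == pc[ju], n) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AnosimResult(R=float(obs), p=float(p), n_perm=n_perm)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney test; returns (U, p).

    U is reported in the classical tabled convention, min(U_a, U_b).  The
    p-value is exact (full enumeration) when both samples are tie-free and
    n_a * n_b <= 400, otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)
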