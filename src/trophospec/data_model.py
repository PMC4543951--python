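"""Domain types and CSV I/O for stomach-content diet analysis.

The central objects are :class:`DietMatrix` (per-individual prey counts),
:class:`AvailabilityTable` (environmental prey counts) and
:class:`CovariateTable` (predator phenotype).  Prey are identified at Order
rank, optionally annotated with a life stage, so "Coleoptera (larvae)" and
"Coleoptera (adults)" are distinct categories.

A packaged fixture carries the published pooled seasonal prey table for the
Spectacled Salamander (*Salamandrina perspicillata*): diet and environment
counts for 27 prey categories in autumn and spring.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("trophospec")

SEASONS = ("autumn", "spring")

#: diet / environment item grand totals of the packaged fixture
FIXTURE_DIET_TOTALS = {"autumn": 1570, "spring": 2342}
FIXTURE_ENV_TOTALS = {"autumn": 1488, "spring": 2336}


class FormatError(ValueError):
    """Raised when an input table violates the expected CSV contract."""


# ---------------------------------------------------------------------------
# Prey taxa
# ---------------------------------------------------------------------------

_STAGE_RE = re.compile(r"^\s*(?P<name>.+?)\s*\(\s*(?P<stage>[^)]+?)\s*\)\s*$")


@dataclass(frozen=True, order=True)
class PreyTaxon:
    """A prey category: Order-rank name plus optional life stage."""

    name: str
    life_stage: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise FormatError("prey taxon name must be non-empty")
        if self.life_stage is not None and not str(self.life_stage).strip():
            object.__setattr__(self, "life_stage", None)

    @property
    def label(self) -> str:
        """Single-string form used in CSV headers, e.g. ``Coleoptera (larvae)``."""
        if self.life_stage:
            return f"{self.name} ({self.life_stage})"
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "PreyTaxon":
        m = _STAGE_RE.match(label)
        if m:
            return cls(m.group("name"), m.group("stage"))
        return cls(label.strip())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _check_unique_taxa(taxa: Sequence[PreyTaxon]) -> None:
    seen: set[PreyTaxon] = set()
    for t in taxa:
        if t in seen:
            raise FormatError(f"duplicate prey taxon {t.label!r}")
        seen.add(t)


# ---------------------------------------------------------------------------
# Diet matrix
# ---------------------------------------------------------------------------


@dataclass
class DietMatrix:
    """Per-individual prey-count matrix (individuals x taxa).

    Rows are predator individuals, columns prey categories.  Counts are
    non-negative integers; individuals whose stomach yielded no items are
    excluded on construction (they carry no dietary information) and their
    ids are kept in :attr:`excluded`.
    """

    individuals: list[str]
    taxa: list[PreyTaxon]
    counts: np.ndarray
    season: str | None = None
    site: str | None = None
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.individuals), len(self.taxa)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.taxa)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("diet counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count for individual {self.individuals[i]!r}, "
                f"taxon {self.taxa[j].label!r}"
            )
        _check_unique_taxa(self.taxa)
        if len(set(self.individuals)) != len(self.individuals):
            raise FormatError("duplicate individual ids")
        empty = self.counts.sum(axis=1) == 0
        if np.any(empty):
            dropped = [self.individuals[i] for i in np.flatnonzero(empty)]
            logger.warning(
                "excluding %d individual(s) with empty stomachs: %s",
                len(dropped), ", ".join(dropped),
            )
            self.excluded = list(self.excluded) + dropped
            keep = ~empty
            self.individuals = [
                ind for ind, k in zip(self.individuals, keep) if k
            ]
            self.counts = self.counts[keep]

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row_totals(self) -> np.ndarray:
        """Items per individual (the foraging-intensity index FORI)."""
        return self.counts.sum(axis=1)

    def pooled_counts(self) -> np.ndarray:
        """Population-level count per taxon (column sums)."""
        return self.counts.sum(axis=0)

    def proportions(self) -> np.ndarray:
        """Within-individual relative abundances p_ij (rows sum to 1)."""
        totals = self.row_totals().astype(float)
        return self.counts / totals[:, None]

    def pooled_proportions(self) -> np.ndarray:
        """Population diet distribution q_j."""
        pooled = self.pooled_counts().astype(float)
        return pooled / pooled.sum()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.individuals, name="id"),
            columns=[t.label for t in self.taxa],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def read_diet_matrix(
    path: str | Path,
    season: str | None = None,
    site: str | None = None,
) -> DietMatrix:
    """Read a wide-format diet matrix CSV (first column = individual id).

    Non-integer or negative cells raise :class:`FormatError` naming the
    offending row and column; all-zero individuals are excluded with a log
    message.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty or df.shape[1] < 2:
        raise FormatError(f"{path}: no records")
    ids = df.iloc[:, 0].astype(str).tolist()
    taxa = [PreyTaxon.from_label(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    counts = np.zeros(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, val in enumerate(raw[col]):
            try:
                x = int(str(val))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {val!r} at row {ids[i]!r}, "
                    f"column {col!r}"
                ) from None
            if x < 0:
                raise FormatError(
                    f"{path}: negative count {x} at row {ids[i]!r}, "
                    f"column {col!r}"
                )
            counts[i, j] = x
    return DietMatrix(ids, taxa, counts, season=season, site=site)


def merge_populations(diet_a: DietMatrix, diet_b: DietMatrix) -> DietMatrix:
    """Row-concatenate two same-season diet matrices over the taxon union.

    Taxa absent from one matrix are zero-filled, so per-individual counts are
    preserved exactly.  Used after a non-significant ANOSIM showed the
    populations share diet composition.
    """
    if diet_a.season != diet_b.season:
        raise FormatError(
            f"cannot merge diet matrices from different seasons "
            f"({diet_a.season!r} vs {diet_b.season!r})"
        )
    taxa = list(diet_a.taxa) + [t for t in diet_b.taxa if t not in set(diet_a.taxa)]
    index = {t: j for j, t in enumerate(taxa)}

    def expand(dm: DietMatrix) -> np.ndarray:
        out = np.zeros((dm.n_individuals, len(taxa)), dtype=np.int64)
        for j_old, t in enumerate(dm.taxa):
            out[:, index[t]] = dm.counts[:, j_old]
        return out

    return DietMatrix(
        individuals=list(diet_a.individuals) + list(diet_b.individuals),
        taxa=taxa,
        counts=np.vstack([expand(diet_a), expand(diet_b)]),
        season=diet_a.season,
        site=None,
        excluded=list(diet_a.excluded) + list(diet_b.excluded),
    )


# ---------------------------------------------------------------------------
# Availability
# ---------------------------------------------------------------------------


@dataclass
class AvailabilityTable:
    """Environmental prey counts for one season (pooled over trap methods)."""

    taxa: list[PreyTaxon]
    counts: np.ndarray
    season: str | None = None
    site: str | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("availability counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("availability counts must be non-negative")
        if self.counts.ndim != 1 or len(self.counts) != len(self.taxa):
            raise FormatError("counts must be a vector matching taxa")
        _check_unique_taxa(self.taxa)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        return self.counts / float(self.counts.sum())

    def count_for(self, taxon: PreyTaxon) -> int:
        for t, c in zip(self.taxa, self.counts):
            if t == taxon:
                return int(c)
        return 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [t.name for t in self.taxa],
                "life_stage": [t.life_stage or "" for t in self.taxa],
                "count": self.counts,
                "season": self.season or "",
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_availability(path: str | Path) -> AvailabilityTable:
    """Read a long-format availability CSV (taxon,count[,life_stage][,season][,site][,method]).

    When a ``method`` column is present (pitfall / soil_core / sticky) the
    counts are summed over methods per taxon.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: no records")
    cols = {c.lower(): c for c in df.columns}
    if "taxon" not in cols or "count" not in cols:
        raise FormatError(f"{path}: need 'taxon' and 'count' columns")
    stage_col = cols.get("life_stage")
    season = None
    if "season" in cols:
        seasons = set(df[cols["season"]].dropna().astype(str))
        if len(seasons) > 1:
            raise FormatError(f"{path}: multiple seasons in one table: {seasons}")
        season = next(iter(seasons), None)
    site = None
    if "site" in cols:
        sites = set(df[cols["site"]].dropna().astype(str))
        site = next(iter(sites)) if len(sites) == 1 else None

    records: dict[PreyTaxon, int] = {}
    for _, row in df.iterrows():
        stage = row[stage_col] if stage_col else None
        if isinstance(stage, float) and np.isnan(stage):
            stage = None
        taxon = PreyTaxon(str(row[cols["taxon"]]), stage)
        val = row[cols["count"]]
        if float(val) != int(val) or int(val) < 0:
            raise FormatError(
                f"{path}: invalid count {val!r} for taxon {taxon.label!r}"
            )
        records[taxon] = records.get(taxon, 0) + int(val)
    taxa = list(records)
    counts = np.array([records[t] for t in taxa], dtype=np.int64)
    return AvailabilityTable(taxa, counts, season=season, site=site)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateTable:
    """Predator phenotype: sex, season, site, SVL (mm), TL (mm), mass (g)."""

    table: pd.DataFrame

    REQUIRED = ("id", "sex", "season", "svl", "total_length", "body_mass")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"covariate table missing columns: {missing}")
        if "site" not in self.table.columns:
            self.table = self.table.assign(site="")
        bad_sex = set(self.table["sex"]) - {"M", "F"}
        if bad_sex:
            raise FormatError(f"sex must be 'M' or 'F'; found {bad_sex}")
        if (self.table["svl"] <= 0).any():
            raise FormatError("svl must be positive")
        if (self.table["body_mass"] <= 0).any():
            raise FormatError("body_mass must be positive")
        self.table = self.table.copy()
        self.table["id"] = self.table["id"].astype(str)

    def __len__(self) -> int:
        return len(self.table)

    def aligned_to(self, diet: DietMatrix) -> pd.DataFrame:
        """Rows reordered to the diet matrix's individuals; ids must match."""
        indexed = self.table.set_index("id")
        missing = [i for i in diet.individuals if i not in indexed.index]
        if missing:
            raise FormatError(f"covariates missing for individuals: {missing}")
        return indexed.loc[diet.individuals].reset_index()

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: no records")
    return CovariateTable(df)


# ---------------------------------------------------------------------------
# Published pooled seasonal prey table (packaged fixture)
# ---------------------------------------------------------------------------


@dataclass
class Table1Fixture:
    """The published pooled diet/environment counts, cell-for-cell.

    27 prey categories x {autumn, spring} x {diet, environment}, with the
    percentages as printed.  Diet columns total 1570 and 2342 items;
    environment columns 1488 and 2336.  Pooled counts cannot be disaggregated
    into per-individual rows, so this fixture backs pooled-mode analyses
    (diversity, electivity, feeding-strategy availability) while
    per-individual analyses run on user or synthetic data.
    """

    taxa: list[PreyTaxon]
    groups: list[str]
    diet_counts: dict[str, np.ndarray]
    diet_pct: dict[str, np.ndarray]
    env_counts: dict[str, np.ndarray]
    env_pct: dict[str, np.ndarray]

    def diet_total(self, season: str) -> int:
        return int(self.diet_counts[season].sum())

    def env_total(self, season: str) -> int:
        return int(self.env_counts[season].sum())

    def availability(self, season: str) -> AvailabilityTable:
        return AvailabilityTable(
            list(self.taxa), self.env_counts[season].copy(), season=season
        )

    def diet_proportions(self, season: str) -> np.ndarray:
        c = self.diet_counts[season].astype(float)
        return c / c.sum()

    def taxon_index(self, name: str, life_stage: str | None = None) -> int:
        target = PreyTaxon(name, life_stage)
        for i, t in enumerate(self.taxa):
            if t == target:
                return i
        raise KeyError(f"taxon {target.label!r} not in fixture")


def _read_fixture_csv(fname: str) -> pd.DataFrame:
    ref = resources.files("trophospec.data").joinpath(fname)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_table1_fixture() -> Table1Fixture:
    """Load and validate the packaged pooled seasonal prey table."""
    diet = _read_fixture_csv("table1_diet.csv")
    env = _read_fixture_csv("table1_environment.csv")
    if not (diet["taxon"].tolist() == env["taxon"].tolist()):
        raise FormatError("fixture tables disagree on taxon order")

    def stage(v) -> str | None:
        return None if (isinstance(v, float) and np.isnan(v)) else v

    taxa = [
        PreyTaxon(n, stage(s)) for n, s in zip(diet["taxon"], diet["life_stage"])
    ]
    fx = Table1Fixture(
        taxa=taxa,
        groups=diet["group"].tolist(),
        diet_counts={
            s: diet[f"{s}_n"].to_numpy(dtype=np.int64) for s in SEASONS
        },
        diet_pct={s: diet[f"{s}_pct"].to_numpy(dtype=float) for s in SEASONS},
        env_counts={s: env[f"{s}_n"].to_numpy(dtype=np.int64) for s in SEASONS},
        env_pct={s: env[f"{s}_pct"].to_numpy(dtype=float) for s in SEASONS},
    )
    # integrity of the packaged data: totals and printed percentages
    for s in SEASONS:
        if fx.diet_total(s) != FIXTURE_DIET_TOTALS[s]:
            raise FormatError(
                f"fixture diet total {fx.diet_total(s)} != "
                f"{FIXTURE_DIET_TOTALS[s]} for {s}"
            )
        if fx.env_total(s) != FIXTURE_ENV_TOTALS[s]:
            raise FormatError(
                f"fixture environment total {fx.env_total(s)} != "
                f"{FIXTURE_ENV_TOTALS[s]} for {s}"
            )
        for pct, counts, total in (
            (fx.diet_pct[s], fx.diet_counts[s], fx.diet_total(s)),
            (fx.env_pct[s], fx.env_counts[s], fx.env_total(s)),
        ):
            if np.max(np.abs(pct - 100.0 * counts / total)) > 0.011:
                raise FormatError(f"fixture percentages inconsistent for {s}")
    return fx
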