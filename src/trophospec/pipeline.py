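"""Stage orchestration: run individual analysis stages or the full workflow.

The full workflow mirrors the analysis order of the study it reimplements:
site/sex ANOSIM merge gates, seasonal diversity with the Hutcheson
comparison, feeding-strategy metrics, electivity against availability,
condition indices, resource-selection models for the main prey, and the
individual-specialization battery (WIC/TNW + Monte Carlo nulls, PSi/IS,
group split and contrasts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import condition as condition_mod
from . import diversity as div
from . import electivity as elec
from . import feeding_strategy as strat
from . import rspf as rspf_mod
from . import specialization as spec_mod
from . import synthetic
from .data_model import (
    AvailabilityTable,
    CovariateTable,
    DietMatrix,
    load_table1_fixture,
    read_availability,
    read_covariates,
    read_diet_matrix,
)

logger = logging.getLogger("trophospec")

STAGES = (
    "diversity", "anosim", "strategy", "electivity", "condition",
    "rspf", "niche", "simulate",
)


@dataclass
class PipelineConfig:
    """Inputs and options for a pipeline run (file paths or a scenario)."""

    seed: int
    out_dir: Path = Path("trophospec-out")
    scenario: str | None = None            # "autumn" / "spring"
    diet_path: str | None = None
    availability_path: str | None = None
    covariates_path: str | None = None
    season: str | None = None
    reps: int = 999
    n_perm: int = 999
    min_avail: int = elec.DEFAULT_MIN_AVAIL
    rspf_method: str = "naive_logistic"
    rspf_strategy: str = "resample"
    rspf_focal: list[str] = field(default_factory=list)
    anosim_alpha: float = 0.05
    n_individuals: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)

    def load_inputs(self):
        """Resolve (diet, covariates, availability); any may be None."""
        if self.scenario:
            return synthetic.paper_scenario(
                self.scenario, self.seed, self.n_individuals
            )
        diet = cov = avail = None
        if self.diet_path:
            diet = read_diet_matrix(self.diet_path, season=self.season)
        if self.covariates_path:
            cov = read_covariates(self.covariates_path)
        if self.availability_path:
            avail = read_availability(self.availability_path)
        return diet, cov, avail


def _dump_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def _need(value, what: str, stage: str):
    if value is None:
        raise ValueError(f"stage {stage!r} requires {what}")
    return value


def _stage_diversity(cfg, diet, cov, avail, out):
    report = {}
    if diet is not None:
        report["diet"] = div.shannon(diet.pooled_counts()).as_dict()
    if avail is not None:
        report["environment"] = div.shannon(avail.counts).as_dict()
    if not report:
        fx = load_table1_fixture()
        for s in ("autumn", "spring"):
            report[f"diet_{s}"] = div.shannon(fx.diet_counts[s]).as_dict()
            report[f"environment_{s}"] = div.shannon(fx.env_counts[s]).as_dict()
        t, dfree, p = div.hutcheson_t(
            fx.diet_counts["autumn"], fx.diet_counts["spring"]
        )
        report["diet_season_t_test"] = {"t": t, "df": dfree, "p": p}
    _dump_json(report, out / "diversity.json")
    return report


def _stage_anosim(cfg, diet, cov, avail, out):
    diet = _need(diet, "per-individual diet data", "anosim")
    cov = _need(cov, "covariates", "anosim")
    aligned = cov.aligned_to(diet)
    report = {}
    for factor in ("site", "sex"):
        labels = aligned[factor].astype(str).to_numpy()
        if len(np.unique(labels)) < 2:
            logger.info("anosim: factor %r has one level; skipped", factor)
            continue
        res = div.anosim(diet, labels, n_perm=cfg.n_perm, seed=cfg.seed)
        report[factor] = res.as_dict()
    _dump_json(report, out / "anosim.json")
    return report


def _stage_strategy(cfg, diet, cov, avail, out):
    diet = _need(diet, "per-individual diet data", "strategy")
    points = strat.amundsen_table(diet)
    strat.export_strategy_csv(points, out / "feeding_strategy.csv")
    return {"n_points": len(points)}


def _stage_electivity(cfg, diet, cov, avail, out):
    if diet is not None and avail is not None:
        # align availability onto the diet's taxon list
        counts = np.array([avail.count_for(t) for t in diet.taxa])
        results = elec.electivity_estar(
            diet.pooled_counts(), taxa=diet.taxa, availability_counts=counts,
            min_avail=cfg.min_avail,
        )
    else:
        fx = load_table1_fixture()
        season = cfg.season or "autumn"
        results = elec.electivity_estar(
            fx.diet_counts[season], fx.availability(season),
            min_avail=cfg.min_avail,
        )
    elec.export_electivity_csv(results, out / "electivity.csv")
    return {
        "n_categories": results[0].n_categories,
        "threshold": results[0].threshold,
        "positive": [x.taxon.label for x in results if x.Estar > 0],
    }


def _stage_condition(cfg, diet, cov, avail, out):
    diet = _need(diet, "per-individual diet data", "condition")
    cov = _need(cov, "covariates", "condition")
    res = condition_mod.condition_table(diet, cov)
    res.write_csv(out / "condition.csv")
    return {"b_sma": res.b_sma, "l0": res.l0,
            "mean_smi": float(res.table["smi"].mean())}


def _stage_rspf(cfg, diet, cov, avail, out):
    diet = _need(diet, "per-individual diet data", "rspf")
    cov = _need(cov, "covariates", "rspf")
    avail = _need(avail, "availability data", "rspf")
    if cfg.rspf_focal:
        from .data_model import PreyTaxon
        focal = [PreyTaxon.from_label(s) for s in cfg.rspf_focal]
    else:
        order = np.argsort(diet.pooled_counts())[::-1]
        focal = [diet.taxa[j] for j in order[:3]]
    report = {}
    for taxon in focal:
        ua = rspf_mod.assemble_use_availability(
            diet, avail, cov, taxon, strategy=cfg.rspf_strategy, seed=cfg.seed
        )
        models = rspf_mod.stepwise_aic(ua, method=cfg.rspf_method)
        best = models[0]
        try:
            rspf_mod.hosmer_lemeshow(best)
        except ValueError as exc:
            logger.warning("Hosmer-Lemeshow unavailable for %s: %s",
                           taxon.label, exc)
        report[taxon.label] = {
            "best": best.as_dict(),
            "ranking": [
                {"terms": m.terms, "aic": m.aic, "delta_aic": m.delta_aic}
                for m in models
            ],
        }
        if "smi" in best.terms:
            used = best.response == 1
            pd_pairs = np.column_stack(
                [ua.table.loc[used, "smi"], best.fitted[used]]
            )
            np.savetxt(
                out / f"rspf_smi_{taxon.name.lower()}.csv", pd_pairs,
                delimiter=",", header="smi,fitted_probability", comments="",
            )
    _dump_json(report, out / "rspf.json")
    return report


def _stage_niche(cfg, diet, cov, avail, out):
    if diet is None:
        raise ValueError(
            "stage 'niche' needs per-individual diet data; the packaged "
            "pooled seasonal table cannot be disaggregated into individuals "
            "— provide a diet CSV or use a synthetic scenario"
        )
    dec, psires, nulls = spec_mod.specialization_analysis(
        diet, reps=cfg.reps, seed=cfg.seed
    )
    report = dec.as_dict() | psires.as_dict() | {"season": diet.season}
    if cov is not None and psires.groups is not None and \
            len(set(psires.groups)) == 2:
        contrasts = spec_mod.split_and_compare(
            diet, cov, psires.threshold, psi_values=psires.psi
        )
        contrasts.to_csv(out / "group_contrasts.csv", index=False)
        report["contrast_metrics"] = contrasts["metric"].tolist()
    # per-individual PSi + group export
    import pandas as pd
    pd.DataFrame(
        {"id": diet.individuals, "psi": psires.psi, "group": psires.groups}
    ).to_csv(out / "psi.csv", index=False)
    hist, edges = np.histogram(nulls.ratios, bins=30)
    _dump_json(
        {
            "bins": edges.tolist(), "counts": hist.tolist(),
            "observed": dec.ratio,
            "ci": [float(np.percentile(nulls.ratios, 2.5)),
                   float(np.percentile(nulls.ratios, 97.5))],
        },
        out / "niche_null_histogram.json",
    )
    _dump_json(report, out / "niche.json")
    return report


def _stage_simulate(cfg, diet, cov, avail, out):
    season = cfg.scenario or cfg.season or "autumn"
    diet, cov, avail = synthetic.paper_scenario(
        season, cfg.seed, cfg.n_individuals
    )
    diet.write_csv(out / "diet.csv")
    cov.write_csv(out / "covariates.csv")
    avail.write_csv(out / "availability.csv")
    return {"n_individuals": diet.n_individuals,
            "n_items": int(diet.counts.sum()),
            "availability_total": avail.total, "seed": cfg.seed}


_STAGE_FN = {
    "diversity": _stage_diversity,
    "anosim": _stage_anosim,
    "strategy": _stage_strategy,
    "electivity": _stage_electivity,
    "condition": _stage_condition,
    "rspf": _stage_rspf,
    "niche": _stage_niche,
    "simulate": _stage_simulate,
}


def run_stage(stage: str, cfg: PipelineConfig):
    """Run one named stage; writes its report files under cfg.out_dir."""
    if stage not in _STAGE_FN:
        raise ValueError(
            f"unknown stage {stage!r}; available: {', '.join(STAGES)}"
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage %s (seed=%s)", stage, cfg.seed)
    diet = cov = avail = None
    if stage != "simulate":
        diet, cov, avail = cfg.load_inputs()
    return _STAGE_FN[stage](cfg, diet, cov, avail, out)


class MergeRefusedError(RuntimeError):
    """A merge-gate ANOSIM found significant structure; pooling refused."""


def run_full(cfg: PipelineConfig) -> dict:
    """Run the complete analysis sequence and write a consolidated report.

    The ANOSIM merge gates come first: if diet composition differs
    significantly between sites (p < alpha) the pipeline refuses to pool
    the populations and raises :class:`MergeRefusedError`.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diet, cov, avail = cfg.load_inputs()
    if diet is None or cov is None:
        raise ValueError("full pipeline requires per-individual diet and covariates")

    consolidated: dict = {"seed": cfg.seed, "season": diet.season}

    gates = _stage_anosim(cfg, diet, cov, avail, out)
    consolidated["anosim"] = gates
    if "site" in gates and gates["site"]["p"] < cfg.anosim_alpha:
        raise MergeRefusedError(
            f"site ANOSIM significant (R={gates['site']['R']:.3f}, "
            f"p={gates['site']['p']:.3f} < {cfg.anosim_alpha}); the two "
            "populations differ in diet composition and must not be pooled"
        )

    consolidated["diversity"] = _stage_diversity(cfg, diet, cov, avail, out)
    consolidated["strategy"] = _stage_strategy(cfg, diet, cov, avail, out)
    if avail is not None:
        consolidated["electivity"] = _stage_electivity(cfg, diet, cov, avail, out)
    consolidated["condition"] = _stage_condition(cfg, diet, cov, avail, out)
    if avail is not None:
        consolidated["rspf"] = _stage_rspf(cfg, diet, cov, avail, out)
    consolidated["niche"] = _stage_niche(cfg, diet, cov, avail, out)

    _dump_json(consolidated, out / "consolidated.json")
    return consolidated
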