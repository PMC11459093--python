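"""End-to-end orchestration: from inputs (or a synthetic scenario) to the
report bundle.

``run_all`` chains every stage — tree pruning, per-plot diversity, NRI/NTI
null models, AGB accounting, trend fits, stage ANOVA with Duncan letters,
mixed models, variance partitioning, and PLS path modeling — and writes tidy
CSV outputs plus a JSON run manifest (seed, version, config hash, record
counts)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomass import AllometryRegistry, agb_table
from .chronostats import duncan_letters, fit_trend, normalize_transform
from .diversity import community_diversity
from .inference import PLSPathModel, fit_mixed, variance_partition
from .io import read_harvest, read_plots, read_stems, read_survey
from .nullmodels import NullModelConfig, ses_table
from .synthetic import ScenarioConfig, simulate_study
from .trees import Phylogeny, read_newick

__all__ = ["RunConfig", "PipelineResult", "run_all", "summarize_composition"]

logger = logging.getLogger(__name__)

LEVELS = ("total", "herb", "woody")
PREDICTORS = ("PD", "PSR", "PSE", "NRI", "NTI")


@dataclass
class RunConfig:
    """Inputs and options for a full pipeline run.

    Provide either the four input paths (tree/survey/harvest + stems/plots/
    registry) or a synthetic ``scenario``; the master ``seed`` drives every
    stochastic stage."""

    tree_path: str | None = None
    survey_path: str | None = None
    stems_path: str | None = None
    harvest_path: str | None = None
    plots_path: str | None = None
    registry_path: str | None = None
    scenario: ScenarioConfig | None = None
    levels: tuple[str, ...] = LEVELS
    n_reps: int = 999
    pool_per_level: bool = True
    seed: int = 0
    include_direct_tvr_path: bool = False
    n_boot: int = 500
    out_dir: str | None = None

    def __post_init__(self):
        has_files = self.tree_path is not None and self.survey_path is not None
        if not has_files and self.scenario is None:
            self.scenario = ScenarioConfig(rng_seed=self.seed)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(dataclasses.asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All tables produced by one run."""

    diversity: pd.DataFrame
    ses: pd.DataFrame
    agb: pd.DataFrame
    trends: pd.DataFrame
    anova: pd.DataFrame
    mixed_models: pd.DataFrame
    vpa: pd.DataFrame
    plspm_paths: pd.DataFrame
    plspm_summary: dict
    composition: pd.DataFrame
    manifest: dict
    plot_table: pd.DataFrame = field(repr=False, default=None)


def _round_half_up(x: float, digits: int = 2) -> float:
    return float(Decimal(str(x)).quantize(Decimal("1." + "0" * digits),
                                          rounding=ROUND_HALF_UP))


def summarize_composition(
    survey: pd.DataFrame,
    categories: tuple[str, ...] = ("ecological_type", "life_form"),
) -> pd.DataFrame:
    """Species counts and percentages per category column of the survey.

    Each species is counted once (its first tagging); percentages are of the
    distinct species total, rounded half-up to 2 decimals.  Missing category
    columns are skipped with a warning.
    """
    rows = []
    per_species = survey.drop_duplicates("species")
    n_species = len(per_species)
    for cat in categories:
        if cat not in survey.columns:
            logger.warning("survey has no %r column; category skipped", cat)
            continue
        counts = per_species.groupby(cat)["species"].count().sort_values(ascending=False)
        for value, n in counts.items():
            rows.append({
                "category": cat, "value": value, "n_species": int(n),
                "percent": _round_half_up(100.0 * n / n_species),
            })
    return pd.DataFrame(rows)


def _wide_scores(ses: pd.DataFrame) -> pd.DataFrame:
    w = ses.pivot_table(index=["plot_id", "level"], columns="metric",
                        values="score", aggfunc="first").reset_index()
    w.columns.name = None
    return w


def run_all(config: RunConfig) -> PipelineResult:
    """Execute the full analysis chain; see the module docstring."""
    stage = "inputs"
    try:
        if config.scenario is not None:
            study = simulate_study(config.scenario)
            tree, survey = study.tree, study.survey
            stems, harvest, plots = study.stems, study.harvest, study.plots
            registry = study.registry
        else:
            tree = read_newick(config.tree_path)
            survey = read_survey(config.survey_path)
            stems = read_stems(config.stems_path) if config.stems_path else pd.DataFrame(
                columns=["plot_id", "species", "dbh_cm"])
            harvest = read_harvest(config.harvest_path) if config.harvest_path else pd.DataFrame(
                columns=["plot_id", "kind", "dry_mass_g", "box_area_m2"])
            plots = read_plots(config.plots_path) if config.plots_path else (
                survey[["plot_id", "stage_years"]].drop_duplicates().assign(plot_area_m2=1.0))
            registry = (AllometryRegistry.read_csv(config.registry_path)
                        if config.registry_path else None)

        stage = "prune"
        observed = sorted(survey.loc[survey["abundance"] > 0, "species"].unique())
        missing = set(observed) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"species absent from phylogeny: {sorted(missing)[:5]}…")
        tree = tree.prune(observed)

        stage = "diversity"
        div = community_diversity(tree, survey, levels=config.levels)

        stage = "structure"
        nm = NullModelConfig(n_reps=config.n_reps, rng_seed=config.seed)
        ses = ses_table(tree, survey, levels=config.levels, config=nm,
                        pool_per_level=config.pool_per_level)

        stage = "biomass"
        agb = agb_table(stems, harvest, registry or _minimal_registry(), plots)

        stage = "stats"
        trend_rows = []
        for level in config.levels:
            sub = div[div["level"] == level]
            for metric in ("PD", "PSR", "PSE"):
                vals = sub[["stage_years", metric]].dropna()
                if vals["stage_years"].nunique() < 4:
                    continue
                tf = fit_trend(vals["stage_years"], vals[metric], degree=2,
                               response=f"{level}:{metric}")
                trend_rows.append({
                    "level": level, "metric": metric,
                    "coef2": tf.coefficients[0], "coef1": tf.coefficients[1],
                    "coef0": tf.coefficients[2], "r2": tf.r2,
                    "p_value": tf.p_value, "peak_tvr": tf.peak_tvr,
                })
        trends = pd.DataFrame(trend_rows)

        anova_rows = []
        scores = _wide_scores(ses)
        for level in config.levels:
            sub = scores[scores["level"] == level].merge(
                plots[["plot_id", "stage_years"]], on="plot_id")
            for metric in ("NRI", "NTI"):
                if metric not in sub.columns:
                    continue
                groups = {
                    s: g[metric].dropna().to_numpy()
                    for s, g in sub.groupby("stage_years")
                }
                groups = {s: v for s, v in groups.items() if v.size >= 2}
                if len(groups) < 2:
                    logger.warning("level %s %s: too few stages for ANOVA", level, metric)
                    continue
                gc = duncan_letters(groups)
                for s in groups:
                    anova_rows.append({
                        "variable": metric, "level": level, "stage_years": s,
                        "mean": gc.means[s], "letters": gc.letters[s],
                        "F": gc.F, "p_value": gc.p_value,
                    })
        agb_groups = {s: g["total_agb"].to_numpy() for s, g in agb.groupby("stage_years")}
        gc = duncan_letters({s: v for s, v in agb_groups.items() if v.size >= 2})
        for s in gc.means:
            anova_rows.append({
                "variable": "AGB", "level": "total", "stage_years": s,
                "mean": gc.means[s], "letters": gc.letters[s],
                "F": gc.F, "p_value": gc.p_value,
            })
        anova = pd.DataFrame(anova_rows)

        stage = "models"
        merged = {}
        for level in config.levels:
            d = div[div["level"] == level][
                ["plot_id", "stage_years", "PD", "PSR", "PSE"]]
            s = scores[scores["level"] == level][["plot_id", "NRI", "NTI"]] \
                if "NRI" in scores.columns else None
            m = d.merge(s, on="plot_id", how="inner") if s is not None else d
            m = m.merge(agb[["plot_id", "total_agb"]], on="plot_id")
            merged[level] = m.dropna()

        mixed_rows = []
        for level in config.levels:
            m = merged[level]
            if len(m) < 10 or m["stage_years"].nunique() < 2:
                logger.warning("level %s: too few complete plots for mixed model", level)
                continue
            y, method, _ = normalize_transform(m["total_agb"].to_numpy())
            m = m.assign(agb_t=y)
            res = fit_mixed(m, "agb_t", list(PREDICTORS), level=level)
            row = {"level": level, "AIC": res.aic, "R2m": res.r2_marginal,
                   "R2c": res.r2_conditional, "transform": method,
                   "boundary_fit": res.boundary_fit}
            for k in PREDICTORS:
                row[f"t_{k}"] = res.t_values[k]
                row[f"sig_{k}"] = res.significant[k]
            mixed_rows.append(row)
        mixed = pd.DataFrame(mixed_rows)

        vpa_rows = []
        plspm_paths = pd.DataFrame()
        plspm_summary: dict = {}
        mw = merged.get("woody", pd.DataFrame())
        if len(mw) > 10:
            yw, method, _ = normalize_transform(mw["total_agb"].to_numpy())
            mw = mw.assign(agb_t=yw)
            v = variance_partition(mw, "agb_t", ["PD", "PSE"], ["NRI"])
            expl = v.adj_r2_full if v.adj_r2_full > 0 else np.nan
            vpa_rows.append({
                "level": "woody",
                "unique_WPD": v.unique1, "unique_WPS": v.unique2,
                "shared": v.shared, "residual": v.residual,
                "adj_r2_full": v.adj_r2_full,
                "unique_WPD_of_explained": v.unique1 / expl,
                "unique_WPS_of_explained": v.unique2 / expl,
                "shared_of_explained": v.shared / expl,
            })
            blocks = {"TVR": ["stage_years"], "WPD": ["PD", "PSE"],
                      "WPS": ["NRI"], "AGB": ["agb_t"]}
            paths = [("TVR", "WPD"), ("TVR", "WPS"), ("WPD", "AGB"), ("WPS", "AGB")]
            if config.include_direct_tvr_path:
                paths.append(("TVR", "AGB"))
            model = PLSPathModel(blocks, paths).fit(mw)
            if config.n_boot:
                model.bootstrap(n_boot=config.n_boot, seed=config.seed)
            r = model.result()
            rows = []
            for tgt in r.path_coefficients.index:
                for src in r.path_coefficients.columns:
                    b = r.path_coefficients.loc[tgt, src]
                    if np.isnan(b):
                        continue
                    rows.append({
                        "source": src, "target": tgt, "coefficient": b,
                        "boot_se": None if r.boot_se is None else r.boot_se.loc[tgt, src],
                        "boot_p": None if r.boot_p is None else r.boot_p.loc[tgt, src],
                    })
            plspm_paths = pd.DataFrame(rows)
            plspm_summary = {
                "gof": r.gof, "r2": r.r2, "communalities": r.communalities,
                "n_iter": r.n_iter,
            }
        vpa = pd.DataFrame(vpa_rows)

        stage = "report"
        composition = summarize_composition(survey)
        manifest = {
            "seed": config.seed,
            "version": __version__,
            "config_hash": config.config_hash(),
            "n_plots": int(plots["plot_id"].nunique()),
            "n_species": int(survey["species"].nunique()),
            "n_reps": config.n_reps,
            "levels": list(config.levels),
            "tables": {
                "diversity": len(div), "ses": len(ses), "agb": len(agb),
                "trends": len(trends), "anova": len(anova),
                "mixed_models": len(mixed), "vpa": len(vpa),
                "plspm_paths": len(plspm_paths),
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        diversity=div, ses=ses, agb=agb, trends=trends, anova=anova,
        mixed_models=mixed, vpa=vpa, plspm_paths=plspm_paths,
        plspm_summary=plspm_summary, composition=composition,
        manifest=manifest, plot_table=plots,
    )
    if config.out_dir:
        _write_bundle(result, config.out_dir)
    return result


def _minimal_registry() -> AllometryRegistry:
    from .biomass import AllometricModel
    return AllometryRegistry([AllometricModel("default_woody", "power_d", 0.08, 2.45)])


def _write_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.diversity.to_csv(out / "diversity.csv", index=False)
    result.ses.to_csv(out / "ses.csv", index=False)
    result.agb.to_csv(out / "agb.csv", index=False)
    result.trends.to_csv(out / "trends.csv", index=False)
    result.anova.to_csv(out / "anova_duncan.csv", index=False)
    result.mixed_models.to_csv(out / "mixed_models.csv", index=False)
    result.vpa.to_csv(out / "vpa.csv", index=False)
    result.plspm_paths.to_csv(out / "plspm_paths.csv", index=False)
    result.composition.to_csv(out / "composition.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({**result.manifest, "plspm": result.plspm_summary}, fh,
                  indent=2, default=float)
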