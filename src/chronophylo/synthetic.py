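"""Synthetic chronosequence studies with known ground truth.

Generates everything the analysis pipeline consumes — an ultrametric
phylogeny, plot survey tables, woody stem lists, harvest-box dry masses, and
an allometric registry — for a recovery chronosequence shaped like the field
design the package targets: 8 recovery stages (0–150 years) x 6 plots, a
~130-species pool, herb-dominated early stages and woody-dominated late
stages.

The assembly model encodes the two textbook processes:

* environmental filtering — species are sampled with Gaussian weights around
  a stage-specific trait optimum on a Brownian trait, so strong filtering
  (small ``sigma_f``) draws close relatives and produces phylogenetic
  aggregation (NRI > 0);
* competition / limiting similarity — with stage-specific probability the
  less-abundant member of the phylogenetically closest pair is replaced by a
  distant species, producing dispersion (NRI < 0).

Filtering dominates the early/middle stages and competition the late stages,
so the default scenario yields a unimodal PD trend, an aggregation-to-
dispersion NRI trajectory over the late stages, and an AGB trajectory that
peaks at stage 135 (a two-dominant mixed forest) and declines at stage 150
(a single-dominant forest).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomass import LITTER_BOX_AREA_M2, AllometricModel, AllometryRegistry
from .trees import Phylogeny

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SyntheticStudy",
    "simulate_phylogeny",
    "assign_traits",
    "assemble_community",
    "simulate_study",
    "simulate_path_data",
    "default_registry",
]

STAGES = (0, 10, 20, 40, 70, 120, 135, 150)


def _stage_map(values) -> dict[int, float]:
    return dict(zip(STAGES, values))


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study; defaults are the standard scenario.

    Schedules are dicts keyed by stage year.  ``filtering_sigma`` is the
    Gaussian niche width of the environmental filter (smaller = stronger
    filtering, trait units where the Brownian trait has variance ~1);
    ``competition`` is the per-round replacement probability of the
    limiting-similarity step.  AGB component targets are g/m² of dry mass.
    """

    rng_seed: int = 0
    pool_size: int = 130
    stages: tuple[int, ...] = STAGES
    plots_per_stage: int = 6
    herb_fraction_pool: float = 79 / 128  # herb share of the species pool
    brownian_sigma: float = 1.0
    richness: dict[int, int] = field(
        default_factory=lambda: _stage_map((6, 10, 14, 18, 22, 24, 20, 16)))
    woody_fraction: dict[int, float] = field(
        default_factory=lambda: _stage_map((0.0, 0.0, 0.0, 0.35, 0.5, 0.65, 0.7, 0.75)))
    filtering_sigma: dict[int, float] = field(
        default_factory=lambda: _stage_map((3.0, 2.0, 1.0, 0.4, 0.25, 0.2, 0.5, 0.8)))
    competition: dict[int, float] = field(
        default_factory=lambda: _stage_map((0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 0.95)))
    trait_optimum: dict[int, float] = field(
        default_factory=lambda: {s: -0.5 + 1.0 * s / 150.0 for s in STAGES})
    herb_target: dict[int, float] = field(
        default_factory=lambda: _stage_map((120, 290, 480, 600, 400, 250, 200, 150)))
    litter_target: dict[int, float] = field(
        default_factory=lambda: _stage_map((0, 10, 70, 300, 600, 900, 1000, 900)))
    agb_target: dict[int, float] = field(
        default_factory=lambda: _stage_map((120, 300, 550, 1800, 5200, 17500, 24200, 15500)))
    plot_area: dict[int, float] = field(
        default_factory=lambda: _stage_map((1, 1, 1, 100, 400, 400, 400, 400)))
    diameter_mean_cm: dict[int, float] = field(
        default_factory=lambda: _stage_map((0, 0, 0, 3, 8, 18, 24, 28)))
    diameter_cv: float = 0.3
    abundance_mu: float = 1.5  # lognormal log-mean of species abundances
    abundance_sigma: float = 1.0
    agb_noise_cv: float = 0.2
    n_boxes: int = 3
    #: inner path coefficients of the latent recovery->diversity->AGB model,
    #: used by :func:`simulate_path_data` for parameter-recovery studies
    path_coefficients: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("TVR", "WPD"): 0.7,
            ("TVR", "WPS"): -0.5,
            ("WPD", "AGB"): 0.6,
            ("WPS", "AGB"): -0.35,
        })

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        for s in self.stages:
            for sched in (self.richness, self.woody_fraction, self.filtering_sigma,
                          self.competition, self.trait_optimum, self.herb_target,
                          self.litter_target, self.agb_target, self.plot_area,
                          self.diameter_mean_cm):
                if s not in sched:
                    raise ValueError(f"schedule missing stage {s}")
        if max(self.richness.values()) > self.pool_size:
            raise ValueError("richness schedule exceeds pool size")


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring recovery downstream."""

    trait_optima: dict[int, float]
    filtering_sigma: dict[int, float]
    competition: dict[int, float]
    assembly_mode: dict[int, str]
    agb_target: dict[int, float]
    dominants: dict[int, tuple[str, ...]]
    path_coefficients: dict[tuple[str, str], float]
    traits: pd.DataFrame


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *tags)))


# ---------------------------------------------------------------------------
# Phylogeny and traits
# ---------------------------------------------------------------------------


def simulate_phylogeny(pool_size: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree rescaled to unit root depth.

    Tips are labelled ``sp001``…; identical seeds give byte-identical Newick.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    rng = _rng(seed, 101)
    t = 0.0
    root_children = [{"birth": 0.0}, {"birth": 0.0}]
    active = list(root_children)
    while len(active) < pool_size:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        node["split"] = t
        c1, c2 = {"birth": t}, {"birth": t}
        node["children"] = [c1, c2]
        active[i] = c1
        active.append(c2)
    total = t + rng.exponential(1.0 / pool_size)

    counter = [0]

    def render(node: dict) -> str:
        end = node.get("split", total)
        length = (end - node["birth"]) / total
        if "children" in node:
            left, right = node["children"]
            return f"({render(left)},{render(right)}):{length:.10f}"
        counter[0] += 1
        return f"sp{counter[0]:03d}:{length:.10f}"

    newick = f"({render(root_children[0])},{render(root_children[1])});"
    return Phylogeny.from_newick(newick)


def assign_traits(
    tree: Phylogeny,
    brownian_sigma: float = 1.0,
    seed: int = 0,
    herb_fraction: float = 79 / 128,
) -> pd.DataFrame:
    """Brownian-motion traits and clade-clumped life forms for every tip.

    Column ``trait`` is the filtering trait; ``life_form`` ("herb"/"woody")
    comes from thresholding a second, independent Brownian trait at the
    ``herb_fraction`` quantile, so life forms aggregate within clades.
    """
    rng = _rng(seed, 202)
    root = tree.tree.seed_node
    vals: dict[int, np.ndarray] = {id(root): np.zeros(2)}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent = vals[id(node.parent_node)]
        step = rng.normal(0.0, 1.0, size=2) * brownian_sigma * np.sqrt(node.edge.length)
        vals[id(node)] = parent + step
    rows = {
        leaf.taxon.label: vals[id(leaf)]
        for leaf in tree.tree.leaf_node_iter()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["trait", "lf_trait"])
    df = df.loc[list(tree.tip_labels)]
    thresh = df["lf_trait"].quantile(herb_fraction)
    df["life_form"] = np.where(df["lf_trait"] <= thresh, "herb", "woody")
    return df


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------


def _weighted_sample_without_replacement(
    rng: np.random.Generator, candidates: list[str], weights: np.ndarray, k: int
) -> list[str]:
    w = np.asarray(weights, dtype=float)
    w = np.clip(w, 1e-300, None)
    chosen: list[str] = []
    cand = list(candidates)
    w = w.copy()
    for _ in range(k):
        p = w / w.sum()
        i = int(rng.choice(len(cand), p=p))
        chosen.append(cand.pop(i))
        w = np.delete(w, i)
    return chosen


def assemble_community(
    stage: int,
    tree: Phylogeny,
    traits: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator,
    force_include: tuple[str, ...] = (),
) -> dict[str, int]:
    """One plot's species -> abundance map for the given recovery stage.

    Filtering step: within each life form, sample without replacement with
    weights ``exp(-(trait - optimum)^2 / (2 sigma_f^2))``.  Competition step:
    for each of ``k`` rounds, with probability ``c(stage)`` the less-abundant
    member of the phylogenetically closest pair is replaced by the available
    species (same life form) farthest from the community.  Abundances are
    lognormal, rounded up to at least 1.
    """
    k = int(config.richness[stage])
    wf = float(config.woody_fraction[stage])
    sigma = float(config.filtering_sigma[stage])
    c = float(config.competition[stage])
    opt = float(config.trait_optimum[stage])

    n_woody = int(round(k * wf))
    n_herb = k - n_woody
    chosen: list[str] = []
    for life_form, n_pick in (("herb", n_herb), ("woody", n_woody)):
        pool = traits.index[traits["life_form"] == life_form].tolist()
        forced = [s for s in force_include if s in pool][:n_pick]
        pool = [s for s in pool if s not in forced]
        n_draw = n_pick - len(forced)
        if n_draw > len(pool):
            raise ValueError(
                f"stage {stage}: cannot draw {n_pick} {life_form} species "
                f"from a pool of {len(pool) + len(forced)}"
            )
        tr = traits.loc[pool, "trait"].to_numpy()
        weights = np.exp(-((tr - opt) ** 2) / (2.0 * sigma * sigma))
        chosen += forced + _weighted_sample_without_replacement(rng, pool, weights, n_draw)

    abundance = {
        sp: max(1, int(round(float(rng.lognormal(config.abundance_mu,
                                                 config.abundance_sigma)))))
        for sp in chosen
    }

    if c > 0 and len(chosen) >= 3:
        D = tree.patristic_matrix
        protected = set(force_include)
        for _ in range(k):
            if rng.random() >= c:
                continue
            idx = tree.indices_of(list(abundance))
            sub = D[np.ix_(idx, idx)].astype(float)
            np.fill_diagonal(sub, np.inf)
            i, j = np.unravel_index(np.argmin(sub), sub.shape)
            names = list(abundance)
            pair = sorted((names[i], names[j]), key=lambda s: (abundance[s], s))
            loser = next((s for s in pair if s not in protected), None)
            if loser is None:
                continue
            lf = traits.loc[loser, "life_form"]
            candidates = [
                s for s in traits.index[traits["life_form"] == lf]
                if s not in abundance
            ]
            if not candidates:
                continue
            comm_idx = tree.indices_of([s for s in abundance if s != loser])
            cand_idx = tree.indices_of(candidates)
            mind = D[np.ix_(cand_idx, comm_idx)].min(axis=1)
            newcomer = candidates[int(np.argmax(mind))]
            del abundance[loser]
            abundance[newcomer] = max(
                1, int(round(float(rng.lognormal(config.abundance_mu,
                                                 config.abundance_sigma)))))
    return abundance


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def default_registry(dominants: dict[int, tuple[str, ...]]) -> AllometryRegistry:
    """Editable placeholder allometric registry used by the generator.

    A generic woody power law plus species-specific (component-split)
    equations for the late-stage dominants.  Coefficients are documented
    placeholders on the scale of temperate-forest allometries, not literature
    values.
    """
    models = [
        AllometricModel("default_woody", "power_d", 0.08, 2.45),
    ]
    names = sorted({s for pair in dominants.values() for s in pair})
    for i, sp in enumerate(names):
        if i == 0:
            # component-split equation exercising the summed-piecewise form
            models += [
                AllometricModel(sp, "power_d", 0.060, 2.45, "stem"),
                AllometricModel(sp, "power_d", 0.018, 2.45, "branch"),
                AllometricModel(sp, "power_d", 0.007, 2.45, "leaf"),
            ]
        else:
            models.append(AllometricModel(sp, "power_d", 0.09 + 0.01 * (i % 3), 2.42))
    return AllometryRegistry(models)


@dataclass
class SyntheticStudy:
    """A complete generated study plus its ground truth."""

    tree: Phylogeny
    traits: pd.DataFrame
    survey: pd.DataFrame
    stems: pd.DataFrame
    harvest: pd.DataFrame
    plots: pd.DataFrame
    registry: AllometryRegistry
    ground_truth: GroundTruth
    config: ScenarioConfig

    def write(self, out_dir) -> dict[str, Path]:
        """Write the study as the file set the pipeline readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": out / "tree.nwk",
            "survey": out / "survey.csv",
            "stems": out / "stems.csv",
            "harvest": out / "harvest.csv",
            "plots": out / "plots.csv",
            "registry": out / "registry.csv",
        }
        self.tree.write(paths["tree"])
        self.survey.to_csv(paths["survey"], index=False)
        self.stems.to_csv(paths["stems"], index=False)
        self.harvest.to_csv(paths["harvest"], index=False)
        self.plots.to_csv(paths["plots"], index=False)
        self.registry.to_frame().to_csv(paths["registry"], index=False)
        return paths


def _pick_dominants(tree: Phylogeny, traits: pd.DataFrame) -> dict[int, tuple[str, ...]]:
    """Two phylogenetically distant woody dominants for stage 135, one for 150."""
    woody = traits.index[traits["life_form"] == "woody"].tolist()
    idx = tree.indices_of(woody)
    D = tree.patristic_matrix[np.ix_(idx, idx)]
    i, j = np.unravel_index(np.argmax(D), D.shape)
    a, b = woody[int(i)], woody[int(j)]
    return {135: (a, b), 150: (b,)}


def simulate_study(config: ScenarioConfig | None = None, out_dir=None) -> SyntheticStudy:
    """Generate a complete synthetic chronosequence study.

    Deterministic for a fixed config: every random sub-step derives its RNG
    stream from ``config.rng_seed`` and a fixed tag, so outputs are
    byte-identical across runs and independent of iteration order.
    """
    config = config or ScenarioConfig()
    seed = config.rng_seed
    tree = simulate_phylogeny(config.pool_size, seed)
    traits = assign_traits(tree, config.brownian_sigma, seed,
                           herb_fraction=config.herb_fraction_pool)
    dominants = _pick_dominants(tree, traits)
    registry = default_registry(dominants)

    eco_rng = _rng(seed, 303)
    eco = pd.Series(
        eco_rng.choice(["mesophyte", "xerophyte", "hygrophyte"],
                       size=tree.n_tips, p=[0.70, 0.19, 0.11]),
        index=list(tree.tip_labels),
    )
    detail_rng = _rng(seed, 304)
    detail_choices = {"herb": ["herb"], "woody": ["bush", "arbor", "bush_or_arbor", "liana"]}
    life_form_detail = pd.Series(
        [
            traits.loc[sp, "life_form"] if traits.loc[sp, "life_form"] == "herb"
            else detail_rng.choice(detail_choices["woody"], p=[0.38, 0.34, 0.2, 0.08])
            for sp in tree.tip_labels
        ],
        index=list(tree.tip_labels),
    )

    survey_rows, stem_rows, harvest_rows, plot_rows = [], [], [], []
    for si, stage in enumerate(config.stages):
        for p in range(config.plots_per_stage):
            plot_id = f"S{stage:03d}P{p + 1}"
            rng = _rng(seed, 1000 + si * 100 + p)
            force = dominants.get(stage, ())
            community = assemble_community(stage, tree, traits, config, rng,
                                           force_include=force)
            area = float(config.plot_area[stage])
            plot_rows.append({"plot_id": plot_id, "stage_years": stage,
                              "plot_area_m2": area})

            # harvest boxes
            def boxes(kind, target, box_area):
                for b in range(config.n_boxes):
                    noise = rng.lognormal(-0.5 * np.log(1 + config.agb_noise_cv ** 2),
                                          np.sqrt(np.log(1 + config.agb_noise_cv ** 2)))
                    mass = max(0.0, target * box_area * noise)
                    harvest_rows.append({
                        "plot_id": plot_id, "kind": kind, "box_id": b + 1,
                        "dry_mass_g": round(float(mass), 3),
                        "box_area_m2": box_area,
                    })
            boxes("herb", float(config.herb_target[stage]), 1.0)
            if config.litter_target[stage] > 0:
                boxes("litter", float(config.litter_target[stage]), LITTER_BOX_AREA_M2)

            # woody stems: add trees until the plot reaches its biomass target
            woody_target = max(
                0.0,
                float(config.agb_target[stage] - config.herb_target[stage]
                      - config.litter_target[stage]),
            )
            woody_species = [s for s in community if traits.loc[s, "life_form"] == "woody"]
            stem_counts = {s: 0 for s in woody_species}
            if woody_target > 0 and woody_species:
                noise = rng.lognormal(-0.5 * np.log(1 + config.agb_noise_cv ** 2),
                                      np.sqrt(np.log(1 + config.agb_noise_cv ** 2)))
                target_kg = woody_target * noise * area / 1000.0
                dmean = float(config.diameter_mean_cm[stage])
                sig = np.sqrt(np.log(1 + config.diameter_cv ** 2))
                mu = np.log(dmean) - 0.5 * sig * sig
                # dominants carry ~75% of the stems at the late stages
                dom = [s for s in dominants.get(stage, ()) if s in stem_counts]
                others = [s for s in woody_species if s not in dom]
                if dom and others:
                    w = np.array([
                        0.75 / len(dom) if s in dom else 0.25 / len(others)
                        for s in woody_species
                    ])
                else:
                    w = np.ones(len(woody_species)) / len(woody_species)
                total_kg, stem_no = 0.0, 0
                while total_kg < target_kg and stem_no < 10000:
                    sp = woody_species[int(rng.choice(len(woody_species), p=w))]
                    d = float(rng.lognormal(mu, sig))
                    d = max(d, 0.5)
                    kg = registry.biomass(sp, d)
                    stem_no += 1
                    stem_counts[sp] += 1
                    total_kg += kg
                    stem_rows.append({
                        "plot_id": plot_id, "species": sp,
                        "stem_id": stem_no, "dbh_cm": round(d, 2),
                    })

            for sp in sorted(community):
                lf = traits.loc[sp, "life_form"]
                ab = stem_counts.get(sp, 0) if lf == "woody" else community[sp]
                if lf == "woody" and ab == 0:
                    ab = community[sp] if woody_target == 0 else 1
                survey_rows.append({
                    "plot_id": plot_id, "stage_years": stage, "species": sp,
                    "abundance": int(ab), "level": lf,
                    "life_form": life_form_detail[sp],
                    "ecological_type": eco[sp],
                })

    truth = GroundTruth(
        trait_optima=dict(config.trait_optimum),
        filtering_sigma=dict(config.filtering_sigma),
        competition=dict(config.competition),
        assembly_mode={
            s: ("competition" if config.competition[s] >= 0.5
                else "filtering" if config.filtering_sigma[s] <= 1.0
                else "neutral")
            for s in config.stages
        },
        agb_target=dict(config.agb_target),
        dominants=dominants,
        path_coefficients=dict(config.path_coefficients),
        traits=traits,
    )
    study = SyntheticStudy(
        tree=tree, traits=traits,
        survey=pd.DataFrame(survey_rows),
        stems=pd.DataFrame(stem_rows),
        harvest=pd.DataFrame(harvest_rows),
        plots=pd.DataFrame(plot_rows),
        registry=registry, ground_truth=truth, config=config,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study


def simulate_path_data(
    coefficients: dict[tuple[str, str], float] | None = None,
    n: int = 48,
    seed: int = 0,
    n_stages: int = 8,
) -> pd.DataFrame:
    """Draw plot-level data from the latent recovery->diversity->AGB path model.

    Latents: TVR (recovery time), WPD (phylogenetic diversity, indicators PD
    and PSE), WPS (phylogenetic structure, indicator NRI), AGB.  Structural
    residuals make each endogenous latent unit-variance.  Used for
    parameter-recovery checks of the PLS path model.
    """
    coeffs = coefficients or ScenarioConfig().path_coefficients
    rng = _rng(seed, 909)
    stages = np.repeat(np.linspace(-1.5, 1.5, n_stages), int(np.ceil(n / n_stages)))[:n]
    tvr = (stages - stages.mean()) / stages.std(ddof=1)
    def resid(explained):
        return np.sqrt(max(1e-9, 1.0 - explained))
    b_tw = coeffs[("TVR", "WPD")]
    b_ts = coeffs[("TVR", "WPS")]
    b_wa = coeffs[("WPD", "AGB")]
    b_sa = coeffs[("WPS", "AGB")]
    wpd = b_tw * tvr + resid(b_tw ** 2) * rng.normal(size=n)
    wps = b_ts * tvr + resid(b_ts ** 2) * rng.normal(size=n)
    var_agb = b_wa ** 2 + b_sa ** 2 + 2 * b_wa * b_sa * b_tw * b_ts
    agb = b_wa * wpd + b_sa * wps + resid(var_agb) * rng.normal(size=n)
    pd_ind = 0.95 * wpd + np.sqrt(1 - 0.95 ** 2) * rng.normal(size=n)
    pse_ind = 0.85 * wpd + np.sqrt(1 - 0.85 ** 2) * rng.normal(size=n)
    return pd.DataFrame({
        "tvr": tvr, "PD": pd_ind, "PSE": pse_ind, "NRI": wps, "agb": agb,
        "stage": np.repeat(np.arange(n_stages), int(np.ceil(n / n_stages)))[:n],
    })
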