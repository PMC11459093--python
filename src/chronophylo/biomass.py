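"""Plot-level aboveground biomass (AGB) accounting.

AGB (g/m²) is the sum of three components:

* herbaceous biomass — complete-harvest dry mass from 1 m² sampling boxes,
* surface litter — dry mass from 31.7 cm x 31.7 cm boxes (0.100489 m²),
* woody biomass — per-individual dry mass from species-specific allometric
  equations summed over the plot and divided by plot area.

Allometric models are kept in an editable CSV registry
(taxon, form, a, b, component, D_unit, H_unit, source).  Supported forms:

* ``power_d``     B = a * D**b
* ``power_d2h``   B = a * (D**2 * H)**b
* ``log_power``   ln(B) = a + b * ln(D), i.e. B = exp(a) * D**b

with D in cm, H in m, B in kg dry mass per individual.  A taxon may have
several component rows (stem/branch/leaf) which are summed.  Lookup falls
back species -> genus -> life-form default, and every fallback is logged.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HERB_BOX_AREA_M2",
    "LITTER_BOX_AREA_M2",
    "AllometricModel",
    "AllometryRegistry",
    "HarvestSample",
    "AGBRecord",
    "density_from_boxes",
    "individual_biomass",
    "plot_agb",
    "agb_table",
]

logger = logging.getLogger(__name__)

HERB_BOX_AREA_M2 = 1.0
#: 0.317 m x 0.317 m litter box
LITTER_BOX_AREA_M2 = 0.317 * 0.317

_FORMS = ("power_d", "power_d2h", "log_power")


@dataclass(frozen=True)
class AllometricModel:
    """One allometric equation (possibly one component of several)."""

    taxon: str
    form: str
    a: float
    b: float
    component: str = "total"

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown allometric form {self.form!r}")
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError(f"non-finite coefficients for {self.taxon}")

    def predict(self, D: float, H: float | None = None) -> float:
        """Dry biomass in kg for stem diameter D (cm) and height H (m)."""
        if D <= 0:
            raise ValueError(f"stem diameter must be positive (got {D})")
        if self.form == "power_d":
            return self.a * D ** self.b
        if self.form == "log_power":
            return math.exp(self.a) * D ** self.b
        if H is None:
            raise ValueError(
                f"allometric form power_d2h for {self.taxon!r} requires height H"
            )
        if H <= 0:
            raise ValueError(f"height must be positive (got {H})")
        return self.a * (D * D * H) ** self.b


def individual_biomass(
    models: "AllometricModel | Sequence[AllometricModel]",
    D: float,
    H: float | None = None,
) -> float:
    """Evaluate one or several component models and sum (kg per individual)."""
    if isinstance(models, AllometricModel):
        models = [models]
    if not models:
        raise ValueError("no allometric model supplied")
    return float(sum(m.predict(D, H) for m in models))


class AllometryRegistry:
    """Taxon-keyed collection of allometric equations with group fallback.

    Fallback chain for an unknown taxon: full name -> genus (the part of the
    label before the first underscore) -> ``default_<life_form>``.
    """

    def __init__(self, models: Iterable[AllometricModel]):
        self._by_taxon: dict[str, list[AllometricModel]] = {}
        for m in models:
            self._by_taxon.setdefault(m.taxon, []).append(m)
        if not self._by_taxon:
            raise ValueError("empty allometric registry")

    @classmethod
    def read_csv(cls, path) -> "AllometryRegistry":
        df = pd.read_csv(path)
        required = {"taxon", "form", "a", "b"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry missing columns: {sorted(missing)}")
        models = [
            AllometricModel(
                taxon=str(r.taxon),
                form=str(r.form),
                a=float(r.a),
                b=float(r.b),
                component=str(getattr(r, "component", "total") or "total"),
            )
            for r in df.itertuples()
        ]
        return cls(models)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": m.taxon, "form": m.form, "a": m.a, "b": m.b,
             "component": m.component, "D_unit": "cm", "H_unit": "m",
             "source": "registry"}
            for ms in self._by_taxon.values()
            for m in ms
        ]
        return pd.DataFrame(rows)

    def lookup(self, taxon: str, life_form: str = "woody") -> list[AllometricModel]:
        if taxon in self._by_taxon:
            return self._by_taxon[taxon]
        genus = taxon.split("_")[0]
        if genus != taxon and genus in self._by_taxon:
            logger.info("allometry fallback %s -> genus %s", taxon, genus)
            return self._by_taxon[genus]
        default = f"default_{life_form}"
        if default in self._by_taxon:
            logger.info("allometry fallback %s -> %s", taxon, default)
            return self._by_taxon[default]
        raise KeyError(
            f"no allometric model for taxon {taxon!r} (no genus or "
            f"{default!r} fallback in registry)"
        )

    def biomass(self, taxon: str, D: float, H: float | None = None,
                life_form: str = "woody") -> float:
        return individual_biomass(self.lookup(taxon, life_form), D, H)


@dataclass(frozen=True)
class HarvestSample:
    """One harvest box: complete-harvest dry mass over a known box area."""

    plot_id: object
    kind: str  # "herb" or "litter"
    dry_mass_g: float
    box_area_m2: float

    def __post_init__(self):
        if self.kind not in ("herb", "litter"):
            raise ValueError(f"harvest kind must be herb or litter, got {self.kind!r}")
        if self.dry_mass_g < 0:
            raise ValueError("dry mass must be nonnegative")
        if self.box_area_m2 <= 0:
            raise ValueError("box area must be positive")


def density_from_boxes(samples: Sequence[HarvestSample]) -> float:
    """Mean dry-mass density (g/m²) over a plot's harvest boxes of one kind."""
    if not samples:
        raise ValueError("density_from_boxes needs at least one sample")
    kinds = {s.kind for s in samples}
    plots = {s.plot_id for s in samples}
    if len(kinds) > 1:
        raise ValueError(f"mixed harvest kinds {sorted(kinds)} in one density")
    if len(plots) > 1:
        raise ValueError(f"mixed plots {sorted(map(str, plots))} in one density")
    return float(np.mean([s.dry_mass_g / s.box_area_m2 for s in samples]))


@dataclass(frozen=True)
class AGBRecord:
    """Per-plot biomass densities; total is exactly the sum of components."""

    plot_id: object
    stage_years: int | None
    herb_density: float
    woody_density: float
    litter_density: float
    plot_area_m2: float

    @property
    def total_agb(self) -> float:
        return self.herb_density + self.woody_density + self.litter_density


def plot_agb(
    plot_id,
    stems: pd.DataFrame | None,
    harvest: Sequence[HarvestSample],
    registry: AllometryRegistry | None,
    plot_area_m2: float,
    stage_years: int | None = None,
) -> AGBRecord:
    """Assemble one plot's AGB record.

    ``stems`` holds the woody individuals (columns ``species``, ``dbh_cm``,
    optional ``height_m``); ``harvest`` the herb and litter boxes.  Woody
    density is the summed individual dry mass (kg -> g) over plot area.
    """
    if plot_area_m2 <= 0:
        raise ValueError("plot area must be positive")
    herb_boxes = [s for s in harvest if s.kind == "herb"]
    litter_boxes = [s for s in harvest if s.kind == "litter"]
    herb = density_from_boxes(herb_boxes) if herb_boxes else 0.0
    litter = density_from_boxes(litter_boxes) if litter_boxes else 0.0

    woody = 0.0
    if stems is not None and len(stems):
        if registry is None:
            raise ValueError("woody stems present but no allometric registry given")
        has_h = "height_m" in stems.columns
        total_kg = 0.0
        for r in stems.itertuples():
            d = float(r.dbh_cm)
            if d < 0:
                raise ValueError(f"negative stem diameter {d} in plot {plot_id}")
            h = float(r.height_m) if has_h and pd.notna(r.height_m) else None
            total_kg += registry.biomass(str(r.species), d, h)
        woody = total_kg * 1000.0 / plot_area_m2

    if woody == 0.0 and herb == 0.0 and litter == 0.0:
        logger.warning("plot %s has zero aboveground biomass", plot_id)
    return AGBRecord(
        plot_id=plot_id,
        stage_years=stage_years,
        herb_density=herb,
        woody_density=woody,
        litter_density=litter,
        plot_area_m2=plot_area_m2,
    )


def agb_table(
    stems: pd.DataFrame,
    harvest: pd.DataFrame,
    registry: AllometryRegistry,
    plots: pd.DataFrame,
) -> pd.DataFrame:
    """AGB records for every plot in ``plots``.

    ``plots`` needs columns ``plot_id``, ``stage_years``, ``plot_area_m2``;
    ``harvest`` needs ``plot_id``, ``kind``, ``dry_mass_g``, ``box_area_m2``;
    ``stems`` needs ``plot_id``, ``species``, ``dbh_cm`` (optional
    ``height_m``).
    """
    rows = []
    stems_by_plot = dict(tuple(stems.groupby("plot_id"))) if len(stems) else {}
    for p in plots.itertuples():
        hb = harvest[harvest["plot_id"] == p.plot_id]
        samples = [
            HarvestSample(p.plot_id, str(r.kind), float(r.dry_mass_g),
                          float(r.box_area_m2))
            for r in hb.itertuples()
        ]
        rec = plot_agb(
            p.plot_id,
            stems_by_plot.get(p.plot_id),
            samples,
            registry,
            float(p.plot_area_m2),
            stage_years=int(p.stage_years),
        )
        rows.append(
            {
                "plot_id": rec.plot_id,
                "stage_years": rec.stage_years,
                "herb_density": rec.herb_density,
                "woody_density": rec.woody_density,
                "litter_density": rec.litter_density,
                "total_agb": rec.total_agb,
                "plot_area_m2": rec.plot_area_m2,
            }
        )
    return pd.DataFrame(rows)
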