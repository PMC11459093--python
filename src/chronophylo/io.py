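"""Readers for the pipeline's tabular inputs (tidy CSV schemas)."""

from __future__ import annotations

import pandas as pd

from .trees import normalize_label

__all__ = ["read_survey", "read_stems", "read_harvest", "read_plots"]


def _require(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")


def read_survey(path) -> pd.DataFrame:
    """One row per (plot, species): plot_id, stage_years, species, abundance, level."""
    df = pd.read_csv(path)
    _require(df, {"plot_id", "stage_years", "species", "abundance", "level"}, "survey")
    df["species"] = df["species"].map(normalize_label)
    if (df["abundance"] < 0).any():
        raise ValueError("survey abundances must be nonnegative")
    bad = set(df["level"]) - {"herb", "woody"}
    if bad:
        raise ValueError(f"survey level tags must be herb/woody, found {sorted(bad)}")
    return df


def read_stems(path) -> pd.DataFrame:
    """One row per woody individual: plot_id, species, dbh_cm (optional height_m)."""
    df = pd.read_csv(path)
    _require(df, {"plot_id", "species", "dbh_cm"}, "stems")
    df["species"] = df["species"].map(normalize_label)
    if (df["dbh_cm"] <= 0).any():
        raise ValueError("stem diameters must be positive")
    return df


def read_harvest(path) -> pd.DataFrame:
    """One row per harvest box: plot_id, kind, dry_mass_g, box_area_m2."""
    df = pd.read_csv(path)
    _require(df, {"plot_id", "kind", "dry_mass_g", "box_area_m2"}, "harvest")
    return df


def read_plots(path) -> pd.DataFrame:
    """One row per plot: plot_id, stage_years, plot_area_m2."""
    df = pd.read_csv(path)
    _require(df, {"plot_id", "stage_years", "plot_area_m2"}, "plots")
    return df
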