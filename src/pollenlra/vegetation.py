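"""Vegetation data handling: cover-scale conversion, taxonomic harmonisation,
taxon selection and regional observed vegetation (OBV) computation.

Regional plant cover is compiled from a land-cover map: each map category has
an area within a circular buffer around the site network, and a per-taxon
plant composition (percent cover, possibly summing past 100 for layered
vegetation).  The observed regional vegetation is the area-weighted mean
composition, normalised over the selected pollen taxa so it is comparable
with REVEALS cover fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BRAUN_BLANQUET_COVER",
    "CompositionTable",
    "BufferAreas",
    "RegionalComposition",
    "braun_blanquet_to_cover",
    "harmonize",
    "select_taxa",
    "regional_obv",
    "fsp_from_stokes",
]

# Fixed translation of Braun-Blanquet cover-abundance classes to percent cover.
BRAUN_BLANQUET_COVER: dict[str, float] = {
    "present": 0.01,
    "i": 5.0,
    "ii": 10.0,
    "iii": 25.0,
    "iv": 50.0,
    "v": 75.0,
}


def braun_blanquet_to_cover(scale_class: str) -> float:
    """Percent cover for a Braun-Blanquet class (case-insensitive).

    present -> 0.01, I -> 5, II -> 10, III -> 25, IV -> 50, V -> 75.
    """
    key = str(scale_class).strip().lower()
    try:
        return BRAUN_BLANQUET_COVER[key]
    except KeyError:
        valid = ", ".join(["present", "I", "II", "III", "IV", "V"])
        raise ValueError(
            f"unknown Braun-Blanquet class {scale_class!r}; valid: {valid}"
        ) from None


@dataclass
class CompositionTable:
    """Per-category plant composition aggregated to pollen taxa.

    table : category_id-indexed DataFrame, one column per taxon, percent
        cover.  Rows may sum to more than 100 (layered vegetation) and are
        never renormalised here.
    names : optional category_id -> human-readable name mapping.
    """

    table: pd.DataFrame
    names: dict | None = None

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("composition covers must be >= 0")

    @property
    def taxa(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class BufferAreas:
    """Area of each land-cover category inside one circular buffer."""

    buffer_km: float
    areas: pd.Series  # category_id -> km^2

    def __post_init__(self) -> None:
        if (self.areas < 0).any():
            raise ValueError("areas must be >= 0")
        if not (self.areas > 0).any():
            raise ValueError("at least one category must have positive area")


@dataclass
class RegionalComposition:
    """Observed regional vegetation (OBV): taxon cover fractions, one buffer."""

    buffer_km: float
    cover: pd.Series  # taxon -> fraction, sums to 1

    def __post_init__(self) -> None:
        if (self.cover < 0).any():
            raise ValueError("cover fractions must be >= 0")
        if abs(self.cover.sum() - 1.0) > 1e-8:
            raise ValueError("OBV fractions must sum to 1")


def harmonize(
    species_table: pd.DataFrame,
    mapping: dict[str, str],
    drop: set[str] | None = None,
) -> pd.DataFrame:
    """Aggregate a species-level cover table to pollen-morphological taxa.

    ``species_table`` has species as columns; covers of species mapping to
    the same pollen taxon are summed.  Species absent from ``mapping`` must
    be listed in ``drop``, otherwise an error names them.
    """
    drop = drop or set()
    unmapped = [s for s in species_table.columns if s not in mapping and s not in drop]
    if unmapped:
        raise ValueError(
            "species without a pollen-taxon mapping (add to mapping or drop "
            f"list): {sorted(unmapped)}"
        )
    kept = [s for s in species_table.columns if s in mapping]
    if not kept:
        return species_table.iloc[:, :0]
    out = species_table[kept].T.groupby(lambda s: mapping[s]).sum().T
    return out


def select_taxa(
    pollen_pct: pd.DataFrame,
    presence_frac: float = 0.60,
    max_pct: float = 1.0,
) -> list[str]:
    """Taxa present in >= ``presence_frac`` of sites AND reaching a maximum
    percentage above ``max_pct`` at some site.

    ``pollen_pct`` is site x taxon pollen percentages (rows sum to ~100).
    Presence means a strictly positive percentage.
    """
    if pollen_pct.empty:
        raise ValueError("empty pollen percentage matrix")
    present = (pollen_pct > 0).mean(axis=0) >= presence_frac
    big = pollen_pct.max(axis=0) > max_pct
    return list(pollen_pct.columns[present & big])


def regional_obv(
    areas: BufferAreas,
    comp: CompositionTable,
    taxa: list[str],
) -> RegionalComposition:
    """Observed regional vegetation within one buffer.

    Mean percent cover per taxon = sum_cat area_cat * cover_cat / sum areas,
    then normalised over ``taxa`` to fractions summing to 1.  Invariant under
    rescaling all areas.
    """
    missing = [c for c in areas.areas.index if c not in comp.table.index]
    if missing:
        raise ValueError(f"categories without composition rows: {missing}")
    a = areas.areas
    sub = comp.table.loc[a.index, taxa]
    mean_cover = sub.mul(a, axis=0).sum(axis=0) / a.sum()
    total = mean_cover.sum()
    if total <= 0:
        raise ValueError("selected taxa have zero cover in every category")
    return RegionalComposition(areas.buffer_km, mean_cover / total)


# Stokes-law defaults: fresh pollen density and air viscosity at ~20 C.
POLLEN_DENSITY = 1000.0  # kg/m^3
AIR_DENSITY = 1.27  # kg/m^3
AIR_VISCOSITY = 1.8e-5  # Pa s
GRAVITY = 9.81  # m/s^2


def fsp_from_stokes(
    long_axis_um: float,
    short_axis_um: float,
    density_kg_m3: float = POLLEN_DENSITY,
    air_viscosity: float = AIR_VISCOSITY,
    air_density: float = AIR_DENSITY,
) -> float:
    """Terminal fall speed of a pollen grain from Stokes' law, m/s.

    The grain is treated as a sphere of equivalent radius
    r = (long * short^2)^(1/3) / 2 built from the long and short axes (um);
    v = 2 g r^2 (rho_p - rho_air) / (9 eta).
    """
    if long_axis_um <= 0 or short_axis_um <= 0:
        raise ValueError("grain axes must be > 0")
    r = ((long_axis_um * short_axis_um**2) ** (1.0 / 3.0)) / 2.0 * 1e-6
    return 2.0 * GRAVITY * r**2 * (density_kg_m3 - air_density) / (9.0 * air_viscosity)
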