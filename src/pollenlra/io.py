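"""File formats and run configuration.

All tabular data are UTF-8 comma-separated CSV with a header row and "."
decimals; configuration is YAML; truth records are JSON.  Distances are
metres internally — buffer radii arrive in km and are converted once at this
boundary.  Writes go through a temp file and an atomic rename.

Schemas:
  counts.csv        site,taxon,count              (integer counts, >= 0)
  rings.csv         site,ring_start_m,ring_end_m,taxon,cover_pct
  fsp.csv           taxon,fall_speed_m_s
  composition.csv   category_id,category_name,taxon,cover_pct
  buffer_areas.csv  buffer_km,category_id,area_km2
  species_map.csv   species,pollen_taxon
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dispersal import BASIN_RADIUS, KernelParams, RingVegetation
from .erv import ErvDataset
from .vegetation import BufferAreas, CompositionTable

__all__ = [
    "RunConfig",
    "read_pollen",
    "write_pollen",
    "read_rings",
    "write_rings",
    "read_fsp",
    "write_fsp",
    "read_composition",
    "write_composition",
    "read_buffer_areas",
    "write_buffer_areas",
    "read_species_map",
    "load_config",
    "build_dataset",
    "atomic_write_text",
    "write_json",
]


def atomic_write_text(path: str | Path, text: str) -> Path:
    """Write text to ``path`` via a temp file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return path


def write_json(path: str | Path, obj) -> Path:
    return atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    return atomic_write_text(path, df.to_csv(index=False))


def read_pollen(path: str | Path) -> pd.DataFrame:
    """Site x taxon integer count matrix from long-format counts.csv.

    Missing (site, taxon) pairs become explicit zeros; negative or
    non-integer counts raise with the offending row number.
    """
    df = pd.read_csv(path)
    _need(df, ["site", "taxon", "count"], path)
    for row, value in enumerate(df["count"], start=2):  # 1-based + header
        v = float(value)
        if v < 0 or v != int(v):
            raise ValueError(
                f"{path}: row {row}: count must be a non-negative integer, "
                f"got {value!r}"
            )
    wide = (
        df.pivot_table(index="site", columns="taxon", values="count",
                       aggfunc="sum", fill_value=0)
        .astype(int)
    )
    wide.index.name = None
    wide.columns.name = None
    return wide


def write_pollen(pollen: pd.DataFrame, path: str | Path) -> Path:
    long = pollen.stack().rename("count").rename_axis(["site", "taxon"]).reset_index()
    return _write_csv(long, path)


def read_rings(path: str | Path) -> dict[str, RingVegetation]:
    """Per-site ring vegetation from rings.csv.

    Rings must be non-overlapping and contiguous per site; a survey starting
    at 0 m is clipped to the 0.5-m basin edge.  Cover is percent in the file,
    fraction in memory.
    """
    df = pd.read_csv(path)
    _need(df, ["site", "ring_start_m", "ring_end_m", "taxon", "cover_pct"], path)
    if (df["cover_pct"] < 0).any():
        bad = df.index[df["cover_pct"] < 0][0] + 2
        raise ValueError(f"{path}: row {bad}: negative cover")
    taxa = sorted(df["taxon"].unique())
    out: dict[str, RingVegetation] = {}
    for site, grp in df.groupby("site", sort=False):
        edges = (
            grp[["ring_start_m", "ring_end_m"]].drop_duplicates()
            .sort_values("ring_start_m")
        )
        starts = edges["ring_start_m"].to_numpy(dtype=float).copy()
        ends = edges["ring_end_m"].to_numpy(dtype=float).copy()
        if starts[0] < BASIN_RADIUS:
            if starts[0] > 0:
                raise ValueError(
                    f"{path}: site {site}: survey starts at {starts[0]} m, "
                    f"inside the {BASIN_RADIUS}-m basin"
                )
            starts[0] = BASIN_RADIUS  # basin edge inserted at 0.5 m
        if np.any(ends <= starts):
            raise ValueError(f"{path}: site {site}: empty or inverted ring")
        gaps = starts[1:] - ends[:-1]
        if np.any(np.abs(gaps) > 1e-6):
            kind = "overlapping" if (gaps < 0).any() else "gapped"
            raise ValueError(f"{path}: site {site}: {kind} rings")
        bounds = np.concatenate([starts, ends[-1:]])
        cover = pd.DataFrame(0.0, index=taxa, columns=range(starts.size))
        ring_of = {
            (s, e): j for j, (s, e) in enumerate(
                zip(edges["ring_start_m"], edges["ring_end_m"])
            )
        }
        for _, r in grp.iterrows():
            j = ring_of[(r["ring_start_m"], r["ring_end_m"])]
            cover.loc[r["taxon"], j] = r["cover_pct"] / 100.0
        out[str(site)] = RingVegetation(str(site), bounds, cover)
    return out


def write_rings(veg: dict[str, RingVegetation], path: str | Path) -> Path:
    rows = []
    for site, rv in veg.items():
        for j in range(rv.ring_bounds.size - 1):
            for taxon in rv.taxa:
                rows.append(
                    {
                        "site": site,
                        "ring_start_m": rv.ring_bounds[j],
                        "ring_end_m": rv.ring_bounds[j + 1],
                        "taxon": taxon,
                        "cover_pct": rv.cover.loc[taxon, j] * 100.0,
                    }
                )
    return _write_csv(pd.DataFrame(rows), path)


def read_fsp(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    _need(df, ["taxon", "fall_speed_m_s"], path)
    s = df.set_index("taxon")["fall_speed_m_s"].astype(float)
    if (s < 0).any():
        raise ValueError(f"{path}: negative fall speed")
    return s


def write_fsp(fsp: pd.Series, path: str | Path) -> Path:
    df = fsp.rename("fall_speed_m_s").rename_axis("taxon").reset_index()
    return _write_csv(df, path)


def read_composition(path: str | Path) -> CompositionTable:
    df = pd.read_csv(path)
    _need(df, ["category_id", "category_name", "taxon", "cover_pct"], path)
    table = df.pivot_table(
        index="category_id", columns="taxon", values="cover_pct",
        aggfunc="sum", fill_value=0.0,
    )
    table.index.name = None
    table.columns.name = None
    names = dict(df.drop_duplicates("category_id")[["category_id", "category_name"]].values)
    return CompositionTable(table, names)


def write_composition(comp: CompositionTable, path: str | Path) -> Path:
    rows = []
    for cat in comp.table.index:
        name = (comp.names or {}).get(cat, str(cat))
        for taxon in comp.table.columns:
            rows.append(
                {"category_id": cat, "category_name": name, "taxon": taxon,
                 "cover_pct": comp.table.loc[cat, taxon]}
            )
    return _write_csv(pd.DataFrame(rows), path)


def read_buffer_areas(path: str | Path) -> dict[float, BufferAreas]:
    df = pd.read_csv(path)
    _need(df, ["buffer_km", "category_id", "area_km2"], path)
    out = {}
    for radius, grp in df.groupby("buffer_km"):
        areas = grp.set_index("category_id")["area_km2"].astype(float)
        out[float(radius)] = BufferAreas(float(radius), areas)
    return out


def write_buffer_areas(buffers: dict[float, BufferAreas], path: str | Path) -> Path:
    rows = []
    for radius in sorted(buffers):
        for cat, area in buffers[radius].areas.items():
            rows.append({"buffer_km": radius, "category_id": cat, "area_km2": area})
    return _write_csv(pd.DataFrame(rows), path)


def read_species_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    _need(df, ["species", "pollen_taxon"], path)
    return dict(zip(df["species"], df["pollen_taxon"]))


def _need(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; need {cols}")


@dataclass
class RunConfig:
    """One analysis run, loadable from YAML.

    The kernel block (wind_speed, sutton_n, cz, basin_radius_m, z_max_m)
    holds the atmospheric constants the plume kernel needs; the rest points
    at input CSVs and names the modelling choices.
    """

    pollen: str | None = None
    veg: str | None = None
    fsp: str | None = None
    reference_taxon: str = "Poaceae"
    submodel: int = 3
    cutoff_m: float = 1500.0
    wind_speed: float = 3.0
    sutton_n: float = 0.25
    cz: float = 0.12
    basin_radius_m: float = BASIN_RADIUS
    z_max_m: float = 1e5
    buffers_km: tuple[float, ...] = (75.0, 100.0, 125.0, 150.0)
    mode: str = "mean_of_sites"
    seed: int = 0
    outdir: str = "out"
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "buffers_km" in kwargs:
        kwargs["buffers_km"] = tuple(float(b) for b in kwargs["buffers_km"])
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extra=extra)


def build_dataset(
    pollen: pd.DataFrame,
    veg: dict[str, RingVegetation],
    fsp: pd.Series,
    reference_taxon: str,
    wind_speed: float = 3.0,
    sutton_n: float = 0.25,
    cz: float = 0.12,
) -> ErvDataset:
    """Assemble an ErvDataset from loaded tables, aligning taxon sets."""
    taxa = [t for t in pollen.columns if t in fsp.index]
    missing = [t for t in pollen.columns if t not in fsp.index]
    if missing:
        raise ValueError(f"taxa without fall speeds: {missing}")
    kernels = {t: KernelParams(float(fsp[t]), wind_speed, sutton_n, cz) for t in taxa}
    aligned = {}
    for site, rv in veg.items():
        cover = rv.cover.reindex(taxa, fill_value=0.0)
        aligned[site] = RingVegetation(site, rv.ring_bounds, cover)
    return ErvDataset(pollen[taxa], aligned, kernels, reference_taxon)
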