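"""Synthetic pollen-vegetation landscapes with known truth.

Emulates the structure of a moss-polster RPP study in a cultural landscape:
a network of small sites split over two subregions, ring-based local
vegetation surveys to 1,500 m, a regional land-cover mosaic summarised as
category areas within 75-150 km buffers plus a category-by-taxon composition
table, and >= 1,000-grain multinomial pollen counts per sample.

The landscape is a category mosaic: each ring of each site draws a land-cover
category from the regional category weights with Markov persistence between
adjacent rings, so the marginal ring composition matches the regional
composition while individual sites differ (the contrast the ERV model needs).
Expected pollen loadings follow the ERV submodel-3 structure exactly,

    y_ik = alpha_i * x_ik + alpha_i * v_i^regional * K_i(extent, z_max),

with x_ik the DWPA over the surveyed rings and the second term the
background from vegetation beyond the survey extent (v^regional is the
area-weighted mean ground-cover fraction, the same units as the ring
covers); counts are multinomial.
Every stage of the pipeline is therefore testable against recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dispersal import (
    BASIN_RADIUS,
    KernelParams,
    RingVegetation,
    distance_weighted_abundance,
    ring_weight,
)
from .erv import ErvDataset
from .vegetation import BufferAreas, CompositionTable, RegionalComposition, regional_obv

__all__ = ["ScenarioConfig", "Scenario", "DEFAULT_TAXA", "generate_scenario", "perturb"]

# (taxon, true RPP relative to Poaceae, fall speed m/s) — a 10-taxon panel
# spanning the RPP range 0.7-27 typical of temperate-China moss-polster
# studies, with plausible fall speeds.
DEFAULT_TAXA: tuple[tuple[str, float, float], ...] = (
    ("Artemisia", 27.0, 0.014),
    ("Pinus", 12.0, 0.031),
    ("Humulus", 9.0, 0.015),
    ("Castanea", 5.0, 0.010),
    ("Quercus", 2.5, 0.035),
    ("Cichorioideae", 1.5, 0.051),
    ("Poaceae", 1.0, 0.035),
    ("Caryophyllaceae", 0.9, 0.029),
    ("Robinia", 0.9, 0.020),
    ("Ulmus", 0.7, 0.032),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic landscape."""

    seed: int = 0
    n_sites: int = 36
    n_subregion_a: int = 17  # "NE" cluster; the rest are "SW"
    taxa: tuple[tuple[str, float, float], ...] = DEFAULT_TAXA
    reference_taxon: str = "Poaceae"
    n_categories: int = 12
    persistence: float = 0.85  # ring-to-ring Markov persistence of categories
    patch_scale_m: float = 50.0  # typical patch radius; rings average over
    # ~ring_area/patch_area patches, so wide outer rings mix many stands
    purity: float = 1.0  # share of a ring's cover from its own patches; the
    # rest is the regional mean (field margins, hedgerows, understorey)
    counts_per_sample: int = 1000
    extent: float = 1500.0  # survey limit, m
    ring_bounds: tuple[float, ...] | None = None  # default: graded grid
    buffer_radii_km: tuple[float, ...] = (75.0, 100.0, 125.0, 150.0)
    primary_buffer_km: float = 100.0  # buffer defining the generating truth
    z_max: float = 1e5  # regional limit, m
    cover_noise_sd: float = 0.15  # lognormal sd on ring covers
    category_concentration: float = 2.0  # Dirichlet conc. of category weights
    wind_speed: float = 3.0
    sutton_n: float = 0.25
    cz: float = 0.12

    def __post_init__(self) -> None:
        names = [t[0] for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names")
        if self.reference_taxon not in names:
            raise ValueError("reference taxon missing from taxa")
        ref_rpp = dict((t[0], t[1]) for t in self.taxa)[self.reference_taxon]
        if ref_rpp != 1.0:
            raise ValueError("true RPP of the reference taxon must be 1")
        if self.counts_per_sample < 1:
            raise ValueError("counts_per_sample must be >= 1")
        if not 0 < self.n_subregion_a < self.n_sites:
            raise ValueError("subregion split must leave both groups non-empty")
        if self.extent <= BASIN_RADIUS:
            raise ValueError("survey extent must exceed the basin radius")
        if self.primary_buffer_km not in self.buffer_radii_km:
            raise ValueError("primary buffer must be one of buffer_radii_km")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        if not 0 < self.patch_scale_m:
            raise ValueError("patch_scale_m must be > 0")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")

    def bounds(self) -> np.ndarray:
        """Ring edges: 10-m rings to 100 m, then 50-m rings to the extent."""
        if self.ring_bounds is not None:
            return np.asarray(self.ring_bounds, dtype=float)
        inner = np.arange(10.5, min(100.5, self.extent), 10.0)
        outer = np.arange(150.5, self.extent, 50.0)
        return np.concatenate([[BASIN_RADIUS], inner, outer, [self.extent]])

    def kernels(self) -> dict[str, KernelParams]:
        return {
            name: KernelParams(fsp, self.wind_speed, self.sutton_n, self.cz)
            for name, _, fsp in self.taxa
        }


@dataclass
class Scenario:
    """A generated landscape: model-ready data plus the generating truth."""

    config: ScenarioConfig
    data: ErvDataset
    composition: CompositionTable
    buffers: dict[float, BufferAreas]
    obvs: dict[float, RegionalComposition]
    truth: dict = field(repr=False)
    expected: pd.DataFrame = field(repr=False)  # site x taxon expected loadings


def _make_composition(rng, config) -> CompositionTable:
    """Category x taxon percent-cover table.

    Each category is dominated by one taxon (rotating so every taxon
    dominates somewhere); the reference taxon is present everywhere, and a
    random handful of minor taxa fill in — mirroring field composition
    tables whose rows need not sum to 100.
    """
    names = [t[0] for t in config.taxa]
    T = len(names)
    rows = np.zeros((config.n_categories, T))
    ref = names.index(config.reference_taxon)
    for j in range(config.n_categories):
        dom = j % T
        rows[j, dom] = rng.uniform(30.0, 80.0)
        # reference (grass) cover is ubiquitous but spans orders of magnitude
        # between closed forest and open grassland, as in field tables
        rows[j, ref] = max(rows[j, ref], np.exp(rng.uniform(np.log(2.0), np.log(60.0))))
        for i in range(T):
            if i not in (dom, ref) and rng.random() < 0.5:
                rows[j, i] = np.exp(rng.uniform(np.log(0.2), np.log(8.0)))
    table = pd.DataFrame(
        rows, index=[f"C{j + 1:02d}" for j in range(config.n_categories)], columns=names
    )
    return CompositionTable(table)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Draw one landscape and its pollen counts, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    names = [t[0] for t in config.taxa]
    rpp = pd.Series({t[0]: t[1] for t in config.taxa}, name="rpp")
    fsp = pd.Series({t[0]: t[2] for t in config.taxa}, name="fall_speed")
    kernels = config.kernels()
    bounds = config.bounds()
    n_rings = bounds.size - 1

    comp = _make_composition(rng, config)
    w = rng.dirichlet(
        np.full(config.n_categories, config.category_concentration)
    )
    cats = list(comp.table.index)

    # buffer area tables; the primary buffer carries the exact mosaic weights
    buffers: dict[float, BufferAreas] = {}
    obvs: dict[float, RegionalComposition] = {}
    for radius in config.buffer_radii_km:
        area_total = np.pi * radius**2
        weights = w if radius == config.primary_buffer_km else (
            w * rng.lognormal(0.0, 0.15, w.size)
        )
        areas = pd.Series(weights / weights.sum() * area_total, index=cats)
        buffers[radius] = BufferAreas(radius, areas)
        obvs[radius] = regional_obv(buffers[radius], comp, names)
    v_reg = obvs[config.primary_buffer_km].cover
    # unnormalised mean ground-cover fraction per taxon — same units as the
    # ring covers, so local and regional loading terms are commensurable
    v_cover = (comp.table.T @ w) / 100.0

    # subregions and site coordinates (planar metres; two ~50-km clusters)
    centers = {"NE": (5.0e4, 5.0e4), "SW": (-5.0e4, -5.0e4)}
    sites, veg, loadings = [], {}, []
    # sites are placed by stratified sampling of the mosaic, as surveys do:
    # the immediate surroundings of the network cover the region's
    # communities in proportion to their area (largest-remainder allocation)
    quota = config.n_sites * w
    alloc = np.floor(quota).astype(int)
    rest = np.argsort(quota - alloc)[::-1][: config.n_sites - alloc.sum()]
    alloc[rest] += 1
    home_cat = rng.permutation(np.repeat(np.arange(w.size), alloc))
    K_bg = pd.Series(
        {t: ring_weight(config.extent, config.z_max, kernels[t]) for t in names}
    )
    omega = rpp * v_cover * K_bg
    for k in range(config.n_sites):
        site = f"S{k + 1:02d}"
        sub = "NE" if k < config.n_subregion_a else "SW"
        sites.append((site, sub))
        # Markov category chain over rings, starting from the site's home
        # category and stationary at the mosaic weights
        chain = np.empty(n_rings, dtype=int)
        chain[0] = home_cat[k]
        for r in range(1, n_rings):
            chain[r] = (
                chain[r - 1]
                if rng.random() < config.persistence
                else rng.choice(w.size, p=w)
            )
        # ring cover: average over the ~ring_area/patch_area patches a ring
        # crosses (the chain category plus independent draws), blended with
        # the regional mean for the non-patch share
        comp_frac = comp.table.to_numpy() / 100.0  # categories x taxa
        patch_area = np.pi * config.patch_scale_m**2
        ring_area = np.pi * (bounds[1:] ** 2 - bounds[:-1] ** 2)
        n_patch = np.clip((ring_area / patch_area).astype(int), 1, 50)
        cover = np.empty((len(names), n_rings))
        for r in range(n_rings):
            draws = [chain[r]] + list(rng.choice(w.size, n_patch[r] - 1, p=w))
            patch_mean = comp_frac[draws].mean(axis=0)
            cover[:, r] = (
                config.purity * patch_mean
                + (1.0 - config.purity) * v_cover.to_numpy()
            )
        if config.cover_noise_sd > 0:
            sd = config.cover_noise_sd  # mean-1 lognormal survey noise
            cover = cover * rng.lognormal(-0.5 * sd**2, sd, cover.shape)
        rv = RingVegetation(
            site, bounds, pd.DataFrame(cover, index=names, columns=range(n_rings))
        )
        veg[site] = rv
        x = distance_weighted_abundance(rv, kernels, config.extent)
        loadings.append(rpp * x + omega)

    site_ids = [s for s, _ in sites]
    expected = pd.DataFrame(loadings, index=site_ids)[names]
    probs = expected.div(expected.sum(axis=1), axis=0)
    counts = pd.DataFrame(
        [
            rng.multinomial(config.counts_per_sample, probs.loc[s].to_numpy())
            for s in site_ids
        ],
        index=site_ids,
        columns=names,
    )

    data = ErvDataset(counts, veg, kernels, config.reference_taxon)
    truth = {
        "rpp": rpp,
        "fall_speed": fsp,
        "background": omega,
        "regional": v_reg,
        "regional_cover": v_cover,
        "primary_buffer_km": config.primary_buffer_km,
        "subregion": pd.Series(dict(sites), name="subregion"),
        "coords": {
            s: (
                centers[sub][0] + 2.0e4 * rng.standard_normal(),
                centers[sub][1] + 2.0e4 * rng.standard_normal(),
            )
            for s, sub in sites
        },
    }
    return Scenario(config, data, comp, buffers, obvs, truth, expected)


def perturb(
    scenario: Scenario, overdispersion: float, seed: int | None = None
) -> Scenario:
    """Redraw counts with Dirichlet-multinomial overdispersion; truth unchanged.

    Per-site proportions are drawn Dirichlet(overdispersion * p) around the
    expected proportions p, then counts multinomially — extra between-site
    variance that vanishes as the concentration grows.
    """
    if not overdispersion > 0:
        raise ValueError("overdispersion concentration must be > 0")
    cfg = scenario.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    probs = scenario.expected.div(scenario.expected.sum(axis=1), axis=0)
    counts = {}
    for site in probs.index:
        p = rng.dirichlet(np.maximum(overdispersion * probs.loc[site], 1e-9))
        counts[site] = rng.multinomial(cfg.counts_per_sample, p)
    pollen = pd.DataFrame(counts, index=probs.columns).T
    data = ErvDataset(
        pollen, scenario.data.veg, scenario.data.kernels, cfg.reference_taxon
    )
    return replace(scenario, data=data)
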