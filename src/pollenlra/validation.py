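"""Evaluation strategies for relative pollen productivity estimates.

Two schemes probe the stability of fitted RPPs and the accuracy of the
regional cover they imply:

* leave-one-out (LOO): drop one site, fit the ERV model on the remainder,
  run REVEALS on the held-out site's counts; repeat for every site and
  average, with delta-method SEs of the means combining within-run variance
  and between-run spread;
* subregion splitting: fit RPPs on one geographic group of sites and apply
  REVEALS to the pollen of the other group.

`compare` lines up the three quantities of interest per taxon — pollen
proportions (PP), REVEALS estimates (RV) and observed regional vegetation
(OBV) at several buffer radii — and derives similarity metrics; `report`
renders the standard bar charts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .erv import ErvDataset, ErvFit, fit_erv
from .reveals import PollenSample, RevealsEstimate, reveals_multi, reveals_single
from .vegetation import RegionalComposition

__all__ = [
    "LooResult",
    "run_loo",
    "run_subregion",
    "pollen_proportions",
    "compare",
    "report",
]


@dataclass
class LooResult:
    """All leave-one-out runs plus the delta-method summaries."""

    fits: list[ErvFit]
    estimates: list[RevealsEstimate]
    left_out: list[str]
    mean_rpp: pd.Series
    rpp_se: pd.Series
    mean_rv: pd.Series
    rv_se: pd.Series
    n_excluded: int = 0
    excluded_sites: list[str] = field(default_factory=list)


def _subset(data: ErvDataset, sites: list[str]) -> ErvDataset:
    return ErvDataset(
        data.pollen.loc[sites],
        {s: data.veg[s] for s in sites},
        data.kernels,
        data.reference_taxon,
    )


def _mean_and_se(values: pd.DataFrame, variances: pd.DataFrame):
    """Delta-method mean and SE over runs.

    Var(mean) = mean within-run variance / S + between-run variance / S.
    """
    S = len(values)
    mean = values.mean(axis=0)
    between = values.var(axis=0, ddof=1) if S > 1 else values.iloc[0] * 0.0
    var = variances.mean(axis=0) / S + between / S
    return mean, np.sqrt(var)


def run_loo(
    data: ErvDataset,
    cutoff: float,
    submodel: int = 3,
    basin_radius: float = 0.5,
    z_max: float = 1e5,
    n_starts: int = 3,
    seed: int = 0,
) -> LooResult:
    """Leave-one-out cross-validation: one ERV fit and one single-site
    REVEALS run per site.

    A non-convergent ERV fit excludes that run with a warning; the exclusion
    count is carried in the result.
    """
    sites = data.sites
    if len(sites) < 3:
        raise ValueError("leave-one-out needs at least 3 sites")
    full = fit_erv(data, cutoff, submodel, n_starts=max(n_starts, 3), seed=seed)

    fits, estimates, left_out, excluded = [], [], [], []
    for site in sites:
        rest = [s for s in sites if s != site]
        try:
            fit = fit_erv(
                _subset(data, rest), cutoff, submodel,
                n_starts=n_starts, seed=seed, warm_start=full,
            )
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"LOO run leaving out {site} failed: {exc}", stacklevel=2)
            excluded.append(site)
            continue
        est = reveals_single(
            data.pollen.loc[site], fit.rpp, data.kernels,
            basin_radius, z_max, rpp_sd=fit.rpp_sd,
        )
        fits.append(fit)
        estimates.append(est)
        left_out.append(site)

    if not fits:
        raise RuntimeError("every leave-one-out run failed")
    rpps = pd.DataFrame([f.rpp for f in fits])
    rpp_vars = pd.DataFrame([f.rpp_sd**2 for f in fits]).fillna(0.0)
    mean_rpp, rpp_se = _mean_and_se(rpps, rpp_vars)
    rvs = pd.DataFrame([e.cover for e in estimates])
    rv_vars = pd.DataFrame([e.se**2 for e in estimates])
    mean_rv, rv_se = _mean_and_se(rvs, rv_vars)
    return LooResult(
        fits=fits,
        estimates=estimates,
        left_out=left_out,
        mean_rpp=mean_rpp,
        rpp_se=rpp_se,
        mean_rv=mean_rv / mean_rv.sum(),
        rv_se=rv_se,
        n_excluded=len(excluded),
        excluded_sites=excluded,
    )


def run_subregion(
    data: ErvDataset,
    split: pd.Series,
    fit_group: str,
    apply_group: str,
    cutoff: float,
    submodel: int = 3,
    basin_radius: float = 0.5,
    z_max: float = 1e5,
    mode: str = "mean_of_sites",
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[ErvFit, RevealsEstimate]:
    """Fit RPPs on one subregion's sites, estimate regional cover on the other.

    ``split`` maps site -> group label.  Emits a stability warning when any
    fitted RPP has an SD exceeding the estimate itself (the screen that
    disqualifies a subregion as the RPP source).
    """
    fit_sites = [s for s in data.sites if split.get(s) == fit_group]
    apply_sites = [s for s in data.sites if split.get(s) == apply_group]
    if not fit_sites or not apply_sites:
        raise ValueError(
            f"empty group: fit={len(fit_sites)} apply={len(apply_sites)} sites"
        )
    if len(fit_sites) < 2:
        raise ValueError("fit group needs at least 2 sites")

    fit = fit_erv(_subset(data, fit_sites), cutoff, submodel, n_starts, seed)
    shaky = fit.rpp_sd > fit.rpp
    if shaky.any():
        warnings.warn(
            "RPP SDs exceed the estimates for "
            f"{list(fit.rpp.index[shaky])}; subregion fit may be unstable",
            stacklevel=2,
        )
    samples = [PollenSample(s, data.pollen.loc[s], apply_group) for s in apply_sites]
    est = reveals_multi(
        samples, fit.rpp, data.kernels, basin_radius, z_max,
        rpp_sd=fit.rpp_sd, mode=mode,
    )
    return fit, est


def pollen_proportions(pollen: pd.DataFrame, pooled: bool = False) -> pd.Series:
    """Mean per-site pollen proportions (default) or pooled-count proportions."""
    if pooled:
        tot = pollen.sum(axis=0)
        return tot / tot.sum()
    props = pollen.div(pollen.sum(axis=1), axis=0)
    mean = props.mean(axis=0)
    return mean / mean.sum()


def compare(
    pp: pd.Series,
    rv: RevealsEstimate,
    obvs: list[RegionalComposition],
) -> pd.DataFrame:
    """Per-taxon comparison of PP, RV and OBV at each buffer radius.

    Headline metrics use the first buffer in ``obvs``:
      cv         RV standard error divided by the OBV;
      ratio_diff |RV - OBV| / OBV;
      fold       max(RV, OBV) / min(RV, OBV)  (>= 1);
      closest_buffer  the radius whose OBV is nearest the RV, per taxon.
    A zero OBV with positive RV makes the ratio metrics infinite and sets
    ``undefined_obv``.
    """
    if not obvs:
        raise ValueError("need at least one observed regional composition")
    taxa = list(rv.cover.index)
    for name, vec in [("pp", pp)] + [(f"obv_{o.buffer_km:g}", o.cover) for o in obvs]:
        if set(vec.index) != set(taxa):
            raise ValueError(f"{name} has a different taxon set")
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1")

    out = pd.DataFrame(index=pd.Index(taxa, name="taxon"))
    out["pp"] = pp[taxa]
    out["rv"] = rv.cover
    out["rv_se"] = rv.se
    for o in obvs:
        out[f"obv_{o.buffer_km:g}"] = o.cover[taxa]

    obv0 = obvs[0].cover[taxa]
    zero = obv0 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cv"] = (rv.se / obv0).where(~zero, np.inf)
        out["ratio_diff"] = ((rv.cover - obv0).abs() / obv0).where(~zero, np.inf)
        hi = np.maximum(rv.cover, obv0)
        lo = np.minimum(rv.cover, obv0)
        fold = hi / lo
    fold = fold.where(hi > 0, 1.0)  # both zero: identical
    out["fold"] = fold
    out["undefined_obv"] = zero & (rv.cover > 0)

    dev = pd.DataFrame({o.buffer_km: (rv.cover - o.cover[taxa]).abs() for o in obvs})
    out["closest_buffer"] = dev.idxmin(axis=1)
    return out


def report(
    outdir: str | Path,
    comparison: pd.DataFrame | None = None,
    fits: dict[str, ErvFit] | None = None,
    loo: LooResult | None = None,
) -> list[Path]:
    """Write bar-chart figures (SVG) and CSVs for whatever inputs are given.

    Deterministic for fixed inputs.  Missing SE columns produce bars without
    error whiskers and a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if comparison is not None:
        path = outdir / "comparison.csv"
        comparison.to_csv(path)
        written.append(path)
        cols = ["pp", "rv"] + [c for c in comparison.columns if c.startswith("obv_")]
        ax = comparison[cols].plot.bar(figsize=(10, 4), width=0.8)
        if "rv_se" in comparison.columns:
            xs = [p.get_x() + p.get_width() / 2 for p in ax.patches][
                len(comparison): 2 * len(comparison)
            ]
            ax.errorbar(
                xs, comparison["rv"], yerr=comparison["rv_se"],
                fmt="none", ecolor="black", capsize=2,
            )
        else:
            warnings.warn("no rv_se column; drawing bars without whiskers",
                          stacklevel=2)
        ax.set_ylabel("cover / proportion")
        fig_path = outdir / "comparison.svg"
        ax.figure.savefig(fig_path, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(fig_path)

    if fits:
        table = pd.DataFrame({label: f.rpp for label, f in fits.items()})
        errs = pd.DataFrame({label: f.rpp_sd for label, f in fits.items()})
        path = outdir / "rpp_estimates.csv"
        table.to_csv(path)
        written.append(path)
        ax = table.plot.bar(yerr=errs, figsize=(10, 4), capsize=2)
        ax.set_ylabel("relative pollen productivity")
        fig_path = outdir / "rpp_estimates.svg"
        ax.figure.savefig(fig_path, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(fig_path)

    if loo is not None:
        spread = pd.DataFrame([f.rpp for f in loo.fits], index=loo.left_out)
        path = outdir / "loo_rpp_runs.csv"
        spread.to_csv(path)
        written.append(path)
        fig, ax = plt.subplots(figsize=(10, 4))
        spread.boxplot(ax=ax, rot=45)
        ax.set_ylabel("RPP across leave-one-out runs")
        fig_path = outdir / "loo_rpp_spread.svg"
        fig.savefig(fig_path, bbox_inches="tight")
        plt.close(fig)
        written.append(fig_path)

    return written
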