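"""REVEALS: regional plant cover from pollen counts and pollen productivities.

For taxon i with pollen count n_i, relative pollen productivity alpha_i and
deposition factor K_i (the plume kernel integrated from the basin edge to the
regional limit z_max), the estimated regional cover fraction is

    V_i = (n_i / (alpha_i K_i)) / sum_j (n_j / (alpha_j K_j)).

Standard errors propagate two sources by the delta method: multinomial
sampling variance of the counts and the variance of the estimated alpha.
With several small sites the regional estimate is the mean of per-site
estimates (or a pooled-count estimate), and the SE of the mean combines the
mean per-site delta-method variance with the between-site variance of the
per-site estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersal import KernelParams, deposition_factor

__all__ = ["PollenSample", "RevealsEstimate", "reveals_single", "reveals_multi"]


@dataclass
class PollenSample:
    """One site's pollen counts, with optional location metadata."""

    site: str
    counts: pd.Series  # taxon -> integer count
    subregion: str | None = None
    x: float | None = None
    y: float | None = None


@dataclass
class RevealsEstimate:
    """Estimated regional cover fractions (RVs) with standard errors."""

    cover: pd.Series
    se: pd.Series
    n_sites: int
    basin_radius: float
    z_max: float

    def __post_init__(self) -> None:
        if (self.cover < -1e-12).any():
            raise ValueError("cover fractions must be >= 0")
        if abs(self.cover.sum() - 1.0) > 1e-10:
            raise ValueError("cover fractions must sum to 1")
        if (self.se.dropna() < 0).any():
            raise ValueError("standard errors must be >= 0")


def _factors(taxa, rpp, kernels, basin_radius, z_max) -> np.ndarray:
    K = np.array(
        [deposition_factor(basin_radius, z_max, kernels[t]) for t in taxa]
    )
    if (K <= 0).any():
        bad = [t for t, k in zip(taxa, K) if k <= 0]
        raise ValueError(f"non-positive deposition factor for {bad}")
    return K


def reveals_single(
    counts: pd.Series,
    rpp: pd.Series,
    kernels: dict[str, KernelParams] | None = None,
    basin_radius: float = 0.5,
    z_max: float = 1e5,
    rpp_sd: pd.Series | None = None,
    factors: pd.Series | None = None,
) -> RevealsEstimate:
    """REVEALS estimate from one site's pollen counts.

    Deposition factors are computed from ``kernels`` unless ``factors``
    supplies them directly.  ``rpp_sd`` (per-taxon SD of the estimated
    alpha) is optional; when given, its variance is added to the multinomial
    term in the delta-method SE.  All alpha must be positive for taxa with
    pollen present.
    """
    taxa = list(counts.index)
    n = counts.to_numpy(dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("zero total pollen count")
    a = rpp[taxa].to_numpy(dtype=float)
    if ((a <= 0) & (n > 0)).any():
        bad = [t for t, ai, ni in zip(taxa, a, n) if ai <= 0 and ni > 0]
        raise ValueError(f"taxa with pollen but zero RPP are unrepresentable: {bad}")
    a = np.where(a > 0, a, np.inf)  # zero-RPP, zero-count taxa drop out
    if factors is not None:
        K = factors[taxa].to_numpy(dtype=float)
        if (K <= 0).any():
            raise ValueError("deposition factors must be > 0")
    elif kernels is not None:
        K = _factors(taxa, rpp, kernels, basin_radius, z_max)
    else:
        raise ValueError("either kernels or factors must be given")

    q = n / total  # pollen proportions
    c = 1.0 / (a * K)
    s = q * c
    S = s.sum()
    V = s / S

    # delta method: gradient of V wrt q with multinomial covariance of q
    # dV_i/dq_k = (delta_ik c_i - V_i c_k) / S
    G = (np.diag(c) - np.outer(V, c)) / S
    cov_q = (np.diag(q) - np.outer(q, q)) / total
    var = np.einsum("ik,kl,il->i", G, cov_q, G)

    if rpp_sd is not None:
        sd_a = rpp_sd[taxa].to_numpy(dtype=float)
        sd_a = np.where(np.isfinite(sd_a), sd_a, 0.0)
        # dV_i/da_k = (V_i - delta_ik) s_k / (a_k S); independent alpha errors
        with np.errstate(invalid="ignore"):
            A = ((V[:, None] - np.eye(len(taxa))) * (s / np.where(np.isfinite(a), a, np.inf))[None, :]) / S
        var = var + (A**2) @ (sd_a**2)

    return RevealsEstimate(
        cover=pd.Series(V, index=taxa, name="cover"),
        se=pd.Series(np.sqrt(np.maximum(var, 0.0)), index=taxa, name="se"),
        n_sites=1,
        basin_radius=basin_radius,
        z_max=z_max,
    )


def reveals_multi(
    samples: list[PollenSample],
    rpp: pd.Series,
    kernels: dict[str, KernelParams],
    basin_radius: float = 0.5,
    z_max: float = 1e5,
    rpp_sd: pd.Series | None = None,
    mode: str = "mean_of_sites",
) -> RevealsEstimate:
    """Regional REVEALS estimate from several small sites.

    mode="mean_of_sites" (default): average the per-site cover estimates;
    Var(mean) = mean per-site delta-method variance / S + between-site
    variance of the per-site estimates / S.  mode="pooled": sum counts over
    sites first and run the single-site estimator.
    """
    if not samples:
        raise ValueError("empty sample list")
    if mode == "pooled":
        counts = sum((s.counts for s in samples[1:]), samples[0].counts.copy())
        est = reveals_single(counts, rpp, kernels, basin_radius, z_max, rpp_sd)
        return RevealsEstimate(est.cover, est.se, len(samples), basin_radius, z_max)
    if mode != "mean_of_sites":
        raise ValueError(f"mode must be 'mean_of_sites' or 'pooled', got {mode!r}")

    ests = [
        reveals_single(s.counts, rpp, kernels, basin_radius, z_max, rpp_sd)
        for s in samples
    ]
    covers = pd.DataFrame([e.cover for e in ests])
    vars_ = pd.DataFrame([e.se**2 for e in ests])
    S = len(samples)
    mean = covers.mean(axis=0)
    between = covers.var(axis=0, ddof=1) if S > 1 else covers.iloc[0] * 0.0
    var_mean = vars_.mean(axis=0) / S + between / S
    return RevealsEstimate(
        cover=mean / mean.sum(),
        se=np.sqrt(var_mean),
        n_sites=S,
        basin_radius=basin_radius,
        z_max=z_max,
    )
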