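"""Gaussian-plume pollen dispersal and deposition.

Sutton's atmospheric diffusion model, in the taxon-specific formulation of
Prentice, gives the deposition density of pollen released uniformly from a
ring of vegetation at distance ``z`` from a point sampling basin:

    g(z) = b * gamma * z**(gamma - 1) * exp(-b * z**gamma)

with ``gamma = n/2`` (``n`` Sutton's turbulence parameter) and

    b = 4 * v_g / (n * u * sqrt(pi) * C_z)

where ``v_g`` is the pollen fall speed (m/s), ``u`` the mean wind speed (m/s)
and ``C_z`` the vertical diffusion coefficient.  ``g`` integrates to 1 over
(0, inf) when ``b > 0``; its antiderivative is ``1 - exp(-b z**gamma)``, so
every ring weight and deposition factor below has a closed form.

All distances are metres, measured from the sampling point; the basin (a moss
polster) has its edge at 0.5 m by convention and rings are half-open
intervals ``[z1, z2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KernelParams",
    "RingVegetation",
    "sutton_b",
    "deposition_density",
    "ring_weight",
    "ring_weights",
    "deposition_factor",
    "distance_weighted_abundance",
]

# Conventional neutral-atmosphere constants; overridable everywhere.
DEFAULT_WIND_SPEED = 3.0  # m/s
DEFAULT_SUTTON_N = 0.25
DEFAULT_CZ = 0.12  # m**(n/2)
BASIN_RADIUS = 0.5  # m, moss polster treated as a 0.5-m basin


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the Sutton plume kernel for one pollen taxon.

    fall_speed : terminal settling velocity v_g of the pollen grain, m/s
    wind_speed : mean horizontal wind speed u, m/s
    turbulence_n : Sutton's turbulence parameter n (dimensionless)
    cz : vertical diffusion coefficient C_z, m**(n/2)
    """

    fall_speed: float
    wind_speed: float = DEFAULT_WIND_SPEED
    turbulence_n: float = DEFAULT_SUTTON_N
    cz: float = DEFAULT_CZ

    def __post_init__(self) -> None:
        if self.fall_speed < 0:
            raise ValueError(f"fall_speed must be >= 0, got {self.fall_speed}")
        for name in ("wind_speed", "turbulence_n", "cz"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not 0 < self.gamma < 1:
            raise ValueError(
                f"gamma = n/2 must lie in (0, 1), got {self.gamma}"
            )

    @property
    def gamma(self) -> float:
        return self.turbulence_n / 2.0

    @property
    def b(self) -> float:
        return sutton_b(self)


def sutton_b(params: KernelParams) -> float:
    """Deposition coefficient b = 4 v_g / (n u sqrt(pi) C_z), units m**(-gamma).

    b = 0 exactly when the fall speed is zero (nothing settles).
    """
    return (
        4.0
        * params.fall_speed
        / (params.turbulence_n * params.wind_speed * np.sqrt(np.pi) * params.cz)
    )


def deposition_density(z, params: KernelParams):
    """Point deposition density g(z) = b g z**(g-1) exp(-b z**g), 1/m.

    Strictly decreasing in z for gamma < 1; integrates to 1 on (0, inf).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("deposition density requires z > 0")
    b, g = params.b, params.gamma
    out = b * g * z ** (g - 1.0) * np.exp(-b * z**g)
    return out if out.ndim else float(out)


def ring_weight(z1: float, z2: float, params: KernelParams) -> float:
    """Fraction of a taxon's pollen deposited from the ring [z1, z2).

    Closed form exp(-b z1**gamma) - exp(-b z2**gamma); additive over
    adjacent rings and bounded in [0, 1].
    """
    if z1 <= 0:
        raise ValueError(f"ring inner bound must be > 0, got {z1}")
    if z1 > z2:
        raise ValueError(f"ring bounds out of order: {z1} > {z2}")
    b, g = params.b, params.gamma
    if b == 0.0:  # zero fall speed: nothing deposits anywhere
        return 0.0
    return float(np.exp(-b * z1**g) - np.exp(-b * np.asarray(z2, dtype=float) ** g))


def ring_weights(bounds: np.ndarray, params: KernelParams) -> np.ndarray:
    """Weights for contiguous rings delimited by increasing ``bounds``."""
    bounds = np.asarray(bounds, dtype=float)
    if bounds[0] <= 0:
        raise ValueError("innermost bound must be > 0")
    if np.any(np.diff(bounds) < 0):
        raise ValueError("ring bounds must be non-decreasing")
    b, g = params.b, params.gamma
    if b == 0.0:
        return np.zeros(bounds.size - 1)
    surv = np.exp(-b * bounds**g)
    return -np.diff(surv)


def deposition_factor(
    basin_radius: float, z_max: float, params: KernelParams
) -> float:
    """REVEALS deposition factor K = integral of g from basin edge to z_max.

    Monotone decreasing in basin_radius and fall speed, increasing in z_max.
    """
    if not 0 < basin_radius < z_max:
        raise ValueError(
            f"need 0 < basin_radius < z_max, got {basin_radius}, {z_max}"
        )
    if params.b == 0.0:
        return 0.0
    if np.isinf(z_max):
        return float(np.exp(-params.b * basin_radius**params.gamma))
    return ring_weight(basin_radius, z_max, params)


@dataclass
class RingVegetation:
    """Plant cover around one site, resolved into concentric distance rings.

    ring_bounds : increasing edges, metres from the sampling point; the first
        edge is the basin edge (0.5 m).  ``len(bounds) == n_rings + 1``.
    cover : taxon x ring DataFrame of fractional ground cover (0-1 within a
        layer; layered vegetation may exceed 1 summed over taxa).
    """

    site: str
    ring_bounds: np.ndarray
    cover: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.ring_bounds = np.asarray(self.ring_bounds, dtype=float)
        if self.ring_bounds.ndim != 1 or self.ring_bounds.size < 2:
            raise ValueError("ring_bounds needs at least two edges")
        if np.any(np.diff(self.ring_bounds) <= 0):
            raise ValueError(
                f"site {self.site}: ring bounds must be strictly increasing"
            )
        if self.ring_bounds[0] <= 0:
            raise ValueError(f"site {self.site}: basin edge must be > 0")
        if self.cover.shape[1] != self.ring_bounds.size - 1:
            raise ValueError(
                f"site {self.site}: cover has {self.cover.shape[1]} rings, "
                f"bounds imply {self.ring_bounds.size - 1}"
            )
        if (self.cover.to_numpy() < 0).any():
            raise ValueError(f"site {self.site}: negative cover")

    @property
    def taxa(self) -> list[str]:
        return list(self.cover.index)

    @property
    def extent(self) -> float:
        return float(self.ring_bounds[-1])


def distance_weighted_abundance(
    veg: RingVegetation,
    params: dict[str, KernelParams],
    cutoff: float,
) -> pd.Series:
    """Distance-weighted plant abundance (DWPA) per taxon out to ``cutoff``.

    DWPA_i = sum over rings of cover_i(ring) * ring_weight(ring), with the
    last ring truncated at the cutoff, so DWPA is continuous and
    non-decreasing in the cutoff.  ``cutoff`` must not exceed the survey
    extent.
    """
    bounds = veg.ring_bounds
    if cutoff > bounds[-1] + 1e-9:
        raise ValueError(
            f"cutoff {cutoff} m beyond survey extent {bounds[-1]} m "
            f"at site {veg.site}"
        )
    if cutoff <= bounds[0]:
        raise ValueError(f"cutoff {cutoff} m is inside the basin edge")
    eff = np.minimum(bounds, cutoff)
    out = {}
    for taxon in veg.taxa:
        p = params[taxon]
        w = ring_weights(eff, p)
        out[taxon] = float(w @ veg.cover.loc[taxon].to_numpy())
    return pd.Series(out, name=veg.site)
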