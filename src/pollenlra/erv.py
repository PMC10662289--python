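"""Extended R-value (ERV) model fitting by multinomial maximum likelihood.

The ERV family relates pollen counts ``n_ik`` (taxon i, site k) to
distance-weighted plant abundance (DWPA) ``x_ik`` through relative pollen
productivities ``alpha_i`` and background pollen terms ``omega_i``.  For
submodel 3 — the primary model here — the expected pollen proportion is

    e_ik = (alpha_i * x_ik + omega_i) / sum_j (alpha_j * x_jk + omega_j)

with ``x_ik`` the absolute DWPA truncated at a distance cutoff.  Counts are
multinomial per site, so the log-likelihood is ``sum_k sum_i n_ik ln e_ik``;
it is invariant to rescaling all (alpha, omega) by one constant, and the
scale is pinned by constraining the reference taxon to alpha = 1 (SD 0).

Submodel variants (optional):
  1 — DWPA normalised to proportions per site, taxon-specific background;
  2 — absolute DWPA, background scaled by the site's total DWPA.

The relevant source area of pollen (RSAP) is the distance at which the
log-likelihood-versus-distance curve reaches an asymptote, located by a
moving-window linear regression whose slope is tested against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dispersal import KernelParams, RingVegetation, distance_weighted_abundance

__all__ = [
    "ErvDataset",
    "ErvFit",
    "LikelihoodCurve",
    "RsapResult",
    "dwpa_matrix",
    "fit_erv",
    "likelihood_curve",
    "estimate_rsap",
]


@dataclass
class ErvDataset:
    """Paired pollen counts and ring vegetation for a network of sites.

    pollen : site x taxon DataFrame of integer counts.
    veg : site -> RingVegetation, same taxon set as the pollen table.
    kernels : taxon -> KernelParams (fall speeds + atmospheric constants).
    reference_taxon : taxon whose relative pollen productivity is fixed at 1.
    """

    pollen: pd.DataFrame
    veg: dict[str, RingVegetation]
    kernels: dict[str, KernelParams]
    reference_taxon: str

    def __post_init__(self) -> None:
        taxa = list(self.pollen.columns)
        if self.reference_taxon not in taxa:
            raise ValueError(f"reference taxon {self.reference_taxon!r} not in pollen table")
        if len(taxa) < 2:
            raise ValueError("need at least 2 taxa")
        if len(self.pollen) < 2:
            raise ValueError("need at least 2 sites")
        missing = [s for s in self.pollen.index if s not in self.veg]
        if missing:
            raise ValueError(f"sites without vegetation survey: {missing}")
        for s, rv in self.veg.items():
            if set(rv.taxa) != set(taxa):
                raise ValueError(f"site {s}: vegetation taxa differ from pollen taxa")
        counts = self.pollen.to_numpy()
        if (counts < 0).any():
            raise ValueError("negative pollen counts")
        if (counts.sum(axis=1) <= 0).any():
            empty = list(self.pollen.index[counts.sum(axis=1) <= 0])
            raise ValueError(f"sites with zero total count: {empty}")
        ref_cover = sum(
            float(rv.cover.loc[self.reference_taxon].sum()) for rv in self.veg.values()
        )
        if ref_cover <= 0:
            raise ValueError("reference taxon has zero cover at every site")

    @property
    def taxa(self) -> list[str]:
        return list(self.pollen.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.pollen.index)

    @property
    def extent(self) -> float:
        return min(rv.extent for rv in self.veg.values())


@dataclass
class ErvFit:
    """Fitted ERV model at one distance cutoff."""

    rpp: pd.Series
    rpp_sd: pd.Series
    background: pd.Series
    loglik: float
    cutoff: float
    submodel: int
    converged: bool = True
    messages: list[str] = field(default_factory=list)


@dataclass
class LikelihoodCurve:
    """Log-likelihood of refitted ERV models against distance cutoff."""

    distances: np.ndarray
    loglik: np.ndarray
    ok: np.ndarray  # per-distance convergence flag; failures kept, flagged

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.loglik = np.asarray(self.loglik, dtype=float)
        self.ok = np.asarray(self.ok, dtype=bool)
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("curve distances must be strictly increasing")


@dataclass
class RsapResult:
    """Relevant source area of pollen from the moving-window slope test."""

    rsap: float  # metres; NaN when no asymptote was found
    window_width: float
    alpha_level: float
    no_asymptote: bool = False


def dwpa_matrix(data: ErvDataset, cutoff: float) -> pd.DataFrame:
    """Site x taxon matrix of DWPA truncated at ``cutoff`` metres."""
    rows = [
        distance_weighted_abundance(data.veg[s], data.kernels, cutoff)[data.taxa]
        for s in data.sites
    ]
    return pd.DataFrame(rows, index=data.sites)


def _design(data: ErvDataset, cutoff: float, submodel: int):
    """DWPA matrix X and background design B for the chosen submodel.

    lambda_ik = alpha_i X_ki + omega_i B_k; submodel 3 has B = 1, submodel 2
    scales the background by the site's total DWPA, submodel 1 uses
    site-normalised DWPA proportions with B = 1.
    """
    X = dwpa_matrix(data, cutoff).to_numpy()  # sites x taxa
    if submodel == 1:
        tot = X.sum(axis=1, keepdims=True)
        if (tot <= 0).any():
            raise ValueError("submodel 1 needs positive total DWPA at every site")
        return X / tot, np.ones(X.shape[0])
    if submodel == 2:
        return X, X.sum(axis=1)
    if submodel == 3:
        return X, np.ones(X.shape[0])
    raise ValueError(f"submodel must be 1, 2 or 3, got {submodel}")


def _loglik_grad(alpha, omega, N, X, B):
    """Multinomial log-likelihood and its gradient in (alpha, omega).

    N: counts (sites x taxa), X: DWPA design, B: background design (sites,).
    """
    lam = X * alpha + np.outer(B, omega)
    lam = np.maximum(lam, 1e-300)
    S = lam.sum(axis=1)
    Nk = N.sum(axis=1)
    ll = float((N * np.log(lam)).sum() - (Nk * np.log(S)).sum())
    resid = N / lam - (Nk / S)[:, None]  # sites x taxa
    g_alpha = (resid * X).sum(axis=0)
    g_omega = resid.T @ B
    return ll, g_alpha, g_omega


def fit_erv(
    data: ErvDataset,
    cutoff: float,
    submodel: int = 3,
    n_starts: int = 5,
    seed: int = 0,
    warm_start: ErvFit | None = None,
) -> ErvFit:
    """Maximum-likelihood ERV fit at one distance cutoff.

    Optimises log-parameterised (alpha, omega) with the reference taxon's
    alpha fixed at 1 (non-negativity by construction, identifiability by the
    reference constraint).  ``n_starts`` jittered restarts guard against
    local optima; SDs come from the inverse observed information at the
    optimum.  Taxa with zero DWPA at every site get alpha = 0 and a message,
    their pollen being absorbed by the background term.
    """
    taxa = data.taxa
    T = len(taxa)
    N = data.pollen.to_numpy(dtype=float)
    X, B = _design(data, cutoff, submodel)
    ref = taxa.index(data.reference_taxon)
    messages: list[str] = []

    zero_dwpa = X.sum(axis=0) <= 0
    if zero_dwpa[ref]:
        raise ValueError("reference taxon has zero DWPA at this cutoff")
    for i in np.flatnonzero(zero_dwpa):
        if N[:, i].sum() > 0:
            msg = (
                f"taxon {taxa[i]!r} absent from vegetation at cutoff "
                f"{cutoff} m; holding its RPP at 0 (background absorbs it)"
            )
            warnings.warn(msg, stacklevel=2)
            messages.append(msg)

    # free alpha indices: all but reference and zero-DWPA taxa
    free_a = [i for i in range(T) if i != ref and not zero_dwpa[i]]

    def unpack(theta):
        alpha = np.zeros(T)
        alpha[ref] = 1.0
        alpha[free_a] = np.exp(theta[: len(free_a)])
        omega = np.exp(theta[len(free_a):])
        return alpha, omega

    def negloglik(theta):
        alpha, omega = unpack(theta)
        ll, ga, go = _loglik_grad(alpha, omega, N, X, B)
        grad = np.concatenate([ga[free_a] * alpha[free_a], go * omega])
        return -ll, -grad

    # moment-style initial values: alpha from mean pollen/DWPA ratios
    p_bar = np.maximum(N.sum(axis=0) / N.sum(), 1e-6)
    x_bar = np.maximum(X.mean(axis=0), 1e-12)
    a0 = (p_bar / x_bar) / (p_bar[ref] / x_bar[ref])
    w0 = np.maximum(0.1 * a0 * x_bar * B.mean(), 1e-8) / np.maximum(B.mean(), 1e-12)
    theta0 = np.concatenate([np.log(a0[free_a]), np.log(w0)])
    if warm_start is not None:
        a_ws = warm_start.rpp[taxa].to_numpy(dtype=float)
        w_ws = warm_start.background[taxa].to_numpy(dtype=float)
        theta0 = np.concatenate(
            [np.log(np.maximum(a_ws[free_a], 1e-8)), np.log(np.maximum(w_ws, 1e-10))]
        )

    rng = np.random.default_rng(seed)
    best = None
    bounds = [(-40.0, 40.0)] * theta0.size
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.7, theta0.size)
        res = optimize.minimize(
            negloglik,
            np.clip(start, -40, 40),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"ERV fit failed to converge: {best}")

    alpha, omega = unpack(best.x)
    loglik = -float(best.fun)

    sd = _rpp_sd(alpha, omega, N, X, B, ref, free_a, messages)

    rpp = pd.Series(alpha, index=taxa, name="rpp")
    rpp_sd = pd.Series(sd, index=taxa, name="rpp_sd")
    background = pd.Series(omega, index=taxa, name="background")
    return ErvFit(
        rpp=rpp,
        rpp_sd=rpp_sd,
        background=background,
        loglik=loglik,
        cutoff=float(cutoff),
        submodel=submodel,
        converged=bool(best.success),
        messages=messages,
    )


def _rpp_sd(alpha, omega, N, X, B, ref, free_a, messages):
    """Asymptotic SDs of alpha from the observed information.

    Hessian of the negative log-likelihood in natural (alpha_free, omega)
    coordinates by central differences of the analytic gradient; the
    reference taxon has SD 0 by construction.
    """
    T = alpha.size
    free = list(free_a) + list(range(T))  # alpha block then omega block
    n_free_a = len(free_a)
    m = n_free_a + T

    def grad_nat(v):
        a = alpha.copy()
        a[free_a] = v[:n_free_a]
        w = v[n_free_a:]
        _, ga, go = _loglik_grad(a, w, N, X, B)
        return -np.concatenate([ga[free_a], go])

    v0 = np.concatenate([alpha[free_a], omega])
    H = np.zeros((m, m))
    h = np.maximum(1e-5 * np.abs(v0), 1e-9)
    for j in range(m):
        e = np.zeros(m)
        e[j] = h[j]
        H[:, j] = (grad_nat(v0 + e) - grad_nat(v0 - e)) / (2 * h[j])
    H = (H + H.T) / 2.0

    sd = np.zeros(T)
    try:
        cov = np.linalg.inv(H)
        var_a = np.diag(cov)[:n_free_a]
        if (var_a < 0).any():
            raise np.linalg.LinAlgError("negative variance")
        sd[free_a] = np.sqrt(var_a)
    except np.linalg.LinAlgError:
        msg = "observed information singular; RPP SDs reported as NaN"
        warnings.warn(msg, stacklevel=3)
        messages.append(msg)
        sd[free_a] = np.nan
    sd[ref] = 0.0
    return sd


def likelihood_curve(
    data: ErvDataset,
    distances,
    submodel: int = 3,
    n_starts: int = 3,
    seed: int = 0,
) -> LikelihoodCurve:
    """Refit the ERV model at each distance and record the log-likelihood.

    Each distance gets a full refit (warm-started from the previous one for
    speed); a failed refit is flagged in ``ok`` rather than dropped.
    """
    distances = np.asarray(sorted(distances), dtype=float)
    lls = np.full(distances.size, np.nan)
    ok = np.zeros(distances.size, dtype=bool)
    prev = None
    for j, d in enumerate(distances):
        try:
            fit = fit_erv(
                data, d, submodel=submodel,
                n_starts=n_starts if prev is None else max(1, n_starts - 2),
                seed=seed, warm_start=prev,
            )
            lls[j] = fit.loglik
            ok[j] = True
            prev = fit
        except (ValueError, RuntimeError) as exc:  # flagged, not dropped
            warnings.warn(f"refit failed at {d} m: {exc}", stacklevel=2)
    return LikelihoodCurve(distances, lls, ok)


def _window_slope_pvalue(d, y):
    """Two-sided p-value for the OLS slope of y on d being zero."""
    if np.allclose(y, y[0]):
        return 0.0, 1.0  # exactly flat: slope 0, never significant
    res = stats.linregress(d, y)
    p = res.pvalue
    if np.isnan(p):  # degenerate (e.g. perfect line): fall back on slope size
        p = 1.0 if abs(res.slope) < 1e-12 * max(1.0, np.abs(y).max()) else 0.0
    return res.slope, p


def estimate_rsap(
    curve: LikelihoodCurve,
    window_width: float,
    alpha_level: float = 0.05,
) -> RsapResult:
    """RSAP = start of the first moving window whose regression slope is not
    significantly different from zero, with every later window also
    non-significant (guards against premature asymptote calls).

    Windows are anchored at curve points and span ``window_width`` metres;
    each needs >= 3 usable points.  A curve whose slope never flattens is
    flagged ``no_asymptote``.
    """
    d = curve.distances[curve.ok]
    y = curve.loglik[curve.ok]
    if d.size < 3:
        raise ValueError("need at least 3 usable curve points")

    starts, signif = [], []
    for s in range(d.size):
        sel = (d >= d[s]) & (d <= d[s] + window_width + 1e-9)
        if sel.sum() < 3:
            continue
        _, p = _window_slope_pvalue(d[sel], y[sel])
        starts.append(d[s])
        signif.append(p < alpha_level)
    if not starts:
        raise ValueError(
            f"window width {window_width} m spans < 3 points; widen it "
            "or refine the distance grid"
        )

    signif = np.asarray(signif)
    if signif.all():
        return RsapResult(np.nan, window_width, alpha_level, no_asymptote=True)
    # first non-significant window after the last significant one
    last_sig = np.flatnonzero(signif)
    first_ok = 0 if last_sig.size == 0 else int(last_sig[-1]) + 1
    if first_ok >= len(starts):
        return RsapResult(np.nan, window_width, alpha_level, no_asymptote=True)
    return RsapResult(float(starts[first_ok]), window_width, alpha_level)
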