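"""Generative point-process models: simulators, fitters, and ranking.

The model menu mirrors the ecological driver table for benthic point
patterns:

* CSR / heterogeneous Poisson (trend in x, y, x+y, or a taxon's density)
  — habitat association; fitted by maximum likelihood in
  :mod:`sppa.intensity`.
* Thomas cluster process (homogeneous or trend-thinned) — reproductive /
  dispersal-limited recruitment; fitted by minimum contrast on the K
  function with the Diggle–Gratton exponents (q = 1/4, p = 2).
* Linked Thomas process — two taxa sharing parents; facilitation.
* Gibbs hard-core / soft-core processes — competition; fitted by maximum
  pseudolikelihood with Berman–Turner quadrature, the soft-core kappa
  profiled on a grid over [0.1, 0.9].

AIC-style criteria are comparable only within a family (cluster fits carry
a contrast value, not a likelihood); cross-family decisions belong to the
goodness-of-fit stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .geometry import InsufficientPointsError, ObservationWindow, PointPattern
from .intensity import IntensitySurface, PoissonFit, fit_poisson
from .summaries import k_function

__all__ = [
    "ThomasParams", "GibbsParams", "ThomasFit", "LinkedThomasFit", "GibbsFit",
    "simulate_csr", "simulate_poisson_surface", "simulate_thomas",
    "simulate_linked_thomas", "simulate_gibbs",
    "fit_thomas", "fit_linked_thomas", "fit_gibbs", "rank_models",
    "thomas_pcf_theoretical", "thomas_k_theoretical",
]


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThomasParams:
    """Thomas cluster process: Poisson(kappa) parents, Poisson(mu) offspring
    displaced by an isotropic Gaussian of s.d. sigma (metres)."""
    kappa: float            # parent intensity, m^-2
    sigma: float            # offspring dispersal s.d., m
    mu: float               # mean offspring per parent

    def __post_init__(self):
        if not (self.kappa > 0 and self.sigma > 0 and self.mu > 0):
            raise ValueError("kappa, sigma and mu must be positive")


@dataclass(frozen=True)
class GibbsParams:
    """Pairwise-interaction Gibbs process parameters.

    hardcore: pair density h(d) = 0 for d < hc_radius.
    softcore: h(d) = exp(-(sc_sigma/d)^(2/sc_kappa)), sc_kappa in [0.1, 0.9].
    """
    family: str             # "hardcore" | "softcore"
    beta: float = 1.0       # first-order intensity parameter, m^-2
    hc_radius: Optional[float] = None
    sc_sigma: Optional[float] = None
    sc_kappa: Optional[float] = None

    def __post_init__(self):
        if self.family == "hardcore":
            if not (self.hc_radius and self.hc_radius > 0):
                raise ValueError("hardcore needs hc_radius > 0")
        elif self.family == "softcore":
            if not (self.sc_sigma and self.sc_sigma > 0):
                raise ValueError("softcore needs sc_sigma > 0")
            if not (0.1 <= (self.sc_kappa or 0) <= 0.9):
                raise ValueError("sc_kappa must lie in [0.1, 0.9]")
        else:
            raise ValueError("family must be 'hardcore' or 'softcore'")


# ---------------------------------------------------------------------------
# theoretical Thomas summaries
# ---------------------------------------------------------------------------

def thomas_pcf_theoretical(r, kappa, sigma):
    """g(r) = 1 + exp(-r^2/(4 sigma^2)) / (4 pi kappa sigma^2)."""
    r = np.asarray(r, float)
    return 1.0 + np.exp(-r**2 / (4 * sigma**2)) / (4 * np.pi * kappa * sigma**2)


def thomas_k_theoretical(r, kappa, sigma):
    """K(r) = pi r^2 + (1 - exp(-r^2/(4 sigma^2))) / kappa."""
    r = np.asarray(r, float)
    return np.pi * r**2 + (1.0 - np.exp(-r**2 / (4 * sigma**2))) / kappa


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _uniform_in_window(window: ObservationWindow, n: int, rng) -> tuple:
    """n uniform points inside the window polygon by rejection sampling."""
    xmin, xmax, ymin, ymax = window.bbox
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = max(64, 2 * (n - got))
        px = rng.uniform(xmin, xmax, m)
        py = rng.uniform(ymin, ymax, m)
        ok = window.contains(px, py)
        px, py = px[ok], py[ok]
        take = min(len(px), n - got)
        xs[got:got + take] = px[:take]
        ys[got:got + take] = py[:take]
        got += take
    return xs, ys


def simulate_csr(window: ObservationWindow, n: Optional[int] = None,
                 intensity: Optional[float] = None, seed=None) -> PointPattern:
    """Complete Spatial Randomness in the window.

    Conditional variant (``n`` given) places exactly n uniform points;
    otherwise the count is Poisson(intensity * |W|).
    """
    rng = np.random.default_rng(seed)
    if n is None:
        if intensity is None:
            raise ValueError("give either n or intensity")
        n = int(rng.poisson(intensity * window.area))
    xs, ys = _uniform_in_window(window, int(n), rng)
    return PointPattern(xs, ys, window, allow_duplicates=True)


def simulate_poisson_surface(surface: IntensitySurface, seed=None,
                             n: Optional[int] = None) -> PointPattern:
    """Heterogeneous Poisson sample from an intensity surface by thinning."""
    rng = np.random.default_rng(seed)
    win = surface.window
    lam_max = surface.max()
    target = int(rng.poisson(surface.integral())) if n is None else int(n)
    xmin, xmax, ymin, ymax = win.bbox
    xs = np.empty(target)
    ys = np.empty(target)
    got = 0
    while got < target:
        m = max(64, 2 * (target - got))
        px = rng.uniform(xmin, xmax, m)
        py = rng.uniform(ymin, ymax, m)
        ok = win.contains(px, py)
        px, py = px[ok], py[ok]
        keep = rng.uniform(0, lam_max, len(px)) < surface.at(px, py)
        px, py = px[keep], py[keep]
        take = min(len(px), target - got)
        xs[got:got + take] = px[:take]
        ys[got:got + take] = py[:take]
        got += take
    return PointPattern(xs, ys, win, allow_duplicates=True)


def _thomas_points(params: ThomasParams, window: ObservationWindow, rng):
    """Raw Thomas offspring falling inside the window (unthinned)."""
    xmin, xmax, ymin, ymax = window.bbox
    pad = 4.0 * params.sigma
    lx, ly = (xmax - xmin) + 2 * pad, (ymax - ymin) + 2 * pad
    n_parents = rng.poisson(params.kappa * lx * ly)
    px = rng.uniform(xmin - pad, xmax + pad, n_parents)
    py = rng.uniform(ymin - pad, ymax + pad, n_parents)
    n_off = rng.poisson(params.mu, n_parents)
    ox = np.repeat(px, n_off) + rng.normal(0, params.sigma, n_off.sum())
    oy = np.repeat(py, n_off) + rng.normal(0, params.sigma, n_off.sum())
    keep = window.contains(ox, oy)
    return ox[keep], oy[keep]


def simulate_thomas(params: ThomasParams, window: ObservationWindow, seed=None,
                    trend: Optional[IntensitySurface] = None) -> PointPattern:
    """Thomas cluster process in the window.

    Parents are simulated on the window dilated by 4 sigma so boundary
    clusters are not lost. With ``trend`` the offspring are independently
    thinned with probability trend(u)/max(trend) (inhomogeneous variant).
    """
    rng = np.random.default_rng(seed)
    ox, oy = _thomas_points(params, window, rng)
    if trend is not None and len(ox):
        p = np.clip(trend.at(ox, oy) / trend.max(), 0, 1)
        keep = rng.uniform(size=len(ox)) < p
        ox, oy = ox[keep], oy[keep]
    return PointPattern(ox, oy, window, allow_duplicates=True)


def simulate_linked_thomas(params: ThomasParams, mu_by_type: dict,
                           window: ObservationWindow, seed=None,
                           trend: Optional[IntensitySurface] = None) -> PointPattern:
    """Linked Thomas process: one shared parent process, per-type offspring.

    Each parent independently spawns Poisson(mu_type) offspring of each
    type, all displaced by the shared Gaussian sigma — the minimal
    shared-parent model for cross-clustered (facilitated) bivariate
    patterns. ``params.mu`` is ignored in favour of ``mu_by_type``.
    """
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = window.bbox
    pad = 4.0 * params.sigma
    lx, ly = (xmax - xmin) + 2 * pad, (ymax - ymin) + 2 * pad
    n_parents = rng.poisson(params.kappa * lx * ly)
    px = rng.uniform(xmin - pad, xmax + pad, n_parents)
    py = rng.uniform(ymin - pad, ymax + pad, n_parents)
    xs, ys, ms = [], [], []
    levels = tuple(mu_by_type)
    for mark in levels:
        n_off = rng.poisson(mu_by_type[mark], n_parents)
        ox = np.repeat(px, n_off) + rng.normal(0, params.sigma, n_off.sum())
        oy = np.repeat(py, n_off) + rng.normal(0, params.sigma, n_off.sum())
        keep = window.contains(ox, oy)
        ox, oy = ox[keep], oy[keep]
        if trend is not None and len(ox):
            p = np.clip(trend.at(ox, oy) / trend.max(), 0, 1)
            sel = rng.uniform(size=len(ox)) < p
            ox, oy = ox[sel], oy[sel]
        xs.append(ox)
        ys.append(oy)
        ms.extend([mark] * len(ox))
    return PointPattern(np.concatenate(xs), np.concatenate(ys), window,
                        marks=ms, mark_levels=levels, allow_duplicates=True)


def _log_interaction_delta(family, coords, k, new_xy, hc=None, sc_sigma=None,
                           sc_kappa=None):
    """Log pairwise-interaction change from moving point k to new_xy.

    Returns -inf when the move violates a hard core. Squared distances
    throughout; the moving point masks itself with +inf.
    """
    d2_new = (coords[:, 0] - new_xy[0]) ** 2 + (coords[:, 1] - new_xy[1]) ** 2
    d2_new[k] = np.inf
    if family == "hardcore":
        return -np.inf if d2_new.min() < hc * hc else 0.0
    d2_old = (coords[:, 0] - coords[k, 0]) ** 2 + (coords[:, 1] - coords[k, 1]) ** 2
    d2_old[k] = np.inf
    s2 = sc_sigma * sc_sigma
    inv_kap = 1.0 / sc_kappa
    pen_new = ((s2 / d2_new) ** inv_kap).sum()
    pen_old = ((s2 / d2_old) ** inv_kap).sum()
    return pen_old - pen_new


def simulate_gibbs(params: GibbsParams, window: ObservationWindow,
                   n_target: int, seed=None, n_sweeps: int = 100_000,
                   log_trend: Optional[Callable] = None) -> PointPattern:
    """Metropolis shift chain for a fixed-count pairwise-interaction process.

    Conditional on n = ``n_target``: each proposal relocates one point
    uniformly in the window and is accepted with the interaction (and
    optional first-order trend) density ratio. ``n_sweeps`` counts
    proposals. Hard-core chains start from a random sequential adsorption
    state; an infeasible packing raises before sampling.
    """
    rng = np.random.default_rng(seed)
    n = int(n_target)
    if n == 0:
        return PointPattern([], [], window)
    if params.family == "hardcore":
        # feasibility: pack n disks by random sequential adsorption
        xs, ys = [], []
        attempts = 0
        limit = 2000 * n
        while len(xs) < n:
            if attempts > limit:
                raise ValueError(
                    f"cannot pack {n} points with hard core {params.hc_radius} m "
                    f"in a {window.area:.2f} m^2 window")
            cx, cy = _uniform_in_window(window, 1, rng)
            attempts += 1
            if xs:
                d = np.hypot(np.array(xs) - cx[0], np.array(ys) - cy[0])
                if d.min() < params.hc_radius:
                    continue
            xs.append(cx[0])
            ys.append(cy[0])
        coords = np.column_stack([xs, ys])
    else:
        xs, ys = _uniform_in_window(window, n, rng)
        coords = np.column_stack([xs, ys])

    log_t = log_trend if log_trend is not None else (lambda x, y: 0.0)
    which = rng.integers(0, n, n_sweeps)
    u = np.log(rng.uniform(size=n_sweeps))
    prop_x, prop_y = _uniform_in_window(window, n_sweeps, rng)
    for step in range(n_sweeps):
        k = which[step]
        new_xy = (prop_x[step], prop_y[step])
        delta = _log_interaction_delta(
            params.family, coords, k, new_xy, hc=params.hc_radius,
            sc_sigma=params.sc_sigma, sc_kappa=params.sc_kappa)
        if delta == -np.inf:
            continue
        delta += (np.asarray(log_t(new_xy[0], new_xy[1])).item()
                  - np.asarray(log_t(coords[k, 0], coords[k, 1])).item())
        if u[step] < delta:
            coords[k, 0] = new_xy[0]
            coords[k, 1] = new_xy[1]
    return PointPattern(coords[:, 0], coords[:, 1], window, allow_duplicates=True)


# ---------------------------------------------------------------------------
# fitted-model records
# ---------------------------------------------------------------------------

@dataclass
class ThomasFit:
    """Minimum-contrast Thomas cluster fit (optionally trend-thinned)."""
    params: ThomasParams
    contrast: float
    family: str = "thomas"              # "thomas" | "thomas_inhom"
    trend_fit: Optional[PoissonFit] = None
    window: Optional[ObservationWindow] = None
    n_obs: int = 0
    flagged: bool = False
    diagnostic: str = ""
    criterion: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.criterion:
            self.criterion = {"contrast": self.contrast}

    def simulate(self, seed, n: Optional[int] = None) -> PointPattern:
        trend = self.trend_fit.fitted_intensity if self.trend_fit is not None else None
        p = self.params
        if trend is not None:
            # compensate thinning so the expected count matches the data
            keep = trend.integral() / (trend.max() * trend.window.area)
            p = ThomasParams(p.kappa, p.sigma, p.mu / max(keep, 1e-9))
        return simulate_thomas(p, self.window, seed=seed, trend=trend)

    def to_dict(self) -> dict:
        return {"family": self.family, "kappa": self.params.kappa,
                "sigma": self.params.sigma, "mu": self.params.mu,
                "contrast": self.contrast, "flagged": self.flagged,
                "diagnostic": self.diagnostic,
                "trend": (self.trend_fit.to_dict() if self.trend_fit else None)}


@dataclass
class LinkedThomasFit:
    """Shared-parent (linked) Thomas fit from the cross-K function."""
    params: ThomasParams                # kappa, sigma shared; mu unused
    mu_by_type: dict
    contrast: float
    window: Optional[ObservationWindow] = None
    family: str = "linked_thomas"
    flagged: bool = False
    diagnostic: str = ""
    criterion: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.criterion:
            self.criterion = {"contrast": self.contrast}

    def simulate(self, seed, n: Optional[int] = None) -> PointPattern:
        return simulate_linked_thomas(self.params, self.mu_by_type,
                                      self.window, seed=seed)

    def to_dict(self) -> dict:
        return {"family": self.family, "kappa": self.params.kappa,
                "sigma": self.params.sigma, "mu_by_type": dict(self.mu_by_type),
                "contrast": self.contrast, "flagged": self.flagged}


@dataclass
class GibbsFit:
    """Maximum-pseudolikelihood Gibbs (hard-core / soft-core) fit."""
    params: GibbsParams
    log_pl: float
    pseudo_aic: float
    trend_spec: str = "constant"
    trend_coefs: Optional[np.ndarray] = None
    window: Optional[ObservationWindow] = None
    n_obs: int = 0
    family: str = "hardcore"
    flagged: bool = False
    diagnostic: str = ""
    criterion: dict = field(default_factory=dict)
    n_sweeps: int = 20_000

    def __post_init__(self):
        if not self.criterion:
            self.criterion = {"pseudo_aic": self.pseudo_aic}

    def _log_trend(self):
        if self.trend_spec == "constant" or self.trend_coefs is None:
            return None
        coefs = self.trend_coefs

        def lt(x, y):
            out = 0.0
            if self.trend_spec in ("x", "x+y"):
                out = out + coefs[0] * x
            if self.trend_spec == "y":
                out = out + coefs[0] * y
            if self.trend_spec == "x+y":
                out = out + coefs[1] * y
            return out
        return lt

    def simulate(self, seed, n: Optional[int] = None) -> PointPattern:
        return simulate_gibbs(self.params, self.window,
                              n_target=n if n is not None else self.n_obs,
                              seed=seed, n_sweeps=self.n_sweeps,
                              log_trend=self._log_trend())

    def to_dict(self) -> dict:
        d = {"family": self.family, "beta": self.params.beta,
             "log_pl": self.log_pl, "pseudo_aic": self.pseudo_aic,
             "trend_spec": self.trend_spec, "flagged": self.flagged,
             "diagnostic": self.diagnostic}
        if self.family == "hardcore":
            d["hc_radius"] = self.params.hc_radius
        else:
            d["sc_sigma"] = self.params.sc_sigma
            d["sc_kappa"] = self.params.sc_kappa
        return d


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------

def _min_contrast_thomas(r, k_emp, area_n_ratio=None):
    """Minimise int (K_emp^1/4 - K_model^1/4)^2 dr over (kappa, sigma)."""
    mask = r > 0
    rr, kk = r[mask], np.clip(k_emp[mask], 0, None)
    k_q = kk ** 0.25

    def objective(theta):
        kappa, sigma = np.exp(theta)
        km = thomas_k_theoretical(rr, kappa, sigma) ** 0.25
        return np.trapezoid((k_q - km) ** 2, rr)

    best = None
    for s0 in (0.03, 0.1, 0.3):
        for k0 in (0.2, 1.0, 5.0):
            res = minimize(objective, np.log([k0, s0]), method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 600})
            if best is None or res.fun < best.fun:
                best = res
    kappa, sigma = np.exp(best.x)
    return kappa, sigma, float(best.fun)


def fit_thomas(pattern: PointPattern, r_max: Optional[float] = None,
               intensity=None, trend_fit: Optional[PoissonFit] = None,
               n_grid: int = 256) -> ThomasFit:
    """Minimum-contrast Thomas fit on the (inhomogeneous) K function.

    With ``trend_fit`` (a fitted heterogeneous Poisson trend) the empirical
    K is the inhomogeneous estimator under that trend and the result is the
    inhomogeneous Thomas family. mu is recovered from n/(kappa |W|).
    Boundary solutions and cluster strengths indistinguishable from CSR are
    flagged, not silently returned.
    """
    if pattern.n < 5:
        raise InsufficientPointsError("Thomas fitting needs at least 5 points")
    if trend_fit is not None and intensity is None:
        intensity = trend_fit.intensity_at(pattern.x, pattern.y)
    K = k_function(pattern, r_max=r_max, intensity=intensity, n_grid=n_grid)
    kappa, sigma, contrast = _min_contrast_thomas(K.r, K.values)
    mu = pattern.n / (kappa * pattern.window.area)
    flagged = False
    diag = ""
    r_hi = K.r[-1]
    excess = 1.0 / (4 * np.pi * kappa * sigma**2)  # g(0) - 1 of the fit
    if sigma > r_hi or sigma < 1e-4:
        flagged = True
        diag = f"sigma at boundary ({sigma:.4g} m)"
    elif excess < 0.15:
        flagged = True
        diag = f"no cluster evidence (fitted g(0)-1 = {excess:.3g})"
    elif kappa * pattern.window.area > 100 * pattern.n:
        flagged = True
        diag = f"implausible parent density (kappa = {kappa:.3g} /m^2)"
    fam = "thomas" if trend_fit is None else "thomas_inhom"
    return ThomasFit(params=ThomasParams(kappa, sigma, mu), contrast=contrast,
                     family=fam, trend_fit=trend_fit, window=pattern.window,
                     n_obs=pattern.n, flagged=flagged, diagnostic=diag)


def fit_linked_thomas(pattern: PointPattern, mark_i: str, mark_j: str,
                      r_max: Optional[float] = None,
                      n_grid: int = 256) -> LinkedThomasFit:
    """Fit the shared-parent Thomas model from the cross-K function.

    For a linked Thomas process the cross-K has the same closed form as the
    univariate Thomas K, because cross pairs share a parent:
    K12(r) = pi r^2 + (1 - exp(-r^2/(4 sigma^2)))/kappa.
    """
    from .summaries import k_multitype
    K = k_multitype(pattern, mark_i, mark_j, r_max=r_max, n_grid=n_grid)
    kappa, sigma, contrast = _min_contrast_thomas(K.r, K.values)
    counts = pattern.counts_by_mark()
    area = pattern.window.area
    mu_by_type = {m: counts[m] / (kappa * area) for m in (mark_i, mark_j)}
    flagged = False
    diag = ""
    excess = 1.0 / (4 * np.pi * kappa * sigma**2)
    if sigma > K.r[-1] or sigma < 1e-4:
        flagged, diag = True, f"sigma at boundary ({sigma:.4g} m)"
    elif excess < 0.15:
        flagged, diag = True, f"no cross-cluster evidence (g12(0)-1 = {excess:.3g})"
    elif kappa * area > 100 * pattern.n:
        flagged, diag = True, f"implausible parent density (kappa = {kappa:.3g} /m^2)"
    return LinkedThomasFit(params=ThomasParams(kappa, sigma, 1.0),
                           mu_by_type=mu_by_type, contrast=contrast,
                           window=pattern.window, flagged=flagged,
                           diagnostic=diag)


def _bt_quadrature(pattern: PointPattern, resolution: float = 0.1):
    """Berman–Turner device: data + dummy points with counting weights."""
    win = pattern.window
    xmin, xmax, ymin, ymax = win.bbox
    nx = max(2, int(np.ceil((xmax - xmin) / resolution)))
    ny = max(2, int(np.ceil((ymax - ymin) / resolution)))
    dx = (np.arange(nx) + 0.5) * (xmax - xmin) / nx + xmin
    dy = (np.arange(ny) + 0.5) * (ymax - ymin) / ny + ymin
    DX, DY = np.meshgrid(dx, dy)
    ok = win.contains(DX.ravel(), DY.ravel())
    qx = np.concatenate([pattern.x, DX.ravel()[ok]])
    qy = np.concatenate([pattern.y, DY.ravel()[ok]])
    is_data = np.zeros(len(qx), bool)
    is_data[:pattern.n] = True
    # counting weights: cell area / points per cell
    cell_w = (xmax - xmin) / nx
    cell_h = (ymax - ymin) / ny
    ix = np.clip(((qx - xmin) / cell_w).astype(int), 0, nx - 1)
    iy = np.clip(((qy - ymin) / cell_h).astype(int), 0, ny - 1)
    cell_id = iy * nx + ix
    counts = np.bincount(cell_id, minlength=nx * ny)
    w = cell_w * cell_h / counts[cell_id]
    return qx, qy, w, is_data


def _trend_columns(spec, x, y):
    if spec == "constant":
        return []
    if spec == "x":
        return [x]
    if spec == "y":
        return [y]
    if spec == "x+y":
        return [x, y]
    raise ValueError(f"unknown trend spec {spec!r}")


def fit_gibbs(pattern: PointPattern, family: str, trend: str = "constant",
              sc_kappa_grid=None, quad_resolution: float = 0.1,
              n_sweeps: int = 20_000) -> GibbsFit:
    """Maximum pseudolikelihood fit of a hard-core or soft-core process.

    Berman–Turner quadrature (data + dummy grid, counting weights). The
    hard-core radius is profiled at its MPLE, the minimum nearest-neighbour
    distance; the soft-core shape kappa is profiled on a grid over
    [0.1, 0.9] with the best profile pseudolikelihood retained.
    pseudo-AIC = 2k - 2 max log PL.
    """
    if pattern.n < 10:
        raise InsufficientPointsError("Gibbs fitting needs at least 10 points")
    from .geometry import nnd_summary
    qx, qy, w, is_data = _bt_quadrature(pattern, quad_resolution)
    cols_q = _trend_columns(trend, qx, qy)
    Z = np.column_stack([np.ones(len(qx))] + cols_q)
    nnd = nnd_summary(pattern)
    tree = cKDTree(pattern.coords)

    if family == "hardcore":
        hc = nnd.min  # profile MPLE: largest radius consistent with the data
        d1_all, i1 = tree.query(np.column_stack([qx, qy]), k=2)
        # distance to nearest *other* point: data points see their NN,
        # dummies see the nearest data point
        d_near = np.where(is_data, d1_all[:, 1], d1_all[:, 0])
        allowed = d_near >= hc * (1 - 1e-9)
        k_beta = Z.shape[1]

        def negpl(beta):
            eta = np.clip(Z @ beta, -500, 500)
            lam = np.exp(eta) * allowed
            ll = (eta[is_data]).sum() - (w * lam).sum()
            return -ll

        def gradpl(beta):
            lam = np.exp(np.clip(Z @ beta, -500, 500)) * allowed
            return -(Z[is_data].sum(axis=0) - Z.T @ (w * lam))

        beta0 = np.zeros(k_beta)
        beta0[0] = np.log(pattern.n / pattern.window.area)
        res = minimize(negpl, beta0, jac=gradpl, method="L-BFGS-B")
        log_pl = -res.fun
        k = k_beta + 1  # + profiled hc radius
        params = GibbsParams(family="hardcore", beta=float(np.exp(res.x[0])),
                             hc_radius=float(hc))
        return GibbsFit(params=params, log_pl=float(log_pl),
                        pseudo_aic=float(2 * k - 2 * log_pl), trend_spec=trend,
                        trend_coefs=res.x[1:] if k_beta > 1 else None,
                        window=pattern.window, n_obs=pattern.n,
                        family="hardcore", flagged=not res.success,
                        diagnostic="" if res.success else str(res.message),
                        n_sweeps=n_sweeps)

    if family != "softcore":
        raise ValueError("family must be 'hardcore' or 'softcore'")
    if sc_kappa_grid is None:
        sc_kappa_grid = np.round(np.arange(0.1, 0.95, 0.1), 2)

    # distances from every quadrature point to every data point, once;
    # self-distances (data rows) masked out of the penalty sum
    D = np.hypot(qx[:, None] - pattern.x[None, :],
                 qy[:, None] - pattern.y[None, :])
    D = np.clip(D, 1e-9, None)
    self_mask = np.zeros_like(D, dtype=bool)
    self_mask[:pattern.n] = np.eye(pattern.n, dtype=bool)
    k_beta = Z.shape[1]
    Zd_sum = Z[is_data].sum(axis=0)
    best = None
    for kap in sc_kappa_grid:
        expo = 2.0 / kap
        S = np.where(self_mask, 0.0, D ** (-expo)).sum(axis=1)
        Sd_sum = S[is_data].sum()

        def negpl(theta):
            beta, th = theta[:k_beta], theta[k_beta]
            eta = np.clip(Z @ beta - th * S, -500, 500)
            lam_w = w * np.exp(eta)
            f = -(eta[is_data].sum() - lam_w.sum())
            g = np.empty(k_beta + 1)
            g[:k_beta] = -(Zd_sum - Z.T @ lam_w)
            g[k_beta] = Sd_sum - S @ lam_w
            return f, g

        theta0 = np.zeros(k_beta + 1)
        theta0[0] = np.log(pattern.n / pattern.window.area)
        res = minimize(negpl, theta0, jac=True, method="L-BFGS-B",
                       bounds=[(None, None)] * k_beta + [(0.0, None)])
        if best is None or -res.fun > best[0]:
            best = (-res.fun, kap, res)
    log_pl, kap, res = best
    theta_hat = float(res.x[-1])               # sigma^(2/kappa)
    sigma_hat = theta_hat ** (kap / 2.0) if theta_hat > 0 else 0.0
    k = Z.shape[1] + 2                          # + sigma + profiled kappa
    params = GibbsParams(family="softcore", beta=float(np.exp(res.x[0])),
                         sc_sigma=max(sigma_hat, 1e-9), sc_kappa=float(kap))
    return GibbsFit(params=params, log_pl=float(log_pl),
                    pseudo_aic=float(2 * k - 2 * log_pl), trend_spec=trend,
                    trend_coefs=res.x[1:-1] if Z.shape[1] > 1 else None,
                    window=pattern.window, n_obs=pattern.n, family="softcore",
                    flagged=not np.isfinite(log_pl),
                    diagnostic="", n_sweeps=n_sweeps)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

_CRITERION_KEYS = ("aic", "pseudo_aic", "contrast")


def rank_models(fits, top_per_family: int = 2):
    """Within-family shortlist by the family's own fit criterion.

    Families are never interleaved by raw criterion values (an AIC and a
    minimum-contrast value are not comparable); the shortlist carries the
    two best fits per family forward to the goodness-of-fit stage.
    """
    if not fits:
        raise ValueError("rank_models needs at least one fit")
    by_family = {}
    for f in fits:
        by_family.setdefault(f.family, []).append(f)
    shortlist = []
    for family in by_family:
        def crit(f):
            for key in _CRITERION_KEYS:
                if key in f.criterion:
                    return f.criterion[key]
            raise ValueError(f"fit of family {f.family} has no criterion")
        ranked = sorted(by_family[family], key=crit)
        shortlist.extend(ranked[:top_per_family])
    return shortlist
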