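"""Monte-Carlo tests and simulation envelopes.

Conventions shared by every test here:

* Monte-Carlo p-values are (1 + #{sim >= obs}) / (n_sim + 1); with the
  999 simulations used throughout, the smallest attainable p is 0.001.
* Envelope limits are the rank-th largest/smallest simulated values per
  distance; the defaults, 999 simulations with the 49th extremes, give a
  pointwise two-sided level of 2*49/1000 = 0.098. When the simulation
  count is reduced the rank is rescaled to preserve that nominal level.
* Null simulations of CSR condition on the observed point count; fitted
  models are simulated parametrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from shapely.geometry import box

from .geometry import PointPattern
from .models import simulate_csr
from .summaries import FunctionEstimate, l_function

__all__ = ["TestResult", "EnvelopeResult", "quadrat_mc_test", "envelope",
           "dclf_test", "nn_segregation_test", "kendall_tau", "scaled_rank"]

DEFAULT_N_SIM = 999
DEFAULT_RANK = 49


@dataclass
class TestResult:
    """Outcome of a statistical test with its Monte-Carlo provenance."""
    __test__ = False  # statistical result record, not a pytest class
    name: str
    statistic_value: float
    p_value: float
    dof: Optional[int] = None
    n_sim: Optional[int] = None
    verdict_threshold: float = 0.05
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value <= self.verdict_threshold

    def to_dict(self) -> dict:
        return {"name": self.name, "statistic": self.statistic_value,
                "dof": self.dof, "p_value": self.p_value, "n_sim": self.n_sim,
                **{k: v for k, v in self.extra.items()
                   if isinstance(v, (int, float, str, bool, type(None)))}}


@dataclass
class EnvelopeResult:
    """Pointwise simulation envelope around an observed summary function."""
    statistic: FunctionEstimate
    lo: np.ndarray
    hi: np.ndarray
    n_sim: int
    rank: int
    model: str
    excursions: list            # (r_start, r_end, direction "above"/"below")

    @property
    def has_excursions(self) -> bool:
        return len(self.excursions) > 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"r": self.statistic.r, "obs": self.statistic.values,
                             "lo": self.lo, "hi": self.hi})


def _mc_p(obs: float, sims: np.ndarray) -> float:
    return (1.0 + np.sum(sims >= obs)) / (len(sims) + 1.0)


def _child_seeds(seed, n):
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    return ss.spawn(n)


def scaled_rank(n_sim: int, rank: int = DEFAULT_RANK,
                ref_n_sim: int = DEFAULT_N_SIM) -> int:
    """Rescale the envelope rank to preserve the nominal pointwise level."""
    return max(1, int(np.floor(rank * (n_sim + 1) / (ref_n_sim + 1))))


# ---------------------------------------------------------------------------
# quadrat inhomogeneity test
# ---------------------------------------------------------------------------

def quadrat_mc_test(pattern: PointPattern, nx: int = 3, ny: int = 2,
                    n_sim: int = DEFAULT_N_SIM, seed=None) -> TestResult:
    """Monte-Carlo chi-square quadrat test of homogeneity.

    The window is partitioned into nx x ny equal sub-rectangles of the
    bounding box, clipped to the polygon; expected counts are proportional
    to clipped areas, and the chi-square statistic is calibrated against
    conditional CSR simulations with the same n (the small per-taxon counts
    make the asymptotic chi-square reference unreliable). p > 0.05 is read
    as homogeneity.
    """
    if nx * ny < 2:
        raise ValueError("need at least 2 quadrats")
    if pattern.n < 1:
        raise ValueError("empty pattern")
    win = pattern.window
    xmin, xmax, ymin, ymax = win.bbox
    xs = np.linspace(xmin, xmax, nx + 1)
    ys = np.linspace(ymin, ymax, ny + 1)
    if win.is_rectangle:
        areas = np.full(nx * ny, (xs[1] - xs[0]) * (ys[1] - ys[0]))
    else:
        areas = np.array([
            win.polygon.intersection(box(xs[i], ys[j], xs[i + 1], ys[j + 1])).area
            for j in range(ny) for i in range(nx)])
    keep = areas > 1e-12 * win.area
    areas = areas[keep]

    def chi2_of(x, y):
        ix = np.clip(((x - xmin) / (xs[1] - xs[0])).astype(int), 0, nx - 1)
        iy = np.clip(((y - ymin) / (ys[1] - ys[0])).astype(int), 0, ny - 1)
        counts = np.bincount(iy * nx + ix, minlength=nx * ny)[keep]
        expected = len(x) * areas / areas.sum()
        return float(np.sum((counts - expected) ** 2 / expected))

    obs = chi2_of(pattern.x, pattern.y)
    sims = np.empty(n_sim)
    for s, cs in enumerate(_child_seeds(seed, n_sim)):
        sim = simulate_csr(win, n=pattern.n, seed=cs)
        sims[s] = chi2_of(sim.x, sim.y)
    p = _mc_p(obs, sims)
    return TestResult(name="quadrat_mc", statistic_value=obs, p_value=p,
                      dof=len(areas) - 1, n_sim=n_sim,
                      extra={"nx": nx, "ny": ny, "homogeneous": p > 0.05})


# ---------------------------------------------------------------------------
# simulation envelopes
# ---------------------------------------------------------------------------

def _simulate_null(model, pattern: PointPattern, child_seed):
    if isinstance(model, str) and model == "csr":
        return simulate_csr(pattern.window, n=pattern.n, seed=child_seed)
    return model.simulate(child_seed)


def _extract_excursions(r, obs, lo, hi):
    out = []
    with np.errstate(invalid="ignore"):
        above = obs > hi
        below = obs < lo
    for mask, direction in ((above, "above"), (below, "below")):
        mask = np.where(np.isnan(obs), False, mask)
        edges = np.diff(mask.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if mask[0]:
            starts = [0] + starts
        if mask[-1]:
            ends = ends + [len(mask)]
        for s, e in zip(starts, ends):
            out.append((float(r[s]), float(r[e - 1]), direction))
    return sorted(out)


def envelope(pattern: PointPattern, statistic_fn: Callable, model="csr",
             n_sim: int = DEFAULT_N_SIM, rank: Optional[int] = None,
             seed=None, return_sims: bool = False) -> EnvelopeResult:
    """Pointwise Monte-Carlo envelope for a summary function.

    ``statistic_fn`` maps a pattern to a :class:`FunctionEstimate` on a
    fixed r grid. ``model`` is "csr" (simulated conditionally on n) or any
    fitted model with a ``simulate(seed)`` method. Excursions above the
    envelope indicate clustering (PCF > 1), below overdispersion (PCF < 1).
    """
    if rank is None:
        rank = scaled_rank(n_sim)
    obs = statistic_fn(pattern)
    sims = np.empty((n_sim, len(obs.r)))
    failures = 0
    for s, cs in enumerate(_child_seeds(seed, n_sim)):
        try:
            sims[s] = statistic_fn(_simulate_null(model, pattern, cs)).values
        except Exception:
            failures += 1
            if failures > max(1, n_sim // 100):
                raise RuntimeError(
                    f"simulation/statistic failed in more than 1% of replicates "
                    f"({failures}/{s + 1})")
            sims[s] = np.nan
    order = np.sort(sims, axis=0)
    lo = order[rank - 1]
    hi = order[n_sim - rank]
    excursions = _extract_excursions(obs.r, obs.values, lo, hi)
    result = EnvelopeResult(statistic=obs, lo=lo, hi=hi, n_sim=n_sim, rank=rank,
                            model=(model if isinstance(model, str)
                                   else getattr(model, "family", "model")),
                            excursions=excursions)
    if return_sims:
        return result, sims
    return result


# ---------------------------------------------------------------------------
# Diggle (DCLF) goodness-of-fit
# ---------------------------------------------------------------------------

def dclf_test(pattern: PointPattern, model="csr", r_max: Optional[float] = None,
              n_sim: int = DEFAULT_N_SIM, seed=None,
              statistic_fn: Optional[Callable] = None,
              n_grid: int = 256) -> TestResult:
    """Diggle's goodness-of-fit test from integrated squared L deviation.

    u = int_0^rmax (L_obs(r) - Lbar(r))^2 dr, with Lbar the mean simulated
    L; the same deviation is computed for every simulation (each against
    the mean of the others, making obs and sims exchangeable under the
    null) and p_d = (1 + #{u_sim >= u_obs}) / (n_sim + 1). p_d close to 1
    indicates a good fit; p_d <= 0.05 rejects the model.
    """
    if statistic_fn is None:
        def statistic_fn(p):
            return l_function(p, r_max=r_max, n_grid=n_grid)
    from .geometry import InsufficientPointsError
    obs = statistic_fn(pattern)
    r = obs.r
    rows = [obs.values]
    failures = 0
    for cs in _child_seeds(seed, n_sim):
        try:
            rows.append(statistic_fn(_simulate_null(model, pattern, cs)).values)
        except InsufficientPointsError:
            # a parametric replicate with < 2 points has no pairs: its
            # cumulative summary is identically zero, which duly penalises
            # models that keep simulating (near-)empty patterns
            rows.append(np.zeros_like(r))
        except Exception:
            failures += 1
            if failures > max(1, n_sim // 10):
                raise
    T = np.asarray(rows)
    m = len(T) - 1
    good = ~np.any(np.isnan(T), axis=0)
    Tg, rg = T[:, good], r[good]
    total = Tg.sum(axis=0)
    # each curve is compared with the mean of the other m curves
    u = np.array([np.trapezoid((Tg[j] - (total - Tg[j]) / m) ** 2, rg)
                  for j in range(m + 1)])
    p = (1.0 + np.sum(u[1:] >= u[0])) / (m + 1.0)
    return TestResult(name="dclf", statistic_value=float(u[0]), p_value=p,
                      n_sim=n_sim,
                      extra={"summary_function": obs.variant,
                             "model": (model if isinstance(model, str)
                                       else getattr(model, "family", "model"))})


# ---------------------------------------------------------------------------
# nearest-neighbour segregation (Dixon contingency) test
# ---------------------------------------------------------------------------

def _nn_counts(marks_idx: np.ndarray, nn: np.ndarray, n_types: int):
    N = np.zeros((n_types, n_types))
    np.add.at(N, (marks_idx, marks_idx[nn]), 1)
    return N


def _dixon_expected(counts: np.ndarray):
    n = counts.sum()
    E = np.outer(counts, counts) / (n - 1.0)
    np.fill_diagonal(E, counts * (counts - 1.0) / (n - 1.0))
    return E


def nn_segregation_test(pattern: PointPattern, n_sim: int = DEFAULT_N_SIM,
                        seed=None):
    """Dixon's nearest-neighbour contingency test of segregation.

    Counts of (type of point, type of its nearest neighbour) are compared
    with their random-labelling expectation; the overall statistic has 2
    degrees of freedom for two types. Returns the overall
    :class:`TestResult` and a per-type dict; p-values are random-labelling
    Monte Carlo (the asymptotic chi-square p is reported alongside).
    """
    if pattern.marks is None:
        raise ValueError("segregation test needs a marked pattern")
    levels = [m for m, c in pattern.counts_by_mark().items() if c > 0]
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 mark types with points, got {levels}")
    counts = np.array([pattern.counts_by_mark()[m] for m in levels], float)
    if np.any(counts < 5):
        raise ValueError("each type needs at least 5 points")
    marks_idx = np.array([levels.index(m) for m in pattern.marks])
    tree = cKDTree(pattern.coords)
    _, knn = tree.query(pattern.coords, k=2)
    nn = knn[:, 1]

    E = _dixon_expected(counts)

    def stats_of(mi):
        N = _nn_counts(mi, nn, 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = (N - E) ** 2 / E
        overall = float(np.nansum(cells))
        per_type = [float(np.nansum(cells[i])) for i in range(2)]
        return overall, per_type

    obs_all, obs_type = stats_of(marks_idx)
    rng = np.random.default_rng(seed)
    sims_all = np.empty(n_sim)
    sims_type = np.empty((n_sim, 2))
    for s in range(n_sim):
        perm = rng.permutation(marks_idx)
        sims_all[s], pt = stats_of(perm)
        sims_type[s] = pt
    overall = TestResult(
        name="nn_segregation", statistic_value=obs_all,
        p_value=_mc_p(obs_all, sims_all), dof=2, n_sim=n_sim,
        extra={"p_asymptotic": float(stats.chi2.sf(obs_all, 2)),
               "types": tuple(levels)})
    per_type = {
        levels[i]: TestResult(
            name=f"nn_segregation[{levels[i]}]", statistic_value=obs_type[i],
            p_value=_mc_p(obs_type[i], sims_type[:, i]), dof=1, n_sim=n_sim,
            extra={"p_asymptotic": float(stats.chi2.sf(obs_type[i], 1))})
        for i in range(2)}
    return overall, per_type


# ---------------------------------------------------------------------------
# Kendall correlation of per-transect densities
# ---------------------------------------------------------------------------

def kendall_tau(x, y) -> TestResult:
    """Kendall's tau-b with tie correction (exact p for n <= 10 when tie-free)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    ties = (len(np.unique(x)) < len(x)) or (len(np.unique(y)) < len(y))
    method = "exact" if (len(x) <= 10 and not ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return TestResult(name="kendall_tau", statistic_value=float(res.statistic),
                      p_value=float(res.pvalue),
                      extra={"n": len(x), "method": method})
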