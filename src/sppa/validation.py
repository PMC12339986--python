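"""End-to-end validation computations: estimator cross-checks, test
calibration, parameter recovery and driver recovery on synthetic suites.

Each function recomputes its quantity from scratch with its own seeded
simulations and an independent brute-force oracle where one applies
(direct pair summation, circumference sampling, concordance counting).
They back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import RunConfig
from .geometry import ObservationWindow, PointPattern, isotropic_weight
from .inference import run_transect_analysis
from .models import (GibbsParams, ThomasParams, fit_gibbs, fit_thomas,
                     simulate_csr, simulate_gibbs, simulate_thomas,
                     thomas_pcf_theoretical)
from .montecarlo import (dclf_test, envelope, nn_segregation_test,
                         quadrat_mc_test)
from .summaries import k_function, pcf
from .synthetic import (EXPECTED_VERDICT, SCENARIO_DRIVERS, scenario_suite,
                        verdict_location)

__all__ = ["estimator_agreement", "weight_oracle_agreement",
           "thomas_closed_form_agreement", "test_calibration",
           "envelope_coverage", "parameter_recovery", "driver_recovery",
           "pipeline_contracts"]


# ---------------------------------------------------------------------------
# 1. estimator correctness vs brute-force oracles
# ---------------------------------------------------------------------------

def _epan(t, h):
    return np.where(np.abs(t) < h, 0.75 / h * (1 - (t / h) ** 2), 0.0)


def _pcf_direct(pattern, r, h):
    n, area = pattern.n, pattern.window.area
    out = np.zeros(len(r))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(pattern.x[i] - pattern.x[j],
                         pattern.y[i] - pattern.y[j])
            w = isotropic_weight((pattern.x[i], pattern.y[i]), d,
                                 pattern.window)
            out += w * (_epan(r - d, h) + _epan(r + d, h))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(r > 0, out / (2 * np.pi * r * n * (n - 1) / area),
                        np.nan)


def _k_direct(pattern, r):
    n, area = pattern.n, pattern.window.area
    out = np.zeros(len(r))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(pattern.x[i] - pattern.x[j],
                         pattern.y[i] - pattern.y[j])
            w = isotropic_weight((pattern.x[i], pattern.y[i]), d,
                                 pattern.window)
            out += w * (d <= r)
    return out * area / (n * (n - 1))


def estimator_agreement(seed=0, n_patterns=5):
    """Max |estimator - direct summation| for PCF and K on <=10-point
    hand-scale patterns (several near edges and corners)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    win = ObservationWindow.rectangle(0, 0, 10, 2)
    worst_g = worst_k = 0.0
    for _ in range(n_patterns):
        n = rng.integers(4, 11)
        pat = PointPattern(rng.uniform(0, 10, n), rng.uniform(0, 2, n), win,
                           allow_duplicates=True)
        h = 0.25
        g = pcf(pat, r_max=1.0, smoothing_bandwidth=h, n_grid=64)
        worst_g = max(worst_g, np.nanmax(np.abs(
            g.values[1:] - _pcf_direct(pat, g.r, h)[1:])))
        K = k_function(pat, r_max=1.0, n_grid=64)
        worst_k = max(worst_k, np.max(np.abs(K.values - _k_direct(pat, K.r))))
    return {"pcf_max_abs_diff": float(worst_g),
            "k_max_abs_diff": float(worst_k)}


def _ray_cast(px, py, verts):
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    px = px[:, None]
    py = py[:, None]
    cond = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    return (cond & (px < xi)).sum(axis=1) % 2 == 1


def weight_oracle_agreement(seed=0, n_cases=60, m=10_000_000):
    """Max |inside fraction - circumference-sampling oracle| over random
    (point, radius, window) cases; half on the rectangle fast path, half on
    an irregular polygon. m = 1e7 samples keep the oracle's own
    quantisation (a fraction of a sample per boundary crossing) below the
    1e-6 comparison scale."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rect = ObservationWindow.rectangle(0, 0, 10, 2)
    angles = np.sort(rng.uniform(0, 2 * np.pi, 8))
    radii = rng.uniform(2, 4, 8)
    octo = ObservationWindow(np.column_stack([5 + radii * np.cos(angles),
                                              5 + radii * np.sin(angles)]))
    worst = 0.0
    chunk = 1_000_000
    for case in range(n_cases):
        win = rect if case % 2 == 0 else octo
        verts = np.asarray(win.vertices)
        while True:
            cx = rng.uniform(verts[:, 0].min(), verts[:, 0].max())
            cy = rng.uniform(verts[:, 1].min(), verts[:, 1].max())
            if win.contains(cx, cy)[0]:
                break
        r = rng.uniform(0.05, 1.0) if win is rect else rng.uniform(0.1, 3.0)
        frac = 1.0 / isotropic_weight((cx, cy), r, win)
        inside = 0
        for s0 in range(0, m, chunk):
            theta = (np.arange(s0, min(s0 + chunk, m)) + 0.5) * (2 * np.pi / m)
            px = cx + r * np.cos(theta)
            py = cy + r * np.sin(theta)
            if win is rect:
                inside += int(((px >= 0) & (px <= 10) & (py >= 0)
                               & (py <= 2)).sum())
            else:
                inside += int(_ray_cast(px, py, verts).sum())
        worst = max(worst, abs(frac - inside / m))
    return {"weight_max_abs_err": float(worst)}


# ---------------------------------------------------------------------------
# 2. Thomas closed-form agreement
# ---------------------------------------------------------------------------

def thomas_closed_form_agreement(seed=0, n_rep=20):
    """Mean empirical PCF over Thomas simulations (kappa=5, sigma=0.1,
    mu=8, 30 x 30 m) vs the closed form, max relative deviation on
    r in [0.05, 0.5] m."""
    kappa, sigma, mu = 5.0, 0.1, 8.0
    win = ObservationWindow.rectangle(0, 0, 30, 30)
    ss = np.random.SeedSequence([seed, 2])
    curves = []
    r_ref = None
    for cs in ss.spawn(n_rep):
        sim = simulate_thomas(ThomasParams(kappa, sigma, mu), win, seed=cs)
        g = pcf(sim, r_max=0.5, n_grid=192)
        curves.append(g.values)
        r_ref = g.r
    mean_g = np.mean(curves, axis=0)
    sel = (r_ref >= 0.05) & (r_ref <= 0.5)
    theo = thomas_pcf_theoretical(r_ref[sel], kappa, sigma)
    rel = np.abs(mean_g[sel] - theo) / theo
    return {"thomas_pcf_max_rel_dev": float(np.max(rel)),
            "thomas_pcf_mean_rel_dev": float(np.mean(rel)), "n_rep": n_rep}


# ---------------------------------------------------------------------------
# 3. calibration of the Monte-Carlo tests
# ---------------------------------------------------------------------------

def test_calibration(seed=0, n_rep=1000, n_sim=99, dclf_rep=200):
    """Type-I error of the quadrat and segregation tests on CSR /
    random-labelling nulls, and DCLF p_d uniformity under the true model."""
    win = ObservationWindow.rectangle(0, 0, 10, 2)
    ss = np.random.SeedSequence([seed, 3])
    quad_seeds, seg_seeds, dclf_seeds = ss.spawn(3)

    rej = 0
    for cs in quad_seeds.spawn(n_rep):
        a, b = cs.spawn(2)
        pat = simulate_csr(win, n=50, seed=a)
        rej += quadrat_mc_test(pat, n_sim=n_sim, seed=b).p_value <= 0.05
    quad_rate = rej / n_rep

    rej = 0
    for cs in seg_seeds.spawn(n_rep):
        a, b, c = cs.spawn(3)
        pat = simulate_csr(win, n=60, seed=a)
        rng = np.random.default_rng(b)
        marks = np.array(["A"] * 30 + ["B"] * 30)
        rng.shuffle(marks)
        marked = PointPattern(pat.x, pat.y, win, marks=marks.tolist(),
                              allow_duplicates=True)
        overall, _ = nn_segregation_test(marked, n_sim=n_sim, seed=c)
        rej += overall.p_value <= 0.05
    seg_rate = rej / n_rep

    pvals = []
    for cs in dclf_seeds.spawn(dclf_rep):
        a, b = cs.spawn(2)
        pat = simulate_csr(win, n=50, seed=a)
        pvals.append(dclf_test(pat, model="csr", r_max=1.0, n_sim=n_sim,
                               seed=b, n_grid=128).p_value)
    ks = stats.kstest(pvals, "uniform").statistic
    return {"quadrat_type1_rate": float(quad_rate),
            "segregation_type1_rate": float(seg_rate),
            "dclf_ks_distance": float(ks), "n_rep": n_rep}


# ---------------------------------------------------------------------------
# 4. envelope coverage
# ---------------------------------------------------------------------------

def envelope_coverage(seed=0, n_meta=1000, n_sim=199):
    """Pointwise exceedance frequency of CSR data against its own envelope
    at a fixed mid-scale distance; nominal level 2*rank/(n_sim+1)."""
    win = ObservationWindow.rectangle(0, 0, 10, 2)
    ss = np.random.SeedSequence([seed, 4])
    exceed = 0
    rank = None
    for cs in ss.spawn(n_meta):
        a, b = cs.spawn(2)
        pat = simulate_csr(win, n=50, seed=a)
        env = envelope(pat, lambda p: pcf(p, r_max=1.0, n_grid=64),
                       model="csr", n_sim=n_sim, seed=b)
        rank = env.rank
        idx = len(env.statistic.r) // 2  # r ~ 0.5 m
        obs = env.statistic.values[idx]
        exceed += (obs < env.lo[idx]) or (obs > env.hi[idx])
    nominal = 2 * rank / (n_sim + 1)
    return {"envelope_exceedance_rate": float(exceed / n_meta),
            "envelope_nominal_level": float(nominal), "n_meta": n_meta}


# ---------------------------------------------------------------------------
# 5. parameter recovery
# ---------------------------------------------------------------------------

def parameter_recovery(seed=0, n_rep=50):
    """Minimum-contrast Thomas recovery (kappa=1.5, sigma=0.05, mu=2,
    10 x 2 m, n ~= 60) and soft-core kappa grid selection (sigma=0.2,
    kappa=0.5, n=60)."""
    win = ObservationWindow.rectangle(0, 0, 10, 2)
    ss = np.random.SeedSequence([seed, 5])
    th_seeds, sc_seeds = ss.spawn(2)

    kappa0, sigma0, mu0 = 1.5, 0.05, 2.0
    kerr, serr = [], []
    for cs in th_seeds.spawn(n_rep):
        pat = simulate_thomas(ThomasParams(kappa0, sigma0, mu0), win, seed=cs)
        if pat.n < 20:
            continue
        fit = fit_thomas(pat, r_max=1.0)
        kerr.append(abs(fit.params.kappa - kappa0) / kappa0)
        serr.append(abs(fit.params.sigma - sigma0) / sigma0)

    hits = tot = 0
    for cs in sc_seeds.spawn(n_rep):
        pat = simulate_gibbs(GibbsParams(family="softcore", sc_sigma=0.2,
                                         sc_kappa=0.5), win, n_target=60,
                             seed=cs, n_sweeps=20_000)
        fit = fit_gibbs(pat, "softcore")
        tot += 1
        hits += abs(fit.params.sc_kappa - 0.5) <= 0.2
    return {"thomas_kappa_median_rel_err": float(np.median(kerr)),
            "thomas_sigma_median_rel_err": float(np.median(serr)),
            "softcore_kappa_within_0p2_rate": float(hits / tot),
            "n_rep": n_rep}


# ---------------------------------------------------------------------------
# 6. driver recovery on the balanced synthetic suite
# ---------------------------------------------------------------------------

def driver_recovery(seed=0, n_per_driver=50, n_sim=99):
    """Full-ladder verdicts on the balanced scenario suite vs ground truth.

    Returns per-class accuracy, the modal verdict per class, and the CSR
    false-alarm rate (CSR scenarios receiving any non-CSR verdict).
    """
    base = int(np.random.SeedSequence([seed, 6]).generate_state(1)[0] % (2**31 - 10**6))
    scenarios, _ = scenario_suite(n_per_driver, base_seed=base)
    cfg = RunConfig(n_sim=n_sim, n_grid_pcf=256, n_grid_l=192,
                    gibbs_sweeps=8000)
    verdicts = {d: [] for d in SCENARIO_DRIVERS}
    for i, (spec, pattern, label) in enumerate(scenarios):
        rep = run_transect_analysis(pattern, cfg, seed=base + 500_000 + i,
                                    transect_id=f"s{i}")
        v = (rep.verdict(spec.taxa[0])
             if verdict_location(label) == "univariate" else rep.verdict())
        verdicts[label].append(v)
    out = {}
    for d in SCENARIO_DRIVERS:
        vs = verdicts[d]
        expected = EXPECTED_VERDICT[d]
        acc = float(np.mean([v == expected for v in vs]))
        vals, counts = np.unique(vs, return_counts=True)
        out[f"accuracy_{d}"] = acc
        out[f"modal_correct_{d}"] = float(vals[np.argmax(counts)] == expected)
    out["csr_false_alarm_rate"] = 1.0 - out["accuracy_csr"]
    out["n_per_driver"] = n_per_driver
    return out


# ---------------------------------------------------------------------------
# 7. pipeline contracts
# ---------------------------------------------------------------------------

def pipeline_contracts(seed=0):
    """n >= 30 filter, the r_max scale rule, and seed determinism."""
    import json

    from .summaries import ScaleRuleError
    win = ObservationWindow.rectangle(0, 0, 10, 2)
    cfg = RunConfig(n_sim=19, n_grid_pcf=64, n_grid_l=64)

    pat29 = simulate_csr(win, n=29, seed=np.random.SeedSequence([seed, 7]))
    rep = run_transect_analysis(pat29, cfg, seed=seed)
    excluded_ok = (rep.status.startswith("excluded")
                   and "minimum of 30 points" in rep.status)

    pat = simulate_csr(win, n=40, seed=np.random.SeedSequence([seed, 8]))
    try:
        pcf(pat, r_max=1.5)
        scale_ok = False
    except ScaleRuleError:
        scale_ok = True
    est = pcf(pat)  # default obeys the rule
    scale_ok = scale_ok and est.r[-1] <= 0.5 * win.shortest_edge + 1e-12

    r1 = run_transect_analysis(pat, cfg, seed=seed + 1)
    r2 = run_transect_analysis(pat, cfg, seed=seed + 1)
    det_ok = (json.dumps(r1.to_dict(), default=str)
              == json.dumps(r2.to_dict(), default=str))
    return {"min_points_filter_ok": float(excluded_ok),
            "scale_rule_ok": float(scale_ok),
            "seed_determinism_ok": float(det_ok)}
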