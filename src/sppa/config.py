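"""Run configuration for the transect analysis pipeline.

Defaults are the analysis settings of the workflow this package
implements: 999 Monte-Carlo simulations with 49th-extreme envelope limits,
a 1 m kernel bandwidth for intensity surfaces, a 3 x 2 quadrat layout for
slender transect windows (expected counts >= 5 at n = 30), the
half-shortest-edge r_max rule, a soft-core kappa grid over [0.1, 0.9], and
the n >= 30 inclusion filter. Every value is echoed into the report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np


@dataclass
class RunConfig:
    n_sim: int = 999                 # Monte-Carlo simulations per test/envelope
    envelope_rank: int | None = None  # None: 49 at n_sim=999, rescaled otherwise
    bandwidth_intensity: float = 1.0  # kernel s.d. for intensity surfaces, m
    quadrat_nx: int = 3
    quadrat_ny: int = 2
    r_max: float | None = None       # None: half the shortest window edge
    n_grid_pcf: int = 512
    n_grid_l: int = 256
    grid_resolution: float = 0.05    # intensity / quadrature grid, m
    sc_kappa_grid: tuple = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))
    gibbs_sweeps: int = 20_000       # proposals per Gibbs simulation in GOF
    alpha: float = 0.05              # significance level throughout
    tie_band: float = 0.05           # |delta p_d| below which fits are tied
    min_points: int = 30             # per-taxon inclusion filter
    envelope_null: str = "fitted_trend"  # or "csr": envelope null for
                                         # inhomogeneous patterns
    top_per_family: int = 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sc_kappa_grid"] = [float(v) for v in self.sc_kappa_grid]
        return d
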