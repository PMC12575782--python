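"""Place-field analysis of CA1 units: occupancy-normalized rate maps and
the spatial information / sparsity / coherence triplet.

Occupancy is per-step (rotations in place accumulate dwell), activity is
the post-nonlinearity CA1 activation magnitude, and all metrics are
evaluated over visited bins only:

    SI        = sum_i p_i (r_i / rbar) log2(r_i / rbar)        [bits]
    Sparsity  = (sum_i p_i r_i)^2 / (sum_i p_i r_i^2 + eps)    in [0, 1]
    Coherence = corr(r_i, rtilde_i)

with p_i the occupancy probability of bin i, r_i the mean activity there,
rbar = sum_i p_i r_i, and rtilde_i the 3x3 local neighbour mean.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

EPS = 1e-8


@dataclass
class RateMap:
    occupancy: np.ndarray            # grid of p_i (sums to 1 over visits)
    rate: np.ndarray                 # units x grid mean activity, NaN unvisited
    visits: np.ndarray               # raw step counts per bin

    @property
    def visited(self) -> np.ndarray:
        return self.visits > 0

    @property
    def n_units(self) -> int:
        return self.rate.shape[0]


def build_rate_map(positions, activations, grid_shape) -> RateMap:
    """Accumulate occupancy and activity maps over episodes, then divide.

    ``positions``: iterable of (row, col) per step, flattened over
    episodes; ``activations``: matching steps x units array.
    """
    acts = np.asarray(activations, dtype=float)
    pos = list(positions)
    if len(pos) == 0:
        raise ValueError("no visited steps")
    if acts.shape[0] != len(pos):
        raise ValueError("positions and activations length mismatch")
    visits = np.zeros(grid_shape)
    activity = np.zeros((acts.shape[1],) + tuple(grid_shape))
    for (r, c), a in zip(pos, acts):
        visits[r, c] += 1
        activity[:, r, c] += a
    occ = visits / visits.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = activity / visits
    rate[:, visits == 0] = np.nan
    return RateMap(occupancy=occ, rate=rate, visits=visits)


def _local_mean(rate: np.ndarray, visited: np.ndarray) -> np.ndarray:
    """3x3 neighbour mean restricted to in-map visited bins."""
    R, C = rate.shape
    out = np.full_like(rate, np.nan)
    for r in range(R):
        for c in range(C):
            if not visited[r, c]:
                continue
            vals = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < R and 0 <= cc < C and visited[rr, cc]:
                        vals.append(rate[rr, cc])
            out[r, c] = np.mean(vals)
    return out


def place_metrics(rate_map: RateMap, unit: int = 0,
                  coherence_method: str = "pearson") -> dict:
    """Spatial information (bits), sparsity and coherence for one unit.

    0 * log 0 is taken as 0; an all-zero map has SI 0 and sparsity 0; a
    constant map has undefined coherence (returned as NaN with a reason).
    """
    mask = rate_map.visited
    p = rate_map.occupancy[mask]
    r = rate_map.rate[unit][mask]
    rbar = float(np.sum(p * r))
    out = {"unit": unit, "mean_rate": rbar}
    if rbar <= 0:
        out.update(si=0.0, sparsity=0.0, coherence=np.nan,
                   coherence_reason="zero mean rate")
        return out
    ratio = r / rbar
    terms = np.where(ratio > 0, ratio * np.log2(np.maximum(ratio, EPS)), 0.0)
    out["si"] = float(np.sum(p * terms))
    out["sparsity"] = float(rbar ** 2 / (np.sum(p * r ** 2) + EPS))
    rt_full = _local_mean(np.where(rate_map.visits > 0, rate_map.rate[unit],
                                   np.nan), mask)
    rt = rt_full[mask]
    if np.std(r) == 0 or np.std(rt) == 0:
        out["coherence"] = np.nan
        out["coherence_reason"] = "constant map"
    elif coherence_method == "spearman":
        out["coherence"] = float(stats.spearmanr(r, rt).statistic)
    else:
        out["coherence"] = float(stats.pearsonr(r, rt).statistic)
    return out


def metric_table(rate_map: RateMap, coherence_method="pearson") -> pd.DataFrame:
    rows = [place_metrics(rate_map, u, coherence_method)
            for u in range(rate_map.n_units)]
    return pd.DataFrame(rows)
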