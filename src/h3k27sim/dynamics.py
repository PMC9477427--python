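"""Time-resolved analyses: cell-cycle dynamics and histone-pool tracking.

These mirror metabolic-labeling (SILAC-style) experiments: from a labeling
epoch t0 onward, histones incorporated by turnover or replication belong to
the "new" pool and pre-existing histones to the "old" pool.  The old-pool
fraction decays through turnover and replication dilution only — it is
independent of the mark kinetics — and its fitted exponential timescale t_e
(the effective histone decay time) is the natural unit for comparing mark
dynamics across systems with different turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import Ensemble, NEW, OLD
from .kinetics import N_STATES, STATE_NAMES

__all__ = [
    "PoolDynamics",
    "cell_cycle_average",
    "track_pools",
    "old_fraction_expected",
    "effective_decay_time",
    "normalize_time",
]


def cell_cycle_average(ensemble: Ensemble, n_bins: int = 27) -> pd.DataFrame:
    """Mark proportions vs time since replication for a synchronized population.

    Requires a synchronized protocol at periodic steady state.  All recorded
    samples (including the pre/post replication snapshots) are binned by their
    time since the last replication and averaged over trajectories and cycles.
    Returns a frame with ``t_since_rep``, ``t_over_T`` and one ``P_<mark>``
    column per state.
    """
    T = None
    num = np.zeros((n_bins, N_STATES))
    cnt = np.zeros(n_bins)
    for tr in ensemble.trajectories:
        if tr.replication_times.size:
            T = np.diff(tr.replication_times).mean() if tr.replication_times.size > 1 else None
        tau = tr.since_rep
        keep = tau >= 0
        tau = tau[keep]
        states = tr.states[keep]
        if T is None:
            T = tau.max()
        bins = np.clip((tau / T * n_bins).astype(int), 0, n_bins - 1)
        for b, row in zip(bins, states):
            for x in range(N_STATES):
                num[b, x] += np.mean(row == x)
            cnt[b] += 1
    with np.errstate(invalid="ignore"):
        frac = num / cnt[:, None]
    centers = (np.arange(n_bins) + 0.5) / n_bins * T
    out = pd.DataFrame({"t_since_rep": centers, "t_over_T": centers / T})
    for x, name in enumerate(STATE_NAMES):
        out[f"P_{name}"] = frac[:, x]
    return out


@dataclass
class PoolDynamics:
    """Per-pool mark proportions over time after the labeling epoch."""

    table: pd.DataFrame  # columns: time_h, pool, P_u..P_me3, pool_fraction

    def pool(self, name: str) -> pd.DataFrame:
        return self.table[self.table["pool"] == name].reset_index(drop=True)

    @property
    def old_fraction(self) -> pd.DataFrame:
        """Fraction of all histones still in the old pool, per time."""
        old = self.pool("old")
        return old[["time_h", "pool_fraction"]]


def track_pools(ensemble: Ensemble, window_sites: np.ndarray | None = None) -> PoolDynamics:
    """Mark proportions in the old and new histone pools at each grid time.

    The labeling epoch is the protocol's ``label_time`` (t=0 by default).
    Within each pool the five mark proportions sum to 1; ``pool_fraction`` is
    the pool's share of all (selected) sites.  New-pool rows before any
    histone has been replaced have NaN proportions and pool_fraction 0.
    """
    states = ensemble._grid_states()
    pools = ensemble._grid_pools()
    if window_sites is not None:
        states = states[:, :, window_sites]
        pools = pools[:, :, window_sites]
    times = ensemble.grid_times
    rows = []
    total = states.shape[0] * states.shape[2]
    for pool_code, pool_name in ((OLD, "old"), (NEW, "new")):
        in_pool = pools == pool_code  # (traj, time, site)
        size = in_pool.sum(axis=(0, 2))
        with np.errstate(invalid="ignore"):
            props = {
                name: np.where(
                    size > 0,
                    ((states == x) & in_pool).sum(axis=(0, 2)) / np.maximum(size, 1),
                    np.nan,
                )
                for x, name in enumerate(STATE_NAMES)
            }
        for k, t in enumerate(times):
            rows.append(
                {"time_h": float(t), "pool": pool_name}
                | {f"P_{name}": float(props[name][k]) for name in STATE_NAMES}
                | {"pool_fraction": float(size[k] / total)}
            )
    return PoolDynamics(pd.DataFrame(rows))


def old_fraction_expected(t: np.ndarray | float, gamma_turn: float = 0.03, T: float = 13.5) -> np.ndarray:
    """Closed-form old-pool fraction for an unsynchronized population.

    A histone survives turnover with probability exp(-gamma_turn * t) and each
    replication with probability 1/2.  With the labeling epoch uniform in the
    cycle, the number of replications within t is floor(t/T) or one more, so

        f(t) = exp(-gamma_turn t) * 2^(-k) * (1 - frac/2),
        k = floor(t/T), frac = t/T - k.
    """
    t = np.asarray(t, dtype=float)
    tau = t / T
    k = np.floor(tau)
    frac = tau - k
    out = np.exp(-gamma_turn * t) * 2.0**-k * (1.0 - frac / 2.0)
    return out if out.ndim else float(out)


def effective_decay_time(
    times: np.ndarray,
    old_fraction: np.ndarray,
    log_scale: bool = False,
) -> tuple[float, float]:
    """Fit exp(-t/t_e) to the old-histone fraction; returns (t_e, residual norm).

    The default is unweighted least squares on the linear scale, which weights
    the early, well-populated part of the curve; ``log_scale`` fits the log of
    the curve instead (asymptotic-slope emphasis).
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(old_fraction, dtype=float)
    if times.shape != f.shape or times.size < 3:
        raise ValueError("times and old_fraction must be equal-length arrays (>= 3 points)")
    if f[0] <= f[-1]:
        raise ValueError("old_fraction must decrease from its initial value")
    if log_scale:
        keep = f > 0
        slope = np.polyfit(times[keep], np.log(f[keep]), 1)[0]
        if slope >= 0:
            raise ValueError("non-decaying input")
        t_e = -1.0 / slope
        resid = float(np.linalg.norm(np.exp(-times / t_e) - f))
        return float(t_e), resid
    (t_e,), _ = curve_fit(lambda t, te: np.exp(-t / te), times, f, p0=(times[-1] / 3 + 1e-9,))
    resid = float(np.linalg.norm(np.exp(-times / t_e) - f))
    return float(t_e), resid


def normalize_time(times: np.ndarray, mode: str, t_e_or_T: float) -> np.ndarray:
    """Express times in units of the cell cycle (``mode='cycle'``) or the
    effective histone decay time (``mode='decay'``)."""
    if mode not in ("cycle", "decay"):
        raise ValueError("mode must be 'cycle' or 'decay'")
    if t_e_or_T <= 0:
        raise ValueError("normalizer must be positive")
    return np.asarray(times, dtype=float) / t_e_or_T
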