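"""Exact stochastic simulation of the lattice model.

A trajectory follows one cell: the five-state configuration of the 200-site
histone lattice evolves by the Gillespie algorithm under the reaction
propensities of :mod:`.kinetics`, interrupted by scheduled replication events
(every ``T`` hours at a per-trajectory phase) that independently reset each
site to the unmodified state with probability 1/2, and optionally by protocol
events that swap the kinetic parameters and/or the enzyme profile at fixed
times (enzyme-inhibitor washout, gene-class switch).

Time convention: burn-in runs over ``t < 0`` (``burn_in_cycles`` cell cycles
starting from a fully unmodified lattice); recording starts at ``t = 0``.
Unsynchronized populations draw the replication phase uniformly per
trajectory; synchronized populations share phase 0, which puts replications
at t = 0, T, 2T, ...

Histone pools: every site starts in the "old" pool; after the labeling epoch
(``label_time``, default t=0) a site lost to turnover or replication is
relabeled "new", emulating a metabolic-labeling (SILAC-style) experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .kinetics import ModelParams, N_STATES, STATE_NAMES, U, contact_kernel
from .profiles import HMEProfile, Lattice

__all__ = [
    "SimulationProtocol",
    "Trajectory",
    "Ensemble",
    "simulate",
    "replicate",
    "run_ensemble",
    "washout_protocol",
    "switch_protocol",
    "ensemble_seeds",
]

OLD, NEW = 0, 1


@dataclass(frozen=True)
class SimulationProtocol:
    """What to simulate: duration, burn-in, synchrony, events, recording.

    ``events`` is an ordered sequence of ``(time, change)`` pairs with
    ``change`` a dict holding a new ``"params"`` (ModelParams) and/or
    ``"profile"`` (HMEProfile); changes apply from that time on.
    ``replication_phase=None`` draws a uniform phase per trajectory
    (unsynchronized population); a float fixes the phase for all trajectories.
    ``initial_params``/``initial_profile`` optionally override the arguments
    of :func:`simulate` so that protocol constructors can bundle a complete
    "before/after" experiment.
    """

    duration: float
    burn_in_cycles: int = 25
    replication_phase: float | None = None
    events: tuple = ()
    record_interval: float = 0.5
    label_time: float | None = 0.0
    initial_params: ModelParams | None = None
    initial_profile: HMEProfile | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.record_interval <= 0:
            raise ValueError("record_interval must be positive")
        if self.burn_in_cycles < 0:
            raise ValueError("burn_in_cycles must be >= 0")
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and times[0] < 0:
            raise ValueError("event times must be >= 0 (after burn-in)")

    @property
    def grid_times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.record_interval + 1e-9))
        return np.arange(n + 1) * self.record_interval


@dataclass
class Trajectory:
    """Recorded samples of one simulated cell (post burn-in)."""

    lattice: Lattice
    times: np.ndarray          # (k,) sample times in hours
    states: np.ndarray         # (k, n_sites) int8 state codes
    pools: np.ndarray          # (k, n_sites) int8, 0 = old, 1 = new
    on_grid: np.ndarray        # (k,) True for regular-grid samples
    since_rep: np.ndarray      # (k,) time since the last applied replication
    replication_times: np.ndarray  # replication times within [0, duration]
    phase: float
    seed: int

    def mark_fraction(self, state_code: int) -> np.ndarray:
        """Per-sample fraction of sites in ``state_code`` (lattice average)."""
        return (self.states == state_code).mean(axis=1)


def replicate(
    config: np.ndarray,
    pools: np.ndarray,
    rng: np.random.Generator,
    label_new: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replication dilution: each site is reset to u with probability 1/2.

    Returns ``(config, pools, lost_mask)``; arrays are modified in place.
    Lost sites are relabeled "new" when ``label_new`` (pool membership is a
    site-level label, so an already-unmodified site still changes pool).
    """
    lost = rng.random(config.shape[0]) < 0.5
    config[lost] = U
    if label_new:
        pools[lost] = NEW
    return config, pools, lost


def _params_tuple(p: ModelParams) -> tuple:
    k = p.k_me
    e = p.eps_me
    return (k[0], k[1], k[2], e[0], e[1], e[2],
            p.gamma_me, p.k_ac, p.gamma_ac, p.gamma_turn)


def simulate(
    profile: HMEProfile | None,
    params: ModelParams | None,
    protocol: SimulationProtocol,
    seed: int,
    initial_config: np.ndarray | None = None,
) -> Trajectory:
    """Run one statistically exact trajectory under ``protocol``.

    ``profile``/``params`` may be None when the protocol carries
    ``initial_profile``/``initial_params``.  The default initial configuration
    is fully unmodified.
    """
    profile = protocol.initial_profile or profile
    params = protocol.initial_params or params
    if profile is None or params is None:
        raise ValueError("profile and params required (directly or via the protocol)")
    lattice = profile.lattice
    n = lattice.n_sites
    T = params.T

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    phase = (
        protocol.replication_phase
        if protocol.replication_phase is not None
        else float(rng.uniform(0.0, T))
    )
    seg_seeds = iter(rng.integers(0, 2**31 - 1, size=2**16))

    t_start = -protocol.burn_in_cycles * T
    t_end = protocol.duration
    first_k = int(np.ceil((t_start - phase) / T - 1e-12))
    rep_times = phase + T * np.arange(first_k, int(np.floor((t_end - phase) / T + 1e-12)) + 1)
    # a replication at the very start would act on the initial condition
    # before any dynamics; the schedule is open at t_start
    rep_times = rep_times[(rep_times > t_start + 1e-12) & (rep_times <= t_end)]

    boundaries: list[tuple[float, str, dict | None]] = [(t, "rep", None) for t in rep_times]
    boundaries += [(t, "event", change) for t, change in protocol.events if t <= t_end]
    if protocol.label_time is not None and t_start < protocol.label_time < t_end:
        boundaries.append((protocol.label_time, "label", None))
    boundaries.sort(key=lambda b: b[0])
    boundaries.append((t_end, "end", None))

    grid = protocol.grid_times

    state = (
        np.full(n, U, dtype=np.int8)
        if initial_config is None
        else np.asarray(initial_config, dtype=np.int8).copy()
    )
    if state.shape != (n,):
        raise ValueError("initial_config must match the lattice")
    pools = np.full(n, OLD, dtype=np.int8)

    cur_params, cur_profile = params, profile
    scalars = _params_tuple(cur_params)
    P = contact_kernel(lattice, cur_params.lambda_exp)
    psi = (cur_profile.psi_suz12, cur_profile.psi_p300, cur_profile.psi_utx)

    max_rec = grid.size + 2 * len(boundaries) + 4
    rec_states = np.empty((max_rec, n), dtype=np.int8)
    rec_pools = np.empty((max_rec, n), dtype=np.int8)
    rec_times: list[float] = []
    rec_on_grid: list[bool] = []
    rec_since: list[float] = []
    rec_n = 0

    label_time = protocol.label_time if protocol.label_time is not None else np.inf
    last_rep = rep_times[0] - T if rep_times.size else t_start - T
    # replications strictly before recording set the initial "since replication"
    past = rep_times[rep_times <= 0]
    if past.size:
        last_rep = past[-1] if past[-1] < 0 else last_rep

    def snapshot(t: float, on_grid: bool) -> None:
        nonlocal rec_n
        rec_states[rec_n] = state
        rec_pools[rec_n] = pools
        rec_times.append(t)
        rec_on_grid.append(on_grid)
        rec_since.append(t - last_rep)
        rec_n += 1

    t_cur = t_start
    if grid.size and grid[0] <= t_start + 1e-12:
        snapshot(float(grid[0]), True)  # recording starts with the run itself
    for t_b, kind, change in boundaries:
        if t_b > t_cur:
            seg_grid = grid[(grid > t_cur + 1e-12) & (grid <= t_b + 1e-12)]
            k_rec = _kernel.run_segment(
                state, pools, t_cur, t_b,
                psi[0], psi[1], psi[2], P,
                *scalars,
                seg_grid, rec_states, rec_pools, rec_n,
                t_cur >= label_time, int(next(seg_seeds)),
            )
            for tg in seg_grid[:k_rec]:
                rec_times.append(float(tg))
                rec_on_grid.append(True)
                rec_since.append(float(tg) - last_rep)
            rec_n += k_rec
            t_cur = t_b
        if kind == "rep":
            if t_b >= 0.0:
                snapshot(t_b, False)  # pre-replication
            replicate(state, pools, rng, label_new=t_b >= label_time)
            last_rep = t_b
            if t_b >= 0.0:
                snapshot(t_b, False)  # post-replication
        elif kind == "event":
            snapshot(t_b, False)
            if "params" in change:
                cur_params = change["params"]
                scalars = _params_tuple(cur_params)
                P = contact_kernel(lattice, cur_params.lambda_exp)
            if "profile" in change:
                cur_profile = change["profile"]
                psi = (cur_profile.psi_suz12, cur_profile.psi_p300, cur_profile.psi_utx)
            snapshot(t_b, False)

    order = np.argsort(np.asarray(rec_times), kind="stable")
    return Trajectory(
        lattice=lattice,
        times=np.asarray(rec_times)[order],
        states=rec_states[:rec_n][order],
        pools=rec_pools[:rec_n][order],
        on_grid=np.asarray(rec_on_grid, dtype=bool)[order],
        since_rep=np.asarray(rec_since)[order],
        replication_times=rep_times[rep_times >= 0.0],
        phase=phase,
        seed=seed,
    )


def ensemble_seeds(master_seed: int, n_traj: int) -> np.ndarray:
    """Deterministic per-trajectory sub-seeds derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n_traj, dtype=np.uint32) & 0x7FFFFFFF


@dataclass
class Ensemble:
    """Independent trajectories sharing a protocol (distinct sub-seeds/phases)."""

    trajectories: list[Trajectory]
    protocol: SimulationProtocol

    @property
    def lattice(self) -> Lattice:
        return self.trajectories[0].lattice

    @property
    def grid_times(self) -> np.ndarray:
        return self.protocol.grid_times

    def _grid_states(self) -> np.ndarray:
        """(n_traj, n_grid, n_sites) int8 states at the shared grid times."""
        return np.stack([tr.states[tr.on_grid] for tr in self.trajectories])

    def _grid_pools(self) -> np.ndarray:
        return np.stack([tr.pools[tr.on_grid] for tr in self.trajectories])

    def occupancy(self) -> np.ndarray:
        """P_x(t, i): (5, n_grid, n_sites) fraction of trajectories in state x."""
        gs = self._grid_states()
        return np.stack([(gs == x).mean(axis=0) for x in range(N_STATES)])

    def mean_mark_fraction(self, state_code: int, window_sites: np.ndarray | None = None) -> np.ndarray:
        """Ensemble-mean fraction of (selected) sites in a state, per grid time."""
        gs = self._grid_states()
        if window_sites is not None:
            gs = gs[:, :, window_sites]
        return (gs == state_code).mean(axis=(0, 2))

    def steady_profiles(self, t_min: float = 0.0) -> dict[str, np.ndarray]:
        """Per-site state probabilities averaged over trajectories and t >= t_min."""
        keep = self.grid_times >= t_min - 1e-9
        gs = self._grid_states()[:, keep, :]
        return {name: (gs == x).mean(axis=(0, 1)) for x, name in enumerate(STATE_NAMES)}

    def pooled_samples(self, t_min: float = 0.0) -> np.ndarray:
        """(n_samples, n_sites) states pooled over trajectories and t >= t_min."""
        keep = self.grid_times >= t_min - 1e-9
        gs = self._grid_states()[:, keep, :]
        return gs.reshape(-1, gs.shape[-1])


def run_ensemble(
    profile: HMEProfile | None,
    params: ModelParams | None,
    protocol: SimulationProtocol,
    n_traj: int,
    seed: int,
) -> Ensemble:
    """Simulate ``n_traj`` independent trajectories; reproducible from ``seed``."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    seeds = ensemble_seeds(seed, n_traj)
    trajs = [simulate(profile, params, protocol, int(s)) for s in seeds]
    return Ensemble(trajs, protocol)


def washout_protocol(
    t0: float = 0.0,
    params_before: ModelParams | None = None,
    params_after: ModelParams | None = None,
    duration: float = 100.0,
    **kwargs,
) -> SimulationProtocol:
    """Inhibitor-washout experiment: evolve without allosteric spreading, then
    restore it.

    The population reaches steady state under ``params_before`` (default: the
    wild-type parameters with R = 0, an EZH2-inhibited situation) during the
    burn-in; at ``t0`` the parameters switch to ``params_after`` (default:
    wild type).  The population is unsynchronized unless a
    ``replication_phase`` is passed.
    """
    params_after = params_after or ModelParams()
    params_before = params_before or params_after.with_(R=0.0)
    if t0 < 0:
        raise ValueError("t0 must be >= 0 (after the burn-in)")
    if t0 >= duration:
        raise ValueError("t0 must fall before the end of the run")
    events = () if params_before == params_after else ((t0, {"params": params_after}),)
    return SimulationProtocol(
        duration=duration,
        events=events,
        initial_params=params_before,
        label_time=t0,
        **kwargs,
    )


def switch_protocol(
    t0: float,
    profile_before: HMEProfile,
    profile_after: HMEProfile,
    duration: float = 100.0,
    **kwargs,
) -> SimulationProtocol:
    """Gene-class switch: swap the enzyme profile at ``t0`` (e.g. active -> PcG)."""
    if t0 < 0:
        raise ValueError("t0 must be >= 0 (after the burn-in)")
    if t0 >= duration:
        raise ValueError("t0 must fall before the end of the run")
    same = (
        np.array_equal(profile_before.psi_suz12, profile_after.psi_suz12)
        and np.array_equal(profile_before.psi_p300, profile_after.psi_p300)
        and np.array_equal(profile_before.psi_utx, profile_after.psi_utx)
    )
    events = () if same else ((t0, {"profile": profile_after}),)
    return SimulationProtocol(
        duration=duration,
        events=events,
        initial_profile=profile_before,
        label_time=t0,
        **kwargs,
    )
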