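"""Steady-state summaries of simulated H3K27 landscapes.

Covers the per-site mark probabilities of an unsynchronized population, the
methylation *valency* (the qualitative ordering of me1/me2/me3 around the
TSS) used to classify a locus as PcG-target-like or active-like, the genomic
distance at which me2 overtakes me3, state-state Pearson correlation maps,
and the recruitment phase diagram obtained by rescaling the PRC2 and
p300/UTX peak amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Ensemble, SimulationProtocol, run_ensemble
from .kinetics import ModelParams, N_STATES, STATE_NAMES
from .profiles import HMEProfile, Lattice, RecruitmentScales, make_profile

__all__ = [
    "ValencyCall",
    "mean_profiles",
    "classify_valency",
    "crossover_distance",
    "correlation_map",
    "correlation_frame",
    "steady_state_ensemble",
    "phase_diagram",
]


def steady_state_ensemble(
    profile: HMEProfile,
    params: ModelParams,
    n_traj: int = 32,
    burn_in_cycles: int = 25,
    sample_cycles: float = 4.0,
    record_interval: float = 0.5,
    seed: int = 0,
    synchronized: bool = False,
) -> Ensemble:
    """Ensemble at periodic steady state, sampled over ``sample_cycles`` cycles."""
    protocol = SimulationProtocol(
        duration=sample_cycles * params.T,
        burn_in_cycles=burn_in_cycles,
        replication_phase=0.0 if synchronized else None,
        record_interval=record_interval,
    )
    return run_ensemble(profile, params, protocol, n_traj, seed)


def mean_profiles(ensemble: Ensemble, t_min: float = 0.0) -> dict[str, np.ndarray]:
    """Per-site probability of each mark, averaged over time and trajectories."""
    return ensemble.steady_profiles(t_min=t_min)


@dataclass(frozen=True)
class ValencyCall:
    """Methylation-valency classification of a TSS window."""

    label: str                  # "pcg_like", "active_like" or "intermediate"
    window_kbp: float
    mean_proportions: dict


def classify_valency(
    p_me1: float, p_me2: float, p_me3: float, window_kbp: float = 2.5
) -> ValencyCall:
    """Label the valency of window-mean methylation proportions.

    PcG-target-like requires me2 > me1 and me3 > 1.5*me2 (trimethylation
    clearly dominant); active-like requires me1 > me2 and me2 > 1.5*me3;
    everything else — including bivalent-like me2 ~ me3 > me1 — is
    intermediate.  The rules partition the input space.
    """
    props = {"me1": float(p_me1), "me2": float(p_me2), "me3": float(p_me3)}
    if p_me2 > p_me1 and p_me3 > 1.5 * p_me2:
        label = "pcg_like"
    elif p_me1 > p_me2 and p_me2 > 1.5 * p_me3:
        label = "active_like"
    else:
        label = "intermediate"
    return ValencyCall(label, window_kbp, props)


def window_valency(
    profiles: dict[str, np.ndarray], lattice: Lattice, window_kbp: float = 2.5
) -> ValencyCall:
    """Valency call from per-site mark probabilities in a ±window around the TSS."""
    idx = lattice.window_indices(window_kbp)
    return classify_valency(
        profiles["me1"][idx].mean(),
        profiles["me2"][idx].mean(),
        profiles["me3"][idx].mean(),
        window_kbp,
    )


def crossover_distance(
    p_me3: np.ndarray,
    p_me2: np.ndarray,
    lattice: Lattice | None = None,
    persistence: int = 3,
) -> float:
    """Distance from the TSS (kbp) at which me2 overtakes me3.

    Scans outward from the TSS independently on each side and reports the
    smallest distance at which ``p_me2 > p_me3`` holds for at least
    ``persistence`` consecutive sites (guarding against single-bin noise
    flips); the two sides are averaged.  Returns NaN when no side crosses.
    """
    lattice = lattice or Lattice(n_sites=len(p_me3))
    p_me3 = np.asarray(p_me3, dtype=float)
    p_me2 = np.asarray(p_me2, dtype=float)
    tss = lattice.tss_index
    above = p_me2 > p_me3

    def scan(indices: np.ndarray) -> float:
        run = 0
        for k, i in enumerate(indices):
            run = run + 1 if above[i] else 0
            if run >= persistence:
                start = indices[k - persistence + 1]
                return abs(lattice.position_of(int(start)))
        return np.nan

    right = scan(np.arange(tss, lattice.n_sites))
    left = scan(np.arange(tss, -1, -1))
    sides = np.array([left, right])
    if np.all(np.isnan(sides)):
        return np.nan
    return float(np.nanmean(sides))


def correlation_map(
    ensemble: Ensemble,
    sites: np.ndarray | None = None,
    t_min: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations between state indicators at pairs of (site, state).

    Samples are pooled over trajectories and recorded times.  Returns
    ``(C, occ)`` where ``C[i*5+x, j*5+y]`` is the correlation between the
    indicator of state x at site i and state y at site j (sites indexed into
    ``sites``) and ``occ`` the matching mean indicator values.  Entries whose
    occupancy is degenerate (0 or 1, zero variance) are NaN — the correlation
    is undefined there, not zero.
    """
    lattice = ensemble.lattice
    if sites is None:
        sites = np.arange(lattice.n_sites)
    samples = ensemble.pooled_samples(t_min=t_min)[:, sites]  # (m, k)
    m, k = samples.shape
    ind = np.empty((m, k * N_STATES), dtype=np.float64)
    for x in range(N_STATES):
        ind[:, x::N_STATES] = samples == x
    occ = ind.mean(axis=0)
    sd = ind.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (ind - occ) / sd
    Z[:, sd == 0] = np.nan
    C = (Z.T @ Z) / m
    return C, occ


def correlation_frame(
    ensemble: Ensemble, sites: np.ndarray | None = None, t_min: float = 0.0
) -> pd.DataFrame:
    """Long-format (i, x, j, y, C) table of the correlation map."""
    lattice = ensemble.lattice
    if sites is None:
        sites = np.arange(lattice.n_sites)
    C, _ = correlation_map(ensemble, sites=sites, t_min=t_min)
    k = len(sites)
    ii, jj = np.meshgrid(np.arange(k * N_STATES), np.arange(k * N_STATES), indexing="ij")
    return pd.DataFrame(
        {
            "site_i": sites[ii.ravel() // N_STATES],
            "state_x": np.array(STATE_NAMES)[ii.ravel() % N_STATES],
            "site_j": sites[jj.ravel() // N_STATES],
            "state_y": np.array(STATE_NAMES)[jj.ravel() % N_STATES],
            "C": C.ravel(),
        }
    )


def phase_diagram(
    params: ModelParams | None = None,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
    lattice: Lattice | None = None,
    window_kbp: float = 2.5,
    n_traj: int = 32,
    burn_in_cycles: int = 25,
    sample_cycles: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Valency phase diagram over the (alpha, beta) recruitment grid.

    ``alpha`` rescales the PRC2 peak (PcG-target reference amplitude) and
    ``beta`` jointly rescales the p300 and UTX peaks (active-gene reference
    amplitudes).  One steady-state ensemble is simulated per grid cell; each
    cell carries its window-mean mark proportions and valency label.
    The default grid is alpha 0..1.4 step 0.2, beta 0..2 step 0.2.
    """
    params = params or ModelParams()
    lattice = lattice or Lattice()
    alphas = np.round(np.arange(0.0, 1.4 + 1e-9, 0.2), 10) if alphas is None else np.asarray(alphas)
    betas = np.round(np.arange(0.0, 2.0 + 1e-9, 0.2), 10) if betas is None else np.asarray(betas)
    idx = lattice.window_indices(window_kbp)
    rows = []
    for a in alphas:
        for b in betas:
            profile = make_profile(RecruitmentScales(float(a), float(b)), lattice)
            ens = steady_state_ensemble(
                profile, params, n_traj=n_traj, burn_in_cycles=burn_in_cycles,
                sample_cycles=sample_cycles, seed=seed,
            )
            profs = ens.steady_profiles()
            means = {name: float(profs[name][idx].mean()) for name in STATE_NAMES}
            call = classify_valency(means["me1"], means["me2"], means["me3"], window_kbp)
            rows.append(
                {"alpha": float(a), "beta": float(b)}
                | {f"P_{name}": means[name] for name in STATE_NAMES}
                | {"label": call.label}
            )
    return pd.DataFrame(rows)
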