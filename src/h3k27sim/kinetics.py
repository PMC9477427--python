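"""State space, kinetic parameters and reaction propensities.

Each H3 tail is in one of five states: unmodified (u), acetylated (ac) or
mono/di/tri-methylated (me1/me2/me3).  Methylation proceeds one group at a
time along u <-> me1 <-> me2 <-> me3; acetylation is reachable only from u.
Per-site transition propensities (in events per hour):

* methylation ``me_{x-1} -> me_x``:
  ``k_mex * psi_suz12(i) + eps_mex * sum_j P(i,j) * psi_suz12(j) * [j is me3]``
  — a local nucleation term proportional to PRC2 occupancy plus a long-range
  spreading term from allosterically activated PRC2 bound at trimethylated
  sites that contact ``i`` in 3D with probability ``P(i,j) = |i-j|^-lambda``;
* demethylation ``me_x -> me_{x-1}``: ``gamma_me * psi_utx(i)``,
  independent of the methylation level;
* acetylation ``u -> ac``: ``k_ac * psi_p300(i)``;
* deacetylation ``ac -> u``: ``gamma_ac`` (uniform);
* turnover ``X -> u`` for any modified state: ``gamma_turn`` (uniform).

On top of these reactions, DNA replication every ``T`` hours independently
resets each site to u with probability 1/2 (handled by the simulation engine,
not as a propensity).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.linalg import expm

from .profiles import HMEProfile, Lattice

__all__ = [
    "U", "AC", "ME1", "ME2", "ME3",
    "STATE_NAMES", "N_STATES",
    "ModelParams", "AllosteryGeometry",
    "contact_kernel", "validate_kernel",
    "propensities", "closed_form_ac",
    "single_site_generator", "single_site_periodic_steady_state",
    "allostery_fold_change",
]

# Integer state codes (also the row/column order of all 5-state vectors).
U, AC, ME1, ME2, ME3 = 0, 1, 2, 3, 4
STATE_NAMES = ("u", "ac", "me1", "me2", "me3")
N_STATES = 5


@dataclass(frozen=True)
class ModelParams:
    """Kinetic rates and structural constants (defaults: wild-type mESC fit).

    Nucleation rates derive from ``k_me3`` via the dimensionless ratios
    ``r13 = k_me1/k_me3`` and ``r23 = k_me2/k_me3``; spreading rates are
    ``eps_mex = R * k_mex`` with the same spreading-to-nucleation ratio R for
    every methylation step (the allosteric boost acts on the whole enzyme).
    """

    k_me3: float = 0.81      # h^-1, nucleation me2 -> me3
    r13: float = 3.0         # k_me1 / k_me3
    r23: float = 3.0         # k_me2 / k_me3
    R: float = 0.85          # spreading-to-nucleation ratio eps_mex / k_mex
    gamma_me: float = 1.5    # h^-1, UTX-mediated demethylation coefficient
    k_ac: float = 1.03       # h^-1, p300-mediated acetylation coefficient
    gamma_ac: float = 0.6    # h^-1, uniform deacetylation
    gamma_turn: float = 0.03  # h^-1, histone turnover
    T: float = 13.5          # h, cell-cycle length
    lambda_exp: float = 1.0  # contact-kernel decay exponent

    def __post_init__(self) -> None:
        for name in ("k_me3", "r13", "r23", "R", "gamma_me", "k_ac",
                     "gamma_ac", "gamma_turn", "lambda_exp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def k_me(self) -> np.ndarray:
        """Nucleation rates (k_me1, k_me2, k_me3)."""
        return np.array([self.r13 * self.k_me3, self.r23 * self.k_me3, self.k_me3])

    @property
    def eps_me(self) -> np.ndarray:
        """Spreading rates (eps_me1, eps_me2, eps_me3) = R * k_me."""
        return self.R * self.k_me

    def with_(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass(frozen=True)
class AllosteryGeometry:
    """Spatial constants relating R to the allosteric fold-change.

    ``a`` is the PRC2 capture distance and ``d0`` the prefactor of the mean
    3D distance ``d_ij = d0 * |i-j|^(lambda/3)``, both in nm.
    """

    a: float = 10.0
    d0: float = 22.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.d0 <= 0:
            raise ValueError("a and d0 must be positive")


def allostery_fold_change(R: float, geometry: AllosteryGeometry | None = None) -> float:
    """Fold-change F of PRC2 activity implied by R = F * (6/pi) * (a/d0)^3."""
    geometry = geometry or AllosteryGeometry()
    return R / ((6.0 / np.pi) * (geometry.a / geometry.d0) ** 3)


def contact_kernel(lattice: Lattice | int, lambda_exp: float = 1.0) -> np.ndarray:
    """Power-law contact probability matrix P(i,j) = |i-j|^(-lambda), P(i,i)=0.

    The on-site enzyme action is already the nucleation term, so the self
    contact is excluded; no normalization is applied (any constant would be
    absorbed in the spreading rates).
    """
    if lambda_exp <= 0:
        raise ValueError("lambda_exp must be positive")
    n = lattice if isinstance(lattice, int) else lattice.n_sites
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        P = d**-lambda_exp
    np.fill_diagonal(P, 0.0)
    return P


def validate_kernel(P: np.ndarray, n_sites: int) -> np.ndarray:
    """Check a user-supplied contact matrix (symmetric, zero diagonal, non-negative)."""
    P = np.asarray(P, dtype=float)
    if P.shape != (n_sites, n_sites):
        raise ValueError(f"kernel must be {n_sites}x{n_sites}")
    if not np.allclose(P, P.T):
        raise ValueError("kernel must be symmetric")
    if np.any(np.diag(P) != 0):
        raise ValueError("kernel must have zero diagonal")
    if np.any(P < 0):
        raise ValueError("kernel entries must be non-negative")
    return P


def spreading_field(config: np.ndarray, psi_suz12: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """S(i) = sum_j P(i,j) * psi_suz12(j) * [config(j) = me3]."""
    return kernel @ (psi_suz12 * (np.asarray(config) == ME3))


def propensities(
    config: np.ndarray,
    profile: HMEProfile,
    params: ModelParams,
    kernel: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-site reaction rates (h^-1) for a lattice configuration.

    Returns arrays keyed by reaction name; an entry is 0 wherever the site's
    current state does not allow that reaction.
    """
    config = np.asarray(config)
    n = profile.lattice.n_sites
    if config.shape != (n,):
        raise ValueError(f"config must have shape ({n},), got {config.shape}")
    if kernel is None:
        kernel = contact_kernel(profile.lattice, params.lambda_exp)
    S = spreading_field(config, profile.psi_suz12, kernel)
    k_me, eps_me = params.k_me, params.eps_me

    methylate = np.zeros(n)
    for x, from_state in enumerate((U, ME1, ME2)):  # targets me1, me2, me3
        mask = config == from_state
        methylate[mask] = (k_me[x] * profile.psi_suz12 + eps_me[x] * S)[mask]

    demethylate = np.where(
        np.isin(config, (ME1, ME2, ME3)), params.gamma_me * profile.psi_utx, 0.0
    )
    acetylate = np.where(config == U, params.k_ac * profile.psi_p300, 0.0)
    deacetylate = np.where(config == AC, params.gamma_ac, 0.0)
    turnover = np.where(config != U, params.gamma_turn, 0.0)
    return {
        "methylate": methylate,
        "demethylate": demethylate,
        "acetylate": acetylate,
        "deacetylate": deacetylate,
        "turnover": turnover,
    }


def closed_form_ac(psi_p300_i: np.ndarray | float, params: ModelParams | None = None) -> np.ndarray | float:
    """Steady-state acetylation probability of the two-state (u <-> ac) model.

    With methylation absent the dynamics at each site reduce to acetylation at
    rate ``k_ac * psi`` against removal by deacetylation, turnover, and
    replication dilution treated as an effective first-order rate ``ln2 / T``:

        P_ac = k_ac*psi / (k_ac*psi + gamma_ac + gamma_turn + ln2/T)
    """
    params = params or ModelParams()
    psi = np.asarray(psi_p300_i, dtype=float)
    num = params.k_ac * psi
    out = num / (num + params.gamma_ac + params.gamma_turn + np.log(2.0) / params.T)
    return out if out.ndim else float(out)


def single_site_generator(
    psi_suz12_i: float, psi_p300_i: float, psi_utx_i: float, params: ModelParams
) -> np.ndarray:
    """Generator matrix Q (column convention: dp/dt = Q p) of one decoupled site.

    Valid when the spreading term vanishes (R = 0, or no me3 anywhere);
    replication is not part of Q and is applied as a periodic map.
    """
    k_me = params.k_me
    up = k_me * psi_suz12_i  # u->me1, me1->me2, me2->me3 nucleation only
    down = params.gamma_me * psi_utx_i
    kac = params.k_ac * psi_p300_i
    Q = np.zeros((N_STATES, N_STATES))

    def add(frm, to, rate):
        Q[to, frm] += rate
        Q[frm, frm] -= rate

    add(U, AC, kac)
    add(AC, U, params.gamma_ac)
    add(U, ME1, up[0])
    add(ME1, ME2, up[1])
    add(ME2, ME3, up[2])
    add(ME1, U, down)
    add(ME2, ME1, down)
    add(ME3, ME2, down)
    for s in (AC, ME1, ME2, ME3):
        add(s, U, params.gamma_turn)
    return Q


def single_site_periodic_steady_state(
    psi_suz12_i: float,
    psi_p300_i: float,
    psi_utx_i: float,
    params: ModelParams | None = None,
    n_phase: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact periodic steady state of one decoupled site over the cell cycle.

    Solves the 5-state master equation with the replication map
    ``p -> p/2 + e_u/2`` applied every ``T`` hours and returns
    ``(p_phase, p_avg)``: the state distribution at ``n_phase`` times within
    the cycle (rows, starting right after replication) and its phase average —
    the marginal seen in an unsynchronized population.  Exact for R = 0, where
    the spreading term vanishes and sites decouple.
    """
    params = params or ModelParams()
    Q = single_site_generator(psi_suz12_i, psi_p300_i, psi_utx_i, params)
    dt = params.T / n_phase
    E_dt = expm(Q * dt)
    E_T = np.linalg.matrix_power(E_dt, n_phase)
    # periodic fixed point right after replication: p0 = (E_T p0)/2 + e_u/2
    e_u = np.zeros(N_STATES)
    e_u[U] = 1.0
    p0 = np.linalg.solve(np.eye(N_STATES) - 0.5 * E_T, 0.5 * e_u)
    p_phase = np.empty((n_phase, N_STATES))
    p = p0
    for k in range(n_phase):
        p_phase[k] = p
        p = E_dt @ p
    return p_phase, p_phase.mean(axis=0)
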