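"""Rate constants and excitation-transfer kinetics.

Transfer rates follow the point-dipole Foerster form

    k = (3/2) * k_D * kappa^2 * Delta^-6

with Delta the center-to-center distance normalized by the kappa^2=2/3
Foerster radius.  The network of one acceptor plus n donors with
unidirectional D->A transfer and reversible D->D hopping is a linear
kinetic system; the probability that an excitation starting on a given
donor is eventually captured by the acceptor (its transfer efficiency
Phi) solves a first-passage linear system and is the production path.
Explicit ODE integration of the populations is retained as an
independent cross-check and for time-course output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro
from scipy.integrate import solve_ivp

from .sampling import Configuration

__all__ = [
    "PhotophysicalParams",
    "RateSystem",
    "forster_radius",
    "build_rate_system",
    "absorption_probability",
    "absorption_probabilities",
    "integrate_populations",
]


@dataclass(frozen=True)
class PhotophysicalParams:
    """Intrinsic rates and (optionally) physical-distance normalization.

    ``k_d`` defaults to (1000 ps)^-1.  Transfer efficiencies are
    invariant under a common rescaling of all rates, so the absolute
    lifetime never matters for Phi; only ratios of rates do.
    """

    k_d: float = 1.0 / 1000.0          # ps^-1
    k_a: float = 0.0                   # ps^-1
    r0_da: float | None = None         # nm; physical mode only
    r0_dd: float | None = None         # nm
    q_d: float | None = None
    refractive_index: float | None = None
    overlap_j_da: float | None = None  # M^-1 cm^-1 nm^4
    overlap_j_dd: float | None = None

    def __post_init__(self):
        if self.k_d <= 0:
            raise ValueError("k_d must be > 0")
        if self.k_a < 0:
            raise ValueError("k_a must be >= 0")
        for r in (self.r0_da, self.r0_dd):
            if r is not None and r <= 0:
                raise ValueError("Foerster radii must be > 0")


@dataclass(frozen=True)
class RateSystem:
    """All rate constants of one configuration's kinetic network."""

    k_da: np.ndarray = field(repr=False)  # (n,)
    k_dd: np.ndarray = field(repr=False)  # (n, n), symmetric, 0 diagonal
    k_d: float = 1.0 / 1000.0
    k_a: float = 0.0

    @property
    def n_donors(self) -> int:
        return self.k_da.shape[0]

    def to_dict(self) -> dict:
        return {
            "k_d": self.k_d,
            "k_a": self.k_a,
            "k_da": self.k_da.tolist(),
            "k_dd": self.k_dd.tolist(),
        }


def forster_radius(q_d: float, refractive_index: float, overlap_j: float) -> float:
    """Foerster radius (nm) at the isotropic dynamic average kappa^2 = 2/3.

    R0^6 = [9 ln(10) / (128 pi^5 N_A)] * kappa2 * Q_D * n^-4 * J, with the
    overlap integral J in M^-1 cm^-1 nm^4 and kappa2 = 2/3 folded in.
    Unit bookkeeping: 1 M^-1 = 1e24 nm^3/mol and 1 cm^-1 = 1e-7 nm^-1,
    so J converts to nm^6/mol by a factor 1e17.
    """
    if q_d <= 0 or refractive_index <= 0 or overlap_j <= 0:
        raise ValueError("q_d, refractive_index and overlap_j must be > 0")
    kappa2 = 2.0 / 3.0
    prefactor = 9.0 * np.log(10.0) / (128.0 * np.pi**5 * Avogadro)
    r6 = prefactor * kappa2 * q_d * refractive_index**-4 * overlap_j * 1e17
    return r6 ** (1.0 / 6.0)


#: Transfer rates are capped at this multiple of k_d.  Branching
#: probabilities saturate once transfer dwarfs decay (difference < 1/cap),
#: but uncapped near-zero distance draws make the first-passage matrix
#: numerically singular (two rows equal to machine precision).
RATE_CAP_FACTOR = 1e9


def transfer_rate(k_d, kappa2, delta):
    """Pointwise Foerster rate (3/2) k_D kappa^2 Delta^-6; vectorized.

    Rates are clipped at ``RATE_CAP_FACTOR * k_d``; the cap perturbs any
    absorption probability by less than 1/RATE_CAP_FACTOR.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta == 0):
        raise ValueError("zero normalized distance gives a singular rate")
    rate = 1.5 * k_d * np.asarray(kappa2, dtype=float) * delta**-6
    return np.minimum(rate, RATE_CAP_FACTOR * k_d)


def build_rate_system(
    config: Configuration, params: PhotophysicalParams
) -> RateSystem:
    """Rate constants for one configuration.

    In normalized mode (radii unset) the configuration's distances are
    taken as Delta directly.  In physical mode distances are in nm and
    are divided by ``r0_da`` / ``r0_dd`` first.
    """
    delta_da = config.delta_da
    delta_dd = config.delta_dd
    if params.r0_da is not None:
        delta_da = delta_da / params.r0_da
    if params.r0_dd is not None:
        delta_dd = delta_dd / params.r0_dd

    n = delta_da.shape[-1]
    k_da = transfer_rate(params.k_d, config.kappa2_da, delta_da)
    off = ~np.eye(n, dtype=bool)
    k_dd = np.zeros_like(delta_dd)
    if n > 1:
        k_dd[..., off] = transfer_rate(
            params.k_d, config.kappa2_dd[..., off], delta_dd[..., off]
        )
    return RateSystem(k_da=k_da, k_dd=k_dd, k_d=params.k_d, k_a=params.k_a)


def absorption_probabilities(system: RateSystem) -> np.ndarray:
    """Phi for every initial donor at once (one multi-RHS linear solve).

    Solves h_i * (k_D + k_iA + sum_j k_ij) - sum_j k_ij h_j = k_iA,
    where h_i is the probability that an excitation on donor i ends on
    the acceptor.  Supports a leading batch axis on the rate tables.
    """
    if system.k_a != 0.0:
        raise ValueError(
            "first-passage Phi requires k_a = 0; use integrate_populations"
        )
    if system.k_d <= 0:
        raise ValueError("k_d must be > 0 for a well-posed first passage")
    k_da = np.asarray(system.k_da, dtype=float)
    k_dd = np.asarray(system.k_dd, dtype=float)
    n = k_da.shape[-1]
    out_rate = system.k_d + k_da + k_dd.sum(axis=-1)
    A = -k_dd.copy()
    idx = np.arange(n)
    A[..., idx, idx] = out_rate
    return np.linalg.solve(A, k_da[..., None])[..., 0]


def absorption_probability(system: RateSystem, initial_donor: int = 0) -> float:
    """Probability that an excitation on ``initial_donor`` reaches the acceptor."""
    phi = absorption_probabilities(system)
    return float(phi[initial_donor])


def integrate_populations(
    system: RateSystem,
    initial_donor: int = 0,
    horizon: float | None = None,
    n_times: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Integrate the population ODEs from a single excited donor.

    Returns ``(times, donor_populations, acceptor_population)`` with
    ``donor_populations`` of shape (n_times, n_donors).  With k_a = 0
    the acceptor population at a long horizon converges to Phi; this is
    the brute-force oracle for :func:`absorption_probability`.
    """
    k_da = np.asarray(system.k_da, dtype=float)
    k_dd = np.asarray(system.k_dd, dtype=float)
    if not (np.all(np.isfinite(k_da)) and np.all(np.isfinite(k_dd))):
        raise ValueError("non-finite rate constants")
    n = k_da.shape[0]
    if horizon is None:
        horizon = 20.0 / system.k_d

    loss = system.k_d + k_da + k_dd.sum(axis=1)

    def rhs(_t, y):
        d, a = y[:n], y[n]
        dd = -loss * d + k_dd.T @ d
        da = -system.k_a * a + k_da @ d
        return np.concatenate([dd, [da]])

    y0 = np.zeros(n + 1)
    y0[initial_donor] = 1.0
    times = np.linspace(0.0, horizon, n_times)
    sol = solve_ivp(
        rhs, (0.0, horizon), y0, t_eval=times, rtol=rtol, atol=atol,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y[:n].T, sol.y[n]
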