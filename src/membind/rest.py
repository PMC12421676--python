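"""Replica exchange with solute tempering (REST): formalism and toy model.

Implements the geometric temperature ladder, the REST-scaled replica
enthalpy H_r = E_ss + sqrt(T_r/T_0) E_sv + (T_r/T_0) E_vv (solute-solute,
solute-solvent, solvent-solvent decomposition), the Metropolis exchange
criterion Delta = beta_r (H_r(X_{r+1}) - H_r(X_r)) + beta_{r+1} (H_{r+1}(X_r)
- H_{r+1}(X_{r+1})) with alpha = min(1, exp(-Delta)), and a one-dimensional
harmonic toy replica-exchange simulator used to validate the statistical
properties of the scheme (solvent-energy cancellation, uniform walker
occupancy, acceptance against exact-sampling oracles).

"Enthalpy" here is configurational energy only; the PV term cancels for the
equal-volume toy states and is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: gas constant, kcal/(mol K)
R_GAS = 1.98720425864e-3


# ---------------------------------------------------------------------------
# ladder and scaled enthalpies
# ---------------------------------------------------------------------------

@dataclass
class ReplicaLadder:
    temperatures: np.ndarray       # K, strictly increasing, geometric

    @property
    def n_replicas(self):
        return len(self.temperatures)

    @property
    def T0(self):
        return float(self.temperatures[0])


def geometric_ladder(T_min: float = 330.0, T_max: float = 430.0,
                     n_replicas: int = 10) -> ReplicaLadder:
    """T_r = T_min (T_max/T_min)^(r/(N_R - 1)), r = 0..N_R-1."""
    if n_replicas < 2 or not (T_max > T_min > 0):
        raise ValueError("need n_replicas >= 2 and T_max > T_min > 0")
    r = np.arange(n_replicas)
    T = T_min * (T_max / T_min) ** (r / (n_replicas - 1))
    return ReplicaLadder(temperatures=T)


@dataclass
class EnergyDecomposition:
    E_ss: float     # solute-solute, kcal/mol
    E_sv: float     # solute-solvent
    E_vv: float     # solvent-solvent


def scaled_enthalpy(decomp: EnergyDecomposition, T_r: float,
                    T_0: float) -> float:
    """REST-scaled replica enthalpy; unmodified when T_r = T_0."""
    s = T_r / T_0
    return decomp.E_ss + np.sqrt(s) * decomp.E_sv + s * decomp.E_vv


def exchange_delta(decomp_r: EnergyDecomposition,
                   decomp_r1: EnergyDecomposition,
                   T_r: float, T_r1: float, T_0: float) -> float:
    """Metropolis exponent for a neighbor exchange.

    ``decomp_r`` is the decomposition of configuration X_r (currently at
    temperature T_r), ``decomp_r1`` of X_{r+1}.  The solvent-solvent terms
    cancel analytically: beta_r (T_r/T_0) = 1/(R T_0) for every replica.
    """
    b_r = 1.0 / (R_GAS * T_r)
    b_r1 = 1.0 / (R_GAS * T_r1)
    H_r = lambda d: scaled_enthalpy(d, T_r, T_0)      # noqa: E731
    H_r1 = lambda d: scaled_enthalpy(d, T_r1, T_0)    # noqa: E731
    return (b_r * (H_r(decomp_r1) - H_r(decomp_r))
            + b_r1 * (H_r1(decomp_r) - H_r1(decomp_r1)))


def acceptance_probability(delta: float) -> float:
    """alpha = min(1, exp(-Delta))."""
    return float(min(1.0, np.exp(-delta)))


# ---------------------------------------------------------------------------
# toy REST simulator
# ---------------------------------------------------------------------------

@dataclass
class ToyModel:
    """1-D harmonic solute x and solvent y with harmonic coupling.

    E_ss = k_ss x^2 / 2, E_vv = k_vv y^2 / 2, E_sv = k_sv (x - y)^2 / 2
    (all kcal/mol with x, y dimensionless).
    """

    k_ss: float = 2.0
    k_sv: float = 1.0
    k_vv: float = 4.0

    def decompose(self, x: float, y: float) -> EnergyDecomposition:
        return EnergyDecomposition(E_ss=0.5 * self.k_ss * x * x,
                                   E_sv=0.5 * self.k_sv * (x - y) ** 2,
                                   E_vv=0.5 * self.k_vv * y * y)

    def hessian_scaled(self, T_r: float, T_0: float) -> np.ndarray:
        """Quadratic form A with H_r(x, y) = (x,y) A (x,y)^T / 2."""
        s = T_r / T_0
        sq = np.sqrt(s)
        return np.array([
            [self.k_ss + sq * self.k_sv, -sq * self.k_sv],
            [-sq * self.k_sv, sq * self.k_sv + s * self.k_vv]])

    def sample_equilibrium(self, T_r: float, T_0: float, size: int,
                           rng: np.random.Generator) -> np.ndarray:
        """Exact samples from exp(-beta_r H_r): a bivariate Gaussian."""
        A = self.hessian_scaled(T_r, T_0) / (R_GAS * T_r)
        cov = np.linalg.inv(A)
        return rng.multivariate_normal(np.zeros(2), cov, size=size)


@dataclass
class RestReport:
    ladder: ReplicaLadder
    acceptance: np.ndarray         # mean acceptance per neighbor pair
    attempts: np.ndarray
    occupancy: np.ndarray          # (n_walkers, n_replicas) visit fractions
    occupancy_blocks: np.ndarray   # (n_blocks, n_walkers, n_replicas)
    round_trips: np.ndarray

    def to_dict(self):
        return {
            "temperatures": self.ladder.temperatures.tolist(),
            "acceptance_per_pair": self.acceptance.tolist(),
            "attempts_per_pair": self.attempts.tolist(),
            "occupancy": self.occupancy.tolist(),
            "round_trips": self.round_trips.tolist(),
        }


def toy_rest_simulator(ladder: ReplicaLadder, steps: int = 20000,
                       exchange_period: int = 2, seed: int = 0,
                       model: ToyModel | None = None,
                       mc_step: float = 0.7, n_blocks: int = 10
                       ) -> RestReport:
    """Metropolis sampling of the toy energies with neighbor exchanges.

    Each replica carries a configuration (x, y) sampled at its scaled
    enthalpy; every ``exchange_period`` sweeps a neighbor pair (alternating
    even/odd) attempts an exchange via :func:`exchange_delta`.  Tracks
    per-pair acceptance, per-walker temperature occupancy (with block
    averages for error estimation), and round trips (walker travels
    bottom -> top -> bottom).
    """
    model = model or ToyModel()
    rng = np.random.default_rng(seed)
    T = ladder.temperatures
    T0 = ladder.T0
    n = ladder.n_replicas
    beta = 1.0 / (R_GAS * T)
    # state per replica slot
    xy = np.zeros((n, 2))
    walker = np.arange(n)          # which walker occupies each replica
    acc = np.zeros(n - 1)
    att = np.zeros(n - 1)
    visits = np.zeros((n_blocks, n, n))
    last_end = np.full(n, -1)      # -1 unset, 0 bottom, 1 top
    round_trips = np.zeros(n)
    block = 0
    H = np.array([model.hessian_scaled(t, T0) for t in T])
    for step in range(steps):
        # single-particle Metropolis moves per replica
        prop = xy + rng.normal(0, mc_step, size=(n, 2))
        e_old = 0.5 * np.einsum("ri,rij,rj->r", xy, H, xy)
        e_new = 0.5 * np.einsum("ri,rij,rj->r", prop, H, prop)
        accept = rng.random(n) < np.exp(-np.clip(beta * (e_new - e_old),
                                                 -700, 700))
        xy[accept] = prop[accept]
        # exchanges
        if (step + 1) % exchange_period == 0:
            start = ((step + 1) // exchange_period) % 2
            for r in range(start, n - 1, 2):
                d_r = model.decompose(*xy[r])
                d_r1 = model.decompose(*xy[r + 1])
                delta = exchange_delta(d_r, d_r1, T[r], T[r + 1], T0)
                att[r] += 1
                if rng.random() < min(1.0, np.exp(-min(delta, 700.0))):
                    acc[r] += 1
                    xy[[r, r + 1]] = xy[[r + 1, r]]
                    walker[[r, r + 1]] = walker[[r + 1, r]]
        # bookkeeping
        block = min(n_blocks - 1, step * n_blocks // steps)
        visits[block, walker, np.arange(n)] += 1
        w_bottom = walker[0]
        w_top = walker[-1]
        if last_end[w_bottom] == 1:
            round_trips[w_bottom] += 1
        last_end[w_bottom] = 0
        last_end[w_top] = 1
    occ = visits.sum(axis=0)
    occ = occ / occ.sum(axis=1, keepdims=True)
    blocks = visits / visits.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore"):
        acc_rate = np.where(att > 0, acc / np.maximum(att, 1), np.nan)
    return RestReport(ladder=ladder, acceptance=acc_rate, attempts=att,
                      occupancy=occ, occupancy_blocks=blocks,
                      round_trips=round_trips)


def exact_exchange_acceptance(model: ToyModel, T_r: float, T_r1: float,
                              T_0: float, n_samples: int = 200000,
                              seed: int = 1) -> float:
    """Oracle: E[min(1, exp(-Delta))] by exact independent equilibrium
    sampling of both replicas (no Markov chain)."""
    rng = np.random.default_rng(seed)
    a = model.sample_equilibrium(T_r, T_0, n_samples, rng)
    b = model.sample_equilibrium(T_r1, T_0, n_samples, rng)

    def comps(xy):
        x, y = xy[:, 0], xy[:, 1]
        return (0.5 * model.k_ss * x * x, 0.5 * model.k_sv * (x - y) ** 2,
                0.5 * model.k_vv * y * y)

    def H(xy, T):
        s = T / T_0
        ss, sv, vv = comps(xy)
        return ss + np.sqrt(s) * sv + s * vv

    b_r = 1.0 / (R_GAS * T_r)
    b_r1 = 1.0 / (R_GAS * T_r1)
    deltas = (b_r * (H(b, T_r) - H(a, T_r))
              + b_r1 * (H(a, T_r1) - H(b, T_r1)))
    return float(np.minimum(1.0, np.exp(-np.minimum(deltas, 700.0))).mean())
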