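"""Deterministic simulation of generated networks.

The ODE system is ``dx/dt = S v(x)`` with stoichiometric matrix ``S`` and
mass-action fluxes ``v_r(x) = k_r prod_i x_i`` over each reaction's reactant
indices.  Amounts are copy numbers per cell (well-mixed implicit
compartments), so bimolecular rate constants are per copy number per time.
Integration uses a stiff-capable BDF method with an analytic sparse Jacobian.

Steady states are found the way the source analyses do: by integrating until
the relative rate of change falls below tolerance over a trailing window, and
classified by the dominant eigenvalue of the Jacobian restricted to the
stoichiometric subspace (conserved moieties contribute structural zero
eigenvalues and are projected out before classification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .model import Observable
from .network import ReactionNetwork
from .sitegraph import find_embeddings

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "Trajectory",
    "SteadyState",
    "SteadyStateError",
    "IntegrationError",
    "simulate_odes",
    "observable_weights",
    "evaluate_observables",
    "find_steady_state",
]


class IntegrationError(RuntimeError):
    def __init__(self, message, time=None):
        super().__init__(message)
        self.time = time


class SteadyStateError(RuntimeError):
    """No steady state within the time budget (possible oscillation)."""


@dataclass
class SimulationSpec:
    network: ReactionNetwork
    times: np.ndarray
    initial: Optional[np.ndarray] = None          # default: seed amounts
    observables: list = field(default_factory=list)
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "BDF"                           # or "Radau" for higher accuracy
    parameters: Optional[dict] = None             # overrides network parameters

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.method not in ("BDF", "Radau", "LSODA"):
            raise ValueError(f"unsupported method {self.method!r}")


@dataclass
class Trajectory:
    times: np.ndarray
    species: np.ndarray            # (n_times, n_species), clipped at 0
    observable_names: list
    observables: np.ndarray        # (n_times, n_observables)

    def observable(self, name: str) -> np.ndarray:
        return self.observables[:, self.observable_names.index(name)]

    def to_frame(self, include_species: bool = False) -> pd.DataFrame:
        data = {"time": self.times}
        for j, name in enumerate(self.observable_names):
            data[name] = self.observables[:, j]
        if include_species:
            for i in range(self.species.shape[1]):
                data[f"s{i}"] = self.species[:, i]
        return pd.DataFrame(data)


@dataclass
class SteadyState:
    state: np.ndarray
    residual: float                # max |dx/dt| / (|x| + floor), 1/time units
    stability: str                 # "stable" | "unstable" | "indeterminate"
    time: float                    # integration time used


class _OdeSystem:
    """Vectorized mass-action right-hand side with analytic sparse Jacobian."""

    def __init__(self, network: ReactionNetwork, parameters=None):
        self.n = len(network.species)
        self.k = network.rate_vector(parameters)
        nr = len(network.reactions)
        rows, cols, vals = [], [], []
        self.react_lists = [list(r.reactants) for r in network.reactions]
        for j, rxn in enumerate(network.reactions):
            for i in rxn.reactants:
                rows.append(i); cols.append(j); vals.append(-1.0)
            for i in rxn.products:
                rows.append(i); cols.append(j); vals.append(1.0)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, nr)
        )
        self.r0 = np.array([j for j, rl in enumerate(self.react_lists) if not rl],
                           dtype=int)
        self.r1 = np.array([(j, rl[0]) for j, rl in enumerate(self.react_lists)
                            if len(rl) == 1], dtype=int).reshape(-1, 2)
        self.r2 = np.array([(j, rl[0], rl[1]) for j, rl in
                            enumerate(self.react_lists) if len(rl) == 2],
                           dtype=int).reshape(-1, 3)
        self.rn = [(j, rl) for j, rl in enumerate(self.react_lists)
                   if len(rl) > 2]
        self.nr = nr
        # fixed Jacobian-of-flux sparsity pattern
        jr, jc = [], []
        for j, rl in enumerate(self.react_lists):
            for i in rl:
                jr.append(j); jc.append(i)
        self._dv_rows = np.array(jr, dtype=int)
        self._dv_cols = np.array(jc, dtype=int)

    def flux(self, x: np.ndarray) -> np.ndarray:
        v = self.k.copy()
        if len(self.r1):
            v[self.r1[:, 0]] *= x[self.r1[:, 1]]
        if len(self.r2):
            v[self.r2[:, 0]] *= x[self.r2[:, 1]] * x[self.r2[:, 2]]
        for j, rl in self.rn:
            v[j] *= np.prod(x[rl])
        return v

    def rhs(self, t, x):
        return self.S.dot(self.flux(x))

    def jac(self, t, x):
        data = []
        for j, rl in enumerate(self.react_lists):
            kj = self.k[j]
            for pos, i in enumerate(rl):
                others = rl[:pos] + rl[pos + 1:]
                d = kj
                for o in others:
                    d *= x[o]
                data.append(d)
        dv = sparse.coo_matrix(
            (data, (self._dv_rows, self._dv_cols)), shape=(self.nr, self.n)
        ).tocsr()
        return self.S.dot(dv)

    def jac_dense(self, x) -> np.ndarray:
        return np.asarray(self.jac(0.0, x).todense())


def observable_weights(
    network: ReactionNetwork, observables: Sequence[Observable]
) -> np.ndarray:
    """Weight matrix W (n_observables x n_species); values = W @ amounts.

    Molecules observables weight each species by its total embedding count
    over the observable's patterns; Species observables weight by one if any
    pattern matches.
    """
    if network.molecule_types:
        for obs in observables:
            for pat in obs.patterns:
                for mol in pat.molecules:
                    if mol.name not in network.molecule_types:
                        raise ValueError(
                            f"observable {obs.name!r} references unknown "
                            f"molecule type {mol.name!r}"
                        )
    W = np.zeros((len(observables), len(network.species)))
    for oi, obs in enumerate(observables):
        for si, sp in enumerate(network.species):
            count = 0
            for pat in obs.patterns:
                count += len(find_embeddings(pat, sp))
            if obs.kind == "Molecules":
                W[oi, si] = count
            else:
                W[oi, si] = 1.0 if count else 0.0
    return W


def evaluate_observables(
    network: ReactionNetwork,
    state: np.ndarray,
    observables: Sequence[Observable],
) -> dict:
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != len(network.species):
        raise ValueError("state length does not match network species count")
    W = observable_weights(network, observables)
    values = state @ W.T
    return {obs.name: values[..., i] for i, obs in enumerate(observables)}


def simulate_odes(spec: SimulationSpec) -> Trajectory:
    """Integrate the network ODEs over the spec's time grid."""
    net = spec.network
    sys = _OdeSystem(net, spec.parameters)
    x0 = spec.initial if spec.initial is not None else net.initial_state()
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(
        sys.rhs,
        (spec.times[0], spec.times[-1]),
        x0,
        method=spec.method,
        t_eval=spec.times,
        jac=sys.jac if spec.method != "LSODA" else None,
        rtol=spec.rtol,
        atol=spec.atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else spec.times[0]}: "
            f"{sol.message}",
            time=sol.t[-1] if len(sol.t) else spec.times[0],
        )
    species = sol.y.T
    worst = species.min() if species.size else 0.0
    if worst < -1e3 * spec.atol:
        logger.warning("negative amounts beyond tolerance (min %.3g); clipping",
                       worst)
    species = np.clip(species, 0.0, None)
    W = observable_weights(net, spec.observables)
    return Trajectory(
        times=sol.t,
        species=species,
        observable_names=[o.name for o in spec.observables],
        observables=species @ W.T,
    )


def find_steady_state(
    network: ReactionNetwork,
    initial: Optional[np.ndarray] = None,
    parameters: Optional[dict] = None,
    ss_tol: float = 1e-8,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_start: float = 1.0,
    max_time: float = 1e9,
    floor: float = 1e-6,
    stability_eps: float = 1e-8,
) -> SteadyState:
    """Integrate until the state stops changing; classify stability.

    The convergence criterion is ``max_i |dx_i/dt| / (|x_i| + floor) < ss_tol``
    held across a trailing window (the last 10% of the elapsed horizon).
    Raises :class:`SteadyStateError` when the criterion is not met within
    ``max_time`` -- which may indicate sustained oscillation.
    """
    sys = _OdeSystem(network, parameters)
    x = np.asarray(
        initial if initial is not None else network.initial_state(), dtype=float
    )

    def crit(state) -> float:
        return float(np.max(np.abs(sys.rhs(0.0, state)) / (np.abs(state) + floor)))

    if crit(x) < ss_tol:
        return SteadyState(x, crit(x), _classify(sys, x, network, stability_eps), 0.0)

    t = 0.0
    horizon = t_start
    while t < max_time:
        t_end = min(t + horizon, max_time)
        window = np.linspace(t + 0.9 * (t_end - t), t_end, 4)
        sol = solve_ivp(
            sys.rhs, (t, t_end), x, method="BDF", jac=sys.jac,
            t_eval=window, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}", time=t)
        x = sol.y[:, -1]
        if all(crit(sol.y[:, i]) < ss_tol for i in range(sol.y.shape[1])):
            x = np.clip(x, 0.0, None)
            return SteadyState(
                x, crit(x), _classify(sys, x, network, stability_eps), t_end
            )
        t = t_end
        horizon *= 10.0
    raise SteadyStateError(
        f"no steady state within t={max_time:g} (residual {crit(x):.3g}); "
        f"the trajectory may be oscillating"
    )


def _classify(sys: _OdeSystem, x, network: ReactionNetwork,
              eps: float) -> str:
    """Sign of the dominant Jacobian eigenvalue on the stoichiometric subspace."""
    n = len(x)
    if n == 0 or sys.nr == 0:
        return "stable"
    S = np.asarray(sys.S.todense())
    u, sv, _ = np.linalg.svd(S, full_matrices=False)
    if len(sv) == 0 or sv[0] == 0:
        return "stable"
    rank = int(np.sum(sv > 1e-12 * sv[0] * max(S.shape)))
    Q = u[:, :rank]
    if rank == 0:
        return "stable"
    J = sys.jac_dense(x)
    Jr = Q.T @ J @ Q
    lead = float(np.max(np.linalg.eigvals(Jr).real))
    scale = max(1.0, float(np.max(np.abs(Jr))))
    if lead > eps * scale:
        return "unstable"
    if lead < -eps * scale:
        return "stable"
    return "indeterminate"
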