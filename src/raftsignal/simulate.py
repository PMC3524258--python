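"""Deterministic ODE integration of a generated reaction network.

Abundances are molecules per cell.  Extracellular (bath) species never
deplete: their molar concentrations are supplied per simulation phase and
folded into pseudo-first-order rate constants at compile time, so the state
vector covers dynamic (membrane + cytosolic) species only.

The system is stiff (naked-phosphotyrosine turnover at 20/s next to ligand
equilibration over minutes), so integration uses the BDF method with an
analytic sparse Jacobian assembled from the reaction list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .network import RAFT, NONRAFT, SINGLE, ReactionNetwork

__all__ = [
    "TimeCourse",
    "SteadyState",
    "IntegrationError",
    "initial_state",
    "integrate",
    "steady_state",
    "observables_of",
    "conserved_totals",
    "OBSERVABLES",
]

OBSERVABLES = ("beta", "gamma", "syk", "lat", "fceri")


class IntegrationError(RuntimeError):
    pass


@dataclass
class TimeCourse:
    """Observable fractions on a time grid, plus the raw state trajectory."""

    t: np.ndarray
    observables: dict[str, np.ndarray]
    states: np.ndarray  # (len(t), n_dynamic)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, observable, value + metadata)."""
        rows = []
        for name, series in self.observables.items():
            df = pd.DataFrame({"time": self.t, "observable": name, "value": series})
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        for k, v in self.metadata.items():
            if np.isscalar(v):
                out[k] = v
        return out


@dataclass
class SteadyState:
    """Final state of a run-to-steady-state integration."""

    x: np.ndarray
    time: float
    converged: bool
    deriv_norm: float


class _CompiledODE:
    """Reaction arrays and Jacobian structure for one bath condition."""

    def __init__(self, network: ReactionNetwork, bath: dict[str, float]):
        self.network = network
        dyn = [sp.index for sp in network.species if sp.dynamic]
        self.dyn = dyn
        self.n = len(dyn)
        self.to_state = {sp_idx: k for k, sp_idx in enumerate(dyn)}
        bath_conc = dict(bath or {})

        a_idx, b_idx, rates, kms, is_mm = [], [], [], [], []
        rows, cols, vals = [], [], []  # stoichiometry triplets
        m = 0
        for rxn in network.reactions:
            rate = rxn.rate
            if rxn.bath is not None:
                rate = rate * bath_conc.get(rxn.bath, 0.0)
                if rate == 0.0:
                    continue
            react = [self.to_state[i] for i in rxn.reactants
                     if network.species[i].dynamic]
            prods = [self.to_state[i] for i in rxn.products
                     if network.species[i].dynamic]
            if rxn.kind == "mm":
                e, s = react
                a_idx.append(e)
                b_idx.append(s)
                kms.append(rxn.km)
                is_mm.append(True)
            else:
                a_idx.append(react[0])
                b_idx.append(react[1] if len(react) > 1 else -1)
                kms.append(0.0)
                is_mm.append(False)
            rates.append(rate)
            net_stoich: dict[int, int] = {}
            for i in react:
                net_stoich[i] = net_stoich.get(i, 0) - 1
            for i in prods:
                net_stoich[i] = net_stoich.get(i, 0) + 1
            for i, v in net_stoich.items():
                if v != 0:
                    rows.append(i)
                    cols.append(m)
                    vals.append(float(v))
            m += 1

        self.m = m
        self.a = np.asarray(a_idx, dtype=np.intp)
        self.b = np.asarray(b_idx, dtype=np.intp)
        self.k = np.asarray(rates)
        self.km = np.asarray(kms)
        self.mm = np.asarray(is_mm, dtype=bool)
        self.uni = ~self.mm & (self.b < 0)
        self.bi = ~self.mm & (self.b >= 0)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, m)
        )
        # Jacobian structure: dflux/dx has at most two entries per reaction
        dr, dc = [], []
        for j in range(m):
            dr.append(j); dc.append(self.a[j])
            if self.b[j] >= 0:
                dr.append(j); dc.append(self.b[j])
        self._jrows = np.asarray(dr, dtype=np.intp)
        self._jcols = np.asarray(dc, dtype=np.intp)
        probe = sparse.csr_matrix(
            (np.ones(len(dr)), (dr, dc)), shape=(m, self.n)
        )
        self.jac_sparsity = (self.S @ probe).tocsr()

    def flux(self, x: np.ndarray) -> np.ndarray:
        v = np.empty(self.m)
        xa = x[self.a]
        v[self.uni] = self.k[self.uni] * xa[self.uni]
        bi = self.bi
        v[bi] = self.k[bi] * xa[bi] * x[self.b[bi]]
        mm = self.mm
        if mm.any():
            s = x[self.b[mm]]
            v[mm] = self.k[mm] * xa[mm] * s / (self.km[mm] + s)
        return v

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.S @ self.flux(x)

    def jac(self, t: float, x: np.ndarray):
        m = self.m
        # per reaction j: d v_j / d x_a and (optionally) d v_j / d x_b
        vals_a = np.empty(m)
        vals_b = np.zeros(m)
        xa = x[self.a]
        xb = np.where(self.b >= 0, x[np.clip(self.b, 0, None)], 1.0)
        vals_a[self.uni] = self.k[self.uni]
        vals_a[self.bi] = self.k[self.bi] * xb[self.bi]
        vals_b[self.bi] = self.k[self.bi] * xa[self.bi]
        mm = self.mm
        if mm.any():
            s = xb[mm]
            den = self.km[mm] + s
            vals_a[mm] = self.k[mm] * s / den
            vals_b[mm] = self.k[mm] * xa[mm] * self.km[mm] / (den * den)
        data = []
        for j in range(m):
            data.append(vals_a[j])
            if self.b[j] >= 0:
                data.append(vals_b[j])
        Dv = sparse.csr_matrix(
            (np.asarray(data), (self._jrows, self._jcols)),
            shape=(m, self.n),
        )
        return (self.S @ Dv).tocsc()


def _compiled(network: ReactionNetwork, bath: dict[str, float] | None):
    key = tuple(sorted((bath or {}).items()))
    cache = getattr(network, "_ode_cache", None)
    if cache is None:
        cache = {}
        network._ode_cache = cache
    if key not in cache:
        cache[key] = _CompiledODE(network, bath or {})
    return cache[key]


def initial_state(network: ReactionNetwork, overrides: dict | None = None) -> np.ndarray:
    """Resting initial condition: free pools at their partition equilibria.

    Membrane seed species are split raft/nonraft according to their class
    partition coefficient; cytosolic pools start unphosphorylated and free.
    ``overrides`` maps molecule-type name to a replacement total copy number.
    """
    params = network.model.params
    totals = {
        "Rec": params.rec_total,
        "Lyn": params.lyn_total,
        "Syk": params.syk_total,
        "LAT": params.lat_total,
        "Grb2": params.grb2_total,
    }
    if overrides:
        totals.update(overrides)
    seeds = {
        "Rec": "Rec(a,b~U,g~U)",
        "Lyn": "Lyn(u,sh2)",
        "LAT": "LAT(y~U)",
        "Syk": "Syk(tsh2,a~U)" if not params.syk_linker_site
        else "Syk(tsh2,l~U,a~U)",
        "Grb2": "Grb2(sh2)",
    }
    ode = _compiled(network, {})
    x = np.zeros(ode.n)
    for mol, label in seeds.items():
        total = totals[mol]
        if total == 0:
            continue
        locs = [sp for sp in network.species if sp.label == label]
        if not locs:
            raise KeyError(f"seed species {label!r} not in network")
        if locs[0].location in (RAFT, NONRAFT):
            raft_sp = network.find(label, RAFT)
            non_sp = network.find(label, NONRAFT)
            rho = raft_sp.rho
            x[ode.to_state[raft_sp.index]] = rho * total
            x[ode.to_state[non_sp.index]] = (1.0 - rho) * total
        else:
            x[ode.to_state[locs[0].index]] = total
    return x


def _observable_matrix(network: ReactionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Rows: beta, gamma, syk, lat, fceri site counts per dynamic species."""
    params = network.model.params
    ode = _compiled(network, {})
    W = np.zeros((5, ode.n))
    for sp in network.species:
        if not sp.dynamic:
            continue
        cpx = network.complex_of(sp.index)
        col = ode.to_state[sp.index]
        nb = sum(1 for m in cpx.mols if m.type == "Rec" and m.states["b"] == "P")
        ng = sum(1 for m in cpx.mols if m.type == "Rec" and m.states["g"] == "P")
        ns = sum(1 for m in cpx.mols if m.type == "Syk" and m.states["a"] == "P")
        nl = sum(1 for m in cpx.mols if m.type == "LAT" and m.states["y"] == "P")
        W[0, col] = nb
        W[1, col] = ng
        W[2, col] = ns
        W[3, col] = nl
        W[4, col] = 0.5 * (nb + ng)
    denom = np.array([
        params.rec_total, params.rec_total, params.syk_total,
        params.lat_total, params.rec_total,
    ])
    return W, denom


def observables_of(network: ReactionNetwork, x: np.ndarray) -> dict[str, float]:
    """Fraction of each protein in the phosphorylated state.

    A site counts as phosphorylated whether naked or occluded by a bound
    SH2 domain; ``fceri`` pools the β and γ ITAMs of the receptor.
    """
    W, denom = _observable_matrix(network)
    vals = W @ np.clip(x, 0.0, None) / denom
    return dict(zip(OBSERVABLES, vals))


def conserved_totals(network: ReactionNetwork, x: np.ndarray) -> dict[str, float]:
    """Total copies of each (non-bath) molecule type in a state vector."""
    types, mat = network.conservation_matrix()
    sub = mat[:, [sp.index for sp in network.species if sp.dynamic]]
    return dict(zip(types, sub @ x))


def integrate(
    network: ReactionNetwork,
    init: np.ndarray,
    t_grid: np.ndarray,
    bath: dict[str, float] | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-3,
    metadata: dict | None = None,
) -> TimeCourse:
    """Integrate the network ODEs and report observables on ``t_grid``."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    ode = _compiled(network, bath)
    if len(init) != ode.n:
        raise ValueError(
            f"initial state has {len(init)} entries, network has {ode.n} "
            "dynamic species"
        )
    t0 = 0.0 if t_grid[0] > 0 else t_grid[0]
    sol = solve_ivp(
        ode.rhs, (t0, t_grid[-1]), init, method="BDF", t_eval=t_grid,
        jac=ode.jac, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed at t={sol.t[-1] if len(sol.t) else t0}: "
            f"{sol.message}"
        )
    states = sol.y.T
    W, denom = _observable_matrix(network)
    obs = {
        name: np.clip(W[i] @ np.clip(states.T, 0.0, None) / denom[i], 0.0, 1.0)
        for i, name in enumerate(OBSERVABLES)
    }
    md = dict(metadata or {})
    md.setdefault("alpha", network.model.params.alpha)
    md.setdefault("raft_lifetime", network.model.params.raft_lifetime)
    return TimeCourse(t=sol.t, observables=obs, states=states, metadata=md)


def steady_state(
    network: ReactionNetwork,
    init: np.ndarray,
    bath: dict[str, float] | None = None,
    deriv_tol: float = 1e-8,
    max_time: float = 1e4,
    rtol: float = 1e-7,
    atol: float = 1e-3,
) -> SteadyState:
    """Integrate until the relative derivative norm falls below ``deriv_tol``.

    Convergence criterion: ||dx/dt|| / ||x|| < deriv_tol (per second).
    Non-convergence within ``max_time`` returns a flagged result rather
    than raising.
    """
    ode = _compiled(network, bath)
    x = np.asarray(init, dtype=float)
    t = 0.0
    window = 10.0
    while t < max_time:
        t_end = min(t + window, max_time)
        sol = solve_ivp(
            ode.rhs, (t, t_end), x, method="BDF", jac=ode.jac,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"integrator failed at t={sol.t[-1]}")
        x = sol.y[:, -1]
        t = t_end
        dn = np.linalg.norm(ode.rhs(t, x)) / max(np.linalg.norm(x), 1.0)
        if dn < deriv_tol:
            return SteadyState(x=x, time=t, converged=True, deriv_norm=dn)
        window *= 4.0
    dn = np.linalg.norm(ode.rhs(t, x)) / max(np.linalg.norm(x), 1.0)
    return SteadyState(x=x, time=t, converged=dn < deriv_tol, deriv_norm=dn)
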