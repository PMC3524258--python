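"""The four in-silico experiments: dose-response, hapten inhibition,
raft-lifetime sweeps and the Lyn palmitoylation-site mutation.

Protocols follow the published experimental designs on RBL-2H3 cells:
stimulation with a bivalent DNP ligand to a signaling steady state, then
(for dephosphorylation kinetics) addition of 100 µM monovalent hapten that
competes receptors out of aggregates and switches transphosphorylation off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import build_model
from .network import generate_network
from .params import ConfigurationError, ParameterSet
from .rafts import RaftGeometry, min_raft_lifetime
from . import simulate as sim

__all__ = [
    "ExperimentProtocol",
    "DoseResponse",
    "dose_response",
    "hapten_inhibition",
    "lifetime_sweep",
    "lyn_mutation",
    "half_life",
    "DEFAULT_DOSE_GRID",
]

#: 1e-4 to 1e3 nM, 8 points per decade
DEFAULT_DOSE_GRID = 10.0 ** np.arange(-13, -5.99, 1.0 / 8.0)

#: hapten-phase observables reported by the dephosphorylation experiments
DEPHOS_OBSERVABLES = ("beta", "gamma", "syk", "lat", "fceri")


@dataclass(frozen=True)
class ExperimentProtocol:
    """Stimulation-then-hapten protocol.

    ``ligand_conc`` (molar) is applied until steady state; ``hapten_conc``
    (molar) is then added at t = 0 and the system integrated on ``t_grid``.
    """

    ligand_conc: float = 1e-9
    hapten_conc: float = 1e-4
    t_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 121.0))

    def __post_init__(self) -> None:
        if self.ligand_conc < 0 or self.hapten_conc < 0:
            raise ConfigurationError("concentrations must be non-negative")


@dataclass
class DoseResponse:
    """Steady-state phospho-fractions per (alpha, dose, observable)."""

    doses: np.ndarray
    alphas: tuple[float, ...]
    table: pd.DataFrame  # columns: alpha, dose, observable, value, converged

    def fractions(self, alpha: float, observable: str) -> np.ndarray:
        t = self.table
        rows = t[(t.alpha == alpha) & (t.observable == observable)]
        return rows.sort_values("dose")["value"].to_numpy()

    def fold_changes(
        self, alpha_low: float, alpha_high: float = 1.0, dose: float = 5e-9
    ) -> dict[str, float]:
        """Fold increase of each observable at the grid dose nearest ``dose``.

        The comparison dose defaults to the optimal ligand concentration for
        aggregate formation (~5 nM).
        """
        nearest = self.doses[np.argmin(np.abs(np.log(self.doses / dose)))]
        t = self.table
        out = {}
        for obs in ("beta", "gamma", "syk", "lat"):
            lo = t[(t.alpha == alpha_low) & (t.observable == obs)
                   & (t.dose == nearest)]["value"].iloc[0]
            hi = t[(t.alpha == alpha_high) & (t.observable == obs)
                   & (t.dose == nearest)]["value"].iloc[0]
            out[obs] = lo / hi if hi > 0 else np.inf
        return out


def _steady(params: ParameterSet, ligand: float, network=None):
    net = network if network is not None else generate_network(build_model(params))
    x0 = sim.initial_state(net)
    ss = sim.steady_state(net, x0, bath={"Lig": ligand, "Hap": 0.0})
    return net, ss


def dose_response(
    alphas,
    dose_grid=None,
    params: ParameterSet | None = None,
) -> DoseResponse:
    """Steady-state phosphorylation versus ligand dose at several raft
    protection levels.

    Larger raft protection (smaller α) always increases the steady-state
    phospho-fraction of every observable.
    """
    params = params or ParameterSet.defaults()
    doses = np.asarray(DEFAULT_DOSE_GRID if dose_grid is None else dose_grid,
                       dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise ConfigurationError("dose grid must be strictly increasing")
    rows = []
    for alpha in alphas:
        p = params.replace(alpha=float(alpha))
        net = generate_network(build_model(p))
        x0 = sim.initial_state(net)
        for dose in doses:
            ss = sim.steady_state(net, x0, bath={"Lig": dose, "Hap": 0.0})
            obs = sim.observables_of(net, ss.x)
            for name in DEPHOS_OBSERVABLES:
                rows.append({
                    "alpha": float(alpha), "dose": dose, "observable": name,
                    "value": float(obs[name]), "converged": ss.converged,
                })
    return DoseResponse(
        doses=doses, alphas=tuple(float(a) for a in alphas),
        table=pd.DataFrame(rows),
    )


def half_life(t: np.ndarray, normalized: np.ndarray) -> float:
    """First time a normalized decay curve crosses 0.5 (log-linear
    interpolation between grid points); inf if it never does."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(normalized, dtype=float)
    below = np.where(c < 0.5)[0]
    if len(below) == 0:
        return float("inf")
    i = int(below[0])
    if i == 0:
        return float(t[0])
    c0, c1 = c[i - 1], c[i]
    return float(t[i - 1] + (t[i] - t[i - 1]) * np.log(c0 / 0.5) / np.log(c0 / c1))


def hapten_inhibition(
    protocol: ExperimentProtocol | None = None,
    alphas=(0.2,),
    params: ParameterSet | None = None,
) -> dict[float, sim.TimeCourse]:
    """Hapten-inhibition dephosphorylation curves per raft protection level.

    Phase 1 runs the bivalent-ligand stimulation to steady state; phase 2
    adds excess monovalent hapten at t = 0 and follows each
    phospho-observable normalized to its value at hapten addition
    ("fraction remaining").  Half-lives are stored in each time course's
    metadata.
    """
    protocol = protocol or ExperimentProtocol()
    params = params or ParameterSet.defaults()
    out: dict[float, sim.TimeCourse] = {}
    for alpha in alphas:
        p = params.replace(alpha=float(alpha))
        net, ss = _steady(p, protocol.ligand_conc)
        tc = sim.integrate(
            net, ss.x, protocol.t_grid,
            bath={"Lig": protocol.ligand_conc, "Hap": protocol.hapten_conc},
        )
        normalized = {}
        halves = {}
        for name in DEPHOS_OBSERVABLES:
            v0 = tc.observables[name][0]
            if v0 <= 0:
                raise ConfigurationError(
                    f"observable {name!r} is zero at hapten addition; "
                    "cannot normalize"
                )
            normalized[name] = tc.observables[name] / v0
            halves[name] = half_life(tc.t, normalized[name])
        out[float(alpha)] = sim.TimeCourse(
            t=tc.t, observables=normalized, states=tc.states,
            metadata={
                "alpha": float(alpha),
                "raft_lifetime": p.raft_lifetime,
                "syk_off_rate": p.syk_off_rate,
                "ligand_conc": protocol.ligand_conc,
                "hapten_conc": protocol.hapten_conc,
                "half_life": halves,
                "t0_fractions": {n: float(tc.observables[n][0])
                                 for n in DEPHOS_OBSERVABLES},
            },
        )
    return out


def lifetime_sweep(
    lambdas=(1.0, 10.0, 100.0),
    alphas=(0.0, 0.2, 1.0),
    params: ParameterSet | None = None,
    protocol: ExperimentProtocol | None = None,
) -> dict[float, dict[float, sim.TimeCourse]]:
    """Hapten-inhibition curves across raft lifetimes.

    Entry rates are re-derived from the equilibrium relation at each
    lifetime so every partition coefficient stays fixed; lifetimes below the
    diffusion-limited minimum for any partition class are rejected.
    """
    params = params or ParameterSet.defaults()
    geometry = RaftGeometry(
        raft_radius=params.raft_radius, coverage=params.coverage,
        cell_area=params.cell_area,
    )
    rho_max = max(params.rho_dimer, params.rho_lyn, params.rho_lat)
    lam_min = min_raft_lifetime(geometry, rho_max, params.diffusion_coefficient)
    out: dict[float, dict[float, sim.TimeCourse]] = {}
    for lam in lambdas:
        if lam < lam_min:
            raise ConfigurationError(
                f"raft lifetime {lam} s is below the diffusion-limited "
                f"minimum {lam_min:.3g} s for partition coefficient {rho_max}"
            )
        out[float(lam)] = hapten_inhibition(
            protocol, alphas, params.replace(raft_lifetime=float(lam))
        )
    return out


def lyn_mutation(
    alpha: float = 0.1,
    rho_wt: float = 0.32,
    rho_ca: float = 0.06,
    params: ParameterSet | None = None,
    ligand_conc: float = 1e-9,
    pool_receptor: bool = True,
) -> dict[str, float]:
    """Percent reduction in phosphorylation due to Lyn palmitoylation loss.

    Two steady states at the stimulating ligand dose: wild-type Lyn
    (partition coefficient ``rho_wt``, conferring its raft preference on a
    bound monomeric receptor) versus the palmitoylation-site mutant
    (partitioning like a nonraft protein, ``rho_ca``, and leaving a bound
    monomeric receptor indifferent to rafts).  Returns
    100*(1 - mutant/wild-type) for the receptor (β+γ pooled by default),
    Syk and LAT.
    """
    if not 0 < rho_wt < 1 or not 0 < rho_ca < 1:
        raise ConfigurationError("partition coefficients must be in (0, 1)")
    params = params or ParameterSet.defaults()
    p_wt = params.replace(alpha=float(alpha), rho_lyn=float(rho_wt),
                          lyn_palmitoylation_mutant=False)
    p_ca = params.replace(alpha=float(alpha), lyn_palmitoylation_mutant=True)
    _, ss_wt = _steady(p_wt, ligand_conc)
    _, ss_ca = _steady(p_ca, ligand_conc)
    net_wt = generate_network(build_model(p_wt))
    net_ca = generate_network(build_model(p_ca))
    obs_wt = sim.observables_of(net_wt, ss_wt.x)
    obs_ca = sim.observables_of(net_ca, ss_ca.x)
    names = ["fceri", "syk", "lat"] if pool_receptor else \
        ["beta", "gamma", "syk", "lat"]
    return {
        n: 100.0 * (1.0 - obs_ca[n] / obs_wt[n]) for n in names
    }
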