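"""Analytic machinery for transient lipid rafts.

The plasma membrane is modelled as two well-mixed compartments: a raft
compartment made up of ``N_rafts`` identical disks of radius ``s`` covering a
fixed fraction of the cell surface, and the remaining nonraft membrane.  Rafts
are transient: each dissolves with mean lifetime ``lam`` (seconds) and a new
raft forms elsewhere, so the raft density is constant in time.

A membrane complex class with equilibrium raft fraction (partition
coefficient) ``rho`` exchanges between the compartments as a two-state
process: raft -> nonraft at rate ``1/lam`` (raft dissolution) and
nonraft -> raft at the entry rate ``k_on = k_plus * N`` where ``k_plus`` is a
two-dimensional forward rate constant (area/time) and ``N`` the raft density.
At equilibrium::

    rho = lam / (lam + 1/(k_plus*N))

which is inverted by :func:`entry_rate_from_partition`.  The entry rate
demanded by a given (rho, lam) pair is physical only if ``k_plus`` does not
exceed the diffusion-limited capture rate for a transient disk trap,
computed by :func:`diffusion_limited_rate`; the lifetime at which the two
cross is :func:`min_raft_lifetime`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ive, kve

__all__ = [
    "RaftGeometry",
    "RaftKinetics",
    "raft_count",
    "entry_rate_from_partition",
    "partition_from_rates",
    "diffusion_limited_rate",
    "min_raft_lifetime",
]


@dataclass(frozen=True)
class RaftGeometry:
    """Raft disk geometry on a cell of total membrane area ``cell_area``.

    Parameters
    ----------
    raft_radius : float
        Radius ``s`` of a single raft disk, in cm (default 100 nm).
    coverage : float
        Fraction of the membrane occupied by the raft compartment.
    cell_area : float
        Total plasma-membrane area in cm^2.
    """

    raft_radius: float = 100e-7
    coverage: float = 0.30
    cell_area: float = 8e-6

    def __post_init__(self) -> None:
        if self.raft_radius <= 0 or self.cell_area <= 0:
            raise ValueError("raft_radius and cell_area must be positive")
        if not 0 <= self.coverage < 1:
            raise ValueError(f"coverage must be in [0, 1), got {self.coverage}")

    @property
    def n_rafts(self) -> int:
        """Number of rafts on the cell (nearest integer)."""
        return raft_count(self)

    @property
    def raft_density(self) -> float:
        """Rafts per cm^2 of membrane."""
        return self.n_rafts / self.cell_area

    @property
    def outer_radius(self) -> float:
        """Outer radius ``b`` of the annulus assigned to each raft.

        ``b = 1/sqrt(pi N)`` so that each raft plus its annulus tiles the
        membrane area exactly.
        """
        if self.n_rafts == 0:
            raise ValueError("no rafts: outer radius undefined")
        return 1.0 / math.sqrt(math.pi * self.raft_density)


@dataclass(frozen=True)
class RaftKinetics:
    """Exchange kinetics of one membrane complex class.

    ``lifetime`` is the mean raft lifetime (s), ``rho`` the equilibrium raft
    fraction of the class and ``diffusion_coefficient`` the relative
    protein-raft diffusion coefficient (cm^2/s) used in the diffusion-limit
    check.  Raft diffusion (~1e-8 cm^2/s) dominates protein diffusion
    (1e-9 to 1e-11 cm^2/s), so one coefficient serves for every protein.
    """

    lifetime: float = 10.0
    rho: float = 0.85
    diffusion_coefficient: float = 1e-8

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ValueError("raft lifetime must be positive")
        if not 0 < self.rho < 1:
            raise ValueError(f"partition coefficient must be in (0,1), got {self.rho}")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be positive")

    @property
    def entry_rate(self) -> float:
        """Nonraft->raft transition rate k_plus*N (per s)."""
        return entry_rate_from_partition(self.rho, self.lifetime)

    @property
    def exit_rate(self) -> float:
        """Raft->nonraft transition rate 1/lifetime (per s)."""
        return 1.0 / self.lifetime

    @property
    def mean_nonraft_sojourn(self) -> float:
        """Mean time (s) spent in the nonraft compartment per cycle."""
        return 1.0 / self.entry_rate


def raft_count(geometry: RaftGeometry) -> int:
    """Number of rafts implied by coverage, cell area and raft radius."""
    s = geometry.raft_radius
    return round(geometry.coverage * geometry.cell_area / (math.pi * s * s))


def entry_rate_from_partition(rho: float, lam: float) -> float:
    """Invert the equilibrium relation rho = lam/(lam + 1/(k+N)) for k+N.

    Returns the nonraft->raft rate (per second).  Its reciprocal is the mean
    time the complex spends in the nonraft compartment between captures.
    """
    if not 0 < rho < 1:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    if lam <= 0:
        raise ValueError(f"raft lifetime must be positive, got {lam}")
    return rho / (lam * (1.0 - rho))


def partition_from_rates(entry_rate: float, lam: float) -> float:
    """Equilibrium raft fraction of a two-state exchange process."""
    return lam / (lam + 1.0 / entry_rate)


def _annulus_mean_capture_time(s: float, b: float, lam: float, D: float) -> float:
    """Mean capture time for a diffuser among transient disk traps.

    Each trap of radius ``s`` owns an annulus of outer radius ``b``
    (reflecting).  The trap dissolves at rate ``1/lam``; a new trap then
    appears at a position uncorrelated with the diffuser, which therefore
    finds itself uniformly distributed over the disk of radius ``b`` around
    the new trap -- inside it (instant capture, probability (s/b)^2) or in
    the annulus.  Solving the backward equation

        D (T'' + T'/r) - T/lam = -(1 + <T after renewal>/lam),  T(s)=0, T'(b)=0

    self-consistently gives, with q = 1/sqrt(D*lam),

        T_ann  = lam * (F - 1),      F = q(b^2-s^2)/(2s) * num/den
        num    = K1(qb) I0(qs) + K0(qs) I1(qb)
        den    = K1(qs) I1(qb) - I1(qs) K1(qb)
        T_mean = T_ann / (1 + (s/b)^2 * T_ann/lam)

    Exponentially scaled Bessel functions keep the ratio finite for large
    arguments (short lifetimes).
    """
    q = 1.0 / math.sqrt(D * lam)
    qs, qb = q * s, q * b
    # I(x) = ive(x) e^x and K(x) = kve(x) e^-x; a common factor e^(qb-qs)
    # cancels between num and den once e^(2(qs-qb)) is attached to the
    # subdominant terms.
    e = math.exp(2.0 * (qs - qb))
    num = kve(1, qb) * ive(0, qs) * e + kve(0, qs) * ive(1, qb)
    den = kve(1, qs) * ive(1, qb) - ive(1, qs) * kve(1, qb) * e
    F = q * (b * b - s * s) / (2.0 * s) * num / den
    t_ann = lam * (F - 1.0)
    sigma = (s / b) ** 2
    return t_ann / (1.0 + sigma * t_ann / lam)


def diffusion_limited_rate(
    geometry: RaftGeometry, lam: float, D: float = 1e-8
) -> float:
    """Diffusion-limited 2D forward rate constant (cm^2/s) for transient rafts.

    The highest rate at which a membrane protein can be captured by rafts of
    radius ``s``, density ``N`` and lifetime ``lam`` by diffusion alone, with
    relative diffusion coefficient ``D``.  Defined so that ``k * N`` is the
    reciprocal of the mean capture time of a protein released in the nonraft
    membrane.  Monotone non-increasing in ``lam``: short-lived traps capture
    faster because trap turnover re-randomizes trap positions relative to
    the protein.
    """
    if lam <= 0 or D <= 0:
        raise ValueError("lam and D must be positive")
    s = geometry.raft_radius
    b = geometry.outer_radius
    if s >= b:
        raise ValueError(f"raft radius {s} must be below outer radius {b}")
    t_mean = _annulus_mean_capture_time(s, b, lam, D)
    return 1.0 / (t_mean * geometry.raft_density)


def min_raft_lifetime(
    geometry: RaftGeometry,
    rho: float,
    D: float = 1e-8,
    bracket: tuple[float, float] = (1e-4, 1e3),
    rtol: float = 1e-4,
) -> float:
    """Shortest physically permissible raft lifetime for a partition class.

    Below the returned lifetime, the entry rate demanded by the equilibrium
    relation for ``rho`` exceeds the diffusion-limited capture rate and the
    compartment model is inconsistent.  Found by bracketed root search on a
    log-spaced lifetime grid.
    """
    if not 0 < rho < 1:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    N = geometry.raft_density

    def gap(lam: float) -> float:
        return entry_rate_from_partition(rho, lam) - N * diffusion_limited_rate(
            geometry, lam, D
        )

    lams = np.logspace(math.log10(bracket[0]), math.log10(bracket[1]), 200)
    vals = [gap(l) for l in lams]
    for lo, hi, vlo, vhi in zip(lams[:-1], lams[1:], vals[:-1], vals[1:]):
        if vlo == 0.0:
            return float(lo)
        if vlo * vhi < 0:
            return float(brentq(gap, lo, hi, rtol=rtol))
    if all(v < 0 for v in vals):
        # demand stays below the diffusion limit throughout: no lower bound
        # on the lifetime within the bracket (the rho -> 0 limit)
        return 0.0
    raise ValueError(
        "no diffusion-limit crossing in lifetime bracket "
        f"[{bracket[0]}, {bracket[1]}] s (gap at endpoints: {vals[0]:.3g}, {vals[-1]:.3g})"
    )


def assert_below_diffusion_limit(
    geometry: RaftGeometry, rho: float, lam: float, D: float = 1e-8
) -> None:
    """Raise if the (rho, lam) pair demands a super-diffusion-limited entry rate."""
    demanded = entry_rate_from_partition(rho, lam) / geometry.raft_density
    limit = diffusion_limited_rate(geometry, lam, D)
    if demanded > limit:
        raise ValueError(
            f"entry rate for rho={rho} at lifetime {lam} s requires forward rate "
            f"constant {demanded:.3g} cm^2/s above the diffusion limit {limit:.3g}; "
            f"minimum lifetime is {min_raft_lifetime(geometry, rho, D):.3g} s"
        )


def extrapolate_detergent_partition(detergent_pct, raft_fraction_pct):
    """Zero-detergent extrapolation of detergent-resistance partition data.

    Detergent solubilization underestimates raft association in a
    concentration-dependent way; a linear extrapolation of the measured
    raft-associated percentage to zero detergent estimates the true
    partition coefficient.  Returns a fraction in (0, 1).
    """
    x = np.asarray(detergent_pct, dtype=float)
    y = np.asarray(raft_fraction_pct, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two detergent concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept) / 100.0
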