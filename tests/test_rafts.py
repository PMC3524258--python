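"""Raft geometry, the partition/exchange relation and the transient-trap
diffusion limit, validated against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from raftsignal.rafts import (
    RaftGeometry,
    RaftKinetics,
    assert_below_diffusion_limit,
    diffusion_limited_rate,
    entry_rate_from_partition,
    extrapolate_detergent_partition,
    min_raft_lifetime,
    partition_from_rates,
    raft_count,
)

GEOM = RaftGeometry()  # 100 nm, 30%, 8e-6 cm^2


class TestGeometry:
    def test_default_raft_count_near_8000(self):
        assert raft_count(GEOM) == 7639
        assert raft_count(GEOM) == pytest.approx(8000, rel=0.05)

    def test_micron_rafts(self):
        g = RaftGeometry(raft_radius=1000e-7)
        # 30% of an 8e-6 cm^2 membrane holds 76 one-micron disks
        assert raft_count(g) == 76

    def test_vanishing_coverage(self):
        assert raft_count(RaftGeometry(coverage=1e-9)) == 0

    def test_coverage_recovered_within_one_raft(self):
        area_one = math.pi * GEOM.raft_radius ** 2
        covered = GEOM.n_rafts * area_one / GEOM.cell_area
        assert abs(covered - GEOM.coverage) < area_one / GEOM.cell_area

    def test_outer_radius_tiles_membrane(self):
        b = GEOM.outer_radius
        assert b > GEOM.raft_radius
        assert GEOM.n_rafts * math.pi * b * b == pytest.approx(
            GEOM.cell_area, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            RaftGeometry(raft_radius=-1)
        with pytest.raises(ValueError):
            RaftGeometry(coverage=1.5)


class TestPartitionExchange:
    def test_lat_sojourn(self):
        # rho = 0.85, lifetime 10 s: 10 s inside, ~1.8 s outside per cycle
        kin = RaftKinetics(lifetime=10.0, rho=0.85)
        assert kin.entry_rate == pytest.approx(0.5667, rel=1e-3)
        assert kin.mean_nonraft_sojourn == pytest.approx(1.76, rel=5e-3)

    def test_symmetric_partition(self):
        # rho = 1/2: time outside equals the raft lifetime, whatever it is
        for lam in (0.1, 1.0, 42.0):
            assert 1.0 / entry_rate_from_partition(0.5, lam) == pytest.approx(lam)

    def test_monomer_sojourn(self):
        assert 1.0 / entry_rate_from_partition(0.30, 10.0) == pytest.approx(
            10 * 0.7 / 0.3
        )

    @given(
        rho=st.floats(0.01, 0.99),
        lam=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equilibrium_round_trip(self, rho, lam):
        k_on = entry_rate_from_partition(rho, lam)
        assert partition_from_rates(k_on, lam) == pytest.approx(rho, rel=1e-12)

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            entry_rate_from_partition(1.0, 10.0)
        with pytest.raises(ValueError):
            entry_rate_from_partition(0.5, -1.0)


def _mean_capture_time_fd(s, b, lam, D, n=4000, iters=200):
    """Independent finite-difference oracle for the transient-trap capture
    time: radial backward equation on [s, b] with absorbing inner and
    reflecting outer boundary, trap renewal at rate 1/lam relocating the
    diffuser uniformly over the disk of radius b (instant capture inside
    the new trap), solved by self-consistent iteration."""
    r = np.linspace(s, b, n)
    h = r[1] - r[0]
    sigma = (s / b) ** 2
    # tridiagonal operator for D(T'' + T'/r) - T/lam
    main = np.full(n, -2 * D / h**2 - 1.0 / lam)
    lower = np.full(n - 1, D / h**2)
    upper = np.full(n - 1, D / h**2)
    lower[:-1] -= D / (2 * r[1:-1] * h)
    upper[1:] += D / (2 * r[1:-1] * h)
    # boundary rows: T(s)=0; reflecting at b via ghost point
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    A = sp.diags([lower, main, upper], [-1, 0, 1], format="lil")
    A[0, :] = 0.0
    A[0, 0] = 1.0
    A[-1, :] = 0.0
    A[-1, -1] = -2 * D / h**2 - 1.0 / lam
    A[-1, -2] = 2 * D / h**2
    A = A.tocsc()
    lu = spla.splu(A)
    t_renew = 0.0
    t_ann = 0.0
    for _ in range(iters):
        rhs = np.full(n, -1.0 - t_renew / lam)
        rhs[0] = 0.0
        T = lu.solve(rhs)
        t_ann = np.trapezoid(T * r, r) / np.trapezoid(r, r)
        new = (1.0 - sigma) * t_ann
        if abs(new - t_renew) < 1e-10 * max(t_renew, 1.0):
            t_renew = new
            break
        t_renew = new
    return t_ann


class TestDiffusionLimit:
    def test_steady_state_limit(self):
        # lam -> inf: classic steady 2D trapping in an annulus
        s, b, D = GEOM.raft_radius, GEOM.outer_radius, 1e-8
        T = lambda r: (b * b / (2 * D)) * np.log(r / s) - (r * r - s * s) / (4 * D)
        num, _ = quad(lambda r: T(r) * 2 * np.pi * r, s, b)
        t_ss = num / (np.pi * (b * b - s * s))
        k_inf = diffusion_limited_rate(GEOM, 1e4, D)
        assert k_inf * GEOM.raft_density == pytest.approx(1.0 / t_ss, rel=1e-4)

    @pytest.mark.parametrize("lam", [0.01, 0.3])
    def test_against_pde_oracle(self, lam):
        s, b, D = GEOM.raft_radius, GEOM.outer_radius, 1e-8
        t_oracle = _mean_capture_time_fd(s, b, lam, D)
        k = diffusion_limited_rate(GEOM, lam, D)
        assert 1.0 / (k * GEOM.raft_density) == pytest.approx(t_oracle, rel=2e-3)

    def test_monotone_in_lifetime(self):
        lams = np.logspace(-3, 3, 40)
        ks = [diffusion_limited_rate(GEOM, lam) for lam in lams]
        assert all(a >= b * (1 - 1e-12) for a, b in zip(ks[:-1], ks[1:]))

    def test_linear_in_diffusion_coefficient(self):
        # fixed s/b and s^2/(D lam): k scales linearly with D
        lam, D = 0.05, 1e-8
        k1 = diffusion_limited_rate(GEOM, lam, D)
        k2 = diffusion_limited_rate(GEOM, lam / 10, 10 * D)
        assert k2 == pytest.approx(10 * k1, rel=1e-12)

    def test_invalid_lifetime(self):
        with pytest.raises(ValueError):
            diffusion_limited_rate(GEOM, -1.0)


class TestMinimumLifetime:
    def test_hundred_nm_rafts(self):
        lam = min_raft_lifetime(GEOM, rho=0.85)
        assert lam == pytest.approx(0.0161, rel=0.01)

    def test_micron_rafts(self):
        g = RaftGeometry(raft_radius=1000e-7)
        lam = min_raft_lifetime(g, rho=0.85)
        assert 1.4 < lam < 2.1

    def test_vanishing_partition_demand(self):
        # rho -> 0: the entry-rate demand vanishes, so does the minimum
        assert min_raft_lifetime(GEOM, rho=1e-3) == 0.0

    def test_inconsistent_bracket_reports_endpoints(self):
        # the whole bracket sits below the crossing: demand always exceeds
        # the diffusion limit there
        with pytest.raises(ValueError, match="bracket"):
            min_raft_lifetime(GEOM, rho=0.85, bracket=(1e-4, 1e-3))

    def test_limit_assertion(self):
        assert_below_diffusion_limit(GEOM, 0.85, 10.0)  # fine at 10 s
        with pytest.raises(ValueError, match="diffusion limit"):
            assert_below_diffusion_limit(GEOM, 0.85, 0.005)


def test_triton_extrapolation():
    # 65.6% raft association at 0.06% detergent, 52.9% at 0.1% -> ~85% at 0
    rho = extrapolate_detergent_partition([0.06, 0.10], [65.6, 52.9])
    assert rho == pytest.approx(0.85, abs=0.005)
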