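"""Shared fixtures and builders for the test suite.

``make_profile`` builds small hand-written profiles (NaN marks a censored
cell); the session-scoped preset fixtures solve the forward model once and
share the noise-free profile, analytic truth and derived zonation.
"""

from __future__ import annotations

import numpy as np
import pytest

import poreflux as pf
from poreflux.profile_io import SoluteSeries

DEFAULT_DLS = {"nitrate": 0.1, "nitrite": 0.1, "ammonium": 0.1, "oxygen": 2.0}


def make_profile(depth_cm, porosity=0.7, site=None, detection_limits=None, **series):
    """Build a DepthProfile from plain lists; NaN cells become censored points."""
    site = site or pf.SiteMetadata(site_id="test", water_depth=1000.0)
    limits = dict(DEFAULT_DLS)
    limits.update(detection_limits or {})
    solutes = {}
    for name, values in series.items():
        vals = np.asarray(values, dtype=float)
        censored = np.isnan(vals) | (np.nan_to_num(vals) < limits[name])
        solutes[name] = SoluteSeries(np.where(censored, 0.0, vals), censored)
    return pf.DepthProfile(
        site=site,
        depth_cm=np.asarray(depth_cm, dtype=float),
        solutes=solutes,
        porosity=np.full(len(depth_cm), porosity),
        detection_limits={k: limits[k] for k in solutes},
    )


@pytest.fixture(scope="session")
def solutes():
    return pf.default_solutes()


@pytest.fixture(scope="session")
def gs14():
    scenario = pf.preset_scenario("GS14-like", noise_sd=0.0)
    profile, truth = pf.generate_profile(scenario)
    zones = pf.derive_zones(profile)
    return scenario, profile, truth, zones


@pytest.fixture(scope="session")
def gs16():
    scenario = pf.preset_scenario("GS16-like", noise_sd=0.0)
    profile, truth = pf.generate_profile(scenario)
    zones = pf.derive_zones(profile)
    return scenario, profile, truth, zones


def finite_difference_solution(edges_m, rates, c_top, c_bot, d, h=0.005):
    """Independent second-order finite-difference solution of the steady state.

    Solves C'' = -R(z)/d on a uniform grid aligned with the zone interfaces
    (the right-hand side at an interface node is the average of the two
    adjacent zones).  Returns (z, C, J_top, J_bot) with fluxes per unit
    (phi*d) from one-sided second-order differences.
    """
    from scipy.sparse import diags
    from scipy.sparse.linalg import spsolve

    length = edges_m[-1]
    n = int(round(length / h)) + 1
    z = np.linspace(0.0, length, n)
    rhs_zone = -np.asarray(rates, dtype=float) / d

    def rhs_at(zi):
        k = np.searchsorted(edges_m, zi, side="right") - 1
        k = min(max(k, 0), len(rates) - 1)
        interior_edges = np.asarray(edges_m[1:-1])
        if interior_edges.size and np.min(np.abs(interior_edges - zi)) < 1e-9:
            # at an interface the discretely consistent RHS is the mean of
            # the two adjacent zones' values
            kb = int(np.argmin(np.abs(interior_edges - zi)))
            return 0.5 * (rhs_zone[kb] + rhs_zone[kb + 1])
        return rhs_zone[k]

    f = np.array([rhs_at(zi) for zi in z])
    main = np.full(n - 2, -2.0)
    off = np.ones(n - 3)
    a = diags([off, main, off], [-1, 0, 1], format="csc") / h**2
    b = f[1:-1].copy()
    b[0] -= c_top / h**2
    b[-1] -= c_bot / h**2
    interior = spsolve(a, b)
    c = np.concatenate([[c_top], interior, [c_bot]])
    j_top = d * (-3 * c[0] + 4 * c[1] - c[2]) / (2 * h)
    j_bot = d * (3 * c[-1] - 4 * c[-2] + c[-3]) / (2 * h)
    return z, c, j_top, j_bot


def random_three_zone_scenarios(n, seed, grid_cm=10.0):
    """Yield n valid (non-negative) random 3-zone single-solute scenarios."""
    rng = np.random.default_rng(seed)
    site = pf.SiteMetadata(site_id="rand", water_depth=1000.0)
    solutes = pf.default_solutes()
    out = []
    while len(out) < n:
        b = np.sort(rng.choice(np.arange(20, 190, 10), size=2, replace=False))
        rates = tuple(rng.uniform(-0.6, 0.8, size=3))
        bc = (rng.uniform(0.5, 20.0), rng.uniform(0.0, 20.0))
        scenario = pf.SyntheticScenario(
            name="random3",
            length_cm=200.0,
            grid_cm=grid_cm,
            boundaries_cm=tuple(float(x) for x in b),
            rates={"nitrate": rates},
            boundary_concentrations={"nitrate": bc},
            porosity=0.7,
            site=site,
            solutes=solutes,
            rng_seed=int(rng.integers(2**31)),
        )
        try:
            truth = pf.solve_steady_state(scenario)
        except pf.PorefluxError:
            continue
        out.append((scenario, truth))
    return out
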