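"""Synthetic data generators with known ground truth.

Two pathway generators mirror the statistical structure of the case studies
used throughout the test suite:

* :func:`branched_fixture` -- a generic branched pathway: 4 metabolites,
  6 power-law (GMA) fluxes, 13 kinetic parameters, all metabolites measured,
  i.i.d. Gaussian noise with a stated coefficient of variation (default 10%).
* :func:`trehalose_fixture` -- a simplified yeast trehalose pathway:
  8 metabolites, 8 fluxes, a Michaelis-Menten glucose transport step across
  the extracellular/intracellular volume ratio, two pure sink metabolites
  (PPP, leakage), and unmeasured intracellular glucose.

The exact stoichiometric right-hand sides and true parameter values of the
original case studies are not published; the generators therefore use
documented default truths chosen so that every published structural fact
holds: dependency patterns and parameter counts, degrees of freedom (2 and
3), and the independent-flux choices {v1, v6} and {v4, v7, v8} emerging from
the selection criteria (invertible S_D, fewest independent parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (KineticModel, MichaelisMentenFlux, ParameterVector,
                         PowerLawFlux, simulate)
from .preprocessing import TimeSeriesData

#: default parameter bounds from the case studies: rate constants in [0, 100],
#: kinetic orders in [0, 5]; Michaelis-Menten vmax/km treated alike.
GAMMA_BOUNDS = (0.0, 100.0)
ORDER_BOUNDS = (0.0, 5.0)

#: bioreactor extracellular and intracellular volumes (litres) of the
#: trehalose case; the transport flux enters the extracellular glucose
#: balance scaled by -V_in/V_ex.
V_EX = 5.00e-2
V_IN = 7.17e-3

#: absolute noise standard deviation applied where the trajectory value is 0
#: (a relative CV would give those points zero noise).
ZERO_VALUE_NOISE_SD = 1e-4

NEGATIVE_DATA_FLOOR = 1e-6


@dataclass
class FixtureResult:
    """Bundle returned by the fixture generators.

    Iterating yields ``(model, truth, data)`` so the common unpacking
    ``model, truth, data = branched_fixture(...)`` works; the noise-free
    trajectory and full initial state are available as attributes.
    """

    model: KineticModel
    truth: ParameterVector
    data: TimeSeriesData
    initial_state: np.ndarray
    noise_free: np.ndarray  # K x m, full model trajectory without noise
    times: np.ndarray

    def __iter__(self):
        return iter((self.model, self.truth, self.data))


def _pl(gamma, orders, name):
    bounds = {"gamma": GAMMA_BOUNDS}
    for i in orders:
        bounds[f"f_{i}"] = ORDER_BOUNDS
    return PowerLawFlux(gamma, dict(orders), name=name, bounds=bounds)


def _add_noise(values, noise_cv, rng):
    """i.i.d. Gaussian noise with sd = cv * value; absolute floor at zeros."""
    sd = noise_cv * np.abs(values)
    sd = np.where(values == 0, ZERO_VALUE_NOISE_SD if noise_cv > 0 else 0.0, sd)
    noisy = values + rng.standard_normal(values.shape) * sd
    return np.clip(noisy, NEGATIVE_DATA_FLOOR, None)


#: default true parameters, chosen so that (i) the pathway relaxes to an
#: O(1) steady state (gamma1 = gamma2 + gamma5, gamma3 = gamma4 + gamma6,
#: gamma5 = gamma3 at unit concentrations), (ii) concentrations stay of
#: order one so all fluxes remain bounded away from zero, and (iii) the
#: kinetic orders sit mid-range, keeping their noisy estimates inside the
#: [0, 5] search box.
BRANCHED_TRUTH = {
    0: (1.7, 1.0),        # v1: influx to X1, activated by X3 (gamma1, f13)
    1: (0.7, 1.5),        # v2: X1 -> X2 (gamma2, f21)
    2: (1.0, 1.5),        # v3: X3 -> sink (gamma3, f33)
    3: (0.5, 1.0, 1.5),   # v4: X4 -> X3, activated by X3 (gamma4, f43, f44)
    4: (1.0, 1.5),        # v5: X1 -> X4 (gamma5, f51)
    5: (0.5, 1.5),        # v6: X4 -> X3 (gamma6, f64)
}

BRANCHED_INITIAL_STATE = (2.5, 0.2, 2.0, 2.5)

#: validation initial states of the branched case study.
BRANCHED_VALIDATION_STATES = ((4.0, 1.0, 3.0, 4.0), (0.2, 0.3, 4.2, 0.01))


def branched_model(params=None):
    """The 4-metabolite, 6-flux branched GMA model (13 kinetic parameters).

    X1 receives an influx (v1) regulated by X3 and branches into X2 (v2) and
    X4 (v5); X4 is converted to X3 by two parallel routes (v4, activated by
    X3, and v6); X3 drains through v3.  The parallel v4/v6 routes give those
    fluxes proportional stoichiometric columns, which is what makes
    {v1, v6} the unique minimal independent set.
    """
    truth = dict(BRANCHED_TRUTH)
    if params:
        truth.update({int(k): tuple(v) for k, v in params.items()})
    S = np.array([
        #  v1  v2  v3  v4  v5  v6
        [1., -1., 0., 0., -1., 0.],   # X1
        [0., 1., 0., 0., 0., 0.],     # X2
        [0., 0., -1., 1., 0., 1.],    # X3
        [0., 0., 0., -1., 1., -1.],   # X4
    ])
    g1, f13 = truth[0]
    g2, f21 = truth[1]
    g3, f33 = truth[2]
    g4, f43, f44 = truth[3]
    g5, f51 = truth[4]
    g6, f64 = truth[5]
    fluxes = [
        _pl(g1, {2: f13}, "v1"),
        _pl(g2, {0: f21}, "v2"),
        _pl(g3, {2: f33}, "v3"),
        _pl(g4, {2: f43, 3: f44}, "v4"),
        _pl(g5, {0: f51}, "v5"),
        _pl(g6, {3: f64}, "v6"),
    ]
    return KineticModel(S, fluxes, ["X1", "X2", "X3", "X4"])


def branched_fixture(params=None, noise_cv=0.10, time_grid=None,
                     initial_state=None, seed=None):
    """Simulate the branched pathway and contaminate it with relative noise.

    Noise is i.i.d. Gaussian per point with standard deviation
    ``noise_cv * value`` (10% CV by default); negative noisy values are
    floored at a small positive constant.
    """
    model = branched_model(params)
    truth = model.true_parameters()
    t = np.linspace(0.0, 6.0, 101) if time_grid is None else np.asarray(time_grid)
    x0 = np.asarray(BRANCHED_INITIAL_STATE if initial_state is None
                    else initial_state, dtype=float)
    traj = simulate(model, initial_state=x0, time_grid=t, rtol=1e-8, atol=1e-10)
    rng = np.random.default_rng(seed)
    noisy = _add_noise(traj, noise_cv, rng) if noise_cv > 0 else traj.copy()
    data = TimeSeriesData(t, noisy, list(model.metabolite_names))
    return FixtureResult(model, truth, data, x0, traj, t)


#: MM transport truth chosen so the glucose pulse traverses both kinetic
#: regimes: a near-constant decrease while X1 >> km and an exponential-like
#: tail once X1 falls below km (this is what makes both vmax and km
#: identifiable from the transport flux profile).
TREHALOSE_TRUTH = {
    0: (3.0, 0.8),              # v1: MM glucose transport (vmax, km)
    1: (1.5, 0.7, 0.2),         # v2: hexokinase, inGlc -> G6P (gamma2, f22, f23)
    2: (1.2, 0.8, 0.3),         # v3: PFK, G6P -> FBP, FBP-activated (gamma3, f33, f35)
    3: (0.6, 0.9),              # v4: trehalase, Tre -> inGlc (gamma4, f44)
    4: (0.9, 0.6, 0.2),         # v5: Tre synthesis, G6P -> Tre (gamma5, f53, f54)
    5: (1.4, 0.2, 0.75),        # v6: lower glycolysis, FBP -> products (gamma6, f63, f65)
    6: (0.5, 0.5),              # v7: PPP drain from G6P (gamma7, f73)
    7: (0.4, 0.6),              # v8: leakage from FBP (gamma8, f85)
}

TREHALOSE_INITIAL_STATE = (10.0, 0.2, 1.0, 0.5, 0.8, 0.05, 0.0, 0.0)

TREHALOSE_NAMES = ["exGlc", "inGlc", "G6P", "Tre", "FBP", "EndProducts",
                   "PPP", "Leakage"]


def trehalose_model(params=None):
    """Simplified yeast trehalose pathway: 8 metabolites, 8 fluxes.

    Glucose is transported into the cell by Michaelis-Menten kinetics (v1);
    the extracellular balance is scaled by -V_in/V_ex.  Intracellular glucose
    (X2, unmeasured) is phosphorylated to G6P (v2), which feeds glycolysis
    (v3, FBP-activated), trehalose synthesis (v5) and the pentose phosphate
    pathway (v7).  Trehalose is recycled to glucose by trehalase (v4); FBP
    drains to end products (v6) and leakage (v8).  PPP and Leakage are pure
    sinks.  Measured set: {exGlc, G6P, Tre, FBP, EndProducts}.
    """
    truth = dict(TREHALOSE_TRUTH)
    if params:
        truth.update({int(k): tuple(v) for k, v in params.items()})
    r = V_IN / V_EX
    S = np.array([
        #   v1   v2   v3   v4   v5   v6   v7   v8
        [-r,   0.,  0.,  0.,  0.,  0.,  0.,  0.],   # X1 exGlc
        [1.,  -1.,  0.,  1.,  0.,  0.,  0.,  0.],   # X2 inGlc (unmeasured)
        [0.,   1., -1.,  0., -1.,  0., -1.,  0.],   # X3 G6P
        [0.,   0.,  0., -1.,  1.,  0.,  0.,  0.],   # X4 Tre
        [0.,   0.,  1.,  0.,  0., -1.,  0., -1.],   # X5 FBP
        [0.,   0.,  0.,  0.,  0.,  1.,  0.,  0.],   # X6 end products
        [0.,   0.,  0.,  0.,  0.,  0.,  1.,  0.],   # X7 PPP (sink)
        [0.,   0.,  0.,  0.,  0.,  0.,  0.,  1.],   # X8 leakage (sink)
    ])
    vmax, km = truth[0]
    fluxes = [
        MichaelisMentenFlux(vmax, km, substrate_index=0, name="v1",
                            bounds={"vmax": GAMMA_BOUNDS, "km": ORDER_BOUNDS}),
        _pl(truth[1][0], {1: truth[1][1], 2: truth[1][2]}, "v2"),
        _pl(truth[2][0], {2: truth[2][1], 4: truth[2][2]}, "v3"),
        _pl(truth[3][0], {3: truth[3][1]}, "v4"),
        _pl(truth[4][0], {2: truth[4][1], 3: truth[4][2]}, "v5"),
        _pl(truth[5][0], {2: truth[5][1], 4: truth[5][2]}, "v6"),
        _pl(truth[6][0], {2: truth[6][1]}, "v7"),
        _pl(truth[7][0], {4: truth[7][1]}, "v8"),
    ]
    measured = np.array([True, False, True, True, True, True, False, False])
    return KineticModel(S, fluxes, list(TREHALOSE_NAMES), measured)


def trehalose_fixture(params=None, noise_model=None, seed=None,
                      time_grid=None, initial_state=None):
    """Simulate the trehalose pathway; emit only the measured columns.

    ``noise_model`` is a mapping with key ``cv`` (relative noise level,
    default 5%, emulating moderately noisy in vivo NMR time courses).
    """
    model = trehalose_model(params)
    truth = model.true_parameters()
    cv = 0.05 if noise_model is None else float(noise_model.get("cv", 0.05))
    t = np.linspace(0.0, 30.0, 61) if time_grid is None else np.asarray(time_grid)
    x0 = np.asarray(TREHALOSE_INITIAL_STATE if initial_state is None
                    else initial_state, dtype=float)
    traj = simulate(model, initial_state=x0, time_grid=t, rtol=1e-8, atol=1e-10)
    rng = np.random.default_rng(seed)
    measured = model.measured_indices
    vals = traj[:, measured]
    noisy = _add_noise(vals, cv, rng) if cv > 0 else vals.copy()
    data = TimeSeriesData(t, noisy, [model.metabolite_names[i] for i in measured])
    return FixtureResult(model, truth, data, x0, traj, t)


def random_gma_fixture(m, n, sparsity=0.3, bounds=None, seed=None,
                       noise_cv=0.0, time_grid=None, max_retries=50):
    """Random sparse full-row-rank GMA model plus simulated (optionally noisy) data.

    The stoichiometry is a chain backbone (guaranteeing full row rank) plus
    random sparse extra columns; every flux depends on its substrate with a
    positive kinetic order, so trajectories stay positive.  Used by
    property-based tests.
    """
    if not (n > m >= 2):
        raise ValueError("need n > m >= 2")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 5.0, 25) if time_grid is None else np.asarray(time_grid)
    glo, ghi = (0.5, 2.0) if bounds is None else bounds.get("gamma", (0.5, 2.0))
    flo, fhi = (0.3, 1.2) if bounds is None else bounds.get("order", (0.3, 1.2))
    for _ in range(max_retries):
        S = np.zeros((m, n))
        # backbone: influx to X1, chain X1 -> ... -> Xm, efflux from Xm
        S[0, 0] = 1.0
        for i in range(m - 1):
            S[i, i + 1] = -1.0
            S[i + 1, i + 1] = 1.0
        S[m - 1, m] = -1.0
        for j in range(m + 1, n):
            src = rng.integers(0, m)
            S[src, j] = -1.0
            if rng.random() > sparsity:
                dst = rng.integers(0, m)
                if dst != src:
                    S[dst, j] = 1.0
        if np.linalg.matrix_rank(S) < m:
            continue
        fluxes = []
        for j in range(n):
            consumed = np.flatnonzero(S[:, j] < 0)
            dep = int(consumed[0]) if consumed.size else int(rng.integers(0, m))
            orders = {dep: float(rng.uniform(flo, fhi))}
            fluxes.append(_pl(float(rng.uniform(glo, ghi)), orders, f"v{j + 1}"))
        model = KineticModel(S, fluxes, [f"X{i + 1}" for i in range(m)])
        x0 = rng.uniform(0.5, 2.0, size=m)
        try:
            traj = simulate(model, initial_state=x0, time_grid=t,
                            rtol=1e-8, atol=1e-10)
        except Exception:
            continue
        if np.any(traj <= 0) or np.any(traj > 1e6):
            continue
        noisy = _add_noise(traj, noise_cv, rng) if noise_cv > 0 else traj.copy()
        data = TimeSeriesData(t, noisy, list(model.metabolite_names))
        return FixtureResult(model, model.true_parameters(), data, x0, traj, t)
    raise RuntimeError("could not draw a valid random GMA model")
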