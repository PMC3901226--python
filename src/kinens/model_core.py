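"""Kinetic ODE models of metabolic pathways.

A model is the mole balance ``dX/dt = S v(X, p)`` where ``X`` is the vector of
``m`` metabolite concentrations, ``v`` the vector of ``n`` reaction fluxes and
``S`` the ``m x n`` stoichiometric matrix.  Two flux kinetics are supported:

* power-law (generalized mass action, GMA): ``v_j = gamma_j * prod_i X_i^f_ji``
  where ``gamma_j > 0`` is the rate constant and ``f_ji`` the kinetic order of
  metabolite ``i`` in flux ``j`` (positive: substrate or activation, negative:
  inhibition);
* Michaelis-Menten: ``v = scale * vmax * X_s / (km + X_s)`` for a single
  substrate ``X_s``, with an optional dimensionless ``scale`` multiplier
  (e.g. a compartment volume ratio).

Each flux carries only its own dependency indices; the dense kinetic-order
matrix is never materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .exceptions import DimensionError, FluxDomainError, SimulationError

logger = logging.getLogger(__name__)

#: concentrations are clipped at this floor before exponentiation so that a
#: smoothed value that dips to zero cannot produce 0^negative.
CONCENTRATION_FLOOR = 1e-12


@dataclass(frozen=True)
class PowerLawFlux:
    """GMA flux ``gamma * prod_i X_i^f_i`` over a sparse dependency set.

    Parameters
    ----------
    rate_constant : float
        Multiplicative rate constant ``gamma`` (> 0).
    kinetic_orders : dict[int, float]
        Map metabolite index -> kinetic order ``f``.
    name : str
        Flux label, e.g. ``"v1"``.
    bounds : dict[str, tuple[float, float]], optional
        Per-parameter (lower, upper) bounds keyed by parameter name.
    """

    rate_constant: float
    kinetic_orders: dict = field(default_factory=dict)
    name: str = "v"
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.rate_constant > 0:
            raise ValueError(f"flux {self.name}: rate constant must be > 0")

    @property
    def dependencies(self):
        return frozenset(self.kinetic_orders)

    @property
    def n_params(self):
        return 1 + len(self.kinetic_orders)

    @property
    def param_names(self):
        return ["gamma"] + [f"f_{i}" for i in sorted(self.kinetic_orders)]

    def get_params(self):
        return (self.rate_constant,) + tuple(
            self.kinetic_orders[i] for i in sorted(self.kinetic_orders)
        )

    def with_params(self, params):
        params = tuple(float(p) for p in params)
        if len(params) != self.n_params:
            raise ValueError(
                f"flux {self.name}: expected {self.n_params} parameters, got {len(params)}"
            )
        orders = dict(zip(sorted(self.kinetic_orders), params[1:]))
        return replace(self, rate_constant=params[0], kinetic_orders=orders)

    def evaluate(self, concentrations):
        """Evaluate the flux at one state vector (length m)."""
        x = np.asarray(concentrations, dtype=float)
        v = self.rate_constant
        for i, f in self.kinetic_orders.items():
            xi = x[i]
            if xi <= 0:
                if f < 0 or f != int(f):
                    if xi < 0:
                        raise FluxDomainError(
                            f"flux {self.name}: negative concentration X[{i}]={xi} "
                            f"raised to non-integer power {f}"
                        )
                    logger.debug("flux %s: clipped X[%d]=%g to floor", self.name, i, xi)
                    xi = CONCENTRATION_FLOOR
            v *= xi**f
        return v

    def evaluate_profile(self, conc_matrix):
        """Vectorized evaluation over a K x m concentration matrix."""
        X = np.asarray(conc_matrix, dtype=float)
        idx = sorted(self.kinetic_orders)
        if not idx:
            return np.full(X.shape[0], self.rate_constant)
        f = np.array([self.kinetic_orders[i] for i in idx])
        cols = X[:, idx]
        if np.any(cols < 0):
            raise FluxDomainError(f"flux {self.name}: negative concentration in profile")
        cols = np.clip(cols, CONCENTRATION_FLOOR, None)
        return self.rate_constant * np.exp(np.log(cols) @ f)


@dataclass(frozen=True)
class MichaelisMentenFlux:
    """Michaelis-Menten flux ``scale * vmax * X / (km + X)``.

    ``vmax`` is the maximal rate (conc/time), ``km`` the half-saturation
    constant (conc) and ``scale`` a dimensionless multiplier (default 1),
    available for compartment volume ratios.
    """

    vmax: float
    km: float
    substrate_index: int
    scale: float = 1.0
    name: str = "v"
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.vmax > 0 and self.km > 0 and self.scale > 0):
            raise ValueError(f"flux {self.name}: vmax, km and scale must be > 0")

    @property
    def dependencies(self):
        return frozenset({self.substrate_index})

    @property
    def n_params(self):
        return 2

    @property
    def param_names(self):
        return ["vmax", "km"]

    def get_params(self):
        return (self.vmax, self.km)

    def with_params(self, params):
        params = tuple(float(p) for p in params)
        if len(params) != 2:
            raise ValueError(f"flux {self.name}: expected 2 parameters (vmax, km)")
        return replace(self, vmax=params[0], km=params[1])

    def evaluate(self, concentrations):
        x = float(np.asarray(concentrations, dtype=float)[self.substrate_index])
        x = max(x, 0.0)
        return self.scale * self.vmax * x / (self.km + x)

    def evaluate_profile(self, conc_matrix):
        x = np.clip(np.asarray(conc_matrix, dtype=float)[:, self.substrate_index], 0.0, None)
        return self.scale * self.vmax * x / (self.km + x)


@dataclass(frozen=True)
class ParameterVector:
    """Complete parameter assignment: flux index -> parameter tuple.

    ``independent`` optionally records which fluxes form the independent set
    ``p_I`` of a flux decomposition (the rest being the regressed ``p_D``).
    """

    values: dict
    independent: frozenset = None

    def __post_init__(self):
        object.__setattr__(
            self, "values", {int(j): tuple(map(float, p)) for j, p in self.values.items()}
        )
        if self.independent is not None:
            object.__setattr__(self, "independent", frozenset(self.independent))

    def __getitem__(self, flux_index):
        return self.values[flux_index]

    def flat(self, flux_indices=None):
        """Concatenate parameter tuples (sorted flux order by default)."""
        if flux_indices is None:
            flux_indices = sorted(self.values)
        return np.concatenate([np.asarray(self.values[j]) for j in flux_indices])


@dataclass
class KineticModel:
    """A stoichiometric matrix plus one kinetic definition per flux.

    Attributes
    ----------
    stoichiometry : (m, n) ndarray
        Stoichiometric matrix ``S``.
    fluxes : list
        ``n`` flux definitions (:class:`PowerLawFlux` / :class:`MichaelisMentenFlux`)
        holding their current (e.g. true or fitted) parameter values.
    metabolite_names : list[str]
    measured_mask : ndarray of bool, length m
        Which metabolites have time-series data.
    """

    stoichiometry: np.ndarray
    fluxes: list
    metabolite_names: list
    measured_mask: np.ndarray = None

    def __post_init__(self):
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        m, n = self.stoichiometry.shape
        if len(self.fluxes) != n:
            raise DimensionError(
                f"stoichiometry has {n} columns but {len(self.fluxes)} fluxes given"
            )
        if len(self.metabolite_names) != m:
            raise DimensionError(
                f"stoichiometry has {m} rows but {len(self.metabolite_names)} names given"
            )
        if self.measured_mask is None:
            self.measured_mask = np.ones(m, dtype=bool)
        self.measured_mask = np.asarray(self.measured_mask, dtype=bool)
        if self.measured_mask.shape != (m,):
            raise DimensionError("measured_mask length must equal the number of metabolites")
        for flux in self.fluxes:
            if any(i >= m or i < 0 for i in flux.dependencies):
                raise DimensionError(f"flux {flux.name} references metabolite index >= m")

    @property
    def n_metabolites(self):
        return self.stoichiometry.shape[0]

    @property
    def n_fluxes(self):
        return self.stoichiometry.shape[1]

    @property
    def measured_indices(self):
        return np.flatnonzero(self.measured_mask)

    @property
    def unmeasured_indices(self):
        return np.flatnonzero(~self.measured_mask)

    @property
    def n_measured(self):
        return int(self.measured_mask.sum())

    @property
    def flux_names(self):
        return [f.name for f in self.fluxes]

    def true_parameters(self):
        """ParameterVector of the parameter values stored on the flux objects."""
        return ParameterVector({j: f.get_params() for j, f in enumerate(self.fluxes)})

    def with_parameters(self, params: ParameterVector):
        """Return a copy whose fluxes carry the given parameter values."""
        fluxes = [
            f.with_params(params[j]) if j in params.values else f
            for j, f in enumerate(self.fluxes)
        ]
        return KineticModel(
            self.stoichiometry.copy(), fluxes, list(self.metabolite_names),
            self.measured_mask.copy(),
        )

    def parameter_bounds(self):
        """Per-flux list of (lower, upper) arrays taken from the flux ``bounds`` maps."""
        out = {}
        for j, f in enumerate(self.fluxes):
            lo, hi = [], []
            for pname in f.param_names:
                b = f.bounds.get(pname, (-np.inf, np.inf))
                lo.append(b[0])
                hi.append(b[1])
            out[j] = (np.array(lo), np.array(hi))
        return out


def evaluate_fluxes(model, concentrations, params=None):
    """Evaluate all fluxes ``v(X, p)`` at one state vector.

    If ``params`` is given the flux parameters are overridden; otherwise the
    parameters stored on the flux objects are used.
    """
    x = np.asarray(concentrations, dtype=float)
    if x.shape != (model.n_metabolites,):
        raise DimensionError(
            f"expected state of length {model.n_metabolites}, got shape {x.shape}"
        )
    mdl = model.with_parameters(params) if params is not None else model
    return np.array([f.evaluate(x) for f in mdl.fluxes])


def evaluate_flux_profiles(model, conc_matrix, params=None):
    """Vectorized ``v(X(t_k), p)`` over a K x m concentration matrix -> K x n."""
    X = np.asarray(conc_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_metabolites:
        raise DimensionError("concentration matrix must be K x m")
    mdl = model.with_parameters(params) if params is not None else model
    return np.column_stack([f.evaluate_profile(X) for f in mdl.fluxes])


def simulate(model, params=None, initial_state=None, time_grid=None,
             rtol=1e-6, atol=1e-8, method="LSODA", max_step=np.inf):
    """Integrate ``dX/dt = S v(X, p)`` on a time grid.

    Uses a stiff-capable integrator (GMA models are frequently stiff).
    Returns a K x m trajectory matrix.

    Raises
    ------
    SimulationError
        If integration fails or the state becomes non-finite; carries the
        last valid time reached.
    """
    from scipy.integrate import solve_ivp

    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing with >= 2 points")
    x0 = np.asarray(initial_state, dtype=float)
    if x0.shape != (model.n_metabolites,):
        raise DimensionError("initial_state length must equal the number of metabolites")
    if np.any(x0 < 0):
        raise ValueError("initial_state must be non-negative")
    mdl = model.with_parameters(params) if params is not None else model
    S = mdl.stoichiometry

    def rhs(_t, x):
        # overflow in a diverging member simulation surfaces as a non-finite
        # state and is reported as a SimulationError, not a warning storm
        with np.errstate(over="ignore", invalid="ignore"):
            v = np.array([f.evaluate(np.clip(x, 0.0, None)) for f in mdl.fluxes])
            return S @ v

    def blowup(_t, x):
        # terminal guard: stop grinding toward a finite-time singularity
        val = 1e12 - float(np.max(np.abs(x)))
        return val if np.isfinite(val) else -1.0

    blowup.terminal = True

    try:
        sol = solve_ivp(rhs, (t[0], t[-1]), x0, t_eval=t, method=method,
                        rtol=rtol, atol=atol, max_step=max_step, events=blowup)
    except (ValueError, RuntimeError, FloatingPointError) as exc:
        raise SimulationError(f"integration failed: {exc}") from exc
    if not sol.success or sol.y.shape[1] != len(t) or not np.all(np.isfinite(sol.y)):
        last = sol.t[-1] if sol.t.size else None
        raise SimulationError(
            f"integration failed: {sol.message}", last_valid_time=last
        )
    return sol.y.T


def mass_balance_residual(model, slopes, flux_values):
    """Residual ``Xdot(t_k) - S v(t_k)`` per time point and metabolite.

    ``slopes`` is K x m, ``flux_values`` K x n; returns K x m.
    """
    slopes = np.atleast_2d(np.asarray(slopes, dtype=float))
    flux_values = np.atleast_2d(np.asarray(flux_values, dtype=float))
    m, n = model.stoichiometry.shape
    if slopes.shape[1] != m or flux_values.shape[1] != n or \
            slopes.shape[0] != flux_values.shape[0]:
        raise DimensionError(
            f"slopes {slopes.shape} / flux values {flux_values.shape} inconsistent "
            f"with S of shape {(m, n)}"
        )
    return slopes - flux_values @ model.stoichiometry.T


# ---------------------------------------------------------------------------
# model definition file (YAML) round-trip
# ---------------------------------------------------------------------------

def _flux_to_dict(flux):
    if isinstance(flux, PowerLawFlux):
        d = {
            "type": "powerlaw",
            "name": flux.name,
            "rate_constant": float(flux.rate_constant),
            "kinetic_orders": {int(i): float(f) for i, f in flux.kinetic_orders.items()},
        }
    elif isinstance(flux, MichaelisMentenFlux):
        d = {
            "type": "mm",
            "name": flux.name,
            "vmax": float(flux.vmax),
            "km": float(flux.km),
            "substrate_index": int(flux.substrate_index),
            "scale": float(flux.scale),
        }
    else:  # pragma: no cover - guarded by construction
        raise TypeError(f"unknown flux type {type(flux)}")
    if flux.bounds:
        d["bounds"] = {k: [float(v[0]), float(v[1])] for k, v in flux.bounds.items()}
    return d


def _flux_from_dict(d):
    bounds = {k: (float(v[0]), float(v[1])) for k, v in d.get("bounds", {}).items()}
    if d["type"] == "powerlaw":
        return PowerLawFlux(
            rate_constant=float(d["rate_constant"]),
            kinetic_orders={int(i): float(f) for i, f in d["kinetic_orders"].items()},
            name=d.get("name", "v"),
            bounds=bounds,
        )
    if d["type"] == "mm":
        return MichaelisMentenFlux(
            vmax=float(d["vmax"]), km=float(d["km"]),
            substrate_index=int(d["substrate_index"]),
            scale=float(d.get("scale", 1.0)),
            name=d.get("name", "v"), bounds=bounds,
        )
    raise ValueError(f"unknown flux type {d['type']!r}")


def model_to_dict(model):
    return {
        "stoichiometry": [[float(x) for x in row] for row in model.stoichiometry],
        "metabolite_names": list(model.metabolite_names),
        "measured": [bool(b) for b in model.measured_mask],
        "fluxes": [_flux_to_dict(f) for f in model.fluxes],
    }


def model_from_dict(d):
    return KineticModel(
        stoichiometry=np.array(d["stoichiometry"], dtype=float),
        fluxes=[_flux_from_dict(fd) for fd in d["fluxes"]],
        metabolite_names=list(d["metabolite_names"]),
        measured_mask=np.array(d["measured"], dtype=bool),
    )


def save_model(model, path):
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
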