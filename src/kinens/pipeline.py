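"""End-to-end ensemble construction and summaries.

The full workflow: smooth the data and estimate slopes; reduce away
unmeasured metabolites; choose the independent fluxes; find an initial
viable point by minimizing the flux error; set the statistical error bound
by Monte Carlo; explore the viable independent-parameter space (OEAMC then
MEBS); estimate the viable volume from the ellipsoid cover; and report
ensemble-level error ranges.  One master seed fans out to per-stage seeds,
so two runs with identical seed and configuration give identical ensembles.

The ensemble stores only the independent parameters of each member; the
dependent parameters are regenerated on demand by per-flux regression,
which keeps the ensemble representation compact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decomposition import choose_independent_fluxes, reduce_unmeasured
from .exceptions import KinensError
from .hyperspace import (ExplorationConfig, estimate_volume, mebs, oeamc)
from .preprocessing import DEFAULT_CANDIDATES, TimeSeriesData, smooth_dataset
from .viability import (Bounds, FluxErrorObjective, OptimizerConfig, check_viable,
                        estimate_error_bound, find_initial_point, phi_C, phi_S)


def initial_box_volume(bounds, dec):
    """Volume of the initial independent-parameter box: prod of (U - L).

    Only the independent parameters contribute, which is what makes the
    viable-to-initial volume ratio meaningful.
    """
    lo, hi = bounds.box_for(dec)
    widths = hi - lo
    if np.any(widths <= 0):
        raise ValueError("zero-width parameter range in the independent box")
    return float(np.prod(widths))


@dataclass
class EnsembleConfig:
    """All knobs of the ensemble pipeline, with the case-study defaults."""

    seed: int = 0
    smoother_candidates: tuple = DEFAULT_CANDIDATES
    n_mc: int = 100
    confidence_level: float = 0.95
    flux_upper: float = 5e5
    phi_bound: float = None          # override: skip the Monte Carlo bound
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    bound_optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(n_starts=3, maxiter=250))
    exploration: dict = field(default_factory=dict)
    volume_samples: int = 20000
    error_sample_size: int = 50      # members used for phi_S / phi_C ranges
    drop_endpoint_slopes: bool = True  # incremental stage uses interior points
    phi_c_outlier_threshold: float = 100.0
    preferred_independent: tuple = None
    unmeasured_initial: dict = None
    initial_state: np.ndarray = None  # full-model state for phi_C simulation


@dataclass
class Ensemble:
    """The viable-model ensemble and its summary statistics."""

    members: np.ndarray              # N x d independent-parameter vectors
    member_phi: np.ndarray           # phi_R per member
    dec: object
    cover: list
    V_ci: float
    V_ev: float
    V_ev_stderr: float
    phi_bound: float
    slope_error_range: tuple = None
    concentration_error_range: tuple = None
    error_sample_indices: np.ndarray = None
    phi_S_values: np.ndarray = None
    phi_C_values: np.ndarray = None
    recipes: list = None
    profiles: object = None
    data: TimeSeriesData = None
    initial_state: np.ndarray = None
    config: EnsembleConfig = None
    stage_log: dict = field(default_factory=dict)

    @property
    def ratio(self):
        return self.V_ev / self.V_ci

    def __len__(self):
        return len(self.members)

    def member_parameters(self, index):
        """Regenerate the full parameter vector of one member."""
        obj = FluxErrorObjective(
            self.dec, self.profiles,
            bounds=None, recipes=self.recipes,
            unmeasured_initial=self.config.unmeasured_initial
            if self.config else None)
        obj.flux_upper = self.config.flux_upper if self.config else np.inf
        fit = obj.regress(self.members[index])
        if not fit.ok:
            raise KinensError(
                f"member {index} no longer regresses cleanly: {fit.signal}")
        return fit.params, fit

    def members_frame(self):
        """Members as a DataFrame: independent columns plus regenerated p_D."""
        from .flux_regression import independent_parameter_layout

        layout = independent_parameter_layout(self.dec)
        cols = {f"{self.dec.model.fluxes[j].name}.{name}": self.members[:, k]
                for k, (j, name) in enumerate(layout)}
        df = pd.DataFrame(cols)
        df["phi_R"] = self.member_phi
        return df


def _align_data(model, data):
    """Reorder/select data columns to the model's measured metabolite order."""
    wanted = [model.metabolite_names[i] for i in model.measured_indices]
    missing = [n for n in wanted if n not in data.metabolite_names]
    if missing:
        raise KinensError(f"data lacks measured metabolite columns: {missing}")
    cols = [data.metabolite_names.index(n) for n in wanted]
    return TimeSeriesData(data.times, data.concentrations[:, cols], wanted)


def build_ensemble(model, data, bounds=None, config=None):
    """Run the full ensemble workflow; returns an :class:`Ensemble`.

    Stage errors propagate with a stage tag prefixed to the message.
    """
    config = config or EnsembleConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    stage_seed = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    log = {}

    def stage(name, fn):
        try:
            out = fn()
        except KinensError as exc:
            raise KinensError(f"[{name}] {exc}") from exc
        log[name] = "ok"
        return out

    red = stage("reduce", lambda: reduce_unmeasured(model))
    rmodel = red.model
    data_m = stage("align", lambda: _align_data(rmodel, data))
    profiles = stage("smooth", lambda: smooth_dataset(
        data_m, config.smoother_candidates))
    if config.drop_endpoint_slopes:
        from .preprocessing import interior_profiles
        profiles = interior_profiles(profiles)
    dec = stage("decompose", lambda: choose_independent_fluxes(
        rmodel, preferred=config.preferred_independent))
    if bounds is None:
        bounds = Bounds.from_model(rmodel, flux_upper=config.flux_upper)
    ctx = dict(recipes=red.recipes, unmeasured_initial=config.unmeasured_initial)

    p0, phi0 = stage("fit-init", lambda: find_initial_point(
        dec, profiles, bounds, optimizer_config=config.optimizer,
        seed=stage_seed[0], **ctx))
    if config.phi_bound is not None:
        phi_bound = float(config.phi_bound)
    else:
        phi_bound = stage("bound", lambda: estimate_error_bound(
            data_m, dec, bounds, n_mc=config.n_mc,
            level=config.confidence_level, seed=stage_seed[1],
            candidates=config.smoother_candidates,
            optimizer_config=config.bound_optimizer,
            drop_endpoints=config.drop_endpoint_slopes, **ctx))
    if phi0 > phi_bound:
        raise KinensError(
            f"[oeamc] initial point infeasible: minimum phi_R {phi0:.4g} "
            f"exceeds the bound {phi_bound:.4g}; the ensemble would be empty")

    def viability(p):
        return check_viable(p, dec, profiles, bounds, phi_bound, **ctx)

    box = bounds.box_for(dec)
    exp_cfg = ExplorationConfig(seed=stage_seed[2], **config.exploration)
    coarse = stage("oeamc", lambda: oeamc(p0, viability, box, exp_cfg))
    fine, cover = stage("mebs", lambda: mebs(
        coarse, viability, replace(exp_cfg, seed=stage_seed[3]), bounds_box=box))
    V_ci = initial_box_volume(bounds, dec)
    V_ev, se = stage("volume", lambda: estimate_volume(
        cover, config.volume_samples, seed=stage_seed[4], box=box))

    members = fine.points
    obj = FluxErrorObjective(dec, profiles, bounds, **ctx)
    member_phi = np.array([obj.phi(p) for p in members])

    ens = Ensemble(members=members, member_phi=member_phi, dec=dec, cover=cover,
                   V_ci=V_ci, V_ev=V_ev, V_ev_stderr=se, phi_bound=phi_bound,
                   recipes=red.recipes, profiles=profiles, data=data_m,
                   initial_state=config.initial_state, config=config,
                   stage_log=log)
    _attach_error_ranges(ens, rmodel, stage_seed[5])
    return ens


def _attach_error_ranges(ens, model, seed):
    """Per-member slope and concentration errors over a seeded member sample."""
    n = len(ens.members)
    k = ens.config.error_sample_size
    rng = np.random.default_rng(seed)
    idx = np.arange(n) if (k is None or n <= k) else \
        np.sort(rng.choice(n, size=k, replace=False))
    phi_s_vals, phi_c_vals = [], []
    for i in idx:
        try:
            params, fit = ens.member_parameters(i)
        except KinensError:
            phi_s_vals.append(np.inf)
            phi_c_vals.append(np.inf)
            continue
        phi_s_vals.append(phi_S(params, model, ens.profiles,
                                concentrations=fit.concentrations))
        if ens.initial_state is not None:
            phi_c_vals.append(phi_C(params, model, ens.data, ens.initial_state))
        else:
            phi_c_vals.append(np.nan)
    ens.error_sample_indices = idx
    ens.phi_S_values = np.asarray(phi_s_vals)
    ens.phi_C_values = np.asarray(phi_c_vals)
    finite_s = ens.phi_S_values[np.isfinite(ens.phi_S_values)]
    ens.slope_error_range = (float(finite_s.min()), float(finite_s.max())) \
        if finite_s.size else None
    finite_c = ens.phi_C_values[np.isfinite(ens.phi_C_values)]
    ens.concentration_error_range = (float(finite_c.min()), float(finite_c.max())) \
        if finite_c.size else None


def select_members(ensemble, k=5, seed=None):
    """Seeded random member subset (e.g. five models for trajectory plots)."""
    rng = np.random.default_rng(seed)
    n = len(ensemble)
    idx = rng.choice(n, size=min(k, n), replace=False)
    return np.sort(idx)


def validate_ensemble(ensemble, model, held_out):
    """Concentration errors of every member on held-out datasets.

    ``held_out`` is a list of ``(TimeSeriesData, initial_state)`` pairs with
    different initial conditions; each member is simulated from each initial
    state.  Returns a DataFrame (member index x dataset) of phi_C values;
    simulation failures appear as +inf.
    """
    rows = {}
    datasets = [( _align_data(model, d), np.asarray(x0, dtype=float))
                for d, x0 in held_out]
    for i in range(len(ensemble)):
        try:
            params, _ = ensemble.member_parameters(i)
        except KinensError:
            rows[i] = [np.inf] * len(datasets)
            continue
        rows[i] = [phi_C(params, model, d, x0) for d, x0 in datasets]
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"dataset_{j}" for j in range(len(datasets))])
    df.index.name = "member"
    return df


def summarize(ensemble):
    """Ensemble summary mirroring the case-study report tables."""
    if len(ensemble) == 0:
        raise ValueError("cannot summarize an empty ensemble")
    thr = ensemble.config.phi_c_outlier_threshold if ensemble.config else 100.0
    finite_c = ensemble.phi_C_values[np.isfinite(ensemble.phi_C_values)] \
        if ensemble.phi_C_values is not None else np.array([])
    n_outliers = int(np.sum(finite_c > thr)) if finite_c.size else 0
    return {
        "n_members": len(ensemble),
        "initial_volume_V_ci": ensemble.V_ci,
        "viable_volume_V_ev": ensemble.V_ev,
        "viable_volume_stderr": ensemble.V_ev_stderr,
        "volume_ratio": ensemble.ratio,
        "phi_bound": ensemble.phi_bound,
        "slope_error_range": ensemble.slope_error_range,
        "concentration_error_range": ensemble.concentration_error_range,
        "n_concentration_outliers": n_outliers,
        "outlier_threshold": thr,
        "error_sample_size": int(len(ensemble.error_sample_indices))
        if ensemble.error_sample_indices is not None else 0,
    }
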