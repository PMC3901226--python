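"""Per-flux regression of dependent kinetic parameters from dynamic fluxes.

Once the dependent flux values ``v_D(t_k)`` are fixed by the mass balance,
each dependent flux is regressed separately:

* power-law fluxes by log-linear least squares,
  ``ln v(t_k) = ln gamma + sum_i f_i ln X_i(t_k)``;
* Michaelis-Menten fluxes by the linearization
  ``v (km + X) = vmax X``, i.e. regressing the element-wise product
  ``[X . v]`` on ``{X, -v}`` to read off ``(vmax, km)``.

Negative dynamic flux values are a *nonviability signal* (the candidate
independent parameters produce a biologically impossible flux), not an
exception; they are reported through the returned result object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .decomposition import assemble_flux_matrix, compute_dependent_fluxes
from .exceptions import FluxDomainError, RankDeficiencyError
from .model_core import (MichaelisMentenFlux, ParameterVector, PowerLawFlux)
from .preprocessing import SMOOTHED_VALUE_FLOOR

#: relative singular-value cutoff declaring a design matrix rank deficient.
RANK_RCOND = 1e-10


@dataclass
class FluxFit:
    """Per-flux regression outcome."""

    params: tuple
    rss: float                 # residual sum of squares (log space for power laws)
    rank: int
    space: str                 # "log" or "linear"
    bound_violations: list = field(default_factory=list)
    time_mask: np.ndarray = None  # points used (None = all)


def _check_bounds(params, names, bounds):
    violations = []
    for value, name in zip(params, names):
        if name in bounds:
            lo, hi = bounds[name]
            if not (lo <= value <= hi):
                violations.append({"param": name, "value": float(value),
                                   "bounds": (float(lo), float(hi))})
    return violations


def fit_powerlaw_flux(flux_values, concentrations, bounds=None, param_names=None):
    """Log-linear least squares for ``v = gamma * prod_i X_i^f_i``.

    ``concentrations`` is K x d with one column per metabolite the flux
    depends on.  Bound violations are reported in the result, never clipped.

    Raises
    ------
    FluxDomainError
        If any flux value or concentration is non-positive (signals a
        nonviable independent-parameter choice upstream).
    RankDeficiencyError
        If the log-concentration profiles are collinear.
    """
    v = np.asarray(flux_values, dtype=float)
    X = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if X.shape[0] != len(v):
        X = X.T
    K, d = X.shape
    if np.any(v <= 0):
        raise FluxDomainError("non-positive flux values: log regression undefined")
    if np.any(X <= 0):
        raise FluxDomainError("non-positive concentrations: log regression undefined")
    if K <= d + 1:
        raise RankDeficiencyError(
            f"{K} time points cannot determine {d + 1} power-law parameters"
        )
    A = np.column_stack([np.ones(K), np.log(X)])
    rank = np.linalg.matrix_rank(A, tol=RANK_RCOND * np.abs(A).max() * max(A.shape))
    if rank < d + 1:
        raise RankDeficiencyError(
            "collinear log-concentration profiles: power-law parameters not "
            "uniquely identifiable"
        )
    coef, res, *_ = np.linalg.lstsq(A, np.log(v), rcond=None)
    rss = float(res[0]) if res.size else float(np.sum((A @ coef - np.log(v)) ** 2))
    params = (float(np.exp(coef[0])),) + tuple(float(c) for c in coef[1:])
    names = param_names or (["gamma"] + [f"f_{i}" for i in range(d)])
    violations = _check_bounds(params, names, bounds or {})
    return FluxFit(params, rss, int(rank), "log", violations)


def fit_mm_flux(flux_values, substrate, bounds=None, nonneg_fallback=False):
    """Linearized Michaelis-Menten fit: regress ``[X . v]`` on ``{X, -v}``.

    Exact on noise-free saturation data.  Negative parameter estimates are
    flagged via bound violations with pseudo-bounds (0, inf) so callers can
    treat them as nonviable.  With ``nonneg_fallback=True`` a negative
    linearized solution triggers a bounded nonlinear least-squares refit
    (parameters constrained positive), used where a usable curve is needed
    even when the unconstrained linearization leaves the domain.
    """
    v = np.asarray(flux_values, dtype=float)
    X = np.asarray(substrate, dtype=float)
    if len(v) < 3:
        raise RankDeficiencyError("need at least 3 points for an MM fit")
    if np.any(X <= 0):
        raise FluxDomainError("non-positive substrate concentrations")
    A = np.column_stack([X, -v])
    rank = np.linalg.matrix_rank(A, tol=RANK_RCOND * np.abs(A).max() * max(A.shape))
    if rank < 2:
        raise RankDeficiencyError(
            "degenerate MM design (e.g. constant substrate profile)"
        )
    b = X * v
    coef, res, *_ = np.linalg.lstsq(A, b, rcond=None)
    vmax, km = float(coef[0]), float(coef[1])
    rss = float(res[0]) if res.size else float(np.sum((A @ coef - b) ** 2))
    space = "linear"
    if nonneg_fallback and (vmax <= 0 or km <= 0):
        from scipy.optimize import least_squares

        x0 = (max(vmax, float(np.max(np.abs(v)))), max(km, 1e-3))
        sol = least_squares(
            lambda p: p[0] * X / (p[1] + X) - v, x0,
            bounds=([1e-9, 1e-9], [np.inf, np.inf]))
        vmax, km = float(sol.x[0]), float(sol.x[1])
        rss = float(np.sum(sol.fun**2))
        space = "nonlinear"
    violations = _check_bounds((vmax, km), ["vmax", "km"], bounds or {})
    for name, value in (("vmax", vmax), ("km", km)):
        if value <= 0:
            violations.append({"param": name, "value": value,
                               "bounds": (0.0, np.inf)})
    return FluxFit((vmax, km), rss, int(rank), space, violations)


@dataclass
class NonviableSignal:
    """Why a candidate p_I cannot yield a viable model (no parameters returned)."""

    kind: str               # "positivity" | "flux_bound" | "domain"
    flux_index: int = None
    time_index: int = None
    value: float = None
    magnitude: float = 1.0  # total constraint violation, for graded penalties
    detail: str = ""


@dataclass
class DependentFit:
    """Result of regressing all dependent parameters for one p_I candidate."""

    ok: bool
    params: ParameterVector = None
    flux_fits: dict = None            # flux index -> FluxFit
    v_independent: np.ndarray = None  # K x |I|
    v_dependent: np.ndarray = None    # K x |D| mass-balance targets
    concentrations: np.ndarray = None  # K x m incl. reconstructed unmeasured
    signal: NonviableSignal = None


def independent_parameter_layout(dec):
    """(flux index, parameter name) pairs in flattened p_I order."""
    layout = []
    for j in dec.independent_indices:
        for name in dec.model.fluxes[j].param_names:
            layout.append((j, name))
    return layout


def pI_to_dict(dec, p_flat):
    """Split a flat p_I vector into {flux index: parameter tuple}."""
    p_flat = np.asarray(p_flat, dtype=float)
    out, pos = {}, 0
    for j in dec.independent_indices:
        k = dec.model.fluxes[j].n_params
        out[j] = tuple(p_flat[pos: pos + k])
        pos += k
    if pos != len(p_flat):
        raise ValueError(f"expected {pos} independent parameters, got {len(p_flat)}")
    return out


def pI_to_flat(dec, p_dict):
    return np.concatenate([np.asarray(p_dict[j], dtype=float)
                           for j in dec.independent_indices])


def _full_concentrations(dec, profiles, recipes, unmeasured_initial, flux_matrix):
    """K x m concentration matrix with unmeasured columns reconstructed.

    Each eliminable unmeasured profile is the time integral (trapezoid) of
    its slope recipe, anchored at the supplied initial value.
    """
    model = dec.model
    K = len(profiles.times)
    conc = np.full((K, model.n_metabolites), np.nan)
    conc[:, model.measured_indices] = profiles.fitted_values
    for recipe in recipes or []:
        u = recipe.metabolite_index
        x0 = (unmeasured_initial or {}).get(u)
        if x0 is None:
            x0 = (unmeasured_initial or {}).get(model.metabolite_names[u])
        if x0 is None:
            raise ValueError(
                f"initial value for unmeasured metabolite "
                f"{model.metabolite_names[u]} required to reconstruct its profile"
            )
        slopes_u = recipe.apply(profiles.slope_estimates, flux_matrix,
                                model.measured_indices)
        prof = x0 + cumulative_trapezoid(slopes_u, profiles.times, initial=0.0)
        conc[:, u] = np.clip(prof, SMOOTHED_VALUE_FLOOR, None)
    return conc


def regress_dependent(p_I, dec, profiles, recipes=None, unmeasured_initial=None,
                      flux_upper=np.inf, positivity="strict",
                      min_positive_fraction=0.8):
    """Evaluate v_I, compute the dependent dynamic fluxes, fit each dependent flux.

    Parameters
    ----------
    p_I : dict or array
        Independent parameters, either {flux index: tuple} or flattened in
        the order of ``dec.independent_indices``.
    dec : FluxDecomposition
    profiles : SmoothedProfiles
        Measured-metabolite smoothing output (column order must match the
        model's measured metabolites).
    recipes : list of UnmeasuredRecipe, optional
        Slope recipes for unmeasured metabolites appearing in dependent
        fluxes (from :func:`kinens.decomposition.reduce_unmeasured`).
    unmeasured_initial : dict, optional
        Initial values (by index or name) anchoring reconstructed profiles.
    flux_upper : float
        Cap above which any dynamic flux value is a nonviability signal.
    positivity : {"strict", "mask"}
        "strict": any non-positive dependent flux value is a nonviability
        signal.  "mask": each dependent flux is fitted on its positive-target
        time points only (nonviable only if fewer than
        ``min_positive_fraction`` of the points are positive); used by the
        Monte Carlo error-bound replicates, where a few noise-flipped slope
        signs at the trajectory tails should not void the whole replicate.

    Returns
    -------
    DependentFit
        ``ok=False`` with a :class:`NonviableSignal` when any dependent flux
        value is non-positive (or any flux exceeds ``flux_upper``); no
        parameters are returned in that case.
    """
    model = dec.model
    if not isinstance(p_I, dict):
        p_I = pI_to_dict(dec, p_I)
    K = len(profiles.times)
    X_M = profiles.fitted_values

    # independent flux profiles v_I(X_M(t_k), p_I)
    conc_measured = np.full((K, model.n_metabolites), np.nan)
    conc_measured[:, model.measured_indices] = X_M
    v_I = np.empty((K, len(dec.independent_indices)))
    for col, j in enumerate(dec.independent_indices):
        try:
            flux = model.fluxes[j].with_params(p_I[j])
            v_I[:, col] = flux.evaluate_profile(conc_measured)
        except (ValueError, FluxDomainError) as exc:
            # e.g. a rate constant clipped to exactly 0 at the box boundary
            return DependentFit(False, signal=NonviableSignal(
                "domain", flux_index=j, detail=str(exc)))

    v_D = compute_dependent_fluxes(dec, profiles.slope_estimates, v_I)

    # positivity of dependent fluxes and the global flux cap
    if np.any(v_D <= 0):
        frac_positive = np.mean(v_D > 0, axis=0)
        strict_fail = positivity == "strict" or \
            np.any(frac_positive < min_positive_fraction)
        if strict_fail:
            neg_total = float(np.sum(np.clip(-v_D, 0.0, None)))
            k, col = map(int, np.argwhere(v_D <= 0)[0])
            j = dec.dependent_indices[col]
            return DependentFit(False, signal=NonviableSignal(
                "positivity", flux_index=j, time_index=k,
                value=float(v_D[k, col]), magnitude=neg_total,
                detail=f"dependent flux {model.fluxes[j].name} non-positive "
                       f"at t index {k}"))
    all_v = assemble_flux_matrix(dec, v_I, v_D)
    if np.any(all_v > flux_upper):
        excess = float(np.sum(np.clip(all_v - flux_upper, 0.0, None)))
        k, j = map(int, np.argwhere(all_v > flux_upper)[0])
        return DependentFit(False, signal=NonviableSignal(
            "flux_bound", flux_index=j, time_index=k, value=float(all_v[k, j]),
            magnitude=excess / max(flux_upper, 1.0),
            detail=f"flux {model.fluxes[j].name} exceeds cap at t index {k}"))

    conc = _full_concentrations(dec, profiles, recipes, unmeasured_initial, all_v)

    if not dec.dependent_indices:
        return DependentFit(True, params=ParameterVector(
            dict(p_I), independent=frozenset(dec.independent_indices)),
            flux_fits={}, v_independent=v_I, v_dependent=v_D, concentrations=conc)

    fits = {}
    values = dict(p_I)
    for col, j in enumerate(dec.dependent_indices):
        flux = model.fluxes[j]
        target = v_D[:, col]
        mask = None
        if positivity == "mask" and np.any(target <= 0):
            mask = target > 0
        t_sel = slice(None) if mask is None else mask
        try:
            if isinstance(flux, PowerLawFlux):
                deps = sorted(flux.kinetic_orders)
                fit = fit_powerlaw_flux(
                    target[t_sel], conc[t_sel][:, deps], bounds=flux.bounds,
                    param_names=flux.param_names)
            elif isinstance(flux, MichaelisMentenFlux):
                fit = fit_mm_flux(target[t_sel] / flux.scale,
                                  conc[t_sel][:, flux.substrate_index],
                                  bounds=flux.bounds,
                                  nonneg_fallback=(positivity == "mask"))
            else:  # pragma: no cover
                raise TypeError(f"unknown flux type {type(flux)}")
        except FluxDomainError as exc:
            return DependentFit(False, signal=NonviableSignal(
                "domain", flux_index=j, detail=str(exc)))
        fit.time_mask = mask
        fits[j] = fit
        values[j] = fit.params
    params = ParameterVector(values, independent=frozenset(dec.independent_indices))
    return DependentFit(True, params=params, flux_fits=fits, v_independent=v_I,
                        v_dependent=v_D, concentrations=conc)
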