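"""Independent/dependent flux decomposition of the mass balance.

With ``n`` fluxes and ``m*`` measured metabolites, the mass balance
``dX_M/dt (t_k) = S_M v(t_k)`` leaves ``n_DOF = n - m*`` degrees of freedom:
a subset ``I`` of ``n_DOF`` fluxes (the independent fluxes) must be specified,
after which the remaining (dependent) fluxes follow from

    v_D(t_k) = S_DM^{-1} (dX_M/dt (t_k) - S_IM v_I(t_k))

provided the square submatrix ``S_DM`` is invertible.  Unmeasured metabolites
are handled by (i) dropping pure sinks (metabolites no flux depends on) and
(ii) eliminating the remaining unmeasured balances through a linear recipe
that expresses each unmeasured slope as a combination of measured slopes and
computable flux values (an overall mass balance around the pathway).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .exceptions import DimensionError, StructuralError
from .model_core import KineticModel

#: submatrices with condition number above this cap are treated as singular.
CONDITION_CAP = 1e8


def degrees_of_freedom(model):
    """Number of independent fluxes: ``n`` fluxes minus measured metabolites."""
    return model.n_fluxes - model.n_measured


@dataclass
class FluxDecomposition:
    """A chosen split of fluxes into independent (``I``) and dependent (``D``) sets."""

    model: KineticModel
    independent_indices: tuple
    dependent_indices: tuple
    S_I: np.ndarray = field(init=False)    # full rows
    S_D: np.ndarray = field(init=False)
    S_IM: np.ndarray = field(init=False)   # measured rows
    S_DM: np.ndarray = field(init=False)
    condition_number: float = field(init=False)

    def __post_init__(self):
        self.independent_indices = tuple(int(i) for i in self.independent_indices)
        self.dependent_indices = tuple(int(i) for i in self.dependent_indices)
        I, D = set(self.independent_indices), set(self.dependent_indices)
        if I & D or I | D != set(range(self.model.n_fluxes)):
            raise StructuralError("I and D must partition the flux set")
        S = self.model.stoichiometry
        rows = self.model.measured_indices
        self.S_I = S[:, self.independent_indices]
        self.S_D = S[:, self.dependent_indices]
        self.S_IM = S[np.ix_(rows, self.independent_indices)]
        self.S_DM = S[np.ix_(rows, self.dependent_indices)]
        if self.S_DM.shape[0] != self.S_DM.shape[1]:
            raise StructuralError(
                f"S_D over measured rows is {self.S_DM.shape}, not square; "
                f"|I| must equal n - m*"
            )
        self.condition_number = 1.0 if self.S_DM.size == 0 else \
            float(np.linalg.cond(self.S_DM))
        if not np.isfinite(self.condition_number) or \
                self.condition_number > CONDITION_CAP:
            raise StructuralError(
                f"S_D is numerically singular (condition {self.condition_number:.3g})"
            )

    @property
    def n_independent_params(self):
        return sum(self.model.fluxes[j].n_params for j in self.independent_indices)

    def report(self):
        return {
            "independent": [self.model.fluxes[j].name for j in self.independent_indices],
            "dependent": [self.model.fluxes[j].name for j in self.dependent_indices],
            "n_independent_params": self.n_independent_params,
            "condition_number": self.condition_number,
        }


def _candidate_valid(model, I, cond_cap):
    """Return condition number of S_DM for independent set I, or None if invalid."""
    measured = set(model.measured_indices.tolist())
    for j in I:
        if not model.fluxes[j].dependencies <= measured:
            return None  # v_I(X_M, p_I) would need unmeasured concentrations
    rows = model.measured_indices
    D = [j for j in range(model.n_fluxes) if j not in I]
    S_DM = model.stoichiometry[np.ix_(rows, D)]
    if S_DM.shape[0] != S_DM.shape[1]:
        return None
    if S_DM.size == 0:
        return 1.0
    cond = np.linalg.cond(S_DM)
    if not np.isfinite(cond) or cond > cond_cap:
        return None
    return float(cond)


def choose_independent_fluxes(model, preferred=None, cond_cap=CONDITION_CAP):
    """Select the independent flux set.

    If ``preferred`` is given and valid it is used.  Otherwise all subsets of
    size ``n_DOF`` are enumerated and the selection minimizes, in order:
    (1) invertibility of ``S_DM`` (condition number below ``cond_cap``) with
    independent fluxes depending only on measured metabolites, (2) the total
    number of independent parameters ``|p_I|``, (3) lexicographically
    smallest tuple of flux *names* (a deterministic tie-break that is
    invariant under reordering of the flux list).
    """
    ndof = degrees_of_freedom(model)
    if ndof < 0:
        raise StructuralError("more measured metabolites than fluxes")
    all_fluxes = range(model.n_fluxes)
    if preferred is not None:
        I = tuple(sorted(int(j) for j in preferred))
        if len(I) != ndof:
            raise StructuralError(
                f"preferred independent set has size {len(I)}, expected n_DOF={ndof}"
            )
        if _candidate_valid(model, I, cond_cap) is None:
            raise StructuralError(
                f"preferred independent set {I} gives a singular or invalid S_D"
            )
        D = tuple(j for j in all_fluxes if j not in I)
        return FluxDecomposition(model, I, D)

    best = None
    for I in combinations(all_fluxes, ndof):
        if _candidate_valid(model, I, cond_cap) is None:
            continue
        n_pI = sum(model.fluxes[j].n_params for j in I)
        key = (n_pI, tuple(sorted(model.fluxes[j].name for j in I)), I)
        if best is None or key < best[0]:
            best = (key, I)
    if best is None:
        raise StructuralError(
            "no independent flux subset yields an invertible S_D; consider a "
            "pseudo-inverse formulation or different measurements"
        )
    I = best[1]
    D = tuple(j for j in all_fluxes if j not in I)
    return FluxDecomposition(model, I, D)


def compute_dependent_fluxes(dec, slopes, independent_flux_values):
    """Dependent flux values ``v_D(t_k)`` from measured slopes and ``v_I(t_k)``.

    ``slopes`` is K x m* (measured metabolites), ``independent_flux_values``
    K x |I|; returns K x |D| in the order of ``dec.dependent_indices``.
    """
    slopes = np.atleast_2d(np.asarray(slopes, dtype=float))
    v_I = np.atleast_2d(np.asarray(independent_flux_values, dtype=float))
    m_star = dec.S_DM.shape[0]
    if slopes.shape[1] != m_star or v_I.shape[1] != len(dec.independent_indices) \
            or slopes.shape[0] != v_I.shape[0]:
        raise DimensionError(
            f"slopes {slopes.shape} / v_I {v_I.shape} inconsistent with "
            f"decomposition (m*={m_star}, |I|={len(dec.independent_indices)})"
        )
    rhs = slopes - v_I @ dec.S_IM.T
    return np.linalg.solve(dec.S_DM, rhs.T).T


def assemble_flux_matrix(dec, v_I, v_D):
    """Interleave K x |I| and K x |D| blocks back into K x n natural flux order."""
    v_I = np.atleast_2d(v_I)
    v_D = np.atleast_2d(v_D)
    out = np.empty((v_I.shape[0], dec.model.n_fluxes))
    out[:, list(dec.independent_indices)] = v_I
    out[:, list(dec.dependent_indices)] = v_D
    return out


@dataclass
class UnmeasuredRecipe:
    """Linear identity for one unmeasured metabolite's slope.

    ``dX_u/dt (t_k) = sum_i c_i dX_i/dt (t_k) + sum_j d_j v_j(t_k)``
    where ``c`` runs over measured metabolites and ``d`` over fluxes whose
    values are computable (dependencies fully measured).
    """

    metabolite_index: int
    slope_coeffs: dict    # measured metabolite index -> coefficient
    flux_coeffs: dict     # flux index -> coefficient

    def apply(self, measured_slopes, flux_values, measured_indices):
        """Evaluate the recipe on K x m* slopes and K x n flux values."""
        measured_slopes = np.atleast_2d(measured_slopes)
        flux_values = np.atleast_2d(flux_values)
        col = {int(i): k for k, i in enumerate(measured_indices)}
        out = np.zeros(measured_slopes.shape[0])
        for i, c in self.slope_coeffs.items():
            out += c * measured_slopes[:, col[i]]
        for j, d in self.flux_coeffs.items():
            out += d * flux_values[:, j]
        return out


@dataclass
class ReducedSystem:
    """Result of eliminating unmeasured metabolites.

    ``model`` is the input model with pure-sink rows removed (indices
    remapped); ``recipes`` reconstruct the slopes of the remaining
    eliminable unmeasured metabolites; ``non_eliminable`` lists unmeasured
    metabolites whose balance cannot be written from measured quantities
    (these require simulation-based handling, not enabled by default).
    """

    model: KineticModel
    recipes: list
    dropped_sinks: list
    non_eliminable: list
    index_map: dict  # old metabolite index -> new index (dropped rows absent)


def reduce_unmeasured(model, tol=1e-9):
    """Drop sink metabolites and build slope recipes for unmeasured ones.

    A *sink* is an unmeasured metabolite that appears in no flux dependency:
    its concentration affects nothing, so its balance row can be removed.
    Each remaining unmeasured row ``S_u`` is eliminable when it can be written
    exactly as ``c . S_M + d`` with ``d`` supported on fluxes whose dependency
    sets are fully measured; the minimum-norm exact solution is returned as
    the recipe.  Models with all metabolites measured are returned unchanged.
    """
    if model.measured_mask.all():
        return ReducedSystem(model, [], [], [],
                             {i: i for i in range(model.n_metabolites)})
    dep_union = set()
    for f in model.fluxes:
        dep_union |= set(f.dependencies)
    sinks = [i for i in model.unmeasured_indices if i not in dep_union]
    keep = [i for i in range(model.n_metabolites) if i not in sinks]
    index_map = {old: new for new, old in enumerate(keep)}
    remap = lambda f: _remap_flux(f, index_map)  # noqa: E731
    reduced = KineticModel(
        stoichiometry=model.stoichiometry[keep, :],
        fluxes=[remap(f) for f in model.fluxes],
        metabolite_names=[model.metabolite_names[i] for i in keep],
        measured_mask=model.measured_mask[keep],
    )
    measured = reduced.measured_indices
    S = reduced.stoichiometry
    S_M = S[measured, :]
    computable = [j for j, f in enumerate(reduced.fluxes)
                  if f.dependencies <= set(measured.tolist())]
    recipes, non_eliminable = [], []
    for u in reduced.unmeasured_indices:
        S_u = S[u, :]
        # columns: measured slope coefficients c, then flux coefficients d
        E = np.zeros((len(computable), reduced.n_fluxes))
        for k, j in enumerate(computable):
            E[k, j] = 1.0
        A = np.vstack([S_M, E]).T          # n x (m* + |computable|)
        z, *_ = np.linalg.lstsq(A, S_u, rcond=None)
        if np.linalg.norm(A @ z - S_u) > tol * max(1.0, np.linalg.norm(S_u)):
            non_eliminable.append(int(u))
            continue
        c = z[: len(measured)]
        d = z[len(measured):]
        recipes.append(UnmeasuredRecipe(
            metabolite_index=int(u),
            slope_coeffs={int(i): float(ci) for i, ci in zip(measured, c)
                          if abs(ci) > 1e-12},
            flux_coeffs={int(j): float(dj) for j, dj in zip(computable, d)
                         if abs(dj) > 1e-12},
        ))
    return ReducedSystem(reduced, recipes, [model.metabolite_names[i] for i in sinks],
                         non_eliminable, index_map)


def _remap_flux(flux, index_map):
    from dataclasses import replace

    from .model_core import MichaelisMentenFlux, PowerLawFlux

    if isinstance(flux, PowerLawFlux):
        return replace(flux, kinetic_orders={index_map[i]: f
                                             for i, f in flux.kinetic_orders.items()})
    if isinstance(flux, MichaelisMentenFlux):
        return replace(flux, substrate_index=index_map[flux.substrate_index])
    raise TypeError(f"unknown flux type {type(flux)}")  # pragma: no cover
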