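"""Exploration of the viable independent-parameter space.

Two stages characterize the viable region:

* **OEAMC** (out-of-equilibrium adaptive Metropolis Monte Carlo): a seeded
  adaptive random walk over the parameter box.  Proposals come from a
  diagonal normal kernel (occasionally inflated, the "out-of-equilibrium"
  jumps that let the chain cross between poorly connected viable pockets);
  a proposal is accepted into the coarse set iff it is viable.  After every
  batch the viable points are clustered, per-cluster minimum-volume
  enclosing ellipsoids (MVEEs) are fitted, and sampling stops once the
  summed ellipsoid volume has converged.

* **MEBS** (multiple ellipsoid-based sampling): starting from each
  unexhausted coarse point, fit an MVEE to the local viable points, inflate
  it by a multiplier ``g_i``, sample uniformly inside the scaled ellipsoid,
  keep the viable samples and refit, shrinking ``g_i`` toward one.  The
  final ellipsoids form a cover of the viable region whose union volume is
  estimated by importance-weighted Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import KinensError


def unit_ball_volume(d):
    from scipy.special import gammaln

    return float(np.exp(d / 2 * np.log(np.pi) - gammaln(d / 2 + 1)))


@dataclass
class Ellipsoid:
    """Region ``{x : (x - c)^T E (x - c) <= 1}`` with E symmetric positive definite."""

    center: np.ndarray
    shape: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)
        d = len(self.center)
        if self.shape.shape != (d, d):
            raise ValueError("shape matrix must be d x d")
        self.shape = 0.5 * (self.shape + self.shape.T)
        eigvals = np.linalg.eigvalsh(self.shape)
        if eigvals[0] <= 0:
            raise ValueError("shape matrix must be positive definite")

    @property
    def dim(self):
        return len(self.center)

    @property
    def volume(self):
        sign, logdet = np.linalg.slogdet(self.shape)
        if sign <= 0:  # pragma: no cover - guarded in __post_init__
            raise ValueError("shape matrix not positive definite")
        return unit_ball_volume(self.dim) * float(np.exp(-0.5 * logdet))

    def mahalanobis_sq(self, points):
        diff = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", diff, self.shape, diff)

    def contains(self, points, tol=1e-9):
        return self.mahalanobis_sq(points) <= 1.0 + tol

    def scaled(self, g):
        """Ellipsoid with all semi-axes multiplied by ``g``."""
        return Ellipsoid(self.center.copy(), self.shape / g**2)

    def sample(self, n, rng):
        """Uniform sample inside the ellipsoid (affine image of a uniform ball)."""
        d = self.dim
        eigvals, eigvecs = np.linalg.eigh(self.shape)
        A = eigvecs @ np.diag(1.0 / np.sqrt(eigvals))
        z = rng.standard_normal((n, d))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        r = rng.random(n) ** (1.0 / d)
        return self.center + (z * r[:, None]) @ A.T

    def to_dict(self):
        return {"center": self.center.tolist(), "shape": self.shape.tolist()}


def mvee(points, tolerance=1e-3, max_iter=2000, floor_radius=None):
    """Minimum-volume enclosing ellipsoid (Khachiyan's algorithm).

    Guarantees containment of every input point (the ellipsoid is rescaled
    so the largest Mahalanobis distance is exactly 1); the volume is within
    roughly ``(1 + tolerance)^d`` of optimal.  Affinely degenerate inputs
    (fewer than d+1 points, or points on a lower-dimensional flat) fall back
    to a regularized ellipsoid with a floor semi-axis.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    N, d = P.shape
    if N == 0:
        raise ValueError("mvee of an empty point set")
    if floor_radius is None:
        scale = float(np.max(np.abs(P))) if np.any(P) else 1.0
        floor_radius = 1e-6 * max(scale, 1.0)
    center_guess = P.mean(axis=0)
    rank = np.linalg.matrix_rank(P - center_guess, tol=1e-12) if N > 1 else 0
    if N <= d or rank < d:
        return _regularized_ellipsoid(P, floor_radius)

    Q = np.vstack([P.T, np.ones(N)])
    u = np.full(N, 1.0 / N)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j = int(np.argmax(M))
        maximum = M[j]
        if maximum <= (1.0 + tolerance) * (d + 1):
            break
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        u *= 1.0 - step
        u[j] += step
    c = P.T @ u
    cov = P.T @ np.diag(u) @ P - np.outer(c, c)
    try:
        E = np.linalg.inv(cov) / d
    except np.linalg.LinAlgError:
        return _regularized_ellipsoid(P, floor_radius)
    eigvals = np.linalg.eigvalsh(0.5 * (E + E.T))
    if eigvals[0] <= 0:
        return _regularized_ellipsoid(P, floor_radius)
    ell = _rescale_to_contain(c, E, P)
    assert bool(np.all(ell.contains(P))), "MVEE must contain all input points"
    return ell


def _rescale_to_contain(c, E, P):
    """Inflate the ellipsoid until every point is inside.

    Construction (symmetrization, eigendecomposition) perturbs the quadratic
    form at round-off level, which matters when the semi-axes span many
    orders of magnitude; a couple of rescale passes make containment exact.
    """
    ell = Ellipsoid(c, E)
    for _ in range(5):
        worst = float(np.max(ell.mahalanobis_sq(P)))
        if worst <= 1.0:
            break
        ell = Ellipsoid(ell.center, ell.shape / (worst * (1.0 + 1e-12)))
    return ell


def _regularized_ellipsoid(P, floor_radius):
    """Degenerate fallback: principal-axes ellipsoid with a floor semi-axis."""
    c = P.mean(axis=0)
    d = P.shape[1]
    diff = P - c
    cov = diff.T @ diff / max(len(P), 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    semi = np.maximum(np.sqrt(np.clip(eigvals, 0, None)) * np.sqrt(d) * 1.001,
                      floor_radius)
    E = eigvecs @ np.diag(1.0 / semi**2) @ eigvecs.T
    ell = _rescale_to_contain(c, E, P)
    assert bool(np.all(ell.contains(P))), "MVEE must contain all input points"
    return ell


@dataclass
class ExplorationConfig:
    """Tunable constants of OEAMC and MEBS.

    Scales are fractions of the parameter-box range; the MEBS multiplier
    follows ``g_{i+1} = 1 + g_decay (g_i - 1)`` from ``g_start`` until it
    falls below ``g_stop``.
    """

    seed: int
    batch_size: int = 200
    max_iterations: int = 6000
    proposal_scale: float = 0.05
    target_acceptance: float = 0.25
    adapt_rate: float = 0.5
    jump_probability: float = 0.10
    jump_factor: float = 10.0
    convergence_tol: float = 0.05
    converged_checks: int = 2
    min_points_for_convergence: int = 20
    cluster_cutoff: float = 0.10
    mvee_tolerance: float = 1e-3
    g_start: float = 2.0
    g_decay: float = 0.7
    g_stop: float = 1.05
    mebs_max_iter: int = 20
    mebs_batch: int = 100
    mebs_local_perturbations: int = 20
    mvee_max_points: int = 400

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory for exploration")


@dataclass
class ViablePointSet:
    """Viable parameter points with their provenance stage tags."""

    points: np.ndarray
    provenance: list = field(default_factory=list)
    converged: bool = True
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self):
        return len(self.points)


def _as_predicate(viability):
    def pred(x):
        out = viability(x)
        return bool(out.viable) if hasattr(out, "viable") else bool(out)
    return pred


def _cluster_points(points, cutoff):
    """Single-linkage clusters (normalized coordinates, distance cutoff)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    if len(points) == 1:
        return [np.array([0])]
    Z = linkage(pdist(points), method="single")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]


def _cover_volume(points, lo, hi, config):
    span = hi - lo
    norm = (points - lo) / span
    clusters = _cluster_points(norm, config.cluster_cutoff * np.sqrt(len(lo)))
    total = 0.0
    count = 0
    for idx in clusters:
        pts = points[idx]
        if len(pts) > config.mvee_max_points:
            sel = np.linspace(0, len(pts) - 1, config.mvee_max_points).astype(int)
            pts = pts[sel]
        total += mvee(pts, tolerance=config.mvee_tolerance).volume
        count += 1
    return total, count


def oeamc(start, viability, bounds_box, config):
    """Coarse global exploration of the viable region by adaptive random walk.

    Parameters
    ----------
    start : array
        A viable point (raises if not).
    viability : callable
        Maps a parameter vector to a truthy verdict (bool or an object with a
        ``viable`` attribute).
    bounds_box : (lo, hi) arrays
        The parameter search box; proposals outside it are nonviable.
    config : ExplorationConfig

    Returns
    -------
    ViablePointSet
        Coarse viable points; ``converged=False`` with a warning tag when
        the iteration cap was hit first.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in bounds_box)
    pred = _as_predicate(viability)
    start = np.asarray(start, dtype=float)
    if not pred(start):
        raise KinensError("OEAMC start point is not viable")
    rng = np.random.default_rng(config.seed)
    span = hi - lo
    scale = config.proposal_scale * span
    # out-of-equilibrium jumps use a fixed box-scale kernel: the adapted
    # local scale shrinks inside a thin region and would strand the chain
    jump_scale = config.jump_factor * config.proposal_scale * span
    x = start.copy()
    points = [start.copy()]
    log = []
    accepted_in_batch = 0
    prev_volume = None
    checks = 0
    converged = False
    for it in range(1, config.max_iterations + 1):
        sigma = jump_scale if rng.random() < config.jump_probability else scale
        proposal = x + rng.standard_normal(len(x)) * sigma
        if np.all(proposal >= lo) and np.all(proposal <= hi) and pred(proposal):
            x = proposal
            points.append(proposal.copy())
            accepted_in_batch += 1
        if it % config.batch_size == 0:
            rate = accepted_in_batch / config.batch_size
            if rate == 0:
                # thin viable regions: shrink hard until proposals land
                scale = scale * 0.3
            else:
                scale = scale * np.exp(config.adapt_rate *
                                       (rate - config.target_acceptance))
            accepted_in_batch = 0
            volume, n_ell = _cover_volume(np.asarray(points), lo, hi, config)
            log.append({"iteration": it, "acceptance": rate,
                        "n_points": len(points), "n_ellipsoids": n_ell,
                        "volume": volume})
            if len(points) < config.min_points_for_convergence:
                prev_volume = volume
                continue
            if prev_volume is not None and volume > 0:
                if abs(volume - prev_volume) <= config.convergence_tol * prev_volume:
                    checks += 1
                    if checks >= config.converged_checks:
                        converged = True
                        break
                else:
                    checks = 0
            prev_volume = volume
    return ViablePointSet(np.asarray(points),
                          provenance=["oeamc"] * len(points),
                          converged=converged, log=log)


def mebs(coarse, viability, config, bounds_box=None):
    """Fine characterization: tightly fitting ellipsoid cover + dense viable points.

    Every coarse point not already covered by an accepted ellipsoid seeds a
    local loop: fit an MVEE to the local viable points, inflate by the
    current multiplier, sample uniformly inside, keep viable samples, refit,
    shrink the multiplier toward one.  Returns all viable points found plus
    the ellipsoid cover.
    """
    pred = _as_predicate(viability)
    pts0 = np.unique(np.atleast_2d(np.asarray(coarse.points, dtype=float)), axis=0)
    if len(pts0) == 0:
        raise KinensError("MEBS needs a nonempty coarse set")
    if bounds_box is not None:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds_box)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    d = pts0.shape[1]
    cover = []
    all_points = [p for p in pts0]
    if bounds_box is not None:
        span = hi - lo
    else:
        span = np.ptp(pts0, axis=0) + 1.0
    coarse_scale = np.ptp(pts0, axis=0) * 0.05
    ladder = [np.maximum(coarse_scale, span * 5e-2)] + \
        [span * frac for frac in (1e-2, 3e-3, 1e-3, 3e-4, 1e-4)]
    for p in pts0:
        if any(e.contains(p[None])[0] for e in cover):
            continue  # exhausted: already covered
        # seed a local cloud; walk a scale ladder down until perturbations
        # start landing inside thin viable regions
        local = [p]
        local_scale = ladder[-1]
        for trial_scale in ladder:
            hits = []
            for _ in range(config.mebs_local_perturbations):
                q = p + rng.standard_normal(d) * trial_scale
                if bounds_box is not None:
                    q = np.clip(q, lo, hi)
                if pred(q):
                    hits.append(q)
            if len(hits) >= max(2, config.mebs_local_perturbations // 4):
                local.extend(hits)
                local_scale = trial_scale
                break
        near = pts0[np.linalg.norm(pts0 - p, axis=1) <=
                    3 * np.linalg.norm(local_scale)]
        local.extend(near)
        g = config.g_start
        ell = mvee(np.asarray(local), tolerance=config.mvee_tolerance)
        for _ in range(config.mebs_max_iter):
            samples = ell.scaled(g).sample(config.mebs_batch, rng)
            if bounds_box is not None:
                inside = np.all((samples >= lo) & (samples <= hi), axis=1)
                samples = samples[inside]
            viable = [s for s in samples if pred(s)]
            if viable:
                local.extend(viable)
                all_points.extend(viable)
            fit_pts = np.asarray(local)
            if len(fit_pts) > config.mvee_max_points:
                sel = rng.choice(len(fit_pts), config.mvee_max_points,
                                 replace=False)
                fit_pts = fit_pts[sel]
            ell = mvee(fit_pts, tolerance=config.mvee_tolerance)
            g = 1.0 + config.g_decay * (g - 1.0)
            if g < config.g_stop:
                break
        cover.append(ell)
    points = np.asarray(all_points)
    return ViablePointSet(points, provenance=["mebs"] * len(points)), cover


def estimate_volume(cover, n_samples, seed, box=None):
    """Monte Carlo union volume of an ellipsoid cover.

    Samples from the ellipsoids proportionally to their individual volumes
    and weights each sample by one over the number of covering ellipsoids
    (zero if outside the bounding box, which the viable region cannot
    leave).  Returns ``(estimate, standard_error)``.
    """
    if not cover:
        raise ValueError("empty ellipsoid cover")
    if n_samples < 100:
        raise ValueError("need at least 100 samples for a volume estimate")
    rng = np.random.default_rng(seed)
    vols = np.array([e.volume for e in cover])
    total = float(vols.sum())
    counts = rng.multinomial(n_samples, vols / total)
    weights = np.empty(n_samples)
    pos = 0
    for e, n_e in zip(cover, counts):
        if n_e == 0:
            continue
        pts = e.sample(n_e, rng)
        cov_count = np.zeros(n_e)
        for other in cover:
            cov_count += other.contains(pts)
        cov_count = np.maximum(cov_count, 1.0)
        w = 1.0 / cov_count
        if box is not None:
            lo, hi = (np.asarray(b, dtype=float) for b in box)
            inside = np.all((pts >= lo) & (pts <= hi), axis=1)
            w = np.where(inside, w, 0.0)
        weights[pos: pos + n_e] = w
        pos += n_e
    estimate = total * float(weights.mean())
    stderr = total * float(weights.std(ddof=1)) / np.sqrt(n_samples)
    return estimate, stderr
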