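"""Smoothing of noisy concentration time series and slope estimation.

The incremental identification workflow starts from measured concentrations
``X_M(t_k)``, ``k = 1..K``.  Each metabolite profile is smoothed (polynomial
or smoothing spline), the smoother is selected by AIC (adjusted R^2 reported
alongside), and time-slopes ``dX_M/dt (t_k)`` are then estimated by central
finite differences of the smoothed values (one-sided at the endpoints).
The smoothing residuals also provide the per-metabolite noise variance used
by the Monte Carlo error-bound procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SmoothingError

#: RSS is floored here before entering the log in the AIC formula.
RSS_FLOOR = 1e-15

#: smoothed values are floored here before any downstream logarithm.
SMOOTHED_VALUE_FLOOR = 1e-6

_EDOF_CACHE = {}


@dataclass
class TimeSeriesData:
    """Measured concentration table: times ``t_k`` plus one column per metabolite."""

    times: np.ndarray
    concentrations: np.ndarray
    metabolite_names: list

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        if self.concentrations.shape[0] != len(self.times):
            self.concentrations = self.concentrations.T
        K, m = self.concentrations.shape
        if K < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.concentrations)):
            raise ValueError("concentrations must be finite")
        if len(self.metabolite_names) != m:
            raise ValueError("one name per concentration column required")

    @property
    def n_points(self):
        return len(self.times)

    @property
    def n_metabolites(self):
        return self.concentrations.shape[1]

    def column(self, metabolite):
        """Concentration profile by index or name."""
        if isinstance(metabolite, str):
            metabolite = self.metabolite_names.index(metabolite)
        return self.concentrations[:, metabolite]

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        if df.columns[0] != "time":
            raise ValueError("first column of a time-series file must be 'time'")
        return cls(df["time"].to_numpy(), df.iloc[:, 1:].to_numpy(),
                   list(df.columns[1:]))

    def to_csv(self, path):
        df = pd.DataFrame(self.concentrations, columns=self.metabolite_names)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


class PolynomialCurve:
    """Least-squares polynomial smoother with analytic derivative."""

    kind = "poly"

    def __init__(self, times, values, degree):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if degree >= len(times):
            raise SmoothingError(
                f"polynomial degree {degree} under-determined with K={len(times)} points"
            )
        self.degree = int(degree)
        self._poly = np.polynomial.Polynomial.fit(times, values, degree)
        self._deriv = self._poly.deriv()
        self.complexity = degree + 1  # number of coefficients
        self.rss = float(np.sum((self._poly(times) - values) ** 2))

    def value(self, t):
        return self._poly(np.asarray(t, dtype=float))

    def derivative(self, t):
        return self._deriv(np.asarray(t, dtype=float))

    @property
    def spec(self):
        return {"kind": "poly", "degree": self.degree}


class SplineCurve:
    """Cubic smoothing spline; penalty strength chosen by GCV by default.

    The effective model complexity is the trace of the linear smoother
    matrix (effective degrees of freedom), computed by smoothing the
    canonical unit vectors at the fitted penalty.
    """

    kind = "spline"

    def __init__(self, times, values, lam=None, lam_grid=None, max_edof=None):
        from scipy.interpolate import make_smoothing_spline

        t = np.asarray(times, dtype=float)
        y = np.asarray(values, dtype=float)
        K = len(t)
        if K < 4:
            raise SmoothingError("spline smoothing needs at least 4 points")
        if lam is None:
            table = self._gcv_table(t, y, lam_grid)
            if max_edof is not None:
                lam = self._select_from_table(table, K, max_edof)
            else:
                # two-stage guard: a conservative effective-dof cap protects
                # against GCV's occasional catastrophic undersmoothing of a
                # noisy realization, but is released when the capped fit's
                # residuals are an order of magnitude above a lightly-capped
                # fit -- noise can only shrink RSS by a bounded factor,
                # unresolved structure shrinks it by orders of magnitude
                lam_c, rss_c = self._select_from_table(
                    table, K, max(8.0, K / 4.0), with_rss=True)
                lam_u, rss_u = self._select_from_table(
                    table, K, 0.8 * K, with_rss=True)
                lam = lam_u if rss_c > 10.0 * max(rss_u, 1e-300) else lam_c
        self.lam = float(lam)
        self._spline = make_smoothing_spline(t, y, lam=self.lam)
        self._deriv = self._spline.derivative()
        self.complexity = self._effective_dof(t, self.lam)
        self.rss = float(np.sum((self._spline(t) - y) ** 2))

    @staticmethod
    def _effective_dof(t, lam):
        # the smoother is linear in y at fixed lam, so its trace (effective
        # degrees of freedom) depends only on (grid, lam); cached because the
        # Monte Carlo bound procedure re-smooths the same grid hundreds of times
        key = (t.tobytes(), float(lam))
        cached = _EDOF_CACHE.get(key)
        if cached is not None:
            return cached
        from scipy.interpolate import make_smoothing_spline

        K = len(t)
        tr = 0.0
        eye = np.eye(K)
        for i in range(K):
            tr += float(make_smoothing_spline(t, eye[i], lam=lam)(t[i]))
        if len(_EDOF_CACHE) > 256:
            _EDOF_CACHE.clear()
        _EDOF_CACHE[key] = tr
        return tr

    @classmethod
    def _gcv_table(cls, t, y, lam_grid=None):
        """(lam, rss, edof) for every candidate penalty on the grid."""
        from scipy.interpolate import make_smoothing_spline

        if lam_grid is None:
            span = (t[-1] - t[0]) ** 3
            lam_grid = span * np.logspace(-13, 1, 15)
        table = []
        for lam in lam_grid:
            try:
                s = make_smoothing_spline(t, y, lam=lam)
            except Exception:
                continue
            rss = float(np.sum((s(t) - y) ** 2))
            table.append((float(lam), rss, cls._effective_dof(t, lam)))
        if not table:
            raise SmoothingError("no usable spline penalty on the grid")
        return table

    @staticmethod
    def _select_from_table(table, K, max_edof, with_rss=False):
        """GCV selection among penalties whose effective dof is capped.

        GCV occasionally undersmooths noisy realizations catastrophically,
        and a wiggly fit ruins the downstream slope estimates; hence the cap.
        """
        best, best_score, best_rss = None, np.inf, None
        for lam, rss, edof in table:
            if edof > max_edof:
                continue
            denom = max(1.0 - edof / K, 1e-8)
            score = (rss / K) / denom**2
            if score < best_score:
                best, best_score, best_rss = lam, score, rss
        if best is None:
            best, best_rss = table[-1][0], table[-1][1]
        return (best, best_rss) if with_rss else best

    def value(self, t):
        return self._spline(np.asarray(t, dtype=float))

    def derivative(self, t):
        return self._deriv(np.asarray(t, dtype=float))

    @property
    def spec(self):
        return {"kind": "spline", "lam": self.lam}


def fit_polynomial(series, metabolite, degree):
    """Least-squares polynomial smoother for one metabolite column."""
    return PolynomialCurve(series.times, series.column(metabolite), degree)


def fit_spline(series, metabolite, smoothing_control=None):
    """Cubic smoothing-spline smoother for one metabolite column.

    ``smoothing_control`` may contain ``lam`` (fixed penalty; 0 interpolates)
    or ``lam_grid`` (candidate penalties for GCV selection).
    """
    smoothing_control = smoothing_control or {}
    return SplineCurve(series.times, series.column(metabolite),
                       lam=smoothing_control.get("lam"),
                       lam_grid=smoothing_control.get("lam_grid"),
                       max_edof=smoothing_control.get("max_edof"))


def _fit_candidate(series, metabolite, spec):
    if spec["kind"] == "poly":
        return fit_polynomial(series, metabolite, spec["degree"])
    if spec["kind"] == "spline":
        return fit_spline(series, metabolite, spec)
    raise ValueError(f"unknown smoother kind {spec['kind']!r}")


def aic(rss, n_points, complexity):
    """AIC with Gaussian errors: K ln(RSS/K) + 2 (complexity + 1).

    ``complexity`` counts fitted curve coefficients; the +1 accounts for the
    noise variance.  RSS is floored at a small positive value so that exact
    fits do not produce -inf.
    """
    return n_points * np.log(max(rss, RSS_FLOOR) / n_points) + 2 * (complexity + 1)


def adjusted_r2(rss, tss, n_points, complexity):
    if tss <= 0:
        return 1.0 if rss <= RSS_FLOOR else 0.0
    dof = max(n_points - complexity, 1)
    return 1.0 - (rss / dof) / (tss / (n_points - 1))


def select_smoother(series, metabolite, candidates):
    """Fit every candidate smoother and return the one minimizing AIC.

    Returns ``(curve, report)`` where the report carries the smoother kind and
    complexity, adjusted R^2 and AIC of the winner.  Ties are broken toward
    lower complexity.
    """
    y = series.column(metabolite)
    K = series.n_points
    tss = float(np.sum((y - y.mean()) ** 2))
    fitted, failures = [], []
    for spec in candidates:
        try:
            curve = _fit_candidate(series, metabolite, spec)
        except Exception as exc:  # noqa: BLE001 - reported per candidate
            failures.append((spec, str(exc)))
            continue
        fitted.append((aic(curve.rss, K, curve.complexity), curve.complexity, curve))
    if not fitted:
        raise SmoothingError(
            f"all smoother candidates failed for metabolite {metabolite}: {failures}"
        )
    fitted.sort(key=lambda item: (item[0], item[1]))
    best_aic, _, curve = fitted[0]
    report = {
        "kind": curve.kind,
        "complexity": curve.complexity,
        "spec": curve.spec,
        "aic": float(best_aic),
        "adjusted_r2": float(adjusted_r2(curve.rss, tss, K, curve.complexity)),
        "rss": float(curve.rss),
    }
    return curve, report


def estimate_slopes(values, times):
    """Finite-difference slopes of smoothed values on the time grid.

    Interior points use central differences; endpoints use one-sided
    differences.  ``values`` may be a smooth-curve object (evaluated at the
    grid) or an array of smoothed values.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 grid points for slope estimation")
    if hasattr(values, "value"):
        values = values.value(times)
    values = np.asarray(values, dtype=float)
    return np.gradient(values, times, edge_order=1)


@dataclass
class SmoothedProfiles:
    """Smoothed curves, slope estimates and residual noise variances."""

    times: np.ndarray
    fitted_values: np.ndarray      # K x m*
    slope_estimates: np.ndarray    # K x m*
    residual_variance: np.ndarray  # per metabolite
    fit_report: list = field(default_factory=list)
    metabolite_names: list = field(default_factory=list)
    curves: list = None

    def __post_init__(self):
        K = len(self.times)
        if self.fitted_values.shape[0] != K or self.slope_estimates.shape != \
                self.fitted_values.shape:
            raise ValueError("inconsistent smoothed-profile shapes")
        if np.any(self.residual_variance < 0):
            raise ValueError("residual variance must be >= 0")

    @property
    def endpoint_mask(self):
        """True at the first and last grid point, where slopes are one-sided."""
        mask = np.zeros(len(self.times), dtype=bool)
        mask[[0, -1]] = True
        return mask

    def report_dict(self):
        return {
            name: {**rep, "residual_variance": float(var)}
            for name, rep, var in zip(
                self.metabolite_names, self.fit_report, self.residual_variance
            )
        }


DEFAULT_CANDIDATES = (
    {"kind": "poly", "degree": 3},
    {"kind": "poly", "degree": 4},
    {"kind": "poly", "degree": 5},
    {"kind": "poly", "degree": 6},
    {"kind": "spline"},
)


def smooth_dataset(series, candidates=DEFAULT_CANDIDATES):
    """Smooth every metabolite column, selecting the smoother per metabolite.

    Returns :class:`SmoothedProfiles` with fitted values floored at a small
    positive value (downstream regressions take logarithms), slope estimates
    and per-metabolite residual variances RSS / (K - complexity).
    """
    K, m = series.n_points, series.n_metabolites
    usable = [c for c in candidates
              if not (c.get("kind") == "poly" and c.get("degree", 0) >= K)]
    if not usable:
        raise SmoothingError("no usable smoother candidates for this grid size")
    fitted = np.empty((K, m))
    slopes = np.empty((K, m))
    variances = np.empty(m)
    reports, curves = [], []
    for i in range(m):
        curve, report = select_smoother(series, i, usable)
        vals = np.clip(curve.value(series.times), SMOOTHED_VALUE_FLOOR, None)
        fitted[:, i] = vals
        slopes[:, i] = estimate_slopes(vals, series.times)
        dof = K - report["complexity"]
        if dof <= 0:
            raise SmoothingError(
                f"metabolite {series.metabolite_names[i]}: complexity >= K, "
                "noise variance undefined"
            )
        variances[i] = report["rss"] / dof
        reports.append(report)
        curves.append(curve)
    return SmoothedProfiles(series.times, fitted, slopes, variances,
                            reports, list(series.metabolite_names), curves)


def interior_profiles(profiles, trim=None):
    """Copy of the profiles with ``trim`` rows removed from each end.

    Edge slopes (one-sided differences, high smoother leverage) carry the
    largest error; the incremental-identification stage works on interior
    points by default, which markedly stabilizes flux positivity and
    per-flux regressions.  The default trim is 1 point per side plus 5% of
    the grid on each side.
    """
    K = len(profiles.times)
    if trim is None:
        trim = (1, 1 + K // 12)
    if np.isscalar(trim):
        trim = (trim, trim)
    t0, t1 = trim
    if K - t0 - t1 < 5:
        raise ValueError(f"trimming {trim} leaves too few of {K} points")
    sl = slice(t0, K - t1)
    return SmoothedProfiles(
        profiles.times[sl],
        profiles.fitted_values[sl],
        profiles.slope_estimates[sl],
        profiles.residual_variance,
        profiles.fit_report,
        list(profiles.metabolite_names),
        profiles.curves,
    )


def estimate_noise_variance(series, profiles):
    """Per-metabolite noise variance RSS / (K - complexity) from smoothing residuals."""
    K = series.n_points
    out = np.empty(series.n_metabolites)
    for i in range(series.n_metabolites):
        complexity = profiles.fit_report[i]["complexity"]
        if K <= complexity:
            raise SmoothingError("K <= complexity: variance undefined")
        resid = series.concentrations[:, i] - profiles.fitted_values[:, i]
        out[i] = np.sum(resid**2) / (K - complexity)
    return out
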