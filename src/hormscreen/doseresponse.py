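"""Viability curves and the four response measures.

Counts are normalized to the vehicle control of the same replicate, giving a
dimensionless viability curve per replicate.  Two routes summarize response:

* piecewise-linear: trapezoid AUC and segment-interpolated IC50, computed per
  replicate and medianized across replicates;
* model-based: a five-parameter curve (decreasing two-parameter sigmoid plus a
  scaled normal-density peak, accommodating low-dose growth stimulation) is
  fitted to all replicate points jointly by bounded nonlinear least squares,
  and AUC/IC50 are read off the fitted curve.

When the direct fit fails (very steep responders make the sigmoid nearly flat
at zero concentration for most parametrizations), the fit falls back to the
best of many randomly started local minimizations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import integrate, optimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "DoseGrid",
    "ViabilityCurve",
    "HormeticParams",
    "HormeticFit",
    "ViabilityMeasures",
    "normalize_counts",
    "trapezoid_auc",
    "interpolate_ic50",
    "median_measures",
    "hormetic_model",
    "fit_hormetic",
    "random_restart_fit",
    "fitted_auc",
    "fitted_ic50",
    "quantify_sample",
]


@dataclasses.dataclass(frozen=True)
class DoseGrid:
    """Ordered concentration grid in µM; first element is the vehicle control."""

    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        if len(conc) < 3:
            raise ValueError(f"dose grid needs >= 3 concentrations, got {len(conc)}")
        if conc[0] != 0.0:
            raise ValueError(f"dose grid must start at 0 (vehicle control), got {conc[0]}")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError(f"dose grid must be strictly increasing: {conc}")

    def __len__(self) -> int:
        return len(self.concentrations)

    @property
    def c_max(self) -> float:
        return self.concentrations[-1]

    @property
    def lowest_nonzero(self) -> float:
        return self.concentrations[1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)


@dataclasses.dataclass(frozen=True)
class ViabilityCurve:
    """Control-normalized viability of one replicate along a dose grid."""

    sample: str
    replicate: str
    grid: DoseGrid
    viability: tuple[float, ...]

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.viability)
        object.__setattr__(self, "viability", v)
        if len(v) != len(self.grid):
            raise ValueError(
                f"{self.sample}/{self.replicate}: viability length {len(v)} "
                f"!= grid length {len(self.grid)}"
            )
        if v[0] != 1.0:
            raise ValueError(f"{self.sample}/{self.replicate}: viability[0] must be 1, got {v[0]}")
        if any(x < 0 for x in v):
            raise ValueError(f"{self.sample}/{self.replicate}: negative viability")


@dataclasses.dataclass(frozen=True)
class HormeticParams:
    """Parameters of the sigmoid + scaled-normal-density viability model.

    mu/sigma locate and scale the low-dose peak (normal density), shift/slope
    parametrize the decreasing sigmoid, amp scales the peak contribution.
    """

    mu: float
    sigma: float
    shift: float
    slope: float
    amp: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.amp < 0:
            raise ValueError(f"amp must be >= 0, got {self.amp}")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma, self.shift, self.slope, self.amp])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "HormeticParams":
        mu, sigma, shift, slope, amp = (float(v) for v in x)
        return cls(mu=mu, sigma=sigma, shift=shift, slope=slope, amp=max(amp, 0.0))


@dataclasses.dataclass(frozen=True)
class HormeticFit:
    params: HormeticParams
    rss: float
    converged: bool
    method: str  # "nls" | "random_restart"
    n_points: int

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if self.method not in ("nls", "random_restart"):
            raise ValueError(f"unknown fit method {self.method!r}")


@dataclasses.dataclass(frozen=True)
class ViabilityMeasures:
    """The four response summaries for one sample."""

    auc_trap: float
    ic50_trap: float
    auc_fit: float
    ic50_fit: float
    ic50_trap_censored: bool
    ic50_fit_censored: bool

    MEASURE_NAMES = ("auc_trap", "ic50_trap", "auc_fit", "ic50_fit")


def normalize_counts(
    counts: Sequence[float], grid: DoseGrid, sample: str = "?", replicate: str = "?"
) -> ViabilityCurve:
    """Divide per-dose counts by the dose-0 control count of the same replicate."""
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(grid):
        raise ValueError(
            f"{sample}/{replicate}: {len(counts)} counts for a {len(grid)}-point grid"
        )
    if np.any(counts < 0):
        raise ValueError(f"{sample}/{replicate}: negative counts")
    if counts[0] <= 0:
        raise ValueError(
            f"{sample}/{replicate}: control (dose 0) count must be positive, got {counts[0]}"
        )
    return ViabilityCurve(
        sample=sample, replicate=replicate, grid=grid, viability=tuple(counts / counts[0])
    )


def trapezoid_auc(curve: ViabilityCurve) -> float:
    """Trapezoidal area under one replicate's viability curve (µM·viability)."""
    return float(np.trapezoid(np.asarray(curve.viability), curve.grid.as_array()))


def interpolate_ic50(curve: ViabilityCurve) -> tuple[float, bool]:
    """Linear interpolation to viability 0.5 on the first downward-crossing segment.

    Returns ``(c_max, True)`` (censored) when the curve never crosses 0.5 from
    above within the grid.
    """
    c = curve.grid.as_array()
    v = np.asarray(curve.viability)
    for i in range(len(c) - 1):
        if v[i] >= 0.5 >= v[i + 1] and v[i] > v[i + 1]:
            frac = (v[i] - 0.5) / (v[i] - v[i + 1])
            return float(c[i] + frac * (c[i + 1] - c[i])), False
    return float(curve.grid.c_max), True


def median_measures(
    aucs: Sequence[float], ic50s: Sequence[tuple[float, bool]]
) -> tuple[float, float, bool]:
    """Component-wise median over replicates.

    Censored IC50 replicates contribute their censoring value (c_max); the
    summary is flagged censored when at least half the replicates are censored.
    """
    if len(aucs) == 0 or len(ic50s) == 0:
        raise ValueError("median_measures requires at least one replicate")
    auc = float(np.median(np.asarray(aucs, dtype=float)))
    values = np.array([v for v, _ in ic50s], dtype=float)
    n_censored = sum(1 for _, cen in ic50s if cen)
    ic50 = float(np.median(values))
    return auc, ic50, n_censored >= len(ic50s) / 2


def hormetic_model(c, params: HormeticParams):
    """v(c) = 1/(1+exp(slope·(c−shift))) + amp·φ(c; mu, sigma)."""
    c = np.asarray(c, dtype=float)
    sig = expit(-params.slope * (c - params.shift))
    peak = params.amp * norm.pdf(c, loc=params.mu, scale=params.sigma)
    out = sig + peak
    return float(out) if out.ndim == 0 else out


_LB = np.array([-np.inf, 1e-8, -np.inf, 1e-8, 0.0])
_UB = np.array([np.inf, np.inf, np.inf, np.inf, np.inf])

#: A sigmoid falling from 0.99 to 0.01 spans 2·log(99)/slope µM.  When the
#: fitted transition is narrower than one grid spacing the slope is not
#: resolvable by the data (the fast-responder degeneracy): the optimizer can
#: push slope arbitrarily high at essentially constant RSS, so a "success"
#: flag there is meaningless and the fit is treated as non-converged.
_TRANSITION_WIDTH = 2.0 * math.log(99.0)


def _residuals(x: np.ndarray, c: np.ndarray, v: np.ndarray) -> np.ndarray:
    mu, sigma, shift, slope, amp = x
    sig = expit(-slope * (c - shift))
    peak = amp * np.exp(-0.5 * ((c - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    return sig + peak - v


def _jacobian(x: np.ndarray, c: np.ndarray, v: np.ndarray) -> np.ndarray:
    mu, sigma, shift, slope, amp = x
    sig = expit(-slope * (c - shift))
    phi = np.exp(-0.5 * ((c - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    ss = sig * (1.0 - sig)
    J = np.empty((c.size, 5))
    J[:, 0] = amp * phi * (c - mu) / sigma**2
    J[:, 1] = amp * phi * ((c - mu) ** 2 / sigma**3 - 1.0 / sigma)
    J[:, 2] = slope * ss
    J[:, 3] = -(c - shift) * ss
    J[:, 4] = phi
    return J


def _local_fit(x0: np.ndarray, c: np.ndarray, v: np.ndarray, max_nfev: int | None = None):
    x0 = np.minimum(np.maximum(x0, _LB + 1e-9), 1e12)
    res = optimize.least_squares(
        _residuals,
        x0,
        jac=_jacobian,
        bounds=(_LB, _UB),
        args=(c, v),
        method="trf",
        max_nfev=max_nfev,
    )
    return res


def _fit_quality(res, c: np.ndarray) -> tuple[float, bool]:
    rss = float(np.sum(res.fun**2))
    if not (res.success and np.isfinite(rss)):
        return rss, False
    spacings = np.diff(np.unique(c))
    slope_cap = _TRANSITION_WIDTH / float(spacings.min())
    return rss, bool(res.x[3] < slope_cap)


def _default_start(c: np.ndarray, v: np.ndarray) -> np.ndarray:
    c_max = float(c.max())
    order = np.argsort(c)
    cs, vs = c[order], v[order]
    # crude IC50 of the point cloud as the sigmoid midpoint start
    below = np.nonzero(vs < 0.5)[0]
    shift0 = float(cs[below[0]]) if below.size else c_max / 2
    shift0 = max(shift0, 0.25 * c_max)
    i_peak = int(np.argmax(vs))
    mu0 = max(float(cs[i_peak]), 1e-3) if vs[i_peak] > 1.05 else max(0.1 * c_max, 1e-3)
    sigma0 = max(c_max / 10, 1e-3)
    amp0 = max(vs[i_peak] - 1.0, 0.0) * sigma0 * math.sqrt(2 * math.pi)
    return np.array([mu0, sigma0, shift0, 1.0, amp0])


def fit_hormetic(
    conc: Sequence[float],
    viability: Sequence[float],
    n_restarts: int = 500,
    seed: int = 0,
    polish: bool = True,
) -> HormeticFit:
    """Least-squares fit of the five-parameter model to pooled replicate points.

    All replicates of a sample are fitted jointly.  If the primary bounded
    least-squares fit does not converge cleanly, falls back to
    :func:`random_restart_fit` with ``n_restarts`` samplings.
    """
    c = np.asarray(conc, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.shape != v.shape:
        raise ValueError("conc and viability must have the same length")
    if c.size < 6:
        raise ValueError(f"need >= 6 points to fit 5 parameters, got {c.size}")
    res = _local_fit(_default_start(c, v), c, v)
    rss, ok = _fit_quality(res, c)
    if ok:
        return HormeticFit(
            params=HormeticParams.from_array(res.x),
            rss=rss,
            converged=True,
            method="nls",
            n_points=int(c.size),
        )
    return random_restart_fit(c, v, n_samplings=n_restarts, seed=seed, polish=polish)


def random_restart_fit(
    conc: Sequence[float],
    viability: Sequence[float],
    n_samplings: int = 500,
    seed: int = 0,
    polish: bool = True,
    starts: np.ndarray | None = None,
) -> HormeticFit:
    """Minimum-RSS solution over many randomly sampled parameter vectors.

    Sampling ranges (c_max is the largest observed concentration):
    mu ∈ [0, c_max], sigma ∈ (0, c_max/2], shift ∈ [−c_max/2, 2·c_max],
    slope ∈ (0, 20], amp ∈ [0, 5].  With ``polish`` each sampling seeds a
    bounded local minimization; otherwise samplings are evaluated directly.
    ``starts`` overrides the sampling with explicit start vectors.
    """
    c = np.asarray(conc, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.size < 6:
        raise ValueError(f"need >= 6 points to fit 5 parameters, got {c.size}")
    c_max = float(c.max())
    if starts is None:
        rng = np.random.default_rng(seed)
        n = int(n_samplings)
        starts = np.column_stack(
            [
                rng.uniform(0.0, c_max, n),
                rng.uniform(1e-6, c_max / 2, n),
                rng.uniform(-c_max / 2, 2 * c_max, n),
                rng.uniform(1e-6, 20.0, n),
                rng.uniform(0.0, 5.0, n),
            ]
        )
    else:
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
    best_x, best_rss, best_ok = None, np.inf, False
    for x0 in starts:
        if polish:
            res = _local_fit(x0, c, v, max_nfev=200)
            rss, ok = _fit_quality(res, c)
            x, success = res.x, bool(res.success and np.isfinite(rss))
        else:
            rss = float(np.sum(_residuals(np.maximum(x0, _LB + 1e-9), c, v) ** 2))
            x, success, ok = x0, np.isfinite(rss), True
        if rss < best_rss:
            best_x, best_rss, best_ok = x, rss, success
    assert best_x is not None
    return HormeticFit(
        params=HormeticParams.from_array(best_x),
        rss=best_rss,
        converged=bool(best_ok),
        method="random_restart",
        n_points=int(c.size),
    )


def fitted_auc(params: HormeticParams, c_max: float) -> float:
    """Area under the fitted curve on [0, c_max] by adaptive quadrature."""
    if c_max <= 0:
        raise ValueError(f"c_max must be > 0, got {c_max}")
    value, _ = integrate.quad(lambda c: hormetic_model(c, params), 0.0, c_max, limit=200)
    return float(value)


def fitted_ic50(
    params: HormeticParams, c_max: float, n_grid: int = 1000, xtol: float = 1e-8
) -> tuple[float, bool]:
    """Smallest downward crossing of the fitted curve through viability 0.5.

    Brackets on an ``n_grid``-point scan of [0, c_max], then bisects to
    ``xtol`` µM.  Censored as ``(c_max, True)`` when no crossing exists.
    """
    if c_max <= 0:
        raise ValueError(f"c_max must be > 0, got {c_max}")
    grid = np.linspace(0.0, c_max, int(n_grid))
    vals = hormetic_model(grid, params) - 0.5
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 and vals[i + 1] < 0.0:
            return float(grid[i]), False
        if vals[i] > 0.0 > vals[i + 1]:
            root = optimize.brentq(
                lambda c: hormetic_model(c, params) - 0.5, grid[i], grid[i + 1], xtol=xtol
            )
            return float(root), False
    return float(c_max), True


def quantify_sample(
    curves: Sequence[ViabilityCurve],
    n_restarts: int = 500,
    seed: int = 0,
    polish: bool = True,
) -> tuple[ViabilityMeasures, HormeticFit]:
    """Compute the four measures for one sample from its replicate curves."""
    if not curves:
        raise ValueError("no replicate curves supplied")
    grid = curves[0].grid
    aucs = [trapezoid_auc(cv) for cv in curves]
    ic50s = [interpolate_ic50(cv) for cv in curves]
    auc_trap, ic50_trap, trap_censored = median_measures(aucs, ic50s)
    conc = np.concatenate([cv.grid.as_array() for cv in curves])
    viab = np.concatenate([np.asarray(cv.viability) for cv in curves])
    fit = fit_hormetic(conc, viab, n_restarts=n_restarts, seed=seed, polish=polish)
    auc_fit = fitted_auc(fit.params, grid.c_max)
    ic50_fit, fit_censored = fitted_ic50(fit.params, grid.c_max)
    measures = ViabilityMeasures(
        auc_trap=auc_trap,
        ic50_trap=ic50_trap,
        auc_fit=auc_fit,
        ic50_fit=ic50_fit,
        ic50_trap_censored=trap_censored,
        ic50_fit_censored=fit_censored,
    )
    return measures, fit
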