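"""Coupling thermal preference to shredding performance via orthogonal NLS.

Each experimental temperature defines a zone extending 1 degC either side.
Habitat use in a zone is the mean number of gradient position records per
15 degC-acclimated individual whose recorded temperature falls in that
zone; functional performance is the mean leaf mass consumed per individual
over the 72 h trial at the corresponding temperature (dividing by
surviving-animal exposure, which partly absorbs mortality).  Because both
axes are measured with error, the model ``shredding ~ alpha + beta /
habitat_use`` is fitted by orthogonal non-linear least squares: the
objective sums squared distances along both axes, each standardised by its
pooled standard error, with a per-datum foot point on the curve nested
inside the outer parameter search.  ``beta < 0`` gives a curve rising to
the asymptote ``alpha`` -- the signature of animals spending more time
where they perform better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .records import PositionTrace, ShreddingTrial
from .shredding import amphipod_days

__all__ = [
    "ZoneSummary",
    "assign_zone",
    "zone_summaries",
    "ONLSFit",
    "onls_fit",
    "onls_significance",
    "t_test_p",
]


@dataclass
class ZoneSummary:
    zone_center_c: float
    zone_bounds_c: tuple[float, float]
    habitat_use: float  # mean position records per individual
    habitat_use_se: float
    performance_mg: float | None  # mean leaf mass consumed per individual / 72 h
    performance_se: float | None
    occupancy_fraction: float
    n_records: int


def assign_zone(temp_c: float, centers: Sequence[float], halfwidth: float = 1.0):
    """Zone center a recorded temperature belongs to, or None.

    A record belongs to a zone when it lies within ``halfwidth`` of the
    center.  Where adjacent zones share a boundary point (e.g. 9.0 degC
    between the 8 and 10 degC zones) the record goes to the nearer center,
    with ties resolved downwards.
    """
    centers = np.asarray(centers, dtype=float)
    dist = np.abs(centers - temp_c)
    inside = dist <= halfwidth
    if not inside.any():
        return None
    cand = centers[inside]
    d = dist[inside]
    best = d.min()
    return float(np.min(cand[d == best]))  # ties -> lower center


def zone_summaries(
    traces: Sequence[PositionTrace],
    trials: Sequence[ShreddingTrial],
    experimental_temps: Sequence[float],
    acclimation_c: float = 15.0,
    halfwidth: float = 1.0,
    trial_days: int = 3,
    divisor: str = "survivor_exposure",
) -> list[ZoneSummary]:
    """Habitat use and per-capita performance for each temperature zone.

    ``divisor`` controls the per-individual denominator of performance:
    ``"survivor_exposure"`` (default) divides each pot's consumed mass by
    its mean number of live animals (amphipod-days / trial length);
    ``"initial_animals"`` divides by the stocked number.
    """
    centers = sorted(float(t) for t in experimental_temps)
    sel = [tr for tr in traces if abs(tr.acclimation_c - acclimation_c) < 1e-9]
    if not sel:
        raise ValueError(f"no traces at acclimation {acclimation_c} degC")
    n_ind = len(sel)
    counts_per_ind = {c: np.zeros(n_ind) for c in centers}
    total_records = 0
    for i, tr in enumerate(sel):
        for temp in tr.temperatures:
            total_records += 1
            z = assign_zone(temp, centers, halfwidth)
            if z is not None:
                counts_per_ind[z][i] += 1

    perf: dict[float, tuple[float | None, float | None]] = {}
    for c in centers:
        vals = []
        for t in trials:
            if t.is_control or abs(t.temp_c - c) > 1e-9 or not t.animals:
                continue
            if any(an.moulted for an in t.animals):
                continue
            ad = amphipod_days(t, trial_days)
            if divisor == "survivor_exposure":
                denom = ad / trial_days
            elif divisor == "initial_animals":
                denom = len(t.animals)
            else:
                raise ValueError(f"unknown divisor {divisor!r}")
            if denom <= 0:
                continue
            consumed = max(0.0, t.leaf_mass_initial_mg - t.leaf_mass_final_mg)
            vals.append(consumed / denom)
        if vals:
            arr = np.asarray(vals)
            se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
            perf[c] = (float(arr.mean()), se)
        else:
            perf[c] = (None, None)

    out = []
    for c in centers:
        per_ind = counts_per_ind[c]
        out.append(
            ZoneSummary(
                zone_center_c=c,
                zone_bounds_c=(c - halfwidth, c + halfwidth),
                habitat_use=float(per_ind.mean()),
                habitat_use_se=float(per_ind.std(ddof=1) / np.sqrt(n_ind))
                if n_ind > 1
                else 0.0,
                performance_mg=perf[c][0],
                performance_se=perf[c][1],
                occupancy_fraction=float(per_ind.sum() / total_records)
                if total_records
                else 0.0,
                n_records=int(per_ind.sum()),
            )
        )
    return out


@dataclass
class ONLSFit:
    alpha: float  # asymptote (performance units)
    beta: float  # curvature; beta < 0 rises to the asymptote
    se_alpha: float
    se_beta: float
    t_stat: float  # beta / se_beta
    df: int  # n - 2
    p: float
    foot_points: np.ndarray  # fitted habitat-use coordinate per datum
    orthogonal_rss: float
    vertical_rss: float  # at the same parameters, y-direction only
    su: float
    sy: float
    n: int
    converged: bool


def _foot_points(
    u: np.ndarray,
    y: np.ndarray,
    alpha: float,
    beta: float,
    su: float,
    sy: float,
    lo: float,
    hi: float,
    n_grid: int = 64,
    n_refine: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-datum projection onto the curve: argmin over u* of the
    standardised squared distance.  Vectorised coarse grid plus golden-
    section refinement; the observed u is kept as a candidate so the
    orthogonal distance never exceeds the vertical one."""

    def g(us):  # us: (n, m)
        return ((u[:, None] - us) / su) ** 2 + (
            (y[:, None] - alpha - beta / us) / sy
        ) ** 2

    grid = np.geomspace(lo, hi, n_grid)
    vals = g(grid[None, :].repeat(u.size, axis=0))
    j = vals.argmin(axis=1)
    a = grid[np.maximum(j - 1, 0)]
    b = grid[np.minimum(j + 1, n_grid - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = g(c[:, None])[:, 0]
    fd = g(d[:, None])[:, 0]
    for _ in range(n_refine):
        left = fc < fd  # minimum lies in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = g(c[:, None])[:, 0]
        fd = g(d[:, None])[:, 0]
    star = (a + b) / 2.0
    f_star = g(star[:, None])[:, 0]
    f_obs = g(u[:, None])[:, 0]  # foot at the observed u: vertical distance
    use_obs = f_obs < f_star
    star = np.where(use_obs, u, star)
    f_star = np.where(use_obs, f_obs, f_star)
    return star, f_star


def onls_fit(
    habitat_use: Sequence[float],
    performance: Sequence[float],
    su: float | None = None,
    sy: float | None = None,
    seed: int = 0,
    n_starts: int = 5,
    floor_frac: float = 1e-6,
) -> ONLSFit:
    """Orthogonal non-linear least squares for ``y = alpha + beta / u``.

    Minimises ``sum_i [(u_i - u*_i)^2 / su^2 + (y_i - alpha - beta/u*_i)^2
    / sy^2]`` over the parameters and the per-datum foot points ``u*_i``
    (bounded below by a small positive floor).  ``su`` and ``sy`` are the
    pooled standard errors of the two axes (unit weights when absent).
    The outer search is Nelder-Mead from an OLS-on-(1/u) initialisation
    plus jittered restarts; standard errors come from the curvature
    (finite-difference Hessian) of the profiled objective, with
    ``t = beta / SE(beta)`` on ``n - 2`` degrees of freedom.
    """
    u = np.asarray(habitat_use, dtype=float)
    y = np.asarray(performance, dtype=float)
    keep = u > 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.sum(~keep)} zone(s) with zero habitat use", stacklevel=2
        )
        u, y = u[keep], y[keep]
    n = u.size
    if n < 3:
        raise ValueError(f"need >= 3 zones with positive habitat use, got {n}")
    su = 1.0 if su is None or not np.isfinite(su) or su <= 0 else float(su)
    sy = 1.0 if sy is None or not np.isfinite(sy) or sy <= 0 else float(sy)
    lo = floor_frac * u.max()
    hi = 3.0 * u.max()

    def objective(theta: np.ndarray) -> float:
        alpha, beta = theta
        _, f = _foot_points(u, y, alpha, beta, su, sy, lo, hi)
        return float(f.sum())

    design = np.column_stack([np.ones(n), 1.0 / u])
    beta0, *_ = np.linalg.lstsq(design, y, rcond=None)
    rng = np.random.default_rng(seed)
    scale = np.abs(beta0) + 1.0
    starts = [beta0] + [
        beta0 + rng.normal(0.0, 0.25 * scale) for _ in range(n_starts - 1)
    ]
    best = None
    converged = False
    for s in starts:
        res = optimize.minimize(
            objective,
            s,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if best is None:  # pragma: no cover - minimize always returns
        raise RuntimeError("ONLS optimisation failed")
    alpha, beta = map(float, best.x)
    feet, fvals = _foot_points(u, y, alpha, beta, su, sy, lo, hi)
    if np.any(feet <= lo * (1 + 1e-9)):
        warnings.warn(
            "foot point driven to the positive floor (model singularity near u=0)",
            stacklevel=2,
        )
    rss = float(fvals.sum())
    vertical = float(np.sum(((y - alpha - beta / u) / sy) ** 2))

    # curvature of the profiled objective -> parameter covariance
    h = np.array([1e-4 * (abs(alpha) + 1.0), 1e-4 * (abs(beta) + 1.0)])
    hess = np.empty((2, 2))
    f0 = rss
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fp = objective(best.x + ei)
                fm = objective(best.x - ei)
                hess[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
            elif j > i:
                fpp = objective(best.x + ei + ej)
                fpm = objective(best.x + ei - ej)
                fmp = objective(best.x - ei + ej)
                fmm = objective(best.x - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4.0 * h[i] * h[j]
                )
    df = n - 2
    sigma2 = rss / df if df > 0 else np.nan
    try:
        cov = 2.0 * sigma2 * np.linalg.inv(hess)
        se_alpha = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_beta = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_alpha = se_beta = float("nan")
    t_stat = beta / se_beta if se_beta > 0 else float("nan")
    p = t_test_p(t_stat, df) if df >= 1 and np.isfinite(t_stat) else float("nan")
    return ONLSFit(
        alpha=alpha,
        beta=beta,
        se_alpha=se_alpha,
        se_beta=se_beta,
        t_stat=float(t_stat),
        df=df,
        p=p,
        foot_points=feet,
        orthogonal_rss=rss,
        vertical_rss=vertical,
        su=su,
        sy=sy,
        n=n,
        converged=converged,
    )


def t_test_p(t_stat: float, df: int) -> float:
    """Two-sided p from Student's t."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t_stat), df))


def onls_significance(fit: ONLSFit) -> tuple[float, float]:
    """(t, two-sided p) for the curvature coefficient beta."""
    if fit.df < 1:
        raise ValueError("no degrees of freedom for a t-test")
    return fit.t_stat, t_test_p(fit.t_stat, fit.df)


def zones_to_frame(zones: Sequence[ZoneSummary], species: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": species,
                "zone_center_c": z.zone_center_c,
                "zone_low_c": z.zone_bounds_c[0],
                "zone_high_c": z.zone_bounds_c[1],
                "habitat_use": z.habitat_use,
                "habitat_use_se": z.habitat_use_se,
                "performance_mg": z.performance_mg,
                "performance_se": z.performance_se,
                "occupancy_fraction": z.occupancy_fraction,
                "n_records": z.n_records,
            }
            for z in zones
        ]
    )
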