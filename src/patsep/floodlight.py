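"""Floodlight (region-of-significance) analysis for age-varying moderation.

Given a fitted interaction model (tensor-product or varying-coefficient),
the moderator is fixed at its 25th and 75th percentile values, covariates
at reference levels (categorical: sample mode; numeric: sample mean), and
the predicted-outcome difference

    d(age) = E[y | age, moderator = Q3] - E[y | age, moderator = Q1]

is evaluated with its pointwise standard error over a fine age grid.  The
regions of significance are the age intervals where the (1 - alpha)
confidence interval of d excludes zero; interval endpoints are linearly
interpolated between grid points.  Pointwise intervals are the default; a
simultaneous (max-|t| over the grid, simulated from the posterior of the
coefficients) option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam.model import GAMResults

__all__ = [
    "DifferenceCurve",
    "RegionResult",
    "Surface",
    "difference_curve",
    "regions_of_significance",
    "contour_surface",
    "plot_floodlight",
]

GRID_N = 201


@dataclass
class DifferenceCurve:
    """Q3 - Q1 moderator contrast across the age grid, with pointwise SEs."""

    age_grid: np.ndarray
    difference: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    q_low_value: float
    q_high_value: float
    moderator: str
    effect_var: str
    alpha: float = 0.05
    critical_value: float = field(default=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.age_grid,
                "difference": self.difference,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class RegionResult:
    """Significant age intervals of a difference curve."""

    intervals: list[tuple[float, float]]
    signs: list[int]  # direction of d within each interval
    alpha: float
    sidedness: str  # "two_sided" | "one_sided"

    def to_dict(self) -> dict:
        return {
            "intervals": [[float(a), float(b)] for a, b in self.intervals],
            "signs": [int(s) for s in self.signs],
            "alpha": self.alpha,
            "sidedness": self.sidedness,
        }


@dataclass
class Surface:
    """Predicted-outcome matrix over an age x moderator grid."""

    age_grid: np.ndarray
    moderator_grid: np.ndarray
    values: np.ndarray  # shape (len(age_grid), len(moderator_grid))
    moderator: str
    effect_var: str

    def to_frame(self) -> pd.DataFrame:
        aa, mm = np.meshgrid(self.age_grid, self.moderator_grid, indexing="ij")
        return pd.DataFrame(
            {
                self.effect_var: aa.ravel(),
                self.moderator: mm.ravel(),
                "predicted": self.values.ravel(),
            }
        )


def _interaction_partner(fit: GAMResults, moderator: str) -> str:
    """The variable the moderator interacts with (the floodlight axis)."""
    for t in fit.model.spec.terms:
        if t.kind in ("tensor", "ti") and moderator in t.vars:
            return t.vars[0] if t.vars[1] == moderator else t.vars[1]
        if t.kind == "varying" and t.by == moderator:
            return t.vars[0]
        if t.kind == "varying" and t.vars[0] == moderator:
            return t.by
        if t.kind == "product" and moderator in t.vars:
            return t.vars[0] if t.vars[1] == moderator else t.vars[1]
    raise ValueError(
        f"fit has no interaction term involving moderator {moderator!r}"
    )


def _reference_row(data: pd.DataFrame, skip: set[str]) -> dict:
    """Covariate reference levels: mode for categoricals, mean for numerics."""
    ref = {}
    for col in data.columns:
        if col in skip:
            continue
        if pd.api.types.is_numeric_dtype(data[col]):
            ref[col] = float(data[col].mean())
        else:
            ref[col] = data[col].mode().iloc[0]
    return ref


def _grid_frame(fit: GAMResults, effect_var: str, moderator: str, grid, mvalue) -> pd.DataFrame:
    data = fit.model.data
    ref = _reference_row(data, skip={fit.model.spec.outcome, effect_var, moderator})
    df = pd.DataFrame({effect_var: grid})
    df[moderator] = mvalue
    for k, v in ref.items():
        df[k] = v
    return df


def difference_curve(
    fit: GAMResults,
    moderator: str,
    data: pd.DataFrame | None = None,
    grid_n: int = GRID_N,
    quantiles: tuple[float, float] = (0.25, 0.75),
    alpha: float = 0.05,
    simultaneous: bool = False,
    n_sim: int = 10_000,
    seed: int = 0,
) -> DifferenceCurve:
    """Predicted-outcome contrast between high and low moderator values.

    The moderator is set to its `quantiles` (default Q1/Q3) in the training
    data (or `data` when given); the other interaction variable sweeps a
    `grid_n`-point grid over its observed range.  With `simultaneous`, the
    critical value is the max-|t| quantile simulated from the coefficient
    posterior instead of the pointwise normal quantile.
    """
    data = fit.model.data if data is None else data
    effect_var = _interaction_partner(fit, moderator)
    q_low, q_high = (float(data[moderator].quantile(q)) for q in quantiles)
    if q_high == q_low:
        raise ValueError(
            f"degenerate contrast: moderator {moderator!r} quartiles coincide"
        )
    lo, hi = float(data[effect_var].min()), float(data[effect_var].max())
    grid = np.linspace(lo, hi, grid_n)

    X_hi = fit.design_row(_grid_frame(fit, effect_var, moderator, grid, q_high))
    X_lo = fit.design_row(_grid_frame(fit, effect_var, moderator, grid, q_low))
    C = X_hi - X_lo
    d = C @ fit.params
    V = fit.cov_params()
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, V, C), 0.0))

    if simultaneous:
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(V.shape[0]) * np.trace(V) / V.shape[0])
        sims = C @ (L @ rng.standard_normal((V.shape[0], n_sim)))
        with np.errstate(divide="ignore", invalid="ignore"):
            tmax = np.nanmax(np.abs(sims) / se[:, None], axis=0)
        crit = float(np.quantile(tmax, 1.0 - alpha))
    else:
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))

    return DifferenceCurve(
        age_grid=grid,
        difference=d,
        se=se,
        ci_low=d - crit * se,
        ci_high=d + crit * se,
        q_low_value=q_low,
        q_high_value=q_high,
        moderator=moderator,
        effect_var=effect_var,
        alpha=alpha,
        critical_value=crit,
    )


def regions_of_significance(
    curve: DifferenceCurve,
    alpha: float | None = None,
    sidedness: str = "two_sided",
    interpolate: bool = True,
) -> RegionResult:
    """Age intervals where the confidence interval of d excludes zero.

    two_sided: |d|/se > z_{1-alpha/2}; one_sided: |d|/se > z_{1-alpha}
    (the direction within each detected interval is reported via `signs`).
    Endpoints are linearly interpolated at the significance crossing unless
    `interpolate` is disabled, in which case grid values are reported.
    """
    if sidedness not in ("two_sided", "one_sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    alpha = curve.alpha if alpha is None else alpha
    if curve.critical_value and alpha == curve.alpha and sidedness == "two_sided":
        crit = curve.critical_value  # honour a simultaneous band if present
    else:
        crit = stats.norm.ppf(1.0 - alpha / 2.0 if sidedness == "two_sided" else 1.0 - alpha)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(curve.se > 0, curve.difference / curve.se, 0.0)
    margin = np.abs(t) - crit  # > 0 where significant
    sig = margin > 0

    intervals: list[tuple[float, float]] = []
    signs: list[int] = []
    grid = curve.age_grid
    dsign = np.sign(curve.difference)
    i = 0
    n = len(grid)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        # extend the run; a sign change of d splits the interval
        while j + 1 < n and sig[j + 1] and dsign[j + 1] == dsign[i]:
            j += 1
        lo, hi = grid[i], grid[j]
        if interpolate:
            if i > 0:
                lo = _crossing(grid[i - 1], grid[i], margin[i - 1], margin[i])
            if j + 1 < n:
                hi = _crossing(grid[j], grid[j + 1], margin[j], margin[j + 1])
        intervals.append((float(lo), float(hi)))
        signs.append(int(np.sign(curve.difference[i : j + 1].mean())))
        i = j + 1
    return RegionResult(intervals=intervals, signs=signs, alpha=alpha, sidedness=sidedness)


def _crossing(x0: float, x1: float, m0: float, m1: float) -> float:
    """Linear interpolation of the zero crossing of the margin."""
    if m1 == m0:
        return x1
    w = -m0 / (m1 - m0)
    return float(x0 + np.clip(w, 0.0, 1.0) * (x1 - x0))


def contour_surface(
    fit: GAMResults,
    moderator: str,
    age_range: tuple[float, float] | None = None,
    moderator_range: tuple[float, float] | None = None,
    grid_n: int = 50,
    effect_var: str | None = None,
) -> Surface:
    """Predicted-outcome surface over the age x moderator grid,
    covariates fixed at reference levels.

    Works for additive (no-interaction) fits too; the effect axis is then
    the first other continuous model variable unless given explicitly."""
    data = fit.model.data
    if effect_var is None:
        try:
            effect_var = _interaction_partner(fit, moderator)
        except ValueError:
            effect_var = next(
                v
                for v in fit.model.spec.variables
                if v != moderator and pd.api.types.is_numeric_dtype(data[v])
            )
    if age_range is None:
        age_range = (float(data[effect_var].min()), float(data[effect_var].max()))
    if moderator_range is None:
        moderator_range = (float(data[moderator].min()), float(data[moderator].max()))
    if age_range[1] <= age_range[0] or moderator_range[1] <= moderator_range[0]:
        raise ValueError("empty grid range")
    ages = np.linspace(*age_range, grid_n)
    mods = np.linspace(*moderator_range, grid_n)
    values = np.empty((grid_n, grid_n))
    for j, m in enumerate(mods):
        df = _grid_frame(fit, effect_var, moderator, ages, m)
        values[:, j] = fit.predict(df)
    return Surface(
        age_grid=ages,
        moderator_grid=mods,
        values=values,
        moderator=moderator,
        effect_var=effect_var,
    )


def plot_floodlight(surface: Surface, curve: DifferenceCurve, regions: RegionResult | None = None):
    """Minimal two-panel figure: contour surface + difference curve."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(9, 3.5), gridspec_kw={"width_ratios": [2, 1]}
    )
    cs = ax1.contourf(
        surface.age_grid, surface.moderator_grid, surface.values.T, levels=12
    )
    fig.colorbar(cs, ax=ax1)
    ax1.set_xlabel(surface.effect_var)
    ax1.set_ylabel(surface.moderator)
    ax2.plot(curve.age_grid, curve.difference, color="k")
    ax2.fill_between(curve.age_grid, curve.ci_low, curve.ci_high, alpha=0.3)
    ax2.axhline(0.0, color="grey", lw=0.8)
    if regions:
        for lo, hi in regions.intervals:
            ax2.axvspan(lo, hi, color="red", alpha=0.15)
    ax2.set_xlabel(curve.effect_var)
    ax2.set_ylabel(f"d ({curve.moderator} Q3-Q1)")
    fig.tight_layout()
    return fig
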