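"""Smooth-versus-linear model selection.

Two ingredients, following the usual additive-model workflow:

* the Akaike information criterion of the two penalized (REML) fits;
* an analysis-of-deviance F test of the extra basis dimensions.

For the F test both models are refit *unpenalized* (smoothing parameters
fixed at zero), making the comparison a classical nested linear-model
test:

    F = (deviance_restricted - deviance_full) / (df_full - df_restricted)
        ------------------------------------------------------------------
                              scale_full

with p from F(delta_df, n - df_full).  Under a Gaussian null this test is
exactly calibrated, which a test based on the REML-adaptive effective
degrees of freedom is not (the smoothing parameters are chosen from the
same data, inflating the apparent evidence).

The richer model is selected only when it both lowers the AIC and the
deviance test is significant; otherwise the more parsimonious model is
kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .model import GAMResults

__all__ = ["ComparisonResult", "compare_models"]


@dataclass
class ComparisonResult:
    delta_aic: float  # AIC(full) - AIC(restricted); negative favours full
    f_statistic: float
    df_num: float  # numerator df of the exact nested test
    delta_edf: float  # effective-df difference of the penalized fits
    p_value: float
    selected: str  # "linear" (restricted) or "smooth" (full)
    degenerate: bool = False

    def __str__(self) -> str:
        tag = " (degenerate)" if self.degenerate else ""
        return (
            f"dAIC={self.delta_aic:+.2f}  F={self.f_statistic:.3f} "
            f"(df={self.df_num:.0f})  p={self.p_value:.4f}  "
            f"selected={self.selected}{tag}"
        )


def _unpenalized(fit: GAMResults) -> GAMResults:
    n_pen = sum(1 for b in fit.model.blocks if b.S is not None)
    if n_pen == 0:
        return fit
    return fit.model.fit(lambdas=[0.0] * n_pen)


def compare_models(
    fit_restricted: GAMResults,
    fit_full: GAMResults,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare a restricted (e.g. linear) against a nested full (smooth) fit.

    Both fits must share the outcome and data.  A non-positive df
    increment makes the comparison degenerate and the restricted model is
    kept (ties go to parsimony).
    """
    if fit_restricted.model.spec.outcome != fit_full.model.spec.outcome:
        raise ValueError("fits have different outcomes")
    if fit_restricted.nobs != fit_full.nobs:
        raise ValueError("fits use different numbers of observations")

    delta_aic = fit_full.aic - fit_restricted.aic
    delta_edf = fit_full.total_edf - fit_restricted.total_edf
    df_num = fit_full.model.p - fit_restricted.model.p
    if df_num <= 0:
        return ComparisonResult(
            delta_aic=delta_aic,
            f_statistic=0.0,
            df_num=float(df_num),
            delta_edf=delta_edf,
            p_value=1.0,
            selected="linear",
            degenerate=True,
        )
    r0 = _unpenalized(fit_restricted)
    f0 = _unpenalized(fit_full)
    delta_dev = r0.deviance - f0.deviance
    df_den = fit_full.nobs - fit_full.model.p
    scale_full = f0.deviance / df_den
    f_stat = max(delta_dev, 0.0) / df_num / scale_full
    p = float(stats.f.sf(f_stat, df_num, df_den))
    selected = "smooth" if (delta_aic < 0.0 and p < alpha) else "linear"
    return ComparisonResult(
        delta_aic=delta_aic,
        f_statistic=float(f_stat),
        df_num=float(df_num),
        delta_edf=float(delta_edf),
        p_value=p,
        selected=selected,
    )
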