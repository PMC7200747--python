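"""Fixed-effects power and sample-size from an R-squared effect size.

The effect size is converted to Cohen's f2 = R2 / (1 - R2); power comes
from the noncentral F distribution with noncentrality f2 * N.  Two
denominator-df conventions are provided: a one-way comparison over
`n_groups` groups (v = N - n_groups) and a multiple-regression test of
u = n_groups - 1 predictors (v = N - u - 1).  With u = n_groups - 1 the
two coincide; both are reported so the convention is explicit.
"""

from __future__ import annotations

from scipy import stats

__all__ = ["power_from_n", "power_sample_size"]

_MAX_N = 10**6


def power_from_n(
    n: int, r_squared: float, alpha: float, df_num: int, df_den: int
) -> float:
    """Power of the fixed-effects F test at total sample size n."""
    if df_den <= 0:
        return 0.0
    f2 = r_squared / (1.0 - r_squared)
    ncp = f2 * n
    fcrit = stats.f.isf(alpha, df_num, df_den)
    return float(stats.ncf.sf(fcrit, df_num, df_den, ncp))


def power_sample_size(
    r_squared: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_groups: int = 3,
    convention: str = "anova",
) -> int:
    """Smallest total N whose noncentral-F power reaches the target.

    convention "anova": numerator df n_groups - 1, denominator N - n_groups;
    convention "regression": u = n_groups - 1 predictors, denominator
    N - u - 1 (identical here, provided for explicitness).
    """
    if not 0.0 < r_squared < 1.0:
        raise ValueError("r_squared must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if convention not in ("anova", "regression"):
        raise ValueError(f"unknown convention {convention!r}")
    u = n_groups - 1
    n = n_groups + 1  # minimal admissible design with a positive error df
    while n <= _MAX_N:
        v = n - n_groups if convention == "anova" else n - u - 1
        if v > 0 and power_from_n(n, r_squared, alpha, u, v) >= power:
            return n
        n += 1
    raise ValueError(f"target power not attainable with N <= {_MAX_N}")
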