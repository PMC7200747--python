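"""Model / Results classes for Gaussian penalized-spline additive models.

The model formula uses a compact term grammar::

    "ldi ~ s(age) + dg_left_vol + sex + education"          additive smooth
    "ldi ~ te(dg_left_vol, age) + sex + education"          tensor interaction
    "ldi ~ s(age) + s(age, by=dg_left_vol) + sex"           varying coefficient
    "ldi ~ s(age) + vol + act + vol:act"                    linear interaction

Smooths use cubic B-spline bases with second-difference penalties; tensor
products use the row-wise Kronecker of two marginal bases penalized by
S1 (x) I + I (x) S2 under a single smoothing parameter.  Smoothing
parameters are chosen by restricted maximum likelihood (default) or GCV.
The coefficient covariance is the Bayesian posterior covariance
(X'X + S)^-1 * scale, and per-term effective degrees of freedom are the
block traces of (X'X + S)^-1 X'X.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .basis import SplineBasis, centering_transform, difference_penalty, row_kron

__all__ = ["Term", "ModelSpec", "parse_formula", "GAM", "GAMResults", "fit_model"]

DEFAULT_K_SMOOTH = 10
DEFAULT_K_TENSOR = 5


@dataclass(frozen=True)
class Term:
    """One model term.

    kind: "linear" | "product" | "smooth" | "tensor" | "varying"
    vars: the variable(s) involved (product: the two factors;
    varying: (smooth_var,) with `by` the multiplier).
    """

    kind: str
    vars: tuple[str, ...]
    k: tuple[int, ...] = ()
    by: str | None = None

    @property
    def label(self) -> str:
        if self.kind == "linear":
            return self.vars[0]
        if self.kind == "product":
            return ":".join(self.vars)
        if self.kind == "smooth":
            return f"s({self.vars[0]})"
        if self.kind == "tensor":
            return f"te({self.vars[0]},{self.vars[1]})"
        if self.kind == "ti":
            return f"ti({self.vars[0]},{self.vars[1]})"
        return f"s({self.vars[0]},by={self.by})"

    @property
    def penalized(self) -> bool:
        return self.kind in ("smooth", "tensor", "ti", "varying")


@dataclass
class ModelSpec:
    """Declarative model description: outcome and ordered terms."""

    outcome: str
    terms: list[Term]

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            key = (t.kind, t.vars, t.by)
            if key in seen:
                raise ValueError(f"duplicate term {t.label}")
            seen.add(key)
        # a variable may not appear as both a linear and a smooth main effect
        linear = {t.vars[0] for t in self.terms if t.kind == "linear"}
        smooth = {t.vars[0] for t in self.terms if t.kind == "smooth"}
        clash = linear & smooth
        if clash:
            raise ValueError(f"variable(s) in both linear and smooth terms: {sorted(clash)}")

    @property
    def variables(self) -> list[str]:
        out: list[str] = []
        for t in self.terms:
            for v in t.vars:
                if v not in out:
                    out.append(v)
            if t.by and t.by not in out:
                out.append(t.by)
        return out


_SMOOTH_RE = re.compile(r"^s\(\s*([^,)]+?)\s*(?:,\s*(.*?))?\)$")
_TENSOR_RE = re.compile(r"^(te|ti)\(\s*([^,)]+?)\s*,\s*([^,)]+?)\s*(?:,\s*(.*?))?\)$")


def _parse_opts(rest: str | None) -> dict[str, str]:
    opts: dict[str, str] = {}
    if rest:
        for part in rest.split(","):
            if "=" not in part:
                raise ValueError(f"malformed smooth option {part!r}")
            key, val = (p.strip() for p in part.split("=", 1))
            opts[key] = val
    return opts


def parse_formula(formula: str) -> ModelSpec:
    """Parse the compact term grammar into a ModelSpec."""
    if "~" not in formula:
        raise ValueError("formula needs '~'")
    lhs, rhs = (side.strip() for side in formula.split("~", 1))
    terms: list[Term] = []
    for raw in re.split(r"\+(?![^()]*\))", rhs):
        token = raw.strip()
        if not token or token == "1":
            continue
        m = _SMOOTH_RE.match(token)
        if m:
            var, opts = m.group(1), _parse_opts(m.group(2))
            k = int(opts.pop("k", DEFAULT_K_SMOOTH))
            by = opts.pop("by", None)
            if opts:
                raise ValueError(f"unknown smooth options {sorted(opts)}")
            kind = "varying" if by else "smooth"
            terms.append(Term(kind, (var,), (k,), by))
            continue
        m = _TENSOR_RE.match(token)
        if m:
            kind, v1, v2 = m.group(1), m.group(2), m.group(3)
            opts = _parse_opts(m.group(4))
            k = int(opts.pop("k", DEFAULT_K_TENSOR))
            if opts:
                raise ValueError(f"unknown tensor options {sorted(opts)}")
            terms.append(Term("tensor" if kind == "te" else "ti", (v1, v2), (k, k)))
            continue
        if ":" in token:
            a, b = (p.strip() for p in token.split(":", 1))
            terms.append(Term("product", (a, b)))
            continue
        if not re.match(r"^[A-Za-z_]\w*$", token):
            raise ValueError(f"cannot parse term {token!r}")
        terms.append(Term("linear", (token,)))
    return ModelSpec(outcome=lhs, terms=terms)


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _Block:
    """Realized design block for one term (plus the intercept block)."""

    label: str
    sl: slice
    term: Term | None = None
    S: np.ndarray | None = None  # penalty in the reparameterized basis
    rank: int = 0
    bases: tuple[SplineBasis, ...] = ()
    Z: np.ndarray | None = None  # centering reparameterization
    levels: tuple | None = None  # categorical linear term levels
    colnames: tuple[str, ...] = ()

    def build(self, df: pd.DataFrame) -> np.ndarray:
        t = self.term
        if t is None:
            return np.ones((len(df), 1))
        if t.kind == "linear":
            col = df[t.vars[0]]
            if self.levels is not None:
                codes = pd.Categorical(col, categories=self.levels)
                if codes.isna().any():
                    raise ValueError(
                        f"unknown level in {t.vars[0]!r} (training levels {self.levels})"
                    )
                dummies = np.zeros((len(df), len(self.levels) - 1))
                for j, lev in enumerate(self.levels[1:]):
                    dummies[:, j] = (codes == lev).astype(float)
                return dummies
            return np.asarray(col, dtype=float)[:, None]
        if t.kind == "product":
            a = np.asarray(df[t.vars[0]], dtype=float)
            b = np.asarray(df[t.vars[1]], dtype=float)
            return (a * b)[:, None]
        if t.kind == "smooth":
            B = self.bases[0].design(df[t.vars[0]].to_numpy())
            return B @ self.Z
        if t.kind == "tensor":
            B1 = self.bases[0].design(df[t.vars[0]].to_numpy())
            B2 = self.bases[1].design(df[t.vars[1]].to_numpy())
            return row_kron(B1, B2) @ self.Z
        if t.kind == "ti":
            Z1, Z2 = self.Z
            B1 = self.bases[0].design(df[t.vars[0]].to_numpy()) @ Z1
            B2 = self.bases[1].design(df[t.vars[1]].to_numpy()) @ Z2
            return row_kron(B1, B2)
        # varying coefficient: by-variable times smooth basis of vars[0]
        B = self.bases[0].design(df[t.vars[0]].to_numpy())
        by = np.asarray(df[t.by], dtype=float)
        return B * by[:, None]

    def out_of_range(self, df: pd.DataFrame) -> np.ndarray:
        flags = np.zeros(len(df), dtype=bool)
        if self.term is None:
            return flags
        for var, basis in zip(self.term.vars, self.bases):
            flags |= basis.out_of_range(df[var].to_numpy())
        return flags


def _build_blocks(data: pd.DataFrame, spec: ModelSpec) -> tuple[list[_Block], np.ndarray]:
    blocks: list[_Block] = [_Block(label="(intercept)", sl=slice(0, 1), colnames=("(intercept)",))]
    pos = 1
    for t in spec.terms:
        for v in (*t.vars, *((t.by,) if t.by else ())):
            if v not in data.columns:
                raise ValueError(f"variable {v!r} not in data")
        if t.kind == "linear" and not pd.api.types.is_numeric_dtype(data[t.vars[0]]):
            levels = tuple(sorted(pd.unique(data[t.vars[0]].astype(str))))
            ncol = len(levels) - 1
            if ncol == 0:
                raise ValueError(f"categorical variable {t.vars[0]!r} is constant")
            blk = _Block(
                label=t.label,
                sl=slice(pos, pos + ncol),
                term=t,
                levels=levels,
                colnames=tuple(f"{t.vars[0]}[{lev}]" for lev in levels[1:]),
            )
        elif t.kind in ("linear", "product"):
            blk = _Block(
                label=t.label, sl=slice(pos, pos + 1), term=t, colnames=(t.label,)
            )
        elif t.kind == "smooth":
            basis = SplineBasis.from_data(data[t.vars[0]].to_numpy(), t.k[0])
            B = basis.design(data[t.vars[0]].to_numpy())
            Z = centering_transform(B.sum(axis=0))
            S = Z.T @ basis.penalty() @ Z
            ncol = Z.shape[1]
            blk = _Block(
                label=t.label,
                sl=slice(pos, pos + ncol),
                term=t,
                S=S,
                rank=t.k[0] - 2,
                bases=(basis,),
                Z=Z,
                colnames=tuple(f"{t.label}.{j}" for j in range(ncol)),
            )
        elif t.kind == "tensor":
            b1 = SplineBasis.from_data(data[t.vars[0]].to_numpy(), t.k[0])
            b2 = SplineBasis.from_data(data[t.vars[1]].to_numpy(), t.k[1])
            T = row_kron(
                b1.design(data[t.vars[0]].to_numpy()), b2.design(data[t.vars[1]].to_numpy())
            )
            Z = centering_transform(T.sum(axis=0))
            S_raw = np.kron(b1.penalty(), np.eye(t.k[1])) + np.kron(np.eye(t.k[0]), b2.penalty())
            S = Z.T @ S_raw @ Z
            rank = int(np.linalg.matrix_rank(S))
            ncol = Z.shape[1]
            blk = _Block(
                label=t.label,
                sl=slice(pos, pos + ncol),
                term=t,
                S=S,
                rank=rank,
                bases=(b1, b2),
                Z=Z,
                colnames=tuple(f"{t.label}.{j}" for j in range(ncol)),
            )
        elif t.kind == "ti":
            # pure-interaction tensor: each margin is sum-to-zero constrained
            # first, so the product space contains no main effects
            b1 = SplineBasis.from_data(data[t.vars[0]].to_numpy(), t.k[0])
            b2 = SplineBasis.from_data(data[t.vars[1]].to_numpy(), t.k[1])
            B1 = b1.design(data[t.vars[0]].to_numpy())
            B2 = b2.design(data[t.vars[1]].to_numpy())
            Z1 = centering_transform(B1.sum(axis=0))
            Z2 = centering_transform(B2.sum(axis=0))
            S1c, S2c = Z1.T @ b1.penalty() @ Z1, Z2.T @ b2.penalty() @ Z2
            S = np.kron(S1c, np.eye(t.k[1] - 1)) + np.kron(np.eye(t.k[0] - 1), S2c)
            rank = int(np.linalg.matrix_rank(S))
            ncol = (t.k[0] - 1) * (t.k[1] - 1)
            blk = _Block(
                label=t.label,
                sl=slice(pos, pos + ncol),
                term=t,
                S=S,
                rank=rank,
                bases=(b1, b2),
                Z=(Z1, Z2),
                colnames=tuple(f"{t.label}.{j}" for j in range(ncol)),
            )
        elif t.kind == "varying":
            basis = SplineBasis.from_data(data[t.vars[0]].to_numpy(), t.k[0])
            S = basis.penalty()
            ncol = t.k[0]
            blk = _Block(
                label=t.label,
                sl=slice(pos, pos + ncol),
                term=t,
                S=S,
                rank=t.k[0] - 2,
                bases=(basis,),
                colnames=tuple(f"{t.label}.{j}" for j in range(ncol)),
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown term kind {t.kind}")
        blocks.append(blk)
        pos = blk.sl.stop
    X = np.hstack([b.build(data) for b in blocks])
    return blocks, X


# ---------------------------------------------------------------------------
# model


class GAM:
    """Gaussian additive model with penalized-spline terms.

    Parameters
    ----------
    data : DataFrame with the outcome and all term variables.
    spec : ModelSpec or formula string (see module docstring).
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | str):
        if isinstance(spec, str):
            spec = parse_formula(spec)
        self.spec = spec
        if spec.outcome not in data.columns:
            raise ValueError(f"outcome {spec.outcome!r} not in data")
        absent = [v for v in spec.variables if v not in data.columns]
        if absent:
            raise ValueError(f"variable(s) {absent} not in data")
        cols = [spec.outcome] + spec.variables
        self.data = data[cols].reset_index(drop=True)
        for c in cols:
            if pd.api.types.is_numeric_dtype(self.data[c]) and not np.isfinite(
                self.data[c].to_numpy(dtype=float)
            ).all():
                raise ValueError(f"non-finite values in column {c!r}")
        self.y = self.data[spec.outcome].to_numpy(dtype=float)
        self.blocks, self.X = _build_blocks(self.data, spec)
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError(
                f"n={self.n} must exceed total basis dimension p={self.p}"
            )
        self._check_rank()

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "GAM":
        return cls(data, formula)

    def _check_rank(self) -> None:
        sv = np.linalg.svd(self.X, compute_uv=False)
        tol = sv[0] * max(self.n, self.p) * np.finfo(float).eps
        if sv[-1] < tol:
            # identify offending terms by dropping-and-retesting
            bad = []
            for b in self.blocks[1:]:
                sub = np.delete(np.arange(self.p), np.r_[b.sl])
                sub_sv = np.linalg.svd(self.X[:, sub], compute_uv=False)
                if sub_sv[-1] >= sub_sv[0] * max(self.n, len(sub)) * np.finfo(float).eps:
                    bad.append(b.label)
            raise ValueError(
                "rank-deficient design; collinear term(s): "
                + (", ".join(bad) if bad else "(undetermined)")
            )

    # -- fitting -----------------------------------------------------------

    def _assemble_penalty(self, lambdas: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lam, b in zip(lambdas, self._penalized_blocks()):
            S[b.sl, b.sl] += lam * b.S
        return S

    def _penalized_blocks(self) -> list[_Block]:
        return [b for b in self.blocks if b.S is not None]

    def fit(
        self,
        method: str = "reml",
        lambdas: Sequence[float] | None = None,
    ) -> "GAMResults":
        """Fit the model; smoothing parameters by REML (default) or GCV,
        or fixed if `lambdas` is given."""
        pen = self._penalized_blocks()
        xtx = self.X.T @ self.X
        xty = self.X.T @ self.y
        yty = float(self.y @ self.y)
        n = self.n
        m_p = self.p - sum(b.rank for b in pen)

        def solve(lams: np.ndarray):
            A = xtx + self._assemble_penalty(lams)
            jitter = 0.0
            for _ in range(4):
                try:
                    c, low = linalg.cho_factor(
                        A + jitter * np.eye(self.p), lower=True
                    )
                    break
                except np.linalg.LinAlgError:
                    jitter = max(jitter * 10, 1e-10 * np.trace(A) / self.p)
            beta = linalg.cho_solve((c, low), xty)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            return beta, (c, low), logdet

        def solve_augmented(lams: np.ndarray) -> np.ndarray:
            """Final-coefficient solve via the augmented least-squares system
            [X; sqrt(lam) E] with E'E = S -- avoids the accuracy loss of the
            normal equations when a smoothing parameter is very large."""
            rows = []
            for lam, b in zip(lams, pen):
                w, U = np.linalg.eigh(b.S)
                keep = w > max(w.max(), 0.0) * 1e-12
                E = (np.sqrt(np.maximum(w[keep] * lam, 0.0))[:, None] * U[:, keep].T)
                block_rows = np.zeros((E.shape[0], self.p))
                block_rows[:, b.sl] = E
                rows.append(block_rows)
            X_aug = np.vstack([self.X, *rows])
            y_aug = np.concatenate([self.y, np.zeros(X_aug.shape[0] - n)])
            return np.linalg.lstsq(X_aug, y_aug, rcond=None)[0]

        def criterion(loglams: np.ndarray) -> float:
            lams = np.exp(np.clip(loglams, -25.0, 25.0))
            beta, chol, logdet = solve(lams)
            if method == "reml":
                d_pen = max(yty - float(beta @ xty), 1e-300)
                val = (n - m_p) * np.log(d_pen) + logdet
                val -= sum(
                    b.rank * np.log(lam) for b, lam in zip(pen, lams)
                )
                return float(val)
            # GCV
            Ainv = linalg.cho_solve(chol, np.eye(self.p))
            tr_f = float(np.einsum("ij,ji->", Ainv, xtx))
            resid = self.y - self.X @ beta
            rss = float(resid @ resid)
            return float(n * rss / (n - tr_f) ** 2)

        if not pen:
            opt_lams = np.array([])
        elif lambdas is not None:
            opt_lams = np.asarray(lambdas, dtype=float)
            if len(opt_lams) != len(pen):
                raise ValueError(
                    f"expected {len(pen)} smoothing parameters, got {len(opt_lams)}"
                )
        else:
            best = None
            for start in (0.0, 6.0, -6.0):
                x0 = np.full(len(pen), start)
                res = optimize.minimize(
                    criterion,
                    x0,
                    method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400 * len(pen)},
                )
                if best is None or res.fun < best.fun:
                    best = res
            opt_lams = np.exp(np.clip(best.x, -25.0, 25.0))

        if len(opt_lams):
            _, chol, _ = solve(opt_lams)
            beta = solve_augmented(opt_lams)
        else:
            chol = linalg.cho_factor(xtx, lower=True)
            beta = linalg.cho_solve(chol, xty)
        Ainv = linalg.cho_solve(chol, np.eye(self.p))
        diag_f = np.einsum("ij,ji->i", Ainv, xtx)
        fitted = self.X @ beta
        resid = self.y - fitted
        rss = float(resid @ resid)
        total_edf = float(diag_f.sum())
        scale = rss / (n - total_edf)
        edf_by_term = {
            b.label: float(diag_f[b.sl].sum()) for b in self.blocks
        }
        sigma2_ml = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
        aic = -2.0 * loglik + 2.0 * (total_edf + 1.0)
        cov = Ainv * scale
        cov = 0.5 * (cov + cov.T)
        lam_map = {b.label: float(l) for b, l in zip(pen, opt_lams)}
        return GAMResults(
            model=self,
            params=beta,
            cov_params_=cov,
            edf_by_term=edf_by_term,
            total_edf=total_edf,
            aic=float(aic),
            deviance=rss,
            scale=float(scale),
            loglik=float(loglik),
            smoothing_params=lam_map,
            fittedvalues=fitted,
            method=method,
        )


def fit_model(data: pd.DataFrame, spec: ModelSpec | str, **kwargs) -> "GAMResults":
    """Convenience wrapper: build and fit in one call."""
    return GAM(data, spec).fit(**kwargs)


# ---------------------------------------------------------------------------
# results


@dataclass
class GAMResults:
    """Fitted state of a GAM: estimates, uncertainty and diagnostics."""

    model: GAM
    params: np.ndarray
    cov_params_: np.ndarray
    edf_by_term: dict[str, float]
    total_edf: float
    aic: float
    deviance: float
    scale: float
    loglik: float
    smoothing_params: dict[str, float]
    fittedvalues: np.ndarray
    method: str

    def cov_params(self) -> np.ndarray:
        return self.cov_params_

    @property
    def nobs(self) -> int:
        return self.model.n

    @property
    def residual_df(self) -> float:
        return self.model.n - self.total_edf

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    # -- prediction --------------------------------------------------------

    def _design(self, newdata: pd.DataFrame, include_terms=None) -> np.ndarray:
        cols = []
        for b in self.model.blocks:
            if include_terms is not None and b.term is not None and b.label not in include_terms:
                cols.append(np.zeros((len(newdata), b.sl.stop - b.sl.start)))
            else:
                cols.append(b.build(newdata))
        return np.hstack(cols)

    def predict(
        self,
        newdata: pd.DataFrame | None = None,
        se: bool = False,
        include_terms: Sequence[str] | None = None,
    ):
        """Predicted mean (and pointwise SE) for new rows.

        Rows requiring evaluation of a spline basis outside its training
        range are flagged (`extrapolated`), not rejected.
        """
        if newdata is None:
            newdata = self.model.data
        X = self._design(newdata, include_terms)
        mean = X @ self.params
        if not se:
            return mean
        var = np.einsum("ij,jk,ik->i", X, self.cov_params_, X)
        flags = np.zeros(len(newdata), dtype=bool)
        for b in self.model.blocks:
            if b.bases:
                flags |= b.out_of_range(newdata)
        return {
            "mean": mean,
            "se": np.sqrt(np.maximum(var, 0.0)),
            "extrapolated": flags,
        }

    def design_row(self, newdata: pd.DataFrame) -> np.ndarray:
        """Full design matrix for new rows (for custom contrasts)."""
        return self._design(newdata)

    # -- inference ---------------------------------------------------------

    def term_test(self, label: str) -> dict[str, float]:
        """Wald test of a term against zero.

        The statistic is computed on the term's fitted values f = X_j b_j
        with their posterior covariance V_f = X_j V_j X_j', using a
        pseudo-inverse truncated to rank round(edf) (at least 1) in the
        directions of largest fitted-value variance — the least-shrunk
        directions, i.e. those the penalized fit can actually express —
        and referred to F(rank, n - total_edf).  For unpenalized terms
        this reduces to the ordinary full-rank Wald F test.
        """
        block = next((b for b in self.model.blocks if b.label == label), None)
        if block is None:
            raise KeyError(f"no term {label!r}; have {[b.label for b in self.model.blocks]}")
        beta = self.params[block.sl]
        V = self.cov_params_[block.sl, block.sl]
        edf = self.edf_by_term[label]
        if block.S is None:
            r = beta.size
        else:
            r = int(max(1, min(round(edf), beta.size)))
        # work in the fitted-value metric: R from the thin QR of X_j
        Xj = self.model.X[:, block.sl]
        R = np.linalg.qr(Xj, mode="r")
        M = R @ V @ R.T
        M = 0.5 * (M + M.T)
        fcoord = R @ beta
        w, U = np.linalg.eigh(M)
        order = np.argsort(w)[::-1]
        w, U = w[order][:r], U[:, order][:, :r]
        w = np.maximum(w, (w[0] if w.size else 1.0) * 1e-12)
        stat = float(((U.T @ fcoord) ** 2 / w).sum())
        fstat = stat / r
        df_den = max(self.residual_df, 1.0)
        pval = float(stats.f.sf(fstat, r, df_den))
        return {"f": fstat, "df_num": float(r), "df_den": df_den, "p": pval, "edf": edf}

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Gaussian additive model: {spec.outcome} ~ "
            + " + ".join(t.label for t in spec.terms),
            f"n = {self.nobs}   edf(total) = {self.total_edf:.2f}   "
            f"AIC = {self.aic:.2f}   deviance = {self.deviance:.4g}   "
            f"scale = {self.scale:.4g}   ({self.method})",
            "",
            f"{'term':<28}{'edf':>8}{'F':>10}{'p':>12}",
        ]
        for t in spec.terms:
            tt = self.term_test(t.label)
            p = tt["p"]
            pstr = f"{p:.2e}" if p < 1e-4 else f"{p:.4f}"
            lines.append(
                f"{t.label:<28}{tt['edf']:>8.2f}{tt['f']:>10.2f}{pstr:>12}"
            )
        if self.smoothing_params:
            lam = ", ".join(f"{k}: {v:.3g}" for k, v in self.smoothing_params.items())
            lines.append(f"\nsmoothing parameters: {lam}")
        return "\n".join(lines)
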