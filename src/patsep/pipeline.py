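"""Full analysis pipeline over a cohort table.

Reproduces the study's model sequence for every subfield-hemisphere and
predictor kind (volume, activation):

* Model 1 - main effects: linear predictor + smooth age;
* Model 2 - tensor-product smooth(predictor) x smooth(age) interaction;
* Model 3 - varying-coefficient linear(predictor) x smooth(age) interaction;

each with sex and education as linear covariates, followed by smooth-vs-
linear selection (AIC + deviance F test, most parsimonious on a tie) and a
floodlight region-of-significance analysis for every selected interaction
model.  Additional stages: age main effects on LDI/CRS/volumes/activations,
age-varying volume->activation coupling, and the volume x activation
interaction on LDI.  p-values are reported uncorrected (the model count is
printed prominently); an optional Benjamini-Hochberg FDR column is
available on the Table-2-style summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SUBFIELDS
from .floodlight import difference_curve, regions_of_significance
from .gam import GAM, ComparisonResult, compare_models

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_COLUMNS",
    "AnalysisPlan",
    "SchemaReport",
    "RunReport",
    "validate_table",
    "run_full_analysis",
]

#: fixed cohort-table schema (12 imaging columns + demographics + scores)
SCHEMA_COLUMNS = (
    ["age", "sex", "education", "ldi", "crs"]
    + [f"{s}_vol" for s in SUBFIELDS]
    + [f"{s}_act" for s in SUBFIELDS]
)

_RANGES = {
    "ldi": (-1.0, 1.0),
    "crs": (-1.0, 1.0),
    "education": (1, 8),
    "age": (0.0, 120.0),
}


@dataclass
class SchemaReport:
    n_rows: int
    missing_columns: list[str]
    violations: list[dict]

    @property
    def ok(self) -> bool:
        return not self.missing_columns and not self.violations


def validate_table(table: pd.DataFrame | str | Path) -> SchemaReport:
    """Validate a cohort table against the fixed schema.

    Reports missing columns and out-of-range values exhaustively; an empty
    table raises."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    if len(table) == 0:
        raise ValueError("no rows in cohort table")
    missing = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    violations: list[dict] = []
    for col, (lo, hi) in _RANGES.items():
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < lo) | (vals > hi) | vals.isna()]
        for idx in bad:
            violations.append(
                {"row": int(idx), "column": col, "value": table.loc[idx, col]}
            )
    if "sex" in table.columns:
        ok_sex = table["sex"].astype(str).str.lower().isin(["female", "male"])
        for idx in table.index[~ok_sex]:
            violations.append(
                {"row": int(idx), "column": "sex", "value": table.loc[idx, "sex"]}
            )
    for col in SCHEMA_COLUMNS:
        if col in ("sex", *_RANGES) or col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[vals.isna()]:
            violations.append(
                {"row": int(idx), "column": col, "value": table.loc[idx, col]}
            )
    return SchemaReport(len(table), missing, violations)


@dataclass
class AnalysisPlan:
    """Which combinations to fit and with what bases."""

    subfields: tuple[str, ...] = SUBFIELDS
    predictor_kinds: tuple[str, ...] = ("vol", "act")
    k_age: int = 10
    k_tensor: int = 5
    alpha: float = 0.05
    grid_n: int = 201
    include_age_effects: bool = True
    include_volume_activation: bool = True
    include_volume_x_activation: bool = True
    fdr: bool = False

    def model_formulas(self, predictor: str, outcome: str = "ldi") -> dict[str, str]:
        return {
            "model1": f"{outcome} ~ {predictor} + s(age, k={self.k_age}) + sex + education",
            "model2": (
                f"{outcome} ~ s({predictor}, k={self.k_age}) + s(age, k={self.k_age}) "
                f"+ ti({predictor}, age, k={self.k_tensor}) + sex + education"
            ),
            "model3": (
                f"{outcome} ~ s(age, k={self.k_age}) "
                f"+ s(age, by={predictor}) + sex + education"
            ),
        }


@dataclass
class RunReport:
    """Everything a run produced, regenerable from config + seed."""

    provenance: dict
    n_models: int = 0
    age_effects: dict = dc_field(default_factory=dict)
    table2: dict = dc_field(default_factory=dict)
    volume_activation: dict = dc_field(default_factory=dict)
    volume_x_activation: dict = dc_field(default_factory=dict)
    curves: dict = dc_field(default_factory=dict)  # label -> DataFrame

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "n_models": self.n_models,
            "age_effects": self.age_effects,
            "table2": self.table2,
            "volume_activation": self.volume_activation,
            "volume_x_activation": self.volume_x_activation,
        }

    def table2_frame(self) -> pd.DataFrame:
        rows = []
        for key, entry in self.table2.items():
            subfield, kind = key.rsplit("_", 1)
            if "error" in entry:
                rows.append({"subfield": subfield, "kind": kind, "error": entry["error"]})
                continue
            rows.append(
                {
                    "subfield": subfield,
                    "kind": kind,
                    "f_model1_predictor": entry["model1"]["f_predictor"],
                    "f_model1_age": entry["model1"]["f_age"],
                    "f_model2_interaction": entry["model2"]["f_interaction"],
                    "f_model3_interaction": entry["model3"]["f_interaction"],
                    "p_model2_interaction": entry["model2"]["p_interaction"],
                    "p_model3_interaction": entry["model3"]["p_interaction"],
                    "best_model": entry["best_model"],
                }
            )
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=_jsonify)
        self.table2_frame().to_csv(outdir / "table2.csv", index=False)
        for label, frame in self.curves.items():
            frame.to_csv(outdir / f"curve_{label}.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _fit_summary(res, labels: dict[str, str]) -> dict:
    out = {"aic": res.aic, "edf": res.total_edf, "deviance": res.deviance}
    for name, label in labels.items():
        tt = res.term_test(label)
        out[f"f_{name}"] = tt["f"]
        out[f"p_{name}"] = tt["p"]
        out[f"edf_{name}"] = tt["edf"]
    return out


def _comparison_dict(c: ComparisonResult) -> dict:
    return {
        "delta_aic": c.delta_aic,
        "f": c.f_statistic,
        "df_num": c.df_num,
        "delta_edf": c.delta_edf,
        "p": c.p_value,
        "selected": c.selected,
        "degenerate": c.degenerate,
    }


def _select_best(
    m1, m2, m3, alpha: float
) -> tuple[str, ComparisonResult, ComparisonResult]:
    """Most-parsimonious selection among the three model families."""
    c2 = compare_models(m1, m2, alpha=alpha)
    c3 = compare_models(m1, m3, alpha=alpha)
    cands = []
    if c2.selected == "smooth":
        cands.append(("model2", m2))
    if c3.selected == "smooth":
        cands.append(("model3", m3))
    if not cands:
        return "model1", c2, c3
    if len(cands) == 1:
        return cands[0][0], c2, c3
    # both interactions beat the main-effects model: lower AIC wins,
    # fewer edf on an effective tie (|dAIC| < 2)
    (n_a, r_a), (n_b, r_b) = cands
    if abs(r_a.aic - r_b.aic) < 2.0:
        best = n_a if r_a.total_edf <= r_b.total_edf else n_b
    else:
        best = n_a if r_a.aic < r_b.aic else n_b
    return best, c2, c3


def run_full_analysis(
    cohort: pd.DataFrame,
    plan: AnalysisPlan | None = None,
    seed: int = 0,
    config_hash: str | None = None,
) -> RunReport:
    """Fit the full model sequence on a validated cohort table."""
    plan = plan or AnalysisPlan()
    schema = validate_table(cohort)
    if schema.missing_columns:
        raise ValueError(f"cohort table missing columns: {schema.missing_columns}")
    if schema.violations:
        raise ValueError(
            f"cohort table has {len(schema.violations)} out-of-range values; "
            f"first: {schema.violations[0]}"
        )
    if config_hash is None:
        config_hash = hashlib.sha256(
            pd.util.hash_pandas_object(cohort[sorted(c for c in cohort.columns)]).values.tobytes()
        ).hexdigest()[:16]
    report = RunReport(
        provenance={"config_hash": config_hash, "seed": seed, "n": len(cohort)}
    )
    n_models = 0

    # --- stage 1: age main effects -------------------------------------
    if plan.include_age_effects:
        outcomes = ["ldi", "crs"] + [
            f"{s}_{k}" for s in plan.subfields for k in plan.predictor_kinds
        ]
        for outcome in outcomes:
            try:
                lin = GAM(cohort, f"{outcome} ~ age + sex + education").fit()
                smo = GAM(
                    cohort, f"{outcome} ~ s(age, k={plan.k_age}) + sex + education"
                ).fit()
                n_models += 2
                comp = compare_models(lin, smo, alpha=plan.alpha)
                chosen = smo if comp.selected == "smooth" else lin
                entry = {
                    "comparison": _comparison_dict(comp),
                    "selected": comp.selected,
                }
                if comp.selected == "linear":
                    idx = next(
                        i
                        for b in lin.model.blocks
                        if b.label == "age"
                        for i in range(b.sl.start, b.sl.stop)
                    )
                    entry["age_slope"] = float(lin.params[idx])
                    entry["age_slope_se"] = float(
                        np.sqrt(lin.cov_params()[idx, idx])
                    )
                    tt = lin.term_test("age")
                    entry["age_t"] = float(np.sign(entry["age_slope"]) * np.sqrt(tt["f"]))
                    entry["age_p"] = tt["p"]
                else:
                    tt = chosen.term_test("s(age)")
                    entry.update(
                        {"age_edf": tt["edf"], "age_f": tt["f"], "age_p": tt["p"]}
                    )
                report.age_effects[outcome] = entry
            except Exception as exc:  # quarantine per outcome
                logger.warning("age-effect model for %s failed: %s", outcome, exc)
                report.age_effects[outcome] = {"error": str(exc)}

    # --- stage 2: Table-2-style subfield x age -> LDI ------------------
    for subfield in plan.subfields:
        for kind in plan.predictor_kinds:
            predictor = f"{subfield}_{kind}"
            key = predictor
            try:
                formulas = plan.model_formulas(predictor)
                m1 = GAM(cohort, formulas["model1"]).fit()
                m2 = GAM(cohort, formulas["model2"]).fit()
                m3 = GAM(cohort, formulas["model3"]).fit()
                n_models += 3
                best, c2, c3 = _select_best(m1, m2, m3, plan.alpha)
                entry = {
                    "model1": _fit_summary(
                        m1, {"predictor": predictor, "age": "s(age)"}
                    ),
                    "model2": _fit_summary(
                        m2, {"interaction": f"ti({predictor},age)"}
                    ),
                    "model3": _fit_summary(
                        m3, {"interaction": f"s(age,by={predictor})"}
                    ),
                    "comparison_model2": _comparison_dict(c2),
                    "comparison_model3": _comparison_dict(c3),
                    "best_model": best,
                }
                if best != "model1":
                    fit = m2 if best == "model2" else m3
                    curve = difference_curve(
                        fit, predictor, grid_n=plan.grid_n, alpha=plan.alpha
                    )
                    regions = regions_of_significance(curve, alpha=plan.alpha)
                    entry["floodlight"] = regions.to_dict()
                    entry["floodlight"]["q_low"] = curve.q_low_value
                    entry["floodlight"]["q_high"] = curve.q_high_value
                    report.curves[key] = curve.to_frame()
                report.table2[key] = entry
            except Exception as exc:
                logger.warning("table2 combination %s failed: %s", key, exc)
                report.table2[key] = {"error": str(exc)}

    # --- stage 3: volume x age -> activation ----------------------------
    if plan.include_volume_activation:
        for subfield in plan.subfields:
            vol, act = f"{subfield}_vol", f"{subfield}_act"
            try:
                main = GAM(
                    cohort, f"{act} ~ {vol} + s(age, k={plan.k_age}) + sex + education"
                ).fit()
                inter = GAM(
                    cohort, f"{act} ~ te({vol}, age, k={plan.k_tensor}) + sex + education"
                ).fit()
                n_models += 2
                comp = compare_models(main, inter, alpha=plan.alpha)
                entry = {
                    "comparison": _comparison_dict(comp),
                    "selected": comp.selected,
                }
                if comp.selected == "smooth":
                    curve = difference_curve(
                        inter, vol, grid_n=plan.grid_n, alpha=plan.alpha
                    )
                    regions = regions_of_significance(curve, alpha=plan.alpha)
                    entry["floodlight"] = regions.to_dict()
                    report.curves[f"{act}_by_{vol}"] = curve.to_frame()
                report.volume_activation[subfield] = entry
            except Exception as exc:
                logger.warning("volume-activation %s failed: %s", subfield, exc)
                report.volume_activation[subfield] = {"error": str(exc)}

    # --- stage 4: volume x activation -> LDI ----------------------------
    if plan.include_volume_x_activation:
        for subfield in plan.subfields:
            vol, act = f"{subfield}_vol", f"{subfield}_act"
            try:
                base = GAM(
                    cohort,
                    f"ldi ~ s(age, k={plan.k_age}) + {vol} + {act} + sex + education",
                ).fit()
                inter = GAM(
                    cohort,
                    f"ldi ~ s(age, k={plan.k_age}) + {vol} + {act} + {vol}:{act} "
                    "+ sex + education",
                ).fit()
                n_models += 2
                comp = compare_models(base, inter, alpha=plan.alpha)
                tt = inter.term_test(f"{vol}:{act}")
                report.volume_x_activation[subfield] = {
                    "comparison": _comparison_dict(comp),
                    "interaction_f": tt["f"],
                    "interaction_p": tt["p"],
                    "selected": comp.selected,
                }
            except Exception as exc:
                logger.warning("volume-x-activation %s failed: %s", subfield, exc)
                report.volume_x_activation[subfield] = {"error": str(exc)}

    report.n_models = n_models
    logger.info("fitted %d models (p-values uncorrected)", n_models)
    if plan.fdr:
        _add_fdr(report)
    return report


def _add_fdr(report: RunReport) -> None:
    """Benjamini-Hochberg adjusted p-values for the interaction tests."""
    keys, ps = [], []
    for key, entry in report.table2.items():
        for model in ("model2", "model3"):
            if "error" in entry:
                continue
            keys.append((key, model))
            ps.append(entry[model]["p_interaction"])
    if not ps:
        return
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, ps[i] * m / (rank_idx + 1))
        adj[i] = running
    for (key, model), q in zip(keys, adj):
        report.table2[key][model]["q_interaction"] = float(q)
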