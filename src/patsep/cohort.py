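"""Synthetic lifespan cohort generator.

Emulates the statistical structure of a three-stratum adult-lifespan study of
mnemonic discrimination and hippocampal subfield structure/function:

* ages sampled from three recruitment strata (20s, 40s, 60s-70s) or a
  continuous alternative;
* six subfield volumes (CA1/CA3/DG x left/right, arbitrary units = mm3/ICV
  x 1000) with linear age slopes and Gaussian residuals;
* six subfield activation contrasts (successful > unsuccessful lure
  discrimination), two of which are coupled to their own volume with an
  age-varying coefficient;
* a latent lure-discrimination index (LDI) following a smooth logistic
  decline over age, moderated by DG volume and left-CA3 activation with
  age-varying coefficients, plus Gaussian noise; and a latent corrected
  recognition score (CRS) declining linearly with age.

Default parameters are calibrated so that the stratified population
reproduces the target cohort moments (LDI mean 0.16 / SD 0.18, CRS mean
0.58 / SD 0.25, the volume and activation means/SDs) and the structural
age slopes (left CA1 -0.06, left DG -0.02, right DG -0.03, CRS -0.007 per
year) exactly, by analytic moment matching under the age sampler.

Trial-level simulation (`simulate_trials`) produces sessions whose computed
LDI/CRS are unbiased for the participant's latent scores by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .scoring import Phase, Response, TrialRecord, TrialType

__all__ = [
    "SUBFIELDS",
    "AgeSampler",
    "PiecewiseLinear",
    "LinearAgeModel",
    "ActivationModel",
    "LdiModel",
    "TrialSimConfig",
    "CohortConfig",
    "default_config",
    "simulate_cohort",
    "simulate_trials",
    "volume_normalize",
    "load_config",
    "save_config",
]

#: subfield-hemisphere keys, fixed column order of the cohort table
SUBFIELDS = ("ca1_left", "ca1_right", "ca3_left", "ca3_right", "dg_left", "dg_right")

#: cohort-table moments being emulated (means and SDs)
VOLUME_MOMENTS = {
    "ca1_left": (30.63, 3.2),
    "ca1_right": (31.19, 3.3),
    "ca3_left": (9.69, 1.1),
    "ca3_right": (10.48, 1.2),
    "dg_left": (13.88, 1.3),
    "dg_right": (14.29, 1.4),
}
ACTIVATION_MOMENTS = {
    "ca1_left": (3.09, 21.5),
    "ca1_right": (1.98, 17.1),
    "ca3_left": (-0.81, 29.1),
    "ca3_right": (2.31, 27.1),
    "dg_left": (8.11, 47.4),
    "dg_right": (5.51, 34.3),
}
#: linear age slopes of subfield volume (au per year); unlisted subfields: 0
VOLUME_AGE_SLOPES = {"ca1_left": -0.06, "dg_left": -0.02, "dg_right": -0.03}

LDI_MEAN, LDI_SD = 0.16, 0.18
CRS_MEAN, CRS_SD = 0.58, 0.25
CRS_AGE_SLOPE = -0.007


# ---------------------------------------------------------------------------
# age sampling


@dataclass
class AgeSampler:
    """Stratified or continuous age distribution over the adult lifespan.

    The stratified default draws uniformly within [21, 30], [40, 50] and
    [60, 73] with weights 18:18:17, mirroring a recruitment design with
    three pre-defined age groups and the observed range 21-73.
    """

    kind: str = "stratified"  # or "continuous"
    strata: tuple[tuple[float, float, float], ...] = (
        (21.0, 30.0, 18.0),
        (40.0, 50.0, 18.0),
        (60.0, 73.0, 17.0),
    )
    bounds: tuple[float, float] = (21.0, 73.0)

    def __post_init__(self) -> None:
        if self.kind not in ("stratified", "continuous"):
            raise ValueError(f"unknown age sampler kind {self.kind!r}")
        if self.kind == "stratified" and not self.strata:
            raise ValueError("stratified sampler needs at least one stratum")

    def _weights(self) -> np.ndarray:
        w = np.array([s[2] for s in self.strata], dtype=float)
        return w / w.sum()

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "continuous":
            return rng.uniform(self.bounds[0], self.bounds[1], size=n)
        idx = rng.choice(len(self.strata), size=n, p=self._weights())
        lo = np.array([s[0] for s in self.strata])[idx]
        hi = np.array([s[1] for s in self.strata])[idx]
        return rng.uniform(lo, hi)

    def stratum_counts(self, n: int) -> list[int]:
        """Deterministic per-stratum counts for an exact design of size n
        (largest-remainder apportionment)."""
        w = self._weights()
        raw = w * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        return counts.tolist()

    def sample_exact(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Sample with exact stratum counts (design-faithful allocation)."""
        if self.kind == "continuous":
            return self.sample(rng, n)
        out = []
        for (lo, hi, _), c in zip(self.strata, self.stratum_counts(n)):
            out.append(rng.uniform(lo, hi, size=c))
        return np.concatenate(out)

    def expect(self, f: Callable[[np.ndarray], np.ndarray]) -> float:
        """E[f(age)] under the sampler, by per-stratum trapezoidal quadrature."""
        if self.kind == "continuous":
            grid = np.linspace(*self.bounds, 4001)
            return float(np.trapezoid(f(grid), grid) / (self.bounds[1] - self.bounds[0]))
        total = 0.0
        for (lo, hi, _), w in zip(self.strata, self._weights()):
            grid = np.linspace(lo, hi, 1001)
            total += w * float(np.trapezoid(f(grid), grid)) / (hi - lo)
        return total

    def mean(self) -> float:
        return self.expect(lambda a: a)

    def var(self) -> float:
        m = self.mean()
        return self.expect(lambda a: (a - m) ** 2)

    def support(self) -> tuple[float, float]:
        if self.kind == "continuous":
            return self.bounds
        return (min(s[0] for s in self.strata), max(s[1] for s in self.strata))


# ---------------------------------------------------------------------------
# age-varying coefficients


@dataclass
class PiecewiseLinear:
    """Piecewise-linear function of age given by (age, value) knots;
    constant extrapolation outside the knot range.  Used for the
    age-varying moderation and coupling coefficients (bilinear-ramp
    building blocks of the tensor-product-like interactions)."""

    knots: tuple[tuple[float, float], ...]

    def __call__(self, age: np.ndarray | float) -> np.ndarray | float:
        xs = np.array([k[0] for k in self.knots], dtype=float)
        ys = np.array([k[1] for k in self.knots], dtype=float)
        return np.interp(age, xs, ys)


# ---------------------------------------------------------------------------
# component models


@dataclass
class LinearAgeModel:
    """value = intercept + age_slope * (age - age_center) + N(0, residual_sd^2).

    `intercept` is the population mean when age_center is the sampler mean.
    """

    intercept: float
    age_slope: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass
class ActivationModel:
    """Activation contrast: mean + coupling(age) * z_volume + noise.

    z_volume is the standardized age-adjusted residual of the same
    subfield's volume, so the coupling coefficient is in activation units
    per volume-SD and the marginal activation mean is unaffected.
    """

    mean: float
    sd: float
    volume_coupling: PiecewiseLinear | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class LdiModel:
    """Latent LDI: offset + logistic age decline + moderation + noise.

        g(age) = offset + plateau - drop / (1 + exp(-(age - center) / scale))

    a plateau through the 20s-30s followed by a smooth decline through
    midlife.  Moderators contribute coeff(age) * z, where z is the
    standardized age-adjusted residual of the named source column.
    """

    plateau: float = 0.30
    drop: float = 0.28
    center: float = 52.0
    scale: float = 5.0
    offset: float = 0.0
    moderators: dict[str, PiecewiseLinear] = dc_field(default_factory=dict)
    residual_sd: float = 0.13

    def g(self, age: np.ndarray | float) -> np.ndarray | float:
        age = np.asarray(age, dtype=float)
        return self.offset + self.plateau - self.drop / (
            1.0 + np.exp(-(age - self.center) / self.scale)
        )


@dataclass
class TrialSimConfig:
    """Designed retrieval trial counts and the response model.

    The response model makes scoring unbiased by construction:
    p(similar|lure) = foil_similar_rate + latent_ldi,
    p(similar|foil) = foil_similar_rate,
    p(old|target)   = foil_old_rate + latent_crs,
    p(old|foil)     = foil_old_rate.
    Remaining probability mass within a trial type is split evenly over the
    unused responses.  `missingness` flags responses as absent (rows are
    kept, never deleted).
    """

    n_targets: int = 50
    n_lures: int = 100
    n_foils: int = 50
    n_encoding: int = 150
    foil_similar_rate: float = 0.30
    foil_old_rate: float = 0.32
    missingness: float = 0.0
    include_encoding: bool = False

    def __post_init__(self) -> None:
        for name in ("foil_similar_rate", "foil_old_rate", "missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n: int = 53
    age_sampler: AgeSampler = dc_field(default_factory=AgeSampler)
    sex_p_female: float = 0.57
    education_mean: float = 5.51
    education_sd: float = 1.6
    education_range: tuple[int, int] = (2, 8)
    age_center: float = 0.0  # reference age for intercepts; sampler mean if 0
    volume_models: dict[str, LinearAgeModel] = dc_field(default_factory=dict)
    volume_residual_corr: float = 0.0
    activation_models: dict[str, ActivationModel] = dc_field(default_factory=dict)
    ldi_model: LdiModel = dc_field(default_factory=LdiModel)
    crs_model: LinearAgeModel = dc_field(
        default_factory=lambda: LinearAgeModel(CRS_MEAN, CRS_AGE_SLOPE, 0.22)
    )
    trial_config: TrialSimConfig = dc_field(default_factory=TrialSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.sex_p_female <= 1.0:
            raise ValueError("sex_p_female must be a probability")
        if self.education_sd < 0:
            raise ValueError("education_sd must be >= 0")
        if not -1.0 < self.volume_residual_corr < 1.0:
            raise ValueError("volume_residual_corr must be in (-1, 1)")


def default_config(n: int = 53, seed: int = 0) -> CohortConfig:
    """Default configuration, moment-matched to the emulated cohort.

    Residual SDs are derived analytically so the *marginal* SD of every
    component equals its target under the stratified age distribution, and
    the LDI offset is chosen so the population LDI mean equals 0.16.
    """
    sampler = AgeSampler()
    age_var = sampler.var()

    volume_models = {}
    for key, (mean, sd) in VOLUME_MOMENTS.items():
        slope = VOLUME_AGE_SLOPES.get(key, 0.0)
        resid_var = sd**2 - slope**2 * age_var
        if resid_var <= 0:
            raise ValueError(f"volume SD for {key} too small for its age slope")
        volume_models[key] = LinearAgeModel(mean, slope, float(np.sqrt(resid_var)))

    # age-varying volume->activation coupling (activation units per volume SD):
    # own-volume coupling positive in the 20s and negative from the mid-50s
    # for left CA1; negative from ~50 onward for left DG.
    couplings = {
        "ca1_left": PiecewiseLinear(((21, 8.0), (28, 8.0), (42, 0.0), (55, -8.0), (73, -8.0))),
        "dg_left": PiecewiseLinear(((21, 0.0), (44, 0.0), (52, -18.0), (73, -18.0))),
    }
    activation_models = {}
    for key, (mean, sd) in ACTIVATION_MOMENTS.items():
        activation_models[key] = ActivationModel(mean, sd, couplings.get(key))

    # age-varying moderation of latent LDI (LDI units per moderator SD):
    # DG volume hurts performance in midlife and helps (left) in late life;
    # left-CA3 activation helps before ~45 and hurts after ~60.
    moderators = {
        "dg_left_vol": PiecewiseLinear(
            ((21, 0.0), (40, 0.0), (46, -0.08), (56, -0.08), (61, 0.0), (66, 0.05), (73, 0.05))
        ),
        "dg_right_vol": PiecewiseLinear(
            ((21, 0.0), (40, 0.0), (45, -0.07), (52, -0.07), (57, 0.0), (73, 0.0))
        ),
        "ca3_left_act": PiecewiseLinear(
            ((21, 0.06), (40, 0.06), (48, 0.0), (58, 0.0), (64, -0.05), (73, -0.05))
        ),
    }
    ldi = LdiModel(moderators=moderators, offset=0.0, residual_sd=0.0)
    # calibrate the offset so E[g(age)] matches the target mean, then the
    # residual SD so the marginal variance matches the target SD
    g_mean = sampler.expect(lambda a: np.asarray(ldi.g(a), dtype=float))
    ldi.offset = LDI_MEAN - g_mean
    g_var = sampler.expect(lambda a: (np.asarray(ldi.g(a)) - LDI_MEAN) ** 2)
    mod_var = sum(
        sampler.expect(lambda a, f=f: np.asarray(f(a)) ** 2) for f in moderators.values()
    )
    resid_var = LDI_SD**2 - g_var - mod_var
    if resid_var <= 0:
        raise ValueError("LDI target SD too small for the configured structure")
    ldi.residual_sd = float(np.sqrt(resid_var))

    crs_resid = float(np.sqrt(CRS_SD**2 - CRS_AGE_SLOPE**2 * age_var))
    crs = LinearAgeModel(CRS_MEAN, CRS_AGE_SLOPE, crs_resid)

    return CohortConfig(
        n=n,
        age_sampler=sampler,
        age_center=sampler.mean(),
        volume_models=volume_models,
        activation_models=activation_models,
        ldi_model=ldi,
        crs_model=crs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort simulation


def _discrete_education(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = cfg.education_range
    levels = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((levels - cfg.education_mean) / cfg.education_sd) ** 2)
    w /= w.sum()
    return rng.choice(levels, size=n, p=w)


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    n: int | None = None,
    exact_strata: bool = True,
) -> pd.DataFrame:
    """Generate a participant table.

    Returns a tidy DataFrame with one row per participant and columns
    participant_id, age, sex, education, the six `<subfield>_vol` and six
    `<subfield>_act` columns, ldi and crs.  Identical (config, seed) give
    identical tables.  With `exact_strata` (default) the stratified design
    allocates exact per-stratum counts, e.g. 18/18/17 at n=53.
    """
    cfg = config if config is not None else default_config()
    if n is not None:
        cfg = dataclasses.replace(cfg, n=n)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n
    center = cfg.age_center if cfg.age_center else cfg.age_sampler.mean()

    if exact_strata:
        age = cfg.age_sampler.sample_exact(rng, n)
    else:
        age = cfg.age_sampler.sample(rng, n)
    sex = np.where(rng.random(n) < cfg.sex_p_female, "female", "male")
    education = _discrete_education(cfg, rng, n)

    # volume residual z-scores, optionally equicorrelated across subfields
    k = len(SUBFIELDS)
    if cfg.volume_residual_corr:
        rho = cfg.volume_residual_corr
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        zvol = rng.multivariate_normal(np.zeros(k), cov, size=n)
    else:
        zvol = rng.standard_normal((n, k))

    data: dict[str, np.ndarray] = {
        "participant_id": np.array([f"p{i:06d}" for i in range(n)]),
        "age": age,
        "sex": sex,
        "education": education,
    }
    zscores: dict[str, np.ndarray] = {}
    for j, key in enumerate(SUBFIELDS):
        m = cfg.volume_models[key]
        data[f"{key}_vol"] = m.intercept + m.age_slope * (age - center) + m.residual_sd * zvol[:, j]
        zscores[f"{key}_vol"] = zvol[:, j]

    for key in SUBFIELDS:
        am = cfg.activation_models[key]
        coupled = np.zeros(n)
        if am.volume_coupling is not None:
            c = np.asarray(am.volume_coupling(age), dtype=float)
            coupled = c * zscores[f"{key}_vol"]
            resid_var = am.sd**2 - cfg.age_sampler.expect(
                lambda a, f=am.volume_coupling: np.asarray(f(a)) ** 2
            )
            resid_sd = float(np.sqrt(max(resid_var, 0.0)))
        else:
            resid_sd = am.sd
        zact = rng.standard_normal(n)
        data[f"{key}_act"] = am.mean + coupled + resid_sd * zact
        # moderation uses the activation's own innovation, standardized
        zscores[f"{key}_act"] = zact

    lm = cfg.ldi_model
    latent_ldi = np.asarray(lm.g(age), dtype=float)
    for source, coeff in lm.moderators.items():
        latent_ldi = latent_ldi + np.asarray(coeff(age), dtype=float) * zscores[source]
    latent_ldi = latent_ldi + lm.residual_sd * rng.standard_normal(n)

    cm = cfg.crs_model
    latent_crs = (
        cm.intercept + cm.age_slope * (age - center) + cm.residual_sd * rng.standard_normal(n)
    )

    n_clipped = int(np.sum((latent_ldi < -1) | (latent_ldi > 1)))
    n_clipped += int(np.sum((latent_crs < -1) | (latent_crs > 1)))
    if n_clipped:
        import logging

        logging.getLogger(__name__).info(
            "clipped %d latent scores to [-1, 1]", n_clipped
        )
    data["ldi"] = np.clip(latent_ldi, -1.0, 1.0)
    data["crs"] = np.clip(latent_crs, -1.0, 1.0)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# trial simulation


def _second_judgement(rng: np.random.Generator, response: Response) -> str:
    if response in (Response.OLD, Response.SIMILAR):
        return f"quadrant{rng.integers(1, 5)}"
    if response is Response.NEW:
        return "sure" if rng.random() < 0.5 else "unsure"
    return "none"


def _response_probs(tcfg: TrialSimConfig, trial_type: TrialType, ldi: float, crs: float):
    """(p_old, p_similar, p_new) for one trial type.

    Invalid base rates raise, naming the trial type; latent-driven
    probabilities are clipped to [0, 1] (scoring stays unbiased whenever
    no clipping occurs).
    """
    if trial_type is TrialType.FOIL:
        p_sim, p_old = tcfg.foil_similar_rate, tcfg.foil_old_rate
        if p_sim + p_old > 1.0:
            raise ValueError("foil: foil_similar_rate + foil_old_rate exceeds 1")
        return (p_old, p_sim, 1.0 - p_sim - p_old)
    if trial_type is TrialType.LURE:
        p_sim = min(max(tcfg.foil_similar_rate + ldi, 0.0), 1.0)
        rest = 1.0 - p_sim
        return (rest / 2, p_sim, rest / 2)
    p_old = min(max(tcfg.foil_old_rate + crs, 0.0), 1.0)
    rest = 1.0 - p_old
    return (p_old, rest / 2, rest / 2)


def simulate_trials(
    participant: pd.Series | dict,
    tcfg: TrialSimConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Simulate one session of retrieval trials for a participant.

    `participant` needs `ldi` and `crs` entries (the latent scores).  The
    expected computed LDI/CRS over sessions equal the latent scores.
    Missingness flags responses as absent; the records remain.
    """
    tcfg = tcfg or TrialSimConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    ldi = float(participant["ldi"])
    crs = float(participant["crs"])
    if not -1.0 <= ldi <= 1.0 or not -1.0 <= crs <= 1.0:
        raise ValueError("latent scores must be in [-1, 1]")

    records: list[TrialRecord] = []
    tid = 0
    if tcfg.include_encoding:
        for _ in range(tcfg.n_encoding):
            resp = Response.INDOOR if rng.random() < 0.5 else Response.OUTDOOR
            records.append(
                TrialRecord(tid, Phase.ENCODING, TrialType.NONE, resp, "none")
            )
            tid += 1

    plan = [
        (TrialType.TARGET, tcfg.n_targets),
        (TrialType.LURE, tcfg.n_lures),
        (TrialType.FOIL, tcfg.n_foils),
    ]
    responses = (Response.OLD, Response.SIMILAR, Response.NEW)
    for trial_type, count in plan:
        probs = _response_probs(tcfg, trial_type, ldi, crs)
        draws = rng.choice(3, size=count, p=probs)
        miss = rng.random(count) < tcfg.missingness
        for d, m in zip(draws, miss):
            resp = Response.NONE if m else responses[d]
            records.append(
                TrialRecord(
                    tid,
                    Phase.RETRIEVAL,
                    trial_type,
                    resp,
                    _second_judgement(rng, resp),
                )
            )
            tid += 1
    # randomized presentation order of retrieval trials
    head = tcfg.n_encoding if tcfg.include_encoding else 0
    tail = records[head:]
    perm = rng.permutation(len(tail))
    records[head:] = [tail[i] for i in perm]
    return records


def volume_normalize(raw_volume: float, icv: float) -> float:
    """Express a subfield volume in arbitrary units: raw mm3 / ICV mm3 x 1000."""
    if icv <= 0:
        raise ValueError("intracranial volume must be positive")
    if raw_volume < 0:
        raise ValueError("raw volume must be non-negative")
    return raw_volume / icv * 1000.0


# ---------------------------------------------------------------------------
# config (de)serialization


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _from_dict(cls, d):
    if not dataclasses.is_dataclass(cls):
        return d
    field_types = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(field_types)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        kwargs[name] = _convert_field(cls, name, value)
    return cls(**kwargs)


def _convert_field(cls, name, value):
    conversions = {
        CohortConfig: {
            "age_sampler": lambda v: _from_dict(AgeSampler, v),
            "volume_models": lambda v: {k: _from_dict(LinearAgeModel, m) for k, m in v.items()},
            "activation_models": lambda v: {
                k: _from_dict(ActivationModel, m) for k, m in v.items()
            },
            "ldi_model": lambda v: _from_dict(LdiModel, v),
            "crs_model": lambda v: _from_dict(LinearAgeModel, v),
            "trial_config": lambda v: _from_dict(TrialSimConfig, v),
            "education_range": tuple,
        },
        AgeSampler: {
            "strata": lambda v: tuple(tuple(s) for s in v),
            "bounds": tuple,
        },
        ActivationModel: {
            "volume_coupling": lambda v: None
            if v is None
            else PiecewiseLinear(tuple(tuple(k) for k in v["knots"]))
        },
        LdiModel: {
            "moderators": lambda v: {
                k: PiecewiseLinear(tuple(tuple(p) for p in m["knots"])) for k, m in v.items()
            }
        },
    }
    conv = conversions.get(cls, {}).get(name)
    return conv(value) if conv is not None else value


def save_config(cfg: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(cfg), fh, sort_keys=False)


def load_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return _from_dict(CohortConfig, d)
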