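"""Synthetic physical-examination cohorts with the 33-predictor schema.

The generator emulates a health-checkup cohort screened by chest CT for
pulmonary nodules: 33 predictors (12 general/lifestyle, 21 laboratory),
a binary nodule label, and a positive prevalence of 1168/4861 (~24%).
Eight predictors carry real group contrasts, calibrated to the published
class-conditional summaries of the cohort this schema mirrors: age,
smoking/passive smoking, psychological stress, occupational exposure,
chronic lung disease, family history of lung cancer, serum albumin, and
elevated carcinoembryonic antigen (CEA).  The remaining 25 predictors use
placeholder marginals from standard clinical reference intervals and carry
no group contrast.

Two generators are provided:

* :func:`generate` draws class-conditionally (label first, then features
  given the class), so the calibrated contrasts hold in expectation --
  the right input for testing univariate statistics.
* :func:`generate_logistic` draws features from pooled marginals and labels
  from a logistic link over scaled predictors (continuous columns z-scored,
  binary columns raw 0/1), recording the generating coefficients as ground
  truth -- the right input for parameter- and feature-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDef",
    "CohortSpec",
    "Cohort",
    "FEATURE_NAMES",
    "default_spec",
    "generate",
    "generate_logistic",
    "standardized_design",
]

N_COHORT = 4861
N_POSITIVE = 1168
PREVALENCE = N_POSITIVE / N_COHORT


@dataclass(frozen=True)
class FeatureDef:
    """One predictor: kind, class-conditional marginals, provenance flag.

    For ``kind == 'binary'`` params are ``(rate_neg, rate_pos)``; for
    ``kind == 'continuous'`` they are ``(mean_neg, sd_neg, mean_pos,
    sd_pos)``.  ``calibrated`` marks the eight features whose marginals
    come from published cohort summaries rather than reference-interval
    placeholders.
    """

    name: str
    kind: str  # "binary" | "continuous"
    params: tuple
    units: str = ""
    calibrated: bool = False


def _b(name, p_neg, p_pos, calibrated=False):
    return FeatureDef(name, "binary", (p_neg, p_pos), calibrated=calibrated)


def _c(name, m_neg, s_neg, m_pos, s_pos, units="", calibrated=False):
    return FeatureDef(name, "continuous", (m_neg, s_neg, m_pos, s_pos),
                      units=units, calibrated=calibrated)


# 12 general + 21 laboratory predictors.  Placeholder marginals (calibrated
# False) sit at typical adult reference values and are identical in both
# classes, so they behave as pure noise features.
_DEFAULT_FEATURES: tuple[FeatureDef, ...] = (
    # --- general / lifestyle -------------------------------------------
    _b("male_gender", 0.55, 0.55),
    _c("age", 33.87, 8.43, 43.32, 9.16, units="year", calibrated=True),
    _b("smoking", 0.3978, 0.6978, calibrated=True),
    _b("alcohol_consumption", 0.30, 0.30),
    _b("urban_residence", 0.70, 0.70),
    _b("higher_education", 0.45, 0.45),
    _b("chronic_lung_disease", 0.0506, 0.1036, calibrated=True),
    _b("family_history_lung_cancer", 0.14, 0.2894, calibrated=True),
    _b("regular_exercise", 0.35, 0.35),
    _c("bmi", 23.5, 3.2, 23.5, 3.2, units="kg/m^2"),
    _b("psychological_stress", 0.2099, 0.2866, calibrated=True),
    _b("depressive_symptoms", 0.10, 0.10),
    _b("occupational_exposure", 0.12, 0.2997, calibrated=True),
    # --- laboratory ----------------------------------------------------
    _b("cea_elevated", 0.0165, 0.0497, calibrated=True),
    _c("tsh", 2.0, 1.0, 2.0, 1.0, units="mIU/L"),
    _c("wbc", 6.3, 1.5, 6.3, 1.5, units="10^9/L"),
    _c("lymphocyte", 2.1, 0.6, 2.1, 0.6, units="10^9/L"),
    _c("platelet", 250.0, 55.0, 250.0, 55.0, units="10^9/L"),
    _c("hemoglobin", 145.0, 13.0, 145.0, 13.0, units="g/L"),
    _c("eosinophil", 0.15, 0.10, 0.15, 0.10, units="10^9/L"),
    _c("basophil", 0.03, 0.02, 0.03, 0.02, units="10^9/L"),
    _c("albumin", 49.14, 11.23, 44.92, 9.33, units="g/L", calibrated=True),
    _c("globulin", 28.0, 4.0, 28.0, 4.0, units="g/L"),
    _c("alt", 25.0, 12.0, 25.0, 12.0, units="U/L"),
    _c("ast", 24.0, 9.0, 24.0, 9.0, units="U/L"),
    _c("indirect_bilirubin", 10.0, 4.0, 10.0, 4.0, units="umol/L"),
    _c("hdl", 1.3, 0.3, 1.3, 0.3, units="mmol/L"),
    _c("ldl", 2.9, 0.8, 2.9, 0.8, units="mmol/L"),
    _c("triglycerides", 1.5, 0.9, 1.5, 0.9, units="mmol/L"),
    _c("fasting_glucose", 5.2, 0.8, 5.2, 0.8, units="mmol/L"),
    _c("creatinine", 75.0, 15.0, 75.0, 15.0, units="umol/L"),
    _c("blood_urea_nitrogen", 5.2, 1.3, 5.2, 1.3, units="mmol/L"),
    _c("uric_acid", 350.0, 80.0, 350.0, 80.0, units="umol/L"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in _DEFAULT_FEATURES)

# Generating log-odds for the logistic-link cohort.  The six published
# multivariable coefficients are used verbatim; family history and albumin
# (retained univariately but dropped by the published stepwise model) carry
# documented placeholder effects.  Continuous effects are per pooled SD,
# binary effects per category.
DEFAULT_EFFECTS: dict[str, float] = {
    "age": 1.536,
    "smoking": 1.231,
    "psychological_stress": 0.515,
    "chronic_lung_disease": 0.742,
    "cea_elevated": 1.011,
    "occupational_exposure": 1.067,
    "family_history_lung_cancer": 0.7,
    "albumin": -0.45,
}


@dataclass
class CohortSpec:
    """Everything needed to draw one synthetic cohort."""

    n: int = N_COHORT
    prevalence: float = PREVALENCE
    features: tuple[FeatureDef, ...] = _DEFAULT_FEATURES
    effects: dict = dc_field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    intercept: float | None = None  # None -> calibrated to hit `prevalence`
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in spec")
        unknown = set(self.effects) - set(names)
        if unknown:
            raise ValueError(f"effects reference unknown features: {sorted(unknown)}")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]


@dataclass
class Cohort:
    """Subjects x predictors table with a binary nodule label."""

    X: pd.DataFrame
    y: np.ndarray
    schema: dict  # name -> {"kind", "units"}
    metadata: dict = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["nodule"] = self.y
        return out

    def to_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.frame().to_csv(path, index=False)
        if sidecar:
            meta = {"schema": self.schema, "metadata": self.metadata}
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, default=float)
            )

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path)
        if "nodule" not in df.columns:
            raise ValueError(f"{path}: missing required label column 'nodule'")
        y = df.pop("nodule").to_numpy(dtype=int)
        side = path.with_suffix(path.suffix + ".meta.json")
        if side.exists():
            meta = json.loads(side.read_text())
            schema, metadata = meta["schema"], meta.get("metadata", {})
        else:
            # infer kinds: two-valued {0,1} columns are binary
            schema, metadata = {}, {}
            for c in df.columns:
                vals = set(pd.unique(df[c].dropna()))
                kind = "binary" if vals <= {0, 1} else "continuous"
                schema[c] = {"kind": kind, "units": ""}
        return cls(X=df, y=y, schema=schema, metadata=metadata)


def default_spec() -> CohortSpec:
    """The calibrated default: n=4,861, prevalence 1168/4861, 33 predictors."""
    return CohortSpec()


def _schema(spec: CohortSpec) -> dict:
    return {
        f.name: {"kind": f.kind, "units": f.units, "calibrated": f.calibrated}
        for f in spec.features
    }


def generate(spec: CohortSpec | None = None) -> Cohort:
    """Class-conditional draw: labels first, then features given the class."""
    spec = spec or default_spec()
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n) < spec.prevalence).astype(int)
    cols = {}
    for f in spec.features:
        if f.kind == "binary":
            p = np.where(y == 1, f.params[1], f.params[0])
            cols[f.name] = (rng.random(spec.n) < p).astype(int)
        else:
            m_neg, s_neg, m_pos, s_pos = f.params
            mu = np.where(y == 1, m_pos, m_neg)
            sd = np.where(y == 1, s_pos, s_neg)
            cols[f.name] = mu + sd * rng.standard_normal(spec.n)
    X = pd.DataFrame(cols, columns=spec.feature_names)
    return Cohort(
        X=X, y=y, schema=_schema(spec),
        metadata={"generator": "class_conditional", "seed": spec.seed,
                  "prevalence": spec.prevalence},
    )


def _pooled_params(f: FeatureDef, prevalence: float):
    """Mixture marginal of a class-conditional feature."""
    w = prevalence
    if f.kind == "binary":
        return (1 - w) * f.params[0] + w * f.params[1]
    m_neg, s_neg, m_pos, s_pos = f.params
    mean = (1 - w) * m_neg + w * m_pos
    var = (1 - w) * (s_neg**2 + m_neg**2) + w * (s_pos**2 + m_pos**2) - mean**2
    return mean, float(np.sqrt(var))


def generate_logistic(spec: CohortSpec | None = None) -> Cohort:
    """Logistic-link draw with recorded ground-truth coefficients.

    Predictors come from their pooled (mixture) marginals; the linear
    predictor applies effects to z-scored continuous columns and raw binary
    columns.  When ``spec.intercept`` is None it is calibrated by bisection
    so the expected prevalence matches ``spec.prevalence``.
    """
    spec = spec or default_spec()
    rng = np.random.default_rng(spec.seed)
    cols, scales = {}, {}
    for f in spec.features:
        if f.kind == "binary":
            p = _pooled_params(f, spec.prevalence)
            cols[f.name] = (rng.random(spec.n) < p).astype(int)
            scales[f.name] = (0.0, 1.0)  # binary enters raw
        else:
            mean, sd = _pooled_params(f, spec.prevalence)
            cols[f.name] = mean + sd * rng.standard_normal(spec.n)
            scales[f.name] = (mean, sd)
    X = pd.DataFrame(cols, columns=spec.feature_names)

    eta = np.zeros(spec.n)
    for name, beta in spec.effects.items():
        center, scale = scales[name]
        eta += beta * (X[name].to_numpy(dtype=float) - center) / scale

    if spec.intercept is None:
        lo, hi = -30.0, 30.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if np.mean(1.0 / (1.0 + np.exp(-(eta + mid)))) < spec.prevalence:
                lo = mid
            else:
                hi = mid
        intercept = 0.5 * (lo + hi)
    else:
        intercept = float(spec.intercept)

    prob = 1.0 / (1.0 + np.exp(-(eta + intercept)))
    y = (rng.random(spec.n) < prob).astype(int)
    return Cohort(
        X=X, y=y, schema=_schema(spec),
        metadata={
            "generator": "logistic",
            "seed": spec.seed,
            "effects": dict(spec.effects),
            "intercept": intercept,
            "scaling": {k: list(v) for k, v in scales.items()},
        },
    )


def standardized_design(cohort: Cohort) -> pd.DataFrame:
    """Continuous columns z-scored, binary columns left raw 0/1.

    This is the scale on which :func:`generate_logistic` defines its
    ground-truth coefficients, so fits on this design are directly
    comparable to the recorded effects.
    """
    out = cohort.X.copy().astype(float)
    for name, info in cohort.schema.items():
        if info["kind"] == "continuous":
            col = out[name]
            sd = col.std(ddof=0)
            out[name] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return out
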