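"""Synthetic patient cohorts with a known feature–grade–survival structure.

Each record carries clinical covariates, ordinal immunohistochemistry (IHC)
grades (CD4/CD8/CD163 cell infiltration, IL-6/MMP-11 expression, each in
{0, 1, 2}), the 10 tumor imaging features plus reference-organ uptake, and a
right-censored recurrence-free-survival (RFS) outcome.

Generative model
----------------
* IHC grades: independent categorical draws per marker.
* Imaging features: log-normal, with the median multiplied by a per-(feature,
  marker) shift raised to the marker's grade — medians and IQRs of PET
  features are right-skewed, so multiplicative median shifts are the natural
  coupling.  BM and spleen SUV are derived as ratio × liver SUV so the
  BLR/SLR identities hold exactly within each record.
* Survival: exponential proportional hazards.  The log-hazard is a linear
  combination of scaled covariates (advanced TNM stage indicator, CoV of
  tumor SUV per 0.10, SLR per 1.0 by default), censoring is uniform over the
  follow-up window, observed time is the minimum of event and censoring
  times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "COLUMN_DICTIONARY"]

MARKERS = ("cd4", "cd8", "cd163", "il6", "mmp11")

#: default grade probabilities per marker (grades 0/1/2)
DEFAULT_GRADE_PROBS: dict[str, tuple[float, float, float]] = {
    "cd4": (33 / 119, 41 / 119, 45 / 119),
    "cd8": (43 / 119, 44 / 119, 32 / 119),
    "cd163": (27 / 119, 46 / 119, 46 / 119),
    "il6": (33 / 119, 38 / 119, 48 / 119),
    "mmp11": (45 / 119, 40 / 119, 34 / 119),
}

#: default log-normal (median, log-scale sigma) per generated feature
DEFAULT_FEATURE_BASE_MEDIANS: dict[str, tuple[float, float]] = {
    "max_suv": (12.4, 0.35),
    "mtv_cm3": (16.0, 0.70),
    "tlg_g": (110.0, 0.90),
    "mean_suv": (6.8, 0.30),
    "median_suv": (6.5, 0.30),
    "cov_suv": (0.24, 0.22),
    "kurtosis": (2.5, 0.30),
    "skewness": (0.5, 0.50),
    "entropy_bits": (4.2, 0.12),
    "uniformity": (0.060, 0.35),
    "liver_suv": (2.1, 0.12),
    "blr": (0.80, 0.14),
    "slr": (0.80, 0.12),
}

#: default multiplicative median shift per grade step, keyed (feature, marker);
#: signs follow the observed feature–grade trends (e.g. MTV/TLG fall with CD4
#: infiltration, entropy and BLR rise with CD163, uniformity falls with IL-6)
DEFAULT_FEATURE_GRADE_SHIFTS: dict[tuple[str, str], float] = {
    ("mtv_cm3", "cd4"): 0.757,
    ("tlg_g", "cd4"): 0.751,
    ("cov_suv", "cd163"): 0.959,
    ("entropy_bits", "cd163"): 1.066,
    ("blr", "cd163"): 1.063,
    ("max_suv", "il6"): 1.038,
    ("mtv_cm3", "il6"): 1.160,
    ("tlg_g", "il6"): 1.258,
    ("mean_suv", "il6"): 1.089,
    ("median_suv", "il6"): 1.092,
    ("uniformity", "il6"): 0.857,
    ("slr", "il6"): 1.032,
    ("cov_suv", "mmp11"): 0.958,
}

#: default log-hazard coefficients (per scaled unit, see DEFAULT_COVARIATE_SCALINGS)
DEFAULT_LOG_HAZARD_COEFS: dict[str, float] = {
    "tnm_stage_34": math.log(2.341),
    "cov_suv": math.log(0.484),
    "slr": math.log(24.901),
}

#: unit per covariate: the coefficient applies per this much of the raw value
DEFAULT_COVARIATE_SCALINGS: dict[str, float] = {
    "tnm_stage_34": 1.0,
    "cov_suv": 0.10,
    "slr": 1.0,
}

COLUMN_DICTIONARY: dict[str, str] = {
    "id": "patient identifier",
    "age_years": "age at surgery, years",
    "sex": "M or F",
    "tumor_location": "right_colon, left_colon or rectum",
    "cea_ng_ml": "preoperative serum carcinoembryonic antigen, ng/ml",
    "tumor_size_cm": "pathologic tumor size, cm",
    "tumor_grade": "low (well/moderately differentiated) or high",
    "lvi": "lymphovascular invasion, absent/present",
    "tnm_stage": "pathologic stage I..IV",
    "adjuvant": "adjuvant treatment, yes/no",
    "cd4_grade": "CD4+ cell infiltration grade 0/1/2",
    "cd8_grade": "CD8+ cell infiltration grade 0/1/2",
    "cd163_grade": "CD163+ cell infiltration grade 0/1/2",
    "il6_grade": "IL-6 expression grade 0/1/2",
    "mmp11_grade": "MMP-11 expression grade 0/1/2",
    "max_suv": "maximum tumor SUV",
    "mean_suv": "mean tumor SUV",
    "median_suv": "median tumor SUV",
    "mtv_cm3": "metabolic tumor volume, cm3",
    "tlg_g": "total lesion glycolysis, g",
    "cov_suv": "coefficient of variation of tumor SUV",
    "kurtosis": "intensity-histogram kurtosis",
    "skewness": "intensity-histogram skewness",
    "entropy_bits": "intensity-histogram entropy, bits",
    "uniformity": "intensity-histogram uniformity",
    "bm_suv": "bone-marrow SUV (six-vertebra mean)",
    "liver_suv": "liver SUV (3-cm VOI mean)",
    "spleen_suv": "spleen SUV (2-cm VOI mean)",
    "blr": "bone marrow-to-liver uptake ratio",
    "slr": "spleen-to-liver uptake ratio",
    "rfs_months": "observed recurrence-free survival time, months",
    "event": "1 = recurrence or death observed, 0 = censored",
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``baseline_hazard_rate`` (events/month for a subject with zero scaled
    covariates) defaults to a value calibrated so that, under the default
    coefficients and feature distributions, roughly a quarter of subjects
    experience an event within the follow-up window.
    """

    n_patients: int = 119
    grade_probs: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_PROBS))
    feature_base_medians: dict = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_BASE_MEDIANS)
    )
    feature_grade_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_GRADE_SHIFTS)
    )
    log_hazard_coefs: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HAZARD_COEFS))
    covariate_scalings: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SCALINGS))
    baseline_hazard_rate: float = 1.05e-3
    censoring_window_months: tuple[float, float] = (26.1, 84.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for marker, probs in self.grade_probs.items():
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"grade probabilities for {marker!r} must be a triple summing to 1")
        lo, hi = self.censoring_window_months
        if not 0 < lo < hi:
            raise ValueError("censoring window must be positive and ordered")
        if not self.log_hazard_coefs:
            raise ValueError("log_hazard_coefs must not be empty")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline hazard rate must be positive")


@dataclass
class Cohort:
    """A patient table plus provenance (generator spec/seed or source file)."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("a cohort needs at least 2 records")
        if self.records["id"].duplicated().any():
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls(pd.read_csv(path), provenance={"file": str(path)})


def _sample_clinical(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinical covariates with frequencies typical of a curative-surgery series."""
    age = np.clip(np.rint(rng.normal(65, 10, n)), 35, 84).astype(int)
    return pd.DataFrame(
        {
            "age_years": age,
            "sex": rng.choice(["M", "F"], n, p=[63 / 119, 56 / 119]),
            "tumor_location": rng.choice(
                ["right_colon", "left_colon", "rectum"], n, p=[41 / 119, 65 / 119, 13 / 119]
            ),
            "cea_ng_ml": np.round(np.exp(rng.normal(np.log(6.4), 1.1, n)), 1),
            "tumor_size_cm": np.round(np.exp(rng.normal(np.log(5.1), 0.35, n)), 1),
            "tumor_grade": rng.choice(["low", "high"], n, p=[101 / 119, 18 / 119]),
            "lvi": rng.choice(["absent", "present"], n, p=[76 / 119, 43 / 119]),
            "tnm_stage": rng.choice(
                ["I", "II", "III", "IV"], n, p=[12 / 119, 51 / 119, 48 / 119, 8 / 119]
            ),
            "adjuvant": rng.choice(["yes", "no"], n, p=[100 / 119, 19 / 119]),
        }
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Sample a cohort from the generative model; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    df = _sample_clinical(rng, n)
    df.insert(0, "id", [f"P{i + 1:04d}" for i in range(n)])

    for marker in MARKERS:
        probs = spec.grade_probs.get(marker, (1 / 3, 1 / 3, 1 / 3))
        df[f"{marker}_grade"] = rng.choice([0, 1, 2], n, p=probs)

    for feat, (median, sigma) in spec.feature_base_medians.items():
        log_med = np.full(n, math.log(median))
        for (f, marker), shift in spec.feature_grade_shifts.items():
            if f == feat:
                log_med += df[f"{marker}_grade"].to_numpy() * math.log(shift)
        df[feat] = np.exp(log_med + sigma * rng.standard_normal(n))

    # ratio identities hold exactly within each record
    df["bm_suv"] = df["blr"] * df["liver_suv"]
    df["spleen_suv"] = df["slr"] * df["liver_suv"]

    df["tnm_stage_34"] = df["tnm_stage"].isin(["III", "IV"]).astype(float)
    lp = np.zeros(n)
    for name, coef in spec.log_hazard_coefs.items():
        if name not in df.columns:
            raise ValueError(f"hazard covariate {name!r} is not a cohort column")
        scale = spec.covariate_scalings.get(name, 1.0)
        lp += coef * df[name].to_numpy(dtype=float) / scale
    rate = spec.baseline_hazard_rate * np.exp(lp)
    if not np.all(np.isfinite(rate)):
        raise ValueError("non-finite hazard rate; check coefficients and scalings")

    event_time = rng.exponential(1.0 / rate)
    lo, hi = spec.censoring_window_months
    censor_time = rng.uniform(lo, hi, n)
    df["rfs_months"] = np.minimum(event_time, censor_time)
    df["event"] = (event_time <= censor_time).astype(int)
    df = df.drop(columns=["tnm_stage_34"])

    return Cohort(
        records=df,
        provenance={"synthetic": True, "seed": spec.seed, "n_patients": n},
    )
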