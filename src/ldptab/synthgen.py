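"""Synthetic validation inputs: simple sequences and an APACHE-like table.

Real ICU tables (eICU and friends) are credentialed, so every stage of
the pipeline is exercised on synthetic stand-ins instead:

* :func:`gen_uniform_grid` — an equally spaced continuous sequence on
  [-1, 1], for eyeballing the bounded mechanism's support;
* :func:`gen_random_categories` — uniform random integer categories,
  for the discretization round trip;
* :func:`gen_clinical_table` — a mixed-type severity-of-illness table:
  four binary treatment flags, the three Glasgow coma components
  (eyes m=4, motor m=5, verbal m=6 — cardinalities as in the APACHE
  input list; published per-component ranges vary and are sometimes
  swapped between verbal and motor), sixteen bounded continuous
  vitals/labs drawn from truncated normals inside hard physiological
  ranges, and a binary in-hospital mortality label.

The mortality label follows a logistic model on five severity markers
(tachycardia, hypotension, renal dysfunction, low motor response, high
oxygen requirement) with fixed, deliberately strong coefficients so
classifiers have recoverable signal and the privacy-utility curve has
visible dynamic range; the intercept is calibrated on the drawn sample
to hit the target prevalence.  Coefficients and intercept are recorded
in the emitted schema's metadata.

What this generator does NOT emulate: inter-variable correlation
structure, missingness patterns, measurement artifacts, or survival
times — tests passing here validate the perturbation machinery, not
clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema import ColumnSchema, TableSchema

__all__ = [
    "ClinicalTableSpec",
    "gen_uniform_grid",
    "gen_random_categories",
    "gen_clinical_table",
    "CONTINUOUS_COLUMNS",
    "OUTCOME_COEFFICIENTS",
]

#: name -> (lower, upper, mean, sd): hard physiological range and the
#: untruncated moments of the truncated-normal draw.
CONTINUOUS_COLUMNS = {
    "urine_output": (0.0, 5000.0, 1500.0, 900.0),      # mL/day
    "temperature": (30.0, 42.0, 36.8, 0.9),            # degC
    "respiratory_rate": (4.0, 60.0, 19.0, 6.0),        # /min
    "sodium": (110.0, 165.0, 139.0, 5.0),              # mmol/L
    "heart_rate": (30.0, 200.0, 92.0, 22.0),           # /min
    "mean_blood_pressure": (30.0, 160.0, 78.0, 16.0),  # mmHg
    "ph": (6.8, 7.8, 7.38, 0.08),
    "hematocrit": (10.0, 60.0, 33.0, 6.0),             # %
    "creatinine": (0.2, 15.0, 1.4, 1.2),               # mg/dL
    "albumin": (1.0, 5.5, 3.0, 0.7),                   # g/dL
    "oxygen_pressure": (30.0, 500.0, 95.0, 40.0),      # mmHg (PaO2)
    "co2_pressure": (10.0, 100.0, 40.0, 10.0),         # mmHg (PaCO2)
    "blood_urea_nitrogen": (2.0, 150.0, 25.0, 18.0),   # mg/dL
    "glucose": (30.0, 600.0, 140.0, 60.0),             # mg/dL
    "bilirubin": (0.1, 30.0, 1.0, 1.5),                # mg/dL
    "fio2": (0.21, 1.0, 0.5, 0.2),                     # fraction
}

_BINARY_COLUMNS = {
    "intubated": 0.35,
    "ventilation": 0.40,
    "dialysis": 0.08,
    "medication": 0.60,
}

#: Glasgow coma components: cardinality and category probabilities
#: (index 0 = worst response), skewed toward intact responses.
_ORDINAL_COLUMNS = {
    "eyes": (4, (0.15, 0.10, 0.15, 0.60)),
    "motor": (5, (0.08, 0.07, 0.10, 0.20, 0.55)),
    "verbal": (6, (0.15, 0.07, 0.08, 0.10, 0.15, 0.45)),
}

#: Logistic mortality model on schema-normalized ([-1, 1]) features.
OUTCOME_COEFFICIENTS = {
    "heart_rate": 3.5,
    "mean_blood_pressure": -4.0,
    "creatinine": 3.5,
    "motor": -4.5,
    "fio2": 4.0,
}


@dataclass(frozen=True)
class ClinicalTableSpec:
    """Size, seed and outcome prevalence of a generated clinical table."""

    n: int = 4740
    seed: int = 0
    prevalence: float = 0.241
    label: str = "mortality"
    coefficients: dict = field(
        default_factory=lambda: dict(OUTCOME_COEFFICIENTS), compare=False
    )

    def __post_init__(self) -> None:
        if self.n < 100:
            raise ValueError(f"need n >= 100, got {self.n}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")


def gen_uniform_grid(n: int) -> np.ndarray:
    """``n`` equally spaced reals from -1 to 1 inclusive."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return np.linspace(-1.0, 1.0, n)


def gen_random_categories(n: int, m: int, seed: int = 0) -> np.ndarray:
    """``n`` uniform draws from the integer categories 0 .. m-1."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if m < 2:
        raise ValueError(f"need m >= 2, got {m}")
    rng = np.random.default_rng(seed)
    return rng.integers(0, m, size=n)


def _truncated_normal(lo, hi, mean, sd, n, rng) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def gen_clinical_table(spec: ClinicalTableSpec = ClinicalTableSpec()):
    """Generate the mixed clinical table and its schema.

    Returns ``(table, schema)``.  Every cell satisfies the emitted
    schema; the schema's continuous bounds are the hard physiological
    ranges (stable across seeds), and its metadata records the outcome
    model.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    data: dict[str, np.ndarray] = {}
    columns: list[ColumnSchema] = []

    for name, p in _BINARY_COLUMNS.items():
        data[name] = (rng.random(n) < p).astype(int)
        columns.append(ColumnSchema(name=name, kind="categorical", labels=(0, 1)))
    for name, (m, probs) in _ORDINAL_COLUMNS.items():
        data[name] = rng.choice(m, size=n, p=probs)
        columns.append(
            ColumnSchema(name=name, kind="categorical", labels=tuple(range(m)))
        )
    for name, (lo, hi, mean, sd) in CONTINUOUS_COLUMNS.items():
        data[name] = _truncated_normal(lo, hi, mean, sd, n, rng)
        columns.append(ColumnSchema(name=name, kind="continuous", lower=lo, upper=hi))

    # linear predictor on schema-normalized features
    z = np.zeros(n)
    norm = {}
    for name, beta in spec.coefficients.items():
        if name in CONTINUOUS_COLUMNS:
            lo, hi = CONTINUOUS_COLUMNS[name][:2]
            x = 2.0 * (data[name] - lo) / (hi - lo) - 1.0
        else:
            m = _ORDINAL_COLUMNS[name][0]
            x = -1.0 + 2.0 * data[name] / (m - 1)
        norm[name] = x
        z += beta * x

    # intercept calibrated on the drawn sample so E[sigmoid] hits the target
    def excess(c):
        return np.mean(1.0 / (1.0 + np.exp(-(z + c)))) - spec.prevalence

    intercept = float(optimize.brentq(excess, -50.0, 50.0))
    p_death = 1.0 / (1.0 + np.exp(-(z + intercept)))
    data[spec.label] = (rng.random(n) < p_death).astype(int)
    columns.append(ColumnSchema(name=spec.label, kind="categorical", labels=(0, 1)))

    schema = TableSchema(
        columns=tuple(columns),
        label=spec.label,
        metadata={
            "generator": "ldptab.synthgen.gen_clinical_table",
            "seed": spec.seed,
            "prevalence_target": spec.prevalence,
            "outcome_model": {
                "type": "logistic on schema-normalized features",
                "coefficients": dict(spec.coefficients),
                "intercept": intercept,
            },
        },
    )
    table = pd.DataFrame(data)
    return table, schema
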