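"""Reference condition table for nine fragmentation pathologies.

Published fluorescence-micrograph analyses of paired normal (NL) and
diseased cells — Huntington's (HD), Alzheimer's (AD), Down syndrome
(DS), Parkinson's (PD), amyotrophic lateral sclerosis (ALS), acute
kidney injury, diabetes/cancer (MitoNEET knockout), optic neuropathy
(OPA) and Ca2+ overload — provide, per condition: the network size N
(unit edges), the image-derived mean degree and normalized giant
cluster, the model values reported for them, and the fitted
fusion-to-fission ratios (C1, C2).  These numbers are the inputs that
drive the simulator when reproducing the reference conditions; the
original micrographs themselves are not redistributable.

``FRACTION_TABLE`` holds the companion normal-vs-diseased comparison:
rate ratios and steady-state species fractions per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["Condition", "CONDITIONS", "FRACTION_TABLE", "conditions_frame",
           "fractions_frame", "get_condition"]


@dataclass(frozen=True)
class Condition:
    """One reference condition: observed metrics and fitted rates."""

    condition: str
    state: str          # "normal" or "diseased"
    n_edges: int
    k_image: float      # mean degree extracted from the micrograph
    g_image: float      # Ng/N extracted from the micrograph
    k_model: float      # mean degree reported for the fitted model
    g_model: float      # Ng/N reported for the fitted model
    c1: float
    c2: float


CONDITIONS = (
    Condition("HD", "normal",   2664, 1.67, 0.0188, 1.67, 0.022,  4.9e-4, 4.40e-5),
    Condition("HD", "diseased", 2150, 1.63, 0.0186, 1.63, 0.0101, 4.9e-4, 2.20e-5),
    Condition("AD", "normal",    642, 1.64, 0.042,  1.64, 0.108,  7.0e-4, 2.30e-4),
    Condition("AD", "diseased", 1061, 1.62, 0.038,  1.62, 0.067,  7.0e-4, 1.90e-4),
    Condition("DS", "normal",   1916, 1.52, 0.017,  1.52, 0.017,  5.0e-4, 0.88e-4),
    Condition("DS", "diseased", 1365, 1.47, 0.010,  1.47, 0.010,  5.0e-4, 0.32e-4),
    Condition("PD", "normal",  19519, 1.72, 0.006,  1.72, 0.008,  1.2e-3, 7.00e-6),
    Condition("PD", "diseased", 8715, 1.70, 0.005,  1.70, 0.007,  9.8e-4, 7.00e-6),
    Condition("ALS", "normal",   103, 1.75, 0.369,  1.75, 0.359,  4.8e-4, 1.00e-4),
    Condition("ALS", "diseased",  72, 1.69, 0.222,  1.69, 0.225,  1.0e-4, 1.00e-4),
    Condition("Kidney", "normal",   5038, 1.66, 0.012, 1.66, 0.016, 9.1e-4, 4.00e-5),
    Condition("Kidney", "diseased", 5386, 1.64, 0.011, 1.64, 0.011, 9.0e-4, 0.25e-4),
    Condition("Diabetes", "normal",   3546, 1.67, 0.023, 1.67, 0.020, 9.8e-4, 4.50e-5),
    Condition("Diabetes", "diseased", 3504, 1.65, 0.010, 1.65, 0.013, 9.8e-4, 2.50e-5),
    Condition("OPA", "normal",   5263, 1.69, 0.0093, 1.69, 0.0081, 9.0e-4, 1.00e-5),
    Condition("OPA", "diseased", 7772, 1.67, 0.0055, 1.67, 0.0075, 7.6e-4, 1.00e-5),
    Condition("Ca", "normal",   3195, 1.59, 0.039, 1.59, 0.038, 7.0e-4, 1.46e-4),
    Condition("Ca", "diseased", 2576, 1.57, 0.032, 1.58, 0.032, 7.0e-4, 1.13e-4),
)

#: Normal-vs-diseased comparison per condition: C ratios and reported
#: steady-state species fractions (X1, X2, X3 sum to 1 per row).
FRACTION_TABLE = {
    "HD":       {"c1_ratio": 1.00, "c2_ratio": 2.00,
                 "x_normal": (0.359, 0.562, 0.079),
                 "x_ratios": (0.985, 0.948, 1.852)},
    "AD":       {"c1_ratio": 1.00, "c2_ratio": 1.21,
                 "x_normal": (0.432, 0.429, 0.140),
                 "x_ratios": (0.992, 0.969, 1.143)},
    "DS":       {"c1_ratio": 1.00, "c2_ratio": 2.75,
                 "x_normal": (0.454, 0.502, 0.044),
                 "x_ratios": (0.980, 0.939, 17.058)},
    "Ca":       {"c1_ratio": 1.00, "c2_ratio": 1.29,
                 "x_normal": (0.441, 0.459, 0.100),
                 "x_ratios": (0.990, 0.969, 1.238)},
    "Kidney":   {"c1_ratio": 1.01, "c2_ratio": 1.60,
                 "x_normal": (0.344, 0.605, 0.052),
                 "x_ratios": (0.991, 0.971, 1.704)},
    "Diabetes": {"c1_ratio": 1.00, "c2_ratio": 1.80,
                 "x_normal": (0.334, 0.614, 0.052),
                 "x_ratios": (0.990, 0.971, 1.739)},
    "OPA":      {"c1_ratio": 1.18, "c2_ratio": 1.00,
                 "x_normal": (0.292, 0.691, 0.018),
                 "x_ratios": (0.938, 1.030, 0.955)},
    "PD":       {"c1_ratio": 1.22, "c2_ratio": 1.00,
                 "x_normal": (0.260, 0.728, 0.012),
                 "x_ratios": (0.922, 1.032, 0.954)},
    "ALS":      {"c1_ratio": 4.80, "c2_ratio": 1.00,
                 "x_normal": (0.341, 0.468, 0.191),
                 "x_ratios": (0.875, 1.129, 0.976)},
}

#: Conditions whose fragmentation acts through the lateral (tip-to-side)
#: channel (C2 drops, C1 constant) vs the longitudinal (tip-to-tip) one.
LATERAL = ("HD", "AD", "DS", "Ca", "Kidney", "Diabetes")
LONGITUDINAL = ("OPA", "PD", "ALS")


def conditions_frame() -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in CONDITIONS])


def fractions_frame() -> pd.DataFrame:
    rows = []
    for cond, rec in FRACTION_TABLE.items():
        x1, x2, x3 = rec["x_normal"]
        r1, r2, r3 = rec["x_ratios"]
        rows.append({"condition": cond, "C1n/C1d": rec["c1_ratio"],
                     "C2n/C2d": rec["c2_ratio"], "X1n": x1, "X2n": x2,
                     "X3n": x3, "X1n/X1d": r1, "X2n/X2d": r2, "X3n/X3d": r3})
    return pd.DataFrame(rows)


def get_condition(condition: str, state: str = "normal") -> Condition:
    for c in CONDITIONS:
        if c.condition == condition and c.state == state:
            return c
    raise KeyError(f"no reference condition {condition!r}/{state!r}")
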