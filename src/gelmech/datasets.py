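"""Bundled reference measurements for six polyacrylamide (PAA) gel
formulations, spanning roughly 0.1-50 kPa.

These small tables are the published characterization results for the PAA
gel series used throughout the package's validation suite: a model-by-model
indentation comparison (Hertz and its corrected variants) and a
micropipette-aspiration pressure-sweep summary.  They serve as fixed inputs
for arithmetic-consistency checks; the package never fits anything to them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["indentation_model_comparison", "aspiration_summary"]

# per-sample moduli (kPa) under the four nested indentation models, plus the
# displayed finite-diameter correction percentage (integer, truncated)
_MODEL_COMPARISON = [
    # sample, E_H, E_H_fh, E_NH_fh, E_NH_fdh, displayed_percent
    ("PAA1", 0.18, 0.12, 0.13, 0.14, 7),
    ("PAA2", 1.82, 1.05, 1.15, 1.20, 4),
    ("PAA4", 3.46, 2.14, 2.27, 2.27, 0),
    ("PAA5", 11.39, 8.29, 8.55, 8.92, 4),
    ("PAA6", 11.39, 9.11, 10.36, 11.23, 7),
    ("PAA7", 67.91, 44.91, 47.11, 50.43, 7),
]

# aspiration pressure-sweep extremes and pooled moduli per sample:
# smallest/largest observed l/a, the pressures at the sweep ends (kPa,
# suction negative), and the pooled mean +/- SD modulus (kPa)
_ASPIRATION_SUMMARY = [
    # sample, l/a min, l/a max, p_min, p_max, E_PA_mean, E_PA_sd
    ("PAA1", 0.384, 0.735, -0.20, -0.08, 0.20, 0.02),
    ("PAA2", 0.338, 0.789, -1.35, -0.35, 1.02, 0.15),
    ("PAA3", 0.345, 0.755, -2.47, -0.88, 2.20, 0.14),
    ("PAA4", 0.423, 0.786, -6.55, -2.48, 5.27, 0.33),
    ("PAA5", 0.421, 0.798, -9.93, -3.84, 8.09, 0.53),
    ("PAA6", 0.393, 0.638, -31.98, -19.71, 40.85, 3.69),
]


def indentation_model_comparison() -> pd.DataFrame:
    """Reference moduli under the H / H-fh / NH-fh / NH-fdh models (kPa)."""
    return pd.DataFrame(
        _MODEL_COMPARISON,
        columns=["sample_id", "E_H", "E_H_fh", "E_NH_fh", "E_NH_fdh", "displayed_percent"],
    )


def aspiration_summary() -> pd.DataFrame:
    """Reference micropipette-aspiration sweep summary per sample."""
    return pd.DataFrame(
        _ASPIRATION_SUMMARY,
        columns=[
            "sample_id",
            "l_over_a_min",
            "l_over_a_max",
            "p_min_kpa",
            "p_max_kpa",
            "E_PA_mean",
            "E_PA_sd",
        ],
    )
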