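"""Arithmetic of the wet-lab validation assays.

Relative miRNA quantification by the 2^(-ddCt) method against a U6 reference,
Renilla/Firefly dual-luciferase normalization, and the two-sample t-test
(pooled-variance Student's by default, Welch available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CtMeasurement:
    """One sample's qPCR cycle thresholds for target and reference (U6)."""

    sample_id: str
    target_ct: float
    reference_ct: float
    condition: Literal["case", "control"]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.target_ct) and np.isfinite(self.reference_ct)):
            raise ValueError(f"{self.sample_id}: Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass(frozen=True)
class LuciferasePair:
    """One well's Renilla (reporter) and Firefly (transfection control) readings."""

    renilla: float
    firefly: float

    def __post_init__(self) -> None:
        if self.renilla <= 0 or self.firefly <= 0:
            raise ValueError("luciferase readings must be strictly positive")


def ddct_relative_expression(
    case: Sequence[CtMeasurement], control: Sequence[CtMeasurement]
) -> pd.DataFrame:
    """Livak 2^(-ddCt) relative expression anchored to the control-group mean dCt.

    dCt = target_ct - reference_ct per sample; ddCt = dCt - mean(control dCt);
    relative expression = 2^(-ddCt). Control folds therefore average to 1 on
    the log2 scale. Returns a DataFrame with one row per sample.
    """
    if not case or not control:
        raise ValueError("both condition groups must be nonempty")
    control_mean_dct = float(np.mean([m.delta_ct for m in control]))
    rows = []
    for m in [*control, *case]:
        ddct = m.delta_ct - control_mean_dct
        rows.append(
            {
                "sample_id": m.sample_id,
                "condition": m.condition,
                "delta_ct": m.delta_ct,
                "ddct": ddct,
                "relative_expression": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)


def luciferase_ratio(
    pairs: Sequence[LuciferasePair],
    normalize_to: Sequence[LuciferasePair] | None = None,
) -> list[float]:
    """Per-well Renilla/Firefly activity, optionally rescaled to a control-group mean of 1."""
    activities = [p.renilla / p.firefly for p in pairs]
    if normalize_to is not None:
        control_mean = float(np.mean([p.renilla / p.firefly for p in normalize_to]))
        activities = [a / control_mean for a in activities]
    return activities


def two_sample_t(
    a: Iterable[float],
    b: Iterable[float],
    variant: Literal["student", "welch"] = "student",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: returns (t, df, p).

    variant="student" pools variances (df = n1 + n2 - 2); "welch" uses the
    Satterthwaite approximation.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("at least one group must have nonzero variance")
    result = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(result.statistic), float(result.df), float(result.pvalue)


def average_technical_replicates(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells per sample on the Ct scale before dCt.

    Expects columns sample_id, condition, target_ct, reference_ct.
    """
    return (
        ct_table.groupby(["sample_id", "condition"], as_index=False)[
            ["target_ct", "reference_ct"]
        ].mean()
    )


def measurements_from_frame(ct_table: pd.DataFrame) -> tuple[list[CtMeasurement], list[CtMeasurement]]:
    """Split a tidy Ct table into (case, control) measurement lists."""
    required = {"sample_id", "condition", "target_ct", "reference_ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = set(ct_table["condition"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    case, control = [], []
    for row in ct_table.itertuples(index=False):
        m = CtMeasurement(
            sample_id=str(row.sample_id),
            target_ct=float(row.target_ct),
            reference_ct=float(row.reference_ct),
            condition=row.condition,
        )
        (case if row.condition == "case" else control).append(m)
    return case, control
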