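"""Paired fold-change differential expression and the commonly dysregulated set.

Fold changes are log2 ratios of tumor over matched-normal linear intensities.
A miRNA is differentially expressed in a grade when its fold change exceeds a
strict linear threshold (default: more than two-fold, in either direction);
the commonly dysregulated set is the per-direction intersection across grades.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from mirkey._ids import RETIRED_MIRNAS, normalize_mirna_id

logger = logging.getLogger(__name__)

Mode = Literal["mean", "all_pairs"]

GRADES = ("GI", "GII", "GIII")
TISSUES = ("tumor", "normal")


class PairingError(ValueError):
    """Sample metadata does not describe exactly one tumor/normal pair per patient."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Linear-scale intensities (miRNAs x samples) with paired sample metadata.

    ``intensities``: DataFrame indexed by miRNA id, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns
    ``patient_id``, ``grade``, ``tissue`` (tissue in {tumor, normal}).
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.samples.index) != set(self.intensities.columns):
            raise PairingError("sample sheet and intensity columns disagree")
        missing = {"patient_id", "grade", "tissue"} - set(self.samples.columns)
        if missing:
            raise PairingError(f"sample sheet missing columns: {sorted(missing)}")
        bad_tissue = set(self.samples["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise PairingError(f"unknown tissue labels: {sorted(bad_tissue)}")
        for patient, grp in self.samples.groupby("patient_id"):
            tissues = sorted(grp["tissue"])
            if tissues != ["normal", "tumor"]:
                raise PairingError(
                    f"patient {patient!r} must have exactly one tumor and one "
                    f"normal sample, got {list(grp['tissue'])}"
                )
        values = self.intensities.to_numpy()
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("intensities must be finite and strictly positive")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.intensities.index)

    def patients(self) -> pd.DataFrame:
        """One row per patient: patient_id, grade, tumor/normal sample ids."""
        rows = []
        for patient, grp in self.samples.groupby("patient_id", sort=True):
            by_tissue = dict(zip(grp["tissue"], grp.index))
            rows.append(
                {
                    "patient_id": patient,
                    "grade": grp["grade"].iloc[0],
                    "tumor_sample": by_tissue["tumor"],
                    "normal_sample": by_tissue["normal"],
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_tsv(cls, expr_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(expr, samples)

    def to_tsv(self, expr_path: str | Path, samples_path: str | Path) -> None:
        self.intensities.to_csv(expr_path, sep="\t", index_label="mirna_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class DifferentialCallSet:
    """Per-grade up/down call sets at a given linear fold threshold."""

    calls: Mapping[str, tuple[frozenset[str], frozenset[str]]]
    threshold_fold: float = 2.0

    def __post_init__(self) -> None:
        for grade, (up, down) in self.calls.items():
            up_keys = {normalize_mirna_id(m) for m in up}
            down_keys = {normalize_mirna_id(m) for m in down}
            if up_keys & down_keys:
                raise ValueError(f"grade {grade}: up and down sets overlap")

    def up(self, grade: str) -> frozenset[str]:
        return self.calls[grade][0]

    def down(self, grade: str) -> frozenset[str]:
        return self.calls[grade][1]

    @property
    def grades(self) -> list[str]:
        return list(self.calls)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mirna": m, "grade": grade, "direction": direction}
            for grade, (up, down) in self.calls.items()
            for direction, members in (("up", sorted(up)), ("down", sorted(down)))
            for m in members
        ]
        return pd.DataFrame(rows, columns=["mirna", "grade", "direction"])


@dataclass(frozen=True)
class CommonSet:
    """miRNAs differential in the same direction across every grade."""

    up: frozenset[str]
    down: frozenset[str]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if {normalize_mirna_id(m) for m in self.up} & {
            normalize_mirna_id(m) for m in self.down
        }:
            raise ValueError("common up and down sets overlap")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass(frozen=True)
class ExclusionAudit:
    """Outcome of removing validation-contradicted ids from a common set."""

    common: CommonSet
    removed: tuple[str, ...]
    not_found: tuple[str, ...] = ()


def pairwise_log2fc(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(tumor/normal) per (miRNA, patient).

    Returns a long DataFrame with columns mirna_id, patient_id, grade, log2fc.
    """
    patients = matrix.patients()
    frames = []
    for row in patients.itertuples(index=False):
        tumor = matrix.intensities[row.tumor_sample]
        normal = matrix.intensities[row.normal_sample]
        frames.append(
            pd.DataFrame(
                {
                    "mirna_id": matrix.intensities.index,
                    "patient_id": row.patient_id,
                    "grade": row.grade,
                    "log2fc": np.log2(tumor.to_numpy() / normal.to_numpy()),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    if not np.all(np.isfinite(records["log2fc"])):
        raise ValueError("non-finite fold change encountered")
    return records


def call_grade_differential(
    records: pd.DataFrame,
    threshold_fold: float = 2.0,
    mode: Mode = "mean",
) -> DifferentialCallSet:
    """Call per-grade differential miRNAs at a strict linear fold threshold.

    mode="mean": up iff mean per-pair log2fc > log2(threshold_fold), down iff
    < -log2(threshold_fold). mode="all_pairs": every pair in the grade must
    individually exceed the threshold in one direction. Inequalities are
    strict (a fold change of exactly the threshold is not called).
    """
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must be > 1")
    if mode not in ("mean", "all_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    cut = math.log2(threshold_fold)
    calls: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for grade, grp in records.groupby("grade", sort=True):
        if grp["patient_id"].nunique() == 0:
            raise ValueError(f"grade {grade}: no pairs")
        per_mirna = grp.groupby("mirna_id")["log2fc"]
        if mode == "mean":
            means = per_mirna.mean()
            up = frozenset(means.index[means > cut])
            down = frozenset(means.index[means < -cut])
        else:
            up = frozenset(per_mirna.min().pipe(lambda s: s.index[s > cut]))
            down = frozenset(per_mirna.max().pipe(lambda s: s.index[s < -cut]))
        calls[str(grade)] = (up, down)
    return DifferentialCallSet(calls=calls, threshold_fold=threshold_fold)


def common_dysregulated(
    callset: DifferentialCallSet, exclude_retired: bool = True
) -> CommonSet:
    """Per-direction intersection of the grade call sets.

    A miRNA must be called in the same direction in every grade; ids are
    matched via :func:`normalize_mirna_id`, and the representative spelling
    from the first grade is reported. By default, identifiers retired from
    miRBase (see :data:`mirkey._ids.RETIRED_MIRNAS`) are not eligible as
    candidates even when they intersect; pass ``exclude_retired=False`` for
    the raw intersection.
    """
    grades = callset.grades
    if len(grades) < 2:
        raise ValueError("need at least two grades to intersect")

    def intersect(direction: int) -> frozenset[str]:
        key_sets = [
            {normalize_mirna_id(m) for m in callset.calls[g][direction]} for g in grades
        ]
        common_keys = set.intersection(*key_sets)
        first = callset.calls[grades[0]][direction]
        return frozenset(m for m in first if normalize_mirna_id(m) in common_keys)

    up, down = intersect(0), intersect(1)
    if exclude_retired:
        up = frozenset(m for m in up if normalize_mirna_id(m) not in RETIRED_MIRNAS)
        down = frozenset(m for m in down if normalize_mirna_id(m) not in RETIRED_MIRNAS)
    # direction-consistency: normalized in both directions anywhere -> drop
    up_keys = {normalize_mirna_id(m) for m in up}
    down_keys = {normalize_mirna_id(m) for m in down}
    conflict = up_keys & down_keys
    if conflict:
        up = frozenset(m for m in up if normalize_mirna_id(m) not in conflict)
        down = frozenset(m for m in down if normalize_mirna_id(m) not in conflict)
    return CommonSet(up=up, down=down, provenance=tuple(grades))


def apply_validation_exclusions(
    common: CommonSet, excluded: Iterable[str]
) -> ExclusionAudit:
    """Remove ids whose independent validation contradicted the array call.

    Removing an id that is absent from the set is a logged no-op.
    """
    excluded_keys = {normalize_mirna_id(m): m for m in excluded}
    removed: list[str] = []

    def keep(members: frozenset[str]) -> frozenset[str]:
        kept = set()
        for m in members:
            if normalize_mirna_id(m) in excluded_keys:
                removed.append(m)
            else:
                kept.add(m)
        return frozenset(kept)

    up, down = keep(common.up), keep(common.down)
    removed_keys = {normalize_mirna_id(m) for m in removed}
    not_found = tuple(
        sorted(orig for key, orig in excluded_keys.items() if key not in removed_keys)
    )
    for orig in not_found:
        logger.info("exclusion id %r not present in common set (no-op)", orig)
    return ExclusionAudit(
        common=CommonSet(up=up, down=down, provenance=common.provenance),
        removed=tuple(sorted(removed)),
        not_found=not_found,
    )


@dataclass(frozen=True)
class FoldChangeRecord:
    """One (miRNA, patient) fold-change observation."""

    mirna_id: str
    patient_id: str
    grade: str
    log2fc: float = field(default=0.0)
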