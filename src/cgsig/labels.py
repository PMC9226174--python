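"""Survival-interval class labels, train/val/test splits, and CV folds.

Binary binning: OS < 24 months -> short-term (0); OS > 48 months ->
long-term (1); the 24-48 month band is *uncategorized* (kept out of
classifier data, retained for survival analysis).  Ternary binning uses 12
and 60 months (short / medium / long); the historical 50-month variant is
selectable.  Censored patients can only be labeled into the top class when
their follow-up already exceeds the upper threshold; otherwise their class
is unknowable and they are excluded from classifier data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cell_table_io import PatientRecord

UNCATEGORIZED = "uncategorized"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class BinningRule:
    mode: str = "binary"  # binary | ternary
    thresholds: tuple[float, float] = None

    def __post_init__(self):
        if self.mode not in ("binary", "ternary"):
            raise ValueError(f"unknown binning mode {self.mode!r}")
        if self.thresholds is None:
            object.__setattr__(
                self, "thresholds", (24.0, 48.0) if self.mode == "binary" else (12.0, 60.0)
            )
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("thresholds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return 2 if self.mode == "binary" else 3


def bin_survival(patient: PatientRecord, rule: BinningRule):
    """Class index for one patient, or 'uncategorized' / 'excluded'.

    Boundary values (OS exactly at a threshold) fall into the middle band.
    """
    t = patient.os_months
    if t < 0:
        raise ValueError("negative OS time")
    lo, hi = rule.thresholds
    if rule.mode == "binary":
        if t > hi:
            return 1  # long follow-up suffices even if censored
        if patient.event == 0:
            return EXCLUDED  # alive, class undecidable
        return 0 if t < lo else UNCATEGORIZED
    if t > hi:
        return 2
    if patient.event == 0:
        return EXCLUDED
    return 0 if t < lo else 1


def label_cohort(
    patients: Iterable[PatientRecord], rule: BinningRule
) -> dict[str, int | str]:
    return {p.patient_id: bin_survival(p, rule) for p in patients}


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.64, 0.16, 0.20)
    seed: int = 0
    stratify_by_class: bool = True

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if min(self.ratios) < 0:
            raise ValueError("split ratios must be non-negative")


def _apportion(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder rounding of n into parts proportional to ratios."""
    raw = [n * r for r in ratios]
    base = [int(np.floor(v)) for v in raw]
    rem = n - sum(base)
    order = np.argsort([b - v for b, v in zip(base, raw)])  # largest remainder first
    for i in order[:rem]:
        base[i] += 1
    return base

_PARTS = ("train", "val", "test")


def split_patients(
    patient_ids: list[str],
    spec: SplitSpec = SplitSpec(),
    labels: dict[str, int] | None = None,
) -> dict[str, str]:
    """Patient-level train/val/test partition, stratified by class when labels given.

    Returns patient_id -> 'train' | 'val' | 'test'.  Every patient lands in
    exactly one partition; the assignment is a pure function of (ids, spec).
    """
    if len(patient_ids) < 5:
        raise ValueError("need at least 5 patients to split")
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("duplicate patient ids")
    rng = np.random.default_rng(spec.seed)
    assignment: dict[str, str] = {}
    if spec.stratify_by_class and labels is not None:
        strata: dict[object, list[str]] = {}
        for pid in patient_ids:
            strata.setdefault(labels.get(pid), []).append(pid)
        groups = [sorted(v) for _, v in sorted(strata.items(), key=lambda kv: str(kv[0]))]
    else:
        groups = [sorted(patient_ids)]
    for members in groups:
        members = list(rng.permutation(members))
        sizes = _apportion(len(members), spec.ratios)
        start = 0
        for part, size in zip(_PARTS, sizes):
            for pid in members[start : start + size]:
                assignment[pid] = part
            start += size
    return assignment


@dataclass
class CVFolds:
    k: int
    assignment: dict[str, int]

    def fold_members(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)


def make_cv_folds(
    patient_ids: list[str],
    k: int = 5,
    seed: int = 0,
    labels: dict[str, int] | None = None,
) -> CVFolds:
    """k non-overlapping patient folds, stratified by class label when given."""
    n = len(patient_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of patients ({n})")
    if len(set(patient_ids)) != n:
        raise ValueError("duplicate patient ids")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    if labels is not None:
        strata: dict[object, list[str]] = {}
        for pid in patient_ids:
            strata.setdefault(labels.get(pid), []).append(pid)
        groups = [sorted(v) for _, v in sorted(strata.items(), key=lambda kv: str(kv[0]))]
    else:
        groups = [sorted(patient_ids)]
    offset = 0  # rotate fold order across strata to keep fold sizes within 1
    for members in groups:
        members = list(rng.permutation(members))
        for i, pid in enumerate(members):
            assignment[pid] = (i + offset) % k
        offset += len(members)
    return CVFolds(k=k, assignment=assignment)
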