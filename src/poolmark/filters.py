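"""Clinical cohort filters.

A filter is a conjunction of constraints on clinical covariates (receptor
status, nodal status, grade, treatment, age, size).  A sample passes iff it
satisfies every stated constraint; a sample with a *missing* value in a
constrained field is excluded, while unconstrained fields never exclude
anyone — so the empty filter is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .data_model import ClinicalTable, DatasetBundle

_STATUS_FIELDS = ("er_status", "pr_status", "her2_status", "ln_status")
_YESNO_FIELDS = ("chemo", "hormone")


@dataclass(frozen=True)
class FilterSpec:
    er_status: Optional[str] = None
    pr_status: Optional[str] = None
    her2_status: Optional[str] = None
    ln_status: Optional[str] = None
    grade: Optional[frozenset[int]] = None
    chemo: Optional[str] = None
    hormone: Optional[str] = None
    age: Optional[tuple[float, float]] = None       # closed interval, years
    size_cm: Optional[tuple[float, float]] = None   # closed interval, cm

    def __post_init__(self) -> None:
        for f in _STATUS_FIELDS:
            v = getattr(self, f)
            if v is not None and v not in ("pos", "neg"):
                raise ValueError(f"{f} constraint must be 'pos' or 'neg', got {v!r}")
        for f in _YESNO_FIELDS:
            v = getattr(self, f)
            if v is not None and v not in ("yes", "no"):
                raise ValueError(f"{f} constraint must be 'yes' or 'no', got {v!r}")
        if self.grade is not None:
            object.__setattr__(self, "grade", frozenset(int(g) for g in self.grade))
            if not self.grade or not self.grade <= {1, 2, 3}:
                raise ValueError(f"grade constraint must be a non-empty subset of {{1,2,3}}")
        for f in ("age", "size_cm"):
            iv = getattr(self, f)
            if iv is not None:
                lo, hi = iv
                if not (lo <= hi):
                    raise ValueError(f"{f} interval {iv} is not well-ordered")

    def is_empty(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in (*_STATUS_FIELDS, *_YESNO_FIELDS, "grade", "age", "size_cm")
        )


def apply_filter(target: DatasetBundle | ClinicalTable, spec: FilterSpec | None) -> pd.Series:
    """Boolean mask (indexed by sample id) of samples passing the filter."""
    clinical = target.clinical if isinstance(target, DatasetBundle) else target
    df = clinical.data
    mask = pd.Series(True, index=df.index)
    if spec is None:
        return mask
    for f in (*_STATUS_FIELDS, *_YESNO_FIELDS):
        want = getattr(spec, f)
        if want is not None:
            mask &= df[f] == want  # NaN compares False -> missing excluded
    if spec.grade is not None:
        mask &= df["grade"].isin([float(g) for g in spec.grade])
    if spec.age is not None:
        lo, hi = spec.age
        mask &= df["age"].notna() & (df["age"] >= lo) & (df["age"] <= hi)
    if spec.size_cm is not None:
        lo, hi = spec.size_cm
        mask &= df["size_cm"].notna() & (df["size_cm"] >= lo) & (df["size_cm"] <= hi)
    return mask
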