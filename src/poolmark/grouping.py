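"""Within-dataset dichotomization and multi-marker combination.

Expression values from different cohorts/platforms are never directly
comparable, so each cohort is split into "high" and "low" expressors on its
own distribution (median or quartile cut-off) and only the *labels* are
pooled.  Because the labels depend on the data only through within-cohort
ranks, any strictly increasing per-cohort transform (re-normalization, log
base change, platform drift) leaves every downstream statistic unchanged.

Tie convention: "high" is strictly greater than the cut-off; samples exactly
at the cut-off go to the majority side (low for median/upper-quartile, high
for lower-quartile).  Quantiles are linear-interpolation quantiles of the
non-missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import StudyCollection
from .errors import DataError, QueryError
from .filters import FilterSpec, apply_filter

logger = logging.getLogger(__name__)

HIGH, LOW, EXCLUDED = "high", "low", "excluded"


class CutoffRule(str, Enum):
    MEDIAN = "median"
    UPPER_QUARTILE = "upper_quartile"
    LOWER_QUARTILE = "lower_quartile"


_QUANTILE = {
    CutoffRule.MEDIAN: 0.5,
    CutoffRule.UPPER_QUARTILE: 0.75,
    CutoffRule.LOWER_QUARTILE: 0.25,
}


@dataclass
class GroupAssignment:
    """Per-sample high/low/excluded labels for one marker set in one cohort."""

    dataset_id: str
    gene_ids: tuple[str, ...]
    rule: CutoffRule
    labels: pd.Series  # index = sample ids, values in {high, low, excluded}

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def _cutoff(nonmissing: np.ndarray, rule: CutoffRule) -> float:
    return float(np.quantile(nonmissing, _QUANTILE[rule], method="linear"))


def _label_against_cutoff(values: pd.Series, cut: float, rule: CutoffRule) -> pd.Series:
    labels = pd.Series(EXCLUDED, index=values.index, dtype=object)
    obs = values.notna()
    if rule is CutoffRule.LOWER_QUARTILE:
        labels[obs] = np.where(values[obs] < cut, LOW, HIGH)
    else:
        labels[obs] = np.where(values[obs] > cut, HIGH, LOW)
    return labels


def dichotomize(values: pd.Series, rule: CutoffRule | str) -> pd.Series:
    """Label each sample high/low by the chosen within-cohort cut-off.

    median: high iff value > median; upper_quartile: high iff value > Q3
    (top quarter vs the rest); lower_quartile: low iff value < Q1 (bottom
    quarter vs the rest).  Missing values are labelled ``excluded``.
    """
    rule = CutoffRule(rule)
    nonmissing = values.dropna().to_numpy(dtype=float)
    if nonmissing.size < 2:
        raise DataError(
            f"degenerate distribution: {nonmissing.size} non-missing value(s)"
        )
    return _label_against_cutoff(values, _cutoff(nonmissing, rule), rule)


def combine_markers(
    assignments: Sequence[GroupAssignment], rule: str = "all_high"
) -> GroupAssignment:
    """Intersect marker groups: all_high labels a sample high iff *every*
    marker labels it high (else low); all_low is the mirror image.  Any
    exclusion propagates."""
    if rule not in ("all_high", "all_low"):
        raise ValueError(f"unknown combination rule {rule!r}")
    if len(assignments) < 2:
        raise ValueError("combine_markers needs at least two assignments")
    first = assignments[0]
    for a in assignments[1:]:
        if a.dataset_id != first.dataset_id:
            raise DataError("assignments come from different datasets")
        if list(a.labels.index) != list(first.labels.index):
            raise DataError("assignments cover different sample sets")
    stack = pd.concat([a.labels for a in assignments], axis=1)
    excluded = (stack == EXCLUDED).any(axis=1)
    if rule == "all_high":
        hit = (stack == HIGH).all(axis=1)
        labels = pd.Series(np.where(hit, HIGH, LOW), index=first.labels.index, dtype=object)
    else:
        hit = (stack == LOW).all(axis=1)
        labels = pd.Series(np.where(hit, LOW, HIGH), index=first.labels.index, dtype=object)
    labels[excluded] = EXCLUDED
    genes = tuple(g for a in assignments for g in a.gene_ids)
    return GroupAssignment(first.dataset_id, genes, first.rule, labels)


def assign_groups(
    collection: StudyCollection,
    gene_ids: Sequence[str],
    rule: CutoffRule | str = CutoffRule.MEDIAN,
    combine: str = "single",
    cohort_filter: Optional[FilterSpec] = None,
    cutoff_scope: str = "filtered",
    sample_masks: Optional[Mapping[str, pd.Series]] = None,
) -> list[GroupAssignment]:
    """Per-dataset group assignment for one marker (or marker combination).

    Samples failing the clinical filter (or an extra per-dataset boolean
    ``sample_masks`` entry, e.g. a molecular-subtype restriction) are
    excluded.  Cut-offs are computed over the filtered sub-cohort when
    ``cutoff_scope='filtered'`` (default) or over all samples when ``'full'``.
    Datasets missing any queried gene contribute no assignment (logged);
    if no dataset carries all genes a :class:`QueryError` is raised.
    """
    rule = CutoffRule(rule)
    gene_ids = tuple(gene_ids)
    if not gene_ids:
        raise QueryError("no genes queried")
    if combine == "single" and len(gene_ids) != 1:
        raise QueryError("combine='single' requires exactly one gene")
    if combine not in ("single", "all_high", "all_low"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if cutoff_scope not in ("filtered", "full"):
        raise ValueError(f"unknown cutoff_scope {cutoff_scope!r}")

    out: list[GroupAssignment] = []
    for bundle in collection.bundles:
        gm = bundle.gene_matrix
        missing = [g for g in gene_ids if g not in gm.data.index]
        if missing:
            logger.warning(
                "dataset %r lacks gene(s) %s; skipped", bundle.dataset_id, missing
            )
            continue
        keep = apply_filter(bundle, cohort_filter)
        if sample_masks is not None and bundle.dataset_id in sample_masks:
            keep = keep & sample_masks[bundle.dataset_id].reindex(keep.index, fill_value=False)
        per_gene: list[GroupAssignment] = []
        degenerate = False
        for gene in gene_ids:
            values = gm.data.loc[gene]
            scope = values[keep] if cutoff_scope == "filtered" else values
            nonmissing = scope.dropna().to_numpy(dtype=float)
            if nonmissing.size < 2:
                logger.warning(
                    "dataset %r: <2 usable values for gene %r under the filter; skipped",
                    bundle.dataset_id, gene,
                )
                degenerate = True
                break
            labels = _label_against_cutoff(values, _cutoff(nonmissing, rule), rule)
            labels[~keep] = EXCLUDED
            per_gene.append(GroupAssignment(bundle.dataset_id, (gene,), rule, labels))
        if degenerate:
            continue
        if combine == "single":
            out.append(per_gene[0])
        else:
            out.append(combine_markers(per_gene, combine))
    if not out:
        raise QueryError(f"gene not measured: no dataset carries all of {list(gene_ids)}")
    return out


def write_assignments(assignments: Sequence[GroupAssignment], path: str | Path) -> None:
    """Audit export: one row per sample (dataset_id, sample_id, label)."""
    with open(Path(path), "w") as fh:
        fh.write("dataset_id\tsample_id\tlabel\n")
        for a in assignments:
            for sid, lab in a.labels.items():
                fh.write(f"{a.dataset_id}\t{sid}\t{lab}\n")
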