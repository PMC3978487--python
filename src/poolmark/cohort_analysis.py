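"""Query orchestration: clinical filtering, subtype stratification, sweeps,
and the consensus significance rule.

A query names one or more genes, a cut-off rule, a survival endpoint, an
optional clinical filter and an optional molecular subtype (with the
classifier that defines it).  The pipeline is: subtype labels (if
requested, computed on the full cohort — labels are sample-intrinsic) ->
per-dataset clinical filter -> per-dataset dichotomization / marker
combination -> pooled KM / log-rank / Cox.

A sweep runs the query grid genes x endpoints x cut-offs under each of
several classifiers and applies a consensus rule: a (gene, endpoint,
cut-off) cell is called significant when the log-rank p is strictly below
alpha under at least ``min_classifiers`` of the classifiers (default 2 of
3 at alpha 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .data_model import StudyCollection
from .errors import DataError, PoolmarkError, QueryError
from .filters import FilterSpec, apply_filter  # re-exported module surface
from .grouping import CutoffRule, GroupAssignment, assign_groups
from .subtype_classifier import CentroidModel, classify_collection, subtype_masks
from .survival_stats import KMCurve, PooledCohort, TestResult, analyze_pooled

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec", "apply_filter", "QuerySpec", "MarkerResult", "ConsensusCall",
    "run_query", "sweep", "consensus_significant", "results_to_tsv",
]


@dataclass(frozen=True)
class QuerySpec:
    gene_ids: tuple[str, ...]
    endpoint: str = "dfs"
    cutoff: CutoffRule = CutoffRule.MEDIAN
    combine: str = "single"  # single | all_high | all_low
    filter: Optional[FilterSpec] = None
    subtype: Optional[str] = None
    classifier: Optional[str] = None
    cutoff_scope: str = "filtered"
    stratify_by_dataset: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "cutoff", CutoffRule(self.cutoff))
        object.__setattr__(self, "endpoint", self.endpoint.lower())
        if self.subtype is not None and self.classifier is None:
            raise QueryError("a subtype restriction requires a classifier")


@dataclass
class MarkerResult:
    """One answered query: pooled statistics plus provenance."""

    query: QuerySpec
    test: TestResult
    km: KMCurve
    cohort: PooledCohort
    per_dataset_n: dict[str, int]
    warnings: list[str] = field(default_factory=list)
    mirna_id: Optional[str] = None
    host_gene_proxy: bool = False  # result inferred from host-gene expression


@dataclass
class ConsensusCall:
    gene_id: str
    endpoint: str
    cutoff: CutoffRule
    cells: dict[str, Optional[dict]]  # classifier -> {hr, p, n} or None (NA cell)
    significant: bool
    messages: list[str] = field(default_factory=list)


def consensus_significant(
    pvalues: Sequence[Optional[float]], alpha: float = 0.05, min_classifiers: int = 2
) -> bool:
    """Strictly-below-alpha consensus over the attempted classifiers."""
    hits = sum(1 for p in pvalues if p is not None and p < alpha)
    return hits >= min_classifiers


def run_query(
    collection: StudyCollection,
    q: QuerySpec,
    centroid_models: Optional[Mapping[str, CentroidModel]] = None,
    _subtype_calls: Optional[dict[str, pd.DataFrame]] = None,
) -> MarkerResult:
    """Answer one marker query against the pooled collection."""
    universe = collection.gene_universe
    absent = [g for g in q.gene_ids if g not in universe]
    if absent:
        raise QueryError(f"gene not measured: {absent}")
    masks = None
    if q.subtype is not None:
        if _subtype_calls is None:
            if not centroid_models or q.classifier not in centroid_models:
                raise QueryError(f"no centroid model supplied for classifier {q.classifier!r}")
            _subtype_calls = classify_collection(collection, centroid_models[q.classifier])
        masks = subtype_masks(_subtype_calls, q.subtype)
    assignments = assign_groups(
        collection,
        q.gene_ids,
        rule=q.cutoff,
        combine=q.combine,
        cohort_filter=q.filter,
        cutoff_scope=q.cutoff_scope,
        sample_masks=masks,
    )
    try:
        cohort, km, test = analyze_pooled(
            assignments, collection.clinical_map(), q.endpoint,
            stratify_by_dataset=q.stratify_by_dataset,
        )
    except DataError as exc:
        raise QueryError(f"{exc} (query: genes={list(q.gene_ids)}, endpoint={q.endpoint})") from exc
    return MarkerResult(
        query=q,
        test=test,
        km=km,
        cohort=cohort,
        per_dataset_n=cohort.per_dataset_n,
    )


def sweep(
    collection: StudyCollection,
    genes: Sequence[str],
    endpoints: Sequence[str],
    cutoffs: Sequence[CutoffRule | str],
    classifiers: Optional[Mapping[str, CentroidModel]] = None,
    cohort_filter: Optional[FilterSpec] = None,
    subtype: Optional[str] = None,
    alpha: float = 0.05,
    min_classifiers: int = 2,
) -> list[ConsensusCall]:
    """Grid of queries with a per-cell consensus call.

    Cells that fail (endpoint absent, single-group cohort, ...) become
    explicit NA cells so the consensus counts attempted classifiers only.
    Without classifiers (or subtype), a single unstratified cell named
    "all" is evaluated per combination.
    """
    if subtype is not None and not classifiers:
        raise QueryError("a subtype sweep requires at least one classifier")
    # Subtype labels are sample-intrinsic: classify once per classifier.
    calls_by_classifier: dict[str, Optional[dict]] = {}
    if classifiers and subtype is not None:
        for name, model in classifiers.items():
            calls_by_classifier[name] = classify_collection(collection, model)
    else:
        calls_by_classifier["all"] = None
    out: list[ConsensusCall] = []
    for gene in genes:
        for endpoint in endpoints:
            for cutoff in cutoffs:
                cutoff = CutoffRule(cutoff)
                cells: dict[str, Optional[dict]] = {}
                messages: list[str] = []
                for name, calls in calls_by_classifier.items():
                    q = QuerySpec(
                        gene_ids=(gene,),
                        endpoint=endpoint,
                        cutoff=cutoff,
                        filter=cohort_filter,
                        subtype=subtype if calls is not None else None,
                        classifier=name if calls is not None else None,
                    )
                    try:
                        res = run_query(collection, q, _subtype_calls=calls)
                    except PoolmarkError as exc:
                        cells[name] = None
                        messages.append(f"{name}: {exc}")
                        continue
                    cells[name] = {
                        "hr": res.test.hr,
                        "p": res.test.logrank_p,
                        "n": res.test.n,
                    }
                pvals = [c["p"] if c is not None else None for c in cells.values()]
                out.append(
                    ConsensusCall(
                        gene_id=gene,
                        endpoint=endpoint.lower(),
                        cutoff=cutoff,
                        cells=cells,
                        significant=consensus_significant(pvals, alpha, min_classifiers),
                        messages=messages,
                    )
                )
    return out


def results_to_tsv(results: Sequence[MarkerResult], path: str | Path) -> None:
    """One row per answered query (per-dataset n packed as ds:n;ds:n)."""
    cols = (
        "marker", "mirna_id", "endpoint", "cutoff", "combine", "n", "events",
        "hr", "hr_ci_low", "hr_ci_high", "logrank_chi2", "logrank_p", "cox_p",
        "separation", "per_dataset_n",
    )
    with open(Path(path), "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            packed = ";".join(f"{ds}:{n}" for ds, n in sorted(r.per_dataset_n.items()))
            t = r.test
            fh.write(
                "\t".join(
                    [
                        "+".join(r.query.gene_ids),
                        r.mirna_id or "",
                        r.query.endpoint,
                        r.query.cutoff.value,
                        r.query.combine,
                        str(t.n),
                        str(t.events),
                        f"{t.hr:.6g}", f"{t.hr_ci_low:.6g}", f"{t.hr_ci_high:.6g}",
                        f"{t.logrank_chi2:.6g}", f"{t.logrank_p:.6g}", f"{t.cox_p:.6g}",
                        str(int(t.separation)),
                        packed,
                    ]
                )
                + "\n"
            )


def sweep_to_tsv(calls: Sequence[ConsensusCall], path: str | Path) -> None:
    """Long-format sweep export: one row per (gene, endpoint, cutoff, classifier)."""
    with open(Path(path), "w") as fh:
        fh.write("gene\tendpoint\tcutoff\tclassifier\thr\tp\tn\tsignificant\n")
        for call in calls:
            for name, cell in call.cells.items():
                if cell is None:
                    hr = p = n = "NA"
                else:
                    hr, p, n = f"{cell['hr']:.6g}", f"{cell['p']:.6g}", str(cell["n"])
                fh.write(
                    f"{call.gene_id}\t{call.endpoint}\t{call.cutoff.value}\t{name}\t"
                    f"{hr}\t{p}\t{n}\t{int(call.significant)}\n"
                )
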