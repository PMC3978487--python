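"""Nearest-centroid molecular-subtype classification.

A pluggable centroid table (subtype x gene, e.g. the published ssp2003 /
ssp2006 / PAM50 tables, supplied by the user as TSV — they are not
redistributed here) drives single-sample classification: a sample is
assigned the subtype whose centroid its expression profile correlates with
most strongly.  Spearman correlation is the default, making calls invariant
to any strictly increasing transform of the sample vector; Pearson is
available per model.  Samples sharing fewer than ``min_genes`` measured
genes with the model, or whose best correlation is not positive, are left
unclassified rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import StudyCollection
from .errors import ParseError

logger = logging.getLogger(__name__)

DEFAULT_SUBTYPES = ("luminal_A", "luminal_B", "HER2", "normal_like", "basal")

UNCLASSIFIED = "unclassified"


@dataclass
class CentroidModel:
    classifier_name: str
    centroids: pd.DataFrame  # genes x subtypes
    correlation_method: str = "spearman"

    def __post_init__(self) -> None:
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if self.centroids.shape[1] < 2:
            raise ParseError("centroid model needs at least two subtypes")
        if self.centroids.shape[0] < 2:
            raise ParseError("each centroid needs at least two genes")
        if self.centroids.index.has_duplicates:
            dup = self.centroids.index[self.centroids.index.duplicated()][0]
            raise ParseError(f"duplicate gene {dup!r} in centroid table")

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index)


@dataclass
class SubtypeCall:
    sample_id: str
    label: str  # one of model.subtypes, or "unclassified"
    correlations: dict[str, float]
    n_genes_used: int

    @property
    def best_correlation(self) -> float:
        if not self.correlations:
            return float("nan")
        return max(self.correlations.values())


def load_centroids(
    path: str | Path,
    classifier_name: Optional[str] = None,
    correlation_method: str = "spearman",
) -> CentroidModel:
    """Read a centroid TSV: first column gene_id, remaining columns subtypes."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: centroid table needs >= 2 subtype columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated gene row {dup!r}")
    return CentroidModel(
        classifier_name=classifier_name or path.stem,
        centroids=df.astype(float),
        correlation_method=correlation_method,
    )


def _correlations(
    sample: np.ndarray, centroids: np.ndarray, method: str
) -> np.ndarray:
    """Correlation of one sample vector with each centroid column."""
    if method == "spearman":
        sample = rankdata(sample)
        centroids = np.apply_along_axis(rankdata, 0, centroids)
    s = sample - sample.mean()
    c = centroids - centroids.mean(axis=0)
    s_norm = np.sqrt((s * s).sum())
    c_norm = np.sqrt((c * c).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (s @ c) / (s_norm * c_norm)
    return np.where(np.isfinite(out), out, np.nan)  # constant vectors -> undefined


def classify_sample(
    expr: pd.Series, model: CentroidModel, min_genes: int = 10
) -> SubtypeCall:
    """Assign the subtype whose centroid correlates best with the sample.

    Restricted to genes measured (non-missing) in both the sample and the
    model.  Fewer than ``min_genes`` shared genes, or a best correlation
    <= 0, yields ``unclassified``.  Correlation ties break by the model's
    subtype order.
    """
    sample_id = str(expr.name) if expr.name is not None else ""
    shared = model.centroids.index.intersection(expr.dropna().index)
    if len(shared) < min_genes:
        return SubtypeCall(sample_id, UNCLASSIFIED, {}, len(shared))
    vec = expr[shared].to_numpy(dtype=float)
    cors = _correlations(vec, model.centroids.loc[shared].to_numpy(dtype=float),
                         model.correlation_method)
    cor_map = {s: float(c) for s, c in zip(model.subtypes, cors)}
    finite = np.where(np.isnan(cors), -np.inf, cors)
    best = int(np.argmax(finite))  # argmax takes the first maximum: model order breaks ties
    if not np.isfinite(finite[best]) or finite[best] <= 0:
        return SubtypeCall(sample_id, UNCLASSIFIED, cor_map, len(shared))
    return SubtypeCall(sample_id, model.subtypes[best], cor_map, len(shared))


def classify_matrix(
    data: pd.DataFrame, model: CentroidModel, min_genes: int = 10
) -> pd.DataFrame:
    """Classify every column (sample) of a genes x samples matrix.

    Returns a frame indexed by sample id with columns label,
    best_correlation, n_genes_used.
    """
    rows = []
    for sid in data.columns:
        call = classify_sample(data[sid], model, min_genes=min_genes)
        rows.append((sid, call.label, call.best_correlation, call.n_genes_used))
    return pd.DataFrame(
        rows, columns=["sample_id", "label", "best_correlation", "n_genes_used"]
    ).set_index("sample_id")


def classify_collection(
    collection: StudyCollection, model: CentroidModel, min_genes: int = 10
) -> dict[str, pd.DataFrame]:
    """Per-dataset subtype calls for every sample in the collection."""
    out: dict[str, pd.DataFrame] = {}
    for bundle in collection.bundles:
        calls = classify_matrix(bundle.gene_matrix.data, model, min_genes=min_genes)
        n_unc = int((calls["label"] == UNCLASSIFIED).sum())
        if n_unc == len(calls) and len(calls):
            logger.warning(
                "dataset %r: every sample unclassified under %r (shared genes below %d?)",
                bundle.dataset_id, model.classifier_name, min_genes,
            )
        counts = calls["label"].value_counts().to_dict()
        logger.info("dataset %r subtype counts (%s): %s",
                    bundle.dataset_id, model.classifier_name, counts)
        out[bundle.dataset_id] = calls
    return out


def subtype_masks(
    calls: dict[str, pd.DataFrame], subtype: str
) -> dict[str, pd.Series]:
    """Boolean per-dataset masks selecting samples called as ``subtype``."""
    return {ds: df["label"] == subtype for ds, df in calls.items()}


def calls_to_tsv(calls: dict[str, pd.DataFrame], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("sample_id\tdataset_id\tlabel\tbest_correlation\tn_genes_used\n")
        for ds, df in calls.items():
            for sid, row in df.iterrows():
                fh.write(
                    f"{sid}\t{ds}\t{row['label']}\t{row['best_correlation']:.6g}\t"
                    f"{int(row['n_genes_used'])}\n"
                )
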