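"""Dataset containers, TSV readers/writers, validation, and probe-to-gene centering.

A study is a collection of independently normalized expression cohorts.  Each
cohort carries a gene-centered log-scale expression matrix (genes x samples)
and an aligned clinical table with up to three survival endpoints (DFS, DDFS,
OS; time in months + binary event flag) and the usual breast-cancer
covariates (ER/PR/HER2 status, nodal status, grade, age, size, treatment
flags).  Raw expression values are *not* comparable across cohorts — every
downstream analysis dichotomizes within a cohort — so no cross-dataset
normalization is attempted here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

ENDPOINTS = ("dfs", "ddfs", "os")

MISSING_TOKEN = "NA"

#: default inclusion threshold: cohorts need survival data and at least this
#: many patients to contribute to a pooled analysis
MIN_SAMPLES_DEFAULT = 48

STATUS_SYNONYMS = {
    "pos": "pos", "positive": "pos", "p": "pos", "1": "pos", "+": "pos",
    "neg": "neg", "negative": "neg", "n": "neg", "0": "neg", "-": "neg",
}
YESNO_SYNONYMS = {
    "yes": "yes", "y": "yes", "1": "yes", "true": "yes", "t": "yes", "treated": "yes",
    "no": "no", "n": "no", "0": "no", "false": "no", "f": "no", "untreated": "no",
}
EVENT_SYNONYMS = {
    "1": 1.0, "1.0": 1.0, "event": 1.0, "yes": 1.0, "true": 1.0, "dead": 1.0, "relapse": 1.0,
    "0": 0.0, "0.0": 0.0, "censored": 0.0, "no": 0.0, "false": 0.0, "alive": 0.0,
}

CLINICAL_COLUMNS = (
    "age", "size_cm", "ln_status", "er_status", "pr_status", "her2_status",
    "grade", "chemo", "hormone",
    "dfs_time", "dfs_event", "ddfs_time", "ddfs_event", "os_time", "os_event",
)

_STATUS_COLUMNS = ("ln_status", "er_status", "pr_status", "her2_status")
_YESNO_COLUMNS = ("chemo", "hormone")
_NUMERIC_COLUMNS = ("age", "size_cm")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_matrix(data: pd.DataFrame, kind: str) -> None:
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise ParseError(f"duplicate {kind} id {dup!r}")
    if data.columns.has_duplicates:
        dup = data.columns[data.columns.duplicated()][0]
        raise ParseError(f"duplicate sample id {dup!r}")


@dataclass
class ProbeMatrix:
    """Probe-level log-scale expression, probes x samples; NaN marks missing."""

    dataset_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.data, "probe")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneMatrix:
    """Gene-centered expression, genes x samples; no gene row is all-missing."""

    dataset_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.data, "gene")
        if len(self.data) and self.data.isna().all(axis=1).any():
            bad = self.data.index[self.data.isna().all(axis=1)][0]
            raise DataError(f"gene row {bad!r} is entirely missing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ProbeAnnotation:
    """probe_id -> set of gene ids (Entrez-role opaque strings)."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for probe, genes in self.mapping.items():
            if any(not g for g in genes):
                raise ParseError(f"probe {probe!r} maps to an empty gene id")


@dataclass
class ClinicalTable:
    """Normalized clinical covariates and survival endpoints, one row per sample.

    The wrapped frame is indexed by sample id and carries exactly the
    canonical columns (:data:`CLINICAL_COLUMNS`); missing values are NaN.
    Endpoint invariant: for each endpoint, time and event are either both
    present or both missing, with time >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"clinical table lacks canonical columns {missing}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        self.data = self.data[list(CLINICAL_COLUMNS)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoint_available(self, endpoint: str) -> pd.Series:
        """Boolean per sample: endpoint time and event both observed."""
        endpoint = endpoint.lower()
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        return self.data[f"{endpoint}_time"].notna() & self.data[f"{endpoint}_event"].notna()

    def endpoints_present(self) -> tuple[str, ...]:
        return tuple(e for e in ENDPOINTS if self.endpoint_available(e).any())


@dataclass
class DatasetBundle:
    """One cohort: gene matrix + clinical table over the same ordered samples."""

    dataset_id: str
    gene_matrix: GeneMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if list(self.gene_matrix.sample_ids) != list(self.clinical.sample_ids):
            raise DataError(
                f"dataset {self.dataset_id!r}: expression and clinical sample ids differ"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.gene_matrix.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class StudyCollection:
    """All cohorts of a study; the gene universe is the exact union of gene ids."""

    bundles: list[DatasetBundle]

    def __post_init__(self) -> None:
        ids = [b.dataset_id for b in self.bundles]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataError(f"duplicate dataset id {dup!r}")

    @property
    def dataset_ids(self) -> list[str]:
        return [b.dataset_id for b in self.bundles]

    @property
    def gene_universe(self) -> set[str]:
        universe: set[str] = set()
        for b in self.bundles:
            universe.update(b.gene_matrix.gene_ids)
        return universe

    def __getitem__(self, dataset_id: str) -> DatasetBundle:
        for b in self.bundles:
            if b.dataset_id == dataset_id:
                return b
        raise KeyError(dataset_id)

    def clinical_map(self) -> dict[str, ClinicalTable]:
        return {b.dataset_id: b.clinical for b in self.bundles}


@dataclass
class ValidationReport:
    dataset_id: str
    n_samples: int
    endpoints_present: tuple[str, ...]
    passes_inclusion: bool
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_matrix_frame(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected an id column plus sample columns")
    raw = raw.set_index(raw.columns[0])
    if len(raw) == 0:
        raise ParseError(f"{path}: no {kind}s")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate {kind} id {dup!r}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col].replace(MISSING_TOKEN, np.nan), errors="coerce")
        bad = converted.isna() & (raw[col] != MISSING_TOKEN) & (raw[col] != "")
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric cell at {kind} {row!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    out = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    out.index.name = None
    return out


def read_expression_matrix(path: str | Path, dataset_id: str) -> ProbeMatrix:
    """Read a probe-level TSV (first column probe ids, header sample ids)."""
    return ProbeMatrix(dataset_id, _read_matrix_frame(path, "probe"))


def read_gene_matrix(path: str | Path, dataset_id: str) -> GeneMatrix:
    """Read an already gene-centered TSV (first column gene ids)."""
    return GeneMatrix(dataset_id, _read_matrix_frame(path, "gene"))


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column TSV probe_id / gene_id; multi-gene probes use multiple rows."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "gene_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation needs columns probe_id, gene_id")
    mapping: dict[str, set[str]] = {}
    for probe, gene in zip(df["probe_id"], df["gene_id"]):
        if not probe or not gene:
            raise ParseError(f"{path}: blank probe or gene id")
        mapping.setdefault(probe, set()).add(gene)
    return ProbeAnnotation({p: frozenset(g) for p, g in mapping.items()})


def _normalize_token(col: str, token: str, sample: str, warnings_out: list[str]):
    token = token.strip()
    if token == "" or token.upper() == MISSING_TOKEN:
        return np.nan
    low = token.lower()
    if col in _STATUS_COLUMNS:
        if low in STATUS_SYNONYMS:
            return STATUS_SYNONYMS[low]
        warnings_out.append(f"sample {sample!r}: unrecognized {col} token {token!r} -> missing")
        return np.nan
    if col in _YESNO_COLUMNS:
        if low in YESNO_SYNONYMS:
            return YESNO_SYNONYMS[low]
        warnings_out.append(f"sample {sample!r}: unrecognized {col} token {token!r} -> missing")
        return np.nan
    if col == "grade":
        try:
            g = float(token)
        except ValueError:
            warnings_out.append(f"sample {sample!r}: non-numeric grade {token!r} -> missing")
            return np.nan
        if g in (1.0, 2.0, 3.0):
            return g
        warnings_out.append(f"sample {sample!r}: grade {token!r} outside 1-3 -> missing")
        return np.nan
    if col.endswith("_event"):
        if low in EVENT_SYNONYMS:
            return EVENT_SYNONYMS[low]
        warnings_out.append(f"sample {sample!r}: unrecognized {col} token {token!r} -> missing")
        return np.nan
    # numeric: age, size_cm, *_time
    try:
        return float(token)
    except ValueError:
        warnings_out.append(f"sample {sample!r}: non-numeric {col} value {token!r} -> missing")
        return np.nan


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read and normalize a clinical TSV.

    Recognized columns are ``sample_id`` plus :data:`CLINICAL_COLUMNS`;
    unknown columns are preserved in the file but ignored here.  Enumeration
    synonyms are folded (positive/1/+ -> pos, ...); out-of-range grades and
    endpoint half-pairs are coerced to missing with a logged warning.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    if raw["sample_id"].duplicated().any():
        dup = raw["sample_id"][raw["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    warnings_out: list[str] = []
    index = pd.Index(raw["sample_id"].astype(str).to_numpy())
    index.name = None
    out = pd.DataFrame(index=index)
    for col in CLINICAL_COLUMNS:
        if col in raw.columns:
            out[col] = [
                _normalize_token(col, tok, sid, warnings_out)
                for sid, tok in zip(raw["sample_id"], raw[col])
            ]
        else:
            out[col] = np.nan
    # enforce time <=> event pairing and non-negative times per endpoint
    for e in ENDPOINTS:
        t, v = out[f"{e}_time"], out[f"{e}_event"]
        bad = t.notna() ^ v.notna()
        neg = t.notna() & (t < 0)
        for sid in out.index[bad]:
            warnings_out.append(
                f"sample {sid!r}: {e} time/event half-pair -> both set missing"
            )
        for sid in out.index[neg]:
            warnings_out.append(f"sample {sid!r}: negative {e} time -> both set missing")
        drop = bad | neg
        out.loc[drop, f"{e}_time"] = np.nan
        out.loc[drop, f"{e}_event"] = np.nan
    for msg in warnings_out:
        logger.warning("%s: %s", path, msg)
    return ClinicalTable(out)


# ---------------------------------------------------------------------------
# gene centering
# ---------------------------------------------------------------------------

def gene_center(pm: ProbeMatrix, ann: ProbeAnnotation) -> GeneMatrix:
    """Collapse probes to genes.

    Probes absent from the annotation are dropped, probes mapping to more
    than one gene are discarded, and multiple probes for the same gene are
    averaged arithmetically on the stored log scale, per sample over
    non-missing values.
    """
    keep: dict[str, list[str]] = {}
    for probe in pm.probe_ids:
        genes = ann.mapping.get(probe)
        if genes is None:
            continue
        if len(genes) != 1:
            continue  # multi-gene (cross-hybridizing) probes are uninformative
        (gene,) = genes
        keep.setdefault(gene, []).append(probe)
    if not keep:
        raise DataError("no mappable probes")
    rows = {}
    for gene, probes in keep.items():
        row = pm.data.loc[probes].mean(axis=0, skipna=True)
        if row.notna().any():
            rows[gene] = row
    if not rows:
        raise DataError("no mappable probes")
    out = pd.DataFrame(rows).T
    out.columns = pm.data.columns
    return GeneMatrix(pm.dataset_id, out)


# ---------------------------------------------------------------------------
# validation / collection
# ---------------------------------------------------------------------------

def validate_dataset(b: DatasetBundle, min_samples: int = MIN_SAMPLES_DEFAULT) -> ValidationReport:
    """Check a cohort against the inclusion policy (size + survival data)."""
    endpoints = b.clinical.endpoints_present()
    messages: list[str] = []
    if b.n_samples < min_samples:
        messages.append(f"only {b.n_samples} samples (< {min_samples})")
    if not endpoints:
        messages.append("no survival information")
    return ValidationReport(
        dataset_id=b.dataset_id,
        n_samples=b.n_samples,
        endpoints_present=endpoints,
        passes_inclusion=(b.n_samples >= min_samples and bool(endpoints)),
        messages=messages,
    )


def build_collection(
    bundles: Sequence[DatasetBundle],
    enforce_inclusion: bool = False,
    min_samples: int = MIN_SAMPLES_DEFAULT,
) -> StudyCollection:
    if not bundles:
        raise DataError("no datasets supplied")
    kept = list(bundles)
    if enforce_inclusion:
        kept = []
        for b in bundles:
            report = validate_dataset(b, min_samples)
            if report.passes_inclusion:
                kept.append(b)
            else:
                logger.warning(
                    "dataset %r excluded: %s", b.dataset_id, "; ".join(report.messages)
                )
        if not kept:
            raise DataError("all datasets failed the inclusion criteria")
    return StudyCollection(kept)


def load_collection(manifest_path: str | Path, enforce_inclusion: bool = False) -> StudyCollection:
    """Build a collection from a YAML/JSON manifest.

    Manifest schema::

        datasets:
          - id: cohort1
            expression: cohort1_expression.tsv
            clinical: cohort1_clinical.tsv
            annotation: cohort1_probes.tsv   # optional; absent => gene-centered

    Relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    if manifest_path.suffix == ".json":
        manifest = json.loads(text)
    else:
        manifest = yaml.safe_load(text)
    if not isinstance(manifest, dict) or "datasets" not in manifest:
        raise ParseError(f"{manifest_path}: manifest needs a top-level 'datasets' list")
    base = manifest_path.parent
    bundles = []
    for entry in manifest["datasets"]:
        ds = str(entry["id"])
        if entry.get("annotation"):
            pm = read_expression_matrix(base / entry["expression"], ds)
            ann = read_probe_annotation(base / entry["annotation"])
            gm = gene_center(pm, ann)
        else:
            gm = read_gene_matrix(base / entry["expression"], ds)
        ct = read_clinical_table(base / entry["clinical"])
        bundles.append(DatasetBundle(ds, gm, ct))
    return build_collection(bundles, enforce_inclusion=enforce_inclusion)


# ---------------------------------------------------------------------------
# writers (full-precision round trip)
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return MISSING_TOKEN
    return repr(float(x))


def write_gene_matrix(gm: GeneMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(gm.sample_ids) + "\n")
        for gene, row in gm.data.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(_fmt_float(v) for v in row) + "\n")


def write_clinical_table(ct: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    df = ct.data
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(CLINICAL_COLUMNS) + "\n")
        for sid, row in df.iterrows():
            cells = [str(sid)]
            for col in CLINICAL_COLUMNS:
                v = row[col]
                if isinstance(v, float) and math.isnan(v):
                    cells.append(MISSING_TOKEN)
                elif col in _STATUS_COLUMNS + _YESNO_COLUMNS:
                    cells.append(str(v))
                elif col == "grade" or col.endswith("_event"):
                    cells.append(str(int(v)))
                else:
                    cells.append(_fmt_float(v))
            fh.write("\t".join(cells) + "\n")
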