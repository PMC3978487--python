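"""Seeded generator of multi-cohort studies with known prognostic structure.

The generator emulates the structure of a multi-platform breast-cancer
compendium: several cohorts of heterogeneous size, each measured on its
own "platform" (a per-cohort affine — optionally monotone-nonlinear —
distortion of a common latent expression scale, so raw values are not
comparable across cohorts), survival endpoints present in varying subsets,
clinical covariates with realistic prevalences and missingness, and an
optional centroid-driven subtype structure.

The survival model is exponential (constant hazard) with the designed
effect injected at the *group* level: for each designated prognostic gene,
samples above that cohort's median expression draw event times at hazard
h0 * HR, the rest at h0.  The designed HR is therefore exactly the
estimand of the pipeline's dichotomized analysis, with no attenuation
bookkeeping.  A continuous log-linear effect mode is provided secondarily.
Censoring is administrative-uniform on [0, tau], with tau solved so the
expected censored share at the baseline hazard matches the requested
fraction.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .data_model import (
    ClinicalTable,
    CLINICAL_COLUMNS,
    DatasetBundle,
    GeneMatrix,
    StudyCollection,
    build_collection,
    write_clinical_table,
    write_gene_matrix,
)
from .errors import DataError
from .subtype_classifier import DEFAULT_SUBTYPES, CentroidModel

#: endpoint availability pattern cycled over datasets: every cohort reports
#: DFS; OS and DDFS appear in overlapping subsets, as in real compendia
_ENDPOINT_CYCLE = (
    ("dfs", "os"),
    ("dfs",),
    ("dfs", "ddfs", "os"),
    ("dfs", "ddfs"),
    ("dfs", "os"),
)


@dataclass
class SimConfig:
    """Study-design knobs for :func:`simulate_collection`.

    Defaults describe a five-cohort study with one prognostic gene whose
    high-expression group carries twice the event hazard, 30% expected
    censoring, and a baseline hazard of 0.01 events/month (median
    event time ~69 months, the follow-up scale of typical breast-cancer
    cohorts).
    """

    n_datasets: int = 5
    n_per_dataset: Sequence[int] = (48, 78, 158, 204, 96)
    n_genes: int = 100
    prognostic_hrs: Mapping[str, float] = field(default_factory=lambda: {"g0001": 2.0})
    dataset_shifts: Optional[Sequence[float]] = None
    dataset_scales: Optional[Sequence[float]] = None
    nonlinear_distortion: bool = False
    censoring_fraction: float = 0.3
    baseline_hazard: float = 0.01  # events per month
    effect_mode: str = "group"  # "group" | "loglinear"
    er_pos_rate: float = 0.70
    pr_pos_rate: float = 0.60
    her2_pos_rate: float = 0.15
    ln_pos_rate: float = 0.45
    grade_probs: Sequence[float] = (0.20, 0.45, 0.35)
    chemo_rate: float = 0.40
    hormone_rate: float = 0.50
    clinical_missing_rate: float = 0.10
    subtype_model: Optional[CentroidModel] = None
    subtype_proportions: Optional[Sequence[float]] = None
    subtype_noise: float = 0.5
    endpoints_per_dataset: Optional[Sequence[Sequence[str]]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise DataError("n_datasets must be >= 1")
        if len(self.n_per_dataset) != self.n_datasets:
            raise DataError("n_per_dataset length must equal n_datasets")
        if any(n < 2 for n in self.n_per_dataset):
            raise DataError("each dataset needs >= 2 samples")
        if self.n_genes < 1:
            raise DataError("n_genes must be >= 1")
        for g, hr in self.prognostic_hrs.items():
            if not hr > 0:
                raise DataError(f"designed hazard ratio for {g!r} must be > 0")
        if not (0 <= self.censoring_fraction < 1):
            raise DataError("censoring_fraction must be in [0, 1)")
        if not self.baseline_hazard > 0:
            raise DataError("baseline_hazard must be > 0")
        if self.effect_mode not in ("group", "loglinear"):
            raise DataError(f"unknown effect_mode {self.effect_mode!r}")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise DataError("grade_probs must sum to 1")
        for s in (self.dataset_shifts, self.dataset_scales):
            if s is not None and len(s) != self.n_datasets:
                raise DataError("per-dataset distortion lists must match n_datasets")
        if self.dataset_scales is not None and any(s <= 0 for s in self.dataset_scales):
            raise DataError("dataset scale factors must be positive")
        if self.subtype_model is not None:
            p = self.subtype_proportions
            if p is not None:
                if len(p) != len(self.subtype_model.subtypes):
                    raise DataError("subtype_proportions must match the model's subtypes")
                if abs(sum(p) - 1.0) > 1e-9:
                    raise DataError("subtype_proportions must sum to 1")
        if self.endpoints_per_dataset is not None and len(self.endpoints_per_dataset) != self.n_datasets:
            raise DataError("endpoints_per_dataset must match n_datasets")


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    designed_hrs: dict[str, float]
    group_labels: dict[str, pd.DataFrame]  # dataset -> samples x prognostic genes ("high"/"low")
    subtype_labels: dict[str, pd.Series]   # dataset -> per-sample true subtype (if designed)
    censoring_horizon: Optional[float]


def _censoring_horizon(hazard: float, fraction: float) -> Optional[float]:
    """Uniform-censoring horizon tau with expected censored share = fraction.

    For T ~ Exp(h), C ~ U(0, tau): P(censored) = (1 - exp(-h tau)) / (h tau),
    decreasing in tau; solved by bisection.
    """
    if fraction <= 0:
        return None

    def share(tau: float) -> float:
        return (1.0 - math.exp(-hazard * tau)) / (hazard * tau) - fraction

    lo, hi = 1e-9 / hazard, 1e9 / hazard
    return float(brentq(share, lo, hi))


def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:04d}" for i in range(n)]


def simulate_collection(cfg: SimConfig) -> tuple[StudyCollection, SimTruth]:
    """Draw a full multi-cohort study from the design in ``cfg``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    for g in cfg.prognostic_hrs:
        if g not in genes and cfg.subtype_model is None:
            raise DataError(f"prognostic gene {g!r} outside the simulated gene list")
    shifts = (
        list(cfg.dataset_shifts)
        if cfg.dataset_shifts is not None
        else [float(3.0 * math.sin(1.7 * k) + k) for k in range(cfg.n_datasets)]
    )
    scales = (
        list(cfg.dataset_scales)
        if cfg.dataset_scales is not None
        else [0.5 + 0.6 * (k % 4) for k in range(cfg.n_datasets)]
    )
    tau = _censoring_horizon(cfg.baseline_hazard, cfg.censoring_fraction)
    gene_mu = rng.normal(7.0, 1.0, size=cfg.n_genes)  # latent per-gene location

    bundles: list[DatasetBundle] = []
    truth_groups: dict[str, pd.DataFrame] = {}
    truth_subtypes: dict[str, pd.Series] = {}

    for k in range(cfg.n_datasets):
        ds = f"sim{k + 1:02d}"
        n = int(cfg.n_per_dataset[k])
        samples = [f"{ds}_s{i + 1:03d}" for i in range(n)]
        latent = rng.normal(gene_mu[:, None], 1.0, size=(cfg.n_genes, n))
        expr = pd.DataFrame(latent, index=genes, columns=samples)

        if cfg.subtype_model is not None:
            model = cfg.subtype_model
            props = (
                np.asarray(cfg.subtype_proportions, dtype=float)
                if cfg.subtype_proportions is not None
                else np.full(len(model.subtypes), 1.0 / len(model.subtypes))
            )
            picks = rng.choice(len(model.subtypes), size=n, p=props)
            centroid_vals = model.centroids.to_numpy(dtype=float)  # genes x subtypes
            block = centroid_vals[:, picks] + rng.normal(
                0.0, cfg.subtype_noise, size=(len(model.gene_ids), n)
            )
            block_df = pd.DataFrame(block, index=model.gene_ids, columns=samples)
            expr = pd.concat([expr.drop(index=expr.index.intersection(block_df.index)), block_df])
            truth_subtypes[ds] = pd.Series(
                [model.subtypes[i] for i in picks], index=samples
            )

        # group labels per prognostic gene: within-cohort, strictly above median
        labels = {}
        log_hr_per_sample = np.zeros(n)
        for g, hr in cfg.prognostic_hrs.items():
            if g not in expr.index:
                raise DataError(f"prognostic gene {g!r} missing from simulated matrix")
            vals = expr.loc[g].to_numpy(dtype=float)
            med = float(np.quantile(vals, 0.5, method="linear"))
            hi = vals > med
            labels[g] = np.where(hi, "high", "low")
            if cfg.effect_mode == "group":
                log_hr_per_sample += np.where(hi, math.log(hr), 0.0)
            else:  # loglinear: per-unit effect on the standardized latent value
                z = (vals - vals.mean()) / (vals.std() or 1.0)
                log_hr_per_sample += math.log(hr) * z
        truth_groups[ds] = pd.DataFrame(labels, index=samples)

        hazard = cfg.baseline_hazard * np.exp(log_hr_per_sample)
        endpoints = (
            tuple(e.lower() for e in cfg.endpoints_per_dataset[k])
            if cfg.endpoints_per_dataset is not None
            else _ENDPOINT_CYCLE[k % len(_ENDPOINT_CYCLE)]
        )
        clin = pd.DataFrame(index=pd.Index(samples), columns=list(CLINICAL_COLUMNS), dtype=object)
        for e in endpoints:
            t_event = rng.exponential(1.0 / hazard)
            if tau is not None:
                c = rng.uniform(0.0, tau, size=n)
                observed = np.minimum(t_event, c)
                event = (t_event <= c).astype(float)
            else:
                observed, event = t_event, np.ones(n)
            observed = np.maximum(observed, 1e-6)  # hazard models need positive times
            clin[f"{e}_time"] = observed
            clin[f"{e}_event"] = event

        def draw_binary(rate: float, tokens=("pos", "neg")) -> np.ndarray:
            vals = np.where(rng.random(n) < rate, tokens[0], tokens[1]).astype(object)
            vals[rng.random(n) < cfg.clinical_missing_rate] = np.nan
            return vals

        clin["er_status"] = draw_binary(cfg.er_pos_rate)
        clin["pr_status"] = draw_binary(cfg.pr_pos_rate)
        clin["her2_status"] = draw_binary(cfg.her2_pos_rate)
        clin["ln_status"] = draw_binary(cfg.ln_pos_rate)
        clin["chemo"] = draw_binary(cfg.chemo_rate, ("yes", "no"))
        clin["hormone"] = draw_binary(cfg.hormone_rate, ("yes", "no"))
        grade = rng.choice([1.0, 2.0, 3.0], size=n, p=np.asarray(cfg.grade_probs, float))
        grade = grade.astype(object)
        grade[rng.random(n) < cfg.clinical_missing_rate] = np.nan
        clin["grade"] = grade
        age = np.round(rng.normal(57.0, 12.0, size=n).clip(25, 95), 1).astype(object)
        age[rng.random(n) < cfg.clinical_missing_rate] = np.nan
        clin["age"] = age
        size = np.round(rng.lognormal(math.log(2.2), 0.4, size=n), 2).astype(object)
        size[rng.random(n) < cfg.clinical_missing_rate] = np.nan
        clin["size_cm"] = size
        for col in CLINICAL_COLUMNS:
            if col not in ("er_status", "pr_status", "her2_status", "ln_status", "chemo", "hormone"):
                clin[col] = pd.to_numeric(clin[col], errors="coerce")

        # platform distortion: strictly increasing per-cohort map of the latent scale
        if cfg.nonlinear_distortion:
            distorted = shifts[k] + scales[k] * np.arcsinh(expr.to_numpy(dtype=float) - 7.0)
        else:
            distorted = shifts[k] + scales[k] * expr.to_numpy(dtype=float)
        gm = GeneMatrix(ds, pd.DataFrame(distorted, index=expr.index, columns=expr.columns))
        bundles.append(DatasetBundle(ds, gm, ClinicalTable(clin)))

    truth = SimTruth(
        designed_hrs=dict(cfg.prognostic_hrs),
        group_labels=truth_groups,
        subtype_labels=truth_subtypes,
        censoring_horizon=tau,
    )
    return build_collection(bundles), truth


def simulate_centroid_cohort(
    model: CentroidModel,
    proportions: Optional[Sequence[float]] = None,
    noise: float = 0.5,
    n: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples = chosen centroid + iid Gaussian noise; returns (matrix, truth labels)."""
    rng = np.random.default_rng(seed)
    k = len(model.subtypes)
    props = (
        np.asarray(proportions, dtype=float) if proportions is not None else np.full(k, 1.0 / k)
    )
    if len(props) != k or abs(props.sum() - 1.0) > 1e-9:
        raise DataError("proportions must match the model's subtypes and sum to 1")
    if noise < 0:
        raise DataError("noise scale must be >= 0")
    picks = rng.choice(k, size=n, p=props)
    base = model.centroids.to_numpy(dtype=float)[:, picks]
    data = base + rng.normal(0.0, noise, size=base.shape)
    samples = [f"s{i + 1:03d}" for i in range(n)]
    mat = pd.DataFrame(data, index=model.gene_ids, columns=samples)
    labels = pd.Series([model.subtypes[i] for i in picks], index=samples)
    return mat, labels


def make_fixture_centroids(
    n_genes: int = 50,
    geometry: str = "orthogonal",
    subtypes: Sequence[str] = DEFAULT_SUBTYPES,
    seed: int = 0,
    correlation_method: str = "spearman",
    name: Optional[str] = None,
) -> CentroidModel:
    """Synthetic centroid tables with distinct geometries for testing.

    orthogonal: independent Gaussian centroids; correlated: common backbone
    plus subtype-specific departures; shifted: a shared profile warped by
    subtype-specific monotone bends.  These are stand-ins for published
    classifier tables, generated rather than redistributed.
    """
    rng = np.random.default_rng(seed)
    k = len(subtypes)
    if geometry == "orthogonal":
        vals = rng.normal(0.0, 1.0, size=(n_genes, k))
    elif geometry == "correlated":
        backbone = rng.normal(0.0, 1.0, size=(n_genes, 1))
        vals = 0.6 * backbone + 0.8 * rng.normal(0.0, 1.0, size=(n_genes, k))
    elif geometry == "shifted":
        base = rng.normal(0.0, 1.0, size=n_genes)
        vals = np.empty((n_genes, k))
        for j in range(k):
            bend = 0.4 * (j + 1)
            vals[:, j] = base + bend * np.sin(base + j) + rng.normal(0, 0.3, n_genes)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    # centroid genes live in their own namespace so a subtype design never
    # collides with (and overwrites) a designated prognostic gene
    gene_ids = [f"cg{i + 1:04d}" for i in range(n_genes)]
    centroids = pd.DataFrame(vals, index=gene_ids, columns=list(subtypes))
    return CentroidModel(
        classifier_name=name or f"fixture_{geometry}",
        centroids=centroids,
        correlation_method=correlation_method,
    )


def write_fixture(
    collection: StudyCollection, out_dir: str | Path, truth: Optional[SimTruth] = None
) -> Path:
    """Emit the TSV + manifest fixture consumed by the data-model readers.

    Returns the manifest path; writing then reloading reproduces the
    collection exactly (full-precision floats, identical orderings).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for b in collection.bundles:
        expr_path = out_dir / f"{b.dataset_id}_expression.tsv"
        clin_path = out_dir / f"{b.dataset_id}_clinical.tsv"
        write_gene_matrix(b.gene_matrix, expr_path)
        write_clinical_table(b.clinical, clin_path)
        entries.append(
            {"id": b.dataset_id, "expression": expr_path.name, "clinical": clin_path.name}
        )
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump({"datasets": entries}, sort_keys=False))
    if truth is not None:
        with open(out_dir / "truth_groups.tsv", "w") as fh:
            fh.write("dataset_id\tsample_id\tgene_id\tlabel\tdesigned_hr\n")
            for ds, df in truth.group_labels.items():
                for gene in df.columns:
                    for sid, lab in df[gene].items():
                        fh.write(
                            f"{ds}\t{sid}\t{gene}\t{lab}\t{truth.designed_hrs[gene]!r}\n"
                        )
    return manifest_path


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from YAML (field names as in the dataclass)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return SimConfig(**raw)
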