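"""miRNA prognosis via host-gene expression proxies.

Roughly half of human miRNAs are intragenic, and a large fraction of those
are co-expressed with the protein-coding gene hosting them; for such
miRNAs, host-gene expression measured on conventional arrays can stand in
for the miRNA level.  This module maps miRNA ids to host genes (from a
user-supplied table pinned to a miRBase/Ensembl release — no live lookup)
and delegates to the standard marker query.  Multi-host miRNAs are
analysed per host gene, one result each; every result is tagged with the
miRNA id and an explicit proxy flag, since not all miRNA/host pairs are
co-expressed and results must be read with that caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .cohort_analysis import MarkerResult, QuerySpec, run_query
from .data_model import StudyCollection
from .errors import ParseError, QueryError
from .subtype_classifier import CentroidModel

logger = logging.getLogger(__name__)


@dataclass
class HostGeneMap:
    """mirna_id -> ordered host gene ids, with a provenance note."""

    mapping: dict[str, tuple[str, ...]]
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        for mirna, genes in self.mapping.items():
            if not mirna or not genes or any(not g for g in genes):
                raise ParseError(f"invalid host map entry for {mirna!r}")


def load_host_map(path: str | Path, provenance: Optional[str] = None) -> HostGeneMap:
    """Read a TSV with columns mirna_id, gene_id (multi-host: multiple rows)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"mirna_id", "gene_id"}.issubset(df.columns):
        raise ParseError(f"{path}: host map needs columns mirna_id, gene_id")
    if len(df) == 0:
        raise ParseError(f"{path}: empty host map")
    mapping: dict[str, list[str]] = {}
    for mirna, gene in zip(df["mirna_id"], df["gene_id"]):
        if not mirna or not gene:
            raise ParseError(f"{path}: blank mirna or gene id")
        hosts = mapping.setdefault(mirna, [])
        if gene in hosts:
            logger.warning("%s: duplicate entry (%s, %s) deduplicated", path, mirna, gene)
            continue
        hosts.append(gene)
    return HostGeneMap({m: tuple(g) for m, g in mapping.items()}, provenance=provenance)


def write_host_map(hmap: HostGeneMap, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mirna, genes in hmap.mapping.items():
            for gene in genes:
                fh.write(f"{mirna}\t{gene}\n")


def resolve_mirna(
    mirna_id: str, hmap: HostGeneMap, collection: StudyCollection
) -> list[str]:
    """Host genes of the miRNA that are measured in at least one dataset."""
    if mirna_id not in hmap.mapping:
        raise QueryError(f"unknown miRNA {mirna_id!r}")
    hosts = hmap.mapping[mirna_id]
    universe = collection.gene_universe
    measured = [g for g in hosts if g in universe]
    if not measured:
        raise QueryError(
            f"host gene not measured: none of {list(hosts)} (hosts of {mirna_id!r}) "
            "appear in the collection"
        )
    unmeasured = [g for g in hosts if g not in universe]
    if unmeasured:
        logger.warning(
            "miRNA %r: host gene(s) %s not measured; proceeding with %s",
            mirna_id, unmeasured, measured,
        )
    return measured


def run_mirna_query(
    mirna_id: str,
    hmap: HostGeneMap,
    collection: StudyCollection,
    q: QuerySpec,
    centroid_models: Optional[Mapping[str, CentroidModel]] = None,
) -> list[MarkerResult]:
    """Run the standard marker query on each measured host gene.

    ``q.gene_ids`` is ignored and replaced by each resolved host gene in
    turn; each returned result carries the miRNA id and the host-gene
    proxy flag.
    """
    results = []
    for gene in resolve_mirna(mirna_id, hmap, collection):
        res = run_query(collection, replace(q, gene_ids=(gene,)), centroid_models)
        res.mirna_id = mirna_id
        res.host_gene_proxy = True
        results.append(res)
    return results
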