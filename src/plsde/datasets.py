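"""Synthetic case/control cohorts with known ground truth.

Every downstream stage (PLS fit, VIP/FDR selection, enrichment, network
hubs) is testable against the planted truth these generators return:

* :func:`generate_expression` — a probes x samples log2 matrix: per-probe
  baseline intensity plus a group mean shift on a planted subset of
  differentially expressed (DE) probes plus i.i.d. Gaussian noise. The
  default design is 63 cases vs 20 controls.
* :func:`generate_annotation` — a many-to-one probe -> gene-symbol map.
* :func:`generate_gene_sets` — a GMT-style collection in which planted
  sets draw a chosen fraction of members from DE-mapped genes.
* :func:`generate_interactions` — an Erdős–Rényi background graph whose
  planted hub nodes are topped up to a guaranteed minimum degree.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .io import GeneSet, GeneSetCollection
from .utils import derive_seed

__all__ = ["SyntheticTruth", "generate_expression", "generate_annotation",
           "generate_gene_sets", "generate_interactions"]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic study."""

    de_probe_ids: list[str] = field(default_factory=list)
    effect_sizes: list[float] = field(default_factory=list)  # signed log2 shifts
    enriched_set_ids: list[str] = field(default_factory=list)
    hub_gene_ids: list[str] = field(default_factory=list)

    def de_genes(self, annotation: pd.Series) -> list[str]:
        """Gene symbols mapped by at least one planted DE probe."""
        symbols = annotation.reindex(self.de_probe_ids).dropna()
        return sorted({s for s in symbols if s})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def generate_expression(n_probes: int, n_cases: int = 63, n_controls: int = 20,
                        n_de: int = 0, effect_size: float = 1.5,
                        noise_sd: float = 1.0, seed: int = 0,
                        up_fraction: float = 0.5,
                        ) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Two-group log2 expression matrix with planted DE probes.

    Exactly ``n_de`` probes get a mean shift of ±``effect_size`` in cases;
    a fraction ``up_fraction`` of them (rounded up) shift upward. Baseline
    intensities are uniform on [4, 12] log2 units; noise is i.i.d.
    Gaussian with standard deviation ``noise_sd``. Columns are cases first
    (label 1), then controls (label 0).
    """
    if n_probes < 1 or n_cases < 2 or n_controls < 2:
        raise InvalidParameterError("need n_probes >= 1 and >= 2 samples per group")
    if not 0 <= n_de <= n_probes:
        raise InvalidParameterError("n_de must be in [0, n_probes]")
    if noise_sd <= 0 or effect_size <= 0:
        raise InvalidParameterError("noise_sd and effect_size must be positive")
    if not 0.0 <= up_fraction <= 1.0:
        raise InvalidParameterError("up_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    probe_ids = [f"PRB{i:05d}" for i in range(n_probes)]
    sample_ids = ([f"CASE{i:03d}" for i in range(n_cases)]
                  + [f"CTRL{i:03d}" for i in range(n_controls)])
    baseline = rng.uniform(4.0, 12.0, size=n_probes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_probes, n))

    de_idx = np.sort(rng.choice(n_probes, size=n_de, replace=False))
    n_up = math.ceil(n_de * up_fraction)
    signs = np.array([1.0] * n_up + [-1.0] * (n_de - n_up))
    effects = signs * effect_size
    values[de_idx, :n_cases] += effects[:, None]

    expr = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sample_ids)
    pheno = pd.Series([1] * n_cases + [0] * n_controls,
                      index=pd.Index(sample_ids, name="sample_id"), name="label")
    truth = SyntheticTruth(
        de_probe_ids=[probe_ids[i] for i in de_idx],
        effect_sizes=[float(e) for e in effects],
    )
    return expr, pheno, truth


def generate_annotation(probe_ids, probes_per_gene: float = 1.2,
                        unannotated_fraction: float = 0.02,
                        seed: int = 0) -> pd.Series:
    """Many-to-one probe -> gene map; a small fraction of probes unannotated.

    Every gene receives at least one probe; remaining probes are assigned
    uniformly at random, so some genes carry several probes (exercising
    the any-probe-selected collapse rule downstream).
    """
    probe_ids = [str(p) for p in probe_ids]
    if not probe_ids:
        raise InvalidParameterError("probe_ids is empty")
    if probes_per_gene < 1.0:
        raise InvalidParameterError("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    n_probes = len(probe_ids)
    n_genes = max(1, round(n_probes / probes_per_gene))
    symbols = [f"GENE{i:05d}" for i in range(n_genes)]
    assignment = list(range(n_genes))  # each gene gets one probe
    assignment += list(rng.integers(0, n_genes, size=n_probes - n_genes))
    order = rng.permutation(n_probes)
    mapped = [symbols[assignment[i]] for i in order.argsort()]
    n_blank = round(unannotated_fraction * n_probes)
    if n_blank:
        for i in rng.choice(n_probes, size=n_blank, replace=False):
            mapped[i] = ""
    ann = pd.Series(mapped, index=pd.Index(probe_ids, name="probe_id"),
                    name="symbol")
    return ann


def generate_gene_sets(probe_annotation: pd.Series, n_sets: int,
                       set_size_min: int, set_size_max: int,
                       truth: SyntheticTruth, enrichment_strength: float,
                       seed: int = 0, namespace: str = "pathway",
                       ) -> GeneSetCollection:
    """Gene-set collection with planted enriched sets.

    Set ids are ``GS0000`` … ``GS{n_sets-1}``; sizes are uniform on
    ``[set_size_min, set_size_max]``. The sets named in
    ``truth.enriched_set_ids`` draw a fraction ``enrichment_strength`` of
    their members from genes mapped by planted DE probes (capped at the
    number of DE genes); every other member is a uniform draw from the
    remaining genes.
    """
    if len(probe_annotation) == 0:
        raise InvalidParameterError("probe annotation is empty")
    genes = sorted({s for s in probe_annotation if s})
    if not genes:
        raise InvalidParameterError("annotation maps no probe to a gene symbol")
    if not 1 <= set_size_min <= set_size_max <= len(genes):
        raise InvalidParameterError(
            f"need 1 <= set_size_min <= set_size_max <= {len(genes)} distinct genes")
    if not 0.0 <= enrichment_strength <= 1.0:
        raise InvalidParameterError("enrichment_strength must be in [0, 1]")
    ids = [f"GS{i:04d}" for i in range(n_sets)]
    unknown = [s for s in truth.enriched_set_ids if s not in ids]
    if unknown:
        raise InvalidParameterError(
            f"enriched set id(s) outside the generated range: {', '.join(unknown)}")

    rng = np.random.default_rng(seed)
    de_genes = np.array(truth.de_genes(probe_annotation))
    other = np.array(sorted(set(genes) - set(de_genes)))
    all_genes = np.array(genes)
    sets: list[GeneSet] = []
    for set_id in ids:
        size = int(rng.integers(set_size_min, set_size_max + 1))
        if set_id in truth.enriched_set_ids and len(de_genes):
            n_from_de = min(round(enrichment_strength * size), len(de_genes), size)
            members = list(rng.choice(de_genes, size=n_from_de, replace=False))
            pool = other if len(other) >= size - n_from_de else all_genes
            rest = [g for g in rng.choice(pool, size=min(size, len(pool)),
                                          replace=False)
                    if g not in members][: size - n_from_de]
            members += rest
        else:
            members = list(rng.choice(all_genes, size=size, replace=False))
        sets.append(GeneSet(set_id, f"synthetic set {set_id}",
                            tuple(sorted(members)), namespace))
    return GeneSetCollection(sets)


def generate_interactions(gene_ids, mean_degree: float, hub_ids,
                          hub_degree: int, seed: int = 0) -> nx.Graph:
    """Random interaction graph with planted high-degree hub nodes.

    Background edges are Erdős–Rényi with expected degree ``mean_degree``;
    each hub is then connected to additional uniformly chosen partners
    until its degree reaches ``hub_degree``. Simple graph (no self-loops
    or multi-edges) by construction.
    """
    gene_ids = [str(g).upper() for g in gene_ids]
    hub_ids = [str(g).upper() for g in hub_ids]
    n = len(gene_ids)
    if len(set(gene_ids)) != n:
        raise InvalidParameterError("gene_ids contains duplicates")
    if not set(hub_ids) <= set(gene_ids):
        raise InvalidParameterError("hub_ids must be a subset of gene_ids")
    if mean_degree <= 0:
        raise InvalidParameterError("mean_degree must be positive")
    if hub_ids and not 1 <= hub_degree < n:
        raise InvalidParameterError("hub_degree must be in [1, n_genes)")

    p_edge = min(1.0, mean_degree / max(n - 1, 1))
    graph = nx.fast_gnp_random_graph(n, p_edge, seed=derive_seed(seed, 1))
    graph = nx.relabel_nodes(graph, dict(enumerate(gene_ids)))
    rng = np.random.default_rng(derive_seed(seed, 2))
    for hub in hub_ids:
        candidates = [g for g in gene_ids
                      if g != hub and not graph.has_edge(hub, g)]
        need = hub_degree - graph.degree(hub)
        if need > 0:
            for partner in rng.choice(candidates, size=need, replace=False):
                graph.add_edge(hub, partner)
    return graph
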