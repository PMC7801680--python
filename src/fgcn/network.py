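"""Per-dataset top-correlation edge lists and the frequency-weighted network.

Per dataset and condition group, all gene pairs are correlated (Pearson for
continuous platforms, Spearman for counts), the top percentile of |r| with
p < 0.05 is kept, and occurrence counts across datasets divided by the
number of datasets become the edge weights that module mining consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from fgcn.io import DataError, ExpressionDataset, logger


@dataclass
class CorrelationTable:
    """Upper-triangular all-pairs correlation results for one dataset/group."""

    gene_ids: list[str]
    r: np.ndarray  # condensed upper-triangular vector, NaN where undefined
    p: np.ndarray  # matching two-sided p-values
    method: str  # "pearson" | "spearman"
    n_samples: int

    def pair_index(self) -> Iterable[tuple[int, int]]:
        m = len(self.gene_ids)
        for i in range(m - 1):
            for j in range(i + 1, m):
                yield i, j


@dataclass
class EdgeList:
    """Selected top-correlation gene pairs for one dataset/condition."""

    dataset: str
    edges: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)  # pair -> (r, p)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise DataError(f"{self.dataset}: self-pair ({a}, {b})")
            if a > b:
                raise DataError(f"{self.dataset}: pair ({a}, {b}) not lexicographically ordered")
        for (a, b), (r, _) in self.edges.items():
            if abs(r) > 1 + 1e-12:
                raise DataError(f"{self.dataset}: |r| > 1 for pair ({a}, {b})")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)


@dataclass
class FrequencyNetwork:
    """Weighted undirected gene graph; weight = occurrence count / K."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # ordered pair -> weight in {1/K .. 1}
    n_datasets: int

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise DataError(f"self-loop on {a}")
            if a > b:
                raise DataError(f"pair ({a}, {b}) not ordered")
            if a not in node_set or b not in node_set:
                raise DataError(f"edge ({a}, {b}) references unknown node")
            k = w * self.n_datasets
            if not (0 < w <= 1 and abs(k - round(k)) < 1e-9):
                raise DataError(f"weight {w} for ({a}, {b}) is not k/{self.n_datasets}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> tuple[np.ndarray, dict[str, int]]:
        """Dense symmetric weight matrix plus node index (zeros off-edge)."""
        index = {g: i for i, g in enumerate(self.nodes)}
        adj = np.zeros((len(self.nodes), len(self.nodes)))
        for (a, b), w in self.edges.items():
            i, j = index[a], index[b]
            adj[i, j] = adj[j, i] = w
        return adj, index

    def weighted_degree(self) -> dict[str, float]:
        deg = {g: 0.0 for g in self.nodes}
        for (a, b), w in self.edges.items():
            deg[a] += w
            deg[b] += w
        return deg


def _pearson_condensed(x: np.ndarray) -> np.ndarray:
    """Condensed upper-triangular Pearson correlations of rows of x."""
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1, ddof=0)
    defined = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = xc / np.where(sd == 0, np.nan, sd)[:, None]
    r = (xn @ xn.T) / x.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    r[~defined, :] = np.nan
    r[:, ~defined] = np.nan
    iu = np.triu_indices(x.shape[0], k=1)
    return r[iu]


def pairwise_correlation(dataset: ExpressionDataset, group: str) -> CorrelationTable:
    """All-pairs correlation within one condition group.

    Pearson for continuous platforms, Spearman for counts; two-sided p via
    the t-approximation with n - 2 degrees of freedom. Zero-variance genes
    yield undefined (NaN) coefficients, excluded from edge selection.
    """
    mask = dataset.condition_mask(group)
    n = int(mask.sum())
    if n < 4:
        raise DataError(f"{dataset.name}: group {group!r} has {n} samples; need >= 4")
    if dataset.platform == "counts":
        # Spearman on raw counts; per-sample library scaling is deliberately
        # not applied first (it would couple every pair through the library)
        method = "spearman"
        x = np.apply_along_axis(stats.rankdata, 1, dataset.values[:, mask])
    else:
        method = "pearson"
        x = dataset.values[:, mask]
    r = _pearson_condensed(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 1.0 - r ** 2
        t = r * np.sqrt((n - 2) / np.where(denom <= 0, np.nan, denom))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # |r| == 1 exactly -> p = 0
    p = np.where(np.isnan(p) & ~np.isnan(r), 0.0, p)
    return CorrelationTable(gene_ids=list(dataset.gene_ids), r=r, p=p, method=method, n_samples=n)


def select_top_edges(
    table: CorrelationTable,
    top_pct: float = 5.0,
    p_max: float = 0.05,
    dataset_name: Optional[str] = None,
) -> EdgeList:
    """Keep pairs with |r| in the top percentile AND p < p_max.

    The percentile is computed over all defined pairs; ties at the threshold
    are kept (inclusive).
    """
    name = dataset_name or "table"
    abs_r = np.abs(table.r)
    defined = ~np.isnan(abs_r)
    if not defined.any():
        logger.warning("select_top_edges[%s]: no defined pairs", name)
        return EdgeList(dataset=name)
    threshold = np.percentile(abs_r[defined], 100.0 - top_pct, method="linear")
    selected = defined & (abs_r >= threshold) & (table.p < p_max)
    if not selected.any():
        logger.warning("select_top_edges[%s]: no pair passed thresholds", name)
        return EdgeList(dataset=name)
    m = len(table.gene_ids)
    iu_i, iu_j = np.triu_indices(m, k=1)
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    for k in np.flatnonzero(selected):
        a, b = table.gene_ids[iu_i[k]], table.gene_ids[iu_j[k]]
        if a > b:
            a, b = b, a
        edges[(a, b)] = (float(table.r[k]), float(table.p[k]))
    logger.info("select_top_edges[%s]: %d edges (threshold |r| >= %.4f)", name, len(edges), threshold)
    return EdgeList(dataset=name, edges=edges)


def frequency_network(edge_lists: list[EdgeList], n_datasets: Optional[int] = None) -> FrequencyNetwork:
    """Aggregate per-dataset edge lists into occurrence-frequency weights."""
    k_total = n_datasets if n_datasets is not None else len(edge_lists)
    if k_total < 2:
        raise DataError("frequency_network requires >= 2 edge lists")
    if len(edge_lists) > k_total:
        raise DataError(f"{len(edge_lists)} edge lists exceed n_datasets={k_total}")
    counts: dict[tuple[str, str], int] = {}
    for el in edge_lists:
        for pair in el.edges:
            counts[pair] = counts.get(pair, 0) + 1
    nodes = sorted({g for pair in counts for g in pair})
    edges = {pair: c / k_total for pair, c in counts.items()}
    return FrequencyNetwork(nodes=nodes, edges=edges, n_datasets=k_total)
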