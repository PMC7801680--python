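"""Gene/probe filtering so all cohorts share one gene universe.

Filter order is fixed: per-condition zero-fraction (counts only), then
bottom-percentile variance, then bottom-percentile mean; every removed gene
is charged to the first rule that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from fgcn.io import DataError, ExpressionDataset, logger


@dataclass
class FilterReport:
    dataset: str
    input_genes: int
    removed_unannotated: int = 0
    removed_zero_fraction: int = 0
    removed_variance: int = 0
    removed_mean: int = 0
    survived: int = 0

    def __post_init__(self) -> None:
        removed = (
            self.removed_unannotated
            + self.removed_zero_fraction
            + self.removed_variance
            + self.removed_mean
        )
        if removed + self.survived != self.input_genes:
            raise ValueError("filter report does not account for every gene exactly once")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def collapse_probes(
    values: np.ndarray,
    probe_ids: list[str],
    probe_to_gene: dict[str, str],
) -> tuple[np.ndarray, list[str]]:
    """Collapse a probe x sample matrix to gene x sample.

    Unannotated probes are dropped; for a multi-probe gene the retained row
    is the probe with the highest mean expression across samples.
    """
    if not probe_to_gene:
        raise DataError("probe-to-gene mapping is empty")
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=1)
    best: dict[str, int] = {}
    for i, probe in enumerate(probe_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or means[i] > means[best[gene]]:
            best[gene] = i
    if not best:
        raise DataError("no probe maps to any gene")
    genes = sorted(best)
    rows = [best[g] for g in genes]
    for g in genes:
        logger.debug("collapse_probes: gene %s <- probe %s", g, probe_ids[best[g]])
    return values[rows, :], genes


def filter_genes(
    dataset: ExpressionDataset,
    zero_frac: float = 0.5,
    var_pct: float = 20.0,
    mean_pct: float = 10.0,
) -> tuple[ExpressionDataset, FilterReport]:
    """Apply the three-stage gene filter; returns surviving dataset + report.

    Rule 1 (counts platforms only): drop genes with > zero_frac zeros within
    either condition group. Rule 2: drop genes with variance in the bottom
    var_pct percentile across all samples (cutoff inclusive). Rule 3: same
    for mean, bottom mean_pct percentile.
    """
    n = dataset.n_genes
    keep = np.ones(n, dtype=bool)
    removed_zero = 0

    if dataset.platform == "counts":
        for group in ("disease", "control"):
            sub = dataset.group_values(group)
            frac_zero = (sub == 0).mean(axis=1)
            fire = keep & (frac_zero > zero_frac)
            removed_zero += int(fire.sum())
            keep &= ~fire

    values = dataset.continuous_values()

    removed_var = 0
    if var_pct > 0 and keep.any():
        variances = values[keep].var(axis=1, ddof=1)
        cutoff = np.percentile(variances, var_pct, method="linear")
        fire = variances <= cutoff
        idx = np.flatnonzero(keep)
        keep[idx[fire]] = False
        removed_var = int(fire.sum())

    removed_mean = 0
    if mean_pct > 0 and keep.any():
        means = values[keep].mean(axis=1)
        cutoff = np.percentile(means, mean_pct, method="linear")
        fire = means <= cutoff
        idx = np.flatnonzero(keep)
        keep[idx[fire]] = False
        removed_mean = int(fire.sum())

    if not keep.any():
        raise DataError(f"{dataset.name}: filtering removed all genes")

    surviving = [g for g, k in zip(dataset.gene_ids, keep) if k]
    out = replace(dataset, values=dataset.values[keep, :], gene_ids=surviving)
    report = FilterReport(
        dataset=dataset.name,
        input_genes=n,
        removed_zero_fraction=removed_zero,
        removed_variance=removed_var,
        removed_mean=removed_mean,
        survived=int(keep.sum()),
    )
    logger.info(
        "filter_genes[%s]: %d -> %d (zero %d, var %d, mean %d)",
        dataset.name, n, report.survived, removed_zero, removed_var, removed_mean,
    )
    return out, report


def intersect_genes(datasets: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the sorted intersection of gene universes."""
    if len(datasets) < 2:
        raise DataError("intersect_genes requires >= 2 datasets")
    common = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.gene_ids)
    if not common:
        raise DataError("gene universes have empty intersection")
    order = sorted(common)
    return [ds.subset_genes(order) for ds in datasets]
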