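"""Attribution of module expression changes to composition vs regulation.

Eigengenes, eigengene/proportion/trait correlation tables with Bonferroni
flags, marker and DE-gene enrichment (exact hypergeometric tail), module
overlap, hub-gene turnover, hub connectivity across proportion splits, and
cross-region proportion concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fgcn.deconv import CELL_TYPES, CellTypeMarkers
from fgcn.io import DataError, ExpressionDataset
from fgcn.lmqcm import GeneModule, GeneModuleCollection
from fgcn.network import FrequencyNetwork
from fgcn.scores import cci


@dataclass
class Eigengene:
    module_id: str
    scores: np.ndarray  # per-sample PC1 score
    sample_ids: list[str]
    explained_variance: float
    flipped: bool  # whether orientation negated the raw PC1


@dataclass
class HubReport:
    hubs_disease: set[str]
    hubs_control: set[str]

    @property
    def gained(self) -> set[str]:
        return self.hubs_disease - self.hubs_control

    @property
    def lost(self) -> set[str]:
        return self.hubs_control - self.hubs_disease


def module_eigengene(module: GeneModule | list[str], dataset: ExpressionDataset) -> Eigengene:
    """PC1 of the gene-standardized member submatrix, oriented to the mean profile.

    The orientation rule makes the score vector positively correlated with the
    module's mean standardized expression; an exact tie orients the
    lexicographically first gene positively.
    """
    genes = list(module.members) if isinstance(module, GeneModule) else sorted(module)
    module_id = module.module_id if isinstance(module, GeneModule) else "module"
    if len(genes) < 2:
        raise DataError("module_eigengene: need >= 2 member genes")
    sub = dataset.subset_genes(genes)
    if sub.n_samples < 3:
        raise DataError("module_eigengene: need >= 3 samples")
    x = sub.continuous_values()
    sd = x.std(axis=1, ddof=0)
    if np.any(sd == 0):
        constant = [genes[i] for i in np.flatnonzero(sd == 0)]
        raise DataError(f"module_eigengene: constant gene(s) {constant}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    explained = float(s[0] ** 2 / np.sum(s ** 2))
    mean_profile = z.mean(axis=0)
    proj = float(np.dot(mean_profile, pc1))
    if proj < 0 or (proj == 0 and np.dot(z[0], pc1) < 0):
        pc1 = -pc1
        flipped = True
    else:
        flipped = False
    return Eigengene(
        module_id=module_id,
        scores=pc1.copy(),
        sample_ids=list(dataset.sample_ids),
        explained_variance=explained,
        flipped=flipped,
    )


def covariate_association(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    method: str = "spearman",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlation of each score column (rows of the result) with each covariate.

    Bonferroni cutoff = alpha / (#rows x #covariates); rows ranked by mean
    absolute coefficient (rank 1 = largest).
    """
    if method not in ("pearson", "spearman"):
        raise DataError(f"unknown method {method!r}")
    shared = scores.index.intersection(covariates.index)
    if len(shared) < 3:
        raise DataError(f"covariate_association: only {len(shared)} shared samples; need >= 3")
    s = scores.loc[shared]
    c = covariates.loc[shared]
    n_tests = s.shape[1] * c.shape[1]
    cutoff = alpha / n_tests
    rows = []
    for score_col in s.columns:
        row: dict = {"row": score_col}
        coefs = []
        for cov_col in c.columns:
            x, y = s[score_col].to_numpy(float), c[cov_col].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                raise DataError(f"covariate_association: < 3 finite pairs for {score_col}/{cov_col}")
            if method == "pearson":
                coef, p = stats.pearsonr(x[ok], y[ok])
            else:
                coef, p = stats.spearmanr(x[ok], y[ok])
            row[f"{cov_col}_coef"] = float(coef)
            row[f"{cov_col}_p"] = float(p)
            row[f"{cov_col}_bonferroni"] = bool(p < cutoff)
            coefs.append(abs(float(coef)))
        row["mean_abs_coef"] = float(np.mean(coefs))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("row")
    table["rank"] = table["mean_abs_coef"].rank(ascending=False, method="min").astype(int)
    table.attrs["bonferroni_cutoff"] = cutoff
    return table.sort_values("rank")


def hypergeom_tail(k: int, m: int, big_k: int, big_g: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(G, K, m) — the one-sided Fisher tail."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, big_g, big_k, m))


def marker_enrichment(
    module: GeneModule,
    markers: CellTypeMarkers,
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail marker enrichment per cell type, BH-adjusted.

    The module's assigned type is the most significant passing type
    (adjusted p < 0.05), or none.
    """
    background = set(background)
    member_set = module.member_set
    if not member_set <= background:
        raise DataError(
            f"marker_enrichment[{module.module_id}]: module not contained in background"
        )
    g = len(background)
    m = len(member_set)
    rows = []
    for ct in CELL_TYPES:
        marker_set = set(markers.markers[ct]) & background
        k = len(member_set & marker_set)
        p = hypergeom_tail(k, m, len(marker_set), g)
        rows.append({"cell_type": ct, "overlap": k, "markers_in_background": len(marker_set), "p": p})
    table = pd.DataFrame(rows)
    table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    passing = table[table["adj_p"] < 0.05]
    table.attrs["assigned_type"] = (
        passing.sort_values(["adj_p", "p"]).iloc[0]["cell_type"] if len(passing) else None
    )
    return table


def module_overlap(
    collection_a: GeneModuleCollection,
    collection_b: GeneModuleCollection,
    shared_threshold: float = 0.3,
) -> pd.DataFrame:
    """Jaccard index for every cross pair; pairs above threshold flagged shared."""
    data = np.zeros((len(collection_a), len(collection_b)))
    for i, ma in enumerate(collection_a):
        for j, mb in enumerate(collection_b):
            inter = len(ma.member_set & mb.member_set)
            union = len(ma.member_set | mb.member_set)
            data[i, j] = inter / union if union else 0.0
    table = pd.DataFrame(data, index=collection_a.ids, columns=collection_b.ids)
    table.attrs["shared_pairs"] = [
        (a, b)
        for a in table.index
        for b in table.columns
        if table.loc[a, b] > shared_threshold
    ]
    return table


def hub_genes(net: FrequencyNetwork, pct: float = 5.0) -> set[str]:
    """Nodes with weighted degree at or above the (100 - pct) percentile (ties kept)."""
    deg = net.weighted_degree()
    if not deg:
        return set()
    values = np.array(list(deg.values()))
    threshold = np.percentile(values, 100.0 - pct, method="linear")
    return {g for g, d in deg.items() if d >= threshold}


def hub_turnover(
    net_disease: FrequencyNetwork,
    net_control: FrequencyNetwork,
    pct: float = 5.0,
) -> HubReport:
    return HubReport(
        hubs_disease=hub_genes(net_disease, pct),
        hubs_control=hub_genes(net_control, pct),
    )


def connectivity_vs_proportion(
    dataset: ExpressionDataset,
    hub_gene_ids: list[str] | set[str],
    proportions: pd.DataFrame,
    cell_type: str,
) -> pd.DataFrame:
    """Hub connectivity in high- vs low-proportion sample halves + sign test.

    Samples split at the median surrogate for the chosen type; connectivity
    of a hub gene is its summed |correlation| with the other hub genes,
    recomputed within each half. The result table carries the two-sided sign
    test p in ``attrs["sign_test_p"]``.
    """
    hubs = sorted(set(hub_gene_ids))
    missing = [g for g in hubs if g not in dataset.gene_ids]
    if missing:
        raise DataError(f"hub genes absent from dataset: {missing[:5]}")
    if cell_type not in proportions.columns:
        raise DataError(f"cell type {cell_type!r} not in proportion table")
    props = proportions.loc[dataset.sample_ids, cell_type].to_numpy(float)
    median = np.median(props)
    high = props > median
    low = ~high
    if high.sum() < 4 or low.sum() < 4:
        raise DataError("connectivity_vs_proportion: need >= 4 samples per half")
    sub = dataset.subset_genes(hubs)
    x = sub.continuous_values()

    def connectivity(mask: np.ndarray) -> np.ndarray:
        xm = x[:, mask]
        if xm.shape[0] == 1:
            return np.zeros(1)
        r = np.corrcoef(xm)
        np.fill_diagonal(r, 0.0)
        return np.nansum(np.abs(r), axis=1)

    conn_high = connectivity(high)
    conn_low = connectivity(low)
    diff = conn_high - conn_low
    n_pos = int((diff > 0).sum())
    n_neg = int((diff < 0).sum())
    n_eff = n_pos + n_neg
    p = float(stats.binomtest(n_pos, n_eff, 0.5).pvalue) if n_eff else 1.0
    table = pd.DataFrame(
        {"gene_id": hubs, "connectivity_high": conn_high, "connectivity_low": conn_low, "diff": diff}
    )
    table.attrs["sign_test_p"] = p
    table.attrs["n_higher_in_high"] = n_pos
    table.attrs["n_higher_in_low"] = n_neg
    return table


def cross_region_concordance(
    proportions_by_region: dict[str, pd.Series],
    cell_type: str = "",
) -> float:
    """CCI of subject-matched proportion vectors across regions.

    Rows of the implied matrix are regions, columns subjects; the statistic
    is the same standardized leading eigenvalue used for module CCI.
    """
    if len(proportions_by_region) < 2:
        raise DataError("cross_region_concordance: need >= 2 regions")
    regions = sorted(proportions_by_region)
    subjects = set(proportions_by_region[regions[0]].index)
    for r in regions[1:]:
        other = set(proportions_by_region[r].index)
        if other != subjects:
            unmatched = sorted(subjects ^ other)
            raise DataError(f"cross_region_concordance: unmatched subjects {unmatched[:10]}")
    order = sorted(subjects)
    matrix = np.vstack([proportions_by_region[r].loc[order].to_numpy(float) for r in regions])
    if matrix.shape[1] < 3:
        raise DataError("cross_region_concordance: need >= 3 matched subjects")
    sd = matrix.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise DataError("cross_region_concordance: constant proportion vector")
    corr = np.corrcoef(matrix)
    return cci(corr)
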