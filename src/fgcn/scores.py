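"""Module-level DE, DC, and CCI scoring; quadrant classification; DE gene calls.

DE score: mean absolute Welch t over member genes. DC score: root-mean-square
of Fisher-z standardized correlation differences over member pairs. CCI:
standardized leading eigenvalue of the member correlation matrix, in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fgcn.io import DataError, ExpressionDataset, logger
from fgcn.lmqcm import GeneModule

R_CLAMP = 1.0 - 1e-7

QUADRANTS = ("HDE_HDC", "HDE_LDC", "LDE_HDC", "LDE_LDC")


@dataclass
class GeneTScore:
    gene_id: str
    mean_d: float
    mean_n: float
    sd_d: float
    sd_n: float
    n_d: int
    n_n: int
    t: float  # absolute Welch statistic; NaN when undefined

    @property
    def defined(self) -> bool:
        return math.isfinite(self.t)


@dataclass
class PairDC:
    pair: tuple[str, str]
    r_n: float
    r_d: float
    z_n: float
    z_d: float
    z: float  # absolute standardized difference


def fisher_z(r: float) -> float:
    """z = 0.5 * ln|(1 + r) / (1 - r)| with |r| clamped below 1."""
    r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return 0.5 * math.log(abs((1.0 + r) / (1.0 - r)))


def gene_t_score(expr_d: Sequence[float], expr_n: Sequence[float], gene_id: str = "") -> GeneTScore:
    """Absolute Welch t-statistic between the disease and control vectors."""
    xd = np.asarray(expr_d, dtype=float)
    xn = np.asarray(expr_n, dtype=float)
    if xd.size < 2 or xn.size < 2:
        raise DataError(f"gene_t_score[{gene_id}]: both groups need >= 2 samples")
    mean_d, mean_n = float(xd.mean()), float(xn.mean())
    sd_d = float(xd.std(ddof=1))
    sd_n = float(xn.std(ddof=1))
    se = math.sqrt(sd_d ** 2 / xd.size + sd_n ** 2 / xn.size)
    if se == 0.0:
        t = 0.0 if mean_d == mean_n else float("nan")
    else:
        t = abs(mean_d - mean_n) / se
    return GeneTScore(gene_id, mean_d, mean_n, sd_d, sd_n, xd.size, xn.size, t)


def module_de_score(module: GeneModule | Sequence[str], dataset: ExpressionDataset) -> float:
    """Mean of defined |t| values over the module's genes.

    Genes with an undefined statistic (zero variance in both groups with
    unequal means) are excluded from both numerator and denominator.
    """
    genes = list(module.members) if isinstance(module, GeneModule) else list(module)
    sub = dataset.subset_genes(genes)
    values = sub.continuous_values()
    mask_d = sub.condition_mask("disease")
    mask_n = sub.condition_mask("control")
    ts = []
    for i, g in enumerate(genes):
        score = gene_t_score(values[i, mask_d], values[i, mask_n], gene_id=g)
        if score.defined:
            ts.append(score.t)
        else:
            logger.warning("module_de_score: gene %s undefined t, excluded", g)
    if not ts:
        raise DataError("module_de_score: every member gene has an undefined t")
    return float(np.mean(ts))


def pair_dc(r_n: float, r_d: float, n_n: int, n_d: int, pair: tuple[str, str] = ("", "")) -> PairDC:
    """Standardized absolute Fisher-z difference between conditions."""
    if n_n <= 3 or n_d <= 3:
        raise DataError("pair_dc: both groups need > 3 samples")
    if abs(r_n) > 1 + 1e-12 or abs(r_d) > 1 + 1e-12:
        raise DataError("pair_dc: |r| must be <= 1")
    z_n = fisher_z(r_n)
    z_d = fisher_z(r_d)
    denom = math.sqrt(1.0 / (n_n - 3) + 1.0 / (n_d - 3))
    return PairDC(pair=pair, r_n=r_n, r_d=r_d, z_n=z_n, z_d=z_d, z=abs(z_n - z_d) / denom)


def _group_correlations(dataset: ExpressionDataset, genes: list[str], group: str) -> np.ndarray:
    """Gene x gene correlation matrix (platform-appropriate) within one group."""
    sub = dataset.subset_genes(genes)
    mask = sub.condition_mask(group)
    if dataset.platform == "counts":
        # rank raw counts, matching the network stage's Spearman convention
        x = np.apply_along_axis(stats.rankdata, 1, sub.values[:, mask])
    else:
        x = sub.values[:, mask]
    sd = x.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, np.nan, sd)[:, None]
        r = (xn @ xn.T) / x.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    return r


def module_dc_score(
    module: GeneModule | Sequence[str],
    dataset: ExpressionDataset,
    statistic: str = "rms",
) -> float:
    """Size-normalized DC over all member pairs.

    ``statistic="rms"`` (default) returns sqrt(sum Z^2 / P) over the P defined
    pairs; ``"mean"`` returns the mean |Z|.
    """
    genes = list(module.members) if isinstance(module, GeneModule) else list(module)
    if len(genes) < 2:
        raise DataError("module_dc_score: module needs >= 2 genes")
    n_d = int(dataset.condition_mask("disease").sum())
    n_n = int(dataset.condition_mask("control").sum())
    if n_d < 4 or n_n < 4:
        raise DataError("module_dc_score: both groups need >= 4 samples")
    r_d = _group_correlations(dataset, genes, "disease")
    r_n = _group_correlations(dataset, genes, "control")
    denom = math.sqrt(1.0 / (n_n - 3) + 1.0 / (n_d - 3))
    iu = np.triu_indices(len(genes), k=1)
    rd, rn = r_d[iu], r_n[iu]
    defined = ~(np.isnan(rd) | np.isnan(rn))
    if not defined.any():
        raise DataError("module_dc_score: no defined pairs")
    rd = np.clip(rd[defined], -R_CLAMP, R_CLAMP)
    rn = np.clip(rn[defined], -R_CLAMP, R_CLAMP)
    z = np.abs(np.arctanh(rn) - np.arctanh(rd)) / denom
    if statistic == "rms":
        return float(np.sqrt(np.mean(z ** 2)))
    if statistic == "mean":
        return float(np.mean(z))
    raise ValueError(f"unknown DC statistic {statistic!r}")


def cci(corr: np.ndarray) -> float:
    """Standardized leading eigenvalue (lambda1 - 1) / (m - 1), clipped to [0, 1]."""
    m = corr.shape[0]
    if m < 2:
        raise DataError("cci: needs >= 2 variables")
    lam1 = float(np.linalg.eigvalsh(corr)[-1])
    return float(np.clip((lam1 - 1.0) / (m - 1.0), 0.0, 1.0))


def module_cci(module: GeneModule | Sequence[str], dataset: ExpressionDataset, group: str) -> float:
    """Concordance of member expression within one condition group, in [0, 1]."""
    genes = list(module.members) if isinstance(module, GeneModule) else list(module)
    if len(genes) < 2:
        raise DataError("module_cci: module needs >= 2 genes")
    mask = dataset.condition_mask(group)
    if int(mask.sum()) < 3:
        raise DataError("module_cci: group needs >= 3 samples")
    r = _group_correlations(dataset, genes, group)
    if np.isnan(r).any():
        bad = [genes[i] for i in range(len(genes)) if np.isnan(r[i]).all()]
        raise DataError(f"module_cci: constant gene(s) {bad}")
    return cci(r)


def score_modules(
    modules,
    datasets: list[ExpressionDataset],
    dc_statistic: str = "rms",
) -> pd.DataFrame:
    """Per-module, per-dataset DE/DC/CCI long table."""
    rows = []
    for mod in modules:
        for ds in datasets:
            rows.append(
                {
                    "module_id": mod.module_id,
                    "dataset": ds.name,
                    "de_score": module_de_score(mod, ds),
                    "dc_score": module_dc_score(mod, ds, statistic=dc_statistic),
                    "cci_disease": module_cci(mod, ds, "disease"),
                    "cci_control": module_cci(mod, ds, "control"),
                }
            )
    return pd.DataFrame(rows)


def aggregate_and_classify(per_dataset_scores: pd.DataFrame) -> pd.DataFrame:
    """Median DE/DC across datasets per module and the quadrant call.

    A module is high-DE iff its median DE strictly exceeds the across-module
    median of median DE; likewise for DC.
    """
    required = {"module_id", "dataset", "de_score", "dc_score"}
    missing = required - set(per_dataset_scores.columns)
    if missing:
        raise DataError(f"aggregate_and_classify: missing columns {sorted(missing)}")
    agg = (
        per_dataset_scores.groupby("module_id")
        .agg(median_de=("de_score", "median"), median_dc=("dc_score", "median"))
        .reset_index()
    )
    if {"cci_disease", "cci_control"} <= set(per_dataset_scores.columns):
        cci_med = (
            per_dataset_scores.groupby("module_id")
            .agg(median_cci_disease=("cci_disease", "median"), median_cci_control=("cci_control", "median"))
            .reset_index()
        )
        agg = agg.merge(cci_med, on="module_id")
    de_split = agg["median_de"].median()
    dc_split = agg["median_dc"].median()
    agg["quadrant"] = [
        ("H" if de > de_split else "L") + "DE_" + ("H" if dc > dc_split else "L") + "DC"
        for de, dc in zip(agg["median_de"], agg["median_dc"])
    ]
    agg.attrs["de_split"] = float(de_split)
    agg.attrs["dc_split"] = float(dc_split)
    return agg


def cci_condition_test(per_dataset_scores: pd.DataFrame, module_id: str) -> tuple[float, float]:
    """Paired two-sided t-test over datasets on (CCI_disease - CCI_control)."""
    sub = per_dataset_scores[per_dataset_scores["module_id"] == module_id]
    if len(sub) < 2:
        raise DataError("cci_condition_test: need scores from >= 2 datasets")
    res = stats.ttest_rel(sub["cci_disease"], sub["cci_control"])
    return float(res.statistic), float(res.pvalue)


def _moderate_variances(sd2: np.ndarray, df: int) -> np.ndarray:
    """Moment-matched inverse-gamma shrinkage of per-gene variances."""
    s2 = sd2[sd2 > 0]
    if s2.size < 3:
        return sd2
    log_s2 = np.log(s2)
    m, v = log_s2.mean(), log_s2.var(ddof=1)
    # approximate prior df from excess variance of log sample variances
    from scipy.special import polygamma

    excess = v - polygamma(1, df / 2.0)
    if excess <= 0:
        # no between-gene variance beyond sampling noise: full shrinkage
        return np.full_like(sd2, s2.mean())
    # solve trigamma(d0/2) = excess for prior df d0 (bisection)
    lo, hi = 0.1, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if polygamma(1, mid / 2.0) > excess:
            lo = mid
        else:
            hi = mid
    d0 = 0.5 * (lo + hi)
    s0_2 = math.exp(m + polygamma(0, df / 2.0) - math.log(df / 2.0))
    return (d0 * s0_2 + df * sd2) / (d0 + df)


def call_de_genes(
    datasets: list[ExpressionDataset],
    fc: float = 1.2,
    fdr: float = 0.05,
    min_datasets: int = 2,
    moderated: bool = False,
) -> pd.DataFrame:
    """Per-gene cross-dataset DE calls.

    Per dataset: Welch t on log2 data, BH adjustment across genes; a gene is
    DE there iff |mean log2 difference| >= log2(fc) and adjusted p < fdr.
    Globally UP (DOWN) requires passing with a consistent sign in at least
    ``min_datasets`` datasets; conflicting-sign passes are recorded but not
    counted toward either direction.
    """
    if len(datasets) < min_datasets:
        raise DataError(f"call_de_genes: need >= {min_datasets} datasets")
    log_fc = math.log2(fc)
    per_gene_up: dict[str, int] = {}
    per_gene_down: dict[str, int] = {}
    all_genes: list[str] = []
    seen: set[str] = set()
    for ds in datasets:
        for g in ds.gene_ids:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)
        values = ds.continuous_values()
        xd = values[:, ds.condition_mask("disease")]
        xn = values[:, ds.condition_mask("control")]
        diff = xd.mean(axis=1) - xn.mean(axis=1)
        vd = xd.var(axis=1, ddof=1)
        vn = xn.var(axis=1, ddof=1)
        nd, nn = xd.shape[1], xn.shape[1]
        if moderated:
            vd = _moderate_variances(vd, nd - 1)
            vn = _moderate_variances(vn, nn - 1)
        se2 = vd / nd + vn / nn
        with np.errstate(invalid="ignore", divide="ignore"):
            t = diff / np.sqrt(se2)
            df = se2 ** 2 / ((vd / nd) ** 2 / (nd - 1) + (vn / nn) ** 2 / (nn - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
        p = np.where(np.isfinite(p), p, 1.0)
        adj = multipletests(p, method="fdr_bh")[1]
        passing = (np.abs(diff) >= log_fc) & (adj < fdr)
        for i, g in enumerate(ds.gene_ids):
            if passing[i]:
                if diff[i] > 0:
                    per_gene_up[g] = per_gene_up.get(g, 0) + 1
                else:
                    per_gene_down[g] = per_gene_down.get(g, 0) + 1
    rows = []
    for g in all_genes:
        up = per_gene_up.get(g, 0)
        down = per_gene_down.get(g, 0)
        if up >= min_datasets and down >= min_datasets:
            direction = "conflict"
        elif up >= min_datasets:
            direction = "up"
        elif down >= min_datasets:
            direction = "down"
        else:
            direction = "none"
        rows.append({"gene_id": g, "n_up": up, "n_down": down, "direction": direction})
    return pd.DataFrame(rows)


def module_de_fractions(module: GeneModule, de_table: pd.DataFrame) -> tuple[float, float]:
    """Fractions of member genes called globally up / down."""
    members = module.member_set
    sub = de_table[de_table["gene_id"].isin(members)]
    m = len(members)
    up = float((sub["direction"] == "up").sum()) / m
    down = float((sub["direction"] == "down").sum()) / m
    return up, down
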