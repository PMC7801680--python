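"""Multi-cohort bulk expression simulator with known cell-type mixtures.

Each sample is a mixture of five brain cell types whose proportions are
drawn from condition-dependent Dirichlet distributions (neurons down,
microglia/astrocytes/endothelia up in disease). Planted gene modules come in
three classes: proportion-driven (expression tracks one type's proportion),
regulation-perturbed (condition-dependent correlation structure plus a mean
shift), and housekeeping (no condition effect). Traits are monotone noisy
functions of pathology. Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fgcn.deconv import CELL_TYPES, CellTypeMarkers
from fgcn.io import DataError, ExpressionDataset

MODULE_CLASSES = ("proportion_driven", "regulation_perturbed", "housekeeping")


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate a five-cohort brain study."""

    n_datasets: int = 5
    platforms: tuple[str, ...] = ("continuous", "continuous", "counts", "counts", "counts")
    n_disease: int = 60
    n_control: int = 60
    n_genes: int = 2000
    markers_per_type: int = 50
    # Dirichlet concentrations per condition over (neu, mic, ast, oli, end).
    # Disease: neurons down, microglia/astrocytes/endothelia up, oligodendrocytes
    # unchanged. The disease total concentration is larger so that per-type
    # sampling variance stays comparable across conditions; otherwise a pure
    # composition shift would also manifest as differential co-expression.
    alpha_control: tuple[float, ...] = (12.0, 2.0, 3.0, 4.0, 1.5)
    alpha_disease: tuple[float, ...] = (16.0, 7.0, 6.2, 7.3, 4.5)
    module_size: int = 30
    baseline: float = 6.0
    signal_offset: float = 1.5  # keeps signal genes above the mean-percentile filter
    proportion_slope: float = 8.0
    noise_sd: float = 0.5
    reg_r_control: float = 0.4
    reg_r_disease: float = 0.7
    reg_mean_shift: float = -0.5
    reg_neuron_coupling: float = 2.0
    trait_noise_sd: float = 0.3
    n_regions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.platforms) != self.n_datasets:
            raise DataError("platforms length must equal n_datasets")
        if any(a <= 0 for a in self.alpha_control + self.alpha_disease):
            raise DataError("Dirichlet concentrations must be positive")
        if len(self.alpha_control) != 5 or len(self.alpha_disease) != 5:
            raise DataError("need 5 Dirichlet concentrations per condition")
        if not -1 < self.reg_r_control < 1 or not -1 < self.reg_r_disease < 1:
            raise DataError("block correlations must be in (-1, 1)")
        needed = 5 * self.markers_per_type + 7 * self.module_size
        if self.n_genes < needed + 100:
            raise DataError(f"n_genes too small; need >= {needed + 100}")
        if self.module_size < 10:
            raise DataError("module_size must be >= 10 to survive default mining")


@dataclass
class SyntheticTruth:
    """Ground truth: proportions, planted memberships, traits, parameters."""

    proportions: dict[str, pd.DataFrame]  # dataset -> samples x 5 types (rows sum to 1)
    modules: dict[str, dict] = field(default_factory=dict)  # name -> {members, class, cell_type}
    traits: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: SimulationConfig | None = None

    def module_members(self, name: str) -> list[str]:
        return self.modules[name]["members"]


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def _equicorrelated(rng: np.random.Generator, n_samples: int, size: int, r: float) -> np.ndarray:
    """size x n_samples draws from N(0, C) with C = (1-r) I + r J (unit variance)."""
    shared = rng.standard_normal(n_samples)
    own = rng.standard_normal((size, n_samples))
    return np.sqrt(r) * shared[None, :] + np.sqrt(1.0 - r) * own


def simulate_cohorts(config: SimulationConfig) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Generate the cohorts and the ground truth they were built from."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    # fixed gene layout shared by all datasets
    cursor = 0
    marker_genes: dict[str, list[str]] = {}
    prop_modules: dict[str, list[str]] = {}
    for ct in CELL_TYPES:
        marker_genes[ct] = genes[cursor:cursor + config.markers_per_type]
        cursor += config.markers_per_type
    for ct in CELL_TYPES:
        prop_modules[ct] = genes[cursor:cursor + config.module_size]
        cursor += config.module_size
    reg_module = genes[cursor:cursor + config.module_size]
    cursor += config.module_size
    hk_module = genes[cursor:cursor + config.module_size]
    cursor += config.module_size
    background = genes[cursor:]

    truth = SyntheticTruth(proportions={}, config=config)
    for ct in CELL_TYPES:
        truth.modules[f"prop_{ct}"] = {
            "members": prop_modules[ct],
            "class": "proportion_driven",
            "cell_type": ct,
        }
    truth.modules["reg_neuron"] = {
        "members": reg_module,
        "class": "regulation_perturbed",
        "cell_type": "neu",
    }
    truth.modules["housekeeping"] = {
        "members": hk_module,
        "class": "housekeeping",
        "cell_type": None,
    }

    datasets: list[ExpressionDataset] = []
    n_total = config.n_disease + config.n_control
    gene_index = {g: i for i, g in enumerate(genes)}

    for d in range(config.n_datasets):
        platform = config.platforms[d]
        name = f"cohort{d + 1}"
        condition = ["disease"] * config.n_disease + ["control"] * config.n_control
        sample_ids = [f"{name}_S{str(i).zfill(3)}" for i in range(n_total)]

        props = np.vstack(
            [
                rng.dirichlet(config.alpha_disease, size=config.n_disease),
                rng.dirichlet(config.alpha_control, size=config.n_control),
            ]
        )
        prop_df = pd.DataFrame(props, index=sample_ids, columns=list(CELL_TYPES))

        # centering proportions at their pooled expectation keeps signal genes
        # from dominating count libraries (which would leak composition shifts
        # into every other gene through CPM normalization)
        alpha_d = np.asarray(config.alpha_disease)
        alpha_c = np.asarray(config.alpha_control)
        prop_center = 0.5 * (alpha_d / alpha_d.sum() + alpha_c / alpha_c.sum())

        log2 = np.empty((config.n_genes, n_total))
        log2[:] = np.nan

        # background + housekeeping: independent noise around the baseline
        for g in background:
            log2[gene_index[g]] = config.baseline + rng.normal(0, config.noise_sd, n_total)
        for g in hk_module:
            log2[gene_index[g]] = config.baseline + rng.normal(0, config.noise_sd, n_total)

        # proportion-driven genes (markers and planted modules alike)
        for ct_i, ct in enumerate(CELL_TYPES):
            signal = (config.baseline + config.signal_offset
                      + config.proportion_slope * (props[:, ct_i] - prop_center[ct_i]))
            for g in marker_genes[ct] + prop_modules[ct]:
                log2[gene_index[g]] = signal + rng.normal(0, config.noise_sd, n_total)

        # regulation-perturbed module: per-condition equicorrelated residuals
        mask_d = np.array([c == "disease" for c in condition])
        block = np.empty((config.module_size, n_total))
        block[:, mask_d] = _equicorrelated(
            rng, int(mask_d.sum()), config.module_size, config.reg_r_disease
        )
        block[:, ~mask_d] = _equicorrelated(
            rng, int((~mask_d).sum()), config.module_size, config.reg_r_control
        )
        reg_mean = (config.baseline + config.signal_offset
                    + config.reg_neuron_coupling * (props[:, 0] - prop_center[0]))
        reg_mean = reg_mean + np.where(mask_d, config.reg_mean_shift, 0.0)
        for k, g in enumerate(reg_module):
            log2[gene_index[g]] = reg_mean + config.noise_sd * block[k]

        if platform == "counts":
            lam = 2.0 ** log2
            lam = lam / lam.sum(axis=0, keepdims=True) * 1e6
            values = rng.poisson(lam).astype(float)
        else:
            values = log2

        datasets.append(
            ExpressionDataset(
                name=name,
                values=values,
                gene_ids=list(genes),
                sample_ids=sample_ids,
                condition=condition,
                platform=platform,
                region=_assign_regions(rng, n_total, config.n_regions),
            )
        )
        truth.proportions[name] = prop_df

    truth.traits = simulate_traits(truth, noise_sd=config.trait_noise_sd, seed=config.seed + 1)
    for ds, name in zip(datasets, truth.traits):
        ds.traits = truth.traits[name]
    return datasets, truth


def _assign_regions(rng: np.random.Generator, n: int, n_regions: int) -> list[str] | None:
    if n_regions <= 1:
        return None
    return [f"R{rng.integers(1, n_regions + 1)}" for _ in range(n)]


def simulate_traits(
    truth: SyntheticTruth,
    noise_sd: float = 0.3,
    seed: int = 1,
) -> dict[str, pd.DataFrame]:
    """CDR, BB score and Plaque_Mean: monotone noisy functions of pathology.

    The latent pathology index increases in microglia + astrocyte proportion
    and decreases in neuron proportion; BB is discretized to 0-6 and CDR to
    {0, 0.5, 1, 2, 3}.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for name, props in truth.proportions.items():
        pathology = (
            props["mic"].to_numpy() + props["ast"].to_numpy() - props["neu"].to_numpy()
        )
        pathology = (pathology - pathology.mean()) / (pathology.std(ddof=0) or 1.0)
        n = len(props)

        def noisy() -> np.ndarray:
            return pathology + rng.normal(0, noise_sd, n)

        cdr_latent = noisy()
        bb_latent = noisy()
        # strictly monotone and non-negative, right-skewed like plaque burden
        plaque = 2.0 * np.exp(0.8 * noisy())
        cdr_bins = np.quantile(cdr_latent, [0.2, 0.4, 0.6, 0.8])
        cdr = np.array([0.0, 0.5, 1.0, 2.0, 3.0])[np.searchsorted(cdr_bins, cdr_latent)]
        bb_bins = np.quantile(bb_latent, np.linspace(1 / 7, 6 / 7, 6))
        bb = np.searchsorted(bb_bins, bb_latent).astype(float)
        out[name] = pd.DataFrame(
            {"cdr": cdr, "bb_score": bb, "plaque_mean": plaque}, index=props.index
        )
    return out


def marker_gene_sets(config: SimulationConfig) -> CellTypeMarkers:
    """The generator's signature genes as a marker collection (for tests/CLI)."""
    genes = _gene_names(config.n_genes)
    cursor = 0
    markers: dict[str, list[str]] = {}
    for ct in CELL_TYPES:
        markers[ct] = genes[cursor:cursor + config.markers_per_type]
        cursor += config.markers_per_type
    return CellTypeMarkers(markers=markers)


def truth_evaluation(
    datasets: list[ExpressionDataset],
    truth: SyntheticTruth,
    mined_modules,
    proportions: dict[str, pd.DataFrame] | None = None,
    dc_statistic: str = "rms",
) -> dict:
    """Recovery report for the planted modules and proportions.

    Planted gene sets are scored directly alongside the mined modules (the
    housekeeping module is never mined — its genes are independent by
    construction — yet still needs a quadrant), so each planted module gets
    its own DE/DC quadrant plus the best-Jaccard mined match, per-dataset
    CCI in both conditions, and eigengene correlations against every true
    cell-type proportion.
    """
    from fgcn.association import module_eigengene
    from fgcn.lmqcm import GeneModule
    from fgcn.scores import aggregate_and_classify, score_modules

    planted = [
        GeneModule(module_id=f"planted_{name}", members=list(info["members"]))
        for name, info in truth.modules.items()
    ]
    scored = list(mined_modules) + planted
    score_table = score_modules(scored, datasets, dc_statistic=dc_statistic)
    agg = aggregate_and_classify(score_table)
    quadrant = dict(zip(agg["module_id"], agg["quadrant"]))

    report: dict = {"modules": {}, "proportions": {}, "score_table": agg}
    for name, info in truth.modules.items():
        members = set(info["members"])
        best_id, best_j = None, 0.0
        for mod in mined_modules:
            inter = len(members & mod.member_set)
            union = len(members | mod.member_set)
            j = inter / union if union else 0.0
            if j > best_j:
                best_id, best_j = mod.module_id, j
        pid = f"planted_{name}"
        sub = score_table[score_table["module_id"] == pid]
        entry = {
            "class": info["class"],
            "cell_type": info["cell_type"],
            "best_match": best_id,
            "jaccard": best_j,
            "quadrant": quadrant[pid],
            "cci_disease": sub["cci_disease"].tolist(),
            "cci_control": sub["cci_control"].tolist(),
        }
        mod = next(m for m in planted if m.module_id == pid)
        eig_r: dict[str, list[float]] = {ct: [] for ct in CELL_TYPES}
        for ds in datasets:
            eig = module_eigengene(mod, ds)
            for ct in CELL_TYPES:
                true_prop = truth.proportions[ds.name][ct].to_numpy(float)
                eig_r[ct].append(float(np.corrcoef(eig.scores, true_prop)[0, 1]))
        entry["eigengene_proportion_r"] = eig_r
        report["modules"][name] = entry
    for ds_name, est in (proportions or {}).items():
        true_props = truth.proportions[ds_name]
        report["proportions"][ds_name] = {
            ct: float(np.corrcoef(est[ct].to_numpy(float), true_props[ct].to_numpy(float))[0, 1])
            for ct in CELL_TYPES
        }
    return report
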