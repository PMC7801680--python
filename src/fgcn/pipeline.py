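"""End-to-end orchestration: preprocess -> networks -> mining -> scores ->
deconvolution -> association, with every stage output written to disk."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from fgcn import association, deconv, network, preprocess, scores
from fgcn.io import (
    DataError,
    ExpressionDataset,
    PipelineConfig,
    logger,
    read_expression,
    read_gmt,
    write_edge_list,
    write_gmt,
    write_json,
)
from fgcn.lmqcm import GeneModuleCollection, LmqcmParams, mine_modules


@dataclass
class RunBundle:
    """Resolved config plus every per-stage output of one pipeline run."""

    config: PipelineConfig
    datasets: list[ExpressionDataset] = field(default_factory=list)
    filter_reports: list[preprocess.FilterReport] = field(default_factory=list)
    edge_lists: dict[str, list[network.EdgeList]] = field(default_factory=dict)
    networks: dict[str, network.FrequencyNetwork] = field(default_factory=dict)
    modules: dict[str, GeneModuleCollection] = field(default_factory=dict)
    score_table: Optional[pd.DataFrame] = None
    aggregate_table: Optional[pd.DataFrame] = None
    de_genes: Optional[pd.DataFrame] = None
    proportions: dict[str, pd.DataFrame] = field(default_factory=dict)
    proportion_tests: dict[str, pd.DataFrame] = field(default_factory=dict)
    eigengene_associations: dict[str, pd.DataFrame] = field(default_factory=dict)
    marker_enrichment: Optional[pd.DataFrame] = None
    hub_report: Optional[association.HubReport] = None

    def all_modules(self) -> list:
        return [m for coll in self.modules.values() for m in coll]


def load_datasets(config: PipelineConfig) -> list[ExpressionDataset]:
    datasets = []
    for entry in config.datasets:
        datasets.append(
            read_expression(
                entry["matrix"],
                entry["phenotype"],
                platform=entry["platform"],
                name=entry.get("name"),
            )
        )
    return datasets


def run_pipeline(
    config: PipelineConfig,
    datasets: Optional[list[ExpressionDataset]] = None,
    markers: Optional[deconv.CellTypeMarkers] = None,
    write_outputs: bool = True,
) -> RunBundle:
    """Execute every stage; deterministic re-runs give identical outputs."""
    if datasets is None:
        datasets = load_datasets(config)
    if len(datasets) < 2:
        raise DataError(">= 2 datasets required (frequency weights undefined otherwise)")
    if markers is None and config.marker_gmt:
        markers = deconv.CellTypeMarkers.from_gene_sets(read_gmt(config.marker_gmt))

    bundle = RunBundle(config=config)
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "resolved_config.yaml")

    # stage: preprocess
    try:
        filtered = []
        for ds in datasets:
            f, report = preprocess.filter_genes(
                ds, zero_frac=config.zero_frac, var_pct=config.var_pct, mean_pct=config.mean_pct
            )
            filtered.append(f)
            bundle.filter_reports.append(report)
        filtered = preprocess.intersect_genes(filtered)
        bundle.datasets = filtered
    except Exception as exc:
        raise DataError(f"stage preprocess failed: {exc}") from exc

    # stage: correlation networks per condition
    try:
        for group in ("disease", "control"):
            lists = []
            for ds in filtered:
                table = network.pairwise_correlation(ds, group)
                lists.append(
                    network.select_top_edges(
                        table, top_pct=config.top_pct, p_max=config.edge_p_max,
                        dataset_name=f"{ds.name}:{group}",
                    )
                )
            bundle.edge_lists[group] = lists
            bundle.networks[group] = network.frequency_network(lists, n_datasets=len(filtered))
    except Exception as exc:
        raise DataError(f"stage network failed: {exc}") from exc

    # stage: module mining (AD prefix for disease-mined, N for control-mined)
    try:
        params = LmqcmParams(
            t=config.lmqcm_t, lam=config.lmqcm_lam, gamma=config.lmqcm_gamma,
            beta=config.lmqcm_beta, min_size=config.lmqcm_min_size,
        )
        bundle.modules["disease"] = mine_modules(
            bundle.networks["disease"], params, prefix="AD", condition="disease"
        )
        bundle.modules["control"] = mine_modules(
            bundle.networks["control"], params, prefix="N", condition="control"
        )
    except Exception as exc:
        raise DataError(f"stage mine failed: {exc}") from exc

    # stage: module scores
    try:
        all_modules = bundle.all_modules()
        if all_modules:
            bundle.score_table = scores.score_modules(
                all_modules, filtered, dc_statistic=config.dc_statistic
            )
            bundle.aggregate_table = scores.aggregate_and_classify(bundle.score_table)
        bundle.de_genes = scores.call_de_genes(
            filtered, fc=config.de_fold_change, fdr=config.de_fdr,
            min_datasets=config.de_min_datasets,
        )
    except Exception as exc:
        raise DataError(f"stage score failed: {exc}") from exc

    # stage: deconvolution
    if markers is not None:
        try:
            for ds in filtered:
                props = deconv.surrogate_proportions(ds, markers, n_markers=config.n_markers)
                bundle.proportions[ds.name] = props
                bundle.proportion_tests[ds.name] = deconv.compare_proportions(props, ds.condition)
        except Exception as exc:
            raise DataError(f"stage deconvolve failed: {exc}") from exc

    # stage: association
    try:
        bundle.hub_report = association.hub_turnover(
            bundle.networks["disease"], bundle.networks["control"]
        )
        all_modules = bundle.all_modules()
        if markers is not None and all_modules:
            enrich_rows = []
            for ds in filtered[:1]:  # gene universe identical across datasets
                background = set(ds.gene_ids)
                for mod in all_modules:
                    table = association.marker_enrichment(mod, markers, background)
                    table.insert(0, "module_id", mod.module_id)
                    table["assigned_type"] = table.attrs["assigned_type"]
                    enrich_rows.append(table)
            bundle.marker_enrichment = pd.concat(enrich_rows, ignore_index=True)
            for ds in filtered:
                eigs = {
                    mod.module_id: association.module_eigengene(mod, ds).scores
                    for mod in all_modules
                }
                eig_df = pd.DataFrame(eigs, index=ds.sample_ids)
                bundle.eigengene_associations[ds.name] = association.covariate_association(
                    eig_df, bundle.proportions[ds.name], method="pearson"
                )
    except Exception as exc:
        raise DataError(f"stage associate failed: {exc}") from exc

    if write_outputs:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: RunBundle, out_dir: Path) -> None:
    write_json([r.to_dict() for r in bundle.filter_reports], out_dir / "filter_reports.json")
    for group, net in bundle.networks.items():
        write_edge_list(
            [(a, b, w) for (a, b), w in net.edges.items()],
            out_dir / f"network_{group}.tsv",
            header=f"K={net.n_datasets}",
        )
    for group, coll in bundle.modules.items():
        if len(coll):
            write_gmt(coll.to_gene_sets(), out_dir / f"modules_{group}.gmt")
    if bundle.score_table is not None:
        bundle.score_table.to_csv(out_dir / "module_scores.tsv", sep="\t", index=False)
    if bundle.aggregate_table is not None:
        bundle.aggregate_table.to_csv(out_dir / "module_quadrants.tsv", sep="\t", index=False)
    if bundle.de_genes is not None:
        bundle.de_genes.to_csv(out_dir / "de_genes.tsv", sep="\t", index=False)
    for name, props in bundle.proportions.items():
        props.to_csv(out_dir / f"proportions_{name}.tsv", sep="\t")
    for name, tests in bundle.proportion_tests.items():
        tests.to_csv(out_dir / f"proportion_tests_{name}.tsv", sep="\t", index=False)
    for name, table in bundle.eigengene_associations.items():
        table.to_csv(out_dir / f"eigengene_proportion_{name}.tsv", sep="\t")
    if bundle.marker_enrichment is not None:
        bundle.marker_enrichment.to_csv(out_dir / "marker_enrichment.tsv", sep="\t", index=False)
    if bundle.hub_report is not None:
        write_json(
            {
                "hubs_disease": sorted(bundle.hub_report.hubs_disease),
                "hubs_control": sorted(bundle.hub_report.hubs_control),
                "gained": sorted(bundle.hub_report.gained),
                "lost": sorted(bundle.hub_report.lost),
            },
            out_dir / "hub_report.json",
        )
    manifest = {
        "config_hash": _config_hash(bundle.config),
        "seed": bundle.config.seed,
        "n_datasets": len(bundle.datasets),
        "n_genes": bundle.datasets[0].n_genes if bundle.datasets else 0,
        "modules_disease": len(bundle.modules.get("disease", [])),
        "modules_control": len(bundle.modules.get("control", [])),
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    write_json(manifest, out_dir / "manifest.json")
    logger.info("pipeline outputs written to %s", out_dir)


def _config_hash(config: PipelineConfig) -> str:
    doc = {k: getattr(config, k) for k in config.__dataclass_fields__}
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]
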