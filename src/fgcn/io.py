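"""On-disk formats, configuration, and logging.

Expression matrices travel as TSV with genes in rows (first column
``gene_id``, header row of sample ids); phenotypes as TSV keyed by
``sample_id``; gene sets as standard GMT; edge lists as three-column TSV
with lexicographically ordered pairs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fgcn")

CONDITION_ALIASES = {
    "disease": "disease",
    "ad": "disease",
    "case": "disease",
    "control": "control",
    "ctl": "control",
    "nd": "control",
    "normal": "control",
}

TRAIT_COLUMNS = ("cdr", "bb_score", "plaque_mean")


def setup_logging(verbosity: int = 0) -> None:
    """Configure timestamped logging to stderr. verbosity: -1 quiet, 0 info, 1 debug."""
    level = logging.DEBUG if verbosity > 0 else (logging.WARNING if verbosity < 0 else logging.INFO)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class DataError(ValueError):
    """Raised when an input file or dataset violates a format contract."""


@dataclass
class ExpressionDataset:
    """One cohort's gene x sample expression matrix with per-sample annotations.

    ``values`` holds log2-scale intensities for platform ``"continuous"`` and
    raw non-negative integer counts for platform ``"counts"``.
    """

    name: str
    values: np.ndarray  # genes x samples
    gene_ids: list[str]
    sample_ids: list[str]
    condition: list[str]  # per-sample, in {"disease", "control"}
    platform: str  # "continuous" | "counts"
    region: Optional[list[str]] = None
    traits: Optional[pd.DataFrame] = None  # indexed by sample_id
    # per-sample library size captured at construction; preserved across gene
    # subsetting so CPM never renormalizes against a gene subset
    library_size: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"{self.name}: matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"{self.name}: expression values must be finite")
        if self.platform not in ("continuous", "counts"):
            raise DataError(f"{self.name}: unknown platform {self.platform!r}")
        if self.platform == "counts":
            if np.any(self.values < 0) or not np.allclose(self.values, np.round(self.values)):
                raise DataError(f"{self.name}: counts platform requires non-negative integers")
            if self.library_size is None:
                self.library_size = self.values.sum(axis=0)
        dup = _duplicates(self.gene_ids)
        if dup:
            raise DataError(f"{self.name}: duplicate gene ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise DataError(f"{self.name}: duplicate sample ids: {sorted(dup)}")
        if len(self.condition) != len(self.sample_ids):
            raise DataError(f"{self.name}: condition length mismatch")
        bad = set(self.condition) - {"disease", "control"}
        if bad:
            raise DataError(f"{self.name}: unrecognized condition labels {sorted(bad)}")
        for group in ("disease", "control"):
            if group not in self.condition:
                raise DataError(f"{self.name}: condition group {group!r} is empty")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condition_mask(self, group: str) -> np.ndarray:
        if group not in ("disease", "control"):
            raise ValueError(f"unknown condition group {group!r}")
        return np.array([c == group for c in self.condition], dtype=bool)

    def group_values(self, group: str) -> np.ndarray:
        """Expression submatrix for one condition group (genes x group samples)."""
        return self.values[:, self.condition_mask(group)]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DataError(f"{self.name}: genes not in dataset: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return replace(self, values=self.values[rows, :], gene_ids=list(gene_ids))

    def continuous_values(self) -> np.ndarray:
        """Values on a continuous (log2) scale.

        Counts are transformed to log2(CPM + 1); continuous data pass through.
        """
        if self.platform == "continuous":
            return self.values
        libsize = np.where(self.library_size == 0, 1.0, self.library_size)
        return np.log2(self.values / libsize * 1e6 + 1.0)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT carrier for marker lists and mined modules)."""

    sets: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.sets]
        dup = _duplicates(names)
        if dup:
            raise DataError(f"duplicate gene-set names: {sorted(dup)}")
        for name, _, members in self.sets:
            if not members:
                raise DataError(f"gene set {name!r} has no members")
            if _duplicates(members):
                raise DataError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        for set_name, _, members in self.sets:
            if set_name == name:
                return members
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.sets]


@dataclass
class PipelineConfig:
    """Run configuration with defaults at the published parameter values."""

    datasets: list[dict] = field(default_factory=list)  # {matrix, phenotype, platform, name}
    top_pct: float = 5.0
    edge_p_max: float = 0.05
    lmqcm_t: float = 1.0
    lmqcm_lam: float = 1.0
    lmqcm_gamma: float = 0.81
    lmqcm_beta: float = 0.3
    lmqcm_min_size: int = 10
    de_fold_change: float = 1.2
    de_fdr: float = 0.05
    de_min_datasets: int = 2
    zero_frac: float = 0.5
    var_pct: float = 20.0
    mean_pct: float = 10.0
    marker_gmt: Optional[str] = None
    n_markers: int = 50
    dc_statistic: str = "rms"  # "rms" | "mean"
    seed: int = 0
    out_dir: str = "fgcn_out"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.top_pct <= 100, "top_pct must be in (0, 100]"),
            (0 < self.edge_p_max <= 1, "edge_p_max must be in (0, 1]"),
            (self.lmqcm_t >= 0, "lmqcm_t must be >= 0"),
            (self.lmqcm_lam > 0, "lmqcm_lam must be > 0"),
            (0 < self.lmqcm_gamma <= 1, "lmqcm_gamma must be in (0, 1]"),
            (0 < self.lmqcm_beta <= 1, "lmqcm_beta must be in (0, 1]"),
            (self.lmqcm_min_size >= 2, "lmqcm_min_size must be >= 2"),
            (self.de_fold_change >= 1, "de_fold_change must be >= 1"),
            (0 < self.de_fdr < 1, "de_fdr must be in (0, 1)"),
            (self.de_min_datasets >= 1, "de_min_datasets must be >= 1"),
            (0 <= self.zero_frac <= 1, "zero_frac must be in [0, 1]"),
            (0 <= self.var_pct < 100, "var_pct must be in [0, 100)"),
            (0 <= self.mean_pct < 100, "mean_pct must be in [0, 100)"),
            (self.n_markers >= 1, "n_markers must be >= 1"),
            (self.dc_statistic in ("rms", "mean"), "dc_statistic must be 'rms' or 'mean'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise DataError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for item in items:
        if item in seen:
            dup.add(item)
        seen.add(item)
    return dup


def normalize_condition(label: str) -> str:
    key = str(label).strip().lower()
    if key not in CONDITION_ALIASES:
        raise DataError(
            f"unrecognized condition label {label!r}; expected one of "
            f"{sorted(set(CONDITION_ALIASES))}"
        )
    return CONDITION_ALIASES[key]


def read_expression(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    platform: str,
    name: Optional[str] = None,
) -> ExpressionDataset:
    """Read a genes-in-rows TSV matrix and its phenotype table.

    Sample order follows the matrix header; phenotype rows are matched by
    ``sample_id``. A transposed matrix is rejected, never silently fixed.
    """
    matrix_path = Path(matrix_path)
    df = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise DataError(
            f"{matrix_path}: first header field must be 'gene_id' "
            f"(got {df.columns[0]!r}); transposed matrices are not accepted"
        )
    gene_ids = df.iloc[:, 0].tolist()
    dup = _duplicates(gene_ids)
    if dup:
        raise DataError(f"{matrix_path}: duplicate gene ids: {sorted(dup)}")
    sample_ids = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:]
    for j, col in enumerate(body.columns):
        coerced = pd.to_numeric(body[col], errors="coerce")
        bad = coerced.isna() & body[col].notna()
        if body[col].isna().any() or bad.any():
            row = int(np.argmax(body[col].isna().to_numpy() | bad.to_numpy()))
            raise DataError(
                f"{matrix_path}: non-numeric or missing value at gene "
                f"{gene_ids[row]!r}, sample {sample_ids[j]!r}"
            )
    values = body.to_numpy(dtype=float)

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in pheno.columns or "condition" not in pheno.columns:
        raise DataError(f"{phenotype_path}: needs columns sample_id, condition")
    pheno = pheno.set_index("sample_id")
    missing = [s for s in sample_ids if s not in pheno.index]
    if missing:
        raise DataError(
            f"{phenotype_path}: samples missing from phenotype: {missing}"
        )
    pheno = pheno.loc[sample_ids]
    condition = [normalize_condition(c) for c in pheno["condition"]]
    region = pheno["region"].astype(str).tolist() if "region" in pheno.columns else None
    trait_cols = [c for c in TRAIT_COLUMNS if c in pheno.columns]
    traits = pheno[trait_cols].astype(float) if trait_cols else None

    return ExpressionDataset(
        name=name or matrix_path.stem,
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        condition=condition,
        platform=platform,
        region=region,
        traits=traits,
    )


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path, phenotype_path: str | Path) -> None:
    """Write a dataset back to the matrix + phenotype TSV pair."""
    df = pd.DataFrame(dataset.values, columns=dataset.sample_ids)
    df.insert(0, "gene_id", dataset.gene_ids)
    if dataset.platform == "counts":
        for c in dataset.sample_ids:
            df[c] = df[c].astype(int)
    df.to_csv(matrix_path, sep="\t", index=False)

    pheno = pd.DataFrame({"sample_id": dataset.sample_ids, "condition": dataset.condition})
    if dataset.region is not None:
        pheno["region"] = dataset.region
    if dataset.traits is not None:
        for c in dataset.traits.columns:
            pheno[c] = dataset.traits[c].to_numpy()
    pheno.to_csv(phenotype_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene TAB gene ...

    Duplicate members within a line are dropped with a logged warning.
    """
    sets: list[tuple[str, str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            name, description = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s line %d: duplicate member %r in set %r dropped", path, lineno, g, name)
                    continue
                seen.add(g)
                members.append(g)
            sets.append((name, description, members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, description, members in collection.sets:
            fh.write("\t".join([name, description, *members]) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read TSV edges gene_a, gene_b, weight (gene_a < gene_b); '#' lines are comments."""
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise DataError(f"{path}: line {lineno}: expected 3 fields")
            a, b, w = fields[0], fields[1], float(fields[2])
            if a >= b:
                raise DataError(f"{path}: line {lineno}: pairs must satisfy gene_a < gene_b")
            edges.append((a, b, w))
    return edges


def write_edge_list(edges: Sequence[tuple[str, str, float]], path: str | Path, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for a, b, w in sorted(edges):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
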