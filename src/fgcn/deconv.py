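"""Marker-based surrogate cell-type proportions and condition comparison.

Per cell type, the first principal component of the z-scored marker
submatrix — sign-oriented to track the majority of markers positively —
serves as a relative abundance index. Surrogates are relative, not
compositional: they are z-scaled per type and need not sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fgcn.io import DataError, ExpressionDataset, GeneSetCollection, logger

CELL_TYPES = ("neu", "mic", "ast", "oli", "end")


@dataclass
class CellTypeMarkers:
    """Ranked marker gene lists for the five major brain cell types."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        missing = set(CELL_TYPES) - set(self.markers)
        if missing:
            raise DataError(f"marker sets missing cell types: {sorted(missing)}")
        assigned: dict[str, str] = {}
        for ct in CELL_TYPES:
            genes = self.markers[ct]
            if not genes:
                raise DataError(f"marker list for {ct!r} is empty")
            for g in genes:
                if g in assigned:
                    raise DataError(f"gene {g!r} marks both {assigned[g]!r} and {ct!r}")
                assigned[g] = ct

    @classmethod
    def from_gene_sets(cls, collection: GeneSetCollection) -> "CellTypeMarkers":
        return cls(markers={name: list(members) for name, _, members in collection.sets})

    def to_gene_sets(self) -> GeneSetCollection:
        return GeneSetCollection(
            sets=[(ct, f"{ct} markers", list(self.markers[ct])) for ct in CELL_TYPES]
        )


def surrogate_proportions(
    dataset: ExpressionDataset,
    markers: CellTypeMarkers,
    n_markers: int = 50,
) -> pd.DataFrame:
    """Samples x cell-types matrix of z-scaled PC1 surrogate indices.

    Per type: take the top ``n_markers`` present markers (rank order
    preserved), z-score each across samples, take PC1 of the marker x sample
    submatrix, orient so that it correlates positively with the majority of
    markers, then z-scale.
    """
    values = dataset.continuous_values()
    index = {g: i for i, g in enumerate(dataset.gene_ids)}
    out = {}
    for ct in CELL_TYPES:
        present = [g for g in markers.markers[ct] if g in index][:n_markers]
        if len(present) < 3:
            raise DataError(
                f"surrogate_proportions[{dataset.name}]: only {len(present)} usable "
                f"markers for cell type {ct!r}; need >= 3"
            )
        x = values[[index[g] for g in present], :]
        sd = x.std(axis=1, ddof=0)
        if np.any(sd == 0):
            constant = [present[i] for i in np.flatnonzero(sd == 0)]
            logger.warning(
                "surrogate_proportions[%s]: constant markers dropped for %s: %s",
                dataset.name, ct, constant,
            )
            ok = sd > 0
            x, present, sd = x[ok], [g for g, k in zip(present, ok) if k], sd[ok]
            if len(present) < 3:
                raise DataError(
                    f"surrogate_proportions[{dataset.name}]: < 3 non-constant markers for {ct!r}"
                )
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        # PC1 scores of the samples = leading right singular vector
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        pc1 = vt[0]
        orient = np.sign(np.array([np.dot(row, pc1) for row in z]))
        pos, neg = np.sum(orient > 0), np.sum(orient < 0)
        if pos < neg or (pos == neg and np.dot(z[0], pc1) < 0):
            pc1 = -pc1
        pc1 = (pc1 - pc1.mean()) / pc1.std(ddof=0)
        out[ct] = pc1
    return pd.DataFrame(out, index=dataset.sample_ids)


def compare_proportions(props: pd.DataFrame, condition: list[str]) -> pd.DataFrame:
    """Per-type two-sided Wilcoxon rank-sum of disease vs control surrogates.

    BH adjustment across the cell types; stars: * adj p < 0.05, ** < 0.01.
    """
    condition = list(condition)
    if len(condition) != len(props):
        raise DataError("compare_proportions: condition length mismatch")
    mask_d = np.array([c == "disease" for c in condition])
    mask_n = np.array([c == "control" for c in condition])
    if not mask_d.any() or not mask_n.any():
        raise DataError("compare_proportions: both condition groups must be non-empty")
    low_power = mask_d.sum() < 2 or mask_n.sum() < 2
    rows = []
    for ct in props.columns:
        x = props[ct].to_numpy()
        d, n = x[mask_d], x[mask_n]
        stat, p = stats.ranksums(d, n)
        direction = "up" if np.median(d) > np.median(n) else ("down" if np.median(d) < np.median(n) else "none")
        rows.append({"cell_type": ct, "statistic": float(stat), "p": float(p), "direction": direction})
    table = pd.DataFrame(rows)
    table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    table["stars"] = ["**" if q < 0.01 else ("*" if q < 0.05 else "") for q in table["adj_p"]]
    table["low_power"] = low_power
    if low_power:
        logger.warning("compare_proportions: a condition group has < 2 samples; low power")
    return table
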