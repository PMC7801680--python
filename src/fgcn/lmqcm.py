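"""Local-maximum Quasi-Clique Merger (lmQCM) module mining.

Seeds are locally weight-maximal edges above gamma; each seed grows greedily
while the subgraph density stays above an adaptive threshold
``gamma * (1 - 1/(2*lam*(n + t)))``; overlapping raw modules are merged at
overlap ratio >= beta and sets below the minimum size are dropped. The
procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from fgcn.io import DataError, GeneSetCollection, logger
from fgcn.network import FrequencyNetwork


@dataclass
class LmqcmParams:
    t: float = 1.0
    lam: float = 1.0
    gamma: float = 0.81
    beta: float = 0.3
    min_size: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise DataError("gamma must be in (0, 1]")
        if not 0 < self.beta <= 1:
            raise DataError("beta must be in (0, 1]")
        if self.min_size < 2:
            raise DataError("min_size must be >= 2")
        if self.lam <= 0:
            raise DataError("lam must be > 0")
        if self.t < 0:
            raise DataError("t must be >= 0")

    def density_threshold(self, n: int) -> float:
        """Adaptive density threshold for a current module of size n."""
        return self.gamma * (1.0 - 1.0 / (2.0 * self.lam * (n + self.t)))


@dataclass
class GeneModule:
    """A mined co-expressed gene set with provenance."""

    module_id: str
    members: list[str]
    seed: Optional[tuple[str, str]] = None
    condition: Optional[str] = None  # network the module was mined from
    params: Optional[LmqcmParams] = None

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise DataError(f"{self.module_id}: duplicate members")
        if self.seed is not None and not set(self.seed) <= set(self.members):
            raise DataError(f"{self.module_id}: seed not contained in members")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> set[str]:
        return set(self.members)


@dataclass
class GeneModuleCollection:
    modules: list[GeneModule] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> GeneModule:
        for mod in self.modules:
            if mod.module_id == module_id:
                return mod
        raise KeyError(module_id)

    @property
    def ids(self) -> list[str]:
        return [m.module_id for m in self.modules]

    def to_gene_sets(self) -> GeneSetCollection:
        sets = []
        for mod in self.modules:
            seed = ",".join(mod.seed) if mod.seed else ""
            p = mod.params
            params = (
                f"t={p.t};lam={p.lam};gamma={p.gamma};beta={p.beta};min_size={p.min_size}"
                if p else ""
            )
            desc = f"condition={mod.condition or ''};seed={seed};{params}"
            sets.append((mod.module_id, desc, list(mod.members)))
        return GeneSetCollection(sets=sets)


def find_seed_edges(net: FrequencyNetwork, gamma: float) -> list[tuple[str, str, float]]:
    """Edges with weight >= gamma that are local weight maxima.

    An edge is a local maximum when no edge sharing an endpoint has strictly
    larger weight. Sorted by weight descending, then pair lexicographically.
    """
    max_at_node: dict[str, float] = {}
    for (a, b), w in net.edges.items():
        max_at_node[a] = max(max_at_node.get(a, 0.0), w)
        max_at_node[b] = max(max_at_node.get(b, 0.0), w)
    seeds = [
        (a, b, w)
        for (a, b), w in net.edges.items()
        if w >= gamma and w >= max_at_node[a] and w >= max_at_node[b]
    ]
    seeds.sort(key=lambda e: (-e[2], e[0], e[1]))
    return seeds


def _build_adjacency(net: FrequencyNetwork) -> dict[str, dict[str, float]]:
    adjacency: dict[str, dict[str, float]] = {}
    for (u, v), w in net.edges.items():
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w
    return adjacency


def expand_module(
    net: FrequencyNetwork,
    seed: tuple[str, str],
    params: LmqcmParams,
    _adjacency: Optional[dict[str, dict[str, float]]] = None,
) -> set[str]:
    """Greedy densest growth from a seed edge under the adaptive threshold.

    At each step the outside vertex with the largest total weight into the
    current set is the candidate (ties broken lexicographically); it is
    admitted only if the resulting density stays >= gamma * alpha(|U|).
    """
    a, b = seed
    pair = (a, b) if a < b else (b, a)
    if pair not in net.edges:
        raise DataError(f"seed {seed} is not an edge of the network")

    adjacency = _adjacency if _adjacency is not None else _build_adjacency(net)

    members: set[str] = {a, b}
    total_weight = net.edges[pair]
    # weight of each outside vertex into the current member set
    gain: dict[str, float] = {}
    for u in (a, b):
        for v, w in adjacency[u].items():
            if v not in members:
                gain[v] = gain.get(v, 0.0) + w

    while gain:
        candidate = min(gain, key=lambda v: (-gain[v], v))
        n_new = len(members) + 1
        new_weight = total_weight + gain[candidate]
        density = 2.0 * new_weight / (n_new * (n_new - 1))
        if density < params.density_threshold(len(members)):
            break
        members.add(candidate)
        total_weight = new_weight
        del gain[candidate]
        for v, w in adjacency.get(candidate, {}).items():
            if v not in members:
                gain[v] = gain.get(v, 0.0) + w
    return members


def merge_modules(
    raw: list[set[str]],
    beta: float,
    min_size: int,
    prefix: str = "M",
    condition: Optional[str] = None,
    params: Optional[LmqcmParams] = None,
    seeds: Optional[list[tuple[str, str]]] = None,
) -> GeneModuleCollection:
    """Merge overlapping raw sets (|A∩B| / min(|A|,|B|) >= beta) to fixed point,
    drop sets below min_size, and id survivors by descending size."""
    sets = [set(s) for s in raw]
    seed_of: list[Optional[tuple[str, str]]] = list(seeds) if seeds else [None] * len(sets)
    changed = True
    while changed:
        changed = False
        for i in range(len(sets)):
            if sets[i] is None:
                continue
            for j in range(i + 1, len(sets)):
                if sets[j] is None:
                    continue
                inter = len(sets[i] & sets[j])
                if inter == 0:
                    continue
                if inter / min(len(sets[i]), len(sets[j])) >= beta:
                    sets[i] |= sets[j]
                    sets[j] = None
                    changed = True
    merged = [
        (s, seed_of[i]) for i, s in enumerate(sets) if s is not None and len(s) >= min_size
    ]
    # descending size, then lexicographic smallest member for determinism
    merged.sort(key=lambda item: (-len(item[0]), sorted(item[0])))
    modules = [
        GeneModule(
            module_id=f"{prefix}{k + 1}",
            members=sorted(s),
            seed=seed,
            condition=condition,
            params=params,
        )
        for k, (s, seed) in enumerate(merged)
    ]
    return GeneModuleCollection(modules=modules)


def mine_modules(
    net: FrequencyNetwork,
    params: Optional[LmqcmParams] = None,
    prefix: str = "M",
    condition: Optional[str] = None,
) -> GeneModuleCollection:
    """Full lmQCM: seeds -> greedy expansion -> overlap merge.

    A seed edge already fully contained in a previously grown module is
    skipped. Deterministic for identical input.
    """
    params = params or LmqcmParams()
    seeds = find_seed_edges(net, params.gamma)
    adjacency = _build_adjacency(net)
    raw: list[set[str]] = []
    raw_seeds: list[tuple[str, str]] = []
    for a, b, _w in seeds:
        if any(a in grown and b in grown for grown in raw):
            continue
        grown = expand_module(net, (a, b), params, _adjacency=adjacency)
        raw.append(grown)
        raw_seeds.append((a, b))
    collection = merge_modules(
        raw, params.beta, params.min_size,
        prefix=prefix, condition=condition, params=params, seeds=raw_seeds,
    )
    logger.info(
        "mine_modules[%s]: %d seeds -> %d raw -> %d modules",
        prefix, len(seeds), len(raw), len(collection),
    )
    return collection
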