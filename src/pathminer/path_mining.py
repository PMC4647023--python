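"""Mine shortest paths between every seed pair and score genes by betweenness.

For a seed set S mapped onto the network, one minimum-weight path is kept per
unordered seed pair (the canonical pair orientation is lexicographic, and ties
among co-optimal paths resolve to the lexicographically smallest node
sequence, so mining is deterministic).  Every non-seed gene appearing on at
least one of these paths is a *shortest path gene*; its *betweenness* is the
number of seed-pair paths whose node sequence contains it.  This is a
seed-restricted statistic, not classical all-pairs betweenness centrality.

Betweenness counts are kept for all on-path nodes, seeds included, so a seed
acting as an intermediate on another pair's path is counted consistently;
reporting of candidates then restricts to non-seed genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .network_core import PPINetwork, SeedPairPath, TieBreak, _greedy_walk, _materialise
from .string_io import SeedSet

log = logging.getLogger(__name__)


@dataclass
class MiningResult:
    """Paths, per-gene betweenness and the shortest-path gene set for one run."""

    paths: list[SeedPairPath]
    betweenness: dict[str, int]
    shortest_path_genes: set[str]
    seeds_used: tuple[str, ...] = ()
    dropped_seeds: tuple[str, ...] = ()
    skipped_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def involved_genes(self) -> set[str]:
        """All distinct IDs appearing on any mined path, seeds included."""
        out: set[str] = set()
        for p in self.paths:
            out.update(p.nodes)
        return out


def compute_betweenness(paths: list[SeedPairPath]) -> dict[str, int]:
    """Count, for every node on any path, the number of paths containing it.

    Paths are simple, so a gene contributes at most once per path.  Endpoint
    nodes are counted.  Nodes on no path are absent from the map.
    """
    counter: Counter[str] = Counter()
    for p in paths:
        counter.update(p.nodes)
    return dict(counter)


def extract_shortest_path_genes(
    paths: list[SeedPairPath], seeds: SeedSet
) -> set[str]:
    """Union of all path nodes minus the seed set."""
    genes: set[str] = set()
    for p in paths:
        genes.update(p.nodes)
    return genes - set(seeds.members)


def mine_seed_paths(
    network: PPINetwork,
    seeds: SeedSet,
    tie_break: TieBreak = "lexicographic",
    strict_connectivity: bool = False,
) -> MiningResult:
    """Mine one shortest path per unordered, mutually reachable seed pair.

    Seeds absent from the network are dropped with a warning and recorded on
    the result; fewer than two mappable seeds is an error.  Unreachable pairs
    are skipped (and recorded) by default; with ``strict_connectivity=True``
    they raise instead.
    """
    present = sorted(s for s in seeds.members if s in network)
    dropped = tuple(sorted(set(seeds.members) - set(present)))
    if dropped:
        log.warning(
            "%d seed(s) not in network, dropped: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if len(present) < 2:
        raise ValueError(
            f"need at least 2 seeds mapped to the network, have {len(present)}"
        )

    if tie_break == "first-found":
        paths = _mine_first_found(network, present, strict_connectivity)
    else:
        paths = _mine_lexicographic(network, present, strict_connectivity)

    mined, skipped = paths
    bet = compute_betweenness(mined)
    spg = extract_shortest_path_genes(mined, seeds)
    return MiningResult(
        paths=mined,
        betweenness=bet,
        shortest_path_genes=spg,
        seeds_used=tuple(present),
        dropped_seeds=dropped,
        skipped_pairs=tuple(skipped),
    )


def result_from_paths(
    paths: list[SeedPairPath], seeds: SeedSet
) -> MiningResult:
    """Rebuild a :class:`MiningResult` from previously mined paths.

    Lets the permutation stage resume from a saved ``paths.tsv`` without
    re-mining the observed seed set.
    """
    endpoints = {p.source for p in paths} | {p.target for p in paths}
    return MiningResult(
        paths=list(paths),
        betweenness=compute_betweenness(paths),
        shortest_path_genes=extract_shortest_path_genes(paths, seeds),
        seeds_used=tuple(sorted(endpoints & set(seeds.members))),
    )


def _mine_lexicographic(
    network: PPINetwork, present: list[str], strict: bool
) -> tuple[list[SeedPairPath], list[tuple[str, str]]]:
    _, index, csr = network.csr()
    dist = network.distances_from(present)  # (n_seeds, n_nodes)
    seed_idx = [index[s] for s in present]
    mined: list[SeedPairPath] = []
    skipped: list[tuple[str, str]] = []
    # Pairs oriented lexicographically: walk from the smaller seed using the
    # distance field of the larger (the walk needs distances *to* the target).
    for ia, ib in combinations(range(len(present)), 2):
        a, b = present[ia], present[ib]
        d_b = dist[ib]
        if not np.isfinite(d_b[seed_idx[ia]]):
            if strict:
                raise RuntimeError(f"seed pair ({a}, {b}) is disconnected")
            skipped.append((a, b))
            continue
        walk = _greedy_walk(seed_idx[ia], seed_idx[ib], d_b, csr)
        mined.append(_materialise(network, walk, int(d_b[seed_idx[ia]])))
    if skipped:
        log.warning("skipped %d unreachable seed pair(s)", len(skipped))
    return mined, skipped


def _mine_first_found(
    network: PPINetwork, present: list[str], strict: bool
) -> tuple[list[SeedPairPath], list[tuple[str, str]]]:
    from .network_core import shortest_path

    mined: list[SeedPairPath] = []
    skipped: list[tuple[str, str]] = []
    for a, b in combinations(present, 2):
        p = shortest_path(network, a, b, tie_break="first-found")
        if p is None:
            if strict:
                raise RuntimeError(f"seed pair ({a}, {b}) is disconnected")
            skipped.append((a, b))
        else:
            mined.append(p)
    return mined, skipped
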