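"""Permutation null for betweenness and the per-gene permutation FDR filter.

Hub proteins collect high betweenness for *any* seed set, related to the
disease or not.  To separate disease-specific connectors from generic hubs,
the observed seed set is compared against random gene sets of the same size:
mining is re-run on each random set, and a gene's permutation FDR is the
fraction of rounds in which its betweenness under the random set *strictly*
exceeds its observed betweenness (ties do not count against the gene).
Genes with FDR >= threshold (default 0.05, boundary excluded) are discarded;
the survivors are the candidate genes.

The FDR here is a raw permutation exceedance fraction with resolution
1/n_rounds — no analytic multiple-testing correction is applied, and the null
samples nodes uniformly (not degree-preserving).
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .network_core import PPINetwork, TieBreak, _greedy_walk
from .path_mining import MiningResult, mine_seed_paths
from .string_io import SeedSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneScore:
    """Observed betweenness, null exceedance count and permutation FDR of a gene."""

    gene: str
    observed_betweenness: int
    exceed_count: int
    permutation_fdr: float
    is_candidate: bool
    n_rounds: int = 0


@dataclass(frozen=True)
class PermutationConfig:
    """Null-model settings: 1,000 rounds and a 0.05 cutoff by default."""

    set_size: int
    n_rounds: int = 1000
    threshold: float = 0.05
    rng_seed: int = 0
    universe: str = "all"  # "all" or "non-seed"

    def __post_init__(self) -> None:
        if self.n_rounds <= 0:
            raise ValueError("n_rounds must be positive")
        if self.set_size <= 0:
            raise ValueError("set_size must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.universe not in ("all", "non-seed"):
            raise ValueError(f"unknown sampling universe {self.universe!r}")


def sample_random_sets(
    network: PPINetwork,
    config: PermutationConfig,
    seeds: SeedSet | None = None,
) -> list[SeedSet]:
    """Draw ``n_rounds`` uniform random node sets of size ``set_size``.

    Sampling is without replacement within a set and independent across
    rounds; each round uses its own RNG stream spawned from ``rng_seed``, so
    the sequence is reproducible and independent of execution order.  The
    default universe is every network node (real seeds are *not* excluded);
    ``universe="non-seed"`` removes the observed seeds from the pool.
    """
    universe = np.array(network.nodes())
    if config.universe == "non-seed":
        if seeds is None:
            raise ValueError('universe="non-seed" requires the seed set')
        universe = np.array([n for n in universe if n not in seeds.members])
    if config.set_size > universe.size:
        raise ValueError(
            f"set_size {config.set_size} exceeds universe of {universe.size} nodes"
        )
    streams = np.random.SeedSequence(config.rng_seed).spawn(config.n_rounds)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        members = rng.choice(universe, size=config.set_size, replace=False)
        out.append(SeedSet(frozenset(members.tolist()), label=f"perm{i:04d}"))
    return out


def _round_betweenness_idx(network: PPINetwork, members: Iterable[str]) -> Counter:
    """Per-node path-membership counts for one round, as node indices.

    Index-level twin of mining + betweenness counting: one lexicographically
    tie-broken shortest path per unordered member pair, unreachable pairs
    skipped, every on-path node counted once per path.
    """
    _, index, csr = network.csr()
    midx = sorted(index[m] for m in members)
    dist = _sp_dijkstra(csr, directed=False, indices=midx)
    counter: Counter = Counter()
    for a_pos, b_pos in combinations(range(len(midx)), 2):
        d_b = dist[b_pos]
        if not np.isfinite(d_b[midx[a_pos]]):
            continue
        walk = _greedy_walk(midx[a_pos], midx[b_pos], d_b, csr)
        counter.update(walk)
    return counter


def scores_from_null(
    observed: Mapping[str, int],
    null_rounds: Sequence[Mapping[str, int]],
    threshold: float = 0.05,
) -> list[GeneScore]:
    """Turn an observed betweenness map and stored per-round null maps into scores.

    ``permutation_fdr = exceed_count / n_rounds`` where ``exceed_count`` is the
    number of rounds whose betweenness for the gene (0 if absent) is strictly
    greater than the observed value.  A gene is a candidate iff its FDR is
    strictly below ``threshold``.
    """
    n_rounds = len(null_rounds)
    if n_rounds == 0:
        raise ValueError("need at least one null round")
    scores = []
    for gene in sorted(observed):
        obs = observed[gene]
        exceed = sum(1 for rnd in null_rounds if rnd.get(gene, 0) > obs)
        fdr = exceed / n_rounds
        scores.append(
            GeneScore(
                gene=gene,
                observed_betweenness=obs,
                exceed_count=exceed,
                permutation_fdr=fdr,
                is_candidate=fdr < threshold,
                n_rounds=n_rounds,
            )
        )
    return scores


def permutation_fdr(
    network: PPINetwork,
    observed: MiningResult,
    random_sets: Sequence[SeedSet],
    tie_break: TieBreak = "lexicographic",
    threshold: float = 0.05,
    n_workers: int = 1,
    null_archive: str | None = None,
) -> list[GeneScore]:
    """Score every observed shortest-path gene against the permutation null.

    Mining is re-run on each random set with the same network and tie-break
    policy; rounds are combined in round order, so the result is independent
    of ``n_workers``.  ``null_archive`` (optionally ``.gz``) writes the full
    per-round per-gene betweenness matrix for audit.
    """
    if not random_sets:
        raise ValueError("need at least one random set (n_rounds >= 1)")
    genes = sorted(observed.shortest_path_genes)
    obs_map = {g: observed.betweenness.get(g, 0) for g in genes}

    if tie_break == "lexicographic":
        nodes, index, _ = network.csr()
        gene_idx = {g: index[g] for g in genes}

        def one_round(members: frozenset) -> Counter:
            return _round_betweenness_idx(network, members)

        if n_workers > 1:
            counters = Parallel(n_jobs=n_workers, prefer="threads")(
                delayed(one_round)(s.members) for s in random_sets
            )
        else:
            counters = [one_round(s.members) for s in random_sets]
        null_rounds = [
            {g: c.get(gene_idx[g], 0) for g in genes} for c in counters
        ]
    else:
        def one_round_named(s: SeedSet) -> dict[str, int]:
            res = mine_seed_paths(network, s, tie_break=tie_break)
            return {g: res.betweenness.get(g, 0) for g in genes}

        if n_workers > 1:
            null_rounds = Parallel(n_jobs=n_workers, prefer="threads")(
                delayed(one_round_named)(s) for s in random_sets
            )
        else:
            null_rounds = [one_round_named(s) for s in random_sets]

    if null_archive is not None:
        _write_null_archive(null_archive, genes, null_rounds)
    return scores_from_null(obs_map, null_rounds, threshold=threshold)


def _write_null_archive(
    path: str, genes: Sequence[str], null_rounds: Sequence[Mapping[str, int]]
) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write("round\t" + "\t".join(genes) + "\n")
        for i, rnd in enumerate(null_rounds):
            fh.write(
                f"{i}\t" + "\t".join(str(rnd.get(g, 0)) for g in genes) + "\n"
            )


def filter_candidates(
    scores: Iterable[GeneScore], threshold: float = 0.05
) -> list[GeneScore]:
    """Keep genes with permutation FDR strictly below the threshold.

    The boundary is excluded: a gene at exactly the threshold is discarded.
    Output is sorted by descending betweenness, then gene ID.
    """
    kept = [
        GeneScore(
            gene=s.gene,
            observed_betweenness=s.observed_betweenness,
            exceed_count=s.exceed_count,
            permutation_fdr=s.permutation_fdr,
            is_candidate=True,
            n_rounds=s.n_rounds,
        )
        for s in scores
        if s.permutation_fdr < threshold
    ]
    kept.sort(key=lambda s: (-s.observed_betweenness, s.gene))
    return kept


def format_fdr(score: GeneScore) -> str:
    """Human-readable FDR: zero exceedances print as '<1/n_rounds'."""
    if score.exceed_count == 0 and score.n_rounds > 0:
        return f"<{1 / score.n_rounds:g}"
    return f"{score.permutation_fdr:g}"
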