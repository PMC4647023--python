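"""Reproducible synthetic PPI networks with planted connector structure.

The generator builds test networks where the ground truth is known by
construction: a random background graph (Erdős–Rényi edges with confidence
scores drawn uniformly from a bounded range), a designated seed set, and
*planted connectors* — non-seed nodes wired to seeds through maximal-score
"bridge" edges.  Because bridge edges get weight ``1000 - bridge_score`` (1 at
the default score of 999) while background edges are capped at a lower score,
seed-pair shortest paths are forced through the connectors, which therefore
must be recovered by the mining + permutation pipeline.

Wiring scheme: a single connector bridges every seed, so all C(n_seeds, 2)
paths run through it.  With k >= 2 connectors, one seed is set aside as a
shared anchor and the remaining seeds are partitioned into k groups; connector
j bridges its group plus the anchor.  Within-group pairs route through their
own connector, cross-group pairs route connector -> anchor -> connector, and
every optimal route is unique — co-optimal ties between connectors (which the
deterministic tie-break would always resolve toward the same one) cannot
arise.  Connectors receive *only* bridge edges: they take part in no
background edges and no scaffold, so under a random gene set they attract
essentially no traffic and their planted signal is specific to the seed set
rather than a generic-hub artefact.

A low-score spanning chain over all nodes guarantees connectivity without
ever contaminating optimal paths (its weight-850 edges are dominated).

The generator does not attempt to match the degree distribution or score
calibration of a real interactome; it exists to make ground truth exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .network_core import PPINetwork, build_network
from .string_io import SCORE_MAX, SCORE_MIN, ScoredInteraction, SeedSet

SCAFFOLD_SCORE = SCORE_MIN  # weight 850: connects, never wins a shortest path


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network instance.

    Defaults are the strong-signal configuration used throughout the test
    suite: 500 background nodes, 20 seeds, 3 planted connectors, sparse
    background (p = 0.02) with scores uniform on [150, 900], and bridges at
    score 999 so planted routes are strictly optimal.
    """

    n_background_nodes: int = 500
    n_seeds: int = 20
    n_planted_connectors: int = 3
    background_edge_prob: float = 0.02
    score_low: int = SCORE_MIN
    score_high: int = 900
    bridge_score: int = 999
    seed_clique_score: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 2:
            raise ValueError("need at least 2 seeds")
        if self.n_background_nodes < 0 or self.n_planted_connectors < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.background_edge_prob <= 1.0):
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if not (SCORE_MIN <= self.bridge_score <= SCORE_MAX):
            raise ValueError(
                f"bridge_score must lie in [{SCORE_MIN}, {SCORE_MAX}]"
            )
        if not (SCORE_MIN <= self.score_low <= self.score_high <= SCORE_MAX):
            raise ValueError("score range must satisfy 150 <= low <= high <= 999")
        if self.n_planted_connectors >= 2:
            # each connector needs a group of >= 2 non-anchor seeds
            if self.n_seeds - 1 < 2 * self.n_planted_connectors:
                raise ValueError(
                    f"{self.n_planted_connectors} connectors need at least "
                    f"{2 * self.n_planted_connectors + 1} seeds"
                )


def _node_names(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    seeds = [f"SEED{i:03d}" for i in range(spec.n_seeds)]
    planted = [f"LINK{i:02d}" for i in range(spec.n_planted_connectors)]
    background = [f"BG{i:04d}" for i in range(spec.n_background_nodes)]
    return seeds, planted, background


def generate_network(
    spec: SyntheticSpec,
) -> tuple[PPINetwork, SeedSet, set[str]]:
    """Build one synthetic instance: (network, seed set, planted connectors).

    Fully reproducible from ``spec.rng_seed``; the same spec always yields an
    identical network.  All seeds are guaranteed mutually reachable via the
    scaffold chain.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seeds, planted, background = _node_names(spec)
    # Background edges and the scaffold cover seeds + background only; planted
    # connectors touch the network exclusively through their bridges, so they
    # carry no generic through-traffic and their betweenness under a *random*
    # gene set stays near zero — planted signal is disease-set-specific, not
    # a hub artefact the permutation filter would (correctly) remove.
    bg_nodes = sorted(seeds + background)
    if len(bg_nodes) < 2:
        raise ValueError("network needs at least two non-connector nodes")

    best: dict[tuple[str, str], int] = {}

    def add(a: str, b: str, score: int) -> None:
        key = (a, b) if a < b else (b, a)
        if best.get(key, 0) < score:
            best[key] = score

    # spanning chain at the minimum score: connectivity without optimality
    for a, b in zip(bg_nodes, bg_nodes[1:]):
        add(a, b, SCAFFOLD_SCORE)

    # Erdős–Rényi background
    n = len(bg_nodes)
    if spec.background_edge_prob > 0:
        mask = rng.random((n, n)) < spec.background_edge_prob
        upper = np.triu(mask, k=1)
        ii, jj = np.nonzero(upper)
        bg_scores = rng.integers(
            spec.score_low, spec.score_high, size=ii.size, endpoint=True
        )
        for i, j, s in zip(ii, jj, bg_scores):
            add(bg_nodes[i], bg_nodes[j], int(s))

    # optional direct seed clique (makes every seed pair directly adjacent)
    if spec.seed_clique_score is not None:
        for i in range(len(seeds)):
            for j in range(i + 1, len(seeds)):
                add(seeds[i], seeds[j], spec.seed_clique_score)

    # planted bridges
    if spec.n_planted_connectors == 1:
        for s in seeds:
            add(planted[0], s, spec.bridge_score)
    elif spec.n_planted_connectors >= 2:
        anchor, rest = seeds[0], seeds[1:]
        groups = np.array_split(np.array(rest), spec.n_planted_connectors)
        for conn, group in zip(planted, groups):
            add(conn, anchor, spec.bridge_score)
            for s in group:
                add(conn, str(s), spec.bridge_score)

    interactions = [
        ScoredInteraction(a, b, s) for (a, b), s in sorted(best.items())
    ]
    network = build_network(interactions)
    return network, SeedSet(frozenset(seeds), label="synthetic-seeds"), set(planted)


def connector_groups(spec: SyntheticSpec) -> dict[str, list[str]]:
    """The seed group each planted connector bridges (anchor excluded)."""
    seeds, planted, _ = _node_names(spec)
    if spec.n_planted_connectors == 0:
        return {}
    if spec.n_planted_connectors == 1:
        return {planted[0]: list(seeds)}
    groups = np.array_split(np.array(seeds[1:]), spec.n_planted_connectors)
    return {c: [str(s) for s in g] for c, g in zip(planted, groups)}


def write_fixture(
    spec: SyntheticSpec,
    out_dir: str | Path,
    species_prefix: str = "9606.",
) -> dict[str, Path]:
    """Write a synthetic instance in the same formats the readers consume.

    Emits ``protein.links.txt`` (STRING-style, both edge directions, species
    prefix attached), ``seeds.txt`` (one ID per line) and
    ``ground_truth.json`` (seeds, planted connectors, spec echo).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network, seed_set, planted = generate_network(spec)

    links = out_dir / "protein.links.txt"
    with open(links, "w", encoding="utf-8") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, data in sorted(
            (min(a, b), max(a, b), d) for a, b, d in network.graph.edges(data=True)
        ):
            s = data["score"]
            fh.write(f"{species_prefix}{u} {species_prefix}{v} {s}\n")
            fh.write(f"{species_prefix}{v} {species_prefix}{u} {s}\n")

    seeds_path = out_dir / "seeds.txt"
    seeds_path.write_text(
        "\n".join(sorted(seed_set.members)) + "\n", encoding="utf-8"
    )

    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seeds": sorted(seed_set.members),
                "planted_connectors": sorted(planted),
                "spec": asdict(spec),
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return {"links": links, "seeds": seeds_path, "ground_truth": truth_path}
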