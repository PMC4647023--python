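"""Readers and writers for STRING-style edge lists, seed-gene lists and result tables.

The interaction format is the STRING ``protein.links`` dump: whitespace-separated
``protein1 protein2 combined_score`` records with species-prefixed Ensembl
protein IDs (e.g. ``9606.ENSP00000216797``) and an integer combined score in
[150, 999].  Files may be plain text or gzip-compressed and may carry a single
header line.  STRING lists every interaction in both directions; parsing merges
the two directed records into one undirected interaction, keeping the maximum
score.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

SCORE_MIN = 150
SCORE_MAX = 999

PATHS_COLUMNS = ["source", "target", "total_weight", "node_sequence"]
EDGES_COLUMNS = ["protein_a", "protein_b", "score", "weight"]
GENES_COLUMNS = ["gene", "betweenness", "permutation_fdr"]
CANDIDATE_COLUMNS = [
    "row_number",
    "protein_id",
    "gene_symbol",
    "betweenness",
    "permutation_fdr",
]


class StringParseError(ValueError):
    """Raised for malformed edge-list input in strict mode or fatal conditions."""


@dataclass(frozen=True, order=True)
class ScoredInteraction:
    """One undirected protein pair with an integer STRING combined score.

    ``protein_a`` and ``protein_b`` are stored in lexicographic order so that
    the directed records (a, b) and (b, a) compare and hash identically.
    """

    protein_a: str
    protein_b: str
    score: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise StringParseError(
                f"self-interaction not allowed: {self.protein_a}"
            )
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)
        if not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise StringParseError(
                f"score {self.score} for ({self.protein_a}, {self.protein_b}) "
                f"outside [{SCORE_MIN}, {SCORE_MAX}]"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class SeedSet:
    """A duplicate-free set of seed (disease) protein IDs."""

    members: frozenset[str]
    label: str = "seeds"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"seed set {self.label!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: object) -> bool:
        return item in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


@dataclass
class ParseResult:
    """Outcome of parsing a ``protein.links`` stream.

    ``n_directed_records`` counts species-matching records before undirected
    deduplication (the granularity at which STRING reports its interaction
    counts); ``interactions`` holds the deduplicated undirected set.
    """

    interactions: list[ScoredInteraction] = field(default_factory=list)
    n_directed_records: int = 0
    n_malformed: int = 0
    n_self_loops: int = 0
    n_species_filtered: int = 0
    header_skipped: bool = False

    @property
    def n_undirected(self) -> int:
        return len(self.interactions)


def _open_text(source: str | os.PathLike | IO, allow_gzip: bool) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if allow_gzip and path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) != 3:
        return True
    try:
        int(fields[2])
    except ValueError:
        return True
    return False


def parse_string_links(
    source: str | os.PathLike | IO,
    species_prefix: str = "9606.",
    allow_gzip: bool = True,
    strip_prefix: bool = True,
    strict: bool = False,
) -> ParseResult:
    """Parse a STRING ``protein.links`` edge list into undirected interactions.

    Only records where *both* protein columns start with ``species_prefix`` are
    kept; the prefix is stripped from the returned IDs unless
    ``strip_prefix=False``.  Duplicate unordered pairs (including the mirrored
    directed records STRING emits) are merged keeping the maximum score.  A
    single leading header line is auto-detected and skipped.  Malformed lines
    are skipped and counted by default; with ``strict=True`` they raise
    :class:`StringParseError` naming the line number.
    """
    result = ParseResult()
    best: dict[tuple[str, str], int] = {}
    stream = _open_text(source, allow_gzip)
    try:
        for lineno, line in enumerate(stream, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and _looks_like_header(fields):
                result.header_skipped = True
                continue
            if len(fields) != 3:
                result.n_malformed += 1
                if strict:
                    raise StringParseError(
                        f"line {lineno}: expected 3 fields, got {len(fields)}"
                    )
                continue
            a, b, raw_score = fields
            try:
                score = int(raw_score)
            except ValueError:
                result.n_malformed += 1
                if strict:
                    raise StringParseError(
                        f"line {lineno}: non-integer score {raw_score!r}"
                    )
                continue
            if not (a.startswith(species_prefix) and b.startswith(species_prefix)):
                result.n_species_filtered += 1
                continue
            if strip_prefix:
                a = a[len(species_prefix):]
                b = b[len(species_prefix):]
            if a == b:
                result.n_self_loops += 1
                if strict:
                    raise StringParseError(f"line {lineno}: self-interaction {a}")
                continue
            if not (SCORE_MIN <= score <= SCORE_MAX):
                result.n_malformed += 1
                if strict:
                    raise StringParseError(
                        f"line {lineno}: score {score} outside "
                        f"[{SCORE_MIN}, {SCORE_MAX}]"
                    )
                continue
            result.n_directed_records += 1
            key = (a, b) if a < b else (b, a)
            prev = best.get(key)
            if prev is None or score > prev:
                best[key] = score
    finally:
        if not hasattr(source, "read"):
            stream.close()

    if not best:
        raise StringParseError(
            f"no interactions for species prefix {species_prefix!r}"
        )
    result.interactions = [
        ScoredInteraction(a, b, s) for (a, b), s in sorted(best.items())
    ]
    if result.n_malformed:
        log.warning("skipped %d malformed line(s)", result.n_malformed)
    if result.n_self_loops:
        log.warning("dropped %d self-interaction(s)", result.n_self_loops)
    return result


def read_seed_set(
    path: str | os.PathLike,
    id_column: str | None = None,
    species_prefix: str | None = "9606.",
    label: str | None = None,
) -> SeedSet:
    """Read a seed gene set from a one-ID-per-line file or a TSV column.

    IDs carrying ``species_prefix`` are normalised by stripping it so seeds
    match the network convention.  Duplicates are collapsed with a warning;
    blank lines are ignored; an empty file is an error.
    """
    path = Path(path)
    if id_column is not None:
        frame = pd.read_csv(path, sep="\t")
        if id_column not in frame.columns:
            raise ValueError(
                f"column {id_column!r} not in {path.name} "
                f"(has {list(frame.columns)})"
            )
        raw = [str(v).strip() for v in frame[id_column].dropna()]
    else:
        raw = [
            line.strip()
            for line in path.read_text(encoding="utf-8").splitlines()
        ]
    ids = []
    for token in raw:
        if not token:
            continue
        if species_prefix and token.startswith(species_prefix):
            token = token[len(species_prefix):]
        ids.append(token)
    if not ids:
        raise ValueError(f"seed file {path} contains no IDs")
    if len(set(ids)) < len(ids):
        log.warning(
            "seed file %s: %d duplicate ID(s) collapsed",
            path.name,
            len(ids) - len(set(ids)),
        )
    return SeedSet(frozenset(ids), label=label or path.stem)


def read_symbol_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column protein-ID -> gene-symbol TSV (no header required)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"mapping file {path} needs at least two columns")
    return dict(zip(frame[0].str.strip(), frame[1].str.strip()))


def _paths_frame(paths: Iterable) -> pd.DataFrame:
    rows = [
        {
            "source": p.source,
            "target": p.target,
            "total_weight": p.total_weight,
            "node_sequence": ",".join(p.nodes),
        }
        for p in paths
    ]
    return pd.DataFrame(rows, columns=PATHS_COLUMNS)


def _edges_frame(paths: Iterable, edge_scores: Mapping[tuple[str, str], int] | None) -> pd.DataFrame:
    edges: dict[tuple[str, str], int] = {}
    for p in paths:
        for u, v, w in p.edges():
            key = (u, v) if u < v else (v, u)
            edges[key] = w
    rows = [
        {
            "protein_a": a,
            "protein_b": b,
            "score": 1000 - w,
            "weight": w,
        }
        for (a, b), w in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=EDGES_COLUMNS)


def _genes_frame(scores: Iterable) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "betweenness": s.observed_betweenness,
            "permutation_fdr": s.permutation_fdr,
        }
        for s in scores
    ]
    return pd.DataFrame(rows, columns=GENES_COLUMNS)


def _candidates_frame(
    candidates: Iterable, symbol_map: Mapping[str, str] | None
) -> pd.DataFrame:
    symbol_map = symbol_map or {}
    rows = [
        {
            "row_number": i,
            "protein_id": s.gene,
            "gene_symbol": symbol_map.get(s.gene, ""),
            "betweenness": s.observed_betweenness,
            "permutation_fdr": s.permutation_fdr,
        }
        for i, s in enumerate(candidates, start=1)
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_results(
    paths: Sequence,
    scores: Sequence,
    out_dir: str | os.PathLike,
    symbol_map: Mapping[str, str] | None = None,
    threshold: float = 0.05,
) -> dict[str, Path]:
    """Write the four tabular outputs of a mining run.

    Produces, under ``out_dir``:

    - ``paths.tsv`` — one row per seed-pair shortest path (source, target,
      total weight, comma-joined node sequence);
    - ``edges.tsv`` — the unique weighted edges used by any path;
    - ``genes.tsv`` — per-gene betweenness and permutation FDR;
    - ``candidates.tsv`` — the filtered candidate table (row number, protein
      ID, optional gene symbol, betweenness, FDR).

    All files are UTF-8, tab-delimited, LF-terminated.  Returns the mapping of
    logical name to written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")

    candidates = [s for s in scores if s.is_candidate]
    frames = {
        "paths": _paths_frame(paths),
        "edges": _edges_frame(paths, None),
        "genes": _genes_frame(scores),
        "candidates": _candidates_frame(candidates, symbol_map),
    }
    written: dict[str, Path] = {}
    for name, frame in frames.items():
        target = out_dir / f"{name}.tsv"
        frame.to_csv(target, sep="\t", index=False, lineterminator="\n")
        written[name] = target
    return written


def read_edges_tsv(path: str | os.PathLike) -> list[ScoredInteraction]:
    """Re-read an ``edges.tsv`` written by :func:`write_results`."""
    frame = pd.read_csv(path, sep="\t")
    return [
        ScoredInteraction(row.protein_a, row.protein_b, int(row.score))
        for row in frame.itertuples()
    ]


def read_paths_tsv(path: str | os.PathLike, network=None):
    """Re-read a ``paths.tsv`` written by :func:`write_results`.

    Per-edge weights are not stored in the TSV; pass the ``network`` the paths
    were mined on to re-attach them (needed if the paths are to be written out
    again with an edge table).
    """
    from .network_core import SeedPairPath

    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples():
        nodes = tuple(row.node_sequence.split(","))
        weights = None
        if network is not None:
            weights = tuple(
                network.weight(nodes[i], nodes[i + 1])
                for i in range(len(nodes) - 1)
            )
        out.append(
            SeedPairPath(
                source=row.source,
                target=row.target,
                nodes=nodes,
                total_weight=int(row.total_weight),
                edge_weights=weights,
            )
        )
    return out
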