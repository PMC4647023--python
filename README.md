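# pathminer

Candidate disease-gene mining on protein–protein interaction (PPI) networks
via seed-pair shortest paths and a permutation FDR.

## The problem and who this is for

Given a set *S* of validated disease genes (for example, the genes of a
KEGG disease pathway, as Ensembl protein IDs) and a confidence-scored PPI
network in the STRING `protein.links` format, which *other* genes are tightly
wired between the disease genes and therefore good candidates for follow-up?
`pathminer` is a command-line tool and library for computational biologists
doing this kind of network-based gene prioritization.

## The method

1. **Network.** Each STRING interaction carries an integer combined score
   *Q* ∈ [150, 999] (higher = stronger evidence). Edges get the distance
   weight **w(e) = 1000 − Q**, so w ∈ [1, 850] and minimum-weight paths chain
   together high-confidence interactions. Mirrored directed records are merged
   to undirected edges keeping the maximum score.
2. **Mining.** For every unordered pair of seed genes, one minimum-weight
   (Dijkstra) path is kept — with *n* mutually reachable seeds, exactly
   C(*n*, 2) paths. Ties among co-optimal paths resolve to the
   lexicographically smallest node sequence, so results do not depend on input
   file order. Non-seed genes on any of these paths are the **shortest path
   genes**; each gets a **betweenness** value = the number of seed-pair paths
   containing it (a seed-restricted statistic, *not* Brandes betweenness
   centrality).
3. **Permutation filter.** Hub proteins score high betweenness for *any* gene
   set. The null is built from random node sets of size |S| (default 1,000
   sets): a gene's **permutation FDR** is the fraction of random sets under
   which its recomputed betweenness strictly exceeds its observed value.
   Genes with FDR ≥ 0.05 are discarded; the survivors are the **candidate
   genes**.

## Worked example

No real STRING download is needed to try the tool: the built-in simulator
emits a STRING-style network with *planted connectors* — non-seed nodes wired
between seeds through maximal-score bridge edges, so the ground truth is known.

```sh
pathminer simulate --rng-seed 17 --out fixture/
pathminer run --network fixture/protein.links.txt --seeds fixture/seeds.txt \
    --n-permutations 200 --rng-seed 42 --out results/
```

prints

```
row	protein_id	gene_symbol	betweenness	permutation_fdr
1	LINK00	-	112	<0.005
2	LINK01	-	99	<0.005
3	LINK02	-	99	<0.005
# 190 paths, 3 shortest-path genes, 3 candidates -> results/
```

Reading: the 20 simulated seed genes form C(20, 2) = 190 shortest paths;
exactly the three planted connectors appear on them (`LINK00` on 112 of the
190 paths), and none of the 200 random 20-gene sets ever beat their observed
betweenness, so all three survive the FDR filter — the planted ground truth
(`fixture/ground_truth.json`) is recovered exactly. `results/` also holds
`paths.tsv` (every seed-pair path), `edges.tsv` (the weighted edges those
paths use), `genes.tsv` (per-gene betweenness and FDR), `candidates.tsv`,
`paths_graph.graphml` and a `run_report.json` with input digests and stage
counts for exact reruns.

On a real analysis, point `--network` at a `protein.links.*.txt.gz` dump
(gzip is read directly; `--species 9606.` filters and strips the human
prefix) and `--seeds` at your disease gene list; defaults are 1,000
permutation rounds and the 0.05 cutoff. `pathminer mine` runs only the path
stage; `pathminer permute --mining-dir …` resumes the expensive null from a
saved mining result.

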