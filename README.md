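# rankrobust

How robust are node-metric rankings to the choice of confidence-score
threshold in scored (protein) interaction networks?

Interaction databases attach a confidence score to every edge; networks
are built by discarding edges scoring strictly below a threshold θ.
Node metrics (degree, betweenness, ...) are then used to pick out key
nodes — but the top-ranked set can depend heavily on θ.  `rankrobust`
quantifies that dependence:

* **thresholding** — sweep θ (default 0.15–0.99 at 0.01 steps, 85
  networks), always preserving the full node set;
* **node metrics** — 12 per-node centralities (degree, local
  clustering, redundancy, PageRank, closeness, harmonic, betweenness,
  and five ego-network statistics) plus 13 leave-one-out-difference
  (LOUD) metrics `f(G) − f(G_v)`, where `G_v` isolates node `v` and `f`
  is a global summary (average clustering, natural connectivity, number
  of connected pairs, ...).  LOUD metrics are NA for nodes of degree < 2;
* **ranking** — per (metric, threshold) full rankings with rank N best,
  NA at the bottom, and uniform random tie-breaking from independently
  seeded substreams;
* **robustness** — top-k overlap (`k_similarity`), its asymmetric
  α-relaxed variant, and three measures per metric:
  *rank continuity* (fraction of (consecutive-threshold, k) cells with
  overlap ≥ 0.90 for k = 0.001..0.05), *rank identifiability* (worst
  relaxed overlap of any single-threshold ranking with the
  region-averaged overall ranking; k = 100/N, α = 1.5), and *rank
  instability* (mean scaled rank range of the overall top 1%);
* **synthetic** — scored-network generators: Bernoulli graphs with
  resampled scores, score-shuffled induced subgraphs, and a
  preferential-attachment fixture with a bimodal score distribution.

## CLI

Generate a synthetic scored network, run the whole pipeline, and
re-score saved rankings:

```sh
# a 500-node Bernoulli network with scores resampled from a PIN-like pool
rankrobust simulate --kind bernoulli --n 500 --p 0.06 --seed 1 --out gnp.tsv

# full pipeline: thresholds, 25 metrics, rankings, robustness report
rankrobust run --input gnp.tsv --outdir results/ \
    --lo 15 --hi 99 --step 1 --mu 60 --nu 90 --top-n 20 --seed 1

# re-score the saved ranks under different parameters
rankrobust report --ranks results/ranks.tsv --mu 60 --nu 80 \
    --top-n 20 --seed 1 --out report2.tsv
```

`run` writes four TSVs (`summaries.tsv`, `metrics.tsv`, `ranks.tsv`,
`report.tsv`), each echoing its full parameterization as `#` comments.
Input edge lists are 3-column TSVs (`node_a  node_b  score`); pass
`--dialect string_v10` for integer 0–999 combined scores (divided by
1000 on input).  A YAML config can replace the flags (`--config`);
explicit flags win.  LOUD metrics cost roughly one eigendecomposition
plus a BFS sweep per node per threshold, so `run` refuses networks above
2000 nodes unless `--force` is given.

## Validating against real organism networks (optional)

The desk-scale suite uses only generated data.  To reproduce
organism-level results, download a scored organism network (e.g. a
STRING `protein.links` file or a HitPredict interaction table), reduce
it to three columns, and run:

```sh
rankrobust run --input string_links.tsv --dialect string_v10 \
    --outdir out/ --mu 60 --nu 90 --force
```

For HitPredict-style scores use `--mu 15 --nu 28`.  Expect long run
times for the LOUD metrics on networks with thousands of nodes.

## Conventions worth knowing

* An edge scoring exactly θ is **kept**; thresholds are integers in
  hundredths internally, so the 85-step grid is exact.
* Duplicate edge records keep the **maximum** score.
* `n_two` (step-2 ego size) counts the ego itself, so
  `n_two = 1 + degree + n_diff` and `n_ratio = (degree+1)/n_two`.
* Top-set sizes are `max(1, round(N·k))` and similarities are
  normalized by the realized size, keeping every measure in [0, 1].
* Betweenness is unnormalized, closeness sums reachable distances only;
  affine rescalings would not change any ranking.
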