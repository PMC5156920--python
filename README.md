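# nmflink

Link prediction in undirected simple graphs by **perturbation-ensemble
non-negative matrix factorization**, together with 17 classical
similarity-index baselines and a precision-at-L evaluation harness.

The core idea: split the observed edges into a training set and a held-out
test set, derive R randomly perturbed copies of the training adjacency
(random edge *deletion* to model noise, or random edge *addition* to model
irregular links), factorize every copy with NMF (squared-Frobenius or
generalized-KL cost, multiplicative updates) at a common latent dimension
K, and average the reconstructions W⁽ʳ⁾H⁽ʳ⁾ into a similarity matrix whose
top-ranked unobserved pairs are the predicted links.

## Layout

| module | contents |
|---|---|
| `nmflink.net_core` | `Network` type, edge-list I/O, network statistics (density, degree, path length, closeness, clustering, assortativity, LCP correlation), bundled karate fixture, synthetic generators |
| `nmflink.sampling` | train/test edge splits, deletion/addition perturbation ensembles |
| `nmflink.rank_selection` | latent-dimension selection by linearly-independent column sampling |
| `nmflink.nmf` | multiplicative-update NMF for Frobenius and KL costs |
| `nmflink.predictor` | the six ensemble-NMF variants (NMF1/2, NMF-D1/A1/D2/A2), candidate ranking |
| `nmflink.baselines` | CN, Salton, Jaccard, Sorenson, HPI, HDI, LHN, AA, RA, PA, LP, CRA, Katz, LHNII, ACT, TSCN, SPM |
| `nmflink.evaluation` | precision at L, analytic/Monte-Carlo random baseline, relative precision, repeated-split harness, precision-ranking, statistic–precision correlations |
| `nmflink.benchmark_tables` | bundled published benchmark precision/statistics tables (regression anchors) |
| `nmflink.cli` | `nmflink` command-line entry point |

## CLI

```bash
# network statistics (TSV; 'karate' loads the bundled fixture)
nmflink stats --in karate

# hold out 10% of edges
nmflink split --in graph.edg --test-fraction 0.1 --seed 1 \
    --train-out train.edg --test-out test.edg

# score unobserved pairs ("u v score" TSV, best first)
nmflink predict --train train.edg --method NMF-D2 --eta 0.1 -R 20 \
    --rank 8 --seed 7 --out scores.tsv

# repeated-split evaluation (f = training fraction)
nmflink evaluate --in graph.edg --methods CN,AA,NMF-D2 --f 0.9 \
    --runs 100 --seed 1 --rank 8

# grid of networks x training fractions from a YAML config
nmflink benchmark --config bench.yaml --out-dir results/
```

Every stochastic output embeds its configuration and master seed in `#`
header lines; rerunning the same command with the same seed is
byte-identical.

## Notes on defaults

* Perturbation defaults are eta = 0.1, R = 20 (so a training edge escapes
  all perturbation sets with probability 0.9²⁰ ≈ 0.12).
* `--rank auto` selects K by residual-thresholded column sampling; at the
  default tight tolerance this equals the numerical rank of the training
  adjacency, which is usually too large for good prediction. For the
  predictive use case prefer a small explicit rank (`--rank 4`…`--rank 16`
  works well on the bundled benchmarks).
* Ranking ties are broken by a seeded random permutation by default;
  `--tie-break index` reproduces the deterministic convention that the
  published benchmark precisions follow.

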