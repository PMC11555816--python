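# dnentropy

Dynamic network entropy for short gene-expression time series: segment a
multivariate series into stationary *plateau intervals*, learn a directed
regulatory network on each interval with the K2 score, screen candidate
edges by correlation-based network entropy, rank genes by the entropy drop
their deletion causes, and compare competing networks by simulated
partial-least-squares (PLS) prediction error.

The package targets the setting of small, densely curated regulatory
modules — the motivating case is an 8-gene yeast cell-cycle module (CLN1,
CLN2, CDC28, SWE1, CDC5, CDH1, SWI5, SIC1) observed as a 17-point
microarray time course — where the regulatory structure itself changes
over time and a single static network would over- or under-fit.

## The method

**Plateau segmentation.** For a gene G on an interval [s, t] the
stationarity ratio

```
RB(s,t) = ( Σ_{i∈[s,t]} |G(i) − μ_G(s,t)| / n ) / ( Σ_{i∈[1,T]} |G(i) − μ_G(1,T)| / N )
```

compares in-interval to whole-series mean absolute deviation; small RB
marks a plateau.  Operationally, consecutive base windows are merged while
a two-sample Kolmogorov–Smirnov test finds no gene whose distributions
differ across the boundary (the merge decision is taken at family-wise
level α via a Šidák correction over genes).

**K2 structure learning.** Expression is coded into three states
(below μ−s, within μ±s, above μ+s per gene) and each interval gets its own
directed acyclic network.  A node i with parent set π_i is scored by the
Cooper–Herskovits marginal likelihood

```
score(i, π_i) = Π_j  (r−1)! / (N_ij + r − 1)!  ·  Π_k N_ijk!
```

(log-space in practice), and the classic greedy K2 search adds, per node,
the score-maximizing predecessor in a fixed gene ordering.  The per-interval
networks are unioned into a summary network whose edges are `confirmed`
(present in a supplied literature prior) or `unconfirmed`.

**Entropy screening.** Node entropy is the Shannon entropy of normalized
absolute correlations with network neighbors,

```
H_i = − Σ_j p_ij log p_ij ,   p_ij = |corr(k_i, k_j)| / Σ_m |corr(k_i, k_m)| ,
```

with Pearson correlation when both series pass a normality test and
Spearman otherwise; network entropy is Σ_i H_i (lower = more stable).
Each unconfirmed edge is tried against every combination of the other
unconfirmed edges in its group: a context is a *violation* when adding the
edge raises network entropy by more than a threshold `a`, and the edge is
accepted while its violation count stays below a threshold `b`.

**Sensitivity ranking.** Gene i scores g_i = c − d_i, where c is the total
entropy and d_i the entropy after deleting node i and its incident edges;
larger g marks a more vital node.

**PLS validation.** Each gene is fit as a contemporaneous linear
combination of its parents, x_i(t) = Σ_j β_j x_j(t) (β_j = 0 for
non-parents) by PLS regression; candidate networks are ranked by the mean
relative error when simulated expression vectors are pushed through the
fitted models.

## Worked example

```python
from dnentropy import (SynthConfig, generate, filter_by_missing_rate, impute_missing,
                       normalize, discretize, segment, K2Config, learn_interval_networks,
                       union_network, ScreenConfig, screen_edges, sensitivity_scores,
                       fit_pls, simulate_error)

cfg = SynthConfig(
    n_genes=6, n_timepoints=160, spacing=1.0,
    segment_boundaries=[80.0],
    edges=[{("G1", "G2"): 0.9, ("G3", "G4"): 0.8},
           {("G1", "G3"): 0.9, ("G5", "G6"): 0.8}],
    segment_means=[0.0, 3.0], noise_sd=0.3, missing_rate=0.05, seed=17,
)
expr, truth = generate(cfg)

m = normalize(impute_missing(filter_by_missing_rate(expr, 0.15)))
disc = discretize(m)
seg = segment(m, window=40.0, alpha=0.01)
print("plateau boundaries:", seg.boundaries)

nets = learn_interval_networks(disc, seg, K2Config(list(disc.gene_ids), max_parents=2))
union = union_network(nets, prior=[("G1", "G2"), ("G3", "G4")])
print("union edges:", union.n_edges,
      "confirmed:", len(union.edges_with_status("confirmed")),
      "unconfirmed:", len(union.edges_with_status("unconfirmed")))

screened, report = screen_edges(union, m, ScreenConfig(a=0.3, b=100))
print("accepted unconfirmed edges:", report["n_accepted"])

ranking = sensitivity_scores(screened, m)
print("baseline network entropy:", round(ranking.baseline_entropy, 4))
print("sensitivity ranking:", ranking.ranking[:3])
print("top score g:", round(ranking.scores[ranking.ranking[0]], 4))

model = fit_pls(m, screened)
err = simulate_error(model, screened, n_draws=1000, seed=42, joint=True, expr=m)
print("network relative error:", round(err.network_error, 4))
```

Output:

```
plateau boundaries: [0.0, 80.0, 159.0]
union edges: 4 confirmed: 2 unconfirmed: 2
accepted unconfirmed edges: 2
baseline network entropy: 1.3857
sensitivity ranking: ['G1', 'G3', 'G4']
top score g: 1.3857
network relative error: 2.5232
```

The segmentation recovers the planted change point at t = 80 (the final
boundary is the last observed time, 159).  The K2 union finds the four
planted edges; both unconfirmed edges survive the entropy screen.  G1 —
the hub regulating targets in both segments — is the most sensitive gene:
removing it erases the entire network entropy (g = c = 1.3857 nats).  The
network relative error is the mean of |predicted − drawn| / |drawn| over
simulated draws for genes with parents; it is comparable *between*
networks on the same data (smaller = better), not an absolute goodness of
fit.

The same pipeline is available from the shell:

```
dnentropy preprocess --in expr.tsv --max-missing 0.15 --out disc.tsv --out-continuous cont.tsv
dnentropy segment    --in cont.tsv --window 20 --alpha 0.01 --out seg.json
dnentropy learn      --disc disc.tsv --seg seg.json --max-parents 3 --out net.tsv
dnentropy screen     --net net.tsv --expr cont.tsv --a 0.3 --groups 8:100,9:200 --out screened.tsv
dnentropy rank       --net screened.tsv --expr cont.tsv --out ranking.json
dnentropy validate   --expr cont.tsv --net screened.tsv --draws 1000 --seed 42 --out report.json
dnentropy run-all    --config run.json --outdir results/
```

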