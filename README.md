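# novagene

Condition-specific nonlinear gene co-expression network analysis.

Pooled weighted gene co-expression analysis (WGCNA) builds one network from
all samples and correlates module eigengenes with traits. When the compared
groups lie on a shared pathophysiological continuum — sepsis non-shock vs
shock is the motivating case — their transcriptomes overlap so strongly
that the pooled, linear approach finds nothing. `novagene` instead builds a
**separate weighted network per condition** from **distance correlations**
(which detect nonlinear dependence), enforces a heavy-tailed topology, and
compares the conditions' modules directly through the coordinated activity
of their hub genes.

## Method

For gene profiles $X, Y \in \mathbb{R}^n$ the empirical distance
covariance and distance correlation are

$$V_n^2(X,Y) = \frac{1}{n^2}\sum_{k,l=1}^{n} A_{kl}B_{kl}, \qquad
R_n(X,Y) = \frac{V_n^2(X,Y)}{\sqrt{V_n^2(X)\,V_n^2(Y)}},$$

where $A_{kl}$ and $B_{kl}$ are the double-centered pairwise distance
matrices of $X$ and $Y$. $R_n \in [0,1]$ vanishes only under full
independence, so cubic or other nonlinear co-expression is visible to it.

Per condition, the pipeline is:

1. **Adjacency** $a_{ij} = R_n(x_i, x_j)^\beta$, with the soft-thresholding
   power $\beta$ chosen as the smallest integer in 1..20 whose connectivity
   distribution reaches scale-free fit $R^2 \ge 0.9$.
2. **Power-law pruning**: a continuous power law is fitted to node
   strengths $k_i=\sum_j a_{ij}$ by the Clauset–Shalizi–Newman procedure
   (maximum-likelihood $\hat\alpha$, KS-optimal $x_{\min}$, Vuong
   likelihood-ratio checks against lognormal/exponential/truncated
   alternatives); nodes with strength below $x_{\min}$ are removed.
3. **Modules**: topological overlap (TOM), average-linkage clustering of
   $1-\mathrm{TOM}$, minimum module size 30, colour labels by size.
4. **Hub signatures**: per module, up to 10 hub genes by eigenvector
   centrality of the module's induced subgraph; the first principal
   component of their standardized expression over the pooled samples of
   both conditions is the module's signature.
5. **Comparison**: Pearson correlation between every cross-condition pair
   of hub signatures, two-sided significance at α = 0.05. +1 means matched
   hub activity, −1 a complete inversion.

Pooled baselines (`pearson` or `dcor` mode, module eigengene vs trait) and
a synthetic differential co-expression benchmark with known ground truth
are included; see `docs/methods.md` for the generative model and all
numerical choices.

## Worked example

Simulate a low-variability (hard) dataset and compare the two condition
networks:

```python
from novagene import run_novagene
from novagene.synthetic_benchmark import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(p=0.1, seed=1))
bundle = run_novagene(ds.expr, ds.design, ("healthy", "diseased"))
for c, net in bundle.networks.items():
    st, pl = net.soft_threshold, net.powerlaw
    print(f"{c}: beta={st.beta} fit_R2={st.fit_index:.3f} alpha={pl.alpha:.2f} "
          f"xmin={pl.xmin:.2f} retained={net.n_genes}")
print(bundle.comparison.pearson_r.round(3).to_string())
print("significant pairs:", bundle.comparison.significant_pairs())
```

prints

```
healthy: beta=10 fit_R2=0.912 alpha=1.83 xmin=0.89 retained=179
diseased: beta=7 fit_R2=0.905 alpha=2.90 xmin=12.31 retained=100
           turquoise
turquoise     -0.163
blue           1.000
significant pairs: [('blue', 'turquoise')]
```

Both condition networks reach the scale-free criterion (fit $R^2 > 0.9$ at
β = 10 and 7), pruning keeps 179 and 100 of the 300 genes, and the healthy
network's `blue` module correlates perfectly (+1.000) with the diseased
network's `turquoise` module: the two networks have recovered the same
latent co-expression program from opposite sides of the comparison, which
is exactly the signal a pooled analysis dilutes away at this overlap level
(the pooled Pearson baseline finds no trait-associated module here).

The same analyses are available from the shell:

```sh
novagene simulate --p 0.1 --seed 1 --out data/
novagene run --expr data/expression.tsv --design data/design.tsv \
             --conditions healthy,diseased --out results/run/
novagene baseline --expr data/expression.tsv --design data/design.tsv \
                  --mode pearson --out results/baseline/
novagene benchmark --methods novagene,wgcna_pearson --p 0.1,0.9 \
                   --replicates 20 --seed 1 --out results/bench/
```

Every run writes edge lists, module assignments, hub tables, the module
comparison matrix, and a checksummed manifest plus config echo sufficient
to reproduce it.

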