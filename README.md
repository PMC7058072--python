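# causalnet

Causal network inference for multi-omics genetics. `causalnet` is for
statistical geneticists who want *directed* structure — which variants,
methylation sites, transcripts and phenotypes cause which — rather than
the undirected co-variation networks that association analysis yields.

It implements, as one toolkit:

- **Discrete additive-noise causation tests** for genome-wide causation
  scans: for variant X and disease Y, fit the integer regressions
  `Y = f(X) + N_Y` and `X = g(Y) + N_X`, measure residual–cause dependence
  `Delta` on each side (Fisher exact / chi-square, `-log10 p` scale) and
  test `T_C = |Delta_{X->Y} - Delta_{Y->X}|` by permutation; the more
  independent residual names the causal direction.
- **Functional principal component scores (FPCS)** of a gene's variants:
  genotypes are coded as frequency-centred functions of genomic position
  (`QQ -> 2P_q`, `Qq -> P_q - P_Q`, `qq -> -2P_Q`) and summarized by
  functional PCA, so one score vector represents all rare variants of a
  gene.
- **Sparse structural equation models** estimated by L1-penalized
  two-stage least squares: each endogenous node's equation
  `y_i = W_i Delta_i + e_i` is estimated through the instrument-weighted
  quadratic form `f(Delta_i) = (X'y_i - X'W_i Delta_i)'(X'X)^{-1}(...)`
  with genotypes as instruments, giving the (possibly cyclic) "SEM"
  network of significant path coefficients.
- **SEMIP**, the DAG estimator: decomposable per-node parent-set scores
  `C(v, W) = RSS(y_v | W) + c|W| log n` minimized over all graphs by
  integer linear programming — one indicator per candidate parent set,
  exactly-one constraints per node, and acyclicity via lazily generated
  cluster constraints (cutting planes) solved with HiGHS branch-and-bound.
  A multilevel variant learns one joint genotype → methylation →
  expression → phenotype → disease network with layer-respecting
  candidate sets.
- **Causal path search**: depth-first enumeration of all simple directed
  paths from any node to a disease node, and classification of nodes as
  directly / indirectly / both / not connected to each of two diseases,
  with the 4x4 shared-connectivity cross-tabulation.
- **A simulation benchmark** reproducing the power/FDR study design:
  random layered DAGs, coefficients U(1,2), N(0,1) noise, and edge-wise
  power and false-discovery evaluation of the correlation baseline, SEM
  and SEMIP.

See `docs/methods.md` for the models, estimators and design choices.

## Worked example

Simulate a 20-node study (5 genotype + 15 expression nodes, mean 30
directed edges), learn the network with SEMIP, and score it against the
truth:

```python
import numpy as np
from causalnet import (
    SimulationConfig, random_dag, simulate_dataset,
    learn_semip_network, evaluate_network,
)

rng = np.random.default_rng(1)
config = SimulationConfig(n_nodes=20, n_genotype_nodes=5, target_edges=30,
                          n_samples=1000, random_sign=False)
model = random_dag(config, rng)
data = simulate_dataset(model, 1000, rng)
net = learn_semip_network(data)
pf = evaluate_network(model.dag, net.graph, "directed")
print(f"true edges {pf.n_t}, detected {pf.n_true + pf.n_false}, "
      f"power {pf.power:.3f}, fdr {pf.fdr_conventional:.3f}")
```

```
true edges 24, detected 24, power 0.958, fdr 0.042
```

This draw's graph had 24 true directed edges; the learner reported 24
edges of which 23 were correct (power 0.958, conventional FDR 0.042).
Single replicates vary — averaged over many replicates the 20-node cell
sits near directed power 0.82 with FDR 0.15 at n=1000.

The same steps from a shell:

```bash
causalnet --seed 1 simulate --nodes 20 --genotype-nodes 5 --edges 30 \
    --samples 1000 --out-data data.tsv --out-edges truth.tsv --out-layers layers.tsv
causalnet fit-semip --data data.tsv --layers layers.tsv --out network.tsv
causalnet paths --network network.tsv --source X1 --target Y7 --out paths.tsv
```

Other entry points: `causalnet gwcs` (genome-wide causation scan from
dosage TSV + BED regions + phenotype table), `causalnet fpca` (per-gene
FPCS), `causalnet fit-sem`, `causalnet fit-multilevel`, and
`causalnet classify` (two-disease connectivity cross-tabulation).

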