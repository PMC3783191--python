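# clonedemix

Deconvolve a **single aggregate aberration-frequency vector** (e.g. bulk
variant allele fractions) into subclone genotypes, subclone frequencies,
and the evolutionary tree relating them.

The model: every cell carries a binary genotype over N aberrations (plus a
dummy aberration present in every cell, so the wildtype fraction is part of
the linear system). Subclones arise by single aberration events from
existing subclones and never lose aberrations. Among all explanations of
the measured frequency vector `y = C x`, the solver returns those that are

1. **evolutionary** (tree-structured, one new aberration per subclone),
2. **parsimonious** (exactly N subclones — each aberration arises once),
3. **sparse** (minimum number of populated subclones `P`), and
4. **shallow** (minimum tree depth `D` among the sparsest).

The search identifies *first-generation trees* — an unpopulated parent
whose frequency equals the sum of its direct descendants' frequencies,
under an exact, interval (*bound*) or Gaussian (*normal*) error model —
combines them into maximal *partial trees*, grows every consistent full
tree from those seeds, and fits frequencies by back-substitution (exact)
or constrained nonnegative least squares (noisy input, zeros forced at
unpopulated parents).

Extras:

* **polyallelic loci** (several derived alleles at one position, possibly
  mutated serially, e.g. `170A>G>C`) via exhaustive phasing hypotheses
  reduced to constrained binary problems;
* **user constraints** (forced ancestor order, forced separate branches);
* **frequency clustering** (merge indistinguishable frequencies via
  median / scaled-MAD statistics) to shrink large inputs;
* **multi-sample joint solving**: keep only per-sample solutions that
  embed into one global evolutionary tree;
* a **brute-force oracle** over all `(N-1)!` ordered trees (N ≤ 9) used as
  an independent reference in the test suite;
* a **simulation harness** (random trees, uniform noise, genotype
  mixtures, recovery metrics, benchmark grids).

## CLI

```bash
# deconvolve a frequency table (TSV: id, freq, optional err/sample)
clonedemix solve input.tsv --error-model bound --out results/run1

# with clustering, constraints, sparsity slack
clonedemix solve input.tsv --error-model normal --alpha 0.05 \
    --cluster --constraints constraints.tsv --slack 1

# random-tree recovery benchmark for one (N, P, E) cell
clonedemix simulate --N 8 --P 3 --E 0.01 --runs 1000 --seed 1

# mix subclone genotypes (TSV: rows aberrations, columns subclones)
clonedemix mix genotypes.tsv --weights 0.5,0.3 --seed 1

# joint solving across samples (multi-sample table or several files)
clonedemix joint samples.tsv
clonedemix joint tm1.tsv tm3.tsv tm4.tsv --error-model normal

# brute-force enumeration (N <= 9)
clonedemix oracle input.tsv
```

Exit codes: `0` success, `2` input error, `3` size/solution cap exceeded
(cluster frequencies first or raise the cap).

Constraint file: TSV rows `ancestor<TAB>a<TAB>b` (a must be an ancestor of
b) or `exclusive<TAB>a<TAB>b` (separate branches), using input labels.

## Output formats

`--out PREFIX` writes:

* `PREFIX.json` — machine-readable signal + solutions (parent arrays with
  `null` for the root, frequencies `x`, `P`, `depth`, residual); lossless
  round trip via `clonedemix.io.read_solutions`.
* `PREFIX.dot` — one GraphViz digraph per solution; each node shows the
  newly acquired aberration and its fitted frequency, unpopulated clones
  are dashed.
* `PREFIX.nwk` — one Newick line per solution. Dialect: every node
  (internal included) is named `C<k>` (1-based clone index) followed by a
  bracketed comment `[&label=<aberration>,x=<frequency>]`; stripping
  comments leaves the bare topology, e.g. `((C3)C2)C1;` for a chain.

## Python API

```python
import numpy as np
from clonedemix import build_signal, solve, ErrorModelConfig

signal = build_signal([("a2", 0.72, 0.0), ("a3", 0.40, 0.0),
                       ("a4", 0.28, 0.0), ("a5", 0.25, 0.0),
                       ("a6", 0.15, 0.0)])
result = solve(signal)                       # exact model
best = result.optimal[0]
print(best.tree.parent, best.x, best.P, best.depth)

noisy = solve(signal, ErrorModelConfig("bound"))   # interval error model
```

Key modules: `model` (domain types, tree arithmetic), `preprocess`
(signal building, clustering, read-count statistics, variant filters),
`solver` (the five-step algorithm, NNLS fitting, joint solving),
`oracle` (brute force), `nonbinary` (polyallelic reduction), `simulate`
(generators and metrics), `io` / `cli` (formats and command line).

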