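# ecosig

Phage **ecogenomic signatures** for virome-based **microbial source tracking
(MST)**.

Faecal contamination of environmental waters is traditionally monitored by
culturing faecal indicator bacteria, which is slow and poorly specific to
human sources. An alternative is to read the signal directly out of
sequencing data: a bacteriophage that co-evolved with the human gut
microbiome leaves a habitat-specific pattern — its *ecogenomic signature* —
in the relative abundance of its gene homologues across metagenomes.
`ecosig` implements, as a tested and reusable pipeline, the analysis that
turns such a signature into a pollution detector: per-ORF abundance
profiling of metagenomes, ordination and significance testing of habitat
groups, identification of gut-affiliated ORFs, in silico simulation of
faecal pollution, and a two-step ROC-thresholded classifier that detects
pollution in a viral metagenome and attributes it to a human source. It is
aimed at microbial ecologists and water-quality researchers prototyping
metagenomic MST tools.

## The quantities at the core

**Profiles.** For phage ORF $j$ in metagenome $i$, relative abundance is

$$a_{ij} = \frac{\#\{\text{valid hits to ORF } j\}}{\text{Mb of sequence in data set } i}\quad\text{(hits/Mb)},$$

where a homology-search hit is *valid* iff identity $\ge 35\%$, query
coverage $\ge 50\%$ and e-value $\le 10^{-5}$ (all inclusive). The
cumulative relative abundance over an ORF set $S$ is
$c_i(S)=\sum_{j\in S} a_{ij}$.

**Ordination.** Profiles are square-root transformed and compared by
Bray–Curtis dissimilarity $d(u,v)=\sum_j|u_j-v_j| / \sum_j(u_j+v_j)$,
embedded by non-metric MDS (best Kruskal stress-1 configuration over many
random starts), and group separation is tested by ANOSIM:
$R=(\bar r_B-\bar r_W)/\tfrac{n(n-1)}{4}$ on distance ranks, with a
permutation p-value.

**Pollution simulation.** A contaminated environmental profile is
$\mathrm{env}_j + s\cdot\overline{\mathrm{source}}_j$ per ORF, with strength
$s\in[0,1]$ ($100\% \leftrightarrow 1$). The Monte-Carlo simulation draws
permuted environmental baselines $\mathrm{Uniform}[0,\max_j]$ per ORF and
pollutes fresh baselines at $s\sim\mathrm{Uniform}[0,1]$.

**Classifier.** Step 1 calls a profile *polluted* iff $c_i(S_1)\ge t_1$;
step 2 calls polluted profiles *human* iff $c_i(S_2)\ge t_2$. $S_1$ is the
gut-affiliated detection subset (ORFs 5, 16, 18, 20, 21, 22, 23, 25, 34,
36, 43, 44, 59, 61, 67), $S_2$ the human-specific attribution subset (ORFs
16, 34, 56). Each threshold maximises specificity on a calibration ROC
curve subject to sensitivity $\ge 0.91$.

## Worked example

Calibrate and evaluate the two-step source tracker on a synthetic
habitat-structured cohort:

```python
from ecosig import (CohortSpec, MonteCarloConfig, TwoStepSourceTracker,
                    generate_cohort, run_monte_carlo)

cohort = generate_cohort(CohortSpec(seed=42))
config = MonteCarloConfig.from_cohort(
    cohort, n_iterations=5, n_env_per_iteration=100,
    n_polluted_per_type=100, seed=43,
)
iterations = run_monte_carlo(config)
results = TwoStepSourceTracker(iterations).fit(min_sensitivity=0.91)
print(results.summary())
```

```
Two-step ecogenomic source-tracking model
=========================================================
Iterations: 5 (calibration: #1, evaluation: 4)
Sensitivity floor for threshold selection: 0.91

Step 1 (pollution detection)  subset 'subset1' (15 ORFs)
  AUC = 0.9998   threshold = 2.5894 hits/Mb
Step 2 (human attribution)    subset 'subset2' (3 ORFs)
  AUC = 0.9827   threshold = 2.1861 hits/Mb

Held-out accuracy by true type (mean +/- SEM over iterations):
  ENV_U     1.0000 +/- 0.0000
  ENV_HGV   0.9800 +/- 0.0100
  ENV_BOV   0.9975 +/- 0.0025
  ENV_PORC  0.9950 +/- 0.0029

Pooled step-1 sensitivity = 0.9967, specificity = 1.0000
Pooled step-2 sensitivity = 0.9825, specificity = 1.0000
```

Reading the output: the step-1 ROC (polluted of any type vs uncontaminated
permutations, scored on the detection subset) is nearly perfect, and the
selected threshold of ≈2.6 hits/Mb generalises — 99.7% of truly polluted
held-out data sets are detected while no uncontaminated set is flagged.
Step 2 then attributes detected pollution: 98% of human-polluted sets are
called human, and no bovine/porcine set is mistaken for human.
`ENV_U` are uncontaminated permuted environmental viromes; `ENV_HGV`,
`ENV_BOV`, `ENV_PORC` are the same baselines polluted with the human,
bovine or porcine gut signature at random strengths.

The same stages are scriptable from the shell via the `ecosig` command
(`ecosig profile`, `ecosig ordinate`, `ecosig anosim`, `ecosig contaminate`,
`ecosig montecarlo`, `ecosig roc`, `ecosig classify`, `ecosig affiliate`,
`ecosig synth`); every subcommand has `--help`.

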