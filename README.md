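# mitotempo

Temporal population genetics for mitochondrial genomes: compare haplotype
and nucleotide diversity between *heterochronous* sample groups — museum
specimens collected decades ago versus modern samples — and infer recent
changes in female effective population size with a serial-coalescent
simulator embedded in an approximate Bayesian computation (ABC) framework.

The package was built around the sampling structure typical of studies of
critically endangered taxa such as the eastern gorillas (Grauer's and
mountain gorillas): tens of ~15 kb mitogenomes per group, collection years
spanning a century, strongly unequal group sizes, and missing data in the
historical sequences. Every stage runs on synthetic study-like data
generated by the package itself, so the full pipeline is testable offline.

## What it computes

**Diversity statistics** (per group, with pairwise deletion of missing
data): haplotype count *H*, haplotype (gene) diversity
*H<sub>d</sub> = n/(n−1)·(1−Σp<sub>i</sub>²)*, mean pairwise differences
*k̄*, per-site nucleotide diversity *π*, segregating sites *S*, and
Tajima's *D*. Between temporal groups: Hudson's
*F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub>* and private-haplotype
counts. Minimum spanning haplotype networks (ε = 0, all tied minimum
spanning trees retained) and variant classification (Ts/Tv, genomic
context, synonymous/nonsynonymous/stop-gained under the vertebrate
mitochondrial code, PAM250 scores) round out the descriptive layer.

**Permutation subsampling**: each group is repeatedly subsampled without
replacement to the smallest group's size (default 1000 replicates) before
diversity comparison, removing sample-size confounding; Welch t and
permutation p-values are reported.

**Demographic inference**: a haploid serial coalescent with piecewise
constant female effective size *N(t)* and a single change 30–110 years
before present, finite-sites K80-like mutations with a configurable Ts/Tv
bias, three competing models (constant / decline / expansion), rejection
ABC on 8 summary statistics with SD standardization and Euclidean distance,
Beaumont-style local-linear regression adjustment on log parameters, and
pseudo-observed-dataset (POD) experiments quantifying power and credible-
interval coverage.

## Worked example

```python
import numpy as np
from mitotempo import synthetic_data as sd, serial_coalescent as sc
from mitotempo import popgen_stats as ps, alignment_io as aio

design = sd.builtin_design("grauer")            # 68 historical + 29 modern, 15 kb
mut = sd.default_mutation_model("grauer")       # 1.28e-8 /site/year, Ts/Tv 0.933
demo = sc.constant_model(3000.0)                # 3000 breeding females
aln, meta, truth = sd.generate_study(design, demo, mut, seed=1)

groups = aio.partition(aln, meta, ("era",))
print(ps.diversity_table(groups).round(4).to_string(index=False))
```

prints

```
     group  n  H     Hd   k_bar     pi   S  tajima_d
historical 68 30 0.9583 40.5228 0.0027 148    1.0787
    modern 29 21 0.9803 42.0887 0.0028 141    0.6666
```

i.e. on this constant-size synthetic dataset the two eras show
indistinguishable haplotype diversity (0.96 vs. 0.98) and mean pairwise
differences (~41 vs. ~42 nucleotides); nothing suggests a temporal change,
as expected under the constant-size truth. An actual decline would instead
depress the modern row — the ABC
layer (`mitotempo abc-build` / `abc-modelchoice` / `abc-estimate`) then
quantifies how strongly the data support it and estimates the
historical-to-present size ratio with a 95% credible interval.

The same pipeline is available from the shell:

```bash
mitotempo synth --taxon grauer --seed 1 --outdir run/
mitotempo stats --fasta run/grauer.fasta --meta run/grauer.meta.tsv \
    --group-by era --outdir run/stats/
mitotempo permute --fasta run/grauer.fasta --meta run/grauer.meta.tsv \
    --group-by era --statistic hd --seed 1 --outdir run/perm/
```

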