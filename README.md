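# mitodiv

Temporal mitochondrial diversity analysis for conservation genetics.

The motivating problem: a population (here, Iberian gray wolves) recovers
demographically after a severe decline, but maternally inherited diversity
can keep eroding for generations afterwards. Quantifying that lag requires
comparing mitochondrial DNA from museum-era specimens (incomplete,
low-coverage consensus sequences) with modern samples, using estimators that
tolerate missing data and that are comparable across epochs.

`mitodiv` provides the full toolchain for such a comparison:

* **haplotype collapsing** from multiple alignments over `{A,C,G,T,N,-}`
  under two missing-data policies (`strict`: N matches only N;
  `merge_compatible`: sequences identical at all mutually observed sites
  are merged);
* **diversity estimators** — unbiased haplotype diversity
  Hd = n(1 − Σp̂ᵢ²)/(n − 1) with Nei's variance; mean pairwise differences
  Θ̂π with Tajima's variance and per-site nucleotide diversity π = Θ̂π/L;
  Watterson's Θ̂S = S/a₁ with a₁ = Σ₁ⁿ⁻¹ 1/i; the Ewens estimator Θ̂K
  solving K = Σᵢ₌₀ⁿ⁻¹ θ/(θ+i), with an exact equal-tail confidence interval
  from the Ewens sampling formula
  P(K=k | θ, n) = |s(n,k)| θᵏ / θ⁽ⁿ⁾ (unsigned Stirling numbers of the
  first kind);
* **haplotype accumulation (rarefaction) curves** by random permutation,
  with the closed-form hypergeometric expectation
  E[K_g] = Σ_h [1 − C(n−c_h, g)/C(n, g)] as an exact cross-check;
* a **permutation test** for between-epoch differences in Hd or π
  (Monte-Carlo with (b+1)/(B+1) correction, exact enumeration on small
  problems);
* **haplotype networks** — equal-weight-closed minimum-spanning network and
  a median-joining network (ε = 0) with mutation-count edge weights;
* **female effective population size** N_ef = (θ/L)/(2μ) for a haploid,
  maternally inherited locus under a mutation-rate interval;
* a **synthetic-data generator**: Ewens-sampling-formula partitions (Hoppe
  urn), a neutral Kingman coalescent with infinite-sites mutations,
  aDNA-style per-individual site masking, and a two-epoch design with
  Wright–Fisher drift between sampling times.

## Worked example

Simulate a two-epoch study in the whole-mitogenome regime (θ = 11.7, 19
historical + 29 modern sequences, historical sequences degraded by up to 30%
missing sites), then summarize diversity per epoch:

```sh
mitodiv simulate --seed 42 --theta 11.7 --length 2000 --out sim
mitodiv diversity --fasta sim/alignment.fasta --groups sim/groups.tsv \
    --missing-policy merge --out div
```

which prints (columns abridged):

```
     group  n  K  S     Hd  theta_pi     pi  theta_S  theta_K
historical 19 12 23  0.936     3.971  0.003    6.581   12.958
    modern 29 12 20  0.911     6.094  0.003    5.093    7.151
```

Each row is one epoch: `K` distinct haplotypes among `n` sequences, `S`
segregating sites, haplotype diversity `Hd`, the three theta estimators on
the per-sequence scale, and per-site `pi`. Under pairwise deletion the
masked historical sequences still contribute; note Θ̂K dropping from 13.0 to
7.2 across the drift phase while Hd barely moves — the haplotype-count
estimator is the more sensitive indicator of a recent loss, the pattern this
kind of study looks for.

Test whether the epochs differ more than chance, and convert a theta
estimate into breeding-female numbers (here: the Ewens MLE for 8 haplotypes
in 29 mitogenomes of 15,460 bp, with a per-site mutation rate between
1.85 × 10⁻⁷ and 3 × 10⁻⁷ per generation):

```sh
mitodiv permtest --fasta sim/alignment.fasta --groups sim/groups.tsv \
    --missing-policy merge --seed 7 --out pt
# |Delta Hd| = 0.0243, p = 0.6024 (1000 permutations)

mitodiv ne --n 29 --k 8 --length 15460 --mu-low 1.85e-7 --mu-high 3e-7 --out ne
# N_ef = 577 (mu=1.85e-07) to 356 (mu=3e-07)
```

The permutation p-value of 0.60 says the observed Hd difference is well
within the null spread; the N_ef pair brackets the number of breeding
females consistent with the observed haplotype diversity — a few hundred,
directly comparable with census pack counts.

`mitodiv network` writes a median-joining network (GraphML + edge/node TSV),
and `mitodiv rarefy` writes per-epoch accumulation curves with the exact
expectation alongside the permutation mean.

The same operations are available as a library
(`from mitodiv import summarize, ewens_theta, median_joining, ...`).

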