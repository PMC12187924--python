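# paleokin

Kinship, IBD-network and demographic analysis of ancient burial communities.

Archaeogenetic studies of cemeteries increasingly rest on two genomic
signals: long chromosome segments shared **identical by descent (IBD)**
between individuals, which reveal biological kinship and the web of marriage
ties within and between sites, and **runs of homozygosity (ROH)**, which
reveal parental relatedness and the effective size of the breeding
population. `paleokin` is a toolkit for the downstream half of such a study.
It consumes the tabular outputs of standard segment callers (ancIBD-style
pairwise IBD tables, hapROH-style per-individual ROH tables, smartpca PC
coordinates, qpAdm ancestry proportions) and provides:

- **Kinship classification** from pairwise IBD summaries. With
  φ = (merged IBD length)/L and L the genetic genome length, relatives are
  binned at the geometric midpoints of the expected sharing fractions
  1, 3/4, 1/2, 1/4, … (parent–offspring and full siblings separated by the
  IBD2 fraction), plus consanguinity calling by the long-ROH rule
  (flag when Σ ROH > 50 cM over blocks > 20 cM) and validation of proposed
  pedigrees against IBD and uniparental (mtDNA / Y) evidence.
- **IBD network analysis**: thresholded graphs (≥ *k* segments of ≥ 12 cM),
  normalised degree centrality k = deg/(n−1), local clustering C,
  within/between-module strength with max-segment weights, maximal-clique
  enumeration with within/between-site and sex classification (χ² tests,
  including a site-stratified Mantel–Haenszel sex contrast), and Leiden
  community detection under the constant Potts model
  Q = Σ_c [E_c − γ n_c(n_c−1)/2].
- **Effective population size** by maximum likelihood from segment-length
  spectra: with G = L/100 Morgans and geometric coalescence-time pmf
  P(g) = (2N)⁻¹(1 − (2N)⁻¹)^(g−1), the expected number of segments in
  [u₁, u₂] Morgans per lineage pair is
  Σ_g P(g)(2gG + K)(e^(−2g·u₁) − e^(−2g·u₂)); a Poisson composite likelihood
  over length bins yields N̂ and a likelihood-ratio 95% CI.
- **Ancestry outliers**: Mahalanobis distance on PC1/PC2 with the χ²₂
  closed form p = exp(−MD²/2), component Z-scores, Levene/Bartlett variance
  tests and two-sample t-tests.
- **Self-contained contingency statistics** (two-sided Fisher exact,
  Pearson/Yates χ², pooled two-proportion Z, permutation tests) and a
  comparative two-site report.
- A **forward simulator** that makes all of the above testable without any
  genomic download: diploid genomes as founder-segment mosaics transmitted
  with Poisson recombination through configurable pedigrees, Wright–Fisher
  populations and multi-site communities with residence rules (patrilocal /
  matrilocal / neolocal), emitting truth IBD/ROH tables in the same formats.

## Worked example

Simulate a patrilocal multi-site community, extract truth segments and ask
whether women carry the between-site connections:

```python
import paleokin as pk
from paleokin.network import build_graph, enumerate_cliques, classify_cliques

cohort = pk.simulate_community(seed=2, **pk.sim.PATRILOCAL_STUDY)
meta = cohort.metadata_frame()
ibd = pk.extract_ibd(cohort)                      # truth segments >= 8 cM

graph = build_graph(ibd, meta, min_seg_cM=12.0, min_n_segments=2)
cliques = enumerate_cliques(graph)                # maximal cliques, size >= 3
result = classify_cliques(cliques, meta)
c = result["overall_sex_contrast"]
print(len(cliques), round(c["z"], 2), f'{c["p"]:.2e}')
```

This prints `414 3.57 3.61e-04`: 414 maximal cliques, and a site-stratified
sex contrast of z = 3.57 (p ≈ 3.6×10⁻⁴) — female between-site clique
participation far exceeds its expectation, the network signature of
patrilocal residence with female exogamy.  Comparative statistics work
from plain counts: a consanguinity rate of 6/30 in one community versus
2/61 in a more open one gives a two-sided Fisher p = 0.014
(`pk.fisher_exact_2x2([[6, 24], [2, 59]])`).

A command-line pipeline covers the same stages
(`paleokin simulate | kinship | consang | network | cliques | communities |
outliers | ne | stats | all`), e.g.:

```sh
paleokin stats --test fisher --counts 6 24 2 59
paleokin simulate --sites 3 --couples 6 --generations 3 --seed 1 --out demo/
paleokin kinship --ibd demo/ibd.tsv --out demo/pairs.tsv
```

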