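# Methods

This note documents the models, conventions and design choices behind
`paleokin`, in the order the pipeline runs.

## Coordinates and genetic map

All positions are genetic-map coordinates in centimorgans, half-open
`[start, end)`, 0-based per chromosome. The packaged default map is a
sex-averaged 22-autosome table of pedigree-map lengths (total
L ≈ 3544.6 cM, K = 22); any per-chromosome table can be supplied instead.
The tools that produce real IBD/ROH input tables do not document a single
canonical map, so the packaged table is a convention, exposed in
configuration and carried explicitly (as L and K) into every downstream
formula.

## Forward simulator

Genomes are mosaics of founder haplotypes: each haplotype is a tiling of
`[0, L)` by `(start, end, founder_allele)` segments, with one globally
unique allele per founder haplotype. Meiosis draws a Poisson(L/100)
number of crossovers uniformly on the concatenated map — equivalent to
independent Poisson(length/100) per chromosome — with no interference and
no obligate chiasma, a fair-coin starting phase per chromosome, and a
sex-averaged map. Only segment-length spectra matter downstream, which
these simplifications preserve; they do not reproduce crossover
interference or sex-specific map differences.

Truth IBD between two individuals is extracted per haplotype combination
(4 per pair) as maximal intervals on which the two mosaics carry equal
founder alleles. Maximality is over the equality predicate: a tract copied
intact from a recent common ancestor carries that ancestor's internal
mosaic boundaries in *both* copies, so runs are not split where both
haplotypes switch to the same allele. Doubly shared regions (IBD2) appear
as overlapping rows of disjoint combinations and are recovered by interval
arithmetic (length covered at depth ≥ 2). ROH are the same computation
between an individual's two homologs. Default floors are 8 cM (IBD) and
4 cM (ROH), matching the detection floors of the upstream callers; truth
extraction has no detection noise, which makes simulated networks *denser*
in distant relatives than real called data (see the community design
below).

Three cohort generators build on this core:

- `simulate_pedigree` transmits founder genomes through a declared pedigree
  (founders, unions, offspring), with mitochondrial labels following the
  maternal line and Y labels the paternal line.
- `simulate_population` is a discrete-generation diploid Wright–Fisher
  population with separate sexes (uniform mother and father per child;
  optional monogamous pairing). Two random haploid lineages coalesce at
  rate 1/(2N) per generation, so census size equals effective size.
- `simulate_community` embeds patrilineal (or matrilineal/neolocal) sites
  in a wide regional marriage network; see "Patrilocality study design".

Emulated ancestry tables draw PC coordinates from per-group bivariate
Gaussians (planted outliers placed at a prescribed Mahalanobis distance)
and ancestry proportions from a logistic-normal on the 4-simplex
(ANF/WHG/EHG/CHG) with fixed standard errors. These emulate the *shape* of
smartpca/qpAdm outputs, not their genetic content.

## Kinship

Pair summaries merge a pair's segments per chromosome into a union track;
φ = union/L. Degree bins sit at the geometric midpoints of the expected
union fractions (1, 3/4, 1/2, 1/4, 1/8, 1/16): parent–offspring requires
φ ≥ 0.9 with IBD2 fraction < 0.1, full siblings high φ with substantial
IBD2, then degree2 (0.354, 0.612], degree3 (0.177, 0.354], degree4
(0.0884, 0.177], degree5 (0.0442, 0.0884]; below that, pairs sharing at
least two segments ≥ 12 cM are `degree6plus`, otherwise unrelated. These
bins are a declared, simulation-validated convention (recovery on seeded
pedigrees: ≥ 95% for 1st–2nd degree, ≥ 80% for 3rd), not a claim about any
specific published caller.

Consanguinity is flagged when the summed length of ROH blocks strictly
longer than 20 cM strictly exceeds 50 cM (ties conservatively not
flagged). The genome-wide ROH fraction F̂ = ROH(≥ 4 cM)/L is binned at
geometric midpoints of the inbreeding coefficients 1/4 … 1/64 to class the
parents' relatedness; F̂ below ≈ 0.011 is called outbred.

Pedigree validation reports mother–child mitochondrial mismatches,
father–son Y mismatches, and pairs whose observed degree call is at least
one full degree away from the pedigree-implied category (implied from the
kinship coefficient, φ_k = 2^−(d+2); parent–offspring and full siblings
count as the same degree, so PO/FS confusion alone is not a violation).

## IBD networks

Edges require at least `min_n_segments` segments of ≥ `min_seg_cM`
(defaults reproduce the 1×12 cM and 2×12 cM analysis variants); edge
attributes carry the count, maximum and summed segment lengths, and node
metrics weight strengths by the maximum shared segment. Cliques are
*maximal* cliques of size ≥ 3 (Bron–Kerbosch with pivoting); participation
counts a node once per clique. Per site, each sex's (within, between)
participation is tested against the site-wide proportions (Pearson χ²,
df = 1), a per-site 2×2 sex-by-classification χ² is reported, and an
overall Mantel–Haenszel test stratified by site summarises the sex
contrast in one statistic — the stratified test is the appropriate
aggregate when sites differ in size and baseline between-rates.

Community detection maximises the unweighted constant Potts model quality
Q = Σ_c [E_c − γ n_c(n_c−1)/2] (default γ = 0.04) with the Leiden
algorithm; because Leiden is a heuristic, the detector runs 10 seeded
restarts and keeps the best Q (verified to attain the exhaustive-search
optimum on graphs of ≤ 8 nodes). Community ids are canonicalised by their
smallest member; all tie-breaking is lexicographic.

## Effective population size

Model: two haploid lineages in a diploid population of constant size N
coalesce g generations ago with probability
P(g) = (1/(2N))(1 − 1/(2N))^(g−1). Given coalescence at g, the genome
(G = L/100 Morgans, K chromosomes) is broken by 2g meioses into on
average 2gG + K segments with approximately Exp(2g) lengths, so the
expected number per lineage pair in a bin [u₁, u₂] Morgans is
(2gG + K)(e^(−2gu₁) − e^(−2gu₂)), summed over g weighted by P(g) (the tail
is truncated when it falls below 10⁻⁸ of the running sum). An individual's
two genomes form one lineage pair (ROH mode); a diploid pair forms four
(IBD mode). Default bins: ROH [4, 8, 12, 16, 20] cM; IBD eight log-spaced
bins in [12, 100] cM — the windows in which segments are informative about
the last ~50 generations while remaining reliably callable.

The likelihood is independent-Poisson over bins and units (a composite
likelihood: segment counts are weakly dependent through the shared
pedigree). N is fitted on log N ∈ [log 10, log 10⁶] by bounded scalar
minimisation; the 95% CI is {N : 2(ℓ_max − ℓ(N)) ≤ 3.84}, clipped at the
search range when a bound is not bracketed. The per-bin log-likelihood
contributions are down-weighted by quasi-Poisson dispersion factors
(variance-to-mean ratio of the unit-level bin counts, floored at 1,
estimated whenever the spectrum carries per-individual or per-pair
counts): segment counts cluster within a unit — one recent common
ancestor leaves several long segments at once — so plain Poisson
information mildly overstates precision. The point estimate is
essentially unaffected.

A calibration caveat belongs here. The interval quantifies sampling noise
around the *realised* genealogy of the population the cohort was drawn
from. A finite population run for a finite time has its own realised
effective size, which fluctuates between replicate histories (measured:
sd ≈ 8–9% around the nominal N for N = 500 populations observed
30 generations after founding, shrinking with depth and with smaller N);
this component is coherent across all sampled individuals and therefore
invisible — and uncorrectable — from within a single cohort. Coverage of
the *nominal* N consequently sits below nominal wherever the likelihood
interval (± ~12% here) is not much wider than that genealogical scatter:
recovery simulations give ~16/20 at N = 500 with 30 generations, against
≥ 18/20 at N = 200 (deeper relative coalescence, small scatter) and
N = 2000 (wide intervals). This is a property of single-replicate
demographic inference, not of the implementation; against each
replicate's realised genealogy the interval behaves as intended. Pre-filters reproduce standard
practice: ROH mode drops individuals flagged consanguineous (their long
ROH reflect mating choice, not population size); IBD mode drops pairs
closer than 4th degree and restricts segments to the 12–100 cM window —
the window reading of the ambiguous "12 < 100 cM" filter phrase.

Two fitting notes:

- **Founder horizon.** An optional `max_gen` truncates (without
  renormalising) the coalescence pmf. A forward simulation started from
  unrelated founders generates no segments from coalescences older than
  the founding; fitting the open-horizon model to such data is a model
  mismatch (about a third of the expected 4–20 cM ROH mass lies beyond
  g = 30). Recovery analyses therefore pass the known simulation depth;
  the default (open horizon) is the setting for real data.
- **Cohort size and CI calibration.** The composite-likelihood CI ignores
  the between-replicate variance of the realised pedigree, which is
  negligible only when the Poisson counting noise dominates — i.e. for
  cohorts much smaller than the population, as in real excavations
  (dozens of individuals from communities of thousands). Recovery tests
  accordingly sample 40 individuals per simulated population; fitting an
  entire simulated population produces CIs far narrower than the
  replicate scatter. This is a property of composite likelihoods, not of
  the implementation.

Problem sizes used by the test suite: populations of N ∈ {200, 500, 2000}
run for 30 generations, 20 replicates each, with 40-individual cohorts.

## Ancestry outliers and group tests

Group moments (mean and sample, n−1, covariance of PC1/PC2) include the
tested point — the procedure computes group statistics first and distances
afterwards; leave-one-out would be stricter but is not what is emulated
here. For two PCs the χ²₂ upper tail has the closed form
p = exp(−MD²/2); individuals are flagged at p < 0.05. Component Z-scores
use the group sample SD (again including the tested point), require more
than 3 group members, and flag |Z| > 2; Z-scores are computed on raw
values even for components whose group distribution is half-normal-like
(EHG), mirroring common practice — a fidelity choice, noted here.
Variance homogeneity uses mean-centred Levene plus Bartlett; mean
comparisons default to the pooled-variance two-sample t.

## Contingency statistics

Fisher's exact test is two-sided by the point-probability criterion (sum
of hypergeometric probabilities of all tables with point probability not
exceeding the observed one, relative tie tolerance 10⁻¹²) — the dominant
convention, verified against exhaustive enumeration for every 2×2 table
with N ≤ 40. The χ² test optionally applies the Yates correction
(|O − E| − 0.5, floored at 0). The two-proportion Z-test uses the pooled
estimate. The permutation test reports (1 + #{|T*| ≥ |T|})/(1 + n_perm).
The comparative two-site report maps each row to the test that reproduces
its published value: Fisher for consanguinity and mtDNA-diversity rates,
Yates χ² for EHG-flag and Y-lineage rows, pooled Z for PC-outlier rates —
a mapping established by recomputation, printed alongside every p-value.
No multiple-testing correction is applied, matching the practice the
report emulates.

## Patrilocality study design

The diagnostic the network module targets is qualitative: under
patrilocal residence with female exogamy, men dominate within-site clique
participation and women the between-site one. Reproducing this from truth
segments needs care, because perfect segment detection connects even
5th-degree relatives (measured: second cousins pass a 2×20 cM edge filter
94% of the time), so any metapopulation with generations of inter-site
exchange collapses into one dense web in which every within-family clique
is absorbed ("flipped") into a between-site clique by some emigrated
female relative.

The validated design (`sim.PATRILOCAL_STUDY`) therefore models what real
regional networks look like to a segment caller: 10 long-established,
patrilineally continuous sites (8 founder couples each, 4 generations,
4 children per union, 25% juvenile mortality with burial at the natal
site) embedded in a wide outside marriage pool (6 in-marrying outside
brides per site per generation), whose *direct* mutual exchange is recent
— sibship-level marriage alliances send a family's daughters together to
one allied site, with probability 0.3 per sibship, during the final
generation only; all other daughters marry beyond the region and leave
the burial record. Between-site co-ancestry then reflects the migrant
women themselves (and their co-migrated sisters) rather than deep common
descent. On the 2×12 cM graph the female-biased between-site clique
participation (stratified Mantel–Haenszel p < 0.05 with female excess) is
detected in ≥ 90% of seeded cohorts on held-out seed ranges.

What this does and does not show: passing tests demonstrate that the
pipeline detects the patrilocality signature when the underlying history
contains it and truth segments are observed; they do not quantify power on
real called data, where detection noise thins distant-relative edges (and,
if anything, sharpens the within/between contrast).

## Degenerate inputs and conventions

Single-node graphs get k = 0 by convention; nodes of degree < 2 get
C = 0. Zero expected cells skip a χ² with a recorded warning. A zero
pooled proportion yields Z = 0, p = 1. Empty spectra and empty site
bundles raise errors naming the remedy. All randomness flows through a
single integer seed per operation; pipeline outputs are byte-identical
under a fixed seed, with every run stamped with the configuration hash.

## Known limitations

No sequence-level simulation (SNPs, genotyping error, coverage), no
detection/HMM noise model, no crossover interference, constant-N
demography only (no trajectories, migration or cross-coalescence), no
automated pedigree reconstruction (pedigrees are validated, not
searched), and no multiple-testing correction in the comparative report.
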