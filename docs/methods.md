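# Methods

## Data model

The unit of analysis is a multilocus dataset of phased haplotype
alignments (nominally 13 nuclear loci), each row a gene copy of a
diploid individual assigned to one of two species. Coordinates are
1-based with closed intervals. Alignment columns containing a gap in
any ingroup sequence are flagged as indel columns and excluded from
every statistic. Columns containing `N` are excluded by complete
deletion by default (the behaviour of the classic desktop tools this
report format mirrors); a pairwise-deletion mode for π is available on
`build_site_table`. Ancestral states come from an optional outgroup
haplotype and are marked unknown wherever the outgroup is gapped,
missing, or carries an allele absent from the ingroup.

Silent sites are all non-coding positions plus coding positions that
are fourfold degenerate for the reference codon (every substitution
synonymous). Without coding annotation the whole locus is treated as
silent, so silent π equals total π — the synthetic loci carry no
annotation by default.

## Statistics

- *S* counts segregating sites; η counts inferred mutations (a
  tri-allelic site contributes 2); η_s counts singletons by allele
  multiplicity (allele present in exactly one sequence), so Fu & Li's
  tests need no outgroup. Tajima's *D* uses *S*; *D\**/*F\** use η and
  η_s with the corrected variance constants of the later literature.
  All three return NA when *S* (or η) is zero or *n* < 4, where the
  variance constants degenerate.
- Fay & Wu's *H* is π − θ_H by default, θ_H = Σ 2 S_i i²/(n(n−1)) over
  derived-allele counts *i*; the normalized variant divides π − θ_L by
  its null standard deviation with θ and θ² estimated from *S*. Sites
  with unresolved ancestral state are skipped; fixed derived sites are
  not polymorphisms and are ignored.
- Fu's *F*_S is computed exactly: S′ = P(K ≥ K_obs) under the Ewens
  sampling distribution with θ = π (mean pairwise differences), using
  log-space unsigned Stirling numbers of the first kind (cached rows,
  stable beyond n = 400), and F_S = ln(S′/(1 − S′)).
- Φ_ST is the AMOVA estimator on pairwise-difference distances with
  species as groups; multilocus values sum variance components over
  loci. The permutation test reassigns whole individuals (both alleles
  together) between species — individuals, not gene copies, are the
  exchangeable units — and reports the fraction of permutations with
  Φ ≥ observed.

### ABC summary vectors

The IM summary vector has 13 components: per-species haplotype counts
(summed over loci), per-species and private polymorphic sites, π within
each species, pooled Tajima's *D*, pooled Fu's *F*_S, Φ_ST, π between
species, and total polymorphic sites; all except haplotype counts are
across-locus means. The enumeration of the 13 statistics is ambiguous
in the source material (a fully per-species reading gives 15), so *D*
and *F*_S are pooled single values here — a documented, configurable
choice. Per-locus statistics undefined at some loci are averaged over
the loci where they are defined; a component is NA only when undefined
everywhere, which marks the whole vector invalid ("exceptional values")
and excludes that simulation from retention. The bottleneck vector is
(mean *S*, mean *D*, mean per-site π, mean *F*_S) over the scoped
sequences (either species or pooled).

## Simulation

Genealogies are simulated with msprime's continuous-time coalescent.
Population sizes are diploid individual counts (rates use 2N gene
copies); times are generations. The IM migration parameter is expected
migrant gene copies per generation into the destination deme, giving a
backward per-lineage rate M/(2N_dest); a per-copy-rate reading is
available as a switch since the source material never fixes the scale.
Mutations are infinite-sites at μ = 10⁻⁸ /site/generation (Jukes-Cantor
states on a continuous axis, mapped to distinct integer columns when an
alignment is rendered). Loci are independent with no intra-locus
recombination. The simulator's true ancestral states double as a
perfect outgroup. In the three-epoch bottleneck model the
post-expansion size N₀ is not specified by the study design and is
treated as a free, prior-sampled parameter.

## ABC inference

Priors are uniform; sizes and times are sampled uniformly in log10
(sizes 10³–10⁶ diploids; T and T_b 10²–10⁵ generations, T_e 10¹–10⁵
with T_e < T_b by rejection), migration uniform on [0, 200]. The
log-uniform choice spans the three orders of magnitude of the reported
intervals without concentrating nearly all prior mass at large values;
the source material does not state its prior scales, so posterior
agreement is approximate by construction.

The reference table draws one parameter vector per row (per-row seeds
derived from a single master seed, so results are independent of
batching), simulates the full multilocus design, and stores the summary
vector with a validity flag. Rejection standardizes each summary by the
valid rows' standard deviation (zero-variance components dropped with a
warning) and keeps the `n_retain` nearest rows by Euclidean distance,
ties broken by row index.

The GLM adjustment fits summaries on parameters by ordinary least
squares over the retained rows (shared residual covariance, small ridge
jitter for conditioning). The posterior is the fitted Gaussian
likelihood at the observed summaries times a uniform prior truncated to
the region where the regression was fitted: the prior support
intersected with the retained draws' bounding box (padded 5%). This
box-truncated, possibly rank-deficient Gaussian is sampled by Gibbs
(100 chains × 300 sweeps, 100 burn-in; each full conditional a 1-D
truncated normal, or uniform for a parameter the summaries carry no
information about). Marginal densities are Rao-Blackwellized averages
of the conditional densities on a 512-point grid, so the grids are
smooth and the mode/HPDI extraction is stable. A Beaumont-style
local-linear adjustment with weighted KDE is available as an
alternative, and plain rejection is the fallback for singular designs.
The HPD interval is the smallest set of grid cells holding 95% of the
mass, reported as its spanning interval with a multimodality flag.
Years are produced only at reporting time as generations × generation
time (50 by default, 25 as the common alternative).

Note one deliberate property of sharp retention: when the retained ball
in summary space is small relative to the summary noise, the fitted
slopes attenuate and the posterior widens toward the truncated prior.
This is conservative (coverage is preserved at the cost of precision);
the conjugate-model test therefore exercises the GLM at full retention,
where the regression is unbiased and the posterior matches the analytic
truncated Gaussian.

## Synthetic data and what the tests show

The default IM scenario uses the reported posterior-mode parameters
(N = 240,982; N_asp = 35,919; N_cra = 51,887; T = 2,551 generations;
M = 26.26 and 14.14; μ = 10⁻⁸) over 13 loci of 800 bp — per-locus
lengths and coding annotation of the real loci are not public, so 800
bp falls in the reported 500–1100 bp range and annotation defaults to
none. The bottleneck scenario contracts at T_b = 3,918 generations
(196,000 years at 50 yr/gen) to N_b = 5,000 and re-expands at
T_e = 740 generations (37,000 years) to N₀ = 35,919; N_b and N₀ are
package choices of a severe but recoverable bottleneck consistent with
the inferred size reduction. Tests default to 20+20 sampled sequences;
the full 176+256 design is one flag away. Reference tables in the
recovery tests use 20,000 simulations with 200 retained; the acceptance
script uses 12,000 with 150 retained — desk-scale stand-ins for the
paper-scale 500,000/5,000 profile, which is a configuration change, not
a code path change.

The generator emulates the statistical structure the analysis assumes
— phased haplotypes, free recombination between loci, none within,
infinite sites, no missing data, a perfect outgroup. It does not
emulate phasing error, sequencing error, indel processes, recombination
within loci, or population structure within species. Passing tests
therefore validate the estimators and the inference machinery under the
model's own assumptions, not robustness to those real-data departures.

## Numerical choices and limitations

- Harmonic-number constants are computed directly; no closed-form
  approximations.
- The Ewens tail probability is clamped away from {0, 1}; F_S is NA
  when π = 0 or the tail degenerates.
- Gibbs chains start from retained draws; determinism is guaranteed by
  a single seeded generator per fit.
- Degenerate inputs: empty site tables are legal everywhere (statistics
  return 0 or NA); a species with fewer than two sequences is a hard
  error for Φ_ST and the fits.
- Multilocus Φ_ST sums variance components, so loci with more variation
  weigh more — the convention of the AMOVA lineage of tools.
- The split-time posterior under high gene flow is intrinsically wide;
  interval coverage, not point accuracy, is the tested guarantee.
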