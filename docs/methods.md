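# Methods

This note documents the models implemented in `archpain`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Coordinates are 1-based inclusive
internally; BED export is 0-based half-open.

## Introgression HMM

Each phased haplotype is modelled as a succession of archaic and modern
tracts over the ascertained sites of a ~4.18 Mb region.

**Emissions.** Under the modern state the derived-allele probability is the
modern-proxy (African-panel) frequency clipped to `[ε_f, 1−ε_f]`; under the
archaic state it is the archaic proxy's derived-genotype fraction (0, ½, 1)
with symmetric error `ε_a`. Defaults `ε_f = ε_a = 0.01`. This is the
minimal emission model consistent with supplying, per site, an archaic
genotype and modern proxy frequencies; it ignores local-ancestry-specific
modern frequencies (a deliberate simplification — the modern proxy stands
for all non-archaic backgrounds).

**Transitions.** Between adjacent sites separated by Δ bp the chain
switches with probability `s = 1 − exp(−ρΔ)`, allocated to the destination
state in proportion to the stationary prior `π = (1−p, p)` with
`p = p_arch_prior`; this makes `π` the exact stationary distribution.
Defaults: `ρ = 1/123,000 bp⁻¹`, matching the target mean tract length of
~123 kb, and `p_arch_prior = 0.02`, a cohort-scale regional archaic
fraction. A constant recombination-rate scaling (≈0.79 cM/Mb in such a
window) could rescale ρ but is not applied by default.

**Decoding.** Viterbi paths and forward–backward posteriors are computed
in log space, vectorised across haplotypes, so 10⁵-site panels do not
underflow. Brute-force enumeration over all 2ⁿ paths on ≤10-site instances
is the test oracle for both.

**Tract retention (">99%" rule).** The default, `retention="per_site"`,
assigns a site to a tract iff its Viterbi state is archaic *and* its
archaic posterior exceeds `posterior_min = 0.99`; maximal runs of such
sites are tracts. The rationale: the posterior near a true tract boundary
is genuinely uncertain about the *endpoint* even when the tract's
*existence* is certain, so boundary sites carry posterior mass below 0.99
in proportion to the local informative-site spacing. An alternative rule
that retains a whole Viterbi run iff its mean per-site posterior exceeds
0.99 (`retention="tract_mean"`) is implemented and tested; it is stricter
on long tracts (whose edge-site count, and hence accumulated boundary
uncertainty, grows with length) and in simulation discards ~25–30% of
genuine tracts longer than the length cutoff while accepting short
confident runs — the per-site rule avoids that inversion and is the
default. Per-tract mean posteriors are recorded either way so the modes
can be compared.

**Length-cutoff calibration.** Chromosomes of uniformly African local
ancestry are assumed to carry essentially no archaic material, so archaic
bp assigned to them estimates the error floor. The cutoff is the smallest
L on a 0.5 kb grid such that discarding tracts shorter than L leaves an
archaic fraction ≤ 10⁻⁴ of African chromosome bp (the tolerance mirrors a
per-mille-scale residual on such chromosomes). A flag marks the degenerate
case where the calibrated L would also discard every non-African tract.
When the simulated African background produces no called tracts at all the
cutoff degenerates to the smallest grid value; this is expected under the
generator (see below) and harmless, since short spurious calls are absent
by construction.

## Haplotype and LD statistics

Per-ancestry allele frequencies are computed only on single-ancestry
chromosomes (haplotypes whose ancestry tracts all share one label across
the region); mixed chromosomes are excluded and counted. Two-locus
haplotypes are counted directly on phased chromosomes. LD follows the
standard definitions (D, D′, r²) with D′ ≔ 0 at D = 0 (continuity) and all
three flagged undefined at a monomorphic locus. Two tightly linked
variants are merged into one locus when their phased alleles co-occur on
≥ 99.9% of chromosomes; discordant chromosomes are reported, never
dropped. `HaplotypeFreqs.normalized` admits table frequencies rounded to
3 dp (which may sum to slightly less than 1) by rescaling.

## Admixture-mapping segments

Dosage(i, s) counts individual i's haplotypes carrying a retained tract
over site s. Segments merge consecutive sites greedily left-to-right: a
site joins the open segment iff its dosage column is identical to the
segment's *first* (representative) column or differs in strictly fewer
than 0.1% of individuals. Comparing to the representative, not the
previous site, prevents unbounded drift under chained near-identity; the
adjacent-comparison variant is available behind `compare="adjacent"` and a
dedicated test shows where the two differ. At threshold 0 the rule reduces
exactly to run-length encoding of identical columns. Segments with archaic
frequency strictly above 1% enter the association battery.

## Phenotype QC and association battery

Individuals with depression score > 15 are excluded outright (they are
removed from sensory testing before trait QC); then, per trait, values
outside mean ± 2 sample SDs on the raw scale are removed and survivors
natural-log transformed. Kinship pruning removes, greedily, the individual
in the most >5% pairs (ties: larger total kinship, then lexicographic id)
until no pair exceeds 5%.

Every association test is OLS of a log trait on [intercept, dosage term(s),
sex, age, depression, PC1–5], fitted by least squares with p-values from
the t statistic at n−k−1 df; listwise deletion gives each test its own n.
The adjusted post-sensitization trait adds the pre-sensitization threshold
as a ninth covariate. The five families are emitted in a fixed order:
14 single-locus tests (2 loci × 6 traits + adjusted), 2 joint betas, 4
haplotype contrasts (the fully ancestral haplotype recoded as its
complement, the any-archaic count 2 − n_ab, so all effects share a
direction), 1 allele-sum test (dosage 0–4), and one test per retained
segment. A monomorphic dosage is emitted as a degenerate record
(β undefined, p = 1) rather than aborting the battery. Benjamini–Hochberg
runs study-wide at q = 0.05 (the FDR level is configurable; the reported
threshold is p(k*), the largest accepted p-value). Covariate coding (sex
indicator, raw age) does not affect dosage betas under full-rank designs.

## Synthetic-data generator

The generator emulates the cohort structure the pipeline assumes; no
generative model exists for the real data, so all distributions are
package choices, fixed once:

* **Sites**: Poisson-spaced positions at 8776/4.18 Mb; 20% of sites
  archaic-informative (archaic homozygous derived, modern frequency
  ~U(0, 0.01)); remaining sites draw the archaic genotype binomially from
  the modern frequency. 2% of sites fail one random ascertainment rule, so
  the site filter does real work. Focal sites are always present, clean,
  and archaic-specific (background frequency ~U(0, 0.002), matching
  variants essentially absent outside the archaic background).
* **Ancestry**: per-individual (AFR, EUR, NAM) proportions from
  Dirichlet(0.22, 2.48, 2.30) — means (4.4%, 49.6%, 46.0%) — and a
  homogeneous Markov switch process along the chromosome at 5.3×10⁻⁸
  switches/bp, which leaves ~80% of haplotypes single-ancestry over
  4.18 Mb, the fraction seen in cohorts of this kind.
* **Archaic tracts** are generated only inside NAM tracts and anchored at
  the focal loci: conditional on NAM background, a haplotype carries
  archaic material at locus A with probability 0.68 and at the merged
  locus B with probability 0.29; 85% of B-carriers also carry A (the
  co-carriage implied by the observed two-locus haplotype frequencies
  0.114/0.135, realised as one long tract spanning both anchors). Tract
  lengths are exponential with mean 123 kb, truncated at the enclosing NAM
  tract. On-tract alleles copy the archaic genotype with a 1% error;
  off-tract alleles draw from ancestry-specific frequencies (logit-normal
  jitter, sd 0.3, around the modern proxy).
* **Phenotypes**: six positive, right-skewed thresholds are exponentials
  of Gaussian log-scale values with sex/age/depression effects
  (−0.10/−0.004/−0.01 per unit), residual sd 0.65, and a shared
  "sensitization" latent (sd 0.3) linking the pre- and post-sensitization
  mechanical thresholds so that adjusting one for the other is meaningful.
  The genetic effect, −0.075 per archaic allele on the log
  post-sensitization mechanical threshold, is sized so that an
  ~1600-individual cohort detects it with ~80% power at the study-wide
  threshold. PCs 1–2 track NAM and AFR proportions; PCs 3–5 are noise.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: background introgression away from the focal
region (real Native-American chromosomes carry ~5–6% archaic DNA
region-wide; simulated ones carry only the focal-anchored tracts, ~2%);
phasing and local-ancestry errors (so African chromosomes yield no
spurious short tracts and the calibrated cutoff is smaller than the
~23.5 kb obtained on real data); shared recombination-hotspot tract
boundaries (so admixture-mapping segments are shorter and more numerous
than the ~17 kb segments of real data); realistic LD between
non-focal sites (alleles are drawn independently given ancestry); and
genotype-imputation uncertainty (hard calls only). Recovery results
(tract-level F1 ≥ 0.9, β within ±0.02 of −0.075, type-I rates at nominal
5%) therefore validate the inference machinery under the generator's
assumptions, not field performance on real cohorts.

**Observed-vs-injected effect.** The recovered allele-sum β averages
≈ −0.063 for an injected −0.075: the ±2 SD trait trimming truncates the
outcome distribution and the 1% on-tract copy error misclassifies some
dosages, both classical attenuation mechanisms also present in any real
analysis with the same QC.

## Problem sizes

Test and acceptance runs use scaled problem sizes chosen to keep each
statistical check well-powered at desk scale: full site density (~8776
sites) wherever the HMM's spatial resolution matters (200 haplotypes), and
reduced densities (~100–1200 sites) for purely genotype/phenotype-level
checks, where site count is irrelevant; replicate counts are 100–200 per
Monte-Carlo assertion. All randomness flows through one
`numpy.random.Generator` per run, so every result in the README and the
acceptance JSON is reproducible from its seed.
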