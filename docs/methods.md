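# Methods

This note records the models, numerical conventions, and design choices
behind `sefscreen`, in the order a user meets them.

## Mendelian engine

Genotypes are ordered (maternal, paternal) allele pairs per named locus;
alleles are strings with `+` for wild type and `O` marking the empty
paternal slot of a hemizygous male X locus. Two alleles per locus plus
free-form allele identifiers are supported; multi-allelic series are not —
every cross scheme the package models segregates at most two alleles per
locus.

Meiosis walks each chromosome's loci in map order: the first locus picks a
strand with probability 1/2 and each subsequent interval switches strands
with probability θ(d). The default map function reads centimorgans directly
as percent recombination, θ = d/100 capped at 0.5 — exact at the small
distances where two-point mapping statements live ("< 20 cM"), and the
convention under which 100·θ is reported back as cM. Haldane's function
θ = (1 − e^(−2d/100))/2 is available via `map_function="haldane"` everywhere
a distance is converted. A male's gamete carries his X with probability 1/2
and is otherwise nullo-X; this coin is flipped even when no X locus is
tracked, since it decides offspring sex. Selfing yields hermaphrodites only
(spontaneous X nondisjunction males, ~0.2% in real populations, are ignored;
every scheme modeled supplies males by crossing).

Exact enumeration produces the offspring distribution as a sum over parental
gamete patterns. Within a chromosome, non-segregating loci are marginalized
by combining consecutive interval switch probabilities as
(1 − Π(1 − 2θᵢ))/2, which is exactly the marginal of the per-interval
simulation chain, so the enumerator and the sampler agree by construction
and the agreement is *tested*, not assumed (20,000-offspring crosses, every
genotype class within 4 binomial SE). Enumeration is guarded at 12
segregating loci (4,096 gamete patterns per parent). Genotype classes are
unordered (A/a ≡ a/A) for presentation; pedigree arithmetic that must track
phase (backcross enumeration) uses the ordered form internally.

## Mutagenesis and screens

Mutagenesis is Bernoulli per gene per transmitted haploid genome: a gamete
acquires a new allele of each suppressor gene with probability f, at most
one per gene (at f ≤ 10⁻³ the Poisson alternative differs at O(f²)).
Neutral background mutations arrive Poisson(background_rate) per gamete at
uniform random map positions; they only matter for backcross-dilution
studies and default to 0 in screen simulations.

The F1 clonal screen places one F1 per plate; a plate is called suppressed
iff its F1 carries a suppressor allele in any gene — detection is perfect by
default (a sensitivity < 1 knob exists for power studies), because the
frequency estimator implicitly assumes full detection. One isolate is kept
per line; if both genomes of one F1 were hit in the same gene (probability
f²), one allele is recorded, keeping the independent-event count ≤ the
isolate count. The F2 selection spreads the plated F2 pool evenly over the
F1 parents and scores each carrier-F1 family binomially (1/4 expressing for
recessive, 3/4 for dominant, all for biallelic F1). Isolates are suppressed
F2 animals; independent events are the distinct mutagenized-gamete origins
among them. Escape of non-suppressed animals defaults to 0, with a
configurable false-positive rate.

Analytic checkpoints are computed by composition rather than simulation:
F1 carrier frequency 1 − (1−f)² ≈ 2f, and suppressed-F2 frequency
2f(1−f)·p_express + f², where p_express comes from exact selfing enumeration
(1/4 recessive, 3/4 dominant) — first order f/2 and 3f/2.

## Frequency estimators

f̂ = n/(2·F1 + F2/2) combines both designs for recessive suppressors;
f̂ = n_i/G uses independent events when alleles have been sequenced.
Effective genomes: G = 2·F1 for the clonal screen. For the selection the
package defines G = F2/2 (recessive) and G = 3·F2/2 (dominant) directly from
the segregation frequencies above, so that E[isolates] = f·G; these
selection G values are reconstructions from first principles, not
transcriptions of any published worksheet. No uncertainty convention exists
for these estimates in the field's tables, so the package attaches an exact
(Garwood) Poisson interval for the event count at exposure G — isolates are
rare events over many genomes, which is precisely the Poisson regime.

Independent-event counting clusters isolates by *identical* linked-variant
signature sets; it is deterministic, permutation-invariant, and idempotent.
Distinguishing partially overlapping signatures (shared chromatid segments)
is out of scope.

## Rescue odds ratio

With f = k_D/N_D the transgenic fraction among escapers on restrictive food
and t = k_H/N_H the transmission rate on permissive food,
r = odds(f)/odds(t) = f(1−t)/(t(1−f)). This orientation makes r ≈ 1 mean
"transgene does not change escape" and r ≪ 1 mean "transgenic animals
escape less", i.e. rescue; the reciprocal is available as
`orientation="reciprocal"` for users who prefer the inverse convention.
Under the generative model (each brood member transgenic w.p. t, escaping
w.p. e_t or e_n), r consistently estimates e_t/e_n.

SEM_r = r·√(1/(N_D f(1−f)) + 1/(N_H t(1−t))) is the delta-method propagation
of the two binomial variances on the log-odds scale. Calibration: across
1,000 simulated assays with broods of several hundred and f, t in
[0.2, 0.8], the empirical SD of r sits within a few percent of the mean
SEM_r (the acceptance run prints the ratio). Boundary counts (k = 0 or
k = N) are refused with a pointer to the Haldane–Anscombe +0.5 correction
flag rather than silently returning 0 or ∞. Significance is plain Pearson
χ² without Yates correction (Yates available as a flag), Bonferroni-adjusted
by the number of lines in the panel.

## Two-point mapping

Expected thrower fractions are *derived* by enumerating the actual
two-generation mapping cross through the Mendelian engine (father carrying
marker and focal mutation in repulsion, informative lines conditioned on
focal carriage), not hard-coded: 1/2 unlinked, θ linked in repulsion.

Per-marker linkage screening is an exact two-sided binomial test against
1/2 with Bonferroni correction over the markers tested — deliberately
conservative, matching the qualitative "not tightly linked" use of such
tallies. The *chromosome assignment* is a separate model-selection step: the
chromosome of the marker with the smallest one-sided depletion p-value,
assigned when that p-value is below α unadjusted, with ties left
unassigned. The two answer different questions (familywise evidence per
marker vs most likely location), and the point assignment retains ~98%
power at 16 informative lines and 10 cM, where the Bonferroni screen alone
would sit near 79% (P(K ≤ 2 | n=16, p=0.1) = 0.79).

Distance bounds are one-sided Clopper–Pearson upper limits
(Beta(k+1, n−k) quantile at the confidence level; for k = 0,
1 − (1−c)^(1/n)), reported as cM = 100·θ_U. The confidence level defaults
to 95% and is a parameter. θ_U is capped at 0.5 (50 cM) only in the
per-marker result table, where values beyond free recombination are
meaningless.

X-linkage from backcross behavior tests two point models: carrier
probability 1/2 (autosomal) vs 1 (X-linked). The autosomal model is
rejected by a one-sided exact binomial excess test (deviation *toward 1* is
the X signal — a deficit of carriers is evidence against X-linkage, not
for it); the X model is rejected by any non-carrier, since under it every
cross-progeny hermaphrodite receives the father's X. The single surviving
model is returned, otherwise `inconclusive` (e.g. 12/16 rejects both).

## Backcross dilution

A backcross round is cross 1 (strain hermaphrodite × clean male, pick a
suppressor-carrying male), cross 2 (that male × clean hermaphrodite, pick a
suppressor-carrying hermaphrodite), then selfing to re-homozygose the
suppressor — the state the next round starts from. The dilution factor is
the ratio of expected background-allele dosage in that suppressor-homozygous
animal across the round. Including the re-homozygosing step is what makes
the three canonical answers exact: 4 (unlinked autosomal: two independent
halvings), 2 (X-linked: halved at the male-picking step only, since the
picked male passes his single X to every daughter), and 1 (fully linked:
co-segregates and is re-homozygosed along with the suppressor). The exact
factors come from staged conditional enumeration with phase tracked; the
Monte Carlo pedigree simulator reproduces them within sampling error.

## Phenotype models

Growth rate is 1/days-to-exhaustion; no claim is made about any particular
absolute scale. The log-brood-size model (growth rate ∝ ln B) gives the
relative factor ln B₁/ln B₂, e.g. ln 300/ln 7 ≈ 2.93 — the reason a
near-total larval arrest costs "only" a factor of three in growth.

Group comparisons are thin contracts over standard machinery: Student
two-sample t; one-way ANOVA plus per-group t tests against a named control
with Bonferroni (or Holm) adjustment, a portable stand-in for Dunnett-style
compare-vs-control tables (exact Dunnett quantiles are not re-derived);
two-way factorial ANOVA (type II) for the interaction. The epistasis
("same pathway") call requires (a) a significant *negative* interaction and
(b) a double-mutant mean that does not *significantly exceed* the larger
single-mutant mean (one-sided t at α). Condition (b) is deliberately
noise-aware: a strict sample-mean comparison would fail ~1/3 of the time
when the double and larger single mutant are truly equal — exactly the
saturating case the call is meant to detect. Constant (zero-residual) data
are flagged `interaction_undefined` and never called.

## Synthetic data

Generator defaults are the study conditions the estimators were built for:
f = 5×10⁻⁴ per gene per genome, F1 = 5128 plates, F2 = 68,000 plated
(≈ 34,000 effective selection genomes for a recessive gene), rescue broods
of ~500 with transmission t = 0.5 (a typical extrachromosomal-array value,
used as a placeholder — no measured rate exists for these arrays), escape
probabilities e_n = 0.8 and e_t = 0.4, pump-rate SD of 15 pumps/min at
n = 12 worms per genotype. The focal-to-linked-marker distance on I in the
mapping fixture defaults to 1 cM and is configurable; it is a fixture
convention, not a measurement. Pump rates are truncated-at-zero normals
(redrawing negatives, which shifts means negligibly at the default CV).

What the generators deliberately do *not* model: EMS dose–response and
mutational spectra, egg viability, growth competition on plates, plate-level
detection noise beyond the sensitivity/false-positive knobs, and brood-size
differences between genotypes. Passing tests therefore demonstrate the
statistical machinery is correct under clean Mendelian sampling, not that
real screens are free of these complications.

## Problem sizes and determinism

All stochastic tests fix seeds; hypothesis property tests are derandomized.
The simulation sizes used throughout (20,000-offspring oracle crosses,
10,000 backcross pedigrees, 200 replicate screens, 1,000 rescue assays, 200
mapping replicates) were chosen so each invariant's Monte Carlo error is
several times smaller than the tolerance it is tested against. Every
randomized entry point takes a `numpy.random.Generator`; the acceptance
script derives everything from its single `--seed`.
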