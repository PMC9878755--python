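# Methods

This note documents the models behind `hennest`, the assumptions they make,
the choices that were genuinely open, and what the synthetic-data tests do
and do not demonstrate about real electronic-nest data.

## 1. Trait derivation from nest-visit events

All times are integer minutes after lights-on; days are 0-based indices
into the recording window. Visits without an egg are ignored by every
trait (and a property test asserts that adding such visits changes
nothing). Only hens alive for at least half of the recording window are
analysed; the boundary is inclusive (alive-days ≥ ⌈0.5 × window⌉).

**LRN** = nest eggs / days alive × 100. The phenotype is kept only at
≥ 50 %; below that, laying rate confounds floor-laying preference, molt
and pausing, so the hen contributes only NAL = 0. LRN is not capped at
100: the generator produces at most one oviposition per hen-day, so values
above 100 cannot arise, and real double-ovulation days are rare enough
that a silent cap would only hide data errors.

**Clutch number.** A hen that lays in a nest on days d and d+g+1 but not
between leaves a gap of g ∈ [1, 4] days that is either a pause or a run of
floor eggs. Within a clutch the oviposition clock advances daily, so floor
days leave the entry time drifting slightly later; only a pause resets it
to the early morning. The classifier therefore compares the 24-h entry
times bracketing the gap: a backward shift strictly greater than the
threshold (180 min brown line, 195 min white line) is a pause; an equal or
smaller backward shift, or any forward shift, is floor laying ("strictly
greater" reads the rule literally, so a decrease of exactly 3 h is floor).
CN = pauses + 1. Hens with any gap longer than 4 days get a missing CN:
their activity is indeterminable, and since such hens are rare among
LRN-qualified hens the conservative choice (missingness, logged) costs
little. If one hen ever shows two ovipositions on one day the derivation
keeps the first and logs a warning; single daily oviposition is the
biological norm.

**MOT** is the mean *entry* time over oviposition visits. Entry times are
preferred to egg-sensor times because eggs can stay stuck behind the nest
until the hen leaves (4.3 %/11.2 % of eggs in the two lines emulated); a
sensor-based MOT restricted to accurately timed eggs, and the mean time of
entry, are stored alongside. Ten records minimum, as for all
nest-preference and duration traits.

**MDN** averages |horizontal nest distance| over pairs of *consecutive
calendar laying days* (day D and D−1 both with a nest egg); top and bottom
rows share the horizontal code; laying in the same nest contributes a
distance of 0 ("distance" is a magnitude and zero is a valid one). The
denominator counts pairs, not laying days — the natural reading of a mean
over day-pairs.

**PNL** = distinct physical nests used / nests in the pen × 100, with top
and bottom rows distinct; computed only for hens with ≥ 100 nest eggs
because the count of distinct nests saturates with egg number.

**Durations.** Per oviposition visit: total duration = exit − entry
(MLD); before = oviposition − entry and after = exit − oviposition (MDB,
MDA) only when the sensor time is flagged accurate. Each of the three
means has its own 10-record minimum, so MLD can be present while MDB/MDA
are missing. The same definitions are recomputed inside each 28-day
period (10 periods; the brown-line preset drops the last period, whose
recording was curtailed in the emulated study).

**NAL** (nest acceptance for laying) is 1 when raw LRN ≥ 50 %, else 0; it
is defined for every analysed hen with no minimum record count — a hen
with zero visits is a legitimate NAL = 0.

Every exclusion passes through one logged filter
(`filter rule=... n_before=... n_after=...`), so each missing cell is
attributable to exactly one rule.

## 2. Normalisation

Whole-window traits are skewed (LRN piles up near 100, durations have long
right tails), which inflates REML residual variances. Each continuous
trait is mapped through a rank-based inverse-normal transform
(average ranks, Φ⁻¹((r − ½)/n)) and then centred and scaled exactly. The
transform is deterministic and strictly monotone; a per-trait
transform-selection step would add a model-choice degree of freedom
without changing what the downstream analysis needs (an approximately
Gaussian margin). NAL stays on the observed 0/1 scale and is analysed
with the same linear model — the usual practice when a threshold model is
not wanted; its h² is therefore on the observed scale. Rank-invariance
under monotone maps is what makes heritability recovery on
link-transformed latents exact (section 5).

## 3. The animal model and REML

The numerator relationship matrix A is built by the tabular method;
A⁻¹ by Henderson's no-inbreeding rules (exactness checked against a dense
inverse; an inbred pedigree triggers a dense-inversion fallback with a
warning). A gene-dropping Monte-Carlo kinship estimator serves as an
independent oracle for A in the tests.

Fits use complete cases for the requested trait subset: univariate fits
for heritabilities and all pairwise bivariate fits for correlations. A
joint nine-trait fit with arbitrary missingness patterns identifies the
same parameters pair by pair but requires missing-data EM machinery that
adds nothing to the estimates reported here. Hatch date enters as a fixed
effect (first level absorbed in the intercept; redundant columns dropped
with a warning; the effect is dropped if only one level remains).

Estimation is EM-REML. Implementation: with one record per hen the
marginal covariance is `V = K ⊗ G₀ + I ⊗ R₀`, `K = A[phenotyped,
phenotyped]`. Eigendecomposing `K = U D U'` once and rotating phenotypes
and design by `U'` makes V block-diagonal (t × t per hen), so each EM step
— BLUPs, prediction-error variances including fixed-effect uncertainty,
and the closed-form updates of G₀ and R₀ — costs O(n t³). This is the
same restricted likelihood as mixed-model-equation EM-REML (the tests
verify agreement with a generic optimizer on an independently coded dense
restricted likelihood to 1e-3 on ≤ 300-record problems, and with the
closed-form balanced half-sib ANOVA to 1e-4); the restricted
log-likelihood is asserted monotone at every iteration. Convergence:
maximum relative parameter change < 1e-8 or 2000 iterations; starting
values put half the phenotypic variance in each component with zero
correlations. Near-singular G₀/R₀ updates are bent (eigenvalues clamped
at 1e-6, logged). Fits whose optimum sits on the |r_a| = 1 boundary
converge slowly by design of EM; the iteration cap returns the flagged
last iterate, which for such fits is within ~0.02 of the boundary optimum.

Standard errors come from a single average-information iteration at the
optimum: `AI_kl = ½ y'P V̇_k P V̇_l P y` over the variance parameters,
inverted and propagated to heritabilities and genetic/residual/phenotypic
correlations by a numerical delta method. The phenotypic correlation is
computed through the identity `r_p = h_i h_j r_a + e_i e_j r_e` (h, e the
square roots of the variance fractions), which for a two-component model
is algebraically the phenotypic covariance over the geometric mean of the
phenotypic variances.

## 4. Period analysis

Per-period three-trait fits (MLD, MDB, MDA) reuse the same REML engine on
the raw scale — within-period duration means are close to normal, so no
rank transform is applied, and the variance trajectories stay in minutes².
Periods with fewer than 50 complete-case hens are skipped.

The repeatability model adds a permanent-environment effect:
`y_hp = hatch + period + a_h + pe_h + e_hp`. It is fitted on balanced
complete cases (hens with records in every analysed period); the pedigree
eigenrotation between hens combined with an orthonormal within-hen
rotation whose first direction is the period mean diagonalises all three
covariance structures, giving closed-form scalar EM updates. The last
period is the reference level, so the period solutions are directly the
least-square-mean deviations from the final period (final period ≡ 0
exactly, SE 0). LS-mean standard errors come from the fixed-effect
covariance of the converged fit. Periods are compared with two-tailed
z-tests, `z = (m_p − m_q)/√(SE_p² + SE_q²)`, significant at |z| > 2.58
(α = 0.01), and summarised with a compact-letter display built by
insert-and-absorb (equivalent to the maximal cliques of the
non-significance graph; an exhaustive-enumeration oracle checks this in
the tests).

## 5. The synthetic flock generator

The generator emulates the recorded generation of a commercial layer
breeding program: ~99 sires × ~350 dams × 3 hens/dam (≈ 1000 recorded
hens, about ten per sire), one unphenotyped ancestor generation, 280
recording days from 24 weeks of age, 100–120 nests in two rows, two
hatch batches with small fixed shifts, uniform mortality hazard
(~7 % over the window, independent of the behavioural latents — mortality
exists only to exercise the survival filter), egg-sensor failure rates of
4.3 %/11.2 %, and non-laying visits at 0.3 visits/hen/day that no trait
may use. Sire-side and dam-side founders are disjoint pools, so every
mating is between unrelated parents and the pedigree is inbreeding-free —
matching the exactness condition of Henderson's A⁻¹ rules.

Each hen's behaviour is governed by eight latent parameters, each
`latent = mu + a + pe` on a Gaussian scale with a monotone link
(sigmoid for probabilities, exp for positive quantities):
pause and floor-egg logits, clock start (minutes after lights-on),
log clock lag (daily drift, min/day), log home-range width W (nests),
log favourite-nest count F, log total visit duration, and the logit
before-fraction of the visit. `a` is drawn over the pedigree (founders
MVN(0, G), descendants midparent + MVN(0, G/2) Mendelian sampling).

**Clutch mechanics.** The oviposition clock starts a clutch at
`clock_start`, advances `lag` min/day (floor days advance it too), and a
pause — forced when the clock passes `start + 360 min`, or spontaneous —
resets it. Spontaneous pauses are gated: they can only fire once the
clock has drifted more than `threshold + 4·lag + 25 min` past the start.
The gate is what makes the pause/floor classifier *exactly* testable: with
bounded (±10 min) entry jitter, every true pause produces a
backward reset strictly above the threshold even if up to three floor
days sit in the same gap, and every pure floor gap of ≤ 4 days produces a
shift strictly below it. Biologically it encodes that pauses interrupt
late, long-drifted clutches rather than day-2 clutches. Pauses are
single-day with probability 0.8, up to 3 days otherwise; hens begin the
window in the first 30 % of a clutch (point of lay).

**Nest choice.** A hen owns F favourite columns, evenly spaced across a
home range of width W placed uniformly within the pen; each laying day
she reuses the previous nest with probability 0.1, otherwise picks a
favourite uniformly and a row at random. Mean consecutive-day distance
(MDN) is then monotone in W, while the distinct-nest count (PNL) is
monotone in F — two distinct genetic channels. A single-latent
choice model (e.g. a Normal spread around a home nest) cannot represent
the published MDN–PNL genetic correlation of 0.85, because any two traits
driven monotonically by one latent are genetically correlated ±1;
the two-latent home-range/favourites model makes the true correlation a
free, exactly-known parameter: `cov(a_W, a_F) = 0.85·σ_aW·σ_aF`.

**Heritability targeting.** For each latent, σ²_a = h²·σ²_total with the
published heritability as h². Derived traits are monotone functions of
single latents averaged over ≥ ~150 daily records, so visit-level noise
attenuates the observable-scale heritability by well under 0.02
(documented approximation), and the rank-based inverse-normal transform
removes the link nonlinearity — together this makes the latent h² equal
the true observable-scale h² for REML to recover. The duration latents
are parameterised as (log total, logit fraction-before) precisely so that
MLD is a single-latent trait; MDB/MDA heritabilities are emergent. The
permanent-environment correlation between W and F is 0.684, back-solved
from the published phenotypic correlation (0.72) given the genetic
parameters.

**Calibration.** Preset latent means/variances were tuned by simulation
against published line summaries and then frozen: brown-line preset → mean
LRN ≈ 91.8 %, mean CN ≈ 4.2, NAL ≈ 91 %, MDN ≈ 7.6 nests, MLD ≈ 44 min;
white-line preset → mean CN ≈ 8.3, NAL ≈ 90 %. The clutch-number and
laying-rate anchors are matched within the recovery tolerances; the
nest-preference means are matched in order of magnitude only (the
home-range model trades exact PNL means for exact truth structure, and
PNL means are not a validation anchor). Durations carry a mild age curve
(rise to a plateau around period 3–6, slight late decline) plus per
hen×period lognormal shocks (SD 0.12), which give the period models
honest residual variance and LS-mean trends.

**What the generator does not emulate.** Gregarious nesting (choice
conditioned on occupancy — the independent-choice model is a deliberate
simplification, not a claim about hens), learned or age-dependent floor
laying, rooster effects, disease outbreaks (beyond an optional truncated
recording window per batch), multi-day sensor outages, and
double-ovulation days. Passing recovery tests therefore show that the
*estimation machinery* is calibrated and unbiased under the stated
genetic architecture — not that real nest-preference traits have these
heritabilities, nor that the clutch classifier is error-free when real
clocks drift non-linearly.

## 6. Problem sizes and runtimes

The validation protocols use the full study-scale design (~1000 recorded
hens, ~1950 pedigree entries, 280 days ≈ 290k visit records per flock):
five replicate flocks for parameter recovery plus one flock per line for
calibration, about 40 s in total on one CPU. The test suite runs the same
protocols plus module tests in under two minutes. Unit tests use a
150-hen, 24-week configuration of the same presets.

## 7. Known limitations

* Complete-case bivariate decomposition, not a joint 9-trait fit; the SEs
  of correlations between rarely-co-phenotyped traits are accordingly
  wider.
* NAL is analysed on the 0/1 scale; a threshold model would report
  liability-scale parameters.
* EM-REML near correlation boundaries converges slowly; estimates at the
  iteration cap are flagged rather than polished by a second-order step.
* The repeatability model requires balanced complete cases; hens with a
  missing period are dropped rather than absorbed.
* A single flock of this design carries an SE of ~0.07 on h² and ~0.10 on
  r_a; single-replicate estimates should be read with that in mind.
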