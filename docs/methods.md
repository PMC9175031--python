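# Methods

## The task and its encoding

Binocular rivalry arises when the two eyes receive incompatible images at
the same retinal location; perception alternates between the two images in
a continuous cycle.  When two spatially separated rivalry targets share a
feature (here, grating orientation), they tend to dominate together —
perceptual grouping — and the strongest grouping cue is eye of origin.  The
task encodes this with four dichoptic layouts crossing eye of origin
(same/different eye, SE/DE) with retinal location (same/different
hemifield, SH/DH), two counterbalanced variants each, plus a central
single-disc control: nine 60-s trials per observer.

`experiment_design` fixes the trial catalog as data.  Geometry defaults:
1.8° discs, 4 cycles/deg gratings, 0.2° separation gap, 0.5° fixation
cross, ±1° horizontal/vertical offsets (1.41° diagonal eccentricity).
Positions are seven named slots on a fixation-centered axis convention
(x rightward, y upward).  Counterbalance variant 1 assigns horizontal to
the left eye (and the left hemifield for SH conditions); variant 2 swaps
both.  The catalog is deterministic: serializing it twice is byte-identical.

## Timeline resolution

`event_stream` converts a two-channel press log into an exhaustive labeled
partition of trial time.  Conventions: seconds, closed–open intervals
[t_on, t_off), trial clock starting at 0.  Validation clamps intervals into
the trial window, sorts, and merges overlapping/adjacent same-button
intervals, recording each repair; reversed intervals, unknown buttons, or a
non-positive duration are rejected with the offending row.

Elementary press states map to percepts: exclusive left = grouped-H,
exclusive right = grouped-V, both = ungrouped, none = unreported.  A
both-pressed span shorter than `tau_overlap` that sits *between the two
different exclusive percepts* is relabeled TRANSITION: it is the motor
signature of the traveling dominance wave, when the new percept's button is
pressed before the old one is released.  The flanking requirement prevents
deliberate sustained both-presses (the ungrouped report in DE conditions)
from being eaten as transitions.  `tau_overlap` defaults to 0.4 s — the
overlap is a sub-second motor phenomenon, while deliberate ungrouped
reports last seconds; the threshold is configurable and `tau_overlap = 0`
disables the relabeling entirely.

Transition time is accounted in its own bucket, assigned to no percept,
because the wave is excluded from epoch calculations; the raw "both buttons
down" total remains recoverable as `t_ungrouped + t_transition` and is
exported for audit.  Dominance components always sum exactly to the trial
duration (partition conservation).

Switches are alternations of the two exclusive grouped percepts after
deleting all non-exclusive interludes, regardless of interlude length; a
finite `tau_gap` (default ∞) optionally breaks the dominance sequence
across long interruptions.  A mixed interlude between two same-orientation
dominance periods therefore does not create a switch, and the run-length
definition splits such an epoch pair into two.  The rivalry rate scales the
switch count to per-minute.  The mean dominance epoch divides grouped time
by the switch count — numerically identical, for 60-s trials, to dividing
by the per-minute rate, but well-defined for any trial length — and is NaN
(undefined, never zero) when no switch occurred.  The epoch difference
D = epoch(SE/DH) − epoch(SE/SH) is computed per participant after averaging
the counterbalanced trial pair within each condition.

## Synthetic observers

The generator is a semi-Markov renewal model with two layers.

**Latent layer.**  One rivalry zone drives the alternation clock: its
dominance durations are Gamma(shape k, mean μ) — the standard positively
skewed family for rivalry dominance durations; shape defaults to 3 — and
its dominant eye flips at every renewal.  The second zone re-couples at
each renewal: with probability c (`eye_coupling`) it adopts the driver's
new dominant eye, otherwise the opposite eye.  Each zone's percept is the
orientation its dominant eye sees at that location, so eye synchrony maps
to a grouped percept under SE layouts and to an ungrouped percept under DE
layouts — the eye-of-origin grouping effect with a single interpretable
parameter.  At c = 1, SE trials are 100% grouped and DE trials 100%
ungrouped; at c = 0.5 grouping is at chance.  With probability
`mixed_prob` a renewal passes through an exponential mixed interlude (mean
`mixed_mean`).  The central condition is a single zone.  The expected
switch rate is 60/(μ + mixed_prob·mixed_mean) per minute, up to the usual
O(1) renewal edge correction on finite trials.

A driver/follower scheme (rather than two independent renewal clocks with
coupling at each zone's own transitions) is deliberate: with independent
clocks, full coupling would freeze the joint percept — a zone that adopts
an eye both zones already share never changes the percept — so no single
parameterization could produce both full grouping and ongoing alternation.
The shared clock gives both, at the cost of perfectly simultaneous zone
transitions, which the motor layer then smears.

**Motor layer.**  Each latent boundary is delayed by a truncated-normal
press latency (0.35 ± 0.10 s); at each change between the two exclusive
percepts the old button's release is extended past the new press by a
truncated-normal overlap (0.15 ± 0.05 s), reproducing the transition-wave
signature the analyzer excludes; each dominance period is unreported
wholesale with probability `lapse_prob` (0.01).  With a noiseless motor
layer the button log reproduces the latent timeline exactly.

**Cohort defaults and calibration.**  The default cohort is 17 glaucoma
observers (age 61 ± 12) and 14 controls (age 53 ± 11), seeded
hierarchically from one master seed (fully reproducible, byte-identical
logs per seed).  The group difference is injected only through the mean
epoch — glaucoma slower — with all other parameters shared: the simplest
configuration consistent with matched dominance times but lower rivalry
rates in the patient group.  Calibrated defaults: μ = 3.8 s (glaucoma) vs
3.0 s (control), mixed_mean 2.8 vs 2.0 s, shared mixed_prob 0.17,
eye_coupling 0.93, between-subject spread of μ 0.6 s.  Under these
settings the same-eye conditions spend ≈ 0.79 of the trial in grouped
dominance (≈ 47 s, with ≈ 3.5 s ungrouped and ≈ 7 s mixed), rivalry rates
average ≈ 17.6/15.4 per minute for controls vs ≈ 13.5/11.8 for glaucoma in
the central and same-eye conditions, the group effect on the rate is
detected at α = 0.05 in ≈ 90% of replicate cohorts, and the condition
effect on grouped time in essentially all of them.

What the generator does *not* emulate: within-disc piecemeal structure
(mixed time enters only as whole interludes), hemifield asymmetries in
wave propagation (the latent model is symmetric, so per-group epoch
differences D center on zero rather than on the ±50–120 ms medians seen in
human groups), reaction-time autocorrelation, eye movements, and blinks.
With a single coupling parameter the different-eye conditions show ≈ 4 s of
grouped time rather than the ≈ 9–13 s human observers produce; the
SE-vs-DE contrast is therefore sharper in simulation than in data.
Passing tests demonstrate the pipeline's correctness and the qualitative
group/condition ordering, not quantitative agreement with any human cohort.

## Statistical battery

`stats_engine` implements the split-plot (mixed factorial) ANOVA in the
orthonormal-contrast formulation.  Between-subject design matrix: intercept,
sum-to-zero group contrasts (Type-III sums of squares; group sizes are
unbalanced), and the centered covariate when supplied.  The between test
runs on subject means.  For each within effect (one or two fully crossed
within factors), subject cell vectors are projected onto an orthonormal
contrast basis (Kronecker products for interactions); the within main
effect is the Type-III intercept test of the transformed scores, the
within×group interaction the test of the group columns, both against the
pooled residual with q·(N − p) error df.  When a covariate is supplied it
stays in the model for the within strata as well, matching standard GLM
software: with 31 subjects, two groups, age, and a 3-level factor the
within tests run on (2, 56) df and the group test on (1, 28).

Greenhouse–Geisser ε is estimated per within effect from the pooled
within-group residual covariance of the contrast scores,
ε = (tr S)²/(q·tr S²), clipped to [1/q, 1]; it is exactly 1 at two levels
and under compound symmetry.  Raw and ε-corrected dfs/p are always reported
side by side, with Mauchly's W and its χ² p as auxiliary diagnostics, since
the sphericity-screening rule is a reporting choice, not a computation.
Partial η² = SS_effect/(SS_effect + SS_error) = F·df₁/(F·df₁ + df₂), an
identity that holds unchanged under the ε rescaling.  Degenerate inputs
(constant response, zero error variance, missing cells) raise errors naming
the offending subject or stratum rather than returning numbers.

Elementary procedures: pooled-variance independent t (df = n₁+n₂−2) with
Cohen's d = t·√(1/n₁+1/n₂); paired t with d = mean difference over SD of
differences; Mann–Whitney U in the min-U convention with mid-ranked ties,
exact two-sided p for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise; Bonferroni (raw p × number of comparisons, capped
at 1) or LSD pairwise follow-ups; Pearson r with the t-transform p.

## Pipeline and reports

`pipeline_io` reads/writes all tables as UTF-8 CSV with explicit headers,
'.' decimals, shortest-round-trip float formatting, empty cells for missing
values (never sentinels), and a provenance comment line (config hash, seed,
package version) at the top of every output.  `run_pipeline` executes
validate → resolve → metrics → aggregate → stats → report deterministically,
and audits itself at report time by recomputing every summary cell from the
emitted per-participant table.  Problem sizes everywhere default to the
study design (31 participants × 9 × 60-s trials); the test suite's
Monte-Carlo checks use 100–1000 replicates of trials or cohorts, sizes at
which the renewal edge bias and sampling error stay within the stated
tolerance bands.

## Known limitations

* Whether a recorded "both buttons pressed" total should include transition
  overlaps is a convention; both accountings are exported rather than
  guessed at.
* The MO DE/SH layout follows the figure-derived position/eye assignment;
  the eye-by-position wording for that condition is internally inconsistent
  in the source description of the task.
* The epoch difference D is highly variable by construction (a difference
  of ratios of noisy quantities); its group comparison is reported with the
  distribution-free U test and a five-number summary, not a t-test.
* No eye-movement or blink artifact rejection, no reaction-time
  deconvolution, no streaming operation.
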