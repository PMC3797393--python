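# Methods

## The measurement model

A trial is a CV syllable sequence of length n ∈ 1…5 drawn from a nested
six-series inventory (the length-k item of a series is its length-(k+1)
item truncated). The chronometric unit is the inter-syllable interval
(ISI): the time from one syllable's consonant onset to the next syllable's
consonant onset, so an n-syllable trial yields n−1 ISIs and length-1
trials yield none. Sequence-final information is never used on its own:
the last syllable contributes only the onset that closes the (n−1)-th
interval.

For obstruents the consonant onset is the release burst — the acoustic
event the high-pass detection pathway monitors — not the closure start;
for nasals and fricatives it is the onset of murmur or frication. Vowel
onsets and offsets bound the syllable nucleus and define the search
windows for consonant onsets.

## Landmark segmentation

Per sound class the signal is reduced to a one-dimensional trajectory:

| pathway | trajectory | hop | derivative scale σ |
|---|---|---|---|
| vowel | dB energy in the speaker's F1 band (5th-order zero-phase Butterworth) | 2 ms | 20 ms |
| nasal | dB energy, 60–500 Hz band | 2 ms | 10 ms |
| stop/affricate | dB energy above 2 kHz | 1 ms | 5 ms |
| fricative | first spectral moment, 12 ms windows stepped 4 ms | 4 ms | 10 ms |

Energy envelopes are 10 ms sliding RMS converted to dB re the trial's
envelope maximum (amplitude-scale invariance) and clipped at a −30 dB
floor. The floor is a timing parameter, not cosmetic: zero-phase filtering
spreads a small fraction of onset energy backward, and on a log scale that
sub-−30 dB tail advances the derivative peak of an onset by more than
10 ms; clipping at −30 dB centres the measured rise on the true amplitude
ramp. Each trajectory is differentiated by convolution with a
first-derivative-of-Gaussian kernel (±4σ support, reflective boundaries);
σ is matched per class to the rise time of the event the pathway detects
(a release burst is faster than a vowel onset; a nasal murmur attack is
~5 ms, hence σ = 10 ms there).

Vowel landmarks solve a small combinatorial problem exactly: choose the n
positive peaks of the vowel derivative maximising total height subject to
a negative valley strictly between consecutive selections and one after
the last (dynamic programming over candidate peaks; ties break to the
earlier peak). The vowel offset is the deepest valley in the span after
each selected peak. The k-th consonant onset is then the largest positive
peak of its class trace inside (vOff_{k−1}, vOn_k), the first window
starting at the trace origin. The centroid pathway gates windows whose
RMS sits more than 35 dB below the loudest window — and requires three
consecutive supra-gate windows — so frication onsets rise from zero
rather than from a noise floor.

Quality control replaces the original two-stage human review: windows for
stop/affricate onsets containing two peaks within a 0.7 height ratio
separated by ≥15 ms are flagged `ambiguousRelease` (the double-release
signature); unfillable landmark slots are flagged `missingLandmark`; and
landmarks whose derivative peak falls below the trial's 10% prominence
quantile are listed in an audit log. Flagged trials are excluded from both
ISI and error tabulations.

Speaker F1 calibration uses the first 25 trials of runs 1 and 5. Vowel
frames are gated by energy in the 500–1200 Hz region that also dominates
the 60–450 Hz band (the ratio test rejects nasal murmurs, which would
otherwise drag the band down to the murmur resonance); per frame, F1 is
the lowest sharp root (bandwidth < 150 Hz, 350–1200 Hz) of a
linear-prediction polynomial of order fs/1000 + 2 after pre-emphasis;
per-trial medians are summarised as min/max across trials widened by a
±10% guard.

## The synthetic-audio generator

Synthesis is deliberately minimal source-filter: a Gaussian-smoothed
impulse train (f0 = 120 Hz default) or white noise through second-order
resonators and Butterworth bands. Segment durations (× a per-speaker rate
scale): burst 15 ms, stop aspiration gap 45 ms, affricate frication
40 ms, fricative frication and nasal murmur 70 ms, vowel 130 ms, default
inter-syllable gap 60 ms — yielding default ISIs in the 205–260 ms range
before rate scaling, in the region typical for these groups. All segment
joins carry 5 ms amplitude ramps; ground truth is the ramp start. An ISI
plan, when supplied, fixes onset-to-onset times exactly (minimum
feasibility gap 10 ms).

What the generator emulates: class-segregated spectra (each phone's
dominant band is the band its detector monitors), speaker differences in
F1 and rate, additive noise at a controlled SNR, and the double-release
artifact (a second, comparable-amplitude burst before the vowel). What it
does not emulate: coarticulation, prosody, f0 movement, vowel reduction,
voice-quality pathology, or a vowel voice bar — vowels are high-passed at
400 Hz so the nasal band stays class-exclusive. Passing the recovery
suite therefore shows the algorithm is correct under clean class-correct
spectro-temporal structure; it does not certify performance on real
dysarthric speech, where stage-two review exists for a reason. A known
soft spot inherited from the design: low-centroid fricatives (/v/) under
broadband noise, where the fading-vowel-plus-noise mixture can imitate a
centroid rise inside the search window.

## The chronometric simulator

Trial-mean ISIs follow a linear mixed model: baseline (anchored at length
2, run-centred) + speaker intercept N(0, 25 ms) + length slope × (n−2) +
run slope × (r−3) + residual N(0, 30 ms). Error outcomes are Bernoulli
with probability (baseline 0.08 at length 1 + length slope × (n−1) + run
slope × (r−3)) × a mean-one log-normal speaker severity (log-SD 0.3),
clipped to [0.001, 0.999]. Two structural choices matter:

* the run predictor is centred at run 3, so baselines are run-averaged
  and noiseless fits reproduce them exactly;
* speaker heterogeneity in the error model is a mean-one multiplicative
  severity rather than a logit intercept: a logit-scale intercept changes
  expected cell rates nonlinearly and biases recovered slopes by ~1%,
  which a 200-replicate recovery harness can resolve; the multiplicative
  form is slope-unbiased by construction while keeping probabilities
  valid. The 8% baseline keeps the additive linear predictor inside
  (0, 1) over the whole 5 × 5 design for every preset, so the clip never
  binds in the nominal model.

Group presets encode the documented effect sizes (healthy 14 speakers:
4.9 ms/syllable, −3.2 ms/run, +5.0 %/syllable, −1.1 %/run; hypokinetic 8:
12, −3.5, +8.2 %, −1.9 %; ataxic 5: 0, 0, +6.3 %, 0) plus group mean-ISI
offsets of 0/76/88 ms over a 230 ms healthy baseline (hence 230/306/318).
Practice slopes are stored signed (negative = speeding up); summaries
report magnitudes. Undocumented fields (baselines, SDs) are package
defaults chosen to put simulated means in a realistic range; they are not
fitted to anything and are configurable.

## Statistics

Length and practice effects are linear mixed models on per-speaker cell
means with a fixed intercept and slope and a per-speaker random intercept
(statsmodels MixedLM, REML). Predictor coding anchors the intercept at
length 2 (ISI), length 1 (errors) or run 1 (practice). The slope p-value
uses a t reference with residual df = n_obs − n_fixed, reported alongside
the df so the convention is explicit. Singular or non-converged mixed
fits fall back to OLS on the same cell means with a diagnostic note; for
the balanced designs used here the fixed-effect point estimates coincide,
which is also why noiseless data reproduces generative coefficients to
machine precision. Error-rate effects are fitted on both the arcsine
scale (variance-stabilised) and the raw percentage scale; percentage
slopes are the reported effect sizes. Two-group comparisons add a group
main effect and group × predictor interaction (the slope difference).
Group-level means are compared by one-way ANOVA with Bonferroni-corrected
pairwise post-hocs, replaced by Kruskal–Wallis when Levene's test rejects
variance homogeneity at p < 0.05; the Bonferroni threshold is 0.05/k for
k tests.

## Problem sizes and numerical conventions

The recovery harness uses 200 replicates of the full 300-trial session
per group; with trial-level residual SD 30 ms, per-cell means average 60
trials, putting Monte-Carlo standard errors of mean recovered slopes near
0.03–0.07 ms, far inside the 10% design tolerance. Type-I calibration of
the zero-slope length test uses 1000 simulations of the ataxic preset
against the Bonferroni α = 0.05/3. Landmark validation sweeps all 30
stimuli across four speaker profiles (120 clean trials). Times are
milliseconds throughout; grids are half-open [t, t+hop) with the landmark
at the derivative-peak grid point; all randomness flows from a single
integer seed per entry point, with per-replicate child seeds below 2³¹.

## Known limitations

* The synthesizer's idealizations (above) make the clean recovery bounds
  easier than real speech; the noise-robustness property (≤2× degradation
  at SNR 30 dB) is the only stress the suite applies.
* The error-coding cascade fixes an order for overlapping criteria
  (markers → alignment → features → perseveration); other orders are
  defensible and would change multi-error code lists, though not the
  error/no-error decision that drives the rate analyses.
* Mixed-model df conventions differ across packages; reported t and p
  values are comparable across fits within this package, not across
  software.
* The ataxic preset treats null reported effects as exactly zero slopes.
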