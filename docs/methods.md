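# Methods

This note documents the models, defaults and numerical choices behind
`gazenum`, and what the synthetic-data experiments do and do not show.

## Stimulus battery

36 items: numerosities 1–9, each in one canonical and three random
arrangements. Geometry models a 24″ 16:9 full-HD screen viewed at 60 cm:
1920/53.1 ≈ 36.1 px/cm, dot diameter 2 cm ≈ 72 px, maximum pattern span
15 cm ≈ 542 px per axis, pattern bounding box centered on the screen
center. Canonical layouts 2–6 are the standard dice faces; 7–9 are
symmetric extensions (dice-six plus a center dot; two columns of four; a
3×3 grid). Coordinates are 0-based screen pixels, origin top-left.

Random arrangements are rejection-sampled under: pairwise center
distance ≥ 1.5 dot diameters (no touching, with clearance), bounding box
between 55% and 100% of the maximum span per axis, and fewer than half
of the dots within 1.6 dot diameters of the dot centroid. The span and
center-clearance constraints are package choices: they keep random
patterns in the visually filled, center-sparse regime of typical
enumeration stimuli; without them, degenerate tiny or centrally crowded
patterns arise in which the three enumeration processes produce nearly
identical gaze distributions and no analysis (human or automatic) could
separate them. Sampling is deterministic per (numerosity, seed) and
aborts with an error after a bounded number of attempts.

Analysis conditions partition the battery: subitizing range (2–4 random,
9 items/participant), counting range (5–9 random, 15), dice range (2–6
canonical, 5), beyond-dice range (7–9 canonical, 3); the four 1-dot
items are excluded (enumeration processes only differentiate from 2
dots), leaving 32 analyzable items per participant.

## Synthetic gaze generator

Each trial draws a latent process from the participant group's
per-condition mixture and generates fixations accordingly:

* **Simultaneous** (type 1): 1–2 fixations at the dot centroid, total
  duration U(300, 600) ms.
* **Groups/structures** (type 2): the dots are split into 2–3 spatially
  contiguous subgroups (contiguous chunks along a random projection
  direction); one fixation per subgroup centroid, U(200, 350) ms each.
  Candidate partitions are re-drawn (bounded retries) until fewer than
  half of the dots lie within 115 px of any subgroup centroid, so that
  group-wise gaze rests between dots rather than on them; for fewer than
  3 dots no meaningful subgroup exists and the trial falls back to
  simultaneous (logged, and recorded as the executed process).
* **Counting** (type 3): serial fixations on m ~ U{⌈n/2⌉, …, n} dots in
  left-to-right, top-to-bottom scan order, U(180, 300) ms per dot.

Fixation positions carry isotropic Gaussian noise, default σ = 38 px
(≈0.9° visual angle at 60 cm — the accuracy class of a screen-mounted
eye tracker). Durations are irrelevant to clustering after per-trial
intensity normalization; their ranges only keep heatmaps realistic.
Gaze originates at the inter-trial fixation star in the screen center,
but the star period is not part of the trial recording, so sequences
contain task fixations only. Responses are incorrect with a
per-condition error rate, default 9% — matching the scale of trial loss
in the emulated study design (227 participants → 7,264 analyzable trials
→ ~6,615 usable after the correctness filter). The default group
profiles make group "dhh" lean toward (quasi-)simultaneous enumeration
in the subitizing, counting and dice conditions, with identical behavior
beyond the dice range; the proportions are package choices mirroring the
direction, not the magnitude, of the emulated effects.

A counts-level path (`simulate_type_counts`) draws the per-condition
process-by-group tables directly (binomial trial loss + multinomial
mixtures) for calibration experiments that do not need rendering.

## Heatmaps

Per fixation, an isotropic Gaussian kernel (default σ = 50 px, truncated
at 3σ) weighted by fixation duration is accumulated on the 1,920×760
band (the vertically centered strip of the 1,080-row screen). The field
is normalized so the hottest cell maps to full scale — scaling all
durations cancels — and colorized on a red–green table, R = 255t,
G = 255(1−t), B = 0. Each channel is affine in intensity, so the
Rec. 601 grayscale used for reduction is affine in intensity too and
Euclidean distances on reduced images are proportional to distances on
the underlying fields; the red channel doubles as an exact intensity
readout (and survives prototype recoloring). The kernel default keeps
single-fixation blobs far wider than one reduced-image cell, so no
fixation is lost in subsampling.

Reduction: grayscale, then area-weighted block averaging to 160×90
(1920/160 = 12 columns exactly; 760/90 fractional rows handled by
overlap-weighted bins; constants preserved exactly). The scalar count
drops by 1920·760·3 / (160·90) = 304.

## SOM clustering

One self-organizing map per item, both groups pooled: six prototypes on
a 3×2 grid (three expected processes plus spare nodes for outliers or
process subvariants). Online Kohonen training: each presented heatmap
pulls its best-matching prototype toward it, grid neighbors follow with
Gaussian weight exp(−g²/2r²) of grid distance g. Two-phase schedule,
conventional toolbox defaults: ordering (100 epochs, learning rate
0.5→0.05, radius 2→1) then tuning (200 epochs, 0.05→0.01, radius 1→0),
both config-exposed; the fixed schedule is the stopping rule (a proxy
for prototype movement ceasing). Prototypes initialize as small seeded
perturbations (σ = 5% of input spread) around the input mean; results
depend on initialization and presentation order, so both derive from an
explicit per-item seed and runs are bit-for-bit reproducible. Ties in
assignment break to the lowest cluster index; empty clusters are legal
and simply produce no prototype. Full-size prototypes are pixel-wise
means of member heatmaps, computed from the originals (clustering runs
on reduced images for speed only).

## Process typing

Features of a heatmap (or prototype) relative to its stimulus, all in
[0, 1]:

* `covered_dot_fraction` — share of dots with intensity ≥ τ × field max
  within r_d of the dot center;
* `central_mass_fraction` — share of total intensity within r_c of the
  dot centroid;
* `side_asymmetry` / `top_bottom_asymmetry` — normalized mass imbalance
  about the centroid axes (exposed for custom rules and manual review;
  unused by the default precedence).

Rule: **counting** if at least half the dots are covered; else
**simultaneous** if central mass ≥ θ_central; else **groups**. In the
counting range, type 1 is reported as "quasi-simultaneous".

Defaults: r_c = 1.5 dot diameters, r_d = 0.5 dot diameters (the dot's
own radius), τ = 0.45, θ_central = 0.5. The verbal criteria leave these
free; they were calibrated once against the synthetic generator so that
prototype typing recovers latent processes from noisy synthetic data.
The coverage radius and τ are deliberately strict: a Gaussian blob
centered between two dots (the groups signature) must not register as
covering them, while a blob centered on a dot always does — with a loose
radius/threshold, groups trials systematically misread as counting.
Typing applies to cluster prototypes (expert workflow), each trial
inheriting its cluster's type; a per-trial mode exists for validation,
and a manual-override CSV takes precedence over the automatic types,
replacing the two-rater review.

## Group statistics

Per condition, the 3×2 process-by-group table gets a Pearson chi-square
with df = k−1 and no continuity correction (expected counts below 5
raise a warning flag, not a switch to an exact test). Effect size is
Cramér's V with Cohen's df-specific benchmarks (df=1: 0.10/0.30/0.50;
df=2: 0.07/0.21/0.35; other df require explicit thresholds). When the
omnibus p < α (default 0.05), each process is followed up with a 2×2
cell test (this process vs. pooled others, by group), Bonferroni-adjusted
by the family size (default ×3); the direction names the group whose
observed count exceeds expectation. The four omnibus p-values are
reported without family-wise adjustment by default; α is configurable.
A collapsed cell table with a zero margin is flagged untestable rather
than tested.

## Calibration experiments and problem sizes

The acceptance script (`scripts/acceptance.py`) and the heavier tests
use these sizes, chosen to estimate rates with useful precision at
desk-scale runtimes:

* **Latent-process recovery**: one synthetic cohort of 24+24
  participants (test suite: 18+18), ~1,300 analyzable trials after
  filtering, full render → reduce → per-item SOM → prototype-typing
  route. With the defaults above, recovery is 92–94% with Cohen's κ
  0.88–0.90 across seeds (premise: ≥90%, κ ≥ 0.8). Remaining loss is
  roughly half cluster impurity (a six-node map occasionally merges a
  small process subpopulation into a neighboring cluster) and half
  prototype-feature ambiguity on items whose geometry makes processes
  genuinely similar.
* **Type-I error**: 500 counts-level cohorts of 30+30 participants with
  identical group profiles; rejection rate of the omnibus test pooled
  over the four conditions ≈ 0.045–0.053 at α = 0.05.
* **Power**: 200 counts-level cohorts with the type-1 mixture
  probability shifted by 0.15 in one group; the rejection rate is
  evaluated in the counting-range condition (15 items/participant, the
  largest per-cohort sample; rate ≈ 1.0; the subitizing range gives
  ≈ 0.88). The canonical conditions contribute only 5 and 3 items per
  participant and cannot carry a high-power requirement at this cohort
  size.
* **Determinism**: the demo pipeline (4+4 participants, shortened SOM
  schedule 20+40 epochs) runs twice under one seed; all result files
  must be byte-identical.

## What the synthetic experiments show — and what they do not

The generator produces exactly the latent structure the analysis
assumes: unimodal-to-trimodal Gaussian gaze fields, process-pure trials,
independent trials within participants, and a response-error process
independent of gaze. Passing the recovery and calibration checks
demonstrates that the pipeline is internally consistent — it recovers
the structure it was designed to detect, at realistic noise — and that
the statistics are correctly calibrated for multinomial sampling. It
does **not** demonstrate performance on real eye-tracking data, where
fixation detection errors, drift, off-stimulus gaze, mixed or switching
strategies within a trial, and participant-level correlation all exist.
The published large-scale statistics of the emulated study are not
reproducible here because its raw gaze recordings are not deposited;
the published dice-five table and marginal counts are used as fixed
reference inputs for arithmetic checks only.

## Known limitations

* The SOM cluster count (3×2) is fixed by design; alternative grids are
  config-level changes but unexplored.
* The typing rule is a hard precedence over three features; prototypes
  mixing processes get a single label, and ambiguous clusters are
  resolved only via the manual-override table.
* Durations are uniform draws, not fitted to empirical fixation-duration
  distributions; they do not affect clustering after normalization.
* Ingested real data must already be fixation-parsed; no raw-gaze event
  detection is included.
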