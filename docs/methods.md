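# Methods

This note documents the model behind the package: what is simulated, which
knobs matter, how the defaults were chosen, and what passing tests do and do
not establish about the real experiment the pipeline emulates.

## 1. The image space

Stimuli are rendered from a two-layer parametric description over K = 16
synthetic texture classes. Each class owns a colored mean texture and
D_z = 12 achromatic cosine-grating basis functions on a 64×64 grid; a latent
vector `z` (entries bounded by the truncation parameter, default 2.0) sets
the basis coefficients. The composite is
`(1−α)·base + α·overlay`, computed per pixel before clipping to [0, 1].
Rendering is a pure function: identical parameters give bit-identical
rasters on any platform at IEEE-754 double precision.

**Perturbation magnitude.** A random perturbation of a seed keeps the
seed's base layer, draws a random overlay supported on non-seed classes
(sparse Dirichlet, concentration 0.2 — a dense mixture over all classes
collapses onto the class centroid and makes all perturbations look alike),
and solves the transparency α so that the fraction of effective
class-weight mass leaving the seed's dominant class equals the requested
magnitude exactly. `measure_magnitude` is the inverse: the relative loss of
effective mass on the seed's dominant class, clipped to [0, 1]. The
round-trip is exact for single-layer seeds, so the ±0.02 Monte-Carlo
tolerance used in tests is conservative.

**Mutation.** Children jitter the parent with Gaussian noise of scale
0.3·spread on both latent vectors and 0.05·spread on α, and resample class
weights from a Dirichlet centered on the parent with concentration
1/spread. The default spread (0.35) moves a rendered child by roughly one
magnitude-grid bin (0.1) in measured feature distance. The 2–6 children
bound is treated as a hard contract and asserted.

**Reconstruction.** `reconstruct_target` is a (1+1) hill climb on pixel
RMSE with geometric step decay (0.97 after every 20 consecutive
rejections). Self-reconstruction of rendered targets reaches RMSE
0.025–0.04 within 4000 iterations; 0.05 counts as success.

## 2. The synthetic observer

The observer stands in for the animal. Its private feature map F_obs
projects pixels onto 16 smooth random fields (Fourier modes up to order 3
per channel, unit-normalized rows, global gain 0.28). The optimizer's
extractor (a 32-filter Gabor energy bank) shares nothing with it, so
percept recovery must cross feature spaces, as it does between a brain and
a generic pretrained network.

**Stimulation percept.** Each site carries a hidden template `s` in
observer space with `‖s‖ = 0.4·intensity^0.5` (normalized feature units;
intensity in mW, operating range 1–11). The direction of `s` depends on the
seed being fixated: when a site is attuned to a set of seeds, the per-seed
direction is the observer-feature direction of one concealed random
perturbation of that seed (magnitude 0.6) — a "to-be-discovered
perceptogram". This choice is load-bearing. If instead `s` is an arbitrary
random axis of the 16-dimensional percept space, the best alignment any
image perturbation can reach is ≈ 0.6, the quoted selection thresholds
(FA > 50%, miss < 5%, stop at 60%) become jointly unreachable, and no
campaign converges. Tying the percept to an achievable image change encodes
the premise that stimulation induces an image-like perceptual event — the
premise that makes perceptography possible at all — while keeping the
template invisible to the optimizer (enforced by a tracing test).

**Decision rule.** Evidence combines three factors — alignment, magnitude
match, and salience:

```
e = cos(p, s) · exp(−(‖p‖−‖s‖)²/(2σ_m²)) · ‖p‖/(‖p‖+k)
```

with σ_m = 0.45·‖s‖ and k = 0.5·‖s‖. On stimulated trials the component of
`p = d + s` parallel to `s` is compressed above ‖s‖ by factor β = 0.2. The
response is "stimulated" iff `e + ε > c` with ε ~ N(0, 0.08) and criterion
c = 0.49; a 2% lapse replaces the response with a coin flip; 5% of trials
abort.

**Calibration.** The defaults were fixed once, by parameter sweep at design
time, against four behavioral anchors: (i) baseline FA of a few percent,
(ii) an interior maximum of FA versus perturbation magnitude, (iii) a
selection gradient — FA rising steeply with alignment near the threshold so
behavioral selection carries signal, and (iv) stimulated detection robust
enough that well-aligned images survive the strict miss gate. The feature
gain 0.28 places a mid-magnitude perturbation's percept change at the 3 mW
template norm and a full-magnitude one ≈ 1.7× above it, which produces the
interior FA maximum (too little overshoot puts the FA peak at the grid
edge). Two anchors could not be met simultaneously with the rest and were
deliberately let go: the simulated sweep's peak FA (~30–45%) and the
session miss rate over a uniform-magnitude stimulated pool (~40–65%) are
both higher than the corresponding animal operating points, because with
this evidence form a large screen perturbation necessarily masks the
stimulation percept. All *ordering* properties (miss strictly decreasing in
intensity, FA collapse under context swap, hit-rate boost for aligned
perturbations) hold regardless.

## 3. Trial engine

Sessions present balanced schedules: every scheduled image appears equally
often with and without stimulation (the balancing that removes all
image-only cues), each at least 5 times per condition; stimulated flags are
fair overall. Dilution mixes 50–80% fresh non-optimized images into every
evolution session. Aborted trials are logged, excluded from every
denominator, and reinjected at a uniformly random future position (10
retries, then dropped with a warning). Stimulus timing (400/150/450 ms,
3.5 s timeout) is recorded as metadata only. Rates are computed over
completed trials; a zero denominator yields a missing rate, never 0.

A scheduling refinement: family members born in later iterations receive
extra presentation pairs until their cumulative count catches up with the
stopping-rule requirement (≥ 12 non-stimulated presentations), capped at
2× the per-session minimum. Without this, a mediocre founding image could
be declared the perceptogram simply because its better children were not
yet eligible.

## 4. Optimizer

Selection, survival, and stopping use the quoted thresholds verbatim and
strictly: FA > 0.5 AND miss < 0.05 per image for selection; pooled family
FA > 0.5 for survival; FA ≥ 0.6 over ≥ 12 non-stimulated presentations for
the win, with ties broken by presentations then id. "Most common feature
vectors" is operationalized as a 10%-trimmed per-dimension mean (the AFP).
New images are proposed by mutating a family's best member 10× the needed
count and keeping the children nearest the AFP in optimizer-feature space.
New families may be founded in any iteration from any selected image not
already in a family; active families are capped at 12. If no image is ever
selected, the magnitude grid for fresh pools is re-centered on the
empirical FA-versus-magnitude peak.

Default desk-scale budget: 5 seeds × 100-image pools, 5 presentations per
condition per session, up to 5 iterations, dilution 0.5 — about 7,000–20,000
simulated trials and a few seconds per campaign. Full-scale pools
(400–1000 per seed) are reachable through the config.

## 5. Metrics

The Fréchet feature distance between two sets fits a Gaussian to each and
evaluates `‖μ_a−μ_b‖² + Tr(Σ_a+Σ_b−2(Σ_aΣ_b)^{1/2})`. Covariances are
regularized with ε = 10⁻⁶·trace/dim (pool sizes of 10–100 in ≥ 16
dimensions are rank-deficient); the trace of the matrix square root is
computed from the symmetric form `Σ_a^{1/2} Σ_b Σ_a^{1/2}` via
eigendecomposition with negative eigenvalues clipped — symmetrizing the
plain product Σ_aΣ_b instead changes the value whenever the covariances do
not commute and fails the textbook-formula oracle. Single images enter
set-level distances as a tight deterministic cloud around their feature
vector. Class-normalized distances divide by the running class maximum;
reports use the two-pass (global maximum) mode, the streaming mode exists
for live campaigns. Motion energy is defined as the summed mean-squared
frame difference (the source procedure names the measure but not a
formula). The bootstrap null holds the observed number of false alarms
fixed and reassigns them uniformly without replacement across all completed
non-stimulated presentations, recording each replicate's maximum pooled
family FA rate; an exhaustive-enumeration mode serves as the exact oracle
on small instances.

## 6. What the synthetic loop does and does not show

The generator emulates: the class/latent/truncation/transparency
parameterization of a generative image engine; behavior whose false alarms
carry graded information about a hidden, seed-dependent, intensity-scaled
percept; the procedural constants of the published loop (pool sizes,
presentation minima, selection/survival/stopping thresholds, dilution,
family sizes). A passing recovery test shows the *procedure* is sound: the
selection rules, bookkeeping, and evolutionary loop can extract a hidden
percept direction from behavioral mistakes alone, across distinct feature
spaces.

It does not show anything about cortex. There is no neural dynamics, no
learning or untraining in the observer (dilution is preserved as a
procedure-fidelity feature only), no eye movements, no response-time
structure, no photorealistic images, and the percept-combination rule
(additive with compressive saturation) is one consistent choice rather than
an empirical fact. Campaigns here typically converge in 2–3 iterations
because a 16-dimensional linear percept is radically easier to search than
a monkey's; the convergence curve correspondingly has few points.

## 7. Reproducibility

Every stochastic operation takes an explicit generator. A campaign derives
independent streams (image generation, scheduling, decisions) from the
master seed; site identity and the observer's feature map derive from it
too, so replicate campaigns with different master seeds test different
hidden percepts. Checkpoints serialize the complete state including
generator states and resume bit-exactly (asserted by test). The acceptance
script (five replicate campaigns paired over 1 vs 3 mW, sweep, bootstrap,
context control, reconstruction) runs in about half a minute on one CPU.
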