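# perceptography

A desk-scale, fully synthetic implementation of *perceptography*: a
closed-loop experiment that evolves image perturbations until one becomes
behaviorally indistinguishable from the percept induced by local cortical
stimulation. In the original experiments the observer is a macaque
performing a cortical-perturbation-detection (CPD) task; here the animal is
replaced by a synthetic signal-detection observer with a hidden per-site
"stimulation percept", so the entire loop — image generation, behavioral
sessions, evolutionary optimization, and the statistical analyses — runs in
seconds on one CPU and can be verified by parameter recovery.

## Who this is for

Researchers in closed-loop visual psychophysics and adaptive stimulus
optimization who want a runnable, testable model of the
false-alarm-driven evolutionary search: to study its convergence behavior,
to prototype alternative selection rules, or to teach how behavioral
mistakes can be used as an optimization signal.

## The model

**Task.** Each trial shows seed → perturbed image (150 ms) → seed. On half
of the trials, randomly chosen, a simulated cortical site is stimulated
during the perturbation frame. The observer reports "stimulated" or "not
stimulated". A *false alarm* (FA) is a non-stimulated trial reported as
stimulated; a *miss* is a stimulated trial reported as non-stimulated.

**Observer.** A private smooth linear feature map `F_obs` projects images
into a 16-dimensional percept space. The percept change on a trial is
`p = F_obs(perturbed) − F_obs(seed)`; stimulation adds a hidden template `s`
whose norm grows with optical power, `‖s‖ = a·I^γ` (defaults a = 0.4,
γ = 0.5), followed by compressive saturation of the component parallel to
`s`. The decision evidence is

```
e = cos(p, s) · exp(−(‖p‖−‖s‖)² / 2σ_m²) · ‖p‖ / (‖p‖ + k)
```

and the observer reports "stimulated" when `e + ε > c` with Gaussian
decision noise ε, plus lapses and aborts. FAs therefore concentrate on
perturbations that match the stimulation percept in *direction and
magnitude* — the signal the optimizer feeds on.

**Optimizer.** The loop scores every image from behavior, selects images
with FA > 50% and miss < 5%, averages their features (in a separate
Gabor-bank feature space — the optimizer never reads `s`) into an
average-feature-prototype (AFP), mutates surviving images into families of
2–6 children sprayed around the AFP, dilutes them 50–80% with fresh random
images, and stops when an image sustains ≥ 60% FA over ≥ 12 non-stimulated
presentations. That image is the *perceptogram*.

## Worked example

```python
from perceptography import Campaign, CampaignConfig, percept_alignment

config = CampaignConfig(master_seed=1)          # 5 seeds, pool 100/seed, 3 mW
campaign = Campaign(config).run()

score = campaign.winner_score()
seed_id = campaign.store.seed_of[campaign.winner]
alignment = percept_alignment(
    campaign.observer, campaign.site,
    campaign.store.raster(seed_id), campaign.store.raster(campaign.winner),
)
print(f"winner FA rate  : {score.fa_rate:.2f} over {score.n_nostim} presentations")
print(f"percept alignment: {alignment:.3f}")
```

Output:

```
winner          : img_000445 (family of seed seed_04)
iterations      : 2
behavioral trials: 7566
winner FA rate  : 1.00 over 15 non-stimulated presentations
percept alignment: 0.949
```

The campaign found an image whose every non-stimulated presentation was
reported as "stimulated" (FA = 1.00 over 15 presentations), and whose
percept change points within 18° (cosine 0.949) of the hidden stimulation
template — although the optimizer only ever saw trial outcomes, never the
template, and operates in a different feature space than the observer.

## Command line

```bash
perceptography run --config campaign.yaml --out out/        # full campaign
perceptography resume --checkpoint out/checkpoints/checkpoint_001.json --out out2/
perceptography sweep --config campaign.yaml --out sweep.tsv # FA vs magnitude
perceptography bootstrap --checkpoint out/checkpoints/final.json --out boot.json
perceptography report --checkpoint out/checkpoints/final.json --out report/
perceptography reconstruct --target photo.png --out recon/  # engine fidelity
```

Exit codes: 0 success, 2 validation error, 3 no convergence, 4 I/O error.
Every run writes a manifest (config hash, master seed) sufficient for
bit-exact replay; campaigns checkpoint each iteration and resume exactly.

## Layout

| module | contents |
| --- | --- |
| `perceptography.image_space` | parametric two-layer texture generator: render, perturb, mutate, reconstruct |
| `perceptography.observer` | synthetic signal-detection observer, stimulation sites, hidden percepts |
| `perceptography.trials` | schedules with dilution and balance, session runner, outcome tallies |
| `perceptography.optimizer` | selection, AFP, spray, families, stopping rule, campaign orchestration |
| `perceptography.metrics` | Fréchet feature distance, bootstrap null, Welch's t, dendrograms |
| `perceptography.config` / `io` / `cli` | YAML configs, JSONL logs, checkpoints, click CLI |

See `docs/methods.md` for the model's assumptions, parameter defaults, and
known limitations.
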