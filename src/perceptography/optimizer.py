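"""Evolutionary optimizer: behavior-guided image search ("Ahab").

Scores images from the observer's behavioral mistakes, selects those with a
false-alarm rate above 50% and a miss rate below 5%, aggregates their
feature vectors into an average-feature-prototype (AFP), proposes new images
near the AFP, manages image families across iterations (a family survives
only while its cumulative FA rate stays above 50%), and declares a
perceptogram once some image sustains >= 60% FA over at least 12
non-stimulated presentations.

The optimizer works in its own feature space (a fixed Gabor-bank extractor)
and never reads the observer's hidden percept template: everything it knows
about the percept arrives through trial outcomes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .config import CampaignConfig
from .errors import DataError, ParameterError
from .image_space import ImageSpace, LatentImageParams
from .observer import ObserverConfig, StimulationSite, SyntheticObserver
from .trials import (
    ImageScore,
    ImageStore,
    TrialRecord,
    build_schedule,
    run_session,
    score_images,
)

__all__ = [
    "ImageScore",
    "ImageFamily",
    "GaborBankExtractor",
    "EmptySelectionError",
    "select_candidates",
    "compute_afp",
    "spray_around_afp",
    "advance_families",
    "check_stopping",
    "Campaign",
    "run_campaign",
    "make_components",
]


class EmptySelectionError(ParameterError):
    """No image passed the behavioral selection criteria."""


# ---------------------------------------------------------------------------
# optimizer feature extractor (F_opt)


class GaborBankExtractor:
    """Fixed Gabor-energy features: 8 orientations x 4 spatial frequencies.

    Each feature is the mean local energy (quadrature-pair magnitude) of the
    grayscale image under one Gabor filter, computed by FFT convolution.
    Deliberately unrelated to the observer's private pixel projection — the
    optimizer's view of image content, like a generic pretrained network,
    shares no parameters with the system it probes.
    """

    extractor_id = "gabor32"

    def __init__(
        self,
        image_size: int = 64,
        n_orientations: int = 8,
        frequencies: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0),
    ) -> None:
        self.image_size = image_size
        self.dim = n_orientations * len(frequencies)
        size = image_size
        coords = np.arange(size) - size // 2
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        kc_fft = []
        ks_fft = []
        for f in frequencies:
            lam = size / f
            sigma = 0.5 * lam
            for i in range(n_orientations):
                theta = np.pi * i / n_orientations
                xr = xx * np.cos(theta) + yy * np.sin(theta)
                yr = -xx * np.sin(theta) + yy * np.cos(theta)
                env = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2))
                kc = env * np.cos(2.0 * np.pi * xr / lam)
                ks = env * np.sin(2.0 * np.pi * xr / lam)
                norm = np.sqrt(np.sum(kc**2 + ks**2))
                kc_fft.append(np.fft.rfft2(np.fft.ifftshift(kc / norm)))
                ks_fft.append(np.fft.rfft2(np.fft.ifftshift(ks / norm)))
        self._kc_fft = np.stack(kc_fft)
        self._ks_fft = np.stack(ks_fft)

    def features_batch(self, pixels: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) rasters -> (N, dim) Gabor-energy features."""
        gray = pixels.mean(axis=-1)
        g_fft = np.fft.rfft2(gray)
        out = np.empty((pixels.shape[0], self.dim))
        for k in range(self.dim):
            rc = np.fft.irfft2(g_fft * self._kc_fft[k], s=gray.shape[-2:])
            rs = np.fft.irfft2(g_fft * self._ks_fft[k], s=gray.shape[-2:])
            out[:, k] = np.sqrt(rc**2 + rs**2).mean(axis=(1, 2))
        return out

    def features(self, raster) -> np.ndarray:
        return self.features_batch(raster.pixels[None])[0]


# ---------------------------------------------------------------------------
# families


@dataclass
class ImageFamily:
    """A lineage of mutated images descending from one surviving perturbation."""

    family_id: str
    root_image_id: str
    members: dict[str, dict] = field(default_factory=dict)
    active: bool = True

    def __post_init__(self) -> None:
        if self.root_image_id not in self.members:
            self.members[self.root_image_id] = {"parent": None, "iteration": 0}

    def add_member(self, image_id: str, parent: str, iteration: int) -> None:
        if parent not in self.members:
            raise DataError(f"parent {parent} not a member of family {self.family_id}")
        if image_id in self.members:
            raise DataError(f"duplicate member {image_id}")
        self.members[image_id] = {"parent": parent, "iteration": iteration}

    def member_ids(self) -> list[str]:
        return list(self.members)

    def cumulative_fa(self, scores: dict[str, ImageScore]) -> tuple[int, int]:
        """Pooled (FA count, non-stimulated presentations) over all members."""
        fa = n = 0
        for img in self.members:
            sc = scores.get(img)
            if sc is not None:
                fa += sc.fa_count
                n += sc.n_nostim
        return fa, n

    def cumulative_fa_rate(self, scores: dict[str, ImageScore]) -> float | None:
        fa, n = self.cumulative_fa(scores)
        return fa / n if n else None

    def best_member(self, scores: dict[str, ImageScore]) -> str:
        """Member with the highest defined FA rate; ties break to more
        presentations, then lexicographic id."""
        candidates = [
            (sc.fa_rate, sc.n_nostim, img)
            for img in self.members
            if (sc := scores.get(img)) is not None and sc.fa_rate is not None
        ]
        if not candidates:
            return self.root_image_id
        candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
        return candidates[0][2]

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "root_image_id": self.root_image_id,
            "members": self.members,
            "active": self.active,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageFamily":
        return cls(**d)


# ---------------------------------------------------------------------------
# selection / prototype / spray / survival / stopping


def select_candidates(
    scores: dict[str, ImageScore],
    fa_threshold: float = 0.5,
    miss_threshold: float = 0.05,
) -> list[str]:
    """Images with FA rate strictly above and miss rate strictly below
    threshold (both rates defined), ordered by descending FA rate with
    lexicographic id tie-break."""
    picked = [
        (sc.fa_rate, sc.image_id)
        for sc in scores.values()
        if sc.fa_rate is not None
        and sc.miss_rate is not None
        and sc.fa_rate > fa_threshold
        and sc.miss_rate < miss_threshold
    ]
    picked.sort(key=lambda t: (-t[0], t[1]))
    return [img for _, img in picked]


def compute_afp(feature_matrix: np.ndarray, trim: float = 0.1) -> np.ndarray:
    """Average-feature-prototype: per-dimension trimmed mean of the selected
    images' feature vectors."""
    x = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if x.shape[0] == 0:
        raise EmptySelectionError("no candidates: cannot build a prototype")
    return np.asarray(_sstats.trim_mean(x, proportiontocut=trim, axis=0))


def spray_around_afp(
    afp: np.ndarray,
    survivors: list[LatentImageParams],
    n_out: int,
    space: ImageSpace,
    extractor: GaborBankExtractor,
    rng: np.random.Generator,
    spread: float = 0.35,
    candidate_multiplier: int = 10,
    return_distances: bool = False,
):
    """Propose images near the AFP: jitter the survivors, rank the rendered
    candidates by feature distance to the prototype, return the nearest.

    The returned list is sorted by ascending distance.
    """
    if n_out < 1:
        raise ParameterError("n_out: must be >= 1")
    if not survivors:
        raise ParameterError("survivors: must be non-empty")
    n_cand = max(candidate_multiplier * n_out, 2)
    candidates: list[LatentImageParams] = []
    i = 0
    while len(candidates) < n_cand:
        parent = survivors[i % len(survivors)]
        k = min(6, max(2, n_cand - len(candidates)))
        candidates.extend(space.mutate(parent, k, spread, rng))
        i += 1
    pixels = space.render_batch(candidates)
    feats = extractor.features_batch(pixels)
    dist = np.linalg.norm(feats - np.asarray(afp)[None, :], axis=1)
    order = np.argsort(dist, kind="stable")[:n_out]
    chosen = [candidates[j] for j in order]
    if return_distances:
        return chosen, dist[order]
    return chosen


def advance_families(
    families: list[ImageFamily],
    scores: dict[str, ImageScore],
    store: ImageStore,
    children_per_parent: int,
    rng: np.random.Generator,
    survival_threshold: float = 0.5,
    mutation_spread: float = 0.35,
    iteration: int = 1,
    proposer=None,
) -> list[ImageFamily]:
    """One evolution step over the family list.

    Families whose cumulative FA rate is strictly above the survival
    threshold receive ``children_per_parent`` mutated children of their best
    member; the rest are frozen but stay in the dendrogram.  ``proposer``
    optionally replaces plain mutation (e.g. AFP-guided spray); it must map
    (parent_params, n_children, rng) to a list of child params.
    """
    if not 2 <= children_per_parent <= 6:
        raise ParameterError(
            f"children_per_parent: {children_per_parent} outside [2, 6]"
        )
    for fam in families:
        if not fam.active:
            continue
        rate = fam.cumulative_fa_rate(scores)
        if rate is None or not rate > survival_threshold:
            fam.active = False
            continue
        best_id = fam.best_member(scores)
        parent_params = store.params(best_id)
        if proposer is not None:
            children = proposer(parent_params, children_per_parent, rng)
        else:
            children = store.space.mutate(
                parent_params, children_per_parent, mutation_spread, rng
            )
        seed_id = store.seed_of[best_id]
        for child in children:
            child_id = store.add_image(child, seed_id)
            fam.add_member(child_id, parent=best_id, iteration=iteration)
    return families


def check_stopping(
    families: list[ImageFamily],
    scores: dict[str, ImageScore],
    stop_fa: float = 0.6,
    min_presentations: int = 12,
) -> str | None:
    """Perceptogram rule: the highest-FA image within any family, provided it
    reaches ``stop_fa`` over at least ``min_presentations`` non-stimulated
    presentations.  Ties break to more presentations, then id."""
    qualifying = []
    for fam in families:
        for img in fam.members:
            sc = scores.get(img)
            if (
                sc is not None
                and sc.fa_rate is not None
                and sc.n_nostim >= min_presentations
                and sc.fa_rate >= stop_fa
            ):
                qualifying.append((sc.fa_rate, sc.n_nostim, img))
    if not qualifying:
        return None
    qualifying.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return qualifying[0][2]


# ---------------------------------------------------------------------------
# campaign orchestration


def make_components(
    config: CampaignConfig,
) -> tuple[ImageSpace, SyntheticObserver, StimulationSite, ImageStore]:
    """Build the image space, observer, stimulation site, and image store a
    campaign needs, with all randomness derived from the master seed."""
    config.validate()
    ss = np.random.SeedSequence(config.master_seed)
    k_site, k_obs = ss.spawn(2)
    site_seed = (
        config.site_seed
        if config.site_seed is not None
        else int(k_site.generate_state(1)[0] & 0x7FFFFFFF)
    )
    obs_feature_seed = int(k_obs.generate_state(1)[0] & 0x7FFFFFFF)
    space = ImageSpace(
        n_classes=config.n_classes,
        latent_dim=config.latent_dim,
        size=config.image_size,
        truncation=config.truncation,
    )
    obs_cfg = ObserverConfig(**config.observer) if config.observer else ObserverConfig()
    observer = SyntheticObserver(
        image_size=config.image_size,
        feature_seed=obs_feature_seed,
        config=obs_cfg,
    )
    site = StimulationSite(
        site_id="site_00",
        intensity_mw=config.intensity_mw,
        feature_dim=observer.feature_dim,
        site_seed=site_seed,
    )
    return space, observer, site, ImageStore(space)


def _rng_from_state(state: dict) -> np.random.Generator:
    bg = np.random.PCG64()
    bg.state = state
    return np.random.Generator(bg)


class Campaign:
    """State and orchestration of one perceptography campaign.

    Runs the loop: random perturbation pool -> CPD sessions -> behavioral
    scoring -> candidate selection -> AFP -> spray-guided mutation of
    surviving families -> dilution with fresh non-optimized images, until the
    stopping rule fires or the iteration budget is exhausted.  The full state
    checkpoints to JSON after every iteration and resumes bit-exactly.
    """

    def __init__(
        self,
        config: CampaignConfig,
        observer: SyntheticObserver | None = None,
        site: StimulationSite | None = None,
        space: ImageSpace | None = None,
    ) -> None:
        config.validate()
        self.config = config
        if observer is None or site is None or space is None:
            space_, observer_, site_, _ = make_components(config)
            space = space if space is not None else space_
            observer = observer if observer is not None else observer_
            site = site if site is not None else site_
        self.space, self.observer, self.site = space, observer, site
        self.store = ImageStore(self.space)
        self.extractor = GaborBankExtractor(image_size=config.image_size)
        ss = np.random.SeedSequence((config.master_seed, 1))
        k_img, k_sched, k_decide = ss.spawn(3)
        self._rng_image = np.random.Generator(np.random.PCG64(k_img))
        self._rng_schedule = np.random.Generator(np.random.PCG64(k_sched))
        self._rng_decide = np.random.Generator(np.random.PCG64(k_decide))

        self.iteration = 0
        self.families: list[ImageFamily] = []
        self.davinci_pool: list[str] = []
        self.seed_ids: list[str] = []
        self.records: list[TrialRecord] = []
        self.scores: dict[str, ImageScore] = {}
        self.winner: str | None = None
        self.iteration_pools: list[list[str]] = []
        self.no_convergence: dict | None = None
        self.log: list[dict] = []
        self._magnitude_center: float | None = None
        self._family_counter = 0
        self._fopt_cache: dict[str, np.ndarray] = {}

    # -- features in the optimizer's space ---------------------------------
    def fopt_features(self, image_ids: list[str]) -> np.ndarray:
        missing = [i for i in image_ids if i not in self._fopt_cache]
        if missing:
            self.store.prerender(missing)
            pixels = np.stack([self.store.raster(i).pixels for i in missing])
            feats = self.extractor.features_batch(pixels)
            for i, img in enumerate(missing):
                self._fopt_cache[img] = feats[i]
        return np.stack([self._fopt_cache[i] for i in image_ids])

    # -- pool construction ---------------------------------------------------
    def _draw_magnitude(self, stratum: float) -> float:
        if self._magnitude_center is None:
            return float(stratum)
        m = self._rng_image.normal(self._magnitude_center, 0.15)
        return float(np.clip(m, 0.0, 1.0))

    def _init_seeds(self) -> None:
        classes = self._rng_image.choice(
            self.config.n_classes, size=self.config.n_seeds, replace=False
        )
        for i, cls_idx in enumerate(classes):
            sid = f"seed_{i:02d}"
            self.store.add_seed(sid, self.space.seed_params(int(cls_idx), self._rng_image))
            self.seed_ids.append(sid)
        self._attune_site()

    def _attune_site(self) -> None:
        # the hidden percept of the site is defined relative to the concrete
        # seed images; this setup step belongs to the observer's side of the
        # interface and happens before any optimization
        from .observer import attune_site_to_seeds

        attune_site_to_seeds(
            self.site,
            self.observer,
            self.space,
            {sid: self.store.seeds[sid] for sid in self.seed_ids},
        )

    def _fresh_davinci_pool(self, n_images: int) -> list[str]:
        """Random perturbations spread across seeds with graded magnitudes."""
        ids = []
        per_seed = max(n_images // len(self.seed_ids), 1)
        for sid in self.seed_ids:
            for j in range(per_seed):
                stratum = (j + 0.5) / per_seed
                m = self._draw_magnitude(stratum)
                params = self.space.perturb_random(
                    self.store.seeds[sid], m, self._rng_image
                )
                ids.append(self.store.add_image(params, sid))
        return ids

    def _estimate_peak_magnitude(self) -> float:
        """FA-vs-magnitude peak over the non-optimized pool (0.1-wide bins)."""
        edges = np.linspace(0.0, 1.0, 11)
        fa = np.zeros(10)
        n = np.zeros(10)
        family_imgs = {img for f in self.families for img in f.members}
        for img in self.davinci_pool:
            if img in family_imgs:
                continue
            sc = self.scores.get(img)
            if sc is None or sc.fa_rate is None:
                continue
            m = self.space.measure_magnitude(
                self.store.seeds[self.store.seed_of[img]], self.store.params(img)
            )
            b = min(int(m * 10), 9)
            fa[b] += sc.fa_count
            n[b] += sc.n_nostim
        with np.errstate(invalid="ignore"):
            rates = np.where(n > 0, fa / np.maximum(n, 1), np.nan)
        if np.all(np.isnan(rates)):
            return 0.5
        best = int(np.nanargmax(rates))
        return float(0.5 * (edges[best] + edges[best + 1]))

    # -- one iteration -------------------------------------------------------
    def step(self) -> None:
        cfg = self.config
        ahab_ids = [
            img for fam in self.families if fam.active for img in fam.members
        ]
        if self.iteration == 0 or not ahab_ids:
            if not self.seed_ids:
                self._init_seeds()
            pool = self._fresh_davinci_pool(cfg.n_seeds * cfg.pool_size)
            self.davinci_pool = pool
            dilution = 0.0
            n_trials = 2 * cfg.min_presentations * len(pool)
            schedule = build_schedule(
                pool, [], n_trials, dilution, cfg.min_presentations, self._rng_schedule
            )
        else:
            dilution = cfg.dilution_fraction
            # equalize cumulative exposure: newly born members catch up to
            # stopping-rule eligibility within two sessions, parents keep the
            # per-session minimum
            target = cfg.stop_min_presentations + cfg.min_presentations
            pairs: dict[str, int] = {}
            for img in ahab_ids:
                sc = self.scores.get(img)
                have = 0 if sc is None else sc.n_nostim
                pairs[img] = int(
                    np.clip(
                        target - have,
                        cfg.min_presentations,
                        2 * cfg.min_presentations,
                    )
                )
            n_ahab = 2 * sum(pairs.values())
            n_trials = int(np.ceil(n_ahab / max(1.0 - dilution, 1e-9)))
            n_dav_imgs = max(
                int(round(dilution * n_trials)) // (2 * cfg.min_presentations), 1
            )
            self.davinci_pool = self._fresh_davinci_pool(n_dav_imgs)
            schedule = build_schedule(
                ahab_ids,
                self.davinci_pool,
                n_trials,
                dilution,
                cfg.min_presentations,
                self._rng_schedule,
                pairs_per_image=pairs,
            )
        presented = {img for img, _ in schedule.entries}
        self.store.prerender(sorted(presented))
        tags = {img: "ahab" for img in ahab_ids}
        records = run_session(
            schedule,
            self.observer,
            self.site,
            self.store,
            self._rng_decide,
            session_id=f"{self.config.master_seed}:{self.iteration:03d}",
            iteration_index=self.iteration,
            pool_tags=tags,
        )
        self.records.extend(records)
        self.scores = score_images(self.records)
        self.iteration_pools.append(sorted(ahab_ids))

        self.winner = check_stopping(
            self.families, self.scores, cfg.stop_fa, cfg.stop_min_presentations
        )
        selected = select_candidates(self.scores, cfg.fa_select, cfg.miss_select)
        self._found_families(selected)
        afp = None
        if selected:
            afp = compute_afp(self.fopt_features(selected))
        proposer = None
        if afp is not None:
            proposer = lambda parent, k, rng: spray_around_afp(  # noqa: E731
                afp,
                [parent],
                k,
                self.space,
                self.extractor,
                rng,
                spread=cfg.mutation_spread,
                candidate_multiplier=cfg.spray_multiplier,
            )
        advance_families(
            self.families,
            self.scores,
            self.store,
            cfg.children_per_parent,
            self._rng_image,
            survival_threshold=cfg.family_survival,
            mutation_spread=cfg.mutation_spread,
            iteration=self.iteration + 1,
            proposer=proposer,
        )
        if not selected:
            self._magnitude_center = self._estimate_peak_magnitude()
        self.log.append(
            {
                "iteration": self.iteration,
                "n_trials": len(schedule),
                "pool_ahab": len(ahab_ids),
                "pool_davinci": len(self.davinci_pool),
                "realized_dilution": schedule.realized_dilution,
                "n_selected": len(selected),
                "n_active_families": sum(f.active for f in self.families),
                "winner": self.winner,
            }
        )
        self.iteration += 1

    def _found_families(self, selected: list[str]) -> None:
        in_family = {img for fam in self.families for img in fam.members}
        for img in selected:
            if img in in_family:
                continue
            if sum(f.active for f in self.families) >= self.config.max_families:
                break
            fam = ImageFamily(family_id=f"fam_{self._family_counter:03d}", root_image_id=img)
            self._family_counter += 1
            self.families.append(fam)
            in_family.add(img)

    # -- full run -------------------------------------------------------------
    def run(self, checkpoint_dir=None) -> "Campaign":
        while self.iteration < self.config.iteration_budget and self.winner is None:
            self.step()
            if checkpoint_dir is not None:
                self.save_checkpoint(
                    os.path.join(
                        checkpoint_dir, f"checkpoint_{self.iteration - 1:03d}.json"
                    )
                )
        if self.winner is None:
            best = max(
                (
                    (sc.fa_rate, sc.n_nostim, sc.image_id)
                    for sc in self.scores.values()
                    if sc.fa_rate is not None
                ),
                default=(None, 0, None),
            )
            self.no_convergence = {
                "reason": "iteration budget exhausted without a perceptogram",
                "iterations_run": self.iteration,
                "best_image": best[2],
                "best_fa_rate": best[0],
                "best_n_nostim": best[1],
                "n_families": len(self.families),
            }
        return self

    def compact(self) -> None:
        """Drop rendered-raster and percept caches; rasters re-render lazily."""
        self.store._raster_cache.clear()
        self.observer.clear_caches()

    # -- convenience accessors -------------------------------------------------
    def winner_family(self) -> ImageFamily | None:
        if self.winner is None:
            return None
        for fam in self.families:
            if self.winner in fam.members:
                return fam
        return None

    def winner_score(self) -> ImageScore | None:
        return None if self.winner is None else self.scores.get(self.winner)

    # -- checkpointing ----------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "iteration": self.iteration,
            "winner": self.winner,
            "seed_ids": self.seed_ids,
            "davinci_pool": self.davinci_pool,
            "iteration_pools": self.iteration_pools,
            "magnitude_center": self._magnitude_center,
            "family_counter": self._family_counter,
            "families": [f.to_dict() for f in self.families],
            "store": {
                "seeds": {k: p.to_dict() for k, p in self.store.seeds.items()},
                "images": {
                    k: {"params": p.to_dict(), "seed": self.store.seed_of[k]}
                    for k, p in self.store.images.items()
                },
                "counter": self.store._counter,
            },
            "records": [r.to_dict() for r in self.records],
            "log": self.log,
            "rng": {
                "image": self._rng_image.bit_generator.state,
                "schedule": self._rng_schedule.bit_generator.state,
                "decide": self._rng_decide.bit_generator.state,
            },
            "no_convergence": self.no_convergence,
        }

    def save_checkpoint(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(), fh)

    @classmethod
    def from_state_dict(cls, d: dict) -> "Campaign":
        config = CampaignConfig.from_dict(d["config"])
        camp = cls(config)
        camp.iteration = d["iteration"]
        camp.winner = d["winner"]
        camp.seed_ids = list(d["seed_ids"])
        camp.davinci_pool = list(d["davinci_pool"])
        camp.iteration_pools = [list(p) for p in d["iteration_pools"]]
        camp._magnitude_center = d["magnitude_center"]
        camp._family_counter = d["family_counter"]
        camp.families = [ImageFamily.from_dict(f) for f in d["families"]]
        for sid, pd in d["store"]["seeds"].items():
            camp.store.add_seed(sid, LatentImageParams.from_dict(pd))
        for img, entry in d["store"]["images"].items():
            camp.store.add_image(
                LatentImageParams.from_dict(entry["params"]), entry["seed"], image_id=img
            )
        camp.store._counter = d["store"]["counter"]
        camp.records = [TrialRecord.from_dict(r) for r in d["records"]]
        camp.scores = score_images(camp.records) if camp.records else {}
        camp.log = list(d["log"])
        camp._rng_image = _rng_from_state(d["rng"]["image"])
        camp._rng_schedule = _rng_from_state(d["rng"]["schedule"])
        camp._rng_decide = _rng_from_state(d["rng"]["decide"])
        camp.no_convergence = d["no_convergence"]
        if camp.seed_ids:
            camp._attune_site()
        return camp

    @classmethod
    def load_checkpoint(cls, path) -> "Campaign":
        with open(path) as fh:
            return cls.from_state_dict(json.load(fh))

    def fingerprint(self) -> dict:
        """Compact summary for bit-exact resume comparisons."""
        return {
            "iteration": self.iteration,
            "winner": self.winner,
            "n_records": len(self.records),
            "n_images": len(self.store.images),
            "families": [f.to_dict() for f in self.families],
            "score_counts": sorted(
                (s.image_id, s.n_stim, s.n_nostim, s.fa_count, s.miss_count)
                for s in self.scores.values()
            ),
            "rng": {
                "image": self._rng_image.bit_generator.state["state"],
                "schedule": self._rng_schedule.bit_generator.state["state"],
                "decide": self._rng_decide.bit_generator.state["state"],
            },
        }


def campaign_convergence_curve(campaign: Campaign) -> list[float | None]:
    """Per-iteration Fréchet distance from the optimized pool to the winner.

    The winner's own family is excluded from every iteration's pool; the
    reference is the winner's feature vector expanded into a tight cloud.
    Iterations whose pool is empty after exclusion come back as None.
    """
    from .metrics import FeatureSet, convergence_curve, singleton_feature_set

    if campaign.winner is None:
        raise DataError("campaign has no winner; convergence curve undefined")
    fam = campaign.winner_family()
    exclude = set(fam.members) if fam is not None else set()
    pools = []
    for ids in campaign.iteration_pools:
        kept = [i for i in ids if i not in exclude]
        if len(kept) < 2:
            pools.append(None)
        else:
            pools.append(
                FeatureSet(
                    campaign.fopt_features(kept),
                    extractor_id=campaign.extractor.extractor_id,
                )
            )
        # iteration 0 presents only the non-optimized pool; drop it from the
        # optimization-iteration axis
    pools = pools[1:] if len(pools) > 1 else pools
    winner_ref = singleton_feature_set(
        campaign.fopt_features([campaign.winner])[0],
        extractor_id=campaign.extractor.extractor_id,
    )
    return convergence_curve(pools, winner_ref)


def campaign_dendrogram(campaign: Campaign):
    """Dendrogram nodes for all families, with per-image feature distance to
    its seed (optimizer feature space) and FA-rate branch thickness."""
    from .metrics import build_dendrogram, frechet_distance, singleton_feature_set

    fid_to_seed: dict[str, float] = {}
    seed_refs = {
        sid: singleton_feature_set(
            campaign.extractor.features(campaign.store.raster(sid)), seed=1
        )
        for sid in campaign.seed_ids
    }
    for fam in campaign.families:
        for img in fam.members:
            sid = campaign.store.seed_of[img]
            img_set = singleton_feature_set(campaign.fopt_features([img])[0], seed=2)
            fid_to_seed[img] = frechet_distance(img_set, seed_refs[sid])
    return build_dendrogram(campaign.families, campaign.scores, fid_to_seed)


def family_membership(campaign: Campaign) -> dict[str, list[str]]:
    """family_id -> member image ids (input to the bootstrap null)."""
    return {f.family_id: f.member_ids() for f in campaign.families}


def run_campaign(
    config: CampaignConfig,
    observer: SyntheticObserver | None = None,
    site: StimulationSite | None = None,
    space: ImageSpace | None = None,
    checkpoint_dir=None,
) -> Campaign:
    """Run a full campaign and return its final state."""
    return Campaign(config, observer=observer, site=site, space=space).run(
        checkpoint_dir=checkpoint_dir
    )
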