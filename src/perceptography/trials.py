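"""Trial engine for cortical-perturbation-detection (CPD) sessions.

Builds balanced stimulated/non-stimulated schedules with dilution, presents
trials to the synthetic observer, reinjects aborted trials into the future
stream, and tallies per-image outcome counts.  Stimulus timing (fixation 500
ms, seed 400 ms, perturbation 150 ms, seed 450 ms, 3.5 s timeout) is recorded
as session metadata only — nothing is simulated in real time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, ParameterError, SchedulingError
from .image_space import ImageRaster, ImageSpace, LatentImageParams
from .observer import (
    RESPONSE_ABORTED,
    RESPONSE_NOT_STIMULATED,
    RESPONSE_STIMULATED,
    StimulationSite,
    SyntheticObserver,
)

__all__ = [
    "TrialRecord",
    "ImageScore",
    "SessionSchedule",
    "ImageStore",
    "TIMING_MS",
    "build_schedule",
    "run_session",
    "score_images",
    "fa_magnitude_sweep",
    "context_swap_fa_rate",
]

#: stimulus timing bookkeeping (milliseconds), logged with every session
TIMING_MS = {
    "fixation": 500,
    "seed_before": 400,
    "perturbation": 150,
    "seed_after": 450,
    "response_timeout": 3500,
}

OUTCOME_HIT = "hit"
OUTCOME_MISS = "miss"
OUTCOME_FA = "false_alarm"
OUTCOME_CR = "correct_rejection"
OUTCOME_ABORTED = "aborted"


def outcome_of(stimulated: bool, response: str) -> str:
    """Outcome is a pure function of (stimulated, response)."""
    if response == RESPONSE_ABORTED:
        return OUTCOME_ABORTED
    if stimulated:
        return OUTCOME_HIT if response == RESPONSE_STIMULATED else OUTCOME_MISS
    return OUTCOME_FA if response == RESPONSE_STIMULATED else OUTCOME_CR


@dataclass
class TrialRecord:
    """One CPD trial: what was shown, what happened, how it was labeled."""

    trial_id: int
    session_id: str
    seed_id: str
    image_id: str
    stimulated: bool
    response: str
    outcome: str
    iteration_index: int = 0
    pool_tag: str = "davinci"
    reward: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(**d)


@dataclass
class ImageScore:
    """Per-image tally of presentations and mistakes; the selection currency."""

    image_id: str
    n_stim: int = 0
    n_nostim: int = 0
    fa_count: int = 0
    miss_count: int = 0

    @property
    def fa_rate(self) -> float | None:
        """FA / completed non-stimulated presentations; None when undefined."""
        if self.n_nostim == 0:
            return None
        return self.fa_count / self.n_nostim

    @property
    def miss_rate(self) -> float | None:
        if self.n_stim == 0:
            return None
        return self.miss_count / self.n_stim

    def merge(self, other: "ImageScore") -> "ImageScore":
        if other.image_id != self.image_id:
            raise ParameterError("image_id: cannot merge scores of different images")
        return ImageScore(
            image_id=self.image_id,
            n_stim=self.n_stim + other.n_stim,
            n_nostim=self.n_nostim + other.n_nostim,
            fa_count=self.fa_count + other.fa_count,
            miss_count=self.miss_count + other.miss_count,
        )


@dataclass
class SessionSchedule:
    """Ordered presentations with per-image stimulation balance."""

    entries: list[tuple[str, bool]]
    dilution_fraction: float = 0.0
    davinci_ids: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def realized_dilution(self) -> float:
        if not self.entries:
            return 0.0
        n_dav = sum(1 for img, _ in self.entries if img in self.davinci_ids)
        return n_dav / len(self.entries)


class ImageStore:
    """Registry mapping image ids to latent params, seeds, and rasters.

    Rasters are rendered lazily and cached; an image's context seed is the
    seed image it perturbs, which is what the observer diffs against.
    """

    def __init__(self, space: ImageSpace) -> None:
        self.space = space
        self.seeds: dict[str, LatentImageParams] = {}
        self.images: dict[str, LatentImageParams] = {}
        self.seed_of: dict[str, str] = {}
        self._raster_cache: dict[str, ImageRaster] = {}
        self._counter = 0

    def add_seed(self, seed_id: str, params: LatentImageParams) -> str:
        params.validate()
        self.seeds[seed_id] = params
        return seed_id

    def add_image(
        self, params: LatentImageParams, seed_id: str, image_id: str | None = None
    ) -> str:
        if seed_id not in self.seeds:
            raise DataError(f"unknown seed id: {seed_id}")
        if image_id is None:
            image_id = f"img_{self._counter:06d}"
            self._counter += 1
        self.images[image_id] = params
        self.seed_of[image_id] = seed_id
        return image_id

    def params(self, image_id: str) -> LatentImageParams:
        try:
            return self.images[image_id]
        except KeyError:
            raise DataError(f"unresolvable image id: {image_id}") from None

    def raster(self, image_id: str) -> ImageRaster:
        if image_id in self._raster_cache:
            return self._raster_cache[image_id]
        if image_id in self.images:
            r = self.space.render(self.images[image_id], params_ref=image_id)
        elif image_id in self.seeds:
            r = self.space.render(self.seeds[image_id], params_ref=image_id)
        else:
            raise DataError(f"unresolvable image id: {image_id}")
        self._raster_cache[image_id] = r
        return r

    def context_raster(self, image_id: str) -> ImageRaster:
        if image_id in self.seeds:
            return self.raster(image_id)
        if image_id not in self.seed_of:
            raise DataError(f"unresolvable image id: {image_id}")
        return self.raster(self.seed_of[image_id])

    def prerender(self, image_ids: Sequence[str]) -> None:
        """Render many images in one vectorized pass (cache warm-up)."""
        todo = [i for i in image_ids if i not in self._raster_cache]
        if not todo:
            return
        params = [self.params(i) for i in todo]
        pixels = self.space.render_batch(params)
        for i, img_id in enumerate(todo):
            self._raster_cache[img_id] = ImageRaster(pixels=pixels[i], params_ref=img_id)


def _paired_slots(
    n_slots: int, ids: Sequence[str], rng: np.random.Generator
) -> list[tuple[str, bool]]:
    """Distribute n_slots as balanced (stim, nostim) pairs across ids."""
    n_pairs = n_slots // 2
    order = list(ids)
    rng.shuffle(order)
    base, extra = divmod(n_pairs, len(order))
    entries: list[tuple[str, bool]] = []
    for i, img in enumerate(order):
        pairs = base + (1 if i < extra else 0)
        entries.extend([(img, True)] * pairs)
        entries.extend([(img, False)] * pairs)
    return entries


def build_schedule(
    ahab_pool: Sequence[str],
    davinci_pool: Sequence[str],
    n_trials: int,
    dilution_fraction: float,
    min_presentations: int,
    rng: np.random.Generator,
    pairs_per_image: dict[str, int] | None = None,
) -> SessionSchedule:
    """Balanced session schedule with dilution.

    Every scheduled image receives at least ``min_presentations`` in each
    stimulation condition (exact per-image stim/non-stim balance); the
    fraction of presentations drawn from the non-optimized pool matches
    ``dilution_fraction`` to within one slot; order is shuffled.

    ``pairs_per_image`` optionally sets per-image presentation pairs for the
    optimized pool (each must be >= ``min_presentations``), which the
    campaign uses to equalize cumulative exposure across family members.
    """
    if not 0.0 <= dilution_fraction <= 1.0:
        raise ParameterError(f"dilution_fraction: {dilution_fraction} outside [0, 1]")
    if min_presentations < 1:
        raise ParameterError("min_presentations: must be >= 1")
    if not ahab_pool:
        raise ParameterError("ahab_pool: must be non-empty")
    if dilution_fraction > 0 and not davinci_pool:
        raise ParameterError("davinci_pool: must be non-empty when dilution is active")

    if pairs_per_image is not None:
        missing = [i for i in ahab_pool if i not in pairs_per_image]
        if missing:
            raise ParameterError(f"pairs_per_image: missing entries for {missing[:3]}")
        low = [i for i in ahab_pool if pairs_per_image[i] < min_presentations]
        if low:
            raise SchedulingError(
                f"pairs_per_image below min_presentations for {low[:3]}"
            )
        n_ahab = 2 * sum(pairs_per_image[i] for i in ahab_pool)
        if dilution_fraction > 0:
            n_trials = int(np.ceil(n_ahab / (1.0 - dilution_fraction)))
        else:
            n_trials = n_ahab

    n_dav = int(round(dilution_fraction * n_trials))
    n_ahab = n_trials - n_dav
    need_ahab = 2 * min_presentations * len(ahab_pool)
    if n_ahab < need_ahab:
        feasible = int(np.ceil(need_ahab / max(1.0 - dilution_fraction, 1e-9)))
        raise SchedulingError(
            f"n_trials={n_trials} cannot give every optimized image "
            f"{min_presentations} presentations per condition; "
            f"minimum feasible n_trials is {feasible}"
        )
    if pairs_per_image is not None:
        entries = []
        for img in ahab_pool:
            entries.extend([(img, True)] * pairs_per_image[img])
            entries.extend([(img, False)] * pairs_per_image[img])
    else:
        entries = _paired_slots(n_ahab, ahab_pool, rng)

    davinci_ids: frozenset = frozenset()
    if n_dav >= 2 * min_presentations and davinci_pool:
        n_dav_images = min(n_dav // (2 * min_presentations), len(davinci_pool))
        chosen_idx = rng.choice(len(davinci_pool), size=n_dav_images, replace=False)
        chosen = [davinci_pool[i] for i in chosen_idx]
        entries.extend(_paired_slots(n_dav, chosen, rng))
        davinci_ids = frozenset(chosen)
    rng.shuffle(entries)
    return SessionSchedule(
        entries=entries,
        dilution_fraction=dilution_fraction,
        davinci_ids=davinci_ids,
    )


def run_session(
    schedule: SessionSchedule,
    observer: SyntheticObserver,
    site: StimulationSite,
    image_store: ImageStore,
    rng: np.random.Generator,
    session_id: str = "session",
    iteration_index: int = 0,
    pool_tags: dict[str, str] | None = None,
    retry_cap: int = 10,
) -> list[TrialRecord]:
    """Present every scheduled trial to the observer.

    Aborted presentations are logged (flagged, never counted in rates) and
    reinjected at a uniformly random future position until completed or the
    retry cap is hit, after which the presentation is dropped with a warning.
    """
    pool_tags = pool_tags or {}
    queue: list[tuple[str, bool, int]] = [
        (img, stim, 0) for img, stim in schedule.entries
    ]
    records: list[TrialRecord] = []
    trial_id = 0
    dropped = 0
    while queue:
        image_id, stimulated, retries = queue.pop(0)
        ctx = image_store.context_raster(image_id)
        pert = image_store.raster(image_id)
        response = observer.respond(ctx, pert, stimulated, site, rng)
        seed_id = image_store.seed_of.get(image_id, image_id)
        records.append(
            TrialRecord(
                trial_id=trial_id,
                session_id=session_id,
                seed_id=seed_id,
                image_id=image_id,
                stimulated=stimulated,
                response=response,
                outcome=outcome_of(stimulated, response),
                iteration_index=iteration_index,
                pool_tag=pool_tags.get(image_id, "davinci"),
                reward=(
                    response != RESPONSE_ABORTED
                    and (response == RESPONSE_STIMULATED) == stimulated
                ),
            )
        )
        trial_id += 1
        if response == RESPONSE_ABORTED:
            if retries < retry_cap:
                pos = int(rng.integers(0, len(queue) + 1))
                queue.insert(pos, (image_id, stimulated, retries + 1))
            else:
                dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} presentation(s) dropped after {retry_cap} abort retries",
            stacklevel=2,
        )
    return records


def score_images(records: Iterable[TrialRecord]) -> dict[str, ImageScore]:
    """Tally completed trials per image.

    Aborted trials are excluded from all denominators; an image with no
    completed presentations in a condition has that rate undefined (None),
    never zero.
    """
    records = list(records)
    if not records:
        raise ParameterError("records: must be non-empty")
    scores: dict[str, ImageScore] = {}
    for r in records:
        if r.outcome == OUTCOME_ABORTED:
            continue
        sc = scores.setdefault(r.image_id, ImageScore(image_id=r.image_id))
        if r.stimulated:
            sc.n_stim += 1
            if r.outcome == OUTCOME_MISS:
                sc.miss_count += 1
        else:
            sc.n_nostim += 1
            if r.outcome == OUTCOME_FA:
                sc.fa_count += 1
    return scores


# ---------------------------------------------------------------------------
# psychophysical probes


def fa_magnitude_sweep(
    space: ImageSpace,
    observer: SyntheticObserver,
    site: StimulationSite,
    seed_params_list: Sequence[LatentImageParams],
    magnitudes: Sequence[float],
    n_images_per_bin: int,
    presentations_per_image: int,
    rng: np.random.Generator,
) -> dict:
    """False-alarm rate as a function of perturbation magnitude.

    For each magnitude bin, random perturbations of the given seeds are
    presented in non-stimulated trials; the pooled FA rate and its binomial
    SE are returned per bin.  This reproduces the shape experiment in which
    FA rises then falls with perturbation size.
    """
    store = ImageStore(space)
    seed_ids = []
    for i, sp in enumerate(seed_params_list):
        sid = f"sweep_seed_{i:02d}"
        store.add_seed(sid, sp)
        seed_ids.append(sid)
    fa_rate = []
    fa_se = []
    n_trials_bin = []
    for m_idx, m in enumerate(magnitudes):
        fa = 0
        n = 0
        for j in range(n_images_per_bin):
            sid = seed_ids[j % len(seed_ids)]
            params = space.perturb_random(store.seeds[sid], float(m), rng)
            img_id = store.add_image(params, sid, image_id=f"sw_{m_idx:02d}_{j:04d}")
            ctx = store.context_raster(img_id)
            pert = store.raster(img_id)
            e = observer.trial_evidence(ctx, pert, False, site)
            for _ in range(presentations_per_image):
                resp = observer._respond(e, rng)
                if resp == RESPONSE_ABORTED:
                    continue
                n += 1
                if resp == RESPONSE_STIMULATED:
                    fa += 1
        rate = fa / n if n else float("nan")
        fa_rate.append(rate)
        fa_se.append(np.sqrt(rate * (1 - rate) / n) if n else float("nan"))
        n_trials_bin.append(n)
    return {
        "magnitude": np.asarray(magnitudes, dtype=float),
        "fa_rate": np.asarray(fa_rate),
        "fa_se": np.asarray(fa_se),
        "n_trials": np.asarray(n_trials_bin),
    }


def context_swap_fa_rate(
    observer: SyntheticObserver,
    site: StimulationSite,
    image_raster: ImageRaster,
    context_raster: ImageRaster,
    n_presentations: int,
    rng: np.random.Generator,
) -> float:
    """FA rate of one image presented inside an arbitrary seed context.

    Presenting a perturbation of seed A sandwiched between images of seed B
    probes whether detection rests on the temporal contrast with the
    surrounding seed: with the wrong context the percept change is large and
    misaligned, and the FA rate collapses.
    """
    e = observer.trial_evidence(context_raster, image_raster, False, site)
    fa = 0
    n = 0
    while n < n_presentations:
        resp = observer._respond(e, rng)
        if resp == RESPONSE_ABORTED:
            continue
        n += 1
        if resp == RESPONSE_STIMULATED:
            fa += 1
    return fa / n_presentations
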