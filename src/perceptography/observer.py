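"""Synthetic signal-detection observer for the cortical-perturbation-detection task.

The observer replaces the animal.  It watches a seed -> perturbed -> seed
sequence and reports whether cortical stimulation occurred.  Internally it
compares the *percept change* — the difference between perturbed and seed
images under a private smooth feature map — against a hidden per-site
"stimulation percept" template whose magnitude grows with optical intensity.
Trials where the percept change resembles the template (in direction and in
magnitude) are reported as "stimulated", which on non-stimulated trials is a
false alarm: the signal the optimizer feeds on.

Nothing optimizer-facing exposes the hidden template; the optimizer operates
in a different feature space entirely (see :mod:`perceptography.optimizer`).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError
from .image_space import ImageRaster

__all__ = [
    "StimulationSite",
    "ObserverConfig",
    "SyntheticObserver",
    "RESPONSE_STIMULATED",
    "RESPONSE_NOT_STIMULATED",
    "RESPONSE_ABORTED",
]

RESPONSE_STIMULATED = "stimulated"
RESPONSE_NOT_STIMULATED = "not_stimulated"
RESPONSE_ABORTED = "aborted"


def _stable_key(seed_key: str | None) -> int:
    if seed_key is None:
        return 0
    return zlib.crc32(str(seed_key).encode("utf8"))


class StimulationSite:
    """A simulated cortical locus with a hidden percept template.

    The template ``s`` lives in the observer's private feature space.  Its
    norm is ``a * intensity**gamma`` (strictly increasing in photometric
    power, square-root compressed so the 1-11 mW operating range stays
    on-scale), and its direction depends on the seed image on screen: each
    seed id selects a fixed rotation of the site's base direction, modeling
    the observation that the visual context strongly shapes the outcome of
    local stimulation.

    ``percept_vector`` is observer/evaluation-private: the optimizer must
    never call it (a tracing test enforces this).
    """

    def __init__(
        self,
        site_id: str,
        intensity_mw: float,
        feature_dim: int = 16,
        site_seed: int = 0,
        norm_scale: float = 0.4,
        norm_exponent: float = 0.5,
        seed_rotation_angle: float = 0.6,
    ) -> None:
        if intensity_mw <= 0:
            raise ParameterError(f"intensity_mw: {intensity_mw} must be positive")
        self.site_id = site_id
        self.intensity_mw = float(intensity_mw)
        self.feature_dim = feature_dim
        self.site_seed = int(site_seed)
        self.norm_scale = norm_scale
        self.norm_exponent = norm_exponent
        self.seed_rotation_angle = seed_rotation_angle
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(self.site_seed)))
        u = rng.normal(size=feature_dim)
        self._base_direction = u / np.linalg.norm(u)
        self._rotation_cache: dict[int, np.ndarray] = {}
        self._seed_directions: dict[int, np.ndarray] = {}

    @property
    def percept_norm(self) -> float:
        """||s|| in normalized feature units; strictly increasing in intensity."""
        return float(self.norm_scale * self.intensity_mw**self.norm_exponent)

    def set_seed_direction(self, seed_key: str | None, direction: np.ndarray) -> None:
        """Fix the percept direction for one seed context (observer-private).

        Used when attuning a site to concrete seed images so the hidden
        percept is an *achievable* visual event — the direction of some
        image perturbation — rather than an arbitrary feature-space axis.
        """
        d = np.asarray(direction, dtype=float)
        self._seed_directions[_stable_key(seed_key)] = d / np.linalg.norm(d)

    def _seed_direction(self, seed_key: str | None) -> np.ndarray:
        key = _stable_key(seed_key)
        if key in self._seed_directions:
            return self._seed_directions[key]
        if key not in self._rotation_cache:
            if key == 0:
                self._rotation_cache[key] = self._base_direction
            else:
                # deterministic partial rotation of the base direction: mix
                # with a seed-specific random direction at a fixed angle, so
                # different seeds see related but distinct percepts
                rng = np.random.Generator(
                    np.random.PCG64(np.random.SeedSequence((self.site_seed, key)))
                )
                v = rng.normal(size=self.feature_dim)
                v -= v @ self._base_direction * self._base_direction
                v /= np.linalg.norm(v)
                ang = self.seed_rotation_angle
                d = np.cos(ang) * self._base_direction + np.sin(ang) * v
                self._rotation_cache[key] = d / np.linalg.norm(d)
        return self._rotation_cache[key]

    def percept_vector(self, seed_key: str | None = None) -> np.ndarray:
        """Hidden percept template s for the given seed context.

        Observer/evaluation-private.  Optimizer code paths must not touch it.
        """
        return self.percept_norm * self._seed_direction(seed_key)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "intensity_mw": self.intensity_mw,
            "feature_dim": self.feature_dim,
            "site_seed": self.site_seed,
            "norm_scale": self.norm_scale,
            "norm_exponent": self.norm_exponent,
            "seed_rotation_angle": self.seed_rotation_angle,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationSite":
        return cls(**d)


@dataclass(frozen=True)
class ObserverConfig:
    """Decision-model parameters of the synthetic observer.

    ``magnitude_tolerance_rel`` and ``salience_halfpoint_rel`` are expressed
    as multiples of the template norm ||s||, so the matching window and the
    salience saturation scale with stimulation intensity.

    Defaults were calibrated once, by parameter sweep at construction time of
    the package, so that the baseline operating point of the simulated task
    (false-alarm rate a few percent, miss rate 5-15% at 3 mW) falls in the
    range reported for the animals, and so that the false-alarm rate varies
    smoothly enough with percept alignment for behavioral selection to carry
    a usable gradient.
    """

    noise_sigma: float = 0.08
    criterion: float = 0.49
    lapse_rate: float = 0.02
    magnitude_tolerance_rel: float = 0.45
    salience_halfpoint_rel: float = 0.5
    saturation_beta: float = 0.2
    abort_rate: float = 0.05

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma: must be >= 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ParameterError("lapse_rate: must be in [0, 0.1]")
        if not 0.0 <= self.saturation_beta <= 1.0:
            raise ParameterError("saturation_beta: must be in [0, 1]")
        if not 0.0 <= self.abort_rate < 0.2:
            raise ParameterError("abort_rate: must be in [0, 0.2)")
        if self.magnitude_tolerance_rel <= 0 or self.salience_halfpoint_rel <= 0:
            raise ParameterError("magnitude/salience scales must be positive")


class SyntheticObserver:
    """Signal-detection observer with a private smooth linear feature map.

    The feature map F_obs projects pixels onto ``feature_dim`` smooth random
    fields (low-frequency Fourier modes), deliberately distinct from the
    optimizer's feature extractor: percept recovery must happen across
    feature spaces, as it does between a monkey's cortex and a generic
    pretrained network.
    """

    #: spatial Fourier modes per feature-map row
    _MAX_MODE = 3

    def __init__(
        self,
        image_size: int = 64,
        feature_dim: int = 16,
        feature_seed: int = 20_240_418,
        config: ObserverConfig | None = None,
        gain: float = 0.28,
    ) -> None:
        # gain is calibrated so a mid-magnitude perturbation's percept change
        # matches the 3 mW template norm and a full-magnitude one overshoots
        # it by ~1.7x (docs/methods.md)
        self.image_size = image_size
        self.feature_dim = feature_dim
        self.feature_seed = int(feature_seed)
        self.gain = gain
        self.config = config or ObserverConfig()
        self.config.validate()
        self._projection = self._build_projection()
        self._feature_cache: dict[str, np.ndarray] = {}
        self._percept_cache: dict[tuple, np.ndarray] = {}
        self._evidence_cache: dict[tuple, float] = {}

    def _build_projection(self) -> np.ndarray:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(self.feature_seed)))
        size = self.image_size
        grid = np.arange(size) / size
        yy, xx = np.meshgrid(grid, grid, indexing="ij")
        rows = np.empty((self.feature_dim, size, size, 3))
        m = self._MAX_MODE
        for i in range(self.feature_dim):
            fld = np.zeros((size, size))
            for u in range(m + 1):
                for v in range(m + 1):
                    if u == 0 and v == 0:
                        continue
                    a, b = rng.normal(size=2)
                    phase = 2.0 * np.pi * (u * xx + v * yy)
                    fld += a * np.cos(phase) + b * np.sin(phase)
            chan = rng.normal(size=3)
            rows[i] = fld[..., None] * chan[None, None, :]
        flat = rows.reshape(self.feature_dim, -1)
        flat /= np.linalg.norm(flat, axis=1, keepdims=True)
        return flat

    # -- feature map ---------------------------------------------------------
    def features(self, raster: ImageRaster) -> np.ndarray:
        """F_obs applied to a raster; cached by ``params_ref`` when present."""
        key = raster.params_ref
        if key is not None and key in self._feature_cache:
            return self._feature_cache[key]
        f = self.gain * (self._projection @ raster.pixels.reshape(-1))
        if key is not None:
            self._feature_cache[key] = f
        return f

    # -- perception ----------------------------------------------------------
    def perceive(
        self,
        context_seed: ImageRaster,
        perturbed: ImageRaster,
        stimulated: bool,
        site: StimulationSite,
    ) -> np.ndarray:
        """Percept-change vector for one trial.  Deterministic given inputs.

        p = F_obs(perturbed) - F_obs(context_seed); on stimulated trials the
        hidden template s is added and the component parallel to s is
        compressively saturated above ||s||: x -> ||s|| + beta * (x - ||s||).
        """
        if context_seed.pixels.shape != perturbed.pixels.shape:
            raise ParameterError("perturbed: raster shape differs from context seed")
        cache_key = None
        if perturbed.params_ref is not None and context_seed.params_ref is not None:
            cache_key = (
                perturbed.params_ref,
                context_seed.params_ref,
                bool(stimulated),
                site.site_id,
                site.intensity_mw,
            )
            if cache_key in self._percept_cache:
                return self._percept_cache[cache_key]
        p = self.features(perturbed) - self.features(context_seed)
        if stimulated:
            s = site.percept_vector(seed_key=context_seed.params_ref)
            s_norm = np.linalg.norm(s)
            p = p + s
            s_hat = s / s_norm
            parallel = float(p @ s_hat)
            if parallel > s_norm:
                compressed = s_norm + self.config.saturation_beta * (parallel - s_norm)
                p = p + (compressed - parallel) * s_hat
        if cache_key is not None:
            self._percept_cache[cache_key] = p
        return p

    # -- decision ------------------------------------------------------------
    def evidence(self, p: np.ndarray, site: StimulationSite, seed_key: str | None = None) -> float:
        """Deterministic evidence that the percept change was stimulation.

        e = cos(p, s) * exp(-(||p|| - ||s||)^2 / (2 sigma_m^2)) * ||p|| / (||p|| + k)
        with sigma_m and k proportional to ||s||; e = 0 for a zero percept.
        """
        p = np.asarray(p, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ParameterError("p: percept vector must be finite")
        norm_p = float(np.linalg.norm(p))
        if norm_p == 0.0:
            return 0.0
        s = site.percept_vector(seed_key=seed_key)
        norm_s = float(np.linalg.norm(s))
        cos = float(p @ s) / (norm_p * norm_s)
        sigma_m = self.config.magnitude_tolerance_rel * norm_s
        k = self.config.salience_halfpoint_rel * norm_s
        match = np.exp(-((norm_p - norm_s) ** 2) / (2.0 * sigma_m**2))
        salience = norm_p / (norm_p + k)
        return float(cos * match * salience)

    def decide(
        self,
        p: np.ndarray,
        site: StimulationSite,
        rng: np.random.Generator,
        seed_key: str | None = None,
    ) -> str:
        """Map a percept-change vector to a behavioral response.

        Draw order is fixed (abort, decision noise, lapse, lapse coin) so a
        given rng stream reproduces the same responses regardless of outcome.
        """
        return self._respond(self.evidence(p, site, seed_key=seed_key), rng)

    def _respond(self, evidence: float, rng: np.random.Generator) -> str:
        cfg = self.config
        abort_u = rng.random()
        eps = rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 0.0
        lapse_u = rng.random()
        coin_u = rng.random()
        if abort_u < cfg.abort_rate:
            return RESPONSE_ABORTED
        says_stim = evidence + eps > cfg.criterion
        if lapse_u < cfg.lapse_rate:
            says_stim = coin_u < 0.5
        return RESPONSE_STIMULATED if says_stim else RESPONSE_NOT_STIMULATED

    # -- fast path for the trial engine ---------------------------------------
    def trial_evidence(
        self,
        context_seed: ImageRaster,
        perturbed: ImageRaster,
        stimulated: bool,
        site: StimulationSite,
    ) -> float:
        """Evidence for a full trial; cached per (image, context, condition)."""
        key = None
        if perturbed.params_ref is not None and context_seed.params_ref is not None:
            key = (
                perturbed.params_ref,
                context_seed.params_ref,
                bool(stimulated),
                site.site_id,
                site.intensity_mw,
            )
            if key in self._evidence_cache:
                return self._evidence_cache[key]
        p = self.perceive(context_seed, perturbed, stimulated, site)
        e = self.evidence(p, site, seed_key=context_seed.params_ref)
        if key is not None:
            self._evidence_cache[key] = e
        return e

    def respond(
        self,
        context_seed: ImageRaster,
        perturbed: ImageRaster,
        stimulated: bool,
        site: StimulationSite,
        rng: np.random.Generator,
    ) -> str:
        return self._respond(
            self.trial_evidence(context_seed, perturbed, stimulated, site), rng
        )

    def clear_caches(self) -> None:
        self._feature_cache.clear()
        self._percept_cache.clear()
        self._evidence_cache.clear()

    # -- state persistence ----------------------------------------------------
    def state_dict(self, site: StimulationSite | None = None) -> dict:
        """Serializable observer state.  Marked observer-private: the file
        holds the hidden percept template parameters and must never be read
        by optimizer code."""
        d = {
            "_observer_private": True,
            "image_size": self.image_size,
            "feature_dim": self.feature_dim,
            "feature_seed": self.feature_seed,
            "gain": self.gain,
            "config": asdict(self.config),
        }
        if site is not None:
            d["site"] = site.to_dict()
        return d

    def save_state(self, path, site: StimulationSite | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(site), fh, indent=2)

    @classmethod
    def from_state_dict(cls, d: dict) -> tuple["SyntheticObserver", StimulationSite | None]:
        obs = cls(
            image_size=d["image_size"],
            feature_dim=d["feature_dim"],
            feature_seed=d["feature_seed"],
            config=ObserverConfig(**d["config"]),
            gain=d["gain"],
        )
        site = StimulationSite.from_dict(d["site"]) if "site" in d else None
        return obs, site

    @classmethod
    def load_state(cls, path) -> tuple["SyntheticObserver", StimulationSite | None]:
        with open(path) as fh:
            return cls.from_state_dict(json.load(fh))


def attune_site_to_seeds(
    site: StimulationSite,
    observer: SyntheticObserver,
    space,
    seed_params: dict,
    hidden_magnitude: float = 0.6,
) -> None:
    """Attune a stimulation site to concrete seed images (observer-private).

    For each seed, the hidden percept direction becomes the observer-feature
    direction of one concealed random perturbation of that seed — the
    "to-be-discovered perceptogram".  This encodes the premise that local
    stimulation produces an image-like perceptual event that depends on the
    fixated seed, and it guarantees the percept is visually achievable while
    remaining unknown to (and unread by) the optimizer.  Deterministic given
    the site seed.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((site.site_seed, 0xA77)))
    )
    for seed_id in sorted(seed_params):
        params = seed_params[seed_id]
        hidden = space.perturb_random(params, hidden_magnitude, rng)
        d = observer.features(space.render(hidden)) - observer.features(
            space.render(params)
        )
        site.set_seed_direction(seed_id, d)


def percept_alignment(
    observer: SyntheticObserver,
    site: StimulationSite,
    seed_raster: ImageRaster,
    image_raster: ImageRaster,
) -> float:
    """Cosine between an image's percept change and the hidden template.

    Evaluation-only: this reads the hidden percept vector and therefore lives
    with the observer, never with the optimizer.  It is how a campaign's
    winning image is judged to have recovered the stimulation percept.
    """
    d = observer.features(image_raster) - observer.features(seed_raster)
    s = site.percept_vector(seed_key=seed_raster.params_ref)
    denom = np.linalg.norm(d) * np.linalg.norm(s)
    if denom == 0:
        return 0.0
    return float(d @ s / denom)
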