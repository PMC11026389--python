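"""Parametric generative image space (the "illustrator" engine).

A deterministic, desk-scale stand-in for a GAN image generator.  Stimuli are
described by :class:`LatentImageParams`: a two-layer composition where each
layer is a mixture over ``K`` synthetic texture *classes* plus a latent vector
``z`` that excites a fixed bank of smooth cosine-grating basis textures.  The
top (overlay) layer is alpha-blended over the base layer, which is how a seed
image acquires controlled amounts of "non-seed-class" content.

The class/latent/truncation/alpha parameterization — and the operations the
closed loop needs (random perturbation at a controlled magnitude, mutation of
survivors, iterative reconstruction of an arbitrary target) — mirror what a
generative-model-backed illustrator exposes, without neural networks or GPUs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "LatentImageParams",
    "ImageRaster",
    "ReconstructionResult",
    "ImageSpace",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class LatentImageParams:
    """Generative description of one stimulus.

    Attributes
    ----------
    seed_class_weights:
        Non-negative mixture over the K classes for the base layer; sums to 1.
    z:
        Latent coefficients (length ``D_z``) for the base layer's texture basis.
    overlay_class_weights:
        Class mixture of the top layer; sums to 1.
    z_overlay:
        Latent coefficients of the top layer.
    alpha:
        Transparency of the top layer in [0, 1]; 0 shows the base layer only.
    truncation:
        Positive bound on the magnitude of every latent entry.
    """

    seed_class_weights: np.ndarray
    z: np.ndarray
    overlay_class_weights: np.ndarray
    z_overlay: np.ndarray
    alpha: float
    truncation: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seed_class_weights", np.asarray(self.seed_class_weights, dtype=float)
        )
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(
            self,
            "overlay_class_weights",
            np.asarray(self.overlay_class_weights, dtype=float),
        )
        object.__setattr__(self, "z_overlay", np.asarray(self.z_overlay, dtype=float))

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ParameterError` naming the first offending field."""
        for name in ("seed_class_weights", "overlay_class_weights"):
            w = getattr(self, name)
            if w.ndim != 1 or w.size == 0:
                raise ParameterError(f"{name}: must be a non-empty 1-D vector")
            if np.any(w < 0):
                raise ParameterError(f"{name}: negative entries are not allowed")
            if abs(float(w.sum()) - 1.0) > _WEIGHT_TOL:
                raise ParameterError(f"{name}: must sum to 1 (got {w.sum():.12f})")
        if self.seed_class_weights.size != self.overlay_class_weights.size:
            raise ParameterError("overlay_class_weights: class count differs from base")
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha: {self.alpha} outside [0, 1]")
        if not self.truncation > 0:
            raise ParameterError(f"truncation: {self.truncation} must be positive")
        for name in ("z", "z_overlay"):
            v = getattr(self, name)
            if v.ndim != 1:
                raise ParameterError(f"{name}: must be a 1-D vector")
            if np.any(np.abs(v) > self.truncation + 1e-12):
                raise ParameterError(
                    f"{name}: entry exceeds truncation bound {self.truncation}"
                )
        if self.z.size != self.z_overlay.size:
            raise ParameterError("z_overlay: latent dimension differs from z")

    @property
    def n_classes(self) -> int:
        return int(self.seed_class_weights.size)

    @property
    def latent_dim(self) -> int:
        return int(self.z.size)

    def effective_class_weights(self) -> np.ndarray:
        """Alpha-blended class mixture of the composite image."""
        return (1.0 - self.alpha) * self.seed_class_weights + self.alpha * self.overlay_class_weights

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed_class_weights": self.seed_class_weights.tolist(),
            "z": self.z.tolist(),
            "overlay_class_weights": self.overlay_class_weights.tolist(),
            "z_overlay": self.z_overlay.tolist(),
            "alpha": float(self.alpha),
            "truncation": float(self.truncation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentImageParams":
        return cls(
            seed_class_weights=np.asarray(d["seed_class_weights"], dtype=float),
            z=np.asarray(d["z"], dtype=float),
            overlay_class_weights=np.asarray(d["overlay_class_weights"], dtype=float),
            z_overlay=np.asarray(d["z_overlay"], dtype=float),
            alpha=float(d["alpha"]),
            truncation=float(d["truncation"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "LatentImageParams":
        return cls.from_dict(json.loads(s))


@dataclass
class ImageRaster:
    """Rendered stimulus: H x W x 3 intensities in [0, 1]."""

    pixels: np.ndarray
    params_ref: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ParameterError("pixels: expected an H x W x 3 array")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1.0 + 1e-12:
            raise ParameterError("pixels: intensities outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class ReconstructionResult:
    """Outcome of iterative target reconstruction."""

    params: LatentImageParams
    loss: float
    loss_history: list[float] = field(default_factory=list)
    n_accepted: int = 0


def _gratings(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """n smooth zero-mean cosine gratings on a size x size grid, peak |.| = 1."""
    yy, xx = np.meshgrid(
        np.arange(size) / size, np.arange(size) / size, indexing="ij"
    )
    out = np.empty((n, size, size))
    for i in range(n):
        # random orientation/frequency; keep at least half a cycle per image
        f = rng.uniform(0.75, 5.0)
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        fx, fy = f * np.cos(theta), f * np.sin(theta)
        out[i] = np.cos(2.0 * np.pi * (fx * xx + fy * yy) + phase)
    return out


class ImageSpace:
    """Deterministic procedural renderer over K texture classes.

    Each class owns a colored mean texture and ``latent_dim`` achromatic
    grating basis functions; a latent vector sets the basis coefficients.
    Rendering is a pure function of the parameters: identical params give
    bit-identical rasters.
    """

    def __init__(
        self,
        n_classes: int = 16,
        latent_dim: int = 12,
        size: int = 64,
        texture_seed: int = 1234,
        mean_amplitude: float = 0.30,
        basis_amplitude: float = 0.035,
        truncation: float = 2.0,
    ) -> None:
        self.n_classes = n_classes
        self.latent_dim = latent_dim
        self.size = size
        self.truncation = truncation
        rng = np.random.Generator(np.random.PCG64(texture_seed))
        # class mean maps: 0.5 + colored mixture of three gratings
        means = np.empty((n_classes, size, size, 3))
        for k in range(n_classes):
            g = _gratings(rng, 3, size)
            cols = rng.uniform(-1.0, 1.0, size=(3, 3))
            cols /= np.maximum(np.abs(cols).sum(axis=0, keepdims=True), 1e-9)
            means[k] = 0.5 + mean_amplitude * np.einsum("ghw,gc->hwc", g, cols)
        self._means = means
        # achromatic basis: (K, D_z, H, W)
        basis = np.empty((n_classes, latent_dim, size, size))
        for k in range(n_classes):
            basis[k] = _gratings(rng, latent_dim, size)
        self._basis = basis_amplitude * basis
        self._basis_flat = self._basis.reshape(n_classes * latent_dim, size * size)

    # -- parameter constructors --------------------------------------------
    def seed_params(self, class_index: int, rng: np.random.Generator) -> LatentImageParams:
        """Canonical single-layer seed: one-hot class, moderate random latent."""
        if not 0 <= class_index < self.n_classes:
            raise ParameterError(f"class_index: {class_index} outside [0, {self.n_classes})")
        w = np.zeros(self.n_classes)
        w[class_index] = 1.0
        z = rng.uniform(-0.5 * self.truncation, 0.5 * self.truncation, self.latent_dim)
        return LatentImageParams(
            seed_class_weights=w,
            z=z,
            overlay_class_weights=w.copy(),
            z_overlay=np.zeros(self.latent_dim),
            alpha=0.0,
            truncation=self.truncation,
        )

    def random_params(self, rng: np.random.Generator) -> LatentImageParams:
        """Fully random two-layer params (used to start target reconstruction)."""
        return LatentImageParams(
            seed_class_weights=rng.dirichlet(np.ones(self.n_classes)),
            z=rng.uniform(-self.truncation, self.truncation, self.latent_dim),
            overlay_class_weights=rng.dirichlet(np.ones(self.n_classes)),
            z_overlay=rng.uniform(-self.truncation, self.truncation, self.latent_dim),
            alpha=float(rng.uniform(0.0, 1.0)),
            truncation=self.truncation,
        )

    # -- rendering ----------------------------------------------------------
    def _layer_batch(self, weights: np.ndarray, latents: np.ndarray) -> np.ndarray:
        """Render N single layers from (N, K) weights and (N, D_z) latents."""
        mean = np.einsum("nk,khwc->nhwc", weights, self._means)
        coeff = (weights[:, :, None] * latents[:, None, :]).reshape(weights.shape[0], -1)
        texture = coeff @ self._basis_flat
        return mean + texture.reshape(-1, self.size, self.size)[..., None]

    def render_batch(self, params_list: Sequence[LatentImageParams]) -> np.ndarray:
        """Render many params at once; returns (N, H, W, 3) clipped to [0, 1]."""
        n = len(params_list)
        wb = np.stack([p.seed_class_weights for p in params_list])
        zb = np.stack([p.z for p in params_list])
        wo = np.stack([p.overlay_class_weights for p in params_list])
        zo = np.stack([p.z_overlay for p in params_list])
        a = np.array([p.alpha for p in params_list])[:, None, None, None]
        base = self._layer_batch(wb, zb)
        overlay = self._layer_batch(wo, zo)
        composite = (1.0 - a) * base + a * overlay
        np.clip(composite, 0.0, 1.0, out=composite)
        return composite if n else composite.reshape(0, self.size, self.size, 3)

    def render(self, params: LatentImageParams, params_ref: str | None = None) -> ImageRaster:
        """Render one stimulus.  Deterministic; validates invariants first."""
        params.validate()
        if params.n_classes != self.n_classes or params.latent_dim != self.latent_dim:
            raise ParameterError(
                "params: class/latent dimensions do not match this image space"
            )
        pixels = self.render_batch([params])[0]
        return ImageRaster(pixels=pixels, params_ref=params_ref)

    # -- perturbation / magnitude -------------------------------------------
    def perturb_random(
        self,
        seed: LatentImageParams,
        magnitude: float,
        rng: np.random.Generator,
    ) -> LatentImageParams:
        """Random perturbation of ``seed`` with controlled non-seed content.

        The base layer is taken from the seed unchanged; a random overlay is
        drawn entirely over non-seed classes with a fresh latent, and the
        transparency is solved so the composite's class-weight mass off the
        seed's dominant class equals ``magnitude`` (exactly, for single-layer
        seeds).  ``magnitude`` = 0 therefore reproduces the seed raster and
        ``magnitude`` = 1 leaves zero effective mass on the seed class.
        """
        seed.validate()
        if not 0.0 <= magnitude <= 1.0:
            raise ParameterError(f"magnitude: {magnitude} outside [0, 1]")
        eff = seed.effective_class_weights()
        dom = int(np.argmax(eff))
        base_dom = float(seed.seed_class_weights[dom])
        if base_dom <= 0:
            raise ParameterError("seed: dominant effective class has zero base weight")
        # overlay supported on non-dominant classes only; a sparse Dirichlet
        # concentrates the overlay on one or two classes, like superimposing
        # a single random image rather than an average of all classes
        w_over = np.zeros(self.n_classes)
        others = [k for k in range(self.n_classes) if k != dom]
        w_over[others] = rng.dirichlet(np.full(len(others), 0.2))
        z_over = rng.uniform(-seed.truncation, seed.truncation, self.latent_dim)
        # solve (1 - alpha) * base_dom = (1 - magnitude) * eff_dom
        alpha = 1.0 - (1.0 - magnitude) * float(eff[dom]) / base_dom
        alpha = float(np.clip(alpha, 0.0, 1.0))
        return LatentImageParams(
            seed_class_weights=seed.seed_class_weights.copy(),
            z=seed.z.copy(),
            overlay_class_weights=w_over,
            z_overlay=z_over,
            alpha=alpha,
            truncation=seed.truncation,
        )

    def measure_magnitude(
        self, seed: LatentImageParams, perturbed: LatentImageParams
    ) -> float:
        """Normalized feature distance of ``perturbed`` from the seed class.

        Fraction of the composite class-weight mass that has left the seed's
        dominant class, relative to the seed's own mass there: 0 when the
        perturbation contributes no non-seed-class content, 1 when all
        effective mass is sourced from other classes.
        """
        seed.validate()
        perturbed.validate()
        if (
            seed.n_classes != perturbed.n_classes
            or seed.latent_dim != perturbed.latent_dim
        ):
            raise ParameterError("perturbed: class/latent dimensions differ from seed")
        eff_s = seed.effective_class_weights()
        dom = int(np.argmax(eff_s))
        es = float(eff_s[dom])
        if es <= 0:
            raise ParameterError("seed: degenerate class weights")
        ep = float(perturbed.effective_class_weights()[dom])
        return float(np.clip(1.0 - ep / es, 0.0, 1.0))

    # -- mutation ------------------------------------------------------------
    def mutate(
        self,
        parent: LatentImageParams,
        n_children: int,
        spread: float,
        rng: np.random.Generator,
    ) -> list[LatentImageParams]:
        """Jitter ``parent`` into 2-6 children (the fixed family-size range).

        Gaussian noise of scale 0.3*spread on latents and 0.05*spread on
        alpha; class weights are resampled from a Dirichlet centered on the
        parent with concentration 1/spread, so children concentrate on the
        parent as spread -> 0.
        """
        parent.validate()
        if not isinstance(n_children, (int, np.integer)) or not 2 <= n_children <= 6:
            raise ParameterError(
                f"n_children: {n_children} outside the fixed family range [2, 6]"
            )
        if not spread > 0:
            raise ParameterError(f"spread: {spread} must be positive")
        children = []
        t = parent.truncation
        for _ in range(n_children):
            z = np.clip(parent.z + rng.normal(0.0, 0.3 * spread, self.latent_dim), -t, t)
            zo = np.clip(
                parent.z_overlay + rng.normal(0.0, 0.3 * spread, self.latent_dim), -t, t
            )
            alpha = float(np.clip(parent.alpha + rng.normal(0.0, 0.05 * spread), 0.0, 1.0))
            wb = self._dirichlet_jitter(parent.seed_class_weights, spread, rng)
            wo = self._dirichlet_jitter(parent.overlay_class_weights, spread, rng)
            children.append(
                LatentImageParams(
                    seed_class_weights=wb,
                    z=z,
                    overlay_class_weights=wo,
                    z_overlay=zo,
                    alpha=alpha,
                    truncation=t,
                )
            )
        return children

    @staticmethod
    def _dirichlet_jitter(
        weights: np.ndarray, spread: float, rng: np.random.Generator
    ) -> np.ndarray:
        # concentration 1/spread around the parent; small floor keeps the
        # Dirichlet proper when the parent weight vector has zeros
        conc = (weights + 1e-3) / spread
        w = rng.dirichlet(conc)
        w = np.maximum(w, 0.0)
        return w / w.sum()

    # -- target reconstruction ------------------------------------------------
    def reconstruct_target(
        self,
        target: ImageRaster,
        n_iters: int,
        rng: np.random.Generator,
        init: LatentImageParams | None = None,
    ) -> ReconstructionResult:
        """(1+1) hill climb minimizing pixel RMSE to ``target``.

        Proposals jitter the incumbent with a step size that decays
        geometrically (factor 0.97) after every 20 consecutive rejections.
        The accepted-loss trajectory is non-increasing by construction.
        """
        if target.pixels.shape != (self.size, self.size, 3):
            raise ParameterError("target: raster shape does not match this image space")
        if n_iters < 1:
            raise ParameterError(f"n_iters: {n_iters} must be >= 1")
        best = init if init is not None else self.random_params(rng)
        best_loss = self._rmse_to(best, target.pixels)
        history = [best_loss]
        step = 1.0
        rejections = 0
        accepted = 0
        for _ in range(n_iters):
            cand = self._jitter(best, step, rng)
            loss = self._rmse_to(cand, target.pixels)
            if loss <= best_loss:
                best, best_loss = cand, loss
                history.append(best_loss)
                accepted += 1
                rejections = 0
            else:
                rejections += 1
                if rejections >= 20:
                    step *= 0.97
                    rejections = 0
        return ReconstructionResult(
            params=best, loss=best_loss, loss_history=history, n_accepted=accepted
        )

    def _rmse_to(self, params: LatentImageParams, target_pixels: np.ndarray) -> float:
        rendered = self.render_batch([params])[0]
        return float(np.sqrt(np.mean((rendered - target_pixels) ** 2)))

    def _jitter(
        self, p: LatentImageParams, step: float, rng: np.random.Generator
    ) -> LatentImageParams:
        t = p.truncation
        return LatentImageParams(
            seed_class_weights=self._dirichlet_jitter(p.seed_class_weights, 0.2 * step, rng),
            z=np.clip(p.z + rng.normal(0.0, 0.3 * step, self.latent_dim), -t, t),
            overlay_class_weights=self._dirichlet_jitter(
                p.overlay_class_weights, 0.2 * step, rng
            ),
            z_overlay=np.clip(
                p.z_overlay + rng.normal(0.0, 0.3 * step, self.latent_dim), -t, t
            ),
            alpha=float(np.clip(p.alpha + rng.normal(0.0, 0.1 * step), 0.0, 1.0)),
            truncation=t,
        )


def save_png(raster: ImageRaster, path) -> None:
    """Write a raster as an 8-bit RGB PNG."""
    from PIL import Image

    arr = np.clip(np.round(raster.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_png(path, params_ref: str | None = None) -> ImageRaster:
    """Read an 8-bit RGB PNG back into a raster with intensities in [0, 1]."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    return ImageRaster(pixels=arr, params_ref=params_ref)
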