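"""Activation maximization of trained classifiers ("DeepDream").

Synthesizes class-characteristic spectrogram stacks by gradient ascent on a
target logit with respect to the input, starting from a null or random-noise
image.  The per-iteration gradient is normalized by its mean absolute value
(standard practice; a fixed step size is meaningless without it) and the
image is clamped to +/-6 standardized units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nets import Network
from .synth import ParameterError

__all__ = ["DreamParams", "DreamMap", "dream", "dream_over_folds",
           "bandtime_summary"]

CLAMP = 6.0


@dataclass(frozen=True)
class DreamParams:
    n_iterations: int = 30
    step_size: float = 1.0
    seed_mode: str = "random_noise"  # or "null_image"
    n_seeds: int = 8
    target: int = 1  # class index; 1 = ADHD
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 0:
            raise ParameterError("n_iterations must be >= 0")
        if self.step_size <= 0:
            raise ParameterError("step_size must be > 0")
        if self.seed_mode not in ("null_image", "random_noise"):
            raise ParameterError("seed_mode must be null_image or random_noise")
        if self.n_seeds < 1:
            raise ParameterError("n_seeds must be >= 1")


@dataclass
class DreamMap:
    """Fold/seed-averaged class-maximizing stacks and their difference."""

    class_stacks: dict[str, np.ndarray]  # group -> (F, T, C)
    class_maps: dict[str, np.ndarray]  # group -> (F, T), channel-averaged
    difference: np.ndarray  # ADHD map - HC map, (F, T)
    freqs: np.ndarray
    time_centres: np.ndarray
    n_models: int


def _input_gradient(model: Network, x: np.ndarray, target: int) -> np.ndarray:
    logits = model.forward(x, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[:, target] = 1.0
    return np.asarray(model.backward(dlogits), dtype=np.float64)


def dream(model: Network, params: DreamParams,
          input_shape: tuple[int, int, int] = (22, 20, 7),
          rng: np.random.Generator | None = None) -> np.ndarray:
    """Gradient-ascent synthesis of one class-maximizing stack."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.seed_mode == "null_image":
        x = np.zeros((1,) + input_shape)
    else:
        x = rng.normal(0.0, params.noise_sd, size=(1,) + input_shape)
    for it in range(params.n_iterations):
        grad = _input_gradient(model, x, params.target)
        scale = np.abs(grad).mean()
        if scale == 0.0:
            if params.seed_mode == "null_image" and it == 0:
                warnings.warn("zero gradient at null seed; restarting from "
                              "random noise")
                x = rng.normal(0.0, params.noise_sd, size=(1,) + input_shape)
                continue
            break
        x = x + params.step_size * grad / scale
        np.clip(x, -CLAMP, CLAMP, out=x)
    return x[0]


def dream_over_folds(models: list[Network], params: DreamParams,
                     freqs: np.ndarray | None = None,
                     time_centres: np.ndarray | None = None,
                     input_shape: tuple[int, int, int] = (22, 20, 7),
                     ) -> DreamMap:
    """Class dreams averaged over fold models and noise seeds."""
    params.validate()
    if not models:
        raise ParameterError("empty model list")
    stacks = {}
    for group, target in (("HC", 0), ("ADHD", 1)):
        acc = np.zeros(input_shape)
        count = 0
        for model in models:
            for si in range(params.n_seeds):
                # noise seeds are shared across models so the fold average is
                # invariant to model order
                rng = np.random.default_rng(
                    np.random.SeedSequence((params.seed, target, si)))
                p = DreamParams(
                    n_iterations=params.n_iterations,
                    step_size=params.step_size, seed_mode=params.seed_mode,
                    n_seeds=1, target=target, noise_sd=params.noise_sd,
                    seed=params.seed)
                acc += dream(model, p, input_shape=input_shape, rng=rng)
                count += 1
        stacks[group] = acc / count
    maps = {g: s.mean(axis=-1) for g, s in stacks.items()}
    nf, nt, _ = input_shape
    return DreamMap(
        class_stacks=stacks,
        class_maps=maps,
        difference=maps["ADHD"] - maps["HC"],
        freqs=np.asarray(freqs) if freqs is not None else np.arange(nf, dtype=float),
        time_centres=(np.asarray(time_centres) if time_centres is not None
                      else np.arange(nt, dtype=float)),
        n_models=len(models),
    )


def bandtime_summary(dmap: DreamMap, band: tuple[float, float],
                     window: tuple[float, float]) -> float:
    """Mean of difference-map cells with frequency in ``band`` (inclusive)
    and time-bin centre in ``window`` (inclusive)."""
    fmask = (dmap.freqs >= band[0]) & (dmap.freqs <= band[1])
    tmask = (dmap.time_centres >= window[0]) & (dmap.time_centres <= window[1])
    if not fmask.any() or not tmask.any():
        raise ParameterError("band/window selects no spectrogram cells")
    return float(dmap.difference[np.ix_(fmask, tmask)].mean())
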