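"""Stage-1 image enhancement: blurry-frame selection and pluggable
deblurring stages.

Endoscope motion produces non-uniform blur across a sequence; the
pipeline's first stage scores frame sharpness, selects the relatively
blurry frames, enhances only those, and merges them back so the
downstream reconstruction sees a uniformly sharp sequence. The heavy
diffusion-network deblurrer used clinically is a pretrained model and is
deliberately *not* part of this package; it plugs into the same
:class:`DeblurStage` interface that the built-in classical stages
(identity, unsharp mask, Wiener) implement, keeping the two-stage
pipeline shape testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence

import numpy as np
from scipy.ndimage import laplace

from .scene import InvalidParameterError


class ConfigurationError(ValueError):
    pass


@dataclass
class DeblurStage:
    """A named image -> image map preserving shape and [0, 1] range."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    parameters: dict = field(default_factory=dict)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        out = self.fn(np.asarray(image, dtype=np.float64))
        return np.clip(out, 0.0, 1.0)


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        return image @ np.array([0.299, 0.587, 0.114])
    return image


def blurriness_score(image: np.ndarray) -> float:
    """Variance of the Laplacian response (higher = sharper)."""
    return float(np.var(laplace(_to_gray(image))))


def select_blurry_frames(frames: Sequence[np.ndarray],
                         percentile: float = 25.0,
                         threshold: float = None) -> np.ndarray:
    """Indices of the relatively blurry frames.

    Percentile mode (default): the ceil(q% * n) frames with the lowest
    sharpness scores, ties broken by frame index. Threshold mode: frames
    with score strictly below ``threshold``.
    """
    if len(frames) == 0:
        raise InvalidParameterError("empty frame sequence")
    scores = np.array([blurriness_score(f) for f in frames])
    if threshold is not None:
        return np.nonzero(scores < threshold)[0]
    n_sel = int(np.ceil(percentile / 100.0 * len(frames)))
    order = np.argsort(scores, kind="stable")  # ties keep index order
    return np.sort(order[:n_sel])


def _unsharp_stage(amount: float = 1.0, radius: float = 2.0) -> DeblurStage:
    from skimage.filters import unsharp_mask

    def fn(img):
        ch = img.ndim == 3
        return unsharp_mask(img, radius=radius, amount=amount,
                            channel_axis=2 if ch else None)
    return DeblurStage("unsharp_mask", fn,
                       {"amount": amount, "radius": radius})


def _wiener_stage(kernel: int = 5) -> DeblurStage:
    from scipy.signal import wiener

    def fn(img):
        if img.ndim == 2:
            return wiener(img, kernel)
        out = np.empty_like(img)
        for c in range(img.shape[2]):
            out[:, :, c] = wiener(img[:, :, c], kernel)
        return out
    return DeblurStage("wiener", fn, {"kernel": kernel})


_STAGES: Dict[str, Callable[..., DeblurStage]] = {
    "identity": lambda: DeblurStage("identity", lambda img: img),
    "unsharp_mask": _unsharp_stage,
    "wiener": _wiener_stage,
}


def register_stage(name: str, factory: Callable[..., DeblurStage]) -> None:
    """Register an external enhancement stage (e.g. a diffusion-network
    adapter) under the common interface."""
    _STAGES[name] = factory


def get_stage(name: str, **params) -> DeblurStage:
    if name not in _STAGES:
        raise ConfigurationError(
            f"unknown deblur stage {name!r}; available: {sorted(_STAGES)}")
    return _STAGES[name](**params)


def run_deblur_stage(frames: Sequence[np.ndarray], selected,
                     stage: DeblurStage):
    """Replace the selected frames by the stage's output; unselected
    frames pass through bit-identically."""
    selected = set(int(i) for i in np.atleast_1d(np.asarray(selected, dtype=int)))
    return [stage(f) if i in selected else f for i, f in enumerate(frames)]


def enhance_sequence(frames: Sequence[np.ndarray], stage_name: str = "identity",
                     percentile: float = 25.0, **params):
    """Select + enhance in one call; returns (frames, selected indices)."""
    stage = get_stage(stage_name, **params)
    sel = select_blurry_frames(frames, percentile=percentile)
    return run_deblur_stage(frames, sel, stage), sel
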