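"""Image-quality metrics: windowed SSIM, PSNR, a pluggable LPIPS adapter,
and the single-scale-train / multi-scale-test evaluation protocol.

SSIM follows the standard windowed form

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with local statistics taken under an 11x11 Gaussian window (sigma = 1.5)
and stabilizers c1 = (0.01 MAX_I)^2, c2 = (0.03 MAX_I)^2. The map is
averaged over the interior region where the window fits entirely inside
the image (so the result does not depend on a boundary convention) and
over channels. The implementation is differentiable: ``ssim`` can return
the gradient with respect to the first image, which the training loss
(L = (1 - lambda) L1 + lambda (1 - SSIM)) requires.

PSNR is 20 log10(MAX_I / sqrt(MSE)) dB; identical images report inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import correlate1d

from .scene import Camera, GaussianCloud, InvalidParameterError

SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
K1, K2 = 0.01, 0.03

_lpips_backend: Optional[Callable[[np.ndarray, np.ndarray], float]] = None


def register_lpips_backend(fn: Optional[Callable[[np.ndarray, np.ndarray], float]]):
    """Install a learned-perceptual-metric backend (e.g. a pretrained
    feature network). ``None`` removes it; without a backend, reports
    simply omit the LPIPS column."""
    global _lpips_backend
    _lpips_backend = fn


def lpips(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    if _lpips_backend is None:
        return None
    return float(_lpips_backend(x, y))


def _gaussian_taps(size=SSIM_WINDOW, sigma=SSIM_SIGMA):
    r = size // 2
    t = np.exp(-np.arange(-r, r + 1, dtype=np.float64) ** 2 / (2 * sigma ** 2))
    return t / t.sum()


_TAPS = _gaussian_taps()


def _filt(img: np.ndarray) -> np.ndarray:
    # boundary mode is irrelevant: statistics are only read on the
    # interior region where the 11x11 window fits entirely
    out = correlate1d(img, _TAPS, axis=0, mode="nearest")
    return correlate1d(out, _TAPS, axis=1, mode="nearest")


def _scatter_back(g: np.ndarray) -> np.ndarray:
    # adjoint of _filt restricted to the interior: zero-pad then correlate
    out = correlate1d(g, _TAPS, axis=0, mode="constant", cval=0.0)
    return correlate1d(out, _TAPS, axis=1, mode="constant", cval=0.0)


def reference_stats(y: np.ndarray):
    """Precompute the filtered statistics of a fixed reference image so
    repeated :func:`ssim` calls against it skip that work."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 2:
        y = y[:, :, None]
    mu_y = _filt(y)
    return {"y": y, "mu_y": mu_y, "var_y": _filt(y * y) - mu_y ** 2}


def ssim(x: np.ndarray, y: np.ndarray, max_i: float = 1.0,
         return_grad: bool = False, y_stats: Optional[dict] = None):
    """Mean windowed SSIM of two images (H, W) or (H, W, C) in [0, max_i].

    With ``return_grad`` also returns d(SSIM)/dx. ``y_stats`` (from
    :func:`reference_stats`) skips recomputing the reference image's
    windowed statistics.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidParameterError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.ndim == 2:
        x = x[:, :, None]
        y = y[:, :, None]
    H, W, C = x.shape
    pad = SSIM_WINDOW // 2
    if H < SSIM_WINDOW or W < SSIM_WINDOW:
        raise InvalidParameterError(
            f"images must be at least {SSIM_WINDOW}x{SSIM_WINDOW} for SSIM")
    c1 = (K1 * max_i) ** 2
    c2 = (K2 * max_i) ** 2

    # one separable pass over the stacked fields (x, x^2, xy)
    fx = _filt(np.concatenate([x, x * x, x * y], axis=2))
    mu_x, m_xx, m_xy = fx[:, :, :C], fx[:, :, C:2 * C], fx[:, :, 2 * C:]
    if y_stats is not None:
        mu_y = y_stats["mu_y"]
        m_yy = y_stats["var_y"] + mu_y ** 2
    else:
        mu_y = _filt(y)
        m_yy = _filt(y * y)
    var_x = m_xx - mu_x ** 2
    var_y = m_yy - mu_y ** 2
    cov = m_xy - mu_x * mu_y

    a1 = 2 * mu_x * mu_y + c1
    a2 = 2 * cov + c2
    b1 = mu_x ** 2 + mu_y ** 2 + c1
    b2 = var_x + var_y + c2
    smap = (a1 * a2) / (b1 * b2)

    interior = np.zeros((H, W, C))
    interior[pad:H - pad, pad:W - pad, :] = 1.0
    n = interior.sum()
    value = float((smap * interior).sum() / n)
    if not return_grad:
        return value

    # d(mean SSIM)/dx via the filtered fields (mu_x, m_xx, m_xy)
    gs = interior / n
    d_mu = gs * ((2 * mu_y * a2 - 2 * mu_y * a1) / (b1 * b2)
                 - smap * (2 * mu_x / b1 - 2 * mu_x / b2))
    d_mxx = gs * (-smap / b2)
    d_mxy = gs * (2 * a1 / (b1 * b2))
    sb = _scatter_back(np.concatenate([d_mu, d_mxx, d_mxy], axis=2))
    grad = sb[:, :, :C] + 2.0 * x * sb[:, :, C:2 * C] + y * sb[:, :, 2 * C:]
    return value, grad


def psnr(x: np.ndarray, y: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; inf for identical images."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidParameterError(f"shape mismatch {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return 20.0 * np.log10(max_i / np.sqrt(mse))


def mse(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidParameterError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def downsample_box(image: np.ndarray, factor: int) -> np.ndarray:
    """Box-average downsampling by an integer factor."""
    H, W = image.shape[:2]
    if H % factor or W % factor:
        raise InvalidParameterError(
            f"image size {H}x{W} not divisible by factor {factor}")
    shape = (H // factor, factor, W // factor, factor) + image.shape[2:]
    return np.asarray(image, dtype=np.float64).reshape(shape).mean(axis=(1, 3))


def downsample_bilinear(image: np.ndarray, factor: int) -> np.ndarray:
    from skimage.transform import resize
    H, W = image.shape[:2]
    return resize(np.asarray(image, dtype=np.float64),
                  (H // factor, W // factor), order=1, anti_aliasing=True)


@dataclass
class MetricReport:
    """Per-image and mean metrics at one resolution factor."""

    resolution_factor: float
    image_ids: list = field(default_factory=list)
    psnr_values: list = field(default_factory=list)
    ssim_values: list = field(default_factory=list)
    lpips_values: Optional[list] = None

    @property
    def mean_psnr(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim_values))

    @property
    def mean_lpips(self) -> Optional[float]:
        if self.lpips_values is None:
            return None
        return float(np.mean(self.lpips_values))

    def to_frame(self):
        import pandas as pd
        data = {"image_id": self.image_ids,
                "factor": [self.resolution_factor] * len(self.image_ids),
                "psnr": self.psnr_values, "ssim": self.ssim_values}
        if self.lpips_values is not None:
            data["lpips"] = self.lpips_values
        return pd.DataFrame(data)


def evaluate_views(cloud: GaussianCloud, cameras: Sequence[Camera],
                   gt_images: Sequence[np.ndarray], factor: int = 1,
                   filter_scale: float = 0.3, background=(0.0, 0.0, 0.0),
                   downsample: str = "box") -> MetricReport:
    """Render each view at 1/factor resolution (scaled intrinsics) and
    compare against downsampled ground truth."""
    from .rasterizer import render
    down = {"box": downsample_box, "bilinear": downsample_bilinear}[downsample]
    report = MetricReport(resolution_factor=1.0 / factor)
    use_lpips = _lpips_backend is not None
    if use_lpips:
        report.lpips_values = []
    for i, (cam, gt) in enumerate(zip(cameras, gt_images)):
        cam_f = cam.scaled(1.0 / factor) if factor != 1 else cam
        gt_f = down(gt, factor) if factor != 1 else np.asarray(gt, dtype=np.float64)
        img = render(cloud, cam_f, filter_scale=filter_scale,
                     background=background).pixels
        report.image_ids.append(i)
        report.psnr_values.append(psnr(img, gt_f))
        report.ssim_values.append(ssim(img, gt_f))
        if use_lpips:
            report.lpips_values.append(lpips(img, gt_f))
    return report


def evaluate_multiresolution(cloud: GaussianCloud, cameras: Sequence[Camera],
                             gt_images: Sequence[np.ndarray],
                             factors: Sequence[int] = (1, 2, 4, 8),
                             filter_scale: float = 0.3,
                             background=(0.0, 0.0, 0.0),
                             downsample: str = "box"):
    """Single-scale-train / multi-scale-test protocol.

    Renders every view at 1, 1/2, 1/4, 1/8 ... resolution and returns one
    :class:`MetricReport` per factor plus an average row (a dict with the
    arithmetic means across factors).
    """
    reports = [evaluate_views(cloud, cameras, gt_images, factor=f,
                              filter_scale=filter_scale, background=background,
                              downsample=downsample)
               for f in factors]
    avg = {"psnr": float(np.mean([r.mean_psnr for r in reports])),
           "ssim": float(np.mean([r.mean_ssim for r in reports]))}
    if all(r.lpips_values is not None for r in reports):
        avg["lpips"] = float(np.mean([r.mean_lpips for r in reports]))
    return reports, avg


def write_report_csv(path, reports) -> None:
    import pandas as pd
    frames = [r.to_frame() for r in reports]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
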