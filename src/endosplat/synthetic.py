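"""Procedural endoscopy-like fixtures: tube-shaped cavity scenes,
fly-through camera trajectories and posed-image datasets.

Real nasal-endoscopy footage is a monocular fly-through of a narrow,
curved, texture-poor cavity. The generator emulates that statistical
structure at desk scale: Gaussians are placed on the inner surface of a
curved tube (the "cavity wall"), colored by a band-limited procedural
field whose frequency controls how hard the scene is to render without
aliasing, and observed by a camera travelling along the tube's
centerline looking forward, with small pose jitter. Ground-truth images
are rendered from the known cloud with a 4x supersampled, unfiltered
renderer so that training targets are independent of the low-pass filter
under test. Every generator is a pure function of (spec, seed).

Defaults: 2000 Gaussians, 256x144 frames (16:9, mirroring the 1280x720
clinical aspect at desk scale), 100-frame trajectories split 90/10 into
train/test with test frames held out evenly along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import convolve

from .scene import (Camera, GaussianCloud, InvalidParameterError,
                    inverse_sigmoid, look_at_camera, rotation_to_quaternion)
from .rasterizer import render_supersampled_reference


@dataclass
class SceneSpec:
    """Parameters of a synthetic tube scene."""

    seed: int = 0
    n_gaussians: int = 2000
    centerline: np.ndarray = field(default_factory=lambda: np.array(
        [[0.0, 0.0, 0.0], [0.25, 0.1, 1.0], [-0.15, -0.1, 2.0], [0.0, 0.05, 3.0]]))
    radius: float = 0.5
    radial_jitter: float = 0.03       # radial spread, fraction of radius (< 0.05)
    texture_frequency: float = 3.0    # cycles per scene unit of the color field
    scale_multiplier: float = 1.0     # shrink factor on splat footprints;
                                      # << 1 gives sub-pixel splats at low
                                      # resolution (the aliasing-stress fixture)
    opacity_range: tuple = (0.6, 0.95)
    scale_range: tuple = (0.8, 1.25)  # multiplicative jitter on base scales
    width: int = 256
    height: int = 144
    fov_scale: float = 0.9            # fx = fov_scale * width
    sh_degree: int = 1

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.radius <= 0:
            raise InvalidParameterError("tube radius must be positive")
        if self.n_gaussians < 1:
            raise InvalidParameterError("need at least one Gaussian")


def _spline(spec: SceneSpec) -> CubicSpline:
    u = np.linspace(0.0, 1.0, len(spec.centerline))
    return CubicSpline(u, spec.centerline, axis=0)


def centerline_points(spec: SceneSpec, n: int = 512) -> np.ndarray:
    """Densely sampled centerline (for distance checks)."""
    return _spline(spec)(np.linspace(0, 1, n))


def _frames_along(spline: CubicSpline, u: np.ndarray):
    """Tangent / normal / binormal frames (parallel-transport-free but
    stable for the gentle curvatures used here)."""
    tang = spline(u, 1)
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.array([0.0, 1.0, 0.0])
    nrm = ref - tang * (tang @ ref)[:, None]
    nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
    binrm = np.cross(tang, nrm)
    return tang, nrm, binrm


def _color_field(pts: np.ndarray, freq: float, rng: np.random.Generator):
    """Band-limited procedural RGB field: a small sum of 3D sinusoids
    mapped to a reddish, tissue-like palette in [0.1, 0.9]."""
    n_waves = 6
    k = rng.normal(0.0, 1.0, (n_waves, 3))
    k = k / np.linalg.norm(k, axis=1, keepdims=True) * (2 * np.pi * freq)
    phase = rng.uniform(0, 2 * np.pi, n_waves)
    amp = rng.uniform(0.5, 1.0, n_waves)
    s = np.sum(amp * np.sin(pts @ k.T + phase), axis=1) / np.sum(amp)
    s = 0.5 + 0.5 * s  # roughly [0, 1]
    base = np.empty((len(pts), 3))
    base[:, 0] = 0.45 + 0.45 * s
    base[:, 1] = 0.15 + 0.35 * s
    base[:, 2] = 0.12 + 0.25 * s
    return np.clip(base, 0.1, 0.9)


def generate_scene(spec: SceneSpec) -> GaussianCloud:
    """Gaussians on the inner surface of the curved tube."""
    rng = np.random.default_rng(spec.seed)
    spline = _spline(spec)
    n = spec.n_gaussians
    u = rng.uniform(0.0, 1.0, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    tang, nrm, binrm = _frames_along(spline, u)
    centers = spline(u)
    radial_dir = np.cos(theta)[:, None] * nrm + np.sin(theta)[:, None] * binrm
    r = spec.radius * (1.0 + spec.radial_jitter * rng.uniform(-1, 1, n))
    means = centers + r[:, None] * radial_dir

    # anisotropic: tangent-plane footprint sized to tile the surface,
    # thin along the inward surface normal
    arc_len = np.linalg.norm(np.diff(centerline_points(spec, 256), axis=0),
                             axis=1).sum()
    area = 2 * np.pi * spec.radius * arc_len
    s_tan = 0.7 * np.sqrt(area / n) * spec.scale_multiplier
    s_norm = 0.15 * s_tan
    jit = rng.uniform(spec.scale_range[0], spec.scale_range[1], (n, 3))
    log_scales = np.log(np.stack([
        s_tan * jit[:, 0], s_tan * jit[:, 1], s_norm * jit[:, 2]], axis=1))

    # rotation: columns = (tangent, circumferential, radial)
    circ = np.cross(radial_dir, tang)
    circ = circ / np.linalg.norm(circ, axis=1, keepdims=True)
    t2 = np.cross(circ, radial_dir)
    quats = np.empty((n, 4))
    for i in range(n):
        R = np.stack([t2[i], circ[i], radial_dir[i]], axis=1)
        if np.linalg.det(R) < 0:
            R[:, 1] = -R[:, 1]
        quats[i] = rotation_to_quaternion(R)

    opac = rng.uniform(spec.opacity_range[0], spec.opacity_range[1], n)
    colors = _color_field(means, spec.texture_frequency, rng)
    K = (spec.sh_degree + 1) ** 2
    sh_coeffs = np.zeros((n, K, 3))
    sh_coeffs[:, 0, :] = (colors - 0.5) / 0.28209479177387814
    if K > 1:
        sh_coeffs[:, 1:, :] = rng.normal(0.0, 0.02, (n, K - 1, 3))

    return GaussianCloud(means, quats, log_scales, inverse_sigmoid(opac),
                         sh_coeffs, sh_degree=spec.sh_degree)


def generate_trajectory(spec: SceneSpec, n_frames: int) -> list:
    """Cameras flying along the centerline looking forward, with small
    deterministic pose jitter; all centers stay inside the tube."""
    if n_frames < 2:
        raise InvalidParameterError("need at least 2 frames")
    from scipy.ndimage import gaussian_filter1d
    rng = np.random.default_rng(spec.seed + 1)
    spline = _spline(spec)
    u = np.linspace(0.1, 0.85, n_frames)
    fx = spec.fov_scale * spec.width
    cams = []
    # hand-held jitter is temporally smooth: low-pass iid noise along the
    # trajectory, then rescale to the intended amplitude
    def smooth_noise(std, n):
        x = gaussian_filter1d(rng.normal(0.0, 1.0, (n, 3)), sigma=2.0, axis=0,
                              mode="nearest")
        return x / max(x.std(), 1e-12) * std
    jitter_pos = smooth_noise(0.02 * spec.radius, n_frames)
    jitter_tgt = smooth_noise(0.03 * spec.radius, n_frames)
    for i in range(n_frames):
        pos = spline(u[i]) + jitter_pos[i]
        tgt = spline(min(1.0, u[i] + 0.08)) + jitter_tgt[i]
        cams.append(look_at_camera(pos, tgt, up=np.array([0.0, 1.0, 0.0]),
                                   fx=fx, fy=fx, width=spec.width,
                                   height=spec.height,
                                   znear=0.2))
    return cams


@dataclass
class PosedImageDataset:
    """Posed RGB images split into train / test views."""

    train_cameras: list
    train_images: list
    test_cameras: list
    test_images: list
    true_cloud: Optional[GaussianCloud] = None
    spec: Optional[SceneSpec] = None

    @property
    def n_frames(self):
        return len(self.train_images) + len(self.test_images)


def split_indices(n_frames: int, split: float = 0.9):
    """Deterministic train/test split with test frames spread evenly
    along the trajectory."""
    n_test = int(round(n_frames * (1.0 - split)))
    if n_test == 0:
        return np.arange(n_frames), np.array([], dtype=int)
    stride = n_frames / n_test
    test = np.unique((np.arange(n_test) * stride + stride / 2).astype(int))
    train = np.setdiff1d(np.arange(n_frames), test)
    return train, test


def generate_dataset(spec: SceneSpec, n_frames: int = 100, split: float = 0.9,
                     supersample: int = 4, motion_blur: Optional[dict] = None
                     ) -> PosedImageDataset:
    """Full synthetic dataset: scene + trajectory + supersampled
    ground-truth renders + 90/10 split.

    Ground truth is rendered with ``supersample``-times supersampling and
    no low-pass filter, so the targets are independent of the filter
    being evaluated. ``motion_blur={'length': px, 'angle': rad}``
    optionally blurs the training images.
    """
    cloud = generate_scene(spec)
    cams = generate_trajectory(spec, n_frames)
    images = []
    for cam in cams:
        img = render_supersampled_reference(cloud, cam, filter_scale=0.0,
                                            factor=supersample).pixels
        images.append(img)
    if motion_blur:
        images = [apply_motion_blur(im, motion_blur.get("length", 7),
                                    motion_blur.get("angle", 0.0))
                  for im in images]
    tr, te = split_indices(n_frames, split)
    return PosedImageDataset(
        train_cameras=[cams[i] for i in tr], train_images=[images[i] for i in tr],
        test_cameras=[cams[i] for i in te], test_images=[images[i] for i in te],
        true_cloud=cloud, spec=spec)


def motion_blur_kernel(length: int, angle: float, supersample: int = 8
                       ) -> np.ndarray:
    """Normalized line kernel of the given pixel length and angle."""
    if length < 1:
        raise InvalidParameterError("blur length must be >= 1")
    if length == 1:
        return np.ones((1, 1))
    size = int(np.ceil(length)) | 1
    hi = size * supersample
    k = np.zeros((hi, hi))
    c = (hi - 1) / 2.0
    t = np.linspace(-0.5, 0.5, length * supersample * 2) * (length - 1) * supersample
    xs = np.clip(np.round(c + t * np.cos(angle)).astype(int), 0, hi - 1)
    ys = np.clip(np.round(c + t * np.sin(angle)).astype(int), 0, hi - 1)
    k[ys, xs] = 1.0
    k = k.reshape(size, supersample, size, supersample).mean(axis=(1, 3))
    return k / k.sum()


def apply_motion_blur(image: np.ndarray, length: int, angle: float = 0.0
                      ) -> np.ndarray:
    """Convolve with a normalized line kernel (camera-shake stand-in)."""
    k = motion_blur_kernel(length, angle)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return convolve(image, k, mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[:, :, c] = convolve(image[:, :, c], k, mode="nearest")
    return out


def perturb_cloud(cloud: GaussianCloud, seed: int = 0,
                  mean_sigma: float = 0.05, log_scale_sigma: float = 0.3,
                  logit_sigma: float = 1.0, sh_sigma: float = 0.2,
                  quat_sigma: float = 0.1) -> GaussianCloud:
    """Perturbed copy of a cloud, the initialization of the parameter-
    recovery experiment. Magnitudes are in the natural units of each
    raw parameter; ``mean_sigma`` is in scene units (default about one
    surface Gaussian's tangential footprint, which visibly corrupts the
    render while leaving recovery well-posed)."""
    rng = np.random.default_rng(seed)
    out = cloud.copy()
    out.means += rng.normal(0, mean_sigma, out.means.shape)
    out.log_scales += rng.normal(0, log_scale_sigma, out.log_scales.shape)
    out.opacity_logits += rng.normal(0, logit_sigma, out.opacity_logits.shape)
    out.sh_coeffs[:, 0, :] += rng.normal(0, sh_sigma, (len(out), 3))
    out.rot_quats += rng.normal(0, quat_sigma, out.rot_quats.shape)
    return out
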