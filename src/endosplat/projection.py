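"""EWA projection of 3D Gaussians to screen space.

Each 3D Gaussian (mu, A) is mapped through the camera's rigid transform W
and the local affine (Jacobian) approximation J of the perspective map,
giving a 2D Gaussian footprint with covariance

    A'' = upper-left 2x2 of  J W A W^T J^T .

The adaptive low-pass filter then replaces A'' by A'' + s I, where s is a
smoothing scale in squared pixel units, and multiplies the splat by the
energy-compensating prefactor det(A'') / det(A'' + s I). Because s is
fixed in *screen* space, the effective world-space smoothing shrinks as
the sampling rate grows, which is what makes the filter adaptive to the
rendering resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import (ActivatedGaussians, Camera, GaussianCloud,
                    InvalidParameterError, quaternion_to_rotation)

# splats are evaluated only within this Mahalanobis radius of their 2D
# mean (chi^2 cutoff 3^2); it also defines the 3-sigma binning extent
TRUNCATION_RADIUS = 3.0


@dataclass
class Splat2D:
    """A projected Gaussian ready for rasterization."""

    uv: np.ndarray            # (2,) pixel coordinates of the projected mean
    cov2d: np.ndarray         # (2, 2) filtered covariance A'' + s I, px^2
    depth: float              # camera-space z, scene units
    color: np.ndarray         # (3,) RGB
    opacity: float            # activated sigma in (0, 1)
    filter_prefactor: float   # det(A'') / det(A'' + s I), in (0, 1]


def perspective_jacobian(t: np.ndarray, fx: float, fy: float) -> np.ndarray:
    """Jacobian of (x, y, z) -> (fx x/z + cx, fy y/z + cy) at camera-space t.

    Supports a single point (3,) or a batch (N, 3); returns (2, 3) or
    (N, 2, 3).
    """
    t = np.asarray(t, dtype=np.float64)
    single = t.ndim == 1
    t = np.atleast_2d(t)
    x, y, z = t[:, 0], t[:, 1], t[:, 2]
    J = np.zeros((t.shape[0], 2, 3), dtype=np.float64)
    J[:, 0, 0] = fx / z
    J[:, 0, 2] = -fx * x / z ** 2
    J[:, 1, 1] = fy / z
    J[:, 1, 2] = -fy * y / z ** 2
    return J[0] if single else J


def project_gaussian(mean: np.ndarray, cov3d: np.ndarray, camera: Camera):
    """Project one 3D Gaussian; returns (uv, cov2d A'', depth) or None.

    ``None`` signals culling (the mean is at or behind the near plane).
    """
    t = camera.world_to_cam(mean)
    z = float(t[2])
    if z <= camera.znear:
        return None
    uv = np.array([camera.fx * t[0] / z + camera.cx,
                   camera.fy * t[1] / z + camera.cy])
    J = perspective_jacobian(t, camera.fx, camera.fy)
    B = J @ camera.R
    cov2d = B @ np.asarray(cov3d, dtype=np.float64) @ B.T
    return uv, cov2d, z


def apply_low_pass_filter(cov2d: np.ndarray, s: float,
                          mode: str = "linear"):
    """Adaptive low-pass filter: (A'' + s I, det(A'')/det(A'' + s I)).

    ``mode='linear'`` is the determinant-ratio prefactor as such; with
    ``mode='sqrt'`` the square root of the ratio is used instead (the
    conventional anti-aliased-splatting normalization).
    """
    if s < 0:
        raise InvalidParameterError("filter scale s must be >= 0")
    if mode not in ("linear", "sqrt"):
        raise InvalidParameterError(f"unknown prefactor mode {mode!r}")
    cov2d = np.asarray(cov2d, dtype=np.float64)
    filtered = cov2d.copy()
    filtered[..., 0, 0] += s
    filtered[..., 1, 1] += s
    det0 = cov2d[..., 0, 0] * cov2d[..., 1, 1] - cov2d[..., 0, 1] * cov2d[..., 1, 0]
    det1 = (filtered[..., 0, 0] * filtered[..., 1, 1]
            - filtered[..., 0, 1] * filtered[..., 1, 0])
    ratio = det0 / det1
    prefactor = np.sqrt(ratio) if mode == "sqrt" else ratio
    return filtered, prefactor


def splat_extent(cov2d: np.ndarray) -> np.ndarray:
    """Screen-space binning radius: 3 sqrt(largest eigenvalue), in pixels."""
    cov2d = np.asarray(cov2d, dtype=np.float64)
    a = cov2d[..., 0, 0]
    b = cov2d[..., 0, 1]
    c = cov2d[..., 1, 1]
    half_tr = 0.5 * (a + c)
    disc = np.sqrt(np.maximum(0.0, half_tr ** 2 - (a * c - b * b)))
    lam_max = half_tr + disc
    return TRUNCATION_RADIUS * np.sqrt(np.maximum(lam_max, 0.0))


def project_cloud(act: ActivatedGaussians, camera: Camera):
    """Vectorized projection of every Gaussian in front of the near plane.

    Returns (indices, t_cam, uv, cov2d) for Gaussians with z > znear;
    cov2d is the unfiltered A''.
    """
    t = act.means @ camera.R.T + camera.t
    front = t[:, 2] > camera.znear
    idx = np.nonzero(front)[0]
    t = t[idx]
    z = t[:, 2]
    uv = np.stack([camera.fx * t[:, 0] / z + camera.cx,
                   camera.fy * t[:, 1] / z + camera.cy], axis=1)
    J = perspective_jacobian(t, camera.fx, camera.fy)
    B = J @ camera.R  # (M, 2, 3)
    R = quaternion_to_rotation(act.quats[idx])
    M = R * act.scales[idx][:, None, :]          # R diag(s)
    P = B @ M                                    # (M, 2, 3)
    cov2d = P @ P.transpose(0, 2, 1)
    return idx, t, uv, cov2d


def frustum_cull(cloud: GaussianCloud, camera: Camera,
                 margin: float = 1.0) -> np.ndarray:
    """Indices of Gaussians visible to ``camera``.

    Keeps Gaussians with camera-space z > znear whose projected mean lies
    inside the image rectangle expanded on each side by
    margin * (projected 3-sigma extent).
    """
    act = cloud.activated()
    idx, _, uv, cov2d = project_cloud(act, camera)
    r = margin * splat_extent(cov2d)
    keep = ((uv[:, 0] >= -r) & (uv[:, 0] <= camera.width + r)
            & (uv[:, 1] >= -r) & (uv[:, 1] <= camera.height + r))
    return idx[keep]
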