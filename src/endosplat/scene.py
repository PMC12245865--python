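"""Scene representation: anisotropic 3D Gaussians and pinhole cameras.

A scene is a cloud of N Gaussians, each carrying a position mean mu, a
rotation (quaternion r), per-axis scales s, an opacity sigma and
spherical-harmonic color coefficients. Parameters are stored in *raw*
(pre-activation) form, as the optimizer updates them without constraints:

* opacity is stored as a logit and passed through a sigmoid, so the
  activated value lies strictly in (0, 1);
* scales are stored as logs and exponentiated, guaranteeing positivity;
* quaternions are stored unnormalized and normalized on use.

The covariance of a Gaussian is A = R S S^T R^T where R is the rotation
matrix of the (normalized) quaternion and S = diag(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import sh


class InvalidParameterError(ValueError):
    """Raised when an operation receives parameters outside its domain."""


# ---------------------------------------------------------------------------
# quaternions / covariance


def quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a quaternion in (w, x, y, z) order.

    The quaternion is normalized internally; q and -q give the same
    matrix. Supports a single quaternion (4,) or a batch (N, 4).
    """
    q = np.asarray(q, dtype=np.float64)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(norm == 0.0) or not np.all(np.isfinite(norm)):
        raise InvalidParameterError("zero-norm or non-finite quaternion")
    w, x, y, z = (q / norm[:, None]).T
    R = np.empty((q.shape[0], 3, 3), dtype=np.float64)
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R[0] if single else R


def rotation_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quaternion_to_rotation` (w >= 0 branch)."""
    R = np.asarray(R, dtype=np.float64)
    w = 0.5 * np.sqrt(max(0.0, 1.0 + R[0, 0] + R[1, 1] + R[2, 2]))
    if w > 1e-8:
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
    else:  # 180-degree rotation: pick the largest diagonal axis
        d = np.diag(R)
        i = int(np.argmax(d))
        x = np.sqrt(max(0.0, 1 + 2 * d[i] - d.sum())) / 2
        axis = np.zeros(3)
        axis[i] = x
        j, k = (i + 1) % 3, (i + 2) % 3
        axis[j] = (R[j, i] + R[i, j]) / (4 * x)
        axis[k] = (R[k, i] + R[i, k]) / (4 * x)
        x, y, z = axis
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)


def build_covariance(rot_quat: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Covariance A = R S S^T R^T from a quaternion and per-axis stds.

    ``scales`` are standard deviations (scene units); the eigenvalues of
    the returned matrix are their squares.
    """
    scales = np.asarray(scales, dtype=np.float64)
    if np.any(scales <= 0) or not np.all(np.isfinite(scales)):
        raise InvalidParameterError("scales must be positive finite stds")
    R = quaternion_to_rotation(rot_quat)
    single = R.ndim == 2
    R = R.reshape(-1, 3, 3)
    s = np.atleast_2d(scales)
    M = R * s[:, None, :]  # R @ diag(s)
    A = M @ M.transpose(0, 2, 1)
    return A[0] if single else A


# ---------------------------------------------------------------------------
# cloud / camera


@dataclass
class GaussianCloud:
    """Raw-parameter storage for N Gaussians (see module docstring)."""

    means: np.ndarray          # (N, 3)
    rot_quats: np.ndarray      # (N, 4), (w, x, y, z)
    log_scales: np.ndarray     # (N, 3)
    opacity_logits: np.ndarray  # (N,)
    sh_coeffs: np.ndarray      # (N, K, 3)
    sh_degree: int = 0
    sh_offset: bool = True     # add 0.5 to the degree-0 color term

    def __post_init__(self):
        self.means = np.ascontiguousarray(self.means, dtype=np.float64).reshape(-1, 3)
        n = self.means.shape[0]
        self.rot_quats = np.ascontiguousarray(self.rot_quats, dtype=np.float64).reshape(n, 4)
        self.log_scales = np.ascontiguousarray(self.log_scales, dtype=np.float64).reshape(n, 3)
        self.opacity_logits = np.ascontiguousarray(
            self.opacity_logits, dtype=np.float64).reshape(n)
        K = sh.n_coeffs(self.sh_degree)
        self.sh_coeffs = np.ascontiguousarray(self.sh_coeffs, dtype=np.float64)
        if self.sh_coeffs.shape != (n, K, 3):
            raise InvalidParameterError(
                f"sh_coeffs shape {self.sh_coeffs.shape} does not match "
                f"(N={n}, K={(self.sh_degree + 1) ** 2}, 3) for degree {self.sh_degree}")

    def __len__(self) -> int:
        return self.means.shape[0]

    @property
    def n_sh_coeffs(self) -> int:
        return sh.n_coeffs(self.sh_degree)

    def copy(self) -> "GaussianCloud":
        return GaussianCloud(
            self.means.copy(), self.rot_quats.copy(), self.log_scales.copy(),
            self.opacity_logits.copy(), self.sh_coeffs.copy(),
            sh_degree=self.sh_degree, sh_offset=self.sh_offset)

    def select(self, idx) -> "GaussianCloud":
        return GaussianCloud(
            self.means[idx], self.rot_quats[idx], self.log_scales[idx],
            self.opacity_logits[idx], self.sh_coeffs[idx],
            sh_degree=self.sh_degree, sh_offset=self.sh_offset)

    def extent(self) -> float:
        """Radius of the bounding sphere of the means around their centroid."""
        if len(self) == 0:
            return 0.0
        c = self.means.mean(axis=0)
        return float(np.linalg.norm(self.means - c, axis=1).max())

    def activated(self) -> "ActivatedGaussians":
        return activate_parameters(self)


@dataclass
class ActivatedGaussians:
    """Activated view of a cloud: constrained-domain parameters."""

    means: np.ndarray       # (N, 3)
    quats: np.ndarray       # (N, 4), unit norm
    scales: np.ndarray      # (N, 3), > 0
    opacities: np.ndarray   # (N,), in (0, 1)
    sh_coeffs: np.ndarray   # (N, K, 3)
    sh_degree: int
    sh_offset: bool

    def rotations(self) -> np.ndarray:
        return quaternion_to_rotation(self.quats)

    def covariances(self) -> np.ndarray:
        return build_covariance(self.quats, self.scales)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(np.asarray(x, dtype=np.float64))
    x = np.asarray(x, dtype=np.float64)
    pos = x >= 0
    out = np.where(pos, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return out


def inverse_sigmoid(p):
    p = np.asarray(p, dtype=np.float64)
    return np.log(p / (1.0 - p))


def activate_parameters(cloud: GaussianCloud) -> ActivatedGaussians:
    """Map raw storage to the constrained domain (sigmoid / exp / normalize)."""
    norms = np.linalg.norm(cloud.rot_quats, axis=1, keepdims=True)
    return ActivatedGaussians(
        means=cloud.means,
        quats=cloud.rot_quats / norms,
        scales=np.exp(cloud.log_scales),
        opacities=sigmoid(cloud.opacity_logits),
        sh_coeffs=cloud.sh_coeffs,
        sh_degree=cloud.sh_degree,
        sh_offset=cloud.sh_offset,
    )


def eval_sh_color(sh_coeffs: np.ndarray, view_dir: np.ndarray, degree: int,
                  offset: bool = True) -> np.ndarray:
    """View-dependent RGB from SH coefficients.

    color = sum_k c_k Y_k(d), plus a 0.5 shift on the degree-0 term when
    ``offset`` (the ecosystem convention that centers DC colors around
    mid-gray), clamped to >= 0. ``sh_coeffs`` is (K, 3) or (N, K, 3);
    ``view_dir`` is a unit 3-vector or (N, 3).
    """
    sh_coeffs = np.asarray(sh_coeffs, dtype=np.float64)
    K = sh.n_coeffs(degree)
    if sh_coeffs.shape[-2] != K:
        raise InvalidParameterError(
            f"got {sh_coeffs.shape[-2]} SH coefficients, degree {degree} needs {K}")
    basis = sh.eval_basis(view_dir, degree)  # (..., K)
    color = np.einsum("...k,...kc->...c", basis, sh_coeffs)
    if offset:
        color = color + 0.5
    return np.maximum(color, 0.0)


@dataclass
class Camera:
    """Pinhole camera: intrinsics plus a world-to-camera rigid transform.

    Convention: camera looks down +z, x right, y down (COLMAP/OpenCV);
    pixel (i, j) has center (j + 0.5, i + 0.5); the stored rotation and
    translation map world points to camera space, p_cam = R p_world + t.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    znear: float = 0.2

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if self.width < 1 or self.height < 1:
            raise InvalidParameterError("image size must be at least 1x1")
        if self.znear <= 0:
            raise InvalidParameterError("znear must be positive")
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-7):
            raise InvalidParameterError("world_to_cam rotation is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise InvalidParameterError("world_to_cam rotation must have det +1")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates, -R^T t."""
        return -self.R.T @ self.t

    def world_to_cam(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=np.float64) @ self.R.T + self.t

    def scaled(self, factor: float) -> "Camera":
        """Camera for a resolution scaled by ``factor`` (e.g. 0.5, 4.0)."""
        w, h = int(round(self.width * factor)), int(round(self.height * factor))
        if w < 1 or h < 1:
            raise InvalidParameterError(
                f"resolution factor {factor} yields a zero-size image")
        return replace(self, fx=self.fx * factor, fy=self.fy * factor,
                       cx=self.cx * factor, cy=self.cy * factor,
                       width=w, height=h)


def look_at_camera(position: np.ndarray, target: np.ndarray, up: np.ndarray,
                   fx: float, fy: float, width: int, height: int,
                   znear: float = 0.2) -> Camera:
    """Camera at ``position`` looking toward ``target`` (y-down convention)."""
    position = np.asarray(position, dtype=np.float64)
    fwd = np.asarray(target, dtype=np.float64) - position
    fwd = fwd / np.linalg.norm(fwd)
    up = np.asarray(up, dtype=np.float64)
    right = np.cross(fwd, up)  # y-down: right = forward x up
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise InvalidParameterError("up vector parallel to view direction")
    right /= nr
    down = np.cross(fwd, right)
    down /= np.linalg.norm(down)
    R_c2w = np.stack([right, down, fwd], axis=1)  # columns = camera axes in world
    R = R_c2w.T
    t = -R @ position
    return Camera(fx=fx, fy=fy, cx=width / 2.0, cy=height / 2.0,
                  width=width, height=height, R=R, t=t, znear=znear)
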