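"""Real spherical harmonics used for view-dependent splat color.

Hard-coded orthonormal real SH basis up to degree 3 in the (x, y, z)
component convention used across the splatting ecosystem, plus analytic
derivatives with respect to the direction vector (required by the
renderer's backward pass: perturbing a Gaussian mean changes the viewing
direction and hence the color).
"""

from __future__ import annotations

import numpy as np

MAX_DEGREE = 3

C0 = 0.28209479177387814
C1 = 0.4886025119029199
C2 = (
    1.0925484305920792,
    -1.0925484305920792,
    0.31539156525252005,
    -1.0925484305920792,
    0.5462742152960396,
)
C3 = (
    -0.5900435899266435,
    2.890611442640554,
    -0.4570457994644658,
    0.3731763325901154,
    -0.4570457994644658,
    1.445305721320277,
    -0.5900435899266435,
)


def n_coeffs(degree: int) -> int:
    """Number of basis functions K = (L+1)^2 for degree L."""
    if degree < 0 or degree > MAX_DEGREE:
        raise ValueError(f"SH degree must be in [0, {MAX_DEGREE}], got {degree}")
    return (degree + 1) ** 2


def eval_basis(dirs: np.ndarray, degree: int) -> np.ndarray:
    """Evaluate the real SH basis at unit directions.

    Parameters
    ----------
    dirs : (..., 3) array of unit vectors.
    degree : maximum SH degree L (0..3).

    Returns
    -------
    (..., (L+1)^2) array of basis values.
    """
    K = n_coeffs(degree)
    dirs = np.asarray(dirs, dtype=np.float64)
    out = np.empty(dirs.shape[:-1] + (K,), dtype=np.float64)
    x, y, z = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    out[..., 0] = C0
    if degree >= 1:
        out[..., 1] = -C1 * y
        out[..., 2] = C1 * z
        out[..., 3] = -C1 * x
    if degree >= 2:
        xx, yy, zz = x * x, y * y, z * z
        out[..., 4] = C2[0] * x * y
        out[..., 5] = C2[1] * y * z
        out[..., 6] = C2[2] * (2.0 * zz - xx - yy)
        out[..., 7] = C2[3] * x * z
        out[..., 8] = C2[4] * (xx - yy)
    if degree >= 3:
        xx, yy, zz = x * x, y * y, z * z
        out[..., 9] = C3[0] * y * (3.0 * xx - yy)
        out[..., 10] = C3[1] * x * y * z
        out[..., 11] = C3[2] * y * (4.0 * zz - xx - yy)
        out[..., 12] = C3[3] * z * (2.0 * zz - 3.0 * xx - 3.0 * yy)
        out[..., 13] = C3[4] * x * (4.0 * zz - xx - yy)
        out[..., 14] = C3[5] * z * (xx - yy)
        out[..., 15] = C3[6] * x * (xx - 3.0 * yy)
    return out


def eval_basis_grad(dirs: np.ndarray, degree: int) -> np.ndarray:
    """Analytic d(basis)/d(direction), shape (..., K, 3)."""
    K = n_coeffs(degree)
    dirs = np.asarray(dirs, dtype=np.float64)
    g = np.zeros(dirs.shape[:-1] + (K, 3), dtype=np.float64)
    x, y, z = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    if degree >= 1:
        g[..., 1, 1] = -C1
        g[..., 2, 2] = C1
        g[..., 3, 0] = -C1
    if degree >= 2:
        g[..., 4, 0] = C2[0] * y
        g[..., 4, 1] = C2[0] * x
        g[..., 5, 1] = C2[1] * z
        g[..., 5, 2] = C2[1] * y
        g[..., 6, 0] = C2[2] * (-2.0 * x)
        g[..., 6, 1] = C2[2] * (-2.0 * y)
        g[..., 6, 2] = C2[2] * (4.0 * z)
        g[..., 7, 0] = C2[3] * z
        g[..., 7, 2] = C2[3] * x
        g[..., 8, 0] = C2[4] * (2.0 * x)
        g[..., 8, 1] = C2[4] * (-2.0 * y)
    if degree >= 3:
        g[..., 9, 0] = C3[0] * 6.0 * x * y
        g[..., 9, 1] = C3[0] * (3.0 * x * x - 3.0 * y * y)
        g[..., 10, 0] = C3[1] * y * z
        g[..., 10, 1] = C3[1] * x * z
        g[..., 10, 2] = C3[1] * x * y
        g[..., 11, 0] = C3[2] * (-2.0 * x * y)
        g[..., 11, 1] = C3[2] * (4.0 * z * z - x * x - 3.0 * y * y)
        g[..., 11, 2] = C3[2] * (8.0 * y * z)
        g[..., 12, 0] = C3[3] * (-6.0 * x * z)
        g[..., 12, 1] = C3[3] * (-6.0 * y * z)
        g[..., 12, 2] = C3[3] * (6.0 * z * z - 3.0 * x * x - 3.0 * y * y)
        g[..., 13, 0] = C3[4] * (4.0 * z * z - 3.0 * x * x - y * y)
        g[..., 13, 1] = C3[4] * (-2.0 * x * y)
        g[..., 13, 2] = C3[4] * (8.0 * x * z)
        g[..., 14, 0] = C3[5] * (2.0 * x * z)
        g[..., 14, 1] = C3[5] * (-2.0 * y * z)
        g[..., 14, 2] = C3[5] * (x * x - y * y)
        g[..., 15, 0] = C3[6] * (3.0 * x * x - 3.0 * y * y)
        g[..., 15, 1] = C3[6] * (-6.0 * x * y)
    return g
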