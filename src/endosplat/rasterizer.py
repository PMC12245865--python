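"""Depth-sorted, tile-binned alpha blending of filtered splats.

The rendering pipeline is: activate parameters -> transform to camera
space and cull -> EWA-project to 2D covariances -> adaptive low-pass
filter -> global depth sort (ties broken by Gaussian index) -> 16x16
tile binning -> front-to-back alpha blending with transmittance

    C(p) = sum_i T_i alpha_i c_i + T_final * background,
    T_i = prod_{j<i} (1 - alpha_j),
    alpha_i = min(0.99, sigma_i * prefactor_i *
                  exp(-0.5 (p - mu_i)^T (A'' + sI)^{-1} (p - mu_i))).

The module also provides two slow oracles used by the test-suite:
``render_bruteforce`` (identical contract, per-pixel global loop, no
tiling or early termination) and ``render_supersampled_reference``
(K-times supersampled, unfiltered, box-downsampled — the alias-free
reference for anti-aliasing experiments).

``render_training`` / ``render_backward`` expose the differentiable
path: the backward pass is fully analytic (hand-derived chain rule
through blending, the filter, the EWA projection, activations and the
spherical-harmonic color), which is what the optimizer trains with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels, sh
from .scene import (Camera, GaussianCloud, InvalidParameterError,
                    activate_parameters, quaternion_to_rotation)
from .projection import (Splat2D, apply_low_pass_filter,
                         perspective_jacobian, splat_extent, project_cloud)

DEFAULT_FILTER_SCALE = 0.3
DEFAULT_TILE = 16


@dataclass
class RenderedImage:
    """H x W x 3 pixels in [0, 1] plus optional per-pixel transmittance."""

    pixels: np.ndarray
    final_transmittance: Optional[np.ndarray] = None
    background: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ParamGradients:
    """Gradients of a scalar loss w.r.t. raw cloud parameters."""

    means: np.ndarray
    rot_quats: np.ndarray
    log_scales: np.ndarray
    opacity_logits: np.ndarray
    sh_coeffs: np.ndarray
    # per-Gaussian screen-space (NDC) positional gradient norm, for
    # adaptive density control; zero for Gaussians culled in this view
    screen_grad_norm: np.ndarray
    visible: np.ndarray  # bool mask of Gaussians that reached the rasterizer


def _prepare(cloud: GaussianCloud, camera: Camera, filter_scale: float,
             prefactor_mode: str, margin: float = 1.0):
    """Project, filter, cull and depth-sort; returns the forward context."""
    act = activate_parameters(cloud)
    idx, t, uv, cov_raw = project_cloud(act, camera)

    filtered, pf = apply_low_pass_filter(cov_raw, filter_scale, prefactor_mode)
    det_f = (filtered[:, 0, 0] * filtered[:, 1, 1]
             - filtered[:, 0, 1] * filtered[:, 1, 0])
    ok = np.isfinite(det_f) & (det_f > 0) & np.isfinite(pf)
    if not np.all(ok):
        warnings.warn(f"skipping {int((~ok).sum())} splats with non-positive-"
                      "definite filtered covariance")
    radii = splat_extent(filtered)
    keep = (ok
            & (uv[:, 0] >= -margin * radii) & (uv[:, 0] <= camera.width + margin * radii)
            & (uv[:, 1] >= -margin * radii) & (uv[:, 1] <= camera.height + margin * radii))

    idx, t, uv = idx[keep], t[keep], uv[keep]
    cov_raw, filtered, pf, radii = cov_raw[keep], filtered[keep], pf[keep], radii[keep]
    det_f = det_f[keep]

    # global front-to-back order; ties broken by original Gaussian index
    order = np.lexsort((idx, t[:, 2]))
    idx, t, uv = idx[order], t[order], uv[order]
    cov_raw, filtered, pf, radii, det_f = (cov_raw[order], filtered[order],
                                           pf[order], radii[order], det_f[order])

    conic = np.empty((len(idx), 3), dtype=np.float64)
    conic[:, 0] = filtered[:, 1, 1] / det_f
    conic[:, 1] = -filtered[:, 0, 1] / det_f
    conic[:, 2] = filtered[:, 0, 0] / det_f

    # view-dependent color
    cam_center = camera.center
    v = act.means[idx] - cam_center
    r_norm = np.linalg.norm(v, axis=1)
    dirs = v / r_norm[:, None]
    basis = sh.eval_basis(dirs, act.sh_degree)              # (M, K)
    color_pre = np.einsum("mk,mkc->mc", basis, act.sh_coeffs[idx])
    if act.sh_offset:
        color_pre = color_pre + 0.5
    color = np.maximum(color_pre, 0.0)

    opac_eff = act.opacities[idx] * pf

    return dict(act=act, idx=idx, t=t, uv=uv, cov_raw=cov_raw,
                filtered=filtered, pf=pf, radii=radii, det_f=det_f,
                conic=conic, dirs=dirs, r_norm=r_norm, basis=basis,
                color_pre=color_pre, color=color, opac_eff=opac_eff,
                camera=camera, filter_scale=filter_scale,
                prefactor_mode=prefactor_mode, n_total=len(cloud))


def _blend(ctx, background, tile, bruteforce=False):
    camera = ctx["camera"]
    bg = np.asarray(background, dtype=np.float64).reshape(3)
    uv = np.ascontiguousarray(ctx["uv"])
    conic = np.ascontiguousarray(ctx["conic"])
    opac = np.ascontiguousarray(ctx["opac_eff"])
    color = np.ascontiguousarray(ctx["color"])
    if len(uv) == 0:
        img = np.ones((camera.height, camera.width, 3)) * bg
        return img, np.ones((camera.height, camera.width))
    if bruteforce:
        return _kernels.forward_bruteforce(uv, conic, opac, color,
                                           camera.height, camera.width, bg)
    filtered = ctx["filtered"]
    # exact axis-aligned 3-sigma bounding box of the truncation ellipse
    rx = 3.0 * np.sqrt(np.maximum(filtered[:, 0, 0], 0.0))
    ry = 3.0 * np.sqrt(np.maximum(filtered[:, 1, 1], 0.0))
    starts, lists, n_tx, n_ty = _kernels.bin_splats(
        uv, conic, np.ascontiguousarray(rx), np.ascontiguousarray(ry),
        camera.height, camera.width, tile)
    ctx["_tiles"] = (starts, lists, n_tx, n_ty, tile)
    img, trans, consumed = _kernels.forward_tiled(
        uv, conic, opac, color, starts, lists, n_tx, n_ty,
        camera.height, camera.width, tile, bg)
    ctx["_consumed"] = consumed
    return img, trans


def render(cloud: GaussianCloud, camera: Camera,
           filter_scale: float = DEFAULT_FILTER_SCALE,
           background=(0.0, 0.0, 0.0), prefactor_mode: str = "linear",
           tile: int = DEFAULT_TILE) -> RenderedImage:
    """Render a cloud through the full anti-aliased splatting pipeline."""
    ctx = _prepare(cloud, camera, filter_scale, prefactor_mode)
    raw, trans = _blend(ctx, background, tile)
    return RenderedImage(np.clip(raw, 0.0, 1.0), trans,
                         np.asarray(background, dtype=np.float64).reshape(3))


def render_bruteforce(cloud: GaussianCloud, camera: Camera,
                      filter_scale: float = DEFAULT_FILTER_SCALE,
                      background=(0.0, 0.0, 0.0),
                      prefactor_mode: str = "linear") -> RenderedImage:
    """Untiled per-pixel oracle with the same contract as :func:`render`."""
    ctx = _prepare(cloud, camera, filter_scale, prefactor_mode)
    raw, trans = _blend(ctx, background, tile=0, bruteforce=True)
    return RenderedImage(np.clip(raw, 0.0, 1.0), trans,
                         np.asarray(background, dtype=np.float64).reshape(3))


def render_supersampled_reference(cloud: GaussianCloud, camera: Camera,
                                  filter_scale: float = 0.0, factor: int = 4,
                                  background=(0.0, 0.0, 0.0)) -> RenderedImage:
    """Alias-free reference: render at ``factor`` x resolution without the
    low-pass filter, then box-downsample."""
    if factor < 1:
        raise InvalidParameterError("supersampling factor must be >= 1")
    if factor == 1:
        return render(cloud, camera, filter_scale=filter_scale,
                      background=background)
    hi = render(cloud, camera.scaled(float(factor)),
                filter_scale=filter_scale, background=background)
    H, W = camera.height, camera.width
    px = hi.pixels.reshape(H, factor, W, factor, 3).mean(axis=(1, 3))
    tr = hi.final_transmittance.reshape(H, factor, W, factor).mean(axis=(1, 3))
    return RenderedImage(px, tr, hi.background)


# ---------------------------------------------------------------------------
# reference (pure python) ops, used as slow oracles and by the test-suite


def sort_and_bin(splats, image_size, tile: int = DEFAULT_TILE):
    """Per-tile depth-ordered splat index lists.

    ``splats`` is a sequence of :class:`Splat2D`; ``image_size`` is
    (height, width). A splat is listed in every tile its axis-aligned
    3-sigma square overlaps; within each tile, indices are sorted
    ascending by depth with ties broken by splat index. Returns a
    (n_tiles_y, n_tiles_x) nested list.
    """
    height, width = image_size
    n_tx = (width + tile - 1) // tile
    n_ty = (height + tile - 1) // tile
    order = sorted(range(len(splats)), key=lambda i: (splats[i].depth, i))
    grid = [[[] for _ in range(n_tx)] for _ in range(n_ty)]
    for i in order:
        s = splats[i]
        r = float(splat_extent(s.cov2d))
        tx0 = max(0, int(np.floor((s.uv[0] - r) / tile)))
        tx1 = min(n_tx - 1, int(np.floor((s.uv[0] + r) / tile)))
        ty0 = max(0, int(np.floor((s.uv[1] - r) / tile)))
        ty1 = min(n_ty - 1, int(np.floor((s.uv[1] + r) / tile)))
        for ty in range(ty0, ty1 + 1):
            for tx in range(tx0, tx1 + 1):
                grid[ty][tx].append(i)
    return grid


def alpha_blend_pixel(p, ordered_splats, background=(0.0, 0.0, 0.0),
                      return_details: bool = False):
    """Front-to-back compositing at one pixel center ``p``.

    ``ordered_splats`` must be depth-ascending :class:`Splat2D` with the
    *filtered* covariance in ``cov2d``. Returns the RGB value, or
    ``(rgb, weights, final_T)`` with ``return_details``.
    """
    p = np.asarray(p, dtype=np.float64)
    bg = np.asarray(background, dtype=np.float64)
    T = 1.0
    rgb = np.zeros(3)
    weights = []
    for s in ordered_splats:
        if T < _kernels.STOP_T:
            break
        d = p - s.uv
        cov = np.asarray(s.cov2d, dtype=np.float64)
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        if not np.isfinite(det) or det <= 0:
            warnings.warn("skipping splat with non-positive-definite covariance")
            continue
        inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
        power = 0.5 * d @ inv @ d
        if power > _kernels.POWER_CUTOFF or power < 0:
            continue
        alpha = min(_kernels.ALPHA_CAP,
                    s.opacity * s.filter_prefactor * np.exp(-power))
        w = T * alpha
        rgb = rgb + w * np.asarray(s.color, dtype=np.float64)
        weights.append(w)
        T *= 1.0 - alpha
    rgb = rgb + T * bg
    if return_details:
        return rgb, np.array(weights), T
    return rgb


def make_splats(cloud: GaussianCloud, camera: Camera,
                filter_scale: float = DEFAULT_FILTER_SCALE,
                prefactor_mode: str = "linear"):
    """Project a cloud into a depth-sorted list of :class:`Splat2D`."""
    ctx = _prepare(cloud, camera, filter_scale, prefactor_mode)
    act = ctx["act"]
    return [Splat2D(uv=ctx["uv"][m], cov2d=ctx["filtered"][m],
                    depth=float(ctx["t"][m, 2]), color=ctx["color"][m],
                    opacity=float(act.opacities[ctx["idx"][m]]),
                    filter_prefactor=float(ctx["pf"][m]))
            for m in range(len(ctx["idx"]))]


# ---------------------------------------------------------------------------
# differentiable path


def render_training(cloud: GaussianCloud, camera: Camera,
                    filter_scale: float = DEFAULT_FILTER_SCALE,
                    background=(0.0, 0.0, 0.0), prefactor_mode: str = "linear",
                    tile: int = DEFAULT_TILE):
    """Forward pass retaining the context needed by :func:`render_backward`.

    Returns ``(raw_image, ctx)``; the raw image is *unclipped* (training
    losses act on it directly so the gradient is exact).
    """
    if camera.width < 1 or camera.height < 1:
        raise InvalidParameterError("camera with zero-size image")
    ctx = _prepare(cloud, camera, filter_scale, prefactor_mode)
    raw, trans = _blend(ctx, background, tile)
    ctx["background"] = np.asarray(background, dtype=np.float64).reshape(3)
    ctx["cloud"] = cloud
    ctx["raw"] = raw
    ctx["trans"] = trans
    return raw, ctx


def render_backward(ctx, grad_pix: np.ndarray) -> ParamGradients:
    """Analytic gradients of a scalar loss w.r.t. raw cloud parameters.

    ``grad_pix`` is dL/d(raw image), shape (H, W, 3).
    """
    cloud: GaussianCloud = ctx["cloud"]
    camera: Camera = ctx["camera"]
    act = ctx["act"]
    idx = ctx["idx"]
    N = ctx["n_total"]
    K = cloud.n_sh_coeffs
    grads = ParamGradients(
        means=np.zeros((N, 3)), rot_quats=np.zeros((N, 4)),
        log_scales=np.zeros((N, 3)), opacity_logits=np.zeros(N),
        sh_coeffs=np.zeros((N, K, 3)), screen_grad_norm=np.zeros(N),
        visible=np.zeros(N, dtype=bool))
    M = len(idx)
    if M == 0:
        return grads
    grads.visible[idx] = True

    starts, lists, n_tx, n_ty, tile = ctx["_tiles"]
    g_uv, g_conic, g_opac, g_color = _kernels.backward_tiled(
        np.ascontiguousarray(ctx["uv"]), np.ascontiguousarray(ctx["conic"]),
        np.ascontiguousarray(ctx["opac_eff"]), np.ascontiguousarray(ctx["color"]),
        starts, lists, n_tx, n_ty, camera.height, camera.width, tile,
        ctx["background"], ctx["trans"], ctx["_consumed"],
        np.ascontiguousarray(grad_pix, dtype=np.float64))

    pf = ctx["pf"]
    sigma = act.opacities[idx]
    # opacity: alpha_eff = sigma * pf
    g_sigma = g_opac * pf
    g_pf = g_opac * sigma
    grads.opacity_logits[idx] = g_sigma * sigma * (1.0 - sigma)

    # color -> SH coefficients and view direction
    mask = (ctx["color_pre"] > 0).astype(np.float64)
    g_pre = g_color * mask                              # (M, 3)
    basis = ctx["basis"]                                # (M, K)
    sh_vis = act.sh_coeffs[idx]                         # (M, K, 3)
    grads.sh_coeffs[idx] = basis[:, :, None] * g_pre[:, None, :]
    if act.sh_degree >= 1:
        dbasis = sh.eval_basis_grad(ctx["dirs"], act.sh_degree)  # (M, K, 3)
        g_d = np.einsum("mc,mkc,mkd->md", g_pre, sh_vis, dbasis)
        d = ctx["dirs"]
        g_v = (g_d - d * np.sum(d * g_d, axis=1, keepdims=True)) / ctx["r_norm"][:, None]
        g_means_color = g_v
    else:
        g_means_color = np.zeros((M, 3))

    # conic -> filtered covariance: dL/dF = -F^-1 Gc F^-1
    conic_mat = np.empty((M, 2, 2))
    conic_mat[:, 0, 0] = ctx["conic"][:, 0]
    conic_mat[:, 0, 1] = conic_mat[:, 1, 0] = ctx["conic"][:, 1]
    conic_mat[:, 1, 1] = ctx["conic"][:, 2]
    Gc = np.empty((M, 2, 2))
    Gc[:, 0, 0] = g_conic[:, 0]
    Gc[:, 0, 1] = Gc[:, 1, 0] = 0.5 * g_conic[:, 1]
    Gc[:, 1, 1] = g_conic[:, 2]
    g_filtered = -np.einsum("mij,mjk,mkl->mil", conic_mat, Gc, conic_mat)

    # prefactor: pf = (det_raw / det_f)^gamma
    cov_raw = ctx["cov_raw"]
    filtered = ctx["filtered"]
    det_f = ctx["det_f"]
    det_r = (cov_raw[:, 0, 0] * cov_raw[:, 1, 1]
             - cov_raw[:, 0, 1] * cov_raw[:, 1, 0])
    ratio = det_r / det_f
    if ctx["prefactor_mode"] == "sqrt":
        g_ratio = g_pf * 0.5 / np.sqrt(np.maximum(ratio, 1e-300))
    else:
        g_ratio = g_pf
    g_det_r = g_ratio / det_f
    g_det_f = -g_ratio * det_r / det_f ** 2

    def adjT(S):
        out = np.empty_like(S)
        out[:, 0, 0] = S[:, 1, 1]
        out[:, 1, 1] = S[:, 0, 0]
        out[:, 0, 1] = -S[:, 0, 1]
        out[:, 1, 0] = -S[:, 1, 0]
        return out

    g_filtered = g_filtered + g_det_f[:, None, None] * adjT(filtered)
    # filtered = cov_raw + s I  =>  identity chain, plus the det_raw term
    g_cov_raw = g_filtered + g_det_r[:, None, None] * adjT(cov_raw)

    # cov_raw = P P^T with P = B M, B = J W, M = R diag(s)
    t = ctx["t"]
    z = t[:, 2]
    J = perspective_jacobian(t, camera.fx, camera.fy)   # (M, 2, 3)
    B = J @ camera.R
    Rm = quaternion_to_rotation(act.quats[idx])         # (M, 3, 3)
    s_act = act.scales[idx]
    Mm = Rm * s_act[:, None, :]
    P = B @ Mm

    g_P = 2.0 * np.einsum("mij,mjk->mik", g_cov_raw, P)
    g_B = np.einsum("mik,mjk->mij", g_P, Mm)            # g_P @ M^T
    g_M = np.einsum("mji,mjk->mik", B, g_P)             # B^T @ g_P
    g_J = np.einsum("mik,jk->mij", g_B, camera.R)       # g_B @ W^T

    # uv and J dependence on the camera-space mean t
    fx, fy = camera.fx, camera.fy
    x, y = t[:, 0], t[:, 1]
    g_t = np.einsum("mij,mi->mj", J, g_uv)              # J^T dL/duv
    g_t[:, 0] += g_J[:, 0, 2] * (-fx / z ** 2)
    g_t[:, 1] += g_J[:, 1, 2] * (-fy / z ** 2)
    g_t[:, 2] += (g_J[:, 0, 0] * (-fx / z ** 2)
                  + g_J[:, 0, 2] * (2 * fx * x / z ** 3)
                  + g_J[:, 1, 1] * (-fy / z ** 2)
                  + g_J[:, 1, 2] * (2 * fy * y / z ** 3))
    grads.means[idx] = g_t @ camera.R + g_means_color

    # M = R diag(s)
    g_R = g_M * s_act[:, None, :]
    g_s = np.einsum("mik,mik->mk", Rm, g_M)
    grads.log_scales[idx] = g_s * s_act

    # rotation -> quaternion (unit), then undo normalization
    q = act.quats[idx]
    w, qx, qy, qz = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    G = g_R
    g_qhat = np.empty((M, 4))
    g_qhat[:, 0] = 2 * (-qz * G[:, 0, 1] + qy * G[:, 0, 2] + qz * G[:, 1, 0]
                        - qx * G[:, 1, 2] - qy * G[:, 2, 0] + qx * G[:, 2, 1])
    g_qhat[:, 1] = 2 * (qy * G[:, 0, 1] + qz * G[:, 0, 2] + qy * G[:, 1, 0]
                        - 2 * qx * G[:, 1, 1] - w * G[:, 1, 2] + qz * G[:, 2, 0]
                        + w * G[:, 2, 1] - 2 * qx * G[:, 2, 2])
    g_qhat[:, 2] = 2 * (-2 * qy * G[:, 0, 0] + qx * G[:, 0, 1] + w * G[:, 0, 2]
                        + qx * G[:, 1, 0] + qz * G[:, 1, 2] - w * G[:, 2, 0]
                        + qz * G[:, 2, 1] - 2 * qy * G[:, 2, 2])
    g_qhat[:, 3] = 2 * (-2 * qz * G[:, 0, 0] - w * G[:, 0, 1] + qx * G[:, 0, 2]
                        + w * G[:, 1, 0] - 2 * qz * G[:, 1, 1] + qy * G[:, 1, 2]
                        + qx * G[:, 2, 0] + qy * G[:, 2, 1])
    qraw = cloud.rot_quats[idx]
    norms = np.linalg.norm(qraw, axis=1)
    g_q = (g_qhat - q * np.sum(q * g_qhat, axis=1, keepdims=True)) / norms[:, None]
    grads.rot_quats[idx] = g_q

    # screen-space positional gradient norm in NDC units, for densification
    ndc = g_uv * np.array([camera.width / 2.0, camera.height / 2.0])
    grads.screen_grad_norm[idx] = np.linalg.norm(ndc, axis=1)
    return grads
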