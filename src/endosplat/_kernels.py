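"""Numba kernels for tile-based alpha blending and its backward pass.

All kernels operate on pre-projected, depth-sorted splat arrays:

* ``uv``    (M, 2)  projected means, pixel coordinates
* ``conic`` (M, 3)  (a, b, c) of the inverse filtered covariance, so the
                    splat exponent is 0.5*(a dx^2 + c dy^2) + b dx dy
* ``opac``  (M,)    effective opacity sigma * prefactor
* ``color`` (M, 3)  RGB

A splat contributes only within Mahalanobis radius 3 of its mean
(power <= 4.5); the same truncation applies in the tiled and the
brute-force paths so the two agree to rounding error. Alpha is capped at
ALPHA_CAP and blending stops once transmittance falls below STOP_T
(tiled path only; the brute-force oracle never terminates early).

Binning uses each splat's exact axis-aligned 3-sigma bounding box
(half-widths 3*sqrt(cov_xx), 3*sqrt(cov_yy)), a tight superset of the
truncation ellipse. The forward pass records how many list entries each
pixel consumed so the backward pass can walk the same list back-to-front
without replaying the forward loop.
"""

import numpy as np
from numba import njit

ALPHA_CAP = 0.99
STOP_T = 1e-4
POWER_CUTOFF = 4.5  # (Mahalanobis radius 3)^2 / 2


@njit(cache=True, inline="always")
def _edge_min(q0, g, h, lo, hi):
    """Min over s in [lo, hi] of q0 + g*s + 0.5*h*s^2 (h >= 0)."""
    s = lo if h <= 0.0 else min(hi, max(lo, -g / h))
    return q0 + g * s + 0.5 * h * s * s


@njit(cache=True)
def _min_power_over_rect(cx, cy, a, b, c, x0, x1, y0, y1):
    """Exact minimum of 0.5*(a dx^2 + c dy^2) + b dx dy over the
    rectangle [x0,x1]x[y0,y1] (dx = x - cx, dy = y - cy); the quadratic
    is convex (conic of a positive-definite covariance)."""
    if x0 <= cx <= x1 and y0 <= cy <= y1:
        return 0.0
    best = np.inf
    # vertical edges: fixed dx, minimize over dy in [y0-cy, y1-cy]
    for xe in (x0, x1):
        dx = xe - cx
        v = _edge_min(0.5 * a * dx * dx, b * dx, c, y0 - cy, y1 - cy)
        if v < best:
            best = v
    # horizontal edges: fixed dy, minimize over dx
    for ye in (y0, y1):
        dy = ye - cy
        v = _edge_min(0.5 * c * dy * dy, b * dy, a, x0 - cx, x1 - cx)
        if v < best:
            best = v
    return best


@njit(cache=True)
def bin_splats(uv, conic, rx, ry, height, width, tile):
    """CSR tile lists: splat m is listed in every tile that its
    truncation ellipse (Mahalanobis radius 3 under ``conic``) actually
    reaches, found by scanning the axis-aligned 3-sigma rectangle
    [uv - (rx, ry), uv + (rx, ry)] and testing the exact minimum of the
    splat exponent over each tile. Input order (depth order) is
    preserved within each tile."""
    n_tx = (width + tile - 1) // tile
    n_ty = (height + tile - 1) // tile
    n_tiles = n_tx * n_ty
    M = uv.shape[0]
    counts = np.zeros(n_tiles + 1, dtype=np.int64)
    hits = np.zeros((M, 4), dtype=np.int64)  # rect in tile coords
    for m in range(M):
        tx0 = max(0, int(np.floor((uv[m, 0] - rx[m]) / tile)))
        tx1 = min(n_tx - 1, int(np.floor((uv[m, 0] + rx[m]) / tile)))
        ty0 = max(0, int(np.floor((uv[m, 1] - ry[m]) / tile)))
        ty1 = min(n_ty - 1, int(np.floor((uv[m, 1] + ry[m]) / tile)))
        hits[m, 0], hits[m, 1], hits[m, 2], hits[m, 3] = tx0, tx1, ty0, ty1
        if tx0 > tx1 or ty0 > ty1:
            continue
        for ty in range(ty0, ty1 + 1):
            for tx in range(tx0, tx1 + 1):
                if _min_power_over_rect(
                        uv[m, 0], uv[m, 1], conic[m, 0], conic[m, 1],
                        conic[m, 2], tx * tile, (tx + 1) * tile,
                        ty * tile, (ty + 1) * tile) <= POWER_CUTOFF:
                    counts[ty * n_tx + tx + 1] += 1
    starts = np.cumsum(counts)
    fill = starts[:-1].copy()
    lists = np.empty(starts[-1], dtype=np.int64)
    for m in range(M):
        tx0, tx1, ty0, ty1 = hits[m, 0], hits[m, 1], hits[m, 2], hits[m, 3]
        if tx0 > tx1 or ty0 > ty1:
            continue
        for ty in range(ty0, ty1 + 1):
            for tx in range(tx0, tx1 + 1):
                if _min_power_over_rect(
                        uv[m, 0], uv[m, 1], conic[m, 0], conic[m, 1],
                        conic[m, 2], tx * tile, (tx + 1) * tile,
                        ty * tile, (ty + 1) * tile) <= POWER_CUTOFF:
                    t = ty * n_tx + tx
                    lists[fill[t]] = m
                    fill[t] += 1
    return starts, lists, n_tx, n_ty


@njit(cache=True)
def forward_tiled(uv, conic, opac, color, starts, lists, n_tx, n_ty,
                  height, width, tile, background):
    """Front-to-back blending per tile.

    Returns (raw image, transmittance, n_consumed) where n_consumed[i,j]
    is the number of tile-list entries the pixel's loop consumed
    (including truncation-skipped ones) before stopping.
    """
    img = np.empty((height, width, 3), dtype=np.float64)
    trans = np.empty((height, width), dtype=np.float64)
    consumed = np.zeros((height, width), dtype=np.int64)
    for ty in range(n_ty):
        for tx in range(n_tx):
            t = ty * n_tx + tx
            lo, hi = starts[t], starts[t + 1]
            for i in range(ty * tile, min((ty + 1) * tile, height)):
                py = i + 0.5
                for j in range(tx * tile, min((tx + 1) * tile, width)):
                    px = j + 0.5
                    T = 1.0
                    r = 0.0
                    g = 0.0
                    b = 0.0
                    n = lo
                    while n < hi:
                        if T < STOP_T:
                            break
                        m = lists[n]
                        dx = px - uv[m, 0]
                        dy = py - uv[m, 1]
                        power = (0.5 * (conic[m, 0] * dx * dx
                                        + conic[m, 2] * dy * dy)
                                 + conic[m, 1] * dx * dy)
                        n += 1
                        if power > POWER_CUTOFF or power < 0.0:
                            continue
                        alpha = opac[m] * np.exp(-power)
                        if alpha > ALPHA_CAP:
                            alpha = ALPHA_CAP
                        w = T * alpha
                        r += w * color[m, 0]
                        g += w * color[m, 1]
                        b += w * color[m, 2]
                        T *= 1.0 - alpha
                    img[i, j, 0] = r + T * background[0]
                    img[i, j, 1] = g + T * background[1]
                    img[i, j, 2] = b + T * background[2]
                    trans[i, j] = T
                    consumed[i, j] = n - lo
    return img, trans, consumed


@njit(cache=True)
def forward_bruteforce(uv, conic, opac, color, height, width, background):
    """Per-pixel global loop over all splats; no tiling, no early stop."""
    img = np.empty((height, width, 3), dtype=np.float64)
    trans = np.empty((height, width), dtype=np.float64)
    M = uv.shape[0]
    for i in range(height):
        py = i + 0.5
        for j in range(width):
            px = j + 0.5
            T = 1.0
            r = 0.0
            g = 0.0
            b = 0.0
            for m in range(M):
                dx = px - uv[m, 0]
                dy = py - uv[m, 1]
                power = (0.5 * (conic[m, 0] * dx * dx + conic[m, 2] * dy * dy)
                         + conic[m, 1] * dx * dy)
                if power > POWER_CUTOFF or power < 0.0:
                    continue
                alpha = opac[m] * np.exp(-power)
                if alpha > ALPHA_CAP:
                    alpha = ALPHA_CAP
                w = T * alpha
                r += w * color[m, 0]
                g += w * color[m, 1]
                b += w * color[m, 2]
                T *= 1.0 - alpha
            img[i, j, 0] = r + T * background[0]
            img[i, j, 1] = g + T * background[1]
            img[i, j, 2] = b + T * background[2]
            trans[i, j] = T
    return img, trans


@njit(cache=True)
def backward_tiled(uv, conic, opac, color, starts, lists, n_tx, n_ty,
                   height, width, tile, background, trans, consumed,
                   grad_pix):
    """Backward pass of :func:`forward_tiled`.

    ``grad_pix`` is dL/d(raw image); ``trans`` and ``consumed`` are the
    forward outputs. Each pixel walks its consumed list range
    back-to-front, dividing out (1 - alpha) to recover the running
    transmittance. Returns per-splat gradients
    (d_uv, d_conic, d_opac, d_color).
    """
    M = uv.shape[0]
    d_uv = np.zeros((M, 2), dtype=np.float64)
    d_conic = np.zeros((M, 3), dtype=np.float64)
    d_opac = np.zeros(M, dtype=np.float64)
    d_color = np.zeros((M, 3), dtype=np.float64)
    suffix = np.empty(3, dtype=np.float64)
    for ty in range(n_ty):
        for tx in range(n_tx):
            t = ty * n_tx + tx
            lo = starts[t]
            if lo == starts[t + 1]:
                continue
            for i in range(ty * tile, min((ty + 1) * tile, height)):
                py = i + 0.5
                for j in range(tx * tile, min((tx + 1) * tile, width)):
                    gl0 = grad_pix[i, j, 0]
                    gl1 = grad_pix[i, j, 1]
                    gl2 = grad_pix[i, j, 2]
                    if gl0 == 0.0 and gl1 == 0.0 and gl2 == 0.0:
                        continue
                    px = j + 0.5
                    T_after = trans[i, j]
                    suffix[0] = T_after * background[0]
                    suffix[1] = T_after * background[1]
                    suffix[2] = T_after * background[2]
                    for n in range(lo + consumed[i, j] - 1, lo - 1, -1):
                        m = lists[n]
                        dx = px - uv[m, 0]
                        dy = py - uv[m, 1]
                        power = (0.5 * (conic[m, 0] * dx * dx
                                        + conic[m, 2] * dy * dy)
                                 + conic[m, 1] * dx * dy)
                        if power > POWER_CUTOFF or power < 0.0:
                            continue
                        G = np.exp(-power)
                        alpha = opac[m] * G
                        capped = alpha > ALPHA_CAP
                        if capped:
                            alpha = ALPHA_CAP
                        T_before = T_after / (1.0 - alpha)
                        w = T_before * alpha
                        d_color[m, 0] += gl0 * w
                        d_color[m, 1] += gl1 * w
                        d_color[m, 2] += gl2 * w
                        if not capped:
                            inv1a = 1.0 / (1.0 - alpha)
                            galpha = (gl0 * (T_before * color[m, 0] - suffix[0] * inv1a)
                                      + gl1 * (T_before * color[m, 1] - suffix[1] * inv1a)
                                      + gl2 * (T_before * color[m, 2] - suffix[2] * inv1a))
                            d_opac[m] += galpha * G
                            dpower = -galpha * alpha  # alpha = opac*G here
                            d_conic[m, 0] += dpower * 0.5 * dx * dx
                            d_conic[m, 1] += dpower * dx * dy
                            d_conic[m, 2] += dpower * 0.5 * dy * dy
                            d_uv[m, 0] += -dpower * (conic[m, 0] * dx + conic[m, 1] * dy)
                            d_uv[m, 1] += -dpower * (conic[m, 1] * dx + conic[m, 2] * dy)
                        suffix[0] += w * color[m, 0]
                        suffix[1] += w * color[m, 1]
                        suffix[2] += w * color[m, 2]
                        T_after = T_before
    return d_uv, d_conic, d_opac, d_color
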