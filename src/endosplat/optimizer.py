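"""Training: photometric loss, first-order updates and adaptive density
control for a Gaussian cloud.

The fitting problem is posed statsmodels-style: a
:class:`GaussianSplattingModel` is constructed from data (a posed-image
dataset plus an initial cloud) and ``fit()`` returns a
:class:`SplattingResults` object carrying the trained cloud, the
per-iteration loss log and evaluation helpers.

Each iteration renders one training view, computes

    L = (1 - lambda) * L1 + lambda * (1 - SSIM),

backpropagates analytically through the renderer, and applies
adaptive-moment (Adam-style) updates per parameter group (plain SGD is
available via ``optimizer='sgd'``). Periodically, adaptive density
control clones small / splits large Gaussians whose accumulated
screen-space positional gradient exceeds tau_pos, and prunes Gaussians
whose activated opacity falls below epsilon_alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import metrics
from .rasterizer import ParamGradients, render, render_backward, render_training
from .scene import Camera, GaussianCloud, InvalidParameterError

PARAM_GROUPS = ("means", "rot_quats", "log_scales", "opacity_logits", "sh_coeffs")


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``learning_rates`` maps parameter groups to positive step sizes; the
    defaults follow the reference splatting pipeline except the means
    rate, which is 1e-4. ``epsilon_alpha`` is the opacity prune
    threshold, ``tau_pos`` the positional-gradient densify threshold (on
    the mean accumulated screen-space/NDC gradient norm), and
    ``filter_scale`` the low-pass scale s in squared pixels.
    """

    lambda_dssim: float = 0.2
    learning_rates: dict = field(default_factory=lambda: {
        "means": 1e-4, "opacity_logits": 0.05, "log_scales": 0.005,
        "rot_quats": 0.001, "sh_coeffs": 0.0025})
    iterations: int = 2000
    densify_interval: int = 100
    densify_from: int = 500
    densify_until: Optional[int] = None  # default: iterations // 2
    epsilon_alpha: float = 0.005
    tau_pos: float = 2e-4
    percent_dense: float = 0.01
    split_factor: float = 1.6
    # prune Gaussians larger than this fraction of the scene extent
    # (suppresses whole-frame "floaters" that pop between viewpoints);
    # None disables
    prune_scale_fraction: Optional[float] = 0.1
    # densification never grows the cloud beyond this size (desk-scale
    # budget; the highest-gradient candidates are densified first when
    # headroom is short); pruning continues. None disables.
    max_gaussians: Optional[int] = 3000
    opacity_reset_interval: int = 3000
    opacity_reset: bool = True
    filter_scale: float = 0.3
    prefactor_mode: str = "linear"
    background: tuple = (0.0, 0.0, 0.0)
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lambda_dssim <= 1.0:
            raise InvalidParameterError("lambda must be in [0, 1]")
        if any(v <= 0 for v in self.learning_rates.values()):
            raise InvalidParameterError("learning rates must be positive")
        if not 0.0 < self.epsilon_alpha < 1.0:
            raise InvalidParameterError("epsilon_alpha must be in (0, 1)")
        if self.tau_pos <= 0:
            raise InvalidParameterError("tau_pos must be positive")
        if self.filter_scale < 0:
            raise InvalidParameterError("filter_scale must be >= 0")
        if self.densify_until is None:
            self.densify_until = self.iterations // 2


def compute_loss(rendered, target, lambda_dssim: float,
                 return_grad: bool = False, target_stats=None):
    """L = (1 - lambda) L1 + lambda (1 - SSIM); optionally d L/d rendered.

    ``rendered`` and ``target`` are (H, W, 3) arrays (a
    :class:`~endosplat.rasterizer.RenderedImage` is also accepted).
    ``target_stats`` (from :func:`endosplat.metrics.reference_stats`)
    skips recomputing the target's windowed SSIM statistics.
    """
    r = getattr(rendered, "pixels", rendered)
    t = getattr(target, "pixels", target)
    r = np.asarray(r, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if r.shape != t.shape:
        raise InvalidParameterError(f"shape mismatch {r.shape} vs {t.shape}")
    diff = r - t
    l1 = float(np.mean(np.abs(diff)))
    need_ssim = lambda_dssim > 0.0
    if need_ssim:
        if return_grad:
            s_val, s_grad = metrics.ssim(r, t, return_grad=True,
                                         y_stats=target_stats)
        else:
            s_val = metrics.ssim(r, t, y_stats=target_stats)
    else:
        s_val, s_grad = 1.0, None
    loss = (1.0 - lambda_dssim) * l1 + lambda_dssim * (1.0 - s_val)
    if not return_grad:
        return loss
    grad = (1.0 - lambda_dssim) * np.sign(diff) / diff.size
    if need_ssim:
        grad = grad - lambda_dssim * s_grad
    return loss, grad


class _AdamState:
    def __init__(self, cloud: GaussianCloud, beta1=0.9, beta2=0.999, eps=1e-15):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step = 0
        self.m = {g: np.zeros_like(getattr(cloud, g)) for g in PARAM_GROUPS}
        self.v = {g: np.zeros_like(getattr(cloud, g)) for g in PARAM_GROUPS}

    def update(self, cloud: GaussianCloud, grads: ParamGradients, lrs: dict):
        self.step += 1
        b1c = 1 - self.beta1 ** self.step
        b2c = 1 - self.beta2 ** self.step
        for g in PARAM_GROUPS:
            gr = getattr(grads, g)
            self.m[g] = self.beta1 * self.m[g] + (1 - self.beta1) * gr
            self.v[g] = self.beta2 * self.v[g] + (1 - self.beta2) * gr ** 2
            mhat = self.m[g] / b1c
            vhat = self.v[g] / b2c
            getattr(cloud, g)[...] -= lrs[g] * mhat / (np.sqrt(vhat) + self.eps)

    def select(self, idx):
        for g in PARAM_GROUPS:
            self.m[g] = self.m[g][idx]
            self.v[g] = self.v[g][idx]

    def append_zeros(self, n_new: int):
        for g in PARAM_GROUPS:
            pad = np.zeros((n_new,) + self.m[g].shape[1:])
            self.m[g] = np.concatenate([self.m[g], pad], axis=0)
            self.v[g] = np.concatenate([self.v[g], pad], axis=0)


class _SGDState:
    def __init__(self, cloud, **_):
        pass

    def update(self, cloud, grads, lrs):
        for g in PARAM_GROUPS:
            getattr(cloud, g)[...] -= lrs[g] * getattr(grads, g)

    def select(self, idx):
        pass

    def append_zeros(self, n_new):
        pass


@dataclass
class DensifyStats:
    pruned: int = 0
    cloned: int = 0
    split: int = 0


def densify_and_prune(cloud: GaussianCloud, grad_accum: np.ndarray,
                      grad_count: np.ndarray, config: TrainConfig,
                      scene_extent: float, rng: np.random.Generator,
                      world_grad: Optional[np.ndarray] = None,
                      opt_state=None):
    """Adaptive density control (returns a new cloud).

    Gaussians whose mean accumulated positional-gradient norm exceeds
    tau_pos are densified first: CLONED (duplicated with a small offset
    along the accumulated gradient direction) when their largest
    activated scale is below percent_dense * scene extent, otherwise
    SPLIT into two children sampled from the parent Gaussian with scales
    divided by split_factor (the parent is removed). The resulting cloud
    is then pruned: activated opacity < epsilon_alpha, or — when
    ``prune_scale_fraction`` is set — largest scale above that fraction
    of the scene extent (whole-frame "floaters" that pop between
    viewpoints). The cloud-size change is exactly
    clones + splits - pruned.

    Returns ``(new_cloud, DensifyStats)``. The caller resets the
    accumulators. ``opt_state`` (optional) is kept aligned.
    """
    if len(grad_accum) != len(cloud):
        raise InvalidParameterError("gradient accumulator misaligned with cloud")
    stats = DensifyStats()

    mean_grad = np.where(grad_count > 0, grad_accum / np.maximum(grad_count, 1), 0.0)
    hot = mean_grad > config.tau_pos
    if config.max_gaussians is not None:
        headroom = config.max_gaussians - len(cloud)
        if headroom <= 0:
            hot[:] = False  # size budget reached: prune only
        elif hot.sum() > headroom:
            # densify the most-demanding candidates first (each clone or
            # split adds exactly one Gaussian net)
            order = np.argsort(-mean_grad, kind="stable")
            allowed = order[:headroom]
            trimmed = np.zeros_like(hot)
            trimmed[allowed] = hot[allowed]
            hot = trimmed
    max_scale = np.exp(cloud.log_scales).max(axis=1)
    small = max_scale < config.percent_dense * scene_extent
    clone_idx = np.nonzero(hot & small)[0]
    split_idx = np.nonzero(hot & ~small)[0]
    stats.cloned = len(clone_idx)
    stats.split = len(split_idx)

    survivors = np.setdiff1d(np.arange(len(cloud)), split_idx,
                             assume_unique=True)
    if opt_state is not None:
        opt_state.select(survivors)

    pieces = [cloud.select(survivors)]
    n_new = 0
    if len(clone_idx):
        clones = cloud.select(clone_idx)
        if world_grad is not None:
            direction = world_grad[clone_idx]
            nrm = np.linalg.norm(direction, axis=1, keepdims=True)
            direction = np.where(nrm > 0, direction / np.maximum(nrm, 1e-30), 0.0)
            step = 0.1 * np.exp(clones.log_scales).mean(axis=1, keepdims=True)
            clones.means = clones.means - step * direction
        pieces.append(clones)
        n_new += len(clone_idx)
    if len(split_idx):
        parents = cloud.select(split_idx)
        pact = parents.activated()
        R = pact.rotations()
        for _ in range(2):
            eps = rng.standard_normal((len(split_idx), 3)) * pact.scales
            offs = np.einsum("nij,nj->ni", R, eps)
            ch = parents.copy()
            ch.means = parents.means + offs
            ch.log_scales = parents.log_scales - np.log(config.split_factor)
            pieces.append(ch)
        n_new += 2 * len(split_idx)

    if len(pieces) > 1:
        new_cloud = GaussianCloud(
            np.concatenate([p.means for p in pieces]),
            np.concatenate([p.rot_quats for p in pieces]),
            np.concatenate([p.log_scales for p in pieces]),
            np.concatenate([p.opacity_logits for p in pieces]),
            np.concatenate([p.sh_coeffs for p in pieces]),
            sh_degree=cloud.sh_degree, sh_offset=cloud.sh_offset)
        if opt_state is not None:
            opt_state.append_zeros(n_new)
    else:
        new_cloud = pieces[0]

    act = new_cloud.activated()
    keep = act.opacities >= config.epsilon_alpha
    if config.prune_scale_fraction is not None:
        keep &= (act.scales.max(axis=1)
                 <= config.prune_scale_fraction * scene_extent)
    stats.pruned = int((~keep).sum())
    if stats.pruned:
        keep_idx = np.nonzero(keep)[0]
        new_cloud = new_cloud.select(keep_idx)
        if opt_state is not None:
            opt_state.select(keep_idx)
    return new_cloud, stats


class GaussianSplattingModel:
    """Anti-aliased Gaussian-splatting reconstruction model.

    Parameters
    ----------
    dataset : object with ``train_cameras``, ``train_images`` (and
        optionally ``test_cameras`` / ``test_images``) attributes, such
        as :class:`endosplat.synthetic.PosedImageDataset`.
    init_cloud : initial :class:`GaussianCloud` (e.g. from an SfM point
        cloud via :func:`endosplat.io.cloud_from_points`).
    config : :class:`TrainConfig`.
    """

    def __init__(self, dataset, init_cloud: GaussianCloud,
                 config: Optional[TrainConfig] = None):
        if len(getattr(dataset, "train_images", [])) < 1:
            raise InvalidParameterError("dataset has no training images")
        if len(init_cloud) < 1:
            raise InvalidParameterError("initial cloud is empty")
        self.dataset = dataset
        self.init_cloud = init_cloud
        self.config = config or TrainConfig()

    @classmethod
    def from_colmap(cls, sparse_dir, images, cameras=None,
                    config: Optional[TrainConfig] = None, **cloud_kw):
        """Build a model from a COLMAP sparse text model plus images."""
        from . import io as eio
        from .synthetic import PosedImageDataset
        model = eio.read_colmap_sparse(sparse_dir)
        cams = cameras if cameras is not None else eio.colmap_cameras(model)
        ds = PosedImageDataset(train_cameras=list(cams), train_images=list(images),
                               test_cameras=[], test_images=[])
        cloud = eio.cloud_from_points(model.points_xyz(), model.points_rgb(),
                                      **cloud_kw)
        return cls(ds, cloud, config)

    def fit(self, progress: bool = False) -> "SplattingResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        cloud = self.init_cloud.copy()
        state_cls = {"adam": _AdamState, "sgd": _SGDState}[cfg.optimizer]
        opt = state_cls(cloud)
        scene_extent = max(cloud.extent(), 1e-6)

        cams = self.dataset.train_cameras
        imgs = self.dataset.train_images
        n_views = len(imgs)
        target_stats = [metrics.reference_stats(im) for im in imgs]
        loss_log = np.empty(cfg.iterations)
        size_log = []
        grad_accum = np.zeros(len(cloud))
        grad_count = np.zeros(len(cloud))
        world_accum = np.zeros((len(cloud), 3))
        view_order = rng.permutation(n_views)
        view_ptr = 0

        for it in range(cfg.iterations):
            if view_ptr >= n_views:
                view_order = rng.permutation(n_views)
                view_ptr = 0
            k = view_order[view_ptr]
            view_ptr += 1
            raw, ctx = render_training(
                cloud, cams[k], filter_scale=cfg.filter_scale,
                background=cfg.background, prefactor_mode=cfg.prefactor_mode)
            loss, gpix = compute_loss(raw, imgs[k], cfg.lambda_dssim,
                                      return_grad=True,
                                      target_stats=target_stats[k])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at iteration {it}: loss={loss}")
            loss_log[it] = loss
            grads = render_backward(ctx, gpix)
            opt.update(cloud, grads, cfg.learning_rates)

            grad_accum += grads.screen_grad_norm
            grad_count += grads.visible
            world_accum += grads.means

            step = it + 1
            if (cfg.densify_from <= step <= cfg.densify_until
                    and step % cfg.densify_interval == 0):
                cloud, stats = densify_and_prune(
                    cloud, grad_accum, grad_count, cfg, scene_extent, rng,
                    world_grad=world_accum, opt_state=opt)
                grad_accum = np.zeros(len(cloud))
                grad_count = np.zeros(len(cloud))
                world_accum = np.zeros((len(cloud), 3))
                size_log.append((step, len(cloud), stats))
            if (cfg.opacity_reset and cfg.opacity_reset_interval > 0
                    and step % cfg.opacity_reset_interval == 0
                    and step < cfg.iterations):
                from .scene import inverse_sigmoid, sigmoid
                cap = np.minimum(sigmoid(cloud.opacity_logits), 0.01)
                cloud.opacity_logits[...] = inverse_sigmoid(cap)
            if progress and (it % 200 == 0 or it == cfg.iterations - 1):
                print(f"iter {it:5d}  loss {loss:.5f}  n={len(cloud)}")

        return SplattingResults(self, cloud, loss_log, size_log)


@dataclass
class SplattingResults:
    """Fit results: the trained cloud plus diagnostics."""

    model: GaussianSplattingModel
    cloud: GaussianCloud
    loss_log: np.ndarray
    size_log: list

    def render(self, camera: Camera, **kw):
        cfg = self.model.config
        kw.setdefault("filter_scale", cfg.filter_scale)
        kw.setdefault("background", cfg.background)
        kw.setdefault("prefactor_mode", cfg.prefactor_mode)
        return render(self.cloud, camera, **kw)

    def evaluate(self, cameras=None, gt_images=None, factors=(1,)):
        """Metric reports on held-out views (default: the dataset's test
        split) at the requested resolution factors."""
        ds = self.model.dataset
        if cameras is None:
            cameras, gt_images = ds.test_cameras, ds.test_images
        cfg = self.model.config
        reports, avg = metrics.evaluate_multiresolution(
            self.cloud, cameras, gt_images, factors=factors,
            filter_scale=cfg.filter_scale, background=cfg.background)
        return reports, avg

    def save(self, ply_path, meta_path=None):
        from . import io as eio
        eio.write_ply(ply_path, self.cloud)
        if meta_path is not None:
            eio.write_run_metadata(meta_path, self.model.config, self.loss_log)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Gaussian splatting fit",
            "=" * 46,
            f"{'iterations':28s} {cfg.iterations}",
            f"{'training views':28s} {len(self.model.dataset.train_images)}",
            f"{'initial Gaussians':28s} {len(self.model.init_cloud)}",
            f"{'final Gaussians':28s} {len(self.cloud)}",
            f"{'filter scale s (px^2)':28s} {cfg.filter_scale}",
            f"{'lambda (D-SSIM weight)':28s} {cfg.lambda_dssim}",
            f"{'initial loss':28s} {self.loss_log[0]:.5f}",
            f"{'final loss':28s} {self.loss_log[-1]:.5f}",
        ]
        ds = self.model.dataset
        if getattr(ds, "test_images", None):
            reports, _ = self.evaluate(factors=(1,))
            lines.append(f"{'held-out PSNR (dB)':28s} {reports[0].mean_psnr:.2f}")
            lines.append(f"{'held-out SSIM':28s} {reports[0].mean_ssim:.4f}")
        return "\n".join(lines)


def fit(dataset, init_cloud: GaussianCloud,
        config: Optional[TrainConfig] = None, progress: bool = False):
    """Functional wrapper: returns (trained cloud, loss log)."""
    res = GaussianSplattingModel(dataset, init_cloud, config).fit(progress=progress)
    return res.cloud, res.loss_log
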