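"""Standard-format I/O: COLMAP sparse text models, splat PLY files,
PNG images, dataset export and run metadata.

The COLMAP sparse model (cameras.txt / images.txt / points3D.txt, text
dialect) is the interchange format for camera poses and the sparse
point cloud that seeds the Gaussian means; quaternions are (w, x, y, z)
and poses are stored world-to-camera, exactly as COLMAP writes them.

Checkpoints are binary little-endian PLY files using the de-facto
splatting layout (x, y, z, nx, ny, nz, f_dc_*, f_rest_*, opacity,
scale_*, rot_*) storing *raw* (pre-activation) parameters, so
third-party splat viewers can open them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scene import Camera, GaussianCloud, InvalidParameterError, inverse_sigmoid


class ColmapParseError(ValueError):
    pass


class PlyFormatError(ValueError):
    pass


@dataclass
class ColmapCamera:
    camera_id: int
    model: str
    width: int
    height: int
    params: np.ndarray  # PINHOLE: fx fy cx cy; SIMPLE_PINHOLE: f cx cy


@dataclass
class ColmapImage:
    image_id: int
    qvec: np.ndarray  # (w, x, y, z), world-to-camera
    tvec: np.ndarray
    camera_id: int
    name: str
    xys: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    point3d_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class ColmapPoint3D:
    point_id: int
    xyz: np.ndarray
    rgb: np.ndarray  # uint8
    error: float
    track: list = field(default_factory=list)  # (image_id, point2d_idx)


@dataclass
class ColmapSparseModel:
    cameras: dict  # id -> ColmapCamera
    images: dict   # id -> ColmapImage
    points3d: dict  # id -> ColmapPoint3D

    def __post_init__(self):
        for im in self.images.values():
            if im.camera_id not in self.cameras:
                raise ColmapParseError(
                    f"image {im.image_id} references missing camera {im.camera_id}")

    def points_xyz(self) -> np.ndarray:
        ids = sorted(self.points3d)
        return np.array([self.points3d[i].xyz for i in ids]).reshape(-1, 3)

    def points_rgb(self) -> np.ndarray:
        ids = sorted(self.points3d)
        return np.array([self.points3d[i].rgb for i in ids],
                        dtype=np.float64).reshape(-1, 3) / 255.0


def _data_lines(path: Path):
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_colmap_sparse(directory) -> ColmapSparseModel:
    """Parse a COLMAP sparse model directory (text dialect)."""
    directory = Path(directory)
    for name in ("cameras.txt", "images.txt", "points3D.txt"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing COLMAP file: {directory / name}")

    cameras = {}
    for lineno, line in _data_lines(directory / "cameras.txt"):
        try:
            parts = line.split()
            cid, model, w, h = int(parts[0]), parts[1], int(parts[2]), int(parts[3])
            params = np.array([float(p) for p in parts[4:]])
        except (ValueError, IndexError) as e:
            raise ColmapParseError(f"cameras.txt line {lineno}: {e}") from e
        cameras[cid] = ColmapCamera(cid, model, w, h, params)

    images = {}
    pending = None
    with open(directory / "images.txt") as f:
        for lineno, line in enumerate(f, 1):
            line = line.strip()
            if pending is None:
                if not line or line.startswith("#"):
                    continue
                try:
                    parts = line.split()
                    iid = int(parts[0])
                    q = np.array([float(x) for x in parts[1:5]])
                    t = np.array([float(x) for x in parts[5:8]])
                    cam_id = int(parts[8])
                    name = parts[9] if len(parts) > 9 else ""
                except (ValueError, IndexError) as e:
                    raise ColmapParseError(f"images.txt line {lineno}: {e}") from e
                nq = np.linalg.norm(q)
                if nq == 0:
                    raise ColmapParseError(
                        f"images.txt line {lineno}: zero quaternion")
                pending = ColmapImage(iid, q / nq, t, cam_id, name)
            else:
                # the observations line may legitimately be empty
                parts = line.split()
                if parts:
                    if len(parts) % 3:
                        raise ColmapParseError(
                            f"images.txt line {lineno}: observations not "
                            "triples of (x, y, point3d_id)")
                    try:
                        vals = np.array([float(x) for x in parts]).reshape(-1, 3)
                    except ValueError as e:
                        raise ColmapParseError(
                            f"images.txt line {lineno}: {e}") from e
                    pending.xys = vals[:, :2]
                    pending.point3d_ids = vals[:, 2].astype(int)
                images[pending.image_id] = pending
                pending = None
    if pending is not None:  # file ended without an observations line
        images[pending.image_id] = pending

    points3d = {}
    for lineno, line in _data_lines(directory / "points3D.txt"):
        try:
            parts = line.split()
            pid = int(parts[0])
            xyz = np.array([float(x) for x in parts[1:4]])
            rgb = np.array([int(x) for x in parts[4:7]], dtype=np.uint8)
            err = float(parts[7])
            track = [(int(parts[i]), int(parts[i + 1]))
                     for i in range(8, len(parts), 2)]
        except (ValueError, IndexError) as e:
            raise ColmapParseError(f"points3D.txt line {lineno}: {e}") from e
        points3d[pid] = ColmapPoint3D(pid, xyz, rgb, err, track)

    return ColmapSparseModel(cameras, images, points3d)


def export_colmap_model(directory, model: ColmapSparseModel) -> None:
    """Write a sparse model in the COLMAP text dialect (deterministic)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "cameras.txt", "w") as f:
        f.write("# Camera list with one line of data per camera:\n"
                "#   CAMERA_ID, MODEL, WIDTH, HEIGHT, PARAMS[]\n")
        for cid in sorted(model.cameras):
            c = model.cameras[cid]
            params = " ".join(repr(float(p)) for p in c.params)
            f.write(f"{c.camera_id} {c.model} {c.width} {c.height} {params}\n")
    with open(directory / "images.txt", "w") as f:
        f.write("# Image list with two lines of data per image:\n"
                "#   IMAGE_ID, QW, QX, QY, QZ, TX, TY, TZ, CAMERA_ID, NAME\n"
                "#   POINTS2D[] as (X, Y, POINT3D_ID)\n")
        for iid in sorted(model.images):
            im = model.images[iid]
            q = " ".join(repr(float(x)) for x in im.qvec)
            t = " ".join(repr(float(x)) for x in im.tvec)
            f.write(f"{im.image_id} {q} {t} {im.camera_id} {im.name}\n")
            obs = " ".join(f"{repr(float(x))} {repr(float(y))} {int(pid)}"
                           for (x, y), pid in zip(im.xys, im.point3d_ids))
            f.write(obs + "\n")
    with open(directory / "points3D.txt", "w") as f:
        f.write("# 3D point list with one line of data per point:\n"
                "#   POINT3D_ID, X, Y, Z, R, G, B, ERROR, TRACK[]\n")
        for pid in sorted(model.points3d):
            p = model.points3d[pid]
            xyz = " ".join(repr(float(x)) for x in p.xyz)
            rgb = " ".join(str(int(x)) for x in p.rgb)
            track = " ".join(f"{a} {b}" for a, b in p.track)
            f.write(f"{p.point_id} {xyz} {rgb} {repr(float(p.error))} {track}".rstrip()
                    + "\n")


def camera_from_colmap(cam: ColmapCamera, image: ColmapImage,
                       znear: float = 0.2) -> Camera:
    """Build a rendering camera from a COLMAP camera + image pose."""
    from .scene import quaternion_to_rotation
    if cam.model == "PINHOLE":
        fx, fy, cx, cy = cam.params
    elif cam.model == "SIMPLE_PINHOLE":
        fx, cx, cy = cam.params
        fy = fx
    else:
        raise ColmapParseError(f"unsupported camera model {cam.model!r}")
    R = quaternion_to_rotation(image.qvec)
    return Camera(fx=fx, fy=fy, cx=cx, cy=cy, width=cam.width, height=cam.height,
                  R=R, t=image.tvec, znear=znear)


def colmap_cameras(model: ColmapSparseModel, znear: float = 0.2):
    """Rendering cameras for every image, ordered by image id."""
    return [camera_from_colmap(model.cameras[model.images[i].camera_id],
                               model.images[i], znear=znear)
            for i in sorted(model.images)]


def cloud_from_points(xyz: np.ndarray, rgb: np.ndarray, sh_degree: int = 1,
                      initial_opacity: float = 0.1) -> GaussianCloud:
    """Seed a Gaussian cloud from a sparse point cloud.

    Scales are initialized isotropically from the mean distance to the
    three nearest neighbors; colors become the SH DC term.
    """
    from scipy.spatial import cKDTree
    xyz = np.asarray(xyz, dtype=np.float64).reshape(-1, 3)
    rgb = np.asarray(rgb, dtype=np.float64).reshape(-1, 3)
    n = len(xyz)
    if n == 0:
        raise InvalidParameterError("empty point cloud")
    if n > 1:
        d, _ = cKDTree(xyz).query(xyz, k=min(4, n))
        mean_d = d[:, 1:].mean(axis=1)
        mean_d = np.maximum(mean_d, 1e-7)
    else:
        mean_d = np.array([0.1])
    K = (sh_degree + 1) ** 2
    sh_coeffs = np.zeros((n, K, 3))
    sh_coeffs[:, 0, :] = (np.clip(rgb, 0, 1) - 0.5) / 0.28209479177387814
    quats = np.zeros((n, 4))
    quats[:, 0] = 1.0
    return GaussianCloud(
        means=xyz, rot_quats=quats,
        log_scales=np.log(mean_d)[:, None].repeat(3, axis=1),
        opacity_logits=np.full(n, inverse_sigmoid(initial_opacity)),
        sh_coeffs=sh_coeffs, sh_degree=sh_degree)


# ---------------------------------------------------------------------------
# PLY


def _ply_property_names(sh_degree: int):
    n_rest = 3 * ((sh_degree + 1) ** 2 - 1)
    names = ["x", "y", "z", "nx", "ny", "nz", "f_dc_0", "f_dc_1", "f_dc_2"]
    names += [f"f_rest_{i}" for i in range(n_rest)]
    names += ["opacity", "scale_0", "scale_1", "scale_2",
              "rot_0", "rot_1", "rot_2", "rot_3"]
    return names


def write_ply(path, cloud: GaussianCloud, dtype: str = "f4") -> None:
    """Binary little-endian PLY checkpoint with raw parameters.

    ``dtype='f4'`` (default) is the ecosystem convention; ``'f8'``
    preserves full double precision.
    """
    if dtype not in ("f4", "f8"):
        raise PlyFormatError("dtype must be 'f4' or 'f8'")
    ply_type = {"f4": "float", "f8": "double"}[dtype]
    names = _ply_property_names(cloud.sh_degree)
    n = len(cloud)
    # f_rest layout: channel-major (all band-k coeffs of channel 0, then 1, 2)
    rest = cloud.sh_coeffs[:, 1:, :].transpose(0, 2, 1).reshape(n, -1)
    cols = [cloud.means, np.zeros((n, 3)), cloud.sh_coeffs[:, 0, :], rest,
            cloud.opacity_logits[:, None], cloud.log_scales, cloud.rot_quats]
    data = np.concatenate(cols, axis=1)
    arr = np.rec.fromarrays(
        [data[:, i].astype("<" + dtype) for i in range(data.shape[1])],
        names=names)
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {n}"]
    header += [f"property {ply_type} {name}" for name in names]
    header += ["end_header"]
    with open(path, "wb") as f:
        f.write(("\n".join(header) + "\n").encode("ascii"))
        f.write(arr.tobytes())


def read_ply(path) -> GaussianCloud:
    """Read a splat PLY checkpoint written by :func:`write_ply` (or any
    conforming file using the same property layout)."""
    with open(path, "rb") as f:
        first = f.readline().strip()
        if first != b"ply":
            raise PlyFormatError("not a PLY file")
        fmt = None
        n = None
        props = []
        while True:
            line = f.readline()
            if not line:
                raise PlyFormatError("unexpected end of header")
            tok = line.decode("ascii").strip().split()
            if not tok:
                continue
            if tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                if tok[1] != "vertex":
                    raise PlyFormatError(f"unsupported element {tok[1]!r}")
                n = int(tok[2])
            elif tok[0] == "property":
                props.append((tok[2], tok[1]))
            elif tok[0] == "end_header":
                break
        if fmt != "binary_little_endian":
            raise PlyFormatError(f"unsupported PLY format {fmt!r}")
        typemap = {"float": "<f4", "float32": "<f4",
                   "double": "<f8", "float64": "<f8"}
        try:
            np_dtype = np.dtype([(name, typemap[t]) for name, t in props])
        except KeyError as e:
            raise PlyFormatError(f"unsupported property type {e}") from e
        arr = np.frombuffer(f.read(n * np_dtype.itemsize), dtype=np_dtype, count=n)

    names = {name for name, _ in props}
    n_rest = len([p for p in names if p.startswith("f_rest_")])
    if n_rest % 3:
        raise PlyFormatError(f"f_rest count {n_rest} not divisible by 3")
    K = n_rest // 3 + 1
    degree = int(np.sqrt(K)) - 1
    if (degree + 1) ** 2 != K:
        raise PlyFormatError(f"f_rest count {n_rest} is not a valid SH layout")
    required = set(_ply_property_names(degree)) - {"nx", "ny", "nz"}
    missing = sorted(required - names)
    if missing:
        raise PlyFormatError(f"missing PLY properties: {missing}")

    def col(name):
        return np.asarray(arr[name], dtype=np.float64)

    means = np.stack([col("x"), col("y"), col("z")], axis=1)
    sh_coeffs = np.zeros((n, K, 3))
    for c in range(3):
        sh_coeffs[:, 0, c] = col(f"f_dc_{c}")
    if K > 1:
        rest = np.stack([col(f"f_rest_{i}") for i in range(n_rest)], axis=1)
        sh_coeffs[:, 1:, :] = rest.reshape(n, 3, K - 1).transpose(0, 2, 1)
    log_scales = np.stack([col(f"scale_{i}") for i in range(3)], axis=1)
    quats = np.stack([col(f"rot_{i}") for i in range(4)], axis=1)
    return GaussianCloud(means, quats, log_scales, col("opacity"), sh_coeffs,
                         sh_degree=degree)


# ---------------------------------------------------------------------------
# images / metadata / dataset export


def write_png(path, image: np.ndarray) -> None:
    import imageio.v3 as iio
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(os.fspath(path), (arr * 255.0 + 0.5).astype(np.uint8))


def read_png(path) -> np.ndarray:
    import imageio.v3 as iio
    arr = iio.imread(os.fspath(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def write_run_metadata(path, config, loss_log) -> None:
    """Plain key-value sidecar: config echo plus the loss log."""
    from dataclasses import asdict
    with open(path, "w") as f:
        for k, v in asdict(config).items():
            f.write(f"{k}: {v}\n")
        f.write("loss_log: " + " ".join(f"{x:.6g}" for x in loss_log) + "\n")


def camera_to_colmap(camera: Camera, image_id: int, name: str) -> tuple:
    from .scene import rotation_to_quaternion
    cam = ColmapCamera(image_id, "PINHOLE", camera.width, camera.height,
                       np.array([camera.fx, camera.fy, camera.cx, camera.cy]))
    img = ColmapImage(image_id, rotation_to_quaternion(camera.R), camera.t,
                      image_id, name)
    return cam, img


def export_dataset(directory, dataset, points_per_axis: int = 0) -> None:
    """Write a posed-image dataset in the layout the pipeline ingests:
    images/*.png plus sparse/0/{cameras.txt, images.txt, points3D.txt}.

    The sparse points are the true cloud's means (with their DC colors)
    when available, standing in for an SfM reconstruction.
    """
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    cams = list(dataset.train_cameras) + list(dataset.test_cameras)
    imgs = list(dataset.train_images) + list(dataset.test_images)
    cameras, images = {}, {}
    for i, (cam, img) in enumerate(zip(cams, imgs)):
        name = f"frame_{i:05d}.png"
        write_png(directory / "images" / name, img)
        c, im = camera_to_colmap(cam, i + 1, name)
        cameras[i + 1], images[i + 1] = c, im
    points3d = {}
    if dataset.true_cloud is not None:
        cloud = dataset.true_cloud
        dc = np.clip(cloud.sh_coeffs[:, 0, :] * 0.28209479177387814 + 0.5, 0, 1)
        for j in range(len(cloud)):
            points3d[j + 1] = ColmapPoint3D(
                j + 1, cloud.means[j], (dc[j] * 255).astype(np.uint8), 0.5, [])
    export_colmap_model(directory / "sparse" / "0",
                        ColmapSparseModel(cameras, images, points3d))


def load_dataset(directory, split: float = 0.9):
    """Re-ingest a dataset written by :func:`export_dataset`."""
    from .synthetic import PosedImageDataset, split_indices
    directory = Path(directory)
    model = read_colmap_sparse(directory / "sparse" / "0")
    ids = sorted(model.images)
    cams = colmap_cameras(model)
    imgs = [read_png(directory / "images" / model.images[i].name) for i in ids]
    tr, te = split_indices(len(ids), split)
    ds = PosedImageDataset(
        train_cameras=[cams[i] for i in tr], train_images=[imgs[i] for i in tr],
        test_cameras=[cams[i] for i in te], test_images=[imgs[i] for i in te])
    return ds, model
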