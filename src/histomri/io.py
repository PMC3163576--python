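"""Readers and writers: volumes (MetaImage/NIfTI), section images (TIFF/PNG),
landmark files, configs and run manifests.

Volume geometry (spacing, origin, direction) round-trips losslessly through
MetaImage and NIfTI via SimpleITK.  Histology pixel sizes are given in µm at
the interface and converted to mm on load (world units are mm throughout).
Landmark files are plain text, one ``id x y z`` per line with ``#`` header
lines naming observer and image.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import tifffile

from .evaluation import LandmarkSet
from .image import SectionStack, VolumeImage

__all__ = [
    "HistoIOError",
    "read_volume",
    "write_volume",
    "read_sections",
    "write_sections",
    "read_landmarks",
    "write_landmarks",
    "load_config",
    "save_config",
    "RunManifest",
]

VOLUME_EXTENSIONS = (".mha", ".mhd", ".nii", ".nii.gz")


class HistoIOError(IOError):
    """Unsupported or malformed input file."""


def _volume_format(path: str) -> str:
    p = path.lower()
    for ext in VOLUME_EXTENSIONS:
        if p.endswith(ext):
            return ext
    raise HistoIOError(
        f"unsupported volume format for {path!r}; expected one of {VOLUME_EXTENSIONS}")


def read_volume(path) -> VolumeImage:
    """Read a MetaImage or NIfTI volume, preserving world geometry."""
    import SimpleITK as sitk

    path = os.fspath(path)
    _volume_format(path)
    if not os.path.exists(path):
        raise HistoIOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise HistoIOError(f"malformed volume file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise HistoIOError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    values = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    return VolumeImage(values, np.array(img.GetSpacing()), np.array(img.GetOrigin()),
                       np.array(img.GetDirection()).reshape(3, 3))


def write_volume(image: VolumeImage, path, dtype=np.float32) -> None:
    """Write a volume as MetaImage or NIfTI (by extension)."""
    import SimpleITK as sitk

    path = os.fspath(path)
    _volume_format(path)
    arr = np.ascontiguousarray(np.asarray(image.values, dtype=dtype).T)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in image.spacing))
    img.SetOrigin(tuple(float(o) for o in image.origin))
    img.SetDirection(tuple(float(d) for d in image.direction.ravel()))
    sitk.WriteImage(img, path, useCompression=False)


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", name)]


def _read_section_image(path: str) -> np.ndarray:
    p = path.lower()
    if p.endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    elif p.endswith(".png"):
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise HistoIOError(f"unsupported section format: {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)  # grayscale replicated to RGB
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise HistoIOError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr[:, :, :3]


def read_sections(paths_or_dir, pixel_size_um: float, interval_um: float,
                  thickness_um: float = 4.0, order_file=None) -> SectionStack:
    """Read digitized sections (TIFF/PNG) into a SectionStack.

    Sections are ordered by natural filename sort unless ``order_file`` (one
    filename per line) is given.  Differing shapes are padded symmetrically
    with the per-image border background.  Files are stored row-major
    (y, x, rgb) and transposed to the internal (x, y, rgb) convention; µm
    sizes become mm.
    """
    if isinstance(paths_or_dir, (str, os.PathLike)) and os.path.isdir(paths_or_dir):
        folder = os.fspath(paths_or_dir)
        names = [n for n in os.listdir(folder)
                 if n.lower().endswith((".tif", ".tiff", ".png"))]
        paths = [os.path.join(folder, n) for n in sorted(names, key=_natural_key)]
    else:
        paths = [os.fspath(p) for p in paths_or_dir]
    if order_file is not None:
        with open(order_file) as fh:
            order = [line.strip() for line in fh if line.strip()]
        by_name = {os.path.basename(p): p for p in paths}
        missing = [n for n in order if n not in by_name]
        if missing:
            raise HistoIOError(f"ordering file names missing sections: {missing}")
        paths = [by_name[n] for n in order]
    if not paths:
        raise HistoIOError("no readable section images found")
    images = [_read_section_image(p) for p in paths]
    dtypes = {im.dtype for im in images}
    if len(dtypes) > 1:
        raise HistoIOError(f"mixed section bit depths: {sorted(map(str, dtypes))}")
    h = max(im.shape[0] for im in images)
    w = max(im.shape[1] for im in images)
    padded = []
    for im in images:
        if im.shape[:2] != (h, w):
            bg = np.median(np.concatenate([im[0].reshape(-1, 3),
                                           im[-1].reshape(-1, 3)]), axis=0)
            out = np.empty((h, w, 3), dtype=im.dtype)
            out[:] = bg.astype(im.dtype)
            dy = (h - im.shape[0]) // 2
            dx = (w - im.shape[1]) // 2
            out[dy:dy + im.shape[0], dx:dx + im.shape[1]] = im
            im = out
        padded.append(np.asarray(im, dtype=float).transpose(1, 0, 2))  # -> (x,y,3)
    return SectionStack(padded, pixel_size_mm=pixel_size_um / 1000.0,
                        interval_mm=interval_um / 1000.0,
                        thickness_mm=thickness_um / 1000.0)


def write_sections(stack: SectionStack, folder, prefix: str = "section",
                   dtype=np.uint8) -> list:
    """Write sections as individual TIFF files; returns the paths."""
    os.makedirs(folder, exist_ok=True)
    paths = []
    for k, sec in enumerate(stack.sections):
        path = os.path.join(os.fspath(folder), f"{prefix}_{k:03d}.tif")
        arr = np.clip(sec, 0, 255).astype(dtype).transpose(1, 0, 2)  # -> (y,x,3)
        tifffile.imwrite(path, arr)
        paths.append(path)
    return paths


def read_landmarks(path) -> LandmarkSet:
    """Read a plain-text landmark file (``id x y z`` per line, mm)."""
    observer = image = ""
    points = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(observer|image)\s*:\s*(.*)", line)
                if m:
                    if m.group(1) == "observer":
                        observer = m.group(2).strip()
                    else:
                        image = m.group(2).strip()
                continue
            parts = line.split()
            if len(parts) != 4:
                raise HistoIOError(f"{path}: bad landmark line {line!r}")
            points[parts[0]] = [float(v) for v in parts[1:]]
    if not points:
        raise HistoIOError(f"{path}: no landmarks found")
    return LandmarkSet(points, observer=observer, image=image)


def write_landmarks(lm: LandmarkSet, path) -> None:
    lines = [f"# observer: {lm.observer}", f"# image: {lm.image}"]
    for name in lm.names():
        x, y, z = (float(v) for v in lm.points[name])
        lines.append(f"{name} {x!r} {y!r} {z!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path) -> dict:
    """Load a YAML/JSON config with per-stage sections."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise HistoIOError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: inputs, config, seeds, outputs.

    Re-running with the manifest's config and seeds reproduces transform
    parameters bit-identically (single-threaded, fully seeded execution).
    """

    tool: str = "histomri"
    version: str = ""
    command: str = ""
    seed: int = 0
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # role -> path
    metrics: dict = field(default_factory=dict)
    timestamp: str = ""

    def add_input(self, path) -> None:
        self.inputs[os.fspath(path)] = sha256_of(path)

    def write(self, path) -> None:
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = datetime.now(timezone.utc).isoformat()
        for role, out in self.outputs.items():
            if not os.path.exists(out):
                raise HistoIOError(f"manifest output {role!r} missing: {out}")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# phantom work directories (ground-truth bundles on disk)


def write_phantom(ph, workdir) -> str:
    """Write a generated phantom (images, masks, landmarks, ground truth)."""
    from dataclasses import asdict as _asdict

    from .phantom import LABELS
    from .transforms import write_transform

    root = os.path.join(os.fspath(workdir), "phantom")
    os.makedirs(root, exist_ok=True)
    write_volume(ph.invivo_native, os.path.join(root, "invivo_native.mha"))
    write_volume(ph.invivo_realigned, os.path.join(root, "invivo_realigned.mha"))
    write_volume(ph.exvivo, os.path.join(root, "exvivo.mha"))
    for frame in ("native", "plane", "exvivo"):
        vol = {"native": ph.invivo_native, "plane": ph.invivo_realigned,
               "exvivo": ph.exvivo}[frame]
        write_volume(vol.copy_with(ph.truth.labels[frame].astype(np.uint8)),
                     os.path.join(root, f"labels_{frame}.mha"), dtype=np.uint8)
    sec_dir = os.path.join(root, "sections")
    write_sections(ph.sections, sec_dir)
    os.makedirs(os.path.join(root, "section_labels"), exist_ok=True)
    for k, lab in enumerate(ph.truth.section_labels):
        tifffile.imwrite(os.path.join(root, "section_labels", f"labels_{k:03d}.tif"),
                         lab.astype(np.uint8).T)
    for frame in ("plane", "exvivo", "stack"):
        names, pts = ph.truth.landmarks[frame]
        write_landmarks(LandmarkSet.from_arrays(names, pts, observer="truth",
                                                image=frame),
                        os.path.join(root, f"landmarks_{frame}.txt"))
    names, ks, w2d = ph.truth.landmark_sections
    with open(os.path.join(root, "landmark_sections.csv"), "w") as fh:
        fh.write("name,section,x_mm,y_mm\n")
        for n, k, w in zip(names, ks, w2d):
            fh.write(f"{n},{int(k)},{float(w[0])!r},{float(w[1])!r}\n")
    tdir = os.path.join(root, "truth")
    os.makedirs(tdir, exist_ok=True)
    write_transform(ph.truth.exvivo_similarity, os.path.join(tdir, "exvivo_similarity.txt"))
    write_transform(ph.truth.exvivo_deform, os.path.join(tdir, "exvivo_deform.txt"))
    write_transform(ph.truth.stack2ex_affine, os.path.join(tdir, "stack2ex_affine.txt"))
    for k, (jit, rec) in enumerate(zip(ph.truth.slice_jitters,
                                       ph.truth.stacking_transforms)):
        write_transform(jit, os.path.join(tdir, f"jitter_{k:03d}.txt"))
        write_transform(rec, os.path.join(tdir, f"stacking_{k:03d}.txt"))
    info = {
        "config": _asdict(ph.cfg),
        "stack_scale": ph.truth.stack_scale,
        "stack_z0": ph.truth.stack_z0,
        "programmed": ph.truth.programmed,
        "labels": LABELS,
    }
    with open(os.path.join(root, "truth.json"), "w") as fh:
        json.dump(info, fh, indent=2, default=_jsonable)
    return root


def load_phantom(workdir):
    """Reload a phantom bundle written by :func:`write_phantom`.

    The continuous tissue model is not serialized; the returned object
    carries everything the pipeline and evaluation need (images, sections,
    masks, landmarks, recorded transforms).
    """
    from .phantom import Phantom, PhantomConfig, PhantomTruth
    from .transforms import read_transform
    from .image import ReferencePlane

    root = os.path.join(os.fspath(workdir), "phantom")
    if not os.path.isdir(root):
        raise HistoIOError(f"phantom directory not found: {root}")
    with open(os.path.join(root, "truth.json")) as fh:
        info = json.load(fh)
    cfg_d = dict(info["config"])
    for key in ("shape", "spacing_mm", "tumor_center_mm", "tumor_radii_mm",
                "realigned_shape", "exvivo_shape", "section_shape",
                "exvivo_translation_bound_mm", "landmark_depth_range_mm"):
        if isinstance(cfg_d.get(key), list):
            cfg_d[key] = tuple(cfg_d[key])
    if isinstance(cfg_d.get("exvivo_rotation_deg"), list):
        cfg_d["exvivo_rotation_deg"] = tuple(cfg_d["exvivo_rotation_deg"])
    cfg = PhantomConfig(**cfg_d)
    truth = PhantomTruth()
    truth.stack_scale = info["stack_scale"]
    truth.stack_z0 = info["stack_z0"]
    truth.programmed = info["programmed"]
    truth.plane = ReferencePlane(normal=(0, 1, 0),
                                 point=np.asarray(cfg.tumor_center_mm, dtype=float),
                                 in_plane_axes=[(0, 0, 1), (1, 0, 0)])
    tdir = os.path.join(root, "truth")
    truth.exvivo_similarity = read_transform(os.path.join(tdir, "exvivo_similarity.txt"))
    truth.exvivo_deform = read_transform(os.path.join(tdir, "exvivo_deform.txt"))
    truth.stack2ex_affine = read_transform(os.path.join(tdir, "stack2ex_affine.txt"))
    truth.slice_jitters = [read_transform(os.path.join(tdir, f"jitter_{k:03d}.txt"))
                           for k in range(cfg.n_sections)]
    truth.stacking_transforms = [
        read_transform(os.path.join(tdir, f"stacking_{k:03d}.txt"))
        for k in range(cfg.n_sections)]
    ph = Phantom(cfg=cfg, truth=truth)
    ph.invivo_native = read_volume(os.path.join(root, "invivo_native.mha"))
    ph.invivo_realigned = read_volume(os.path.join(root, "invivo_realigned.mha"))
    ph.exvivo = read_volume(os.path.join(root, "exvivo.mha"))
    for frame in ("native", "plane", "exvivo"):
        truth.labels[frame] = read_volume(
            os.path.join(root, f"labels_{frame}.mha")).values.astype(np.int8)
    ph.sections = read_sections(os.path.join(root, "sections"),
                                pixel_size_um=cfg.section_pixel_mm * 1000.0,
                                interval_um=cfg.section_interval_mm * 1000.0,
                                thickness_um=cfg.section_thickness_mm * 1000.0)
    lab_dir = os.path.join(root, "section_labels")
    truth.section_labels = [
        tifffile.imread(os.path.join(lab_dir, f"labels_{k:03d}.tif")).T.astype(np.int8)
        for k in range(cfg.n_sections)]
    for frame in ("plane", "exvivo", "stack"):
        lm = read_landmarks(os.path.join(root, f"landmarks_{frame}.txt"))
        names = lm.names()
        truth.landmarks[frame] = (names, lm.as_array(names))
    names, ks, w2d = [], [], []
    with open(os.path.join(root, "landmark_sections.csv")) as fh:
        next(fh)
        for line in fh:
            n, k, x, y = line.strip().split(",")
            names.append(n)
            ks.append(int(k))
            w2d.append([float(x), float(y)])
    order = np.argsort(names)
    truth.landmark_sections = (list(np.asarray(names)[order]),
                               np.asarray(ks)[order], np.asarray(w2d)[order])
    return ph
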