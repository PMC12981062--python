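"""Synthetic two-channel 3D confocal-like stacks with planted puncta.

Emulates VGAT/CB1 (or VGAT/PV) double stainings: presynaptic puncta are
drawn as a uniform Poisson point process at a planted density, a fixed
fraction of them is duplicated into the second channel (with a small
centroid jitter, mirroring co-labeling of the same terminal), every
punctum is rendered as an anisotropic 3D Gaussian, and Poisson photon
noise plus Gaussian read noise is applied.

Axis conventions: centroids are (x, y, z) in micrometers; voxel arrays
are indexed [z, y, x] as is conventional for z-stacks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImagingGenConfig",
    "ImageStack",
    "PunctaSet",
    "plant_truth",
    "generate_stack",
    "save_stack_tiff",
    "load_stack_tiff",
    "truth_to_csv",
    "imaging_config_from_yaml",
]


@dataclass
class ImagingGenConfig:
    """Ground truth for one synthetic stack.

    ``density_vgat`` is the planted presynaptic punctum density in
    puncta/um^3; ``frac_double`` is the fraction of VGAT puncta that are
    also positive in the second channel (exact by construction, not a
    Bernoulli draw). The default 50 x 50 x 7 um stack at 0.10 x 0.10 x
    0.14 um voxels matches an AiryScan acquisition with a 0.14 um z-step.
    """

    stack_size_um: tuple[float, float, float] = (50.0, 50.0, 7.0)  # (x, y, z)
    voxel_um: tuple[float, float, float] = (0.10, 0.10, 0.14)  # (x, y, z)
    density_vgat: float = 0.14  # puncta / um^3
    frac_double: float = 0.2731
    density_ch2_extra: float = 0.0  # channel-2-only puncta, puncta / um^3
    punctum_sigma_um: tuple[float, float] = (0.12, 0.35)  # (lateral, axial)
    peak_intensity: float = 100.0  # a.u. added at a punctum center
    background: float = 10.0  # a.u.
    background_gradient: float = 0.0  # a.u. per um along x
    poisson_noise: bool = True
    read_noise_sd: float = 2.0  # a.u.
    centroid_jitter_um: float = 0.05  # offset between paired channel centroids
    channel2: str = "CB1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_vgat < 0 or self.density_ch2_extra < 0:
            raise ValueError("densities must be non-negative")
        if not 0.0 <= self.frac_double <= 1.0:
            raise ValueError("frac_double must be in [0, 1]")
        lat, ax = self.punctum_sigma_um
        vx, vy, vz = self.voxel_um
        if lat < 0.5 * max(vx, vy) or ax < 0.5 * vz:
            raise ValueError("punctum sigma smaller than half a voxel: unresolvable")

    @property
    def volume_um3(self) -> float:
        sx, sy, sz = self.stack_size_um
        return sx * sy * sz

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        sx, sy, sz = self.stack_size_um
        vx, vy, vz = self.voxel_um
        return (int(round(sz / vz)), int(round(sy / vy)), int(round(sx / vx)))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ImageStack:
    """Named 3D channels sharing one voxel grid."""

    channels: dict[str, np.ndarray]  # name -> [z, y, x] array
    voxel_um: tuple[float, float, float]  # (x, y, z)
    provenance: str = ""

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channels must share one shape")
        for name, arr in self.channels.items():
            if np.min(arr) < 0:
                raise ValueError(f"channel {name} has negative intensities")

    @property
    def volume_um3(self) -> float:
        nz, ny, nx = next(iter(self.channels.values())).shape
        vx, vy, vz = self.voxel_um
        return nx * vx * ny * vy * nz * vz


@dataclass
class PunctaSet:
    """Punctum centroids for one channel, planted or detected."""

    centroids: np.ndarray  # (N, 3) in um, columns (x, y, z)
    channel: str
    truth_flag: str = "planted"  # planted | detected

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.centroids.shape[0]


def _render_puncta(
    image: np.ndarray,
    centroids_um: np.ndarray,
    voxel_um: tuple[float, float, float],
    sigma_um: tuple[float, float],
    peak: float,
) -> None:
    """Add an anisotropic 3D Gaussian of amplitude ``peak`` per centroid."""
    vx, vy, vz = voxel_um
    lat, ax = sigma_um
    sig_vox = np.array([ax / vz, lat / vy, lat / vx])  # (z, y, x)
    half = np.maximum(1, np.ceil(4.0 * sig_vox).astype(int))
    nz, ny, nx = image.shape
    for cx, cy, cz in centroids_um:
        center = np.array([cz / vz, cy / vy, cx / vx])  # voxel coords (z, y, x)
        lo = np.maximum(0, np.floor(center - half).astype(int))
        hi = np.minimum([nz, ny, nx], np.ceil(center + half).astype(int) + 1)
        if np.any(lo >= hi):
            continue
        zz = np.arange(lo[0], hi[0])[:, None, None]
        yy = np.arange(lo[1], hi[1])[None, :, None]
        xx = np.arange(lo[2], hi[2])[None, None, :]
        d2 = (
            ((zz - center[0]) / sig_vox[0]) ** 2
            + ((yy - center[1]) / sig_vox[1]) ** 2
            + ((xx - center[2]) / sig_vox[2]) ** 2
        )
        image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * np.exp(-0.5 * d2)


def plant_truth(
    config: ImagingGenConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Draw planted centroids: (vgat, channel2, double-positive pairs).

    VGAT counts are Poisson at density x volume with uniform positions;
    exactly round(frac_double x count) of them are duplicated into the
    second channel with Gaussian centroid jitter, plus optional
    independent channel-2-only puncta.
    """
    sx, sy, sz = config.stack_size_um
    n_vgat = int(rng.poisson(config.density_vgat * config.volume_um3))
    vgat = rng.uniform([0, 0, 0], [sx, sy, sz], size=(n_vgat, 3))

    n_double = int(round(config.frac_double * n_vgat))
    chosen = rng.choice(n_vgat, size=n_double, replace=False) if n_double else np.empty(0, int)
    ch2_paired = vgat[chosen] + rng.normal(0.0, config.centroid_jitter_um, (n_double, 3))
    ch2_paired = np.clip(ch2_paired, 0, [sx, sy, sz])

    n_extra = int(rng.poisson(config.density_ch2_extra * config.volume_um3))
    ch2_extra = rng.uniform([0, 0, 0], [sx, sy, sz], size=(n_extra, 3))
    ch2 = np.vstack([ch2_paired, ch2_extra])
    pairs = [(int(v), int(k)) for k, v in enumerate(chosen)]
    return vgat, ch2, pairs


def generate_stack(
    config: ImagingGenConfig,
) -> tuple[ImageStack, dict[str, PunctaSet], list[tuple[int, int]]]:
    """Generate one two-channel stack with recorded ground truth.

    Returns the stack, the planted centroid sets per channel, and the
    list of (vgat_index, channel2_index) pairs that were planted as
    double-positive.
    """
    rng = np.random.default_rng(config.seed)
    vgat, ch2, pairs = plant_truth(config, rng)

    shape = config.shape_zyx
    vx, vy, vz = config.voxel_um
    xx_um = (np.arange(shape[2]) * vx)[None, None, :]
    channels: dict[str, np.ndarray] = {}
    for name, centroids in (("VGAT", vgat), (config.channel2, ch2)):
        img = np.full(shape, config.background, dtype=float)
        if config.background_gradient:
            img = img + config.background_gradient * xx_um
        _render_puncta(img, centroids, config.voxel_um,
                       config.punctum_sigma_um, config.peak_intensity)
        if config.poisson_noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=shape)
        channels[name] = np.maximum(img, 0.0)

    stack = ImageStack(channels=channels, voxel_um=config.voxel_um,
                       provenance=config.config_hash())
    truth = {
        "VGAT": PunctaSet(vgat, "VGAT", "planted"),
        config.channel2: PunctaSet(ch2, config.channel2, "planted"),
    }
    return stack, truth, pairs


def save_stack_tiff(path: str, stack: ImageStack) -> None:
    """Multi-channel TIFF, channel axis first, voxel size in metadata."""
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    vx, vy, vz = stack.voxel_um
    tifffile.imwrite(
        path,
        data,
        metadata={
            "axes": "CZYX",
            "channels": names,
            "voxel_um_xyz": [vx, vy, vz],
            "provenance": stack.provenance,
        },
    )


def load_stack_tiff(path: str) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    names = meta.get("channels", [f"ch{i}" for i in range(data.shape[0])])
    voxel = tuple(meta.get("voxel_um_xyz", (0.10, 0.10, 0.14)))
    channels = {n: np.maximum(data[i].astype(float), 0.0) for i, n in enumerate(names)}
    return ImageStack(channels=channels, voxel_um=voxel,
                      provenance=str(meta.get("provenance", "")))


def truth_to_csv(path: str, puncta: PunctaSet) -> None:
    pd.DataFrame(puncta.centroids, columns=["x_um", "y_um", "z_um"]).assign(
        channel=puncta.channel, truth_flag=puncta.truth_flag
    ).to_csv(path, index=False)


def imaging_config_from_yaml(path: str) -> ImagingGenConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("stack_size_um", "voxel_um", "punctum_sigma_um"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ImagingGenConfig(**raw)
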