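"""3D puncta detection, double-positive identification, and densities.

Re-implements a spot-reconstruction workflow as a transparent,
parameterized chain: large-scale Gaussian background subtraction,
scale-matched Laplacian-of-Gaussian blob detection with local-maximum
extraction and sub-voxel center-of-mass refinement, one-to-one
nearest-centroid colocalization within a fixed radius, and densities as
counts over the whole z-stack volume with per-animal aggregation (the
animal is the statistical unit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .synth_imaging import ImageStack, PunctaSet

__all__ = [
    "DetectionParams",
    "ColocResult",
    "subtract_background",
    "detect_puncta",
    "colocalize",
    "analyze_stack",
    "per_animal_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the detection chain; all surfaced, none hidden.

    ``quality_threshold`` is in units of the robust noise scale (MAD) of
    the blob-detector response; ``axial_psf_ratio`` stretches the
    detection kernel along z to match the elongated confocal PSF.
    """

    background_sigma_um: float = 2.0
    spot_diameter_um: float = 0.35
    quality_threshold: float = 10.0
    coloc_radius_um: float = 0.3
    axial_psf_ratio: float = 2.2

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ColocResult:
    """Densities (puncta/um^3) and the double-positive percentage."""

    density_vgat: float
    density_double: float
    pct_double: float
    stack_volume_um3: float
    n_vgat: int
    n_double: int

    def __post_init__(self) -> None:
        if self.density_double > self.density_vgat + 1e-12:
            raise ValueError("density_double cannot exceed density_vgat")


def subtract_background(
    channel: np.ndarray,
    voxel_um: tuple[float, float, float],
    background_sigma_um: float = 2.0,
) -> np.ndarray:
    """Remove a smooth background estimate (large-scale Gaussian blur).

    The blur scale must be much larger than a punctum so that punctum
    peaks survive; the result is clipped at zero.
    """
    vx, vy, vz = voxel_um
    sigma_vox = (background_sigma_um / vz, background_sigma_um / vy,
                 background_sigma_um / vx)
    bg = ndimage.gaussian_filter(np.asarray(channel, dtype=float), sigma_vox)
    return np.clip(channel - bg, 0.0, None)


def _log_response(
    channel: np.ndarray,
    voxel_um: tuple[float, float, float],
    params: DetectionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale-normalized (negated) Laplacian-of-Gaussian blob response."""
    vx, vy, vz = voxel_um
    sigma_lat = params.spot_diameter_um / 4.0  # kernel matched to punctum scale
    sigma_ax = sigma_lat * params.axial_psf_ratio
    sigma_vox = np.array([sigma_ax / vz, sigma_lat / vy, sigma_lat / vx])
    resp = -ndimage.gaussian_laplace(np.asarray(channel, dtype=float), sigma_vox)
    resp *= sigma_lat**2  # scale normalization
    return resp, sigma_vox


def detect_puncta(
    channel: np.ndarray,
    voxel_um: tuple[float, float, float],
    params: DetectionParams = DetectionParams(),
) -> PunctaSet:
    """Blob detection on a background-subtracted channel.

    Local maxima of the LoG response above ``quality_threshold`` times
    the robust noise scale (1.4826 x MAD) are kept; centroids are refined
    to sub-voxel precision by the center of mass of the response in a
    3x3x3 neighborhood. Deterministic; an empty set is a valid result.
    """
    resp, sigma_vox = _log_response(channel, voxel_um, params)
    noise = 1.4826 * float(np.median(np.abs(resp - np.median(resp))))
    # relative floor keeps noise-free images from a zero threshold, where
    # every flat background plateau would count as a local maximum
    floor = 1e-3 * float(resp.max()) if resp.size else 0.0
    threshold = params.quality_threshold * max(noise, floor)
    footprint = tuple(
        max(3, int(2 * np.floor(s) + 1)) for s in sigma_vox
    )
    local_max = ndimage.maximum_filter(resp, size=footprint, mode="nearest")
    # strict equality keeps plateau ties; they collapse in the CoM step
    peaks = np.argwhere((resp >= local_max) & (resp > threshold))
    nz, ny, nx = resp.shape
    vx, vy, vz = voxel_um
    centroids = []
    for z, y, x in peaks:
        z0, z1 = max(0, z - 1), min(nz, z + 2)
        y0, y1 = max(0, y - 1), min(ny, y + 2)
        x0, x1 = max(0, x - 1), min(nx, x + 2)
        block = resp[z0:z1, y0:y1, x0:x1]
        w = np.clip(block, 0.0, None)
        total = w.sum()
        if total == 0:
            zc, yc, xc = float(z), float(y), float(x)
        else:
            zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
            zc = float((w * zz).sum() / total)
            yc = float((w * yy).sum() / total)
            xc = float((w * xx).sum() / total)
        centroids.append((xc * vx, yc * vy, zc * vz))
    arr = np.asarray(centroids, dtype=float).reshape(-1, 3)
    return PunctaSet(arr, channel="", truth_flag="detected")


def match_puncta(
    a: PunctaSet, b: PunctaSet, radius_um: float
) -> list[tuple[int, int]]:
    """One-to-one centroid matching within ``radius_um``.

    Candidate pairs within the radius are sorted by distance and accepted
    greedily so that each centroid on either side is used at most once —
    the closest available partner wins. Deterministic.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    tree = cKDTree(b.centroids)
    pairs = []
    for ia, neighbors in enumerate(tree.query_ball_point(a.centroids, radius_um)):
        for ib in neighbors:
            d = float(np.linalg.norm(a.centroids[ia] - b.centroids[ib]))
            pairs.append((d, ia, ib))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        matches.append((ia, ib))
    return matches


def colocalize(
    vgat: PunctaSet,
    other: PunctaSet,
    stack_volume_um3: float,
    coloc_radius_um: float = 0.3,
) -> ColocResult:
    """Double-positive densities from two detected centroid sets.

    A VGAT punctum is double-positive iff it is matched one-to-one to a
    channel-2 centroid within the colocalization radius. Densities divide
    counts by the whole z-stack volume. With zero VGAT puncta the
    percentage is undefined (nan) and the densities are zero.
    """
    n_vgat = len(vgat)
    matches = match_puncta(vgat, other, coloc_radius_um)
    n_double = len(matches)
    if n_vgat == 0:
        return ColocResult(0.0, 0.0, float("nan"), stack_volume_um3, 0, 0)
    return ColocResult(
        density_vgat=n_vgat / stack_volume_um3,
        density_double=n_double / stack_volume_um3,
        pct_double=100.0 * n_double / n_vgat,
        stack_volume_um3=stack_volume_um3,
        n_vgat=n_vgat,
        n_double=n_double,
    )


def analyze_stack(
    stack: ImageStack,
    pair: tuple[str, str] = ("VGAT", "CB1"),
    params: DetectionParams = DetectionParams(),
) -> tuple[ColocResult, PunctaSet, PunctaSet]:
    """Full per-stack chain: background subtraction, detection, coloc.

    Baseline subtraction is applied to the VGAT channel (the channel with
    diffuse neuropil background in the stainings this emulates) before
    detection; the second channel is detected as acquired.
    """
    vgat_name, other_name = pair
    vgat_img = subtract_background(stack.channels[vgat_name], stack.voxel_um,
                                   params.background_sigma_um)
    vgat = detect_puncta(vgat_img, stack.voxel_um, params)
    vgat.channel = vgat_name
    other = detect_puncta(stack.channels[other_name], stack.voxel_um, params)
    other.channel = other_name
    result = colocalize(vgat, other, stack.volume_um3, params.coloc_radius_um)
    return result, vgat, other


def per_animal_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-animal means — the animal is the statistical unit.

    ``results`` must have one row per stack with columns ``animal_id``,
    ``density_vgat``, ``density_double`` and ``pct_double`` (plus any
    grouping metadata such as ``genotype``, which is carried through).
    Twelve stacks per animal are expected; fewer produce a warning and
    the mean over what is available.
    """
    required = {"animal_id", "density_vgat", "density_double", "pct_double"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = results.groupby("animal_id").size()
    for animal, n in counts.items():
        if n < 12:
            logger.warning("animal %s has %d stacks (12 expected)", animal, n)
    keep = ["density_vgat", "density_double", "pct_double"]
    meta = [c for c in ("genotype",) if c in results.columns]
    grouped = results.groupby(["animal_id"] + meta, as_index=False)[keep].mean()
    return grouped
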