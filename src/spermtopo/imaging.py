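"""Image front-end: nucleus segmentation, spot detection, IF intensities.

Stands in for the manual microscope workflow: sperm nuclei are segmented
from the nuclear-stain channel by global (Otsu) thresholding and
connected components, an intensity-moment ellipse fit yields the nuclear
axes, FISH spots are found as local maxima with sub-pixel centroids, and
per-nucleus immunofluorescence intensities are measured against a median
background.

Pixel convention: x right, y down, 0-based indices, pixel centers at
integer coordinates; µm = pixel · pixel_size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from spermtopo.geometry import FishSignal, NucleusGeometry

__all__ = [
    "ChannelMap",
    "SegmentationParams",
    "SpotParams",
    "SegmentedNucleus",
    "segment_nuclei",
    "assign_basal_end",
    "detect_spots",
    "measure_if_intensity",
]


class ConfigError(ValueError):
    """Channel-map or parameter misconfiguration."""


@dataclass(frozen=True)
class ChannelMap:
    """Mapping channel index → role, plus the pixel size.

    Roles: ``nuclear``, ``fish:<chromosome>``, ``if:5mC``, ``if:5hmC``.
    Exactly one nuclear channel; at most one of each IF role.
    """

    roles: dict[int, str]
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for role in self.roles.values():
            counts[role] = counts.get(role, 0) + 1
        if counts.get("nuclear", 0) != 1:
            raise ConfigError("channel map must contain exactly one 'nuclear' channel")
        for role in ("if:5mC", "if:5hmC"):
            if counts.get(role, 0) > 1:
                raise ConfigError(f"duplicate channel role {role!r}")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")

    @property
    def nuclear_index(self) -> int:
        return next(i for i, r in self.roles.items() if r == "nuclear")

    def fish_channels(self) -> dict[str, int]:
        """chromosome label → channel index."""
        return {
            r.split(":", 1)[1]: i for i, r in self.roles.items() if r.startswith("fish:")
        }

    def if_channel(self, mark: str) -> int | None:
        for i, r in self.roles.items():
            if r == f"if:{mark}":
                return i
        return None

    def to_json(self) -> str:
        return json.dumps(
            {"pixel_size_um": self.pixel_size_um,
             "roles": {str(k): v for k, v in self.roles.items()}},
            indent=2,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelMap":
        payload = json.loads(Path(path).read_text())
        return cls(
            roles={int(k): v for k, v in payload["roles"].items()},
            pixel_size_um=float(payload["pixel_size_um"]),
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Nucleus segmentation knobs (areas in µm²)."""

    min_area_um2: float = 10.0
    max_area_um2: float = 80.0
    min_solidity: float = 0.9
    exclude_border: bool = True


#: Converts a median absolute deviation to a normal-equivalent sigma.
MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class SpotParams:
    """FISH spot detection knobs.

    The detection threshold is background median + ``mad_k`` robust sigmas
    (MAD · 1.4826), so ``mad_k`` reads as a z-score against Poisson-ish
    background noise.
    """

    mad_k: float = 5.0
    min_separation_px: int = 3
    centroid_window_px: int = 5


@dataclass
class SegmentedNucleus:
    """One segmented nucleus: mask, moment-fit ellipse, and flags."""

    mask: np.ndarray = field(repr=False)
    center_um: tuple[float, float]
    major_um: float  # fitted major-axis length (= L)
    minor_um: float  # fitted minor-axis length (= l)
    axis_direction: tuple[float, float]  # unit vector along the major axis (x, y)
    touches_border: bool
    label: int = 0
    axis_ambiguous: bool = False

    @property
    def endpoints_um(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_um)
        d = np.asarray(self.axis_direction)
        half = self.major_um / 2.0
        return c - half * d, c + half * d


def segment_nuclei(
    image: np.ndarray,
    channel_map: ChannelMap,
    params: SegmentationParams = SegmentationParams(),
) -> list[SegmentedNucleus]:
    """Segment elliptical nuclei from the nuclear-stain channel.

    ``image`` is either the 2-D nuclear channel itself or a (C, H, W)
    stack, in which case the channel map selects the nuclear plane.
    Global Otsu threshold → connected components → size/solidity filters;
    each surviving component gets a moment-based ellipse fit.  Components
    touching the image border are flagged and (by default) excluded.
    """
    if image.ndim == 3:
        plane = image[channel_map.nuclear_index]
    elif image.ndim == 2:
        plane = image
    else:
        raise ValueError(f"expected 2-D or 3-D image, got shape {image.shape}")
    plane = np.asarray(plane, float)
    if np.ptp(plane) == 0:
        return []  # blank field

    thresh = threshold_otsu(plane)
    binary = plane > thresh
    if not binary.any():
        return []
    labels = sk_label(binary)
    ps = channel_map.pixel_size_um
    min_area_px = params.min_area_um2 / ps**2
    max_area_px = params.max_area_um2 / ps**2

    h, w = plane.shape
    out: list[SegmentedNucleus] = []
    for rp in regionprops(labels, intensity_image=plane):
        if not min_area_px <= rp.area <= max_area_px:
            continue
        if rp.solidity < params.min_solidity:
            continue
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if touches and params.exclude_border:
            continue
        cy, cx = rp.centroid_weighted
        theta = rp.orientation  # angle between row axis and major axis, CCW
        # skimage convention: major axis direction (x, y) = (-sin θ, -cos θ);
        # the overall sign is arbitrary for an axis
        direction = (-math.sin(theta), -math.cos(theta))
        out.append(
            SegmentedNucleus(
                mask=labels == rp.label,
                center_um=(cx * ps, cy * ps),
                major_um=rp.axis_major_length * ps,
                minor_um=rp.axis_minor_length * ps,
                axis_direction=direction,
                touches_border=touches,
                label=rp.label,
            )
        )
    return out


def assign_basal_end(
    nucleus: SegmentedNucleus, hint_um: tuple[float, float] | None = None
) -> NucleusGeometry:
    """Orient the fitted axis: choose which endpoint is the basal (tail) end.

    With an annotation hint (e.g. from a simulator sidecar), the endpoint
    nearer the hint becomes the basal point.  Without one, the orientation
    is ambiguous: the nucleus is flagged and the returned geometry carries
    ``qc_pass=False`` with an arbitrary orientation.
    """
    e1, e2 = nucleus.endpoints_um
    if hint_um is None:
        nucleus.axis_ambiguous = True
        geom = NucleusGeometry(
            basal_point=tuple(e1), apex_point=tuple(e2), l=nucleus.minor_um,
            qc_pass=False,
        )
        return geom
    hint = np.asarray(hint_um, float)
    d1 = float(np.linalg.norm(hint - e1))
    d2 = float(np.linalg.norm(hint - e2))
    if math.isclose(d1, d2, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("basal-end hint is equidistant from both axis endpoints")
    basal, apex = (e1, e2) if d1 < d2 else (e2, e1)
    return NucleusGeometry(
        basal_point=tuple(basal), apex_point=tuple(apex), l=nucleus.minor_um
    )


def _background_stats(plane: np.ndarray, nuclei: list[SegmentedNucleus]) -> tuple[float, float]:
    """Median and MAD of pixels outside all nucleus masks."""
    if nuclei:
        union = np.zeros(plane.shape, bool)
        for nuc in nuclei:
            union |= nuc.mask
        bg = plane[~union]
    else:
        bg = plane.ravel()
    if bg.size == 0:
        return float(np.median(plane)), 0.0
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med, mad


def detect_spots(
    image: np.ndarray,
    channel_index: int,
    channel_map: ChannelMap,
    nuclei: list[SegmentedNucleus],
    params: SpotParams = SpotParams(),
    chromosome: str = "",
) -> list[FishSignal]:
    """Detect FISH spots in one channel and assign them to nuclei.

    Local maxima above background + k·MAD, minimum mutual separation,
    sub-pixel centroid by background-subtracted intensity-weighted mean
    over a square window.  Spots falling outside every nucleus mask are
    discarded.  Centroids are reported in µm; ``nucleus_id`` is the string
    of the segmentation label.
    """
    plane = np.asarray(image[channel_index] if image.ndim == 3 else image, float)
    med, mad = _background_stats(plane, nuclei)
    threshold = med + params.mad_k * MAD_TO_SIGMA * max(mad, 1e-12)
    peaks = peak_local_max(
        plane, min_distance=params.min_separation_px, threshold_abs=threshold
    )
    ps = channel_map.pixel_size_um
    half = params.centroid_window_px // 2
    h, w = plane.shape

    signals: list[FishSignal] = []
    for r, c in peaks:
        owner = next((n for n in nuclei if n.mask[r, c]), None)
        if owner is None:
            continue
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        window = plane[r0:r1, c0:c1] - med
        window = np.clip(window, 0.0, None)
        total = window.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        cy = float((rr * window).sum() / total)
        cx = float((cc * window).sum() / total)
        signals.append(
            FishSignal(
                chromosome=chromosome,
                centroid=(cx * ps, cy * ps),
                nucleus_id=str(owner.label),
            )
        )
    return signals


def measure_if_intensity(
    image: np.ndarray,
    channel_index: int,
    nucleus: SegmentedNucleus,
    all_nuclei: list[SegmentedNucleus] | None = None,
) -> float:
    """Mean within-mask intensity minus the median out-of-mask background."""
    plane = np.asarray(image[channel_index] if image.ndim == 3 else image, float)
    if not nucleus.mask.any():
        raise ValueError("empty nucleus mask")
    med, _ = _background_stats(plane, all_nuclei if all_nuclei is not None else [nucleus])
    return float(plane[nucleus.mask].mean() - med)
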