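"""Per-nucleus quantitative feature extraction.

Given an ROI image — a grayscale intensity channel plus an integer label
mask whose connected components are individual nuclei — this module computes
an ordered feature vector per nucleus.  The default manifest has exactly 80
features spanning three families:

* **shape** (20): size and contour descriptors of the labeled component
  (area, perimeter, form factor, axis lengths, Feret diameters, ...).
* **texture** (52): the 13 classic Haralick statistics of the symmetric,
  normalized gray-level co-occurrence matrix (GLCM), restricted to pixel
  pairs that both lie inside the nucleus, direction-averaged over the four
  principal directions, at offset distances 1, 2, 4 and 8, with intensities
  quantized per nucleus to 8 gray levels by min–max scaling.
* **radial** (8): concentric-ring intensity-distribution statistics
  (intensity fraction and pixel-share-normalized mean fraction, 4 rings).

Coordinates are row-major, origin top-left, 0-based; centroids are
unweighted pixel centroids.  Perimeter uses scikit-image's weighted boundary
estimator, so the form factor 4*pi*A/P**2 can slightly exceed 1 on small
digitized disks; it is reported as computed, not clamped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "ROIImage",
    "FeatureManifest",
    "NucleusRecord",
    "MissingObjectError",
    "EmptyROIError",
    "extract_shape_features",
    "extract_texture_features",
    "extract_radial_features",
    "extract_nucleus_table",
    "HARALICK_NAMES",
    "SHAPE_NAMES",
]


class MissingObjectError(KeyError):
    """Requested nucleus label is absent from the mask."""


class EmptyROIError(ValueError):
    """The label mask contains no nuclei."""


@dataclass
class ROIImage:
    """Paired grayscale intensity image and integer label mask for one ROI.

    ``labels`` uses 0 for background and consecutive positive integers
    1..N for the N nuclei.
    """

    intensity: np.ndarray
    labels: np.ndarray
    roi_id: str = "roi"
    case_id: str = "case"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.labels = np.asarray(self.labels)
        if self.intensity.shape != self.labels.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != labels shape "
                f"{self.labels.shape}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())


SHAPE_NAMES = [
    "area",
    "perimeter",
    "form_factor",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_length",
    "minor_axis_length",
    "orientation",
    "equivalent_diameter",
    "compactness",
    "max_feret_diameter",
    "min_feret_diameter",
    "bbox_height",
    "bbox_width",
    "euler_number",
    "convex_area",
    "mean_radius",
    "max_radius",
    "aspect_ratio",
]

HARALICK_NAMES = [
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
]

# (dr, dc) unit directions averaged for each offset distance
_GLCM_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class FeatureManifest:
    """Ordered list of per-nucleus feature names plus extraction settings.

    The default configuration yields exactly 80 features:
    20 shape + 13 Haralick x 4 offset distances + 2 radial x 4 rings.
    """

    n_gray_levels: int = 8
    offsets: tuple[int, ...] = (1, 2, 4, 8)
    symmetric: bool = True
    n_rings: int = 4
    radial_cv: bool = False
    shape_names: tuple[str, ...] = field(default_factory=lambda: tuple(SHAPE_NAMES))

    @property
    def texture_names(self) -> list[str]:
        return [f"texture_{s}_d{d}" for d in self.offsets for s in HARALICK_NAMES]

    @property
    def radial_names(self) -> list[str]:
        names = []
        for r in range(1, self.n_rings + 1):
            names.append(f"radial_frac_r{r}")
            names.append(f"radial_meanfrac_r{r}")
        if self.radial_cv:
            names += [f"radial_cv_r{r}" for r in range(1, self.n_rings + 1)]
        return names

    @property
    def names(self) -> list[str]:
        return (
            [f"shape_{n}" for n in self.shape_names]
            + self.texture_names
            + self.radial_names
        )

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_gray_levels": self.n_gray_levels,
                "offsets": list(self.offsets),
                "symmetric": self.symmetric,
                "n_rings": self.n_rings,
                "radial_cv": self.radial_cv,
                "shape_names": list(self.shape_names),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FeatureManifest":
        d = json.loads(s)
        return cls(
            n_gray_levels=d["n_gray_levels"],
            offsets=tuple(d["offsets"]),
            symmetric=d["symmetric"],
            n_rings=d["n_rings"],
            radial_cv=d.get("radial_cv", False),
            shape_names=tuple(d["shape_names"]),
        )


@dataclass
class NucleusRecord:
    nucleus_id: int
    centroid: tuple[float, float]
    features: np.ndarray


# ---------------------------------------------------------------------------
# shape


def _min_feret(coords: np.ndarray) -> float:
    """Minimum caliper width over the convex hull of the pixel corners."""
    # pixel corners make 1-pixel-wide shapes well-posed
    corners = np.concatenate(
        [coords + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    try:
        hull = ConvexHull(corners)
    except QhullError:  # pragma: no cover - corners are never collinear
        return 0.0
    pts = corners[hull.vertices]
    best = np.inf
    m = len(pts)
    for a in range(m):
        edge = pts[(a + 1) % m] - pts[a]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.ptp((pts - pts[a]) @ normal)
        best = min(best, width)
    return float(best)


def _boundary_radii(mask: np.ndarray, centroid: tuple[float, float]) -> np.ndarray:
    """Distances from centroid to the 4-connected boundary pixels."""
    pad = np.pad(mask, 1)
    interior = pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    boundary = mask & ~interior
    rr, cc = np.nonzero(boundary)
    return np.hypot(rr - centroid[0], cc - centroid[1])


def extract_shape_features(labels: np.ndarray, nucleus_id: int) -> np.ndarray:
    """Compute the 20 default shape features for one labeled nucleus."""
    mask = labels == nucleus_id
    if not mask.any():
        raise MissingObjectError(f"nucleus {nucleus_id} not present in mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    form_factor = 4 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    compactness = perimeter**2 / (4 * np.pi * area) if perimeter > 0 else 0.0
    minr, minc, maxr, maxc = props.bbox
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    aspect = major / minor if minor > 0 else 0.0
    radii = _boundary_radii(mask, props.centroid)
    values = {
        "area": area,
        "perimeter": perimeter,
        "form_factor": form_factor,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "orientation": float(props.orientation),
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "compactness": compactness,
        "max_feret_diameter": float(props.feret_diameter_max),
        "min_feret_diameter": _min_feret(props.coords.astype(float)),
        "bbox_height": float(maxr - minr),
        "bbox_width": float(maxc - minc),
        "euler_number": float(props.euler_number),
        "convex_area": float(props.area_convex),
        "mean_radius": float(radii.mean()) if radii.size else 0.0,
        "max_radius": float(radii.max()) if radii.size else 0.0,
        "aspect_ratio": aspect,
    }
    return np.array([values[n] for n in SHAPE_NAMES])


# ---------------------------------------------------------------------------
# texture


def quantize_intensity(
    intensity: np.ndarray, mask: np.ndarray, n_levels: int
) -> np.ndarray:
    """Min–max quantize within-nucleus intensities to 0..n_levels-1.

    Per-nucleus scaling makes texture contrast-invariant across staining
    intensity.  Constant nuclei map to level 0.
    """
    vals = intensity[mask].astype(float)
    lo, hi = vals.min(), vals.max()
    out = np.zeros(intensity.shape, dtype=np.intp)
    if hi > lo:
        q = (intensity.astype(float) - lo) / (hi - lo) * n_levels
        out = np.clip(q.astype(np.intp), 0, n_levels - 1)
    return out


def masked_glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    distance: int,
    n_levels: int,
    symmetric: bool = True,
) -> np.ndarray:
    """Direction-averaged co-occurrence counts restricted to in-mask pairs.

    Counts pixel pairs (p, p + d*direction) with both endpoints inside the
    mask, accumulated over the four principal directions, symmetrized, and
    returned un-normalized.
    """
    L = n_levels
    counts = np.zeros((L, L), dtype=np.int64)
    H, W = quantized.shape
    for dr, dc in _GLCM_DIRECTIONS:
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = quantized[r0:r1, c0:c1]
        dst = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        both = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if both.any():
            flat = src[both] * L + dst[both]
            counts += np.bincount(flat, minlength=L * L).reshape(L, L)
    if symmetric:
        counts = counts + counts.T
    return counts


def haralick_statistics(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of a normalized co-occurrence matrix.

    Natural-log entropies with 0*log(0) = 0; degenerate denominators
    (zero marginal variance) yield 0 for correlation and IMC1.
    """
    L = P.shape[0]
    i = np.arange(L)[:, None].astype(float)
    j = np.arange(L)[None, :].astype(float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (np.arange(L) * px).sum()
    mu_y = (np.arange(L) * py).sum()
    var_x = ((np.arange(L) - mu_x) ** 2 * px).sum()
    var_y = ((np.arange(L) - mu_y) ** 2 * py).sum()

    def _ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    asm = float((P**2).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = float(((i - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    k_sum = np.arange(2 * L - 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel(), P.ravel())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _ent(p_sum)

    entropy = _ent(P.ravel())

    k_diff = np.arange(L)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), P.ravel())
    mu_d = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - mu_d) ** 2 * p_diff).sum())
    diff_ent = _ent(p_diff)

    hx, hy = _ent(px), _ent(py)
    with np.errstate(divide="ignore"):
        log_pxy = np.log(np.outer(px, py))
    valid = np.isfinite(log_pxy)
    hxy1 = float(-(P[valid] * log_pxy[valid]).sum())
    outer = np.outer(px, py)
    hxy2 = float(-(outer[valid] * log_pxy[valid]).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_avg,
            sum_var,
            sum_ent,
            entropy,
            diff_var,
            diff_ent,
            imc1,
            imc2,
        ]
    )


def extract_texture_features(
    intensity: np.ndarray,
    labels: np.ndarray,
    nucleus_id: int,
    manifest: FeatureManifest | None = None,
) -> np.ndarray:
    """Haralick texture sub-vector for one nucleus (13 stats per offset).

    Offsets with no valid within-nucleus pixel pair contribute zeros (with
    a logged warning), so the sub-vector length is always 13 * n_offsets.
    """
    manifest = manifest or FeatureManifest()
    mask = labels == nucleus_id
    if not mask.any():
        raise MissingObjectError(f"nucleus {nucleus_id} not present in mask")
    quant = quantize_intensity(intensity, mask, manifest.n_gray_levels)
    out = []
    for d in manifest.offsets:
        counts = masked_glcm(
            quant, mask, d, manifest.n_gray_levels, symmetric=manifest.symmetric
        )
        total = counts.sum()
        if total == 0:
            logger.warning(
                "nucleus %d has no pixel pair at offset %d; texture set to 0",
                nucleus_id,
                d,
            )
            out.append(np.zeros(len(HARALICK_NAMES)))
        else:
            out.append(haralick_statistics(counts / total))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# radial


def extract_radial_features(
    intensity: np.ndarray,
    labels: np.ndarray,
    nucleus_id: int,
    n_rings: int = 4,
    include_cv: bool = False,
    n_wedges: int = 8,
) -> np.ndarray:
    """Concentric-ring intensity distribution around the nucleus centroid.

    Rings are equal-width distance bands from the centroid out to the most
    distant pixel.  Per ring: fraction of total intensity, and that fraction
    normalized by the ring's pixel share.  Optionally the coefficient of
    variation of intensity across ``n_wedges`` angular wedges per ring.
    A degenerate nucleus (all pixels equidistant) falls back to one ring.
    """
    mask = labels == nucleus_id
    if not mask.any():
        raise MissingObjectError(f"nucleus {nucleus_id} not present in mask")
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    d = np.hypot(rr - cy, cc - cx)
    vals = intensity[rr, cc].astype(float)
    dmax = d.max()
    if dmax == 0:
        ring = np.zeros(d.size, dtype=int)
    else:
        ring = np.minimum((d / dmax * n_rings).astype(int), n_rings - 1)
    total = vals.sum()
    n_pix = d.size
    fracs = np.zeros(n_rings)
    meanfracs = np.zeros(n_rings)
    cvs = np.zeros(n_rings)
    theta = np.arctan2(rr - cy, cc - cx)
    wedge = np.minimum(((theta + np.pi) / (2 * np.pi) * n_wedges).astype(int), n_wedges - 1)
    for r in range(n_rings):
        sel = ring == r
        cnt = sel.sum()
        if cnt == 0:
            continue
        frac = vals[sel].sum() / total if total > 0 else cnt / n_pix
        fracs[r] = frac
        meanfracs[r] = frac / (cnt / n_pix)
        if include_cv:
            sums = np.bincount(wedge[sel], weights=vals[sel], minlength=n_wedges)
            counts = np.bincount(wedge[sel], minlength=n_wedges)
            means = sums[counts > 0] / counts[counts > 0]
            cvs[r] = means.std() / means.mean() if means.mean() > 0 else 0.0
    interleaved = np.empty(2 * n_rings)
    interleaved[0::2] = fracs
    interleaved[1::2] = meanfracs
    if include_cv:
        return np.concatenate([interleaved, cvs])
    return interleaved


# ---------------------------------------------------------------------------
# per-ROI table


def extract_nucleus_table(
    roi: ROIImage, manifest: FeatureManifest | None = None
) -> list[NucleusRecord]:
    """One :class:`NucleusRecord` per label, ascending nucleus_id."""
    manifest = manifest or FeatureManifest()
    present = np.unique(roi.labels)
    present = present[present > 0]
    if present.size == 0:
        raise EmptyROIError(f"ROI {roi.roi_id} has an empty label mask")
    records = []
    for nid in present:
        nid = int(nid)
        mask = roi.labels == nid
        rr, cc = np.nonzero(mask)
        shape = extract_shape_features(roi.labels, nid)
        texture = extract_texture_features(roi.intensity, roi.labels, nid, manifest)
        radial = extract_radial_features(
            roi.intensity,
            roi.labels,
            nid,
            n_rings=manifest.n_rings,
            include_cv=manifest.radial_cv,
        )
        vec = np.concatenate([shape, texture, radial])
        assert vec.size == len(manifest)
        records.append(
            NucleusRecord(
                nucleus_id=nid,
                centroid=(float(rr.mean()), float(cc.mean())),
                features=vec,
            )
        )
    return records


def nucleus_table_to_frame(
    records: list[NucleusRecord],
    manifest: FeatureManifest,
    case_id: str = "case",
    roi_id: str = "roi",
) -> pd.DataFrame:
    """Flatten records to the on-disk CSV layout."""
    rows = []
    for rec in records:
        row = {
            "case_id": case_id,
            "roi_id": roi_id,
            "nucleus_id": rec.nucleus_id,
            "centroid_row": rec.centroid[0],
            "centroid_col": rec.centroid[1],
        }
        row.update(dict(zip(manifest.names, rec.features)))
        rows.append(row)
    return pd.DataFrame(rows)
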