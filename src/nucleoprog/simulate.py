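"""Seeded synthetic ROI images and cohorts.

No public imaging data accompany the recurrence-prognosis study design this
package implements, so every downstream stage is exercised on synthetic
data with the same statistical structure:

* **ROI images** — non-overlapping rotated ellipses with lognormal area and
  Beta-distributed eccentricity on a constant background; chromatin texture
  is smoothed multiplicative noise whose spatial frequency and amplitude
  rise with ``texture_contrast_level``.
* **Cohorts** — four outcome groups (A: recurrence within 5 years, B:
  recurrence between 5 and 10, C: censored at 5–10 years, D: recurrence-free
  beyond 10), where recurrence groups draw nuclei from a phenotype shifted
  by a controllable effect size (group A shifted twice as far as group B,
  so the two horizons are distinguishable; C and D share the baseline).

A fast path draws per-nucleus feature tables directly — Gaussian features
with group-shifted means, case- and ROI-level random effects, and a
spatially autocorrelated two-variant mixing field — bypassing image
rendering so classifier-level behaviour can be tested at cohort scale.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .features import FeatureManifest, ROIImage
from .prognosis import CaseRecord, assign_group

__all__ = [
    "NucleusPhenotype",
    "CohortSpec",
    "SyntheticCase",
    "PlacementError",
    "generate_roi_image",
    "generate_nucleus_table",
    "generate_cohort",
    "attach_roi_vectors",
    "write_cohort",
    "GROUP_SHIFT_FACTOR",
]

#: relative phenotype shift per group (times CohortSpec.effect_size)
GROUP_SHIFT_FACTOR = {"A": 1.0, "B": 0.5, "C": 0.0, "D": 0.0}

#: follow-up month ranges per group: (low, high, recurrence)
_GROUP_MONTHS = {
    "A": (6.0, 59.0, True),
    "B": (61.0, 119.0, True),
    "C": (61.0, 119.0, False),
    "D": (121.0, 200.0, False),
}


class PlacementError(RuntimeError):
    """Could not place the requested nuclei without overlap."""


@dataclass
class NucleusPhenotype:
    """Morphology/texture parameters of one nucleus population.

    ``spatial_mixing`` in [0, 1] controls how the two sub-variants of the
    population intermix across an ROI: 0 keeps them spatially clustered,
    1 interleaves them at random.
    """

    mean_area: float = 180.0  # pixels^2
    area_cv: float = 0.3
    mean_eccentricity: float = 0.55
    texture_contrast_level: float = 0.6
    spatial_mixing: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_area <= 0:
            raise ValueError("mean_area must be positive")
        if not 0 <= self.mean_eccentricity < 1:
            raise ValueError("mean_eccentricity must lie in [0, 1)")
        if self.area_cv < 0:
            raise ValueError("area_cv must be nonnegative")
        if self.texture_contrast_level < 0:
            raise ValueError("texture_contrast_level must be nonnegative")
        if not 0 <= self.spatial_mixing <= 1:
            raise ValueError("spatial_mixing must lie in [0, 1]")

    def shifted(self, shift: float) -> "NucleusPhenotype":
        """Phenotype displaced toward the high-risk morphology.

        Larger, more elongated nuclei with coarser chromatin — the
        qualitative direction nuclear grading responds to.
        """
        return NucleusPhenotype(
            mean_area=self.mean_area * (1 + 0.15 * shift),
            area_cv=self.area_cv,
            mean_eccentricity=min(0.95, self.mean_eccentricity + 0.08 * shift),
            texture_contrast_level=self.texture_contrast_level + 0.3 * shift,
            spatial_mixing=self.spatial_mixing,
        )


@dataclass
class CohortSpec:
    """Conditions for one synthetic cohort.

    The default case counts mirror the study design (40/22/37/32 across
    groups A–D, 131 cases); ``effect_size`` separates recurrence from
    non-recurrence phenotypes in units of the nucleus-level feature SD.
    """

    n_cases_per_group: dict = field(
        default_factory=lambda: {"A": 40, "B": 22, "C": 37, "D": 32}
    )
    rois_per_case: int = 10
    nuclei_per_roi: int = 100
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_cases_per_group) != {"A", "B", "C", "D"}:
            raise ValueError("group labels must be exactly {A, B, C, D}")
        if any(v < 1 for v in self.n_cases_per_group.values()):
            raise ValueError("every group needs at least one case")
        if self.rois_per_case < 1 or self.nuclei_per_roi < 1:
            raise ValueError("rois_per_case and nuclei_per_roi must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")


@dataclass
class SyntheticCase(CaseRecord):
    """CaseRecord plus its generating payload (tables and/or images)."""

    nucleus_table: pd.DataFrame | None = None
    images: list[ROIImage] = field(default_factory=list)


# ---------------------------------------------------------------------------
# image path


def _rasterize_ellipse(cy, cx, a, b, theta, shape):
    """Pixel centers inside the rotated ellipse, clipped to the image."""
    H, W = shape
    r_ext = max(a, b)
    r0 = max(0, int(np.floor(cy - r_ext)) - 1)
    r1 = min(H, int(np.ceil(cy + r_ext)) + 2)
    c0 = max(0, int(np.floor(cx - r_ext)) - 1)
    c1 = min(W, int(np.ceil(cx + r_ext)) + 2)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - cy, cc - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def generate_roi_image(
    phenotype: NucleusPhenotype,
    n_nuclei: int,
    image_size: int = 128,
    seed: int = 0,
    max_attempts: int = 1000,
    roi_id: str = "roi",
    case_id: str = "case",
) -> ROIImage:
    """Render one ROI: label mask with exactly ``n_nuclei`` components.

    Nuclei are rejected-and-retried until they neither overlap nor touch an
    already placed nucleus (a 1-pixel clearance keeps components
    unambiguous); after ``max_attempts`` failures per nucleus a
    :class:`PlacementError` reports the capacity problem.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.zeros((image_size, image_size), dtype=np.uint16)
    blocked = np.zeros((image_size, image_size), dtype=bool)
    intensity = np.full((image_size, image_size), 40.0)

    sigma2 = np.log1p(phenotype.area_cv**2)
    mu = np.log(phenotype.mean_area) - sigma2 / 2
    me = phenotype.mean_eccentricity
    kappa = 10.0

    for nid in range(1, n_nuclei + 1):
        placed = False
        for _ in range(max_attempts):
            area = rng.lognormal(mu, np.sqrt(sigma2))
            ecc = rng.beta(me * kappa, (1 - me) * kappa) if me > 0 else 0.0
            theta = rng.uniform(0, np.pi)
            axis_ratio = np.sqrt(1 - ecc**2)
            a = np.sqrt(area / (np.pi * axis_ratio))
            b = a * axis_ratio
            cy = rng.uniform(a, image_size - a) if image_size > 2 * a else image_size / 2
            cx = rng.uniform(a, image_size - a) if image_size > 2 * a else image_size / 2
            rr, cc = _rasterize_ellipse(cy, cx, a, b, theta, labels.shape)
            if rr.size == 0:
                rr = np.array([int(round(cy))])
                cc = np.array([int(round(cx))])
                rr = np.clip(rr, 0, image_size - 1)
                cc = np.clip(cc, 0, image_size - 1)
            if blocked[rr, cc].any():
                continue
            labels[rr, cc] = nid
            # block the nucleus and a 1-px margin around it
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rb = np.clip(rr + dr, 0, image_size - 1)
                    cb = np.clip(cc + dc, 0, image_size - 1)
                    blocked[rb, cb] = True
            # chromatin texture: smoothed multiplicative noise; finer grain
            # and larger amplitude at higher contrast levels
            tc = phenotype.texture_contrast_level
            base = 150.0
            noise = rng.standard_normal(rr.size)
            field_img = np.zeros(labels.shape)
            field_img[rr, cc] = noise
            sigma = max(0.6, 2.5 / (1.0 + tc))
            smooth = gaussian_filter(field_img, sigma)[rr, cc]
            sd = smooth.std()
            if sd > 0:
                smooth = smooth / sd
            amp = min(0.5, 0.25 * tc)
            intensity[rr, cc] = np.clip(base * (1 + amp * smooth), 1, 255)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {nid}/{n_nuclei} in a "
                f"{image_size}x{image_size} image after {max_attempts} attempts"
            )
    return ROIImage(
        intensity=intensity.astype(np.uint8),
        labels=labels,
        roi_id=roi_id,
        case_id=case_id,
    )


# ---------------------------------------------------------------------------
# fast path: per-nucleus feature tables


def generate_nucleus_table(
    n_nuclei: int,
    rng: np.random.Generator,
    shift: float = 0.0,
    case_effect: np.ndarray | None = None,
    roi_sigma: float = 0.15,
    spatial_mixing: float = 0.5,
    variant_amplitude: float = 0.5,
    roi_size: float = 512.0,
    manifest: FeatureManifest | None = None,
    case_id: str = "case",
    roi_id: str = "roi",
) -> pd.DataFrame:
    """Draw one ROI's per-nucleus feature table directly.

    Features are unit-variance Gaussians with mean ``shift / sqrt(F)`` per
    feature (so ``shift`` is the total Mahalanobis displacement), plus a
    shared case effect, an ROI-level random effect of sd ``roi_sigma``, and
    a two-variant offset of ±``variant_amplitude`` on the first 10 features
    assigned by a spatially autocorrelated field.  ``spatial_mixing``
    interpolates the variant layout from clustered (0) to random (1).
    """
    manifest = manifest or FeatureManifest()
    names = manifest.names
    F = len(names)
    u = np.full(F, 1.0 / np.sqrt(F))
    case_effect = np.zeros(F) if case_effect is None else case_effect
    roi_effect = rng.normal(0, roi_sigma, size=F)

    rows = rng.uniform(0, roi_size, size=n_nuclei)
    cols = rng.uniform(0, roi_size, size=n_nuclei)
    # low-frequency field splits the ROI into two spatial domains
    wx, wy = rng.uniform(0.5, 1.5, size=2)
    phase = rng.uniform(0, 2 * np.pi)
    fieldvals = np.cos(2 * np.pi * (wx * rows + wy * cols) / roi_size + phase)
    variant = (fieldvals > 0).astype(int)
    flip = rng.random(n_nuclei) < spatial_mixing
    variant[flip] = rng.integers(0, 2, size=int(flip.sum()))

    X = rng.standard_normal((n_nuclei, F))
    X += shift * u + case_effect + roi_effect
    delta = np.zeros(F)
    delta[:10] = variant_amplitude
    X += np.where(variant[:, None] == 1, delta, -delta)

    df = pd.DataFrame(X, columns=names)
    df.insert(0, "centroid_col", cols)
    df.insert(0, "centroid_row", rows)
    df.insert(0, "nucleus_id", np.arange(1, n_nuclei + 1))
    df.insert(0, "roi_id", roi_id)
    df.insert(0, "case_id", case_id)
    return df


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    spec: CohortSpec,
    mode: str = "tables",
    case_sigma: float = 0.3,
    roi_sigma: float = 0.15,
    base_phenotype: NucleusPhenotype | None = None,
    image_size: int = 128,
    manifest: FeatureManifest | None = None,
) -> list[SyntheticCase]:
    """Generate a full cohort, tables (fast) or rendered images.

    Every case's (recurrence, months) pair is consistent with its group
    label by construction; a recurrence-group case draws nuclei from a
    phenotype shifted by ``effect_size * GROUP_SHIFT_FACTOR[group]``.
    """
    if mode not in ("tables", "images"):
        raise ValueError("mode must be 'tables' or 'images'")
    manifest = manifest or FeatureManifest()
    base_phenotype = base_phenotype or NucleusPhenotype()
    root = np.random.SeedSequence(spec.seed)
    cases: list[SyntheticCase] = []
    idx = 0
    for group in ("A", "B", "C", "D"):
        lo, hi, rec = _GROUP_MONTHS[group]
        shift = spec.effect_size * GROUP_SHIFT_FACTOR[group]
        for _ in range(spec.n_cases_per_group[group]):
            idx += 1
            case_id = f"case{idx:04d}"
            rng = np.random.default_rng(root.spawn(1)[0])
            months = float(rng.uniform(lo, hi))
            assert assign_group(rec, months) == group
            if mode == "tables":
                F = len(manifest)
                case_effect = rng.normal(0, case_sigma, size=F)
                tables = [
                    generate_nucleus_table(
                        spec.nuclei_per_roi,
                        rng,
                        shift=shift,
                        case_effect=case_effect,
                        roi_sigma=roi_sigma,
                        manifest=manifest,
                        case_id=case_id,
                        roi_id=f"{case_id}_roi{r + 1:03d}",
                    )
                    for r in range(spec.rois_per_case)
                ]
                cases.append(
                    SyntheticCase(
                        case_id=case_id,
                        recurrence=rec,
                        months=months,
                        group=group,
                        nucleus_table=pd.concat(tables, ignore_index=True),
                    )
                )
            else:
                pheno = base_phenotype.shifted(shift)
                images = [
                    generate_roi_image(
                        pheno,
                        spec.nuclei_per_roi,
                        image_size=image_size,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        roi_id=f"{case_id}_roi{r + 1:03d}",
                        case_id=case_id,
                    )
                    for r in range(spec.rois_per_case)
                ]
                cases.append(
                    SyntheticCase(
                        case_id=case_id,
                        recurrence=rec,
                        months=months,
                        group=group,
                        images=images,
                    )
                )
    return cases


def attach_roi_vectors(
    cases: list[SyntheticCase],
    manifest: FeatureManifest | None = None,
    n_levels: int = 8,
    k: int = 5,
    min_nuclei: int = 5,
) -> list[SyntheticCase]:
    """Run feature extraction/aggregation so each case carries ROI vectors."""
    from .cflcm import aggregate_table
    from .features import extract_nucleus_table, nucleus_table_to_frame

    manifest = manifest or FeatureManifest()
    for case in cases:
        table = case.nucleus_table
        if table is None:
            frames = [
                nucleus_table_to_frame(
                    extract_nucleus_table(img, manifest),
                    manifest,
                    case_id=img.case_id,
                    roi_id=img.roi_id,
                )
                for img in case.images
            ]
            table = pd.concat(frames, ignore_index=True)
        roi_df = aggregate_table(
            table, feature_columns=manifest.names, n_levels=n_levels, k=k,
            min_nuclei=min_nuclei,
        )
        feat_cols = [c for c in roi_df.columns if c not in ("case_id", "roi_id")]
        case.roi_vectors = roi_df[feat_cols].to_numpy()
        case.roi_ids = list(roi_df["roi_id"])
    return cases


def write_cohort(cases: list[SyntheticCase], out_dir: str | Path) -> Path:
    """Write cohort CSV plus per-ROI payloads (tables or TIFF pairs)."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    tables = []
    for case in cases:
        roi_paths = []
        if case.nucleus_table is not None:
            tables.append(case.nucleus_table)
        for img in case.images:
            mask_path = out_dir / f"{img.roi_id}_mask.tif"
            int_path = out_dir / f"{img.roi_id}_intensity.tif"
            tifffile.imwrite(mask_path, img.labels.astype(np.uint16))
            tifffile.imwrite(int_path, img.intensity.astype(np.uint8))
            roi_paths.append(mask_path.name)
        rows.append(
            {
                "case_id": case.case_id,
                "group": case.group,
                "recurrence": int(case.recurrence),
                "months": case.months,
                "roi_paths": ";".join(roi_paths),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)
    if tables:
        pd.concat(tables, ignore_index=True).to_csv(
            out_dir / "nucleus_features.csv", index=False
        )
    return out_dir
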