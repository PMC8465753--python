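"""Tumor feature computation from a refined mask and an atlas bundle.

From a binary glioblastoma segmentation registered to the reference space,
233 named features are extracted:

* volume (2): in patient space and in reference space, both in mL;
* laterality (3): left/right overlap percentages and a midline-crossing flag;
* multifocality (3): flag, focus count and the largest satellite distance
  (−1.0 mm sentinel for unifocal tumors);
* resectability (2): expected residual volume (mL) and resectability index;
* cortical location profile (87): tumor-overlap percentage per structure of
  four parcellations (15 + 48 + 7 + 17);
* subcortical location profile (2 x 68): overlap percentage and, for
  non-overlapping structures, the directed 95th-percentile distance from
  the tumor boundary to the thresholded structure.

The mask is first refined: binary closing (spherical kernel, radius 2
voxels, two iterations) followed by removal of connected components smaller
than 0.1 mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasBundle, HemisphereMask, ProbabilisticAtlas, ResectionHeatmap
from .volumes import (
    BinaryMask,
    EmptyMaskError,
    LabeledComponents,
    binary_closing,
    connected_components,
    directed_distance_percentile,
    min_surface_distance,
)

#: Minimum component volume kept by refinement (components strictly smaller
#: are discarded).
MIN_COMPONENT_ML = 0.1
#: Minimum surface separation for a component to count as an independent focus.
SATELLITE_MIN_DISTANCE_MM = 5.0
#: Distance reported for unifocal tumors and for structures empty after
#: thresholding.
UNIFOCAL_SENTINEL_MM = -1.0

TOTAL_FEATURE_COUNT = 233


def refine_tumor_mask(mask: BinaryMask, closing_radius: int = 2,
                      closing_iterations: int = 2,
                      min_component_ml: float = MIN_COMPONENT_ML,
                      connectivity: int = 26) -> BinaryMask:
    """Close small gaps, then drop components below the volume floor.

    May return an empty mask when nothing survives the 0.1 mL filter.
    """
    closed = binary_closing(mask, closing_radius, closing_iterations)
    if closed.is_empty:
        return closed
    comps = connected_components(closed, connectivity)
    voxel_ml = mask.geometry.voxel_volume_mm3 / 1000.0
    keep = np.flatnonzero(comps.sizes * voxel_ml >= min_component_ml) + 1
    kept = np.isin(comps.labels, keep) if keep.size else np.zeros_like(closed.data)
    return BinaryMask(mask.geometry, kept)


def compute_volume(mask: BinaryMask) -> float:
    """Tumor volume in mL: voxel count x voxel volume (mm^3) / 1000."""
    return mask.volume_ml()


def compute_laterality(mask: BinaryMask, hemi: HemisphereMask
                       ) -> tuple[float, float, bool]:
    """Left/right tumor-volume percentages and the midline-crossing flag.

    Crossing is true iff at least one tumor voxel lies in each hemisphere.
    """
    if mask.is_empty:
        raise EmptyMaskError("laterality is undefined for an empty mask")
    total = mask.voxel_count
    left = int(np.logical_and(mask.data, hemi.left).sum())
    right = total - left
    return 100.0 * left / total, 100.0 * right / total, left > 0 and right > 0


@dataclass
class FociSet:
    """Connected tumor foci with per-focus volumes and diameters."""

    components: LabeledComponents
    volumes_ml: np.ndarray
    diameters_mm: np.ndarray          # equivalent-sphere diameters
    index_of_biggest: int             # 1-based component label
    satellite_labels: list[int]       # labels >= 5 mm from the biggest
    satellite_distances_mm: dict[int, float] = field(default_factory=dict)


def find_foci(mask: BinaryMask, connectivity: int = 26,
              min_distance_mm: float = SATELLITE_MIN_DISTANCE_MM) -> FociSet:
    """Split the tumor into foci and qualify satellites by the distance rule.

    The biggest focus is the one of maximal volume. A secondary component
    counts as an independent satellite focus only when its minimum surface
    distance to the biggest focus is at least ``min_distance_mm``.
    """
    if mask.is_empty:
        raise EmptyMaskError("no foci in an empty mask")
    comps = connected_components(mask, connectivity)
    voxel_ml = mask.geometry.voxel_volume_mm3 / 1000.0
    volumes = comps.sizes * voxel_ml
    # d = (6V/pi)^(1/3) with V in mm^3
    diameters = np.cbrt(6.0 * volumes * 1000.0 / np.pi)
    biggest = int(np.argmax(volumes)) + 1
    biggest_mask = comps.component_mask(biggest)
    satellites: list[int] = []
    distances: dict[int, float] = {}
    for label in range(1, comps.count + 1):
        if label == biggest:
            continue
        d = min_surface_distance(comps.component_mask(label), biggest_mask)
        if d >= min_distance_mm:
            satellites.append(label)
            distances[label] = d
    return FociSet(comps, volumes, diameters, biggest, satellites, distances)


def compute_multifocality(mask: BinaryMask, connectivity: int = 26
                          ) -> tuple[bool, int, float]:
    """Multifocality flag, independent focus count and largest satellite distance.

    Unifocal tumors (including ones whose secondary components all fall
    within 5 mm of the biggest focus) report the −1.0 mm sentinel.
    """
    foci = find_foci(mask, connectivity)
    count = 1 + len(foci.satellite_labels)
    if count == 1:
        return False, 1, UNIFOCAL_SENTINEL_MM
    return True, count, float(max(foci.satellite_distances_mm.values()))


def compute_resectability(mask: BinaryMask, heatmap: ResectionHeatmap,
                          left_pct: float, right_pct: float
                          ) -> tuple[float, float]:
    """Expected residual volume (mL) and resectability index in [0, 1].

    The heat map of the hemisphere holding most of the tumor is integrated
    over the tumor voxels; ties go to the left hemisphere.
    """
    if mask.is_empty:
        raise EmptyMaskError("resectability is undefined for an empty mask")
    chosen = heatmap.left_map if left_pct >= right_pct else heatmap.right_map
    voxel_ml = mask.geometry.voxel_volume_mm3 / 1000.0
    resectable_ml = float(chosen[mask.data].sum()) * voxel_ml
    volume_ml = mask.volume_ml()
    residual_ml = volume_ml - resectable_ml
    index = min(max(resectable_ml / volume_ml, 0.0), 1.0)
    return residual_ml, index


def cortical_profile(mask: BinaryMask, cortical: dict) -> dict[str, float]:
    """Per-structure tumor-overlap percentages across the four parcellations.

    Keys are ``cortical.<atlas_id>.<structure>``; values are
    100 x |tumor ∩ structure| / |tumor|.
    """
    if mask.is_empty:
        raise EmptyMaskError("cortical profile is undefined for an empty mask")
    total = mask.voxel_count
    out: dict[str, float] = {}
    for atlas_id, atlas in cortical.items():
        tumor_labels = atlas.labels[mask.data]
        counts = np.bincount(tumor_labels, minlength=max(atlas.names) + 1)
        for label in sorted(atlas.names):
            out[f"cortical.{atlas_id}.{atlas.names[label]}"] = (
                100.0 * counts[label] / total)
    return out


def subcortical_profile(mask: BinaryMask, atlas: ProbabilisticAtlas
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """Overlap percentage and distance (mm) per subcortical structure.

    Each structure is thresholded at the atlas probability threshold
    (inclusive). Overlapping structures report distance 0.0; structures
    empty after thresholding report the −1.0 sentinel; otherwise the
    directed 95th-percentile distance from the tumor boundary to the
    structure is reported.
    """
    if mask.is_empty:
        raise EmptyMaskError("subcortical profile is undefined for an empty mask")
    total = mask.voxel_count
    overlaps: dict[str, float] = {}
    distances: dict[str, float] = {}
    for name in atlas.names:
        smask = atlas.structure_mask(name)
        inter = int(np.logical_and(mask.data, smask.data).sum())
        overlaps[name] = 100.0 * inter / total
        if inter > 0:
            distances[name] = 0.0
        elif smask.is_empty:
            distances[name] = UNIFOCAL_SENTINEL_MM
        else:
            distances[name] = directed_distance_percentile(mask, smask, 95.0)
    return overlaps, distances


@dataclass
class TumorFeatureRecord:
    """The named feature values of one case, grouped by category.

    ``has_tumor`` is False when refinement left no tumor; the scalar fields
    are then None and the profiles empty — an explicit "no tumor" variant
    rather than silent zeros.
    """

    patient_id: str
    has_tumor: bool
    volume_patient_ml: float | None = None
    volume_mni_ml: float | None = None
    left_pct: float | None = None
    right_pct: float | None = None
    midline_crossing: bool | None = None
    multifocal: bool | None = None
    focus_count: int | None = None
    satellite_distance_mm: float | None = None
    expected_residual_ml: float | None = None
    resectability_index: float | None = None
    cortical_overlap_pct: dict[str, float] = field(default_factory=dict)
    subcortical_overlap_pct: dict[str, float] = field(default_factory=dict)
    subcortical_distance_mm: dict[str, float] = field(default_factory=dict)

    SCALAR_NAMES = (
        "volume.patient_space_ml",
        "volume.mni_space_ml",
        "laterality.left_pct",
        "laterality.right_pct",
        "laterality.midline_crossing",
        "multifocality.multifocal",
        "multifocality.focus_count",
        "multifocality.largest_satellite_distance_mm",
        "resectability.expected_residual_ml",
        "resectability.resectability_index",
    )

    def to_dict(self) -> dict[str, object]:
        """All 233 named feature values in stable registry order."""
        out: dict[str, object] = dict(zip(self.SCALAR_NAMES, (
            self.volume_patient_ml, self.volume_mni_ml,
            self.left_pct, self.right_pct, self.midline_crossing,
            self.multifocal, self.focus_count, self.satellite_distance_mm,
            self.expected_residual_ml, self.resectability_index)))
        out.update(self.cortical_overlap_pct)
        for name, v in self.subcortical_overlap_pct.items():
            out[f"subcortical_overlap.BCB.{name}"] = v
        for name, v in self.subcortical_distance_mm.items():
            out[f"subcortical_distance.BCB.{name}"] = v
        return out

    @property
    def feature_count(self) -> int:
        return len(self.to_dict())


def feature_names(bundle: AtlasBundle) -> list[str]:
    """The stable, namespaced ordering of the 233 feature names for a bundle."""
    names = list(TumorFeatureRecord.SCALAR_NAMES)
    for atlas_id, atlas in bundle.cortical.items():
        names += [f"cortical.{atlas_id}.{atlas.names[k]}" for k in sorted(atlas.names)]
    names += [f"subcortical_overlap.BCB.{n}" for n in bundle.subcortical.names]
    names += [f"subcortical_distance.BCB.{n}" for n in bundle.subcortical.names]
    return names


def assemble_feature_record(patient_mask: BinaryMask, mni_mask: BinaryMask,
                            bundle: AtlasBundle, patient_id: str = "case",
                            refine: bool = True) -> TumorFeatureRecord:
    """Run the full feature computation for one case.

    ``mni_mask`` must live in the bundle geometry; ``patient_mask`` may be in
    native patient geometry and only contributes the patient-space volume.
    With ``refine=True`` both masks are refined first (closing + 0.1 mL
    component filter).
    """
    if not mni_mask.geometry.close_to(bundle.geometry):
        raise ValueError("reference-space mask must share the bundle geometry")
    if refine:
        patient_mask = refine_tumor_mask(patient_mask)
        mni_mask = refine_tumor_mask(mni_mask)
    if mni_mask.is_empty:
        return TumorFeatureRecord(patient_id, has_tumor=False)

    left_pct, right_pct, crossing = compute_laterality(mni_mask, bundle.hemisphere)
    multifocal, count, sat_dist = compute_multifocality(mni_mask)
    residual, index = compute_resectability(mni_mask, bundle.heatmap,
                                            left_pct, right_pct)
    cortical = cortical_profile(mni_mask, bundle.cortical)
    sub_overlap, sub_dist = subcortical_profile(mni_mask, bundle.subcortical)

    return TumorFeatureRecord(
        patient_id=patient_id,
        has_tumor=True,
        volume_patient_ml=compute_volume(patient_mask),
        volume_mni_ml=compute_volume(mni_mask),
        left_pct=left_pct,
        right_pct=right_pct,
        midline_crossing=crossing,
        multifocal=multifocal,
        focus_count=count,
        satellite_distance_mm=sat_dist,
        expected_residual_ml=residual,
        resectability_index=index,
        cortical_overlap_pct=cortical,
        subcortical_overlap_pct=sub_overlap,
        subcortical_distance_mm=sub_dist,
    )
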