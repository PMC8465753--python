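"""Seeded synthetic phantoms and atlas bundles for offline testing.

The generator builds, from a seed alone, everything the feature pipeline
consumes: an atlas bundle in a small reference lattice (hemisphere mask
split at the world mid-plane, four disjoint box parcellations with the
required 15/48/7/17 structure counts, a 68-structure probabilistic
subcortical atlas with radially decaying profiles, per-hemisphere radial
resection heat maps) and spherical tumor phantoms with a matching truth
table. The truth is recorded from the voxelized lattice, not from the
analytic ideal, so recovery tests can be exact.

Rater variants perturb only the one-voxel boundary shell of the phantom,
giving majority voting a meaningful gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .atlas import (
    CORTICAL_ATLAS_COUNTS,
    AtlasBundle,
    HemisphereMask,
    ParcellationAtlas,
    ProbabilisticAtlas,
    ResectionHeatmap,
    save_bundle,
)
from .features import SATELLITE_MIN_DISTANCE_MM, UNIFOCAL_SENTINEL_MM
from .volumes import BinaryMask, ProbabilityMap, VolumeGeometry, save_volume

#: Number of bilateral subcortical base names (each yields a left and a right
#: structure) and of midline singletons: 28 * 2 + 12 = 68 structures, 40 base.
_BILATERAL_TRACTS = 28
_MIDLINE_TRACTS = 12


def default_geometry(shape: tuple[int, int, int] = (48, 48, 48),
                     spacing: float = 1.0) -> VolumeGeometry:
    """A reference lattice centred on the world origin (midline at x = 0)."""
    origin = tuple(-(s - 1) / 2.0 * spacing for s in shape)
    return VolumeGeometry.isotropic(shape, spacing, origin)


def _grid_boxes(shape: tuple[int, int, int], count: int) -> np.ndarray:
    """Partition the lattice into >= count disjoint boxes; label the first
    ``count`` of them 1..count, leave the rest background."""
    nx = int(np.ceil(np.sqrt(count)))
    ny = int(np.ceil(count / nx))
    if shape[0] < nx or shape[1] < ny:
        raise ValueError(f"geometry too small to host {count} structures")
    labels = np.zeros(shape, dtype=np.int32)
    x_edges = np.linspace(0, shape[0], nx + 1).astype(int)
    y_edges = np.linspace(0, shape[1], ny + 1).astype(int)
    label = 0
    for i in range(nx):
        for j in range(ny):
            label += 1
            if label > count:
                return labels
            labels[x_edges[i]:x_edges[i + 1], y_edges[j]:y_edges[j + 1], :] = label
    return labels


def generate_bundle(geometry: VolumeGeometry | None = None,
                    seed: int = 0) -> AtlasBundle:
    """Generate a complete synthetic atlas bundle; pure function of the seed."""
    if geometry is None:
        geometry = default_geometry()
    rng = np.random.default_rng(seed)
    wx, wy, wz = geometry.world_coordinates()

    # hemisphere split at the world mid-plane; the midline goes to the left
    hemisphere = HemisphereMask(geometry, wx <= 0)

    cortical: dict[str, ParcellationAtlas] = {}
    for atlas_id, count in CORTICAL_ATLAS_COUNTS.items():
        labels = _grid_boxes(geometry.shape, count)
        names = {k: f"{atlas_id.lower()}_region_{k:02d}" for k in range(1, count + 1)}
        cortical[atlas_id] = ParcellationAtlas(geometry, labels, names, atlas_id)

    # subcortical structures: radially decaying probability around a seeded
    # centre; bilateral tracts are mirrored through the mid-plane
    extent = np.array([wx.max(), wy.max(), wz.max()])
    structures: dict[str, np.ndarray] = {}

    def _profile(centre: np.ndarray, radius: float) -> np.ndarray:
        d = np.sqrt((wx - centre[0]) ** 2 + (wy - centre[1]) ** 2
                    + (wz - centre[2]) ** 2)
        return np.clip(1.0 - d / radius, 0.0, 1.0)

    for i in range(1, _BILATERAL_TRACTS + 1):
        radius = rng.uniform(5.0, 9.0)
        centre = np.array([
            rng.uniform(-0.8 * extent[0], -0.2 * extent[0]),
            rng.uniform(-0.6 * extent[1], 0.6 * extent[1]),
            rng.uniform(-0.6 * extent[2], 0.6 * extent[2]),
        ])
        structures[f"Left_tract_{i:02d}"] = _profile(centre, radius)
        structures[f"Right_tract_{i:02d}"] = _profile(centre * [-1, 1, 1], radius)
    for i in range(_BILATERAL_TRACTS + 1, _BILATERAL_TRACTS + _MIDLINE_TRACTS + 1):
        radius = rng.uniform(5.0, 9.0)
        centre = np.array([
            0.0,
            rng.uniform(-0.6 * extent[1], 0.6 * extent[1]),
            rng.uniform(-0.6 * extent[2], 0.6 * extent[2]),
        ])
        structures[f"tract_{i:02d}"] = _profile(centre, radius)
    subcortical = ProbabilisticAtlas(geometry, structures, threshold=0.5)

    # per-hemisphere heat maps: resection probability decays radially from
    # the hemisphere centroid and vanishes at the far corner of the lattice
    span = float(np.linalg.norm(2 * extent))

    def _heat(side: np.ndarray) -> np.ndarray:
        cx = np.array([wx[side].mean(), wy[side].mean(), wz[side].mean()])
        d = np.sqrt((wx - cx[0]) ** 2 + (wy - cx[1]) ** 2 + (wz - cx[2]) ** 2)
        return np.clip(1.0 - d / span, 0.0, 1.0)

    heatmap = ResectionHeatmap(geometry, _heat(hemisphere.left),
                               _heat(hemisphere.right))
    return AtlasBundle(geometry, hemisphere, cortical, subcortical, heatmap)


@dataclass(frozen=True)
class Focus:
    """A spherical tumor focus: world-mm centre and radius."""

    centre_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("focus radius must be positive")

    @property
    def hemisphere(self) -> str:
        return "left" if self.centre_mm[0] <= 0 else "right"

    def analytic_volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm ** 3 / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic tumor case."""

    geometry: VolumeGeometry
    foci: tuple[Focus, ...]
    rater_noise: float = 0.0   # boundary-shell toggle probability in [0, 1]
    n_raters: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.foci:
            raise ValueError("at least one focus is required")
        if not 0.0 <= self.rater_noise <= 1.0:
            raise ValueError("rater_noise must lie in [0, 1]")


@dataclass
class PhantomTruth:
    """Ground-truth table for a phantom, recorded from the voxelized lattice."""

    focus_voxel_counts: list[int]
    focus_volumes_ml: list[float]
    analytic_volumes_ml: list[float]
    left_pct: float
    right_pct: float
    midline_crossing: bool
    multifocal: bool
    focus_count: int
    satellite_distance_mm: float
    pairwise_min_distances_mm: dict[tuple[int, int], float]
    cortical_overlap_pct: dict[str, float] = field(repr=False, default_factory=dict)
    subcortical_overlap_pct: dict[str, float] = field(repr=False, default_factory=dict)
    expected_resectable_ml: float = 0.0
    expected_residual_ml: float = 0.0
    expected_resectability_index: float = 0.0

    def total_volume_ml(self) -> float:
        return float(sum(self.focus_volumes_ml))


def _component_min_distances(labels: np.ndarray, geometry: VolumeGeometry
                             ) -> dict[tuple[int, int], float]:
    """Exact pairwise minimum voxel-centre distances between labelled components."""
    k = int(labels.max())
    coords = {}
    for lab in range(1, k + 1):
        idx = np.argwhere(labels == lab)
        coords[lab] = geometry.voxel_to_world(idx)
    out: dict[tuple[int, int], float] = {}
    for a in range(1, k + 1):
        tree = cKDTree(coords[a])
        for b in range(a + 1, k + 1):
            d, _ = tree.query(coords[b], k=1)
            out[(a, b)] = float(d.min())
    return out


def generate_phantom(spec: PhantomSpec, bundle: AtlasBundle
                     ) -> tuple[BinaryMask, ProbabilityMap, list[BinaryMask], PhantomTruth]:
    """Voxelize the phantom, derive its soft map and rater variants, and
    record the truth table by direct counting on the generated lattice."""
    geometry = spec.geometry
    if not geometry.close_to(bundle.geometry):
        raise ValueError("phantom geometry must match the bundle geometry")
    wx, wy, wz = geometry.world_coordinates()
    bounds_lo = np.array([wx.min(), wy.min(), wz.min()])
    bounds_hi = np.array([wx.max(), wy.max(), wz.max()])

    data = np.zeros(geometry.shape, dtype=bool)
    for focus in spec.foci:
        c = np.asarray(focus.centre_mm, float)
        if np.any(c - focus.radius_mm < bounds_lo) or np.any(c + focus.radius_mm > bounds_hi):
            raise ValueError(f"focus at {focus.centre_mm} exceeds the lattice bounds")
        d2 = (wx - c[0]) ** 2 + (wy - c[1]) ** 2 + (wz - c[2]) ** 2
        data |= d2 <= focus.radius_mm ** 2
    mask = BinaryMask(geometry, data)

    # soft map: Gaussian-blurred mask rescaled to peak 1 (sigma 1.5 voxels)
    blurred = ndimage.gaussian_filter(data.astype(np.float64), sigma=1.5)
    if blurred.max() > 0:
        blurred = blurred / blurred.max()
    prob = ProbabilityMap(geometry, np.clip(blurred, 0.0, 1.0))

    # rater variants: toggle voxels of the one-voxel boundary shells
    struct = ndimage.generate_binary_structure(3, 1)
    shell_out = ndimage.binary_dilation(data, struct) & ~data
    shell_in = data & ~ndimage.binary_erosion(data, struct, border_value=0)
    raters: list[BinaryMask] = []
    for r in range(spec.n_raters):
        rng = np.random.default_rng([spec.seed, r])
        variant = data.copy()
        if spec.rater_noise > 0:
            add = shell_out & (rng.random(geometry.shape) < spec.rater_noise)
            remove = shell_in & (rng.random(geometry.shape) < spec.rater_noise)
            variant |= add
            variant &= ~remove
        raters.append(BinaryMask(geometry, variant))

    truth = _record_truth(spec, mask, bundle)
    return mask, prob, raters, truth


def _record_truth(spec: PhantomSpec, mask: BinaryMask,
                  bundle: AtlasBundle) -> PhantomTruth:
    geometry = spec.geometry
    data = mask.data
    voxel_ml = geometry.voxel_volume_mm3 / 1000.0

    labels, k = ndimage.label(data, ndimage.generate_binary_structure(3, 3))
    counts = [int((labels == lab).sum()) for lab in range(1, k + 1)]
    volumes = [c * voxel_ml for c in counts]
    analytic = [f.analytic_volume_ml() for f in spec.foci]

    total = int(data.sum())
    left = int((data & bundle.hemisphere.left).sum())
    left_pct = 100.0 * left / total
    right_pct = 100.0 - left_pct

    distances = _component_min_distances(labels, geometry)
    biggest = int(np.argmax(counts)) + 1
    sat = {lab: distances[tuple(sorted((biggest, lab)))]
           for lab in range(1, k + 1) if lab != biggest}
    qualifying = {lab: d for lab, d in sat.items() if d >= SATELLITE_MIN_DISTANCE_MM}
    focus_count = 1 + len(qualifying)
    sat_dist = max(qualifying.values()) if qualifying else UNIFOCAL_SENTINEL_MM

    cortical = {}
    for atlas_id, atlas in bundle.cortical.items():
        for lab in sorted(atlas.names):
            inter = int((data & (atlas.labels == lab)).sum())
            cortical[f"cortical.{atlas_id}.{atlas.names[lab]}"] = 100.0 * inter / total
    subcortical = {}
    for name, lattice in bundle.subcortical.structures.items():
        inter = int((data & (lattice >= bundle.subcortical.threshold)).sum())
        subcortical[name] = 100.0 * inter / total

    heat = bundle.heatmap.left_map if left_pct >= right_pct else bundle.heatmap.right_map
    resectable = float(heat[data].sum()) * voxel_ml
    tumor_ml = total * voxel_ml

    return PhantomTruth(
        focus_voxel_counts=counts,
        focus_volumes_ml=volumes,
        analytic_volumes_ml=analytic,
        left_pct=left_pct,
        right_pct=right_pct,
        midline_crossing=0 < left < total,
        multifocal=focus_count > 1,
        focus_count=focus_count,
        satellite_distance_mm=float(sat_dist),
        pairwise_min_distances_mm=distances,
        cortical_overlap_pct=cortical,
        subcortical_overlap_pct=subcortical,
        expected_resectable_ml=resectable,
        expected_residual_ml=tumor_ml - resectable,
        expected_resectability_index=resectable / tumor_ml,
    )


def random_phantom_spec(geometry: VolumeGeometry, seed: int,
                        rater_noise: float = 0.0,
                        multifocal_probability: float = 0.5) -> PhantomSpec:
    """Draw a plausible phantom: one main focus, sometimes a distant satellite."""
    rng = np.random.default_rng(seed)
    extent = (np.array(geometry.shape) - 1) * geometry.spacing / 2.0
    main_r = rng.uniform(5.0, 0.35 * extent.min())
    margin = main_r + 2.0
    main_c = rng.uniform(-extent + margin, extent - margin)
    foci = [Focus(tuple(main_c), float(main_r))]
    if rng.random() < multifocal_probability:
        # satellite radius >= 3 mm keeps its volume above the 0.1 mL
        # refinement floor (4/3 pi 27 mm^3 ~ 0.11 mL)
        for _ in range(50):
            sat_r = rng.uniform(3.0, 4.5)
            sat_c = rng.uniform(-extent + sat_r + 1, extent - sat_r - 1)
            gap = np.linalg.norm(sat_c - main_c) - main_r - sat_r
            if gap > SATELLITE_MIN_DISTANCE_MM + 2.0:
                foci.append(Focus(tuple(sat_c), float(sat_r)))
                break
    return PhantomSpec(geometry, tuple(foci), rater_noise=rater_noise, seed=seed)


def write_case_directory(directory: str | Path, spec: PhantomSpec,
                         bundle: AtlasBundle) -> Path:
    """Write a ready-to-use case: bundle, masks, soft map, raters, truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_bundle(bundle, directory / "bundle")
    mask, prob, raters, truth = generate_phantom(spec, bundle)
    save_volume(mask, directory / "tumor_mask.nii.gz")
    save_volume(prob, directory / "tumor_probability.nii.gz")
    for i, r in enumerate(raters):
        save_volume(r, directory / f"rater_{i:02d}.nii.gz")
    rows = {
        "total_volume_ml": truth.total_volume_ml(),
        "left_pct": truth.left_pct,
        "right_pct": truth.right_pct,
        "midline_crossing": int(truth.midline_crossing),
        "multifocal": int(truth.multifocal),
        "focus_count": truth.focus_count,
        "satellite_distance_mm": truth.satellite_distance_mm,
        "expected_resectable_ml": truth.expected_resectable_ml,
        "expected_resectability_index": truth.expected_resectability_index,
    }
    pd.DataFrame([rows]).to_csv(directory / "truth.csv", index=False)
    return directory
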