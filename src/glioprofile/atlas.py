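"""Reference-space atlas bundle: data model, validation and loaders.

The bundle groups everything feature computation needs in one geometry:
a hemisphere laterality mask, four cortical parcellations (15 + 48 + 7 + 17
structures, 87 parameters in total), a probabilistic subcortical atlas of
68 structures (40 base names once left/right designations are stripped),
and per-hemisphere resection-probability heat maps.

On disk a bundle is a directory with one NIfTI per volume, two-column
plain-text name tables, and a ``manifest.txt`` of ``key = filename`` lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import BinaryMask, GeometryMismatchError, VolumeGeometry

#: Expected structure counts for the supported cortical parcellations.
CORTICAL_ATLAS_COUNTS = {
    "MNI-structural": 15,
    "Harvard-Oxford": 48,
    "Schaefer7": 7,
    "Schaefer17": 17,
}
CORTICAL_ATLAS_IDS = tuple(CORTICAL_ATLAS_COUNTS)

SUBCORTICAL_STRUCTURE_COUNT = 68
SUBCORTICAL_BASE_NAME_COUNT = 40

_SIDE_RE = re.compile(r"(^(left|right)[_\- ])|([_\- ](left|right)$)", re.IGNORECASE)


def strip_laterality(name: str) -> str:
    """Remove a leading/trailing left/right designation from a structure name."""
    return _SIDE_RE.sub("", name)


@dataclass
class ParcellationAtlas:
    """A labelled cortical parcellation with a label -> structure-name table."""

    geometry: VolumeGeometry
    labels: np.ndarray
    names: dict[int, str]
    atlas_id: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.geometry.shape:
            raise ValueError("label lattice shape must equal geometry.shape")
        if self.atlas_id not in CORTICAL_ATLAS_COUNTS:
            raise ValueError(f"unknown atlas_id {self.atlas_id!r}")
        expected = CORTICAL_ATLAS_COUNTS[self.atlas_id]
        if len(self.names) != expected:
            raise ValueError(
                f"{self.atlas_id} must define {expected} structures, "
                f"got {len(self.names)}")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names in {self.atlas_id}: {sorted(missing)}")

    @property
    def structure_count(self) -> int:
        return len(self.names)


@dataclass
class ProbabilisticAtlas:
    """Probabilistic subcortical atlas: named probability lattices in [0, 1]."""

    geometry: VolumeGeometry
    structures: dict[str, np.ndarray]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.structures) != SUBCORTICAL_STRUCTURE_COUNT:
            raise ValueError(
                f"subcortical atlas must have {SUBCORTICAL_STRUCTURE_COUNT} "
                f"structures, got {len(self.structures)}")
        for name, lattice in self.structures.items():
            lattice = np.asarray(lattice, dtype=np.float64)
            if lattice.shape != self.geometry.shape:
                raise ValueError(f"structure {name!r} shape mismatch")
            if lattice.min() < 0.0 or lattice.max() > 1.0:
                raise ValueError(f"structure {name!r} probabilities outside [0, 1]")
            self.structures[name] = lattice
        base = {strip_laterality(n) for n in self.structures}
        if len(base) != SUBCORTICAL_BASE_NAME_COUNT:
            raise ValueError(
                f"subcortical names must reduce to {SUBCORTICAL_BASE_NAME_COUNT} "
                f"base names, got {len(base)}")

    @property
    def names(self) -> list[str]:
        return list(self.structures)

    def base_names(self) -> set[str]:
        return {strip_laterality(n) for n in self.structures}

    def structure_mask(self, name: str) -> BinaryMask:
        """Threshold one structure at ``threshold`` (inclusive: p >= t is inside)."""
        if name not in self.structures:
            raise KeyError(f"unknown subcortical structure {name!r}")
        return BinaryMask(self.geometry, self.structures[name] >= self.threshold)


def threshold_probabilistic(atlas: ProbabilisticAtlas, structure: str) -> BinaryMask:
    return atlas.structure_mask(structure)


@dataclass
class HemisphereMask:
    """Per-voxel left/right assignment: a total partition of the lattice."""

    geometry: VolumeGeometry
    left: np.ndarray  # boolean; right is the complement

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left).astype(bool)
        if self.left.shape != self.geometry.shape:
            raise ValueError("hemisphere lattice shape must equal geometry.shape")

    @property
    def right(self) -> np.ndarray:
        return ~self.left


@dataclass
class ResectionHeatmap:
    """Per-hemisphere resection-probability lattices in [0, 1]."""

    geometry: VolumeGeometry
    left_map: np.ndarray
    right_map: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("left_map", "right_map"):
            lattice = np.asarray(getattr(self, attr), dtype=np.float64)
            if lattice.shape != self.geometry.shape:
                raise ValueError(f"{attr} shape mismatch")
            if lattice.min() < 0.0 or lattice.max() > 1.0:
                raise ValueError(f"{attr} values outside [0, 1]")
            setattr(self, attr, lattice)


@dataclass
class AtlasBundle:
    """All reference-space atlas volumes of one bundle, in a shared geometry."""

    geometry: VolumeGeometry
    hemisphere: HemisphereMask
    cortical: dict[str, ParcellationAtlas] = field(repr=False)
    subcortical: ProbabilisticAtlas = field(repr=False)
    heatmap: ResectionHeatmap = field(repr=False)

    def __post_init__(self) -> None:
        members = [self.hemisphere, self.subcortical, self.heatmap,
                   *self.cortical.values()]
        for m in members:
            if not m.geometry.close_to(self.geometry):
                raise GeometryMismatchError("bundle members do not share a geometry")
        if tuple(self.cortical) != CORTICAL_ATLAS_IDS:
            raise ValueError(f"cortical atlases must be {CORTICAL_ATLAS_IDS}")

    @property
    def cortical_parameter_count(self) -> int:
        return sum(a.structure_count for a in self.cortical.values())


# --------------------------------------------------------------------------
# Directory layout

def _load_lattice(path: Path, geometry: VolumeGeometry | None):
    if not path.exists():
        raise FileNotFoundError(f"bundle member missing: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    geo = VolumeGeometry(data.shape[:3], np.asarray(img.affine, dtype=float))
    if geometry is not None and not geo.close_to(geometry):
        raise GeometryMismatchError(f"{path.name} geometry differs from bundle geometry")
    return data, geo


def _read_name_table(path: Path) -> dict[str, str]:
    if not path.exists():
        raise FileNotFoundError(f"name table missing: {path}")
    table: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, name = line.partition("\t")
        table[key.strip()] = name.strip()
    return table


def _read_manifest(directory: Path) -> dict[str, str]:
    path = directory / "manifest.txt"
    if not path.exists():
        raise FileNotFoundError(f"bundle manifest missing: {path}")
    manifest: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        manifest[key.strip()] = value.strip()
    return manifest


def load_bundle(directory: str | Path) -> AtlasBundle:
    """Load and validate an atlas bundle directory.

    The manifest names each member file; geometry consistency and the
    per-atlas structure counts are enforced at load time.
    """
    directory = Path(directory)
    manifest = _read_manifest(directory)

    hemi_data, geometry = _load_lattice(directory / manifest["hemisphere"], None)
    hemisphere = HemisphereMask(geometry, hemi_data > 0)

    cortical: dict[str, ParcellationAtlas] = {}
    for atlas_id in CORTICAL_ATLAS_IDS:
        key = atlas_id.lower().replace("-", "_")
        labels, _ = _load_lattice(directory / manifest[f"cortical_{key}"], geometry)
        table = _read_name_table(directory / manifest[f"cortical_{key}_names"])
        names = {int(k): v for k, v in table.items()}
        cortical[atlas_id] = ParcellationAtlas(geometry, labels.astype(np.int32),
                                               names, atlas_id)

    sub_data, _ = _load_lattice(directory / manifest["subcortical"], geometry)
    if sub_data.ndim != 4:
        raise ValueError("subcortical atlas must be a 4D NIfTI (one volume per structure)")
    sub_names_table = _read_name_table(directory / manifest["subcortical_names"])
    ordered = [sub_names_table[str(i)] for i in range(sub_data.shape[3])]
    structures = {name: sub_data[..., i] for i, name in enumerate(ordered)}
    threshold = float(manifest.get("subcortical_threshold", "0.5"))
    subcortical = ProbabilisticAtlas(geometry, structures, threshold)

    left_map, _ = _load_lattice(directory / manifest["heatmap_left"], geometry)
    right_map, _ = _load_lattice(directory / manifest["heatmap_right"], geometry)
    heatmap = ResectionHeatmap(geometry, left_map, right_map)

    return AtlasBundle(geometry, hemisphere, cortical, subcortical, heatmap)


def save_bundle(bundle: AtlasBundle, directory: str | Path) -> None:
    """Write a bundle to the documented directory layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = bundle.geometry.affine
    manifest: dict[str, str] = {}

    def _write(name: str, data: np.ndarray) -> str:
        fname = f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(data, aff), str(directory / fname))
        return fname

    manifest["hemisphere"] = _write("hemisphere", bundle.hemisphere.left.astype(np.uint8))
    for atlas_id, atlas in bundle.cortical.items():
        key = atlas_id.lower().replace("-", "_")
        manifest[f"cortical_{key}"] = _write(f"cortical_{key}", atlas.labels.astype(np.int16))
        names_file = f"cortical_{key}_names.txt"
        (directory / names_file).write_text(
            "".join(f"{k}\t{v}\n" for k, v in sorted(atlas.names.items())))
        manifest[f"cortical_{key}_names"] = names_file

    stack = np.stack([bundle.subcortical.structures[n] for n in bundle.subcortical.names],
                     axis=3).astype(np.float32)
    manifest["subcortical"] = _write("subcortical", stack)
    (directory / "subcortical_names.txt").write_text(
        "".join(f"{i}\t{n}\n" for i, n in enumerate(bundle.subcortical.names)))
    manifest["subcortical_names"] = "subcortical_names.txt"
    manifest["subcortical_threshold"] = str(bundle.subcortical.threshold)

    manifest["heatmap_left"] = _write("heatmap_left", bundle.heatmap.left_map.astype(np.float32))
    manifest["heatmap_right"] = _write("heatmap_right", bundle.heatmap.right_map.astype(np.float32))

    (directory / "manifest.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in manifest.items()))
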