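"""Readers, writers and validation for feature bags, manifests and mask grids.

A *feature bag* is the per-slide unit of the MIL pipeline: an ``N x d``
matrix of patch embeddings plus the patch-grid coordinate of each patch.
Bags are stored one HDF5 file per slide (datasets ``features`` float32 and
``coords`` int32, ids and label as attributes), the way patch encoders in
computational pathology usually emit them.  Cohort manifests are plain CSV;
biomarker mask grids are single-channel PNGs with pixel (r, c) mapped to
grid cell (r, c) and any nonzero value meaning marker-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, ValidationError

SCHEMA_VERSION = 1

MANIFEST_COLUMNS = ["patient_id", "slide_id", "label", "cohort_tag", "bag_path"]


@dataclass
class FeatureBag:
    """One slide: patch embeddings, grid coordinates, and the slide label.

    ``features[k]`` is the d-dimensional embedding h_k of patch k;
    ``coords[k]`` is its 0-based (row, col) position on the patch grid.
    ``label`` is 1 for pCR, 0 for non-pCR, or None when unlabeled.
    """

    patient_id: str
    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int32)

    @property
    def n_patches(self) -> int:
        return int(self.features.shape[0])

    @property
    def dim(self) -> int:
        return int(self.features.shape[1])

    def validate(self) -> None:
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D (N x d) array")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an N x 2 array")
        if self.features.shape[0] != self.coords.shape[0]:
            raise FormatError(
                f"features has {self.features.shape[0]} rows but coords has "
                f"{self.coords.shape[0]} rows"
            )
        if self.n_patches < 1:
            raise ValidationError("bag must contain at least one patch")
        if self.dim < 1:
            raise ValidationError("feature dimension must be >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("features contain non-finite values")
        if len(np.unique(self.coords, axis=0)) != self.n_patches:
            raise ValidationError("coords must be unique within a bag")


def write_bag(bag: FeatureBag, path: str | Path) -> Path:
    """Write a bag to one HDF5 file; returns the path written."""
    bag.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int32))
        f.attrs["patient_id"] = bag.patient_id
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["label"] = -1 if bag.label is None else int(bag.label)
        f.attrs["schema_version"] = SCHEMA_VERSION
    return path


def read_bag(path: str | Path) -> FeatureBag:
    """Read a bag written by :func:`write_bag`; lossless for float32/int32."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise FormatError(
                f"unknown bag schema version {version!r} in {path} "
                f"(expected {SCHEMA_VERSION})"
            )
        features = f["features"][()]
        coords = f["coords"][()]
        label = int(f.attrs["label"])
        bag = FeatureBag(
            patient_id=str(f.attrs["patient_id"]),
            slide_id=str(f.attrs["slide_id"]),
            features=features,
            coords=coords,
            label=None if label < 0 else label,
        )
    if bag.features.shape[0] != bag.coords.shape[0]:
        raise FormatError(
            f"corrupt bag {path}: features has {bag.features.shape[0]} rows "
            f"but coords has {bag.coords.shape[0]} rows"
        )
    bag.validate()
    return bag


@dataclass
class CohortManifest:
    """Cohort table: one row per slide with patient id, label and bag path."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return [str(p) for p in self.table["patient_id"]]

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping]) -> "CohortManifest":
        return cls(pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS))


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.table.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    return CohortManifest(pd.read_csv(path, dtype={"patient_id": str, "slide_id": str}))


@dataclass
class BiomarkerMaskSet:
    """Per-slide binary marker grids (e.g. PD-L1, CD8, CD163) on the patch grid."""

    slide_id: str
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = {m: np.asarray(g).astype(bool) for m, g in self.masks.items()}
        shapes = {g.shape for g in self.masks.values()}
        if len(shapes) > 1:
            raise ValidationError(f"markers of slide {self.slide_id} disagree on grid shape: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, int] | None:
        for g in self.masks.values():
            return g.shape
        return None

    @property
    def markers(self) -> list[str]:
        return sorted(self.masks)


def write_mask_set(mask_set: BiomarkerMaskSet, mask_dir: str | Path) -> list[Path]:
    """One PNG per marker: ``<slide_id>__<marker>.png``, 255 = positive."""
    mask_dir = Path(mask_dir)
    mask_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for marker, grid in sorted(mask_set.masks.items()):
        img = Image.fromarray((grid.astype(np.uint8) * 255))
        p = mask_dir / f"{mask_set.slide_id}__{marker}.png"
        img.save(p)
        paths.append(p)
    return paths


def read_mask_set(mask_dir: str | Path, slide_id: str, markers: Sequence[str]) -> BiomarkerMaskSet:
    mask_dir = Path(mask_dir)
    masks = {}
    for marker in markers:
        p = mask_dir / f"{slide_id}__{marker}.png"
        if not p.exists():
            raise FormatError(f"missing mask file {p}")
        masks[marker] = np.asarray(Image.open(p)) > 0
    return BiomarkerMaskSet(slide_id=slide_id, masks=masks)


def project_mask_to_grid(pixel_mask: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Down-project a pixel-resolution mask to the patch grid.

    A grid cell is marker-positive if any pixel inside it is positive
    (any-positive pooling).  Pixel blocks are the equal integer tiling of
    the mask by the grid shape.
    """
    pixel_mask = np.asarray(pixel_mask).astype(bool)
    rows, cols = grid_shape
    h, w = pixel_mask.shape
    if h % rows or w % cols:
        raise ValidationError(
            f"pixel mask shape {pixel_mask.shape} is not an integer multiple of grid {grid_shape}"
        )
    blocks = pixel_mask.reshape(rows, h // rows, cols, w // cols)
    return blocks.any(axis=(1, 3))


@dataclass
class Violation:
    kind: str
    message: str


@dataclass
class ValidationReport:
    ok: bool
    violations: list[Violation]

    def kinds(self) -> list[str]:
        return [v.kind for v in self.violations]


def validate_cohort(manifest: CohortManifest, base_dir: str | Path | None = None) -> ValidationReport:
    """Check a manifest for duplicate patients, bad labels, missing or
    inconsistent bag files.  Violations are reported, never raised."""
    violations: list[Violation] = []
    seen: set[str] = set()
    dims: dict[str, int] = {}
    base = Path(base_dir) if base_dir is not None else None
    for _, row in manifest.table.iterrows():
        pid = str(row["patient_id"])
        if pid in seen:
            violations.append(Violation("duplicate_patient", f"patient_id {pid} appears more than once"))
        seen.add(pid)
        if row["label"] not in (0, 1):
            violations.append(Violation("bad_label", f"patient {pid}: label {row['label']!r} not in {{0, 1}}"))
        bag_path = Path(str(row["bag_path"]))
        if base is not None and not bag_path.is_absolute():
            bag_path = base / bag_path
        if not bag_path.exists():
            violations.append(Violation("missing_file", f"patient {pid}: bag file {bag_path} not found"))
            continue
        try:
            bag = read_bag(bag_path)
        except (FormatError, ValidationError, OSError) as exc:
            violations.append(Violation("bag_error", f"patient {pid}: {exc}"))
            continue
        dims[pid] = bag.dim
    if len(set(dims.values())) > 1:
        violations.append(
            Violation("inconsistent_dim", f"feature dimensions differ across cohort: {sorted(set(dims.values()))}")
        )
    return ValidationReport(ok=not violations, violations=violations)
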