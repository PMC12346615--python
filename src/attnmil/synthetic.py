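"""Synthetic cohort generator for end-to-end testing of the MIL pipeline.

Real slide cohorts for chemotherapy-response prediction are rarely public,
so this module generates cohorts with the statistical structure the MIL
analysis assumes: each patient contributes one bag of patch feature
vectors; positive (pCR) bags contain a fraction of *witness* patches whose
features are drawn from a mean-shifted Gaussian; biomarker mask grids are
spatially co-localized with the witness patches.  The feature model is an
isotropic Gaussian with a mean shift on a configurable leading subset of
dimensions — the simplest structure under which attention localization is
testable.

Ground-truth witness flags are carried separately from the bags (and
written to a separate file) so the classifier path can never consume them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import (
    BiomarkerMaskSet,
    CohortManifest,
    FeatureBag,
    write_bag,
    write_manifest,
    write_mask_set,
)

DEFAULT_MARKERS = ("PD-L1", "CD8", "CD163")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated cohort.

    Defaults mirror the cohort the model targets: 174 patients with a
    roughly 81:93 pCR/non-pCR split, 1536-dimensional patch embeddings,
    and 50-2000 patches per biopsy slide.  ``signal_shift`` is the
    per-dimension mean offset of witness-patch features, applied to the
    first ``min(signal_dims, d)`` dimensions; ``noise_sd`` is the isotropic
    feature standard deviation, so ``signal_shift / noise_sd`` is the
    per-dimension effect size.
    """

    n_patients: int = 174
    prevalence: float = 81 / 174
    d: int = 1536
    bag_size_range: tuple[int, int] = (50, 2000)
    witness_rate: float = 0.3
    signal_shift: float = 2.0
    noise_sd: float = 1.0
    grid_shape: tuple[int, int] = (45, 45)
    mask_markers: tuple[str, ...] = DEFAULT_MARKERS
    mask_colocalization: float = 0.9
    background_positive_rate: float = 0.02
    signal_dims: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must lie in (0, 1)")
        if self.d < 1:
            raise ValidationError("d must be >= 1")
        lo, hi = self.bag_size_range
        if lo < 1 or lo > hi:
            raise ValidationError("bag_size_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.witness_rate <= 1.0:
            raise ValidationError("witness_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.grid_shape[0] * self.grid_shape[1] < hi:
            raise ValidationError(
                f"grid_shape {self.grid_shape} holds {self.grid_shape[0] * self.grid_shape[1]} "
                f"cells but bag_size_range allows up to {hi} patches"
            )
        if not 0.0 <= self.mask_colocalization <= 1.0:
            raise ValidationError("mask_colocalization must lie in [0, 1]")
        if not 0.0 <= self.background_positive_rate <= 0.05:
            raise ValidationError("background_positive_rate must lie in [0, 0.05]")


def demo_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The small study cohort used for tests and worked examples: 60
    patients, 16-dimensional features, 50-100 patches per bag, 30%
    witnesses with a strong (2 sd) mean shift."""
    base = SyntheticSpec(
        n_patients=60,
        prevalence=0.5,
        d=16,
        bag_size_range=(50, 100),
        witness_rate=0.3,
        signal_shift=2.0,
        noise_sd=1.0,
        grid_shape=(10, 10),
        signal_dims=16,
        seed=seed,
    )
    return replace(base, **overrides)


def sparse_witness_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Hotspot-like cohort: 5% witnesses with a 3 sd shift.  Used for
    attention-localization checks, where enrichment relative to the
    witness rate is only informative when witnesses are rare."""
    return demo_spec(seed=seed, witness_rate=0.05, signal_shift=3.0, **overrides)


@dataclass
class GeneratedCohort:
    """A generated cohort: manifest rows, one bag per patient, per-patient
    marker mask grids, and ground-truth witness flags (tests only)."""

    spec: SyntheticSpec
    manifest: list[tuple[str, int]]
    bags: list[FeatureBag]
    masks: dict[str, BiomarkerMaskSet]
    witness_flags: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.manifest], dtype=int)

    def bag_for(self, patient_id: str) -> FeatureBag:
        for bag in self.bags:
            if bag.patient_id == patient_id:
                return bag
        raise KeyError(patient_id)

    def save(self, out_dir: str | Path, cohort_tag: str = "synthetic") -> CohortManifest:
        """Write bags (HDF5), masks (PNG), manifest (CSV) and witness flags
        (separate JSON, never referenced by the manifest)."""
        out_dir = Path(out_dir)
        bag_dir = out_dir / "bags"
        mask_dir = out_dir / "masks"
        rows = []
        for (pid, label), bag in zip(self.manifest, self.bags):
            path = write_bag(bag, bag_dir / f"{bag.slide_id}.h5")
            rows.append(
                {
                    "patient_id": pid,
                    "slide_id": bag.slide_id,
                    "label": label,
                    "cohort_tag": cohort_tag,
                    "bag_path": str(path),
                }
            )
            write_mask_set(self.masks[pid], mask_dir)
        manifest = CohortManifest.from_rows(rows)
        write_manifest(manifest, out_dir / "manifest.csv")
        flags = {pid: [int(v) for v in f] for pid, f in self.witness_flags.items()}
        (out_dir / "witness_flags.json").write_text(json.dumps(flags, sort_keys=True))
        return manifest


def generate_cohort(spec: SyntheticSpec) -> GeneratedCohort:
    """Generate a cohort reproducibly from ``spec.seed``.

    Exactly ``round(n_patients * prevalence)`` patients are positive.  Each
    bag draws N ~ uniform over ``bag_size_range``; positive bags contain
    ``round(witness_rate * N)`` witness patches with features
    Normal(signal_shift, noise_sd) on the signal dimensions, all other
    patches Normal(0, noise_sd).  Patches occupy the first N grid cells in
    row-major order.  Each witness patch is marker-positive with
    probability ``mask_colocalization`` per marker; background patches
    with probability ``background_positive_rate``.

    Every patient draws from an independent child of the seed, so the
    cohort is invariant to manifest ordering.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    label_seq, *patient_seqs = root.spawn(spec.n_patients + 1)

    n_pos = int(round(spec.n_patients * spec.prevalence))
    label_rng = np.random.default_rng(label_seq)
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[label_rng.permutation(spec.n_patients)[:n_pos]] = 1

    n_signal = min(spec.signal_dims, spec.d)
    cols = spec.grid_shape[1]

    manifest: list[tuple[str, int]] = []
    bags: list[FeatureBag] = []
    masks: dict[str, BiomarkerMaskSet] = {}
    witness_flags: dict[str, np.ndarray] = {}

    width = max(3, len(str(spec.n_patients)))
    for i in range(spec.n_patients):
        pid = f"pt{i:0{width}d}"
        sid = f"{pid}_s1"
        label = int(labels[i])
        rng = np.random.default_rng(patient_seqs[i])

        n = int(rng.integers(spec.bag_size_range[0], spec.bag_size_range[1] + 1))
        flags = np.zeros(n, dtype=bool)
        if label == 1:
            n_wit = int(round(spec.witness_rate * n))
            flags[rng.choice(n, size=n_wit, replace=False)] = True

        features = rng.normal(0.0, spec.noise_sd, size=(n, spec.d))
        features[flags, :n_signal] += spec.signal_shift
        coords = np.column_stack([np.arange(n) // cols, np.arange(n) % cols])

        marker_grids = {}
        for marker in spec.mask_markers:
            p_positive = np.where(flags, spec.mask_colocalization, spec.background_positive_rate)
            patch_positive = rng.random(n) < p_positive
            grid = np.zeros(spec.grid_shape, dtype=bool)
            grid[coords[patch_positive, 0], coords[patch_positive, 1]] = True
            marker_grids[marker] = grid

        manifest.append((pid, label))
        bags.append(
            FeatureBag(patient_id=pid, slide_id=sid, features=features, coords=coords, label=label)
        )
        masks[pid] = BiomarkerMaskSet(slide_id=sid, masks=marker_grids)
        witness_flags[pid] = flags

    return GeneratedCohort(spec=spec, manifest=manifest, bags=bags, masks=masks, witness_flags=witness_flags)


def feature_jitter(bag: FeatureBag, magnitude: float, seed: int) -> FeatureBag:
    """Additive zero-mean Gaussian feature noise (sd = ``magnitude``).

    Feature-space stand-in for patch-level train-time augmentation;
    coordinates, label and ids are untouched.  ``magnitude=0`` returns an
    exact copy.
    """
    if magnitude < 0:
        raise ValidationError("jitter magnitude must be >= 0")
    features = bag.features.astype(np.float32, copy=True)
    if magnitude > 0:
        rng = np.random.default_rng(seed)
        features = features + rng.normal(0.0, magnitude, size=features.shape).astype(np.float32)
    return FeatureBag(
        patient_id=bag.patient_id,
        slide_id=bag.slide_id,
        features=features,
        coords=bag.coords.copy(),
        label=bag.label,
    )
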