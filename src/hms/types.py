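"""Core domain types: latent eye states, image samples, dataset bundles.

Label order for the multi-label parent task is fixed as
(NORM, AMD, DR, DME); AMD staging uses five AREDS-derived classes and DR
staging the four ICDR classes MILD_NPDR..PDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CLASS_NAMES = ("NORM", "AMD", "DR", "DME")
NORM, AMD, DR, DME = range(4)

AMD_STAGES = ("EARLY", "INTERMEDIATE", "ATROPHY", "NAMD", "FIBROSIS")
DR_STAGES = ("MILD_NPDR", "MODERATE_NPDR", "SEVERE_NPDR", "PDR")

OCT = "OCT"
FUNDUS = "FUNDUS"


@dataclass
class MultiLabelTarget:
    """Binary indicators ordered (NORM, AMD, DR, DME); NORM excludes the rest."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.shape != (4,):
            raise ValueError("multi-label target must have 4 entries")
        if self.y[NORM] == 1 and self.y[1:].any():
            raise ValueError("NORM=1 excludes AMD/DR/DME")


@dataclass
class LatentEyeState:
    """Ground-truth per-eye disease state; both modalities render from it."""

    eye_id: str
    has_amd: bool = False
    amd_stage: Optional[int] = None     # 0..4 iff has_amd
    has_dr: bool = False
    dr_stage: Optional[int] = None      # 0..3 iff has_dr
    has_dme: bool = False
    drusen_count: float = 0.0
    drusen_size: float = 0.0
    fluid_area: float = 0.0
    lesion_count: int = 0
    peripheral_only_dr: bool = False
    domain_id: str = "A"

    @property
    def norm(self) -> bool:
        return not (self.has_amd or self.has_dr or self.has_dme)

    def labels(self) -> MultiLabelTarget:
        y = np.zeros(4, dtype=np.int8)
        y[AMD] = self.has_amd
        y[DR] = self.has_dr
        y[DME] = self.has_dme
        y[NORM] = int(self.norm)
        return MultiLabelTarget(y)

    def __post_init__(self):
        if self.has_amd and self.amd_stage is None:
            raise ValueError("amd_stage required when has_amd")
        if not self.has_amd:
            self.amd_stage = None
        if self.has_dr and self.dr_stage is None:
            raise ValueError("dr_stage required when has_dr")
        if not self.has_dr:
            self.dr_stage = None
            self.peripheral_only_dr = False


@dataclass
class ImageSample:
    """One grayscale image with its labels and provenance tags."""

    pixels: np.ndarray           # H x W floats in [0, 1]
    modality: str                # OCT | FUNDUS
    labels: MultiLabelTarget
    eye_id: str
    domain_id: str = "A"
    stage: Optional[int] = None  # AMD stage for OCT, DR stage for FUNDUS
    paired: bool = False

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.modality not in (OCT, FUNDUS):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.pixels = px


@dataclass
class DatasetBundle:
    """Eye-disjoint train/val/test corpora per modality plus a paired hold-out.

    The paired hold-out is evaluation-only: its eyes never appear in any
    training split, mirroring a strictly unpaired training protocol.
    """

    oct_train: list = field(default_factory=list)
    oct_val: list = field(default_factory=list)
    oct_test: list = field(default_factory=list)
    fundus_train: list = field(default_factory=list)
    fundus_val: list = field(default_factory=list)
    fundus_test: list = field(default_factory=list)
    paired_holdout: list = field(default_factory=list)  # (oct, fundus) tuples
    folds: dict = field(default_factory=dict)           # eye_id -> fold index
    states: dict = field(default_factory=dict)          # eye_id -> LatentEyeState

    def splits(self) -> dict[str, list]:
        return {
            "oct_train": self.oct_train, "oct_val": self.oct_val,
            "oct_test": self.oct_test, "fundus_train": self.fundus_train,
            "fundus_val": self.fundus_val, "fundus_test": self.fundus_test,
        }

    def label_counts(self):
        """Per-split counts of each parent label (logged at build time)."""
        counts = {}
        for name, samples in self.splits().items():
            if samples:
                counts[name] = np.sum([s.labels.y for s in samples], axis=0)
            else:
                counts[name] = np.zeros(4, dtype=int)
        counts["paired_holdout"] = (
            np.sum([p[0].labels.y for p in self.paired_holdout], axis=0)
            if self.paired_holdout else np.zeros(4, dtype=int))
        return counts

    def check_disjoint(self):
        """Raise if any eye appears in more than one split or in the hold-out."""
        seen: dict[str, str] = {}
        for name, samples in self.splits().items():
            base = name.split("_")[1]
            for s in samples:
                prev = seen.get(s.eye_id)
                if prev is not None and prev != base:
                    raise ValueError(f"eye {s.eye_id} in both {prev} and {base}")
                seen[s.eye_id] = base
        for o, f in self.paired_holdout:
            for eid in (o.eye_id, f.eye_id):
                if eid in seen:
                    raise ValueError(f"paired eye {eid} leaks into {seen[eid]}")


def stack_pixels(samples: list[ImageSample], dtype=np.float32) -> np.ndarray:
    """(N, 1, H, W) batch array from a list of samples."""
    return np.stack([s.pixels for s in samples])[:, None, :, :].astype(dtype)


def stack_labels(samples: list[ImageSample]) -> np.ndarray:
    return np.stack([s.labels.y for s in samples]).astype(np.float64)
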