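"""Core in-memory containers shared across the pipeline.

Conventions (used everywhere in this package): arrays are row-major with the
origin at the top-left corner, indices are 0-based, crop windows are half-open
``[r0, r1) x [c0, c1)``, and dorsal is the top of the image.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Label codes for per-pixel categorical maps.
BACKGROUND = 0
MATRIX = 1
STRIOSOME = 2
FIBER_BUNDLE = 3
VESSEL = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    MATRIX: "matrix",
    STRIOSOME: "striosome",
    FIBER_BUNDLE: "fiber_bundle",
    VESSEL: "vessel",
}

#: Indexed-PNG palette for label maps (RGB per label code).
LABEL_PALETTE = {
    BACKGROUND: (0, 0, 0),
    MATRIX: (80, 80, 80),
    STRIOSOME: (255, 200, 0),
    FIBER_BUNDLE: (0, 120, 255),
    VESSEL: (255, 0, 80),
}

SEGMENTS = ("DM", "DL", "VM", "VL")
ALL_SEGMENTS = ("WH",) + SEGMENTS  # WH is the union of the four quadrants
COMPARTMENTS = ("striosome", "matrix")
MOLECULES = ("MOR1", "PDE10A", "Gaolf", "Drd2", "A2A", "Drd1")
GENOTYPES = ("WT", "Q175KI")
AGES = (3, 6, 12)

#: The compartment-defining channel: striosomes are demarcated on MOR1.
REFERENCE_MOLECULE = "MOR1"


@dataclass
class LabelMap:
    """Per-pixel categorical map over background/matrix/striosome/fiber/vessel.

    Serves both as ground truth for synthetic sections and as the prediction
    output of the segmentation model. Every pixel carries exactly one label;
    striosome and matrix together form the striatal tissue, while fiber
    bundles and vessels are carved-out structures excluded from densitometry.
    """

    labels: np.ndarray  # 2-D uint8 array of label codes

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMap requires a 2-D array of label codes")
        if self.labels.size and self.labels.max() > VESSEL:
            raise ValueError("unknown label code in LabelMap")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def striosome(self) -> np.ndarray:
        return self.labels == STRIOSOME

    @property
    def matrix(self) -> np.ndarray:
        return self.labels == MATRIX

    @property
    def striatal(self) -> np.ndarray:
        """Striatal tissue proper: striosome plus matrix."""
        return (self.labels == STRIOSOME) | (self.labels == MATRIX)

    @property
    def excluded_structures(self) -> np.ndarray:
        """Fiber bundles and vessels, excluded from densitometry."""
        return (self.labels == FIBER_BUNDLE) | (self.labels == VESSEL)

    @property
    def territory(self) -> np.ndarray:
        """The full tissue territory: striatal tissue plus carved structures."""
        return self.labels != BACKGROUND

    @property
    def background(self) -> np.ndarray:
        return self.labels == BACKGROUND

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == code))
            for code, name in LABEL_NAMES.items()
        }


@dataclass
class SectionImage:
    """A two-channel section: the MOR1 reference channel that defines the
    striosome/matrix compartments, and the channel of the molecule under
    study. Channels share dimensions and live on a common gray-level scale
    (default 8-bit, stored as float32 so noiseless renders stay exact).
    """

    reference_channel: np.ndarray
    target_channel: np.ndarray
    channel_names: tuple[str, str] = (REFERENCE_MOLECULE, REFERENCE_MOLECULE)
    bit_depth: int = 8
    pixel_size_um: float = 10.0

    def __post_init__(self) -> None:
        self.reference_channel = np.asarray(self.reference_channel, dtype=np.float32)
        self.target_channel = np.asarray(self.target_channel, dtype=np.float32)
        if self.reference_channel.shape != self.target_channel.shape:
            raise ValueError("channels must share identical dimensions")
        if self.reference_channel.ndim != 2:
            raise ValueError("channels must be 2-D gray-level arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference_channel.shape

    @property
    def max_gray(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class SegmentPartition:
    """Assignment of striatal pixels to the DM/DL/VM/VL quadrants.

    ``segment_of`` holds one code per pixel (-1 outside the striatum,
    otherwise an index into :data:`SEGMENTS`). WH is the union of all four.
    """

    segment_of: np.ndarray  # int8; -1 outside striatal mask
    medial_side: str = "left"

    def mask(self, segment: str) -> np.ndarray:
        if segment == "WH":
            return self.segment_of >= 0
        try:
            idx = SEGMENTS.index(segment)
        except ValueError:
            raise KeyError(f"unknown segment {segment!r}") from None
        return self.segment_of == idx


@dataclass
class DensitometryRecord:
    """Background-referenced mean optical intensity for one
    (sample, segment, compartment) cell."""

    animal: str
    hemisphere: str
    molecule: str
    genotype: str
    age: int
    segment: str
    compartment: str
    mean_intensity: float
    n_pixels: int
    qc_excluded: bool = False


@dataclass
class StatSummary:
    """One pairwise comparison: Mann-Whitney U, raw p, Bonferroni-adjusted
    threshold, significance flag, Cohen's r and its conventional bin."""

    comparison: str
    n1: int
    n2: int
    U: float
    p_raw: float
    alpha_adjusted: float
    r: float
    effect_bin: str
    H: float | None = None  # omnibus Kruskal-Wallis statistic, when computed
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_raw < self.alpha_adjusted
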