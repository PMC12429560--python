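"""Seeded synthetic cohorts of two-channel striatal sections with known
striosome/matrix/fiber/vessel ground truth.

The generator emulates double-stained coronal sections of the mouse
caudoputamen: a convex-ish tissue territory inside the frame, labyrinthine
striosome blobs occupying a configurable minority fraction of the striatal
area (band-pass-filtered seeded noise thresholded at the matching quantile),
elliptical fiber bundles and thin vessels carved out of the tissue, a MOR1
reference channel that defines the compartments, a target-molecule channel
whose per-(segment, compartment) means come from an effect table, additive
Gaussian noise clipped to the bit-depth range, and per-sample multiplicative
between-animal intensity offsets so that group comparisons are
statistically nontrivial.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
from scipy import ndimage

from .types import (
    SectionImage, LabelMap,
    BACKGROUND, MATRIX, STRIOSOME, FIBER_BUNDLE, VESSEL,
    SEGMENTS, COMPARTMENTS, MOLECULES, GENOTYPES, AGES, REFERENCE_MOLECULE,
)
from .densito import partition_segments


@dataclass
class SynthesisConfig:
    """Geometry, intensity and noise settings for one rendered section.

    ``striosome_area_fraction`` is the fraction of striatal (striosome +
    matrix) pixels labelled striosome; striosomes are the minority
    compartment, so it must lie strictly inside (0, 0.5).
    ``striosome_scale_px`` sets the characteristic blob width of the
    band-pass field. Identical configs (seed included) yield bit-identical
    outputs.
    """

    image_height_px: int = 768
    image_width_px: int = 1024
    striosome_area_fraction: float = 0.10
    striosome_scale_px: float = 32.0
    n_fiber_bundles: int = 6
    n_vessels: int = 4
    noise_sd: float = 25.0
    background_level: float = 10.0
    structure_level: float = 40.0   # gray level of fiber bundles / vessels
    between_animal_cv: float = 0.08  # log-normal CV of per-sample offsets
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 < self.striosome_area_fraction < 0.5:
            raise ValueError("striosome_area_fraction must lie in (0, 0.5): "
                             "striosomes are the minority compartment")
        if self.striosome_scale_px <= 0:
            raise ValueError("striosome_scale_px must be > 0")
        if self.n_fiber_bundles < 0 or self.n_vessels < 0:
            raise ValueError("structure counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def max_gray(self) -> float:
        return float(2**self.bit_depth - 1)


class EffectTable:
    """Mean gray level per (molecule, genotype, age, segment, compartment).

    The default table constrains only effect *directions* to the study
    design being emulated — MOR1 upregulated in Q175KI striosomes and
    progressively so with age; PDE10A, Gα_olf, Drd2, A2A and Drd1 all
    downregulated; WT PDE10A slightly striosome-predominant — with plausible
    magnitudes that are configuration, not ground truth.
    """

    def __init__(self, means: dict[tuple[str, str, int, str, str], float],
                 background_level: float = 10.0):
        self.means = dict(means)
        self.background_level = float(background_level)
        self._validate()

    def _validate(self) -> None:
        for key, v in self.means.items():
            if v <= self.background_level:
                raise ValueError(f"mean intensity for {key} must exceed the "
                                 f"background level {self.background_level}")

    def mean(self, molecule: str, genotype: str, age: int,
             segment: str, compartment: str) -> float:
        key = (molecule, genotype, int(age), segment, compartment)
        try:
            return self.means[key]
        except KeyError:
            raise KeyError(f"no effect-table row for {key}") from None

    def has(self, molecule: str, genotype: str, age: int) -> bool:
        return (molecule, genotype, int(age), SEGMENTS[0], "striosome") in self.means

    @property
    def molecules(self) -> list[str]:
        return sorted({k[0] for k in self.means},
                      key=lambda m: MOLECULES.index(m) if m in MOLECULES else 99)

    # -- expected values under background subtraction -----------------------
    def expected_intensity(self, molecule, genotype, age, segment, compartment) -> float:
        """Background-referenced amplitude a densitometry record recovers."""
        if segment == "WH":
            vals = [self.mean(molecule, genotype, age, s, compartment)
                    for s in SEGMENTS]
            if len(set(vals)) != 1:
                raise ValueError("WH expectation undefined for segment-varying "
                                 "tables; query the four quadrants instead")
            return vals[0] - self.background_level
        return self.mean(molecule, genotype, age, segment, compartment) - self.background_level

    def expected_ismp(self, molecule, genotype, age, segment) -> float:
        s = self.expected_intensity(molecule, genotype, age, segment, "striosome")
        m = self.expected_intensity(molecule, genotype, age, segment, "matrix")
        return s / m

    def expected_ri(self, molecule, age, segment, compartment) -> float:
        ki = self.expected_intensity(molecule, "Q175KI", age, segment, compartment)
        wt = self.expected_intensity(molecule, "WT", age, segment, compartment)
        return ki / wt

    @classmethod
    def default(cls, background_level: float = 10.0) -> "EffectTable":
        # (WT striosome, WT matrix, KI striosome by age, KI matrix by age)
        spec = {
            "MOR1":   (150, 95, {3: 165, 6: 180, 12: 195}, {3: 95, 6: 95, 12: 105}),
            "PDE10A": (120, 110, {3: 95, 6: 88, 12: 82},   {3: 100, 6: 95, 12: 92}),
            "Gaolf":  (130, 115, {3: 100, 6: 95, 12: 90},  {3: 100, 6: 96, 12: 93}),
            "Drd2":   (125, 120, {3: 98, 6: 92, 12: 88},   {3: 102, 6: 98, 12: 96}),
            "A2A":    (118, 112, {3: 105, 6: 96, 12: 90},  {3: 104, 6: 97, 12: 92}),
            "Drd1":   (122, 118, {3: 112, 6: 104, 12: 98}, {3: 110, 6: 104, 12: 100}),
        }
        means: dict[tuple, float] = {}
        for mol, (wt_s, wt_m, ki_s, ki_m) in spec.items():
            for age in AGES:
                for seg in SEGMENTS:
                    means[(mol, "WT", age, seg, "striosome")] = float(wt_s)
                    means[(mol, "WT", age, seg, "matrix")] = float(wt_m)
                    means[(mol, "Q175KI", age, seg, "striosome")] = float(ki_s[age])
                    means[(mol, "Q175KI", age, seg, "matrix")] = float(ki_m[age])
        return cls(means, background_level=background_level)

    @classmethod
    def null(cls, background_level: float = 10.0) -> "EffectTable":
        """No-genotype-effect table: Q175KI rows copy the WT rows."""
        base = cls.default(background_level)
        means = dict(base.means)
        for (mol, gt, age, seg, comp), v in base.means.items():
            if gt == "WT":
                means[(mol, "Q175KI", age, seg, comp)] = v
        return cls(means, background_level)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"molecule": m, "genotype": g, "age": a, "segment": s,
             "compartment": c, "mean_intensity": v}
            for (m, g, a, s, c), v in sorted(self.means.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame, background_level: float = 10.0) -> "EffectTable":
        means = {
            (r.molecule, r.genotype, int(r.age), r.segment, r.compartment):
                float(r.mean_intensity)
            for r in frame.itertuples()
        }
        return cls(means, background_level)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _territory_mask(config: SynthesisConfig, rng: np.random.Generator) -> np.ndarray:
    """Convex-ish filled tissue territory: an ellipse with mild low-order
    radial modulation, leaving a background margin on every side."""
    h, w = config.image_height_px, config.image_width_px
    rr = (np.arange(h)[:, None] - h / 2) / (0.42 * h)
    cc = (np.arange(w)[None, :] - w / 2) / (0.45 * w)
    theta = np.arctan2(np.broadcast_to(rr, (h, w)), np.broadcast_to(cc, (h, w)))
    radius = np.ones((h, w))
    for k in (2, 3, 4):
        amp = rng.uniform(0.0, 0.06)
        phase = rng.uniform(0, 2 * np.pi)
        radius = radius + amp * np.cos(k * theta + phase)
    return rr**2 + cc**2 <= radius**2


def _bandpass_field(shape, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Difference-of-Gaussians filtered white noise: labyrinthine blobs with
    characteristic width ~``scale`` pixels."""
    g = rng.standard_normal(shape)
    lo = ndimage.gaussian_filter(g, scale / 2.0)
    hi = ndimage.gaussian_filter(g, scale)
    return lo - hi


def _draw_ellipse(mask, center, axes, angle, value, labels):
    from skimage.draw import ellipse

    rr, cc = ellipse(center[0], center[1], axes[0], axes[1],
                     shape=labels.shape, rotation=angle)
    sel = mask[rr, cc]
    labels[rr[sel], cc[sel]] = value


def _draw_vessel(mask, p0, angle, length, width, labels):
    from skimage.draw import line
    from skimage.morphology import disk

    r1 = int(round(p0[0] + length * np.sin(angle)))
    c1 = int(round(p0[1] + length * np.cos(angle)))
    h, w = labels.shape
    r1 = np.clip(r1, 0, h - 1)
    c1 = np.clip(c1, 0, w - 1)
    rr, cc = line(int(p0[0]), int(p0[1]), r1, c1)
    canvas = np.zeros(labels.shape, bool)
    canvas[rr, cc] = True
    if width > 1:
        canvas = ndimage.binary_dilation(canvas, structure=disk(width // 2))
    sel = canvas & mask
    labels[sel] = VESSEL


def generate_striosome_mask(config: SynthesisConfig,
                            rng: np.random.Generator | None = None) -> LabelMap:
    """Ground-truth label map for one section.

    The striatum is a filled convex-ish territory inside the frame.
    Striosome pixels are the top quantile of a band-pass-filtered seeded
    noise field, so their fraction of striatal pixels matches
    ``striosome_area_fraction`` to within quantization. Fiber bundles are
    elliptical patches, vessels thin tubes; both are carved out of the
    tissue before the striosome quantile is taken, so the fraction is exact
    over the remaining striatal (striosome + matrix) pixels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    territory = _territory_mask(config, rng)
    labels = np.full(territory.shape, BACKGROUND, dtype=np.uint8)
    labels[territory] = MATRIX

    h, w = labels.shape
    scale = min(h, w)
    centers = np.argwhere(territory)
    for _ in range(config.n_fiber_bundles):
        center = centers[rng.integers(len(centers))]
        axes = rng.uniform(0.015, 0.04, size=2) * scale
        _draw_ellipse(territory, center, axes, rng.uniform(0, np.pi),
                      FIBER_BUNDLE, labels)
    for _ in range(config.n_vessels):
        p0 = centers[rng.integers(len(centers))]
        _draw_vessel(territory, p0, rng.uniform(0, 2 * np.pi),
                     rng.uniform(0.3, 0.7) * scale,
                     int(rng.integers(2, 5)), labels)

    eligible = labels == MATRIX
    field = _bandpass_field(labels.shape, config.striosome_scale_px, rng)
    thr = np.quantile(field[eligible], 1.0 - config.striosome_area_fraction)
    labels[eligible & (field > thr)] = STRIOSOME
    return LabelMap(labels)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _mean_image(labels: LabelMap, effects: EffectTable, molecule, genotype, age,
                config: SynthesisConfig, partition, offsets) -> np.ndarray:
    img = np.full(labels.shape, config.background_level, dtype=np.float32)
    img[labels.excluded_structures] = config.structure_level
    b = config.background_level
    for segment in SEGMENTS:
        seg_mask = partition.mask(segment)
        for compartment in COMPARTMENTS:
            mean = effects.mean(molecule, genotype, age, segment, compartment)
            off = offsets.get(compartment, 1.0)
            comp_mask = labels.striosome if compartment == "striosome" else labels.matrix
            # offsets scale the amplitude above background, so background
            # subtraction downstream recovers off * (mean - b) exactly
            img[comp_mask & seg_mask] = b + off * (mean - b)
    return img


def render_section(
    labels: LabelMap,
    effects: EffectTable,
    molecule: str,
    genotype: str,
    age: int,
    config: SynthesisConfig,
    medial_side: str = "left",
    offsets: dict | None = None,
    rng: np.random.Generator | None = None,
) -> SectionImage:
    """Render the two channels for one section.

    Each striatal pixel's expected value is the effect-table mean for its
    (segment, compartment); fiber/vessel pixels get a distinct low level and
    background pixels the background level. Independent Gaussian noise of sd
    ``noise_sd`` is added per channel, then clipped to the bit-depth range.
    The reference channel is always rendered from the MOR1 row.

    ``offsets`` optionally carries per-compartment multiplicative offsets
    for each channel: ``{"reference": {...}, "target": {...}}``.
    """
    if not effects.has(molecule, genotype, age):
        raise KeyError(f"no effect-table rows for ({molecule}, {genotype}, {age})")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    offsets = offsets or {}
    partition = partition_segments(labels.striatal, medial_side=medial_side)
    ref = _mean_image(labels, effects, REFERENCE_MOLECULE, genotype, age,
                      config, partition, offsets.get("reference", {}))
    tgt = _mean_image(labels, effects, molecule, genotype, age,
                      config, partition, offsets.get("target", {}))
    if config.noise_sd > 0:
        ref = ref + rng.normal(0.0, config.noise_sd, ref.shape).astype(np.float32)
        tgt = tgt + rng.normal(0.0, config.noise_sd, tgt.shape).astype(np.float32)
        np.clip(ref, 0.0, config.max_gray, out=ref)
        np.clip(tgt, 0.0, config.max_gray, out=tgt)
    return SectionImage(ref, tgt, channel_names=(REFERENCE_MOLECULE, molecule),
                        bit_depth=config.bit_depth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _lognormal_offset(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative offset with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))


def iter_cohort(
    effects: EffectTable,
    n_mice_per_group: int,
    config: SynthesisConfig,
    molecules: tuple[str, ...] | None = None,
    ages: tuple[int, ...] = AGES,
) -> Iterator[tuple[SectionImage, LabelMap, dict]]:
    """Stream a full cohort: for every molecule, 2 genotypes x len(ages) ages
    x n mice x 2 hemispheres sections, each with ground-truth labels and a
    metadata dict (animal, hemisphere, genotype, age, molecule, seed).

    Per-(sample, molecule, compartment) multiplicative intensity offsets are
    drawn log-normally with CV ``config.between_animal_cv``, emulating
    between-animal and staining-batch variability. Section seeds derive from
    ``config.seed`` through a counter scheme, so an identical config
    reproduces the cohort bit-identically and extending the cohort never
    reshuffles existing sections.
    """
    if n_mice_per_group < 1:
        raise ValueError("n_mice_per_group must be >= 1")
    molecules = tuple(molecules) if molecules is not None else tuple(effects.molecules)
    root = np.random.SeedSequence(config.seed)
    counter = 0
    for molecule in molecules:
        for genotype in GENOTYPES:
            for age in ages:
                for mouse in range(n_mice_per_group):
                    animal = f"{genotype}_{age}m_{mouse:02d}"
                    for hemisphere in ("L", "R"):
                        child = np.random.SeedSequence(
                            entropy=root.entropy, spawn_key=(counter,))
                        counter += 1
                        rng = np.random.default_rng(child)
                        section_seed = int(rng.integers(2**31))
                        off = {
                            ch: {c: _lognormal_offset(rng, config.between_animal_cv)
                                 for c in COMPARTMENTS}
                            for ch in ("reference", "target")
                        }
                        medial = "left" if hemisphere == "R" else "right"
                        geom_cfg = SynthesisConfig(**{
                            **asdict(config), "seed": section_seed})
                        labels = generate_striosome_mask(geom_cfg)
                        image = render_section(
                            labels, effects, molecule, genotype, age, config,
                            medial_side=medial, offsets=off, rng=rng)
                        meta = {
                            "animal": animal, "hemisphere": hemisphere,
                            "molecule": molecule, "genotype": genotype,
                            "age": age, "medial_side": medial,
                            "seed": section_seed,
                        }
                        yield image, labels, meta


def generate_cohort(effects, n_mice_per_group, config, molecules=None,
                    ages=AGES) -> list[tuple[SectionImage, LabelMap, dict]]:
    """Materialized cohort; see :func:`iter_cohort` for the streaming form."""
    return list(iter_cohort(effects, n_mice_per_group, config,
                            molecules=molecules, ages=ages))
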