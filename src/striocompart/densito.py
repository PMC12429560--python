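"""Compartmental densitometry: quadrant segment partition (DM/DL/VM/VL, with
WH their union), background-referenced mean optical intensity per
(segment, compartment), fiber/vessel exclusion, and the two summary indices:

* RI, the relative intensity: ratio of the Q175KI group-mean intensity to the
  WT group-mean intensity per (molecule, age, segment, compartment);
* ISMP, the index of striosome-to-matrix predominance: per-sample ratio of
  striosomal to matrix intensity, summarized as group mean +/- SEM.

Intensity polarity follows the fluorescence convention (higher gray level =
stronger immunoreactivity). Background is handled by subtracting the mean
gray level of the out-of-tissue region, which makes every downstream record
invariant to a constant shift of the whole image.
"""
from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .types import (
    LabelMap, SectionImage, SegmentPartition, DensitometryRecord,
    SEGMENTS, ALL_SEGMENTS, COMPARTMENTS,
)


def partition_segments(striatal_mask: np.ndarray, medial_side: str = "left") -> SegmentPartition:
    """Split a striatal mask into DM/DL/VM/VL quadrants about its centroid.

    Dorsal/ventral splits by row (dorsal = top of the image), medial/lateral
    by column. ``medial_side`` names the image side that faces the midline
    for this hemisphere ("left" or "right"); flipping it under a mirrored
    mask swaps DM with DL and VM with VL.
    """
    mask = np.asarray(striatal_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("striatal mask must be 2-D")
    if not mask.any():
        raise ValueError("empty striatal mask")
    if medial_side not in ("left", "right"):
        raise ValueError("medial_side must be 'left' or 'right'")
    rows, cols = np.nonzero(mask)
    r0 = rows.mean()
    c0 = cols.mean()
    rr = np.arange(mask.shape[0])[:, None]
    cc = np.arange(mask.shape[1])[None, :]
    dorsal = np.broadcast_to(rr < r0, mask.shape)
    left_half = np.broadcast_to(cc < c0, mask.shape)
    medial = left_half if medial_side == "left" else ~left_half
    seg = np.full(mask.shape, -1, dtype=np.int8)
    seg[mask & dorsal & medial] = SEGMENTS.index("DM")
    seg[mask & dorsal & ~medial] = SEGMENTS.index("DL")
    seg[mask & ~dorsal & medial] = SEGMENTS.index("VM")
    seg[mask & ~dorsal & ~medial] = SEGMENTS.index("VL")
    return SegmentPartition(segment_of=seg, medial_side=medial_side)


def measure(
    section: SectionImage,
    compartments: LabelMap,
    parts: SegmentPartition,
    exclusions: np.ndarray | None = None,
    background_region: np.ndarray | None = None,
    channel: str = "target",
    background_stat: str = "median",
    **meta,
) -> list[DensitometryRecord]:
    """Background-referenced mean intensity per (segment, compartment).

    ``compartments`` supplies the striosome/matrix masks (ground truth or a
    model prediction). Fiber-bundle and vessel pixels (``exclusions``,
    defaulting to those labels in ``compartments``) are removed before
    averaging. ``background_region`` defaults to the background label; it
    must be non-empty. Cells with no remaining pixels — poorly stained or
    lost tissue in the real assay — are returned flagged ``qc_excluded``.

    The background reference is the *median* gray level of the background
    region by default: near the bottom of the detector range the noise
    distribution is clipped, which biases the sample mean upward, while
    the median stays unbiased as long as less than half the background
    mass clips. ``background_stat="mean"`` restores the plain mean.
    """
    img = section.target_channel if channel == "target" else section.reference_channel
    if img.shape != compartments.shape:
        raise ValueError("section and label map dimensions differ")
    if parts.segment_of.shape != img.shape:
        raise ValueError("segment partition dimensions differ")
    if exclusions is None:
        exclusions = compartments.excluded_structures
    else:
        exclusions = np.asarray(exclusions, dtype=bool)
    if background_region is None:
        background_region = compartments.background
    else:
        background_region = np.asarray(background_region, dtype=bool)
    if not background_region.any():
        raise ValueError("background region is empty")
    if background_stat == "median":
        bg = float(np.median(img[background_region].astype(np.float64)))
    elif background_stat == "mean":
        bg = float(img[background_region].mean(dtype=np.float64))
    else:
        raise ValueError("background_stat must be 'median' or 'mean'")

    comp_masks = {
        "striosome": compartments.striosome & ~exclusions,
        "matrix": compartments.matrix & ~exclusions,
    }
    defaults = dict(animal="", hemisphere="", molecule="", genotype="", age=0)
    defaults.update(meta)
    records = []
    for segment in ALL_SEGMENTS:
        seg_mask = parts.mask(segment)
        for compartment in COMPARTMENTS:
            sel = comp_masks[compartment] & seg_mask
            n = int(np.count_nonzero(sel))
            if n == 0:
                records.append(DensitometryRecord(
                    segment=segment, compartment=compartment,
                    mean_intensity=np.nan, n_pixels=0, qc_excluded=True,
                    **defaults))
                continue
            mean = float(img[sel].mean(dtype=np.float64)) - bg
            records.append(DensitometryRecord(
                segment=segment, compartment=compartment,
                mean_intensity=mean, n_pixels=n, qc_excluded=False,
                **defaults))
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def compute_RI(records_ki: pd.DataFrame, records_wt: pd.DataFrame) -> pd.DataFrame:
    """Relative intensity per (molecule, age, segment, compartment).

    RI is the ratio of *group means* — mean intensity over Q175KI samples
    divided by mean over WT samples — not a mean of per-sample ratios.
    QC-excluded records are dropped before averaging.
    """
    keys = ["molecule", "age", "segment", "compartment"]
    ki = records_ki[~records_ki["qc_excluded"]].groupby(keys)["mean_intensity"].mean()
    wt = records_wt[~records_wt["qc_excluded"]].groupby(keys)["mean_intensity"].mean()
    joined = pd.concat({"KI": ki, "WT": wt}, axis=1).dropna()
    if (joined["WT"] <= 0).any():
        bad = joined.index[joined["WT"] <= 0].tolist()
        raise ValueError(f"non-positive WT group mean for {bad}")
    out = (joined["KI"] / joined["WT"]).rename("RI").reset_index()
    return out


def compute_ISMP(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ISMP = striosome intensity / matrix intensity, per segment.

    Samples whose matrix mean is non-positive are dropped with a warning
    (the ratio is not interpretable). Group summaries (mean +/- SEM) are
    produced downstream by the stats module so that raw per-sample ratios
    remain available for rank tests.
    """
    import warnings

    rec = records[~records["qc_excluded"]]
    keys = ["animal", "hemisphere", "molecule", "genotype", "age", "segment"]
    wide = rec.pivot_table(index=keys, columns="compartment",
                           values="mean_intensity", aggfunc="first")
    wide = wide.dropna(subset=["striosome", "matrix"])
    bad = wide["matrix"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} samples with non-positive "
                      "matrix intensity", stacklevel=2)
        wide = wide[~bad]
    out = (wide["striosome"] / wide["matrix"]).rename("ismp").reset_index()
    return out


def ismp_group_summary(ismp: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SEM of ISMP per (molecule, genotype, age, segment)."""
    g = ismp.groupby(["molecule", "genotype", "age", "segment"])["ismp"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")
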