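"""Densitometry: quadrant partition, background-referenced means, RI, ISMP."""
import numpy as np
import pandas as pd
import pytest

from striocompart.densito import (
    partition_segments, measure, records_to_frame, compute_RI, compute_ISMP,
    ismp_group_summary,
)
from striocompart.synth import (
    SynthesisConfig, generate_striosome_mask, render_section,
)
from striocompart.types import (
    LabelMap, SectionImage, BACKGROUND, MATRIX, STRIOSOME, FIBER_BUNDLE,
    SEGMENTS,
)


def _square_mask(n=40, pad=4):
    m = np.zeros((n + 2 * pad, n + 2 * pad), bool)
    m[pad:pad + n, pad:pad + n] = True
    return m


class TestPartition:
    def test_centered_square_splits_evenly(self):
        parts = partition_segments(_square_mask())
        counts = {s: int(parts.mask(s).sum()) for s in SEGMENTS}
        assert len(set(counts.values())) == 1

    def test_partition_law(self):
        mask = _square_mask()
        parts = partition_segments(mask)
        union = np.zeros_like(mask)
        for s in SEGMENTS:
            seg = parts.mask(s)
            assert not np.any(union & seg)  # pairwise disjoint
            union |= seg
        assert np.array_equal(union, mask)
        assert np.array_equal(parts.mask("WH"), mask)

    def test_hemisphere_flag_swaps_medial_lateral(self):
        rng = np.random.default_rng(0)
        mask = rng.random((30, 40)) < 0.4
        mask[0, :] = False
        left = partition_segments(mask, medial_side="left")
        right = partition_segments(mask[:, ::-1], medial_side="right")
        assert np.array_equal(left.mask("DM"), right.mask("DM")[:, ::-1])
        assert np.array_equal(left.mask("VL"), right.mask("VL")[:, ::-1])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            partition_segments(np.zeros((5, 5), bool))


def _uniform_section(strio=150.0, matrix=100.0, background=10.0, fiber=None):
    """Small section with striosome band on top-left, known means."""
    labels = np.full((16, 16), BACKGROUND, np.uint8)
    labels[2:14, 2:14] = MATRIX
    labels[3:6, 3:13] = STRIOSOME
    if fiber:
        labels[10:12, 4:8] = FIBER_BUNDLE
    img = np.full((16, 16), background, np.float32)
    img[LabelMap(labels).matrix] = matrix
    img[LabelMap(labels).striosome] = strio
    if fiber:
        img[labels == FIBER_BUNDLE] = fiber
    lm = LabelMap(labels)
    section = SectionImage(img, img)
    return section, lm


class TestMeasure:
    def test_background_subtraction_arithmetic(self):
        section, lm = _uniform_section()
        parts = partition_segments(lm.striatal)
        rec = records_to_frame(measure(section, lm, parts))
        wh = rec[rec["segment"] == "WH"].set_index("compartment")
        assert wh.loc["striosome", "mean_intensity"] == pytest.approx(140.0)
        assert wh.loc["matrix", "mean_intensity"] == pytest.approx(90.0)

    def test_wh_is_pixel_weighted_mean_of_quadrants(self, noiseless_render):
        section, lm = noiseless_render
        parts = partition_segments(lm.striatal)
        rec = records_to_frame(measure(section, lm, parts))
        for comp in ("striosome", "matrix"):
            sub = rec[(rec["compartment"] == comp) & (rec["segment"] != "WH")]
            sub = sub[~sub["qc_excluded"]]
            wh = rec[(rec["compartment"] == comp) & (rec["segment"] == "WH")]
            weighted = (sub["mean_intensity"] * sub["n_pixels"]).sum() / sub["n_pixels"].sum()
            assert float(wh["mean_intensity"].iloc[0]) == pytest.approx(weighted)

    def test_fiber_pixels_excluded_from_matrix(self):
        clean, lm_clean = _uniform_section()
        spiked, lm_spiked = _uniform_section(fiber=999.0)
        rec_a = records_to_frame(measure(clean, lm_clean,
                                         partition_segments(lm_clean.striatal)))
        rec_b = records_to_frame(measure(spiked, lm_spiked,
                                         partition_segments(lm_spiked.striatal)))
        a = rec_a[(rec_a["segment"] == "WH") & (rec_a["compartment"] == "matrix")]
        b = rec_b[(rec_b["segment"] == "WH") & (rec_b["compartment"] == "matrix")]
        assert float(a["mean_intensity"].iloc[0]) == \
            pytest.approx(float(b["mean_intensity"].iloc[0]))

    def test_background_shift_invariance(self):
        section, lm = _uniform_section()
        parts = partition_segments(lm.striatal)
        rec1 = records_to_frame(measure(section, lm, parts))
        shifted = SectionImage(section.reference_channel + 37.0,
                               section.target_channel + 37.0)
        rec2 = records_to_frame(measure(shifted, lm, parts))
        assert np.allclose(rec1["mean_intensity"], rec2["mean_intensity"],
                           equal_nan=True)

    def test_empty_cell_flagged_qc_excluded(self):
        # striosome band only in the dorsal half -> ventral cells empty
        section, lm = _uniform_section()
        parts = partition_segments(lm.striatal)
        rec = records_to_frame(measure(section, lm, parts))
        vm = rec[(rec["segment"] == "VM") & (rec["compartment"] == "striosome")]
        assert bool(vm["qc_excluded"].iloc[0])
        assert int(vm["n_pixels"].iloc[0]) == 0

    def test_empty_background_raises(self):
        section, lm = _uniform_section()
        parts = partition_segments(lm.striatal)
        with pytest.raises(ValueError):
            measure(section, lm, parts,
                    background_region=np.zeros(lm.shape, bool))


def _records(genotype, strio, matrix, n=4, molecule="PDE10A", age=3):
    rows = []
    for i in range(n):
        for seg in ("WH",) + SEGMENTS:
            rows.append({"animal": f"{genotype}{i}", "hemisphere": "L",
                         "molecule": molecule, "genotype": genotype,
                         "age": age, "segment": seg,
                         "compartment": "striosome",
                         "mean_intensity": strio[i] if hasattr(strio, "__len__") else strio,
                         "n_pixels": 100, "qc_excluded": False})
            rows.append({"animal": f"{genotype}{i}", "hemisphere": "L",
                         "molecule": molecule, "genotype": genotype,
                         "age": age, "segment": seg, "compartment": "matrix",
                         "mean_intensity": matrix[i] if hasattr(matrix, "__len__") else matrix,
                         "n_pixels": 900, "qc_excluded": False})
    return pd.DataFrame(rows)


class TestRI:
    def test_ratio_of_group_means(self):
        ki = _records("Q175KI", strio=80.0, matrix=80.0)
        wt = _records("WT", strio=100.0, matrix=100.0)
        ri = compute_RI(ki, wt)
        assert np.allclose(ri["RI"], 0.8)

    def test_identical_groups_give_unity(self):
        wt = _records("WT", strio=120.0, matrix=90.0)
        ki = wt.assign(genotype="Q175KI")
        assert np.allclose(compute_RI(ki, wt)["RI"], 1.0)

    def test_nonpositive_wt_mean_raises(self):
        ki = _records("Q175KI", strio=80.0, matrix=80.0)
        wt = _records("WT", strio=0.0, matrix=0.0)
        with pytest.raises(ValueError):
            compute_RI(ki, wt)


class TestISMP:
    def test_ratio_arithmetic(self):
        rec = _records("WT", strio=140.0, matrix=90.0)
        ismp = compute_ISMP(rec)
        assert np.allclose(ismp["ismp"], 140.0 / 90.0)

    def test_equal_compartments_give_unity(self):
        rec = _records("WT", strio=77.0, matrix=77.0)
        assert np.allclose(compute_ISMP(rec)["ismp"], 1.0)

    def test_nonpositive_matrix_dropped_with_warning(self):
        rec = _records("WT", strio=[140.0] * 4, matrix=[90.0, 90.0, 0.0, -5.0])
        with pytest.warns(UserWarning):
            ismp = compute_ISMP(rec)
        assert set(ismp["animal"]) == {"WT0", "WT1"}

    def test_group_summary_mean_sem(self):
        rec = pd.concat([_records("WT", strio=[140, 150, 130, 140],
                                  matrix=100.0)])
        summary = ismp_group_summary(compute_ISMP(rec))
        wh = summary[summary["segment"] == "WH"].iloc[0]
        vals = np.array([1.4, 1.5, 1.3, 1.4])
        assert wh["mean"] == pytest.approx(vals.mean())
        assert wh["sem"] == pytest.approx(vals.std(ddof=1) / 2)


class TestParameterRecovery:
    """Noiseless end-to-end: configured table ratios recovered exactly."""

    def test_noiseless_ismp_and_ri_exact(self, effects):
        cfg = SynthesisConfig(image_height_px=160, image_width_px=224,
                              striosome_scale_px=16, noise_sd=0.0, seed=13)
        labels = generate_striosome_mask(cfg)
        parts = partition_segments(labels.striatal)
        frames = {}
        for gt in ("WT", "Q175KI"):
            sec = render_section(labels, effects, "PDE10A", gt, 6, cfg)
            frames[gt] = records_to_frame(measure(
                sec, labels, parts, molecule="PDE10A", genotype=gt, age=6,
                animal=gt, hemisphere="L"))
        ismp = compute_ISMP(frames["WT"])
        expected = effects.expected_ismp("PDE10A", "WT", 6, "WH")
        wh = ismp[ismp["segment"] == "WH"]["ismp"].iloc[0]
        assert wh == pytest.approx(expected, rel=1e-12)
        ri = compute_RI(frames["Q175KI"], frames["WT"])
        row = ri[(ri["segment"] == "WH") & (ri["compartment"] == "striosome")]
        assert float(row["RI"].iloc[0]) == pytest.approx(
            effects.expected_ri("PDE10A", 6, "WH", "striosome"), rel=1e-12)
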