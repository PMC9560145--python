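"""Thresholding, cavity filling, instance counting and the parasitoid rate."""

import numpy as np
import pytest

from cocoonct.phantom import generate_phantom
from cocoonct.postprocess import (CountRecord, PostprocessConfig, binarize_classes,
                                  count_from_probabilities, count_instances,
                                  fill_cavities, parasitoid_rate, round_half_up)
from conftest import clean_phantom_spec


def _probs_from_fg(p_healthy, p_parasitoid):
    """Single-voxel probability volume (3, 1, 1, 1)."""
    bg = 1.0 - p_healthy - p_parasitoid
    return np.array([bg, p_healthy, p_parasitoid]).reshape(3, 1, 1, 1)


class TestBinarize:
    def test_single_class_above_threshold(self):
        assert binarize_classes(_probs_from_fg(0.85, 0.0))[0, 0, 0] == 1

    def test_nothing_reaches_threshold(self):
        assert binarize_classes(_probs_from_fg(0.35, 0.35))[0, 0, 0] == 0

    def test_both_above_larger_wins_tie_to_healthy(self):
        cfg = PostprocessConfig(probability_threshold=0.45)
        assert binarize_classes(_probs_from_fg(0.45, 0.55), cfg)[0, 0, 0] == 2
        assert binarize_classes(_probs_from_fg(0.5, 0.5), cfg)[0, 0, 0] == 1

    def test_threshold_monotonicity(self, rng):
        raw = rng.random((3, 8, 8, 8))
        probs = raw / raw.sum(axis=0)
        fg_sets = []
        for t in (0.4, 0.5, 0.6, 0.8, 0.9):
            lab = binarize_classes(probs, PostprocessConfig(probability_threshold=t))
            fg_sets.append(set(map(tuple, np.argwhere(lab > 0))))
        for smaller, larger in zip(fg_sets[1:], fg_sets):
            assert smaller <= larger


class TestFillCavities:
    def test_enclosed_hole_filled_with_surrounding_class(self):
        lab = np.zeros((12, 12, 12), dtype=np.uint8)
        lab[2:10, 2:10, 2:10] = 1
        lab[5:8, 5:8, 5:8] = 0  # 3^3 air hole
        out = fill_cavities(lab)
        assert np.all(out[2:10, 2:10, 2:10] == 1)
        assert not out[0].any()

    def test_all_background_unchanged(self):
        lab = np.zeros((6, 6, 6), dtype=np.uint8)
        np.testing.assert_array_equal(fill_cavities(lab), lab)

    def test_cavity_with_channel_to_border_not_filled(self):
        lab = np.zeros((12, 12, 12), dtype=np.uint8)
        lab[2:10, 2:10, 2:10] = 1
        lab[4:8, 4:8, 4:8] = 0  # cavity ...
        lab[5:7, 5:7, 0:8] = 0  # ... vented to the border through a channel
        out = fill_cavities(lab)
        assert not out[5, 5, 2]  # channel stays open
        assert not out[5, 5, 5]  # cavity connected to border: not filled

    def test_idempotent_on_phantom_labels(self, clean_phantom):
        _, labels, _, _ = clean_phantom
        once = fill_cavities(labels)
        twice = fill_cavities(once)
        np.testing.assert_array_equal(once, twice)
        # cocoon interiors are air in HU but labelled; synthetic cavities we
        # punch into the labels must be restored to the surrounding class
        from scipy import ndimage
        punched = once.copy()
        interior = ndimage.binary_erosion(punched == 1, iterations=2)
        core = tuple(np.argwhere(interior)[0])
        punched[core] = 0
        refilled = fill_cavities(punched)
        assert refilled[core] == 1


class TestCountInstances:
    def test_disjoint_blobs_counted_per_class(self):
        lab = np.zeros((20, 20, 20), dtype=np.uint8)
        lab[2:5, 2:5, 2:5] = 1
        lab[10:14, 10:14, 10:14] = 1
        lab[2:6, 12:16, 2:6] = 2
        for method in ("components", "watershed"):
            inst, id2c, rec = count_instances(lab, PostprocessConfig(instance_method=method))
            assert (rec.healthy, rec.parasitoid) == (2, 1)
            # conservation: tallies equal the distinct nonzero instance ids
            assert sorted(id2c) == sorted(np.unique(inst)[1:])
            assert len(id2c) == rec.healthy + rec.parasitoid

    def test_empty_volume_counts_zero_and_flags_rate(self):
        inst, id2c, rec = count_instances(np.zeros((8, 8, 8), dtype=np.uint8))
        assert (rec.healthy, rec.parasitoid) == (0, 0)
        assert rec.rate_undefined
        assert rec.parasitoid_rate is None

    def test_speckle_below_min_volume_discarded(self):
        lab = np.zeros((16, 16, 16), dtype=np.uint8)
        lab[2:6, 2:6, 2:6] = 1  # 64 voxels, kept
        lab[10, 10, 10] = 1  # single-voxel speckle, dropped
        _, _, rec = count_instances(lab, PostprocessConfig(instance_method="components"))
        assert rec.healthy == 1

    @pytest.mark.parametrize("method", ["components", "watershed"])
    def test_ground_truth_phantom_counts_match_manifest(self, clean_phantom, method):
        _, labels, _, truth = clean_phantom
        _, _, rec = count_instances(labels, PostprocessConfig(instance_method=method))
        assert rec.healthy == truth.healthy_count
        assert rec.parasitoid == truth.parasitoid_count

    def test_watershed_splits_touching_cocoons(self):
        # two overlapping spheres with a neck deeper than watershed_h
        z, y, x = np.ogrid[0:26, 0:26, 0:26]
        s1 = (z - 13) ** 2 + (y - 13) ** 2 + (x - 7) ** 2 <= 36
        s2 = (z - 13) ** 2 + (y - 13) ** 2 + (x - 18) ** 2 <= 36
        lab = ((s1 | s2) * 1).astype(np.uint8)
        _, _, rec_w = count_instances(lab, PostprocessConfig(instance_method="watershed"))
        _, _, rec_c = count_instances(lab, PostprocessConfig(instance_method="components"))
        assert rec_c.healthy == 1  # plain components under-count
        assert rec_w.healthy == 2


class TestParasitoidRate:
    @pytest.mark.parametrize("healthy,parasitoid,expected", [
        (5864, 65, 1.11), (3371, 21, 0.62), (466, 18, 3.86), (400, 0, 0.0),
        (301, 2, 0.66), (378, 6, 1.59),
    ])
    def test_rate_formula_and_rounding(self, healthy, parasitoid, expected):
        assert parasitoid_rate(healthy, parasitoid) == expected

    def test_zero_healthy_is_undefined_not_an_error(self):
        assert parasitoid_rate(0, 5) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            parasitoid_rate(-1, 0)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(-0.125, 2) == -0.13
        assert round_half_up(2.675, 2) == 2.68


def test_full_postprocess_chain_on_sharp_probabilities(clean_phantom):
    _, labels, _, truth = clean_phantom
    probs = np.zeros((3,) + labels.shape, dtype=np.float32)
    for c in range(3):
        probs[c] = (labels == c) * 0.97 + 0.01
    _, _, rec = count_from_probabilities(probs)
    assert (rec.healthy, rec.parasitoid) == (truth.healthy_count, truth.parasitoid_count)


def test_postprocess_config_validation():
    with pytest.raises(ValueError):
        PostprocessConfig(probability_threshold=1.5)
    with pytest.raises(ValueError):
        PostprocessConfig(instance_method="blobs")
    with pytest.raises(ValueError):
        CountRecord(sample_id="x", healthy=-1, parasitoid=0)
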