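"""Five-label segmentation and nodule-label editing."""

import numpy as np
import pytest

from synthct import annotation, labels as L, phantom
from synthct.annotation import NoduleSpec
from synthct.errors import (
    ConstraintError,
    DataError,
    NotFoundError,
    SegmentationFailure,
    SizeError,
)


def nodule_phantom(seed=5, diameter=8.0, center=(31.0, 21.0)):
    spec = phantom.PhantomSpec(
        seed=seed, nodule=NoduleSpec(center=center, diameter=diameter)
    )
    return phantom.generate_phantom_slice(spec)


class TestSegmentSlice:
    def test_five_anatomical_labels_on_nodule_phantom(self):
        px, lab = nodule_phantom()
        seg = annotation.segment_slice(px, nodule_mask=lab == L.NODULE)
        anatomical = set(np.unique(seg)) - {L.EXTERIOR}
        assert anatomical == {L.BODY, L.SOFT, L.DENSE, L.LUNG, L.NODULE}

    def test_dice_against_ground_truth(self):
        scores = {lbl: [] for lbl in (L.BODY, L.SOFT, L.DENSE, L.LUNG)}
        for seed in range(20):
            px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=seed))
            seg = annotation.segment_slice(px)
            for lbl in scores:
                scores[lbl].append(annotation.dice(seg, lab, lbl))
        for lbl, vals in scores.items():
            assert np.mean(vals) >= 0.85, f"label {lbl} mean dice {np.mean(vals)}"
        assert np.mean(scores[L.BODY]) >= 0.90
        assert np.mean(scores[L.LUNG]) >= 0.90

    def test_all_air_slice_fails_explicitly(self):
        with pytest.raises(SegmentationFailure):
            annotation.segment_slice(np.full((64, 64), -1000.0))

    def test_threshold_order_enforced(self):
        from synthct.errors import ParameterError

        with pytest.raises(ParameterError):
            annotation.SegmentationParams(
                body_threshold=0.0, lung_threshold=-320.0
            ).validate()


class TestAttachNoduleMask:
    def test_mask_inside_lung_becomes_label_five(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        seg = annotation.segment_slice(px)
        rr, cc = np.nonzero(seg == L.LUNG)
        mask = np.zeros_like(seg, dtype=bool)
        mask[rr[:20], cc[:20]] = True
        out = annotation.attach_nodule_mask(seg, mask)
        assert np.all(out[mask] == L.NODULE)
        assert int((out == L.NODULE).sum()) == int(mask.sum())

    def test_mask_in_exterior_rejected(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        seg = annotation.segment_slice(px)
        mask = np.zeros_like(seg, dtype=bool)
        mask[0:3, 0:3] = True
        with pytest.raises(ConstraintError, match="overlap"):
            annotation.attach_nodule_mask(seg, mask)

    def test_partial_overlap_above_threshold_accepted(self):
        # 6 lung pixels + 4 soft pixels = 60% overlap, threshold 0.5
        seg = np.full((16, 16), L.SOFT, dtype=np.uint8)
        seg[4:10, 4:10] = L.LUNG
        mask = np.zeros_like(seg, dtype=bool)
        mask[8:10, 7:10] = True  # 6 in lung
        mask[10:12, 7:9] = True  # 4 in soft
        out = annotation.attach_nodule_mask(seg, mask, require_lung_overlap=0.5)
        assert int((out == L.NODULE).sum()) == int(mask.sum())


class TestEditOperations:
    def test_remove_all_clears_nodule_label(self):
        px, lab = nodule_phantom()
        out = annotation.remove_nodule(lab, "all")
        assert int((out == L.NODULE).sum()) == 0
        assert np.all(out[lab == L.NODULE] == L.LUNG)

    def test_remove_on_nodule_free_map_is_identity(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        assert np.array_equal(annotation.remove_nodule(lab, "all"), lab)

    def test_remove_missing_id_raises(self):
        px, lab = nodule_phantom()
        with pytest.raises(NotFoundError):
            annotation.remove_nodule(lab, 7)

    def test_remove_one_of_two_preserves_the_other(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        m1 = annotation.insert_nodule(lab, NoduleSpec((31.0, 21.0), 6.0), seed=1)
        m2 = annotation.insert_nodule(m1, NoduleSpec((31.0, 43.0), 6.0), seed=1)
        comp, n = annotation.nodule_components(m2)
        assert n == 2
        before = int((comp == 2).sum())
        out = annotation.remove_nodule(m2, 1)
        comp2, n2 = annotation.nodule_components(out)
        assert n2 == 1
        assert int((comp2 == 1).sum()) == before

    def test_insert_area_matches_disk(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        out = annotation.insert_nodule(
            lab, NoduleSpec((31.0, 21.0), 10.0, roughness=0.0), seed=0
        )
        area = int((out == L.NODULE).sum())
        assert area == pytest.approx(np.pi * 25, rel=0.10)

    def test_insert_on_soft_tissue_rejected(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        rr, cc = np.nonzero(lab == L.SOFT)
        with pytest.raises(ConstraintError, match="lung"):
            annotation.insert_nodule(
                lab, NoduleSpec((float(rr[0]), float(cc[0])), 6.0), seed=0
            )

    def test_insert_is_deterministic(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        spec = NoduleSpec((31.0, 21.0), 7.0, roughness=0.6)
        a = annotation.insert_nodule(lab, spec, seed=9)
        b = annotation.insert_nodule(lab, spec, seed=9)
        assert np.array_equal(a, b)

    def test_remove_after_insert_is_identity(self):
        px, lab = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=3))
        ins = annotation.insert_nodule(lab, NoduleSpec((31.0, 21.0), 8.0), seed=2)
        back = annotation.remove_nodule(ins, "all")
        assert np.array_equal(back, lab)

    def test_relocate_preserves_area_and_round_trips(self):
        px, lab = nodule_phantom(center=(31.0, 21.0), diameter=6.0)
        comp, _ = annotation.nodule_components(lab)
        rr, cc = np.nonzero(comp == 1)
        orig_centroid = (rr.mean(), cc.mean())
        area = len(rr)
        moved = annotation.relocate_nodule(lab, 1, (31.0, 43.0))
        assert int((moved == L.NODULE).sum()) == area
        back = annotation.relocate_nodule(moved, 1, orig_centroid)
        assert np.array_equal(back, lab)

    def test_relocate_to_exterior_rejected(self):
        px, lab = nodule_phantom()
        with pytest.raises(ConstraintError):
            annotation.relocate_nodule(lab, 1, (1.0, 1.0))

    def test_resize_identity_at_scale_one(self):
        px, lab = nodule_phantom()
        assert np.array_equal(annotation.resize_nodule(lab, 1, 1.0), lab)

    def test_resize_doubles_area_within_tolerance(self):
        px, lab = nodule_phantom(diameter=6.0)
        before = int((lab == L.NODULE).sum())
        out = annotation.resize_nodule(lab, 1, 2.0)
        after = int((out == L.NODULE).sum())
        assert after == pytest.approx(4 * before, rel=0.15)

    def test_resize_below_minimum_raises(self):
        px, lab = nodule_phantom(diameter=6.0)
        with pytest.raises(SizeError):
            annotation.resize_nodule(lab, 1, 0.01)

    def test_random_edit_sequences_keep_map_valid(self, rng):
        px, lab = nodule_phantom()
        current = lab
        lung_px = np.argwhere(current == L.LUNG)
        for step in range(30):
            op = rng.integers(0, 4)
            try:
                if op == 0:
                    r, c = lung_px[rng.integers(len(lung_px))]
                    current = annotation.insert_nodule(
                        current,
                        NoduleSpec((float(r), float(c)),
                                   float(rng.uniform(3, 9)),
                                   float(rng.uniform(0, 0.8))),
                        seed=int(rng.integers(1 << 31)),
                    )
                elif op == 1:
                    current = annotation.remove_nodule(current, "all")
                elif op == 2:
                    _, n = annotation.nodule_components(current)
                    if n:
                        r, c = lung_px[rng.integers(len(lung_px))]
                        current = annotation.relocate_nodule(
                            current, 1, (float(r), float(c))
                        )
                else:
                    _, n = annotation.nodule_components(current)
                    if n:
                        current = annotation.resize_nodule(
                            current, 1, float(rng.uniform(0.7, 1.5))
                        )
            except (ConstraintError, SizeError):
                continue  # rejected edits must leave the map untouched
            L.validate_map(current)
            # every nodule component touches lung-or-body, never exterior
            assert not np.any(current[lab == L.EXTERIOR] == L.NODULE)
            lung_px = np.argwhere(current == L.LUNG)


class TestOneHotAndDice:
    def test_one_hot_partitions_and_round_trips(self):
        px, lab = nodule_phantom()
        stack = annotation.one_hot(lab)
        assert stack.shape == (L.N_LABELS,) + lab.shape
        assert np.all(stack.sum(axis=0) == 1.0)
        assert np.array_equal(np.argmax(stack, axis=0).astype(np.uint8), lab)

    def test_exterior_only_map(self):
        stack = annotation.one_hot(np.zeros((8, 8), dtype=np.uint8))
        assert np.all(stack[0] == 1.0) and np.all(stack[1:] == 0.0)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (np.ones((4, 4)), np.ones((4, 4)), 1.0),
            (np.eye(4), 1 - np.eye(4), 0.0),
        ],
    )
    def test_dice_extremes(self, a, b, expected):
        assert annotation.dice(a.astype(int), b.astype(int), 1) == expected

    def test_dice_hand_count(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, :4] = 1  # |A| = 4
        b[0, 2:] = 1
        b[1, :2] = 1  # |B| = 4, overlap = 2
        assert annotation.dice(a, b, 1) == 0.5

    def test_dice_shape_mismatch(self):
        with pytest.raises(DataError):
            annotation.dice(np.zeros((3, 3)), np.zeros((4, 4)), 1)

    def test_dice_both_empty_is_one(self):
        assert annotation.dice(np.zeros((3, 3)), np.zeros((3, 3)), 5) == 1.0


class TestMapIO:
    def test_npz_round_trip(self, tmp_path):
        px, lab = nodule_phantom()
        p = tmp_path / "map.npz"
        annotation.save_map(lab, p)
        assert np.array_equal(annotation.load_map(p), lab)

    def test_indexed_png_preserves_labels(self, tmp_path):
        from PIL import Image

        px, lab = nodule_phantom()
        p = tmp_path / "map.png"
        annotation.save_map_png(lab, p)
        back = np.asarray(Image.open(p))
        assert np.array_equal(back, lab)
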