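"""Action stacks, undo, erase walls and frame-to-frame propagation."""

import numpy as np
import pytest

from conftest import box_closure_oracle
from depthmask import (ActionStack, ContractError, DepthFrame, SelectionAction,
                       apply_stack, bridge_pixels, frame_to_points,
                       generate_scene, load_session, propagate,
                       propagate_batch, propagate_sequence, save_session,
                       scene_preset, torso_seed_pixel, undo)


def flat_frame(w=8, h=8, depth=5.0, index=0):
    return DepthFrame(np.full((h, w), depth), index=index)


def manual(*pixels, brush=0):
    return SelectionAction(kind="manual", pixels=frozenset(pixels),
                           brush=brush)


def erase(*pixels, brush=0):
    return SelectionAction(kind="erase", pixels=frozenset(pixels),
                           brush=brush)


def auto(seed_pixel, b):
    return SelectionAction(kind="auto", seed_pixel=seed_pixel, b=b)


class TestActions:
    def test_action_validation(self):
        with pytest.raises(ContractError):
            SelectionAction(kind="auto")  # no seed
        with pytest.raises(ContractError):
            SelectionAction(kind="manual")  # no pixels
        with pytest.raises(ContractError):
            SelectionAction(kind="auto", seed_pixel=(1, 1), b=0.0)
        with pytest.raises(ContractError):
            SelectionAction(kind="lasso", pixels=frozenset({(1, 1)}))

    def test_brush_footprint_clipped(self):
        act = manual((0, 0), brush=1)
        assert act.selector_pixels(8, 8) == {(0, 0), (1, 0), (0, 1), (1, 1)}


class TestApplyStack:
    def test_single_manual_pixel(self):
        seg = apply_stack(flat_frame(), ActionStack([manual((1, 1))]))
        assert seg.mask.pixel_set() == {(1, 1)}

    def test_auto_on_isolated_figure_recovers_gt(self):
        spec = scene_preset("clean")
        seq, masks = generate_scene(spec)
        stack = ActionStack([auto(torso_seed_pixel(spec), 4.0)])
        seg = apply_stack(seq.frames[0], stack, params=None)
        np.testing.assert_array_equal(seg.mask.bits, masks[0].bits)

    def test_erase_dominates_everything(self):
        stack = ActionStack([manual((1, 1), (2, 2)), erase((2, 2))])
        seg = apply_stack(flat_frame(), stack)
        assert seg.mask.pixel_set() == {(1, 1)}

    def test_auto_seed_on_hole_falls_back_to_nearest(self):
        vals = np.full((6, 6), 5.0)
        vals[3, 3] = 0.0
        seg = apply_stack(DepthFrame(vals),
                          ActionStack([auto((3, 3), 1.5)]), params=None)
        assert not seg.failed_actions
        assert len(seg.mask.pixel_set()) == 35  # everything except the hole

    def test_auto_on_empty_cloud_records_failure(self):
        seg = apply_stack(DepthFrame(np.zeros((4, 4))),
                          ActionStack([auto((2, 2), 1.0)]), params=None)
        assert seg.failed_actions == [0]
        assert seg.mask.pixel_set() == set()

    def test_erase_wall_blocks_bridge(self):
        """An erase wall across the figure-floor bridge confines the auto
        cluster to the figure, matching the closure oracle run with the
        bridge points pre-removed."""
        spec = scene_preset("bridged")
        seq, masks = generate_scene(spec)
        frame = seq.frames[0]
        wall = bridge_pixels(spec)
        seed_px = torso_seed_pixel(spec)
        free = apply_stack(frame, ActionStack([auto(seed_px, 4.0)]),
                           params=None)
        walled = apply_stack(
            frame, ActionStack([erase(*wall), auto(seed_px, 4.0)]),
            params=None)
        free_auto = next(c for c in free.clusters if c.origin == "auto")
        walled_auto = next(c for c in walled.clusters if c.origin == "auto")
        assert len(walled_auto) < len(free_auto)
        np.testing.assert_array_equal(walled.mask.bits, masks[0].bits)
        # oracle: closure over the point list with bridge points removed
        pts = frame_to_points(frame)
        walls = {id(p) for p in pts if (p.px, p.py) in wall}
        seed_pt = next(p for p in pts if (p.px, p.py) == seed_px)
        oracle_ids = box_closure_oracle(pts, seed_pt, 4.0, removed=walls)
        oracle_pixels = {(p.px, p.py) for p in pts if id(p) in oracle_ids}
        assert walled_auto.pixel_set == oracle_pixels


class TestUndo:
    def test_undo_restores_previous_mask(self):
        a, b = manual((1, 1)), manual((2, 2))
        seg = apply_stack(flat_frame(), ActionStack([a, b]))
        undone = undo(seg)
        expected = apply_stack(flat_frame(), ActionStack([a]))
        np.testing.assert_array_equal(undone.mask.bits, expected.mask.bits)

    def test_undo_to_empty_mask(self):
        seg = apply_stack(flat_frame(), ActionStack([manual((1, 1))]))
        assert undo(seg).mask.pixel_set() == set()

    def test_undo_on_empty_warns_and_noop(self):
        seg = apply_stack(flat_frame(), ActionStack([]))
        with pytest.warns(UserWarning):
            assert undo(seg) is seg

    def test_random_push_undo_equals_replay_of_surviving_prefix(self, rng):
        frame = flat_frame(10, 10)
        actions = []
        seg = apply_stack(frame, ActionStack([]))
        for _ in range(60):
            if actions and rng.random() < 0.4:
                actions.pop()
                seg = undo(seg)
            else:
                kind = rng.choice(["manual", "erase"])
                px = (int(rng.integers(0, 10)), int(rng.integers(0, 10)))
                act = (manual(px, brush=1) if kind == "manual"
                       else erase(px, brush=1))
                actions.append(act)
                seg = apply_stack(frame, ActionStack(list(actions)))
            fresh = apply_stack(frame, ActionStack(list(actions)))
            np.testing.assert_array_equal(seg.mask.bits, fresh.mask.bits)


class TestPropagate:
    def test_static_scene_identical_masks(self):
        spec = scene_preset("clean", frame_count=2)
        seq, _ = generate_scene(spec)
        stack = ActionStack([auto(torso_seed_pixel(spec), 4.0)])
        seg0 = apply_stack(seq.frames[0], stack, params=None)
        seg1 = propagate(seg0, seq.frames[1], params=None)
        np.testing.assert_array_equal(seg0.mask.bits, seg1.mask.bits)

    def test_manual_transfers_pixels_regardless_of_depth(self):
        stack = ActionStack([manual((2, 3), (4, 5))])
        seg0 = apply_stack(flat_frame(depth=5.0), stack)
        seg1 = propagate(seg0, flat_frame(depth=50.0, index=1))
        np.testing.assert_array_equal(seg0.mask.bits, seg1.mask.bits)

    def test_moving_figure_tracked_with_gt_accuracy(self):
        from depthmask import accuracy
        spec = scene_preset("moving", frame_count=5)
        seq, masks = generate_scene(spec)
        stack = ActionStack([auto(torso_seed_pixel(spec, 0), 4.0)])
        seg = apply_stack(seq.frames[0], stack, params=None)
        segs = [seg] + propagate_batch(seg, seq.frames[1:], params=None)
        for s, m in zip(segs, masks):
            assert accuracy(s.mask, m) == 1.0

    def test_three_identical_frames(self):
        frames = [flat_frame(index=i) for i in range(3)]
        seg0 = apply_stack(frames[0], ActionStack([auto((4, 4), 2.0)]))
        segs = propagate_batch(seg0, frames[1:])
        for s in segs:
            np.testing.assert_array_equal(s.mask.bits, seg0.mask.bits)

    def test_exit_frame_fails_seed_and_stays_failed(self):
        spec = scene_preset("exit")
        seq, _ = generate_scene(spec)
        stack = ActionStack([auto(torso_seed_pixel(spec, 0), 4.0)])
        seg0 = apply_stack(seq.frames[0], stack, params=None)
        segs = propagate_batch(seg0, seq.frames[1:], params=None)
        for i, s in enumerate(segs, start=1):
            if i >= spec.exit_frame:
                assert s.failed_actions == [0]
                assert s.mask.pixel_set() == set()
            else:
                assert not s.failed_actions

    def test_windowed_equals_whole_sequence(self):
        spec = scene_preset("moving", frame_count=8)
        seq, _ = generate_scene(spec)
        stack = ActionStack([auto(torso_seed_pixel(spec, 0), 4.0)])
        seg0 = apply_stack(seq.frames[0], stack, params=None)
        whole = propagate_batch(seg0, seq.frames[1:], params=None)
        windowed = propagate_sequence(seg0, seq.frames[1:], window_frames=3,
                                      params=None)
        assert len(whole) == len(windowed)
        for a, b in zip(whole, windowed):
            np.testing.assert_array_equal(a.mask.bits, b.mask.bits)

    def test_dimension_mismatch_rejected(self):
        seg = apply_stack(flat_frame(8, 8), ActionStack([manual((1, 1))]))
        with pytest.raises(ContractError):
            propagate(seg, flat_frame(9, 9))


class TestSessionFiles:
    def test_roundtrip(self, tmp_path):
        stacks = {0: ActionStack([auto((3, 4), 2.5), manual((1, 1), brush=2),
                                  erase((5, 5))])}
        path = save_session(stacks, tmp_path / "s.json")
        back = load_session(path)
        assert back[0].actions == stacks[0].actions

    def test_invalid_session_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{\"nope\": 1}")
        with pytest.raises(ContractError):
            load_session(p)
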