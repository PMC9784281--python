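"""The gridworld MDP: tiling, transitions, rewards, observation encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesionrl.env import (
    Action,
    AgentState,
    GridSpec,
    LesionImage,
    REWARD_MOVE_OFF,
    REWARD_ON_LESION,
    REWARD_STAY_OFF,
    REWARD_VALUES,
    block_overlap,
    build_grid,
    encode_observation,
    initial_state,
    reachable_blocks,
    step,
)

from conftest import make_image


def make_240(lesion_pixels=((70, 130),)) -> LesionImage:
    return make_image(240, lesion_pixels=lesion_pixels)


class TestGrid:
    def test_default_tiling_is_4x4(self):
        grid = build_grid(make_240(), block_size=60)
        assert (grid.n_rows, grid.n_cols, grid.n_blocks) == (4, 4, 16)

    def test_block_120_gives_2x2(self):
        grid = build_grid(make_240(), block_size=120)
        assert (grid.n_rows, grid.n_cols) == (2, 2)

    def test_indivisible_dimension_names_axis(self):
        img = make_image(16)
        bad = LesionImage("bad", img.intensities[:-1, :], img.lesion_mask[:-1, :])
        with pytest.raises(ValueError, match="height"):
            build_grid(bad, block_size=4)

    def test_lesion_image_requires_positive_mask(self):
        with pytest.raises(ValueError, match="mask"):
            LesionImage("empty", np.zeros((8, 8), dtype=np.float32),
                        np.zeros((8, 8), dtype=bool))


class TestInitialState:
    def test_starts_top_left_and_is_pure(self, tiny_image, tiny_block_size):
        s1 = initial_state(tiny_image, tiny_block_size)
        s2 = initial_state(tiny_image, tiny_block_size)
        assert s1.block == (0, 0) == s2.block

    def test_encoder_marks_only_top_left_block(self, tiny_image, tiny_block_size):
        obs = encode_observation(initial_state(tiny_image, tiny_block_size))
        marked = np.argwhere(obs[1] > 0)
        assert marked.shape[0] == tiny_block_size**2
        assert marked.max() < tiny_block_size


class TestBlockOverlap:
    def test_single_pixel_hits_exactly_one_block(self):
        img = make_240(lesion_pixels=((70, 130),))
        grid = build_grid(img, 60)
        hits = {
            (r, c)
            for r in range(4)
            for c in range(4)
            if block_overlap(img, r, c, grid)
        }
        # pixel (70, 130) lies in rows [60,120), cols [120,180)
        assert hits == {(1, 2)}

    def test_straddling_lesion_hits_both_blocks(self):
        img = make_240(lesion_pixels=((59, 10), (60, 10)))
        grid = build_grid(img, 60)
        assert block_overlap(img, 0, 0, grid) and block_overlap(img, 1, 0, grid)

    def test_out_of_grid_raises(self, tiny_image, tiny_block_size):
        grid = build_grid(tiny_image, tiny_block_size)
        with pytest.raises(IndexError):
            block_overlap(tiny_image, 4, 0, grid)


class TestStep:
    def test_reward_scheme(self, tiny_image, tiny_block_size):
        # lesion in block (2, 2); start at (0, 0)
        s = initial_state(tiny_image, tiny_block_size)
        assert step(s, Action.STAY).reward == REWARD_STAY_OFF
        assert step(s, Action.DOWN).reward == REWARD_MOVE_OFF
        on = AgentState(tiny_image, s.grid, 2, 2)
        assert step(on, Action.STAY).reward == REWARD_ON_LESION
        left = AgentState(tiny_image, s.grid, 2, 1)
        assert step(left, Action.RIGHT).reward == REWARD_ON_LESION

    def test_clipped_move_keeps_block_and_uses_move_rule(self, tiny_image,
                                                         tiny_block_size):
        grid = build_grid(tiny_image, tiny_block_size)
        corner = AgentState(tiny_image, grid, grid.n_rows - 1, grid.n_cols - 1)
        out = step(corner, Action.DOWN)
        assert out.clipped and out.next_state.block == corner.block
        assert out.reward == REWARD_MOVE_OFF  # lesion is elsewhere? (3,3) no
        # lesion block (2,2): corner (3,3) does not overlap

    def test_reward_branch_matches_block_overlap_everywhere(self, tiny_image,
                                                            tiny_block_size):
        """Brute force over all 16 blocks x 3 actions."""
        grid = build_grid(tiny_image, tiny_block_size)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                state = AgentState(tiny_image, grid, r, c)
                for a in Action:
                    out = step(state, a)
                    lands_on = block_overlap(tiny_image, out.next_state.row,
                                             out.next_state.col, grid)
                    if lands_on:
                        assert out.reward == REWARD_ON_LESION
                    elif a is Action.STAY:
                        assert out.reward == REWARD_STAY_OFF
                    else:
                        assert out.reward == REWARD_MOVE_OFF
                    assert out.reward in REWARD_VALUES

    @settings(deadline=None)
    @given(st.lists(st.sampled_from(list(Action)), min_size=1, max_size=30))
    def test_rows_cols_never_decrease_and_determinism(self, actions):
        img = make_image(16, lesion_pixels=((10, 10),))
        state = initial_state(img, 4)
        for a in actions:
            out1 = step(state, a)
            out2 = step(state, a)
            assert (out1.reward, out1.next_state.block) == \
                   (out2.reward, out2.next_state.block)
            assert out1.next_state.row >= state.row
            assert out1.next_state.col >= state.col
            state = out1.next_state


class TestEncodeObservation:
    def test_position_channel_pixel_count(self):
        img = make_240()
        obs = encode_observation(initial_state(img, 60))
        assert obs.shape == (2, 240, 240)
        assert int(obs[1].sum()) == 3600  # 60^2

    def test_image_channel_is_state_independent(self, tiny_image, tiny_block_size):
        grid = build_grid(tiny_image, tiny_block_size)
        a = encode_observation(AgentState(tiny_image, grid, 0, 0))
        b = encode_observation(AgentState(tiny_image, grid, 2, 1))
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[0], tiny_image.intensities)
        assert not np.array_equal(a[1], b[1])


class TestReachability:
    def test_full_grid_reachable(self, tiny_image, tiny_block_size):
        grid = build_grid(tiny_image, tiny_block_size)
        blocks = reachable_blocks(grid)
        assert blocks == {(r, c) for r in range(4) for c in range(4)}

    def test_single_block_grid(self):
        assert reachable_blocks(GridSpec(4, 4, 4)) == {(0, 0)}

    def test_monotone_shortest_path_length(self, tiny_image, tiny_block_size):
        """Block (3, 0) takes exactly row+col = 3 moves from the corner."""
        state = initial_state(tiny_image, tiny_block_size)
        for _ in range(3):
            state = step(state, Action.DOWN).next_state
        assert state.block == (3, 0)
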