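import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latticepick.core import ExpansionParams, Orientation, TransitionList
from latticepick.matching import SearchGrid, constrained_align, masked_cc
from latticepick.synthetic import (
    LatticeTruth,
    default_template,
    embed_template,
    planar_frame,
    render_tomogram,
    spherical_mask,
)


def _params(**kw):
    defaults = dict(
        transition_list=TransitionList([[8, 0, 0]]),
        spacing=8.0,
        cc_threshold=0.5,
        box_size=16,
        angular_ranges=(8, 8, 8),
        angular_steps=(4, 4, 4),
        translational_range=2.0,
        translational_step=1.0,
    )
    defaults.update(kw)
    return ExpansionParams(**defaults)


class TestMaskedCC:
    def test_self_correlation_is_one(self, rng):
        v = rng.standard_normal((6, 6, 6))
        assert abs(masked_cc(v, v) - 1.0) < 1e-9

    def test_negation_gives_minus_one(self, rng):
        v = rng.standard_normal((6, 6, 6))
        assert abs(masked_cc(v, -v) + 1.0) < 1e-9

    def test_matches_brute_force_sum_oracle(self, rng):
        a = rng.standard_normal((5, 5, 5))
        b = rng.standard_normal((5, 5, 5))
        mask = (rng.random((5, 5, 5)) > 0.4).astype(float)
        # elementwise-sum oracle over the masked voxels
        w = mask.ravel()
        av, bv = a.ravel(), b.ravel()
        wsum = w.sum()
        ma = (w * av).sum() / wsum
        mb = (w * bv).sum() / wsum
        cov = (w * (av - ma) * (bv - mb)).sum() / wsum
        va = (w * (av - ma) ** 2).sum() / wsum
        vb = (w * (bv - mb) ** 2).sum() / wsum
        expected = cov / np.sqrt(va * vb)
        assert abs(masked_cc(a, b, mask) - expected) < 1e-9

    def test_symmetry(self, rng):
        a = rng.standard_normal((4, 4, 4))
        b = rng.standard_normal((4, 4, 4))
        assert abs(masked_cc(a, b) - masked_cc(b, a)) < 1e-12

    @given(alpha=st.floats(0.1, 50.0), beta=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_intensity_invariance(self, alpha, beta):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((4, 4, 4))
        b = rng.standard_normal((4, 4, 4))
        assert abs(masked_cc(alpha * a + beta, b) - masked_cc(a, b)) < 1e-9

    def test_constant_volume_returns_zero(self):
        a = np.zeros((4, 4, 4))
        b = np.arange(64, dtype=float).reshape(4, 4, 4)
        assert masked_cc(a, b) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes differ"):
            masked_cc(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))

    def test_mask_values_validated(self):
        v = np.ones((3, 3, 3))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            masked_cc(v, v, np.full((3, 3, 3), 2.0))


class TestSearchGrid:
    def test_includes_zero_offset(self):
        grid = SearchGrid.from_params(_params())
        assert any(n < 1e-9 for n in grid.angle_norms)
        assert any(np.linalg.norm(s) < 1e-9 for s in grid.shifts)

    def test_sizes(self):
        grid = SearchGrid.from_params(_params())
        assert len(grid.rotations) == 5**3
        assert len(grid.shifts) == 5**3

    def test_zero_ranges_degenerate(self):
        grid = SearchGrid.from_params(
            _params(angular_ranges=(0, 0, 0), translational_range=0.0)
        )
        assert len(grid.rotations) == 1 and len(grid.shifts) == 1


class TestConstrainedAlign:
    def _single_site(self, orientation=None, pos=(24.0, 24.0, 24.0)):
        template = default_template()
        frame = orientation or planar_frame()
        truth = LatticeTruth(
            np.array([pos]), [frame], np.array([0]), spacing=8.0
        )
        vol = render_tomogram(truth, template, (48, 48, 48))
        return vol, np.array(pos), frame, embed_template(template, 16)

    def test_degenerate_grid_returns_prior_with_its_cc(self):
        vol, pos, frame, ref = self._single_site()
        params = _params(angular_ranges=(0, 0, 0), translational_range=0.0)
        res = constrained_align(vol, pos, frame, ref, None, params)
        assert np.allclose(res.position, pos)
        assert res.orientation.angle_to(frame) < 1e-6
        # the degenerate-grid cc equals a direct masked_cc of the
        # extracted box against the frame-rotated reference
        from scipy.ndimage import map_coordinates

        c = 8
        ax = np.arange(16) - c
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        g = np.stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
        sub = map_coordinates(vol.astype(float), pos[:, None] + g, order=1)
        rot = map_coordinates(ref.astype(float), frame.matrix.T @ g + c, order=1)
        assert abs(res.cc - masked_cc(rot.reshape(16, 16, 16), sub.reshape(16, 16, 16))) < 1e-5

    def test_recovers_known_offset(self):
        # template rendered 2 voxels + 8 degrees (about local Y) away
        # from the prior pose; grid step (1 voxel, 4 degrees)
        true_frame = planar_frame(spin_deg=8.0)
        true_pos = np.array([26.0, 24.0, 24.0])
        vol, _, _, ref = self._single_site(orientation=true_frame, pos=tuple(true_pos))
        prior_pos = true_pos - np.array([2.0, 0.0, 0.0])
        prior = planar_frame()
        mask = spherical_mask(16, 4.5)
        res = constrained_align(vol, prior_pos, prior, ref, mask, _params(), refine=False)
        assert np.linalg.norm(res.position - true_pos) <= 1.0
        assert res.orientation.angle_to(true_frame) <= 4.0
        assert res.cc > 0.9

    def test_empty_region_scores_zero(self):
        vol = np.zeros((48, 48, 48), dtype=np.float32)
        ref = embed_template(default_template(), 16)
        params = _params(angular_ranges=(0, 0, 0), translational_range=0.0)
        res = constrained_align(vol, np.array([24.0, 24, 24]), Orientation.identity(), ref, None, params)
        assert res.cc == 0.0

    def test_cc_at_least_prior_pose_cc(self):
        vol, pos, frame, ref = self._single_site()
        mask = spherical_mask(16, 4.5)
        prior_pos = pos + np.array([0.7, -0.4, 0.2])
        degenerate = _params(angular_ranges=(0, 0, 0), translational_range=0.0)
        prior_cc = constrained_align(vol, prior_pos, frame, ref, mask, degenerate).cc
        full = constrained_align(vol, prior_pos, frame, ref, mask, _params(), refine=False)
        assert full.cc >= prior_cc - 1e-6

    def test_out_of_bounds_raises_with_name(self):
        vol = np.zeros((20, 20, 20), dtype=np.float32)
        ref = embed_template(default_template(), 16)
        with pytest.raises(ValueError, match="part_7"):
            constrained_align(
                vol, np.array([2.0, 10, 10]), Orientation.identity(), ref, None,
                _params(), name="part_7",
            )

    def test_reference_shape_mismatch(self):
        vol = np.zeros((48, 48, 48), dtype=np.float32)
        with pytest.raises(ValueError, match="box_size"):
            constrained_align(
                vol, np.array([24.0, 24, 24]), Orientation.identity(),
                np.zeros((8, 8, 8)), None, _params(),
            )


class TestFig3Separation:
    def test_on_site_high_off_site_low(self, fig3):
        """On-site candidates score cc > 0.9; off-site ones < 0.2."""
        from scipy.spatial import cKDTree

        params = fig3.default_params()
        ref = fig3.reference(16)
        mask = fig3.mask(16)
        tree = cKDTree(fig3.truth.positions)
        frame = planar_frame()
        from latticepick.expansion import generate_candidates
        from latticepick.core import ParticleSet

        seeds = ParticleSet([s.copy() for s in fig3.seeds], "fig3")
        cands = generate_candidates(fig3.seeds, fig3.transition_list, seeds, params.d_min)
        on = off = 0
        for c in cands:
            res = constrained_align(
                fig3.volume, c.position, frame, ref, mask, params
            )
            d, _ = tree.query(c.position)
            if d < 1.0:
                assert res.cc > 0.9
                on += 1
            else:
                assert res.cc < 0.2
                off += 1
        assert on == 14 and off == 4
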