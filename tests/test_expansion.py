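import numpy as np
import pytest
from scipy.spatial import cKDTree

from latticepick.core import (
    ExpansionParams,
    Orientation,
    Particle,
    ParticleSet,
    TransitionList,
)
from latticepick.expansion import (
    ExpansionRun,
    IterationRecord,
    generate_candidates,
    load_cache,
    load_record,
    regather,
    run_expansion,
    save_record,
)
from latticepick.synthetic import (
    LatticeTruth,
    default_template,
    embed_template,
    filament_transitions,
    hexagonal_transitions,
    make_filament_lattice,
    render_tomogram,
    spherical_mask,
)


class TestGenerateCandidates:
    def test_single_seed_six_transitions(self):
        seed = Particle(position=(0.0, 0.0, 0.0), orientation=Orientation.identity())
        # identity orientation: local X-Z plane is the tomogram X-Z plane
        trans = hexagonal_transitions(8.0)
        cands = generate_candidates([seed], trans, ParticleSet(), d_min=4.0)
        assert len(cands) == 6
        got = sorted(tuple(np.round(c.position, 6)) for c in cands)
        want = sorted(
            tuple(np.round(t, 6)) for t in trans.transitions
        )
        assert got == want

    def test_fig3_three_seeds_give_18(self, fig3, fig3_seeds):
        cands = generate_candidates(
            fig3.seeds, fig3.transition_list, fig3_seeds, d_min=4.0
        )
        assert len(cands) == 18

    def test_candidates_inherit_seed_orientation(self, fig3, fig3_seeds):
        cands = generate_candidates(
            fig3.seeds, fig3.transition_list, fig3_seeds, d_min=4.0
        )
        for c in cands:
            assert c.orientation.angle_to(fig3.seeds[0].orientation) < 1e-9

    def test_picked_positions_are_excluded(self):
        seed = Particle(position=(0.0, 0.0, 0.0))
        trans = hexagonal_transitions(8.0)
        picked = ParticleSet(
            [Particle(position=(8.0, 0.0, 0.0), status="accepted"), seed]
        )
        cands = generate_candidates([seed], trans, picked, d_min=4.0)
        assert len(cands) == 5

    def test_mutual_dedup_first_kept(self):
        a = Particle(position=(0.0, 0.0, 0.0))
        b = Particle(position=(8.0, 0.0, 0.0))
        trans = TransitionList([[8.0, 0, 0], [-8.0, 0, 0]])
        cands = generate_candidates([a, b], trans, ParticleSet(), d_min=4.0)
        # a proposes (8,0,0) and (-8,0,0); b proposes (16,0,0) and (0,0,0):
        # all four are distinct positions, no dedup
        assert len(cands) == 4
        cands2 = generate_candidates([a, a], trans, ParticleSet(), d_min=4.0)
        assert len(cands2) == 2  # duplicate seed's proposals collapse

    def test_symmetric_transition_fan_invariant_to_180_spin(self):
        """A seed spun 180 degrees about local Y proposes the same positions."""
        trans = hexagonal_transitions(8.0)
        seed = Particle(position=(0.0, 0.0, 0.0), orientation=Orientation.identity())
        spun = Particle(
            position=(0.0, 0.0, 0.0),
            orientation=Orientation.from_rotvec([0.0, 180.0, 0.0]),
        )
        p1 = sorted(
            tuple(np.round(c.position, 6))
            for c in generate_candidates([seed], trans, ParticleSet(), 4.0)
        )
        p2 = sorted(
            tuple(np.round(c.position, 6))
            for c in generate_candidates([spun], trans, ParticleSet(), 4.0)
        )
        assert np.allclose(p1, p2, atol=1e-6)


@pytest.fixture(scope="module")
def fig3_run(request):
    fig3 = request.getfixturevalue("fig3")
    seeds = ParticleSet([s.copy() for s in fig3.seeds], "fig3")
    params = fig3.default_params()
    return run_expansion(
        fig3.volume, seeds, fig3.reference(16), fig3.mask(16), params
    ), params, fig3


class TestRunExpansion:
    def test_fig3_iteration0_accepts_14(self, fig3_run):
        run, _, _ = fig3_run
        assert len(run.records[0].candidates_raw) == 18
        assert len(run.records[0].accepted) == 14

    def test_fig3_recovers_whole_patch(self, fig3_run):
        run, params, fig3 = fig3_run
        assert run.stop_reason == "no_candidates"
        patch_a = fig3.truth.positions[fig3.truth.patch_ids == 0]
        assert len(run.final) == len(patch_a)
        d, _ = cKDTree(patch_a).query(run.final.positions())
        assert np.all(d < params.d_min)

    def test_final_set_is_dedup_clean(self, fig3_run):
        run, params, _ = fig3_run
        assert run.final.min_pair_distance() >= params.d_min

    def test_accept_reject_partition(self, fig3_run):
        run, params, _ = fig3_run
        for rec in run.records:
            assert len(rec.accepted) + len(rec.rejected) + len(rec.duplicates) == len(
                rec.candidates_aligned
            ) + len(rec.duplicates)
            for p in rec.accepted:
                assert p.cc >= params.cc_threshold
            for p in rec.rejected:
                assert np.isnan(p.cc) or p.cc < params.cc_threshold

    def test_iteration_added_tracks_first_acceptance(self, fig3_run):
        run, _, _ = fig3_run
        for p in run.final:
            if p.status == "seed":
                assert p.iteration_added == 0
        for i, rec in enumerate(run.records):
            for p in rec.accepted:
                assert p.iteration_added == i

    def test_straight_filament_chain(self):
        truth = make_filament_lattice(9, 8.0, curvature=0.0, start=(24.0, 24.0, 24.0))
        tpl = default_template()
        vol = render_tomogram(truth, tpl, (120, 48, 48))
        params = ExpansionParams(
            transition_list=filament_transitions(8.0),
            spacing=8.0,
            cc_threshold=0.5,
            box_size=16,
            angular_ranges=(8, 8, 8),
            translational_range=2,
            max_iterations=20,
        )
        seed_idx = 4  # interior seed
        seeds = ParticleSet(
            [Particle(truth.positions[seed_idx], truth.frames[seed_idx], status="seed")]
        )
        run = run_expansion(vol, seeds, embed_template(tpl, 16), spherical_mask(16, 3.4), params)
        assert run.stop_reason == "no_candidates"
        assert len(run.final) == 9
        d, _ = cKDTree(truth.positions).query(run.final.positions())
        assert np.all(d < 4.0)

    def test_zero_iterations_returns_seeds(self, fig3):
        seeds = ParticleSet([s.copy() for s in fig3.seeds], "fig3")
        params = fig3.default_params()
        params.max_iterations = 0
        run = run_expansion(
            fig3.volume, seeds, fig3.reference(16), fig3.mask(16), params
        )
        assert len(run.final) == 3
        assert run.records == []

    def test_empty_seed_set_raises(self, fig3):
        with pytest.raises(ValueError, match="non-empty"):
            run_expansion(
                fig3.volume, ParticleSet(), fig3.reference(16), fig3.mask(16),
                fig3.default_params(),
            )

    def test_out_of_volume_candidates_rejected_not_fatal(self):
        # seed near the volume edge: some candidates fall outside
        truth = make_filament_lattice(3, 8.0, curvature=0.0, start=(12.0, 24.0, 24.0))
        tpl = default_template()
        vol = render_tomogram(truth, tpl, (48, 48, 48))
        params = ExpansionParams(
            transition_list=filament_transitions(8.0),
            spacing=8.0,
            cc_threshold=0.5,
            box_size=16,
            translational_range=2,
            max_iterations=3,
        )
        seeds = ParticleSet([Particle(truth.positions[0], truth.frames[0], status="seed")])
        run = run_expansion(vol, seeds, embed_template(tpl, 16), None, params)
        nan_rejected = [
            p for rec in run.records for p in rec.rejected if np.isnan(p.cc)
        ]
        assert nan_rejected  # the out-of-bounds neighbor was rejected, run survived


class TestCachePersistence:
    def test_record_roundtrip(self, tmp_path, fig3_run):
        run, _, _ = fig3_run
        rec = run.records[0]
        save_record(rec, tmp_path / "iteration_000.json")
        back = load_record(tmp_path / "iteration_000.json")
        assert back.iteration == rec.iteration
        assert len(back.accepted) == len(rec.accepted)
        for a, b in zip(rec.accepted, back.accepted):
            assert np.allclose(a.position, b.position)
            assert a.orientation.angle_to(b.orientation) < 1e-9
            assert a.cc == pytest.approx(b.cc)

    def test_cache_dir_layout(self, tmp_path, fig3):
        seeds = ParticleSet([s.copy() for s in fig3.seeds], "fig3")
        params = fig3.default_params()
        params.max_iterations = 2
        run = run_expansion(
            fig3.volume, seeds, fig3.reference(16), fig3.mask(16), params,
            cache_dir=tmp_path / "cache",
        )
        files = sorted((tmp_path / "cache").glob("iteration_*.json"))
        assert len(files) == len(run.records) == 2
        cache = load_cache(tmp_path / "cache")
        assert [r.iteration for r in cache] == [0, 1]


class TestRegather:
    def test_same_threshold_reproduces_final(self, fig3_run):
        run, params, fig3 = fig3_run
        seeds = ParticleSet([s.copy() for s in fig3.seeds], "fig3")
        re = regather(run.records, params.cc_threshold, seeds, params.d_min)
        a = np.round(np.sort(run.final.positions(), axis=0), 6)
        b = np.round(np.sort(re.positions(), axis=0), 6)
        assert np.allclose(a, b, atol=1e-6)

    def test_higher_threshold_gives_subset(self, fig3_run):
        run, params, fig3 = fig3_run
        seeds = ParticleSet([s.copy() for s in fig3.seeds], "fig3")
        lo = regather(run.records, 0.5, seeds, params.d_min)
        hi = regather(run.records, 0.99, seeds, params.d_min)
        lo_pos = {tuple(np.round(p.position, 6)) for p in lo}
        hi_pos = {tuple(np.round(p.position, 6)) for p in hi}
        assert hi_pos <= lo_pos
        assert len(hi) < len(lo)

    def test_matches_independent_refilter_oracle(self, fig3_run):
        run, params, fig3 = fig3_run
        threshold = 0.7
        seeds = ParticleSet([s.copy() for s in fig3.seeds], "fig3")
        re = regather(run.records, threshold, seeds, params.d_min)

        # brute-force oracle: walk cached candidates in iteration order,
        # keep those above threshold and not within d_min of a keeper
        kept = [s.position for s in seeds]
        for rec in sorted(run.records, key=lambda r: r.iteration):
            for c in rec.candidates_aligned:
                if c.cc is None or np.isnan(c.cc) or c.cc < threshold:
                    continue
                if any(np.linalg.norm(c.position - q) < params.d_min for q in kept):
                    continue
                kept.append(c.position)
        assert len(re) == len(kept)
        a = np.round(np.sort(np.stack(kept), axis=0), 6)
        b = np.round(np.sort(re.positions(), axis=0), 6)
        assert np.allclose(a, b, atol=1e-6)

    def test_empty_cache_raises(self, fig3_seeds):
        with pytest.raises(ValueError, match="nothing to regather"):
            regather([], 0.5, fig3_seeds, 4.0)
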