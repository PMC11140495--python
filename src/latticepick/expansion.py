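"""Iterative lattice tracing: candidate generation, correlation filtering,
iteration bookkeeping, on-disk caching, and the regather (re-threshold) mode.

Each iteration proposes neighbor positions of the current seeds through
the local-frame transition list, aligns every candidate to the reference
with a restricted grid search, and accepts those whose correlation
reaches the threshold; accepted particles seed the next iteration. A
position counts as picked once it is a seed or accepted; rejected
positions may be re-proposed from a different seed, but at most
``attempt_cap`` times per spatial cell of side ``d_min`` so every run
terminates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from latticepick.core import ExpansionParams, Orientation, Particle, ParticleSet, TransitionList
from latticepick.matching import SearchGrid, check_box_fits, constrained_align

__all__ = [
    "IterationRecord",
    "ExpansionRun",
    "generate_candidates",
    "run_expansion",
    "regather",
    "save_record",
    "load_record",
    "load_cache",
]


@dataclass
class IterationRecord:
    """Full bookkeeping of one expansion iteration."""

    iteration: int
    seeds_in: list[Particle]
    candidates_raw: list[Particle]
    candidates_aligned: list[Particle]
    accepted: list[Particle]
    rejected: list[Particle]
    # Candidates whose refined position collided (within d_min) with an
    # already-picked site; merged away, not part of accepted/rejected.
    duplicates: list[Particle] = field(default_factory=list)


@dataclass
class ExpansionRun:
    """All iteration records plus the deduplicated final particle set."""

    records: list[IterationRecord]
    final: ParticleSet
    stop_reason: str = ""


def _too_close(position: np.ndarray, others: Sequence[np.ndarray], d_min: float) -> bool:
    for q in others:
        if np.linalg.norm(position - q) < d_min:
            return True
    return False


def generate_candidates(
    seeds: Sequence[Particle],
    transitions: TransitionList,
    picked: ParticleSet,
    d_min: float,
) -> list[Particle]:
    """Propose unpicked neighbor positions of ``seeds`` via the transition list.

    For each seed ``s`` and transition ``t`` the candidate sits at
    ``position(s) + R(s) t`` with the seed's orientation as prior pose.
    Candidates within ``d_min`` of any picked particle, or of an
    earlier-generated candidate in the same call, are dropped (first
    occurrence kept; enumeration is seed order, then transition order).
    """
    picked_positions = [
        p.position for p in picked if p.status in ("seed", "accepted")
    ]
    out: list[Particle] = []
    out_positions: list[np.ndarray] = []
    for s in seeds:
        for t in transitions:
            pos = s.position + s.orientation.apply(t)
            if _too_close(pos, picked_positions, d_min):
                continue
            if _too_close(pos, out_positions, d_min):
                continue
            out.append(
                Particle(
                    position=pos,
                    orientation=s.orientation,
                    status="candidate",
                    iteration_added=s.iteration_added,
                    tomo_name=s.tomo_name,
                )
            )
            out_positions.append(pos)
    return out


def _cell(position: np.ndarray, d_min: float) -> tuple[int, int, int]:
    return tuple(int(math.floor(c / d_min)) for c in position)


def run_expansion(
    tomo: np.ndarray,
    seeds: ParticleSet,
    reference: np.ndarray,
    mask: Optional[np.ndarray],
    params: ExpansionParams,
    cache_dir: Optional[Path] = None,
    attempt_cap: int = 3,
    log: Optional[Callable[[str], None]] = None,
    order: int = 1,
    retry_sweeps: int = 0,
) -> ExpansionRun:
    """Iterate candidate generation, alignment and thresholding until done.

    Stops when no candidates remain or after ``params.max_iterations``
    iterations. All iteration-0 seeds and every accepted particle enter
    the final set; candidates whose search box leaves the volume are
    rejected without alignment (``cc`` = NaN). When ``cache_dir`` is
    given, one JSON record per iteration is written there.

    With ``retry_sweeps > 0``, after the normal loop ends every particle
    of the final set proposes its neighbors again (per-cell attempt caps
    still bound the total work). Unpicked holes left behind by the
    passing wavefront then get proposals from all surrounding picked
    particles — useful where the lattice orientation field is rough and
    the first prior was poor.
    """
    if len(seeds) == 0:
        raise ValueError("seed set must be non-empty")
    box = params.box_size
    if reference.shape != (box, box, box):
        raise ValueError(
            f"reference shape {reference.shape} does not match box_size {box}"
        )
    if mask is not None and mask.shape != (box, box, box):
        raise ValueError(f"mask shape {mask.shape} does not match box_size {box}")
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
    emit = log if log is not None else (lambda _msg: None)

    grid = SearchGrid.from_params(params)
    # Second, fine translational pass around the coarse optimum: sharp
    # templates make the correlation peak narrow in position, so the
    # coarse argmax can trade rotation against a half-voxel position
    # error; re-searching all rotations on a half-step shift grid around
    # the refined position removes that coupling.
    fine_params = ExpansionParams(
        transition_list=params.transition_list,
        spacing=params.spacing,
        cc_threshold=params.cc_threshold,
        box_size=params.box_size,
        angular_ranges=params.angular_ranges,
        angular_steps=params.angular_steps,
        translational_range=0.5 * params.translational_step,
        translational_step=0.5 * params.translational_step,
        max_iterations=params.max_iterations,
        d_min=params.d_min,
    )
    fine_grid = SearchGrid.from_params(fine_params)
    d_min = params.d_min
    if order > 1:
        from scipy.ndimage import spline_filter

        tomo = spline_filter(tomo.astype(np.float32), order=order, mode="constant")
        reference = spline_filter(
            reference.astype(np.float32), order=order, mode="constant"
        )
    picked = ParticleSet(
        [p.copy(status="seed") for p in seeds], seeds.tomo_name, seeds.voxel_size
    )
    final = list(picked.particles)
    current = list(picked.particles)
    attempts: dict[tuple[int, int, int], int] = {}
    records: list[IterationRecord] = []
    stop_reason = "max_iterations"

    def _round(iteration: int, proposers: list[Particle], tag: str = "iteration"):
        """One propose-align-threshold round; returns accepted or None."""
        raw = generate_candidates(proposers, params.transition_list, picked, d_min)
        raw = [
            c
            for c in raw
            if attempts.setdefault(_cell(c.position, d_min), 0) < attempt_cap
        ]
        for c in raw:
            attempts[_cell(c.position, d_min)] += 1
        if not raw:
            emit(f"{tag} {iteration}: no candidates")
            return None

        aligned: list[Particle] = []
        for c in raw:
            if not check_box_fits(
                tomo.shape, c.position, box, params.translational_range
            ):
                aligned.append(c.copy(status="rejected", cc=float("nan")))
                continue
            res = constrained_align(
                tomo,
                c.position,
                c.orientation,
                reference,
                mask,
                params,
                grid=grid,
                order=order,
                prefiltered=True,
            )
            # Hopeless candidates (empty or off-lattice positions) are
            # not worth the fine pass; the margin covers how much the
            # coarse pass may undershoot the refined score.
            if res.cc >= params.cc_threshold - 0.2 and check_box_fits(
                tomo.shape, res.position, box, fine_params.translational_range + 1
            ):
                res = constrained_align(
                    tomo,
                    res.position,
                    c.orientation,
                    reference,
                    mask,
                    fine_params,
                    grid=fine_grid,
                    order=order,
                    prefiltered=True,
                )
            aligned.append(
                c.copy(
                    position=res.position,
                    orientation=res.orientation,
                    cc=res.cc,
                    status="candidate",
                )
            )

        accepted: list[Particle] = []
        rejected: list[Particle] = []
        duplicates: list[Particle] = []
        duplicate_idx: set[int] = set()
        picked_positions = [p.position for p in picked]
        for i, c in enumerate(aligned):
            cc = c.cc if c.cc is not None else float("nan")
            if not (cc == cc) or cc < params.cc_threshold:  # NaN-safe
                rejected.append(c.copy(status="rejected", iteration_added=iteration))
            elif _too_close(c.position, picked_positions, d_min):
                duplicates.append(c.copy(iteration_added=iteration))
                duplicate_idx.add(i)
            else:
                acc = c.copy(status="accepted", iteration_added=iteration)
                accepted.append(acc)
                picked_positions.append(acc.position)

        record = IterationRecord(
            iteration=iteration,
            seeds_in=[p.copy() for p in proposers],
            candidates_raw=raw,
            candidates_aligned=[
                c for i, c in enumerate(aligned) if i not in duplicate_idx
            ],
            accepted=accepted,
            rejected=rejected,
            duplicates=duplicates,
        )
        records.append(record)
        if cache_dir is not None:
            save_record(record, cache_dir / f"iteration_{iteration:03d}.json")
        emit(
            f"{tag} {iteration}: seeds {len(proposers)}, "
            f"candidates {len(raw)}, accepted {len(accepted)}, "
            f"rejected {len(rejected)}"
            + (f", duplicates {len(duplicates)}" if duplicates else "")
        )

        for p in accepted:
            picked.add(p)
            final.append(p)
        return accepted

    for iteration in range(params.max_iterations):
        accepted = _round(iteration, current)
        if accepted is None or not accepted:
            stop_reason = "no_candidates"
            break
        current = accepted

    # Candidate dedup keeps only the first proposal per unpicked cell,
    # so each sweep shuffles the proposer order (deterministically) to
    # give remaining holes a different prior orientation each time. On a
    # hexagonal lattice the local orientation field is only defined up
    # to 60 degrees; where it turns sharply (disclinations, grain
    # seams) every direct prior can sit a full branch off, so sweeps
    # also cycle branch-rotated spin priors (0, +60, -60 about local Y).
    import random

    spin_offsets = (0.0, 60.0, -60.0, 120.0, -120.0)
    for sweep in range(retry_sweeps):
        off = spin_offsets[sweep % len(spin_offsets)]
        proposers = []
        for p in final:
            if off == 0.0:
                proposers.append(p)
            else:
                spun = Orientation.from_rotvec([0.0, off, 0.0])
                proposers.append(
                    p.copy(orientation=p.orientation.compose(spun))
                )
        random.Random(sweep).shuffle(proposers)
        accepted = _round(len(records), proposers, tag="retry sweep")
        if accepted is None:
            break

    final_set = ParticleSet(final, seeds.tomo_name, seeds.voxel_size)
    return ExpansionRun(records=records, final=final_set, stop_reason=stop_reason)


def polish_orientations(
    tomo: np.ndarray,
    particles: ParticleSet,
    reference: np.ndarray,
    mask: Optional[np.ndarray],
    params: ExpansionParams,
    spin_range: float = 64.0,
    passes: int = 2,
    order: int = 1,
) -> ParticleSet:
    """Re-align every scored particle around its own pose, spin-wide.

    During expansion a particle's spin prior comes from its proposing
    neighbor; where the lattice orientation field turns quickly (seams,
    five-fold sites) the truth spin can sit outside the restricted
    search range, leaving the accepted orientation clipped or on a wrong
    60-degree branch. This pass re-searches a wide spin range (with the
    tilt window narrowed to one step) around each particle's current
    pose; positions move at most half a voxel. Seeds without a score are
    left untouched.
    """
    pol_params = ExpansionParams(
        transition_list=params.transition_list,
        spacing=params.spacing,
        cc_threshold=params.cc_threshold,
        box_size=params.box_size,
        angular_ranges=(params.angular_steps[0], spin_range, params.angular_steps[2]),
        angular_steps=params.angular_steps,
        translational_range=1.0,
        translational_step=0.5,
        d_min=params.d_min,
    )
    grid = SearchGrid.from_params(pol_params)
    if order > 1:
        from scipy.ndimage import spline_filter

        tomo = spline_filter(tomo.astype(np.float32), order=order, mode="constant")
        reference = spline_filter(
            reference.astype(np.float32), order=order, mode="constant"
        )
    out = particles
    for _ in range(passes):
        polished = []
        for p in out:
            if p.cc is None or not check_box_fits(
                tomo.shape, p.position, params.box_size, pol_params.translational_range
            ):
                polished.append(p.copy())
                continue
            res = constrained_align(
                tomo,
                p.position,
                p.orientation,
                reference,
                mask,
                pol_params,
                grid=grid,
                order=order,
                prefiltered=order > 1,
            )
            polished.append(
                p.copy(position=res.position, orientation=res.orientation, cc=res.cc)
            )
        out = ParticleSet(polished, particles.tomo_name, particles.voxel_size)
    return out


def regather(
    cache: Sequence[IterationRecord],
    new_threshold: float,
    seeds: ParticleSet,
    d_min: float,
) -> ParticleSet:
    """Rebuild the final set from cached alignments at a new threshold.

    No new alignment happens: every cached aligned candidate is re-tested
    against ``new_threshold`` and the final set is rebuilt from the seeds
    plus re-accepted candidates, deduplicated by ``d_min`` with
    earlier-iteration particles taking precedence.
    """
    if not cache:
        raise ValueError("nothing to regather: the iteration cache is empty")
    final = [p.copy(status="seed") for p in seeds]
    positions = [p.position for p in final]
    for record in sorted(cache, key=lambda r: r.iteration):
        for c in record.candidates_aligned:
            cc = c.cc if c.cc is not None else float("nan")
            if not (cc == cc) or cc < new_threshold:
                continue
            if _too_close(c.position, positions, d_min):
                continue
            final.append(c.copy(status="accepted", iteration_added=record.iteration))
            positions.append(c.position)
    return ParticleSet(final, seeds.tomo_name, seeds.voxel_size)


# ---------------------------------------------------------------------------
# Cache persistence (one JSON file per iteration).


def _particle_to_dict(p: Particle) -> dict:
    cc = p.cc
    if cc is not None and not (cc == cc):
        cc = None  # NaN -> null for strict JSON
    return {
        "position": [float(x) for x in p.position],
        "rot": p.orientation.rot,
        "tilt": p.orientation.tilt,
        "psi": p.orientation.psi,
        "cc": cc,
        "status": p.status,
        "iteration_added": p.iteration_added,
        "tomo_name": p.tomo_name,
    }


def _particle_from_dict(d: dict) -> Particle:
    return Particle(
        position=np.asarray(d["position"], dtype=float),
        orientation=Orientation(d["rot"], d["tilt"], d["psi"]),
        cc=d["cc"],
        status=d["status"],
        iteration_added=int(d["iteration_added"]),
        tomo_name=d.get("tomo_name", ""),
    )


def save_record(record: IterationRecord, path: Path) -> None:
    payload = {
        "iteration": record.iteration,
        "seeds_in": [_particle_to_dict(p) for p in record.seeds_in],
        "candidates_raw": [_particle_to_dict(p) for p in record.candidates_raw],
        "candidates_aligned": [_particle_to_dict(p) for p in record.candidates_aligned],
        "accepted": [_particle_to_dict(p) for p in record.accepted],
        "rejected": [_particle_to_dict(p) for p in record.rejected],
        "duplicates": [_particle_to_dict(p) for p in record.duplicates],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_record(path: Path) -> IterationRecord:
    d = json.loads(Path(path).read_text())
    return IterationRecord(
        iteration=int(d["iteration"]),
        seeds_in=[_particle_from_dict(p) for p in d["seeds_in"]],
        candidates_raw=[_particle_from_dict(p) for p in d["candidates_raw"]],
        candidates_aligned=[_particle_from_dict(p) for p in d["candidates_aligned"]],
        accepted=[_particle_from_dict(p) for p in d["accepted"]],
        rejected=[_particle_from_dict(p) for p in d["rejected"]],
        duplicates=[_particle_from_dict(p) for p in d.get("duplicates", [])],
    )


def load_cache(cache_dir: Path) -> list[IterationRecord]:
    """Load every per-iteration record file from a cache directory."""
    paths = sorted(Path(cache_dir).glob("iteration_*.json"))
    return [load_record(p) for p in paths]
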