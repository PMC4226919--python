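"""Experiment protocols: individual, competitive and induced-fit runs,
sequential multi-ligand binding, and the trajectory filters.

A run launches ``n_chains`` independent Monte Carlo chains (per-chain RNG
derived from the base seed and the chain id, so sequential and parallel
execution give identical results).  Filters drop the per-chain burn-in,
frames that wandered beyond a COM-distance ceiling, and frames with
non-negative interaction energy — the same scatter-cleanup convention the
migration protocol uses.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError, ProtocolError
from .energy import ForceFieldParams
from .mc_engine import MCConfig, Trajectory, run_chain
from .structures import CompetitiveSystem, LigandPose

__all__ = [
    "FilterSpec",
    "RunSpec",
    "TrajectorySet",
    "run_experiment",
    "run_sequential_binding",
    "filter_frames",
    "select_bound_frame",
]

logger = logging.getLogger(__name__)

MODES = ("individual", "competitive", "induced_fit")


@dataclass(frozen=True)
class FilterSpec:
    """Frame-level cleanup rules applied before analysis."""

    max_com_distance: float = 100.0
    max_energy: float = 0.0
    burn_in: int = 100

    def __post_init__(self):
        if self.burn_in < 0:
            raise DomainError("burn_in must be non-negative")


@dataclass
class RunSpec:
    """One experiment: mode, system, engine config and filters."""

    mode: str
    system: CompetitiveSystem
    mc: MCConfig = field(default_factory=MCConfig)
    filters: FilterSpec = field(default_factory=FilterSpec)
    ligand_index: int = 0
    params: ForceFieldParams = field(default_factory=ForceFieldParams)

    def __post_init__(self):
        if self.mode not in MODES:
            raise DomainError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.mode == "competitive" and self.system.receptor_b is None:
            raise DomainError("competitive mode requires both receptors")
        if self.mode == "individual" and self.system.receptor_b is not None:
            raise DomainError(
                "individual mode requires a system with the second receptor deleted"
            )
        if self.mode == "induced_fit" and not any(
            lp.bound for lp in self.system.ligands
        ):
            raise DomainError("induced_fit mode requires at least one bound ligand")


@dataclass
class TrajectorySet:
    """Trajectories of one run plus the system they were generated on."""

    trajectories: list[Trajectory]
    system: CompetitiveSystem
    mode: str
    filter_report: dict = field(default_factory=dict)

    def all_frames(self):
        return [f for t in self.trajectories for f in t.frames]

    @property
    def pooled_acceptance(self) -> float:
        prop = sum(t.n_proposed for t in self.trajectories)
        acc = sum(t.n_accepted for t in self.trajectories)
        return acc / prop if prop else 0.0


def run_experiment(spec: RunSpec) -> TrajectorySet:
    """Run all chains of one experiment.

    Individual mode requires a system without receptor_b (energies and
    distances reference one receptor only).  Induced-fit mode holds bound
    ligands fixed as part of the receptor, switches side-chain sampling
    on, applies the wider rotation magnitude (rot_r 0.5) and spawns
    around the target receptor only.
    """
    spec.__post_init__()  # revalidate: system may have changed since construction
    mc = spec.mc
    restrict = None
    # spawning confines individual and induced-fit exploration; competitive
    # migration is unconstrained (ligand free to visit and leave both)
    spawning = spec.mode != "competitive"
    if spec.mode == "induced_fit":
        mc = replace(mc, rot_r=max(mc.rot_r, 0.5), side_chain_sampling=True)
        restrict = "a"
    trajectories = []
    for chain in range(mc.n_chains):
        rng = np.random.default_rng([mc.seed, chain])
        trajectories.append(
            run_chain(
                spec.system,
                spec.ligand_index,
                mc,
                rng=rng,
                chain_id=chain,
                params=spec.params,
                spawn_restrict_to=restrict,
                spawning=spawning,
            )
        )
    return TrajectorySet(trajectories=trajectories, system=spec.system, mode=spec.mode)


def filter_frames(trajs: TrajectorySet, filters: FilterSpec) -> TrajectorySet:
    """Apply burn-in, COM-distance and energy filters; report counts.

    Per chain: the first ``burn_in`` frames are dropped; then frames with
    ``min(dist_to_a, dist_to_b) > max_com_distance`` and frames with
    ``e_interaction >= max_energy``.  Idempotent.  ``filter_report``
    carries kept/dropped counts per rule.
    """
    # burn-in removal is a one-shot rule; the distance/energy rules are
    # naturally idempotent, so skipping it on re-filter makes the whole
    # filter idempotent
    burn_in = 0 if trajs.filter_report.get("burn_in_applied") else filters.burn_in
    report = {
        "total": 0, "burn_in": 0, "distance": 0, "energy": 0, "kept": 0,
        "burn_in_applied": True,
    }
    new_trajs = []
    for traj in trajs.trajectories:
        kept = []
        report["total"] += len(traj.frames)
        for i, fr in enumerate(traj.frames):
            if i < burn_in:
                report["burn_in"] += 1
                continue
            dmin = fr.dist_to_a if fr.dist_to_b is None else min(fr.dist_to_a, fr.dist_to_b)
            if dmin > filters.max_com_distance:
                report["distance"] += 1
                continue
            if fr.e_interaction >= filters.max_energy:
                report["energy"] += 1
                continue
            kept.append(fr)
        if not kept:
            logger.warning(
                "chain %d: no frames survive filtering (%d frames, burn_in %d)",
                traj.chain_id, len(traj.frames), filters.burn_in,
            )
        new = Trajectory(
            chain_id=traj.chain_id,
            frames=kept,
            n_proposed=traj.n_proposed,
            n_accepted=traj.n_accepted,
            capture=traj.capture,
            config_fingerprint=traj.config_fingerprint,
            ligand_masses=traj.ligand_masses,
        )
        new_trajs.append(new)
    report["kept"] = sum(len(t.frames) for t in new_trajs)
    # re-filtering a filtered set must change nothing: zero out burn-in only
    # when it was already applied (frames no longer start at step 0)
    filtered = TrajectorySet(
        trajectories=new_trajs,
        system=trajs.system,
        mode=trajs.mode,
        filter_report=report,
    )
    return filtered


def select_bound_frame(trajs: TrajectorySet, competitor: str = "a"):
    """Pick the binding pose for sequential rounds.

    Lexicographic rule: restrict to the quartile of filtered frames
    farthest from the competitor receptor's COM, then take the frame of
    minimum interaction energy (ties: first occurrence).
    """
    frames = trajs.all_frames()
    if not frames:
        raise ProtocolError("no frames available for bound-pose selection")

    def comp_dist(fr):
        if competitor == "a":
            return fr.dist_to_a
        if fr.dist_to_b is None:
            raise DomainError("no receptor_b in this run")
        return fr.dist_to_b

    dists = np.array([comp_dist(f) for f in frames])
    q75 = np.quantile(dists, 0.75)
    far = [f for f, d in zip(frames, dists) if d >= q75]
    return min(far, key=lambda f: f.e_interaction)


def run_sequential_binding(
    spec: RunSpec, n_ligands: int, competitor: str = "a"
) -> list[TrajectorySet]:
    """Sequential multi-ligand exploration.

    After each round the selected frame (see :func:`select_bound_frame`)
    is frozen as a bound ligand — it joins the receptor side of the
    interaction energy for later rounds — and the next ligand explores
    the updated system from the standard unbound start.
    """
    if n_ligands < 2:
        raise DomainError("sequential binding needs at least 2 ligands")
    results = []
    system = spec.system
    lig_index = spec.ligand_index
    for round_idx in range(n_ligands):
        round_spec = RunSpec(
            mode=spec.mode,
            system=system,
            mc=replace(spec.mc, seed=spec.mc.seed + 1000 * round_idx),
            filters=spec.filters,
            ligand_index=lig_index,
            params=spec.params,
        )
        trajs = run_experiment(round_spec)
        filtered = filter_frames(trajs, spec.filters)
        results.append(filtered)
        if round_idx == n_ligands - 1:
            break
        try:
            chosen = select_bound_frame(filtered, competitor=competitor)
        except ProtocolError as exc:
            raise ProtocolError(
                f"round {round_idx}: no frame survives filters "
                f"(report: {filtered.filter_report})"
            ) from exc
        new_system = copy.deepcopy(system)
        lig = new_system.ligands[lig_index]
        bound = LigandPose(
            structure=lig.structure, coords=chosen.coords.copy(), bound=True
        )
        # re-spawn a fresh unbound ligand at the standard start for next round
        fresh = LigandPose(
            structure=lig.structure, coords=system.ligands[lig_index].coords.copy()
        )
        new_system.ligands = [lp for lp in new_system.ligands if lp.bound] + [bound, fresh]
        lig_index = len(new_system.ligands) - 1
        system = new_system
    return results
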