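"""Three-step Monte Carlo ligand-migration propagator.

Each step perturbs the ligand as a rigid body (random translation in a
ball of radius ``tra_r``, random rotation up to ``rot_r * pi``), optionally
resamples receptor side chains near the ligand, relaxes the pose by a
rigid-body local minimization, and accepts or rejects the relaxed pose by
the Metropolis criterion against the previous accepted energy.  Receptor
backbones are rigid throughout (backbone normal-mode perturbation is
deliberately omitted from migration runs).

With spawning enabled (individual and induced-fit protocols), once the
ligand first approaches a receptor's centre of mass closer than
``spawn_trigger`` the chain is "captured": subsequent proposals leaving a
sphere of radius ``spawn_radius`` around that COM are rejected outright,
and the translation proposal is scaled down to the exploration domain.
Competitive migration runs unconstrained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

from .errors import DomainError
from .energy import ForceFieldParams, _lj_arrays
from .structures import CompetitiveSystem, Structure, center_of_mass

try:  # jitted nonbonded kernel; pure-numpy fallback below keeps parity
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _numba_kernel(poses, coords, eps4, sig6, qqk, shift, rc2, coul_power):
        B, L, _ = poses.shape
        N = coords.shape[0]
        out = np.zeros(B)
        for b in range(B):
            total = 0.0
            for i in range(L):
                x, y, z = poses[b, i, 0], poses[b, i, 1], poses[b, i, 2]
                for j in range(N):
                    dx = x - coords[j, 0]
                    dy = y - coords[j, 1]
                    dz = z - coords[j, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 >= rc2:
                        continue
                    if r2 == 0.0:
                        total = np.inf
                        continue
                    inv = 1.0 / r2
                    sr6 = sig6[i, j] * inv * inv * inv
                    e = eps4[i, j] * (sr6 * sr6 - sr6)
                    if coul_power == 2:
                        e += qqk[i, j] * inv
                    else:
                        e += qqk[i, j] * np.sqrt(inv)
                    total += e - shift[i, j]
            out[b] = total
        return out

except ImportError:  # pragma: no cover - numba is a standard dependency
    _numba_kernel = None

__all__ = [
    "MCConfig",
    "Frame",
    "Trajectory",
    "perturb_ligand",
    "sample_side_chains",
    "minimize_ligand",
    "metropolis_accept",
    "run_chain",
    "spawn_check_and_constrain",
]


@dataclass
class MCConfig:
    """All engine tunables.

    ``tra_r`` and ``sprad`` are in Å; ``rot_r`` is a dimensionless
    magnitude scaling a [0, pi] rotation angle; ``temperature_kT`` is in
    kcal/mol (default 1.0, ~500 K — ligand-migration engines run their
    Metropolis test well above 300 K to keep a workable acceptance rate;
    0 recovers greedy accept-if-not-worse, 0.596 is 300 K).
    """

    steps: int = 2000
    tra_r: float = 12.0
    rot_r: float = 0.2
    sprad: float = 6.0
    spawn_radius: float = 8.0
    spawn_trigger: float = 10.0
    n_chains: int = 8
    temperature_kT: float = 1.0
    side_chain_sampling: bool = False
    minimize_iters: int = 24
    minimize_step: float = 2.0
    minimize_tol: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.steps <= 0:
            raise DomainError("steps must be positive")
        if self.tra_r < 0 or self.rot_r < 0:
            raise DomainError("tra_r and rot_r must be non-negative")
        if self.spawn_radius > self.spawn_trigger:
            raise DomainError("spawn_radius must not exceed spawn_trigger")
        if self.temperature_kT < 0:
            raise DomainError("temperature_kT must be non-negative")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Frame:
    """One accepted MC state of a single ligand."""

    step_index: int
    coords: np.ndarray
    e_interaction: float
    e_a: float
    e_b: float
    dist_to_a: float
    dist_to_b: Optional[float]
    accepted: bool = True
    spawned: Optional[str] = None  # receptor token 'a'/'b' once captured
    chain_id: int = 0

    def ligand_com(self, masses: np.ndarray) -> np.ndarray:
        return (self.coords * masses[:, None]).sum(axis=0) / masses.sum()


@dataclass
class Trajectory:
    """Ordered accepted frames of one chain plus acceptance bookkeeping."""

    chain_id: int
    frames: list[Frame] = field(default_factory=list)
    n_proposed: int = 0
    n_accepted: int = 0
    capture: Optional[str] = None
    config_fingerprint: str = ""
    ligand_masses: np.ndarray | None = None

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0


# --- elementary moves ------------------------------------------------------


def perturb_ligand(
    coords: np.ndarray,
    tra_r: float,
    rot_r: float,
    rng: np.random.Generator,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Rigid-body pose proposal.

    Rotation: uniform random axis, angle uniform in [0, rot_r * pi],
    about *center* (default: coordinate centroid).  Translation: uniform
    in the ball of radius ``tra_r``.  Internal geometry is preserved.
    """
    if tra_r < 0 or rot_r < 0:
        raise DomainError("tra_r and rot_r must be non-negative")
    coords = np.asarray(coords, dtype=float)
    c = coords.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    out = coords
    if rot_r > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, rot_r * np.pi)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        out = (out - c) @ R.T + c
    if tra_r > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = tra_r * rng.uniform() ** (1.0 / 3.0)
        out = out + radius * direction
    return out


def sample_side_chains(
    receptor: Structure,
    ligand_coords: np.ndarray,
    sprad: float,
    rng: np.random.Generator,
    max_disp: float = 0.3,
    clash_distance: float = 1.5,
) -> Structure:
    """Randomly displace residues with any atom within *sprad* of the ligand.

    Each eligible residue gets an independent random displacement of its
    atoms (magnitude <= *max_disp* Å), a stand-in for rotamer-library
    torsion moves at pseudo-atom resolution.  A move is rejected when it
    brings any receptor atom pair closer than *clash_distance*; atoms of
    ineligible residues are bitwise unchanged.
    """
    lig = np.asarray(ligand_coords, dtype=float)
    d2 = ((receptor.coords[:, None, :] - lig[None, :, :]) ** 2).sum(-1)
    near_atom = (d2 <= sprad**2).any(axis=1)
    if not near_atom.any():
        return receptor
    keys = [f"{c}|{s}" for c, s in zip(receptor.chain_ids, receptor.residue_seqs)]
    eligible = {k for k, hit in zip(keys, near_atom) if hit}
    new = receptor.copy()
    for res in sorted(eligible):
        idx = np.array([i for i, k in enumerate(keys) if k == res])
        disp = rng.normal(size=3)
        disp *= (max_disp * rng.uniform() ** (1.0 / 3.0)) / np.linalg.norm(disp)
        trial = new.coords.copy()
        trial[idx] += disp
        others = np.setdiff1d(np.arange(len(new)), idx)
        if others.size:
            dmin = np.sqrt(
                (((trial[idx][:, None, :] - trial[others][None, :, :]) ** 2).sum(-1)).min()
            )
            if dmin < clash_distance:
                continue  # clash: reject this residue's move
        new.coords = trial
    return new


_AXES = np.eye(3)


def _axis_rotation(axis: int, angle: float) -> np.ndarray:
    K = np.zeros((3, 3))
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    K[i, j], K[j, i] = -1.0, 1.0
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _sweep_candidates(x: np.ndarray, t_step: float, r_step: float) -> np.ndarray:
    """Stack of the 6 translation and 6 rotation candidate poses."""
    cands = [x + sign * t_step * _AXES[axis] for axis in range(3) for sign in (1, -1)]
    if x.shape[0] > 1 and r_step > 0:
        c = x.mean(axis=0)
        for axis in range(3):
            for sign in (1.0, -1.0):
                R = _axis_rotation(axis, sign * r_step)
                cands.append((x - c) @ R.T + c)
    return np.stack(cands)


def minimize_ligand(
    coords: np.ndarray,
    energy_fn: Callable[[np.ndarray], float],
    max_iters: int = 16,
    tol: float = 1e-3,
    initial_step: float = 2.0,
    rot_step: float = 0.1,
    energy_batch_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Rigid-body pattern-search descent on the 6 pose degrees of freedom.

    Sweeps +-x/y/z translations and +-rotations about the centroid,
    taking the best improving move per sweep and halving the step sizes
    when none improves.  Terminates after *max_iters* sweeps or when the
    translation step falls below *tol*.  The returned energy is never
    above the starting energy.  *energy_batch_fn*, when given, evaluates
    a (B, n_atoms, 3) stack of poses in one call (same energies as
    *energy_fn*, just vectorised).
    """
    x = np.asarray(coords, dtype=float)
    e = energy_fn(x)
    if not np.isfinite(e):
        raise DomainError("non-finite energy at minimization start")

    def sweep(x, e, t_step, r_step):
        cands = _sweep_candidates(x, t_step, r_step)
        if energy_batch_fn is not None:
            energies = np.asarray(energy_batch_fn(cands), dtype=float)
        else:
            energies = np.array([energy_fn(c) for c in cands])
        best = int(np.argmin(energies))
        if energies[best] < e:
            return cands[best], float(energies[best]), True
        return x, e, False

    t_step, r_step = initial_step, rot_step
    for _ in range(max_iters):
        if t_step < tol:
            break
        x, e, improved = sweep(x, e, t_step, r_step)
        if not improved:
            t_step *= 0.5
            r_step *= 0.5
    # refinement: anneal the step down to tol so the returned pose sits at
    # the basin bottom rather than at coarse-step resolution
    for _ in range(40):
        if t_step < tol:
            break
        x, e, improved = sweep(x, e, t_step, r_step)
        if not improved:
            t_step *= 0.5
            r_step *= 0.5
    return x, e


def metropolis_accept(
    e_new: float, e_ref: float, kT: float, rng: np.random.Generator
) -> bool:
    """Metropolis criterion: accept if not worse, else with Boltzmann odds.

    ``e_new <= e_ref`` always accepts; at ``kT == 0`` any uphill move is
    rejected (the greedy limit); otherwise an uphill move is accepted
    with probability exp(-(e_new - e_ref) / kT).
    """
    if not (np.isfinite(e_new) and np.isfinite(e_ref)):
        raise DomainError("Metropolis requires finite energies")
    if kT < 0:
        raise DomainError("kT must be non-negative")
    if e_new <= e_ref:
        return True
    if kT == 0.0:
        return False
    return bool(rng.random() < np.exp(-(e_new - e_ref) / kT))


def spawn_check_and_constrain(
    frame: Frame, system: CompetitiveSystem, config: MCConfig
) -> Optional[str]:
    """Exploration-domain token for *frame*: 'a', 'b' or None (unconstrained).

    A chain becomes constrained to the first receptor whose COM the
    ligand approaches within ``spawn_trigger``; the engine then rejects
    proposals farther than ``spawn_radius`` from that COM.
    """
    if frame.spawned is not None:
        return frame.spawned
    if frame.dist_to_a < config.spawn_trigger:
        return "a"
    if frame.dist_to_b is not None and frame.dist_to_b < config.spawn_trigger:
        return "b"
    return None


# --- chain propagation -----------------------------------------------------


class _EnergyContext:
    """Precomputed receptor arrays for fast per-pose cross-energy evaluation.

    Bound ligands are folded into the receptor group nearer to them, so
    they contribute to the receptor side of the interaction energy.
    """

    def __init__(
        self,
        system: CompetitiveSystem,
        ligand_index: int,
        params: ForceFieldParams,
    ):
        self.params = params
        lig = system.ligands[ligand_index]
        self.lig_struct = lig.structure
        self.lig_charges = lig.structure.charges
        self.lig_masses = lig.structure.masses
        eps_l, sig_l = _lj_arrays(lig.structure, params)
        self.com_a = center_of_mass(system.receptor_a)
        self.com_b = (
            center_of_mass(system.receptor_b) if system.receptor_b is not None else None
        )

        rc = params.nonbonded_cutoff
        self._rc2 = rc * rc

        def build(members):
            coords, charges, eps, sig = [], [], [], []
            for st, xyz in members:
                e, s = _lj_arrays(st, params)
                coords.append(np.asarray(xyz, float))
                charges.append(st.charges)
                eps.append(e)
                sig.append(s)
            coords = np.concatenate(coords)
            charges = np.concatenate(charges)
            eps = np.concatenate(eps)
            sig = np.concatenate(sig)
            # precombined pair tables, (n_lig, n_group): LJ prefactor,
            # sigma^6, screened-charge product and the cutoff energy shift
            eps4 = 4.0 * np.sqrt(eps_l[:, None] * eps[None, :])
            sig_ij = 0.5 * (sig_l[:, None] + sig[None, :])
            sig6 = sig_ij**6
            qq = self.lig_charges[:, None] * charges[None, :]
            if params.dielectric_model == "distance_dependent":
                # E_coul = k q_i q_j / (scale * r^2)
                qqk = params.coulomb_constant * qq / params.dielectric_scale
                coul_shift = qqk / self._rc2
                coul_power = 2
            else:
                qqk = params.coulomb_constant * qq / params.dielectric_scale
                coul_shift = qqk / rc
                coul_power = 1
            sr6c = sig6 / rc**6
            shift = eps4 * (sr6c**2 - sr6c) + coul_shift
            return {
                "coords": coords,
                "eps4": eps4,
                "sig6": sig6,
                "qqk": qqk,
                "shift": shift,
                "coul_power": coul_power,
            }

        members_a = [(system.receptor_a, system.receptor_a.coords)]
        members_b = (
            [(system.receptor_b, system.receptor_b.coords)]
            if system.receptor_b is not None
            else []
        )
        for j, other in enumerate(system.ligands):
            if j == ligand_index or not other.bound:
                continue
            com = other.com()
            da = np.linalg.norm(com - self.com_a)
            db = np.linalg.norm(com - self.com_b) if self.com_b is not None else np.inf
            (members_a if da <= db else members_b).append((other.structure, other.coords))
        self.group_a = build(members_a)
        self.group_b = build(members_b) if members_b else None
        # merged table for the minimizer hot path (total energy only)
        if self.group_b is not None:
            self.group_all = {
                "coords": np.concatenate(
                    [self.group_a["coords"], self.group_b["coords"]]
                ),
                "coul_power": self.group_a["coul_power"],
                **{
                    k: np.concatenate([self.group_a[k], self.group_b[k]], axis=1)
                    for k in ("eps4", "sig6", "qqk", "shift")
                },
            }
        else:
            self.group_all = self.group_a

    def update_receptor_a(self, receptor: Structure) -> None:
        n = len(receptor)
        self.group_a["coords"][:n] = receptor.coords
        if self.group_all is not self.group_a:
            self.group_all["coords"][:n] = receptor.coords

    def _group_energy_batch(self, group, poses: np.ndarray) -> np.ndarray:
        """Energies of a (..., n_lig, 3) stack of poses against one group."""
        squeeze = poses.ndim == 2
        stack = poses[None] if squeeze else poses
        if _numba_kernel is not None:
            out = _numba_kernel(
                np.ascontiguousarray(stack),
                group["coords"],
                group["eps4"],
                group["sig6"],
                group["qqk"],
                group["shift"],
                self._rc2,
                group["coul_power"],
            )
        else:
            diff = stack[:, :, None, :] - group["coords"]
            r2 = (diff * diff).sum(-1)
            if (r2 == 0.0).any():
                raise DomainError("overlapping atoms at zero separation")
            mask = r2 < self._rc2
            inv_r2 = np.where(mask, 1.0 / np.where(mask, r2, 1.0), 0.0)
            sr6 = group["sig6"] * inv_r2**3
            e = group["eps4"] * (sr6 * sr6 - sr6)
            if group["coul_power"] == 2:
                e = e + group["qqk"] * inv_r2
            else:
                e = e + group["qqk"] * np.sqrt(inv_r2)
            e = np.where(mask, e - group["shift"], 0.0)
            out = e.sum(axis=(-1, -2))
        if np.isinf(out).any():
            raise DomainError("overlapping atoms at zero separation")
        return out[0] if squeeze else out

    def energies(self, lig_xyz: np.ndarray) -> tuple[float, float]:
        e_a = float(self._group_energy_batch(self.group_a, lig_xyz))
        e_b = (
            float(self._group_energy_batch(self.group_b, lig_xyz))
            if self.group_b
            else 0.0
        )
        return e_a, e_b

    def total_energy(self, lig_xyz: np.ndarray) -> float:
        return float(self._group_energy_batch(self.group_all, lig_xyz))

    def total_energy_batch(self, poses: np.ndarray) -> np.ndarray:
        return self._group_energy_batch(self.group_all, poses)

    def ligand_com(self, lig_xyz: np.ndarray) -> np.ndarray:
        m = self.lig_masses
        return (lig_xyz * m[:, None]).sum(axis=0) / m.sum()

    def within_reach(self, lig_xyz: np.ndarray, margin: float) -> bool:
        """Whether any group atom could interact within cutoff + margin."""
        com = self.ligand_com(lig_xyz)
        reach = self.params.nonbonded_cutoff + margin
        d2 = ((self.group_all["coords"] - com) ** 2).sum(-1)
        return bool((d2 <= reach * reach).any())


def run_chain(
    system: CompetitiveSystem,
    ligand_index: int,
    config: MCConfig,
    rng: np.random.Generator | None = None,
    chain_id: int = 0,
    params: ForceFieldParams | None = None,
    spawn_restrict_to: Optional[str] = None,
    spawning: bool = True,
) -> Trajectory:
    """Propagate one chain and return its trajectory of accepted frames.

    Deterministic given (*system*, *config*, *rng* seed).  The Metropolis
    reference is the previous accepted state's total interaction energy
    (sum over both receptors in competitive mode).  *spawning* turns the
    capture-and-constrain mechanism on (individual and induced-fit
    protocols) or off (unconstrained competitive migration);
    *spawn_restrict_to* limits capture to one receptor token (induced-fit
    refinement).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, chain_id])
    params = params or ForceFieldParams()
    ctx = _EnergyContext(system, ligand_index, params)
    receptor_a = system.receptor_a
    coords = np.asarray(system.ligands[ligand_index].coords, dtype=float).copy()

    def distances(xyz):
        com = ctx.ligand_com(xyz)
        da = float(np.linalg.norm(com - ctx.com_a))
        db = float(np.linalg.norm(com - ctx.com_b)) if ctx.com_b is not None else None
        return da, db

    e_a, e_b = ctx.energies(coords)
    e = e_a + e_b
    da, db = distances(coords)
    traj = Trajectory(
        chain_id=chain_id,
        config_fingerprint=config.fingerprint(),
        ligand_masses=ctx.lig_masses.copy(),
    )
    frame = Frame(0, coords.copy(), e, e_a, e_b, da, db, spawned=None, chain_id=chain_id)
    captured = spawn_check_and_constrain(frame, system, config) if spawning else None
    if spawn_restrict_to is not None and captured != spawn_restrict_to:
        captured = None
    frame.spawned = captured
    traj.frames.append(frame)
    lig_margin = float(
        np.linalg.norm(coords - coords.mean(0), axis=1).max() + config.tra_r
    )

    for step in range(1, config.steps + 1):
        traj.n_proposed += 1
        # a captured chain explores within the spawning sphere, so the
        # translation proposal is scaled down to the exploration domain
        tra = min(config.tra_r, config.spawn_radius) if captured else config.tra_r
        prop = perturb_ligand(
            coords, tra, config.rot_r, rng, center=ctx.ligand_com(coords)
        )
        if config.side_chain_sampling:
            moved = sample_side_chains(receptor_a, prop, config.sprad, rng)
            if moved is not receptor_a:
                receptor_a = moved
                ctx.update_receptor_a(receptor_a)
        # far-field poses see a flat zero landscape: skip minimization there
        if ctx.within_reach(prop, lig_margin):
            prop, e_new = minimize_ligand(
                prop,
                ctx.total_energy,
                max_iters=config.minimize_iters,
                tol=config.minimize_tol,
                initial_step=config.minimize_step,
                energy_batch_fn=ctx.total_energy_batch,
            )
            e_a_new, e_b_new = ctx.energies(prop)
        else:
            e_a_new, e_b_new = ctx.energies(prop)
            e_new = e_a_new + e_b_new
        da_new, db_new = distances(prop)
        if captured is not None:
            d_cap = da_new if captured == "a" else db_new
            if d_cap is None or d_cap > config.spawn_radius:
                continue  # proposal left the spawning sphere: reject outright
        if not metropolis_accept(e_new, e, config.temperature_kT, rng):
            continue
        coords, e, e_a, e_b, da, db = prop, e_new, e_a_new, e_b_new, da_new, db_new
        traj.n_accepted += 1
        frame = Frame(
            step, coords.copy(), e, e_a, e_b, da, db, spawned=captured, chain_id=chain_id
        )
        if spawning and captured is None:
            token = spawn_check_and_constrain(frame, system, config)
            if spawn_restrict_to is not None and token != spawn_restrict_to:
                token = None
            captured = token
            frame.spawned = captured
        traj.frames.append(frame)
    traj.capture = captured
    return traj
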