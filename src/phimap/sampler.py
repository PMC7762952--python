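"""ϕ-restrained transition-state sampling with a coarse-grained Gō model.

The transition-state ensemble of a coupled binding-and-folding
reaction can be modelled as the set of conformations whose
back-calculated ϕ-values (fraction of native contacts formed per
residue) reproduce the experimental ones. This module provides a
desk-scale realization of that idea: a structure-based (Gō-type) model
with one bead per residue at the side-chain centroid, sampled by
Metropolis Monte-Carlo simulated annealing under a squared-deviation
ϕ-restraint pseudo-energy, with transition-state structures collected
at the reference temperature in the late part of the run.

The model is deliberately minimal — native-contact Gaussian wells,
harmonic virtual bonds and angles, and a soft excluded-volume term in
reduced units with k_B = 1. It reproduces the logic of the restrained
sampling protocol (restraint eligibility 0 < ϕ < 1, annealing cycles
between a low reference and a high melting temperature, collection at
the reference temperature) at toy-system scale; it makes no attempt at
all-atom fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import (
    ContactDefinition,
    ContactMap,
    PhiRestraint,
    ResKey,
    StructureEnsemble,
    native_contacts,
    _switch,
)

__all__ = [
    "GoModel",
    "AnnealingSchedule",
    "SamplerConfig",
    "build_go_model",
    "anneal",
    "collect_ts",
]


@dataclass
class GoModel:
    """Structure-based one-bead-per-residue model of a complex.

    Energy terms (reduced units, contact well depth ε = 1):

    * native contact (i, j):  −ε·exp(−(r−r₀)²/2σ²)
    * virtual bond:           k_b·(r−r₀)²
    * virtual angle:          k_a·(θ−θ₀)²
    * excluded volume:        ε_rep·(σ_rep/r)¹² for non-bonded pairs

    The unrestrained energy has its minimum at the native conformation.
    ``contact_cutoffs`` hold the per-pair distance below which a native
    contact counts as formed when back-calculating ϕ.
    """

    atoms: pd.DataFrame
    native_coords: np.ndarray
    residue_keys: list[ResKey]
    bonds: np.ndarray          # (n_bonds, 2) int
    bond_r0: np.ndarray
    angles: np.ndarray         # (n_angles, 3) int
    angle_t0: np.ndarray
    contacts: np.ndarray       # (n_contacts, 2) int bead indices
    contact_r0: np.ndarray
    contact_cutoffs: np.ndarray
    nonbonded: np.ndarray      # (n_pairs, 2) int, repulsion-only pairs
    registry: ContactMap       # bead-level registry (ensemble conventions)
    epsilon: float = 1.0
    well_sigma: float = 0.05
    k_bond: float = 200.0
    k_angle: float = 20.0
    eps_rep: float = 0.1
    sigma_rep: float = 0.35
    #: reduced temperatures the laboratory 278/378 K endpoints map onto
    t_red_low: float = 0.12
    t_red_high: float = 1.2
    lab_t_low: float = 278.0
    lab_t_high: float = 378.0

    def reduced_temperature(self, T_lab: float) -> float:
        """Linear map of laboratory K onto reduced units.

        The endpoints are chosen so the model's folding midpoint falls
        between the mapped low and high temperatures: contacts are
        stable at the reference temperature and melt near the top of
        the annealing cycle.
        """
        f = (T_lab - self.lab_t_low) / (self.lab_t_high - self.lab_t_low)
        return self.t_red_low + f * (self.t_red_high - self.t_red_low)

    def energy(self, coords: np.ndarray) -> float:
        e = 0.0
        if len(self.bonds):
            d = np.linalg.norm(
                coords[self.bonds[:, 0]] - coords[self.bonds[:, 1]], axis=1
            )
            e += float(self.k_bond * np.sum((d - self.bond_r0) ** 2))
        if len(self.angles):
            v1 = coords[self.angles[:, 0]] - coords[self.angles[:, 1]]
            v2 = coords[self.angles[:, 2]] - coords[self.angles[:, 1]]
            cos = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            theta = np.arccos(np.clip(cos, -1.0, 1.0))
            e += float(self.k_angle * np.sum((theta - self.angle_t0) ** 2))
        if len(self.contacts):
            d = np.linalg.norm(
                coords[self.contacts[:, 0]] - coords[self.contacts[:, 1]], axis=1
            )
            e += float(
                -self.epsilon
                * np.sum(np.exp(-((d - self.contact_r0) ** 2) / (2 * self.well_sigma**2)))
            )
        if len(self.nonbonded):
            d = np.linalg.norm(
                coords[self.nonbonded[:, 0]] - coords[self.nonbonded[:, 1]], axis=1
            )
            d = np.maximum(d, 1e-6)
            e += float(self.eps_rep * np.sum((self.sigma_rep / d) ** 12))
        return e

    def _residue_contact_rows(self, residue: ResKey) -> np.ndarray:
        idx = self.residue_keys.index(residue)
        return np.flatnonzero(
            (self.contacts[:, 0] == idx) | (self.contacts[:, 1] == idx)
        )

    def phi(self, coords: np.ndarray, residue: ResKey, smooth: bool = False) -> float:
        """Back-calculated ϕ of a residue: fraction of native contacts formed."""
        rows = self._residue_contact_rows(residue)
        if rows.size == 0:
            raise ValueError(f"residue {residue} has no native contacts in the model")
        d = np.linalg.norm(
            coords[self.contacts[rows, 0]] - coords[self.contacts[rows, 1]], axis=1
        )
        if smooth:
            # per-pair cutoff: normalize distances, switch at 1
            return float(np.mean(_switch(d / self.contact_cutoffs[rows], 1.0)))
        return float(np.mean(d <= self.contact_cutoffs[rows]))

    def restraint_energy(
        self, coords: np.ndarray, restraints: list[PhiRestraint], smooth: bool = False
    ) -> float:
        e = 0.0
        for r in restraints:
            dev = self.phi(coords, r.residue, smooth=smooth) - r.target
            e += r.weight * dev * dev
        return float(e)


@dataclass(frozen=True)
class AnnealingSchedule:
    """Simulated-annealing protocol.

    Each cycle cools from ``T_high`` to ``T_low`` and then holds at the
    reference temperature for the final ``hold_fraction`` of its steps;
    transition-state structures are taken from reference-temperature
    states in the last ``collect_fraction`` of the cycles (the analog
    of keeping the last stretch of a long annealing run).
    """

    n_cycles: int = 1334
    steps_per_cycle: int = 150
    T_low: float = 278.0
    T_high: float = 378.0
    reference_T: float = 278.0
    collect_fraction: float = 0.75
    hold_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.T_low > self.T_high:
            raise ValueError("T_low must not exceed T_high")
        if not 0 < self.collect_fraction <= 1:
            raise ValueError("collect_fraction must be in (0, 1]")
        if not 0 < self.hold_fraction <= 1:
            raise ValueError("hold_fraction must be in (0, 1]")

    def temperature(self, step: int) -> float:
        """Laboratory temperature at a given step within a cycle."""
        n_hold = max(int(self.hold_fraction * self.steps_per_cycle), 1)
        n_ramp = self.steps_per_cycle - n_hold
        if step >= n_ramp:
            return self.reference_T
        if n_ramp <= 1:
            return self.T_high
        f = step / (n_ramp - 1)
        return self.T_high + f * (self.T_low - self.T_high)


@dataclass
class SamplerConfig:
    """Monte-Carlo move-set and restraint settings; seeded runs are
    bit-reproducible."""

    seed: int = 0
    restraint_weight: float = 50.0
    displacement_amp: float = 0.04
    crank_angle: float = 0.5       # rad
    rigid_trans_amp: float = 0.04
    rigid_rot_angle: float = 0.25  # rad
    autotune: bool = True
    target_acceptance: tuple[float, float] = (0.3, 0.5)


def build_go_model(
    native: StructureEnsemble,
    defn: ContactDefinition | None = None,
    **model_kwargs,
) -> GoModel:
    """Construct the Gō model from a native-state ensemble.

    Beads sit at per-residue heavy side-chain centroids (Cα for
    residues without side-chain heavy atoms); the native-contact
    registry of the input ensemble defines one attractive well per
    contacting residue pair. The per-pair ϕ cutoff equals the contact
    definition cutoff whenever the native bead distance lies within it,
    so bead-level ϕ back-calculation agrees with the ensemble-module
    definition on such systems.
    """
    defn = defn or ContactDefinition()
    atom_registry = native_contacts(native, defn)
    if not atom_registry.registry:
        raise ValueError("native-contact registry is empty; cannot build a Gō model")

    residues = native.residues
    keys = native.atom_residue_keys()
    coords0 = native.coords[0]
    sc_mask = np.zeros(native.n_atoms, dtype=bool)
    sc_mask[native.sidechain_heavy_indices()] = True

    bead_xyz = np.empty((len(residues), 3))
    resnames = []
    for b, res in enumerate(residues):
        own = np.array([i for i, k in enumerate(keys) if k == res])
        sc = own[sc_mask[own]]
        bead_xyz[b] = coords0[sc if sc.size else own].mean(axis=0)
        resnames.append(
            str(native.atoms["resname"].iloc[own[0]])
            if "resname" in native.atoms
            else "ALA"
        )

    atoms = pd.DataFrame(
        {
            "chain": [r[0] for r in residues],
            "resid": [r[1] for r in residues],
            "resname": resnames,
            "name": ["CB"] * len(residues),
            "element": ["C"] * len(residues),
        }
    )

    bidx = {r: i for i, r in enumerate(residues)}
    chains: dict[str, list[int]] = {}
    for r in residues:
        chains.setdefault(r[0], []).append(bidx[r])
    bonds, angles = [], []
    for beads in chains.values():
        bonds += [(beads[i], beads[i + 1]) for i in range(len(beads) - 1)]
        angles += [
            (beads[i], beads[i + 1], beads[i + 2]) for i in range(len(beads) - 2)
        ]
    bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    angles = np.array(angles, dtype=int).reshape(-1, 3)
    bond_r0 = np.linalg.norm(bead_xyz[bonds[:, 0]] - bead_xyz[bonds[:, 1]], axis=1) \
        if len(bonds) else np.empty(0)
    if len(angles):
        v1 = bead_xyz[angles[:, 0]] - bead_xyz[angles[:, 1]]
        v2 = bead_xyz[angles[:, 2]] - bead_xyz[angles[:, 1]]
        cos = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angle_t0 = np.arccos(np.clip(cos, -1.0, 1.0))
    else:
        angle_t0 = np.empty(0)

    contacts, r0s, cutoffs = [], [], []
    bead_registry = ContactMap()
    for (a, b) in sorted(atom_registry.registry):
        i, j = bidx[a], bidx[b]
        r0 = float(np.linalg.norm(bead_xyz[i] - bead_xyz[j]))
        contacts.append((i, j))
        r0s.append(r0)
        cutoffs.append(defn.cutoff if r0 <= defn.cutoff else 1.2 * r0)
        bead_registry.registry[ContactMap.pair_key(a, b)] = [(i, j)]
    contacts = np.array(contacts, dtype=int)

    bonded = {tuple(sorted(b)) for b in map(tuple, bonds)}
    contact_set = {tuple(sorted(c)) for c in map(tuple, contacts)}
    nonbonded = [
        (i, j)
        for i in range(len(residues))
        for j in range(i + 1, len(residues))
        if (i, j) not in bonded and (i, j) not in contact_set
    ]
    return GoModel(
        atoms=atoms,
        native_coords=bead_xyz,
        residue_keys=list(residues),
        bonds=bonds,
        bond_r0=np.asarray(bond_r0),
        angles=angles,
        angle_t0=np.asarray(angle_t0),
        contacts=contacts,
        contact_r0=np.array(r0s),
        contact_cutoffs=np.array(cutoffs),
        nonbonded=np.array(nonbonded, dtype=int).reshape(-1, 2),
        registry=bead_registry,
        **model_kwargs,
    )


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def anneal(
    model: GoModel,
    restraints: list[PhiRestraint],
    schedule: AnnealingSchedule,
    config: SamplerConfig,
) -> StructureEnsemble:
    """Run restrained Monte-Carlo simulated annealing.

    Total energy is the Gō energy plus weight·Σ(ϕ_sim − ϕ_target)²
    evaluated on the instantaneous conformation, counting contacts with
    the same hard cutoff used when ϕ is reported, so the restrained
    quantity and the measured one coincide. Moves are
    single-bead displacements, crankshaft rotations of interior beads,
    and rigid-body moves of whole chains, accepted by the Metropolis
    rule at the reduced temperature of the current step. One snapshot
    per step is recorded, labelled with its laboratory temperature and
    cycle index.
    """
    for r in restraints:
        if r.residue not in model.residue_keys:
            raise ValueError(f"restrained residue {r.residue} not in the model")
        model._residue_contact_rows(r.residue)  # raises if contact-free
        if model._residue_contact_rows(r.residue).size == 0:
            raise ValueError(f"restraint on contact-free residue {r.residue}")

    rng = np.random.default_rng(config.seed)
    coords = model.native_coords.copy()
    weight = config.restraint_weight

    def total_energy(x: np.ndarray) -> float:
        e = model.energy(x)
        if restraints:
            e += weight * model.restraint_energy(x, restraints, smooth=False)
        return e

    e_cur = total_energy(coords)
    if not np.isfinite(e_cur):
        raise RuntimeError(
            f"non-finite starting energy ({e_cur}); check the model geometry"
        )

    chains: dict[str, list[int]] = {}
    for i, r in enumerate(model.residue_keys):
        chains.setdefault(r[0], []).append(i)
    chain_ids = list(chains)
    n_beads = len(model.residue_keys)

    amp = config.displacement_amp
    crank = config.crank_angle
    rtrans = config.rigid_trans_amp
    rrot = config.rigid_rot_angle

    n_total = schedule.n_cycles * schedule.steps_per_cycle
    snapshots = np.empty((n_total, n_beads, 3))
    temps = np.empty(n_total)
    cycles = np.empty(n_total, dtype=int)

    accepted = tried = 0
    snap = 0
    burn_in = max(schedule.n_cycles // 10, 1)
    for cycle in range(schedule.n_cycles):
        for step in range(schedule.steps_per_cycle):
            T_lab = schedule.temperature(step)
            t_red = model.reduced_temperature(T_lab)
            move = rng.integers(0, 3 if len(chain_ids) > 1 else 2)
            trial = coords.copy()
            if move == 0:  # single-bead displacement
                b = rng.integers(0, n_beads)
                trial[b] += rng.normal(0.0, amp, size=3)
            elif move == 1:  # crankshaft about the neighbour axis
                ch = chains[chain_ids[rng.integers(0, len(chain_ids))]]
                if len(ch) < 3:
                    b = rng.integers(0, n_beads)
                    trial[b] += rng.normal(0.0, amp, size=3)
                else:
                    k = rng.integers(1, len(ch) - 1)
                    i0, i1, i2 = ch[k - 1], ch[k], ch[k + 1]
                    axis = trial[i2] - trial[i0]
                    if np.linalg.norm(axis) < 1e-9:
                        axis = rng.normal(size=3)
                    R = _rotation(axis, rng.uniform(-crank, crank))
                    trial[i1] = trial[i0] + R @ (trial[i1] - trial[i0])
            else:  # rigid-body move of one whole chain
                ch = chains[chain_ids[rng.integers(0, len(chain_ids))]]
                idx = np.array(ch)
                com = trial[idx].mean(axis=0)
                R = _rotation(rng.normal(size=3), rng.uniform(-rrot, rrot))
                trial[idx] = (trial[idx] - com) @ R.T + com
                trial[idx] += rng.normal(0.0, rtrans, size=3)

            e_new = total_energy(trial)
            if not np.isfinite(e_new):
                raise RuntimeError(
                    f"non-finite trial energy at cycle {cycle} step {step}"
                )
            tried += 1
            if e_new <= e_cur or rng.random() < np.exp(-(e_new - e_cur) / t_red):
                coords = trial
                e_cur = e_new
                accepted += 1

            snapshots[snap] = coords
            temps[snap] = T_lab
            cycles[snap] = cycle
            snap += 1

        if config.autotune and cycle < burn_in and tried:
            rate = accepted / tried
            lo, hi = config.target_acceptance
            factor = 0.8 if rate < lo else (1.25 if rate > hi else 1.0)
            # stay within 4x of the configured amplitudes either way
            amp = float(np.clip(amp * factor, config.displacement_amp / 4,
                                config.displacement_amp * 4))
            crank = float(np.clip(crank * factor, config.crank_angle / 4,
                                  config.crank_angle * 4))
            rtrans = float(np.clip(rtrans * factor, config.rigid_trans_amp / 4,
                                   config.rigid_trans_amp * 4))
            rrot = float(np.clip(rrot * factor, config.rigid_rot_angle / 4,
                                 config.rigid_rot_angle * 4))
            accepted = tried = 0

    return StructureEnsemble(
        atoms=model.atoms,
        coords=snapshots,
        labels={
            "temperature": temps,
            "cycle": cycles,
            "schedule": schedule,
        },
    )


def collect_ts(
    trajectory: StructureEnsemble, schedule: AnnealingSchedule | None = None
) -> StructureEnsemble:
    """Keep reference-temperature states from the final part of the run.

    Retains states labelled with the reference temperature whose cycle
    index lies in the last ``collect_fraction`` of the cycles.
    """
    if "temperature" not in trajectory.labels or "cycle" not in trajectory.labels:
        raise ValueError("trajectory lacks temperature/cycle labels")
    schedule = schedule or trajectory.labels.get("schedule")
    if schedule is None:
        raise ValueError("no annealing schedule available for collection")
    temps = np.asarray(trajectory.labels["temperature"])
    cycles = np.asarray(trajectory.labels["cycle"])
    if temps.size != trajectory.n_models:
        raise ValueError("label arrays do not match the trajectory length")
    first_kept = int(np.ceil((1.0 - schedule.collect_fraction) * schedule.n_cycles))
    keep = np.isclose(temps, schedule.reference_T) & (cycles >= first_kept)
    if not np.any(keep):
        raise ValueError(
            "empty transition-state selection: no states at "
            f"T={schedule.reference_T} K in cycles >= {first_kept} "
            f"(cycles run: {cycles.max() + 1 if cycles.size else 0})"
        )
    return StructureEnsemble(
        atoms=trajectory.atoms,
        coords=trajectory.coords[keep],
        labels={
            "temperature": temps[keep],
            "cycle": cycles[keep],
            "n_collected": int(keep.sum()),
        },
    )
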