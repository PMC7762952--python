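"""Structural-ensemble analytics for transition-state characterization.

Native contacts between two residues that are not nearest neighbours
are defined as the heavy side-chain atom pairs within 0.6 nm in at
least 50% of the frames of a native-state reference ensemble. From any
conformation, the ϕ-value of a residue is then back-calculated as the
fraction of its registered native atom pairs currently formed — the
structural counterpart of the experimental ΔΔG ratio.

This module also computes the standard ensemble observables used to
characterize a transition-state ensemble: residue–residue contact
probability maps, per-residue α-helix content (a backbone-dihedral
surrogate for hydrogen-bond-based assignment), radius of gyration and
pairwise-RMSD distributions.

Coordinates are in nm throughout (PDB Å are converted at file I/O).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureEnsemble",
    "ContactDefinition",
    "ContactMap",
    "PhiRestraint",
    "native_contacts",
    "backcalc_phi",
    "ensemble_phi",
    "restraint_energy",
    "contact_probability_map",
    "helix_content",
    "rg_and_rmsd",
    "superpose",
]

#: Backbone atom names excluded from the heavy side-chain scope.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_ATOM_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

ResKey = tuple[str, int]  # (chain id, author residue number)


@dataclass
class StructureEnsemble:
    """A multi-model conformational ensemble with shared topology.

    ``atoms`` is one row per atom (chain, resid, resname, name,
    element); ``coords`` has shape (n_models, n_atoms, 3) in nm.
    Residue numbering follows the author convention of the reference
    structures (NCBD 2058–2116, CID 1018–1088 frames).
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    weights: np.ndarray | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one model")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match the atom table")
        if self.weights is None:
            self.weights = np.full(self.n_models, 1.0 / self.n_models)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            self.weights = self.weights / self.weights.sum()

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residues(self) -> list[ResKey]:
        """Residue keys in order of first appearance."""
        seen: dict[ResKey, None] = {}
        for ch, ri in zip(self.atoms["chain"], self.atoms["resid"]):
            seen.setdefault((str(ch), int(ri)), None)
        return list(seen)

    def residue_ordinals(self) -> dict[ResKey, int]:
        """0-based per-chain sequence position for neighbour exclusion."""
        out: dict[ResKey, int] = {}
        counters: dict[str, int] = {}
        for key in self.residues:
            ch = key[0]
            out[key] = counters.get(ch, 0)
            counters[ch] = out[key] + 1
        return out

    def sidechain_heavy_indices(self) -> np.ndarray:
        mask = (~self.atoms["name"].isin(BACKBONE_ATOMS)) & (
            self.atoms["element"].str.upper() != "H"
        )
        return np.flatnonzero(mask.to_numpy())

    def atom_residue_keys(self) -> list[ResKey]:
        return [
            (str(ch), int(ri))
            for ch, ri in zip(self.atoms["chain"], self.atoms["resid"])
        ]

    def model(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class ContactDefinition:
    """Native-contact criterion.

    A heavy side-chain atom pair is a native contact when it is within
    ``cutoff`` (nm) in at least ``frame_fraction`` of the native-state
    frames; nearest neighbours (|i−j| ≤ 1 in the same chain) are
    excluded, inter-chain pairs never are.
    """

    cutoff: float = 0.6
    frame_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.frame_fraction <= 1:
            raise ValueError("frame_fraction must be in (0, 1]")


@dataclass
class ContactMap:
    """Residue-pair contact bookkeeping.

    ``probability`` maps unordered residue-key pairs to contact
    probabilities; ``registry`` maps them to the list of native atom
    index pairs. Keys are stored with the two residues sorted, so the
    map is symmetric by construction; diagonal and nearest-neighbour
    entries are never present.
    """

    probability: dict[tuple[ResKey, ResKey], float] = field(default_factory=dict)
    registry: dict[tuple[ResKey, ResKey], list[tuple[int, int]]] = field(
        default_factory=dict
    )

    @staticmethod
    def pair_key(a: ResKey, b: ResKey) -> tuple[ResKey, ResKey]:
        return (a, b) if a <= b else (b, a)

    def get_probability(self, a: ResKey, b: ResKey) -> float:
        return self.probability.get(self.pair_key(a, b), 0.0)

    def residue_pairs(self, residue: ResKey):
        for pair in self.registry:
            if residue in pair:
                yield pair

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        pairs = set(self.probability) | set(self.registry)
        for (a, b) in sorted(pairs):
            rows.append(
                {
                    "chain_i": a[0], "res_i": a[1],
                    "chain_j": b[0], "res_j": b[1],
                    "probability": self.probability.get((a, b), np.nan),
                    "n_native_atom_pairs": len(self.registry.get((a, b), [])),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhiRestraint:
    """Target ϕ for one residue; only 0 < ϕ < 1 is a usable restraint."""

    residue: ResKey
    target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target < 1.0:
            raise ValueError(
                f"restraint target must lie strictly inside (0, 1), got {self.target}"
            )
        if self.weight <= 0:
            raise ValueError("restraint weight must be positive")


def _eligible_pairs(ensemble: StructureEnsemble):
    ordinals = ensemble.residue_ordinals()
    residues = ensemble.residues
    for i, a in enumerate(residues):
        for b in residues[i + 1:]:
            if a[0] == b[0] and abs(ordinals[a] - ordinals[b]) <= 1:
                continue
            yield ContactMap.pair_key(a, b)


def _sidechain_by_residue(ensemble: StructureEnsemble) -> dict[ResKey, np.ndarray]:
    sc = ensemble.sidechain_heavy_indices()
    keys = ensemble.atom_residue_keys()
    out: dict[ResKey, list[int]] = {}
    for idx in sc:
        out.setdefault(keys[idx], []).append(int(idx))
    return {k: np.array(v) for k, v in out.items()}


def native_contacts(
    ensemble: StructureEnsemble, defn: ContactDefinition | None = None
) -> ContactMap:
    """Build the native-contact registry from a native-state ensemble.

    Returns a ContactMap whose registry stores, per residue pair, the
    qualifying heavy side-chain atom index pairs. Glycine contributes
    no side-chain heavy atoms and therefore no contacts.
    """
    defn = defn or ContactDefinition()
    if ensemble.n_models < 1:
        raise ValueError("empty ensemble")
    sc_by_res = _sidechain_by_residue(ensemble)
    cmap = ContactMap()
    X = ensemble.coords
    w = ensemble.weights
    for pair in _eligible_pairs(ensemble):
        a, b = pair
        ia = sc_by_res.get(a)
        ib = sc_by_res.get(b)
        if ia is None or ib is None:
            continue
        # (M, |ia|, |ib|) distances across all frames at once
        d = np.linalg.norm(X[:, ia, None, :] - X[:, None, ib, :], axis=-1)
        frac = np.tensordot(w, (d <= defn.cutoff).astype(float), axes=1)
        qual = np.argwhere(frac >= defn.frame_fraction)
        if qual.size:
            cmap.registry[pair] = [
                (int(ia[i]), int(ib[j])) for i, j in qual
            ]
    return cmap


def _pair_distances(coords: np.ndarray, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    idx = np.asarray(pairs)
    return np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=-1)


def _switch(d: np.ndarray, d0: float, n: int = 6, m: int = 12) -> np.ndarray:
    # PLUMED-style rational switching function, 0.5 at d = d0
    r = d / d0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(np.isclose(r, 1.0), n / m, (1 - r**n) / (1 - r**m))
    return np.clip(s, 0.0, 1.0)


def backcalc_phi(
    coords: np.ndarray,
    registry_map: ContactMap,
    residue: ResKey,
    cutoff: float = 0.6,
    smooth: bool = False,
) -> float:
    """ϕ of one residue in one conformation.

    The fraction of the residue's registered native atom pairs within
    the cutoff. With ``smooth=True`` the hard count is replaced by a
    rational switching function (differentiable, for samplers); hard
    counting is used for reporting.
    """
    pairs: list[tuple[int, int]] = []
    for key in registry_map.residue_pairs(residue):
        pairs.extend(registry_map.registry[key])
    if not pairs:
        raise ValueError(f"residue {residue} has no registered native contacts")
    d = _pair_distances(np.asarray(coords, dtype=float), pairs)
    if smooth:
        return float(np.mean(_switch(d, cutoff)))
    return float(np.mean(d <= cutoff))


def ensemble_phi(
    ensemble: StructureEnsemble,
    registry_map: ContactMap,
    residue: ResKey,
    cutoff: float = 0.6,
    smooth: bool = False,
) -> float:
    """Weighted ensemble average of the back-calculated ϕ."""
    vals = np.array(
        [
            backcalc_phi(ensemble.coords[m], registry_map, residue, cutoff, smooth)
            for m in range(ensemble.n_models)
        ]
    )
    return float(np.dot(ensemble.weights, vals))


def restraint_energy(
    phi_sim: Mapping[ResKey, float], restraints: Sequence[PhiRestraint]
) -> tuple[float, dict[ResKey, float]]:
    """Squared-deviation restraint pseudo-energy and its ϕ-gradient.

    E = Σ w·(ϕ_sim − ϕ_exp)²; ∂E/∂ϕ_sim = 2w·(ϕ_sim − ϕ_exp).
    Zero exactly when every target is met.
    """
    energy = 0.0
    grad: dict[ResKey, float] = {}
    for r in restraints:
        if r.residue not in phi_sim:
            raise ValueError(f"no back-calculated phi for restrained residue {r.residue}")
        dev = phi_sim[r.residue] - r.target
        energy += r.weight * dev * dev
        grad[r.residue] = grad.get(r.residue, 0.0) + 2.0 * r.weight * dev
    return float(energy), grad


def contact_probability_map(
    ensemble: StructureEnsemble, defn: ContactDefinition | None = None
) -> ContactMap:
    """Per-residue-pair contact probability over the ensemble.

    A pair is in contact in a model when any of its heavy side-chain
    atom pairs is within the cutoff; the probability is the weighted
    fraction of models in contact, so duplicating a model leaves the
    map unchanged.
    """
    defn = defn or ContactDefinition()
    if ensemble.n_models < 1:
        raise ValueError("empty ensemble")
    sc_by_res = _sidechain_by_residue(ensemble)
    cmap = ContactMap()
    X = ensemble.coords
    w = ensemble.weights
    for pair in _eligible_pairs(ensemble):
        a, b = pair
        ia = sc_by_res.get(a)
        ib = sc_by_res.get(b)
        if ia is None or ib is None:
            continue
        d = np.linalg.norm(X[:, ia, None, :] - X[:, None, ib, :], axis=-1)
        in_contact = (d <= defn.cutoff).any(axis=(1, 2))
        cmap.probability[pair] = float(np.dot(w, in_contact.astype(float)))
    return cmap


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral (degrees); inputs shaped (..., 3)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


#: α-helical (φ, ψ) window of the dihedral-based assignment surrogate.
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-67.0, -7.0)
MIN_HELIX_RUN = 4


def helix_content(ensemble: StructureEnsemble) -> dict[ResKey, float]:
    """Per-residue α-helix probability.

    A residue counts as helical in a model when its backbone (φ, ψ)
    fall inside the α window and it belongs to a run of at least four
    consecutive in-window residues of the same chain. This is a
    dihedral surrogate for hydrogen-bond-based secondary-structure
    assignment: it needs no hydrogens and agrees with it on regular
    helices, but is more permissive at fraying helix ends.
    """
    atoms = ensemble.atoms
    keys = ensemble.atom_residue_keys()
    bb: dict[ResKey, dict[str, int]] = {}
    for idx, (name, key) in enumerate(zip(atoms["name"], keys)):
        if name in ("N", "CA", "C"):
            bb.setdefault(key, {})[name] = idx

    chains: dict[str, list[ResKey]] = {}
    for key in ensemble.residues:
        chains.setdefault(key[0], []).append(key)

    M = ensemble.n_models
    result: dict[ResKey, float] = {key: 0.0 for key in ensemble.residues}
    w = ensemble.weights
    for ch, reslist in chains.items():
        n = len(reslist)
        in_window = np.zeros((M, n), dtype=bool)
        for i in range(1, n - 1):
            prev, cur, nxt = reslist[i - 1], reslist[i], reslist[i + 1]
            need = (
                "C" in bb.get(prev, {}),
                all(k in bb.get(cur, {}) for k in ("N", "CA", "C")),
                "N" in bb.get(nxt, {}),
            )
            if not all(need):
                continue
            X = ensemble.coords
            phi = _dihedral(
                X[:, bb[prev]["C"]], X[:, bb[cur]["N"]],
                X[:, bb[cur]["CA"]], X[:, bb[cur]["C"]],
            )
            psi = _dihedral(
                X[:, bb[cur]["N"]], X[:, bb[cur]["CA"]],
                X[:, bb[cur]["C"]], X[:, bb[nxt]["N"]],
            )
            in_window[:, i] = (
                (phi >= PHI_WINDOW[0]) & (phi <= PHI_WINDOW[1])
                & (psi >= PSI_WINDOW[0]) & (psi <= PSI_WINDOW[1])
            )
        helical = np.zeros_like(in_window)
        for m in range(M):
            run = 0
            for i in range(n + 1):
                if i < n and in_window[m, i]:
                    run += 1
                else:
                    if run >= MIN_HELIX_RUN:
                        helical[m, i - run:i] = True
                    run = 0
        for i, key in enumerate(reslist):
            result[key] = float(np.dot(w, helical[:, i].astype(float)))
    return result


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``."""
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    P = mobile - mu_m
    Q = reference - mu_r
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return P @ R.T + mu_r


def rg_and_rmsd(
    ensemble: StructureEnsemble,
    align_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius-of-gyration and pairwise-RMSD distributions.

    Rg is mass-weighted over heavy atoms, per model. Pairwise RMSD is
    computed over the alignment selection after optimal (Kabsch)
    superposition on that same selection; by construction it is
    invariant under rigid-body motion of either model. Returns
    (rg[n_models], rmsd[n_models·(n_models−1)/2]).
    """
    heavy = np.flatnonzero(
        ensemble.atoms["element"].str.upper().to_numpy() != "H"
    )
    masses = np.array(
        [_ATOM_MASS.get(str(e).upper(), 12.011) for e in ensemble.atoms["element"]]
    )[heavy]
    rg = np.empty(ensemble.n_models)
    for m in range(ensemble.n_models):
        x = ensemble.coords[m, heavy]
        com = np.average(x, axis=0, weights=masses)
        rg[m] = np.sqrt(np.average(np.sum((x - com) ** 2, axis=1), weights=masses))

    sel = heavy if align_indices is None else np.asarray(align_indices)
    rmsd = []
    for i in range(ensemble.n_models):
        ref = ensemble.coords[i, sel]
        for j in range(i + 1, ensemble.n_models):
            mob = superpose(ensemble.coords[j, sel], ref)
            rmsd.append(float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))))
    return rg, np.array(rmsd)
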