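"""Seeded generators for every input class the pipeline consumes.

Every generator is a pure function of its specification and seed and
returns the generated object together with a ground-truth record, so
each downstream stage (global fitting, ϕ analysis, ensemble analytics,
restrained sampling) can be scored without external data.

The default stopped-flow conditions mirror the experimental regime:
labelled protein at 1 µM, ligand varied over 1–10 µM, 1000 points per
trace, recording distorted by the instrument dead time (−1.25 ms time
zero, points before 2 ms unusable). Noise is i.i.d. Gaussian on the
signal; real photomultiplier noise is neither stated in the source data
nor modelled here, so the noise level is an explicit parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import Constants, DEFAULT_CONSTANTS
from .ensemble import StructureEnsemble
from .kinetics import (
    DeadTimeConvention,
    ObservableModel,
    RateParameters,
    Trace,
    TraceSet,
    analytic_kobs,
    get_scheme,
    integrate_scheme,
)

__all__ = [
    "TraceSpec",
    "ToyEnsembleSpec",
    "make_traces",
    "make_mutant_table",
    "make_toy_ensemble",
    "make_toy_dimer",
]


@dataclass
class TraceSpec:
    """Specification of a synthetic stopped-flow concentration series.

    For binding schemes (``two_state``, ``induced_fit``) the labelled
    species A is held at ``labeled_conc`` and the ligand B takes the
    values in ``ligand_series``. For ``displacement`` the preformed
    labelled complex AB is held at ``labeled_conc`` and the series
    gives competitor (C) concentrations.
    """

    scheme: str = "two_state"
    rates: RateParameters = field(default_factory=lambda: RateParameters(kon=30.4, koff=24.7))
    labeled_conc: float = 1.0
    ligand_series: Sequence[float] = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    n_points: int = 1000
    t_end: float | None = None
    noise_sd: float = 0.0
    observable: ObservableModel | None = None
    dead_time: DeadTimeConvention = field(default_factory=DeadTimeConvention)
    seed: int = 0


_DEFAULT_COEFFS = {
    "two_state": {"AB": 1.0},
    "induced_fit": {"AB": 1.0, "ABx": 0.5},
    "displacement": {"AB": 1.0},
}


def _initial_concentrations(spec: TraceSpec, ligand: float) -> dict[str, float]:
    if spec.scheme == "displacement":
        return {"AB": spec.labeled_conc, "C": ligand}
    return {"A": spec.labeled_conc, "B": ligand}


def _slowest_kobs(spec: TraceSpec) -> float:
    scheme = get_scheme(spec.scheme)
    if spec.scheme == "displacement":
        return spec.rates.koff
    rates = [analytic_kobs(scheme, spec.rates, b)[-1] for b in spec.ligand_series]
    return min(rates)


def make_traces(spec: TraceSpec) -> tuple[TraceSet, dict]:
    """Simulate a concentration series as the instrument records it.

    Signals are generated by numerical integration on the true reaction
    timeline, then time-stamped on the recorded timeline (shifted by
    the dead-time convention) with Gaussian noise added. The returned
    traces therefore require the same preprocessing as measured ones.
    """
    scheme = get_scheme(spec.scheme)
    observable = spec.observable or ObservableModel(
        baseline=1.0, species_coefficients=_DEFAULT_COEFFS[spec.scheme]
    )
    k_slow = _slowest_kobs(spec)
    t_end = spec.t_end if spec.t_end is not None else 5.0 / k_slow
    if t_end < 3.0 / k_slow:
        warnings.warn(
            f"t_end={t_end:g}s covers less than 3/kobs of the slowest "
            "relaxation; traces will be incomplete",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    traces = []
    for ligand in spec.ligand_series:
        recorded = np.linspace(0.0, t_end, spec.n_points)
        true_t = recorded - spec.dead_time.t_zero_shift
        conc0 = _initial_concentrations(spec, ligand)
        traj = integrate_scheme(scheme, spec.rates, conc0, true_t)
        signal = np.full_like(true_t, observable.baseline)
        for sp, c in observable.species_coefficients.items():
            signal = signal + c * traj[sp]
        signal *= observable.scale
        if spec.noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        traces.append(
            Trace(time=recorded, signal=signal, concentrations=conc0)
        )
    truth = {
        "scheme": spec.scheme,
        "rates": spec.rates,
        "observable": observable,
        "t_end": t_end,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return TraceSet(traces=traces, label=f"synthetic_{spec.scheme}"), truth


def make_mutant_table(
    base_kon: float = 30.4,
    base_koff: float = 24.7,
    perturbations: Sequence[tuple[str, float, float]] = (
        ("mutA", 0.3, 0.8),
        ("mutB", 0.6, 1.2),
        ("mutC", 0.9, 0.5),
    ),
    kon_error_fraction: float = 0.10,
    koff_error_fraction: float = 0.01,
    include_unstable_row: bool = True,
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, dict]:
    """Build a rate-constant table with designed ϕ-values.

    Each perturbation is ``(name, phi, ddG_EQ)``; the mutant rates are
    constructed by inverting the ϕ definition:

        kon_mt  = kon_wt · exp(−ϕ·ΔΔG_EQ/RT)
        Kd_mt   = Kd_wt · exp(ΔΔG_EQ/RT)
        koff_mt = Kd_mt · kon_mt

    so re-deriving ϕ from the table recovers the design exactly. A
    ``too_unstable`` row can be included to exercise exclusion logic.
    """
    RT = constants.RT
    rows = [
        {
            "complex_id": "pWT", "ncbd_variant": "pWT", "cid_variant": "WT",
            "probe": "synthetic", "condition": "",
            "kon": base_kon, "kon_se": kon_error_fraction * base_kon,
            "koff": base_koff, "koff_se": koff_error_fraction * base_koff,
            "koff_source": "binding_fit", "status": "ok", "group": "reference",
        }
    ]
    truth: dict[str, dict] = {}
    Kd_wt = base_koff / base_kon
    for name, phi_true, ddg_eq in perturbations:
        kon = base_kon * np.exp(-phi_true * ddg_eq / RT)
        Kd = Kd_wt * np.exp(ddg_eq / RT)
        koff = Kd * kon
        rows.append(
            {
                "complex_id": name, "ncbd_variant": "pWT", "cid_variant": name,
                "probe": "synthetic", "condition": "",
                "kon": kon, "kon_se": kon_error_fraction * kon,
                "koff": koff, "koff_se": koff_error_fraction * koff,
                "koff_source": "binding_fit", "status": "ok", "group": "designed",
            }
        )
        truth[name] = {"phi": phi_true, "ddG_EQ": ddg_eq,
                       "ddG_TS": phi_true * ddg_eq}
    if include_unstable_row:
        rows.append(
            {
                "complex_id": "unstable", "ncbd_variant": "pWT",
                "cid_variant": "unstable", "probe": "synthetic", "condition": "",
                "kon": None, "kon_se": None, "koff": None, "koff_se": None,
                "koff_source": "", "status": "too_unstable", "group": "designed",
            }
        )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# toy structural ensembles

# standard backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_HELIX = (-57.0, -47.0)
_EXTENDED = (-139.0, 135.0)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A, B, C with given internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            -bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(n_residues: int, helical: Sequence[bool]) -> tuple[np.ndarray, list]:
    """Backbone + CB coordinates (Å) for one chain from ideal geometry."""
    coords: list[np.ndarray] = []
    names: list[str] = []
    res_of: list[int] = []

    def add(pos, name, ri):
        coords.append(np.asarray(pos, float))
        names.append(name)
        res_of.append(ri)

    # seed residue 0
    add([0.0, 0.0, 0.0], "N", 0)
    add([_B_N_CA, 0.0, 0.0], "CA", 0)
    ang = np.radians(_A_N_CA_C)
    add(
        [_B_N_CA - _B_CA_C * np.cos(ang), _B_CA_C * np.sin(ang), 0.0],
        "C", 0,
    )
    idx = {("N", 0): 0, ("CA", 0): 1, ("C", 0): 2}
    for i in range(1, n_residues):
        phi, psi = _HELIX if helical[i] else _EXTENDED
        psi_prev = _HELIX[1] if helical[i - 1] else _EXTENDED[1]
        N = _nerf(coords[idx[("N", i - 1)]], coords[idx[("CA", i - 1)]],
                  coords[idx[("C", i - 1)]], _B_C_N, _A_CA_C_N, psi_prev)
        add(N, "N", i)
        idx[("N", i)] = len(coords) - 1
        CA = _nerf(coords[idx[("CA", i - 1)]], coords[idx[("C", i - 1)]],
                   N, _B_N_CA, _A_C_N_CA, 180.0)
        add(CA, "CA", i)
        idx[("CA", i)] = len(coords) - 1
        C = _nerf(coords[idx[("C", i - 1)]], N, CA, _B_CA_C, _A_N_CA_C, phi)
        add(C, "C", i)
        idx[("C", i)] = len(coords) - 1
    # side-chain pseudo-atoms (one CB per residue)
    for i in range(n_residues):
        CB = _nerf(coords[idx[("C", i)]], coords[idx[("N", i)]],
                   coords[idx[("CA", i)]], 1.53, 110.5, -122.0)
        add(CB, "CB", i)
    atom_info = list(zip(names, res_of))
    return np.array(coords), atom_info


@dataclass
class ToyEnsembleSpec:
    """Specification of a two-chain toy ensemble with known truth.

    Chains are ideal-geometry peptides (helical dihedrals over the
    first ``helix_fraction`` of each chain, extended otherwise) brought
    into contact. Designated native contacts are broken in an exact
    fraction of the models so downstream contact probabilities are
    known by construction.
    """

    n_residues: int = 10
    n_models: int = 10
    helix_fraction: float = 1.0
    contact_break_prob: float = 0.0
    perturbation: float = 0.005  # nm, Gaussian, per coordinate
    target_gap: float = 0.45     # nm, closest inter-chain CB distance
    seed: int = 0


def make_toy_ensemble(spec: ToyEnsembleSpec) -> tuple[StructureEnsemble, dict]:
    """Generate a two-chain toy ensemble plus ground truth.

    Truth keys: ``native_pairs`` (inter-chain CB contact pairs of the
    base structure at 0.6 nm), ``broken`` (pair → sorted model indices
    in which it was broken, exactly ⌊p·M⌋ of them), ``helical_true``
    (residues built with helical dihedrals, interior positions only).
    """
    n = spec.n_residues
    n_hel = int(round(spec.helix_fraction * n))
    helical = [i < n_hel for i in range(n)]
    xyz_a, atom_info = _build_chain(n, helical)
    xyz_b = xyz_a.copy()

    # search the inter-chain offset giving the requested closest approach
    cb_rows = np.array([i for i, (nm, _) in enumerate(atom_info) if nm == "CB"])
    direction = np.array([1.0, 0.3, 0.0])
    direction /= np.linalg.norm(direction)
    best_t, best_err = 8.0, np.inf
    for t in np.linspace(3.0, 30.0, 271):
        d = np.linalg.norm(
            (xyz_a[cb_rows, None, :] + 0)
            - (xyz_b[cb_rows][None, :, :] + t * direction),
            axis=-1,
        ).min()
        err = abs(d - spec.target_gap * 10.0)
        if err < best_err:
            best_err, best_t = err, t
    xyz_b = xyz_b + best_t * direction

    coords0 = np.vstack([xyz_a, xyz_b]) / 10.0  # Å -> nm
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * len(xyz_a) + ["B"] * len(xyz_b),
            "resid": [ri + 1 for _, ri in atom_info] * 2,
            "resname": ["ALA"] * (2 * len(xyz_a)),
            "name": [nm for nm, _ in atom_info] * 2,
            "element": [nm[0] for nm, _ in atom_info] * 2,
        }
    )

    # designated native pairs: inter-chain CB-CB within 0.6 nm in the base
    cb_a = cb_rows
    cb_b = cb_rows + len(xyz_a)
    d = np.linalg.norm(coords0[cb_a, None] - coords0[None, cb_b], axis=-1)
    native_pairs = [
        (("A", int(i + 1)), ("B", int(j + 1)))
        for i, j in np.argwhere(d <= 0.6)
    ]

    rng = np.random.default_rng(spec.seed)
    M = spec.n_models
    coords = np.repeat(coords0[None], M, axis=0)
    if spec.perturbation > 0:
        coords += rng.normal(0.0, spec.perturbation, size=coords.shape)

    # break designated contacts in an exact number of models; only pairs
    # whose B-side CB is unique among native pairs are breakable, so one
    # displacement cannot disturb another designated contact
    b_counts: dict[int, int] = {}
    for (_, (chb, rj)) in native_pairs:
        b_counts[rj] = b_counts.get(rj, 0) + 1
    broken: dict[tuple, list[int]] = {}
    if spec.contact_break_prob > 0:
        k = int(round(spec.contact_break_prob * M))
        for pair in native_pairs:
            (cha, ri), (chb, rj) = pair
            if b_counts[rj] != 1:
                continue
            models = sorted(rng.choice(M, size=k, replace=False).tolist())
            ai = cb_a[ri - 1]
            bj = cb_b[rj - 1]
            for m in models:
                u = coords[m, bj] - coords[m, ai]
                u /= np.linalg.norm(u)
                coords[m, bj] = coords[m, ai] + u * 0.95  # well past cutoff
            broken[pair] = models

    interior = set(range(1, n - 1))
    helical_true = [
        i + 1 for i in range(n) if helical[i] and i in interior and n_hel >= 4
    ]
    truth = {
        "native_pairs": native_pairs,
        "broken": broken,
        "helical_true": helical_true,
        "n_helical_built": n_hel,
    }
    return StructureEnsemble(atoms=atoms, coords=coords), truth


def make_toy_dimer(
    n_per_chain: int = 6, spacing: float = 0.33, separation: float = 0.45
) -> StructureEnsemble:
    """Bead-level native structure of a small dimer for Gō sampling.

    Two straight parallel chains of side-chain beads forming a slanted
    ladder: chain B is shifted by half a bead spacing along the chain
    axis, so every bead contacts the two quasi-opposite beads of the
    other chain (native distances ≈0.48 nm, inside the 0.6 nm cutoff)
    except the two chain ends, which have one contact each. An even
    contact count per interior residue means ϕ = 0.5 is exactly
    realizable, which makes this the reference system for restrained
    sampling tests.
    """
    z = np.arange(n_per_chain) * spacing
    xyz_a = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    xyz_b = np.column_stack(
        [np.full_like(z, separation), np.zeros_like(z), z + spacing / 2.0]
    )
    coords = np.vstack([xyz_a, xyz_b])
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * n_per_chain + ["B"] * n_per_chain,
            "resid": list(range(1, n_per_chain + 1)) * 2,
            "resname": ["ALA"] * (2 * n_per_chain),
            "name": ["CB"] * (2 * n_per_chain),
            "element": ["C"] * (2 * n_per_chain),
        }
    )
    return StructureEnsemble(atoms=atoms, coords=coords[None])
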