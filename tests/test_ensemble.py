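"""Native contacts, ϕ back-calculation, and ensemble observables.

The load-bearing checks compare the vectorized implementations against
a literal brute-force double loop on small random ensembles.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phimap as pm
from phimap.ensemble import ContactMap, superpose


def _random_ensemble(rng, n_res=6, n_models=8, box=1.2):
    """Two-chain ensemble of CB-only residues at random positions."""
    n_chain = n_res // 2
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * n_chain + ["B"] * (n_res - n_chain),
            "resid": list(range(1, n_chain + 1)) + list(range(1, n_res - n_chain + 1)),
            "resname": ["ALA"] * n_res,
            "name": ["CB"] * n_res,
            "element": ["C"] * n_res,
        }
    )
    coords = rng.uniform(0, box, size=(n_models, n_res, 3))
    return pm.StructureEnsemble(atoms=atoms, coords=coords)


def _brute_force_contacts(ens, cutoff=0.6, frame_fraction=0.5):
    """O(N^2 M) reference: literal loops over residues, atoms and models."""
    keys = ens.atom_residue_keys()
    ordinals = ens.residue_ordinals()
    sc = set(ens.sidechain_heavy_indices().tolist())
    registry, probability = {}, {}
    residues = ens.residues
    for i, a in enumerate(residues):
        for b in residues[i + 1:]:
            if a[0] == b[0] and abs(ordinals[a] - ordinals[b]) <= 1:
                continue
            ia = [k for k in sc if keys[k] == a]
            ib = [k for k in sc if keys[k] == b]
            pairs = []
            any_contact_frames = 0
            for m in range(ens.n_models):
                pass
            for p in ia:
                for q in ib:
                    n_in = sum(
                        np.linalg.norm(ens.coords[m, p] - ens.coords[m, q]) <= cutoff
                        for m in range(ens.n_models)
                    )
                    if n_in / ens.n_models >= frame_fraction:
                        pairs.append((p, q))
            for m in range(ens.n_models):
                hit = any(
                    np.linalg.norm(ens.coords[m, p] - ens.coords[m, q]) <= cutoff
                    for p in ia for q in ib
                )
                any_contact_frames += hit
            key = ContactMap.pair_key(a, b)
            if pairs:
                registry[key] = sorted(pairs)
            if ia and ib:
                probability[key] = any_contact_frames / ens.n_models
    return registry, probability


class TestNativeContacts:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        """Registry and probability map equal the double-loop reference exactly."""
        rng = np.random.default_rng(seed)
        ens = _random_ensemble(rng, n_res=8, n_models=10)
        reg = pm.native_contacts(ens)
        cmap = pm.contact_probability_map(ens)
        bf_reg, bf_prob = _brute_force_contacts(ens)
        assert {k: sorted(v) for k, v in reg.registry.items()} == bf_reg
        for key, p in bf_prob.items():
            assert cmap.probability.get(key, 0.0) == pytest.approx(p)

    def test_cutoff_boundary_pair_included(self):
        """An atom pair at 0.59 nm in every frame is one native contact."""
        atoms = pd.DataFrame({"chain": ["A", "A", "A"], "resid": [1, 2, 3],
                              "resname": ["ALA"] * 3, "name": ["CB"] * 3,
                              "element": ["C"] * 3})
        coords = np.zeros((4, 3, 3))
        coords[:, 1] = [5.0, 0, 0]     # neighbour, excluded anyway
        coords[:, 2] = [0.59, 0, 0]    # pair (1,3) at 0.59 nm
        ens = pm.StructureEnsemble(atoms=atoms, coords=coords)
        reg = pm.native_contacts(ens)
        assert len(reg.registry[(("A", 1), ("A", 3))]) == 1

    def test_frame_fraction_threshold(self):
        """In contact in 49 of 100 frames -> excluded; 50 -> included."""
        atoms = pd.DataFrame({"chain": ["A", "B"], "resid": [1, 1],
                              "resname": ["ALA"] * 2, "name": ["CB"] * 2,
                              "element": ["C"] * 2})
        for n_in, expected in ((49, 0), (50, 1)):
            coords = np.zeros((100, 2, 3))
            coords[:n_in, 1, 0] = 0.5
            coords[n_in:, 1, 0] = 2.0
            ens = pm.StructureEnsemble(atoms=atoms, coords=coords)
            reg = pm.native_contacts(ens)
            assert len(reg.registry.get((("A", 1), ("B", 1)), [])) == expected

    def test_glycine_has_no_contacts(self):
        """A residue with only backbone atoms contributes no native contacts."""
        atoms = pd.DataFrame(
            {"chain": ["A", "A", "B"], "resid": [1, 1, 1],
             "resname": ["GLY", "GLY", "ALA"],
             "name": ["N", "CA", "CB"], "element": ["N", "C", "C"]}
        )
        coords = np.zeros((2, 3, 3))
        ens = pm.StructureEnsemble(atoms=atoms, coords=coords)
        reg = pm.native_contacts(ens)
        assert reg.registry == {}

    def test_nearest_neighbours_excluded_interchain_kept(self, toy_dimer):
        reg = pm.native_contacts(toy_dimer)
        for (a, b) in reg.registry:
            assert not (a[0] == b[0] and abs(a[1] - b[1]) <= 1)
        assert any(a[0] != b[0] for a, b in reg.registry)

    def test_empty_ensemble_rejected(self):
        atoms = pd.DataFrame({"chain": [], "resid": [], "resname": [],
                              "name": [], "element": []})
        with pytest.raises(ValueError):
            pm.StructureEnsemble(atoms=atoms, coords=np.empty((0, 0, 3)))


class TestBackcalcPhi:
    def test_native_conformation_is_one(self, toy_dimer, dimer_registry):
        for res in toy_dimer.residues:
            assert pm.backcalc_phi(toy_dimer.coords[0], dimer_registry,
                                   res) == 1.0

    def test_dissociated_conformation_is_zero(self, toy_dimer, dimer_registry):
        coords = toy_dimer.coords[0].copy()
        coords[6:] += np.array([5.0, 0.0, 0.0])  # pull chain B away
        for res in toy_dimer.residues:
            assert pm.backcalc_phi(coords, dimer_registry, res) == 0.0

    def test_half_contacts_gives_half(self, toy_dimer, dimer_registry):
        """Breaking one of a residue's two contacts gives phi = 0.5 exactly."""
        res = ("A", 3)
        pairs = [p for key in dimer_registry.residue_pairs(res)
                 for p in dimer_registry.registry[key]]
        assert len(pairs) == 2
        coords = toy_dimer.coords[0].copy()
        i, j = pairs[0]
        other = j if toy_dimer.atom_residue_keys()[i] == res else i
        coords[other] += np.array([0.0, 5.0, 0.0])
        assert pm.backcalc_phi(coords, dimer_registry, res) == 0.5

    def test_monotone_under_expansion(self, toy_dimer, dimer_registry):
        """phi never increases as coordinates are scaled away from the COM."""
        base = toy_dimer.coords[0]
        com = base.mean(axis=0)
        res = ("A", 3)
        vals = [
            pm.backcalc_phi(com + s * (base - com), dimer_registry, res)
            for s in (1.0, 1.2, 1.5, 2.0, 4.0)
        ]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_contact_free_residue_rejected(self, dimer_registry, toy_dimer):
        with pytest.raises(ValueError, match="no registered native contacts"):
            pm.backcalc_phi(toy_dimer.coords[0], dimer_registry, ("A", 99))

    def test_smooth_variant_brackets_hard(self, toy_dimer, dimer_registry):
        res = ("A", 3)
        smooth = pm.backcalc_phi(toy_dimer.coords[0], dimer_registry, res,
                                 smooth=True)
        assert 0.5 < smooth <= 1.0


class TestRestraintEnergy:
    def test_zero_when_targets_met(self):
        restraints = [pm.PhiRestraint(("A", 1), 0.4), pm.PhiRestraint(("A", 2), 0.7)]
        e, grad = pm.restraint_energy({("A", 1): 0.4, ("A", 2): 0.7}, restraints)
        assert e == 0.0
        assert all(g == 0.0 for g in grad.values())

    def test_closed_form_quarter(self):
        e, grad = pm.restraint_energy({("A", 1): 0.9},
                                      [pm.PhiRestraint(("A", 1), 0.4)])
        assert e == pytest.approx(0.25)
        assert grad[("A", 1)] == pytest.approx(1.0)

    @given(phi_sim=st.floats(0, 1), target=st.floats(0.01, 0.99),
           weight=st.floats(0.1, 10))
    def test_non_negative(self, phi_sim, target, weight):
        e, _ = pm.restraint_energy({("A", 1): phi_sim},
                                   [pm.PhiRestraint(("A", 1), target, weight)])
        assert e >= 0.0

    def test_missing_phi_rejected(self):
        with pytest.raises(ValueError, match="no back-calculated"):
            pm.restraint_energy({}, [pm.PhiRestraint(("A", 1), 0.5)])

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.4])
    def test_targets_outside_open_interval_rejected(self, bad):
        with pytest.raises(ValueError, match="strictly inside"):
            pm.PhiRestraint(("A", 1), bad)


class TestContactProbability:
    def test_single_model_probabilities_binary(self, rng):
        ens = _random_ensemble(rng, n_models=1)
        cmap = pm.contact_probability_map(ens)
        assert set(cmap.probability.values()) <= {0.0, 1.0}

    def test_duplicated_model_invariant(self, rng):
        ens = _random_ensemble(rng, n_models=4)
        dup = pm.StructureEnsemble(
            atoms=ens.atoms, coords=np.concatenate([ens.coords, ens.coords])
        )
        c1 = pm.contact_probability_map(ens)
        c2 = pm.contact_probability_map(dup)
        for k, v in c1.probability.items():
            assert c2.probability[k] == pytest.approx(v)

    def test_probabilities_in_unit_interval_and_symmetric(self, rng):
        ens = _random_ensemble(rng, n_models=6)
        cmap = pm.contact_probability_map(ens)
        for (a, b), v in cmap.probability.items():
            assert 0.0 <= v <= 1.0
            assert a <= b  # canonical ordering = symmetry by construction
            assert cmap.get_probability(b, a) == v


class TestHelixContent:
    def test_ideal_helix_interior_is_one(self):
        ens, truth = pm.make_toy_ensemble(
            pm.ToyEnsembleSpec(n_residues=8, n_models=3, helix_fraction=1.0,
                               perturbation=0.001, seed=5))
        hel = pm.helix_content(ens)
        for ch in ("A", "B"):
            for resid in truth["helical_true"]:
                assert hel[(ch, resid)] == 1.0

    def test_extended_chain_is_zero(self):
        ens, _ = pm.make_toy_ensemble(
            pm.ToyEnsembleSpec(n_residues=8, n_models=3, helix_fraction=0.0,
                               perturbation=0.001, seed=5))
        assert max(pm.helix_content(ens).values()) == 0.0

    def test_mixed_ensemble_averages(self):
        """Half the models helical, half extended -> probability 0.5."""
        hel_ens, truth = pm.make_toy_ensemble(
            pm.ToyEnsembleSpec(n_residues=8, n_models=2, helix_fraction=1.0,
                               perturbation=0.0, seed=0))
        ext_ens, _ = pm.make_toy_ensemble(
            pm.ToyEnsembleSpec(n_residues=8, n_models=2, helix_fraction=0.0,
                               perturbation=0.0, seed=0))
        mixed = pm.StructureEnsemble(
            atoms=hel_ens.atoms,
            coords=np.concatenate([hel_ens.coords, ext_ens.coords]))
        hel = pm.helix_content(mixed)
        for resid in truth["helical_true"]:
            assert hel[("A", resid)] == pytest.approx(0.5)


class TestRgRmsd:
    def test_single_model_degenerate(self, toy_dimer):
        rg, rmsd = pm.rg_and_rmsd(toy_dimer)
        assert rg.shape == (1,)
        assert rmsd.size == 0

    def test_rigid_copies_have_zero_rmsd(self, toy_dimer, rng):
        base = toy_dimer.coords[0]
        # arbitrary rotation + translation of the whole structure
        theta = 0.8
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = base @ R.T + np.array([1.0, -2.0, 0.5])
        ens = pm.StructureEnsemble(atoms=toy_dimer.atoms,
                                   coords=np.stack([base, moved]))
        rg, rmsd = pm.rg_and_rmsd(ens)
        assert rmsd[0] == pytest.approx(0.0, abs=1e-9)
        assert rg[0] == pytest.approx(rg[1], rel=1e-12)

    def test_point_mass_rg_zero(self):
        atoms = pd.DataFrame({"chain": ["A"], "resid": [1], "resname": ["ALA"],
                              "name": ["CB"], "element": ["C"]})
        ens = pm.StructureEnsemble(atoms=atoms, coords=np.zeros((1, 1, 3)))
        rg, _ = pm.rg_and_rmsd(ens)
        assert rg[0] == 0.0

    def test_superpose_recovers_rotated(self, rng):
        x = rng.normal(size=(10, 3))
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        y = x @ R.T + 3.0
        np.testing.assert_allclose(superpose(y, x), x, atol=1e-10)
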