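"""Two-state ensemble bookkeeping and real-space validation metrics."""

import numpy as np
import pytest

from densdelta.grid_io import Atom, DensityMap, StructureModel
from densdelta.modeling import (
    NoEnvironmentError,
    bfactor_ratio,
    coord_rmsd,
    extract_changed_state,
    merge_ensemble,
    rscc,
    rszd,
    validate,
)
from densdelta.synthetic import density_from_atoms


def protein(n=6, b=20.0):
    return StructureModel([
        Atom("A", i + 1, "ALA", "CA", "C", "", 4.0 + 1.8 * i,
             5.0 + 0.9 * (i % 2), 5.0, 1.0, b)
        for i in range(n)
    ])


class TestMergeExtract:
    def test_identical_states_all_shared(self):
        g = protein()
        ens = merge_ensemble(g, g, bdc=0.5)
        assert len(ens.ground_only()) == 0
        assert len(ens.changed_only()) == 0
        assert len(ens.shared()) == len(g)
        assert all(a.occupancy == 1.0 for a in ens.shared())

    def test_occupancy_formula(self):
        """bdc = 0.8 gives changed occupancy q = 2·(1-0.8) = 0.4."""
        g = protein()
        moved = StructureModel(
            [g.atoms[0].moved(g.atoms[0].position + [2.0, 0, 0])]
            + g.atoms[1:])
        ens = merge_ensemble(g, moved, bdc=0.8)
        assert ens.occupancy_changed == pytest.approx(0.4)
        assert all(a.occupancy == pytest.approx(0.6)
                   for a in ens.ground_only())
        assert all(a.occupancy == pytest.approx(0.4)
                   for a in ens.changed_only())

    def test_occupancy_clamped_for_extreme_bdc(self):
        g = protein()
        moved = StructureModel(
            [g.atoms[0].moved(g.atoms[0].position + [2.0, 0, 0])]
            + g.atoms[1:])
        assert merge_ensemble(g, moved, 0.99).occupancy_changed == pytest.approx(0.05)
        assert merge_ensemble(g, moved, 0.1).occupancy_changed == pytest.approx(1.0)

    def test_water_displaced_by_ligand(self):
        """A ground-state water replaced by a ligand atom: paired conformer
        occupancies sum to one."""
        g = StructureModel(protein().atoms
                           + [Atom("W", 500, "HOH", "O", "O", "",
                                   10.0, 10.0, 10.0, 1.0, 30.0)])
        c = StructureModel(protein().atoms
                           + [Atom("L", 900, "LIG", "C1", "C", "",
                                   10.2, 10.0, 10.0, 1.0, 25.0)])
        ens = merge_ensemble(g, c, bdc=0.7)
        q = ens.occupancy_changed
        assert q == pytest.approx(0.6)
        water = [a for a in ens.model if a.resname == "HOH"]
        ligand = [a for a in ens.model if a.resname == "LIG"]
        assert water[0].altloc == ens.ground_conformer
        assert ligand[0].altloc == ens.changed_conformer
        assert water[0].occupancy + ligand[0].occupancy == pytest.approx(1.0, abs=1e-9)

    def test_merge_extract_round_trip(self):
        g = protein()
        changed_atoms = ([g.atoms[0].moved(g.atoms[0].position + [1.7, 0.3, 0])]
                         + g.atoms[1:]
                         + [Atom("L", 900, "LIG", "C1", "C", "",
                                 8.0, 9.0, 5.5, 1.0, 25.0)])
        changed = StructureModel(changed_atoms)
        ens = merge_ensemble(g, changed, bdc=0.6)
        back = extract_changed_state(ens)
        assert len(back) == len(changed)
        orig = {(a.chain, a.resnum, a.name): a for a in changed}
        for a in back:
            ref = orig[(a.chain, a.resnum, a.name)]
            assert np.allclose(a.position, ref.position, atol=1e-6)

    def test_extract_counts(self, rng):
        for _ in range(10):
            g = protein(8)
            movers = rng.choice(8, rng.integers(0, 4), replace=False)
            atoms = [
                a.moved(a.position + [2.0, 0, 0]) if i in movers else a
                for i, a in enumerate(g.atoms)
            ]
            changed = StructureModel(atoms)
            ens = merge_ensemble(g, changed, bdc=0.5)
            got = extract_changed_state(ens)
            assert len(got) == len(ens.shared()) + len(ens.changed_only())

    def test_occupancy_sum_rule_any_bdc(self, rng):
        g = protein()
        moved = StructureModel(
            [g.atoms[0].moved(g.atoms[0].position + [2.0, 0, 0])]
            + g.atoms[1:])
        for bdc in rng.uniform(0.0, 0.99, 20):
            ens = merge_ensemble(g, moved, float(bdc))
            go = {(a.chain, a.resnum, a.name): a for a in ens.ground_only()}
            co = {(a.chain, a.resnum, a.name): a for a in ens.changed_only()}
            for key in set(go) & set(co):
                total = go[key].occupancy + co[key].occupancy
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_distant_frames_rejected(self):
        g = protein()
        far = StructureModel([a.moved(a.position + [100.0, 0, 0])
                              for a in g.atoms])
        with pytest.raises(ValueError):
            merge_ensemble(g, far, 0.5)


def _grid(shape=(28, 28, 28), spacing=0.5):
    return DensityMap(np.zeros(shape), spacing)


class TestRSCC:
    def test_perfect_model_scores_one(self):
        atoms = protein(4)
        grid = _grid()
        observed = density_from_atoms(atoms, grid)
        assert rscc(atoms, observed) == pytest.approx(1.0, abs=1e-12)

    def test_noise_only_scores_near_zero(self, rng):
        atoms = protein(4)
        grid = _grid()
        scores = []
        for _ in range(20):
            observed = grid.like(rng.standard_normal(grid.shape))
            scores.append(abs(rscc(atoms, observed)))
        assert np.quantile(scores, 0.95) < 0.25

    def test_attenuation_by_noise_matches_formula(self, rng):
        """observed = model + N(0, 0.5·sd(model)) attenuates the correlation
        toward 1/sqrt(1.25) ≈ 0.894, comfortably above 0.85."""
        atoms = protein(4)
        grid = _grid()
        model_density = density_from_atoms(atoms, grid)
        from densdelta.modeling import _atom_mask
        mask_sd = model_density.values[_atom_mask(
            atoms.coordinates(), grid, 1.5)].std()
        scores = []
        for _ in range(10):
            observed = grid.like(model_density.values
                                 + 0.5 * mask_sd * rng.standard_normal(grid.shape))
            scores.append(rscc(atoms, observed))
        assert np.mean(scores) > 0.85
        assert np.mean(scores) == pytest.approx(1 / np.sqrt(1.25), abs=0.03)

    def test_tiny_mask_rejected(self):
        atoms = protein(1)
        grid = DensityMap(np.zeros((8, 8, 8)), 2.0)  # coarse -> few voxels
        with pytest.raises(ValueError):
            rscc(atoms, grid, radius=0.5)


class TestRSZD:
    def test_zero_for_exact_model(self):
        atoms = protein(3)
        grid = _grid()
        md = density_from_atoms(atoms, grid)
        assert rszd(atoms, md, md, 0.1) == 0.0

    def test_null_calibration(self, rng):
        """With correct model and matched sigma, the score stays below 3 in
        at least 95% of trials."""
        atoms = protein(3)
        grid = _grid()
        md = density_from_atoms(atoms, grid)
        below = 0
        for _ in range(200):
            observed = grid.like(md.values + 0.1 * rng.standard_normal(grid.shape))
            below += rszd(atoms, observed, md, 0.1) < 3.0
        assert below / 200 >= 0.95

    def test_missing_atom_detected(self, rng):
        """Density for an unmodelled atom drives the score above 3."""
        modelled = protein(3)
        extra = Atom("L", 900, "LIG", "C1", "C", "", 6.0, 7.2, 5.0, 1.0, 20.0)
        grid = _grid()
        md = density_from_atoms(modelled, grid)
        full = density_from_atoms(list(modelled) + [extra], grid)
        peak = full.values.max()
        observed = grid.like(full.values
                             + 0.1 * peak * rng.standard_normal(grid.shape))
        probe = StructureModel(list(modelled) + [extra])
        assert rszd(probe, observed, md, 0.1 * peak) > 3.0

    def test_nonpositive_sigma_rejected(self):
        atoms = protein(3)
        grid = _grid()
        md = density_from_atoms(atoms, grid)
        observed = grid.like(md.values + 1.0)
        with pytest.raises(ValueError):
            rszd(atoms, observed, md, 0.0)


class TestBFactorRatio:
    def test_equal_b_gives_unity(self):
        env = protein(6, b=20.0)
        lig = StructureModel([Atom("L", 900, "LIG", "C1", "C", "",
                                   6.0, 6.0, 5.0, 1.0, 20.0)])
        model = StructureModel(list(env)
                               + [Atom("A", 2, "ALA", "CB", "C", "",
                                       5.5, 6.5, 5.2, 1.0, 20.0)]
                               + list(lig))
        assert bfactor_ratio(lig, model) == pytest.approx(1.0)

    def test_hot_ligand_flagged(self):
        lig = StructureModel([Atom("L", 900, "LIG", "C1", "C", "",
                                   6.0, 6.0, 5.0, 1.0, 60.0)])
        model = StructureModel(list(protein(6))
                               + [Atom("A", 2, "ALA", "CB", "C", "",
                                       5.5, 6.5, 5.2, 1.0, 20.0)]
                               + list(lig))
        assert bfactor_ratio(lig, model) == pytest.approx(3.0)

    def test_backbone_only_environment_is_error(self):
        """Backbone atoms never count as environment."""
        lig = StructureModel([Atom("L", 900, "LIG", "C1", "C", "",
                                   6.0, 6.0, 5.0, 1.0, 30.0)])
        model = StructureModel(list(protein(6)) + list(lig))  # CA only
        with pytest.raises(NoEnvironmentError):
            bfactor_ratio(lig, model)


class TestCoordRMSD:
    def test_identical_models_zero(self):
        g = protein()
        assert coord_rmsd(g, g) == 0.0

    def test_one_of_four_displaced(self):
        before = protein(4)
        after = StructureModel(
            [before.atoms[0].moved(before.atoms[0].position + [2.0, 0, 0])]
            + before.atoms[1:])
        assert coord_rmsd(before, after) == pytest.approx(1.0)

    def test_gaussian_perturbation_matches_chi(self, rng):
        before = protein(200 // 6 * 6)
        sd = 0.1
        after = StructureModel([
            a.moved(a.position + sd * rng.standard_normal(3))
            for a in before
        ])
        expected = sd * np.sqrt(3)
        assert coord_rmsd(before, after) == pytest.approx(expected, rel=0.10)

    def test_disjoint_models_rejected(self):
        a = protein(3)
        b = StructureModel([Atom("B", 9, "GLY", "CA", "C", "", 0, 0, 0)])
        with pytest.raises(ValueError):
            coord_rmsd(a, b)


class TestValidate:
    def _setup(self, rng, ligand_b=20.0, noise=0.02, rmsd_shift=0.0,
               observed_from="changed"):
        ground = protein(6)
        lig_atoms = [
            Atom("L", 900, "LIG", f"C{i+1}", "C", "",
                 6.0 + 1.4 * i, 8.5, 5.0, 1.0, ligand_b)
            for i in range(3)
        ]
        side = Atom("A", 3, "ALA", "CB", "C", "", 7.2, 7.0, 5.3, 1.0, 20.0)
        ground_full = StructureModel(list(ground) + [side])
        changed = StructureModel(list(ground) + [side] + lig_atoms)
        grid = _grid((32, 32, 32))
        model_density = density_from_atoms(changed, grid)
        if observed_from == "changed":
            base = model_density.values
        else:
            base = rng.standard_normal(grid.shape)
        observed = grid.like(base + noise * rng.standard_normal(grid.shape))
        ens = merge_ensemble(ground_full, changed, bdc=0.5)
        refined = StructureModel([
            a.moved(a.position + [rmsd_shift, 0.0, 0.0]) for a in changed
        ])
        ligand = StructureModel(lig_atoms)
        return ligand, ens, refined, observed, model_density

    def test_good_ligand_passes_everything(self, rng):
        ligand, ens, refined, observed, md = self._setup(rng)
        report = validate(ligand, ens, refined, observed, md, 0.05)
        assert report.rscc_pass and report.rszd_pass
        assert report.b_ratio_flag == "pass" and report.rmsd_pass
        assert report.all_pass

    def test_ligand_in_noise_fails_rscc(self, rng):
        ligand, ens, refined, observed, md = self._setup(
            rng, observed_from="noise", noise=1.0)
        report = validate(ligand, ens, refined, observed, md, 1.0)
        assert report.rscc_pass is False

    def test_hot_ligand_fails_b_ratio_only(self, rng):
        ligand, ens, refined, observed, md = self._setup(rng, ligand_b=70.0)
        report = validate(ligand, ens, refined, observed, md, 0.05)
        assert report.b_ratio_flag == "fail"
        assert report.rmsd_pass

    def test_boundary_semantics_are_strict(self):
        from densdelta.modeling import ValidationReport
        r = ValidationReport(rscc=0.7, rszd=3.0, b_ratio=1.5, rmsd=1.0)
        assert r.rscc_pass is False       # strict >
        assert r.rszd_pass is False       # strict <
        assert r.b_ratio_flag == "pass"   # warn only above 1.5
        assert r.rmsd_pass is False       # strict <
        r2 = ValidationReport(rscc=0.71, rszd=2.9, b_ratio=1.6, rmsd=0.9)
        assert r2.rscc_pass and r2.rszd_pass and r2.rmsd_pass
        assert r2.b_ratio_flag == "warn"
        assert ValidationReport(b_ratio=3.01).b_ratio_flag == "fail"
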