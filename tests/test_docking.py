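import numpy as np
import pytest

from spindock import synthetic
from spindock.docking import (
    DockingParams,
    Pose,
    average_models,
    extrapolate_tetramer,
    minimize_pose,
    pose_energy,
    run_docking,
    validate_model,
)
from spindock.geometry import Atom, RigidBody, Transform, sample_rotation, transform_body
from spindock.restraints import AtomSite, DistanceRestraint

FAST = DockingParams(clash_atom_stride=3, max_iterations=25, funnel_width=2.0)


def single_atom_body(name, chain, resnum, pos):
    return RigidBody(name, [Atom(chain, resnum, "GLY", "CA", "C", np.asarray(pos, float))])


def simple_restraint(target, half=1.0, weight=1.0, label="r"):
    return DistanceRestraint(
        label=label,
        source="SYNTH",
        site_a=AtomSite("A", "A", 1, "CA"),
        site_b=AtomSite("B", "B", 1, "CA"),
        target=target,
        lower_bound=target - half,
        upper_bound=target + half,
        weight=weight,
    )


class TestPoseEnergy:
    def test_satisfied_and_clash_free_is_zero(self, toy_problem):
        body_a, body_b, restraints, truth = toy_problem
        e_noe, e_clash, dev = pose_energy(body_a, body_b, Pose(truth), restraints)
        assert e_noe == 0.0
        assert e_clash == 0.0
        assert np.abs(dev).max() < 1e-9

    def test_single_violation_quadratic(self):
        a = single_atom_body("a", "A", 1, [0, 0, 0])
        b = single_atom_body("b", "B", 1, [20, 0, 0])
        r = simple_restraint(10.0, half=1.0, weight=2.5)
        e_noe, _, dev = pose_energy(a, b, Pose(Transform.identity()), [r])
        # distance 20, upper bound 11 -> violation 9
        assert e_noe == pytest.approx(2.5 * 9.0**2)
        assert dev[0] == pytest.approx(10.0)

    def test_clash_matches_bruteforce_all_pairs(self, rng):
        from conftest import random_body

        a = random_body(rng, 25, "a")
        b = random_body(rng, 25, "b")
        params = DockingParams()  # stride 1: every heavy atom
        r = DistanceRestraint(
            "r", "SYNTH",
            AtomSite("A", "X", 1, "CA"), AtomSite("B", "X", 1, "CA"),
            10.0, 0.0, 50.0,
        )
        _, e_clash, _ = pose_energy(a, b, Pose(Transform.identity()), [r], params=params)
        brute = 0.0
        for pa in a.coords:
            for pb in b.coords:
                d = np.linalg.norm(pa - pb)
                if d < params.clash_distance:
                    brute += params.k_rep * (params.clash_distance - d) ** 2
        assert e_clash == pytest.approx(brute, abs=1e-12)

    def test_invariant_under_global_rigid_motion(self, toy_problem, rng):
        body_a, body_b, restraints, truth = toy_problem
        pose = Pose(truth)
        e0 = pose_energy(body_a, body_b, pose, restraints)
        g = Transform(sample_rotation(rng).rotation, rng.uniform(-15, 15, size=3))
        moved_a = transform_body(body_a, g)
        pose_g = Pose(g @ truth)  # B coords unchanged; A frame moved by g
        e1 = pose_energy(moved_a, body_b, pose_g, restraints)
        assert e0[0] == pytest.approx(e1[0], abs=1e-6)
        assert e0[1] == pytest.approx(e1[1], abs=1e-6)

    def test_zero_iff_inside_flat_bottom(self):
        a = single_atom_body("a", "A", 1, [0, 0, 0])
        b = single_atom_body("b", "B", 1, [10.5, 0, 0])
        r = simple_restraint(10.0, half=1.0)
        e_noe, _, _ = pose_energy(a, b, Pose(Transform.identity()), [r])
        assert e_noe == 0.0
        b2 = single_atom_body("b", "B", 1, [11.5, 0, 0])
        e_noe2, _, _ = pose_energy(a, b2, Pose(Transform.identity()), [r])
        assert e_noe2 > 0.0


class TestMinimizePose:
    def test_zero_energy_start_unchanged(self, toy_problem):
        body_a, body_b, restraints, truth = toy_problem
        sol = minimize_pose(body_a, body_b, Pose(truth), restraints, params=FAST)
        assert sol.e_noe == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(
            sol.pose.transform.apply(body_b.coords),
            truth.apply(body_b.coords),
            atol=1e-3,
        )

    def test_one_dimensional_well(self):
        a = single_atom_body("a", "A", 1, [0, 0, 0])
        b = single_atom_body("b", "B", 1, [30, 0, 0])
        r = simple_restraint(10.0, half=0.5)
        sol = minimize_pose(a, b, Pose(Transform.identity()), [r], params=FAST)
        d = np.linalg.norm(sol.pose.transform.apply(b.coords)[0] - a.coords[0])
        assert r.lower_bound - 1e-4 <= d <= r.upper_bound + 1e-4
        assert sol.e_noe < 1e-8

    def test_best_of_50_starts_recovers_truth(self):
        body_a, body_b, restraints, truth = synthetic.docking_scenario(seed=11)
        sols = run_docking(
            body_a, body_b, restraints, n_starts=50, seed=11,
            params=DockingParams(d_acc=0.1, clash_max=0.5, clash_atom_stride=3,
                                 max_iterations=25, funnel_width=2.0),
        )
        bb = body_b.backbone_indices()
        tc = truth.apply(body_b.coords[bb])
        best = min(
            np.sqrt(((s.pose.transform.apply(body_b.coords[bb]) - tc) ** 2).sum(axis=1).mean())
            for s in sols
            if s.accepted
        )
        assert best <= 1.0


class TestRunDocking:
    def test_zero_restraints_refused(self, toy_problem):
        body_a, body_b, _, _ = toy_problem
        with pytest.raises(ValueError):
            run_docking(body_a, body_b, [], n_starts=5)

    def test_deterministic_for_fixed_seed(self, toy_problem):
        body_a, body_b, restraints, _ = toy_problem
        s1 = run_docking(body_a, body_b, restraints, n_starts=12, seed=4, params=FAST)
        s2 = run_docking(body_a, body_b, restraints, n_starts=12, seed=4, params=FAST)
        assert [s.accepted for s in s1] == [s.accepted for s in s2]
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(
                a.pose.transform.translation, b.pose.transform.translation
            )

    def test_inconsistent_restraints_zero_acceptance(self):
        body_a, body_b, _, truth = synthetic.docking_scenario(seed=5)
        # targets drawn from two incompatible poses
        r1 = synthetic.docking_scenario(seed=5)[2][:3]
        r2 = synthetic.docking_scenario(seed=50)[2][3:]
        mixed = list(r1) + list(r2)
        params = DockingParams(d_acc=0.05, clash_max=0.5, clash_atom_stride=3,
                               max_iterations=25, funnel_width=2.0)
        sols = run_docking(body_a, body_b, mixed, n_starts=20, seed=0, params=params)
        assert sum(s.accepted for s in sols) == 0

    def test_acceptance_monotone_in_d_acc(self, toy_problem):
        body_a, body_b, restraints, _ = toy_problem
        params = DockingParams(d_acc=5.0, clash_max=0.5, clash_atom_stride=3,
                               max_iterations=25, funnel_width=2.0)
        sols = run_docking(body_a, body_b, restraints, n_starts=25, seed=1, params=params)
        counts = []
        for d_acc in (5.0, 2.0, 0.5, 0.1):
            counts.append(
                sum(
                    1
                    for s in sols
                    if s.converged
                    and s.violations.max() <= d_acc
                    and s.e_clash <= params.clash_max
                )
            )
        assert all(counts[i + 1] <= counts[i] for i in range(len(counts) - 1))


class TestAverageModels:
    def test_identical_solutions_zero_rmsd(self, toy_problem):
        body_a, body_b, restraints, truth = toy_problem
        sol = minimize_pose(body_a, body_b, Pose(truth), restraints, params=FAST)
        sol.accepted = True
        import copy

        ens = average_models([sol, copy.deepcopy(sol), copy.deepcopy(sol)], body_a, body_b)
        assert ens.rmsd_backbone_mean == pytest.approx(0.0, abs=1e-9)
        assert ens.rmsd_heavy_mean == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_pair_equal_rmsd(self, toy_problem):
        body_a, body_b, restraints, truth = toy_problem
        s1 = minimize_pose(body_a, body_b, Pose(truth), restraints, params=FAST)
        shift = Transform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        s2 = minimize_pose(
            body_a, body_b, Pose(shift @ truth), restraints, params=FAST
        )
        s1.accepted = s2.accepted = True
        # force exact poses (skip minimizer drift) for the symmetry statement
        s1.pose = Pose(truth)
        s2.pose = Pose(shift @ truth)
        ens = average_models([s1, s2], body_a, body_b)
        bb = body_b.backbone_indices()
        mean_b = ens.average_coords_b
        r = []
        na_bb = len(body_a.backbone_indices())
        for s in (s1, s2):
            diff = s.pose.transform.apply(body_b.coords) - mean_b
            r.append(np.sqrt((diff[bb] ** 2).sum() / (na_bb + len(bb))))
        assert r[0] == pytest.approx(r[1], rel=1e-9)

    def test_rmsd_matches_independent_recomputation(self, toy_problem):
        body_a, body_b, restraints, truth = toy_problem
        params = DockingParams(d_acc=0.5, clash_max=0.5, clash_atom_stride=3,
                               max_iterations=25, funnel_width=2.0)
        sols = run_docking(body_a, body_b, restraints, n_starts=15, seed=2, params=params)
        accepted = [s for s in sols if s.accepted]
        if not accepted:
            pytest.skip("no accepted solutions in this tiny run")
        ens = average_models(accepted, body_a, body_b)
        bb = body_b.backbone_indices()
        coords = np.stack([s.pose.transform.apply(body_b.coords) for s in accepted])
        mean_b = coords.mean(axis=0)
        na = len(body_a)
        na_bb = len(body_a.backbone_indices())
        r_bb, r_heavy = [], []
        for c in coords:
            sq = ((c - mean_b) ** 2).sum(axis=1)
            r_heavy.append(np.sqrt(sq.sum() / (na + len(body_b))))
            r_bb.append(np.sqrt(sq[bb].sum() / (na_bb + len(bb))))
        assert ens.rmsd_backbone_mean == pytest.approx(np.mean(r_bb), rel=1e-9)
        assert ens.rmsd_heavy_mean == pytest.approx(np.mean(r_heavy), rel=1e-9)

    def test_empty_accepted_rejected(self, toy_problem):
        body_a, body_b, _, _ = toy_problem
        with pytest.raises(ValueError):
            average_models([], body_a, body_b)


class TestValidateModel:
    def test_exact_model_zero_deviation(self, toy_problem):
        body_a, body_b, restraints, truth = toy_problem
        deviations, max_dev = validate_model(body_a, body_b, Pose(truth), restraints)
        assert max_dev < 1e-9

    def test_two_restraint_toy_hand_measured(self):
        a = RigidBody(
            "a",
            [
                Atom("A", 1, "GLY", "CA", "C", [0.0, 0.0, 0.0]),
                Atom("A", 2, "GLY", "CA", "C", [3.0, 0.0, 0.0]),
            ],
        )
        b = RigidBody(
            "b",
            [
                Atom("B", 1, "GLY", "CA", "C", [10.0, 0.0, 0.0]),
                Atom("B", 2, "GLY", "CA", "C", [10.0, 4.0, 0.0]),
            ],
        )
        rs = [
            DistanceRestraint("r1", "SYNTH", AtomSite("A", "A", 1, "CA"),
                              AtomSite("B", "B", 1, "CA"), 9.0, 8.0, 10.0),
            DistanceRestraint("r2", "SYNTH", AtomSite("A", "A", 2, "CA"),
                              AtomSite("B", "B", 2, "CA"), 5.0, 4.0, 6.0),
        ]
        deviations, max_dev = validate_model(a, b, Pose(Transform.identity()), rs)
        # hand measurement: d1 = 10 -> dev +1; d2 = sqrt(49+16) = 8.0623 -> dev 3.0623
        assert deviations[0] == pytest.approx(1.0)
        assert deviations[1] == pytest.approx(np.sqrt(65) - 5.0)
        assert max_dev == pytest.approx(np.sqrt(65) - 5.0)


def _tetramer_fixture():
    """Model with a 'chaperone' chain V, histone chain H, partner chain Y."""

    def chain(chain_id, offset, n=6):
        atoms = []
        for i in range(n):
            base = np.array([float(i) * 2.0, offset, 0.0])
            for atom_name, shift in (("N", [0.0, 0.3, 0.0]), ("CA", [0.5, 0.0, 0.0]),
                                     ("C", [1.0, -0.3, 0.0]), ("O", [1.0, -1.3, 0.0])):
                atoms.append(
                    Atom(chain_id, i + 1, "ALA", atom_name, atom_name[0],
                         base + np.array(shift))
                )
        return atoms

    model = RigidBody("model", chain("V", 8.0) + chain("H", 0.0) + chain("Y", -6.0))
    twofold = np.diag([-1.0, -1.0, 1.0])
    h_atoms = chain("P", 0.0)
    h2 = [
        Atom("Q", a.residue_number, a.residue_name, a.atom_name, a.element,
             twofold @ a.position + np.array([0.0, -30.0, 0.0]))
        for a in chain("Q", 0.0)
    ]
    template = RigidBody("template", h_atoms + h2)
    return model, template, twofold


class TestExtrapolate:
    def test_twofold_symmetry_carried_to_copies(self):
        model, template, twofold = _tetramer_fixture()
        copies, n_clash = extrapolate_tetramer(
            model,
            template,
            model_dimer_chains=("H",),
            template_dimer_chains=[("P",), ("Q",)],
            drop_chains=("Y",),
        )
        assert len(copies) == 2
        v0 = np.array([a.position for a in copies[0].atoms if a.chain_id == "V"])
        v1 = np.array([a.position for a in copies[1].atoms if a.chain_id == "V"])
        expected = v0 @ twofold.T + np.array([0.0, -30.0, 0.0])
        np.testing.assert_allclose(v1, expected, atol=1e-6)

    def test_dropped_chains_absent(self):
        model, template, _ = _tetramer_fixture()
        copies, _ = extrapolate_tetramer(
            model, template, ("H",), [("P",), ("Q",)], drop_chains=("Y",)
        )
        for c in copies:
            assert all(a.chain_id != "Y" for a in c.atoms)

    def test_no_clashes_between_separated_copies(self):
        model, template, _ = _tetramer_fixture()
        _, n_clash = extrapolate_tetramer(
            model, template, ("H",), [("P",), ("Q",)], drop_chains=("Y",)
        )
        assert n_clash == 0

    def test_chain_mapping_failure(self):
        model, template, _ = _tetramer_fixture()
        with pytest.raises((KeyError, ValueError)):
            extrapolate_tetramer(model, template, ("Z",), [("P",)], drop_chains=())
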