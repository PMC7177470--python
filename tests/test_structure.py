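"""Structural statistics: superposition, RMSD, frame selection, SASA,
contact surface, interaction energies — each against a closed form or an
independent recomputation."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vsensemble import structure as st
from vsensemble import synthetic as syn


@pytest.fixture
def peptide():
    frames, ref = syn.generate_toy_assembly(
        "copied_reference_frame", n_frames=5, noise=0.6, seed=3
    )
    return frames, ref


def rigid_copy(cs, angle=37.0, shift=(5.0, -3.0, 2.0)):
    rot = Rotation.from_euler("xyz", [angle, 10.0, -20.0], degrees=True)
    return cs.transformed(rot, np.asarray(shift))


# -- Kabsch / RMSD -------------------------------------------------------


def test_identity_superposition(peptide):
    _, ref = peptide
    fitted = st.kabsch_superpose(ref, ref)
    assert st.rmsd(fitted, ref) == pytest.approx(0.0, abs=1e-9)


def test_rigid_motion_recovered_exactly(peptide):
    _, ref = peptide
    moved = rigid_copy(ref)
    fitted = st.kabsch_superpose(moved, ref)
    assert st.rmsd(fitted, ref) == pytest.approx(0.0, abs=1e-6)


def test_kabsch_matches_rotation_grid_oracle(rng):
    """10 random atom pairs: the Kabsch RMSD equals brute-force
    minimization over a dense grid of rotations about the best axis."""
    n = 10
    a_xyz = rng.normal(size=(n, 3)) * 3
    b_xyz = rng.normal(size=(n, 3)) * 3
    mk = lambda xyz: st.CoordinateSet(
        np.array(["A"] * n),
        np.arange(1, n + 1),
        np.array(["GLY"] * n),
        np.array([f"C{i}" for i in range(n)]),
        np.array(["C"] * n),
        xyz,
    )
    a, b = mk(a_xyz), mk(b_xyz)
    fitted = st.kabsch_superpose(a, b)
    got = st.rmsd(fitted, b)
    # oracle: random-rotation search with local refinement
    ac = a_xyz - a_xyz.mean(0)
    bc = b_xyz - b_xyz.mean(0)
    best = np.inf
    rots = Rotation.random(4000, random_state=np.random.RandomState(0))
    vals = [np.sqrt(np.mean(np.sum((r.apply(ac) - bc) ** 2, axis=1))) for r in rots]
    r0 = rots[int(np.argmin(vals))]
    best = min(vals)
    for scale in (0.2, 0.05, 0.01):
        for r in Rotation.random(2000, random_state=np.random.RandomState(1)):
            rr = Rotation.from_rotvec(r.as_rotvec() * scale) * r0
            v = np.sqrt(np.mean(np.sum((rr.apply(ac) - bc) ** 2, axis=1)))
            if v < best:
                best, r0 = v, rr
    assert got == pytest.approx(best, abs=1e-3)


def test_rmsd_hand_value_and_symmetry():
    mk = lambda xyz: st.CoordinateSet(
        np.array(["A", "A"]),
        np.array([1, 2]),
        np.array(["GLY", "GLY"]),
        np.array(["CA", "CA"]),
        np.array(["C", "C"]),
        np.asarray(xyz, dtype=float),
    )
    a = mk([[0, 0, 0], [0, 0, 0]])
    b = mk([[0, 0, 0], [1, 0, 0]])  # deviations (0, 1)
    assert st.rmsd(a, b) == pytest.approx(math.sqrt(0.5), abs=1e-12)
    assert st.rmsd(a, b) == st.rmsd(b, a)


def test_pose_rmsd_order_paired_no_superposition(peptide):
    """Pose RMSD pairs atoms by order in a shared frame: a rigidly moved
    copy shows the full displacement (no fitting), identical poses zero."""
    _, ref = peptide
    assert st.pose_rmsd(ref, ref) == 0.0
    shifted = ref.transformed(Rotation.identity(), np.array([3.0, 4.0, 0.0]))
    assert st.pose_rmsd(ref, shifted) == pytest.approx(5.0)
    with pytest.raises(ValueError, match="differ"):
        st.pose_rmsd(ref, ref.subset(np.arange(len(ref)) < 4))


def test_unpaired_fit_atoms_reported(peptide):
    _, ref = peptide
    truncated = ref.subset(np.arange(len(ref)) < len(ref) - 4)
    with pytest.raises(ValueError, match="unpaired"):
        st.kabsch_superpose(ref, truncated)


def test_rmsd_profile_flags_drift_and_means(peptide):
    frames, ref = peptide
    sels = {
        "front": st.AtomSelection(residues=frozenset(range(1, 5)), name="front"),
        "back": st.AtomSelection(residues=frozenset(range(5, 9)), name="back"),
    }
    # linearly drifting back half only
    drift_frames = []
    for i in range(4):
        xyz = ref.xyz.copy()
        mask = sels["back"].mask(ref)
        xyz[mask] += np.array([0.5 * i, 0.0, 0.0])
        drift_frames.append(
            st.CoordinateSet(
                ref.chain, ref.resnum, ref.resname, ref.atom_name,
                ref.element, xyz, frame_id=str(i),
            )
        )
    prof = st.rmsd_profile(drift_frames, ref, sels)
    assert np.allclose(prof["front"], 0.0)
    assert (np.diff(prof["back"]) > 0).all()
    assert prof["back"].mean() == pytest.approx(
        float(np.mean([st.rmsd(f, ref, sels["back"]) for f in drift_frames]))
    )
    # all frames equal to reference -> all-zero profile
    zero = st.rmsd_profile([ref, ref], ref, sels)
    assert np.allclose(zero.to_numpy(), 0.0)


def _binding_site_structure(seed, n_chains=2):
    """Synthetic chains carrying the binding-site residues."""
    rng = np.random.default_rng(seed)
    residues = sorted(st.BINDING_SITE_RESIDUES)
    names = ["N", "CA", "C", "O", "CB"]
    chains, resnum, resname, atom_name, element, xyz = [], [], [], [], [], []
    for c in "ABCD"[:n_chains]:
        offset = rng.normal(0, 20, 3)
        for r in residues:
            for nm in names:
                chains.append(c)
                resnum.append(r)
                resname.append("ALA")
                atom_name.append(nm)
                element.append(nm[0])
                xyz.append(rng.normal(0, 5, 3) + offset)
    return st.CoordinateSet(
        np.array(chains), np.array(resnum), np.array(resname),
        np.array(atom_name), np.array(element), np.array(xyz),
    )


def test_select_frames_exact_copy_and_shape():
    ref = _binding_site_structure(seed=1)
    rng = np.random.default_rng(2)
    frames = []
    for i in range(3):
        xyz = ref.xyz + rng.normal(0, 1.0, ref.xyz.shape)
        frames.append(
            st.CoordinateSet(ref.chain, ref.resnum, ref.resname,
                             ref.atom_name, ref.element, xyz, frame_id=str(i))
        )
    frames.append(
        st.CoordinateSet(ref.chain, ref.resnum, ref.resname, ref.atom_name,
                         ref.element, ref.xyz.copy(), frame_id="copy")
    )
    refs = {"xtal1": ref, "xtal2": frames[0]}
    out = st.select_frames(frames, refs, chains=["A", "B"])
    assert len(out) == 2 * 2 * 2  # chains x references x criteria
    picked = out[(out.reference == "xtal1")]
    assert (picked.best_frame == "copy").all()
    assert np.allclose(picked.rmsd, 0.0, atol=1e-6)
    # minima equal an exhaustive rescan
    for _, row in out.iterrows():
        sel = (st.binding_site_backbone([row.chain]) if row.criterion == "backbone"
               else st.binding_site_heavy([row.chain]))
        fit = st.binding_site_backbone([row.chain])
        vals = {
            f.frame_id: st.rmsd(f, refs[row.reference], sel,
                                superpose=True, fit_selection=fit)
            for f in frames
        }
        assert row.rmsd == pytest.approx(min(vals.values()))
        assert vals[row.best_frame] == pytest.approx(row.rmsd)


# -- SASA and contact surface -------------------------------------------


def test_isolated_sphere_sasa_closed_form():
    coords, radii = syn.generate_toy_assembly("two_spheres", r1=2.0, r2=2.0, d=100.0)
    lone = coords.subset(coords.chain == "A")
    _, total = st.sasa(lone, probe=1.4, radii=radii)
    assert total == pytest.approx(4 * math.pi * 3.4**2, rel=0.005)


def test_sasa_point_count_convergence():
    coords, radii = syn.generate_toy_assembly("two_spheres", r1=2.0, r2=2.0, d=3.0)
    _, t1 = st.sasa(coords, probe=1.4, n_points=960, radii=radii)
    _, t2 = st.sasa(coords, probe=1.4, n_points=1920, radii=radii)
    assert abs(t2 - t1) / t1 < 0.005


def test_unknown_element_requires_override():
    coords, _ = syn.generate_toy_assembly("two_spheres")
    weird = st.CoordinateSet(
        coords.chain, coords.resnum, coords.resname, coords.atom_name,
        np.array(["XX", "XX"]), coords.xyz,
    )
    with pytest.raises(KeyError, match="XX"):
        st.sasa(weird)
    _, total = st.sasa(weird, radii={"XX": 2.0})
    assert total > 0


def two_sphere_sigma_analytic(r1, r2, d, probe):
    """Half the buried area of two intersecting extended spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 0.0
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return (2 * math.pi * R1 * h1 + 2 * math.pi * R2 * h2) / 2.0


def test_two_sphere_contact_surface_closed_form():
    coords, radii = syn.generate_toy_assembly("two_spheres", r1=2.0, r2=2.0, d=3.0)
    series = st.contact_surface_series([coords], "A", probe=1.4, radii=radii)
    expected = two_sphere_sigma_analytic(2.0, 2.0, 3.0, 1.4)
    assert series.sigma[0] == pytest.approx(expected, rel=0.01)


def test_separated_chains_have_zero_contact():
    sep = syn.generate_toy_assembly("separated_chains", gap=100.0)
    series = st.contact_surface_series([sep], "A")
    assert series.sigma[0] == pytest.approx(0.0, abs=0.5)


def test_sigma_decreases_when_pulled_apart():
    sigmas = []
    for d in (2.5, 3.5, 4.5, 6.0, 7.5):
        coords, radii = syn.generate_toy_assembly("two_spheres", r1=2.0, r2=2.0, d=d)
        sigmas.append(st.contact_surface_series([coords], "A", radii=radii).sigma[0])
    assert all(a >= b - 1e-6 for a, b in zip(sigmas, sigmas[1:]))
    assert sigmas[-1] == pytest.approx(0.0, abs=0.5)


def test_sigma_nonnegative_for_random_clusters(rng):
    for _ in range(25):
        n = int(rng.integers(4, 10))
        cs = st.CoordinateSet(
            np.array(["A"] * (n // 2) + ["B"] * (n - n // 2)),
            np.arange(1, n + 1),
            np.array(["GLY"] * n),
            np.array([f"C{i}" for i in range(n)]),
            np.array(["C"] * n),
            rng.normal(0, 3, (n, 3)),
        )
        series = st.contact_surface_series([cs], "A", n_points=480)
        assert series.sigma[0] >= -0.5


def test_sasa_invariant_under_rigid_motion():
    """Point-sampled areas are rigid-motion invariant up to the sampling
    resolution (the sphere-point grid does not rotate with the body)."""
    coords, radii = syn.generate_toy_assembly("two_spheres", r1=2.0, r2=3.0, d=4.0)
    moved = rigid_copy(coords)
    _, t0 = st.sasa(coords, radii=radii)
    _, t1 = st.sasa(moved, radii=radii)
    assert t1 == pytest.approx(t0, rel=5e-3)


# -- interaction energies ------------------------------------------------


def _pair(r, q1=1.0, q2=1.0):
    mk = lambda x, nm: st.CoordinateSet(
        np.array(["A"]), np.array([1]), np.array(["GLY"]),
        np.array([nm]), np.array(["C"]), np.array([[x, 0.0, 0.0]]),
    )
    return mk(0.0, "C1"), mk(r, "C2")


def test_coulomb_formula_instantiation():
    a, b = _pair(1.0)
    params = st.EnergyParams(
        charges={"C1": 1.0, "C2": 1.0}, lj={"C1": (1.0, 0.0), "C2": (1.0, 0.0)},
    )
    elec, _ = st.pairwise_interaction_energy(a, b, params)
    assert elec == pytest.approx(332.0716)
    # distance-dependent dielectric: r^2 in the denominator
    a2, b2 = _pair(2.0)
    elec2, _ = st.pairwise_interaction_energy(a2, b2, params)
    assert elec2 == pytest.approx(332.0716 / 4.0)


def test_lj_minimum_at_rmin():
    a, b = _pair(2.4)
    params = st.EnergyParams(
        charges={"C1": 0.0, "C2": 0.0},
        lj={"C1": (1.2, 0.5), "C2": (1.2, 0.5)},  # Rmin_ij = 2.4
    )
    _, lj = st.pairwise_interaction_energy(a, b, params)
    assert lj == pytest.approx(-0.5)


def test_energy_additive_over_partner_groups(rng):
    def rand_group(chain, n, offset):
        return st.CoordinateSet(
            np.array([chain] * n), np.arange(1, n + 1), np.array(["GLY"] * n),
            np.array([f"C{i}" for i in range(n)]), np.array(["C"] * n),
            rng.normal(0, 2, (n, 3)) + offset,
        )

    a = rand_group("A", 4, np.zeros(3))
    b1 = rand_group("B", 3, np.array([4.0, 0, 0]))
    b2 = rand_group("C", 3, np.array([0, 4.0, 0]))
    union = st.CoordinateSet(
        np.concatenate([b1.chain, b2.chain]),
        np.concatenate([b1.resnum, b2.resnum + 10]),
        np.concatenate([b1.resname, b2.resname]),
        np.concatenate([b1.atom_name, b2.atom_name]),
        np.concatenate([b1.element, b2.element]),
        np.vstack([b1.xyz, b2.xyz]),
    )
    params = st.EnergyParams(
        charges={f"C{i}": 0.3 for i in range(10)},
        lj={f"C{i}": (1.5, 0.2) for i in range(10)},
        cutoff=50.0,
    )
    e_union = st.pairwise_interaction_energy(a, union, params)
    e1 = st.pairwise_interaction_energy(a, b1, params)
    e2 = st.pairwise_interaction_energy(a, b2, params)
    assert e_union[0] == pytest.approx(e1[0] + e2[0])
    assert e_union[1] == pytest.approx(e1[1] + e2[1])


def test_overlapping_atoms_rejected():
    a, b = _pair(0.05)
    params = st.EnergyParams(charges={"C1": 0.0, "C2": 0.0},
                             lj={"C1": (1.0, 0.1), "C2": (1.0, 0.1)})
    with pytest.raises(ValueError, match="overlap"):
        st.pairwise_interaction_energy(a, b, params)


def test_energy_invariant_under_rigid_motion(rng):
    a = st.CoordinateSet(
        np.array(["A"] * 3), np.arange(1, 4), np.array(["GLY"] * 3),
        np.array(["C1", "C2", "C3"]), np.array(["C"] * 3),
        rng.normal(0, 2, (3, 3)),
    )
    b = st.CoordinateSet(
        np.array(["B"] * 3), np.arange(1, 4), np.array(["GLY"] * 3),
        np.array(["C1", "C2", "C3"]), np.array(["C"] * 3),
        rng.normal(0, 2, (3, 3)) + np.array([5.0, 0, 0]),
    )
    params = st.EnergyParams(
        charges={"C1": 0.2, "C2": -0.1, "C3": 0.4},
        lj={"C1": (1.5, 0.1), "C2": (1.6, 0.2), "C3": (1.4, 0.05)},
        cutoff=50.0,
    )
    e0 = st.pairwise_interaction_energy(a, b, params)
    rot = Rotation.from_euler("y", 73.0, degrees=True)
    shift = np.array([1.0, -2.0, 0.5])
    e1 = st.pairwise_interaction_energy(
        a.transformed(rot, shift), b.transformed(rot, shift), params
    )
    assert e1[0] == pytest.approx(e0[0], rel=1e-9)
    assert e1[1] == pytest.approx(e0[1], rel=1e-9)
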