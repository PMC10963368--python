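"""Superposition, RMSD, RMSF, equilibration, and region comparison."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from cotrans.datatypes import CoreRegionMap, Trajectory
from cotrans.dynamics import (
    RmsdSeries,
    RmsfResult,
    equilibration_check,
    kabsch_superpose,
    region_rmsf_compare,
    rmsd_series,
    rmsf,
)
from cotrans.exceptions import SuperpositionError, ValidationError
from cotrans.synthetic import ToyComplexSpec, gen_toy_complex

RNG = np.random.default_rng(42)


def random_coords(n):
    return RNG.normal(size=(n, 3)) * 5.0


def oracle_superpose(mobile, reference):
    """Independent superposition via scipy's align_vectors."""
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return (mobile - cm) @ rot.as_matrix().T + cr


class TestKabsch:
    def test_exact_recovery_of_rigid_transform(self):
        ref = random_coords(10)
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot90.T + np.array([3.0, -1.0, 2.0])
        _, _, fitted = kabsch_superpose(mobile, ref)
        assert np.abs(fitted - ref).max() < 1e-10

    def test_mirror_image_cannot_reach_zero(self):
        ref = random_coords(8)
        mirror = ref * np.array([-1.0, 1.0, 1.0])
        rot, _, fitted = kabsch_superpose(mirror, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        assert np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))) > 0.1

    def test_uniform_weights_equal_unweighted(self):
        ref, mobile = random_coords(7), random_coords(7)
        _, _, f1 = kabsch_superpose(mobile, ref)
        _, _, f2 = kabsch_superpose(mobile, ref, weights=np.full(7, 3.7))
        assert np.allclose(f1, f2, atol=1e-12)

    def test_matches_scipy_align_vectors(self):
        for _ in range(20):
            ref, mobile = random_coords(6), random_coords(6)
            _, _, fitted = kabsch_superpose(mobile, ref)
            assert np.allclose(fitted, oracle_superpose(mobile, ref), atol=1e-8)

    def test_too_few_or_collinear_atoms(self):
        with pytest.raises(SuperpositionError):
            kabsch_superpose(random_coords(2), random_coords(2))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(SuperpositionError):
            kabsch_superpose(line, line)


def make_traj(frames, times=None):
    """Wrap bare coordinate frames in a single-chain structure."""
    from cotrans.datatypes import Atom, Chain, ComplexStructure, Residue

    frames = np.asarray(frames, dtype=float)
    n_atoms = frames.shape[1]
    residues = [
        Residue(i + 1, "GLY", [Atom("CA", "C", frames[0, i])])
        for i in range(n_atoms)
    ]
    structure = ComplexStructure([Chain("A", residues)])
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return Trajectory(reference=structure, frames=frames,
                      frame_times=np.asarray(times, dtype=float))


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        base = random_coords(6)
        traj = make_traj(np.repeat(base[None], 4, axis=0))
        series = rmsd_series(traj)
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_two_atoms_single_displacement_formula(self):
        # one of two atoms displaced by d in one frame, no superposition:
        # RMSD = sqrt(d^2 / 2) = d / sqrt(2)
        d = 1.4
        f0 = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        f1 = f0.copy()
        f1[1, 0] += d
        traj = make_traj([f0, f1])
        series = rmsd_series(traj, reference=0, superpose=False)
        assert series.values[1] == pytest.approx(d / np.sqrt(2), abs=1e-12)

    def test_mass_weighted_equal_masses_matches_unweighted(self):
        frames = np.stack([random_coords(5) for _ in range(3)])
        traj = make_traj(frames)
        traj.masses = np.full(5, 12.011)
        a = rmsd_series(traj, mass_weighted=True)
        b = rmsd_series(traj, mass_weighted=False)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_matches_brute_force_formula_after_oracle_superposition(self):
        frames = np.stack([random_coords(8) for _ in range(5)])
        traj = make_traj(frames)
        traj.masses = RNG.uniform(1.0, 20.0, size=8)
        series = rmsd_series(traj, reference=0, mass_weighted=True)
        ref = frames[0]
        for k in range(5):
            fitted = oracle_superpose(frames[k], ref)  # unweighted fit
            m = traj.masses
            # brute-force mass-weighted fit via explicit weighted Kabsch:
            _, _, fitted_w = kabsch_superpose(frames[k], ref, weights=m)
            brute = np.sqrt(np.sum(m[:, None] * (fitted_w - ref) ** 2) / m.sum())
            assert series.values[k] == pytest.approx(brute, abs=1e-10)
        # the unweighted series matches the fully independent oracle
        series_u = rmsd_series(traj, reference=0, mass_weighted=False)
        for k in range(5):
            fitted = oracle_superpose(frames[k], ref)
            brute = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
            assert series_u.values[k] == pytest.approx(brute, abs=1e-8)

    def test_rigid_transform_invariance(self):
        frames = np.stack([random_coords(6) for _ in range(4)])
        traj = make_traj(frames)
        rot = Rotation.from_euler("xyz", [30, -60, 45], degrees=True).as_matrix()
        moved = frames @ rot.T + np.array([5.0, 5.0, -2.0])
        traj2 = make_traj(moved)
        a = rmsd_series(traj).values
        b = rmsd_series(traj2).values
        assert np.allclose(a, b, atol=1e-8)


class TestRmsf:
    def test_static_trajectory_zero(self):
        base = random_coords(6)
        traj = make_traj(np.repeat(base[None], 5, axis=0))
        assert np.allclose(rmsf(traj).values, 0.0, atol=1e-10)

    def test_single_atom_plus_minus_d(self):
        # one atom at +/- d along x, others fixed; fitting on the fixed
        # atoms leaves the displacement untouched -> RMSF exactly d
        d = 0.8
        base = random_coords(6)
        f0, f1 = base.copy(), base.copy()
        f0[0, 0] += d
        f1[0, 0] -= d
        traj = make_traj([f0, f1])
        result = rmsf(traj, fit_selection=np.arange(1, 6))
        assert result.values[0] == pytest.approx(d, abs=1e-10)
        assert np.allclose(result.values[1:], 0.0, atol=1e-10)

    def test_isotropic_gaussian_closed_form(self):
        # per-axis amplitude a -> RMSF a*sqrt(3)
        spec = ToyComplexSpec(
            n_residues_chain_a=10, n_residues_chain_b=10,
            interface_pairs=[(5, 5, 4.5)],
            fluctuation_amplitudes=0.5, n_frames=4000, seed=21,
        )
        _, traj = gen_toy_complex(spec)
        result = rmsf(traj, selection="ca")
        assert np.mean(result.values) == pytest.approx(0.5 * np.sqrt(3), rel=0.05)

    def test_subset_selection_consistent_with_full(self, toy_complex):
        _, _, traj = toy_complex
        full = rmsf(traj, selection=None)
        sub_idx = np.arange(4, 20)
        sub = rmsf(traj, selection=sub_idx)
        assert np.allclose(sub.values, full.values[sub_idx], atol=1e-12)

    def test_single_frame_window_rejected(self, toy_complex):
        _, _, traj = toy_complex
        with pytest.raises(ValidationError):
            rmsf(traj, frames=(0, 0))

    def test_rigid_transform_invariance(self):
        frames = np.stack([random_coords(7) for _ in range(6)])
        rot = Rotation.from_euler("y", 75, degrees=True).as_matrix()
        a = rmsf(make_traj(frames)).values
        b = rmsf(make_traj(frames @ rot.T + 4.2)).values
        assert np.allclose(a, b, atol=1e-8)


class TestEquilibration:
    def make_series(self, values, times=None):
        values = np.asarray(values, dtype=float)
        if times is None:
            times = np.arange(len(values), dtype=float)
        return RmsdSeries(values=values, frame_times=np.asarray(times, float),
                          mass_weighted=False, selection="all")

    def test_constant_after_ramp(self):
        values = np.concatenate([np.linspace(0, 5, 20), np.full(30, 5.0)])
        series = self.make_series(values)
        t = equilibration_check(series, window_ns=10, sd_tol=0.1)
        assert t is not None and t <= 20.0

    def test_monotone_rise_never_stabilizes(self):
        series = self.make_series(np.linspace(0, 20, 50))
        assert equilibration_check(series, window_ns=10, sd_tol=0.01) is None

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([np.linspace(0, 3, 15),
                                 3 + 0.05 * rng.normal(size=35)])
        series = self.make_series(values)
        got = equilibration_check(series, window_ns=8, sd_tol=0.2)
        brute = None
        t = series.frame_times
        for k in range(len(t)):
            if t[k] + 8 > t[-1]:
                break
            window = series.values[(t >= t[k]) & (t <= t[k] + 8)]
            if len(window) >= 2 and np.std(window, ddof=1) <= 0.2:
                brute = t[k]
                break
        assert got == brute

    def test_window_longer_than_series_rejected(self):
        series = self.make_series(np.zeros(5))
        with pytest.raises(ValidationError):
            equilibration_check(series, window_ns=100)


def make_rmsf_result(values):
    values = np.asarray(values, dtype=float)
    return RmsfResult(
        values=values,
        atom_indices=np.arange(len(values)),
        residues=[("A", i + 1) for i in range(len(values))],
        selection="ca",
        frames_used=(0, 1),
    )


class TestRegionCompare:
    def test_identical_samples(self):
        a = make_rmsf_result([1.0, 2.0, 3.0, 4.0])
        rmap = CoreRegionMap(pairs=[(i, i) for i in range(1, 5)])
        t, p, summary = region_rmsf_compare(a, a, rmap)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)
        assert summary["a"]["n"] == 4

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        base = rng.normal(1.0, 0.05, size=60)
        a = make_rmsf_result(base)
        b = make_rmsf_result(base + 5.0)
        rmap = CoreRegionMap(pairs=[(i, i) for i in range(1, 61)])
        _, p, _ = region_rmsf_compare(a, b, rmap)
        assert p < 1e-6

    def test_matches_welch_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            xa = rng.normal(1.0, 0.3, size=15)
            xb = rng.normal(1.4, 0.6, size=22)
            a, b = make_rmsf_result(xa), make_rmsf_result(xb)
            n = min(len(xa), len(xb))
            rmap = CoreRegionMap(pairs=[(i, i) for i in range(1, n + 1)])
            t_got, p_got, _ = region_rmsf_compare(a, b, rmap)
            ya, yb = xa[:n], xb[:n]
            va, vb = ya.var(ddof=1) / n, yb.var(ddof=1) / n
            t_brute = (ya.mean() - yb.mean()) / np.sqrt(va + vb)
            dof = (va + vb) ** 2 / (va**2 / (n - 1) + vb**2 / (n - 1))
            p_brute = 2 * stats.t.sf(abs(t_brute), dof)
            assert t_got == pytest.approx(t_brute, abs=1e-10)
            assert p_got == pytest.approx(p_brute, abs=1e-10)

    def test_pooled_variant_matches_student(self):
        rng = np.random.default_rng(3)
        xa, xb = rng.normal(size=10), rng.normal(0.5, 1.0, size=10)
        a, b = make_rmsf_result(xa), make_rmsf_result(xb)
        rmap = CoreRegionMap(pairs=[(i, i) for i in range(1, 11)])
        t_got, p_got, _ = region_rmsf_compare(a, b, rmap, welch=False)
        res = stats.ttest_ind(xa, xb, equal_var=True)
        assert t_got == pytest.approx(float(res.statistic), abs=1e-12)
        assert p_got == pytest.approx(float(res.pvalue), abs=1e-12)

    def test_empty_mapping_rejected(self):
        a = make_rmsf_result([1.0, 2.0])
        rmap = CoreRegionMap(pairs=[(90, 90)])
        with pytest.raises(ValidationError):
            region_rmsf_compare(a, a, rmap)
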