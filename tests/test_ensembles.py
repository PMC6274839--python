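"""Trajectory container, I/O round trips, trimming, superposition, RMSD."""

import numpy as np
import pandas as pd
import pytest

import coilflex as cf
from conftest import random_rotation


def _kabsch_rmsd(ref, mob):
    """Independent brute-force Kabsch superposition RMSD (SVD by hand)."""
    ref = ref - ref.mean(axis=0)
    mob = mob - mob.mean(axis=0)
    u, s, vt = np.linalg.svd(mob.T @ ref)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    fitted = mob @ rot.T
    return np.sqrt(((fitted - ref) ** 2).sum() / len(ref))


def _toy_ensemble(n_frames=5, n_res=8, seed=0, jitter=0.02):
    rng = np.random.default_rng(seed)
    rows = []
    base = []
    for cid, x0 in (("A", 0.0), ("B", 0.9)):
        for r in range(1, n_res + 1):
            rows.append((cid, r, "ALA", "CA"))
            base.append([x0, 0.13 * r, 0.05 * (r % 3)])
    atoms = pd.DataFrame(rows, columns=["chain_id", "residue_index",
                                        "residue_name", "atom_name"])
    base = np.array(base)
    coords = base[None] + rng.normal(0, jitter, (n_frames, len(base), 3))
    times = np.arange(n_frames) * 10.0
    return cf.ConformationEnsemble(atoms, coords, times, ("A", "B"), 300.0)


class TestIO:
    def test_pdb_round_trip_preserves_counts_and_coords(self, tmp_path):
        ens = _toy_ensemble(n_frames=3)
        path = tmp_path / "traj.pdb"
        cf.write_ensemble(ens, path, format="pdb")
        back = cf.read_ensemble(path, format="pdb", chain_ids=("A", "B"))
        assert back.n_frames == 3
        assert set(back.atoms["chain_id"]) == {"A", "B"}
        # PDB stores 3 decimals in Angstrom -> 1e-3 nm round-trip tolerance
        assert np.abs(back.coords - ens.coords).max() < 1e-3
        assert back.atoms["residue_index"].tolist() == ens.atoms["residue_index"].tolist()

    def test_xyz_round_trip_is_lossless(self, tmp_path):
        ens = _toy_ensemble(n_frames=4, seed=3)
        path = tmp_path / "traj.tsv"
        cf.write_ensemble(ens, path, format="xyz")
        back = cf.read_ensemble(path, format="xyz")
        np.testing.assert_allclose(back.coords, ens.coords, atol=1e-9)
        np.testing.assert_allclose(back.times, ens.times)

    def test_missing_chain_is_a_named_error(self, tmp_path):
        ens = _toy_ensemble()
        path = tmp_path / "traj.pdb"
        cf.write_ensemble(ens, path, format="pdb")
        with pytest.raises(ValueError, match="chain C not found"):
            cf.read_ensemble(path, format="pdb", chain_ids=("A", "C"))

    def test_ragged_frames_are_rejected_with_offenders_listed(self, tmp_path):
        ens = _toy_ensemble(n_frames=3)
        path = tmp_path / "traj.tsv"
        cf.write_ensemble(ens, path, format="xyz")
        df = pd.read_csv(path, sep="\t")
        df = df.drop(df[(df.frame_index == 1)].index[:2])  # maim frame 1
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match=r"offending frame indices: \[1\]"):
            cf.read_ensemble(path, format="xyz")


class TestTrim:
    def test_paper_scale_trim_keeps_8000_of_10000_frames(self):
        # 10 ps spacing over 0..99990 ps; trimming at 20 ns keeps 8000
        ens = _toy_ensemble(n_frames=10000, n_res=2, jitter=0.0)
        out = cf.trim_equilibration(ens, 20_000.0)
        assert out.n_frames == 8000
        assert out.times[0] == 20_000.0

    def test_zero_threshold_is_identity(self):
        ens = _toy_ensemble(n_frames=6)
        out = cf.trim_equilibration(ens, 0.0)
        assert out.n_frames == ens.n_frames
        np.testing.assert_array_equal(out.coords, ens.coords)

    def test_threshold_beyond_last_time_raises(self):
        ens = _toy_ensemble(n_frames=5)
        with pytest.raises(ValueError, match="beyond the last frame"):
            cf.trim_equilibration(ens, 1e6)


class TestSuperpose:
    def _selection(self):
        return cf.SelectionSpec(("A", "B"), (1, 8))

    def test_pure_rigid_motions_are_removed_exactly(self, rng):
        ens = _toy_ensemble(n_frames=2, jitter=0.0)
        frames = []
        for _ in range(6):
            R = random_rotation(rng)
            t = rng.normal(0, 2.0, 3)
            frames.append(ens.coords[0] @ R.T + t)
        moved = cf.ConformationEnsemble(
            ens.atoms, np.stack(frames), np.arange(6) * 10.0, ("A", "B")
        )
        out = cf.superpose(moved, self._selection())
        mean = out.coords.mean(axis=0)
        rmsd = np.sqrt(((out.coords - mean) ** 2).sum(axis=(1, 2)) / out.n_atoms)
        assert rmsd.max() < 1e-6

    def test_idempotence(self):
        ens = _toy_ensemble(n_frames=5, seed=11)
        once = cf.superpose(ens, self._selection())
        twice = cf.superpose(once, self._selection())
        assert np.abs(twice.coords - once.coords).max() < 1e-9

    def test_superposition_is_an_isometry(self, rng):
        ens = _toy_ensemble(n_frames=4, seed=5, jitter=0.05)
        out = cf.superpose(ens, self._selection())
        for f in range(ens.n_frames):
            before = np.linalg.norm(
                ens.coords[f][:, None] - ens.coords[f][None], axis=-1
            )
            after = np.linalg.norm(
                out.coords[f][:, None] - out.coords[f][None], axis=-1
            )
            np.testing.assert_allclose(after, before, atol=1e-9)

    def test_collinear_selection_raises(self):
        atoms = pd.DataFrame(
            {
                "chain_id": ["A", "A", "A", "B"],
                "residue_index": [1, 2, 3, 1],
                "residue_name": "ALA",
                "atom_name": "CA",
            }
        )
        coords = np.zeros((2, 4, 3))
        coords[:, :, 2] = [0.0, 1.0, 2.0, 3.0]
        ens = cf.ConformationEnsemble(atoms, coords, [0.0, 10.0], ("A", "B"))
        with pytest.raises(ValueError, match="collinear"):
            cf.superpose(ens, cf.SelectionSpec(("A", "B"), (1, 3)))


class TestRMSD:
    def test_identical_frames_give_zero(self):
        ens = _toy_ensemble(n_frames=4, jitter=0.0)
        tc = cf.rmsd_timecourse(ens, cf.SelectionSpec(("A", "B"), (1, 8)))
        assert np.abs(tc["rmsd_nm"]).max() < 1e-9
        assert len(tc) == ens.n_frames

    def test_translation_is_removed(self):
        ens = _toy_ensemble(n_frames=2, jitter=0.0)
        coords = ens.coords.copy()
        coords[1] += np.array([1.0, 0.0, 0.0])
        ens = ens.with_coords(coords)
        tc = cf.rmsd_timecourse(ens, cf.SelectionSpec(("A", "B"), (1, 8)))
        assert tc["rmsd_nm"].iloc[1] < 1e-9

    def test_matches_brute_force_kabsch_on_random_frames(self, rng):
        ens = _toy_ensemble(n_frames=6, seed=9, jitter=0.08)
        sel = cf.SelectionSpec(("A", "B"), (1, 8))
        idx = sel.indices(ens)
        tc = cf.rmsd_timecourse(ens, sel)
        for f in range(ens.n_frames):
            want = _kabsch_rmsd(ens.coords[0, idx], ens.coords[f, idx])
            assert tc["rmsd_nm"].iloc[f] == pytest.approx(want, abs=1e-7)

    def test_invariant_under_rigid_motion_of_whole_ensemble(self, rng):
        ens = _toy_ensemble(n_frames=5, seed=2, jitter=0.05)
        sel = cf.SelectionSpec(("A", "B"), (1, 8))
        base = cf.rmsd_timecourse(ens, sel)["rmsd_nm"].to_numpy()
        R = random_rotation(rng)
        moved = ens.with_coords(ens.coords @ R.T + np.array([0.3, -1.2, 5.0]))
        got = cf.rmsd_timecourse(moved, sel)["rmsd_nm"].to_numpy()
        np.testing.assert_allclose(got, base, atol=1e-7)
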