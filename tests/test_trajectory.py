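"""Trajectory reading, bond configs, and geometry extraction."""

import math

import numpy as np
import pytest
import yaml

from hairpinhb import (
    AtomLookupError,
    ConfigurationError,
    GeometrySeries,
    HBondDefinition,
    TrajectoryError,
    extract_geometries,
    hbond_geometry,
    read_hbond_config,
    read_trajectory,
)
from hairpinhb.synthetic import (
    emit_coordinates,
    synthetic_hbond_definitions,
    write_synthetic_pdb,
)

from conftest import series_from_patterns


def brute_force_geometry(d, h, a):
    """Independent oracle: explicit arccos of the normalized dot product."""
    ha = [a[i] - h[i] for i in range(3)]
    hd = [d[i] - h[i] for i in range(3)]
    n_ha = math.sqrt(sum(x * x for x in ha))
    n_hd = math.sqrt(sum(x * x for x in hd))
    dot = sum(x * y for x, y in zip(ha, hd))
    return n_ha, math.degrees(math.acos(max(-1.0, min(1.0, dot / (n_ha * n_hd)))))


class TestGeometry:
    @pytest.mark.parametrize(
        "donor,hydrogen,acceptor,exp_dist,exp_angle",
        [
            ((0, 0, 0), (1, 0, 0), (3, 0, 0), 2.0, 180.0),
            ((0, 0, 0), (1, 0, 0), (1, 0, 2), 2.0, 90.0),
        ],
    )
    def test_reference_placements(self, donor, hydrogen, acceptor, exp_dist, exp_angle):
        dist, ang = hbond_geometry(np.array(donor, float), np.array(hydrogen, float),
                                   np.array(acceptor, float))
        assert dist == pytest.approx(exp_dist, abs=1e-12)
        assert ang == pytest.approx(exp_angle, abs=1e-12)

    def test_random_placements_match_brute_force_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            d, h, a = rng.normal(size=(3, 3)) * 5
            dist, ang = hbond_geometry(d, h, a)
            exp_dist, exp_ang = brute_force_geometry(d, h, a)
            assert dist == pytest.approx(exp_dist, abs=1e-9)
            assert ang == pytest.approx(exp_ang, abs=1e-9)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(3, 3)) * 4
        dist0, ang0 = hbond_geometry(*pts)
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3) * 10
            moved = pts @ R.T + t
            dist, ang = hbond_geometry(*moved)
            assert dist == pytest.approx(dist0, abs=1e-9)
            assert ang == pytest.approx(ang0, abs=1e-9)

    def test_donor_acceptor_swap_symmetry(self):
        # placing donor and acceptor at the same distance from the hydrogen
        # makes the angle invariant under swapping them
        h = np.zeros(3)
        d = np.array([1.5, 0, 0])
        a = np.array([-1.2, 0.9, 0])
        a *= 1.5 / np.linalg.norm(a)
        _, ang1 = hbond_geometry(d, h, a)
        _, ang2 = hbond_geometry(a, h, d)
        assert ang1 == pytest.approx(ang2, abs=1e-9)

    def test_emit_coordinates_round_trip(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            target_d = rng.uniform(0.5, 10)
            target_a = rng.uniform(0, 180)
            d, h, a = emit_coordinates(target_d, target_a)
            dist, ang = hbond_geometry(d, h, a)
            assert dist == pytest.approx(target_d, abs=1e-9)
            assert ang == pytest.approx(target_a, abs=1e-9)


class TestPDBReading:
    def test_model_count_and_run_per_file(self, tmp_path):
        series = series_from_patterns([["cccc", "oooo"]])
        pdb = tmp_path / "two.pdb"
        write_synthetic_pdb(series, pdb)
        bundle = read_trajectory(pdb)
        assert bundle.n_runs == 1
        assert bundle.runs[0].shape[0] == 2

        bundle3 = read_trajectory([pdb, pdb, pdb])
        assert bundle3.n_runs == 3
        assert bundle3.n_frames == 6

    def test_extraction_matches_written_geometry(self, tmp_path):
        series = series_from_patterns([["cocc", "oooo", "cccc"]])
        pdb = tmp_path / "traj.pdb"
        write_synthetic_pdb(series, pdb)
        bundle = read_trajectory(pdb)
        out = extract_geometries(bundle, synthetic_hbond_definitions())
        # PDB stores 3 decimals per coordinate
        assert np.allclose(out.distances(), series.distances(), atol=5e-3)
        assert np.allclose(out.angles(), series.angles(), atol=0.2)

    def test_missing_atom_in_second_model_errors(self, tmp_path):
        series = series_from_patterns([["cccc", "oooo"]])
        pdb = tmp_path / "ok.pdb"
        write_synthetic_pdb(series, pdb)
        lines = pdb.read_text().splitlines(keepends=True)
        # drop the last ATOM record of the second MODEL
        for i in range(len(lines) - 1, -1, -1):
            if lines[i].startswith("ATOM"):
                del lines[i]
                break
        broken = tmp_path / "broken.pdb"
        broken.write_text("".join(lines))
        with pytest.raises(TrajectoryError):
            read_trajectory(broken)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(TrajectoryError, match="not found"):
            read_trajectory(tmp_path / "nope.pdb")


class TestHBondConfig:
    def write_config(self, path, bonds):
        path.write_text(yaml.safe_dump({"bonds": bonds}))
        return path

    def hairpin_bonds(self):
        return [
            {"label": "HB1", "donor": "VAL 9 N", "hydrogen": "ALA 2 H", "acceptor": "VAL 9 O"},
            {"label": "HB2", "donor": "ALA 2 N", "hydrogen": "VAL 9 H", "acceptor": "ALA 2 O"},
            {"label": "HB3", "donor": "GLN 7 N", "hydrogen": "VAL 4 H", "acceptor": "GLN 7 O"},
            {"label": "HB4", "donor": "VAL 4 N", "hydrogen": "GLN 7 H", "acceptor": "VAL 4 O"},
        ]

    def test_four_bonds_in_order(self, tmp_path):
        cfg = self.write_config(tmp_path / "hb.yaml", self.hairpin_bonds())
        defs = read_hbond_config(cfg)
        assert [d.label for d in defs] == ["HB1", "HB2", "HB3", "HB4"]
        assert not any(d.auxiliary for d in defs)

    def test_duplicate_label_rejected(self, tmp_path):
        bonds = self.hairpin_bonds()
        bonds[1]["label"] = "HB1"
        cfg = self.write_config(tmp_path / "dup.yaml", bonds)
        with pytest.raises(ConfigurationError, match="duplicate"):
            read_hbond_config(cfg)

    def test_too_few_fingerprint_bonds_rejected(self, tmp_path):
        cfg = self.write_config(tmp_path / "few.yaml", self.hairpin_bonds()[:3])
        with pytest.raises(ConfigurationError, match="fingerprint"):
            read_hbond_config(cfg)

    def test_auxiliary_bond_carried(self, tmp_path):
        bonds = self.hairpin_bonds() + [
            {"label": "S3OH", "donor": "SER 3 OG", "hydrogen": "SER 3 HG",
             "acceptor": "ALA 2 O", "auxiliary": True}
        ]
        cfg = self.write_config(tmp_path / "aux.yaml", bonds)
        defs = read_hbond_config(cfg)
        assert len(defs) == 5
        assert [d.label for d in defs if d.auxiliary] == ["S3OH"]

    def test_identical_atoms_rejected(self):
        with pytest.raises(ConfigurationError, match="distinct"):
            HBondDefinition("HB1", "VAL 9 O", "VAL 9 O", "ALA 2 H")


class TestAtomResolution:
    def test_unresolvable_and_ambiguous_identifiers(self, tmp_path):
        series = series_from_patterns([["cccc", "oooo"]])
        pdb = tmp_path / "t.pdb"
        write_synthetic_pdb(series, pdb)
        bundle = read_trajectory(pdb)
        bad = [HBondDefinition("HB1", "SYN 1 D", "SYN 1 H1", "XXX 1 A")]
        with pytest.raises(AtomLookupError, match="no atoms"):
            extract_geometries(bundle, bad)
        # every residue has an atom named D -> "SYN" resid mismatch is fine,
        # but a duplicated topology row makes the identifier ambiguous
        import pandas as pd

        bundle.atoms = pd.concat([bundle.atoms, bundle.atoms.iloc[:1]], ignore_index=True)
        bundle.runs = [np.concatenate([r, r[:, :1]], axis=1) for r in bundle.runs]
        amb = [HBondDefinition("HB1", "SYN 1 D", "SYN 1 H1", "SYN 1 A")]
        with pytest.raises(AtomLookupError, match="2 atoms"):
            extract_geometries(bundle, amb)


class TestGeometryTable:
    def test_tsv_round_trip(self, tmp_path, mixed_series):
        path = tmp_path / "g.tsv"
        mixed_series.to_tsv(path)
        back = GeometrySeries.from_tsv(path)
        assert back.bond_labels == mixed_series.bond_labels
        assert np.allclose(back.distances(), mixed_series.distances(), atol=1e-6)
        assert np.allclose(back.angles(), mixed_series.angles(), atol=1e-6)
        assert (back.data["run"] == mixed_series.data["run"]).all()

    def test_invariants_rejected(self, mixed_series):
        bad = mixed_series.data.copy()
        bad.loc[0, "HB1_dist"] = -1.0
        with pytest.raises(Exception, match="positive"):
            GeometrySeries(data=bad, bond_labels=mixed_series.bond_labels)
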