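"""Spatial distances, DSSP categories and structure file round trips."""

import numpy as np
import pandas as pd
import pytest

from metophos.structure_3d import (ProteinStructure, StructureSet,
                                   read_structures, spatial_distance_table,
                                   spatial_nearest, ss_category,
                                   ss_tabulation, structured_sequence_distances)
from metophos.proximity_seq import build_distance_records
from metophos.synthetic_data import (simulate_proteome, SimConfig,
                                     simulate_structures, write_simulation)


class TestSSCategory:
    @pytest.mark.parametrize("code,category", [
        ("H", "helix"), ("G", "helix"), ("I", "helix"),
        ("E", "strand"), ("B", "strand"),
        ("T", "coil"), ("S", "coil"), ("C", "coil"),
    ])
    def test_grouping(self, code, category):
        assert ss_category(code) == category

    def test_unknown_code(self):
        with pytest.raises(ValueError):
            ss_category("Z")


def _structure(seq, coords):
    """Structure with CA at given coords and side atoms colocated with CA."""
    from metophos.structure_3d import SIDECHAIN_ATOM
    struct = ProteinStructure("P1", sequence=seq)
    for i, letter in enumerate(seq, start=1):
        atoms = {"CA": np.asarray(coords[i - 1], dtype=float)}
        name = SIDECHAIN_ATOM.get(letter)
        if name:
            atoms[name] = atoms["CA"].copy()
        struct.atoms[i] = atoms
    return struct


class TestSpatialNearest:
    def test_three_four_five(self):
        struct = _structure("MS", [(0, 0, 0), (3, 4, 0)])
        dist, idx = spatial_nearest(struct, 1, [2])
        assert dist == pytest.approx(5.0) and idx == 2

    def test_identical_coordinates_and_tie_break(self):
        struct = _structure("MSS", [(0, 0, 0), (0, 0, 0), (0, 0, 0)])
        dist, idx = spatial_nearest(struct, 1, [3, 2])
        assert dist == 0.0 and idx == 2  # lowest residue index wins the tie

    def test_unresolved_met_returns_none(self):
        struct = _structure("MS", [(0, 0, 0), (1, 0, 0)])
        del struct.atoms[1]["SD"]
        assert spatial_nearest(struct, 1, [2]) is None

    def test_matches_brute_force(self, rng):
        n = 12
        seq = "M" + "S" * (n - 1)
        coords = rng.normal(size=(n, 3)) * 10
        struct = _structure(seq, coords)
        acceptors = list(range(2, n + 1))
        dist, idx = spatial_nearest(struct, 1, acceptors)
        brute = min((float(np.linalg.norm(coords[0] - coords[j - 1])), j)
                    for j in acceptors)
        assert dist == pytest.approx(brute[0]) and idx == brute[1]


@pytest.fixture(scope="module")
def sim_structures(tmp_path_factory):
    config = SimConfig(n_proteins=8, length_law=(90.0, 6.0), seed=17)
    proteins, sites = simulate_proteome(config)
    structures = simulate_structures(proteins, seed=17)
    outdir = tmp_path_factory.mktemp("structs")
    write_simulation(proteins, sites, outdir, structures)
    return proteins, sites, structures, outdir / "structures"


class TestReadStructures:
    def test_round_trip(self, sim_structures):
        proteins, _, structures, sdir = sim_structures
        loaded = read_structures(sorted(sdir.glob("*.pdb")),
                                 sorted(sdir.glob("*.dssp")), proteins)
        assert set(loaded.accessions()) == set(structures.accessions())
        acc = structures.accessions()[0]
        for idx, atoms in structures[acc].atoms.items():
            for name, xyz in atoms.items():
                np.testing.assert_allclose(loaded[acc].atoms[idx][name], xyz,
                                           atol=2e-3)  # PDB stores 3 decimals
        assert loaded[acc].dssp == structures[acc].dssp

    def test_missing_sidechain_excluded_from_distances(self, sim_structures):
        proteins, sites, structures, _ = sim_structures
        # drop the SD atom of one protein's first methionine
        target_acc = next(p.accession for p in proteins
                          if p.positions_of("M").size
                          and sites.positions(p.accession, "phospho").size)
        met_pos = int(proteins[target_acc].positions_of("M")[0])
        pruned = StructureSet()
        for struct in structures:
            copy = ProteinStructure(struct.accession,
                                    {k: dict(v) for k, v in struct.atoms.items()},
                                    dict(struct.dssp), struct.sequence)
            pruned.add(copy)
        pruned[target_acc].atoms[met_pos] = {
            k: v for k, v in pruned[target_acc].atoms[met_pos].items()
            if k != "SD"}
        table, report = spatial_distance_table(pruned, proteins, sites)
        assert report["unresolved_met"] >= 1
        sub = table[(table["accession"] == target_acc)
                    & (table["met_position"] == met_pos)]
        assert sub.empty

    def test_blank_dssp_code_becomes_coil(self, tmp_path, sim_structures):
        proteins, _, structures, sdir = sim_structures
        acc = structures.accessions()[0]
        text = (sdir / f"{acc}.dssp").read_text().splitlines()
        # blank out the structure column of the first residue line
        line = text[3]
        text[3] = line[:16] + " " + line[17:]
        path = tmp_path / f"{acc}.dssp"
        path.write_text("\n".join(text) + "\n")
        loaded = read_structures([sdir / f"{acc}.pdb"], [path], proteins)
        assert loaded[acc].dssp[1] == "C"


class TestTabulationsAndDelegation:
    def test_ss_proportions_sum_to_one(self, sim_structures):
        proteins, sites, structures, _ = sim_structures
        tab = ss_tabulation(structures, proteins, sites)
        assert tab.index.tolist() == list("HGIEBTSC")
        for col in tab.columns:
            total = tab[col].sum()
            assert total == pytest.approx(1.0) or total == 0.0

    def test_sequence_distances_delegate_to_proximity_module(self, sim_structures):
        proteins, sites, structures, _ = sim_structures
        via_structure = structured_sequence_distances(structures, proteins, sites)
        direct = build_distance_records(
            proteins.subset([a for a in structures.accessions()]), sites)
        pd.testing.assert_frame_equal(via_structure, direct)
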