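"""Spatial Met-to-phosphosite distances and secondary-structure tabulation.

Works on per-residue coordinates read from PDB files (biotite) joined with
8-state secondary-structure codes from classic DSSP output files (parsed with
``Bio.PDB.DSSP.make_dssp_dict``).  The side-chain atoms used for distances are
fixed: Met sulfur ``SD``, Ser ``OG``, Thr ``OG1``, Tyr ``OH``.  Residues whose
required atom is not resolved are excluded from distance analyses and counted.
Only intra-chain distances are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.PDB.DSSP import make_dssp_dict
from biotite.structure.io import pdb as pdbio

from . import proximity_seq
from .ptm_tables import ProteinSet, SiteTable

logger = logging.getLogger(__name__)

DSSP_CODES = "HGIEBTSC"

#: atom holding the side-chain oxygen (acceptors) / sulfur (Met)
SIDECHAIN_ATOM = {"M": "SD", "S": "OG", "T": "OG1", "Y": "OH"}

_CATEGORY = {"H": "helix", "G": "helix", "I": "helix",
             "E": "strand", "B": "strand",
             "T": "coil", "S": "coil", "C": "coil"}


def ss_category(dssp_code: str) -> str:
    """Collapse an 8-state DSSP code to helix / strand / coil.

    3-10, alpha and pi helices (G, H, I) are 'helix'; beta sheet and bridge
    (E, B) are 'strand'; turn, bend and coil (T, S, C) are 'coil'.
    """
    try:
        return _CATEGORY[dssp_code]
    except KeyError:
        raise ValueError(f"unknown DSSP code {dssp_code!r}") from None


@dataclass
class ProteinStructure:
    """Per-residue coordinates and DSSP codes for one chain of one protein.

    ``atoms`` maps 1-based residue index (sequence coordinates) to
    atom-name -> xyz (Angstroms).  Every residue with coordinates carries at
    least ``CA``; modifiable residues may carry their side-chain atom.
    """

    accession: str
    atoms: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    dssp: dict[int, str] = field(default_factory=dict)
    sequence: str | None = None

    def sidechain_coord(self, index: int, residue_letter: str) -> np.ndarray | None:
        name = SIDECHAIN_ATOM.get(residue_letter)
        if name is None:
            return None
        return self.atoms.get(index, {}).get(name)


class StructureSet:
    """Keyed collection of :class:`ProteinStructure`."""

    def __init__(self, structures: Iterable[ProteinStructure] = ()) -> None:
        self._structures: dict[str, ProteinStructure] = {}
        for s in structures:
            self.add(s)

    def add(self, structure: ProteinStructure) -> None:
        if structure.accession in self._structures:
            raise ValueError(f"duplicate structure for {structure.accession!r}")
        self._structures[structure.accession] = structure

    def __len__(self) -> int:
        return len(self._structures)

    def __iter__(self) -> Iterator[ProteinStructure]:
        return iter(self._structures.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._structures

    def __getitem__(self, accession: str) -> ProteinStructure:
        return self._structures[accession]

    def accessions(self) -> list[str]:
        return list(self._structures)


def _read_mapping(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", comment="#",
                      dtype={"accession": str, "pdb_id": str, "chain": str})
    need = {"accession", "pdb_id", "chain", "offset"}
    if not need <= set(tab.columns):
        raise ValueError("mapping file needs columns accession, pdb_id, chain, offset")
    return tab


def read_structures(pdb_paths: Iterable[str | Path],
                    dssp_paths: Iterable[str | Path] = (),
                    proteins: ProteinSet | None = None,
                    mapping_path: str | Path | None = None) -> StructureSet:
    """Load PDB files (and optional DSSP outputs) into a StructureSet.

    Without a mapping file, the file stem is taken as the accession, chain A
    is used and PDB residue numbers are assumed to be sequence coordinates.
    A mapping TSV ``accession  pdb_id  chain  offset`` selects the chain and
    shifts PDB numbering by ``offset`` into sequence coordinates.  Residues
    whose PDB residue letter disagrees with the protein sequence are dropped
    and logged (curation of mismatched models is deliberately conservative).
    """
    mapping = _read_mapping(mapping_path) if mapping_path is not None else None
    structures = StructureSet()
    dssp_by_stem = {Path(p).stem: Path(p) for p in dssp_paths}

    for path in pdb_paths:
        path = Path(path)
        stem = path.stem
        if mapping is not None:
            rows = mapping[mapping["pdb_id"] == stem]
            if rows.empty:
                logger.warning("no mapping entry for PDB %s; skipped", stem)
                continue
            row = rows.iloc[0]
            accession, chain, offset = row["accession"], row["chain"], int(row["offset"])
        else:
            accession, chain, offset = stem, "A", 0

        pfile = pdbio.PDBFile.read(str(path))
        arr = pfile.get_structure(model=1, altloc="occupancy")
        arr = arr[arr.chain_id == chain]
        if arr.array_length() == 0:
            raise ValueError(f"{path}: no atoms on chain {chain}")

        struct = ProteinStructure(accession)
        seq = proteins[accession].sequence if (proteins and accession in proteins) else None
        struct.sequence = seq
        n_mismatch = 0
        for res_id in np.unique(arr.res_id):
            index = int(res_id) + offset
            sel = arr[arr.res_id == res_id]
            letter = _THREE_TO_ONE.get(sel.res_name[0], "X")
            if seq is not None:
                if not 1 <= index <= len(seq) or (letter != "X" and seq[index - 1] != letter):
                    n_mismatch += 1
                    continue
            struct.atoms[index] = {
                str(name): sel.coord[i].astype(float)
                for i, name in enumerate(sel.atom_name)
            }
        if n_mismatch:
            logger.warning("%s: dropped %d residue(s) mismatching the sequence",
                           accession, n_mismatch)

        if stem in dssp_by_stem:
            dssp_dict, _ = make_dssp_dict(str(dssp_by_stem[stem]))
            for (chainid, (_, resseq, _)), fields in dssp_dict.items():
                if chainid != chain:
                    continue
                code = fields[1]
                struct.dssp[int(resseq) + offset] = "C" if code in ("-", " ") else code
        structures.add(struct)
    return structures


def spatial_nearest(structure: ProteinStructure, met_index: int,
                    acceptor_indices: Iterable[int]
                    ) -> tuple[float, int] | None:
    """Distance (Angstrom) from a Met sulfur to the closest acceptor hydroxyl O.

    Returns ``(distance, acceptor residue index)`` with ties broken by the
    lowest residue index, or None when the Met sulfur or every acceptor
    side-chain oxygen is unresolved.
    """
    seq = structure.sequence
    if seq is None:
        raise ValueError("spatial_nearest needs structure.sequence")
    sd = structure.sidechain_coord(met_index, "M")
    if sd is None:
        return None
    best: tuple[float, int] | None = None
    for idx in sorted(acceptor_indices):
        coord = structure.sidechain_coord(idx, seq[idx - 1])
        if coord is None:
            continue
        dist = float(np.linalg.norm(sd - coord))
        if best is None or dist < best[0]:
            best = (dist, idx)
    return best


def spatial_distance_table(structures: StructureSet, proteins: ProteinSet,
                           sites: SiteTable) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-methionine spatial distance to the closest phosphosite.

    One row per methionine with both atoms resolved: accession, met_position,
    met_oxidized, spatial_distance, nearest_site.  The returned report counts
    methionines excluded because the Met sulfur or all phosphosite oxygens
    were unresolved.
    """
    rows = []
    report = {"unresolved_met": 0, "no_resolved_acceptor": 0}
    sulf = sites.by_kind("sulfoxide")
    for struct in structures:
        acc = struct.accession
        if acc not in proteins:
            continue
        protein = proteins[acc]
        struct.sequence = struct.sequence or protein.sequence
        phospho = sites.positions(acc, "phospho")
        if phospho.size == 0:
            continue
        oxidized = set(sulf.loc[sulf["accession"] == acc, "position"])
        for met_pos in protein.positions_of("M"):
            met_pos = int(met_pos)
            if struct.sidechain_coord(met_pos, "M") is None:
                report["unresolved_met"] += 1
                continue
            hit = spatial_nearest(struct, met_pos, phospho.tolist())
            if hit is None:
                report["no_resolved_acceptor"] += 1
                continue
            rows.append((acc, met_pos, met_pos in oxidized, hit[0], hit[1]))
    frame = pd.DataFrame(rows, columns=["accession", "met_position",
                                        "met_oxidized", "spatial_distance",
                                        "nearest_site"])
    for key, count in report.items():
        if count:
            logger.info("spatial distances: %d methionine(s) excluded (%s)",
                        count, key)
    return frame, report


def structured_sequence_distances(structures: StructureSet, proteins: ProteinSet,
                                  sites: SiteTable) -> pd.DataFrame:
    """Sequence-distance records restricted to the structured protein subset.

    Delegates to :func:`metophos.proximity_seq.build_distance_records` on the
    sub-proteome with structures, so the primary-structure analysis of
    structured proteins runs through exactly the same code path as the
    whole-proteome analysis.
    """
    accs = [a for a in structures.accessions() if a in proteins]
    return proximity_seq.build_distance_records(proteins.subset(accs), sites)


def ss_tabulation(structures: StructureSet, proteins: ProteinSet,
                  sites: SiteTable) -> pd.DataFrame:
    """Proportions of Met and MetO per 8-state DSSP code (each column sums to 1)."""
    sulf = sites.by_kind("sulfoxide")
    counts = {code: {"Met": 0, "MetO": 0} for code in DSSP_CODES}
    for struct in structures:
        acc = struct.accession
        if acc not in proteins or not struct.dssp:
            continue
        oxidized = set(sulf.loc[sulf["accession"] == acc, "position"])
        for met_pos in proteins[acc].positions_of("M"):
            code = struct.dssp.get(int(met_pos))
            if code is None:
                continue
            counts[code]["MetO" if int(met_pos) in oxidized else "Met"] += 1
    frame = pd.DataFrame(counts).T.reindex(list(DSSP_CODES))
    totals = frame.sum(axis=0)
    return frame.div(totals.where(totals > 0, 1.0), axis=1)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"
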