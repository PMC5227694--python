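"""Synthetic proteomes with plantable PTM-crosstalk effects.

The generator emulates the statistical structure the analyses assume:
residue composition with methionine at 2.3% of residues, per-acceptor
phosphorylation rates, per-methionine oxidation with an optional
proximity-to-phosphoserine effect on the odds scale, correlated per-protein
ubiquitylation/acetylation, log-normal protein abundances, and toy backbone
structures with DSSP-style secondary-structure labels.

The proximity effect is logit-additive: a methionine within
``proximity_radius`` residues of a phosphoserine is oxidized with probability
``odds' / (1 + odds')`` where ``odds' = proximity_odds * p0 / (1 - p0)``,
so the planted effect composes with any baseline rate ``p0``.  An optional
``positional_boost`` multiplies the phosphorylation probability of a serine
that has a methionine at the given offsets (e.g. ``{+1: 3, +4: 3}``),
planting positional Met-phosphosite coupling.

Randomness: one root ``numpy.random.SeedSequence`` derived from the config
seed; every protein draws from its own spawned sub-stream, so outputs are
byte-identical under a fixed seed and individual proteins can be regenerated
without rerunning the whole simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ptm_tables import ProteinRecord, ProteinSet, SiteTable, SITE_COLUMNS
from .structure_3d import (ONE_TO_THREE, SIDECHAIN_ATOM, ProteinStructure,
                           StructureSet)

MIN_LENGTH = 30

_BASE_COMPOSITION = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "F": 0.037, "P": 0.063, "S": 0.083,
    "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.060,
}


def default_composition(met_freq: float = 0.023) -> dict[str, float]:
    """Human-like residue frequencies with methionine pinned at ``met_freq``."""
    other = sum(_BASE_COMPOSITION.values())
    scale = (1.0 - met_freq) / other
    comp = {aa: f * scale for aa, f in _BASE_COMPOSITION.items()}
    comp["M"] = met_freq
    return comp


@dataclass
class SimConfig:
    """Parameters of the synthetic proteome.

    Defaults follow the observed per-site rates of the curated oxidative
    stress dataset: phosphorylation of 24.9% of serines, 15.5% of threonines
    and 22.8% of tyrosines; baseline oxidation of 6.7% of methionines;
    methionine at 2.3% of residues.  ``proximity_odds=1`` and
    ``positional_boost=None`` mean no planted crosstalk (the null).
    ``ptm_corr_odds`` multiplies the ubiquitylation/acetylation odds of
    proteins carrying at least one oxidized methionine.  ``abundance_law``
    is (mu, sigma) of a natural-log-normal over linear abundance units.
    """

    n_proteins: int = 200
    length_law: tuple[float, float] = (350.0, 6.0)  # mean, NB dispersion
    composition: Mapping[str, float] = field(default_factory=default_composition)
    p_phospho: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.249, "T": 0.155, "Y": 0.228})
    p_oxidize_base: float = 0.067
    proximity_odds: float = 1.0
    proximity_radius: int = 7
    positional_boost: Mapping[int, float] | None = None
    p_ubiq: float = 0.45
    p_acetyl: float = 0.35
    ptm_corr_odds: float = 1.0
    abundance_law: tuple[float, float] = (9.2, 2.3)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        mean, disp = self.length_law
        if mean <= MIN_LENGTH or disp <= 0:
            raise ValueError(f"length mean must exceed {MIN_LENGTH}, dispersion > 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1 (got {total})")
        if any(f < 0 for f in self.composition.values()):
            raise ValueError("composition frequencies must be non-negative")
        probs = [*self.p_phospho.values(), self.p_oxidize_base,
                 self.p_ubiq, self.p_acetyl]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.proximity_odds <= 0 or self.ptm_corr_odds <= 0:
            raise ValueError("odds multipliers must be positive")
        if self.proximity_radius < 1:
            raise ValueError("proximity_radius must be >= 1")
        if self.positional_boost is not None:
            if any(o == 0 for o in self.positional_boost):
                raise ValueError("positional_boost offsets must be non-zero")
            if any(k < 0 for k in self.positional_boost.values()):
                raise ValueError("positional_boost multipliers must be >= 0")


def _shift_odds(p: np.ndarray | float, odds_multiplier: float):
    """Shift a probability on the odds (logit-additive) scale."""
    odds = odds_multiplier * np.asarray(p) / (1.0 - np.asarray(p))
    return odds / (1.0 + odds)


def simulate_proteome(config: SimConfig) -> tuple[ProteinSet, SiteTable]:
    """Draw a proteome and its PTM site table under the configured effects.

    Sequences are i.i.d. draws from the composition; phosphosites are drawn
    per acceptor; each methionine is oxidized with its (possibly
    proximity-shifted) probability, and oxidized methionines get an oxidized
    fraction uniform on [0.2, 1] so the default curation filter keeps them
    all.  Ubiquityl/acetyl flags are realized as a site on one random lysine.
    """
    config.validate()
    letters = sorted(config.composition)
    probs = np.array([config.composition[aa] for aa in letters])
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    letter_bytes = np.frombuffer("".join(letters).encode(), dtype=np.uint8)
    code_of = {aa: i for i, aa in enumerate(letters)}
    met_code = code_of.get("M", -1)
    lys_code = code_of.get("K", -1)

    mean, disp = config.length_law
    nb_mean = mean - MIN_LENGTH
    nb_p = disp / (disp + nb_mean)
    mu, sigma = config.abundance_law
    boost = dict(config.positional_boost or {})

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_proteins)

    records = []
    acc_col: list[str] = []
    pos_col: list[int] = []
    res_col: list[str] = []
    kind_col: list[str] = []
    frac_col: list[float] = []

    for i in range(config.n_proteins):
        rng = np.random.default_rng(children[i])
        accession = f"SYN{i:05d}"
        length = MIN_LENGTH + int(rng.negative_binomial(disp, nb_p))
        codes = np.searchsorted(cum, rng.random(length), side="right")
        sequence = letter_bytes[codes].tobytes().decode()

        met0 = np.flatnonzero(codes == met_code)  # 0-based
        pser_arr = np.zeros(0, dtype=int)  # 1-based phosphoserines
        for residue, base_p in config.p_phospho.items():
            idx0 = np.flatnonzero(codes == code_of.get(residue, -2))
            if idx0.size == 0:
                continue
            p = np.full(idx0.size, base_p)
            if boost and residue == "S" and met0.size:
                for offset, mult in boost.items():
                    has_met = np.isin(idx0 + offset, met0)
                    p = np.where(has_met, p * mult, p)
                p = np.minimum(p, 1.0)
            hit = idx0[rng.random(idx0.size) < p]
            if hit.size:
                if residue == "S":
                    pser_arr = np.sort(hit + 1)
                acc_col.extend([accession] * hit.size)
                pos_col.extend((hit + 1).tolist())
                res_col.extend([residue] * hit.size)
                kind_col.extend(["phospho"] * hit.size)
                frac_col.extend([np.nan] * hit.size)

        has_meto = False
        if met0.size:
            p_ox = np.full(met0.size, config.p_oxidize_base)
            if config.proximity_odds != 1.0 and pser_arr.size:
                mets1 = met0 + 1
                idx = np.searchsorted(pser_arr, mets1)
                right = np.where(idx < pser_arr.size,
                                 pser_arr[np.minimum(idx, pser_arr.size - 1)] - mets1,
                                 np.iinfo(np.int64).max)
                left = np.where(idx > 0, mets1 - pser_arr[np.maximum(idx - 1, 0)],
                                np.iinfo(np.int64).max)
                near = np.minimum(right, left) <= config.proximity_radius
                p_ox = np.where(near, _shift_odds(p_ox, config.proximity_odds), p_ox)
            ox = rng.random(met0.size) < p_ox
            n_ox = int(ox.sum())
            if n_ox:
                has_meto = True
                fracs = rng.uniform(0.2, 1.0, n_ox)
                hit = met0[ox] + 1
                acc_col.extend([accession] * n_ox)
                pos_col.extend(hit.tolist())
                res_col.extend(["M"] * n_ox)
                kind_col.extend(["sulfoxide"] * n_ox)
                frac_col.extend(fracs.tolist())

        corr = config.ptm_corr_odds if has_meto else 1.0
        lys0 = np.flatnonzero(codes == lys_code)
        for kind, base_p in (("ubiquityl", config.p_ubiq),
                             ("acetyl", config.p_acetyl)):
            p = _shift_odds(base_p, corr) if corr != 1.0 else base_p
            flagged = rng.random() < p
            if flagged and lys0.size:
                site = int(lys0[rng.integers(lys0.size)]) + 1
                acc_col.append(accession)
                pos_col.append(site)
                res_col.append("K")
                kind_col.append(kind)
                frac_col.append(np.nan)

        abundance = float(rng.lognormal(mu, sigma))
        records.append(ProteinRecord(accession, sequence, abundance))

    proteins = ProteinSet(records)
    frame = pd.DataFrame({
        "accession": acc_col, "position": pos_col, "residue": res_col,
        "kind": kind_col, "oxidized_fraction": frac_col,
    }, columns=SITE_COLUMNS)
    return proteins, SiteTable(frame)


# ---------------------------------------------------------------------------
# toy structures


def simulate_structures(proteins: ProteinSet, seed: int = 0,
                        step: float = 3.8, sidechain_offset: float = 2.0,
                        min_separation: float = 3.4,
                        segment_mean: float = 6.0) -> StructureSet:
    """Self-avoiding random-walk backbones with pseudo side-chain atoms.

    Consecutive C-alpha positions are ``step`` Angstroms apart; a new point is
    re-drawn (up to 30 tries) whenever it comes within ``min_separation`` of
    any earlier residue, giving loosely self-avoiding toy chains.  Met, Ser,
    Thr and Tyr get a pseudo side-chain atom (SD / OG / OG1 / OH) offset
    ``sidechain_offset`` from the backbone in a random direction.  DSSP codes
    are assigned in runs with geometric lengths (mean ``segment_mean``).
    """
    if len(proteins) == 0:
        raise ValueError("proteins must be non-empty")
    ss_probs = {"H": 0.30, "E": 0.20, "C": 0.20, "T": 0.12,
                "S": 0.10, "G": 0.04, "B": 0.02, "I": 0.02}
    codes = list(ss_probs)
    weights = np.array([ss_probs[c] for c in codes])
    root = np.random.SeedSequence(seed)
    out = StructureSet()
    for child, protein in zip(root.spawn(len(proteins)), proteins):
        rng = np.random.default_rng(child)
        n = len(protein.sequence)
        coords = np.empty((n, 3))
        coords[0] = 0.0
        for i in range(1, n):
            for _ in range(30):
                v = rng.normal(size=3)
                v *= step / np.linalg.norm(v)
                cand = coords[i - 1] + v
                if i < 2:
                    break
                d2 = np.sum((coords[:i - 1] - cand) ** 2, axis=1)
                if d2.min() >= min_separation ** 2:
                    break
            coords[i] = cand

        struct = ProteinStructure(protein.accession, sequence=protein.sequence)
        for i, letter in enumerate(protein.sequence):
            atoms = {"CA": coords[i].copy()}
            name = SIDECHAIN_ATOM.get(letter)
            if name is not None:
                u = rng.normal(size=3)
                u *= sidechain_offset / np.linalg.norm(u)
                atoms[name] = coords[i] + u
            struct.atoms[i + 1] = atoms

        ss = []
        while len(ss) < n:
            code = codes[int(rng.choice(len(codes), p=weights / weights.sum()))]
            run = 1 + int(rng.geometric(1.0 / segment_mean))
            ss.extend([code] * run)
        for i, code in enumerate(ss[:n]):
            struct.dssp[i + 1] = code
        out.add(struct)
    return out


def write_structure_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a toy structure as a single-model, chain-A PDB file."""
    import biotite.structure as bst
    from biotite.structure.io import pdb as pdbio

    indices = sorted(structure.atoms)
    n_atoms = sum(len(structure.atoms[i]) for i in indices)
    arr = bst.AtomArray(n_atoms)
    k = 0
    seq = structure.sequence or ""
    for idx in indices:
        letter = seq[idx - 1] if idx <= len(seq) else "X"
        for name, xyz in structure.atoms[idx].items():
            arr.coord[k] = xyz
            arr.chain_id[k] = "A"
            arr.res_id[k] = idx
            arr.res_name[k] = ONE_TO_THREE.get(letter, "UNK")
            arr.atom_name[k] = name
            arr.element[k] = "S" if name == "SD" else ("O" if name in
                                                       ("OG", "OG1", "OH") else "C")
            k += 1
    arr.hetero[:] = False
    pfile = pdbio.PDBFile()
    pfile.set_structure(arr)
    pfile.write(str(path))


def write_structure_dssp(structure: ProteinStructure, path: str | Path) -> None:
    """Write secondary structure as a classic fixed-column DSSP file.

    Only the columns the standard parsers read are meaningful (residue
    number, chain, amino acid, structure code); accessibility, H-bond and
    dihedral fields are filled with zeros.
    """
    seq = structure.sequence or ""
    lines = [
        "==== Secondary Structure Definition; synthetic toy structure ====",
        f"  {len(structure.dssp):4d}  1  0  0  0  TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    for j, idx in enumerate(sorted(structure.dssp), start=1):
        aa = seq[idx - 1] if idx <= len(seq) else "X"
        code = structure.dssp[idx]
        ca = structure.atoms.get(idx, {}).get("CA", np.zeros(3))
        line = (
            f"{j:5d}{idx:5d} A {aa}  {code}"       # cols 0-16: idx, resnum, chain, aa, ss
            + " " * 17                             # structure detail, cols 17-33
            + f"{0:4d}"                            # ACC, cols 34-37
            + f"{0:7d},{0.0:4.1f}"                 # N-H-->O, cols 38-49
            + f"{0:6d},{0.0:4.1f}"                 # O-->H-N, cols 50-60
            + f"{0:6d},{0.0:4.1f}"                 # N-H-->O, cols 61-71
            + f"{0:6d},{0.0:4.1f}"                 # O-->H-N, cols 72-82
            + f"{0.0:8.3f}{0.0:6.1f}{0.0:6.1f}"    # TCO KAPPA ALPHA, cols 83-102
            + f"{0.0:6.1f}{0.0:6.1f}"              # PHI PSI, cols 103-114
            + f" {ca[0]:6.1f} {ca[1]:6.1f} {ca[2]:6.1f}"
        )
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_simulation(proteins: ProteinSet, sites: SiteTable, outdir: str | Path,
                     structures: StructureSet | None = None) -> dict[str, Path]:
    """Write a simulated dataset in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": outdir / "proteome.fasta",
             "sites": outdir / "sites.tsv",
             "abundance": outdir / "abundance.tsv"}
    proteins.write_fasta(paths["fasta"])
    sites.write_tsv(paths["sites"])
    ab = proteins.abundances()
    ab.rename("abundance").to_csv(paths["abundance"], sep="\t",
                                  index_label="accession")
    if structures is not None:
        sdir = outdir / "structures"
        sdir.mkdir(exist_ok=True)
        for struct in structures:
            write_structure_pdb(struct, sdir / f"{struct.accession}.pdb")
            write_structure_dssp(struct, sdir / f"{struct.accession}.dssp")
        paths["structures"] = sdir
    return paths
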