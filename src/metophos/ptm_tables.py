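"""Domain types, file I/O and curation for proteomes and PTM site tables.

All coordinates are 1-based, matching UniProt / PhosphoSitePlus conventions:
position 1 is the initiator residue and ``record.residue(position)`` returns
the letter stored for that site.  Sequences use the 20 canonical amino-acid
letters plus ``X`` for unknown residues; ``X`` never matches a modifiable
residue.

The site-table TSV format is tab-delimited UTF-8 with header
``accession  position  residue  kind  oxidized_fraction`` and ``#`` comment
lines.  The abundance TSV carries ``accession  abundance``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
MOD_KINDS = ("phospho", "sulfoxide", "ubiquityl", "acetyl")
PHOSPHO_ACCEPTORS = frozenset("STY")

#: residues a modification kind may legally sit on
KIND_RESIDUES: Mapping[str, frozenset] = {
    "phospho": PHOSPHO_ACCEPTORS,
    "sulfoxide": frozenset("M"),
    "ubiquityl": frozenset("K"),
    "acetyl": frozenset("K"),
}

SITE_COLUMNS = ["accession", "position", "residue", "kind", "oxidized_fraction"]

_EMPTY_POSITIONS = np.zeros(0, dtype=int)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, sequence and optional abundance.

    Abundance is in arbitrary linear units (copy numbers, iBAQ, ...);
    downstream analyses work on its decimal logarithm.
    """

    accession: str
    sequence: str
    abundance: float | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue letters {sorted(bad)}"
            )
        if self.abundance is not None and not self.abundance > 0:
            raise ValueError(f"{self.accession}: abundance must be > 0")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]

    def positions_of(self, letters: str | Iterable[str]) -> np.ndarray:
        """Sorted 1-based positions of the given residue letters."""
        wanted = set(letters)
        arr = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
        mask = np.zeros(arr.shape, dtype=bool)
        for letter in wanted:
            mask |= arr == ord(letter)
        return np.flatnonzero(mask) + 1


@dataclass(frozen=True)
class ModSite:
    """One modification observation on one residue."""

    accession: str
    position: int
    residue: str
    kind: str
    oxidized_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.kind not in MOD_KINDS:
            raise ValueError(f"unknown modification kind {self.kind!r}")
        if self.residue not in KIND_RESIDUES[self.kind]:
            raise ValueError(
                f"kind {self.kind!r} not allowed on residue {self.residue!r}"
            )
        if self.oxidized_fraction is not None:
            if self.kind != "sulfoxide":
                raise ValueError("oxidized_fraction only applies to sulfoxide sites")
            if not 0.0 <= self.oxidized_fraction <= 1.0:
                raise ValueError("oxidized_fraction must lie in [0, 1]")


class ProteinSet:
    """Keyed collection of :class:`ProteinRecord` with unique accessions."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._records:
            raise ValueError(f"duplicate accession {record.accession!r}")
        self._records[record.accession] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._records[accession]

    def accessions(self) -> list[str]:
        return list(self._records)

    def subset(self, accessions: Iterable[str]) -> "ProteinSet":
        return ProteinSet(self._records[a] for a in accessions)

    def abundances(self) -> pd.Series:
        """Abundances of all proteins that have one, indexed by accession."""
        data = {a: r.abundance for a, r in self._records.items()
                if r.abundance is not None}
        return pd.Series(data, dtype=float)

    def missing_abundance(self) -> list[str]:
        return [a for a, r in self._records.items() if r.abundance is None]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self:
                fh.write(f">{rec.accession}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i:i + 60] + "\n")


class SiteTable:
    """Validated table of modification sites.

    Backed by a :class:`pandas.DataFrame` with columns ``accession, position,
    residue, kind, oxidized_fraction``.  Duplicate ``(accession, position,
    kind)`` rows are collapsed on construction.  Equality is
    order-independent.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.reindex(columns=SITE_COLUMNS).copy()
        frame["position"] = frame["position"].astype(int)
        frame["oxidized_fraction"] = frame["oxidized_fraction"].astype(float)
        frame = frame.drop_duplicates(subset=["accession", "position", "kind"])
        self._frame = frame.reset_index(drop=True)
        self._pos_index: dict[tuple[str, str], np.ndarray] | None = None

    @classmethod
    def from_sites(cls, sites: Iterable[ModSite]) -> "SiteTable":
        rows = [(s.accession, s.position, s.residue, s.kind, s.oxidized_fraction)
                for s in sites]
        return cls(pd.DataFrame(rows, columns=SITE_COLUMNS))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteTable):
            return NotImplemented
        key = ["accession", "position", "kind"]
        a = self._frame.sort_values(key).reset_index(drop=True)
        b = other._frame.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    def by_kind(self, kind: str) -> pd.DataFrame:
        if kind not in MOD_KINDS:
            raise ValueError(f"unknown modification kind {kind!r}")
        return self._frame[self._frame["kind"] == kind]

    def positions(self, accession: str, kind: str) -> np.ndarray:
        """Sorted positions of sites of one kind on one protein."""
        if kind not in MOD_KINDS:
            raise ValueError(f"unknown modification kind {kind!r}")
        if self._pos_index is None:
            self._pos_index = {
                (k, a): np.sort(grp["position"].to_numpy())
                for (k, a), grp in self._frame.groupby(["kind", "accession"])
            }
        return self._pos_index.get((kind, accession), _EMPTY_POSITIONS)

    def accessions_with(self, kind: str) -> set[str]:
        return set(self.by_kind(kind)["accession"])

    def write_tsv(self, path: str | Path) -> None:
        out = self._frame.copy()
        out["oxidized_fraction"] = out["oxidized_fraction"].map(
            lambda v: "" if pd.isna(v) else format(v, ".6g")
        )
        out.to_csv(path, sep="\t", index=False)


def load_abundances(path: str | Path) -> pd.Series:
    """Read an ``accession<TAB>abundance`` table; raise on non-positive values."""
    tab = pd.read_csv(path, sep="\t", comment="#", dtype={"accession": str})
    if not {"accession", "abundance"} <= set(tab.columns):
        raise ValueError("abundance table needs columns: accession, abundance")
    if (tab["abundance"] <= 0).any():
        bad = tab.loc[tab["abundance"] <= 0, "accession"].tolist()
        raise ValueError(f"non-positive abundance for {bad}")
    if tab["accession"].duplicated().any():
        raise ValueError("duplicate accessions in abundance table")
    return tab.set_index("accession")["abundance"].astype(float)


def load_proteome(fasta_path: str | Path,
                  abundance_path: str | Path | None = None) -> ProteinSet:
    """Read a FASTA proteome and optionally join per-protein abundances.

    The FASTA identifier (first whitespace-delimited token of the header) is
    the accession.  Proteins absent from the abundance table are kept with
    ``abundance=None`` and reported through ``ProteinSet.missing_abundance``.
    """
    abundances = (load_abundances(abundance_path)
                  if abundance_path is not None else pd.Series(dtype=float))
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ab = float(abundances[rec.id]) if rec.id in abundances.index else None
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), ab))
    if not records:
        raise ValueError(f"no records in FASTA {fasta_path}")
    proteins = ProteinSet()
    for rec in records:
        proteins.add(rec)  # raises on duplicate accessions
    n_missing = len(proteins.missing_abundance())
    if abundance_path is not None and n_missing:
        logger.warning("%d protein(s) without abundance data", n_missing)
    return proteins


def validate_sites(frame: pd.DataFrame, proteins: ProteinSet
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Validate site rows against a proteome.

    Rows on unknown accessions, or whose stored residue letter does not match
    the sequence at that position (including positions beyond the chain), are
    dropped and counted; structurally malformed rows (position < 1, unknown
    kind, residue illegal for the kind) raise ``ValueError``.
    """
    report = {"unknown_accession": 0, "residue_mismatch": 0}
    if (frame["position"] < 1).any():
        raise ValueError("positions are 1-based; found position < 1")
    bad_kind = set(frame["kind"]) - set(MOD_KINDS)
    if bad_kind:
        raise ValueError(f"unknown modification kind(s) {sorted(bad_kind)}")
    for kind, grp in frame.groupby("kind"):
        illegal = set(grp["residue"]) - KIND_RESIDUES[kind]
        if illegal:
            raise ValueError(f"kind {kind!r} not allowed on {sorted(illegal)}")

    known = frame["accession"].map(lambda a: a in proteins)
    report["unknown_accession"] = int((~known).sum())
    frame = frame[known]

    def matches(row: pd.Series) -> bool:
        seq = proteins[row["accession"]].sequence
        return row["position"] <= len(seq) and seq[row["position"] - 1] == row["residue"]

    ok = frame.apply(matches, axis=1) if len(frame) else pd.Series(dtype=bool)
    report["residue_mismatch"] = int((~ok).sum()) if len(frame) else 0
    frame = frame[ok] if len(frame) else frame
    for key, count in report.items():
        if count:
            logger.warning("dropped %d site row(s): %s", count, key)
    return frame, report


def load_sites(tsv_path: str | Path, proteins: ProteinSet) -> SiteTable:
    """Read and validate a site-table TSV against a proteome."""
    frame = pd.read_csv(
        tsv_path, sep="\t", comment="#",
        dtype={"accession": str, "residue": str, "kind": str},
    )
    missing = set(SITE_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise ValueError(f"site table missing column(s) {sorted(missing)}")
    if "oxidized_fraction" not in frame.columns:
        frame["oxidized_fraction"] = np.nan
    try:
        frame["position"] = frame["position"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed position column: {exc}") from exc
    clean, _ = validate_sites(frame, proteins)
    return SiteTable(clean)


def curate_meto(sites: SiteTable, min_fraction: float = 0.20) -> SiteTable:
    """Apply the oxidation-extent curation filter to sulfoxide rows.

    Sulfoxide sites with ``oxidized_fraction >= min_fraction`` are retained
    (the boundary is inclusive); sulfoxide rows with no recorded fraction are
    ambiguous and dropped with a warning.  Rows of other kinds pass through
    unchanged.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    frame = sites.frame
    sulf = frame["kind"] == "sulfoxide"
    ambiguous = sulf & frame["oxidized_fraction"].isna()
    if ambiguous.any():
        logger.warning("dropped %d sulfoxide row(s) without oxidized_fraction",
                       int(ambiguous.sum()))
    keep = ~sulf | (frame["oxidized_fraction"] >= min_fraction)
    keep &= ~ambiguous
    return SiteTable(frame[keep])
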