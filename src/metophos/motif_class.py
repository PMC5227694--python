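"""Kinase-motif windows and the phosphoserine decision-tree classifier.

The classifier assigns each phosphoserine window to one of the broad Ser/Thr
kinase substrate classes using a fixed-order binary decision tree; the first
matching rule wins:

1. proline at P+1                                   -> Pro-directed
2. five or more D/E within P+1..P+6                 -> Acidophilic
3. R or K at P-3                                    -> Basophilic
4. D or E at P+1, P+2 or P+3                        -> Acidophilic
5. two or more R/K within P-6..P-1                  -> Basophilic
6. otherwise                                        -> Others

The rule order matters (rule 2 can pre-empt rule 3).  Windows are 15-mers
(half-width 7) with ``-`` padding beyond the chain termini; a padding slot
never satisfies any residue test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .ptm_tables import ProteinSet, SiteTable

PAD = "-"
HALFWIDTH = 7


class KinaseClass(str, Enum):
    ProDirected = "Pro-directed"
    Acidophilic = "Acidophilic"
    Basophilic = "Basophilic"
    Others = "Others"


@dataclass(frozen=True)
class MotifWindow:
    """Fixed-width sequence window centred on a phospho-acceptor."""

    residues: str
    center_is_phospho: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) % 2 != 1:
            raise ValueError("window width must be odd")
        inner = self.residues.strip(PAD)
        if PAD in inner:
            raise ValueError("padding must be contiguous at the ends")

    @property
    def halfwidth(self) -> int:
        return len(self.residues) // 2

    @property
    def center_residue(self) -> str:
        return self.residues[self.halfwidth]

    def at(self, offset: int) -> str:
        """Residue letter at a P+/-offset (PAD beyond the termini)."""
        if abs(offset) > self.halfwidth:
            raise IndexError(f"offset {offset} outside +/-{self.halfwidth}")
        return self.residues[self.halfwidth + offset]

    def offsets_of(self, letter: str) -> list[int]:
        return [o for o in range(-self.halfwidth, self.halfwidth + 1)
                if o != 0 and self.at(o) == letter]


def extract_window(sequence: str, center: int,
                   halfwidth: int = HALFWIDTH,
                   center_is_phospho: bool = False) -> MotifWindow:
    """Copy the +/-halfwidth window around a 1-based centre, padding ends."""
    if not 1 <= center <= len(sequence):
        raise ValueError(f"center {center} outside 1..{len(sequence)}")
    chars = []
    for off in range(-halfwidth, halfwidth + 1):
        pos = center + off
        chars.append(sequence[pos - 1] if 1 <= pos <= len(sequence) else PAD)
    return MotifWindow("".join(chars), center_is_phospho)


def classify_pser_motif(window: MotifWindow,
                        allow_thr: bool = False) -> KinaseClass:
    """Apply the kinase-class decision tree to a phosphoserine window."""
    allowed = "ST" if allow_thr else "S"
    if window.center_residue not in allowed:
        raise ValueError(
            f"center residue {window.center_residue!r} is not in {allowed!r}")
    if window.halfwidth < 7:
        raise ValueError("classifier needs a half-width >= 7 window")
    if window.at(+1) == "P":
        return KinaseClass.ProDirected
    if sum(window.at(o) in "DE" for o in range(1, 7)) >= 5:
        return KinaseClass.Acidophilic
    if window.at(-3) in "RK":
        return KinaseClass.Basophilic
    if any(window.at(o) in "DE" for o in (1, 2, 3)):
        return KinaseClass.Acidophilic
    if sum(window.at(o) in "RK" for o in range(-6, 0)) >= 2:
        return KinaseClass.Basophilic
    return KinaseClass.Others


def tally_determinant_positions(patterns: Iterable[str]) -> dict[int, int]:
    """Count, per offset, how many motif patterns place an M there.

    Patterns are one-per-line strings aligned on the acceptor, which is
    marked with lowercase ``s`` or ``t``; ``X`` is a wildcard and any other
    uppercase letter a fixed residue (e.g. ``sXXXM`` marks M at P+4).
    """
    counts: dict[int, int] = {}
    for pattern in patterns:
        pattern = pattern.strip()
        if not pattern or pattern.startswith("#"):
            continue
        acceptor = [i for i, ch in enumerate(pattern) if ch in "st"]
        if len(acceptor) != 1:
            raise ValueError(
                f"pattern {pattern!r} needs exactly one lowercase s/t acceptor")
        center = acceptor[0]
        for i, ch in enumerate(pattern):
            if ch == "M":
                counts[i - center] = counts.get(i - center, 0) + 1
    return counts


def read_pattern_file(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")]


def class_frequencies(subsets: Mapping[str, Iterable[MotifWindow]],
                      allow_thr: bool = False) -> pd.DataFrame:
    """Kinase-class frequency table: one row per subset, columns sum to 1."""
    classes = [c.value for c in KinaseClass]
    rows = {}
    for name, windows in subsets.items():
        windows = list(windows)
        if not windows:
            raise ValueError(f"subset {name!r} is empty")
        tally = {c: 0 for c in classes}
        for w in windows:
            tally[classify_pser_motif(w, allow_thr=allow_thr).value] += 1
        total = len(windows)
        rows[name] = {c: tally[c] / total for c in classes}
    return pd.DataFrame.from_dict(rows, orient="index", columns=classes)


def pser_subsets(proteins: ProteinSet, sites: SiteTable,
                 halfwidth: int = HALFWIDTH
                 ) -> dict[str, list[MotifWindow]]:
    """The standard phosphoserine window subsets for class-frequency tables.

    Subsets: all pSer; pSer on sulfoxidized proteins; pSer with a MetO within
    +/-halfwidth; pSer with MetO at P+1; pSer with MetO at P+4.  Subsets that
    come out empty on a given dataset are omitted.
    """
    sulf = sites.by_kind("sulfoxide")
    meto_accs = set(sulf["accession"])
    phospho = sites.by_kind("phospho")
    pser = phospho[phospho["residue"] == "S"]

    out: dict[str, list[MotifWindow]] = {
        "all_pser": [], "meto_proteome_pser": [], "meto_within_window": [],
        "meto_at_p1": [], "meto_at_p4": [],
    }
    for acc, grp in pser.groupby("accession"):
        protein = proteins[acc]
        metos = set(sulf.loc[sulf["accession"] == acc, "position"])
        for pos in grp["position"]:
            window = extract_window(protein.sequence, int(pos), halfwidth,
                                    center_is_phospho=True)
            out["all_pser"].append(window)
            if acc in meto_accs:
                out["meto_proteome_pser"].append(window)
            near = {pos + o for o in range(-halfwidth, halfwidth + 1)
                    if o != 0} & metos
            if near:
                out["meto_within_window"].append(window)
            if pos + 1 in metos:
                out["meto_at_p1"].append(window)
            if pos + 4 in metos:
                out["meto_at_p4"].append(window)
    return {name: ws for name, ws in out.items() if ws}
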