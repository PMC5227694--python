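"""Worked example: sulfoxidized phosphoproteins of cytoplasmic stress granules.

Four human stress-granule proteins carry both a phosphoserine and a nearby
oxidation-prone methionine inside the kinase recognition window; they are the
package's standard worked example for window extraction, offset arithmetic
and kinase-class assignment.  The 15-mer motifs are centred on the
phosphoserine; ``met_offset`` locates the oxidized methionine relative to it
(eIF2α's M223 sits four residues C-terminal of S219).
"""

from __future__ import annotations

from dataclasses import dataclass

from .motif_class import KinaseClass, MotifWindow, classify_pser_motif
from .ptm_tables import ModSite, ProteinRecord, ProteinSet, SiteTable


@dataclass(frozen=True)
class StressGranuleCase:
    name: str
    accession: str
    motif: str          # 15-mer centred on the phosphoserine
    pser_position: int
    meto_position: int
    kinase_class: KinaseClass

    @property
    def met_offset(self) -> int:
        return self.meto_position - self.pser_position

    def window(self) -> MotifWindow:
        return MotifWindow(self.motif, center_is_phospho=True)

    def classify(self) -> KinaseClass:
        return classify_pser_motif(self.window())


STRESS_GRANULE_CASES = (
    StressGranuleCase("eIF2 subunit 1", "P05198", "LRAGLNCSTENMPIK",
                      219, 223, KinaseClass.Acidophilic),
    StressGranuleCase("Pumilio homologue 1", "Q14671", "HAEHQVRSMDELNHD",
                      124, 125, KinaseClass.Acidophilic),
    StressGranuleCase("Ataxin-2", "Q99700", "QPSSTSESMDQLLNK",
                      814, 815, KinaseClass.Acidophilic),
    StressGranuleCase("Ataxin-2-like protein", "Q8WWM7", "TKDKFTDSAIAMNSK",
                      211, 215, KinaseClass.Basophilic),
)


def carrier_proteins(pad_residue: str = "G") -> tuple[ProteinSet, SiteTable]:
    """Synthetic carrier sequences embedding each motif at its true position.

    The 15-mer is placed so that its centre falls at the published
    phosphoserine position; everything outside the window is filler, so
    window-level analyses see exactly the published sequence context.  The
    site table carries the phosphoserine and the sulfoxide site (oxidized
    fraction 0.5, i.e. past the curation threshold).
    """
    proteins = ProteinSet()
    sites = []
    for case in STRESS_GRANULE_CASES:
        start = case.pser_position - 7  # 1-based start of the motif
        length = case.pser_position + 7 + 5
        seq = list(pad_residue * length)
        seq[start - 1:start - 1 + 15] = list(case.motif)
        proteins.add(ProteinRecord(case.accession, "".join(seq)))
        sites.append(ModSite(case.accession, case.pser_position, "S", "phospho"))
        sites.append(ModSite(case.accession, case.meto_position, "M",
                             "sulfoxide", oxidized_fraction=0.5))
    return proteins, SiteTable.from_sites(sites)
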