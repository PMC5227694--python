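"""Window extraction and the kinase-class decision tree."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metophos.examples import STRESS_GRANULE_CASES, carrier_proteins
from metophos.motif_class import (HALFWIDTH, PAD, KinaseClass, MotifWindow,
                                  class_frequencies, classify_pser_motif,
                                  extract_window, pser_subsets,
                                  tally_determinant_positions)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _window(n_term: str, c_term: str, center: str = "S") -> MotifWindow:
    n_term = n_term.rjust(7, "A")
    c_term = c_term.ljust(7, "A")
    return MotifWindow(n_term + center + c_term)


class TestExtractWindow:
    def test_published_stress_granule_windows(self):
        proteins, _ = carrier_proteins()
        for case in STRESS_GRANULE_CASES:
            window = extract_window(proteins[case.accession].sequence,
                                    case.pser_position)
            assert window.residues == case.motif

    def test_n_terminal_padding(self):
        window = extract_window("SAAAAAAAA", center=1)
        assert window.residues[:7] == PAD * 7
        assert window.center_residue == "S"

    @given(st.text(alphabet=AA, min_size=1, max_size=40), st.data())
    def test_round_trip_against_slice(self, seq, data):
        center = data.draw(st.integers(1, len(seq)))
        window = extract_window(seq, center)
        for off in range(-HALFWIDTH, HALFWIDTH + 1):
            pos = center + off
            expected = seq[pos - 1] if 1 <= pos <= len(seq) else PAD
            assert window.at(off) == expected


class TestDecisionTree:
    def test_published_group_assignments(self):
        for case in STRESS_GRANULE_CASES:
            assert case.classify() is case.kinase_class

    def test_proline_rule_has_absolute_precedence(self):
        # P at +1 wins over any acidic or basic context
        window = _window("RRRRRRR", "PDDDDDD")
        assert classify_pser_motif(window) is KinaseClass.ProDirected

    def test_five_acidics_preempt_basophilic_p_minus_3(self):
        window = MotifWindow("AAAAKAASEDEDEEA")
        assert window.at(-3) == "K"  # rule 3 would fire...
        assert classify_pser_motif(window) is KinaseClass.Acidophilic  # ...but rule 2 wins

    def test_basophilic_p_minus_3_preempts_acidic_p1_to_p3(self):
        window = _window("AAAAKAA", "AEAAAAA")
        assert classify_pser_motif(window) is KinaseClass.Basophilic

    def test_acidic_p1_p2_p3_preempts_two_basics_upstream(self):
        window = _window("AKKAAAA", "AAEAAAA")  # 2 basics in P-6..P-1
        assert classify_pser_motif(window) is KinaseClass.Acidophilic

    def test_two_basics_between_m6_and_m1(self):
        window = _window("AKAAKAA", "AAAAAAA")
        assert classify_pser_motif(window) is KinaseClass.Basophilic

    def test_others_fallback(self):
        window = _window("AAAAAAA", "AAAAAAA")
        assert classify_pser_motif(window) is KinaseClass.Others

    def test_late_acidics_do_not_trigger_any_acidic_rule(self):
        # D at +5,+6,+7: two inside P+1..P+6 (rule 2 needs 5), none in
        # P+1..P+3 (rule 4) -> falls through to Others
        window = MotifWindow("AAAAAAA" + "S" + "AAAADDD")
        assert classify_pser_motif(window) is KinaseClass.Others

    def test_pad_never_matches(self):
        window = MotifWindow(PAD * 7 + "S" + PAD * 7)
        assert classify_pser_motif(window) is KinaseClass.Others

    def test_center_must_be_serine_by_default(self):
        with pytest.raises(ValueError):
            classify_pser_motif(_window("AAAAAAA", "AAAAAAA", center="T"))
        assert classify_pser_motif(_window("AAAAAAA", "PAAAAAA", center="T"),
                                   allow_thr=True) is KinaseClass.ProDirected

    def test_total_and_deterministic_on_random_windows(self, rng):
        letters = np.array(list(AA + PAD))
        for _ in range(2000):
            chars = letters[rng.integers(0, len(letters), 15)]
            chars[7] = "S"
            w = "".join(chars)
            inner = w.strip(PAD)
            if PAD in inner:
                continue  # not a legal window shape
            window = MotifWindow(w)
            first = classify_pser_motif(window)
            assert first is classify_pser_motif(window)
            assert first in KinaseClass


class TestTally:
    def test_examples(self):
        assert tally_determinant_positions(["sM", "sXXXM"]) == {1: 1, 4: 1}
        assert tally_determinant_positions([]) == {}
        assert tally_determinant_positions(["MXs", "sXM"]) == {-2: 1, 2: 1}

    def test_pattern_without_acceptor_rejected(self):
        with pytest.raises(ValueError):
            tally_determinant_positions(["SXXM"])

    def test_bundled_example_pattern_file(self):
        from importlib.resources import files
        from metophos.motif_class import read_pattern_file
        path = files("metophos").joinpath("data/example_kinase_motifs.txt")
        tally = tally_determinant_positions(read_pattern_file(str(path)))
        assert tally[1] >= 2 and tally[4] >= 2  # M-containing demo patterns

    @given(st.lists(st.text(alphabet="MXA", max_size=6), max_size=8))
    def test_matches_per_offset_scan(self, tails):
        patterns = ["s" + t for t in tails]
        tally = tally_determinant_positions(patterns)
        for off in range(1, 7):
            expected = sum(1 for t in tails
                           if len(t) >= off and t[off - 1] == "M")
            assert tally.get(off, 0) == expected


class TestClassFrequencies:
    def test_single_window_subset(self):
        freq = class_frequencies({"one": [_window("AAAAAAA", "PAAAAAA")]})
        assert freq.loc["one", "Pro-directed"] == 1.0
        assert freq.loc["one"].sum() == pytest.approx(1.0)

    def test_rows_normalized(self, sim_default):
        proteins, sites = sim_default
        subsets = pser_subsets(proteins, sites)
        assert "all_pser" in subsets
        freq = class_frequencies(subsets)
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            class_frequencies({"empty": []})

    def test_planted_acidic_context_raises_acidophilic_share(self):
        # windows with MetO at +1 built on acidic context vs neutral pool
        acidic = [_window("AAAAAAA", "MEAAAAA") for _ in range(20)]
        neutral = [_window("AAAAAAA", "AAAAAAA") for _ in range(20)]
        freq = class_frequencies({"meto_at_p1": acidic, "all": neutral})
        assert (freq.loc["meto_at_p1", "Acidophilic"]
                > freq.loc["all", "Acidophilic"])
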