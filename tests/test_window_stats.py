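"""Window counts around phospho-acceptors, acceptor nulls, positional profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metophos.ptm_tables import ModSite, ProteinRecord, ProteinSet, SiteTable
from metophos.stats_core import ks_two_sample
from metophos.window_stats import (acceptor_null, build_window_counts,
                                   count_window, mean_per_site,
                                   positional_profile, profile_frame)


class TestCountWindow:
    def test_stress_granule_motif_example(self):
        # Pumilio-style 15-mer: the only Met sits at P+1 of the central Ser
        seq = "HAEHQVRSMDELNHD"
        wc = count_window(seq, center=8, met_positions=[9], metO_positions=[])
        assert wc.n_met == 1 and wc.n_metO == 0

    def test_terminal_truncation(self):
        wc = count_window("MASAAAAA", center=1, met_positions=[1],
                          metO_positions=[])
        # the Met at the centre itself is excluded; offsets -7..-1 are gone
        assert wc.n_met == 0

    def test_center_bounds(self):
        with pytest.raises(ValueError):
            count_window("MAS", 4, [], [])

    @given(st.integers(1, 60), st.sets(st.integers(1, 60), max_size=15),
           st.data())
    def test_matches_brute_scan(self, center, mets, data):
        metos = data.draw(st.sets(st.sampled_from(sorted(mets) or [1]),
                                  max_size=len(mets))) if mets else set()
        seq = "A" * 60
        wc = count_window(seq, center, mets, metos)
        assert wc.n_met == sum(1 <= p <= 60 and 0 < abs(p - center) <= 7
                               for p in mets)
        assert wc.n_metO == sum(0 < abs(p - center) <= 7 for p in metos)
        assert wc.n_metO <= wc.n_met


def _window_data():
    proteins = ProteinSet([
        ProteinRecord("P1", "SAMASAAAMASAAAS"),  # S1 S5 S11 S15; M3 M9
    ])
    sites = SiteTable.from_sites([
        ModSite("P1", 5, "S", "phospho"),
        ModSite("P1", 9, "M", "sulfoxide", oxidized_fraction=0.8),
    ])
    return proteins, sites


class TestBuildWindowCounts:
    def test_counts_and_flags(self):
        proteins, sites = _window_data()
        windows = build_window_counts(proteins, sites, "S")
        assert len(windows) == 4
        w5 = windows[windows["position"] == 5].iloc[0]
        assert w5["is_phosphosite"]
        assert w5["n_met"] == 2 and w5["n_metO"] == 1
        w15 = windows[windows["position"] == 15].iloc[0]
        assert w15["n_met"] == 1 and w15["n_metO"] == 1

    def test_mean_per_site(self):
        proteins, sites = _window_data()
        windows = build_window_counts(proteins, sites, "S")
        mean_met, mean_meto = mean_per_site(windows)
        assert mean_met == pytest.approx(windows["n_met"].mean())
        with pytest.raises(ValueError):
            mean_per_site(windows.iloc[0:0])

    def test_iid_expectation(self, sim_default):
        # under i.i.d. composition the mean Met per 14-slot window is close
        # to 14 x 0.023 (edge truncation pulls it slightly down)
        proteins, sites = sim_default
        windows = build_window_counts(proteins, sites, "S")
        mean_met, _ = mean_per_site(windows)
        assert mean_met == pytest.approx(14 * 0.023, rel=0.15)


class TestAcceptorNull:
    def test_population_sample_is_degenerate(self, sim_default):
        proteins, sites = sim_default
        windows = build_window_counts(proteins, sites, "S")
        null = acceptor_null(windows, len(windows), n_samples=50, seed=1)
        assert np.allclose(null.values, windows["n_met"].mean())

    def test_moments_match_sampling_theory(self, sim_default):
        proteins, sites = sim_default
        windows = build_window_counts(proteins, sites, "S")
        n, N = 400, len(windows)
        null = acceptor_null(windows, n, n_samples=4000, seed=2)
        counts = windows["n_met"].to_numpy(dtype=float)
        exp_sd = counts.std(ddof=0) / np.sqrt(n) * np.sqrt((N - n) / (N - 1))
        se_mean = exp_sd / np.sqrt(4000)
        assert null.values.mean() == pytest.approx(counts.mean(), abs=4 * se_mean)
        assert null.values.std() == pytest.approx(exp_sd, rel=0.1)

    def test_exact_and_counting_paths_agree(self, sim_default):
        proteins, sites = sim_default
        windows = build_window_counts(proteins, sites, "S")
        a = acceptor_null(windows, 200, 2000, seed=3, method="exact")
        b = acceptor_null(windows, 200, 2000, seed=4, method="count")
        assert ks_two_sample(a.values, b.values).p > 0.01

    def test_seed_reproducibility_and_guard(self, sim_default):
        proteins, sites = sim_default
        windows = build_window_counts(proteins, sites, "S")
        a = acceptor_null(windows, 100, 200, seed=9)
        b = acceptor_null(windows, 100, 200, seed=9)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ValueError):
            acceptor_null(windows, len(windows) + 1, 10)


class TestPositionalProfile:
    def test_meto_per_500_definition(self):
        # 50 phosphosites, one MetO at P+1 -> 10 per 500 phosphosites
        proteins = ProteinSet([ProteinRecord(
            f"Q{i}", "AAAAAAAASMAAAAAAA") for i in range(50)])
        sites = [ModSite(f"Q{i}", 9, "S", "phospho") for i in range(50)]
        sites.append(ModSite("Q0", 10, "M", "sulfoxide", oxidized_fraction=0.5))
        profile = positional_profile(proteins, SiteTable.from_sites(sites), "S")
        frame = profile_frame(profile).set_index("offset")
        assert frame.loc[1, "metO_per_500"] == pytest.approx(10.0)
        assert frame.loc[1, "met_freq_percent"] == pytest.approx(100.0)
        assert frame.loc[-1, "met_freq_percent"] == 0.0

    def test_no_methionine_anywhere(self):
        proteins = ProteinSet([ProteinRecord("Q1", "AAAASAAAA")])
        sites = SiteTable.from_sites([ModSite("Q1", 5, "S", "phospho")])
        profile = positional_profile(proteins, sites, "S")
        assert np.all(profile.met_freq_percent == 0)
        assert np.all(profile.metO_per_500 == 0)

    def test_offset_counts_conserve_window_totals(self, sim_default):
        proteins, sites = sim_default
        profile = positional_profile(proteins, sites, "S")
        windows = build_window_counts(proteins, sites, "S")
        phospho = windows[windows["is_phosphosite"]]
        denoms = np.zeros(len(profile.offsets))
        # reconstruct counts from frequencies and offset-specific denominators
        total_from_profile = 0.0
        for j, off in enumerate(profile.offsets):
            # recompute the denominator: windows where the offset is in range
            total_from_profile += profile.met_freq_percent[j] / 100.0 * _denom(
                proteins, sites, off)
        assert total_from_profile == pytest.approx(phospho["n_met"].sum(), abs=0.5)

    def test_control_band_brackets_control_mean(self, sim_default):
        proteins, sites = sim_default
        profile = positional_profile(proteins, sites, "S")
        lo, hi = profile.control_band
        assert lo <= profile.control_freq_percent.mean() <= hi


def _denom(proteins, sites, offset):
    total = 0
    for protein in proteins:
        phospho = sites.positions(protein.accession, "phospho")
        if phospho.size == 0:
            continue
        pser = [p for p in phospho if protein.sequence[p - 1] == "S"]
        length = len(protein.sequence)
        total += sum(1 <= p + offset <= length for p in pser)
    return total
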