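"""Met and MetO content of +/-7 windows around phospho-acceptors.

A window is the 14 offsets -7..-1, +1..+7 around an acceptor (the centre is
excluded; it is S/T/Y, never Met); windows are truncated at the chain
termini.  The per-site statistic (mean methionines per site) is contrasted
against nulls built by resampling same-sized acceptor sets of the same
residue type regardless of phosphorylation status.  A methionine is counted
once per window even when it falls inside the windows of several acceptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ptm_tables import ProteinSet, SiteTable
from .stats_core import NullDistribution

OFFSETS = tuple(o for o in range(-7, 8) if o != 0)


@dataclass(frozen=True)
class WindowCount:
    accession: str
    acceptor_position: int
    acceptor_residue: str
    is_phosphosite: bool
    n_met: int
    n_metO: int


def count_window(sequence: str, center: int, met_positions, metO_positions,
                 halfwidth: int = 7) -> WindowCount:
    """Count Met and MetO within +/-halfwidth of one acceptor position."""
    length = len(sequence)
    if not 1 <= center <= length:
        raise ValueError(f"center {center} outside 1..{length}")
    met = np.asarray(sorted(met_positions), dtype=int)
    meto = np.asarray(sorted(metO_positions), dtype=int)

    def _count(arr: np.ndarray) -> int:
        if arr.size == 0:
            return 0
        lo = np.searchsorted(arr, center - halfwidth, side="left")
        hi = np.searchsorted(arr, center + halfwidth, side="right")
        n = int(hi - lo)
        # exclude the centre slot (cannot be Met for S/T/Y acceptors, but the
        # contract is offsets +/-1..halfwidth whatever the centre holds)
        if lo < hi and np.searchsorted(arr, center, side="left") < np.searchsorted(
                arr, center, side="right"):
            n -= 1
        return n

    n_met = _count(met)
    n_meto = _count(meto)
    return WindowCount("", center, sequence[center - 1], False, n_met, n_meto)


def build_window_counts(proteins: ProteinSet, sites: SiteTable,
                        residue: str, halfwidth: int = 7,
                        restrict_to_phosphoproteins: bool = True
                        ) -> pd.DataFrame:
    """WindowCount rows for every acceptor of one residue type.

    Returns a frame with columns accession, position, is_phosphosite, n_met,
    n_metO covering all acceptors (phosphorylated or not) of ``residue`` in
    the analysed proteins.
    """
    if residue not in "STY":
        raise ValueError("residue must be one of S, T, Y")
    rows = []
    for protein in proteins:
        phospho = sites.positions(protein.accession, "phospho")
        if restrict_to_phosphoproteins and phospho.size == 0:
            continue
        acceptors = protein.positions_of(residue)
        if acceptors.size == 0:
            continue
        mets = protein.positions_of("M")
        metos = sites.positions(protein.accession, "sulfoxide")
        phospho_set = set(phospho.tolist())
        n_met = _window_counts_vec(mets, acceptors, halfwidth)
        n_meto = _window_counts_vec(metos, acceptors, halfwidth)
        for pos, nm, no in zip(acceptors, n_met, n_meto):
            rows.append((protein.accession, int(pos), int(pos) in phospho_set,
                         int(nm), int(no)))
    return pd.DataFrame(rows, columns=["accession", "position",
                                       "is_phosphosite", "n_met", "n_metO"])


def _window_counts_vec(met: np.ndarray, centers: np.ndarray,
                       halfwidth: int) -> np.ndarray:
    if met.size == 0:
        return np.zeros(centers.size, dtype=int)
    hi = np.searchsorted(met, centers + halfwidth, side="right")
    lo = np.searchsorted(met, centers - halfwidth, side="left")
    return (hi - lo).astype(int)


def mean_per_site(windows: pd.DataFrame) -> tuple[float, float]:
    """Arithmetic means of n_met and n_metO over a window subset."""
    if len(windows) == 0:
        raise ValueError("empty window subset")
    return float(windows["n_met"].mean()), float(windows["n_metO"].mean())


def acceptor_null(windows: pd.DataFrame, n_phospho: int,
                  n_samples: int = 10_000, seed: int = 0,
                  statistic: str = "n_met",
                  method: str = "exact") -> NullDistribution:
    """Null distribution of the mean per-site count under acceptor resampling.

    ``windows`` must contain all acceptors of one residue type; each sample
    draws ``n_phospho`` of them uniformly without replacement (regardless of
    phosphorylation status) and records the mean of ``statistic``.

    The per-site counts are small integers, so the sample mean depends only
    on how many sites of each count value the sample picks up; the default
    ``method='exact'`` therefore draws those tallies from the corresponding
    multivariate hypergeometric — the same distribution as materializing the
    samples (``method='count'``), checked against it in the test suite.
    """
    if statistic not in ("n_met", "n_metO"):
        raise ValueError("statistic must be n_met or n_metO")
    counts = windows[statistic].to_numpy(dtype=float)
    if n_phospho > counts.size:
        raise ValueError("n_phospho exceeds the acceptor population")
    rng = np.random.default_rng(seed)
    if method == "exact":
        vals, tallies = np.unique(counts, return_counts=True)
        draws = rng.multivariate_hypergeometric(tallies, n_phospho,
                                                size=n_samples)
        values = draws @ vals / n_phospho
    elif method == "count":
        if n_samples * counts.size <= 40_000_000:
            order = np.argpartition(rng.random((n_samples, counts.size)),
                                    n_phospho - 1, axis=1)[:, :n_phospho]
            values = counts[order].mean(axis=1)
        else:
            values = np.array([
                counts[rng.choice(counts.size, n_phospho, replace=False)].mean()
                for _ in range(n_samples)])
    else:
        raise ValueError("method must be 'exact' or 'count'")
    return NullDistribution(values, f"mean_{statistic}_per_site", seed,
                            constraint=f"acceptor samples of {n_phospho}")


@dataclass
class PositionalProfile:
    """Per-offset Met frequency and MetO density around phosphosites.

    ``met_freq_percent[o]`` is the percentage of phosphosite windows with a
    methionine at offset ``o`` among windows where that offset exists;
    ``metO_per_500[o]`` is the number of oxidized methionines at offset ``o``
    per 500 phosphosites.  ``control_band`` is (mean - sd, mean + sd) of the
    14 per-offset control (non-phosphorylated acceptor) frequencies pooled
    across offsets; ``control_freq_percent`` keeps the per-offset values.
    """

    site_kind: str
    offsets: tuple[int, ...]
    met_freq_percent: np.ndarray
    metO_per_500: np.ndarray
    control_freq_percent: np.ndarray
    control_band: tuple[float, float]
    n_phospho_windows: int
    n_control_windows: int


def positional_profile(proteins: ProteinSet, sites: SiteTable,
                       residue: str, halfwidth: int = 7,
                       restrict_to_phosphoproteins: bool = True
                       ) -> PositionalProfile:
    """Positional Met/MetO profile around phosphosites of one residue type."""
    if residue not in "STY":
        raise ValueError("residue must be one of S, T, Y")
    offsets = tuple(o for o in range(-halfwidth, halfwidth + 1) if o != 0)
    n_off = len(offsets)
    met_hits = np.zeros(n_off)
    meto_hits = np.zeros(n_off)
    denom = np.zeros(n_off)
    ctrl_hits = np.zeros(n_off)
    ctrl_denom = np.zeros(n_off)
    n_phospho = 0
    n_control = 0

    for protein in proteins:
        phospho = sites.positions(protein.accession, "phospho")
        if restrict_to_phosphoproteins and phospho.size == 0:
            continue
        acceptors = protein.positions_of(residue)
        if acceptors.size == 0:
            continue
        length = len(protein.sequence)
        codes = np.frombuffer(protein.sequence.encode(), dtype=np.uint8)
        is_met = codes == ord("M")
        meto_mask = np.zeros(length + 1, dtype=bool)
        meto_mask[sites.positions(protein.accession, "sulfoxide")] = True

        is_p = np.isin(acceptors, phospho, assume_unique=True)
        centers_p = acceptors[is_p]
        centers_c = acceptors[~is_p]
        n_phospho += centers_p.size
        n_control += centers_c.size
        for j, off in enumerate(offsets):
            for centers, hits, den in ((centers_p, met_hits, denom),
                                       (centers_c, ctrl_hits, ctrl_denom)):
                if centers.size == 0:
                    continue
                tgt = centers + off
                ok = (tgt >= 1) & (tgt <= length)
                den[j] += int(ok.sum())
                hits[j] += int(is_met[tgt[ok] - 1].sum())
            if centers_p.size:
                tgt = centers_p + off
                ok = (tgt >= 1) & (tgt <= length)
                meto_hits[j] += int(meto_mask[tgt[ok]].sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        met_freq = np.where(denom > 0, 100.0 * met_hits / denom, 0.0)
        ctrl_freq = np.where(ctrl_denom > 0, 100.0 * ctrl_hits / ctrl_denom, 0.0)
    meto_per_500 = (500.0 * meto_hits / n_phospho if n_phospho
                    else np.zeros(n_off))
    band = (float(ctrl_freq.mean() - ctrl_freq.std(ddof=0)),
            float(ctrl_freq.mean() + ctrl_freq.std(ddof=0)))
    kind = {"S": "pSer", "T": "pThr", "Y": "pTyr"}[residue]
    return PositionalProfile(kind, offsets, met_freq, meto_per_500,
                             ctrl_freq, band, int(n_phospho), int(n_control))


def profile_frame(profile: PositionalProfile) -> pd.DataFrame:
    """Tidy per-offset view of a PositionalProfile."""
    return pd.DataFrame({
        "offset": profile.offsets,
        "met_freq_percent": profile.met_freq_percent,
        "metO_per_500": profile.metO_per_500,
        "control_freq_percent": profile.control_freq_percent,
    })
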