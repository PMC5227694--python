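"""Primary-structure proximity between methionines and phosphosites.

Distances are absolute differences of 1-based residue positions, not counts
of intervening residues.  Analyses are restricted to phosphoproteins (proteins
carrying at least one phosphosite), and a methionine enters a per-site-kind
comparison only when the protein has at least one site of that kind; those
exclusions are reported in a coverage log rather than coded as infinite
distances.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .ptm_tables import ProteinSet, SiteTable
from .stats_core import NullDistribution, empirical_p, welch_t

logger = logging.getLogger(__name__)

SITE_KINDS = ("pSer", "pThr", "pTyr", "any_pSite", "nonP_acceptor")

_KIND_RESIDUE = {"pSer": "S", "pThr": "T", "pTyr": "Y"}


def nearest_distance(pos: int, sites: Iterable[int]) -> int | None:
    """Distance from a position to the closest site, or None if no sites."""
    if pos < 1:
        raise ValueError("positions are 1-based")
    arr = np.asarray(sorted(sites), dtype=int)
    if arr.size == 0:
        return None
    i = int(np.searchsorted(arr, pos))
    candidates = []
    if i < arr.size:
        candidates.append(int(arr[i] - pos))
    if i > 0:
        candidates.append(int(pos - arr[i - 1]))
    return min(candidates)


def _site_positions(protein, phospho: np.ndarray, kind: str) -> np.ndarray:
    """Positions of the queried site kind on one protein."""
    if kind == "any_pSite":
        return phospho
    if kind == "nonP_acceptor":
        acceptors = protein.positions_of("STY")
        return np.setdiff1d(acceptors, phospho, assume_unique=True)
    residue = _KIND_RESIDUE[kind]
    keep = [p for p in phospho if protein.sequence[p - 1] == residue]
    return np.asarray(keep, dtype=int)


def build_distance_records(proteins: ProteinSet, sites: SiteTable,
                           kinds: Iterable[str] = SITE_KINDS,
                           restrict_to_phosphoproteins: bool = True
                           ) -> pd.DataFrame:
    """One row per (methionine x site kind) with the nearest-site distance.

    Columns: accession, met_position, met_oxidized, site_kind, distance.
    Methionine oxidation status comes from the (curated) sulfoxide rows of
    ``sites``.  Proteins lacking any site of a queried kind contribute no
    rows for that kind; the count of such exclusions is logged.
    """
    kinds = list(kinds)
    unknown = set(kinds) - set(SITE_KINDS)
    if unknown:
        raise ValueError(f"unknown site kind(s) {sorted(unknown)}")
    rows = []
    no_site_counts = {kind: 0 for kind in kinds}
    for protein in proteins:
        phospho = sites.positions(protein.accession, "phospho")
        if restrict_to_phosphoproteins and phospho.size == 0:
            continue
        mets = protein.positions_of("M")
        if mets.size == 0:
            continue
        oxidized = set(sites.positions(protein.accession, "sulfoxide").tolist())
        for kind in kinds:
            targets = _site_positions(protein, phospho, kind)
            if targets.size == 0:
                no_site_counts[kind] += 1
                continue
            # vectorized nearest distance for all Mets at once
            idx = np.searchsorted(targets, mets)
            right = np.where(idx < targets.size, targets[np.minimum(idx, targets.size - 1)] - mets,
                             np.iinfo(np.int64).max)
            left = np.where(idx > 0, mets - targets[np.maximum(idx - 1, 0)],
                            np.iinfo(np.int64).max)
            dist = np.minimum(right, left)
            for m, d in zip(mets, dist):
                rows.append((protein.accession, int(m), int(m) in oxidized,
                             kind, int(d)))
    for kind, count in no_site_counts.items():
        if count:
            logger.info("coverage: %d protein(s) had no %s sites", count, kind)
    return pd.DataFrame(rows, columns=["accession", "met_position",
                                       "met_oxidized", "site_kind", "distance"])


def proportion_within(distances, threshold: int = 7,
                      strict: bool = True) -> float:
    """Fraction of distances closer than ``threshold`` residues.

    ``strict=True`` implements "less than 7 residues away" as distance <= 6;
    set ``strict=False`` for the inclusive variant (distance <= threshold).
    """
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise ValueError("empty distance vector")
    return float((arr < threshold).mean() if strict else (arr <= threshold).mean())


def cluster_counts(met_positions: Iterable[int], phospho_positions: Iterable[int],
                   radius: int = 10) -> np.ndarray:
    """Number of phosphosites within ``radius`` residues of each methionine.

    The default interprets the neighbourhood as a radius (|delta| <= 10, a
    21-residue interval); pass ``radius=5`` for the half-window reading of a
    10-residue window.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mets = np.asarray(list(met_positions), dtype=int)
    targets = np.sort(np.asarray(list(phospho_positions), dtype=int))
    if mets.size == 0:
        return np.zeros(0, dtype=int)
    hi = np.searchsorted(targets, mets + radius, side="right")
    lo = np.searchsorted(targets, mets - radius, side="left")
    return (hi - lo).astype(int)


def cluster_histogram(records: pd.DataFrame, proteins: ProteinSet,
                      sites: SiteTable, radius: int = 10) -> pd.DataFrame:
    """Histogram of per-methionine phosphosite counts, split by oxidation.

    ``records`` is a distance-record frame (used for the Met list and
    oxidation flags); counts are recomputed from the phosphosite table.
    Returns a frame indexed by count with columns Met / MetO; each column
    sums to the number of methionines of that status.
    """
    per_met = records[["accession", "met_position", "met_oxidized"]].drop_duplicates()
    counts, flags = [], []
    for acc, grp in per_met.groupby("accession"):
        phospho = sites.positions(acc, "phospho")
        c = cluster_counts(grp["met_position"].to_numpy(), phospho, radius)
        counts.extend(c.tolist())
        flags.extend(grp["met_oxidized"].tolist())
    frame = pd.DataFrame({"count": counts, "oxidized": flags})
    hist = (frame.groupby(["count", "oxidized"]).size().unstack(fill_value=0)
            .rename(columns={False: "Met", True: "MetO"}))
    return hist.reindex(columns=["Met", "MetO"], fill_value=0)


def summarize_distances(records: pd.DataFrame, threshold: int = 7
                        ) -> dict[str, dict]:
    """Mean-distance and lower-tail comparisons of MetO vs Met per site kind.

    For each site kind present: Welch's t-test on the distances and the
    proportions of MetO / Met closer than ``threshold`` residues with the
    counts needed for a two-proportion test.
    """
    out: dict[str, dict] = {}
    for kind, grp in records.groupby("site_kind"):
        meto = grp.loc[grp["met_oxidized"], "distance"].to_numpy()
        met = grp.loc[~grp["met_oxidized"], "distance"].to_numpy()
        entry: dict = {"n_metO": int(meto.size), "n_met": int(met.size)}
        if meto.size:
            entry["mean_metO"] = float(meto.mean())
        if met.size:
            entry["mean_met"] = float(met.mean())
        if meto.size >= 2 and met.size >= 2:
            res = welch_t(meto, met)
            entry.update(welch_t=res.statistic, welch_p=res.p, welch_df=res.df)
        if meto.size >= 1 and met.size >= 1:
            entry.update(
                prop_within_metO=proportion_within(meto, threshold),
                prop_within_met=proportion_within(met, threshold),
                x_metO=int((meto < threshold).sum()),
                x_met=int((met < threshold).sum()),
            )
        out[str(kind)] = entry
    return out


def permutation_test_distances(distances, oxidized_flags, n_perm: int = 2000,
                               seed: int = 0) -> tuple[float, NullDistribution, float]:
    """Permutation test of mean(MetO distance) - mean(Met distance).

    Oxidation labels are permuted across methionines; the lower tail is used
    (oxidized methionines closer to phosphosites than expected by chance).
    Returns (observed difference, null, p).
    """
    d = np.asarray(list(distances), dtype=float)
    flags = np.asarray(list(oxidized_flags), dtype=bool)
    if d.shape != flags.shape:
        raise ValueError("distances and flags must align")
    n_ox = int(flags.sum())
    if n_ox == 0 or n_ox == flags.size:
        raise ValueError("need both oxidized and non-oxidized methionines")
    observed = float(d[flags].mean() - d[~flags].mean())
    rng = np.random.default_rng(seed)
    total = d.sum()
    n = d.size
    # the mean difference is a function of the oxidized-group sum only
    shuffled = rng.permuted(np.broadcast_to(d, (n_perm, n)), axis=1)
    s = shuffled[:, :n_ox].sum(axis=1)
    perm = s / n_ox - (total - s) / (n - n_ox)
    null = NullDistribution(perm, "mean_distance_diff", seed,
                            constraint="oxidation labels permuted")
    p, _ = empirical_p(null, observed, tail="lower")
    return observed, null, p
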