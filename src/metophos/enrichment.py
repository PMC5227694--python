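"""Term enrichment of a protein set against a background annotation table.

Upper-tail hypergeometric test with Bonferroni correction over the terms
actually tested (terms annotating no background protein are skipped and do
not enter the correction denominator).  Fold enrichment is the ratio of
proportions (k/n) / (K/N); a scale-dependent literal variant k/K is available
behind a flag.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

COLUMNS = ["term", "k", "K", "n", "N", "fold", "p_raw", "p_bonferroni"]


def load_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a GAF-like TSV (accession, term_id[, term_label]) into a mapping."""
    tab = pd.read_csv(path, sep="\t", comment="#",
                      dtype=str, header=0)
    cols = list(tab.columns)
    if len(cols) < 2:
        raise ValueError("annotation table needs at least two columns")
    acc_col, term_col = cols[0], cols[1]
    out: dict[str, set[str]] = {}
    for term, grp in tab.groupby(term_col):
        out[str(term)] = set(grp[acc_col])
    return out


def hypergeom_enrichment(test: Iterable[str], background: Iterable[str],
                         annotations: Mapping[str, Iterable[str]],
                         literal_fold: bool = False) -> pd.DataFrame:
    """Per-term enrichment table, sorted by raw p (ties by term id).

    For each term with K annotated background proteins, k of which are in the
    test set of size n drawn from a background of size N:
    ``p_raw = P(X >= k)`` for X hypergeometric(N, K, n), and
    ``p_bonferroni = min(1, p_raw * #terms tested)``.
    """
    test = set(test)
    background = set(background)
    if not test:
        raise ValueError("test set must be non-empty")
    if not test <= background:
        raise ValueError("test set must be a subset of the background")
    n, N = len(test), len(background)

    rows = []
    for term, accs in annotations.items():
        annotated = set(accs) & background
        K = len(annotated)
        if K == 0:
            continue  # untestable; excluded from the Bonferroni denominator
        k = len(annotated & test)
        p_raw = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / K) if literal_fold else (k / n) / (K / N)
        rows.append((str(term), k, K, n, N, fold, p_raw))
    n_tested = len(rows)
    frame = pd.DataFrame(rows, columns=COLUMNS[:7])
    frame["p_bonferroni"] = (frame["p_raw"] * n_tested).clip(upper=1.0)
    return (frame.sort_values(["p_raw", "term"], kind="mergesort")
            .reset_index(drop=True))
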