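"""End-to-end orchestration of the crosstalk analyses.

A run is described by a :class:`RunConfig` (typically read from YAML) naming
either input files or a simulation block, stage toggles, thresholds and a
single global seed.  Every stochastic stage draws its own sub-seed from the
global one and records it in the outputs, so any stage can be re-executed
independently.  The bundle written to the output directory is reproducible:
identical config and seed give byte-identical files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import cooccurrence_test
from .enrichment import hypergeom_enrichment, load_annotations
from .motif_class import class_frequencies, pser_subsets
from .proximity_seq import (build_distance_records, cluster_histogram,
                            summarize_distances)
from .ptm_tables import ProteinSet, SiteTable, curate_meto, load_proteome, load_sites
from .stats_core import empirical_p
from .structure_3d import (read_structures, spatial_distance_table,
                           ss_tabulation, structured_sequence_distances)
from .synthetic_data import SimConfig, simulate_proteome, simulate_structures
from .window_stats import (acceptor_null, build_window_counts, mean_per_site,
                           positional_profile, profile_frame)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
ALL_STAGES = ("cooccur", "proximity", "structure", "windows", "classify",
              "enrich")

_SUMMARY_REQUIRED = {"schema_version", "package_version", "seed", "stages"}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``inputs`` (paths: fasta, sites, optional abundance,
    structures/dssp directories, annotations) or ``simulate`` (SimConfig
    fields, optional ``structures: true``) must be given.
    """

    inputs: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    stages: tuple[str, ...] = ALL_STAGES
    min_fraction: float = 0.20
    distance_threshold: int = 7
    window_halfwidth: int = 7
    cluster_radius: int = 10
    n_samples: int = 10_000
    seed: int = 0
    out_dir: str = "metophos_out"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("give exactly one of 'inputs' or 'simulate'")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in [0, 1]")
        if min(self.distance_threshold, self.window_halfwidth,
               self.cluster_radius) < 1:
            raise ValueError("thresholds must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def validate_summary(summary: Mapping[str, Any]) -> None:
    missing = _SUMMARY_REQUIRED - set(summary)
    if missing:
        raise ValueError(f"summary missing key(s) {sorted(missing)}")
    if summary["schema_version"] != SCHEMA_VERSION:
        raise ValueError("summary schema_version mismatch")


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _overlap_entry(result) -> dict[str, Any]:
    return {
        "observed": result.observed_proportion,
        "p": result.p,
        "is_bound": bool(result.is_bound),
        "n_samples": result.null.n_samples,
        "seed": result.null.seed,
        "constraint": result.null.constraint,
    }


def stage_cooccurrence(proteins: ProteinSet, sites: SiteTable, outdir: Path,
                       n_samples: int, seed: int) -> dict[str, Any]:
    """Overlap of the sulfoxidized set with each other PTM, plain and matched."""
    target = sites.accessions_with("sulfoxide")
    if not target:
        return {"skipped": "no sulfoxidized proteins"}
    out: dict[str, Any] = {"n_target": len(target)}
    have_ab = [a for a in target if proteins[a].abundance is not None]
    seeds = np.random.SeedSequence(seed).generate_state(6) % (2 ** 31)
    for j, kind in enumerate(("phospho", "ubiquityl", "acetyl")):
        other = sites.accessions_with(kind)
        res = cooccurrence_test(proteins, target, other, n_samples,
                                seed=int(seeds[j]))
        entry = {"plain": _overlap_entry(res)}
        pd.Series(res.null.values).to_csv(
            outdir / f"null_overlap_{kind}.tsv", sep="\t", index=False,
            header=["null_value"])
        if len(have_ab) == len(target) and len(have_ab) >= 8:
            matched = cooccurrence_test(proteins, target, other, n_samples,
                                        seed=int(seeds[3 + j]), matched=True)
            entry["abundance_matched"] = _overlap_entry(matched)
        out[kind] = entry
    return out


def stage_proximity(proteins: ProteinSet, sites: SiteTable, outdir: Path,
                    threshold: int, radius: int) -> dict[str, Any]:
    records = build_distance_records(proteins, sites)
    if records.empty:
        return {"skipped": "no methionines on phosphoproteins"}
    records.to_csv(outdir / "distance_records.tsv", sep="\t", index=False)
    summary = summarize_distances(records, threshold)
    hist = cluster_histogram(records, proteins, sites, radius)
    hist.to_csv(outdir / "cluster_histogram.tsv", sep="\t")
    return {"site_kinds": summary, "cluster_radius": radius,
            "n_records": int(len(records))}


def stage_structure(structures, proteins: ProteinSet, sites: SiteTable,
                    outdir: Path, threshold: int) -> dict[str, Any]:
    spatial, report = spatial_distance_table(structures, proteins, sites)
    spatial.to_csv(outdir / "spatial_distances.tsv", sep="\t", index=False)
    seq_records = structured_sequence_distances(structures, proteins, sites)
    summary = summarize_distances(seq_records, threshold) if len(seq_records) else {}
    ss = ss_tabulation(structures, proteins, sites)
    ss.to_csv(outdir / "secondary_structure.tsv", sep="\t")
    entry: dict[str, Any] = {
        "n_structures": len(structures),
        "exclusions": report,
        "sequence_distance_summary": summary,
    }
    meto = spatial.loc[spatial["met_oxidized"], "spatial_distance"]
    met = spatial.loc[~spatial["met_oxidized"], "spatial_distance"]
    if len(meto) >= 2 and len(met) >= 2:
        from .stats_core import welch_t
        res = welch_t(meto, met)
        entry["spatial"] = {"mean_metO": float(meto.mean()),
                            "mean_met": float(met.mean()),
                            "welch_p": res.p}
    return entry


def stage_windows(proteins: ProteinSet, sites: SiteTable, outdir: Path,
                  halfwidth: int, n_samples: int, seed: int) -> dict[str, Any]:
    out: dict[str, Any] = {}
    seeds = np.random.SeedSequence(seed).generate_state(6) % (2 ** 31)
    for j, residue in enumerate("STY"):
        windows = build_window_counts(proteins, sites, residue, halfwidth)
        if windows.empty:
            continue
        windows.to_csv(outdir / f"window_counts_{residue}.tsv", sep="\t",
                       index=False)
        phospho = windows[windows["is_phosphosite"]]
        entry: dict[str, Any] = {"n_acceptors": int(len(windows)),
                                 "n_phosphosites": int(len(phospho))}
        if len(phospho):
            mean_met, mean_meto = mean_per_site(phospho)
            entry["mean_met_per_site"] = mean_met
            entry["mean_metO_per_site"] = mean_meto
            for stat, observed in (("n_met", mean_met), ("n_metO", mean_meto)):
                null = acceptor_null(windows, len(phospho), n_samples,
                                     seed=int(seeds[2 * j]), statistic=stat)
                up, bound_up = empirical_p(null, observed, "upper")
                lo, bound_lo = empirical_p(null, observed, "lower")
                entry[f"p_upper_{stat}"] = up
                entry[f"p_lower_{stat}"] = lo
                entry[f"is_bound_{stat}"] = bool(bound_up or bound_lo)
            profile = positional_profile(proteins, sites, residue, halfwidth)
            profile_frame(profile).to_csv(
                outdir / f"positional_profile_{residue}.tsv", sep="\t",
                index=False)
            entry["control_band"] = list(profile.control_band)
        out[residue] = entry
    return out


def stage_classify(proteins: ProteinSet, sites: SiteTable,
                   outdir: Path, halfwidth: int) -> dict[str, Any]:
    subsets = pser_subsets(proteins, sites, halfwidth)
    if not subsets:
        return {"skipped": "no phosphoserine windows"}
    freqs = class_frequencies(subsets)
    freqs.to_csv(outdir / "kinase_class_frequencies.tsv", sep="\t")
    return {"subset_sizes": {k: len(v) for k, v in subsets.items()},
            "frequencies": {k: dict(row) for k, row in freqs.iterrows()}}


def stage_enrichment(proteins: ProteinSet, sites: SiteTable,
                     annotations_path: str | Path, outdir: Path,
                     halfwidth: int) -> dict[str, Any]:
    """Enrichment of pSer proteins with MetO at P+1/P+4 vs all phosphoproteins."""
    sulf = sites.by_kind("sulfoxide")
    phospho = sites.by_kind("phospho")
    pser = phospho[phospho["residue"] == "S"]
    test: set[str] = set()
    for acc, grp in pser.groupby("accession"):
        metos = set(sulf.loc[sulf["accession"] == acc, "position"])
        for pos in grp["position"]:
            if pos + 1 in metos or pos + 4 in metos:
                test.add(acc)
                break
    background = sites.accessions_with("phospho")
    if not test:
        return {"skipped": "no pSer with MetO at P+1/P+4"}
    table = hypergeom_enrichment(test, background, load_annotations(annotations_path))
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    sig = table[table["p_bonferroni"] < 0.05]
    return {"n_test": len(test), "n_background": len(background),
            "n_terms_tested": int(len(table)),
            "n_significant": int(len(sig))}


def run_pipeline(config: RunConfig, outdir: str | Path | None = None
                 ) -> dict[str, Any]:
    """Run the configured stages and write the report bundle.

    Returns the summary dict (also written to ``summary.json``).  A stage
    whose inputs are unavailable is skipped with a note; a stage whose
    preconditions fail aborts with a stage-named error.
    """
    outdir = Path(outdir if outdir is not None else config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2 ** 31)

    structures = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        want_structures = bool(sim_kwargs.pop("structures", False))
        sim_kwargs.setdefault("seed", int(seeds[0]))
        sim = SimConfig(**sim_kwargs)
        proteins, sites = simulate_proteome(sim)
        if want_structures:
            structures = simulate_structures(proteins, seed=int(seeds[1]))
        data_note = {"source": "simulation", "n_proteins": len(proteins),
                     "sim_seed": sim.seed}
    else:
        paths = config.inputs or {}
        if "fasta" not in paths or "sites" not in paths:
            raise ValueError("inputs must provide 'fasta' and 'sites'")
        proteins = load_proteome(paths["fasta"], paths.get("abundance"))
        sites = load_sites(paths["sites"], proteins)
        if "pdb" in paths:
            pdbs = sorted(Path(paths["pdb"]).glob("*.pdb"))
            dssps = sorted(Path(paths["dssp"]).glob("*.dssp")) if "dssp" in paths else []
            structures = read_structures(pdbs, dssps, proteins,
                                         paths.get("mapping"))
        data_note = {"source": "files", "n_proteins": len(proteins)}

    sites = curate_meto(sites, config.min_fraction)
    data_note["n_sites_after_curation"] = len(sites)

    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "n_samples": config.n_samples,
        "data": data_note,
        "stages": {},
    }

    runners = {
        "cooccur": lambda: stage_cooccurrence(proteins, sites, outdir,
                                              config.n_samples, int(seeds[2])),
        "proximity": lambda: stage_proximity(proteins, sites, outdir,
                                             config.distance_threshold,
                                             config.cluster_radius),
        "structure": lambda: (stage_structure(structures, proteins, sites,
                                              outdir, config.distance_threshold)
                              if structures is not None
                              else {"skipped": "no structures provided"}),
        "windows": lambda: stage_windows(proteins, sites, outdir,
                                         config.window_halfwidth,
                                         config.n_samples, int(seeds[3])),
        "classify": lambda: stage_classify(proteins, sites, outdir,
                                           config.window_halfwidth),
        "enrich": lambda: (stage_enrichment(
            proteins, sites, (config.inputs or {}).get("annotations"),
            outdir, config.window_halfwidth)
            if config.inputs and config.inputs.get("annotations")
            else {"skipped": "no annotation table provided"}),
    }
    for stage in config.stages:
        start = time.perf_counter()
        try:
            summary["stages"][stage] = runners[stage]()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", stage,
                    time.perf_counter() - start)

    validate_summary(summary)
    _dump_json(summary, outdir / "summary.json")
    return summary
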