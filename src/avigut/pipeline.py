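"""End-to-end orchestration of the analysis stages.

Stage order respects the data dependencies: (simulate | load) -> species
refinement -> rank aggregation / relative abundance -> rarefied alpha
diversity -> Bray-Curtis / PCoA / PERMANOVA -> core & Venn -> variable
network -> qPCR quantification.  A single master seed fans out to
per-stage substreams so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as avio
from .abundance import aggregate_by_rank, to_relative
from .beta import bray_curtis, pcoa, permanova
from .core import compute_cores
from .diversity import DEFAULT_DEPTH, DEFAULT_ITERATIONS, rarefied_alpha
from .io import FormatError
from .network import build_network, variable_profiles
from .qpcr import estimate_copies, fit_standard_curve
from .refine import RefinementParams, refine_species
from .simulate import (GeneratorConfig, QpcrSimConfig, default_template,
                       generate_blast_hits, generate_dataset, generate_qpcr)

log = logging.getLogger("avigut")

_STAGES = ("data", "refine", "abundance", "alpha", "beta", "core",
           "network", "qpcr")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML, overridable by flags."""

    outdir: str = "avigut_out"
    seed: int = 0
    simulate: bool = True
    # input paths (non-simulation mode)
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    blast_path: str | None = None
    fasta_path: str | None = None
    qpcr_path: str | None = None
    # analysis parameters
    rank: str = "genus"
    depth: int = DEFAULT_DEPTH
    iterations: int = DEFAULT_ITERATIONS
    permutations: int = 999
    network_cutoff: float = 0.6
    core_groupings: tuple[tuple[str, ...], ...] = (("segment",),
                                                   ("segment", "age_days"))
    refinement: RefinementParams = field(default_factory=RefinementParams)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qpcr_sim: QpcrSimConfig = field(default_factory=QpcrSimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, sub in (("refinement", RefinementParams),
                         ("generator", GeneratorConfig),
                         ("qpcr_sim", QpcrSimConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "core_groupings" in raw:
            raw["core_groupings"] = tuple(tuple(g) for g in raw["core_groupings"])
        return cls(**raw)


def _substream(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    import zlib
    return int(np.random.default_rng(
        [master_seed, zlib.crc32(stage.encode())]).integers(0, 2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing a deterministic directory layout.

    Returns the run manifest (also written to `manifest.json`).  A stage
    failure raises after recording earlier stages' outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "rank": config.rank, "depth": config.depth,
            "iterations": config.iterations,
            "permutations": config.permutations,
            "network_cutoff": config.network_cutoff,
            "core_groupings": [list(g) for g in config.core_groupings],
        },
        "stages": {},
    }

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        log.info("stage %s: ok %s", stage, info or "")

    try:
        # ---- data ----
        if config.simulate:
            gen = dataclasses.replace(config.generator,
                                      seed=_substream(config.seed, "simulate"))
            counts, taxonomy, meta = generate_dataset(default_template(), gen)
            hits, truth = generate_blast_hits(
                taxonomy, gen,
                np.random.default_rng(_substream(config.seed, "blast")))
            standards, unknowns = generate_qpcr(
                config.qpcr_sim,
                np.random.default_rng(_substream(config.seed, "qpcr_sim")))
            avio.write_count_table(counts, out / "counts.tsv")
            avio.write_taxonomy(taxonomy, out / "taxonomy.tsv")
            avio.write_metadata(meta, out / "metadata.csv")
            truth.to_csv(out / "blast_truth.tsv", sep="\t",
                         header=["branch"], index_label="taxon_id")
            standards.to_csv(out / "qpcr_standards.csv", index=False)
            unknowns.to_csv(out / "qpcr_unknowns.csv", index=False)
        else:
            for name, p in (("counts", config.counts_path),
                            ("taxonomy", config.taxonomy_path),
                            ("metadata", config.metadata_path)):
                if p is None or not Path(p).exists():
                    raise FormatError(f"missing {name} file: {p}")
            counts = avio.read_count_table(config.counts_path)
            taxonomy = avio.read_taxonomy(config.taxonomy_path)
            meta = avio.read_metadata(config.metadata_path)
            hits = None
            if config.blast_path:
                if config.fasta_path is None:
                    raise FormatError(
                        "blast input requires a FASTA for query lengths")
                lengths = avio.read_fasta_lengths(config.fasta_path)
                hits = avio.read_blast_tabular(config.blast_path, lengths)
            standards = unknowns = None
            if config.qpcr_path:
                qdf = pd.read_csv(config.qpcr_path)
                standards = qdf[qdf["role"] == "standard"]
                unknowns = qdf[qdf["role"] == "unknown"]
        meta.require_samples(counts.sample_ids)
        done("data", n_samples=len(counts.sample_ids),
             n_taxa=len(counts.taxon_ids))

        # ---- refine ----
        if hits is not None and len(hits):
            taxonomy, refine_log = refine_species(taxonomy, hits,
                                                  config.refinement)
            refine_log.to_csv(out / "refinement_log.tsv", sep="\t", index=False)
            n_assigned = int((refine_log["outcome"] == "assigned").sum())
        else:
            refine_log, n_assigned = None, 0
        avio.write_taxonomy(taxonomy, out / "taxonomy_refined.tsv")
        done("refine", assigned=n_assigned)

        # ---- abundance ----
        rank_counts = aggregate_by_rank(counts, taxonomy, config.rank)
        rel = to_relative(rank_counts)
        avio.write_count_table(rank_counts, out / f"counts_{config.rank}.tsv")
        avio.write_matrix(rel.df, out / f"relabund_{config.rank}.tsv",
                          index_label="taxon_id")
        done("abundance", rank=config.rank, n_taxa=len(rank_counts.taxon_ids))

        # ---- alpha ----
        alpha = rarefied_alpha(rank_counts, depth=config.depth,
                               iterations=config.iterations,
                               seed=_substream(config.seed, "alpha"))
        avio.write_matrix(alpha.table, out / "alpha.tsv",
                          index_label="sample_id")
        done("alpha", depth=alpha.depth, iterations=alpha.n_iterations)

        # ---- beta ----
        dm = bray_curtis(rel)
        ordination = pcoa(dm)
        beta_summary = {}
        for factor in ("segment", "age_days"):
            res = permanova(dm, meta.groups([factor]),
                            n_permutations=config.permutations,
                            seed=_substream(config.seed, f"permanova_{factor}"))
            beta_summary[factor] = {
                "pseudo_F": res.pseudo_f, "R2": res.r_squared,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        avio.write_matrix(dm.to_data_frame(), out / "bray_curtis.tsv",
                          index_label="sample_id")
        avio.write_matrix(ordination.coordinates, out / "pcoa.tsv",
                          index_label="sample_id")
        avio.write_json(beta_summary, out / "permanova.json")
        done("beta", **{f"R2_{k}": round(v["R2"], 4)
                        for k, v in beta_summary.items()})

        # ---- core ----
        for factors in config.core_groupings:
            groups = meta.groups(list(factors)).loc[rel.sample_ids]
            result = compute_cores(rel, groups)
            tag = "_".join(factors)
            if result.regions:
                avio.write_venn(result.regions, out / f"venn_{tag}.tsv")
            avio.write_json(
                {"threshold": result.threshold,
                 "retained": sorted(result.retained),
                 "cores": {g: sorted(c) for g, c in result.cores.items()}},
                out / f"core_{tag}.json")
        done("core", groupings=[list(g) for g in config.core_groupings])

        # ---- network ----
        profiles = variable_profiles(rel, meta)
        net = build_network(profiles, cutoff=config.network_cutoff)
        avio.write_network(net, out / "network_edges.tsv",
                           out / "network_nodes.tsv")
        done("network", n_edges=net.graph.number_of_edges())

        # ---- qpcr ----
        if standards is not None and len(standards):
            curve = fit_standard_curve(standards["log10_copies"],
                                       standards["ct"])
            quant = estimate_copies(curve, unknowns)
            avio.write_json(
                {"slope": curve.slope, "intercept": curve.intercept,
                 "r_squared": curve.r_squared,
                 "efficiency_percent": 100 * curve.efficiency,
                 "dynamic_range": curve.dynamic_range},
                out / "qpcr_curve.json")
            avio.write_matrix(quant, out / "qpcr_quant.tsv",
                              index_label="sample_id")
            done("qpcr", r_squared=round(curve.r_squared, 4))
        else:
            manifest["stages"]["qpcr"] = {"status": "skipped"}
    except Exception:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.exception("pipeline failed after stages: %s",
                      list(manifest["stages"]))
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
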