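"""End-to-end orchestration: cohort -> sites -> networks -> comparisons -> bundle.

``run_pipeline`` chains every stage on either a real input triplet
(aligned FASTA, metadata TSV, annotation TSV) or a synthetic cohort, and
writes a report bundle of flat artifacts (TSV / GraphML / Newick / JSON)
under one output directory, together with a machine-readable run manifest
(seed, config hash, package and library versions) sufficient to reproduce
the bundle bit-for-bit.

Seed policy: every stochastic stage derives its seed from the single run
seed — the synthetic generator uses the seed itself, and the null ensemble
of altitude group g uses ``(seed + 100 + g) mod 2**31``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import AlignedCohort, GroupScheme, read_alignment
from .annotation import GenomeAnnotation, rcrs_annotation, RCRS_LENGTH
from .categorize import categorize_nodes, local_pair_fraction, NodeCatalog
from .compare import (
    all_proportion_tests,
    group_node_sets,
    jaccard_matrix,
    similarity_dendrogram,
)
from .cooccurrence import GroupContext, MasterNetwork, average_degree, build_master_network
from .errors import MtcoocError, ConfigurationError
from .genenet import build_gene_network
from .nulls import deviating_gene_pairs, null_gene_ensemble
from .sites import site_statistics, sites_to_frame
from .synthetic import SynthConfig, generate_cohort, toy_annotation, write_fixture

log = logging.getLogger("mtcooc")


class PipelineError(MtcoocError, RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-loadable."""

    outdir: Path = Path("mtcooc_run")
    fasta: Path | None = None
    metadata: Path | None = None
    annotation: Path | None = None  # TSV path, or None for the embedded rCRS table
    reference_id: str | None = None
    synthetic: SynthConfig | None = None
    c_th: float = 1.0
    altitude_bins: tuple[float, ...] = GroupScheme().boundaries
    null_replicates: int = 100
    seed: int = 0
    jaccard_nodes: str = "connected"  # or "all"
    jaccard_exclude_global: bool = False
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_th <= 1.0:
            raise ConfigurationError(f"C_th {self.c_th} outside [0, 1]")
        if self.synthetic is None and (self.fasta is None or self.metadata is None):
            raise ConfigurationError(
                "either a synthetic config or FASTA + metadata paths are required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        if synth is not None:
            synth = SynthConfig(**synth)
        for key in ("outdir", "fasta", "metadata", "annotation"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "altitude_bins" in raw:
            raw["altitude_bins"] = tuple(raw["altitude_bins"])
        return cls(synthetic=synth, **raw)

    def config_hash(self) -> str:
        def default(obj):
            if isinstance(obj, Path):
                return str(obj)
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            return repr(obj)

        fields = dataclasses.asdict(self)
        fields.pop("outdir", None)  # the output location is not part of the run identity
        payload = json.dumps(fields, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def null_seed(run_seed: int, group: int) -> int:
    """Documented per-stage seed derivation for group null ensembles."""
    return (run_seed + 100 + group) % 2**31


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort, manifest = generate_cohort(synth)
        write_fixture(cohort, manifest, outdir / "fixture")
        annotation = toy_annotation(synth.genome_length)
        return cohort, annotation, manifest
    scheme = GroupScheme(boundaries=config.altitude_bins)
    cohort = read_alignment(
        config.fasta, config.metadata, scheme, reference_id=config.reference_id
    )
    if config.annotation is not None:
        length = int(max(cohort.column_to_ref))
        annotation = GenomeAnnotation.from_tsv(config.annotation, length)
    else:
        annotation = rcrs_annotation()
        if int(max(cohort.column_to_ref)) > RCRS_LENGTH:
            raise ConfigurationError(
                "alignment longer than the rCRS; supply a matching annotation TSV"
            )
    return cohort, annotation, None


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run every stage and write the report bundle; returns in-memory results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    stage = "load-inputs"
    try:
        cohort, annotation, manifest = _load_inputs(config, outdir)
        results["cohort"], results["annotation"] = cohort, annotation
        results["truth_manifest"] = manifest
        groups = cohort.group_labels
        log.info("stage %s: %d samples, %d groups", stage, cohort.n_samples, len(groups))

        stage = "extract-variants"
        contexts: dict[int, GroupContext] = {}
        masters: dict[int, MasterNetwork] = {}
        stats_rows = []
        site_frames = []
        for g in groups:
            ctx, master = build_master_network(
                cohort, g, c_th=config.c_th, annotation=annotation
            )
            contexts[g], masters[g] = ctx, master
            st = site_statistics(ctx.sites, annotation)
            stats_rows.append(
                {
                    "group": g,
                    "n_variable_sites": st.n_variable_sites,
                    "n_coding": st.n_coding,
                    "n_noncoding": st.n_noncoding,
                    "n_transitions": st.n_transitions,
                    "n_transversions": st.n_transversions,
                    "ts_tv_ratio": st.ts_tv_ratio,
                    "n_triallelic": st.n_triallelic,
                    "n_quadallelic": st.n_quadallelic,
                }
            )
            site_frames.append(sites_to_frame(ctx.sites, g))
        site_stats = pd.DataFrame(stats_rows)
        site_stats.to_csv(outdir / "site_stats.tsv", sep="\t", index=False)
        pd.concat(site_frames).to_csv(outdir / "variable_sites.tsv", sep="\t", index=False)
        results["site_stats"] = site_stats
        results["masters"] = masters

        stage = "build-network"
        for g, master in masters.items():
            master.write_tsv(outdir / f"master_group{g}.tsv")
            master.write_graphml(outdir / f"master_group{g}.graphml")

        stage = "categorize"
        catalog = categorize_nodes(masters)
        results["catalog"] = catalog
        catalog.to_frame().to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        summary = catalog.summary()
        summary["nc"] = [masters[g].n_edges for g in catalog.groups]
        summary["mean_degree_all"] = [
            average_degree(masters[g], "all") for g in catalog.groups
        ]
        summary["mean_degree_connected"] = [
            average_degree(masters[g], "connected")
            if masters[g].connected_nodes() else float("nan")
            for g in catalog.groups
        ]
        summary["local_pair_pct"] = [
            local_pair_fraction(catalog, masters[g]) for g in catalog.groups
        ]
        summary.to_csv(outdir / "catalog_summary.tsv", sep="\t", index=False)
        (outdir / "catalog_summary.json").write_text(
            summary.to_json(orient="records", indent=1)
        )
        results["catalog_summary"] = summary

        stage = "gene-network"
        gene_nets = {g: build_gene_network(masters[g], annotation) for g in groups}
        results["gene_networks"] = gene_nets
        for g, net in gene_nets.items():
            net.write_tsv(outdir / f"gene_network_group{g}.tsv")
            net.write_graphml(outdir / f"gene_network_group{g}.graphml")

        stage = "null-compare"
        deviation_frames = []
        for g in groups:
            ensemble = null_gene_ensemble(
                cohort, g, annotation,
                n_replicates=config.null_replicates,
                seed=null_seed(config.seed, g),
                c_th=config.c_th,
                ctx=contexts[g],
            )
            deviation_frames.append(deviating_gene_pairs(gene_nets[g], ensemble))
        non_empty = [f for f in deviation_frames if not f.empty]
        deviations = (
            pd.concat(non_empty, ignore_index=True)
            if non_empty else deviation_frames[0]
        )
        deviations.to_csv(outdir / "null_deviations.tsv", sep="\t", index=False)
        results["null_deviations"] = deviations

        stage = "group-compare"
        ztests = all_proportion_tests(catalog)
        ztests.to_csv(outdir / "ztests.tsv", sep="\t", index=False)
        results["ztests"] = ztests
        node_sets = group_node_sets(
            catalog,
            node_set=config.jaccard_nodes,
            exclude_global=config.jaccard_exclude_global,
        )
        jac = jaccard_matrix(node_sets)
        jac.to_csv(outdir / "jaccard.tsv", sep="\t")
        sim = similarity_dendrogram(jac, linkage_method=config.linkage)
        (outdir / "dendrogram.nwk").write_text(sim.newick + "\n")
        results["jaccard"] = jac
        results["similarity"] = sim

        stage = "run-manifest"
        run_manifest = {
            "package": "mtcooc",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "c_th": config.c_th,
            "null_replicates": config.null_replicates,
            "groups": groups,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=1, sort_keys=True)
        )
        results["run_manifest"] = run_manifest
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
    return results
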