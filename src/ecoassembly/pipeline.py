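"""End-to-end orchestration: filter -> rarefy -> alpha -> beta/ordination ->
group tests -> null-model partition, with every intermediate written to disk.

Each stage writes plain TSV artifacts into the output directory and the run
manifest (``manifest.json``) records the resolved configuration, seed, input
checksums, per-stage wall time, and collected warnings, so a run can be
audited and reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly_inference import assembly_pair_stats, partition_processes
from .community_structure import (
    anosim,
    bray_curtis,
    covariate_distance,
    mantel,
    nmds,
    pcoa,
    shared_taxa,
    simper,
    unweighted_unifrac,
)
from .diversity import alpha_table
from .synthetic_community import ScenarioConfig, simulate_scenario
from .tables_io import (
    ZotuTable,
    align_table_tree,
    filter_min_count,
    rarefy,
    read_metadata,
    read_tree,
    read_zotu_table,
    write_metadata,
    write_tree,
    write_zotu_table,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one analysis run."""

    table_path: str
    metadata_path: str
    tree_path: str | None = None
    output_dir: str = "ecoassembly_out"
    min_total_count: int = 4
    rarefaction_depth: int | None = None  # None = minimum sample total
    n_null: int = 999
    n_permutations: int = 9999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    group_column: str = "habitat"
    mantel_covariates: tuple = ()
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")
        if self.rarefaction_depth is not None and self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be > 0")
        for name in ("n_null", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        return self


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_dm(dm, path):
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)) \
        .rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")


def run_synthetic(scenario: ScenarioConfig, output_dir) -> dict:
    """Generate a synthetic dataset bundle consumable by ``run_analysis``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, tree, metadata, truth = simulate_scenario(scenario)
    write_zotu_table(table, out / "table.tsv")
    write_tree(tree, out / "tree.nwk")
    write_metadata(metadata, out / "metadata.tsv")
    truth.to_frame().to_csv(out / "ground_truth_samples.tsv", sep="\t")
    truth.taxon_trait.rename_axis("taxon_id").to_csv(
        out / "ground_truth_traits.tsv", sep="\t"
    )
    manifest = {
        "kind": "synthetic_dataset",
        "version": __version__,
        "seed": scenario.seed,
        "scenario": asdict(scenario),
        "files": {
            name: _sha256(out / name)
            for name in ("table.tsv", "tree.nwk", "metadata.tsv")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_analysis(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    config = config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "kind": "analysis_run",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "warnings": [],
        "inputs": {},
    }
    collected: list[str] = []

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.ctx = warnings.catch_warnings(record=True)
                self_inner.records = self_inner.ctx.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.ctx.__exit__(None, None, None)
                for w in self_inner.records:
                    collected.append(f"{name}: {w.message}")
                manifest["stages"][name] = round(
                    time.perf_counter() - self_inner.t0, 4
                )
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    # --- load -------------------------------------------------------------
    with stage("load"):
        table = read_zotu_table(config.table_path)
        metadata = read_metadata(config.metadata_path)
        manifest["inputs"]["table"] = _sha256(config.table_path)
        manifest["inputs"]["metadata"] = _sha256(config.metadata_path)
        tree = None
        if config.tree_path:
            tree = read_tree(config.tree_path)
            manifest["inputs"]["tree"] = _sha256(config.tree_path)
        missing = set(table.sample_ids) - set(metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:10]}")
        if tree is None:
            raise ValueError(
                "a rooted tree with branch lengths is required for "
                "phylogenetic diversity, UniFrac, and betaNTI"
            )

    # --- filter + rarefy ----------------------------------------------------
    with stage("filter"):
        table = filter_min_count(table, config.min_total_count)
        write_zotu_table(table, out / "table_filtered.tsv")
    with stage("rarefy"):
        depth = config.rarefaction_depth or int(table.sample_totals.min())
        manifest["rarefaction_depth"] = depth
        table = rarefy(table, depth, seed=config.seed)
        table, tree = align_table_tree(table, tree)
        write_zotu_table(table, out / "table_rarefied.tsv")
        metadata = metadata.loc[table.sample_ids]
        groups = metadata[config.group_column]

    # --- alpha -------------------------------------------------------------
    with stage("alpha"):
        alpha = alpha_table(table, tree)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t",
                     float_format="%.10g")

    # --- beta + ordination ---------------------------------------------------
    with stage("beta"):
        bc = bray_curtis(table)
        _write_dm(bc, out / "bray_curtis.tsv")
        uf = unweighted_unifrac(table, tree)
        _write_dm(uf, out / "unweighted_unifrac.tsv")
    with stage("ordination"):
        nm = nmds(bc, k=2, seed=config.seed)
        nm.coordinates.rename_axis("sample_id").to_csv(
            out / "nmds_coordinates.tsv", sep="\t", float_format="%.10g"
        )
        pc = pcoa(uf)
        pc.coordinates.rename_axis("sample_id").to_csv(
            out / "pcoa_coordinates.tsv", sep="\t", float_format="%.10g"
        )
        ordination_stats = {
            "nmds_stress": nm.stress,
            "nmds_converged": nm.converged,
            "pcoa_eigenvalues": [float(e) for e in pc.eigenvalues],
            "pcoa_negative_eigenvalue_magnitudes":
                [float(e) for e in pc.negative_eigenvalues],
        }
        (out / "ordination_stats.json").write_text(
            json.dumps(ordination_stats, indent=2)
        )

    # --- group statistics -----------------------------------------------------
    with stage("group_tests"):
        res = anosim(bc, groups, n_permutations=config.n_permutations,
                     seed=config.seed)
        tests = [{
            "test": "anosim", "distance": "bray_curtis",
            "grouping": config.group_column, "statistic": res.statistic,
            "p_value": res.p_value, "n_permutations": res.n_permutations,
            "exact": res.exact,
        }]
        for cov in config.mantel_covariates:
            cd = covariate_distance(metadata[cov], ids=bc.ids)
            mres = mantel(cd, bc, n_permutations=config.n_permutations,
                          seed=config.seed)
            tests.append({
                "test": "mantel", "distance": "bray_curtis",
                "grouping": cov, "statistic": mres.statistic,
                "r_squared": mres.r_squared, "p_value": mres.p_value,
                "n_permutations": mres.n_permutations, "exact": mres.exact,
            })
        pd.DataFrame(tests).to_csv(out / "group_tests.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        labels = sorted(groups.unique())
        if len(labels) == 2:
            records, overall = simper(table, groups)
            records.to_csv(out / "simper.tsv", sep="\t",
                           float_format="%.10g")
            venn = shared_taxa(table, groups)
            pd.DataFrame(
                [{"region": "+".join(k), "n_taxa": v}
                 for k, v in sorted(venn.items())]
            ).to_csv(out / "shared_taxa.tsv", sep="\t", index=False)
            manifest["simper_overall_dissimilarity"] = overall

    # --- assembly processes ---------------------------------------------------
    with stage("assembly"):
        pair_stats = assembly_pair_stats(
            table, tree, n_null_bnti=config.n_null,
            n_null_rc=config.n_null, seed=config.seed,
        )
        pair_stats.to_csv(out / "assembly_pair_stats.tsv", sep="\t",
                          index=False, float_format="%.10g")
        part = partition_processes(
            pair_stats, groups, bnti_threshold=config.bnti_threshold,
            rc_threshold=config.rc_threshold, include_between=True,
        )
        part.to_csv(out / "assembly_partition.tsv", sep="\t",
                    float_format="%.10g")
        # per size-fraction partitions within each habitat
        if "size_fraction" in metadata.columns:
            combo = groups.astype(str) + ":" + metadata["size_fraction"].astype(str)
            part_sf = partition_processes(
                pair_stats, combo, bnti_threshold=config.bnti_threshold,
                rc_threshold=config.rc_threshold,
            )
            part_sf.to_csv(out / "assembly_partition_by_fraction.tsv",
                           sep="\t", float_format="%.10g")

    manifest["warnings"] = collected
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
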