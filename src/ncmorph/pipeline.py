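"""End-to-end orchestration of the delimitation and mimicry analysis.

``run_full`` reproduces the whole workflow on one specimen table (and,
optionally, one site table): nest centroids -> Ward clustering and the two
partitioning routes -> wild-card resolution by confirmative stepwise LDA ->
final discriminant with error rates -> allometry fitting and RAV correction ->
correlation-matrix PCA with hull overlap -> per-character t-test table ->
latitude correlation -> co-occurrence association tests. Every artifact is
written to the report directory together with a manifest (inputs, seed,
config, versions, output hashes) that is identical across reruns with the
same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import fit_species_pooled, printed_parameters, rav_correct_table
from .biogeo import table3_report
from .discrim import (StepwiseConfig, error_rates, iterate_confirmative,
                      pearson_with_latitude, ttest_table)
from .morphodata import CHARACTERS, compute_indices, nest_centroids, read_specimen_table
from .ncpart import PartitionConfig, run_partitioning, ward_tree
from .ordination import PCA_INDICES, hull_overlap, pca_correlation, plot_scores


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialisable to/from YAML."""

    specimens: str | None = None          # CSV path; None -> synthetic
    sites: str | None = None              # CSV path of site records
    out_dir: str = "ncmorph_report"
    seed: int = 0
    rav_provenance: str = "fitted"        # "fitted" or "printed"
    pca_indices: list = field(default_factory=lambda: list(PCA_INDICES))
    cluster_variables: list = field(default_factory=lambda: list(CHARACTERS))
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    positive_group: str | None = None
    fisher_alternative: str = "greater"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "partition" in raw:
            raw["partition"] = PartitionConfig(**raw["partition"])
        if "stepwise" in raw:
            raw["stepwise"] = StepwiseConfig(**raw["stepwise"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_full(config: PipelineConfig, records: pd.DataFrame | None = None,
             sites: pd.DataFrame | None = None) -> dict:
    """Run the complete analysis; returns a dict of result objects and paths.

    ``records``/``sites`` may be passed directly (e.g. fresh from the
    synthetic generator); otherwise they are read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if records is None:
        if config.specimens is None:
            from .synthdata import SynthConfig, generate_specimens
            records, truth = generate_specimens(SynthConfig(seed=config.seed))
            results["truth"] = truth
        else:
            records = read_specimen_table(config.specimens)
    usable = records[records["complete"]] if "complete" in records.columns else records

    # --- unsupervised stage: nest centroids, Ward tree, partitions ---------
    centroids = nest_centroids(usable, config.cluster_variables)
    matrix = centroids[config.cluster_variables]
    config.partition.seed = config.seed
    tree = ward_tree(matrix, config.partition)
    (out / "dendrogram.nwk").write_text(tree.to_newick())
    parts = run_partitioning(matrix, config.partition)
    parts.to_frame().to_csv(out / "partitions.csv")
    results["partitions"] = parts
    results["dendrogram"] = tree

    # --- wild-card resolution by confirmative LDA --------------------------
    k_joint = max(parts.k_hclust, parts.k_kmeans)
    reference = (parts.labels_hclust if parts.k_hclust >= parts.k_kmeans
                 else parts.labels_kmeans)
    if k_joint < 2:
        raise RuntimeError("no cluster structure found; nothing to delimit")
    concordant_nests = parts.concordant[parts.concordant].index
    initial = {nest: f"cluster_{reference[nest]}" for nest in concordant_nests}
    final_labels, model, info = iterate_confirmative(
        usable, usable["nest_id"], initial, parts.wildcards,
        variables=CHARACTERS, config=config.stepwise,
        positive_group=config.positive_group,
    )
    pd.DataFrame({"nest_id": final_labels.index, "label": final_labels.values,
                  "wildcard": [n in set(parts.wildcards) for n in final_labels.index]
                  }).to_csv(out / "wildcards.csv", index=False)
    results["final_labels"] = final_labels
    results["confirmative_info"] = info
    results["discriminant"] = model
    model.to_json(out / "discriminant.json")

    worker_labels = usable["nest_id"].map(final_labels)
    err = error_rates(model, usable, worker_labels, nest_ids=usable["nest_id"])
    err.to_csv(out / "error_rates.csv", index=False)
    results["error_rates"] = err

    # --- allometry + RAV ----------------------------------------------------
    indices = compute_indices(usable.assign(species=worker_labels.values))
    if config.rav_provenance == "printed":
        rav_params = printed_parameters()
    else:
        rav_params = fit_species_pooled(indices, species_col="species")
    rav_params.to_csv(out / "rav_parameters.csv")
    corrected = rav_correct_table(indices, rav_params)
    results["rav_params"] = rav_params

    # --- nest-mean PCA on the reduced corrected index set ------------------
    corr_centroids = nest_centroids(
        corrected.assign(nest_id=usable["nest_id"].values),
        variables=config.pca_indices)
    pca = pca_correlation(corr_centroids[config.pca_indices])
    pca.scores.to_csv(out / "pca_scores.csv")
    pca.loadings.to_csv(out / "pca_loadings.csv")
    nest_group = final_labels.reindex(pca.scores.index)
    overlap = hull_overlap(pca.scores, nest_group)
    (out / "hull_overlap.json").write_text(json.dumps(overlap, indent=2))
    try:
        plot_scores(pca, nest_group, out / "pca_scatter.png")
    except Exception:
        pass  # plotting is best-effort; the numeric outputs are authoritative
    results["pca"] = pca
    results["hull_overlap"] = overlap

    # --- per-character comparison table -------------------------------------
    table2 = ttest_table(indices, species_col="species")
    table2.to_csv(out / "character_table.csv", index=False)
    results["character_table"] = table2

    # --- latitude correlation ----------------------------------------------
    if "latitude" in usable.columns and usable["latitude"].notna().any():
        scores = model.score(usable)
        lat_results = {}
        for group in pd.unique(worker_labels.dropna()):
            mask = (worker_labels == group).values
            if usable.loc[mask, "latitude"].notna().sum() >= 3:
                res = pearson_with_latitude(scores[mask],
                                            usable.loc[mask, "latitude"])
                lat_results[str(group)] = {"R": res.R, "n": res.n, "p": res.p}
        (out / "latitude_correlation.json").write_text(
            json.dumps(lat_results, indent=2))
        results["latitude_correlation"] = lat_results

    # --- mimicry co-occurrence ----------------------------------------------
    if sites is None and config.sites is not None:
        sites = pd.read_csv(config.sites)
    if sites is not None:
        class_block, tests = table3_report(sites,
                                           alternative=config.fisher_alternative)
        class_block.to_csv(out / "association_classes.csv", index=False)
        tests.to_csv(out / "associations.csv", index=False)
        results["associations"] = tests

    _write_manifest(out, config)
    results["out_dir"] = out
    return results


def _write_manifest(out: Path, config: PipelineConfig) -> None:
    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    hashes = {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files}
    manifest = {
        "ncmorph_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "outputs": hashes,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True,
                       default=str).encode()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
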