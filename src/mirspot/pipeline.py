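"""End-to-end orchestration: preprocess -> DE -> cluster -> enrich (-> qPCR).

``run_pipeline`` drives the whole analysis from a :class:`PipelineConfig`
holding input paths and the tunable parameters (all defaulting to the
values the processing chain was designed around: log2 floor 1 raw unit,
20% trim, qualification SD < 1.25, detection margin 1 log2 unit, detection
in >= 10% of arrays, two-fold DE threshold).  Each stage writes its TSV
output into the run directory and a JSON manifest records parameters,
seeds, input checksums and the stage outputs, so identical inputs and
configuration reproduce byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import diffexp, enrichment, preprocess, qpcr, reference_data, tables
from .errors import MirspotError
from .simulate import ArraySimConfig, generate_array_experiment


@dataclass
class PipelineConfig:
    """Inputs and parameters of a pipeline run."""

    spot_table: str | None = None        # TSV path (all arrays in one table)
    annotation: str | None = None
    design: str | None = None
    ct_table: str | None = None          # optional qPCR stage input
    outdir: str = "mirspot_run"
    floor: float = 1.0
    trim: float = 0.20
    sd_max: float = 1.25
    margin: float = 1.0
    min_fraction: float = 0.10
    de_threshold: float = 1.0
    control_group: str = "control"
    treatment_groups: tuple = ("over", "under")
    qpcr_reference: str = "U6"
    seed: int = 20170101


class StageFailure(MirspotError):
    """A pipeline stage failed; the stage name leads the message."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("spot_table", "annotation", "design"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise StageFailure(f"validate: required input {name!r} missing: {path}")
    if config.ct_table is not None and not Path(config.ct_table).exists():
        raise StageFailure(f"validate: ct_table missing: {config.ct_table}")

    manifest = {
        "parameters": asdict(config),
        "inputs": {name: _sha256(Path(getattr(config, name)))
                   for name in ("spot_table", "annotation", "design")
                   if getattr(config, name)},
        "stages": {},
    }
    outputs = {}

    def record(stage, name, path):
        outputs[name] = str(path)
        manifest["stages"].setdefault(stage, []).append(str(path))

    stage = "preprocess"
    try:
        spots = tables.read_spot_table(config.spot_table)
        annotation = tables.read_probe_annotation(config.annotation)
        design = tables.read_design(config.design)

        thresholds = preprocess.thresholds_from_spots(spots, annotation, config.floor)
        human_ids = set(annotation.loc[annotation["probe_class"] == "human", "probe_id"])
        slog = preprocess.spot_log2(spots, config.floor)
        human_log = slog[slog["probe_id"].isin(human_ids)]

        qual_matrix = tables.IntensityMatrix(
            preprocess.probe_array_means(human_log), "log2")
        probes = preprocess.select_normalization_probes(
            qual_matrix, thresholds, config.margin, config.sd_max)
        factors = preprocess.normalization_factors(qual_matrix, probes, config.trim)

        norm_spots = preprocess.normalize_spots(slog, factors)
        norm_thresholds = thresholds.shifted(-factors.n + factors.grand_mean)
        averaged = preprocess.average_triplicates(
            norm_spots[norm_spots["probe_id"].isin(human_ids)])
        detected = preprocess.detection_filter(
            averaged, norm_thresholds, config.margin, config.min_fraction)

        p = outdir / "detection_thresholds.tsv"
        thresholds.to_tsv(p); record(stage, "thresholds", p)
        p = outdir / "normalization_factors.tsv"
        factors.to_tsv(p); record(stage, "factors", p)
        p = outdir / "normalized_averaged.tsv"
        tables.write_intensity_matrix(averaged, p); record(stage, "averaged", p)
        p = outdir / "detected.tsv"
        tables.write_intensity_matrix(detected, p); record(stage, "detected", p)
    except MirspotError as err:
        _fail(manifest, outdir, stage, err)

    stage = "de"
    try:
        means = diffexp.group_means(detected, design)
        de_table, excluded = diffexp.call_de(
            means, config.de_threshold, config.control_group,
            tuple(config.treatment_groups))
        p = outdir / "differential_expression.tsv"
        de_table.to_csv(p, sep="\t"); record(stage, "de", p)
        manifest["de_excluded_probes"] = excluded
    except MirspotError as err:
        _fail(manifest, outdir, stage, err)

    stage = "cluster"
    try:
        tree, centered = _cluster.cluster_matrix(detected)
        cdt, gtr = outdir / "clustered.cdt", outdir / "clustered.gtr"
        tables.write_cdt_gtr(tree, centered, cdt, gtr)
        record(stage, "cdt", cdt)
        record(stage, "gtr", gtr)
    except MirspotError as err:
        _fail(manifest, outdir, stage, err)

    stage = "enrich"
    try:
        assoc = reference_data.load_association_table()
        relations = enrichment.filter_targets(
            [m for m, _a in reference_data.SIX_MIRNAS], assoc)
        genes = enrichment.unique_genes(relations)
        reference = reference_data.load_pathway_reference()
        mapped, unmapped = enrichment.map_to_reference(genes, reference)
        table = enrichment.enrich(mapped, reference)
        p = outdir / "enrichment.tsv"
        table.to_csv(p, sep="\t", index=False); record(stage, "enrichment", p)
        manifest["enrichment_summary"] = {
            "relations": int(len(relations)),
            "unique_genes": int(len(genes)),
            "mapped_genes": int(len(mapped)),
            "unmapped_genes": sorted(unmapped),
        }
    except MirspotError as err:
        _fail(manifest, outdir, stage, err)

    if config.ct_table is not None:
        stage = "qpcr"
        try:
            ct = qpcr.read_ct_table(config.ct_table)
            rows = []
            for assay in sorted(set(ct["assay"]) - {config.qpcr_reference}):
                res = qpcr.ddct_fold_change(ct, assay, config.qpcr_reference)
                rows.append({"assay": assay, "delta_delta_ct": res.delta_delta_ct,
                             "fold_change": res.fold_change,
                             "t": res.t_statistic, "p": res.p_value})
            p = outdir / "qpcr_fold_changes.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            record(stage, "qpcr", p)
        except MirspotError as err:
            _fail(manifest, outdir, stage, err)

    manifest["outputs"] = outputs
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _fail(manifest, outdir, stage, err):
    manifest["failed_stage"] = stage
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    raise StageFailure(f"{stage}: {err}") from err


def simulate_inputs(outdir, sim_config: ArraySimConfig | None = None):
    """Write a simulated experiment to disk and return a ready PipelineConfig."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spots, annotation, design, truth = generate_array_experiment(sim_config)
    spot_path = outdir / "spots.tsv"
    ann_path = outdir / "annotation.tsv"
    design_path = outdir / "design.tsv"
    tables.write_spot_table(spots, spot_path)
    tables.write_probe_annotation(annotation, ann_path)
    tables.write_design(design, design_path)
    config = PipelineConfig(spot_table=str(spot_path), annotation=str(ann_path),
                            design=str(design_path), outdir=str(outdir / "run"))
    return config, truth
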