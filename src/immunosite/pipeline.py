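"""End-to-end orchestration: qc -> repertoire -> diversity -> track -> score
-> nominate -> concordance, driven by a single manifest.

The manifest is a YAML/JSON mapping with keys ``samples`` (sample id ->
{matrix, features, barcodes, contigs}), ``cells``, ``gene_sets`` and
optionally ``viral_reference``. Every stage writes its report under the
output directory; a run log records all materialized configuration so the
run is reproducible from the log alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import concordance_report
from .diversity import d50, jaccard, rarefaction
from .errors import ImmunositeError, ValidationError
from .io_formats import (
    ExpressionMatrix,
    concat_cells,
    read_cell_table,
    read_contig_table,
    read_gmt,
    read_mtx_triplet,
    read_viral_reference,
)
from .nomination import (
    DEFAULT_PAIRING,
    EligibilityConfig,
    consensus,
    filter_tils,
    nominate,
    track_consensus,
)
from .qc_filter import QcThresholds, apply_qc
from .repertoire import Repertoire, assemble_clonotypes, bin_expansion, build_repertoire
from .signature_scoring import ScoringConfig, score_matrix
from .tracking import tracking_report

logger = logging.getLogger("immunosite.pipeline")

STAGES = ("qc", "repertoire", "diversity", "track", "score", "nominate", "concordance")


class StageError(ImmunositeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    qc: QcThresholds = field(default_factory=QcThresholds)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    pairing: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_PAIRING))
    n_top_clones: int = 20
    rarefaction_points: int = 10
    correlation: str = "pearson"


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    manifest = yaml.safe_load(path.read_text())
    validate_manifest(manifest)
    return manifest


def validate_manifest(manifest: Mapping) -> None:
    """Check structure and that every referenced path exists, before any
    stage runs."""
    for key in ("samples", "cells", "gene_sets"):
        if key not in manifest:
            raise ValidationError(f"manifest missing key {key!r}")
    if len(manifest["samples"]) != len(set(manifest["samples"])):
        raise ValidationError("duplicate sample ids in manifest")
    missing: list[str] = []
    for sid, paths in manifest["samples"].items():
        for part in ("matrix", "features", "barcodes", "contigs"):
            if part not in paths:
                raise ValidationError(f"sample {sid!r}: manifest missing {part!r}")
            if not Path(paths[part]).exists():
                missing.append(paths[part])
    for key in ("cells", "gene_sets", "viral_reference"):
        if key in manifest and manifest[key] is not None and not Path(manifest[key]).exists():
            missing.append(manifest[key])
    if missing:
        raise ValidationError(f"manifest references missing files: {missing}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_pipeline(
    manifest: Mapping | str | Path,
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run every stage; returns the run log (also written to run_log.json)."""
    if not isinstance(manifest, Mapping):
        manifest = load_manifest(manifest)
    else:
        validate_manifest(manifest)
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    run_log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "qc": config.qc.__dict__ if hasattr(config.qc, "__dict__") else str(config.qc),
            "scoring": {
                "max_rank_fraction": config.scoring.max_rank_fraction,
                "top_cell_percent": config.scoring.top_cell_percent,
                "tie_policy": config.scoring.tie_policy,
                "ssgsea_alpha": config.scoring.ssgsea_alpha,
                "min_geneset_coverage": config.scoring.min_geneset_coverage,
            },
            "pairing": {k: list(v) for k, v in config.pairing.items()},
            "n_top_clones": config.n_top_clones,
            "correlation": config.correlation,
        },
        "stages": {},
    }

    cells = read_cell_table(manifest["cells"])
    sample_meta = cells.drop_duplicates("sample_id").set_index("sample_id")

    # ---- qc ---------------------------------------------------------------
    stage = "qc"
    try:
        matrices: dict[str, ExpressionMatrix] = {}
        qc_reports = {}
        for sid, paths in manifest["samples"].items():
            raw = read_mtx_triplet(paths["matrix"], paths["features"], paths["barcodes"], sid)
            filtered, report = apply_qc(raw, config.qc)
            matrices[sid] = filtered
            qc_reports[sid] = report.to_dict()
            logger.info("qc %s: %d -> %d cells", sid, report.cells_in, report.cells_out)
        _write_json(qc_reports, out_dir / "qc_report.json")
        run_log["stages"][stage] = {
            sid: {"cells_in": r["cells_in"], "cells_out": r["cells_out"]}
            for sid, r in qc_reports.items()
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- repertoire -------------------------------------------------------
    stage = "repertoire"
    try:
        cell_clonotypes: dict = {}
        repertoires: dict[str, Repertoire] = {}
        rep_rows = []
        for sid, paths in manifest["samples"].items():
            contigs = read_contig_table(paths["contigs"])
            kept = set(matrices[sid].barcodes)
            mapping = {
                bc: clone
                for bc, clone in assemble_clonotypes(contigs).items()
                if bc in kept
            }
            cell_clonotypes.update(mapping)
            rep = build_repertoire(mapping, cells, sid)
            repertoires[sid] = rep
            if rep.pool_size:
                bins = bin_expansion(rep)
                for clone, count in sorted(rep.clone_counts.items(), key=lambda kv: kv[0].key):
                    rep_rows.append(
                        {"sample_id": sid, "clonotype": clone.key, "count": count,
                         "frequency": count / rep.pool_size, "bin": bins[clone]}
                    )
            logger.info("repertoire %s: pool %d, clones %d", sid, rep.pool_size, rep.n_clones)
        pd.DataFrame(rep_rows).to_csv(out_dir / "repertoire.tsv", sep="\t", index=False)
        run_log["stages"][stage] = {
            sid: {"pool_size": r.pool_size, "n_clones": r.n_clones}
            for sid, r in repertoires.items()
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- diversity --------------------------------------------------------
    stage = "diversity"
    try:
        div_rows = []
        curve_rows = []
        for sid, rep in repertoires.items():
            if rep.pool_size == 0:
                continue
            k, index = d50(rep)
            div_rows.append({"sample_id": sid, "d50_k": k, "d50_index": index,
                             "pool_size": rep.pool_size, "n_clones": rep.n_clones})
            depths = sorted(set(np.linspace(1, rep.pool_size, config.rarefaction_points).astype(int)))
            curve = rarefaction(rep, depths)
            for m, richness in zip(curve.depths, curve.expected_richness):
                curve_rows.append({"sample_id": sid, "depth": m, "expected_richness": richness})
        pd.DataFrame(div_rows).to_csv(out_dir / "diversity.tsv", sep="\t", index=False)
        pd.DataFrame(curve_rows).to_csv(out_dir / "rarefaction.tsv", sep="\t", index=False)
        sids = sorted(repertoires)
        jac = pd.DataFrame(
            [[jaccard(repertoires[a], repertoires[b]) for b in sids] for a in sids],
            index=sids, columns=sids,
        )
        jac.to_csv(out_dir / "jaccard.tsv", sep="\t")
        run_log["stages"][stage] = {"samples": len(div_rows)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    viral_ref = None
    if manifest.get("viral_reference"):
        viral_ref = read_viral_reference(manifest["viral_reference"])

    # ---- track ------------------------------------------------------------
    stage = "track"
    try:
        track_rows = []
        for patient in sorted(sample_meta["patient_id"].unique()):
            patient_samples = sample_meta[sample_meta["patient_id"] == patient]
            tumor_ids = patient_samples[patient_samples["tissue"] == "tumor"].index
            site_ids = patient_samples[patient_samples["tissue"] != "tumor"].index
            for tumor_id in tumor_ids:
                rep = repertoires[tumor_id]
                if rep.pool_size == 0:
                    continue
                sites = [repertoires[s] for s in site_ids]
                n_top = min(config.n_top_clones, rep.n_clones)
                for tracked in tracking_report(rep, sites, viral_ref, n_top=n_top):
                    row = {"patient_id": patient, "tumor_sample": tumor_id}
                    row.update(tracked.to_dict())
                    track_rows.append(row)
        _write_json(track_rows, out_dir / "tracking.json")
        run_log["stages"][stage] = {"tracked_clones": len(track_rows)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- score ------------------------------------------------------------
    stage = "score"
    try:
        gene_sets = read_gmt(manifest["gene_sets"])
        signature_names = {name for sigs in config.pairing.values() for name in sigs}
        reactivity_sets = [gs for gs in gene_sets if gs.name in signature_names]
        missing_sets = signature_names - {gs.name for gs in reactivity_sets}
        if missing_sets:
            raise ValidationError(f"gene sets missing from GMT: {sorted(missing_sets)}")
        tumor_ids = sorted(sample_meta[sample_meta["tissue"] == "tumor"].index)
        tumor_matrix = concat_cells([matrices[sid] for sid in tumor_ids], sample_id="tumor_all")
        scores = score_matrix(tumor_matrix, reactivity_sets, method="auc", config=config.scoring)
        scores.to_long_frame().to_csv(out_dir / "scores.tsv", sep="\t", index=False)
        run_log["stages"][stage] = {
            "cells_scored": len(scores.barcodes),
            "signatures": sorted(s.name for s in reactivity_sets),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- nominate ---------------------------------------------------------
    stage = "nominate"
    try:
        all_contigs = pd.concat(
            [read_contig_table(paths["contigs"]) for paths in manifest["samples"].values()],
            ignore_index=True,
        )
        eligible, exclusion_log = filter_tils(cells, cell_clonotypes, all_contigs, config.eligibility)
        lineage_map = dict(zip(cells["barcode"], cells["lineage"]))
        signature_lineage = {
            name: lineage for lineage, names in config.pairing.items() for name in names
        }
        result = nominate(scores, eligible, lineage_map, signature_lineage, config.eligibility)
        result.exclusion_log = exclusion_log
        result = consensus(result, cell_clonotypes, config.pairing)
        site_ids = sorted(sample_meta[sample_meta["tissue"] != "tumor"].index)
        presence = track_consensus(result, [repertoires[s] for s in site_ids])
        payload = result.to_dict()
        payload["consensus_site_frequencies"] = {
            lineage: {clone.key: freqs for clone, freqs in table.items()}
            for lineage, table in presence.items()
        }
        _write_json(payload, out_dir / "nomination.json")
        ranked_rows = [
            {"lineage": lineage, "rank": i + 1, "clonotype": clone.key,
             "n_signatures": n, "mean_score": score}
            for lineage, ranked in result.consensus_clonotypes.items()
            for i, (clone, n, score) in enumerate(ranked)
        ]
        pd.DataFrame(ranked_rows).to_csv(out_dir / "consensus_clonotypes.tsv", sep="\t", index=False)
        run_log["stages"][stage] = {
            "eligible": len(eligible),
            "consensus": {lin: len(bcs) for lin, bcs in result.consensus_barcodes.items()},
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- concordance ------------------------------------------------------
    stage = "concordance"
    try:
        report = concordance_report(cells, matrices, repertoires, correlation=config.correlation)
        report.proportion_corr.to_csv(out_dir / "concordance_proportions.tsv", sep="\t")
        report.pseudobulk_corr.to_csv(out_dir / "concordance_pseudobulk.tsv", sep="\t")
        report.repertoire_jaccard.to_csv(out_dir / "concordance_jaccard.tsv", sep="\t")
        _write_json(
            {"metadata": report.metadata, "samples": report.samples},
            out_dir / "concordance.json",
        )
        run_log["stages"][stage] = {"samples": len(report.samples)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _write_json(run_log, out_dir / "run_log.json")
    return run_log
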