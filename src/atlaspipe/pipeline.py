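"""End-to-end workflows: atlas characterization of the smoking response and
the lineage/mucin-program analysis, with provenance stamping.

Each workflow validates its inputs up front, runs the stages in a fixed
order, writes every intermediate table, and records a manifest (config
hash, seed, per-stage output paths, row counts and content checksums) so
reruns with the same config and inputs can be verified bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp, markers, mucin, qc, taxonomy, trajectory
from .io_formats import CellAnnotations, CountMatrix, RunConfig, ValidationError

__all__ = ["PipelineManifest", "run_smoking_workflow", "run_lineage_workflow"]

log = logging.getLogger("atlaspipe")


@dataclass
class PipelineManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, path: Path | None, table: pd.DataFrame | None, **extra) -> None:
        entry: dict = dict(extra)
        if table is not None:
            entry["rows"] = int(len(table))
        if path is not None:
            entry["path"] = str(path)
            entry["sha256"] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.stages[stage] = entry

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _prepare(config: RunConfig, counts: CountMatrix, annotations: CellAnnotations):
    """Shared QC + normalization front end; returns aligned pieces."""
    ann = annotations.aligned_to(counts.cell_ids)
    thresholds = qc.QCThresholds(
        min_genes_per_cell=config.min_genes_per_cell,
        max_mito_fraction=config.max_mito_fraction,
        upper_percentile=config.upper_percentile,
        min_cell_fraction_per_gene=config.min_cell_fraction_per_gene,
    )
    mito_mask = np.array(
        [g.startswith("MT-") for g in counts.gene_ids], dtype=bool
    )
    cells_kept, cell_report = qc.filter_cells(counts, mito_mask, thresholds)
    log.info("cell QC: %d -> %d cells (%s)", cell_report.n_input, cell_report.survivors, cell_report.removed)
    genes_kept, gene_report = qc.filter_genes(cells_kept, thresholds)
    log.info("gene QC: %d -> %d genes (%s)", gene_report.n_input, gene_report.survivors, gene_report.removed)
    ann = ann.aligned_to(genes_kept.cell_ids)
    normalized = qc.normalize(genes_kept, config.scale_total)
    return genes_kept, ann, normalized, cell_report, gene_report


def run_smoking_workflow(
    config: RunConfig,
    counts: CountMatrix,
    annotations: CellAnnotations,
    out_dir: str | Path,
) -> PipelineManifest:
    """QC → normalize → per-population smoker DE → taxonomy → marker-set
    enrichment → composition shifts.

    Writes one TSV per stage under ``out_dir`` and returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = PipelineManifest(config_hash=_config_hash(config), seed=config.seed)
    t0 = time.time()

    ann0 = annotations.aligned_to(counts.cell_ids)
    roster = list(config.roster) or sorted(ann0.table["population"].dropna().unique())
    present = set(ann0.table["population"].dropna().unique())
    missing = [p for p in roster if p not in present]
    if missing:
        raise ValidationError(f"roster population(s) absent from annotations: {missing}")

    kept, ann, normalized, cell_report, gene_report = _prepare(config, counts, annotations)
    manifest.record("qc", None, None, cells=cell_report.survivors, genes=gene_report.survivors)

    de_thresholds = diffexp.DEThresholds(config.min_logfc, config.min_pct, config.alpha_fdr)
    pop = ann.table["population"].to_numpy()
    smoking = ann.table["smoking"].to_numpy()
    excluded = ann.table["excluded_flag"].to_numpy()
    de_tables: dict[str, pd.DataFrame] = {}
    for p in roster:
        cells_s = np.flatnonzero((pop == p) & (smoking == "heavy") & ~excluded)
        cells_n = np.flatnonzero((pop == p) & (smoking == "never") & ~excluded)
        table = diffexp.de_contrast(
            normalized, kept.values, kept.gene_ids, cells_s, cells_n,
            t=de_thresholds, test="wilcoxon",
        )
        de_tables[p] = table
        path = out / f"de_smoking_{p}.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest.record(f"de_smoking_{p}", path, table)
    log.info("smoking DE done for %d populations", len(roster))

    tax_thresholds = taxonomy.TaxonomyThresholds(
        core_min=config.core_min,
        unique_logfc_max=config.unique_logfc_max,
        unique_fdr_min=config.unique_fdr_min,
        alpha=config.alpha_fdr,
    )
    tax = taxonomy.classify_response(de_tables, tax_thresholds, roster=roster)
    tax_frame = tax.to_frame()
    path = out / "taxonomy.tsv"
    tax_frame.to_csv(path, sep="\t", index=False)
    manifest.record("taxonomy", path, tax_frame)

    marker_table = markers.pairwise_markers(
        normalized, kept.values, kept.gene_ids, pop,
        t=de_thresholds, seed=config.seed, test="wilcoxon",
    )
    path = out / "markers.tsv"
    marker_table.to_csv(path, sep="\t", index=False)
    manifest.record("markers", path, marker_table)

    marker_sets = {
        p: list(g["gene"]) for p, g in marker_table.groupby("population")
    }
    response_sets = {
        f"{cls}_{direction}": tax.genes_in_class(direction, cls)
        for direction in ("up", "down")
        for cls in ("core", "unique", "semi_unique")
    }
    response_sets = {k: v for k, v in response_sets.items() if v}
    if marker_sets and response_sets:
        enr = taxonomy.marker_set_enrichment(
            marker_sets, response_sets, kept.gene_ids, alpha=config.alpha_fdr
        )
        path = out / "marker_enrichment.tsv"
        enr.to_csv(path, sep="\t", index=False)
        manifest.record("marker_enrichment", path, enr)

    per_donor, summary = taxonomy.proportion_shift(ann)
    path = out / "composition_shift.tsv"
    per_donor.to_csv(path, sep="\t", index=False)
    manifest.record("composition_shift", path, per_donor)
    path = out / "composition_summary.tsv"
    summary.to_csv(path, sep="\t", index=False)
    manifest.record("composition_summary", path, summary)

    manifest.record("runtime", None, None, seconds=round(time.time() - t0, 2))
    manifest.to_json(out / "manifest.json")
    return manifest


def run_lineage_workflow(
    config: RunConfig,
    counts: CountMatrix,
    annotations: CellAnnotations,
    out_dir: str | Path,
) -> PipelineManifest:
    """QC → PCA → MST lineage → pseudotime association → smoothing → GMM
    endpoint isolation → mucin programs → program shift test."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = PipelineManifest(config_hash=_config_hash(config), seed=config.seed)
    t0 = time.time()

    if config.lineage_root is None:
        raise ValidationError("lineage_root must be set for the lineage workflow")
    ann0 = annotations.aligned_to(counts.cell_ids)
    present = set(ann0.table["population"].dropna().unique())
    for p in (config.lineage_root, config.lineage_end):
        if p is not None and p not in present:
            raise ValidationError(f"lineage population {p!r} absent from annotations")

    kept, ann, normalized, cell_report, gene_report = _prepare(config, counts, annotations)
    manifest.record("qc", None, None, cells=cell_report.survivors, genes=gene_report.survivors)

    pop = ann.table["population"].to_numpy()
    coords = trajectory.pca_reduce(normalized)
    path_obj = trajectory.build_lineage(coords, pop, config.lineage_root, config.lineage_end)
    pt = path_obj.pseudotime
    pt_table = pd.DataFrame(
        {"cell_id": kept.cell_ids, "population": pop, "pseudotime": pt}
    )
    path = out / "pseudotime.tsv"
    pt_table.to_csv(path, sep="\t", index=False)
    manifest.record("pseudotime", path, pt_table, path_populations=path_obj.populations)

    smoker = (ann.table["smoking"] == "heavy").to_numpy().astype(float)
    on_path = ~np.isnan(pt)
    assoc = trajectory.pseudotime_association(
        normalized, kept.gene_ids, pt, covariate=smoker, q_threshold=config.association_q
    )
    path = out / "pseudotime_association.tsv"
    assoc.to_csv(path, sep="\t", index=False)
    manifest.record("association", path, assoc, flagged=int(assoc["flagged"].sum()))

    flagged = assoc.sort_values("q").head(20)["gene"]
    lookup = {g: i for i, g in enumerate(kept.gene_ids)}
    window = min(config.smoothing_window, max(3, int(on_path.sum())))
    smooth_rows = {}
    for g in flagged:
        vals = np.asarray(normalized[lookup[g], np.flatnonzero(on_path)].todense()).ravel()
        smooth_rows[g] = trajectory.smooth_expression(vals, pt[on_path], window=window)
    smooth_table = pd.DataFrame(smooth_rows)
    path = out / "smoothed_expression.tsv"
    smooth_table.to_csv(path, sep="\t", index=False)
    manifest.record("smoothing", path, smooth_table, window=window)

    fit = trajectory.fit_gmm2(pt[on_path], seed=config.seed)
    fit_payload = {
        "weights": fit.weights, "means": fit.means, "sds": fit.sds,
        "log_likelihood": fit.log_likelihood, "iterations": fit.iterations,
        "converged": fit.converged, "separated": fit.separated,
    }
    path = out / "mixture_fit.json"
    path.write_text(json.dumps(fit_payload, indent=2))
    manifest.record("mixture_fit", path, None)
    terminal_mask = np.zeros(len(kept.cell_ids), dtype=bool)
    if fit.separated:
        terminal_mask[np.flatnonzero(on_path)] = trajectory.isolate_terminal(pt[on_path], fit)
    term_table = pd.DataFrame({"cell_id": kept.cell_ids, "terminal": terminal_mask})
    path = out / "terminal_cells.tsv"
    term_table.to_csv(path, sep="\t", index=False)
    manifest.record("terminal_cells", path, term_table, n_terminal=int(terminal_mask.sum()))

    # mucin programs within the isolated terminal secretory state
    if config.anchor_a in lookup and config.anchor_b in lookup and terminal_mask.sum() >= 50:
        cells = np.flatnonzero(terminal_mask)
        smoking_flag = (ann.table["smoking"] == "heavy").to_numpy()[cells]
        excluded = ann.table["excluded_flag"].to_numpy()[cells]
        try:
            programs = mucin.derive_programs(
                normalized, kept.values, kept.gene_ids, cells,
                (config.anchor_a, config.anchor_b), smoking_flag,
                excluded=excluded, min_rho_report=config.min_rho_report,
                alpha=config.alpha_fdr,
            )
            path = out / "mucin_programs.tsv"
            programs.to_csv(path, sep="\t", index=False)
            manifest.record("mucin_programs", path, programs)
            has_a = (programs["program"] == "A_specific").any()
            has_b = (programs["program"] == "B_specific").any()
            if has_a and has_b:
                smoker_cells = cells[smoking_flag & ~excluded]
                nonsmoker_cells = cells[~smoking_flag & ~excluded]
                shift = mucin.program_shift_test(
                    normalized, kept.gene_ids, programs,
                    smoker_cells, nonsmoker_cells, top_n=config.program_top_n,
                )
                path = out / "program_shift.tsv"
                shift.to_csv(path, sep="\t", index=False)
                manifest.record("program_shift", path, shift)
        except ValidationError as exc:
            manifest.record("mucin_programs", None, None, skipped=str(exc))

    manifest.record("runtime", None, None, seconds=round(time.time() - t0, 2))
    manifest.to_json(out / "manifest.json")
    return manifest
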