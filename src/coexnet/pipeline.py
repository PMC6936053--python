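"""End-to-end orchestration: integrate -> associate -> threshold -> network
-> score -> enrich, with deterministic, individually re-loadable outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, enrichment, ingest, network, thresholding
from .errors import ValidationError

__all__ = ["RunConfig", "run_pipeline", "load_association"]

log = logging.getLogger("coexnet")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialized verbatim next to outputs.

    ``inputs`` are expression-table paths (ignored when ``simulate`` is
    set); numeric fields mirror the library defaults and are validated
    before any work starts.
    """

    inputs: list[str] = field(default_factory=list)
    labels: list[str] | None = None
    orientation: str = "genes"
    delimiter: str | None = None
    output_dir: str = "coexnet_run"

    # association settings
    absolute_pcc: bool = True
    n_bins: int | str = "auto"
    scheme: str = "equal_width"
    log_base: float = float(np.e)

    # threshold selection
    head_fraction: float = 0.02
    smooth_window: int = 51
    fallback_quantile: float = 0.99
    t_pcc: float | None = None  # manual overrides bypass selection
    t_mi: float | None = None

    # network / ranking
    min_module_size: int = 15
    top_k: int = 10

    # enrichment
    gmt: str | None = None

    # synthetic input instead of files
    simulate: dict | None = None
    seed: int = 0

    save_associations: bool = False
    float_digits: int = 6

    def validate(self) -> None:
        if self.orientation not in ("genes", "samples"):
            raise ValidationError("orientation must be 'genes' or 'samples'")
        if not (0 < self.head_fraction <= 1):
            raise ValidationError("head_fraction must be in (0, 1]")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be odd and >= 3")
        if not (0 < self.fallback_quantile < 1):
            raise ValidationError("fallback_quantile must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not self.inputs and self.simulate is None:
            raise ValidationError("provide input paths or a simulate block")


def _write_tsv(frame: pd.DataFrame, path: Path, digits: int, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", float_format=f"%.{digits}g", index=index)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed: {exc} "
                    f"(check the inputs and settings for this stage)"
                ) from exc

        return run

    return wrap


def load_association(path: str | os.PathLike, measure: str) -> association.AssociationMatrix:
    """Re-load an association matrix written by a previous run."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return association.AssociationMatrix(
        gene_ids=tuple(str(g) for g in frame.index),
        values=frame.to_numpy(dtype=float),
        measure=measure,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return a run summary.

    The summary records counts (genes, samples, edges, modules, retained
    nodes), the thresholds used and how they were obtained, warnings about
    degenerate genes, and a manifest of every file written.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        summary = _run(cfg, out, manifest)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest.append("run.log")
    summary["manifest"] = sorted(manifest)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _run(cfg: RunConfig, out: Path, manifest: list[str]) -> dict:
    cfg_dict = dataclasses.asdict(cfg)
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg_dict, fh, indent=2, sort_keys=True, default=str)
    manifest.append("config.json")

    # ingest ----------------------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        from .synthetic import generate_expression

        matrix, truth = _stage("simulate")(generate_expression)(
            seed=cfg.seed, **cfg.simulate
        )
        ingest.write_expression(matrix, out / "expression.tsv")
        manifest.append("expression.tsv")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "module_assignments": truth.module_assignments,
                    "module_kinds": truth.module_kinds,
                    "generator_params": truth.generator_params,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        manifest.append("truth.json")
    else:
        matrices = [
            _stage("ingest")(ingest.read_expression)(
                p, delimiter=cfg.delimiter, orientation=cfg.orientation
            )
            for p in cfg.inputs
        ]
        matrix = _stage("integrate")(ingest.integrate_datasets)(matrices, labels=cfg.labels)
    log.info("integrated matrix: %d genes x %d samples", matrix.n_genes, matrix.n_samples)

    # association -----------------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pcc = _stage("association")(association.pearson_matrix)(
            matrix, absolute=cfg.absolute_pcc
        )
        codes = _stage("association")(association.discretize)(
            matrix, n_bins=cfg.n_bins, scheme=cfg.scheme
        )
        mi = _stage("association")(association.mutual_information_matrix)(
            codes, log_base=cfg.log_base
        )
    for w in caught:
        log.warning("%s", w.message)
    if cfg.save_associations:
        for name, mat in (("pcc", pcc), ("mi", mi)):
            frame = pd.DataFrame(
                mat.values, index=list(mat.gene_ids), columns=list(mat.gene_ids)
            )
            _write_tsv(frame, out / f"{name}.tsv", digits=17, index=True)
            manifest.append(f"{name}.tsv")

    # thresholding ----------------------------------------------------------
    thresholds: dict[str, float] = {}
    fallbacks: dict[str, bool] = {}
    for name, mat, manual in (("pcc", pcc, cfg.t_pcc), ("mi", mi, cfg.t_mi)):
        if manual is not None:
            thresholds[name] = float(manual)
            fallbacks[name] = False
            log.info("%s threshold set manually: %g", name, manual)
            continue
        values = _stage("threshold")(thresholding.collect_offdiag)(mat)
        result = _stage("threshold")(thresholding.select_threshold)(
            values,
            head_fraction=cfg.head_fraction,
            smooth_window=cfg.smooth_window,
            fallback_quantile=cfg.fallback_quantile,
        )
        thresholds[name] = result.threshold
        fallbacks[name] = result.fallback_used
        diag = thresholding.threshold_diagnostics(result)
        _write_tsv(diag, out / f"threshold_curve_{name}.tsv", cfg.float_digits)
        manifest.append(f"threshold_curve_{name}.tsv")
        log.info(
            "%s threshold selected: %g at rank %d (fallback=%s)",
            name,
            result.threshold,
            result.inflection_rank,
            result.fallback_used,
        )

    # network ---------------------------------------------------------------
    net = _stage("network")(network.build_adjacency)(
        pcc, mi, thresholds["pcc"], thresholds["mi"]
    )
    non_isolated = sum(1 for _, d in net.graph.degree if d > 0)
    modular = _stage("network")(network.extract_modules)(net, cfg.min_module_size)
    log.info(
        "network: %d edges; %d non-isolated nodes; %d retained in %d modules",
        net.n_edges,
        non_isolated,
        modular.graph.number_of_nodes(),
        len(modular.modules),
    )
    network.write_sif(modular, out / "network.sif")
    network.write_graphml(modular, out / "network.graphml")
    manifest += ["network.sif", "network.graphml"]

    # scoring ---------------------------------------------------------------
    scores = _stage("score")(network.score_nodes)(modular)
    ranking = network.rank_genes(scores, top_k=max(cfg.top_k, 1))
    full = network.rank_genes(scores, top_k=max(len(scores), 1)) if scores else ranking
    _write_tsv(full, out / "node_scores.tsv", cfg.float_digits)
    _write_tsv(ranking, out / "top_genes.tsv", cfg.float_digits)
    manifest += ["node_scores.tsv", "top_genes.tsv"]

    # enrichment ------------------------------------------------------------
    n_enriched = 0
    if cfg.gmt is not None and modular.modules:
        collection = _stage("enrich")(ingest.read_gmt)(cfg.gmt)
        background = set(matrix.gene_ids)
        frames = []
        for idx, members in enumerate(modular.modules, start=1):
            results = _stage("enrich")(enrichment.hypergeometric_enrich)(
                set(members), collection, background, module_id=f"M{idx}"
            )
            frames.append(enrichment.enrichment_table(results))
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        _write_tsv(table, out / "enrichment.tsv", cfg.float_digits)
        manifest.append("enrichment.tsv")
        n_enriched = len(table)

    summary = {
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "n_edges": net.n_edges,
        "n_non_isolated_nodes": non_isolated,
        "n_modules": len(modular.modules),
        "n_retained_nodes": modular.graph.number_of_nodes(),
        "module_sizes": [len(m) for m in modular.modules],
        "thresholds": thresholds,
        "threshold_fallbacks": fallbacks,
        "zero_variance_genes": pcc.params.get("zero_variance_genes", []),
        "n_enrichment_rows": n_enriched,
        "output_dir": str(out),
    }
    return summary
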