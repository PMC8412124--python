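"""End-to-end orchestration: discover → enrich → transfer → correlate → pathways.

Each stage is a pure function over files; :func:`run_pipeline` wires them
together, writes one TSV per result table plus a machine-readable JSON
manifest (input hashes, parameters, seed) and a human-readable summary.
Reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .association import correlate_tf_targets
from .discovery import select_candidate_tfs
from .enrichment import enrich_tfs
from .io import (
    read_de_table,
    read_expression,
    read_gmt,
    read_ortholog_map,
    write_enrichment_table,
)
from .model import CandidateTF, Regulon, RegulonDB, TailConvention
from .orthology import transfer_db
from .pathways import ora, tf_pathway_counts

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "regulon_db_from_collection"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    de_table: str
    regulons: str
    tf_universe: str
    out_dir: str
    species: str = "human"
    de_table_secondary: str | None = None
    secondary_species: str = "zebrafish"
    ortholog_map: str | None = None
    expression: str | None = None
    sample_metadata: str | None = None
    pathway_collection: str | None = None
    forced: list[str] = field(default_factory=list)
    alpha: float = 0.05
    rho_min: float = 0.70
    p_max: float = 0.05
    tail: str = "ge"
    top_n: int = 20
    correlate_tf: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label in ("de_table", "regulons", "tf_universe", "de_table_secondary",
                      "ortholog_map", "expression", "sample_metadata",
                      "pathway_collection"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {label} file not found: {p}")
        if self.tail not in ("ge", "gt"):
            raise PipelineError(f"config: tail must be 'ge' or 'gt', got {self.tail!r}")

    @property
    def convention(self) -> TailConvention:
        return TailConvention(self.tail)


def regulon_db_from_collection(collection, species: str) -> RegulonDB:
    """Interpret a gene-set collection (one set per TF) as a regulon database."""
    regulons = {
        set_id: Regulon(tf_id=set_id, targets=genes, species=species)
        for set_id, (_name, genes) in collection.sets.items()
    }
    return RegulonDB(regulons=regulons, species=species)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage provenance."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig, log=None) -> dict:
    """Run every configured stage and write the report bundle to ``out_dir``.

    Returns the manifest dictionary.  Optional ``log`` is a callable
    receiving stage-tagged progress lines (e.g. ``click.echo`` to stderr).
    """
    cfg.validate()
    emit = log or (lambda msg: None)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    summary: list[str] = []
    warnings: list[str] = []

    with _stage("read-inputs"):
        de = read_de_table(cfg.de_table, species=cfg.species)
        tf_universe = read_gmt(cfg.tf_universe, kind="TF-universe")
        db = regulon_db_from_collection(
            read_gmt(cfg.regulons, kind="TF-universe"), species=cfg.species
        )
        emit(f"[read-inputs] {len(de)} genes, {len(db)} regulons")

    with _stage("discover-tfs"):
        selection = select_candidate_tfs(
            de, tf_universe, db, forced=cfg.forced, alpha=cfg.alpha
        )
        warnings += selection.warnings
        emit(f"[discover-tfs] {len(selection)} candidate TF(s)")

    with _stage("enrich"):
        rows = enrich_tfs(selection.candidates, db, de,
                          alpha=cfg.alpha, convention=cfg.convention)
        path = out / f"enrichment_{cfg.species}.tsv"
        write_enrichment_table(rows, path, allow_empty=True)
        outputs[f"enrichment_{cfg.species}"] = str(path)
        enriched_primary = [r.tf_id for r in rows if r.enriched]
        emit(f"[enrich] {len(enriched_primary)} enriched of {len(rows)}")

    enriched_secondary: list[str] = []
    if cfg.ortholog_map and cfg.de_table_secondary:
        with _stage("transfer-enrich"):
            omap = read_ortholog_map(cfg.ortholog_map, cfg.species,
                                     cfg.secondary_species)
            de2 = read_de_table(cfg.de_table_secondary,
                                species=cfg.secondary_species)
            transfer = transfer_db(db, omap)
            warnings += transfer.warnings
            candidate_keys = {c.tf_id for c in selection.candidates}
            tf_map = {}
            for tf in candidate_keys:
                homs = omap.homologs(tf)
                if homs:
                    tf_map[tf] = min(homs)
            cands2 = [
                CandidateTF(tf_id=tf_map[tf], log2fc=float("nan"), padj=None,
                            in_regulon_db=True, forced=False)
                for tf in sorted(candidate_keys)
                if tf in tf_map and tf_map[tf] in transfer.db
            ]
            rows2 = enrich_tfs(cands2, transfer.db, de2,
                               alpha=cfg.alpha, convention=cfg.convention)
            path = out / f"enrichment_{cfg.secondary_species}.tsv"
            write_enrichment_table(rows2, path, allow_empty=True)
            outputs[f"enrichment_{cfg.secondary_species}"] = str(path)
            enriched_secondary = [r.tf_id for r in rows2 if r.enriched]
            emit(f"[transfer-enrich] {len(enriched_secondary)} enriched "
                 f"of {len(rows2)} in {cfg.secondary_species}")

    if cfg.expression and cfg.sample_metadata:
        with _stage("correlate"):
            expr = read_expression(cfg.expression, cfg.sample_metadata)
            tf = cfg.correlate_tf or (rows[0].tf_id if rows else None)
            if tf is None:
                warnings.append("correlate stage skipped: no candidate TF")
                emit("[correlate] skipped (no candidate TF)")
            else:
                reg = db.get(tf)
                if reg is None:
                    raise PipelineError(
                        f"stage 'correlate': TF {tf!r} has no regulon"
                    )
                up = de.upregulated(cfg.alpha)
                corr_rows, passing, corr_warn = correlate_tf_targets(
                    expr, tf, reg.targets & up,
                    rho_min=cfg.rho_min, p_max=cfg.p_max,
                )
                warnings += corr_warn
                path = out / "correlations.tsv"
                with open(path, "w", encoding="utf-8", newline="") as fh:
                    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                    w.writerow(["tf", "target", "rho", "p", "n", "method"])
                    for r in sorted(corr_rows, key=lambda r: (-r.rho, r.gene_b)):
                        w.writerow([r.gene_a, r.gene_b, f"{r.rho:.4f}",
                                    f"{r.p:.3e}", r.n, r.method])
                outputs["correlations"] = str(path)
                summary.append(
                    f"{tf}: {passing} of {len(corr_rows)} upregulated targets "
                    f"pass rho > {cfg.rho_min}, p < {cfg.p_max}"
                )
                emit(f"[correlate] {passing}/{len(corr_rows)} targets pass")

    if cfg.pathway_collection:
        with _stage("pathways"):
            collection = read_gmt(cfg.pathway_collection, kind="pathway")
            up = de.upregulated(cfg.alpha)
            prows, ora_warn = ora(up, collection, de.expressed, cfg.convention)
            warnings += ora_warn
            overlay = tf_pathway_counts(prows, db, collection, up, top_n=cfg.top_n)
            warnings += overlay.warnings
            path = out / "pathways.tsv"
            tf_ids = sorted(db.regulons)
            with open(path, "w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["set_id", "name", "K_expressed", "k_up", "p", "padj"]
                           + [f"targets_{tf}" for tf in tf_ids])
                for r in prows:
                    counts = [r.tf_target_counts.get(tf, "") for tf in tf_ids]
                    w.writerow([r.set_id, r.name, r.K_expressed, r.k_up,
                                f"{r.p:.3e}", f"{r.padj:.3e}"] + counts)
            outputs["pathways"] = str(path)
            for tf, cnt in sorted(overlay.multiple_target_pathways.items()):
                summary.append(
                    f"{tf}: multiple targets in {cnt} of the top "
                    f"{len(overlay.rows)} pathways"
                )
            emit(f"[pathways] {sum(r.padj < 0.05 for r in prows)} significant sets")

    # headline: TFs enriched in the primary species, and (when the transfer
    # stage ran) whose ortholog regulon is enriched in the secondary species
    headline: list[str] = []
    if enriched_secondary:
        cross = []
        omap = read_ortholog_map(cfg.ortholog_map, cfg.species, cfg.secondary_species)
        for tf in enriched_primary:
            homs = omap.homologs(tf)
            if homs & {t.casefold() for t in enriched_secondary} or \
               homs & set(enriched_secondary):
                cross.append(tf)
        if cross:
            headline.append(
                "TF(s) with regulons enriched in both species: " + ", ".join(cross)
            )
    if enriched_primary and not headline:
        headline.append(
            f"TF(s) with enriched regulons in {cfg.species}: "
            + ", ".join(enriched_primary)
        )
    if not enriched_primary:
        headline.append("no TF regulon enriched at p < 0.05")

    summary_path = out / "summary.txt"
    with open(summary_path, "w", encoding="utf-8") as fh:
        for line in headline + summary:
            fh.write(line + "\n")
        if warnings:
            fh.write("\nwarnings:\n")
            for wmsg in warnings:
                fh.write(f"  - {wmsg}\n")
    outputs["summary"] = str(summary_path)

    manifest = {
        "tool": {"name": "regulonscan", "version": __version__},
        "seed": cfg.seed,
        "parameters": {
            "alpha": cfg.alpha, "rho_min": cfg.rho_min, "p_max": cfg.p_max,
            "tail": cfg.tail, "top_n": cfg.top_n, "forced": list(cfg.forced),
        },
        "inputs": {
            label: {"path": str(p), "sha256": _sha256(p)}
            for label in ("de_table", "regulons", "tf_universe",
                          "de_table_secondary", "ortholog_map", "expression",
                          "sample_metadata", "pathway_collection")
            if (p := getattr(cfg, label)) is not None
        },
        "outputs": {label: {"path": p, "sha256": _sha256(p)}
                    for label, p in outputs.items()},
        "headline": headline,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    emit(f"[done] manifest at {manifest_path}")
    return manifest
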