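"""End-to-end orchestration: annotation -> clusters -> blocks -> Ka/Ks -> expression.

`run_pipeline` executes every stage on the files named in a
:class:`PipelineConfig`, emits fixed-column TSV reports plus a JSON run
manifest, and is deterministic for a given config and seed (reports carry
no timestamps). The census helpers reproduce the family-identification
percentage arithmetic used in comparative-genome survey tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from crpevol.genome_io import (
    GenomeIOError,
    read_cds_fasta,
    read_expression_table,
    read_gff,
    read_pairs_table,
    read_subfamily_table,
    round_half_up,
    write_tsv,
)
from crpevol.clustering import cluster_summary, clusters_to_rows, detect_clusters
from crpevol.collinearity import (
    HomologPair,
    blocks_to_rows,
    chain_anchors,
    classify_duplicates,
    duplication_census,
)
from crpevol.kaks import (
    CodingPair,
    compute_kaks,
    kaks_to_rows,
    ks_density_peaks,
    likelihood_ratio_test,
    read_site_model_fits,
)
from crpevol.expression import (
    coordinated_expression,
    coordination_to_rows,
    divergence_by_class,
    divergence_to_rows,
    expression_divergence,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    annotation_path: str
    pairs_path: str
    output_dir: str
    cds_path: str | None = None
    peptides_path: str | None = None
    subfamily_path: str | None = None
    expression_path: str | None = None
    site_model_fits_path: str | None = None
    feature_type: str = "gene"
    max_gap_bp: int = 10_000
    max_evalue: float = 0.01
    min_anchors: int = 5
    max_gap_ranks: int = 25
    proximal_window_ranks: int = 20
    alpha: float = 0.05
    max_ks: float = 2.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise GenomeIOError(f"config {path}: expected a mapping")
        return cls(**data)

    def validate(self) -> None:
        for name in (
            "max_gap_bp", "max_evalue", "min_anchors", "max_gap_ranks",
            "proximal_window_ranks", "alpha", "max_ks",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        required = {"annotation_path": self.annotation_path, "pairs_path": self.pairs_path}
        optional = {
            "cds_path": self.cds_path,
            "peptides_path": self.peptides_path,
            "subfamily_path": self.subfamily_path,
            "expression_path": self.expression_path,
            "site_model_fits_path": self.site_model_fits_path,
        }
        for name, p in required.items():
            if not p:
                raise ValueError(f"config: {name} is required")
            if not Path(p).exists():
                raise FileNotFoundError(f"config: {name} {p!r} does not exist")
        for name, p in optional.items():
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config: {name} {p!r} does not exist")


def percentage(numerator: int, denominator: int) -> str:
    """Half-up two-decimal percent string, e.g. (401, 786) -> "51.02%"."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    return f"{round_half_up(100.0 * numerator / denominator, 2):.2f}%"


def family_census(counts: dict[str, int]) -> dict:
    """Total family size and per-source percentage of the total."""
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    total = sum(counts.values())
    fractions = {
        src: percentage(n, total) if total else "0.00%" for src, n in counts.items()
    }
    return {"total": total, "fractions": fractions}


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage and return a mapping report-name -> file path."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("crpevol")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    reports: dict[str, str] = {"log": str(log_path)}
    try:
        annotation = _stage("genome_io")(read_gff)(
            config.annotation_path, config.feature_type
        )
        pair_rows = _stage("genome_io")(read_pairs_table)(
            config.pairs_path, config.max_evalue
        )
        pairs = [HomologPair(a, b, sc, ev) for a, b, sc, ev in pair_rows]
        if config.subfamily_path:
            subfams = read_subfamily_table(config.subfamily_path)
            family_ids = [g.gene_id for g in annotation if g.gene_id in subfams]
        else:
            family_ids = [g.gene_id for g in annotation]
        family_set = set(family_ids)
        family_genes = [g for g in annotation if g.gene_id in family_set]
        logger.info("pipeline: %d genes, %d family, %d homolog pairs",
                    len(annotation), len(family_ids), len(pairs))

        # clustering
        clusters = _stage("clustering")(detect_clusters)(
            family_genes, config.max_gap_bp
        )
        stats = cluster_summary(clusters, len(family_ids))
        write_tsv(
            clusters_to_rows(clusters),
            out / "clusters.tsv",
            ["cluster_id", "chromosome", "span_start", "span_end", "size", "members"],
        )
        write_tsv(
            [
                {
                    "n_clusters": stats.n_clusters,
                    "n_clusters_gt2": stats.n_clusters_gt2,
                    "n_clustered_genes": stats.n_clustered_genes,
                    "fraction_clustered_pct": f"{stats.fraction_clustered:.2f}",
                }
            ],
            out / "cluster_stats.tsv",
        )
        reports["clusters"] = str(out / "clusters.tsv")
        reports["cluster_stats"] = str(out / "cluster_stats.tsv")

        # collinearity + classification
        blocks = _stage("collinearity")(chain_anchors)(
            pairs, annotation, config.max_gap_ranks, config.min_anchors
        )
        classes = _stage("collinearity")(classify_duplicates)(
            family_ids, pairs, blocks, annotation, config.proximal_window_ranks
        )
        census = duplication_census(classes)
        write_tsv(
            blocks_to_rows(blocks),
            out / "blocks.tsv",
            ["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "anchors"],
        )
        write_tsv(
            [{"gene_id": g, "duplication_class": c.value} for g, c in sorted(classes.items())],
            out / "classification.tsv",
            ["gene_id", "duplication_class"],
        )
        write_tsv(
            [
                {"class": k, "count": v["count"], "percent": f"{v['percent']:.2f}"}
                for k, v in census.items()
            ],
            out / "duplication_census.tsv",
            ["class", "count", "percent"],
        )
        reports["blocks"] = str(out / "blocks.tsv")
        reports["classification"] = str(out / "classification.tsv")
        reports["duplication_census"] = str(out / "duplication_census.tsv")

        # Ka/Ks
        if config.cds_path:
            cds = _stage("kaks")(read_cds_fasta)(config.cds_path)
            results = []
            for p in pairs:
                if p.gene_a in cds and p.gene_b in cds:
                    sa, sb = cds[p.gene_a], cds[p.gene_b]
                    if len(sa) != len(sb):
                        logger.info("kaks: skipping unequal-length pair (%s,%s)",
                                    p.gene_a, p.gene_b)
                        continue
                    results.append(
                        _stage("kaks")(compute_kaks)(
                            CodingPair(p.gene_a, p.gene_b, sa, sb), config.alpha
                        )
                    )
            write_tsv(
                kaks_to_rows(results),
                out / "kaks.tsv",
                ["gene_a", "gene_b", "S", "N", "Sd", "Nd", "Ka", "Ks", "Ka_Ks",
                 "p_value", "selection"],
            )
            reports["kaks"] = str(out / "kaks.tsv")
            ks_vals = [r.ks for r in results if r.ks is not None and r.ks > 0]
            n_null = sum(1 for r in results if r.ks is None or r.ka is None)
            logger.info("kaks: %d pairs, %d null values removed", len(results), n_null)
            if len([v for v in ks_vals if v < config.max_ks]) >= 10:
                peaks = ks_density_peaks(ks_vals, config.max_ks)
                write_tsv(
                    [{"peak_rank": i + 1, "ks": f"{k:.4f}"} for i, k in enumerate(peaks)],
                    out / "ks_peaks.tsv",
                    ["peak_rank", "ks"],
                )
                reports["ks_peaks"] = str(out / "ks_peaks.tsv")
            else:
                logger.info("kaks: too few Ks values for density peaks; skipped")

        # LRT on supplied site-model fits
        if config.site_model_fits_path:
            fits = _stage("lrt")(read_site_model_fits)(config.site_model_fits_path)
            rows = []
            for null_name, alt_name, df in (("M0", "M8", 2), ("M7", "M8", 2)):
                if null_name in fits and alt_name in fits:
                    stat, p = likelihood_ratio_test(fits[null_name], fits[alt_name], df)
                    rows.append(
                        {
                            "null": null_name,
                            "alt": alt_name,
                            "df": df,
                            "statistic": f"{stat:.5f}",
                            "p_value": f"{p:.6g}",
                        }
                    )
            write_tsv(rows, out / "lrt.tsv", ["null", "alt", "df", "statistic", "p_value"])
            reports["lrt"] = str(out / "lrt.tsv")

        # expression divergence and cluster coordination
        if config.expression_path:
            matrix = _stage("expression")(read_expression_table)(config.expression_path)
            expr_pairs = [
                (p.gene_a, p.gene_b)
                for p in pairs
                if p.gene_a in matrix and p.gene_b in matrix
            ]
            records = _stage("expression")(expression_divergence)(
                matrix, expr_pairs, classes
            )
            write_tsv(
                divergence_to_rows(records),
                out / "divergence.tsv",
                ["gene_a", "gene_b", "correlation", "divergence", "duplication_class"],
            )
            reports["divergence"] = str(out / "divergence.tsv")
            if records:
                summaries, ordering = divergence_by_class(records)
                write_tsv(
                    [
                        {"class": k, **{kk: f"{vv:.6g}" for kk, vv in v.items()}}
                        for k, v in sorted(summaries.items())
                    ],
                    out / "divergence_by_class.tsv",
                    ["class", "n", "q1", "median", "q3"],
                )
                (out / "divergence_ordering.txt").write_text(ordering + "\n")
                reports["divergence_by_class"] = str(out / "divergence_by_class.tsv")
            coord_rows = []
            for i, cluster in enumerate(clusters):
                present = [g for g in cluster.member_ids if g in matrix]
                if len(present) < 2:
                    continue
                recs = _stage("expression")(coordinated_expression)(cluster, matrix)
                coord_rows.extend(coordination_to_rows(recs, f"cluster_{i + 1}"))
            write_tsv(
                coord_rows,
                out / "coordination.tsv",
                ["cluster_id", "gene_a", "gene_b", "abs_r", "p_value", "stars"],
            )
            reports["coordination"] = str(out / "coordination.tsv")

        from crpevol import __version__ as pkg_version

        manifest = {
            "package": "crpevol",
            "version": pkg_version,
            "config": asdict(config),
            "reports": sorted(reports),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        reports["manifest"] = str(out / "manifest.json")
    finally:
        root.removeHandler(handler)
        handler.close()
    return reports
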