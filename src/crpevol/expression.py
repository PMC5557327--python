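"""Expression divergence and coordination of duplicate genes.

Divergence between a duplicate pair is 1 - r, with r the signed Pearson
correlation of the two genes' RPKM profiles across developmental stages
(so perfectly anti-correlated duplicates are maximally divergent at 2).
Coordination within a chromosome cluster is reported as |r| with the
t-distribution significance and the conventional star codes. Also here:
the 2^-ddCt relative-expression estimator for qPCR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from crpevol.clustering import GeneCluster
from crpevol.collinearity import DuplicationClass
from crpevol.genome_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DivergenceRecord:
    gene_a: str
    gene_b: str
    correlation: float
    divergence: float  # 1 - correlation, in [0, 2]
    duplication_class: DuplicationClass | None = None


@dataclass(frozen=True)
class CoordinationRecord:
    gene_a: str
    gene_b: str
    abs_r: float
    p_value: float
    stars: str  # "" | "*" (p<0.05) | "**" (p<0.01)


def _prepare(profile: np.ndarray, log2p1: bool) -> np.ndarray:
    return np.log2(profile + 1.0) if log2p1 else profile


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Signed Pearson r; None when either profile has zero variance."""
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def expression_divergence(
    matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    class_map: dict[str, DuplicationClass] | None = None,
    use_abs: bool = False,
    log2p1: bool = False,
) -> list[DivergenceRecord]:
    """1 - Pearson divergence for each duplicate pair across stages.

    Raw RPKM by default (``log2p1`` applies log2(x+1) first); signed r by
    default (``use_abs`` switches to |r|). Pairs with a zero-variance
    profile are skipped and logged. A pair's duplication class, when a
    ``class_map`` is given, is the class shared by its genes (or of gene_a).
    """
    if len(matrix.stage_ids) < 3:
        raise ValueError("need >= 3 stages for correlation")
    records: list[DivergenceRecord] = []
    skipped = 0
    for a, b in pairs:
        if a not in matrix or b not in matrix:
            raise KeyError(f"pair ({a},{b}): gene missing from expression matrix")
        x = _prepare(matrix.profile(a), log2p1)
        y = _prepare(matrix.profile(b), log2p1)
        r = _pearson(x, y)
        if r is None:
            skipped += 1
            continue
        if use_abs:
            r = abs(r)
        cls = class_map.get(a) if class_map else None
        records.append(
            DivergenceRecord(
                gene_a=a, gene_b=b, correlation=r, divergence=1.0 - r,
                duplication_class=cls,
            )
        )
    if skipped:
        logger.info("expression_divergence: skipped %d zero-variance pairs", skipped)
    return records


def divergence_by_class(
    records: list[DivergenceRecord],
    tie_margin: float = 0.05,
) -> tuple[dict[str, dict[str, float]], str]:
    """Per-class divergence summaries and a median-ordered class string.

    Classes are ordered by descending median divergence; medians within
    ``tie_margin`` of the previous class are joined with an approximate sign,
    e.g. ``"singleton > tandem > wgd_segmental ≈ proximal > dispersed"``.
    """
    if not records:
        raise ValueError("no divergence records")
    grouped: dict[str, list[float]] = {}
    for rec in records:
        key = rec.duplication_class.value if rec.duplication_class else "unclassified"
        grouped.setdefault(key, []).append(rec.divergence)
    summaries: dict[str, dict[str, float]] = {}
    for key, vals in grouped.items():
        arr = np.asarray(vals)
        summaries[key] = {
            "n": int(arr.size),
            "q1": float(np.percentile(arr, 25)),
            "median": float(np.median(arr)),
            "q3": float(np.percentile(arr, 75)),
        }
    ordered = sorted(summaries, key=lambda k: -summaries[k]["median"])
    parts = [ordered[0]]
    for prev, cur in zip(ordered, ordered[1:]):
        gap = summaries[prev]["median"] - summaries[cur]["median"]
        parts.append("≈" if gap < tie_margin else ">")
        parts.append(cur)
    return summaries, " ".join(parts)


def correlation_p_value(r: float, n_stages: int) -> float:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)), n-2 df."""
    if n_stages < 3:
        raise ValueError("need >= 3 stages")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n_stages - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n_stages - 2))


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def coordinated_expression(
    cluster: GeneCluster,
    matrix: ExpressionMatrix,
) -> list[CoordinationRecord]:
    """|r| with significance stars for every within-cluster gene pair.

    Members absent from the matrix or with zero-variance profiles are
    skipped with a log entry; at least two members must remain.
    """
    if len(matrix.stage_ids) < 3:
        raise ValueError("need >= 3 stages for correlation")
    present = []
    for gid in cluster.member_ids:
        if gid in matrix:
            present.append(gid)
        else:
            logger.info("coordinated_expression: %s absent from matrix", gid)
    if len(present) < 2:
        raise ValueError("fewer than 2 cluster members in the expression matrix")
    n = len(matrix.stage_ids)
    out: list[CoordinationRecord] = []
    for a, b in combinations(present, 2):
        r = _pearson(matrix.profile(a), matrix.profile(b))
        if r is None:
            logger.info("coordinated_expression: zero-variance pair (%s,%s)", a, b)
            continue
        p = correlation_p_value(r, n)
        out.append(
            CoordinationRecord(gene_a=a, gene_b=b, abs_r=abs(r), p_value=p, stars=_stars(p))
        )
    return out


def relative_expression_ddct(
    ct_target_sample,
    ct_ref_sample,
    ct_target_calibrator,
    ct_ref_calibrator,
) -> float:
    """Fold change by the 2^-ddCt method.

    Each argument is a threshold cycle or an iterable of replicate Ct values,
    which are averaged first. ddCt = (Ct_target - Ct_ref)_sample -
    (Ct_target - Ct_ref)_calibrator; the fold change is 2^-ddCt.
    """

    def mean_ct(v, name: str) -> float:
        vals = np.atleast_1d(np.asarray(v, dtype=float))
        if vals.size == 0:
            raise ValueError(f"{name}: missing replicate values")
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError(f"{name}: Ct values must be finite and > 0")
        return float(vals.mean())

    ddct = (
        mean_ct(ct_target_sample, "ct_target_sample")
        - mean_ct(ct_ref_sample, "ct_ref_sample")
    ) - (
        mean_ct(ct_target_calibrator, "ct_target_calibrator")
        - mean_ct(ct_ref_calibrator, "ct_ref_calibrator")
    )
    return float(2.0 ** (-ddct))


def standardise_to_stage(matrix: ExpressionMatrix, stage_id: str) -> ExpressionMatrix:
    """Scale each gene's profile to its value at a reference stage.

    Report option for expressing profiles relative to (e.g.) mature pollen;
    genes with zero expression at the reference stage are left unscaled.
    """
    if stage_id not in matrix.stage_ids:
        raise KeyError(f"unknown stage {stage_id!r}")
    df = matrix.values.copy()
    ref = df[stage_id]
    scale = ref.where(ref > 0, 1.0)
    return ExpressionMatrix.from_dataframe(df.div(scale, axis=0))


def divergence_to_rows(records: list[DivergenceRecord]) -> list[dict]:
    return [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "correlation": f"{r.correlation:.6g}",
            "divergence": f"{r.divergence:.6g}",
            "duplication_class": (
                r.duplication_class.value if r.duplication_class else "NA"
            ),
        }
        for r in records
    ]


def coordination_to_rows(
    records: list[CoordinationRecord], cluster_id: str = ""
) -> list[dict]:
    return [
        {
            "cluster_id": cluster_id,
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "abs_r": f"{r.abs_r:.3f}",
            "p_value": f"{r.p_value:.6g}",
            "stars": r.stars,
        }
        for r in records
    ]
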