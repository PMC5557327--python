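"""Synthetic genomes, codon pairs and expression profiles with known truth.

Generators emit the same GFF3/TSV/FASTA dialects the readers consume, plus
a :class:`SyntheticTruth` ledger naming every planted structure: chromosome
clusters (internal gaps at a chosen value, background spacing wide enough
to never cluster), tandem homolog arrays at consecutive ranks, rank-
preserving collinear segments across chromosomes, codon pairs with exact
planted synonymous/nonsynonymous difference counts, and expression profiles
with a target pairwise correlation. Every generator is a pure function of
its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from crpevol.genome_io import CodingPair, ExpressionMatrix, GeneModel, _assign_ranks
from crpevol.kaks import _AA, _STOPS, _BASES

# background spacing guarantees no accidental clusters under the 10 kb rule
_BG_GAP_LO, _BG_GAP_HI = 10_001, 50_000
_GENE_LEN_LO, _GENE_LEN_HI = 300, 3_000
_TANDEM_ARRAY_LEN = 3  # longer arrays would chain into a collinear block
_CLUSTER_SIZES = (2, 3, 4)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one synthetic dataset."""

    seed: int
    planted_clusters: list[list[str]] = field(default_factory=list)
    planted_tandem_arrays: list[list[str]] = field(default_factory=list)
    planted_collinear_segments: list[list[tuple[str, str]]] = field(default_factory=list)
    planted_pair_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_correlations: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


class CapacityError(ValueError):
    """Requested planted structures exceed chromosome capacity."""


def _one_step_neighbors(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for base in _BASES:
            if base != codon[pos]:
                out.append(codon[:pos] + base + codon[pos + 1 :])
    return out


_SENSE = sorted(_AA)
_SYN_CAPABLE = sorted(
    c for c in _SENSE
    if any(n not in _STOPS and _AA[n] == _AA[c] for n in _one_step_neighbors(c))
)
_NONSYN_CAPABLE = sorted(
    c for c in _SENSE
    if any(n not in _STOPS and _AA[n] != _AA[c] for n in _one_step_neighbors(c))
)


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(
    n_chromosomes: int,
    genes_per_chromosome: int,
    n_clusters: int,
    cluster_gap_bp: int,
    n_tandem_arrays: int,
    n_collinear_segments: int,
    segment_length_anchors: int,
    seed: int,
) -> tuple[list[GeneModel], list[tuple[str, str, float, float]], SyntheticTruth]:
    """Simulate one annotated genome with planted clusters, arrays and segments.

    Background genes are spaced 10 001–50 000 bp apart so only planted
    clusters (all internal gaps exactly ``cluster_gap_bp``) satisfy the 10 kb
    cluster rule. Tandem arrays are three-gene homolog runs at consecutive
    ranks; collinear segments are rank-preserving homolog runs across two
    chromosomes. Returns (annotation, homolog-pair rows, truth ledger).
    """
    if cluster_gap_bp >= 10_000:
        raise ValueError("cluster_gap_bp must be < 10000 to be detectable")
    if n_collinear_segments and segment_length_anchors < 5:
        raise ValueError("segment_length_anchors must be >= 5")
    if n_collinear_segments and n_chromosomes < 2:
        raise CapacityError("collinear segments need >= 2 chromosomes")
    rng = np.random.default_rng(seed)

    chroms = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
    cursors = {c: 0 for c in chroms}
    # homolog-bearing runs must sit further apart in rank than the chaining
    # gap limit, or anchors of neighbouring structures would chain together
    anchor_spacer = 26

    def alloc(length: int, spacer: int, exclude: str | None = None) -> tuple[str, range]:
        # least-used chromosome with room for the run
        open_chroms = [
            c for c in chroms
            if c != exclude and cursors[c] + length <= genes_per_chromosome
        ]
        if not open_chroms:
            raise CapacityError(
                f"no chromosome has room for a run of {length} genes"
            )
        c = min(open_chroms, key=lambda c: (cursors[c], c))
        run = range(cursors[c], cursors[c] + length)
        cursors[c] += length + spacer
        return c, run

    # structure -> set of (chrom, index) memberships
    cluster_runs: list[tuple[str, range]] = []
    tandem_runs: list[tuple[str, range]] = []
    segment_runs: list[tuple[tuple[str, range], tuple[str, range]]] = []
    for _ in range(n_collinear_segments):
        a = alloc(segment_length_anchors, anchor_spacer)
        b = alloc(segment_length_anchors, anchor_spacer, exclude=a[0])
        segment_runs.append((a, b))
    for _ in range(n_tandem_arrays):
        tandem_runs.append(alloc(_TANDEM_ARRAY_LEN, anchor_spacer))
    cluster_sizes = rng.choice(_CLUSTER_SIZES, size=n_clusters) if n_clusters else []
    for size in cluster_sizes:
        cluster_runs.append(alloc(int(size), 1))

    # gaps: positions (chrom, i) whose gap to the previous gene is the cluster gap
    cluster_gap_at: set[tuple[str, int]] = set()
    for chrom, run in cluster_runs:
        for i in run[1:]:
            cluster_gap_at.add((chrom, i))

    genes: list[GeneModel] = []
    gid_of: dict[tuple[str, int], str] = {}
    counter = 0
    for chrom in chroms:
        pos = 1
        for i in range(genes_per_chromosome):
            counter += 1
            gid = f"g{counter:05d}"
            gid_of[(chrom, i)] = gid
            if i > 0:
                if (chrom, i) in cluster_gap_at:
                    gap = cluster_gap_bp
                else:
                    gap = int(rng.integers(_BG_GAP_LO, _BG_GAP_HI + 1))
                pos = pos + gap
            length = int(rng.integers(_GENE_LEN_LO, _GENE_LEN_HI + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, chrom, pos, pos + length - 1, strand))
            pos = pos + length
    genes = _assign_ranks(genes)

    pairs: list[tuple[str, str, float, float]] = []
    truth = SyntheticTruth(seed=seed)
    for chrom, run in cluster_runs:
        truth.planted_clusters.append([gid_of[(chrom, i)] for i in run])
    for chrom, run in tandem_runs:
        ids = [gid_of[(chrom, i)] for i in run]
        truth.planted_tandem_arrays.append(ids)
        for a, b in zip(ids, ids[1:]):
            pairs.append((a, b, 200.0, 1e-30))
    for (ca, ra), (cb, rb) in segment_runs:
        anchors = [
            (gid_of[(ca, i)], gid_of[(cb, j)]) for i, j in zip(ra, rb)
        ]
        truth.planted_collinear_segments.append(anchors)
        for a, b in anchors:
            pairs.append((a, b, 500.0, 1e-50))
    pairs.sort()
    return genes, pairs, truth


# ---------------------------------------------------------------------------
# Codon pairs


def simulate_codon_pair(
    n_codons: int,
    syn_changes: int,
    nonsyn_changes: int,
    seed: int,
) -> tuple[CodingPair, tuple[int, int]]:
    """A coding pair differing by exactly the requested one-step codon edits.

    Each edit changes one nucleotide in a distinct codon: synonymous edits
    use a one-step synonymous neighbour, nonsynonymous edits a one-step
    nonsynonymous non-stop neighbour, so NG86 pathway averaging recovers the
    planted (Sd, Nd) exactly. Returns (pair, (Sd_true, Nd_true)).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if syn_changes < 0 or nonsyn_changes < 0:
        raise ValueError("change counts must be >= 0")
    if syn_changes + nonsyn_changes > n_codons:
        raise ValueError(
            f"cannot place {syn_changes + nonsyn_changes} single-codon edits "
            f"in {n_codons} codons"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_codons)
    syn_pos = set(perm[:syn_changes].tolist())
    nonsyn_pos = set(perm[syn_changes : syn_changes + nonsyn_changes].tolist())
    codons_a: list[str] = []
    for i in range(n_codons):
        if i in syn_pos:
            pool = _SYN_CAPABLE
        elif i in nonsyn_pos:
            pool = _NONSYN_CAPABLE
        else:
            pool = _SENSE
        codons_a.append(pool[int(rng.integers(len(pool)))])
    codons_b = list(codons_a)
    for i in sorted(syn_pos):
        opts = sorted(
            n for n in _one_step_neighbors(codons_a[i])
            if n not in _STOPS and _AA[n] == _AA[codons_a[i]]
        )
        codons_b[i] = opts[int(rng.integers(len(opts)))]
    for i in sorted(nonsyn_pos):
        opts = sorted(
            n for n in _one_step_neighbors(codons_a[i])
            if n not in _STOPS and _AA[n] != _AA[codons_a[i]]
        )
        codons_b[i] = opts[int(rng.integers(len(opts)))]
    pair = CodingPair("simA", "simB", "".join(codons_a), "".join(codons_b))
    return pair, (syn_changes, nonsyn_changes)


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    gene_pairs: list[tuple[str, str]],
    target_correlation: float,
    n_stages: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression profiles whose pairwise correlation targets a chosen value.

    Each pair is a bivariate-Gaussian draw with correlation
    ``target_correlation`` (exact at ``noise_sd`` 0; independent measurement
    noise of sd ``noise_sd`` attenuates it by 1/(1+noise_sd^2)), then mapped
    to non-negative RPKM-like values by a per-gene positive-scale shift,
    which leaves the Pearson correlation untouched.
    """
    if abs(target_correlation) > 1:
        raise ValueError("|target_correlation| must be <= 1")
    if n_stages < 3:
        raise ValueError("n_stages must be >= 3")
    seen: set[str] = set()
    for a, b in gene_pairs:
        for g in (a, b):
            if g in seen:
                raise ValueError(f"gene {g!r} appears in more than one pair")
            seen.add(g)
    rng = np.random.default_rng(seed)
    rho = float(target_correlation)
    rows: dict[str, np.ndarray] = {}
    truth = SyntheticTruth(seed=seed)
    for a, b in gene_pairs:
        z = rng.standard_normal(n_stages)
        eps = rng.standard_normal(n_stages)
        x = z.copy()
        y = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        if noise_sd:
            x = x + noise_sd * rng.standard_normal(n_stages)
            y = y + noise_sd * rng.standard_normal(n_stages)
        rows[a] = 20.0 * (x - x.min())
        rows[b] = 20.0 * (y - y.min())
        truth.planted_correlations[f"{a}|{b}"] = rho
    stage_ids = [f"S{i + 1}" for i in range(n_stages)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=stage_ids)
    return ExpressionMatrix.from_dataframe(df), truth


# ---------------------------------------------------------------------------
# Truth serialization


def write_truth(truth: SyntheticTruth, directory: str | Path) -> None:
    """Write the truth ledger: TSVs per structure plus a JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "truth.json").write_text(truth.to_json() + "\n")
    lines = ["structure\tindex\tcontent"]
    for i, members in enumerate(truth.planted_clusters):
        lines.append(f"cluster\t{i}\t{','.join(members)}")
    for i, members in enumerate(truth.planted_tandem_arrays):
        lines.append(f"tandem_array\t{i}\t{','.join(members)}")
    for i, anchors in enumerate(truth.planted_collinear_segments):
        content = ";".join(f"{a}|{b}" for a, b in anchors)
        lines.append(f"collinear_segment\t{i}\t{content}")
    for key, (sd, nd) in sorted(truth.planted_pair_counts.items()):
        lines.append(f"pair_counts\t{key}\t{sd},{nd}")
    for key, rho in sorted(truth.planted_correlations.items()):
        lines.append(f"correlation\t{key}\t{rho:g}")
    (d / "truth.tsv").write_text("\n".join(lines) + "\n")


def read_truth(directory: str | Path) -> SyntheticTruth:
    data = json.loads((Path(directory) / "truth.json").read_text())
    data["planted_collinear_segments"] = [
        [tuple(a) for a in seg] for seg in data["planted_collinear_segments"]
    ]
    data["planted_pair_counts"] = {
        k: tuple(v) for k, v in data["planted_pair_counts"].items()
    }
    return SyntheticTruth(**data)
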