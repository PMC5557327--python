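"""Collinear-block chaining and duplicate-gene classification.

Homolog pairs between two chromosomal regions are chained into collinear
blocks (evidence of whole-genome/segmental duplication) by iterated
maximum-weight chaining, in the style of synteny tools such as MCScanX.
Every family gene is then assigned one of five duplication classes:
wgd_segmental, tandem, proximal, dispersed or singleton, in that precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from crpevol.genome_io import GeneModel, round_half_up


class DuplicationClass(str, Enum):
    SINGLETON = "singleton"
    DISPERSED = "dispersed"
    PROXIMAL = "proximal"
    TANDEM = "tandem"
    WGD_SEGMENTAL = "wgd_segmental"


@dataclass(frozen=True)
class HomologPair:
    """A similarity edge between two distinct genes, stored in canonical id order."""

    gene_a: str
    gene_b: str
    score: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if self.evalue < 0:
            raise ValueError("negative E-value")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class CollinearBlock:
    """A chained run of anchors between two chromosomal regions."""

    anchors: tuple[HomologPair, ...]
    chrom_pair: tuple[str, str]
    orientation: str  # "parallel" | "antiparallel"

    @property
    def score(self) -> int:
        return len(self.anchors)


def _gene_index(annotation: list[GeneModel]) -> dict[str, GeneModel]:
    return {g.gene_id: g for g in annotation}


def _anchor_positions(
    pairs: list[HomologPair], index: dict[str, GeneModel]
) -> dict[tuple[str, str], list[tuple[int, int, HomologPair]]]:
    """Group anchors by unordered chromosome pair as (rank_A, rank_B, pair).

    rank_A is the rank on the lexically smaller chromosome of the pair; for
    same-chromosome anchors rank_A is the smaller of the two ranks.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for p in pairs:
        for gid in p.genes:
            if gid not in index:
                raise KeyError(f"pair references unknown gene {gid!r}")
        ga, gb = index[p.gene_a], index[p.gene_b]
        if (ga.chromosome, ga.rank) > (gb.chromosome, gb.rank):
            ga, gb = gb, ga
        key = (ga.chromosome, gb.chromosome)
        grouped.setdefault(key, []).append((ga.rank, gb.rank, p))
    return grouped


def _best_chain(
    anchors: list[tuple[int, int, HomologPair]],
    orientation: str,
    max_gap_ranks: int,
) -> list[tuple[int, int, HomologPair]]:
    """Canonical maximum-weight chain (weight = anchor count) for one orientation.

    Among equal-weight chains, returns the lexicographically smallest sequence
    of (rank_A, rank_B) positions, which makes extraction deterministic.
    """
    if not anchors:
        return []
    items = sorted(anchors, key=lambda t: (t[0], t[1]))
    n = len(items)
    sign = 1 if orientation == "parallel" else -1

    def edge(i: int, j: int) -> bool:
        da = items[j][0] - items[i][0]
        db = sign * (items[j][1] - items[i][1])
        return 0 < da <= max_gap_ranks and 0 < db <= max_gap_ranks

    # L[i]: longest chain starting at i (following sorted order only, since
    # edges require strictly increasing rank_A)
    L = [1] * n
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            if edge(i, j) and L[j] + 1 > L[i]:
                L[i] = L[j] + 1
    best = max(L)
    # canonical reconstruction: earliest eligible anchor at each step
    chain: list[tuple[int, int, HomologPair]] = []
    cur = next(i for i in range(n) if L[i] == best)
    chain.append(items[cur])
    need = best - 1
    while need:
        nxt = next(
            j for j in range(cur + 1, n) if edge(cur, j) and L[j] == need
        )
        chain.append(items[nxt])
        cur = nxt
        need -= 1
    return chain


def chain_anchors(
    pairs: list[HomologPair],
    annotation: list[GeneModel],
    max_gap_ranks: int = 25,
    min_anchors: int = 5,
) -> list[CollinearBlock]:
    """Chain homolog anchors into collinear blocks by iterated best-chain extraction.

    Per chromosome pair, anchors are placed on a rank-vs-rank grid and the
    maximum-weight chain (anchor count; consecutive rank gaps in (0,
    ``max_gap_ranks``] on both axes, rank_B monotone per orientation) is
    extracted; its anchors are removed and chaining repeats until no chain of
    at least ``min_anchors`` remains. Ties between orientations break to the
    earlier rank_A start, then parallel-first.
    """
    index = _gene_index(annotation)
    grouped = _anchor_positions(pairs, index)
    blocks: list[CollinearBlock] = []
    for key in sorted(grouped):
        remaining = grouped[key]
        while True:
            candidates = []
            for orientation in ("parallel", "antiparallel"):
                chain = _best_chain(remaining, orientation, max_gap_ranks)
                if len(chain) >= min_anchors:
                    candidates.append((orientation, chain))
            if not candidates:
                break
            orientation, chain = min(
                candidates,
                key=lambda c: (-len(c[1]), c[1][0][0], c[0] != "parallel"),
            )
            blocks.append(
                CollinearBlock(
                    anchors=tuple(a[2] for a in chain),
                    chrom_pair=key,
                    orientation=orientation,
                )
            )
            used = {id(a[2]) for a in chain}
            remaining = [a for a in remaining if id(a[2]) not in used]
    return blocks


def classify_duplicates(
    family_ids: list[str],
    pairs: list[HomologPair],
    blocks: list[CollinearBlock],
    annotation: list[GeneModel],
    proximal_window_ranks: int = 20,
) -> dict[str, DuplicationClass]:
    """Assign each family gene its duplication class by fixed precedence.

    (1) wgd_segmental if the gene anchors any collinear block; else (2)
    tandem if it has a homolog at the adjacent rank on the same chromosome;
    else (3) proximal if a same-chromosome homolog lies within
    ``proximal_window_ranks`` ranks; else (4) dispersed if it has any
    homolog; else (5) singleton. Ranks are full-annotation ranks.
    """
    index = _gene_index(annotation)
    anchor_genes: set[str] = set()
    for b in blocks:
        for p in b.anchors:
            anchor_genes.update(p.genes)
    partners: dict[str, set[str]] = {}
    for p in pairs:
        partners.setdefault(p.gene_a, set()).add(p.gene_b)
        partners.setdefault(p.gene_b, set()).add(p.gene_a)
    out: dict[str, DuplicationClass] = {}
    for gid in family_ids:
        gene = index[gid]
        if gid in anchor_genes:
            out[gid] = DuplicationClass.WGD_SEGMENTAL
            continue
        mates = partners.get(gid, set())
        if not mates:
            out[gid] = DuplicationClass.SINGLETON
            continue
        deltas = [
            abs(index[m].rank - gene.rank)
            for m in mates
            if m in index and index[m].chromosome == gene.chromosome
        ]
        if any(d == 1 for d in deltas):
            out[gid] = DuplicationClass.TANDEM
        elif any(1 < d <= proximal_window_ranks for d in deltas):
            out[gid] = DuplicationClass.PROXIMAL
        else:
            out[gid] = DuplicationClass.DISPERSED
    return out


def duplication_census(
    mapping: dict[str, DuplicationClass],
) -> dict[str, dict[str, float]]:
    """Per-class gene counts and half-up two-decimal percentages."""
    if not mapping:
        raise ValueError("empty family: nothing to census")
    total = len(mapping)
    out: dict[str, dict[str, float]] = {}
    for cls in DuplicationClass:
        n = sum(1 for v in mapping.values() if v is cls)
        out[cls.value] = {
            "count": n,
            "percent": round_half_up(100.0 * n / total, 2),
        }
    return out


def blocks_to_rows(blocks: list[CollinearBlock]) -> list[dict]:
    return [
        {
            "block_id": f"block_{i + 1}",
            "chrom_a": b.chrom_pair[0],
            "chrom_b": b.chrom_pair[1],
            "orientation": b.orientation,
            "n_anchors": b.score,
            "anchors": ";".join(f"{p.gene_a}|{p.gene_b}" for p in b.anchors),
        }
        for i, b in enumerate(blocks)
    ]
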