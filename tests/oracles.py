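"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package
implementation: genetic-code enumeration through Biopython translation,
hypergeometric enumeration for the exact test, exhaustive subset
enumeration for chain finding, union-find for cluster components, and the
textbook Bartlett formula.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def codon_sites_oracle(codon: str) -> tuple[float, float]:
    """NG86 site fractions of one codon by direct enumeration of all 9 changes.

    Stop-codon changes count as nonsynonymous (the default policy).
    """
    aa = translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOPS and translate(alt) == aa:
                syn += 1.0
    s = syn / 3.0
    return s, 3.0 - s


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher probability of [[a,b],[c,d]] by hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def chi2_sf_df2_oracle(x: float) -> float:
    """Upper chi-square tail with 2 df has the closed form exp(-x/2)."""
    return math.exp(-x / 2.0)


def _chain_valid(points: list[tuple[int, int]], sign: int, max_gap: int) -> bool:
    for (ra1, rb1), (ra2, rb2) in zip(points, points[1:]):
        da = ra2 - ra1
        db = sign * (rb2 - rb1)
        if not (0 < da <= max_gap and 0 < db <= max_gap):
            return False
    return True


def best_chain_oracle(
    anchors: list[tuple[int, int]], max_gap: int
) -> tuple[list[tuple[int, int]], str] | None:
    """Canonical maximum-weight chain by exhaustive subset enumeration.

    Mirrors the chainer's tie-break contract: weight first, then earlier
    rank_A start, then parallel before antiparallel, then the
    lexicographically smallest position sequence. None when no chain of
    length >= 1 exists (only when there are no anchors).
    """
    if not anchors:
        return None
    n = len(anchors)
    best: tuple | None = None
    for mask in range(1, 1 << n):
        sub = sorted(
            (anchors[i] for i in range(n) if mask >> i & 1),
            key=lambda t: (t[0], t[1]),
        )
        for orientation, sign in (("parallel", 1), ("antiparallel", -1)):
            if not _chain_valid(sub, sign, max_gap):
                continue
            key = (-len(sub), sub[0][0], orientation != "parallel", tuple(sub))
            if best is None or key < best[0]:
                best = (key, sub, orientation)
    if best is None:
        return None
    return best[1], best[2]


def extract_blocks_oracle(
    anchors: list[tuple[int, int]], max_gap: int, min_anchors: int
) -> list[tuple[list[tuple[int, int]], str]]:
    """Iterated canonical best-chain extraction by exhaustive enumeration."""
    remaining = list(anchors)
    blocks = []
    while remaining:
        found = best_chain_oracle(remaining, max_gap)
        if found is None or len(found[0]) < min_anchors:
            break
        chain, orientation = found
        blocks.append((chain, orientation))
        used = set(chain)
        remaining = [a for a in remaining if a not in used]
    return blocks


def clusters_oracle(
    genes: list[tuple[str, int, int]], max_gap: int
) -> set[frozenset[str]]:
    """Connected components (union-find) of the adjacent-gap-below-threshold graph.

    ``genes`` are (id, start, end) on one chromosome; returns the components
    of size >= 2 as id sets.
    """
    parent = {gid: gid for gid, _, _ in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    ordered = sorted(genes, key=lambda t: (t[1], t[2], t[0]))
    for (id1, _s1, e1), (id2, s2, _e2) in zip(ordered, ordered[1:]):
        if max(0, s2 - e1 - 1) < max_gap:
            union(id1, id2)
    groups: dict[str, set[str]] = {}
    for gid, _, _ in genes:
        groups.setdefault(find(gid), set()).add(gid)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


def bartlett_oracle(groups: list[list[float]]) -> float:
    """Bartlett's statistic from the textbook formula."""
    k = len(groups)
    ns = [len(g) for g in groups]
    n_tot = sum(ns)

    def var(g: list[float]) -> float:
        m = sum(g) / len(g)
        return sum((x - m) ** 2 for x in g) / (len(g) - 1)

    variances = [var(g) for g in groups]
    sp2 = sum((n - 1) * v for n, v in zip(ns, variances)) / (n_tot - k)
    num = (n_tot - k) * math.log(sp2) - sum(
        (n - 1) * math.log(v) for n, v in zip(ns, variances)
    )
    den = 1 + (sum(1 / (n - 1) for n in ns) - 1 / (n_tot - k)) / (3 * (k - 1))
    return num / den


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
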