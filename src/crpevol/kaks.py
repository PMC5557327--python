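"""Nei–Gojobori (NG86) Ka/Ks estimation and downstream evolutionary statistics.

The NG86 procedure counts, for each codon, the fraction of one-step
nucleotide changes that are synonymous (synonymous "sites"), classifies the
observed between-codon differences by averaging over equally weighted
mutational pathways, applies the Jukes–Cantor multiple-hit correction to
the per-site proportions, and screens the Ka/Ks ratio for significance.
Also here: kernel-density dating of duplication bursts from Ks values, the
likelihood-ratio test on externally fitted site models (M0/M7/M8), and
Bartlett's variance-homogeneity test for comparing rate groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from crpevol.genome_io import CodingPair, GenomeIOError, round_half_up, validate_cds

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)  # sense codon -> amino acid
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


@dataclass(frozen=True)
class CodonSiteCounts:
    """NG86 site and difference counts for a coding pair (possibly fractional)."""

    S: float
    N: float
    Sd: float
    Nd: float


@dataclass(frozen=True)
class KaKsResult:
    """Ka, Ks, their ratio and significance for one coding pair.

    ``ka``/``ks`` are None when undefined (zero sites, or observed
    proportion at/over the Jukes–Cantor 3/4 ceiling); the ratio is defined
    only when ks is defined and positive.
    """

    id_a: str
    id_b: str
    ka: float | None
    ks: float | None
    ratio: float | None
    p_value: float
    counts: CodonSiteCounts
    selection_class: str  # "positive" | "negative" | "undetermined"


@dataclass(frozen=True)
class SiteModelFit:
    """An externally fitted codon site model: name, -ln L and free-parameter count.

    Extra fitted quantities (omega, beta shape parameters, selected-site
    counts) ride along as opaque annotations; fitting itself is not done here.
    """

    model_name: str
    neg_log_likelihood: float
    n_free_params: int
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.neg_log_likelihood):
            raise ValueError(f"{self.model_name}: -lnL must be finite")


# ---------------------------------------------------------------------------
# Site counting


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str, stop_policy: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon; sums to 3."""
    if codon in _STOPS or codon not in _AA:
        raise GenomeIOError(f"cannot count sites of codon {codon!r}")
    s_total = 0.0
    for pos in range(3):
        syn = 0
        stops = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in _STOPS:
                stops += 1
            elif _AA[alt] == _AA[codon]:
                syn += 1
        if stop_policy == "nonsyn":
            s_total += syn / 3.0
        elif stop_policy == "exclude":
            denom = 3 - stops
            s_total += syn / denom if denom else 0.0
        else:
            raise ValueError(f"unknown stop_policy {stop_policy!r}")
    return s_total, 3.0 - s_total


def count_sites(cds: str, stop_policy: str = "nonsyn") -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts (S, N) of one CDS; S + N = 3L.

    Per codon position, the fraction of the three single-nucleotide changes
    that are synonymous contributes to S and the remainder to N. Changes to
    stop codons count as nonsynonymous under the default policy; under
    ``stop_policy="exclude"`` they are removed from the denominator instead.
    """
    validate_cds(cds)
    S = N = 0.0
    for i in range(0, len(cds), 3):
        s, n = _codon_site_fractions(cds[i : i + 3], stop_policy)
        S += s
        N += n
    return S, N


# ---------------------------------------------------------------------------
# Difference counting


def _step_is_syn(codon_from: str, codon_to: str) -> bool:
    """A one-nucleotide step is synonymous iff the amino acid is unchanged.

    Steps into or out of a stop codon are treated as nonsynonymous.
    """
    if codon_from in _STOPS or codon_to in _STOPS:
        return False
    return _AA[codon_from] == _AA[codon_to]


def _codon_pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (sd, nd) between two codons.

    Codons differing at two (three) positions average the per-step
    synonymous/nonsynonymous counts over the 2 (6) equally weighted
    mutational orders; pathways passing through a stop codon are excluded
    unless every pathway does.
    """
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        return (1.0, 0.0) if _step_is_syn(ca, cb) else (0.0, 1.0)
    paths = []
    for order in permutations(diff):
        cur = ca
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != cb:
                through_stop = True
            if _step_is_syn(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    usable = [(sd, nd) for through, sd, nd in paths if not through]
    if not usable:  # all pathways cross a stop: fall back to including them
        usable = [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def count_differences(pair: CodingPair) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts (Sd, Nd)."""
    Sd = Nd = 0.0
    for i in range(0, len(pair.cds_a), 3):
        sd, nd = _codon_pair_differences(pair.cds_a[i : i + 3], pair.cds_b[i : i + 3])
        Sd += sd
        Nd += nd
    return Sd, Nd


# ---------------------------------------------------------------------------
# Distances and significance


def jukes_cantor(p: float) -> float | None:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3); None when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_significance(counts: CodonSiteCounts, method: str = "fisher") -> float:
    """Two-sided significance of Ka != Ks from the 2x2 site/difference table.

    Default is Fisher's exact test on [[Sd, Nd], [S-Sd, N-Nd]] with
    fractional entries rounded half-up; ``method="z"`` gives the pooled
    two-proportion normal approximation instead.
    """
    if counts.S <= 0 or counts.N <= 0:
        raise ValueError("S and N must be positive")
    if counts.Sd + counts.Nd == 0:
        return 1.0
    if method == "fisher":
        sd = int(round_half_up(counts.Sd, 0))
        nd = int(round_half_up(counts.Nd, 0))
        s = int(round_half_up(counts.S, 0))
        n = int(round_half_up(counts.N, 0))
        table = [[sd, nd], [max(s - sd, 0), max(n - nd, 0)]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "z":
        ps = counts.Sd / counts.S
        pn = counts.Nd / counts.N
        pooled = (counts.Sd + counts.Nd) / (counts.S + counts.N)
        se = math.sqrt(pooled * (1 - pooled) * (1 / counts.S + 1 / counts.N))
        if se == 0:
            return 1.0
        z = (pn - ps) / se
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")


def compute_kaks(
    pair: CodingPair,
    alpha: float = 0.05,
    stop_policy: str = "nonsyn",
    test: str = "fisher",
) -> KaKsResult:
    """Full NG86 Ka/Ks for one pair with significance-based selection class.

    Sites are averaged over the two sequences; Ks = JC(Sd/S), Ka = JC(Nd/N).
    The pair is called positively (negatively) selected when the ratio is
    defined, differs from 1 in the corresponding direction, and the
    two-sided p-value is below ``alpha``; otherwise undetermined.
    """
    sa, na = count_sites(pair.cds_a, stop_policy)
    sb, nb = count_sites(pair.cds_b, stop_policy)
    S, N = (sa + sb) / 2.0, (na + nb) / 2.0
    Sd, Nd = count_differences(pair)
    counts = CodonSiteCounts(S=S, N=N, Sd=Sd, Nd=Nd)
    ks = jukes_cantor(Sd / S) if S > 0 else None
    ka = jukes_cantor(Nd / N) if N > 0 else None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    p = kaks_significance(counts, method=test)
    selection = "undetermined"
    if ratio is not None and p < alpha:
        if ratio > 1:
            selection = "positive"
        elif ratio < 1:
            selection = "negative"
    return KaKsResult(
        id_a=pair.id_a,
        id_b=pair.id_b,
        ka=ka,
        ks=ks,
        ratio=ratio,
        p_value=p,
        counts=counts,
        selection_class=selection,
    )


# ---------------------------------------------------------------------------
# Ks-density dating


def ks_density_peaks(
    ks_values,
    max_ks: float = 2.0,
    bandwidth: float | None = None,
) -> list[float]:
    """Modes of the Ks distribution among duplicate pairs, strongest first.

    Values outside (0, ``max_ks``) and undefined (None/NaN) values are
    dropped; a Gaussian kernel density (Silverman bandwidth unless a fixed
    ``bandwidth`` is given) is evaluated on a 512-point grid over
    (0, max_ks] and its strict local maxima are returned in order of
    decreasing density.
    """
    vals = np.array(
        [v for v in ks_values if v is not None and not math.isnan(v) and 0 < v < max_ks],
        dtype=float,
    )
    if vals.size < 10:
        raise ValueError(
            f"need >= 10 Ks values in (0, {max_ks}) after filtering, got {vals.size}"
        )
    if bandwidth is None:
        kde = stats.gaussian_kde(vals, bw_method="silverman")
    else:
        sd = float(np.std(vals, ddof=1))
        if sd == 0:
            raise ValueError("zero-variance Ks values")
        kde = stats.gaussian_kde(vals, bw_method=bandwidth / sd)
    grid = np.linspace(max_ks / 512.0, max_ks, 512)
    dens = kde(grid)
    peaks = []
    for i in range(len(grid)):
        left_ok = i == 0 or dens[i] > dens[i - 1]
        right_ok = i == len(grid) - 1 or dens[i] > dens[i + 1]
        if 0 < i < len(grid) - 1 and left_ok and right_ok:
            peaks.append((dens[i], grid[i]))
    peaks.sort(key=lambda t: -t[0])
    return [float(x) for _, x in peaks]


# ---------------------------------------------------------------------------
# Likelihood-ratio and rate-group tests


def likelihood_ratio_test(
    fit_null: SiteModelFit, fit_alt: SiteModelFit, df: int
) -> tuple[float, float]:
    """LRT of nested site models from their -ln L values.

    statistic = 2 (−lnL_null − −lnL_alt), clamped at 0 when the alternative
    fits worse; p is the upper chi-square tail with ``df`` degrees of freedom.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    stat = 2.0 * (fit_null.neg_log_likelihood - fit_alt.neg_log_likelihood)
    stat = max(0.0, stat)
    p = float(stats.chi2.sf(stat, df))
    return stat, p


def rate_group_test(groups) -> tuple[float, float]:
    """Bartlett's homogeneity-of-variance test across >= 2 groups of Ka/Ks values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i}: need n >= 2")
        if np.var(g, ddof=1) <= 0:
            raise ValueError(f"group {i}: zero variance")
    stat, p = stats.bartlett(*groups)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# I/O helpers


def coding_pair_from_alignment(
    id_a: str, id_b: str, aln_a: str, aln_b: str
) -> tuple[CodingPair, int]:
    """Build a CodingPair from an aligned pair, dropping gapped codon columns.

    Returns the pair and the number of codon columns dropped (for logging).
    """
    aln_a, aln_b = aln_a.upper(), aln_b.upper()
    if len(aln_a) != len(aln_b):
        raise GenomeIOError(f"({id_a},{id_b}): aligned lengths differ")
    if len(aln_a) % 3:
        raise GenomeIOError(f"({id_a},{id_b}): alignment length not divisible by 3")
    kept_a, kept_b, dropped = [], [], 0
    for i in range(0, len(aln_a), 3):
        ca, cb = aln_a[i : i + 3], aln_b[i : i + 3]
        if "-" in ca or "-" in cb:
            dropped += 1
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    return CodingPair(id_a, id_b, "".join(kept_a), "".join(kept_b)), dropped


def read_site_model_fits(path: str | Path) -> dict[str, SiteModelFit]:
    """Read site-model fits from a TSV: model_name, neg_log_likelihood, n_free_params.

    Any extra columns become opaque annotations on the fit.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise GenomeIOError("empty site-model table")
    header = lines[0].split("\t")
    required = {"model_name", "neg_log_likelihood", "n_free_params"}
    if not required <= set(header):
        raise GenomeIOError(f"site-model table needs columns {sorted(required)}")
    fits: dict[str, SiteModelFit] = {}
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        extras = {k: v for k, v in row.items() if k not in required}
        fit = SiteModelFit(
            model_name=row["model_name"],
            neg_log_likelihood=float(row["neg_log_likelihood"]),
            n_free_params=int(row["n_free_params"]),
            annotations=extras,
        )
        fits[fit.model_name] = fit
    return fits


def kaks_to_rows(results: list[KaKsResult]) -> list[dict]:
    def fmt(x):
        return "NA" if x is None else f"{x:.6g}"

    return [
        {
            "gene_a": r.id_a,
            "gene_b": r.id_b,
            "S": f"{r.counts.S:.4f}",
            "N": f"{r.counts.N:.4f}",
            "Sd": f"{r.counts.Sd:.4f}",
            "Nd": f"{r.counts.Nd:.4f}",
            "Ka": fmt(r.ka),
            "Ks": fmt(r.ks),
            "Ka_Ks": fmt(r.ratio),
            "p_value": f"{r.p_value:.6g}",
            "selection": r.selection_class,
        }
        for r in results
    ]
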