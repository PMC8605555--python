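"""Family clustering, divergence, gene conversion and insertion dating.

The two LTRs of a retrotransposon are identical at insertion, so their
HKY85 divergence d converts to an insertion age T = d / (2 r) with r the
per-year substitution rate (default 2.5e-8 per generation over a 5-year
generation time, i.e. 5e-9 / year).  Gene conversion between LTRs erases
divergence inside the converted tract and biases ages downward; tracts are
found with a Sawyer-style maximal-segment statistic over informative sites
and a seeded permutation null, and divergence is re-estimated from the
columns outside accepted tracts (linear scaling to the whole element).

Families follow the 80-80-80 rule: two copies are related when a local
alignment reaches >= 80 % identity over >= 80 % of the shorter sequence with
>= 80 aligned bp; families are the connected components of that relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .align import PairwiseResult, align_pair, align_score
from .hky import HkyParams, ml_distance

__all__ = [
    "ClusterRule",
    "HkyParams",
    "GeneConversionTract",
    "GeneConversionScan",
    "CorrectedDivergence",
    "AgeEstimate",
    "LengthComparison",
    "align_pair",
    "align_score",
    "cluster_80_80_80",
    "hky85_distance",
    "detect_gene_conversion",
    "detect_pair_tracts",
    "corrected_divergence",
    "estimate_age",
    "compare_length_distributions",
    "MU_PER_GENERATION",
    "GENERATION_YEARS",
]

MU_PER_GENERATION = 2.5e-8
GENERATION_YEARS = 5.0


@dataclass(frozen=True)
class ClusterRule:
    """Thresholds of the 80-80-80 family relation."""

    min_identity: float = 0.80
    min_coverage: float = 0.80
    min_aligned: int = 80

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_coverage <= 1:
            raise ValueError("identity and coverage thresholds must be in (0, 1]")
        if self.min_aligned < 1:
            raise ValueError("min_aligned must be >= 1 bp")


def related_80_80_80(a: str, b: str, rule: ClusterRule = ClusterRule()) -> bool:
    """True when a local alignment of a and b satisfies the family rule."""
    res = align_pair(a, b, mode="local")
    shorter = min(len(a), len(b))
    return (
        res.identity >= rule.min_identity
        and res.aligned_length >= rule.min_coverage * shorter
        and res.aligned_length >= rule.min_aligned
    )


def cluster_80_80_80(
    sequences: Sequence[str] | Mapping[str, str], rule: ClusterRule = ClusterRule()
) -> tuple[list[list[str]], list[str]]:
    """Partition sequences into families (single linkage) plus singletons.

    Returns ``(clusters, singletons)`` where clusters have >= 2 members.
    Member ids are list indices (as strings) for a plain sequence list, or
    the mapping keys.  Output order is deterministic (by first appearance).
    """
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(str(i), s) for i, s in enumerate(sequences)]
    if not items:
        raise ValueError("need at least one sequence")
    order = {k: i for i, (k, _) in enumerate(items)}
    g = nx.Graph()
    g.add_nodes_from(k for k, _ in items)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if related_80_80_80(items[i][1], items[j][1], rule):
                g.add_edge(items[i][0], items[j][0])
    comps = [sorted(c, key=order.get) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: order[c[0]])
    clusters = [c for c in comps if len(c) > 1]
    singletons = [c[0] for c in comps if len(c) == 1]
    return clusters, singletons


def hky85_distance(a: str, b: str) -> HkyParams:
    """HKY85 ML distance for a pair; unaligned inputs are globally aligned first.

    Gap and N columns are excluded from the counts.  Identical sequences
    return d = 0 exactly; estimates at the branch-length bound are flagged
    saturated.
    """
    if not a or not b:
        raise ValueError("cannot estimate a distance for an empty sequence")
    if len(a) != len(b) or "-" in a or "-" in b:
        res = align_pair(a.replace("-", ""), b.replace("-", ""), mode="global")
        a, b = res.a_aligned, res.b_aligned
    return ml_distance(a, b)


# ---------------------------------------------------------------------------
# Gene conversion tracts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneConversionTract:
    """A homogenized segment of one element's LTR pair alignment.

    ``start_col``/``end_col`` are half-open column indices in the pair
    alignment; ``supporting_sites`` counts informative matching columns
    inside the tract (>= 3 required for acceptance).
    """

    element_id: str
    start_col: int
    end_col: int
    supporting_sites: int
    score: float
    p_value: float


@dataclass(frozen=True)
class GeneConversionScan:
    tracts: tuple[GeneConversionTract, ...]
    no_context: bool = False


@dataclass(frozen=True)
class CorrectedDivergence:
    d_raw: float
    d_corrected: float
    kappa: float
    fallback: bool = False
    saturated: bool = False


def _maximal_segments(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences (Ruzzo-Tompa)."""
    stack: list[list[float]] = []  # [start, end, Lcum, Rcum]
    cum = 0.0
    for i, s in enumerate(scores):
        left = cum
        cum += s
        if s <= 0:
            continue
        k = [i, i + 1, left, cum]
        while True:
            j = None
            for idx in range(len(stack) - 1, -1, -1):
                if stack[idx][2] < k[2]:
                    j = idx
                    break
            if j is None or stack[j][3] >= k[3]:
                stack.append(k)
                break
            k = [stack[j][0], k[1], stack[j][2], k[3]]
            del stack[j:]
    return [(int(s0), int(e0), r - l) for s0, e0, l, r in stack]


def _null_max_segment(series: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Best segment sum of each of n_perm column-order permutations."""
    mat = rng.permuted(np.tile(series, (n_perm, 1)), axis=1)
    cs = np.cumsum(mat, axis=1)
    prefix = np.minimum.accumulate(np.hstack([np.zeros((n_perm, 1)), cs]), axis=1)[:, :-1]
    return (cs - prefix).max(axis=1)


def detect_pair_tracts(
    ltr5: str,
    ltr3: str,
    context: Sequence[str],
    element_id: str = "element",
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> GeneConversionScan:
    """Scan one element's aligned LTR pair for gene-conversion tracts.

    ``context`` holds the other aligned cluster members (same alignment
    length); without at least one context sequence the informative-site
    definition has no outgroup and the scan returns a ``no_context`` result.

    Informative columns are those where the pair matches but at least one
    context member differs, or where the pair mismatches.  Over those
    columns a match scores +1 and a mismatch -(1/f - 1), f being the overall
    mismatch fraction, so the expected segment score is zero under uniform
    divergence.  Maximal-scoring segments are tested against a seeded
    permutation null on the column order.
    """
    if not context:
        return GeneConversionScan((), no_context=True)
    length = len(ltr5)
    if len(ltr3) != length or any(len(c) != length for c in context):
        raise ValueError("pair and context must share one alignment length")
    inf_cols: list[int] = []
    is_match: list[bool] = []
    for col in range(length):
        x, y = ltr5[col], ltr3[col]
        if x not in "ACGT" or y not in "ACGT":
            continue
        if x != y:
            inf_cols.append(col)
            is_match.append(False)
        else:
            others = [c[col] for c in context if c[col] in "ACGT"]
            if any(o != x for o in others):
                inf_cols.append(col)
                is_match.append(True)
    if not inf_cols:
        return GeneConversionScan(())
    match_arr = np.array(is_match)
    f = 1.0 - match_arr.mean()
    if f <= 0 or f >= 1:
        # no mismatches (nothing to contrast) or no matches (no tract signal)
        return GeneConversionScan(())
    penalty = -(1.0 / f - 1.0)
    series = np.where(match_arr, 1.0, penalty)
    segments = _maximal_segments(series)
    if not segments:
        return GeneConversionScan(())
    rng = np.random.default_rng(seed)
    null_max = _null_max_segment(series, n_permutations, rng)
    tracts = []
    for s0, e0, score in segments:
        support = int(match_arr[s0:e0].sum())
        if support < 3:
            continue
        p = (1.0 + float((null_max >= score).sum())) / (1.0 + n_permutations)
        if p <= alpha:
            tracts.append(
                GeneConversionTract(
                    element_id=element_id,
                    start_col=inf_cols[s0],
                    end_col=inf_cols[e0 - 1] + 1,
                    supporting_sites=support,
                    score=float(score),
                    p_value=float(p),
                )
            )
    tracts.sort(key=lambda t: t.start_col)
    return GeneConversionScan(tuple(tracts))


def detect_gene_conversion(
    cluster: Mapping[str, str],
    pairs: Mapping[str, tuple[str, str]],
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> GeneConversionScan:
    """Scan every element's LTR pair within one cluster alignment.

    ``cluster`` maps member id to aligned sequence; ``pairs`` maps element id
    to the (5' LTR, 3' LTR) member ids.  Clusters with fewer than 3 members
    lack the outgroup context needed to call informative sites and yield an
    empty, ``no_context``-flagged result.
    """
    if len(cluster) < 3:
        return GeneConversionScan((), no_context=True)
    all_tracts: list[GeneConversionTract] = []
    for k, element_id in enumerate(sorted(pairs)):
        id5, id3 = pairs[element_id]
        context = [v for key, v in cluster.items() if key not in (id5, id3)]
        scan = detect_pair_tracts(
            cluster[id5],
            cluster[id3],
            context,
            element_id=element_id,
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed + k,
        )
        all_tracts.extend(scan.tracts)
    return GeneConversionScan(tuple(all_tracts))


def corrected_divergence(
    ltr5: str, ltr3: str, tracts: Sequence[GeneConversionTract]
) -> CorrectedDivergence:
    """Divergence with gene-conversion tracts excised, scaled linearly.

    The non-tract columns are assumed to diverge at the element's true rate,
    so the distance computed outside the tract union applies to the whole
    element.  With no accepted tracts the corrected value equals the raw
    one; tracts covering > 90 % of columns trigger a flagged fallback to the
    raw estimate.
    """
    raw = hky85_distance(ltr5, ltr3)
    if not tracts:
        return CorrectedDivergence(raw.d, raw.d, raw.kappa, saturated=raw.saturated)
    length = len(ltr5)
    covered = np.zeros(length, dtype=bool)
    for t in tracts:
        covered[t.start_col : t.end_col] = True
    if covered.mean() > 0.9:
        return CorrectedDivergence(raw.d, raw.d, raw.kappa, fallback=True, saturated=raw.saturated)
    keep = ~covered
    a = "".join(c for c, k in zip(ltr5, keep) if k)
    b = "".join(c for c, k in zip(ltr3, keep) if k)
    corr = ml_distance(a, b)
    return CorrectedDivergence(raw.d, corr.d, corr.kappa, saturated=raw.saturated or corr.saturated)


# ---------------------------------------------------------------------------
# Dating and length statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeEstimate:
    """Insertion age of one element under the molecular-clock rate model."""

    element_id: str
    d_raw: float
    d_corrected: float
    kappa: float
    age_years: float
    mu_per_generation: float = MU_PER_GENERATION
    generation_years: float = GENERATION_YEARS
    flags: tuple[str, ...] = ()

    @property
    def age_my(self) -> float:
        return self.age_years / 1e6


def estimate_age(
    element_id: str,
    d_corrected: float,
    d_raw: float | None = None,
    kappa: float = 1.0,
    mu_per_generation: float = MU_PER_GENERATION,
    generation_years: float = GENERATION_YEARS,
    flags: Sequence[str] = (),
) -> AgeEstimate:
    """Convert an LTR-LTR divergence to years: T = d / (2 r), r = mu / g."""
    if d_corrected < 0:
        raise ValueError("divergence must be >= 0")
    r = mu_per_generation / generation_years
    age = d_corrected / (2.0 * r)
    return AgeEstimate(
        element_id=element_id,
        d_raw=d_corrected if d_raw is None else d_raw,
        d_corrected=d_corrected,
        kappa=kappa,
        age_years=age,
        mu_per_generation=mu_per_generation,
        generation_years=generation_years,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class LengthComparison:
    """Kruskal-Wallis across groups plus pairwise Welch t statistics."""

    h: float
    p: float
    pairwise: Mapping[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


def compare_length_distributions(groups: Mapping[str, Sequence[float]]) -> LengthComparison:
    """Rank (Kruskal-Wallis, tie-corrected) and mean (Welch t) comparisons.

    P-values are two-sided and unadjusted.  Every group needs >= 2
    observations; offenders are named in the error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    names = list(groups)
    h, p = stats.kruskal(*[np.asarray(groups[n], dtype=float) for n in names])
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, tp = stats.ttest_ind(
                np.asarray(groups[names[i]], dtype=float),
                np.asarray(groups[names[j]], dtype=float),
                equal_var=False,
            )
            pairwise[(names[i], names[j])] = (float(t), float(tp))
    return LengthComparison(float(h), float(p), pairwise)
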