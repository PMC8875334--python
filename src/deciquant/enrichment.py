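"""Gene-set enrichment: weighted KS statistic with permutation significance.

Genes are ranked by a two-class association metric (signal-to-noise ratio
by default), a weighted Kolmogorov-Smirnov running sum is walked down the
ranking for each gene set, and significance comes from phenotype-label
permutation (which preserves inter-gene correlation).  The running sum at
rank k is the weighted hit CDF minus the uniform CDF,

    D(k) = Σ_{hits ≤ k} |m_i|^p / Σ_{hits} |m_i|^p  −  k / N,

so it starts and ends at 0; the enrichment score ES is the signed maximum
deviation, bounded in (−1, 1).  With weight p = 0 the statistic reduces to
the classical KS deviation of the set's ranks from uniformity.  The
normalized score NES divides ES by the mean magnitude of the same-signed
permutation scores, so the permutation null of |NES| has mean 1 by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedExpression",
    "EnrichmentResult",
    "rank_by_phenotype",
    "enrichment_score",
    "nes_and_p",
    "run_table",
    "NRF2_SET_NAMES",
]

#: the five NRF2 functional gene-set names used for the tabular output
NRF2_SET_NAMES = (
    "antioxidant proteins",
    "phase I and II metabolizing enzymes",
    "chaperone and stress response proteins",
    "phase III detoxifying proteins",
    "ubiquitination and proteasomal degradation",
)

_SD_FLOOR = 1e-3


@dataclass
class RankedExpression:
    """Genes ordered by a phenotype-association metric (descending).

    Keeps a reference to the source matrix and labels so that the
    permutation stage can re-rank under shuffled phenotypes.
    """

    gene_order: np.ndarray  # gene identifiers, metric-descending
    metric_values: np.ndarray  # metric aligned with gene_order
    phenotype: np.ndarray
    matrix: pd.DataFrame
    metric: str


@dataclass
class EnrichmentResult:
    set_name: str
    n_transcripts: int
    es: float
    nes: float
    p_value: float
    p_floored: bool = False


def _metric_values(
    values: np.ndarray, phenotype: np.ndarray, metric: str
) -> np.ndarray:
    """Per-gene class-1 vs class-0 association metric (vectorized)."""
    g1 = values[:, phenotype == 1]
    g0 = values[:, phenotype == 0]
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    s1, s0 = g1.std(axis=1, ddof=1), g0.std(axis=1, ddof=1)
    if metric == "s2n":
        denom = s1 + s0
    elif metric == "t":
        denom = np.sqrt(s1**2 / g1.shape[1] + s0**2 / g0.shape[1])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return (m1 - m0) / np.maximum(denom, _SD_FLOOR)


def rank_by_phenotype(
    matrix: pd.DataFrame, phenotype, metric: str = "s2n"
) -> RankedExpression:
    """Rank genes by class association, descending; ties break by gene id.

    ``metric`` is ``"s2n"`` (signal-to-noise: difference of class means over
    the sum of class SDs) or ``"t"`` (Welch t statistic).  Near-constant
    genes have the denominator floored at a small epsilon, with a warning.
    """
    phenotype = np.asarray(phenotype)
    classes = np.unique(phenotype)
    if classes.size != 2:
        raise ValueError("phenotype must have exactly two classes")
    counts = [(phenotype == c).sum() for c in classes]
    if min(counts) < 3:
        raise ValueError("each phenotype class needs at least 3 samples")
    labels01 = (phenotype == classes[1]).astype(int)

    values = matrix.to_numpy(dtype=float)
    g1 = values[:, labels01 == 1]
    g0 = values[:, labels01 == 0]
    if np.any(g1.std(axis=1, ddof=1) + g0.std(axis=1, ddof=1) < _SD_FLOOR):
        warnings.warn(
            f"near-constant gene(s): metric denominator floored at {_SD_FLOOR}",
            stacklevel=2,
        )
    m = _metric_values(values, labels01, metric)
    genes = np.asarray(matrix.index.astype(str))
    order = np.lexsort((genes, -m))  # descending metric, gene id breaks ties
    return RankedExpression(
        gene_order=genes[order],
        metric_values=m[order],
        phenotype=labels01,
        matrix=matrix,
        metric=metric,
    )


def _running_sum(
    order_hits: np.ndarray, metric_sorted: np.ndarray, weight_p: float
) -> np.ndarray:
    """Running deviation D(k) over the ranking; length N, D(N) = 0."""
    n = order_hits.size
    if weight_p == 0:
        weights = order_hits.astype(float)
    else:
        weights = np.where(order_hits, np.abs(metric_sorted) ** weight_p, 0.0)
    total = weights.sum()
    if total <= 0:
        # all hit metrics are zero: fall back to unweighted hits
        weights = order_hits.astype(float)
        total = weights.sum()
    hit_cdf = np.cumsum(weights) / total
    uniform_cdf = np.arange(1, n + 1) / n
    return hit_cdf - uniform_cdf


def _es_from_profile(profile: np.ndarray) -> float:
    idx = int(np.argmax(np.abs(profile)))
    return float(profile[idx])


def enrichment_score(
    ranked: RankedExpression, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score of a gene set against a ranking.

    Returns ``(ES, running-sum profile)``.  The set must be a nonempty
    proper subset of the ranked genes (a set equal to all genes makes the
    running sum degenerate).
    """
    members = set(map(str, gene_set))
    if not members:
        raise ValueError("gene set is empty")
    unknown = members - set(ranked.gene_order)
    if unknown:
        raise KeyError(f"gene set members not in the ranking: {sorted(unknown)[:5]}")
    if len(members) >= ranked.gene_order.size:
        raise ValueError("gene set equals the full gene list; running sum degenerate")
    hits = np.isin(ranked.gene_order, list(members))
    profile = _running_sum(hits, ranked.metric_values, weight_p)
    return _es_from_profile(profile), profile


def nes_and_p(
    ranked: RankedExpression,
    gene_set,
    n_permutations: int = 100,
    seed: int = 0,
    weight_p: float = 1.0,
    set_name: str = "",
) -> EnrichmentResult:
    """Permutation-normalized enrichment score and p-value.

    Phenotype labels are permuted ``n_permutations`` times; the metric,
    ranking and ES are recomputed for each.  NES is ES divided by the mean
    |permuted ES| of matching sign; p is the fraction of matching-sign
    permutation scores at least as extreme, computed with the
    ``(r + 1)/(m + 1)`` convention so p is never exactly 0.  With no
    matching-sign permutations p is reported at the floor and flagged.
    Deterministic under a fixed seed.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    if seed is None:
        raise ValueError("seed is required")
    es, _ = enrichment_score(ranked, gene_set, weight_p=weight_p)

    rng = np.random.default_rng([int(seed), 0x65E5])
    values = ranked.matrix.to_numpy(dtype=float)
    genes = np.asarray(ranked.matrix.index.astype(str))
    members = np.isin(genes, list(map(str, gene_set)))
    perm_es = np.empty(n_permutations)
    labels = ranked.phenotype.copy()
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        m = _metric_values(values, perm, ranked.metric)
        order = np.lexsort((genes, -m))
        profile = _running_sum(members[order], m[order], weight_p)
        perm_es[b] = _es_from_profile(profile)

    same_sign = perm_es * np.sign(es) > 0 if es != 0 else np.ones_like(perm_es, bool)
    m_same = int(same_sign.sum())
    floored = False
    if m_same == 0:
        nes = float("nan")
        p = 1.0 / (n_permutations + 1)
        floored = True
    else:
        nes = es / np.mean(np.abs(perm_es[same_sign]))
        r = int(np.sum(np.abs(perm_es[same_sign]) >= abs(es) - 1e-12))
        p = (r + 1) / (m_same + 1)
    return EnrichmentResult(
        set_name=set_name,
        n_transcripts=int(np.isin(genes, list(map(str, gene_set))).sum()),
        es=float(es),
        nes=float(nes),
        p_value=float(p),
        p_floored=floored,
    )


def run_table(
    matrix: pd.DataFrame,
    phenotype,
    gene_sets: dict[str, list[str]],
    n_permutations: int = 100,
    seed: int = 0,
    weight_p: float = 1.0,
    metric: str = "s2n",
    pooled_name: str = "All gene sets",
) -> pd.DataFrame:
    """Enrichment table: one row per gene set plus a pooled all-sets row.

    Output columns: ``set``, ``n_transcripts``, ``ES``, ``NES``,
    ``p_value``.  The pooled row deduplicates genes shared between sets
    (with a warning).  Per-set results do not depend on the order in which
    the sets are supplied.  An empty set mapping yields an empty table.
    """
    columns = ["set", "n_transcripts", "ES", "NES", "p_value"]
    if not gene_sets:
        return pd.DataFrame(columns=columns)
    ranked = rank_by_phenotype(matrix, phenotype, metric=metric)
    records = []
    for name in gene_sets:  # supplied order is reporting order only
        res = nes_and_p(
            ranked,
            gene_sets[name],
            n_permutations=n_permutations,
            seed=_set_seed(seed, name),
            weight_p=weight_p,
            set_name=name,
        )
        records.append(res)

    pooled: list[str] = []
    seen: set[str] = set()
    overlap = False
    for members in gene_sets.values():
        for g in members:
            if g in seen:
                overlap = True
            else:
                seen.add(g)
                pooled.append(g)
    if overlap:
        warnings.warn("overlapping gene sets; pooled row deduplicated", stacklevel=2)
    records.append(
        nes_and_p(
            ranked,
            pooled,
            n_permutations=n_permutations,
            seed=_set_seed(seed, pooled_name),
            weight_p=weight_p,
            set_name=pooled_name,
        )
    )
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "n_transcripts": r.n_transcripts,
                "ES": r.es,
                "NES": r.nes,
                "p_value": r.p_value,
            }
            for r in records
        ],
        columns=columns,
    )


def _set_seed(seed: int, name: str) -> int:
    """Stable per-set sub-seed so results are order-independent."""
    h = 2166136261
    for ch in name.encode():
        h = ((h ^ ch) * 16777619) % (2**31)
    return (int(seed) * 1000003 + h) % (2**31)
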