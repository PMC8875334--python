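"""Synthetic expression matrices with implanted gene-set enrichment.

Emulates a two-class microarray experiment: null genes are i.i.d. standard
normal across samples; the members of one named gene set are shifted in one
phenotype class by a stated effect size in units of the within-group SD, so
the enrichment stage has a known truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionPhantom", "generate_expression"]


@dataclass
class ExpressionPhantom:
    """Genes × samples matrix with phenotype labels and gene-set truth.

    ``implanted_effect`` is the mean shift (in within-group SD units, here
    SD = 1) applied to ``implanted_set`` members in phenotype class 1; with
    effect 0 the matrix is exchangeable across labels.
    """

    matrix: pd.DataFrame  # genes (index) × samples (columns)
    phenotype: np.ndarray  # per-sample 0/1 labels
    gene_sets: dict[str, list[str]]
    implanted_set: str | None
    implanted_effect: float
    seed: int


def generate_expression(
    n_genes: int = 1000,
    n_samples_per_class: int = 20,
    gene_sets: dict[str, list[str]] | None = None,
    implanted_effect: float = 0.0,
    seed: int = 0,
    *,
    implanted_set: str | None = None,
    allow_overlap: bool = False,
) -> ExpressionPhantom:
    """Generate a seeded two-class expression phantom.

    ``gene_sets`` maps set names to gene identifiers; identifiers must exist
    among the generated genes (``G0001`` ...), otherwise an error is raised.
    If ``gene_sets`` is omitted a single 40-gene set named ``"implanted"``
    is created.  ``implanted_set`` selects which set carries the effect
    (default: the first set).  Sets must be disjoint unless
    ``allow_overlap`` is set.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng([int(seed), 0xE4B])
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]

    if gene_sets is None:
        gene_sets = {"implanted": genes[:40]}
    known = set(genes)
    seen: set[str] = set()
    for name, members in gene_sets.items():
        missing = [g for g in members if g not in known]
        if missing:
            raise KeyError(f"gene set {name!r} references unknown genes: {missing[:5]}")
        if not allow_overlap and seen & set(members):
            raise ValueError(f"gene set {name!r} overlaps another set (pass allow_overlap=True)")
        seen |= set(members)

    if implanted_set is None:
        implanted_set = next(iter(gene_sets)) if gene_sets else None

    n = 2 * n_samples_per_class
    values = rng.standard_normal((n_genes, n))
    phenotype = np.repeat([0, 1], n_samples_per_class)
    if implanted_effect != 0.0 and implanted_set is not None:
        idx = [genes.index(g) for g in gene_sets[implanted_set]]
        values[np.ix_(idx, np.flatnonzero(phenotype == 1))] += implanted_effect

    matrix = pd.DataFrame(
        values, index=genes, columns=[f"S{j + 1:03d}" for j in range(n)]
    )
    return ExpressionPhantom(
        matrix=matrix,
        phenotype=phenotype,
        gene_sets={k: list(v) for k, v in gene_sets.items()},
        implanted_set=implanted_set,
        implanted_effect=float(implanted_effect),
        seed=int(seed),
    )
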