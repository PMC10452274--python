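"""Single-sample GSEA and preranked GSEA, implemented from scratch.

The single-sample enrichment score (ES) walks the genes of one sample in
descending expression order and accumulates the difference between the
cumulative weighted-rank mass of the signature genes (weights
``rank**alpha``) and the cumulative uniform mass of the non-signature
genes; the ES is the sum of that difference over all positions (the
"integral"/area form). With ``alpha = 0`` every signature gene carries the
same mass. Because only expression *ranks* within the sample enter, the ES
is invariant under any strictly monotone transform of the sample.

NES normalization follows the ssGSEA convention: every raw ES of a run is
divided by the global range ``max(ES) - min(ES)`` across all samples and
sets of that run. A per-set normalization mode is provided for combined
scores whose source publications normalized per set.

:func:`preranked_gsea` is the classical two-sided weighted KS statistic on
a user-supplied ranked gene list with gene-label permutation testing; it is
used to characterize which pathways the biomarker catalogue's frequent
genes fall in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateDataError, DegenerateWarning, MissingGeneError

DEFAULT_ALPHA = 0.25
MIN_COVERAGE = 0.5


def rank_sample(expression: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Order genes of one sample by descending expression.

    Returns ``(order, ranks)`` where ``order`` indexes genes from highest to
    lowest expression (ties broken by gene id for determinism) and ``ranks``
    are average-tie ranks (highest expression -> rank N) aligned to
    ``order``.
    """
    values = expression.to_numpy(dtype=float)
    # lexsort: primary key descending expression, secondary ascending gene id
    gene_ids = expression.index.to_numpy(dtype=object)
    order = np.lexsort((gene_ids, -values))
    ranks = rankdata(values, method="average")  # 1..N, ascending
    return order, ranks[order]


def ssgsea_es(
    sample_expression: pd.Series,
    gene_set: list[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Raw single-sample enrichment score of one gene set in one sample."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    genes = pd.Index(sample_expression.index)
    members = {g for g in gene_set if g in genes}
    if not members:
        raise MissingGeneError("gene set has no overlap with the transcriptome")
    if len(members) == len(genes):
        raise DegenerateDataError("gene set equals the whole transcriptome")
    order, ranks = rank_sample(sample_expression)
    in_set = np.fromiter(
        (genes[i] in members for i in order), dtype=bool, count=len(order)
    )
    weights = np.where(in_set, ranks**alpha, 0.0)
    hit = np.cumsum(weights)
    hit /= hit[-1]
    miss = np.cumsum(~in_set)
    miss = miss / miss[-1]
    return float(np.sum(hit - miss))


def ssgsea_es_matrix(
    expr_values: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Raw ES for every (sample, set): samples in rows, sets in columns.

    ``expr_values`` is genes x samples on any scale (ranks only). Signature
    genes absent from the matrix are dropped; coverage below
    ``MIN_COVERAGE`` raises.
    """
    genes = expr_values.index
    n = len(genes)
    usable: dict[str, set[str]] = {}
    for name, members in gene_sets.items():
        present = {g for g in members if g in genes}
        coverage = len(present) / len(set(members)) if members else 0.0
        if not present or coverage < MIN_COVERAGE:
            raise MissingGeneError(
                f"gene set {name!r}: coverage {coverage:.0%} below "
                f"{MIN_COVERAGE:.0%}"
            )
        if coverage < 1.0:
            warnings.warn(
                f"gene set {name!r}: {len(set(members)) - len(present)} of "
                f"{len(set(members))} genes missing",
                DegenerateWarning,
                stacklevel=2,
            )
        if len(present) == n:
            raise DegenerateDataError(f"gene set {name!r} covers the transcriptome")
        usable[name] = present

    gene_ids = genes.to_numpy(dtype=object)
    out = np.empty((expr_values.shape[1], len(usable)))
    set_masks = {
        name: np.fromiter((g in present for g in gene_ids), dtype=bool, count=n)
        for name, present in usable.items()
    }
    for j, sample in enumerate(expr_values.columns):
        values = expr_values[sample].to_numpy(dtype=float)
        order = np.lexsort((gene_ids, -values))
        ranks = rankdata(values, method="average")[order]
        ralpha = ranks**alpha
        for k, (name, mask) in enumerate(set_masks.items()):
            in_set = mask[order]
            weights = np.where(in_set, ralpha, 0.0)
            hit = np.cumsum(weights)
            hit /= hit[-1]
            miss = np.cumsum(~in_set).astype(float)
            miss /= miss[-1]
            out[j, k] = np.sum(hit - miss)
    return pd.DataFrame(out, index=expr_values.columns, columns=list(usable))


@dataclass
class NesMatrix:
    """Samples x sets normalized enrichment scores, with the raw ES kept."""

    nes: pd.DataFrame
    es: pd.DataFrame
    normalization: str  # "global_range" or "per_set_range"


def ssgsea_nes(es_matrix: pd.DataFrame, per_set: bool = False) -> NesMatrix:
    """Normalize raw ES values to NES by the ES range of the run.

    Default divides by the single global ``max - min`` over all samples and
    sets; ``per_set`` divides each column by its own range. A zero range
    yields NES 0 with a warning.
    """
    if es_matrix.shape[0] < 2:
        raise DegenerateDataError(
            "NES normalization needs >=2 samples; compute ES at cohort level"
        )
    values = es_matrix.to_numpy(dtype=float)
    if per_set:
        span = values.max(axis=0) - values.min(axis=0)
        degenerate = span == 0
        if degenerate.any():
            warnings.warn(
                "zero ES range for some sets; their NES set to 0",
                DegenerateWarning,
                stacklevel=2,
            )
        safe = np.where(degenerate, 1.0, span)
        nes = np.where(degenerate[None, :], 0.0, values / safe[None, :])
        mode = "per_set_range"
    else:
        span = values.max() - values.min()
        if span == 0:
            warnings.warn(
                "constant ES matrix; all NES set to 0", DegenerateWarning,
                stacklevel=2,
            )
            nes = np.zeros_like(values)
        else:
            nes = values / span
        mode = "global_range"
    return NesMatrix(
        nes=pd.DataFrame(nes, index=es_matrix.index, columns=es_matrix.columns),
        es=es_matrix.copy(),
        normalization=mode,
    )


def combine_nes(
    nes_matrix: NesMatrix | pd.DataFrame,
    sets: list[str],
    mode: str,
    weights: list[float] | None = None,
) -> pd.Series:
    """Combine per-set NES columns into one score per sample."""
    table = nes_matrix.nes if isinstance(nes_matrix, NesMatrix) else nes_matrix
    missing = [s for s in sets if s not in table.columns]
    if missing:
        raise KeyError(f"unknown set names: {missing}")
    block = table[list(sets)]
    if mode == "sum":
        return block.sum(axis=1)
    if mode == "mean":
        return block.mean(axis=1)
    if mode == "weighted_sum":
        if weights is None or len(weights) != len(sets):
            raise ValueError("weighted_sum needs one weight per set")
        return block @ np.asarray(weights, dtype=float)
    raise ValueError(f"unknown combine mode {mode!r}")


def _walk_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Max-deviation (classical GSEA) ES for a fixed gene ordering."""
    hit_mass = np.where(in_set, weights, 0.0)
    total = hit_mass.sum()
    if total == 0:
        return 0.0
    hit = np.cumsum(hit_mass) / total
    n_miss = (~in_set).sum()
    miss = np.cumsum(~in_set) / max(n_miss, 1)
    deviation = hit - miss
    return float(deviation[np.argmax(np.abs(deviation))])


def preranked_gsea(
    ranked_genes: pd.Series,
    gene_set: list[str] | set[str],
    n_permutations: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> tuple[float, float]:
    """Classical weighted-KS GSEA on a preranked gene list.

    ``ranked_genes`` maps unique gene ids to ranking scores (e.g. biomarker
    membership frequencies), sorted or not; genes are walked in descending
    score order with running-sum weights ``|score|**weight``. The ES is
    normalized against gene-label permutations: NES = ES / mean(|ES_perm|)
    over permutation ESs of the same sign, and the p-value is the same-sign
    permutation tail frequency with add-one smoothing.
    """
    if ranked_genes.index.duplicated().any():
        raise ValueError("ranked gene list contains duplicate genes")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    members = {g for g in gene_set if g in ranked_genes.index}
    if not members:
        raise MissingGeneError("gene set has no overlap with the ranked list")
    ordered = ranked_genes.sort_values(ascending=False, kind="mergesort")
    # deterministic tie-break by gene id within equal scores
    ordered = ordered.iloc[
        np.lexsort((ordered.index.to_numpy(dtype=object), -ordered.to_numpy()))
    ]
    in_set = ordered.index.isin(list(members)).astype(bool)
    weights = np.abs(ordered.to_numpy(dtype=float)) ** weight
    es = _walk_es(in_set, weights)

    rng = np.random.default_rng(seed)
    k = int(in_set.sum())
    n = len(in_set)
    perm_es = np.empty(n_permutations)
    for i in range(n_permutations):
        idx = rng.choice(n, size=k, replace=False)
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[idx] = True
        perm_es[i] = _walk_es(perm_mask, weights)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size == 0:
        nes = 0.0
        p_value = 1.0 / (n_permutations + 1)
    else:
        denom = np.abs(same_sign).mean()
        nes = es / denom if denom > 0 else 0.0
        exceed = int((np.abs(same_sign) >= abs(es)).sum())
        p_value = (exceed + 1) / (same_sign.size + 1)
    return float(nes), float(p_value)
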