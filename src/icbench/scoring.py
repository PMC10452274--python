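"""Per-sample computation of the native scoring systems.

All arithmetic self-contained scores (single gene, mean, geometric mean,
weighted sum, PCA, marker mean) operate on the ``log2(TPM + 1)`` scale by
default; a ``use_log`` flag allows raw-scale computation for sensitivity
checks. Rank-based scores (IMPRES, all enrichment scores) are unaffected by
that choice. Missing signature genes are tolerated down to 50% coverage
(with a warning, and the missing fraction recorded per score); below that
the score errors out rather than silently degrade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoverageWarning,
    DegenerateDataError,
    MissingGeneError,
)
from .io import ExpressionMatrix
from .registry import Registry, SignatureSpec
from .ssgsea import DEFAULT_ALPHA, combine_nes, ssgsea_es_matrix, ssgsea_nes

MIN_COVERAGE = 0.5


@dataclass
class ScoreTable:
    """Samples x scoring-systems values with per-score provenance."""

    values: pd.DataFrame  # samples in rows, score names in columns
    methods: dict[str, str] = field(default_factory=dict)
    missing_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def score_names(self) -> list[str]:
        return list(self.values.columns)


def _log_values(expr: ExpressionMatrix, use_log: bool) -> pd.DataFrame:
    return expr.log2p1().values if use_log else expr.values


def _present_genes(
    expr: ExpressionMatrix, genes: list[str] | tuple[str, ...], label: str
) -> tuple[list[str], float]:
    """Signature genes present in the matrix plus the missing fraction."""
    unique = list(dict.fromkeys(g.upper() for g in genes))
    index = expr.values.index
    present = [g for g in unique if g in index]
    missing_fraction = 1.0 - len(present) / len(unique) if unique else 1.0
    if not present:
        raise MissingGeneError(f"{label}: no signature genes in the matrix")
    coverage = 1.0 - missing_fraction
    if coverage < MIN_COVERAGE:
        raise MissingGeneError(
            f"{label}: only {len(present)}/{len(unique)} signature genes "
            f"present (coverage {coverage:.0%} < {MIN_COVERAGE:.0%})"
        )
    if missing_fraction > 0:
        absent = sorted(set(unique) - set(present))
        warnings.warn(
            f"{label}: missing genes {absent}", CoverageWarning, stacklevel=3
        )
    return present, missing_fraction


def score_single_gene(
    expr: ExpressionMatrix, gene: str, use_log: bool = True
) -> pd.Series:
    """Expression of one marker gene per sample (log2(x+1) by default)."""
    gene = gene.upper()
    if gene not in expr.values.index:
        raise MissingGeneError(f"gene {gene!r} absent from the matrix")
    return _log_values(expr, use_log).loc[gene].astype(float)


def score_mean(
    expr: ExpressionMatrix, genes: list[str], use_log: bool = True
) -> pd.Series:
    """Arithmetic mean of marker-gene expression per sample."""
    present, _ = _present_genes(expr, genes, "mean score")
    return _log_values(expr, use_log).loc[present].mean(axis=0)


def score_geometric_mean(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Geometric mean with +1 pseudocount: exp(mean(ln(x+1))) - 1.

    All-zero input maps to 0; a single-gene set reduces to that gene's
    value. Operates on the raw TPM scale (the log is intrinsic here).
    """
    present, _ = _present_genes(expr, genes, "geometric mean score")
    if expr.log_transformed:
        raise ValueError("geometric mean expects a raw-scale matrix")
    block = expr.values.loc[present].astype(float)
    return np.exp(np.log1p(block).mean(axis=0)) - 1.0


def score_weighted_sum(
    expr: ExpressionMatrix,
    genes: list[str],
    weights: list[float],
    use_log: bool = True,
) -> pd.Series:
    """Weighted sum of marker-gene expression; absent genes contribute 0."""
    if len(genes) != len(weights):
        raise ValueError(f"{len(weights)} weights for {len(genes)} genes")
    weight_of = {g.upper(): w for g, w in zip(genes, weights)}
    present, _ = _present_genes(expr, genes, "weighted sum score")
    block = _log_values(expr, use_log).loc[present]
    w = np.array([weight_of[g] for g in present], dtype=float)
    return pd.Series(block.to_numpy().T @ w, index=block.columns)


def score_pca1(
    expr: ExpressionMatrix, genes: list[str], use_log: bool = True
) -> pd.Series:
    """First principal-component coordinate of samples over signature genes.

    The signature submatrix is z-scored per gene; the PC1 sign is fixed so
    the score correlates non-negatively with the signature mean, making the
    score usable in directional tests.
    """
    present, _ = _present_genes(expr, genes, "PCA score")
    if len(present) < 2:
        raise DegenerateDataError("PCA score needs >=2 signature genes present")
    block = _log_values(expr, use_log).loc[present].astype(float)
    if block.shape[1] < 3:
        raise DegenerateDataError("PCA score needs >=3 samples")
    sd = block.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise DegenerateDataError("zero-variance signature submatrix")
    keep = sd > 0
    block = block.loc[keep.index[keep]]
    z = block.sub(block.mean(axis=1), axis=0).div(
        block.std(axis=1, ddof=1), axis=0
    )
    # samples as observations: SVD of the centered samples x genes matrix
    x = z.to_numpy().T
    x = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[0]
    reference = z.mean(axis=0).to_numpy()
    reference = reference - reference.mean()
    if float(scores @ reference) < 0:
        scores = -scores
    return pd.Series(scores, index=block.columns)


def score_impres(
    expr: ExpressionMatrix, pairs: list[tuple[str, str]] | tuple
) -> pd.Series:
    """Count of pairwise checkpoint-gene inequalities satisfied per sample.

    Each pair ``(a, b)`` contributes 1 when ``expr[a] > expr[b]`` strictly;
    ties contribute 0, so the score is an integer in ``[0, n_pairs]``
    (0..15 for the built-in catalogue). Pairs with either gene absent are
    skipped with a warning.
    """
    if not pairs:
        raise ValueError("IMPRES needs a non-empty pair list")
    index = expr.values.index
    counts = np.zeros(expr.values.shape[1], dtype=int)
    skipped = []
    for a, b in pairs:
        a, b = a.upper(), b.upper()
        if a not in index or b not in index:
            skipped.append((a, b))
            continue
        counts += (
            expr.values.loc[a].to_numpy() > expr.values.loc[b].to_numpy()
        ).astype(int)
    if skipped:
        warnings.warn(
            f"IMPRES: skipped {len(skipped)} pairs with absent genes",
            CoverageWarning,
            stacklevel=2,
        )
    if len(skipped) == len(pairs):
        raise MissingGeneError("IMPRES: no pair fully present in the matrix")
    return pd.Series(counts, index=expr.values.columns)


def score_overall_expression(
    expr: ExpressionMatrix,
    genes: list[str],
    n_bins: int = 50,
    n_controls: int = 100,
    seed: int | None = 0,
    use_log: bool = True,
) -> pd.Series:
    """Overall expression (OE) of a gene program, bin-matched and z-scored.

    Genes are binned into ``n_bins`` equal-frequency bins by their average
    expression across samples; each signature gene is compared against
    ``n_controls`` genes sampled (seeded) from its own bin. The score is
    the mean over signature genes of the gene's z-scored expression minus
    the mean z-scored expression of its matched controls, which removes
    the sample-level association between program score and overall
    expression depth.
    """
    values = _log_values(expr, use_log).astype(float)
    n_genes = values.shape[0]
    if n_genes < n_bins:
        raise DegenerateDataError(
            f"transcriptome of {n_genes} genes is smaller than {n_bins} bins"
        )
    present, _ = _present_genes(expr, genes, "overall expression score")
    if len(present) >= n_genes:
        raise DegenerateDataError("signature covers the whole transcriptome")
    sd = values.std(axis=1, ddof=0).replace(0, 1.0)
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    mean_expr = values.mean(axis=1)
    bins = pd.qcut(mean_expr.rank(method="first"), q=n_bins, labels=False)
    rng = np.random.default_rng(seed)
    z_np = z.to_numpy()
    gene_pos = {g: i for i, g in enumerate(values.index)}
    bin_members: dict[int, np.ndarray] = {
        int(b): np.flatnonzero(bins.to_numpy() == b) for b in np.unique(bins)
    }
    signature_rows = np.array([gene_pos[g] for g in present])
    control_means = np.zeros((len(present), values.shape[1]))
    for i, g in enumerate(present):
        pool = bin_members[int(bins.iloc[gene_pos[g]])]
        pool = pool[pool != gene_pos[g]]
        if pool.size == 0:
            continue
        chosen = rng.choice(pool, size=n_controls, replace=pool.size < n_controls)
        control_means[i] = z_np[chosen].mean(axis=0)
    signal = z_np[signature_rows] - control_means
    return pd.Series(signal.mean(axis=0), index=values.columns)


def score_marker_mean(
    expr: ExpressionMatrix, genes: list[str], use_log: bool = True
) -> pd.Series:
    """Cell-population abundance as the mean log-expression of its markers
    (MCP-counter convention); shares the mean kernel."""
    return score_mean(expr, genes, use_log=use_log)


def compute_all_scores(
    expr: ExpressionMatrix,
    registry: Registry,
    adapter_tables: dict[str, pd.Series] | pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    use_log: bool = True,
    oe_seed: int = 0,
    nes_per_set: bool = False,
) -> ScoreTable:
    """Compute every registry entry for every sample.

    Native entries are computed from the matrix; adapter entries (external
    models such as TIDE or CIBERSORTx-derived fractions) are joined by
    sample id from ``adapter_tables`` and left as NA when not provided. All
    enrichment-based entries share one ES computation and one cohort-level
    NES normalization.
    """
    if isinstance(adapter_tables, pd.DataFrame):
        adapter_tables = {c: adapter_tables[c] for c in adapter_tables.columns}
    adapter_tables = adapter_tables or {}
    sample_index = pd.Index(expr.sample_ids)
    for name, series in adapter_tables.items():
        unknown = set(series.index.astype(str)) - set(sample_index)
        if unknown:
            raise ValueError(
                f"adapter table {name!r} has unknown sample ids: "
                f"{sorted(unknown)[:5]}"
            )

    # one ES/NES pass over every member set any enrichment entry needs
    needed_sets: dict[str, list[str]] = {}
    for spec in registry.entries:
        if spec.method == "ssgsea_single":
            needed_sets[spec.gene_sets[0] if spec.gene_sets else spec.name] = list(
                spec.genes
            )
        elif spec.method == "ssgsea_combo":
            for set_name in spec.gene_sets:
                needed_sets.setdefault(set_name, registry.gene_sets[set_name])
    nes = None
    if needed_sets:
        es = ssgsea_es_matrix(expr.values, needed_sets, alpha=alpha)
        nes = ssgsea_nes(es, per_set=nes_per_set)

    columns: dict[str, pd.Series] = {}
    methods: dict[str, str] = {}
    missing: dict[str, float] = {}
    for spec in registry.entries:
        methods[spec.name] = spec.method
        missing[spec.name] = 0.0
        genes = list(spec.genes)
        try:
            if spec.method == "adapter":
                series = adapter_tables.get(spec.name)
                if series is None:
                    column = pd.Series(np.nan, index=sample_index)
                else:
                    column = series.reindex(sample_index)
            elif spec.method == "single_gene":
                column = score_single_gene(expr, genes[0], use_log=use_log)
            elif spec.method == "mean":
                column = score_mean(expr, genes, use_log=use_log)
            elif spec.method == "geometric_mean":
                column = score_geometric_mean(expr, genes)
            elif spec.method == "weighted_sum":
                column = score_weighted_sum(
                    expr, genes, list(spec.weights), use_log=use_log
                )
            elif spec.method == "pca1":
                column = score_pca1(expr, genes, use_log=use_log)
            elif spec.method == "impres_pairs":
                column = score_impres(expr, list(spec.pairs))
            elif spec.method == "overall_expression":
                column = score_overall_expression(
                    expr, genes, seed=oe_seed, use_log=use_log
                )
            elif spec.method == "marker_mean":
                column = score_marker_mean(expr, genes, use_log=use_log)
            elif spec.method == "ssgsea_single":
                set_name = spec.gene_sets[0] if spec.gene_sets else spec.name
                column = nes.nes[set_name]
            elif spec.method == "ssgsea_combo":
                column = combine_nes(
                    nes,
                    list(spec.gene_sets),
                    mode=spec.combine,
                    weights=list(spec.weights) if spec.weights else None,
                )
            else:  # pragma: no cover - registry validation prevents this
                raise ValueError(f"unknown method {spec.method!r}")
        except MissingGeneError:
            warnings.warn(
                f"score {spec.name!r} not computable on this matrix; column NA",
                CoverageWarning,
                stacklevel=2,
            )
            column = pd.Series(np.nan, index=sample_index)
            missing[spec.name] = 1.0
        if spec.method not in ("adapter",) and genes:
            unique = set(g.upper() for g in genes)
            present = unique & set(expr.values.index)
            missing[spec.name] = max(
                missing[spec.name], 1.0 - len(present) / len(unique)
            )
        columns[spec.name] = column.reindex(sample_index)

    table = pd.DataFrame(columns, index=sample_index)[registry.names]
    return ScoreTable(values=table, methods=methods, missing_fraction=missing)
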