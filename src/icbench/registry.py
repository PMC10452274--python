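"""The built-in catalogue of 48 ICB-response scoring systems.

Each scoring system is a :class:`SignatureSpec`: a gene list (or a list of
member gene sets for combined enrichment scores), a computation method tag,
the expected direction of association with ICB response, and whether the
score is computed natively or imported from an external tool ("adapter"
entries such as TIDE or CIBERSORTx-derived fractions).

The 48 systems derive from 39 underlying biomarker sets: nine gene sets
contributed both a self-contained score and an additional single-set
enrichment score, and those pairs share a ``set_id``. Gene lists ship as
static data files; lists whose full published tables could not be
transcribed are synthetic reconstructions and are flagged as such in their
``provenance`` field and data-file descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd
import yaml

from .errors import RegistryError
from .io import GeneSetCollection, read_gmt

CATEGORIES = ("self_contained", "competitive", "deconvolution_like")
METHODS = (
    "single_gene", "mean", "geometric_mean", "weighted_sum", "pca1",
    "impres_pairs", "overall_expression", "ssgsea_single", "ssgsea_combo",
    "marker_mean", "adapter",
)
DIRECTIONS = ("positive", "negative")


@dataclass(frozen=True)
class SignatureSpec:
    """One scoring system of the catalogue (or a user-defined addition)."""

    name: str
    category: str
    method: str
    direction: str
    genes: tuple[str, ...] = ()
    gene_sets: tuple[str, ...] = ()  # member set names (ssgsea_combo)
    weights: tuple[float, ...] | None = None  # aligned to genes or gene_sets
    pairs: tuple[tuple[str, str], ...] | None = None  # impres_pairs only
    combine: str | None = None  # sum | mean | weighted_sum (ssgsea_combo)
    native: bool = True
    continuous: bool = True
    set_id: str | None = None  # underlying biomarker set (39 distinct)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RegistryError(f"{self.name}: unknown category {self.category!r}")
        if self.method not in METHODS:
            raise RegistryError(f"{self.name}: unknown method {self.method!r}")
        if self.direction not in DIRECTIONS:
            raise RegistryError(f"{self.name}: unknown direction {self.direction!r}")
        if self.method == "impres_pairs" and not self.pairs:
            raise RegistryError(f"{self.name}: impres_pairs requires pairs")
        if self.weights is not None:
            target = self.gene_sets if self.method == "ssgsea_combo" else self.genes
            if len(self.weights) != len(target):
                raise RegistryError(
                    f"{self.name}: {len(self.weights)} weights for "
                    f"{len(target)} genes/sets"
                )
        if self.native and self.method != "adapter":
            if self.method == "ssgsea_combo":
                if not self.gene_sets:
                    raise RegistryError(f"{self.name}: combo entry without sets")
            elif self.method != "impres_pairs" and not self.genes:
                raise RegistryError(f"{self.name}: native entry without genes")


@dataclass
class Registry:
    """Ordered collection of scoring systems plus their member gene sets."""

    entries: list[SignatureSpec] = field(default_factory=list)
    gene_sets: GeneSetCollection = field(default_factory=GeneSetCollection)

    def __post_init__(self) -> None:
        names = [spec.name for spec in self.entries]
        if len(names) != len(set(names)):
            raise RegistryError("duplicate scoring-system names in registry")

    @property
    def names(self) -> list[str]:
        return [spec.name for spec in self.entries]

    def __getitem__(self, name: str) -> SignatureSpec:
        for spec in self.entries:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.entries)

    def member_genes(self, spec: SignatureSpec) -> tuple[str, ...]:
        """All genes a spec touches (union of member sets for combos)."""
        if spec.method == "impres_pairs":
            return spec.genes
        if spec.method == "ssgsea_combo":
            out: list[str] = []
            for set_name in spec.gene_sets:
                for gene in self.gene_sets[set_name]:
                    if gene not in out:
                        out.append(gene)
            return tuple(out)
        return spec.genes

    def all_genes(self) -> list[str]:
        """Union of genes across all native entries (insertion order)."""
        out: list[str] = []
        for spec in self.entries:
            if not spec.native:
                continue
            for gene in self.member_genes(spec):
                if gene not in out:
                    out.append(gene)
        return out

    def validate(self) -> None:
        """Check that every native entry has the fields its method needs."""
        for spec in self.entries:
            if spec.method == "ssgsea_combo":
                missing = [s for s in spec.gene_sets if s not in self.gene_sets.names]
                if missing:
                    raise RegistryError(f"{spec.name}: unknown member sets {missing}")
                if spec.combine not in ("sum", "mean", "weighted_sum"):
                    raise RegistryError(f"{spec.name}: bad combine {spec.combine!r}")
                if spec.combine == "weighted_sum" and spec.weights is None:
                    raise RegistryError(f"{spec.name}: weighted combo without weights")
            if spec.method == "weighted_sum" and spec.weights is None:
                raise RegistryError(f"{spec.name}: weighted_sum without weights")


def _data_path(name: str):
    return resources.files("icbench.data").joinpath(name)


def load_builtin_registry() -> Registry:
    """Load the 48-system catalogue shipped with the package."""
    with resources.as_file(_data_path("registry.yaml")) as path:
        manifest = yaml.safe_load(path.read_text())
    with resources.as_file(_data_path("gene_sets.gmt")) as path:
        sets = read_gmt(path)
    with resources.as_file(_data_path("gene_sets_synthetic.gmt")) as path:
        synth = read_gmt(path)
    gene_sets = GeneSetCollection(sets.entries + synth.entries)
    with resources.as_file(_data_path("weights.tsv")) as path:
        weight_rows = pd.read_csv(path, sep="\t")
    weight_map: dict[str, dict[str, float]] = {}
    for owner, group in weight_rows.groupby("owner"):
        weight_map[owner] = dict(zip(group["key"], group["weight"].astype(float)))
    with resources.as_file(_data_path("impres_pairs.tsv")) as path:
        pair_rows = pd.read_csv(path, sep="\t")
    impres_pairs = tuple(
        (str(a), str(b)) for a, b in zip(pair_rows["high_gene"], pair_rows["low_gene"])
    )

    entries: list[SignatureSpec] = []
    for raw in manifest["entries"]:
        name = raw["name"]
        method = raw["method"]
        member_sets = tuple(raw.get("gene_sets") or ())
        genes: tuple[str, ...] = ()
        weights = None
        pairs = None
        if method == "impres_pairs":
            genes = tuple(gene_sets[member_sets[0]])
            pairs = impres_pairs
        elif method == "ssgsea_combo":
            if raw.get("weights"):
                table = weight_map[raw["weights"]]
                weights = tuple(table[s] for s in member_sets)
        elif member_sets:
            merged: list[str] = []
            for set_name in member_sets:
                for gene in gene_sets[set_name]:
                    if gene not in merged:
                        merged.append(gene)
            genes = tuple(merged)
            if raw.get("weights"):
                table = weight_map[raw["weights"]]
                weights = tuple(table[g] for g in genes)
        entries.append(
            SignatureSpec(
                name=name,
                category=raw["category"],
                method=method,
                direction=raw["direction"],
                genes=genes,
                gene_sets=member_sets if method == "ssgsea_combo" else (),
                weights=weights,
                pairs=pairs,
                combine=raw.get("combine"),
                native=bool(raw.get("native", True)),
                continuous=bool(raw.get("continuous", True)),
                set_id=raw.get("set_id", name),
                provenance=str(raw.get("provenance", "")),
            )
        )
    registry = Registry(entries=entries, gene_sets=gene_sets)
    registry.validate()
    return registry


def register_custom(
    registry: Registry,
    name: str,
    genes: list[str],
    calc: str,
    direction: str = "positive",
) -> Registry:
    """Return a new registry extended with a user-supplied signature.

    ``calc`` selects the computation applied to the submitted gene list:
    ``ssgsea`` (single-set enrichment), ``mean``, or ``sum``. A single-gene
    submission maps to the single-gene method regardless of ``calc``.
    """
    if name in registry:
        raise RegistryError(f"scoring system {name!r} already registered")
    genes = [g.strip().upper() for g in genes if g.strip()]
    if not genes:
        raise RegistryError("custom signature has an empty gene list")
    if calc not in ("ssgsea", "mean", "sum"):
        raise RegistryError(f"unknown calc {calc!r}; use ssgsea, mean, or sum")
    if len(genes) == 1:
        method = "single_gene"
        weights = None
    elif calc == "ssgsea":
        method = "ssgsea_single"
        weights = None
    elif calc == "mean":
        method = "mean"
        weights = None
    else:  # sum == weighted sum with unit weights
        method = "weighted_sum"
        weights = tuple(1.0 for _ in genes)
    spec = SignatureSpec(
        name=name,
        category="self_contained" if calc != "ssgsea" else "competitive",
        method=method,
        direction=direction,
        genes=tuple(genes),
        weights=weights,
        set_id=name,
        provenance="user-defined",
    )
    new_sets = GeneSetCollection(
        registry.gene_sets.entries + [(name, "user-defined", list(genes))]
    )
    return Registry(entries=registry.entries + [spec], gene_sets=new_sets)


def rank_genes_by_frequency(
    registry: Registry, direction: str
) -> list[tuple[str, int]]:
    """Rank genes by how many distinct biomarker *sets* of a direction use them.

    Counting is over the underlying biomarker sets (``set_id``), not the
    scoring systems, so a gene list scored both directly and through
    enrichment counts once. Ties are broken lexicographically.
    """
    if direction not in DIRECTIONS:
        raise RegistryError(f"unknown direction {direction!r}")
    genes_by_set: dict[str, set[str]] = {}
    for spec in registry.entries:
        if spec.direction != direction or not spec.native:
            continue
        set_id = spec.set_id or spec.name
        genes_by_set.setdefault(set_id, set()).update(registry.member_genes(spec))
    counts: dict[str, int] = {}
    for members in genes_by_set.values():
        for gene in members:
            counts[gene] = counts.get(gene, 0) + 1
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


def with_direction(spec: SignatureSpec, direction: str) -> SignatureSpec:
    """Copy of a spec with its direction overridden (config-driven runs)."""
    return replace(spec, direction=direction)
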