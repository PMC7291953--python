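"""Reading, validation, filtering, and rarefaction of ZOTU count tables.

A ZOTU (zero-radius operational taxonomic unit) table holds integer read
counts per taxon per sample.  On disk it is a tab-separated file with taxa
as rows, a ``#ZOTU_ID`` first header field, and one column per sample.
Sample metadata is a TSV with mandatory columns ``sample_id``, ``habitat``
(``MP`` melt pond / ``SW`` sea water) and ``size_fraction``
(``micro``/``nano``/``pico``), plus arbitrary numeric covariate columns.
Phylogenies are rooted newick trees with branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

HABITATS = frozenset({"MP", "SW"})
SIZE_FRACTIONS = frozenset({"micro", "nano", "pico"})

METADATA_REQUIRED = ("sample_id", "habitat", "size_fraction")


class ValidationError(ValueError):
    """Input violates a structural contract (duplicate ids, bad vocabulary...)."""


@dataclass(frozen=True)
class ZotuTable:
    """Integer count matrix, taxa x samples.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = taxon ids, columns = sample ids.
    """

    counts: pd.DataFrame = field()

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate taxon id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not all(np.issubdtype(t, np.integer) for t in df.dtypes):
            raise ValidationError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as a (taxa x samples) integer ndarray."""
        return self.counts.to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def drop_empty_taxa(self) -> "ZotuTable":
        """Remove taxa with zero total count."""
        return ZotuTable(self.counts.loc[self.counts.sum(axis=1) > 0])

    def select_samples(self, sample_ids) -> "ZotuTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return ZotuTable(self.counts[list(sample_ids)])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts / totals


def read_zotu_table(path) -> ZotuTable:
    """Read a taxa-by-samples count table from TSV.

    First column holds taxon ids (header field conventionally ``#ZOTU_ID``);
    remaining header fields are sample ids.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = pd.to_numeric(vals, errors="coerce")
            bad = as_float.isna() | (as_float != np.floor(as_float))
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValidationError(
                    f"{path}: non-integer count at row {row!r}, column {col!r}"
                )
            df[col] = as_float.astype(np.int64)
    return ZotuTable(df)


def write_zotu_table(table: ZotuTable, path, id_header: str = "#ZOTU_ID") -> None:
    table.counts.rename_axis(id_header).to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    Returns a DataFrame indexed by ``sample_id`` with ``habitat`` and
    ``size_fraction`` categorical columns plus any numeric covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.name == "sample_id":
        df = df.reset_index()
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
    bad_h = set(df["habitat"]) - HABITATS
    if bad_h:
        raise ValidationError(
            f"unknown habitat label(s) {sorted(bad_h)}; allowed: {sorted(HABITATS)}"
        )
    bad_f = set(df["size_fraction"]) - SIZE_FRACTIONS
    if bad_f:
        raise ValidationError(
            f"unknown size_fraction label(s) {sorted(bad_f)}; "
            f"allowed: {sorted(SIZE_FRACTIONS)}"
        )
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; every non-root branch must have a length."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen = set()
        dup = next(t for t in tips if t in seen or seen.add(t))
        raise ValidationError(f"duplicate tip label: {dup!r}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                "tree has branches without lengths; phylogenetic metrics "
                "(PD, UniFrac, betaMNTD) are undefined"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


def filter_min_count(table: ZotuTable, min_total: int = 4) -> ZotuTable:
    """Drop taxa whose total count across samples is below ``min_total``.

    The default of 4 removes ZOTUs represented by fewer than four reads,
    the usual guard against denoising artifacts.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.taxon_totals >= min_total
    return ZotuTable(table.counts.loc[keep])


def rarefy(table: ZotuTable, depth: int, seed: int = 0) -> ZotuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample column is drawn from a multivariate hypergeometric
    distribution (equivalent to permuting the sample's reads and keeping the
    first ``depth``), so a taxon absent from a sample stays absent.  Samples
    whose total is below ``depth`` are dropped with a warning.  Taxa left
    with zero counts everywhere are removed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be > 0")
    totals = table.sample_totals
    shallow = list(totals.index[totals < depth])
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: {shallow}",
            stacklevel=2,
        )
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    if not keep:
        raise ValidationError(f"no sample has total count >= depth {depth}")
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth)
    rare = pd.DataFrame(out, index=table.counts.index, dtype=np.int64)
    return ZotuTable(rare).drop_empty_taxa()


def align_table_tree(
    table: ZotuTable, tree: TreeNode, strict: bool = False
) -> tuple[ZotuTable, TreeNode]:
    """Reconcile the taxon sets of a count table and a phylogeny.

    The tree is pruned to tips present in the table.  Table taxa absent
    from the tree are dropped with a warning, or raise in ``strict`` mode.
    """
    tips = {t.name for t in tree.tips()}
    taxa = set(table.taxon_ids)
    common = taxa & tips
    if not common:
        raise ValidationError("table taxa and tree tips are disjoint")
    missing = sorted(taxa - tips)
    if missing:
        if strict:
            raise ValidationError(
                f"{len(missing)} table taxa missing from tree: {missing[:10]}"
            )
        warnings.warn(
            f"dropping {len(missing)} table taxa missing from tree",
            stacklevel=2,
        )
        table = ZotuTable(table.counts.loc[[t for t in table.taxon_ids if t in common]])
    if tips - common:
        tree = tree.shear(common)
        tree.prune()
    return table, tree
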