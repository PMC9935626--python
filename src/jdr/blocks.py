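"""Expression-matrix containers and preprocessing.

The unit of data is an :class:`ExpressionBlock`: one cohort's expression
matrix held internally as samples x genes so that genes — the axis shared
between cohorts — are the feature axis and right singular vectors of any
decomposition are metagenes.

Preprocessing follows the standard bulk RNA-seq recipe for joint dimension
reduction: upper-quartile normalisation, log2 transform, intersection to a
common gene list, and per-gene mean centering.  Mouse cohorts are mapped
onto human gene symbols through the Jackson Laboratory homolog report
before intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionBlock",
    "HomologMap",
    "read_expression_matrix",
    "upper_quartile_log_normalize",
    "intersect_and_align",
    "mean_center_genes",
    "parse_homolog_map",
    "apply_homolog_map",
]


@dataclass
class ExpressionBlock:
    """One cohort's expression matrix (samples x genes) plus metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Samples in rows, genes in columns.  Gene labels are upper-cased and
        must be unique after upper-casing.
    sample_meta : pandas.DataFrame, optional
        Per-sample annotations (tissue, subtype, response ...), indexed by
        sample id.
    centered : bool
        True once every gene column has mean zero.
    block_name : str
        Human-readable cohort tag used in reports.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    centered: bool = False
    block_name: str = "block"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.columns = [str(c).upper() for c in self.values.columns]
        genes = pd.Index(self.values.columns)
        if genes.has_duplicates:
            dups = genes[genes.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate gene labels after upper-casing in block "
                f"'{self.block_name}': {dups[:5]}"
            )
        if pd.Index(self.values.index).has_duplicates:
            raise ValueError(f"duplicate sample ids in block '{self.block_name}'")
        if self.values.shape[0] == 0:
            raise ValueError("no samples")
        if self.centered:
            col_means = np.asarray(self.values, dtype=float).mean(axis=0)
            if np.abs(col_means).max() > 1e-8:
                raise ValueError("centered flag set but gene means are nonzero")

    @property
    def gene_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        """Dense float array, samples x genes."""
        return np.asarray(self.values, dtype=float)

    def with_values(self, values: pd.DataFrame, *, centered: bool | None = None) -> "ExpressionBlock":
        return ExpressionBlock(
            values=values,
            sample_meta=self.sample_meta,
            centered=self.centered if centered is None else centered,
            block_name=self.block_name,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionBlock({self.block_name!r}, {self.n_samples} samples x "
            f"{self.n_genes} genes, centered={self.centered})"
        )


@dataclass
class HomologMap:
    """Single-valued mapping from non-human gene symbols to human symbols."""

    pairs: dict[str, str]
    source_organism: str = "mouse, laboratory"

    def __post_init__(self) -> None:
        for k, v in self.pairs.items():
            if not k or not v:
                raise ValueError("homolog map contains empty symbol")
        self.pairs = {k.upper(): v.upper() for k, v in self.pairs.items()}


def read_expression_matrix(
    path,
    orientation: str = "genes_as_rows",
    block_name: str | None = None,
) -> ExpressionBlock:
    """Read a tab-separated expression matrix into the internal orientation.

    The file must have one header row of ids and one leading label column.
    ``orientation`` says what the file's rows are; internally the block is
    always samples x genes.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("no samples")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "genes_as_rows":
        df = df.T
    name = block_name if block_name is not None else str(path)
    return ExpressionBlock(values=df, block_name=name)


def _upper_quartile(nonzero: np.ndarray) -> float:
    # linear-interpolation 75th percentile of the nonzero entries
    return float(np.percentile(nonzero, 75, method="linear"))


def upper_quartile_log_normalize(
    block: ExpressionBlock,
    target: float | None = None,
    pseudo: float = 1.0,
) -> ExpressionBlock:
    """Upper-quartile normalise each sample, then log2(x + pseudo).

    Each sample is rescaled so its 75th percentile of nonzero values equals
    ``target``.  When ``target`` is None the geometric mean of the per-sample
    upper quartiles is used, which leaves a typical sample near its original
    scale.  Proportional samples map to identical vectors.
    """
    X = block.matrix()
    if np.any(X < 0):
        raise ValueError("negative expression value; expected raw non-negative quantifications")
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    uqs = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        nz = X[i][X[i] > 0]
        if nz.size == 0:
            raise ValueError(f"all-zero sample: {block.sample_ids[i]!r}")
        uqs[i] = _upper_quartile(nz)
    if target is None:
        target = float(np.exp(np.mean(np.log(uqs))))
    elif target <= 0:
        raise ValueError("target must be positive")
    scaled = X * (target / uqs)[:, None]
    out = pd.DataFrame(
        np.log2(scaled + pseudo), index=block.values.index, columns=block.values.columns
    )
    return block.with_values(out, centered=False)


def intersect_and_align(
    blocks: list[ExpressionBlock],
    drop_zero_genes: str = "any_block",
) -> list[ExpressionBlock]:
    """Restrict all blocks to a shared, identically ordered gene list.

    ``drop_zero_genes`` controls removal of unexpressed genes:

    - ``"any_block"`` (default, strict): drop a gene if it is zero in every
      sample of at least one block;
    - ``"all_blocks"``: drop only genes zero everywhere in every block;
    - ``"keep"``: no zero filtering.

    Sample sets are untouched.
    """
    if len(blocks) < 2:
        raise ValueError("need at least two blocks to intersect")
    if drop_zero_genes not in ("any_block", "all_blocks", "keep"):
        raise ValueError(f"unknown drop_zero_genes mode: {drop_zero_genes!r}")
    common = blocks[0].values.columns
    for b in blocks[1:]:
        common = common.intersection(b.values.columns)
    common = common.sort_values()
    if len(common) == 0:
        raise ValueError("empty gene intersection across blocks")
    if drop_zero_genes != "keep":
        zero_flags = np.vstack(
            [(b.values[common].to_numpy() == 0).all(axis=0) for b in blocks]
        )
        drop = zero_flags.any(axis=0) if drop_zero_genes == "any_block" else zero_flags.all(axis=0)
        common = common[~drop]
        if len(common) == 0:
            raise ValueError("empty gene intersection after zero-gene filtering")
    return [b.with_values(b.values[common].copy(), centered=False) for b in blocks]


def mean_center_genes(block: ExpressionBlock) -> ExpressionBlock:
    """Center each gene to mean zero across the block's samples."""
    centered = block.values - block.values.mean(axis=0)
    return block.with_values(centered, centered=True)


def parse_homolog_map(path, organism: str = "mouse, laboratory") -> HomologMap:
    """Parse the JAX ``HOM_MouseHumanSequence.rpt`` report into symbol pairs.

    Rows sharing a homology-class key are grouped; within each class the
    ``organism`` symbols are mapped to the human symbol.  Classes with no
    human entry are dropped; classes with several human symbols keep the
    first in file order (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    key_col = next((c for c in df.columns if "homologene" in c.lower() or "class key" in c.lower()), None)
    org_col = next((c for c in df.columns if "organism" in c.lower()), None)
    sym_col = next((c for c in df.columns if c.lower() == "symbol"), None)
    if key_col is None or org_col is None or sym_col is None:
        raise ValueError(
            "malformed homolog report header: need homology class key, "
            f"organism and Symbol columns, got {list(df.columns)}"
        )
    organisms = {str(o).strip().lower() for o in df[org_col].dropna().unique()}
    if organism.strip().lower() not in organisms:
        raise ValueError(f"unknown organism {organism!r}; file contains {sorted(organisms)}")
    pairs: dict[str, str] = {}
    for _, grp in df.groupby(key_col, sort=False):
        orgs = grp[org_col].str.strip().str.lower()
        humans = grp.loc[orgs.str.startswith("human"), sym_col].dropna().tolist()
        sources = grp.loc[orgs == organism.strip().lower(), sym_col].dropna().tolist()
        if not humans or not sources:
            continue
        if len(humans) > 1:
            logger.info("homology class with %d human symbols; keeping %r", len(humans), humans[0])
        human = str(humans[0]).upper()
        for s in sources:
            pairs[str(s).upper()] = human
    return HomologMap(pairs=pairs, source_organism=organism)


def apply_homolog_map(block: ExpressionBlock, homolog_map: HomologMap) -> ExpressionBlock:
    """Rename genes to human symbols via the homolog map.

    Labels are upper-cased; labels present in the map are translated, others
    kept as-is.  When several source genes map to one human symbol, the one
    with the highest variance across samples is kept and the drops logged.
    """
    df = block.values
    new_labels = [homolog_map.pairs.get(g, g) for g in df.columns]
    variances = df.var(axis=0, ddof=0).to_numpy()
    keep: dict[str, int] = {}
    dropped = []
    for idx, label in enumerate(new_labels):
        if label not in keep:
            keep[label] = idx
        elif variances[idx] > variances[keep[label]]:
            dropped.append(df.columns[keep[label]])
            keep[label] = idx
        else:
            dropped.append(df.columns[idx])
    if dropped:
        logger.info(
            "homolog mapping collapsed %d lower-variance genes: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    cols = sorted(keep, key=keep.get)
    out = df.iloc[:, [keep[c] for c in cols]].copy()
    out.columns = cols
    return block.with_values(out, centered=False)
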