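"""Per-sample and per-gene-set partition of variation after decomposition.

Because J, I and E are pairwise orthogonal projections of each sample's
row, a sample's total sum of squares splits additively across the three
components; the per-sample percentages quantify how well that sample is
represented by structure shared with the partner cohort.  The same
bookkeeping applied to gene variances within a gene set shows how much of
a signature's variation translates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ajive import AJIVEResults

logger = logging.getLogger(__name__)

__all__ = ["VariationProfile", "GeneSetPartition", "sample_variation_profile", "gene_set_partition"]


@dataclass
class VariationProfile:
    """Per-sample percent of variation in joint/individual/residual structure."""

    block_name: str
    table: pd.DataFrame  # index: sample ids; pct_joint, pct_individual, pct_residual, joint_individual_ratio

    @property
    def pct_joint(self) -> pd.Series:
        return self.table["pct_joint"]

    @property
    def pct_individual(self) -> pd.Series:
        return self.table["pct_individual"]

    @property
    def pct_residual(self) -> pd.Series:
        return self.table["pct_residual"]

    @property
    def joint_individual_ratio(self) -> pd.Series:
        return self.table["joint_individual_ratio"]

    def grouped_ratio(self, groups: pd.Series) -> pd.DataFrame:
        """Distribution of the joint/individual ratio per group (e.g. tissue)."""
        df = self.table.copy()
        df["group"] = groups.reindex(df.index)
        return df.groupby("group")["joint_individual_ratio"].describe()


@dataclass
class GeneSetPartition:
    """How a gene set's summed variance splits across O, J and I."""

    gene_set_name: str
    n_genes_used: int
    var_original: float
    var_joint: float
    var_individual: float

    @property
    def frac_joint(self) -> float:
        return self.var_joint / self.var_original

    @property
    def frac_individual(self) -> float:
        return self.var_individual / self.var_original


def sample_variation_profile(result: AJIVEResults, block_name: str) -> VariationProfile:
    """Percent of each sample's sum of squares in J, I and E.

    Computed directly from the component rows: the components are exact
    row-space projections, so the row norms reproduce the SVD-based
    formulation.  Samples with zero total sum of squares are flagged with
    NaN percentages.
    """
    dec = result.block(block_name)
    tot = np.sum(dec.X**2, axis=1)
    zero = tot == 0
    if zero.any():
        logger.warning("%d zero-variance samples in %s; percentages set to NaN", zero.sum(), block_name)
    safe_tot = np.where(zero, np.nan, tot)
    pj = 100.0 * np.sum(dec.J**2, axis=1) / safe_tot
    pi = 100.0 * np.sum(dec.I**2, axis=1) / safe_tot
    pe = 100.0 * np.sum(dec.E**2, axis=1) / safe_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pj / pi
    table = pd.DataFrame(
        {
            "pct_joint": pj,
            "pct_individual": pi,
            "pct_residual": pe,
            "joint_individual_ratio": ratio,
        },
        index=pd.Index(result.sample_ids[block_name], name="sample_id"),
    )
    return VariationProfile(block_name=block_name, table=table)


def gene_set_partition(
    result: AJIVEResults,
    block_name: str,
    gene_set,
    gene_set_name: str = "gene_set",
) -> GeneSetPartition:
    """Summed gene variances of a set within the original, joint and
    individual matrices, as fractions of the original."""
    dec = result.block(block_name)
    genes = pd.Index(result.gene_labels)
    wanted = pd.Index([str(g).upper() for g in gene_set])
    if len(wanted) == 0:
        raise ValueError("empty gene set")
    present = wanted.intersection(genes)
    missing = wanted.difference(genes)
    if len(present) == 0:
        raise ValueError(f"no genes of set {gene_set_name!r} present in block {block_name!r}")
    if len(missing):
        logger.warning("gene set %s: %d genes absent from block", gene_set_name, len(missing))
    cols = genes.get_indexer(present)
    var_o = float(np.var(dec.X[:, cols], axis=0, ddof=0).sum())
    var_j = float(np.var(dec.J[:, cols], axis=0, ddof=0).sum())
    var_i = float(np.var(dec.I[:, cols], axis=0, ddof=0).sum())
    return GeneSetPartition(
        gene_set_name=gene_set_name,
        n_genes_used=int(len(present)),
        var_original=var_o,
        var_joint=var_j,
        var_individual=var_i,
    )
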