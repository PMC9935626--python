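"""Per-gene joint statistic, permutation p-values and SAM-style FDR cutoffs.

For each gene g the joint statistic is the signed log-ratio of its variance
in the joint matrix to its variance in the individual matrix, with both
variances floored at a threshold s that suppresses artefacts from
low-variance genes::

    T_g = log( max(var_J_g, s) / max(var_I_g, s) )

(natural log; s defaults to 0.5).  Positive values indicate joint-acting
(translatable) behaviour, negative values block-specific behaviour.

Significance is assessed by permutation: per gene, the joint-row and
individual-row entries are pooled, shuffled and re-split, and the statistic
recomputed.  False-discovery-rate cutoffs follow the SAM permutation
estimator — for a candidate cutoff c the estimated FDR is the median over
permutations of the number of null statistics beyond c, divided by the
number of observed statistics beyond c — applied independently to the
positive and negative tails.

Genes significant in both integrated cohorts are "fully joint"
(translatable); significant in one, "unidirectional"; in neither,
"not joint".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "JointStatTable",
    "gene_joint_statistic",
    "permutation_null",
    "fdr_cutoffs",
    "classify_translatability",
    "joint_statistic_table",
]

DEFAULT_VARIANCE_FLOOR = 0.5


def _floored_log_ratio(var_j: np.ndarray, var_i: np.ndarray, s: float, strict_prose: bool) -> np.ndarray:
    # difference of logs rather than log of ratio: exactly antisymmetric
    # under J <-> I and immune to ratio overflow
    stat = np.log(np.maximum(var_j, s)) - np.log(np.maximum(var_i, s))
    if strict_prose:
        # stricter reading: zero whenever EITHER variance is at/below the floor
        stat = np.where((var_j <= s) | (var_i <= s), 0.0, stat)
    return stat


def gene_joint_statistic(
    J: np.ndarray,
    I: np.ndarray,
    s: float = DEFAULT_VARIANCE_FLOOR,
    strict_prose: bool = False,
) -> np.ndarray:
    """Signed log variance ratio per gene, floored at ``s``.

    ``J`` and ``I`` are samples x genes with matching shapes.  Variances use
    denominator n; since both matrices share the sample count the choice
    cancels in the unfloored ratio.  ``strict_prose=True`` zeroes the
    statistic whenever either variance is at or below the floor instead of
    only flooring it.
    """
    J = np.asarray(J, dtype=float)
    I = np.asarray(I, dtype=float)
    if J.shape != I.shape:
        raise ValueError(f"J and I shapes differ: {J.shape} vs {I.shape}")
    if s <= 0:
        raise ValueError("variance floor s must be positive")
    var_j = np.var(J, axis=0, ddof=0)
    var_i = np.var(I, axis=0, ddof=0)
    return _floored_log_ratio(var_j, var_i, s, strict_prose)


def permutation_null(
    J: np.ndarray,
    I: np.ndarray,
    s: float = DEFAULT_VARIANCE_FLOOR,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "pool_resplit",
    strict_prose: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null statistics and two-tailed p-values.

    ``pool_resplit`` (default): per gene, the 2n pooled joint/individual
    entries are shuffled and re-split into two pseudo-rows of the original
    sizes — an exchangeable per-gene null.  ``label_swap``: per sample, the
    joint and individual rows are swapped with probability 1/2 (the
    whole-row label shuffle).

    Returns ``(null, p)`` where ``null`` is (n_perm, n_genes) and
    ``p[g] = (1 + #{|null_g| >= |obs_g|}) / (1 + n_perm)``.
    """
    J = np.asarray(J, dtype=float)
    I = np.asarray(I, dtype=float)
    if J.shape != I.shape:
        raise ValueError("J and I shapes differ")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n, p = J.shape
    rng = np.random.default_rng(seed)
    observed = gene_joint_statistic(J, I, s=s, strict_prose=strict_prose)
    pooled = np.vstack([J, I])  # 2n x p
    null = np.empty((n_perm, p))
    for b in range(n_perm):
        if scheme == "pool_resplit":
            order = np.argsort(rng.random(pooled.shape), axis=0)
            shuffled = np.take_along_axis(pooled, order, axis=0)
            pj, pi = shuffled[:n], shuffled[n:]
        elif scheme == "label_swap":
            swap = rng.random(n) < 0.5
            pj = np.where(swap[:, None], I, J)
            pi = np.where(swap[:, None], J, I)
        else:
            raise ValueError(f"unknown permutation scheme: {scheme!r}")
        null[b] = _floored_log_ratio(
            np.var(pj, axis=0, ddof=0), np.var(pi, axis=0, ddof=0), s, strict_prose
        )
    p_values = (1.0 + np.sum(np.abs(null) >= np.abs(observed)[None, :], axis=0)) / (1.0 + n_perm)
    return null, p_values


def fdr_cutoffs(
    observed: np.ndarray,
    null: np.ndarray,
    target_fdr: float = 0.05,
) -> tuple[float, float]:
    """SAM-style per-tail statistic cutoffs at the target FDR.

    For a positive candidate cutoff c, FDR(c) = median over permutations of
    #{null >= c}, divided by #{observed >= c}; the positive cutoff is the
    smallest observed positive statistic attaining FDR <= target.  The
    negative tail is handled symmetrically and independently.  Returns
    ``(+inf, -inf)`` tails when no cutoff attains the target.
    """
    if not 0 < target_fdr <= 1:
        raise ValueError("target_fdr must be in (0, 1]")
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    null_sorted = np.sort(null, axis=1)  # per permutation, ascending
    n_genes = null.shape[1]
    obs_sorted = np.sort(observed)

    # positive tail: candidates are the observed positive statistics, ascending
    pos_cut = np.inf
    pos_cands = np.unique(observed[observed > 0])
    if pos_cands.size:
        # counts beyond each candidate, vectorized over candidates
        obs_counts = observed.size - np.searchsorted(obs_sorted, pos_cands, side="left")
        null_counts = np.stack(
            [n_genes - np.searchsorted(row, pos_cands, side="left") for row in null_sorted]
        )  # n_perm x n_cands
        fdr = np.minimum(np.median(null_counts, axis=0) / obs_counts, 1.0)
        ok = np.nonzero(fdr <= target_fdr)[0]
        if ok.size:
            pos_cut = float(pos_cands[ok[0]])

    # negative tail, mirrored independently
    neg_cut = -np.inf
    neg_cands = np.unique(observed[observed < 0])[::-1]  # magnitudes ascending
    if neg_cands.size:
        obs_counts = np.searchsorted(obs_sorted, neg_cands, side="right")
        null_counts = np.stack(
            [np.searchsorted(row, neg_cands, side="right") for row in null_sorted]
        )
        fdr = np.minimum(np.median(null_counts, axis=0) / obs_counts, 1.0)
        ok = np.nonzero(fdr <= target_fdr)[0]
        if ok.size:
            neg_cut = float(neg_cands[ok[0]])
    return pos_cut, neg_cut


@dataclass
class JointStatTable:
    """Per-gene joint statistics with permutation p-values and FDR cutoffs."""

    block_name: str
    table: pd.DataFrame  # gene-indexed: var_joint, var_individual, statistic, p_value, significant_joint, significant_individual
    s: float
    fdr_cutoff_pos: float
    fdr_cutoff_neg: float
    target_fdr: float
    n_permutations: int
    seed: int

    @property
    def gene_labels(self) -> list[str]:
        return list(self.table.index)

    @property
    def statistic(self) -> pd.Series:
        return self.table["statistic"]

    @property
    def significant_joint(self) -> pd.Series:
        return self.table["significant_joint"]

    @property
    def significant_individual(self) -> pd.Series:
        return self.table["significant_individual"]


def joint_statistic_table(
    result,
    block_name: str,
    s: float = DEFAULT_VARIANCE_FLOOR,
    n_perm: int = 1000,
    target_fdr: float = 0.05,
    seed: int = 0,
    scheme: str = "pool_resplit",
    strict_prose: bool = False,
) -> JointStatTable:
    """Full per-gene joint-statistic analysis of one block of a fitted
    decomposition: statistic, permutation p, per-tail FDR cutoffs and
    significance flags."""
    dec = result.block(block_name)
    stats = gene_joint_statistic(dec.J, dec.I, s=s, strict_prose=strict_prose)
    null, p_values = permutation_null(
        dec.J, dec.I, s=s, n_perm=n_perm, seed=seed, scheme=scheme, strict_prose=strict_prose
    )
    pos_cut, neg_cut = fdr_cutoffs(stats, null, target_fdr=target_fdr)
    var_j = np.var(dec.J, axis=0, ddof=0)
    var_i = np.var(dec.I, axis=0, ddof=0)
    table = pd.DataFrame(
        {
            "var_joint": var_j,
            "var_individual": var_i,
            "statistic": stats,
            "p_value": p_values,
            "significant_joint": stats >= pos_cut,
            "significant_individual": stats <= neg_cut,
        },
        index=pd.Index(result.gene_labels, name="gene"),
    )
    return JointStatTable(
        block_name=block_name,
        table=table,
        s=s,
        fdr_cutoff_pos=pos_cut,
        fdr_cutoff_neg=neg_cut,
        target_fdr=target_fdr,
        n_permutations=n_perm,
        seed=seed,
    )


def classify_translatability(table_a: JointStatTable, table_b: JointStatTable) -> pd.DataFrame:
    """Cross-cohort translatability class per gene.

    fully_joint: significantly joint in both cohorts; unidirectional_A/B:
    significant only in that cohort; not_joint otherwise.  Returns a
    gene-indexed frame with both statistics and the class.
    """
    if table_a.gene_labels != table_b.gene_labels:
        raise ValueError("tables do not share gene labels; map homologs first")
    sig_a = table_a.significant_joint.to_numpy()
    sig_b = table_b.significant_joint.to_numpy()
    cls = np.where(
        sig_a & sig_b,
        "fully_joint",
        np.where(sig_a, "unidirectional_A", np.where(sig_b, "unidirectional_B", "not_joint")),
    )
    return pd.DataFrame(
        {
            "statistic_A": table_a.statistic.to_numpy(),
            "statistic_B": table_b.statistic.to_numpy(),
            "significant_A": sig_a,
            "significant_B": sig_b,
            "translatability": cls,
        },
        index=table_a.table.index,
    )
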