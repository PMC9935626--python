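"""Half-split bootstrap selection of each block's initial signal rank.

The initial signal rank r_k controls how much of a block survives the
first truncated SVD.  Too small a rank discards genuine structure; too
large a rank lets noise directions masquerade as signal.  The selection
procedure splits the block's samples into two random halves and integrates
the halves against each other over a grid of candidate ranks: true signal
directions reproduce in both halves and land in the joint component, while
noise directions do not and inflate the individual component.  Over
repeated splits the rank maximising joint variation while minimising
individual variation is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ajive import AJIVE, AjiveConfig, _cached_angle_cutoff
from .blocks import ExpressionBlock, mean_center_genes

__all__ = ["RankCurve", "half_split_curve", "select_rank"]


@dataclass
class RankCurve:
    """Joint/individual/residual percentages over a rank grid.

    Each percentage array is (n_ranks, n_reps); percentages are of the total
    sum of squares pooled over both halves.
    """

    rank_grid: np.ndarray
    pct_joint: np.ndarray
    pct_individual: np.ndarray
    pct_residual: np.ndarray
    n_reps: int
    seed: int
    selected_rank: int | None = None

    def mean_joint(self) -> np.ndarray:
        return self.pct_joint.mean(axis=1)

    def mean_individual(self) -> np.ndarray:
        return self.pct_individual.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rank_grid):
            for rep in range(self.n_reps):
                rows.append(
                    {
                        "rank": int(r),
                        "rep": rep,
                        "pct_joint": self.pct_joint[i, rep],
                        "pct_individual": self.pct_individual[i, rep],
                        "pct_residual": self.pct_residual[i, rep],
                    }
                )
        return pd.DataFrame(rows)


def half_split_curve(
    block: ExpressionBlock,
    rank_grid,
    n_reps: int = 10,
    seed: int = 0,
    ajive_config: AjiveConfig | None = None,
) -> RankCurve:
    """Self-integration curve of a block over a grid of candidate ranks.

    Per repetition the samples are shuffled and split into two equal halves
    (one sample dropped at random when the count is odd); both halves are
    re-centered and integrated with AJIVE at every grid rank (the same rank
    for both halves).  Percentages are pooled over the two halves by total
    sum of squares.
    """
    rank_grid = np.asarray(sorted(int(r) for r in rank_grid))
    if rank_grid.size == 0 or rank_grid[0] < 1:
        raise ValueError("rank grid must contain positive integers")
    n = block.n_samples
    half = n // 2
    if rank_grid[-1] > half:
        raise ValueError(f"max rank {rank_grid[-1]} exceeds half the sample count ({half})")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = ajive_config if ajive_config is not None else AjiveConfig()
    rng = np.random.default_rng(seed)
    X = block.matrix()

    # the Monte Carlo cutoff depends only on (p, r, r); compute once per rank
    cutoffs = {}
    for r in rank_grid:
        if cfg.angle_cutoff is not None:
            cutoffs[int(r)] = float(cfg.angle_cutoff)
        else:
            cutoffs[int(r)] = _cached_angle_cutoff(
                block.n_genes, int(r), int(r), cfg.n_random_draws, cfg.angle_percentile, cfg.seed
            )

    pj = np.empty((rank_grid.size, n_reps))
    pi = np.empty((rank_grid.size, n_reps))
    pe = np.empty((rank_grid.size, n_reps))
    for rep in range(n_reps):
        order = rng.permutation(n)
        idx1, idx2 = order[:half], order[half : 2 * half]
        halves = []
        for part, tag in ((idx1, "h1"), (idx2, "h2")):
            sub = ExpressionBlock(
                pd.DataFrame(X[part], index=[f"{tag}_{i}" for i in range(half)], columns=block.gene_labels),
                block_name=tag,
            )
            halves.append(mean_center_genes(sub))
        for i, r in enumerate(rank_grid):
            cfg_r = AjiveConfig(
                angle_percentile=cfg.angle_percentile,
                n_random_draws=cfg.n_random_draws,
                angle_cutoff=cutoffs[int(r)],
                seed=cfg.seed,
            )
            res = AJIVE(halves[0], halves[1], int(r), int(r), config=cfg_r).fit()
            ss = {k: 0.0 for k in ("total", "joint", "individual", "residual")}
            for dec in res.decompositions.values():
                for k, v in dec.sum_of_squares().items():
                    ss[k] += v
            pj[i, rep] = 100.0 * ss["joint"] / ss["total"]
            pi[i, rep] = 100.0 * ss["individual"] / ss["total"]
            pe[i, rep] = 100.0 - pj[i, rep] - pi[i, rep]
    return RankCurve(
        rank_grid=rank_grid,
        pct_joint=pj,
        pct_individual=pi,
        pct_residual=pe,
        n_reps=n_reps,
        seed=seed,
    )


def select_rank(curve: RankCurve) -> int:
    """Rank maximising mean joint minus mean individual variation.

    Ties break toward the smaller rank.  The raw curve is retained so users
    can apply their own elbow criterion instead.
    """
    score = curve.mean_joint() - curve.mean_individual()
    best = int(curve.rank_grid[int(np.argmax(score))])  # argmax takes first max -> smaller rank
    curve.selected_rank = best
    return best
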