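"""Angle-based joint and individual variation explained (AJIVE) for two blocks.

Given two mean-centered expression blocks X_A (n_A x p) and X_B (n_B x p)
sharing the gene axis, each block is decomposed additively as

    X_k = J_k + I_k + E_k

where J_k is variation whose gene-space structure is shared between the
blocks, I_k is block-specific low-rank structure and E_k is residual noise.

The procedure is the two-stage SVD construction:

1. Per block, a truncated SVD X_k ~ U_k D_k V_k' at a chosen initial signal
   rank r_k strips residual noise.
2. The right singular vector (metagene) matrices are stacked,
   M = [V_A'; V_B'], and an SVD of M yields singular values sigma_M from
   which the principal angles between the two metagene subspaces follow as
   phi_i = arccos(sigma_M_i^2 - 1), i = 1..min(r_A, r_B).
3. Angles smaller than a cutoff calibrated on random subspaces of the same
   dimensions mark joint components; the joint gene-space basis is the
   corresponding top right singular vectors of M.
4. Each block is reprojected: J_k = X_k P, I_k = X_hat_k (Id - P),
   E_k = X_k - J_k - I_k, with P the orthogonal projector onto the joint
   gene subspace and X_hat_k the rank-r_k approximation.  This makes J, I, E
   pairwise Frobenius-orthogonal, so sums of squares decompose additively.

The user-facing entry points are the :class:`AJIVE` model (construct from
two blocks, call :meth:`AJIVE.fit`) and the :func:`run_ajive` convenience
wrapper; both return an :class:`AJIVEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .blocks import ExpressionBlock

__all__ = [
    "AjiveConfig",
    "InitialDecomposition",
    "PrincipalAngleAnalysis",
    "BlockDecomposition",
    "AJIVEResults",
    "AJIVE",
    "initial_svd",
    "principal_angles",
    "random_angle_cutoff",
    "select_joint_rank",
    "reproject",
    "run_ajive",
]


@dataclass
class AjiveConfig:
    """Tuning knobs for the joint-subspace selection.

    angle_percentile : percentile of the random smallest-angle distribution
        used as the joint/not-joint cutoff (degrees), default 5.
    n_random_draws : Monte Carlo draws for that distribution, default 1000.
    angle_cutoff : explicit cutoff in degrees; overrides the Monte Carlo
        calibration when set (e.g. a Wedin-bound cutoff computed externally).
    seed : seed for the Monte Carlo draws.
    """

    angle_percentile: float = 5.0
    n_random_draws: int = 1000
    angle_cutoff: float | None = None
    seed: int = 0


@dataclass
class InitialDecomposition:
    """Truncated SVD of one centered block: X ~ U diag(D) V'."""

    U: np.ndarray  # samples x r
    D: np.ndarray  # r, descending, positive
    V: np.ndarray  # genes x r (metagenes)
    rank: int
    block_name: str = "block"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.D) > 1e-12) or np.any(self.D <= 0):
            raise ValueError("singular values must be positive and non-increasing")
        for mat, nm in ((self.U, "U"), (self.V, "V")):
            gram = mat.T @ mat
            if np.abs(gram - np.eye(self.rank)).max() > 1e-8:
                raise ValueError(f"{nm} columns are not orthonormal")

    def reconstruction(self) -> np.ndarray:
        return (self.U * self.D) @ self.V.T


@dataclass
class PrincipalAngleAnalysis:
    """Stacked-metagene SVD and the principal angles it induces."""

    M: np.ndarray  # (r_A + r_B) x genes
    sigma_M: np.ndarray  # singular values of M, descending
    phi: np.ndarray  # principal angles, degrees, ascending
    V_M: np.ndarray  # genes x len(sigma_M) right singular vectors of M
    angle_cutoff: float | None = None
    joint_rank: int | None = None
    joint_basis: np.ndarray | None = None  # genes x joint_rank


@dataclass
class BlockDecomposition:
    """Per-block decomposition X = J + I + E (all samples x genes)."""

    J: np.ndarray
    I: np.ndarray
    E: np.ndarray
    X: np.ndarray
    block_name: str

    def sum_of_squares(self) -> dict[str, float]:
        return {
            "total": float(np.sum(self.X**2)),
            "joint": float(np.sum(self.J**2)),
            "individual": float(np.sum(self.I**2)),
            "residual": float(np.sum(self.E**2)),
        }

    def percent_variation(self) -> dict[str, float]:
        ss = self.sum_of_squares()
        tot = ss["total"]
        return {k: 100.0 * ss[k] / tot for k in ("joint", "individual", "residual")}


def _sign_fix(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: each V column's largest-|.| entry > 0."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def initial_svd(block: ExpressionBlock, r: int) -> InitialDecomposition:
    """Rank-``r`` truncated SVD of a centered block.

    If ``r`` exceeds the numerical rank the decomposition is truncated to
    the numerical rank with a warning.
    """
    if not block.centered:
        raise ValueError("block must be mean-centered before the initial SVD")
    X = block.matrix()
    if r < 1 or r > min(X.shape):
        raise ValueError(f"rank {r} outside [1, {min(X.shape)}] for shape {X.shape}")
    U, D, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (D[0] if D.size else 0.0)
    num_rank = int(np.sum(D > tol))
    if r > num_rank:
        import warnings

        warnings.warn(
            f"requested rank {r} exceeds numerical rank {num_rank}; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        r = num_rank
    U, V = _sign_fix(U[:, :r], Vt[:r].T)
    return InitialDecomposition(U=U, D=D[:r].copy(), V=V, rank=r, block_name=block.block_name)


def principal_angles(decomps: list[InitialDecomposition]) -> PrincipalAngleAnalysis:
    """Principal angles between the two blocks' metagene subspaces.

    Stacks V_A' over V_B' into M, takes its SVD and converts the singular
    values to angles via phi_i = arccos(sigma_i^2 - 1), clamped to [0, 90]
    degrees against floating-point overshoot.
    """
    if len(decomps) != 2:
        raise ValueError("exactly two blocks are supported")
    d1, d2 = decomps
    if d1.V.shape[0] != d2.V.shape[0]:
        raise ValueError("gene dimensions differ between blocks")
    M = np.vstack([d1.V.T, d2.V.T])
    _, sigma, Vt = np.linalg.svd(M, full_matrices=False)
    n_angles = min(d1.rank, d2.rank)
    cos_phi = np.clip(sigma[:n_angles] ** 2 - 1.0, -1.0, 1.0)
    phi = np.degrees(np.arccos(cos_phi))
    phi = np.clip(phi, 0.0, 90.0)
    return PrincipalAngleAnalysis(M=M, sigma_M=sigma, phi=phi, V_M=Vt.T)


def _min_random_angle(rng: np.random.Generator, n_genes: int, r1: int, r2: int) -> float:
    q1, _ = np.linalg.qr(rng.standard_normal((n_genes, r1)))
    q2, _ = np.linalg.qr(rng.standard_normal((n_genes, r2)))
    s = np.linalg.svd(q1.T @ q2, compute_uv=False)
    return float(np.degrees(np.arccos(np.clip(s[0], -1.0, 1.0))))


def random_angle_cutoff(
    n_genes: int,
    r_1: int,
    r_2: int,
    n_draws: int = 1000,
    percentile: float = 5.0,
    seed: int = 0,
) -> float:
    """Percentile of the smallest principal angle between random subspaces.

    Draws ``n_draws`` independent pairs of uniformly random r_1- and
    r_2-dimensional subspaces of gene space, records each pair's smallest
    principal angle, and returns the requested percentile (default 5th) of
    that distribution.  Angles below this cutoff are unlikely to arise
    between unrelated subspaces, so they mark joint structure.
    """
    if r_1 > n_genes or r_2 > n_genes:
        raise ValueError("subspace ranks exceed the gene dimension")
    rng = np.random.default_rng(seed)
    mins = np.array([_min_random_angle(rng, n_genes, r_1, r_2) for _ in range(n_draws)])
    return float(np.percentile(mins, percentile))


@lru_cache(maxsize=256)
def _cached_angle_cutoff(n_genes: int, r_1: int, r_2: int, n_draws: int, percentile: float, seed: int) -> float:
    return random_angle_cutoff(n_genes, r_1, r_2, n_draws=n_draws, percentile=percentile, seed=seed)


def select_joint_rank(phi: np.ndarray, cutoff: float) -> int:
    """Number of principal angles strictly below the cutoff."""
    phi = np.asarray(phi, dtype=float)
    if np.any(np.diff(phi) < -1e-9):
        raise ValueError("angles must be ascending")
    return int(np.sum(phi < cutoff))


def reproject(
    block: ExpressionBlock,
    decomp: InitialDecomposition,
    joint_basis: np.ndarray,
) -> BlockDecomposition:
    """Split a centered block into joint, individual and residual matrices.

    The original data are reprojected through mutually orthogonal
    gene-space projectors: J = X P_W with P_W the projector onto the joint
    basis, I = X P_I with P_I the projector onto the part of the block's
    retained rank-r row space orthogonal to the joint basis, and
    E = X - J - I.  Because the projectors have pairwise orthogonal ranges,
    every sample's row splits exactly: ||x||^2 = ||j||^2 + ||i||^2 + ||e||^2,
    and the three matrices are pairwise Frobenius-orthogonal.
    """
    X = block.matrix()
    W = np.asarray(joint_basis, dtype=float)
    if W.size and W.shape[0] != X.shape[1]:
        raise ValueError("joint basis gene dimension does not match the block")
    if W.size == 0:
        W = W.reshape(X.shape[1], 0)
    # individual gene-space basis: retained metagenes minus their joint part
    Q = decomp.V - W @ (W.T @ decomp.V)
    u, sv, _ = np.linalg.svd(Q, full_matrices=False)
    keep = sv > 1e-8 * max(sv[0], 1.0) if sv.size else np.zeros(0, bool)
    B_ind = u[:, keep]
    J = (X @ W) @ W.T
    I = (X @ B_ind) @ B_ind.T
    E = X - J - I
    return BlockDecomposition(J=J, I=I, E=E, X=X, block_name=block.block_name)


@dataclass
class AJIVEResults:
    """Fitted joint/individual/residual decomposition of two blocks."""

    decompositions: dict[str, BlockDecomposition]
    angles: PrincipalAngleAnalysis
    initial: dict[str, InitialDecomposition]
    config: AjiveConfig
    gene_labels: list[str]
    sample_ids: dict[str, list[str]]

    @property
    def block_names(self) -> list[str]:
        return list(self.decompositions)

    @property
    def joint_rank(self) -> int:
        return int(self.angles.joint_rank)

    @property
    def joint_basis(self) -> np.ndarray:
        return self.angles.joint_basis

    def block(self, block_name: str) -> BlockDecomposition:
        try:
            return self.decompositions[block_name]
        except KeyError:
            raise KeyError(
                f"unknown block {block_name!r}; have {self.block_names}"
            ) from None

    # --- downstream analyses (implemented in sibling modules) -----------

    def sample_variation(self, block_name: str):
        from .variation import sample_variation_profile

        return sample_variation_profile(self, block_name)

    def gene_set_partition(self, block_name: str, gene_set):
        from .variation import gene_set_partition

        return gene_set_partition(self, block_name, gene_set)

    def joint_statistic_table(self, block_name: str, **kwargs):
        from .jointstat import joint_statistic_table

        return joint_statistic_table(self, block_name, **kwargs)

    def summary(self) -> str:
        """Plain-text fit report."""
        lines = ["AJIVE decomposition", "=" * 60]
        cut = self.angles.angle_cutoff
        lines.append(f"joint rank: {self.joint_rank}   angle cutoff: {cut:.2f} deg")
        shown = ", ".join(f"{a:.1f}" for a in self.angles.phi[:10])
        lines.append(f"principal angles (deg): {shown}" + (" ..." if len(self.angles.phi) > 10 else ""))
        lines.append("-" * 60)
        lines.append(f"{'block':<20}{'r_k':>5}{'% joint':>10}{'% indiv':>10}{'% resid':>10}")
        for name, dec in self.decompositions.items():
            pct = dec.percent_variation()
            lines.append(
                f"{name:<20}{self.initial[name].rank:>5}"
                f"{pct['joint']:>10.2f}{pct['individual']:>10.2f}{pct['residual']:>10.2f}"
            )
        return "\n".join(lines)


class AJIVE:
    """Two-block AJIVE model.

    Parameters
    ----------
    block_a, block_b : ExpressionBlock
        Gene-aligned, mean-centered blocks (samples x genes).
    rank_a, rank_b : int
        Initial signal ranks r_k for the per-block truncated SVDs.
    config : AjiveConfig, optional
        Joint-rank selection settings.

    Examples
    --------
    >>> model = AJIVE(block_a, block_b, rank_a=35, rank_b=135)  # doctest: +SKIP
    >>> res = model.fit()  # doctest: +SKIP
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        block_a: ExpressionBlock,
        block_b: ExpressionBlock,
        rank_a: int,
        rank_b: int,
        config: AjiveConfig | None = None,
    ) -> None:
        if block_a.gene_labels != block_b.gene_labels:
            raise ValueError("blocks are not gene-aligned; run intersect_and_align first")
        if not (block_a.centered and block_b.centered):
            raise ValueError("blocks must be mean-centered (mean_center_genes)")
        if block_a.block_name == block_b.block_name:
            block_b = replace(block_b, block_name=block_b.block_name + "_2")
        self.block_a = block_a
        self.block_b = block_b
        self.rank_a = rank_a
        self.rank_b = rank_b
        self.config = config if config is not None else AjiveConfig()

    def fit(self) -> AJIVEResults:
        cfg = self.config
        dec_a = initial_svd(self.block_a, self.rank_a)
        dec_b = initial_svd(self.block_b, self.rank_b)
        paa = principal_angles([dec_a, dec_b])
        if cfg.angle_cutoff is not None:
            cutoff = float(cfg.angle_cutoff)
        else:
            cutoff = _cached_angle_cutoff(
                self.block_a.n_genes,
                dec_a.rank,
                dec_b.rank,
                cfg.n_random_draws,
                cfg.angle_percentile,
                cfg.seed,
            )
        joint_rank = select_joint_rank(paa.phi, cutoff)
        if joint_rank > 0:
            basis = paa.V_M[:, :joint_rank]
            q, _ = np.linalg.qr(basis)  # re-orthonormalize against roundoff
            _, basis = _sign_fix(q, q)
        else:
            basis = np.zeros((self.block_a.n_genes, 0))
        paa.angle_cutoff = cutoff
        paa.joint_rank = joint_rank
        paa.joint_basis = basis
        decs = {
            self.block_a.block_name: reproject(self.block_a, dec_a, basis),
            self.block_b.block_name: reproject(self.block_b, dec_b, basis),
        }
        return AJIVEResults(
            decompositions=decs,
            angles=paa,
            initial={dec_a.block_name: dec_a, dec_b.block_name: dec_b},
            config=cfg,
            gene_labels=self.block_a.gene_labels,
            sample_ids={
                self.block_a.block_name: self.block_a.sample_ids,
                self.block_b.block_name: self.block_b.sample_ids,
            },
        )


def run_ajive(
    block_a: ExpressionBlock,
    block_b: ExpressionBlock,
    rank_a: int,
    rank_b: int,
    config: AjiveConfig | None = None,
) -> AJIVEResults:
    """Convenience wrapper: ``AJIVE(block_a, block_b, rank_a, rank_b).fit()``."""
    return AJIVE(block_a, block_b, rank_a, rank_b, config=config).fit()
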