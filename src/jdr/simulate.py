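"""Synthetic paired-cohort generator with planted joint/individual structure.

Two blocks sharing a gene axis are built as low-rank signal plus isotropic
Gaussian noise::

    X_k = S_J_k @ W_J.T + S_I_k @ W_k.T + noise_sd * N_k

where ``W_J`` is an orthonormal gene-space basis shared by both blocks (the
joint subspace), ``W_k`` is a block-specific orthonormal basis orthogonal to
``W_J`` and to the other block's basis, and the score matrices ``S`` have
i.i.d. N(0, signal_sd^2) entries.  Genes are partitioned into disjoint
classes — joint-acting, individual-acting per block, and null — and each
basis is supported only on its class's genes, so the classes are ground
truth for recovery tests of the decomposition, the per-gene joint statistic
and the translation models.

The generator works on the post-normalisation log scale the decomposition
consumes; it does not emulate count-level RNA-seq artefacts (library size,
overdispersion, dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import ExpressionBlock

__all__ = [
    "SyntheticTruth",
    "simulate_joint_blocks",
    "simulate_response",
    "simulate_translation_scenario",
    "snr_to_signal_sd",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated block pair."""

    joint_rank: int
    individual_ranks: tuple[int, int]
    joint_basis_true: np.ndarray  # genes x joint_rank, orthonormal
    gene_classes: np.ndarray  # per gene: joint | individual_A | individual_B | null
    response_coefficients: np.ndarray  # over joint metagene scores
    noise_sd: float
    seed: int
    signal_sd: float = 1.0
    individual_bases: tuple[np.ndarray, np.ndarray] | None = None
    joint_scores: tuple[np.ndarray, np.ndarray] | None = None
    individual_scores: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.joint_rank > 0:
            gram = self.joint_basis_true.T @ self.joint_basis_true
            if np.abs(gram - np.eye(self.joint_rank)).max() > 1e-8:
                raise ValueError("joint_basis_true columns are not orthonormal")


def snr_to_signal_sd(snr: float, n_samples: int, n_genes: int, noise_sd: float) -> float:
    """Score scale giving a planted-signal-to-noise-edge ratio of ``snr``.

    SNR is defined as the expected smallest planted singular value,
    ``signal_sd * sqrt(n)``, divided by the expected operator norm of the
    n x p noise matrix, ``noise_sd * (sqrt(n) + sqrt(p))``.  Detectability of
    a planted component sets in near SNR = 1, so SNR >= 4 is a strong-signal
    regime.
    """
    return snr * noise_sd * (np.sqrt(n_samples) + np.sqrt(n_genes)) / np.sqrt(n_samples)


def _orthonormal_on_support(rng: np.random.Generator, n_genes: int, support: np.ndarray, rank: int) -> np.ndarray:
    """Orthonormal genes x rank basis, zero off ``support``, with
    (near-)equal row norms on the support.

    Built as disjoint random-sign columns rotated by a random orthogonal
    matrix.  Equalised loadings make every supported gene carry its class's
    signal, so the planted gene classes are meaningful ground truth; a
    Gaussian+QR basis instead gives chi-square row norms whose small tail
    plants genes that no method could flag.
    """
    basis = np.zeros((n_genes, rank))
    if rank == 0:
        return basis
    m = support.size
    if m < rank:
        raise ValueError("gene-class support smaller than requested rank")
    groups = np.array_split(rng.permutation(m), rank)
    w0 = np.zeros((m, rank))
    for j, grp in enumerate(groups):
        w0[grp, j] = rng.choice([-1.0, 1.0], size=grp.size) / np.sqrt(grp.size)
    q, r = np.linalg.qr(rng.standard_normal((rank, rank)))
    q *= np.sign(np.diag(r))[None, :]
    basis[support] = w0 @ q
    return basis


def simulate_joint_blocks(
    n_samples_a: int,
    n_samples_b: int,
    n_genes: int,
    joint_rank: int,
    individual_ranks: tuple[int, int] = (0, 0),
    signal_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    class_fractions: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> tuple[ExpressionBlock, ExpressionBlock, SyntheticTruth]:
    """Simulate two expression blocks with planted joint/individual structure.

    ``class_fractions`` gives the fraction of genes assigned to the joint,
    individual-A and individual-B classes (remainder null).  Ranks must fit
    inside ``min(n_samples_a, n_samples_b, n_genes)``.
    """
    r_a, r_b = individual_ranks
    if joint_rank + max(r_a, r_b) >= min(n_samples_a, n_samples_b, n_genes):
        raise ValueError("infeasible ranks for the requested dimensions")
    if joint_rank < 0 or r_a < 0 or r_b < 0:
        raise ValueError("ranks must be non-negative")
    rng = np.random.default_rng(seed)

    n_joint = int(round(class_fractions[0] * n_genes))
    n_ia = int(round(class_fractions[1] * n_genes))
    n_ib = int(round(class_fractions[2] * n_genes))
    if n_joint + n_ia + n_ib > n_genes:
        raise ValueError("gene-class fractions exceed 1")
    classes = np.array(["null"] * n_genes, dtype=object)
    perm = rng.permutation(n_genes)
    sup_joint = np.sort(perm[:n_joint])
    sup_ia = np.sort(perm[n_joint : n_joint + n_ia])
    sup_ib = np.sort(perm[n_joint + n_ia : n_joint + n_ia + n_ib])
    if joint_rank > 0:
        classes[sup_joint] = "joint"
    if r_a > 0:
        classes[sup_ia] = "individual_A"
    if r_b > 0:
        classes[sup_ib] = "individual_B"

    w_joint = _orthonormal_on_support(rng, n_genes, sup_joint, joint_rank)
    w_a = _orthonormal_on_support(rng, n_genes, sup_ia, r_a)
    w_b = _orthonormal_on_support(rng, n_genes, sup_ib, r_b)

    s_joint_a = rng.standard_normal((n_samples_a, joint_rank)) * signal_sd
    s_joint_b = rng.standard_normal((n_samples_b, joint_rank)) * signal_sd
    s_ind_a = rng.standard_normal((n_samples_a, r_a)) * signal_sd
    s_ind_b = rng.standard_normal((n_samples_b, r_b)) * signal_sd

    x_a = s_joint_a @ w_joint.T + s_ind_a @ w_a.T + noise_sd * rng.standard_normal((n_samples_a, n_genes))
    x_b = s_joint_b @ w_joint.T + s_ind_b @ w_b.T + noise_sd * rng.standard_normal((n_samples_b, n_genes))

    genes = [f"G{i:05d}" for i in range(n_genes)]
    block_a = ExpressionBlock(
        pd.DataFrame(x_a, index=[f"A{i:04d}" for i in range(n_samples_a)], columns=genes),
        block_name="synthetic_A",
    )
    block_b = ExpressionBlock(
        pd.DataFrame(x_b, index=[f"B{i:04d}" for i in range(n_samples_b)], columns=genes),
        block_name="synthetic_B",
    )
    truth = SyntheticTruth(
        joint_rank=joint_rank,
        individual_ranks=(r_a, r_b),
        joint_basis_true=w_joint,
        gene_classes=classes,
        response_coefficients=rng.standard_normal(joint_rank),
        noise_sd=noise_sd,
        seed=seed,
        signal_sd=signal_sd,
        individual_bases=(w_a, w_b),
        joint_scores=(s_joint_a, s_joint_b),
        individual_scores=(s_ind_a, s_ind_b),
    )
    return block_a, block_b, truth


def simulate_response(
    truth: SyntheticTruth,
    scores_joint: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "continuous",
) -> np.ndarray:
    """Response linear in the joint metagene scores.

    ``continuous`` returns ``scores @ beta + noise``; ``binary`` draws labels
    from the logistic transform of the same linear predictor.
    """
    scores_joint = np.asarray(scores_joint, dtype=float)
    if scores_joint.ndim != 2 or scores_joint.shape[1] != truth.joint_rank:
        raise ValueError(
            f"scores_joint must be n x {truth.joint_rank}, got {scores_joint.shape}"
        )
    rng = np.random.default_rng(seed)
    linear = scores_joint @ truth.response_coefficients
    if kind == "continuous":
        return linear + noise_sd * rng.standard_normal(linear.shape)
    if kind == "binary":
        noisy = linear + noise_sd * rng.standard_normal(linear.shape)
        prob = 1.0 / (1.0 + np.exp(-noisy))
        return (rng.uniform(size=prob.shape) < prob).astype(int)
    raise ValueError(f"unknown response kind: {kind!r}")


def simulate_translation_scenario(
    n_train: int = 80,
    n_partner: int = 100,
    n_test: int = 120,
    n_genes: int = 300,
    joint_rank: int = 3,
    individual_rank: int = 2,
    signal_sd: float = 10.0,
    noise_sd: float = 1.0,
    response_noise_sd: float = 0.3,
    seed: int = 0,
) -> dict:
    """Training/partner/external-test cohorts with adversarial nuisance.

    Emulates the model-system translation problem: the training cohort's
    response is linear in its joint metagene scores, but its block-specific
    (individual) variation is ALSO correlated with the response in training
    and anti-correlated in the external test cohort.  A model trained on
    the original matrix latches onto the nuisance genes and is misled out
    of sample; a model trained on the joint matrix is not.

    Returns a dict with the training block, partner block (defining the
    joint structure), external test block, continuous training response
    ``y_train``, binary test outcome ``y_test`` (top half of the latent
    response, a pCR-like label), and the truth object.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    block_a, block_b, truth = simulate_joint_blocks(
        n_train,
        n_partner,
        n_genes,
        joint_rank,
        (individual_rank, individual_rank),
        signal_sd=signal_sd,
        noise_sd=noise_sd,
        seed=int(seeds[0]),
    )
    w_joint = truth.joint_basis_true
    w_ind_a = truth.individual_bases[0]
    beta = truth.response_coefficients

    # training response, linear in the joint scores
    s_joint_a = truth.joint_scores[0]
    lin_a = s_joint_a @ beta
    lin_a_std = (lin_a - lin_a.mean()) / lin_a.std()
    y_train = lin_a + response_noise_sd * lin_a.std() * np.random.default_rng(int(seeds[1])).standard_normal(n_train)

    # overwrite the training block's individual scores: correlated with response
    rng_a = np.random.default_rng(int(seeds[2]))
    s_ind_a = rng_a.standard_normal((n_train, individual_rank)) * 0.3 * signal_sd
    s_ind_a[:, 0] = lin_a_std * signal_sd
    x_a = (
        s_joint_a @ w_joint.T
        + s_ind_a @ w_ind_a.T
        + noise_sd * rng_a.standard_normal((n_train, n_genes))
    )
    block_a = ExpressionBlock(
        pd.DataFrame(x_a, index=block_a.sample_ids, columns=block_a.gene_labels),
        block_name="train",
    )

    # external test cohort: same joint structure, nuisance anti-correlated
    rng_t = np.random.default_rng(int(seeds[3]))
    s_joint_t = rng_t.standard_normal((n_test, joint_rank)) * signal_sd
    lin_t = s_joint_t @ beta
    lin_t_std = (lin_t - lin_t.mean()) / lin_t.std()
    s_ind_t = rng_t.standard_normal((n_test, individual_rank)) * 0.3 * signal_sd
    s_ind_t[:, 0] = -lin_t_std * signal_sd
    x_t = (
        s_joint_t @ w_joint.T
        + s_ind_t @ w_ind_a.T
        + noise_sd * rng_t.standard_normal((n_test, n_genes))
    )
    block_test = ExpressionBlock(
        pd.DataFrame(x_t, index=[f"T{i:04d}" for i in range(n_test)], columns=block_a.gene_labels),
        block_name="external_test",
    )
    y_test = (lin_t > np.median(lin_t)).astype(int)

    return {
        "train": block_a,
        "partner": block_b,
        "test": block_test,
        "y_train": y_train,
        "y_test": y_test,
        "truth": truth,
    }
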