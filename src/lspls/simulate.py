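"""Synthetic clinico-genomic data generator.

Emulates a binary-outcome study in which a handful of clinical covariates and
a large block-structured gene-expression matrix jointly drive the outcome:

* the genomic matrix ``X`` (p = 1000 by default) is drawn in four independent
  Gaussian blocks of sizes 475/475/25/25 with within-block AR(1) covariance
  ``c_k * rho^|i-j|`` (rho = 0.9) and block variance scales c = (8, 4, 2, 1);
* the clinical matrix ``D`` (q = 4) is N(0, Sigma_D) with AR(1) correlation
  rho = 0.5;
* the outcome is Bernoulli through the logistic link,
  ``Y_i ~ B(h(gamma_1 + D_i gamma_D + X_i gamma_X))`` with intercept -2.5,
  clinical effects 0.5 each, and genomic effects 0.1 on the two small
  (low-variance) blocks and 0 on the two large high-variance blocks — a
  design deliberately unfavourable to unsupervised compression, since the
  directions of greatest genomic variance carry no signal.

Each replicate draws a training set of 100 samples and a test set of 450.
Two variants: ``variance_inverted`` swaps the block scales so the influential
blocks carry the large variances, and ``dx_correlation`` mixes a shared
latent factor into D and the influential genomic blocks to induce
clinico-genomic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg


def ar1_block_cov(size: int, c: float, rho: float) -> np.ndarray:
    """AR(1) covariance matrix with entries ``c * rho^|i-j|``.

    Symmetric positive definite for ``c > 0`` and ``|rho| < 1``.
    """
    if c <= 0:
        raise ValueError("variance scale c must be > 0")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(size)
    return c * rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SimulationConfig:
    """Parameters of the simulated clinico-genomic study."""

    n_train: int = 100
    n_test: int = 450
    q: int = 4
    block_sizes: tuple[int, ...] = (475, 475, 25, 25)
    block_scales: tuple[float, ...] = (8.0, 4.0, 2.0, 1.0)
    rho_X: float = 0.9
    rho_D: float = 0.5
    gamma_intercept: float = -2.5
    gamma_D: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)
    gamma_X_block: tuple[float, ...] = (0.0, 0.0, 0.1, 0.1)
    n_replicates: int = 100
    seed: int = 0
    variance_inverted: bool = False
    dx_correlation: float = 0.0
    raw_pi: bool = False
    p_red: int = 500
    kappa_max: tuple[int, ...] = (1, 4, 8)

    def __post_init__(self):
        if len(self.block_scales) != len(self.block_sizes):
            raise ValueError("block_scales and block_sizes length mismatch")
        if len(self.gamma_X_block) != len(self.block_sizes):
            raise ValueError("gamma_X_block and block_sizes length mismatch")
        if len(self.gamma_D) != self.q:
            raise ValueError("gamma_D must have length q")
        if not 0.0 <= self.dx_correlation < 1.0:
            raise ValueError("dx_correlation must be in [0, 1)")

    @property
    def p(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def effective_scales(self) -> tuple[float, ...]:
        """Block scales after the optional variance inversion.

        Inversion gives the influential (last two) blocks the large scales
        and the null blocks the small ones: (8,4,2,1) -> (2,1,8,4).
        """
        if not self.variance_inverted:
            return self.block_scales
        k = len(self.block_scales) // 2
        return tuple(self.block_scales[k:]) + tuple(self.block_scales[:k])

    @property
    def gamma_X(self) -> np.ndarray:
        return np.repeat(self.gamma_X_block, self.block_sizes).astype(float)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """One replicate: train/test triples plus the generating truth."""

    D_train: np.ndarray
    X_train: np.ndarray
    Y_train: np.ndarray
    D_test: np.ndarray
    X_test: np.ndarray
    Y_test: np.ndarray
    gamma_intercept: float
    gamma_D: np.ndarray
    gamma_X: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)
    replicate_id: int = 0


def _rng_for(config: SimulationConfig, replicate_id: int) -> np.random.Generator:
    # independent, individually reproducible substream per replicate
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed),
                               spawn_key=(int(replicate_id),))
    )


def _draw(config: SimulationConfig, n: int, rng: np.random.Generator,
          chols: list[np.ndarray], chol_D: np.ndarray):
    blocks = []
    for size, L in zip(config.block_sizes, chols):
        blocks.append(rng.standard_normal((n, size)) @ L.T)
    r = config.dx_correlation
    eps_D = rng.standard_normal((n, config.q))
    g = rng.standard_normal(n)  # shared latent factor (unused when r == 0)
    Z_D = np.sqrt(1.0 - r) * eps_D + np.sqrt(r) * g[:, None]
    D = Z_D @ chol_D.T
    if r > 0:
        # mix the shared factor into the influential (nonzero-effect) blocks
        for k, gx in enumerate(config.gamma_X_block):
            if gx != 0.0:
                scale = np.sqrt(np.diag(ar1_block_cov(
                    config.block_sizes[k], config.effective_scales[k],
                    config.rho_X)))
                blocks[k] = (np.sqrt(1.0 - r) * blocks[k]
                             + np.sqrt(r) * g[:, None] * scale[None, :])
    X = np.hstack(blocks)
    eta = (config.gamma_intercept
           + D @ np.asarray(config.gamma_D, dtype=float)
           + X @ config.gamma_X)
    if config.raw_pi:
        pi = np.clip(eta, 0.0, 1.0)
    else:
        pi = 1.0 / (1.0 + np.exp(-eta))
    Y = (rng.random(n) < pi).astype(int)
    return D, X, Y


def simulate_dataset(config: SimulationConfig, replicate_id: int = 0) -> SyntheticDataset:
    """Draw one train/test replicate of the simulated study.

    The same ``(config.seed, replicate_id)`` pair always produces the
    bit-identical dataset.
    """
    rng = _rng_for(config, replicate_id)
    chols = [
        linalg.cholesky(ar1_block_cov(size, c, config.rho_X), lower=True)
        for size, c in zip(config.block_sizes, config.effective_scales)
    ]
    chol_D = linalg.cholesky(ar1_block_cov(config.q, 1.0, config.rho_D),
                             lower=True)
    D_tr, X_tr, Y_tr = _draw(config, config.n_train, rng, chols, chol_D)
    D_te, X_te, Y_te = _draw(config, config.n_test, rng, chols, chol_D)
    return SyntheticDataset(
        D_train=D_tr, X_train=X_tr, Y_train=Y_tr,
        D_test=D_te, X_test=X_te, Y_test=Y_te,
        gamma_intercept=config.gamma_intercept,
        gamma_D=np.asarray(config.gamma_D, dtype=float),
        gamma_X=config.gamma_X,
        config=config, replicate_id=int(replicate_id),
    )
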