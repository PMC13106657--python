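"""Seeded generators for synthetic expression data.

Two generators cover the two things the pipeline needs to be tested
against without external downloads:

* :func:`generate_planted_factorization` — an exactly low-rank
  nonnegative matrix ``X = W* H* + noise`` for factorization-recovery
  tests.
* :func:`generate_timecourse` — a two-class (control / diseased)
  longitudinal design with equally spaced time points, a small planted
  set of co-correlated differentially expressed "signal" biomarkers
  among many null features, and nonnegative noise.  This emulates the
  structure of small-sample rodent time-course studies (two diet or
  genotype arms sampled at fixed intervals, a few replicates per arm
  and time point, far more features than samples).

Default study conditions: ``g = 40`` samples (2 classes x 4 time points
x 5 replicates), ``s = 300`` biomarkers, 15 planted signal features,
diseased-arm expression of a signal feature scaled by ``1 + effect * t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidRankError, ValidationError
from .expression import CONTROL, DISEASED, ExpressionMatrix


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated dataset.

    ``W_star`` / ``H_star`` are the planted factors (``None`` for the
    time-course generator, which plants a signal set rather than an
    explicit factorization).  ``signal_features`` indexes the planted
    differentially expressed columns.
    """

    W_star: np.ndarray | None
    H_star: np.ndarray | None
    signal_features: np.ndarray
    noise_sd: float
    design: list[tuple[str, float]]


def generate_planted_factorization(
    g: int, s: int, k: int, noise_sd: float = 0.0, seed: int = 0
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Nonnegative matrix with planted rank-``k`` structure.

    ``W*`` and ``H*`` are gamma(2, 1) distributed (right-skewed positive
    values, the usual rough shape of normalized expression); Gaussian
    noise of standard deviation ``noise_sd`` is added and the result is
    clipped at zero.  Samples get alternating class labels and time 0;
    the metadata is present only so the matrix is a valid
    :class:`ExpressionMatrix`.
    """
    if not 1 <= k <= min(g, s):
        raise InvalidRankError(f"rank k={k} outside [1, {min(g, s)}]")
    rng = np.random.default_rng(seed)
    W = rng.gamma(shape=2.0, scale=1.0, size=(g, k))
    H = rng.gamma(shape=2.0, scale=1.0, size=(k, s))
    X = W @ H
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=(g, s))
    X = np.clip(X, 0.0, None)
    classes = [CONTROL if i % 2 == 0 else DISEASED for i in range(g)]
    times = np.zeros(g)
    em = ExpressionMatrix(
        values=X,
        feature_ids=[f"f{j:04d}" for j in range(s)],
        sample_class=classes,
        sample_time=times,
    )
    truth = SyntheticTruth(
        W_star=W,
        H_star=H,
        signal_features=np.arange(0),
        noise_sd=noise_sd,
        design=list(zip(classes, times.tolist())),
    )
    return em, truth


def generate_coefficient_matrix(
    k: int, s: int, seed: int = 0, min_gram: float = 0.05, max_tries: int = 10000
) -> np.ndarray:
    """Random nonnegative ``k x s`` coefficient matrix with a
    well-conditioned centred Gram.

    Entries are uniform on [0, 1); draws are rejected until every
    off-diagonal entry of the centred Gram ``Hc^T Hc`` has magnitude at
    least ``min_gram``.  The topology penalty divides by this Gram, so
    its curvature — and the truncation error of any finite-difference
    oracle — explodes as entries approach zero; gradient validation is
    therefore performed on this smooth, bounded-curvature ensemble.
    """
    rng = np.random.default_rng(seed)
    eye = np.eye(s, dtype=bool)
    for _ in range(max_tries):
        H = rng.random((k, s))
        Hc = H - H.mean(axis=0, keepdims=True)
        S = Hc.T @ Hc
        if np.abs(S[~eye]).min() >= min_gram:
            return H
    raise ValidationError(
        f"no well-conditioned draw in {max_tries} tries; lower min_gram"
    )


def generate_timecourse(
    n_per_class_per_time: int = 5,
    n_times: int = 4,
    s: int = 300,
    n_signal: int = 15,
    effect: float = 0.5,
    block_rho: float = 0.6,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-class time-course expression with a planted signal block.

    Every feature ``j`` has a baseline level ``b_j = 0.5 + gamma(2, 1)``
    (bounded away from zero so ratio statistics stay meaningful).  A
    diseased sample at time index ``t`` expresses a signal feature at
    ``b_j * (1 + effect * t)`` — a progressive multiplicative disease
    effect; control samples and null features stay at baseline.  Noise
    is additive Gaussian with standard deviation ``noise_sd``; within the
    signal set it is exchangeably correlated with coefficient
    ``block_rho`` (shared per-sample fluctuation), mimicking
    co-regulation; null features get independent noise.  The result is
    clipped at zero.
    """
    if not 0 <= n_signal < s:
        raise ValidationError(f"n_signal={n_signal} must be in [0, s)")
    if not 0 <= block_rho < 1:
        raise ValidationError(f"block_rho={block_rho} must be in [0, 1)")
    if n_per_class_per_time < 1 or n_times < 1:
        raise ValidationError("need at least one sample per class per time")
    rng = np.random.default_rng(seed)
    g = 2 * n_per_class_per_time * n_times

    baseline = 0.5 + rng.gamma(shape=2.0, scale=1.0, size=s)
    signal = rng.choice(s, size=n_signal, replace=False)
    signal.sort()
    is_signal = np.zeros(s, dtype=bool)
    is_signal[signal] = True

    classes: list[str] = []
    times = np.zeros(g)
    mean = np.tile(baseline, (g, 1))
    i = 0
    for t in range(n_times):
        for label in (CONTROL, DISEASED):
            for _ in range(n_per_class_per_time):
                classes.append(label)
                times[i] = t
                if label == DISEASED:
                    mean[i, is_signal] *= 1.0 + effect * t
                i += 1

    noise = rng.normal(0.0, noise_sd, size=(g, s))
    if n_signal > 0 and block_rho > 0:
        shared = rng.normal(0.0, 1.0, size=(g, 1))
        indep = rng.normal(0.0, 1.0, size=(g, n_signal))
        noise[:, is_signal] = noise_sd * (
            np.sqrt(block_rho) * shared + np.sqrt(1.0 - block_rho) * indep
        )
    X = np.clip(mean + noise, 0.0, None)

    em = ExpressionMatrix(
        values=X,
        feature_ids=[f"f{j:04d}" for j in range(s)],
        sample_class=classes,
        sample_time=times,
    )
    truth = SyntheticTruth(
        W_star=None,
        H_star=None,
        signal_features=signal,
        noise_sd=noise_sd,
        design=list(zip(classes, times.tolist())),
    )
    return em, truth
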