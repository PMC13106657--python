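"""Biomarker ranking: hierarchical SOM clustering, class contrast,
relative expression.

After factorization, each biomarker ``j`` is represented by the
coefficient column ``h_j`` (length ``k``).  The ranking stage:

1. clusters the columns with a two-layer self-organizing-map hierarchy
   (a large layer-1 grid, a C-means consolidation of its prototypes, and
   a small layer-2 refinement into exactly four groups),
2. contrasts coefficient mass between control-associated and
   diseased-associated column sets (the ``C_mu`` / ``C_sigma``
   statistics),
3. scores each biomarker by its relative expression ``X_r`` — an
   elementwise product of disease/progression ratio matrices over a
   control baseline — and returns the top fraction.

SOM training here is *batch*: each epoch assigns every input to its
best-matching unit (BMU) and recomputes prototypes as
neighborhood-weighted averages.  Batch training is order-independent, so
clustering is equivariant under permutations of the biomarker columns —
a property the sequential one-sample-at-a-time rule does not have.  The
classical online rule is still exposed as :func:`som_step`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import (
    DegenerateClassError,
    DimensionError,
    TooFewFeaturesError,
    ValidationError,
)
from .expression import CONTROL, DISEASED, ExpressionMatrix


@dataclass
class SomLayer:
    """A grid of SOM prototypes.

    ``weights`` is ``m x k`` with ``m = rows * cols`` prototypes laid out
    row-major on the grid.  ``eta0`` and ``sigma0`` are the initial
    learning rate and neighborhood radius; both decay exponentially over
    ``epochs``.
    """

    weights: np.ndarray
    grid_shape: tuple[int, int]
    eta0: float = 0.5
    sigma0: float | None = None
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        rows, cols = self.grid_shape
        if rows * cols < 2:
            raise ValidationError("SOM grid needs at least 2 nodes")
        if self.weights.shape[0] != rows * cols:
            raise DimensionError(
                f"{rows * cols} grid nodes but {self.weights.shape[0]} prototypes"
            )
        if self.sigma0 is None:
            # half the grid diagonal
            self.sigma0 = 0.5 * math.hypot(rows - 1, cols - 1)
            self.sigma0 = max(self.sigma0, 0.5)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def grid_coordinates(self) -> np.ndarray:
        rows, cols = self.grid_shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


@dataclass
class ClusterHierarchy:
    """Result of the two-layer SOM clustering of coefficient columns."""

    layer1: SomLayer
    layer2: SomLayer
    assignments: np.ndarray  # per-biomarker group label in {1, 2, 3, 4}
    centroids: np.ndarray  # group centroid vectors (n_groups x k)


@dataclass
class ClassContrast:
    """Class-contrast statistics over coefficient-column L1 masses.

    ``mu_B`` / ``mu_D`` are summed masses over the control- and
    diseased-associated column sets of sizes ``n_B`` / ``n_D``;
    ``C_mu = (mu_B - mu_D) / (n_B + n_D)`` and ``C_sigma`` is the
    (unnormalized) squared-deviation difference over the same sets.
    """

    mu_B: float
    mu_D: float
    n_B: int
    n_D: int
    C_mu: float
    C_sigma: float


@dataclass
class RelativeExpression:
    """Relative-expression matrix ``X_r`` and its ingredients."""

    Xr: np.ndarray
    gammas: tuple[float, float, float]
    group_matrices: dict[str, np.ndarray] = field(repr=False)


# ---------------------------------------------------------------------------
# SOM primitives
# ---------------------------------------------------------------------------


def bmu(h: np.ndarray, layer: SomLayer) -> int:
    """Index of the best-matching unit (nearest prototype, lowest-index tie)."""
    h = np.asarray(h, dtype=float)
    d2 = np.sum((layer.weights - h[None, :]) ** 2, axis=1)
    return int(np.argmin(d2))


def _neighborhood(layer: SomLayer, winner: int, sigma: float) -> np.ndarray:
    coords = layer.grid_coordinates()
    d2 = np.sum((coords - coords[winner]) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * max(sigma, 1e-12) ** 2))


def som_step(
    h: np.ndarray,
    layer: SomLayer,
    t: int,
    eta: float | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """One online (winner-takes-all) update of the prototype grid.

    ``w_i <- w_i + eta(t) N_i(t) (h - w_i)`` where ``N_i`` is a Gaussian
    on grid distance to the BMU of ``h``.  ``eta`` and ``sigma`` decay
    exponentially with ``t`` over the layer's epoch horizon unless given
    explicitly.  Updates ``layer.weights`` in place and returns them.
    """
    h = np.asarray(h, dtype=float)
    horizon = max(layer.epochs, 1)
    if eta is None:
        eta = layer.eta0 * math.exp(-t / horizon)
    if sigma is None:
        sigma = layer.sigma0 * math.exp(-t / horizon)
    if not 0.0 <= eta <= 1.0:
        raise ValidationError(f"learning rate eta={eta} must lie in [0, 1]")
    winner = bmu(h, layer)
    N = _neighborhood(layer, winner, sigma)
    layer.weights = layer.weights + eta * N[:, None] * (h[None, :] - layer.weights)
    return layer.weights


def som_fit(
    data: np.ndarray,
    grid_shape: tuple[int, int],
    eta0: float = 0.5,
    sigma0: float | None = None,
    epochs: int = 100,
    seed: int = 0,
    init_weights: np.ndarray | None = None,
) -> SomLayer:
    """Fit a SOM to ``data`` (n x k) with batch epochs.

    Prototypes are initialized uniformly within the per-dimension data
    range (deterministic given ``seed``) unless ``init_weights`` is
    given.  Each epoch assigns all inputs to BMUs and replaces every
    prototype by the neighborhood-weighted mean of the data; the radius
    decays exponentially over epochs.  Order-independent by construction.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise DimensionError("SOM input must be an n x k matrix")
    m = grid_shape[0] * grid_shape[1]
    rng = np.random.default_rng(seed)
    if init_weights is None:
        lo = data.min(axis=0)
        hi = data.max(axis=0)
        init_weights = lo[None, :] + rng.random((m, data.shape[1])) * (hi - lo)[None, :]
    layer = SomLayer(
        weights=np.array(init_weights, dtype=float),
        grid_shape=grid_shape,
        eta0=eta0,
        sigma0=sigma0,
        epochs=epochs,
        seed=seed,
    )
    coords = layer.grid_coordinates()
    grid_d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    for epoch in range(epochs):
        sigma = layer.sigma0 * math.exp(-3.0 * epoch / max(epochs, 1))
        sigma = max(sigma, 1e-3)
        d2 = (
            np.sum(data * data, axis=1)[:, None]
            - 2.0 * data @ layer.weights.T
            + np.sum(layer.weights * layer.weights, axis=1)[None, :]
        )
        winners = np.argmin(d2, axis=1)
        N = np.exp(-grid_d2[winners] / (2.0 * sigma**2))  # n x m
        mass = N.sum(axis=0)
        numer = N.T @ data
        nonzero = mass > 1e-12
        new_w = layer.weights.copy()
        new_w[nonzero] = numer[nonzero] / mass[nonzero, None]
        layer.weights = new_w
    return layer


# ---------------------------------------------------------------------------
# Hierarchical clustering of coefficient columns
# ---------------------------------------------------------------------------


def hierarchical_cluster(
    H: np.ndarray,
    grid1: tuple[int, int] = (8, 8),
    grid2: tuple[int, int] = (2, 2),
    n_groups: int = 4,
    epochs: int = 100,
    eta0: float = 0.5,
    seed: int = 0,
) -> ClusterHierarchy:
    """Two-layer SOM hierarchy assigning each biomarker to one of four groups.

    Layer 1 maps the coefficient columns onto a large prototype grid;
    C-means (k-means with ``n_groups`` centres) consolidates the layer-1
    prototypes; layer 2, initialized at the C-means centroids, refines
    them on the columns' layer-1 representatives.  Each biomarker's
    group is the layer-2 BMU of its layer-1 prototype, so equal columns
    always land in the same group and permuting columns permutes the
    assignments identically.
    """
    H = np.asarray(H, dtype=float)
    cols = H.T  # s x k
    s = cols.shape[0]
    if s < n_groups:
        raise TooFewFeaturesError(f"need at least {n_groups} biomarkers, got {s}")
    if grid2[0] * grid2[1] != n_groups:
        raise ValidationError("layer-2 grid must have exactly n_groups nodes")
    layer1 = som_fit(cols, grid1, eta0=eta0, epochs=epochs, seed=seed)
    b1 = np.array([bmu(c, layer1) for c in cols])
    reps = layer1.weights[b1]  # each column's layer-1 representative

    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
    km.fit(layer1.weights)
    layer2 = som_fit(
        reps,
        grid2,
        eta0=eta0,
        sigma0=0.5,
        epochs=max(epochs // 2, 1),
        seed=seed + 1,
        init_weights=km.cluster_centers_,
    )
    assignments = np.array([bmu(r, layer2) for r in reps]) + 1  # groups 1..4
    centroids = np.zeros((n_groups, H.shape[0]))
    for grp in range(1, n_groups + 1):
        members = cols[assignments == grp]
        centroids[grp - 1] = members.mean(axis=0) if len(members) else layer2.weights[grp - 1]
    return ClusterHierarchy(
        layer1=layer1, layer2=layer2, assignments=assignments, centroids=centroids
    )


# ---------------------------------------------------------------------------
# Class contrast
# ---------------------------------------------------------------------------


def associate_groups_with_classes(
    X: ExpressionMatrix, assignments: np.ndarray
) -> np.ndarray:
    """Label each biomarker column control- or diseased-associated.

    A cluster group is diseased-associated when the mean expression of
    its member features over diseased samples exceeds that over control
    samples; all members inherit the group's association.  This realizes
    the cluster-membership index sets the class contrast is evaluated
    over.
    """
    assignments = np.asarray(assignments)
    ctrl = X.class_mask(CONTROL)
    dis = X.class_mask(DISEASED)
    if not ctrl.any() or not dis.any():
        raise DegenerateClassError("both control and diseased samples are required")
    out = np.empty(X.n_features, dtype=object)
    for grp in np.unique(assignments):
        members = assignments == grp
        mean_d = X.values[np.ix_(dis, members)].mean()
        mean_c = X.values[np.ix_(ctrl, members)].mean()
        out[members] = DISEASED if mean_d > mean_c else CONTROL
    return out.astype(str)


def class_contrast(
    H: np.ndarray,
    column_classes: np.ndarray | None = None,
    control_cols: np.ndarray | None = None,
    diseased_cols: np.ndarray | None = None,
) -> ClassContrast:
    """Contrast coefficient mass between class-associated column sets.

    Either pass ``column_classes`` (a length-``s`` array of ``control`` /
    ``diseased`` labels, e.g. from
    :func:`associate_groups_with_classes`) or explicit index arrays
    ``control_cols`` / ``diseased_cols``.

    With ``m_j = ||h_j||_1`` the L1 mass of column ``j``::

        mu_B = sum_{j in B} m_j            mu_D = sum_{j in D} m_j
        C_mu = (mu_B - mu_D) / (n_B + n_D)
        C_sigma = (sum_{j in B} (m_j - mu_B)^2
                   - sum_{j in D} (m_j - mu_D)^2) / (n_B + n_D)

    The squared deviations are taken against the *summed* masses, kept
    literal to the originating formulation.
    """
    H = np.asarray(H, dtype=float)
    masses = np.abs(H).sum(axis=0)
    if column_classes is not None:
        column_classes = np.asarray(column_classes)
        if column_classes.shape[0] != H.shape[1]:
            raise DimensionError("one class label per coefficient column required")
        control_cols = np.flatnonzero(column_classes == CONTROL)
        diseased_cols = np.flatnonzero(column_classes == DISEASED)
    if control_cols is None or diseased_cols is None:
        raise ValidationError("provide column_classes or both index sets")
    control_cols = np.asarray(control_cols, dtype=int)
    diseased_cols = np.asarray(diseased_cols, dtype=int)
    if control_cols.size == 0 or diseased_cols.size == 0:
        raise DegenerateClassError("both class-associated column sets must be nonempty")
    mu_B = float(masses[control_cols].sum())
    mu_D = float(masses[diseased_cols].sum())
    n_B = int(control_cols.size)
    n_D = int(diseased_cols.size)
    denom = n_B + n_D
    C_mu = (mu_B - mu_D) / denom
    C_sigma = (
        float(np.sum((masses[control_cols] - mu_B) ** 2))
        - float(np.sum((masses[diseased_cols] - mu_D) ** 2))
    ) / denom
    return ClassContrast(mu_B=mu_B, mu_D=mu_D, n_B=n_B, n_D=n_D, C_mu=C_mu, C_sigma=C_sigma)


# ---------------------------------------------------------------------------
# Relative expression and ranking
# ---------------------------------------------------------------------------


def build_group_matrices(
    X: ExpressionMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Default construction of the four ``g x s`` ratio ingredients.

    Convention (documented, swappable — pass any four matrices to
    :func:`relative_expression`):

    * ``B`` (baseline): mean control expression at the earliest time
      point, per feature, broadcast over samples.
    * ``D`` (disease): mean diseased expression over all time points.
    * ``P`` (progression): mean diseased expression at each sample's own
      time point.
    * ``Pc`` (control progression): mean control expression at each
      sample's own time point.
    """
    ctrl = X.class_mask(CONTROL)
    dis = X.class_mask(DISEASED)
    if not ctrl.any() or not dis.any():
        raise DegenerateClassError("both classes are required")
    g, s = X.values.shape
    t0 = X.sample_time.min()
    base_mask = ctrl & (X.sample_time == t0)
    if not base_mask.any():
        base_mask = ctrl
    B_row = X.values[base_mask].mean(axis=0)
    D_row = X.values[dis].mean(axis=0)
    Bm = np.tile(B_row, (g, 1))
    Dm = np.tile(D_row, (g, 1))
    Pm = np.empty((g, s))
    Pcm = np.empty((g, s))
    for t in np.unique(X.sample_time):
        rows = X.sample_time == t
        dt = dis & rows
        ct = ctrl & rows
        Pm[rows] = X.values[dt].mean(axis=0) if dt.any() else D_row
        Pcm[rows] = X.values[ct].mean(axis=0) if ct.any() else B_row
    return Dm, Bm, Pm, Pcm


def relative_expression(
    Dm: np.ndarray,
    Bm: np.ndarray,
    Pm: np.ndarray,
    Pcm: np.ndarray,
    gammas: tuple[float, float, float] = (1.0, 1.0, 1.0),
    floor_eps: float = 1e-10,
) -> RelativeExpression:
    """Relative expression ``X_r`` from the four group matrices.

    ``Xr = g1 (D / B) * g2 (P / B) * g3 (Pc / B)`` elementwise, with the
    baseline denominator floored at ``floor_eps``.
    """
    mats = {"D": Dm, "B": Bm, "P": Pm, "Pc": Pcm}
    shapes = {m.shape for m in map(np.asarray, mats.values())}
    if len(shapes) != 1:
        raise DimensionError(f"group matrices must share one shape, got {shapes}")
    for name, m in mats.items():
        m = np.asarray(m, dtype=float)
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValidationError(f"group matrix {name} must be finite and nonnegative")
        mats[name] = m
    g1, g2, g3 = gammas
    Bf = np.maximum(mats["B"], floor_eps)
    Xr = (g1 * (mats["D"] / Bf)) * (g2 * (mats["P"] / Bf)) * (g3 * (mats["Pc"] / Bf))
    return RelativeExpression(Xr=Xr, gammas=tuple(gammas), group_matrices=mats)


def rank_biomarkers(
    rel: RelativeExpression | np.ndarray,
    feature_ids: list[str],
    top_fraction: float = 0.03,
    contrast: ClassContrast | None = None,
    assignments: np.ndarray | None = None,
    floor_eps: float = 1e-10,
):
    """Order biomarkers by relative-expression deviation from baseline.

    The per-feature score is the mean over samples of ``|log Xr_ij|`` —
    features whose relative expression departs from 1 in either
    direction score high.  Returns a pandas DataFrame with the top
    ``ceil(top_fraction * s)`` rows: feature_id, score, rank, group
    (group 0 when no cluster assignments are supplied) and, when a
    :class:`ClassContrast` is given, the sign of ``C_mu`` as the
    direction annotation.
    """
    import pandas as pd

    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must lie in (0, 1]")
    Xr = rel.Xr if isinstance(rel, RelativeExpression) else np.asarray(rel, dtype=float)
    if Xr.shape[1] != len(feature_ids):
        raise DimensionError("one feature id per Xr column required")
    scores = np.mean(np.abs(np.log(np.maximum(Xr, floor_eps))), axis=0)
    order = np.argsort(-scores, kind="stable")
    n_top = math.ceil(top_fraction * len(feature_ids))
    top = order[:n_top]
    groups = (
        np.asarray(assignments)[top]
        if assignments is not None
        else np.zeros(n_top, dtype=int)
    )
    df = pd.DataFrame(
        {
            "feature_id": [feature_ids[j] for j in top],
            "score": scores[top],
            "rank": np.arange(1, n_top + 1),
            "group": groups,
        }
    )
    if contrast is not None:
        df["contrast_direction"] = int(np.sign(contrast.C_mu))
    return df
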