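"""From-scratch self-organizing map on a rectangular grid.

One observation is one gene: its feature vector is the normalized log2
expression across all replicate libraries.  The map is a rows x cols lattice
of codebook vectors trained with the online Kohonen rule; after training,
each gene is assigned to its best matching unit (BMU), the codebook vector
nearest in Euclidean distance.  Genes sharing a node therefore share an
expression profile, and node-level aggregates ("Tatami maps") summarize the
transcriptome or secretome on the grid.

Node IDs are 1-based and row-major: node = row * n_cols + col + 1, so
consecutive IDs within a row are laterally adjacent on the grid.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

__all__ = ["SelfOrganizingMap", "grid_coordinates"]

#: default lattice for the genome-wide map: 19 x 23 = 437 units, the
#: near-square factorization of the 437-unit map size.
DEFAULT_ROWS = 19
DEFAULT_COLS = 23


def grid_coordinates(n_rows: int, n_cols: int) -> np.ndarray:
    """(row, col) integer coordinates of nodes 1..n_rows*n_cols, row-major."""
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    return np.column_stack([rows, cols])


class SelfOrganizingMap(ClusterMixin, TransformerMixin, BaseEstimator):
    """Kohonen self-organizing map with online (or batch) training.

    Parameters
    ----------
    n_rows, n_cols : int, default 19 x 23
        Grid shape; the number of map units is ``n_rows * n_cols``.
    iterations_per_unit : int, default=100
        Online training runs ``iterations_per_unit * n_units`` single-profile
        update steps (so the 437-unit default map trains for 43,700 steps).
        In batch mode this is the number of whole-data epochs divided by one
        (see `mode`).
    initial_learning_rate, final_learning_rate : float
        Linear decay endpoints of the update step size.
    initial_radius : float or None
        Gaussian neighborhood radius at step 0; ``None`` means
        ``max(n_rows, n_cols) / 2``.
    final_radius : float, default=0.5
        Radius at the last step (linear decay).  The radius is the Gaussian
        neighborhood width sigma; ending at 0.5 makes the late phase close
        to winner-take-all vector quantization, which is what lets training
        lower the quantization error instead of smoothing the codebook
        toward the global mean.
    mode : {"online", "batch"}, default="online"
        Online: sequential Kohonen updates, one profile per step, profiles
        presented cyclically in a seeded shuffled order.  Batch: repeated
        assign-then-average epochs with the same decaying neighborhood
        (``n_epochs = iterations_per_unit``).
    random_state : int, RandomState or None
        Seeds codebook initialization (rows sampled with replacement from the
        data) and the presentation order.

    Attributes
    ----------
    codebook_ : ndarray of shape (n_units, n_features)
    labels_ : ndarray of shape (n_genes,)
        1-based BMU node ID of each fitted profile.
    grid_ : ndarray of shape (n_units, 2)
        (row, col) of each node, row-major.
    n_units_ : int
    total_iterations_ : int
        Number of online update steps performed (``iterations_per_unit *
        n_units``).
    """

    def __init__(
        self,
        n_rows: int = DEFAULT_ROWS,
        n_cols: int = DEFAULT_COLS,
        iterations_per_unit: int = 100,
        initial_learning_rate: float = 0.05,
        final_learning_rate: float = 0.01,
        initial_radius: float | None = None,
        final_radius: float = 0.5,
        mode: str = "online",
        random_state=None,
    ):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.iterations_per_unit = iterations_per_unit
        self.initial_learning_rate = initial_learning_rate
        self.final_learning_rate = final_learning_rate
        self.initial_radius = initial_radius
        self.final_radius = final_radius
        self.mode = mode
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _validate_config(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.iterations_per_unit < 1:
            raise ValueError("iterations_per_unit must be positive")
        if not (0 < self.final_learning_rate <= self.initial_learning_rate):
            raise ValueError("need 0 < final_learning_rate <= initial_learning_rate")
        if self.final_radius <= 0:
            raise ValueError("final_radius must be positive")
        if self.initial_radius is not None and self.final_radius > self.initial_radius:
            raise ValueError("need final_radius <= initial_radius")
        if self.mode not in ("online", "batch"):
            raise ValueError("mode must be 'online' or 'batch'")

    def _radius0(self) -> float:
        if self.initial_radius is not None:
            return float(self.initial_radius)
        return max(self.n_rows, self.n_cols) / 2.0

    def _init_codebook(self, X: np.ndarray, rng) -> np.ndarray:
        idx = rng.randint(0, X.shape[0], size=self.n_rows * self.n_cols)
        return X[idx].copy()

    # -- estimator API -----------------------------------------------------

    def initialize(self, X):
        """Sample the initial codebook from the data without training.

        Codebook rows are drawn with replacement from the profile vectors;
        no assignment is made (``labels_`` stays unset until :meth:`fit`).
        """
        self._validate_config()
        X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        n_units = self.n_rows * self.n_cols
        if n_units > 10 * X.shape[0]:
            raise ValueError(
                f"{n_units} map units for {X.shape[0]} profiles: the map is "
                "implausibly large (limit: 10 units per profile)"
            )
        rng = check_random_state(self.random_state)
        self.grid_ = grid_coordinates(self.n_rows, self.n_cols)
        self.codebook_ = self._init_codebook(X, rng)
        self.n_units_ = n_units
        self.n_features_in_ = X.shape[1]
        return self

    def fit(self, X, y=None):
        """Train the map and assign every profile to its BMU."""
        self._validate_config()
        X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        n_units = self.n_rows * self.n_cols
        if n_units > 10 * X.shape[0]:
            raise ValueError(
                f"{n_units} map units for {X.shape[0]} profiles: the map is "
                "implausibly large (limit: 10 units per profile)"
            )
        rng = check_random_state(self.random_state)
        self.grid_ = grid_coordinates(self.n_rows, self.n_cols)
        # squared grid distances between all node pairs, precomputed once
        d2 = ((self.grid_[:, None, :] - self.grid_[None, :, :]) ** 2).sum(-1)
        codebook = self._init_codebook(X, rng)
        self.n_units_ = n_units
        self.total_iterations_ = self.iterations_per_unit * n_units

        if self.mode == "online":
            self._fit_online(X, codebook, d2, rng)
        else:
            self._fit_batch(X, codebook, d2)
        self.codebook_ = codebook
        self.n_features_in_ = X.shape[1]
        self.labels_ = self._bmu(X)
        return self

    def _schedule(self, t: int, total: int) -> tuple[float, float]:
        frac = t / (total - 1) if total > 1 else 0.0
        lr = self.initial_learning_rate + frac * (
            self.final_learning_rate - self.initial_learning_rate
        )
        r0 = self._radius0()
        r1 = min(self.final_radius, r0)  # degenerate grids: r0 < 1
        radius = r0 + frac * (r1 - r0)
        return lr, radius

    def _fit_online(self, X, codebook, d2, rng):
        total = self.total_iterations_
        order = rng.permutation(X.shape[0])
        n = X.shape[0]
        for t in range(total):
            x = X[order[t % n]]
            lr, radius = self._schedule(t, total)
            diff = x - codebook
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = np.exp(-d2[bmu] / (2.0 * radius * radius))
            codebook += (lr * h)[:, None] * diff

    def _fit_batch(self, X, codebook, d2):
        n_epochs = self.iterations_per_unit
        for epoch in range(n_epochs):
            _, radius = self._schedule(epoch, n_epochs)
            dist = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
            bmu = dist.argmin(axis=1)
            h = np.exp(-d2[bmu] / (2.0 * radius * radius))  # (n_genes, n_units)
            wsum = h.sum(axis=0)
            num = h.T @ X
            nz = wsum > 0
            codebook[nz] = num[nz] / wsum[nz, None]

    def _bmu(self, X: np.ndarray) -> np.ndarray:
        # returns 1-based node IDs; ties broken toward the lowest node ID
        # (argmin takes the first minimum)
        d = self.transform(X, _validated=True)
        return d.argmin(axis=1) + 1

    def predict(self, X) -> np.ndarray:
        """1-based BMU node ID for each profile (Euclidean nearest codebook)."""
        check_is_fitted(self)
        X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        if X.shape[1] != self.codebook_.shape[1]:
            raise ValueError(
                f"profile has {X.shape[1]} features, codebook has "
                f"{self.codebook_.shape[1]}"
            )
        return self._bmu(X)

    def transform(self, X, _validated: bool = False) -> np.ndarray:
        """Euclidean distance of each profile to every codebook vector."""
        if not _validated:
            check_is_fitted(self)
            X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        return cdist(X, self.codebook_)

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance of profiles to their BMU codebook vector."""
        check_is_fitted(self)
        X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        return float(self.transform(X, _validated=True).min(axis=1).mean())

    def node_positions(self) -> np.ndarray:
        """(row, col) per node ID, in node-ID order (alias for ``grid_``)."""
        check_is_fitted(self)
        return self.grid_
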