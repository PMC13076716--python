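"""Spatial weight matrices and global spatial autocorrelation.

Divisions are related through a row-standardized spatial weights matrix
``W`` (``w_ii = 0``, each non-empty row summing to one).  The default
neighbourhood definition is k-nearest-neighbour contiguity on planar
centroid coordinates; the weight specification actually used downstream
is chosen by Monte Carlo trials that maximize global Moran's i of the
prevalence surface.

Moran's i for values :math:`x` with mean :math:`\\bar x` and
:math:`z_i = x_i - \\bar x` is

.. math::

    I = \\frac{n}{\\sum_{ij} w_{ij}}
        \\frac{\\sum_{ij} w_{ij} z_i z_j}{\\sum_i z_i^2},

and significance is assessed with a Monte Carlo permutation test using
the pseudo p-value rule ``p = (1 + #{permuted >= observed}) / (n_sims + 1)``
for the upper tail.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Sequence

import numpy as np
import scipy.sparse as sp


class UndefinedStatisticError(ValueError):
    """Raised when a spatial statistic is undefined (e.g. constant input)."""


@dataclasses.dataclass(frozen=True)
class ClusterTestResult:
    """Outcome of a Monte Carlo permutation test of spatial clustering."""

    statistic: float
    p_value: float
    n_sims: int
    spec: str
    seed: int | None
    tail: str = "upper"


class SpatialWeights:
    """Row-standardized sparse spatial weights over an ordered id set.

    Parameters
    ----------
    ids : sequence of str
        Ordered division identifiers; row/column ``i`` of the matrix
        refers to ``ids[i]``.
    matrix : scipy.sparse matrix or (n, n) array
        Nonnegative weights with zero diagonal.  Rows with at least one
        neighbour are row-standardized on construction.
    spec : str
        Human-readable descriptor, e.g. ``"knn:k=3"``.
    """

    def __init__(
        self, ids: Sequence[str], matrix, spec: str = "custom", allow_self: bool = False
    ):
        ids = np.asarray(list(ids), dtype=object)
        if ids.size != np.unique(ids).size:
            raise ValueError("division ids must be unique")
        W = sp.csr_matrix(matrix, dtype=float)
        if W.shape[0] != W.shape[1] or W.shape[0] != ids.size:
            raise ValueError("weights matrix must be square and match ids")
        if not allow_self and W.diagonal().any():
            raise ValueError("self-neighbour weights (w_ii != 0) are not allowed")
        if (W.data < 0).any():
            raise ValueError("weights must be nonnegative")
        rs = np.asarray(W.sum(axis=1)).ravel()
        scale = np.ones_like(rs)
        nz = rs > 0
        scale[nz] = 1.0 / rs[nz]
        W = sp.diags(scale) @ W
        self.ids = ids
        self.W = sp.csr_matrix(W)
        self.spec = spec

    # -- basic interface -------------------------------------------------

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def s0(self) -> float:
        """Sum of all weights (equals the number of non-empty rows)."""
        return float(self.W.sum())

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()

    def neighbours(self, division_id: str) -> dict[str, float]:
        i = int(np.flatnonzero(self.ids == division_id)[0])
        row = self.W.getrow(i)
        return {str(self.ids[j]): float(v) for j, v in zip(row.indices, row.data)}

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatially lagged values ``(W x)_i``."""
        return self.W @ np.asarray(values, dtype=float)

    def align(self, table, value_col: str, id_col: str = "division_id") -> np.ndarray:
        """Extract ``value_col`` from a DataFrame in this object's id order."""
        s = table.set_index(id_col)[value_col]
        missing = [i for i in self.ids if i not in s.index]
        if missing:
            raise KeyError(f"values missing for divisions: {missing[:5]}")
        return s.loc[list(self.ids)].to_numpy(dtype=float)

    def subset(self, keep_ids: Sequence[str]) -> "SpatialWeights":
        """Restrict to ``keep_ids`` (re-row-standardizing surviving rows)."""
        keep = np.asarray(list(keep_ids), dtype=object)
        pos = {d: i for i, d in enumerate(self.ids)}
        idx = np.array([pos[d] for d in keep], dtype=int)
        sub = self.W[np.ix_(idx, idx)]
        return SpatialWeights(keep, sub, spec=f"{self.spec}|subset:{keep.size}")

    # -- serialization ---------------------------------------------------

    def to_edgelist(self, path) -> None:
        """Write a sparse ``i_id<TAB>j_id<TAB>w_ij`` text file (bit-exact)."""
        coo = self.W.tocoo()
        with open(path, "w") as fh:
            fh.write(f"# spec={self.spec}\n")
            fh.write("# ids=" + ",".join(map(str, self.ids)) + "\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{v.hex()}\n")

    @classmethod
    def from_edgelist(cls, path) -> "SpatialWeights":
        spec = "edgelist"
        ids: list[str] = []
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# spec="):
                    spec = line[len("# spec=") :]
                elif line.startswith("# ids="):
                    ids = line[len("# ids=") :].split(",")
                elif line:
                    a, b, v = line.split("\t")
                    rows.append(a)
                    cols.append(b)
                    vals.append(float.fromhex(v))
        if not ids:
            raise ValueError("edge-list file lacks an ids header")
        pos = {d: i for i, d in enumerate(ids)}
        W = sp.coo_matrix(
            (vals, ([pos[a] for a in rows], [pos[b] for b in cols])),
            shape=(len(ids), len(ids)),
        )
        return cls(ids, W, spec=spec)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpatialWeights(n={self.n}, spec={self.spec!r})"


def knn_weights(geography, k: int) -> SpatialWeights:
    """k-nearest-neighbour contiguity weights from division centroids.

    Each division's neighbours are its ``k`` nearest by Euclidean
    distance between centroids, each receiving weight ``1/k``
    (row-standardized).  The relation need not be symmetric.  Distance
    ties are broken lexicographically by division id so the matrix is
    reproducible.

    Parameters
    ----------
    geography : pandas.DataFrame
        Columns ``division_id``, ``x``, ``y``.
    k : int
        Number of neighbours, ``1 <= k < n``.
    """
    ids = geography["division_id"].to_numpy(dtype=object)
    order = np.argsort(ids.astype(str), kind="stable")
    ids = ids[order]
    xy = geography[["x", "y"]].to_numpy(dtype=float)[order]
    n = ids.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} divisions, got {n}")
    if not np.isfinite(xy).all():
        raise ValueError("centroid coordinates must be finite")
    # O(n^2) distances; ids are pre-sorted so argsort's stable tie order
    # is lexicographic by id.
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    W = sp.coo_matrix(
        (np.full(n * k, 1.0 / k), (rows, nbr.ravel())), shape=(n, n)
    )
    return SpatialWeights(ids, W, spec=f"knn:k={k}")


def _check_variable(x: np.ndarray, name: str = "values") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contain non-finite entries")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError(
            f"{name} are constant; the statistic is undefined"
        )
    return x


def morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's i of ``values`` under ``weights``.

    Raises
    ------
    UndefinedStatisticError
        If the values are constant (zero variance).
    """
    x = _check_variable(values)
    if x.size != weights.n:
        raise ValueError("values length does not match weights")
    z = x - x.mean()
    den = float(z @ z)
    num = float(z @ (weights.W @ z))
    return weights.n / weights.s0 * num / den


def _morans_i_batch(Z: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Moran's i per column of ``Z`` (columns already centred)."""
    WZ = weights.W @ Z
    num = (Z * WZ).sum(axis=0)
    den = (Z**2).sum(axis=0)
    return weights.n / weights.s0 * num / den


def mc_permutation_test(
    values: np.ndarray,
    weights: SpatialWeights,
    statistic: str | Callable = "morans_i",
    n_sims: int = 999,
    seed: int | None = None,
    tail: str = "upper",
) -> ClusterTestResult:
    """Monte Carlo permutation test of spatial clustering.

    ``values`` are randomly reassigned to locations ``n_sims`` times and
    the statistic recomputed; the pseudo p-value follows the
    ``(1 + count) / (n_sims + 1)`` rule.  Deterministic given ``seed``.

    Parameters
    ----------
    statistic : "morans_i" or callable ``f(values, weights) -> float``
    tail : {"upper", "lower", "two-sided"}
        "upper" (default) tests positive clustering; "two-sided" compares
        absolute deviations from the permutation mean.
    """
    if n_sims < 19:
        raise ValueError("n_sims must be >= 19")
    if tail not in {"upper", "lower", "two-sided"}:
        raise ValueError(f"unknown tail {tail!r}")
    x = _check_variable(values)
    rng = np.random.default_rng(seed)
    perm_idx = rng.permuted(
        np.tile(np.arange(x.size), (n_sims, 1)), axis=1
    )
    if statistic == "morans_i":
        obs = morans_i(x, weights)
        Z = x[perm_idx.T] - x.mean()  # (n, n_sims); mean is permutation-invariant
        sims = _morans_i_batch(Z, weights)
    elif callable(statistic):
        obs = float(statistic(x, weights))
        sims = np.array([statistic(x[p], weights) for p in perm_idx])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = _pseudo_p(obs, sims, tail)
    return ClusterTestResult(
        statistic=float(obs),
        p_value=p,
        n_sims=n_sims,
        spec=weights.spec,
        seed=seed,
        tail=tail,
    )


def _pseudo_p(obs: float, sims: np.ndarray, tail: str) -> float:
    if tail == "upper":
        count = int((sims >= obs).sum())
    elif tail == "lower":
        count = int((sims <= obs).sum())
    else:
        centre = sims.mean()
        count = int((np.abs(sims - centre) >= abs(obs - centre)).sum())
    return (1 + count) / (sims.size + 1)


def select_weights(
    values: np.ndarray,
    candidates: Sequence[SpatialWeights],
    n_sims: int = 999,
    seed: int | None = 0,
    tail: str = "upper",
) -> tuple[SpatialWeights, list[ClusterTestResult]]:
    """Choose the weight specification maximizing Moran's i of ``values``.

    Every candidate is evaluated with its own Monte Carlo permutation
    test (sub-seeded from ``seed`` so the trial table is reproducible);
    the candidate with the largest observed Moran's i is returned
    together with the full trial table.  Ties go to the earlier
    candidate in the list.
    """
    if len(candidates) == 0:
        raise ValueError("at least one candidate specification is required")
    trials: list[ClusterTestResult] = []
    errors: list[str] = []
    for idx, cand in enumerate(candidates):
        sub_seed = None if seed is None else int(
            np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31)
        )
        try:
            trials.append(
                mc_permutation_test(
                    values, cand, "morans_i", n_sims=n_sims, seed=sub_seed, tail=tail
                )
            )
        except UndefinedStatisticError as exc:
            errors.append(f"{cand.spec}: {exc}")
    if not trials:
        raise UndefinedStatisticError(
            "all candidate specifications failed: " + "; ".join(errors)
        )
    stats = [t.statistic for t in trials]
    best_spec = trials[int(np.argmax(stats))].spec
    best = next(c for c in candidates if c.spec == best_spec)
    return best, trials
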