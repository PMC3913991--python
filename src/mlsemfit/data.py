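"""Clustered data ingestion and sufficient statistics.

A two-level data set stacks observations from level-1 units (students,
patients, repeated measures) nested in level-2 clusters (schools, clinics,
persons).  Everything the two-level maximum-likelihood machinery needs is a
small set of sufficient statistics: cluster sizes, cluster means, the
between-cluster cross-product matrices

    S_Bj = n_j (ybar_j - ybar)(ybar_j - ybar)'

and the within-cluster covariance matrices S_Wj (divisor n_j - 1), which pool
into a single within matrix with divisor N - J.  Downstream modules consume
:class:`SufficientStatistics` only, never raw files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_log = logging.getLogger(__name__)

__all__ = [
    "TwoLevelDataset",
    "SufficientStatistics",
    "read_dataset",
    "compute_sufficient_stats",
]


@dataclass
class TwoLevelDataset:
    """Raw clustered observations plus cluster labels.

    Parameters
    ----------
    values : (N, p) array of finite floats, one row per level-1 unit.
    cluster_id : length-N array of cluster labels (any hashable scalars).
    variable_names : length-p list of column identifiers.
    """

    values: np.ndarray
    cluster_id: np.ndarray
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cluster_id = np.asarray(self.cluster_id)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d (N x p) array")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError("need at least 2 rows and 1 variable")
        if len(self.cluster_id) != n:
            raise ValueError("cluster_id length does not match row count")
        if len(self.variable_names) != p:
            raise ValueError("variable_names length does not match column count")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column "
                f"'{self.variable_names[bad[1]]}' (missing data is not supported)"
            )
        if len(pd.unique(self.cluster_id)) < 2:
            raise ValueError("two-level data requires >= 2 clusters")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]


@dataclass
class SufficientStatistics:
    """Summaries consumed by the two-level fitting function and likelihood.

    ``S_Bj`` holds n_j (ybar_j - ybar)(ybar_j - ybar)' per cluster and
    ``S_Wj`` the per-cluster covariance with divisor n_j - 1 (a zero matrix
    for singleton clusters, which carry zero within weight).
    ``pooled_within`` is sum_j (n_j - 1) S_Wj / (N - J).
    """

    J: int
    N: int
    n_j: np.ndarray
    grand_mean: np.ndarray
    cluster_means: np.ndarray
    S_Bj: np.ndarray
    S_Wj: np.ndarray
    pooled_within: np.ndarray
    balanced: bool
    variable_names: list[str]
    cluster_labels: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.variable_names)

    @property
    def n_effective_within(self) -> int:
        """Effective level-1 sample size N - J."""
        return self.N - self.J

    def mean_S_B(self) -> np.ndarray:
        """Average between matrix (1/J) sum_j S_Bj."""
        return self.S_Bj.mean(axis=0)

    def grouped_between(self) -> list[tuple[int, int, np.ndarray]]:
        """Between summaries grouped by distinct cluster size.

        Returns ``[(n, J_n, mean of S_Bj over clusters of size n), ...]``;
        the group covariance Sigma_W + n Sigma_B is constant within a group,
        so the fitting function needs only these aggregates.
        """
        out = []
        for n in np.unique(self.n_j):
            mask = self.n_j == n
            out.append((int(n), int(mask.sum()), self.S_Bj[mask].mean(axis=0)))
        return out

    def subset(self, names: list[str]) -> "SufficientStatistics":
        """Restrict/reorder the variable axis to ``names``."""
        missing = [v for v in names if v not in self.variable_names]
        if missing:
            raise KeyError(f"variables not present in data: {missing}")
        idx = [self.variable_names.index(v) for v in names]
        ix = np.ix_(idx, idx)
        return SufficientStatistics(
            J=self.J,
            N=self.N,
            n_j=self.n_j,
            grand_mean=self.grand_mean[idx],
            cluster_means=self.cluster_means[:, idx],
            S_Bj=self.S_Bj[(slice(None),) + ix],
            S_Wj=self.S_Wj[(slice(None),) + ix],
            pooled_within=self.pooled_within[ix],
            balanced=self.balanced,
            variable_names=list(names),
            cluster_labels=self.cluster_labels,
        )


def read_dataset(path, cluster_column: str) -> TwoLevelDataset:
    """Read a delimited text file (comma or tab, header row) into a dataset.

    All columns other than ``cluster_column`` must be numeric and complete;
    a missing or non-numeric cell raises with its row and column named.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if cluster_column not in df.columns:
        raise KeyError(f"cluster column '{cluster_column}' not found in {path}")
    cluster = df[cluster_column].to_numpy()
    if pd.isna(cluster).any():
        row = int(np.flatnonzero(pd.isna(cluster))[0])
        raise ValueError(f"missing cluster label at row {row}")
    value_cols = [c for c in df.columns if c != cluster_column]
    if not value_cols:
        raise ValueError("no variable columns besides the cluster column")
    for c in value_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise ValueError(f"missing or non-numeric value at row {row}, column '{c}'")
    values = df[value_cols].to_numpy(dtype=float)
    return TwoLevelDataset(values=values, cluster_id=cluster, variable_names=value_cols)


def compute_sufficient_stats(data: TwoLevelDataset) -> SufficientStatistics:
    """Reduce a dataset to the sufficient statistics of the two-level likelihood.

    Cluster indices are assigned by first appearance of each label.  Singleton
    clusters are retained: they contribute to the between part with weight
    n_j = 1 and nothing to the within part.
    """
    labels = list(pd.unique(data.cluster_id))
    index = {lab: k for k, lab in enumerate(labels)}
    J = len(labels)
    N, p = data.values.shape
    n_j = np.zeros(J, dtype=int)
    sums = np.zeros((J, p))
    for lab, row in zip(data.cluster_id, data.values):
        k = index[lab]
        n_j[k] += 1
        sums[k] += row
    if np.all(n_j < 2):
        raise ValueError(
            "all clusters have a single observation; the within covariance is undefined"
        )
    n_single = int(np.sum(n_j == 1))
    if n_single:
        _log.info("%d singleton cluster(s) retained (between weight 1, zero within weight)", n_single)

    cluster_means = sums / n_j[:, None]
    grand_mean = data.values.mean(axis=0)

    dev_b = cluster_means - grand_mean
    S_Bj = n_j[:, None, None] * np.einsum("jk,jl->jkl", dev_b, dev_b)

    S_Wj = np.zeros((J, p, p))
    for k in range(J):
        if n_j[k] >= 2:
            mask = np.asarray([index[lab] == k for lab in data.cluster_id])
            resid = data.values[mask] - cluster_means[k]
            S_Wj[k] = resid.T @ resid / (n_j[k] - 1)
    pooled_within = np.einsum("j,jkl->kl", (n_j - 1).astype(float), S_Wj) / (N - J)

    return SufficientStatistics(
        J=J,
        N=N,
        n_j=n_j,
        grand_mean=grand_mean,
        cluster_means=cluster_means,
        S_Bj=S_Bj,
        S_Wj=S_Wj,
        pooled_within=pooled_within,
        balanced=bool(np.all(n_j == n_j[0])),
        variable_names=list(data.variable_names),
        cluster_labels=labels,
    )
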