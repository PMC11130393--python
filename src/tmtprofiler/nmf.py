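"""Consensus non-negative matrix factorization subtyping with rank selection.

Samples are clustered by repeated NMF of the non-negative protein-ratio matrix
from random starts.  Each run factorizes X ~ W Hc under the generalized
Kullback-Leibler divergence with multiplicative updates; samples are assigned
to the basis component with the largest coefficient.  Co-assignment
frequencies across runs form a consensus matrix whose crispness - cophenetic
correlation of its dendrogram and the dispersion (1/n^2) sum 4 (C - 1/2)^2 -
guides the choice of the cluster number k.  Final labels come from
average-linkage hierarchical clustering of 1 - C.  Per-protein cluster
relevance follows the Kim-Park entropy score of the basis rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .preprocess import ProteinMatrix

__all__ = [
    "NmfRun",
    "ConsensusResult",
    "select_input_features",
    "nmf_factorize",
    "consensus_cluster",
    "rank_selection",
    "feature_scores",
    "dispersion",
    "cophenetic_correlation",
    "ConsensusNMF",
    "ConsensusNMFResults",
]

_EPS = np.finfo(float).eps


@dataclass
class NmfRun:
    """One stochastic NMF factorization X ~ W @ coefficients."""

    basis: np.ndarray          # proteins x k
    coefficients: np.ndarray   # k x samples
    objective: float           # generalized KL divergence
    objective_trace: np.ndarray
    iterations: int
    seed: int

    @property
    def labels(self) -> np.ndarray:
        """Per-sample hard assignment: argmax over coefficient rows."""
        return np.argmax(self.coefficients, axis=0)


@dataclass
class ConsensusResult:
    """Consensus over stochastic NMF runs at a fixed rank k."""

    k: int
    consensus: np.ndarray          # samples x samples in [0, 1]
    cophenetic: float
    dispersion: float
    labels: np.ndarray             # sample -> cluster id (0..k-1)
    best_run: NmfRun
    samples: list[str] | None = None

    def feature_scores(self, features: list[str] | None = None,
                       top_fraction: float = 0.25) -> tuple[pd.Series, list]:
        scores = feature_scores(self.best_run.basis)
        index = features if features is not None else range(len(scores))
        series = pd.Series(scores, index=index, name="cluster_relevance")
        valid = series.dropna().sort_values(ascending=False)
        n_top = max(1, int(round(top_fraction * len(valid))))
        return series, valid.index[:n_top].tolist()


def select_input_features(
    matrix: ProteinMatrix,
    sheet: pd.DataFrame | None = None,
    fraction: float = 0.25,
) -> pd.DataFrame:
    """Most-variant fraction of the invariance-ranked proteins, tumor samples only.

    Returns the complete (no missing cells) block of the normalized ratio
    matrix restricted to the worst-ranked (most variant) proteins; NMF input
    stays on the non-negative ratio scale.
    """
    from .preprocess import rank_invariance

    if matrix.invariance_rank.empty:
        rank_invariance(matrix)
    rank = matrix.invariance_rank
    n_keep = max(1, int(round(fraction * len(rank))))
    chosen = rank.nlargest(n_keep, keep="first").index
    block = matrix.ratios.loc[chosen]
    if sheet is not None:
        tumors = sheet[(sheet.tissue == "tumor")].sample_id
        cols = [s for s in block.columns if s in set(tumors)]
        block = block[cols]
    if block.isna().any().any():
        raise ValueError("selected feature block contains missing cells; NMF "
                         "requires a complete matrix")
    return block


def _init_vcol(rng: np.random.Generator, X: np.ndarray, k: int,
               n_cols: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """random_vcol initialization: basis columns are means of sampled data columns."""
    n_rows, n_samples = X.shape
    W = np.empty((n_rows, k))
    H = np.empty((k, n_samples))
    p_c = min(n_cols, n_samples)
    p_r = min(n_cols, n_rows)
    for q in range(k):
        W[:, q] = X[:, rng.choice(n_samples, size=p_c, replace=False)].mean(axis=1)
        H[q, :] = X[rng.choice(n_rows, size=p_r, replace=False), :].mean(axis=0)
    return np.maximum(W, _EPS), np.maximum(H, _EPS)


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    mask = X > 0
    div = np.sum(X[mask] * np.log(X[mask] / WH[mask])) - X.sum() + WH.sum()
    return float(div)


def nmf_factorize(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int | None = None,
    tol: float | None = None,
    track_objective: bool = False,
) -> NmfRun:
    """KL-divergence NMF by multiplicative updates with random_vcol start.

    ``max_iter`` defaults to k*100 with no early stopping (the study's
    configuration); pass ``tol`` for an optional relative-change stop.
    ``track_objective`` records the divergence after every iteration (the
    multiplicative updates guarantee a non-increasing sequence); otherwise
    only the final objective is evaluated.
    """
    X = np.asarray(X, float)
    if np.any(X < 0):
        raise ValueError("NMF input must be elementwise non-negative")
    if k >= min(X.shape):
        raise ValueError(f"rank k={k} must be smaller than min(X.shape)={min(X.shape)}")
    if max_iter is None:
        max_iter = k * 100
    rng = np.random.default_rng(seed)
    W, H = _init_vcol(rng, X, k)
    trace = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        W *= (X / WH) @ H.T
        W /= np.maximum(H.sum(axis=1), _EPS)
        np.maximum(W, _EPS, out=W)
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        H *= W.T @ (X / WH)
        H /= np.maximum(W.sum(axis=0), _EPS)[:, None]
        np.maximum(H, _EPS, out=H)
        if track_objective or tol is not None:
            obj = _kl_divergence(X, np.maximum(W @ H, _EPS))
            trace.append(obj)
            if tol is not None and prev < np.inf and abs(prev - obj) <= tol * max(prev, _EPS):
                break
            prev = obj
    final = trace[-1] if trace else _kl_divergence(X, np.maximum(W @ H, _EPS))
    return NmfRun(basis=W, coefficients=H, objective=final,
                  objective_trace=np.asarray(trace), iterations=it, seed=seed)


def dispersion(C: np.ndarray) -> float:
    """Consensus crispness: (1/n^2) sum_ij 4*(C_ij - 1/2)^2; 1 iff C is binary."""
    n = C.shape[0]
    return float(np.sum(4.0 * (C - 0.5) ** 2) / (n * n))


def cophenetic_correlation(C: np.ndarray) -> tuple[float, np.ndarray]:
    """Cophenetic correlation of 1-C against its average-linkage dendrogram."""
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    condensed = squareform(D, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    if np.allclose(condensed, condensed[0] if len(condensed) else 0.0):
        # degenerate (e.g. perfect consensus): cophenetic corr of a constant
        # distance vector is undefined; perfect agreement by convention
        return 1.0, linkage
    coph, _ = hierarchy.cophenet(linkage, condensed)
    return float(coph), linkage


def consensus_cluster(
    X: np.ndarray,
    k: int,
    n_run: int = 100,
    seed: int = 0,
    max_iter: int | None = None,
    samples: list[str] | None = None,
) -> ConsensusResult:
    """Consensus matrix, rank metrics and labels from n_run stochastic NMF runs."""
    if n_run < 2:
        raise ValueError("consensus requires n_run >= 2")
    n_samples = X.shape[1]
    seeds = np.random.SeedSequence(seed).generate_state(n_run) % (2**31)
    C = np.zeros((n_samples, n_samples))
    best: NmfRun | None = None
    for s in seeds:
        run = nmf_factorize(X, k, seed=int(s), max_iter=max_iter)
        lab = run.labels
        C += (lab[:, None] == lab[None, :]).astype(float)
        if best is None or run.objective < best.objective:
            best = run
    C /= n_run
    disp = dispersion(C)
    coph, linkage = cophenetic_correlation(C)
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust") - 1
    return ConsensusResult(k=k, consensus=C, cophenetic=coph, dispersion=disp,
                           labels=labels, best_run=best, samples=samples)


def rank_selection(
    X: np.ndarray,
    k_range=range(2, 11),
    n_run: int = 100,
    seed: int = 0,
    max_iter: int | None = None,
    samples: list[str] | None = None,
) -> dict[int, ConsensusResult]:
    """Consensus results for every rank in ``k_range`` (metrics table via summary)."""
    return {
        k: consensus_cluster(X, k, n_run=n_run, seed=seed + k, max_iter=max_iter,
                             samples=samples)
        for k in k_range
    }


def feature_scores(W: np.ndarray) -> np.ndarray:
    """Kim-Park cluster-relevance score per basis row.

    With row-normalized loadings q_iq = W_iq / sum_q W_iq the score is
    1 + (1/log2 k) * sum_q q_iq log2 q_iq: 1 for a row loading on a single
    component, 0 for uniform loading.  All-zero rows yield NaN.
    """
    W = np.asarray(W, float)
    k = W.shape[1]
    if k < 2:
        raise ValueError("feature scores need k >= 2")
    row_sum = W.sum(axis=1)
    scores = np.full(W.shape[0], np.nan)
    ok = row_sum > 0
    q = W[ok] / row_sum[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(q > 0, q * np.log2(q), 0.0).sum(axis=1)
    scores[ok] = 1.0 + ent / np.log2(k)
    return scores


class ConsensusNMF:
    """Consensus-NMF subtyping model over a non-negative feature block.

    Build it from a preprocessed :class:`ProteinMatrix` (most-variant feature
    selection included) or any complete non-negative DataFrame, then ``fit``
    over a rank range.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        k_range=range(2, 11),
        n_run: int = 100,
        max_iter: int | None = None,
    ):
        if X.isna().any().any():
            raise ValueError("NMF input must be complete")
        self.X = X
        self.k_range = list(k_range)
        self.n_run = n_run
        self.max_iter = max_iter

    @classmethod
    def from_matrix(
        cls,
        matrix: ProteinMatrix,
        sheet: pd.DataFrame | None = None,
        fraction: float = 0.25,
        **kwargs,
    ) -> "ConsensusNMF":
        return cls(select_input_features(matrix, sheet, fraction), **kwargs)

    def fit(self, seed: int = 0) -> "ConsensusNMFResults":
        results = rank_selection(
            self.X.to_numpy(float), self.k_range, n_run=self.n_run, seed=seed,
            max_iter=self.max_iter, samples=list(self.X.columns),
        )
        return ConsensusNMFResults(self, results)


class ConsensusNMFResults:
    """Per-rank consensus results with a rank-selection summary table."""

    def __init__(self, model: ConsensusNMF, by_rank: dict[int, ConsensusResult]):
        self.model = model
        self.by_rank = by_rank

    def summary(self) -> pd.DataFrame:
        rows = [
            (k, r.cophenetic, r.dispersion)
            for k, r in sorted(self.by_rank.items())
        ]
        return pd.DataFrame(rows, columns=["k", "cophenetic", "dispersion"]).set_index("k")

    def labels(self, k: int) -> pd.Series:
        r = self.by_rank[k]
        return pd.Series(r.labels, index=self.model.X.columns, name=f"cluster_k{k}")

    def consensus(self, k: int) -> pd.DataFrame:
        r = self.by_rank[k]
        return pd.DataFrame(r.consensus, index=self.model.X.columns,
                            columns=self.model.X.columns)

    def feature_scores(self, k: int, top_fraction: float = 0.25) -> tuple[pd.Series, list]:
        return self.by_rank[k].feature_scores(list(self.model.X.index), top_fraction)

    def best_k(self, metric: str = "dispersion") -> int:
        table = self.summary()
        return int(table[metric].idxmax())
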