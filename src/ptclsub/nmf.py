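"""NMF consensus clustering with cophenetic rank selection.

The subtyping core: repeated Kullback-Leibler (Brunet-style) nonnegative
matrix factorizations of the binary driver matrix, a consensus matrix of
co-assignment frequencies per candidate rank, cophenetic-coefficient rank
selection, and subtype assignment by cutting the average-linkage tree of the
selected consensus matrix.

The model/results pair :class:`ConsensusNMF` / :class:`ConsensusNMFResults`
wraps the functional layer (:func:`brunet_nmf`, :func:`connectivity`,
:func:`consensus_cluster`, :func:`cophenetic_coefficient`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import rel_entr

from .features import DriverMatrix

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass
class NMFFactorization:
    """One multiplicative-update factorization V ~ W @ H."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    seed: int
    converged: bool


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # D(V || WH) = sum V log(V/WH) - V + WH
    return float(rel_entr(V, WH).sum() - V.sum() + WH.sum())


def brunet_nmf(V, rank: int, seed: int = 0, max_iter: int = 2000,
               tol: float = 1e-6) -> NMFFactorization:
    """KL-divergence NMF by multiplicative updates.

    W and H are initialized uniform-random in (0, 1) per ``seed`` — the
    run-to-run variability this creates is what the consensus machinery
    measures.  Entries are floored at machine epsilon.  Iteration stops when
    the relative objective change drops below ``tol`` or after ``max_iter``
    updates.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    zero_cols = np.flatnonzero(V.sum(axis=0) == 0)
    if zero_cols.size:
        raise ValueError(
            f"all-zero columns at positions {zero_cols.tolist()}: remove "
            "these cases upstream (cluster-0 handling) before factorizing")
    m, n = V.shape
    if not 1 <= rank < min(m, n):
        raise ValueError(f"rank must satisfy 1 <= rank < min{V.shape}")

    rng = np.random.default_rng(seed)
    W = np.maximum(rng.uniform(size=(m, rank)), _EPS)
    H = np.maximum(rng.uniform(size=(rank, n)), _EPS)

    trace: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        H = np.maximum(H, _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        W = np.maximum(W, _EPS)
        WH = np.maximum(W @ H, _EPS)
        obj = _kl_divergence(V, WH)
        trace.append(obj)
        if np.isfinite(prev) and abs(prev - obj) <= tol * max(abs(prev), _EPS):
            converged = True
            break
        prev = obj
    return NMFFactorization(W=W, H=H, objective_trace=trace, seed=seed,
                            converged=converged)


def connectivity(H) -> np.ndarray:
    """Binary co-assignment matrix from a factor matrix.

    Each case goes to the argmax component of its H column (ties break to
    the lowest component index); entry (i, j) is 1 iff cases i and j share a
    component.
    """
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be nonnegative")
    labels = H.argmax(axis=0)
    return (labels[:, None] == labels[None, :]).astype(float)


def cophenetic_coefficient(consensus) -> float:
    """Cophenetic correlation of a consensus matrix (Brunet convention).

    Pearson correlation between the off-diagonal distances D = 1 - consensus
    and the cophenetic distances induced by average-linkage hierarchical
    clustering of D.  A constant D (perfectly stable clustering) returns 1.0
    by convention, with a warning.
    """
    C = np.asarray(consensus, dtype=float)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    coph = cophenet(Z)
    if condensed.std() == 0 or coph.std() == 0:
        warnings.warn("constant consensus distances; cophenetic coefficient "
                      "set to 1.0 by convention", stacklevel=2)
        return 1.0
    return float(np.corrcoef(condensed, coph)[0, 1])


def _cut_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def _label_by_size(raw: np.ndarray) -> np.ndarray:
    """Map raw cluster ids to C1..Ck by descending cluster size.

    Size ties break by first occurrence, keeping labels deterministic.
    """
    ids, first_pos = np.unique(raw, return_index=True)
    sizes = {i: int((raw == i).sum()) for i in ids}
    order = sorted(ids, key=lambda i: (-sizes[i], first_pos[list(ids).index(i)]))
    mapping = {i: f"C{r + 1}" for r, i in enumerate(order)}
    return np.array([mapping[i] for i in raw], dtype=object)


@dataclass
class ConsensusResult:
    """Per-rank consensus matrices, cophenetic coefficients and assignments."""

    per_rank: dict[int, dict]
    selected_rank: int
    assignments: pd.Series  # case_id -> subtype label
    n_runs: int
    seed: int

    @property
    def cophenetic(self) -> dict[int, float]:
        return {r: info["cophenetic"] for r, info in self.per_rank.items()}


def consensus_cluster(V, ranks=range(2, 9), n_runs: int = 30, seed: int = 0,
                      case_ids=None, max_iter: int = 2000,
                      tol: float = 1e-6) -> ConsensusResult:
    """Consensus clustering over candidate ranks.

    Per rank, ``n_runs`` factorizations (run seeds ``seed+1 .. seed+n_runs``)
    are averaged into a consensus matrix; the rank maximizing the cophenetic
    coefficient is selected (ties to the smallest rank) and case assignments
    come from cutting the average-linkage tree of 1 - consensus into that
    many groups, labelled C1..Ck by descending group size.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    if case_ids is None:
        case_ids = [f"case{i}" for i in range(n)]
    ranks = sorted(set(int(r) for r in ranks))

    per_rank: dict[int, dict] = {}
    for r in ranks:
        consensus = np.zeros((n, n))
        for run in range(1, n_runs + 1):
            fac = brunet_nmf(V, rank=r, seed=seed + run, max_iter=max_iter,
                             tol=tol)
            consensus += connectivity(fac.H)
        consensus /= n_runs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coph = cophenetic_coefficient(consensus)
        per_rank[r] = {"consensus": consensus, "cophenetic": coph}

    selected = ranks[0]
    for r in ranks[1:]:
        if per_rank[r]["cophenetic"] > per_rank[selected]["cophenetic"]:
            selected = r

    raw = _cut_consensus(per_rank[selected]["consensus"], selected)
    labels = _label_by_size(raw)
    assignments = pd.Series(labels, index=pd.Index(case_ids, name="case_id"),
                            name="subtype")
    return ConsensusResult(per_rank=per_rank, selected_rank=selected,
                           assignments=assignments, n_runs=n_runs, seed=seed)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------
class ConsensusNMF:
    """Consensus-NMF subtyping model over a binary driver matrix.

    Parameters
    ----------
    matrix : DriverMatrix, DataFrame (features x cases) or ndarray
    ranks : candidate cluster numbers searched (default 2..8)
    n_runs : factorization restarts per rank (default 30)
    seed : master seed; run r uses seed+r
    """

    def __init__(self, matrix, ranks=range(2, 9), n_runs: int = 30,
                 seed: int = 0, max_iter: int = 2000, tol: float = 1e-6):
        if isinstance(matrix, DriverMatrix):
            self.values = matrix.values
            self.excluded_cases = list(matrix.excluded_cases)
        elif isinstance(matrix, pd.DataFrame):
            self.values = matrix
            self.excluded_cases = []
        else:
            arr = np.asarray(matrix, dtype=float)
            self.values = pd.DataFrame(arr)
            self.excluded_cases = []
        self.ranks = list(ranks)
        self.n_runs = n_runs
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> "ConsensusNMFResults":
        res = consensus_cluster(
            self.values.to_numpy(dtype=float), ranks=self.ranks,
            n_runs=self.n_runs, seed=self.seed,
            case_ids=list(self.values.columns),
            max_iter=self.max_iter, tol=self.tol)
        return ConsensusNMFResults(model=self, result=res)


@dataclass
class ConsensusNMFResults:
    """Fitted consensus-NMF subtyping results."""

    model: ConsensusNMF
    result: ConsensusResult
    _assignments: pd.Series | None = field(default=None, repr=False)

    @property
    def selected_rank(self) -> int:
        return self.result.selected_rank

    @property
    def cophenetic(self) -> dict[int, float]:
        return self.result.cophenetic

    @property
    def assignments(self) -> pd.Series:
        """Subtype per case; cases excluded upstream are labelled C0."""
        if self._assignments is None:
            extra = pd.Series("C0", index=pd.Index(self.model.excluded_cases,
                                                   name="case_id"),
                              name="subtype")
            self._assignments = pd.concat([self.result.assignments, extra])
        return self._assignments

    def consensus(self, rank: int | None = None) -> pd.DataFrame:
        rank = self.selected_rank if rank is None else rank
        cases = list(self.model.values.columns)
        return pd.DataFrame(self.result.per_rank[rank]["consensus"],
                            index=cases, columns=cases)

    def summary(self) -> pd.DataFrame:
        """Rank-selection table: candidate rank, cophenetic coefficient."""
        rows = [{"rank": r, "cophenetic": c, "selected": r == self.selected_rank}
                for r, c in sorted(self.cophenetic.items())]
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        counts = self.assignments.value_counts().sort_index()
        lines = ["Consensus NMF subtyping",
                 f"  selected rank: {self.selected_rank} "
                 f"(runs per rank: {self.result.n_runs})",
                 "  cluster sizes: " + ", ".join(
                     f"{k}={v}" for k, v in counts.items())]
        return "\n".join(lines)
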