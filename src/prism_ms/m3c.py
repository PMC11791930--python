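"""Monte Carlo reference-based consensus clustering.

Decides, per feature (or feature set), whether a cell population splits
into subpopulations — and into how many — by comparing the stability of
consensus clustering on the real data against its stability on simulated
reference data with no subpopulation structure.

For each candidate number of clusters k in 2..max_k:

* **consensus**: the data are repeatedly subsampled (default 80% of
  objects), hierarchically clustered, and cut at k; entry (i, j) of the
  consensus matrix is the fraction of co-sampled iterations in which
  objects i and j landed in the same cluster.
* **PAC** (proportion of ambiguous clustering): the fraction of
  off-diagonal consensus entries strictly inside a window (default
  (0.1, 0.9)).  PAC 0 means perfectly stable clustering.
* **reference null**: datasets of the same shape are drawn from a
  multivariate normal with the data's mean and covariance estimated in
  principal-component space (a plain fitted normal in the univariate
  case); each reference dataset yields one reference PAC.  A
  permutation null (independent column shuffles) is available as an
  alternative.
* **RCSI** = ln(mean reference PAC / real PAC) — how much more stable
  the real clustering is than chance; **empirical p-value** =
  (1 + #{reference PAC <= real PAC}) / (n_reference + 1), add-one
  corrected so p is never zero.

The selected k is the one with the highest RCSI among k with p below
the significance threshold (default 0.01); if no k qualifies the
feature is declared homogeneous (no subclustering).

The module follows the statsmodels model/results idiom:
``M3C(values, config).fit()`` returns an :class:`M3CResult` carrying all
per-k diagnostics, the selected k, object assignments and a
``summary()`` table.  ``run_m3c`` is the functional shorthand.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from ._errors import WorkflowError

log = logging.getLogger(__name__)

HOMOGENEOUS = "homogeneous"


@dataclass(frozen=True)
class M3CConfig:
    """Tuning parameters of the consensus-clustering procedure.

    Defaults mirror the study conditions: maxK 8, 200 real and 200
    reference iterations, seed 42, significance threshold 0.01.  The
    resample fraction (0.8) and the PAC window (0.1, 0.9) are standard
    consensus-clustering practice.  ``repeats`` > 1 runs the whole
    procedure that many times and requires a majority vote on the
    selected k.
    """

    max_k: int = 8
    real_iterations: int = 200
    reference_iterations: int = 200
    resample_fraction: float = 0.8
    linkage: str = "complete"
    seed: int = 42
    p_threshold: float = 0.01
    pac_window: tuple = (0.1, 0.9)
    reference_method: str = "pca_normal"  # or "permute"
    pac_floor: float = 1e-6
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.max_k < 2:
            raise WorkflowError("max_k must be >= 2")
        if min(self.real_iterations, self.reference_iterations) < 10:
            raise WorkflowError("iterations must be >= 10")
        if not (0 < self.resample_fraction <= 1):
            raise WorkflowError("resample_fraction must be in (0, 1]")
        if self.reference_method not in ("pca_normal", "permute"):
            raise WorkflowError(f"unknown reference method {self.reference_method!r}")


def _as_matrix(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.ndim != 2:
        raise WorkflowError("values must be a 1-D or 2-D array")
    return v


def _labels_all_k(z: np.ndarray, n: int, ks) -> dict:
    """Partitions at every requested k from one linkage matrix.

    Replays the merge sequence once with a union-find, snapshotting the
    partition each time the cluster count reaches a requested k —
    equivalent (in co-membership) to cutting the dendrogram at each k,
    without per-k tree validation.
    """
    parent = np.arange(2 * n - 1)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    want = sorted((k for k in ks if k < n), reverse=True)
    out = {k: np.arange(n) for k in ks if k >= n}  # singletons when k >= n
    wi = 0
    count = n
    for step, (a, b) in enumerate(z[:, :2].astype(int)):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
        count -= 1
        if wi < len(want) and count == want[wi]:
            roots = np.array([find(j) for j in range(n)])
            out[want[wi]] = np.unique(roots, return_inverse=True)[1]
            wi += 1
    return out


def _cluster_labels(values: np.ndarray, ks, method: str) -> dict:
    """Hierarchical clustering cut at each k (one linkage per call)."""
    if len(values) < 2:
        raise WorkflowError("need at least 2 objects to cluster")
    z = scipy_linkage(values, method=method)
    return _labels_all_k(z, len(values), ks)


def _consensus_counts(values: np.ndarray, ks, iterations: int,
                      resample_fraction: float, method: str, rng):
    """Co-cluster counts per k and the (k-independent) co-sample counts.

    One dendrogram per subsample is shared across all k (cutting a tree
    is cheap, building it is not), and the pairwise counts are formed as
    sparse incidence products: with A the objects × (iteration, cluster)
    membership matrix, the co-cluster count matrix is A·Aᵀ; likewise the
    co-sample counts from the objects × iteration sampling incidence.
    """
    from scipy import sparse

    n = len(values)
    m = max(2, int(round(resample_fraction * n)))
    idx_per_iter = []
    labels_per_k: dict = {k: [] for k in ks}
    for _ in range(iterations):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        idx_per_iter.append(idx)
        for k, labels in _cluster_labels(values[idx], ks, method).items():
            labels_per_k[k].append(labels)

    rows = np.concatenate(idx_per_iter)
    ones = np.ones(len(rows), dtype=np.float64)
    iter_cols = np.repeat(np.arange(iterations), [len(i) for i in idx_per_iter])
    b = sparse.csr_matrix((ones, (rows, iter_cols)), shape=(n, iterations))
    sampled = np.asarray((b @ b.T).todense())

    together = {}
    for k in ks:
        offsets = np.arange(iterations) * (k + 1)
        cols = np.concatenate(
            [lab + off for lab, off in zip(labels_per_k[k], offsets)]
        )
        a = sparse.csr_matrix((ones, (rows, cols)), shape=(n, iterations * (k + 1)))
        together[k] = np.asarray((a @ a.T).todense())
    return together, sampled


def _consensus_from_counts(together: np.ndarray, sampled: np.ndarray) -> np.ndarray:
    never = sampled == 0
    n_never = int(never[np.triu_indices_from(never, k=1)].sum())
    if n_never:
        log.warning("consensus: %d object pair(s) never co-sampled, set to 0", n_never)
    consensus = np.divide(together, sampled, out=np.zeros_like(together), where=~never)
    np.fill_diagonal(consensus, 1.0)
    return consensus


def consensus_cluster(values, k: int, iterations: int = 100,
                      resample_fraction: float = 0.8, linkage: str = "complete",
                      rng=None) -> np.ndarray:
    """Consensus matrix for a single k.

    Entry (i, j) is the number of iterations in which i and j
    co-clustered divided by the number in which both were sampled; pairs
    never co-sampled are 0 (logged).  Symmetric with unit diagonal.
    """
    values = _as_matrix(values)
    if k > len(values):
        raise WorkflowError(f"k={k} exceeds the number of objects ({len(values)})")
    rng = np.random.default_rng(rng)
    together, sampled = _consensus_counts(values, [k], iterations,
                                          resample_fraction, linkage, rng)
    return _consensus_from_counts(together[k], sampled)


def pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal
    consensus entries strictly inside (lower, upper)."""
    consensus = np.asarray(consensus, dtype=float)
    if consensus.shape[0] < 2:
        raise WorkflowError("PAC needs a consensus matrix of at least 2 objects")
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def simulate_reference(values, rng=None, method: str = "pca_normal") -> np.ndarray:
    """Draw a same-shape dataset from a null with no subpopulation
    structure that preserves the feature covariance scale.

    ``pca_normal``: multivariate normal with the data's mean vector and
    covariance, sampled in principal-component space (univariate case: a
    normal with the sample mean and sd).  A singular covariance falls
    back to its diagonal with a logged warning.  ``permute`` shuffles
    each column independently instead.
    """
    values = _as_matrix(values)
    n, p = values.shape
    if n < 3:
        raise WorkflowError("need at least 3 objects to simulate a reference")
    rng = np.random.default_rng(rng)
    if method == "permute":
        return np.column_stack([rng.permutation(values[:, j]) for j in range(p)])
    mean = values.mean(axis=0)
    if p == 1:
        sd = values.std(axis=0, ddof=1)
        return (mean + sd * rng.standard_normal((n, 1))).reshape(n, 1)
    cov = np.cov(values, rowvar=False)
    # eigendecomposition = sampling in principal-component space
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) < -1e-10 * max(np.max(evals), 1.0):
        log.warning("simulate_reference: singular covariance, falling back to diagonal")
        cov = np.diag(np.diag(cov))
        evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    z = rng.standard_normal((n, p))
    return mean + z * np.sqrt(evals) @ evecs.T


@dataclass
class KDiagnostics:
    """Everything computed for one candidate k."""

    k: int
    consensus: np.ndarray = field(repr=False)
    pac_real: float
    pac_reference: np.ndarray = field(repr=False)
    rcsi: float
    p_value: float


@dataclass
class M3CResult:
    """Fitted consensus-clustering result.

    ``selected_k`` is an int, or the string "homogeneous" when no k
    reached significance.  ``assignments`` (cluster label per object,
    1..k) is present only when ``selected_k`` >= 2.
    """

    per_k: dict
    selected_k: object
    assignments: np.ndarray | None
    config: M3CConfig
    n_objects: int
    repeat_votes: list | None = None

    @property
    def is_homogeneous(self) -> bool:
        return self.selected_k == HOMOGENEOUS

    def summary(self) -> pd.DataFrame:
        """Per-k diagnostics table (PAC real/reference, RCSI, p)."""
        rows = [
            {
                "k": d.k,
                "pac_real": d.pac_real,
                "pac_reference_mean": float(np.mean(d.pac_reference)),
                "rcsi": d.rcsi,
                "p_value": d.p_value,
                "significant": d.p_value < self.config.p_threshold,
                "selected": d.k == self.selected_k,
            }
            for d in self.per_k.values()
        ]
        return pd.DataFrame(rows).set_index("k")

    def to_dict(self) -> dict:
        return {
            "selected_k": self.selected_k,
            "n_objects": self.n_objects,
            "p_threshold": self.config.p_threshold,
            "assignments": None if self.assignments is None else self.assignments.tolist(),
            "per_k": {
                str(d.k): {
                    "pac_real": d.pac_real,
                    "pac_reference_mean": float(np.mean(d.pac_reference)),
                    "rcsi": d.rcsi,
                    "p_value": d.p_value,
                }
                for d in self.per_k.values()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class M3C:
    """Monte Carlo reference-based consensus clustering model.

    Parameters
    ----------
    values : array-like, (n_objects,) or (n_objects, n_features)
        Object-level feature values (typically standardized cell mean
        intensities of one marker m/z).
    config : M3CConfig, optional

    Randomness is fully determined by ``config.seed``; the seed is
    applied after a canonical (lexicographic) ordering of objects, so
    the selected k does not depend on input order.
    """

    def __init__(self, values, config: M3CConfig | None = None) -> None:
        self.values = _as_matrix(values)
        self.config = config or M3CConfig()
        if len(self.values) < self.config.max_k + 1:
            raise WorkflowError(
                f"need at least max_k+1={self.config.max_k + 1} objects, "
                f"got {len(self.values)}"
            )

    def fit(self) -> M3CResult:
        cfg = self.config
        order = np.lexsort(self.values.T[::-1])  # canonical object order
        canonical = self.values[order]
        if cfg.repeats == 1:
            result = self._fit_once(canonical, cfg.seed)
        else:
            votes = []
            results = []
            for r in range(cfg.repeats):
                res = self._fit_once(canonical, cfg.seed + r)
                votes.append(res.selected_k)
                results.append(res)
            winner, n_votes = Counter(votes).most_common(1)[0]
            log.info("M3C repeats: votes=%s -> selected %s (%d/%d)",
                     votes, winner, n_votes, cfg.repeats)
            result = next(r for r in results if r.selected_k == winner)
            result = replace(result, repeat_votes=votes)
        # map assignments back to the caller's object order
        if result.assignments is not None:
            undo = np.empty_like(order)
            undo[order] = np.arange(len(order))
            result = replace(result, assignments=result.assignments[undo])
        return result

    # -- internals ---------------------------------------------------------

    def _fit_once(self, values: np.ndarray, seed: int) -> M3CResult:
        cfg = self.config
        rng = np.random.default_rng(seed)
        ks = list(range(2, cfg.max_k + 1))
        lower, upper = cfg.pac_window

        real_tog, real_sam = _consensus_counts(
            values, ks, cfg.real_iterations, cfg.resample_fraction, cfg.linkage, rng
        )
        consensus = {k: _consensus_from_counts(real_tog[k], real_sam) for k in ks}
        pac_real = {k: pac_score(consensus[k], lower, upper) for k in ks}

        pac_ref = {k: np.empty(cfg.reference_iterations) for k in ks}
        for b in range(cfg.reference_iterations):
            ref = simulate_reference(values, rng, cfg.reference_method)
            ref_tog, ref_sam = _consensus_counts(
                ref, ks, cfg.real_iterations, cfg.resample_fraction, cfg.linkage, rng
            )
            for k in ks:
                pac_ref[k][b] = pac_score(_consensus_from_counts(ref_tog[k], ref_sam),
                                          lower, upper)

        per_k = {}
        for k in ks:
            real = max(pac_real[k], cfg.pac_floor)
            ref_mean = max(float(np.mean(pac_ref[k])), cfg.pac_floor)
            rcsi = float(np.log(ref_mean / real))
            p = (1.0 + float(np.sum(pac_ref[k] <= pac_real[k]))) / (
                cfg.reference_iterations + 1.0
            )
            per_k[k] = KDiagnostics(k, consensus[k], pac_real[k], pac_ref[k], rcsi, p)

        significant = [k for k in ks if per_k[k].p_value < cfg.p_threshold]
        if significant:
            selected = max(significant, key=lambda k: (per_k[k].rcsi, -k))
            assignments = self._assign(consensus[selected], selected, cfg.linkage)
        else:
            selected, assignments = HOMOGENEOUS, None
        return M3CResult(per_k, selected, assignments, cfg, len(values))

    @staticmethod
    def _assign(consensus: np.ndarray, k: int, method: str) -> np.ndarray:
        """Final object assignments: hierarchical clustering of the
        consensus dissimilarity (1 - consensus) cut at the selected k."""
        dist = squareform(1.0 - consensus, checks=False)
        z = scipy_linkage(dist, method=method)
        return fcluster(z, t=k, criterion="maxclust")


def run_m3c(values, config: M3CConfig | None = None) -> M3CResult:
    """Functional shorthand for ``M3C(values, config).fit()``."""
    return M3C(values, config).fit()


# ---------------------------------------------------------------------------
# Marker-axis labeling and population statistics


@dataclass
class SubpopulationLabels:
    """Per-cell labels over binary marker axes.

    Each axis (e.g. "Ita", "Taur") is "+" or "-"; the label is the
    cross-product, e.g. "Ita+Taur-".  Cells negative on every axis are
    flagged ``omitted`` and excluded from population statistics.
    """

    axes: list
    positive: dict  # axis -> bool array
    labels: list
    omitted: np.ndarray


def assign_subpopulations(marker_values: dict, marker_results: dict) -> SubpopulationLabels:
    """Label cells as +/- per marker from the fitted clustering results.

    For a marker with selected k=2, the cluster with the higher mean
    marker value is "+"; a homogeneous marker labels every cell "-".
    Markers with selected k > 2 are refused: the labeling is defined
    only for binary axes.
    """
    axes = list(marker_results)
    if not axes:
        raise WorkflowError("need at least one marker result")
    n = len(np.asarray(marker_values[axes[0]]))
    positive = {}
    for axis in axes:
        res = marker_results[axis]
        vals = np.asarray(marker_values[axis], dtype=float)
        if len(vals) != n:
            raise WorkflowError("marker value vectors must have equal length")
        if res.is_homogeneous:
            positive[axis] = np.zeros(n, dtype=bool)
            continue
        if res.selected_k != 2:
            raise WorkflowError(
                f"marker {axis!r} selected k={res.selected_k}; labeling is "
                "defined only for binary (k=2) axes"
            )
        labels = res.assignments
        means = {lab: vals[labels == lab].mean() for lab in np.unique(labels)}
        pos_label = max(means, key=means.get)
        positive[axis] = labels == pos_label
    labels = [
        "".join(f"{axis}{'+' if positive[axis][i] else '-'}" for axis in axes)
        for i in range(n)
    ]
    omitted = ~np.logical_or.reduce([positive[a] for a in axes])
    return SubpopulationLabels(axes, positive, labels, omitted)


def population_statistics(labels: SubpopulationLabels, groups) -> pd.DataFrame:
    """Per-condition label fractions over non-omitted cells.

    Rows are conditions, columns label classes; each row sums to 1.
    Conditions with no labeled (non-omitted) cell are dropped with a
    warning.
    """
    groups = np.asarray(groups)
    if len(groups) != len(labels.labels):
        raise WorkflowError("groups must align with the labeled cells")
    frame = pd.DataFrame({"label": labels.labels, "group": groups,
                          "omitted": labels.omitted})
    kept = frame[~frame["omitted"]]
    empty = set(np.unique(groups)) - set(kept["group"].unique())
    if empty:
        log.warning("population_statistics: condition(s) with no labeled cells: %s",
                    sorted(empty))
    if kept.empty:
        return pd.DataFrame()
    counts = kept.groupby(["group", "label"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
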