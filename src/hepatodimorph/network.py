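"""Weighted gene co-expression network construction and module detection.

The pipeline is: Pearson correlation -> soft-threshold adjacency
``a_ij = |cor(x_i, x_j)| ** beta`` -> scale-free topology fit to pick beta ->
topological overlap matrix (TOM) -> average-linkage (UPGMA) clustering of the
dissimilarity ``1 - TOM`` -> static height cut into colour-labelled modules,
with "grey" reserved for unassigned genes.

The TOM used is the standard weighted-network generalisation

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj  (u != i, j),   omega_ii = 1

which is bounded in [0, 1] whenever the adjacency is. Connectivity ``k_i``
is the row sum of the adjacency (self-adjacency excluded: the diagonal is
kept at zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """A matrix argument violates the documented domain (symmetry, range)."""


class FitError(RuntimeError):
    """The scale-free regression cannot be computed (too few occupied bins)."""


#: module colour labels, assigned to modules in decreasing size order
MODULE_PALETTE = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
)
GREY = "grey"


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise DomainError("correlation matrix shape does not match gene_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise DomainError("correlation matrix not symmetric")


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    beta: float
    values: np.ndarray


@dataclass
class TOMMatrix:
    gene_ids: list[str]
    values: np.ndarray


@dataclass
class ScaleFreeFit:
    """OLS fit of log10 p(k) on log10 k over occupied connectivity bins."""

    beta: float
    r_squared: float
    slope: float
    signed_index: float
    bins_used: int


@dataclass
class Dendrogram:
    """Average-linkage merge sequence in SciPy linkage-matrix convention.

    Row i merges clusters ``Z[i, 0]`` and ``Z[i, 1]`` (ids < n are leaves,
    id n + i is the cluster created at step i) at height ``Z[i, 2]``.
    """

    gene_ids: list[str]
    merges: np.ndarray  # (n-1, 4) linkage matrix

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise DomainError("merge heights must be non-decreasing")


@dataclass
class ModuleAssignment:
    """gene_id -> colour label; GREY marks unassigned genes."""

    labels: dict[str, str]
    cut_height: float | None = None
    min_size: int | None = None

    def modules(self) -> dict[str, list[str]]:
        """Non-grey module -> member gene ids (input order preserved)."""
        out: dict[str, list[str]] = {}
        for g, c in self.labels.items():
            if c != GREY:
                out.setdefault(c, []).append(g)
        return out


def pearson_correlation(matrix) -> CorrelationMatrix:
    """All-pairs Pearson correlation across samples (rows = genes)."""
    x = matrix.values
    if x.shape[1] < 3:
        raise DomainError("need at least 3 samples for pairwise correlation")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(matrix.gene_ids, sd) if s == 0]
        raise DomainError(f"zero-variance gene(s): {bad[:5]} — filter before correlating")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(matrix.gene_ids), r)


def soft_adjacency(cor: CorrelationMatrix, beta: float) -> AdjacencyMatrix:
    """Soft-threshold adjacency |r|**beta with a zero diagonal."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    a = np.abs(cor.values) ** beta
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(list(cor.gene_ids), float(beta), a)


def connectivity(adj: AdjacencyMatrix) -> np.ndarray:
    """Per-gene connectivity k_i = sum_j a_ij (diagonal is zero)."""
    return adj.values.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10, beta: float = float("nan")) -> ScaleFreeFit:
    """Fit index of the log-log degree-density regression.

    k is binned into ``n_bins`` equal-width bins spanning [min k, max k];
    p(k) is the fraction of genes per bin; empty bins are dropped; ordinary
    least squares of log10 p(k) on log10(mean k per bin). The signed index
    ``-sign(slope) * R^2`` rewards only a decreasing density.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        raise FitError("need at least 2 genes with positive connectivity")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max in the last bin
    which = np.digitize(k, edges) - 1
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / k.size))
    if len(log_k) < 2:
        raise FitError(f"only {len(log_k)} occupied bin(s); cannot regress")
    log_k = np.asarray(log_k)
    log_p = np.asarray(log_p)
    slope, intercept = np.polyfit(log_k, log_p, 1)
    fitted = slope * log_k + intercept
    ss_res = float(np.sum((log_p - fitted) ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    # treat numerically-zero slopes (flat density) as sign 0, not +-1
    sign = 0.0 if abs(slope) <= 1e-10 else math.copysign(1.0, slope)
    signed = -sign * r2
    return ScaleFreeFit(beta, float(r2), float(slope), float(signed), len(log_k))


def select_beta(
    cor: CorrelationMatrix,
    candidates=range(1, 21),
    target: float = 0.8,
    n_bins: int = 10,
) -> tuple[float, list[ScaleFreeFit]]:
    """Pick the smallest soft-threshold power reaching the target fit index.

    Returns the chosen beta and the full diagnostic table (one fit per
    candidate). If no candidate reaches the target, the argmax of the signed
    index is returned with a warning.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    fits: list[ScaleFreeFit] = []
    for beta in candidates:
        adj = soft_adjacency(cor, beta)
        try:
            fit = scale_free_fit(connectivity(adj), n_bins=n_bins, beta=float(beta))
        except FitError as exc:
            logger.warning("beta=%s: fit failed (%s)", beta, exc)
            fit = ScaleFreeFit(float(beta), float("nan"), float("nan"), -np.inf, 0)
        fits.append(fit)
    if all(not np.isfinite(f.signed_index) for f in fits):
        raise FitError("scale-free fit failed for every candidate beta")
    for fit in fits:
        if np.isfinite(fit.signed_index) and fit.signed_index >= target:
            return fit.beta, fits
    best = max(fits, key=lambda f: (f.signed_index, -f.beta))
    logger.warning(
        "no beta reached signed fit index >= %.3g; falling back to argmax "
        "beta=%g (index %.3f)",
        target,
        best.beta,
        best.signed_index,
    )
    return best.beta, fits


def tom(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap of a weighted network (unit diagonal)."""
    a = adj.values
    if np.any(a < 0) or np.any(a > 1):
        raise DomainError("adjacency values must lie in [0, 1]")
    k = a.sum(axis=1)
    # diagonal of `a` is zero, so (a @ a)_ij already excludes u in {i, j}
    l = a @ a
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (l + a) / (min_k + 1.0 - a)
    omega = np.where(np.isfinite(omega), omega, 0.0)
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 1.0)
    return TOMMatrix(list(adj.gene_ids), omega)


def average_linkage(dissim: np.ndarray, gene_ids: list[str]) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal dissimilarity."""
    d = np.asarray(dissim, dtype=float)
    n = len(gene_ids)
    if d.shape != (n, n):
        raise DomainError("dissimilarity shape does not match gene_ids")
    if not np.allclose(d, d.T, atol=1e-12, rtol=0.0):
        raise DomainError("dissimilarity must be symmetric")
    if np.any(np.diag(d) != 0):
        raise DomainError("dissimilarity diagonal must be zero")
    if np.any(d < 0):
        raise DomainError("dissimilarity must be non-negative")
    condensed = squareform((d + d.T) / 2.0, checks=False)
    merges = linkage(condensed, method="average")
    return Dendrogram(list(gene_ids), merges)


def default_cut_height(
    dendrogram: Dendrogram, method: str = "gap", height_quantile: float = 0.98
) -> float:
    """Data-driven static cut height for a merge-height profile.

    ``"gap"`` (default) cuts at the midpoint of the largest jump between
    consecutive sorted merge heights — in a network of tight modules on a
    weakly connected background the within-module merges sit well below the
    background merges and the largest jump separates the two regimes.
    ``"quantile"`` cuts at the given quantile of merge heights instead.
    """
    heights = np.sort(dendrogram.merges[:, 2])
    if method == "quantile":
        return float(np.quantile(heights, height_quantile))
    if method != "gap":
        raise ValueError(f"unknown cut method {method!r}")
    if heights.size < 2:
        return float(heights[-1])  # single merge: cut at it (one cluster)
    gaps = np.diff(heights)
    i = int(np.argmax(gaps))
    return float((heights[i] + heights[i + 1]) / 2.0)


def cut_modules(
    dendrogram: Dendrogram,
    height: float | None = None,
    min_size: int = 30,
    method: str = "gap",
    height_quantile: float = 0.98,
) -> ModuleAssignment:
    """Static height cut of the dendrogram into colour-labelled modules.

    Clusters are the groups still joined below ``height`` (default: chosen
    by :func:`default_cut_height`). Clusters smaller than ``min_size``
    become GREY; survivors take palette colours in decreasing size order
    (ties by smallest member index).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if height is None:
        height = default_cut_height(dendrogram, method, height_quantile)
    if height <= 0:
        raise ValueError("cut height must be positive")
    flat = fcluster(dendrogram.merges, t=height, criterion="distance")

    members: dict[int, list[int]] = {}
    for idx, c in enumerate(flat):
        members.setdefault(int(c), []).append(idx)
    big = [m for m in members.values() if len(m) >= min_size]
    big.sort(key=lambda m: (-len(m), m[0]))
    if len(big) > len(MODULE_PALETTE):
        logger.warning(
            "%d modules exceed the %d-colour palette; extras named module<N>",
            len(big),
            len(MODULE_PALETTE),
        )

    labels = {g: GREY for g in dendrogram.gene_ids}
    for rank, member_idx in enumerate(big):
        colour = (
            MODULE_PALETTE[rank]
            if rank < len(MODULE_PALETTE)
            else f"module{rank + 1}"
        )
        for i in member_idx:
            labels[dendrogram.gene_ids[i]] = colour
    return ModuleAssignment(labels, cut_height=height, min_size=min_size)


def module_recovery(assignment: ModuleAssignment, truth: dict[str, str]) -> float:
    """Adjusted Rand index between detected modules and planted truth.

    Grey / background genes each form one class of their partition. Both
    partitions must cover the same gene universe.
    """
    genes = sorted(assignment.labels)
    if set(genes) != set(truth):
        raise ValueError("assignment and truth cover different gene universes")
    pred = [assignment.labels[g] for g in genes]
    true = [truth[g] for g in genes]
    return float(adjusted_rand_score(true, pred))


def export_edges(
    matrix: TOMMatrix | AdjacencyMatrix, threshold: float
) -> list[tuple[str, str, float]]:
    """Undirected edge list (gene_a < gene_b by id) with weight >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    ids = matrix.gene_ids
    vals = matrix.values
    edges = []
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = vals[iu, ju] >= threshold
    for i, j in zip(iu[keep], ju[keep]):
        a, b = ids[i], ids[j]
        if b < a:
            a, b = b, a
        edges.append((a, b, float(vals[i, j])))
    edges.sort()
    return edges


@dataclass
class NetworkResult:
    """Bundle of everything the network stage computes."""

    beta: float
    fits: list[ScaleFreeFit] = field(default_factory=list)
    adjacency: AdjacencyMatrix | None = None
    tom: TOMMatrix | None = None
    dendrogram: Dendrogram | None = None
    assignment: ModuleAssignment | None = None


def build_network(
    matrix,
    beta: float | None = 6.0,
    beta_candidates=range(1, 21),
    target_fit: float = 0.8,
    n_bins: int = 10,
    cut_height: float | None = None,
    cut_method: str = "gap",
    cut_height_quantile: float = 0.98,
    min_module_size: int = 30,
    keep_matrices: bool = False,
) -> NetworkResult:
    """Run the full network stage on an expression matrix.

    With ``beta=None`` the soft-threshold power is selected by the smallest
    candidate whose signed scale-free fit index reaches ``target_fit``.
    """
    cor = pearson_correlation(matrix)
    if beta is None:
        beta, fits = select_beta(cor, beta_candidates, target=target_fit, n_bins=n_bins)
    else:
        adj0 = soft_adjacency(cor, beta)
        try:
            fits = [scale_free_fit(connectivity(adj0), n_bins=n_bins, beta=beta)]
        except FitError:
            fits = []
    adj = soft_adjacency(cor, beta)
    omega = tom(adj)
    dendro = average_linkage(1.0 - omega.values, omega.gene_ids)
    assignment = cut_modules(
        dendro,
        height=cut_height,
        min_size=min_module_size,
        method=cut_method,
        height_quantile=cut_height_quantile,
    )
    result = NetworkResult(beta=float(beta), fits=fits, dendrogram=dendro, assignment=assignment)
    if keep_matrices:
        result.adjacency = adj
        result.tom = omega
    return result
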