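"""Sex-differential expression screening on log10-ratio expression data.

Per gene: group means by sex, a pooled-variance (Student's) two-sample
t-test, and a fold change defined on the ratio scale as

    FC = 10 ** |mean_F - mean_M|

with the bias direction (which sex is higher) reported separately, so FC is
always >= 1. Genes pass the screen when P < p_max and FC > fc_min (both
strict), and survivors are ranked by fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneTable, SampleTable, split_by_sex

logger = logging.getLogger(__name__)


class ComputationError(ValueError):
    """Invalid numeric input to a statistical primitive."""


@dataclass
class DiffExprResult:
    """Per-gene screening statistics.

    ``mean_f``/``mean_m``/``t_stat`` may be None for externally supplied
    tables (e.g. a published results table) that report only P, FC and bias.
    """

    gene_id: str
    fold_change: float
    bias: str  # "F", "M" or "none"
    p_value: float
    mean_f: float | None = None
    mean_m: float | None = None
    t_stat: float | None = None
    symbol: str | None = None


def compute_fold_change(mean_f: float, mean_m: float) -> tuple[float, str]:
    """Fold change (>= 1, linear scale) and bias direction from log10 means."""
    if not (math.isfinite(mean_f) and math.isfinite(mean_m)):
        raise ComputationError(f"non-finite group mean: F={mean_f}, M={mean_m}")
    diff = mean_f - mean_m
    if diff == 0:
        return 1.0, "none"
    return 10.0 ** abs(diff), ("F" if diff > 0 else "M")


def student_t(values_f, values_m) -> tuple[float, float]:
    """Classical pooled-variance two-sample t-test, two-sided P.

    Degenerate inputs: all values equal across both groups -> (0.0, 1.0);
    zero pooled variance with unequal means -> (+-inf, 0.0), the limit of
    perfect separation.
    """
    f = np.asarray(values_f, dtype=float)
    m = np.asarray(values_m, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ComputationError("each group needs at least 2 values")
    if not (np.isfinite(f).all() and np.isfinite(m).all()):
        raise ComputationError("non-finite expression values")
    nf, nm = f.size, m.size
    df = nf + nm - 2
    mean_diff = f.mean() - m.mean()
    pooled_var = ((nf - 1) * f.var(ddof=1) + (nm - 1) * m.var(ddof=1)) / df
    if pooled_var == 0.0:
        if mean_diff == 0.0:
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means: degenerate P=0")
        return math.copysign(math.inf, mean_diff), 0.0
    t = mean_diff / math.sqrt(pooled_var * (1.0 / nf + 1.0 / nm))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def screen(
    results: list[DiffExprResult], p_max: float = 0.05, fc_min: float = 1.1
) -> list[DiffExprResult]:
    """Retain genes with P < p_max and FC > fc_min, ranked by fold change.

    Descending fold change; ties broken by ascending P, then gene_id.
    """
    if not 0.0 < p_max <= 1.0:
        raise ValueError(f"p_max must lie in (0, 1], got {p_max}")
    if fc_min < 1.0:
        raise ValueError(f"fc_min must be >= 1, got {fc_min}")
    kept = [r for r in results if r.p_value < p_max and r.fold_change > fc_min]
    kept.sort(key=lambda r: (-r.fold_change, r.p_value, r.gene_id))
    return kept


def run_screen(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    p_max: float = 0.05,
    fc_min: float = 1.1,
) -> list[DiffExprResult]:
    """Per-gene t-test + fold change over the whole matrix, then screen.

    Genes with zero variance in both groups are excluded with a warning (no
    test is defined for them). Fully vectorised; deterministic.
    """
    stats_table = gene_statistics(matrix, samples)
    results = [
        DiffExprResult(
            gene_id=row.gene_id,
            fold_change=row.fold_change,
            bias=row.bias,
            p_value=row.p_value,
            mean_f=row.mean_f,
            mean_m=row.mean_m,
            t_stat=row.t_stat,
        )
        for row in stats_table.itertuples(index=False)
    ]
    return screen(results, p_max=p_max, fc_min=fc_min)


def gene_statistics(matrix: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Unscreened per-gene statistics table (one row per testable gene)."""
    female, male = split_by_sex(matrix, samples)
    xf = matrix.values[:, female]
    xm = matrix.values[:, male]
    nf, nm = xf.shape[1], xm.shape[1]
    df = nf + nm - 2

    mean_f = xf.mean(axis=1)
    mean_m = xm.mean(axis=1)
    var_f = xf.var(axis=1, ddof=1)
    var_m = xm.var(axis=1, ddof=1)
    pooled = ((nf - 1) * var_f + (nm - 1) * var_m) / df
    diff = mean_f - mean_m

    degenerate = pooled == 0.0
    zero_flat = degenerate & (diff == 0.0)
    if degenerate.any():
        n_dropped = int(zero_flat.sum())
        if n_dropped:
            logger.warning(
                "excluding %d gene(s) with zero variance in both groups", n_dropped
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1.0 / nf + 1.0 / nm))
    t = np.where(degenerate, np.where(diff == 0.0, 0.0, np.inf * np.sign(diff)), t)
    p = np.where(
        degenerate,
        np.where(diff == 0.0, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(t), df),
    )

    fc = 10.0 ** np.abs(diff)
    bias = np.where(diff > 0, "F", np.where(diff < 0, "M", "none"))

    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean_f": mean_f,
            "mean_m": mean_m,
            "fold_change": fc,
            "bias": bias,
            "t_stat": t,
            "p_value": p,
        }
    )
    return table[~zero_flat].reset_index(drop=True)


def chromosome_breakdown(gene_ids: list[str], genes: GeneTable) -> dict[str, int]:
    """Count X / Y / autosome / unknown locations among the given genes."""
    chrom_of = dict(zip(genes.gene_ids, genes.chromosomes))
    counts = {"X": 0, "Y": 0, "autosome": 0, "unknown": 0}
    for g in gene_ids:
        c = chrom_of.get(g)
        if c is None:
            logger.warning("gene %r missing annotation; counted as unknown", g)
            counts["unknown"] += 1
        elif c in ("X", "Y"):
            counts[c] += 1
        elif c == "unknown":
            counts["unknown"] += 1
        else:
            counts["autosome"] += 1
    return counts


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """One row per gene: keep each gene's maximum-variance probe.

    Ties broken by lexicographically smallest probe id. Probes without a
    mapping are dropped with a warning.
    """
    variances = matrix.values.var(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    n_unmapped = 0
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            n_unmapped += 1
            continue
        # higher variance wins; on exact ties the smaller probe id wins
        candidate = (-variances[i], probe, i)
        if gene not in best or candidate < best[gene]:
            best[gene] = candidate
    if n_unmapped:
        logger.warning("dropped %d unmapped probe(s)", n_unmapped)
    genes_sorted = sorted(best)  # deterministic gene order
    rows = [best[g][2] for g in genes_sorted]
    return ExpressionMatrix(genes_sorted, list(matrix.sample_ids), matrix.values[rows])
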