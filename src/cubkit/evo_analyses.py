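"""Cohort-level evolutionary-force analyses.

Given per-gene composition and codon-usage metrics for a cohort of coding
sequences, this module quantifies the forces shaping codon usage:

* neutrality analysis — OLS of %GC12 on %GC3; a slope of 1 means codon usage
  is driven purely by mutational force, 100*(1-slope) is read as the percent
  relative constraint (selection).
* parity-rule-2 summary — cohort mean +/- SD of A3/(A3+T3) and G3/(G3+C3).
* mutational-force regressions — overall %N on %N3 for each nucleotide;
  100*r^2 is read as the percent contribution of mutation to that
  nucleotide's composition.
* per-codon RSCU ~ %GC3 (and %AT3) regressions, a correlation battery with
  significance stars, and the over/under-representation tally.
* correspondence analysis of the genes x 59 RSCU matrix (chi-square metric
  SVD) and hierarchical clustering of codons on correlation distance.

All composition variables are on the 0-100 percent scale throughout; missing
values are excluded pairwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .codon_metrics import classify_rscu
from .composition import ParityCoordinates, PositionalComposition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int

    @property
    def r2(self) -> float:
        return self.r * self.r


@dataclass(frozen=True)
class NeutralitySummary:
    """Neutrality-plot regression of %GC12 (y) on %GC3 (x)."""

    regression: RegressionResult

    @property
    def relative_neutrality_pct(self) -> float:
        """Percent of GC12 variation attributed to mutational force (100*slope)."""
        return 100.0 * self.regression.slope

    @property
    def relative_constraint_pct(self) -> float:
        return 100.0 - self.relative_neutrality_pct

    @property
    def mutation_selection_ratio(self) -> float:
        s = self.regression.slope
        return s / (1.0 - s) if s != 1.0 else math.inf


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        """Raw-p significance stars: * <0.05, ** <0.01, *** <0.001."""
        if math.isnan(self.p):
            return ""
        for stars, cut in (("***", 0.001), ("**", 0.01), ("*", 0.05)):
            if self.p < cut:
                return stars
        return "NS"


@dataclass(frozen=True)
class CaResult:
    """Correspondence analysis principal coordinates and inertia fractions."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertia: np.ndarray
    total_inertia: float

    @property
    def inertia_fraction(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.inertia)
        return self.inertia / self.total_inertia


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=int(len(x)),
    )


def neutrality_analysis(
    cohort: Sequence[PositionalComposition],
) -> NeutralitySummary:
    gc3 = np.array([c.gc3 for c in cohort], dtype=float)
    gc12 = np.array([c.gc12 for c in cohort], dtype=float)
    return NeutralitySummary(regression=_ols(gc3, gc12))


def parity_summary(
    cohort: Sequence[ParityCoordinates],
) -> dict[str, tuple[float, float]]:
    """Mean and sample SD of each parity axis, NaN coordinates excluded."""
    out: dict[str, tuple[float, float]] = {}
    for axis in ("at_bias3", "gc_bias3"):
        vals = np.array([getattr(c, axis) for c in cohort], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            raise ValueError(f"fewer than 2 defined values for {axis}")
        out[axis] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def mutational_force_regressions(
    cohort: Sequence[PositionalComposition],
) -> dict[str, RegressionResult]:
    """For each nucleotide N, OLS of overall %N on %N3; r2*100 is the
    percent contribution of mutational force."""
    out: dict[str, RegressionResult] = {}
    for base in "ATGC":
        x = np.array([c.pct_pos[base][3] for c in cohort], dtype=float)
        y = np.array([c.pct[base] for c in cohort], dtype=float)
        out[base] = _ols(x, y)
    return out


def rscu_gc3_regression(
    codon: str,
    rscu_matrix: pd.DataFrame,
    gc3: Sequence[float],
    predictor: str = "gc3",
) -> RegressionResult:
    """OLS of a codon's RSCU values on %GC3 (or %AT3 = 100 - %GC3)."""
    y = rscu_matrix[codon].to_numpy(dtype=float)
    x = np.asarray(gc3, dtype=float)
    if predictor == "at3":
        x = 100.0 - x
    elif predictor != "gc3":
        raise ValueError("predictor must be 'gc3' or 'at3'")
    return _ols(x, y)


def correlation_battery(
    table: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
) -> list[CorrelationResult]:
    """Pearson correlations (two-sided t-test p) for requested column pairs.

    Missing values are dropped pairwise; a zero-variance variable yields a
    NaN coefficient flagged via a warning rather than an exception.
    """
    results: list[CorrelationResult] = []
    for xname, yname in pairs:
        sub = table[[xname, yname]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"pair ({xname}, {yname}) has n={n} < 3")
        x = sub[xname].to_numpy(dtype=float)
        y = sub[yname].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("zero-variance variable in pair (%s, %s)", xname, yname)
            results.append(CorrelationResult(xname, yname, math.nan, math.nan, n))
            continue
        r, p = stats.pearsonr(x, y)
        results.append(CorrelationResult(xname, yname, float(r), float(p), n))
    return results


def representation_tally(rscu_matrix: pd.DataFrame) -> pd.DataFrame:
    """Percent of cohort genes in each RSCU class, per codon.

    Denominator per codon: genes where the codon's family is observed
    (non-missing RSCU).  Columns: pct_genes_over/under/random, n_genes.
    """
    rows = []
    for codon in rscu_matrix.columns:
        vals = rscu_matrix[codon].dropna()
        n = len(vals)
        classes = vals.map(classify_rscu)
        rows.append(
            {
                "codon": codon,
                "pct_genes_over": 100.0 * (classes == "OVER").sum() / n if n else math.nan,
                "pct_genes_under": 100.0 * (classes == "UNDER").sum() / n if n else math.nan,
                "pct_genes_random": 100.0 * (classes == "RANDOM").sum() / n if n else math.nan,
                "n_genes": n,
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def correspondence_analysis(
    rscu_matrix: pd.DataFrame, n_axes: int | None = None
) -> CaResult:
    """Plain correspondence analysis of a non-negative matrix.

    Missing entries (unobserved families) contribute 0.  The chi-square
    standardized residual matrix is decomposed by SVD; principal coordinates
    are returned for rows (genes) and columns (codons), with per-axis
    inertias (squared singular values) and their fractions of total inertia.
    """
    x = rscu_matrix.fillna(0.0).to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("correspondence analysis requires a non-negative matrix")
    total = x.sum()
    if total <= 0:
        raise ValueError("matrix has zero total")
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    keep_r = r > 0
    keep_c = c > 0
    p = p[np.ix_(keep_r, keep_c)]
    r = r[keep_r]
    c = c[keep_c]
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    # drop numerically-zero axes (incl. the trivial dimension)
    nz = sv > 1e-12
    u, sv, vt = u[:, nz], sv[nz], vt[nz, :]
    if n_axes is not None:
        u, sv, vt = u[:, :n_axes], sv[:n_axes], vt[:n_axes, :]
    row_coords = (u * sv) / np.sqrt(r)[:, None]
    col_coords = (vt.T * sv) / np.sqrt(c)[:, None]
    axes = [f"axis{i+1}" for i in range(len(sv))]
    return CaResult(
        row_coords=pd.DataFrame(
            row_coords, index=rscu_matrix.index[keep_r], columns=axes
        ),
        col_coords=pd.DataFrame(
            col_coords, index=rscu_matrix.columns[keep_c], columns=axes
        ),
        inertia=sv**2,
        total_inertia=float((s**2).sum()),
    )


def codon_clustering(
    rscu_matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "correlation",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of codon columns on their RSCU profiles.

    Default distance is 1 - Pearson r between codon columns with average
    linkage.  Constant columns (undefined correlation to everything) are
    dropped with a warning.  Returns (scipy linkage matrix, codon labels).
    """
    mat = rscu_matrix.dropna(axis=1)
    const = [c for c in mat.columns if np.ptp(mat[c].to_numpy()) == 0]
    if const:
        logger.warning("dropping constant codon columns: %s", ", ".join(const))
        mat = mat.drop(columns=const)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 non-constant codon columns")
    dist = pdist(mat.to_numpy(dtype=float).T, metric=metric)
    link = hierarchy.linkage(dist, method=method)
    return link, list(mat.columns)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
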