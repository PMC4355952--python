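"""Rank-based gene-set dysregulation tests and spline-residual scoring.

Each gene set is compared against background genes by a two-sided Wilcoxon
rank-sum test on the per-gene differential-expression p-values. Across
nested target subsets, the relationship between set size and test p-value
is captured by a quadratic smoothing fit whose residuals highlight subsets
more (or less) dysregulated than their size predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PATHWAY_MIN_SIZE = 20
PATHWAY_SIG = 0.00011
PATHWAY_NOTABLE = 0.001
RISK_LIST_ALPHA = 0.025
EXACT_MAX_N = 25


@dataclass
class GeneSetTestResult:
    set_label: str
    n_genes: int
    wilcoxon_p: float
    direction: int  # -1: members have smaller p-values (more dysregulated)


def wilcoxon_set_test(
    p_values: pd.Series,
    set_members: set[str],
    background: set[str],
    set_label: str = "set",
) -> GeneSetTestResult:
    """Two-sided rank-sum test: member vs background DE p-values.

    ``set_members`` and ``background`` must be disjoint (pre-partitioned by
    the caller). Exact enumeration is used when both sides have <= 25 genes,
    the continuity-corrected normal approximation otherwise. ``direction``
    is the sign of (median member p - median background p).
    """
    overlap = set_members & background
    if overlap:
        raise ValueError(f"set and background overlap: {sorted(overlap)[:5]}...")
    x = p_values.reindex(sorted(set_members)).dropna().to_numpy()
    yv = p_values.reindex(sorted(background)).dropna().to_numpy()
    if len(x) == 0 or len(yv) == 0:
        raise ValueError("set or background has no genes with p-values")
    method = "exact" if max(len(x), len(yv)) <= EXACT_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(x, yv, alternative="two-sided", method=method,
                             use_continuity=True)
    direction = int(np.sign(np.median(x) - np.median(yv)))
    return GeneSetTestResult(set_label=set_label, n_genes=len(x),
                             wilcoxon_p=float(res.pvalue), direction=direction)


@dataclass
class SplineResidualTable:
    table: pd.DataFrame  # columns: n_genes, wilcoxon_p, fitted, residual


def spline_residuals(
    points: Mapping[str, tuple[int, float]],
    neg_log10: bool = False,
) -> SplineResidualTable:
    """Quadratic smoothing fit of set p-value against set size, with residuals.

    Residual = observed - fitted. With fewer than 8 sets the fit is a plain
    least-squares quadratic (the smoothing-spline limit); with more, a
    quadratic smoothing spline with the smoothing level chosen by
    generalized cross-validation over a grid. ``neg_log10`` fits on the
    -log10 p scale instead of the raw p scale.
    """
    labels = list(points)
    if len(labels) < 4:
        raise ValueError(
            "need >= 4 sets for a quadratic fit with residual degrees of freedom"
        )
    n = np.array([points[l][0] for l in labels], dtype=float)
    p = np.array([points[l][1] for l in labels], dtype=float)
    yv = -np.log10(p) if neg_log10 else p

    order = np.argsort(n, kind="stable")
    fitted = np.empty_like(yv)
    if len(labels) < 8 or len(np.unique(n)) < 8:
        coef = np.polyfit(n, yv, deg=2)
        fitted[:] = np.polyval(coef, n)
    else:
        from scipy.interpolate import UnivariateSpline

        ns, ys = n[order], yv[order]
        m = len(ns)
        best = (np.inf, None)
        for s in np.geomspace(1e-10, max(np.var(ys) * m, 1e-8), 25):
            try:
                spl = UnivariateSpline(ns, ys, k=2, s=s)
            except Exception:
                continue
            resid = ys - spl(ns)
            dof = len(spl.get_knots()) + 1  # effective parameters (rough)
            gcv = (np.sum(resid**2) / m) / max((1 - dof / m) ** 2, 1e-6)
            if gcv < best[0]:
                best = (gcv, spl)
        if best[1] is None:
            coef = np.polyfit(n, yv, deg=2)
            fitted[:] = np.polyval(coef, n)
        else:
            fitted[:] = best[1](n)

    table = pd.DataFrame(
        {
            "n_genes": n.astype(int),
            "wilcoxon_p": p,
            "fitted": fitted,
            "residual": yv - fitted,
        },
        index=labels,
    )
    return SplineResidualTable(table=table)


def pathway_tests(
    p_values: pd.Series,
    pathway_db: Mapping[str, set[str]],
    min_size: int = PATHWAY_MIN_SIZE,
    sig: float = PATHWAY_SIG,
    notable: float = PATHWAY_NOTABLE,
) -> pd.DataFrame:
    """Wilcoxon test per pathway of resolvable size >= min_size.

    Pathway size is counted after intersection with the tested genes; the
    background for each pathway is every other tested gene.
    """
    if not pathway_db:
        raise ValueError("empty pathway database")
    tested = set(p_values.index)
    rows = []
    for name, members in pathway_db.items():
        inset = members & tested
        if len(inset) < min_size:
            continue
        res = wilcoxon_set_test(p_values, inset, tested - inset, set_label=name)
        rows.append(
            {
                "pathway": name,
                "n_genes": res.n_genes,
                "wilcoxon_p": res.wilcoxon_p,
                "direction": res.direction,
                "significant": res.wilcoxon_p < sig,
                "notable": res.wilcoxon_p < notable,
            }
        )
    return pd.DataFrame(rows).set_index("pathway") if rows else pd.DataFrame(
        columns=["n_genes", "wilcoxon_p", "direction", "significant", "notable"]
    )


def risk_list_tests(
    p_values_by_contrast: Mapping[str, pd.Series],
    risk_lists: Mapping[str, set[str]],
    bound_filter: set[str] | None = None,
    alpha: float = RISK_LIST_ALPHA,
) -> pd.DataFrame:
    """Wilcoxon test per risk list per contrast at the two-test level 0.025.

    Lists are intersected with the tested genes (and, when given, with the
    bound set); untestable lists are reported with NaN p.
    """
    rows = []
    for contrast, pvals in p_values_by_contrast.items():
        tested = set(pvals.index)
        for name, members in risk_lists.items():
            inset = members & tested
            if bound_filter is not None:
                inset &= bound_filter
            bg = tested - inset
            if not inset or not bg:
                rows.append({"list": name, "contrast": contrast, "n_genes": len(inset),
                             "wilcoxon_p": np.nan, "direction": 0, "significant": False})
                continue
            res = wilcoxon_set_test(pvals, inset, bg, set_label=name)
            rows.append(
                {
                    "list": name,
                    "contrast": contrast,
                    "n_genes": res.n_genes,
                    "wilcoxon_p": res.wilcoxon_p,
                    "direction": res.direction,
                    "significant": res.wilcoxon_p < alpha,
                }
            )
    return pd.DataFrame(rows)
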