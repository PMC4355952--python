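"""Quality filtering, normalization and count modelling for knockdown RNA-seq.

The pipeline order is fixed: low-total filter (grand total <= 20), then the
single-unit filter, then the within-treatment variance-to-mean-ratio screen
(max group VMR > 100). Counts are modelled per gene with a log-linear model
containing batch and knockdown effects, offset by the log effective library
size; p-values come from a likelihood-ratio test of the knockdown term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOW_COUNT_TOTAL = 20
VMR_THRESHOLD = 100.0
STRONG_P = 1.68e-6
STRONG_LFC = 0.1
STRONG_CPM_RANGE = (2.0, 10.0)


@dataclass
class SampleInfo:
    """Per-unit metadata: treatment arm and batch label."""

    unit: str
    treatment: str
    batch: str


@dataclass
class FilterReport:
    n_input: int
    n_removed_lowcount: int = 0
    n_removed_single_unit: int = 0
    n_removed_vmr: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.n_removed_lowcount
                - self.n_removed_single_unit - self.n_removed_vmr)


@dataclass
class NormalizationState:
    library_sizes: np.ndarray
    mean_library: float
    scale_factors: np.ndarray
    tmm_factors: np.ndarray | None = None

    @property
    def effective_library_sizes(self) -> np.ndarray:
        # trimmed-mean factors are computed on raw count ratios, so they
        # already carry the depth difference; the mean library sets the scale
        if self.tmm_factors is None:
            return self.library_sizes.astype(float)
        return self.mean_library * self.tmm_factors


def filter_low_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop genes with grand total <= 20, then genes supported by one unit."""
    if counts.empty:
        raise ValueError("empty count matrix")
    report = FilterReport(n_input=counts.shape[0])
    totals = counts.sum(axis=1)
    keep = totals > LOW_COUNT_TOTAL
    report.n_removed_lowcount = int((~keep).sum())
    counts = counts.loc[keep]
    single_unit = (counts > 0).sum(axis=1) <= 1
    report.n_removed_single_unit = int(single_unit.sum())
    return counts.loc[~single_unit], report


def normalize_library_scale(counts: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationState]:
    """Scale each unit to the mean library size: x_ij * s_bar / s_i."""
    s = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(s <= 0):
        bad = list(counts.columns[s <= 0])
        raise ValueError(f"zero-size libraries: {bad}")
    s_bar = float(s.mean())
    factors = s_bar / s
    state = NormalizationState(library_sizes=s, mean_library=s_bar, scale_factors=factors)
    return counts * factors, state


def vmr(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Sample variance over sample mean; 0 when the group is all zero."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=axis)
    var = values.var(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return out


def vmr_filter(
    normalized: pd.DataFrame,
    treatment_groups: Mapping[str, Sequence[str]],
    threshold: float = VMR_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove genes whose max within-treatment VMR exceeds the threshold."""
    for t, units in treatment_groups.items():
        if len(units) < 2:
            raise ValueError(f"treatment group {t!r} has < 2 units")
    max_vmr = np.zeros(normalized.shape[0])
    for units in treatment_groups.values():
        group = normalized[list(units)].to_numpy(dtype=float)
        max_vmr = np.maximum(max_vmr, vmr(group, axis=1))
    removed = list(normalized.index[max_vmr > threshold])
    return normalized.drop(index=removed), removed


def trimmed_mean_factors(
    counts: pd.DataFrame,
    reference_unit: str | None = None,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
    recenter: bool = True,
) -> pd.Series:
    """Trimmed-mean scale factors from raw log count ratios to a reference.

    For each unit, log2 ratios of raw counts to the reference (M) and
    average log2 abundances (A) are computed over genes expressed in both;
    the most extreme 30% of M and 5% of A are trimmed and the remaining M
    values averaged with inverse approximate-variance weights, then
    exponentiated. Factors carry both depth and composition differences
    (a column exactly 2x the reference gets factor 2 before re-centering);
    with ``recenter`` they are normalized to multiply to 1. The default
    reference is the unit whose upper quartile (depth-normalized) is
    closest to the mean upper quartile.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if reference_unit is None:
        uq = np.array([np.quantile(mat[:, i][mat[:, i] > 0], 0.75) / lib[i]
                       if (mat[:, i] > 0).any() else 0.0
                       for i in range(mat.shape[1])])
        reference_unit = counts.columns[int(np.argmin(np.abs(uq - uq.mean())))]
    ref_idx = counts.columns.get_loc(reference_unit)
    ref = mat[:, ref_idx]
    ref_lib = lib[ref_idx]

    factors = np.ones(mat.shape[1])
    for i in range(mat.shape[1]):
        if i == ref_idx:
            continue
        obs = mat[:, i]
        use = (obs > 0) & (ref > 0)
        if not use.any():
            raise ValueError(
                f"unit {counts.columns[i]!r} shares no expressed genes with the reference"
            )
        p_obs = obs[use] / lib[i]
        p_ref = ref[use] / ref_lib
        M = np.log2(obs[use] / ref[use])
        A = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
        if np.allclose(M, M[0]):
            factors[i] = 2.0 ** M[0]
            continue
        m_lo, m_hi = np.quantile(M, [log_ratio_trim, 1 - log_ratio_trim])
        a_lo, a_hi = np.quantile(A, [abs_expr_trim, 1 - abs_expr_trim])
        keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        if not keep.any():
            keep = np.ones_like(M, dtype=bool)
        # delta-method weights for the log ratio of two binomial proportions
        w = 1.0 / ((1 - p_obs[keep]) / (lib[i] * p_obs[keep])
                   + (1 - p_ref[keep]) / (ref_lib * p_ref[keep]))
        factors[i] = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))
    if recenter:
        factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


# ---------------------------------------------------------------------------
# Per-gene log-linear count models, vectorized across genes.

def _irls_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS for log-link Poisson (alpha None) or NB with known dispersion.

    y: genes x units; X: units x p; offset: units (log effective library).
    Returns (beta [genes x p], loglik [genes]). NB uses the NB2 variance
    mu + alpha mu^2 with per-gene alpha.
    """
    G, m = y.shape
    p = X.shape[1]
    # start from the null-ish rate
    mu0 = np.maximum(y.mean(axis=1, keepdims=True), 0.1)
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(mu0[:, 0]) - np.log(np.exp(offset).mean())
    eta = beta @ X.T + offset
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        if alpha is None:
            W = mu
        else:
            W = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-12)
        XtWX = np.einsum("gm,mp,mq->gpq", W, X, X)
        XtWz = np.einsum("gm,mp,gm->gp", W, X, z)
        XtWX += 1e-10 * np.eye(p)
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        new_eta = new_beta @ X.T + offset
        if np.max(np.abs(new_eta - eta)) < tol:
            beta, eta = new_beta, new_eta
            break
        beta, eta = new_beta, new_eta
    mu = np.exp(np.clip(eta, -30, 30))
    if alpha is None:
        ll = np.sum(y * np.log(np.maximum(mu, 1e-300)) - mu - _lgamma1p(y), axis=1)
    else:
        a = alpha[:, None]
        r = 1.0 / np.maximum(a, 1e-12)
        ll = np.sum(
            stats.nbinom.logpmf(y, r, r / (r + mu)),
            axis=1,
        )
    return beta, ll


def _lgamma1p(y: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(y + 1.0)


def estimate_dispersion(
    counts: pd.DataFrame,
    design: np.ndarray,
    offset: np.ndarray,
    shrink: float = 0.5,
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion, shrunk toward the global mean.

    ``shrink`` is the weight on the global mean dispersion.
    """
    y = counts.to_numpy(dtype=float)
    beta, _ = _irls_fit(y, design, offset, alpha=None)
    mu = np.exp(np.clip(beta @ design.T + offset, -30, 30))
    resid2 = (y - mu) ** 2
    p = design.shape[1]
    dof = max(y.shape[1] - p, 1)
    # E[(y-mu)^2] = mu + alpha mu^2
    num = np.sum(resid2 - mu, axis=1) * (y.shape[1] / dof)
    den = np.sum(mu**2, axis=1)
    alpha = np.clip(num / np.maximum(den, 1e-12), 0.0, 10.0)
    return (1 - shrink) * alpha + shrink * alpha.mean()


@dataclass
class DEResult:
    table: pd.DataFrame  # columns: p_value, log2_fold_change, log2_cpm
    contrast: str
    model: str
    params: dict = field(default_factory=dict)


def fit_counts_glm(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    contrast: str,
    control: str = "control",
    model: Literal["poisson", "negbin"] = "poisson",
    norm_state: NormalizationState | None = None,
    test: Literal["lrt", "wald"] = "lrt",
    dispersion_shrink: float = 0.5,
) -> DEResult:
    """Per-gene log-linear model with batch + knockdown effects.

    Only units in the contrast arm or the control arm enter the fit. The
    offset is the log effective library size (library size x trimmed-mean
    factor when available). The knockdown coefficient is tested by
    likelihood ratio against the batch-only model (Wald by option);
    log2FC is the coefficient / ln 2 and log2CPM comes from mean
    normalized counts.
    """
    meta = {s.unit: s for s in samples}
    units = [u for u in counts.columns if meta[u].treatment in (contrast, control)]
    if not units:
        raise ValueError(f"no units for contrast {contrast!r} vs {control!r}")
    sub = counts[units]
    y = sub.to_numpy(dtype=float)
    allzero = y.sum(axis=1) == 0
    if allzero.any():
        import warnings

        warnings.warn(f"{int(allzero.sum())} all-zero genes excluded from the fit")
        sub = sub.loc[~allzero]
        y = y[~allzero]

    batches = sorted({meta[u].batch for u in units})
    kd = np.array([1.0 if meta[u].treatment == contrast else 0.0 for u in units])
    cols = [np.ones(len(units))]
    for b in batches[1:]:
        cols.append(np.array([1.0 if meta[u].batch == b else 0.0 for u in units]))
    X0 = np.column_stack(cols)
    X1 = np.column_stack(cols + [kd])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("design matrix (batch + knockdown) is not full rank")

    if norm_state is None:
        lib = y.sum(axis=0)
    else:
        eff = pd.Series(norm_state.effective_library_sizes,
                        index=counts.columns)
        lib = eff[units].to_numpy(dtype=float)
    offset = np.log(lib)

    alpha = None
    if model == "negbin":
        alpha = estimate_dispersion(sub, X1, offset, shrink=dispersion_shrink)

    beta1, ll1 = _irls_fit(y, X1, offset, alpha=alpha)
    beta0, ll0 = _irls_fit(y, X0, offset, alpha=alpha)
    lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
    if test == "lrt":
        pvals = stats.chi2.sf(lr, df=1)
    else:  # wald via the observed information of the full model
        mu1 = np.exp(np.clip(beta1 @ X1.T + offset, -30, 30))
        W = mu1 if alpha is None else mu1 / (1.0 + alpha[:, None] * mu1)
        XtWX = np.einsum("gm,mp,mq->gpq", W, X1, X1)
        se = np.sqrt(np.linalg.inv(XtWX)[:, -1, -1])
        pvals = 2.0 * stats.norm.sf(np.abs(beta1[:, -1] / se))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    cpm = (y / lib * 1e6).mean(axis=1)
    table = pd.DataFrame(
        {
            "p_value": pvals,
            "log2_fold_change": beta1[:, -1] / np.log(2.0),
            "log2_cpm": np.log2(np.maximum(cpm, 1e-12)),
        },
        index=sub.index,
    )
    return DEResult(table=table, contrast=contrast, model=model)


def bonferroni_threshold(n_tests_1: int, n_tests_2: int, alpha: float = 0.05) -> float:
    """Familywise threshold alpha / (n_tests_1 * n_tests_2)."""
    if n_tests_1 < 1 or n_tests_2 < 1:
        raise ValueError("test counts must be positive integers")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / (n_tests_1 * n_tests_2)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (for reporting thresholds)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def strong_de(
    results: DEResult,
    p_max: float = STRONG_P,
    lfc_min: float = STRONG_LFC,
    cpm_range: tuple[float, float] = STRONG_CPM_RANGE,
) -> set[str]:
    """Strongly dysregulated genes: small p, meaningful |log2FC|, mid CPM."""
    t = results.table
    lo, hi = cpm_range
    mask = (
        (t["p_value"] < p_max)
        & (t["log2_fold_change"].abs() > lfc_min)
        & (t["log2_cpm"] >= lo)
        & (t["log2_cpm"] <= hi)
    )
    return set(t.index[mask])
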