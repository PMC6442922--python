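"""Negative-binomial differential expression for a paired 2x2 design.

Implements the count-model workflow used for small paired intervention
studies: median-of-ratios size factors, gene-wise negative-binomial
dispersion estimation, an NB generalised linear model with per-subject
effects, a time main effect and a condition:time interaction, and a
likelihood-ratio test of the interaction term against the nested model
without it, followed by Benjamini–Hochberg adjustment.

The design is the classic nested-individuals coding: one indicator per
subject (absorbing the intercept and the condition main effect, which is
confounded with subjects in a paired design), plus ``time`` and
``condition:time`` columns.  The interaction coefficient is the log fold
change of the (post/pre) ratio in the intervention arm over the control
arm — the quantity of interest.

Model per gene g and sample s:

    K_gs ~ NB(mean = sf_s * mu_gs, dispersion = alpha_g)
    log mu_gs = x_s' beta_g            (log link, log sf_s as offset)
    Var(K_gs) = mu + alpha * mu^2

Dispersions are estimated gene-wise by maximising the Cox–Reid adjusted
profile likelihood, alternating with IRLS refits of the mean model; no
empirical-Bayes shrinkage across genes is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DesignError, NormalizationError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "validate_sample_sheet",
    "validate_counts",
    "build_design",
    "estimate_size_factors",
    "estimate_dispersions",
    "fit_nb_glm",
    "lrt_interaction",
    "bh_adjust",
    "run_de",
]

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100

CONDITIONS = ("performance", "control")
TIMES = ("pre", "post")


# ---------------------------------------------------------------------------
# input validation and design construction
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the paired 2x2 sample sheet invariants and return it.

    Every pair_id must occur exactly twice (once pre, once post) and the
    condition must be constant within a pair.
    """
    required = {"sample_id", "pair_id", "condition", "time"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown condition values: {sorted(bad_cond)}")
    bad_time = set(sheet["time"]) - set(TIMES)
    if bad_time:
        raise ValidationError(f"unknown time values: {sorted(bad_time)}")
    for pair, grp in sheet.groupby("pair_id"):
        if len(grp) != 2 or set(grp["time"]) != {"pre", "post"}:
            raise ValidationError(
                f"pair_id {pair!r} must occur exactly twice, once pre and once post"
            )
        if grp["condition"].nunique() != 1:
            raise ValidationError(f"pair_id {pair!r} changes condition between samples")
    return sheet


def validate_counts(counts: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the count matrix against its sample sheet."""
    if (counts.values < 0).any():
        raise ValidationError("count matrix contains negative entries")
    if list(counts.columns) != list(sheet["sample_id"]):
        raise ValidationError("count matrix columns do not match sample sheet sample_ids")
    return counts


def build_design(sheet: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full and reduced design matrices for the paired interaction model.

    Returns ``(X_full, X_reduced, column_names)`` where the last column of
    the full design is the condition:time interaction (performance * post)
    and the reduced design drops exactly that column.
    """
    pairs = list(dict.fromkeys(sheet["pair_id"]))
    n = len(sheet)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for p in pairs:
        cols.append((sheet["pair_id"] == p).to_numpy(dtype=float))
        names.append(f"subject[{p}]")
    post = (sheet["time"] == "post").to_numpy(dtype=float)
    perf = (sheet["condition"] == "performance").to_numpy(dtype=float)
    cols.append(post)
    names.append("time[post]")
    cols.append(post * perf)
    names.append("condition[performance]:time[post]")
    X = np.column_stack(cols)
    assert X.shape == (n, len(pairs) + 2)
    check_full_rank(X, names)
    return X, X[:, :-1], names


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise :class:`DesignError` naming the offending columns if X is rank deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # pivoted QR: columns pivoted beyond the numerical rank are the culprits
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[j] for j in piv[np.count_nonzero(diag > tol):]]
    raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    For genes with an all-positive row the per-sample ratio of the count
    to the gene's geometric mean is formed; a sample's factor is the
    median of those ratios.  Factors are then divided by their own
    geometric mean so the convention ``geomean(sf) == 1`` holds exactly.
    """
    K = np.asarray(counts, dtype=float)
    if K.ndim != 2:
        raise ValidationError("counts must be a 2-D matrix (genes x samples)")
    positive = (K > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has all-positive counts; median-of-ratios normalization impossible"
        )
    Kp = K[positive]
    log_geomean = np.log(Kp).mean(axis=1)
    ratios = np.log(Kp) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf /= np.exp(np.log(sf).mean())
    return sf


# ---------------------------------------------------------------------------
# NB likelihood and IRLS
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """Exact NB log-likelihood, elementwise; broadcasts alpha over rows."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-300)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _irls_batch(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
):
    """Batched IRLS fit of an NB GLM with log link across all genes at once.

    Returns ``(beta, mu, loglik, converged)``.  Genes whose fits produce
    non-finite values are marked non-converged.
    """
    G, S = Y.shape
    P = X.shape[1]
    eta = np.log(np.maximum(Y, 0.5))  # init at (clamped) observed counts
    mu = np.exp(eta)
    ll = nb_loglik(Y, mu, alpha).sum(axis=1)
    beta = np.zeros((G, P))
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-10
    eye = np.eye(P)

    for _ in range(max_iter):
        w = mu / (1.0 + alpha[:, None] * mu)  # IRLS working weights
        z = (eta - offset) + (Y - mu) / mu     # working response
        A = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
        b = np.einsum("sp,gs,gs->gp", X, w, z, optimize=True)
        try:
            beta_new = np.linalg.solve(A + ridge * eye, b[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(A + 1e-6 * eye, b[:, :, None])[:, :, 0]
        eta = np.clip(beta_new @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        ll_new = nb_loglik(Y, mu, alpha).sum(axis=1)
        delta = np.abs(ll_new - ll) / (np.abs(ll_new) + 0.1)
        beta = beta_new
        newly = delta < tol
        converged |= newly
        ll = ll_new
        if converged.all():
            break

    finite = np.isfinite(ll) & np.isfinite(beta).all(axis=1)
    converged &= finite
    return beta, mu, ll, converged


@dataclass
class GLMFit:
    """Per-gene NB GLM fit: coefficients and exact log-likelihood."""

    coefficients: np.ndarray
    log_likelihood: float
    mu: np.ndarray
    alpha: float
    converged: bool
    column_names: list[str] = field(default_factory=list)


def fit_nb_glm(
    counts_g: np.ndarray,
    size_factors: np.ndarray,
    design_matrix: np.ndarray,
    alpha: float,
    column_names: list[str] | None = None,
) -> GLMFit:
    """Fit one gene's NB GLM (log link, log size-factor offset) by IRLS.

    Raises :class:`DesignError` for a rank-deficient design; a fit that
    fails to converge is returned flagged so callers can exclude the gene
    from testing.
    """
    y = np.asarray(counts_g, dtype=float).reshape(1, -1)
    X = np.asarray(design_matrix, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValidationError("size factors must be positive")
    names = column_names or [f"x{j}" for j in range(X.shape[1])]
    check_full_rank(X, names)
    a = np.asarray([alpha], dtype=float)
    beta, mu, ll, conv = _irls_batch(y, X, np.log(sf), a)
    return GLMFit(
        coefficients=beta[0],
        log_likelihood=float(ll[0]),
        mu=mu[0],
        alpha=float(alpha),
        converged=bool(conv[0]),
        column_names=names,
    )


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _moments_dispersion(Y: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion on normalized counts (init / fallback)."""
    Z = Y / sf
    m = Z.mean(axis=1)
    v = Z.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (v - m) / np.maximum(m, 1e-8) ** 2
    return np.clip(np.nan_to_num(a, nan=ALPHA_MIN), 1e-4, ALPHA_MAX)


def _cr_objective(Y, X, mu, log_alpha):
    """Cox–Reid adjusted profile log-likelihood of alpha at fixed fitted means."""
    alpha = np.exp(log_alpha)
    ll = nb_loglik(Y, mu, alpha).sum(axis=1)
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
    sign, logdet = np.linalg.slogdet(A)
    logdet = np.where(sign > 0, logdet, np.inf)
    return ll - 0.5 * logdet


def _golden_max(fun, lo: float, hi: float, n_genes: int, iters: int = 45):
    """Vectorized golden-section maximisation of a per-gene scalar objective."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_genes, lo)
    b = np.full(n_genes, hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = fun(c)
    fd = fun(d)
    for _ in range(iters):
        go_left = fc > fd
        b = np.where(go_left, d, b)
        a = np.where(go_left, a, c)
        fc_old, fd_old = fc, fd
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        # per gene only one probe point is new; the other reuses its objective
        probe = np.where(go_left, c, d)
        f_probe = fun(probe)
        fc = np.where(go_left, f_probe, fd_old)
        fd = np.where(go_left, fc_old, f_probe)
    return (a + b) / 2.0


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    size_factors: np.ndarray,
    design: np.ndarray,
    n_alternations: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-wise NB dispersions by Cox–Reid adjusted profile likelihood.

    Alternates batched IRLS refits of the mean model with a vectorized
    golden-section maximisation of the adjusted profile likelihood over
    log(alpha) in ``[1e-8, 10]``.  Genes whose IRLS fit does not converge
    fall back to the method-of-moments estimate and are flagged.

    Returns ``(alpha, mom_fallback)`` with one entry per gene.
    """
    Y = np.asarray(counts, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValidationError("size factors must be positive")
    X = np.asarray(design, dtype=float)
    offset = np.log(sf)
    alpha = _moments_dispersion(Y, sf)
    mom = alpha.copy()
    conv = np.zeros(Y.shape[0], dtype=bool)
    for _ in range(n_alternations):
        _, mu, _, conv = _irls_batch(Y, X, offset, alpha)
        log_alpha = _golden_max(
            lambda la: _cr_objective(Y, X, mu, la),
            np.log(ALPHA_MIN),
            np.log(ALPHA_MAX),
            Y.shape[0],
        )
        alpha = np.exp(log_alpha)
    fallback = ~conv
    if fallback.any():
        log.warning("dispersion fit fell back to method of moments for %d genes", fallback.sum())
        alpha[fallback] = mom[fallback]
    return np.clip(alpha, ALPHA_MIN, ALPHA_MAX), fallback


# ---------------------------------------------------------------------------
# LRT and multiple testing
# ---------------------------------------------------------------------------

def lrt_interaction(
    full_fit: GLMFit, reduced_fit: GLMFit, df_resid: int | None = None
) -> tuple[float, float]:
    """Likelihood-ratio test of the interaction term (1 df).

    The reduced design must be nested in the full design with a single
    dropped column.  With ``df_resid=None`` the statistic is referenced
    to chi-square with 1 df (the large-sample limit); passing the
    residual degrees of freedom ``n - p_full`` references it to
    F(1, df_resid) instead, which compensates for the dispersion and
    mean parameters consumed by a small sample and is what
    :func:`run_de` uses.
    """
    p_full = len(full_fit.coefficients)
    p_red = len(reduced_fit.coefficients)
    if p_full - p_red != 1:
        raise ValidationError(
            f"expected a 1-df nested comparison, got {p_full} vs {p_red} coefficients"
        )
    stat = max(0.0, 2.0 * (full_fit.log_likelihood - reduced_fit.log_likelihood))
    if df_resid is None:
        return stat, float(stats.chi2.sf(stat, df=1))
    if df_resid < 1:
        raise ValidationError(f"df_resid must be >= 1, got {df_resid}")
    return stat, float(stats.f.sf(stat, 1, df_resid))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Missing values (NaN) pass through and do not count toward the number
    of tests.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_de(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    fdr_threshold: float = 0.05,
    test_reference: str = "f",
) -> pd.DataFrame:
    """Complete paired-interaction DE analysis over all miRNAs.

    ``test_reference`` selects the null reference for the 1-df LRT
    statistic: ``"f"`` (default) uses F(1, n - p_full), which stays
    calibrated when many subject parameters are fitted to few samples;
    ``"chisq"`` uses the asymptotic chi-square with 1 df.

    Returns a table indexed by miRNA id with columns ``base_mean``,
    ``interaction_lfc`` (log2 of the performance (post/pre) ratio over
    the control (post/pre) ratio), ``lrt_stat``, ``p_value``, ``q_value``,
    ``perf_post_pre_fold``, ``ctrl_post_pre_fold``, ``dispersion`` and
    ``status``.  All-zero miRNAs and non-converged fits keep their row
    but report a missing p-value.
    """
    validate_sample_sheet(sheet)
    validate_counts(counts, sheet)
    Y_all = counts.to_numpy(dtype=float)
    ids = counts.index

    nonzero = Y_all.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        log.info("dropping %d all-zero miRNAs from testing", n_dropped)

    sf = estimate_size_factors(Y_all[nonzero])
    offset = np.log(sf)
    X_full, X_red, names = build_design(sheet)
    Y = Y_all[nonzero]

    alpha, mom_flag = estimate_dispersions(Y, sf, X_full)
    beta_f, mu_f, ll_f, conv_f = _irls_batch(Y, X_full, offset, alpha)
    beta_r, mu_r, ll_r, conv_r = _irls_batch(Y, X_red, offset, alpha)

    if test_reference not in ("f", "chisq"):
        raise ValidationError(f"unknown test reference {test_reference!r}")
    stat = np.maximum(0.0, 2.0 * (ll_f - ll_r))
    if test_reference == "f":
        df_resid = Y.shape[1] - X_full.shape[1]
        pval = stats.f.sf(stat, 1, df_resid)
    else:
        pval = stats.chi2.sf(stat, df=1)
    ok = conv_f & conv_r
    n_failed = int((~ok).sum())
    if n_failed:
        log.warning("%d miRNAs excluded from testing (non-converged GLM)", n_failed)
    pval = np.where(ok, pval, np.nan)
    qval = bh_adjust(pval)

    # arm-level post/pre folds from normalized means
    Z = Y / sf
    post = (sheet["time"] == "post").to_numpy()
    perf = (sheet["condition"] == "performance").to_numpy()

    def cell_mean(mask):
        return Z[:, mask].mean(axis=1)

    perf_pre = cell_mean(perf & ~post)
    perf_post = cell_mean(perf & post)
    ctrl_pre = cell_mean(~perf & ~post)
    ctrl_post = cell_mean(~perf & post)
    with np.errstate(divide="ignore", invalid="ignore"):
        perf_fold = perf_post / perf_pre
        ctrl_fold = ctrl_post / ctrl_pre

    status = np.where(ok, "ok", "not_converged")
    status = np.where(mom_flag & ok, "ok_mom_dispersion", status)

    sub = pd.DataFrame(
        {
            "base_mean": Z.mean(axis=1),
            "interaction_lfc": beta_f[:, -1] / np.log(2.0),
            "lrt_stat": stat,
            "p_value": pval,
            "q_value": qval,
            "perf_post_pre_fold": perf_fold,
            "ctrl_post_pre_fold": ctrl_fold,
            "dispersion": alpha,
            "status": status,
        },
        index=ids[nonzero],
    )
    dropped = pd.DataFrame(
        {
            "base_mean": 0.0,
            "interaction_lfc": np.nan,
            "lrt_stat": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
            "perf_post_pre_fold": np.nan,
            "ctrl_post_pre_fold": np.nan,
            "dispersion": np.nan,
            "status": "all_zero",
        },
        index=ids[~nonzero],
    )
    out = pd.concat([sub, dropped]).loc[ids]
    out.index.name = "mirna_id"
    return out
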