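"""Negative-binomial differential expression for circRNA count matrices.

The model follows the standard bulk RNA-seq quasi-likelihood workflow:
between-sample normalisation by trimmed mean of M-values (TMM), a per-feature
negative-binomial log-linear model (intercept + genotype) with the library
size as offset, dispersion estimated by Cox-Reid adjusted profile likelihood
and smoothed against abundance, and the genotype contrast tested with a
quasi-likelihood F statistic whose denominator variance is empirical-Bayes
moderated across features.

Sign convention: log2FC = log2(mutant / wild-type), so positive means higher
in the mutant. ``classify_de(..., invert_contrast=True)`` flips the orientation
for workflows that report the contrast the other way around.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Features x samples integer counts with genotype labels.

    ``lib_sizes`` defaults to column sums; ``norm_factors`` (set by
    :func:`normalize`) multiply them into effective library sizes.
    """

    counts: pd.DataFrame
    genotypes: pd.Series
    lib_sizes: pd.Series | None = None
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.genotypes.index]
        if missing:
            raise ValueError(f"samples without genotype: {missing}")
        self.genotypes = self.genotypes.reindex(self.counts.columns)
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.reindex(self.counts.columns).astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def effective_lib_sizes(self) -> pd.Series:
        if self.norm_factors is None:
            return self.lib_sizes
        return self.lib_sizes * self.norm_factors


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    log_ratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric-mean centred.

    The reference sample is the column whose log library size is closest to
    the mean log library size. M (log2 ratio) and A (average log2 abundance)
    values over features positive in both columns are doubly trimmed, then
    averaged with inverse asymptotic-variance weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float) if lib_sizes is None else lib_sizes.astype(float)
    zero_cols = lib[lib == 0]
    if len(zero_cols):
        raise ValueError(f"all-zero sample(s): {list(zero_cols.index)}")

    log_lib = np.log(lib)
    ref = (log_lib - log_lib.mean()).abs().idxmin()
    x_ref = counts[ref].to_numpy(float)
    n_ref = lib[ref]

    factors = {}
    for sample in counts.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        x = counts[sample].to_numpy(float)
        n = lib[sample]
        ok = (x > 0) & (x_ref > 0)
        if ok.sum() == 0:
            factors[sample] = 1.0
            continue
        p, p_ref = x[ok] / n, x_ref[ok] / n_ref
        m = np.log2(p / p_ref)
        a = 0.5 * (np.log2(p) + np.log2(p_ref))
        w = (n - x[ok]) / (n * x[ok]) + (n_ref - x_ref[ok]) / (n_ref * x_ref[ok])
        keep = np.ones(ok.sum(), bool)
        for vals, trim in ((m, log_ratio_trim), (a, abundance_trim)):
            lo, hi = np.quantile(vals, [trim, 1 - trim])
            keep &= (vals >= lo) & (vals <= hi)
        if keep.sum() == 0:
            keep[:] = True
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[sample] = float(2.0 ** f)

    fac = pd.Series(factors).reindex(counts.columns)
    fac /= np.exp(np.log(fac).mean())  # geometric-mean centring
    return fac


def normalize(cm: CountMatrix, **kwargs) -> CountMatrix:
    """Return a copy of the matrix with TMM effective library sizes."""
    fac = tmm_factors(cm.counts, cm.lib_sizes, **kwargs)
    return CountMatrix(cm.counts.copy(), cm.genotypes.copy(),
                       cm.lib_sizes.copy(), norm_factors=fac)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# NB GLM machinery (two-group design with offsets)


def _fit_group_rate(y: np.ndarray, n: np.ndarray, phi: float) -> float:
    """MLE of the common rate q (mu_i = q * n_i) for an NB sample.

    Solves sum (y - mu) / (1 + phi * mu) = 0 by Newton on log q; for phi = 0
    this is the weighted mean y/n.
    """
    tot = y.sum()
    if tot == 0:
        return 0.0
    q = tot / n.sum()
    if phi == 0:
        return q
    for _ in range(50):
        mu = q * n
        w = 1.0 + phi * mu
        score = np.sum((y - mu) / w)
        info = np.sum(n * (1.0 + phi * y) / w ** 2)
        if info <= 0:
            break
        q_new = q + score / info
        if q_new <= 0:
            q_new = q / 2.0
        if abs(q_new - q) <= 1e-12 + 1e-8 * q:
            q = q_new
            break
        q = q_new
    return float(q)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Negative-binomial unit deviance summed over observations."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        if phi == 0:
            term2 = -(y - mu)
        else:
            term2 = -(y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
    return float(2.0 * np.sum(term1 + term2))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-12)
    if phi == 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
                        + y * np.log(phi * mu / (1.0 + phi * mu))
                        - r * np.log1p(phi * mu)))


def _cr_adjusted_profile(y: np.ndarray, n: np.ndarray, groups: list[np.ndarray],
                         phi: float) -> float:
    """Cox-Reid adjusted profile log-likelihood of the dispersion."""
    ll = 0.0
    adj = 0.0
    for m in groups:
        q = _fit_group_rate(y[m], n[m], phi)
        mu = q * n[m]
        ll += _nb_loglik(y[m], mu, phi)
        info = np.sum(mu / (1.0 + phi * mu))
        adj += 0.5 * math.log(max(info, 1e-12))
    return ll - adj


def estimate_dispersion(y: np.ndarray, n: np.ndarray, groups: list[np.ndarray],
                        lo: float = 1e-6, hi: float = 20.0) -> float:
    """Per-feature dispersion by maximising the CR-adjusted profile likelihood."""
    obj = lambda lphi: -_cr_adjusted_profile(y, n, groups, math.exp(lphi))
    res = optimize.minimize_scalar(obj, bounds=(math.log(lo), math.log(hi)),
                                   method="bounded", options={"xatol": 1e-3})
    return float(math.exp(res.x))


def _trend_dispersion(mean_norm: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Smooth dispersion against abundance (lowess on log scales); falls back
    to the global mean when there are too few features to fit a trend."""
    if len(disp) < 20:
        return np.full_like(disp, float(np.exp(np.mean(np.log(np.maximum(disp, 1e-8))))))
    from statsmodels.nonparametric.smoothers_lowess import lowess
    x = np.log(np.maximum(mean_norm, 1e-8))
    z = np.log(np.maximum(disp, 1e-8))
    fit = lowess(z, x, frac=0.5, return_sorted=False)
    return np.exp(fit)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, np.ndarray]:
    """limma-style moderation of deviance variances: fit a scaled F prior by
    moments on log(s2) and return (prior df, posterior variances)."""
    s2 = np.maximum(s2, 1e-10)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return math.inf, np.full_like(s2, math.exp(e_mean))

    # invert trigamma(d0/2) = e_var by Newton on d0/2
    x = 0.5 + 1.0 / e_var
    for _ in range(50):
        f = special.polygamma(1, x) - e_var
        fp = special.polygamma(2, x)
        x_new = x - f / fp
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * x:
            x = x_new
            break
        x = x_new
    d0 = 2.0 * float(x)
    s0_2 = math.exp(e_mean + special.digamma(x) - math.log(x))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return d0, post


@dataclass
class DeOptions:
    prior_count: float = 0.125   # per group, stabilises log2FC at zeros
    min_prior_df: float = 0.0    # floor on the EB prior df (0 = data-driven)


def fit_nb_test(
    cm: CountMatrix,
    mutant: str,
    wildtype: str,
    options: DeOptions | None = None,
) -> pd.DataFrame:
    """Per-feature NB quasi-likelihood F-test of mutant vs wild-type.

    Returns a frame with log2FC (mutant over wild-type), raw ``P``, BH
    ``FDR`` and the mean normalised abundance. Features with zero counts in
    every sample are excluded (reported in the ``excluded`` attribute of the
    frame's ``attrs``).
    """
    opts = options or DeOptions()
    geno = cm.genotypes
    for lab in (mutant, wildtype):
        if (geno == lab).sum() < 2:
            raise ValueError(f"need >=2 replicates of genotype {lab!r}")
    use = geno.isin([mutant, wildtype])
    counts = cm.counts.loc[:, use.values]
    n_eff = cm.effective_lib_sizes[use.values].to_numpy(float)
    labels = geno[use.values]
    m_mut = (labels == mutant).to_numpy()
    m_wt = (labels == wildtype).to_numpy()
    groups = [m_mut, m_wt]

    y_all = counts.to_numpy(float)
    nonzero = y_all.sum(axis=1) > 0
    excluded = list(counts.index[~nonzero])
    feats = counts.index[nonzero]
    y_all = y_all[nonzero]

    n_samp = y_all.shape[1]
    df_res = n_samp - 2
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    mean_norm = (y_all / n_eff).mean(axis=1) * n_eff.mean()
    disp = np.array([estimate_dispersion(y, n_eff, groups) for y in y_all])
    trended = _trend_dispersion(mean_norm, disp)

    dev_alt = np.empty(len(y_all))
    dev_null = np.empty(len(y_all))
    log2fc = np.empty(len(y_all))
    for i, (y, phi) in enumerate(zip(y_all, trended)):
        q_mut = _fit_group_rate(y[m_mut], n_eff[m_mut], phi)
        q_wt = _fit_group_rate(y[m_wt], n_eff[m_wt], phi)
        q_all = _fit_group_rate(y, n_eff, phi)
        mu_alt = np.where(m_mut, q_mut, q_wt) * n_eff
        dev_alt[i] = _nb_deviance(y, mu_alt, phi)
        dev_null[i] = _nb_deviance(y, q_all * n_eff, phi)
        # prior-damped fold change on the counts-per-million scale, so a
        # common rescaling of counts and library sizes cancels exactly
        pc = opts.prior_count
        a_mut = q_mut * 1e6 + pc
        a_wt = q_wt * 1e6 + pc
        log2fc[i] = math.log2(a_mut / a_wt)

    s2 = dev_alt / df_res
    d0, s2_post = _squeeze_var(s2, df_res)
    if not math.isfinite(d0):
        d0 = 1e6
    d0 = max(d0, opts.min_prior_df)
    f_stat = np.maximum(dev_null - dev_alt, 0.0) / np.maximum(s2_post, 1e-10)
    df2 = df_res + min(d0, 1e6)
    p = stats.f.sf(f_stat, 1, df2)
    p = np.clip(p, 1e-300, 1.0)

    out = pd.DataFrame({
        "feature": feats,
        "log2FC": log2fc,
        "P": p,
        "FDR": bh_adjust(p),
        "mean_norm": mean_norm,
        "dispersion": trended,
    }).set_index("feature")
    out.attrs["excluded"] = excluded
    out.attrs["prior_df"] = d0
    out.attrs["residual_df"] = df_res
    return out


def min_fold_change(lfc_threshold: float) -> float:
    """Smallest detectable fold change implied by a |log2FC| threshold."""
    return 2.0 ** lfc_threshold


def classify_de(
    results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    use: str = "p",
    invert_contrast: bool = False,
) -> pd.DataFrame:
    """Attach up/down/ns calls.

    ``use="p"`` gates on the raw P value (default), ``"fdr"`` on the BH
    value. With ``invert_contrast=True`` the log2FC column is negated first, for
    pipelines whose contrast is wild-type relative to mutant.
    """
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if use not in ("p", "fdr"):
        raise ValueError("use must be 'p' or 'fdr'")
    out = results.copy()
    lfc = -out["log2FC"] if invert_contrast else out["log2FC"]
    out["log2FC"] = lfc
    crit = out["P"] if use == "p" else out["FDR"]
    call = np.where((lfc > lfc_threshold) & (crit < p_threshold), "up",
                    np.where((lfc < -lfc_threshold) & (crit < p_threshold), "down", "ns"))
    out["call"] = call
    return out
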