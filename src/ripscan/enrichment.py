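"""Enrichment calling from RIP-Seq count matrices.

The caller identifies transcripts bound by the tagged protein from gene-level
read counts of immunoprecipitated (IP) and input libraries under control (C),
wild-type (W) and, optionally, binding-deficient mutant (Wmut) conditions,
each in triplicate. Counts are transformed to log2 counts-per-million with
observation-level precision weights estimated from a fitted mean-variance
trend, then a weighted least-squares cell-means model is fit per gene and the
double-difference contrast

    (IP.W - IP.C) - (input.W - input.C)

is tested with an empirical-Bayes moderated t-statistic (gene-wise residual
variances shrunk toward a common prior fitted by method of moments on the
log variances). A transcript is called bound when its contrast estimate
exceeds 1 (i.e. more than 2-fold IP-specific enrichment) and its
Benjamini-Hochberg adjusted p-value is below 0.05. Dual-criterion calling
(vs both C and Wmut) and cross-cell-line intersection are provided for the
stricter experimental designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("sample", "cell_line", "condition", "fraction", "replicate")

CONTRAST_W_VS_C = "W_vs_C"
CONTRAST_W_VS_WMUT = "W_vs_Wmut"

_CONTRASTS = {
    # label -> {group: coefficient}; group key is "<condition>.<fraction>"
    CONTRAST_W_VS_C: {"W.IP": 1.0, "C.IP": -1.0, "W.input": -1.0, "C.input": 1.0},
    CONTRAST_W_VS_WMUT: {"W.IP": 1.0, "Wmut.IP": -1.0, "W.input": -1.0, "Wmut.input": 1.0},
}


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-design table: required columns, unique design cells."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table lacks columns: {missing}")
    key = ["cell_line", "condition", "fraction", "replicate"]
    dup = design.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"duplicate design cells: {design.loc[dup, key].values.tolist()}")
    bad = set(design["fraction"]) - {"input", "IP"}
    if bad:
        raise ValueError(f"unknown fractions {bad}; expected input/IP")
    return design


@dataclass
class CountMatrix:
    """Gene x sample nonnegative integer counts with a sample design."""

    counts: pd.DataFrame  # genes in rows, samples in columns
    design: pd.DataFrame
    lib_size: pd.Series | None = None

    def __post_init__(self) -> None:
        validate_design(self.design)
        if (self.counts.values < 0).any():
            r, c = np.argwhere(self.counts.values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        missing = set(self.design["sample"]) - set(self.counts.columns)
        if missing:
            raise ValueError(f"design samples absent from counts: {sorted(missing)}")
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).astype(float)
        if (self.lib_size <= 0).any():
            bad = self.lib_size.index[self.lib_size <= 0][0]
            raise ValueError(f"sample {bad!r} has non-positive library size")


@dataclass
class NormalizedExpression:
    """log2-CPM values with observation-level precision weights."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame
    design: pd.DataFrame
    pseudocount: float


@dataclass
class ContrastResult:
    """Per-gene moderated contrast: estimate, t, p, BH-adjusted p, call flag."""

    table: pd.DataFrame  # columns: log2FC, t, p, adj_p, enriched
    contrast: str
    df_prior: float = np.nan
    s2_prior: float = np.nan


@dataclass(frozen=True)
class TranscriptSet:
    """A named gene set with provenance (cell line / criterion)."""

    name: str
    genes: frozenset[str]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.genes)


def _groups(design: pd.DataFrame) -> pd.Series:
    return design["condition"].astype(str) + "." + design["fraction"].astype(str)


def normalize_counts(
    counts: CountMatrix, pseudocount: float = 0.5, span: float = 0.5
) -> NormalizedExpression:
    """log2-CPM transform with mean-variance precision weights.

    Each observation becomes
    ``log2((count + pseudocount) / (lib_size + 2*pseudocount) * 1e6)``.
    Gene-wise residual standard deviations from a group-means fit are
    square-rooted and regressed (lowess, span 0.5) on the mean log2 count;
    the trend is linearly interpolated at each observation's fitted log2
    count (clamped at the trend's ends) and inverted to the fourth power to
    give a precision weight. Genes with zero counts in every sample are
    dropped (count logged).

    Proportional columns (a sample scaled together with its library size)
    yield identical log2-CPM.
    """
    design = counts.design.set_index("sample").loc[counts.counts.columns].reset_index()
    raw = counts.counts.astype(float)
    all_zero = (raw.sum(axis=1) == 0)
    if all_zero.any():
        logger.info("dropping %d genes with zero counts in all samples", all_zero.sum())
        raw = raw.loc[~all_zero]
    lib = counts.lib_size.loc[raw.columns].astype(float)
    logcpm = np.log2((raw + pseudocount).div(lib + 2 * pseudocount, axis=1) * 1e6)

    groups = _groups(design).values
    y = logcpm.values
    n_genes, n_samples = y.shape
    uniq = sorted(set(groups))
    fitted = np.empty_like(y)
    resid_ss = np.zeros(n_genes)
    df_resid = n_samples - len(uniq)
    for g in uniq:
        mask = groups == g
        means = y[:, mask].mean(axis=1)
        fitted[:, mask] = means[:, None]
        resid_ss += ((y[:, mask] - means[:, None]) ** 2).sum(axis=1)
    sigma = np.sqrt(resid_ss / max(df_resid, 1))

    # mean log2 count per gene, on the scale of the trend's x axis
    mean_log_lib = np.mean(np.log2(lib.values + 2 * pseudocount))
    sx = y.mean(axis=1) + mean_log_lib - np.log2(1e6)
    sy = np.sqrt(sigma)
    if np.ptp(sy) < 1e-12 or np.ptp(sx) < 1e-8:
        # (near-)constant variance or abundance: flat trend, no smoothing
        tx = np.array([sx.min(), sx.max() + 1e-9])
        ty = np.maximum(np.full(2, float(np.mean(sy)) if len(sy) else 1.0), 1e-6)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):  # ties in sx
            trend = lowess(sy, sx, frac=span, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        if np.isnan(ty).any():  # degenerate smooth (heavy ties): fall back flat
            ty = np.where(np.isnan(ty), float(np.nanmean(ty)) if np.isfinite(
                np.nanmean(ty)) else float(np.mean(sy)), ty)
        ty = np.maximum(ty, 1e-6)

    fitted_logcount = fitted + (np.log2(lib.values + 2 * pseudocount) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)  # clamps outside the range
    weights = 1.0 / pred_sqrt_sd**4

    return NormalizedExpression(
        logcpm=logcpm,
        weights=pd.DataFrame(weights, index=logcpm.index, columns=logcpm.columns),
        design=design,
        pseudocount=pseudocount,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior on variances.

    Returns (prior df, prior variance). Operates on log variances: with
    z = log(s2), e = z - digamma(df/2) + log(df/2) has mean log(s2_prior)
    adjusted by the prior digamma term and excess variance trigamma(d0/2).
    """
    ok = s2 > 1e-15
    if ok.sum() < 2:
        return np.inf, float(max(np.mean(s2), 1e-12))
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = np.exp(emean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return float(df_prior), float(s2_prior)


def fit_contrast(
    norm: NormalizedExpression,
    contrast: str = CONTRAST_W_VS_C,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> ContrastResult:
    """Weighted cell-means fit and moderated double-difference test per gene.

    The design has one coefficient per (condition, fraction) cell; with
    precision weights w the fitted coefficient is the weighted group mean and
    the contrast c'beta is the difference of differences. Residual variances
    are shrunk toward the moments-fitted prior; the moderated t uses the
    augmented degrees of freedom (residual + prior) and a two-sided p.
    Calls (``enriched``) apply log2FC > ``lfc_threshold`` and BH-adjusted
    p < ``alpha``.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {sorted(_CONTRASTS)}")
    coef = _CONTRASTS[contrast]
    groups = _groups(norm.design).values
    uniq = sorted(set(groups))
    missing = [g for g in coef if g not in uniq]
    if missing:
        raise ValueError(f"design lacks cells required by contrast: {missing}")
    for g in coef:
        if (groups == g).sum() < 2:
            raise ValueError(f"design cell {g} has fewer than 2 replicates")

    y = norm.logcpm.values
    w = norm.weights.values
    n_genes, n_samples = y.shape
    df_resid = n_samples - len(uniq)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    beta = np.zeros((n_genes, len(uniq)))
    var_unscaled = np.zeros(n_genes)
    resid_ss = np.zeros(n_genes)
    for gi, g in enumerate(uniq):
        mask = groups == g
        wg = w[:, mask]
        sw = wg.sum(axis=1)
        mu = (wg * y[:, mask]).sum(axis=1) / sw
        beta[:, gi] = mu
        resid_ss += (wg * (y[:, mask] - mu[:, None]) ** 2).sum(axis=1)
        c = coef.get(g, 0.0)
        if c:
            var_unscaled += c**2 / sw
    estimate = sum(coef[g] * beta[:, uniq.index(g)] for g in coef)
    s2 = resid_ss / df_resid

    df_prior, s2_prior = _squeeze_var(s2, df_resid)
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
        df_total = 1e6
    else:
        s2_post = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
        df_total = df_resid + df_prior
    se = np.sqrt(s2_post * var_unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, estimate / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * t_dist.sf(np.abs(t_stat), df=min(df_total, 1e6))
    adj = adjust_bh(p)
    enriched = (estimate > lfc_threshold) & (adj < alpha)

    table = pd.DataFrame(
        {
            "log2FC": estimate,
            "t": t_stat,
            "p": p,
            "adj_p": adj,
            "enriched": enriched,
        },
        index=norm.logcpm.index,
    )
    return ContrastResult(table=table, contrast=contrast, df_prior=df_prior, s2_prior=s2_prior)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enriched(
    res: ContrastResult,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    name: str = "enriched",
) -> TranscriptSet:
    """Genes with log2FC strictly above the threshold and adjusted p strictly below alpha."""
    t = res.table
    mask = (t["log2FC"] > lfc_threshold) & (t["adj_p"] < alpha)
    return TranscriptSet(
        name=name,
        genes=frozenset(t.index[mask]),
        provenance=(res.contrast, f"lfc>{lfc_threshold}", f"adj_p<{alpha}"),
    )


def call_enriched_dual(
    res_vs_c: ContrastResult,
    res_vs_wmut: ContrastResult,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    name: str = "enriched_dual",
) -> TranscriptSet:
    """Bound only if enriched both vs the empty control and vs the binding-dead mutant."""
    if set(res_vs_c.table.index) != set(res_vs_wmut.table.index):
        raise ValueError("contrast results cover different gene universes")
    a = call_enriched(res_vs_c, lfc_threshold, alpha)
    b = call_enriched(res_vs_wmut, lfc_threshold, alpha)
    return TranscriptSet(
        name=name,
        genes=a.genes & b.genes,
        provenance=a.provenance + b.provenance,
    )


def intersect_sets(a: TranscriptSet, b: TranscriptSet, name: str | None = None) -> TranscriptSet:
    """Set intersection with combined provenance (e.g. across cell lines)."""
    return TranscriptSet(
        name=name or f"{a.name}&{b.name}",
        genes=a.genes & b.genes,
        provenance=a.provenance + b.provenance,
    )
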