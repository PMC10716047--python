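"""Negative-binomial depletion statistics for pooled CRISPR screens.

Counts are normalized with ratio-median (median-of-ratios) size factors
anchored on negative-control guides, per-row dispersions are estimated by
method of moments on within-condition residuals, and each row gets a Wald
test on the log2 fold change between the two conditions (day 21 vs day 0 in
the screen; the same machinery serves gene-level RNA-seq contrasts).

The module exposes both the individual operations and a statsmodels-style
``ScreenDepletionModel`` whose :meth:`~ScreenDepletionModel.fit` returns a
``ScreenDepletionResults`` object carrying the per-row statistics, the size
factors and dispersions, and a ``summary()`` table.

Divergences from the versioned external framework the field commonly uses:
log2 fold changes are unshrunk MLEs and the dispersion estimator has no
empirical-Bayes trend; at screen-typical depths these are minor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "control_size_factors",
    "estimate_dispersion",
    "pooled_dispersion",
    "moderate_dispersion",
    "nb_wald_test",
    "ScreenDepletionModel",
    "ScreenDepletionResults",
]

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8
_PSEUDO_MEAN = 0.5  # added to each condition's normalized mean when one is 0


def _check_counts(counts: pd.DataFrame) -> None:
    values = counts.to_numpy()
    if np.isnan(values).any():
        raise ValueError("count matrix contains missing cells")
    if (values < 0).any():
        raise ValueError("counts must be non-negative")


def control_size_factors(
    counts: pd.DataFrame, control_rows=None
) -> pd.Series:
    """Ratio-median size factors anchored on control rows.

    For each sample j the factor is the median over control rows i of
    ``count_ij / geomean_k(count_ik)``, using only control rows positive in
    every sample, then divided by the median factor so the typical sample
    sits at 1.  That last step makes the factors exactly scale-equivariant:
    multiplying one (minority) sample's counts by c multiplies its factor by
    c and leaves the others untouched.  With ``control_rows=None`` every row
    is a control (the all-rows median-of-ratios variant used for RNA-seq).
    """
    _check_counts(counts)
    sub = counts if control_rows is None else counts.loc[sorted(control_rows)]
    values = sub.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no usable controls: no control row positive in all samples")
    values = values[usable]
    log_geomean = np.log(values).mean(axis=1)
    ratios = np.exp(np.log(values) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.median(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame, size_factors: pd.Series, conditions: pd.Series
) -> pd.Series:
    """Per-row NB dispersion by method of moments on normalized counts.

    Within each condition with >= 2 replicates, alpha_c = (s^2 - mu)/mu^2;
    these are pooled across conditions weighted by residual degrees of
    freedom, clipped below at 0 and floored at 1e-8.  All-zero rows get 0.
    """
    norm = counts.to_numpy(dtype=float) / size_factors.loc[counts.columns].to_numpy()
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for cond in conditions.unique():
        cols = np.flatnonzero((conditions == cond).to_numpy())
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        w = len(cols) - 1
        num += w * alpha_c
        den += w
    if not den.any():
        raise ValueError("need >= 2 replicates in at least one condition")
    alpha = np.maximum(num / den, 0.0)
    expressed = norm.sum(axis=1) > 0
    alpha = np.where(expressed, np.maximum(alpha, _DISPERSION_FLOOR), 0.0)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def pooled_dispersion(
    counts: pd.DataFrame, size_factors: pd.Series, conditions: pd.Series
) -> float:
    """Matrix-wide NB dispersion by the pooled moment ratio.

    alpha = sum_i w_i (s_i^2 - mu_i) / sum_i w_i mu_i^2 over within-condition
    moments, weighted by residual degrees of freedom.  The ratio form is far
    less biased than averaging per-row estimates and anchors the shrinkage in
    :func:`moderate_dispersion`.
    """
    norm = counts.to_numpy(dtype=float) / size_factors.loc[counts.columns].to_numpy()
    num = 0.0
    den = 0.0
    for cond in conditions.unique():
        cols = np.flatnonzero((conditions == cond).to_numpy())
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = len(cols) - 1
        num += w * (s2 - mu).sum()
        den += w * (mu**2).sum()
    if den <= 0:
        return 0.0
    return float(max(num / den, 0.0))


def moderate_dispersion(
    raw: pd.Series,
    counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions: pd.Series,
    prior_df: float = 50.0,
) -> pd.Series:
    """Shrink noisy per-row dispersions toward the pooled matrix value.

    With only a handful of replicates the per-row moment estimate has far
    too much sampling noise to plug into a Wald test (rows whose dispersion
    is underestimated get overconfident standard errors, inflating the
    type-I error well above nominal).  Each expressed row is therefore
    blended as ``w * raw + (1 - w) * pooled`` with ``w = resid_df /
    (resid_df + prior_df)`` — a deliberately strong prior given the few
    residual degrees of freedom a screen design provides.  All-zero rows
    keep dispersion 0.
    """
    resid_df = sum(
        max((conditions == c).sum() - 1, 0) for c in conditions.unique()
    )
    pooled = pooled_dispersion(counts, size_factors, conditions)
    w = resid_df / (resid_df + prior_df)
    blended = w * raw.to_numpy() + (1.0 - w) * pooled
    out = np.where(raw.to_numpy() > 0, np.maximum(blended, _DISPERSION_FLOOR), 0.0)
    return pd.Series(out, index=raw.index, name="dispersion")


def _nb_condition_mean(K: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-row fitted condition mean on the normalized scale.

    The mean of the normalized counts k_j/s_j is the NB maximum-likelihood
    mean when all samples share one size factor (the score equation
    sum_j (y_j - q)/(1 + alpha*q) = 0 gives q = mean(y)); fitting on the
    normalized scale keeps every downstream statistic an exact function of
    the normalized counts, so rescaling one sample is absorbed entirely.
    """
    return (K / s[None, :]).mean(axis=1)


def _nb_log_mean_information(
    q: np.ndarray, n_samples: int, alpha: np.ndarray
) -> np.ndarray:
    """Fisher information for eta = ln q on the normalized scale.

    I = n * q / (1 + alpha * q), i.e. each sample contributes at the common
    normalized mean.  Evaluating at the per-sample means s_j*q instead would
    make the p-value depend on the overall scale of one sample's counts,
    which control-anchored normalization is supposed to absorb exactly.
    """
    return n_samples * q / (1.0 + alpha * q)


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    conditions: pd.Series,
    contrast: tuple[str, str] = ("day21", "day0"),
    t_df: float | None = None,
) -> pd.DataFrame:
    """Per-row NB Wald test of ``contrast[0]`` vs ``contrast[1]``.

    Returns a DataFrame with columns (base_mean, log2fc, se, z, p, fdr).
    Rows with zero base mean are reported but excluded from testing and from
    the BH denominator.  When one condition's fitted mean is zero, 0.5 is
    added to both normalized means before the ratio (and the information is
    evaluated at the stabilized means).

    ``t_df`` selects the reference distribution for the Wald statistic:
    ``None`` uses the standard normal; a finite value uses Student's t with
    that many degrees of freedom, accounting for the sampling noise of the
    plug-in dispersion (pass the moderated df, residual + prior, when the
    dispersions come from :func:`moderate_dispersion`).
    """
    _check_counts(counts)
    num_cond, den_cond = contrast
    for cond in contrast:
        if (conditions == cond).sum() < 1:
            raise ValueError(f"condition {cond!r} has no samples")
    if len(set(conditions.loc[counts.columns])) < 2:
        raise ValueError("degenerate design: need two conditions")

    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)
    K = counts.to_numpy(dtype=float)
    cond_arr = conditions.loc[counts.columns].to_numpy()

    cols_num = np.flatnonzero(cond_arr == num_cond)
    cols_den = np.flatnonzero(cond_arr == den_cond)
    q_num = _nb_condition_mean(K[:, cols_num], s[cols_num])
    q_den = _nb_condition_mean(K[:, cols_den], s[cols_den])

    needs_pseudo = (q_num == 0) | (q_den == 0)
    q_num_st = np.where(needs_pseudo, q_num + _PSEUDO_MEAN, q_num)
    q_den_st = np.where(needs_pseudo, q_den + _PSEUDO_MEAN, q_den)
    log2fc = np.log2(q_num_st / q_den_st)

    info_num = _nb_log_mean_information(q_num_st, len(cols_num), alpha)
    info_den = _nb_log_mean_information(q_den_st, len(cols_den), alpha)
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / info_num + 1.0 / info_den) / _LN2
    z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    if t_df is None:
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = 2.0 * stats.t.sf(np.abs(z), df=t_df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    base_mean = (K / s[None, :]).mean(axis=1)
    tested = base_mean > 0
    fdr = np.full(len(p), np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])
    p = np.where(tested, p, np.nan)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se, np.nan),
            "z": np.where(tested, z, np.nan),
            "p": p,
            "fdr": fdr,
        },
        index=counts.index,
    )


@dataclass
class ScreenDepletionResults:
    """Fitted screen statistics: per-guide table plus the fit internals."""

    stats: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    contrast: tuple[str, str]
    model: "ScreenDepletionModel"

    def depleted(
        self, lfc_max: float = -np.log2(1.5), p_max: float = 0.05
    ) -> pd.Index:
        """Rows significantly depleted: log2fc <= lfc_max and p < p_max."""
        df = self.stats
        mask = (df["log2fc"] <= lfc_max) & (df["p"] < p_max)
        return df.index[mask.fillna(False)]

    def summary(self, top: int = 10) -> str:
        df = self.stats.dropna(subset=["p"]).sort_values("p")
        lines = [
            "Screen depletion test (NB Wald)",
            "=" * 54,
            f"rows tested: {int(self.stats['p'].notna().sum())} / {len(self.stats)}",
            f"contrast: {self.contrast[0]} vs {self.contrast[1]}",
            f"size factors: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.size_factors.items()),
            f"median dispersion: {float(self.dispersions.median()):.4f}",
            f"depleted (log2FC <= -log2(1.5), p < 0.05): "
            f"{len(self.depleted())}",
            "",
            df.head(top).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class ScreenDepletionModel:
    """Two-condition NB depletion model for a guides x samples count matrix.

    Parameters
    ----------
    counts
        Integer count matrix, rows = guides (or genes), columns = samples.
    conditions
        Mapping/Series sample -> condition label.
    control_rows
        Row ids used to anchor the size factors (negative-control guides);
        ``None`` uses every row (RNA-seq style).
    contrast
        (numerator, denominator) condition labels; default day21 vs day0.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        conditions,
        control_rows=None,
        contrast: tuple[str, str] = ("day21", "day0"),
    ):
        _check_counts(counts)
        self.counts = counts
        self.conditions = pd.Series(conditions).loc[counts.columns]
        for cond, n in self.conditions.value_counts().items():
            if cond in contrast and n < 2:
                raise ValueError(f"condition {cond!r} needs >= 2 samples, has {n}")
        self.control_rows = control_rows
        self.contrast = contrast

    @classmethod
    def from_tsv(
        cls,
        counts_path: str,
        samples_path: str,
        controls_path: str | None = None,
        contrast: tuple[str, str] = ("day21", "day0"),
    ) -> "ScreenDepletionModel":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        conditions = pd.Series(
            samples["condition"].to_numpy(), index=samples["sample"].astype(str)
        )
        control_rows = None
        if controls_path is not None:
            with open(controls_path) as fh:
                control_rows = [ln.strip() for ln in fh if ln.strip()]
        return cls(counts, conditions, control_rows=control_rows, contrast=contrast)

    def fit(self, dispersion_prior_df: float = 50.0) -> ScreenDepletionResults:
        size_factors = control_size_factors(self.counts, self.control_rows)
        raw = estimate_dispersion(self.counts, size_factors, self.conditions)
        dispersions = moderate_dispersion(
            raw, self.counts, size_factors, self.conditions,
            prior_df=dispersion_prior_df,
        )
        resid_df = sum(
            max((self.conditions == c).sum() - 1, 0)
            for c in self.conditions.unique()
        )
        stats_df = nb_wald_test(
            self.counts, size_factors, dispersions, self.conditions,
            self.contrast, t_df=resid_df + dispersion_prior_df,
        )
        return ScreenDepletionResults(
            stats=stats_df,
            size_factors=size_factors,
            dispersions=dispersions,
            contrast=self.contrast,
            model=self,
        )
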