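"""Core statistics for label-free differential enrichment.

Left-censored (MNAR) missingness is the dominant missing-data mechanism in
LC-MS label-free quantification: peptides fall below the detection limit,
so missing cells are biased toward low abundance.  The stack implemented
here mirrors the standard proteomics DEA toolchain:

* ``minprob_impute`` — draw missing cells from a Gaussian centered at a low
  quantile of the sample's observed log2 intensities (the "MinProb" model).
* ``moderated_t_test`` — two-sample t-test with empirical-Bayes variance
  moderation: per-row variances are shrunk toward a prior estimated across
  rows by moment-matching on the log variances.
* ``bh_adjust`` — Benjamini–Hochberg step-up FDR adjustment.
* ``StabilityDEA`` — because single imputations are random, imputation is
  repeated many times and a protein is called differentially enriched only
  when it passes the fold-change and adjusted-p thresholds in more than a
  configured share (default 80%) of iterations.
* ``iqr_outlier_test`` — the forward/reverse label-swap outlier rule for
  chemically labeled (dimethyl) ratio designs: a protein is significant
  only if its log ratio exceeds Q3 + 1.5*IQR (or falls below Q1 - 1.5*IQR)
  in the forward run and crosses the opposite threshold in the reverse run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .io_tables import QuantMatrix

__all__ = [
    "MinProbConfig",
    "ModTConfig",
    "minprob_impute",
    "moderated_t_test",
    "bh_adjust",
    "StabilityDEA",
    "StabilityDEAResults",
    "stability_dea",
    "IQROutlierResult",
    "iqr_outlier_test",
]


@dataclass(frozen=True)
class MinProbConfig:
    """MinProb imputation parameters.

    ``q`` positions the censoring center at the q-quantile of each sample's
    observed log2 intensities; the imputation s.d. is ``tune_sigma`` times
    the median of the per-row observed standard deviations.
    """

    q: float = 0.01
    tune_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.q < 0.5:
            raise ValueError(f"q must be in (0, 0.5), got {self.q}")
        if self.tune_sigma <= 0:
            raise ValueError(f"tune_sigma must be positive, got {self.tune_sigma}")


@dataclass(frozen=True)
class ModTConfig:
    """Moderated t-test configuration.

    ``prior_df`` / ``prior_var`` fix the empirical-Bayes prior; when ``None``
    both are estimated from the data by moment-matching on log variances.
    ``prior_df = 0`` recovers the ordinary equal-variance two-sample t-test.
    """

    prior_df: float | None = None
    prior_var: float | None = None

    def __post_init__(self) -> None:
        if self.prior_df is not None and self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.prior_var is not None and self.prior_var <= 0:
            raise ValueError("prior_var must be > 0")


def _impute_array(
    values: np.ndarray,
    q: float,
    tune_sigma: float,
    rng: np.random.Generator,
    sample_names=None,
) -> np.ndarray:
    """MinProb-fill NaN cells of a rows x samples log2 array, column-wise."""
    out = values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return out
    # Imputation width: median over rows of the per-row observed s.d.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_sd = np.nanstd(values, axis=1, ddof=1)
    row_sd = row_sd[np.isfinite(row_sd) & (row_sd > 0)]
    sd = tune_sigma * (np.median(row_sd) if row_sd.size else 0.3)
    for j in range(values.shape[1]):
        col_missing = mask[:, j]
        if not col_missing.any():
            continue
        observed = values[~np.isnan(values[:, j]), j]
        if observed.size < 3:
            name = sample_names[j] if sample_names is not None else f"column {j}"
            raise ValueError(
                f"sample {name!r} has fewer than 3 observed values; "
                "its censoring center is undefined"
            )
        center = np.quantile(observed, q)
        out[col_missing, j] = rng.normal(center, sd, size=int(col_missing.sum()))
    return out


def minprob_impute(
    matrix: QuantMatrix, cfg: MinProbConfig | None = None, seed: int = 0
) -> QuantMatrix:
    """Impute missing cells by the MinProb model; observed cells untouched.

    Per sample, missing cells are replaced by independent draws from a
    Gaussian centered at the ``cfg.q`` quantile of that sample's observed
    log2 values.  Deterministic under ``seed``.
    """
    cfg = cfg or MinProbConfig()
    rng = np.random.default_rng(seed)
    filled = _impute_array(
        matrix.values.to_numpy(float),
        cfg.q,
        cfg.tune_sigma,
        rng,
        sample_names=list(matrix.values.columns),
    )
    values = pd.DataFrame(filled, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (prior_df, prior_var) from per-row variances.

    Under the hierarchical model the log variances follow a scaled log-F
    distribution; matching mean and variance of ``log s2`` yields the prior.
    Returns ``prior_df = inf`` when the observed spread is no larger than
    the sampling noise alone.
    """
    pos = s2[np.isfinite(s2) & (s2 > 0)]
    if pos.size == 0:
        raise ValueError("zero variance in every row; prior estimation impossible")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if pos.size < 2:
        return np.inf, float(np.exp(e.mean()))
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def _moderated_t_arrays(
    a: np.ndarray, b: np.ndarray, cfg: ModTConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t on two rows x replicates arrays. Returns (lfc, t, p, df)."""
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 replicates")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = mean_a - mean_b
    df_g = float(na + nb - 2)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_g

    d0 = cfg.prior_df
    s02 = cfg.prior_var
    if d0 is None:
        d0, s02_est = _estimate_prior(s2, df_g)
        if s02 is None:
            s02 = s02_est
    elif d0 > 0 and s02 is None:
        _, s02 = _estimate_prior(s2, df_g)

    if d0 == 0:
        s2_post = s2
        df_total = df_g
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_g * s2) / (d0 + df_g)
        df_total = d0 + df_g

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.where((lfc == 0) & (se == 0), 1.0, p)
    return lfc, t, p, np.full_like(lfc, df_total)


def moderated_t_test(
    matrix: QuantMatrix,
    group_a: str,
    group_b: str,
    cfg: ModTConfig | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per row.

    ``matrix`` must be complete (imputed) over the two conditions.  Returns
    a frame with ``log2fc`` (mean_a - mean_b), ``t``, ``p`` and ``df``.
    """
    cfg = cfg or ModTConfig()
    cols_a = matrix.samples_for(group_a)
    cols_b = matrix.samples_for(group_b)
    a = matrix.values[cols_a].to_numpy(float)
    b = matrix.values[cols_b].to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix has missing cells; impute before testing")
    lfc, t, p, df = _moderated_t_arrays(a, b, cfg)
    return pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "df": df}, index=matrix.values.index
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("p must be a non-empty 1-D sequence")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class StabilityDEAResults:
    """Differential-enrichment result across repeated imputations.

    ``frame`` carries, per protein: median and mean log2 fold change and
    adjusted p across iterations, the stability fraction (share of
    iterations passing both thresholds), and the ``significant`` flag
    (fraction strictly greater than the stability threshold).
    """

    frame: pd.DataFrame
    n_iter: int
    fc: float
    alpha: float
    stability: float
    group_a: str
    group_b: str

    @property
    def significant_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Imputation-stability differential enrichment",
            f"  groups: {self.group_a} vs {self.group_b}",
            f"  proteins tested: {len(f)}   iterations: {self.n_iter}",
            f"  thresholds: FC > {self.fc}, BH-adjusted p < {self.alpha}, "
            f"stable in > {100 * self.stability:.0f}% of iterations",
            f"  significant: {int(f['significant'].sum())}",
        ]
        sig = f[f["significant"]].sort_values("median_log2fc", ascending=False)
        for pid, row in sig.iterrows():
            lines.append(
                f"    {pid}: median log2FC {row['median_log2fc']:+.2f}, "
                f"median p.adj {row['median_p_adj']:.2e}, "
                f"stability {row['stability_fraction']:.2f}"
            )
        return "\n".join(lines)


class StabilityDEA:
    """Differential enrichment with the repeated-imputation stability rule.

    Only proteins detected in all replicates of at least one of the two
    conditions are tested.  Each iteration draws a fresh MinProb imputation,
    applies the moderated t-test and BH adjustment, and records which
    proteins pass ``|log2FC| > log2(fc)`` with ``p.adj < alpha``; a protein
    is flagged significant when it passes in more than ``stability`` of the
    iterations.
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        group_a: str,
        group_b: str,
        fc: float = 1.5,
        alpha: float = 0.05,
        stability: float = 0.8,
        minprob: MinProbConfig | None = None,
        modt: ModTConfig | None = None,
    ) -> None:
        if fc <= 1 or not 0 < alpha < 1 or not 0 < stability < 1:
            raise ValueError("require fc > 1, 0 < alpha < 1, 0 < stability < 1")
        self.matrix = matrix
        self.group_a = group_a
        self.group_b = group_b
        self.fc = fc
        self.alpha = alpha
        self.stability = stability
        self.minprob = minprob or MinProbConfig()
        self.modt = modt or ModTConfig()
        cols_a = matrix.samples_for(group_a)
        cols_b = matrix.samples_for(group_b)
        observed = ~matrix.values.isna()
        keep = observed[cols_a].all(axis=1) | observed[cols_b].all(axis=1)
        self._cols_a = cols_a
        self._cols_b = cols_b
        self._rows = matrix.values.index[keep]

    def fit(self, n_iter: int = 1000, seed: int = 0) -> StabilityDEAResults:
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        cols = self._cols_a + self._cols_b
        sub = self.matrix.values.loc[self._rows, cols].to_numpy(float)
        na = len(self._cols_a)
        log2_fc = np.log2(self.fc)
        streams = np.random.SeedSequence(seed).spawn(n_iter)

        n_rows = sub.shape[0]
        lfc_all = np.empty((n_iter, n_rows))
        padj_all = np.empty((n_iter, n_rows))
        hits = np.zeros(n_rows)
        for it in range(n_iter):
            rng = np.random.default_rng(streams[it])
            filled = _impute_array(sub, self.minprob.q, self.minprob.tune_sigma, rng, cols)
            lfc, _, p, _ = _moderated_t_arrays(filled[:, :na], filled[:, na:], self.modt)
            padj = bh_adjust(p)
            lfc_all[it] = lfc
            padj_all[it] = padj
            hits += ((padj < self.alpha) & (np.abs(lfc) > log2_fc)).astype(float)

        fraction = hits / n_iter
        frame = pd.DataFrame(
            {
                "median_log2fc": np.median(lfc_all, axis=0),
                "mean_log2fc": lfc_all.mean(axis=0),
                "median_p_adj": np.median(padj_all, axis=0),
                "mean_p_adj": padj_all.mean(axis=0),
                "stability_fraction": fraction,
                "significant": fraction > self.stability,
            },
            index=self._rows,
        )
        return StabilityDEAResults(
            frame=frame,
            n_iter=n_iter,
            fc=self.fc,
            alpha=self.alpha,
            stability=self.stability,
            group_a=self.group_a,
            group_b=self.group_b,
        )


def stability_dea(
    matrix: QuantMatrix,
    group_a: str,
    group_b: str,
    n_iter: int = 1000,
    fc: float = 1.5,
    alpha: float = 0.05,
    stability: float = 0.8,
    seed: int = 0,
    minprob: MinProbConfig | None = None,
) -> StabilityDEAResults:
    """Functional wrapper around :class:`StabilityDEA`."""
    model = StabilityDEA(
        matrix, group_a, group_b, fc=fc, alpha=alpha, stability=stability, minprob=minprob
    )
    return model.fit(n_iter=n_iter, seed=seed)


@dataclass
class IQROutlierResult:
    """Outcome of the forward/reverse IQR outlier test.

    ``significant`` maps protein id to direction ("up" means enriched in
    the condition of interest: above the upper threshold in the forward
    run and below the lower threshold in the reverse run).  ``n_unpaired``
    counts proteins present in only one of the two runs.
    """

    significant: dict[str, str]
    n_unpaired: int
    forward_thresholds: tuple[float, float]
    reverse_thresholds: tuple[float, float]


def _iqr_thresholds(values: np.ndarray, k: float) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def iqr_outlier_test(
    forward_ratios: dict[str, float] | pd.Series,
    reverse_ratios: dict[str, float] | pd.Series,
    k: float = 1.5,
) -> IQROutlierResult:
    """Label-swap outlier test on forward/reverse log2 ratio maps.

    Thresholds are computed independently per run from that run's full
    ratio distribution (quartiles by linear interpolation).  Ratios are
    stored in label order, so a true change flips sign between the runs:
    a protein is significant only if it is above ``Q3 + k*IQR`` in one run
    and below ``Q1 - k*IQR`` in the other.
    """
    fwd = pd.Series(forward_ratios, dtype=float)
    rev = pd.Series(reverse_ratios, dtype=float)
    if fwd.empty or rev.empty:
        raise ValueError("both runs must be non-empty")
    lo_f, hi_f = _iqr_thresholds(fwd.to_numpy(), k)
    lo_r, hi_r = _iqr_thresholds(rev.to_numpy(), k)
    paired = fwd.index.intersection(rev.index)
    n_unpaired = len(fwd.index.symmetric_difference(rev.index))

    significant: dict[str, str] = {}
    for pid in paired:
        f, r = fwd[pid], rev[pid]
        if f > hi_f and r < lo_r:
            significant[pid] = "up"
        elif f < lo_f and r > hi_r:
            significant[pid] = "down"
    return IQROutlierResult(
        significant=significant,
        n_unpaired=n_unpaired,
        forward_thresholds=(lo_f, hi_f),
        reverse_thresholds=(lo_r, hi_r),
    )
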