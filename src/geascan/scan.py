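"""Per-SNP environmental association scan with a MAF-matched empirical null.

The scan correlates each SNP's per-population allele frequency with an environmental
variable (Kendall tau-b, tie-corrected normal p).  Because allele-frequency spectra are
shaped by demography as well as selection, raw p-values are inflated; each SNP is
therefore also assigned a percentile rank of |tau| among all SNPs of similar minor
allele frequency (the MAF-matched empirical null).  A SNP is called significant only if
it passes both a Bonferroni-corrected p threshold and the rank cutoff.

:class:`EnvAssociationScan` packages the scan as a scikit-learn style univariate
feature selector: ``X`` is a populations x SNPs matrix, ``y`` the per-population
environment, and ``transform`` keeps the significant SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, ConstantInputError, ValidationError
from .io import EnvVector, FrequencyMatrix
from .kendall import _tau_p_from_stats, _tie_moments, kendall_tau_b, tau_scan

__all__ = [
    "ScanConfig",
    "EnvAssociationScan",
    "compute_maf",
    "scan_snps",
    "maf_matched_rank",
    "call_significant",
]

RESULT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "tau",
    "p_value",
    "maf",
    "n_used",
    "window_n",
    "rank",
    "widened_window",
    "bonferroni_sig",
    "rank_sig",
    "final_sig",
]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the scan.

    alpha : family-wise Bonferroni level (0.05 genome-wide; 0.01 for list-restricted runs).
    rank_cutoff : percentile-rank threshold of |tau| among MAF peers (default 0.99).
    maf_window : MAF half-width defining "similar MAF" (default 0.01, the 1% range).
    min_window : minimum MAF-window occupancy; sparse windows are widened to the
        nearest-MAF neighbours until this is reached.
    min_populations : minimum pairwise-complete populations per SNP; below this the
        normal approximation of tau is not trusted and the SNP is skipped.
    """

    alpha: float = 0.05
    rank_cutoff: float = 0.99
    maf_window: float = 0.01
    min_window: int = 50
    min_populations: int = 10
    use_partial: bool = False
    covariate: EnvVector | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.rank_cutoff < 1.0:
            raise ConfigurationError(f"rank_cutoff must be in (0, 1), got {self.rank_cutoff}")
        if self.maf_window <= 0:
            raise ConfigurationError(f"maf_window must be > 0, got {self.maf_window}")
        if self.min_window < 2:
            raise ConfigurationError(f"min_window must be >= 2, got {self.min_window}")
        if self.use_partial and self.covariate is None:
            raise ConfigurationError("use_partial requires a covariate")


def compute_maf(freqs) -> float:
    """Minor allele frequency of one SNP: fold of the unweighted across-population mean.

    The mean of the non-missing coded-allele frequencies is folded to ``min(m, 1-m)``,
    so the result is in [0, 0.5] and invariant to which allele was coded.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.isnan(freqs).all():
        raise ValidationError("cannot compute MAF: all populations missing")
    m = float(np.nanmean(freqs))
    return min(m, 1.0 - m)


def _maf_rank_core(
    maf: np.ndarray, abs_tau: np.ndarray, maf_window: float, min_window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """window_n, midrank percentile of |tau| among MAF peers, and widened flags.

    The window of SNP i is every SNP j with |MAF_j - MAF_i| <= maf_window (self
    included); under-occupied windows are widened symmetrically by nearest MAF
    distance.  rank_i = (#{|tau_j| < |tau_i|} + 0.5 #{|tau_j| = |tau_i|, j != i})
    / (window_n - 1).
    """
    m = maf.size
    if m < min_window:
        raise ConfigurationError(
            f"only {m} SNPs with defined tau, fewer than min_window={min_window}"
        )
    order = np.argsort(maf, kind="stable")
    maf_s = maf[order]
    at_s = abs_tau[order]
    window_n = np.empty(m, dtype=np.int64)
    rank = np.empty(m)
    widened = np.zeros(m, dtype=bool)
    for i in range(m):
        lo = int(np.searchsorted(maf_s, maf_s[i] - maf_window, side="left"))
        hi = int(np.searchsorted(maf_s, maf_s[i] + maf_window, side="right"))
        while hi - lo < min_window:
            widened[i] = True
            d_left = maf_s[i] - maf_s[lo - 1] if lo > 0 else np.inf
            d_right = maf_s[hi] - maf_s[i] if hi < m else np.inf
            if d_left <= d_right:
                lo -= 1
            else:
                hi += 1
        win = at_s[lo:hi]
        ti = at_s[i]
        less = int(np.count_nonzero(win < ti))
        equal = int(np.count_nonzero(win == ti)) - 1
        window_n[i] = hi - lo
        rank[i] = (less + 0.5 * equal) / (window_n[i] - 1)
    # undo the MAF sort
    inv = np.empty(m, dtype=np.int64)
    inv[order] = np.arange(m)
    return window_n[inv], rank[inv], widened[inv]


def _partial_tau_scan(X: np.ndarray, y: np.ndarray, z: np.ndarray, min_n: int):
    """Per-row partial tau given a covariate, p by plugging partial tau into the
    tie-corrected normal approximation of the (x, y) pair."""
    n_snps = X.shape[0]
    tau = np.full(n_snps, np.nan)
    p = np.full(n_snps, np.nan)
    n_used = np.zeros(n_snps, dtype=np.int64)
    skip = np.full(n_snps, None, dtype=object)
    t_yz, _ = kendall_tau_b(y, z)
    for k in range(n_snps):
        row = X[k]
        keep = ~np.isnan(row)
        xk, yk, zk = row[keep], y[keep], z[keep]
        n_used[k] = xk.size
        if xk.size < min_n:
            skip[k] = "too_few_populations"
            continue
        if np.unique(xk).size < 2:
            skip[k] = "constant_frequency"
            continue
        t_xy, _ = kendall_tau_b(xk, yk)
        t_xz, _ = kendall_tau_b(xk, zk)
        tyz = t_yz if keep.all() else kendall_tau_b(yk, zk)[0]
        denom_sq = (1.0 - t_xz**2) * (1.0 - tyz**2)
        if denom_sq <= 0:
            skip[k] = "degenerate_covariate"
            continue
        t_part = (t_xy - t_xz * tyz) / np.sqrt(denom_sq)
        xm, ym = _tie_moments(xk), _tie_moments(yk)
        n = xk.size
        n0 = n * (n - 1) / 2.0
        s_equiv = t_part * np.sqrt((n0 - xm[0]) * (n0 - ym[0]))
        tau[k], p[k] = _tau_p_from_stats(s_equiv, n, xm, ym)
    return tau, p, n_used, skip


class EnvAssociationScan(BaseEstimator):
    """Univariate genotype-environment association selector.

    Parameters mirror :class:`ScanConfig`.  ``fit(X, y)`` expects ``X`` of shape
    (n_populations, n_snps) with allele frequencies (NaN = missing) and ``y`` of
    length n_populations holding the environmental value (country-level values
    broadcast to populations, hence tied).

    Attributes (per SNP, NaN / False where the SNP was skipped)
    ----------
    tau_, pvalue_, maf_, n_used_, window_n_, rank_, widened_window_,
    bonferroni_sig_, rank_sig_, final_sig_, skip_reason_, n_tests_
    """

    def __init__(
        self,
        alpha: float = 0.05,
        rank_cutoff: float = 0.99,
        maf_window: float = 0.01,
        min_window: int = 50,
        min_populations: int = 10,
        n_tests: int | None = None,
        use_partial: bool = False,
        covariate=None,
    ):
        self.alpha = alpha
        self.rank_cutoff = rank_cutoff
        self.maf_window = maf_window
        self.min_window = min_window
        self.min_populations = min_populations
        self.n_tests = n_tests
        self.use_partial = use_partial
        self.covariate = covariate

    def _config(self) -> ScanConfig:
        cov = self.covariate
        if cov is not None and not isinstance(cov, EnvVector):
            cov = EnvVector(np.asarray(cov, dtype=float), "covariate")
        return ScanConfig(
            alpha=self.alpha,
            rank_cutoff=self.rank_cutoff,
            maf_window=self.maf_window,
            min_window=self.min_window,
            min_populations=self.min_populations,
            use_partial=self.use_partial,
            covariate=cov,
        )

    def fit(self, X, y):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (populations x SNPs)")
        if y.shape != (X.shape[0],):
            raise ValueError(
                f"y length {y.shape} does not match {X.shape[0]} populations"
            )
        if np.isnan(y).any():
            raise ValidationError("environmental vector contains missing values")
        if np.unique(y).size < 2:
            raise ConstantInputError("environmental vector is constant")
        self.n_features_in_ = X.shape[1]

        Xt = X.T  # SNPs x populations
        if cfg.use_partial:
            z = np.asarray(cfg.covariate.values, dtype=float)
            if z.shape != y.shape:
                raise ValidationError("covariate length does not match the panel")
            tau, p, n_used, skip = _partial_tau_scan(Xt, y, z, cfg.min_populations)
        else:
            tau, p, n_used, skip = tau_scan(Xt, y, min_n=cfg.min_populations)

        maf = np.full(Xt.shape[0], np.nan)
        not_all_missing = ~np.isnan(Xt).all(axis=1)
        means = np.nanmean(np.where(np.isnan(Xt), np.nan, Xt)[not_all_missing], axis=1)
        maf[not_all_missing] = np.minimum(means, 1.0 - means)
        for k in np.flatnonzero(~not_all_missing):
            skip[k] = "all_missing"

        ok = ~np.isnan(tau)
        window_n = np.zeros(Xt.shape[0], dtype=np.int64)
        rank = np.full(Xt.shape[0], np.nan)
        widened = np.zeros(Xt.shape[0], dtype=bool)
        if ok.any():
            w_n, r, wd = _maf_rank_core(maf[ok], np.abs(tau[ok]), cfg.maf_window, cfg.min_window)
            window_n[ok], rank[ok], widened[ok] = w_n, r, wd

        n_tests = self.n_tests if self.n_tests is not None else int(ok.sum())
        if n_tests < 1:
            raise ConfigurationError("n_tests must be >= 1 (no usable SNPs?)")
        with np.errstate(invalid="ignore"):
            bonf = np.where(np.isnan(p), False, p <= cfg.alpha / n_tests)
            rsig = np.where(np.isnan(rank), False, rank > cfg.rank_cutoff)

        self.tau_ = tau
        self.pvalue_ = p
        self.maf_ = maf
        self.n_used_ = n_used
        self.window_n_ = window_n
        self.rank_ = rank
        self.widened_window_ = widened
        self.bonferroni_sig_ = bonf.astype(bool)
        self.rank_sig_ = rsig.astype(bool)
        self.final_sig_ = self.bonferroni_sig_ & self.rank_sig_
        self.skip_reason_ = skip
        self.n_tests_ = n_tests
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "final_sig_")
        return np.flatnonzero(self.final_sig_) if indices else self.final_sig_.copy()

    def transform(self, X):
        check_is_fitted(self, "final_sig_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.final_sig_]
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X[:, self.final_sig_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def results(self, snp_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-SNP results table for computed SNPs (skipped SNPs are excluded)."""
        check_is_fitted(self, "final_sig_")
        ok = ~np.isnan(self.tau_)
        if snp_meta is not None:
            ids = snp_meta["snp_id"].to_numpy()
            chrom = snp_meta["chrom"].to_numpy()
            pos = snp_meta["pos"].to_numpy()
        elif hasattr(self, "feature_names_in_"):
            ids = self.feature_names_in_
            chrom = np.full(ids.size, "", dtype=object)
            pos = np.zeros(ids.size, dtype=np.int64)
        else:
            ids = np.array([f"snp{i:06d}" for i in range(self.n_features_in_)], dtype=object)
            chrom = np.full(ids.size, "", dtype=object)
            pos = np.zeros(ids.size, dtype=np.int64)
        df = pd.DataFrame(
            {
                "snp_id": ids[ok],
                "chrom": chrom[ok],
                "pos": pos[ok],
                "tau": self.tau_[ok],
                "p_value": self.pvalue_[ok],
                "maf": self.maf_[ok],
                "n_used": self.n_used_[ok],
                "window_n": self.window_n_[ok],
                "rank": self.rank_[ok],
                "widened_window": self.widened_window_[ok],
                "bonferroni_sig": self.bonferroni_sig_[ok],
                "rank_sig": self.rank_sig_[ok],
                "final_sig": self.final_sig_[ok],
            }
        )
        return df.reset_index(drop=True)

    def skip_report(self, snp_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        """SNPs excluded from the scan, with reason codes."""
        check_is_fitted(self, "final_sig_")
        skipped = np.array([r is not None for r in self.skip_reason_], dtype=bool)
        if snp_meta is not None:
            ids = snp_meta["snp_id"].to_numpy()
        elif hasattr(self, "feature_names_in_"):
            ids = self.feature_names_in_
        else:
            ids = np.array([f"snp{i:06d}" for i in range(self.n_features_in_)], dtype=object)
        return pd.DataFrame(
            {"snp_id": ids[skipped], "reason": self.skip_reason_[skipped]}
        ).reset_index(drop=True)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        tags.requires_fit = True
        return tags


# ---------------------------------------------------------------------------
# functional wrappers over the estimator (the pipeline's surface)
# ---------------------------------------------------------------------------


def scan_snps(
    fm: FrequencyMatrix, env: EnvVector, cfg: ScanConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every SNP of a frequency matrix against an environmental vector.

    Returns ``(results, skip_report)``; rank and significance columns are present but
    unset (NaN / False) until :func:`maf_matched_rank` and :func:`call_significant`
    are applied.
    """
    cfg = cfg or ScanConfig()
    if len(env) != fm.n_populations:
        raise ValidationError(
            f"environment has {len(env)} values for {fm.n_populations} populations"
        )
    est = EnvAssociationScan(
        alpha=cfg.alpha,
        rank_cutoff=cfg.rank_cutoff,
        maf_window=cfg.maf_window,
        min_window=cfg.min_window,
        min_populations=cfg.min_populations,
        use_partial=cfg.use_partial,
        covariate=cfg.covariate,
    )
    est.fit(fm.freqs.T, env.values)
    results = est.results(fm.snp_meta)
    # rank fields are filled by maf_matched_rank; reset them here
    results["window_n"] = 0
    results["rank"] = np.nan
    results["widened_window"] = False
    results[["bonferroni_sig", "rank_sig", "final_sig"]] = False
    return results, est.skip_report(fm.snp_meta)


def maf_matched_rank(results: pd.DataFrame, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Fill ``window_n``, ``rank`` and ``widened_window`` on a scan results table."""
    cfg = cfg or ScanConfig()
    out = results.copy()
    window_n, rank, widened = _maf_rank_core(
        out["maf"].to_numpy(), np.abs(out["tau"].to_numpy()), cfg.maf_window, cfg.min_window
    )
    out["window_n"] = window_n
    out["rank"] = rank
    out["widened_window"] = widened
    return out


def call_significant(
    results: pd.DataFrame, cfg: ScanConfig | None = None, n_tests: int | None = None
) -> pd.DataFrame:
    """Set the two-criterion significance flags.

    ``bonferroni_sig`` iff p <= alpha / n_tests, ``rank_sig`` iff rank > rank_cutoff,
    ``final_sig`` iff both.  ``n_tests`` defaults to the number of SNPs in the table
    (the analysis set actually tested).
    """
    cfg = cfg or ScanConfig()
    if n_tests is None:
        n_tests = len(results)
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    if results["rank"].isna().any():
        raise ConfigurationError("ranks are unset; run maf_matched_rank first")
    out = results.copy()
    out["bonferroni_sig"] = out["p_value"] <= cfg.alpha / n_tests
    out["rank_sig"] = out["rank"] > cfg.rank_cutoff
    out["final_sig"] = out["bonferroni_sig"] & out["rank_sig"]
    return out
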