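"""Two-sample Mendelian randomization on GWAS summary statistics.

Instruments are selected from exposure summary statistics by a P-value
threshold and distance-based clumping, harmonized against the outcome
study (palindromic variants removed, strand-consistent sign flips), and
fed to the standard summary-data estimators:

* IVW — inverse-variance-weighted regression of outcome on exposure betas
  through the origin, with multiplicative random-effects scaling of the
  standard error by max(1, sqrt(Q / (k - 1))).
* MR-Egger — weighted regression with an intercept; the intercept tests
  directional pleiotropy under the InSIDE assumption.  Instrument-level
  bootstrap standard errors optional.
* Simple / weighted median of per-SNP Wald ratios, bootstrap SEs.

Heterogeneity is summarized by Cochran's Q on Wald ratios, and instruments
can be screened for pleiotropic association with measured risk factors by
per-(SNP, factor) regression with a Bonferroni threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .loci_overlap import merge_loci

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MRInstrumentSet:
    """Harmonized per-SNP summary statistics for exposure and outcome."""

    table: pd.DataFrame  # columns: rsid, beta_exp, se_exp, beta_out, se_out, ea, oa

    def __post_init__(self):
        req = {"beta_exp", "se_exp", "beta_out", "se_out"}
        if not req <= set(self.table.columns):
            raise ValueError(f"instrument table needs columns {sorted(req)}")
        if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
            raise ValueError("standard errors must be positive")

    def __len__(self):
        return len(self.table)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy(float)


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_instruments: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_p: float | None = None

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_instruments,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "intercept": self.intercept,
            "intercept_p": self.intercept_p,
            "Q": self.q_stat,
            "Q_p": self.q_p,
        }


# method labels reserved for externally computed sensitivity analyses
EXTERNAL_METHOD_LABELS = ("mr_presso", "contamination_mixture")


def select_instruments(
    summary: pd.DataFrame, p_thresh: float = 1e-6, window_kb: int = 5000
) -> pd.DataFrame:
    """P-value filter plus distance-based clumping; returns locus leads.

    Distance-based greedy merging (strongest P first) stands in for
    LD-based clumping; with the default 5-Mb radius it is conservative
    about treating nearby signals as independent instruments.
    """
    if "p" not in summary.columns:
        raise ValueError("summary statistics need a 'p' column")
    hits = summary[summary["p"] < p_thresh]
    if len(hits) == 0:
        raise ValueError(f"no variants reach p < {p_thresh:g}")
    return merge_loci(hits, window_kb=window_kb).leads


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> MRInstrumentSet:
    """Align outcome effects to the exposure effect allele.

    Palindromic (A/T, C/G) variants are removed because their strand is
    ambiguous.  Outcome rows whose alleles are swapped relative to the
    exposure get their beta negated; allele pairs that match neither way
    are dropped with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    merged = exposure.merge(
        outcome, on="rsid", suffixes=("_exp", "_out"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError("no overlapping variants between exposure and outcome")
    rows = []
    for _, r in merged.iterrows():
        ea_e, oa_e = str(r["ea_exp"]).upper(), str(r["oa_exp"]).upper()
        ea_o, oa_o = str(r["ea_out"]).upper(), str(r["oa_out"]).upper()
        if (ea_e, oa_e) in PALINDROMIC:
            continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            beta_out = r["beta_out"]
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out = -r["beta_out"]
        else:
            log.warning("dropping %s: allele mismatch %s/%s vs %s/%s",
                        r["rsid"], ea_e, oa_e, ea_o, oa_o)
            continue
        rows.append(
            {
                "rsid": r["rsid"],
                "ea": ea_e,
                "oa": oa_e,
                "beta_exp": float(r["beta_exp"]),
                "se_exp": float(r["se_exp"]),
                "beta_out": float(beta_out),
                "se_out": float(r["se_out"]),
            }
        )
    if not rows:
        raise ValueError("no variants left after harmonization")
    return MRInstrumentSet(table=pd.DataFrame(rows))


def _normal_ci_p(estimate: float, se: float) -> tuple[float, float, float]:
    z = estimate / se if se > 0 else np.inf
    p = float(min(1.0, 2 * stats.norm.sf(abs(z)))) if np.isfinite(z) else 0.0
    half = 1.959963984540054 * se
    return estimate - half, estimate + half, max(p, np.finfo(float).tiny)


def mr_ivw(instruments: MRInstrumentSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate (regression through the origin).

    With ``random_effects`` (default) the SE is inflated multiplicatively
    by sqrt(Q / (k - 1)) when Q exceeds its degrees of freedom, the
    convention suited to instrument sets with significant heterogeneity.
    """
    k = len(instruments)
    if k < 2:
        raise ValueError("IVW needs at least 2 instruments; use a Wald ratio for 1")
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    w = 1.0 / sy**2
    estimate = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    resid = by - estimate * bx
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (k - 1))) if random_effects else 1.0
    se = se_fixed * scale
    lo, hi, p = _normal_ci_p(estimate, se)
    return MRResult(
        method="ivw" if random_effects else "ivw_fe",
        estimate=estimate,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_instruments=k,
        q_stat=q,
        q_p=float(stats.chi2.sf(q, k - 1)),
    )


def _egger_fit(bx, by, w):
    # weighted least squares of by on bx with intercept, closed form
    sw = np.sum(w)
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    slope = np.sum(w * (bx - mx) * (by - my)) / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    k = len(bx)
    sigma2 = np.sum(w * resid**2) / (k - 2)
    scale = max(1.0, np.sqrt(sigma2))  # multiplicative random effects
    se_slope = scale / np.sqrt(sxx)
    se_int = scale * np.sqrt(1.0 / sw + mx**2 / sxx)
    return slope, se_slope, intercept, se_int


def mr_egger(
    instruments: MRInstrumentSet, n_boot: int = 0, seed: int | None = None
) -> MRResult:
    """MR-Egger regression; intercept estimates directional pleiotropy.

    Instruments are oriented so every exposure beta is non-negative before
    fitting (required for the intercept to be identifiable).  With
    ``n_boot`` > 0, instrument-level bootstrap SEs replace the analytic
    ones.
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(instruments.beta_exp)
    flip[flip == 0] = 1.0
    bx = instruments.beta_exp * flip
    by = instruments.beta_out * flip
    w = 1.0 / instruments.se_out**2
    slope, se_slope, intercept, se_int = _egger_fit(bx, by, w)
    if n_boot:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, 2))
        for b in range(n_boot):
            idx = rng.integers(0, k, size=k)
            if len(np.unique(bx[idx])) < 2:
                reps[b] = (np.nan, np.nan)
                continue
            s, _, c, _ = _egger_fit(bx[idx], by[idx], w[idx])
            reps[b] = (s, c)
        se_slope = float(np.nanstd(reps[:, 0], ddof=1))
        se_int = float(np.nanstd(reps[:, 1], ddof=1))
    lo, hi, p = _normal_ci_p(slope, se_slope)
    _, _, p_int = _normal_ci_p(intercept, se_int)
    return MRResult(
        method="egger_boot" if n_boot else "egger",
        estimate=float(slope),
        se=float(se_slope),
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_instruments=k,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=p_int,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Classical weighted median: smallest value at cumulative weight >= 1/2.

    With one value holding more than half the total weight, that value is
    returned exactly (the outlier-robustness the estimator is chosen for).
    """
    order = np.argsort(values)
    v = values[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cum, 0.5))
    # exact half-weight split (e.g. equal weights, even count): midpoint
    if idx + 1 < len(v) and abs(cum[idx] - 0.5) <= 1e-12:
        return float(0.5 * (v[idx] + v[idx + 1]))
    return float(v[idx])


def mr_median(
    instruments: MRInstrumentSet,
    weighted: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Simple or weighted median of per-SNP Wald ratios.

    The weighted median uses inverse-variance weights of the Wald ratio
    (first-order delta-method variances).  The standard error comes from a
    parametric bootstrap — each instrument's betas perturbed by their
    standard errors — which is better calibrated for this non-smooth
    estimator than resampling instruments.  Instruments with a zero
    exposure beta have no defined ratio and are dropped with a warning.
    """
    import logging

    tbl = instruments.table
    nonzero = tbl["beta_exp"] != 0
    if not nonzero.all():
        logging.getLogger(__name__).warning(
            "dropping %d instrument(s) with zero exposure beta", int((~nonzero).sum())
        )
        tbl = tbl[nonzero]
    if len(tbl) < 3:
        raise ValueError("median estimators need at least 3 usable instruments")
    bx = tbl["beta_exp"].to_numpy(float)
    sx = tbl["se_exp"].to_numpy(float)
    by = tbl["beta_out"].to_numpy(float)
    sy = tbl["se_out"].to_numpy(float)

    def _estimate(bx_, by_):
        ratios = by_ / bx_
        w = bx_**2 / sy**2 if weighted else np.ones_like(ratios)
        return _weighted_median(ratios, w)

    estimate = _estimate(bx, by)
    rng = np.random.default_rng(seed)
    k = len(bx)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _estimate(
            bx + sx * rng.standard_normal(k), by + sy * rng.standard_normal(k)
        )
    se = float(boots.std(ddof=1))
    if se == 0:
        lo = hi = estimate
        p = 1.0 if estimate == 0 else np.finfo(float).tiny
    else:
        lo, hi, p = _normal_ci_p(estimate, se)
    return MRResult(
        method="weighted_median" if weighted else "simple_median",
        estimate=estimate,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_instruments=k,
    )


def cochran_q(instruments: MRInstrumentSet, estimate: float) -> tuple[float, float]:
    """Cochran's Q over Wald ratios with first-order weights, and its p."""
    k = len(instruments)
    if k < 2:
        raise ValueError("Q needs at least 2 instruments")
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - estimate) ** 2))
    return q, float(stats.chi2.sf(q, k - 1))


def pleiotropy_screen(
    dosages: pd.DataFrame,
    risk_factors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(SNP, risk factor) association screen with Bonferroni flagging.

    Each risk factor is regressed on each SNP dosage (plus covariates) by
    OLS; associations with p below alpha / (n_snps * n_factors) flag the
    SNP for a leave-out sensitivity rerun of the MR analysis.
    """
    import statsmodels.api as sm

    n = len(dosages)
    if len(risk_factors) != n or (covariates is not None and len(covariates) != n):
        raise ValueError("dosages, risk factors and covariates must align on samples")
    n_tests = dosages.shape[1] * risk_factors.shape[1]
    threshold = alpha / n_tests
    base = np.ones((n, 1))
    if covariates is not None:
        base = np.column_stack([base, covariates.to_numpy(float)])
    rows = []
    for snp in dosages.columns:
        x = np.column_stack([base, dosages[snp].to_numpy(float)])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"design matrix is rank deficient for SNP {snp}")
        for factor in risk_factors.columns:
            fit = sm.OLS(risk_factors[factor].to_numpy(float), x).fit()
            p = float(fit.pvalues[-1])
            rows.append(
                {
                    "snp": snp,
                    "risk_factor": factor,
                    "beta": float(fit.params[-1]),
                    "p": p,
                    "flagged": p < threshold,
                    "threshold": threshold,
                }
            )
    return pd.DataFrame(rows)


def bonferroni_threshold(n_snps: int, n_factors: int = 7, alpha: float = 0.05) -> float:
    """Family-wise Bonferroni threshold for the pleiotropy screen."""
    return alpha / (n_snps * n_factors)


def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    p_thresh: float = 1e-6,
    window_kb: int = 5000,
    methods: tuple[str, ...] = ("ivw", "egger", "simple_median", "weighted_median"),
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Select, harmonize, and estimate; returns the MR report table."""
    leads = select_instruments(exposure, p_thresh=p_thresh, window_kb=window_kb)
    iv = harmonize(leads, outcome)
    results = []
    for m in methods:
        if m == "ivw":
            results.append(mr_ivw(iv))
        elif m == "ivw_fe":
            results.append(mr_ivw(iv, random_effects=False))
        elif m == "egger":
            results.append(mr_egger(iv))
        elif m == "egger_boot":
            results.append(mr_egger(iv, n_boot=n_boot, seed=seed))
        elif m == "simple_median":
            results.append(mr_median(iv, weighted=False, n_boot=n_boot, seed=seed))
        elif m == "weighted_median":
            results.append(mr_median(iv, weighted=True, n_boot=n_boot, seed=seed))
        else:
            raise ValueError(f"unknown MR method {m!r}")
    return pd.DataFrame([r.as_row() for r in results])
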