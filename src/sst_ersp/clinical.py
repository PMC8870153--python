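"""Clinical descriptive statistics and age-adjusted correlation analyses.

Covers the statistics applied to the per-subject clinical table (YGTSS total
tic score, PUTS, CY-BOCS, DuPaul ADHD): descriptives (mean, n-1 SD, median),
first-order partial Pearson correlations with age as the covariate,
Benjamini-Hochberg FDR correction across the three clinical scales, and the
gating rule that power-vs-severity correlations are run only when a
significant case-control cluster exists.

A reference CTD cohort table (n = 14 children, tic disorder diagnoses with
scale scores) ships with the package for tests and examples; see
:func:`load_reference_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Descriptives",
    "CorrelationResult",
    "load_reference_cohort",
    "describe",
    "partial_corr",
    "fdr_adjust",
    "correlate_eeg_clinical",
    "behavior_clinical_corr",
]

#: clinical scales entering the EEG-correlation FDR family
DEFAULT_SCALES = ("ygtss_total_tic", "cybocs", "dupaul_adhd")


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float  # n-1 denominator
    median: float

    def rounded(self, decimals: int = 1) -> "Descriptives":
        return Descriptives(self.n, round(self.mean, decimals),
                            round(self.sd, decimals), round(self.median, decimals))


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    n: int
    r: float
    p: float
    covariates: tuple[str, ...] = ()
    p_fdr: float | None = None


def load_reference_cohort() -> pd.DataFrame:
    """Bundled reference cohort: 14 children with chronic tic disorder,
    with age, sex, handedness and clinical scale scores."""
    with resources.files("sst_ersp.data").joinpath(
            "ctd_cohort_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def describe(column) -> Descriptives:
    """Mean, SD (n-1) and median of a clinical column."""
    x = pd.Series(column).dropna().astype(float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    return Descriptives(n=len(x), mean=float(x.mean()),
                        sd=float(x.std(ddof=1)), median=float(x.median()))


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), covs])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_corr(x, y, covariates=None, pair: str = "x~y") -> CorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Computed as the Pearson correlation of the least-squares residuals of x
    and y on the covariates (plus intercept); p from
    ``t = r * sqrt((n - k - 2) / (1 - r**2))`` with k covariates.
    With no (or constant) covariates this reduces to the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or len(covariates) == 0:
        covs = np.empty((n, 0))
        cov_names: tuple[str, ...] = ()
    else:
        covs = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
        cov_names = tuple(f"cov{i}" for i in range(covs.shape[1]))
    k = covs.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} for {k} covariates")
    rx = _residualize(x, covs)
    ry = _residualize(y, covs)
    sx, sy = rx.std(), ry.std()
    # relative floor: residuals that are pure round-off count as zero
    if sx <= 1e-10 * max(1.0, float(np.abs(x).max())) \
            or sy <= 1e-10 * max(1.0, float(np.abs(y).max())):
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        tval = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(tval), df))
    return CorrelationResult(pair=pair, n=n, r=r, p=p, covariates=cov_names)


def fdr_adjust(p_values, fwer: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=fwer, method="fdr_bh")
    return p_adj, reject


def correlate_eeg_clinical(
    extracted: pd.Series,
    clinical: pd.DataFrame,
    scales=DEFAULT_SCALES,
    covariate: str = "age",
    group: str = "CTD",
    has_significant_cluster: bool = True,
    fwer: float = 0.05,
) -> list[CorrelationResult]:
    """Age-adjusted correlations between extracted cluster power and each
    clinical scale, FDR-corrected across the scales.

    ``extracted`` is indexed by subject id (signed dB, CTD subjects).  The
    analysis is gated on the existence of a significant case-control
    cluster: with ``has_significant_cluster=False`` an empty list is
    returned (mirroring the study design).
    """
    if not has_significant_cluster:
        return []
    tab = clinical[clinical["diagnosis"] == group].set_index("subject")
    missing = [s for s in extracted.index if s not in tab.index]
    extra = [s for s in tab.index if s not in extracted.index]
    if missing or extra:
        raise ValueError(
            f"subject mismatch between EEG and clinical table: "
            f"missing from clinical {missing}, missing from EEG {extra}"
        )
    tab = tab.loc[extracted.index]
    results = []
    for scale in scales:
        res = partial_corr(extracted.to_numpy(), tab[scale].to_numpy(),
                           covariates=[tab[covariate].to_numpy()],
                           pair=f"cluster_db~{scale}")
        results.append(CorrelationResult(res.pair, res.n, res.r, res.p,
                                         (covariate,)))
    p_adj, _ = fdr_adjust([r.p for r in results], fwer=fwer)
    return [CorrelationResult(r.pair, r.n, r.r, r.p, r.covariates, float(q))
            for r, q in zip(results, p_adj)]


def behavior_clinical_corr(
    ssrt: pd.Series, clinical: pd.DataFrame, group: str = "CTD"
) -> CorrelationResult:
    """Plain Pearson correlation between per-subject SSRT and self-rated tic
    suppressibility (PUTS item 10) in the patient group.

    By construction a *negative* r means that subjects reporting better
    suppressibility stop faster (smaller SSRT)."""
    tab = clinical[clinical["diagnosis"] == group].set_index("subject")
    common = [s for s in ssrt.index if s in tab.index]
    if len(common) < 4:
        raise ValueError("need at least 4 subjects with both measures")
    x = ssrt.loc[common].to_numpy(dtype=float)
    y = tab.loc[common, "puts_item10"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant measure; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(pair="ssrt~puts_item10", n=len(common),
                             r=float(r), p=float(p))
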