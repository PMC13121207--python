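"""Per-feature differential statistics for two-arm contrasts.

For a contrast (test arm vs reference arm) each feature gets a log2
fold-change (mean difference on the log2 scale), a two-sample t statistic
(Welch by default), a two-sided p-value, and a Benjamini-Hochberg q-value
computed across all features of the dataset for that contrast. Features are
handled complete-case: only non-missing values inside each arm enter, and a
feature with fewer than two values in either arm is emitted with missing
statistics (and excluded from the BH family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AbundanceTable, SampleDesign

Arm = tuple[str, str]  # (genotype, treatment)


class ContrastError(ValueError):
    """Raised when a contrast cannot be resolved against the design."""


@dataclass(frozen=True)
class Contrast:
    """Two-arm comparison; log2FC is mean(test) - mean(reference)."""

    test: Arm
    reference: Arm
    label: str = ""

    def __post_init__(self) -> None:
        if self.test == self.reference:
            raise ContrastError("test and reference arms are identical")
        if not self.label:
            object.__setattr__(
                self, "label",
                f"{self.test[0]}_{self.test[1]}_vs_{self.reference[0]}_{self.reference[1]}",
            )


@dataclass(frozen=True)
class Thresholds:
    """Significance cutoffs: |log2FC| >= lfc_min and BH q <= q_max.

    ``lfc_min_primary`` is the separately configurable cutoff for the primary
    disease filter; defaults follow the published filtering procedure
    (|log2FC| >= 0.2, q <= 0.05).
    """

    lfc_min: float = 0.2
    q_max: float = 0.05
    lfc_min_primary: float = 0.2

    def __post_init__(self) -> None:
        if self.lfc_min < 0 or self.lfc_min_primary < 0:
            raise ValueError("log2FC thresholds must be >= 0")
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must be in (0, 1]")


def _arm_values(table: AbundanceTable, design: SampleDesign, arm: Arm) -> np.ndarray:
    samples = design.arm_samples(*arm)
    if len(samples) < 2:
        raise ContrastError(
            f"arm {arm} has {len(samples)} sample(s); at least 2 required"
        )
    missing = [s for s in samples if s not in table.values.columns]
    if missing:
        raise ContrastError(f"arm {arm}: samples absent from table: {missing}")
    return table.values[samples].to_numpy(dtype=float)


def log2_fold_change(
    table: AbundanceTable, design: SampleDesign, contrast: Contrast
) -> pd.Series:
    """Per-feature log2FC = mean(test) - mean(reference); NaN if an arm is empty."""
    a = _arm_values(table, design, contrast.test)
    b = _arm_values(table, design, contrast.reference)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lfc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    return pd.Series(lfc, index=table.values.index, name="log2FC")


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t test on rows of two feature x sample arrays.

    Returns (t, df, p). Rows with <2 non-missing values in either arm are NaN.
    Degenerate rows with zero variance in both arms get t=0, p=1 when the
    means agree and p at the smallest positive float when they differ.
    """
    n1 = np.sum(~np.isnan(a), axis=1).astype(float)
    n2 = np.sum(~np.isnan(b), axis=1).astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        v1, v2 = np.nanvar(a, axis=1, ddof=1), np.nanvar(b, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    diff = m1 - m2
    degenerate = ok & (se2 == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(degenerate, n1 + n2 - 2, df)
    p = np.where(degenerate, np.where(diff == 0, 1.0, np.nextafter(0.0, 1.0)), p)
    t = np.where(ok, t, np.nan)
    df = np.where(ok, df, np.nan)
    p = np.where(ok, p, np.nan)
    return t, df, p


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised equal-variance (pooled) two-sample t test on rows."""
    n1 = np.sum(~np.isnan(a), axis=1).astype(float)
    n2 = np.sum(~np.isnan(b), axis=1).astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        v1, v2 = np.nanvar(a, axis=1, ddof=1), np.nanvar(b, axis=1, ddof=1)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se2 = sp2 * (1 / n1 + 1 / n2)
        t = (m1 - m2) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    diff = m1 - m2
    degenerate = ok & (se2 == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, np.nextafter(0.0, 1.0)), p)
    t = np.where(ok, t, np.nan)
    df = np.where(ok, df, np.nan)
    p = np.where(ok, p, np.nan)
    return t, df, p


def two_sample_test(
    table: AbundanceTable,
    design: SampleDesign,
    contrast: Contrast,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-feature two-sample test; method 'welch' (default) or 'pooled'."""
    if method not in ("welch", "pooled"):
        raise ValueError(f"unknown test method {method!r}")
    a = _arm_values(table, design, contrast.test)
    b = _arm_values(table, design, contrast.reference)
    fn = welch_t if method == "welch" else pooled_t
    t, df, p = fn(a, b)
    return pd.DataFrame({"t": t, "df": df, "p": p}, index=table.values.index)


def bh_adjust(p: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are excluded from the
    family size m and returned as NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class ZMatrix:
    """Per-feature z-scores across all samples (sample sd, ddof=1).

    Features with zero variance get all-zero rows and appear in
    ``constant_features``.
    """

    values: pd.DataFrame
    constant_features: list[str] = field(default_factory=list)


def z_scores(table: AbundanceTable) -> ZMatrix:
    x = table.values.to_numpy(dtype=float)
    n = np.sum(~np.isnan(x), axis=1)
    if (n < 2).any():
        bad = table.values.index[n < 2][0]
        raise ValueError(f"feature {bad!r} has fewer than 2 values; cannot standardise")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=1, keepdims=True)
        sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd_safe
    z[constant, :] = np.where(np.isnan(x[constant, :]), np.nan, 0.0)
    zdf = pd.DataFrame(z, index=table.values.index, columns=table.values.columns)
    return ZMatrix(zdf, list(table.values.index[constant]))


def run_contrast(
    table: AbundanceTable,
    design: SampleDesign,
    contrast: Contrast,
    thresholds: Thresholds = Thresholds(),
    *,
    method: str = "welch",
    lfc_min: float | None = None,
) -> pd.DataFrame:
    """Full per-feature comparison for one contrast.

    Columns: feature (index), contrast, log2FC, t, df, p, q, n_test, n_ref,
    significant. ``lfc_min`` overrides ``thresholds.lfc_min`` for the
    significance flag (used by callers that apply a different fold-change
    cutoff to the same statistics).
    """
    a = _arm_values(table, design, contrast.test)
    b = _arm_values(table, design, contrast.reference)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lfc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    fn = welch_t if method == "welch" else pooled_t
    t, df, p = fn(a, b)
    q = bh_adjust(p)
    cut = thresholds.lfc_min if lfc_min is None else lfc_min
    sig = (np.abs(lfc) >= cut) & (q <= thresholds.q_max)
    sig = np.where(np.isnan(q) | np.isnan(lfc), False, sig)
    res = pd.DataFrame(
        {
            "contrast": contrast.label,
            "log2FC": lfc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "n_test": np.sum(~np.isnan(a), axis=1),
            "n_ref": np.sum(~np.isnan(b), axis=1),
            "significant": sig.astype(bool),
        },
        index=table.values.index,
    )
    res.index.name = "feature"
    return res


def percent_of_reference(log2fc: float) -> float:
    """Linear-scale percentage implied by a log2 fold-change.

    A log2FC of -1.9 corresponds to 2**(-1.9) = 26.8% of the reference level.
    """
    return 100.0 * 2.0**log2fc
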