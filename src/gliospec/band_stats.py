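"""Group-level spectral statistics for the two tissue classes.

Per-class mean +/- SD spectra, band intensity ratios on mean spectra, and a
per-band nonparametric comparison table: Shapiro-Wilk normality per class
(reported, not gating) and a two-tailed Mann-Whitney U test per catalog
shift at alpha = 0.05.  A Benjamini-Hochberg adjusted p column is emitted
alongside the raw p-values for callers who want multiplicity control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .peak_features import PeakCatalog, FeatureTable, extract_intensity
from .spectra_io import Spectrum, SpectraSet

HEALTHY, TUMOR = "Healthy", "Tumor"


def group_mean_spectra(
    sset: SpectraSet, ddof: int = 1
) -> dict[str, tuple[Spectrum, Spectrum]]:
    """Pointwise per-class (mean, SD) spectra; sample SD (ddof=1) by default."""
    axis = sset.common_axis
    out = {}
    for label in sorted(sset.labels.unique()):
        ids = sset.meta.loc[sset.meta["label"] == label, "spectrum_id"]
        mat = np.vstack(
            [s.intensities for s in sset.spectra if s.spectrum_id in set(ids)]
        )
        if not len(mat):
            raise ValueError(f"empty class {label!r}")
        mean = Spectrum(f"mean_{label}", axis, mat.mean(axis=0))
        sd = mat.std(axis=0, ddof=ddof) if len(mat) > ddof else np.zeros(len(axis))
        out[label] = (mean, Spectrum(f"sd_{label}", axis, sd))
    return out


def band_ratio(
    mean: Spectrum,
    numerator: float = 720.0,
    denominator: float = 701.0,
    halfwidth: float = 3.0,
) -> float:
    """Intensity ratio of two bands on a mean spectrum (e.g. 720:701 cm^-1)."""
    num = extract_intensity(mean, numerator, halfwidth)
    den = extract_intensity(mean, denominator, halfwidth)
    if den == 0.0:
        raise ValueError(f"zero intensity at denominator band {denominator}")
    return num / den


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError(f"Shapiro-Wilk defined for 3 <= n <= 5000, got {len(values)}")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact p by enumeration for small tie-free samples (both sizes <= 8);
    otherwise the normal approximation with tie and continuity corrections.
    Returns (U of the first group, two-tailed p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compare_bands(table: FeatureTable, catalog: PeakCatalog) -> pd.DataFrame:
    """Per-catalog-shift class comparison table, sorted by shift.

    Columns: medians per class, direction of the tumor-class median shift,
    Mann-Whitney U and two-tailed p, BH-adjusted p, Shapiro-Wilk normality
    flags per class (at alpha 0.05).  Bands that cannot be computed (e.g. a
    single-spectrum class) are flagged rather than aborting the table.
    """
    labels = table.labels
    rows = []
    for shift in catalog.shifts:
        if shift not in set(table.shifts):
            continue
        a = table.X[shift][labels == HEALTHY].to_numpy()
        b = table.X[shift][labels == TUMOR].to_numpy()
        row: dict = {"shift_cm1": shift}
        if len(a) < 3 or len(b) < 3:
            row.update(flagged=True, flag_reason="class with < 3 spectra")
            rows.append(row)
            continue
        med_h, med_t = float(np.median(a)), float(np.median(b))
        try:
            U, p = mann_whitney(b, a)  # U of the tumor group
        except ValueError as exc:
            row.update(flagged=True, flag_reason=str(exc))
            rows.append(row)
            continue
        def _normal(v):
            try:
                return shapiro_wilk(v)[1] > 0.05
            except ValueError:
                return False
        row.update(
            median_healthy=med_h,
            median_tumor=med_t,
            direction="up" if med_t >= med_h else "down",
            U=U,
            p_two_tailed=p,
            normal_healthy=_normal(a),
            normal_tumor=_normal(b),
            flagged=False,
            flag_reason="",
        )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("shift_cm1").reset_index(drop=True)
    ok = ~out["flagged"].astype(bool) if "flagged" in out else pd.Series([], dtype=bool)
    if "p_two_tailed" in out and ok.any():
        adj = np.full(len(out), np.nan)
        adj[ok.to_numpy()] = benjamini_hochberg(
            out.loc[ok, "p_two_tailed"].to_numpy()
        )
        out["p_bh"] = adj
    if ok.any() == False:
        warnings.warn("no band could be computed; all rows flagged")
    return out
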