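"""Peak catalog, candidate screening, feature extraction and ANOVA ranking.

The bundled catalog holds the 60 discriminative Raman shifts with their
tentative biochemical assignments; 19 of them are flagged as novel for
glioma-versus-healthy discrimination on fresh tissue and 28 as previously
described in the ex-vivo literature.  Features are per-spectrum band
intensities (window maximum around each catalog shift, taken after RMS
normalization so values are comparable across acquisitions) and are ranked
by the one-way ANOVA F statistic between the two tissue classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spectra_io import Spectrum, SpectraSet

DIRECTIONS = ("up", "down", "unknown")


@dataclass
class PeakCatalog:
    """The Raman-shift feature dictionary (shift, assignment, flags)."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"shift_cm1", "assignment", "novel", "previously_described",
                "tumor_direction"}
        missing = need - set(self.entries.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        shifts = self.entries["shift_cm1"]
        if shifts.duplicated().any():
            dup = shifts[shifts.duplicated()].iloc[0]
            raise ValueError(f"duplicate catalog shift: {dup}")
        if ((shifts < 400) | (shifts > 1700)).any():
            raise ValueError("catalog shift outside 400-1700 cm^-1")
        bad = set(self.entries["tumor_direction"]) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"invalid tumor_direction values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def shifts(self) -> np.ndarray:
        return self.entries["shift_cm1"].to_numpy(dtype=float)

    @property
    def n_novel(self) -> int:
        return int(self.entries["novel"].sum())

    @property
    def n_previously_described(self) -> int:
        return int(self.entries["previously_described"].sum())

    def direction(self, shift: float) -> str:
        row = self.entries[self.entries["shift_cm1"] == shift]
        if row.empty:
            raise KeyError(f"shift {shift} not in catalog")
        return str(row["tumor_direction"].iloc[0])


def load_catalog(path=None) -> PeakCatalog:
    """Load a peak catalog; with no path, the bundled 60-shift catalog."""
    if path is None:
        src = resources.files("gliospec.data").joinpath("peak_catalog.csv")
        with resources.as_file(src) as p:
            entries = pd.read_csv(p)
    else:
        entries = pd.read_csv(path)
    for col in ("novel", "previously_described"):
        if entries[col].dtype == object:
            entries[col] = entries[col].map({"true": True, "false": False})
        entries[col] = entries[col].astype(bool)
    entries["shift_cm1"] = entries["shift_cm1"].astype(float)
    return PeakCatalog(entries=entries.sort_values("shift_cm1").reset_index(drop=True))


def detect_candidate_peaks(
    mean_spectra: list[Spectrum],
    min_prominence: float = 0.02,
    min_separation: float = 4.0,
) -> list[float]:
    """Screen candidate band positions from per-class mean spectra.

    Local maxima of each class mean with prominence at least
    ``min_prominence`` times that spectrum's maximum intensity are collected;
    the union over classes is de-duplicated by greedy clustering within
    ``min_separation`` cm^-1 and returned sorted ascending.
    """
    found: list[float] = []
    for s in mean_spectra:
        step = float(np.median(np.diff(s.wavenumbers)))
        prom = min_prominence * float(np.max(s.intensities))
        idx, _ = find_peaks(
            s.intensities,
            prominence=max(prom, 0.0),
            distance=max(int(round(min_separation / step)), 1),
        )
        found.extend(float(s.wavenumbers[i]) for i in idx)
    found.sort()
    merged: list[list[float]] = []
    for w in found:
        if merged and w - merged[-1][-1] < min_separation:
            merged[-1].append(w)
        else:
            merged.append([w])
    return [float(np.mean(group)) for group in merged]


def extract_intensity(s: Spectrum, shift: float, halfwidth: float = 3.0) -> float:
    """Maximum intensity within [shift - halfwidth, shift + halfwidth].

    The window maximum tolerates small peak-position jitter relative to the
    nominal catalog shift.
    """
    w = s.wavenumbers
    if shift - halfwidth < w[0] or shift + halfwidth > w[-1]:
        raise ValueError(
            f"{s.spectrum_id}: window {shift}±{halfwidth} outside axis "
            f"[{w[0]:g}, {w[-1]:g}]"
        )
    mask = (w >= shift - halfwidth) & (w <= shift + halfwidth)
    return float(np.max(s.intensities[mask]))


@dataclass
class FeatureTable:
    """Spectra x shifts matrix of band intensities with labels and grouping."""

    X: pd.DataFrame  # index: spectrum_id, columns: shifts (float)
    labels: pd.Series  # per-row class label
    groups: pd.Series  # per-row patient_id

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not (self.X.index.equals(self.labels.index) and
                self.X.index.equals(self.groups.index)):
            raise ValueError("labels/groups not aligned with feature rows")

    @property
    def shifts(self) -> np.ndarray:
        return np.asarray(self.X.columns, dtype=float)

    def __len__(self) -> int:
        return len(self.X)

    def select(self, shifts: list[float]) -> "FeatureTable":
        return FeatureTable(
            X=self.X[list(shifts)], labels=self.labels, groups=self.groups
        )

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out["label"] = self.labels
        out["patient_id"] = self.groups
        out.to_csv(path, index_label="spectrum_id", float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    tab = pd.read_csv(path, index_col="spectrum_id")
    labels = tab.pop("label")
    groups = tab.pop("patient_id").astype(str)
    tab.columns = tab.columns.astype(float)
    return FeatureTable(X=tab, labels=labels, groups=groups)


def build_feature_table(
    sset: SpectraSet, shifts: list[float] | np.ndarray, halfwidth: float = 3.0
) -> FeatureTable:
    """Extract the (n_spectra x n_shifts) band-intensity matrix."""
    shifts = sorted(float(v) for v in shifts)
    rows = {
        s.spectrum_id: [extract_intensity(s, v, halfwidth) for v in shifts]
        for s in sset.spectra
    }
    X = pd.DataFrame.from_dict(rows, orient="index", columns=shifts)
    X.index.name = "spectrum_id"
    meta = sset.meta.set_index("spectrum_id")
    return FeatureTable(
        X=X,
        labels=meta.loc[X.index, "label"],
        groups=meta.loc[X.index, "patient_id"].astype(str),
    )


def anova_f_scores(table: FeatureTable) -> pd.Series:
    """One-way ANOVA F statistic per feature column (two tissue classes).

    F = (between-class SS / (g-1)) / (within-class SS / (n-g)) with g = 2.
    """
    classes = table.labels.unique()
    if len(classes) < 2:
        raise ValueError("both classes required for ANOVA ranking")
    X = table.X.to_numpy(dtype=float)
    n = len(X)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    g = len(classes)
    for c in classes:
        sub = X[(table.labels == c).to_numpy()]
        if len(sub) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 spectra")
        ssb += len(sub) * (sub.mean(axis=0) - grand) ** 2
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (g - 1)) / (ssw / (n - g))
    F = np.where(np.isfinite(F), F, np.inf * np.sign(ssb + 1))
    F = np.where(ssb == 0, 0.0, F)  # zero between-class spread => F = 0
    return pd.Series(F, index=table.X.columns, name="F")


def select_top_k(scores: pd.Series, k: int = 60) -> list[float]:
    """The k shifts with largest F, descending; ties broken by ascending shift."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored shifts")
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [float(shift) for shift, _ in order[:k]]
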