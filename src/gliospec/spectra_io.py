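"""Reading, writing, validation and axis alignment of point Raman spectra.

A :class:`Spectrum` is one acquisition: an ascending wavenumber axis (cm^-1)
and an intensity vector in arbitrary detector counts.  A :class:`SpectraSet`
bundles many acquisitions with per-spectrum metadata (sample, patient, class
label).  Files are plain delimited text:

* spectra file (long format): ``spectrum_id, wavenumber_cm1, intensity``,
  rows grouped by spectrum with the axis ascending within each group;
* metadata file: ``spectrum_id, sample_id, patient_id, label[, histology]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LABELS = ("Healthy", "Tumor")

META_COLUMNS = ["spectrum_id", "sample_id", "patient_id", "label"]


@dataclass
class Spectrum:
    """One Raman acquisition: wavenumber axis (cm^-1) vs intensity (counts)."""

    spectrum_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError(f"{self.spectrum_id}: axis and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError(f"{self.spectrum_id}: axis/intensity length mismatch")
        if len(self.wavenumbers) < 1:
            raise ValueError(f"{self.spectrum_id}: empty spectrum")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError(f"{self.spectrum_id}: non-monotone wavenumber axis")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError(f"{self.spectrum_id}: non-finite wavenumbers")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"{self.spectrum_id}: non-finite intensities")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_values(
        self,
        intensities: np.ndarray | None = None,
        wavenumbers: np.ndarray | None = None,
    ) -> "Spectrum":
        """Copy of this spectrum with replaced intensity and/or axis vectors."""
        return Spectrum(
            spectrum_id=self.spectrum_id,
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=self.intensities if intensities is None else intensities,
        )


def _validate_meta(meta: pd.DataFrame, spectrum_ids: list[str]) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["spectrum_id"].duplicated().any():
        dup = meta.loc[meta["spectrum_id"].duplicated(), "spectrum_id"].iloc[0]
        raise ValueError(f"duplicate spectrum_id in metadata: {dup!r}")
    bad = set(meta["label"]) - set(VALID_LABELS)
    if bad:
        raise ValueError(
            f"label outside {VALID_LABELS}: {sorted(bad)!r}"
        )
    meta_ids = set(meta["spectrum_id"])
    spec_ids = set(spectrum_ids)
    if meta_ids != spec_ids:
        extra, absent = meta_ids - spec_ids, spec_ids - meta_ids
        raise ValueError(
            f"metadata/spectra id mismatch (meta-only={sorted(extra)[:3]}, "
            f"spectra-only={sorted(absent)[:3]})"
        )
    # every sample maps to exactly one patient and one label
    per_sample = meta.groupby("sample_id")[["patient_id", "label"]].nunique()
    inconsistent = per_sample[(per_sample > 1).any(axis=1)]
    if len(inconsistent):
        raise ValueError(
            f"sample(s) with conflicting patient/label: {list(inconsistent.index)[:3]}"
        )
    if "histology" not in meta.columns:
        meta = meta.assign(histology="")
    return meta.set_index("spectrum_id", drop=False)


@dataclass
class SpectraSet:
    """A collection of spectra plus aligned per-spectrum metadata."""

    spectra: list[Spectrum]
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = [s.spectrum_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate spectrum_id: {dup!r}")
        self.meta = _validate_meta(pd.DataFrame(self.meta), ids)
        # keep metadata rows in spectrum order
        self.meta = self.meta.loc[ids]

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    @property
    def spectrum_ids(self) -> list[str]:
        return [s.spectrum_id for s in self.spectra]

    @property
    def labels(self) -> pd.Series:
        return self.meta["label"]

    @property
    def common_axis_flag(self) -> bool:
        """True iff every spectrum shares an identical wavenumber axis."""
        if not self.spectra:
            return True
        ax0 = self.spectra[0].wavenumbers
        return all(
            len(s) == len(ax0) and np.array_equal(s.wavenumbers, ax0)
            for s in self.spectra
        )

    @property
    def common_axis(self) -> np.ndarray:
        if not self.common_axis_flag:
            raise ValueError("spectra are not on a common axis")
        return self.spectra[0].wavenumbers

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) intensity stack; requires a common axis."""
        _ = self.common_axis
        return np.vstack([s.intensities for s in self.spectra])

    def subset(self, keep_ids: list[str]) -> "SpectraSet":
        keep = set(keep_ids)
        spectra = [s for s in self.spectra if s.spectrum_id in keep]
        meta = self.meta[self.meta["spectrum_id"].isin(keep)]
        return SpectraSet(spectra=spectra, meta=meta.reset_index(drop=True))

    def with_spectra(self, spectra: list[Spectrum]) -> "SpectraSet":
        """Same metadata (restricted to surviving ids), new spectra list."""
        ids = {s.spectrum_id for s in spectra}
        meta = self.meta[self.meta["spectrum_id"].isin(ids)]
        return SpectraSet(spectra=spectra, meta=meta.reset_index(drop=True))


def read_spectra(spectra_path, meta_path) -> SpectraSet:
    """Read and validate a spectra file plus its metadata file."""
    tab = pd.read_csv(spectra_path)
    need = {"spectrum_id", "wavenumber_cm1", "intensity"}
    if not need.issubset(tab.columns):
        raise ValueError(f"{spectra_path}: expected columns {sorted(need)}")
    if len(tab) and not np.isfinite(tab[["wavenumber_cm1", "intensity"]]).all().all():
        bad = tab.index[~np.isfinite(tab[["wavenumber_cm1", "intensity"]]).all(axis=1)][0]
        raise ValueError(f"{spectra_path}: non-finite value at data row {bad + 1}")
    spectra = []
    for sid, grp in tab.groupby("spectrum_id", sort=False):
        if len(grp) < 2:
            raise ValueError(f"{spectra_path}: spectrum {sid!r} has < 2 points")
        spectra.append(
            Spectrum(
                spectrum_id=str(sid),
                wavenumbers=grp["wavenumber_cm1"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
            )
        )
    meta = pd.read_csv(meta_path, dtype=str)
    return SpectraSet(spectra=spectra, meta=meta)


def write_spectra(sset: SpectraSet, spectra_path, meta_path) -> None:
    """Write a SpectraSet to the delimited-text pair; round-trips to 1e-12."""
    if sset.spectra:
        frames = [
            pd.DataFrame(
                {
                    "spectrum_id": s.spectrum_id,
                    "wavenumber_cm1": s.wavenumbers,
                    "intensity": s.intensities,
                }
            )
            for s in sset.spectra
        ]
        tab = pd.concat(frames, ignore_index=True)
    else:
        tab = pd.DataFrame(columns=["spectrum_id", "wavenumber_cm1", "intensity"])
    tab.to_csv(spectra_path, index=False, float_format="%.17g")
    cols = META_COLUMNS + (["histology"] if "histology" in sset.meta.columns else [])
    sset.meta[cols].to_csv(meta_path, index=False)


def resample_common_axis(
    sset: SpectraSet, start: float = 400.0, stop: float = 1700.0, step: float = 1.0
) -> SpectraSet:
    """Linearly interpolate every spectrum onto the grid start..stop (inclusive).

    The default 400-1700 cm^-1 @ 1 cm^-1 grid covers every catalog shift as an
    exact grid point.  Errors if any spectrum's native axis does not cover the
    requested range.
    """
    axis = np.arange(start, stop + step / 2, step)
    out = []
    for s in sset.spectra:
        if s.wavenumbers[0] > start or s.wavenumbers[-1] < stop:
            raise ValueError(
                f"{s.spectrum_id}: native axis "
                f"[{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}] does not cover "
                f"requested range [{start:g}, {stop:g}]"
            )
        out.append(
            s.with_values(
                wavenumbers=axis,
                intensities=np.interp(axis, s.wavenumbers, s.intensities),
            )
        )
    return sset.with_spectra(out)
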