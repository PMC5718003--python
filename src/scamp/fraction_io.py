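"""Containers and TSV readers/writers for fractionated-extract data.

The canonical interchange formats are plain TSV (UTF-8, tab separated,
'.' decimal, mandatory header):

* peak tables — long format with columns ``fraction, mz, intensity[, snr]``,
  or one file per fraction with columns ``mz, intensity[, snr]``;
* activity profiles — columns ``fraction, activity``;
* binned matrices — one row per mass bin: ``mz`` then one intensity column
  per fraction (``f1..fN``), optionally ``group_center``/``group_size``
  annotation columns;
* candidate reports — the ranked scoring output.

All readers reject NaN/Inf cells: silent missing values in a quantitative
pipeline are how wrong ranks happen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "FractionSpectrum",
    "FractionSet",
    "ActivityProfile",
    "dpph_inhibition",
    "read_peak_table",
    "write_peak_table",
    "read_activity_profile",
    "write_activity_profile",
    "read_binned_matrix",
    "write_binned_matrix",
    "read_mzml_fraction",
    "write_candidates",
    "read_candidates",
]


@dataclass(frozen=True)
class Peak:
    """A centroided mass peak: m/z, intensity, optional signal-to-noise."""

    mz: float
    intensity: float
    snr: float | None = None

    def __post_init__(self) -> None:
        if not (self.mz > 0 and math.isfinite(self.mz)):
            raise ValueError(f"peak m/z must be positive and finite, got {self.mz}")
        if not (self.intensity >= 0 and math.isfinite(self.intensity)):
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")
        if self.snr is not None and not (self.snr >= 0 and math.isfinite(self.snr)):
            raise ValueError(f"peak S/N must be non-negative, got {self.snr}")


@dataclass
class FractionSpectrum:
    """The centroid peak list of one chromatographic fraction.

    Peaks are kept sorted by m/z; peaks at exactly equal m/z are merged by
    summing intensity (keeping the larger S/N), so the list is strictly
    ascending.
    """

    fraction_index: int
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fraction_index < 1:
            raise ValueError("fraction indices are 1-based")
        self.peaks = _canonical_peaks(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


def _canonical_peaks(peaks: list[Peak]) -> list[Peak]:
    ordered = sorted(peaks, key=lambda p: p.mz)
    merged: list[Peak] = []
    for p in ordered:
        if merged and merged[-1].mz == p.mz:
            last = merged[-1]
            snrs = [s for s in (last.snr, p.snr) if s is not None]
            merged[-1] = Peak(p.mz, last.intensity + p.intensity,
                              max(snrs) if snrs else None)
        else:
            merged.append(p)
    return merged


@dataclass
class FractionSet:
    """An ordered collection of N sequential fraction spectra (indices 1..N)."""

    fractions: list[FractionSpectrum]

    def __post_init__(self) -> None:
        indices = [f.fraction_index for f in self.fractions]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(
                f"fraction indices must be exactly 1..N in order, got {indices}"
            )

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    def __iter__(self):
        return iter(self.fractions)

    def __getitem__(self, k: int) -> FractionSpectrum:
        """1-based access by fraction index."""
        return self.fractions[k - 1]

    def total_peaks(self) -> int:
        return sum(len(f) for f in self.fractions)


@dataclass
class ActivityProfile:
    """Per-fraction bioactivity vector A = (a_1 .. a_N).

    Higher values mean more active.  ``normalized`` records whether the
    stored values are the unit-Euclidean-norm form A0.
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("activity profile must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity profile contains non-finite values")
        if self.normalized:
            nrm = float(np.linalg.norm(self.values))
            if nrm > 0 and abs(nrm - 1.0) > 1e-12:
                raise ValueError("normalized activity profile must have unit norm")

    @property
    def n_fractions(self) -> int:
        return int(self.values.size)

    def normalize(self) -> "ActivityProfile":
        """Return the unit-norm form A0 (all-zero input stays all-zero)."""
        nrm = float(np.linalg.norm(self.values))
        if nrm == 0.0:
            return ActivityProfile(self.values.copy(), normalized=True)
        return ActivityProfile(self.values / nrm, normalized=True)


def dpph_inhibition(ab_t: float, ab_0: float, ab_b: float) -> float:
    """Percent DPPH radical remaining: ((Ab_t - Ab_b) / Ab_0) x 100.

    ``ab_t`` is the absorbance of the DPPH solution with the tested
    fraction, ``ab_0`` the DPPH-only control, ``ab_b`` the fraction-only
    blank.  Lower remaining %DPPH means stronger radical scavenging.
    """
    if ab_0 <= 0:
        raise ValueError("control absorbance Ab_0 must be positive")
    return (ab_t - ab_b) / ab_0 * 100.0


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in required:
        if col not in table.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    numeric = table[[c for c in table.columns if c in required or c == "snr"]]
    for col in numeric.columns:
        values = pd.to_numeric(numeric[col], errors="coerce")
        bad = values.index[~np.isfinite(values) & numeric[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric or non-finite cell in column "
                             f"{col!r}, row {int(bad[0]) + 2}")
        if numeric[col].isna().any():
            row = int(numeric[col].isna().idxmax()) + 2
            raise ValueError(f"{path}: empty cell in column {col!r}, row {row}")
    return table


def read_peak_table(path, dialect: str = "long",
                    n_fractions: int | None = None) -> FractionSet:
    """Read fraction peak lists from TSV.

    ``dialect="long"``: one file with columns ``fraction, mz, intensity``
    and optional ``snr``.  ``dialect="per-fraction"``: ``path`` is a list of
    per-fraction file paths in fraction order, each with ``mz, intensity``
    and optional ``snr``.  Fractions with no rows are present and empty;
    ``n_fractions`` may extend the set with trailing empty fractions.
    """
    if dialect == "long":
        table = _read_tsv(path, ("fraction", "mz", "intensity"))
        frac_col = table["fraction"].astype(int)
        n = max(int(frac_col.max()) if len(table) else 0, n_fractions or 0)
        has_snr = "snr" in table.columns
        buckets: dict[int, list[Peak]] = {k: [] for k in range(1, n + 1)}
        for i in range(len(table)):
            k = int(frac_col.iloc[i])
            if k not in buckets:
                raise ValueError(f"{path}: fraction index {k} out of range, row {i + 2}")
            snr = float(table["snr"].iloc[i]) if has_snr else None
            buckets[k].append(Peak(float(table["mz"].iloc[i]),
                                   float(table["intensity"].iloc[i]), snr))
        return FractionSet([FractionSpectrum(k, buckets[k]) for k in range(1, n + 1)])
    if dialect == "per-fraction":
        spectra = []
        for k, fp in enumerate(path, start=1):
            table = _read_tsv(fp, ("mz", "intensity"))
            has_snr = "snr" in table.columns
            peaks = [
                Peak(float(r.mz), float(r.intensity),
                     float(r.snr) if has_snr else None)
                for r in table.itertuples()
            ]
            spectra.append(FractionSpectrum(k, peaks))
        return FractionSet(spectra)
    raise ValueError(f"unknown peak-table dialect {dialect!r}")


def write_peak_table(path, fset: FractionSet) -> None:
    """Write a FractionSet as a long-format TSV (lossless round trip)."""
    rows = []
    for spec in fset:
        for p in spec.peaks:
            rows.append((spec.fraction_index, repr(float(p.mz)),
                         repr(float(p.intensity)),
                         "" if p.snr is None else repr(float(p.snr))))
    frame = pd.DataFrame(rows, columns=["fraction", "mz", "intensity", "snr"])
    if all(r[3] == "" for r in rows):
        frame = frame.drop(columns=["snr"])
    frame.to_csv(path, sep="\t", index=False)


def read_activity_profile(path, convert: str | None = None) -> ActivityProfile:
    """Read a two-column (fraction, activity) TSV.

    ``convert="percent_dpph_remaining"`` turns remaining-%DPPH readings into
    scavenging strength via ``100 - value`` (higher = more active).  The
    conversion is never applied implicitly.
    """
    table = _read_tsv(path, ("fraction", "activity"))
    idx = table["fraction"].astype(int).to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise ValueError(f"{path}: duplicate fraction index")
    order = np.argsort(idx)
    idx = idx[order]
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError(f"{path}: fraction indices must cover 1..N without gaps")
    values = table["activity"].to_numpy(dtype=float)[order]
    if convert == "percent_dpph_remaining":
        values = 100.0 - values
    elif convert is not None:
        raise ValueError(f"unknown activity conversion {convert!r}")
    return ActivityProfile(values)


def write_activity_profile(path, profile: ActivityProfile) -> None:
    frame = pd.DataFrame({
        "fraction": np.arange(1, profile.n_fractions + 1),
        "activity": [repr(float(v)) for v in profile.values],
    })
    frame.to_csv(path, sep="\t", index=False)


def read_binned_matrix(path):
    """Read a wide bin x fraction intensity matrix.

    Layout: one row per mass bin; first column ``mz`` (bin center), then one
    intensity column per fraction named ``f1..fN`` (or bare fraction
    numbers), plus optional ``group_center`` / ``group_size`` annotation
    columns.  Returns a :class:`scamp.preprocess.BinnedMatrix`; detected
    intensity scaling ("unit-norm", "0-100", or "raw") is recorded on its
    ``normalization`` attribute, and any grouping annotations on
    ``group_annotations``.
    """
    from .preprocess import BinnedMatrix

    table = pd.read_csv(path, sep="\t")
    if "mz" not in table.columns:
        raise ValueError(f"{path}: missing mandatory column 'mz'")
    annot_cols = [c for c in ("group_center", "group_size") if c in table.columns]
    frac_cols = [c for c in table.columns if c != "mz" and c not in annot_cols]
    if not frac_cols:
        raise ValueError(f"{path}: no fraction intensity columns")
    expected = [f"f{k}" for k in range(1, len(frac_cols) + 1)]
    bare = [str(k) for k in range(1, len(frac_cols) + 1)]
    if frac_cols != expected and frac_cols != bare:
        raise ValueError(
            f"{path}: fraction columns must be f1..fN (or 1..N) in order; "
            f"got {frac_cols[:5]}..."
        )
    values = table[frac_cols].to_numpy(dtype=float)
    centers = table["mz"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or not np.all(np.isfinite(centers)):
        raise ValueError(f"{path}: non-finite cell in matrix")
    order = np.argsort(centers, kind="stable")
    matrix = BinnedMatrix(bin_centers=centers[order],
                          intensities=values[order], bin_width_ppm=float("nan"))
    row_norms = np.linalg.norm(values, axis=1)
    nonzero = row_norms[row_norms > 0]
    if nonzero.size and np.allclose(nonzero, 1.0, atol=1e-6):
        matrix.normalization = "unit-norm"
    elif values.max(initial=0.0) <= 100.0 + 1e-9:
        matrix.normalization = "0-100"
    else:
        matrix.normalization = "raw"
    if annot_cols:
        matrix.group_annotations = table.iloc[order][annot_cols].reset_index(drop=True)
    return matrix


def write_binned_matrix(path, matrix) -> None:
    columns = {"mz": [repr(float(v)) for v in matrix.bin_centers]}
    for k in range(matrix.n_fractions):
        columns[f"f{k + 1}"] = [repr(float(v)) for v in matrix.intensities[:, k]]
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)


def read_mzml_fraction(path, fraction_index: int) -> FractionSpectrum:
    """Read one centroided mzML file as a fraction spectrum (via pyteomics).

    Peaks from all spectra in the file are pooled; exact-duplicate m/z
    values are merged by the FractionSpectrum invariant.
    """
    from pyteomics import mzml as _mzml

    peaks: list[Peak] = []
    with _mzml.MzML(str(path)) as reader:
        for spectrum in reader:
            mzs = spectrum.get("m/z array")
            intens = spectrum.get("intensity array")
            if mzs is None or intens is None:
                continue
            peaks.extend(Peak(float(m), float(i)) for m, i in zip(mzs, intens))
    return FractionSpectrum(fraction_index, peaks)


_CANDIDATE_COLUMNS = [
    "rank", "mz", "start", "end", "cj", "intensity", "sigma", "n_f",
    "score2", "score3", "score", "name",
]


def write_candidates(path, candidates) -> None:
    """Write a ranked candidate report TSV (lossless float round trip)."""
    rows = []
    for c in candidates:
        rows.append({
            "rank": c.rank, "mz": repr(float(c.mz)), "start": c.start,
            "end": c.end, "cj": repr(float(c.cj)),
            "intensity": repr(float(c.intensity)),
            "sigma": repr(float(c.sigma)), "n_f": c.n_f,
            "score2": repr(float(c.score2)), "score3": repr(float(c.score3)),
            "score": repr(float(c.score)), "name": c.name or "",
        })
    pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates(path):
    """Read a candidate report back into ScoredCandidate objects."""
    from .scoring import ScoredCandidate

    table = _read_tsv(path, ("rank", "mz", "cj", "score"))
    out = []
    for r in table.itertuples():
        name = getattr(r, "name", "")
        out.append(ScoredCandidate(
            mz=float(r.mz), start=int(r.start), end=int(r.end),
            cj=float(r.cj), intensity=float(r.intensity),
            sigma=float(r.sigma), n_f=int(r.n_f),
            score2=float(r.score2), score3=float(r.score3),
            score=float(r.score), rank=int(r.rank),
            name=None if (isinstance(name, float) and math.isnan(name)) or name == ""
            else str(name),
        ))
    return out
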