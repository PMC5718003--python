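"""Spectral preprocessing: blank handling, S/N filtering, de-isotoping,
and cross-fraction ppm binning.

The fixed order of operations is S/N filter -> blank subtraction ->
de-isotoping -> binning.  All tolerances are relative (ppm), matching the
mass accuracy regime of high-field FT-ICR data where absolute windows
would be too loose at low m/z and too tight at high m/z.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .chem_mass import C13_DELTA
from .fraction_io import FractionSet, FractionSpectrum, Peak

__all__ = [
    "BinnedMatrix",
    "average_blanks",
    "subtract_blank",
    "filter_snr",
    "deisotope",
    "bin_across_fractions",
    "count_unit_bins",
    "preprocess_fraction_set",
]


@dataclass
class BinnedMatrix:
    """Per-bin intensity profiles over fractions.

    ``bin_centers`` holds the intensity-weighted centroid m/z of each bin in
    strictly increasing order; ``intensities`` is the (n_bins, N) matrix
    whose row j is the mass profile M_j = (m_1j .. m_Nj).
    """

    bin_centers: np.ndarray
    intensities: np.ndarray
    bin_width_ppm: float
    normalization: str = "raw"
    group_annotations: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensity matrix must be 2-D (bins x fractions)")
        if self.bin_centers.shape[0] != self.intensities.shape[0]:
            raise ValueError("one center per bin row required")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("bin intensities must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    @property
    def n_fractions(self) -> int:
        return int(self.intensities.shape[1])

    def profile(self, j: int) -> np.ndarray:
        """Mass profile of bin j (0-based row index)."""
        return self.intensities[j]


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / b * 1e6


class _CentroidClusterer:
    """Greedy centroid clustering of peaks in descending intensity order.

    A peak joins the nearest existing cluster if it lies within ``tol_ppm``
    of that cluster's running intensity-weighted centroid, otherwise it
    seeds a new cluster.  Visiting peaks by descending intensity anchors
    each cluster on its strongest member, so weak shoulders cannot drag a
    centroid away before the apex is seen.
    """

    def __init__(self, tol_ppm: float) -> None:
        if tol_ppm <= 0:
            raise ValueError("tolerance must be positive")
        self.tol_ppm = tol_ppm
        self._centers: list[float] = []          # sorted
        self._members: dict[int, list[int]] = {}  # cluster id -> peak ids
        self._center_of: dict[int, float] = {}
        self._weight_of: dict[int, float] = {}
        self._id_at: list[int] = []               # parallel to _centers
        self._next_id = 0

    def add(self, peak_id: int, mz: float, intensity: float) -> None:
        cluster = self._nearest_within(mz)
        if cluster is None:
            cluster = self._next_id
            self._next_id += 1
            self._center_of[cluster] = mz
            self._weight_of[cluster] = intensity
            self._members[cluster] = [peak_id]
            self._insert_sorted(mz, cluster)
            return
        pos = self._locate(cluster)
        del self._centers[pos], self._id_at[pos]
        w_old = self._weight_of[cluster]
        c_old = self._center_of[cluster]
        w_new = w_old + intensity
        # zero-intensity peaks join but do not move the centroid
        center = (c_old * w_old + mz * intensity) / w_new if w_new > 0 else c_old
        self._center_of[cluster] = center
        self._weight_of[cluster] = w_new
        self._members[cluster].append(peak_id)
        self._insert_sorted(center, cluster)

    def _nearest_within(self, mz: float) -> int | None:
        if not self._centers:
            return None
        i = bisect_left(self._centers, mz)
        best, best_ppm = None, self.tol_ppm
        for k in (i - 1, i):
            if 0 <= k < len(self._centers):
                d = _ppm(mz, self._centers[k])
                if d <= best_ppm:
                    best, best_ppm = self._id_at[k], d
        return best

    def _locate(self, cid: int) -> int:
        pos = bisect_left(self._centers, self._center_of[cid])
        while self._id_at[pos] != cid:
            pos += 1
        return pos

    def _insert_sorted(self, center: float, cid: int) -> None:
        pos = bisect_left(self._centers, center)
        self._centers.insert(pos, center)
        self._id_at.insert(pos, cid)

    def clusters(self) -> list[tuple[float, list[int]]]:
        """(centroid, member peak ids) sorted by centroid ascending."""
        return [
            (self._center_of[cid], self._members[cid])
            for cid in sorted(self._center_of, key=lambda c: self._center_of[c])
        ]


def average_blanks(blanks: list[FractionSpectrum], tol_ppm: float = 1.0) -> FractionSpectrum:
    """Average replicate blank spectra into one consensus blank.

    Peaks within ``tol_ppm`` across replicates are merged: the merged m/z is
    the intensity-weighted mean and the merged intensity is the mean over
    ALL replicates (a peak absent from a replicate contributes zero), so a
    sporadic contaminant is down-weighted by its absence.
    """
    if not blanks:
        raise ValueError("at least one blank spectrum is required")
    n_blanks = len(blanks)
    pool: list[tuple[float, float]] = []
    for blank in blanks:
        pool.extend((p.mz, p.intensity) for p in blank.peaks)
    order = sorted(range(len(pool)), key=lambda i: (-pool[i][1], pool[i][0]))
    clusterer = _CentroidClusterer(tol_ppm)
    for i in order:
        clusterer.add(i, pool[i][0], pool[i][1])
    merged = [
        Peak(center, sum(pool[i][1] for i in members) / n_blanks)
        for center, members in clusterer.clusters()
    ]
    return FractionSpectrum(1, merged)


def subtract_blank(spectrum: FractionSpectrum, blank: FractionSpectrum,
                   tol_ppm: float = 1.0, ratio: float = 3.0) -> FractionSpectrum:
    """Remove sample peaks attributable to the blank.

    A sample peak is removed iff a blank peak lies within ``tol_ppm`` AND
    the sample intensity is at most ``ratio`` times that blank intensity.
    ``ratio=inf`` removes on mass match alone; the finite default protects a
    genuine sample signal that happens to coincide with a trace blank peak.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if ratio < 1:
        raise ValueError("blank ratio must be >= 1")
    if not blank.peaks:
        return FractionSpectrum(spectrum.fraction_index, list(spectrum.peaks))
    blank_mz = blank.mz_array()
    blank_int = blank.intensity_array()
    kept = []
    for p in spectrum.peaks:
        lo = np.searchsorted(blank_mz, p.mz * (1 - tol_ppm * 1e-6))
        hi = np.searchsorted(blank_mz, p.mz * (1 + tol_ppm * 1e-6), side="right")
        window = blank_int[lo:hi]
        matched = window.size > 0 and (
            math.isinf(ratio) or p.intensity <= ratio * window.max()
        )
        if not matched:
            kept.append(p)
    return FractionSpectrum(spectrum.fraction_index, kept)


def filter_snr(spectrum: FractionSpectrum, min_snr: float = 4.0) -> FractionSpectrum:
    """Keep peaks with S/N strictly greater than ``min_snr``.

    Peaks lacking an S/N estimate are kept (there is nothing to test).
    """
    if min_snr < 0:
        raise ValueError("min_snr must be non-negative")
    kept = [p for p in spectrum.peaks if p.snr is None or p.snr > min_snr]
    return FractionSpectrum(spectrum.fraction_index, kept)


def deisotope(spectrum: FractionSpectrum, tol_ppm: float = 1.0,
              max_shift: int = 3) -> FractionSpectrum:
    """Remove carbon-13 isotopologue satellites.

    Peaks are processed in descending intensity (ties by ascending m/z).
    For each still-retained peak P, any retained peak within ``tol_ppm`` of
    P.mz + n x 1.0033548378 Da (n = 1..max_shift) whose intensity is lower
    than P's is removed.  Removed peaks are never themselves used as
    parents, so a satellite cannot shelter its own satellites.  Idempotent.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if not 1 <= max_shift <= 3:
        raise ValueError("max_shift must be in 1..3")
    peaks = spectrum.peaks
    if len(peaks) < 2:
        return FractionSpectrum(spectrum.fraction_index, list(peaks))
    mz = spectrum.mz_array()
    intensity = spectrum.intensity_array()
    retained = np.ones(len(peaks), dtype=bool)
    order = sorted(range(len(peaks)), key=lambda i: (-intensity[i], mz[i]))
    for i in order:
        if not retained[i]:
            continue
        for n in range(1, max_shift + 1):
            target = mz[i] + n * C13_DELTA
            lo = np.searchsorted(mz, target * (1 - tol_ppm * 1e-6))
            hi = np.searchsorted(mz, target * (1 + tol_ppm * 1e-6), side="right")
            for j in range(lo, hi):
                if retained[j] and intensity[j] < intensity[i]:
                    retained[j] = False
    kept = [p for keep, p in zip(retained, peaks) if keep]
    return FractionSpectrum(spectrum.fraction_index, kept)


def bin_across_fractions(fset: FractionSet, bin_ppm: float = 0.5) -> BinnedMatrix:
    """Cluster peaks from all fractions into ppm mass bins.

    ``bin_ppm`` is a tolerance radius: every member peak lies within
    ``bin_ppm`` of its bin's intensity-weighted centroid.  Multiple peaks
    from the same fraction falling in one bin have their intensities
    summed into m_kj.  Total intensity is conserved.
    """
    if bin_ppm <= 0:
        raise ValueError("bin width must be positive")
    entries: list[tuple[float, float, int]] = []  # (mz, intensity, fraction k)
    for spec in fset:
        entries.extend((p.mz, p.intensity, spec.fraction_index) for p in spec.peaks)
    n = fset.n_fractions
    if not entries:
        return BinnedMatrix(np.empty(0), np.empty((0, n)), bin_ppm)
    order = sorted(range(len(entries)), key=lambda i: (-entries[i][1], entries[i][0]))
    clusterer = _CentroidClusterer(bin_ppm)
    for i in order:
        clusterer.add(i, entries[i][0], entries[i][1])
    clusters = clusterer.clusters()
    centers = np.array([c for c, _ in clusters])
    matrix = np.zeros((len(clusters), n))
    for j, (_, members) in enumerate(clusters):
        for i in members:
            _, inten, k = entries[i]
            matrix[j, k - 1] += inten
    # centroids of distinct clusters can coincide only for zero-weight bins
    keep = np.concatenate([[True], np.diff(centers) > 0])
    return BinnedMatrix(centers[keep], matrix[keep], bin_ppm)


def count_unit_bins(mz_lo: int, mz_hi: int) -> int:
    """Number of unit-resolution bins covering [mz_lo, mz_hi] inclusive."""
    if mz_hi < mz_lo:
        raise ValueError("inverted m/z range")
    return int(mz_hi) - int(mz_lo) + 1


def preprocess_fraction_set(
    fset: FractionSet,
    blanks: list[FractionSpectrum] | None = None,
    min_snr: float = 4.0,
    blank_tol_ppm: float = 1.0,
    blank_ratio: float = 3.0,
    deisotope_tol_ppm: float = 1.0,
    max_shift: int = 3,
    bin_ppm: float = 0.5,
) -> BinnedMatrix:
    """Full preprocessing chain: S/N filter -> blank subtraction ->
    de-isotoping -> ppm binning."""
    consensus = average_blanks(blanks, blank_tol_ppm) if blanks else None
    cleaned = []
    for spec in fset:
        spec = filter_snr(spec, min_snr)
        if consensus is not None:
            spec = subtract_blank(spec, consensus, blank_tol_ppm, blank_ratio)
        spec = deisotope(spec, deisotope_tol_ppm, max_shift)
        cleaned.append(spec)
    return bin_across_fractions(FractionSet(cleaned), bin_ppm)
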