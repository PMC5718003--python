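"""Synthetic fractionated-extract datasets with known ground truth.

The simulator emulates the data a bioassay-guided fractionation study
produces: N sequential chromatographic fractions, each compound eluting as
a discretized Gaussian over fractions, centroid peak lists with carbon-13
isotopologue satellites and blank contaminant peaks, and a per-fraction
activity profile that is a noisy weighted sum of the planted active
compounds' amounts.  Because the true actives and their m/z are known,
every pipeline stage — de-isotoping, blank removal, binning, scoring,
enrichment — can be checked against ground truth.

The linearity of activity in active-compound amounts is the additivity
assumption implicit in correlation-based ranking itself; the simulator
makes it explicit.  It does not model ionization suppression, detector
saturation, or retention-time drift.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .chem_mass import C13_DELTA
from .enrichment import LabeledRanking
from .fraction_io import ActivityProfile, FractionSet, FractionSpectrum, Peak

__all__ = [
    "SimulationConfig",
    "CompoundTruth",
    "GroundTruth",
    "elution_profile",
    "simulate_dataset",
    "truth_labels",
    "labeled_ranking",
]

#: natural abundance of carbon-13
_P_C13 = 0.0107


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a simulated fractionation experiment.

    Defaults mirror a 33-fraction preparative-LC campaign: a couple of
    hundred detectable compounds, a handful of genuine actives, compound
    abundances spanning roughly two orders of magnitude (log-normal), and
    an assay whose replicate noise is a few percent of the activity range.
    """

    seed: int
    n_fractions: int = 33
    n_compounds: int = 200
    n_active: int = 8
    mz_min: float = 120.0
    mz_max: float = 1200.0
    min_spacing_ppm: float = 20.0
    elution_width_range: tuple[float, float] = (0.4, 0.9)
    abundance_log_mean: float = 12.0
    abundance_log_sd: float = 1.0
    active_abundance_log_shift: float = 2.0
    active_abundance_log_sd: float = 0.35
    activity_contribution_range: tuple[float, float] = (0.3, 1.0)
    isomer_fraction: float = 0.1
    activity_noise_sd: float = 0.05
    blank_n_peaks: int = 30
    blank_intensity_range: tuple[float, float] = (1e3, 1e5)
    noise_peaks_per_fraction: int = 60
    noise_intensity_range: tuple[float, float] = (5e2, 2e4)
    n_blank_replicates: int = 3
    isotope_satellites: bool = True
    noise_floor: float = 200.0
    intensity_rel_threshold: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("need at least one compound")
        if not 0 <= self.n_active <= self.n_compounds:
            raise ValueError("n_active must be in 0..n_compounds")
        if self.mz_max <= self.mz_min or self.mz_min <= 0:
            raise ValueError("invalid m/z range")
        if self.elution_width_range[0] <= 0 or (
                self.elution_width_range[1] < self.elution_width_range[0]):
            raise ValueError("invalid elution width range")
        if self.activity_noise_sd < 0:
            raise ValueError("activity noise sd must be non-negative")
        if self.n_fractions < 2:
            raise ValueError("need at least two fractions")
        if not 0.0 <= self.isomer_fraction < 1.0:
            raise ValueError("isomer fraction must be in [0, 1)")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class CompoundTruth:
    """Ground truth for one simulated compound."""

    identifier: str
    mz: float
    n_carbon: int
    amounts: np.ndarray
    active: bool
    potency: float


@dataclass
class GroundTruth:
    """All planted compounds plus the noiseless activity vector."""

    compounds: list[CompoundTruth]
    noiseless_activity: np.ndarray = field(default=None)

    @property
    def active_mz(self) -> np.ndarray:
        return np.array([c.mz for c in self.compounds if c.active])


def elution_profile(center: float, width: float, n: int) -> np.ndarray:
    """Discretized Gaussian elution over fraction indices 1..n, unit sum.

    ``width`` is the Gaussian sigma in fraction units; as width -> 0 the
    profile tends to an indicator at the nearest fraction.
    """
    if width <= 0:
        raise ValueError("elution width must be positive")
    if n < 1:
        raise ValueError("need at least one fraction")
    k = np.arange(1, n + 1, dtype=float)
    z = (k - center) / width
    profile = np.exp(-0.5 * z**2)
    total = profile.sum()
    if total == 0.0:  # width so small every exponent underflows except nearest
        profile = np.zeros(n)
        profile[int(np.clip(round(center), 1, n)) - 1] = 1.0
        return profile
    return profile / total


def _draw_mz_values(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Draw compound m/z values, rejecting near-coincidences.

    Two constraints keep ground truth unambiguous: monoisotopic peaks of
    distinct compounds are at least ``min_spacing_ppm`` apart, and no
    compound sits within 5 ppm of another compound's +1..+3 carbon-13
    satellite position (so de-isotoping cannot be tricked by construction).
    """
    accepted: list[float] = []
    attempts = 0
    while len(accepted) < cfg.n_compounds:
        attempts += 1
        if attempts > 1000 * cfg.n_compounds:
            raise ValueError("m/z range too crowded for requested compound count")
        mz = float(rng.uniform(cfg.mz_min, cfg.mz_max))
        ok = True
        for other in accepted:
            if abs(mz - other) / other * 1e6 < cfg.min_spacing_ppm:
                ok = False
                break
            for shift in (C13_DELTA, 2 * C13_DELTA, 3 * C13_DELTA):
                if (abs(mz - (other + shift)) / mz * 1e6 < 5.0
                        or abs(other - (mz + shift)) / other * 1e6 < 5.0):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            accepted.append(mz)
    return np.array(accepted)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[FractionSet, list[FractionSpectrum], ActivityProfile, GroundTruth]:
    """Simulate (fraction spectra, blank replicates, activity, ground truth).

    Each compound contributes abundance x elution peaks at its m/z, plus +1
    and +2 carbon-13 satellites at the binomially expected intensity ratios
    from its carbon count when satellites are enabled.  Blank contaminant
    peaks appear both in every fraction and in the blank replicate spectra.
    Activity is a_k = sum_i(active) potency_i x amount_ik plus Gaussian
    noise (sd = activity_noise_sd x max signal), clipped at zero.  The same
    seed reproduces the dataset bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fractions

    mz_values = _draw_mz_values(rng, cfg)
    # structural isomers: a share of compounds reuses another compound's
    # m/z while eluting independently — the shared-mass-bin scenario the
    # grouping step exists to disentangle
    n_isomers = int(round(cfg.isomer_fraction * cfg.n_compounds))
    if n_isomers and cfg.n_compounds > 1:
        isomer_idx = rng.choice(np.arange(1, cfg.n_compounds),
                                size=min(n_isomers, cfg.n_compounds - 1),
                                replace=False)
        for i in isomer_idx:
            mz_values[i] = mz_values[int(rng.integers(0, i))]
    centers = rng.uniform(1.0, float(n), size=cfg.n_compounds)
    widths = rng.uniform(*cfg.elution_width_range, size=cfg.n_compounds)
    abundances = rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd,
                               size=cfg.n_compounds)
    active_idx = rng.choice(cfg.n_compounds, size=cfg.n_active, replace=False)
    active_mask = np.zeros(cfg.n_compounds, dtype=bool)
    active_mask[active_idx] = True

    # Actives elute spread across the fractionation (stratified centers
    # with within-stratum jitter), matching how a validation panel of
    # standards covers the whole elution range rather than piling into one
    # fraction window.
    if cfg.n_active:
        strata = rng.permutation(cfg.n_active)
        centers[active_idx] = 1.0 + (n - 1.0) * (
            strata + rng.uniform(0.1, 0.9, size=cfg.n_active)) / cfg.n_active

    # Planted actives are assay-detectable by construction: a compound can
    # only drive a measurable assay signal if it is physically present in
    # quantity, so active abundances sit in the upper-middle of the global
    # abundance distribution (log shift + tighter spread), and each
    # active's peak contribution to the activity profile is a comparable
    # share of the activity scale.  An "active" whose contribution drowns
    # in assay noise would not be meaningful ground truth.
    active_abundance = rng.lognormal(
        cfg.abundance_log_mean + cfg.active_abundance_log_shift * cfg.abundance_log_sd,
        cfg.active_abundance_log_sd, size=cfg.n_compounds)
    abundances = np.where(active_mask, active_abundance, abundances)

    compounds: list[CompoundTruth] = []
    amounts = np.zeros((cfg.n_compounds, n))
    for i in range(cfg.n_compounds):
        amounts[i] = abundances[i] * elution_profile(centers[i], widths[i], n)

    contributions = rng.uniform(*cfg.activity_contribution_range,
                                size=cfg.n_compounds)
    peak_amount = amounts.max(axis=1)
    potencies = np.where(active_mask, contributions / peak_amount, 0.0)

    for i in range(cfg.n_compounds):
        n_carbon = max(5, int(round(mz_values[i] * 0.55 / 12.0)))
        compounds.append(CompoundTruth(
            identifier=f"cmpd{i + 1:04d}", mz=float(mz_values[i]),
            n_carbon=n_carbon, amounts=amounts[i],
            active=bool(active_mask[i]),
            potency=float(potencies[i]) if active_mask[i] else 0.0,
        ))

    # blank contaminants: constant background present everywhere
    blank_mz = rng.uniform(cfg.mz_min, cfg.mz_max, size=cfg.blank_n_peaks)
    blank_int = np.exp(rng.uniform(np.log(cfg.blank_intensity_range[0]),
                                   np.log(cfg.blank_intensity_range[1]),
                                   size=cfg.blank_n_peaks))
    blanks = []
    for b in range(cfg.n_blank_replicates):
        jitter = 1.0 + 0.05 * rng.standard_normal(cfg.blank_n_peaks)
        intens = np.clip(blank_int * jitter, 0.0, None)
        blanks.append(FractionSpectrum(1, [
            Peak(float(m), float(v), float(v / cfg.noise_floor))
            for m, v in zip(blank_mz, intens) if v > 0
        ]))

    fractions = []
    for k in range(1, n + 1):
        peaks: list[Peak] = []
        for i, compound in enumerate(compounds):
            base = amounts[i, k - 1]
            if base < cfg.intensity_rel_threshold * abundances[i]:
                continue
            satellite_ratios = [(0, 1.0)]
            if cfg.isotope_satellites:
                p1 = compound.n_carbon * _P_C13
                satellite_ratios += [(1, p1), (2, p1 * p1 / 2.0)]
            for shift, ratio in satellite_ratios:
                inten = base * ratio
                peaks.append(Peak(compound.mz + shift * C13_DELTA, inten,
                                  inten / cfg.noise_floor))
        jitter = 1.0 + 0.05 * rng.standard_normal(cfg.blank_n_peaks)
        for m, v in zip(blank_mz, np.clip(blank_int * jitter, 0.0, None)):
            if v > 0:
                peaks.append(Peak(float(m), float(v), float(v / cfg.noise_floor)))
        # sporadic low-intensity noise peaks, independent per fraction
        if cfg.noise_peaks_per_fraction:
            noise_mz = rng.uniform(cfg.mz_min, cfg.mz_max,
                                   size=cfg.noise_peaks_per_fraction)
            noise_int = np.exp(rng.uniform(
                np.log(cfg.noise_intensity_range[0]),
                np.log(cfg.noise_intensity_range[1]),
                size=cfg.noise_peaks_per_fraction))
            peaks.extend(Peak(float(m), float(v), float(v / cfg.noise_floor))
                         for m, v in zip(noise_mz, noise_int))
        fractions.append(FractionSpectrum(k, peaks))

    noiseless = potencies @ amounts
    noise_scale = cfg.activity_noise_sd * (noiseless.max() if noiseless.max() > 0
                                           else 1.0)
    activity = noiseless + noise_scale * rng.standard_normal(n)
    activity = np.clip(activity, 0.0, None)

    truth = GroundTruth(compounds=compounds, noiseless_activity=noiseless)
    return FractionSet(fractions), blanks, ActivityProfile(activity), truth


def truth_labels(gt: GroundTruth, candidate_mz, tol_ppm: float = 1.0) -> np.ndarray:
    """Boolean labels: candidate m/z within ``tol_ppm`` of an active's m/z."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    candidate_mz = np.asarray(candidate_mz, dtype=float)
    actives = gt.active_mz
    labels = np.zeros(candidate_mz.size, dtype=bool)
    for i, mz in enumerate(candidate_mz):
        if actives.size:
            labels[i] = bool(np.min(np.abs(actives - mz) / mz) * 1e6 <= tol_ppm)
    return labels


def labeled_ranking(candidates, gt: GroundTruth,
                    tol_ppm: float = 1.0) -> LabeledRanking:
    """Build a LabeledRanking from scored candidates and ground truth."""
    flags = truth_labels(gt, [c.mz for c in candidates], tol_ppm)
    return LabeledRanking(
        ids=[f"{c.mz:.5f}@{c.start}-{c.end}" for c in candidates],
        active=flags,
        scores=np.array([c.score for c in candidates], dtype=float),
    )
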