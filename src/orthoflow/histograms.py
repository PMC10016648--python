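"""Internal-standard flow-cytometry genome size measurement.

A stained-nuclei suspension run on a flow cytometer yields a fluorescence
histogram with (at least) two G0/G1 peaks: the sample's nuclei and the nuclei
of a co-processed internal standard of known DNA content.  Genome size follows
from the ratio of peak positions,

    2C_sample = 2C_standard * (sample peak mean / standard peak mean),

which cancels instrument gain.  This module fits the peaks, forms the ratio,
converts picograms to gigabase pairs (1 pg = 0.978 Gbp) and attaches
quality-control flags based on peak coefficients of variation (CV) and the
number of recorded particles.

The peak model is deliberately simple: a centered moving average smooths the
histogram, local maxima above a height threshold seed per-peak windows, and a
Gaussian is least-squares fitted inside each window.  Instrument software does
the same job interactively; any method that recovers simulated peak ratios to
well under a percent is adequate for 2C estimation, where biological and
staining variation dominate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .errors import (
    EmptyHistogramError,
    InvalidMassError,
    InvalidPeakError,
    PeaksNotFoundError,
)

#: Picograms of DNA per gigabase pair conversion factor.
PG_TO_GBP = 0.978


class Dye(str, enum.Enum):
    """Fluorochrome class.

    AT-selective dyes (DAPI) report genome size *and* base composition;
    intercalating dyes (propidium iodide) report genome size only.
    """

    AT_SELECTIVE = "AT_SELECTIVE"
    INTERCALATING = "INTERCALATING"

    @classmethod
    def parse(cls, value: "Dye | str") -> "Dye":
        if isinstance(value, Dye):
            return value
        key = str(value).strip().upper()
        aliases = {"DAPI": cls.AT_SELECTIVE, "PI": cls.INTERCALATING}
        if key in aliases:
            return aliases[key]
        return cls(key)


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, value: "Sex | str | None") -> "Sex":
        if value is None:
            return cls.UNKNOWN
        if isinstance(value, Sex):
            return value
        key = str(value).strip().upper()
        aliases = {"FEMALE": cls.F, "MALE": cls.M, "": cls.UNKNOWN}
        return aliases.get(key, cls(key))


@dataclass(frozen=True)
class StandardRef:
    """An internal standard of known diploid DNA content and GC fraction."""

    name: str
    genome_size_2C_pg: float
    gc_percent: float

    def __post_init__(self):
        if self.genome_size_2C_pg <= 0:
            raise InvalidMassError("invalid-mass: standard 2C must be positive")
        if not 0 < self.gc_percent < 100:
            raise InvalidMassError("invalid-mass: GC percent outside (0, 100)")

    @property
    def at_fraction(self) -> float:
        return 1.0 - self.gc_percent / 100.0


#: Garden pea cultivar widely used as an internal plant standard:
#: 2C = 9.09 pg, GC = 38.50 %.
PISUM_CTIRAD = StandardRef("Pisum sativum 'Ctirad'", 9.09, 38.50)


@dataclass
class Histogram:
    """A single-parameter fluorescence histogram for one run.

    Parameters
    ----------
    bin_centers
        Strictly increasing fluorescence channel values (arbitrary units).
    counts
        Non-negative particle counts per bin; at least one particle total.
    dye
        Which fluorochrome class was used.
    meta
        Free-form run annotations (specimen id, species, sex, instrument...).
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    dye: Dye = Dye.INTERCALATING
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.dye = Dye.parse(self.dye)
        if self.bin_centers.ndim != 1 or self.bin_centers.shape != self.counts.shape:
            raise EmptyHistogramError("empty-histogram: shape mismatch")
        if self.bin_centers.size == 0:
            raise EmptyHistogramError("empty-histogram: no bins")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise InvalidPeakError("invalid-peak: bin centers not strictly increasing")
        if np.any(self.counts < 0):
            raise InvalidPeakError("invalid-peak: negative counts")

    @property
    def total_particles(self) -> float:
        return float(self.counts.sum())


def read_histogram_tsv(path: str | Path, dye: Dye | str, **meta) -> Histogram:
    """Read a plain two-column (channel, count) TSV; header row optional."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    # a non-numeric first row is a header
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.astype(float)
    if df.shape[1] < 2:
        raise EmptyHistogramError("empty-histogram: expected two columns")
    return Histogram(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                     dye=dye, meta={"path": str(path), **meta})


def write_histogram_tsv(hist: Histogram, path: str | Path) -> None:
    pd.DataFrame({"channel": hist.bin_centers, "count": hist.counts}).to_csv(
        path, sep="\t", index=False)


@dataclass(frozen=True)
class PeakFit:
    """A fitted Gaussian peak.

    ``window`` is the (lo, hi) bin-index range (inclusive) used for the fit;
    ``area`` is the number of recorded particles inside that window.
    """

    mean: float
    sd: float
    cv_percent: float
    area: float
    window: tuple[int, int]


class PeakFitResults:
    """Result container for :class:`HistogramPeakModel`."""

    def __init__(self, model: "HistogramPeakModel", peaks: list[PeakFit]):
        self.model = model
        self.peaks = peaks

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i) -> PeakFit:
        return self.peaks[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"mean": p.mean, "sd": p.sd, "cv_percent": p.cv_percent,
              "area": p.area, "window_lo": p.window[0], "window_hi": p.window[1]}
             for p in self.peaks])

    def summary(self) -> str:
        lines = ["Gaussian peak fit",
                 f"  histogram: {self.model.hist.total_particles:.0f} particles, "
                 f"{self.model.hist.bin_centers.size} bins, dye={self.model.hist.dye.value}",
                 self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)


class HistogramPeakModel:
    """Detect and fit ``n_expected`` Gaussian peaks in a fluorescence histogram.

    Parameters
    ----------
    hist
        The histogram to fit.
    n_expected
        Number of G0/G1 peaks expected (1 for a bare sample, 2 with an
        internal standard).
    smoothing_window
        Odd bin count of the centered moving average applied before maximum
        detection.  Smoothing affects detection only, never the fit itself.
    min_height_frac
        Local maxima below this fraction of the tallest smoothed bin are
        ignored (debris/noise rejection).
    """

    def __init__(self, hist: Histogram, n_expected: int = 2,
                 smoothing_window: int = 5, min_height_frac: float = 0.1):
        if n_expected not in (1, 2):
            raise InvalidPeakError("invalid-peak: n_expected must be 1 or 2")
        if smoothing_window < 1 or smoothing_window % 2 == 0:
            raise InvalidPeakError("invalid-peak: smoothing_window must be odd")
        if not 0 < min_height_frac < 1:
            raise InvalidPeakError("invalid-peak: min_height_frac outside (0, 1)")
        self.hist = hist
        self.n_expected = n_expected
        self.smoothing_window = smoothing_window
        self.min_height_frac = min_height_frac

    def fit(self) -> PeakFitResults:
        hist = self.hist
        counts = hist.counts
        if counts.sum() < 1:
            raise EmptyHistogramError("empty-histogram: all counts zero")

        kernel = np.ones(self.smoothing_window) / self.smoothing_window
        smoothed = np.convolve(counts, kernel, mode="same")
        threshold = self.min_height_frac * smoothed.max()
        # maxima closer than ~1% of the scale are jitter on one physical peak
        min_sep = max(self.smoothing_window, counts.size // 100)
        idx, props = signal.find_peaks(smoothed, height=threshold,
                                       distance=min_sep)
        if idx.size < self.n_expected:
            raise PeaksNotFoundError(
                f"peaks-not-found: {idx.size} maxima above threshold, "
                f"{self.n_expected} expected")

        # keep the n_expected tallest maxima, in channel order
        order = np.argsort(props["peak_heights"])[::-1][: self.n_expected]
        sel = np.sort(idx[order])

        widths, *_ = signal.peak_widths(smoothed, sel, rel_height=0.5)
        bin_width = float(np.median(np.diff(hist.bin_centers)))

        peaks = []
        for k, i0 in enumerate(sel):
            sd0_bins = max(widths[k] / 2.355, 1.0)  # FWHM -> sd
            lo = int(max(0, math.floor(i0 - 3 * sd0_bins)))
            hi = int(min(counts.size - 1, math.ceil(i0 + 3 * sd0_bins)))
            # keep windows disjoint: cut at midpoints between selected maxima
            if k > 0:
                lo = max(lo, (sel[k - 1] + i0) // 2 + 1)
            if k < len(sel) - 1:
                hi = min(hi, (i0 + sel[k + 1]) // 2)
            peaks.append(self._fit_window(i0, lo, hi, sd0_bins * bin_width))
        return PeakFitResults(self, peaks)

    def _fit_window(self, i0: int, lo: int, hi: int, sd0: float) -> PeakFit:
        hist = self.hist
        x = hist.bin_centers[lo:hi + 1]
        y = hist.counts[lo:hi + 1]
        mu0 = float(hist.bin_centers[i0])
        a0 = float(max(hist.counts[i0], 1.0))

        def gauss(x, a, mu, sd):
            return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

        try:
            popt, _ = optimize.curve_fit(
                gauss, x, y, p0=(a0, mu0, max(sd0, 1e-6)),
                bounds=([0.0, x[0], 1e-9], [np.inf, x[-1], (x[-1] - x[0]) + 1.0]),
                maxfev=10000)
            _, mu, sd = popt
        except RuntimeError:
            # fall back to moment estimates over the window
            w = y / y.sum() if y.sum() > 0 else np.full_like(y, 1.0 / y.size)
            mu = float(np.sum(w * x))
            sd = float(np.sqrt(np.sum(w * (x - mu) ** 2)))
        mu, sd = float(mu), abs(float(sd))
        if mu <= 0:
            raise InvalidPeakError("invalid-peak: non-positive fitted mean")
        return PeakFit(mean=mu, sd=sd, cv_percent=100.0 * sd / mu,
                       area=float(hist.counts[lo:hi + 1].sum()), window=(lo, hi))


def fit_peaks(hist: Histogram, n_expected: int = 2, smoothing_window: int = 5,
              min_height_frac: float = 0.1) -> list[PeakFit]:
    """Functional wrapper around :class:`HistogramPeakModel`.

    Returns exactly ``n_expected`` :class:`PeakFit` objects sorted by
    ascending mean.
    """
    res = HistogramPeakModel(hist, n_expected, smoothing_window,
                             min_height_frac).fit()
    return sorted(res.peaks, key=lambda p: p.mean)


def genome_size_from_ratio(sample_peak_mean: float, standard_peak_mean: float,
                           standard: StandardRef) -> float:
    """2C genome size (pg) from the sample/standard peak-position ratio."""
    if sample_peak_mean <= 0 or standard_peak_mean <= 0:
        raise InvalidPeakError("invalid-peak: peak means must be positive")
    return standard.genome_size_2C_pg * (sample_peak_mean / standard_peak_mean)


def pg_to_gbp(mass_pg: float) -> float:
    """Convert a DNA mass in picograms to gigabase pairs (1 pg = 0.978 Gbp)."""
    if mass_pg < 0:
        raise InvalidMassError("invalid-mass: negative picogram value")
    return PG_TO_GBP * mass_pg


# QC flag labels
HIGH_CV_SAMPLE = "HIGH_CV_SAMPLE"
HIGH_CV_STANDARD = "HIGH_CV_STANDARD"
LOW_PARTICLES = "LOW_PARTICLES"
RELATIVE = "RELATIVE"          # AT-selective dye only: relative genome size
GC_OUT_OF_RANGE = "GC_OUT_OF_RANGE"


@dataclass
class Measurement:
    """One specimen x one dye genome size measurement."""

    specimen_id: str
    species: str
    sex: Sex
    dye: Dye
    ratio: float
    genome_size_2C_pg: float
    genome_size_1C_pg: float
    genome_size_1C_gbp: float
    cv_sample: float
    cv_standard: float
    n_particles: float
    qc_flags: set = field(default_factory=set)

    @classmethod
    def from_ratio(cls, specimen_id: str, species: str, sex, dye, ratio: float,
                   standard: StandardRef, cv_sample: float, cv_standard: float,
                   n_particles: float) -> "Measurement":
        if ratio <= 0:
            raise InvalidPeakError("invalid-peak: non-positive ratio")
        c2 = standard.genome_size_2C_pg * ratio
        c1 = c2 / 2.0
        return cls(specimen_id, species, Sex.parse(sex), Dye.parse(dye), ratio,
                   c2, c1, pg_to_gbp(c1), cv_sample, cv_standard, n_particles)


def qc_check(m: Measurement, max_cv_percent: float = 5.0,
             min_particles: float = 3000) -> set:
    """QC predicate: empty set means pass.

    Thresholds default to 5 % CV and 3,000 particles — loose enough to accept
    routine runs (median CVs around 2-4 %, 3,500-5,000 particles) while
    flagging clearly degraded data.
    """
    flags = set()
    if m.cv_sample > max_cv_percent:
        flags.add(HIGH_CV_SAMPLE)
    if m.cv_standard > max_cv_percent:
        flags.add(HIGH_CV_STANDARD)
    if m.n_particles < min_particles:
        flags.add(LOW_PARTICLES)
    return flags


def measure_histogram(hist: Histogram, standard: StandardRef,
                      standard_window: tuple[float, float],
                      smoothing_window: int = 5, min_height_frac: float = 0.1,
                      max_cv_percent: float = 5.0, min_particles: float = 3000,
                      ) -> Measurement:
    """Fit sample + standard peaks and form a Measurement.

    The standard peak is NOT assumed to be the lower-fluorescence one — sample
    2C values straddle plant standards — so the caller supplies the channel
    window ``(lo, hi)`` where instrument gain places the standard.
    """
    peaks = fit_peaks(hist, 2, smoothing_window, min_height_frac)
    lo, hi = standard_window
    in_window = [p for p in peaks if lo <= p.mean <= hi]
    if not in_window:
        raise PeaksNotFoundError(
            f"peaks-not-found: no fitted peak inside standard window {lo}:{hi}")
    centre = 0.5 * (lo + hi)
    std_peak = min(in_window, key=lambda p: abs(p.mean - centre))
    others = [p for p in peaks if p is not std_peak]
    sample_peak = others[0]

    meta = hist.meta
    m = Measurement.from_ratio(
        specimen_id=str(meta.get("specimen_id", "unknown")),
        species=str(meta.get("species", "unknown")),
        sex=meta.get("sex", Sex.UNKNOWN), dye=hist.dye,
        ratio=sample_peak.mean / std_peak.mean, standard=standard,
        cv_sample=sample_peak.cv_percent, cv_standard=std_peak.cv_percent,
        n_particles=hist.total_particles)
    m.qc_flags = qc_check(m, max_cv_percent, min_particles)
    return m


def measurements_to_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    """Tabulate measurements with the stable output column contract."""
    rows = []
    for m in measurements:
        rows.append({
            "specimen_id": m.specimen_id, "species": m.species,
            "sex": m.sex.value, "dye": m.dye.value, "ratio": m.ratio,
            "c2_pg": m.genome_size_2C_pg, "c1_pg": m.genome_size_1C_pg,
            "c1_gbp": m.genome_size_1C_gbp, "cv_sample": m.cv_sample,
            "cv_standard": m.cv_standard, "n_particles": m.n_particles,
            "qc_flags": ";".join(sorted(m.qc_flags))})
    return pd.DataFrame(rows)


def measure_directory(histograms: Sequence[tuple[Histogram, dict]] | Sequence[Histogram],
                      standard: StandardRef, standard_window: tuple[float, float],
                      **kwargs) -> pd.DataFrame:
    """Measure a batch of histograms; returns the tabulated measurements."""
    out = []
    for h in histograms:
        hist = h[0] if isinstance(h, tuple) else h
        if isinstance(h, tuple):
            hist.meta.update(h[1])
        out.append(measure_histogram(hist, standard, standard_window, **kwargs))
    return measurements_to_frame(out)
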