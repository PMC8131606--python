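"""Spectral FRET, acceptor-photobleach FRET and bleach-step counting.

Three fluorescence readouts of membrane-protein self-association:

* **FRET_scaled** — in-vitro spectral FRET for donor/acceptor-labelled
  protein mixtures.  Emission spectra (donor excitation) are buffer-
  subtracted using the Rayleigh scatter peak to scale the buffer spectrum,
  corrected for protein loss via direct acceptor excitation (area ratio
  over 660-700 nm), and summarised as the 670 nm emission ratio of the
  donor-acceptor mixture versus the acceptor-only sample, minus the same
  ratio for mock-treated samples.
* **Donor recovery** — ensemble acceptor-photobleach FRET in cells: the
  percentage increase of donor fluorescence after bleaching the acceptor,
  corrected by the incidental recovery of donor-only controls.
* **Step counting** — single-molecule photobleaching: a change-point fit
  classifies each spot's intensity trace by the number of downward bleach
  steps (1-4, else uncountable), from which the subunit-count
  distribution of an immobilised population follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "SpectrumSet",
    "FretScaledResult",
    "StepTrace",
    "subtract_buffer_rayleigh",
    "acceptor_loss_correction",
    "fret_scaled",
    "donor_recovery",
    "detect_bleach_steps",
    "step_distribution",
]


@dataclass
class EmissionSpectrum:
    """Emission spectrum on a strictly increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    excitation: float

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must align")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def intensity_at(self, wavelength: float) -> float:
        """Intensity at the nearest grid point (no interpolation)."""
        i = int(np.argmin(np.abs(self.wavelength - wavelength)))
        return float(self.intensity[i])

    def band_area(self, lo: float, hi: float) -> float:
        """Trapezoid-rule area over [lo, hi] nm."""
        m = (self.wavelength >= lo) & (self.wavelength <= hi)
        if m.sum() < 2:
            raise ValueError(f"band {lo}-{hi} nm not covered by the grid")
        return float(np.trapezoid(self.intensity[m], self.wavelength[m]))

    def replace(self, intensity: np.ndarray) -> "EmissionSpectrum":
        return EmissionSpectrum(self.wavelength.copy(), np.asarray(intensity, float),
                                self.excitation)


def subtract_buffer_rayleigh(sample: EmissionSpectrum, buffer: EmissionSpectrum,
                             rayleigh_halfwidth: float = 10.0) -> EmissionSpectrum:
    """Buffer subtraction with Rayleigh-peak scaling.

    The buffer spectrum is scaled by the ratio of sample to buffer area
    over the Rayleigh (excitation-scatter) window, excitation ± the
    half-width, constrained to >= 1, then subtracted.
    """
    if sample.excitation != buffer.excitation:
        raise ValueError("sample and buffer use different excitation wavelengths")
    lo = sample.excitation - rayleigh_halfwidth
    hi = sample.excitation + rayleigh_halfwidth
    area_s = sample.band_area(lo, hi)
    area_b = buffer.band_area(lo, hi)
    if area_b <= 0:
        raise ValueError("buffer spectrum has no Rayleigh peak to scale on")
    scale = max(area_s / area_b, 1.0)
    if not np.array_equal(sample.wavelength, buffer.wavelength):
        raise ValueError("spectra must share one wavelength grid")
    return sample.replace(sample.intensity - scale * buffer.intensity)


def acceptor_loss_correction(da_direct: EmissionSpectrum, a_direct: EmissionSpectrum,
                             band: tuple = (660.0, 700.0)) -> float:
    """Protein-loss correction factor from direct acceptor excitation.

    Ratio of the 660-700 nm emission areas of the donor-acceptor sample
    versus the matched acceptor-only sample (both at 650 nm excitation).
    """
    area_a = a_direct.band_area(*band)
    if area_a == 0:
        raise ValueError("acceptor-only direct-excitation area is zero")
    return da_direct.band_area(*band) / area_a


@dataclass
class SpectrumSet:
    """All spectra needed for one FRET_scaled evaluation.

    Donor-excitation spectra for the donor-acceptor mixture and the
    acceptor-only sample plus buffer; direct-excitation (650 nm) spectra
    for the loss correction; and the mock-treated (no detergent
    withdrawal) pair supplying the offset.
    """

    donor_acceptor: EmissionSpectrum
    acceptor_only: EmissionSpectrum
    buffer: EmissionSpectrum
    da_direct: EmissionSpectrum | None = None
    a_direct: EmissionSpectrum | None = None
    buffer_direct: EmissionSpectrum | None = None
    mock_donor_acceptor: EmissionSpectrum | None = None
    mock_acceptor_only: EmissionSpectrum | None = None
    donor_only: EmissionSpectrum | None = None


@dataclass
class FretScaledResult:
    fret_scaled: float
    ratio: float
    offset: float
    loss_correction: float
    offset_missing: bool = False


def fret_scaled(spectra: SpectrumSet, emission_wavelength: float = 670.0) -> FretScaledResult:
    """FRET_scaled: offset-corrected 670 nm emission ratio DA / A-only.

    Both donor-excitation spectra are buffer-subtracted; the DA intensity
    is divided by the acceptor-loss factor when direct-excitation spectra
    are supplied.  The offset is the same ratio computed for the
    mock-treated pair (so a mock pair fed as the sample maps to exactly
    zero); without a mock pair the offset is 0 and the result is flagged.
    """
    da = subtract_buffer_rayleigh(spectra.donor_acceptor, spectra.buffer)
    ac = subtract_buffer_rayleigh(spectra.acceptor_only, spectra.buffer)
    loss = 1.0
    if spectra.da_direct is not None and spectra.a_direct is not None:
        da_dir, a_dir = spectra.da_direct, spectra.a_direct
        if spectra.buffer_direct is not None:
            da_dir = subtract_buffer_rayleigh(da_dir, spectra.buffer_direct)
            a_dir = subtract_buffer_rayleigh(a_dir, spectra.buffer_direct)
        loss = acceptor_loss_correction(da_dir, a_dir)
    i_a = ac.intensity_at(emission_wavelength)
    if i_a == 0:
        raise ValueError("acceptor-only emission at the FRET wavelength is zero")
    ratio = (da.intensity_at(emission_wavelength) / loss) / i_a

    offset_missing = False
    if spectra.mock_donor_acceptor is not None and spectra.mock_acceptor_only is not None:
        mda = subtract_buffer_rayleigh(spectra.mock_donor_acceptor, spectra.buffer)
        mac = subtract_buffer_rayleigh(spectra.mock_acceptor_only, spectra.buffer)
        offset = mda.intensity_at(emission_wavelength) / mac.intensity_at(emission_wavelength)
    else:
        offset = 0.0
        offset_missing = True
    return FretScaledResult(fret_scaled=ratio - offset, ratio=ratio, offset=offset,
                            loss_correction=loss, offset_missing=offset_missing)


def donor_recovery(pre: float, post: float,
                   donor_only_pre: float, donor_only_post: float):
    """Acceptor-photobleach donor recovery, % of pre-bleach donor.

    raw% = 100 (post - pre)/pre; the signed donor-only control change is
    subtracted, so a control that *bleaches* by 10% adds 10 points to the
    corrected recovery.  Returns (corrected%, raw%, control_raw%).
    """
    if pre <= 0 or donor_only_pre <= 0:
        raise ValueError("pre-bleach intensities must be positive")
    raw = 100.0 * (post - pre) / pre
    control = 100.0 * (donor_only_post - donor_only_pre) / donor_only_pre
    return raw - control, raw, control


# ---------------------------------------------------------------------------
# Single-molecule bleaching-step counting
# ---------------------------------------------------------------------------

@dataclass
class StepTrace:
    """A classified single-spot intensity trace.

    ``classification`` is the bleach-step count 1-4, or 0 for
    "uncountable" (no clean downward staircase).
    """

    time: np.ndarray
    intensity: np.ndarray
    change_points: np.ndarray      # sample indices of accepted level changes
    levels: np.ndarray             # fitted level per segment
    step_times: np.ndarray         # indices of downward bleach steps
    step_sizes: np.ndarray         # positive drop magnitudes
    classification: int
    noise_sigma: float

    @property
    def countable(self) -> bool:
        return self.classification > 0


def _segment_cost(csum, csum2, lo, hi):
    """SSE of the mean-fit over samples [lo, hi)."""
    n = hi - lo
    s = csum[hi] - csum[lo]
    s2 = csum2[hi] - csum2[lo]
    return s2 - s * s / n


def _binary_segmentation(y: np.ndarray, penalty: float, min_size: int) -> list:
    """Change-point indices by greedy binary segmentation with a fixed
    per-changepoint penalty on the SSE improvement."""
    n = y.size
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def best_split(lo, hi):
        base = _segment_cost(csum, csum2, lo, hi)
        best_gain, best_k = 0.0, None
        for k in range(lo + min_size, hi - min_size + 1):
            gain = base - _segment_cost(csum, csum2, lo, k) - _segment_cost(csum, csum2, k, hi)
            if gain > best_gain:
                best_gain, best_k = gain, k
        return best_gain, best_k

    cps: list = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_size:
            continue
        gain, k = best_split(lo, hi)
        if k is not None and gain > penalty:
            cps.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(cps)


def detect_bleach_steps(time, intensity, k_sigma: float = 3.0,
                        penalty_factor: float = 3.0, min_segment: int = 5,
                        max_steps: int = 4) -> StepTrace:
    """Count photobleaching steps in a single-spot intensity trace.

    A piecewise-constant fit by binary segmentation (penalty
    ``penalty_factor * sigma² * ln N`` per change point, BIC-style, with
    sigma the robust noise level from the median absolute deviation of
    first differences) yields candidate level changes; downward changes
    exceeding ``k_sigma * sigma`` count as bleach steps.  Traces with
    1-``max_steps`` downward steps, no comparable upward jumps and a
    bleached (near-baseline) tail are classified by their step count;
    anything else is uncountable (classification 0).  An uncountable
    outcome is valid, not an error.
    """
    t = np.asarray(time, float)
    y = np.asarray(intensity, float)
    if y.size < 100:
        raise ValueError("need >= 100 samples per trace")
    sigma = float(np.median(np.abs(np.diff(y))) / (np.sqrt(2.0) * 0.6745))
    sigma = max(sigma, 1e-12)
    penalty = penalty_factor * sigma**2 * np.log(y.size)
    cps = _binary_segmentation(y, penalty, min_segment)
    bounds = [0] + cps + [y.size]
    levels = np.array([y[bounds[i]:bounds[i + 1]].mean() for i in range(len(bounds) - 1)])
    diffs = np.diff(levels)
    down = [(cps[i], -diffs[i]) for i in range(len(diffs))
            if diffs[i] < -k_sigma * sigma]
    up = [d for d in diffs if d > k_sigma * sigma]
    step_times = np.array([d[0] for d in down], int)
    step_sizes = np.array([d[1] for d in down], float)

    n_steps = len(down)
    classification = 0
    if 1 <= n_steps <= max_steps and not up:
        # require the trace to end bleached: final level within noise of
        # the minimum level, and well below the initial level
        if (levels[-1] - levels.min() <= 2.0 * k_sigma * sigma
                and levels[0] - levels[-1] > k_sigma * sigma):
            classification = n_steps
    return StepTrace(time=t, intensity=y, change_points=np.array(cps, int),
                     levels=levels, step_times=step_times, step_sizes=step_sizes,
                     classification=classification, noise_sigma=sigma)


def step_distribution(traces) -> pd.Series:
    """Fractions of classified traces bleaching in 1-4 steps.

    Fractions are over countable traces only; the uncountable fraction
    (of all traces) is reported separately under ``'uncountable'``.
    Raises if every trace is uncountable.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces")
    counts = {k: 0 for k in (1, 2, 3, 4)}
    n_uncountable = 0
    for tr in traces:
        cls = tr.classification if isinstance(tr, StepTrace) else int(tr)
        if cls in counts:
            counts[cls] += 1
        else:
            n_uncountable += 1
    n_classified = sum(counts.values())
    if n_classified == 0:
        raise ValueError("all traces are uncountable")
    out = {k: counts[k] / n_classified for k in counts}
    out["uncountable"] = n_uncountable / len(traces)
    return pd.Series(out)
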