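"""Scramblase-reconstitution statistics from dithionite bleach assays.

The end-point assay: symmetric NBD-labelled vesicles are treated with
dithionite, a membrane-impermeant reductant that bleaches the NBD on the
outer leaflet only.  Protein-free vesicles therefore plateau at
F_min = 0.55 of the starting fluorescence (slightly above half because of
probe asymmetry and incomplete chemistry), while a vesicle carrying at
least one functional scramblase lets inner-leaflet lipids flip out and
bleaches essentially completely.  The ensemble plateau F_min of a
reconstituted sample thus encodes the fraction of vesicles with >= 1
scramblase.

Pipeline:

1. :func:`normalize_trace` scales a raw trace to F_0, the pre-addition
   fluorescence, and isolates the post-addition segment.
2. :func:`fit_double_exponential` fits
   F(t) = F_min + A_f exp(-k_f t) + A_s exp(-k_s t); the fast component
   (t_1/2 ≈ 16.8 s under standard conditions) carries the assay signal,
   the slow one is retained in the fit only.
3. :func:`p_scramblase_curve` converts (PPR, F_min) samples to
   p(>=1) = (0.55 - F_min) / (0.55 - F_min,norm), normalised to a sample
   reconstituted at high protein-to-phospholipid ratio (PPR), and rescales
   PPR* = PPR / x with x = 2 * F_min,norm to discount vesicles refractory
   to reconstitution.
4. :func:`fit_mono_exponential` fits p = 1 - exp(-PPR*/alpha); alpha is a
   characteristic PPR* so, under Poisson occupancy, a protein that
   reconstitutes as a monomer has half the alpha of one that must
   assemble as a dimer — :func:`alpha_ratio` reports the construct/WT
   ratio with propagated uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "F_MIN_PROTEIN_FREE",
    "FluorescenceTrace",
    "NormalizedTrace",
    "DoubleExpFit",
    "MonoExpFit",
    "normalize_trace",
    "fit_double_exponential",
    "p_scramblase_curve",
    "fit_mono_exponential",
    "alpha_ratio",
]

#: Plateau of protein-free liposomes.
F_MIN_PROTEIN_FREE = 0.55

#: PPR (mg protein / mmol phospholipid) above which a sample counts as
#: reconstituted "at high PPR" and may serve as the normalisation sample.
HIGH_PPR_THRESHOLD = 0.48


@dataclass
class FluorescenceTrace:
    """Raw time-based fluorescence with the dithionite-addition time (s)."""

    time: np.ndarray
    intensity: np.ndarray
    dithionite_time: float

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must align")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def read_csv(cls, path, dithionite_time: float) -> "FluorescenceTrace":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), dithionite_time)


@dataclass
class NormalizedTrace:
    """Post-addition segment normalised to F_0; t = 0 at addition."""

    time: np.ndarray
    intensity: np.ndarray
    f0: float


def normalize_trace(trace: FluorescenceTrace, f0_window: float = 10.0) -> NormalizedTrace:
    """Normalise to F_0 and return the post-addition segment.

    F_0 is the mean intensity over the ``f0_window`` seconds immediately
    before dithionite addition (the recording should hold a stable
    baseline for at least ~50 s beforehand).
    """
    t0 = trace.dithionite_time
    if t0 <= trace.time[0]:
        raise ValueError("dithionite addition precedes the recording")
    pre = (trace.time >= t0 - f0_window) & (trace.time < t0)
    if not pre.any():
        raise ValueError("no samples in the pre-addition F_0 window")
    f0 = float(trace.intensity[pre].mean())
    if f0 <= 0:
        raise ValueError("nonpositive baseline fluorescence")
    post = trace.time >= t0
    return NormalizedTrace(time=trace.time[post] - t0,
                           intensity=trace.intensity[post] / f0, f0=f0)


@dataclass
class DoubleExpFit:
    """F(t) = f_min + a_fast exp(-k_fast t) + a_slow exp(-k_slow t)."""

    f_min: float
    a_fast: float
    t_half_fast: float
    a_slow: float
    t_half_slow: float
    redchi: float
    success: bool

    @property
    def k_fast(self) -> float:
        return np.log(2.0) / self.t_half_fast

    @property
    def k_slow(self) -> float:
        return np.log(2.0) / self.t_half_slow


def _double_exp(t, f_min, a_fast, k_fast, a_slow, k_frac):
    return f_min + a_fast * np.exp(-k_fast * t) + a_slow * np.exp(-k_fast * k_frac * t)


def fit_double_exponential(trace: NormalizedTrace, min_points: int = 100) -> DoubleExpFit:
    """Bounded least-squares double-exponential fit of a normalised trace.

    The rate ordering k_fast > k_slow is enforced structurally by fitting
    the slow rate as a fraction (< 1) of the fast one.  Initialisation is
    deterministic: the plateau from the trace tail, the fast rate from a
    log-linear fit to the early decay.
    """
    t, y = trace.time, trace.intensity
    if t.size < min_points:
        raise ValueError(f"need >= {min_points} post-addition points, got {t.size}")
    f_min0 = float(np.mean(y[-max(5, t.size // 20):]))
    amp0 = max(float(y[0] - f_min0), 1e-3)
    # log-linear estimate of the fast rate over the first decade of decay
    resid = y - f_min0
    early = resid > 0.2 * amp0
    if early.sum() >= 3:
        slope, _ = np.polyfit(t[early], np.log(np.clip(resid[early], 1e-12, None)), 1)
        k0 = max(-float(slope), 1e-3)
    else:
        k0 = 0.05
    model = lmfit.Model(_double_exp)
    params = model.make_params(
        f_min=dict(value=min(max(f_min0, 0.0), 1.0), min=0.0, max=1.0),
        a_fast=dict(value=0.9 * amp0, min=0.0, max=2.0),
        k_fast=dict(value=k0, min=1e-5, max=10.0),
        a_slow=dict(value=0.1 * amp0, min=0.0, max=2.0),
        k_frac=dict(value=0.1, min=1e-4, max=0.999),
    )
    result = model.fit(y, params, t=t)
    if not result.success:
        raise RuntimeError(f"double-exponential fit failed: {result.message}")
    p = result.params
    k_fast = p["k_fast"].value
    k_slow = k_fast * p["k_frac"].value
    return DoubleExpFit(
        f_min=p["f_min"].value, a_fast=p["a_fast"].value,
        t_half_fast=np.log(2.0) / k_fast,
        a_slow=p["a_slow"].value, t_half_slow=np.log(2.0) / k_slow,
        redchi=result.redchi, success=result.success,
    )


def p_scramblase_curve(samples: pd.DataFrame, f_min_free: float = F_MIN_PROTEIN_FREE,
                       normalization_index=None,
                       high_ppr_threshold: float = HIGH_PPR_THRESHOLD) -> pd.DataFrame:
    """Convert (PPR, F_min) samples to a (PPR*, p(>=1)) curve.

    ``samples`` needs columns ``ppr`` and ``f_min``.  The normalisation
    sample defaults to the largest-PPR sample and must lie above
    ``high_ppr_threshold``; its F_min must fall below ``f_min_free``
    (otherwise there is no scrambling signal to normalise to).  Returns
    the input with columns ``ppr_star`` and ``p_ge1`` added; the
    normalisation sample has p(>=1) = 1 by construction.
    """
    df = samples.copy().reset_index(drop=True)
    if normalization_index is None:
        normalization_index = int(df["ppr"].idxmax())
    ppr_norm = float(df.loc[normalization_index, "ppr"])
    f_norm = float(df.loc[normalization_index, "f_min"])
    if ppr_norm < high_ppr_threshold:
        raise ValueError(
            f"normalisation sample PPR {ppr_norm:.3g} below the high-PPR "
            f"threshold {high_ppr_threshold}"
        )
    if f_norm >= f_min_free:
        raise ValueError("normalisation sample shows no scrambling signal "
                         f"(F_min {f_norm:.3g} >= {f_min_free})")
    x = 2.0 * f_norm
    df["p_ge1"] = (f_min_free - df["f_min"]) / (f_min_free - f_norm)
    df["ppr_star"] = df["ppr"] / x
    df.attrs["x_factor"] = x
    df.attrs["normalization_index"] = normalization_index
    return df


@dataclass
class MonoExpFit:
    """p = 1 - exp(-PPR*/alpha); alpha in mg protein / mmol phospholipid."""

    alpha: float
    alpha_stderr: float
    redchi: float


def fit_mono_exponential(curve: pd.DataFrame) -> MonoExpFit:
    """Least-squares fit of p(>=1) = 1 - exp(-PPR*/alpha)."""
    x = curve["ppr_star"].to_numpy(float)
    p = curve["p_ge1"].to_numpy(float)
    if x.size < 3:
        raise ValueError("need >= 3 samples spanning the PPR* range")
    if np.all(p < 0.05):
        raise ValueError("degenerate curve: no sample shows appreciable scrambling")
    model = lmfit.Model(lambda ppr_star, alpha: 1.0 - np.exp(-ppr_star / alpha))
    # characteristic scale from the sample closest to p = 1 - 1/e
    i0 = int(np.argmin(np.abs(p - (1 - np.exp(-1)))))
    alpha0 = max(x[i0], 1e-3)
    result = model.fit(p, model.make_params(alpha=dict(value=alpha0, min=1e-6)),
                       ppr_star=x)
    a = result.params["alpha"]
    return MonoExpFit(alpha=float(a.value),
                      alpha_stderr=float(a.stderr) if a.stderr else float("nan"),
                      redchi=result.redchi)


def alpha_ratio(construct_fit: MonoExpFit, wt_fit: MonoExpFit):
    """alpha_construct / alpha_WT with propagated uncertainty.

    Under Poisson vesicle occupancy a monomer-functional protein reaches
    half the characteristic PPR* of one that must dimerise, so a ratio
    near 0.5 indicates monomeric reconstitution and near 1 indicates the
    same oligomeric state as the reference.
    """
    ratio = construct_fit.alpha / wt_fit.alpha
    rel = []
    for fit in (construct_fit, wt_fit):
        if np.isfinite(fit.alpha_stderr):
            rel.append((fit.alpha_stderr / fit.alpha) ** 2)
    err = ratio * float(np.sqrt(sum(rel))) if rel else float("nan")
    return float(ratio), err
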