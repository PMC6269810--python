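"""Stern-Volmer, modified Stern-Volmer and double-log quenching analyses.

For a titration with quencher-free reference intensity F₀ and quenched
intensity F at quencher concentration [Q]:

* Stern-Volmer:           F₀/F = 1 + Ksv·[Q], with Ksv = k_q·τ₀.
* Modified Stern-Volmer:  F₀/(F₀ − F) = 1/fa + 1/(fa·ka·[Q]) — intercept
  1/fa (fa = accessible fraction), slope 1/(fa·ka).
* Double-log (Hill-type): log₁₀((F₀ − F)/F) = log₁₀ K_A + n·log₁₀[Q] —
  slope n (number of binding sites), intercept log₁₀ K_A.

The Stern-Volmer slope is estimated with the intercept pinned to 1, which the
equation forces; the correlation coefficient reported alongside comes from the
unconstrained regression and is purely diagnostic. The apparent bimolecular
quenching rate constant k_q = Ksv/τ₀ (τ₀ = 10⁻⁸ s for a typical protein
fluorophore) is compared against the diffusion-collision ceiling
2×10¹⁰ M⁻¹s⁻¹: a k_q above it cannot arise from collisional quenching alone,
so the mechanism is called static.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import Spectrum, TitrationSeries, peak_intensity
from .units import per_concentration_to_per_molar

DIFFUSION_LIMIT = 2e10  # maximum collisional quenching rate constant, M^-1 s^-1
DEFAULT_TAU0 = 1e-8     # fluorophore lifetime, s


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class QuenchingFit:
    """Stern-Volmer fit. ``ksv`` (and ``ksv2``) are in ``unit``⁻¹; ``kq`` in
    ``unit``⁻¹s⁻¹; ``kq = ksv/tau0`` holds exactly. ``intercept`` and ``r``
    are the free-regression diagnostics (the fitted line itself has intercept
    pinned to 1). Two-regime fields are populated only when a split was
    requested: ``regime_split`` is the highest concentration assigned to the
    first regime."""

    ksv: float
    kq: float
    tau0: float
    intercept: float
    r: float
    unit: str = "M"
    regime_split: float | None = None
    split_index: int | None = None
    ksv2: float | None = None
    kq2: float | None = None
    r2: float | None = None
    sse: float = 0.0

    @property
    def n_regimes(self) -> int:
        return 2 if self.ksv2 is not None else 1


@dataclass
class AccessibilityFit:
    """Modified Stern-Volmer fit: accessible fraction ``fa`` = 1/intercept and
    effective quenching constant ``ka`` = intercept/slope (``unit``⁻¹).
    ``unphysical`` is set when the raw parameters violate their physical
    bounds (intercept ≤ 0, fa > 1 or ka ≤ 0); raw values are never clamped."""

    fa: float
    ka: float
    r: float
    intercept: float
    slope: float
    unit: str = "M"
    unphysical: bool = False
    note: str = ""


@dataclass
class TwoRegimeAccessibility:
    """Pair of modified Stern-Volmer fits split at ``split_concentration``
    (exhaustive contiguous-split search, ≥3 points per side). ``low`` covers
    the low-concentration side."""

    low: AccessibilityFit
    high: AccessibilityFit
    split_index: int
    split_concentration: float
    sse: float
    sse_single: float


@dataclass
class BindingSitesFit:
    """Double-log fit: ``n`` binding sites, association constant
    10**``log_ka`` (in ``unit``⁻ⁿ)."""

    log_ka: float
    n: float
    r: float
    unit: str = "M"

    @property
    def ka(self) -> float:
        return 10.0 ** self.log_ka


# ---------------------------------------------------------------------------
# Readout helpers


def _readout_value(s: Spectrum, readout) -> float:
    if isinstance(readout, str):
        if readout != "peak":
            raise ValueError(f"unknown readout {readout!r}; use 'peak' or a "
                             "wavelength in nm")
        return peak_intensity(s)
    return s.interp_at(float(readout))


def _quenching_points(series: TitrationSeries, readout,
                      require_quenched: bool = False):
    """Extract ([Q] > 0 concentrations, F values, F0) with the shared guards:
    nonpositive intensities are refused; F > F0 points are excluded with a
    warning; with ``require_quenched``, F == F0 points are dropped too."""
    F = np.array([_readout_value(s, readout) for s in series.spectra])
    if np.any(F <= 0):
        raise ValueError("nonpositive fluorescence intensity in series; "
                         "cannot form quenching ratios")
    f0 = F[0]
    q = series.concentrations
    mask = q > 0
    over = mask & (F > f0)
    if np.any(over):
        warnings.warn(f"excluding {int(over.sum())} point(s) with F > F0 "
                      "from the quenching fit", stacklevel=3)
        mask &= ~over
    if require_quenched:
        eq = mask & (F == f0)
        if np.any(eq):
            warnings.warn(f"dropping {int(eq.sum())} unquenched point(s) "
                          "(F = F0) from the fit", stacklevel=3)
            mask &= ~eq
    return q[mask], F[mask], f0


def _pinned_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y = 1 + k·x (intercept pinned to 1); returns
    (k, sse)."""
    denom = float(x @ x)
    k = float(x @ (y - 1.0)) / denom if denom > 0 else 0.0
    resid = y - 1.0 - k * x
    return k, float(resid @ resid)


# ---------------------------------------------------------------------------
# Fits


def stern_volmer_fit(series: TitrationSeries, readout="peak",
                     tau0: float = DEFAULT_TAU0,
                     two_regime: bool = False) -> QuenchingFit:
    """Fit F₀/F = 1 + Ksv·[Q] to a titration series.

    ``readout`` is ``"peak"`` (interpolated peak intensity) or a wavelength in
    nm. With ``two_regime=True`` every contiguous split with at least three
    points per side is scored by total squared residual — the first segment
    with intercept pinned to 1, the second unconstrained (the two regimes
    join away from [Q]=0) — and the minimising split is reported alongside
    both slopes.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    q, F, f0 = _quenching_points(series, readout)
    if q.size < 3:
        raise ValueError("Stern-Volmer fit needs at least 3 nonzero-"
                         "concentration points")
    y = f0 / F
    diag = stats.linregress(q, y)

    if not two_regime:
        ksv, sse = _pinned_slope(q, y)
        return QuenchingFit(ksv=ksv, kq=ksv / tau0, tau0=tau0,
                            intercept=float(diag.intercept),
                            r=float(diag.rvalue), unit=series.unit, sse=sse)

    if q.size < 6:
        raise ValueError("two-regime fit needs at least 6 nonzero points")
    best = None
    for i in range(3, q.size - 2):
        k1, sse1 = _pinned_slope(q[:i], y[:i])
        seg2 = stats.linregress(q[i:], y[i:])
        resid2 = y[i:] - (seg2.intercept + seg2.slope * q[i:])
        sse = sse1 + float(resid2 @ resid2)
        if best is None or sse < best[0]:
            best = (sse, i, k1, seg2)
    sse, i, k1, seg2 = best
    r1 = stats.linregress(q[:i], y[:i]).rvalue if i >= 3 else np.nan
    return QuenchingFit(
        ksv=k1, kq=k1 / tau0, tau0=tau0, intercept=float(diag.intercept),
        r=float(r1), unit=series.unit, regime_split=float(q[i - 1]),
        split_index=int(i), ksv2=float(seg2.slope),
        kq2=float(seg2.slope) / tau0, r2=float(seg2.rvalue), sse=sse,
    )


def quenching_rate_constant(ksv: float, tau0: float = DEFAULT_TAU0) -> float:
    """k_q = Ksv/τ₀ (same reciprocal-concentration unit as Ksv, per second)."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if ksv < 0:
        raise ValueError("ksv must be nonnegative")
    return ksv / tau0


def classify_mechanism(kq: float, diffusion_limit: float = DIFFUSION_LIMIT,
                       unit: str = "M") -> str:
    """Classify the quenching mechanism from the apparent rate constant.

    ``kq`` must be on the reciprocal-molar scale; pass the unit of the fit's
    concentration grid so a mismatch is refused rather than silently
    misclassified. Returns ``"static"`` iff kq strictly exceeds the
    diffusion-collision limit, else ``"dynamic_possible"`` (a boundary value
    is conservatively not called static).
    """
    if unit != "M":
        raise ValueError(
            f"kq is expressed per {unit}; convert with "
            f"per_concentration_to_per_molar(kq, {unit!r}) before classifying"
        )
    return "static" if kq > diffusion_limit else "dynamic_possible"


def classify_fit(fit: QuenchingFit,
                 diffusion_limit: float = DIFFUSION_LIMIT) -> str:
    """Mechanism call for a fit, converting its kq to M⁻¹s⁻¹ first."""
    kq_molar = per_concentration_to_per_molar(fit.kq, fit.unit)
    return classify_mechanism(kq_molar, diffusion_limit)


def modified_stern_volmer_fit(series: TitrationSeries, readout="peak",
                              two_regime: bool = False):
    """Fit F₀/(F₀−F) = 1/fa + 1/(fa·ka·[Q]).

    Returns an :class:`AccessibilityFit`, or a :class:`TwoRegimeAccessibility`
    when ``two_regime=True``: every contiguous split of the concentration-
    ordered points with ≥3 points per side is scored by the total squared
    residual of two independent lines in (1/[Q], F₀/(F₀−F)) space and the
    minimiser is returned.

    An intercept ≤ 0 (or fa > 1, as reported for fully accessible tryptophans
    with cooperative quenching) marks the fit ``unphysical``; raw parameters
    are returned unclamped.
    """
    q, F, f0 = _quenching_points(series, readout, require_quenched=True)
    if q.size < 3:
        raise ValueError("modified Stern-Volmer fit needs at least 3 quenched "
                         "points")
    x = 1.0 / q
    y = f0 / (f0 - F)

    def _one(xs, ys) -> AccessibilityFit:
        reg = stats.linregress(xs, ys)
        intercept, slope = float(reg.intercept), float(reg.slope)
        fa = 1.0 / intercept if intercept != 0 else np.inf
        ka = intercept / slope if slope != 0 else np.inf
        # 1e-9 headroom: round-off can push an exactly-unit intercept to
        # fa marginally above 1 without any physical violation
        unphysical = not (intercept > 0 and 0 < fa <= 1 + 1e-9 and ka > 0)
        note = ""
        if unphysical:
            note = (f"raw intercept {intercept:.4g} gives fa={fa:.4g}, "
                    f"ka={ka:.4g}; outside physical bounds (0<fa≤1, ka>0)")
            warnings.warn("modified Stern-Volmer parameters are unphysical: "
                          + note, stacklevel=3)
        return AccessibilityFit(fa=float(fa), ka=float(ka), r=float(reg.rvalue),
                                intercept=intercept, slope=slope,
                                unit=series.unit, unphysical=unphysical,
                                note=note)

    if not two_regime:
        return _one(x, y)

    if q.size < 6:
        raise ValueError("two-regime fit needs at least 6 quenched points")
    reg_all = stats.linregress(x, y)
    resid_all = y - (reg_all.intercept + reg_all.slope * x)
    sse_single = float(resid_all @ resid_all)
    best = None
    for i in range(3, q.size - 2):
        sse = 0.0
        for xs, ys in ((x[:i], y[:i]), (x[i:], y[i:])):
            reg = stats.linregress(xs, ys)
            resid = ys - (reg.intercept + reg.slope * xs)
            sse += float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, i)
    sse, i = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-segment flags surface below
        low, high = _one(x[:i], y[:i]), _one(x[i:], y[i:])
    for seg in (low, high):
        if seg.unphysical:
            warnings.warn("two-regime segment flagged unphysical: " + seg.note,
                          stacklevel=2)
    return TwoRegimeAccessibility(low=low, high=high, split_index=int(i),
                                  split_concentration=float(q[i - 1]),
                                  sse=sse, sse_single=sse_single)


def double_log_fit(series: TitrationSeries, readout="peak") -> BindingSitesFit:
    """Fit log₁₀((F₀−F)/F) = log₁₀ K_A + n·log₁₀[Q].

    Points with F = F₀ carry no quenching signal (log of zero) and are
    dropped with a warning; at least 3 quenched points are required.
    """
    q, F, f0 = _quenching_points(series, readout, require_quenched=True)
    if q.size < 3:
        raise ValueError("double-log fit needs at least 3 points with "
                         "0 < F < F0")
    reg = stats.linregress(np.log10(q), np.log10((f0 - F) / F))
    return BindingSitesFit(log_ka=float(reg.intercept), n=float(reg.slope),
                           r=float(reg.rvalue), unit=series.unit)
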