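"""QA biomarkers of a time-density curve and post/pre relative ratios.

The biomarkers quantify the shape of a contrast bolus passing through the
aneurysm dome:

* BAT    — bolus arrival time, first sample strictly exceeding 1 % of peak.
* TTP/PH — time of (first) maximum and the maximum itself.
* MTT    — mean transit time, estimated as full width at half maximum
           (half-maximum = PH/2), crossings located by linear interpolation.
* Max-Df — maximum forward-difference derivative between BAT and TTP
           (contrast inflow rate); also called Max-Gr.
* AUC    — trapezoidal integral over the whole acquisition, plus windowed
           integrals over [BAT, BAT + k*MTT] for k in {0.5, 1, 1.5, 2}.
* Cor    — maximum over non-negative lags of the Pearson correlation between
           the standardized arterial input and the dome curve (the dome
           cannot lead the inlet, hence lags >= 0 only).

Treatment effect is expressed as the fieldwise post/pre ratio of these
parameters; denominators below a degeneracy floor yield NaN, never infinity.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .tdc import DegenerateCurveError, InvalidInputError, TimeDensityCurve

#: Canonical field order, matching the extraction CSV column order.
QA_FIELDS = (
    "bat",
    "ttp",
    "ph",
    "mtt",
    "max_df",
    "auc",
    "auc_05",
    "auc_10",
    "auc_15",
    "auc_20",
    "cor",
)


@dataclasses.dataclass(frozen=True)
class QAParameterSet:
    """All QA biomarkers of one curve. ``flags`` records degeneracies
    (e.g. an FWHM window that never closes) without invalidating the row."""

    bat: float
    ttp: float
    ph: float
    mtt: float
    max_df: float
    auc: float
    auc_05: float
    auc_10: float
    auc_15: float
    auc_20: float
    cor: float
    flags: frozenset = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in QA_FIELDS}


@dataclasses.dataclass(frozen=True)
class RelativeQAParameterSet:
    """Post/pre ratios of QA biomarkers (dimensionless); NaN marks a
    degenerate (near-zero) pre-treatment denominator."""

    bat: float
    ttp: float
    ph: float
    mtt: float
    max_df: float
    auc: float
    auc_05: float
    auc_10: float
    auc_15: float
    auc_20: float
    cor: float

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in QA_FIELDS}


# ---------------------------------------------------------------------------
# Individual biomarkers
# ---------------------------------------------------------------------------

def bolus_arrival_time(tdc: TimeDensityCurve, peak_fraction: float = 0.01) -> float:
    """Time of the first sample strictly exceeding ``peak_fraction`` of peak."""
    peak = float(tdc.values.max())
    if peak <= 0:
        raise DegenerateCurveError("curve has no positive peak; BAT undefined")
    above = tdc.values > peak_fraction * peak
    idx = int(np.argmax(above))
    if not above[idx]:  # pragma: no cover - peak itself always exceeds its fraction
        raise DegenerateCurveError("no sample exceeds the arrival threshold")
    return float(tdc.t0 + idx * tdc.dt)


def time_to_peak_and_height(tdc: TimeDensityCurve) -> tuple[float, float]:
    """(TTP, PH): time of the first attainment of the maximum, and the maximum."""
    idx = int(np.argmax(tdc.values))
    return float(tdc.t0 + idx * tdc.dt), float(tdc.values[idx])


def _fwhm_window(tdc: TimeDensityCurve) -> tuple[float, float, bool]:
    """(t_up, t_down, degenerate): half-maximum crossing times around TTP.

    Crossings are located by linear interpolation between the bracketing
    samples.  If the curve never falls below PH/2 after the peak, the window
    closes at the last sample and the degenerate flag is set; symmetrically
    for a curve already above PH/2 at its first sample.
    """
    v = tdc.values
    t = tdc.times
    peak_idx = int(np.argmax(v))
    ph = float(v[peak_idx])
    if ph <= 0:
        raise DegenerateCurveError("curve has no positive peak; FWHM undefined")
    half = ph / 2.0
    degenerate = False

    # first upward crossing of half-max at or before the peak
    i = peak_idx
    while i > 0 and v[i - 1] >= half:
        i -= 1
    if i == 0:
        t_up = float(t[0])
        if v[0] >= half:
            degenerate = True
    else:
        # v[i-1] < half <= v[i]
        frac = (half - v[i - 1]) / (v[i] - v[i - 1])
        t_up = float(t[i - 1] + frac * tdc.dt)

    # first downward crossing after the peak
    j = peak_idx
    n = v.size
    while j < n - 1 and v[j + 1] >= half:
        j += 1
    if j == n - 1:
        t_down = float(t[-1])
        degenerate = True
    else:
        frac = (v[j] - half) / (v[j] - v[j + 1])
        t_down = float(t[j] + frac * tdc.dt)

    return t_up, t_down, degenerate


def mtt_fwhm(tdc: TimeDensityCurve) -> float:
    """Mean transit time estimated as the full width at half maximum."""
    t_up, t_down, _ = _fwhm_window(tdc)
    return t_down - t_up


def max_derivative(tdc: TimeDensityCurve, peak_fraction: float = 0.01) -> float:
    """Maximum forward-difference slope on the [BAT, TTP] window (a.u./s).

    A single-sample window (BAT == TTP) returns 0.
    """
    bat = bolus_arrival_time(tdc, peak_fraction)
    ttp, _ = time_to_peak_and_height(tdc)
    i0 = int(round((bat - tdc.t0) / tdc.dt))
    i1 = int(round((ttp - tdc.t0) / tdc.dt))
    if i1 <= i0:
        return 0.0
    diffs = np.diff(tdc.values[i0 : i1 + 1]) / tdc.dt
    return float(diffs.max())


def auc_total(tdc: TimeDensityCurve) -> float:
    """Trapezoidal integral of the curve over the whole acquisition."""
    return float(np.trapezoid(tdc.values, dx=tdc.dt))


def _value_at(tdc: TimeDensityCurve, t: float) -> float:
    return float(np.interp(t, tdc.times, tdc.values))


def auc_window(tdc: TimeDensityCurve, k: float, mtt: float, bat: float) -> float:
    """Trapezoidal integral of the curve from BAT to ``min(BAT + k*MTT, end)``.

    The partial last trapezoid is handled by linear interpolation.  A zero
    MTT yields 0 (degenerate window).
    """
    if mtt <= 0:
        return 0.0
    t_end_acq = tdc.t0 + tdc.duration
    a = float(bat)
    b = min(a + k * mtt, t_end_acq)
    if b <= a:
        return 0.0
    t = tdc.times
    inside = (t > a) & (t < b)
    ts = np.concatenate([[a], t[inside], [b]])
    vs = np.concatenate([[_value_at(tdc, a)], tdc.values[inside], [_value_at(tdc, b)]])
    return float(np.trapezoid(vs, ts))


def cross_correlation_index(
    reference: TimeDensityCurve,
    qnew: TimeDensityCurve,
    min_overlap: int = 5,
    max_lag: int | None = None,
) -> float:
    """Maximum over non-negative lags of the Pearson correlation between the
    reference (standardized AIF) and the lag-shifted dome curve.

    Lag ``l`` compares ``reference[:N-l]`` with ``qnew[l:]`` (the dome delayed
    relative to the inlet); overlaps shorter than ``min_overlap`` samples are
    not considered.  ``max_lag`` optionally caps the lag scan (``max_lag=0``
    gives the plain Pearson correlation).
    """
    if not np.isclose(reference.dt, qnew.dt, rtol=1e-9, atol=0):
        raise InvalidInputError("reference and qnew must share dt")
    r, q = reference.values, qnew.values
    if np.ptp(r) == 0 or np.ptp(q) == 0:
        raise DegenerateCurveError("constant curve has undefined correlation")
    n = min(r.size, q.size)
    last_lag = n - min_overlap
    if max_lag is not None:
        last_lag = min(last_lag, max_lag)
    best = -2.0
    for lag in range(0, last_lag + 1):
        a = r[: n - lag]
        b = q[lag : lag + a.size]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        c = float(np.corrcoef(a, b)[0, 1])
        if c > best:
            best = c
    if best < -1.5:  # pragma: no cover
        raise DegenerateCurveError("no admissible lag with non-constant overlap")
    return best


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def extract_all(
    tdc: TimeDensityCurve,
    reference: TimeDensityCurve | None = None,
    peak_fraction: float = 0.01,
    anchor_windows_at_bat: bool = True,
) -> QAParameterSet:
    """Extract every QA biomarker from one curve.

    ``reference`` is the standardized AIF used for the correlation index; if
    omitted, Cor is NaN.  AUC windows anchor at this curve's own BAT (set
    ``anchor_windows_at_bat=False`` to anchor at acquisition start instead)
    and use this curve's own MTT.
    """
    flags = set()
    bat = bolus_arrival_time(tdc, peak_fraction)
    ttp, ph = time_to_peak_and_height(tdc)
    t_up, t_down, degen = _fwhm_window(tdc)
    mtt = t_down - t_up
    if degen:
        flags.add("fwhm_window_open")
    max_df = max_derivative(tdc, peak_fraction)
    if ttp <= bat:
        flags.add("degenerate_inflow_window")
    anchor = bat if anchor_windows_at_bat else tdc.t0
    if mtt <= 0:
        flags.add("zero_mtt_window")
    aucs = {k: auc_window(tdc, k, mtt, anchor) for k in (0.5, 1.0, 1.5, 2.0)}
    if reference is not None:
        cor = cross_correlation_index(reference, tdc)
    else:
        cor = math.nan
    return QAParameterSet(
        bat=bat,
        ttp=ttp,
        ph=ph,
        mtt=mtt,
        max_df=max_df,
        auc=auc_total(tdc),
        auc_05=aucs[0.5],
        auc_10=aucs[1.0],
        auc_15=aucs[1.5],
        auc_20=aucs[2.0],
        cor=cor,
        flags=frozenset(flags),
    )


def relative_parameters(
    post: QAParameterSet, pre: QAParameterSet, floor: float = 1e-6
) -> RelativeQAParameterSet:
    """Fieldwise post/pre ratios; pre-values with ``|value| < floor`` give NaN."""
    if floor <= 0:
        raise InvalidInputError("floor must be > 0")
    out = {}
    for f in QA_FIELDS:
        denom = getattr(pre, f)
        num = getattr(post, f)
        if not np.isfinite(denom) or abs(denom) < floor or not np.isfinite(num):
            out[f] = math.nan
        else:
            out[f] = num / denom
    return RelativeQAParameterSet(**out)
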