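"""QRS delineation: Pan-Tompkins R detection and the mirrored Q/S search.

R peaks are found with the classic Pan-Tompkins cascade (band-pass ->
derivative -> squaring -> moving-window integration -> adaptive dual
thresholds with search-back).  S peaks are then located as the first
derivative-sign-inversion local minimum after each R within a short search
window.  Q peaks reuse the S detector on the time-reversed signal: with
``xf[n] = x[N-1-n]`` the Q trough of a beat becomes an S-type trough after the
mirrored R position, so ``q = N-1-s'`` where ``s'`` is the S index found on
the flipped signal.  This mirror identity is exact by construction and is
asserted bit-for-bit in the tests.

Filtering is zero-phase (``filtfilt``) and the integration window is centred,
so detected fiducials need no group-delay correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sps

from .synthetic import BeatAnnotations, ECGRecord

__all__ = [
    "DetectorConfig",
    "FAILED",
    "time_flip",
    "detect_r_peaks",
    "locate_s_peaks",
    "locate_q_peaks",
    "delineate",
    "delineate_record",
]

#: sentinel index for a beat whose Q or S search found no derivative inversion
FAILED = -1


@dataclass(frozen=True)
class DetectorConfig:
    """Detector parameters (the classic Pan-Tompkins values by default).

    All windows are in milliseconds.  ``qs_search_window`` bounds how far from
    R the Q/S troughs may lie; the 120 ms default is the upper range of a
    normal QRS duration with margin.
    """

    bandpass_low: float = 5.0
    bandpass_high: float = 15.0
    integration_window: float = 150.0
    refractory: float = 200.0
    qs_search_window: float = 120.0

    def validate(self, sample_rate: float) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.bandpass_high >= sample_rate / 2:
            raise ValueError("bandpass_high must be below Nyquist")
        if self.integration_window <= 0 or self.qs_search_window <= 0:
            raise ValueError("windows must be positive")


def time_flip(x: np.ndarray) -> np.ndarray:
    """Reverse a signal in time: out[n] = x[N-1-n]."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("cannot time-flip an empty signal")
    return x[::-1].copy()


def _preprocess(x: np.ndarray, fs: float, config: DetectorConfig) -> np.ndarray:
    """Band-pass -> derivative -> square -> centred moving-window integration."""
    sos = _sps.butter(
        3, [config.bandpass_low, config.bandpass_high], btype="bandpass", fs=fs, output="sos"
    )
    bp = _sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    w = max(1, int(round(config.integration_window / 1000.0 * fs)))
    return _sps.convolve(sq, np.ones(w) / w, mode="same")


def detect_r_peaks(
    x: np.ndarray, sample_rate: float, config: DetectorConfig | None = None
) -> np.ndarray:
    """Pan-Tompkins R-peak detection on a single lead.

    Returns strictly increasing sample indices separated by at least the
    refractory period; each index is refined to the extremum of the raw
    signal (polarity taken from the band-passed signal) within +/-50 ms of
    the integrator peak.  A constant signal yields an empty list; a signal
    shorter than 2 s raises.
    """
    x = np.asarray(x, dtype=float)
    config = config or DetectorConfig()
    config.validate(sample_rate)
    if x.size < 2 * sample_rate:
        raise ValueError("signal shorter than 2 s; too short for detector warm-up")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if np.ptp(x) == 0.0:
        return np.array([], dtype=np.int64)

    fs = sample_rate
    integ = _preprocess(x, fs, config)
    refr = int(round(config.refractory / 1000.0 * fs))
    cand, _ = _sps.find_peaks(integ, distance=max(1, refr))
    if cand.size == 0:
        return np.array([], dtype=np.int64)

    # adaptive dual thresholds over the integrated signal (signal/noise peak
    # running estimates), with search-back at half threshold when an expected
    # beat is missed
    spki = float(np.percentile(integ[cand], 75))
    npki = float(np.percentile(integ[cand], 25)) * 0.1
    accepted: list[int] = []
    rr_hist: list[float] = []
    missed_buffer: list[int] = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[c] > thr:
            if accepted and rr_hist:
                rr_avg = float(np.mean(rr_hist[-8:]))
                gap = c - accepted[-1]
                if gap > 1.66 * rr_avg and missed_buffer:
                    # search-back: best missed candidate above half threshold
                    back = [b for b in missed_buffer if integ[b] > 0.5 * thr]
                    if back:
                        b = max(back, key=lambda i: integ[i])
                        if b - accepted[-1] >= refr and c - b >= refr:
                            accepted.append(b)
                            rr_hist.append(float(b - accepted[-2]))
            if not accepted or c - accepted[-1] >= refr:
                if accepted:
                    rr_hist.append(float(c - accepted[-1]))
                accepted.append(c)
                spki = 0.125 * integ[c] + 0.875 * spki
            missed_buffer = []
        else:
            missed_buffer.append(c)
            npki = 0.125 * integ[c] + 0.875 * npki

    if not accepted:
        return np.array([], dtype=np.int64)

    # refine to raw-signal extremum within +/-50 ms, polarity per candidate
    # taken from the band-passed signal
    sos = _sps.butter(
        3, [config.bandpass_low, config.bandpass_high], btype="bandpass", fs=fs, output="sos"
    )
    bp = _sps.sosfiltfilt(sos, x)
    half = int(round(0.050 * fs))
    base = np.median(x)
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        seg_bp = bp[lo:hi]
        pol = 1.0 if seg_bp.max() >= -seg_bp.min() else -1.0
        refined.append(lo + int(np.argmax(pol * (x[lo:hi] - base))))
    refined = np.unique(refined).astype(np.int64)
    # enforce the refractory after refinement (keep the larger extremum)
    keep: list[int] = []
    for r in refined:
        if keep and r - keep[-1] < refr:
            if abs(x[r] - base) > abs(x[keep[-1]] - base):
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    out = np.array(keep, dtype=np.int64)
    # amplitude sanity filter: filter edge transients and residual P/T
    # candidates sit well below the QRS amplitude scale
    if out.size >= 3:
        amp = np.abs(x[out] - base)
        out = out[amp >= 0.35 * np.median(amp)]
    return out


def locate_s_peaks(
    x: np.ndarray,
    r_peaks: np.ndarray,
    sample_rate: float,
    config: DetectorConfig | None = None,
) -> np.ndarray:
    """First derivative-inversion local minimum after each R peak.

    Returns one index per R peak; beats with no sign inversion inside the
    search window (or truncated by the record end) carry the ``FAILED``
    sentinel rather than raising.
    """
    x = np.asarray(x, dtype=float)
    config = config or DetectorConfig()
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    win = max(2, int(round(config.qs_search_window / 1000.0 * sample_rate)))
    d = np.diff(x)
    out = np.full(len(r_peaks), FAILED, dtype=np.int64)
    for i, r in enumerate(r_peaks):
        hi = min(x.size - 1, r + win)
        if r + 1 >= hi:
            continue
        # local minimum at j: d[j-1] < 0 <= d[j]  (descent then ascent)
        seg_prev = d[r : hi - 1]
        seg_next = d[r + 1 : hi]
        inv = np.nonzero((seg_prev < 0) & (seg_next >= 0))[0]
        if inv.size:
            out[i] = r + 1 + inv[0]
    return out


def locate_q_peaks(
    x: np.ndarray,
    r_peaks: np.ndarray,
    sample_rate: float,
    config: DetectorConfig | None = None,
) -> np.ndarray:
    """Q peaks via the time-flip trick: run the S search on the reversed signal.

    For each R at index r the mirrored position is ``N-1-r``; the S-type
    minimum ``s'`` found after it on the flipped signal maps back to
    ``q = N-1-s'``, which lies before R on the original time axis.
    """
    x = np.asarray(x, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    n = x.size
    flipped = time_flip(x)
    mirrored = (n - 1 - r_peaks)[::-1]  # ascending on the flipped axis
    s_flip = locate_s_peaks(flipped, mirrored, sample_rate, config)[::-1]
    q = np.where(s_flip == FAILED, FAILED, n - 1 - s_flip)
    return q.astype(np.int64)


def delineate(
    x: np.ndarray, sample_rate: float, config: DetectorConfig | None = None
) -> tuple[BeatAnnotations, int]:
    """Full single-lead delineation.

    Returns ``(annotations, n_failed)`` where annotations contain only beats
    with a complete, correctly ordered q < r < s triplet; ``n_failed`` counts
    beats dropped because either trough search failed.
    """
    r = detect_r_peaks(x, sample_rate, config)
    s = locate_s_peaks(x, r, sample_rate, config)
    q = locate_q_peaks(x, r, sample_rate, config)
    ok = (q != FAILED) & (s != FAILED) & (q < r) & (r < s)
    ann = BeatAnnotations(q_idx=q[ok], r_idx=r[ok], s_idx=s[ok])
    return ann, int(np.sum(~ok))


def choose_detection_lead(record: ECGRecord, config: DetectorConfig | None = None) -> str:
    """Lead with the largest band-passed QRS energy (detection default)."""
    config = config or DetectorConfig()
    config.validate(record.sample_rate)
    sos = _sps.butter(
        3,
        [config.bandpass_low, config.bandpass_high],
        btype="bandpass",
        fs=record.sample_rate,
        output="sos",
    )
    energy = [float(np.mean(_sps.sosfiltfilt(sos, row) ** 2)) for row in record.samples]
    return record.lead_names[int(np.argmax(energy))]


def delineate_record(
    record: ECGRecord,
    lead: str | None = None,
    config: DetectorConfig | None = None,
    reuse_across_leads: bool = True,
) -> dict[str, BeatAnnotations]:
    """Delineate a record, by default detecting on the strongest lead and
    reusing the fiducials across leads (QRS timing is lead-independent in the
    dipole model).  With ``reuse_across_leads=False`` each lead is delineated
    independently on its own waveform.
    """
    if lead is None:
        lead = choose_detection_lead(record, config)
    if reuse_across_leads:
        ann, _ = delineate(record.lead(lead), record.sample_rate, config)
        return {name: ann for name in record.lead_names}
    out = {}
    for name in record.lead_names:
        out[name], _ = delineate(record.lead(name), record.sample_rate, config)
    return out
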