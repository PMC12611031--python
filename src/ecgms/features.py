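"""The 30-feature cardiac interval/axis set from leads I (DI) and aVF.

Per lead: mean and variance of RR, RS, QS and QR intervals (ms, ms^2), of the
R/Q and R/S amplitude ratios (dimensionless) and of the R amplitude (mV).
Jointly from both leads: mean and variance of the frontal-plane cardiac axis
(degrees), where the per-beat axis is atan2(net_aVF, net_I) over the signed
net QRS amplitude of each lead (sum of baseline-corrected amplitudes at the
Q, R and S fiducials).  Lead I points at 0 deg and aVF at +90 deg, so a
purely inferior depolarisation maps to +90 deg, matching the clinical
convention.

Amplitudes are read from the raw (unfiltered) signal at the annotated
indices, with the per-lead record median as baseline.  Variances use the
sample (n-1) convention; a run of identical values yields exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BeatAnnotations, ECGRecord

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "beat_intervals",
    "cardiac_axis",
    "extract_features",
    "cohort_features",
]

#: feature names in canonical order (1-30): lead-I block with the joint axis
#: rows (5 and 13), then the aVF block
FEATURE_NAMES = [
    "f01_rr_mean_di",
    "f02_rs_mean_di",
    "f03_qs_mean_di",
    "f04_qr_mean_di",
    "f05_axis_mean",
    "f06_rq_ratio_mean_di",
    "f07_rs_ratio_mean_di",
    "f08_r_amp_mean_di",
    "f09_rr_var_di",
    "f10_rs_var_di",
    "f11_qs_var_di",
    "f12_qr_var_di",
    "f13_axis_var",
    "f14_rq_ratio_var_di",
    "f15_rs_ratio_var_di",
    "f16_r_amp_var_di",
    "f17_rr_mean_avf",
    "f18_rs_mean_avf",
    "f19_qs_mean_avf",
    "f20_qr_mean_avf",
    "f21_rq_ratio_mean_avf",
    "f22_rs_ratio_mean_avf",
    "f23_r_amp_mean_avf",
    "f24_rr_var_avf",
    "f25_rs_var_avf",
    "f26_qs_var_avf",
    "f27_qr_var_avf",
    "f28_rq_ratio_var_avf",
    "f29_rs_ratio_var_avf",
    "f30_r_amp_var_avf",
]

#: ratio guard: beats whose |Q| or |S| amplitude is below this fraction of
#: that beat's |R| are dropped from the ratio statistics only
RATIO_GUARD = 0.01


@dataclass
class FeatureVector:
    """The 30 named features, ordered as :data:`FEATURE_NAMES`."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (30,):
            raise ValueError("a FeatureVector has exactly 30 entries")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=FEATURE_NAMES)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def __len__(self) -> int:
        return 30


def _mean(x: np.ndarray) -> float:
    return float(np.mean(x))


def _var(x: np.ndarray) -> float:
    """Sample variance (ddof=1); exactly 0.0 for a constant run."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.ptp(x) == 0.0:
        return 0.0
    return float(np.var(x, ddof=1))


def beat_intervals(ann: BeatAnnotations, sample_rate: float) -> pd.DataFrame:
    """Per-beat RR, RS, QS and QR intervals in milliseconds.

    RR[i] spans beat i to beat i+1, so the RR column has one fewer entry
    than there are beats (NaN in the last row).  QS = QR + RS holds exactly.
    """
    if len(ann) < 2:
        raise ValueError("need at least 2 beats for interval features (RR requires a pair)")
    ms = 1000.0 / sample_rate
    rr = np.diff(ann.r_idx) * ms
    out = pd.DataFrame(
        {
            "RR": np.append(rr, np.nan),
            "RS": (ann.s_idx - ann.r_idx) * ms,
            "QS": (ann.s_idx - ann.q_idx) * ms,
            "QR": (ann.r_idx - ann.q_idx) * ms,
        }
    )
    return out


def cardiac_axis(net_amp_i: float, net_amp_avf: float) -> float:
    """Frontal-plane axis (degrees in (-180, 180]) from two orthogonal leads."""
    if net_amp_i == 0.0 and net_amp_avf == 0.0:
        raise ValueError("cardiac axis undefined: both net amplitudes are zero")
    deg = float(np.degrees(np.arctan2(net_amp_avf, net_amp_i)))
    return 180.0 if deg <= -180.0 else deg


def _amplitudes(x: np.ndarray, ann: BeatAnnotations) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    base = float(np.median(x))
    return x[ann.q_idx] - base, x[ann.r_idx] - base, x[ann.s_idx] - base


def _ratio_stats(num: np.ndarray, den: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    ok = np.abs(den) >= RATIO_GUARD * np.abs(ref)
    if not np.any(ok):
        return np.nan, np.nan
    r = num[ok] / den[ok]
    return _mean(r), _var(r)


def _align_beats(ann_a: BeatAnnotations, ann_b: BeatAnnotations, tol: int) -> tuple[np.ndarray, np.ndarray]:
    """Pair beats of two annotation sets by nearest R within ``tol`` samples."""
    ia, ib = [], []
    j = 0
    for i, r in enumerate(ann_a.r_idx):
        while j < len(ann_b) - 1 and abs(ann_b.r_idx[j + 1] - r) <= abs(ann_b.r_idx[j] - r):
            j += 1
        if j < len(ann_b) and abs(int(ann_b.r_idx[j]) - int(r)) <= tol:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def extract_features(
    record: ECGRecord,
    ann_i: BeatAnnotations,
    ann_avf: BeatAnnotations,
    signed_ratios: bool = True,
) -> FeatureVector:
    """Compute the full 30-entry feature vector for one record.

    ``ann_i`` and ``ann_avf`` may be the same object (fiducials reused across
    leads) or independent per-lead delineations, in which case beats are
    paired by nearest R within 50 ms for the joint axis features.  With
    ``signed_ratios=False`` the R/Q and R/S ratios use absolute amplitudes.
    """
    if len(ann_i) < 2 or len(ann_avf) < 2:
        raise ValueError("need at least 2 valid beats per lead")
    x_i = record.lead("I")
    x_avf = record.lead("aVF")
    fs = record.sample_rate

    vals = {}
    for suffix, x, ann in (("di", x_i, ann_i), ("avf", x_avf, ann_avf)):
        ivl = beat_intervals(ann, fs)
        rr = ivl["RR"].dropna().to_numpy()
        aq, ar, as_ = _amplitudes(x, ann)
        if not signed_ratios:
            aq, ar, as_ = np.abs(aq), np.abs(ar), np.abs(as_)
        rq_m, rq_v = _ratio_stats(ar, aq, ar)
        rs_m, rs_v = _ratio_stats(ar, as_, ar)
        vals[f"rr_mean_{suffix}"], vals[f"rr_var_{suffix}"] = _mean(rr), _var(rr)
        vals[f"rs_mean_{suffix}"], vals[f"rs_var_{suffix}"] = (
            _mean(ivl["RS"]),
            _var(ivl["RS"].to_numpy()),
        )
        vals[f"qs_mean_{suffix}"], vals[f"qs_var_{suffix}"] = (
            _mean(ivl["QS"]),
            _var(ivl["QS"].to_numpy()),
        )
        vals[f"qr_mean_{suffix}"], vals[f"qr_var_{suffix}"] = (
            _mean(ivl["QR"]),
            _var(ivl["QR"].to_numpy()),
        )
        vals[f"rq_ratio_mean_{suffix}"], vals[f"rq_ratio_var_{suffix}"] = rq_m, rq_v
        vals[f"rs_ratio_mean_{suffix}"], vals[f"rs_ratio_var_{suffix}"] = rs_m, rs_v
        vals[f"r_amp_mean_{suffix}"], vals[f"r_amp_var_{suffix}"] = _mean(ar), _var(ar)

    ia, ib = _align_beats(ann_i, ann_avf, tol=int(round(0.050 * fs)))
    if ia.size == 0:
        raise ValueError("no beats could be paired across leads for the axis features")
    aq_i, ar_i, as_i = _amplitudes(x_i, ann_i)
    aq_f, ar_f, as_f = _amplitudes(x_avf, ann_avf)
    net_i = aq_i[ia] + ar_i[ia] + as_i[ia]
    net_f = aq_f[ib] + ar_f[ib] + as_f[ib]
    axes = np.array([cardiac_axis(a, b) for a, b in zip(net_i, net_f)])
    vals["axis_mean"], vals["axis_var"] = _mean(axes), _var(axes)

    ordered = [vals[name.split("_", 1)[1]] for name in FEATURE_NAMES]
    return FeatureVector(np.array(ordered))


def cohort_features(
    cohort: list[tuple[ECGRecord, BeatAnnotations]],
    from_annotations: bool = True,
    detector_config=None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per (subject, stage).

    With ``from_annotations=True`` the supplied ground-truth annotations are
    used directly; otherwise each record is delineated with the detector
    (detection on the strongest lead, fiducials shared across leads).
    """
    from .peaks import delineate_record

    rows = []
    for rec, ann in cohort:
        if not from_annotations:
            anns = delineate_record(rec, config=detector_config)
            ann_i, ann_avf = anns["I"], anns["aVF"]
        else:
            ann_i = ann_avf = ann
        fv = extract_features(rec, ann_i, ann_avf)
        row = {"subject_id": rec.subject_id, "group": rec.group, "stage": rec.stage}
        row.update(fv.as_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
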