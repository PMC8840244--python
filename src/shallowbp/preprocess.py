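"""Signal conditioning: baseline correction, normalization, PPG derivatives,
per-segment BP labels, and bad-signal rejection.

The front end turns raw synchronized PPG/ECG/ABP snippets into the fixed
1024-sample, unit-scaled tensors the autoencoder consumes:

1. *Baseline-drift correction.*  A moving-minimum of the signal with window
   equal to the median inter-peak distance approximates the wandering
   baseline; a low-order polynomial is fitted to that estimate and
   subtracted.  The output is shifted so its minimum is 0 and rescaled so
   its range equals the input range.  If peak detection finds fewer than
   two peaks the polynomial is fitted to the signal directly (fallback
   branch).
2. *Normalization.*  Predictor channels (PPG, ECG and the PPG derivatives)
   are z-scored then affinely mapped onto [0, 1] per segment.  The pressure
   waveform is instead divided by a single global systolic maximum so that
   segments keep their relative amplitude — the amplitude *is* the label
   information.
3. *PPG derivatives.*  Velocity (VPG) and acceleration (APG) channels are
   first differences passed through a linear-phase FIR band-pass; the
   constant group delay is compensated exactly by shifting, and all three
   signals are trimmed to a common 1024 samples.
4. *Quality screening.*  Segments are rejected on label ranges (systolic,
   diastolic, pulse pressure), blank channels, non-uniform peak heights or
   spacings, and implausible peak counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks, lfilter, peak_prominences, remez

from .segment_io import SegmentRecord, SegmentStore, WaveformSegment


class DegenerateSegmentError(ValueError):
    """Raised when an operation receives a constant (zero-range) segment."""


class LabelExtractionError(ValueError):
    """Raised when per-segment BP labels cannot be extracted."""


class PipelineFailure(RuntimeError):
    """Raised when preprocessing leaves no surviving segments."""

    def __init__(self, msg: str, report: pd.DataFrame | None = None):
        super().__init__(msg)
        self.report = report


# ---------------------------------------------------------------------------
# peaks


@dataclass(frozen=True)
class PeakSet:
    """Detected local maxima with prominences and successive spacings."""

    indices: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.indices)


def detect_peaks(x: Sequence[float], min_prominence: float | None = None) -> PeakSet:
    """Strict local maxima of ``x``; a plateau contributes its first sample.

    Prominence is the height above the higher of the two flanking minima
    between neighbouring higher points (the standard topographic
    definition).  ``min_prominence`` drops peaks below that prominence.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        return PeakSet(np.empty(0, dtype=int), np.empty(0))
    idx, props = find_peaks(x, plateau_size=1)
    idx = props["left_edges"]  # plateau tie-break: first sample
    if idx.size == 0:
        return PeakSet(idx, np.empty(0))
    # prominences are invariant to which plateau sample represents the peak
    prom = peak_prominences(x, idx)[0]
    if min_prominence is not None:
        keep = prom >= min_prominence
        idx, prom = idx[keep], prom[keep]
    return PeakSet(idx, prom)


def beat_peaks(
    x: np.ndarray, prominence_frac: float = 0.1, height_frac: float = 0.5
) -> PeakSet:
    """Beat-delineation peaks: prominence at least ``prominence_frac`` of the
    signal range *and* amplitude above the signal midline
    (min + ``height_frac`` * range).

    The prominence floor suppresses dicrotic-notch double counting; the
    height floor drops noise excursions on the flat diastolic runoff, where
    systolic peaks by definition cannot lie.
    """
    x = np.asarray(x, dtype=np.float64)
    rng = float(np.ptp(x))
    if rng == 0:
        return PeakSet(np.empty(0, dtype=int), np.empty(0))
    ps = detect_peaks(x, min_prominence=prominence_frac * rng)
    floor = float(x.min()) + height_frac * rng
    keep = x[ps.indices] >= floor
    return PeakSet(ps.indices[keep], ps.prominences[keep])


# ---------------------------------------------------------------------------
# baseline correction


@dataclass(frozen=True)
class BaselineFit:
    """Diagnostics of one baseline-correction run."""

    baseline: np.ndarray
    poly_order: int
    branch: Literal["peak-driven", "fallback", "degenerate"]


def correct_baseline(
    x: Sequence[float],
    fallback_order: int = 6,
    order_cap: int = 8,
) -> tuple[np.ndarray, BaselineFit]:
    """Remove slow baseline wander, preserving the signal's amplitude range.

    Peak-driven branch: median inter-peak distance ``d`` sets both the
    moving-minimum window and the polynomial order ``min(round(d),
    order_cap)`` fitted to that moving minimum (the cap replaces the
    numerically unusable order ~d of the raw recipe; the fit uses a
    centred/scaled abscissa).  Fallback (< 2 peaks): fit ``x`` directly with
    ``fallback_order``.  The fitted curve is subtracted, the result shifted
    to min 0 and rescaled so output range equals input range exactly.

    A constant input is returned unchanged with the ``"degenerate"`` branch
    flag instead of dividing by zero.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 8:
        raise ValueError(f"segment too short for baseline correction: {x.size}")
    x_amp = float(np.ptp(x))
    if x_amp == 0:
        return x.copy(), BaselineFit(np.zeros_like(x), 0, "degenerate")

    t = np.arange(x.size, dtype=np.float64)
    peaks = detect_peaks(x)
    if len(peaks) >= 2:
        d = float(np.median(peaks.intervals))
        window = max(int(round(d)), 1)
        baseline = minimum_filter1d(x, size=window, mode="nearest")
        order = min(int(round(d)), order_cap)
        series = np.polynomial.Polynomial.fit(t, baseline, order)
        branch = "peak-driven"
    else:
        baseline = x
        order = fallback_order
        series = np.polynomial.Polynomial.fit(t, x, order)
        branch = "fallback"
    fit = series(t)
    y = x - fit
    y -= y.min()
    y_amp = float(np.ptp(y))
    if y_amp == 0:
        return x.copy(), BaselineFit(fit, order, "degenerate")
    y *= x_amp / y_amp
    return y, BaselineFit(fit, order, branch)


# ---------------------------------------------------------------------------
# normalization


def normalize_unit_range(x: Sequence[float]) -> np.ndarray:
    """Z-score then affinely map onto [0, 1] (min 0, max 1).

    The composition is equivalent to ``(x - min) / (max - min)`` because
    range normalization is invariant to the affine z-score step; the
    two-stage form is kept because it is the conditioning recipe as
    specified, and the equivalence is asserted in the test suite.
    """
    x = np.asarray(x, dtype=np.float64)
    sigma = x.std()
    if sigma == 0:
        raise DegenerateSegmentError("constant segment cannot be unit-range normalized")
    z = (x - x.mean()) / sigma
    z -= z.min()
    return z / z.max()


@dataclass(frozen=True)
class NormalizationContext:
    """Frozen global pressure divisor plus per-segment z-score bookkeeping.

    ``global_sbp_max`` is the maximum pressure amplitude (mmHg) observed on
    the partition the context was fitted on; dividing every pressure
    waveform by it preserves relative amplitudes across segments.
    """

    global_sbp_max: float
    per_segment_mu: dict = field(default_factory=dict)
    per_segment_sigma: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.global_sbp_max > 0:
            raise ValueError("global_sbp_max must be positive")


def normalize_abp(abp: Sequence[float], ctx: NormalizationContext) -> np.ndarray:
    """Divide a mmHg pressure waveform by the frozen global systolic maximum."""
    return np.asarray(abp, dtype=np.float64) / ctx.global_sbp_max


# ---------------------------------------------------------------------------
# PPG derivatives


@dataclass(frozen=True)
class BandpassSpec:
    """Linear-phase FIR band-pass design for the derivative chain.

    Band edges are in Hz at sampling rate ``fs``; ``order`` is the number of
    taps (odd => integer group delay (order-1)/2 samples, compensated
    exactly downstream).
    """

    stop_lo: float = 0.25
    pass_lo: float = 0.5
    pass_hi: float = 10.0
    stop_hi: float = 15.0
    order: int = 51
    fs: float = 125.0
    design: Literal["FIR-equiripple", "FIR-window"] = "FIR-equiripple"

    def __post_init__(self) -> None:
        if not (0 < self.stop_lo < self.pass_lo < self.pass_hi < self.stop_hi < self.fs / 2):
            raise ValueError("band edges must satisfy 0 < stop_lo < pass_lo < pass_hi < stop_hi < fs/2")
        if self.order % 2 == 0:
            raise ValueError("odd tap count required for an integer group delay")

    @property
    def group_delay(self) -> int:
        """Exact constant group delay of the linear-phase design, in samples."""
        return (self.order - 1) // 2

    def taps(self) -> np.ndarray:
        bands = [0, self.stop_lo, self.pass_lo, self.pass_hi, self.stop_hi, self.fs / 2]
        if self.design == "FIR-equiripple":
            return remez(self.order, bands, [0, 1, 0], fs=self.fs)
        from scipy.signal import firwin

        return firwin(
            self.order, [self.pass_lo, self.pass_hi], pass_zero=False, fs=self.fs
        )


def required_margin(spec: BandpassSpec) -> int:
    """Extra samples (beyond the output length) the derivative chain consumes:
    two causal filter delays plus one sample per finite difference."""
    return 2 * spec.group_delay + 2


def compute_derivatives(
    ppg: Sequence[float],
    spec: BandpassSpec | None = None,
    out_length: int = 1024,
    pad_mode: Literal["margin", "reflect"] = "margin",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive time-aligned, unit-range PPG / VPG / APG channels.

    VPG is the band-passed first difference of the normalized PPG; APG is
    the band-passed first difference of VPG.  Each causal FIR pass delays
    its output by the constant group delay ``D``; alignment trims the PPG
    head by 0, shifts VPG by ``D`` and APG by ``2 D``, then cuts all three
    to ``out_length`` samples.

    ``pad_mode="margin"`` requires ``len(ppg) >= out_length + 2 D + 2``;
    ``"reflect"`` accepts exactly ``out_length`` samples and reflects the
    tail to create the margin.
    """
    spec = spec or BandpassSpec()
    ppg = np.asarray(ppg, dtype=np.float64)
    margin = required_margin(spec)
    if pad_mode == "reflect" and ppg.size < out_length + margin:
        pad = out_length + margin - ppg.size
        ppg = np.concatenate([ppg, ppg[-2 : -2 - pad : -1]])
    if ppg.size < out_length + margin:
        raise ValueError(
            f"need >= {out_length + margin} samples (output {out_length} + margin {margin}), "
            f"got {ppg.size}"
        )
    if np.ptp(ppg) == 0:
        raise DegenerateSegmentError("constant PPG has no derivative content")
    h = spec.taps()
    delay = spec.group_delay
    dt = 1.0  # sample-index abscissa: unit spacing

    ppg_n = normalize_unit_range(ppg)
    v_raw = lfilter(h, 1.0, np.diff(ppg_n) / dt)
    if np.ptp(v_raw) == 0:
        raise DegenerateSegmentError("derivative collapsed to a constant")
    vpg = normalize_unit_range(v_raw)
    a_raw = lfilter(h, 1.0, np.diff(vpg) / dt)
    if np.ptp(a_raw) == 0:
        raise DegenerateSegmentError("second derivative collapsed to a constant")
    apg = normalize_unit_range(a_raw)

    ppg_out = ppg_n[:out_length]
    vpg_out = vpg[delay : delay + out_length]
    apg_out = apg[2 * delay : 2 * delay + out_length]
    return ppg_out, vpg_out, apg_out


# ---------------------------------------------------------------------------
# labels


@dataclass(frozen=True)
class BPLabels:
    """Per-segment systolic / diastolic / mean arterial pressure in mmHg."""

    sbp: float
    dbp: float
    map: float

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp:
            raise LabelExtractionError(f"SBP {self.sbp} must exceed DBP {self.dbp}")
        if not (self.dbp <= self.map <= self.sbp):
            raise LabelExtractionError("MAP must lie between DBP and SBP")

    @property
    def pulse_pressure(self) -> float:
        return self.sbp - self.dbp


def extract_bp_labels(
    abp: Sequence[float],
    method: Literal["peak-mean", "extrema"] = "peak-mean",
    prominence_frac: float = 0.1,
) -> BPLabels:
    """Reduce a mmHg pressure waveform to scalar SBP/DBP/MAP labels.

    ``peak-mean``: SBP is the mean systolic-peak amplitude and DBP the mean
    inter-beat trough amplitude (dicrotic bumps suppressed by a relative
    prominence floor); falls back to extrema when no beat peak is found.
    ``extrema``: SBP = max, DBP = min.  MAP = DBP + (SBP - DBP)/3.
    """
    abp = np.asarray(abp, dtype=np.float64)
    if np.ptp(abp) == 0:
        raise LabelExtractionError("flat pressure waveform carries no beats")
    if method == "peak-mean":
        peaks = beat_peaks(abp, prominence_frac)
        troughs = beat_peaks(-abp, prominence_frac)
        if len(peaks) >= 1 and len(troughs) >= 1:
            # +/-1-sample mean tempers the upward argmax-selection bias of
            # reading the raw noisy sample at each detected peak
            pvals = [
                float(abp[max(0, i - 1) : i + 2].mean()) for i in peaks.indices
            ]
            sbp = float(np.mean(pvals))
            # the diastolic foot is locally flat, so the raw sample at a
            # detected trough is minimum-biased under noise; a short local
            # mean around each trough is nearly unbiased either way
            w = 4
            vals = [
                float(abp[max(0, i - w) : i + w + 1].mean()) for i in troughs.indices
            ]
            dbp = float(np.mean(vals))
        else:
            sbp, dbp = float(abp.max()), float(abp.min())
    elif method == "extrema":
        sbp, dbp = float(abp.max()), float(abp.min())
    else:
        raise ValueError(f"unknown label method {method!r}")
    if not sbp > dbp:
        raise LabelExtractionError("peak/trough amplitudes do not bracket a pulse")
    return BPLabels(sbp=sbp, dbp=dbp, map=dbp + (sbp - dbp) / 3.0)


# ---------------------------------------------------------------------------
# quality screening


@dataclass(frozen=True)
class QualityThresholds:
    """Acceptance windows for the bad-signal filter (all bounds inclusive).

    Label windows follow the standard cuffless-BP cleaning convention
    (systolic 80-190, diastolic 50-120, pulse pressure 20-120 mmHg).  The
    peak-statistic ceilings are on unit-range-normalized signals: peak
    heights in normalized amplitude units, peak intervals normalized by
    their median.  Peak counts bound plausible heart rates for an 8.192 s
    segment (roughly 30-180 bpm).
    """

    sbp_min: float = 80.0
    sbp_max: float = 190.0
    dbp_min: float = 50.0
    dbp_max: float = 120.0
    pp_min: float = 20.0
    pp_max: float = 120.0
    max_peak_height_std: float = 0.15
    max_peak_interval_std: float = 0.20
    peak_count_min: int = 4
    peak_count_max: int = 25

    def __post_init__(self) -> None:
        ok = (
            self.sbp_min < self.sbp_max
            and self.dbp_min < self.dbp_max
            and self.pp_min < self.pp_max
            and self.max_peak_height_std > 0
            and self.max_peak_interval_std > 0
        )
        if not ok:
            raise ValueError("inconsistent quality thresholds")

    def loosened(self) -> "QualityThresholds":
        """Vacuous thresholds that accept everything (for ablations)."""
        return replace(
            self,
            sbp_min=-np.inf, sbp_max=np.inf, dbp_min=-np.inf, dbp_max=np.inf,
            pp_min=0.0, pp_max=np.inf,
            max_peak_height_std=np.inf, max_peak_interval_std=np.inf,
            peak_count_min=0, peak_count_max=10**9,
        )


@dataclass(frozen=True)
class Decision:
    accepted: bool
    reason: str | None = None
    value: float | None = None


def _peak_stats(x: np.ndarray, prominence_frac: float = 0.1) -> tuple[int, float, float]:
    """(count, height std, interval std / median interval) on a unit-range signal."""
    xn = (x - x.min()) / np.ptp(x)
    peaks = beat_peaks(xn, prominence_frac)
    n = len(peaks)
    if n < 2:
        return n, 0.0, 0.0
    heights = xn[peaks.indices]
    intervals = peaks.intervals.astype(np.float64)
    med = float(np.median(intervals))
    h_std = float(heights.std())
    i_std = float(intervals.std() / med) if med > 0 else np.inf
    return n, h_std, i_std


def assess_quality(
    record: SegmentRecord,
    labels: BPLabels | None,
    thr: QualityThresholds | None = None,
) -> Decision:
    """Accept or reject a segment; the reason names the first failed rule.

    Rule order: label windows (sbp, dbp), pulse pressure, blank channels,
    peak-height / peak-interval uniformity on PPG and ABP, peak count.
    ``labels=None`` (label extraction already failed) rejects immediately.
    """
    thr = thr or QualityThresholds()
    if labels is None:
        return Decision(False, "label_failure")
    if not (thr.sbp_min <= labels.sbp <= thr.sbp_max):
        return Decision(False, "sbp_range", labels.sbp)
    if not (thr.dbp_min <= labels.dbp <= thr.dbp_max):
        return Decision(False, "dbp_range", labels.dbp)
    pp = labels.pulse_pressure
    if not (thr.pp_min <= pp <= thr.pp_max):
        return Decision(False, "pulse_pressure", pp)
    screened = [k for k in ("PPG", "ABP") if k in record.channels]
    for kind in screened:
        if np.ptp(record.channel(kind).samples) == 0:
            return Decision(False, "blank", 0.0)
    for kind in screened:
        n, h_std, i_std = _peak_stats(record.channel(kind).samples)
        if h_std > thr.max_peak_height_std:
            return Decision(False, f"peak_height_std_{kind.lower()}", h_std)
        if i_std > thr.max_peak_interval_std:
            return Decision(False, f"peak_interval_std_{kind.lower()}", i_std)
        if not (thr.peak_count_min <= n <= thr.peak_count_max):
            return Decision(False, f"peak_count_{kind.lower()}", float(n))
    return Decision(True)


# ---------------------------------------------------------------------------
# whole-store pipeline


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration for the whole conditioning pipeline."""

    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    label_method: Literal["peak-mean", "extrema"] = "peak-mean"
    fallback_order: int = 6
    order_cap: int = 8
    out_length: int = 1024
    pad_mode: Literal["margin", "reflect"] = "margin"
    with_derivatives: bool = True
    prominence_frac: float = 0.1


@dataclass
class PreprocessResult:
    store: SegmentStore
    labels: pd.DataFrame
    context: NormalizationContext
    report: pd.DataFrame

    def rejection_counts(self) -> pd.Series:
        rejected = self.report[self.report["rule"] != "accept"]
        return rejected["rule"].value_counts()

    @property
    def fraction_removed(self) -> float:
        return float((self.report["rule"] != "accept").mean())


def preprocess_record(
    record: SegmentRecord, cfg: PreprocessConfig
) -> tuple[SegmentRecord | None, BPLabels | None, Decision]:
    """Condition one record: baseline-correct, label, screen, derive, trim.

    Returns ``(conditioned record or None, labels or None, decision)``.
    The returned record's predictor channels are unit-range normalized; its
    ABP channel is still in mmHg (the global divisor is applied at store
    level, once the normalization context is known).
    """
    L = cfg.out_length
    try:
        raw_abp = record.channel("ABP").samples
        labels = extract_bp_labels(raw_abp, cfg.label_method, cfg.prominence_frac)
    except (LabelExtractionError, KeyError):
        labels = None

    corrected = {}
    degenerate = False
    for kind, seg in record.channels.items():
        y, fit = correct_baseline(seg.samples, cfg.fallback_order, cfg.order_cap)
        if fit.branch == "degenerate":
            degenerate = True
        if kind == "ABP":
            y = y + seg.samples.min()  # re-anchor: keep the absolute mmHg level
        corrected[kind] = WaveformSegment(y, seg.fs, kind, seg.units)
    screened = record.with_channels(**corrected)

    decision = assess_quality(screened, labels, cfg.thresholds)
    if degenerate and decision.accepted:
        decision = Decision(False, "blank", 0.0)
    if not decision.accepted:
        return None, labels, decision

    out_channels: dict[str, WaveformSegment] = {}
    fs = record.fs
    try:
        if cfg.with_derivatives:
            ppg, vpg, apg = compute_derivatives(
                corrected["PPG"].samples, cfg.bandpass, L, cfg.pad_mode
            )
            out_channels["PPG"] = WaveformSegment(ppg, fs, "PPG", "norm")
            out_channels["VPG"] = WaveformSegment(vpg, fs, "VPG", "norm")
            out_channels["APG"] = WaveformSegment(apg, fs, "APG", "norm")
        else:
            ppg = normalize_unit_range(corrected["PPG"].samples)[:L]
            out_channels["PPG"] = WaveformSegment(ppg, fs, "PPG", "norm")
        if "ECG" in corrected:
            ecg = normalize_unit_range(corrected["ECG"].samples)[:L]
            out_channels["ECG"] = WaveformSegment(ecg, fs, "ECG", "norm")
        abp = corrected["ABP"].samples[:L]
        if np.ptp(abp) == 0:
            raise DegenerateSegmentError("trimmed ABP is constant")
        out_channels["ABP"] = WaveformSegment(abp, fs, "ABP", "mmHg")
    except DegenerateSegmentError:
        return None, labels, Decision(False, "blank", 0.0)
    except ValueError as exc:
        return None, labels, Decision(False, "margin", None) if "margin" in str(exc) or "samples" in str(exc) else Decision(False, "error", None)

    clean = SegmentRecord(record.segment_id, record.subject_id, out_channels)
    return clean, labels, decision


def preprocess_store(
    store: SegmentStore,
    cfg: PreprocessConfig | None = None,
    context: NormalizationContext | None = None,
) -> PreprocessResult:
    """Run the full conditioning pipeline over a store.

    Stages (in order): per-channel baseline correction -> label extraction
    from mmHg pressure -> quality rejection -> derivative channels ->
    per-segment predictor normalization -> global pressure normalization.

    ``context`` carries a frozen global systolic maximum fitted on a
    training partition; pass it when conditioning held-out data so the test
    set never influences the divisor.  When omitted, the divisor is the
    maximum conditioned pressure amplitude of *this* store's accepted
    segments.
    """
    cfg = cfg or PreprocessConfig()
    clean_records: list[SegmentRecord] = []
    label_rows: list[dict] = []
    report_rows: list[dict] = []
    for record in store:
        clean, labels, decision = preprocess_record(record, cfg)
        report_rows.append(
            {
                "segment_id": record.segment_id,
                "rule": "accept" if decision.accepted else decision.reason,
                "value": decision.value if not decision.accepted else np.nan,
            }
        )
        if clean is not None and labels is not None:
            clean_records.append(clean)
            label_rows.append(
                {
                    "segment_id": record.segment_id,
                    "subject_id": record.subject_id,
                    "sbp": labels.sbp,
                    "dbp": labels.dbp,
                    "map": labels.map,
                }
            )
    report = pd.DataFrame(report_rows, columns=["segment_id", "rule", "value"])
    if not clean_records:
        raise PipelineFailure("no segments survived quality screening", report)

    if context is None:
        global_max = max(float(r.channel("ABP").samples.max()) for r in clean_records)
        context = NormalizationContext(global_sbp_max=global_max)
    normalized = [
        r.with_channels(
            ABP=WaveformSegment(
                normalize_abp(r.channel("ABP").samples, context), r.fs, "ABP", "norm"
            )
        )
        for r in clean_records
    ]
    out = SegmentStore(
        normalized, store.source, store.history + ["preprocessed"]
    )
    labels_df = pd.DataFrame(label_rows, columns=["segment_id", "subject_id", "sbp", "dbp", "map"])
    return PreprocessResult(out, labels_df, context, report)
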