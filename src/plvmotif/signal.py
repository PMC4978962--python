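"""Band-limiting, trial segmentation, phase-locking value and FC ratios.

The connectivity measure is the phase-locking value (PLV): per trial, the
modulus of the time-averaged unit phasor of the instantaneous phase
difference between two nodes, then averaged across trials.  PLV is 0 for
independent wandering phases (up to a finite-sample Rayleigh floor of about
``sqrt(pi / (4 T))`` for ``T`` effective samples) and 1 for perfect locking.

Longitudinal change is summarised per link as the post/pre PLV ratio; a
ratio above 1 means the link synchronised further over the follow-up
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import firwin, filtfilt, lfilter, hilbert


class InsufficientDataError(ValueError):
    """Too few samples/trials to honour the segmentation contract."""


class AlignmentError(ValueError):
    """Matrices to combine disagree on subject, band or node order."""


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with half-open physical limits in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got {self}")

    def validate_for_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2.0:
            raise ValueError(
                f"band {self.name} upper edge {self.f_hi} Hz >= Nyquist ({fs / 2} Hz)"
            )


#: canonical electrophysiological band edges used throughout
DEFAULT_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 2.0, 3.9),
    "theta": BandSpec("theta", 4.1, 7.9),
    "alpha": BandSpec("alpha", 8.1, 11.9),
    "beta": BandSpec("beta", 12.1, 29.9),
}

#: reference FIR order at the reference sampling rate (see :func:`bandpass`)
FIR_ORDER_REF = 1500
FS_REF = 1000.0


@dataclass
class TrialSet:
    """Per subject/session/band stack of trials (trials x nodes x samples).

    ``kind`` is ``"signal"`` for real-valued time series (phases are then
    extracted with the analytic signal) or ``"phase"`` for precomputed
    instantaneous phases in radians.
    """

    subject_id: str
    session: str
    band: BandSpec
    fs: float
    data: np.ndarray
    kind: str = "signal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("TrialSet data must be trials x nodes x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("TrialSet data contains non-finite samples")
        if self.kind not in ("signal", "phase"):
            raise ValueError("kind must be 'signal' or 'phase'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric nodes x nodes PLV matrix with unit diagonal."""

    subject_id: str
    session: str
    band: BandSpec
    plv: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.plv, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("plv must be square")
        if not np.all(np.isfinite(p)):
            raise ValueError("plv contains non-finite values")
        self.plv = p


@dataclass
class RatioMatrix:
    """Elementwise post/pre PLV ratio for one subject and band."""

    subject_id: str
    band: BandSpec
    ratio: np.ndarray


def fir_order_for_fs(fs: float, order_ref: int = FIR_ORDER_REF) -> int:
    """Scale the reference FIR order to the working rate.

    Scaling the tap count by ``fs / 1000`` preserves the transition width
    (in Hz) of the reference order-1500 design at 1 kHz.
    """
    return max(2, int(round(order_ref * fs / FS_REF)))


def bandpass(
    ts: np.ndarray,
    band: BandSpec,
    fs: float,
    order: int | None = None,
    two_pass: bool = True,
) -> np.ndarray:
    """Zero-phase FIR band-pass of continuous multichannel data.

    A windowed-sinc (Hamming) FIR filter with ``order`` taps minus one
    (default: 1500 scaled by ``fs/1000``), applied forward-backward when
    ``two_pass`` so the net response has zero phase.  Input is
    ``nodes x samples`` continuous data; filter *before* segmenting into
    trials to keep edge effects out of the trials.

    Note the transition width is ~3.3/order*fs Hz; bands narrower than that
    (delta at these settings) are passed with some passband droop.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    band.validate_for_fs(fs)
    if order is None:
        order = fir_order_for_fs(fs)
    n_samples = ts.shape[-1]
    if n_samples <= 3 * order:
        raise InsufficientDataError(
            f"need more than 3*order={3 * order} samples, got {n_samples}"
        )
    taps = firwin(order + 1, [band.f_lo, band.f_hi], pass_zero=False, fs=fs)
    if two_pass:
        return filtfilt(taps, [1.0], ts, axis=-1)
    return lfilter(taps, [1.0], ts, axis=-1)


def segment(
    ts: np.ndarray,
    fs: float,
    trial_len: float = 4.0,
    min_trials: int = 15,
    subject_id: str = "",
    session: str = "",
    band: BandSpec = DEFAULT_BANDS["theta"],
    kind: str = "signal",
) -> TrialSet:
    """Cut continuous ``nodes x samples`` data into non-overlapping trials.

    The remainder after ``floor(samples / (trial_len * fs))`` trials is
    dropped; fewer than ``min_trials`` trials is an error (clean-data
    requirement for a stable across-trial PLV).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    per_trial = trial_len * fs
    if abs(per_trial - round(per_trial)) > 1e-9:
        raise ValueError("trial_len * fs must be an integer sample count")
    per_trial = int(round(per_trial))
    n_trials = ts.shape[-1] // per_trial
    if n_trials < min_trials:
        raise InsufficientDataError(
            f"{n_trials} trials of {trial_len} s available, need >= {min_trials}"
        )
    data = ts[:, : n_trials * per_trial]
    data = data.reshape(ts.shape[0], n_trials, per_trial).transpose(1, 0, 2)
    return TrialSet(
        subject_id=subject_id, session=session, band=band, fs=fs,
        data=data, kind=kind,
    )


def plv_matrix(trials: TrialSet, edge_trim: float | None = None) -> ConnectivityMatrix:
    """Across-trial mean PLV matrix of a trial set.

    Per trial the instantaneous phase of each node is taken from the
    analytic signal (or used directly for phase-kind data); a fraction
    ``edge_trim`` of samples is discarded at each trial end before the
    phasor time-average, since the analytic-signal phase is unreliable
    there.  The default trim is 10% per end for signal-kind data and none
    for phase-kind data (no analytic-signal edge effect exists there).
    The result is symmetric with unit diagonal and every entry in [0, 1].
    """
    if trials.n_trials < 1:
        raise InsufficientDataError("need at least one trial")
    if edge_trim is None:
        edge_trim = 0.0 if trials.kind == "phase" else 0.1
    if not 0.0 <= edge_trim < 0.5:
        raise ValueError("edge_trim must be in [0, 0.5)")
    if trials.kind == "phase":
        phase = trials.data
    else:
        phase = np.angle(hilbert(trials.data, axis=-1))
    n_samp = phase.shape[-1]
    trim = int(round(edge_trim * n_samp))
    if trim:
        phase = phase[..., trim : n_samp - trim]
    t_eff = phase.shape[-1]
    if t_eff < 2:
        raise InsufficientDataError("trial too short after edge trimming")
    z = np.exp(1j * phase)
    # per-trial cross phasor average, then modulus, then mean across trials
    cross = np.einsum("knt,kmt->knm", z, z.conj()) / t_eff
    plv = np.abs(cross).mean(axis=0)
    plv = 0.5 * (plv + plv.T)
    np.fill_diagonal(plv, 1.0)
    plv = np.clip(plv, 0.0, 1.0)
    return ConnectivityMatrix(
        subject_id=trials.subject_id, session=trials.session,
        band=trials.band, plv=plv,
    )


def ratio_matrix(
    post: ConnectivityMatrix,
    pre: ConnectivityMatrix,
    eps: float = 1e-6,
) -> RatioMatrix:
    """Elementwise post/pre PLV ratio for one subject and band.

    Pre-session values are floored at ``eps`` (with a warning) so a
    measure-zero exact-zero PLV cannot produce an infinite ratio.
    """
    if post.subject_id != pre.subject_id:
        raise AlignmentError(
            f"subject mismatch: {post.subject_id!r} vs {pre.subject_id!r}"
        )
    if post.band != pre.band:
        raise AlignmentError(f"band mismatch: {post.band} vs {pre.band}")
    if post.plv.shape != pre.plv.shape:
        raise AlignmentError("node-count mismatch between sessions")
    denom = pre.plv
    n_floored = int(np.count_nonzero(denom < eps))
    if n_floored:
        warnings.warn(
            f"{n_floored} pre-session PLV values below {eps} floored in ratio",
            RuntimeWarning,
            stacklevel=2,
        )
        denom = np.maximum(denom, eps)
    ratio = post.plv / denom
    ratio = 0.5 * (ratio + ratio.T)
    np.fill_diagonal(ratio, 1.0)
    return RatioMatrix(subject_id=post.subject_id, band=post.band, ratio=ratio)
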