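"""Two-state hidden Markov detection of lid opening/closing transitions.

Transitions are detected on the stored, unfiltered 30 kHz stream with a
two-state Gaussian-emission HMM (Baum–Welch fit, Viterbi decoding);
display filtering (37.5 Hz low-pass) is cosmetic only and never feeds
the detector.  Dwells are extracted by run-length encoding of the
decoded path; the first and last dwells are censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .dwells import CLOSED, OPEN, DwellSet
from .trace import Trace


class DegenerateFitError(RuntimeError):
    """The two emission levels collapsed — likely single-state data."""


@dataclass
class TwoStateHMM:
    """Fitted two-state Gaussian HMM in signal (nm) space.

    State convention: ``open`` is the extended conformation.  Whether
    the open state sits at the higher or lower signal level depends on
    the signal coordinate (deflection sum vs corrected protein
    extension); ``open_is_high`` records the convention used.
    """

    level_open: float
    level_closed: float
    sd_open: float
    sd_closed: float
    transmat: np.ndarray  # 2x2, row-stochastic, index order (open, closed)
    startprob: np.ndarray
    log_likelihood: float
    sampling_rate: float
    open_is_high: bool = True

    def __post_init__(self) -> None:
        self.transmat = np.asarray(self.transmat, dtype=float)
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if self.level_open == self.level_closed:
            raise ValueError("emission levels must differ")
        if not (self.sd_open > 0 and self.sd_closed > 0):
            raise ValueError("emission s.d. must be > 0")

    @property
    def levels(self) -> np.ndarray:
        return np.array([self.level_open, self.level_closed])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_open, self.sd_closed])

    def rates(self) -> dict:
        """Naive per-sample transition probabilities as rates (s⁻¹)."""
        fs = self.sampling_rate
        return {
            "closing": -fs * np.log1p(-self.transmat[OPEN, CLOSED]),
            "opening": -fs * np.log1p(-self.transmat[CLOSED, OPEN]),
        }


def _two_means_split(signal: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """1D 2-means (Lloyd) initialisation from the signal histogram."""
    lo, hi = np.percentile(signal, [10, 90])
    centers = np.array([lo, hi], dtype=float)
    for _ in range(max_iter):
        assign = np.abs(signal[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([
            signal[assign == k].mean() if np.any(assign == k) else centers[k]
            for k in (0, 1)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    sds = np.array([
        signal[assign == k].std() if np.sum(assign == k) > 1 else signal.std()
        for k in (0, 1)
    ])
    sds = np.clip(sds, 1e-12 * max(1.0, np.abs(centers).max()), None)
    return centers, sds


def _build_model(levels, sds, transmat, startprob, n_iter=0, tol=np.inf) -> GaussianHMM:
    model = GaussianHMM(
        n_components=2, covariance_type="diag",
        init_params="", params="stmc", n_iter=max(n_iter, 1), tol=tol,
    )
    model.startprob_ = np.asarray(startprob, dtype=float)
    model.transmat_ = np.asarray(transmat, dtype=float)
    model.means_ = np.asarray(levels, dtype=float).reshape(2, 1)
    model.covars_ = np.asarray(sds, dtype=float).reshape(2, 1) ** 2
    return model


def fit_hmm(
    trace: Trace,
    init: TwoStateHMM | None = None,
    max_iter: int = 500,
    tol_per_sample: float = 1e-8,
    open_is_high: bool = True,
    min_samples: int = 1000,
) -> TwoStateHMM:
    """Baum–Welch maximum-likelihood fit of the two-state model.

    Initialised from a 2-means split of the signal unless ``init`` is
    given; converged when the log-likelihood gain drops below
    ``tol_per_sample`` per sample or after ``max_iter`` iterations.
    Raises :class:`DegenerateFitError` when the fitted levels collapse
    within 0.1 pooled s.d. (single-state data).
    """
    signal = np.asarray(trace.signal, dtype=float)
    if signal.size < min_samples:
        raise ValueError(f"trace has {signal.size} samples; need >= {min_samples}")
    if init is not None:
        levels, sds = init.levels, init.sds
        transmat, startprob = init.transmat, init.startprob
    else:
        centers, sds = _two_means_split(signal)
        levels = centers
        transmat = np.array([[0.99, 0.01], [0.01, 0.99]])
        startprob = np.array([0.5, 0.5])

    model = _build_model(levels, sds, transmat, startprob,
                         n_iter=max_iter, tol=tol_per_sample * signal.size)
    X = signal.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
    loglik = float(model.score(X))

    means = model.means_.ravel()
    stds = np.sqrt(model.covars_.ravel())
    pooled_sd = float(np.mean(stds))
    if abs(means[0] - means[1]) < 0.1 * pooled_sd:
        raise DegenerateFitError(
            f"emission levels collapse ({means[0]:.4g} vs {means[1]:.4g} nm, "
            f"pooled sd {pooled_sd:.4g} nm): data look single-state"
        )
    # map component index -> physical state
    hi, lo = int(np.argmax(means)), int(np.argmin(means))
    open_idx = hi if open_is_high else lo
    closed_idx = lo if open_is_high else hi
    perm = [open_idx, closed_idx]
    return TwoStateHMM(
        level_open=float(means[open_idx]),
        level_closed=float(means[closed_idx]),
        sd_open=float(stds[open_idx]),
        sd_closed=float(stds[closed_idx]),
        transmat=model.transmat_[np.ix_(perm, perm)],
        startprob=model.startprob_[perm],
        log_likelihood=loglik,
        sampling_rate=trace.sampling_rate,
        open_is_high=open_is_high,
    )


def forward_log_likelihood(hmm: TwoStateHMM, trace: Trace) -> float:
    """Forward-algorithm log P(signal | model)."""
    model = _build_model(hmm.levels, hmm.sds, hmm.transmat, hmm.startprob)
    return float(model.score(np.asarray(trace.signal, dtype=float).reshape(-1, 1)))


def state_posteriors(hmm: TwoStateHMM, trace: Trace) -> np.ndarray:
    """Forward–backward posterior state probabilities, shape (n, 2)."""
    model = _build_model(hmm.levels, hmm.sds, hmm.transmat, hmm.startprob)
    _, post = model.score_samples(np.asarray(trace.signal, dtype=float).reshape(-1, 1))
    return post


def viterbi_path(hmm: TwoStateHMM, trace: Trace) -> np.ndarray:
    """Most probable state path (OPEN/CLOSED per sample), deterministic."""
    model = _build_model(hmm.levels, hmm.sds, hmm.transmat, hmm.startprob)
    _, path = model.decode(np.asarray(trace.signal, dtype=float).reshape(-1, 1),
                           algorithm="viterbi")
    return path.astype(int)


def extract_dwells(path: np.ndarray, trace: Trace) -> DwellSet:
    """Run-length encode a decoded path into a censoring-aware dwell set.

    Per-dwell mean force comes from the trace's force channel (NaN when
    absent).  The first and last dwells are censored; a path with no
    interior dwell yields an empty set with a warning.
    """
    path = np.asarray(path, dtype=int)
    if path.size != len(trace):
        raise ValueError("path length must match trace length")
    fs = trace.sampling_rate
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [path.size]])
    states = path[starts]
    durations = (ends - starts) / fs
    t0 = trace.time[0] - 0.5 / fs
    t_start = t0 + starts / fs
    if trace.force is not None:
        forces = np.array([trace.force[s:e].mean() for s, e in zip(starts, ends)])
    else:
        forces = np.full(states.size, np.nan)
    censored = np.zeros(states.size, dtype=bool)
    censored[0] = True
    censored[-1] = True
    meta = {k: trace.meta[k] for k in trace.meta if k != "history"}
    # missed-event diagnostic: dwells shorter than ~2 samples are unreliable
    meta["dead_time_s"] = 2.0 / fs
    if states.size <= 2:
        warnings.warn("no interior dwells: all dwells censored", stacklevel=2)
    return DwellSet(state=states, duration=durations, mean_force=forces,
                    censored=censored, t_start=t_start, meta=meta)


def lowpass_display(trace: Trace, cutoff: float = 37.5, order: int = 4) -> Trace:
    """Zero-phase low-pass filter for display only (default 37.5 Hz).

    Never use the output as input to :func:`fit_hmm`; detection runs on
    the unfiltered stream.  The DC level is preserved.
    """
    from scipy.signal import butter, sosfiltfilt

    fs = trace.sampling_rate
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    sos = butter(order, cutoff / (fs / 2), btype="low", output="sos")
    filtered = sosfiltfilt(sos, trace.signal)
    return trace.with_signal(filtered, history_entry=f"lowpass_display({cutoff}Hz)")
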