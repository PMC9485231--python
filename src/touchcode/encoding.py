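"""Curvature-driven encoding model of touch-evoked GCaMP ΔF/F.

The model predicts a neuron's ΔF/F trace from the per-frame whisker
curvature change Δκ of the two whiskers:

    r_model = d · [ (j_w2w1 · a_w1 + j_w1w2 · a_w2) * g ]

where the per-whisker drive at each frame is

    a_w = s_pro · log10(−Δκ_pro + o_pro) + s_ret · log10(Δκ_ret + o_ret)

with the protraction term active on frames with Δκ < 0 and the retraction
term on frames with Δκ > 0 (log arguments are floored at 1, so the offsets
o act as soft force thresholds and each term is non-negative).  g is the
indicator-kinetics kernel — a difference of exponentials with rise and
decay time constants, peak-normalised to 1 — d a per-session scaling
(max over sessions fixed at 1), and j a cross-whisker interaction gain
applied to the second-touching whisker on near-coincident multi-whisker
trials.  An additive Gaussian noise variance σ², estimated from negative
ΔF/F samples, completes the generative description but is never added to
the point prediction.

Fitting is block coordinate descent under a mean-square-error cost with
5-fold cross-validation over whole trials.  Classification compares the
cross-validated prediction/data Pearson correlation per single-whisker
touch type against both an absolute floor (0.1) and the 99th percentile of
scores from fits to circularly time-shifted traces of activity-matched
neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import toeplitz
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve

from .data import (
    TOUCH_TYPES,
    DegenerateTraceError,
    NeuronRecord,
    Trial,
    single_whisker_trials,
    total_frames,
    trials_of_type,
)
from .kinematics import classify_trial_type

TAU_RISE_BOUNDS = (0.1, 0.5)  # s, physiological range of GCaMP6s rise
TAU_DECAY_BOUNDS = (1.0, 5.0)  # s, decay range
J_BOUNDS = (0.0, 10.0)
OFFSET_BOUNDS = (0.05, 10.0)
MULTI_INTERVAL_MS = 200.0  # interaction fit uses only near-coincident trials
SCORE_FLOOR = 0.1
KERNEL_TAIL = 5.0  # kernel truncated at 5 tau_decay


class ParameterError(ValueError):
    """An encoding-model parameter violates its constraint."""


@dataclass
class EncodingParams:
    """All parameters of the encoding model for one neuron.

    Arrays are indexed by whisker (0 -> W1, 1 -> W2).  ``d`` maps session id
    to the session scaling in [0, 1] with max 1.
    """

    s_pro: np.ndarray
    s_ret: np.ndarray
    o_pro: np.ndarray
    o_ret: np.ndarray
    tau_rise: float
    tau_decay: float
    d: dict[int, float]
    j_w1w2: float = 1.0
    j_w2w1: float = 1.0
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s_pro", "s_ret", "o_pro", "o_ret"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.s_pro < 0) or np.any(self.s_ret < 0):
            raise ParameterError("response slopes s must be >= 0")
        if np.any(self.o_pro <= 0) or np.any(self.o_ret <= 0):
            raise ParameterError("curvature offsets o must be > 0")
        if not (TAU_RISE_BOUNDS[0] <= self.tau_rise <= TAU_RISE_BOUNDS[1]):
            raise ParameterError(f"tau_rise outside {TAU_RISE_BOUNDS}")
        if not (TAU_DECAY_BOUNDS[0] <= self.tau_decay <= TAU_DECAY_BOUNDS[1]):
            raise ParameterError(f"tau_decay outside {TAU_DECAY_BOUNDS}")
        if self.d:
            vals = np.array(list(self.d.values()))
            if np.any(vals < 0) or np.any(vals > 1 + 1e-9):
                raise ParameterError("session scalings d must lie in [0, 1]")
        for j in (self.j_w1w2, self.j_w2w1):
            if not (J_BOUNDS[0] <= j <= J_BOUNDS[1]):
                raise ParameterError(f"interaction gain outside {J_BOUNDS}")
        if self.sigma2 < 0:
            raise ParameterError("noise variance sigma2 must be >= 0")


@dataclass
class EncodingScore:
    """Per-touch-type model/data correlations and pass flags.

    ``r[t]`` is the Pearson correlation between the (cross-validated)
    prediction and the data over the concatenated frames of type-t
    single-whisker trials.  A type passes when r exceeds both the absolute
    floor 0.1 and the shuffle-null threshold for the neuron's event-rate bin.
    """

    r: dict[str, float]
    threshold: dict[str, float] = field(default_factory=dict)

    def passes(self, touch_type: str) -> bool:
        r = self.r.get(touch_type, 0.0)
        thr = self.threshold.get(touch_type, np.inf)
        return r > SCORE_FLOOR and r > thr

    @property
    def passing_types(self) -> list[str]:
        return [t for t in TOUCH_TYPES if self.passes(t)]


@dataclass(frozen=True)
class NeuronClass:
    """Touch-class label with subtype detail.

    uSW carries (whisker, direction); bSW carries whisker; MW and non-touch
    carry neither.
    """

    label: str
    whisker: int | None = None
    direction: str | None = None


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def gcamp_kernel(
    tau_rise: float, tau_decay: float, dt: float, duration: float | None = None
) -> np.ndarray:
    """Peak-normalised indicator kernel exp(−t/τ_decay) − exp(−t/τ_rise).

    k(0) = 0, a single interior maximum at t* = ln(τd/τr)/(1/τr − 1/τd),
    rescaled so its peak equals 1.  Truncated at ``duration`` (default
    5 × τ_decay).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if tau_rise >= tau_decay:
        raise ParameterError("tau_rise must be smaller than tau_decay")
    if duration is None:
        duration = KERNEL_TAIL * tau_decay
    t = np.arange(0.0, duration, dt)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:  # duration shorter than the rise: no interior maximum yet
        t_star = np.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay)
        peak = np.exp(-t_star / tau_decay) - np.exp(-t_star / tau_rise)
    return k / peak


def whisker_drive(
    dkappa: np.ndarray,
    s_pro: float,
    o_pro: float,
    s_ret: float,
    o_ret: float,
) -> np.ndarray:
    """Per-frame response amplitude a_w for one whisker.

    Frames with Δκ < 0 take the protraction term s_pro·log10(−Δκ + o_pro),
    frames with Δκ > 0 the retraction term, zero-Δκ frames contribute 0.
    Log arguments are floored at 1 so contributions are never negative and
    offsets act as soft thresholds on the minimal effective force.
    """
    if o_pro <= 0 or o_ret <= 0:
        raise ParameterError("curvature offsets must be > 0")
    dkappa = np.asarray(dkappa, dtype=float)
    out = np.zeros_like(dkappa)
    pro = dkappa < 0
    ret = dkappa > 0
    if np.any(pro):
        out[pro] = s_pro * np.log10(np.maximum(-dkappa[pro] + o_pro, 1.0))
    if np.any(ret):
        out[ret] = s_ret * np.log10(np.maximum(dkappa[ret] + o_ret, 1.0))
    return out


def _interaction_gains(
    trial: Trial, params: EncodingParams, frame_rate_hz: float
) -> tuple[float, float]:
    """Gains applied to (whisker-1 drive, whisker-2 drive) on this trial.

    The interaction gain scales the second-touching whisker's drive only on
    multi-whisker trials whose first two touches are < 200 ms apart.
    """
    if trial.trial_type != "multi":
        return 1.0, 1.0
    _, first, interval_ms = classify_trial_type(trial, frame_rate_hz)
    if interval_ms is None or interval_ms >= MULTI_INTERVAL_MS:
        return 1.0, 1.0
    if first == 1:
        return 1.0, params.j_w1w2
    return params.j_w2w1, 1.0


def predict_trace(
    params: EncodingParams,
    trials: list[Trial],
    frame_rate_hz: float,
    n_frames: int | None = None,
) -> np.ndarray:
    """Noiseless model prediction over the concatenated recording.

    Per trial the two whisker drives are combined (with interaction gains
    where they apply), convolved with the kernel within the trial, and
    scaled by the session factor d.  Frames outside every trial are 0.
    The σ² noise term is excluded: the prediction is the model mean.
    """
    if n_frames is None:
        n_frames = total_frames(trials)
    dt = 1.0 / frame_rate_hz
    kernel = gcamp_kernel(params.tau_rise, params.tau_decay, dt)
    out = np.zeros(n_frames)
    for trial in trials:
        if trial.session_id not in params.d:
            raise ParameterError(
                f"no session scaling d for session {trial.session_id}"
            )
        g1, g2 = _interaction_gains(trial, params, frame_rate_hz)
        a1 = whisker_drive(
            trial.dkappa[0], params.s_pro[0], params.o_pro[0],
            params.s_ret[0], params.o_ret[0],
        )
        a2 = whisker_drive(
            trial.dkappa[1], params.s_pro[1], params.o_pro[1],
            params.s_ret[1], params.o_ret[1],
        )
        drive = g1 * a1 + g2 * a2
        pred = np.convolve(drive, kernel)[: trial.n_frames]
        lo, hi = trial.frame_span
        out[lo:hi] = params.d[trial.session_id] * pred
    return out


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _kernel_matrix(kernel: np.ndarray, nf: int) -> np.ndarray:
    """Lower-triangular Toeplitz operator for causal within-trial convolution."""
    first_col = np.zeros(nf)
    m = min(kernel.size, nf)
    first_col[:m] = kernel[:m]
    return toeplitz(first_col, np.zeros(nf))


def _conv_rows(mat: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Row-wise causal convolution truncated to the row length.

    For the short trials used in fitting a dense Toeplitz matmul beats
    FFT-based convolution; long inputs fall back to fftconvolve.
    """
    nf = mat.shape[1]
    if mat.shape[0] == 0:
        return mat.copy()
    if nf <= 256:
        return mat @ _kernel_matrix(kernel, nf).T
    full = fftconvolve(mat, kernel[None, :], axes=1)
    return full[:, :nf]


class _WhiskerFitData:
    """Pre-extracted arrays for fitting one whisker's drive terms."""

    def __init__(self, trials: list[Trial], trace: np.ndarray, whisker_id: int):
        self.trials = trials
        nf = {t.n_frames for t in trials}
        if len(nf) != 1:
            raise ValueError("fitting requires equal-length trials")
        self.nf = nf.pop()
        self.dk = np.stack([t.dkappa[whisker_id - 1] for t in trials])
        self.y = np.stack(
            [trace[t.frame_span[0] : t.frame_span[1]] for t in trials]
        )
        self.sessions = np.array([t.session_id for t in trials])
        self.session_ids = sorted(set(self.sessions))
        self.pro = self.dk < 0
        self.ret = self.dk > 0

    def d_vector(self, d: dict[int, float]) -> np.ndarray:
        return np.array([d[s] for s in self.sessions])[:, None]

    def log_pro(self, o_pro: float) -> np.ndarray:
        out = np.zeros_like(self.dk)
        out[self.pro] = np.log10(np.maximum(-self.dk[self.pro] + o_pro, 1.0))
        return out

    def log_ret(self, o_ret: float) -> np.ndarray:
        out = np.zeros_like(self.dk)
        out[self.ret] = np.log10(np.maximum(self.dk[self.ret] + o_ret, 1.0))
        return out


def _solve_slopes(
    B_pro: np.ndarray, B_ret: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Non-negative least squares for the two slopes given drive bases.

    2-variable closed form with clipping at 0; returns (s_pro, s_ret, sse).
    """
    bp = B_pro.ravel()
    br = B_ret.ravel()
    yv = y.ravel()
    gpp = bp @ bp
    grr = br @ br
    gpr = bp @ br
    cp = bp @ yv
    cr = br @ yv
    det = gpp * grr - gpr * gpr
    s_p = s_r = 0.0
    if det > 1e-12:
        s_p = (grr * cp - gpr * cr) / det
        s_r = (gpp * cr - gpr * cp) / det
    if s_p < 0 or s_r < 0 or det <= 1e-12:
        # active-set fallback: try each single-variable solution
        cands = []
        if gpp > 1e-12:
            cands.append((max(cp / gpp, 0.0), 0.0))
        if grr > 1e-12:
            cands.append((0.0, max(cr / grr, 0.0)))
        cands.append((0.0, 0.0))
        best = None
        for sp, sr in cands:
            resid = yv - sp * bp - sr * br
            sse = resid @ resid
            if best is None or sse < best[2]:
                best = (sp, sr, sse)
        return best
    resid = yv - s_p * bp - s_r * br
    return s_p, s_r, float(resid @ resid)


@dataclass
class _WhiskerFitState:
    s_pro: float
    s_ret: float
    o_pro: float
    o_ret: float
    tau_rise: float
    tau_decay: float
    d: dict[int, float]
    sse: float = np.inf
    r2: float = 0.0


def _fit_single_whisker(
    data: _WhiskerFitData,
    dt: float,
    init: _WhiskerFitState,
    max_cycles: int = 25,
    tol: float = 1e-6,
) -> _WhiskerFitState:
    """Block coordinate descent for one whisker's drive, kernel and scaling.

    Blocks: (slopes, offsets) -> (tau_rise, tau_decay) -> d per session,
    cycled until the relative SSE improvement falls below ``tol``.
    """
    st = replace(init, d=dict(init.d))
    y = data.y
    y_var = float(np.sum((y - y.mean()) ** 2))

    def drive_mats(o_pro, o_ret):
        return data.log_pro(o_pro), data.log_ret(o_ret)

    def sse_for(st: _WhiskerFitState) -> float:
        kernel = gcamp_kernel(st.tau_rise, st.tau_decay, dt)
        Lp, Lr = drive_mats(st.o_pro, st.o_ret)
        dvec = data.d_vector(st.d)
        pred = dvec * _conv_rows(st.s_pro * Lp + st.s_ret * Lr, kernel)
        return float(np.sum((y - pred) ** 2))

    prev_sse = sse_for(st)
    for _ in range(max_cycles):
        kernel = gcamp_kernel(st.tau_rise, st.tau_decay, dt)
        dvec = data.d_vector(st.d)

        # --- block 1: offsets (scalar searches) with slopes solved inline;
        # the fixed side's basis is cached across evaluations
        def basis_pro(o):
            return dvec * _conv_rows(data.log_pro(o), kernel)

        def basis_ret(o):
            return dvec * _conv_rows(data.log_ret(o), kernel)

        Br = basis_ret(st.o_ret)
        if data.pro.any():
            res = minimize_scalar(
                lambda o: _solve_slopes(basis_pro(o), Br, y)[2],
                bounds=OFFSET_BOUNDS, method="bounded",
                options={"xatol": 1e-3},
            )
            st.o_pro = float(res.x)
        Bp = basis_pro(st.o_pro)
        if data.ret.any():
            res = minimize_scalar(
                lambda o: _solve_slopes(Bp, basis_ret(o), y)[2],
                bounds=OFFSET_BOUNDS, method="bounded",
                options={"xatol": 1e-3},
            )
            st.o_ret = float(res.x)
        st.s_pro, st.s_ret, sse = _solve_slopes(Bp, basis_ret(st.o_ret), y)

        # --- block 2: kernel time constants (scalar searches)
        Lp, Lr = drive_mats(st.o_pro, st.o_ret)
        drive = st.s_pro * Lp + st.s_ret * Lr

        def tau_obj(tr, td):
            if tr >= td:
                return np.inf
            k = gcamp_kernel(tr, td, dt)
            pred = dvec * _conv_rows(drive, k)
            return float(np.sum((y - pred) ** 2))

        res = minimize_scalar(
            lambda tr: tau_obj(tr, st.tau_decay),
            bounds=TAU_RISE_BOUNDS, method="bounded",
            options={"xatol": 1e-3},
        )
        st.tau_rise = float(res.x)
        res = minimize_scalar(
            lambda td: tau_obj(st.tau_rise, td),
            bounds=(max(TAU_DECAY_BOUNDS[0], st.tau_rise + 1e-3), TAU_DECAY_BOUNDS[1]),
            method="bounded", options={"xatol": 1e-3},
        )
        st.tau_decay = float(res.x)

        # --- block 3: per-session scaling, closed form, then renormalise
        kernel = gcamp_kernel(st.tau_rise, st.tau_decay, dt)
        base = _conv_rows(drive, kernel)  # prediction with d = 1
        scales = {}
        for sid in data.session_ids:
            rows = data.sessions == sid
            p = base[rows].ravel()
            denom = p @ p
            scales[sid] = max(float((y[rows].ravel() @ p) / denom), 0.0) if denom > 1e-12 else 0.0
        m = max(scales.values()) if scales else 0.0
        if m > 0:
            st.d = {sid: c / m for sid, c in scales.items()}
            st.s_pro *= m
            st.s_ret *= m
        else:
            st.d = {sid: 1.0 for sid in data.session_ids}
        sse = sse_for(st)
        if prev_sse - sse <= tol * max(prev_sse, 1e-12):
            prev_sse = sse
            break
        prev_sse = sse
    st.sse = prev_sse
    st.r2 = 1.0 - prev_sse / y_var if y_var > 0 else 0.0
    return st


def _random_state(rng: np.random.Generator, session_ids: list[int]) -> _WhiskerFitState:
    lo, hi = OFFSET_BOUNDS
    return _WhiskerFitState(
        s_pro=1.0, s_ret=1.0,
        o_pro=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        o_ret=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        tau_rise=float(rng.uniform(*TAU_RISE_BOUNDS)),
        tau_decay=float(rng.uniform(*TAU_DECAY_BOUNDS)),
        d={sid: 1.0 for sid in session_ids},
    )


def sigma2_from_trace(trace: np.ndarray) -> float:
    """Noise variance from negative ΔF/F samples (half-normal mean of squares).

    For a zero-centred trace whose negative excursions are pure noise, the
    mean square of the negative samples is the maximum-likelihood estimate
    of the Gaussian noise variance.
    """
    neg = trace[trace < 0]
    if neg.size == 0:
        raise DegenerateTraceError("trace has no negative samples")
    return float(np.mean(neg**2))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; undefined (zero-variance) correlations score 0."""
    if a.size < 2:
        return 0.0
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class TouchEncodingModel:
    """Encoding model of one neuron's ΔF/F given the trial structure.

    Parameters
    ----------
    trace : concatenated ΔF/F trace covering all trials.
    trials : the trial structure (per-frame Δκ, touch events, sessions).
    frame_rate_hz : imaging frame rate.

    ``fit`` runs the cross-validated block-coordinate-descent procedure and
    returns an :class:`EncodingResults`.
    """

    def __init__(self, trace: np.ndarray, trials: list[Trial], frame_rate_hz: float):
        self.trace = np.asarray(trace, dtype=float)
        self.trials = trials
        self.frame_rate_hz = float(frame_rate_hz)
        n = total_frames(trials)
        if self.trace.size < n:
            raise ValueError(
                f"trace has {self.trace.size} frames but trials span {n}"
            )
        self.session_ids = sorted({t.session_id for t in trials})

    # -- data selection -----------------------------------------------------

    def _whisker_fit_trials(
        self, whisker_id: int, pool: list[Trial], rng: np.random.Generator
    ) -> list[Trial]:
        """Single-whisker trials of one whisker plus an equal non-touch sample."""
        sw = [t for t in pool if t.trial_type == f"W{whisker_id}-only"]
        nt = [t for t in pool if t.trial_type == "none"]
        if len(nt) > len(sw):
            idx = rng.choice(len(nt), size=len(sw), replace=False)
            nt = [nt[i] for i in sorted(idx)]
        return sw + nt

    # -- fitting ------------------------------------------------------------

    def _fit_whisker(
        self,
        whisker_id: int,
        pool: list[Trial],
        trace: np.ndarray,
        rng: np.random.Generator,
        restarts: int,
        warm: _WhiskerFitState | None = None,
        max_cycles: int = 25,
    ) -> _WhiskerFitState | None:
        trials = self._whisker_fit_trials(whisker_id, pool, rng)
        if not any(t.trial_type == f"W{whisker_id}-only" for t in trials):
            return None
        data = _WhiskerFitData(trials, trace, whisker_id)
        dt = 1.0 / self.frame_rate_hz
        starts: list[_WhiskerFitState] = []
        if warm is not None:
            starts.append(replace(warm, d=dict(warm.d)))
        while len(starts) < max(restarts, 1):
            starts.append(_random_state(rng, data.session_ids))
        best = None
        for st0 in starts:
            st0.d = {sid: st0.d.get(sid, 1.0) for sid in data.session_ids}
            st = _fit_single_whisker(data, dt, st0, max_cycles=max_cycles)
            if best is None or st.sse < best.sse:
                best = st
        return best

    def _combine(
        self, fits: dict[int, _WhiskerFitState | None]
    ) -> EncodingParams:
        """Merge per-whisker fits: average τ and d weighted by fit quality.

        The two whisker fits each estimate the shared kernel and session
        scalings; the estimates are averaged with weights given by each
        fit's explained variance (floored at 0) so that an unresponsive
        whisker's uninformative estimate does not dilute the other's.
        """
        present = {w: f for w, f in fits.items() if f is not None}
        if not present:
            raise ValueError("no whisker could be fit")
        ws = np.array([max(f.r2, 0.0) for f in present.values()])
        if ws.sum() <= 0:
            ws = np.ones_like(ws)
        ws = ws / ws.sum()
        tau_r = float(sum(w * f.tau_rise for w, f in zip(ws, present.values())))
        tau_d = float(sum(w * f.tau_decay for w, f in zip(ws, present.values())))
        tau_d = max(tau_d, tau_r + 1e-3)
        d = {}
        for sid in self.session_ids:
            d[sid] = float(
                sum(w * f.d.get(sid, 1.0) for w, f in zip(ws, present.values()))
            )
        m = max(d.values())
        if m > 0:
            d = {sid: v / m for sid, v in d.items()}
        else:
            d = {sid: 1.0 for sid in d}
        s_pro = np.zeros(2)
        s_ret = np.zeros(2)
        o_pro = np.ones(2)
        o_ret = np.ones(2)
        for w, f in fits.items():
            if f is None:
                continue
            s_pro[w - 1] = f.s_pro
            s_ret[w - 1] = f.s_ret
            o_pro[w - 1] = f.o_pro
            o_ret[w - 1] = f.o_ret
        return EncodingParams(
            s_pro=s_pro, s_ret=s_ret, o_pro=o_pro, o_ret=o_ret,
            tau_rise=tau_r, tau_decay=tau_d, d=d,
        )

    def _refit_slopes(
        self, params: EncodingParams, pool: list[Trial], trace: np.ndarray,
        rng: np.random.Generator,
    ) -> EncodingParams:
        """One slope/offset pass per whisker with the merged kernel and d fixed."""
        dt = 1.0 / self.frame_rate_hz
        for w in (1, 2):
            trials = self._whisker_fit_trials(w, pool, rng)
            if not any(t.trial_type == f"W{w}-only" for t in trials):
                continue
            data = _WhiskerFitData(trials, trace, w)
            kernel = gcamp_kernel(params.tau_rise, params.tau_decay, dt)
            dvec = data.d_vector({s: params.d.get(s, 1.0) for s in data.session_ids})

            def basis_pro(o):
                return dvec * _conv_rows(data.log_pro(o), kernel)

            def basis_ret(o):
                return dvec * _conv_rows(data.log_ret(o), kernel)

            o_pro = params.o_pro[w - 1]
            o_ret = params.o_ret[w - 1]
            Br = basis_ret(o_ret)
            if data.pro.any():
                res = minimize_scalar(
                    lambda o: _solve_slopes(basis_pro(o), Br, data.y)[2],
                    bounds=OFFSET_BOUNDS, method="bounded", options={"xatol": 1e-3},
                )
                o_pro = float(res.x)
            Bp = basis_pro(o_pro)
            if data.ret.any():
                res = minimize_scalar(
                    lambda o: _solve_slopes(Bp, basis_ret(o), data.y)[2],
                    bounds=OFFSET_BOUNDS, method="bounded", options={"xatol": 1e-3},
                )
                o_ret = float(res.x)
            sp, sr, _ = _solve_slopes(Bp, basis_ret(o_ret), data.y)
            params.s_pro[w - 1] = sp
            params.s_ret[w - 1] = sr
            params.o_pro[w - 1] = o_pro
            params.o_ret[w - 1] = o_ret
        return params

    def fit(
        self,
        folds: int = 5,
        restarts: int = 3,
        seed: int | None = None,
        fit_interactions: bool = True,
    ) -> "EncodingResults":
        """Cross-validated fit.

        Trials are partitioned whole into ``folds`` disjoint folds; each
        fold's model is fit on the remaining trials and predicts the held
        out ones, giving an unbiased prediction for every frame.  The full
        data fit (with ``restarts`` random restarts; fold fits warm-start
        from it) provides the reported parameters.
        """
        rng = np.random.default_rng(seed)
        trials = self.trials
        if len(trials) < folds:
            raise ValueError(f"need at least {folds} trials for {folds}-fold CV")
        for w in (1, 2):
            n_sw = len(trials_of_type(trials, f"W{w}-only"))
            if 0 < n_sw < folds:
                raise ValueError(
                    f"whisker {w} has only {n_sw} single-whisker trials; "
                    f"cannot form {folds} folds"
                )
        sigma2 = sigma2_from_trace(self.trace)

        # full-data fit (random restarts)
        full_fits = {
            w: self._fit_whisker(w, trials, self.trace, rng, restarts)
            for w in (1, 2)
        }
        params = self._combine(full_fits)
        params = self._refit_slopes(params, trials, self.trace, rng)
        params.sigma2 = sigma2

        # fold assignment: whole trials, stratified by trial type so every
        # training set contains single-whisker and non-touch trials
        fold_of = np.zeros(len(trials), dtype=int)
        for ttype in ("none", "W1-only", "W2-only", "multi"):
            idx = [i for i, t in enumerate(trials) if t.trial_type == ttype]
            perm = rng.permutation(len(idx))
            for k, p in enumerate(perm):
                fold_of[idx[p]] = k % folds

        n = total_frames(trials)
        cv_pred = np.zeros(n)
        warm = {w: full_fits[w] for w in (1, 2)}
        for k in range(folds):
            train = [t for i, t in enumerate(trials) if fold_of[i] != k]
            test = [t for i, t in enumerate(trials) if fold_of[i] == k]
            fits_k = {
                w: self._fit_whisker(
                    w, train, self.trace, rng, restarts=1,
                    warm=warm[w], max_cycles=8,
                )
                for w in (1, 2)
            }
            try:
                params_k = self._combine(fits_k)
            except ValueError:
                params_k = params
            params_k = self._refit_slopes(params_k, train, self.trace, rng)
            pred_k = predict_trace(params_k, test, self.frame_rate_hz, n_frames=n)
            for t in test:
                lo, hi = t.frame_span
                cv_pred[lo:hi] = pred_k[lo:hi]

        # interaction terms on near-coincident multi trials
        warning = None
        if fit_interactions:
            params, warning = fit_interaction_terms(
                params, self.trace, trials, self.frame_rate_hz
            )

        score = EncodingScore(
            r={
                t: _score_touch_type(self.trace, cv_pred, trials, t)
                for t in TOUCH_TYPES
            }
        )
        return EncodingResults(
            model=self, params=params, score=score, cv_prediction=cv_pred,
            fold_of=fold_of, interaction_warning=warning,
        )


def _score_touch_type(
    trace: np.ndarray, pred: np.ndarray, trials: list[Trial], touch_type: str
) -> float:
    """Pearson r over the concatenated frames of one touch type's trials."""
    sel = single_whisker_trials(trials, touch_type)
    if not sel:
        return 0.0
    idx = np.concatenate([np.arange(*t.frame_span) for t in sel])
    return _pearson(trace[idx], pred[idx])


@dataclass
class EncodingResults:
    """Fitted encoding model: parameters, scores and diagnostics."""

    model: TouchEncodingModel
    params: EncodingParams
    score: EncodingScore
    cv_prediction: np.ndarray
    fold_of: np.ndarray
    interaction_warning: str | None = None

    @property
    def in_sample_prediction(self) -> np.ndarray:
        return predict_trace(
            self.params, self.model.trials, self.model.frame_rate_hz,
            n_frames=self.model.trace.size,
        )

    def classify(self, thresholds: dict[str, float] | None = None) -> NeuronClass:
        if thresholds is not None:
            self.score.threshold = dict(thresholds)
        return classify_neuron(self.score)

    def simulate(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw a synthetic trace from the fitted generative model."""
        rng = rng or np.random.default_rng()
        mean = self.in_sample_prediction
        return mean + rng.normal(0.0, np.sqrt(self.params.sigma2), mean.size)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Touch encoding model fit",
            "=" * 54,
            f"{'tau_rise (s)':<22}{p.tau_rise:>10.3f}",
            f"{'tau_decay (s)':<22}{p.tau_decay:>10.3f}",
            f"{'sigma2 (dFF^2)':<22}{p.sigma2:>10.4f}",
            f"{'j_w1w2':<22}{p.j_w1w2:>10.3f}",
            f"{'j_w2w1':<22}{p.j_w2w1:>10.3f}",
        ]
        for w in (1, 2):
            lines.append(
                f"W{w}: s_pro={p.s_pro[w-1]:.3f} o_pro={p.o_pro[w-1]:.3f} "
                f"s_ret={p.s_ret[w-1]:.3f} o_ret={p.o_ret[w-1]:.3f}"
            )
        lines.append(
            "d: " + ", ".join(f"s{s}={v:.3f}" for s, v in sorted(p.d.items()))
        )
        lines.append("-" * 54)
        lines.append("touch type   CV r      threshold  pass")
        for t in TOUCH_TYPES:
            thr = self.score.threshold.get(t)
            thr_s = f"{thr:9.3f}" if thr is not None else "      n/a"
            lines.append(
                f"{t:<12}{self.score.r[t]:7.3f} {thr_s}  "
                f"{'yes' if self.score.passes(t) else 'no'}"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None, n_frames: int = 500):
        """Overlay data and cross-validated prediction for a trace snippet."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = np.arange(min(n_frames, self.model.trace.size)) / self.model.frame_rate_hz
        ax.plot(t, self.model.trace[: t.size], lw=0.8, label="data")
        ax.plot(t, self.cv_prediction[: t.size], lw=0.8, label="model (CV)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("ΔF/F")
        ax.legend(frameon=False)
        return ax


# ---------------------------------------------------------------------------
# spec-surface wrappers and population-level operations
# ---------------------------------------------------------------------------

def fit_encoding_model(
    trace: np.ndarray,
    trials: list[Trial],
    frame_rate_hz: float,
    folds: int = 5,
    restarts: int = 3,
    seed: int | None = None,
) -> tuple[EncodingParams, EncodingScore]:
    """Fit the encoding model; returns (parameters, per-type scores)."""
    res = TouchEncodingModel(trace, trials, frame_rate_hz).fit(
        folds=folds, restarts=restarts, seed=seed
    )
    return res.params, res.score


def fit_interaction_terms(
    params: EncodingParams,
    trace: np.ndarray,
    trials: list[Trial],
    frame_rate_hz: float,
) -> tuple[EncodingParams, str | None]:
    """Fit the cross-whisker gains j on near-coincident multi-whisker trials.

    For trials where whisker 1 touched first, j_w1w2 scales the whole
    whisker-2 drive of that trial (and analogously for whisker 2 first).
    The prediction is linear in j, so each gain has a closed-form least
    squares solution, clipped to [0, 10].  Trials whose first two touches
    are >= 200 ms apart are excluded.  With no qualifying trials the gains
    stay at the neutral value 1 and a warning string is returned.
    """
    dt = 1.0 / frame_rate_hz
    kernel = gcamp_kernel(params.tau_rise, params.tau_decay, dt)
    groups: dict[int, list[Trial]] = {1: [], 2: []}
    for t in trials_of_type(trials, "multi"):
        _, first, interval_ms = classify_trial_type(t, frame_rate_hz)
        if first is not None and interval_ms is not None and interval_ms < MULTI_INTERVAL_MS:
            groups[first].append(t)
    new_j = {}
    for first, sel in groups.items():
        second = 2 if first == 1 else 1
        if not sel:
            new_j[first] = 1.0
            continue
        num = den = 0.0
        for t in sel:
            d = params.d.get(t.session_id, 1.0)
            a_first = whisker_drive(
                t.dkappa[first - 1], params.s_pro[first - 1], params.o_pro[first - 1],
                params.s_ret[first - 1], params.o_ret[first - 1],
            )
            a_second = whisker_drive(
                t.dkappa[second - 1], params.s_pro[second - 1], params.o_pro[second - 1],
                params.s_ret[second - 1], params.o_ret[second - 1],
            )
            base = d * np.convolve(a_first, kernel)[: t.n_frames]
            comp = d * np.convolve(a_second, kernel)[: t.n_frames]
            y = trace[t.frame_span[0] : t.frame_span[1]]
            num += float(comp @ (y - base))
            den += float(comp @ comp)
        new_j[first] = float(np.clip(num / den, *J_BOUNDS)) if den > 1e-12 else 1.0
    out = replace(
        params,
        s_pro=params.s_pro.copy(), s_ret=params.s_ret.copy(),
        o_pro=params.o_pro.copy(), o_ret=params.o_ret.copy(),
        d=dict(params.d),
        j_w1w2=new_j[1], j_w2w1=new_j[2],
    )
    warning = None
    if not groups[1] and not groups[2]:
        warning = "no multi-whisker trials with inter-touch interval < 200 ms"
        warnings.warn(warning, stacklevel=2)
    return out, warning


def calcium_event_frames(
    trace: np.ndarray, frame_rate_hz: float, sigma: float | None = None
) -> np.ndarray:
    """Onset frames of detected calcium events.

    An event is an upward crossing of 3σ (σ the half-normal noise scale
    from negative samples) with at least 1 s separation from the previous
    event onset.
    """
    if sigma is None:
        neg = trace[trace < 0]
        sigma = float(np.sqrt(np.mean(neg**2))) if neg.size else 0.0
    if sigma <= 0:
        return np.array([], dtype=int)
    above = trace > 3.0 * sigma
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    min_gap = int(round(frame_rate_hz))
    keep = []
    last = -np.inf
    for c in crossings:
        if c - last >= min_gap:
            keep.append(c)
            last = c
    return np.array(keep, dtype=int)


def calcium_event_rate(trace: np.ndarray, frame_rate_hz: float) -> float:
    """Calcium events per second over the whole trace."""
    n_events = calcium_event_frames(trace, frame_rate_hz).size
    return n_events / (trace.size / frame_rate_hz)


def shuffled_null_scores(
    neurons: list[NeuronRecord],
    trials: list[Trial],
    frame_rate_hz: float,
    n_bins: int = 10,
    folds: int = 5,
    seed: int | None = None,
    min_shift_s: float = 10.0,
) -> tuple[dict[int, dict[str, float]], dict[int, np.ndarray]]:
    """Shuffle-null thresholds for every neuron of one subvolume.

    One shuffled fit is run per neuron: the trace is circularly shifted by
    at least ``min_shift_s`` (about one trial length) while Δκ stays put,
    and the full cross-validated fit is repeated.  Neurons are grouped into
    ``n_bins`` equal-count bins by calcium event rate; each bin pools its
    members' per-type shuffled scores into one null set whose 99th
    percentile is the threshold for every neuron in the bin.

    Returns ``(thresholds, null_sets)`` keyed by neuron id; thresholds map
    touch type -> threshold (identical across types within a bin).
    """
    rng = np.random.default_rng(seed)
    if len(neurons) < n_bins:
        n_bins = max(len(neurons), 1)
    rates = np.array(
        [calcium_event_rate(nr.dff, frame_rate_hz) for nr in neurons]
    )
    order = np.argsort(rates, kind="stable")
    bins = np.array_split(order, n_bins)

    min_shift = int(round(min_shift_s * frame_rate_hz))
    shuffled_r: dict[int, list[float]] = {}
    for i, nr in enumerate(neurons):
        n = nr.dff.size
        shift = int(rng.integers(min_shift, max(n - min_shift, min_shift + 1)))
        shifted = np.roll(nr.dff, shift)
        try:
            _, score = fit_encoding_model(
                shifted, trials, frame_rate_hz, folds=folds, restarts=1,
                seed=int(rng.integers(2**31)),
            )
            shuffled_r[i] = [score.r[t] for t in TOUCH_TYPES]
        except (ValueError, DegenerateTraceError):
            shuffled_r[i] = [0.0] * len(TOUCH_TYPES)

    thresholds: dict[int, dict[str, float]] = {}
    null_sets: dict[int, np.ndarray] = {}
    for members in bins:
        pool = np.array([r for i in members for r in shuffled_r[i]])
        thr = float(np.percentile(pool, 99)) if pool.size else 0.0
        for i in members:
            nid = neurons[i].neuron_id
            thresholds[nid] = {t: thr for t in TOUCH_TYPES}
            null_sets[nid] = pool
    return thresholds, null_sets


def classify_neuron(score: EncodingScore) -> NeuronClass:
    """Touch-class label from the per-type pass flags.

    Exactly one passing type -> unidirectional single-whisker; both types
    of one whisker (and none of the other) -> bidirectional single-whisker;
    at least one passing type for each whisker -> multi-whisker, even if
    neither whisker passes bidirectionally; no passing type -> non-touch.
    """
    passing = set(score.passing_types)
    if not passing:
        return NeuronClass("non-touch")
    w1 = {t for t in passing if t.startswith("W1")}
    w2 = {t for t in passing if t.startswith("W2")}
    if w1 and w2:
        return NeuronClass("MW")
    only = w1 or w2
    whisker = 1 if w1 else 2
    if len(only) == 2:
        return NeuronClass("bSW", whisker=whisker)
    t = next(iter(only))
    direction = "protraction" if t.endswith("P") else "retraction"
    return NeuronClass("uSW", whisker=whisker, direction=direction)
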