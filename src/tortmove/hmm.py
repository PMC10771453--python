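"""Covariate-linked hidden Markov movement models for tortoise GPS tracks.

Observed movement metrics are the step length (straight-line distance
between consecutive 30-min fixes, metres) and the turning angle (change in
heading between consecutive steps, radians).  Step lengths are modelled with
a gamma distribution and turning angles with a zero-mean von Mises
distribution, both conditional on a latent behavioural state ("resting" or
"traveling") that evolves as a Markov chain.  State-dependent gamma mean and
SD use a log link on a linear predictor in the covariates; off-diagonal
transition probabilities use a logit link.

Covariate terms available on any component:

``hour``
    diel cycle, by default the cosinor pair cos(2*pi*h/24), sin(2*pi*h/24)
    counted as one term (a lone cosine would pin the activity peak to
    midnight; a single-cosine mode is available via ``single_cosine``)
``temperature``
    ambient temperature at the step's starting fix, deg C (z-scored
    internally when fitted)
``sex``
    0 = female, 1 = male
``log_dist``
    natural log of the perpendicular distance (m, floored at 1 m) from the
    step's starting fix to the highway line (z-scored internally)
``log_dist:sex``
    interaction of the two above
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize
from scipy.special import expit, gammaln, i0e, logit

__all__ = [
    "Track",
    "HmmSpec",
    "HmmParams",
    "HmmFit",
    "ModelTable",
    "derive_steps",
    "forward_loglik",
    "fit_hmm",
    "model_ladder",
    "predict_step_mean",
    "predict_transitions",
    "viterbi_decode",
    "read_fixes",
    "read_highway",
]

# canonical covariate term order
TERMS = ("hour", "temperature", "sex", "log_dist", "log_dist:sex")

STATE_NAMES = ("resting", "traveling")

#: step lengths below this are floored (stationary animal + GPS jitter),
#: keeping the strictly positive gamma support
STEP_FLOOR_M = 0.1

#: distances to the highway are floored here before taking the log
DIST_FLOOR_M = 1.0

#: segments are split at gaps exceeding 1.5x the nominal 30-min interval
DEFAULT_GAP_TOLERANCE_MIN = 45.0

SEX_CODE = {"female": 0, "male": 1}


# ---------------------------------------------------------------------------
# tracks and step derivation
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """One animal's ordered 30-min GPS fixes plus its sex label.

    ``fixes`` is a DataFrame with columns ``timestamp`` (UTC datetimes),
    ``x``, ``y`` (projected metres) and ``temperature`` (deg C).
    """

    animal_id: str
    sex: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODE:
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        f = self.fixes
        ts = pd.to_datetime(f["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(f"track {self.animal_id}: timestamps must be strictly increasing")
        if not (np.isfinite(f["x"]).all() and np.isfinite(f["y"]).all()):
            raise ValueError(f"track {self.animal_id}: non-finite coordinates")
        t = np.asarray(f["temperature"], dtype=float)
        if ((t < -20) | (t > 60)).any():
            raise ValueError(f"track {self.animal_id}: temperature outside [-20, 60] C")


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    w = np.mod(-np.asarray(a) + np.pi, 2 * np.pi)
    return -(w - np.pi)


def derive_steps(
    track: Track,
    highway=None,
    gap_tolerance: float = DEFAULT_GAP_TOLERANCE_MIN,
    step_floor: float = STEP_FLOOR_M,
) -> pd.DataFrame:
    """Derive step lengths, turning angles and covariates from a track.

    Parameters
    ----------
    track
        A validated :class:`Track`.
    highway
        A shapely line geometry in the same projection, or ``None`` (then
        ``log_dist`` is NaN).
    gap_tolerance
        Maximum inter-fix gap in minutes; larger gaps split the track into
        segments, and turning angles are undefined at segment starts.

    Returns
    -------
    DataFrame with one row per consecutive fix pair inside a segment:
    ``animal_id, segment_id, t_start, step, angle, hour, cos_hour, sin_hour,
    temperature, sex, log_dist``.  ``angle`` is NaN on each segment's first
    step.
    """
    f = track.fixes
    ts = pd.to_datetime(f["timestamp"]).to_numpy()
    x = np.asarray(f["x"], dtype=float)
    y = np.asarray(f["y"], dtype=float)
    temp = np.asarray(f["temperature"], dtype=float)
    n = len(x)
    if n < 2:
        warnings.warn(f"track {track.animal_id}: fewer than 2 fixes, no steps derived")
        return _empty_steps()

    gaps_min = np.diff(ts).astype("timedelta64[s]").astype(float) / 60.0
    # segment id of each *step* (fix pair); a step is dropped when its gap
    # exceeds the tolerance, starting a new segment at the next fix
    ok = gaps_min <= gap_tolerance + 1e-9
    seg_of_fix = np.concatenate([[0], np.cumsum(~ok)])

    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    heading = np.arctan2(dy, dx)

    rows = []
    for seg in np.unique(seg_of_fix):
        idx = np.flatnonzero(seg_of_fix == seg)
        if len(idx) < 2:
            continue
        first = idx[0]
        last = idx[-1]
        sl = np.maximum(step[first:last], step_floor)
        hd = heading[first:last]
        ang = np.concatenate([[np.nan], _wrap_angle(np.diff(hd))])
        t0 = ts[first:last]
        hours = (
            pd.DatetimeIndex(t0).hour.to_numpy()
            + pd.DatetimeIndex(t0).minute.to_numpy() / 60.0
        )
        if highway is not None:
            from shapely.geometry import Point

            dist = np.array(
                [highway.distance(Point(px, py)) for px, py in zip(x[first:last], y[first:last])]
            )
            ld = np.log(np.maximum(dist, DIST_FLOOR_M))
        else:
            ld = np.full(len(sl), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": track.animal_id,
                    "segment_id": f"{track.animal_id}/{seg}",
                    "t_start": t0,
                    "step": sl,
                    "angle": ang,
                    "hour": hours,
                    "cos_hour": np.cos(2 * np.pi * hours / 24.0),
                    "sin_hour": np.sin(2 * np.pi * hours / 24.0),
                    "temperature": temp[first:last],
                    "sex": SEX_CODE[track.sex],
                    "log_dist": ld,
                }
            )
        )
    if not rows:
        warnings.warn(f"track {track.animal_id}: no segment with 2+ fixes")
        return _empty_steps()
    return pd.concat(rows, ignore_index=True)


def _empty_steps() -> pd.DataFrame:
    cols = [
        "animal_id", "segment_id", "t_start", "step", "angle", "hour",
        "cos_hour", "sin_hour", "temperature", "sex", "log_dist",
    ]
    return pd.DataFrame({c: pd.Series(dtype=object if c in ("animal_id", "segment_id") else float) for c in cols})


def derive_steps_all(tracks, highway=None, **kw) -> pd.DataFrame:
    """Concatenate :func:`derive_steps` over several tracks."""
    frames = [derive_steps(t, highway, **kw) for t in tracks]
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_steps()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------

def _validate_terms(terms) -> tuple:
    terms = tuple(terms)
    for t in terms:
        if t not in TERMS:
            raise ValueError(f"unknown term {t!r}; valid: {TERMS}")
    if "log_dist:sex" in terms and not ("log_dist" in terms and "sex" in terms):
        raise ValueError("log_dist:sex requires both log_dist and sex terms")
    # canonical order, no duplicates
    return tuple(t for t in TERMS if t in terms)


@dataclass(frozen=True)
class HmmSpec:
    """Structure of a k-state movement HMM: which covariates enter where."""

    n_states: int = 2
    mean_terms: tuple = ()
    sd_terms: tuple = ()
    transition_terms: tuple = ()
    single_cosine: bool = False

    def __post_init__(self):
        if self.n_states not in (1, 2):
            raise ValueError("n_states must be 1 or 2")
        object.__setattr__(self, "mean_terms", _validate_terms(self.mean_terms))
        object.__setattr__(self, "sd_terms", _validate_terms(self.sd_terms))
        object.__setattr__(self, "transition_terms", _validate_terms(self.transition_terms))
        if self.n_states == 1 and self.transition_terms:
            raise ValueError("a one-state model has no transition formula")


def _term_columns(terms, single_cosine: bool):
    cols = ["1"]
    for t in terms:
        if t == "hour":
            cols += ["cos_hour"] if single_cosine else ["cos_hour", "sin_hour"]
        elif t == "temperature":
            cols += ["temperature"]
        elif t == "sex":
            cols += ["sex"]
        elif t == "log_dist":
            cols += ["log_dist"]
        elif t == "log_dist:sex":
            cols += ["log_dist:sex"]
    return cols


def _design(steps: pd.DataFrame, terms, centers, scales, single_cosine: bool) -> np.ndarray:
    """Design matrix (T, 1+p): intercept plus centred/scaled covariates."""
    T = len(steps)
    cols = [np.ones(T)]
    for t in terms:
        if t == "hour":
            cols.append(np.asarray(steps["cos_hour"], dtype=float))
            if not single_cosine:
                cols.append(np.asarray(steps["sin_hour"], dtype=float))
        elif t == "temperature":
            z = (np.asarray(steps["temperature"], dtype=float) - centers.get("temperature", 0.0)) / scales.get("temperature", 1.0)
            cols.append(z)
        elif t == "sex":
            cols.append(np.asarray(steps["sex"], dtype=float))
        elif t == "log_dist":
            z = (np.asarray(steps["log_dist"], dtype=float) - centers.get("log_dist", 0.0)) / scales.get("log_dist", 1.0)
            cols.append(z)
        elif t == "log_dist:sex":
            z = (np.asarray(steps["log_dist"], dtype=float) - centers.get("log_dist", 0.0)) / scales.get("log_dist", 1.0)
            cols.append(z * np.asarray(steps["sex"], dtype=float))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate values in design matrix (missing log_dist or temperature?)")
    return X


@dataclass
class HmmParams:
    """Full parameterisation of a k-state movement HMM.

    Coefficient vectors apply to design matrices built by :func:`_design`
    with the stored ``centers``/``scales`` (so a preset can use raw degC
    while a fitted model uses z-scores — the design machinery is identical).
    State 0 is "resting", state 1 "traveling".
    """

    spec: HmmSpec
    beta_mean: np.ndarray   # (k, 1+p_mean)  log link, metres per 30 min
    beta_sd: np.ndarray     # (k, 1+p_sd)    log link
    kappa: np.ndarray       # (k,)           von Mises concentration, >= 0
    alpha: np.ndarray       # (k*(k-1), 1+p_trans)  logit link; row 0: 1->2, row 1: 2->1
    centers: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)

    def __post_init__(self):
        k = self.spec.n_states
        self.beta_mean = np.atleast_2d(np.asarray(self.beta_mean, dtype=float))
        self.beta_sd = np.atleast_2d(np.asarray(self.beta_sd, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(k * (k - 1), -1) if k > 1 else np.zeros((0, 1))
        if self.beta_mean.shape[0] != k or self.beta_sd.shape[0] != k or self.kappa.shape[0] != k:
            raise ValueError("per-state parameter arrays must have k rows")
        if (self.kappa < 0).any():
            raise ValueError("kappa must be >= 0")

    @property
    def n_parameters(self) -> int:
        return self.beta_mean.size + self.beta_sd.size + self.kappa.size + self.alpha.size

    def emission_moments(self, steps: pd.DataFrame):
        """Per-observation gamma mean/SD arrays, each (T, k)."""
        Xm = _design(steps, self.spec.mean_terms, self.centers, self.scales, self.spec.single_cosine)
        Xs = _design(steps, self.spec.sd_terms, self.centers, self.scales, self.spec.single_cosine)
        mu = np.exp(np.clip(Xm @ self.beta_mean.T, -30, 30))
        sd = np.exp(np.clip(Xs @ self.beta_sd.T, -30, 30))
        return mu, sd

    def transition_matrices(self, steps: pd.DataFrame) -> np.ndarray:
        """Per-observation transition matrices Gamma(x_t), shape (T, k, k)."""
        k = self.spec.n_states
        T = len(steps)
        if k == 1:
            return np.ones((T, 1, 1))
        Xt = _design(steps, self.spec.transition_terms, self.centers, self.scales, self.spec.single_cosine)
        g12 = expit(Xt @ self.alpha[0])
        g21 = expit(Xt @ self.alpha[1])
        gam = np.empty((T, 2, 2))
        gam[:, 0, 0] = 1 - g12
        gam[:, 0, 1] = g12
        gam[:, 1, 0] = g21
        gam[:, 1, 1] = 1 - g21
        return gam

    def fingerprint(self) -> str:
        """SHA-256 hash of the full parameterisation (preset drift guard)."""
        import hashlib

        h = hashlib.sha256()
        h.update(repr(self.spec).encode())
        for a in (self.beta_mean, self.beta_sd, self.kappa, self.alpha):
            h.update(np.ascontiguousarray(a, dtype=float).tobytes())
        for d in (self.centers, self.scales):
            h.update(repr(sorted(d.items())).encode())
        return h.hexdigest()


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution of a single transition matrix."""
    k = gamma.shape[0]
    if k == 1:
        return np.ones(1)
    g12, g21 = gamma[0, 1], gamma[1, 0]
    s = g12 + g21
    if s <= 0:
        return np.full(2, 0.5)
    return np.array([g21 / s, g12 / s])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_kernel(logb, gamma, seg_start, delta):  # pragma: no cover - numba
    T, k = logb.shape
    ll = 0.0
    phi = np.empty(k)
    tmp = np.empty(k)
    for t in range(T):
        m = logb[t, 0]
        for j in range(1, k):
            if logb[t, j] > m:
                m = logb[t, j]
        if not np.isfinite(m):
            m = 0.0
        if seg_start[t]:
            for j in range(k):
                tmp[j] = delta[t, j] * np.exp(logb[t, j] - m)
        else:
            for j in range(k):
                s = 0.0
                for i in range(k):
                    s += phi[i] * gamma[t, i, j]
                tmp[j] = s * np.exp(logb[t, j] - m)
        c = 0.0
        for j in range(k):
            c += tmp[j]
        if not (c > 0.0) or not np.isfinite(c):
            return -np.inf
        for j in range(k):
            phi[j] = tmp[j] / c
        ll += np.log(c) + m
    return ll


def _gamma_logpdf(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Gamma log-density parameterised by mean and SD (x broadcast over states)."""
    a = (mu / sd) ** 2
    rate = a / mu
    xx = x[:, None]
    return a * np.log(rate) - gammaln(a) + (a - 1) * np.log(xx) - rate * xx


def _vonmises_logpdf(theta: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Zero-mean von Mises log-density; theta (T,), kappa (k,) -> (T, k)."""
    logi0 = np.log(i0e(kappa)) + kappa
    return kappa[None, :] * np.cos(theta)[:, None] - np.log(2 * np.pi) - logi0[None, :]


def _log_emissions(params: HmmParams, steps: pd.DataFrame) -> np.ndarray:
    mu, sd = params.emission_moments(steps)
    step = np.asarray(steps["step"], dtype=float)
    logb = _gamma_logpdf(step, mu, sd)
    angle = np.asarray(steps["angle"], dtype=float)
    defined = np.isfinite(angle)
    if defined.any():
        logb[defined] += _vonmises_logpdf(angle[defined], params.kappa)
    return logb


def _segment_layout(steps: pd.DataFrame):
    seg = np.asarray(steps["segment_id"])
    seg_start = np.zeros(len(seg), dtype=np.bool_)
    if len(seg):
        seg_start[0] = True
        seg_start[1:] = seg[1:] != seg[:-1]
    return seg_start


class _LikContext:
    """Precomputed arrays for repeated likelihood evaluations on one dataset."""

    def __init__(self, steps: pd.DataFrame, spec: HmmSpec, centers, scales):
        self.spec = spec
        self.step = np.asarray(steps["step"], dtype=float)
        self.log_step = np.log(self.step)
        angle = np.asarray(steps["angle"], dtype=float)
        self.defined = np.isfinite(angle)
        self.cos_angle = np.where(self.defined, np.cos(np.where(self.defined, angle, 0.0)), 0.0)
        self.Xm = _design(steps, spec.mean_terms, centers, scales, spec.single_cosine)
        self.Xs = _design(steps, spec.sd_terms, centers, scales, spec.single_cosine)
        self.Xt = (_design(steps, spec.transition_terms, centers, scales, spec.single_cosine)
                   if spec.n_states > 1 else None)
        self.seg_start = _segment_layout(steps)

    def loglik(self, params: HmmParams) -> float:
        k = self.spec.n_states
        mu = np.exp(np.clip(self.Xm @ params.beta_mean.T, -30, 30))
        sd = np.exp(np.clip(self.Xs @ params.beta_sd.T, -30, 30))
        a = (mu / sd) ** 2
        rate = a / mu
        logb = (a * np.log(rate) - gammaln(a)
                + (a - 1) * self.log_step[:, None] - rate * self.step[:, None])
        kap = params.kappa
        logi0 = np.log(i0e(kap)) + kap
        vm = kap[None, :] * self.cos_angle[:, None] - (np.log(2 * np.pi) + logi0)[None, :]
        logb = np.where(self.defined[:, None], logb + vm, logb)
        if k == 1:
            return float(logb.sum()) if np.isfinite(logb).all() else -np.inf
        g12 = expit(self.Xt @ params.alpha[0])
        g21 = expit(self.Xt @ params.alpha[1])
        T = len(self.step)
        gamma = np.empty((T, 2, 2))
        gamma[:, 0, 0] = 1 - g12
        gamma[:, 0, 1] = g12
        gamma[:, 1, 0] = g21
        gamma[:, 1, 1] = 1 - g21
        delta = np.empty((T, 2))
        s = g12 + g21
        with np.errstate(invalid="ignore", divide="ignore"):
            d0 = np.where(s > 0, g21 / np.where(s > 0, s, 1.0), 0.5)
        delta[:, 0] = d0
        delta[:, 1] = 1 - d0
        if not np.isfinite(gamma).all():
            return -np.inf
        return float(_forward_kernel(logb, gamma, self.seg_start, delta))


def forward_loglik(params: HmmParams, steps: pd.DataFrame) -> float:
    """HMM log-likelihood via the scaled forward recursion.

    The recursion renormalises at every step, so sequences of a full
    two-year deployment (35,040+ records) do not underflow.  Turning angles
    that are undefined (segment starts) contribute only their step-length
    density.  Invalid parameter evaluations return ``-inf`` rather than
    raising, so an optimizer can recover.
    """
    if len(steps) == 0:
        return 0.0
    try:
        logb = _log_emissions(params, steps)
        gamma = params.transition_matrices(steps)
    except (FloatingPointError, ValueError):
        return -np.inf
    if not np.isfinite(gamma).all():
        return -np.inf
    seg_start = _segment_layout(steps)
    k = params.spec.n_states
    delta = np.empty((len(steps), k))
    for t in np.flatnonzero(seg_start):
        delta[t] = stationary_distribution(gamma[t])
    return float(_forward_kernel(logb, gamma, seg_start, delta))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class HmmFit:
    """Maximum-likelihood fit of an :class:`HmmSpec`."""

    spec: HmmSpec
    params: HmmParams
    log_likelihood: float
    n_parameters: int
    aic: float
    se: np.ndarray | None            # packed working-scale SEs
    cov: np.ndarray | None           # packed working-scale covariance
    converged: bool
    degenerate: bool
    restart_diagnostics: list
    col_means: dict                  # data means of raw covariates (for "mean covariates")

    def to_dict(self) -> dict:
        return {
            "spec": {
                "n_states": self.spec.n_states,
                "mean_terms": list(self.spec.mean_terms),
                "sd_terms": list(self.spec.sd_terms),
                "transition_terms": list(self.spec.transition_terms),
                "single_cosine": self.spec.single_cosine,
            },
            "beta_mean": self.params.beta_mean.tolist(),
            "beta_sd": self.params.beta_sd.tolist(),
            "kappa": self.params.kappa.tolist(),
            "alpha": self.params.alpha.tolist(),
            "centers": self.params.centers,
            "scales": self.params.scales,
            "log_likelihood": self.log_likelihood,
            "n_parameters": self.n_parameters,
            "aic": self.aic,
            "se": None if self.se is None else self.se.tolist(),
            "converged": self.converged,
            "degenerate": self.degenerate,
            "col_means": self.col_means,
        }


def _pack(params: HmmParams) -> np.ndarray:
    return np.concatenate(
        [
            params.beta_mean.ravel(),
            params.beta_sd.ravel(),
            np.log(np.maximum(params.kappa, 1e-8)),
            params.alpha.ravel(),
        ]
    )


def _unpack(x: np.ndarray, template: HmmParams) -> HmmParams:
    k = template.spec.n_states
    nm = template.beta_mean.size
    ns = template.beta_sd.size
    i = 0
    bm = x[i:i + nm].reshape(template.beta_mean.shape); i += nm
    bs = x[i:i + ns].reshape(template.beta_sd.shape); i += ns
    kap = np.exp(np.clip(x[i:i + k], -20, 20)); i += k
    al = x[i:].reshape(template.alpha.shape) if k > 1 else np.zeros((0, 1))
    return HmmParams(template.spec, bm, bs, kap, al, dict(template.centers), dict(template.scales))


def _label_permutation(template: HmmParams):
    """Packed-index permutation that swaps states 0 and 1."""
    k = template.spec.n_states
    if k != 2:
        return None
    pm = template.beta_mean.shape[1]
    ps = template.beta_sd.shape[1]
    pt = template.alpha.shape[1]
    perm = []
    # beta_mean rows swapped
    perm += list(range(pm, 2 * pm)) + list(range(0, pm))
    off = 2 * pm
    perm += [off + j for j in range(ps, 2 * ps)] + [off + j for j in range(0, ps)]
    off += 2 * ps
    perm += [off + 1, off + 0]
    off += 2
    perm += [off + j for j in range(pt, 2 * pt)] + [off + j for j in range(0, pt)]
    return np.array(perm)


def _initial_params(steps: pd.DataFrame, spec: HmmSpec, centers, scales) -> HmmParams:
    """Moment-style starting values from a median split of step lengths."""
    step = np.asarray(steps["step"], dtype=float)
    k = spec.n_states
    pm = len(_term_columns(spec.mean_terms, spec.single_cosine))
    ps = len(_term_columns(spec.sd_terms, spec.single_cosine))
    pt = len(_term_columns(spec.transition_terms, spec.single_cosine))
    bm = np.zeros((k, pm))
    bs = np.zeros((k, ps))
    if k == 1:
        bm[0, 0] = np.log(step.mean())
        bs[0, 0] = np.log(max(step.std(), 0.1))
        al = np.zeros((0, 1))
    else:
        med = np.median(step)
        lo, hi = step[step <= med], step[step > med]
        bm[0, 0] = np.log(max(lo.mean(), STEP_FLOOR_M))
        bm[1, 0] = np.log(max(hi.mean(), STEP_FLOOR_M))
        bs[0, 0] = np.log(max(lo.std(), 0.5 * lo.mean(), 0.05))
        bs[1, 0] = np.log(max(hi.std(), 0.5 * hi.mean(), 0.05))
        al = np.zeros((2, pt))
        al[0, 0] = logit(0.1)
        al[1, 0] = logit(0.2)
    kap = np.full(k, 0.7)
    return HmmParams(spec, bm, bs, kap, al, centers, scales)


def fit_hmm(
    steps: pd.DataFrame,
    spec: HmmSpec,
    n_restarts: int = 10,
    seed: int = 0,
    compute_se: bool = True,
    maxiter: int = 500,
) -> HmmFit:
    """Fit a movement HMM by direct maximum likelihood.

    Quasi-Newton (L-BFGS-B) optimisation on the working scale (log links
    for gamma mean/SD and kappa, logit-linear transitions), with
    ``n_restarts`` jittered restarts from moment-based starting values.
    Temperature and log-distance covariates are z-scored internally; the
    centring constants are stored on the returned parameters.  After
    fitting, states are relabelled so the state with the larger fitted mean
    step at mean covariates is "traveling" (index 1).
    """
    if len(steps) == 0:
        raise ValueError("no steps to fit")
    centers, scales = {}, {}
    for name in ("temperature", "log_dist"):
        if any(name in t for t in spec.mean_terms + spec.sd_terms + spec.transition_terms):
            v = np.asarray(steps[name], dtype=float)
            if not np.isfinite(v).all():
                raise ValueError(f"covariate {name} has missing values")
            centers[name] = float(v.mean())
            scales[name] = float(v.std()) or 1.0

    template = _initial_params(steps, spec, centers, scales)
    x0_base = _pack(template)

    steps = steps.reset_index(drop=True)
    ctx = _LikContext(steps, spec, centers, scales)

    def nll(x):
        with np.errstate(all="ignore"):
            ll = ctx.loglik(_unpack(x, template))
        if not np.isfinite(ll):
            return 1e10
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    for r in range(n_restarts):
        x0 = x0_base.copy()
        if r > 0:
            x0 += rng.normal(0, 0.3, size=x0.shape)
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
        diagnostics.append(
            {"restart": r, "fun": float(res.fun), "success": bool(res.success),
             "nit": int(res.nit), "message": str(res.message)}
        )
        if res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"no restart converged to a valid optimum: {diagnostics}")

    x_hat = best.x.copy()
    # relabel: larger mean step at mean covariates -> state 1 ("traveling")
    col_means = {
        c: float(np.asarray(steps[c], dtype=float).mean())
        for c in ("cos_hour", "sin_hour", "temperature", "sex", "log_dist")
        if c in steps and np.isfinite(np.asarray(steps[c], dtype=float)).all()
    }
    if spec.n_states == 2:
        p_hat = _unpack(x_hat, template)
        row = _mean_design_row(p_hat, spec.mean_terms, col_means)
        mu = np.exp(row @ p_hat.beta_mean.T)
        if mu[0] > mu[1]:
            x_hat = x_hat[_label_permutation(template)]
        degenerate = bool(abs(mu[0] - mu[1]) / max(mu.max(), 1e-12) < 1e-3)
    else:
        degenerate = False

    params = _unpack(x_hat, template)
    ll = float(-best.fun)
    k_par = len(x_hat)
    aic = -2 * ll + 2 * k_par

    se = cov = None
    if compute_se:
        H = _numerical_hessian(nll, x_hat)
        with np.errstate(all="ignore"):
            cov = np.linalg.pinv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        se = np.sqrt(d)

    return HmmFit(
        spec=spec, params=params, log_likelihood=ll, n_parameters=k_par,
        aic=aic, se=se, cov=cov, converged=bool(best.success),
        degenerate=degenerate, restart_diagnostics=diagnostics,
        col_means=col_means,
    )


def _numerical_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    hs = h * (1 + np.abs(x))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = hs[i], hs[j]
            if i == j:
                fp = f(x + _e(n, i, xi))
                fm = f(x - _e(n, i, xi))
                H[i, i] = (fp - 2 * f0 + fm) / xi**2
            else:
                fpp = f(x + _e(n, i, xi) + _e(n, j, xj))
                fpm = f(x + _e(n, i, xi) - _e(n, j, xj))
                fmp = f(x - _e(n, i, xi) + _e(n, j, xj))
                fmm = f(x - _e(n, i, xi) - _e(n, j, xj))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * xi * xj)
    return H


def _e(n, i, h):
    v = np.zeros(n)
    v[i] = h
    return v


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _mean_design_row(params: HmmParams, terms, col_means: dict, overrides: dict | None = None) -> np.ndarray:
    """One design row at mean covariates (optionally overridden), centred/scaled."""
    ov = overrides or {}
    row = [1.0]
    for t in terms:
        if t == "hour":
            row.append(ov.get("cos_hour", col_means.get("cos_hour", 0.0)))
            if not params.spec.single_cosine:
                row.append(ov.get("sin_hour", col_means.get("sin_hour", 0.0)))
        elif t == "temperature":
            v = ov.get("temperature", col_means.get("temperature", params.centers.get("temperature", 0.0)))
            row.append((v - params.centers.get("temperature", 0.0)) / params.scales.get("temperature", 1.0))
        elif t == "sex":
            row.append(ov.get("sex", col_means.get("sex", 0.0)))
        elif t == "log_dist":
            v = ov.get("log_dist", col_means.get("log_dist", params.centers.get("log_dist", 0.0)))
            row.append((v - params.centers.get("log_dist", 0.0)) / params.scales.get("log_dist", 1.0))
        elif t == "log_dist:sex":
            v = ov.get("log_dist", col_means.get("log_dist", params.centers.get("log_dist", 0.0)))
            z = (v - params.centers.get("log_dist", 0.0)) / params.scales.get("log_dist", 1.0)
            row.append(z * ov.get("sex", col_means.get("sex", 0.0)))
    return np.array(row)


def predict_step_mean(fit, covariates="mean", sex=None, state="traveling", ci: bool = True):
    """Predicted mean step length (m / 30 min) for one state, with 95% CI.

    ``fit`` may be an :class:`HmmFit` (CI available when SEs were computed)
    or a bare :class:`HmmParams` (point estimate only).  ``covariates`` is
    ``"mean"`` or a dict of raw covariate values (``temperature``,
    ``log_dist``, ``cos_hour``, ``sin_hour``); ``sex`` (``"female"`` /
    ``"male"``) overrides the sex indicator.  The CI is a delta-method
    interval, symmetric on the log scale, hence strictly positive.
    """
    if isinstance(fit, HmmParams):
        params, cov, col_means = fit, None, {}
    else:
        params, cov, col_means = fit.params, fit.cov, fit.col_means
    s = STATE_NAMES.index(state) if isinstance(state, str) else int(state)
    if s >= params.spec.n_states:
        raise ValueError(f"state {state!r} out of range for k={params.spec.n_states}")
    overrides = {} if covariates == "mean" else dict(covariates)
    if sex is not None:
        overrides["sex"] = float(SEX_CODE[sex]) if isinstance(sex, str) else float(sex)
    row = _mean_design_row(params, params.spec.mean_terms, col_means, overrides)
    eta = float(row @ params.beta_mean[s])
    mean = math.exp(eta)
    if not ci or cov is None:
        return {"mean": mean, "lo": None, "hi": None}
    pm = params.beta_mean.shape[1]
    idx = np.arange(s * pm, (s + 1) * pm)
    var = float(row @ cov[np.ix_(idx, idx)] @ row)
    sd = math.sqrt(max(var, 0.0))
    return {"mean": mean, "lo": math.exp(eta - 1.96 * sd), "hi": math.exp(eta + 1.96 * sd)}


def predict_transitions(fit, covariates="mean") -> np.ndarray:
    """2x2 transition matrix Gamma(x) at the given (or mean) covariates."""
    if isinstance(fit, HmmParams):
        params, col_means = fit, {}
    else:
        params, col_means = fit.params, fit.col_means
    if params.spec.n_states != 2:
        raise ValueError("predict_transitions requires a 2-state model")
    overrides = {} if covariates == "mean" else dict(covariates)
    row = _mean_design_row(params, params.spec.transition_terms, col_means, overrides)
    g12 = float(expit(row @ params.alpha[0]))
    g21 = float(expit(row @ params.alpha[1]))
    return np.array([[1 - g12, g12], [g21, 1 - g21]])


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def viterbi_decode(fit, steps: pd.DataFrame) -> np.ndarray:
    """Most-likely latent state sequence (0 = resting, 1 = traveling)."""
    params = fit.params if isinstance(fit, HmmFit) else fit
    if isinstance(fit, HmmFit) and fit.degenerate:
        raise ValueError("refusing to decode a degenerate fit (states collapsed)")
    k = params.spec.n_states
    T = len(steps)
    if T == 0:
        return np.zeros(0, dtype=int)
    if k == 1:
        return np.zeros(T, dtype=int)
    steps = steps.reset_index(drop=True)
    logb = _log_emissions(params, steps)
    gamma = params.transition_matrices(steps)
    with np.errstate(divide="ignore"):
        loggam = np.log(gamma)
    seg_start = _segment_layout(steps)
    v = np.empty((T, k))
    back = np.zeros((T, k), dtype=int)
    for t in range(T):
        if seg_start[t]:
            with np.errstate(divide="ignore"):
                v[t] = np.log(stationary_distribution(gamma[t])) + logb[t]
        else:
            cand = v[t - 1][:, None] + loggam[t]
            back[t] = np.argmax(cand, axis=0)
            v[t] = cand[back[t], np.arange(k)] + logb[t]
    states = np.empty(T, dtype=int)
    t = T - 1
    states[t] = int(np.argmax(v[t]))
    for t in range(T - 2, -1, -1):
        if seg_start[t + 1]:
            states[t] = int(np.argmax(v[t]))
        else:
            states[t] = back[t + 1][states[t + 1]]
    return states


# ---------------------------------------------------------------------------
# model ladders
# ---------------------------------------------------------------------------

#: the seven biological covariate subsets, in the conventional table order
BIOLOGICAL_MODELS = (
    ("Hour + Temp + Sex", ("hour", "temperature", "sex")),
    ("Hour + Sex", ("hour", "sex")),
    ("Hour + Temp", ("hour", "temperature")),
    ("Hour", ("hour",)),
    ("Temp + Sex", ("temperature", "sex")),
    ("Sex", ("sex",)),
    ("Temp", ("temperature",)),
)

BIOL = ("hour", "temperature", "sex")
HWY = BIOL + ("log_dist",)
HWY_SEX = BIOL + ("log_dist", "log_dist:sex")

#: highway-extension ladder: label -> (mean/sd terms, transition terms)
HIGHWAY_MODELS = (
    ("Step (Biol + Hwy*Sex) + Transition (Biol + Hwy*Sex)", (HWY_SEX, HWY_SEX)),
    ("Step (Biol + Hwy) + Transition (Biol + Hwy)", (HWY, HWY)),
    ("Step (Biol + Hwy) + Transition (Biol)", (HWY, BIOL)),
    ("Step (Biol) + Transition (Biol + Hwy)", (BIOL, HWY)),
    ("Step (Biol) + Transition (Biol)", (BIOL, BIOL)),
)


@dataclass
class ModelTable:
    """AIC model-comparison table; rows sorted ascending by AIC."""

    table: pd.DataFrame            # columns: model, AIC, dAIC, converged
    fits: dict                     # label -> HmmFit (successful fits only)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def model_ladder(
    steps: pd.DataFrame,
    component: str = "steps",
    n_restarts: int = 3,
    seed: int = 0,
    maxiter: int = 300,
) -> ModelTable:
    """Fit and tabulate one of the model-selection ladders.

    ``component`` is one of:

    - ``"steps"``: the 7 biological covariate subsets on the gamma mean and
      SD (transitions held constant);
    - ``"transitions"``: the 7 subsets on the transition probabilities
      (mean/SD held at the full biological model);
    - ``"combined"``: the 7 subsets applied to both components at once;
    - ``"highway"`` (or ``"highway_extension"``): the 5-model ladder adding
      log(distance to highway) and its sex interaction to the best
      biological model.
    """
    if component in ("highway", "highway_extension"):
        members = [
            (label, HmmSpec(2, mean_terms=mt, sd_terms=mt, transition_terms=tt))
            for label, (mt, tt) in HIGHWAY_MODELS
        ]
    elif component in ("steps", "transitions", "combined"):
        members = []
        for label, terms in BIOLOGICAL_MODELS:
            if component == "steps":
                spec = HmmSpec(2, mean_terms=terms, sd_terms=terms, transition_terms=())
            elif component == "transitions":
                spec = HmmSpec(2, mean_terms=BIOL, sd_terms=BIOL, transition_terms=terms)
            else:
                spec = HmmSpec(2, mean_terms=terms, sd_terms=terms, transition_terms=terms)
            members.append((label, spec))
    else:
        raise ValueError(f"unknown ladder component {component!r}")

    rows, fits = [], {}
    for label, spec in members:
        try:
            fit = fit_hmm(steps, spec, n_restarts=n_restarts, seed=seed,
                          compute_se=False, maxiter=maxiter)
            rows.append({"model": label, "AIC": fit.aic, "converged": True})
            fits[label] = fit
        except (RuntimeError, ValueError) as exc:  # failed member kept, flagged
            warnings.warn(f"ladder member {label!r} failed: {exc}")
            rows.append({"model": label, "AIC": np.nan, "converged": False})
    tab = pd.DataFrame(rows)
    base = tab.loc[tab["converged"], "AIC"].min()
    tab["dAIC"] = tab["AIC"] - base
    tab = tab.sort_values("AIC", na_position="last").reset_index(drop=True)
    return ModelTable(table=tab[["model", "AIC", "dAIC", "converged"]], fits=fits)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_fixes(path) -> list:
    """Read a fixes CSV (`animal_id,timestamp,x,y,temperature`, plus an
    optional `sex` column) into a list of :class:`Track`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    tracks = []
    for aid, grp in df.groupby("animal_id", sort=True):
        sex = str(grp["sex"].iloc[0]) if "sex" in grp else "female"
        tracks.append(Track(str(aid), sex, grp.drop(columns=[c for c in ("animal_id", "sex") if c in grp]).reset_index(drop=True)))
    return tracks


def read_highway(path):
    """Read a highway line as WKT (.wkt) or a two-column x,y vertex CSV."""
    from shapely import wkt
    from shapely.geometry import LineString

    text = open(path).read().strip()
    if text.upper().startswith("LINESTRING"):
        return wkt.loads(text)
    df = pd.read_csv(path)
    return LineString(np.column_stack([df.iloc[:, 0], df.iloc[:, 1]]))
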