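"""The Epileptor neural field model.

The Epileptor is a phenomenological model of seizure dynamics with a
fast population (u1, u2) producing rapid discharges, an intermediate
population (q1, q2) producing the dominant ictal oscillations, and a
slow permittivity variable v steering the tissue into and out of the
seizure.  The field variant couples points on a cortical sheet through
an exponentially decaying kernel of geodesic distance,

    w(x, y) = alpha * exp(-d_g(x, y) / b),    alpha = 1 / (2 pi b^2),

applied to Heaviside-thresholded activity, so that recruited tissue
pulls its neighbourhood over the seizure threshold and a slow ictal
wavefront emerges, while the intermediate subsystem synchronises into
fast travelling waves.

Time is integrated in milliseconds with Heun's method (dt = 0.2 ms by
default); all public durations are expressed in seconds (1 s = 1000
model time units).  The memory kernel g is carried as a sixth state
variable obtained by differentiating its integral definition:

    dg/dt = a_12 u1 + gamma_12 (w * S(u1, theta_12)) - g / (tau_s tau_12).

Local excitability is set by the spatial parameter u0(x): tissue below
the critical value u0_crit rests in a stable fixed point (bistable
against perturbations for u0 > u0_ms), tissue above it seizes
autonomously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize, sparse

from .mesh import TriSurface, geodesic_distance_matrix, unique_edges

__all__ = [
    "EpileptorParams",
    "LocalKernel",
    "SimulationResult",
    "RegimeError",
    "build_local_kernel",
    "field_derivatives",
    "simulate_field",
    "single_node_fixed_point",
    "classify_excitability_regime",
    "find_critical_u0",
    "fast_subsystem_bistability",
    "find_ms_boundary",
    "recruitment_times",
    "onset_oscillation_frequency",
    "RECRUITMENT_THRESHOLD",
]

#: u1 level above which a vertex counts as recruited into the seizure
RECRUITMENT_THRESHOLD = -0.8


class RegimeError(RuntimeError):
    """Raised when an operation is attempted in the wrong dynamical regime."""


@dataclass
class EpileptorParams:
    """Constants of the Epileptor field model.

    Time constants are in model time units (ms); ``b`` and the kernel
    cutoff are in mm.  ``gamma_11`` sets the coupling of the fast
    subsystem and thereby the seizure spread velocity; it is the one
    parameter recalibrated per simulation (see
    :func:`epifield.analysis.calibrate_gamma11`).  ``tau_12`` sets the
    decay of the memory kernel g.
    """

    tau_s: float = 5.88
    tau_0: float = 20000.0
    tau_2: float = 100.0
    tau_12: float = 100.0
    I_1: float = 3.1
    I_2: float = 0.45
    a_12: float = 3.0
    gamma_11: float = 0.53
    gamma_12: float = 10.0
    gamma_22: float = 1.0
    theta_11: float = -1.0
    theta_12: float = -1.0
    theta_22: float = -0.5
    b: float = 1.0
    dt: float = 0.2
    u0_ez: float = -1.8
    u0_surround: float = -2.3

    def __post_init__(self):
        for name in ("tau_s", "tau_0", "tau_2", "tau_12", "dt", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "EpileptorParams":
        return replace(self, **kw)


@dataclass
class LocalKernel:
    """Discretised Laplacian coupling operator on a mesh.

    ``weights[i, j] = alpha * exp(-d_g(i, j) / b) * A_j`` for
    ``d_g <= cutoff``, including the self term ``alpha * A_i`` on the
    diagonal.  Applying the CSR matrix to a thresholded activity vector
    is the area-weighted quadrature of the convolution integral.
    """

    weights: sparse.csr_matrix
    b: float
    cutoff: float

    @property
    def alpha(self) -> float:
        return 1.0 / (2.0 * np.pi * self.b**2)


@dataclass
class SimulationResult:
    """Output of a field simulation.

    ``s = q1 - u1`` is the source activity projected to the sensors;
    ``u1`` (optional) supports recruitment maps; ``states`` (optional)
    holds all six variables.  Times are in seconds.
    """

    times: np.ndarray
    s: np.ndarray
    fs: float
    params: EpileptorParams
    u1: np.ndarray | None = None
    states: np.ndarray | None = None
    recruitment_threshold: float = RECRUITMENT_THRESHOLD
    meta: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.s.shape[1]


# ---------------------------------------------------------------------------
# kernel


def build_local_kernel(
    surface: TriSurface,
    b: float = 1.0,
    cutoff: float | None = None,
    method: str = "steiner",
    steiner_per_edge: int = 3,
) -> LocalKernel:
    """Build the sparse local coupling kernel on a mesh.

    ``cutoff`` defaults to ``6 b``, at which the truncated mass of the
    planar kernel is within 2% of unity.
    """
    if cutoff is None:
        cutoff = 6.0 * b
    edges = unique_edges(surface.triangles)
    mean_edge = float(
        np.mean(np.linalg.norm(surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]], axis=1))
    )
    if cutoff < mean_edge:
        raise ValueError(
            f"kernel cutoff {cutoff} mm below mean edge length {mean_edge:.3g} mm; "
            "the kernel would be diagonal-only"
        )
    if cutoff < 3 * b:
        warnings.warn(
            f"cutoff {cutoff} mm < 3 b truncates a non-negligible part of the kernel",
            stacklevel=2,
        )
    alpha = 1.0 / (2.0 * np.pi * b**2)
    D = geodesic_distance_matrix(surface, cutoff, method=method, steiner_per_edge=steiner_per_edge)
    A = surface.vertex_areas
    W = D.copy()
    W.data = alpha * np.exp(-D.data / b) * A[_csr_col_indices(D)]
    W = W + sparse.diags(alpha * A)
    return LocalKernel(W.tocsr(), b=b, cutoff=cutoff)


def _csr_col_indices(m: sparse.csr_matrix) -> np.ndarray:
    return m.indices


# ---------------------------------------------------------------------------
# right-hand side

# state layout (rows): u1, u2, v, q1, q2, g
U1, U2, V, Q1, Q2, G = range(6)


def field_derivatives(
    state: np.ndarray,
    params: EpileptorParams,
    kernel: LocalKernel | None,
    u0: np.ndarray,
) -> np.ndarray:
    """Time derivative of the full field state, shape (6, n_vertices).

    The Heaviside gate is closed (S = 1) exactly at threshold.  With
    ``kernel=None`` every vertex is an unconnected Epileptor.
    """
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state")
    p = params
    u1, u2, v, q1, q2, g = state
    if kernel is not None:
        # theta_11 == theta_12 in the stated parameter set shares one gate,
        # but keep the two gates distinct for generality
        s11 = (u1 >= p.theta_11).astype(float)
        c11 = kernel.weights @ s11
        if p.theta_12 == p.theta_11:
            c12 = c11
        else:
            c12 = kernel.weights @ (u1 >= p.theta_12).astype(float)
        c22 = kernel.weights @ (q1 >= p.theta_22).astype(float)
    else:
        c11 = c12 = c22 = 0.0

    f1 = np.where(u1 < 0, u1**3 - 3 * u1**2, (q1 - 0.6 * (v - 4.0) ** 2) * u1)
    f2 = np.where(q1 < -0.25, 0.0, 6.0 * (q1 + 0.25))

    out = np.empty_like(state)
    out[U1] = (u2 - f1 - v + p.I_1 + p.gamma_11 * c11) / p.tau_s
    out[U2] = (1.0 - 5.0 * u1**2 - u2) / p.tau_s
    out[V] = (4.0 * (u1 - u0) - v) / (p.tau_s * p.tau_0)
    out[Q1] = (
        -q2 + q1 - q1**3 + p.I_2 + 0.002 * g - 0.3 * (v - 3.5) + p.gamma_22 * c22
    ) / p.tau_s
    out[Q2] = (-q2 + f2) / (p.tau_s * p.tau_2)
    out[G] = p.a_12 * u1 + p.gamma_12 * c12 - g / (p.tau_s * p.tau_12)
    return out


# ---------------------------------------------------------------------------
# single-node machinery


def _uncoupled_rhs(z: np.ndarray, p: EpileptorParams, u0: float) -> np.ndarray:
    u1, u2, v, q1, q2, g = z
    f1 = u1**3 - 3 * u1**2 if u1 < 0 else (q1 - 0.6 * (v - 4.0) ** 2) * u1
    f2 = 0.0 if q1 < -0.25 else 6.0 * (q1 + 0.25)
    return np.array(
        [
            (u2 - f1 - v + p.I_1) / p.tau_s,
            (1.0 - 5.0 * u1**2 - u2) / p.tau_s,
            (4.0 * (u1 - u0) - v) / (p.tau_s * p.tau_0),
            (-q2 + q1 - q1**3 + p.I_2 + 0.002 * g - 0.3 * (v - 3.5)) / p.tau_s,
            (-q2 + f2) / (p.tau_s * p.tau_2),
            p.a_12 * u1 - g / (p.tau_s * p.tau_12),
        ]
    )


def _jacobian(z: np.ndarray, p: EpileptorParams, u0: float, eps: float = 1e-7) -> np.ndarray:
    J = np.empty((6, 6))
    f0 = _uncoupled_rhs(z, p, u0)
    for j in range(6):
        dz = z.copy()
        dz[j] += eps
        J[:, j] = (_uncoupled_rhs(dz, p, u0) - f0) / eps
    return J


def single_node_fixed_point(params: EpileptorParams, u0: float) -> np.ndarray:
    """Stable fixed point of the unconnected Epileptor, shape (6,).

    The u1 equation decouples at equilibrium into a monotone cubic with
    a single real root; the remaining variables follow in closed form
    except q1, which solves a piecewise cubic.  Raises
    :class:`RegimeError` when the fixed point is unstable (supercritical
    excitability): check the regime with
    :func:`classify_excitability_regime`.
    """
    p = params
    # u1^3 + 2 u1^2 + 4 u1 - (1 + I_1 + 4 u0) = 0
    roots = np.roots([1.0, 2.0, 4.0, -(1.0 + p.I_1 + 4.0 * u0)])
    u1 = float(roots[np.isreal(roots)].real[0])
    if u1 >= 0:
        raise RegimeError("fixed-point u1 is non-negative; outside the supported regime")
    u2 = 1.0 - 5.0 * u1**2
    v = 4.0 * (u1 - u0)
    g = p.tau_s * p.tau_12 * p.a_12 * u1
    c = p.I_2 + 0.002 * g - 0.3 * (v - 3.5)

    def hq(q1):
        f2 = 0.0 if q1 < -0.25 else 6.0 * (q1 + 0.25)
        return q1 - q1**3 - f2 + c

    qs = np.linspace(-6.0, 6.0, 2401)
    hv = np.array([hq(q) for q in qs])
    sign_change = np.flatnonzero(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0)
    candidates = []
    for i in sign_change:
        q1 = optimize.brentq(hq, qs[i], qs[i + 1], xtol=1e-14)
        q2 = 0.0 if q1 < -0.25 else 6.0 * (q1 + 0.25)
        candidates.append(np.array([u1, u2, v, q1, q2, g]))
    stable = []
    for z in candidates:
        if np.linalg.norm(_uncoupled_rhs(z, p, u0)) > 1e-10:
            z = optimize.fsolve(lambda x: _uncoupled_rhs(x, p, u0), z, full_output=False)
        if np.linalg.norm(_uncoupled_rhs(z, p, u0)) > 1e-10:
            continue
        eigs = np.linalg.eigvals(_jacobian(z, p, u0))
        if eigs.real.max() < 0:
            stable.append(z)
    if not stable:
        raise RegimeError(
            f"no stable fixed point at u0 = {u0}; the excitability is supercritical "
            "(check with classify_excitability_regime)"
        )
    return stable[0]


# ---------------------------------------------------------------------------
# numba scalar integrators


@njit(cache=False)
def _heun_scalar(z0, u0, tau_s, tau_0, tau_2, tau_12, I_1, I_2, a_12, dt, n_steps, stride):
    n_rec = n_steps // stride + 1
    rec = np.empty((n_rec, 6))
    z = z0.copy()
    d1 = np.empty(6)
    d2 = np.empty(6)
    zp = np.empty(6)
    rec[0] = z
    r = 1
    for step in range(1, n_steps + 1):
        for which in range(2):
            src = z if which == 0 else zp
            u1, u2, v, q1, q2, g = src[0], src[1], src[2], src[3], src[4], src[5]
            if u1 < 0.0:
                f1 = u1**3 - 3.0 * u1**2
            else:
                f1 = (q1 - 0.6 * (v - 4.0) ** 2) * u1
            f2 = 0.0 if q1 < -0.25 else 6.0 * (q1 + 0.25)
            d = d1 if which == 0 else d2
            d[0] = (u2 - f1 - v + I_1) / tau_s
            d[1] = (1.0 - 5.0 * u1**2 - u2) / tau_s
            d[2] = (4.0 * (u1 - u0) - v) / (tau_s * tau_0)
            d[3] = (-q2 + q1 - q1**3 + I_2 + 0.002 * g - 0.3 * (v - 3.5)) / tau_s
            d[4] = (-q2 + f2) / (tau_s * tau_2)
            d[5] = a_12 * u1 - g / (tau_s * tau_12)
            if which == 0:
                for i in range(6):
                    zp[i] = z[i] + dt * d1[i]
        for i in range(6):
            z[i] = z[i] + 0.5 * dt * (d1[i] + d2[i])
        if step % stride == 0:
            rec[r] = z
            r += 1
    return rec[:r]


@njit(cache=False)
def _heun_frozen_slow(z0, q2f, v0, v1, n_ramp, n_hold, tau_s, tau_12, I_1, I_2, a_12, dt):
    """Fast subsystem (u1, u2, q1, g) with v and q2 frozen.

    The frozen permittivity is ramped linearly from v0 to v1 over
    ``n_ramp`` steps (adiabatic continuation of the seizure oscillation,
    whose basin is vanishingly thin away from the attractor) and then
    held for ``n_hold`` steps.  Returns the step index of the last
    oscillation peak (u1 > 0) counted from the start of the hold phase,
    or a negative value if none occurred there.
    """
    u1, u2, q1, g = z0[0], z0[1], z0[3], z0[5]
    last_hi = -n_ramp - 1
    n = n_ramp + n_hold
    for i in range(n):
        vf = v0 + (v1 - v0) * min(i, n_ramp) / n_ramp
        if u1 < 0.0:
            f1 = u1**3 - 3.0 * u1**2
        else:
            f1 = (q1 - 0.6 * (vf - 4.0) ** 2) * u1
        da = (u2 - f1 - vf + I_1) / tau_s
        db = (1.0 - 5.0 * u1**2 - u2) / tau_s
        dc = (-q2f + q1 - q1**3 + I_2 + 0.002 * g - 0.3 * (vf - 3.5)) / tau_s
        de = a_12 * u1 - g / (tau_s * tau_12)
        u1p = u1 + dt * da
        u2p = u2 + dt * db
        q1p = q1 + dt * dc
        gp = g + dt * de
        if u1p < 0.0:
            f1p = u1p**3 - 3.0 * u1p**2
        else:
            f1p = (q1p - 0.6 * (vf - 4.0) ** 2) * u1p
        da2 = (u2p - f1p - vf + I_1) / tau_s
        db2 = (1.0 - 5.0 * u1p**2 - u2p) / tau_s
        dc2 = (-q2f + q1p - q1p**3 + I_2 + 0.002 * gp - 0.3 * (vf - 3.5)) / tau_s
        de2 = a_12 * u1p - gp / (tau_s * tau_12)
        u1 += 0.5 * dt * (da + da2)
        u2 += 0.5 * dt * (db + db2)
        q1 += 0.5 * dt * (dc + dc2)
        g += 0.5 * dt * (de + de2)
        if u1 > 0.0:
            last_hi = i - n_ramp
    return last_hi


def integrate_single_node(
    params: EpileptorParams,
    u0: float,
    duration: float,
    initial_state: np.ndarray,
    output_rate: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Heun integration of one unconnected Epileptor.

    ``duration`` in seconds; returns ``(times_s, states)`` with states of
    shape (n_times, 6).
    """
    p = params
    n_steps = int(round(duration * 1000.0 / p.dt))
    stride = max(1, int(round(1000.0 / (p.dt * output_rate))))
    rec = _heun_scalar(
        np.asarray(initial_state, dtype=float),
        u0, p.tau_s, p.tau_0, p.tau_2, p.tau_12, p.I_1, p.I_2, p.a_12,
        p.dt, n_steps, stride,
    )
    times = np.arange(len(rec)) * (p.dt * stride) / 1000.0
    return times, rec


# ---------------------------------------------------------------------------
# regime classification


def classify_excitability_regime(
    params: EpileptorParams,
    u0: float,
    duration: float = 60.0,
    transient: float = 30.0,
    tol: float = 1e-3,
) -> str:
    """Classify the unconnected Epileptor at excitability ``u0``.

    Integrates ``duration`` seconds from the resting state (the stable
    fixed point at ``u0`` when it exists, otherwise the fixed point of
    the surround excitability) and tests the u1 oscillation amplitude in
    the window after ``transient`` seconds.  Returns ``"fixed_point"``
    or ``"oscillatory"``.
    """
    try:
        z0 = single_node_fixed_point(params, u0)
    except RegimeError:
        z0 = single_node_fixed_point(params, params.u0_surround)
    times, rec = integrate_single_node(params, u0, duration, z0, output_rate=200.0)
    late = rec[times >= transient, U1]
    amp = float(late.max() - late.min())
    return "oscillatory" if amp > tol else "fixed_point"


def find_critical_u0(
    params: EpileptorParams,
    bracket: tuple[float, float] = (-2.5, -1.5),
    xtol: float = 1e-3,
    **classify_kw,
) -> float:
    """Bisect the boundary between resting and seizing excitability."""
    lo, hi = bracket
    c_lo = classify_excitability_regime(params, lo, **classify_kw)
    c_hi = classify_excitability_regime(params, hi, **classify_kw)
    if c_lo == c_hi:
        raise ValueError(f"bracket endpoints both classify as {c_lo}")
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if classify_excitability_regime(params, mid, **classify_kw) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _seizure_state(params: EpileptorParams, settle: float = 3.0) -> np.ndarray:
    """Full state of an unconnected supercritical Epileptor mid-seizure."""
    key = ("seizure_state", params.u0_ez, settle)
    cache = _seizure_state.__dict__.setdefault("cache", {})
    pkey = (key, tuple(sorted(params.__dict__.items())))
    if pkey in cache:
        return cache[pkey]
    z0 = single_node_fixed_point(params, params.u0_surround)
    times, rec = integrate_single_node(params, params.u0_ez, 30.0, z0, output_rate=1000.0)
    on = np.flatnonzero(rec[:, U1] >= RECRUITMENT_THRESHOLD)
    if not on.size:
        raise RegimeError("supercritical excitability did not produce a seizure")
    i = min(on[0] + int(settle * 1000), len(rec) - 1)
    cache[pkey] = rec[i].copy()
    return cache[pkey]


def fast_subsystem_bistability(
    params: EpileptorParams,
    u0: float,
    ramp_rate: float = 0.004,
    hold: float = 30.0,
) -> str:
    """Monostable vs bistable fast subsystem at the frozen slow state.

    The slow variables -- the permittivity v and the slow intermediate
    variable q2 -- are frozen at their values in the full-system fixed
    point at excitability ``u0``; the remaining fast equations
    (u1, u2, q1, g) are integrated from a seizure state.  Because the
    oscillation's basin is extremely thin away from the attractor, the
    frozen v is ramped adiabatically (``ramp_rate`` per second of model
    time) from the seizure working point to its target before the hold
    window is evaluated.  Returns ``"bistable"`` when the seizure
    oscillation coexists with the stable fixed point, ``"monostable"``
    when it collapses.  Raises :class:`RegimeError` above the critical
    excitability, where no stable fixed point exists.
    """
    z = single_node_fixed_point(params, u0)  # raises RegimeError above u0_crit
    p = params
    zic = _seizure_state(p)
    v0 = float(zic[V])
    v1 = float(z[V])
    ramp_time = max(abs(v1 - v0) / ramp_rate, 1.0)  # seconds of model time
    n_ramp = int(round(ramp_time * 1000.0 / p.dt))
    n_hold = int(round(hold * 1000.0 / p.dt))
    last = _heun_frozen_slow(
        zic, float(z[Q2]), v0, v1, n_ramp, n_hold,
        p.tau_s, p.tau_12, p.I_1, p.I_2, p.a_12, p.dt,
    )
    # sustained iff an oscillation peak occurs in the second half of the hold
    return "bistable" if last * p.dt / 1000.0 > hold / 2.0 else "monostable"


def find_ms_boundary(
    params: EpileptorParams,
    bracket: tuple[float, float] = (-3.5, -2.5),
    xtol: float = 1e-3,
    **kw,
) -> float:
    """Bisect the monostable/bistable boundary of the frozen fast subsystem."""
    lo, hi = bracket
    c_lo = fast_subsystem_bistability(params, lo, **kw)
    c_hi = fast_subsystem_bistability(params, hi, **kw)
    if c_lo == c_hi:
        raise ValueError(f"bracket endpoints both classify as {c_lo}")
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if fast_subsystem_bistability(params, mid, **kw) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def onset_oscillation_frequency(
    params: EpileptorParams,
    u0: float | None = None,
    n_intervals: int = 3,
    duration: float = 20.0,
) -> float:
    """Discharge frequency (Hz) of an unconnected Epileptor at seizure onset.

    Integrates one unconnected node at supercritical excitability
    (default ``u0_ez``) from the surround fixed point and returns the
    mean rate of the first ``n_intervals`` discharge cycles after onset
    (upward zero crossings of u1).  The discharge rate accelerates as
    the seizure matures -- it roughly doubles within two seconds as the
    trajectory leaves the saddle-node ghost -- so the frequency *at*
    onset is the initial inter-discharge interval, not the spectral
    peak over a longer window.
    """
    p = params
    if u0 is None:
        u0 = p.u0_ez
    z0 = single_node_fixed_point(p, p.u0_surround)
    fs = 5000.0
    times, rec = integrate_single_node(p, u0, duration, z0, output_rate=fs)
    u1 = rec[:, U1]
    if not np.any(u1 >= RECRUITMENT_THRESHOLD):
        raise RegimeError(f"no seizure onset within {duration} s at u0 = {u0}")
    ups = np.flatnonzero((u1[1:] > 0.0) & (u1[:-1] <= 0.0))
    if len(ups) < n_intervals + 1:
        raise RegimeError("too few discharge cycles to estimate the onset frequency")
    isi = np.diff(times[ups[: n_intervals + 1]])
    return float(1.0 / isi.mean())


# ---------------------------------------------------------------------------
# field simulation


@njit(cache=False)
def _field_chunk(
    z, c11, c22, g1, g2,
    indptr, indices, data,
    u0, tau_s, tau_0, tau_2, tau_12,
    I_1, I_2, a_12, g11c, g12c, g22c, th11, th22,
    dt, n_sub,
    zp, d1, d2, c11p, c22p, g1p, g2p,
):
    """Advance the field by ``n_sub`` Heun steps in place.

    The coupling sums c11 = W @ S(u1, th11) and c22 = W @ S(q1, th22)
    are maintained incrementally: a Heaviside gate flips only a few
    times per discharge cycle, so adding/subtracting the corresponding
    CSC column of W on each flip replaces the full matvec.  ``g1``/``g2``
    are the current gate vectors (uint8).  Scratch arrays are passed in
    to avoid per-call allocation.  Returns max |u1|.
    """
    n = z.shape[1]
    for _ in range(n_sub):
        # d1 = rhs(z) using the maintained c11/c22
        for i in range(n):
            u1 = z[0, i]; u2 = z[1, i]; v = z[2, i]
            q1 = z[3, i]; q2 = z[4, i]; g = z[5, i]
            if u1 < 0.0:
                f1 = u1**3 - 3.0 * u1**2
            else:
                f1 = (q1 - 0.6 * (v - 4.0) ** 2) * u1
            f2 = 0.0 if q1 < -0.25 else 6.0 * (q1 + 0.25)
            d1[0, i] = (u2 - f1 - v + I_1 + g11c * c11[i]) / tau_s
            d1[1, i] = (1.0 - 5.0 * u1**2 - u2) / tau_s
            d1[2, i] = (4.0 * (u1 - u0[i]) - v) / (tau_s * tau_0)
            d1[3, i] = (-q2 + q1 - q1 ** 3 + I_2 + 0.002 * g
                        - 0.3 * (v - 3.5) + g22c * c22[i]) / tau_s
            d1[4, i] = (-q2 + f2) / (tau_s * tau_2)
            d1[5, i] = a_12 * u1 + g12c * c11[i] - g / (tau_s * tau_12)
            for k in range(6):
                zp[k, i] = z[k, i] + dt * d1[k, i]
        # predictor coupling sums: start from current, apply gate flips
        for i in range(n):
            c11p[i] = c11[i]
            c22p[i] = c22[i]
        for j in range(n):
            gp = 1 if zp[0, j] >= th11 else 0
            g1p[j] = gp
            if gp != g1[j]:
                sgn = 1.0 if gp == 1 else -1.0
                for k in range(indptr[j], indptr[j + 1]):
                    c11p[indices[k]] += sgn * data[k]
            qp = 1 if zp[3, j] >= th22 else 0
            g2p[j] = qp
            if qp != g2[j]:
                sgn = 1.0 if qp == 1 else -1.0
                for k in range(indptr[j], indptr[j + 1]):
                    c22p[indices[k]] += sgn * data[k]
        # d2 = rhs(zp), corrector
        for i in range(n):
            u1 = zp[0, i]; u2 = zp[1, i]; v = zp[2, i]
            q1 = zp[3, i]; q2 = zp[4, i]; g = zp[5, i]
            if u1 < 0.0:
                f1 = u1**3 - 3.0 * u1**2
            else:
                f1 = (q1 - 0.6 * (v - 4.0) ** 2) * u1
            f2 = 0.0 if q1 < -0.25 else 6.0 * (q1 + 0.25)
            d2[0, i] = (u2 - f1 - v + I_1 + g11c * c11p[i]) / tau_s
            d2[1, i] = (1.0 - 5.0 * u1**2 - u2) / tau_s
            d2[2, i] = (4.0 * (u1 - u0[i]) - v) / (tau_s * tau_0)
            d2[3, i] = (-q2 + q1 - q1 ** 3 + I_2 + 0.002 * g
                        - 0.3 * (v - 3.5) + g22c * c22p[i]) / tau_s
            d2[4, i] = (-q2 + f2) / (tau_s * tau_2)
            d2[5, i] = a_12 * u1 + g12c * c11p[i] - g / (tau_s * tau_12)
            for k in range(6):
                z[k, i] += 0.5 * dt * (d1[k, i] + d2[k, i])
        # refresh gates and coupling sums for the updated state
        for j in range(n):
            gn = 1 if z[0, j] >= th11 else 0
            if gn != g1[j]:
                sgn = 1.0 if gn == 1 else -1.0
                for k in range(indptr[j], indptr[j + 1]):
                    c11[indices[k]] += sgn * data[k]
                g1[j] = gn
            qn = 1 if z[3, j] >= th22 else 0
            if qn != g2[j]:
                sgn = 1.0 if qn == 1 else -1.0
                for k in range(indptr[j], indptr[j + 1]):
                    c22[indices[k]] += sgn * data[k]
                g2[j] = qn
    m = 0.0
    for i in range(n):
        a = abs(z[0, i])
        if a > m:
            m = a
    return m


def simulate_field(
    surface: TriSurface,
    params: EpileptorParams,
    u0map,
    duration: float,
    output_rate: float = 256.0,
    record_full_state: bool = False,
    record_u1: bool = True,
    kernel: LocalKernel | None = None,
    early_stop=None,
    initial_state: np.ndarray | None = None,
) -> SimulationResult:
    """Deterministic Heun integration of the Epileptor field on a mesh.

    The field starts in the stable fixed point of the unconnected
    Epileptor at the surround excitability everywhere (supercritical
    vertices then drift into seizure on their own); no input enters from
    outside the patch.  ``u0map`` is a per-vertex excitability array or
    an object with a ``values`` attribute.  ``early_stop(t, state)`` is
    evaluated at output samples and terminates the run when it returns
    True.

    Source activity ``s = q1 - u1`` is stored at ``output_rate``
    (rounded to a whole number of dt steps; the achieved rate is in
    ``result.fs``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = params
    u0 = np.asarray(getattr(u0map, "values", u0map), dtype=float)
    if u0.shape != (surface.n_vertices,):
        raise ValueError("u0 map does not match the vertex count")
    if kernel is None:
        kernel = build_local_kernel(surface, b=p.b)

    if initial_state is None:
        z0 = single_node_fixed_point(p, p.u0_surround)
        state = np.tile(z0[:, None], (1, surface.n_vertices))
    else:
        state = np.array(initial_state, dtype=float, copy=True)

    if p.theta_12 != p.theta_11:
        raise NotImplementedError(
            "the integrator shares the u1 gate between the gamma_11 and gamma_12 "
            "terms, which requires theta_12 == theta_11 (as in the stated "
            "parameter set)"
        )

    dt = p.dt
    n_steps = int(round(duration * 1000.0 / dt))
    stride = max(1, int(round(1000.0 / (dt * output_rate))))
    fs = 1000.0 / (dt * stride)
    n_rec = n_steps // stride + 1
    n = surface.n_vertices

    csc = kernel.weights.tocsc()
    indptr = csc.indptr
    indices = csc.indices
    data = csc.data

    g1 = (state[U1] >= p.theta_11).astype(np.uint8)
    g2 = (state[Q1] >= p.theta_22).astype(np.uint8)
    c11 = kernel.weights @ g1.astype(float)
    c22 = kernel.weights @ g2.astype(float)
    zp = np.empty_like(state)
    d1 = np.empty_like(state)
    d2 = np.empty_like(state)
    c11p = np.empty(n)
    c22p = np.empty(n)
    g1p = np.empty(n, dtype=np.uint8)
    g2p = np.empty(n, dtype=np.uint8)

    s_rec = np.empty((n_rec, n))
    u1_rec = np.empty((n_rec, n)) if record_u1 else None
    full_rec = np.empty((n_rec, 6, n)) if record_full_state else None

    def record(r, z):
        s_rec[r] = z[Q1] - z[U1]
        if u1_rec is not None:
            u1_rec[r] = z[U1]
        if full_rec is not None:
            full_rec[r] = z

    record(0, state)
    r = 1
    stopped = False
    done = 0
    while done < n_steps:
        n_sub = min(stride, n_steps - done)
        u1max = _field_chunk(
            state, c11, c22, g1, g2,
            indptr, indices, data,
            u0, p.tau_s, p.tau_0, p.tau_2, p.tau_12,
            p.I_1, p.I_2, p.a_12,
            p.gamma_11, p.gamma_12, p.gamma_22, p.theta_11, p.theta_22,
            dt, n_sub,
            zp, d1, d2, c11p, c22p, g1p, g2p,
        )
        done += n_sub
        t_s = done * dt / 1000.0
        if u1max > 50.0 or not np.isfinite(u1max):
            raise FloatingPointError(f"field diverged (|u1| > 50) at t = {t_s:.3f} s")
        if done % stride == 0:
            record(r, state)
            r += 1
            if early_stop is not None and early_stop(t_s, state):
                stopped = True
                break

    times = np.arange(r) * (dt * stride) / 1000.0
    return SimulationResult(
        times=times,
        s=s_rec[:r],
        fs=fs,
        params=p,
        u1=u1_rec[:r] if u1_rec is not None else None,
        states=full_rec[:r] if full_rec is not None else None,
        meta={"early_stopped": stopped, "n_vertices": surface.n_vertices},
    )


def recruitment_times(
    result: SimulationResult, threshold: float = RECRUITMENT_THRESHOLD
) -> np.ndarray:
    """Per-vertex time (s) of the first u1 crossing above ``threshold``.

    Vertices that never cross are NaN.  Requires the u1 recording.
    """
    if result.u1 is None and result.states is None:
        raise ValueError("u1 was not recorded; rerun with record_u1=True")
    u1 = result.u1 if result.u1 is not None else result.states[:, U1, :]
    above = u1 >= threshold
    first = np.argmax(above, axis=0)
    ever = above.any(axis=0)
    out = np.where(ever, result.times[first], np.nan)
    return out
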