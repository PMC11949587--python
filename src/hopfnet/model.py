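"""The Hopf (Stuart-Landau) whole-brain model.

Each brain region i carries a Hopf normal-form oscillator with complex state
z_i = x_i + i y_i, natural frequency omega_i and a shared excitability
(bifurcation) parameter lambda. Regions interact through a sigmoidal function
of the weighted sum of the other regions' real parts:

    dz_i/dt = z_i (lambda + i omega_i - |z_i|^2)
              + K tanh( C sum_j w_ij x_j )

K is the global coupling strength, C a global scaling of the (unitless)
structural connectome. For lambda > 0 an isolated node (K = 0) settles on a
stable limit cycle of radius sqrt(lambda); for lambda < 0 it decays to rest.
The real parts x_i(t) play the role of simulated MEG signals.

The phase dynamics of the coupled system depends, for lambda well above the
bifurcation, essentially only on the normalized coupling strength
k = K / sqrt(lambda); `rescaled_equivalent` maps parameters along these
invariance curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._integrator import hopf_rhs, integrate_hopf
from .connectome import ConnectomeMatrix
from .errors import IntegrationError, ValidationError

DEFAULT_C = 20.0


@dataclass(frozen=True)
class ModelParameters:
    """Global parameters of the coupled Hopf system.

    Parameters
    ----------
    K : float
        Global coupling strength, >= 0 (dimensionless).
    lambda_ : float
        Global excitability (Hopf bifurcation) parameter.
    omega : np.ndarray
        Angular natural frequencies, rad/s, one per region, all > 0.
    C : float
        Global scaling of the structural connectome (> 0, default 20; the
        goodness of fit is insensitive to C once it is large enough).
    coupling_gain : np.ndarray or None
        Optional per-region multiplicative gain on the coupling input,
        used to model regionally elevated coupling influence (all >= 0,
        default None = uniform gain 1).
    """

    K: float
    lambda_: float
    omega: np.ndarray
    C: float = DEFAULT_C
    coupling_gain: np.ndarray | None = None

    def __post_init__(self):
        if self.K < 0:
            raise ValidationError("coupling strength K must be >= 0")
        if self.C <= 0:
            raise ValidationError("connectome scaling C must be > 0")
        omega = np.asarray(self.omega, dtype=float)
        if omega.ndim != 1 or np.any(omega <= 0):
            raise ValidationError("omega must be a 1-D vector of positive rad/s values")
        object.__setattr__(self, "omega", omega)
        if self.coupling_gain is not None:
            g = np.asarray(self.coupling_gain, dtype=float)
            if g.shape != omega.shape or np.any(g < 0):
                raise ValidationError("coupling_gain must be length-N and nonnegative")
            object.__setattr__(self, "coupling_gain", g)

    @property
    def n_regions(self) -> int:
        return self.omega.shape[0]


@dataclass(frozen=True)
class SimulationSettings:
    """Integration and sampling settings.

    Defaults follow the study protocol: 14.5 s of simulation at a 1250 Hz
    output rate with the first second discarded as transient, integrated by
    adaptive RK45 at absolute tolerance 1e-6 and relative tolerance 1e-3.
    """

    duration_s: float = 14.5
    burn_in_s: float = 1.0
    fs_hz: float = 1250.0
    abs_tol: float = 1e-6
    rel_tol: float = 1e-3

    def __post_init__(self):
        if not self.duration_s > self.burn_in_s > 0:
            raise ValidationError("need duration_s > burn_in_s > 0")
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be positive")


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Uniformly sampled multichannel real signals (T samples x N regions)."""

    values: np.ndarray
    fs_hz: float
    labels: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.labels):
            raise ValidationError(
                f"values must be T x {len(self.labels)}, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("time series contains non-finite samples")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def drift(z: np.ndarray, params: ModelParameters, W: ConnectomeMatrix) -> np.ndarray:
    """Right-hand side dz/dt of the coupled Hopf system at state z."""
    z = np.asarray(z, dtype=complex)
    if z.shape != (params.n_regions,):
        raise ValidationError(f"state must have length {params.n_regions}")
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite oscillator state")
    u = np.concatenate([z.real, z.imag])
    gain = params.coupling_gain
    if gain is None:
        gain = np.ones(params.n_regions)
    du = hopf_rhs(u, W.W, params.omega, float(params.K), float(params.lambda_),
                  float(params.C), gain)
    n = params.n_regions
    return du[:n] + 1j * du[n:]


def sample_initial_conditions(n: int, n_regions: int, seed: int) -> list[np.ndarray]:
    """Draw n random complex initial states, reproducibly.

    Real and imaginary parts are independent uniform on [-1, 1] — bounded,
    unbiased and scale-neutral across the excitability range.
    """
    if n < 1:
        raise ValidationError("need n >= 1 initial conditions")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(-1.0, 1.0, size=(n, 2, n_regions))
    return [draws[i, 0] + 1j * draws[i, 1] for i in range(n)]


def _output_grid(settings: SimulationSettings) -> np.ndarray:
    dt = 1.0 / settings.fs_hz
    n_out = int(round((settings.duration_s - settings.burn_in_s) * settings.fs_hz))
    return settings.burn_in_s + dt * np.arange(n_out)


def simulate_states(
    params: ModelParameters,
    W: ConnectomeMatrix,
    ic: np.ndarray,
    settings: SimulationSettings = SimulationSettings(),
) -> np.ndarray:
    """Integrate the model and return complex states z(t) on the output grid.

    The adaptive RK45 solution is interpolated onto a uniform grid at
    ``settings.fs_hz``; the first ``burn_in_s`` seconds are discarded.
    """
    N = params.n_regions
    if W.n_regions != N:
        raise ValidationError("connectome size does not match omega length")
    ic = np.asarray(ic, dtype=complex)
    if ic.shape != (N,):
        raise ValidationError(f"initial condition must have length {N}")
    if settings.fs_hz <= params.omega.max() / np.pi:
        raise ValidationError("sampling rate below Nyquist for max natural frequency")
    gain = params.coupling_gain
    if gain is None:
        gain = np.ones(N)
    u0 = np.concatenate([ic.real, ic.imag])
    t_out = _output_grid(settings)
    out, status, t_fail = integrate_hopf(
        u0, 0.0, float(settings.duration_s), t_out,
        W.W, params.omega, float(params.K), float(params.lambda_), float(params.C),
        gain, float(settings.rel_tol), float(settings.abs_tol),
    )
    if status != 0:
        reason = "non-finite state" if status == 1 else "step size underflow"
        raise IntegrationError(f"integration failed at t={t_fail:.6g} s: {reason}",
                               t_fail=t_fail)
    return out[:, :N] + 1j * out[:, N:]


def simulate(
    params: ModelParameters,
    W: ConnectomeMatrix,
    ic: np.ndarray,
    settings: SimulationSettings = SimulationSettings(),
) -> TimeSeriesPanel:
    """Simulate the model and return the real parts x_i(t) (the MEG proxy)."""
    z = simulate_states(params, W, ic, settings)
    return TimeSeriesPanel(values=z.real, fs_hz=settings.fs_hz,
                           labels=W.atlas.labels)


def origin_max_real_eigenvalue(
    params: ModelParameters,
    W: ConnectomeMatrix,
    eps: float = 1e-7,
) -> float:
    """Largest real part of the eigenvalues of the drift linearized at z = 0.

    The Jacobian is computed by central finite differences of :func:`drift`
    in real coordinates, so the result reflects the full coupled system. For
    an isolated node (K = 0) the linearization has eigenvalues
    lambda +- i omega, so the origin changes stability exactly at lambda = 0
    (the Hopf bifurcation).
    """
    N = params.n_regions
    n = 2 * N

    def f(u: np.ndarray) -> np.ndarray:
        dz = drift(u[:N] + 1j * u[N:], params, W)
        return np.concatenate([dz.real, dz.imag])

    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = eps
        J[:, j] = (f(e) - f(-e)) / (2 * eps)
    return float(np.max(np.linalg.eigvals(J).real))


def write_timeseries(ts: TimeSeriesPanel, path, meta: dict | None = None) -> None:
    """Write a panel as TSV (labeled columns) plus a JSON sidecar (fs_hz, meta)."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    pd.DataFrame(ts.values, columns=list(ts.labels)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    sidecar = {"fs_hz": ts.fs_hz, **(meta or {})}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_timeseries(path) -> TimeSeriesPanel:
    """Read a TSV panel written by :func:`write_timeseries`."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return TimeSeriesPanel(values=df.to_numpy(dtype=float), fs_hz=float(meta["fs_hz"]),
                           labels=tuple(str(c) for c in df.columns))


def normalized_coupling(K: float, lambda_: float) -> float:
    """Normalized coupling strength k = K / sqrt(lambda)."""
    if lambda_ <= 0:
        raise ValidationError("normalized coupling requires lambda > 0")
    return K / np.sqrt(lambda_)


def rescaled_equivalent(params: ModelParameters, lambda_target: float) -> ModelParameters:
    """Map parameters to a different excitability along the invariance curve.

    Returns parameters with lambda = lambda_target and K scaled as
    K' = K sqrt(lambda_target / lambda) so that the normalized coupling
    strength k = K / sqrt(lambda) is preserved; omega, C and any coupling
    gain are unchanged.
    """
    if params.lambda_ <= 0 or lambda_target <= 0:
        raise ValidationError("rescaling requires positive excitability values")
    K_new = params.K * np.sqrt(lambda_target / params.lambda_)
    return replace(params, K=K_new, lambda_=lambda_target)


def rescaled_initial_condition(ic: np.ndarray, lambda_from: float, lambda_to: float) -> np.ndarray:
    """Scale a complex initial state by sqrt(lambda_to / lambda_from).

    Matches initial conditions across excitability levels so that rescaled
    parameter pairs start at corresponding points relative to their limit
    cycles (radius sqrt(lambda)).
    """
    if lambda_from <= 0 or lambda_to <= 0:
        raise ValidationError("rescaling requires positive excitability values")
    return np.asarray(ic, dtype=complex) * np.sqrt(lambda_to / lambda_from)
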