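"""Functional connectotomy: masking tumor regions out of the fit objective.

The procedure quantifies how much a set of (tumor) regions contributes to
the global phase dynamics: at fixed excitability (lambda = 40 by default),
the optimal coupling strength is found twice per initial condition — once
against the full PLI matrices and once with the tumor regions' rows and
columns removed from both the empirical and simulated matrices. The regions
are never removed from the dynamical model itself; only the objective
changes. A drop in optimal K after masking means the masked regions were
pushing the fit toward stronger coupling.

Each patient run is paired with a control run: the same mask, the same
initial conditions and the same simulations, but fit against the healthy
control-average PLI. The per-initial-condition difference of changes
(delta K_patient - delta K_control) is the outcome measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectomeMatrix, TumorMask
from .errors import ValidationError
from .fitting import goodness_of_fit, simulate_pli
from .model import SimulationSettings, sample_initial_conditions
from .spectral import PLIMatrix

DEFAULT_LAMBDA_FIXED = 40.0


@dataclass(frozen=True)
class ConnectotomyHalf:
    """One arm (patient or control) of a connectotomy comparison."""

    subject_id: str
    mask: TumorMask
    lambda_fixed: float
    K_grid: np.ndarray
    ic_seed: int
    K_before: np.ndarray  # (n_ic,)
    K_after: np.ndarray  # (n_ic,)
    # simulated PLIs [i_K][i_ic], kept so the control arm can reuse them
    sim_plis: list = field(repr=False, default=None)

    @property
    def delta(self) -> np.ndarray:
        """Change in optimal coupling strength per initial condition."""
        return self.K_after - self.K_before

    @property
    def n_ic(self) -> int:
        return len(self.K_before)


@dataclass(frozen=True)
class ConnectotomyOutcome:
    """Seed-paired patient and control connectotomy arms."""

    patient: ConnectotomyHalf
    control: ConnectotomyHalf

    def __post_init__(self):
        p, c = self.patient, self.control
        if p.ic_seed != c.ic_seed or p.n_ic != c.n_ic:
            raise ValidationError("patient and control arms must share seeds")
        if p.mask.regions != c.mask.regions:
            raise ValidationError("patient and control arms must share the mask")

    @property
    def paired_differences(self) -> np.ndarray:
        """delta K_patient - delta K_control, per initial condition."""
        return self.patient.delta - self.control.delta


def _simulate_table(
    W: ConnectomeMatrix,
    omega: np.ndarray,
    K_grid: np.ndarray,
    lambda_fixed: float,
    ics: list[np.ndarray],
    settings: SimulationSettings,
    C: float,
) -> list[list[PLIMatrix]]:
    return [
        [simulate_pli(float(K), lambda_fixed, W, omega, ic, settings, C) for ic in ics]
        for K in K_grid
    ]


def _optimal_K(
    sim_plis: list[list[PLIMatrix]],
    K_grid: np.ndarray,
    emp: PLIMatrix,
    exclude: frozenset[int],
) -> np.ndarray:
    n_ic = len(sim_plis[0])
    r = np.empty((len(K_grid), n_ic))
    for ik in range(len(K_grid)):
        for ii in range(n_ic):
            r[ik, ii] = goodness_of_fit(sim_plis[ik][ii], emp, exclude)
    return K_grid[np.argmax(r, axis=0)]  # first argmax = smallest K on ties


def connectotomy_refit(
    emp: PLIMatrix,
    mask: TumorMask,
    W: ConnectomeMatrix,
    omega: np.ndarray,
    K_grid: np.ndarray,
    lambda_fixed: float = DEFAULT_LAMBDA_FIXED,
    n_ic: int = 100,
    seed: int = 0,
    settings: SimulationSettings = SimulationSettings(),
    C: float = 20.0,
    subject_id: str | None = None,
    sim_plis: list | None = None,
) -> ConnectotomyHalf:
    """Optimal K before and after masking, per initial condition.

    The same simulated PLI per (K, initial condition) is used for both the
    full and the masked objective — the mask affects only which matrix
    entries the Pearson objective sees, never the simulation. ``sim_plis``
    may be passed to reuse simulations (e.g. between the patient and control
    arm); it must have been generated with the same grids, seed and settings.
    """
    if lambda_fixed <= 0:
        raise ValidationError("connectotomy requires lambda_fixed > 0")
    K_grid = np.asarray(K_grid, dtype=float)
    if np.any(np.diff(K_grid) <= 0):
        raise ValidationError("K grid must be strictly increasing")
    n_keep = W.n_regions - len(mask.regions)
    if n_keep < 3:
        raise ValidationError(
            f"mask leaves {n_keep} regions; the objective needs >= 3"
        )
    ics = sample_initial_conditions(n_ic, W.n_regions, seed)
    if sim_plis is None:
        sim_plis = _simulate_table(W, omega, K_grid, lambda_fixed, ics, settings, C)
    K_before = _optimal_K(sim_plis, K_grid, emp, frozenset())
    K_after = _optimal_K(sim_plis, K_grid, emp, frozenset(mask.regions))
    return ConnectotomyHalf(
        subject_id=subject_id or mask.subject_id,
        mask=mask,
        lambda_fixed=lambda_fixed,
        K_grid=K_grid,
        ic_seed=seed,
        K_before=K_before,
        K_after=K_after,
        sim_plis=sim_plis,
    )


def pair_with_control(
    patient_half: ConnectotomyHalf,
    control_emp: PLIMatrix,
    W: ConnectomeMatrix,
    omega: np.ndarray,
    settings: SimulationSettings = SimulationSettings(),
    C: float = 20.0,
) -> ConnectotomyOutcome:
    """Run the identical connectotomy against the control-average PLI.

    Reuses the patient arm's simulations (same connectome, mask, K grid and
    initial-condition seeds), so the two arms are exactly paired.
    """
    if patient_half.sim_plis is None:
        raise ValidationError("patient arm carries no simulations to reuse")
    control_half = connectotomy_refit(
        control_emp,
        patient_half.mask,
        W,
        omega,
        patient_half.K_grid,
        lambda_fixed=patient_half.lambda_fixed,
        n_ic=patient_half.n_ic,
        seed=patient_half.ic_seed,
        settings=settings,
        C=C,
        subject_id=f"control[{patient_half.subject_id}]",
        sim_plis=patient_half.sim_plis,
    )
    return ConnectotomyOutcome(patient=patient_half, control=control_half)
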