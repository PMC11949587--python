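"""Synthetic study inputs: connectomes, frequencies, cohorts with known truth.

The empirical MEG/dMRI cohorts this pipeline was designed around are not
publicly available, so every input is emulated with known ground truth:

* a nonnegative, symmetric, connected weighted connectome (Erdos-Renyi
  topology, log-normal weights, centroids in a unit sphere);
* alpha-band regional natural frequencies (uniform on 9-11 Hz by default);
* "empirical" PLI matrices generated by the model itself at known
  (K*, lambda*), averaged over epochs from distinct initial conditions,
  with truncated Gaussian observation noise;
* a two-cohort design in which patients carry a tumor mask whose regions
  receive an elevated coupling gain g > 1 (regionally increased influence
  of interregional interactions) and/or a higher global coupling K*.

Every draw is derived from a single master seed, so cohorts are exactly
reproducible and each subject can be regenerated bit-identically from its
recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .connectome import (
    ConnectomeMatrix,
    RegionAtlas,
    TumorMask,
    read_atlas,
    read_connectome,
    read_tumor_masks,
    write_atlas,
    write_connectome,
    write_tumor_masks,
)
from .errors import GenerationError, ValidationError
from .model import ModelParameters, SimulationSettings, sample_initial_conditions, simulate
from .spectral import PLIMatrix, epoch_average_pli, pli_from_timeseries, read_pli, write_pli

_MAX_CONNECT_RETRIES = 50
_SEED_MOD = 2**31 - 1


def _child_seed(master_seed: int, *tags) -> int:
    """Deterministic child seed below 2**31 derived from the master seed."""
    import hashlib

    digest = hashlib.sha256(repr(tags).encode()).digest()
    tag_int = int.from_bytes(digest[:4], "little") % _SEED_MOD
    h = np.random.SeedSequence([int(master_seed) % _SEED_MOD, tag_int])
    return int(h.generate_state(1)[0] % _SEED_MOD)


def make_connectome(
    N: int = 20,
    density: float = 0.3,
    seed: int = 0,
    weight_sigma: float = 1.0,
) -> ConnectomeMatrix:
    """Random connected weighted connectome with spatial centroids.

    Edges follow an Erdos-Renyi model at the given density with log-normal
    weights; the graph is resampled (bounded retries) until connected.
    Region centroids are drawn uniformly in the unit sphere so spatial
    clustering of region subsets is meaningful.
    """
    if not 0 < density <= 1:
        raise ValidationError("edge density must be in (0, 1]")
    if N < 4:
        raise ValidationError("need at least 4 regions")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_CONNECT_RETRIES):
        iu = np.triu_indices(N, k=1)
        present = rng.random(len(iu[0])) < density
        weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=len(iu[0]))
        W = np.zeros((N, N))
        W[iu] = present * weights
        W = W + W.T
        n_comp, _ = connected_components((W > 0).astype(int), directed=False)
        if n_comp == 1:
            break
    else:
        raise GenerationError(
            f"could not draw a connected graph at density {density} in "
            f"{_MAX_CONNECT_RETRIES} tries"
        )
    # centroids uniform in the unit sphere
    direction = rng.normal(size=(N, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = rng.random(N) ** (1 / 3)
    centroids = direction * radius[:, None]
    labels = tuple(f"roi_{i:02d}" for i in range(N))
    atlas = RegionAtlas(labels=labels, centroids=centroids)
    return ConnectomeMatrix(W=W, atlas=atlas)


def make_natural_frequencies(
    N: int,
    band_hz: tuple[float, float] = (9.0, 11.0),
    seed: int = 0,
) -> np.ndarray:
    """Angular natural frequencies with peak frequencies uniform in a band.

    The default 9-11 Hz band emulates regional alpha peak frequencies.
    Returns rad/s values (2 pi times the peak frequency in Hz).
    """
    low, high = band_hz
    if not 4.0 < low <= high:
        raise ValidationError("frequency band must satisfy 4 < low <= high (Hz)")
    rng = np.random.default_rng(seed)
    peaks_hz = rng.uniform(low, high, size=N) if high > low else np.full(N, low)
    return 2 * np.pi * peaks_hz


def make_empirical_pli(
    W: ConnectomeMatrix,
    omega: np.ndarray,
    K_true: float,
    lambda_true: float,
    epochs: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    tumor_mask: TumorMask | None = None,
    gain: float = 1.0,
    settings: SimulationSettings = SimulationSettings(),
    C: float = 20.0,
) -> tuple[PLIMatrix, dict]:
    """Ground-truth "empirical" PLI generated by the model itself.

    Simulates ``epochs`` runs from distinct seeded initial conditions at
    (K_true, lambda_true), epoch-averages the PLI, and adds symmetric
    Gaussian entry noise truncated to [0, 1]. If a tumor mask is given with
    gain g > 1, the coupling input of the masked regions is multiplied by g.

    Returns the PLI matrix and a ground-truth record sufficient to regenerate
    it bit-identically.
    """
    if epochs < 1:
        raise ValidationError("need at least one epoch")
    if gain < 1.0:
        raise ValidationError("tumor coupling gain must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise sd must be >= 0")
    coupling_gain = None
    if tumor_mask is not None and gain != 1.0:
        coupling_gain = np.ones(W.n_regions)
        coupling_gain[sorted(tumor_mask.regions)] = gain
    params = ModelParameters(K=K_true, lambda_=lambda_true, omega=omega, C=C,
                             coupling_gain=coupling_gain)
    ics = sample_initial_conditions(epochs, W.n_regions, seed)
    plis = [
        pli_from_timeseries(simulate(params, W, ic, settings), source="empirical")
        for ic in ics
    ]
    pli = epoch_average_pli(plis)
    values = pli.values
    if noise_sd > 0:
        rng = np.random.default_rng(_child_seed(seed, "obs-noise"))
        iu = np.triu_indices(W.n_regions, k=1)
        noise = rng.normal(0.0, noise_sd, size=len(iu[0]))
        noisy = values.copy()
        noisy[iu] = np.clip(noisy[iu] + noise, 0.0, 1.0)
        noisy.T[iu] = noisy[iu]
        values = noisy
    truth = {
        "K_true": float(K_true),
        "lambda_true": float(lambda_true),
        "epochs": int(epochs),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
        "gain": float(gain),
        "tumor_regions": sorted(tumor_mask.regions) if tumor_mask else None,
        "C": float(C),
    }
    return PLIMatrix(values=values, labels=W.atlas.labels, source="empirical"), truth


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of a synthetic two-cohort study.

    Defaults match the package's reference study conditions: 20 regions,
    ground truth (K* = 8, lambda* = 40), 3 epochs per subject, observation
    noise sd 0.02, tumor masks of 2-4 regions with coupling gain 1.5.
    """

    N: int = 20
    n_controls: int = 3
    n_patients: int = 2
    K_control: float = 8.0
    K_patient: float = 8.0
    lambda_true: float = 40.0
    tumor_size_range: tuple[int, int] = (2, 4)
    tumor_gain: float = 1.5
    epochs: int = 3
    noise_sd: float = 0.02
    density: float = 0.3
    band_hz: tuple[float, float] = (9.0, 11.0)
    seed: int = 0
    C: float = 20.0

    def __post_init__(self):
        if self.N < 4:
            raise ValidationError("need N >= 4 regions")
        if self.tumor_gain < 1.0:
            raise ValidationError("tumor gain must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        lo, hi = self.tumor_size_range
        if not 1 <= lo <= hi < self.N:
            raise ValidationError("invalid tumor size range")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: shared substrate plus per-subject PLIs and truth."""

    spec: SyntheticCohortSpec
    connectome: ConnectomeMatrix
    omega: np.ndarray
    plis: dict[str, PLIMatrix]
    masks: dict[str, TumorMask]  # patients only
    truth: dict[str, dict]

    @property
    def control_ids(self) -> list[str]:
        return sorted(s for s in self.plis if s.startswith("control"))

    @property
    def patient_ids(self) -> list[str]:
        return sorted(s for s in self.plis if s.startswith("patient"))

    def control_average_pli(self) -> PLIMatrix:
        return epoch_average_pli([self.plis[s] for s in self.control_ids])


def make_cohort(
    spec: SyntheticCohortSpec,
    settings: SimulationSettings = SimulationSettings(),
) -> SyntheticCohort:
    """Generate a full two-cohort dataset from a master seed."""
    conn = make_connectome(spec.N, spec.density, _child_seed(spec.seed, "connectome"))
    omega = make_natural_frequencies(spec.N, spec.band_hz, _child_seed(spec.seed, "omega"))
    plis: dict[str, PLIMatrix] = {}
    masks: dict[str, TumorMask] = {}
    truth: dict[str, dict] = {}
    for i in range(spec.n_controls):
        sid = f"control_{i:02d}"
        pli, rec = make_empirical_pli(
            conn, omega, spec.K_control, spec.lambda_true, spec.epochs,
            spec.noise_sd, _child_seed(spec.seed, "subject", sid),
            settings=settings, C=spec.C,
        )
        plis[sid], truth[sid] = pli, rec
    mask_rng = np.random.default_rng(_child_seed(spec.seed, "masks"))
    for i in range(spec.n_patients):
        sid = f"patient_{i:02d}"
        size = int(mask_rng.integers(spec.tumor_size_range[0],
                                     spec.tumor_size_range[1] + 1))
        regions = frozenset(
            int(r) for r in mask_rng.choice(spec.N, size=size, replace=False)
        )
        mask = TumorMask(subject_id=sid, regions=regions, n_regions=spec.N)
        pli, rec = make_empirical_pli(
            conn, omega, spec.K_patient, spec.lambda_true, spec.epochs,
            spec.noise_sd, _child_seed(spec.seed, "subject", sid),
            tumor_mask=mask, gain=spec.tumor_gain, settings=settings, C=spec.C,
        )
        plis[sid], masks[sid], truth[sid] = pli, mask, rec
    return SyntheticCohort(spec=spec, connectome=conn, omega=omega,
                           plis=plis, masks=masks, truth=truth)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write a cohort as a directory of CSV/JSON files."""
    directory = Path(directory)
    (directory / "subjects").mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.connectome.atlas, directory / "atlas.csv")
    write_connectome(cohort.connectome, directory / "connectome.csv")
    pd.DataFrame({
        "label": list(cohort.connectome.atlas.labels),
        "peak_hz": cohort.omega / (2 * np.pi),
    }).to_csv(directory / "omega.csv", index=False, float_format="%.17g")
    for sid, pli in cohort.plis.items():
        write_pli(pli, directory / "subjects" / f"{sid}.csv")
    write_tumor_masks(cohort.masks, cohort.connectome.atlas, directory / "masks.json")
    meta = {"spec": asdict(cohort.spec), "truth": cohort.truth}
    (directory / "truth.json").write_text(json.dumps(meta, indent=1))


def load_cohort(directory: str | Path) -> SyntheticCohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    atlas = read_atlas(directory / "atlas.csv")
    conn = read_connectome(directory / "connectome.csv", atlas)
    freq = pd.read_csv(directory / "omega.csv", float_precision="round_trip")
    omega = 2 * np.pi * freq["peak_hz"].to_numpy(dtype=float)
    meta = json.loads((directory / "truth.json").read_text())
    raw_spec = meta["spec"]
    for key in ("tumor_size_range", "band_hz"):
        raw_spec[key] = tuple(raw_spec[key])
    spec = SyntheticCohortSpec(**raw_spec)
    plis = {
        p.stem: read_pli(p, labels=atlas.labels)
        for p in sorted((directory / "subjects").glob("*.csv"))
    }
    masks = read_tumor_masks(directory / "masks.json", atlas)
    return SyntheticCohort(spec=spec, connectome=conn, omega=omega,
                           plis=plis, masks=masks, truth=meta["truth"])
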