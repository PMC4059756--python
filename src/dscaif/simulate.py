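"""Synthetic DSC-MRI bolus-passage simulator.

Builds a population of per-voxel signal–time curves with known ground truth,
emulating a single-slice dynamic susceptibility contrast acquisition:

* a "true" arterial input function (AIF) modelled as a gamma-variate first
  passage plus a delayed, exponentially dispersed recirculation,
* "false" arterial curves (delayed/dispersed copies, as seen in veins and
  distal vessels),
* tissue curves for normal grey matter, pathological grey matter and white
  matter obtained by tracer-kinetic convolution of the AIF with a residue
  function (central volume theorem: CBF = CBV/MTT),
* partial-volume (PVE) voxels mixing arterial and tissue *signals* with a
  random weight,
* Gaussian noise on a random subset of curves at a prescribed SNR.

Concentration curves are converted to MR signal through the standard
exponential T2* relationship S(t) = S0·exp(−k·C(t)·TE), with k calibrated so
that the mean normal-grey-matter signal dips 40% below baseline — the
amplitude regime typical of clinical bolus-tracking data.

The default configuration is the study condition used throughout the test
suite: 6 true arterial + 16 false arterial + 440 normal GM + 440 pathological
GM + 600 WM + 400 PVE voxels, 90 s at 1 s sampling, noise on 100 curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats

__all__ = [
    "TimeGrid",
    "AifModelParams",
    "TissueClassSpec",
    "AcquisitionParams",
    "NoiseSpec",
    "VoxelLabel",
    "SimulationConfig",
    "SyntheticDataset",
    "gamma_variate",
    "gamma_variate_peak",
    "make_true_aif",
    "make_false_aifs",
    "residue_function",
    "tissue_concentration",
    "calibrate_k",
    "concentration_to_signal",
    "mix_pve",
    "add_noise",
    "build_dataset",
]

TRUE_ARTERIAL = "true_arterial"
FALSE_ARTERIAL = "false_arterial"
NORMAL_GM = "normal_GM"
PATH_GM = "path_GM"
WM = "WM"
PVE_MIX = "pve_mix"


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition time axis.

    ``times`` runs from ``start`` in steps of ``dt`` for ``duration`` seconds
    (endpoint excluded), so the default grid is t = 0, 1, …, 89 s.
    """

    start: float = 0.0
    duration: float = 90.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("duration and dt must be positive")
        if self.n_points < 2:
            raise ValueError("grid needs at least two samples")

    @property
    def n_points(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n_points)

    def upsampled(self, dt: float) -> "TimeGrid":
        return TimeGrid(self.start, self.duration, dt)


@dataclass(frozen=True)
class AifModelParams:
    """Gamma-variate bolus parameters.

    t0           tracer arrival time [s]
    a            inflow-steepness exponent (dimensionless)
    b            washout time scale [s]
    recirc_delay delay of the recirculation copy [s]
    recirc_tau   time constant of the dispersing exponential [s]
    recirc_kernel  'unit_area' normalises the exponential to unit area
                   (1/τ)·e^(−t/τ); 'raw' uses e^(−t/τ) directly.
    """

    t0: float = 26.0
    a: float = 3.0
    b: float = 1.5
    recirc_delay: float = 8.0
    recirc_tau: float = 30.0
    recirc_kernel: str = "unit_area"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.recirc_tau <= 0:
            raise ValueError("a, b and recirc_tau must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        if self.recirc_kernel not in ("unit_area", "raw"):
            raise ValueError("recirc_kernel must be 'unit_area' or 'raw'")


@dataclass(frozen=True)
class TissueClassSpec:
    """One tissue compartment: CBV [ml/100 g], MTT mean±SD [s], voxel count."""

    name: str
    cbv: float
    mtt_mean: float
    mtt_sd: float
    count: int

    def __post_init__(self) -> None:
        if self.cbv <= 0 or self.mtt_mean <= 0 or self.mtt_sd < 0:
            raise ValueError("cbv and mtt_mean must be positive, mtt_sd >= 0")


DEFAULT_TISSUES = (
    TissueClassSpec(NORMAL_GM, cbv=4.0, mtt_mean=4.0, mtt_sd=0.33, count=440),
    TissueClassSpec(PATH_GM, cbv=3.3, mtt_mean=10.0, mtt_sd=0.7, count=440),
    TissueClassSpec(WM, cbv=2.0, mtt_mean=5.45, mtt_sd=0.33, count=600),
)


@dataclass(frozen=True)
class AcquisitionParams:
    """Signal model parameters: baseline S0 [a.u.], echo time TE [s], and the
    concentration→ΔR2* proportionality k [1/(concentration·s)]."""

    s0: float = 100.0
    te: float = 0.030
    k_const: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.te <= 0 or self.k_const <= 0:
            raise ValueError("s0, te and k_const must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: SD = S0/SNR, applied to ``n_noisy_curves``
    rows chosen without replacement."""

    snr: float = 20.0
    n_noisy_curves: int = 100

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_noisy_curves < 0:
            raise ValueError("n_noisy_curves must be non-negative")


@dataclass(frozen=True)
class VoxelLabel:
    """Ground-truth class of one voxel; ``mix_weight`` is the arterial signal
    fraction and is present iff the class is a PVE mixture."""

    cls: str
    mix_weight: float | None = None

    def __post_init__(self) -> None:
        if (self.cls == PVE_MIX) != (self.mix_weight is not None):
            raise ValueError("mix_weight present iff cls == 'pve_mix'")


@dataclass(frozen=True)
class SimulationConfig:
    grid: TimeGrid = field(default_factory=TimeGrid)
    aif: AifModelParams = field(default_factory=AifModelParams)
    tissues: tuple[TissueClassSpec, ...] = DEFAULT_TISSUES
    n_true_arterial: int = 6
    false_t0_values: tuple[float, ...] = (27.0, 28.0, 29.0, 30.0)
    false_delay_values: tuple[float, ...] = (9.0, 10.0, 11.0, 12.0)
    n_pve: int = 400
    s0: float = 100.0
    te: float = 0.030
    gm_peak_drop: float = 0.40
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    residue_shape: float = 0.0
    mtt_jitter: str = "gaussian"  # or "uniform"
    mtt_floor: float = 0.5
    noise_model: str = "magnitude"  # or "additive"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """Curves plus ground truth.

    signals       (n_voxels, n_times) signal matrix [a.u.]
    labels        VoxelLabel per row
    true_aif      noise-free arterial concentration curve (model units)
    k_const       calibrated concentration→ΔR2* constant
    noisy_indices rows that received additive noise (sorted)
    """

    grid: TimeGrid
    signals: np.ndarray
    labels: list[VoxelLabel]
    true_aif: np.ndarray
    k_const: float
    config: SimulationConfig
    seed: int
    noisy_indices: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.signals.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.array([lab.cls for lab in self.labels])

    @property
    def acq(self) -> AcquisitionParams:
        return AcquisitionParams(self.config.s0, self.config.te, self.k_const)


def gamma_variate(t, t0: float, a: float, b: float):
    """Unnormalised gamma-variate bolus (t−t0)^a · e^(−(t−t0)/b), zero for
    t ≤ t0.

    The leading constant is deliberately 1: the continuous maximum is then
    (a·b)^a · e^(−a), which equals 4.5369 for the default arterial parameters
    a = 3, b = 1.5.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    tau = t - t0
    out = np.zeros_like(tau)
    m = tau > 0
    out[m] = tau[m] ** a * np.exp(-tau[m] / b)
    return out if out.ndim else float(out)


def gamma_variate_peak(a: float, b: float) -> float:
    """Closed-form continuous maximum (a·b)^a · e^(−a)."""
    return (a * b) ** a * np.exp(-a)


def make_true_aif(grid: TimeGrid, p: AifModelParams | None = None) -> np.ndarray:
    """Arterial concentration curve: first passage plus recirculation.

    The recirculation is a copy of the first passage delayed by
    ``recirc_delay`` and discretely convolved (rectangle rule, scaled by dt)
    with an exponential kernel of time constant ``recirc_tau``.
    """
    p = p or AifModelParams()
    t = grid.times
    first = gamma_variate(t, p.t0, p.a, p.b)
    delayed = gamma_variate(t, p.t0 + p.recirc_delay, p.a, p.b)
    kern = np.exp(-(t - t[0]) / p.recirc_tau)
    if p.recirc_kernel == "unit_area":
        kern = kern / p.recirc_tau
    recirc = np.convolve(delayed, kern)[: grid.n_points] * grid.dt
    return first + recirc


def make_false_aifs(
    grid: TimeGrid, base: AifModelParams | None = None,
    t0_values=(27.0, 28.0, 29.0, 30.0), delay_values=(9.0, 10.0, 11.0, 12.0),
) -> tuple[np.ndarray, list[AifModelParams]]:
    """Delayed/dispersed arterial look-alikes: one curve per (t0, delay) in
    the Cartesian product of the given values (16 curves by default)."""
    base = base or AifModelParams()
    params = [
        replace(base, t0=t0, recirc_delay=d)
        for t0, d in itertools.product(t0_values, delay_values)
    ]
    curves = np.stack([make_true_aif(grid, q) for q in params])
    return curves, params


def residue_function(grid: TimeGrid, mtt: float, shape: float = 0.0) -> np.ndarray:
    """Residue function R(t): fraction of tracer still intravascular t seconds
    after an ideal instantaneous injection.

    R(0) = 1, R is non-increasing and its time integral equals the mean
    transit time. ``shape`` = 0 gives the exponential member e^(−t/MTT) of the
    gamma-variate family; shape > 0 gives the survival function of a
    Gamma(shape+1, MTT/(shape+1)) transit-time distribution (mean MTT).
    """
    if mtt <= 0:
        raise ValueError("mtt must be positive")
    if shape < 0:
        raise ValueError("shape must be non-negative")
    t = grid.times - grid.times[0]
    if shape == 0:
        return np.exp(-t / mtt)
    return stats.gamma.sf(t, a=shape + 1.0, scale=mtt / (shape + 1.0))


def tissue_concentration(
    aif: np.ndarray, cbv: float, mtt: float, grid: TimeGrid, shape: float = 0.0
) -> np.ndarray:
    """Tissue concentration by tracer kinetics: Ct = CBF · (Ca ⊛ R) · dt.

    CBV enters in ml/100 g and is converted to a blood volume fraction
    (ml/ml, unit tissue density and hematocrit correction), so
    CBF = (CBV/100)/MTT per the central volume theorem. Convolution is the
    causal rectangle rule on the grid.
    """
    aif = np.asarray(aif, dtype=float)
    if aif.shape != (grid.n_points,):
        raise ValueError("aif must be sampled on the given grid")
    cbf = (cbv / 100.0) / mtt
    r = residue_function(grid, mtt, shape)
    return cbf * np.convolve(aif, r)[: grid.n_points] * grid.dt


def calibrate_k(
    grid: TimeGrid,
    aif: np.ndarray,
    gm_spec: TissueClassSpec,
    s0: float = 100.0,
    te: float = 0.030,
    peak_drop: float = 0.40,
    shape: float = 0.0,
) -> float:
    """Concentration→ΔR2* constant giving a ``peak_drop`` (default 40%)
    signal dip from baseline for mean normal grey matter.

    Solves min_t S0·exp(−k·Ct_GM(t)·TE) = (1 − peak_drop)·S0, i.e.
    k = −ln(1 − peak_drop)/(TE · max Ct_GM).
    """
    ct = tissue_concentration(aif, gm_spec.cbv, gm_spec.mtt_mean, grid, shape)
    peak = float(ct.max())
    if peak <= 0:
        raise ValueError("grey-matter concentration peak is zero; cannot calibrate")
    return -np.log(1.0 - peak_drop) / (te * peak)


def concentration_to_signal(ct: np.ndarray, acq: AcquisitionParams) -> np.ndarray:
    """MR signal S(t) = S0 · exp(−k·C(t)·TE)."""
    ct = np.asarray(ct, dtype=float)
    return acq.s0 * np.exp(-acq.k_const * ct * acq.te)


def mix_pve(arterial_signal: np.ndarray, tissue_signal: np.ndarray, w: float) -> np.ndarray:
    """Signal-level partial-volume mixture w·arterial + (1−w)·tissue."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("mix weight must lie in [0, 1]")
    a = np.asarray(arterial_signal, dtype=float)
    t = np.asarray(tissue_signal, dtype=float)
    if a.shape != t.shape:
        raise ValueError("signals must share a grid")
    return w * a + (1.0 - w) * t


def add_noise(
    signals: np.ndarray,
    spec: NoiseSpec,
    s0: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Add i.i.d. zero-mean Gaussian noise (SD = S0/SNR) to ``n_noisy_curves``
    rows chosen without replacement; other rows are untouched.

    Returns the noisy matrix and the sorted affected row indices.
    """
    signals = np.asarray(signals, dtype=float)
    n = signals.shape[0]
    if spec.n_noisy_curves > n:
        raise ValueError("cannot select more noisy curves than rows")
    out = signals.copy()
    if spec.n_noisy_curves == 0:
        return out, np.array([], dtype=int)
    idx = rng.choice(n, size=spec.n_noisy_curves, replace=False)
    out[idx] += rng.normal(0.0, s0 / spec.snr, size=(spec.n_noisy_curves, signals.shape[1]))
    return out, np.sort(idx)


def _draw_mtts(rng: np.random.Generator, spec: TissueClassSpec, mode: str, floor: float) -> np.ndarray:
    if spec.mtt_sd == 0:
        return np.full(spec.count, spec.mtt_mean)
    if mode == "uniform":
        return rng.uniform(spec.mtt_mean - spec.mtt_sd, spec.mtt_mean + spec.mtt_sd, spec.count)
    vals = rng.normal(spec.mtt_mean, spec.mtt_sd, spec.count)
    # truncate: redraw anything at or below the physiological floor
    bad = vals <= floor
    while bad.any():
        vals[bad] = rng.normal(spec.mtt_mean, spec.mtt_sd, int(bad.sum()))
        bad = vals <= floor
    return vals


def build_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Build the full synthetic voxel population (default 1902 curves).

    Row order: true arterial, false arterial, normal GM, pathological GM, WM,
    PVE mixtures. One master seed feeds four independent sub-streams (MTT
    jitter, PVE mixing, noisy-row selection, noise values) so that each
    stochastic component is reproducible in isolation.
    """
    cfg = config or SimulationConfig()
    grid = cfg.grid
    ss = np.random.SeedSequence(seed)
    r_jitter, r_pve, r_sel, r_noise = (np.random.default_rng(s) for s in ss.spawn(4))

    true_aif = make_true_aif(grid, cfg.aif)
    false_curves, _ = make_false_aifs(
        grid, cfg.aif, cfg.false_t0_values, cfg.false_delay_values
    )

    gm = next(t for t in cfg.tissues if t.name == NORMAL_GM)
    k = calibrate_k(grid, true_aif, gm, cfg.s0, cfg.te, cfg.gm_peak_drop, cfg.residue_shape)
    acq = AcquisitionParams(cfg.s0, cfg.te, k)

    rows: list[np.ndarray] = []
    labels: list[VoxelLabel] = []

    art_signal = concentration_to_signal(true_aif, acq)
    for _ in range(cfg.n_true_arterial):
        rows.append(art_signal)
        labels.append(VoxelLabel(TRUE_ARTERIAL))
    for curve in false_curves:
        rows.append(concentration_to_signal(curve, acq))
        labels.append(VoxelLabel(FALSE_ARTERIAL))

    tissue_signals: dict[str, np.ndarray] = {}
    for spec in cfg.tissues:
        mtts = _draw_mtts(r_jitter, spec, cfg.mtt_jitter, cfg.mtt_floor)
        sigs = np.stack([
            concentration_to_signal(
                tissue_concentration(true_aif, spec.cbv, m, grid, cfg.residue_shape), acq
            )
            for m in mtts
        ])
        tissue_signals[spec.name] = sigs
        rows.extend(sigs)
        labels.extend(VoxelLabel(spec.name) for _ in range(spec.count))

    tissue_names = [t.name for t in cfg.tissues]
    for _ in range(cfg.n_pve):
        cls = tissue_names[int(r_pve.integers(len(tissue_names)))]
        member = int(r_pve.integers(tissue_signals[cls].shape[0]))
        w = float(r_pve.uniform())
        rows.append(mix_pve(art_signal, tissue_signals[cls][member], w))
        labels.append(VoxelLabel(PVE_MIX, mix_weight=w))

    signals = np.stack(rows)
    noisy, noisy_idx = _add_noise_split(signals, cfg.noise, cfg.s0, r_sel, r_noise)
    if cfg.noise_model == "magnitude":
        # MR images are magnitude images: complex noise on a crushed signal
        # appears as a positive (Rician) floor, not as negative intensities.
        noisy = np.abs(noisy)
    elif cfg.noise_model != "additive":
        raise ValueError("noise_model must be 'magnitude' or 'additive'")
    return SyntheticDataset(
        grid=grid,
        signals=noisy,
        labels=labels,
        true_aif=true_aif,
        k_const=k,
        config=cfg,
        seed=seed,
        noisy_indices=noisy_idx,
    )


def _add_noise_split(
    signals: np.ndarray,
    spec: NoiseSpec,
    s0: float,
    rng_select: np.random.Generator,
    rng_noise: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    # like add_noise, but row selection and noise values come from
    # independent streams so changing SNR does not move the selected rows
    n = signals.shape[0]
    if spec.n_noisy_curves > n:
        raise ValueError("cannot select more noisy curves than rows")
    out = signals.copy()
    if spec.n_noisy_curves == 0:
        return out, np.array([], dtype=int)
    idx = rng_select.choice(n, size=spec.n_noisy_curves, replace=False)
    out[idx] += rng_noise.normal(0.0, s0 / spec.snr, size=(spec.n_noisy_curves, signals.shape[1]))
    return out, np.sort(idx)
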