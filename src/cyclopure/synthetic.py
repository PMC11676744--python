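"""Synthetic data generator for both analytical branches.

Emulates the statistical structure of the study design so the whole pipeline
is testable without instrument data:

* **ER-MS branch** — centroided MS/MS peak lists over a ladder of excitation
  voltages.  Pure-isomer SY curves are Boltzmann sigmoids, the cyclic one
  shifted to higher voltage (cyclisation raises the fragmentation threshold).
  A mixture's curve is a convex combination weighted not by the molar ratio x
  but by an *effective* fraction a_eff(x) distorted by electrospray ion
  suppression of the linear peptide.
* **IR branch** — absorbance spectra on a fixed wavenumber grid with bands
  shared by the two isomers, a linear-peptide-specific alkyne/azide band in
  2040-2170 cm^-1 scaled by x, a random smooth baseline (scattering drift)
  and white noise; many raw spectra per replicate are averaged to one.

Two ion-suppression laws are available:

* ``"saturation"`` (default): a_eff = r*x / (r*x + (1 - x)), a response-factor
  model whose slope is r at x = 0 and 1/r at x = 1.
* ``"piecewise"``: exactly linear with slope r up to a breakpoint (default
  0.3), then linear up to (1, 1); the low-range calibration is then an exact
  line with slope r, convenient for exactness tests.  With r = 0.483 and
  breakpoint 0.3 the high/low slope ratio is (1 - 0.3 r)/(0.7 r) = 2.53.

All randomness flows from a single seed; per-(ratio, replicate) substreams
are derived deterministically, so equal seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .ir_pipeline import IRDataset
from .survival_yield import BoltzmannParams, MsmsSpectrum

__all__ = [
    "MixtureDesign",
    "ErmsSimConfig",
    "IrSimConfig",
    "ErmsSample",
    "effective_linear_fraction",
    "simulate_erms_dataset",
    "simulate_ir_dataset",
    "ERMS_DESIGN",
    "ERMS_CALIBRATION_RATIOS",
    "IR_DESIGN",
]

#: Nominal m/z of the caesium-cationised precursor (label only).
PRECURSOR_MZ = 2141.3

#: Mass of the dominant N2-loss fragment, shared by both isomers.
N2_LOSS_MZ = 2112.8


@dataclass(frozen=True)
class MixtureDesign:
    """Calibration design: molar ratios x = n_lin/n_total and replicate count."""

    ratios: tuple
    replicates: int = 3

    def __post_init__(self):
        ratios = tuple(float(r) for r in self.ratios)
        object.__setattr__(self, "ratios", ratios)
        if not ratios:
            raise ConfigurationError("design needs at least one ratio")
        if any(not 0.0 <= r <= 1.0 for r in ratios):
            raise ConfigurationError("ratios must lie in [0, 1]")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    def __iter__(self):
        for i, ratio in enumerate(self.ratios):
            for rep in range(1, self.replicates + 1):
                yield i, ratio, rep


#: Mixture series measured by ER-MS (molar ratios of linear peptide).
ERMS_DESIGN = MixtureDesign(
    ratios=(0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0), replicates=3
)

#: The low-range subset used for the ER-MS calibration models (6 levels x 3).
ERMS_CALIBRATION_RATIOS = (0.0, 0.05, 0.1, 0.15, 0.2, 0.3)

#: Mixture series measured by IR microscopy (11 levels x 3 = 33 spectra).
IR_DESIGN = MixtureDesign(
    ratios=(0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0), replicates=3
)


def _default_voltage_grid():
    # 1.7 to 2.9 V in 0.1 V steps
    return tuple(np.round(np.arange(17, 30) * 0.1, 10))


@dataclass(frozen=True)
class ErmsSimConfig:
    """Settings for the ER-MS peak-list simulator.

    ``suppression_r`` is the linear peptide's relative electrospray response
    factor (1 = no suppression); ``noise_sd_rel`` is the relative sd of the
    multiplicative Gaussian noise on every peak intensity.
    """

    voltage_grid: tuple = field(default_factory=_default_voltage_grid)
    boltzmann_linear: BoltzmannParams = BoltzmannParams(a1=1.0, a2=0.0, v0=2.05, dv=0.10)
    boltzmann_cyclic: BoltzmannParams = BoltzmannParams(a1=1.0, a2=0.0, v0=2.55, dv=0.10)
    suppression_r: float = 0.483
    suppression_mode: str = "saturation"  # or "piecewise"
    suppression_breakpoint: float = 0.3
    intensity_scale: float = 1e5
    noise_sd_rel: float = 0.01
    n_fragments: int = 5
    precursor_mz: float = PRECURSOR_MZ
    seed: int = 0

    def __post_init__(self):
        grid = tuple(float(v) for v in self.voltage_grid)
        object.__setattr__(self, "voltage_grid", grid)
        if len(grid) == 0:
            raise ConfigurationError("voltage grid is empty")
        if len(grid) > 1 and any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError("voltage grid must be strictly increasing")
        if not 0 < self.suppression_r <= 1:
            raise ConfigurationError("suppression_r must lie in (0, 1]")
        if self.suppression_mode not in ("saturation", "piecewise"):
            raise ConfigurationError(
                f"unknown suppression_mode {self.suppression_mode!r}"
            )
        if not 0 < self.suppression_breakpoint < 1:
            raise ConfigurationError("suppression_breakpoint must lie in (0, 1)")
        if self.noise_sd_rel < 0:
            raise ConfigurationError("noise_sd_rel must be >= 0")
        if self.n_fragments < 1:
            raise ConfigurationError("n_fragments must be >= 1")


def _default_wavenumber_grid():
    return tuple(np.linspace(675.0, 4000.0, 1725))


def _default_shared_bands():
    # (centre cm^-1, Gaussian sd cm^-1, amplitude AU): amide I/II, amide III,
    # CH stretch and the broad amide A / OH region, present in both isomers.
    return (
        (1655.0, 25.0, 0.90),
        (1545.0, 20.0, 0.60),
        (1240.0, 30.0, 0.25),
        (2930.0, 40.0, 0.30),
        (3290.0, 85.0, 0.50),
    )


def _default_linear_band():
    # Unresolved alkyne + azide stretches of the linear peptide.
    return ((2105.0, 18.0, 0.25),)


@dataclass(frozen=True)
class IrSimConfig:
    """Settings for the IR spectra simulator.

    The linear band amplitude scales with the molar ratio x; ``noise_sd`` is
    per raw spectrum (absorbance units) and ``raw_spectra_per_replicate`` raw
    spectra are averaged into each dataset row, as a microscope grid scan
    averages its points.
    """

    wavenumber_grid: tuple = field(default_factory=_default_wavenumber_grid)
    shared_bands: tuple = field(default_factory=_default_shared_bands)
    linear_band: tuple = field(default_factory=_default_linear_band)
    baseline_order: int = 3
    baseline_scale: float = 0.05
    noise_sd: float = 0.01
    raw_spectra_per_replicate: int = 100
    seed: int = 0

    def __post_init__(self):
        grid = tuple(float(w) for w in self.wavenumber_grid)
        object.__setattr__(self, "wavenumber_grid", grid)
        if len(grid) < 2:
            raise ConfigurationError("wavenumber grid needs at least 2 points")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError("wavenumber grid must be strictly increasing")
        for centre, _, _ in self.linear_band:
            if not 2040.0 <= centre <= 2170.0:
                raise ConfigurationError(
                    f"linear band centre {centre} cm^-1 outside 2040-2170 cm^-1"
                )
        if self.baseline_order < 0:
            raise ConfigurationError("baseline_order must be >= 0")
        if self.baseline_scale < 0 or self.noise_sd < 0:
            raise ConfigurationError("baseline_scale and noise_sd must be >= 0")
        if self.raw_spectra_per_replicate < 1:
            raise ConfigurationError("raw_spectra_per_replicate must be >= 1")


def effective_linear_fraction(x, config: ErmsSimConfig):
    """Effective convex-combination weight a_eff(x) under ion suppression.

    Saturation law: a_eff = r x / (r x + (1 - x)); its derivative is
    r / (1 + (r - 1) x)^2, i.e. r at x = 0 and 1/r at x = 1.  Piecewise law:
    slope r up to the breakpoint, then linear to (1, 1).
    """
    x = np.asarray(x, dtype=float)
    r = config.suppression_r
    if config.suppression_mode == "saturation":
        a = r * x / (r * x + (1.0 - x))
    else:
        bp = config.suppression_breakpoint
        a_bp = r * bp
        a = np.where(x <= bp, r * x, a_bp + (1.0 - a_bp) * (x - bp) / (1.0 - bp))
    return float(a) if a.ndim == 0 else a


def _sample_id(prefix: str, ratio: float, rep: int) -> str:
    return f"{prefix}_x{ratio:.3f}_rep{rep}"


@dataclass(frozen=True)
class ErmsSample:
    """One simulated sample: its design metadata and per-voltage spectra."""

    sample_id: str
    ratio: float
    replicate: int
    spectra: tuple


def simulate_erms_dataset(config: ErmsSimConfig, design: MixtureDesign):
    """Simulate MS/MS peak lists for every (ratio, replicate, voltage).

    At each voltage V the precursor's intensity fraction is
    ``SY_mix(V) = a_eff * SY_lin(V) + (1 - a_eff) * SY_cyc(V)``; the remaining
    current is split over ``n_fragments`` fragment channels by a symmetric
    Dirichlet draw, and every peak gets multiplicative Gaussian noise
    (truncated at zero).  Returns a list of :class:`ErmsSample`.
    """
    voltages = np.asarray(config.voltage_grid)
    sy_lin = config.boltzmann_linear(voltages)
    sy_cyc = config.boltzmann_cyclic(voltages)
    frag_mz = np.array(
        [N2_LOSS_MZ - 150.0 * k for k in range(config.n_fragments)], dtype=float
    )
    samples = []
    for i_ratio, ratio, rep in design:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), i_ratio, rep])
        )
        a_eff = effective_linear_fraction(ratio, config)
        sy_mix = a_eff * sy_lin + (1.0 - a_eff) * sy_cyc
        sid = _sample_id("erms", ratio, rep)
        spectra = []
        for v, sy in zip(voltages, sy_mix):
            precursor = config.intensity_scale * sy
            frac = rng.dirichlet(np.ones(config.n_fragments))
            fragments = config.intensity_scale * (1.0 - sy) * frac
            intensity = np.concatenate(([precursor], fragments))
            if config.noise_sd_rel > 0:
                intensity = intensity * (
                    1.0 + rng.normal(0.0, config.noise_sd_rel, intensity.size)
                )
                intensity = np.clip(intensity, 0.0, None)
            spectra.append(
                MsmsSpectrum(
                    sample_id=sid,
                    voltage=float(v),
                    mz=np.concatenate(([config.precursor_mz], frag_mz)),
                    intensity=intensity,
                    precursor_mz=config.precursor_mz,
                )
            )
        samples.append(
            ErmsSample(sample_id=sid, ratio=ratio, replicate=rep, spectra=tuple(spectra))
        )
    return samples


def _band_profile(grid: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(grid)
    for centre, width, amp in bands:
        out += amp * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    return out


def simulate_ir_dataset(
    config: IrSimConfig, design: MixtureDesign, return_raw: bool = False
):
    """Simulate averaged IR spectra for a mixture design.

    Per (ratio, replicate), ``raw_spectra_per_replicate`` raw spectra are
    drawn as shared bands + x-scaled linear band + a random smooth polynomial
    baseline + white noise, then averaged arithmetically into one dataset
    row.  Row count is ``len(ratios) * replicates``.

    With ``return_raw=True`` also returns ``{sample_id: raw matrix}``.
    """
    grid = np.asarray(config.wavenumber_grid)
    shared = _band_profile(grid, config.shared_bands)
    linear = _band_profile(grid, config.linear_band)
    u = np.linspace(-1.0, 1.0, grid.size)  # scaled coordinate for the baseline
    powers = np.vstack([u**k for k in range(config.baseline_order + 1)])

    rows, ids, ratios, reps = [], [], [], []
    raw_store = {}
    for i_ratio, ratio, rep in design:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 1, i_ratio, rep])
        )
        n_raw = config.raw_spectra_per_replicate
        signal = shared + ratio * linear
        coeffs = rng.normal(0.0, 1.0, (n_raw, config.baseline_order + 1))
        baselines = config.baseline_scale * coeffs @ powers
        noise = (
            rng.normal(0.0, config.noise_sd, (n_raw, grid.size))
            if config.noise_sd > 0
            else 0.0
        )
        raw = signal[None, :] + baselines + noise
        sid = _sample_id("ir", ratio, rep)
        rows.append(raw.mean(axis=0))
        ids.append(sid)
        ratios.append(ratio)
        reps.append(rep)
        if return_raw:
            raw_store[sid] = raw
    dataset = IRDataset(
        wavenumbers=grid,
        absorbance=np.vstack(rows),
        sample_ids=ids,
        ratios=np.array(ratios),
        replicates=np.array(reps),
    )
    if return_raw:
        return dataset, raw_store
    return dataset
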