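"""Seeded generator of Vis-NIR-like grape spectra with known ground truth.

Each synthetic sample is built as a smooth reflectance baseline minus
Gaussian absorption bands whose depths are tied to latent constituent
concentrations, then corrupted by the distortions scatter-correction
preprocessing is designed to remove: per-spectrum multiplicative scatter,
additive offset, a random low-order polynomial baseline, and i.i.d. channel
noise. Because band placement, link functions and concentrations are known,
every downstream stage (preprocessing, partitioning, wavelength selection,
regression) can be tested against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .core import (
    INDICATORS,
    Dataset,
    ReferenceTable,
    SpectraMatrix,
    WavelengthGrid,
    write_reference_csv,
    write_spectra_csv,
)

import pandas as pd


class ConfigError(ValueError):
    """Raised for an invalid synthetic-data configuration."""


@dataclass(frozen=True)
class ConstituentSpec:
    """One chemical constituent and its spectral signature.

    ``bands`` are (center_nm, width_nm, amplitude_per_unit) Gaussian
    absorbers; the band magnitude for a sample with concentration ``c`` is
    ``amplitude_per_unit * link(c)`` with ``link`` either identity or the
    square. A degenerate range (low == high) pins the concentration.
    """

    name: str
    concentration_range: tuple[float, float]
    bands: tuple[tuple[float, float, float], ...]
    link: str = "linear"

    def __post_init__(self) -> None:
        low, high = self.concentration_range
        if low > high:
            raise ConfigError(f"{self.name}: concentration low > high")
        if self.link not in ("linear", "quadratic"):
            raise ConfigError(f"{self.name}: link must be linear or quadratic")
        for center, width, _amp in self.bands:
            if width <= 0:
                raise ConfigError(f"{self.name}: band width must be > 0 ({width})")

    def link_fn(self, c: np.ndarray) -> np.ndarray:
        return c * c if self.link == "quadratic" else c


@dataclass(frozen=True)
class ArtifactSpec:
    """Per-spectrum distortion magnitudes (all standard deviations >= 0)."""

    scatter_multiplier_sd: float = 0.1   # sd of log multiplicative scatter
    scatter_offset_sd: float = 0.02     # additive offset, reflectance units
    baseline_poly_coeffs_sd: tuple[float, ...] = (0.02, 0.01, 0.005)
    noise_sd: float = 0.003             # i.i.d. channel noise

    def __post_init__(self) -> None:
        sds = (
            self.scatter_multiplier_sd,
            self.scatter_offset_sd,
            *self.baseline_poly_coeffs_sd,
            self.noise_sd,
        )
        if any(s < 0 for s in sds):
            raise ConfigError("artifact standard deviations must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(0.0, 0.0, (), 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int
    grid: tuple[float, float, int]  # (start_nm, end_nm, n_points)
    constituents: tuple[ConstituentSpec, ...]
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0
    #: shared ripening latent inducing cross-constituent correlation ~rho
    maturity_correlation: float = 0.5
    #: smooth mean reflectance curve; None -> zero baseline (bands only)
    baseline_mean: str | None = "grape"

    def __post_init__(self) -> None:
        start, end, n_points = self.grid
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        if n_points < 2:
            raise ConfigError("grid needs at least 2 points")
        if start >= end:
            raise ConfigError("grid start must be below end")
        if not 0.0 <= self.maturity_correlation < 1.0:
            raise ConfigError("maturity_correlation must be in [0, 1)")
        wavelengths = self.wavelengths()
        for spec in self.constituents:
            for center, _w, _a in spec.bands:
                if not (wavelengths[0] <= center <= wavelengths[-1]):
                    raise ConfigError(
                        f"band center {center} nm of {spec.name} lies outside "
                        f"the grid [{wavelengths[0]}, {wavelengths[-1]}] nm"
                    )

    def wavelengths(self) -> np.ndarray:
        start, end, n_points = self.grid
        return np.linspace(start, end, n_points)


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to reconstruct the observed spectra exactly."""

    concentrations: pd.DataFrame        # n_samples x constituents
    clean: np.ndarray                   # artifact-free spectra
    multipliers: np.ndarray             # per-sample scatter multiplier m_i
    offsets: np.ndarray                 # per-sample additive offset o_i
    baselines: np.ndarray               # per-sample polynomial baseline(lambda)
    noise: np.ndarray                   # additive noise matrix
    bands: tuple[ConstituentSpec, ...]

    def reconstruct(self) -> np.ndarray:
        return (
            self.multipliers[:, None] * self.clean
            + self.offsets[:, None]
            + self.baselines
            + self.noise
        )


@dataclass(frozen=True)
class SyntheticDataset:
    spectra: SpectraMatrix
    references: ReferenceTable
    truth: SyntheticTruth

    def as_dataset(self) -> Dataset:
        return Dataset(spectra=self.spectra, references=self.references)


def _grape_baseline(wavelengths: np.ndarray) -> np.ndarray:
    # Low reflectance in the pigment-absorbing visible region rising to a
    # NIR plateau, the overall shape of berry diffuse reflectance.
    return 0.25 + 0.40 / (1.0 + np.exp(-(wavelengths - 550.0) / 80.0))


def _sample_concentrations(
    config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Uniform marginals per constituent, coupled by a shared maturity latent.

    A Gaussian copula: z_ik = sqrt(rho) * m_i + sqrt(1-rho) * e_ik mapped
    through the normal CDF, so marginals stay uniform over each range while
    constituents covary as they do during ripening.
    """
    rho = config.maturity_correlation
    n = config.n_samples
    maturity = rng.standard_normal(n)
    cols = {}
    for spec in config.constituents:
        z = np.sqrt(rho) * maturity + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        u = norm.cdf(z)
        low, high = spec.concentration_range
        cols[spec.name] = low + u * (high - low)
    return pd.DataFrame(cols)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a seeded synthetic dataset; bit-identical for equal configs."""
    rng = np.random.default_rng(config.seed)
    wavelengths = config.wavelengths()
    n, p = config.n_samples, len(wavelengths)

    concentrations = _sample_concentrations(config, rng)

    clean = np.zeros((n, p))
    if config.baseline_mean == "grape":
        clean += _grape_baseline(wavelengths)[None, :]
    elif config.baseline_mean is not None:
        raise ConfigError(f"unknown baseline_mean {config.baseline_mean!r}")
    for spec in config.constituents:
        magnitude = spec.link_fn(concentrations[spec.name].to_numpy())
        profile = np.zeros(p)
        for center, width, amp in spec.bands:
            profile_band = amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
            clean += magnitude[:, None] * profile_band[None, :]
            profile += profile_band

    art = config.artifacts
    multipliers = np.exp(rng.normal(0.0, art.scatter_multiplier_sd, size=n))
    offsets = rng.normal(0.0, art.scatter_offset_sd, size=n)
    t = np.linspace(-1.0, 1.0, p)
    baselines = np.zeros((n, p))
    for j, sd in enumerate(art.baseline_poly_coeffs_sd):
        coeffs = rng.normal(0.0, sd, size=n)
        baselines += coeffs[:, None] * t[None, :] ** j
    noise = rng.normal(0.0, art.noise_sd, size=(n, p)) if art.noise_sd > 0 else np.zeros((n, p))

    observed = multipliers[:, None] * clean + offsets[:, None] + baselines + noise

    ids = tuple(f"S{i:03d}" for i in range(n))
    spectra = SpectraMatrix(
        sample_ids=ids, grid=WavelengthGrid(wavelengths), reflectance=observed
    )
    known = [c for c in concentrations.columns if c in INDICATORS]
    references = ReferenceTable(sample_ids=ids, values=concentrations[known])
    truth = SyntheticTruth(
        concentrations=concentrations,
        clean=clean,
        multipliers=multipliers,
        offsets=offsets,
        baselines=baselines,
        noise=noise,
        bands=tuple(config.constituents),
    )
    return SyntheticDataset(spectra=spectra, references=references, truth=truth)


def default_grape_config(seed: int = 0) -> SyntheticConfig:
    """Study-scale default: 192 samples on a 1507-point 400-1100 nm grid.

    Six constituents named after the grape quality indicators, with
    absorption bands in the pigment-dominated visible region and the
    800-920 nm sugar/phenolic region. Concentration ranges span plausible
    veraison-to-maturity values; band depths (~0.1-0.15 reflectance units at
    the top of each range) sit well above the 0.003 channel noise.
    """
    def bands(*triples: tuple[float, float, float], high: float):
        # amplitude_per_unit scaled so full-range concentration produces the
        # stated fractional reflectance dip
        return tuple((c, w, -depth / high) for c, w, depth in triples)

    constituents = (
        ConstituentSpec("pH", (2.5, 3.8),
                        bands((445, 25, 0.12), (680, 30, 0.08), high=3.8)),
        ConstituentSpec("TSS", (8.0, 25.0),
                        bands((840, 20, 0.15), (910, 25, 0.10), high=25.0)),
        ConstituentSpec("TA", (5.0, 18.0),
                        bands((540, 25, 0.10), (890, 18, 0.08), high=18.0)),
        ConstituentSpec("RS", (40.0, 200.0),
                        bands((850, 15, 0.12), (960, 22, 0.09), high=200.0)),
        ConstituentSpec("TPCN", (1.5, 12.0),
                        bands((520, 22, 0.11), (620, 28, 0.07), high=12.0)),
        ConstituentSpec("TPCD", (20.0, 90.0),
                        bands((480, 20, 0.10), (800, 16, 0.08), high=90.0)),
    )
    return SyntheticConfig(
        n_samples=192,
        grid=(400.0, 1100.0, 1507),
        constituents=constituents,
        artifacts=ArtifactSpec(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Persistence


def write_synthetic_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write spectra.csv / references.csv plus a truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(dataset.spectra, outdir / "spectra.csv")
    write_reference_csv(dataset.references, outdir / "references.csv")
    truth = dataset.truth
    payload = {
        "concentrations": truth.concentrations.to_dict(orient="list"),
        "multipliers": truth.multipliers.tolist(),
        "offsets": truth.offsets.tolist(),
        "bands": [
            {
                "name": s.name,
                "concentration_range": list(s.concentration_range),
                "bands": [list(b) for b in s.bands],
                "link": s.link,
            }
            for s in truth.bands
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
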