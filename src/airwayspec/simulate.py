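"""Synthetic spectrometer cohorts with the oxyhemoglobin signature.

The generator emulates the acquisition this pipeline analyzes: a
broadband 470-850 nm LED envelope recorded against dark and white
(diffuse reflectance standard) references, and tissue reflectance
carrying the trough-peak-trough signature of oxyhemoglobin's two
visible absorption bands flanking the 561 nm reflectance peak. The
underlying reflectance of one acquisition is

    R(lambda) = B(lambda) * [1 - d543 G(lambda; 543, s1) - d578 G(lambda; 578, s2)]

with B a gentle positive baseline, G unit-height Gaussians, and the
trough depths (d543, d578) realized per acquisition as
class mean x per-organ lognormal factor x per-spectrum lognormal jitter.
Tracheal depths are deeper than esophageal ones by default, reproducing
the "pronounced vs less pronounced" contrast between the tissues.
Raw counts are dark + (white - dark) * R * (1 + multiplicative noise).

The defaults give a cohort of 9 sample pairs x 2 organs x 50
acquisitions = 900 spectra that is linearly separable in the
(r543, r578) feature plane; ``hard_mode()`` returns an overlapping
preset for classifier stress tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import (
    ANALYSIS_BAND,
    ESOPHAGUS,
    ORGANS,
    TRACHEA,
    AcquisitionMeta,
    RawSpectrum,
    ReferenceSet,
    SpectraDataset,
)

__all__ = ["SimulationConfig", "make_references", "make_tissue_spectrum",
           "simulate_cohort", "expected_features"]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; a pure function of this config
    plus ``seed`` reproduces the dataset bit for bit.

    Depths are mean fractional trough depths at (543, 578) nm;
    ``organ_depth_sd`` is the relative SD of the lognormal factor drawn
    once per (pair, organ); ``spectrum_jitter_sd`` the per-acquisition
    relative depth jitter; ``noise_rel`` the multiplicative detector
    noise SD per grid point. ``baseline_slope`` is the total fractional
    tilt of the reflectance baseline across the full grid (kept small so
    the baseline is flat to ~1e-3 across the 543-578 nm band).
    """

    n_pairs: int = 9
    n_per_organ: int = 50
    seed: int = 0
    grid_start: float = 470.0
    grid_stop: float = 850.0
    grid_step: float = 0.5
    trough_centers: tuple[float, float] = (543.0, 578.0)
    trough_widths: tuple[float, float] = (9.0, 11.0)
    depth_trachea: tuple[float, float] = (0.35, 0.40)
    depth_esophagus: tuple[float, float] = (0.12, 0.15)
    organ_depth_sd: float = 0.10
    spectrum_jitter_sd: float = 0.02
    noise_rel: float = 0.01
    dark_level: float = 100.0
    dark_noise_sd: float = 2.0
    white_peak: float = 50000.0
    baseline_slope: float = 0.02

    def __post_init__(self) -> None:
        for d in (*self.depth_trachea, *self.depth_esophagus):
            if not 0 <= d < 1:
                raise ValueError(f"trough depths must be in [0, 1), got {d}")
        if min(self.trough_widths) <= 0:
            raise ValueError("trough widths must be positive")
        if self.grid_start > ANALYSIS_BAND[0] or self.grid_stop < ANALYSIS_BAND[1]:
            raise ValueError(
                f"grid must cover the analysis band {ANALYSIS_BAND} nm"
            )
        for sd in (self.organ_depth_sd, self.spectrum_jitter_sd,
                   self.noise_rel, self.dark_noise_sd):
            if sd < 0:
                raise ValueError("all noise SDs must be >= 0")
        if self.n_pairs < 1 or self.n_per_organ < 1:
            raise ValueError("n_pairs and n_per_organ must be >= 1")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    @classmethod
    def hard_mode(cls, **overrides) -> "SimulationConfig":
        """Overlapping-classes preset for classifier stress tests."""
        base = dict(
            depth_trachea=(0.22, 0.26),
            depth_esophagus=(0.17, 0.20),
            organ_depth_sd=0.20,
            noise_rel=0.03,
        )
        base.update(overrides)
        return cls(**base)


def _envelope(grid: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Smooth positive LED envelope, peak scaled to ``white_peak``."""
    e = 0.8 * np.exp(-0.5 * ((grid - 560.0) / 90.0) ** 2) + 0.5 * np.exp(
        -0.5 * ((grid - 700.0) / 120.0) ** 2
    )
    return cfg.white_peak * e / e.max()


def _baseline(grid: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    span = cfg.grid_stop - cfg.grid_start
    return 1.0 + cfg.baseline_slope * (grid - 561.0) / span


def _troughs(grid: np.ndarray, cfg: SimulationConfig,
             d543: float, d578: float) -> np.ndarray:
    (c1, c2), (s1, s2) = cfg.trough_centers, cfg.trough_widths
    g1 = np.exp(-0.5 * ((grid - c1) / s1) ** 2)
    g2 = np.exp(-0.5 * ((grid - c2) / s2) ** 2)
    return 1.0 - d543 * g1 - d578 * g2


def true_reflectance(grid: np.ndarray, cfg: SimulationConfig,
                     d543: float, d578: float) -> np.ndarray:
    """Noise-free underlying reflectance R(lambda)."""
    return _baseline(grid, cfg) * _troughs(grid, cfg, d543, d578)


def expected_features(cfg: SimulationConfig, d543: float, d578: float
                      ) -> tuple[float, float]:
    """Closed-form (r543, r578) for known depths at zero noise: the
    true reflectance at each trough divided by its value at 561 nm."""
    lams = np.array([cfg.trough_centers[0], 561.0, cfg.trough_centers[1]])
    r = true_reflectance(lams, cfg, d543, d578)
    return float(r[0] / r[1]), float(r[2] / r[1])


def make_references(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> ReferenceSet:
    """Dark reference (constant level + Gaussian read noise) and white
    reference (dark + LED envelope)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    dark = cfg.dark_level + rng.normal(0.0, cfg.dark_noise_sd, grid.size) \
        if cfg.dark_noise_sd > 0 else np.full(grid.size, cfg.dark_level)
    white = dark + _envelope(grid, cfg)
    return ReferenceSet(grid=grid, dark=dark, white=white)


def make_tissue_spectrum(
    cfg: SimulationConfig,
    organ: str,
    meta: AcquisitionMeta,
    refs: ReferenceSet,
    rng: np.random.Generator,
    organ_factor: float = 1.0,
) -> tuple[RawSpectrum, dict]:
    """One raw acquisition plus its ground-truth record.

    ``organ_factor`` is the per-(pair, organ) lognormal depth factor; the
    per-spectrum jitter and detector noise are drawn from ``rng`` here.
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    means = cfg.depth_trachea if organ == TRACHEA else cfg.depth_esophagus
    jit = (
        np.exp(rng.normal(0.0, cfg.spectrum_jitter_sd, 2))
        if cfg.spectrum_jitter_sd > 0
        else np.ones(2)
    )
    d543 = means[0] * organ_factor * jit[0]
    d578 = means[1] * organ_factor * jit[1]
    grid = refs.grid
    refl = true_reflectance(grid, cfg, d543, d578)
    noise = (
        1.0 + rng.normal(0.0, cfg.noise_rel, grid.size)
        if cfg.noise_rel > 0
        else 1.0
    )
    counts = refs.dark + (refs.white - refs.dark) * refl * noise
    counts = np.clip(counts, 0.0, None)
    raw = RawSpectrum(grid=grid, counts=counts, meta=meta)
    record = {
        "pair_id": meta.pair_id,
        "organ": organ,
        "acq_index": meta.acq_index,
        "d543": d543,
        "d578": d578,
    }
    return raw, record


def simulate_cohort(cfg: SimulationConfig
                    ) -> tuple[SpectraDataset, pd.DataFrame]:
    """Full cohort: n_pairs x 2 organs x n_per_organ raw spectra with one
    shared reference set, plus the ground-truth depth table."""
    rng = np.random.default_rng(cfg.seed)
    refs = make_references(cfg, rng)
    spectra: list[RawSpectrum] = []
    records: list[dict] = []
    for pair_id in range(1, cfg.n_pairs + 1):
        for organ in (TRACHEA, ESOPHAGUS):
            organ_factor = (
                float(np.exp(rng.normal(0.0, cfg.organ_depth_sd)))
                if cfg.organ_depth_sd > 0
                else 1.0
            )
            for acq in range(1, cfg.n_per_organ + 1):
                meta = AcquisitionMeta(pair_id=pair_id, organ=organ, acq_index=acq)
                raw, rec = make_tissue_spectrum(
                    cfg, organ, meta, refs, rng, organ_factor
                )
                spectra.append(raw)
                records.append(rec)
    ds = SpectraDataset(
        spectra=spectra,
        references=refs,
        provenance=f"airwayspec.simulate seed={cfg.seed} cfg={cfg}",
    )
    return ds, pd.DataFrame.from_records(records)
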