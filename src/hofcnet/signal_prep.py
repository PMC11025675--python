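"""ROI-level temporal preprocessing.

Mirrors the standard resting-state pipeline once voxel data have been
reduced to regional mean time series: drop initial volumes, remove a
per-region linear trend, zero-phase band-pass to the low-frequency BOLD
band (0.01-0.08 Hz by default), then regress out nuisance signals (white
matter / CSF averages and motion expansions supplied as columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


@dataclass
class PrepConfig:
    drop_volumes: int = 5
    band: tuple[float, float] = (0.01, 0.08)
    tr: float = 2.0
    filter_order: int = 4
    realization: str = "butter"  # or "fft" (ideal brick-wall, exactly idempotent)

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr)
        low, high = self.band
        if not 0 < low < high < nyquist:
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist "
                f"({nyquist:g} Hz at TR={self.tr:g} s)")
        if self.realization not in ("butter", "fft"):
            raise ValueError(f"unknown filter realization {self.realization!r}")


def bandpass(series: np.ndarray, config: PrepConfig) -> np.ndarray:
    """Zero-phase band-pass of each column.

    ``butter``: Butterworth band-pass applied forward-backward
    (``sosfiltfilt``), so phase is exactly zero and the effective
    attenuation is the squared magnitude response.  ``fft``: ideal
    rectangular passband in the frequency domain (idempotent by
    construction, at the price of ringing at sharp spectral edges).
    """
    fs = 1.0 / config.tr
    if config.realization == "fft":
        freqs = np.fft.rfftfreq(series.shape[0], d=config.tr)
        mask = (freqs >= config.band[0]) & (freqs <= config.band[1])
        spec = np.fft.rfft(series, axis=0)
        spec[~mask] = 0.0
        return np.fft.irfft(spec, n=series.shape[0], axis=0)
    sos = sps.butter(config.filter_order, config.band, btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, series, axis=0)


def detrend_and_bandpass(series: np.ndarray, config: PrepConfig | None = None
                         ) -> np.ndarray:
    """Drop leading volumes, remove per-column linear trends, band-pass."""
    config = config or PrepConfig()
    if series.shape[0] - config.drop_volumes < 30:
        raise ValueError(
            f"only {series.shape[0] - config.drop_volumes} volumes would remain "
            f"after dropping {config.drop_volumes}; need >= 30")
    trimmed = series[config.drop_volumes:]
    detrended = sps.detrend(trimmed, axis=0, type="linear")
    return bandpass(detrended, config)


def regress_nuisance(series: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualise each column on [intercept, nuisance] by least squares.

    Rank-deficient designs (common for motion-expansion regressor sets) are
    handled by the SVD pseudo-inverse rather than raised as errors.
    """
    t = series.shape[0]
    if nuisance.shape[0] != t:
        raise ValueError(
            f"nuisance has {nuisance.shape[0]} rows, series has {t}")
    if nuisance.shape[1] >= t:
        raise ValueError("more nuisance regressors than timepoints")
    design = np.column_stack([np.ones(t), nuisance])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "nuisance design is rank deficient (rank %d of %d columns); "
            "using pseudo-inverse solution", rank, design.shape[1])
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def preprocess(series: np.ndarray, config: PrepConfig | None = None,
               nuisance: np.ndarray | None = None,
               nuisance_last: bool = True) -> np.ndarray:
    """Full temporal pipeline: drop -> detrend -> band-pass -> nuisance.

    ``nuisance_last=False`` regresses nuisance signals before filtering
    instead (the alternative ordering some pipelines use); the regressor
    table must always have one row per *retained* volume.
    """
    config = config or PrepConfig()
    logger.info("prep order: drop(%d) -> detrend -> bandpass%s",
                config.drop_volumes,
                " -> nuisance" if nuisance is not None and nuisance_last
                else (" (nuisance before filter)" if nuisance is not None else ""))
    if nuisance is not None and not nuisance_last:
        trimmed = series[config.drop_volumes:]
        trimmed = regress_nuisance(trimmed, nuisance)
        cfg = PrepConfig(drop_volumes=0, band=config.band, tr=config.tr,
                         filter_order=config.filter_order,
                         realization=config.realization)
        return detrend_and_bandpass(trimmed, cfg)
    out = detrend_and_bandpass(series, config)
    if nuisance is not None:
        out = regress_nuisance(out, nuisance)
    return out
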