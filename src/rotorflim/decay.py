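"""Containers for TCSPC decay histograms and instrument response functions.

A TCSPC (time-correlated single photon counting) measurement histograms
photon arrival times relative to the excitation pulse into uniform time
channels.  The measured decay is the true fluorescence decay convolved with
the instrument response function (IRF), so both objects share the same
channel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MIN_CHANNELS = 32


@dataclass(frozen=True)
class DecayHistogram:
    """Binned photon arrival counts on a uniform time grid.

    Parameters
    ----------
    time_ps : ndarray
        Channel start times in picoseconds; uniformly spaced.
    counts : ndarray
        Non-negative photon counts per channel.
    """

    time_ps: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ps, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "time_ps", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("time_ps and counts must be 1-D arrays of equal length")
        if t.size < MIN_CHANNELS:
            raise ValueError(f"need at least {MIN_CHANNELS} channels, got {t.size}")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValueError("channel grid must be uniform with positive width")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def dt(self) -> float:
        """Channel width in ps."""
        return float(self.time_ps[1] - self.time_ps[0])

    @property
    def n_channels(self) -> int:
        return self.time_ps.size

    @property
    def window(self) -> float:
        """Total time window covered by the histogram (ps)."""
        return self.dt * self.n_channels

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ps": self.time_ps, "counts": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecayHistogram":
        df = pd.read_csv(path)
        return cls(df["time_ps"].to_numpy(), df["counts"].to_numpy())


@dataclass(frozen=True)
class IRF:
    """Instrument response function on the same grid as the decays it serves.

    The stored profile is normalised to unit area on construction; the
    original total is kept in :attr:`raw_total` for reference.
    """

    time_ps: np.ndarray
    profile: np.ndarray
    raw_total: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ps, dtype=float)
        p = np.asarray(self.profile, dtype=float)
        if t.ndim != 1 or p.shape != t.shape:
            raise ValueError("time_ps and profile must be 1-D arrays of equal length")
        if np.any(p < 0):
            raise ValueError("IRF must be non-negative")
        total = p.sum()
        if total <= 0:
            raise ValueError("IRF must have positive area")
        object.__setattr__(self, "time_ps", t)
        object.__setattr__(self, "raw_total", float(total))
        object.__setattr__(self, "profile", p / total)

    @property
    def dt(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])

    @property
    def n_channels(self) -> int:
        return self.time_ps.size

    @classmethod
    def gaussian(
        cls,
        n_channels: int,
        dt: float,
        fwhm_ps: float = 90.0,
        center_ps: float | None = None,
    ) -> "IRF":
        """Gaussian IRF with the stated full width at half maximum.

        ``fwhm_ps = 0`` gives a delta function in the channel containing
        ``center_ps``.  When ``center_ps`` is omitted the pulse is centred
        at 5% of the window, leaving room for the rising edge.
        """
        t = (np.arange(n_channels) + 0.5) * dt
        if center_ps is None:
            center_ps = 0.05 * n_channels * dt
        if fwhm_ps < 0:
            raise ValueError("fwhm_ps must be >= 0")
        if fwhm_ps == 0:
            p = np.zeros(n_channels)
            p[min(int(center_ps / dt), n_channels - 1)] = 1.0
        else:
            sigma = fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            p = np.exp(-0.5 * ((t - center_ps) / sigma) ** 2)
        return cls(np.arange(n_channels) * dt, p)

    @classmethod
    def from_decay(cls, hist: DecayHistogram) -> "IRF":
        """Treat a measured histogram (e.g. quenched-dye decay) as the IRF."""
        return cls(hist.time_ps, hist.counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IRF":
        return cls.from_decay(DecayHistogram.from_csv(path))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ps": self.time_ps, "counts": self.profile}).to_csv(
            path, index=False
        )

    def shifted(self, shift_ps: float) -> np.ndarray:
        """IRF profile translated by ``shift_ps`` with linear interpolation.

        Positive shifts move the pulse to later times.  Mass shifted past
        either end of the window is dropped, so the result is re-normalised.
        """
        p = np.interp(self.time_ps - shift_ps, self.time_ps, self.profile,
                      left=0.0, right=0.0)
        total = p.sum()
        if total <= 0:
            raise ValueError("IRF shifted entirely out of the window")
        return p / total
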