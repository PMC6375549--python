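"""Förster-Hoffman lifetime-viscosity calibration for molecular rotors.

A fluorescent molecular rotor obeys the empirical power law

    tau = z * eta**alpha

between its fluorescence lifetime tau and the medium viscosity eta, a
straight line of gradient alpha in log-log space.  BODIPY rotors commonly
show two regimes with distinct gradients; the calibration here is therefore
a continuous two-segment power law with the breakpoint chosen by exhaustive
search over candidate positions in log viscosity.  Continuity at the
breakpoint is imposed so the lifetime-to-viscosity inversion is
single-valued.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "CalibrationFit",
    "ForsterHoffmanModel",
    "fit_forster_hoffman",
    "anchor_curve",
    "QuantumYieldMeasurement",
    "quantum_yield",
    "PM546_METHANOL_REFERENCE",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One (viscosity, lifetime) calibration measurement."""

    eta_cp: float
    tau_ps: float
    temperature_c: float | None = None
    label: str | None = None

    def __post_init__(self):
        if self.eta_cp <= 0 or self.tau_ps <= 0:
            raise ValueError("viscosity and lifetime must be strictly positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise (one- or two-segment) power law tau = z * eta**alpha.

    ``alphas`` and ``log10_z`` are per segment in order of increasing
    viscosity; a single-segment curve has ``eta_break`` None.  Continuity at
    the breakpoint is a construction invariant.
    """

    alphas: tuple[float, ...]
    log10_z: tuple[float, ...]
    eta_break: float | None = None
    eta_range: tuple[float, float] | None = None

    def __post_init__(self):
        if len(self.alphas) != len(self.log10_z) or len(self.alphas) not in (1, 2):
            raise ValueError("curve needs one or two (alpha, log10_z) segments")
        for a in self.alphas:
            if not 0 < a <= 1.5:
                raise ValueError(f"gradient {a} outside (0, 1.5]")
        if len(self.alphas) == 2:
            if self.eta_break is None or self.eta_break <= 0:
                raise ValueError("two-segment curve requires a positive breakpoint")
            lo = self.log10_z[0] + self.alphas[0] * np.log10(self.eta_break)
            hi = self.log10_z[1] + self.alphas[1] * np.log10(self.eta_break)
            if not np.isclose(lo, hi, atol=1e-8):
                raise ValueError("segments do not join continuously at the breakpoint")

    # -- evaluation -------------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.alphas)

    @property
    def tau_break(self) -> float | None:
        """Lifetime at the breakpoint viscosity (ps)."""
        if self.eta_break is None:
            return None
        return float(self.viscosity_to_lifetime(self.eta_break))

    def _segment_of_eta(self, eta: np.ndarray) -> np.ndarray:
        if self.n_segments == 1:
            return np.zeros_like(eta, dtype=int)
        return (eta > self.eta_break).astype(int)

    def viscosity_to_lifetime(self, eta_cp):
        """Forward relation: tau(eta) in ps."""
        eta = np.asarray(eta_cp, dtype=float)
        if np.any(eta <= 0):
            raise ValueError("viscosity must be strictly positive")
        seg = self._segment_of_eta(eta)
        a = np.asarray(self.alphas)[seg]
        lz = np.asarray(self.log10_z)[seg]
        tau = 10.0 ** (lz + a * np.log10(eta))
        return tau if tau.ndim else float(tau)

    def lifetime_to_viscosity(self, tau_ps, with_flags: bool = False):
        """Exact inverse of the piecewise power law.

        With ``with_flags=True`` additionally returns a boolean array marking
        values obtained by extrapolating beyond the calibrated viscosity
        range (allowed, never silent).
        """
        tau = np.asarray(tau_ps, dtype=float)
        if np.any(tau[np.isfinite(tau)] <= 0):
            raise ValueError("lifetime must be strictly positive")
        if self.n_segments == 1:
            seg = np.zeros_like(tau, dtype=int)
        else:
            seg = (tau > self.tau_break).astype(int)
        a = np.asarray(self.alphas)[seg]
        lz = np.asarray(self.log10_z)[seg]
        with np.errstate(invalid="ignore"):
            eta = 10.0 ** ((np.log10(tau) - lz) / a)
        out = eta if eta.ndim else float(eta)
        if with_flags:
            if self.eta_range is None:
                flags = np.zeros_like(eta, dtype=bool)
            else:
                lo, hi = self.eta_range
                with np.errstate(invalid="ignore"):
                    flags = (eta < lo) | (eta > hi)
                flags = np.where(np.isfinite(eta), flags, False)
            return out, (flags if np.ndim(flags) else bool(flags))
        return out

    # -- serialisation ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "alphas": list(self.alphas),
                "log10_z": list(self.log10_z),
                "eta_break": self.eta_break,
                "eta_range": list(self.eta_range) if self.eta_range else None,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            alphas=tuple(d["alphas"]),
            log10_z=tuple(d["log10_z"]),
            eta_break=d.get("eta_break"),
            eta_range=tuple(d["eta_range"]) if d.get("eta_range") else None,
        )


@dataclass
class CalibrationFit:
    """Fitted calibration: the curve plus residual diagnostics."""

    curve: CalibrationCurve
    points: list[CalibrationPoint]
    ssr_log10: float
    residuals_log10: np.ndarray = field(repr=False)

    @property
    def rmse_log10(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_log10**2)))

    def summary(self) -> str:
        c = self.curve
        lines = [f"Forster-Hoffman calibration, {c.n_segments} segment(s), "
                 f"{len(self.points)} points"]
        names = ("low-viscosity", "high-viscosity") if c.n_segments == 2 else ("",)
        for name, a, lz in zip(names, c.alphas, c.log10_z):
            lines.append(f"  {name} gradient alpha = {a:.4f}, "
                         f"log10 z = {lz:.4f}")
        if c.eta_break is not None:
            lines.append(f"  breakpoint eta* = {c.eta_break:.3g} cP "
                         f"(tau* = {c.tau_break:.0f} ps)")
        if c.eta_range is not None:
            lines.append(f"  validity range: {c.eta_range[0]:.3g} - "
                         f"{c.eta_range[1]:.3g} cP")
        lines.append(f"  log10 residual RMSE = {self.rmse_log10:.3g}")
        return "\n".join(lines)


class ForsterHoffmanModel:
    """Piecewise log-log regression of lifetime on viscosity.

    ``fit(n_segments=2)`` searches candidate breakpoints exhaustively over
    the interior data positions and gap midpoints in log10 viscosity,
    fitting the continuous two-slope model by least squares at each, and
    keeps the breakpoint with the smallest total squared residual.
    """

    MIN_POINTS_PER_SEGMENT = 3

    def __init__(self, points):
        pts = [
            p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p)
            for p in points
        ]
        etas = [p.eta_cp for p in pts]
        if len(set(etas)) != len(etas):
            raise ValueError("calibration viscosities must be distinct")
        self.points = sorted(pts, key=lambda p: p.eta_cp)
        self._x = np.log10([p.eta_cp for p in self.points])
        self._y = np.log10([p.tau_ps for p in self.points])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ForsterHoffmanModel":
        """Build from a table with ``viscosity_cp`` and ``lifetime_ps`` columns."""
        return cls(
            [
                CalibrationPoint(
                    row["viscosity_cp"], row["lifetime_ps"],
                    label=row.get("label") if "label" in df.columns else None,
                )
                for _, row in df.iterrows()
            ]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ForsterHoffmanModel":
        return cls.from_dataframe(pd.read_csv(path))

    def _fit_single(self):
        A = np.column_stack([np.ones_like(self._x), self._x])
        beta, *_ = np.linalg.lstsq(A, self._y, rcond=None)
        resid = self._y - A @ beta
        return beta, float(resid @ resid), resid

    def _fit_at_breakpoint(self, b: float):
        # continuous piecewise linear: y = b0 + b1*x + b2*max(x - b, 0)
        hinge = np.maximum(self._x - b, 0.0)
        A = np.column_stack([np.ones_like(self._x), self._x, hinge])
        beta, *_ = np.linalg.lstsq(A, self._y, rcond=None)
        resid = self._y - A @ beta
        return beta, float(resid @ resid), resid

    def fit(self, n_segments: int = 2) -> CalibrationFit:
        if n_segments not in (1, 2):
            raise ValueError("n_segments must be 1 or 2")
        n = self._x.size
        if n < self.MIN_POINTS_PER_SEGMENT * n_segments:
            raise ValueError(
                f"need at least {self.MIN_POINTS_PER_SEGMENT * n_segments} points "
                f"for {n_segments} segment(s), got {n}"
            )
        eta_range = (self.points[0].eta_cp, self.points[-1].eta_cp)
        if n_segments == 1:
            beta, ssr, resid = self._fit_single()
            curve = CalibrationCurve(
                alphas=(float(beta[1]),), log10_z=(float(beta[0]),),
                eta_range=eta_range,
            )
            return CalibrationFit(curve, self.points, ssr, resid)

        m = self.MIN_POINTS_PER_SEGMENT
        # candidates: interior data positions and gap midpoints, keeping at
        # least m points strictly on the left and on the right-or-at of b
        candidates = []
        for i in range(m - 1, n - m):
            candidates.append(self._x[i])
            candidates.append(0.5 * (self._x[i] + self._x[i + 1]))
        best = None
        for b in candidates:
            if np.sum(self._x <= b) < m or np.sum(self._x >= b) < m:
                continue
            beta, ssr, resid = self._fit_at_breakpoint(b)
            if best is None or ssr < best[1] - 1e-15:
                best = (beta, ssr, resid, b)
        if best is None:
            raise ValueError("no admissible breakpoint candidate")
        beta, ssr, resid, b = best
        # polish the breakpoint continuously inside its bracketing data gap
        lo = self._x[np.searchsorted(self._x, b, side="left") - 1]
        hi_idx = np.searchsorted(self._x, b, side="right")
        hi = self._x[min(hi_idx, n - 1)]
        if hi > lo:
            from scipy.optimize import minimize_scalar

            def ssr_of(bb: float) -> float:
                if np.sum(self._x <= bb) < m or np.sum(self._x >= bb) < m:
                    return 1e30  # inadmissible: fewer than m points a side
                return self._fit_at_breakpoint(bb)[1]

            opt = minimize_scalar(
                ssr_of, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            if np.isfinite(opt.fun) and opt.fun < ssr:
                b = float(opt.x)
                beta, ssr, resid = self._fit_at_breakpoint(b)
        a_lo = float(beta[1])
        a_hi = float(beta[1] + beta[2])
        curve = CalibrationCurve(
            alphas=(a_lo, a_hi),
            log10_z=(float(beta[0]), float(beta[0] - beta[2] * b)),
            eta_break=float(10.0**b),
            eta_range=eta_range,
        )
        return CalibrationFit(curve, self.points, ssr, resid)


def fit_forster_hoffman(points, n_segments: int = 2) -> CalibrationCurve:
    """Fit the piecewise Förster-Hoffman relation; returns the curve."""
    return ForsterHoffmanModel(points).fit(n_segments=n_segments).curve


def anchor_curve(point: CalibrationPoint | tuple, alpha: float) -> CalibrationCurve:
    """Single-segment curve with known gradient through one measured pair.

    Useful for consistency checks when only summary (lifetime, viscosity)
    pairs are available rather than the full calibration table.  The curve
    carries no validity range, so every conversion is formally an
    extrapolation and flagged as such.
    """
    if not isinstance(point, CalibrationPoint):
        point = CalibrationPoint(*point)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    log10_z = np.log10(point.tau_ps) - alpha * np.log10(point.eta_cp)
    return CalibrationCurve(alphas=(float(alpha),), log10_z=(float(log10_z),))


# ---------------------------------------------------------------------------
# Relative quantum yield
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantumYieldMeasurement:
    """Inputs for a relative quantum-yield determination.

    ``absorbance`` should sit in the 0.02-0.05 band where fluorescence
    responds linearly to absorbed light; values outside it are accepted
    with a warning.
    """

    intensity: float
    absorbance: float
    refractive_index: float
    qy_ref: float = 1.0

    def __post_init__(self):
        if self.absorbance <= 0:
            raise ValueError("absorbance must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if not 0 < self.qy_ref <= 1:
            raise ValueError("reference quantum yield must be in (0, 1]")
        if not 0.02 <= self.absorbance <= 0.05:
            warnings.warn(
                f"absorbance {self.absorbance} outside the 0.02-0.05 linear band"
            )


#: Packaged reference: PM546 in methanol (QY 0.95, n = 1.3292).
PM546_METHANOL_REFERENCE = dict(refractive_index=1.3292, qy_ref=0.95)


def quantum_yield(
    sample: QuantumYieldMeasurement, reference: QuantumYieldMeasurement
) -> float:
    """Relative quantum yield against a reference dye.

    QY = QY_ref * (n^2 / n_ref^2) * (I / Abs) * (Abs_ref / I_ref)
    """
    if reference.intensity <= 0:
        raise ValueError("reference intensity must be positive")
    return (
        reference.qy_ref
        * (sample.refractive_index**2 / reference.refractive_index**2)
        * (sample.intensity / sample.absorbance)
        * (reference.absorbance / reference.intensity)
    )
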