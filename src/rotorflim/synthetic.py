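"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline — decay fitting, calibration,
colocalisation, trajectory observables — can be exercised on data built
here, where the generating parameters are returned alongside the data so
that analyse-and-compare round trips are exact.

Defaults emulate the acquisition regime of a confocal TCSPC setup with a
20 MHz pulsed diode laser (50 ns window) and a 90 ps instrument response,
and a two-regime Förster-Hoffman rotor calibrated between methanol
(0.6 cP, ~200 ps) and glycerol (1178 cP, ~4.6 ns).

Each generator is a pure function of its spec and seed: identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationPoint
from .decay import IRF, DecayHistogram
from .tcspc import FLIMCube, LifetimeMap, convolve_model
from .trajectory import BilayerTopology, ChainCarbon, LipidRecord, Trajectory

__all__ = [
    "DecaySpec",
    "generate_decay",
    "expected_decay",
    "SceneObject",
    "SceneSpec",
    "generate_flim_cube",
    "generate_coloc_pair",
    "TrajectorySpec",
    "generate_brownian_trajectory",
    "ToyBilayer",
    "generate_toy_bilayer",
    "CalibrationDataset",
    "generate_calibration_set",
]


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecaySpec:
    """Ground truth for one multi-exponential TCSPC decay.

    ``total_counts`` is the expected photon total of the histogram
    (decay plus offset); the relative ``amplitudes`` are rescaled to meet
    it.  Set it to ``None`` to use the amplitudes as absolute expected
    counts.  ``irf`` may be an explicit :class:`~rotorflim.decay.IRF`;
    otherwise a Gaussian of ``irf_fwhm_ps`` centred at ``irf_center_ps``
    (default 5% of the window) is built.  ``irf_fwhm_ps = 0`` gives a
    delta IRF.
    """

    amplitudes: tuple[float, ...] = (1.0,)
    lifetimes_ps: tuple[float, ...] = (2473.0,)
    offset: float = 0.0
    irf: IRF | None = None
    irf_fwhm_ps: float = 90.0
    irf_center_ps: float | None = None
    n_channels: int = 256
    window_ps: float = 50_000.0
    total_counts: float | None = 1e5
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.amplitudes) != len(self.lifetimes_ps) or not self.amplitudes:
            raise ValueError("amplitudes and lifetimes must align (1-3 components)")
        if len(self.amplitudes) > 3:
            raise ValueError("at most 3 components")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if any(t <= 0 for t in self.lifetimes_ps):
            raise ValueError("lifetimes must be strictly positive")
        if len(self.lifetimes_ps) > 1 and any(
            b <= a for a, b in zip(self.lifetimes_ps, self.lifetimes_ps[1:])
        ):
            raise ValueError("multiple lifetimes must be strictly increasing")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if self.window_ps <= 0 or self.n_channels < 32:
            raise ValueError("window must be positive with at least 32 channels")

    @property
    def dt(self) -> float:
        return self.window_ps / self.n_channels

    def build_irf(self) -> IRF:
        if self.irf is not None:
            return self.irf
        return IRF.gaussian(
            self.n_channels, self.dt, self.irf_fwhm_ps, self.irf_center_ps
        )


def expected_decay(spec: DecaySpec) -> np.ndarray:
    """Noiseless expected counts per channel for a decay spec."""
    irf = spec.build_irf()
    shape = convolve_model(
        irf,
        np.asarray(spec.amplitudes, dtype=float),
        np.asarray(spec.lifetimes_ps, dtype=float),
        offset=0.0,
        period=spec.window_ps,
    )
    total_shape = shape.sum()
    if spec.total_counts is not None and total_shape > 0:
        budget = spec.total_counts - spec.offset * spec.n_channels
        if budget < 0:
            raise ValueError("total_counts smaller than the offset contribution")
        shape = shape * (budget / total_shape)
    return shape + spec.offset


def generate_decay(spec: DecaySpec) -> DecayHistogram:
    """Simulate one TCSPC histogram (Poisson draws of the expected model)."""
    expected = expected_decay(spec)
    if spec.poisson_noise:
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    time_ps = np.arange(spec.n_channels) * spec.dt
    return DecayHistogram(time_ps, counts)


# ---------------------------------------------------------------------------
# FLIM scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneObject:
    """One disc-shaped object with its own decay parameters."""

    center: tuple[float, float]  # (y, x) pixels
    radius: float
    lifetimes_ps: tuple[float, ...]
    amplitudes: tuple[float, ...] = (1.0,)
    expected_counts: float = 5000.0  # per in-object pixel


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic FLIM scene: discs on a (possibly empty) background.

    Overlapping objects are resolved by the front-most (earliest listed)
    object.  ``background_counts`` is the expected total per background
    pixel, spread uniformly over channels.
    """

    objects: tuple[SceneObject, ...]
    shape: tuple[int, int] = (32, 32)
    background_counts: float = 0.0


def generate_flim_cube(
    scene: SceneSpec, decay_defaults: DecaySpec
) -> tuple[FLIMCube, LifetimeMap]:
    """Build a FLIM cube plus the ground-truth lifetime map used to build it.

    ``decay_defaults`` supplies the channel grid, IRF, noise flag and seed;
    per-pixel amplitudes/lifetimes/counts come from the scene objects.
    """
    h, w = scene.shape
    n = decay_defaults.n_channels
    k = max(len(o.lifetimes_ps) for o in scene.objects) if scene.objects else 1
    irf = decay_defaults.build_irf()
    rng = np.random.default_rng(decay_defaults.seed)

    data = np.zeros((n, h, w))
    lt = np.full((h, w, k), np.nan)
    am = np.full((h, w, k), np.nan)
    mask = np.zeros((h, w), dtype=bool)

    yy, xx = np.mgrid[0:h, 0:w]
    owner = np.full((h, w), -1, dtype=int)
    for i, obj in enumerate(scene.objects):  # front-most object wins
        inside = (yy - obj.center[0]) ** 2 + (xx - obj.center[1]) ** 2 <= obj.radius**2
        owner[inside & (owner < 0)] = i

    # one expected-decay template per object, then per-pixel Poisson draws
    templates = []
    for obj in scene.objects:
        shape_counts = convolve_model(
            irf,
            np.asarray(obj.amplitudes, dtype=float),
            np.asarray(obj.lifetimes_ps, dtype=float),
            offset=0.0,
            period=decay_defaults.window_ps,
        )
        shape_counts *= obj.expected_counts / shape_counts.sum()
        templates.append(shape_counts)
    background = np.full(n, scene.background_counts / n)

    for y in range(h):
        for x in range(w):
            i = owner[y, x]
            expected = background if i < 0 else templates[i] + background
            if expected.sum() == 0:
                continue
            data[:, y, x] = (
                rng.poisson(expected) if decay_defaults.poisson_noise else expected
            )
            if i >= 0:
                obj = scene.objects[i]
                ki = len(obj.lifetimes_ps)
                lt[y, x, :ki] = obj.lifetimes_ps
                am[y, x, :ki] = obj.amplitudes
                mask[y, x] = True

    truth = LifetimeMap(
        lifetimes=lt,
        amplitudes=am,
        offset=np.zeros((h, w)),
        chisq_reduced=np.zeros((h, w)),
        mask=mask,
    )
    return FLIMCube(data, decay_defaults.dt), truth


# ---------------------------------------------------------------------------
# Colocalisation image pairs
# ---------------------------------------------------------------------------


def generate_coloc_pair(
    n_objects: int,
    overlap_fraction: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    object_size: tuple[int, int] = (6, 8),
    intensity: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Two-channel image pair with a controlled object-overlap fraction.

    Each object is a uniform rectangle; the channel-2 copy is shifted
    sideways so that exactly ``round(overlap_fraction * width)`` of its
    columns coincide with the channel-1 object.  Returns
    ``(image1, image2, expected_M1, expected_M2)`` where the expectations
    are the Manders coefficients of the noiseless pair.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be within [0, 1]")
    oh, ow = object_size
    overlap_cols = int(round(overlap_fraction * ow))
    shift = ow - overlap_cols
    cell_h, cell_w = oh + 2, 2 * ow + 2
    rows, cols = shape[0] // cell_h, shape[1] // cell_w
    if n_objects > rows * cols:
        raise ValueError("too many objects for the image size")
    rng = np.random.default_rng(seed)
    cells = rng.choice(rows * cols, size=n_objects, replace=False)
    img1 = np.zeros(shape)
    img2 = np.zeros(shape)
    for c in cells:
        y0 = (c // cols) * cell_h + 1
        x0 = (c % cols) * cell_w + 1
        img1[y0: y0 + oh, x0: x0 + ow] = intensity
        img2[y0: y0 + oh, x0 + shift: x0 + shift + ow] = intensity
    m_expected = overlap_cols / ow
    if noise_sd > 0:
        img1 = np.clip(img1 + rng.normal(0.0, noise_sd, shape), 0.0, None)
        img2 = np.clip(img2 + rng.normal(0.0, noise_sd, shape), 0.0, None)
    return img1, img2, m_expected, m_expected


# ---------------------------------------------------------------------------
# Brownian trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySpec:
    """2-D Brownian motion in the x-y plane of a periodic box.

    Per-axis increments are independent Gaussians with variance
    ``2 * D * dt``, the Einstein relation for each coordinate.
    """

    n_atoms: int = 100
    diffusion_nm2_per_ps: float = 1e-5
    dt_ps: float = 100.0
    n_frames: int = 1000
    box_nm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms <= 0 or self.n_frames <= 0:
            raise ValueError("n_atoms and n_frames must be positive")
        if self.diffusion_nm2_per_ps < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.dt_ps <= 0 or any(b <= 0 for b in self.box_nm):
            raise ValueError("dt and box lengths must be positive")


def generate_brownian_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Simulate lateral Brownian motion; wrapped and unwrapped coords stored."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box_nm)
    start = rng.uniform(0.0, 1.0, size=(spec.n_atoms, 3)) * box
    start[:, 2] = box[2] / 2.0
    sigma = np.sqrt(2.0 * spec.diffusion_nm2_per_ps * spec.dt_ps)
    steps = rng.normal(0.0, sigma, size=(spec.n_frames - 1, spec.n_atoms, 2))
    unwrapped = np.empty((spec.n_frames, spec.n_atoms, 3))
    unwrapped[0] = start
    unwrapped[1:, :, :2] = start[None, :, :2] + np.cumsum(steps, axis=0)
    unwrapped[1:, :, 2] = start[:, 2]
    wrapped = np.mod(unwrapped, box)
    return Trajectory(
        coords=wrapped,
        box=box,
        dt_ps=spec.dt_ps,
        roles={"diffusing": list(range(spec.n_atoms))},
        unwrapped=unwrapped,
        is_wrapped=True,
    )


# ---------------------------------------------------------------------------
# Toy bilayer
# ---------------------------------------------------------------------------


@dataclass
class ToyBilayer:
    """Constructed bilayer with exactly known observables."""

    trajectory: Trajectory
    topology: BilayerTopology
    expected_scd: float
    expected_shell_counts: dict[str, int]
    beta_deg: float


def generate_toy_bilayer(
    beta_deg: float = 30.0,
    n_per_leaflet: int = 16,
    n_carbons: int = 2,
    waters_per_group: dict[str, int] | None = None,
    water_distance: float = 0.15,
    lipid_spacing: float = 0.8,
    bond_length: float = 0.11,
    probe_xy: tuple[float, float] | None = None,
    include_probe: bool = True,
    n_frames: int = 1,
    dt_ps: float = 100.0,
) -> ToyBilayer:
    """Bilayer of grid-placed lipids whose C-H bonds all make angle beta
    with the box normal, plus waters at known distances from each headgroup.

    The expected order parameter is (3 cos^2 beta - 1)/2 exactly; the
    expected first-shell count per group equals ``waters_per_group`` for
    any cutoff in (water_distance, 0.3] nm.  The probe sits in the upper
    leaflet, so upper lipids are the ``same`` leaflet.
    """
    if not 0.0 <= beta_deg <= 180.0:
        raise ValueError("beta must lie in [0, 180] degrees")
    if bond_length <= 0:
        raise ValueError("degenerate zero-length bond vector")
    if waters_per_group is None:
        waters_per_group = {"onium": 3, "phosphate": 2, "ester": 1}
    beta = np.radians(beta_deg)
    ch_vec = bond_length * np.array([np.sin(beta), 0.0, np.cos(beta)])

    n_side = int(np.ceil(np.sqrt(n_per_leaflet)))
    box = np.array([n_side * lipid_spacing, n_side * lipid_spacing, 6.0])
    z_mid = box[2] / 2.0
    if probe_xy is None:
        probe_xy = (box[0] / 2.0, box[1] / 2.0)

    positions: list[np.ndarray] = []
    lipids: list[LipidRecord] = []

    def add_atom(p) -> int:
        positions.append(np.asarray(p, dtype=float))
        return len(positions) - 1

    for leaflet_sign in (+1, -1):
        z_p = z_mid + leaflet_sign * 1.0
        count = 0
        for gy in range(n_side):
            for gx in range(n_side):
                if count >= n_per_leaflet:
                    break
                x = (gx + 0.5) * lipid_spacing
                y = (gy + 0.5) * lipid_spacing
                p_idx = add_atom([x, y, z_p])
                n_idx = add_atom([x, y, z_p + 0.5 * leaflet_sign])
                e1 = add_atom([x + 0.05, y, z_p - 0.5 * leaflet_sign])
                e2 = add_atom([x - 0.05, y, z_p - 0.5 * leaflet_sign])
                chains = {}
                for chain_name, dx in (("sn1", +0.2), ("sn2", -0.2)):
                    carbons = []
                    for ci in range(n_carbons):
                        cz = z_p - (0.9 + 0.3 * ci) * leaflet_sign
                        c_idx = add_atom([x + dx, y, cz])
                        h_idx = add_atom(positions[c_idx] + ch_vec)
                        carbons.append(ChainCarbon(c_idx, (h_idx,)))
                    chains[chain_name] = tuple(carbons)
                lipids.append(
                    LipidRecord(
                        phosphorus=p_idx,
                        onium=n_idx,
                        phosphate=(p_idx,),
                        ester_oxygens=(e1, e2),
                        sn1=chains["sn1"],
                        sn2=chains["sn2"],
                    )
                )
                count += 1

    # waters in the x-y plane around each group's first atom, spread evenly
    water_indices: list[int] = []
    for lip in lipids:
        for grp, k in waters_per_group.items():
            anchor = positions[lip.group_atoms(grp)[0]]
            for j in range(k):
                theta = 2.0 * np.pi * j / max(k, 1)
                offset = water_distance * np.array(
                    [np.cos(theta), np.sin(theta), 0.0]
                )
                water_indices.append(add_atom(anchor + offset))

    probe_idx = None
    if include_probe:
        probe_idx = add_atom([probe_xy[0], probe_xy[1], z_mid + 1.2])

    frame = np.array(positions)
    coords = np.repeat(frame[None, :, :], n_frames, axis=0)
    traj = Trajectory(
        coords=coords, box=box, dt_ps=dt_ps, roles={}, is_wrapped=True
    )
    topo = BilayerTopology(
        lipids=lipids, water_oxygens=water_indices, probe_atom=probe_idx
    )
    expected_scd = 0.5 * (3.0 * np.cos(beta) ** 2 - 1.0)
    return ToyBilayer(traj, topo, float(expected_scd), dict(waters_per_group), beta_deg)


# ---------------------------------------------------------------------------
# Calibration datasets
# ---------------------------------------------------------------------------

# Defaults chosen so the noiseless curve reproduces the rotor's dynamic
# range: ~200 ps at 0.6 cP (methanol) through ~4.6 ns at 1178 cP (glycerol)
# with gradients 0.25 / 0.63.
_DEFAULT_ALPHA_LOW = 0.25
_DEFAULT_ALPHA_HIGH = 0.63
_DEFAULT_LOG10_Z = np.log10(200.0) - _DEFAULT_ALPHA_LOW * np.log10(0.6)
_DEFAULT_ETA_BREAK = 10.0 ** (
    (
        _DEFAULT_LOG10_Z
        - (np.log10(4600.0) - _DEFAULT_ALPHA_HIGH * np.log10(1178.0))
    )
    / (_DEFAULT_ALPHA_HIGH - _DEFAULT_ALPHA_LOW)
)


@dataclass
class CalibrationDataset:
    """Generated calibration points plus the curve that generated them."""

    points: list[CalibrationPoint]
    true_curve: CalibrationCurve

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "viscosity_cp": [p.eta_cp for p in self.points],
                "lifetime_ps": [p.tau_ps for p in self.points],
                "label": [p.label for p in self.points],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def generate_calibration_set(
    z: float | None = None,
    alpha_low: float = _DEFAULT_ALPHA_LOW,
    alpha_high: float = _DEFAULT_ALPHA_HIGH,
    eta_break: float | None = None,
    viscosity_grid: np.ndarray | None = None,
    relative_noise: float = 0.05,
    seed: int = 0,
) -> CalibrationDataset:
    """Lifetime-viscosity points on a continuous two-segment power law.

    With ``relative_noise = 0`` the points lie exactly on the law; noise is
    multiplicative Gaussian on the lifetimes.  Passing
    ``alpha_low == alpha_high`` degenerates to a single power law.
    """
    if alpha_low <= 0 or alpha_high <= 0:
        raise ValueError("gradients must be positive")
    if z is None:
        z = 10.0**_DEFAULT_LOG10_Z
    if eta_break is None:
        eta_break = _DEFAULT_ETA_BREAK
    if viscosity_grid is None:
        viscosity_grid = np.geomspace(0.6, 1178.0, 16)
    log10_z_low = np.log10(z)
    if np.isclose(alpha_low, alpha_high):
        curve = CalibrationCurve(
            alphas=(float(alpha_low),), log10_z=(float(log10_z_low),),
            eta_range=(float(viscosity_grid.min()), float(viscosity_grid.max())),
        )
    else:
        log10_z_high = log10_z_low + (alpha_low - alpha_high) * np.log10(eta_break)
        curve = CalibrationCurve(
            alphas=(float(alpha_low), float(alpha_high)),
            log10_z=(float(log10_z_low), float(log10_z_high)),
            eta_break=float(eta_break),
            eta_range=(float(viscosity_grid.min()), float(viscosity_grid.max())),
        )
    taus = np.asarray(curve.viscosity_to_lifetime(viscosity_grid), dtype=float)
    if relative_noise > 0:
        rng = np.random.default_rng(seed)
        taus = taus * np.clip(
            1.0 + rng.normal(0.0, relative_noise, taus.shape), 1e-6, None
        )
    points = [
        CalibrationPoint(float(e), float(t)) for e, t in zip(viscosity_grid, taus)
    ]
    return CalibrationDataset(points, curve)
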