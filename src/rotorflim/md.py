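"""Bilayer trajectory observables: lateral MSD, C-H order parameters,
radial distribution functions and first-shell hydration tables.

All distances use the minimum-image convention in an orthorhombic box.
Lateral quantities (MSD, lipid-to-probe distance) live in the x-y plane;
the bilayer normal is fixed to the box z axis, the standard choice for a
planar bilayer.

The lateral mean square displacement for a selection of N atoms is

    MSD(t) = (1/N) sum_n [ (x_n(t) - x_n(t_ref))^2 + (y_n(t) - y_n(t_ref))^2 ]

optionally averaged over several reference times.  The carbon-hydrogen
order parameter of an acyl-chain carbon is

    S_CD = (3 <cos^2 beta> - 1) / 2

with beta the angle each C-H bond makes with the bilayer normal: +1 for
bonds along the normal, -0.5 perpendicular, 0 isotropic.  Hydration is the
number of water oxygens inside a group-specific first-shell cutoff, the
cutoff being the first minimum after the first peak of the corresponding
radial distribution function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .trajectory import BilayerTopology, Trajectory

__all__ = [
    "DistanceBins",
    "MSDResult",
    "msd_xy",
    "unwrap",
    "assign_leaflet",
    "order_parameter",
    "RDFResult",
    "rdf",
    "first_shell_cutoff",
    "HydrationTable",
    "hydration_counts",
    "HYDRATION_GROUPS",
]

HYDRATION_GROUPS = ("onium", "phosphate", "ester")


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


@dataclass(frozen=True)
class DistanceBins:
    """Lateral (x-y) distance bins around the probe, closed-left/open-right.

    The default edges 0.7, 1.0, 1.6 and 2.0 nm define five ranges; the
    innermost one corresponds to first-neighbour lipids of the probe.
    """

    edges: tuple[float, ...] = (0.7, 1.0, 1.6, 2.0)

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.size == 0 or np.any(np.diff(e) <= 0) or e[0] <= 0:
            raise ValueError("bin edges must be positive and strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    @property
    def labels(self) -> list[str]:
        e = self.edges
        out = [f"d<{e[0]:g}"]
        out += [f"{a:g}<=d<{b:g}" for a, b in zip(e[:-1], e[1:])]
        out.append(f"d>={e[-1]:g}")
        return out

    def assign(self, d) -> np.ndarray:
        """Bin index for each distance; a partition (every d lands once)."""
        return np.searchsorted(np.asarray(self.edges), np.asarray(d), side="right")


# ---------------------------------------------------------------------------
# Lateral MSD
# ---------------------------------------------------------------------------


@dataclass
class MSDResult:
    """Lateral MSD versus lag time with the number of (origin, atom) pairs."""

    lag_ps: np.ndarray
    msd_nm2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_ps": self.lag_ps, "msd_nm2": self.msd_nm2, "n_pairs": self.n_pairs}
        )

    def fit_diffusion(self, lag_fraction: float = 0.25) -> tuple[float, float]:
        """Fit MSD = 4 D t + c over the short-lag window; returns (D, slope).

        Only the first ``lag_fraction`` of lags is used, where origin
        averaging is best and free diffusion is least affected by noise.
        D is in nm^2/ps for lags in ps.
        """
        n_fit = max(int(self.lag_ps.size * lag_fraction), 3)
        t, m = self.lag_ps[1:n_fit], self.msd_nm2[1:n_fit]
        slope, _ = np.polyfit(t, m, 1)
        return float(slope) / 4.0, float(slope)


def msd_xy(
    traj: Trajectory,
    selection: str | np.ndarray = "all",
    origin_stride: int | None = 10,
    max_lag: int | None = None,
) -> MSDResult:
    """Lateral mean square displacement of the selected atoms.

    ``origin_stride`` spaces the reference times in frames; ``None`` uses
    the single reference t_ref = 0.  The z coordinate is excluded
    throughout.  Requires continuous (unwrapped) coordinates.
    """
    if traj.unwrapped is not None:
        coords = traj.unwrapped
    elif not traj.is_wrapped:
        coords = traj.coords
    else:
        raise ValueError(
            "trajectory is wrapped: periodic jumps would corrupt displacements; "
            "apply rotorflim.md.unwrap() first"
        )
    idx = traj.select(selection) if isinstance(selection, str) else np.asarray(selection)
    X = coords[:, idx, :2]
    n_frames, n_atoms = X.shape[0], X.shape[1]
    if max_lag is None:
        max_lag = n_frames - 1
    max_lag = min(max_lag, n_frames - 1)
    origins = [0] if origin_stride is None else list(range(0, n_frames - 1, origin_stride))
    sums = np.zeros(max_lag + 1)
    pairs = np.zeros(max_lag + 1, dtype=int)
    for o in origins:
        stop = min(o + max_lag + 1, n_frames)
        d = X[o:stop] - X[o]
        sq = np.einsum("lac,lac->l", d, d)  # sum over atoms and x,y per lag
        sums[: stop - o] += sq
        pairs[: stop - o] += n_atoms
    covered = pairs > 0
    msd = np.full(max_lag + 1, np.nan)
    msd[covered] = sums[covered] / pairs[covered]
    return MSDResult(np.arange(max_lag + 1) * traj.dt_ps, msd, pairs)


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps by accumulating minimum-image increments.

    Assumes frames are saved often enough that no atom moves half a box
    length between consecutive frames; near-ambiguous jumps trigger a
    warning about undersampled frames.
    """
    d = np.diff(traj.coords, axis=0)
    dmin = _min_image(d, traj.box)
    if np.any(np.abs(dmin) > 0.45 * traj.box):
        warnings.warn(
            "inter-frame displacement close to half the box: frames may be "
            "undersampled and the unwrapping ambiguous"
        )
    unwrapped = np.concatenate(
        [traj.coords[:1], traj.coords[0] + np.cumsum(dmin, axis=0)], axis=0
    )
    return Trajectory(
        coords=traj.coords,
        box=traj.box,
        dt_ps=traj.dt_ps,
        roles=traj.roles,
        unwrapped=unwrapped,
        is_wrapped=traj.is_wrapped,
    )


# ---------------------------------------------------------------------------
# Leaflets and probe-distance binning
# ---------------------------------------------------------------------------


def assign_leaflet(
    traj: Trajectory, topology: BilayerTopology, frame: int = 0
) -> np.ndarray:
    """Classify each lipid as ``same`` or ``opposite`` leaflet as the probe.

    The midplane is the mean z of all lipid phosphorus atoms in the frame.
    A lipid sitting exactly on the midplane is resolved by majority over
    the other frames and flagged with a warning.
    """
    if topology.probe_atom is None:
        raise ValueError("leaflet assignment relative to the probe needs a probe atom")
    p_idx = topology.phosphorus_indices()
    z = traj.coords[frame, p_idx, 2]
    mid = z.mean()
    probe_side = np.sign(traj.coords[frame, topology.probe_atom, 2] - mid)
    if probe_side == 0:
        raise ValueError("probe sits exactly on the midplane")
    side = np.sign(z - mid)
    ambiguous = side == 0
    if ambiguous.any():
        warnings.warn(
            f"{int(ambiguous.sum())} lipid(s) exactly at the midplane; "
            "assigned by majority over the other frames"
        )
        for i in np.nonzero(ambiguous)[0]:
            other = np.delete(np.arange(traj.n_frames), frame)
            zs = traj.coords[other, p_idx[i], 2]
            mids = traj.coords[other][:, p_idx, 2].mean(axis=1)
            s = np.sign(zs - mids)
            side[i] = 1.0 if (s > 0).sum() >= (s < 0).sum() else -1.0
    return np.where(side == probe_side, "same", "opposite")


def _lateral_probe_distance(
    traj: Trajectory, topology: BilayerTopology, frame: int
) -> np.ndarray:
    """x-y minimum-image distance of each lipid phosphorus to the probe."""
    p = traj.coords[frame, topology.phosphorus_indices(), :2]
    q = traj.coords[frame, topology.probe_atom, :2]
    d = _min_image(p - q, traj.box[:2])
    return np.hypot(d[:, 0], d[:, 1])


# ---------------------------------------------------------------------------
# C-H order parameter
# ---------------------------------------------------------------------------


def _carbon_scd(
    coords_frame: np.ndarray, carbon: int, hydrogens, box: np.ndarray
) -> float:
    """S_CD for one carbon: per-bond values averaged over its hydrogens."""
    vals = []
    c = coords_frame[carbon]
    for h in hydrogens:
        v = _min_image(coords_frame[h] - c, box)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("zero-length C-H bond vector")
        cosb = v[2] / norm
        vals.append(0.5 * (3.0 * cosb**2 - 1.0))
    return float(np.mean(vals))


def order_parameter(
    traj: Trajectory,
    topology: BilayerTopology,
    bins: DistanceBins | None = None,
) -> pd.DataFrame:
    """Per-carbon C-H order parameters grouped by leaflet and probe distance.

    One sample is one (lipid, frame) value of a carbon: per-bond S_CD
    averaged over that carbon's hydrogens.  With a probe present, lipids
    are binned each frame by lateral distance to the probe (dynamic
    assignment) and split into same/opposite leaflet; without a probe a
    single ``all``/``bilayer`` group is reported.

    Returns a long-form table: chain, carbon_index, leaflet, bin,
    scd_mean, scd_sd, n_samples.
    """
    binned = topology.probe_atom is not None
    if bins is None:
        bins = DistanceBins()
    acc: dict[tuple, list[float]] = {}
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        if binned:
            leaflets = assign_leaflet(traj, topology, frame=f)
            dists = _lateral_probe_distance(traj, topology, f)
            bin_idx = bins.assign(dists)
        for li, lip in enumerate(topology.lipids):
            leaf = leaflets[li] if binned else "bilayer"
            blabel = bins.labels[bin_idx[li]] if binned else "all"
            for chain_name, chain in (("sn1", lip.sn1), ("sn2", lip.sn2)):
                for ci, cc in enumerate(chain, start=1):
                    s = _carbon_scd(frame, cc.carbon, cc.hydrogens, traj.box)
                    acc.setdefault((chain_name, ci, leaf, blabel), []).append(s)
    rows = []
    for (chain_name, ci, leaf, blabel), vals in sorted(acc.items()):
        v = np.asarray(vals)
        rows.append(
            {
                "chain": chain_name,
                "carbon_index": ci,
                "leaflet": leaf,
                "bin": blabel,
                "scd_mean": float(v.mean()),
                "scd_sd": float(v.std()),
                "n_samples": int(v.size),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Radial distribution function and hydration
# ---------------------------------------------------------------------------


@dataclass
class RDFResult:
    """Shell-volume-normalised pair density g(r)."""

    r_nm: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    dr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r_nm, "g": self.g, "counts": self.counts})


def _pair_distances(
    frame: np.ndarray, centers: np.ndarray, partners: np.ndarray, box: np.ndarray
) -> np.ndarray:
    d = _min_image(frame[partners][None, :, :] - frame[centers][:, None, :], box)
    dist = np.sqrt(np.einsum("cpk,cpk->cp", d, d))
    # exclude self-pairs when the selections overlap
    same = centers[:, None] == partners[None, :]
    return dist[~same]


def rdf(
    traj: Trajectory,
    centers: str | np.ndarray,
    partners: str | np.ndarray,
    r_max: float,
    dr: float = 0.02,
) -> RDFResult:
    """Radial distribution function of partners around centers."""
    c = traj.select(centers) if isinstance(centers, str) else np.asarray(centers, int)
    p = traj.select(partners) if isinstance(partners, str) else np.asarray(partners, int)
    if c.size == 0 or p.size == 0:
        raise ValueError("empty center or partner selection")
    if r_max > 0.5 * traj.box.min():
        raise ValueError("r_max exceeds half the smallest box length")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(edges.size - 1)
    for f in range(traj.n_frames):
        dist = _pair_distances(traj.coords[f], c, p, traj.box)
        h, _ = np.histogram(dist, bins=edges)
        counts += h
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    volume = float(np.prod(traj.box))
    rho = p.size / volume
    norm = traj.n_frames * c.size * shell_vol * rho
    g = counts / norm
    r = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r, g, counts, dr)


def first_shell_cutoff(
    result: RDFResult, smooth_window: int = 3
) -> float | None:
    """First local minimum of g(r) after its first peak.

    A moving average of ``smooth_window`` bins (1 = raw) suppresses bin
    noise.  Returns ``None`` (with a warning) when g(r) has no
    peak-then-minimum structure, e.g. a flat or monotone profile.
    """
    g = result.g
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")
    maxima = argrelextrema(g, np.greater)[0]
    minima = argrelextrema(g, np.less)[0]
    for peak in maxima:
        after = minima[minima > peak]
        if after.size:
            return float(result.r_nm[after[0]])
    warnings.warn("g(r) has no first peak followed by a minimum; no cutoff")
    return None


@dataclass
class HydrationTable:
    """Mean and SD of first-shell water counts per group, leaflet and bin.

    The full 3 (headgroup groups) x 2 (leaflets) x n_bins grid is always
    present; combinations never sampled have NaN means and n = 0.
    """

    data: pd.DataFrame
    bins: DistanceBins = field(default_factory=DistanceBins)

    def wide(self) -> pd.DataFrame:
        """Table-style layout: rows are distance bins, columns group x leaflet."""
        return self.data.pivot_table(
            index="bin", columns=["group", "leaflet"], values="mean",
            sort=False, dropna=False,
        ).reindex(self.bins.labels)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def hydration_counts(
    traj: Trajectory,
    topology: BilayerTopology,
    cutoffs: dict[str, float],
    bins: DistanceBins | None = None,
) -> HydrationTable:
    """First-shell water counts around onium, phosphate and ester groups.

    For each frame and lipid, water oxygens within the group's cutoff of
    *any* of the group's atoms are counted once (a union over atoms, which
    matters for the two ester oxygens).  Counts are averaged over frames
    and over the lipids falling in each (leaflet, distance-bin) cell.
    """
    for grp in HYDRATION_GROUPS:
        if grp not in cutoffs:
            raise ValueError(f"missing cutoff for group {grp!r}")
        if cutoffs[grp] <= 0:
            raise ValueError("cutoffs must be positive")
    if not topology.water_oxygens:
        raise ValueError("topology defines no water oxygens")
    if bins is None:
        bins = DistanceBins()
    binned = topology.probe_atom is not None
    waters = np.asarray(topology.water_oxygens, dtype=int)
    acc: dict[tuple, list[int]] = {}
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        w = frame[waters]
        if binned:
            leaflets = assign_leaflet(traj, topology, frame=f)
            bin_idx = bins.assign(_lateral_probe_distance(traj, topology, f))
        for li, lip in enumerate(topology.lipids):
            leaf = leaflets[li] if binned else "bilayer"
            blabel = bins.labels[bin_idx[li]] if binned else "all"
            for grp in HYDRATION_GROUPS:
                atoms = np.asarray(lip.group_atoms(grp), dtype=int)
                d = _min_image(w[None, :, :] - frame[atoms][:, None, :], traj.box)
                dist = np.sqrt(np.einsum("apk,apk->ap", d, d))
                inside = (dist < cutoffs[grp]).any(axis=0)
                acc.setdefault((grp, leaf, blabel), []).append(int(inside.sum()))
    leaf_labels = ("same", "opposite") if binned else ("bilayer",)
    bin_labels = bins.labels if binned else ["all"]
    rows = []
    for grp in HYDRATION_GROUPS:
        for leaf in leaf_labels:
            for blabel in bin_labels:
                vals = acc.get((grp, leaf, blabel), [])
                v = np.asarray(vals, dtype=float)
                rows.append(
                    {
                        "group": grp,
                        "leaflet": leaf,
                        "bin": blabel,
                        "mean": float(v.mean()) if v.size else float("nan"),
                        "sd": float(v.std()) if v.size else float("nan"),
                        "n": int(v.size),
                    }
                )
    return HydrationTable(pd.DataFrame(rows), bins)
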