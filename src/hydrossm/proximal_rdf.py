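"""Proximal radial distribution function and hydration-shell boundaries.

The pRDF ``gp(r)`` bins solvent oxygens in thin cylindrical annuli by
their minimum-image distance to a fixed z-aligned axis (the stretched
polymer backbone), over the full box height ``lz``, and normalises by the
bulk density and the annulus volume:

    gp(r_k) = <count in [r_k, r_k + dr)> / (rho * 2 pi rbar_k * lz * dr).

Hydration shells are delimited from ``gp``:

* the inner boundary ``r1`` of the first shell is the smallest radius at
  which the cumulative mean number of solvent molecules in the solid
  cylinder of height lz, ``rho * sum 2 pi rbar lz dr gp``, first exceeds
  one molecule (midpoint quadrature, returned as a bin edge);
* the outer boundaries are the successive local minima of the (smoothed)
  ``gp`` curve beyond its first maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import SOLVENT_OXYGEN, Trajectory
from .ssm_core import AxisSpec, _radial_distances

__all__ = ["ProximalRDF", "ShellBoundaries", "compute_prdf", "inner_boundary", "shell_minima"]

DEFAULT_DR = 0.005  # nm
DEFAULT_SMOOTH_WINDOW = 5  # bins


@dataclass
class ProximalRDF:
    """Estimated pRDF on uniform bins, plus the normalisation it used."""

    edges: np.ndarray  # (n_bins + 1,)
    gp: np.ndarray  # (n_bins,)
    rho: float  # bulk solvent density, nm^-3
    lz: float  # chain/box height, nm
    mean_counts: np.ndarray  # mean per-bin counts (diagnostics / conservation)
    n_frames: int

    @property
    def dr(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r_nm": self.centers, "gp": self.gp})


@dataclass(frozen=True)
class ShellBoundaries:
    """Hydration-shell delimiters: inner onset r1 and outer minima b1 < b2 < ...

    Shell 1 spans [r1, b1), shell k >= 2 spans [b_{k-1}, b_k).
    """

    r1: float
    boundaries: tuple

    def __post_init__(self):
        bs = tuple(float(b) for b in self.boundaries)
        if len(bs) < 1:
            raise ValueError("at least one outer boundary is required")
        if not all(x < y for x, y in zip((self.r1,) + bs, bs)):
            raise ValueError("boundaries must satisfy r1 < b1 < b2 < ...")
        object.__setattr__(self, "boundaries", bs)

    @property
    def n_shells(self) -> int:
        return len(self.boundaries)

    def shell_interval(self, shell_id: int) -> tuple[float, float]:
        """Radial interval [r_in, r_out) of shell ``shell_id`` (1-based)."""
        if not 1 <= shell_id <= self.n_shells:
            raise ValueError(f"shell_id must be in 1..{self.n_shells}")
        lo = self.r1 if shell_id == 1 else self.boundaries[shell_id - 2]
        return (lo, self.boundaries[shell_id - 1])

    @property
    def widths(self) -> tuple:
        return tuple(
            self.shell_interval(k)[1] - self.shell_interval(k)[0]
            for k in range(1, self.n_shells + 1)
        )


def compute_prdf(
    traj: Trajectory,
    axis: AxisSpec,
    dr: float = DEFAULT_DR,
    r_max: float = 1.5,
    rho: float | None = None,
    label: str = SOLVENT_OXYGEN,
) -> ProximalRDF:
    """Estimate the proximal RDF of ``label`` particles around the axis.

    ``rho`` defaults to the trajectory-mean bulk density
    ``<N_solvent>/V_b``.  ``r_max`` must not exceed half the smaller in-
    plane box side, or the minimum image would fold annuli onto each
    other.
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    n_bins = int(round(r_max / dr))
    edges = dr * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    n_frames = 0
    total = 0.0
    lz = None
    for frame in traj:
        if lz is None:
            lz = frame.lz
            v_box = frame.volume
            half_min = min(frame.box_lengths[0], frame.box_lengths[1]) / 2.0
            if r_max > half_min + 1e-9:
                raise ValueError(
                    f"r_max={r_max} nm exceeds half the smaller box side "
                    f"({half_min:.4f} nm): minimum image invalid"
                )
        pos = frame.positions[frame.labels == label]
        total += len(pos)
        r = _radial_distances(frame, axis, pos)
        hist, _ = np.histogram(r, bins=edges)
        counts += hist
        n_frames += 1
    if n_frames == 0:
        raise ValueError("trajectory is empty")
    mean_counts = counts / n_frames
    if rho is None:
        rho = total / n_frames / v_box
    centers = 0.5 * (edges[:-1] + edges[1:])
    norm = rho * 2.0 * np.pi * centers * lz * dr
    return ProximalRDF(
        edges=edges,
        gp=mean_counts / norm,
        rho=float(rho),
        lz=lz,
        mean_counts=mean_counts,
        n_frames=n_frames,
    )


def cumulative_count(prdf: ProximalRDF) -> np.ndarray:
    """Mean number of particles within radius edge[k+1] (midpoint rule).

    By the binning identity this equals the cumulative sum of the mean
    per-bin counts exactly when rho is the density used to normalise.
    """
    centers = prdf.centers
    return np.cumsum(prdf.rho * 2.0 * np.pi * centers * prdf.lz * prdf.dr * prdf.gp)


def inner_boundary(prdf: ProximalRDF, full_output: bool = False):
    """Onset radius r1 of the first hydration shell.

    Returns the smallest bin edge at which the cumulative mean count of
    solvent in the solid cylinder of height lz first exceeds one
    molecule.  The cumulative integral uses the midpoint rule on the bin
    centres; r1 is reported as the upper edge of the crossing bin
    (``full_output=True`` also returns the bracketing bin index).
    """
    cum = cumulative_count(prdf)
    above = np.nonzero(cum > 1.0)[0]
    if len(above) == 0:
        raise ValueError(
            f"cumulative solvent count never exceeds 1 within r_max={prdf.edges[-1]} nm"
        )
    k = int(above[0])
    r1 = float(prdf.edges[k + 1])
    return (r1, k) if full_output else r1


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation."""
    if window <= 1:
        return y.copy()
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def shell_minima(
    prdf: ProximalRDF,
    n_shells: int = 2,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> ShellBoundaries:
    """Detect the first ``n_shells`` hydration-shell outer boundaries.

    The gp curve is smoothed with a centered moving average, the first
    local maximum beyond r1 is located, and the first ``n_shells`` strict
    local minima after it become the shell boundaries (positions are bin
    centres; plateau ties break towards smaller r).  Finding fewer minima
    than requested is an error that names how many were found.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    r1 = inner_boundary(prdf)
    centers = prdf.centers
    g = _smooth(prdf.gp, smooth_window)

    start = int(np.searchsorted(centers, r1))
    # first strict local maximum at or beyond r1
    i_max = None
    for i in range(max(start, 1), len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1]:
            i_max = i
            break
    if i_max is None:
        raise ValueError("no local maximum of gp found beyond r1 (monotone profile?)")

    minima = []
    i = i_max + 1
    while i < len(g) - 1 and len(minima) < n_shells:
        if g[i] < g[i - 1] and g[i] <= g[i + 1]:
            minima.append(float(centers[i]))
            # skip to the next rise so a flat basin yields a single boundary
            j = i + 1
            while j < len(g) - 1 and g[j] <= g[i]:
                j += 1
            # require an intervening maximum before the next minimum counts
            while j < len(g) - 1 and not (g[j] > g[j - 1] and g[j] >= g[j + 1]):
                j += 1
            i = j + 1
        else:
            i += 1
    if len(minima) < n_shells:
        raise ValueError(
            f"requested {n_shells} shell boundaries but found only {len(minima)} "
            f"local minima of gp within r_max={prdf.edges[-1]} nm"
        )
    return ShellBoundaries(r1=r1, boundaries=tuple(minima))
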