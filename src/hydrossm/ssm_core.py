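"""Small-system method core: fluctuation sampling and finite-size extrapolation.

Particle-number fluctuations are sampled in open cylindrical subvolumes
(solid cylinders of radius ``rc`` or concentric cylindrical shells
``[r_in, r_out)``) of height ``L`` around a fixed z-aligned axis embedded
in a closed simulation box of volume ``V_b``.  For each subvolume the
inverse thermodynamic correction factor is the normalised variance

    1/Gamma(L) = (<N^2> - <N>^2) / <N>,

which for subvolume sizes between the correlation length and the box
dimension follows the small-system scaling law

    1/Gamma(L) = 1/Gamma_inf + c / L,

so an ordinary least-squares fit of 1/Gamma against 1/L inside a window
of intermediate ``L`` extrapolates to the thermodynamic-limit intercept.
For bulk solvent a second extrapolation of the per-radius intercepts
against 1/rc yields the bulk limit, which converts to the isothermal
compressibility through

    1/Gamma_inf = rho * kB * T * chi_T.

Statistical uncertainty is delegated entirely to block averaging: the
trajectory is split into ``n_blocks`` contiguous windows (four by
default), every quantity is recomputed per block, and the standard error
is the between-block scatter.  Overlapping z-translations of the
observation window within one frame are pooled as if independent — they
improve the mean but their correlation is absorbed by the block SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .trajectory_io import SOLVENT_OXYGEN, Frame, Trajectory, minimum_image

__all__ = [
    "KB_BAR_NM3",
    "AxisSpec",
    "CylinderShell",
    "SubvolumeSpec",
    "FluctuationProfile",
    "ScalingFit",
    "CompressibilityResult",
    "count_particles",
    "sample_profile",
    "fit_scaling",
    "extrapolate_radius",
    "compressibility",
    "block_average",
    "block_slices",
    "default_L_grid",
    "default_rc_grid",
]

#: Boltzmann constant in bar nm^3 / K (1.380649e-23 J/K, 1 bar nm^3 = 1e-22 J),
#: so that rho[nm^-3] * KB * T[K] is a pressure in bar.
KB_BAR_NM3 = 0.1380649

# Default grids: L and the z-translation step advance in 0.1 nm steps,
# cylinder radii span 0.25-2.5 nm.
DEFAULT_Z_STEP = 0.1
BULK_L_WINDOW = (1.0, 2.0)
SHELL_L_WINDOW = (1.2, 2.5)
RC_WINDOW_MAX = 1.5


def default_L_grid(lz: float, step: float = 0.1, L_max: float | None = None) -> np.ndarray:
    """Subvolume heights 0.1, 0.2, ... nm up to ``L_max`` (default lz)."""
    top = lz if L_max is None else min(L_max, lz)
    n = int(np.floor(top / step + 1e-9))
    return step * np.arange(1, n + 1)


def default_rc_grid(lo: float = 0.25, hi: float = 2.5, step: float = 0.25) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(0, n + 1)


@dataclass(frozen=True)
class AxisSpec:
    """z-aligned reference axis anchored at (x0, y0) in the box cross-section."""

    x0: float
    y0: float

    @classmethod
    def box_center(cls, box_lengths) -> "AxisSpec":
        box = np.asarray(box_lengths, dtype=float)
        return cls(box[0] / 2.0, box[1] / 2.0)

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x0, self.y0])


@dataclass(frozen=True)
class CylinderShell:
    """Radial geometry of an observation volume: the annulus [r_in, r_out).

    A solid cylinder of radius rc is the degenerate case r_in = 0.
    """

    r_in: float
    r_out: float

    def __post_init__(self):
        if not (0 <= self.r_in < self.r_out):
            raise ValueError(f"need 0 <= r_in < r_out, got [{self.r_in}, {self.r_out})")

    @classmethod
    def cylinder(cls, rc: float) -> "CylinderShell":
        return cls(0.0, rc)

    def cross_section_area(self) -> float:
        return np.pi * (self.r_out**2 - self.r_in**2)

    def validate_for_box(self, box_lengths) -> None:
        half_min = min(box_lengths[0], box_lengths[1]) / 2.0
        if self.r_out > half_min + 1e-9:
            raise ValueError(
                f"r_out={self.r_out} nm exceeds half the smaller box side "
                f"({half_min:.4f} nm); minimum-image radial distances would be invalid"
            )


@dataclass(frozen=True)
class SubvolumeSpec:
    """One observation subvolume: radial geometry + height L at offset z0."""

    geometry: CylinderShell
    L: float
    z0: float = 0.0

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("L must be > 0")

    @classmethod
    def cylinder(cls, rc: float, L: float, z0: float = 0.0) -> "SubvolumeSpec":
        return cls(CylinderShell.cylinder(rc), L, z0)

    @classmethod
    def shell(cls, r_in: float, r_out: float, L: float, z0: float = 0.0) -> "SubvolumeSpec":
        return cls(CylinderShell(r_in, r_out), L, z0)

    def volume(self) -> float:
        return self.geometry.cross_section_area() * self.L


def _radial_distances(frame: Frame, axis: AxisSpec, positions: np.ndarray) -> np.ndarray:
    """Minimum-image in-plane distances from the axis (x, y only)."""
    dxy = minimum_image(positions[:, :2] - axis.xy[None, :], frame.box_lengths[:2])
    return np.hypot(dxy[:, 0], dxy[:, 1])


def count_particles(frame: Frame, axis: AxisSpec, sub: SubvolumeSpec) -> int:
    """Count particles inside one subvolume (all positions in the frame).

    Membership uses the half-open radial interval [r_in, r_out) under the
    x,y minimum image, and the half-open axial window [z0, z0+L) with
    periodic wrap across the z boundary, so concentric shells and stacked
    windows partition space exactly.  Deterministic.
    """
    if sub.L > frame.lz + 1e-9:
        raise ValueError(f"L={sub.L} exceeds the box height lz={frame.lz}")
    sub.geometry.validate_for_box(frame.box_lengths)
    r = _radial_distances(frame, axis, frame.positions)
    in_shell = (r >= sub.geometry.r_in) & (r < sub.geometry.r_out)
    z = np.mod(frame.positions[in_shell, 2] - sub.z0, frame.lz)
    return int(np.count_nonzero(z < sub.L))


def _window_counts(
    z_sorted: np.ndarray, lz: float, z0_grid: np.ndarray, L_grid: np.ndarray
) -> np.ndarray:
    """Counts in [z0, z0+L) with z wrap, for all (z0, L); shape (n_z0, n_L).

    Uses the cumulative count C(q) = #{z < q} extended periodically:
    count = C(z0+L) - C(z0) with C(q) = n + C(q-lz) for q > lz.
    """
    n = len(z_sorted)

    def cum(q):
        q = np.asarray(q, dtype=float)
        over = q > lz
        qq = np.where(over, q - lz, q)
        return np.searchsorted(z_sorted, qq, side="left") + over * n

    starts = cum(z0_grid)[:, None]
    ends = cum(z0_grid[:, None] + L_grid[None, :])
    return ends - starts


@dataclass
class FluctuationProfile:
    """1/Gamma versus subvolume height L at fixed radial geometry.

    ``block_inv_gamma`` has shape (n_blocks, n_L); the reported
    ``inv_gamma`` is the mean over blocks and ``se`` the between-block
    standard error.  Heights with an empty subvolume are NaN.
    """

    geometry: CylinderShell
    L: np.ndarray
    n_samples: np.ndarray
    mean_n: np.ndarray
    mean_n2: np.ndarray
    inv_gamma: np.ndarray
    se: np.ndarray
    block_inv_gamma: np.ndarray
    lz: float
    box_volume: float
    mean_solvent_count: float
    z_step: float
    n_blocks: int

    def __post_init__(self):
        if np.any(np.diff(self.L) <= 0):
            raise ValueError("L grid must be strictly increasing")

    def shell_volume_full_height(self) -> float:
        """Volume of the radial geometry extended over the full box height."""
        return self.geometry.cross_section_area() * self.lz

    def shell_density(self) -> float:
        """Mean density inside the shell at L = lz, in nm^-3."""
        # mean_n scales linearly with L for a homogeneous z direction; use
        # the largest L as the best-sampled proxy for the full-height count
        k = len(self.L) - 1
        return float(self.mean_n[k] / (self.geometry.cross_section_area() * self.L[k]))

    def bulk_density(self) -> float:
        return self.mean_solvent_count / self.box_volume

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "L_nm": self.L,
                "n_samples": self.n_samples,
                "mean_N": self.mean_n,
                "mean_N2": self.mean_n2,
                "inv_gamma": self.inv_gamma,
                "se": self.se,
            }
        )


def sample_profile(
    traj: Trajectory,
    axis: AxisSpec,
    geometry: CylinderShell,
    L_grid: Sequence[float] | None = None,
    z_step: float = DEFAULT_Z_STEP,
    n_blocks: int = 4,
    label: str = SOLVENT_OXYGEN,
) -> FluctuationProfile:
    """Sample particle-number fluctuations over heights L and z-translations.

    For every height in ``L_grid`` the observation window is translated
    along the axis in steps of ``z_step`` (periodic wrap) and the counts
    of ``label`` particles are pooled over all placements and frames.
    1/Gamma(L) is computed per contiguous trajectory block and averaged;
    the SE is the between-block standard error.

    Heights where the mean count vanishes are recorded as NaN with a
    warning.  An empty trajectory is an error.
    """
    if z_step <= 0:
        raise ValueError("z_step must be > 0")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")

    per_frame_s1 = []  # per frame: sum of counts over z0 placements, per L
    per_frame_s2 = []
    lz = box_volume = None
    n_z0 = None
    L = None
    total_solvent = 0.0

    for frame in traj:
        if lz is None:
            lz = frame.lz
            box_volume = frame.volume
            geometry.validate_for_box(frame.box_lengths)
            grid = default_L_grid(lz) if L_grid is None else np.sort(np.asarray(L_grid, dtype=float))
            if grid[0] <= 0 or grid[-1] > lz + 1e-9:
                raise ValueError(f"L grid must lie in (0, lz={lz}]")
            L = grid
            z0_grid = np.arange(0.0, lz - 1e-9, z_step)
            n_z0 = len(z0_grid)
        pos = frame.positions[frame.labels == label]
        total_solvent += len(pos)
        r = _radial_distances(frame, axis, pos)
        z_in = np.sort(pos[(r >= geometry.r_in) & (r < geometry.r_out), 2])
        counts = _window_counts(z_in, lz, z0_grid, L)
        per_frame_s1.append(counts.sum(axis=0).astype(float))
        per_frame_s2.append((counts.astype(float) ** 2).sum(axis=0))

    n_frames = len(per_frame_s1)
    if n_frames == 0:
        raise ValueError("trajectory is empty")
    if n_frames < n_blocks:
        raise ValueError(f"{n_frames} frames cannot fill {n_blocks} blocks")

    s1 = np.asarray(per_frame_s1)  # (n_frames, n_L)
    s2 = np.asarray(per_frame_s2)

    block_ig = np.full((n_blocks, len(L)), np.nan)
    block_m1 = np.empty((n_blocks, len(L)))
    block_m2 = np.empty((n_blocks, len(L)))
    for b, sl in enumerate(block_slices(n_frames, n_blocks)):
        ns = (sl.stop - sl.start) * n_z0
        m1 = s1[sl].sum(axis=0) / ns
        m2 = s2[sl].sum(axis=0) / ns
        block_m1[b] = m1
        block_m2[b] = m2
        with np.errstate(invalid="ignore", divide="ignore"):
            block_ig[b] = np.where(m1 > 0, (m2 - m1**2) / m1, np.nan)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        inv_gamma = np.nanmean(block_ig, axis=0)
        se = np.nanstd(block_ig, axis=0, ddof=1) / np.sqrt(n_blocks)
    mean_n = block_m1.mean(axis=0)
    mean_n2 = block_m2.mean(axis=0)
    if np.any(~np.isfinite(inv_gamma)):
        bad = L[~np.isfinite(inv_gamma)]
        warnings.warn(
            f"1/Gamma undefined (empty subvolume) at L = {np.round(bad, 3).tolist()} nm",
            RuntimeWarning,
            stacklevel=2,
        )

    return FluctuationProfile(
        geometry=geometry,
        L=L,
        n_samples=np.full(len(L), n_frames * n_z0),
        mean_n=mean_n,
        mean_n2=mean_n2,
        inv_gamma=inv_gamma,
        se=se,
        block_inv_gamma=block_ig,
        lz=lz,
        box_volume=box_volume,
        mean_solvent_count=total_solvent / n_frames,
        z_step=z_step,
        n_blocks=n_blocks,
    )


@dataclass
class ScalingFit:
    """Result of a linear extrapolation of 1/Gamma against an inverse size.

    ``intercept`` is the infinite-size limit (1/Gamma_inf for a bulk
    1/rc fit, 1/Gamma(rc) or 1/Gamma_s_inf for a 1/L fit), ``slope`` the
    finite-size coefficient c.  ``block_intercepts`` hold the per-block
    refits from which ``intercept_se`` derives.
    """

    intercept: float
    slope: float
    window: tuple[float, float]
    variable: str  # "1/L" or "1/rc"
    r_squared: float
    x: np.ndarray
    y: np.ndarray
    residuals: np.ndarray
    intercept_se: float = np.nan
    slope_se: float = np.nan
    block_intercepts: np.ndarray | None = None
    n_points: int = 0


def _ols_line(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    slope, intercept = np.polyfit(x, y, 1, w=w)
    fitted = intercept + slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(intercept), float(slope), r2, y - fitted


def fit_scaling(
    profile: FluctuationProfile,
    window: tuple[float, float],
    weighted: bool = False,
) -> ScalingFit:
    """OLS of 1/Gamma(L) against 1/L inside a height window.

    The intercept is the L -> infinity limit; the slope is the
    size-scaling constant c (in nm).  The fit is unweighted by default;
    ``weighted=True`` uses 1/SE^2 weights.  The intercept SE comes from
    refitting each trajectory block separately.
    """
    lo, hi = window
    if not (lo < hi):
        raise ValueError("fit window must satisfy L_min < L_max")
    mask = (profile.L >= lo - 1e-9) & (profile.L <= hi + 1e-9) & np.isfinite(profile.inv_gamma)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 L grid points with defined 1/Gamma inside [{lo}, {hi}] nm, "
            f"got {int(mask.sum())}"
        )
    x = 1.0 / profile.L[mask]
    y = profile.inv_gamma[mask]
    w = None
    if weighted:
        se = profile.se[mask]
        if np.any(se <= 0) or np.any(~np.isfinite(se)):
            raise ValueError("weighted fit requires positive finite SEs")
        w = 1.0 / se  # polyfit weights multiply residuals (sqrt of 1/SE^2)
    intercept, slope, r2, resid = _ols_line(x, y, w)

    block_intercepts = []
    for b in range(profile.n_blocks):
        yb = profile.block_inv_gamma[b, mask]
        if np.all(np.isfinite(yb)):
            bi, _, _, _ = _ols_line(x, yb, w)
            block_intercepts.append(bi)
    block_intercepts = np.asarray(block_intercepts)
    if len(block_intercepts) >= 2:
        intercept_se = float(np.std(block_intercepts, ddof=1) / np.sqrt(len(block_intercepts)))
    else:
        intercept_se = np.nan

    return ScalingFit(
        intercept=intercept,
        slope=slope,
        window=(lo, hi),
        variable="1/L",
        r_squared=r2,
        x=x,
        y=y,
        residuals=resid,
        intercept_se=intercept_se,
        block_intercepts=block_intercepts,
        n_points=int(mask.sum()),
    )


def extrapolate_radius(
    fits_by_rc: Sequence[tuple[float, "ScalingFit | float"]],
    rc_max: float = RC_WINDOW_MAX,
) -> ScalingFit:
    """Second-stage extrapolation: per-radius intercepts against 1/rc.

    ``fits_by_rc`` pairs each cylinder radius with either the
    :class:`ScalingFit` of its 1/L extrapolation or the bare intercept.
    Only radii strictly below ``rc_max`` (the linear regime) enter the
    OLS of 1/Gamma(rc) against 1/rc; the intercept is the bulk
    thermodynamic-limit 1/Gamma_inf (both 1/L and 1/rc -> 0).  When the
    per-radius fits carry block intercepts, the two-stage fit is repeated
    per block to propagate the SE.
    """
    rcs, intercepts, blocks = [], [], []
    for rc, fit in fits_by_rc:
        if rc >= rc_max:
            continue
        rcs.append(float(rc))
        if isinstance(fit, ScalingFit):
            intercepts.append(fit.intercept)
            blocks.append(fit.block_intercepts)
        else:
            intercepts.append(float(fit))
            blocks.append(None)
    if len(rcs) < 3:
        raise ValueError(f"need >= 3 radii below rc_max={rc_max}, got {len(rcs)}")
    x = 1.0 / np.asarray(rcs)
    y = np.asarray(intercepts)
    intercept, slope, r2, resid = _ols_line(x, y)

    block_intercepts = np.array([])
    if all(b is not None and len(b) > 0 for b in blocks):
        n_b = min(len(b) for b in blocks)
        per_block = []
        for k in range(n_b):
            yb = np.array([b[k] for b in blocks])
            bi, _, _, _ = _ols_line(x, yb)
            per_block.append(bi)
        block_intercepts = np.asarray(per_block)
    if len(block_intercepts) >= 2:
        intercept_se = float(np.std(block_intercepts, ddof=1) / np.sqrt(len(block_intercepts)))
    else:
        intercept_se = np.nan

    return ScalingFit(
        intercept=intercept,
        slope=slope,
        window=(float(min(rcs)), float(max(rcs))),
        variable="1/rc",
        r_squared=r2,
        x=x,
        y=y,
        residuals=resid,
        intercept_se=intercept_se,
        block_intercepts=block_intercepts,
        n_points=len(rcs),
    )


@dataclass(frozen=True)
class CompressibilityResult:
    """Isothermal compressibility from the fluctuation route."""

    chi: float  # bar^-1
    rho: float  # nm^-3
    temperature: float  # K
    inv_gamma_inf: float

    @property
    def chi_ideal(self) -> float:
        """Ideal-gas compressibility 1/(rho kB T) at the same state point."""
        return 1.0 / (self.rho * KB_BAR_NM3 * self.temperature)


def compressibility(inv_gamma_inf: float, rho: float, T: float) -> CompressibilityResult:
    """Convert a thermodynamic-limit 1/Gamma_inf to chi = 1/Gamma_inf/(rho kB T).

    ``rho`` in nm^-3, ``T`` in K; the result is in bar^-1.  With
    inv_gamma_inf = 1 this reduces to the ideal-gas compressibility.
    """
    if rho <= 0 or T <= 0:
        raise ValueError("rho and T must be > 0")
    if inv_gamma_inf < 0:
        raise ValueError("1/Gamma_inf must be >= 0")
    return CompressibilityResult(
        chi=inv_gamma_inf / (rho * KB_BAR_NM3 * T),
        rho=rho,
        temperature=T,
        inv_gamma_inf=inv_gamma_inf,
    )


def block_slices(n: int, n_blocks: int) -> list[slice]:
    """Contiguous block boundaries; remainder frames go to the last block."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n < n_blocks:
        raise ValueError(f"{n} samples cannot fill {n_blocks} blocks")
    base = n // n_blocks
    edges = [b * base for b in range(n_blocks)] + [n]
    return [slice(edges[b], edges[b + 1]) for b in range(n_blocks)]


def block_average(
    values: Sequence[float] | np.ndarray,
    n_blocks: int = 4,
    statistic: Callable[[np.ndarray], float] | None = None,
) -> tuple[float, float]:
    """Block average a per-sample series: (mean, between-block SE).

    The series is split into ``n_blocks`` contiguous blocks (remainder in
    the last), ``statistic`` (default: the mean) is evaluated per block,
    and the SE is stdev(block values)/sqrt(n_blocks).
    """
    values = np.asarray(values, dtype=float)
    stat = statistic if statistic is not None else np.mean
    block_vals = np.array([stat(values[sl]) for sl in block_slices(len(values), n_blocks)])
    return float(np.mean(block_vals)), float(np.std(block_vals, ddof=1) / np.sqrt(n_blocks))
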