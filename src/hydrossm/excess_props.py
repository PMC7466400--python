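"""Excess hydration-shell properties relative to matched pure-solvent shells.

The net effect of the solute on shell thermodynamics is isolated by
subtracting, from every shell property of the polymer system, the same
property computed in cylindrical shells of *exactly the same radii* in a
pure-solvent system (axis through the box centre by default):

    Delta 1/Gamma_s_inf = 1/Gamma_s_inf - 1/Gamma_s_inf(pure),
    Delta chi_s         = chi_s - chi_s(pure),
    Delta q_tet         = q_tet(shell) - q_tet(pure shell),

plus finite-height variants Delta 1/Gamma_s(L) evaluated pointwise on
the shared L grid without extrapolation.  Standard errors of the two
legs combine in quadrature.  Mismatched shell radii, fit windows or
grids between the legs are a hard error — a silent mismatch would
invalidate the subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .proximal_rdf import ShellBoundaries
from .ssm_core import (
    KB_BAR_NM3,
    SHELL_L_WINDOW,
    AxisSpec,
    CylinderShell,
    FluctuationProfile,
    ScalingFit,
    compressibility,
    fit_scaling,
    sample_profile,
)
from .trajectory_io import Trajectory
from .water_structure import shell_qtet

__all__ = [
    "ShellThermodynamics",
    "ExcessRecord",
    "analyze_shells",
    "reference_shell_analysis",
    "excess",
    "finite_L_excess",
    "DEFAULT_FINITE_L",
]

#: Finite shell heights at which Delta 1/Gamma_s(L) is reported (nm).
DEFAULT_FINITE_L = (0.4, 0.8, 2.0, 2.5)


@dataclass
class ShellThermodynamics:
    """One leg (polymer or pure reference) of a per-shell analysis."""

    shell_id: int
    interval: tuple[float, float]  # [r_in, r_out) in nm
    window: tuple[float, float]  # L fit window in nm
    inv_gamma_inf: float
    inv_gamma_inf_se: float
    chi: float  # bar^-1
    chi_se: float
    rho: float  # density used in the chi conversion, nm^-3
    density_mode: str  # "shell" or "bulk"
    temperature: float
    qtet: float = np.nan
    qtet_se: float = np.nan
    profile: FluctuationProfile | None = None
    fit: ScalingFit | None = None

    def settings(self) -> tuple:
        """The knobs that must agree between legs before subtracting."""
        return (
            self.shell_id,
            tuple(np.round(self.interval, 9)),
            tuple(np.round(self.window, 9)),
            self.density_mode,
            round(self.temperature, 6),
        )


def analyze_shells(
    traj: Trajectory,
    boundaries: ShellBoundaries,
    axis: AxisSpec,
    temperature: float,
    window: tuple[float, float] = SHELL_L_WINDOW,
    L_grid=None,
    z_step: float = 0.1,
    n_blocks: int = 4,
    density_mode: str = "shell",
    shell_ids=None,
    include_qtet: bool = True,
) -> dict[int, ShellThermodynamics]:
    """Per-shell fluctuation thermodynamics (and optionally q_tet).

    For every requested shell the fluctuation profile is sampled over the
    L grid with z-translations, fitted over ``window`` against 1/L, and
    the intercept converted to a shell compressibility.  ``density_mode``
    chooses the density entering the conversion: ``"shell"`` (default)
    uses the shell-local density ``<N_shell>/(shell volume at L=lz)``,
    ``"bulk"`` the box-average solvent density.
    """
    if density_mode not in ("shell", "bulk"):
        raise ValueError("density_mode must be 'shell' or 'bulk'")
    if shell_ids is None:
        shell_ids = range(1, boundaries.n_shells + 1)
    out: dict[int, ShellThermodynamics] = {}
    for shell_id in shell_ids:
        lo, hi = boundaries.shell_interval(shell_id)
        profile = sample_profile(
            traj,
            axis,
            CylinderShell(lo, hi),
            L_grid=L_grid,
            z_step=z_step,
            n_blocks=n_blocks,
        )
        fit = fit_scaling(profile, window)
        rho = profile.shell_density() if density_mode == "shell" else profile.bulk_density()
        comp = compressibility(max(fit.intercept, 0.0), rho, temperature)
        # chi is linear in the intercept, so the SE maps through the same factor
        chi_se = fit.intercept_se / (rho * KB_BAR_NM3 * temperature)
        qtet = qtet_se = np.nan
        if include_qtet:
            qtet, qtet_se = shell_qtet(traj, boundaries, axis, shell_id, n_blocks=n_blocks)
        out[shell_id] = ShellThermodynamics(
            shell_id=shell_id,
            interval=(lo, hi),
            window=tuple(window),
            inv_gamma_inf=fit.intercept,
            inv_gamma_inf_se=fit.intercept_se,
            chi=comp.chi,
            chi_se=chi_se,
            rho=rho,
            density_mode=density_mode,
            temperature=temperature,
            qtet=qtet,
            qtet_se=qtet_se,
            profile=profile,
            fit=fit,
        )
    return out


def reference_shell_analysis(
    pure_traj: Trajectory,
    boundaries: ShellBoundaries,
    axis: AxisSpec,
    temperature: float,
    window: tuple[float, float] = SHELL_L_WINDOW,
    **kwargs,
) -> dict[int, ShellThermodynamics]:
    """Analyse matched shells in a pure-solvent system.

    The polymer-derived shell radii are reused verbatim on the
    solute-free trajectory (axis through the box centre unless given), so
    the reference shells have exactly the same widths as the hydration
    shells they will be subtracted from.
    """
    return analyze_shells(
        pure_traj, boundaries, axis, temperature, window=window, **kwargs
    )


@dataclass(frozen=True)
class ExcessRecord:
    """Excess (polymer minus matched pure-solvent) properties of one shell."""

    shell_id: int
    interval: tuple[float, float]
    delta_inv_gamma_inf: float
    delta_inv_gamma_inf_se: float
    delta_chi: float  # bar^-1
    delta_chi_se: float
    delta_qtet: float
    delta_qtet_se: float
    alpha_label: str = ""


def _quad(a: float, b: float) -> float:
    if np.isnan(a) and np.isnan(b):
        return np.nan
    return float(np.hypot(np.nan_to_num(a), np.nan_to_num(b)))


def excess(
    polymer: ShellThermodynamics,
    reference: ShellThermodynamics,
    alpha_label: str = "",
) -> ExcessRecord:
    """Subtract a matched pure-solvent leg from a polymer-shell leg.

    Both legs must have been computed with identical shell radii, fit
    windows, density convention and temperature; any mismatch is a hard
    error.  SEs combine in quadrature.
    """
    if polymer.settings() != reference.settings():
        raise ValueError(
            "legs were computed with different settings and cannot be "
            f"subtracted: polymer={polymer.settings()} vs "
            f"reference={reference.settings()}"
        )
    return ExcessRecord(
        shell_id=polymer.shell_id,
        interval=polymer.interval,
        delta_inv_gamma_inf=polymer.inv_gamma_inf - reference.inv_gamma_inf,
        delta_inv_gamma_inf_se=_quad(polymer.inv_gamma_inf_se, reference.inv_gamma_inf_se),
        delta_chi=polymer.chi - reference.chi,
        delta_chi_se=_quad(polymer.chi_se, reference.chi_se),
        delta_qtet=polymer.qtet - reference.qtet,
        delta_qtet_se=_quad(polymer.qtet_se, reference.qtet_se),
        alpha_label=alpha_label,
    )


def finite_L_excess(
    polymer_profile: FluctuationProfile,
    reference_profile: FluctuationProfile,
    L_list=DEFAULT_FINITE_L,
) -> dict[float, tuple[float, float]]:
    """Pointwise Delta 1/Gamma_s(L) at finite shell heights, no extrapolation.

    Each requested L must be present (within half a grid spacing) in both
    profiles' L grids; SEs combine in quadrature.  Returns
    ``{L: (delta, se)}``.
    """
    if polymer_profile.geometry != reference_profile.geometry:
        raise ValueError(
            "profiles were sampled with different shell radii: "
            f"{polymer_profile.geometry} vs {reference_profile.geometry}"
        )
    out: dict[float, tuple[float, float]] = {}
    for L in L_list:
        deltas = []
        for prof in (polymer_profile, reference_profile):
            spacing = np.min(np.diff(prof.L)) if len(prof.L) > 1 else prof.z_step
            idx = int(np.argmin(np.abs(prof.L - L)))
            if abs(prof.L[idx] - L) > spacing / 2 + 1e-9:
                raise ValueError(
                    f"L={L} nm not on the profile grid "
                    f"[{prof.L[0]:.3g}..{prof.L[-1]:.3g}] (step {spacing:.3g})"
                )
            deltas.append((prof.inv_gamma[idx], prof.se[idx]))
        (gp, sp), (gr, sr) = deltas
        out[float(L)] = (float(gp - gr), _quad(sp, sr))
    return out
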