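"""Repulsion-scaled Lennard-Jones solute-water potential and effective bead size.

The hydrophobic polymer bead interacts with water through a 12-6 potential
whose repulsive term is multiplied by a dimensionless factor ``alpha``:

    U_pw(r) = alpha * C12 / r^12 - C6 / r^6,
    C12 = 4 eps_pw sigma_pw^12,   C6 = 4 eps_pw sigma_pw^6.

Raising ``alpha`` pushes the minimal polymer-water approach distance
outward without changing the attraction coefficient, which maps onto an
effective bead diameter

    sigma_pw_eff = alpha^(1/6) sigma_pw,
    sigma_p_eff  = 2 sigma_pw_eff - sigma_ww,

since by Lorentz-Berthelot mixing sigma_pw = (sigma_p + sigma_ww)/2, so
at alpha = 1 the effective diameter reduces to sigma_p exactly.  The
module exists for this size mapping (and documentation plots); no forces
or simulation are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LJPair",
    "ScaledPotential",
    "lorentz_berthelot",
    "potential",
    "effective_sigma",
    "WATER_MODELS",
    "POLYMER_BEAD_LJ",
    "ALPHA_GRID",
]


@dataclass(frozen=True)
class LJPair:
    """Lennard-Jones site parameters: sigma in nm, epsilon in kJ/mol."""

    sigma: float
    epsilon: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


#: Polymer bead parameters (sigma_p = 0.4 nm, eps_p = 1.0 kJ/mol).
POLYMER_BEAD_LJ = LJPair(0.4, 1.0)

#: Water oxygen self-parameters by model name.  These enter only through
#: Lorentz-Berthelot mixing and the effective-diameter map.
WATER_MODELS = {
    "tip4p2005": LJPair(0.31589, 0.7749),
    "spce": LJPair(0.3166, 0.650),
}

#: Repulsion-scaling values studied for the bead string.
ALPHA_GRID = (1, 2, 4, 6, 8, 10, 12, 15, 20)


def lorentz_berthelot(a: LJPair, b: LJPair) -> LJPair:
    """Mix two LJ sites: arithmetic-mean sigma, geometric-mean epsilon."""
    return LJPair((a.sigma + b.sigma) / 2.0, float(np.sqrt(a.epsilon * b.epsilon)))


@dataclass(frozen=True)
class ScaledPotential:
    """alpha-scaled 12-6 potential with precomputed C12 / C6 coefficients."""

    alpha: float
    c12: float  # kJ/mol nm^12
    c6: float  # kJ/mol nm^6

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.c12 < 0 or self.c6 < 0:
            raise ValueError("C12 and C6 must be >= 0")

    @classmethod
    def from_pair(cls, pair: LJPair, alpha: float) -> "ScaledPotential":
        return cls(
            alpha=float(alpha),
            c12=4.0 * pair.epsilon * pair.sigma**12,
            c6=4.0 * pair.epsilon * pair.sigma**6,
        )

    @property
    def r_min(self) -> float:
        """Location of the potential minimum: alpha^(1/6) * 2^(1/6) * sigma."""
        return float((2.0 * self.alpha * self.c12 / self.c6) ** (1.0 / 6.0))

    def __call__(self, r):
        return potential(self, r)


def potential(p: ScaledPotential, r):
    """Evaluate U_pw(r) = alpha*C12/r^12 - C6/r^6 in kJ/mol (r in nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    inv6 = r**-6
    out = p.alpha * p.c12 * inv6 * inv6 - p.c6 * inv6
    return float(out) if out.ndim == 0 else out


def effective_sigma(alpha: float, sigma_pw: float, sigma_ww: float) -> float:
    """Effective bead diameter: 2 * alpha^(1/6) * sigma_pw - sigma_ww (nm).

    Strictly increasing in alpha; equals sigma_p at alpha = 1 whenever
    sigma_pw came from Lorentz-Berthelot mixing with the same sigma_ww.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return 2.0 * alpha ** (1.0 / 6.0) * sigma_pw - sigma_ww
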