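"""Shared test helper: synthetic fluctuation profiles on an exact 1/L line."""

import numpy as np

from hydrossm.ssm_core import CylinderShell, FluctuationProfile, default_L_grid


def exact_line_profile(intercept, slope, L=None, n_blocks=4, noise=None, rng=None):
    """FluctuationProfile lying exactly (or noisily) on inv_gamma = a + c/L."""
    if L is None:
        L = default_L_grid(2.5)
    L = np.asarray(L, dtype=float)
    y = intercept + slope / L
    block = np.tile(y, (n_blocks, 1))
    if noise is not None:
        block = block + rng.normal(0.0, noise, size=block.shape)
    y_obs = block.mean(axis=0)
    se = block.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return FluctuationProfile(
        geometry=CylinderShell.cylinder(1.0),
        L=L,
        n_samples=np.full(len(L), 1000),
        mean_n=np.full(len(L), 50.0),
        mean_n2=np.full(len(L), 2500.0),
        inv_gamma=y_obs,
        se=se,
        block_inv_gamma=block,
        lz=6.0,
        box_volume=216.0,
        mean_solvent_count=7128.0,
        z_step=0.1,
        n_blocks=n_blocks,
    )
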