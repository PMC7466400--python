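"""Synthetic trajectories and geometries with analytically known statistics.

Every analysis stage in this package is validated against constructions
whose answers are known in closed form, without running an MD engine:

* **Ideal gas** — a fixed number ``N_b`` of points placed independently
  and uniformly in a closed box.  The count ``K`` in any fixed subvolume
  ``v`` is Binomial(``N_b``, ``v/V_b``), so the normalised variance obeys
  ``var(K)/mean(K) = 1 - v/V_b`` exactly in expectation.  This is the
  oracle for the fluctuation sampler.
* **Prescribed radial profile** — an inhomogeneous Poisson point process
  with intensity ``rho * g*(r)`` around a z-aligned axis, the oracle for
  the proximal RDF estimator.
* **Constructed neighbour geometries** — perfect tetrahedra, collinear
  neighbours and uniform-random directions, the closed-form oracles for
  the tetrahedral order parameter (1, -3 and mean 0 respectively).
* **Bead-string system** — a rigid z-periodic chain of beads on the axis
  with a cylindrical solvent exclusion zone, emulating the stretched
  hydrophobic polymer geometry.

All generators are bit-reproducible for a fixed seed.  Random sub-streams
are derived per frame index, so extending a trajectory never reshuffles
earlier frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import (
    POLYMER_BEAD,
    SOLVENT_OTHER,
    SOLVENT_OXYGEN,
    Frame,
    Trajectory,
)

__all__ = [
    "IdealGasSpec",
    "RadialProfileSpec",
    "generate_ideal_gas",
    "generate_radial_profile",
    "generate_neighbor_geometry",
    "generate_bead_string_system",
    "rigid_water_frame",
]

#: Ideal rigid three-site water geometry used by hydrogen-bond fixtures.
OH_LENGTH = 0.09572  # nm
HOH_ANGLE_DEG = 104.52


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    """Independent, reproducible random stream for one frame."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(frame_index),))
    )


@dataclass(frozen=True)
class IdealGasSpec:
    """Uniform uncorrelated solvent in a closed box.

    ``number_density`` is in nm^-3; the realised per-frame particle count
    is ``n_particles = round(number_density * V_b)``.
    """

    number_density: float
    box_lengths: tuple[float, float, float]
    n_frames: int
    seed: int

    def __post_init__(self):
        if self.number_density <= 0:
            raise ValueError("number_density must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if len(self.box_lengths) != 3 or any(b <= 0 for b in self.box_lengths):
            raise ValueError("box_lengths must be 3 positive floats")

    @property
    def volume(self) -> float:
        return float(np.prod(self.box_lengths))

    @property
    def n_particles(self) -> int:
        """Realised N_b (closed-box particle number)."""
        return int(round(self.number_density * self.volume))


def generate_ideal_gas(spec: IdealGasSpec) -> Trajectory:
    """Uniform independent points; the binomial count-statistics oracle."""
    box = np.asarray(spec.box_lengths, dtype=float)
    n = spec.n_particles
    labels = np.full(n, SOLVENT_OXYGEN)

    def _factory():
        for i in range(spec.n_frames):
            rng = _frame_rng(spec.seed, i)
            pos = rng.random((n, 3)) * box[None, :]
            yield Frame(box, pos, labels, frame_time=float(i))

    return Trajectory(
        factory=_factory,
        n_frames=spec.n_frames,
        description=f"ideal gas rho={spec.number_density} N={n}",
    )


@dataclass(frozen=True)
class RadialProfileSpec:
    """Solvent with a prescribed radial density profile around a z axis.

    ``profile_r`` / ``profile_g`` tabulate the target g*(r) on [0, r_max];
    between the nodes the profile is linearly interpolated, beyond
    ``r_max`` the density is exactly the bulk value ``number_density``.
    """

    profile_r: tuple
    profile_g: tuple
    number_density: float
    axis_xy: tuple[float, float]
    box_lengths: tuple[float, float, float]
    n_frames: int
    seed: int

    def __post_init__(self):
        r = np.asarray(self.profile_r, dtype=float)
        g = np.asarray(self.profile_g, dtype=float)
        if r.ndim != 1 or r.shape != g.shape or r.size < 2:
            raise ValueError("profile_r and profile_g must be matching 1-d tables")
        if np.any(np.diff(r) <= 0):
            raise ValueError("profile_r must be strictly increasing")
        if np.any(g < 0):
            raise ValueError("g*(r) must be non-negative")
        if np.max(g) > 50:
            raise ValueError("sup g* > 50: rejection sampling would be too inefficient")
        if self.number_density <= 0:
            raise ValueError("number_density must be > 0")

    @property
    def r_max(self) -> float:
        return float(self.profile_r[-1])

    def g_of_r(self, r) -> np.ndarray:
        """Target profile: interpolated inside r_max, exactly 1 beyond."""
        r = np.asarray(r, dtype=float)
        return np.where(
            r >= self.r_max, 1.0, np.interp(r, self.profile_r, self.profile_g)
        )


def generate_radial_profile(spec: RadialProfileSpec) -> Trajectory:
    """Inhomogeneous Poisson process with intensity rho*g*(r) around the axis.

    Sampling is by thinning: candidates are placed uniformly at the
    envelope density ``rho * M`` (``M = max(sup g*, 1)``) and accepted
    with probability ``g*(r)/M`` (``1/M`` beyond ``r_max``), yielding the
    exact target intensity.
    """
    box = np.asarray(spec.box_lengths, dtype=float)
    axis = np.asarray(spec.axis_xy, dtype=float)
    envelope = max(float(np.max(spec.profile_g)), 1.0)
    mean_candidates = spec.number_density * envelope * float(np.prod(box))

    def _factory():
        for i in range(spec.n_frames):
            rng = _frame_rng(spec.seed, i)
            n_cand = rng.poisson(mean_candidates)
            pos = rng.random((n_cand, 3)) * box[None, :]
            dxy = pos[:, :2] - axis[None, :]
            dxy -= box[None, :2] * np.round(dxy / box[None, :2])
            r = np.hypot(dxy[:, 0], dxy[:, 1])
            accept = rng.random(n_cand) < spec.g_of_r(r) / envelope
            pos = pos[accept]
            yield Frame(box, pos, np.full(len(pos), SOLVENT_OXYGEN), frame_time=float(i))

    return Trajectory(
        factory=_factory,
        n_frames=spec.n_frames,
        description="radial-profile Poisson fixture",
    )


# ---------------------------------------------------------------------------
# neighbour geometries for the tetrahedral order parameter
# ---------------------------------------------------------------------------

# unit vertices of a regular tetrahedron centred on the origin
_TETRA_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_neighbor_geometry(kind: str, n_samples: int, seed: int):
    """Central points with four neighbours of known angular statistics.

    Parameters
    ----------
    kind:
        ``"perfect-tetrahedron"`` — all six pair angles have
        cos(psi) = -1/3, so the tetrahedral order parameter is exactly 1;
        ``"collinear"`` — all four neighbours along one direction
        (order parameter exactly -3);
        ``"uniform-random"`` — neighbour directions i.i.d. uniform on the
        sphere (order parameter has mean 0).

    Returns a list of ``(central_position, neighbours)`` pairs with
    ``neighbours`` of shape (4, 3).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        center = rng.random(3)
        dists = rng.uniform(0.25, 0.35, size=4)
        if kind == "perfect-tetrahedron":
            dirs = _TETRA_DIRS @ _random_rotation(rng).T
        elif kind == "collinear":
            d = _random_unit_vectors(rng, 1)[0]
            dirs = np.tile(d, (4, 1))
            dists = np.sort(dists)  # distinct distances along one ray
        elif kind == "uniform-random":
            dirs = _random_unit_vectors(rng, 4)
        else:
            raise ValueError(
                "kind must be 'perfect-tetrahedron', 'collinear' or 'uniform-random'"
            )
        out.append((center, center[None, :] + dirs * dists[:, None]))
    return out


def generate_bead_string_system(
    bead_spacing: float,
    n_beads: int,
    exclusion_radius: float,
    number_density: float,
    box_lengths,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """z-periodic bead string on the box axis plus excluded-cylinder solvent.

    Beads sit on a line through the box centre at z = 0, spacing,
    2*spacing, ...; solvent points are uniform outside the cylindrical
    exclusion radius around that line.  The solvent count is fixed per
    frame at ``round(rho * V_free)`` so the density *outside* the
    exclusion cylinder equals ``number_density`` and the proximal RDF of
    the output is ~0 inside the exclusion radius and ~1 outside.
    """
    box = np.asarray(box_lengths, dtype=float)
    lz = box[2]
    if n_beads * bead_spacing > lz + 1e-9:
        raise ValueError(
            f"chain of {n_beads} beads at spacing {bead_spacing} nm exceeds lz={lz} nm"
        )
    if exclusion_radius >= min(box[0], box[1]) / 2:
        raise ValueError("exclusion cylinder must fit inside the box cross-section")
    axis = box[:2] / 2.0
    v_box = float(np.prod(box))
    v_excl = np.pi * exclusion_radius**2 * lz
    v_free = v_box - v_excl
    n_solvent = int(round(number_density * v_free))

    bead_pos = np.zeros((n_beads, 3))
    bead_pos[:, 0] = axis[0]
    bead_pos[:, 1] = axis[1]
    bead_pos[:, 2] = np.arange(n_beads) * bead_spacing

    labels = np.concatenate(
        [np.full(n_beads, POLYMER_BEAD), np.full(n_solvent, SOLVENT_OXYGEN)]
    )

    def _factory():
        for i in range(n_frames):
            rng = _frame_rng(seed, i)
            solvent = np.empty((0, 3))
            while len(solvent) < n_solvent:
                short = n_solvent - len(solvent)
                # oversample to amortise rejection
                cand = rng.random((int(short * 1.3) + 16, 3)) * box[None, :]
                dxy = cand[:, :2] - axis[None, :]
                dxy -= box[None, :2] * np.round(dxy / box[None, :2])
                keep = np.hypot(dxy[:, 0], dxy[:, 1]) >= exclusion_radius
                solvent = np.vstack([solvent, cand[keep]])
            solvent = solvent[:n_solvent]
            yield Frame(
                box,
                np.vstack([bead_pos, solvent]),
                labels,
                frame_time=float(i),
            )

    return Trajectory(
        factory=_factory,
        n_frames=n_frames,
        description=f"bead string n={n_beads} spacing={bead_spacing} excl={exclusion_radius}",
    )


def rigid_water_frame(
    oxygen_positions,
    bisector_directions,
    plane_directions,
    box_lengths,
) -> Frame:
    """Assemble rigid three-site waters at controlled orientations.

    Each molecule has the ideal geometry (O-H length 0.09572 nm, H-O-H
    angle 104.52 deg).  ``bisector_directions`` point from the oxygen
    along the H-O-H bisector towards the hydrogens;
    ``plane_directions`` (not parallel to the bisector) fix the molecular
    plane.  Sites are ordered O, H, H per molecule — the layout the
    hydrogen-bond analysis expects.
    """
    o_pos = np.atleast_2d(np.asarray(oxygen_positions, dtype=float))
    bis = np.atleast_2d(np.asarray(bisector_directions, dtype=float))
    pl = np.atleast_2d(np.asarray(plane_directions, dtype=float))
    if not (len(o_pos) == len(bis) == len(pl)):
        raise ValueError("one bisector and one plane direction per oxygen required")
    half = np.deg2rad(HOH_ANGLE_DEG) / 2.0
    positions, labels = [], []
    for o, b, p in zip(o_pos, bis, pl):
        b = b / np.linalg.norm(b)
        p = p - np.dot(p, b) * b
        norm = np.linalg.norm(p)
        if norm < 1e-12:
            raise ValueError("plane direction parallel to bisector")
        p = p / norm
        positions.append(o)
        for sgn in (+1.0, -1.0):
            h_dir = np.cos(half) * b + sgn * np.sin(half) * p
            positions.append(o + OH_LENGTH * h_dir)
        labels.extend([SOLVENT_OXYGEN, SOLVENT_OTHER, SOLVENT_OTHER])
    return Frame(
        np.asarray(box_lengths, dtype=float),
        np.asarray(positions),
        np.asarray(labels),
    )
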