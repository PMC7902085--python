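"""Coarse-grained two-chain complex: topology, potential energy, forces.

One bead per residue. The inter-chain interaction is a Go-like model:
a small set of attractive Lennard-Jones 6-12 contacts between native-contact
bead pairs, written in the R_min convention

    U(r) = epsilon * [ (R_min/r)^12 - 2 (R_min/r)^6 ]

so that the tabulated minimum distance R_min is exactly the minimum of the
pair potential and -epsilon its depth.  Each chain's fold is maintained by an
intra-chain harmonic elastic network; chain A is tethered per-bead to its
reference pose (pinning position and orientation); chain B diffuses freely
inside a flat-bottom spherical wall acting on its center of mass, which fixes
the effective concentration.  An optional harmonic umbrella bias acts on the
chain A - chain B center-of-mass distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bead",
    "GoContact",
    "RestraintSpec",
    "ConfinementSphere",
    "UmbrellaBias",
    "CGComplex",
    "build_complex",
    "potential_energy",
    "forces",
    "go_pair_energy",
    "com_distance",
]


@dataclass(frozen=True)
class Bead:
    """A single residue bead."""

    index: int
    chain: str  # "A" or "B"
    mass: float  # amu
    reference_position: np.ndarray  # (3,), Angstrom

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"bead mass must be positive, got {self.mass}")
        if self.chain not in ("A", "B"):
            raise ValueError(f"chain label must be 'A' or 'B', got {self.chain!r}")


@dataclass(frozen=True)
class GoContact:
    """An attractive native-contact LJ 6-12 pair between the two chains."""

    index_A: int
    index_B: int
    r_min: float  # Angstrom, position of the potential minimum
    epsilon: float  # kcal/mol, well depth

    def __post_init__(self):
        if self.r_min <= 0:
            raise ValueError("r_min must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class RestraintSpec:
    """Fold-preserving and pose-pinning restraints.

    ``elastic_network_cutoff``/``elastic_network_k`` define the intra-chain
    harmonic network standing in for fold (RMSD-type) restraints;
    ``chainA_positional_k`` tethers every chain-A bead to its reference
    position, pinning chain A at the origin in position and orientation.
    """

    elastic_network_cutoff: float = 12.0  # Angstrom
    elastic_network_k: float = 10.0  # kcal/mol/A^2
    chainA_positional_k: float = 10.0  # kcal/mol/A^2

    def __post_init__(self):
        if min(self.elastic_network_k, self.chainA_positional_k) < 0:
            raise ValueError("spring constants must be non-negative")


@dataclass(frozen=True)
class ConfinementSphere:
    """Flat-bottom spherical wall on the chain-B center of mass.

    Zero inside radius ``r_cavity``, half-harmonic outside.  The default
    radius 73.46 A matches the production cavity of the reference system.
    """

    r_cavity: float = 73.46  # Angstrom
    wall_k: float = 10.0  # kcal/mol/A^2

    def __post_init__(self):
        if self.r_cavity <= 0:
            raise ValueError("r_cavity must be positive")
        if self.wall_k < 0:
            raise ValueError("wall_k must be non-negative")


@dataclass(frozen=True)
class UmbrellaBias:
    """Harmonic umbrella window U = (k/2) (d - d0)^2 on the COM-COM distance."""

    center: float  # d0, Angstrom
    spring_k: float = 1.0  # kcal/mol/A^2

    def __post_init__(self):
        if self.spring_k < 0:
            raise ValueError("spring_k must be non-negative")


@dataclass
class CGComplex:
    """Two bead chains with Go contacts, restraints and confinement."""

    beads: list[Bead]
    contacts: list[GoContact]
    restraints: RestraintSpec
    confinement: ConfinementSphere
    elastic_bonds: list[tuple[int, int, float]] = field(default_factory=list)

    # ---- derived arrays (built once, used by the energy/force kernels) ----
    def __post_init__(self):
        self.n_beads = len(self.beads)
        self.masses = np.array([b.mass for b in self.beads])
        self.chain_ids = np.array([0 if b.chain == "A" else 1 for b in self.beads])
        self.reference = np.array([b.reference_position for b in self.beads], dtype=float)
        self.idx_A = np.where(self.chain_ids == 0)[0]
        self.idx_B = np.where(self.chain_ids == 1)[0]
        self.mass_A = self.masses[self.idx_A]
        self.mass_B = self.masses[self.idx_B]
        # global bead indices of each contact endpoint
        self._c_i = np.array([self.idx_A[c.index_A] for c in self.contacts], dtype=int)
        self._c_j = np.array([self.idx_B[c.index_B] for c in self.contacts], dtype=int)
        self._c_rmin = np.array([c.r_min for c in self.contacts])
        self._c_eps = np.array([c.epsilon for c in self.contacts])
        self._b_i = np.array([b[0] for b in self.elastic_bonds], dtype=int)
        self._b_j = np.array([b[1] for b in self.elastic_bonds], dtype=int)
        self._b_r0 = np.array([b[2] for b in self.elastic_bonds])

    @property
    def n_A(self) -> int:
        return len(self.idx_A)

    @property
    def n_B(self) -> int:
        return len(self.idx_B)


def build_complex(
    coords_A,
    coords_B,
    contacts,
    restraints: RestraintSpec | None = None,
    confinement: ConfinementSphere | None = None,
    masses_A=None,
    masses_B=None,
) -> CGComplex:
    """Assemble a :class:`CGComplex` from per-chain reference coordinates.

    Parameters
    ----------
    coords_A, coords_B
        Reference (bound-pose) bead coordinates of each chain, (n, 3) A.
    contacts
        Iterable of ``(iA, iB, r_min, epsilon)`` with per-chain 0-based
        bead indices.
    masses_A, masses_B
        Optional per-bead masses in amu; default 110 amu (average residue).

    The intra-chain elastic network links every bead pair of the same chain
    whose reference separation is at most ``restraints.elastic_network_cutoff``,
    with rest length equal to that separation.
    """
    restraints = restraints or RestraintSpec()
    confinement = confinement or ConfinementSphere()
    coords_A = np.asarray(coords_A, dtype=float)
    coords_B = np.asarray(coords_B, dtype=float)
    if coords_A.size == 0 or coords_B.size == 0:
        raise ValueError("both chains must contain at least one bead")
    if coords_A.ndim != 2 or coords_A.shape[1] != 3 or coords_B.ndim != 2 or coords_B.shape[1] != 3:
        raise ValueError("coordinates must have shape (n, 3)")
    if not (np.isfinite(coords_A).all() and np.isfinite(coords_B).all()):
        raise ValueError("non-finite reference coordinate")
    nA, nB = len(coords_A), len(coords_B)
    if masses_A is None:
        masses_A = np.full(nA, 110.0)
    if masses_B is None:
        masses_B = np.full(nB, 110.0)

    go: list[GoContact] = []
    seen = set()
    for iA, iB, r_min, eps in contacts:
        iA, iB = int(iA), int(iB)
        if not (0 <= iA < nA) or not (0 <= iB < nB):
            raise IndexError(f"contact index ({iA}, {iB}) out of range for chains ({nA}, {nB})")
        if (iA, iB) in seen:
            raise ValueError(f"duplicate contact pair ({iA}, {iB})")
        seen.add((iA, iB))
        go.append(GoContact(iA, iB, float(r_min), float(eps)))

    beads = [Bead(i, "A", float(masses_A[i]), coords_A[i]) for i in range(nA)]
    beads += [Bead(i, "B", float(masses_B[i]), coords_B[i]) for i in range(nB)]

    bonds: list[tuple[int, int, float]] = []
    cutoff = restraints.elastic_network_cutoff
    for offset, coords in ((0, coords_A), (nA, coords_B)):
        n = len(coords)
        if n < 2:
            continue
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        ii, jj = np.triu_indices(n, k=1)
        keep = d[ii, jj] <= cutoff
        for i, j in zip(ii[keep], jj[keep]):
            bonds.append((offset + int(i), offset + int(j), float(d[i, j])))

    return CGComplex(beads, go, restraints, confinement, bonds)


def go_pair_energy(contact: GoContact, r) -> np.ndarray | float:
    """LJ 6-12 energy of a single Go contact at separation ``r`` (A)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    s6 = (contact.r_min / r) ** 6
    out = contact.epsilon * (s6 * s6 - 2.0 * s6)
    return float(out) if out.ndim == 0 else out


def com_distance(cplx: CGComplex, positions: np.ndarray) -> float:
    """Mass-weighted COM separation of the two chains, Angstrom."""
    pos = np.asarray(positions, dtype=float)
    com_A = np.average(pos[cplx.idx_A], axis=0, weights=cplx.mass_A)
    com_B = np.average(pos[cplx.idx_B], axis=0, weights=cplx.mass_B)
    return float(np.linalg.norm(com_B - com_A))


def _check_positions(cplx: CGComplex, positions) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (cplx.n_beads, 3):
        raise ValueError(f"expected positions of shape ({cplx.n_beads}, 3), got {pos.shape}")
    if not np.isfinite(pos).all():
        raise ValueError("non-finite position")
    return pos


def potential_energy(cplx: CGComplex, positions, bias: UmbrellaBias | None = None) -> float:
    """Total potential energy in kcal/mol.

    Sums Go contacts, the intra-chain elastic network, chain-A positional
    tethers, the flat-bottom wall on the chain-B COM radius, and the optional
    umbrella term on the COM-COM distance.
    """
    pos = _check_positions(cplx, positions)
    energy = 0.0

    if len(cplx._c_i):
        dr = pos[cplx._c_i] - pos[cplx._c_j]
        r = np.linalg.norm(dr, axis=1)
        if np.any(r == 0.0):
            raise ZeroDivisionError("zero separation for a Go contact pair (singular LJ)")
        s6 = (cplx._c_rmin / r) ** 6
        energy += float(np.sum(cplx._c_eps * (s6 * s6 - 2.0 * s6)))

    if len(cplx._b_i):
        r = np.linalg.norm(pos[cplx._b_i] - pos[cplx._b_j], axis=1)
        energy += 0.5 * cplx.restraints.elastic_network_k * float(np.sum((r - cplx._b_r0) ** 2))

    k_pos = cplx.restraints.chainA_positional_k
    if k_pos > 0:
        dev = pos[cplx.idx_A] - cplx.reference[cplx.idx_A]
        energy += 0.5 * k_pos * float(np.sum(dev * dev))

    wall = cplx.confinement
    if wall.wall_k > 0:
        com_B = np.average(pos[cplx.idx_B], axis=0, weights=cplx.mass_B)
        r_com = np.linalg.norm(com_B)
        if r_com > wall.r_cavity:
            energy += 0.5 * wall.wall_k * (r_com - wall.r_cavity) ** 2

    if bias is not None and bias.spring_k > 0:
        d = com_distance(cplx, pos)
        energy += 0.5 * bias.spring_k * (d - bias.center) ** 2

    return energy


def forces(cplx: CGComplex, positions, bias: UmbrellaBias | None = None) -> np.ndarray:
    """Analytic forces -dU/dx, kcal/mol/A, shape (n_beads, 3)."""
    pos = _check_positions(cplx, positions)
    f = np.zeros_like(pos)

    if len(cplx._c_i):
        dr = pos[cplx._c_i] - pos[cplx._c_j]
        r = np.linalg.norm(dr, axis=1)
        if np.any(r == 0.0):
            raise ZeroDivisionError("zero separation for a Go contact pair (singular LJ)")
        s6 = (cplx._c_rmin / r) ** 6
        # dU/dr = 12 eps (s6 - s12)/r ; force along dr is -dU/dr * dr/r
        coef = -12.0 * cplx._c_eps * (s6 - s6 * s6) / (r * r)  # multiplies dr
        fvec = coef[:, None] * dr
        np.add.at(f, cplx._c_i, fvec)
        np.add.at(f, cplx._c_j, -fvec)

    if len(cplx._b_i):
        dr = pos[cplx._b_i] - pos[cplx._b_j]
        r = np.linalg.norm(dr, axis=1)
        coef = -cplx.restraints.elastic_network_k * (r - cplx._b_r0) / r
        fvec = coef[:, None] * dr
        np.add.at(f, cplx._b_i, fvec)
        np.add.at(f, cplx._b_j, -fvec)

    k_pos = cplx.restraints.chainA_positional_k
    if k_pos > 0:
        f[cplx.idx_A] -= k_pos * (pos[cplx.idx_A] - cplx.reference[cplx.idx_A])

    wall = cplx.confinement
    if wall.wall_k > 0:
        com_B = np.average(pos[cplx.idx_B], axis=0, weights=cplx.mass_B)
        r_com = np.linalg.norm(com_B)
        if r_com > wall.r_cavity:
            # dU/dx_i = wall_k (r - r_cav) * (m_i/M) * com/r
            grad_com = wall.wall_k * (r_com - wall.r_cavity) * com_B / r_com
            w = cplx.mass_B / cplx.mass_B.sum()
            f[cplx.idx_B] -= w[:, None] * grad_com[None, :]

    if bias is not None and bias.spring_k > 0:
        com_A = np.average(pos[cplx.idx_A], axis=0, weights=cplx.mass_A)
        com_B = np.average(pos[cplx.idx_B], axis=0, weights=cplx.mass_B)
        sep = com_B - com_A
        d = np.linalg.norm(sep)
        if d > 0:
            g = bias.spring_k * (d - bias.center) * sep / d
            wB = cplx.mass_B / cplx.mass_B.sum()
            wA = cplx.mass_A / cplx.mass_A.sum()
            f[cplx.idx_B] -= wB[:, None] * g[None, :]
            f[cplx.idx_A] += wA[:, None] * g[None, :]

    return f
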