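"""Coarse-grained system setup: topology, placement, velocities, pair tables.

Each residue contributes four beads in chain order NH, CαH, CO, R. The
template chain is near-extended (colinear backbone beads along the strand
axis, side-chain beads alternating ± perpendicular); backbone geometry is
enforced by auxiliary pseudo-bonds between all close intra-chain bead pairs,
built automatically from the template distances. This keeps chains
near-extended — the dispersed starting state is an unassembled monomer gas
rather than a true random coil, a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crossbeta.residues import check_sequence
from crossbeta.cgdmd.params import (
    BOND_CA_CO,
    BOND_CO_NH,
    BOND_NH_CA,
    RISE,
    CGModelParams,
)

AVOGADRO = 6.02214076e23
BEADS_PER_RESIDUE = 4
BEAD_KINDS = ("NH", "CA", "CO", "R")


class SystemError_(ValueError):
    """Raised for invalid CG system construction."""


@dataclass(frozen=True)
class Topology:
    """Bead indexing for ``n_peptides`` copies of one sequence.

    Bead index = ((chain · n_residues + residue) · 4 + kind), with kinds
    NH=0, CA=1, CO=2, R=3.
    """

    sequence: str
    n_peptides: int

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return self.n_peptides * self.n_residues * BEADS_PER_RESIDUE

    def bead(self, chain: int, residue: int, kind: int) -> int:
        return (chain * self.n_residues + residue) * BEADS_PER_RESIDUE + kind

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chain_id, residue_id, kind) per bead."""
        n = self.n_beads
        idx = np.arange(n)
        kind = idx % BEADS_PER_RESIDUE
        residue = (idx // BEADS_PER_RESIDUE) % self.n_residues
        chain = idx // (BEADS_PER_RESIDUE * self.n_residues)
        return chain, residue, kind

    def bead_positions_by_kind(self, positions: np.ndarray, kind: int) -> np.ndarray:
        """Positions of one bead kind, shape (n_peptides, n_residues, 3)."""
        pos = positions.reshape(self.n_peptides, self.n_residues, BEADS_PER_RESIDUE, 3)
        return pos[:, :, kind, :]


def template_chain(sequence: str, params: CGModelParams) -> np.ndarray:
    """Ideal near-extended chain along +x, shape (n_res, 4, 3)."""
    n = len(sequence)
    coords = np.empty((n, BEADS_PER_RESIDUE, 3))
    for r, aa in enumerate(sequence):
        x = r * RISE
        side = (-1) ** r * params.ca_r_bond[aa]
        coords[r, 0] = (x - BOND_NH_CA, 0.0, 0.0)
        coords[r, 1] = (x, 0.0, 0.0)
        coords[r, 2] = (x + BOND_CA_CO, 0.0, 0.0)
        coords[r, 3] = (x, 0.0, side)
    return coords


def _chain_bonds(sequence: str, params: CGModelParams) -> list[tuple[int, int, float]]:
    """Covalent bonds plus geometry-enforcing pseudo-bonds for one chain.

    Pseudo-bonds are added between every intra-chain bead pair whose template
    distance is within (contact diameter + 1.0 Å): this both fixes backbone
    angles/planarity and exempts template near-contacts from hard-core
    overlap. Nominal lengths are the template distances.
    """
    tmpl = template_chain(sequence, params).reshape(-1, 3)
    n_res = len(sequence)

    def bead(r, k):
        return r * BEADS_PER_RESIDUE + k

    bonds = {}
    for r, aa in enumerate(sequence):
        bonds[(bead(r, 0), bead(r, 1))] = BOND_NH_CA
        bonds[(bead(r, 1), bead(r, 2))] = BOND_CA_CO
        bonds[(bead(r, 1), bead(r, 3))] = params.ca_r_bond[aa]
        if r + 1 < n_res:
            bonds[(bead(r, 2), bead(r + 1, 0))] = BOND_CO_NH

    diam = _bead_diameters(sequence, params)
    sig = np.array([diam[k] for k in range(len(tmpl))])
    for i in range(len(tmpl)):
        for j in range(i + 1, len(tmpl)):
            if (i, j) in bonds:
                continue
            d = float(np.linalg.norm(tmpl[i] - tmpl[j]))
            contact = 0.5 * (sig[i] + sig[j])
            if d < contact + 1.0:
                bonds[(i, j)] = d
    return [(i, j, d) for (i, j), d in sorted(bonds.items())]


def _bead_diameters(sequence: str, params: CGModelParams):
    out = {}
    for r, aa in enumerate(sequence):
        base = r * BEADS_PER_RESIDUE
        out[base + 0] = params.bead_diameter["NH"]
        out[base + 1] = params.bead_diameter["CA"]
        out[base + 2] = params.bead_diameter["CO"]
        out[base + 3] = params.bead_diameter[f"R_{aa}"]
    return out


@dataclass
class CGSystem:
    """Bead positions/velocities plus interaction tables for the DMD engine."""

    topology: Topology
    params: CGModelParams
    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    box_edge: float
    temperature_K: float
    bonds: list  # (i, j, nominal length)
    #: per-pair tables, shape (n_beads, n_beads)
    core2: np.ndarray      # squared hard-core contact; 0 where exempt
    well_r2: np.ndarray    # squared well outer radius; 0 where none
    well_eps: np.ndarray   # well depth (ε₀; >0 attractive, <0 shoulder)
    bond_lo2: np.ndarray   # squared bond window bounds; 0 where unbonded
    bond_hi2: np.ndarray

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def kT(self) -> float:
        return self.params.kT(self.temperature_K)

    def kinetic_energy(self) -> float:
        return float(0.5 * (self.masses * (self.velocities**2).sum(axis=1)).sum())

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        return d - self.box_edge * np.round(d / self.box_edge)

    def validate_constraints(self, tol: float = 1e-9) -> None:
        """Post-hoc scan: no core overlap, all bonds inside their windows."""
        n = self.n_beads
        d2 = _pair_distances_sq(self.positions, self.box_edge)
        viol_core = (self.core2 > 0) & (d2 < self.core2 * (1 - 1e-12) - tol)
        if viol_core.any():
            i, j = np.argwhere(viol_core)[0]
            raise SystemError_(
                f"hard-core overlap between beads {i} and {j}: "
                f"d={np.sqrt(d2[i, j]):.4f}"
            )
        bonded = self.bond_hi2 > 0
        viol = bonded & ((d2 > self.bond_hi2 + tol) | (d2 < self.bond_lo2 - tol))
        if viol.any():
            i, j = np.argwhere(viol)[0]
            raise SystemError_(
                f"bond window violated for beads {i}-{j}: d={np.sqrt(d2[i, j]):.4f}"
            )


def _pair_distances_sq(positions: np.ndarray, box: float) -> np.ndarray:
    d = positions[:, None, :] - positions[None, :, :]
    d -= box * np.round(d / box)
    return (d**2).sum(axis=-1)


def concentration(n_peptides: int, box_edge: float) -> float:
    """Peptide concentration in mM for a cubic box edge in Å."""
    if n_peptides <= 0 or box_edge <= 0:
        raise ValueError("inputs must be positive")
    volume_L = (box_edge * 1e-9) ** 3  # Å³ → dm³ (1 Å = 1e-9 dm)
    return n_peptides / AVOGADRO / volume_L * 1e3


def measure_temperature(system_or_velocities, masses=None, params=None) -> float:
    """Kinetic temperature in Kelvin from velocity variance (equipartition)."""
    if isinstance(system_or_velocities, CGSystem):
        sys_ = system_or_velocities
        vel, m, scale = sys_.velocities, sys_.masses, sys_.params.energy_scale_K
    else:
        vel = np.asarray(system_or_velocities)
        m = np.asarray(masses)
        scale = (params.energy_scale_K if params is not None else 1000.0)
    if vel.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    ke = 0.5 * (m * (vel**2).sum(axis=1)).sum()
    kT = 2.0 * ke / (3.0 * vel.shape[0])
    return float(kT * scale)


def maxwell_boltzmann_velocities(
    masses: np.ndarray, kT: float, rng: np.random.Generator
) -> np.ndarray:
    """MB velocities at reduced temperature kT with zero net momentum."""
    sigma = np.sqrt(kT / masses)[:, None]
    vel = rng.normal(size=(len(masses), 3)) * sigma
    vel -= (masses[:, None] * vel).sum(axis=0) / masses.sum()
    return vel


def build_pair_tables(topology: Topology, params: CGModelParams):
    """Interaction tables for every bead pair.

    Bonded/pseudo-bonded pairs get an infinite-well window (±bond_tolerance
    of the nominal length) and are exempt from cores and wells. Inter-chain
    NH–CO pairs get the H-bond square well; inter-chain R–R pairs get the
    side-chain well from the depth table. All remaining distinct-bead pairs
    interact as hard spheres (additive diameters).
    """
    n = topology.n_beads
    chain, residue, kind = topology.arrays()
    seq = topology.sequence
    aa_idx = np.array(
        ["ACDEFGHIKLMNPQRSTVWY".index(seq[r]) for r in residue], dtype=int
    )

    diam = np.empty(n)
    mass = np.empty(n)
    for k, name in enumerate(BEAD_KINDS):
        sel = kind == k
        if name == "R":
            for i in np.flatnonzero(sel):
                aa = seq[residue[i]]
                diam[i] = params.bead_diameter[f"R_{aa}"]
                mass[i] = params.bead_mass[f"R_{aa}"]
        else:
            diam[sel] = params.bead_diameter[name]
            mass[sel] = params.bead_mass[name]

    core2 = ((diam[:, None] + diam[None, :]) / 2.0) ** 2
    np.fill_diagonal(core2, 0.0)

    well_r2 = np.zeros((n, n))
    well_eps = np.zeros((n, n))
    inter = chain[:, None] != chain[None, :]

    if params.hb_depth != 0.0:
        is_nh = kind == 0
        is_co = kind == 2
        hb = inter & (
            (is_nh[:, None] & is_co[None, :]) | (is_co[:, None] & is_nh[None, :])
        )
        well_r2[hb] = params.hb_range**2
        well_eps[hb] = params.hb_depth

    is_r = kind == 3
    rr = inter & is_r[:, None] & is_r[None, :]
    depths = params.pair_depths[aa_idx[:, None], aa_idx[None, :]]
    sc_range2 = (params.sc_well_factor * np.sqrt(core2)) ** 2
    mask = rr & (depths != 0.0)
    well_r2[mask] = sc_range2[mask]
    well_eps[mask] = depths[mask]

    # bonds
    bond_lo2 = np.zeros((n, n))
    bond_hi2 = np.zeros((n, n))
    per_chain = _chain_bonds(seq, params)
    bonds = []
    stride = topology.n_residues * BEADS_PER_RESIDUE
    tol = params.bond_tolerance
    for c in range(topology.n_peptides):
        for i, j, d in per_chain:
            a, b = c * stride + i, c * stride + j
            bonds.append((a, b, d))
            bond_lo2[a, b] = bond_lo2[b, a] = (d * (1 - tol)) ** 2
            bond_hi2[a, b] = bond_hi2[b, a] = (d * (1 + tol)) ** 2
            core2[a, b] = core2[b, a] = 0.0
            well_r2[a, b] = well_r2[b, a] = 0.0
            well_eps[a, b] = well_eps[b, a] = 0.0

    # wells narrower than the core are ill-defined; drop them
    bad = (well_r2 > 0) & (well_r2 <= core2)
    well_r2[bad] = 0.0
    well_eps[bad] = 0.0

    return diam, mass, core2, well_r2, well_eps, bond_lo2, bond_hi2, bonds


def build_cg_system(
    sequence: str,
    n_peptides: int,
    box_edge: float,
    temperature_K: float,
    params: CGModelParams | None = None,
    seed: int = 0,
    max_tries: int = 2000,
) -> CGSystem:
    """Place ``n_peptides`` chains at random non-overlapping poses.

    Chains start dispersed (near-extended template conformation, random
    position and orientation) with Maxwell–Boltzmann velocities at the target
    temperature and zero net momentum; identical seeds give identical
    systems.
    """
    check_sequence(sequence)
    if n_peptides < 1:
        raise SystemError_("n_peptides must be >= 1")
    params = params or CGModelParams.from_files()
    topology = Topology(sequence=sequence, n_peptides=n_peptides)
    diam, mass, core2, well_r2, well_eps, bond_lo2, bond_hi2, bonds = (
        build_pair_tables(topology, params)
    )
    rng = np.random.default_rng(seed)
    tmpl = template_chain(sequence, params).reshape(-1, 3)
    tmpl = tmpl - tmpl.mean(axis=0)
    span = np.linalg.norm(tmpl, axis=1).max()
    if 2 * span > box_edge:
        raise SystemError_("box too small for the peptide template")

    placed: list[np.ndarray] = []
    clearance = diam.max() + 0.5
    for _ in range(n_peptides):
        ok = False
        for _try in range(max_tries):
            rot = _random_rotation(rng)
            offset = rng.uniform(0.0, box_edge, size=3)
            cand = tmpl @ rot.T + offset
            if _clear_of(placed, cand, box_edge, clearance):
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise SystemError_(
                f"could not place chain {len(placed)} after {max_tries} tries; "
                "try a larger box"
            )
    positions = np.concatenate(placed)
    kT = params.kT(temperature_K)
    velocities = maxwell_boltzmann_velocities(mass, kT, rng)

    system = CGSystem(
        topology=topology,
        params=params,
        positions=positions,
        velocities=velocities,
        masses=mass,
        box_edge=float(box_edge),
        temperature_K=float(temperature_K),
        bonds=bonds,
        core2=core2,
        well_r2=well_r2,
        well_eps=well_eps,
        bond_lo2=bond_lo2,
        bond_hi2=bond_hi2,
    )
    system.validate_constraints()
    return system


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _clear_of(placed, cand, box, clearance) -> bool:
    for other in placed:
        d = cand[:, None, :] - other[None, :, :]
        d -= box * np.round(d / box)
        if (d**2).sum(axis=-1).min() < clearance**2:
            return False
    return True
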