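"""Idealized cross-β spine backbone scaffolds.

A cross-β spine is a pair of stacked β-sheets. Sawaya's Class 1 has parallel
strands within each sheet and antiparallel strands between the two sheets;
Class 8 has antiparallel strands within each sheet. The builder here produces
idealized extended-strand backbones (φ ≈ −120°, ψ ≈ +120°, 3.4 Å rise per
residue) on a regular lattice: strand axis along x, in-sheet stacking along y
at spacing ``d_strand`` (~5.5 Å), sheet normal along z at spacing ``d_sheet``
(~12 Å). These serve as the fixed geometry for sequence design and as
ideal-fibril fixtures for the trajectory analytics.

Only backbone atoms (N, Cα, C, O) are represented; side chains enter the
scoring stage as pseudo-centroids placed along the local sheet normal.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from crossbeta.residues import THREE_LETTER, check_sequence

ATOM_NAMES = ("N", "CA", "C", "O")
RISE_PER_RESIDUE = 3.4  # Å, extended β-strand
PLEAT = 0.30            # Å, alternating Cα displacement along the sheet normal
CLASH_FLOOR = 1.0       # Å, hard minimum inter-atom distance for replication
#: x-shift applied to reversed strands so the antiparallel H-bond ladder forms
ANTIPARALLEL_SHIFT = 0.5


class ScaffoldError(ValueError):
    """Raised for invalid scaffold construction or validation failures."""


class ScaffoldIOError(ValueError):
    """Raised for malformed scaffold PDB files."""


@dataclass(frozen=True)
class StrandSpec:
    """Geometry of a single idealized β-strand."""

    n_residues: int = 7
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    rise_per_residue: float = RISE_PER_RESIDUE

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ScaffoldError("n_residues must be >= 1")
        d = np.asarray(self.direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, abs_tol=1e-8):
            raise ScaffoldError("direction must have unit norm")


@dataclass(frozen=True)
class SymmetryTransform:
    """Rigid-body (rotation, translation) transform in Å."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ScaffoldError("rotation must be 3x3 and translation a 3-vector")
        det = float(np.linalg.det(rot))
        if abs(abs(det) - 1.0) > 1e-8 or not np.allclose(
            rot @ rot.T, np.eye(3), atol=1e-8
        ):
            raise ScaffoldError("rotation must be orthonormal with |det| = 1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class Scaffold:
    """Fixed backbone coordinates of a cross-β assembly.

    Attributes
    ----------
    coords : ndarray, shape (n_chains, n_residues, 4, 3)
        Backbone atoms N, Cα, C, O per residue, in Å.
    sheet_id : ndarray of int, shape (n_chains,)
        Sheet membership of each strand.
    strand_direction : ndarray, shape (n_chains, 3)
        Unit N→C axis of each strand.
    d_strand, d_sheet : float
        Nominal in-sheet and inter-sheet spacings, Å.
    n_capped, c_capped : bool
        N-acetyl / C-amide capping flags (neutralize terminal charges).
    sequence : str or None
        Optional one-letter sequence draped on every strand.
    """

    coords: np.ndarray
    sheet_id: np.ndarray
    strand_direction: np.ndarray
    d_strand: float = 5.5
    d_sheet: float = 12.0
    n_capped: bool = False
    c_capped: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.sheet_id = np.asarray(self.sheet_id, dtype=int)
        self.strand_direction = np.asarray(self.strand_direction, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (4, 3):
            raise ScaffoldError("coords must have shape (n_chains, n_residues, 4, 3)")
        if len(self.sheet_id) != self.n_chains:
            raise ScaffoldError("sheet_id length must equal chain count")
        if self.strand_direction.shape != (self.n_chains, 3):
            raise ScaffoldError("strand_direction must be (n_chains, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ScaffoldError("coordinates must be finite")
        if self.sequence is not None:
            check_sequence(self.sequence)
            if len(self.sequence) != self.n_residues:
                raise ScaffoldError("sequence length must match residue count")

    @property
    def n_chains(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def ca(self) -> np.ndarray:
        """Cα coordinates, shape (n_chains, n_residues, 3)."""
        return self.coords[:, :, 1, :]

    def copy(self) -> "Scaffold":
        return replace(
            self,
            coords=self.coords.copy(),
            sheet_id=self.sheet_id.copy(),
            strand_direction=self.strand_direction.copy(),
        )

    def transformed(self, transform: SymmetryTransform) -> "Scaffold":
        out = self.copy()
        out.coords = transform.apply(self.coords.reshape(-1, 3)).reshape(
            self.coords.shape
        )
        out.strand_direction = self.strand_direction @ transform.rotation.T
        return out

    # -- geometry probes -------------------------------------------------

    def adjacent_in_sheet_pairs(self) -> list[tuple[int, int]]:
        """Chain-index pairs of adjacent strands within each sheet.

        Adjacency is by distance between strand centroids: within a sheet,
        strands closer than 1.5 × d_strand are adjacent.
        """
        centroids = self.ca.mean(axis=1)
        pairs = []
        for i in range(self.n_chains):
            for j in range(i + 1, self.n_chains):
                if self.sheet_id[i] != self.sheet_id[j]:
                    continue
                if np.linalg.norm(centroids[i] - centroids[j]) < 1.5 * self.d_strand:
                    pairs.append((i, j))
        return pairs

    def measured_d_strand(self) -> float:
        """Mean Cα–Cα distance between matched residues of adjacent in-sheet strands."""
        pairs = self.adjacent_in_sheet_pairs()
        if not pairs:
            raise ScaffoldError("no adjacent in-sheet strand pairs")
        dists = []
        for i, j in pairs:
            # match each residue of i to its nearest Cα on j (handles
            # reversed numbering of antiparallel strands)
            d = np.linalg.norm(self.ca[i][:, None, :] - self.ca[j][None, :, :], axis=-1)
            dists.append(d.min(axis=1).mean())
        return float(np.mean(dists))

    def measured_d_sheet(self) -> float:
        """Distance between the mean Cα planes of the two sheets."""
        ids = np.unique(self.sheet_id)
        if len(ids) != 2:
            raise ScaffoldError("d_sheet is defined for two-sheet scaffolds")
        planes = [self.ca[self.sheet_id == s].reshape(-1, 3).mean(axis=0) for s in ids]
        normal = _sheet_normal(self)
        return float(abs((planes[1] - planes[0]) @ normal))

    def validate(self, class_id: int | None = None) -> None:
        """Check orientation-pattern and spacing invariants; raise on failure."""
        dirs = self.strand_direction
        for i, j in self.adjacent_in_sheet_pairs():
            dot = float(dirs[i] @ dirs[j])
            if class_id == 1 and dot <= 0:
                raise ScaffoldError("Class 1 requires parallel in-sheet strands")
            if class_id == 8 and dot >= 0:
                raise ScaffoldError("Class 8 requires antiparallel in-sheet strands")
        if class_id == 1 and len(np.unique(self.sheet_id)) == 2:
            s0, s1 = np.unique(self.sheet_id)
            for i in np.flatnonzero(self.sheet_id == s0):
                for j in np.flatnonzero(self.sheet_id == s1):
                    if float(dirs[i] @ dirs[j]) >= 0:
                        raise ScaffoldError(
                            "Class 1 requires antiparallel strands across sheets"
                        )
        if self.adjacent_in_sheet_pairs():
            if abs(self.measured_d_strand() - self.d_strand) > 0.1:
                raise ScaffoldError("in-sheet spacing deviates more than 0.1 Å")


def _sheet_normal(scaffold: Scaffold) -> np.ndarray:
    ids = np.unique(scaffold.sheet_id)
    if len(ids) != 2:
        raise ScaffoldError("sheet normal requires exactly two sheets")
    planes = [
        scaffold.ca[scaffold.sheet_id == s].reshape(-1, 3).mean(axis=0) for s in ids
    ]
    v = planes[1] - planes[0]
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# construction


def _strand_template(n_residues: int, rise: float) -> np.ndarray:
    """Backbone atoms of one extended strand along +x.

    Carbonyl oxygens alternate ±y so that successive residues H-bond to the
    two flanking strands of a sheet, as in a real β-sheet ladder.
    """
    coords = np.empty((n_residues, 4, 3))
    signs = np.array([(-1) ** i for i in range(n_residues)], dtype=float)
    pleats = PLEAT * (signs - signs.mean())  # zero-mean: Cα plane at z = 0
    for i in range(n_residues):
        x = i * rise
        pleat = pleats[i]
        carbonyl = 1.23 * signs[i]  # O points +y for even residues
        coords[i, 0] = (x - 1.20, 0.0, pleat * 0.5)        # N
        coords[i, 1] = (x, 0.0, pleat)                     # CA
        coords[i, 2] = (x + 1.20, 0.0, pleat * 0.5)        # C
        coords[i, 3] = (x + 1.20, carbonyl, pleat * 0.5)   # O
    return coords


def build_cross_beta_scaffold(
    class_id: int,
    n_strands_per_sheet: int,
    n_residues: int,
    d_strand: float = 5.5,
    d_sheet: float = 12.0,
    rise_per_residue: float = RISE_PER_RESIDUE,
    registry_offset: float = 0.0,
    sequence: str | None = None,
) -> Scaffold:
    """Build a two-layer cross-β spine scaffold.

    Parameters
    ----------
    class_id : {1, 8}
        Cross-β symmetry class: 1 = parallel strands within each sheet,
        antiparallel between sheets; 8 = antiparallel within each sheet.
    n_strands_per_sheet, n_residues : int
        Lattice dimensions (two sheets are always built).
    d_strand, d_sheet : float
        In-sheet strand spacing and inter-sheet spacing, Å.
    registry_offset : float
        x-shift of sheet 2 relative to sheet 1 (cross-sheet registry);
        default directly opposed strands.
    """
    if class_id not in (1, 8):
        raise ScaffoldError(f"unsupported cross-beta class {class_id!r}")
    if n_strands_per_sheet < 1 or n_residues < 1:
        raise ScaffoldError("strand and residue counts must be >= 1")
    if d_strand <= 0 or d_sheet <= 0:
        raise ScaffoldError("spacings must be positive")

    template = _strand_template(n_residues, rise_per_residue)
    length_x = (n_residues - 1) * rise_per_residue
    # reversal of a strand: rotate 180° about z through the strand midpoint
    reverse = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]])

    chains, sheets, directions = [], [], []
    for sheet in range(2):
        for k in range(n_strands_per_sheet):
            if class_id == 1:
                reversed_strand = sheet == 1
            else:  # class 8: alternate within each sheet
                reversed_strand = (k % 2) == 1
            c = template.copy()
            if reversed_strand:
                c = (c - [length_x / 2, 0, 0]) @ reverse.T + [length_x / 2, 0, 0]
                c[:, :, 0] += ANTIPARALLEL_SHIFT
                direction = np.array([-1.0, 0.0, 0.0])
            else:
                direction = np.array([1.0, 0.0, 0.0])
            c[:, :, 1] += k * d_strand
            if sheet == 1:
                c[:, :, 2] = d_sheet - c[:, :, 2]
                c[:, :, 0] += registry_offset
            chains.append(c)
            sheets.append(sheet)
            directions.append(direction)

    scaffold = Scaffold(
        coords=np.stack(chains),
        sheet_id=np.array(sheets),
        strand_direction=np.stack(directions),
        d_strand=d_strand,
        d_sheet=d_sheet,
        sequence=sequence,
    )
    scaffold.validate(class_id=class_id)
    return scaffold


def replicate_unit(
    unit: Scaffold, transform: SymmetryTransform, n_copies: int
) -> Scaffold:
    """Concatenate ``n_copies`` of a scaffold, transform applied cumulatively.

    Copy 0 is the unit itself; copy k has the transform applied k times.
    Raises if any two atoms of different copies come within 1.0 Å.
    """
    if n_copies < 1:
        raise ScaffoldError("n_copies must be >= 1")
    copies = [unit.copy()]
    current = unit
    for _ in range(n_copies - 1):
        current = current.transformed(transform)
        copies.append(current)

    for a in range(len(copies)):
        for b in range(a + 1, len(copies)):
            xa = copies[a].coords.reshape(-1, 3)
            xb = copies[b].coords.reshape(-1, 3)
            dmin = np.sqrt(
                ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)
            ).min()
            if dmin < CLASH_FLOOR:
                raise ScaffoldError(
                    f"steric clash between copies {a} and {b}: "
                    f"minimum inter-atom distance {dmin:.2f} Å < {CLASH_FLOOR} Å"
                )

    # sheet ids: offset per copy so sheets remain distinct components
    n_sheets = len(np.unique(unit.sheet_id))
    out = Scaffold(
        coords=np.concatenate([c.coords for c in copies]),
        sheet_id=np.concatenate(
            [c.sheet_id + i * n_sheets for i, c in enumerate(copies)]
        ),
        strand_direction=np.concatenate([c.strand_direction for c in copies]),
        d_strand=unit.d_strand,
        d_sheet=unit.d_sheet,
        n_capped=unit.n_capped,
        c_capped=unit.c_capped,
        sequence=unit.sequence,
    )
    return out


def cap_termini(scaffold: Scaffold, n_cap: bool, c_cap: bool) -> Scaffold:
    """Return a scaffold with N-acetyl / C-amide capping flags set.

    Capping neutralizes the terminal charges used by the scoring stage; it is
    idempotent and does not alter coordinates.
    """
    out = scaffold.copy()
    out.n_capped = bool(n_cap) or out.n_capped
    out.c_capped = bool(c_cap) or out.c_capped
    return out


# ---------------------------------------------------------------------------
# PDB serialization

_REMARK_TAG = "REMARK 250 CROSSBETA "


def write_pdb(scaffold: Scaffold, path) -> None:
    """Write the scaffold as standard ATOM records, one chain per strand.

    Scaffold metadata (sheet ids, spacings, caps) is carried in a REMARK 250
    line so that round trips are lossless; foreign PDBs without the remark are
    still readable, with sheets inferred from geometry.
    """
    meta = {
        "sheet_id": scaffold.sheet_id.tolist(),
        "strand_direction": np.round(scaffold.strand_direction, 6).tolist(),
        "d_strand": scaffold.d_strand,
        "d_sheet": scaffold.d_sheet,
        "n_capped": scaffold.n_capped,
        "c_capped": scaffold.c_capped,
        "sequence": scaffold.sequence,
    }
    chain_ids = _chain_ids(scaffold.n_chains)
    lines = [_REMARK_TAG + json.dumps(meta, separators=(",", ":"))]
    serial = 1
    seq = scaffold.sequence
    for c in range(scaffold.n_chains):
        for r in range(scaffold.n_residues):
            resname = THREE_LETTER[seq[r]] if seq else "UNK"
            for a, name in enumerate(ATOM_NAMES):
                x, y, z = scaffold.coords[c, r, a]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:>5d}  {name:<3s} {resname:>3s} {chain_ids[c]}"
                    f"{r + 1:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _chain_ids(n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    if n > len(alphabet):
        raise ScaffoldError(f"cannot assign chain IDs for {n} chains")
    return list(alphabet[:n])


def read_pdb(path) -> Scaffold:
    """Read a scaffold from a PDB file written by :func:`write_pdb` or similar.

    Requires complete N/CA/C/O backbone records per residue and equal residue
    counts per chain. Malformed ATOM records raise with the offending line
    number.
    """
    with open(path) as fh:
        text = fh.read()
    meta = None
    chains: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    chain_order: list[str] = []
    resnames: dict[str, dict[int, str]] = {}
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if line.startswith(_REMARK_TAG):
            meta = json.loads(line[len(_REMARK_TAG):])
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ScaffoldIOError(f"line {lineno}: truncated ATOM record")
        try:
            name = line[12:16].strip()
            chain_id = line[21]
            resseq = int(line[22:26])
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
        except ValueError as exc:
            raise ScaffoldIOError(f"line {lineno}: malformed ATOM record ({exc})")
        if chain_id not in chains:
            chains[chain_id] = {}
            resnames[chain_id] = {}
            chain_order.append(chain_id)
        chains[chain_id].setdefault(resseq, {})[name] = xyz
        resnames[chain_id][resseq] = line[17:20].strip()

    if not chains:
        raise ScaffoldIOError("no ATOM records found")

    per_chain = []
    for chain_id in chain_order:
        residues = chains[chain_id]
        order = sorted(residues)
        coords = np.empty((len(order), 4, 3))
        for ri, resseq in enumerate(order):
            atoms = residues[resseq]
            for ai, name in enumerate(ATOM_NAMES):
                if name not in atoms:
                    raise ScaffoldIOError(
                        f"chain {chain_id} residue {resseq}: missing {name} atom"
                    )
                coords[ri, ai] = atoms[name]
        per_chain.append(coords)
    n_res = {c.shape[0] for c in per_chain}
    if len(n_res) != 1:
        raise ScaffoldIOError("chains have unequal residue counts")
    coords = np.stack(per_chain)

    if meta is not None:
        return Scaffold(
            coords=coords,
            sheet_id=np.array(meta["sheet_id"]),
            strand_direction=np.array(meta["strand_direction"]),
            d_strand=meta["d_strand"],
            d_sheet=meta["d_sheet"],
            n_capped=meta["n_capped"],
            c_capped=meta["c_capped"],
            sequence=meta["sequence"],
        )

    # foreign PDB: infer directions from Cα end-to-end vectors and sheets by
    # single-linkage clustering of strand centroids at an 8 Å cutoff
    ca = coords[:, :, 1, :]
    if coords.shape[1] > 1:
        vec = ca[:, -1] - ca[:, 0]
        directions = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    else:
        directions = np.tile([1.0, 0.0, 0.0], (coords.shape[0], 1))
    centroids = ca.mean(axis=1)
    n = coords.shape[0]
    sheet_id = -np.ones(n, dtype=int)
    next_id = 0
    for i in range(n):
        if sheet_id[i] >= 0:
            continue
        stack = [i]
        sheet_id[i] = next_id
        while stack:
            a = stack.pop()
            for b in range(n):
                if sheet_id[b] < 0 and np.linalg.norm(
                    centroids[a] - centroids[b]
                ) < 8.0:
                    sheet_id[b] = next_id
                    stack.append(b)
        next_id += 1
    return Scaffold(
        coords=coords,
        sheet_id=sheet_id,
        strand_direction=directions,
    )
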