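"""Sequence scoring on a fixed cross-β scaffold.

The design objective is

    Γ_score = ΔG_binding − λ · P_aggregation

where ΔG_binding is the binding energy of a test chain with its scaffold
neighbors and P_aggregation is the sequence's intrinsic aggregation
propensity. This package evaluates ΔG_binding with a residue-level pairwise
contact potential (20×20 table, side-chain pseudo-centroids, 6.5 Å cutoff)
plus a constant per-backbone-H-bond term, and P_aggregation as an additive
per-residue scale. Both tables ship as plain-text data files and are
swappable; the absolute energies are this package's own parameterization in
dimensionless score units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from crossbeta.residues import AMINO_ACIDS, RESIDUE_CLASSES, SIDE_CHAIN_CHARGE, check_sequence
from crossbeta.scaffolds import Scaffold

#: spec-level class sizes: hydrophobic 9, polar 5, charged 4, other 2
ResidueClassTable = dict(RESIDUE_CLASSES)

DEFAULT_CUTOFF = 6.5       # Å, side-chain centroid contact cutoff
DEFAULT_HB_ENERGY = -0.5   # score units per backbone H-bond of the test chain
DEFAULT_HB_CUTOFF = 4.5    # Å, N–O distance for a backbone H-bond
DEFAULT_TERMINAL_ENERGY = 0.25  # score units per unit terminal charge product
SIDECHAIN_EXTENSION = 2.0  # Å, Cα → pseudo-centroid offset along local normal


def _data_path(name: str):
    return resources.files("crossbeta.data").joinpath(name)


def _read_matrix(path) -> tuple[np.ndarray, str]:
    rows = {}
    order = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if order is None:
                order = "".join(parts[1:])
                continue
            rows[parts[0]] = [float(x) for x in parts[1:]]
    mat = np.array([rows[a] for a in order])
    return mat, order


@dataclass(frozen=True)
class CaseSpec:
    """Hydration-composition constraint: per-class residue counts."""

    n_hydrophobic: int
    n_polar: int
    n_charge: int
    n_other: int

    def __post_init__(self) -> None:
        for n in self.as_tuple():
            if n < 0:
                raise ValueError("class counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_hydrophobic, self.n_polar, self.n_charge, self.n_other)

    @property
    def length(self) -> int:
        return sum(self.as_tuple())

    def satisfied_by(self, sequence: str) -> bool:
        return composition(sequence) == self


#: the two hydration cases explored in the design campaign (7-mers)
CASE_1 = CaseSpec(n_hydrophobic=5, n_polar=0, n_charge=2, n_other=0)
CASE_2 = CaseSpec(n_hydrophobic=5, n_polar=2, n_charge=0, n_other=0)
CASES = {1: CASE_1, 2: CASE_2}


class PotentialTable:
    """Symmetric 20×20 residue-pair contact energies plus backbone terms.

    Parameters are dimensionless score units; ``cutoff`` is the side-chain
    centroid contact distance in Å.
    """

    def __init__(
        self,
        pair_energies: np.ndarray,
        residues: str = AMINO_ACIDS,
        cutoff: float = DEFAULT_CUTOFF,
        hb_energy: float = DEFAULT_HB_ENERGY,
        hb_cutoff: float = DEFAULT_HB_CUTOFF,
        terminal_energy: float = DEFAULT_TERMINAL_ENERGY,
    ) -> None:
        pair_energies = np.asarray(pair_energies, dtype=float)
        if pair_energies.shape != (20, 20):
            raise ValueError("pair_energies must be 20x20")
        if not np.all(np.isfinite(pair_energies)):
            raise ValueError("pair energies must be finite")
        if not np.allclose(pair_energies, pair_energies.T, atol=1e-9):
            raise ValueError("pair energies must be symmetric")
        self.pair_energies = pair_energies
        self.index = {aa: i for i, aa in enumerate(residues)}
        self.cutoff = float(cutoff)
        self.hb_energy = float(hb_energy)
        self.hb_cutoff = float(hb_cutoff)
        self.terminal_energy = float(terminal_energy)

    def energy(self, a: str, b: str) -> float:
        return float(self.pair_energies[self.index[a], self.index[b]])

    @classmethod
    def from_files(cls, path=None, **kwargs) -> "PotentialTable":
        """Load the shipped (or a user) tab-separated 20×20 table."""
        path = path or _data_path("contact_potential.tsv")
        mat, order = _read_matrix(path)
        return cls(mat, residues=order, **kwargs)

    @classmethod
    def zeros(cls, **kwargs) -> "PotentialTable":
        kwargs.setdefault("hb_energy", 0.0)
        kwargs.setdefault("terminal_energy", 0.0)
        return cls(np.zeros((20, 20)), **kwargs)


class AggregationScale:
    """Additive per-residue intrinsic aggregation propensities."""

    def __init__(self, values: dict[str, float]) -> None:
        if set(values) != set(AMINO_ACIDS):
            raise ValueError("scale must cover exactly the 20 canonical residues")
        for v in values.values():
            if not math.isfinite(v):
                raise ValueError("scale values must be finite")
        self.values = dict(values)

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    @classmethod
    def from_file(cls, path=None) -> "AggregationScale":
        path = path or _data_path("aggregation_scale.tsv")
        values = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("res\t"):
                    continue
                aa, val = line.split("\t")
                values[aa] = float(val)
        return cls(values)

    @classmethod
    def zeros(cls) -> "AggregationScale":
        return cls({aa: 0.0 for aa in AMINO_ACIDS})


@dataclass(frozen=True)
class ScoreBreakdown:
    """Γ_score with its binding and weighted-aggregation components."""

    gamma_score: float
    dg_binding: float
    lambda_weight: float
    p_aggregation: float

    @property
    def lambda_times_p(self) -> float:
        return self.lambda_weight * self.p_aggregation

    def __post_init__(self) -> None:
        if abs(self.gamma_score - (self.dg_binding - self.lambda_times_p)) > 0.02:
            raise ValueError("gamma_score must equal dg_binding - lambda*P")


# ---------------------------------------------------------------------------
# operations


def classify_residue(aa: str) -> str:
    """Classify a one-letter code into hydrophobic/polar/charged/other."""
    try:
        return RESIDUE_CLASSES[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid code {aa!r}") from None


def composition(sequence: str) -> CaseSpec:
    """Per-class residue counts of a sequence."""
    check_sequence(sequence)
    counts = {"hydrophobic": 0, "polar": 0, "charged": 0, "other": 0}
    for aa in sequence:
        counts[RESIDUE_CLASSES[aa]] += 1
    return CaseSpec(
        n_hydrophobic=counts["hydrophobic"],
        n_polar=counts["polar"],
        n_charge=counts["charged"],
        n_other=counts["other"],
    )


def sidechain_centroids(scaffold: Scaffold) -> np.ndarray:
    """Pseudo side-chain centroids: Cα displaced along the local pleat normal.

    The direction is Cα minus the N/C midpoint (the β-pleat direction), which
    is rigid-motion covariant, so contact energies are invariant under rigid
    transforms of the whole scaffold.
    """
    n = scaffold.coords[:, :, 0, :]
    ca = scaffold.coords[:, :, 1, :]
    c = scaffold.coords[:, :, 2, :]
    v = ca - 0.5 * (n + c)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    norm[norm < 1e-9] = 1.0
    return ca + SIDECHAIN_EXTENSION * v / norm


def _test_chain(scaffold: Scaffold, centroids: np.ndarray, cutoff: float) -> int:
    """Interior chain: the one with the most inter-chain centroid contacts."""
    nc = scaffold.n_chains
    flat = centroids.reshape(nc, -1, 3)
    best, best_count = 0, -1
    for i in range(nc):
        count = 0
        for j in range(nc):
            if j == i:
                continue
            d = np.linalg.norm(flat[i][:, None, :] - flat[j][None, :, :], axis=-1)
            count += int((d <= cutoff).sum())
        if count > best_count:
            best, best_count = i, count
    return best


def count_backbone_hbonds(scaffold: Scaffold, chain: int, hb_cutoff: float) -> int:
    """Backbone H-bonds of one chain with all others (N–O distance criterion)."""
    n_atoms = scaffold.coords[:, :, 0, :]
    o_atoms = scaffold.coords[:, :, 3, :]
    count = 0
    for j in range(scaffold.n_chains):
        if j == chain:
            continue
        d_no = np.linalg.norm(
            n_atoms[chain][:, None, :] - o_atoms[j][None, :, :], axis=-1
        )
        d_on = np.linalg.norm(
            o_atoms[chain][:, None, :] - n_atoms[j][None, :, :], axis=-1
        )
        count += int((d_no <= hb_cutoff).sum()) + int((d_on <= hb_cutoff).sum())
    return count


def binding_free_energy(
    scaffold: Scaffold, sequence: str, potential: PotentialTable
) -> float:
    """Binding energy of the test chain with its neighbors, score units.

    The same sequence is draped on every strand. Contributions: residue-pair
    contact energies for inter-chain centroid pairs within the cutoff,
    a constant per backbone H-bond of the test chain, and terminal-charge
    interactions unless the corresponding terminus is capped.
    """
    check_sequence(sequence)
    if len(sequence) != scaffold.n_residues:
        raise ValueError(
            f"sequence length {len(sequence)} != scaffold residue count "
            f"{scaffold.n_residues}"
        )
    if scaffold.n_chains < 2:
        return 0.0
    centroids = sidechain_centroids(scaffold)
    test = _test_chain(scaffold, centroids, potential.cutoff)

    energy = 0.0
    for j in range(scaffold.n_chains):
        if j == test:
            continue
        d = np.linalg.norm(
            centroids[test][:, None, :] - centroids[j][None, :, :], axis=-1
        )
        for a, b in zip(*np.nonzero(d <= potential.cutoff)):
            energy += potential.energy(sequence[a], sequence[b])

    energy += potential.hb_energy * count_backbone_hbonds(
        scaffold, test, potential.hb_cutoff
    )

    # terminal charges: +1 on the free amine, -1 on the free carboxylate
    terminals = []  # (charge, coords per chain)
    if not scaffold.n_capped:
        terminals.append((+1, scaffold.coords[:, 0, 0, :]))
    if not scaffold.c_capped:
        terminals.append((-1, scaffold.coords[:, -1, 2, :]))
    for qa, xa in terminals:
        for qb, xb in terminals:
            for j in range(scaffold.n_chains):
                if j == test:
                    continue
                if np.linalg.norm(xa[test] - xb[j]) <= potential.cutoff:
                    energy += potential.terminal_energy * qa * qb
    return float(energy)


def aggregation_propensity(sequence: str, scale: AggregationScale) -> float:
    """Additive intrinsic aggregation propensity of a sequence."""
    check_sequence(sequence)
    return float(sum(scale[aa] for aa in sequence))


def gamma_score(dg_binding: float, lambda_times_p: float) -> float:
    """Design score: ΔG_binding minus the weighted aggregation propensity."""
    if not (math.isfinite(dg_binding) and math.isfinite(lambda_times_p)):
        raise ValueError("gamma_score requires finite inputs")
    return dg_binding - lambda_times_p


def score_sequence(
    scaffold: Scaffold,
    sequence: str,
    potential: PotentialTable,
    scale: AggregationScale,
    lambda_weight: float,
) -> ScoreBreakdown:
    """Full Γ_score breakdown for a sequence draped on a scaffold."""
    dg = binding_free_energy(scaffold, sequence, potential)
    p = aggregation_propensity(sequence, scale)
    return ScoreBreakdown(
        gamma_score=gamma_score(dg, lambda_weight * p),
        dg_binding=dg,
        lambda_weight=lambda_weight,
        p_aggregation=p,
    )
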