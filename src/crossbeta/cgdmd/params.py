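"""Coarse-grained model parameters, loaded from tabular text data files.

Reduced units: length in Å, mass in amu, energy in units of the backbone
H-bond well depth ε₀ (so the H-bond depth is 1), time in τ = Å·√(amu/ε₀).
Laboratory temperature maps to reduced temperature through
``energy_scale_K`` = ε₀/k_B, chosen so that the 296–310 K window spans the
fibrillization regime of the shipped parameter set.

The shipped numeric values are a nominal parameterization of this package
(flagged in the data-file headers); the file format, not any particular
published constant, is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from crossbeta.residues import AMINO_ACIDS

BACKBONE_BEADS = ("NH", "CA", "CO")
#: backbone bond lengths, Å: NH–CA, CA–CO, CO–NH(next)
BOND_NH_CA = 1.46
BOND_CA_CO = 1.51
BOND_CO_NH = 1.33
#: Cα–Cα rise of the extended CG chain (colinear backbone template)
RISE = BOND_NH_CA + BOND_CA_CO + BOND_CO_NH


def _data_path(name: str):
    return resources.files("crossbeta.data").joinpath(name)


@dataclass(frozen=True)
class CGModelParams:
    """Bead geometry, masses, and square-well interaction tables."""

    #: bead name -> (diameter Å, mass amu); side chains keyed "R_<aa>"
    bead_diameter: dict = field(default_factory=dict)
    bead_mass: dict = field(default_factory=dict)
    #: per-amino-acid Cα–R bond length, Å
    ca_r_bond: dict = field(default_factory=dict)
    #: 20×20 side-chain pair well depths, ε₀ units (order = AMINO_ACIDS)
    pair_depths: np.ndarray = field(
        default_factory=lambda: np.zeros((20, 20))
    )
    hb_depth: float = 1.0        # ε₀, backbone NH–CO H-bond well depth
    hb_range: float = 4.5        # Å, H-bond well outer radius
    sc_well_factor: float = 1.5  # side-chain well range = factor × contact σ
    bond_tolerance: float = 0.02375  # fractional half-width of bond windows
    energy_scale_K: float = 1000.0   # ε₀/k_B, Kelvin per reduced energy unit
    ghost_rate: float = 0.1          # thermostat refreshes per bead per τ

    def __post_init__(self) -> None:
        depths = np.asarray(self.pair_depths, dtype=float)
        if depths.shape != (20, 20):
            raise ValueError("pair_depths must be 20x20")
        if not np.allclose(depths, depths.T, atol=1e-9):
            raise ValueError("pair_depths must be symmetric")
        object.__setattr__(self, "pair_depths", depths)
        for aa in AMINO_ACIDS:
            key = f"R_{aa}"
            if self.bead_diameter and key not in self.bead_diameter:
                raise ValueError(f"missing side-chain bead {key}")
        for d in self.bead_diameter.values():
            if d <= 0:
                raise ValueError("bead diameters must be positive")

    @classmethod
    def from_files(cls, beads_path=None, wells_path=None, **kwargs) -> "CGModelParams":
        beads_path = beads_path or _data_path("cg_beads.tsv")
        wells_path = wells_path or _data_path("cg_pair_wells.tsv")
        diameter, mass, ca_r = {}, {}, {}
        with open(beads_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("bead\t"):
                    continue
                name, d, m, b = line.split("\t")
                diameter[name] = float(d)
                mass[name] = float(m)
                if b != "-":
                    ca_r[name.removeprefix("R_")] = float(b)
        rows = {}
        order = None
        with open(wells_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if order is None:
                    order = parts[1:]
                    continue
                rows[parts[0]] = [float(x) for x in parts[1:]]
        mat = np.array([rows[a] for a in AMINO_ACIDS])
        idx = [order.index(a) for a in AMINO_ACIDS]
        mat = mat[:, idx]
        return cls(
            bead_diameter=diameter, bead_mass=mass, ca_r_bond=ca_r,
            pair_depths=mat, **kwargs,
        )

    def without_attraction(self) -> "CGModelParams":
        """Purely repulsive control: hard spheres and bonds only."""
        return replace(
            self, pair_depths=np.zeros((20, 20)), hb_depth=0.0
        )

    def with_tolerance(self, bond_tolerance: float) -> "CGModelParams":
        return replace(self, bond_tolerance=bond_tolerance)

    def kT(self, temperature_K: float) -> float:
        """Reduced temperature (ε₀ units) for a laboratory temperature."""
        return temperature_K / self.energy_scale_K

    def sc_depth(self, aa_a: str, aa_b: str) -> float:
        i = AMINO_ACIDS.index(aa_a)
        j = AMINO_ACIDS.index(aa_b)
        return float(self.pair_depths[i, j])
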