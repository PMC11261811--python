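"""Two-round design-loop orchestration and fixture generation.

One *round* runs the Monte Carlo sequence design for every configured
(hydration case, λ) combination on a fixed scaffold, screens the selected
candidates in short coarse-grained simulations across a set of temperatures,
extends the best temperature, and classifies each candidate's final
structure. The best predominantly-parallel candidate then seeds the next
round's extended capped scaffold.

Classification: "predominantly parallel" = final parallel_fraction ≥ 50%;
"mixed" = fibrils with < 50% parallel pairs; "low fibril content" = final
β-sheet content < 20%. The 50% split mirrors the campaign's partition of
candidates; the 20% fibril threshold is this package's declared choice.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossbeta import fibrilmetrics as fm
from crossbeta.cgdmd import CGModelParams, build_cg_system, run_dmd
from crossbeta.mcdesign import DesignConfig, run_design
from crossbeta.scaffolds import Scaffold, build_cross_beta_scaffold, cap_termini
from crossbeta.scoring import (
    CASES,
    AggregationScale,
    CaseSpec,
    PotentialTable,
    composition,
    score_sequence,
)

#: the eight designed 7-mers of the two-round campaign, with their case
DESIGNED_PEPTIDES = {
    "PP1": ("GDIKIVV", 1),
    "PP2": ("GNIVTFV", 2),
    "PP3": ("GAIDWVK", 1),
    "PP4": ("GGIDWKI", 1),
    "PP5": ("ADKVMFV", 1),
    "PP6": ("GDFVKFV", 1),
    "PP7": ("GNYTMFI", 2),
    "PP8": ("ANMTVFV", 2),
}

PARALLEL_THRESHOLD = 50.0  # % parallel pairs for "predominantly parallel"
FIBRIL_THRESHOLD = 20.0    # % β-content below which a run is "low fibril content"


@dataclass(frozen=True)
class RoundConfig:
    """Settings of one design round (desk-scale defaults)."""

    cases: tuple[int, ...] = (1, 2)
    lambdas: tuple[float, ...] = (2.0, 3.0)
    design_steps: int = 500
    temperatures_K: tuple[float, ...] = (296.0, 303.0, 310.0)
    screen_t_end: float = 500.0
    extended_t_end: float = 1500.0
    n_peptides: int = 12
    box_edge: float = 126.0
    bond_tolerance: float = 0.075
    seed: int = 0
    selection_count: int = 2
    n_strands_per_sheet: int = 4
    n_residues: int = 7

    def __post_init__(self) -> None:
        if not (self.cases and self.lambdas and self.temperatures_K):
            raise ValueError("need at least one case, lambda, and temperature")


@dataclass
class CandidateReport:
    sequence: str
    case: int
    lambda_weight: float
    gamma: float
    dg_binding: float
    lambda_times_p: float
    screen: dict = field(default_factory=dict)  # T -> final FrameMetrics
    best_temperature: float | None = None
    final_beta: float | None = None
    final_parallel: float | None = None
    classification: str = "failed"


@dataclass
class RoundReport:
    config: RoundConfig
    candidates: list[CandidateReport] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.candidates, key=lambda c: c.gamma):
            rows.append(
                {
                    "sequence": c.sequence,
                    "case": c.case,
                    "lambda": c.lambda_weight,
                    "gamma": c.gamma,
                    "dg_binding": c.dg_binding,
                    "lambda_times_p": c.lambda_times_p,
                    "best_T_K": c.best_temperature,
                    "final_beta_content": c.final_beta,
                    "final_parallel_fraction": c.final_parallel,
                    "classification": c.classification,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "candidates": self.to_frame().to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def classify(final_beta: float, final_parallel: float | None) -> str:
    """Partition a candidate by its final simulated structure.

    Exhaustive and mutually exclusive: low fibril content / predominantly
    parallel / mixed (< 50% parallel pairs).
    """
    if final_beta < FIBRIL_THRESHOLD or final_parallel is None:
        return "low fibril content"
    if final_parallel >= PARALLEL_THRESHOLD:
        return "predominantly parallel"
    return "mixed"


def simulate_candidate(
    sequence: str,
    config: RoundConfig,
    cg_params: CGModelParams,
    criterion: fm.HBondCriterion,
    seed: int,
) -> tuple[dict, float, fm.FrameMetrics]:
    """Temperature screen + extended run; returns (screen, best_T, final)."""
    screen = {}
    for T in config.temperatures_K:
        system = build_cg_system(
            sequence, config.n_peptides, config.box_edge, T, cg_params, seed=seed
        )
        traj = run_dmd(
            system,
            t_end=config.screen_t_end,
            frame_interval=config.screen_t_end / 4,
            seed=seed + int(T),
        )
        frame = list(traj.frames(system.topology, config.box_edge))[-1]
        screen[T] = fm.frame_metrics(frame, criterion)
    # highest fibrillization propensity: max final β-content, ties → lower T
    best_T = max(
        config.temperatures_K, key=lambda T: (screen[T].beta_content, -T)
    )
    system = build_cg_system(
        sequence, config.n_peptides, config.box_edge, best_T, cg_params,
        seed=seed + 1,
    )
    traj = run_dmd(
        system,
        t_end=config.extended_t_end,
        frame_interval=config.extended_t_end / 4,
        seed=seed + 2,
    )
    final_frame = list(traj.frames(system.topology, config.box_edge))[-1]
    return screen, best_T, fm.frame_metrics(final_frame, criterion)


def run_round(
    config: RoundConfig,
    scaffold: Scaffold | None = None,
    potential: PotentialTable | None = None,
    scale: AggregationScale | None = None,
    cg_params: CGModelParams | None = None,
    criterion: fm.HBondCriterion | None = None,
) -> RoundReport:
    """Execute design → screen → extend → classify for one round."""
    scaffold = scaffold or build_cross_beta_scaffold(
        1, config.n_strands_per_sheet, config.n_residues
    )
    potential = potential or PotentialTable.from_files()
    scale = scale or AggregationScale.from_file()
    cg_params = (
        cg_params or CGModelParams.from_files()
    ).with_tolerance(config.bond_tolerance)
    criterion = criterion or fm.HBondCriterion()

    report = RoundReport(config=config)
    report.provenance = {
        "seed": config.seed,
        "params_hash": hashlib.sha256(
            cg_params.pair_depths.tobytes()
        ).hexdigest()[:16],
        "design_steps": config.design_steps,
    }

    candidates: list[CandidateReport] = []
    for case_id in config.cases:
        for lam in config.lambdas:
            dconf = DesignConfig(
                case=CASES[case_id],
                lambda_weight=lam,
                n_steps=config.design_steps,
                seed=config.seed + case_id * 100 + int(lam * 10),
            )
            trace = run_design(scaffold, dconf, potential, scale)
            for seq, _gamma in trace.top_sequences(config.selection_count):
                breakdown = score_sequence(scaffold, seq, potential, scale, lam)
                candidates.append(
                    CandidateReport(
                        sequence=seq,
                        case=case_id,
                        lambda_weight=lam,
                        gamma=breakdown.gamma_score,
                        dg_binding=breakdown.dg_binding,
                        lambda_times_p=breakdown.lambda_times_p,
                    )
                )

    for rank, cand in enumerate(sorted(candidates, key=lambda c: c.gamma)):
        try:
            screen, best_T, final = simulate_candidate(
                cand.sequence, config, cg_params, criterion,
                seed=config.seed + 1000 + rank,
            )
        except Exception:  # stage failure: mark candidate failed, continue
            cand.classification = "failed"
            report.candidates.append(cand)
            continue
        cand.screen = {T: m for T, m in screen.items()}
        cand.best_temperature = best_T
        cand.final_beta = final.beta_content
        cand.final_parallel = final.parallel_fraction
        cand.classification = classify(final.beta_content, final.parallel_fraction)
        report.candidates.append(cand)
    return report


def refine_scaffold(
    report: RoundReport,
    n_strands_per_sheet: int = 8,
    d_strand: float = 5.5,
    d_sheet: float = 12.0,
) -> Scaffold:
    """Seed the next round: the best predominantly-parallel candidate's
    sequence draped on an extended (16-chain) capped Class-1 scaffold."""
    qualifying = [
        c for c in report.candidates if c.classification == "predominantly parallel"
    ]
    if not qualifying:
        raise ValueError("no predominantly-parallel candidate in the report")
    best = min(qualifying, key=lambda c: c.gamma)
    scaffold = build_cross_beta_scaffold(
        1,
        n_strands_per_sheet,
        len(best.sequence),
        d_strand,
        d_sheet,
        sequence=best.sequence,
    )
    return cap_termini(scaffold, n_cap=True, c_cap=True)


def make_fixtures(seed: int = 0, out_dir=None) -> dict:
    """Deterministic fixture bundle: designed sequences, ideal scaffolds,
    coil/fibril frames, and parallel/antiparallel synthetic spectra."""
    from crossbeta import ftir
    from crossbeta.scaffolds import write_pdb

    rng = np.random.default_rng(seed)
    sequences = {name: seq for name, (seq, _case) in DESIGNED_PEPTIDES.items()}
    for name, (seq, case_id) in DESIGNED_PEPTIDES.items():
        if not CASES[case_id].satisfied_by(seq):
            raise ValueError(f"{name} violates its case composition")

    class1 = build_cross_beta_scaffold(1, 4, 7)
    class8 = build_cross_beta_scaffold(8, 4, 7)

    fibril_frame = fm.Frame.from_scaffold(class1)
    coil = fibril_frame.nh + rng.uniform(0, 100, size=(class1.n_chains, 1, 3))
    coil_frame = fm.Frame(
        nh=coil,
        co=coil + rng.normal(0, 0.5, size=coil.shape),
        ca=coil + rng.normal(0, 0.5, size=coil.shape),
    )

    spectra = {
        "parallel": ftir.synth_spectrum(
            ftir.PRESETS["parallel"], noise_sigma=0.005, seed=seed, label="parallel"
        ),
        "antiparallel": ftir.synth_spectrum(
            ftir.PRESETS["antiparallel"],
            noise_sigma=0.005,
            seed=seed + 1,
            label="antiparallel",
        ),
    }

    bundle = {
        "sequences": sequences,
        "class1": class1,
        "class8": class8,
        "fibril_frame": fibril_frame,
        "coil_frame": coil_frame,
        "spectra": spectra,
    }
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "sequences.tsv"), "w") as fh:
            fh.write("name\tsequence\tcase\n")
            for name, (seq, case_id) in DESIGNED_PEPTIDES.items():
                fh.write(f"{name}\t{seq}\t{case_id}\n")
        write_pdb(class1, os.path.join(out_dir, "class1.pdb"))
        write_pdb(class8, os.path.join(out_dir, "class8.pdb"))
        for name, spec in spectra.items():
            spec.to_csv(os.path.join(out_dir, f"spectrum_{name}.csv"))
    return bundle


def bundle_hash(bundle: dict) -> str:
    """Stable digest of a fixture bundle (determinism checks)."""
    h = hashlib.sha256()
    for name in sorted(bundle["sequences"]):
        h.update(name.encode())
        h.update(bundle["sequences"][name].encode())
    for key in ("class1", "class8"):
        h.update(np.ascontiguousarray(bundle[key].coords).tobytes())
    h.update(np.ascontiguousarray(bundle["coil_frame"].nh).tobytes())
    for name in sorted(bundle["spectra"]):
        h.update(np.ascontiguousarray(bundle["spectra"][name].absorbance).tobytes())
    return h.hexdigest()
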