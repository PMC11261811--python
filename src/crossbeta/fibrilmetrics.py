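"""β-sheet structure metrics for coarse-grained frames and scaffolds.

A backbone H-bond is operationalized as an NH(donor)–CO(acceptor) bead
distance below a threshold (default 4.5 Å, matched to the CG H-bond well
range and the idealized scaffold geometry). Two chains form a *strand pair*
when their mutual H-bonds form a ladder: participating residues spaced at
most two apart (β-sheet ladders intrinsically alternate donors/acceptors,
so every-other-residue participation is a contiguous ladder), with at least
``min_run`` participants. "% parallel content" is computed over H-bonded
strand PAIRS, not residues — the orientation of a pair is the sign of the
dot product of the two strands' end-to-end N→C vectors.

All metrics are deterministic functions of a frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

DEFAULT_HB_THRESHOLD = 4.5   # Å
DEFAULT_MIN_RUN = 3          # participating residues per ladder
DEFAULT_AGGREGATE_CUTOFF = 13.0  # Å, chain-to-chain contact distance


class MetricsError(ValueError):
    """Raised for invalid frames or metric preconditions."""


@dataclass(frozen=True)
class HBondCriterion:
    """Operational β-sheet definition for the CG model."""

    threshold: float = DEFAULT_HB_THRESHOLD
    min_run: int = DEFAULT_MIN_RUN
    aggregate_cutoff: float = DEFAULT_AGGREGATE_CUTOFF

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise MetricsError("threshold must be non-negative")
        if self.min_run < 2:
            raise MetricsError("min_run must be >= 2")


@dataclass
class Frame:
    """Per-chain bead positions needed by the metrics.

    ``nh``, ``co``, ``ca`` have shape (n_chains, n_residues, 3); ``sc``
    (side-chain beads) is optional. ``box_edge`` enables minimum-image
    distances for periodic systems.
    """

    nh: np.ndarray
    co: np.ndarray
    ca: np.ndarray
    sc: np.ndarray | None = None
    box_edge: float | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.nh = np.asarray(self.nh, dtype=float)
        self.co = np.asarray(self.co, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        shapes = {self.nh.shape, self.co.shape, self.ca.shape}
        if len(shapes) != 1 or self.nh.ndim != 3 or self.nh.shape[2] != 3:
            raise MetricsError("nh/co/ca must share shape (n_chains, n_res, 3)")
        if self.sc is not None:
            self.sc = np.asarray(self.sc, dtype=float)
            if self.sc.shape != self.nh.shape:
                raise MetricsError("sc must match nh/co/ca shape")

    @property
    def n_chains(self) -> int:
        return self.nh.shape[0]

    @property
    def n_residues(self) -> int:
        return self.nh.shape[1]

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """a − b with minimum-image convention when periodic."""
        d = a - b
        if self.box_edge is not None:
            d -= self.box_edge * np.round(d / self.box_edge)
        return d

    @classmethod
    def from_scaffold(cls, scaffold, time: float = 0.0) -> "Frame":
        """Map a backbone scaffold onto CG-equivalent beads.

        The amide N plays the NH bead, the carbonyl O the CO bead (it is the
        H-bond acceptor atom), and Cα itself the CA bead.
        """
        return cls(
            nh=scaffold.coords[:, :, 0, :],
            co=scaffold.coords[:, :, 3, :],
            ca=scaffold.coords[:, :, 1, :],
            time=time,
        )


@dataclass
class FrameMetrics:
    """Per-frame summary of β-sheet organization."""

    time: float
    beta_content: float
    parallel_fraction: float | None
    n_layers: int
    largest_aggregate: int


# ---------------------------------------------------------------------------
# operations


def backbone_hbonds(
    frame: Frame, criterion: HBondCriterion
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All NH–CO bead pairs within the threshold.

    Returns (donor (chain, residue), acceptor (chain, residue)) pairs.
    Intra-chain pairs are excluded unless the residues are at least three
    apart (nearest-neighbor amide geometry is not an H-bond).
    """
    nc, nr = frame.n_chains, frame.n_residues
    nh = frame.nh.reshape(-1, 3)
    co = frame.co.reshape(-1, 3)
    if criterion.threshold <= 0:
        return []
    d = np.linalg.norm(
        frame.displacement(nh[:, None, :], co[None, :, :]), axis=-1
    )
    out = []
    for i, j in zip(*np.nonzero(d <= criterion.threshold)):
        ci, ri = divmod(int(i), nr)
        cj, rj = divmod(int(j), nr)
        if ci == cj and abs(ri - rj) < 3:
            continue
        out.append(((ci, ri), (cj, rj)))
    return out


def _max_ladder_run(residues: set[int]) -> tuple[int, set[int]]:
    """Longest ladder run in a participant set (gap ≤ 2 between successive
    participants); returns (participant count, residues spanned by the run).
    """
    if not residues:
        return 0, set()
    order = sorted(residues)
    best_count, best_span = 1, {order[0]}
    count, start = 1, 0
    for k in range(1, len(order)):
        if order[k] - order[k - 1] <= 2:
            count += 1
        else:
            count, start = 1, k
        if count > best_count:
            best_count = count
            best_span = set(range(order[start], order[k] + 1))
    return best_count, best_span


def strand_pairs(
    frame: Frame, criterion: HBondCriterion
) -> dict[tuple[int, int], tuple[set[int], set[int]]]:
    """Chain pairs joined by a qualifying H-bond ladder.

    Maps (chain_a, chain_b) with a < b to the ladder residue sets (including
    interior alternation gaps) on each chain.
    """
    participants: dict[tuple[int, int], tuple[set, set]] = {}
    for (ci, ri), (cj, rj) in backbone_hbonds(frame, criterion):
        if ci == cj:
            continue
        a, b = (ci, cj) if ci < cj else (cj, ci)
        sa, sb = participants.setdefault((a, b), (set(), set()))
        (sa if ci == a else sb).add(ri)
        (sb if cj == b else sa).add(rj)
    pairs = {}
    for key, (sa, sb) in participants.items():
        run_a, span_a = _max_ladder_run(sa)
        run_b, span_b = _max_ladder_run(sb)
        if min(run_a, run_b) >= criterion.min_run:
            pairs[key] = (span_a, span_b)
    return pairs


def beta_content(frame: Frame, criterion: HBondCriterion) -> float:
    """Percentage of residues inside qualifying β-sheet ladders."""
    pairs = strand_pairs(frame, criterion)
    in_beta: set[tuple[int, int]] = set()
    for (a, b), (span_a, span_b) in pairs.items():
        in_beta.update((a, r) for r in span_a)
        in_beta.update((b, r) for r in span_b)
    total = frame.n_chains * frame.n_residues
    return 100.0 * len(in_beta) / total


def _orientations(frame: Frame) -> np.ndarray:
    vec = frame.ca[:, -1, :] - frame.ca[:, 0, :]
    return vec


def parallel_fraction(frame: Frame, criterion: HBondCriterion) -> float | None:
    """Percentage of H-bonded strand pairs with parallel N→C orientation.

    Returns None ("no sheets") when no qualifying pair exists — a sentinel,
    not 0%, so kinetics averages are not biased by empty frames.
    """
    pairs = strand_pairs(frame, criterion)
    if not pairs:
        return None
    vec = _orientations(frame)
    n_parallel = sum(
        1 for (a, b) in pairs if float(vec[a] @ vec[b]) > 0
    )
    return 100.0 * n_parallel / len(pairs)


def _chain_components(adjacency: np.ndarray) -> list[list[int]]:
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in np.flatnonzero(adjacency[a]):
                if not seen[b]:
                    seen[b] = True
                    stack.append(int(b))
        comps.append(sorted(comp))
    return comps


def _aggregates(frame: Frame, criterion: HBondCriterion) -> list[list[int]]:
    """Connected components of the chain contact graph (min bead distance)."""
    nc = frame.n_chains
    beads = [frame.nh, frame.co, frame.ca]
    if frame.sc is not None:
        beads.append(frame.sc)
    pos = np.concatenate([b.reshape(nc, -1, 3) for b in beads], axis=1)
    adj = np.zeros((nc, nc), dtype=bool)
    for a, b in combinations(range(nc), 2):
        d = np.linalg.norm(
            frame.displacement(pos[a][:, None, :], pos[b][None, :, :]), axis=-1
        )
        if d.min() <= criterion.aggregate_cutoff:
            adj[a, b] = adj[b, a] = True
    return _chain_components(adj)


def largest_aggregate(frame: Frame, criterion: HBondCriterion) -> int:
    """Chain count of the largest contact-connected aggregate."""
    return max(len(c) for c in _aggregates(frame, criterion))


def count_layers(frame: Frame, criterion: HBondCriterion) -> int:
    """Number of β-sheets (strand-pair graph components with ≥ 2 strands)
    stacked in the largest aggregate."""
    aggs = _aggregates(frame, criterion)
    target = max(aggs, key=len)
    pairs = strand_pairs(frame, criterion)
    nc = frame.n_chains
    adj = np.zeros((nc, nc), dtype=bool)
    for a, b in pairs:
        adj[a, b] = adj[b, a] = True
    sheets = [
        comp
        for comp in _chain_components(adj)
        if len(comp) >= 2 and all(c in target for c in comp)
    ]
    return len(sheets)


def frame_metrics(frame: Frame, criterion: HBondCriterion) -> FrameMetrics:
    return FrameMetrics(
        time=frame.time,
        beta_content=beta_content(frame, criterion),
        parallel_fraction=parallel_fraction(frame, criterion),
        n_layers=count_layers(frame, criterion),
        largest_aggregate=largest_aggregate(frame, criterion),
    )


def timeseries(frames, criterion: HBondCriterion) -> pd.DataFrame:
    """Per-frame metrics table (CSV-exportable); requires ≥ 1 frame."""
    frames = list(frames)
    if not frames:
        raise MetricsError("empty trajectory")
    rows = []
    for fr in frames:
        m = frame_metrics(fr, criterion)
        rows.append(
            {
                "time": m.time,
                "beta_content": m.beta_content,
                "parallel_fraction": (
                    np.nan if m.parallel_fraction is None else m.parallel_fraction
                ),
                "n_layers": m.n_layers,
                "largest_aggregate": m.largest_aggregate,
            }
        )
    df = pd.DataFrame(rows)
    if not df["time"].is_monotonic_increasing:
        raise MetricsError("frame times must be non-decreasing")
    return df
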