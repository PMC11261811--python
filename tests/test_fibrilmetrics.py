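"""β-sheet metrics: H-bond detection, content, orientation, layer counting."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from crossbeta import fibrilmetrics as fm
from crossbeta.scaffolds import build_cross_beta_scaffold


@pytest.fixture(scope="module")
def crit():
    return fm.HBondCriterion()


@pytest.fixture(scope="module")
def class1_frame():
    return fm.Frame.from_scaffold(build_cross_beta_scaffold(1, 4, 7))


@pytest.fixture(scope="module")
def class8_frame():
    return fm.Frame.from_scaffold(build_cross_beta_scaffold(8, 4, 7))


def single_sheet_frame(n_strands=4, class_id=1):
    s = build_cross_beta_scaffold(class_id, n_strands, 7)
    keep = s.sheet_id == 0
    return fm.Frame(nh=s.coords[keep][:, :, 0, :], co=s.coords[keep][:, :, 3, :],
                    ca=s.coords[keep][:, :, 1, :])


class TestHBonds:
    def test_two_strand_count_matches_distance_matrix(self, crit):
        frame = single_sheet_frame(n_strands=2)
        hb = fm.backbone_hbonds(frame, crit)
        # independent oracle: full NH×CO distance matrix scan
        nh = frame.nh.reshape(-1, 3)
        co = frame.co.reshape(-1, 3)
        d = cdist(nh, co)
        expected = 0
        nr = frame.n_residues
        for i in range(len(nh)):
            for j in range(len(co)):
                ci, cj = i // nr, j // nr
                if ci == cj and abs(i % nr - j % nr) < 3:
                    continue
                if d[i, j] <= crit.threshold:
                    expected += 1
        assert len(hb) == expected > 0

    def test_distant_chains_no_hbonds(self, crit):
        frame = single_sheet_frame(n_strands=2)
        far = frame.nh.copy()
        far[1] += 50.0
        co = frame.co.copy()
        co[1] += 50.0
        ca = frame.ca.copy()
        ca[1] += 50.0
        assert fm.backbone_hbonds(fm.Frame(nh=far, co=co, ca=ca), crit) == []

    def test_zero_threshold_empty(self, class1_frame):
        crit0 = fm.HBondCriterion(threshold=0.0)
        assert fm.backbone_hbonds(class1_frame, crit0) == []

    def test_periodic_wrap_detected(self, crit):
        frame = single_sheet_frame(n_strands=2)
        shifted = fm.Frame(
            nh=frame.nh + [0, 98.0, 0], co=frame.co.copy(), ca=frame.ca.copy(),
            box_edge=100.0,
        )
        # chain 0 moved a full period away in y minus 2: still neighbors
        shifted.nh[0] -= [0, 98.0, 0]
        shifted.co[1] += [0, 98.0, 0]
        shifted.ca[1] += [0, 98.0, 0]
        hb = fm.backbone_hbonds(shifted, crit)
        assert len(hb) > 0


class TestBetaContent:
    def test_ideal_class1_high(self, class1_frame, crit):
        assert fm.beta_content(class1_frame, crit) >= 90.0

    def test_dispersed_coils_zero(self, crit, rng):
        nh = rng.uniform(0, 300, size=(8, 7, 3))
        frame = fm.Frame(
            nh=nh, co=nh + rng.normal(0, 0.3, nh.shape),
            ca=nh + rng.normal(0, 0.3, nh.shape),
        )
        assert fm.beta_content(frame, crit) == 0.0

    def test_half_sheet_half_dispersed(self, crit):
        s = build_cross_beta_scaffold(1, 4, 7)
        coords = s.coords.copy()
        # move one full sheet (4 chains) far away, each chain separately
        for k, c in enumerate(np.flatnonzero(s.sheet_id == 1)):
            coords[c] += 200.0 + 60.0 * k
        frame = fm.Frame(
            nh=coords[:, :, 0, :], co=coords[:, :, 3, :], ca=coords[:, :, 1, :]
        )
        # half the residues remain in the intact sheet, within one residue
        quantum = 100.0 / (s.n_chains * s.n_residues)
        expected_half = fm.beta_content(
            fm.Frame.from_scaffold(s), crit
        ) / 2
        assert abs(fm.beta_content(frame, crit) - expected_half) <= quantum

    def test_rigid_motion_invariance(self, class1_frame, crit):
        theta = 0.9
        rot = np.array(
            [[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
             [-np.sin(theta), 0, np.cos(theta)]]
        )
        moved = fm.Frame(
            nh=class1_frame.nh @ rot.T + 5.0,
            co=class1_frame.co @ rot.T + 5.0,
            ca=class1_frame.ca @ rot.T + 5.0,
        )
        assert fm.beta_content(moved, crit) == fm.beta_content(class1_frame, crit)


class TestParallelFraction:
    @pytest.mark.parametrize("n_strands", [2, 3, 4, 6])
    def test_class1_single_sheet_fully_parallel(self, crit, n_strands):
        frame = single_sheet_frame(n_strands=n_strands, class_id=1)
        assert fm.parallel_fraction(frame, crit) == 100.0

    @pytest.mark.parametrize("n_strands", [2, 3, 4, 6])
    def test_class8_single_sheet_fully_antiparallel(self, crit, n_strands):
        frame = single_sheet_frame(n_strands=n_strands, class_id=8)
        assert fm.parallel_fraction(frame, crit) == 0.0

    def test_two_layer_class1_all_pairs_parallel(self, class1_frame, crit):
        # cross-sheet strands are antiparallel but not H-bonded: only
        # in-sheet pairs count, all parallel
        assert fm.parallel_fraction(class1_frame, crit) == 100.0

    def test_no_pairs_gives_sentinel(self, crit, rng):
        nh = rng.uniform(0, 500, size=(4, 7, 3))
        frame = fm.Frame(nh=nh, co=nh + 0.1, ca=nh + 0.2)
        assert fm.parallel_fraction(frame, crit) is None

    def test_mixed_fixture_enumerated(self, crit):
        # 4 parallel strands (3 pairs) in one sheet + an antiparallel pair
        # placed far away: 3/4 pairs parallel
        s1 = build_cross_beta_scaffold(1, 4, 7)
        s8 = build_cross_beta_scaffold(8, 2, 7)
        keep1 = s1.sheet_id == 0
        keep8 = s8.sheet_id == 0
        nh = np.concatenate([s1.coords[keep1][:, :, 0, :],
                             s8.coords[keep8][:, :, 0, :] + 300.0])
        co = np.concatenate([s1.coords[keep1][:, :, 3, :],
                             s8.coords[keep8][:, :, 3, :] + 300.0])
        ca = np.concatenate([s1.coords[keep1][:, :, 1, :],
                             s8.coords[keep8][:, :, 1, :] + 300.0])
        frame = fm.Frame(nh=nh, co=co, ca=ca)
        assert fm.parallel_fraction(frame, crit) == pytest.approx(75.0)


class TestLayers:
    def test_two_layer_scaffold(self, class1_frame, crit):
        assert fm.count_layers(class1_frame, crit) == 2

    def test_single_sheet(self, crit):
        assert fm.count_layers(single_sheet_frame(), crit) == 1

    def test_distant_fibrils_count_largest_only(self, crit):
        s = build_cross_beta_scaffold(1, 4, 7)
        nh = np.concatenate([s.coords[:, :, 0, :], s.coords[:, :, 0, :] + 100.0])
        co = np.concatenate([s.coords[:, :, 3, :], s.coords[:, :, 3, :] + 100.0])
        ca = np.concatenate([s.coords[:, :, 1, :], s.coords[:, :, 1, :] + 100.0])
        frame = fm.Frame(nh=nh, co=co, ca=ca)
        assert fm.count_layers(frame, crit) == 2
        assert fm.largest_aggregate(frame, crit) == 8

    def test_layer_graph_matches_bruteforce_components(self, class1_frame, crit):
        # brute-force connected components over the strand-pair graph
        pairs = fm.strand_pairs(class1_frame, crit)
        n = class1_frame.n_chains
        adj = {i: set() for i in range(n)}
        for a, b in pairs:
            adj[a].add(b)
            adj[b].add(a)
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            if len(comp) >= 2:
                comps.append(comp)
        assert fm.count_layers(class1_frame, crit) == len(comps)


class TestTimeseries:
    def test_static_fixture_constant_metrics(self, crit):
        s = build_cross_beta_scaffold(1, 4, 7)
        frames = [fm.Frame.from_scaffold(s, time=t) for t in (0.0, 1.0, 2.0)]
        df = fm.timeseries(frames, crit)
        assert df["beta_content"].nunique() == 1
        assert df["parallel_fraction"].nunique() == 1

    def test_progressive_assembly_monotone(self, crit, rng):
        # chains join the fibril one per frame; content grows monotonically
        s = build_cross_beta_scaffold(1, 4, 7)
        fibril = s.coords.copy()
        offsets = rng.uniform(60, 120, size=(s.n_chains, 1, 1, 3))
        rows = []
        for k in range(s.n_chains + 1):
            coords = fibril.copy()
            for c in range(k, s.n_chains):  # chains ≥ k still dispersed
                coords[c] += offsets[c]
            rows.append(
                fm.Frame(
                    nh=coords[:, :, 0, :], co=coords[:, :, 3, :],
                    ca=coords[:, :, 1, :], time=float(k),
                )
            )
        df = fm.timeseries(rows, crit)
        beta = df["beta_content"].to_numpy()
        assert beta[0] == 0.0
        assert beta[-1] >= 90.0
        assert (np.diff(beta) >= -1e-9).all()

    def test_empty_trajectory_rejected(self, crit):
        with pytest.raises(fm.MetricsError):
            fm.timeseries([], crit)

    def test_metrics_deterministic(self, class1_frame, crit):
        m1 = fm.frame_metrics(class1_frame, crit)
        m2 = fm.frame_metrics(class1_frame, crit)
        assert m1 == m2
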