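"""Network store, persistence, fastest paths and refinement schemes."""

import itertools

import numpy as np
import pytest

from conftest import FourWell2D, make_random_network
from ktntools import localopt, thermo, tssearch
from ktntools.errors import (KTNParseError, NotConnectedError,
                             ReferentialIntegrityError)
from ktntools.ktn import (KTN, Path, connectunc_refine, fastest_path,
                          integrated_path_length, read_ktn, shortcut_refine,
                          untrap_refine, write_ktn)
from ktntools.localopt import Minimum
from ktntools.tssearch import TransitionState


def _mb_network(mb, mb_census):
    """Package-built Müller-Brown network (3 minima, 2 ts)."""
    # the two ends of the three-minimum chain (the middle basin joins them)
    m_lo = localopt.minimize(mb, mb_census["minima"][0][0])
    m_hi = localopt.minimize(mb, mb_census["minima"][1][0])
    res = tssearch.connect_pair(mb, m_lo, m_hi, max_cycles=10)
    net = KTN()
    for (mm, ts, mp) in res:
        a = net.add_minimum(mm)
        b = net.add_minimum(mp)
        net.add_transition_state(ts, minus_id=a, plus_id=b)
    return net


@pytest.fixture(scope="module")
def mb_network(mb, mb_census):
    return _mb_network(mb, mb_census)


class TestAddStationaryPoint:
    def test_duplicate_minimum_is_idempotent(self, mb_network):
        net = mb_network
        m0 = net.minima[0]
        before = len(net)
        again = net.add_minimum(Minimum(energy=m0.energy,
                                        coordinates=m0.coordinates.copy()))
        assert again == 0
        assert len(net) == before

    def test_below_tolerance_records_merge(self):
        net = KTN()
        rng = np.random.default_rng(0)
        c = rng.normal(size=6)
        i1 = net.add_minimum(Minimum(energy=-1.0, coordinates=c))
        i2 = net.add_minimum(Minimum(energy=-1.0 + 1e-9,
                                     coordinates=c + 1e-7))
        assert i1 == i2
        assert len(net) == 1

    def test_ts_with_unknown_minima_rejected(self):
        net = KTN()
        net.add_minimum(Minimum(energy=0.0, coordinates=np.zeros(2)))
        ts = TransitionState(energy=1.0, coordinates=np.ones(2),
                             negative_eigenvalue=-1.0)
        with pytest.raises(ReferentialIntegrityError):
            net.add_transition_state(ts, minus_id=0, plus_id=5)

    def test_unconverged_record_rejected(self, mb):
        net = KTN()
        with pytest.raises(ValueError):
            net.add_minimum(Minimum(energy=mb.energy([0.1, 0.1]),
                                    coordinates=np.array([0.1, 0.1])),
                            model=mb)

    def test_mb_census_network_shape(self, mb_network):
        assert len(mb_network) == 3
        assert mb_network.n_ts == 2
        mb_network.validate()


class TestPersistence:
    def test_write_read_write_is_byte_identical(self, mb_network, tmp_path):
        p1 = tmp_path / "a.ktn"
        p2 = tmp_path / "b.ktn"
        write_ktn(mb_network, p1)
        net2 = read_ktn(p1)
        write_ktn(net2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "a.ktn.coords").read_bytes() == \
            (tmp_path / "b.ktn.coords").read_bytes()

    def test_roundtrip_preserves_values_exactly(self, mb_network, tmp_path):
        p = tmp_path / "net.ktn"
        write_ktn(mb_network, p)
        net2 = read_ktn(p)
        for mid, m in mb_network.minima.items():
            assert net2.minima[mid].energy == m.energy
            assert net2.minima[mid].log_product_freq == m.log_product_freq
            assert np.array_equal(net2.minima[mid].coordinates, m.coordinates)
        for tid, ts in mb_network.transition_states.items():
            assert net2.transition_states[tid].energy == ts.energy

    def test_empty_network_roundtrip(self, tmp_path):
        p = tmp_path / "empty.ktn"
        write_ktn(KTN(), p)
        net = read_ktn(p)
        assert len(net) == 0 and net.n_ts == 0

    def test_hand_written_fixture(self, tmp_path):
        text = ("# ktn 1\n[minima]\n"
                "0 -5.0 1.25 0 rg=4.5\n"
                "1 -4.0 1.5 0 rg=6.25\n"
                "2 -3.5 0.75 0 rg=8.0\n"
                "[ts]\n"
                "0 -2.0 1.0 -0.5 0 1\n"
                "1 -1.5 0.5 -0.25 1 2\n")
        p = tmp_path / "hand.ktn"
        p.write_text(text)
        net = read_ktn(p)
        assert [net.minima[i].energy for i in range(3)] == [-5.0, -4.0, -3.5]
        assert net.minima[1].order_params == {"rg": 6.25}
        assert net.transition_states[1].minus_min_id == 1

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.ktn"
        p.write_text("# ktn 1\n[minima]\n0 not_a_number 0 0\n")
        with pytest.raises(KTNParseError) as err:
            read_ktn(p)
        assert err.value.line_number == 3

    def test_dangling_ts_reference_rejected(self, tmp_path):
        p = tmp_path / "dangling.ktn"
        p.write_text("# ktn 1\n[minima]\n0 -1.0 0.0 0\n[ts]\n"
                     "0 0.0 0.0 -1.0 0 7\n")
        with pytest.raises(ReferentialIntegrityError):
            read_ktn(p)


def _brute_force_cost(net, a, b, temperature, kB):
    """Exhaustive minimal cost over all simple paths, with the edge
    weights recomputed here directly from the TST-rate definition."""
    lnk = {}
    for tid, ts in net.transition_states.items():
        for mid in {ts.minus_min_id, ts.plus_min_id}:
            m = net.minima[mid]
            lnk[(mid, tid)] = (-np.log(2 * np.pi) + m.log_product_freq
                               - ts.log_product_freq
                               - (ts.energy - m.energy) / (kB * temperature))
    shift = max(lnk.values())
    adj = {}
    for tid, ts in net.transition_states.items():
        if ts.minus_min_id == ts.plus_min_id:
            continue
        adj.setdefault(ts.minus_min_id, []).append((tid, ts.plus_min_id))
        adj.setdefault(ts.plus_min_id, []).append((tid, ts.minus_min_id))
    best = [np.inf]

    def walk(node, seen, cost):
        if cost >= best[0]:
            return
        if node == b:
            best[0] = cost
            return
        for tid, nb in adj.get(node, ()):
            if nb in seen:
                continue
            walk(nb, seen | {nb}, cost + (shift - lnk[(node, tid)]))

    walk(a, {a}, 0.0)
    return best[0]


class TestFastestPath:
    def test_identity_path(self, mb_network):
        p = fastest_path(mb_network, 1, 1, temperature=1.0, kB=1.0)
        assert p.cost == 0.0
        assert p.min_ids == [1] and p.ts_ids == []

    def test_two_minima_forced_path(self):
        rng = np.random.default_rng(1)
        net = make_random_network(rng, n_min=2)
        p = fastest_path(net, 0, 1, temperature=1.0, kB=1.0)
        assert p.min_ids == [0, 1]
        assert len(p.ts_ids) == 1

    def test_cost_matches_exhaustive_enumeration(self):
        """100 random networks (<= 8 minima): Dijkstra equals brute force."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            net = make_random_network(rng)
            ids = sorted(net.minima)
            a, b = ids[0], ids[-1]
            p = fastest_path(net, a, b, temperature=2.0, kB=1.0)
            expect = _brute_force_cost(net, a, b, 2.0, 1.0)
            assert p.cost == pytest.approx(expect, abs=1e-9)

    def test_unknown_minimum_rejected(self, mb_network):
        with pytest.raises(ValueError):
            fastest_path(mb_network, 0, 99, temperature=1.0, kB=1.0)

    def test_disconnected_raises(self):
        net = KTN()
        rng = np.random.default_rng(0)
        net.add_minimum(Minimum(energy=-1.0, coordinates=rng.normal(size=3)))
        net.add_minimum(Minimum(energy=-2.0, coordinates=rng.normal(size=3)))
        with pytest.raises(NotConnectedError):
            fastest_path(net, 0, 1, temperature=1.0, kB=1.0)


class TestIntegratedPathLength:
    def test_empty_path_is_zero(self, mb_network):
        p = fastest_path(mb_network, 0, 0, temperature=1.0, kB=1.0)
        assert integrated_path_length(mb_network, p) == 0.0

    def test_collinear_points(self):
        net = KTN()
        for i, x in enumerate([0.0, 1.0]):
            net.add_minimum(Minimum(energy=-1.0 - i,
                                    coordinates=np.array([x, 0.0])))
        ts = TransitionState(energy=0.0, coordinates=np.array([0.5, 0.0]),
                             negative_eigenvalue=-1.0)
        net.add_transition_state(ts, minus_id=0, plus_id=1)
        p = fastest_path(net, 0, 1, temperature=1.0, kB=1.0)
        assert integrated_path_length(net, p) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_distance_sum(self):
        rng = np.random.default_rng(12)
        net = make_random_network(rng, n_min=5, p_edge=1.0)
        ids = sorted(net.minima)
        p = fastest_path(net, ids[0], ids[-1], temperature=1.0, kB=1.0)
        got = integrated_path_length(net, p)
        pts = []
        for kind, rid in p.sequence:
            rec = net.minima[rid] if kind == "min" \
                else net.transition_states[rid]
            pts.append(rec.coordinates)
        expect = sum(np.linalg.norm(q - r) for q, r in zip(pts, pts[1:]))
        assert got == pytest.approx(expect, abs=1e-12)


# --------------------------------------------------------------------------
# refinement schemes on the four-well surface
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fourwell():
    return FourWell2D()


@pytest.fixture(scope="module")
def fourwell_minima(fourwell):
    out = {}
    for name, start in (("mm", (-1, -1)), ("mp", (-1, 1)), ("pp", (1, 1)),
                        ("pm", (1, -1))):
        out[name] = localopt.minimize(fourwell, np.array(start, dtype=float))
    return out


def _chain_network(fourwell, fourwell_minima, corners):
    """Network holding the given corner chain, edges via connect_pair."""
    net = KTN()
    ids = {}
    for name in corners:
        ids[name] = net.add_minimum(fourwell_minima[name])
    for u, v in zip(corners[:-1], corners[1:]):
        res = tssearch.connect_pair(fourwell, fourwell_minima[u],
                                    fourwell_minima[v], max_cycles=5)
        assert res.connected
        for (mm, ts, mp) in res:
            a = net.add_minimum(mm)
            b = net.add_minimum(mp)
            net.add_transition_state(ts, minus_id=a, plus_id=b)
    return net, ids


class TestShortcutRefine:
    def test_zero_attempts_is_noop(self, fourwell, fourwell_minima):
        net, ids = _chain_network(fourwell, fourwell_minima,
                                  ["mm", "mp", "pp", "pm"])
        before = (len(net), net.n_ts)
        p = fastest_path(net, ids["mm"], ids["pm"], temperature=1.0, kB=1.0)
        shortcut_refine(net, fourwell, p, max_attempts=0)
        assert (len(net), net.n_ts) == before

    def test_planted_shortcut_reduces_path_steps(self, fourwell,
                                                 fourwell_minima):
        """A 4-corner chain a-b-c-d where a direct a-d saddle exists:
        after SHORTCUT the fastest a->d path takes fewer steps."""
        net, ids = _chain_network(fourwell, fourwell_minima,
                                  ["mm", "mp", "pp", "pm"])
        a, d = ids["mm"], ids["pm"]
        p_before = fastest_path(net, a, d, temperature=1.0, kB=1.0)
        assert len(p_before) == 3
        shortcut_refine(net, fourwell, p_before, max_attempts=3)
        net.validate()
        p_after = fastest_path(net, a, d, temperature=1.0, kB=1.0)
        assert len(p_after) < len(p_before)
        assert p_after.cost <= p_before.cost + 1e-12

    def test_additive_only(self, fourwell, fourwell_minima):
        net, ids = _chain_network(fourwell, fourwell_minima,
                                  ["mm", "mp", "pp", "pm"])
        minima_before = dict(net.minima)
        ts_before = dict(net.transition_states)
        p = fastest_path(net, ids["mm"], ids["pm"], temperature=1.0, kB=1.0)
        shortcut_refine(net, fourwell, p, max_attempts=3)
        for mid in minima_before:
            assert net.minima[mid] is minima_before[mid]
        for tid in ts_before:
            assert net.transition_states[tid] is ts_before[tid]


def _minimax_barrier(net, a, b):
    """Brute-force minimax ts energy over all simple paths a -> b."""
    adj = {}
    for tid, ts in net.transition_states.items():
        if ts.minus_min_id == ts.plus_min_id:
            continue
        adj.setdefault(ts.minus_min_id, []).append((tid, ts.plus_min_id))
        adj.setdefault(ts.plus_min_id, []).append((tid, ts.minus_min_id))
    best = [np.inf]

    def walk(node, seen, hi):
        if node == b:
            best[0] = min(best[0], hi)
            return
        for tid, nb in adj.get(node, ()):
            if nb in seen:
                continue
            walk(nb, seen | {nb},
                 max(hi, net.transition_states[tid].energy))

    walk(a, {a}, -np.inf)
    return best[0]


class TestUntrapRefine:
    def test_single_minimum_unchanged(self, fourwell, fourwell_minima):
        net = KTN()
        net.add_minimum(fourwell_minima["mm"])
        untrap_refine(net, fourwell, n_candidates=3)
        assert len(net) == 1 and net.n_ts == 0

    def test_zero_candidates_is_noop(self, fourwell, fourwell_minima):
        net, _ = _chain_network(fourwell, fourwell_minima, ["mm", "mp"])
        before = (len(net), net.n_ts)
        untrap_refine(net, fourwell, n_candidates=0)
        assert (len(net), net.n_ts) == before

    def test_planted_trap_barrier_strictly_decreases(self, fourwell,
                                                     fourwell_minima):
        """Trap reachable only over the top of the cycle; a lower direct
        saddle to the global minimum exists and UNTRAP must find it."""
        net, ids = _chain_network(fourwell, fourwell_minima,
                                  ["pm", "pp", "mp", "mm"])
        # global minimum is mm (tilt); trap pm connected only via pp, mp
        a, g = ids["pm"], ids["mm"]
        barrier_before = _minimax_barrier(net, a, g)
        untrap_refine(net, fourwell, n_candidates=2)
        net.validate()
        barrier_after = _minimax_barrier(net, a, g)
        assert barrier_after < barrier_before


class TestConnectuncRefine:
    def test_fully_connected_unchanged(self, fourwell, fourwell_minima):
        net, _ = _chain_network(fourwell, fourwell_minima, ["mm", "mp"])
        before = (len(net), net.n_ts)
        connectunc_refine(net, fourwell)
        assert (len(net), net.n_ts) == before

    def test_distance_gate_blocks_attempts(self, fourwell, fourwell_minima):
        net = KTN()
        net.add_minimum(fourwell_minima["mm"])
        net.add_minimum(fourwell_minima["pp"])
        before = (len(net), net.n_ts)
        connectunc_refine(net, fourwell, distance_tol=0.1)
        assert (len(net), net.n_ts) == before

    def test_joins_two_components(self, mb, mb_census):
        """Two single-minimum components of the Müller-Brown surface are
        joined (an oracle saddle exists between them)."""
        net = KTN()
        m1 = localopt.minimize(mb, mb_census["minima"][0][0])
        m2 = localopt.minimize(mb, mb_census["minima"][1][0])
        net.add_minimum(m1)
        net.add_minimum(m2)
        assert len(net.connected_components()) == 2
        connectunc_refine(net, mb, distance_tol=np.inf)
        net.validate()
        assert len(net.connected_components()) == 1

    def test_refinement_never_raises_fastest_path_cost(self, fourwell,
                                                       fourwell_minima):
        net, ids = _chain_network(fourwell, fourwell_minima,
                                  ["mm", "mp", "pp", "pm"])
        a, d = ids["mm"], ids["pm"]
        c_before = fastest_path(net, a, d, temperature=1.0, kB=1.0).cost
        p = fastest_path(net, a, d, temperature=1.0, kB=1.0)
        shortcut_refine(net, fourwell, p, max_attempts=3)
        untrap_refine(net, fourwell, n_candidates=2)
        connectunc_refine(net, fourwell)
        c_after = fastest_path(net, a, d, temperature=1.0, kB=1.0).cost
        assert c_after <= c_before + 1e-12
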