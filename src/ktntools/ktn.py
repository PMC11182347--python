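"""Kinetic transition networks: storage, persistence, refinement, paths.

A KTN holds deduplicated local minima and the index-1 saddles connecting
them.  Plain-text persistence uses a two-section table (modelled on the
classic min.data / ts.data stationary-point tables) plus a coordinate
sidecar keyed by id; numeric fields are printed at full round-trip
precision so write → read → write is byte-identical.

Three additive refinement schemes grow a database: SHORTCUT searches for
alternative pathways between well-separated members of an existing path,
UNTRAP attacks minima whose escape barrier is large relative to their
energy above the global minimum, and CONNECTUNC attempts connections
between nearby minima in different connected components.

"Fastest" paths are Dijkstra shortest paths with non-negative edge
weights w(i -> ts) = ln k_max - ln k_(i->ts), where k is the harmonic
transition-state-theory rate at the analysis temperature, so the minimal
cost corresponds to the largest product of rates.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .align import aligned_distance
from .errors import (KTNParseError, NotConnectedError,
                     ReferentialIntegrityError)
from .localopt import Minimum, rms_gradient
from .tssearch import TransitionState, connect_pair
from .units import KB_KCAL

__all__ = [
    "KTN", "Path",
    "write_ktn", "read_ktn",
    "fastest_path", "integrated_path_length",
    "shortcut_refine", "untrap_refine", "connectunc_refine",
]

ENERGY_TOL = 1e-6
DIST_TOL = 1e-3
FORMAT_HEADER = "# ktn 1"


@dataclass
class Path:
    """Alternating minimum/transition-state walk through a KTN."""

    min_ids: list[int]
    ts_ids: list[int]
    cost: float = 0.0
    integrated_length: float | None = None

    def __len__(self):
        return len(self.ts_ids)

    @property
    def sequence(self) -> list[tuple[str, int]]:
        seq: list[tuple[str, int]] = []
        for i, m in enumerate(self.min_ids):
            seq.append(("min", m))
            if i < len(self.ts_ids):
                seq.append(("ts", self.ts_ids[i]))
        return seq


class KTN:
    """Kinetic transition network of minima and transition states."""

    def __init__(self, permute_identical: bool = False):
        self.minima: dict[int, Minimum] = {}
        self.transition_states: dict[int, TransitionState] = {}
        self.permute_identical = permute_identical
        self._next_min_id = 0
        self._next_ts_id = 0

    # -- insertion with deduplication -----------------------------------

    def add_minimum(self, record: Minimum, model=None,
                    rms_tol: float = 1e-5) -> int:
        """Insert a minimum; returns the canonical id (new or existing)."""
        if model is not None:
            rms = rms_gradient(model.gradient(record.coordinates))
            if rms > rms_tol:
                raise ValueError(
                    f"record not converged (RMS gradient {rms:.2e})")
        existing = self.find_minimum(record.energy, record.coordinates)
        if existing is not None:
            return existing
        mid = self._next_min_id
        self._next_min_id += 1
        self.minima[mid] = record.copy_with_id(mid)
        return mid

    def add_transition_state(self, record: TransitionState,
                             minus_id: int | None = None,
                             plus_id: int | None = None,
                             model=None, rms_tol: float = 1e-5) -> int:
        """Insert a transition state referencing two existing minima."""
        minus = record.minus_min_id if minus_id is None else minus_id
        plus = record.plus_min_id if plus_id is None else plus_id
        if minus not in self.minima or plus not in self.minima:
            raise ReferentialIntegrityError(
                f"transition state references unknown minima ({minus}, {plus})")
        if model is not None:
            rms = rms_gradient(model.gradient(record.coordinates))
            if rms > rms_tol:
                raise ValueError(
                    f"record not converged (RMS gradient {rms:.2e})")
        pair = frozenset((minus, plus))
        for tid, ts in self.transition_states.items():
            if (abs(ts.energy - record.energy) <= ENERGY_TOL
                    and frozenset((ts.minus_min_id, ts.plus_min_id)) == pair):
                return tid
        tid = self._next_ts_id
        self._next_ts_id += 1
        new = record.copy_with_id(tid)
        new.minus_min_id = minus
        new.plus_min_id = plus
        self.transition_states[tid] = new
        return tid

    def add_stationary_point(self, record, **kwargs) -> int:
        if isinstance(record, Minimum):
            return self.add_minimum(record, **kwargs)
        if isinstance(record, TransitionState):
            return self.add_transition_state(record, **kwargs)
        raise TypeError(f"not a stationary-point record: {type(record)!r}")

    def find_minimum(self, energy: float, coordinates) -> int | None:
        for mid, m in self.minima.items():
            if abs(m.energy - energy) <= ENERGY_TOL:
                if self.permute_identical:
                    return mid
                if (m.coordinates is not None and coordinates is not None
                        and aligned_distance(m.coordinates,
                                             coordinates) <= DIST_TOL):
                    return mid
        return None

    # -- structure queries ------------------------------------------------

    def __len__(self):
        return len(self.minima)

    @property
    def n_ts(self) -> int:
        return len(self.transition_states)

    def adjacency(self) -> dict[int, list[tuple[int, int]]]:
        """minimum id -> list of (ts id, neighbour minimum id)."""
        adj: dict[int, list[tuple[int, int]]] = {m: [] for m in self.minima}
        for tid, ts in sorted(self.transition_states.items()):
            a, b = ts.minus_min_id, ts.plus_min_id
            adj[a].append((tid, b))
            if a != b:
                adj[b].append((tid, a))
        return adj

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(sorted(self.minima))
        for tid, ts in sorted(self.transition_states.items()):
            g.add_edge(ts.minus_min_id, ts.plus_min_id, key=tid,
                       energy=ts.energy)
        return g

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.graph())]

    def is_connected(self) -> bool:
        return len(self.minima) <= 1 or nx.is_connected(self.graph())

    def global_minimum(self) -> int:
        return min(self.minima, key=lambda i: (self.minima[i].energy, i))

    def validate(self) -> None:
        """Raise if any referential-integrity or dedup invariant is broken."""
        for tid, ts in self.transition_states.items():
            if ts.minus_min_id not in self.minima \
                    or ts.plus_min_id not in self.minima:
                raise ReferentialIntegrityError(
                    f"ts {tid} references missing minima")
        seen: list[tuple[int, float, frozenset]] = []
        for tid, ts in self.transition_states.items():
            sig = frozenset((ts.minus_min_id, ts.plus_min_id))
            for t2, e2, s2 in seen:
                if abs(ts.energy - e2) <= ENERGY_TOL and sig == s2:
                    raise ValueError(f"duplicate transition states {t2}/{tid}")
            seen.append((tid, ts.energy, sig))


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def write_ktn(ktn: KTN, path) -> None:
    """Write the two-section network table plus the coordinate sidecar."""
    path = str(path)
    lines = [FORMAT_HEADER, "[minima]"]
    order_param_names: list[str] = []
    for m in ktn.minima.values():
        for k in m.order_params:
            if k not in order_param_names:
                order_param_names.append(k)
    for mid in sorted(ktn.minima):
        m = ktn.minima[mid]
        fields = [str(mid), _fmt(m.energy), _fmt(m.log_product_freq),
                  str(m.n_zero_modes)]
        fields += [f"{k}={_fmt(m.order_params[k])}"
                   for k in order_param_names if k in m.order_params]
        lines.append(" ".join(fields))
    lines.append("[ts]")
    for tid in sorted(ktn.transition_states):
        ts = ktn.transition_states[tid]
        lines.append(" ".join([
            str(tid), _fmt(ts.energy), _fmt(ts.log_product_freq),
            _fmt(ts.negative_eigenvalue),
            str(ts.minus_min_id), str(ts.plus_min_id)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    coord_lines = [FORMAT_HEADER + " coords"]
    for kind, table in (("min", ktn.minima), ("ts", ktn.transition_states)):
        for rid in sorted(table):
            rec = table[rid]
            if rec.coordinates is None:
                continue
            vals = " ".join(_fmt(v) for v in np.asarray(rec.coordinates).ravel())
            coord_lines.append(f"{kind} {rid} {vals}")
    with open(path + ".coords", "w") as fh:
        fh.write("\n".join(coord_lines) + "\n")


def read_ktn(path, permute_identical: bool = False) -> KTN:
    """Read a network written by :func:`write_ktn`."""
    path = str(path)
    ktn = KTN(permute_identical=permute_identical)
    coords: dict[tuple[str, int], np.ndarray] = {}
    try:
        with open(path + ".coords") as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                try:
                    kind, rid = parts[0], int(parts[1])
                    coords[(kind, rid)] = np.array(
                        [float(v) for v in parts[2:]])
                except (ValueError, IndexError) as exc:
                    raise KTNParseError(
                        f"bad coordinate line: {exc}", line_number=ln) from exc
    except FileNotFoundError:
        pass
    section = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "[minima]":
                section = "minima"
                continue
            if line == "[ts]":
                section = "ts"
                continue
            parts = line.split()
            try:
                if section == "minima":
                    mid = int(parts[0])
                    order = {}
                    for tok in parts[4:]:
                        k, v = tok.split("=")
                        order[k] = float(v)
                    m = Minimum(energy=float(parts[1]),
                                coordinates=coords.get(("min", mid)),
                                log_product_freq=float(parts[2]),
                                n_zero_modes=int(parts[3]),
                                order_params=order, id=mid)
                    ktn.minima[mid] = m
                    ktn._next_min_id = max(ktn._next_min_id, mid + 1)
                elif section == "ts":
                    tid = int(parts[0])
                    ts = TransitionState(
                        energy=float(parts[1]),
                        coordinates=coords.get(("ts", tid)),
                        negative_eigenvalue=float(parts[3]),
                        log_product_freq=float(parts[2]),
                        minus_min_id=int(parts[4]), plus_min_id=int(parts[5]),
                        id=tid)
                    ktn.transition_states[tid] = ts
                    ktn._next_ts_id = max(ktn._next_ts_id, tid + 1)
                else:
                    raise ValueError("data before section header")
            except (ValueError, IndexError) as exc:
                raise KTNParseError(f"malformed line: {exc}",
                                    line_number=ln) from exc
    for ts in ktn.transition_states.values():
        if ts.minus_min_id not in ktn.minima \
                or ts.plus_min_id not in ktn.minima:
            raise ReferentialIntegrityError(
                f"ts {ts.id} references missing minima")
    return ktn


# --------------------------------------------------------------------------
# fastest path (Dijkstra on -ln rate weights)
# --------------------------------------------------------------------------

def _edge_weights(ktn: KTN, temperature: float, kB: float
                  ) -> dict[tuple[int, int], float]:
    """Non-negative directed weights (min id, ts id) -> ln k_max - ln k."""
    from .thermo import ln_tst_rate
    lnk: dict[tuple[int, int], float] = {}
    for tid, ts in ktn.transition_states.items():
        for mid in {ts.minus_min_id, ts.plus_min_id}:
            lnk[(mid, tid)] = ln_tst_rate(ktn, tid, mid, temperature, kB)
    if not lnk:
        return {}
    ln_max = max(lnk.values())
    return {key: ln_max - v for key, v in lnk.items()}


def fastest_path(ktn: KTN, a: int, b: int, temperature: float,
                 kB: float = KB_KCAL) -> Path:
    """Dijkstra minimal-cost path between two minima.

    Ties are broken deterministically toward the lexicographically
    smallest sequence of minimum ids.
    """
    if a not in ktn.minima or b not in ktn.minima:
        raise ValueError(f"unknown minimum id: {a if a not in ktn.minima else b}")
    if a == b:
        return Path(min_ids=[a], ts_ids=[], cost=0.0)
    weights = _edge_weights(ktn, temperature, kB)
    adj = ktn.adjacency()
    # heap entries: (cost, min id sequence, ts id sequence)
    heap: list[tuple[float, tuple[int, ...], tuple[int, ...]]] = [
        (0.0, (a,), ())]
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    while heap:
        cost, mseq, tseq = heapq.heappop(heap)
        node = mseq[-1]
        if node in best and (best[node][0], best[node][1]) < (cost, mseq):
            continue
        if node == b:
            return Path(min_ids=list(mseq), ts_ids=list(tseq), cost=cost)
        best[node] = (cost, mseq)
        for tid, nb in adj[node]:
            if nb == node:
                continue  # degenerate rearrangement: no progress
            w = weights[(node, tid)]
            ncost = cost + w
            if nb in best and (best[nb][0], best[nb][1]) <= (ncost, mseq + (nb,)):
                continue
            heapq.heappush(heap, (ncost, mseq + (nb,), tseq + (tid,)))
    raise NotConnectedError(f"no path from {a} to {b}")


def integrated_path_length(ktn: KTN, path: Path) -> float:
    """Sum of aligned Euclidean distances along a stationary-point path."""
    seq = path.sequence
    pts = []
    for kind, rid in seq:
        rec = ktn.minima[rid] if kind == "min" else ktn.transition_states[rid]
        if rec.coordinates is None:
            raise ValueError(f"missing coordinates for {kind} {rid}")
        pts.append(np.asarray(rec.coordinates))
    total = 0.0
    for p, q in zip(pts[:-1], pts[1:]):
        total += aligned_distance(p, q, permute=ktn.permute_identical)
    return float(total)


# --------------------------------------------------------------------------
# refinement schemes (all additive-only)
# --------------------------------------------------------------------------

def _merge_connection(ktn: KTN, result) -> int:
    """Fold connect_pair triples into the network; returns #new ts."""
    added = 0
    for (m_minus, ts, m_plus) in result:
        id_minus = ktn.add_minimum(m_minus)
        id_plus = ktn.add_minimum(m_plus)
        before = ktn.n_ts
        ktn.add_transition_state(ts, minus_id=id_minus, plus_id=id_plus)
        added += ktn.n_ts - before
    return added


def shortcut_refine(ktn: KTN, model, path_source: Path,
                    max_attempts: int = 5, max_cycles: int = 5,
                    **connect_kwargs) -> KTN:
    """Search for alternative, shorter pathways (SHORTCUT scheme).

    Attempts double-ended connections between the path endpoints and
    between members ceil(n/3) apart along the path.  Never removes
    anything.
    """
    if max_attempts <= 0:
        return ktn
    mids = path_source.min_ids
    n = len(mids)
    pairs: list[tuple[int, int]] = []
    if n >= 2:
        pairs.append((mids[0], mids[-1]))
    gap = max(2, int(np.ceil(n / 3)))
    for i in range(0, n - gap):
        pairs.append((mids[i], mids[i + gap]))
    attempts = 0
    adj = ktn.adjacency()
    for (u, v) in pairs:
        if attempts >= max_attempts:
            break
        if any(nb == v for _, nb in adj[u]):
            continue  # already directly connected
        attempts += 1
        res = connect_pair(model, ktn.minima[u], ktn.minima[v],
                           max_cycles=max_cycles,
                           permute_identical=ktn.permute_identical,
                           **connect_kwargs)
        _merge_connection(ktn, res)
        adj = ktn.adjacency()
    return ktn


def _minimax_barriers(ktn: KTN, target: int) -> dict[int, float]:
    """Lowest maximum-ts-energy over all paths from each minimum to target."""
    adj = ktn.adjacency()
    best: dict[int, float] = {target: -np.inf}
    heap: list[tuple[float, int]] = [(-np.inf, target)]
    while heap:
        h, node = heapq.heappop(heap)
        if h > best.get(node, np.inf):
            continue
        for tid, nb in adj[node]:
            cand = max(h, ktn.transition_states[tid].energy)
            if cand < best.get(nb, np.inf):
                best[nb] = cand
                heapq.heappush(heap, (cand, nb))
    return best


def untrap_refine(ktn: KTN, model, temperature: float = 310.0,
                  n_candidates: int = 3, max_cycles: int = 5,
                  **connect_kwargs) -> KTN:
    """Attack kinetic traps (UNTRAP scheme).

    Minima are ranked by the ratio of the potential-energy barrier for
    reaching the global minimum to their energy above it; the worst
    ``n_candidates`` get new connection attempts toward the global
    minimum.  Additive only.
    """
    if n_candidates <= 0 or len(ktn) <= 1:
        return ktn
    gid = ktn.global_minimum()
    e0 = ktn.minima[gid].energy
    barrier = _minimax_barriers(ktn, gid)
    scores: list[tuple[float, int]] = []
    for mid, m in ktn.minima.items():
        if mid == gid or mid not in barrier:
            continue
        gap = m.energy - e0
        if gap <= ENERGY_TOL:
            continue
        scores.append(((barrier[mid] - m.energy) / gap, mid))
    scores.sort(reverse=True)
    for _, mid in scores[:n_candidates]:
        res = connect_pair(model, ktn.minima[mid], ktn.minima[gid],
                           max_cycles=max_cycles,
                           permute_identical=ktn.permute_identical,
                           **connect_kwargs)
        _merge_connection(ktn, res)
    return ktn


def connectunc_refine(ktn: KTN, model, distance_tol: float = np.inf,
                      max_cycles: int = 5, max_attempts: int = 10,
                      **connect_kwargs) -> KTN:
    """Join unconnected components through nearby minima (CONNECTUNC).

    Finds pairs of minima in different connected components closer than
    ``distance_tol`` (aligned distance) and attempts a connection on
    each, closest pairs first.  Additive only.
    """
    attempts = 0
    attempted: set[tuple[int, int]] = set()
    while attempts < max_attempts:
        comps = ktn.connected_components()
        if len(comps) <= 1:
            return ktn
        comp_of = {}
        for ci, comp in enumerate(comps):
            for mid in comp:
                comp_of[mid] = ci
        cands = []
        mids = sorted(ktn.minima)
        for i, u in enumerate(mids):
            for v in mids[i + 1:]:
                if comp_of[u] == comp_of[v] or (u, v) in attempted:
                    continue
                d = aligned_distance(ktn.minima[u].coordinates,
                                     ktn.minima[v].coordinates,
                                     permute=ktn.permute_identical)
                if d < distance_tol:
                    cands.append((d, u, v))
        if not cands:
            return ktn
        cands.sort()
        _, u, v = cands[0]
        attempted.add((u, v))
        attempts += 1
        res = connect_pair(model, ktn.minima[u], ktn.minima[v],
                           max_cycles=max_cycles,
                           permute_identical=ktn.permute_identical,
                           **connect_kwargs)
        _merge_connection(ktn, res)
    return ktn
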