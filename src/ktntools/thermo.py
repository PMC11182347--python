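"""Harmonic-superposition thermodynamics on a kinetic transition network.

Each minimum contributes a classical harmonic partition function

    ln Z_i = -E_i / kT - sum_j ln nu_j + (n_vib / 2) ln(kT / 2 pi)

with nu_j = sqrt(lambda_j) / 2 pi the normal-mode frequencies of its
positive modes (zero modes excluded); for unit masses this is exactly the
Gaussian configuration integral of the basin.  Occupation probabilities
p_i = Z_i / sum Z_j are evaluated in log space, rates between adjacent
minima come from harmonic transition-state theory

    k_(i->ts) = (1 / 2 pi) exp(L_i - L_ts) exp(-(E_ts - E_i) / kT)

with L the stored log frequency products, and minima joined by
free-energy barriers below a threshold can be regrouped into
free-energy groups (the "funnels" of a free-energy landscape at
temperature T).

Temperatures are in Kelvin with kB in kcal/mol/K by default; analytic
model-unit systems pass ``kB=1``.  Symmetry numbers are taken as 1 for
all species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .units import KB_KCAL

__all__ = [
    "ln_z_harmonic",
    "occupation_probabilities",
    "tst_rate",
    "ln_tst_rate",
    "regroup_free_energy",
    "FreeEnergyGroup",
    "GroupedNetwork",
]

TWO_PI = 2.0 * np.pi


def ln_z_harmonic(minimum, temperature: float, kB: float = KB_KCAL) -> float:
    """Log harmonic partition function of one minimum at temperature T."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kT = kB * temperature
    if minimum.coordinates is not None:
        n_vib = int(np.asarray(minimum.coordinates).size) - minimum.n_zero_modes
    else:
        # without coordinates the dimension is unknown; drop the
        # kT-dependent constant, which is common to all minima of a system
        n_vib = 0
    return (-minimum.energy / kT - minimum.log_product_freq
            + 0.5 * n_vib * np.log(kT / TWO_PI))


def occupation_probabilities(ktn, temperature: float,
                             kB: float = KB_KCAL) -> dict[int, float]:
    """Equilibrium occupation probability of each minimum (sums to 1)."""
    if len(ktn.minima) == 0:
        raise ValueError("empty network")
    ids = sorted(ktn.minima)
    lnz = np.array([ln_z_harmonic(ktn.minima[i], temperature, kB)
                    for i in ids])
    p = np.exp(lnz - logsumexp(lnz))
    p /= p.sum()
    return dict(zip(ids, p))


def ln_tst_rate(ktn, ts_id: int, from_min_id: int, temperature: float,
                kB: float = KB_KCAL) -> float:
    """Log harmonic TST rate out of ``from_min_id`` through ``ts_id``."""
    ts = ktn.transition_states[ts_id]
    if from_min_id not in (ts.minus_min_id, ts.plus_min_id):
        raise ValueError(f"ts {ts_id} is not adjacent to minimum {from_min_id}")
    m = ktn.minima[from_min_id]
    kT = kB * temperature
    return (-np.log(TWO_PI) + m.log_product_freq - ts.log_product_freq
            - (ts.energy - m.energy) / kT)


def tst_rate(ktn, ts_id: int, from_min_id: int, temperature: float,
             kB: float = KB_KCAL) -> float:
    """Harmonic transition-state-theory rate (model units of 1/time)."""
    return float(np.exp(ln_tst_rate(ktn, ts_id, from_min_id, temperature, kB)))


# --------------------------------------------------------------------------
# free-energy regrouping
# --------------------------------------------------------------------------

@dataclass
class FreeEnergyGroup:
    """A set of minima lumped below a free-energy barrier threshold."""

    member_min_ids: frozenset
    free_energy: float
    occupation_probability: float


@dataclass
class GroupedNetwork:
    """Free-energy groups plus inter-group barrier free energies."""

    groups: list[FreeEnergyGroup]
    edge_free_energies: dict[frozenset, float]
    temperature: float
    kB: float = KB_KCAL

    def group_of(self, min_id: int) -> int:
        for gi, g in enumerate(self.groups):
            if min_id in g.member_min_ids:
                return gi
        raise KeyError(min_id)


def _ln_z_ts(ts, n_vib: int, temperature: float, kB: float) -> float:
    """Harmonic partition function of a transition state (positive modes)."""
    kT = kB * temperature
    return (-ts.energy / kT - ts.log_product_freq
            + 0.5 * n_vib * np.log(kT / TWO_PI))


def regroup_free_energy(ktn, temperature: float,
                        barrier_threshold: float,
                        kB: float = KB_KCAL) -> GroupedNetwork:
    """Merge minima separated by free-energy barriers below a threshold.

    Groups are merged iteratively (to a fixed point) whenever the
    inter-group barrier — the free energy of the connecting
    transition-state ensemble minus the group free energy — is below
    ``barrier_threshold`` in both directions.  Each group's free energy
    is -kT ln sum_i Z_i over its members.
    """
    if barrier_threshold < 0:
        raise ValueError("barrier_threshold must be >= 0")
    kT = kB * temperature
    ids = sorted(ktn.minima)
    lnz = {i: ln_z_harmonic(ktn.minima[i], temperature, kB) for i in ids}
    group_of = {i: i for i in ids}

    def find(i):
        while group_of[i] != i:
            group_of[i] = group_of[group_of[i]]
            i = group_of[i]
        return i

    n_vib_ts = None
    if ktn.transition_states:
        any_ts = next(iter(ktn.transition_states.values()))
        if any_ts.coordinates is not None:
            # one negative mode and the zero modes drop out of the count
            n_zero = max((m.n_zero_modes for m in ktn.minima.values()),
                         default=0)
            n_vib_ts = np.asarray(any_ts.coordinates).size - 1 - n_zero
    changed = True
    while changed:
        changed = False
        # group partition functions
        members: dict[int, list[int]] = {}
        for i in ids:
            members.setdefault(find(i), []).append(i)
        ln_zg = {g: logsumexp([lnz[i] for i in mids])
                 for g, mids in members.items()}
        # transition-state ensembles between distinct groups
        ens: dict[frozenset, list[float]] = {}
        for ts in ktn.transition_states.values():
            ga, gb = find(ts.minus_min_id), find(ts.plus_min_id)
            if ga == gb:
                continue
            nv = n_vib_ts
            if nv is None:
                nv = 0
            ens.setdefault(frozenset((ga, gb)), []).append(
                _ln_z_ts(ts, nv, temperature, kB))
        for pair, lnz_list in ens.items():
            ga, gb = sorted(pair)
            f_ts = -kT * logsumexp(lnz_list)
            f_a = -kT * ln_zg[ga]
            f_b = -kT * ln_zg[gb]
            if (f_ts - f_a) < barrier_threshold \
                    and (f_ts - f_b) < barrier_threshold:
                group_of[find(gb)] = find(ga)
                changed = True
                break
    # final groups
    members = {}
    for i in ids:
        members.setdefault(find(i), []).append(i)
    probs = occupation_probabilities(ktn, temperature, kB)
    groups = []
    roots = sorted(members, key=lambda g: min(members[g]))
    root_index = {}
    for g in roots:
        mids = members[g]
        f = -kT * logsumexp([lnz[i] for i in mids])
        p = float(sum(probs[i] for i in mids))
        root_index[g] = len(groups)
        groups.append(FreeEnergyGroup(member_min_ids=frozenset(mids),
                                      free_energy=float(f),
                                      occupation_probability=p))
    edges: dict[frozenset, list[float]] = {}
    for ts in ktn.transition_states.values():
        ga, gb = find(ts.minus_min_id), find(ts.plus_min_id)
        if ga == gb:
            continue
        nv = n_vib_ts if n_vib_ts is not None else 0
        edges.setdefault(frozenset((root_index[ga], root_index[gb])),
                         []).append(_ln_z_ts(ts, nv, temperature, kB))
    edge_f = {pair: float(-kT * logsumexp(v)) for pair, v in edges.items()}
    return GroupedNetwork(groups=groups, edge_free_energies=edge_f,
                          temperature=temperature, kB=kB)
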