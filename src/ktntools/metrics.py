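"""Structural order parameters and the CD-signal unit conversion.

For the coarse-grained chain, secondary structure is assigned from
backbone dihedrals: a residue is helix-like when its dihedral falls in
the helix window and strand-like in the strand window, with runs shorter
than three consecutive identical labels relabelled coil (mimicking the
refusal of hydrogen-bond-based assignment to call one-residue helices).
The windows are the synthetic model's own constants, not a claim about
real secondary-structure definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import HELIX_WINDOW, STRAND_WINDOW, PotentialModel

__all__ = [
    "OrderParameterSet",
    "radius_of_gyration",
    "secondary_structure_fractions",
    "molar_ellipticity",
]

MIN_RUN_LENGTH = 3


@dataclass
class OrderParameterSet:
    """Compactness and secondary-structure content of one configuration."""

    rg: float
    helix_fraction: float
    strand_fraction: float
    coil_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {"rg": self.rg, "helix": self.helix_fraction,
                "strand": self.strand_fraction, "coil": self.coil_fraction}


def radius_of_gyration(config: np.ndarray, masses: np.ndarray | None = None
                       ) -> float:
    """Mass-weighted RMS distance of beads from their centre of mass (A)."""
    pos = np.asarray(config, dtype=float)
    if pos.ndim == 1:
        pos = pos.reshape(-1, 3)
    n = pos.shape[0]
    if n < 1:
        raise ValueError("need at least one bead")
    if masses is None:
        masses = np.ones(n)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = np.average(pos, axis=0, weights=masses)
    sq = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def _in_window(phi_deg: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    p = np.mod(phi_deg, 360.0)
    lo_m, hi_m = np.mod(lo, 360.0), np.mod(hi, 360.0)
    if lo_m <= hi_m:
        return (p >= lo_m) & (p <= hi_m)
    return (p >= lo_m) | (p <= hi_m)


def assign_labels(model: PotentialModel, config: np.ndarray) -> list[str]:
    """Per-labelled-residue labels 'H' / 'E' / 'C' from dihedral windows.

    Dihedral j (over beads j..j+3) labels residue j+1; runs of H or E
    shorter than three residues are relabelled coil.
    """
    topo = model.topology
    if topo is None or len(topo.dihedrals) < 3:
        warnings.warn("chain too short for secondary-structure assignment; "
                      "returning all-coil", stacklevel=2)
        n = 0 if topo is None else len(topo.dihedrals)
        return ["C"] * n
    pos = model.check_configuration(config).reshape(-1, 3)
    phi = np.rad2deg(model.dihedral_angles(pos))
    labels = np.where(_in_window(phi, HELIX_WINDOW), "H",
                      np.where(_in_window(phi, STRAND_WINDOW), "E", "C"))
    labels = list(labels)
    # suppress runs shorter than MIN_RUN_LENGTH
    out = list(labels)
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in ("H", "E") and (j - i) < MIN_RUN_LENGTH:
            for k in range(i, j):
                out[k] = "C"
        i = j
    return out


def secondary_structure_fractions(model: PotentialModel,
                                  config: np.ndarray) -> OrderParameterSet:
    """Helix/strand/coil fractions plus radius of gyration."""
    labels = assign_labels(model, config)
    masses = (model.topology.masses if model.topology is not None else None)
    rg = radius_of_gyration(np.asarray(config).reshape(-1, 3), masses)
    if not labels:
        return OrderParameterSet(rg=rg, helix_fraction=0.0,
                                 strand_fraction=0.0, coil_fraction=1.0)
    n = len(labels)
    h = labels.count("H") / n
    e = labels.count("E") / n
    return OrderParameterSet(rg=rg, helix_fraction=h, strand_fraction=e,
                             coil_fraction=1.0 - h - e)


def molar_ellipticity(machine_signal_mdeg: float, path_length_cm: float,
                      concentration_molar: float,
                      per_residue: bool = False,
                      n_residues: int | None = None) -> float:
    """Convert a CD machine signal (millidegrees) to molar ellipticity.

    [theta]_molar = m_deg / (10 * l * c) with the signal converted from
    millidegrees to degrees, ``l`` in cm and ``c`` in mol/L; units are
    deg cm^2 dmol^-1.  With ``per_residue=True`` the result is divided by
    ``n_residues`` (mean residue ellipticity).
    """
    if path_length_cm <= 0 or concentration_molar <= 0:
        raise ValueError("path length and concentration must be positive")
    theta_deg = machine_signal_mdeg / 1000.0
    val = theta_deg / (10.0 * path_length_cm * concentration_molar)
    if per_residue:
        if not n_residues or n_residues <= 0:
            raise ValueError("per-residue conversion needs n_residues >= 1")
        val /= n_residues
    return val
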