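"""Built-in potential-energy models.

Three families of differentiable test systems drive the landscape
machinery:

* the Müller–Brown surface, the standard 2-D benchmark with three minima
  and two index-1 saddles, used to validate samplers against a dense-grid
  oracle;
* Lennard-Jones clusters in reduced units, the classic benchmark for
  basin-hopping global optimisation;
* a coarse-grained one-bead-per-residue peptide whose backbone dihedral
  potential carries two competing wells — a "helix window" and a "strand
  window" — and whose titratable per-residue charges interact through a
  Debye–Hückel screened Coulomb term.  Three charge presets emulate the
  protonation patterns of a peptide at neutral, mildly acidic and strongly
  acidic pH: lowering the pH protonates acidic side chains and histidine,
  raising the net positive charge.  The acidic and basic sites form two
  sequence blocks that touch in the compact helix, so the ionised acids of
  the neutral-pH preset act as helix-stabilising salt bridges which
  acidification strips away while adding His+ repulsion; the helix–strand
  stability gap therefore narrows as the pH analogue drops — the designed
  pH response of this synthetic system.

All models expose ``energy`` / ``gradient`` (and a fused
``energy_gradient``); gradients are analytic and are verified against
central finite differences by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .units import COULOMB_KCAL, WATER_EPS_R, T_BODY, debye_length

__all__ = [
    "PotentialModel",
    "BeadTopology",
    "ProtonationPreset",
    "MullerBrown",
    "LJCluster",
    "BeadPeptide",
    "make_muller_brown",
    "make_lj_cluster",
    "make_bead_peptide",
    "make_preset",
    "PRESET_NAMES",
    "debye_screening_factor",
]


# --------------------------------------------------------------------------
# base class and topology containers
# --------------------------------------------------------------------------

@dataclass
class BeadTopology:
    """Bonded topology of a bead chain.

    bonds/angles/dihedrals are index tuples into the bead list; masses in
    Da and charges in elementary charge units, one entry per bead.
    """

    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    dihedrals: list[tuple[int, int, int, int]]
    masses: np.ndarray
    charges: np.ndarray


class PotentialModel:
    """A differentiable energy function over a flat configuration vector."""

    #: number of degrees of freedom
    dimension: int
    #: bead topology, or None for analytic surfaces
    topology: BeadTopology | None = None
    name: str = "model"

    def energy(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.energy_gradient(x)[1]

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    # per-coordinate masses (length ``dimension``); unit masses by default
    def coordinate_masses(self) -> np.ndarray:
        if self.topology is not None:
            return np.repeat(self.topology.masses, 3)
        return np.ones(self.dimension)

    def n_beads(self) -> int | None:
        if self.topology is not None:
            return len(self.topology.masses)
        if self.dimension % 3 == 0 and self.dimension > 3:
            return self.dimension // 3
        return None

    def check_configuration(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.dimension:
            raise ValueError(
                f"configuration has {x.size} coordinates, model needs {self.dimension}"
            )
        return x

    def describe(self) -> dict:
        info: dict = {"name": self.name, "dimension": self.dimension}
        if self.topology is not None:
            t = self.topology
            info.update(
                n_beads=len(t.masses),
                n_bonds=len(t.bonds),
                n_angles=len(t.angles),
                n_dihedrals=len(t.dihedrals),
                charges=[float(q) for q in t.charges],
                masses=[float(m) for m in t.masses],
            )
        return info


# --------------------------------------------------------------------------
# Müller–Brown
# --------------------------------------------------------------------------

class MullerBrown(PotentialModel):
    """The Müller–Brown surface: sum of four exponential-quadratic terms."""

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    dimension = 2
    name = "muller_brown"

    def _terms(self, x: np.ndarray) -> np.ndarray:
        dx = x[0] - self.x0
        dy = x[1] - self.y0
        with np.errstate(over="ignore"):
            return self.A * np.exp(self.a * dx**2 + self.b * dx * dy
                                   + self.c * dy**2)

    def energy(self, x: np.ndarray) -> float:
        x = self.check_configuration(x)
        return float(self._terms(x).sum())

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = self.check_configuration(x)
        dx = x[0] - self.x0
        dy = x[1] - self.y0
        t = self._terms(x)
        gx = np.sum(t * (2.0 * self.a * dx + self.b * dy))
        gy = np.sum(t * (self.b * dx + 2.0 * self.c * dy))
        return float(t.sum()), np.array([gx, gy])


# --------------------------------------------------------------------------
# Lennard-Jones cluster
# --------------------------------------------------------------------------

class LJCluster(PotentialModel):
    """Pairwise Lennard-Jones cluster in reduced units (eps = sigma = 1)."""

    def __init__(self, n_atoms: int):
        if n_atoms < 2:
            raise ValueError("LJ cluster needs at least 2 atoms")
        self.n_atoms = n_atoms
        self.dimension = 3 * n_atoms
        self.name = f"lj{n_atoms}"
        iu = np.triu_indices(n_atoms, k=1)
        self._pi, self._pj = iu

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = self.check_configuration(x)
        pos = x.reshape(self.n_atoms, 3)
        if _kernels.HAVE_NUMBA:
            e, g = _kernels.lj_energy_gradient(pos)
            return float(e), g.ravel()
        return self.energy_gradient_numpy(x)

    def energy_gradient_numpy(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Vectorised numpy reference path (kernel-independent)."""
        x = self.check_configuration(x)
        pos = x.reshape(self.n_atoms, 3)
        rij = pos[self._pi] - pos[self._pj]
        r2 = np.einsum("ij,ij->i", rij, rij)
        inv2 = 1.0 / r2
        inv6 = inv2**3
        inv12 = inv6**2
        e = 4.0 * float(np.sum(inv12 - inv6))
        # dE/dr2 = 4 * (-12 r^-14 + 6 r^-8) / 2 ... use force on rij directly
        coef = 4.0 * (-12.0 * inv12 + 6.0 * inv6) * inv2  # dE/dr / r
        fvec = coef[:, None] * rij
        grad = np.zeros_like(pos)
        np.add.at(grad, self._pi, fvec)
        np.add.at(grad, self._pj, -fvec)
        return e, grad.ravel()

    def energy(self, x: np.ndarray) -> float:
        return self.energy_gradient(x)[0]


# --------------------------------------------------------------------------
# protonation presets
# --------------------------------------------------------------------------

PRESET_NAMES = ("prot1", "prot2", "prot3")

# Titratable layout (0-based indices): an N-terminal acidic block
# (His-like at 0, Glu-like at 1-2, Asp-like at 3) facing a basic block
# (Lys/Arg-like) four residues downstream.  In the helix the two blocks
# are in contact, so the ionised acids of the neutral-pH preset form
# helix-stabilising salt bridges that acidification removes while adding
# His+ repulsion against the basic block; extended and hairpin strand
# structures keep the blocks apart.  The layout was selected by scoring
# candidate layouts on a charge-free structural library for a large and
# robust preset ordering of the strand-helix gap, then frozen.


def _titratable_positions(n_residues: int) -> dict[str, int]:
    if n_residues >= 8:
        return {"his": 0, "glu_a": 1, "glu_b": 2, "asp": 3,
                "lys": n_residues - 4, "arg": n_residues - 3}
    # short chains: drop one Glu so all sites stay distinct
    return {"his": 0, "glu_a": 1, "asp": 2,
            "lys": n_residues - 2, "arg": n_residues - 1}


@dataclass(frozen=True)
class ProtonationPreset:
    """Per-residue formal charges emulating one protonation pattern.

    prot1 emulates neutral pH (acidic residues deprotonated, His neutral),
    prot2 a mildly acidic solution (most carboxylates and His protonated)
    and prot3 a strongly acidic one (everything titratable protonated), so
    net charge increases prot1 < prot2 < prot3.
    """

    name: str
    charges: dict[int, float]
    titratable_map: dict[int, bool]

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges.values()))

    def charge_vector(self, n_residues: int) -> np.ndarray:
        q = np.zeros(n_residues)
        for idx, val in self.charges.items():
            if not 0 <= idx < n_residues:
                raise ValueError(f"charge index {idx} outside chain of {n_residues}")
            q[idx] = val
        return q


def make_preset(name: str, n_residues: int = 10) -> ProtonationPreset:
    """Build one of the three built-in charge presets for a chain length."""
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    pos = _titratable_positions(n_residues)
    glu_sites = [pos[k] for k in ("glu_a", "glu_b") if k in pos]
    asp_site = pos["asp"]
    his_site = pos["his"]
    basic = {pos["lys"]: 1.0, pos["arg"]: 1.0}
    if name == "prot1":      # neutral-pH analogue: COO-, His neutral
        acid = {s: -1.0 for s in glu_sites + [asp_site]}
        his = {his_site: 0.0}
        prot = {**{s: False for s in glu_sites + [asp_site]},
                his_site: False}
    elif name == "prot2":    # pH ~4 analogue: Glu protonated, Asp ionised, His+
        acid = {**{s: 0.0 for s in glu_sites}, asp_site: -1.0}
        his = {his_site: 1.0}
        prot = {**{s: True for s in glu_sites}, asp_site: False,
                his_site: True}
    else:                    # prot3, pH ~3 analogue: all titratables protonated
        acid = {s: 0.0 for s in glu_sites + [asp_site]}
        his = {his_site: 1.0}
        prot = {**{s: True for s in glu_sites + [asp_site]},
                his_site: True}
    charges = {**acid, **his, **basic}
    return ProtonationPreset(name=name, charges=charges, titratable_map=prot)


# --------------------------------------------------------------------------
# Debye–Hückel screening
# --------------------------------------------------------------------------

def debye_screening_factor(r: float, ionic_strength: float,
                           temperature: float = T_BODY) -> float:
    """exp(-r / lambda_D) for a 1:1 electrolyte; 1.0 at zero ionic strength."""
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be positive")
    if ionic_strength < 0:
        raise ValueError("ionic_strength must be non-negative")
    lam = debye_length(ionic_strength, temperature)
    if np.isinf(lam):
        return np.ones_like(np.asarray(r, dtype=float)) if np.ndim(r) else 1.0
    return np.exp(-np.asarray(r, dtype=float) / lam) if np.ndim(r) else float(np.exp(-r / lam))


# --------------------------------------------------------------------------
# coarse-grained bead peptide
# --------------------------------------------------------------------------

# force-field constants (frozen package constants; see docs/methods.md)
BOND_R0 = 3.8          # Angstrom, Calpha-Calpha virtual bond
BOND_K = 25.0         # kcal/mol/A^2 (soft virtual bond; keeps minimisation well conditioned)
ANGLE_THETA0 = np.deg2rad(105.0)
ANGLE_K = 10.0         # kcal/mol/rad^2
LJ_EPS = 0.25          # kcal/mol
LJ_SIGMA = 4.8         # Angstrom
DIHEDRAL_HELIX_CENTER = np.deg2rad(60.0)
DIHEDRAL_STRAND_CENTER = np.deg2rad(180.0)
# first+second harmonic Fourier coefficients of the backbone dihedral term:
# exactly two wells: a helix well at 60 deg (depth -3.0 kcal/mol,
# curvature 6 kcal/mol/rad^2) and a strand well at 180 deg shallower by
# 0.3 kcal/mol, solved once from the zero-slope / depth-gap / curvature
# conditions and frozen
DIHEDRAL_C1 = 1.7999999999999998
DIHEDRAL_S1 = -3.34863156129983
DIHEDRAL_C2 = -0.9000000000000006
DIHEDRAL_S2 = -1.6743157806499147
# cooperative coupling between neighbouring dihedrals: contiguous helical
# runs are rewarded (emulating i,i+4 hydrogen-bond cooperativity) and
# contiguous strand runs more strongly (emulating sheet/hairpin pairing),
# so the two pure secondary structures form distinct low-energy funnels
# while mixed dihedral strings are pushed up in energy
COOP_HELIX = 0.4              # kcal/mol per adjacent helix-helix pair
COOP_STRAND = 0.65            # kcal/mol per adjacent strand-strand pair
COOP_POWER = 4                # sharpness of the smooth well-membership
RESIDUE_MASS = 110.0          # Da, average residue mass
# helix / strand assignment windows (degrees) shared with structure metrics
HELIX_WINDOW = (40.0, 80.0)
STRAND_WINDOW = (160.0, 200.0)


def _angular_diff(phi: np.ndarray, center: float) -> np.ndarray:
    """Periodic difference phi - center wrapped to (-pi, pi]."""
    d = phi - center
    return (d + np.pi) % (2.0 * np.pi) - np.pi


class BeadPeptide(PotentialModel):
    """One-bead-per-residue chain with a two-well backbone dihedral term.

    Energy terms: harmonic bonds and angles, a double-well dihedral
    potential (Gaussian wells centred in the helix and strand windows),
    Lennard-Jones between beads at least three bonds apart, and screened
    Coulomb between charged beads (Debye–Hückel, 1:1 electrolyte).
    """

    def __init__(self, n_residues: int, preset: ProtonationPreset | str,
                 ionic_strength: float = 0.1, temperature: float = T_BODY):
        if n_residues < 5:
            raise ValueError("need at least 5 residues")
        if ionic_strength < 0:
            raise ValueError("ionic_strength must be non-negative")
        if isinstance(preset, str):
            preset = make_preset(preset, n_residues)
        self.n_residues = n_residues
        self.preset = preset
        self.ionic_strength = float(ionic_strength)
        self.temperature = float(temperature)
        self.dimension = 3 * n_residues
        self.name = f"peptide{n_residues}-{preset.name}"
        charges = preset.charge_vector(n_residues)
        self.topology = BeadTopology(
            bonds=[(i, i + 1) for i in range(n_residues - 1)],
            angles=[(i, i + 1, i + 2) for i in range(n_residues - 2)],
            dihedrals=[(i, i + 1, i + 2, i + 3) for i in range(n_residues - 3)],
            masses=np.full(n_residues, RESIDUE_MASS),
            charges=charges,
        )
        self._lambda_d = debye_length(ionic_strength, temperature)
        # nonbonded pairs: |i-j| >= 3 (1-2 and 1-3 excluded)
        pi, pj = np.triu_indices(n_residues, k=3)
        self._pi, self._pj = pi, pj
        self._qq = charges[pi] * charges[pj] * COULOMB_KCAL / WATER_EPS_R

    # -- individual terms (energy + gradient accumulated into g) ----------

    def _bond_terms(self, pos, g):
        i = np.arange(self.n_residues - 1)
        d = pos[i + 1] - pos[i]
        r = np.linalg.norm(d, axis=1)
        e = BOND_K * np.sum((r - BOND_R0) ** 2)
        coef = (2.0 * BOND_K * (r - BOND_R0) / r)[:, None] * d
        g[1:] += coef
        g[:-1] -= coef
        return e

    def _angle_terms(self, pos, g):
        i = np.arange(self.n_residues - 2)
        u = pos[i] - pos[i + 1]
        v = pos[i + 2] - pos[i + 1]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.clip(1.0 - cos**2, 1e-12, None))
        e = ANGLE_K * np.sum((theta - ANGLE_THETA0) ** 2)
        dEdt = 2.0 * ANGLE_K * (theta - ANGLE_THETA0)
        dti = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
        dtk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
        gi = dEdt[:, None] * dti
        gk = dEdt[:, None] * dtk
        n = self.n_residues
        g[: n - 2] += gi
        g[2:] += gk
        g[1 : n - 1] -= gi + gk
        return e

    def dihedral_angles(self, pos: np.ndarray) -> np.ndarray:
        """Backbone dihedral angles (radians in (-pi, pi]) for all quadruples."""
        i = np.arange(self.n_residues - 3)
        b1 = pos[i + 1] - pos[i]
        b2 = pos[i + 2] - pos[i + 1]
        b3 = pos[i + 3] - pos[i + 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
        return np.arctan2(y, x)

    @staticmethod
    def dihedral_energy(phi: np.ndarray) -> np.ndarray:
        return (DIHEDRAL_C1 * np.cos(phi) + DIHEDRAL_S1 * np.sin(phi)
                + DIHEDRAL_C2 * np.cos(2.0 * phi)
                + DIHEDRAL_S2 * np.sin(2.0 * phi))

    @staticmethod
    def _dihedral_energy_deriv(phi: np.ndarray) -> np.ndarray:
        return (-DIHEDRAL_C1 * np.sin(phi) + DIHEDRAL_S1 * np.cos(phi)
                - 2.0 * DIHEDRAL_C2 * np.sin(2.0 * phi)
                + 2.0 * DIHEDRAL_S2 * np.cos(2.0 * phi))

    @staticmethod
    def _membership(phi: np.ndarray, center: float) -> tuple[np.ndarray,
                                                             np.ndarray]:
        """Smooth well membership w(phi) in [0, 1] and its derivative."""
        d = phi - center
        b = (1.0 + np.cos(d)) / 2.0
        w = b ** COOP_POWER
        dw = COOP_POWER * b ** (COOP_POWER - 1) * (-np.sin(d) / 2.0)
        return w, dw

    @classmethod
    def cooperative_energy(cls, phi: np.ndarray) -> float:
        """Neighbour-dihedral cooperativity for a dihedral-angle vector."""
        wh, _ = cls._membership(phi, DIHEDRAL_HELIX_CENTER)
        ws, _ = cls._membership(phi, DIHEDRAL_STRAND_CENTER)
        return float(-COOP_HELIX * np.sum(wh[:-1] * wh[1:])
                     - COOP_STRAND * np.sum(ws[:-1] * ws[1:]))

    def _dihedral_terms(self, pos, g):
        i = np.arange(self.n_residues - 3)
        b1 = pos[i + 1] - pos[i]
        b2 = pos[i + 2] - pos[i + 1]
        b3 = pos[i + 3] - pos[i + 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
        phi = np.arctan2(y, x)
        e = float(np.sum(self.dihedral_energy(phi)))
        dEdphi = self._dihedral_energy_deriv(phi)
        # cooperative neighbour coupling
        wh, dwh = self._membership(phi, DIHEDRAL_HELIX_CENTER)
        ws, dws = self._membership(phi, DIHEDRAL_STRAND_CENTER)
        e += float(-COOP_HELIX * np.sum(wh[:-1] * wh[1:])
                   - COOP_STRAND * np.sum(ws[:-1] * ws[1:]))
        nb_h = np.zeros_like(wh)
        nb_h[:-1] += wh[1:]
        nb_h[1:] += wh[:-1]
        nb_s = np.zeros_like(ws)
        nb_s[:-1] += ws[1:]
        nb_s[1:] += ws[:-1]
        dEdphi = dEdphi - COOP_HELIX * dwh * nb_h - COOP_STRAND * dws * nb_s
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        dphi_di = (-nb2 / n1sq)[:, None] * n1
        dphi_dl = (nb2 / n2sq)[:, None] * n2
        f1 = (np.einsum("ij,ij->i", b1, b2) / nb2**2)
        f3 = (np.einsum("ij,ij->i", b3, b2) / nb2**2)
        dphi_dj = -(1.0 + f1)[:, None] * dphi_di + f3[:, None] * dphi_dl
        dphi_dk = f1[:, None] * dphi_di - (1.0 + f3)[:, None] * dphi_dl
        n = self.n_residues
        w = dEdphi[:, None]
        g[: n - 3] += w * dphi_di
        g[1 : n - 2] += w * dphi_dj
        g[2 : n - 1] += w * dphi_dk
        g[3:] += w * dphi_dl
        return e

    def _nonbonded_terms(self, pos, g, include_coulomb=True, include_lj=True):
        if self._pi.size == 0:
            return 0.0, 0.0
        d = pos[self._pi] - pos[self._pj]
        r2 = np.einsum("ij,ij->i", d, d)
        r = np.sqrt(r2)
        e_lj = 0.0
        e_c = 0.0
        dEdr = np.zeros_like(r)
        if include_lj:
            s6 = (LJ_SIGMA**2 / r2) ** 3
            e_lj = 4.0 * LJ_EPS * float(np.sum(s6**2 - s6))
            dEdr += 4.0 * LJ_EPS * (-12.0 * s6**2 + 6.0 * s6) / r
        if include_coulomb and np.any(self._qq):
            if np.isinf(self._lambda_d):
                screen = np.ones_like(r)
                dscreen = np.zeros_like(r)
            else:
                screen = np.exp(-r / self._lambda_d)
                dscreen = -screen / self._lambda_d
            e_pair = self._qq * screen / r
            e_c = float(np.sum(e_pair))
            dEdr += self._qq * (dscreen / r - screen / r2)
        coef = (dEdr / r)[:, None] * d
        n = self.n_residues
        for c in range(3):
            acc = np.bincount(self._pi, weights=coef[:, c], minlength=n)
            acc -= np.bincount(self._pj, weights=coef[:, c], minlength=n)
            g[:, c] += acc
        return e_lj, e_c

    def coulomb_energy(self, x: np.ndarray) -> float:
        """Screened-Coulomb contribution alone at a configuration."""
        x = self.check_configuration(x)
        pos = x.reshape(self.n_residues, 3)
        g = np.zeros_like(pos)
        _, e_c = self._nonbonded_terms(pos, g, include_lj=False)
        return e_c

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = self.check_configuration(x)
        if _kernels.HAVE_NUMBA:
            pos = x.reshape(self.n_residues, 3)
            lam = 0.0 if np.isinf(self._lambda_d) else self._lambda_d
            e, g = _kernels.peptide_energy_gradient(
                pos, self._qq, self._pi, self._pj, lam,
                BOND_R0, BOND_K, ANGLE_THETA0, ANGLE_K,
                LJ_EPS, LJ_SIGMA,
                DIHEDRAL_C1, DIHEDRAL_S1, DIHEDRAL_C2, DIHEDRAL_S2,
                DIHEDRAL_HELIX_CENTER, DIHEDRAL_STRAND_CENTER,
                COOP_HELIX, COOP_STRAND, float(COOP_POWER),
            )
            return float(e), g.ravel()
        return self.energy_gradient_numpy(x)

    def energy_gradient_numpy(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Vectorised numpy reference path (kernel-independent)."""
        x = self.check_configuration(x)
        pos = x.reshape(self.n_residues, 3)
        g = np.zeros_like(pos)
        e = self._bond_terms(pos, g)
        e += self._angle_terms(pos, g)
        e += self._dihedral_terms(pos, g)
        e_lj, e_c = self._nonbonded_terms(pos, g)
        return float(e + e_lj + e_c), g.ravel()

    def energy(self, x: np.ndarray) -> float:
        return self.energy_gradient(x)[0]

    # -- reference geometries ---------------------------------------------

    def build_chain(self, dihedrals_deg) -> np.ndarray:
        """Construct a chain with ideal bonds/angles and given dihedrals.

        ``dihedrals_deg`` is a scalar or per-dihedral sequence in degrees.
        """
        n = self.n_residues
        phis = np.deg2rad(np.broadcast_to(np.asarray(dihedrals_deg, dtype=float),
                                          (n - 3,)).copy())
        pos = np.zeros((n, 3))
        pos[1] = [BOND_R0, 0.0, 0.0]
        # place third bead at ideal angle in the xy plane
        th = np.pi - ANGLE_THETA0
        pos[2] = pos[1] + BOND_R0 * np.array([np.cos(th), np.sin(th), 0.0])
        for k in range(3, n):
            pos[k] = _place_bead(pos[k - 3], pos[k - 2], pos[k - 1],
                                 BOND_R0, ANGLE_THETA0, phis[k - 3])
        return pos.ravel()

    def helix_configuration(self) -> np.ndarray:
        return self.build_chain(np.rad2deg(DIHEDRAL_HELIX_CENTER))

    def strand_configuration(self) -> np.ndarray:
        return self.build_chain(np.rad2deg(DIHEDRAL_STRAND_CENTER))


def _place_bead(p0, p1, p2, bond, angle, dihedral):
    """NeRF-style placement of the next bead given three predecessors."""
    bc = p2 - p1
    bc /= np.linalg.norm(bc)
    ab = p1 - p0
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return p2 + d[0] * bc + d[1] * m + d[2] * n


# --------------------------------------------------------------------------
# factories (spec-level entry points)
# --------------------------------------------------------------------------

def make_muller_brown() -> MullerBrown:
    """The standard 2-D Müller–Brown benchmark surface."""
    return MullerBrown()


def make_lj_cluster(n_atoms: int) -> LJCluster:
    """Lennard-Jones cluster of ``n_atoms`` in reduced units."""
    return LJCluster(n_atoms)


def make_bead_peptide(n_residues: int = 10,
                      preset: ProtonationPreset | str = "prot1",
                      ionic_strength: float = 0.1) -> BeadPeptide:
    """Coarse-grained titratable peptide chain (see :class:`BeadPeptide`)."""
    return BeadPeptide(n_residues, preset, ionic_strength)
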