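"""Discrete (multi-step) pair potentials for all bead-class pairs.

The engine integrates only stepwise potentials: a hard core followed by a
small number of constant-energy shells ending at a cutoff, beyond which the
energy is exactly zero.  Continuous model potentials (a flat-bottomed
Lennard-Jones-like well for van der Waals + hydrophobic association, and
Debye-Hueckel screened electrostatics for charged beads) are discretized by
shell averaging at table-construction time.

Well depths are expressed in units of kT at 300 K.  The hydrophobic /
aromatic ladder is calibrated so that ligand self-assembly propensity is
curcumin > resveratrol > aspirin (per-species `eps_scale` multipliers live
in the species library; see ``scripts/calibrate_ligands.py``).

Hydrogen bonds use a reaction-like rule: an unreacted donor/acceptor pair
that crosses the reaction distance inward, with capacity available on both
beads, forms a bond (a square well of depth ``bond_energy``); the bond
breaks when the pair crosses outward with enough radial kinetic energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (AVOGADRO, COULOMB_KCAL, E_CHARGE, EPS0, KB, KB_SI,
                        WATER_EPS_R, kt)
from .system_builder import BEAD_CLASSES, _CLASS_RADIUS

__all__ = [
    "StepPotential",
    "PairTable",
    "HBondRule",
    "ElectrostaticsParams",
    "debye_length",
    "screened_coulomb",
    "discretize",
    "pair_potential",
    "default_pair_table",
    "default_hbond_rule",
    "second_virial",
]

_KT300 = kt(300.0)


@dataclass(frozen=True)
class StepPotential:
    """Hard core + piecewise-constant shells; exactly zero beyond the cutoff.

    ``shell_energies[k]`` applies between ``shell_radii[k-1]`` (or the hard
    core for k = 0) and ``shell_radii[k]``.
    """

    hardcore: float
    shell_radii: tuple
    shell_energies: tuple

    def __post_init__(self):
        radii = np.asarray(self.shell_radii, dtype=float)
        energies = np.asarray(self.shell_energies, dtype=float)
        if len(radii) != len(energies):
            raise ValueError("one energy per shell required")
        if len(radii):
            if radii[0] <= self.hardcore:
                raise ValueError("first shell radius must exceed the hard core")
            if not np.all(np.diff(radii) > 0):
                raise ValueError("shell radii must be strictly increasing")
        if not np.all(np.isfinite(energies)):
            raise ValueError("shell energies must be finite")
        object.__setattr__(self, "shell_radii", tuple(radii))
        object.__setattr__(self, "shell_energies", tuple(energies))

    @property
    def cutoff(self) -> float:
        return self.shell_radii[-1] if self.shell_radii else self.hardcore

    def energy(self, r) -> np.ndarray:
        """Evaluate the step potential (inf inside the hard core)."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        out[r <= self.hardcore] = np.inf
        edges = (self.hardcore,) + self.shell_radii
        for k, e in enumerate(self.shell_energies):
            out[(r > edges[k]) & (r <= edges[k + 1])] = e
        return out

    def scaled(self, factor: float) -> "StepPotential":
        return StepPotential(self.hardcore, self.shell_radii,
                             tuple(e * factor for e in self.shell_energies))


@dataclass(frozen=True)
class ElectrostaticsParams:
    """Debye-Hueckel screening length and dielectric-lumped prefactor."""

    screening_length: float = 10.0          # A
    prefactor: float = COULOMB_KCAL / WATER_EPS_R  # kcal mol^-1 A per e^2

    def __post_init__(self):
        if self.screening_length <= 0:
            raise ValueError("screening_length must be positive")


@dataclass(frozen=True)
class HBondRule:
    """Distance-only hydrogen-bond reaction rule with per-bead capacities."""

    donor_classes: tuple = ("backbone", "sidechain_polar", "sidechain_charged",
                            "sidechain_aromatic", "ligand_aromatic",
                            "ligand_polar_O")
    acceptor_classes: tuple = ("backbone", "sidechain_polar",
                               "sidechain_aromatic", "ligand_aromatic",
                               "ligand_polar_O")
    bond_range: tuple = (3.0, 4.2)   # (d_min, d_max) A; react at d_max
    bond_energy: float = -3.5 * _KT300  # kcal/mol, negative

    def __post_init__(self):
        if not self.bond_range[0] < self.bond_range[1]:
            raise ValueError("bond_range d_min must be < d_max")
        if self.bond_energy >= 0:
            raise ValueError("bond_energy must be negative")


def debye_length(ionic_strength: float, temperature: float) -> float:
    """Debye screening length (A) of a 1:1 electrolyte.

    ``ionic_strength`` in mM, temperature in K; relative permittivity 78.4.
    """
    if ionic_strength <= 0 or temperature <= 0:
        raise ValueError("ionic strength and temperature must be positive")
    conc = ionic_strength * 1e-3 * 1e3 * AVOGADRO  # mM -> ions/m^3
    kappa2 = 2 * conc * E_CHARGE ** 2 / (EPS0 * WATER_EPS_R * KB_SI * temperature)
    return 1.0 / math.sqrt(kappa2) * 1e10


def screened_coulomb(q1: float, q2: float, r: float,
                     params: ElectrostaticsParams | None = None) -> float:
    """Debye-Hueckel pair energy (kcal/mol) at separation r (A)."""
    if r <= 0:
        raise ValueError("r must be positive")
    p = params or ElectrostaticsParams()
    return p.prefactor * q1 * q2 * math.exp(-r / p.screening_length) / r


def discretize(U, hardcore: float, cutoff: float, n_shells: int,
               samples_per_shell: int = 32) -> StepPotential:
    """Shell-average a continuous potential into a StepPotential.

    Shell radii are equally spaced on (hardcore, cutoff]; each shell energy
    is the mean of ``U`` over a midpoint grid inside the shell.  The energy
    beyond the last shell is exactly zero.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if cutoff <= hardcore:
        raise ValueError("cutoff must exceed hardcore")
    edges = np.linspace(hardcore, cutoff, n_shells + 1)
    energies = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        xs = lo + (np.arange(samples_per_shell) + 0.5) * (hi - lo) / samples_per_shell
        vals = np.asarray([U(x) for x in xs], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("potential diverges inside the discretization range")
        energies.append(float(vals.mean()))
    return StepPotential(hardcore, tuple(edges[1:]), tuple(energies))


@dataclass
class PairTable:
    """Symmetric map (bead class, bead class) -> StepPotential."""

    table: dict = field(default_factory=dict)

    def set(self, a: str, b: str, pot: StepPotential) -> None:
        self._check(a), self._check(b)
        self.table[frozenset((a, b)) if a != b else frozenset((a,))] = pot

    def get(self, a: str, b: str) -> StepPotential:
        self._check(a), self._check(b)
        key = frozenset((a, b)) if a != b else frozenset((a,))
        try:
            return self.table[key]
        except KeyError:
            raise KeyError(f"no potential for class pair ({a}, {b})") from None

    @staticmethod
    def _check(name: str) -> None:
        if name not in BEAD_CLASSES:
            raise KeyError(f"unknown bead class {name!r}")

    def max_cutoff(self) -> float:
        return max(p.cutoff for p in self.table.values())


def pair_potential(a: str, b: str, table: PairTable) -> StepPotential:
    """Symmetric lookup of the discrete potential for a class pair."""
    return table.get(a, b)


# ---------------------------------------------------------------------------
# default table construction

#: pairwise well depths in units of kT at 300 K.  Hydrophobic and aromatic
#: classes attract (aromatic-aromatic is the pi-stacking surrogate); polar
#: and mixed polar/hydrophobic pairs are near-athermal because the implicit
#: solvation penalty is folded in.
_HPHOB = "sidechain_hydrophobic"
_POLAR = "sidechain_polar"
_CHARGED = "sidechain_charged"
_AROM = "sidechain_aromatic"
_LAR = "ligand_aromatic"
_LAL = "ligand_aliphatic"
_LOX = "ligand_polar_O"
_BB = "backbone"

_DEPTH_KT = {
    (_BB, _BB): 0.45,
    (_BB, _HPHOB): 0.40, (_BB, _POLAR): 0.35, (_BB, _CHARGED): 0.15,
    (_BB, _AROM): 0.45, (_BB, _LAR): 1.00, (_BB, _LAL): 0.80,
    (_BB, _LOX): 0.30,
    (_HPHOB, _HPHOB): 1.00, (_HPHOB, _POLAR): 0.10, (_HPHOB, _CHARGED): 0.05,
    (_HPHOB, _AROM): 0.90, (_HPHOB, _LAR): 0.90, (_HPHOB, _LAL): 0.85,
    (_HPHOB, _LOX): 0.05,
    (_POLAR, _POLAR): 0.55, (_POLAR, _CHARGED): 0.30, (_POLAR, _AROM): 0.30,
    (_POLAR, _LAR): 0.70, (_POLAR, _LAL): 0.50, (_POLAR, _LOX): 0.40,
    (_CHARGED, _CHARGED): 0.05, (_CHARGED, _AROM): 0.30,
    (_CHARGED, _LAR): 0.40, (_CHARGED, _LAL): 0.05, (_CHARGED, _LOX): 0.25,
    (_AROM, _AROM): 1.20, (_AROM, _LAR): 1.20, (_AROM, _LAL): 0.80,
    (_AROM, _LOX): 0.10,
    (_LAR, _LAR): 1.20, (_LAR, _LAL): 0.85, (_LAR, _LOX): 0.10,
    (_LAL, _LAL): 0.85, (_LAL, _LOX): 0.05,
    (_LOX, _LOX): 0.25,
}

_VDW_CUTOFF = 6.5
_VDW_SHOULDER = 6.0
_ELEC_CUTOFF = 7.0
_ELEC_SHELLS = 4
#: classes that carry unit charge (electrostatic shells added to their pairs;
#: every bead of the charged class carries exactly +1 in the species library)
_CHARGED_CLASSES = {_CHARGED: 1.0}


def _depth_kt(a: str, b: str) -> float:
    return _DEPTH_KT.get((a, b), _DEPTH_KT.get((b, a), 0.05))


def _flat_bottom_lj(eps: float, hardcore: float, r_min: float):
    """-eps inside r_min, Lennard-Jones attractive tail beyond."""
    sigma = r_min * 2.0 ** (-1.0 / 6.0)

    def U(r):
        if r < r_min:
            return -eps
        sr6 = (sigma / r) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6)

    return U


def default_pair_table(temperature: float = 300.0,
                       elec: ElectrostaticsParams | None = None) -> PairTable:
    """Build the shipped class-pair table by discretizing the model potentials.

    Uncharged class pairs: a flat-bottomed LJ well of depth ``_DEPTH_KT`` kT,
    4 shells to 7.5 A.  The charged-class pair additionally includes the
    unit-charge screened-Coulomb repulsion, 6 shells to 12 A (every bead of
    that class carries +1 in the species library).
    """
    elec = elec or ElectrostaticsParams()
    kT = kt(temperature)
    table = PairTable()
    for ia, a in enumerate(BEAD_CLASSES):
        for b in BEAD_CLASSES[ia:]:
            hc = _CLASS_RADIUS[a] + _CLASS_RADIUS[b]
            eps = _depth_kt(a, b) * kT
            if a in _CHARGED_CLASSES and b in _CHARGED_CLASSES:
                q2 = _CHARGED_CLASSES[a] * _CHARGED_CLASSES[b]
                vdw = _flat_bottom_lj(eps, hc, hc + 0.7)

                def U(r, vdw=vdw, q2=q2):
                    u = vdw(r) if r < _VDW_CUTOFF else 0.0
                    return u + screened_coulomb(1.0, q2, r, elec)

                pot = discretize(U, hc, _ELEC_CUTOFF, _ELEC_SHELLS)
            else:
                # single wide square well: the wide flat bottom keeps the
                # boundary-crossing rate low at dense packing
                pot = StepPotential(hc, (_VDW_CUTOFF,), (-eps,))
            table.set(a, b, pot)
    return table


def default_hbond_rule() -> HBondRule:
    return HBondRule()


def second_virial(pot: StepPotential, temperature: float = 300.0,
                  scale: float = 1.0) -> float:
    """Second virial coefficient (A^3) of a step potential, closed form.

    B2 = 2*pi/3 * hc^3 - 2*pi * sum_shells (e^{-beta U} - 1)(r1^3 - r0^3)/3.
    ``scale`` multiplies the shell energies (species eps_scale product).
    """
    beta = 1.0 / kt(temperature)
    b2 = 2.0 * math.pi / 3.0 * pot.hardcore ** 3
    edges = (pot.hardcore,) + pot.shell_radii
    for k, e in enumerate(pot.shell_energies):
        r0, r1 = edges[k], edges[k + 1]
        b2 -= (2.0 * math.pi / 3.0) * (math.exp(-beta * e * scale) - 1.0) * (
            r1 ** 3 - r0 ** 3)
    return b2
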