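"""Cα-bead force field: Gō-like quasi-rigid core plus flexible chains.

Every residue is a single bead at its Cα position. Residues with deposited
coordinates form the quasi-rigid core, held near its reference geometry by a
12-10 native-contact potential and harmonic pseudo-bonds; residues without
coordinates are flexible polymer beads with harmonic bonds and angles and a
purely repulsive excluded volume. Cross-link restraints enter through a
sigmoidal potential whose force vanishes at large separations, so restraints
incompatible with the instantaneous conformation do not blow up the dynamics
and can be switched stochastically.

Energies are kcal/mol, lengths Å, angles radians.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .structure_io import Structure

__all__ = [
    "ForceFieldParams",
    "CGTopology",
    "RestraintSpec",
    "build_topology",
    "bond_energy",
    "angle_energy",
    "repulsive_energy",
    "go_contact_energy",
    "restraint_energy",
    "total_energy_forces",
]

#: Boltzmann constant, kcal/mol/K
KBOLTZ = 0.0019872041
#: 1 kcal/mol expressed in Da·Å²/ps² (the engine's internal unit system)
KCAL_TO_INTERNAL = 418.4


@dataclass
class ForceFieldParams:
    """All force-field constants with their published defaults.

    k_b/b_0 govern virtual bonds, k_alpha/alpha_0 bending of flexible
    triples, eps_rep/sigma_rep the excluded volume, and the cross-link
    restraint is a sigmoid of height k_xl, midpoint l_0 (the 25 Å PhoX
    Cα–Cα limit) and slope beta; n_active restraints are re-drawn every
    tau_xl picoseconds. go_epsilon/go_cutoff parametrize the 12-10
    native-contact term that keeps the core quasi-rigid.
    """

    k_b: float = 50.0          # kcal/mol/Å²
    b_0: float = 3.8           # Å
    k_alpha: float = 1.75      # kcal/mol/rad²
    alpha_0: float = np.deg2rad(112.0)   # rad
    eps_rep: float = 2.0       # kcal/mol
    sigma_rep: float = 4.0     # Å
    k_xl: float = 10.0         # kcal/mol
    beta: float = 0.5          # Å⁻¹
    l_0: float = 25.0          # Å
    n_active: int = 5          # restraints active at a time (N_c)
    tau_xl: float = 500.0      # ps between restraint re-draws
    go_epsilon: float = 3.0    # kcal/mol per native contact
    go_cutoff: float = 8.0     # Å contact-enumeration cutoff
    nonbonded_cutoff: float = 12.0  # Å repulsion truncation

    def __post_init__(self) -> None:
        for name in ("k_b", "b_0", "k_alpha", "eps_rep", "sigma_rep", "k_xl",
                     "beta", "l_0", "tau_xl", "go_epsilon", "go_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_active < 1:
            raise ValueError("n_active must be >= 1")


@dataclass(frozen=True)
class RestraintSpec:
    """One cross-link distance restraint between two beads."""

    index: int          # 1-based restraint id k
    i: int              # bead indices into the topology
    j: int
    l_0: float = 25.0   # Å upper bound

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("restraint bead pair must be distinct")


@dataclass
class CGTopology:
    """Bead topology with precomputed interaction lists (numpy index arrays)."""

    keys: list[tuple[str, int]]            # bead -> (chain, residue number)
    flexible: np.ndarray                   # bool per bead
    reference: np.ndarray                  # (N,3) Å; NaN rows for flexible beads
    bond_ij: np.ndarray                    # (B,2) int
    bond_b0: np.ndarray                    # (B,) Å
    angle_ijk: np.ndarray                  # (A,3) int
    contact_ij: np.ndarray                 # (C,2) int  rigid native contacts
    contact_r0: np.ndarray                 # (C,) Å
    nonbonded_ij: np.ndarray               # (P,2) int  repulsive pairs
    lysines: list[int] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.keys)

    def index(self, chain: str, number: int) -> int:
        return self.keys.index((chain, number))

    # -- (de)serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "keys": [[c, n] for c, n in self.keys],
            "flexible": self.flexible.astype(int).tolist(),
            "reference": np.where(np.isnan(self.reference), None,
                                  self.reference).tolist(),
            "bonds": [[int(i), int(j), float(b)] for (i, j), b in
                      zip(self.bond_ij, self.bond_b0)],
            "angles": self.angle_ijk.tolist(),
            "contacts": [[int(i), int(j), float(r)] for (i, j), r in
                         zip(self.contact_ij, self.contact_r0)],
            "lysines": self.lysines,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CGTopology":
        d = json.loads(Path(path).read_text())
        keys = [tuple(k) for k in d["keys"]]
        ref = np.array([[np.nan if v is None else v for v in row]
                        for row in d["reference"]], dtype=float)
        bonds = np.array([b[:2] for b in d["bonds"]], dtype=int).reshape(-1, 2)
        b0 = np.array([b[2] for b in d["bonds"]], dtype=float)
        contacts = np.array([c[:2] for c in d["contacts"]], dtype=int).reshape(-1, 2)
        r0 = np.array([c[2] for c in d["contacts"]], dtype=float)
        angles = np.array(d["angles"], dtype=int).reshape(-1, 3)
        flexible = np.array(d["flexible"], dtype=bool)
        nb = _nonbonded_pairs(len(keys), bonds, angles, contacts)
        return cls(keys=keys, flexible=flexible, reference=ref, bond_ij=bonds,
                   bond_b0=b0, angle_ijk=angles, contact_ij=contacts,
                   contact_r0=r0, nonbonded_ij=nb, lysines=list(d["lysines"]))


# ---------------------------------------------------------------------------
# scalar closed forms (each returns value and derivative)


def bond_energy(b: float, params: ForceFieldParams) -> tuple[float, float]:
    """Harmonic bond K_b(b − b_0)² and its derivative."""
    db = b - params.b_0
    return params.k_b * db * db, 2.0 * params.k_b * db


def angle_energy(alpha: float, params: ForceFieldParams) -> tuple[float, float]:
    """Harmonic bend K_α(α − α_0)² and its derivative."""
    da = alpha - params.alpha_0
    return params.k_alpha * da * da, 2.0 * params.k_alpha * da


def repulsive_energy(r: float, params: ForceFieldParams) -> tuple[float, float]:
    """Pure r⁻¹² excluded volume ε_R(σ_R/r)¹²."""
    if r <= 0:
        raise ValueError("singular distance r = 0")
    v = params.eps_rep * (params.sigma_rep / r) ** 12
    return v, -12.0 * v / r


def go_contact_energy(r: float, r_native: float,
                      params: ForceFieldParams) -> tuple[float, float]:
    """12-10 native-contact well, minimum −go_epsilon at r = r_native."""
    s10 = (r_native / r) ** 10
    s12 = (r_native / r) ** 12
    v = params.go_epsilon * (5.0 * s12 - 6.0 * s10)
    dv = 60.0 * params.go_epsilon * (s10 - s12) / r
    return v, dv


def restraint_energy(l: float, params: ForceFieldParams) -> tuple[float, float]:
    """Sigmoidal restraint K_XL/(1 + e^{−β(l − l_0)}).

    Half height at l = l_0; the force peaks at the midpoint and decays to
    zero both for satisfied links and for links far beyond the bound, which
    is what makes random re-selection of restraints numerically safe.
    """
    s = 1.0 / (1.0 + np.exp(-params.beta * (l - params.l_0)))
    return params.k_xl * s, params.k_xl * params.beta * s * (1.0 - s)


# ---------------------------------------------------------------------------
# topology construction


def _nonbonded_pairs(n: int, bonds: np.ndarray, angles: np.ndarray,
                     contacts: np.ndarray) -> np.ndarray:
    """All i<j pairs excluding bonded, 1-3 (angle ends) and native pairs."""
    iu, ju = np.triu_indices(n, k=1)
    excluded = set()
    for i, j in bonds:
        excluded.add((min(i, j), max(i, j)))
    for i, _, k in angles:
        excluded.add((min(i, k), max(i, k)))
    for i, j in contacts:
        excluded.add((min(i, j), max(i, j)))
    mask = np.fromiter(((int(a), int(b)) not in excluded for a, b in zip(iu, ju)),
                       dtype=bool, count=len(iu))
    return np.stack([iu[mask], ju[mask]], axis=1)


def build_topology(structure: Structure,
                   full_sequences: dict[str, tuple[int, int]],
                   flexible_override: dict[str, list[tuple[int, int]]] | None = None,
                   params: ForceFieldParams | None = None) -> CGTopology:
    """Build the bead topology from a structure and per-chain residue ranges.

    ``full_sequences`` maps each chain to its (first, last) residue number
    inclusive; residues inside the range but absent from the structure (or
    inside ``flexible_override`` ranges) become flexible beads. Rigid beads
    carry their Cα reference coordinate. Native contacts are enumerated over
    rigid pairs within ``go_cutoff``, skipping pairs closer than 3 residues
    along a chain.
    """
    params = params or ForceFieldParams()
    flexible_override = flexible_override or {}
    keys: list[tuple[str, int]] = []
    flex: list[bool] = []
    ref: list[np.ndarray] = []

    for chain, (lo, hi) in full_sequences.items():
        if hi < lo:
            raise ValueError(f"chain {chain!r} has zero residues in full_sequences")
        for (a, b) in flexible_override.get(chain, []):
            if a > b:
                warnings.warn(f"empty flexible range {a}-{b} in chain {chain!r}")
            if a < lo or b > hi:
                raise ValueError(f"flexible_override {a}-{b} outside chain {chain!r}")
        present = {}
        if chain in structure.residues:
            present = {r.number: r for r in structure.residues[chain] if r.present}
        for num in range(lo, hi + 1):
            forced = any(a <= num <= b for a, b in flexible_override.get(chain, []))
            keys.append((chain, num))
            if num in present and not forced:
                flex.append(False)
                ref.append(np.asarray(present[num].ca, dtype=float))
            else:
                flex.append(True)
                ref.append(np.full(3, np.nan))

    flexible = np.asarray(flex, dtype=bool)
    reference = np.asarray(ref, dtype=float)
    n = len(keys)

    # bonds between consecutive residues of a chain; rigid-rigid pairs keep
    # their reference length (pseudo-bonds), anything touching a flexible
    # bead uses b_0
    bond_ij, bond_b0 = [], []
    for a in range(n - 1):
        (ca, na), (cb, nb) = keys[a], keys[a + 1]
        if ca != cb or nb != na + 1:
            continue
        bond_ij.append((a, a + 1))
        if not flexible[a] and not flexible[a + 1]:
            bond_b0.append(float(np.linalg.norm(reference[a] - reference[a + 1])))
        else:
            bond_b0.append(params.b_0)
    bond_ij = np.asarray(bond_ij, dtype=int).reshape(-1, 2)
    bond_b0 = np.asarray(bond_b0, dtype=float)

    # angles only for consecutive triples containing >= 1 flexible bead;
    # rigid-core internal geometry is the Gō terms' job
    angle_ijk = []
    for a in range(n - 2):
        (ca, na), (cb, nb), (cc, nc) = keys[a], keys[a + 1], keys[a + 2]
        if ca != cb or cb != cc or nb != na + 1 or nc != nb + 1:
            continue
        if flexible[a] or flexible[a + 1] or flexible[a + 2]:
            angle_ijk.append((a, a + 1, a + 2))
    angle_ijk = np.asarray(angle_ijk, dtype=int).reshape(-1, 3)

    # native contacts over rigid beads within go_cutoff, |i-j| >= 3 in-chain
    rigid_idx = np.flatnonzero(~flexible)
    contact_ij, contact_r0 = [], []
    if len(rigid_idx) >= 2:
        rc = reference[rigid_idx]
        d = np.linalg.norm(rc[:, None, :] - rc[None, :, :], axis=-1)
        for ii in range(len(rigid_idx)):
            for jj in range(ii + 1, len(rigid_idx)):
                a, b = int(rigid_idx[ii]), int(rigid_idx[jj])
                (ca, na), (cb, nb) = keys[a], keys[b]
                if ca == cb and abs(nb - na) < 3:
                    continue
                if d[ii, jj] <= params.go_cutoff:
                    contact_ij.append((a, b))
                    contact_r0.append(float(d[ii, jj]))
    contact_ij = np.asarray(contact_ij, dtype=int).reshape(-1, 2)
    contact_r0 = np.asarray(contact_r0, dtype=float)

    lysines = [i for i, (c, num) in enumerate(keys)
               if c in structure.residues and
               any(r.number == num and r.name == "LYS"
                   for r in structure.residues[c])]

    nb = _nonbonded_pairs(n, bond_ij, angle_ijk, contact_ij)
    return CGTopology(keys=keys, flexible=flexible, reference=reference,
                      bond_ij=bond_ij, bond_b0=bond_b0, angle_ijk=angle_ijk,
                      contact_ij=contact_ij, contact_r0=contact_r0,
                      nonbonded_ij=nb, lysines=lysines)


# ---------------------------------------------------------------------------
# total energy and analytic forces


def _pair_accumulate(forces: np.ndarray, ij: np.ndarray, unit: np.ndarray,
                     dvdr: np.ndarray) -> None:
    # force on i is -dV/dr * unit(i->j)... unit points from j to i
    np.add.at(forces, ij[:, 0], -(dvdr[:, None] * unit))
    np.add.at(forces, ij[:, 1], dvdr[:, None] * unit)


def total_energy_forces(topology: CGTopology, coords: np.ndarray,
                        active_restraints: Sequence[RestraintSpec] = (),
                        params: ForceFieldParams | None = None,
                        ) -> tuple[float, np.ndarray]:
    """Total potential energy (kcal/mol) and exact negative gradient.

    Sums bonds + angles + native contacts + nonbonded repulsion (truncated
    at ``nonbonded_cutoff``) + active sigmoidal restraints.
    """
    params = params or ForceFieldParams()
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_beads, 3):
        raise ValueError(f"expected coords of shape ({topology.n_beads}, 3), "
                         f"got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise FloatingPointError("non-finite coordinate in state")

    energy = 0.0
    forces = np.zeros_like(coords)

    # bonds
    if len(topology.bond_ij):
        ij = topology.bond_ij
        dvec = coords[ij[:, 0]] - coords[ij[:, 1]]
        r = np.linalg.norm(dvec, axis=1)
        db = r - topology.bond_b0
        energy += float(np.sum(params.k_b * db * db))
        _pair_accumulate(forces, ij, dvec / r[:, None], 2.0 * params.k_b * db)

    # angles
    if len(topology.angle_ijk):
        ijk = topology.angle_ijk
        u = coords[ijk[:, 0]] - coords[ijk[:, 1]]
        v = coords[ijk[:, 2]] - coords[ijk[:, 1]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh, vh = u / nu[:, None], v / nv[:, None]
        cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-16, None))
        theta = np.arccos(cos)
        da = theta - params.alpha_0
        energy += float(np.sum(params.k_alpha * da * da))
        dvdt = 2.0 * params.k_alpha * da
        dti = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
        dtk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
        fi = -dvdt[:, None] * dti
        fk = -dvdt[:, None] * dtk
        np.add.at(forces, ijk[:, 0], fi)
        np.add.at(forces, ijk[:, 2], fk)
        np.add.at(forces, ijk[:, 1], -(fi + fk))

    # native contacts (12-10)
    if len(topology.contact_ij):
        ij = topology.contact_ij
        dvec = coords[ij[:, 0]] - coords[ij[:, 1]]
        r = np.linalg.norm(dvec, axis=1)
        s10 = (topology.contact_r0 / r) ** 10
        s12 = (topology.contact_r0 / r) ** 12
        energy += float(params.go_epsilon * np.sum(5.0 * s12 - 6.0 * s10))
        dvdr = 60.0 * params.go_epsilon * (s10 - s12) / r
        _pair_accumulate(forces, ij, dvec / r[:, None], dvdr)

    # nonbonded repulsion, truncated without shifting
    if len(topology.nonbonded_ij):
        ij = topology.nonbonded_ij
        dvec = coords[ij[:, 0]] - coords[ij[:, 1]]
        r = np.linalg.norm(dvec, axis=1)
        within = r < params.nonbonded_cutoff
        if np.any(within):
            ijw, rw, dw = ij[within], r[within], dvec[within]
            v = params.eps_rep * (params.sigma_rep / rw) ** 12
            energy += float(np.sum(v))
            _pair_accumulate(forces, ijw, dw / rw[:, None], -12.0 * v / rw)

    # active cross-link restraints
    for spec in active_restraints:
        dvec = coords[spec.i] - coords[spec.j]
        l = float(np.linalg.norm(dvec))
        p = ForceFieldParams(**{**asdict(params), "l_0": spec.l_0}) \
            if spec.l_0 != params.l_0 else params
        v, dv = restraint_energy(l, p)
        energy += v
        unit = dvec / l
        forces[spec.i] -= dv * unit
        forces[spec.j] += dv * unit

    return energy, forces
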