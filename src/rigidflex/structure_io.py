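"""Reading and writing Cα-level structures, superposition and distances.

Structures are reduced to one Cα coordinate per residue, which is the
resolution of everything downstream: the coarse-grained bead model, the
cross-link distance checks (Cα–Cα) and the scattering calculator.
Residues that appear in the deposited sequence but have no Cα coordinate
(unresolved loops, disordered termini) are kept as *absent* placeholders so
that the topology builder can flag them flexible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Structure",
    "Superposition",
    "read_structure",
    "write_ensemble_pdb",
    "write_structure_pdb",
    "superpose",
    "ca_distance",
]


class StructureError(ValueError):
    """Raised for unreadable or degenerate structure input."""


@dataclass(frozen=True)
class Residue:
    """One residue: author number, name, and an optional Cα coordinate."""

    number: int
    name: str
    ca: np.ndarray | None  # shape (3,) Å, or None if unresolved

    @property
    def present(self) -> bool:
        return self.ca is not None


@dataclass
class Structure:
    """Ordered chains of residues, Cα-only.

    Residue identity is (chain id, author residue number). Residue numbers
    are strictly increasing within a chain; insertion codes are rejected on
    input to avoid silent misnumbering.
    """

    chains: list[str] = field(default_factory=list)
    residues: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid in self.chains:
            nums = [r.number for r in self.residues.get(cid, [])]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise StructureError(
                    f"residue numbers not strictly increasing in chain {cid!r}"
                )

    # -- queries -----------------------------------------------------------
    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues[chain]:
            if r.number == number:
                return r
        raise KeyError((chain, number))

    def present_keys(self) -> list[tuple[str, int]]:
        return [
            (cid, r.number)
            for cid in self.chains
            for r in self.residues[cid]
            if r.present
        ]

    def n_present(self) -> int:
        return len(self.present_keys())

    def coords(self, selection: Iterable[tuple[str, int]]) -> np.ndarray:
        """Cα coordinates for (chain, residue) keys, in the given order."""
        out = []
        for chain, number in selection:
            r = self.residue(chain, number)
            if not r.present:
                raise StructureError(f"residue {chain}/{number} has no coordinates")
            out.append(r.ca)
        return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid-body fit of a mobile selection onto a reference."""

    rotation: np.ndarray  # (3,3), orthonormal, det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å over the fitted selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# reading


def _full_sequence_numbers(chain: gemmi.Chain, st: gemmi.Structure) -> dict[int, str]:
    """Author-numbered residue names from the entity full sequence, if any."""
    out: dict[int, str] = {}
    try:
        ent = st.get_entity_of(chain.get_polymer())
    except Exception:
        ent = None
    if ent is None or not ent.full_sequence:
        return out
    # map label_seq -> author number through present residues; fall back to
    # assuming author numbering is contiguous with the first present residue
    label_to_auth = {}
    for res in chain:
        if res.label_seq is not None and res.seqid.num is not None:
            label_to_auth[res.label_seq] = res.seqid.num
    if not label_to_auth:
        return out
    # infer offset (author - label) from the observed residues; only trust a
    # single consistent offset, else report nothing
    offsets = {a - l for l, a in label_to_auth.items()}
    if len(offsets) != 1:
        return out
    off = offsets.pop()
    for i, item in enumerate(ent.full_sequence, start=1):
        out[i + off] = gemmi.Entity.first_mon(item)
    return out


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a Cα-only :class:`Structure`.

    Residues listed in the sequence (SEQRES / entity) but lacking a Cα atom,
    and numbering gaps between observed residues, become absent placeholders.
    The first model and the first altloc are used; occupancy is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    st.assign_label_seq_id()

    model = st[0]
    out = Structure()
    for chain in model:
        seen: dict[int, tuple[str, np.ndarray | None]] = {}
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise StructureError(
                    f"insertion code {res.seqid.icode!r} at {chain.name}/{res.seqid.num}"
                    " is not supported"
                )
            ca = res.find_atom("CA", "*")
            num = res.seqid.num
            if num in seen:
                continue  # first altloc/conformer wins
            seen[num] = (res.name, None if ca is None else
                         np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
        if not seen:
            continue
        full = _full_sequence_numbers(chain, st)
        lo = min(min(seen), min(full, default=min(seen)))
        hi = max(max(seen), max(full, default=max(seen)))
        residues = []
        for num in range(lo, hi + 1):
            if num in seen:
                name, ca = seen[num]
                residues.append(Residue(num, name, ca))
            elif num in full:
                residues.append(Residue(num, full[num], None))
            elif min(seen) < num < max(seen):
                residues.append(Residue(num, "UNK", None))  # numbering gap
        out.chains.append(chain.name)
        out.residues[chain.name] = residues
    if sum(1 for _ in out.present_keys()) == 0:
        raise StructureError(f"{path} contains no Cα atoms")
    return Structure(chains=out.chains, residues=out.residues)


# ---------------------------------------------------------------------------
# writing


def _as_gemmi(frames: Sequence[np.ndarray], keys: Sequence[tuple[str, int]],
              names: Sequence[str] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "rigidflex"
    for m, coords in enumerate(frames, start=1):
        model = gemmi.Model(m)
        by_chain: dict[str, gemmi.Chain] = {}
        for (cid, num), xyz in zip(keys, coords):
            if cid not in by_chain:
                by_chain[cid] = gemmi.Chain(cid)
            res = gemmi.Residue()
            res.name = names[keys.index((cid, num))] if names else "ALA"
            res.seqid = gemmi.SeqId(num, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            res.add_atom(atom)
            by_chain[cid].add_residue(res)
        for ch in by_chain.values():
            model.add_chain(ch)
        st.add_model(model)
    return st


def write_ensemble_pdb(path: str | Path, frames: Sequence[np.ndarray],
                       keys: Sequence[tuple[str, int]]) -> None:
    """Write frames as a multi-model Cα-only PDB (MODEL/ENDMDL records)."""
    st = _as_gemmi(frames, list(keys))
    st.write_pdb(str(path))


def write_structure_pdb(path: str | Path, structure: Structure,
                        seqres: dict[str, list[str]] | None = None) -> None:
    """Write present residues of a Structure as a Cα-only PDB.

    ``seqres`` maps chain id to the full residue-name list (covering absent
    residues too); when given, SEQRES records are emitted so readers can
    recover which residues are unresolved.
    """
    keys = structure.present_keys()
    names = [structure.residue(c, n).name for c, n in keys]
    st = _as_gemmi([structure.coords(keys)], keys, names)
    lines = st.make_pdb_string().splitlines(keepends=True)
    header = []
    if seqres:
        for cid, res_names in seqres.items():
            for i in range(0, len(res_names), 13):
                chunk = res_names[i:i + 13]
                header.append(
                    f"SEQRES {i // 13 + 1:>3} {cid:>1} {len(res_names):>4}  "
                    + " ".join(f"{n:>3}" for n in chunk) + "\n")
    with open(path, "w") as fh:
        fh.writelines(header)
        fh.writelines(l for l in lines if l.startswith(("ATOM", "TER", "END", "MODEL")))


# ---------------------------------------------------------------------------
# geometry


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose_arrays(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Kabsch least-squares fit of ``mobile`` onto ``reference`` (N×3 each)."""
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise StructureError("coordinate arrays must both be N×3")
    if len(mobile) < 3:
        raise StructureError("superposition needs at least 3 points")
    rot, trans = _kabsch(mobile, reference)
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def superpose(mobile: Structure, reference: Structure,
              selection: Iterable[tuple[str, int]]) -> Superposition:
    """Least-squares rigid-body superposition over selected Cα atoms.

    The selection must be present in both structures; offenders are listed.
    """
    sel = sorted(set(selection))
    if not sel:
        raise StructureError("empty selection")
    missing = []
    for strict, st in (("mobile", mobile), ("reference", reference)):
        for key in sel:
            try:
                if not st.residue(*key).present:
                    missing.append((strict, key))
            except KeyError:
                missing.append((strict, key))
    if missing:
        raise StructureError(f"selection residues missing: {missing}")
    if len(sel) < 3:
        raise StructureError("fewer than 3 selected residues: under-determined")
    return superpose_arrays(mobile.coords(sel), reference.coords(sel))


def common_present(a: Structure, b: Structure) -> list[tuple[str, int]]:
    """Keys of residues present (with Cα) in both structures."""
    return sorted(set(a.present_keys()) & set(b.present_keys()))


def ca_distance(structure: Structure, a: tuple[str, int], b: tuple[str, int]) -> float:
    """Euclidean Cα–Cα distance in Å between two present residues."""
    ra, rb = structure.residue(*a), structure.residue(*b)
    if not (ra.present and rb.present):
        absent = [k for k, r in ((a, ra), (b, rb)) if not r.present]
        raise StructureError(f"unmappable residue(s): {absent}")
    return float(np.linalg.norm(ra.ca - rb.ca))
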