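"""Parsing of protein-RNA complex structures and interface contact detection.

This module turns PDB-format text into light-weight chain objects, computes
solvent-accessible surface areas (ASA) on isolated chains with a
Shrake-Rupley sphere-sampling scheme, enumerates overlapping dinucleotide
sites along each RNA chain, and detects residue-dinucleotide contacts at a
strict 3.5 A atom-atom cutoff.

Conventions
-----------
* Only the first model of multi-model (NMR) files is used.
* Alternate locations collapse to the highest-occupancy conformer
  (ties broken by altloc label order).
* Selenomethionine (MSE) is read as methionine.
* Chains that are neither protein nor RNA (e.g. DNA) are excluded with a
  warning; a file without at least one protein and one RNA chain is
  rejected.
* Dinucleotide sites are overlapping with step 1; a pair of nucleotides
  forms a valid site only when the chain is continuous there (O3'-P
  distance < 2 A, or consecutive author residue numbers).
* Contacts use *all* atoms present in the file (hydrogens included when
  present); ASA uses heavy atoms only.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .alphabets import (
    CONTACT_CUTOFF,
    DINUC_INDEX,
    DINUCLEOTIDES,
    DNA_RESNAMES,
    N_DINUC,
    PROBE_RADIUS,
    PROTEIN_RESNAMES,
    RNA_RESNAMES,
    SOLVENT_RESNAMES,
    THREE_TO_ONE,
    VDW_RADII,
)

__all__ = [
    "Atom",
    "Residue",
    "ProteinChain",
    "RNAChain",
    "ComplexStructure",
    "DinucleotideSite",
    "ContactRecord",
    "ContactProfile",
    "PDBFormatError",
    "NotProteinRNAComplexError",
    "parse_complex",
    "compute_asa",
    "ensure_asa",
    "enumerate_dinucleotide_sites",
    "residue_site_contacts",
    "detect_contacts",
    "write_contact_profile_tsv",
]


class PDBFormatError(ValueError):
    """Raised when PDB text cannot be parsed."""


class NotProteinRNAComplexError(ValueError):
    """Raised when a structure lacks a protein chain or an RNA chain."""


class Atom(NamedTuple):
    name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class Residue:
    """One residue or nucleotide: name, 0-based chain position, atoms.

    ``auth_seq`` keeps the author residue number from the file for
    reporting and for the chain-continuity check.
    """

    name: str
    seq_index: int
    atoms: list[Atom]
    auth_seq: int

    def coords(self) -> np.ndarray:
        return np.array([(a.x, a.y, a.z) for a in self.atoms], dtype=float)


@dataclass
class ProteinChain:
    chain_id: str
    residues: list[Residue]
    asa: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)


@dataclass
class RNAChain:
    chain_id: str
    nucleotides: list[Residue]
    asa: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def sequence(self) -> str:
        return "".join(r.name for r in self.nucleotides)


@dataclass
class ComplexStructure:
    id: str
    protein_chains: list[ProteinChain]
    rna_chains: list[RNAChain]


@dataclass(frozen=True)
class DinucleotideSite:
    """Two consecutive nucleotides 5'->3'; ``start_index`` is the 5' one."""

    chain_id: str
    start_index: int
    klass: str
    asa: float


class ContactRecord(NamedTuple):
    """One contacting (protein residue, dinucleotide site) pair."""

    protein_chain: str
    residue_index: int
    resname: str  # 3-letter
    rna_chain: str
    site_start: int
    klass: str


@dataclass
class ContactProfile:
    """Per-residue 16-long binary target vector for one protein chain."""

    protein_id: str
    matrix: np.ndarray  # (n_residues, 16) of 0/1, columns AA..UU

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_DINUC:
            raise ValueError("contact profile must be n_residues x 16")


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

_RNA_NAME_MAP = {"RA": "A", "RC": "C", "RG": "G", "RU": "U"}


def _classify_resname(name: str) -> str:
    if name in PROTEIN_RESNAMES:
        return "protein"
    if name in RNA_RESNAMES:
        return "rna"
    if name in DNA_RESNAMES:
        return "dna"
    return "other"


def parse_complex(pdb_text: str, complex_id: str = "complex") -> ComplexStructure:
    """Parse PDB text into a :class:`ComplexStructure`.

    Chains are classified protein vs RNA by residue names (majority over
    polymer residues); DNA or otherwise unclassifiable chains are dropped
    with a warning.  Raises :class:`NotProteinRNAComplexError` when either
    a protein or an RNA chain is missing, and :class:`PDBFormatError` on
    unparseable input.
    """
    if not any(
        line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()
    ):
        raise PDBFormatError("no ATOM/HETATM records found")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(complex_id, io.StringIO(pdb_text))
    except PDBConstructionException as exc:  # names the offending record
        raise PDBFormatError(f"unparseable PDB record: {exc}") from exc
    models = list(structure)
    if not models:
        raise PDBFormatError("no coordinate model in file")
    model = models[0]  # first (NMR) model only

    protein_chains: list[ProteinChain] = []
    rna_chains: list[RNAChain] = []
    seen_ids: set[str] = set()
    for chain in model:
        cid = chain.id
        votes = {"protein": 0, "rna": 0, "dna": 0, "other": 0}
        polymer = []
        for res in chain:
            name = res.get_resname().strip()
            if name in SOLVENT_RESNAMES:
                continue
            kind = _classify_resname(name)
            votes[kind] += 1
            polymer.append((name, kind, res))
        if not polymer:
            continue
        kind = max(("protein", "rna", "dna", "other"), key=lambda k: votes[k])
        if kind in ("dna", "other"):
            warnings.warn(
                f"chain {cid!r} excluded: not a protein or RNA chain "
                f"(residues look like {kind})",
                stacklevel=2,
            )
            continue
        if cid in seen_ids:
            raise PDBFormatError(f"duplicate chain id {cid!r} in first model")
        seen_ids.add(cid)

        residues: list[Residue] = []
        for name, res_kind, res in polymer:
            if res_kind != kind:
                warnings.warn(
                    f"residue {name} {res.id[1]} in chain {cid!r} does not "
                    f"match chain type {kind}; dropped",
                    stacklevel=2,
                )
                continue
            if name == "MSE":
                name = "MET"
            name = _RNA_NAME_MAP.get(name, name)
            atoms = []
            for atom in res:  # DisorderedAtom -> highest-occupancy child
                element = (atom.element or "").strip().upper()
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(Atom(atom.get_name(), element, x, y, z))
            residues.append(
                Residue(name=name, seq_index=len(residues), atoms=atoms,
                        auth_seq=int(res.id[1]))
            )
        if not residues:
            continue
        if kind == "protein":
            protein_chains.append(ProteinChain(chain_id=cid, residues=residues))
        else:
            rna_chains.append(RNAChain(chain_id=cid, nucleotides=residues))

    if not protein_chains or not rna_chains:
        raise NotProteinRNAComplexError(
            f"{complex_id}: not a protein-RNA complex "
            f"({len(protein_chains)} protein, {len(rna_chains)} RNA chains)"
        )
    return ComplexStructure(id=complex_id, protein_chains=protein_chains,
                            rna_chains=rna_chains)


# ---------------------------------------------------------------------------
# Accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into a principal-axes frame.

    Sphere-point sampling is direction-dependent; evaluating it in a frame
    derived from the coordinates themselves makes the resulting areas
    invariant under rigid motion of the chain.  Axis signs follow the sign
    of the third moment of the projections so the frame is equivariant.
    """
    c = coords - coords.mean(axis=0)
    if len(c) < 2:
        return c
    w, v = np.linalg.eigh(c.T @ c)
    v = v[:, ::-1]  # descending variance
    skew = np.einsum("ij,ij,ij->j", c @ v, c @ v, c @ v)
    flip = np.where(skew < 0, -1.0, 1.0)
    v = v * flip
    if np.linalg.det(v) < 0:
        k = int(np.argmin(np.abs(skew)))
        v[:, k] = -v[:, k]
    return c @ v


def compute_asa(
    chain: ProteinChain | RNAChain,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-residue/nucleotide absolute ASA (A^2) of an isolated chain.

    Heavy atoms only; each atom's exposed fraction of ``n_sphere_points``
    test points on its solvent-extended sphere is converted to area.
    Raises ``ValueError`` for an element with no tabulated radius.
    """
    units = chain.residues if isinstance(chain, ProteinChain) else chain.nucleotides
    atom_coords: list[tuple[float, float, float]] = []
    atom_radii: list[float] = []
    atom_unit: list[int] = []
    for ui, res in enumerate(units):
        for atom in res.atoms:
            if atom.element in ("H", "D"):
                continue
            try:
                r = VDW_RADII[atom.element]
            except KeyError:
                raise ValueError(
                    f"no van der Waals radius for atom {atom.name!r} "
                    f"(element {atom.element!r}) in {res.name} {res.auth_seq}"
                ) from None
            atom_coords.append((atom.x, atom.y, atom.z))
            atom_radii.append(r)
            atom_unit.append(ui)

    asa = np.zeros(len(units), dtype=float)
    if not atom_coords:
        return asa
    coords = _canonical_frame(np.asarray(atom_coords, dtype=float))
    radii = np.asarray(atom_radii, dtype=float)
    points = _sphere_points(n_sphere_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    reach = 2.0 * ext.max()
    for i in range(len(coords)):
        neighbours = [j for j in tree.query_ball_point(coords[i], reach)
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        surface = coords[i] + ext[i] * points
        exposed = np.ones(len(points), dtype=bool)
        for j in neighbours:
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            exposed &= d2 >= ext[j] ** 2
        frac = float(np.count_nonzero(exposed)) / len(points)
        asa[atom_unit[i]] += frac * 4.0 * np.pi * ext[i] ** 2
    return asa


def ensure_asa(chain: ProteinChain | RNAChain) -> np.ndarray:
    """Compute and cache ASA on the chain if not already present."""
    if chain.asa is None:
        chain.asa = compute_asa(chain)
    return chain.asa


def compute_complex_asa(complex: ComplexStructure) -> None:
    """Fill the per-chain ASA caches for every chain (isolated-chain ASA)."""
    for ch in complex.protein_chains:
        ensure_asa(ch)
    for ch in complex.rna_chains:
        ensure_asa(ch)


# ---------------------------------------------------------------------------
# Dinucleotide sites
# ---------------------------------------------------------------------------

def _atom_by_name(res: Residue, name: str) -> Atom | None:
    name = name.replace("*", "'")
    for atom in res.atoms:
        if atom.name.replace("*", "'") == name:
            return atom
    return None


def _is_continuous(nt5: Residue, nt3: Residue, max_link: float = 2.0) -> bool:
    """Chain continuity between consecutive nucleotides.

    True when the O3'(5' nt) - P(3' nt) distance is below ``max_link`` A,
    or, lacking those atoms, when author residue numbers are consecutive.
    """
    o3 = _atom_by_name(nt5, "O3'")
    p = _atom_by_name(nt3, "P")
    if o3 is not None and p is not None:
        d = np.hypot(np.hypot(o3.x - p.x, o3.y - p.y), o3.z - p.z)
        if d < max_link:
            return True
    return nt3.auth_seq == nt5.auth_seq + 1


def enumerate_dinucleotide_sites(rna: RNAChain) -> list[DinucleotideSite]:
    """Overlapping (step-1) dinucleotide sites of an RNA chain, 5'->3'.

    Pairs spanning a chain break are skipped.  Site ASA is the sum of the
    two nucleotides' ASA when the chain ASA has been computed, else 0.
    """
    sites: list[DinucleotideSite] = []
    asa = rna.asa if rna.asa is not None else np.zeros(len(rna))
    for i in range(len(rna.nucleotides) - 1):
        nt5, nt3 = rna.nucleotides[i], rna.nucleotides[i + 1]
        if nt5.name + nt3.name not in DINUC_INDEX:
            continue
        if not _is_continuous(nt5, nt3):
            continue
        sites.append(
            DinucleotideSite(
                chain_id=rna.chain_id,
                start_index=i,
                klass=nt5.name + nt3.name,
                asa=float(asa[i] + asa[i + 1]),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _chain_atom_arrays(units: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    coords, owner = [], []
    for res in units:
        for atom in res.atoms:
            coords.append((atom.x, atom.y, atom.z))
            owner.append(res.seq_index)
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def residue_site_contacts(
    complex: ComplexStructure, cutoff: float = CONTACT_CUTOFF
) -> list[ContactRecord]:
    """All contacting (residue, dinucleotide-site) pairs in the complex.

    A pair contacts when any protein-residue atom is strictly closer than
    ``cutoff`` to any atom of either nucleotide of the site.
    """
    records: list[ContactRecord] = []
    for rna in complex.rna_chains:
        sites = enumerate_dinucleotide_sites(rna)
        if not sites:
            continue
        nt_sites: dict[int, list[DinucleotideSite]] = {}
        for s in sites:
            nt_sites.setdefault(s.start_index, []).append(s)
            nt_sites.setdefault(s.start_index + 1, []).append(s)
        rcoords, rowner = _chain_atom_arrays(rna.nucleotides)
        rtree = cKDTree(rcoords)
        for prot in complex.protein_chains:
            pcoords, powner = _chain_atom_arrays(prot.residues)
            pairs = cKDTree(pcoords).query_ball_tree(rtree, r=cutoff)
            touched: set[tuple[int, int]] = set()
            for pi, rlist in enumerate(pairs):
                for ri in rlist:
                    # strict '<' at the cutoff
                    if np.linalg.norm(pcoords[pi] - rcoords[ri]) < cutoff:
                        touched.add((int(powner[pi]), int(rowner[ri])))
            seen: set[tuple[int, int]] = set()
            for res_idx, nt_idx in sorted(touched):
                for site in nt_sites.get(nt_idx, ()):
                    key = (res_idx, site.start_index)
                    if key in seen:
                        continue
                    seen.add(key)
                    records.append(
                        ContactRecord(
                            protein_chain=prot.chain_id,
                            residue_index=res_idx,
                            resname=prot.residues[res_idx].name,
                            rna_chain=rna.chain_id,
                            site_start=site.start_index,
                            klass=site.klass,
                        )
                    )
    return records


def detect_contacts(
    complex: ComplexStructure, cutoff: float = CONTACT_CUTOFF
) -> dict[str, ContactProfile]:
    """Binary residue x 16 contact profile for every protein chain.

    Entry (i, c) is 1 iff residue i contacts at least one site of class c
    on any RNA chain of the complex.
    """
    records = residue_site_contacts(complex, cutoff=cutoff)
    profiles: dict[str, ContactProfile] = {}
    for prot in complex.protein_chains:
        profiles[prot.chain_id] = ContactProfile(
            protein_id=f"{complex.id}_{prot.chain_id}",
            matrix=np.zeros((len(prot), N_DINUC), dtype=np.int8),
        )
    for rec in records:
        profiles[rec.protein_chain].matrix[
            rec.residue_index, DINUC_INDEX[rec.klass]
        ] = 1
    return profiles


def write_contact_profile_tsv(
    path, complex_id: str, chain: ProteinChain, profile: ContactProfile
) -> None:
    """Write a contact profile as TSV (header comment names column order)."""
    with open(path, "w") as fh:
        fh.write("# dinucleotide column order: " + " ".join(DINUCLEOTIDES) + "\n")
        fh.write(
            "protein_id\tchain\tresidue_index\tresname\t"
            + "\t".join(DINUCLEOTIDES)
            + "\n"
        )
        for res in chain.residues:
            row = profile.matrix[res.seq_index]
            fh.write(
                f"{complex_id}\t{chain.chain_id}\t{res.seq_index}\t{res.name}\t"
                + "\t".join(str(int(v)) for v in row)
                + "\n"
            )
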