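"""Seeded synthetic protein-RNA complexes for offline testing.

Real interface statistics and training need curated PDB complexes plus
externally computed PSSMs; this module generates small, fully valid
stand-ins with *known* ground truth: PDB text with a pseudo-backbone
protein chain and a continuous RNA chain, blastpgp-layout PSSM files, and
contact profiles recorded from the same geometry that produced the file.

Geometry is deliberately schematic (three pseudo-atoms per residue, four
per nucleotide, chains laid out along parallel axes): it is sufficient
for every distance, surface-area and chain-continuity rule in the
pipeline, while remaining cheap and reproducible.  Contacts are created
by pulling a residue's side-chain pseudo-atom to a configured distance
(default 3.2 A, inside the 3.5 A cutoff) from the C1' atom of a chosen
nucleotide.

Two contact mechanisms are available:

* stochastic planting — every residue contacts a uniformly chosen site
  with probability ``background_contact_rate``; residues named in
  ``planted_pairs`` additionally contact a site of the planted class with
  probability min(0.95, background_contact_rate * enrichment_odds), so
  odds of 1 reduce to background and large odds make the planted
  (residue, dinucleotide) cell strongly enriched;
* ``identity_rule`` — a deterministic map residue-letter -> dinucleotide
  class; rule residues always contact a site of their class and all other
  residues never contact, giving a noise-free, learnable target for
  end-to-end cross-validation tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .alphabets import (
    AMINO_ACIDS,
    DINUC_INDEX,
    N_DINUC,
    ONE_TO_THREE,
    RNA_BASES,
)
from .structure_io import ContactProfile

__all__ = [
    "SimConfig",
    "SimulatedComplex",
    "make_complex",
    "make_pssm",
    "make_dataset",
]

#: PSI-BLAST's native column order, used when writing PSSM files so the
#: reader's remapping to the package alphabet is exercised.
BLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

_FUNCTIONAL_CYCLE = ("viral", "mRNA", "tRNA", "rRNA")

# layout constants (Angstrom)
_NT_SPACING = 6.0
_PROT_Y = 25.0


@dataclass
class SimConfig:
    """Generator settings; defaults give sparse, mostly background contacts."""

    n_complexes: int = 10
    protein_length: tuple[int, int] = (25, 35)
    rna_length: tuple[int, int] = (14, 20)
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    contact_distance: float = 3.2
    background_contact_rate: float = 0.05
    identity_rule: dict[str, str] | None = None
    pssm_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length[0] < 5:
            raise ValueError("protein length must be >= 5")
        if self.rna_length[0] < 3:
            raise ValueError("RNA length must be >= 3")
        if not self.contact_distance < 3.5:
            raise ValueError("contact placement distance must be < 3.5 A")
        for aa, dinuc, odds in self.planted_pairs:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown amino acid {aa!r} in planted pair")
            if dinuc not in DINUC_INDEX:
                raise ValueError(f"unknown dinucleotide {dinuc!r} in planted pair")
            if odds < 1:
                raise ValueError("enrichment odds must be >= 1")
        if self.identity_rule:
            for aa, dinuc in self.identity_rule.items():
                if aa not in AMINO_ACIDS or dinuc not in DINUC_INDEX:
                    raise ValueError(f"bad identity rule entry {aa!r} -> {dinuc!r}")


@dataclass
class SimulatedComplex:
    complex_id: str
    pdb_text: str
    profile: ContactProfile  # ground truth for the (single) protein chain
    protein_sequence: str
    rna_sequence: str


def _complex_rng(config: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index]))


def _sample_rna_sequence(
    rng: np.random.Generator,
    length: int,
    must_contain: list[str],
    triplet_context: bool = False,
) -> tuple[str, dict[str, int]]:
    """Random RNA sequence with required dinucleotides embedded.

    Returns the sequence and the 5' position of each embedded class.
    With ``triplet_context`` (identity-rule datasets) class b1b2 is
    embedded as the triplet b2-b1-b2, so the class of the *other* site
    overlapping the embedded 5' nucleotide is also a pure function of
    the class — keeping rule-generated contact labels deterministic.
    """
    seq = list(rng.choice(list(RNA_BASES), size=length))
    positions: dict[str, int] = {}
    unique = list(dict.fromkeys(must_contain))
    if triplet_context:
        slots = list(range(1, length - 1, 3))
        if len(slots) < len(unique):
            raise ValueError(
                f"RNA length {length} too short to embed {len(unique)} "
                "dinucleotide classes in triplet context"
            )
        rng.shuffle(slots)
        for dinuc, pos in zip(unique, slots):
            seq[pos - 1], seq[pos], seq[pos + 1] = dinuc[1], dinuc[0], dinuc[1]
            positions[dinuc] = pos
    else:
        slots = list(range(0, length - 1, 2))
        rng.shuffle(slots)
        for dinuc, pos in zip(unique, slots):
            seq[pos], seq[pos + 1] = dinuc[0], dinuc[1]
            positions[dinuc] = pos
    return "".join(seq), positions


def _site_classes(rna_seq: str) -> list[str]:
    return [rna_seq[i : i + 2] for i in range(len(rna_seq) - 1)]


def _choose_contacts(
    config: SimConfig,
    rng: np.random.Generator,
    protein_seq: str,
    rna_seq: str,
    embedded: dict[str, int],
) -> dict[int, int]:
    """Map residue index -> 5' nucleotide index of the contacted site."""
    classes = _site_classes(rna_seq)
    by_class: dict[str, list[int]] = {}
    for i, k in enumerate(classes):
        by_class.setdefault(k, []).append(i)
    planted_by_aa: dict[str, list[tuple[str, float]]] = {}
    for aa, dinuc, odds in config.planted_pairs:
        planted_by_aa.setdefault(aa, []).append((dinuc, odds))

    contacts: dict[int, int] = {}
    for r, aa in enumerate(protein_seq):
        wanted: list[int] = []
        if config.identity_rule is not None:
            dinuc = config.identity_rule.get(aa)
            if dinuc and dinuc in embedded:
                wanted.append(embedded[dinuc])
        else:
            for dinuc, odds in planted_by_aa.get(aa, ()):
                p = min(0.95, config.background_contact_rate * odds)
                if by_class.get(dinuc) and rng.random() < p:
                    wanted.append(int(rng.choice(by_class[dinuc])))
            if classes and rng.random() < config.background_contact_rate:
                wanted.append(int(rng.integers(len(classes))))
        if wanted:
            contacts[r] = wanted[int(rng.integers(len(wanted)))]
    return contacts


def _build_coordinates(
    config: SimConfig,
    rng: np.random.Generator,
    protein_seq: str,
    rna_seq: str,
    contacts: dict[int, int],
):
    """Atom coordinates for both chains; contacts realised geometrically."""
    rna_atoms = []  # (nt_index, atom_name, element, xyz)
    for i in range(len(rna_seq)):
        x = _NT_SPACING * i
        rna_atoms += [
            (i, "P", "P", np.array([x, 0.0, 0.0])),
            (i, "C1'", "C", np.array([x + 1.5, 0.8, 0.0])),
            (i, "N1", "N", np.array([x + 3.0, 1.6, 0.0])),
            (i, "O3'", "O", np.array([x + 4.8, 0.2, 0.0])),
        ]

    prot_atoms = []  # (res_index, atom_name, element, xyz)
    for r in range(len(protein_seq)):
        if r in contacts:
            k = contacts[r]
            c1 = np.array([_NT_SPACING * k + 1.5, 0.8, 0.0])
            # direction mostly +y with a small seeded tilt, length = contact distance
            tilt = rng.uniform(-0.15, 0.15, size=2)
            direction = np.array([tilt[0], 1.0, tilt[1]])
            direction /= np.linalg.norm(direction)
            cg = c1 + config.contact_distance * direction
            cb = cg + np.array([0.0, 1.8, 0.3])
            ca = cg + np.array([0.0, 3.6, 0.6])
        else:
            x = 4.0 * r
            jitter = rng.uniform(-0.3, 0.3, size=3)
            ca = np.array([x, _PROT_Y, 0.0]) + jitter
            cb = ca + np.array([0.0, 1.5, 0.5])
            cg = ca + np.array([0.0, 3.0, 1.0])
        prot_atoms += [
            (r, "CA", "C", ca),
            (r, "CB", "C", cb),
            (r, "CG", "C", cg),
        ]
    return prot_atoms, rna_atoms


def _ground_truth_profile(
    complex_id: str, protein_seq: str, rna_seq: str, prot_atoms, rna_atoms
) -> ContactProfile:
    """Brute-force all-atom-pair recount of the generated geometry."""
    matrix = np.zeros((len(protein_seq), N_DINUC), dtype=np.int8)
    pcoords = np.array([a[3] for a in prot_atoms])
    rcoords = np.array([a[3] for a in rna_atoms])
    powner = np.array([a[0] for a in prot_atoms])
    rowner = np.array([a[0] for a in rna_atoms])
    d = np.linalg.norm(pcoords[:, None, :] - rcoords[None, :, :], axis=2)
    close = d < 3.5
    classes = _site_classes(rna_seq)
    for pi, ri in zip(*np.nonzero(close)):
        r, nt = int(powner[pi]), int(rowner[ri])
        for start in (nt - 1, nt):
            if 0 <= start < len(classes):
                matrix[r, DINUC_INDEX[classes[start]]] = 1
    return ContactProfile(protein_id=f"{complex_id}_A", matrix=matrix)


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz: np.ndarray, element: str) -> str:
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded:4s} {resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def _render_pdb(protein_seq: str, rna_seq: str, prot_atoms, rna_atoms) -> str:
    lines: list[str] = []
    serial = 1
    for r, name, element, xyz in prot_atoms:
        resname = ONE_TO_THREE[protein_seq[r]]
        lines.append(_pdb_atom_line(serial, name, resname, "A", r + 1, xyz, element))
        serial += 1
    lines.append("TER")
    for i, name, element, xyz in rna_atoms:
        lines.append(_pdb_atom_line(serial, name, rna_seq[i], "B", i + 1, xyz, element))
        serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_complex(config: SimConfig, index: int) -> SimulatedComplex:
    """Generate one complex (PDB text + geometry-derived ground truth).

    Reproducible per (config.seed, index): the same pair always yields
    byte-identical PDB text.
    """
    rng = _complex_rng(config, index)
    n = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
    m = int(rng.integers(config.rna_length[0], config.rna_length[1] + 1))
    protein_seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    needed = [d for _, d, _ in config.planted_pairs]
    if config.identity_rule:
        needed += list(config.identity_rule.values())
    rna_seq, embedded = _sample_rna_sequence(
        rng, m, needed, triplet_context=config.identity_rule is not None
    )
    contacts = _choose_contacts(config, rng, protein_seq, rna_seq, embedded)
    prot_atoms, rna_atoms = _build_coordinates(config, rng, protein_seq,
                                               rna_seq, contacts)
    complex_id = f"sim{index:03d}"
    profile = _ground_truth_profile(complex_id, protein_seq, rna_seq,
                                    prot_atoms, rna_atoms)
    pdb_text = _render_pdb(protein_seq, rna_seq, prot_atoms, rna_atoms)
    return SimulatedComplex(
        complex_id=complex_id,
        pdb_text=pdb_text,
        profile=profile,
        protein_sequence=protein_seq,
        rna_sequence=rna_seq,
    )


def make_pssm(
    sequence: str,
    signal_rule: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    identity_signal: float = 4.0,
) -> str:
    """blastpgp-layout ASCII PSSM text with a planted signal.

    Every row carries ``identity_signal`` on its own residue's column
    (mimicking the self-conservation of real profiles) plus integer
    Gaussian noise; ``signal_rule`` adds extra values per residue letter,
    e.g. ``{"R": {"R": 5}}``.  The output parses with ``read_pssm``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    scores = np.rint(rng.normal(0.0, noise_sd, size=(L, 20))).astype(int)
    col = {a: j for j, a in enumerate(BLAST_COLUMN_ORDER)}
    for i, aa in enumerate(sequence):
        scores[i, col[aa]] += int(identity_signal)
        for target, value in (signal_rule or {}).get(aa, {}).items():
            scores[i, col[target]] += int(value)
    header = "  ".join(BLAST_COLUMN_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {header}   {header}",
    ]
    for i, aa in enumerate(sequence):
        nums = "".join(f"{v:4d}" for v in scores[i])
        pcts = "".join(f"{v:4d}" for v in np.zeros(20, dtype=int))
        lines.append(f"{i + 1:5d} {aa}  {nums} {pcts}  0.00 0.00")
    lines += ["", "                      K         Lambda",
              "Standard Ungapped    0.1337     0.3176", ""]
    return "\n".join(lines)


def make_dataset(config: SimConfig, out_dir: str) -> str:
    """Write a full synthetic dataset directory; returns the manifest path.

    One PDB, FASTA and PSSM file per complex plus a ``manifest.tsv``
    (complex id, functional class cycling viral->mRNA->tRNA->rRNA, file
    paths).  Byte-identical for identical configs.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for index in range(config.n_complexes):
        sim = make_complex(config, index)
        pdb_path = os.path.join(out_dir, f"{sim.complex_id}.pdb")
        fasta_path = os.path.join(out_dir, f"{sim.complex_id}.fasta")
        pssm_path = os.path.join(out_dir, f"{sim.complex_id}.pssm")
        with open(pdb_path, "w") as fh:
            fh.write(sim.pdb_text)
        with open(fasta_path, "w") as fh:
            fh.write(f">{sim.complex_id}_A\n{sim.protein_sequence}\n")
        pssm_seed = int(
            np.random.SeedSequence([config.seed, index, 1]).generate_state(1)[0]
            % (2**31)
        )
        with open(pssm_path, "w") as fh:
            fh.write(make_pssm(sim.protein_sequence, noise_sd=config.pssm_noise_sd,
                               seed=pssm_seed))
        rows.append(
            (sim.complex_id, _FUNCTIONAL_CYCLE[index % 4],
             os.path.basename(pdb_path), os.path.basename(fasta_path),
             os.path.basename(pssm_path))
        )
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("complex_id\tclass_label\tpdb\tfasta\tpssm\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return manifest
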