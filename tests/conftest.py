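"""Shared fixtures: hand-built PDB texts with known geometry."""


import pytest


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              element, occ=1.00, altloc=" "):
    """Independent PDB ATOM-record formatter for hand-built fixtures."""
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded:4s}{altloc}{resname:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
        f"{element:>2s}"
    )


def rna_nucleotide_lines(start_serial, base, chain, resseq, x0):
    """Four-atom nucleotide at x offset x0 (P, C1', N1, O3')."""
    return [
        atom_line(start_serial, "P", base, chain, resseq, x0, 0.0, 0.0, "P"),
        atom_line(start_serial + 1, "C1'", base, chain, resseq, x0 + 1.5, 0.8, 0.0, "C"),
        atom_line(start_serial + 2, "N1", base, chain, resseq, x0 + 3.0, 1.6, 0.0, "N"),
        atom_line(start_serial + 3, "O3'", base, chain, resseq, x0 + 4.8, 0.2, 0.0, "O"),
    ]


@pytest.fixture
def tiny_complex_pdb():
    """3-residue protein + 4-nt RNA (ACGU) with known contact geometry.

    * ARG 1 (CA 3.0 A from N1 of nt 0)  -> contacts only the AC site.
    * LYS 2 (CA exactly 3.5 A from N1 of nt 2, its nearest atom)
      -> no contact (strict <).
    * ALA 3 (CA 2.7 A from N1 of middle nt 1) -> AC and CG sites.
    """
    lines = [
        atom_line(1, "CA", "ARG", "A", 1, 1.5, 4.2, 0.0, "C"),
        atom_line(2, "CA", "LYS", "A", 2, 15.0, 1.6, 3.5, "C"),
        atom_line(3, "CA", "ALA", "A", 3, 7.5, 3.8, 0.0, "C"),
        "TER",
    ]
    serial = 4
    for i, base in enumerate("ACGU"):
        lines += rna_nucleotide_lines(serial, base, "B", i + 1, 6.0 * i)
        serial += 4
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


@pytest.fixture
def broken_rna_pdb():
    """4-nt RNA with a gap between nt 3 and nt 4 (far apart, numbering gap)."""
    lines = [atom_line(1, "CA", "GLY", "A", 1, 0.0, 25.0, 0.0, "C"), "TER"]
    serial = 2
    for i, (base, resseq, x0) in enumerate(
        [("A", 1, 0.0), ("C", 2, 6.0), ("G", 3, 12.0), ("U", 5, 40.0)]
    ):
        lines += rna_nucleotide_lines(serial, base, "B", resseq, x0)
        serial += 4
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


@pytest.fixture
def dna_chain_pdb(tiny_complex_pdb):
    """tiny complex plus a DT chain that must be excluded with a warning."""
    extra = [
        atom_line(90, "C1'", "DT", "C", 1, 60.0, 60.0, 0.0, "C"),
        atom_line(91, "N1", "DT", "C", 1, 61.0, 60.0, 0.0, "N"),
    ]
    return tiny_complex_pdb.replace("END", "\n".join(extra) + "\nEND")
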