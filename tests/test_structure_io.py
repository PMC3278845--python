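"""Structure parsing, ASA, dinucleotide sites and contact detection."""

import math

import numpy as np
import pytest

from dinucpred.alphabets import DINUC_INDEX, DINUCLEOTIDES
from dinucpred.simgen import SimConfig, make_complex
from dinucpred.structure_io import (
    Atom,
    NotProteinRNAComplexError,
    PDBFormatError,
    ProteinChain,
    Residue,
    compute_asa,
    detect_contacts,
    enumerate_dinucleotide_sites,
    parse_complex,
    residue_site_contacts,
)

from conftest import atom_line, rna_nucleotide_lines


class TestParseComplex:
    def test_parses_protein_and_rna_chains(self, tiny_complex_pdb):
        cplx = parse_complex(tiny_complex_pdb, "tiny")
        assert len(cplx.protein_chains) == 1
        assert len(cplx.rna_chains) == 1
        assert cplx.protein_chains[0].sequence == "RKA"
        assert cplx.rna_chains[0].sequence == "ACGU"
        assert [r.seq_index for r in cplx.protein_chains[0].residues] == [0, 1, 2]

    def test_dna_chain_excluded_with_warning(self, dna_chain_pdb):
        with pytest.warns(UserWarning, match="excluded"):
            cplx = parse_complex(dna_chain_pdb, "dna")
        assert {c.chain_id for c in cplx.rna_chains} == {"B"}

    def test_empty_file_is_format_error(self):
        with pytest.raises(PDBFormatError):
            parse_complex("", "empty")

    def test_protein_only_rejected(self):
        text = atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C") + "\nEND\n"
        with pytest.raises(NotProteinRNAComplexError):
            parse_complex(text, "protonly")

    def test_mse_maps_to_met(self, tiny_complex_pdb):
        text = tiny_complex_pdb.replace(
            atom_line(1, "CA", "ARG", "A", 1, 1.5, 4.2, 0.0, "C"),
            "HETATM" + atom_line(1, "CA", "MSE", "A", 1, 1.5, 4.2, 0.0, "C")[6:],
        )
        cplx = parse_complex(text, "mse")
        assert cplx.protein_chains[0].residues[0].name == "MET"

    def test_altloc_keeps_highest_occupancy(self):
        lines = [
            atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C", occ=0.4, altloc="A"),
            atom_line(2, "CA", "GLY", "A", 1, 9.0, 0.0, 0.0, "C", occ=0.6, altloc="B"),
            "TER",
        ]
        serial = 3
        for i, base in enumerate("AC"):
            lines += rna_nucleotide_lines(serial, base, "B", i + 1, 6.0 * i)
            serial += 4
        cplx = parse_complex("\n".join(lines + ["TER", "END"]) + "\n", "alt")
        res = cplx.protein_chains[0].residues[0]
        assert len(res.atoms) == 1
        assert res.atoms[0].x == pytest.approx(9.0)


class TestComputeASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        chain = ProteinChain("A", [Residue("GLY", 0, [Atom("CA", "C", 0, 0, 0)], 1)])
        expected = 4 * math.pi * (1.87 + 1.4) ** 2
        assert compute_asa(chain)[0] == pytest.approx(expected, rel=5e-3)

    def test_enclosed_atom_is_fully_buried(self):
        import itertools

        shell = [
            Atom("CA", "C", *(2.0 * np.array(d)))
            for d in itertools.product([-1, 0, 1], repeat=3)
            if d != (0, 0, 0)
        ]
        chain = ProteinChain(
            "A",
            [Residue("GLY", 0, [Atom("CA", "C", 0, 0, 0)], 1),
             Residue("GLY", 1, shell, 2)],
        )
        assert compute_asa(chain)[0] == 0.0

    def test_two_atoms_match_monte_carlo_oracle(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        chain = ProteinChain(
            "A",
            [Residue("GLY", i, [Atom("CA", "C", *c)], i + 1)
             for i, c in enumerate(coords)],
        )
        sr = compute_asa(chain)
        rng = np.random.default_rng(7)
        r = 1.87 + 1.4
        for i, other in ((0, coords[1]), (1, coords[0])):
            v = rng.normal(size=(10**6, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = coords[i] + r * v
            frac = np.mean(np.linalg.norm(pts - other, axis=1) >= r)
            assert sr[i] == pytest.approx(frac * 4 * math.pi * r**2, rel=0.02)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        coords = rng.uniform(-4, 4, size=(10, 3))

        def chain_of(c):
            return ProteinChain(
                "A",
                [Residue("GLY", i, [Atom("CA", "C", *p)], i + 1)
                 for i, p in enumerate(c)],
            )

        base = compute_asa(chain_of(coords))
        rot = Rotation.from_rotvec([0.9, -0.4, 1.7]).as_matrix()
        moved = compute_asa(chain_of(coords @ rot.T + np.array([12.0, -5.0, 3.0])))
        np.testing.assert_allclose(moved, base, rtol=1e-6)

    def test_unknown_element_raises(self):
        chain = ProteinChain("A", [Residue("GLY", 0, [Atom("XX", "ZZ", 0, 0, 0)], 1)])
        with pytest.raises(ValueError, match="XX"):
            compute_asa(chain)


class TestDinucleotideSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGU", ["AC", "CG", "GU"]), ("AAAA", ["AA", "AA", "AA"]), ("A", [])],
    )
    def test_enumeration_matches_definition(self, seq, expected):
        lines = [atom_line(1, "CA", "GLY", "A", 1, 0.0, 25.0, 0.0, "C"), "TER"]
        serial = 2
        for i, base in enumerate(seq):
            lines += rna_nucleotide_lines(serial, base, "B", i + 1, 6.0 * i)
            serial += 4
        cplx = parse_complex("\n".join(lines + ["TER", "END"]) + "\n", "enum")
        sites = enumerate_dinucleotide_sites(cplx.rna_chains[0])
        assert [s.klass for s in sites] == expected
        if len(seq) >= 2:
            assert len(sites) == len(seq) - 1

    def test_chain_break_skips_site(self, broken_rna_pdb):
        cplx = parse_complex(broken_rna_pdb, "broken")
        sites = enumerate_dinucleotide_sites(cplx.rna_chains[0])
        assert [s.klass for s in sites] == ["AC", "CG"]  # GU spans the gap

    def test_site_asa_is_sum_of_nucleotides(self, tiny_complex_pdb):
        cplx = parse_complex(tiny_complex_pdb, "tiny")
        rna = cplx.rna_chains[0]
        asa = compute_asa(rna)
        rna.asa = asa
        for site in enumerate_dinucleotide_sites(rna):
            assert site.asa == pytest.approx(
                asa[site.start_index] + asa[site.start_index + 1]
            )


def brute_force_profile(cplx, cutoff=3.5):
    """Independent all-atom-pairs contact scan (oracle)."""
    out = {}
    for prot in cplx.protein_chains:
        matrix = np.zeros((len(prot), 16), dtype=int)
        for rna in cplx.rna_chains:
            sites = enumerate_dinucleotide_sites(rna)
            for res in prot.residues:
                pc = res.coords()
                for site in sites:
                    atoms = (rna.nucleotides[site.start_index].atoms
                             + rna.nucleotides[site.start_index + 1].atoms)
                    rc = np.array([(a.x, a.y, a.z) for a in atoms])
                    d = np.linalg.norm(pc[:, None] - rc[None], axis=2)
                    if (d < cutoff).any():
                        matrix[res.seq_index, DINUC_INDEX[site.klass]] = 1
        out[prot.chain_id] = matrix
    return out


class TestDetectContacts:
    def test_known_geometry(self, tiny_complex_pdb):
        cplx = parse_complex(tiny_complex_pdb, "tiny")
        profile = detect_contacts(cplx)["A"].matrix
        # ARG 1 touches nt 0 -> only the AC site
        assert profile[0, DINUC_INDEX["AC"]] == 1
        assert profile[0].sum() == 1
        # LYS 2 sits exactly at 3.5 A -> no contact (strict less-than)
        assert profile[1].sum() == 0
        # ALA 3 touches the middle nt -> both overlapping sites AC and CG
        assert profile[2, DINUC_INDEX["AC"]] == 1
        assert profile[2, DINUC_INDEX["CG"]] == 1
        assert profile[2].sum() == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_simulated_complexes(self, seed):
        cfg = SimConfig(seed=seed, n_complexes=1,
                        planted_pairs=[("K", "AA", 20.0)],
                        background_contact_rate=0.1)
        sim = make_complex(cfg, 0)
        cplx = parse_complex(sim.pdb_text, sim.complex_id)
        fast = detect_contacts(cplx)
        slow = brute_force_profile(cplx)
        for cid in fast:
            np.testing.assert_array_equal(fast[cid].matrix, slow[cid])

    def test_pair_records_agree_with_profile(self, tiny_complex_pdb):
        cplx = parse_complex(tiny_complex_pdb, "tiny")
        records = residue_site_contacts(cplx)
        profile = detect_contacts(cplx)["A"].matrix
        rebuilt = np.zeros_like(profile)
        for rec in records:
            rebuilt[rec.residue_index, DINUC_INDEX[rec.klass]] = 1
        np.testing.assert_array_equal(rebuilt, profile)

    def test_column_order_is_the_fixed_alphabet(self):
        assert list(DINUCLEOTIDES) == sorted(DINUCLEOTIDES)
        assert len(DINUC_INDEX) == 16
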