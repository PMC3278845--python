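"""Protein-RNA fragment-pair generation, features and the pair classifier.

Fixed-length windows slide (stride 1) over every protein and RNA chain of
a complex; every protein-fragment x RNA-fragment combination is a pair,
labelled 1 when any atom of the protein fragment lies strictly within
3.5 A of any atom of the RNA fragment.  A pair's feature vector
concatenates the predicted 16 dinucleotide scores of each residue in the
protein fragment with the 16-dimensional dinucleotide composition of the
RNA fragment (16*L + 16 values).  A single-output network, trained with
the same early-stopping/cross-validation machinery as the residue model
but with folds assigned per complex, separates paired from non-paired
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .alphabets import CONTACT_CUTOFF, DINUC_INDEX, N_DINUC
from .features import FeatureMatrix
from .model import CVResult, Hyper, PredictionMatrix, cross_validate
from .structure_io import ComplexStructure, ProteinChain, RNAChain

__all__ = [
    "FragmentPair",
    "generate_pairs",
    "pair_features",
    "build_pair_dataset",
    "train_pair_classifier",
]


@dataclass
class FragmentPair:
    """One (protein fragment, RNA fragment) combination with contact label."""

    protein_id: str
    prot_start: int
    prot_len: int
    rna_id: str
    rna_start: int
    rna_len: int
    label: int
    features: np.ndarray | None = None


def _residue_nt_contact_matrix(
    prot: ProteinChain, rna: RNAChain, cutoff: float
) -> np.ndarray:
    """Boolean (n_residues, n_nucleotides): any atom pair strictly < cutoff."""
    pc, po = [], []
    for res in prot.residues:
        for a in res.atoms:
            pc.append((a.x, a.y, a.z))
            po.append(res.seq_index)
    rc, ro = [], []
    for nt in rna.nucleotides:
        for a in nt.atoms:
            rc.append((a.x, a.y, a.z))
            ro.append(nt.seq_index)
    pc, rc = np.asarray(pc, float), np.asarray(rc, float)
    contact = np.zeros((len(prot), len(rna)), dtype=bool)
    hits = cKDTree(pc).query_ball_tree(cKDTree(rc), r=cutoff)
    for pi, rlist in enumerate(hits):
        for ri in rlist:
            if np.linalg.norm(pc[pi] - rc[ri]) < cutoff:
                contact[po[pi], ro[ri]] = True
    return contact


def _window_any(contact: np.ndarray, L: int, M: int) -> np.ndarray:
    """(n-L+1, m-M+1) booleans: any contact inside each L x M submatrix."""
    c = contact.astype(np.int32)
    s = np.zeros((c.shape[0] + 1, c.shape[1] + 1), dtype=np.int64)
    s[1:, 1:] = np.cumsum(np.cumsum(c, axis=0), axis=1)
    n_p, n_r = c.shape[0] - L + 1, c.shape[1] - M + 1
    out = np.zeros((n_p, n_r), dtype=bool)
    for i in range(n_p):
        for j in range(n_r):
            total = (s[i + L, j + M] - s[i, j + M] - s[i + L, j] + s[i, j])
            out[i, j] = total > 0
    return out


def generate_pairs(
    complex: ComplexStructure,
    L: int = 5,
    M: int = 5,
    cutoff: float = CONTACT_CUTOFF,
) -> list[FragmentPair]:
    """All stride-1 fragment pairs of a complex, labelled by atom contact.

    Yields (n-L+1)*(m-M+1) pairs per protein/RNA chain combination; a
    chain shorter than its window contributes none.  Requires L >= 1 and
    M >= 2 (the composition block needs at least one dinucleotide).
    """
    if L < 1:
        raise ValueError("protein fragment length must be >= 1")
    if M < 2:
        raise ValueError("RNA fragment length must be >= 2")
    pairs: list[FragmentPair] = []
    for prot in complex.protein_chains:
        if len(prot) < L:
            continue
        for rna in complex.rna_chains:
            if len(rna) < M:
                continue
            contact = _residue_nt_contact_matrix(prot, rna, cutoff)
            window = _window_any(contact, L, M)
            for i in range(window.shape[0]):
                for j in range(window.shape[1]):
                    pairs.append(
                        FragmentPair(
                            protein_id=f"{complex.id}_{prot.chain_id}",
                            prot_start=i,
                            prot_len=L,
                            rna_id=f"{complex.id}_{rna.chain_id}",
                            rna_start=j,
                            rna_len=M,
                            label=int(window[i, j]),
                        )
                    )
    return pairs


def dinucleotide_composition(rna_fragment: str) -> np.ndarray:
    """16 fractions of the fragment's M-1 overlapping dinucleotides."""
    comp = np.zeros(N_DINUC)
    for a, b in zip(rna_fragment, rna_fragment[1:]):
        dinuc = a + b
        if dinuc not in DINUC_INDEX:
            raise ValueError(f"unknown base in RNA fragment: {dinuc!r}")
        comp[DINUC_INDEX[dinuc]] += 1
    total = comp.sum()
    if total == 0:
        raise ValueError("RNA fragment must contain at least one dinucleotide")
    return comp / total


def pair_features(
    pred: PredictionMatrix,
    rna_sequence: str,
    prot_start: int,
    prot_len: int,
    rna_start: int,
    rna_len: int,
) -> np.ndarray:
    """Feature vector of one pair: [16 scores x L residues] ++ [16 fractions]."""
    if prot_start < 0 or prot_start + prot_len > len(pred.scores):
        raise ValueError("protein fragment outside prediction matrix")
    block = pred.scores[prot_start : prot_start + prot_len].ravel()
    comp = dinucleotide_composition(rna_sequence[rna_start : rna_start + rna_len])
    return np.concatenate([block, comp])


def build_pair_dataset(
    complex: ComplexStructure,
    predictions: dict[str, PredictionMatrix],
    L: int = 5,
    M: int = 5,
    cutoff: float = CONTACT_CUTOFF,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Featurised pairs and labels for one complex (one CV unit).

    ``predictions`` maps protein chain id to that chain's residue-level
    16-score prediction matrix.
    """
    pairs = generate_pairs(complex, L=L, M=M, cutoff=cutoff)
    rna_seq = {f"{complex.id}_{ch.chain_id}": ch.sequence for ch in complex.rna_chains}
    rows, labels = [], []
    for pair in pairs:
        chain_id = pair.protein_id.split("_")[-1]
        pred = predictions[chain_id]
        vec = pair_features(pred, rna_seq[pair.rna_id], pair.prot_start,
                            pair.prot_len, pair.rna_start, pair.rna_len)
        pair.features = vec
        rows.append(vec)
        labels.append(pair.label)
    if not rows:
        return FeatureMatrix(protein_id=complex.id, rows=np.zeros((0, 16 * L + 16))), \
            np.zeros((0, 1))
    return (
        FeatureMatrix(protein_id=complex.id, rows=np.asarray(rows)),
        np.asarray(labels, dtype=float).reshape(-1, 1),
    )


def train_pair_classifier(
    dataset: list[tuple[FeatureMatrix, np.ndarray]],
    hyper: Hyper,
) -> CVResult:
    """Cross-validated single-output pair classifier.

    ``dataset`` holds one (features, labels) entry per complex; folds are
    assigned at the complex level so near-duplicate sliding windows from
    one complex never straddle a train/test split.
    """
    all_labels = np.concatenate([lab.ravel() for _, lab in dataset])
    if all_labels.min() == all_labels.max():
        raise ValueError("pair dataset contains a single class")
    return cross_validate(dataset, hyper)
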