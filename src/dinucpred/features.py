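"""Sequence feature encoding for the residue-level contact predictor.

Each residue is represented by a sliding window (n neighbours per side)
of per-position blocks — a 21-bit one-hot block (20 amino acids plus a
terminal marker for positions beyond the sequence ends) and/or a 20-column
PSI-BLAST PSSM block — optionally followed by one 20-vector of global
amino-acid composition (GAC) of the whole sequence.  PSSM log-odds are
squashed through the logistic function by default so all inputs live on a
comparable 0..1 scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .alphabets import AA_INDEX, AMINO_ACIDS

__all__ = [
    "PSSM",
    "EncodingConfig",
    "FeatureMatrix",
    "TERMINAL",
    "sparse_encode",
    "read_pssm",
    "compute_gac",
    "assemble_features",
    "feature_dim",
]

#: Marker for window positions beyond the protein termini.
TERMINAL = "-"


@dataclass
class PSSM:
    """A PSI-BLAST position-specific scoring matrix for one protein.

    ``scores`` rows follow the sequence; columns are remapped on read to
    the package alphabet ACDEFGHIKLMNPQRSTVWY regardless of file order.
    """

    protein_id: str
    scores: np.ndarray  # (L, 20) floats
    sequence: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM scores must be L x 20")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError("PSSM does not match sequence")


@dataclass
class EncodingConfig:
    """Feature-encoding switches.

    neighbours_per_side: window radius n, giving a (2n+1)-residue window.
    use_sparse / use_pssm: include the 21-bit one-hot and/or PSSM block.
    use_gac: append the global amino-acid composition 20-vector.
    pssm_squash: 'sigmoid' (default), 'div10' or 'none'.
    """

    neighbours_per_side: int = 2
    use_sparse: bool = False
    use_pssm: bool = True
    use_gac: bool = True
    pssm_squash: str = "sigmoid"

    def __post_init__(self) -> None:
        if not 0 <= self.neighbours_per_side <= 8:
            raise ValueError("neighbours_per_side must be in [0, 8]")
        if not (self.use_sparse or self.use_pssm):
            raise ValueError("at least one of use_sparse/use_pssm required")
        if self.pssm_squash not in ("sigmoid", "div10", "none"):
            raise ValueError(f"unknown pssm_squash {self.pssm_squash!r}")

    @property
    def window_length(self) -> int:
        return 2 * self.neighbours_per_side + 1


@dataclass
class FeatureMatrix:
    protein_id: str
    rows: np.ndarray  # (n_residues, dim)

    @property
    def dim(self) -> int:
        return int(self.rows.shape[1])

    def __len__(self) -> int:
        return int(self.rows.shape[0])


def feature_dim(config: EncodingConfig) -> int:
    """Closed-form feature dimension: (2n+1)(21*sparse + 20*pssm) + 20*gac."""
    per_pos = 21 * config.use_sparse + 20 * config.use_pssm
    return config.window_length * per_pos + 20 * config.use_gac


def sparse_encode(window: str | list[str]) -> np.ndarray:
    """21-bit one-hot encoding of a window of residue symbols.

    Each position sets exactly one bit: its amino-acid bit, or bit 20 for
    the terminal marker (positions beyond the sequence ends).  Returns a
    flat vector of 21 * len(window).
    """
    out = np.zeros(21 * len(window))
    for k, sym in enumerate(window):
        if sym == TERMINAL or sym is None:
            out[21 * k + 20] = 1.0
        elif sym in AA_INDEX:
            out[21 * k + AA_INDEX[sym]] = 1.0
        else:
            raise ValueError(f"unknown residue symbol {sym!r}")
    return out


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(.*)$")


def read_pssm(text: str, sequence: str | None = None, protein_id: str = "") -> PSSM:
    """Parse a blastpgp ASCII PSSM (the ``-Q`` output file).

    Reads the first 20 numeric columns (log-odds) of each residue row;
    column order is taken from the header line and remapped to the
    package alphabet.  When ``sequence`` is given, the residue column of
    the file must agree with it.
    """
    lines = text.splitlines()
    header_order: list[str] | None = None
    rows: list[list[float]] = []
    seq_chars: list[str] = []
    for line in lines:
        tokens = line.split()
        if header_order is None:
            if len(tokens) in (20, 40) and all(
                t in AA_INDEX for t in tokens[:20]
            ):
                header_order = tokens[:20]
            continue
        m = _PSSM_ROW.match(line)
        if m is None:
            if rows and tokens:
                break  # trailing K/Lambda block etc.
            continue
        values = m.group(3).split()
        if len(values) < 20:
            raise ValueError(
                f"truncated PSSM row {m.group(1)}: expected >= 20 scores, "
                f"got {len(values)}"
            )
        try:
            rows.append([float(v) for v in values[:20]])
        except ValueError as exc:
            raise ValueError(f"bad PSSM value in row {m.group(1)}: {exc}") from exc
        seq_chars.append(m.group(2))
    if header_order is None:
        raise ValueError("no PSSM header line with 20 amino-acid columns found")
    if not rows:
        raise ValueError("PSSM contains no residue rows")
    raw = np.asarray(rows, dtype=float)
    # remap file column order -> package alphabet
    remap = [header_order.index(a) for a in AMINO_ACIDS]
    scores = raw[:, remap]
    seq = "".join(seq_chars)
    if sequence is not None and seq != sequence:
        raise ValueError(
            f"PSSM does not match sequence ({len(seq)} PSSM rows vs "
            f"{len(sequence)} residues)"
        )
    return PSSM(protein_id=protein_id, scores=scores, sequence=seq)


def compute_gac(sequence: str) -> np.ndarray:
    """Global amino-acid composition: 20 fractions summing to 1.

    Symbols outside the 20-letter alphabet are dropped before
    normalisation; an empty or all-invalid sequence is an error.
    """
    counts = np.zeros(20)
    for sym in sequence:
        if sym in AA_INDEX:
            counts[AA_INDEX[sym]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no standard amino acids")
    return counts / total


def _squash(scores: np.ndarray, mode: str) -> np.ndarray:
    if mode == "sigmoid":
        return 1.0 / (1.0 + np.exp(-scores))
    if mode == "div10":
        return scores / 10.0
    return scores


def assemble_features(
    sequence: str,
    pssm: PSSM | None,
    config: EncodingConfig,
    protein_id: str = "",
) -> FeatureMatrix:
    """Windowed feature matrix for one protein.

    Per residue: concatenation over the (2n+1)-window of
    [sparse block][squashed PSSM block] per position, then one GAC block.
    Out-of-range window positions carry the terminal one-hot bit and
    all-zero PSSM rows.
    """
    if config.use_pssm and pssm is None:
        raise ValueError("config requests PSSM features but no PSSM given")
    if not config.use_pssm and pssm is not None:
        raise ValueError("PSSM given but config does not use it")
    if pssm is not None and pssm.sequence != sequence:
        raise ValueError("PSSM does not match sequence")
    L = len(sequence)
    n = config.neighbours_per_side
    squashed = _squash(pssm.scores, config.pssm_squash) if pssm is not None else None
    gac = compute_gac(sequence) if config.use_gac else None
    dim = feature_dim(config)
    rows = np.zeros((L, dim))
    for i in range(L):
        parts: list[np.ndarray] = []
        for off in range(-n, n + 1):
            j = i + off
            in_range = 0 <= j < L
            if config.use_sparse:
                sym = sequence[j] if in_range else TERMINAL
                parts.append(sparse_encode([sym]))
            if config.use_pssm:
                parts.append(squashed[j] if in_range else np.zeros(20))
        if gac is not None:
            parts.append(gac)
        rows[i] = np.concatenate(parts)
    return FeatureMatrix(protein_id=protein_id, rows=rows)
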