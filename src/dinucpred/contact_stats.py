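"""Residue-dinucleotide contact statistics under a random-docking null.

Observed contacts are counted per (amino-acid type, dinucleotide class)
cell.  The expected count allocates each complex's total number of
observed contacts N to the 20 x 16 cells proportionally to the product of
the total accessible surface area (ASA) of residues of type i and of
dinucleotide sites of class j, both computed on chains isolated from the
complex:

    E_ij = N * ASA(i) * ASA(j) / sum_kl ASA(k) * ASA(l)

Observed and expected counts are summed over all complexes first, then a
Pearson chi-squared statistic with one degree of freedom is computed per
cell; its sign is set negative when observed < expected, so positive
values mark interface enrichment and negative values exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy import stats

from .alphabets import (
    AA_INDEX,
    AMINO_ACIDS,
    DINUC_INDEX,
    DINUCLEOTIDES,
    N_DINUC,
    THREE_TO_ONE,
)
from .structure_io import (
    ComplexStructure,
    ContactRecord,
    compute_complex_asa,
    enumerate_dinucleotide_sites,
)

__all__ = [
    "ContactCountMatrix",
    "ExpectedContactMatrix",
    "ComplexSummary",
    "PreferenceTable",
    "count_observed",
    "summarize_complex",
    "expected_counts",
    "pooled_signed_chi2",
    "chi2_pvalue",
    "preference_table",
    "write_preference_tables",
]

#: Cells with expected count below this and zero observed are null cells.
ZERO_EXPECTED_EPS = 1e-9


@dataclass
class ContactCountMatrix:
    """Observed contacts, rows = 20 amino acids, columns = 16 dinucleotides."""

    counts: np.ndarray  # (20, 16) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (20, N_DINUC):
            raise ValueError("count matrix must be 20 x 16")
        if (self.counts < 0).any():
            raise ValueError("negative contact count")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExpectedContactMatrix:
    """Random-docking expected contacts on the same 20 x 16 grid."""

    expected: np.ndarray  # (20, 16) non-negative reals

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        if self.expected.shape != (20, N_DINUC):
            raise ValueError("expected matrix must be 20 x 16")

    @property
    def n_total(self) -> float:
        return float(self.expected.sum())


class ComplexSummary(NamedTuple):
    """Per-complex totals needed for the random-docking expectation."""

    asa_residue: np.ndarray  # (20,) total ASA per amino-acid type
    asa_site: np.ndarray  # (16,) total ASA per dinucleotide class
    n_contacts: int  # observed residue-site contact pairs


@dataclass
class PreferenceTable:
    """Signed chi-squared preference statistics with companion p-values.

    ``signed_chi2`` is NaN where the expectation vanished but contacts
    were observed (the statistic is undefined there).
    """

    signed_chi2: np.ndarray
    p_value: np.ndarray
    observed: ContactCountMatrix
    expected: ExpectedContactMatrix


def count_observed(
    records: Iterable[ContactRecord],
    per_contact_granularity: bool = True,
) -> ContactCountMatrix:
    """Pool contact records from any number of complexes into 20 x 16 counts.

    With ``per_contact_granularity`` (default) each (residue, site) pair
    contributes one count, so a residue touching two distinct GA sites
    counts twice; otherwise counting collapses to distinct
    (residue, class) combinations.  Residues outside the 20-letter
    alphabet are dropped with a warning.
    """
    counts = np.zeros((20, N_DINUC), dtype=np.int64)
    seen: set[tuple] = set()
    for rec in records:
        aa = THREE_TO_ONE.get(rec.resname) or (
            rec.resname if rec.resname in AA_INDEX else None
        )
        if aa is None:
            warnings.warn(
                f"non-standard residue {rec.resname!r} dropped from contact counts",
                stacklevel=2,
            )
            continue
        if not per_contact_granularity:
            key = (rec.protein_chain, rec.residue_index, rec.klass)
            if key in seen:
                continue
            seen.add(key)
        counts[AA_INDEX[aa], DINUC_INDEX[rec.klass]] += 1
    return ContactCountMatrix(counts)


def summarize_complex(
    complex: ComplexStructure, records: Iterable[ContactRecord]
) -> ComplexSummary:
    """ASA totals by residue type and site class, plus the contact total N.

    Isolated-chain ASAs are computed on demand.  Residues or sites outside
    the standard alphabets contribute nothing.
    """
    compute_complex_asa(complex)
    asa_residue = np.zeros(20)
    for prot in complex.protein_chains:
        for res, a in zip(prot.residues, prot.asa):
            aa = THREE_TO_ONE.get(res.name)
            if aa is not None:
                asa_residue[AA_INDEX[aa]] += a
    asa_site = np.zeros(N_DINUC)
    for rna in complex.rna_chains:
        for site in enumerate_dinucleotide_sites(rna):
            asa_site[DINUC_INDEX[site.klass]] += site.asa
    n = sum(1 for _ in records)
    return ComplexSummary(asa_residue=asa_residue, asa_site=asa_site, n_contacts=n)


def expected_counts(summaries: Iterable[ComplexSummary]) -> ExpectedContactMatrix:
    """Random-docking expectation, allocated per complex then summed.

    For each complex, E_ij = N * ASA(i)ASA(j) / sum ASA(k)ASA(l); the
    allocation conserves the complex's contact total exactly.
    """
    total = np.zeros((20, N_DINUC))
    for s in summaries:
        if s.n_contacts == 0:
            continue
        if (s.asa_residue < 0).any() or (s.asa_site < 0).any():
            raise ValueError("negative ASA total")
        weights = np.outer(s.asa_residue, s.asa_site)
        denom = weights.sum()
        if denom <= 0:
            raise ValueError(
                "cannot allocate expected contacts: all ASA products are zero "
                f"with N={s.n_contacts} observed contacts"
            )
        total += s.n_contacts * weights / denom
    return ExpectedContactMatrix(total)


def chi2_pvalue(x, df: int = 1):
    """Survival function of the chi-squared distribution (default 1 df)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("chi-squared statistic must be non-negative")
    p = stats.chi2.sf(x, df)
    return float(p) if p.ndim == 0 else p


def pooled_signed_chi2(
    observed: ContactCountMatrix, expected: ExpectedContactMatrix
) -> PreferenceTable:
    """Signed per-cell Pearson chi-squared on pooled observed/expected counts.

    chi2_ij = (O_ij - E_ij)^2 / E_ij, negated when O < E; p-values from
    the 1-df chi-squared survival function of the unsigned statistic.
    Cells with E < eps: statistic 0 and p = 1 when O = 0, NaN (undefined)
    when O > 0.
    """
    O = observed.counts.astype(float)
    E = expected.expected
    chi2 = np.zeros_like(E)
    pval = np.ones_like(E)
    ok = E >= ZERO_EXPECTED_EPS
    chi2[ok] = (O[ok] - E[ok]) ** 2 / E[ok]
    pval[ok] = stats.chi2.sf(chi2[ok], 1)
    sign = np.sign(O - E)
    chi2 = chi2 * np.where(sign == 0, 0.0, sign)
    undefined = (~ok) & (O > 0)
    chi2[undefined] = np.nan
    pval[undefined] = np.nan
    return PreferenceTable(signed_chi2=chi2, p_value=pval,
                           observed=observed, expected=expected)


def preference_table(
    complexes_with_records: Iterable[tuple[ComplexStructure, list[ContactRecord]]],
) -> PreferenceTable:
    """End-to-end preference statistics from parsed complexes.

    Counts observed contacts and the random-docking expectation per
    complex, pools both, and returns the signed chi-squared table.
    """
    all_records: list[ContactRecord] = []
    summaries: list[ComplexSummary] = []
    for cplx, records in complexes_with_records:
        all_records.extend(records)
        summaries.append(summarize_complex(cplx, records))
    return pooled_signed_chi2(count_observed(all_records), expected_counts(summaries))


def _write_matrix(path, matrix: np.ndarray, fmt: str = "%.6g") -> None:
    with open(path, "w") as fh:
        fh.write("aa\t" + "\t".join(DINUCLEOTIDES) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            cells = [
                "NA" if np.isnan(v) else fmt % v for v in np.atleast_1d(matrix[i])
            ]
            fh.write(aa + "\t" + "\t".join(cells) + "\n")


def write_preference_tables(table: PreferenceTable, out_dir) -> dict[str, str]:
    """Write signed chi2, p-value, observed and expected matrices as TSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, matrix in [
        ("signed_chi2", table.signed_chi2),
        ("p_value", table.p_value),
        ("observed", table.observed.counts),
        ("expected", table.expected.expected),
    ]:
        path = os.path.join(out_dir, f"{name}.tsv")
        _write_matrix(path, np.asarray(matrix, dtype=float))
        paths[name] = path
    return paths
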