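"""Reading and writing spectral-count matrices, protein metadata, and
identification records.

The on-disk dialect is deliberately plain: tab-separated UTF-8 text with a
header row.  A count matrix carries four metadata columns (``accession``,
``gene``, ``description``, ``length``) followed by one column of spectral
counts per LC-MS/MS run; a companion design table maps each ``run_id`` to its
experimental ``group`` and technical ``replicate`` number.  Counts are stored
as non-negative reals rather than integers because group-mean tables
(e.g. a triplicate mean of 26.3) share the same container as raw per-run
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "InputError",
    "ProteinRecord",
    "IdentificationRecord",
    "SpectralCountMatrix",
    "read_count_matrix",
    "read_design",
    "lengths_from_fasta",
    "read_identifications",
    "filter_identifications",
]

METADATA_COLUMNS = ("accession", "gene", "description", "length")
DESIGN_COLUMNS = ("run_id", "group", "replicate")


class InputError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """Static metadata for one protein entry.

    ``accession`` is UniProt-style and may carry an isoform suffix
    (``P05023-4``); isoforms are distinct proteins here, never collapsed to
    the canonical accession.  ``length`` (amino acids) supplies the L term of
    NSAF.
    """

    accession: str
    gene: str = ""
    description: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if not self.accession:
            raise InputError("protein accession must be non-empty")
        if self.length < 0:
            raise InputError(f"negative length for {self.accession}")


@dataclass(frozen=True)
class IdentificationRecord:
    """Search-engine validation summary for one protein.

    Probabilities are the outputs of upstream protein/peptide validation
    (e.g. ProteinProphet / PeptideProphet); this package only thresholds
    them, it does not model them.
    """

    accession: str
    protein_probability: float
    n_peptides: int
    peptide_probability: float

    def __post_init__(self) -> None:
        for name in ("protein_probability", "peptide_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name}={p} outside [0, 1] for {self.accession}")
        if self.n_peptides < 0:
            raise InputError(f"negative n_peptides for {self.accession}")


@dataclass
class SpectralCountMatrix:
    """Non-negative spectral counts for proteins x labeled runs.

    Attributes
    ----------
    proteins : pandas.DataFrame
        Indexed by accession; columns ``gene``, ``description``, ``length``.
    counts : pandas.DataFrame
        Indexed by accession, one float column per ``run_id``, aligned with
        ``proteins``.
    design : pandas.DataFrame
        Indexed by ``run_id``; columns ``group`` and ``replicate``.
    """

    proteins: pd.DataFrame
    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.proteins.index.duplicated().any():
            dups = self.proteins.index[self.proteins.index.duplicated()].tolist()
            raise InputError(f"duplicate accession(s): {dups}")
        if not self.proteins.index.equals(self.counts.index):
            raise InputError("proteins and counts indexed by different accessions")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("negative spectral count")
        missing = [r for r in self.counts.columns if r not in self.design.index]
        if missing:
            raise InputError(f"run_id(s) absent from design: {missing}")
        if self.design.index.duplicated().any():
            raise InputError("duplicate run_id in design")
        pairs = self.design[["group", "replicate"]]
        if pairs.duplicated().any():
            raise InputError("duplicate (group, replicate) pair in design")

    # -- convenience accessors -------------------------------------------------

    @property
    def accessions(self) -> pd.Index:
        return self.proteins.index

    @property
    def run_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def runs_for_group(self, group: str) -> list[str]:
        runs = [r for r in self.counts.columns if self.design.loc[r, "group"] == group]
        if not runs:
            raise InputError(f"unknown group {group!r}")
        return runs

    def lengths(self) -> pd.Series:
        return self.proteins["length"]

    def group_mean_counts(self, group: str) -> pd.Series:
        return self.counts[self.runs_for_group(group)].mean(axis=1)

    # -- I/O -------------------------------------------------------------------

    def write(self, counts_path: str | Path, design_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally the design) back to TSV.

        Round-trips bit-identically through :func:`read_count_matrix` for
        values that TSV can represent exactly.
        """
        table = self.proteins.copy()
        for run in self.counts.columns:
            table[run] = self.counts[run]
        table.reset_index().rename(columns={"index": "accession"}).to_csv(
            counts_path, sep="\t", index=False
        )
        if design_path is not None:
            self.design.reset_index().rename(columns={"index": "run_id"}).to_csv(
                design_path, sep="\t", index=False
            )


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a run design TSV (run_id, group, replicate) into a DataFrame."""
    design = pd.read_csv(path, sep="\t", dtype={"run_id": str, "group": str})
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise InputError(f"design file missing column(s): {missing}")
    design = design.set_index("run_id")
    if design.index.duplicated().any():
        raise InputError("duplicate run_id in design")
    if (design["replicate"] < 1).any():
        raise InputError("replicate numbers must be >= 1")
    return design


def read_count_matrix(path: str | Path, design_path: str | Path) -> SpectralCountMatrix:
    """Read a spectral-count matrix TSV plus its run design.

    The count file header must start with the four metadata columns and then
    list one column per run_id; every run_id must appear in the design.  Run
    order follows the design file.
    """
    table = pd.read_csv(path, sep="\t", dtype={"accession": str})
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"count matrix missing column(s): {missing}")
    design = read_design(design_path)

    table = table.set_index("accession")
    run_cols = [c for c in table.columns if c not in METADATA_COLUMNS[1:]]
    unknown = [r for r in run_cols if r not in design.index]
    if unknown:
        raise InputError(f"run_id(s) absent from design: {unknown}")
    ordered = [r for r in design.index if r in run_cols]
    proteins = table[list(METADATA_COLUMNS[1:])].copy()
    if (proteins["length"] < 1).any():
        bad = proteins.index[proteins["length"] < 1].tolist()
        raise InputError(f"length < 1 for {bad}")
    counts = table[ordered].astype(float)
    return SpectralCountMatrix(proteins=proteins, counts=counts, design=design)


def lengths_from_fasta(path: str | Path) -> dict[str, int]:
    """Map accession -> sequence length from a protein FASTA.

    Both the UniProt header dialect (``sp|P02788|TRFL_HUMAN``: the accession
    is the second pipe-delimited field) and bare-accession headers are
    accepted.
    """
    lengths: dict[str, int] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        token = record.id
        if "|" in token:
            fields = token.split("|")
            accession = fields[1] if len(fields) >= 2 and fields[1] else fields[0]
        else:
            accession = token
        if accession in lengths:
            raise InputError(f"duplicate accession in FASTA: {accession}")
        lengths[accession] = len(record.seq)
    if n == 0:
        raise InputError(f"no FASTA records in {path}")
    return lengths


def read_identifications(path: str | Path) -> list[IdentificationRecord]:
    """Read an identification TSV (accession, protein_probability, n_peptides,
    peptide_probability)."""
    table = pd.read_csv(path, sep="\t", dtype={"accession": str})
    needed = ["accession", "protein_probability", "n_peptides", "peptide_probability"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise InputError(f"identification file missing column(s): {missing}")
    return [
        IdentificationRecord(
            accession=row.accession,
            protein_probability=float(row.protein_probability),
            n_peptides=int(row.n_peptides),
            peptide_probability=float(row.peptide_probability),
        )
        for row in table.itertuples(index=False)
    ]


def filter_identifications(
    records: Iterable[IdentificationRecord],
    min_peptides: int = 2,
    min_protein_prob: float = 0.90,
    min_peptide_prob: float = 0.95,
) -> set[str]:
    """Apply the protein-acceptance thresholds and return accepted accessions.

    A protein is accepted iff its validation probability strictly exceeds
    ``min_protein_prob``, it carries at least ``min_peptides`` distinct
    identified peptides, and its best peptide strictly exceeds
    ``min_peptide_prob``.  The probability comparisons are strict: a protein
    at exactly 90% probability is rejected.
    """
    return {
        r.accession
        for r in records
        if r.protein_probability > min_protein_prob
        and r.n_peptides >= min_peptides
        and r.peptide_probability > min_peptide_prob
    }
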