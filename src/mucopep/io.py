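"""Peptide, labeled-set and abundance-table I/O.

File conventions:

* peptides — plain FASTA, or TSV with columns ``peptide_id`` and ``sequence``;
* labeled sets — TSV with columns ``peptide_id``, ``sequence``, ``label`` (0/1);
* abundance tables — TSV/CSV with a ``peptide_id`` column followed by one
  column per (species, replicate) sample named ``<species>|<replicate>``.
  Blank cells mean "not detected" and are read as intensity 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid letters. Ambiguity/rare codes (B, J, O, U, X, Z)
#: are rejected: the dipeptide feature space is defined over exactly 20 letters.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class PeptideValidationError(ValueError):
    """Raised when a sequence violates the peptide alphabet or length rules."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with an identifier.

    Sequences must be at least two residues long (dipeptide composition needs
    one adjacent pair) and use only the 20 canonical letters.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise PeptideValidationError(
                f"peptide {self.id!r}: sequence must have >= 2 residues, got {len(seq)}"
            )
        bad = set(seq) - _AA_SET
        if bad:
            raise PeptideValidationError(
                f"peptide {self.id!r}: illegal residue character(s) "
                f"{sorted(bad)} (alphabet is {AMINO_ACIDS})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledPeptideSet:
    """Peptides with binary bioactivity labels for one property category."""

    property_name: str
    peptides: list[Peptide]
    labels: np.ndarray  # binary, aligned 1:1 with peptides

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.peptides):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.peptides)} peptides"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    def subset(self, idx: Sequence[int]) -> "LabeledPeptideSet":
        idx = np.asarray(idx, dtype=int)
        return LabeledPeptideSet(
            self.property_name,
            [self.peptides[i] for i in idx],
            self.labels[idx],
        )


@dataclass
class AbundanceTable:
    """Peptide x (species, replicate) intensity matrix.

    ``intensities`` is a DataFrame indexed by peptide id with a two-level
    column MultiIndex (species, replicate). All intensities are >= 0; zero
    means "not detected".
    """

    intensities: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.intensities
        if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 2:
            raise ValueError("columns must be a (species, replicate) MultiIndex")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicated (species, replicate) columns: {dups}")
        if (df.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        df.columns = df.columns.set_names(["species", "replicate"])
        df.index = df.index.astype(str)
        df.index.name = "peptide_id"

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.intensities.columns.get_level_values(0)))

    def species_max(self) -> pd.DataFrame:
        """Per-(peptide, species) maximum intensity over replicates."""
        return self.intensities.T.groupby(level="species", sort=False).max().T

    def species_mean(self) -> pd.DataFrame:
        """Per-(peptide, species) mean intensity over replicates."""
        return self.intensities.T.groupby(level="species", sort=False).mean().T


def read_peptides(
    path: str | Path, format: Literal["fasta", "tsv"] = "fasta"
) -> list[Peptide]:
    """Read peptides from FASTA or TSV, validating the residue alphabet.

    Duplicate sequences are retained; identity is the record id. An empty
    file yields an empty list with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peptide file not found: {path}")
    peptides: list[Peptide] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            peptides.append(Peptide(rec.id, str(rec.seq)))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("peptide_id", "sequence"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        for _, row in df.iterrows():
            peptides.append(Peptide(str(row["peptide_id"]), str(row["sequence"])))
    else:
        raise ValueError(f"unknown peptide format: {format!r}")
    if not peptides:
        logger.warning("no peptide records found in %s", path)
    return peptides


def write_peptides(
    peptides: Iterable[Peptide], path: str | Path, format: Literal["fasta", "tsv"] = "fasta"
) -> None:
    path = Path(path)
    peptides = list(peptides)
    if format == "fasta":
        records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides]
        SeqIO.write(records, str(path), "fasta")
    elif format == "tsv":
        pd.DataFrame(
            {"peptide_id": [p.id for p in peptides], "sequence": [p.sequence for p in peptides]}
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown peptide format: {format!r}")


def read_labeled_set(path: str | Path, property_name: str) -> LabeledPeptideSet:
    """Read a TSV of ``peptide_id, sequence, label`` into a labeled set."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "sequence": str})
    for col in ("peptide_id", "sequence", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    peptides = [Peptide(r.peptide_id, r.sequence) for r in df.itertuples()]
    return LabeledPeptideSet(property_name, peptides, df["label"].to_numpy())


def write_labeled_set(s: LabeledPeptideSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "peptide_id": [p.id for p in s.peptides],
            "sequence": [p.sequence for p in s.peptides],
            "label": s.labels,
        }
    ).to_csv(path, sep="\t", index=False)


def _split_sample_column(name: str) -> tuple[str, str]:
    if "|" not in name:
        raise ValueError(
            f"sample column {name!r} must be named '<species>|<replicate>'"
        )
    species, replicate = name.split("|", 1)
    return species, replicate


def read_abundance(path: str | Path, sep: str | None = None) -> AbundanceTable:
    """Read a peptide x (species, replicate) abundance table.

    Missing cells are read as 0 ("not detected"); negative intensities and
    duplicated sample columns are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"abundance file not found: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen = set()
    for col in header[1:]:
        if col in seen:
            raise ValueError(f"{path}: duplicated (species, replicate) column {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "peptide_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'peptide_id'")
    df = df.set_index(df["peptide_id"].astype(str)).drop(columns="peptide_id")
    pairs = [_split_sample_column(c) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(pairs, names=["species", "replicate"])
    df = df.astype(float).fillna(0.0)
    return AbundanceTable(df)


def write_abundance(table: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    """Write an abundance table; exact round-trip with :func:`read_abundance`."""
    df = table.intensities.copy()
    df.columns = [f"{s}|{r}" for s, r in df.columns]
    df.index.name = "peptide_id"
    # repr-format floats so read(write(t)) reproduces intensities exactly
    df.to_csv(path, sep=sep, float_format=lambda x: repr(float(x)))
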