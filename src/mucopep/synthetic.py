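"""Synthetic peptide data with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`gen_labeled_peptides` emulates a labeled positive/negative training
  set for one bioactive property. The positive-class signal is compositional:
  positive sequences draw each residue from an enriched residue set with
  probability ``effect`` (and uniformly otherwise), so the class signal maps
  directly onto the dipeptide feature space the classifiers consume.
  ``effect = 0`` makes the classes indistinguishable; ``effect = 1`` makes
  positives use only enriched residues.
* :func:`gen_presence_matrix` emulates a cross-species peptide abundance
  table with a planted core/variable structure: core peptides present in
  every species, each variable peptide carrying one of ``n_patterns``
  distinct binary species profiles (never all-present or all-absent).
  Intensities are lognormal where present and 0 where absent, so the
  planted presence structure is recovered exactly by presence calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mucopep.io import AMINO_ACIDS, AbundanceTable, LabeledPeptideSet, Peptide


@dataclass
class PeptideGenConfig:
    """Conditions for a synthetic labeled peptide set.

    Defaults give 400 peptides per class of tryptic-like length (6-30
    residues) with a strong compositional signal (``effect = 0.9``) toward
    residues typical of cationic/amphipathic bioactive peptides (K, R, W, L).
    """

    n_per_class: int = 400
    length_range: tuple[int, int] = (6, 30)
    effect: float = 0.9
    enriched_residues: tuple[str, ...] = ("K", "R", "W", "L")
    seed: int = 1
    property_name: str = "synthetic-bioactive"

    def __post_init__(self) -> None:
        if self.length_range[0] < 2:
            raise ValueError("minimum length must be >= 2")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must be in [0, 1]")
        if not set(self.enriched_residues) <= set(AMINO_ACIDS):
            raise ValueError("enriched_residues must be canonical amino acids")


@dataclass
class MatrixGenConfig:
    """Conditions for a synthetic cross-species abundance matrix.

    Defaults plant the observed scenario of a seven-species mucus
    peptidome: 1218 core + 1600 variable peptides across 28 patterns,
    triplicate samples, lognormal intensity spread of 0.5 log-units.
    """

    n_species: int = 7
    n_core: int = 1218
    n_variable: int = 1600
    n_patterns: int = 28
    replicates: int = 3
    noise_sd: float = 0.5
    seed: int = 1
    base_log_intensity: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_core, self.n_variable, self.replicates) < 0:
            raise ValueError("counts must be >= 0")
        n_profiles = 2**self.n_species - 2  # excludes all-present and all-absent
        if not 1 <= self.n_patterns <= n_profiles:
            raise ValueError(
                f"n_patterns must be in [1, {n_profiles}] for {self.n_species} species"
            )


def _draw_sequence(rng: np.random.Generator, length: int, effect: float,
                   enriched: tuple[str, ...]) -> str:
    from_enriched = rng.random(length) < effect
    uniform = rng.integers(0, len(AMINO_ACIDS), size=length)
    special = rng.integers(0, len(enriched), size=length)
    return "".join(
        enriched[special[i]] if from_enriched[i] else AMINO_ACIDS[uniform[i]]
        for i in range(length)
    )


def gen_labeled_peptides(cfg: PeptideGenConfig) -> LabeledPeptideSet:
    """Seeded labeled set: uniform negatives, composition-shifted positives."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    peptides: list[Peptide] = []
    labels: list[int] = []
    for label, prefix, effect in ((1, "pos", cfg.effect), (0, "neg", 0.0)):
        lengths = rng.integers(lo, hi + 1, size=cfg.n_per_class)
        for i, length in enumerate(lengths):
            seq = _draw_sequence(rng, int(length), effect, cfg.enriched_residues)
            peptides.append(Peptide(f"{prefix}_{i:05d}", seq))
            labels.append(label)
    return LabeledPeptideSet(cfg.property_name, peptides, np.asarray(labels))


@dataclass
class PlantedTruth:
    """Ground-truth structure of a generated presence matrix."""

    core_ids: list[str]
    variable_ids: list[str]
    pattern_labels: pd.Series = field(repr=False)  # pattern id per variable peptide
    pattern_profiles: pd.DataFrame = field(repr=False)  # binary species profile per pattern


def gen_presence_matrix(cfg: MatrixGenConfig) -> tuple[AbundanceTable, PlantedTruth]:
    """Generate an abundance table with planted core/variable/pattern structure.

    Where a peptide is present in a species, every replicate intensity is a
    positive lognormal draw (all equal to exp(base_log_intensity) when
    ``noise_sd = 0``); absent cells are exactly 0, so presence calling is
    noise-free by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    core_ids = [f"core_{i:05d}" for i in range(cfg.n_core)]
    var_ids = [f"var_{i:05d}" for i in range(cfg.n_variable)]

    # n_patterns distinct non-trivial binary profiles, encoded as 1..2^n-2
    codes = rng.choice(np.arange(1, 2**cfg.n_species - 1), size=cfg.n_patterns,
                       replace=False)
    profiles = (
        (codes[:, None] >> np.arange(cfg.n_species)[None, :]) & 1
    ).astype(int)
    pattern_profiles = pd.DataFrame(
        profiles, index=pd.RangeIndex(cfg.n_patterns, name="pattern"), columns=species
    )

    # every pattern gets used: round-robin assignment, then shuffled
    labels = np.arange(cfg.n_variable) % cfg.n_patterns
    rng.shuffle(labels)
    pattern_labels = pd.Series(labels, index=var_ids, name="pattern")

    presence = np.vstack(
        [np.ones((cfg.n_core, cfg.n_species), dtype=int), profiles[labels]]
    )
    n_total = cfg.n_core + cfg.n_variable
    log_i = cfg.base_log_intensity + cfg.noise_sd * rng.standard_normal(
        (n_total, cfg.n_species, cfg.replicates)
    )
    intensities = np.exp(log_i) * presence[:, :, None]
    flat = intensities.reshape(n_total, cfg.n_species * cfg.replicates)
    columns = pd.MultiIndex.from_product(
        [species, [f"rep{r + 1}" for r in range(cfg.replicates)]],
        names=["species", "replicate"],
    )
    table = AbundanceTable(
        pd.DataFrame(flat, index=pd.Index(core_ids + var_ids, name="peptide_id"),
                     columns=columns)
    )
    truth = PlantedTruth(core_ids, var_ids, pattern_labels, pattern_profiles)
    return table, truth
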