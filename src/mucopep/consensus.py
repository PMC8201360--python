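"""Consensus fusion of kNN and RF bioactivity calls.

A peptide-property assignment is a *consensus call* when both the kNN and
the RF classifier call it positive and the property is supported by both
methods. Not every property category yields a usable classifier under both
algorithms, so the registry tracks three label sets: the full vocabulary,
the kNN-supported subset, and the RF-supported subset; consensus calls are
restricted to their intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Full vocabulary of bioactive-property categories.
ALL_PROPERTIES: tuple[str, ...] = (
    "antibacterial",
    "antibiofilm",
    "anticancer",
    "antifungal",
    "antihypertensive",
    "antioxidant",
    "antiparasitic",
    "anti-inflammatory",
    "antiprotease",
    "antiviral",
    "cell-communicating",
    "cell-penetrating",
    "chemotactic",
    "drug-delivering",
    "haemolytic",
    "insecticide",
    "quorum-sensing",
    "spermicide",
    "surface-immobilized",
    "toxic",
    "tumor-homing",
    "wound-healing",
)

#: Categories for which a usable kNN classifier exists (14 labels).
KNN_SUPPORTED: tuple[str, ...] = (
    "antibacterial",
    "antibiofilm",
    "anticancer",
    "antifungal",
    "antihypertensive",
    "antiparasitic",
    "anti-inflammatory",
    "antiviral",
    "cell-communicating",
    "cell-penetrating",
    "drug-delivering",
    "quorum-sensing",
    "toxic",
    "tumor-homing",
)

#: Categories for which a usable RF classifier exists (11 labels).
RF_SUPPORTED: tuple[str, ...] = (
    "antibacterial",
    "antihypertensive",
    "antiparasitic",
    "anti-inflammatory",
    "antiviral",
    "cell-communicating",
    "cell-penetrating",
    "drug-delivering",
    "quorum-sensing",
    "toxic",
    "tumor-homing",
)


def consensus_properties(
    knn_supported: set[str] | tuple[str, ...],
    rf_supported: set[str] | tuple[str, ...],
    vocabulary: tuple[str, ...] = ALL_PROPERTIES,
) -> list[str]:
    """Lexicographically sorted intersection of the two supported-label sets."""
    knn_supported, rf_supported = set(knn_supported), set(rf_supported)
    unknown = (knn_supported | rf_supported) - set(vocabulary)
    if unknown:
        raise ValueError(f"unknown property label(s): {sorted(unknown)}")
    return sorted(knn_supported & rf_supported)


@dataclass
class PropertyRegistry:
    """The property vocabulary and each method's supported subset."""

    all_properties: tuple[str, ...] = ALL_PROPERTIES
    knn_supported: tuple[str, ...] = KNN_SUPPORTED
    rf_supported: tuple[str, ...] = RF_SUPPORTED
    consensus_set: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.consensus_set = tuple(
            consensus_properties(
                self.knn_supported, self.rf_supported, self.all_properties
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropertyRegistry":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            tuple(data.get("all_properties", ALL_PROPERTIES)),
            tuple(data["knn_supported"]),
            tuple(data["rf_supported"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "all_properties": list(self.all_properties),
                    "knn_supported": list(self.knn_supported),
                    "rf_supported": list(self.rf_supported),
                },
                sort_keys=False,
            )
        )


def consensus_calls(
    knn: pd.DataFrame, rf: pd.DataFrame, registry: PropertyRegistry | None = None
) -> pd.DataFrame:
    """Combine per-method binary call tables into consensus calls.

    ``knn`` and ``rf`` are peptide x property binary tables sharing both
    indices. The result stacks them into a long table with columns
    ``knn_call``, ``rf_call`` and ``consensus_call`` where
    consensus = knn AND rf AND (property in the registry's consensus set).
    """
    registry = registry or PropertyRegistry()
    if not knn.index.equals(rf.index) or not knn.columns.equals(rf.columns):
        raise ValueError("kNN and RF tables must share peptide and property indices")
    unknown = set(knn.columns) - set(registry.all_properties)
    if unknown:
        raise ValueError(f"unknown property label(s): {sorted(unknown)}")
    in_consensus = knn.columns.isin(registry.consensus_set)
    cons = (knn.astype(bool) & rf.astype(bool)).to_numpy() & in_consensus[None, :]
    long = pd.DataFrame(
        {
            "knn_call": knn.to_numpy().astype(int).ravel(),
            "rf_call": rf.to_numpy().astype(int).ravel(),
            "consensus_call": cons.astype(int).ravel(),
        },
        index=pd.MultiIndex.from_product(
            [knn.index, knn.columns], names=["peptide_id", "property"]
        ),
    )
    return long


def multifunctionality_summary(
    calls: pd.DataFrame,
    min_properties: int = 5,
    use: str = "any-method",
) -> tuple[int, float, pd.Series]:
    """Count peptides whose positive-call property count reaches a threshold.

    ``use`` selects the calls counted per peptide: ``"any-method"`` counts a
    property positive when either classifier calls it; ``"consensus"``
    counts only consensus calls. Returns ``(count, percentage, histogram)``
    where the percentage is over all peptides, rounded to one decimal, and
    the histogram maps per-peptide property counts to peptide numbers.
    """
    if min_properties < 1:
        raise ValueError("min_properties must be >= 1")
    if use == "any-method":
        pos = (calls["knn_call"].astype(bool) | calls["rf_call"].astype(bool))
    elif use == "consensus":
        pos = calls["consensus_call"].astype(bool)
    else:
        raise ValueError(f"use must be 'any-method' or 'consensus', got {use!r}")
    per_peptide = pos.groupby(level="peptide_id").sum()
    count = int((per_peptide >= min_properties).sum())
    percentage = round(100.0 * count / len(per_peptide), 1)
    histogram = per_peptide.value_counts().sort_index()
    histogram.index.name = "n_properties"
    return count, percentage, histogram
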