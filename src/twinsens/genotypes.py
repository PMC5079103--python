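"""Genotype containers.

Dosages are stored as a dense ``samples x variants`` float matrix holding
effect-allele counts in {0, 1, 2} with ``NaN`` for missing calls.  The
effect allele is fixed dataset-wide as the allele listed in
``variants["effect_allele"]`` (written to the A1 slot of .bim files).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of the variant table, in order
VARIANT_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "allele_frequency",
]


@dataclass
class GenotypeDataset:
    """Samples x variants additive-dosage matrix plus variant metadata.

    Parameters
    ----------
    variants
        One row per variant with columns :data:`VARIANT_COLUMNS`.
        ``position`` is 1-based as in .bim files; ``allele_frequency`` is
        the effect-allele frequency (from simulation truth or computed).
    samples
        Ordered sample identifiers, one per matrix row.
    dosage
        ``(n_samples, n_variants)`` float array; entries in {0, 1, 2} or NaN.
    """

    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)
    dosage: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(
                f"dosage has {n} rows but {len(self.samples)} sample ids"
            )
        if m != len(self.variants):
            raise ValueError(
                f"dosage has {m} columns but {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def effect_allele_frequency(self) -> np.ndarray:
        """Per-variant effect-allele frequency among called genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        eaf = self.effect_allele_frequency()
        return np.minimum(eaf, 1.0 - eaf)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom other, het, hom effect) counts for variant column ``j``."""
        col = self.dosage[:, j]
        col = col[~np.isnan(col)]
        return (
            int(np.sum(col == 0)),
            int(np.sum(col == 1)),
            int(np.sum(col == 2)),
        )

    def subset_samples(self, index: np.ndarray | list[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in index],
            dosage=self.dosage[index, :].copy(),
        )

    def subset_variants(self, index: np.ndarray | list[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[:, index].copy(),
        )

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants["variant_id"])}
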