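"""Core in-memory containers shared across the package.

Genotypes are stored as minor-allele dosages (0/1/2) in a dense integer
matrix of individuals x markers, with ``MISSING`` (-1) as the single
reserved sentinel for no-calls.  The marker map carries chromosome label,
1-based physical position, marker id and the minor/major allele letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved sentinel for a missing genotype call.
MISSING: int = -1

MAP_COLUMNS = ("chrom", "pos", "id", "minor", "major")


class ParameterError(ValueError):
    """An argument was outside its documented range."""


class EmptyPanelError(ValueError):
    """An operation removed every marker (or individual) from a panel."""


@dataclass
class GenotypeMatrix:
    """Dense biallelic SNP panel.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_markers)`` integer array of minor-allele counts
        in {0, 1, 2}, with :data:`MISSING` marking no-calls.
    taxa
        Unique individual identifiers, one per row.
    marker_map
        One row per marker with columns ``chrom, pos, id, minor, major``;
        positions are 1-based and non-decreasing within a chromosome.
    groups
        Optional per-individual subpopulation labels (simulator truth).
    families
        Optional per-individual family labels (simulator truth).
    """

    dosages: np.ndarray
    taxa: list[str]
    marker_map: pd.DataFrame
    groups: np.ndarray | None = None
    families: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be a 2-D individuals x markers array")
        self.taxa = list(self.taxa)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n < 2:
            raise ParameterError("n_individuals must be >= 2")
        if len(self.taxa) != n:
            raise ParameterError("taxa length does not match dosage rows")
        if len(set(self.taxa)) != n:
            raise ParameterError("taxa identifiers must be unique")
        if len(self.marker_map) != m:
            raise ParameterError("marker_map length does not match dosage columns")
        for col in MAP_COLUMNS:
            if col not in self.marker_map.columns:
                raise ParameterError(f"marker_map missing column {col!r}")
        if self.marker_map["id"].duplicated().any():
            raise ParameterError("marker ids must be unique")
        vals = self.dosages[self.dosages != MISSING]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ParameterError("non-missing dosages must lie in {0, 1, 2}")
        pos = self.marker_map["pos"].to_numpy()
        for _, idx in self.marker_map.groupby("chrom", sort=False).indices.items():
            p = pos[idx]
            if np.any(np.diff(p) < 0):
                raise ParameterError("positions must be non-decreasing within a chromosome")

    # -- summaries ------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return self.missing_mask().mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of the coded (minor) allele among observed calls."""
        d = self.dosages.astype(float)
        obs = d != MISSING
        with np.errstate(invalid="ignore"):
            f = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return f

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency among observed calls."""
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def is_complete(self) -> bool:
        return not self.missing_mask().any()

    def dosages_filled(self) -> np.ndarray:
        """Float dosages with missing calls replaced by the marker mean."""
        d = self.dosages.astype(float)
        obs = d != MISSING
        col_mean = np.where(obs, d, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
        return np.where(obs, d, col_mean[None, :])

    # -- subsetting -----------------------------------------------------
    def select_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            taxa=list(self.taxa),
            marker_map=self.marker_map.iloc[index].reset_index(drop=True),
            groups=None if self.groups is None else self.groups.copy(),
            families=None if self.families is None else self.families.copy(),
        )

    def select_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :].copy(),
            taxa=[self.taxa[i] for i in index],
            marker_map=self.marker_map.copy(),
            groups=None if self.groups is None else self.groups[index].copy(),
            families=None if self.families is None else self.families[index].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.copy(),
            taxa=list(self.taxa),
            marker_map=self.marker_map.copy(),
            groups=None if self.groups is None else self.groups.copy(),
            families=None if self.families is None else self.families.copy(),
        )

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.taxa == other.taxa
            and self.marker_map[list(MAP_COLUMNS)].equals(other.marker_map[list(MAP_COLUMNS)])
        )


@dataclass
class TraitArchitecture:
    """Simulated truth for one quantitative trait.

    ``causal_indices`` are column indices into the genotype matrix the
    trait was simulated from; ``effects`` are additive allele-substitution
    effects in trait units per dosage unit.
    """

    causal_indices: np.ndarray
    effects: np.ndarray
    h2_target: float
    n_reps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if len(np.unique(self.causal_indices)) != len(self.causal_indices):
            raise ParameterError("causal_indices must be distinct")
        if self.effects.shape != self.causal_indices.shape:
            raise ParameterError("effects and causal_indices must have equal length")
        if not (0.0 < self.h2_target <= 1.0):
            raise ParameterError("h2_target must lie in (0, 1]")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")

    @property
    def n_qtl(self) -> int:
        return len(self.causal_indices)

    def genetic_values(self, geno: GenotypeMatrix) -> np.ndarray:
        """Dosage-weighted sum of QTL effects for each individual."""
        if self.causal_indices.size and self.causal_indices.max() >= geno.n_markers:
            raise ParameterError("causal index outside the genotype matrix")
        return geno.dosages_filled()[:, self.causal_indices] @ self.effects

    def to_frame(self, geno: GenotypeMatrix) -> pd.DataFrame:
        mm = geno.marker_map.iloc[self.causal_indices]
        return pd.DataFrame(
            {
                "id": mm["id"].to_numpy(),
                "chrom": mm["chrom"].to_numpy(),
                "pos": mm["pos"].to_numpy(),
                "effect": self.effects,
            }
        )


@dataclass
class PhenotypeVector:
    """Taxa-aligned trait values.

    ``values`` has shape ``(n,)`` for one observation per individual or
    ``(n, r)`` for r replicate observations per individual.
    """

    values: np.ndarray
    taxa: list[str]
    name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxa = list(self.taxa)
        n = self.values.shape[0]
        if len(self.taxa) != n:
            raise ParameterError("phenotype length does not match taxa")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("phenotype values must be finite")

    @property
    def n_reps(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    def line_means(self) -> np.ndarray:
        return self.values if self.values.ndim == 1 else self.values.mean(axis=1)


@dataclass
class QCReport:
    """Counts of markers removed by each quality-control rule, in the order
    the rules are applied (categories are disjoint)."""

    n_input: int
    n_monomorphic: int
    n_low_maf: int
    n_high_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_monomorphic + self.n_low_maf + self.n_high_missing
        if removed + self.n_retained != self.n_input:
            raise ParameterError("QC counts do not add up to the input marker count")


@dataclass
class HeritabilityInputs:
    """Variance components feeding the broad-sense heritability formula."""

    sigma2_g: float
    sigma2_e: float
    n_reps: int = 1

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ParameterError("variance components must be non-negative")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
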