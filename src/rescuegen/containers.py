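"""Core in-memory containers for genotype, haplotype and environmental data.

Genotypes are stored as microsatellite allele sizes (base pairs), not
recoded indices, because allele-size-based statistics (R_ST and the
allele-size permutation test) need the sizes themselves. Missing genotypes
are encoded as 0 on both chromosomes; a genotype is either fully observed
or fully missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


class AlignmentError(ValueError):
    """Raised when sequences that must be aligned have unequal lengths."""


@dataclass
class GenotypeTable:
    """Diploid microsatellite calls with population labels.

    Parameters
    ----------
    individual_ids : list of str
    populations : list of str
        Population label per individual.
    loci : list of str
        Locus names, identical ordering for every individual.
    genotypes : ndarray of shape (n_individuals, n_loci, 2), int
        Allele sizes in base pairs; 0 marks a missing allele. Both
        alleles of a genotype are present or both are 0.
    sites : list of str or None
        Optional finer-grained sampling site per individual.
    """

    individual_ids: list[str]
    populations: list[str]
    loci: list[str]
    genotypes: np.ndarray
    sites: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int32)
        n, m = len(self.individual_ids), len(self.loci)
        if self.genotypes.shape != (n, m, 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n} individuals x {m} loci x 2"
            )
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        if self.sites is not None and len(self.sites) != n:
            raise ValueError("one site label required per individual")
        if (self.genotypes < 0).any():
            raise ValueError("allele sizes must be non-negative integers")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for {self.individual_ids[i]} at "
                f"locus {self.loci[j]}: both alleles must be present or missing"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where genotype is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        """Row subset by boolean or integer index array."""
        idx = np.arange(self.n_individuals)[mask]
        return GenotypeTable(
            [self.individual_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            list(self.loci),
            self.genotypes[idx],
            None if self.sites is None else [self.sites[i] for i in idx],
        )

    def population(self, name: str) -> "GenotypeTable":
        """All individuals belonging to one population."""
        mask = np.array([p == name for p in self.populations])
        if not mask.any():
            raise KeyError(f"no population named {name!r}")
        return self.subset(mask)

    def drop_high_missing(self, max_missing: int = 3) -> "GenotypeTable":
        """Curation filter: drop individuals missing more than `max_missing` loci."""
        keep = self.missing_mask().sum(axis=1) <= max_missing
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (one row per individual, two columns per locus)."""
        data: dict[str, object] = {
            "individual_id": self.individual_ids,
            "population": self.populations,
        }
        if self.sites is not None:
            data["site"] = self.sites
        for j, locus in enumerate(self.loci):
            data[f"{locus}.1"] = self.genotypes[:, j, 0]
            data[f"{locus}.2"] = self.genotypes[:, j, 1]
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


VALID_BASES = frozenset("ACGTN-")


@dataclass
class HaplotypeSet:
    """Aligned mtDNA sequences with population labels."""

    sequence_ids: list[str]
    populations: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not (len(self.sequence_ids) == len(self.populations) == len(self.sequences)):
            raise ValueError("ids, populations and sequences must have equal length")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences not aligned: lengths {sorted(lengths)}")
        for sid, seq in zip(self.sequence_ids, self.sequences):
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"illegal character(s) {sorted(bad)} in {sid}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population(self, name: str) -> "HaplotypeSet":
        idx = [i for i, p in enumerate(self.populations) if p == name]
        if not idx:
            raise KeyError(f"no population named {name!r}")
        return HaplotypeSet(
            [self.sequence_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            [self.sequences[i] for i in idx],
        )

    def matrix(self) -> np.ndarray:
        """Sequences as a (n, L) byte matrix for vectorized comparisons."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n_sequences, self.length)


@dataclass
class SiteEnvTable:
    """Environmental variables per sampling site.

    Sites nest in populations, populations in basins. The standardized
    form has column mean 0 and variance 1 (computed across sites).
    """

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    ID_COLS = ("site_id", "population", "basin")

    def __post_init__(self) -> None:
        for col in self.ID_COLS:
            if col not in self.frame.columns:
                raise ValueError(f"missing required column {col!r}")
        if self.frame["site_id"].duplicated().any():
            dups = self.frame.loc[self.frame["site_id"].duplicated(), "site_id"]
            raise ValueError(f"duplicated site_id(s): {sorted(set(dups))}")
        for col in self.variables:
            if not np.issubdtype(self.frame[col].dtype, np.number):
                raise ValueError(f"environmental variable {col!r} is not numeric")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.ID_COLS]

    @property
    def n_sites(self) -> int:
        return len(self.frame)

    def values(self) -> np.ndarray:
        return self.frame[self.variables].to_numpy(dtype=float)

    def standardized(self) -> "SiteEnvTable":
        """Zero-mean, unit-variance copy (per variable, across sites)."""
        out = self.frame.copy()
        for col in self.variables:
            x = out[col].to_numpy(dtype=float)
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"variable {col!r} is constant; cannot standardize")
            out[col] = (x - x.mean()) / sd
        return SiteEnvTable(out)
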