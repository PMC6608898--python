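"""Core data containers for inversion genotyping.

Genotypes are stored as alt-allele counts in {0, 1, 2}; missing calls use
the sentinel :data:`MISSING` (-1).  Probabilistic genotypes are stored as
samples x sites x 3 posterior triples; a missing triple is all-NaN.
Positions are 1-based at every public interface (as in VCF); any internal
interval arithmetic uses 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING: int = -1

#: Allowed inversion-genotype strings. N = standard (non-inverted) allele,
#: I = inverted allele.  Hemizygous males on chromosome X carry N or I.
INV_GENOTYPES = ("NN", "NI", "II")
NO_CALL = "NO_CALL"

#: Haplotype-group symbols, assigned to clusters by descending size.
GROUP_SYMBOLS = "ABCD"


class InvscoreError(Exception):
    """Base class for invscore errors."""


class EmptyRegionError(InvscoreError):
    """No biallelic SNPs found in the requested region."""


class NoOverlapError(InvscoreError):
    """Query data shares no usable sites with the reference panel."""


class UnmappableInversionError(InvscoreError):
    """The cohort cannot be mapped to a clean haplotype-genotype structure.

    Raised when no candidate haplotype-group count produces the expected
    cluster pattern (line / triangle / tetrahedron with heterozygous
    clusters at homozygous midpoints), or when experimental labels show a
    haplotype group shared between standard and inverted chromosomes
    (the recurrent-inversion failure mode).
    """


class UnresolvableGroupError(InvscoreError):
    """A haplotype group has no labeled information to assign N/I status."""


class AmbiguousMappingError(InvscoreError):
    """Status vote for a haplotype group is tied; lists offending samples."""


class NoScorableSitesError(InvscoreError):
    """A sample has no site usable for any reference class."""


class DegenerateReferenceError(InvscoreError):
    """All reference sites carry zero weight; the panel cannot score."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP (or explicit indel) site.

    Attributes
    ----------
    id : str
        Variant identifier (e.g. rs id, or ``chrom:pos`` if absent).
    chrom : str
        Chromosome name.
    pos : int
        1-based position as printed in VCF.
    ref_allele, alt_allele : str
        Reference and alternate allele strings.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.id}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class GenotypeMatrix:
    """Hard genotype codes for a cohort over a set of sites.

    ``codes`` is an ``(n_samples, n_sites)`` int8 array of alt-allele
    counts with :data:`MISSING` for no-calls.
    """

    samples: list[str]
    sites: list[VariantSite]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        _check_unique(self.samples, "sample")
        _check_unique([s.id for s in self.sites], "site")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def call_rates(self) -> np.ndarray:
        """Per-site fraction of non-missing codes across samples."""
        return (self.codes != MISSING).mean(axis=0)

    def take_sites(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            codes=self.codes[:, idx].copy(),
        )

    def take_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=list(self.sites),
            codes=self.codes[idx, :].copy(),
        )


@dataclass
class GenotypeProbMatrix:
    """Genotype posterior probabilities P_i(t) for t in {0,1,2}.

    ``probs`` is ``(n_samples, n_sites, 3)``; each triple sums to 1 within
    1e-6 or is flagged missing as all-NaN.
    """

    samples: list[str]
    sites: list[VariantSite]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.samples), len(self.sites), 3):
            raise ValueError(
                f"probs shape {self.probs.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites x 3"
            )
        finite = np.isfinite(self.probs).all(axis=2)
        vals = self.probs[finite]
        if vals.size:
            if (vals < -1e-12).any():
                raise ValueError("negative genotype probability")
            sums = vals.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValueError("probability triple does not sum to 1")
        _check_unique(self.samples, "sample")
        _check_unique([s.id for s in self.sites], "site")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        """(n_samples, n_sites) boolean mask of missing triples."""
        return ~np.isfinite(self.probs).all(axis=2)


def one_hot_probs(gm: GenotypeMatrix) -> GenotypeProbMatrix:
    """Degenerate probability triples from hard codes (missing -> NaN)."""
    n, m = gm.codes.shape
    probs = np.full((n, m, 3), np.nan)
    called = gm.codes != MISSING
    ii, jj = np.nonzero(called)
    probs[ii, jj, :] = 0.0
    probs[ii, jj, gm.codes[ii, jj]] = 1.0
    return GenotypeProbMatrix(list(gm.samples), list(gm.sites), probs)


@dataclass(frozen=True, order=True)
class HaplotypeGenotypeLabel:
    """Unordered pair of haplotype-group symbols, e.g. AB.

    For J haplotype groups there are exactly J(J+1)/2 distinct labels.
    """

    first: str
    second: str

    def __post_init__(self) -> None:
        a, b = sorted((self.first, self.second))
        object.__setattr__(self, "first", a)
        object.__setattr__(self, "second", b)
        for g in (a, b):
            if g not in GROUP_SYMBOLS:
                raise ValueError(f"unknown haplotype-group symbol {g!r}")

    @property
    def groups(self) -> tuple[str, str]:
        return (self.first, self.second)

    @property
    def is_homozygous(self) -> bool:
        return self.first == self.second

    def dosage(self, group: str) -> int:
        """Copies of ``group`` carried under this label (0, 1 or 2)."""
        return (self.first == group) + (self.second == group)

    def __str__(self) -> str:
        return self.first + self.second

    @classmethod
    def parse(cls, text: str) -> "HaplotypeGenotypeLabel":
        if len(text) != 2:
            raise ValueError(f"cannot parse haplotype-genotype label {text!r}")
        return cls(text[0], text[1])


def enumerate_labels(J: int) -> list[HaplotypeGenotypeLabel]:
    """All J(J+1)/2 haplotype-genotype labels for J groups (sorted)."""
    if not 1 <= J <= len(GROUP_SYMBOLS):
        raise ValueError(f"J must be in 1..{len(GROUP_SYMBOLS)}, got {J}")
    syms = GROUP_SYMBOLS[:J]
    return sorted(
        HaplotypeGenotypeLabel(syms[a], syms[b])
        for a in range(J)
        for b in range(a, J)
    )
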