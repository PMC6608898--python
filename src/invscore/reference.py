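"""Inversion reference panels: per-class genotype frequencies and LD weights.

A panel stores, for every reference haplotype-genotype class k and SNP i,
the genotype frequencies f_ki(x) for x in {0,1,2}, plus one LD weight per
site (rho_i^2, the maximum squared correlation between the SNP and any
haplotype group's dosage across reference individuals), the map from
haplotype-genotype class to inversion-genotype, and bookkeeping metadata.
Panels serialize to a versioned JSON document with bit-exact round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import HaplotypeGenotypeLabel, VariantSite

FORMAT_VERSION = 1


@dataclass
class InversionReference:
    """Reference panel for one inversion.

    Attributes
    ----------
    inversion_id : str
    region : (chrom, start, end, build)
        1-based inclusive region plus a genome-build tag.
    sites : list of VariantSite
        N panel SNPs, the coordinate frame queries are harmonized to.
    classes : list of HaplotypeGenotypeLabel
        All J(J+1)/2 labels for the detected J, in sorted order; classes
        with zero reference samples are retained but flagged unsupported.
    freq : (K, N, 3) float array
        f_ki(x); NaN triple where class k has no data at site i.
    weights : (N,) float array in [0, 1]
        rho_i^2 per site.
    class_to_inv : dict label -> {NN, NI, II}
    class_sizes : (K,) int array
        M_k, reference individuals per class.
    concordance : float
        Percent agreement between mapped haplotype-genotypes and the
        experimental inversion-genotype labels of the reference cohort.
    """

    inversion_id: str
    region: tuple[str, int, int, str]
    sites: list[VariantSite]
    classes: list[HaplotypeGenotypeLabel]
    freq: np.ndarray
    weights: np.ndarray
    class_to_inv: dict[HaplotypeGenotypeLabel, str]
    class_sizes: np.ndarray
    concordance: float = float("nan")

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.class_sizes = np.asarray(self.class_sizes, dtype=int)
        K, N = len(self.classes), len(self.sites)
        if self.freq.shape != (K, N, 3):
            raise ValueError(f"freq shape {self.freq.shape}, expected {(K, N, 3)}")
        if self.weights.shape != (N,):
            raise ValueError("weights length mismatch")
        if self.class_sizes.shape != (K,):
            raise ValueError("class_sizes length mismatch")
        if ((self.weights < -1e-12) | (self.weights > 1 + 1e-12)).any():
            raise ValueError("weights must lie in [0, 1]")
        have = np.isfinite(self.freq).all(axis=2)
        sums = self.freq.sum(axis=2)
        if have.any() and np.abs(sums[have] - 1.0).max() > 1e-9:
            raise ValueError("frequency triple does not sum to 1")
        missing = set(self.classes) - set(self.class_to_inv)
        if missing:
            raise ValueError(f"classes without inversion-genotype map: {missing}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def supported(self) -> np.ndarray:
        """Boolean mask of classes with at least one reference sample."""
        return self.class_sizes >= 1

    # -- JSON serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "inversion_id": self.inversion_id,
            "region": {
                "chrom": self.region[0],
                "start": self.region[1],
                "end": self.region[2],
                "build": self.region[3],
            },
            "concordance": self.concordance,
            "sites": [
                {
                    "id": s.id,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref_allele,
                    "alt": s.alt_allele,
                }
                for s in self.sites
            ],
            "classes": [str(c) for c in self.classes],
            "class_sizes": self.class_sizes.tolist(),
            "class_to_inv": {str(k): v for k, v in self.class_to_inv.items()},
            # NaN is not valid JSON; encode no-data triples as null
            "freq": [
                [
                    None if not np.isfinite(triple).all() else triple.tolist()
                    for triple in row
                ]
                for row in self.freq
            ],
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InversionReference":
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported panel format version {d.get('format_version')}"
            )
        sites = [
            VariantSite(s["id"], s["chrom"], s["pos"], s["ref"], s["alt"])
            for s in d["sites"]
        ]
        classes = [HaplotypeGenotypeLabel.parse(c) for c in d["classes"]]
        K, N = len(classes), len(sites)
        freq = np.full((K, N, 3), np.nan)
        for k, row in enumerate(d["freq"]):
            for i, triple in enumerate(row):
                if triple is not None:
                    freq[k, i] = triple
        reg = d["region"]
        return cls(
            inversion_id=d["inversion_id"],
            region=(reg["chrom"], reg["start"], reg["end"], reg["build"]),
            sites=sites,
            classes=classes,
            freq=freq,
            weights=np.asarray(d["weights"], dtype=float),
            class_to_inv={
                HaplotypeGenotypeLabel.parse(k): v
                for k, v in d["class_to_inv"].items()
            },
            class_sizes=np.asarray(d["class_sizes"], dtype=int),
            concordance=d["concordance"],
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "InversionReference":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
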