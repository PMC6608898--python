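"""Synthetic cohorts with inversion-induced haplotype structure.

The generator produces the statistical structure the classifier assumes,
directly rather than through a forward-in-time population simulation:
J divergent ancestral haplotypes with suppressed recombination between
groups, within-group variation as independent per-site mutation, diploids
drawn by group frequency, plus trio pedigrees and coverage-degraded or
probabilistically-softened variants of the same data.

Defaults model a common autosomal inversion: two haplotype groups, an
inverted-allele frequency of 0.4, 100 SNPs with 30% of sites fixed
between groups, and a 1% per-site within-group mutation rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GenotypeMatrix,
    GenotypeProbMatrix,
    HaplotypeGenotypeLabel,
    VariantSite,
    one_hot_probs,
)

_DEFAULT_STATUS = {2: ("N", "I"), 3: ("N", "I", "N"), 4: ("N", "N", "I", "I")}
#: Default group frequencies; each default gives an inverted-allele
#: frequency of 0.4.  Builder group naming is cluster-size based and may
#: differ from the simulator's index-based naming; compare assignments
#: with evaluation.class_assignment_accuracy, which is naming-invariant.
_DEFAULT_FREQS = {
    2: (0.6, 0.4),
    3: (0.35, 0.4, 0.25),
    4: (0.35, 0.25, 0.25, 0.15),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic inversion cohort.

    Attributes
    ----------
    J : int
        Number of divergent haplotype groups (2-4).
    n_sites : int
        SNPs in the inverted region.
    divergence : float
        Fraction of sites at which each pair of ancestral haplotypes
        differs (fixed differences).
    theta : float
        Per-site mutation probability when a chromosome copies its
        group's ancestral haplotype (within-group polymorphism).
    group_freqs : tuple of float
        Haplotype-group frequencies, summing to 1.
    group_status : tuple of str
        Inversion status N or I per group.
    n_samples : int
    missing_rate : float
        i.i.d. genotype missingness.
    seed : int
        Mandatory; the cohort is fully reproducible from it.
    ancestral_seed : int, optional
        Draw the ancestral haplotypes from their own random stream so
        that cohorts with different ``seed`` values share the same
        underlying inversion (e.g. an independent query cohort for a
        panel built elsewhere).  A cohort with ``seed=s`` has the same
        ancestral haplotypes as any cohort with ``ancestral_seed=s``.
    recurrence_mode : bool
        Make the first haplotype group recurrent: each of its chromosomes
        is standard or inverted with probability 1/2, breaking the
        haplotype -> status map.
    """

    J: int = 2
    n_sites: int = 100
    divergence: float = 0.3
    theta: float = 0.01
    group_freqs: tuple[float, ...] | None = None
    group_status: tuple[str, ...] | None = None
    n_samples: int = 200
    missing_rate: float = 0.0
    seed: int = 0
    ancestral_seed: int | None = None
    recurrence_mode: bool = False

    def resolved(self) -> "SimConfig":
        """Fill group_freqs / group_status defaults for this J."""
        cfg = self
        if not 2 <= cfg.J <= 4:
            raise ValueError(f"J must be 2-4, got {cfg.J}")
        if cfg.group_freqs is None:
            cfg = replace(cfg, group_freqs=_DEFAULT_FREQS[cfg.J])
        if cfg.group_status is None:
            cfg = replace(cfg, group_status=_DEFAULT_STATUS[cfg.J])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 2 <= self.J <= 4:
            raise ValueError(f"J must be 2-4, got {self.J}")
        for name in ("divergence", "theta", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.group_freqs is not None:
            if len(self.group_freqs) != self.J:
                raise ValueError("group_freqs length must equal J")
            if abs(sum(self.group_freqs) - 1.0) > 1e-9:
                raise ValueError("group_freqs must sum to 1")
        if self.group_status is not None:
            if len(self.group_status) != self.J:
                raise ValueError("group_status length must equal J")
            if set(self.group_status) - {"N", "I"}:
                raise ValueError("group_status entries must be N or I")
            if not self.recurrence_mode and (
                "N" not in self.group_status or "I" not in self.group_status
            ):
                raise ValueError(
                    "need at least one N and one I group "
                    "(unless recurrence_mode)"
                )


@dataclass
class SimCohort:
    """A simulated cohort with full truth.

    ``truth`` maps sample -> (haplotype-genotype label, inversion
    genotype); ``chrom_groups``/``chrom_status`` record each chromosome's
    haplotype-group index and inversion status; ``haplotypes`` keeps the
    per-chromosome allele vectors so trios can transmit them faithfully.
    """

    gm: GenotypeMatrix
    truth: dict[str, tuple[HaplotypeGenotypeLabel, str]]
    chrom_groups: np.ndarray  # (n, 2) int
    chrom_status: np.ndarray  # (n, 2) '<U1'
    haplotypes: np.ndarray  # (n, 2, n_sites) int8
    config: SimConfig

    def truth_labels(self) -> dict[str, str]:
        """Experimental-style inversion-genotype label table."""
        return {s: t[1] for s, t in self.truth.items()}

    def truth_classes(self) -> dict[str, HaplotypeGenotypeLabel]:
        return {s: t[0] for s, t in self.truth.items()}


def _ancestral_haplotypes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """J ancestral haplotypes differing pairwise at ~divergence*n_sites sites.

    Group 0 is the all-ancestral haplotype.  For J=2 a single block of
    d = ceil(divergence*n_sites) sites carries the derived allele in
    group 1, so the pair differs at exactly d sites.  For J>=3 each
    non-shared group gets a private derived block of ceil(d/2) sites, so
    every pair differs at 2*ceil(d/2) ~ d sites.
    """
    d = int(np.ceil(cfg.divergence * cfg.n_sites))
    haps = np.zeros((cfg.J, cfg.n_sites), dtype=np.int8)
    if d < 1:
        warnings.warn(
            "divergence * n_sites < 1: haplotype groups are "
            "indistinguishable",
            stacklevel=3,
        )
        return haps
    if cfg.J == 2:
        block = rng.choice(cfg.n_sites, size=min(d, cfg.n_sites), replace=False)
        haps[1, block] = 1
        return haps
    b = int(np.ceil(d / 2))
    need = cfg.J * b
    if need > cfg.n_sites:
        raise ValueError(
            f"divergence {cfg.divergence} with J={cfg.J} needs "
            f"{need} private sites but only {cfg.n_sites} available"
        )
    sites = rng.choice(cfg.n_sites, size=need, replace=False)
    for g in range(cfg.J):
        haps[g, sites[g * b : (g + 1) * b]] = 1
    return haps


def _make_sites(n_sites: int) -> list[VariantSite]:
    return [
        VariantSite(f"snp{i:04d}", "1", 10_000 + 100 * i, "A", "G")
        for i in range(n_sites)
    ]


def _draw_chromosomes(
    cfg: SimConfig,
    ancestral: np.ndarray,
    n_chrom: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample chromosomes: group draw, ancestral copy, mutation, status."""
    groups = rng.choice(cfg.J, size=n_chrom, p=cfg.group_freqs)
    haps = ancestral[groups].copy()
    if cfg.theta > 0:
        flips = rng.random(haps.shape) < cfg.theta
        haps[flips] = 1 - haps[flips]
    status = np.array([cfg.group_status[g] for g in groups])
    if cfg.recurrence_mode:
        shared = groups == 0
        status[shared] = np.where(rng.random(shared.sum()) < 0.5, "N", "I")
    return groups, haps, status


def _assemble(
    cfg: SimConfig,
    sample_names: list[str],
    groups: np.ndarray,
    haps: np.ndarray,
    status: np.ndarray,
    rng: np.random.Generator,
) -> SimCohort:
    """Pair consecutive chromosomes into diploids and apply missingness."""
    n = len(sample_names)
    groups = groups.reshape(n, 2)
    status = status.reshape(n, 2)
    haps = haps.reshape(n, 2, cfg.n_sites)
    codes = haps.sum(axis=1).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = MISSING
    truth = {}
    for i, name in enumerate(sample_names):
        g1, g2 = sorted(groups[i])
        lab = HaplotypeGenotypeLabel("ABCD"[g1], "ABCD"[g2])
        n_inv = int((status[i] == "I").sum())
        truth[name] = (lab, ("NN", "NI", "II")[n_inv])
    gm = GenotypeMatrix(sample_names, _make_sites(cfg.n_sites), codes)
    return SimCohort(gm, truth, groups, status, haps, cfg)


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Simulate a diploid cohort under the divergent-haplotype model."""
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    anc_rng = (
        np.random.default_rng(cfg.ancestral_seed)
        if cfg.ancestral_seed is not None
        else rng
    )
    ancestral = _ancestral_haplotypes(cfg, anc_rng)
    names = [f"s{i:04d}" for i in range(cfg.n_samples)]
    groups, haps, status = _draw_chromosomes(cfg, ancestral, 2 * cfg.n_samples, rng)
    return _assemble(cfg, names, groups, haps, status, rng)


def simulate_trios(cfg: SimConfig, n_trios: int) -> tuple[SimCohort, pd.DataFrame]:
    """Simulate trios: parents as in simulate_cohort, each child inheriting
    one uniformly chosen chromosome from each parent (no recombination, no
    new mutation at meiosis).

    Returns the combined cohort (fathers, mothers, children) and a trio
    table with columns father/mother/child.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    anc_rng = (
        np.random.default_rng(cfg.ancestral_seed)
        if cfg.ancestral_seed is not None
        else rng
    )
    ancestral = _ancestral_haplotypes(cfg, anc_rng)
    n_parents = 2 * n_trios
    groups, haps, status = _draw_chromosomes(cfg, ancestral, 2 * n_parents, rng)
    groups = groups.reshape(n_parents, 2)
    haps = haps.reshape(n_parents, 2, cfg.n_sites)
    status = status.reshape(n_parents, 2)

    names = [f"fa{t:03d}" for t in range(n_trios)]
    names += [f"mo{t:03d}" for t in range(n_trios)]
    names += [f"ch{t:03d}" for t in range(n_trios)]
    pick = rng.integers(0, 2, size=(n_trios, 2))
    child_groups = np.empty((n_trios, 2), dtype=groups.dtype)
    child_haps = np.empty((n_trios, 2, cfg.n_sites), dtype=haps.dtype)
    child_status = np.empty((n_trios, 2), dtype=status.dtype)
    for t in range(n_trios):
        fa, mo = t, n_trios + t
        child_groups[t] = (groups[fa, pick[t, 0]], groups[mo, pick[t, 1]])
        child_haps[t, 0] = haps[fa, pick[t, 0]]
        child_haps[t, 1] = haps[mo, pick[t, 1]]
        child_status[t] = (status[fa, pick[t, 0]], status[mo, pick[t, 1]])

    all_groups = np.concatenate([groups, child_groups]).reshape(-1)
    all_haps = np.concatenate([haps, child_haps]).reshape(-1, cfg.n_sites)
    all_status = np.concatenate([status, child_status]).reshape(-1)
    cfg_all = replace(cfg, n_samples=3 * n_trios)
    cohort = _assemble(cfg_all, names, all_groups, all_haps, all_status, rng)
    trios = pd.DataFrame(
        {
            "father": names[:n_trios],
            "mother": names[n_trios : 2 * n_trios],
            "child": names[2 * n_trios :],
        }
    )
    return cohort, trios


def degrade_coverage(
    gm: GenotypeMatrix, fraction: float, seed: int
) -> GenotypeMatrix:
    """Retain a uniform random fraction of sites (SNP-coverage degradation,
    e.g. the 10%/20%/50%/75% grid used for robustness curves)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"coverage fraction must be in (0,1], got {fraction}")
    if fraction == 1.0:
        return gm
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(fraction * gm.n_sites)))
    keep = np.sort(rng.choice(gm.n_sites, size=n_keep, replace=False))
    return gm.take_sites(keep)


def degrade_probs(gm: GenotypeMatrix, w: float) -> GenotypeProbMatrix:
    """Soften hard genotypes into probability triples:
    (1-w) * one-hot + w * (1/3, 1/3, 1/3).  w=0 reproduces hard scoring
    exactly; w=1 is completely uninformative."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"softening weight must be in [0,1], got {w}")
    ohp = one_hot_probs(gm)
    probs = ohp.probs
    called = np.isfinite(probs).all(axis=2)
    probs[called] = (1.0 - w) * probs[called] + w / 3.0
    return GenotypeProbMatrix(ohp.samples, ohp.sites, probs)


def degrade(data: SimCohort | GenotypeMatrix, mode: str, param: float, seed: int = 0):
    """Dispatch to coverage or probability degradation."""
    gm = data.gm if isinstance(data, SimCohort) else data
    if mode == "coverage":
        return degrade_coverage(gm, param, seed)
    if mode == "probs":
        return degrade_probs(gm, param)
    raise ValueError(f"unknown degradation mode {mode!r}")
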