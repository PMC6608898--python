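"""Build inversion reference panels from a labeled cohort.

An ancient non-recurrent inversion suppresses recombination in
heterozygotes, so chromosomes in the region fall into J divergent
haplotype groups (J = 2-4), each fixed for one inversion status.  Diploid
individuals then occupy J(J+1)/2 haplotype-genotype classes that appear as
distinct clusters in the leading principal coordinates of the SNP
genotypes: 3 collinear clusters for J = 2, a 6-cluster triangle for J = 3,
a 10-cluster tetrahedron for J = 4, with every heterozygous cluster at the
midpoint of its two homozygous clusters.

The builder makes that visual heuristic algorithmic: classical MDS of
pairwise genotype distances, a Gaussian-mixture fit per candidate J, a
geometric pattern test (midpoint equidistance plus cluster separation),
mapping of clusters to experimental inversion-genotypes by vote, and
compilation of the per-class genotype frequency tables and per-SNP LD
weights used by the scorer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

from .reference import InversionReference
from .types import (
    MISSING,
    AmbiguousMappingError,
    DegenerateReferenceError,
    GenotypeMatrix,
    HaplotypeGenotypeLabel,
    UnmappableInversionError,
    UnresolvableGroupError,
    enumerate_labels,
)

logger = logging.getLogger(__name__)

#: MDS axes used per haplotype-group count: a line needs 1, a triangle 2,
#: a tetrahedron 3.
_DIMS_FOR_J = {2: 1, 3: 2, 4: 3}
_PATTERN_FOR_J = {2: "line-3", 3: "triangle-6", 4: "tetrahedron-10"}

#: Homozygous clusters must be separated by at least this many pooled
#: within-cluster standard deviations for a pattern to count as resolved.
MIN_SEPARATION = 3.0

#: A haplotype group's status vote must reach this majority fraction;
#: lower purity indicates haplotype sharing between inversion statuses
#: (the recurrent-inversion signature).
MIN_STATUS_PURITY = 0.7


@dataclass
class MDSResult:
    """Principal-coordinates embedding of a genotype matrix."""

    coords: np.ndarray  # samples x components
    eigenvalues: np.ndarray  # descending
    samples: list[str]


@dataclass
class ClusterModel:
    """A fitted haplotype-genotype clustering.

    ``equidistance_residual`` is the maximum relative deviation of a
    heterozygous-cluster centroid from the midpoint of its homozygous
    pair, relative to that pair's distance.
    """

    J: int
    n_components_used: int
    assignments: dict[str, HaplotypeGenotypeLabel]
    centroids: dict[HaplotypeGenotypeLabel, np.ndarray]
    pattern: str
    equidistance_residual: float
    bic: float = float("nan")


def _pairwise_manhattan(codes: np.ndarray) -> np.ndarray:
    """Mean per-site Manhattan distance with pairwise-complete missing data."""
    X = codes.astype(float)
    X[codes == MISSING] = np.nan
    n = X.shape[0]
    D = np.zeros((n, n))
    M = np.isfinite(X)
    for a in range(n):
        diff = np.abs(X[a] - X)  # nan where either missing
        shared = (M[a] & M).sum(axis=1)
        with np.errstate(invalid="ignore"):
            D[a] = np.where(shared > 0, np.nansum(diff, axis=1) / shared, np.nan)
    if np.isnan(D).any():
        # sample pairs with no shared sites: fall back to the global mean
        fill = np.nanmean(D)
        logger.warning("sample pairs with no shared sites; distance imputed")
        D = np.where(np.isnan(D), fill, D)
        np.fill_diagonal(D, 0.0)
    return D


def compute_mds(gm: GenotypeMatrix, n_components: int) -> MDSResult:
    """Classical MDS (principal coordinates) of genotype distances.

    Deterministic up to per-axis sign, which is fixed by forcing the
    largest-magnitude coordinate of each axis positive.
    """
    if gm.n_samples < 3:
        raise ValueError("MDS requires at least 3 samples")
    if gm.n_sites < 2:
        raise ValueError("MDS requires at least 2 sites")
    if gm.n_samples < n_components + 1:
        raise ValueError(
            f"{n_components} components require at least "
            f"{n_components + 1} samples, got {gm.n_samples}"
        )
    D = _pairwise_manhattan(gm.codes)
    n = D.shape[0]
    D2 = D**2
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * C @ D2 @ C
    evals, evecs = np.linalg.eigh(B)  # ascending
    order = np.argsort(evals)[::-1][:n_components]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = evecs * np.sqrt(np.clip(evals, 0.0, None))
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return MDSResult(
        coords=coords,
        eigenvalues=np.clip(evals, 0.0, None),
        samples=list(gm.samples),
    )


def _pattern_fit(
    means: np.ndarray, J: int, tol: float
) -> tuple[list[int], dict[int, tuple[int, int]], float] | None:
    """Search for a simplex-with-midpoints geometry among K centroids.

    Returns (homozygous component indices sorted, het component ->
    homozygous pair, max relative residual), or None if no arrangement
    satisfies ``tol``.
    """
    K = means.shape[0]
    best = None
    for homo in itertools.combinations(range(K), J):
        het = [c for c in range(K) if c not in homo]
        pairs = list(itertools.combinations(homo, 2))
        if len(het) != len(pairs):
            continue
        midpoints = np.array([(means[a] + means[b]) / 2 for a, b in pairs])
        pair_dist = np.array(
            [np.linalg.norm(means[a] - means[b]) for a, b in pairs]
        )
        if (pair_dist <= 0).any():
            continue
        cost = np.linalg.norm(
            means[het][:, None, :] - midpoints[None, :, :], axis=2
        )
        rel = cost / pair_dist[None, :]
        row, col = linear_sum_assignment(rel)
        resid = rel[row, col].max() if len(row) else 0.0
        if resid <= tol and (best is None or resid < best[2]):
            matching = {het[r]: pairs[c] for r, c in zip(row, col)}
            best = (sorted(homo), matching, float(resid))
    return best


def _separation(
    means: np.ndarray, covs: np.ndarray, counts: np.ndarray, homo: list[int]
) -> float:
    """Minimum homozygous-pair distance in pooled within-cluster SD units."""
    spread = np.sqrt(np.array([np.trace(c) / c.shape[0] for c in covs]))
    w = counts / counts.sum()
    pooled = float((w * spread).sum())
    dmin = min(
        np.linalg.norm(means[a] - means[b])
        for a, b in itertools.combinations(homo, 2)
    )
    return dmin / max(pooled, 1e-12)


def _hard_assignment_bic(coords: np.ndarray, labels: np.ndarray) -> float:
    """BIC of a Gaussian mixture defined by hard cluster assignments.

    Evaluated in a common coordinate space so that models fitted on
    different numbers of MDS axes can be compared.
    """
    n, d = coords.shape
    uniq = np.unique(labels)
    logl = 0.0
    n_params = 0
    for u in uniq:
        pts = coords[labels == u]
        m = pts.mean(axis=0)
        cov = np.cov(pts.T, bias=True).reshape(d, d) + 1e-6 * np.eye(d)
        sign, logdet = np.linalg.slogdet(cov)
        inv = np.linalg.inv(cov)
        diff = pts - m
        quad = np.einsum("ij,jk,ik->i", diff, inv, diff)
        pi = len(pts) / n
        logl += np.sum(
            np.log(pi) - 0.5 * (d * np.log(2 * np.pi) + logdet + quad)
        )
        n_params += d + d * (d + 1) // 2 + 1
    return float(-2 * logl + n_params * np.log(n))


def fit_haplotype_genotype_clusters(
    mds: MDSResult,
    candidate_J: tuple[int, ...] = (2, 3, 4),
    tol_equidistance: float = 0.35,
    seed: int = 0,
    min_separation: float = MIN_SEPARATION,
) -> ClusterModel:
    """Detect the haplotype-group count J and assign samples to classes.

    For each candidate J (ascending) a Gaussian mixture with J(J+1)/2
    components is fitted on the first 1/2/3 MDS axes (for J = 2/3/4), with
    20 k-means++ restarts under a fixed seed.  A candidate passes when J
    of its centroids form a simplex whose remaining centroids sit within
    ``tol_equidistance`` (relative to the homozygous pair distance) of the
    pairwise midpoints, and the homozygous clusters are separated by at
    least ``min_separation`` pooled within-cluster standard deviations.
    Among passing candidates the one with the lowest hard-assignment BIC
    (computed on a common axis space) wins; ties go to the smallest J.
    Homozygous clusters are named A-D by descending size.

    Raises
    ------
    UnmappableInversionError
        If no candidate J produces the expected cluster pattern.
    """
    candidates = sorted(candidate_J)
    for J in candidates:
        if J not in _DIMS_FOR_J:
            raise ValueError(f"candidate J must be in {{2,3,4}}, got {J}")
    max_dims = max(_DIMS_FOR_J[J] for J in candidates)
    if mds.coords.shape[1] < max_dims:
        raise ValueError(
            f"need {max_dims} MDS components for candidate_J={candidates}, "
            f"got {mds.coords.shape[1]}"
        )
    common = mds.coords[:, :max_dims]

    fits: list[tuple[int, ClusterModel]] = []
    for J in candidates:
        d = _DIMS_FOR_J[J]
        K = J * (J + 1) // 2
        X = mds.coords[:, :d]
        if len(mds.samples) < K + 1:
            continue
        gmm = GaussianMixture(
            n_components=K,
            covariance_type="full",
            n_init=20,
            init_params="k-means++",
            random_state=seed,
            reg_covar=1e-6,
        ).fit(X)
        comp = gmm.predict(X)
        counts = np.bincount(comp, minlength=K)
        if (counts == 0).any():
            continue  # an empty mixture component cannot anchor the pattern
        hit = _pattern_fit(gmm.means_, J, tol_equidistance)
        if hit is None:
            continue
        homo, het_pairs, resid = hit
        if _separation(gmm.means_, gmm.covariances_, counts, homo) < min_separation:
            continue
        # name homozygous clusters A.. by descending size
        homo_sorted = sorted(homo, key=lambda c: (-counts[c], c))
        sym = {c: "ABCD"[r] for r, c in enumerate(homo_sorted)}
        comp_label: dict[int, HaplotypeGenotypeLabel] = {}
        for c in homo:
            comp_label[c] = HaplotypeGenotypeLabel(sym[c], sym[c])
        for c, (a, b) in het_pairs.items():
            comp_label[c] = HaplotypeGenotypeLabel(sym[a], sym[b])
        assignments = {
            s: comp_label[comp[i]] for i, s in enumerate(mds.samples)
        }
        centroids = {comp_label[c]: gmm.means_[c].copy() for c in range(K)}
        bic = _hard_assignment_bic(common, comp)
        fits.append(
            (
                J,
                ClusterModel(
                    J=J,
                    n_components_used=d,
                    assignments=assignments,
                    centroids=centroids,
                    pattern=_PATTERN_FOR_J[J],
                    equidistance_residual=resid,
                    bic=bic,
                ),
            )
        )
    if not fits:
        raise UnmappableInversionError(
            "no haplotype-genotype cluster pattern found for "
            f"candidate J in {candidates}; the region does not show the "
            "divergent-haplotype structure required for score-based "
            "inversion genotyping"
        )
    fits.sort(key=lambda t: (t[1].bic, t[0]))
    return fits[0][1]


def _normalize_label(lab: str) -> str:
    """Hemizygous N/I labels are treated as their homozygous equivalent."""
    return {"N": "NN", "I": "II"}.get(lab, lab)


def map_clusters_to_inversion_genotypes(
    cm: ClusterModel,
    labels: dict[str, str],
    min_status_purity: float = MIN_STATUS_PURITY,
) -> tuple[dict[HaplotypeGenotypeLabel, str], float]:
    """Assign inversion status N/I to each haplotype group by vote.

    A labeled sample in homozygous class {g,g} votes for g: NN votes N,
    II votes I (an NI label on a homozygous class is discordant and casts
    no vote).  Groups without homozygote votes are resolved from
    heterozygous labeled samples once their partner group is known.

    Returns the class -> inversion-genotype map and the concordance
    (percent of labeled, clustered samples whose mapped genotype equals
    their experimental label).

    Raises
    ------
    UnresolvableGroupError
        A group has no labeled information.
    AmbiguousMappingError
        A group's vote is exactly tied.
    UnmappableInversionError
        A group's majority falls below ``min_status_purity``: its
        haplotype occurs on both standard and inverted chromosomes, the
        recurrent-inversion failure mode.
    """
    groups = sorted({g for lab in cm.assignments.values() for g in lab.groups})
    labeled = {
        s: _normalize_label(labels[s]) for s in cm.assignments if s in labels
    }
    if not labeled:
        raise UnresolvableGroupError("no labeled samples among clustered samples")

    votes: dict[str, dict[str, list[str]]] = {
        g: {"N": [], "I": []} for g in groups
    }
    for s, lab in labeled.items():
        cls = cm.assignments[s]
        if cls.is_homozygous:
            g = cls.first
            if lab == "NN":
                votes[g]["N"].append(s)
            elif lab == "II":
                votes[g]["I"].append(s)
            # NI on a homozygous class: discordant, no vote

    status: dict[str, str] = {}
    for g in groups:
        n, i = len(votes[g]["N"]), len(votes[g]["I"])
        if n + i == 0:
            continue
        maj, tot = max(n, i), n + i
        # with substantial conflicting evidence the haplotype is shared
        # between inversion statuses (recurrent inversion); a tie among a
        # handful of labels is merely ambiguous
        if tot >= 5 and maj / tot < min_status_purity:
            raise UnmappableInversionError(
                f"haplotype group {g} is labeled standard in {n} and "
                f"inverted in {i} homozygous reference samples; the "
                "haplotype is shared between inversion statuses "
                "(recurrent inversion)"
            )
        if n == i:
            raise AmbiguousMappingError(
                f"status vote tied for haplotype group {g}: "
                f"{votes[g]['N'] + votes[g]['I']}"
            )
        status[g] = "N" if n > i else "I"

    # resolve remaining groups from heterozygous labeled samples
    changed = True
    while changed:
        changed = False
        for s, lab in labeled.items():
            cls = cm.assignments[s]
            if cls.is_homozygous:
                continue
            g, h = cls.groups
            for a, b in ((g, h), (h, g)):
                if a in status or b not in status:
                    continue
                if lab == "NN":
                    inferred = "N"
                elif lab == "II":
                    inferred = "I"
                else:  # NI: the unresolved group carries the other allele
                    inferred = "I" if status[b] == "N" else "N"
                status[a] = inferred
                changed = True

    unresolved = [g for g in groups if g not in status]
    if unresolved:
        raise UnresolvableGroupError(
            f"no labeled information resolves haplotype group(s) {unresolved}"
        )

    class_to_inv: dict[HaplotypeGenotypeLabel, str] = {}
    for cls in enumerate_labels(len(groups)):
        pair = sorted(status[g] for g in cls.groups)
        class_to_inv[cls] = "".join(pair) if pair != ["I", "N"] else "NI"

    agree = sum(
        1
        for s, lab in labeled.items()
        if class_to_inv[cm.assignments[s]] == lab
    )
    concordance = 100.0 * agree / len(labeled)
    return class_to_inv, concordance


def compute_site_weights(
    gm: GenotypeMatrix, assignments: dict[str, HaplotypeGenotypeLabel]
) -> np.ndarray:
    """LD weight rho_i^2 per site: max squared correlation between the
    SNP's genotype codes and any haplotype group's dosage.

    For two haplotype groups this reduces to the LD R^2 between the SNP
    and the inversion-allele dosage.  Sites with zero genotype or dosage
    variance (or no called genotypes) get weight 0.
    """
    rows = [i for i, s in enumerate(gm.samples) if s in assignments]
    if not rows:
        raise ValueError("no assigned samples present in genotype matrix")
    sub = gm.codes[rows]
    labs = [assignments[gm.samples[i]] for i in rows]
    groups = sorted({g for lab in labs for g in lab.groups})

    X = sub.astype(float)
    X[sub == MISSING] = np.nan
    M = np.isfinite(X)
    n_called = M.sum(axis=0)
    if (n_called == 0).any():
        logger.warning(
            "%d sites have no called genotypes; weight set to 0",
            int((n_called == 0).sum()),
        )
    weights = np.zeros(gm.n_sites)
    X0 = np.nan_to_num(X)
    for g in groups:
        d = np.array([lab.dosage(g) for lab in labs], dtype=float)
        n = n_called.astype(float)
        sx = X0.sum(axis=0)
        sx2 = (X0**2).sum(axis=0)
        sd = d @ M
        sd2 = (d**2) @ M
        sxd = d @ X0
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxd - sx * sd / n
            varx = sx2 - sx**2 / n
            vard = sd2 - sd**2 / n
            r2 = np.where((varx > 1e-12) & (vard > 1e-12), cov**2 / (varx * vard), 0.0)
        r2 = np.nan_to_num(r2)
        weights = np.maximum(weights, r2)
    return np.clip(weights, 0.0, 1.0)


def build_reference(
    gm: GenotypeMatrix,
    cm: ClusterModel,
    class_to_inv: dict[HaplotypeGenotypeLabel, str],
    concordance: float,
    region: tuple[str, int, int, str],
    inversion_id: str,
    weights: np.ndarray | None = None,
) -> InversionReference:
    """Compile frequency tables and weights into an InversionReference.

    f_ki(x) = n_k(x) / M_{k,i}, where M_{k,i} counts the non-missing codes
    of class k at site i (the per-class denominator, made per-site to
    tolerate missing reference genotypes).  No smoothing is applied: a
    genotype unseen in class k has frequency exactly 0 and contributes
    nothing to that class's score.
    """
    classes = enumerate_labels(cm.J)
    K, N = len(classes), gm.n_sites
    sample_idx = {s: i for i, s in enumerate(gm.samples)}
    members: dict[HaplotypeGenotypeLabel, list[int]] = {c: [] for c in classes}
    for s, lab in cm.assignments.items():
        if s in sample_idx:
            members[lab].append(sample_idx[s])

    freq = np.full((K, N, 3), np.nan)
    sizes = np.zeros(K, dtype=int)
    for k, cls in enumerate(classes):
        idx = members[cls]
        sizes[k] = len(idx)
        if not idx:
            continue
        sub = gm.codes[idx]
        counts = np.stack([(sub == x).sum(axis=0) for x in (0, 1, 2)], axis=1)
        m_ki = counts.sum(axis=1)  # non-missing members per site
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts / m_ki[:, None]
        freq[k] = f  # sites with m_ki == 0 stay NaN (no data)

    if weights is None:
        weights = compute_site_weights(gm, cm.assignments)
    if (np.asarray(weights) <= 0).all():
        raise DegenerateReferenceError(
            f"all sites have zero LD weight for inversion {inversion_id!r}"
        )
    return InversionReference(
        inversion_id=inversion_id,
        region=region,
        sites=list(gm.sites),
        classes=classes,
        freq=freq,
        weights=np.asarray(weights, dtype=float),
        class_to_inv=dict(class_to_inv),
        class_sizes=sizes,
        concordance=concordance,
    )


def build_panel(
    gm: GenotypeMatrix,
    labels: dict[str, str],
    inversion_id: str = "inversion",
    build: str = "synthetic",
    candidate_J: tuple[int, ...] = (2, 3, 4),
    tol_equidistance: float = 0.35,
    seed: int = 0,
) -> tuple[InversionReference, ClusterModel]:
    """Full builder pipeline: MDS -> clustering -> label mapping -> panel."""
    max_dims = max(_DIMS_FOR_J[J] for J in sorted(candidate_J))
    n_comp = min(max_dims, gm.n_samples - 1)
    mds = compute_mds(gm, n_components=n_comp)
    cm = fit_haplotype_genotype_clusters(
        mds, candidate_J=tuple(candidate_J), tol_equidistance=tol_equidistance,
        seed=seed,
    )
    class_to_inv, concordance = map_clusters_to_inversion_genotypes(cm, labels)
    chroms = [s.chrom for s in gm.sites]
    region = (chroms[0], min(s.pos for s in gm.sites), max(s.pos for s in gm.sites), build)
    ref = build_reference(
        gm, cm, class_to_inv, concordance, region, inversion_id
    )
    return ref, cm
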