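"""Classifier evaluation and population-genetic summaries.

Leave-one-out accuracy, robustness to SNP-coverage and reference-panel
size, Mendelian transmission errors in trios, genotype-frequency
summaries with Wilson confidence intervals and an exact Hardy-Weinberg
test, and inheritance-model encodings for export to association tools.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from .builder import (
    ClusterModel,
    build_panel,
    build_reference,
    compute_site_weights,
    map_clusters_to_inversion_genotypes,
)
from .reference import InversionReference
from .scorer import ScoreResult, classify, genotype_cohort, score_sample
from .simdata import SimCohort, degrade_coverage
from .types import (
    NO_CALL,
    GenotypeMatrix,
    HaplotypeGenotypeLabel,
    InvscoreError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# accuracy helpers


def class_assignment_accuracy(
    truth: dict[str, HaplotypeGenotypeLabel],
    predicted: dict[str, HaplotypeGenotypeLabel],
) -> float:
    """Fraction of samples whose predicted haplotype-genotype matches
    truth, maximized over haplotype-group relabelings.

    Group symbols are arbitrary names (the builder assigns them by
    cluster size, a simulator by group index), so agreement is assessed
    up to a bijection of the symbols.
    """
    common = sorted(set(truth) & set(predicted))
    if not common:
        raise ValueError("no samples in common")
    t_groups = sorted({g for s in common for g in truth[s].groups})
    p_groups = sorted({g for s in common for g in predicted[s].groups})
    k = max(len(t_groups), len(p_groups))
    t_groups += [f"_t{i}" for i in range(k - len(t_groups))]
    p_groups += [f"_p{i}" for i in range(k - len(p_groups))]
    best = 0
    for perm in itertools.permutations(p_groups):
        m = dict(zip(t_groups, perm))
        hits = sum(
            1
            for s in common
            if tuple(sorted(m[g] for g in truth[s].groups))
            == predicted[s].groups
        )
        best = max(best, hits)
    return best / len(common)


def call_accuracy(
    results: list[ScoreResult], truth_labels: dict[str, str]
) -> float:
    """Fraction of correct inversion-genotype calls; NO_CALL counts as an
    error (accuracy judges the classifier, not only its called subset)."""
    evaluated = [r for r in results if r.sample in truth_labels]
    if not evaluated:
        raise ValueError("no evaluated samples")
    hits = sum(1 for r in evaluated if r.inv_genotype == truth_labels[r.sample])
    return hits / len(evaluated)


# ---------------------------------------------------------------------------
# leave-one-out


def loo_accuracy(
    gm: GenotypeMatrix,
    labels: dict[str, str],
    inversion_id: str = "inversion",
    candidate_J: tuple[int, ...] = (2, 3, 4),
    seed: int = 0,
    min_margin: float = 0.0,
) -> float:
    """Leave-one-out inversion-genotype accuracy.

    Clusters are fitted once on the full cohort (mirroring the use of
    fixed experimental labels); for each labeled sample the frequency
    tables and LD weights are rebuilt from all remaining samples and the
    held-out sample is classified against them.  NO_CALL counts as an
    error.  Holdouts that would empty a reference class are skipped with
    a warning.
    """
    held = [s for s in gm.samples if s in labels]
    if len(held) < 2:
        raise ValueError("leave-one-out needs at least 2 labeled samples")
    ref_full, cm = build_panel(
        gm, labels, inversion_id=inversion_id, candidate_J=candidate_J, seed=seed
    )
    class_to_inv = ref_full.class_to_inv
    sample_idx = {s: i for i, s in enumerate(gm.samples)}

    n_correct = 0
    n_eval = 0
    for s in held:
        rest_assign = {k: v for k, v in cm.assignments.items() if k != s}
        cls = cm.assignments.get(s)
        if cls is not None and not any(v == cls for v in rest_assign.values()):
            warnings.warn(
                f"holdout {s} would empty class {cls}; skipped", stacklevel=2
            )
            continue
        keep = [i for t, i in sample_idx.items() if t != s]
        gm_rest = gm.take_samples(keep)
        try:
            ref = build_reference(
                gm_rest,
                _with_assignments(cm, rest_assign),
                class_to_inv,
                ref_full.concordance,
                ref_full.region,
                inversion_id,
            )
            H = score_sample(gm.codes[sample_idx[s]], ref)
            res = classify(H, ref, min_margin=min_margin, sample=s)
        except InvscoreError as exc:
            logger.info("holdout %s: %s", s, exc)
            res = None
        n_eval += 1
        if res is not None and res.inv_genotype == labels[s]:
            n_correct += 1
    if n_eval == 0:
        raise ValueError("no evaluable holdouts")
    return n_correct / n_eval


def _with_assignments(cm: ClusterModel, assignments) -> ClusterModel:
    return ClusterModel(
        J=cm.J,
        n_components_used=cm.n_components_used,
        assignments=assignments,
        centroids=cm.centroids,
        pattern=cm.pattern,
        equidistance_residual=cm.equidistance_residual,
        bic=cm.bic,
    )


# ---------------------------------------------------------------------------
# robustness curves


def reference_from_truth(
    gm: GenotypeMatrix,
    classes: dict[str, HaplotypeGenotypeLabel],
    class_to_inv: dict[HaplotypeGenotypeLabel, str],
    inversion_id: str = "inversion",
) -> InversionReference:
    """Build a panel directly from known class assignments (no clustering),
    as when references carry experimental haplotype-genotypes."""
    J = len({g for lab in classes.values() for g in lab.groups})
    cm = ClusterModel(
        J=J,
        n_components_used=0,
        assignments=dict(classes),
        centroids={},
        pattern={2: "line-3", 3: "triangle-6", 4: "tetrahedron-10"}[J],
        equidistance_residual=0.0,
    )
    chrom = gm.sites[0].chrom
    region = (chrom, min(s.pos for s in gm.sites), max(s.pos for s in gm.sites), "synthetic")
    return build_reference(gm, cm, class_to_inv, float("nan"), region, inversion_id)


def truth_class_to_inv(cohort: SimCohort) -> dict[HaplotypeGenotypeLabel, str]:
    """Class -> inversion-genotype map implied by the simulator's
    group-status configuration."""
    cfg = cohort.config.resolved()
    out = {}
    J = cfg.J
    for a in range(J):
        for b in range(a, J):
            lab = HaplotypeGenotypeLabel("ABCD"[a], "ABCD"[b])
            n_inv = (cfg.group_status[a] == "I") + (cfg.group_status[b] == "I")
            out[lab] = ("NN", "NI", "II")[n_inv]
    return out


def robustness_curves(
    cohort: SimCohort,
    coverage_grid: tuple[float, ...] = (0.1, 0.2, 0.5, 0.75, 1.0),
    refs_per_class_grid: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_reps: int = 200,
    seed: int = 0,
    min_margin: float = 0.0,
) -> pd.DataFrame:
    """Mean classification accuracy over a grid of SNP-coverage fractions
    and reference-panel sizes.

    For each condition and replicate, a random subset of sites and of
    ``refs_per_class`` reference individuals per class is drawn, the
    frequency tables and weights rebuilt from those references (class
    assignments taken from the simulator truth), and all non-reference
    samples classified.  Returns a table with mean and SD accuracy per
    condition.
    """
    if not coverage_grid or not refs_per_class_grid:
        raise ValueError("grids must be non-empty")
    truth_cls = cohort.truth_classes()
    truth_inv = cohort.truth_labels()
    c2i = truth_class_to_inv(cohort)
    by_class: dict[HaplotypeGenotypeLabel, list[str]] = {}
    for s, lab in truth_cls.items():
        by_class.setdefault(lab, []).append(s)
    rng = np.random.default_rng(seed)

    rows = []
    for cov, rpc in itertools.product(coverage_grid, refs_per_class_grid):
        if rpc > min(len(v) for v in by_class.values()):
            warnings.warn(
                f"refs_per_class={rpc} exceeds smallest class; condition "
                "skipped",
                stacklevel=2,
            )
            continue
        accs = []
        for _ in range(n_reps):
            sub = degrade_coverage(
                cohort.gm, cov, seed=int(rng.integers(2**31))
            )
            ref_samples: list[str] = []
            for lab, mem in by_class.items():
                pick = rng.choice(len(mem), size=rpc, replace=False)
                ref_samples += [mem[i] for i in pick]
            ref_set = set(ref_samples)
            idx_ref = [i for i, s in enumerate(sub.samples) if s in ref_set]
            idx_query = [i for i, s in enumerate(sub.samples) if s not in ref_set]
            try:
                panel = reference_from_truth(
                    sub.take_samples(idx_ref),
                    {s: truth_cls[s] for s in ref_samples},
                    c2i,
                )
            except InvscoreError:
                # e.g. every retained site monomorphic in the drawn
                # references: nothing is scorable, so no sample is called
                accs.append(0.0)
                continue
            results = genotype_cohort(
                sub.take_samples(idx_query), panel, min_margin=min_margin
            )
            accs.append(call_accuracy(results, truth_inv))
        rows.append(
            {
                "coverage": cov,
                "refs_per_class": rpc,
                "n_reps": n_reps,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mendelian errors


def _alleles(genotype: str) -> tuple[str, str]:
    return (genotype[0], genotype[1])


def is_mendelian_consistent(father: str, mother: str, child: str) -> bool:
    """Whether the child's inversion genotype is possible given the
    parents', treating N and I as codominant alleles."""
    fa, mo, ch = _alleles(father), _alleles(mother), _alleles(child)
    return any(
        sorted((a, b)) == sorted(ch) for a in fa for b in mo
    )


def mendelian_error_rate(
    calls: list[ScoreResult] | dict[str, str], trios: pd.DataFrame
) -> float:
    """Proportion of evaluable trios with a Mendelian-impossible child
    call.  Trios containing any NO_CALL are excluded from the
    denominator: transmission errors judge called genotypes, not call
    rate."""
    if isinstance(calls, dict):
        geno = calls
    else:
        geno = {r.sample: r.inv_genotype for r in calls}
    n_err = 0
    n_eval = 0
    for row in trios.itertuples(index=False):
        g = [geno.get(x, NO_CALL) for x in (row.father, row.mother, row.child)]
        if NO_CALL in g:
            continue
        n_eval += 1
        if not is_mendelian_consistent(*g):
            n_err += 1
    if n_eval == 0:
        raise ValueError("no evaluable trios (all contain NO_CALL)")
    return n_err / n_eval


# ---------------------------------------------------------------------------
# frequency summaries


def hwe_exact_pvalue(n_nn: int, n_ni: int, n_ii: int) -> float:
    """Exact Hardy-Weinberg test on genotype counts.

    The p-value sums, over all heterozygote counts compatible with the
    observed allele counts, the conditional probabilities that do not
    exceed the observed count's probability (no mid-p correction).
    """
    n = n_nn + n_ni + n_ii
    if n == 0:
        raise ValueError("no genotype counts")
    n_rare = min(2 * n_nn + n_ni, 2 * n_ii + n_ni)  # minor allele count
    if n_rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        # P(het | n, n_rare) under HWE, via the standard hypergeometric-
        # style conditional distribution
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            het * np.log(2)
            + gammaln(n + 1)
            - gammaln(het + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logs = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_ni][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


@dataclass
class FrequencySummary:
    """Genotype counts, proportions with 95% CIs, inverted-allele
    frequency, and the Hardy-Weinberg exact-test p-value."""

    counts: dict[str, int]
    proportions: dict[str, float]
    ci: dict[str, tuple[float, float]]
    allele_freq_inverted: float
    allele_freq_ci: tuple[float, float]
    hwe_pvalue: float
    n_called: int
    n_no_call: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in ("NN", "NI", "II"):
            lo, hi = self.ci[g]
            rows.append(
                {
                    "genotype": g,
                    "count": self.counts[g],
                    "proportion": self.proportions[g],
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def summarize_genotypes(
    calls: list[ScoreResult] | list[str], alpha: float = 0.05
) -> FrequencySummary:
    """Summarize called inversion genotypes.

    Proportions get Wilson score intervals at level 1 - alpha; the
    inverted-allele frequency is (2 n_II + n_NI) / (2 n_called) with its
    own Wilson interval on allele counts; HWE is tested exactly.
    """
    geno = [
        r.inv_genotype if isinstance(r, ScoreResult) else r for r in calls
    ]
    called = [g for g in geno if g in ("NN", "NI", "II")]
    if not called:
        raise ValueError("no called samples")
    counts = {g: called.count(g) for g in ("NN", "NI", "II")}
    n = len(called)
    proportions = {g: counts[g] / n for g in counts}
    ci = {
        g: tuple(
            float(x)
            for x in proportion_confint(counts[g], n, alpha=alpha, method="wilson")
        )
        for g in counts
    }
    n_i_alleles = 2 * counts["II"] + counts["NI"]
    af = n_i_alleles / (2 * n)
    af_ci = tuple(
        float(x)
        for x in proportion_confint(n_i_alleles, 2 * n, alpha=alpha, method="wilson")
    )
    return FrequencySummary(
        counts=counts,
        proportions=proportions,
        ci=ci,
        allele_freq_inverted=af,
        allele_freq_ci=af_ci,
        hwe_pvalue=hwe_exact_pvalue(counts["NN"], counts["NI"], counts["II"]),
        n_called=n,
        n_no_call=len(geno) - n,
    )


# ---------------------------------------------------------------------------
# inheritance-model encoding

_ENCODINGS = {
    "additive": {"NN": 0, "NI": 1, "II": 2},
    "dominant": {"NN": 0, "NI": 1, "II": 1},
    "recessive": {"NN": 0, "NI": 0, "II": 1},
}


def encode_inheritance(
    calls: list[ScoreResult], model: str = "additive"
) -> pd.DataFrame:
    """Numeric inversion-genotype coding under an inheritance model, for
    export as a covariate to external association tools.  NO_CALL becomes
    missing (NaN)."""
    if model not in _ENCODINGS:
        raise ValueError(f"model must be one of {sorted(_ENCODINGS)}")
    enc = _ENCODINGS[model]
    return pd.DataFrame(
        {
            "sample": [r.sample for r in calls],
            model: [enc.get(r.inv_genotype, np.nan) for r in calls],
        }
    )
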