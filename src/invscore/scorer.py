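"""LD-weighted similarity scoring and inversion-genotype classification.

For a subject with genotype codes s_1..s_L at the panel SNPs, the score
against reference class k is

    H_k = sum_{i in L} f_ki(s_i) * rho_i^2  /  sum_{i in L} rho_i^2

where L is the set of sites that are non-missing in the subject, have
positive LD weight, and have frequency data for class k; the numerator
and denominator of each class run over the same L.  For probabilistic
(imputed) genotypes f_ki(s_i) is replaced by the expectation
sum_t P_i(t) f_ki(t).  H_k is a weighted average of frequencies and thus
always lies in [0, 1]; the subject is assigned the class with the highest
score, and the inversion genotype follows from the panel's class map.
Each individual is classified independently, so cohorts can be processed
in batches of any size without changing results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reference import InversionReference
from .types import (
    MISSING,
    NO_CALL,
    GenotypeMatrix,
    GenotypeProbMatrix,
    HaplotypeGenotypeLabel,
    NoScorableSitesError,
)

logger = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    """Classification outcome for one sample.

    ``H`` has one entry per panel class; NaN marks classes that could not
    be scored (unsupported, or no usable sites).  ``margin`` is the best
    minus second-best defined score (0 when only one class is defined).
    """

    sample: str
    H: np.ndarray
    classes: list[HaplotypeGenotypeLabel]
    best_class: HaplotypeGenotypeLabel | str
    margin: float
    n_sites_used: int
    inv_genotype: str
    reason: str = ""

    @property
    def is_called(self) -> bool:
        return self.inv_genotype != NO_CALL

    def scores_by_class(self) -> dict[str, float]:
        return {str(c): float(h) for c, h in zip(self.classes, self.H)}


def _class_site_masks(ref: InversionReference) -> np.ndarray:
    """(K, N) mask: class k has frequency data and positive weight at i."""
    have = np.isfinite(ref.freq).all(axis=2)
    return have & (ref.weights > 0)[None, :] & ref.supported[:, None]


def score_matrix(
    codes: np.ndarray, ref: InversionReference
) -> tuple[np.ndarray, np.ndarray]:
    """Score a (n_samples, N) hard-code array against every panel class.

    Returns (H, n_sites): H is (n_samples, K) with NaN for undefined
    class scores; n_sites is (n_samples, K) counts of sites used.
    """
    codes = np.atleast_2d(np.asarray(codes))
    n, N = codes.shape
    if N != ref.n_sites:
        raise ValueError(f"expected {ref.n_sites} sites, got {N}")
    K = len(ref.classes)
    class_mask = _class_site_masks(ref)  # (K, N)
    called = codes != MISSING  # (n, N)
    safe = np.where(called, codes, 0)
    H = np.full((n, K), np.nan)
    n_sites = np.zeros((n, K), dtype=int)
    for k in range(K):
        if not ref.supported[k]:
            continue
        # f_k(s_i) gathered per sample/site
        fk = ref.freq[k][np.arange(N)[None, :], safe]  # (n, N)
        use = called & class_mask[k][None, :]
        # per-row reductions keep results bit-identical across batch sizes
        wsum = (use * ref.weights[None, :]).sum(axis=1)
        num = (np.where(use, fk, 0.0) * ref.weights[None, :]).sum(axis=1)
        ok = wsum > 0
        H[ok, k] = num[ok] / wsum[ok]
        n_sites[:, k] = use.sum(axis=1)
    return H, n_sites


def score_prob_matrix(
    probs: np.ndarray, ref: InversionReference
) -> tuple[np.ndarray, np.ndarray]:
    """Score a (n_samples, N, 3) probability array against every class.

    The per-site contribution is the expected genotype frequency
    sum_t P_i(t) f_ki(t); one-hot triples reproduce hard scoring exactly.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 2:
        probs = probs[None, :, :]
    n, N, three = probs.shape
    if N != ref.n_sites or three != 3:
        raise ValueError(f"expected shape (*, {ref.n_sites}, 3), got {probs.shape}")
    K = len(ref.classes)
    class_mask = _class_site_masks(ref)
    called = np.isfinite(probs).all(axis=2)  # (n, N)
    P = np.nan_to_num(probs)
    H = np.full((n, K), np.nan)
    n_sites = np.zeros((n, K), dtype=int)
    for k in range(K):
        if not ref.supported[k]:
            continue
        # expected frequency per sample/site: sum_t P[n,i,t] * f[k,i,t]
        exp_f = (P * np.nan_to_num(ref.freq[k])[None, :, :]).sum(axis=2)
        use = called & class_mask[k][None, :]
        # per-row reductions keep results bit-identical across batch sizes
        wsum = (use * ref.weights[None, :]).sum(axis=1)
        num = (np.where(use, exp_f, 0.0) * ref.weights[None, :]).sum(axis=1)
        ok = wsum > 0
        H[ok, k] = num[ok] / wsum[ok]
        n_sites[:, k] = use.sum(axis=1)
    return H, n_sites


def score_sample(codes: np.ndarray, ref: InversionReference) -> np.ndarray:
    """Score one sample's hard codes; returns the length-K vector H."""
    H, _ = score_matrix(np.asarray(codes)[None, :], ref)
    if np.isnan(H[0]).all():
        raise NoScorableSitesError("no scorable sites for any class")
    return H[0]


def score_sample_prob(probs: np.ndarray, ref: InversionReference) -> np.ndarray:
    """Score one sample's probability triples; returns the vector H."""
    H, _ = score_prob_matrix(np.asarray(probs)[None, :, :], ref)
    if np.isnan(H[0]).all():
        raise NoScorableSitesError("no scorable sites for any class")
    return H[0]


def classify(
    H: np.ndarray,
    ref: InversionReference,
    min_margin: float = 0.0,
    sample: str = "",
    n_sites_used: int | None = None,
) -> ScoreResult:
    """Pick the class with the maximum score and map it to an
    inversion genotype.

    An exactly tied maximum, or a margin below ``min_margin``, yields
    NO_CALL with a diagnostic reason rather than an arbitrary call.
    """
    H = np.asarray(H, dtype=float)
    defined = np.isfinite(H)
    ns = int(n_sites_used) if n_sites_used is not None else 0
    if not defined.any():
        return ScoreResult(
            sample, H, list(ref.classes), NO_CALL, 0.0, ns, NO_CALL,
            reason="no-scorable-sites",
        )
    vals = H[defined]
    idx = np.nonzero(defined)[0]
    order = np.argsort(vals)[::-1]
    best = idx[order[0]]
    if len(order) > 1:
        margin = float(vals[order[0]] - vals[order[1]])
    else:
        margin = 0.0
    if len(order) > 1 and vals[order[0]] == vals[order[1]]:
        tied = [str(ref.classes[i]) for i in idx[vals == vals[order[0]]]]
        return ScoreResult(
            sample, H, list(ref.classes), NO_CALL, 0.0, ns, NO_CALL,
            reason=f"tied-maximum:{','.join(tied)}",
        )
    if len(order) > 1 and margin < min_margin:
        return ScoreResult(
            sample, H, list(ref.classes), NO_CALL, margin, ns, NO_CALL,
            reason=f"margin-below-threshold:{margin:.4g}<{min_margin:g}",
        )
    cls = ref.classes[best]
    return ScoreResult(
        sample, H, list(ref.classes), cls, margin, ns,
        ref.class_to_inv[cls],
    )


def genotype_cohort(
    data: GenotypeMatrix | GenotypeProbMatrix,
    ref: InversionReference,
    min_margin: float = 0.0,
    batch_size: int | None = None,
) -> list[ScoreResult]:
    """Classify every sample in a (harmonized) cohort independently.

    Results are identical for any ``batch_size`` and any sample order;
    per-sample failures become NO_CALL results, never abort the cohort.
    """
    n = data.n_samples
    if batch_size is None or batch_size <= 0:
        batch_size = n
    results: list[ScoreResult] = []
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        if isinstance(data, GenotypeProbMatrix):
            H, n_sites = score_prob_matrix(data.probs[start:stop], ref)
        else:
            H, n_sites = score_matrix(data.codes[start:stop], ref)
        for r, i in enumerate(range(start, stop)):
            ns = int(n_sites[r].max(initial=0))
            res = classify(
                H[r], ref, min_margin=min_margin,
                sample=data.samples[i], n_sites_used=ns,
            )
            if res.is_called:
                k = ref.classes.index(res.best_class)
                res.n_sites_used = int(n_sites[r, k])
            results.append(res)
        logger.debug("scored samples %d-%d of %d", start, stop, n)
    return results


def results_to_table(results: list[ScoreResult], inversion_id: str):
    """Flatten ScoreResults to a pandas DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "sample": r.sample,
                "inversion": inversion_id,
                "call": r.inv_genotype,
                "best_class": str(r.best_class),
                "scores": ";".join(
                    f"{c}={h:.6g}" for c, h in r.scores_by_class().items()
                ),
                "margin": r.margin,
                "n_sites": r.n_sites_used,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
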