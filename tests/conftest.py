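import numpy as np
import pytest

from invscore import (
    GenotypeMatrix,
    HaplotypeGenotypeLabel,
    InversionReference,
    VariantSite,
    build_panel,
    simulate_cohort,
)
from invscore.simdata import SimConfig


def make_sites(n, chrom="1", start=100, step=10, ref="A", alt="G"):
    return [
        VariantSite(f"v{i}", chrom, start + step * i, ref, alt)
        for i in range(n)
    ]


def make_reference(freq, weights, class_names=("AA", "AB", "BB"),
                   class_to_inv=None, class_sizes=None, sites=None):
    """Small hand-specified panel for scorer tests."""
    freq = np.asarray(freq, dtype=float)
    K, N, _ = freq.shape
    classes = [HaplotypeGenotypeLabel.parse(c) for c in class_names]
    if class_to_inv is None:
        class_to_inv = {"AA": "NN", "AB": "NI", "BB": "II"}
    if class_sizes is None:
        class_sizes = [10] * K
    return InversionReference(
        inversion_id="test_inv",
        region=("1", 1, 10_000, "synthetic"),
        sites=sites if sites is not None else make_sites(N),
        classes=classes,
        freq=freq,
        weights=np.asarray(weights, dtype=float),
        class_to_inv={
            HaplotypeGenotypeLabel.parse(k): v for k, v in class_to_inv.items()
        },
        class_sizes=np.asarray(class_sizes),
        concordance=100.0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default two-haplotype cohort: 200 samples, 100 SNPs, divergence 0.3."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_panel(default_cohort):
    ref, cm = build_panel(
        default_cohort.gm, default_cohort.truth_labels(), seed=1
    )
    return ref, cm


def random_reference(rng, n_sites=None, n_classes=None):
    """Randomized small panel (with missing frequency data and zero
    weights sprinkled in) for oracle-equivalence tests."""
    n_sites = n_sites or rng.integers(1, 11)
    n_classes = n_classes or rng.integers(2, 7)
    # use labels from a large-enough J so n_classes distinct labels exist
    from invscore.types import enumerate_labels

    labels = enumerate_labels(4)[:n_classes]
    counts = rng.integers(0, 5, size=(n_classes, n_sites, 3)).astype(float)
    totals = counts.sum(axis=2)
    freq = np.full((n_classes, n_sites, 3), np.nan)
    ok = totals > 0
    freq[ok] = counts[ok] / totals[ok, None]
    weights = rng.random(n_sites)
    weights[rng.random(n_sites) < 0.2] = 0.0
    class_to_inv = {lab: rng.choice(["NN", "NI", "II"]) for lab in labels}
    sizes = rng.integers(0, 6, size=n_classes)
    return InversionReference(
        inversion_id="rand",
        region=("1", 1, 10_000, "synthetic"),
        sites=make_sites(n_sites),
        classes=labels,
        freq=freq,
        weights=weights,
        class_to_inv=class_to_inv,
        class_sizes=sizes,
    )
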