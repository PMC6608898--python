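"""MDS embedding, haplotype-genotype clustering, label mapping, weights
and frequency-table compilation."""

import numpy as np
import pytest

from invscore import (
    MISSING,
    GenotypeMatrix,
    HaplotypeGenotypeLabel,
    InversionReference,
    build_panel,
    build_reference,
    compute_mds,
    compute_site_weights,
    enumerate_labels,
    fit_haplotype_genotype_clusters,
    map_clusters_to_inversion_genotypes,
)
from invscore.builder import ClusterModel
from invscore.evaluation import class_assignment_accuracy
from invscore.simdata import SimConfig, simulate_cohort
from invscore.types import (
    AmbiguousMappingError,
    DegenerateReferenceError,
    UnmappableInversionError,
    UnresolvableGroupError,
)

from conftest import make_sites

L = HaplotypeGenotypeLabel.parse


def _gm(codes, samples=None):
    codes = np.asarray(codes)
    samples = samples or [f"s{i}" for i in range(codes.shape[0])]
    return GenotypeMatrix(samples, make_sites(codes.shape[1]), codes)


class TestEnumeration:
    @pytest.mark.parametrize("J,expected", [(2, 3), (3, 6), (4, 10)])
    def test_label_count_is_J_choose_2_plus_J(self, J, expected):
        labels = enumerate_labels(J)
        assert len(labels) == expected
        assert len(set(labels)) == expected
        homo = [lab for lab in labels if lab.is_homozygous]
        assert len(homo) == J


class TestMDS:
    def test_identical_samples_coincide(self):
        gm = _gm([[0, 1], [0, 1], [2, 2]])
        mds = compute_mds(gm, 2)
        np.testing.assert_allclose(mds.coords[0], mds.coords[1], atol=1e-7)

    def test_additive_codes_are_collinear(self):
        gm = _gm([[0, 0], [1, 1], [2, 2]])
        mds = compute_mds(gm, 2)
        assert mds.eigenvalues[0] > 1e-6
        assert mds.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)
        # equally spaced along axis 1
        x = np.sort(mds.coords[:, 0])
        assert np.diff(x)[0] == pytest.approx(np.diff(x)[1], rel=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        """Coordinates equal a direct eigendecomposition of the
        double-centered squared-distance matrix on small instances."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n, m = rng.integers(4, 11), rng.integers(2, 8)
            codes = rng.integers(0, 3, size=(n, m))
            gm = _gm(codes)
            mds = compute_mds(gm, n - 1)
            # oracle: brute-force distances, then PCoA by hand
            D = np.zeros((n, n))
            for a in range(n):
                for b in range(n):
                    D[a, b] = np.abs(codes[a] - codes[b]).mean()
            J = np.eye(n) - 1.0 / n
            B = -0.5 * J @ (D**2) @ J
            ev, evec = np.linalg.eigh(B)
            order = np.argsort(ev)[::-1]
            for j in range(min(3, n - 1)):
                lam = ev[order[j]]
                if lam < 1e-8:
                    continue
                expect = evec[:, order[j]] * np.sqrt(lam)
                got = mds.coords[:, j]
                # sign-fixed comparison
                if np.sign(got[np.argmax(np.abs(got))]) != np.sign(
                    expect[np.argmax(np.abs(expect))]
                ):
                    expect = -expect
                np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_agrees_with_skbio_pcoa(self):
        """Independent cross-check against scikit-bio's PCoA."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(12, 9))
        gm = _gm(codes)
        mds = compute_mds(gm, 3)
        D = np.array(
            [[np.abs(a - b).mean() for b in codes.astype(float)]
             for a in codes.astype(float)]
        )
        res = pcoa(skbio.DistanceMatrix(D), number_of_dimensions=3)
        ref = res.samples.values
        for j in range(3):
            col = ref[:, j]
            if not np.allclose(col, mds.coords[:, j], atol=1e-6):
                col = -col
            np.testing.assert_allclose(mds.coords[:, j], col, atol=1e-6)

    def test_duplicate_sample_preserves_other_distances(self):
        from invscore.builder import _pairwise_manhattan

        rng = np.random.default_rng(11)
        codes = rng.integers(0, 3, size=(6, 10))
        dup = np.vstack([codes, codes[0]])
        D1 = _pairwise_manhattan(codes)
        D2 = _pairwise_manhattan(dup)
        # the metric is untouched by duplication ...
        np.testing.assert_allclose(D1, D2[:6, :6], atol=1e-12)
        # ... and the duplicated pair coincides in the embedding
        mds = compute_mds(_gm(dup), 3)
        np.testing.assert_allclose(mds.coords[6], mds.coords[0], atol=1e-8)

    def test_dimension_error(self):
        gm = _gm(np.zeros((3, 4), dtype=int))
        with pytest.raises(ValueError, match="components"):
            compute_mds(gm, 3)


class TestClusterFit:
    @pytest.mark.parametrize("J", [2, 3])
    def test_recovers_simulated_pattern(self, J):
        cohort = simulate_cohort(SimConfig(J=J, seed=8))
        mds = compute_mds(cohort.gm, 3)
        cm = fit_haplotype_genotype_clusters(mds, seed=1)
        assert cm.J == J
        assert cm.pattern == {2: "line-3", 3: "triangle-6"}[J]
        assert len(set(cm.assignments.values())) == J * (J + 1) // 2
        acc = class_assignment_accuracy(cohort.truth_classes(), cm.assignments)
        assert acc >= 0.99

    def test_tetrahedron_pattern(self):
        cohort = simulate_cohort(SimConfig(J=4, seed=8))
        mds = compute_mds(cohort.gm, 3)
        cm = fit_haplotype_genotype_clusters(mds, seed=1)
        assert cm.J == 4 and cm.pattern == "tetrahedron-10"
        assert cm.n_components_used == 3

    def test_zero_divergence_unmappable(self):
        with pytest.warns(UserWarning, match="indistinguishable"):
            cohort = simulate_cohort(SimConfig(seed=8, divergence=0.0))
        mds = compute_mds(cohort.gm, 3)
        with pytest.raises(UnmappableInversionError):
            fit_haplotype_genotype_clusters(mds, seed=1)

    def test_deterministic_under_seed(self):
        cohort = simulate_cohort(SimConfig(seed=15))
        mds = compute_mds(cohort.gm, 3)
        cm1 = fit_haplotype_genotype_clusters(mds, seed=5)
        cm2 = fit_haplotype_genotype_clusters(mds, seed=5)
        assert cm1.assignments == cm2.assignments


def _model(assign, J=2):
    return ClusterModel(
        J=J,
        n_components_used=1,
        assignments={s: L(c) for s, c in assign.items()},
        centroids={},
        pattern={2: "line-3", 3: "triangle-6"}[J],
        equidistance_residual=0.0,
    )


class TestMapClusters:
    def test_perfect_two_group_mapping(self):
        assign = {f"s{i}": "AA" for i in range(4)}
        assign |= {f"h{i}": "AB" for i in range(4)}
        assign |= {f"b{i}": "BB" for i in range(2)}
        labels = {s: {"AA": "NN", "AB": "NI", "BB": "II"}[c]
                  for s, c in assign.items()}
        c2i, conc = map_clusters_to_inversion_genotypes(_model(assign), labels)
        assert c2i == {L("AA"): "NN", L("AB"): "NI", L("BB"): "II"}
        assert conc == 100.0

    def test_three_groups_two_standard(self):
        """Two standard groups (A, C) and one inverted (B): AA/AC/CC map
        to NN, AB/BC to NI, BB to II."""
        assign = {}
        labels = {}
        truth = {"AA": "NN", "AC": "NN", "CC": "NN",
                 "AB": "NI", "BC": "NI", "BB": "II"}
        i = 0
        for cls, inv in truth.items():
            for _ in range(3):
                assign[f"s{i}"] = cls
                labels[f"s{i}"] = inv
                i += 1
        c2i, conc = map_clusters_to_inversion_genotypes(_model(assign, J=3), labels)
        assert {str(k): v for k, v in c2i.items()} == truth
        assert conc == 100.0

    def test_one_discordant_sample_gives_90_percent(self):
        assign = {f"s{i}": "AA" for i in range(4)}
        assign |= {f"h{i}": "AB" for i in range(3)}
        assign |= {f"b{i}": "BB" for i in range(3)}
        labels = {s: {"AA": "NN", "AB": "NI", "BB": "II"}[c]
                  for s, c in assign.items()}
        labels["h0"] = "II"  # one discordant experimental label
        c2i, conc = map_clusters_to_inversion_genotypes(_model(assign), labels)
        assert conc == pytest.approx(90.0)

    def test_heterozygotes_resolve_group_without_homozygotes(self):
        assign = {"s0": "AA", "s1": "AA", "s2": "AB", "s3": "AB"}
        labels = {"s0": "NN", "s1": "NN", "s2": "NI", "s3": "NI"}
        c2i, _ = map_clusters_to_inversion_genotypes(_model(assign), labels)
        assert c2i[L("BB")] == "II"

    def test_unlabeled_group_raises(self):
        assign = {"s0": "AA", "s1": "AA", "s2": "BB"}
        labels = {"s0": "NN", "s1": "NN"}
        with pytest.raises(UnresolvableGroupError):
            map_clusters_to_inversion_genotypes(_model(assign), labels)

    def test_small_tie_is_ambiguous(self):
        assign = {"s0": "AA", "s1": "AA", "s2": "BB"}
        labels = {"s0": "NN", "s1": "II", "s2": "II"}
        with pytest.raises(AmbiguousMappingError, match="s0"):
            map_clusters_to_inversion_genotypes(_model(assign), labels)

    def test_large_mixed_vote_is_recurrence(self):
        assign = {f"s{i}": "AA" for i in range(10)}
        assign |= {"b0": "BB", "b1": "AB"}
        labels = {f"s{i}": ("NN" if i < 5 else "II") for i in range(10)}
        labels |= {"b0": "II", "b1": "NI"}
        with pytest.raises(UnmappableInversionError, match="shared"):
            map_clusters_to_inversion_genotypes(_model(assign), labels)


class TestSiteWeights:
    def test_perfect_ld_gives_one(self):
        # SNP codes equal the B-dosage of each sample exactly
        assign = {"s0": L("AA"), "s1": L("AB"), "s2": L("BB"), "s3": L("AA")}
        gm = _gm([[0], [1], [2], [0]])
        w = compute_site_weights(gm, assign)
        assert w[0] == pytest.approx(1.0)

    def test_monomorphic_snp_gives_zero(self):
        assign = {"s0": L("AA"), "s1": L("AB"), "s2": L("BB")}
        gm = _gm([[1], [1], [1]])
        assert compute_site_weights(gm, assign)[0] == 0.0

    def test_hand_computed_r2(self):
        """inv dosage (0,1,2,0,1,2) vs codes (0,1,2,0,1,1):
        r^2 = cov^2/(var*var) = 0.79412 by direct evaluation."""
        assign = {
            "s0": L("AA"), "s1": L("AB"), "s2": L("BB"),
            "s3": L("AA"), "s4": L("AB"), "s5": L("BB"),
        }
        gm = _gm([[0], [1], [2], [0], [1], [1]])
        w = compute_site_weights(gm, assign)
        assert w[0] == pytest.approx(9.0 / (4.0 * (7 - 25 / 6)), abs=1e-9)
        assert w[0] == pytest.approx(0.794117647, abs=1e-6)

    def test_two_group_weight_equals_inversion_dosage_r2(self, default_cohort):
        """For J=2 the haplotype-dosage route reduces to the squared
        Pearson correlation with inversion-allele dosage."""
        cohort = default_cohort
        assign = cohort.truth_classes()
        w = compute_site_weights(cohort.gm, assign)
        inv_dos = (cohort.chrom_groups == 1).sum(axis=1).astype(float)
        codes = cohort.gm.codes.astype(float)
        expect = np.zeros(cohort.gm.n_sites)
        for i in range(cohort.gm.n_sites):
            x = codes[:, i]
            if np.var(x) > 1e-12 and np.var(inv_dos) > 1e-12:
                expect[i] = np.corrcoef(x, inv_dos)[0, 1] ** 2
        np.testing.assert_allclose(w, expect, atol=1e-10)

    def test_all_missing_site_gets_zero_weight(self):
        assign = {"s0": L("AA"), "s1": L("AB"), "s2": L("BB")}
        codes = np.array([[0, MISSING], [1, MISSING], [2, MISSING]])
        w = compute_site_weights(_gm(codes), assign)
        assert w[1] == 0.0


class TestBuildReference:
    def test_frequency_counting(self):
        assign = {f"s{i}": L("AA") for i in range(4)}
        assign |= {"h0": L("AB"), "b0": L("BB")}
        codes = np.array([[0], [0], [0], [1], [1], [2]])
        gm = _gm(codes, samples=["s0", "s1", "s2", "s3", "h0", "b0"])
        cm = ClusterModel(2, 1, assign, {}, "line-3", 0.0)
        ref = build_reference(
            gm, cm, {L("AA"): "NN", L("AB"): "NI", L("BB"): "II"},
            100.0, ("1", 1, 1000, "synthetic"), "inv_t",
            weights=np.array([0.9]),
        )
        k = ref.classes.index(L("AA"))
        np.testing.assert_allclose(ref.freq[k, 0], [0.75, 0.25, 0.0])
        # single-member class: degenerate frequency triple
        k2 = ref.classes.index(L("BB"))
        np.testing.assert_allclose(ref.freq[k2, 0], [0.0, 0.0, 1.0])
        assert ref.class_sizes[k] == 4 and ref.class_sizes[k2] == 1

    def test_missing_everywhere_in_class_flags_no_data(self):
        assign = {"s0": L("AA"), "s1": L("AB"), "s2": L("BB")}
        codes = np.array([[0, MISSING], [1, 1], [2, 2]])
        gm = _gm(codes)
        cm = ClusterModel(2, 1, assign, {}, "line-3", 0.0)
        ref = build_reference(
            gm, cm, {L("AA"): "NN", L("AB"): "NI", L("BB"): "II"},
            100.0, ("1", 1, 1000, "synthetic"), "inv_t",
            weights=np.array([0.9, 0.9]),
        )
        k = ref.classes.index(L("AA"))
        assert np.isnan(ref.freq[k, 1]).all()

    def test_frequency_triples_sum_to_one(self, default_panel):
        ref, _ = default_panel
        have = np.isfinite(ref.freq).all(axis=2)
        sums = ref.freq.sum(axis=2)[have]
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_degenerate_reference_raises(self):
        assign = {"s0": L("AA"), "s1": L("AB"), "s2": L("BB")}
        gm = _gm([[1], [1], [1]])  # monomorphic: zero weight everywhere
        cm = ClusterModel(2, 1, assign, {}, "line-3", 0.0)
        with pytest.raises(DegenerateReferenceError):
            build_reference(
                gm, cm, {L("AA"): "NN", L("AB"): "NI", L("BB"): "II"},
                100.0, ("1", 1, 1000, "synthetic"), "inv_t",
            )


class TestPanelRoundTrip:
    def test_json_round_trip_bit_exact(self, default_panel, tmp_path):
        ref, _ = default_panel
        p = tmp_path / "panel.json"
        ref.save(p)
        ref2 = InversionReference.load(p)
        assert ref2.inversion_id == ref.inversion_id
        assert ref2.region == ref.region
        assert ref2.sites == ref.sites
        assert ref2.classes == ref.classes
        assert ref2.class_to_inv == ref.class_to_inv
        np.testing.assert_array_equal(ref2.class_sizes, ref.class_sizes)
        np.testing.assert_array_equal(
            np.isnan(ref2.freq), np.isnan(ref.freq)
        )
        assert np.array_equal(
            ref2.freq[~np.isnan(ref.freq)], ref.freq[~np.isnan(ref.freq)]
        )
        assert np.array_equal(ref2.weights, ref.weights)


class TestFullPipelineRecovery:
    @pytest.mark.parametrize("J", [2, 3, 4])
    def test_recovers_truth_on_divergent_cohorts(self, J):
        cohort = simulate_cohort(SimConfig(J=J, seed=21, n_samples=200))
        ref, cm = build_panel(cohort.gm, cohort.truth_labels(), seed=1)
        assert cm.J == J
        acc = class_assignment_accuracy(cohort.truth_classes(), cm.assignments)
        assert acc >= 0.99
        assert ref.concordance >= 99.0
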