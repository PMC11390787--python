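"""Single-nucleus pipeline: dosage inference, compartments, scoring, states."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from oligohox import snstates as sn
from oligohox import synthetic as syn


@pytest.fixture(scope="module")
def clustered(sn_dataset):
    truth, counts, features, barcodes, annotation = sn_dataset
    labels, emb, keep = sn.cluster_nuclei(counts, n_clusters=8, seed=0)
    return truth, counts.tocsr()[keep], features, annotation[keep], labels


class TestClustering:
    def test_planted_populations_recovered_with_high_purity(self, clustered):
        _, _, _, truth_ann, labels = clustered
        ct = truth_ann["cell_type"].to_numpy()
        purities = []
        for cl in pd.unique(labels):
            members = ct[labels == cl]
            purities.append(pd.Series(members).value_counts(normalize=True).iloc[0])
        assert np.mean(np.array(purities) > 0.9) >= 5 / 8

    def test_all_zero_nuclei_dropped(self):
        rng = np.random.default_rng(0)
        counts = sparse.csr_matrix(rng.poisson(2.0, size=(100, 60)))
        counts[3] = 0
        counts.eliminate_zeros()
        labels, _, keep = sn.cluster_nuclei(counts, n_clusters=3, seed=0)
        assert not keep[3]
        assert keep.sum() == 99 and len(labels) == 99

    def test_duplicated_nuclei_cluster_identically(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(3.0, size=(60, 40))
        doubled = sparse.csr_matrix(np.vstack([base, base]))
        labels, _, _ = sn.cluster_nuclei(doubled, n_clusters=3, seed=0)
        np.testing.assert_array_equal(labels[:60], labels[60:])


class TestArmDosage:
    def test_reference_cluster_scored_against_itself_is_flat(self, clustered):
        _, counts, features, truth_ann, labels = clustered
        ct = truth_ann["cell_type"].to_numpy()
        # purest sizeable non-neoplastic cluster, used as its own reference
        candidates = [
            cl for cl in pd.unique(labels)
            if (labels == cl).sum() >= 100
            and pd.Series(ct[labels == cl]).value_counts(normalize=True).iloc[0] > 0.85
            and (ct[labels == cl] != "neoplastic").all()
        ]
        ref_cl = candidates[0]
        prof = sn.infer_arm_dosage(counts, labels, [ref_cl], features, seed=0)
        rows = (prof.meta_cluster == ref_cl).to_numpy()
        assert prof.meta_scores[rows].mean(axis=0).abs().max() < 0.02

    def test_planted_codeletion_called_in_neoplastic_clusters_only(self, clustered):
        _, counts, features, truth_ann, labels = clustered
        ct = truth_ann["cell_type"].to_numpy()
        ref = [cl for cl in pd.unique(labels)
               if (ct[labels == cl] != "neoplastic").mean() > 0.5]
        prof = sn.infer_arm_dosage(counts, labels, ref, features, seed=0)
        for cl in pd.unique(labels):
            is_neo = (ct[labels == cl] == "neoplastic").mean() > 0.5
            calls = prof.cluster_calls.loc[cl]
            if is_neo:
                assert calls["1p"] == "loss" and calls["19q"] == "loss"
                assert calls["1q"] == "intact" and calls["19p"] == "intact"
            else:
                assert calls["1p"] == "intact" and calls["19q"] == "intact"

    def test_dosage_log_ratio_recovered_within_tolerance(self, clustered):
        """Arm score within 0.1 of log(planted dosage) for >=150-gene arms."""
        truth, counts, features, truth_ann, labels = clustered
        ct = truth_ann["cell_type"].to_numpy()
        ref = [cl for cl in pd.unique(labels)
               if (ct[labels == cl] != "neoplastic").mean() > 0.5]
        prof = sn.infer_arm_dosage(counts, labels, ref, features, seed=0)
        target = np.log(truth.deleted_arm_dosage)
        for cl in pd.unique(labels):
            if (ct[labels == cl] == "neoplastic").mean() > 0.5:
                rows = (prof.meta_cluster == cl).to_numpy()
                for arm in ("1p", "19q"):
                    assert prof.meta_scores.loc[rows, arm].mean() == pytest.approx(
                        target, abs=0.1
                    )

    def test_unit_dosage_produces_no_loss_calls(self):
        t = syn.SnTruth(
            n_nuclei=600, genes_per_arm=80, n_background_genes=200,
            deleted_arm_dosage=1.0, seed=13,
        )
        counts, features, _, ann = syn.gen_snseq(t)
        labels, _, keep = sn.cluster_nuclei(counts, n_clusters=6, seed=0)
        prof = sn.infer_arm_dosage(
            counts.tocsr()[keep], labels, list(pd.unique(labels)), features, seed=0
        )
        arm_cols = [c for c in ("1p", "1q", "19p", "19q")
                    if c in prof.cluster_calls.columns]
        assert not (prof.cluster_calls[arm_cols] == "loss").any().any()

    def test_empty_reference_rejected(self, clustered):
        _, counts, features, _, labels = clustered
        with pytest.raises(ValueError):
            sn.infer_arm_dosage(counts, labels, [], features)


class TestCompartments:
    def test_codeletion_fraction_rules(self):
        prof = sn.ArmDosageProfile(
            meta_scores=pd.DataFrame(),
            meta_cluster=pd.Series(dtype=int),
            cluster_calls=pd.DataFrame(),
            codeletion_fraction=pd.Series({0: 1.0, 1: 0.0, 2: 0.5, 3: 0.96, 4: 0.04}),
        )
        comp = sn.call_compartments(prof, universality=0.95)
        assert comp[0] == "neoplastic"
        assert comp[1] == "non-neoplastic"
        assert comp[2] == "excluded"
        assert comp[3] == "neoplastic"
        assert comp[4] == "non-neoplastic"

    def test_invariant_to_cluster_relabeling(self):
        f = pd.Series({10: 1.0, 20: 0.3, 30: 0.0})
        prof = sn.ArmDosageProfile(
            meta_scores=pd.DataFrame(), meta_cluster=pd.Series(dtype=int),
            cluster_calls=pd.DataFrame(), codeletion_fraction=f,
        )
        relabeled = sn.ArmDosageProfile(
            meta_scores=pd.DataFrame(), meta_cluster=pd.Series(dtype=int),
            cluster_calls=pd.DataFrame(),
            codeletion_fraction=f.rename({10: 30, 30: 10}),
        )
        a = sn.call_compartments(prof)
        b = sn.call_compartments(relabeled)
        assert a[10] == b[30] and a[30] == b[10] and a[20] == b[20]


class TestCellTyping:
    def test_planted_marker_clusters_typed(self, clustered):
        _, counts, features, truth_ann, labels = clustered
        lognorm = sn.normalize_log(counts)
        typed = sn.assign_cell_types(lognorm, features.index, labels)
        ct = truth_ann["cell_type"].to_numpy()
        for cl in pd.unique(labels):
            majority = pd.Series(ct[labels == cl]).mode()[0]
            if majority in ("oligodendrocyte", "microglia") and (
                ct[labels == cl] == majority
            ).mean() > 0.8:
                assert typed[cl] == majority

    def test_flat_expression_is_unassigned(self):
        rng = np.random.default_rng(0)
        genes = pd.Index(["MBP", "MOG", "CNP", "RBFOX3", "PTPRC", "CD163",
                          "CD14", "GFAP", "AQP4", "SLC1A2", "ALDH1L1", "other"])
        lognorm = rng.normal(1.0, 0.01, size=(90, len(genes)))
        clusters = np.repeat([0, 1, 2], 30)
        typed = sn.assign_cell_types(lognorm, genes, clusters)
        assert (typed == "unassigned").all()

    def test_all_panels_absent_rejected(self):
        rng = np.random.default_rng(0)
        genes = pd.Index(["g1", "g2"])
        with pytest.raises(ValueError):
            sn.assign_cell_types(
                rng.normal(size=(60, 2)), genes, np.repeat([0, 1], 30)
            )


class TestProgramScore:
    def test_toy_profile_matches_hand_computation(self):
        """10-gene, 1-bin toy profile: score equals the direct difference of
        centered means (controls drawn from the single bin)."""
        rng = np.random.default_rng(0)
        genes = pd.Index([f"g{i}" for i in range(10)])
        X = rng.normal(2.0, 1.0, size=(4, 10))
        prog = ["g1", "g4", "g7"]
        score = sn.relative_program_score(
            X, genes, prog, n_bins=1, controls_per_gene=2000, seed=1
        )
        centered = X - X.mean(axis=0)
        # with one bin the control draw converges on each nucleus's mean
        # centered expression over all genes
        hand = centered[:, [1, 4, 7]].mean(axis=1) - centered.mean(axis=1)
        np.testing.assert_allclose(score, hand, atol=0.05)

    def test_identical_program_and_background_scores_zero(self):
        genes = pd.Index([f"g{i}" for i in range(20)])
        X = np.tile(np.arange(20, dtype=float), (5, 1))
        X = X + np.random.default_rng(1).normal(0, 1e-9, X.shape)
        score = sn.relative_program_score(
            X, genes, ["g0"], n_bins=1, controls_per_gene=500, seed=0
        )
        # per-gene centering removes all structure shared across nuclei
        np.testing.assert_allclose(score, 0.0, atol=1e-6)

    def test_random_gene_sets_score_near_zero_on_average(self, clustered):
        _, counts, features, _, _ = clustered
        lognorm = sn.normalize_log(counts)[:200]
        rng = np.random.default_rng(2)
        means = []
        for _ in range(200):
            gene_set = rng.choice(features.index, size=20, replace=False)
            s = sn.relative_program_score(
                lognorm, features.index, gene_set, seed=int(rng.integers(2**31))
            )
            means.append(s.mean())
        assert abs(np.mean(means)) < 0.02

    def test_empty_intersection_rejected(self, clustered):
        _, counts, features, _, _ = clustered
        lognorm = sn.normalize_log(counts)[:50]
        with pytest.raises(ValueError):
            sn.relative_program_score(lognorm, features.index, ["NOPE"])


class TestPermutationTest:
    def test_p_floor_is_one_over_nperm_plus_one(self, clustered):
        truth, counts, features, truth_ann, _ = clustered
        neo = (truth_ann["cell_type"] == "neoplastic").to_numpy()
        lognorm = sn.normalize_log(counts)[neo][:300]
        n_perm = 500
        scores, pvals, fdrs = sn.permutation_state_test(
            lognorm, features.index, truth.program_gene_sets,
            n_perm=n_perm, seed=0,
        )
        assert (pvals.to_numpy() >= 1.0 / (n_perm + 1) - 1e-12).all()
        assert (pvals.to_numpy() > 0).all()
        # strongly planted states hit the floor
        assert np.isclose(pvals.to_numpy(), 1.0 / (n_perm + 1)).any()

    def test_null_median_score_gives_p_near_half(self):
        rng = np.random.default_rng(3)
        genes = pd.Index([f"g{i}" for i in range(200)])
        X = rng.normal(size=(50, 200))
        _, pvals, _ = sn.permutation_state_test(
            X, genes, {"null": [f"g{i}" for i in range(0, 40, 2)]},
            n_perm=400, seed=0,
        )
        assert pvals["null"].median() == pytest.approx(0.5, abs=0.15)

    def test_zero_permutations_rejected(self):
        genes = pd.Index(["g0", "g1"])
        with pytest.raises(ValueError):
            sn.permutation_state_test(
                np.zeros((5, 2)), genes, {"s": ["g0"]}, n_perm=0
            )

    def test_bh_monotonicity_respected(self, clustered):
        truth, counts, features, truth_ann, _ = clustered
        neo = (truth_ann["cell_type"] == "neoplastic").to_numpy()
        lognorm = sn.normalize_log(counts)[neo][:150]
        _, pvals, fdrs = sn.permutation_state_test(
            lognorm, features.index, truth.program_gene_sets, n_perm=300, seed=0
        )
        p = pvals.to_numpy().ravel()
        f = fdrs.to_numpy().ravel()
        order = np.argsort(p)
        assert (np.diff(f[order]) >= -1e-12).all()


class TestStateAssignment:
    def test_argmin_fdr_below_alpha(self):
        fdrs = pd.DataFrame(
            [{"OPC-like": 0.001, "Astro-like": 0.2, "Cycling": 0.9, "RE": 1.0}]
        )
        assert sn.assign_state(fdrs)[0] == "OPC-like"

    def test_all_above_alpha_is_gradient(self):
        fdrs = pd.DataFrame(
            [{"OPC-like": 0.0125, "Astro-like": 0.2, "Cycling": 0.9, "RE": 1.0}]
        )
        assert sn.assign_state(fdrs)[0] == "gradient"

    def test_tie_broken_by_larger_score_then_state_order(self):
        fdrs = pd.DataFrame(
            [{"OPC-like": 0.001, "Astro-like": 0.001, "Cycling": 0.5, "RE": 0.5}] * 2
        )
        scores = pd.DataFrame(
            [
                {"OPC-like": 0.1, "Astro-like": 0.9, "Cycling": 0, "RE": 0},
                {"OPC-like": 0.5, "Astro-like": 0.5, "Cycling": 0, "RE": 0},
            ]
        )
        out = sn.assign_state(fdrs, scores)
        assert out[0] == "Astro-like"  # larger score wins
        assert out[1] == "OPC-like"  # exact tie falls back to fixed order

    def test_planted_cycling_nuclei_assigned_cycling(self, clustered):
        truth, counts, features, truth_ann, _ = clustered
        cyc = (truth_ann["state"] == "Cycling").to_numpy()
        neo = (truth_ann["cell_type"] == "neoplastic").to_numpy()
        lognorm = sn.normalize_log(counts)[neo]
        scores, pvals, fdrs = sn.permutation_state_test(
            lognorm, features.index, truth.program_gene_sets, n_perm=1500, seed=0
        )
        state = sn.assign_state(fdrs, scores)
        planted = truth_ann.loc[neo, "state"].to_numpy()
        cyc_rate = (state.to_numpy()[planted == "Cycling"] == "Cycling").mean()
        assert cyc_rate >= 0.90


class TestLineageAndPrevalence:
    def test_oc_dominates_for_oc_expressing_nuclei(self, clustered):
        truth, counts, features, truth_ann, _ = clustered
        neo = (truth_ann["cell_type"] == "neoplastic").to_numpy()
        lognorm = sn.normalize_log(counts)[neo]
        lin = sn.stemness_lineage_scores(
            lognorm, features.index, truth.lineage_gene_sets, seed=0
        )
        states = truth_ann.loc[neo, "state"].to_numpy()
        opc = states == "OPC-like"
        assert (lin.loc[opc, "OC_score"] > lin.loc[opc, "AC_score"]).mean() > 0.9

    def test_planted_stem_states_have_higher_stemness(self, clustered):
        from scipy.stats import ttest_ind

        truth, counts, features, truth_ann, _ = clustered
        neo = (truth_ann["cell_type"] == "neoplastic").to_numpy()
        lognorm = sn.normalize_log(counts)[neo]
        lin = sn.stemness_lineage_scores(
            lognorm, features.index, truth.lineage_gene_sets, seed=0
        )
        states = truth_ann.loc[neo, "state"].to_numpy()
        stemlike = np.isin(states, ["Cycling", "OPC-like"])
        t, p = ttest_ind(lin.loc[stemlike, "stemness_score"],
                         lin.loc[~stemlike, "stemness_score"])
        assert t > 0 and p < 0.01

    def test_zero_marker_reads_give_p_one(self):
        active = pd.Series([False] * 40)
        grouping = pd.Series(["a"] * 20 + ["b"] * 20)
        res = sn.compare_marker_prevalence(active, grouping)
        assert res["fisher_p"].iloc[0] == pytest.approx(1.0)

    def test_planted_prevalence_contrast_is_significant(self):
        rng = np.random.default_rng(0)
        n = 2000
        grouping = pd.Series(np.where(rng.uniform(size=n) < 0.3, "Cycling", "other"))
        p = np.where(grouping == "Cycling", 0.15, 0.02)
        active = pd.Series(rng.uniform(size=n) < p)
        res = sn.compare_marker_prevalence(active, grouping)
        assert res["fisher_p"].iloc[0] < 1e-6


class TestEndToEnd:
    def test_annotation_recovers_compartments_and_states(self, sn_dataset):
        truth, counts, features, barcodes, annotation = sn_dataset
        ann = sn.annotate_nuclei(
            counts, features, barcodes,
            program_sets=truth.program_gene_sets,
            lineage_sets=truth.lineage_gene_sets,
            sparse_marker=truth.sparse_marker,
            n_clusters=8, n_perm=1500, seed=0,
        )
        tr = annotation.loc[ann.index]
        neo_true = (tr["cell_type"] == "neoplastic").to_numpy()
        neo_called = (ann["compartment"] == "neoplastic").to_numpy()
        # no cross-compartment confusions
        assert not (neo_called & ~neo_true).any()
        assert (neo_called | (ann["compartment"] == "excluded").to_numpy())[
            neo_true
        ].mean() > 0.95
        mask = neo_called & tr["state"].isin(sn.STATE_ORDER).to_numpy()
        acc = (ann.loc[mask, "state"] == tr.loc[mask, "state"]).mean()
        assert acc >= 0.85

    def test_seed_change_preserves_compartment_calls(self, sn_dataset):
        truth, counts, features, barcodes, annotation = sn_dataset
        calls = []
        for seed in (0, 1):
            ann = sn.annotate_nuclei(
                counts, features, barcodes,
                program_sets=truth.program_gene_sets,
                n_clusters=8, n_perm=200, seed=seed,
            )
            calls.append(ann["compartment"])
        agreement = (calls[0] == calls[1]).mean()
        assert agreement > 0.95
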