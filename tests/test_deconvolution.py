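import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls

import trisodeconv as td
from trisodeconv.containers import CountMatrix
from trisodeconv.deconvolution import ReferenceBasis, build_basis, solve_dwls, to_fpkm


class TestBuildBasis:
    def test_thirty_markers_per_single_cluster_type(self, reference, basis):
        single = [ct for ct, n in
                  pd.Series(reference.cluster_to_celltype).value_counts().items() if n == 1]
        counts = basis.provenance.groupby("celltype").size()
        for ct in single:
            assert counts[ct] == 30

    def test_no_excluded_genes_in_basis(self, reference, basis):
        ann = reference.annotation.loc[basis.genes]
        assert not (ann.chromosome == "chr21").any()
        assert not ann.is_ribo_or_mito.any()

    def test_every_celltype_contributes_markers(self, basis):
        assert set(basis.provenance.celltype) == set(basis.celltypes)
        assert (basis.S.to_numpy() >= 0).all()

    def test_identical_profiles_average_is_identity(self, reference):
        b = build_basis(reference.marker_table, reference.profiles_A,
                        reference.profiles_A, reference.cluster_to_celltype,
                        reference.annotation)
        cpm = reference.profiles_A / reference.profiles_A.sum(axis=0) * 1e6 / 100.0
        expected = {}
        for cl, ct in reference.cluster_to_celltype.items():
            expected.setdefault(ct, []).append(cl)
        for ct, cls in expected.items():
            np.testing.assert_allclose(b.S[ct], cpm[cls].mean(axis=1).loc[b.genes])

    def test_multicluster_top5_then_merged_fill(self):
        """Hand-built marker table: 2 clusters -> one type; top 5 from each,
        then fill to 30 from the merged p-value ranking."""
        genes = [f"g{i:03d}" for i in range(80)]
        ann = pd.DataFrame({"chromosome": "chr1", "exonic_length": 1000,
                            "biotype": "pc", "is_ribo_or_mito": False}, index=genes)
        rows = []
        for i in range(40):
            rows.append((genes[i], "cA", 0.001 * (i + 1), 2.0))
        for i in range(40):
            rows.append((genes[40 + i], "cB", 0.0005 * (i + 1), 2.0))
        mt = pd.DataFrame(rows, columns=["gene_id", "cluster", "p_value", "fold_change"])
        prof = pd.DataFrame(1.0, index=genes, columns=["cA", "cB"])
        b = build_basis(mt, prof, prof, {"cA": "T", "cB": "T"}, ann)
        prov = b.provenance
        assert len(prov) == 30
        top5 = prov[prov.rule == "top5"]
        assert len(top5) == 10
        assert set(top5[top5.cluster == "cA"].gene_id) == set(genes[:5])
        assert set(top5[top5.cluster == "cB"].gene_id) == set(genes[40:45])
        # merged fill: smallest remaining (p, gene_id) pairs across both clusters
        fill = prov[prov.rule == "merged-fill"]
        assert len(fill) == 20
        chosen5 = set(top5.gene_id)
        remaining = mt[~mt.gene_id.isin(chosen5)].sort_values(["p_value", "gene_id"])
        assert set(fill.gene_id) == set(remaining.gene_id.head(20))

    def test_no_eligible_markers_names_celltype(self, reference):
        ann = reference.annotation.copy()
        cluster = next(iter(reference.cluster_to_celltype))
        ct = reference.cluster_to_celltype[cluster]
        only = [c for c, t in reference.cluster_to_celltype.items() if t == ct]
        genes = reference.marker_table.query("cluster in @only").gene_id
        ann.loc[ann.index.isin(genes), "is_ribo_or_mito"] = True
        with pytest.raises(ValueError, match=ct):
            build_basis(reference.marker_table, reference.profiles_A,
                        reference.profiles_B, reference.cluster_to_celltype, ann)


class TestFpkm:
    @staticmethod
    def _cm(counts, lengths):
        genes = [f"g{i}" for i in range(len(lengths))]
        ann = pd.DataFrame({"chromosome": "chr1", "exonic_length": lengths,
                            "biotype": "pc", "is_ribo_or_mito": False}, index=genes)
        return CountMatrix(pd.DataFrame(counts, index=genes), ann)

    def test_unit_conversion_identity(self):
        # 10 counts, library 1e6, 1 kb -> FPKM 10
        counts = {"s": [10] + [0] * 8 + [1_000_000 - 10]}
        cm = self._cm(counts, [1000] * 9 + [10_000_000])
        assert to_fpkm(cm).loc["g0", "s"] == pytest.approx(10.0)

    def test_zero_gene_zero_everywhere(self):
        cm = self._cm({"a": [0, 5], "b": [0, 7]}, [500, 900])
        assert (to_fpkm(cm).loc["g0"] == 0).all()

    def test_doubling_one_sample_leaves_fpkm_unchanged(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=30)
        cm1 = self._cm({"a": base, "b": base[::-1]}, rng.integers(200, 5000, 30))
        cm2 = self._cm({"a": base * 2, "b": base[::-1]}, cm1.annotation.exonic_length)
        pd.testing.assert_frame_equal(to_fpkm(cm1), to_fpkm(cm2))


def _random_basis(seed=0, n_genes=120, k=13):
    rng = np.random.default_rng(seed)
    genes = [f"m{i}" for i in range(n_genes)]
    S = pd.DataFrame(rng.lognormal(1.0, 1.0, size=(n_genes, k)),
                     index=genes, columns=[f"ct{j}" for j in range(k)])
    # sparsify so columns are distinguishable
    mask = rng.random(S.shape) < 0.6
    S = S.where(~mask, 0.0)
    S.iloc[:13] += np.eye(13) * 50
    return ReferenceBasis(S=S, provenance=pd.DataFrame())


class TestSolveDwls:
    def test_pure_column_recovery(self):
        basis = _random_basis()
        for k in (0, 5, 12):
            est = solve_dwls(basis, basis.S.iloc[:, k] * 3.7)
            assert est.p.iloc[k] == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_mixture(self):
        basis = _random_basis(1)
        bulk = 0.5 * basis.S.iloc[:, 2] + 0.5 * basis.S.iloc[:, 7]
        est = solve_dwls(basis, bulk)
        assert est.p.iloc[2] == pytest.approx(0.5, abs=1e-5)
        assert est.p.iloc[7] == pytest.approx(0.5, abs=1e-5)

    def test_random_mixtures_match_nnls_oracle(self):
        """Noiseless bulk = S p: solution within 1e-3 of truth and of the
        normalized NNLS solution (exact in the noiseless case)."""
        basis = _random_basis(2)
        rng = np.random.default_rng(42)
        for _ in range(10):
            p_true = rng.dirichlet(np.ones(13))
            bulk = pd.Series(basis.S.to_numpy() @ p_true, index=basis.genes)
            est = solve_dwls(basis, bulk)
            oracle, _ = nnls(basis.S.to_numpy(), bulk.to_numpy())
            oracle = oracle / oracle.sum()
            assert np.abs(est.p.to_numpy() - p_true).mean() < 1e-3
            assert np.abs(est.p.to_numpy() - oracle).mean() < 1e-3

    def test_scale_invariance(self):
        basis = _random_basis(3)
        rng = np.random.default_rng(0)
        bulk = pd.Series(basis.S.to_numpy() @ rng.dirichlet(np.ones(13)),
                         index=basis.genes)
        a = solve_dwls(basis, bulk)
        b = solve_dwls(basis, bulk * 250.0)
        np.testing.assert_allclose(a.p, b.p, atol=1e-6)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_always_on_simplex(self, seed):
        basis = _random_basis(4)
        rng = np.random.default_rng(seed)
        bulk = pd.Series(rng.lognormal(0, 1.5, size=len(basis.genes)) *
                         rng.integers(0, 2, size=len(basis.genes)),
                         index=basis.genes)
        est = solve_dwls(basis, bulk)
        assert (est.p >= 0).all()
        assert est.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_bulk_rejected(self):
        basis = _random_basis(5)
        bulk = pd.Series(-1.0, index=basis.genes)
        with pytest.raises(ValueError):
            solve_dwls(basis, bulk)

    def test_monotone_degradation_with_noise(self):
        """Mean recovery error does not improve as injected noise grows."""
        basis = _random_basis(6)
        rng = np.random.default_rng(7)
        p_true = [rng.dirichlet(np.ones(13)) for _ in range(6)]
        errors = []
        for noise_sd in (0.0, 0.3, 0.9):
            errs = []
            for i, p in enumerate(p_true):
                clean = basis.S.to_numpy() @ p
                noisy = clean * np.exp(np.random.default_rng(100 + i).normal(0, noise_sd, clean.size))
                est = solve_dwls(basis, pd.Series(noisy, index=basis.genes))
                errs.append(np.abs(est.p.to_numpy() - p).mean())
            errors.append(np.mean(errs))
        assert errors[0] <= errors[1] + 1e-6 <= errors[2] + 2e-2


class TestDeconvolveSamples:
    def test_noiseless_simulated_samples_recover_truth(self):
        d = td.make_design(td.DesignConfig(n_batches=1,
                                           pools_per_line_per_batch_sequenced=1,
                                           pools_per_line_per_batch_total=1))
        ref = td.simulate_reference(seed=21, dataset_noise_sd=0.0)
        params = td.BulkParams(dosage=1.0, batch_effect_sd=0, pool_noise_sd=0,
                               gene_noise_sd=0, nb_dispersion=0)
        cm, truth = td.simulate_bulk_counts(d, ref, params, seed=21)
        basis = td.build_basis(ref.marker_table, ref.profiles_A, ref.profiles_B,
                               ref.cluster_to_celltype, ref.annotation)
        res = td.deconvolve_samples(cm, basis)
        err = (res.proportions - truth.true_proportions.loc[res.proportions.index]).abs()
        assert err.mean().mean() < 0.01

    def test_proportion_vector_length_13(self, bulk_default, basis):
        cm, _ = bulk_default
        res = td.deconvolve_samples(cm.subset_genes(cm.genes), basis)
        assert res.proportions.shape[1] == 13
        assert not res.failures

    def test_gene_order_permutation_invariance(self, basis):
        rng = np.random.default_rng(3)
        genes = list(basis.genes)
        counts = pd.DataFrame(rng.integers(0, 2000, size=(len(genes), 2)),
                              index=genes, columns=["s1", "s2"])
        ann = pd.DataFrame({"chromosome": "chr1",
                            "exonic_length": rng.integers(300, 3000, len(genes)),
                            "biotype": "pc", "is_ribo_or_mito": False}, index=genes)
        cm = CountMatrix(counts, ann)
        perm = rng.permutation(len(genes))
        cm_perm = CountMatrix(counts.iloc[perm], ann.iloc[perm])
        basis_perm = ReferenceBasis(S=basis.S.iloc[perm], provenance=basis.provenance)
        a = td.deconvolve_samples(cm, basis)
        b = td.deconvolve_samples(cm_perm, basis_perm)
        np.testing.assert_allclose(a.proportions, b.proportions[a.proportions.columns],
                                   atol=1e-9)
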