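import numpy as np
import pandas as pd
import pytest

from ssrkit.admixture import (
    align_labels,
    assign_memberships,
    evanno_delta_k,
    run_admixture,
)
from ssrkit.diversity import allele_frequencies
from ssrkit.simulate import SimulationConfig, simulate_collection


@pytest.fixture(scope="module")
def two_pop_run(structured_collection):
    table, manifest = structured_collection
    run = run_admixture(table, K=2, seed=0, burn_in=300, n_iter=1200)
    return table, manifest, run


# reuse session fixture from conftest inside this module-scoped one
@pytest.fixture(scope="module")
def structured_collection():
    cfg = SimulationConfig(
        seed=7, n_loci=15, n_subpops=2, fst_target=0.3,
        n_founders=50, triploid_fraction=0.0,
    )
    table, _, manifest = simulate_collection(cfg)
    return table, manifest


class TestSampler:
    def test_invalid_arguments(self, structured_collection):
        table, _ = structured_collection
        with pytest.raises(ValueError):
            run_admixture(table, K=0)
        with pytest.raises(ValueError):
            run_admixture(table, K=2, burn_in=100, n_iter=50)

    def test_k1_degenerate(self, structured_collection):
        table, _ = structured_collection
        run = run_admixture(table, K=1, seed=0, burn_in=50, n_iter=200)
        assert np.allclose(run.Q.to_numpy(), 1.0)
        assert np.all(np.isfinite(run.lnP_trace))

    def test_q_rows_sum_to_one(self, two_pop_run):
        _, _, run = two_pop_run
        assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_k1_frequencies_converge_to_sample(self, structured_collection):
        table, _ = structured_collection
        run = run_admixture(table, K=1, seed=1, burn_in=200, n_iter=800)
        locus = table.loci[0]
        f = allele_frequencies(table, locus)
        for allele, p in f.freq.items():
            post = run.P_state.loc["cluster_1", f"{locus}_{allele}"]
            assert post == pytest.approx(p, abs=0.05)

    def test_recovers_subpopulations(self, two_pop_run):
        table, manifest, run = two_pop_run
        q = run.Q.to_numpy()
        true = np.array(
            [manifest.subpop_label[a] for a in table.accession_ids]
        )
        strong = q.max(axis=1) >= 0.80
        pred = q.argmax(axis=1)
        acc = max(
            np.mean(pred[strong] == true[strong]),
            np.mean(pred[strong] == 1 - true[strong]),
        )
        assert strong.mean() > 0.8
        assert acc >= 0.95

    def test_seed_reproducible(self, structured_collection):
        table, _ = structured_collection
        a = run_admixture(table, K=2, seed=5, burn_in=100, n_iter=400)
        b = run_admixture(table, K=2, seed=5, burn_in=100, n_iter=400)
        assert np.array_equal(a.Q.to_numpy(), b.Q.to_numpy())
        assert np.array_equal(a.lnP_trace, b.lnP_trace)

    def test_label_switching_alignment(self, structured_collection):
        table, _ = structured_collection
        a = run_admixture(table, K=2, seed=2, burn_in=200, n_iter=800)
        b = run_admixture(table, K=2, seed=3, burn_in=200, n_iter=800)
        perm = align_labels(a.Q, b.Q)
        qa = a.Q.to_numpy().argmax(axis=1)
        qb = b.Q.to_numpy()[:, perm].argmax(axis=1)
        assert np.mean(qa == qb) >= 0.95

    def test_rmse_decreases_with_loci(self):
        rmses = []
        for n_loci in (10, 50):
            cfg = SimulationConfig(
                seed=42, n_loci=n_loci, n_subpops=2, fst_target=0.25,
                n_founders=30, triploid_fraction=0.0,
            )
            table, _, manifest = simulate_collection(cfg)
            run = run_admixture(table, K=2, seed=0, burn_in=200,
                                n_iter=800)
            q = run.Q.to_numpy()
            true = np.array([
                manifest.subpop_label[a] for a in table.accession_ids
            ])
            target = np.column_stack([1 - true, true]).astype(float)
            rmse = min(
                np.sqrt(np.mean((q - target) ** 2)),
                np.sqrt(np.mean((q[:, ::-1] - target) ** 2)),
            )
            rmses.append(rmse)
        assert rmses[1] < rmses[0]

    def test_polyploids_participate(self):
        cfg = SimulationConfig(
            seed=8, n_loci=12, n_subpops=2, fst_target=0.3,
            n_founders=25, triploid_fraction=0.3,
        )
        table, _, manifest = simulate_collection(cfg)
        run = run_admixture(table, K=2, seed=0, burn_in=200, n_iter=800)
        assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)
        tri = [a for a, p in manifest.true_ploidy.items() if p == 3]
        true = np.array([manifest.subpop_label[a] for a in tri])
        pred = run.Q.loc[tri].to_numpy().argmax(axis=1)
        assert max(np.mean(pred == true), np.mean(pred == 1 - true)) > 0.8

    def test_correlated_model_runs(self, structured_collection):
        table, _ = structured_collection
        run = run_admixture(table, K=2, seed=0, burn_in=100, n_iter=400,
                            freq_model="correlated")
        assert np.all(np.isfinite(run.lnP_trace))
        assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)


class TestEvanno:
    def test_constructed_kink_found(self):
        L = {
            k: [-1000 + 100 * min(k, 5) - 10 * max(k - 5, 0) + d
                for d in (-1.0, 0.0, 1.0)]
            for k in range(1, 9)
        }
        res = evanno_delta_k(L)
        assert res.best_k == 5

    def test_linear_profile_no_peak(self):
        L = {k: [-100 + 7 * k + d for d in (-1.0, 0.0, 1.0)]
             for k in range(1, 6)}
        res = evanno_delta_k(L)
        assert res.best_k is None
        interior = res.table.dropna(subset=["delta_K"])
        assert (interior["delta_K"] == 0).all()

    def test_zero_sd_reported_as_missing(self):
        L = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        res = evanno_delta_k(L)
        assert res.table["delta_K"].isna().all()

    def test_needs_three_k_values(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [-1.0], 2: [-2.0]})


class TestAssignment:
    @staticmethod
    def run_with_q(q):
        import types
        df = pd.DataFrame(
            q, index=[f"a{i}" for i in range(len(q))],
            columns=[f"cluster_{j + 1}" for j in range(len(q[0]))],
        )
        return types.SimpleNamespace(Q=df)

    @pytest.mark.parametrize("q,expected", [
        ((0.85, 0.15), "cluster_1"),
        ((0.60, 0.40), "admixture"),
        ((0.80, 0.20), "cluster_1"),   # boundary inclusive
        ((0.15, 0.85), "cluster_2"),
    ])
    def test_threshold_rule(self, q, expected):
        run = self.run_with_q([q])
        res = assign_memberships(run, threshold=0.80)
        assert res.labels["label"].iloc[0] == expected

    def test_admixed_count(self):
        run = self.run_with_q([(0.9, 0.1), (0.5, 0.5), (0.15, 0.85)])
        res = assign_memberships(run)
        assert res.n_admixed == 1
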