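import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrkit.diversity import (
    allele_frequencies,
    combined_pid,
    diversity_table,
    hwe_test,
    locus_diversity,
    null_allele_screen,
    _pid_formulas,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles

def pid_bruteforce(p):
    """P(two independent HWE genotypes identical) by genotype enumeration."""
    n = len(p)
    total = 0.0
    for i in range(n):
        for j in range(i, n):
            prob = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            total += prob**2
    return total


def pidsib_bruteforce(p):
    """P(two full sibs share a genotype) by parent-pair enumeration."""
    n = len(p)
    genos = [(i, j) for i in range(n) for j in range(i, n)]

    def gprob(g):
        i, j = g
        return p[i] ** 2 if i == j else 2 * p[i] * p[j]

    total = 0.0
    for gm in genos:
        for gf in genos:
            # each sib draws one allele per parent, 4 equally likely combos
            offspring = {}
            for a in gm:
                for b in gf:
                    key = (min(a, b), max(a, b))
                    offspring[key] = offspring.get(key, 0.0) + 0.25
            total += gprob(gm) * gprob(gf) * sum(
                q**2 for q in offspring.values()
            )
    return total


def random_freq_vectors(n_vectors, seed, max_alleles=8):
    rng = np.random.default_rng(seed)
    for _ in range(n_vectors):
        k = int(rng.integers(2, max_alleles + 1))
        v = rng.dirichlet(np.ones(k))
        yield v


# ---------------------------------------------------------------------------

class TestFormulas:
    def test_biallelic_worked_example(self):
        pic, pid, pidsib = _pid_formulas(np.array([0.5, 0.5]))
        assert pic == pytest.approx(0.375, abs=1e-12)
        assert pid == pytest.approx(0.375, abs=1e-12)
        assert pidsib == pytest.approx(0.59375, abs=1e-12)

    def test_four_equifrequent_alleles(self):
        pic, pid, _ = _pid_formulas(np.array([0.25] * 4))
        assert pic == pytest.approx(0.703125, abs=1e-12)
        assert pid == pytest.approx(0.109375, abs=1e-12)

    def test_monomorphic_limit(self):
        pic, pid, pidsib = _pid_formulas(np.array([1.0]))
        assert pic == 0.0
        assert pid == 1.0
        assert pidsib == 1.0

    def test_pid_matches_bruteforce_enumeration(self):
        for p in random_freq_vectors(200, seed=42):
            _, pid, pidsib = _pid_formulas(p)
            assert pid == pytest.approx(pid_bruteforce(p), abs=1e-12)
            assert pidsib >= pid
            assert pidsib >= 0.25

    def test_pidsib_matches_sib_enumeration(self):
        for p in random_freq_vectors(20, seed=7, max_alleles=5):
            _, _, pidsib = _pid_formulas(p)
            assert pidsib == pytest.approx(pidsib_bruteforce(p), abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=10))
    def test_inequalities_hold_for_any_frequencies(self, weights):
        p = np.array(weights) / np.sum(weights)
        pic, pid, pidsib = _pid_formulas(p)
        he = 1 - np.sum(p**2)
        assert pic <= he + 1e-12
        assert pid <= pidsib <= 1.0
        assert 0.0 <= pid <= 1.0
        # lower bound: PID = 2 s2^2 - s4 >= s2^2 = (sum p^2)^2
        assert pid >= float(np.sum(p**2)) ** 2 - 1e-12


class TestAlleleFrequencies:
    def test_single_homozygote(self):
        t = make_table({"a": {"L1": {100}}})
        f = allele_frequencies(t, "L1")
        assert f.freq == {100: 1.0}
        assert f.n_obs == 2

    def test_homozygote_counted_twice(self):
        t = make_table({"a": {"L1": {100}}, "b": {"L1": {100, 104}}})
        f = allele_frequencies(t, "L1")
        assert f.freq[100] == pytest.approx(0.75)
        assert f.freq[104] == pytest.approx(0.25)

    def test_triploid_contributes_one_per_distinct_allele(self):
        t = make_table({"a": {"L1": {100, 104, 108}}})
        f = allele_frequencies(t, "L1")
        assert all(v == pytest.approx(1 / 3) for v in f.freq.values())

    def test_all_missing_raises(self):
        t = make_table({"a": {"L1": set(), "L2": {100}}})
        with pytest.raises(ValueError, match="missing"):
            allele_frequencies(t, "L1")


class TestLocusDiversity:
    def test_biallelic_statistics(self):
        # 2 AB het + 1 AA + 1 BB -> p = [0.5, 0.5]
        t = make_table({
            "a": {"L1": {100, 104}}, "b": {"L1": {100, 104}},
            "c": {"L1": {100}}, "d": {"L1": {104}},
        })
        f = allele_frequencies(t, "L1")
        d = locus_diversity(f, t, "L1", hwe_reps=100, null_boot=0)
        assert d.Ne == pytest.approx(2.0)
        assert d.He == pytest.approx(0.5)
        assert d.Ho == pytest.approx(0.5)
        assert d.PIC == pytest.approx(0.375)
        assert d.PID == pytest.approx(0.375)
        assert d.PD == pytest.approx(0.625)

    def test_ne_equals_na_only_when_uniform(self):
        for p in random_freq_vectors(50, seed=3):
            ne = 1.0 / np.sum(p**2)
            if np.allclose(p, p[0]):
                assert ne == pytest.approx(len(p))
            else:
                assert ne < len(p)

    def test_rare_allele_percentage(self):
        profiles = {f"h{i}": {"L1": {100}} for i in range(120)}
        profiles["x"] = {"L1": {100, 200}}  # 1/242 < 0.01
        t = make_table(profiles)
        f = allele_frequencies(t, "L1")
        d = locus_diversity(f, t, "L1", hwe_reps=0, null_boot=0)
        assert d.Na == 2
        assert d.RA == pytest.approx(50.0)


class TestCombinedPid:
    def test_product_over_loci(self):
        t = make_table({
            "a": {"L1": {100, 104}, "L2": {200, 204}},
            "b": {"L1": {100, 104}, "L2": {200, 204}},
            "c": {"L1": {100}, "L2": {200}},
            "d": {"L1": {104}, "L2": {204}},
        })
        recs = [
            locus_diversity(allele_frequencies(t, l), t, l,
                            hwe_reps=0, null_boot=0)
            for l in t.loci
        ]
        pid, pidsib = combined_pid(recs)
        assert pid == pytest.approx(0.375**2)
        assert pidsib == pytest.approx(0.59375**2)
        assert combined_pid(recs[:1])[0] == pytest.approx(recs[0].PID)


class TestHWE:
    @staticmethod
    def genotype_table(n_aa, n_ab, n_bb):
        profiles = {}
        for i in range(n_aa):
            profiles[f"aa{i}"] = {"L1": {100}}
        for i in range(n_ab):
            profiles[f"ab{i}"] = {"L1": {100, 104}}
        for i in range(n_bb):
            profiles[f"bb{i}"] = {"L1": {104}}
        return make_table(profiles)

    def test_equilibrium_counts_not_rejected(self):
        t = self.genotype_table(25, 50, 25)
        assert hwe_test(t, "L1", n_mc=2000, seed=1) > 0.5

    def test_heterozygote_void_rejected(self):
        t = self.genotype_table(50, 0, 50)
        assert hwe_test(t, "L1", n_mc=2000, seed=1) < 0.001

    def test_too_few_diploids_gives_nan(self):
        t = self.genotype_table(2, 1, 0)
        assert np.isnan(hwe_test(t, "L1"))

    def test_calibration_on_simulated_hwe_loci(self, hwe_population):
        table, _ = hwe_population
        ps = [hwe_test(table, l, n_mc=400, seed=5) for l in table.loci]
        rejections = np.mean([p < 0.05 for p in ps])
        assert rejections <= 0.25  # ~alpha over 12 loci, binomial noise


class TestNullAlleleScreen:
    @staticmethod
    def with_null_allele(n, null_freq, seed):
        """Visible biallelic locus plus a hidden null at null_freq."""
        rng = np.random.default_rng(seed)
        p = np.array([(1 - null_freq) / 2, (1 - null_freq) / 2, null_freq])
        profiles = {}
        for i in range(n):
            g = rng.choice(3, size=2, p=p)
            visible = {100 + 4 * a for a in g if a < 2}
            if not visible:  # null homozygote scored as missing
                visible = set()
            profiles[f"i{i}"] = {"L1": visible}
        return make_table(profiles)

    def test_flags_planted_null(self):
        flags = []
        for seed in range(6):
            t = self.with_null_allele(200, 0.25, seed)
            _, flag = null_allele_screen(t, "L1", n_boot=300, seed=seed)
            flags.append(flag)
        assert sum(flags) >= 5

    def test_no_flag_under_hwe(self, hwe_population):
        table, _ = hwe_population
        flags = [
            null_allele_screen(table, l, n_boot=300, seed=2)[1]
            for l in table.loci
        ]
        assert np.mean(flags) <= 0.2

    def test_equal_ho_he_estimate_zero(self):
        t = make_table({"a": {"L1": {100, 104}}, "b": {"L1": {100, 104}}})
        est, flag = null_allele_screen(t, "L1", n_boot=100, seed=0)
        assert est <= 0.0 or est == pytest.approx(0.0)
        assert not flag

    def test_monomorphic_locus(self):
        t = make_table({"a": {"L1": {100}}, "b": {"L1": {100}}})
        assert null_allele_screen(t, "L1") == (0.0, False)


class TestDiversityTable:
    def test_pd_column_complements_pid(self, mixed_collection):
        table, _ = mixed_collection
        df = diversity_table(table, hwe_reps=0, null_boot=0)
        per_locus = df[df["locus_id"].isin(table.loci)]
        assert np.allclose(per_locus["PD"], 1 - per_locus["PID"])
        assert len(per_locus) == table.n_loci

    def test_monomorphic_table_degenerate(self):
        t = make_table({
            "a": {"L1": {100}, "L2": {200}},
            "b": {"L1": {100}, "L2": {200}},
        })
        df = diversity_table(t, hwe_reps=0, null_boot=0)
        mean = df[df["locus_id"] == "Mean"].iloc[0]
        total = df[df["locus_id"] == "Total"].iloc[0]
        assert mean["He"] == 0.0
        assert total["PID"] == 1.0
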