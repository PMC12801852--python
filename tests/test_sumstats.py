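import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relictabc import sumstats as ss
from relictabc.coalsim import (DemographicEvent, DemographyProgram, LocusSpec,
                               drop_mutations, simulate_genealogy)
from relictabc.seqio import LocusAlignment

from conftest import make_locus


def locus_from_strings(seqs):
    haps = {}
    for i, s in enumerate(seqs):
        ind = f"X{i + 1}"
        haps[f"{ind}_1"] = s
        haps[f"{ind}_2"] = s
    return LocusAlignment("l", haps)


def _mat(seqs):
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}
    return np.array([[code[c] for c in s] for s in seqs], dtype=np.int8)


class TestNucleotideDiversity:
    def test_single_difference(self):
        assert ss.nucleotide_diversity(_mat(["AAAA", "AAAT"])) == 0.25

    def test_identical_sequences(self):
        assert ss.nucleotide_diversity(_mat(["ACGT"] * 5)) == 0.0

    def test_brute_force_oracle(self, rng):
        """pi equals an explicit double loop over all pairs."""
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(6)]
        mat = _mat(seqs)
        expected = np.mean([
            sum(a != b for a, b in zip(seqs[i], seqs[j])) / 20
            for i, j in itertools.combinations(range(6), 2)
        ])
        assert math.isclose(ss.nucleotide_diversity(mat), expected)

    def test_pairwise_deletion(self):
        # N sites excluded per pair: 1 difference over 3 comparable sites
        assert ss.nucleotide_diversity(_mat(["AANA", "AATT"])) == pytest.approx(1 / 3)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            ss.nucleotide_diversity(_mat(["AAAA"]))


class TestHaplotypeDiversity:
    def test_two_classes_of_two(self):
        mat = _mat(["AA", "AA", "TT", "TT"])
        assert ss.haplotype_diversity(mat) == pytest.approx(2 / 3)

    def test_extremes(self):
        assert ss.haplotype_diversity(_mat(["ACG"] * 6)) == 0.0
        distinct = _mat(["AAA", "CCC", "GGG", "TTT"])
        assert ss.haplotype_diversity(distinct) == 1.0

    def test_recount_oracle(self, rng):
        pool = ["AAA", "AAC", "CCC"]
        seqs = [pool[i] for i in rng.integers(0, 3, 10)]
        counts = np.array([seqs.count(p) for p in set(seqs)])
        n = 10
        expected = n * (1 - ((counts / n) ** 2).sum()) / (n - 1)
        assert math.isclose(ss.haplotype_diversity(_mat(seqs)), expected)


class TestSegregatingSites:
    @pytest.mark.parametrize("seqs,expected", [(["AAAA", "AAAT"], 1), (["AA", "AA"], 0)])
    def test_examples(self, seqs, expected):
        assert ss.segregating_sites(_mat(seqs)) == expected

    def test_equals_mutations_placed(self, rng):
        prog = DemographyProgram(1, [1.0], [[0.0]], [])
        for _ in range(20):
            g = simulate_genealogy(prog, [8], rng)
            mat = drop_mutations(g, LocusSpec("l", 5000, 3.0), rng)
            assert ss.segregating_sites(mat) == mat.shape[1]


def _tajima_oracle(seqs):
    """Independent implementation of the 1989 statistic (constants spelled out)."""
    n = len(seqs)
    L = len(seqs[0])
    S = sum(1 for j in range(L) if len({s[j] for s in seqs}) > 1)
    if S == 0:
        return None
    k = np.mean([sum(a != b for a, b in zip(seqs[i], seqs[j]))
                 for i, j in itertools.combinations(range(n), 2)])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_pair_is_zero_when_variable(self):
        assert ss.tajimas_d(_mat(["AAAA", "AATT"])) == 0.0

    def test_no_variation_undefined(self):
        assert ss.tajimas_d(_mat(["AAAA", "AAAA", "AAAA"])) is None

    def test_worked_case_against_second_implementation(self):
        seqs = ["AAAA", "AAAT", "ACAT", "GCAT"]
        assert ss.tajimas_d(_mat(seqs)) == pytest.approx(_tajima_oracle(seqs), rel=1e-12)

    def test_random_cases_against_second_implementation(self, rng):
        for _ in range(25):
            seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(6)]
            got = ss.tajimas_d(_mat(seqs))
            want = _tajima_oracle(seqs)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, rel=1e-12)

    def test_neutral_simulations_centered(self, rng):
        """Mean D over neutral constant-size replicates is close to 0."""
        prog = DemographyProgram(1, [1.0], [[0.0]], [])
        spec = LocusSpec("l", 100_000, 5.0)
        vals = []
        for _ in range(5000):
            mat = drop_mutations(simulate_genealogy(prog, [20], rng), spec, rng)
            d = ss.tajimas_d_from_counts(
                20, mat.shape[1],
                float((mat.sum(0) * (20 - mat.sum(0))).sum() / (20 * 19 / 2)))
            if d is not None:
                vals.append(d)
        assert abs(np.mean(vals)) < 0.1


def _fs_exact(n, k_obs, theta):
    """Fu's F_S by exact rational Ewens probabilities (big-int Stirling)."""
    stirling = [[0] * (n + 1) for _ in range(n + 1)]
    stirling[0][0] = 1
    for m in range(1, n + 1):
        for k in range(1, m + 1):
            stirling[m][k] = stirling[m - 1][k - 1] + (m - 1) * stirling[m - 1][k]
    th = Fraction(*float(theta).as_integer_ratio())
    probs = [stirling[n][k] * th ** k for k in range(n + 1)]
    total = sum(probs)
    s_prime = sum(probs[k_obs:]) / total
    return math.log(float(s_prime)) - math.log(float(1 - s_prime))


class TestFusFs:
    def test_no_variation_undefined(self):
        assert ss.fus_fs(_mat(["AAAA", "AAAA"])) is None

    def test_exact_stirling_oracle(self, rng):
        """Matches exact rational-arithmetic Ewens tail probabilities, n <= 10."""
        for _ in range(30):
            n = int(rng.integers(3, 11))
            k_obs = int(rng.integers(2, n + 1))
            theta = float(rng.uniform(0.2, 8.0))
            got = ss.fus_fs(n=n, k_obs=k_obs, theta_pi=theta)
            want = _fs_exact(n, k_obs, theta)
            assert got == pytest.approx(want, rel=1e-10)

    def test_neutral_simulations_centered(self, rng):
        """F_S median near 0 under neutrality (n = 20, theta = 5)."""
        prog = DemographyProgram(1, [1.0], [[0.0]], [])
        spec = LocusSpec("l", 100_000, 5.0)
        vals = []
        for _ in range(2000):
            mat = drop_mutations(simulate_genealogy(prog, [20], rng), spec, rng)
            if mat.shape[1] == 0:
                continue
            n = 20
            c = mat.sum(0)
            k_hat = float((c * (n - c)).sum() / (n * (n - 1) / 2))
            k_obs = len(np.unique(mat, axis=0))
            f = ss.fus_fs(n=n, k_obs=k_obs, theta_pi=k_hat)
            if f is not None:
                vals.append(f)
        assert abs(np.median(vals)) < 0.5


class TestEwensWatterson:
    def test_single_class(self):
        f, p = ss.ewens_watterson_test(_mat(["AAA"] * 5), n_null=100)
        assert f == 1.0 and p == 1.0

    def test_all_distinct_forced_f(self):
        mat = _mat(["AAA", "CCC", "GGG", "TTT"])
        f, _ = ss.ewens_watterson_test(mat, n_null=100)
        assert f == pytest.approx(1 / 4)

    def test_against_exact_partition_enumeration(self):
        """n = 6, k = 3: Monte-Carlo p within error of exhaustive enumeration
        over partitions of 6 into 3 classes weighted by Ewens probabilities."""
        def ewens_weight(partition):
            n = sum(partition)
            mult = {}
            for part in partition:
                mult[part] = mult.get(part, 0) + 1
            w = Fraction(math.factorial(n))
            for j, a in mult.items():
                w /= Fraction(j ** a * math.factorial(a))
            return w

        partitions = [p for p in [(4, 1, 1), (3, 2, 1), (2, 2, 2)]]
        weights = {p: ewens_weight(p) for p in partitions}
        total = sum(weights.values())
        fvals = {p: sum((x / 6) ** 2 for x in p) for p in partitions}

        observed = (3, 2, 1)  # e.g. haplotype counts 3/2/1
        f_obs = fvals[observed]
        lo = sum(w for p, w in weights.items() if fvals[p] <= f_obs + 1e-12) / total
        hi = sum(w for p, w in weights.items() if fvals[p] >= f_obs - 1e-12) / total
        p_exact = min(1, 2 * min(float(lo), float(hi)))

        seqs = ["AAA"] * 3 + ["CCC"] * 2 + ["GGG"]
        _, p_mc = ss.ewens_watterson_test(_mat(seqs), n_null=3000, rng_seed=7)
        assert p_mc == pytest.approx(p_exact, abs=0.05)


class TestAllelicRichness:
    def test_worked_example(self):
        # counts {2, 2}, g = 2: closed form 5/3
        assert ss.allelic_richness_from_counts([2, 2], 2) == pytest.approx(5 / 3)

    def test_monomorphic(self):
        assert ss.allelic_richness_from_counts([7], 3) == pytest.approx(1.0)

    def test_full_depth_recovers_allele_count(self):
        counts = [4, 3, 2, 1]
        assert ss.allelic_richness_from_counts(counts, sum(counts)) == pytest.approx(4.0)

    @given(st.lists(st.integers(1, 4), min_size=1, max_size=5), st.integers(1, 12))
    @settings(max_examples=60, derandomize=True)
    def test_equals_exhaustive_enumeration(self, counts, g):
        """Hypergeometric closed form == mean distinct alleles over all
        C(N, g) subsamples, exactly, for N <= 12."""
        n_tot = sum(counts)
        if n_tot > 12 or g > n_tot:
            return
        pool = [i for i, c in enumerate(counts) for _ in range(c)]
        subsets = list(itertools.combinations(pool, g))
        expected = Fraction(sum(len(set(s)) for s in subsets), len(subsets))
        got = ss.allelic_richness_from_counts(counts, g)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_depth_exceeding_copies_rejected(self):
        with pytest.raises(ValueError):
            ss.allelic_richness_from_counts([2, 1], 4)


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        a = _mat(["AAAA"] * 4)
        b = _mat(["TTTT"] * 4)
        assert ss.hudson_fst_matrices([(a, b)]) == pytest.approx(1.0)

    def test_identical_multisets_zero(self):
        a = _mat(["AAAT", "AATT"])
        assert ss.hudson_fst_matrices([(a, a.copy())]) == 0.0

    def test_no_between_diversity_defined_zero(self):
        a = _mat(["AAAA", "AAAA"])
        assert ss.hudson_fst_matrices([(a, a.copy())]) == 0.0

    def test_bounded(self, rng):
        for _ in range(30):
            a = _mat(["".join(rng.choice(list("ACGT"), 8)) for _ in range(4)])
            b = _mat(["".join(rng.choice(list("ACGT"), 8)) for _ in range(4)])
            fst = ss.hudson_fst_matrices([(a, b)])
            assert -1e-9 - 1.0 < fst <= 1.0

    def test_panmictic_split_within_permutation_null(self, tiny_dataset, rng):
        """A random split of one panmictic pool is not significantly
        differentiated (permutation p above 0.05)."""
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(12)]
        pooled = _mat(seqs)
        idx = rng.permutation(12)
        obs = ss.hudson_fst_matrices([(pooled[idx[:6]], pooled[idx[6:]])])
        null = []
        for _ in range(200):
            jdx = rng.permutation(12)
            null.append(ss.hudson_fst_matrices([(pooled[jdx[:6]], pooled[jdx[6:]])]))
        p = np.mean([x >= obs for x in null])
        assert p > 0.05

    def test_pairwise_fst_cluster_ordering(self):
        """Deep inter-region divergence with shallower within-region structure:
        inter-region pairs exceed both intra-region values (echoing the
        observed 0.75-0.79 > 0.54 > 0.39 ordering)."""
        from relictabc.seqio import PhasedMultilocusDataset
        from conftest import make_locus, make_sample_map

        sm = make_sample_map(n_sea=2, n_nea=2)
        # sites 0-7: fixed inter-region difference; sites 8-9: within-region
        # cluster difference; last sites: within-cluster polymorphism
        loc = make_locus("l", {
            "S1_i1": ("AAAAAAAAAACCCC", "AAAAAAAAAACCCT"),
            "S2_i1": ("AAAAAAAATTCCCC", "AAAAAAAATTCTCC"),
            "N1_i1": ("GGGGGGGGAACCCC", "GGGGGGGGAACCTC"),
            "N2_i1": ("GGGGGGGGTTCCCC", "GGGGGGGGTTTCCC"),
        })
        ds = PhasedMultilocusDataset([loc], sm)
        grouping = {"W-SEA": ["S1"], "E-SEA": ["S2"], "W-NEA": ["N1"], "E-NEA": ["N2"]}
        fst, _ = ss.pairwise_fst(ds, grouping)
        inter = [fst.loc[a, b] for a in ("W-SEA", "E-SEA") for b in ("W-NEA", "E-NEA")]
        intra = [fst.loc["W-SEA", "E-SEA"], fst.loc["W-NEA", "E-NEA"]]
        assert min(inter) > max(intra)


class TestSummaryVector:
    def test_deterministic(self, tiny_dataset):
        v1 = ss.summary_vector(tiny_dataset)
        v2 = ss.summary_vector(tiny_dataset)
        assert v1 == v2

    def test_region_swap_symmetry(self, tiny_dataset):
        """Swapping region labels swaps region-indexed entries; F_ST unchanged."""
        from relictabc.seqio import PhasedMultilocusDataset, SampleMap, SampleRecord

        swapped_map = SampleMap([
            SampleRecord(r.individual_id, r.population,
                         "NEA" if r.region == "SEA" else "SEA",
                         r.latitude, r.longitude)
            for r in (tiny_dataset.sample_map[i] for i in tiny_dataset.sample_map.individuals)
        ])
        swapped = PhasedMultilocusDataset(tiny_dataset.loci, swapped_map)
        v = ss.summary_vector(tiny_dataset).to_series()
        w = ss.summary_vector(swapped).to_series()
        assert v["fst_regions"] == w["fst_regions"]
        assert v["SEA_pi_mean"] == w["NEA_pi_mean"]
        assert v["SEA_private_S"] == w["NEA_private_S"]
        assert v["pooled_S_mean"] == w["pooled_S_mean"]

    def test_haplotype_order_invariance(self, rng):
        """Statistics are invariant to the order haplotypes appear in."""
        mats = [_mat(["".join(rng.choice(list("ACGT"), 10)) for _ in range(8)])
                for _ in range(3)]
        idx = {"SEA": np.arange(4), "NEA": np.arange(4, 8)}
        v1 = ss.summary_vector_from_binary([(m == 3).astype(np.int8) for m in mats],
                                           idx, [10, 10, 10])
        perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        v2 = ss.summary_vector_from_binary([(m[perm] == 3).astype(np.int8) for m in mats],
                                           idx, [10, 10, 10])
        assert np.allclose(v1.values, v2.values)

    def test_binary_path_matches_sequence_path(self):
        """The fast binary feature path and the sequence-dataset path agree
        on equivalent complete data."""
        from relictabc.scenarios import catalogue, sample_prior
        from relictabc.coalsim import simulate_dataset, LocusSpec
        import numpy as np

        spec = next(s for s in catalogue() if s.scenario_id == "VIC")
        draw = sample_prior(spec, np.random.default_rng(3))
        loci = [LocusSpec(f"l{i}", 400, 1.2) for i in range(4)]
        ds = simulate_dataset(draw.program, loci, [6, 6], seed=9)
        v_seq = ss.summary_vector(ds)
        from relictabc.coalsim import simulate_binary_replicate
        mats = simulate_binary_replicate(draw.program, [6, 6], loci, seed=9)
        v_bin = ss.summary_vector_from_binary(
            mats, {"SEA": np.arange(6), "NEA": np.arange(6, 12)}, [400] * 4)
        assert np.allclose(v_seq.values, v_bin.values, atol=1e-12)

    def test_divergent_vs_panmictic_fst_feature_separates(self, rng):
        """The F_ST feature distinguishes deep-divergence from panmixia."""
        from relictabc.coalsim import simulate_binary_replicate

        idx = {"SEA": np.arange(6), "NEA": np.arange(6, 12)}
        loci = [LocusSpec(f"l{i}", 500, 2.0) for i in range(5)]
        div = DemographyProgram(2, [1.0, 1.0], np.zeros((2, 2)),
                                [DemographicEvent(2.0, "merge", source=1, dest=0)])
        pan = DemographyProgram(2, [1.0, 1.0], np.full((2, 2), 50.0) - 50 * np.eye(2),
                                [DemographicEvent(0.01, "merge", source=1, dest=0)])
        wins = 0
        for rep in range(100):
            f_div = ss.summary_vector_from_binary(
                simulate_binary_replicate(div, [6, 6], loci, seed=1000 + rep),
                idx, [500] * 5).to_series()["fst_regions"]
            f_pan = ss.summary_vector_from_binary(
                simulate_binary_replicate(pan, [6, 6], loci, seed=2000 + rep),
                idx, [500] * 5).to_series()["fst_regions"]
            wins += f_div > f_pan
        assert wins >= 95


class TestRegionalDiversityShape:
    def test_asymmetric_world_pi_ratio(self):
        """The study-shaped fixture (2:1 theta asymmetry, deep vicariance)
        shows SEA/NEA pi ratio in [1.5, 2.5] and high inter-region F_ST in
        most seeds."""
        from relictabc.synthetic_data import WorldConfig, generate_sequence_world

        ok_ratio = ok_fst = 0
        n_seeds = 8
        for seed in range(n_seeds):
            ds, _ = generate_sequence_world(WorldConfig(seed=seed, n_loci=12))
            v = ss.summary_vector(ds).to_series()
            ratio = v["SEA_pi_mean"] / v["NEA_pi_mean"]
            ok_ratio += 1.5 <= ratio <= 2.5
            ok_fst += v["fst_regions"] > 0.5
        assert ok_ratio >= int(0.8 * n_seeds) - 1
        assert ok_fst >= int(0.8 * n_seeds)
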