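"""Minimum-father reconstruction and Lynch & Ritland relatedness."""

import itertools

import numpy as np
import pytest

import caretta as ct
from caretta.genotypes import Clutch, MultilocusGenotype
from caretta.kinship import IncompatibleMotherError
from caretta.synthetic import draw_parent


def G(*pairs, loci=None):
    loci = loci or tuple(f"L{i+1}" for i in range(len(pairs)))
    return MultilocusGenotype(loci=loci, alleles=tuple(pairs))


def brute_min_fathers(clutch: Clutch, max_k: int = 3) -> int | None:
    """Fully naive oracle: enumerate every (mother, father-set, assignment)
    triple over the observed alleles plus one phantom (unobserved) allele
    per locus, and check Mendelian compatibility directly."""
    n = len(clutch.offspring)
    n_loci = len(clutch.loci)
    pairs_by_locus = []
    for li in range(n_loci):
        observed = sorted(
            {a for g in clutch.offspring if g.alleles[li] for a in g.alleles[li]}
        )
        universe = observed + [9999]  # phantom allele
        pairs_by_locus.append(
            list(itertools.combinations_with_replacement(universe, 2))
        )

    def compatible(off_pair, mother_pair, father_pair):
        if off_pair is None:
            return True
        a, b = off_pair
        m, f = set(mother_pair), set(father_pair)
        return (a in m and b in f) or (b in m and a in f)

    def locus_group_ok(li, mother_pair, members):
        return any(
            all(
                compatible(clutch.offspring[o].alleles[li], mother_pair, fp)
                for o in members
            )
            for fp in pairs_by_locus[li]
        )

    if clutch.maternal_genotype is not None:
        mothers = [tuple(clutch.maternal_genotype.alleles)]
    else:
        mothers = list(itertools.product(*pairs_by_locus))
    for k in range(1, max_k + 1):
        for assignment in itertools.product(range(k), repeat=n):
            if len(set(assignment)) != k:
                continue
            for mother in mothers:
                ok = True
                for li in range(n_loci):
                    for fidx in range(k):
                        members = [o for o in range(n) if assignment[o] == fidx]
                        if not locus_group_ok(li, mother[li], members):
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    return k
    return None


def random_tiny_clutch(rng, n_loci=2, n_alleles=4, n_off=4, k=None):
    k = k if k is not None else int(rng.integers(1, 3))
    loci = tuple(f"L{i+1}" for i in range(n_loci))
    alleles = list(range(101, 101 + n_alleles))

    def parent():
        return G(
            *[tuple(sorted(rng.choice(alleles, 2))) for _ in range(n_loci)], loci=loci
        )

    mother = parent()
    fathers = [parent() for _ in range(k)]
    clutch, _ = ct.simulate_clutch(
        mother, fathers, n_off, int(rng.integers(2**31 - 1)), include_mother=False
    )
    return clutch


class TestDetectMultiplePaternity:
    def test_five_alleles_at_a_locus_is_proof(self):
        off = [G((101, 103)), G((105, 107)), G((107, 109))]
        res = ct.detect_multiple_paternity(Clutch(nest_id="x", offspring=off))
        assert res.flag is True
        assert res.evidencing_loci == ("L1",)
        assert res.allele_counts["L1"] == 5

    def test_identical_homozygotes_are_consistent_with_one_father(self):
        off = [G((101, 101), (105, 105)) for _ in range(6)]
        res = ct.detect_multiple_paternity(Clutch(nest_id="x", offspring=off))
        assert res.flag is False

    def test_known_mother_tightens_the_bound(self):
        # three non-maternal alleles at one locus exceed a single father
        mother = G((101, 103))
        off = [G((101, 105)), G((103, 107)), G((101, 109))]
        clutch = Clutch(nest_id="x", offspring=off, maternal_genotype=mother)
        res = ct.detect_multiple_paternity(clutch)
        assert res.flag is True
        # confirmed independently by the exhaustive search
        assert brute_min_fathers(clutch) >= 2

    def test_all_missing_is_indeterminate(self):
        off = [G(None), G(None)]
        res = ct.detect_multiple_paternity(Clutch(nest_id="x", offspring=off))
        assert res.flag is None

    def test_positive_screen_implies_at_least_two_fathers(self, rng):
        for _ in range(20):
            clutch = random_tiny_clutch(rng, n_loci=3, n_alleles=6, n_off=5)
            res = ct.detect_multiple_paternity(clutch)
            if res.flag:
                assert ct.min_fathers(clutch).k >= 2


class TestMinFathers:
    def test_agrees_with_naive_enumeration_on_tiny_instances(self, rng):
        for _ in range(8):
            clutch = random_tiny_clutch(rng)
            expected = brute_min_fathers(clutch, max_k=3)
            got = ct.min_fathers(clutch, max_fathers=3)
            assert got.k == expected, f"clutch {clutch.offspring}"

    def test_agrees_with_naive_enumeration_with_known_mother(self, rng):
        for _ in range(4):
            clutch = random_tiny_clutch(rng)
            sols = ct.min_fathers(clutch, max_fathers=3).solutions
            mother = sols[0].maternal_genotype
            # re-pose the problem with the reconstructed mother fixed
            loci = clutch.loci
            fixed = Clutch(
                nest_id=clutch.nest_id,
                offspring=clutch.offspring,
                maternal_genotype=MultilocusGenotype(loci=loci, alleles=mother.alleles),
            )
            assert ct.min_fathers(fixed, max_fathers=3).k == brute_min_fathers(fixed)

    def test_recovers_simulated_father_counts(self, baseline):
        """At 7 loci x 8 alleles and 12 offspring, the minimum-father count
        equals the simulated truth in >= 95% of replicates and never
        exceeds it (it is a lower bound by construction)."""
        _, _, truth = baseline
        hits = total = 0
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            for k in (1, 2, 3):
                mother = draw_parent(rng, truth, ct.MED)
                fathers = [draw_parent(rng, truth, ct.MED) for _ in range(k)]
                clutch, _ = ct.simulate_clutch(
                    mother, fathers, 12, rng, include_mother=False
                )
                res = ct.min_fathers(clutch)
                total += 1
                hits += res.k == k
                assert res.k <= k
        assert hits / total >= 0.95

    def test_mendelian_validity_of_solutions(self, baseline):
        _, _, truth = baseline
        rng = np.random.default_rng(5)
        mother = draw_parent(rng, truth, ct.ATL)
        fathers = [draw_parent(rng, truth, ct.ATL) for _ in range(2)]
        clutch, _ = ct.simulate_clutch(mother, fathers, 10, rng, include_mother=False)
        res = ct.min_fathers(clutch)
        assert res.k == 2 and res.solutions
        for sol in res.solutions:
            for o, g in enumerate(clutch.offspring):
                father = sol.paternal_genotypes[sol.father_assignment[o]]
                for li, locus in enumerate(sol.maternal_genotype.loci):
                    off = g.at(locus)
                    mp = sol.maternal_genotype.alleles[li]
                    fp = father.alleles[li]
                    if off is None or fp is None:
                        continue
                    a, b = off
                    assert (a in mp and b in fp) or (b in mp and a in fp)

    def test_two_offspring_flagged_low_power(self):
        off = [G((101, 103), (105, 107)), G((101, 105), (105, 109))]
        res = ct.min_fathers(Clutch(nest_id="x", offspring=off))
        assert res.low_power is True
        assert res.k is not None

    def test_incompatible_known_mother_is_a_data_error(self):
        mother = G((101, 101))
        off = [G((103, 105)), G((103, 103))]
        clutch = Clutch(nest_id="bad", offspring=off, maternal_genotype=mother)
        assert clutch.maternal_incompatibilities()
        with pytest.raises(IncompatibleMotherError, match="L1"):
            ct.min_fathers(clutch)

    def test_sparse_locus_excluded_from_inference(self):
        # L2 typed in 1/4 offspring: below the 50% coverage rule
        off = [
            G((101, 103), (201, 203)),
            G((101, 105), None),
            G((103, 105), None),
            G((101, 103), None),
        ]
        res = ct.min_fathers(Clutch(nest_id="x", offspring=off))
        assert res.loci_used == ("L1",)

    def test_likelihood_ranking_prefers_common_parental_alleles(self):
        off = [G((101, 103)), G((101, 103)), G((101, 103))]
        freqs = {"L1": {101: 0.7, 103: 0.2, 105: 0.1}}
        res = ct.min_fathers(Clutch(nest_id="x", offspring=off), freqs=freqs)
        lls = [s.log_likelihood for s in res.solutions]
        assert all(a >= b for a, b in zip(lls, lls[1:]))


class TestLynchRitland:
    def test_unrelated_pairs_centre_on_zero(self, baseline):
        _, panel, truth = baseline
        freqs = ct.pooled_frequencies(panel.genotypes)
        rng = np.random.default_rng(42)
        vals = [
            ct.lynch_ritland_pair(
                draw_parent(rng, truth, ct.MED), draw_parent(rng, truth, ct.MED), freqs
            )
            for _ in range(500)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_full_sibs_centre_on_half_on_the_doubled_scale(self, baseline):
        _, panel, truth = baseline
        freqs = ct.pooled_frequencies(panel.genotypes)
        rng = np.random.default_rng(43)
        vals = []
        for _ in range(500):
            mother = draw_parent(rng, truth, ct.MED)
            father = draw_parent(rng, truth, ct.MED)
            clutch, _ = ct.simulate_clutch(mother, [father], 2, rng, include_mother=False)
            vals.append(
                ct.lynch_ritland_pair(clutch.offspring[0], clutch.offspring[1], freqs)
            )
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_duplicated_genotype_scores_near_the_maximum(self, baseline):
        _, panel, truth = baseline
        freqs = ct.pooled_frequencies(panel.genotypes)
        rng = np.random.default_rng(44)
        self_vals, unrel_vals = [], []
        for _ in range(200):
            g = draw_parent(rng, truth, ct.ATL)
            h = draw_parent(rng, truth, ct.ATL)
            self_vals.append(ct.lynch_ritland_pair(g, g, freqs))
            unrel_vals.append(ct.lynch_ritland_pair(g, h, freqs))
        assert np.mean(self_vals) > 0.8 > np.mean(unrel_vals) + 0.5

    def test_matrix_symmetry_and_permutation_consistency(self, baseline):
        _, panel, _ = baseline
        samples = panel.genotypes[:12]
        mat = ct.lynch_ritland_matrix(samples)
        np.testing.assert_allclose(mat.doubled, mat.doubled.T)
        assert np.all((mat.doubled >= -1) & (mat.doubled <= 1))
        perm = list(reversed(range(12)))
        mat2 = ct.lynch_ritland_matrix([samples[i] for i in perm])
        np.testing.assert_allclose(
            mat2.doubled, mat.doubled[np.ix_(perm, perm)], atol=1e-12
        )

    def test_raw_values_are_half_the_doubled_scale(self, baseline):
        _, panel, _ = baseline
        mat = ct.lynch_ritland_matrix(panel.genotypes[:6])
        np.testing.assert_allclose(mat.doubled, 2.0 * mat.raw)

    def test_monomorphic_locus_is_skipped(self):
        a = G((101, 101), (201, 203))
        b = G((101, 101), (201, 205))
        freqs = {"L1": {101: 1.0}, "L2": {201: 0.5, 203: 0.3, 205: 0.2}}
        # L1 monomorphic: estimate still defined from L2 alone
        assert ct.lynch_ritland_pair(a, b, freqs) is not None


class TestHeatmapExport:
    def _sib_dataset(self, truth):
        rng = np.random.default_rng(9)
        samples, ids, grouping = [], [], {}
        for nest in range(4):
            mother = draw_parent(rng, truth, ct.MED)
            father = draw_parent(rng, truth, ct.MED)
            clutch, _ = ct.simulate_clutch(
                mother, [father], 5, rng, nest_id=f"N{nest}", include_mother=False
            )
            for oid, g in zip(clutch.offspring_ids, clutch.offspring):
                samples.append(g)
                ids.append(oid)
                grouping[oid] = f"N{nest}"
        return samples, ids, grouping

    def test_pair_count_and_within_vs_between(self, baseline):
        _, panel, truth = baseline
        samples, ids, grouping = self._sib_dataset(truth)
        mat = ct.lynch_ritland_matrix(
            samples, ct.pooled_frequencies(panel.genotypes), sample_ids=ids
        )
        df, summary = ct.relatedness_heatmap_export(mat, grouping)
        n = len(samples)
        assert len(df) == n * (n - 1) // 2
        assert summary["within_nest_mean"] > summary["between_nest_mean"]

    def test_single_nest_grouping(self, baseline):
        _, panel, _ = baseline
        samples = panel.genotypes[:5]
        mat = ct.lynch_ritland_matrix(samples)
        df, _ = ct.relatedness_heatmap_export(
            mat, {s: "N1" for s in mat.sample_ids}
        )
        assert df["same_nest"].all()
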