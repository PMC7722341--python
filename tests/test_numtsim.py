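"""The numtDNA evolution simulator: exactness, determinism, calibration."""

import numpy as np
import pytest

import nimtscan as ns
from nimtscan.core import revcomp
from nimtscan.numtsim import jc_evolve, jc_expected_divergence, _encode


class TestZeroRates:
    def test_inserted_copies_identical_to_source(self, zero_rate_truth):
        tr = zero_rate_truth
        for ins in tr.insertions:
            nu, mt = ins.numt.nuclear, ins.numt.mt_source
            copy = tr.nuclear.sequence[nu.start:nu.end]
            src = tr.template.genome.sequence[mt.start:mt.end]
            assert copy == (src if mt.strand == "+" else revcomp(src))

    def test_truth_mtl_coordinates_carry_exact_gene_sequences(self, zero_rate_truth):
        tr = zero_rate_truth
        for ins in tr.insertions:
            src = ins.numt.mt_source
            for m in ins.mtls:
                seq = tr.nuclear.sequence[m.nuclear.start:m.nuclear.end]
                if m.nuclear.strand == "-":
                    seq = revcomp(seq)
                gs = max(src.start, m.mt_gene.start)
                ge = min(src.end, m.mt_gene.end)
                assert seq == tr.template.genome.sequence[gs:ge]

    def test_extant_mito_unchanged(self, zero_rate_truth):
        assert zero_rate_truth.extant_mito.sequence == \
            zero_rate_truth.template.genome.sequence


class TestInvariants:
    def test_determinism_same_seed_same_output(self):
        p = dict(seed=7, n_insertions=4, nuclear_length=15_000)
        a = ns.simulate(ns.EvolutionParams(**p))
        b = ns.simulate(ns.EvolutionParams(**p))
        assert a.nuclear.sequence == b.nuclear.sequence
        assert a.extant_mito.sequence == b.extant_mito.sequence
        assert [i.t0 for i in a.insertions] == [i.t0 for i in b.insertions]
        assert [m.mtl_id for m in a.mtls] == [m.mtl_id for m in b.mtls]

    def test_total_inserted_length_conserved(self, evolved_truth):
        tr = evolved_truth
        inserted = sum(i.numt.nuclear.length for i in tr.insertions)
        assert len(tr.nuclear.sequence) == tr.params.nuclear_length
        assert inserted == sum(i.numt.mt_source.length for i in tr.insertions)

    def test_truth_mtl_count_matches_containment_rule(self, evolved_truth):
        tr = evolved_truth
        for ins in tr.insertions:
            src = ins.numt.mt_source
            expected = [g for g in tr.template.genes
                        if max(0, min(src.end, g.end) - max(src.start, g.start))
                        * 2 >= g.length]
            assert sorted(m.isotype for m in ins.mtls) == \
                sorted(g.isotype for g in expected)

    def test_every_mtl_inside_its_numt(self, evolved_truth):
        for ins in evolved_truth.insertions:
            for m in ins.mtls:
                assert ins.numt.nuclear.contains(m.nuclear)
            assert 0 < ins.t0 <= evolved_truth.params.t_max

    def test_saturating_rates_refused(self):
        with pytest.raises(ValueError, match="0.75"):
            ns.EvolutionParams(sn=0.1, sp=0.3, t_max=3.0)

    def test_mean_divergence_monotone_in_insertion_age(self):
        """Mean dt and dp are non-decreasing in t0 over a grid."""
        means = []
        for t0 in (0.2, 1.0, 2.0):
            divs = []
            for seed in range(30):
                p = ns.EvolutionParams(seed=seed, sn=0.02, sp=0.1,
                                       fixed_insertion_time=t0, t_max=2.0,
                                       n_insertions=1, nuclear_length=3000,
                                       insertion_length_range=(400, 400),
                                       functional_fraction=0, intronic_fraction=0)
                tr = ns.simulate(p)
                ins = tr.insertions[0]
                nu, mt = ins.numt.nuclear, ins.numt.mt_source
                copy = tr.nuclear.sequence[nu.start:nu.end]
                if mt.strand == "-":
                    copy = revcomp(copy)
                divs.append(ns.divergence(
                    copy, tr.extant_mito.sequence[mt.start:mt.end]))
            means.append(np.mean(divs))
        assert means[0] < means[1] < means[2]


class TestJukesCantor:
    def test_site_substitution_probability_matches_closed_form(self):
        rng = np.random.default_rng(0)
        arr = _encode("A" * 200_000)
        out = jc_evolve(arr, 0.1, 1.0, rng)
        p_obs = np.mean(out != arr)
        p_exp = jc_expected_divergence(0.1, 1.0)
        se = np.sqrt(p_exp * (1 - p_exp) / arr.size)
        assert abs(p_obs - p_exp) < 4 * se

    def test_changed_bases_uniform_over_alternatives(self):
        rng = np.random.default_rng(1)
        arr = _encode("A" * 90_000)
        out = jc_evolve(arr, 0.5, 1.0, rng)
        changed = out[out != arr]
        counts = [np.sum(changed == ord(b)) for b in "CGT"]
        assert max(counts) - min(counts) < 6 * np.sqrt(len(changed) / 3)

    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(2)
        arr = _encode("ACGTACGT")
        assert np.array_equal(jc_evolve(arr, 0.0, 5.0, rng), arr)

    def test_small_indel_mode_perturbs_divergence_only_mildly(self):
        """Alignment-based divergence is robust to sparse small indels."""
        from nimtscan.numtsim import evolve_with_indels
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 2000))
        mutant = evolve_with_indels(seq, sub_rate=0.1, indel_rate=0.002,
                                    time=1.0, rng=rng)
        assert len(mutant) != len(seq) or mutant != seq
        div = ns.divergence(seq, mutant)
        expected = jc_expected_divergence(0.1, 1.0)
        assert abs(div - expected) < 0.05


class TestBindingSiteSimulation:
    def test_null_fold_densities_indistinguishable(self, evolved_truth):
        """fold=1: nimtRNA and background densities agree (two-proportion)."""
        from scipy.stats import norm
        tr = evolved_truth
        sites = ns.simulate_binding_sites(tr, ["RBP00"], 1.0, seed=5)
        r = tr.binding_truth["realized"]["RBP00"]
        # pooled two-proportion z-test at alpha = 0.01
        from nimtscan.rbp import merged_length
        n1 = merged_length([m.nuclear for m in tr.nimtrnas])
        d1, d2 = r["density_nimt"], r["density_bg"]
        pool = (d1 * n1 + d2 * 10_000) / (n1 + 10_000)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / 10_000))
        assert abs(d1 - d2) < norm.ppf(0.995) * se + 0.05

    def test_empty_enriched_list_behaves_as_background(self, evolved_truth):
        tr = evolved_truth
        ns.simulate_binding_sites(tr, [], 5.0, seed=3)
        realized = tr.binding_truth["realized"]
        ratios = [v["density_nimt"] / v["density_bg"] for v in realized.values()
                  if v["density_bg"] > 0]
        assert np.median(ratios) < 2.5

    def test_fold_must_be_positive(self, evolved_truth):
        with pytest.raises(ValueError):
            ns.simulate_binding_sites(evolved_truth, [], 0.0, seed=1)

    def test_sites_are_stranded_and_deterministic(self, evolved_truth):
        a = ns.simulate_binding_sites(evolved_truth, ["RBP01"], 3.0, seed=9)
        b = ns.simulate_binding_sites(evolved_truth, ["RBP01"], 3.0, seed=9)
        assert a == b
        for rbp, sites in a.items():
            assert all(s.interval.strand in "+-" for s in sites)
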