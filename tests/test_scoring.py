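"""Fragment generation, matching, Poisson scoring, two-step search."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from xlscout.chemistry import DSS, CrossLinkCandidate
from xlscout.proteome import RESIDUE_MASS, WATER, Peptide
from xlscout.scoring import (FragTol, LinearCandidate, SearchConfig,
                             linear_fragments, match_fragments,
                             poisson_pvalue, score_spectrum,
                             theoretical_fragments, two_step_search)
from xlscout.simulate import gen_proteome, gen_spectra
from xlscout.spectra import NeutralPeakList, deconvolute


def make_candidate(seq_a, seq_b, pos_a, pos_b, form="light"):
    pa = Peptide("A", 1, len(seq_a), seq_a)
    pb = Peptide("B", 1, len(seq_b), seq_b)
    return CrossLinkCandidate(
        pa, pb, pos_a, pos_b, form,
        pa.mass + pb.mass + DSS.bridge_mass(form), DSS)


class TestTheoreticalFragments:
    def test_ion_count_formula(self):
        cand = make_candidate("AGKLV", "GKAR", 3, 2)
        frags = theoretical_fragments(cand)
        assert len(frags) == 2 * 4 + 2 * 3  # 2(n_a-1) + 2(n_b-1)

    def test_y1_without_link_is_plain_residue(self):
        cand = make_candidate("AGKLV", "GKAR", 3, 2)
        y1_alpha = next(f for f in frags_of(cand, "alpha", "y", 1))
        assert not y1_alpha.carries_partner
        assert y1_alpha.neutral_mass == pytest.approx(
            RESIDUE_MASS["V"] + WATER, abs=1e-6)

    def test_spanning_fragments_carry_partner(self):
        cand = make_candidate("AGK", "GKR", 3, 2)
        partner_mass = cand.peptide_beta.mass
        b2 = next(f for f in frags_of(cand, "alpha", "b", 2))
        assert not b2.carries_partner  # b2 of AGK does not reach K3
        y1 = next(f for f in frags_of(cand, "alpha", "y", 1))
        assert y1.carries_partner
        assert y1.neutral_mass == pytest.approx(
            RESIDUE_MASS["K"] + WATER + DSS.bridge_mass_light + partner_mass,
            abs=1e-6)

    def test_toy_pair_matches_brute_force(self):
        """Full mass list of a 3x3 pair against prefix/suffix enumeration."""
        seq_a, seq_b, la, lb = "AGK", "GKR", 3, 2
        cand = make_candidate(seq_a, seq_b, la, lb)
        got = sorted(f.neutral_mass for f in theoretical_fragments(cand))
        bridge = DSS.bridge_mass_light
        expect = []
        for seq, link, partner in ((seq_a, la, seq_b), (seq_b, lb, seq_a)):
            pmass = sum(RESIDUE_MASS[c] for c in partner) + WATER
            for i in range(1, len(seq)):
                b = sum(RESIDUE_MASS[c] for c in seq[:i])
                if i >= link:
                    b += bridge + pmass
                y = sum(RESIDUE_MASS[c] for c in seq[len(seq) - i:]) + WATER
                if i >= len(seq) - link + 1:
                    y += bridge + pmass
                expect.extend([b, y])
        assert got == pytest.approx(sorted(expect), abs=1e-9)


def frags_of(cand, origin, series, index):
    return [f for f in theoretical_fragments(cand)
            if f.origin == origin and f.series == series and f.index == index]


def oracle_max_matching(theo_masses, peaks, tol: FragTol):
    g = nx.Graph()
    t_nodes = [("t", i) for i in range(len(theo_masses))]
    p_nodes = [("p", j) for j in range(len(peaks))]
    g.add_nodes_from(t_nodes)
    g.add_nodes_from(p_nodes)
    for i, tm in enumerate(theo_masses):
        for j, pm in enumerate(peaks):
            if abs(pm - tm) <= tol.window(tm):
                g.add_edge(("t", i), ("p", j))
    return len(nx.algorithms.matching.max_weight_matching(
        g, maxcardinality=True))


class TestMatchFragments:
    def test_perfect_match(self):
        cand = make_candidate("AGKLV", "GKAR", 3, 2)
        frags = theoretical_fragments(cand)
        peaks = NeutralPeakList("s", 5000.0,
                                [(f.neutral_mass, 1.0) for f in frags])
        n_m, n_t = match_fragments(frags, peaks)
        assert n_m == n_t == len(frags)

    def test_empty_peaks(self):
        cand = make_candidate("AGKLV", "GKAR", 3, 2)
        frags = theoretical_fragments(cand)
        n_m, n_t = match_fragments(frags, NeutralPeakList("s", 5000.0, []))
        assert (n_m, n_t) == (0, len(frags))

    def test_one_to_one_assignment(self):
        """Two ions near one peak: only one may claim it."""
        cand = make_candidate("AGK", "GKR", 3, 2)
        frags = theoretical_fragments(cand)[:2]
        peak = frags[0].neutral_mass + 0.001
        peaks = NeutralPeakList("s", 5000.0, [(peak, 1.0)])
        tol = FragTol(abs_da=5.0, ppm=10.0)
        n_m, _ = match_fragments(frags, peaks, tol)
        assert n_m == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_count_matches_bipartite_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        theo = sorted(rng.uniform(100, 1000, size=8))
        peaks = sorted(rng.uniform(100, 1000, size=10))
        tol = FragTol(abs_da=20.0, ppm=10.0)

        class Frag:
            def __init__(self, m):
                self.neutral_mass = m

        n_m, _ = match_fragments([Frag(m) for m in theo],
                                 NeutralPeakList("s", 5000.0,
                                                 [(p, 1.0) for p in peaks]),
                                 tol)
        assert n_m == oracle_max_matching(theo, peaks, tol)


class TestPoisson:
    def test_zero_matched_is_one(self):
        assert poisson_pvalue(0, 20, 0.05) == 1.0

    def test_closed_form_mu_one(self):
        # mu = 1, n = 1: P[X >= 1] = 1 - exp(-1)
        assert poisson_pvalue(1, 20, 0.05) == pytest.approx(0.6321206, abs=1e-7)

    def test_monotone_in_matches(self):
        ps = [poisson_pvalue(n, 30, 0.03) for n in range(0, 12)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_p_match(self):
        with pytest.raises(ValueError):
            poisson_pvalue(1, 10, 1.5)


class TestScoreSpectrum:
    def test_zero_matched_single_candidate(self):
        cand = make_candidate("AGKLV", "GKAR", 3, 2)
        peaks = NeutralPeakList("s", 3000.0, [])
        (m,) = score_spectrum(peaks, [cand])
        assert m.p_value == 1.0 and m.e_value == 1.0

    def test_planted_candidate_ranks_first(self, small_proteome):
        spectra, truth = gen_spectra(small_proteome, n_links=5,
                                     frag_fraction=1.0, ppm_sigma=0.0,
                                     n_noise_peaks=0, seed=21)
        from xlscout.chemistry import PeptideIndex, enumerate_candidates
        index = PeptideIndex.from_proteins(small_proteome)
        for sp in spectra:
            link = truth.provenance[sp.scan_id]
            peaks = deconvolute(sp)
            cands = enumerate_candidates(index, peaks.precursor_neutral_mass,
                                         "light", 10.0)
            if not cands:
                continue
            ranked = score_spectrum(peaks, cands)
            top = ranked[0].candidate
            assert top.key == link.candidate.key

    def test_evalue_scales_with_candidate_count(self):
        cand = make_candidate("AGKLV", "GKAR", 3, 2)
        frags = theoretical_fragments(cand)
        peaks = NeutralPeakList("s", 3000.0,
                                [(f.neutral_mass, 1.0) for f in frags[:4]])
        (single,) = score_spectrum(peaks, [cand])
        doubled = score_spectrum(peaks, [cand, cand])
        assert doubled[0].e_value == pytest.approx(2 * single.e_value)


class TestTwoStepSearch:
    def test_self_validation(self, small_proteome):
        spectra, truth = gen_spectra(small_proteome, n_links=8,
                                     frag_fraction=0.9, ppm_sigma=3.0,
                                     n_noise_peaks=5, seed=31)
        hits = two_step_search(spectra, small_proteome, small_proteome)
        assert hits, "step 2 against the same database must validate hits"
        want = {tuple(sorted([(l.protein_a, l.residue_a),
                              (l.protein_b, l.residue_b)]))
                for l in truth.links}
        got = {tuple(sorted([(h.protein_a, h.residue_a),
                             (h.protein_b, h.residue_b)])) for h in hits}
        assert got <= want

    def test_decoy_database_does_not_displace(self, small_proteome,
                                              decoy_proteome):
        spectra, truth = gen_spectra(small_proteome, n_links=10,
                                     frag_fraction=0.9, ppm_sigma=3.0,
                                     n_noise_peaks=5, seed=32)
        hits = two_step_search(spectra, small_proteome,
                               small_proteome + decoy_proteome)
        assert len(hits) >= 9

    def test_pure_noise_not_validated(self, small_proteome, decoy_proteome):
        spectra, _ = gen_spectra(small_proteome, n_links=0, n_pure_noise=30,
                                 seed=33)
        hits = two_step_search(spectra, small_proteome,
                               small_proteome + decoy_proteome)
        assert hits == []

    def test_isotope_pairing_flagged(self, small_proteome):
        spectra, truth = gen_spectra(small_proteome, n_links=4,
                                     frag_fraction=1.0, ppm_sigma=1.0,
                                     n_noise_peaks=0, isotope_pairing=True,
                                     seed=34)
        cfg = SearchConfig(pair_rt_window=None)
        hits = two_step_search(spectra, small_proteome, small_proteome, cfg)
        assert any(h.isotope_evidence == "paired" for h in hits)

    def test_determinism(self, small_proteome, decoy_proteome):
        spectra, _ = gen_spectra(small_proteome, n_links=5, seed=35)
        a = two_step_search(spectra, small_proteome,
                            small_proteome + decoy_proteome)
        b = two_step_search(spectra, small_proteome,
                            small_proteome + decoy_proteome)
        assert a == b

    def test_missing_database_rejected(self, small_proteome):
        with pytest.raises(ValueError):
            two_step_search([], [], small_proteome)


class TestEvalueCalibration:
    def test_noise_evalues_conservative(self, small_proteome):
        """On pure-noise spectra the E-value must be honest: the fraction
        of spectra whose best hit reaches e <= t stays within a small
        multiple of t."""
        spectra, _ = gen_spectra(small_proteome, n_links=0, n_pure_noise=100,
                                 seed=41)
        from xlscout.chemistry import PeptideIndex, enumerate_candidates
        index = PeptideIndex.from_proteins(small_proteome)
        t = 0.05
        n_low = 0
        for sp in spectra:
            peaks = deconvolute(sp)
            cands = enumerate_candidates(index, peaks.precursor_neutral_mass,
                                         "light", 10.0)
            ranked = score_spectrum(peaks, cands)
            if ranked and ranked[0].e_value <= t:
                n_low += 1
        assert n_low <= 3 * t * len(spectra)
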