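"""Precursor matching, the b->complementary-y filter, scoring, localization."""

import numpy as np
import pytest

from xlpm.chem import DSS, SDA, N_TERMINUS, neutral_mass_to_mz
from xlpm.database import build_pair_database
from xlpm.search import (
    DEFAULT_RYB,
    RybTable,
    SearchConfig,
    by_filter_match,
    localize_sites,
    match_precursors,
    xlpm_score,
    _chain_ladders,
)
from xlpm.spectra_io import Spectrum
from xlpm.synthetic import CLEAN_PARAMS, SimulationParams, simulate_spectrum
from tests.conftest import brute_force_fragment_counts, make_peptide

CONFIG = SearchConfig()


def _pair(seq_a="MAKDDGSK", start_a=1, seq_b="DDGSKR", start_b=4, linker=DSS):
    pairs = build_pair_database(
        [make_peptide(seq_a, start_a), make_peptide(seq_b, start_b)], linker
    )
    match = [p for p in pairs
             if {p.peptide_a.sequence, p.peptide_b.sequence} == {seq_a, seq_b}]
    assert len(match) == 1
    return match[0]


def _empty_spectrum(pair, charge=4):
    return Spectrum("empty", neutral_mass_to_mz(pair.mass, charge), charge,
                    np.array([]), np.array([]))


class TestRybTable:
    def test_nearest_charge_fallback(self):
        t = RybTable({2: 0.5, 4: 0.3})
        assert t[2] == 0.5 and t[4] == 0.3
        assert t[3] == 0.5  # tie toward the lower charge
        assert t[7] == 0.3

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ValueError):
            RybTable({2: 1.5})


class TestScore:
    @pytest.mark.parametrize(
        "nmb,ntb,nmy,nty,ryb,expected",
        [
            (8, 8, 8, 8, 0.5, 3.0),   # saturated: 1 + 1/Ryb
            (0, 8, 0, 8, 0.5, 0.0),
            (4, 8, 2, 8, 0.25, 1.5),  # 0.5 + 0.25 * 4
        ],
    )
    def test_arithmetic(self, nmb, ntb, nmy, nty, ryb, expected):
        table = RybTable({4: ryb})
        assert xlpm_score(nmb, ntb, nmy, nty, table, 4) == pytest.approx(expected)

    def test_global_grouping_divides_both_terms(self):
        table = RybTable({4: 0.5})
        assert xlpm_score(4, 8, 2, 8, table, 4, grouping="global") == pytest.approx(
            (0.5 + 0.25) / 0.5
        )

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            xlpm_score(0, 0, 0, 0, DEFAULT_RYB, 4)


class TestByFilter:
    def test_saturated_clean_spectrum(self):
        pair = _pair()
        sites = pair.site_combinations()[0]
        spec, _ = simulate_spectrum(pair, sites, 4, CLEAN_PARAMS, seed=1)
        res = by_filter_match(spec, pair, *sites, CONFIG)
        assert res.n_matched_b == res.n_total_b
        assert res.n_matched_y == res.n_total_y
        assert res.n_total_b == (len(pair.peptide_a) - 1) + (len(pair.peptide_b) - 1)
        assert res.score == pytest.approx(1 + 1 / DEFAULT_RYB[4])

    def test_empty_spectrum_gives_zero_counts(self):
        pair = _pair()
        sites = pair.site_combinations()[0]
        res = by_filter_match(_empty_spectrum(pair), pair, *sites, CONFIG)
        assert (res.n_matched_b, res.n_matched_y, res.score) == (0, 0, 0.0)

    def test_b_only_spectrum_yields_no_complements(self):
        """Complementary y ions are sought, never assumed: a spectrum holding
        only b-series peaks produces Nmy = 0."""
        pair = _pair()
        sites = pair.site_combinations()[0]
        (b_a, _), (b_b, _) = _chain_ladders(pair, *sites)
        mzs = [neutral_mass_to_mz(m, 1) for m in np.concatenate([b_a, b_b])]
        spec = Spectrum("b-only", neutral_mass_to_mz(pair.mass, 4), 4,
                        np.array(mzs), np.ones(len(mzs)))
        res = by_filter_match(spec, pair, *sites, CONFIG)
        assert res.n_matched_b > 0
        assert res.n_matched_y == 0

    def test_matches_brute_force_matcher(self):
        """Counts agree with an exhaustive independent matcher on noisy
        simulated fixtures."""
        pair = _pair("MAKWDDGSK", 1, "KLEDAGHR", 20)
        params = SimulationParams(detect_prob=0.6, noise_peaks=30, mz_jitter=0.1)
        for seed in range(8):
            sites = pair.site_combinations()[seed % len(pair.site_combinations())]
            spec, _ = simulate_spectrum(pair, sites, 5, params, seed=seed)
            res = by_filter_match(spec, pair, *sites, CONFIG)
            ladders = _chain_ladders(pair, *sites)
            nmb = nmy = 0
            for b, y in ladders:
                db, dy = brute_force_fragment_counts(
                    spec, b, y, 5, CONFIG.fragment_tol_da
                )
                nmb += db
                nmy += dy
            assert (res.n_matched_b, res.n_matched_y) == (nmb, nmy)

    def test_higher_charge_fragments_are_annotated(self):
        """4+ precursors produce multi-charged fragment matches: removing all
        z>=2 fragment peaks lowers the matched-b count."""
        pair = _pair("MAKWDDGSK", 1, "KLEDAGHR", 20)
        sites = pair.site_combinations()[0]
        rng_spec, _ = simulate_spectrum(pair, sites, 5, CLEAN_PARAMS, seed=11)
        full = by_filter_match(rng_spec, pair, *sites, CONFIG)
        (b_a, y_a), (b_b, y_b) = _chain_ladders(pair, *sites)
        singly = set()
        for ladder in (b_a, y_a, b_b, y_b):
            singly.update(round(neutral_mass_to_mz(m, 1), 3) for m in ladder)
        kept = [m for m in rng_spec.mz if round(m, 3) in singly]
        stripped = Spectrum("stripped", rng_spec.precursor_mz, 5,
                            np.array(kept), np.ones(len(kept)))
        reduced = by_filter_match(stripped, pair, *sites, CONFIG)
        assert reduced.n_matched_b < full.n_matched_b

    def test_score_monotone_in_added_theoretical_peak(self):
        """Appending a peak at a theoretical fragment m/z never lowers the
        score."""
        pair = _pair()
        sites = pair.site_combinations()[0]
        params = SimulationParams(detect_prob=0.4, noise_peaks=0, mz_jitter=0.0)
        spec, _ = simulate_spectrum(pair, sites, 4, params, seed=5)
        base = by_filter_match(spec, pair, *sites, CONFIG).score
        (b_a, _), _ = _chain_ladders(pair, *sites)
        for frag in b_a:
            mzs = np.append(spec.mz, neutral_mass_to_mz(frag, 1))
            augmented = Spectrum("aug", spec.precursor_mz, 4, mzs, np.ones(len(mzs)))
            assert by_filter_match(augmented, pair, *sites, CONFIG).score >= base


class TestPrecursorMatch:
    def test_exact_mass_always_matches(self):
        pair = _pair()
        spec = _empty_spectrum(pair, 4)
        out = match_precursors([spec], [pair], CONFIG)
        assert [(s.scan_id, p.mass) for s, _, p in out] == [("empty", pair.mass)]

    def test_boundary_just_outside_tolerance_excluded(self):
        pair = _pair()
        off = pair.mass * (1 + 10.1e-6)
        spec = Spectrum("off", neutral_mass_to_mz(off, 4), 4,
                        np.array([]), np.array([]))
        assert match_precursors([spec], [pair], CONFIG) == []

    def test_planted_spectra_match_only_their_pairs(self):
        """With pair masses separated by > 50 ppm, each planted spectrum
        matches exactly its own pair at 5 ppm."""
        peps = [make_peptide(s, 1 + 10 * i) for i, s in enumerate(
            ["MAKDDGSK", "KLEDAGHR", "WWKGGDDR", "KHHLLMNR", "AAKYYEGR"]
        )]
        pairs = build_pair_database(peps, DSS)
        config = SearchConfig(precursor_ppm=5.0)
        masses = sorted(p.mass for p in pairs)
        spaced = [m for i, m in enumerate(masses)
                  if i == 0 or (m - masses[i - 1]) / m * 1e6 > 50]
        chosen = [p for p in pairs if p.mass in spaced][:5]
        spectra = [
            Spectrum(f"s{i}", neutral_mass_to_mz(p.mass, 4), 4,
                     np.array([]), np.array([]))
            for i, p in enumerate(chosen)
        ]
        out = match_precursors(spectra, pairs, config)
        assert len(out) == len(chosen)
        for (spec, _, matched), planted in zip(sorted(out, key=lambda t: t[0].scan_id),
                                               chosen):
            assert matched.mass == pytest.approx(planted.mass)

    def test_chargeless_spectrum_tries_candidate_charges(self):
        pair = _pair()
        spec = Spectrum("nocharge", neutral_mass_to_mz(pair.mass, 5), None,
                        np.array([]), np.array([]))
        out = match_precursors([spec], [pair], CONFIG)
        assert [(z, p.mass) for _, z, p in out] == [(5, pair.mass)]

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            match_precursors([], [], CONFIG)


class TestLocalization:
    def test_planted_site_recovered_without_ambiguity(self):
        """Clean spectra discriminate the true site among several candidates
        on a non-specific end."""
        pair = _pair("MAKWDDGSK", 1, "GAVLDER", 20, linker=SDA)
        combos = pair.site_combinations()
        assert len(combos) > 2
        truth = combos[3]
        spec, _ = simulate_spectrum(pair, truth, 4, CLEAN_PARAMS, seed=2)
        res = localize_sites(spec, pair, CONFIG)
        assert (res.site_a, res.site_b) == truth
        assert res.ambiguous_sites == ()

    def test_no_discriminating_fragments_flags_all_sites(self):
        pair = _pair("MAKWDDGSK", 1, "GAVLDER", 20, linker=SDA)
        res = localize_sites(_empty_spectrum(pair), pair, CONFIG)
        assert res.score == 0.0
        assert set(res.ambiguous_sites) == set(pair.site_combinations())
        # deterministic tie-break: the lexicographically smallest assignment
        assert (res.site_a, res.site_b) == pair.site_combinations()[0]

    def test_single_site_pair_evaluates_one_combination(self):
        # canonical chain order puts DDGSKR (site 5) first
        pair = _pair("GAKDDGSR", 10, "DDGSKR", 30)
        assert pair.site_combinations() == [(5, 3)]
        res = localize_sites(_empty_spectrum(pair), pair, CONFIG)
        assert (res.site_a, res.site_b) == (5, 3)
        assert res.ambiguous_sites == ()
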