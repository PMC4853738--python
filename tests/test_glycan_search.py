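"""Y1 filtering, the weighted Y-ion score, and database ranking."""

import numpy as np
import pytest

from glycopipe import glycan_search as GS
from glycopipe.glycans import CORE_IONS, enumerate_y_ions, parse_glycan
from glycopipe.masses import MONOSACCHARIDES, mz_from_neutral
from glycopipe.spectra import Peak, Spectrum, SpectrumPair
from glycopipe.synthetic import SimConfig, random_glycan_db, simulate_run


BACKBONE = 1407.80856


def pair_from_peaks(hcd_peaks, cid_peaks, precursor_neutral, charge=2):
    mz = mz_from_neutral(precursor_neutral, charge)
    hcd = Spectrum(
        title="h", precursor_mz=mz, precursor_charge=charge, retention_time=100.0,
        peaks=[Peak(m, i) for m, i in hcd_peaks], kind="HCD2",
    )
    cid = Spectrum(
        title="c", precursor_mz=mz, precursor_charge=charge, retention_time=101.0,
        peaks=[Peak(m, i) for m, i in cid_peaks], kind="CID2",
    )
    return SpectrumPair(hcd=hcd, cid=cid)


def core_peak(label, backbone=BACKBONE, z=1, inten=100.0):
    return (mz_from_neutral(backbone + CORE_IONS[label], z), inten)


class TestDeduceBackbone:
    def test_consistent_with_worked_example(self):
        # glycan (6,5,1,0,1): 6 Hex + 5 HexNAc + NeuAc + dHex
        gm = (
            6 * MONOSACCHARIDES["Hex"] + 5 * MONOSACCHARIDES["HexNAc"]
            + MONOSACCHARIDES["NeuAc"] + MONOSACCHARIDES["dHex"]
        )
        backbone = GS.deduce_backbone(BACKBONE + gm, gm)
        assert backbone == pytest.approx(BACKBONE, abs=1e-6)
        # printed as MH+ 1408.816 in reports
        assert mz_from_neutral(backbone, 1) == pytest.approx(1408.8158, abs=1e-3)

    def test_nonpositive_discarded(self):
        assert GS.deduce_backbone(1000.0, 1000.0) is None
        assert GS.deduce_backbone(1000.0, 1200.0) is None

    def test_zero_glycan_degenerate(self):
        assert GS.deduce_backbone(1000.0, 0.0) == 1000.0


class TestFilterY1:
    params = GS.ScoringParams()

    def test_three_core_ions_pass(self, trimannosyl_core):
        pair = pair_from_peaks(
            [core_peak("Y0"), core_peak("Y1"), core_peak("Y2")],
            [],
            BACKBONE + trimannosyl_core.mass,
        )
        ok, matches = GS.filter_y1(pair, trimannosyl_core, self.params)
        assert ok and len({m.ion_label for m in matches}) >= 3

    def test_y1_x0_pair_same_charge_passes(self, trimannosyl_core):
        pair = pair_from_peaks(
            [core_peak("Y1", z=2), core_peak("0,2X0", z=2)],
            [],
            BACKBONE + trimannosyl_core.mass,
        )
        ok, _ = GS.filter_y1(pair, trimannosyl_core, self.params)
        assert ok

    def test_y1_x0_in_different_charges_fails(self, trimannosyl_core):
        pair = pair_from_peaks(
            [core_peak("Y1", z=1), core_peak("0,2X0", z=2)],
            [],
            BACKBONE + trimannosyl_core.mass,
        )
        ok, _ = GS.filter_y1(pair, trimannosyl_core, self.params)
        assert not ok

    def test_only_y1_fails(self, trimannosyl_core):
        pair = pair_from_peaks(
            [core_peak("Y1")], [], BACKBONE + trimannosyl_core.mass
        )
        ok, _ = GS.filter_y1(pair, trimannosyl_core, self.params)
        assert not ok

    def test_core_ions_split_across_pair_count_together(self, trimannosyl_core):
        pair = pair_from_peaks(
            [core_peak("Y0"), core_peak("Y1")],
            [core_peak("Y2")],
            BACKBONE + trimannosyl_core.mass,
        )
        ok, _ = GS.filter_y1(pair, trimannosyl_core, self.params)
        assert ok


class TestScore:
    params = GS.ScoringParams()

    def test_no_matches_scores_zero(self, trimannosyl_core):
        pair = pair_from_peaks([(500.0, 1.0)], [], BACKBONE + trimannosyl_core.mass)
        gsm = GS.score_glycan(pair, trimannosyl_core, BACKBONE, self.params)
        assert gsm.score == 0.0

    def test_perfect_single_peak_full_ratio(self):
        # a single-HexNAc glycan whose entire theoretical set is matched
        glycan = parse_glycan("(N)")
        ions = GS.glycan_ion_offsets(glycan)
        peaks = [
            (mz_from_neutral(BACKBONE + i.offset, 1), 100.0) for i in ions
        ]
        pair = pair_from_peaks(peaks, [], BACKBONE + glycan.mass)
        gsm = GS.score_glycan(pair, glycan, BACKBONE, self.params)
        # every peak matched at merr 0 with unit ratios: score = sum intensities
        assert gsm.score == pytest.approx(100.0 * len(ions), rel=1e-6)

    def test_match_at_tolerance_boundary_contributes_nothing(self):
        glycan = parse_glycan("(N)")
        ions = GS.glycan_ion_offsets(glycan)
        tol = self.params.frag_tol_ppm * 1e-6
        peaks = [
            (mz_from_neutral(BACKBONE + i.offset, 1) * (1 + tol), 100.0)
            for i in ions
        ]
        pair = pair_from_peaks(peaks, [], BACKBONE + glycan.mass)
        gsm = GS.score_glycan(pair, glycan, BACKBONE, self.params)
        assert gsm.score == pytest.approx(0.0, abs=1e-6)

    def test_quartic_weight_in_unit_interval_and_continuous(self):
        merr_frac = np.linspace(0, 1, 101)
        w = 1 - merr_frac**4
        assert np.all((w >= 0) & (w <= 1))
        assert w[0] == 1.0 and w[-1] == pytest.approx(0.0)

    def test_adding_matched_ion_never_decreases_sum_term(self, trimannosyl_core):
        base_peaks = [core_peak("Y0"), core_peak("Y1"), core_peak("Y2")]
        extra = core_peak("Y3")
        p1 = pair_from_peaks(base_peaks, [], BACKBONE + trimannosyl_core.mass)
        p2 = pair_from_peaks(base_peaks + [extra], [], BACKBONE + trimannosyl_core.mass)
        g1 = GS.score_glycan(p1, trimannosyl_core, BACKBONE, self.params)
        g2 = GS.score_glycan(p2, trimannosyl_core, BACKBONE, self.params)
        assert g2.score >= g1.score

    def test_invariant_to_hcd_cid_split_of_evidence(self, trimannosyl_core):
        peaks = [core_peak("Y0"), core_peak("Y1"), core_peak("Y2"), core_peak("Y3")]
        together = pair_from_peaks(peaks, [], BACKBONE + trimannosyl_core.mass)
        split = pair_from_peaks(peaks[:2], peaks[2:], BACKBONE + trimannosyl_core.mass)
        s1 = GS.score_glycan(together, trimannosyl_core, BACKBONE, self.params).score
        s2 = GS.score_glycan(split, trimannosyl_core, BACKBONE, self.params).score
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestSearchPair:
    def test_empty_candidates_no_gsm(self, small_db):
        pair = pair_from_peaks([(500.0, 1.0)], [], 2500.0)
        top, ranked = GS.search_pair(pair, small_db)
        assert top is None and ranked == []

    def test_competition_lowers_score_without_truth(self, small_db):
        glycan = small_db[0]
        ions = GS.glycan_ion_offsets(glycan)
        peaks = [(mz_from_neutral(BACKBONE + i.offset, 1), 100.0) for i in ions]
        pair = pair_from_peaks(peaks, [], BACKBONE + glycan.mass)
        top_with, _ = GS.search_pair(pair, small_db)
        top_without, _ = GS.search_pair(pair, small_db[1:])
        assert top_with is not None
        if top_without is not None:
            assert top_without.score < top_with.score

    def test_planted_glycan_top_ranked_on_noiseless_pairs(self, tmp_path):
        """On noiseless spectra the planted glycan's Y-mass set wins >=99%."""
        cfg = SimConfig(
            rng_seed=17,
            n_glycopeptides=200,
            glycan_db_size=50,
            ppm_noise_sd=0.0,
            noise_peaks=0,
            hcd_pick={"Y0": 1.0, "Y1": 1.0, "0,2X0": 1.0, "outer": 1.0, "oxonium": 0.0},
            cid_pick={"inner": 1.0, "outer": 1.0, "0,2X0": 1.0},
        )
        truth = simulate_run(cfg, tmp_path)
        from glycopipe.glycans import load_glycan_db
        from glycopipe.spectra import pair_spectra, read_mgf

        db = load_glycan_db(truth.glycan_db_path)
        by_canonical = {t.canonical(): t for t in db}
        pairs, _ = pair_spectra(read_mgf(truth.run1_mgf))
        table = truth.table.set_index("hcd_title")
        wins = 0
        for pair in pairs:
            top, _ = GS.search_pair(pair, db)
            assert top is not None
            planted = by_canonical[table.loc[pair.pair_id, "glycan"]]
            planted_set = np.sort(enumerate_y_ions(planted).distinct_masses)
            top_set = np.sort(enumerate_y_ions(top.glycan).distinct_masses)
            if len(planted_set) == len(top_set) and np.allclose(
                planted_set, top_set, atol=1e-6
            ):
                wins += 1
        assert wins / len(pairs) >= 0.99
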