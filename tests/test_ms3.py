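"""Digestion, sequon substitution, MS3 b/y matching, PSM FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopipe import ms3 as M3
from glycopipe.masses import MOD_MASSES, PROTON, peptide_neutral_mass
from glycopipe.spectra import Peak, Spectrum

HEXNAC = MOD_MASSES["HexNAc_J"]


class TestSequon:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("LVPVPITNATLDR", "LVPVPITJATLDR"),
            ("NPT", "NPT"),  # X = P blocks the motif
            ("NNTT", "JJTT"),  # overlapping sequons both substituted
            ("NAC", "JAC"),  # N-X-C counts as a sequon
            ("NAT", "JAT"),
            ("NA", "NA"),  # too short
        ],
    )
    def test_substitution(self, seq, expected):
        assert M3.sequon_substitute(seq) == expected


class TestDigest:
    def test_full_tryptic_simple(self):
        peps = {
            p.sequence
            for p in M3.digest(
                "AKRLSTR",
                M3.DigestParams(specificity="full", max_missed=0, min_length=1),
            )
        }
        assert peps == {"AK", "R", "LSTR"}

    def test_no_cleavage_before_proline(self):
        peps = {
            p.sequence
            for p in M3.digest(
                "AKPR", M3.DigestParams(specificity="full", max_missed=0, min_length=1)
            )
        }
        assert peps == {"AKPR"}

    def test_missed_cleavages(self):
        peps = {
            p.sequence
            for p in M3.digest(
                "AKRLSTR",
                M3.DigestParams(specificity="full", max_missed=2, min_length=1),
            )
        }
        assert {"AKR", "AKRLSTR", "RLSTR"} <= peps

    def test_semi_includes_ragged_termini(self):
        peps = {
            p.sequence
            for p in M3.digest(
                "LSTR", M3.DigestParams(specificity="semi", max_missed=0, min_length=2)
            )
        }
        assert {"LSTR", "STR", "TR", "LST", "LS"} <= peps

    def test_every_peptide_is_substring_of_source(self):
        protein = "AKMNSTRLDPEKRGGWLVK"
        for pep in M3.digest(protein, M3.DigestParams(min_length=3)):
            assert pep.sequence in protein

    def test_duplicate_proteins_do_not_change_index(self):
        proteins1 = {"P1": "LVPVPITNATLDKR"}
        proteins2 = {"P1": "LVPVPITNATLDKR", "P2": "LVPVPITNATLDKR"}
        i1 = M3.PeptideIndex.build(proteins1, with_decoys=False)
        i2 = M3.PeptideIndex.build(proteins2, with_decoys=False)
        assert {(e[0], e[1].sequence, e[2]) for e in i1.entries} == {
            (e[0], e[1].sequence, e[2]) for e in i2.entries
        }


class TestTheoreticalIons:
    def test_by_count_unmodified(self):
        ions = M3.theoretical_ms3_ions("PEPTIDE", [])
        labels = {l for _, l in ions}
        assert labels == {f"b{i}" for i in range(1, 7)} | {
            f"y{i}" for i in range(1, 7)
        }

    def test_hexnac_fragments_get_neutral_loss(self):
        seq = "AJR"
        ions = dict(
            (l, m) for m, l in M3.theoretical_ms3_ions(seq, [(1, HEXNAC)])
        )
        # b2 contains the modified J, so b2-HexNAc exists; b1 does not
        assert "b2-HexNAc" in ions and "b1-HexNAc" not in ions
        assert ions["b2"] - ions["b2-HexNAc"] == pytest.approx(HEXNAC, abs=1e-6)
        assert "y2-HexNAc" in ions and "y1-HexNAc" not in ions

    def test_b_y_complementarity(self):
        seq = "LVPK"
        total = peptide_neutral_mass(seq)
        ions = dict((l, m) for m, l in M3.theoretical_ms3_ions(seq, []))
        for i in range(1, 4):
            assert ions[f"b{i}"] + ions[f"y{4 - i}"] == pytest.approx(
                total + 2 * PROTON, abs=1e-6
            )


def spectrum_of(sequence, mods, title="ms3", charge=1, jitter=0.0, rng=None):
    ions = M3.theoretical_ms3_ions(sequence, mods)
    peaks = []
    for mz, _ in ions:
        if rng is not None and jitter:
            mz = mz + rng.normal(0, jitter)
        peaks.append(Peak(mz, 100.0))
    neutral = peptide_neutral_mass(sequence, mods)
    return Spectrum(
        title=title,
        precursor_mz=(neutral + charge * PROTON) / charge,
        precursor_charge=charge,
        retention_time=60.0,
        peaks=peaks,
        kind="MS3",
    )


SIX_PROTEINS = {
    "P1": "MLVPVPITNATLDKR",
    "P2": "GAVLDNSTWFEKLLR",
    "P3": "TTYHENATGGFLDEKAAR",
    "P4": "QWESNFTLPLDHKR",
    "P5": "IILDVANQTAFEKGGR",
    "P6": "DDFYLNGSVVLTKHHR",
}


class TestSearch:
    @pytest.fixture(scope="class")
    def index(self):
        return M3.PeptideIndex.build(SIX_PROTEINS)

    def test_generating_peptide_ranks_first(self, index):
        seq = M3.sequon_substitute("LVPVPITNATLDK")
        j = seq.index("J")
        s = spectrum_of(seq, [(j, HEXNAC)])
        psms = M3.search_ms3(s, index)
        assert psms and psms[0].peptide.sequence == seq
        assert psms[0].has_hexnac_on_j
        # nearly every b/y ion of the 13-mer should be matched
        assert psms[0].n_matched_ions >= 20

    def test_removing_source_protein_lowers_top_score(self, index):
        seq = M3.sequon_substitute("LVPVPITNATLDK")
        j = seq.index("J")
        s = spectrum_of(seq, [(j, HEXNAC)])
        best_with = M3.search_ms3(s, index)[0].psm_score
        without = M3.PeptideIndex.build(
            {k: v for k, v in SIX_PROTEINS.items() if k != "P1"}
        )
        rest = M3.search_ms3(s, without)
        assert not rest or rest[0].psm_score < best_with

    def test_empty_spectrum_scores_nothing(self, index):
        s = Spectrum(
            title="e", precursor_mz=700.0, precursor_charge=1,
            retention_time=0.0, peaks=[], kind="MS3",
        )
        assert M3.search_ms3(s, index) == []

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_random_peptide_spectra_recover_their_peptide(self, seed):
        rng = np.random.default_rng(seed)
        proteins = {}
        for i in range(4):
            core = "".join(
                "ADEFGHILQSTVWY"[j] for j in rng.integers(0, 14, 10)
            )
            proteins[f"R{i}"] = core + "NAT" + core[::-1] + "K"
        index = M3.PeptideIndex.build(proteins)
        target = M3.sequon_substitute(proteins["R0"])
        j = target.index("J")
        s = spectrum_of(target, [(j, HEXNAC)], jitter=0.05, rng=rng)
        psms = M3.search_ms3(s, index)
        assert psms and psms[0].peptide.sequence == target


class TestPsmFdr:
    def _mk(self, i, score, decoy, with_j=True):
        pep = M3.Peptide("AJK" if with_j else "ALK", "P", 0, 0, is_decoy=decoy)
        mods = ((1, HEXNAC),) if with_j else ()
        return M3.PSM(
            spectrum_id=f"s{i}", peptide=pep, mods=mods,
            peptide_neutral=500.0, charge=1, n_matched_ions=3,
            psm_score=score, is_decoy=decoy,
        )

    def test_separated_scores_accept_all_targets(self):
        psms = [self._mk(i, 10.0, False) for i in range(50)]
        psms += [self._mk(100 + i, 1.0, True) for i in range(50)]
        assert len(M3.psm_fdr(psms, q_cut=0.01)) == 50

    def test_null_accepts_almost_nothing(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(0, 10, 400)
        psms = [
            self._mk(i, float(s), bool(i % 2)) for i, s in enumerate(scores)
        ]
        assert len(M3.psm_fdr(psms, q_cut=0.01)) <= 4

    def test_hexnac_filter_applies_regardless_of_score(self):
        psms = [self._mk(0, 100.0, False, with_j=False)]
        psms += [self._mk(1, 10.0, False) for _ in range(10)]
        accepted = M3.psm_fdr(psms, q_cut=0.5)
        assert all(p.has_hexnac_on_j for p in accepted)

    def test_acceptance_monotone_in_q_cut(self):
        rng = np.random.default_rng(9)
        psms = [
            self._mk(i, float(s), bool(rng.random() < 0.3))
            for i, s in enumerate(rng.uniform(0, 10, 200))
        ]
        counts = [len(M3.psm_fdr(psms, q_cut=q)) for q in (0.001, 0.01, 0.05, 0.2)]
        assert counts == sorted(counts)

    def test_backbone_subtracts_hexnac(self):
        p = self._mk(0, 5.0, False)
        assert p.backbone_neutral == pytest.approx(500.0 - HEXNAC, abs=1e-9)
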