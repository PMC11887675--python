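"""Candidate index construction, precursor matching and backbone scoring."""

import itertools

import pytest

from glycopull.digest import (
    Peptide,
    ProteinRecord,
    chymotryptic_digest,
    glycopeptide_mass,
    mz_from_mass,
)
from glycopull.glycan import Attachment, parse_composition
from glycopull.match import (
    GlycopeptideMatch,
    SearchSettings,
    assign_confidence,
    backbone_ion_mz,
    build_index,
    match_precursor,
    read_matches_tsv,
    score_backbone,
    search_spectra,
    write_matches_tsv,
)
from glycopull.spectra import Ms2Spectrum, ToleranceSettings

N_GLYCAN = parse_composition("H5N4F1S1", Attachment.N_LINKED)
O_GLYCAN = parse_composition("H1N1S1", Attachment.O_LINKED)


def toy_settings(**kwargs):
    defaults = dict(glycan_panel=(N_GLYCAN, O_GLYCAN), min_len=2, max_len=60)
    defaults.update(kwargs)
    return SearchSettings(**defaults)


class TestBuildIndex:
    def test_attachment_constraints_enforced(self):
        settings = toy_settings(glycan_panel=(N_GLYCAN,))
        index = build_index([ProteinRecord("P1", "NAYSAF")], settings)
        # chymotryptic peptides: NAY, SAF (plus missed-cleavage NAYSAF);
        # only those containing N may carry the N-glycan
        assert len(index) > 0
        assert all("N" in c.peptide.sequence for c in index.candidates)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            build_index([], toy_settings())

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            SearchSettings(glycan_panel=())

    def test_sorted_by_mass(self):
        index = build_index(
            [ProteinRecord("P1", "NAYSTFMGWNKL")], toy_settings()
        )
        masses = [c.neutral_mass for c in index.candidates]
        assert masses == sorted(masses)

    def test_count_matches_brute_force_triple_loop(self):
        proteins = [
            ProteinRecord("P1", "NAYSTF"),
            ProteinRecord("P2", "MMGWNKL"),
            ProteinRecord("P3", "ACDNESTY"),
        ]
        settings = toy_settings()
        index = build_index(proteins, settings)
        expected = 0
        for protein in proteins:
            for pep in chymotryptic_digest(protein, 2, 2, 60):
                for n_ox in range(pep.sequence.count("M") + 1):
                    for glycan in settings.glycan_panel:
                        needs = {"N"} if glycan.attachment == Attachment.N_LINKED else {"S", "T"}
                        if set(pep.sequence) & needs:
                            expected += 1
        assert len(index) == expected

    def test_candidates_unique(self):
        index = build_index([ProteinRecord("P1", "NAYSTFMGWNKL")], toy_settings())
        keys = [
            (c.peptide.parent, c.peptide.start, c.peptide.end,
             c.peptide.n_oxidized_met, str(c.glycan), c.glycan.attachment)
            for c in index.candidates
        ]
        assert len(keys) == len(set(keys))


class TestMatchPrecursor:
    def test_exact_spectrum_matches_at_zero_ppm(self):
        settings = toy_settings()
        index = build_index([ProteinRecord("P1", "NAYSTF")], settings)
        c = index.candidates[0]
        s = Ms2Spectrum("s0", mz_from_mass(c.neutral_mass, 2), 2)
        matches = match_precursor(s, index, settings)
        assert matches
        assert matches[0].mass_error_ppm == pytest.approx(0.0, abs=1e-9)
        assert matches[0].peptide == c.peptide

    def test_offset_beyond_tolerance_yields_nothing(self):
        settings = toy_settings()
        index = build_index([ProteinRecord("P1", "NAYSTF")], settings)
        c = index.candidates[0]
        s = Ms2Spectrum("s0", mz_from_mass(c.neutral_mass * (1 + 20e-6), 2), 2)
        assert match_precursor(s, index, settings) == []

    def test_equals_linear_scan_oracle(self):
        import numpy as np

        rng = np.random.default_rng(11)
        from glycopull.synthetic import generate_proteome

        proteome = generate_proteome(12, (60, 120), seed=11)
        settings = toy_settings()
        index = build_index(proteome, settings)
        assert len(index) >= 500
        tol = settings.tolerances.precursor_ppm
        for _ in range(50):
            c = index.candidates[int(rng.integers(len(index)))]
            offset = float(rng.uniform(-15, 15))
            observed = c.neutral_mass * (1 + offset * 1e-6)
            s = Ms2Spectrum("s", mz_from_mass(observed, 2), 2)
            got = {
                (m.peptide.parent, m.peptide.start, m.peptide.end,
                 m.peptide.n_oxidized_met, str(m.glycan))
                for m in match_precursor(s, index, settings)
            }
            oracle = {
                (c2.peptide.parent, c2.peptide.start, c2.peptide.end,
                 c2.peptide.n_oxidized_met, str(c2.glycan))
                for c2 in index.candidates
                if abs(1e6 * (observed - c2.neutral_mass) / c2.neutral_mass) <= tol
            }
            assert got == oracle

    def test_monotone_in_tolerance(self):
        from glycopull.synthetic import generate_proteome

        proteome = generate_proteome(5, (60, 120), seed=3)
        narrow = toy_settings(tolerances=ToleranceSettings(5.0, 0.02))
        wide = toy_settings(tolerances=ToleranceSettings(20.0, 0.02))
        index_n = build_index(proteome, narrow)
        index_w = build_index(proteome, wide)
        c = index_n.candidates[7]
        s = Ms2Spectrum("s", mz_from_mass(c.neutral_mass * (1 + 4e-6), 2), 2)
        got_n = {m.theoretical_mass for m in match_precursor(s, index_n, narrow)}
        got_w = {m.theoretical_mass for m in match_precursor(s, index_w, wide)}
        assert got_n <= got_w


class TestBackboneScore:
    TOL = ToleranceSettings()

    def test_full_by_series_of_peptide(self):
        ions = backbone_ion_mz("PEPTIDE")
        assert len(ions) == 12  # 6 b + 6 y
        s = Ms2Spectrum("s", 500.0, 2, tuple((ion, 0.3) for ion in ions))
        assert score_backbone(s, "PEPTIDE", self.TOL) == 12

    def test_empty_spectrum_scores_zero(self):
        assert score_backbone(Ms2Spectrum("s", 500.0, 2), "PEPTIDE", self.TOL) == 0

    def test_intensity_free(self):
        ions = backbone_ion_mz("PEPTIDE")
        a = Ms2Spectrum("s", 500.0, 2, tuple((ion, 0.3) for ion in ions))
        b = Ms2Spectrum("s", 500.0, 2, tuple((ion, 30.0) for ion in ions))
        assert score_backbone(a, "PEPTIDE", self.TOL) == score_backbone(
            b, "PEPTIDE", self.TOL
        )

    def test_by_ion_masses_against_manual_sums(self):
        # b2 of "AGC" = A + G + proton; y1 = C(+carbamidomethyl) + water + proton
        ions = set(round(i, 4) for i in backbone_ion_mz("AGC"))
        b2 = 71.03711 + 57.02146 + 1.007276
        y1 = 103.00919 + 57.02146 + 18.010565 + 1.007276
        assert any(abs(i - b2) < 1e-3 for i in ions)
        assert any(abs(i - y1) < 1e-3 for i in ions)


class TestConfidence:
    def _match(self, count, ppm=0.0):
        pep = Peptide("P", 0, 7, "PEPTIDE")
        return GlycopeptideMatch("s", pep, O_GLYCAN, 1000.0, ppm, backbone_ion_count=count)

    def test_threshold_inclusive(self):
        settings = toy_settings(high_confidence_ions=6)
        assert assign_confidence(self._match(10), settings) == "high"
        assert assign_confidence(self._match(6), settings) == "high"
        assert assign_confidence(self._match(5), settings) == "low"
        assert assign_confidence(self._match(0), settings) == "low"


class TestSearchAndTsv:
    def test_round_trip_match_table(self, tmp_path):
        from glycopull.synthetic import generate_proteome, plant_and_synthesize

        proteome = generate_proteome(10, (60, 120), seed=5)
        spectra_by_run, _ = plant_and_synthesize(
            proteome, n_true=5, n_decoy=0, seed=5, n_contaminants=2
        )
        settings = SearchSettings()
        index = build_index(proteome, settings)
        spectra = [s for run in sorted(spectra_by_run) for s in spectra_by_run[run]]
        matches = search_spectra(spectra, index, settings)
        assert matches
        path = tmp_path / "matches.tsv"
        write_matches_tsv(matches, path)
        back = read_matches_tsv(path)
        assert [(m.spectrum_id, m.peptide.sequence, str(m.glycan)) for m in back] == [
            (m.spectrum_id, m.peptide.sequence, str(m.glycan)) for m in matches
        ]
        assert all(a.confidence == b.confidence for a, b in zip(matches, back))
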