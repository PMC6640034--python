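"""Allele harmonization: swaps, strand flips, palindromes, proxies."""

import dataclasses

import numpy as np
import pytest

from cytomr.estimators import ivw
from cytomr.exceptions import InputError
from cytomr.harmonize import audit_report, format_audit, harmonize, read_harmonized, write_harmonized
from cytomr.summary_io import COMPLEMENT, LDTable, SummaryStatSet, load_table1_fixture
from cytomr.synthetic_data import CorruptionConfig, SimulationConfig, simulate
from cytomr.instruments import instrument_sets_from_table1
from tests.conftest import instrument_set_from_records, make_record, make_set


def _harm1(exp_rec, out_rec, **kw):
    inst = instrument_set_from_records([exp_rec])
    outcome = make_set([out_rec] if out_rec else [], trait_type="binary")
    return harmonize(inst, outcome, **kw)


class TestAlignment:
    def test_same_alleles_same_orientation_kept(self):
        h = _harm1(make_record("rs1", "A", "G", beta=0.2), make_record("rs1", "A", "G", beta=0.1))
        (i,) = h.instruments
        assert i.beta_outcome == 0.1 and i.terminal_decision == "kept"

    def test_allele_swap_flips_outcome_sign_and_frequency(self):
        h = _harm1(
            make_record("rs1", "A", "G", beta=0.2, eaf=0.3),
            make_record("rs1", "G", "A", beta=0.1, eaf=0.68),
        )
        (i,) = h.instruments
        assert i.beta_outcome == -0.1
        assert i.eaf_outcome == pytest.approx(0.32)
        assert i.terminal_decision == "flipped"

    def test_strand_flip_resolved_by_complementing(self):
        # Exposure A/G; outcome reported on the other strand as T/C.
        h = _harm1(
            make_record("rs1", "A", "G", beta=0.2),
            make_record("rs1", "T", "C", beta=0.1),
        )
        (i,) = h.instruments
        assert i.beta_outcome == 0.1 and i.terminal_decision == "strand_swapped"

    def test_strand_flip_plus_swap(self):
        h = _harm1(
            make_record("rs1", "A", "G", beta=0.2, eaf=0.3),
            make_record("rs1", "C", "T", beta=0.1, eaf=0.7),
        )
        (i,) = h.instruments
        assert i.beta_outcome == -0.1 and i.terminal_decision == "strand_swapped"

    def test_allele_mismatch_dropped(self):
        h = _harm1(make_record("rs1", "A", "G"), make_record("rs1", "A", "C"))
        assert not h.instruments and "mismatch" in h.dropped[0][1]

    def test_unknown_outcome_other_allele_dropped_with_reason(self):
        h = _harm1(make_record("rs1", "A", "G"), make_record("rs1", "A", None))
        assert not h.instruments and "strand unresolvable" in h.dropped[0][1]

    def test_missing_exposure_allele_is_input_error(self):
        with pytest.raises(InputError, match="rs1"):
            _harm1(make_record("rs1", "A", None), make_record("rs1", "A", "G"))


class TestPalindromes:
    def test_ambiguous_frequency_dropped(self):
        h = _harm1(
            make_record("rs1", "A", "T", eaf=0.49),
            make_record("rs1", "A", "T", eaf=0.51),
            palindrome_eaf_window=0.08,
        )
        assert not h.instruments
        assert "palindromic" in h.dropped[0][1]

    def test_concordant_frequencies_kept_as_reported(self):
        h = _harm1(
            make_record("rs1", "C", "G", eaf=0.2, beta=0.2),
            make_record("rs1", "C", "G", eaf=0.25, beta=0.1),
        )
        (i,) = h.instruments
        assert i.beta_outcome == 0.1 and i.terminal_decision == "palindromic_aligned"

    def test_discordant_frequencies_flip_strand_interpretation(self):
        h = _harm1(
            make_record("rs1", "C", "G", eaf=0.2, beta=0.2),
            make_record("rs1", "C", "G", eaf=0.8, beta=0.1),
        )
        (i,) = h.instruments
        assert i.beta_outcome == -0.1 and i.eaf_outcome == pytest.approx(0.2)

    def test_zero_window_orients_purely_by_frequency(self):
        h = _harm1(
            make_record("rs1", "A", "T", eaf=0.49, beta=0.2),
            make_record("rs1", "A", "T", eaf=0.51, beta=0.1),
            palindrome_eaf_window=0.0,
        )
        (i,) = h.instruments  # retained, oriented by the (noisy) frequencies
        assert i.beta_outcome == -0.1

    @pytest.mark.parametrize("eaf_exp,eaf_out", [(0.45, 0.3), (0.3, 0.45), (0.5, 0.5)])
    def test_window_applies_to_either_dataset(self, eaf_exp, eaf_out):
        h = _harm1(
            make_record("rs1", "A", "T", eaf=eaf_exp),
            make_record("rs1", "A", "T", eaf=eaf_out),
            palindrome_eaf_window=0.08,
        )
        assert not h.instruments


class TestProxies:
    def _setup(self, proxy_r2_value):
        exp_full = make_set(
            [make_record("rs1", "A", "G", beta=0.2), make_record("rs_proxy", "C", "T", beta=0.19)]
        )
        inst = instrument_set_from_records([exp_full.get("rs1")])
        outcome = make_set([make_record("rs_proxy", "C", "T", beta=0.05)], trait_type="binary")
        ld = LDTable()
        ld.add("rs1", "rs_proxy", proxy_r2_value)
        return inst, outcome, ld, exp_full

    def test_high_ld_proxy_substituted_with_provenance(self):
        inst, outcome, ld, exp_full = self._setup(0.9)
        h = harmonize(inst, outcome, ld, exposure_full=exp_full)
        (i,) = h.instruments
        assert i.variant_id == "rs_proxy" and i.proxy_of == "rs1"
        assert i.beta_exposure == 0.19 and i.beta_outcome == 0.05
        assert i.terminal_decision == "proxied"

    def test_no_proxy_above_threshold_dropped_unmatched(self):
        inst, outcome, ld, exp_full = self._setup(0.7)
        h = harmonize(inst, outcome, ld, exposure_full=exp_full)
        assert h.dropped == [("rs1", "dropped_unmatched")]

    def test_proxy_absent_from_exposure_set_drops_original(self):
        inst, outcome, ld, _ = self._setup(0.9)
        exp_without_proxy = make_set([inst.index_snps[0]])
        h = harmonize(inst, outcome, ld, exposure_full=exp_without_proxy)
        assert h.dropped == [("rs1", "dropped_unmatched")]

    def test_threshold_is_strict(self):
        inst, outcome, ld, exp_full = self._setup(0.8)
        h = harmonize(inst, outcome, ld, proxy_r2=0.8, exposure_full=exp_full)
        assert not h.instruments


class TestAudit:
    def test_one_row_per_input_snp(self):
        inst = instrument_set_from_records(
            [make_record("rs1", "A", "G"), make_record("rs2", "A", "G")]
        )
        outcome = make_set([make_record("rs1", "A", "G")], trait_type="binary")
        h = harmonize(inst, outcome)
        df = audit_report(h)
        assert len(df) == 2
        assert set(df.variant_id) == {"rs1", "rs2"}
        assert df.set_index("variant_id").loc["rs2", "kept"] == False  # noqa: E712

    def test_empty_set_gives_header_only(self):
        df = audit_report(harmonize(instrument_set_from_records([]), make_set([])))
        assert df.empty and list(df.columns)[:2] == ["variant_id", "harmonized_as"]
        assert "no variants" in format_audit(df)

    def test_fixture_identity_harmonization_keeps_all_twelve(self):
        # Outcome stub built with the exposure's own allele pairs: every
        # variant aligns trivially and all 12 survive.
        fx = load_table1_fixture()
        outcome = SummaryStatSet("ad_stub", "binary")
        for rec in fx.exposure:
            oa = "G" if rec.effect_allele in "AT" else "T"
            outcome.add(dataclasses.replace(
                rec, other_allele=oa, beta=0.01, se=0.05, pvalue=0.5))
        total = 0
        for biomarker, inst in instrument_sets_from_table1(fx).items():
            for r in inst.index_snps:
                r.other_allele = "G" if r.effect_allele in "AT" else "T"
            h = harmonize(inst, outcome)
            assert not h.dropped
            total += len(h)
        assert total == 12


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(10))
    def test_corruption_then_harmonize_restores_effects_exactly(self, seed):
        cfg = SimulationConfig(
            m=12, theta=0.2, palindromic_fraction=0.0, seed=seed,
            corruption=CorruptionConfig(allele_swap_fraction=0.5, strand_flip_fraction=0.5),
        )
        study = simulate(cfg)
        clean = simulate(dataclasses.replace(cfg, corruption=CorruptionConfig()))
        inst = instrument_set_from_records(list(study.exposure))
        h = harmonize(inst, study.outcome)
        assert len(h) == cfg.m and not h.dropped
        for i in h.instruments:
            orig = clean.outcome.get(i.variant_id)
            assert i.beta_outcome == pytest.approx(orig.beta, abs=0.0)
            assert i.effect_allele == study.truth.allele_coding[i.variant_id][0]

    def test_sign_coherence_flipping_every_outcome_allele(self):
        study = simulate(SimulationConfig(m=8, theta=0.3, palindromic_fraction=0.0, seed=3))
        inst = instrument_set_from_records(list(study.exposure))
        h_plain = harmonize(inst, study.outcome)
        flipped = SummaryStatSet("flipped", "binary")
        for rec in study.outcome:
            flipped.add(dataclasses.replace(
                rec, effect_allele=rec.other_allele, other_allele=rec.effect_allele,
                beta=-rec.beta, eaf=1 - rec.eaf))
        h_flip = harmonize(inst, flipped)
        bx1, _, by1, sy1 = h_plain.arrays()
        bx2, _, by2, sy2 = h_flip.arrays()
        np.testing.assert_array_equal(by1, by2)
        assert ivw(h_plain).beta == ivw(h_flip).beta


def test_harmonized_tsv_round_trip(tmp_path):
    study = simulate(SimulationConfig(m=5, seed=7, palindromic_fraction=0.0))
    inst = instrument_set_from_records(list(study.exposure))
    h = harmonize(inst, study.outcome)
    path = tmp_path / "harmonized.tsv"
    write_harmonized(h, path)
    back = read_harmonized(path)
    assert ivw(back).beta == ivw(h).beta
    assert [i.variant_id for i in back.instruments] == [i.variant_id for i in h.instruments]
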