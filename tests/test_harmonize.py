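"""Allele harmonization: strand logic, palindromes, exclusions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from summr import (ExclusionList, GwasRecord, HarmonizationError,
                   apply_exclusions, build_set, gen_two_sample,
                   harmonize_pair, is_palindromic, ivw)
from summr.harmonize import HarmonizedEntry, Rejection


def rec(rsid="rs1", ea="A", oa="G", beta=0.02, se=0.004, eaf=0.3):
    return GwasRecord(rsid, ea, oa, beta, se, eaf)


@pytest.mark.parametrize("ea,oa,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("a", "t", True),
    ("A", "G", False), ("C", "T", False), ("A", "C", False),
    ("CT", "C", False),  # indel is never palindromic
])
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_aligned_pair_unchanged():
    entry = harmonize_pair(rec(), rec(beta=-0.05, se=0.01))
    assert isinstance(entry, HarmonizedEntry)
    assert entry.gamma == 0.02 and entry.Gamma == -0.05
    assert not entry.palindromic


def test_swapped_alleles_flip_sign_and_eaf():
    entry = harmonize_pair(rec(), rec(ea="G", oa="A", beta=-0.05, eaf=0.7))
    assert entry.Gamma == pytest.approx(0.05)
    assert entry.eaf_outcome == pytest.approx(0.3)


def test_strand_complement_aligns():
    # exposure A/G; outcome reported on the other strand as T/C
    entry = harmonize_pair(rec(), rec(ea="T", oa="C", beta=-0.05))
    assert entry.Gamma == -0.05
    # complement + swap
    entry = harmonize_pair(rec(), rec(ea="C", oa="T", beta=-0.05))
    assert entry.Gamma == pytest.approx(0.05)


def test_incompatible_alleles_rejected():
    result = harmonize_pair(rec(), rec(ea="A", oa="C"))
    assert isinstance(result, Rejection)
    assert result.reason == "allele mismatch"


def test_palindromic_frequency_alignment_flips_discordant_strand():
    # A/T SNP, exposure eaf 0.30 vs outcome 0.70: opposite strands
    entry = harmonize_pair(rec(ea="A", oa="T", eaf=0.30),
                           rec(ea="A", oa="T", beta=-0.05, eaf=0.70),
                           ambiguity_threshold=0.42)
    assert isinstance(entry, HarmonizedEntry)
    assert entry.Gamma == pytest.approx(0.05)
    assert entry.palindromic


def test_palindromic_frequency_alignment_concordant_keeps_sign():
    entry = harmonize_pair(rec(ea="A", oa="T", eaf=0.30),
                           rec(ea="A", oa="T", beta=-0.05, eaf=0.25))
    assert entry.Gamma == -0.05


def test_palindromic_ambiguous_frequency_rejected():
    result = harmonize_pair(rec(ea="A", oa="T", eaf=0.45),
                            rec(ea="A", oa="T", beta=-0.05, eaf=0.30))
    assert isinstance(result, Rejection)
    assert "ambiguous" in result.reason


def test_palindromic_missing_eaf_rejected():
    result = harmonize_pair(rec(ea="A", oa="T", eaf=None),
                            rec(ea="A", oa="T", beta=-0.05, eaf=0.2))
    assert isinstance(result, Rejection)
    assert "missing eaf" in result.reason


def test_palindromic_dropped_in_drop_mode():
    result = harmonize_pair(rec(ea="A", oa="T", eaf=0.1),
                            rec(ea="A", oa="T", beta=-0.05, eaf=0.1),
                            mode="drop-palindromic")
    assert isinstance(result, Rejection)
    assert result.reason == "palindromic"


def test_harmonization_is_involution_safe():
    """Harmonizing an already-aligned pair changes nothing."""
    entry = harmonize_pair(rec(), rec(beta=-0.05, se=0.01))
    realigned = harmonize_pair(
        rec(),
        GwasRecord("rs1", "A", "G", entry.Gamma, 0.01, entry.eaf_outcome))
    assert realigned.Gamma == entry.Gamma
    assert realigned.eaf_outcome == entry.eaf_outcome


def test_build_set_retains_all_without_palindromes():
    exp, out, ivs, _ = gen_two_sample(J=99, seed=11)
    hset = build_set(exp, out, ivs)
    assert hset.n_active == 99


def test_build_set_drop_mode_removes_planted_palindromes():
    # 99 instruments, ~15% palindromic: drop-palindromic keeps 84
    exp, out, ivs, _ = gen_two_sample(J=99, palindromic_fraction=15 / 99,
                                      seed=12)
    dropped = build_set(exp, out, ivs, mode="drop-palindromic")
    assert dropped.n_active == 84
    assert {r.reason for r in dropped.rejections} == {"palindromic"}


def test_drop_palindromic_subset_of_frequency_align():
    exp, out, ivs, _ = gen_two_sample(J=60, palindromic_fraction=0.3, seed=13)
    aligned = build_set(exp, out, ivs, mode="frequency-align")
    dropped = build_set(exp, out, ivs, mode="drop-palindromic")
    assert set(dropped.rsids()) <= set(aligned.rsids())


def test_build_set_all_mismatched_is_hard_error():
    exp, out, ivs, _ = gen_two_sample(J=5, seed=14)
    broken = [GwasRecord(r.rsid, "AA", "ACGT", r.beta, r.se, r.eaf)
              for r in out]
    with pytest.raises(HarmonizationError):
        build_set(exp, broken, ivs)


def test_exposure_allele_convention_is_irrelevant_downstream():
    """Flipping the exposure study's effect allele at every SNP flips every
    gamma but leaves the causal estimate unchanged."""
    exp, out, ivs, _ = gen_two_sample(J=30, theta_true=-0.2, seed=15)
    base = build_set(exp, out, ivs)
    flipped_exp = [GwasRecord(r.rsid, r.other_allele, r.effect_allele,
                              -r.beta, r.se,
                              None if r.eaf is None else 1 - r.eaf)
                   for r in exp]
    flipped = build_set(flipped_exp, out, ivs)
    assert np.allclose(flipped.table["gamma"], -base.table["gamma"])
    assert ivw(flipped).theta == pytest.approx(ivw(base).theta, abs=1e-12)
    assert ivw(flipped).se == pytest.approx(ivw(base).se, abs=1e-12)


def test_apply_exclusions_flags_and_counts():
    exp, out, ivs, _ = gen_two_sample(J=98, seed=16)
    hset = build_set(exp, out, ivs)
    listed = tuple(hset.table["rsid"][:27])
    excl = ExclusionList(listed, {r: "confounder" for r in listed})
    curated = apply_exclusions(hset, excl)
    assert curated.n_active == 71
    assert curated.n_total == 98
    # estimators only ever see active SNPs
    assert len(curated.arrays()[0]) == 71


def test_apply_exclusions_identity_cases():
    exp, out, ivs, _ = gen_two_sample(J=10, seed=17)
    hset = build_set(exp, out, ivs)
    empty = apply_exclusions(hset, ExclusionList((), {}))
    assert empty.n_active == 10
    disjoint = apply_exclusions(
        hset, ExclusionList(("rs_absent",), {"rs_absent": "x"}))
    assert disjoint.n_active == 10


@settings(derandomize=True, max_examples=50, deadline=None)
@given(beta=st.floats(-0.5, 0.5), eaf=st.floats(0.01, 0.99),
       swap=st.booleans())
def test_harmonized_outcome_effect_invariant_to_reporting_convention(
        beta, eaf, swap):
    """The harmonized Gamma is the same however the outcome study labels
    its alleles."""
    outcome = (GwasRecord("rs1", "G", "A", -beta, 0.01, 1 - eaf) if swap
               else GwasRecord("rs1", "A", "G", beta, 0.01, eaf))
    entry = harmonize_pair(rec(), outcome)
    assert entry.Gamma == pytest.approx(beta)
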