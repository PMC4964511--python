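"""RSCU, ENC (against an independent oracle), CAI, GRAVY, aromaticity."""

import math

import numpy as np
import pytest
from Bio.Data import CodonTable
from hypothesis import given, strategies as st

from codonbias import (
    CdsRecord,
    CodonCountTable,
    aromaticity,
    cai,
    cai_weights,
    count_codons,
    enc,
    family_homozygosity,
    gravy,
    pool_counts,
    rscu,
)

# ---------------------------------------------------------------------------
# independent ENC oracle: Wright's equations re-derived from scratch, using
# biopython's code table directly rather than the package's structures
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1].forward_table
_FAMILIES: dict[str, list[str]] = {}
for _c, _a in _TABLE.items():
    _FAMILIES.setdefault(_a, []).append(_c)


def enc_oracle(counts: dict[str, int]) -> float:
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in _FAMILIES.items():
        k = len(codons)
        if k == 1:
            continue
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in ns)
        class_F[k].append((n * sum_p2 - 1) / (n - 1))
    if not class_F[2] or not class_F[4]:
        return math.nan
    f2 = sum(class_F[2]) / len(class_F[2])
    f4 = sum(class_F[4]) / len(class_F[4])
    if f2 == 0 or f4 == 0:
        return math.nan
    fb = 2 / (1 / f2 + 1 / f4)
    f3 = sum(class_F[3]) / len(class_F[3]) if class_F[3] else fb
    f6 = sum(class_F[6]) / len(class_F[6]) if class_F[6] else fb
    if f3 == 0 or f6 == 0:
        return math.nan
    return min(2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6, 61.0)


# ---------------------------------------------------------------------------
# codon counting
# ---------------------------------------------------------------------------


def test_count_codons_separates_sense_and_stop():
    t = count_codons(CdsRecord("g", "ATGAAAAAATAA"))
    assert t["ATG"] == 1 and t["AAA"] == 2 and t["TAA"] == 1
    assert t.n_sense == 3 and t.n_stop == 1


def test_ambiguous_codons_skipped_and_pooling_adds():
    t = count_codons(CdsRecord("g", "ATGANAAAATAA"))
    assert t.n_sense + t.n_stop == 3  # ANA skipped
    t2 = t + t
    assert t2["AAA"] == 2 * t["AAA"] and t2.scope == "pooled"
    assert pool_counts([t, t]).counts == t2.counts


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


def test_rscu_hand_computed_lysine(code):
    t = CodonCountTable({"AAA": 1, "AAG": 3})
    vals = rscu(t, code).values
    assert vals["AAA"] == pytest.approx(0.5)
    assert vals["AAG"] == pytest.approx(1.5)
    assert math.isnan(vals["TTT"])  # unobserved family flagged


def test_rscu_uniform_usage_is_one_everywhere(code):
    t = CodonCountTable({c: 7 for c in code.sense_codons})
    vals = rscu(t, code).values
    for c in code.sense_codons:
        assert vals[c] == pytest.approx(1.0)


def test_rscu_stop_family_only_when_requested(code):
    t = CodonCountTable({"TAA": 1, "TGA": 2, "TAG": 0, "AAA": 2, "AAG": 2})
    assert "TAA" not in rscu(t, code).values
    vals = rscu(t, code, include_stops=True).values
    assert vals["TGA"] == pytest.approx(2.0)


@given(st.integers(0, 2**31 - 1))
def test_rscu_family_sums_equal_family_size(code, seed):
    rng = np.random.default_rng(seed)
    t = CodonCountTable(dict(zip(code.sense_codons, rng.poisson(2.0, 61))))
    table = rscu(t, code)
    for aa, fam in code.families.items():
        total = sum(t[c] for c in fam)
        if total > 0:
            assert table.family_sums[aa] == pytest.approx(len(fam), abs=1e-9)
        else:
            assert math.isnan(table.family_sums[aa])


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------


def test_family_homozygosity_hand_values():
    assert family_homozygosity([2, 2]) == pytest.approx(1 / 3)
    assert family_homozygosity([4, 0]) == pytest.approx(1.0)
    assert math.isnan(family_homozygosity([1]))
    assert math.isnan(family_homozygosity([1, 0]))


def test_enc_is_20_for_one_codon_per_amino_acid(code):
    t = CodonCountTable({fam[0]: 10 for fam in code.families.values()})
    assert enc(t, code) == pytest.approx(20.0)


def test_enc_capped_at_61_for_uniform_usage(code):
    t = CodonCountTable({c: 1000 for c in code.synonymous_codons})
    assert enc(t, code) == 61.0


def test_enc_undefined_without_2_or_4_fold_families(code):
    # Phe (2-fold) and Lys (2-fold) only: the 4-fold class has no estimate
    t = CodonCountTable({"TTT": 2, "TTC": 2, "AAA": 4})
    assert math.isnan(enc(t, code))
    assert math.isnan(enc_oracle({"TTT": 2, "TTC": 2, "AAA": 4}))


def test_enc_uses_harmonic_fallback_for_missing_3_and_6_fold(code):
    # one 2-fold and one 4-fold family observed; Ile and 6-fold absent
    counts = {"TTT": 2, "TTC": 2, "GGT": 3, "GGC": 1}
    got = enc(CodonCountTable(counts), code)
    assert got == pytest.approx(enc_oracle(counts), abs=1e-9)


def test_enc_matches_oracle_on_random_genes(code):
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(200):
        lam = rng.uniform(0.3, 5.0)
        counts = dict(zip(code.sense_codons, rng.poisson(lam, 61)))
        got = enc(CodonCountTable(counts), code)
        want = enc_oracle(counts)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-9)
            assert 20.0 <= got <= 61.0
            checked += 1
    assert checked > 150


def test_enc_nearly_scale_invariant_for_large_counts(code):
    # biased usage, large counts: the small-sample correction has shrunk,
    # so a 10x rescale moves ENC by little
    rng = np.random.default_rng(7)
    counts = dict(zip(code.sense_codons, rng.integers(5, 100, 61)))
    base = enc(CodonCountTable(counts), code)
    scaled = enc(CodonCountTable({c: 10 * n for c, n in counts.items()}), code)
    assert base < 61.0  # not capped, the comparison is informative
    assert abs(base - scaled) < 0.5


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------


def test_cai_weights_hand_values(code):
    ref = CodonCountTable({"AAA": 75, "AAG": 25})
    w = cai_weights(ref, code)
    assert w["AAA"] == 1.0
    assert w["AAG"] == pytest.approx(1 / 3)
    # zero-count codon in an observed family gets the floor
    ref2 = CodonCountTable({"AAA": 50})
    assert cai_weights(ref2, code)["AAG"] == 0.01
    # unobserved families are uninformative: weight 1
    assert cai_weights(ref2, code)["TTT"] == 1.0


def test_cai_weights_uniform_reference(code):
    ref = CodonCountTable({c: 9 for c in code.sense_codons})
    w = cai_weights(ref, code)
    assert all(w[c] == 1.0 for c in code.sense_codons)


def test_cai_hand_value_and_bounds(code):
    ref = CodonCountTable({"AAA": 75, "AAG": 25, "TTT": 10, "TTC": 30})
    w = cai_weights(ref, code)
    gene = CodonCountTable({"AAA": 1, "AAG": 1})
    assert cai(gene, w, code) == pytest.approx(math.sqrt(1 / 3))
    best = CodonCountTable({"AAA": 5, "TTC": 5})
    assert cai(best, w, code) == pytest.approx(1.0)


def test_cai_ignores_met_trp_and_is_scale_invariant(code):
    ref = CodonCountTable({"AAA": 75, "AAG": 25})
    w = cai_weights(ref, code)
    gene = CodonCountTable({"AAA": 1, "AAG": 1, "ATG": 50, "TGG": 50})
    assert cai(gene, w, code) == pytest.approx(math.sqrt(1 / 3))
    doubled = CodonCountTable({"AAA": 2, "AAG": 2})
    assert cai(doubled, w, code) == pytest.approx(math.sqrt(1 / 3))
    only_met = CodonCountTable({"ATG": 3})
    assert math.isnan(cai(only_met, w, code))


def test_cai_monotone_under_preferred_substitution(code):
    rng = np.random.default_rng(11)
    ref = CodonCountTable(dict(zip(code.sense_codons, rng.poisson(20.0, 61) + 1)))
    w = cai_weights(ref, code)
    gene_counts = dict(zip(code.sense_codons, rng.poisson(2.0, 61)))
    base = cai(CodonCountTable(gene_counts), w, code)
    for aa, fam in code.families.items():
        if len(fam) == 1:
            continue
        worst = min(fam, key=lambda c: w[c])
        best = max(fam, key=lambda c: w[c])
        if gene_counts.get(worst, 0) == 0 or worst == best:
            continue
        swapped = dict(gene_counts)
        swapped[worst] -= 1
        swapped[best] = swapped.get(best, 0) + 1
        assert cai(CodonCountTable(swapped), w, code) >= base - 1e-12


def test_cai_empty_reference_raises(code):
    with pytest.raises(ValueError):
        cai_weights(CodonCountTable({}), code)


# ---------------------------------------------------------------------------
# GRAVY / aromaticity
# ---------------------------------------------------------------------------


def test_gravy_hand_lookups(make_record):
    assert gravy(make_record(["ATT"] * 5)) == pytest.approx(4.5)  # poly-Ile
    assert gravy(make_record(["CGT"] * 4)) == pytest.approx(-4.5)  # poly-Arg


def test_gravy_order_invariance(make_record):
    a = gravy(make_record(["ATT", "CGT", "GGG", "TTT"]))
    b = gravy(make_record(["TTT", "GGG", "CGT", "ATT"]))
    assert a == pytest.approx(b)


def test_aromaticity_counts_phe_tyr_trp(make_record):
    codons = ["TTT", "TTT", "TGG"] + ["GCC"] * 7  # 2 Phe + 1 Trp in 10 residues
    assert aromaticity(make_record(codons)) == pytest.approx(0.3)
    assert aromaticity(make_record(["GCC"] * 4)) == 0.0
    assert aromaticity(make_record(["TAC"] * 6)) == 1.0
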