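"""In-silico PCR vs an exhaustive sliding-window oracle, plus panel logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgptyper.errors import InputError
from rgptyper.fixtures import FixtureSpec, generate_locus
from rgptyper.insilico_pcr import (
    IUPAC_MASK,
    find_binding_sites,
    predict_amplicons,
    reverse_complement,
    run_panel,
)
from rgptyper.scheme_db import Primer, PrimerPair

# ---------------------------------------------------------------- oracle


def oracle_sites(seq, primer, max_mismatch, exact_3prime):
    """Brute-force scan of every window on both strands."""
    k = len(primer)
    smask = [IUPAC_MASK[c] for c in seq]
    out = []
    for strand, pat in (("+", primer), ("-", reverse_complement(primer))):
        three = min(exact_3prime, k)
        # primer 3' end is window-right on "+", window-left on "-"
        protected = set(range(k - three, k)) if strand == "+" else set(range(three))
        pmask = [IUPAC_MASK[c] for c in pat]
        for i in range(len(seq) - k + 1):
            mm = 0
            ok = True
            for j in range(k):
                if not (smask[i + j] & pmask[j]):
                    if j in protected:
                        ok = False
                        break
                    mm += 1
                    if mm > max_mismatch:
                        ok = False
                        break
            if ok:
                out.append((i, i + k, strand, mm))
    return sorted(out)


def oracle_amplicons(seq, pair, max_mismatch, min_len, max_len, exact_3prime=3):
    fsites = oracle_sites(seq, pair.forward.sequence, max_mismatch, exact_3prime)
    rsites = oracle_sites(seq, pair.reverse.sequence, max_mismatch, exact_3prime)
    floor = max(min_len, len(pair.forward) + len(pair.reverse))
    spans = []
    for ups, downs in ((fsites, rsites), (rsites, fsites)):
        for us, ue, ustr, _ in ups:
            if ustr != "+":
                continue
            for ds, de, dstr, _ in downs:
                if dstr != "-":
                    continue
                length = de - us
                if floor <= length <= max_len:
                    spans.append((us, de, length))
    return sorted(spans)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mk_pair(fwd, rev, amplicon, name="P"):
    return PrimerPair(
        name=name,
        forward=Primer(f"{name}F", fwd, "forward"),
        reverse=Primer(f"{name}R", rev, "reverse"),
        expected_amplicon=amplicon,
        target_groups=frozenset({"1"}),
        panel="multiplex1",
    )


# ------------------------------------------------------- binding sites


def test_primer_binds_itself():
    p = "CAGGTGCAAATGGCCAACTCG"
    sites = find_binding_sites(p, p, max_mismatch=0)
    assert [(s.start, s.strand, s.mismatches) for s in sites] == [(0, "+", 0)]


def test_primer_binds_its_reverse_complement():
    p = "CAGGTGCAAATGGCCAACTCG"
    sites = find_binding_sites(reverse_complement(p), p, max_mismatch=0)
    assert [(s.start, s.strand) for s in sites] == [(0, "-")]


def test_primer_longer_than_sequence_gives_empty():
    assert find_binding_sites("ACGT", "CAGGTGCAAATGGCCAACTCG") == []


def test_non_iupac_sequence_rejected():
    with pytest.raises(InputError):
        find_binding_sites("ACGT?ACGTACGTACGTACGTACG", "ACGTACGTACGTACGT")


def test_iupac_degeneracy_matches_by_intersection():
    primer = "ACGTNCGTACGTACGT"  # N matches anything
    seq = "ACGTACGTACGTACGT"
    sites = find_binding_sites(seq, primer, max_mismatch=0, exact_3prime=0)
    assert any(s.strand == "+" and s.mismatches == 0 for s in sites)
    # R (A/G) in the template intersects A in the primer
    sites = find_binding_sites("RCGTACGTACGTACGT", "ACGTACGTACGTACGT",
                               max_mismatch=0, exact_3prime=0)
    assert any(s.strand == "+" for s in sites)


def test_three_prime_mismatch_blocks_binding():
    primer = "ACGTACGTACGTACGTACGT"
    seq = primer[:-1] + "C"  # mismatch at the 3'-terminal base
    plus = [s for s in find_binding_sites(seq, primer, max_mismatch=2,
                                          exact_3prime=3) if s.strand == "+"]
    assert plus == []
    plus = [s for s in find_binding_sites(seq, primer, max_mismatch=2,
                                          exact_3prime=0) if s.strand == "+"]
    assert len(plus) == 1 and plus[0].mismatches == 1


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("max_mm", [0, 1, 2])
def test_sites_equal_bruteforce_oracle(seed, max_mm):
    rng = np.random.default_rng(1000 + seed)
    seq = random_dna(rng, 3000)
    primer = "CAGGTGCAAATGGCCAACTCG"
    # plant some near-exact copies to make hits likely
    for pos, nmut in ((200, 0), (900, 1), (1700, 2)):
        copy = list(primer)
        for j in range(nmut):
            copy[5 + j] = "T" if copy[5 + j] != "T" else "A"
        seq = seq[:pos] + "".join(copy) + seq[pos + len(primer):]
    got = [
        (s.start, s.end, s.strand, s.mismatches)
        for s in find_binding_sites(seq, primer, max_mm, 3)
    ]
    assert sorted(got) == oracle_sites(seq, primer, max_mm, 3)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_mismatch_monotonicity(seed):
    """Raising max_mismatch never removes a reported site."""
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 400)
    primer = "GCTGGTCGTAATTACCTCG"
    prev = set()
    for mm in range(3):
        cur = {
            (s.start, s.strand)
            for s in find_binding_sites(seq, primer, mm, 3)
        }
        assert prev <= cur
        prev = cur


# ---------------------------------------------------------- amplicons


def test_planted_amplicon_has_expected_length():
    pair = mk_pair("CAGGTGCAAATGGCCAACTCG", "CTTGCCATGTTGGGATGAC", 801)
    rng = np.random.default_rng(5)
    inner = 801 - len(pair.forward) - len(pair.reverse)
    seq = (
        random_dna(rng, 100)
        + pair.forward.sequence
        + random_dna(rng, inner)
        + reverse_complement(pair.reverse.sequence)
        + random_dna(rng, 100)
    )
    hits = predict_amplicons(seq, pair)
    assert len(hits) == 1
    assert hits[0].length == 801
    assert hits[0].start == 100 and hits[0].end == 901


def test_forward_site_alone_yields_no_product():
    pair = mk_pair("CAGGTGCAAATGGCCAACTCG", "CTTGCCATGTTGGGATGAC", 801)
    rng = np.random.default_rng(6)
    seq = random_dna(rng, 200) + pair.forward.sequence + random_dna(rng, 200)
    assert predict_amplicons(seq, pair) == []


def test_multiple_sites_enumerate_all_convergent_pairings():
    pair = mk_pair("CAGGTGCAAATGGCCAACTCG", "CTTGCCATGTTGGGATGAC", 801)
    rng = np.random.default_rng(7)
    f = pair.forward.sequence
    r = reverse_complement(pair.reverse.sequence)
    seq = (
        random_dna(rng, 50) + f + random_dna(rng, 100) + f
        + random_dna(rng, 150) + r + random_dna(rng, 120) + r
        + random_dna(rng, 50)
    )
    got = sorted((h.start, h.end, h.length) for h in predict_amplicons(
        seq, pair, min_len=40, max_len=2000))
    assert got == oracle_amplicons(seq, pair, 0, 40, 2000)
    assert len(got) == 4  # 2 forward x 2 reverse, all in range


def test_strand_symmetry_of_amplicon_lengths(fixture_map, scheme):
    seq = fixture_map["3"].sequence
    lengths = lambda s: sorted(
        h.length
        for pair in scheme.panel_pairs("multiplex1")
        for h in predict_amplicons(s, pair, max_len=6000)
    )
    assert lengths(seq) == lengths(reverse_complement(seq))


def test_min_len_above_max_len_rejected():
    pair = mk_pair("CAGGTGCAAATGGCCAACTCG", "CTTGCCATGTTGGGATGAC", 801)
    with pytest.raises(InputError):
        predict_amplicons("ACGT" * 300, pair, min_len=500, max_len=100)


# ------------------------------------------------------------- panels


def test_multiplex1_panel_on_genotype3_fixture(fixture_map, scheme):
    res = run_panel(fixture_map["3"].sequence, scheme, "multiplex1")
    assert res.control_ok
    assert res.amplified == {"Var3"}
    [hit] = [
        h for h in res.per_pair["Var3"]
        if abs(h.length - 271) <= 0.1 * 271
    ]
    assert hit.length == 271


def test_all_a_sequence_has_no_products_and_fails_control(scheme):
    res = run_panel("A" * 5000, scheme, "multiplex1")
    assert not res.control_ok
    assert res.amplified == frozenset()


def test_deleted_control_region_fails_control_but_var_amplifies(scheme):
    fix = generate_locus(
        FixtureSpec(genotype="3", seed=3, include_control=False), scheme=scheme
    )
    res = run_panel(fix.sequence, scheme, "multiplex1")
    assert not res.control_ok
    assert "Var3" in res.amplified


def test_amplicons_do_not_span_contigs(fixture_map, scheme):
    seq = fixture_map["3"].sequence
    # split the genome in the middle of the Var3 product
    res_whole = run_panel({"c1": seq}, scheme, "multiplex1")
    [hit] = res_whole.per_pair["Var3"]
    cut = hit.start + 100
    res_split = run_panel(
        {"c1": seq[:cut], "c2": seq[cut:]}, scheme, "multiplex1"
    )
    assert "Var3" not in res_split.amplified
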