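"""Gene-family construction and locus clustering."""

import numpy as np
import pytest

from rgptyper.errors import InputError
from rgptyper.family_clustering import (
    build_families,
    hcl_cluster,
    pairwise_similarity,
    presence_absence,
    similarity_edges,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, n):
    return "M" + "".join(rng.choice(AA, size=n - 1))


def mutate(seq, rate, rng):
    out = list(seq)
    for i in range(1, len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AA if a != out[i]])
    return "".join(out)


# -------------------------------------------------- pairwise similarity


def test_identical_sequences_have_full_identity_and_coverage():
    seq = random_protein(np.random.default_rng(0), 120)
    edge = pairwise_similarity(seq, seq)
    assert edge.identity == 100.0
    assert edge.coverage_a == 100.0 and edge.coverage_b == 100.0
    assert edge.bidirectional_pass


def test_half_length_prefix_has_half_coverage_of_longer():
    rng = np.random.default_rng(1)
    b = random_protein(rng, 200)
    a = b[:100]
    edge = pairwise_similarity(a, b)
    assert edge.identity == 100.0
    assert edge.coverage_a == 100.0
    assert edge.coverage_b == 50.0
    assert edge.bidirectional_pass  # >= is inclusive at the 50% boundary
    # just under half: fails the both-coverage criterion, passes "either"
    under = pairwise_similarity(b[:99], b)
    assert under.coverage_b < 50.0
    assert not under.bidirectional_pass
    relaxed = pairwise_similarity(b[:99], b, coverage_mode="either")
    assert relaxed.bidirectional_pass


def test_random_sequences_fail_fifty_fifty():
    rng = np.random.default_rng(2)
    a, b = random_protein(rng, 200), random_protein(rng, 200)
    edge = pairwise_similarity(a, b)
    assert not edge.bidirectional_pass


def test_non_amino_acid_characters_rejected():
    with pytest.raises(InputError):
        pairwise_similarity("MKLV123", "MKLV")


# ------------------------------------------------------ family building


def test_three_identical_proteins_one_family():
    seq = random_protein(np.random.default_rng(3), 150)
    fams = build_families({"l1": {"p1": seq}, "l2": {"p2": seq}, "l3": {"p3": seq}})
    assert len(fams) == 1
    assert fams.families[0] == frozenset({"p1", "p2", "p3"})


def test_unrelated_singletons_stay_separate():
    rng = np.random.default_rng(4)
    prots = {f"p{i}": random_protein(rng, 180) for i in range(6)}
    fams = build_families(prots)
    assert len(fams) == 6


def test_planted_families_recovered_exactly():
    """10 seed proteins, 3 mutated copies each (intra-family identity
    roughly 70-90%, inter-family background ~5%) -> exactly 10 families."""
    rng = np.random.default_rng(5)
    seeds = [random_protein(rng, 200) for _ in range(10)]
    proteins = {}
    truth = {}
    for fi, seed in enumerate(seeds):
        for ci in range(3):
            pid = f"f{fi}c{ci}"
            proteins[pid] = mutate(seed, rng.uniform(0.05, 0.15), rng)
            truth[pid] = fi
    fams = build_families(proteins)
    assert len(fams) == 10
    for fam in fams.families:
        assert len({truth[p] for p in fam}) == 1


def test_family_partition_is_input_order_invariant():
    rng = np.random.default_rng(6)
    seeds = [random_protein(rng, 150) for _ in range(4)]
    proteins = {f"p{i}{j}": mutate(s, 0.05, rng)
                for i, s in enumerate(seeds) for j in range(2)}
    fwd = build_families(dict(sorted(proteins.items())))
    rev = build_families(dict(sorted(proteins.items(), reverse=True)))
    assert fwd.families == rev.families
    assert fwd.labels == rev.labels


def test_strict_thresholds_give_exact_duplicate_classes():
    rng = np.random.default_rng(7)
    a = random_protein(rng, 120)
    b = mutate(a, 0.02, rng)  # near- but not exact duplicate
    fams = build_families({"a1": a, "a2": a, "b": b}, min_id=100, min_cov=100,
                          prefilter=False)
    by_str = {frozenset({"a1", "a2"}), frozenset({"b"})}
    assert set(fams.families) == by_str


def test_mcl_agrees_with_components_on_separated_graph():
    rng = np.random.default_rng(8)
    seeds = [random_protein(rng, 160) for _ in range(5)]
    proteins = {f"p{i}{j}": mutate(s, 0.05, rng)
                for i, s in enumerate(seeds) for j in range(3)}
    comp = build_families(proteins, method="components")
    mcl = build_families(proteins, method="mcl")
    assert comp.families == mcl.families


def test_empty_input_rejected():
    with pytest.raises(InputError):
        build_families({})


# ---------------------------------------------------- presence/absence


def test_single_locus_matrix_all_true():
    rng = np.random.default_rng(9)
    prots = {f"p{i}": random_protein(rng, 150) for i in range(4)}
    fams = build_families({"locus": prots})
    m = presence_absence(fams, {"locus": prots.keys()})
    assert m.shape == (1, 4)
    assert m.to_numpy().all()


def test_disjoint_loci_give_block_diagonal_matrix():
    rng = np.random.default_rng(10)
    l1 = {f"a{i}": random_protein(rng, 150) for i in range(3)}
    l2 = {f"b{i}": random_protein(rng, 150) for i in range(3)}
    fams = build_families({"L1": l1, "L2": l2})
    m = presence_absence(fams, {"L1": l1.keys(), "L2": l2.keys()})
    row1 = m.loc["L1"].to_numpy()
    row2 = m.loc["L2"].to_numpy()
    assert (row1 & row2).sum() == 0
    assert row1.sum() == 3 and row2.sum() == 3


def test_seven_genotype_fixture_row_sums_match_planted_counts(fixture_map):
    fixtures = [fixture_map[g] for g in ("1", "2", "2A", "3", "4", "6", "7")]
    per_locus = {f.strain: {g.id: g.protein for g in f.locus_genes}
                 for f in fixtures}
    fams = build_families(per_locus)
    m = presence_absence(fams, {k: v.keys() for k, v in per_locus.items()})
    for f in fixtures:
        assert m.loc[f.strain].sum() == f.truth.n_locus_genes


def test_unassigned_protein_rejected():
    rng = np.random.default_rng(11)
    prots = {"p1": random_protein(rng, 150)}
    fams = build_families(prots)
    with pytest.raises(InputError):
        presence_absence(fams, {"L": ["p1", "ghost"]})


# ---------------------------------------------------------------- HCL


def test_identical_rows_merge_at_zero_distance():
    import pandas as pd

    m = pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
        index=["a", "b", "c"], dtype=bool,
    )
    res = hcl_cluster(m, k=2)
    assert res.flat_clusters["a"] == res.flat_clusters["b"] != res.flat_clusters["c"]
    assert res.linkage[0, 2] == 0.0  # first merge at distance 0


def test_opposite_rows_have_jaccard_distance_one():
    import pandas as pd

    m = pd.DataFrame([[1, 1, 1], [0, 0, 0]], index=["x", "y"], dtype=bool)
    res = hcl_cluster(m)
    assert res.linkage[0, 2] == 1.0


def test_single_row_rejected():
    import pandas as pd

    with pytest.raises(InputError):
        hcl_cluster(pd.DataFrame([[1, 0]], index=["only"], dtype=bool))


def test_newick_contains_all_leaves():
    import pandas as pd

    m = pd.DataFrame(np.eye(4, dtype=bool), index=list("wxyz"))
    res = hcl_cluster(m)
    for leaf in "wxyz":
        assert leaf in res.newick
    assert res.newick.endswith(";")
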