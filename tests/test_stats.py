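"""Fisher/BH selection, hypergeometric ORA and catalogue joins."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctvar.concordance import build_presence, group_presence, derive_tumor_centric
from ctvar.stats import (
    bh_adjust,
    catalogue_join,
    fisher_one_sided,
    ora_hypergeom,
    read_gmt,
    select_variants,
)
from ctvar.vcf_io import VariantKey


# -- independent oracles ----------------------------------------------------

def fisher_enumeration(a, b, c, d):
    """Exhaustive same-margin enumeration: P(count >= a) among all tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(
        math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(a, hi + 1)
    ) / denom


def bh_naive(p):
    """Naive O(m^2) step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[j] / (r) for r, j in enumerate(order, start=1) if r >= rank_pos),
            1.0,
        )
    return q


def test_fisher_closed_form_case():
    # C(3,3)*C(3,0)/C(6,3) = 1/20
    assert fisher_one_sided(3, 0, 0, 3) == pytest.approx(0.05)


def test_fisher_no_signal_and_degenerate_cases():
    assert fisher_one_sided(0, 5, 0, 5) == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        assert fisher_one_sided(0, 0, 0, 0) == 1.0
    with pytest.raises(ValueError):
        fisher_one_sided(-1, 0, 0, 0)


def test_fisher_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 11, size=4)
        if a + b + c + d == 0:
            continue
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            fisher_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
        )


def test_bh_small_examples():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.5]) == pytest.approx([0.5])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_matches_naive_on_random_vectors():
    rng = np.random.default_rng(99)
    for _ in range(100):
        m = int(rng.integers(1, 51))
        p = rng.random(m)
        assert bh_adjust(p) == pytest.approx(bh_naive(list(p)), rel=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(derandomize=True, max_examples=60)
def test_bh_monotone_dominating_and_permutation_equivariant(p):
    q = bh_adjust(p)
    assert all(0 <= qi <= 1 for qi in q)
    assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p))  # q dominates p
    order = sorted(range(len(p)), key=p.__getitem__)
    assert all(  # step-up: q non-decreasing in p-rank
        q[order[i]] <= q[order[i + 1]] + 1e-12 for i in range(len(p) - 1)
    )
    perm = list(reversed(range(len(p))))
    q_perm = bh_adjust([p[i] for i in perm])
    assert [q[i] for i in perm] == pytest.approx(list(q_perm))


# -- variant selection ------------------------------------------------------

def test_select_variants_on_planted_cohort(sim):
    matrix, cohort, gp = sim["matrix"], sim["cohort"], sim["gp"]
    tc = derive_tumor_centric(gp).included
    res = select_variants(matrix, cohort, tc, case="HCC", controls=("LC", "NHC"))
    assert len(res) == len(tc)
    # margins are the case/control plasma sample counts
    assert (res["a"] + res["b"] == 14).all()
    assert (res["c"] + res["d"] == 14).all()
    # tumor-centric variants are absent from control plasma by construction
    assert (res["c"] == 0).all()
    strong = res[res["a"] >= 6]
    assert (strong["selected"]).all()
    # q respects the step-up ordering
    assert (res["q"] >= res["p"] - 1e-12).all()


def test_selection_independent_of_candidate_order(sim):
    matrix, cohort = sim["matrix"], sim["cohort"]
    tc = derive_tumor_centric(sim["gp"]).included
    res1 = select_variants(matrix, cohort, tc)
    res2 = select_variants(matrix, cohort, list(reversed(tc)))
    assert res1.equals(res2)


def test_ubiquitous_candidate_not_selected(sim):
    matrix, cohort = sim["matrix"], sim["cohort"]
    # pick a background HIGH variant present in controls too, if any
    gp = sim["gp"]
    everywhere = [
        v
        for v in matrix.variants
        if gp.freq(v, ("HCC", "plasma")) > 0 and gp.freq(v, ("NHC", "plasma")) > 0
    ]
    if not everywhere:
        pytest.skip("no shared variant in this draw")
    res = select_variants(matrix, cohort, everywhere[:1])
    assert not res["selected"].iloc[0] or res["p"].iloc[0] < 1.0


def test_selection_requires_controls(sim):
    with pytest.raises(ValueError, match="control"):
        select_variants(
            sim["matrix"], sim["cohort"], sim["matrix"].variants[:1], controls=()
        )


# -- over-representation ----------------------------------------------------

def ora_enumeration(overlap, universe, set_size, query):
    denom = math.comb(universe, query)
    hi = min(set_size, query)
    return sum(
        math.comb(set_size, k) * math.comb(universe - set_size, query - k)
        for k in range(overlap, hi + 1)
    ) / denom


def test_ora_perfect_overlap_closed_form():
    universe = [f"g{i}" for i in range(100)]
    query = universe[:5]
    res = ora_hypergeom(query, {"S": query}, universe)
    assert res["p"].iloc[0] == pytest.approx(1 / math.comb(100, 5))


def test_ora_zero_overlap_is_one():
    universe = [f"g{i}" for i in range(20)]
    res = ora_hypergeom(universe[:5], {"S": universe[10:15]}, universe)
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_ora_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(7)
    universe = [f"g{i}" for i in range(50)]
    for _ in range(50):
        q = rng.choice(universe, size=rng.integers(1, 20), replace=False).tolist()
        s = rng.choice(universe, size=rng.integers(1, 30), replace=False).tolist()
        res = ora_hypergeom(q, {"S": s}, universe)
        k = len(set(q) & set(s))
        assert res["p"].iloc[0] == pytest.approx(
            ora_enumeration(k, 50, len(s), len(q)), rel=1e-9
        )


def test_ora_empty_universe_errors():
    with pytest.raises(ValueError, match="universe"):
        ora_hypergeom(["a"], {"S": ["a"]}, [])


def test_read_gmt(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("pathA\tdesc\tg1\tg2\ng3\nshort\tonly_two_fields\n")
    sets = read_gmt(gmt)
    assert sets == {"pathA": {"g1", "g2"}}


# -- catalogue join ---------------------------------------------------------

def test_catalogue_join_flags_known_and_normalizes(tmp_path):
    cat = tmp_path / "cat.tsv"
    cat.write_text(
        "chrom\tpos\tref\talt\tid\n"
        "chr1\t100\tA\tG\trs1\n"
        "chr1\t199\tCAT\tCA\trs2\n"  # un-normalized deletion of T at 201
        "chr1\tnotanint\tA\tG\trs3\n"
    )
    variants = [
        VariantKey("chr1", 100, "A", "G"),
        VariantKey("chr1", 200, "AT", "A"),
        VariantKey("chr2", 5, "C", "T"),
    ]
    res = catalogue_join(variants, cat).set_index(["chrom", "pos"])
    assert res.loc[("chr1", 100), "known"].item() is True or bool(res.loc[("chr1", 100), "known"])
    assert bool(res.loc[("chr1", 200), "known"])  # matched after normalization
    assert not bool(res.loc[("chr2", 5), "known"])


def test_catalogue_join_empty_catalogue_all_novel():
    cat = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    res = catalogue_join([VariantKey("chr1", 1, "A", "G")], cat)
    assert not res["known"].any()
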