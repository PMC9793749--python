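"""Presence matrix, once-only group counting and the exclusion cascade."""

import numpy as np
import pytest

from ctvar.cohort import CohortDesign, SampleMeta
from ctvar.concordance import (
    build_presence,
    cross_group_concordance,
    derive_tumor_centric,
    ev_enriched,
    group_presence,
    sorted_variants,
    triple_concordant,
    venn_sources,
)
from ctvar.vcf_io import FilterConfig, VariantKey, apply_call_filters
from .conftest import make_call, tiny_cohort


def filtered(calls):
    return apply_call_filters(calls)


def calls_map(cohort, calls):
    out = {s: [] for s in cohort.sample_ids}
    for c in calls:
        out[c.sample_id].append(c)
    return out


def test_build_presence_rows_reflect_passed_calls():
    cohort = tiny_cohort()
    calls = filtered([make_call("HP1", pos=100), make_call("HT1", pos=100)])
    m = build_presence(calls_map(cohort, calls), cohort)
    v = VariantKey("chr1", 100, "A", "G")
    assert m.present(v, "HP1") and m.present(v, "HT1")
    assert not m.present(v, "HP2")


def test_moderate_only_variant_dropped_from_high_matrix():
    cohort = tiny_cohort()
    calls = filtered([make_call("HP1", impact="MODERATE", effects=("missense_variant",))])
    m = build_presence(calls_map(cohort, calls), cohort)
    assert m.variants == []


def test_subthreshold_call_is_not_presence():
    cohort = tiny_cohort()
    calls = filtered([make_call("HP1", qual=10.0)])
    m = build_presence(calls_map(cohort, calls), cohort)
    assert m.variants == []


def test_missing_sample_call_list_is_hard_error():
    cohort = tiny_cohort()
    with pytest.raises(ValueError, match="no VCF loaded"):
        build_presence({"HP1": []}, cohort)


def test_group_presence_counts_once_only_with_frequency():
    cohort = tiny_cohort()
    calls = filtered(
        [make_call("HT1", pos=5), make_call("HT2", pos=5), make_call("HP1", pos=5)]
    )
    gp = group_presence(build_presence(calls_map(cohort, calls), cohort), cohort)
    v = VariantKey("chr1", 5, "A", "G")
    assert ("HCC", "tumor") in gp.membership[v]
    assert gp.freq(v, ("HCC", "tumor")) == 1.0  # 2 of 2 tumors
    assert gp.freq(v, ("HCC", "plasma")) == 0.5  # 1 of 2 plasmas
    assert gp.freq(v, ("LC", "plasma")) == 0.0


def test_cascade_includes_concordant_and_vetoes_controls():
    cohort = tiny_cohort()
    concordant = [make_call("HT1", pos=10), make_call("HP1", pos=10)]
    vetoed = [make_call("HT1", pos=20), make_call("HP1", pos=20), make_call("NP1", pos=20)]
    tumor_only = [make_call("HT1", pos=30)]
    gp = group_presence(
        build_presence(calls_map(cohort, filtered(concordant + vetoed + tumor_only)), cohort),
        cohort,
    )
    res = derive_tumor_centric(gp)
    assert res.included == [VariantKey("chr1", 10, "A", "G")]
    assert res.excluded[VariantKey("chr1", 20, "A", "G")] == ["NHC/plasma"]
    assert VariantKey("chr1", 30, "A", "G") not in res.candidates


def test_subthreshold_control_call_does_not_veto():
    cohort = tiny_cohort()
    calls = [
        make_call("HT1", pos=10),
        make_call("HP1", pos=10),
        make_call("NP1", pos=10, qual=5.0),  # below QUAL threshold
    ]
    gp = group_presence(build_presence(calls_map(cohort, filtered(calls)), cohort), cohort)
    assert derive_tumor_centric(gp).included == [VariantKey("chr1", 10, "A", "G")]


def test_missing_required_stratum_is_hard_error():
    cohort = CohortDesign(
        samples=[
            SampleMeta("HP1", "H1", "HCC", "plasma", "x.vcf"),
            SampleMeta("NP1", "N1", "NHC", "plasma", "y.vcf"),
        ]
    )
    gp = group_presence(
        build_presence(calls_map(cohort, filtered([make_call("HP1")])), cohort), cohort
    )
    with pytest.raises(ValueError, match="HCC/tumor"):
        derive_tumor_centric(gp)


def test_planted_recovery_is_exact_on_noise_free_cohort(sim):
    res = derive_tumor_centric(sim["gp"])
    planted = set(sim["truth"].tumor_centric)
    assert set(res.included) == planted  # precision = recall = 1.0
    # every control-shared trap was vetoed, never included
    assert set(sim["truth"].control_shared) <= set(res.excluded)


def test_planted_frequencies_within_study_ranges(sim):
    gp = sim["gp"]
    for v in sim["truth"].tumor_centric:
        assert 0.30 - 1e-9 <= gp.freq(v, ("HCC", "tumor")) <= 1.0
        assert 0.07 - 1e-9 <= gp.freq(v, ("HCC", "plasma")) <= 0.50 + 1e-9


def test_ev_enriched_recovers_planted_set():
    from ctvar.simulate import SimDesign, simulate_calls

    design = SimDesign(seed=21, ev_subset_fraction=0.0, cca_overlap_fraction=0.0)
    calls, cohort, truth = simulate_calls(design)
    calls = {s: filtered(c) for s, c in calls.items()}
    gp = group_presence(build_presence(calls, cohort), cohort)
    res = ev_enriched(gp)
    assert set(res.included) == set(truth.ev_enriched)
    assert len(truth.ev_enriched) == 12


def test_derivation_invariant_under_sample_order(sim):
    cohort = sim["cohort"]
    reversed_cohort = CohortDesign(samples=list(reversed(cohort.samples)))
    m2 = build_presence(sim["calls"], reversed_cohort)
    res2 = derive_tumor_centric(group_presence(m2, reversed_cohort))
    assert res2.included == derive_tumor_centric(sim["gp"]).included


def test_adding_control_sample_never_grows_the_set(sim):
    base = set(derive_tumor_centric(sim["gp"]).included)
    cohort = sim["cohort"]
    extra = SampleMeta("NPX", "NX", "NHC", "plasma", "npx.vcf")
    bigger = CohortDesign(samples=cohort.samples + [extra])
    v = sorted_variants(base)[0]
    calls = dict(sim["calls"])
    calls["NPX"] = filtered([make_call("NPX", chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt)])
    m2 = build_presence(calls, bigger)
    grown = set(derive_tumor_centric(group_presence(m2, bigger)).included)
    assert grown <= base


# -- Venn decomposition -----------------------------------------------------

def brute_force_regions(sets):
    names = list(sets)
    regions = {}
    universe = set().union(*sets.values())
    for el in universe:
        membership = frozenset(n for n in names if el in sets[n])
        regions.setdefault(membership, set()).add(el)
    return regions


def test_venn_toy_three_sets():
    A = {1, 2, 3}
    B = {2, 3}
    C = {3}
    regions = venn_sources(sets={"A": A, "B": B, "C": C})
    assert regions[frozenset({"A"})] == {1}
    assert regions[frozenset({"A", "B"})] == {2}
    assert regions[frozenset({"A", "B", "C"})] == {3}
    assert regions[frozenset({"B"})] == set()
    assert len(regions) == 7


def test_venn_disjoint_sets_have_empty_intersections():
    regions = venn_sources(sets={"A": {1}, "B": {2}})
    assert regions[frozenset({"A", "B"})] == set()
    assert regions[frozenset({"A"})] == {1}


def test_venn_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        sets = {
            name: set(rng.choice(100, size=rng.integers(0, 60), replace=False).tolist())
            for name in "ABC"
        }
        regions = venn_sources(sets=sets)
        brute = brute_force_regions(sets)
        union = set()
        for membership, members in regions.items():
            assert members == brute.get(membership, set())
            assert not union & members  # pairwise disjoint
            union |= members
        assert union == set().union(*sets.values())  # union exact


def test_venn_rejects_duplicate_strata(sim):
    with pytest.raises(ValueError, match="duplicate"):
        venn_sources(gp=sim["gp"], strata=[("HCC", "plasma"), ("HCC", "plasma")])


# -- per-subject and cross-group concordance -------------------------------

def test_triple_concordant_recovers_planted_set(sim):
    _, pooled = triple_concordant(sim["matrix"], sim["cohort"])
    assert set(sim["truth"].triple_concordant) <= set(pooled)
    # pooled is restricted to variants absent from every control sample
    assert not set(pooled) & set(sim["truth"].control_shared)


def test_triple_concordant_toy_cases():
    cohort = tiny_cohort()
    # identical sets in H1's three specimens, nothing in controls
    calls = [make_call(s, pos=p) for s in ("HP1", "HT1", "HE1") for p in (10, 20)]
    m = build_presence(calls_map(cohort, filtered(calls)), cohort)
    venns, pooled = triple_concordant(m, cohort)
    h1 = next(v for v in venns if v.subject_id == "H1")
    assert h1.center == set(pooled) == {
        VariantKey("chr1", 10, "A", "G"),
        VariantKey("chr1", 20, "A", "G"),
    }
    # disjoint specimen sets: empty center
    calls2 = [make_call("HP1", pos=10), make_call("HT1", pos=20), make_call("HE1", pos=30)]
    m2 = build_presence(calls_map(cohort, filtered(calls2)), cohort)
    venns2, pooled2 = triple_concordant(m2, cohort)
    h1b = next(v for v in venns2 if v.subject_id == "H1")
    assert h1b.center == set() and pooled2 == []


def test_cca_concordant_contained_in_hcc_reference(sim):
    gp = sim["gp"]
    hcc_union = (
        gp.stratum_set(("HCC", "plasma"))
        | gp.stratum_set(("HCC", "tumor"))
        | gp.stratum_set(("HCC", "EV"))
    )
    overlap = cross_group_concordance(gp, "CCA", hcc_union)
    assert set(overlap.query_set) == set(sim["truth"].cca_shared)
    assert overlap.containment == 1.0


def test_cross_group_edge_cases(sim):
    gp = sim["gp"]
    empty = cross_group_concordance(gp, "CCA", set())
    assert empty.containment == 0.0 or empty.overlap == 0
    # empty query set reports undefined containment
    from ctvar.simulate import SimDesign, simulate_calls

    design = SimDesign(seed=5, cca_overlap_fraction=0.0)
    calls, cohort, truth = simulate_calls(design)
    calls = {s: filtered(c) for s, c in calls.items()}
    gp2 = group_presence(build_presence(calls, cohort), cohort)
    res = cross_group_concordance(gp2, "CCA", set(truth.tumor_centric))
    assert res.query_set == [] and res.containment is None
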