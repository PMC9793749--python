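"""Descriptive variant profiling by type, impact, functional class and region.

Per-sample counts and within-sample proportions are aggregated to
(group, specimen) means and standard deviations. Proportions are computed
per sample and then averaged (not pooled across samples) so the reported
standard deviation reflects between-sample variation.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CohortDesign
from .vcf_io import (
    IMPACTS,
    VariantCall,
    classify_variant_type,
    functional_class_of,
    max_impact,
    region_of,
)

log = logging.getLogger(__name__)

AXES = ("type", "impact", "functional_class", "region")

AXIS_VALUES = {
    "type": ("SNP", "insertion", "deletion", "MNP"),
    "impact": IMPACTS,
    "functional_class": ("missense", "synonymous", "nonsense", "none"),
    "region": (
        "intron",
        "upstream",
        "downstream",
        "intergenic",
        "exon",
        "splicing",
        "genic_other",
    ),
}


def _categorize(call: VariantCall, axis: str) -> str:
    if axis == "type":
        return classify_variant_type(call.key)
    if axis == "impact":
        return max_impact(call.annotations)
    # annotation-derived axes use the variant's maximal-impact annotation
    anns = call.annotations
    if not anns:
        return "none" if axis == "functional_class" else "genic_other"
    best = min(anns, key=lambda a: IMPACTS.index(a.impact))
    if axis == "functional_class":
        return functional_class_of(best.effect_terms)
    if axis == "region":
        return region_of(best.effect_terms)
    raise ValueError(f"unknown axis {axis!r} (expected one of {AXES})")


def sample_counts(
    calls: Sequence[VariantCall], axis: str, passed_only: bool = True
) -> dict[str, int]:
    """Category counts for one sample; each distinct variant counted once."""
    counts = {v: 0 for v in AXIS_VALUES[axis]}
    seen = set()
    for c in calls:
        if passed_only and not c.passed:
            continue
        if c.key in seen:
            continue
        seen.add(c.key)
        counts[_categorize(c, axis)] += 1
    return counts


def profile_samples(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    cohort: CohortDesign,
    axis: str,
) -> pd.DataFrame:
    """Tidy profile table: per (group, specimen, category) mean count, sd and
    mean within-sample percentage.

    Columns: group, specimen, axis, value, mean_count, sd, mean_pct.
    Strata with no samples carrying any categorized call are omitted with a
    logged warning. Within one sample the percentages sum to 100.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r} (expected one of {AXES})")
    per_sample_rows = []
    for s in cohort.samples:
        counts = sample_counts(calls_by_sample.get(s.sample_id, ()), axis)
        total = sum(counts.values())
        for value, n in counts.items():
            per_sample_rows.append(
                {
                    "group": s.group,
                    "specimen": s.specimen,
                    "sample_id": s.sample_id,
                    "value": value,
                    "count": n,
                    "pct": 100.0 * n / total if total else 0.0,
                }
            )
    df = pd.DataFrame(per_sample_rows)
    rows = []
    for (group, specimen), sub in df.groupby(["group", "specimen"], sort=False):
        if sub["count"].sum() == 0:
            log.warning("stratum %s/%s has no categorized calls; omitted", group, specimen)
            continue
        agg = sub.groupby("value", sort=False).agg(
            mean_count=("count", "mean"),
            sd=("count", "std"),
            mean_pct=("pct", "mean"),
        )
        agg["sd"] = agg["sd"].fillna(0.0)
        for value in AXIS_VALUES[axis]:
            rows.append(
                {
                    "group": group,
                    "specimen": specimen,
                    "axis": axis,
                    "value": value,
                    "mean_count": float(agg.loc[value, "mean_count"]),
                    "sd": float(agg.loc[value, "sd"]),
                    "mean_pct": float(agg.loc[value, "mean_pct"]),
                }
            )
    return pd.DataFrame(rows)


def group_trend(
    profile: pd.DataFrame,
    categories: Sequence[str],
    groups: Sequence[str] = ("NHC", "LC", "HCC"),
    specimen: str = "plasma",
) -> pd.DataFrame:
    """Ordered comparison of category percentages across disease progression.

    Returns one row per category with the mean percentage in each group
    (NHC -> LC -> HCC order by default) and a monotone-increase flag;
    categories with a missing group are flagged "incomparable".
    """
    rows = []
    for cat in categories:
        pcts = []
        ok = True
        for g in groups:
            sel = profile[
                (profile["group"] == g)
                & (profile["specimen"] == specimen)
                & (profile["value"] == cat)
            ]
            if sel.empty:
                ok = False
                break
            pcts.append(float(sel["mean_pct"].iloc[0]))
        row: dict = {"value": cat}
        if not ok:
            row.update({g: float("nan") for g in groups})
            row["monotone_increasing"] = "incomparable"
        else:
            row.update(dict(zip(groups, pcts)))
            row["monotone_increasing"] = all(
                b >= a for a, b in zip(pcts, pcts[1:])
            )
        rows.append(row)
    return pd.DataFrame(rows)
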