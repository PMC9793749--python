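"""Variant selection and gene-set statistics.

Variant-level selection compares presence in case versus control plasma by a
one-sided (case-enriched) Fisher exact test, with Benjamini-Hochberg step-up
adjustment over the candidate family only. Gene-set over-representation is a
generic upper-tail hypergeometric test over user-supplied GMT collections.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import CohortDesign
from .concordance import PresenceMatrix, variant_sort_key
from .vcf_io import VariantKey

log = logging.getLogger(__name__)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (case-enriched) Fisher exact p for the 2x2 table
    [[a, b], [c, d]] = [[case with, case without], [control with, control without]].

    The p-value is the hypergeometric upper-tail probability of observing a
    count >= a among tables with the same margins.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        warnings.warn("all-zero contingency table; p = 1")
        return 1.0
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(min(p, 1.0))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1. Idempotent on already
    adjusted monotone sequences.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_variants(
    matrix: PresenceMatrix,
    cohort: CohortDesign,
    candidate_set: Iterable[VariantKey],
    case: str = "HCC",
    controls: Sequence[str] = ("LC", "NHC"),
    q_threshold: float = 0.05,
    case_specimens: Sequence[str] = ("plasma",),
) -> pd.DataFrame:
    """Fisher/BH selection of candidate variants: case plasma vs pooled
    control plasma presence.

    The BH family is the candidate set passed in, not the whole matrix.
    Returns a tidy frame sorted by (q, p, genomic position) with columns
    chrom, pos, ref, alt, a, b, c, d, p, q, selected.
    """
    candidates = sorted(set(candidate_set), key=variant_sort_key)
    unknown = [v for v in candidates if v not in matrix._vidx]
    if unknown:
        raise ValueError(f"{len(unknown)} candidates absent from the presence matrix")
    case_samples = [
        s for sp in case_specimens for s in cohort.stratum_samples(case, sp)
    ]
    control_samples = [
        s.sample_id
        for s in cohort.samples
        if s.group in controls and s.specimen == "plasma"
    ]
    if not control_samples:
        raise ValueError(f"no control plasma samples in groups {list(controls)}")
    if not case_samples:
        raise ValueError(f"no case samples in stratum {case}/{list(case_specimens)}")
    case_cols = [matrix._sidx[s] for s in case_samples]
    ctrl_cols = [matrix._sidx[s] for s in control_samples]

    rows = []
    for v in candidates:
        row = matrix.data[matrix._vidx[v]]
        a = int(row[case_cols].sum())
        c = int(row[ctrl_cols].sum())
        b = len(case_cols) - a
        d = len(ctrl_cols) - c
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": fisher_one_sided(a, b, c, d),
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "a", "b", "c", "d", "p"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["selected"] = df["q"] <= q_threshold
        df = df.sort_values(["q", "p", "chrom", "pos", "ref", "alt"], kind="mergesort")
        df = df.reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["selected"] = pd.Series(dtype=bool)
    return df


# -- gene-set over-representation ------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            log.warning("GMT line with <3 fields skipped: %r", line[:80])
            continue
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def ora_hypergeom(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list.

    For each set, p = P(X >= overlap) with X ~ Hypergeom(universe, set, query);
    sets are intersected with the universe first; BH across sets. Columns:
    gene_set, overlap, set_size, universe_size, query_size, p, q.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        overlap = len(query & members)
        # sf(k-1) = P(X >= k)
        p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "set_size": len(members),
                "universe_size": len(universe),
                "query_size": len(query),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_set", "overlap", "set_size", "universe_size", "query_size", "p"],
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df


# -- known-variant catalogue join ------------------------------------------

def catalogue_join(
    variants: Iterable[VariantKey],
    catalogue: str | Path | pd.DataFrame,
) -> pd.DataFrame:
    """Exact join of variants against a known-variant catalogue table.

    The catalogue needs chrom, pos, ref, alt (+ optional id) columns; its
    keys are parsimony-normalized before matching so alternative indel
    representations still hit. Malformed rows are skipped with a logged
    count. Output columns: chrom, pos, ref, alt, known, catalogue_id.
    """
    if isinstance(catalogue, pd.DataFrame):
        cat = catalogue
    else:
        path = Path(catalogue)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        cat = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(cat.columns):
        raise ValueError(f"catalogue lacks columns {sorted(required - set(cat.columns))}")
    lookup: dict[VariantKey, str] = {}
    skipped = 0
    for row in cat.itertuples(index=False):
        try:
            key = VariantKey.normalized(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        except (ValueError, TypeError):
            skipped += 1
            continue
        lookup.setdefault(key, str(getattr(row, "id", "")) if hasattr(row, "id") else "")
    if skipped:
        log.warning("catalogue_join: %d malformed catalogue rows skipped", skipped)
    rows = []
    for v in sorted(set(variants), key=variant_sort_key):
        known = v in lookup
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "known": known,
                "catalogue_id": lookup.get(v, ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "known", "catalogue_id"]
    )
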