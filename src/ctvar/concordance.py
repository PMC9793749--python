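"""Group-level concordance logic: the tumor-centric filtration cascade.

This is the analytical core. From per-sample filtered calls it builds a
binary variant x sample presence matrix restricted to high-risk (HIGH
SnpEff impact) variants, aggregates presence to (group, specimen) strata
with once-only counting (a variant seen in several samples of one stratum
contributes a single stratum membership, while its within-stratum sample
frequency is reported descriptively), and derives named variant sets:

tumor_centric       in HCC tumors AND HCC plasma, absent from LC plasma,
                    NHC plasma and normal liver tissue
ev_enriched         the plasma-free analogue: HCC tumors AND HCC EVs,
                    absent from LC/NHC plasma
plasma_selective    in HCC plasma, absent from LC/NHC plasma
ev_selective        in HCC EVs, absent from LC/NHC plasma
triple_concordant   present in plasma, tumor and EV of the same subject
                    and absent from all control samples
cca_concordant      the same cascade run with CCA in the case role

Every exclusion is audited: for each vetoed candidate the report records
which control stratum would have vetoed it. Exclusions are evaluated on
PASSED calls only — a control sample carrying only a sub-threshold call
does not veto.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import CohortDesign
from .vcf_io import FilterConfig, VariantCall, VariantKey, max_impact

Stratum = tuple[str, str]  # (group, specimen)

_CHROM_NAT = re.compile(r"(\d+)")


def _natural_chrom(chrom: str) -> tuple:
    """Natural sort key: chr2 before chr10, X/Y/M after numerals."""
    parts = _CHROM_NAT.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def variant_sort_key(key: VariantKey) -> tuple:
    return (_natural_chrom(key.chrom), key.pos, key.ref, key.alt)


def sorted_variants(keys: Iterable[VariantKey]) -> list[VariantKey]:
    """Deterministic output order: (chrom natural order, pos, ref, alt)."""
    return sorted(keys, key=variant_sort_key)


@dataclass
class PresenceMatrix:
    """Boolean variant x sample occurrence matrix with annotation sidecar."""

    variants: list[VariantKey]
    samples: list[str]
    data: np.ndarray  # bool, shape (n_variants, n_samples)
    impact: dict[VariantKey, str] = field(default_factory=dict)
    genes: dict[VariantKey, frozenset[str]] = field(default_factory=dict)
    effects: dict[VariantKey, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids on the sample axis")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant keys on the variant axis")
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != (len(self.variants), len(self.samples)):
            raise ValueError("matrix shape does not match axes")
        self._vidx = {v: i for i, v in enumerate(self.variants)}
        self._sidx = {s: j for j, s in enumerate(self.samples)}

    def present(self, key: VariantKey, sample_id: str) -> bool:
        return bool(self.data[self._vidx[key], self._sidx[sample_id]])

    def sample_variants(self, sample_id: str) -> set[VariantKey]:
        col = self.data[:, self._sidx[sample_id]]
        return {self.variants[i] for i in np.flatnonzero(col)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "PresenceMatrix":
        cols = [self._sidx[s] for s in sample_ids]
        return PresenceMatrix(
            variants=list(self.variants),
            samples=list(sample_ids),
            data=self.data[:, cols],
            impact=self.impact,
            genes=self.genes,
            effects=self.effects,
        )


def build_presence(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    cohort: CohortDesign,
    cfg: FilterConfig | None = None,
) -> PresenceMatrix:
    """Build the high-risk presence matrix from filtered calls.

    Only calls with ``passed=True`` count as presence; variants whose maximal
    impact (across all passing calls anywhere) is outside ``cfg.impact_keep``
    are dropped. Every cohort sample must have a call list (possibly empty).
    """
    cfg = cfg or FilterConfig()
    missing = [s for s in cohort.sample_ids if s not in calls_by_sample]
    if missing:
        raise ValueError(f"cohort samples with no VCF loaded: {missing}")

    presence: dict[VariantKey, set[str]] = {}
    impact: dict[VariantKey, str] = {}
    genes: dict[VariantKey, set[str]] = {}
    effects: dict[VariantKey, set[str]] = {}
    rank = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
    for sample_id in cohort.sample_ids:
        for call in calls_by_sample[sample_id]:
            if call.passed is None:
                raise ValueError("calls must pass through apply_call_filters first")
            if not call.passed:
                continue
            k = call.key
            presence.setdefault(k, set()).add(sample_id)
            ci = max_impact(call.annotations)
            if k not in impact or rank[ci] < rank[impact[k]]:
                impact[k] = ci
            genes.setdefault(k, set()).update(a.gene for a in call.annotations if a.gene)
            effects.setdefault(k, set()).update(
                t for a in call.annotations for t in a.effect_terms
            )

    kept = sorted_variants(k for k in presence if impact[k] in cfg.impact_keep)
    samples = cohort.sample_ids
    data = np.zeros((len(kept), len(samples)), dtype=bool)
    sidx = {s: j for j, s in enumerate(samples)}
    for i, k in enumerate(kept):
        for s in presence[k]:
            data[i, sidx[s]] = True
    return PresenceMatrix(
        variants=kept,
        samples=samples,
        data=data,
        impact={k: impact[k] for k in kept},
        genes={k: frozenset(genes[k]) for k in kept},
        effects={k: frozenset(effects[k]) for k in kept},
    )


@dataclass
class GroupPresence:
    """Per-variant stratum membership (once-only) and sample frequencies."""

    membership: dict[VariantKey, frozenset[Stratum]]
    frequency: dict[VariantKey, dict[Stratum, float]]
    stratum_sizes: dict[Stratum, int]

    def stratum_set(self, stratum: Stratum) -> set[VariantKey]:
        return {v for v, strata in self.membership.items() if stratum in strata}

    def freq(self, key: VariantKey, stratum: Stratum) -> float:
        return self.frequency.get(key, {}).get(stratum, 0.0)


def group_presence(matrix: PresenceMatrix, cohort: CohortDesign) -> GroupPresence:
    """Aggregate the presence matrix to (group, specimen) strata.

    Once-only counting: presence in k >= 1 samples of a stratum yields ONE
    stratum membership; frequency = k / stratum size is kept alongside.
    """
    strata = cohort.strata()
    stratum_cols = {
        st: [matrix._sidx[s] for s in cohort.stratum_samples(*st)] for st in strata
    }
    membership: dict[VariantKey, frozenset[Stratum]] = {}
    frequency: dict[VariantKey, dict[Stratum, float]] = {}
    for i, key in enumerate(matrix.variants):
        row = matrix.data[i]
        mem: list[Stratum] = []
        freqs: dict[Stratum, float] = {}
        for st in strata:
            cols = stratum_cols[st]
            if not cols:
                continue
            k = int(row[cols].sum())
            if k > 0:
                mem.append(st)
                freqs[st] = k / len(cols)
        membership[key] = frozenset(mem)
        frequency[key] = freqs
    sizes = {st: len(cols) for st, cols in stratum_cols.items()}
    return GroupPresence(membership=membership, frequency=frequency, stratum_sizes=sizes)


@dataclass
class CascadeResult:
    """Outcome of one exclusion cascade: the kept set plus a full audit."""

    included: list[VariantKey]
    #: candidate -> names of control strata that vetoed it
    excluded: dict[VariantKey, list[str]]
    #: candidate pool before control exclusion
    candidates: list[VariantKey]

    def __iter__(self):
        return iter(self.included)

    def __len__(self) -> int:
        return len(self.included)

    @property
    def included_set(self) -> set[VariantKey]:
        return set(self.included)


def _stratum_name(st: Stratum) -> str:
    return f"{st[0]}/{st[1]}"


def _cascade(
    gp: GroupPresence,
    require: Sequence[Stratum],
    exclude: Sequence[Stratum],
    min_frequency: float = 0.0,
) -> CascadeResult:
    """Generic cascade: membership in all ``require`` strata (optionally at a
    minimum within-stratum frequency), then veto by any ``exclude`` stratum."""
    for st in require:
        if st not in gp.stratum_sizes:
            raise ValueError(f"required stratum {_stratum_name(st)} absent from cohort")
    candidates = [
        v
        for v, strata in gp.membership.items()
        if all(st in strata and gp.freq(v, st) >= min_frequency for st in require)
    ]
    present_exclude = [st for st in exclude if st in gp.stratum_sizes]
    included: list[VariantKey] = []
    excluded: dict[VariantKey, list[str]] = {}
    for v in candidates:
        vetoes = [_stratum_name(st) for st in present_exclude if st in gp.membership[v]]
        if vetoes:
            excluded[v] = vetoes
        else:
            included.append(v)
    return CascadeResult(
        included=sorted_variants(included),
        excluded=excluded,
        candidates=sorted_variants(candidates),
    )


#: control strata whose presence vetoes a tumor-centric candidate
CONTROL_STRATA: tuple[Stratum, ...] = (
    ("LC", "plasma"),
    ("NHC", "plasma"),
    ("NHC", "normal_liver"),
)


def derive_tumor_centric(
    gp: GroupPresence,
    case_group: str = "HCC",
    min_frequency: float = 0.0,
) -> CascadeResult:
    """Concordant tumor/plasma variants of the case group, control-vetoed.

    Keeps variants present in >= 1 passing case tumor AND >= 1 passing case
    plasma sample, and absent from LC plasma, NHC plasma and normal liver.
    """
    return _cascade(
        gp,
        require=[(case_group, "tumor"), (case_group, "plasma")],
        exclude=CONTROL_STRATA,
        min_frequency=min_frequency,
    )


def ev_enriched(
    gp: GroupPresence,
    case_group: str = "HCC",
    min_frequency: float = 0.0,
) -> CascadeResult:
    """Tumor/EV concordant variants absent from LC and NHC plasma."""
    return _cascade(
        gp,
        require=[(case_group, "tumor"), (case_group, "EV")],
        exclude=(("LC", "plasma"), ("NHC", "plasma")),
        min_frequency=min_frequency,
    )


def selective_set(
    gp: GroupPresence,
    stratum: Stratum,
    min_frequency: float = 0.0,
) -> CascadeResult:
    """Variants of one case stratum absent from LC/NHC plasma (the
    'plasma-selective' / 'EV-selective' heat-map sets)."""
    return _cascade(
        gp,
        require=[stratum],
        exclude=(("LC", "plasma"), ("NHC", "plasma")),
        min_frequency=min_frequency,
    )


def venn_sources(
    sets: Mapping[str, set[VariantKey]] | None = None,
    gp: GroupPresence | None = None,
    strata: Sequence[Stratum] | None = None,
) -> dict[frozenset[str], set[VariantKey]]:
    """Disjoint Venn decomposition of 2 or 3 named variant sets.

    Pass either ``sets`` (name -> set) or ``gp`` + ``strata`` (stratum
    presence sets). All 2^n - 1 regions are reported, keyed by the frozenset
    of member names; regions are pairwise disjoint and their union equals the
    union of the inputs.
    """
    if sets is None:
        if gp is None or strata is None:
            raise ValueError("pass either sets= or gp= and strata=")
        if len(set(strata)) != len(strata):
            raise ValueError("duplicate strata")
        sets = {_stratum_name(st): gp.stratum_set(st) for st in strata}
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn decomposition supports 2 or 3 sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    regions: dict[frozenset[str], set[VariantKey]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = inside - outside
    return regions


@dataclass
class SubjectVenn:
    subject_id: str
    specimens: list[str]
    regions: dict[frozenset[str], set[VariantKey]]

    @property
    def center(self) -> set[VariantKey]:
        """Variants shared by every specimen of the subject."""
        return self.regions.get(frozenset(self.specimens), set())


def triple_concordant(
    matrix: PresenceMatrix,
    cohort: CohortDesign,
    case_groups: Sequence[str] = ("HCC", "CCA"),
    control_groups: Sequence[str] = ("LC", "NHC"),
) -> tuple[list[SubjectVenn], list[VariantKey]]:
    """Per-subject specimen Venn decompositions and the pooled concordant set.

    For every cancer subject with >= 2 specimens the plasma/tumor/EV variant
    sets are decomposed into Venn regions. The pooled set collects variants
    triple-concordant (plasma AND tumor AND EV) in >= 1 three-specimen
    subject and absent from every control-group sample.
    """
    control_samples = [
        s.sample_id for s in cohort.samples if s.group in control_groups
    ]
    control_union: set[VariantKey] = set()
    for s in control_samples:
        control_union |= matrix.sample_variants(s)

    per_subject: list[SubjectVenn] = []
    pooled: set[VariantKey] = set()
    for group in case_groups:
        for subject in cohort.subjects(group):
            specs = {
                s.specimen: s.sample_id
                for s in cohort.samples
                if s.subject_id == subject and s.specimen in ("plasma", "tumor", "EV")
            }
            if len(specs) < 2:
                continue
            sets = {sp: matrix.sample_variants(sid) for sp, sid in sorted(specs.items())}
            regions = venn_sources(sets=sets)
            sv = SubjectVenn(subject_id=subject, specimens=sorted(specs), regions=regions)
            per_subject.append(sv)
            if len(sv.specimens) == 3:
                pooled |= sv.center
    pooled -= control_union
    return per_subject, sorted_variants(pooled)


@dataclass
class CrossGroupOverlap:
    query_set: list[VariantKey]
    reference_size: int
    overlap: int
    containment: float | None  # None when the query set is empty

    @property
    def contained(self) -> bool:
        return self.containment == 1.0


def cross_group_concordance(
    gp: GroupPresence,
    query_group: str,
    reference_set: Iterable[VariantKey],
    min_frequency: float = 0.0,
) -> CrossGroupOverlap:
    """Run the cascade with ``query_group`` in the case role and measure the
    fraction of its concordant set contained in ``reference_set``."""
    qc = derive_tumor_centric(gp, case_group=query_group, min_frequency=min_frequency)
    ref = set(reference_set)
    overlap = len(qc.included_set & ref)
    containment = overlap / len(qc.included) if qc.included else None
    return CrossGroupOverlap(
        query_set=qc.included,
        reference_size=len(ref),
        overlap=overlap,
        containment=containment,
    )


@dataclass
class ConcordanceReport:
    """All named variant sets of the analysis, with exclusion provenance."""

    tumor_centric: CascadeResult
    ev_enriched: CascadeResult
    plasma_selective: CascadeResult
    ev_selective: CascadeResult
    subject_venns: list[SubjectVenn]
    triple_concordant: list[VariantKey]
    cca_concordant: CrossGroupOverlap | None
    group_presence: GroupPresence

    def named_sets(self) -> dict[str, list[VariantKey]]:
        out = {
            "tumor_centric": self.tumor_centric.included,
            "ev_enriched": self.ev_enriched.included,
            "plasma_selective": self.plasma_selective.included,
            "ev_selective": self.ev_selective.included,
            "triple_concordant": self.triple_concordant,
        }
        if self.cca_concordant is not None:
            out["cca_concordant"] = self.cca_concordant.query_set
        return out


def derive_concordance_report(
    matrix: PresenceMatrix,
    cohort: CohortDesign,
    min_frequency: float = 0.0,
) -> ConcordanceReport:
    """Run the full concordance analysis on a cohort presence matrix.

    CCA specimens are excluded from the HCC derivation and its control side;
    the CCA concordant set is derived by the same cascade with CCA in the
    case role and compared against the union of HCC high-risk strata.
    """
    gp = group_presence(matrix, cohort)
    tc = derive_tumor_centric(gp, min_frequency=min_frequency)
    has_ev = ("HCC", "EV") in gp.stratum_sizes
    ev = (
        ev_enriched(gp, min_frequency=min_frequency)
        if has_ev
        else CascadeResult(included=[], excluded={}, candidates=[])
    )
    ps = selective_set(gp, ("HCC", "plasma"), min_frequency=min_frequency)
    es = (
        selective_set(gp, ("HCC", "EV"), min_frequency=min_frequency)
        if has_ev
        else CascadeResult(included=[], excluded={}, candidates=[])
    )
    venns, triple = triple_concordant(matrix, cohort)
    cca = None
    if ("CCA", "tumor") in gp.stratum_sizes and ("CCA", "plasma") in gp.stratum_sizes:
        hcc_union: set[VariantKey] = set()
        for sp in ("plasma", "tumor", "EV"):
            if ("HCC", sp) in gp.stratum_sizes:
                hcc_union |= gp.stratum_set(("HCC", sp))
        cca = cross_group_concordance(gp, "CCA", hcc_union, min_frequency=min_frequency)
    return ConcordanceReport(
        tumor_centric=tc,
        ev_enriched=ev,
        plasma_selective=ps,
        ev_selective=es,
        subject_venns=venns,
        triple_concordant=triple,
        cca_concordant=cca,
        group_presence=gp,
    )
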