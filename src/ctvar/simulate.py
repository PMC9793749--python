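"""Seeded synthetic multi-sample SnpEff-annotated VCF cohorts with planted truth.

The generator emulates the study cohort layout — 14 HCC plasma with 6
matched tumors and 5 matched extracellular-vesicle (EV) preparations, 8 LC
and 6 NHC control plasmas, one normal liver tissue, and 2 CCA subjects with
three matched specimens each — and plants variant classes with known
membership so every pipeline stage can be tested against ground truth:

background       variants shared across all clinical groups; SnpEff impact
                 drawn from the configured marginals (mostly MODIFIER)
control_shared   HIGH-impact variants planted in HCC tumors AND plasma AND
                 at least one control stratum: the veto-bait class proving
                 the exclusion arms of the cascade work
tumor_centric    HIGH-impact variants planted in HCC tumors at 30-100%
                 sample frequency and HCC plasma at 7-50%, never in any
                 control sample; the recovery target
ev_enriched      HIGH-impact variants planted in HCC tumors and EVs but not
                 plasma and never in controls

A configurable fraction of the tumor-centric class is additionally planted
in HCC EVs (with one subject forced to carry it in all three specimens, the
triple-concordance target) and a fraction is replanted in the CCA specimens
so cross-group containment is exercised. Detection noise is controlled by a
per-stratum dropout (false-negative) rate and a sub-threshold-QUAL fraction;
both default to zero, so the default cohort is exactly recoverable.

All randomness flows from one integer seed; per-sample depth/QUAL/dropout
streams are derived by stable hashing of the sample id, so adding a sample
does not perturb the calls of the others. Identical seed + design yields
byte-identical VCF output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import CohortDesign, SampleMeta
from .concordance import sorted_variants, variant_sort_key
from .vcf_io import Annotation, VariantCall, VariantKey

CLASSES = ("background", "control_shared", "tumor_centric", "ev_enriched")

_HIGH_EFFECTS = (
    ("splice_donor_variant", 0.35),
    ("splice_acceptor_variant", 0.30),
    ("frameshift_variant", 0.28),
    ("stop_gained", 0.07),
)

_MODIFIER_EFFECTS = (
    ("intron_variant", 0.56 / 0.916),
    ("downstream_gene_variant", 0.126 / 0.916),
    ("upstream_gene_variant", 0.125 / 0.916),
    ("intergenic_region", 0.105 / 0.916),
)


@dataclass
class SimDesign:
    """Cohort layout, planted-class sizes and noise models of one simulation."""

    # cohort layout (study-layout defaults)
    n_hcc_plasma: int = 14
    n_hcc_tumor: int = 6
    n_hcc_ev: int = 5
    n_lc_plasma: int = 8
    n_nhc_plasma: int = 6
    n_normal_liver: int = 1
    n_cca_subjects: int = 2  # each with plasma + tumor + EV

    # planted classes
    n_background: int = 200
    n_control_shared: int = 30
    n_tumor_centric: int = 50
    n_ev_enriched: int = 12

    # carrier-frequency models (observed study ranges)
    tumor_freq_range: tuple[float, float] = (0.30, 1.00)
    plasma_freq_range: tuple[float, float] = (0.07, 0.50)
    ev_subset_fraction: float = 0.4
    cca_overlap_fraction: float = 0.2
    background_carrier_prob: float = 0.5

    # annotation model
    impact_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "MODIFIER": 0.943,
            "HIGH": 0.023,
            "LOW": 0.023,
            "MODERATE": 0.011,
        }
    )
    n_genes: int = 300

    # call-level noise models
    depth_floor: int = 5
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    frac_qual_below: float = 0.0  # fraction of calls with QUAL < 20
    dropout: dict[str, float] = field(default_factory=dict)  # "group/specimen" -> delta

    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.impact_marginals.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"impact marginals sum to {total}, expected 1")
        for lo, hi in (self.tumor_freq_range, self.plasma_freq_range):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(f"frequency range ({lo}, {hi}) not within (0, 1]")
        if not 0.0 <= self.frac_qual_below < 1.0:
            raise ValueError("frac_qual_below must lie in [0, 1)")
        for st, d in self.dropout.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"dropout for {st} outside [0, 1]")
        if self.n_tumor_centric > 0 or self.n_control_shared > 0:
            if self.n_hcc_tumor < 1 or self.n_hcc_plasma < 1:
                raise ValueError(
                    "planting tumor-centric variants requires HCC tumor and plasma samples"
                )
            if int(round(self.tumor_freq_range[0] * self.n_hcc_tumor)) < 1 and (
                self.tumor_freq_range[1] * self.n_hcc_tumor < 1
            ):
                raise ValueError("tumor frequency range yields zero carriers")
        if self.n_ev_enriched > 0 and self.n_hcc_ev < 1:
            raise ValueError("planting EV-enriched variants requires HCC EV samples")

    def delta(self, group: str, specimen: str) -> float:
        return self.dropout.get(f"{group}/{specimen}", 0.0)


@dataclass
class GroundTruth:
    """Planted membership and intended carriers of every simulated variant."""

    classes: dict[VariantKey, str]
    carriers: dict[VariantKey, frozenset[str]]  # intended carrier sample ids
    tumor_centric: list[VariantKey]
    ev_enriched: list[VariantKey]
    control_shared: list[VariantKey]
    triple_concordant: list[VariantKey]  # forced triple-subject subset
    cca_shared: list[VariantKey]  # tumor-centric keys replanted in CCA
    #: (n_tumor_carriers, n_plasma_carriers) per tumor-centric variant
    tc_carrier_counts: dict[VariantKey, tuple[int, int]]

    def to_json(self) -> str:
        def keys(ks):
            return [[k.chrom, k.pos, k.ref, k.alt] for k in ks]

        payload = {
            "classes": {
                f"{k.chrom}:{k.pos}:{k.ref}:{k.alt}": c for k, c in sorted(
                    self.classes.items(), key=lambda kv: variant_sort_key(kv[0])
                )
            },
            "tumor_centric": keys(self.tumor_centric),
            "ev_enriched": keys(self.ev_enriched),
            "control_shared": keys(self.control_shared),
            "triple_concordant": keys(self.triple_concordant),
            "cca_shared": keys(self.cca_shared),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def study_cohort_layout(design: SimDesign, vcf_dir: str = ".") -> CohortDesign:
    """Build the matched cohort layout implied by the design.

    HCC tumors are matched to the first plasma subjects; EVs to the first
    four tumor subjects plus one plasma-only subject, reproducing the study's
    matched-set structure (4 HCC subjects with all three specimens, 2 with
    plasma+tumor, 1 with plasma+EV). Each CCA subject has all three.
    """
    samples: list[SampleMeta] = []

    def add(sample_id: str, subject: str, group: str, specimen: str) -> None:
        samples.append(
            SampleMeta(
                sample_id=sample_id,
                subject_id=subject,
                group=group,
                specimen=specimen,
                vcf_path=str(Path(vcf_dir) / f"{sample_id}.vcf"),
            )
        )

    for i in range(design.n_hcc_plasma):
        add(f"HCCP{i + 1:02d}", f"H{i + 1:02d}", "HCC", "plasma")
    for i in range(design.n_hcc_tumor):
        add(f"HCCT{i + 1:02d}", f"H{i + 1:02d}", "HCC", "tumor")
    # EVs: prefer tumor subjects (all-three sets), cap at 4, then plasma-only
    ev_subjects = []
    n_triple = min(4, design.n_hcc_ev, design.n_hcc_tumor)
    ev_subjects += [f"H{i + 1:02d}" for i in range(n_triple)]
    j = design.n_hcc_tumor
    while len(ev_subjects) < design.n_hcc_ev and j < design.n_hcc_plasma:
        ev_subjects.append(f"H{j + 1:02d}")
        j += 1
    k = n_triple
    while len(ev_subjects) < design.n_hcc_ev:  # fall back to remaining tumor subjects
        ev_subjects.append(f"H{k + 1:02d}")
        k += 1
    for i, subj in enumerate(ev_subjects):
        add(f"HCCMV{i + 1:02d}", subj, "HCC", "EV")
    for i in range(design.n_lc_plasma):
        add(f"LCP{i + 1:02d}", f"L{i + 1:02d}", "LC", "plasma")
    for i in range(design.n_nhc_plasma):
        add(f"NHCP{i + 1:02d}", f"N{i + 1:02d}", "NHC", "plasma")
    for i in range(design.n_normal_liver):
        add(f"NLT{i + 1:02d}", f"NL{i + 1:02d}", "NHC", "normal_liver")
    for i in range(design.n_cca_subjects):
        subj = f"C{i + 1:02d}"
        add(f"CCAP{i + 1:02d}", subj, "CCA", "plasma")
        add(f"CCAT{i + 1:02d}", subj, "CCA", "tumor")
        add(f"CCAMV{i + 1:02d}", subj, "CCA", "EV")
    return CohortDesign(samples=samples, notes="synthetic study-layout cohort")


def _sample_stream(seed: int, sample_id: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(sample_id.encode()).digest()[:4], "big")
    return np.random.default_rng([seed & 0x7FFFFFFF, h])


def _weighted_choice(rng: np.random.Generator, table: Sequence[tuple[str, float]]) -> str:
    names = [t[0] for t in table]
    w = np.array([t[1] for t in table], dtype=float)
    return names[rng.choice(len(names), p=w / w.sum())]


@dataclass(frozen=True)
class _SimVariant:
    key: VariantKey
    impact: str
    effect: str
    gene: str
    cls: str


def _make_variants(design: SimDesign, rng: np.random.Generator) -> list[_SimVariant]:
    n_total = (
        design.n_background
        + design.n_control_shared
        + design.n_tumor_centric
        + design.n_ev_enriched
    )
    # unique positions on a synthetic 2-chromosome coordinate space
    positions = rng.choice(np.arange(1_000, 10_000_000), size=n_total, replace=False)
    chroms = rng.choice(["chr1", "chr2"], size=n_total)
    classes = (
        ["background"] * design.n_background
        + ["control_shared"] * design.n_control_shared
        + ["tumor_centric"] * design.n_tumor_centric
        + ["ev_enriched"] * design.n_ev_enriched
    )
    imp_names = list(design.impact_marginals)
    imp_w = np.array([design.impact_marginals[n] for n in imp_names])
    bases = "ACGT"
    out: list[_SimVariant] = []
    for i, cls in enumerate(classes):
        if cls == "background":
            impact = imp_names[rng.choice(len(imp_names), p=imp_w / imp_w.sum())]
        else:
            impact = "HIGH"  # planted classes are the high-risk analysis substrate
        if impact == "HIGH":
            effect = _weighted_choice(rng, _HIGH_EFFECTS)
        elif impact == "MODERATE":
            effect = "missense_variant"
        elif impact == "LOW":
            effect = "synonymous_variant"
        else:
            effect = _weighted_choice(rng, _MODIFIER_EFFECTS)
        ref_base = bases[rng.integers(4)]
        if effect == "frameshift_variant":
            ins = bases[rng.integers(4)]
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + ins  # insertion
            else:
                ref, alt = ref_base + ins, ref_base  # deletion
        else:
            alt_base = bases[(bases.index(ref_base) + 1 + rng.integers(3)) % 4]
            ref, alt = ref_base, alt_base
        key = VariantKey(chrom=str(chroms[i]), pos=int(positions[i]), ref=ref, alt=alt)
        gene = f"GENE{rng.integers(design.n_genes) + 1:04d}"
        out.append(_SimVariant(key=key, impact=impact, effect=effect, gene=gene, cls=cls))
    return out


def _pick(rng: np.random.Generator, pool: Sequence[str], k: int) -> list[str]:
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def _carriers_for_freq(
    rng: np.random.Generator, pool: Sequence[str], freq_range: tuple[float, float]
) -> list[str]:
    f = rng.uniform(*freq_range)
    k = max(1, int(round(f * len(pool))))
    return _pick(rng, pool, k)


def simulate_calls(
    design: SimDesign,
) -> tuple[dict[str, list[VariantCall]], CohortDesign, GroundTruth]:
    """Simulate the cohort in memory: per-sample call lists + ground truth.

    Calls come back unfiltered (``passed`` unset); run them through
    ``apply_call_filters`` as with real data. Carrier structure is drawn from
    the cohort-level stream; depth/QUAL/dropout from per-sample streams.
    """
    cohort = study_cohort_layout(design)
    rng = np.random.default_rng([design.seed & 0x7FFFFFFF, 0xC0FFEE])
    variants = _make_variants(design, rng)

    strata_pools = {
        (g, sp): cohort.stratum_samples(g, sp) for (g, sp) in cohort.strata()
    }
    hcc_tumor = strata_pools.get(("HCC", "tumor"), [])
    hcc_plasma = strata_pools.get(("HCC", "plasma"), [])
    hcc_ev = strata_pools.get(("HCC", "EV"), [])
    control_pools = [
        strata_pools[st]
        for st in (("LC", "plasma"), ("NHC", "plasma"), ("NHC", "normal_liver"))
        if st in strata_pools and strata_pools[st]
    ]

    # subjects carrying all three specimens (triple-concordance targets)
    triple_subjects = {}
    for s in cohort.samples:
        triple_subjects.setdefault(s.subject_id, {})[s.specimen] = s.sample_id
    triple_subjects = {
        subj: specs
        for subj, specs in triple_subjects.items()
        if {"plasma", "tumor", "EV"} <= set(specs)
        and cohort.sample(specs["plasma"]).group == "HCC"
    }
    triple_subject_ids = sorted(triple_subjects)

    carriers: dict[VariantKey, set[str]] = {}
    classes: dict[VariantKey, str] = {}
    tc_counts: dict[VariantKey, tuple[int, int]] = {}
    tc_keys: list[VariantKey] = []
    ev_keys: list[VariantKey] = []
    cs_keys: list[VariantKey] = []
    triple_keys: list[VariantKey] = []
    cca_keys: list[VariantKey] = []

    tc_variants = [v for v in variants if v.cls == "tumor_centric"]
    n_ev_subset = int(round(design.ev_subset_fraction * len(tc_variants)))
    n_cca = int(round(design.cca_overlap_fraction * len(tc_variants)))
    ev_subset_idx = set(
        rng.choice(len(tc_variants), size=n_ev_subset, replace=False)
    ) if n_ev_subset else set()
    cca_idx = set(rng.choice(len(tc_variants), size=n_cca, replace=False)) if n_cca else set()

    tc_i = 0
    for v in variants:
        classes[v.key] = v.cls
        cset: set[str] = set()
        if v.cls == "background":
            # shared across all groups: >=1 forced carrier per group, plus noise
            for group in ("HCC", "LC", "NHC", "CCA"):
                pool = [s.sample_id for s in cohort.samples if s.group == group]
                if pool:
                    cset.add(pool[rng.integers(len(pool))])
            for s in cohort.sample_ids:
                if rng.random() < design.background_carrier_prob:
                    cset.add(s)
        elif v.cls == "control_shared":
            cset.update(_carriers_for_freq(rng, hcc_tumor, design.tumor_freq_range))
            cset.update(_carriers_for_freq(rng, hcc_plasma, design.plasma_freq_range))
            pool = control_pools[rng.integers(len(control_pools))]
            cset.update(_pick(rng, pool, 1 + int(rng.integers(2))))
            cs_keys.append(v.key)
        elif v.cls == "tumor_centric":
            t = _carriers_for_freq(rng, hcc_tumor, design.tumor_freq_range)
            p = _carriers_for_freq(rng, hcc_plasma, design.plasma_freq_range)
            if tc_i in ev_subset_idx and hcc_ev:
                cset.update(_pick(rng, hcc_ev, 1 + int(rng.integers(len(hcc_ev)))))
                if triple_subject_ids:
                    # force one all-three subject to carry the variant in all
                    # specimens, swapping carriers so the drawn stratum
                    # frequencies stay inside the study ranges
                    subj = triple_subject_ids[rng.integers(len(triple_subject_ids))]
                    trio = triple_subjects[subj]
                    for pool, target in ((t, trio["tumor"]), (p, trio["plasma"])):
                        if target not in pool:
                            others = [s for s in pool if s != target]
                            if others:
                                pool.remove(others[rng.integers(len(others))])
                            pool.append(target)
                    cset.add(trio["EV"])
                    triple_keys.append(v.key)
            cset.update(t)
            cset.update(p)
            if tc_i in cca_idx:
                for s in cohort.samples:
                    if s.group == "CCA" and s.specimen in ("tumor", "plasma"):
                        cset.add(s.sample_id)
                    elif s.group == "CCA" and rng.random() < 0.5:
                        cset.add(s.sample_id)
                cca_keys.append(v.key)
            tc_keys.append(v.key)
            n_t = len({s for s in cset if s in set(hcc_tumor)})
            n_p = len({s for s in cset if s in set(hcc_plasma)})
            tc_counts[v.key] = (n_t, n_p)
            tc_i += 1
        elif v.cls == "ev_enriched":
            cset.update(_carriers_for_freq(rng, hcc_tumor, design.tumor_freq_range))
            cset.update(_pick(rng, hcc_ev, 1 + int(rng.integers(len(hcc_ev)))))
            ev_keys.append(v.key)
        carriers[v.key] = cset

    # generator-side safety: planted case-only classes never touch controls
    control_samples = {
        s.sample_id for s in cohort.samples if s.group in ("LC", "NHC")
    }
    for k in tc_keys + ev_keys:
        assert not (carriers[k] & control_samples), "planted variant leaked into controls"

    variants_sorted = sorted(variants, key=lambda v: variant_sort_key(v.key))
    by_key = {v.key: v for v in variants}

    n_var = len(variants_sorted)
    nb_r = design.depth_dispersion
    nb_p = nb_r / (nb_r + design.depth_mean)
    calls_by_sample: dict[str, list[VariantCall]] = {s: [] for s in cohort.sample_ids}
    for meta in cohort.samples:
        srng = _sample_stream(design.seed, meta.sample_id)
        delta = design.delta(meta.group, meta.specimen)
        # one block of draws per (sample, variant) grid keeps each sample's
        # stream independent of every other sample
        u_drop = srng.random(n_var)
        u_qual = srng.random(n_var)
        depth = design.depth_floor + srng.negative_binomial(nb_r, nb_p, size=n_var)
        qual_hi = 20.0 + srng.exponential(15.0, size=n_var)
        qual_lo = srng.uniform(0.0, 20.0, size=n_var)
        sid = meta.sample_id
        out = calls_by_sample[sid]
        for i, v in enumerate(variants_sorted):
            if sid not in carriers[v.key]:
                continue
            if delta > 0 and u_drop[i] < delta:
                continue  # false negative: carrier call not emitted
            qual = qual_lo[i] if u_qual[i] < design.frac_qual_below else qual_hi[i]
            ann = Annotation(
                effect_terms=(v.effect,),
                impact=v.impact,
                gene=v.gene,
                transcript=f"{v.gene}.t1",
            )
            out.append(
                VariantCall(
                    key=v.key,
                    sample_id=sid,
                    depth=int(depth[i]),
                    qual=round(float(qual), 2),
                    annotations=(ann,),
                )
            )

    truth = GroundTruth(
        classes=classes,
        carriers={k: frozenset(v) for k, v in carriers.items()},
        tumor_centric=sorted_variants(tc_keys),
        ev_enriched=sorted_variants(ev_keys),
        control_shared=sorted_variants(cs_keys),
        triple_concordant=sorted_variants(triple_keys),
        cca_shared=sorted_variants(cca_keys),
        tc_carrier_counts=tc_counts,
    )
    return calls_by_sample, cohort, truth


# -- VCF output -------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ctvar-simulator
##contig=<ID=chr1,length=10000000>
##contig=<ID=chr2,length=10000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | CDS.pos / CDS.length | AA.pos / AA.length | Distance | ERRORS / WARNINGS / INFO'">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _ann_string(call: VariantCall) -> str:
    a = call.annotations[0]
    fields = [
        call.key.alt,
        "&".join(a.effect_terms),
        a.impact,
        a.gene,
        f"{a.gene}_id",
        "transcript",
        a.transcript,
        "protein_coding",
        "1/1",
    ] + [""] * 7
    return "|".join(fields)


def write_sample_vcf(calls: Sequence[VariantCall], sample_id: str, path: Path) -> None:
    lines = [_VCF_HEADER.format(sample=sample_id)]
    for c in sorted(calls, key=lambda c: variant_sort_key(c.key)):
        info = f"DP={c.depth};ANN={_ann_string(c)}"
        lines.append(
            f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t"
            f"{c.qual:.2f}\t.\t{info}\tGT\t0/1\n"
        )
    path.write_text("".join(lines))


def simulate_cohort(
    design: SimDesign, out_dir: str | Path
) -> tuple[CohortDesign, GroundTruth]:
    """Write a full synthetic cohort: one VCF per sample, cohort TSV,
    ground-truth JSON and a design echo. Deterministic per seed + design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls_by_sample, cohort, truth = simulate_calls(design)
    cohort = CohortDesign(
        samples=[
            SampleMeta(
                sample_id=s.sample_id,
                subject_id=s.subject_id,
                group=s.group,
                specimen=s.specimen,
                vcf_path=str(out_dir / f"{s.sample_id}.vcf"),
            )
            for s in cohort.samples
        ],
        notes=cohort.notes,
    )
    for s in cohort.samples:
        write_sample_vcf(calls_by_sample[s.sample_id], s.sample_id, Path(s.vcf_path))
    cohort.to_table(out_dir / "cohort.tsv")
    (out_dir / "ground_truth.json").write_text(truth.to_json())
    (out_dir / "design.json").write_text(
        json.dumps(asdict(design), indent=2, sort_keys=True)
    )
    return cohort, truth


# -- closed-form recall -----------------------------------------------------

def _carrier_count_pmf(freq_range: tuple[float, float], n: int) -> dict[int, float]:
    """Distribution of k = max(1, round(f*n)) for f ~ Uniform(freq_range)."""
    lo, hi = freq_range
    width = hi - lo
    pmf: dict[int, float] = {}
    if width == 0:
        pmf[max(1, int(round(lo * n)))] = 1.0
        return pmf
    for k in range(0, n + 1):
        a = max(lo, (k - 0.5) / n)
        b = min(hi, (k + 0.5) / n)
        mass = max(0.0, b - a) / width
        if mass > 0:
            kk = max(1, k)
            pmf[kk] = pmf.get(kk, 0.0) + mass
    return pmf


def expected_recall(design: SimDesign, truth: GroundTruth | None = None) -> float:
    """Closed-form expected recall of planted tumor-centric variants.

    A tumor-centric variant survives the cascade iff >= 1 of its tumor
    carrier calls and >= 1 of its plasma carrier calls are emitted and pass
    the QUAL filter. With per-call miss probability
    e = 1 - (1 - delta) * (1 - frac_qual_below), survival for carrier counts
    (k_t, k_p) is (1 - e_t**k_t) * (1 - e_p**k_p). With ``truth`` the
    realized carrier counts are used; otherwise the expectation integrates
    over the design's carrier-count distribution.
    """
    probs = tumor_centric_survival_probs(design, truth)
    return float(np.mean(probs)) if len(probs) else 1.0


def tumor_centric_survival_probs(
    design: SimDesign, truth: GroundTruth | None = None
) -> np.ndarray:
    """Per-variant survival probabilities (see :func:`expected_recall`)."""
    e_t = 1.0 - (1.0 - design.delta("HCC", "tumor")) * (1.0 - design.frac_qual_below)
    e_p = 1.0 - (1.0 - design.delta("HCC", "plasma")) * (1.0 - design.frac_qual_below)
    if truth is not None:
        return np.array(
            [
                (1.0 - e_t**kt) * (1.0 - e_p**kp)
                for kt, kp in (truth.tc_carrier_counts[k] for k in truth.tumor_centric)
            ]
        )
    pmf_t = _carrier_count_pmf(design.tumor_freq_range, design.n_hcc_tumor)
    pmf_p = _carrier_count_pmf(design.plasma_freq_range, design.n_hcc_plasma)
    s_t = sum(w * (1.0 - e_t**k) for k, w in pmf_t.items())
    s_p = sum(w * (1.0 - e_p**k) for k, w in pmf_p.items())
    return np.full(max(design.n_tumor_centric, 1), s_t * s_p)
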