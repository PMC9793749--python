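"""VCF ingestion: variant identity, SnpEff ANN parsing and true-positive filters.

Variant identity is the normalized (chrom, pos, ref, alt) key: multi-allelic
records are split, shared suffix/prefix bases are trimmed (parsimony; no
reference genome required) so identity comparisons across samples are
well-defined. Calls are filtered by the study's true-positive definition —
read depth >= 5 and QUAL >= 20, both inclusive — where QUAL is -log10 of the
call p-value (a QUAL of 20 corresponds to p = 1e-20).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {imp: i for i, imp in enumerate(IMPACTS)}  # lower rank = more severe

#: number of pipe-delimited sub-fields in a standard SnpEff ANN entry
_ANN_FIELDS = 16

_ALLOWED_BASES = frozenset("ACGTN")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be read or a record is malformed."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity of a variant (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLOWED_BASES:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} not [ACGTN]+"
                )

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a key with parsimony trimming applied.

        Shared trailing bases are removed first, then shared leading bases
        (advancing ``pos``), always leaving at least one base on each allele.
        """
        ref = ref.upper()
        alt = alt.upper()
        # trim common suffix
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        # trim common prefix, advancing pos
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return cls(chrom=chrom, pos=pos, ref=ref, alt=alt)


@dataclass(frozen=True)
class Annotation:
    """One SnpEff transcript-level annotation of a variant."""

    effect_terms: tuple[str, ...]
    impact: str
    gene: str
    transcript: str

    @property
    def functional_class(self) -> str:
        return functional_class_of(self.effect_terms)

    @property
    def region(self) -> str:
        return region_of(self.effect_terms)


@dataclass
class VariantCall:
    """One sample's observation of a variant with depth, QUAL and annotations."""

    key: VariantKey
    sample_id: str
    depth: int
    qual: float
    annotations: tuple[Annotation, ...] = ()
    passed: bool | None = None

    @property
    def max_impact(self) -> str:
        return max_impact(self.annotations)


@dataclass(frozen=True)
class FilterConfig:
    """True-positive call thresholds and the impact class kept downstream."""

    depth_min: int = 5
    qual_min: float = 20.0
    impact_keep: frozenset[str] = frozenset({"HIGH"})
    min_frequency: float = 0.0  # optional stricter stratum-frequency gate

    def __post_init__(self) -> None:
        if self.depth_min < 0 or self.qual_min < 0:
            raise ValueError("thresholds must be non-negative")
        unknown = set(self.impact_keep) - set(IMPACTS)
        if unknown:
            raise ValueError(f"unknown impact classes {sorted(unknown)}")


# -- QUAL convention -------------------------------------------------------

def qual_from_p(p: float) -> float:
    """QUAL = -log10(p); a QUAL of 20 corresponds to p = 1e-20."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -math.log10(p)


def p_from_qual(qual: float) -> float:
    """Inverse of :func:`qual_from_p`: p = 10**(-qual)."""
    if qual < 0:
        raise ValueError(f"qual must be non-negative, got {qual}")
    return 10.0 ** (-qual)


# -- classification --------------------------------------------------------

def classify_variant_type(key: VariantKey) -> str:
    """SNP / insertion / deletion / MNP classification of a normalized key."""
    if len(key.ref) == 1 and len(key.alt) == 1:
        return "SNP"
    if len(key.alt) > len(key.ref):
        return "insertion"
    if len(key.alt) < len(key.ref):
        return "deletion"
    return "MNP"


def max_impact(annotations: Sequence[Annotation]) -> str:
    """Most severe impact across annotations (HIGH > MODERATE > LOW > MODIFIER).

    A variant's impact for filtering is variant-level, not transcript-level:
    SnpEff emits one annotation per transcript and the analysis filters
    variants. Returns MODIFIER for an empty annotation list.
    """
    if not annotations:
        return "MODIFIER"
    return min((a.impact for a in annotations), key=_IMPACT_RANK.__getitem__)


def functional_class_of(effect_terms: Sequence[str]) -> str:
    """missense / synonymous / nonsense (stop gained) / none."""
    terms = set(effect_terms)
    if "stop_gained" in terms:
        return "nonsense"
    if "missense_variant" in terms:
        return "missense"
    if "synonymous_variant" in terms:
        return "synonymous"
    return "none"


#: coding effect terms binned as exonic for the region axis
_EXON_TERMS = {
    "missense_variant",
    "synonymous_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "inframe_insertion",
    "inframe_deletion",
    "disruptive_inframe_insertion",
    "disruptive_inframe_deletion",
    "exon_variant",
    "coding_sequence_variant",
    "stop_retained_variant",
    "initiator_codon_variant",
}


def region_of(effect_terms: Sequence[str]) -> str:
    """Map SnpEff effect terms to one of seven genomic-region bins.

    Priority: splicing > exon > intron > upstream > downstream > intergenic >
    genic_other, mirroring severity of the annotated location.
    """
    terms = set(effect_terms)
    if any("splice" in t for t in terms):
        return "splicing"
    if terms & _EXON_TERMS:
        return "exon"
    if "intron_variant" in terms:
        return "intron"
    if "upstream_gene_variant" in terms:
        return "upstream"
    if "downstream_gene_variant" in terms:
        return "downstream"
    if "intergenic_region" in terms or "intergenic_variant" in terms:
        return "intergenic"
    return "genic_other"


# -- parsing ----------------------------------------------------------------

def parse_ann_field(ann: str, n_alts: int = 1) -> dict[str, list[Annotation]]:
    """Parse a SnpEff ANN INFO value into per-allele annotation lists.

    Entries with a grossly short sub-field list are skipped with a warning;
    the call itself is retained.
    """
    out: dict[str, list[Annotation]] = {}
    for entry in ann.split(","):
        fields = entry.split("|")
        if len(fields) < 4:
            warnings.warn(f"ANN entry with {len(fields)} sub-fields skipped: {entry!r}")
            continue
        allele = fields[0].upper()
        effect_terms = tuple(t for t in fields[1].split("&") if t)
        impact = fields[2].upper()
        if impact not in IMPACTS:
            warnings.warn(f"ANN entry with unknown impact {impact!r} skipped")
            continue
        gene = fields[3]
        transcript = fields[6] if len(fields) > 6 else ""
        out.setdefault(allele, []).append(
            Annotation(effect_terms=effect_terms, impact=impact, gene=gene, transcript=transcript)
        )
    return out


def _record_depth(variant) -> int:
    """DP from INFO if present, else summed FORMAT AD (caller-dialect tolerance)."""
    dp = variant.INFO.get("DP")
    if dp is not None:
        return int(dp)
    try:
        ad = variant.format("AD")
    except Exception:
        ad = None
    if ad is not None:
        return int(ad.clip(min=0).sum())
    return 0


def read_sample_vcf(path: str | Path, sample_id: str) -> list[VariantCall]:
    """Read a (possibly SnpEff-annotated) VCF into one VariantCall per alt allele.

    Multi-allelic records are split; keys are parsimony-normalized; records
    without an ANN field carry an empty annotation tuple. Filters are NOT
    applied here (see :func:`apply_call_filters`).
    """
    path = Path(path)
    if not path.exists():
        raise VcfParseError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on garbled input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    calls: list[VariantCall] = []
    lineno = 0
    try:
        for variant in vcf:
            lineno += 1
            ann_raw = variant.INFO.get("ANN")
            per_allele = parse_ann_field(str(ann_raw)) if ann_raw else {}
            depth = _record_depth(variant)
            qual = float(variant.QUAL) if variant.QUAL is not None else 0.0
            for alt in variant.ALT:
                if alt is None or alt.startswith("<"):
                    continue  # symbolic alleles carry no sequence identity
                key = VariantKey.normalized(variant.CHROM, variant.POS, variant.REF, alt)
                anns = tuple(per_allele.get(alt.upper(), ()))
                calls.append(
                    VariantCall(
                        key=key,
                        sample_id=sample_id,
                        depth=depth,
                        qual=qual,
                        annotations=anns,
                    )
                )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path} near record {lineno + 1}: {exc}") from exc
    finally:
        vcf.close()
    return calls


def apply_call_filters(calls: Iterable[VariantCall], cfg: FilterConfig | None = None) -> list[VariantCall]:
    """Set the ``passed`` flag per the inclusive true-positive thresholds.

    A call passes iff depth >= depth_min AND qual >= qual_min. Idempotent and
    monotone: raising either threshold never adds a passing call.
    """
    cfg = cfg or FilterConfig()
    return [
        replace(c, passed=(c.depth >= cfg.depth_min and c.qual >= cfg.qual_min))
        for c in calls
    ]


def write_call_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Per-sample filtered call table (TSV; coordinates are 1-based)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based (VCF convention); QUAL = -log10(p)\n")
        fh.write("chrom\tpos\tref\talt\tdepth\tqual\tmax_impact\tgene\teffect\tpassed\n")
        for c in calls:
            genes = ";".join(sorted({a.gene for a in c.annotations if a.gene}))
            effects = ";".join(sorted({t for a in c.annotations for t in a.effect_terms}))
            fh.write(
                f"{c.key.chrom}\t{c.key.pos}\t{c.key.ref}\t{c.key.alt}\t"
                f"{c.depth}\t{c.qual:g}\t{c.max_impact}\t{genes}\t{effects}\t"
                f"{bool(c.passed)}\n"
            )
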