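import pytest

from ctvar.cohort import CohortDesign, SampleMeta
from ctvar.concordance import build_presence, group_presence
from ctvar.simulate import SimDesign, simulate_calls
from ctvar.vcf_io import Annotation, FilterConfig, VariantCall, VariantKey, apply_call_filters


def make_call(
    sample_id: str,
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
    depth: int = 30,
    qual: float = 50.0,
    impact: str = "HIGH",
    gene: str = "GENE1",
    effects: tuple[str, ...] = ("splice_donor_variant",),
) -> VariantCall:
    return VariantCall(
        key=VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt),
        sample_id=sample_id,
        depth=depth,
        qual=qual,
        annotations=(
            Annotation(effect_terms=effects, impact=impact, gene=gene, transcript=f"{gene}.t1"),
        ),
    )


def tiny_cohort(vcf_dir: str = ".") -> CohortDesign:
    """Minimal cohort exercising every stratum the cascade needs."""
    rows = [
        ("HP1", "H1", "HCC", "plasma"),
        ("HP2", "H2", "HCC", "plasma"),
        ("HT1", "H1", "HCC", "tumor"),
        ("HT2", "H2", "HCC", "tumor"),
        ("HE1", "H1", "HCC", "EV"),
        ("LP1", "L1", "LC", "plasma"),
        ("NP1", "N1", "NHC", "plasma"),
        ("NL1", "NL1", "NHC", "normal_liver"),
    ]
    return CohortDesign(
        samples=[
            SampleMeta(sample_id=s, subject_id=subj, group=g, specimen=sp, vcf_path=f"{vcf_dir}/{s}.vcf")
            for s, subj, g, sp in rows
        ]
    )


@pytest.fixture(scope="session")
def default_design():
    return SimDesign(seed=7)


@pytest.fixture(scope="session")
def sim(default_design):
    """One study-layout noise-free simulated cohort, filtered, with matrix."""
    calls, cohort, truth = simulate_calls(default_design)
    fcfg = FilterConfig()
    calls = {s: apply_call_filters(c, fcfg) for s, c in calls.items()}
    matrix = build_presence(calls, cohort, fcfg)
    gp = group_presence(matrix, cohort)
    return {
        "design": default_design,
        "calls": calls,
        "cohort": cohort,
        "truth": truth,
        "matrix": matrix,
        "gp": gp,
    }
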