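"""Run orchestration: ingest -> filter -> presence -> concordance -> selection.

Produces a machine-readable summary JSON with the count at every filtration
step, per-set TSV tables, and deterministic heat-map sample ordering
(hierarchical clustering of binary occurrence profiles, Jaccard distance,
average linkage). Every output carries the hash of the fully-serialized run
configuration, so two runs with equal config hashes are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .cohort import CohortDesign, load_cohort
from .concordance import (
    ConcordanceReport,
    PresenceMatrix,
    build_presence,
    derive_concordance_report,
    sorted_variants,
)
from .gene_load import LIVER_PANEL, GenePanel, gene_loads, top_genes_by_concordant_load
from .profiles import AXES, profile_samples
from .stats import select_variants
from .vcf_io import FilterConfig, apply_call_filters, read_sample_vcf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; serialized into the output for provenance."""

    cohort_path: str
    out_dir: str
    depth_min: int = 5
    qual_min: float = 20.0
    impact_keep: tuple[str, ...] = ("HIGH",)
    min_frequency: float = 0.0
    q_threshold: float = 0.05
    selection_controls: tuple[str, ...] = ("LC", "NHC")
    panel_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            depth_min=self.depth_min,
            qual_min=self.qual_min,
            impact_keep=frozenset(self.impact_keep),
            min_frequency=self.min_frequency,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cluster_order(matrix: PresenceMatrix) -> tuple[list[str], list]:
    """Deterministic heat-map ordering of a presence-matrix subset.

    Samples are clustered hierarchically on their binary variant profiles
    (Jaccard distance, average linkage); ties are broken by sample_id via a
    canonical pre-sort, so permuting the input column order does not change
    the leaf order. Variants are ordered genomically. A single sample (or
    none) maps to the identity order.
    """
    order = sorted(range(len(matrix.samples)), key=lambda j: matrix.samples[j])
    samples = [matrix.samples[j] for j in order]
    variant_order = sorted_variants(matrix.variants)
    if len(samples) < 2 or len(matrix.variants) == 0:
        return samples, variant_order
    profiles = matrix.data[:, order].T.astype(bool)
    dist = pdist(profiles, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # all-empty profile pairs: distance 0
    linkage = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(linkage)
    return [samples[i] for i in leaves], variant_order


def _write_set_table(
    path: Path,
    keys,
    matrix: PresenceMatrix,
    report: ConcordanceReport,
    audit: dict | None,
    cfg_hash: str,
) -> None:
    gp = report.group_presence
    strata = sorted(gp.stratum_sizes)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}; coordinates 1-based\n")
        cols = ["chrom", "pos", "ref", "alt", "gene", "effect", "impact"]
        cols += [f"freq_{g}_{sp}" for g, sp in strata] + ["audit"]
        fh.write("\t".join(cols) + "\n")
        for k in keys:
            row = [
                k.chrom,
                str(k.pos),
                k.ref,
                k.alt,
                ";".join(sorted(matrix.genes.get(k, ()))),
                ";".join(sorted(matrix.effects.get(k, ()))),
                matrix.impact.get(k, ""),
            ]
            row += [f"{gp.freq(k, st):.4f}" for st in strata]
            row.append(";".join(audit.get(k, [])) if audit else "")
            fh.write("\t".join(row) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the output bundle.

    Returns the summary dict (also written as ``summary.json``). Any stage
    failure aborts with the stage name in the raised error's message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "run_config.json").write_text(
        json.dumps({"config_hash": cfg_hash, **asdict(config)}, indent=2, sort_keys=True)
    )
    stage = "load_cohort"
    try:
        cohort = load_cohort(config.cohort_path)
        (out / "cohort.json").write_text(cohort.to_json())

        stage = "ingest"
        fcfg = config.filter_config()
        calls_by_sample = {}
        n_calls_raw = 0
        n_calls_passed = 0
        for s in cohort.samples:
            calls = read_sample_vcf(s.vcf_path, s.sample_id)
            calls = apply_call_filters(calls, fcfg)
            n_calls_raw += len(calls)
            n_calls_passed += sum(c.passed for c in calls)
            calls_by_sample[s.sample_id] = calls

        stage = "presence"
        matrix = build_presence(calls_by_sample, cohort, fcfg)

        stage = "profiles"
        for axis in AXES:
            prof = profile_samples(calls_by_sample, cohort, axis)
            prof.to_csv(out / f"profile_{axis}.tsv", sep="\t", index=False)

        stage = "concordance"
        report = derive_concordance_report(
            matrix, cohort, min_frequency=config.min_frequency
        )
        _write_set_table(
            out / "tumor_centric.tsv",
            report.tumor_centric.included,
            matrix,
            report,
            None,
            cfg_hash,
        )
        _write_set_table(
            out / "tumor_centric_excluded.tsv",
            sorted_variants(report.tumor_centric.excluded),
            matrix,
            report,
            report.tumor_centric.excluded,
            cfg_hash,
        )
        for name, keys in report.named_sets().items():
            if name != "tumor_centric":
                _write_set_table(out / f"{name}.tsv", keys, matrix, report, None, cfg_hash)

        stage = "venn"
        venn_json = {
            "per_subject": [
                {
                    "subject": sv.subject_id,
                    "specimens": sv.specimens,
                    "regions": {
                        "&".join(sorted(r)): len(v) for r, v in sv.regions.items()
                    },
                }
                for sv in report.subject_venns
            ]
        }
        (out / "venn_regions.json").write_text(
            json.dumps(venn_json, indent=2, sort_keys=True)
        )

        stage = "gene_load"
        panel = (
            GenePanel.from_file(config.panel_path) if config.panel_path else LIVER_PANEL
        )
        loads = gene_loads(matrix, cohort, panel)
        loads.to_csv(out / "gene_loads_panel.tsv", sep="\t", index=False)
        top, heat = top_genes_by_concordant_load(
            report.triple_concordant or report.tumor_centric.included, matrix, n=50
        )
        heat.to_csv(out / "top_gene_counts.tsv", sep="\t")

        stage = "selection"
        selection = select_variants(
            matrix,
            cohort,
            report.tumor_centric.included,
            case="HCC",
            controls=config.selection_controls,
            q_threshold=config.q_threshold,
        ) if report.tumor_centric.included else None
        if selection is not None:
            selection.to_csv(out / "selection.tsv", sep="\t", index=False)
            n_selected = int(selection["selected"].sum())
        else:
            (out / "selection.tsv").write_text(
                "chrom\tpos\tref\talt\ta\tb\tc\td\tp\tq\tselected\n"
            )
            n_selected = 0

        stage = "heatmap_order"
        sample_order, _ = cluster_order(matrix)

        stage = "summary"
        gp = report.group_presence
        step_counts = {
            "01_raw_calls": n_calls_raw,
            "02_passed_calls": int(n_calls_passed),
            "03_high_risk_variants": len(matrix.variants),
            "04_hcc_tumor_present": len(gp.stratum_set(("HCC", "tumor")))
            if ("HCC", "tumor") in gp.stratum_sizes
            else 0,
            "05_tumor_plasma_concordant": len(report.tumor_centric.candidates),
            "06_tumor_centric": len(report.tumor_centric.included),
            "07_selected": n_selected,
        }
        summary = {
            "config_hash": cfg_hash,
            "n_samples": len(cohort),
            "strata": {f"{g}/{sp}": n for (g, sp), n in sorted(gp.stratum_sizes.items())},
            "step_counts": step_counts,
            "sets": {name: len(keys) for name, keys in report.named_sets().items()},
            "cca_containment": report.cca_concordant.containment
            if report.cca_concordant
            else None,
            "top_genes": top[:10],
            "heatmap_sample_order": sample_order,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
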