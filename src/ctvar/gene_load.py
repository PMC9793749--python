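"""Per-gene variant-load accounting.

Counts unique high-risk variants per gene per (group, specimen) stratum,
summarizes load on a liver-specific transcript panel, and ranks genes by the
number of concordant variants they carry (the top-gene heat-map input).
A variant annotated to multiple genes contributes to each gene's load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDesign
from .concordance import PresenceMatrix, variant_sort_key
from .vcf_io import VariantKey

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene panel has duplicate symbols")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GenePanel":
        """One gene symbol per line; blank lines and '#' comments ignored."""
        genes = []
        for line in Path(path).read_text().splitlines():
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.append(sym)
        return cls(name=name or Path(path).stem, genes=tuple(genes))


#: liver-derived transcripts reported to carry a large variant load in HCC
LIVER_PANEL = GenePanel(
    name="liver_specific",
    genes=("FGL1", "CYP2E1", "SERPINA1", "ALB", "TF", "SYCE1"),
)


def gene_loads(
    matrix: PresenceMatrix,
    cohort: CohortDesign,
    panel: GenePanel | None = None,
) -> pd.DataFrame:
    """Per (gene, group, specimen): unique-variant count, per-sample mean and sd.

    ``unique_count`` counts distinct variant keys annotated to the gene with
    presence in >= 1 sample of the stratum — call occurrences are not summed.
    Panel genes absent from the data get zero rows. With ``panel=None`` all
    genes carrying any matrix variant are reported.
    """
    gene_variants: dict[str, list[int]] = {}
    for i, key in enumerate(matrix.variants):
        for gene in matrix.genes.get(key, ()):
            gene_variants.setdefault(gene, []).append(i)
    genes = list(panel.genes) if panel else sorted(gene_variants)

    rows = []
    for group, specimen in cohort.strata():
        sample_ids = cohort.stratum_samples(group, specimen)
        cols = [matrix._sidx[s] for s in sample_ids]
        for gene in genes:
            vidx = gene_variants.get(gene, [])
            if vidx:
                sub = matrix.data[np.ix_(vidx, cols)]
                unique = int(sub.any(axis=1).sum())
                per_sample = sub.sum(axis=0)
            else:
                unique = 0
                per_sample = np.zeros(len(cols))
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "specimen": specimen,
                    "unique_count": unique,
                    "mean_per_sample": float(per_sample.mean()) if len(cols) else 0.0,
                    "sd_per_sample": float(per_sample.std(ddof=1)) if len(cols) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def top_genes_by_concordant_load(
    concordant: Iterable[VariantKey],
    matrix: PresenceMatrix,
    n: int = 50,
) -> tuple[list[str], pd.DataFrame]:
    """Rank genes by their number of concordant variants; ties alphabetical.

    Returns the ranked gene list (length <= n) and a gene x sample matrix of
    per-sample concordant-variant counts for heat-map plotting.
    """
    concordant = sorted(set(concordant), key=variant_sort_key)
    gene_keys: dict[str, list[VariantKey]] = {}
    for key in concordant:
        for gene in matrix.genes.get(key, ()):
            gene_keys.setdefault(gene, []).append(key)
    ranked = sorted(gene_keys, key=lambda g: (-len(gene_keys[g]), g))
    if n > len(ranked):
        log.info("requested top %d genes but only %d available", n, len(ranked))
    top = ranked[: max(n, 0)]
    counts = np.zeros((len(top), len(matrix.samples)), dtype=int)
    for gi, gene in enumerate(top):
        for key in gene_keys[gene]:
            counts[gi] += matrix.data[matrix._vidx[key]].astype(int)
    heat = pd.DataFrame(counts, index=top, columns=matrix.samples)
    return top, heat
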