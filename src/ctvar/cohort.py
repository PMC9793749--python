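"""Cohort data model: sample metadata, clinical groups and specimen types.

Every group-level computation downstream (once-only counting, the exclusion
cascade, per-subject Venn decompositions) is driven by the sample -> (subject,
group, specimen) mapping defined here. Groups are the clinical cohorts of a
liver-cancer liquid-biopsy study: HCC (hepatocellular carcinoma), LC (liver
cirrhosis without HCC), NHC (normal healthy control) and CCA
(cholangiocarcinoma). Specimens are plasma, tumor tissue, plasma-derived
extracellular vesicles (EV) and a single normal liver tissue carried under
the NHC group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

GROUPS = ("HCC", "LC", "NHC", "CCA")
SPECIMENS = ("plasma", "tumor", "EV", "normal_liver")

#: specimen spellings accepted case-insensitively in metadata sheets
_SPECIMEN_ALIASES = {
    "plasma": "plasma",
    "tumor": "tumor",
    "tumour": "tumor",
    "ev": "EV",
    "evs": "EV",
    "vesicle": "EV",
    "microvesicle": "EV",
    "normal_liver": "normal_liver",
    "normal-liver": "normal_liver",
    "liver": "normal_liver",
}

REQUIRED_COLUMNS = ("sample_id", "subject_id", "group", "specimen", "vcf_path")


class CohortError(ValueError):
    """Raised when cohort metadata violates the cohort invariants."""


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: a (subject, specimen) observation with its VCF."""

    sample_id: str
    subject_id: str
    group: str
    specimen: str
    vcf_path: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group {self.group!r} for sample {self.sample_id!r}")
        if self.specimen not in SPECIMENS:
            raise CohortError(
                f"unknown specimen {self.specimen!r} for sample {self.sample_id!r}"
            )


@dataclass
class CohortDesign:
    """A validated collection of samples; the unit of all group-level logic."""

    samples: list[SampleMeta]
    notes: str = ""
    _by_id: dict[str, SampleMeta] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._by_id = {s.sample_id: s for s in self.samples}

    def validate(self) -> None:
        seen_ids: set[str] = set()
        seen_pairs: set[tuple[str, str]] = set()
        subject_group: dict[str, str] = {}
        for s in self.samples:
            if s.sample_id in seen_ids:
                raise CohortError(f"duplicate sample_id {s.sample_id!r}")
            seen_ids.add(s.sample_id)
            pair = (s.subject_id, s.specimen)
            if pair in seen_pairs:
                raise CohortError(
                    f"duplicate (subject_id, specimen) pair {pair!r} at sample {s.sample_id!r}"
                )
            seen_pairs.add(pair)
            if s.group in ("NHC", "LC") and s.specimen not in ("plasma", "normal_liver"):
                raise CohortError(
                    f"sample {s.sample_id!r}: group {s.group} admits only plasma"
                    " (or the single NHC normal_liver tissue)"
                )
            if s.specimen == "normal_liver" and s.group != "NHC":
                raise CohortError(
                    f"sample {s.sample_id!r}: normal_liver tissue must carry group NHC"
                )
            prev = subject_group.setdefault(s.subject_id, s.group)
            if prev != s.group:
                raise CohortError(
                    f"subject {s.subject_id!r} appears in groups {prev} and {s.group}"
                )

    # -- lookups ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.samples)

    def sample(self, sample_id: str) -> SampleMeta:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def stratum_samples(self, group: str, specimen: str) -> list[str]:
        """Sample ids of one (group, specimen) stratum, in cohort order."""
        return [s.sample_id for s in self.samples if s.group == group and s.specimen == specimen]

    def strata(self) -> list[tuple[str, str]]:
        """All non-empty (group, specimen) strata, deterministic order."""
        present = {(s.group, s.specimen) for s in self.samples}
        return [
            (g, sp) for g in GROUPS for sp in SPECIMENS if (g, sp) in present
        ]

    def subjects(self, group: str | None = None) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if group is not None and s.group != group:
                continue
            if s.subject_id not in seen:
                seen.append(s.subject_id)
        return sorted(seen)

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "specimen": s.specimen,
                    "vcf_path": s.vcf_path,
                }
                for s in self.samples
            ],
            columns=list(REQUIRED_COLUMNS),
        )

    def to_table(self, path: str | Path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.to_frame().to_csv(path, sep=sep, index=False)

    def to_json(self) -> str:
        """Normalized cohort JSON for provenance logging."""
        return json.dumps(
            {
                "notes": self.notes,
                "samples": self.to_frame().to_dict(orient="records"),
            },
            indent=2,
            sort_keys=True,
        )


def _canon_group(token: str, row: int) -> str:
    g = token.strip().upper()
    if g not in GROUPS:
        raise CohortError(f"row {row}: unknown group token {token!r} (expected one of {GROUPS})")
    return g


def _canon_specimen(token: str, row: int) -> str:
    sp = _SPECIMEN_ALIASES.get(token.strip().lower())
    if sp is None:
        raise CohortError(
            f"row {row}: unknown specimen token {token!r} (expected one of {SPECIMENS})"
        )
    return sp


def load_cohort(metadata_table: str | Path, notes: str = "") -> CohortDesign:
    """Read and validate a cohort metadata sheet (TSV or CSV with header).

    Required columns: sample_id, subject_id, group, specimen, vcf_path.
    Group and specimen tokens are canonicalized case-insensitively.
    """
    path = Path(metadata_table)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"metadata table {path} lacks required columns: {missing}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if not row.vcf_path.strip():
            raise CohortError(f"row {i} (sample {row.sample_id!r}): missing VCF path")
        samples.append(
            SampleMeta(
                sample_id=row.sample_id.strip(),
                subject_id=row.subject_id.strip(),
                group=_canon_group(row.group, i),
                specimen=_canon_specimen(row.specimen, i),
                vcf_path=row.vcf_path.strip(),
            )
        )
    return CohortDesign(samples=samples, notes=notes)


def matched_sets(cohort: CohortDesign, group: str) -> list[tuple[str, frozenset[str]]]:
    """Per subject in ``group``, which of {plasma, tumor, EV} that subject has.

    One entry per subject, ordered by subject_id. The normal_liver specimen is
    not a matched-set member (it is a tissue control, not a liquid-biopsy
    analyte).
    """
    by_subject: dict[str, set[str]] = {}
    for s in cohort.samples:
        if s.group != group:
            continue
        by_subject.setdefault(s.subject_id, set())
        if s.specimen in ("plasma", "tumor", "EV"):
            by_subject[s.subject_id].add(s.specimen)
    return [(sid, frozenset(sp)) for sid, sp in sorted(by_subject.items())]
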