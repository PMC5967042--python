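"""Input readers: variant annotation table, sample panel, and VCF genotypes.

Genotypes are oriented as counts of the effect (trait-lowering) allele,
regardless of whether that allele is REF or ALT in the VCF. Matching is by
chromosome + position; rsIDs are used for labelling only, since VCF ID
columns are unreliable. Alleles are compared literally — no strand flipping
or palindromic-SNP resolution is attempted; mismatches are excluded and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import AnalysisError, FormatError, ValidationError

logger = logging.getLogger(__name__)

ALLELE_STATES = ("ancestral", "derived")
SEXES = ("male", "female", "unknown")

_ANNOTATION_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "allele_state",
    "cadd_phred",
)


@dataclass(frozen=True)
class VariantAnnotation:
    """One trait-associated SNP with its scoring metadata.

    ``beta`` is the magnitude of the per-allele lowering effect and must be
    positive; ``allele_state`` classifies the effect allele as ancestral or
    derived; ``cadd_phred`` is a non-negative deleteriousness score.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    allele_state: str
    cadd_phred: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValidationError(
                f"variant {self.rsid}: beta must be > 0, got {self.beta}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"variant {self.rsid}: effect and other allele are identical"
            )
        if self.allele_state not in ALLELE_STATES:
            raise ValidationError(
                f"variant {self.rsid}: allele_state must be one of "
                f"{ALLELE_STATES}, got {self.allele_state!r}"
            )
        if self.cadd_phred < 0:
            raise ValidationError(
                f"variant {self.rsid}: cadd_phred must be >= 0, got {self.cadd_phred}"
            )

    def flipped(self) -> "VariantAnnotation":
        """Annotation with effect/other alleles swapped (state label follows)."""
        state = "derived" if self.allele_state == "ancestral" else "ancestral"
        return VariantAnnotation(
            rsid=self.rsid,
            chrom=self.chrom,
            pos=self.pos,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=self.beta,
            allele_state=state,
            cadd_phred=self.cadd_phred,
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    population: str
    super_population: str
    sex: str = "unknown"


class SamplePanel:
    """Mapping of sample -> population -> super-population (+ sex).

    Enforces unique sample ids and a many-to-one population to
    super-population mapping.
    """

    def __init__(self, records: Iterable[SampleRecord]):
        self.records: list[SampleRecord] = list(records)
        seen: dict[str, SampleRecord] = {}
        pop_to_super: dict[str, str] = {}
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {rec.sample_id!r} in panel")
            if rec.sex not in SEXES:
                raise ValidationError(
                    f"sample {rec.sample_id}: sex must be one of {SEXES}"
                )
            prev = pop_to_super.setdefault(rec.population, rec.super_population)
            if prev != rec.super_population:
                raise ValidationError(
                    f"population {rec.population!r} mapped to two super-populations "
                    f"({prev!r} and {rec.super_population!r})"
                )
            seen[rec.sample_id] = rec
        self._by_id = seen
        self.pop_to_super = pop_to_super

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def populations(self) -> list[str]:
        return sorted({r.population for r in self.records})

    @property
    def super_populations(self) -> list[str]:
        return sorted({r.super_population for r in self.records})

    def group_of(self, sample_id: str, grouping: str) -> str:
        rec = self._by_id[sample_id]
        if grouping == "population":
            return rec.population
        if grouping == "super_population":
            return rec.super_population
        if grouping == "sex":
            return rec.sex
        raise ValueError(f"unknown grouping {grouping!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [r.sample_id for r in self.records],
                "pop": [r.population for r in self.records],
                "super_pop": [r.super_population for r in self.records],
                "gender": [r.sex for r in self.records],
            }
        )


@dataclass
class ExtractionReport:
    """Bookkeeping from `extract_dosages`: what was dropped and why."""

    missing_variants: list[str] = field(default_factory=list)
    allele_mismatch: list[str] = field(default_factory=list)
    samples_not_in_vcf: list[str] = field(default_factory=list)
    samples_not_in_panel: list[str] = field(default_factory=list)


@dataclass
class DosageMatrix:
    """Samples x variants counts of the effect allele.

    ``dosages`` is a float array with entries in {0, 1, 2} or NaN for
    missing genotypes.
    """

    samples: list[str]
    variants: list[str]
    dosages: np.ndarray
    report: ExtractionReport | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValidationError("non-missing dosages must be in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, rsids: Sequence[str]) -> "DosageMatrix":
        index = {v: i for i, v in enumerate(self.variants)}
        missing = [r for r in rsids if r not in index]
        if missing:
            raise AnalysisError(f"variants not in dosage matrix: {missing}")
        cols = [index[r] for r in rsids]
        return DosageMatrix(self.samples, list(rsids), self.dosages[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.variants)


def read_annotation_table(path) -> list[VariantAnnotation]:
    """Read a tab-separated variant annotation table.

    Required columns: rsid, chrom, pos, effect_allele, other_allele, beta,
    allele_state, cadd_phred. Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"annotation table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    annotations: list[VariantAnnotation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rsid = str(row.rsid).strip()
        if rsid in seen:
            raise ValidationError(f"duplicate rsid {rsid!r} at line {i} of {path}")
        seen.add(rsid)
        try:
            ann = VariantAnnotation(
                rsid=rsid,
                chrom=str(row.chrom).strip(),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele).strip().upper(),
                other_allele=str(row.other_allele).strip().upper(),
                beta=float(row.beta),
                allele_state=str(row.allele_state).strip().lower(),
                cadd_phred=float(row.cadd_phred),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"line {i} of {path}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"line {i} of {path}: {exc}") from exc
        annotations.append(ann)
    return annotations


def write_annotation_table(annotations: Sequence[VariantAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "rsid": [a.rsid for a in annotations],
            "chrom": [a.chrom for a in annotations],
            "pos": [a.pos for a in annotations],
            "effect_allele": [a.effect_allele for a in annotations],
            "other_allele": [a.other_allele for a in annotations],
            "beta": [a.beta for a in annotations],
            "allele_state": [a.allele_state for a in annotations],
            "cadd_phred": [a.cadd_phred for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


_SEX_ALIASES = {
    "male": "male",
    "m": "male",
    "1": "male",
    "female": "female",
    "f": "female",
    "2": "female",
}


def read_sample_panel(path) -> SamplePanel:
    """Read a whitespace- or tab-delimited sample panel.

    Expects columns sample, pop, super_pop and optionally gender (the 1000
    Genomes integrated_call_samples dialect). A missing gender column yields
    sex = "unknown" for every sample.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    required = ["sample", "pop", "super_pop"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"sample panel {path} is missing required column(s): " + ", ".join(missing)
        )
    has_gender = "gender" in df.columns
    records = []
    for row in df.itertuples(index=False):
        sex = "unknown"
        if has_gender and isinstance(row.gender, str):
            sex = _SEX_ALIASES.get(row.gender.strip().lower(), "unknown")
        records.append(
            SampleRecord(
                sample_id=str(row.sample).strip(),
                population=str(row.pop).strip(),
                super_population=str(row.super_pop).strip(),
                sex=sex,
            )
        )
    return SamplePanel(records)


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def extract_dosages(
    vcf_path, annotations: Sequence[VariantAnnotation], panel: SamplePanel
) -> DosageMatrix:
    """Extract effect-allele dosages for annotated variants from a VCF.

    Variants are located by chrom+pos and allele-checked: a record is usable
    iff its REF together with one of its ALTs equals the annotation's
    {effect, other} allele pair (multi-allelic records are decomposed per
    ALT). Unusable or absent variants are excluded and logged; samples are
    restricted to the intersection of the panel and the VCF header. Missing
    genotypes are stored as NaN.
    """
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    panel_ids = set(panel.sample_ids)
    report = ExtractionReport()
    report.samples_not_in_vcf = [s for s in panel.sample_ids if s not in set(vcf_samples)]
    report.samples_not_in_panel = [s for s in vcf_samples if s not in panel_ids]
    if report.samples_not_in_vcf:
        logger.warning(
            "%d panel sample(s) absent from VCF: %s ...",
            len(report.samples_not_in_vcf),
            report.samples_not_in_vcf[:5],
        )
    if report.samples_not_in_panel:
        logger.warning(
            "%d VCF sample(s) absent from panel: %s ...",
            len(report.samples_not_in_panel),
            report.samples_not_in_panel[:5],
        )
    keep_idx = [i for i, s in enumerate(vcf_samples) if s in panel_ids]
    if not keep_idx:
        raise AnalysisError("no overlap between VCF samples and panel samples")
    kept_samples = [vcf_samples[i] for i in keep_idx]

    targets: dict[tuple[str, int], VariantAnnotation] = {}
    for ann in annotations:
        targets[(_norm_chrom(ann.chrom), ann.pos)] = ann

    found: dict[str, np.ndarray] = {}
    mismatched: set[str] = set()
    for rec in vcf:
        key = (_norm_chrom(rec.CHROM), rec.POS)
        ann = targets.get(key)
        if ann is None or ann.rsid in found:
            continue
        pair = {ann.effect_allele, ann.other_allele}
        alleles = [rec.REF] + list(rec.ALT)
        # usable iff REF plus one ALT matches the annotation allele pair
        usable = rec.REF in pair and any(alt in pair for alt in rec.ALT)
        if not usable:
            mismatched.add(ann.rsid)
            logger.warning(
                "variant %s at %s:%d excluded: VCF alleles %s do not contain "
                "annotation pair %s/%s",
                ann.rsid,
                rec.CHROM,
                rec.POS,
                alleles,
                ann.effect_allele,
                ann.other_allele,
            )
            continue
        mismatched.discard(ann.rsid)
        # genotypes: rows of [allele1, allele2, phased]; -1 encodes missing
        gts = np.asarray([g[:2] for g in rec.genotypes], dtype=int)[keep_idx]
        allele_is_effect = np.array(
            [a == ann.effect_allele for a in alleles], dtype=bool
        )
        dose = np.zeros(len(keep_idx), dtype=float)
        any_missing = (gts < 0).any(axis=1)
        valid = ~any_missing
        if valid.any():
            calls = gts[valid]
            dose[valid] = allele_is_effect[calls[:, 0]].astype(float) + allele_is_effect[
                calls[:, 1]
            ].astype(float)
        dose[any_missing] = np.nan
        found[ann.rsid] = dose

    kept_rsids = [a.rsid for a in annotations if a.rsid in found]
    report.allele_mismatch = sorted(mismatched)
    report.missing_variants = [
        a.rsid
        for a in annotations
        if a.rsid not in found and a.rsid not in mismatched
    ]
    if report.missing_variants:
        logger.warning(
            "%d annotated variant(s) not found in VCF: %s",
            len(report.missing_variants),
            report.missing_variants,
        )
    if not kept_rsids:
        raise AnalysisError(f"no annotated variants matched in {vcf_path}")
    matrix = np.column_stack([found[r] for r in kept_rsids])
    return DosageMatrix(kept_samples, kept_rsids, matrix, report=report)
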