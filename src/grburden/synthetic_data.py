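"""Synthetic multi-population cohorts with known ground truth.

Population allele frequencies follow the Balding–Nichols model: for a
variant with ancestral risk-allele frequency p and a population with
differentiation F, the population frequency is drawn

    RAF ~ Beta(p * (1 - F) / F,  (1 - p) * (1 - F) / F)

independently across variants and populations, so E[RAF] = p and
Var[RAF] = F * p * (1 - p). Genotypes are Binomial(2, RAF) within each
population (Hardy–Weinberg). Variants are unlinked. Monomorphic draws are
retained deliberately, to exercise fixed-allele and rarity edge cases
downstream.

A fixed seed makes every emitted file byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations_io import (
    SamplePanel,
    SampleRecord,
    VariantAnnotation,
    write_annotation_table,
)
from .errors import ValidationError

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, super-population, size, FST."""

    label: str
    super_label: str
    n_samples: int
    fst: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"population {self.label}: n_samples must be >= 1")
        if not 0 < self.fst < 1:
            raise ValidationError(f"population {self.label}: fst must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    n_variants: int = 59
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("POP1", "SUP1", 100, 0.05),
        PopulationSpec("POP2", "SUP2", 100, 0.05),
    )
    ancestral_raf_range: tuple[float, float] = (0.05, 0.95)
    beta_range: tuple[float, float] = (0.01, 0.09)
    prop_ancestral_effect: float = 0.5
    cadd_range: tuple[float, float] = (0.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValidationError("n_variants must be >= 1")
        if not 0 <= self.prop_ancestral_effect <= 1:
            raise ValidationError("prop_ancestral_effect must be in [0, 1]")
        lo, hi = self.ancestral_raf_range
        if not 0 < lo <= hi < 1:
            raise ValidationError("ancestral_raf_range must satisfy 0 < lo <= hi < 1")
        if self.beta_range[0] <= 0:
            raise ValidationError("beta_range must be positive")


@dataclass
class SimulatedCohort:
    """In-memory cohort: annotations, panel, oriented dosages, ground truth."""

    config: SimulationConfig
    annotations: list[VariantAnnotation]
    panel: SamplePanel
    samples: list[str]
    effect_dosages: np.ndarray  # samples x variants, counts of the effect allele
    ancestral_raf: np.ndarray  # variants
    true_raf: np.ndarray  # populations x variants, effect-allele frequency
    effect_is_alt: np.ndarray  # variants, bool: effect allele written as VCF ALT
    expected_grb: dict[str, float] = field(default_factory=dict)

    @property
    def population_labels(self) -> list[str]:
        return [p.label for p in self.config.populations]


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-population risk-allele frequencies.

    Returns (ancestral_raf of shape [n_variants],
    raf of shape [n_populations, n_variants]).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_raf_range
    p = rng.uniform(lo, hi, size=config.n_variants)
    raf = np.empty((len(config.populations), config.n_variants))
    for k, pop in enumerate(config.populations):
        f = pop.fst
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        raf[k] = rng.beta(a, b)
    return p, raf


def expected_grb(raf: np.ndarray, betas: np.ndarray) -> float:
    """Analytic population mean of the rescaled weighted score.

    For HWE genotypes, E[GRB] = N * (sum_i 2 p_i beta_i) / (sum_i beta_i).
    """
    betas = np.asarray(betas, dtype=float)
    return float(len(betas) * (2 * raf * betas).sum() / betas.sum())


def _draw_annotations(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[VariantAnnotation], np.ndarray]:
    n = config.n_variants
    betas = rng.uniform(*config.beta_range, size=n)
    cadd = rng.uniform(*config.cadd_range, size=n)
    ancestral = rng.random(n) < config.prop_ancestral_effect
    effect_idx = rng.integers(0, 4, size=n)
    other_offset = rng.integers(1, 4, size=n)
    other_idx = (effect_idx + other_offset) % 4
    annotations = []
    chroms = (np.arange(n) % 22) + 1
    positions = 10_000 + 1_000 * np.arange(n)
    for i in range(n):
        annotations.append(
            VariantAnnotation(
                rsid=f"rs{1_000_000 + i}",
                chrom=str(chroms[i]),
                pos=int(positions[i]),
                effect_allele=str(_BASES[effect_idx[i]]),
                other_allele=str(_BASES[other_idx[i]]),
                beta=round(float(betas[i]), 6),
                allele_state="ancestral" if ancestral[i] else "derived",
                cadd_phred=round(float(cadd[i]), 3),
            )
        )
    return annotations, betas


def simulate_cohort_arrays(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a cohort entirely in memory (no files written)."""
    rng = np.random.default_rng(config.seed)
    p, raf = simulate_frequencies(config, rng)
    annotations, _ = _draw_annotations(config, rng)
    betas = np.array([a.beta for a in annotations])
    samples: list[str] = []
    records: list[SampleRecord] = []
    blocks = []
    grb_truth: dict[str, float] = {}
    for k, pop in enumerate(config.populations):
        ids = [f"{pop.label}_{j:04d}" for j in range(pop.n_samples)]
        samples.extend(ids)
        records.extend(
            SampleRecord(s, pop.label, pop.super_label, "male" if j % 2 else "female")
            for j, s in enumerate(ids)
        )
        blocks.append(rng.binomial(2, raf[k], size=(pop.n_samples, config.n_variants)))
        grb_truth[pop.label] = expected_grb(raf[k], betas)
    dosages = np.concatenate(blocks, axis=0).astype(float)
    effect_is_alt = rng.random(config.n_variants) < 0.5
    return SimulatedCohort(
        config=config,
        annotations=annotations,
        panel=SamplePanel(records),
        samples=samples,
        effect_dosages=dosages,
        ancestral_raf=p,
        true_raf=raf,
        effect_is_alt=effect_is_alt,
        expected_grb=grb_truth,
    )


def write_vcf(cohort: SimulatedCohort, path) -> None:
    """Write cohort genotypes as an uncompressed VCF 4.2.

    The effect allele is the ALT for the random half of variants flagged in
    ``effect_is_alt`` and the REF otherwise, so re-extraction exercises both
    orientations of the dosage logic. Variants are written sorted by
    (chrom, pos) as integers where possible.
    """
    anns = cohort.annotations
    order = sorted(
        range(len(anns)), key=lambda i: (_chrom_key(anns[i].chrom), anns[i].pos)
    )
    lines = [
        "##fileformat=VCFv4.2",
        "##source=grburden-simulate",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for c in sorted({a.chrom for a in anns}, key=_chrom_key):
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.samples)
    )
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    for i in order:
        ann = anns[i]
        dose = cohort.effect_dosages[:, i].astype(int)
        if cohort.effect_is_alt[i]:
            ref, alt = ann.other_allele, ann.effect_allele
            alt_count = dose
        else:
            ref, alt = ann.effect_allele, ann.other_allele
            alt_count = 2 - dose
        row = "\t".join(
            [ann.chrom, str(ann.pos), ann.rsid, ref, alt, ".", "PASS", ".", "GT"]
            + list(gt_strings[alt_count])
        )
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def write_panel(panel: SamplePanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def write_truth(cohort: SimulatedCohort, raf_path, grb_path) -> None:
    rows = []
    for k, pop in enumerate(cohort.config.populations):
        for i, ann in enumerate(cohort.annotations):
            rows.append(
                {
                    "rsid": ann.rsid,
                    "population": pop.label,
                    "true_raf": cohort.true_raf[k, i],
                }
            )
    pd.DataFrame(rows).to_csv(raf_path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        {
            "population": list(cohort.expected_grb),
            "expected_grb": [cohort.expected_grb[p] for p in cohort.expected_grb],
        }
    ).to_csv(grb_path, sep="\t", index=False, float_format="%.10g")


def simulate_cohort(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Simulate and write a full cohort (VCF + panel + annotations + truth).

    Returns the paths of the four emitted files. Deterministic given
    ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort_arrays(config)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "panel": outdir / "panel.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth_raf": outdir / "truth_raf.tsv",
        "truth_grb": outdir / "truth_expected_grb.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_panel(cohort.panel, paths["panel"])
    write_annotation_table(cohort.annotations, paths["annotations"])
    write_truth(cohort, paths["truth_raf"], paths["truth_grb"])
    return paths
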