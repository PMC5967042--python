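"""Per-individual genetic risk burden (GRB) scores.

The weighted score over a subset of N variants is

    GRB_j = N * (sum_i c_ij * beta_i) / (sum_i beta_i)

where c_ij is the count (0/1/2) of the effect allele. The leading factor N
puts the score on the 0..2N allele-count scale, so that with equal weights
it reduces exactly to the plain allele count. Individuals with missing
dosages have both sums restricted to their observed variants while N stays
the full subset size (per-individual weight renormalization); an individual
with no observed variant gets a missing (NaN) score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations_io import DosageMatrix, VariantAnnotation
from .errors import AnalysisError, ValidationError

STRATIFY_CRITERIA = ("by_allele_state", "by_deleteriousness")


@dataclass(frozen=True)
class WeightVector:
    """Positive per-variant effect sizes aligned to an rsid list."""

    rsids: tuple[str, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rsids) != len(self.betas):
            raise ValidationError("rsids and betas differ in length")
        if any(b <= 0 for b in self.betas):
            raise ValidationError("all betas must be > 0")

    @classmethod
    def from_annotations(
        cls, annotations: Sequence[VariantAnnotation], rsids: Sequence[str] | None = None
    ) -> "WeightVector":
        """Build weights from annotations, optionally restricted to ``rsids``."""
        by_id = {a.rsid: a.beta for a in annotations}
        if rsids is None:
            rsids = [a.rsid for a in annotations]
        missing = [r for r in rsids if r not in by_id]
        if missing:
            raise AnalysisError(f"no annotation for variant(s): {missing}")
        return cls(tuple(rsids), tuple(by_id[r] for r in rsids))

    def __len__(self) -> int:
        return len(self.rsids)


@dataclass
class ScoreSet:
    """Per-sample GRB values for one named variant subset."""

    subset_label: str
    n_variants: int
    samples: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.n_variants <= 0:
            raise ValidationError("n_variants must be > 0")
        if self.scores.shape != (len(self.samples),):
            raise ValidationError("scores length does not match samples")
        observed = self.scores[~np.isnan(self.scores)]
        if observed.size and (
            observed.min() < -1e-9 or observed.max() > 2 * self.n_variants + 1e-9
        ):
            raise ValidationError(
                f"scores outside [0, {2 * self.n_variants}] for subset "
                f"{self.subset_label!r}"
            )


def compute_grb(
    dosages: DosageMatrix, weights: WeightVector, subset_label: str = "all"
) -> ScoreSet:
    """Weighted GRB over the variants named in ``weights``.

    ``weights`` must cover a (non-empty) subset of the matrix's variants.
    """
    if len(weights) == 0:
        raise AnalysisError("empty variant subset")
    sub = dosages.subset_variants(weights.rsids)
    c = sub.dosages  # samples x N, NaN for missing
    beta = np.asarray(weights.betas, dtype=float)
    n = len(weights)
    observed = ~np.isnan(c)
    num = np.nansum(c * beta, axis=1)
    denom = (observed * beta).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = n * num / denom
    scores[denom == 0] = np.nan  # all dosages missing for that individual
    return ScoreSet(subset_label, n, sub.samples, scores)


def compute_unweighted_grb(
    dosages: DosageMatrix,
    rsids: Sequence[str] | None = None,
    subset_label: str = "all",
) -> ScoreSet:
    """Plain sum of effect-allele counts over observed variants."""
    sub = dosages if rsids is None else dosages.subset_variants(rsids)
    if sub.n_variants == 0:
        raise AnalysisError("empty variant subset")
    c = sub.dosages
    observed = ~np.isnan(c)
    scores = np.nansum(c, axis=1)
    scores[~observed.any(axis=1)] = np.nan
    return ScoreSet(subset_label, sub.n_variants, sub.samples, scores)


def stratify_variants(
    annotations: Sequence[VariantAnnotation],
    criterion: str,
    threshold: float | None = None,
) -> dict[str, list[str]]:
    """Partition variants into two labelled subsets.

    ``by_allele_state`` splits on the ancestral/derived flag of the effect
    allele. ``by_deleteriousness`` splits on the CADD score at ``threshold``
    (default: the median of the input set), with strictly greater ->
    "deleterious" and less-or-equal -> "benign", so median-valued variants
    land in the benign stratum.
    """
    if not annotations:
        raise AnalysisError("no annotations to stratify")
    if criterion == "by_allele_state":
        return {
            "ancestral": [a.rsid for a in annotations if a.allele_state == "ancestral"],
            "derived": [a.rsid for a in annotations if a.allele_state == "derived"],
        }
    if criterion == "by_deleteriousness":
        if threshold is None:
            threshold = float(np.median([a.cadd_phred for a in annotations]))
        return {
            "benign": [a.rsid for a in annotations if a.cadd_phred <= threshold],
            "deleterious": [a.rsid for a in annotations if a.cadd_phred > threshold],
        }
    raise ValueError(
        f"criterion must be one of {STRATIFY_CRITERIA}, got {criterion!r}"
    )
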