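"""Group-level analyses of burden scores and risk-allele frequencies.

Conventions (fixed across the module):

* group comparisons use the Welch two-sample t-test with the
  Welch–Satterthwaite degrees of freedom, two-sided, alpha = 0.05; a
  pooled-variance variant is available behind ``equal_var=True``;
* "rare" classification folds to the minor allele frequency
  min(RAF, 1 - RAF) within each group, whereas the selection test works on
  unfolded RAF tails — the two conventions are deliberately distinct;
* no multiple-testing correction is applied anywhere; p-values are nominal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import DosageMatrix, SamplePanel, VariantAnnotation
from .errors import AnalysisError, ValidationError
from .grb_core import ScoreSet

logger = logging.getLogger(__name__)

GROUPINGS = ("super_population", "population", "sex")


@dataclass
class GroupComparison:
    """Summary of one group versus the reference group."""

    group: str
    n: int
    mean: float
    sd: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    is_reference: bool = False


@dataclass
class SelectionTestResult:
    """Reciprocal-tail comparison of risk-allele frequencies in one group."""

    group: str
    n_rare: int
    n_common_reciprocal: int
    p_value: float  # NaN when both tails are empty
    conclusion: str  # "excess_rare" or "no_excess"


def _group_scores(
    scores: ScoreSet, panel: SamplePanel, grouping: str
) -> dict[str, np.ndarray]:
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    groups: dict[str, list[float]] = {}
    for sample, value in zip(scores.samples, scores.scores):
        if sample not in panel:
            continue
        groups.setdefault(panel.group_of(sample, grouping), []).append(value)
    return {
        g: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for g, v in groups.items()
    }


def welch_test(a: np.ndarray, b: np.ndarray, equal_var: bool = False):
    """Two-sample t-test of mean(a) - mean(b) with 95% CI.

    Returns (mean_diff, ci_low, ci_high, t, df, p). Welch by default.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise AnalysisError("both groups need n >= 2 for a t-test")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return diff, diff, diff, t, df, p
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return diff, diff - half, diff + half, t, df, p


def compare_grb_groups(
    scores: ScoreSet,
    panel: SamplePanel,
    grouping: str,
    reference: str,
    equal_var: bool = False,
) -> list[GroupComparison]:
    """Compare each group's mean score to the reference group.

    Groups with n < 2 are excluded with a warning. The reference group is
    emitted first with a null difference.
    """
    groups = _group_scores(scores, panel, grouping)
    if reference not in groups:
        raise AnalysisError(f"reference group {reference!r} not present")
    ref = groups[reference]
    if len(ref) < 2:
        raise AnalysisError(f"reference group {reference!r} has n < 2")
    out = [
        GroupComparison(
            group=reference,
            n=len(ref),
            mean=float(ref.mean()),
            sd=float(ref.std(ddof=1)),
            mean_diff=0.0,
            ci_low=0.0,
            ci_high=0.0,
            p_value=np.nan,
            is_reference=True,
        )
    ]
    for group in sorted(groups):
        if group == reference:
            continue
        values = groups[group]
        if len(values) < 2:
            logger.warning("group %s has n < 2; excluded from comparison", group)
            continue
        diff, lo, hi, _t, _df, p = welch_test(values, ref, equal_var=equal_var)
        out.append(
            GroupComparison(
                group=group,
                n=len(values),
                mean=float(values.mean()),
                sd=float(values.std(ddof=1)),
                mean_diff=float(diff),
                ci_low=float(lo),
                ci_high=float(hi),
                p_value=float(p),
            )
        )
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [c.group for c in comparisons],
            "n": [c.n for c in comparisons],
            "mean": [c.mean for c in comparisons],
            "sd": [c.sd for c in comparisons],
            "mean_diff": [c.mean_diff for c in comparisons],
            "ci_low": [c.ci_low for c in comparisons],
            "ci_high": [c.ci_high for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "is_reference": [c.is_reference for c in comparisons],
        }
    )


def compute_group_raf(
    dosages: DosageMatrix, panel: SamplePanel, grouping: str = "super_population"
) -> pd.DataFrame:
    """Risk-allele frequency per group per variant.

    Returns a tidy frame with columns group, rsid, raf, n_chromosomes;
    raf is NaN (and n_chromosomes 0) where a variant is entirely missing
    within a group.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    members: dict[str, list[int]] = {}
    for i, sample in enumerate(dosages.samples):
        if sample not in panel:
            continue
        members.setdefault(panel.group_of(sample, grouping), []).append(i)
    if not members:
        raise AnalysisError("no panel samples present in dosage matrix")
    rows = []
    for group in sorted(members):
        sub = dosages.dosages[members[group], :]
        observed = ~np.isnan(sub)
        n_chrom = 2 * observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            raf = np.nansum(sub, axis=0) / n_chrom
        for j, rsid in enumerate(dosages.variants):
            rows.append(
                {
                    "group": group,
                    "rsid": rsid,
                    "raf": raf[j] if n_chrom[j] > 0 else np.nan,
                    "n_chromosomes": int(n_chrom[j]),
                }
            )
    return pd.DataFrame(rows)


def classify_rare(
    freqs: pd.DataFrame,
    annotations: list[VariantAnnotation] | None = None,
    maf_cut: float = 0.05,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-group rare-variant counts with Fisher exact tests vs reference.

    A variant is rare in a group iff its folded MAF = min(raf, 1 - raf)
    computed within that group is < ``maf_cut``. Variants with a missing raf
    are dropped from that group's denominator (logged). Returns columns
    group, n_rare, n_total, proportion, p_value (NaN for the reference row
    or when no reference is given).
    """
    if not 0 < maf_cut < 0.5:
        raise ValidationError(f"maf_cut must be in (0, 0.5), got {maf_cut}")
    rows = []
    for group, sub in freqs.groupby("group", sort=True):
        raf = sub["raf"].to_numpy(dtype=float)
        dropped = int(np.isnan(raf).sum())
        if dropped:
            logger.warning("group %s: %d variant(s) with missing raf dropped", group, dropped)
        raf = raf[~np.isnan(raf)]
        maf = np.minimum(raf, 1 - raf)
        rows.append(
            {
                "group": group,
                "n_rare": int((maf < maf_cut).sum()),
                "n_total": len(raf),
                "proportion": float((maf < maf_cut).mean()) if len(raf) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out["p_value"] = np.nan
    if reference is not None:
        ref_rows = out[out["group"] == reference]
        if ref_rows.empty:
            raise AnalysisError(f"reference group {reference!r} not present")
        ref_rare = int(ref_rows["n_rare"].iloc[0])
        ref_total = int(ref_rows["n_total"].iloc[0])
        for i, row in out.iterrows():
            if row["group"] == reference:
                continue
            table = [
                [int(row["n_rare"]), int(row["n_total"] - row["n_rare"])],
                [ref_rare, ref_total - ref_rare],
            ]
            out.loc[i, "p_value"] = stats.fisher_exact(table, alternative="two-sided")[1]
    return out


def detect_fixed(
    freqs: pd.DataFrame, fix_cut: float = 0.99, reference: str = "EUR"
) -> pd.DataFrame:
    """Variants fixed (raf >= fix_cut) in >= 1 non-reference group while
    still polymorphic (raf < fix_cut) in the reference group.

    Returns columns rsid, fixed_in (comma-joined sorted group labels),
    raf_reference.
    """
    if not 0 < fix_cut <= 1:
        raise ValidationError(f"fix_cut must be in (0, 1], got {fix_cut}")
    ref = freqs[freqs["group"] == reference].set_index("rsid")["raf"]
    if ref.empty:
        raise AnalysisError(f"reference group {reference!r} not present")
    rows = []
    for rsid, sub in freqs[freqs["group"] != reference].groupby("rsid", sort=False):
        ref_raf = ref.get(rsid, np.nan)
        if np.isnan(ref_raf) or ref_raf >= fix_cut:
            continue
        fixed_groups = sorted(sub.loc[sub["raf"] >= fix_cut, "group"])
        if fixed_groups:
            rows.append(
                {
                    "rsid": rsid,
                    "fixed_in": ",".join(fixed_groups),
                    "raf_reference": float(ref_raf),
                }
            )
    return pd.DataFrame(rows, columns=["rsid", "fixed_in", "raf_reference"])


def selection_test(
    freqs: pd.DataFrame, low: float = 0.05, high: float = 0.95
) -> list[SelectionTestResult]:
    """Exact binomial test of rare vs reciprocal common risk-allele tails.

    Reciprocal mode (low + high == 1, low < 0.5): counts RAF < low against
    RAF > high among the variants falling in either tail, two-sided exact
    binomial with p0 = 1/2. Half-split mode (low == high == 0.5): RAF < 0.5
    against RAF >= 0.5 over all variants. "excess_rare" is declared iff
    p < 0.05 with the rare count the larger one.
    """
    half_split = low == 0.5 and high == 0.5
    if not half_split and not np.isclose(low + high, 1.0):
        raise ValidationError(
            f"tail cuts must be reciprocal (low + high = 1) or 0.5/0.5, got {low}/{high}"
        )
    results = []
    for group, sub in freqs.groupby("group", sort=True):
        raf = sub["raf"].to_numpy(dtype=float)
        raf = raf[~np.isnan(raf)]
        if half_split:
            n_rare = int((raf < 0.5).sum())
            n_common = int((raf >= 0.5).sum())
        else:
            n_rare = int((raf < low).sum())
            n_common = int((raf > high).sum())
        total = n_rare + n_common
        if total == 0:
            logger.warning("group %s: no variants in either RAF tail", group)
            results.append(
                SelectionTestResult(group, 0, 0, float("nan"), "no_excess")
            )
            continue
        p = stats.binomtest(n_rare, total, 0.5, alternative="two-sided").pvalue
        conclusion = "excess_rare" if (p < 0.05 and n_rare > n_common) else "no_excess"
        results.append(SelectionTestResult(group, n_rare, n_common, float(p), conclusion))
    return results


def selection_results_to_frame(results: list[SelectionTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "n_rare": [r.n_rare for r in results],
            "n_common_reciprocal": [r.n_common_reciprocal for r in results],
            "p_value": [r.p_value for r in results],
            "conclusion": [r.conclusion for r in results],
        }
    )


def within_group_strata_contrast(
    scores_a: ScoreSet,
    scores_b: ScoreSet,
    panel: SamplePanel,
    grouping: str = "super_population",
) -> pd.DataFrame:
    """Paired per-individual contrast of two score sets within each group.

    Both score sets must cover the same samples in the same order. Returns
    columns group, n, mean_diff (a - b), p_value from a paired t-test.
    """
    if scores_a.samples != scores_b.samples:
        raise AnalysisError("score sets cover different samples")
    diffs = scores_a.scores - scores_b.scores
    groups: dict[str, list[float]] = {}
    for sample, d in zip(scores_a.samples, diffs):
        if sample not in panel or np.isnan(d):
            continue
        groups.setdefault(panel.group_of(sample, grouping), []).append(d)
    rows = []
    for group in sorted(groups):
        d = np.asarray(groups[group], dtype=float)
        if len(d) < 2:
            logger.warning("group %s has n < 2; excluded from paired contrast", group)
            continue
        if d.std(ddof=1) == 0:
            p = 1.0 if d.mean() == 0 else 0.0
        else:
            p = stats.ttest_1samp(d, 0.0).pvalue
        rows.append(
            {"group": group, "n": len(d), "mean_diff": float(d.mean()), "p_value": float(p)}
        )
    return pd.DataFrame(rows)


def frequency_spectrum(
    freqs: pd.DataFrame, bins: int = 10, grid_points: int = 101
) -> dict[str, dict]:
    """Histogram + Gaussian-kernel density of RAF per group.

    Bins partition [0, 1] right-open except the last (closed) bin. The
    density is evaluated on a fixed uniform grid; groups whose frequencies
    are all identical get NaN densities (the kernel bandwidth is undefined).
    Returns {group: {"bin_edges", "counts", "modal_bin", "grid", "density"}}.
    """
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    edges = np.linspace(0.0, 1.0, bins + 1)
    grid = np.linspace(0.0, 1.0, grid_points)
    out: dict[str, dict] = {}
    for group, sub in freqs.groupby("group", sort=True):
        raf = sub["raf"].to_numpy(dtype=float)
        raf = raf[~np.isnan(raf)]
        counts, _ = np.histogram(raf, bins=edges)
        if len(raf) >= 2 and np.ptp(raf) > 0:
            density = stats.gaussian_kde(raf)(grid)
        else:
            density = np.full_like(grid, np.nan)
        out[group] = {
            "bin_edges": edges,
            "counts": counts,
            "modal_bin": int(np.argmax(counts)),
            "grid": grid,
            "density": density,
        }
    return out
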