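"""Cohort assembly and cross-family analyses.

Family selection mirrors the curation a structural-evolution study applies
before regression: drop NMR and engineered-mutant structures, require a
minimum number of non-redundant structures per family (default 20),
optionally restrict to high-resolution crystal structures (better than
2.2 A), and require a minimum number of accurate alignments (P-score > 3,
default 10) for the family to be fittable.

Cross-family analyses summarize the per-family bilinear fits: quartiles of
the multiple correlation coefficient R over significant families, a
two-sample t test of a fit variable between disulfide-rich and
disulfide-poor families, and a Pearson correlation table over family-level
covariates (structure size, indel frequency, SSS, SIDS, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GroupingError, InsufficientDataError, ValidationError
from .structio import PairRecord
from .pairstats import filter_accurate

#: subset rule for cross-family coefficient comparisons: high bilinear
#: correlation and both coefficients individually significant
SUBSET_R_MIN = 0.75
SUBSET_ALPHA = 0.01

DISULFIDE_THRESHOLD = 1.5  # mean disulfide bonds splitting rich/poor families


@dataclass
class StructureInfo:
    domain_id: str
    method: str = "xray"  # {"xray", "nmr", "other"}
    resolution_A: float | None = None
    is_mutant: bool = False


@dataclass
class FamilyCatalogEntry:
    """One family's structures and pairwise alignment records."""

    family_id: str
    structures: list[StructureInfo]
    pair_records: list[PairRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.structures:
            raise ValidationError(f"family {self.family_id}: no structures")


@dataclass
class GroupTestResult:
    variable: str
    mean_diff: float  # mean(group >= threshold) - mean(group < threshold)
    t_statistic: float
    p_value: float
    group_sizes: tuple[int, int]


@dataclass
class CohortSummary:
    n_families: int
    n_families_significant: int
    median_R: float
    upper_quartile_R: float
    lower_quartile_R: float
    frac_both_partials_significant: float
    group_test: GroupTestResult | None = None
    correlation_table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_families(
    catalog: Sequence[FamilyCatalogEntry],
    min_structures: int = 20,
    exclude_nmr: bool = True,
    exclude_mutants: bool = True,
    max_resolution: float | None = None,
    min_accurate_pairs: int = 10,
    p_score_threshold: float = 3.0,
    log: list | None = None,
) -> list[FamilyCatalogEntry]:
    """Apply the family-selection filters in order.

    Structure-level exclusions run first (NMR, mutants, resolution), then
    the surviving-structure count, then the accurate-alignment count on the
    P-score-gated pair records restricted to surviving structures.  Each
    exclusion is appended to ``log`` as ``(family_id, rule)`` when given.
    """
    selected = []
    for entry in catalog:
        structures = list(entry.structures)
        if exclude_nmr:
            structures = [s for s in structures if s.method != "nmr"]
        if exclude_mutants:
            structures = [s for s in structures if not s.is_mutant]
        if max_resolution is not None:
            structures = [
                s
                for s in structures
                if s.resolution_A is not None and s.resolution_A < max_resolution
            ]
        if len(structures) < min_structures:
            if log is not None:
                log.append((entry.family_id, f"min_structures<{min_structures}"))
            continue
        surviving = {s.domain_id for s in structures}
        pair_records = [
            r
            for r in entry.pair_records
            if r.domain_a in surviving and r.domain_b in surviving
        ]
        accurate, _ = filter_accurate(pair_records, threshold=p_score_threshold)
        if len(accurate) < min_accurate_pairs:
            if log is not None:
                log.append((entry.family_id, f"min_accurate_pairs<{min_accurate_pairs}"))
            continue
        selected.append(
            FamilyCatalogEntry(entry.family_id, structures, pair_records)
        )
    return selected


def sss_sids_subset(
    fits: pd.DataFrame, r_min: float = SUBSET_R_MIN, alpha: float = SUBSET_ALPHA
) -> pd.DataFrame:
    """Families eligible for cross-family SSS/SIDS comparison.

    Requires a high bilinear correlation (R > ``r_min``) and both regression
    coefficients individually significant (p < ``alpha``).
    """
    f = _fitted_only(fits)
    mask = (f["R"] > r_min) & (f["p_b1"] < alpha) & (f["p_b2"] < alpha)
    return f[mask]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _fitted_only(fits: pd.DataFrame) -> pd.DataFrame:
    if "note" in fits.columns:
        fits = fits[(fits["note"] == "") | fits["note"].isna()]
    return fits.dropna(subset=["R", "p_model"]) if "p_model" in fits.columns else fits


def summarize_cohort(fits: pd.DataFrame, alpha: float = 0.01) -> CohortSummary:
    """Cohort-level summary of per-family bilinear fits.

    Counts families significant at ``alpha`` on the overall F test; the
    median and quartiles of R (type-7, linear interpolation between order
    statistics) are taken over the significant families only.  Also reports
    the fraction of fitted families whose two partial correlations are both
    significant at ``alpha``.
    """
    f = _fitted_only(fits)
    if len(f) == 0:
        raise InsufficientDataError("no fitted families to summarize")
    sig = f[f["p_model"] < alpha]
    if len(sig):
        lo, med, hi = np.quantile(sig["R"].to_numpy(float), [0.25, 0.5, 0.75])
    else:
        lo = med = hi = math.nan
    both = float(
        ((f["partial_p_pni"] < alpha) & (f["partial_p_sng"] < alpha)).mean()
    )
    return CohortSummary(
        n_families=len(f),
        n_families_significant=len(sig),
        median_R=float(med),
        upper_quartile_R=float(hi),
        lower_quartile_R=float(lo),
        frac_both_partials_significant=both,
    )


def compare_disulfide_groups(
    fits: pd.DataFrame,
    threshold: float = DISULFIDE_THRESHOLD,
    variable: str = "b1",
    welch: bool = False,
) -> GroupTestResult:
    """Two-sample t test of a fit variable between disulfide groups.

    Group 1 holds families whose mean disulfide count is at least
    ``threshold``; group 2 the rest.  Student's pooled-variance test by
    default; Welch's unequal-variance test behind ``welch=True``.
    """
    f = _fitted_only(fits).dropna(subset=["mean_disulfide", variable])
    rich = f[f["mean_disulfide"] >= threshold][variable].to_numpy(float)
    poor = f[f["mean_disulfide"] < threshold][variable].to_numpy(float)
    if len(rich) == 0 or len(poor) == 0:
        raise GroupingError(
            f"disulfide threshold {threshold} leaves an empty group "
            f"(sizes {len(rich)}, {len(poor)})"
        )
    t, p = sps.ttest_ind(rich, poor, equal_var=not welch)
    return GroupTestResult(
        variable=variable,
        mean_diff=float(rich.mean() - poor.mean()),
        t_statistic=float(t),
        p_value=float(p),
        group_sizes=(len(rich), len(poor)),
    )


DEFAULT_CORRELATION_PAIRS = [
    ("mean_n_algn", "R"),
    ("gaps_per_unit_length", "R"),
    ("total_indels", "R"),
    ("pni_sd", "R"),
    ("mean_n_algn", "b1"),
    ("mean_n_algn", "b2"),
    ("gaps_per_unit_length", "b1"),
    ("gaps_per_unit_length", "b2"),
    ("b1", "b2"),
]


def cross_family_correlations(
    fits: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between family-level covariates.

    The default pair list covers the relationships a cross-family analysis
    reports: structure size (mean alignment length) vs bilinear correlation
    and vs the sensitivities, indel frequency vs the same, PNI spread vs R,
    and SSS vs SIDS.  Constant variables yield a flagged NaN row rather
    than an error.
    """
    f = _fitted_only(fits)
    if len(f) < 5:
        raise InsufficientDataError(f"need >= 5 families, got {len(f)}")
    rows = []
    for x, y in pairs or DEFAULT_CORRELATION_PAIRS:
        sub = f.dropna(subset=[x, y])
        xv = sub[x].to_numpy(float)
        yv = sub[y].to_numpy(float)
        if len(sub) < 5 or xv.std() == 0 or yv.std() == 0:
            rows.append(
                {"x": x, "y": y, "n": len(sub), "pearson_r": math.nan,
                 "p_value": math.nan, "flag": "undefined"}
            )
            continue
        r, p = sps.pearsonr(xv, yv)
        rows.append(
            {"x": x, "y": y, "n": len(sub), "pearson_r": float(r),
             "p_value": float(p), "flag": ""}
        )
    return pd.DataFrame(rows)
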