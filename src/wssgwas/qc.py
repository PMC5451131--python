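"""Genotype quality control and phenotype editing.

Marker rules run in a fixed order — (1) non-autosomal, (2) duplicate map
position, (3) GC-score masking, (4) Hardy-Weinberg, (5) call rate,
(6) minor allele frequency — and each marker is charged to the first rule
that removes it, so the per-rule counts in the report reconcile exactly
with input = output + removals. Quality masking happens before the
statistical rules so call rate, HWE and MAF are computed on post-mask
genotypes. Sample filtering is applied after marker filtering.

All inequalities are strict exactly as the thresholds read: a call rate of
exactly 0.95 passes, an age at first calving of exactly 21 months passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import GenotypePanel


@dataclass(frozen=True)
class QcThresholds:
    """Genotype QC cutoffs (all strict '<' comparisons)."""

    hwe_p_min: float = 1e-5
    gc_min: float = 0.15
    marker_call_rate_min: float = 0.95
    maf_min: float = 0.02
    sample_call_rate_min: float = 0.90

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QcReport:
    """Ordered per-rule removal counts plus what survived."""

    removed: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0
    unit: str = "markers"

    def add(self, rule: str, count: int) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + int(count)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        if self.n_input != self.n_output + self.total_removed:
            raise AssertionError(
                f"QC bookkeeping broken: {self.n_input} != "
                f"{self.n_output} + {self.total_removed}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(rule, n) for rule, n in self.removed.items()]
        rows.append(("surviving", self.n_output))
        return pd.DataFrame(rows, columns=["rule", f"n_{self.unit}"])


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square, no
    continuity correction). Monomorphic markers return p = 1."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test (mid-p not applied): sums probabilities of
    heterozygote counts no more likely than the observed one, conditional on
    allele counts. Optional alternative to the chi-square rule."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    n_b = 2 * n_bb + n_ab
    n_b = min(n_b, 2 * n - n_b)  # rarer allele count
    if n_b == 0:
        return 1.0
    from scipy.special import gammaln

    hets = np.arange(n_b % 2, n_b + 1, 2)
    n_a = 2 * n - n_b
    logs = (gammaln(n + 1)
            - gammaln((n_b - hets) / 2 + 1) - gammaln(hets + 1)
            - gammaln((n_a - hets) / 2 + 1)
            + hets * np.log(2) + gammaln(n_b + 1) + gammaln(n_a + 1)
            - gammaln(2 * n + 1))
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hets == min(n_ab, n_b)]
    if len(obs) == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(probs[probs <= obs[0] + 1e-12].sum())


def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """(n_markers, 3) counts of dosage 0/1/2, ignoring missing."""
    counts = np.zeros((dosages.shape[0], 3), dtype=np.int64)
    for g in range(3):
        counts[:, g] = np.nansum(dosages == g, axis=1)
    return counts


class MarkerFilter(BaseEstimator):
    """Transformer applying the marker-level QC rules in their fixed order.

    Parameters mirror :class:`QcThresholds`; ``hwe_method`` selects the
    chi-square (default) or exact Hardy-Weinberg test. After ``fit`` the
    surviving-marker mask is in ``kept_`` and the removal report in
    ``report_``; ``transform`` applies mask + quality masking to a panel.
    """

    def __init__(self, hwe_p_min: float = 1e-5, gc_min: float = 0.15,
                 marker_call_rate_min: float = 0.95, maf_min: float = 0.02,
                 hwe_method: str = "chi2"):
        self.hwe_p_min = hwe_p_min
        self.gc_min = gc_min
        self.marker_call_rate_min = marker_call_rate_min
        self.maf_min = maf_min
        self.hwe_method = hwe_method

    def fit(self, panel: GenotypePanel, y=None):
        report = QcReport(n_input=panel.n_markers, unit="markers")
        alive = np.ones(panel.n_markers, dtype=bool)
        mmap = panel.marker_map

        autosomal = mmap["chrom"].astype(str).str.fullmatch(r"\d+").to_numpy()
        report.add("non_autosomal", (~autosomal).sum())
        alive &= autosomal

        dup = mmap.duplicated(["chrom", "bp"], keep=False).to_numpy()
        report.add("duplicate_position", (dup & alive).sum())
        alive &= ~dup

        masked = panel.dosages.copy()
        masked[panel.quality < self.gc_min] = np.nan

        test = hwe_test if self.hwe_method == "chi2" else hwe_exact_test
        counts = _genotype_counts(masked)
        hwe_p = np.ones(panel.n_markers)
        for i in np.flatnonzero(alive):
            if counts[i].sum() > 0:
                hwe_p[i] = test(*counts[i])
        fails = hwe_p < self.hwe_p_min
        report.add("hwe", (fails & alive).sum())
        alive &= ~fails

        call_rate = 1.0 - np.isnan(masked).mean(axis=1)
        fails = call_rate < self.marker_call_rate_min
        report.add("call_rate", (fails & alive).sum())
        alive &= ~fails

        with np.errstate(invalid="ignore"):
            p = np.nanmean(masked, axis=1) / 2.0
        p = np.nan_to_num(p)
        maf = np.minimum(p, 1.0 - p)
        fails = maf < self.maf_min
        report.add("maf", (fails & alive).sum())
        alive &= ~fails

        report.n_output = int(alive.sum())
        report.check()
        self.kept_ = alive
        self.report_ = report
        return self

    def transform(self, panel: GenotypePanel) -> GenotypePanel:
        out = panel.subset(marker_mask=self.kept_)
        out.dosages[out.quality < self.gc_min] = np.nan
        return out


class SampleFilter(BaseEstimator):
    """Drop animals whose post-mask genotype call rate is below the cutoff."""

    def __init__(self, sample_call_rate_min: float = 0.90):
        self.sample_call_rate_min = sample_call_rate_min

    def fit(self, panel: GenotypePanel, y=None):
        if panel.n_markers == 0:
            call_rate = np.ones(panel.n_animals)
        else:
            call_rate = 1.0 - np.isnan(panel.dosages).mean(axis=0)
        self.kept_ = call_rate >= self.sample_call_rate_min
        self.report_ = QcReport(
            removed={"sample_call_rate": int((~self.kept_).sum())},
            n_input=panel.n_animals, n_output=int(self.kept_.sum()),
            unit="samples")
        self.report_.check()
        return self

    def transform(self, panel: GenotypePanel) -> GenotypePanel:
        return panel.subset(animal_mask=self.kept_)


def filter_markers(panel: GenotypePanel,
                   thresholds: QcThresholds = QcThresholds(),
                   hwe_method: str = "chi2") -> tuple[GenotypePanel, QcReport]:
    f = MarkerFilter(thresholds.hwe_p_min, thresholds.gc_min,
                     thresholds.marker_call_rate_min, thresholds.maf_min,
                     hwe_method).fit(panel)
    return f.transform(panel), f.report_


def filter_samples(panel: GenotypePanel,
                   thresholds: QcThresholds = QcThresholds(),
                   ) -> tuple[GenotypePanel, QcReport]:
    f = SampleFilter(thresholds.sample_call_rate_min).fit(panel)
    return f.transform(panel), f.report_


# ---------------------------------------------------------------------------
# phenotype editing

#: (column, low, high) — record removed if value < low or value > high
EDIT_RULES = [
    ("age_first_calving", 21.0, 40.0),
    ("age_second_calving", 32.0, 53.0),
    ("calving_interval", 11.0, np.inf),
]


def edit_phenotypes(table: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Drop records outside the calving-age edit windows.

    Missing covariates (e.g. no second calving yet) never trigger a rule on
    their own; each record is charged to the first rule it violates.
    """
    report = QcReport(n_input=len(table), unit="records")
    alive = np.ones(len(table), dtype=bool)
    for col, low, high in EDIT_RULES:
        v = table[col].to_numpy(float)
        fails = ((v < low) | (v > high)) & ~np.isnan(v)
        report.add(col, (fails & alive).sum())
        alive &= ~fails
    out = table.loc[alive].reset_index(drop=True)
    report.n_output = len(out)
    report.check()
    return out, report


CG_COMPONENTS = ["herd", "birth_year", "birth_season", "weaning_group",
                 "yearling_group"]


def build_contemporary_groups(table: pd.DataFrame,
                              min_size: int = 5,
                              ) -> tuple[pd.DataFrame, QcReport]:
    """Attach cg_id (concatenation of herd, birth year/season, weaning and
    yearling groups) and drop groups smaller than ``min_size`` or without
    variability in the trait."""
    out = table.copy()
    out["cg_id"] = out[CG_COMPONENTS].astype(str).agg("_".join, axis=1)
    report = QcReport(n_input=len(out), unit="records")
    sizes = out.groupby("cg_id")["trait"].transform("size")
    small = (sizes < min_size).to_numpy()
    report.add("cg_too_small", small.sum())
    out = out.loc[~small]
    novar = (out.groupby("cg_id")["trait"].transform("nunique") < 2).to_numpy()
    report.add("cg_no_variability", novar.sum())
    out = out.loc[~novar].reset_index(drop=True)
    report.n_output = len(out)
    report.check()
    return out, report


class PhenotypeEditor(BaseEstimator):
    """Transformer chaining the record edits and contemporary-group rules."""

    def __init__(self, min_cg_size: int = 5):
        self.min_cg_size = min_cg_size

    def fit(self, table: pd.DataFrame, y=None):
        edited, self.edit_report_ = edit_phenotypes(table)
        self.grouped_, self.cg_report_ = build_contemporary_groups(
            edited, self.min_cg_size)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.grouped_

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)
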