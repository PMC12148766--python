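"""Reader-agreement metrics, the regional heterogeneity criterion, and
nonparametric paired statistics.

The reader comparison treats one set of binary defect calls as reference and
summarizes the agreement of another set as a confusion matrix with
sensitivity / precision / specificity / accuracy, optionally requiring the
called lobe to match.  Dose-function differences across imaging methods are
tested with a Friedman test (with tie correction) followed by post-hoc
Wilcoxon signed-rank tests at a Bonferroni-adjusted alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.stats import chi2, norm, rankdata

from .core import FunctionImage

__all__ = [
    "ConfusionSummary",
    "PairedTestResult",
    "WilcoxonResult",
    "binary_agreement",
    "heterogeneity_criterion",
    "friedman_test",
    "wilcoxon_signed_rank",
    "posthoc_wilcoxon",
    "bonferroni_alpha",
]


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _rate(num, den):
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self):
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def precision(self):
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def specificity(self):
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def accuracy(self):
        return self._rate(self.tp + self.tn, self.n)

    @property
    def has_undefined_rates(self) -> bool:
        return any(
            np.isnan(v)
            for v in (self.sensitivity, self.precision, self.specificity, self.accuracy)
        )


def binary_agreement(reference, test, use_location: bool = False) -> ConfusionSummary:
    """Confusion summary of test calls against reference calls.

    Without location, a true positive is both arms calling a defect.  With
    location, a test positive on a reference-positive case counts as TP only
    if the called lobe matches the reference lobe; a lobe mismatch counts
    against the test arm as a false positive (the strict reading).
    """
    ref_by = {s.patient: s for s in reference}
    test_by = {s.patient: s for s in test}
    if set(ref_by) != set(test_by):
        diff = sorted(set(ref_by) ^ set(test_by))
        raise ValueError(f"patient sets differ; symmetric difference: {diff}")
    tp = fp = tn = fn = 0
    for pid, r in ref_by.items():
        t = test_by[pid]
        if r.call and t.call:
            if use_location and t.location != r.location:
                fp += 1
            else:
                tp += 1
        elif r.call and not t.call:
            fn += 1
        elif not r.call and t.call:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def heterogeneity_criterion(
    f: FunctionImage,
    tumor_mask: np.ndarray,
    lung_mask: np.ndarray,
    shell_mm: float = 30.0,
    threshold: float = 0.15,
):
    """Peritumoral lung-function decrease against the whole-lung mean.

    The peritumoral region is the lung within ``shell_mm`` of the tumor
    surface (tumor excluded); the decrease is
    1 - mean(f, peritumoral) / mean(f, lung minus tumor) and the criterion
    passes when the decrease meets ``threshold`` (inclusive).
    """
    tumor = np.asarray(tumor_mask).astype(bool)
    lung = np.asarray(lung_mask).astype(bool)
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    dist = ndimage.distance_transform_edt(~tumor, sampling=f.spacing)
    peri = (dist <= shell_mm) & lung & ~tumor & f.defined_mask
    if not peri.any():
        raise ValueError("peritumoral shell contains no lung voxels")
    rest = lung & ~tumor & f.defined_mask
    decrease = 1.0 - float(f.values[peri].mean()) / float(f.values[rest].mean())
    return decrease, decrease >= threshold


@dataclass
class PairedTestResult:
    label: str
    statistic: float
    p_value: float
    adjusted_alpha: float = 0.05
    n: int = 0
    exact: bool = False
    all_zero: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.adjusted_alpha

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def friedman_test(values: np.ndarray, label: str = "friedman") -> PairedTestResult:
    """Friedman test over a patients x methods matrix.

    Uses within-patient mid-ranks, the standard tie correction, and the
    chi-square approximation with k - 1 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (>=2 patients) x (>=2 methods) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = x.shape
    ranks = np.vstack([rankdata(row, method="average") for row in x])
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:  # every row fully tied
        return PairedTestResult(label, 0.0, 1.0, n=n)
    q /= correction
    p = float(chi2.sf(q, df=k - 1))
    return PairedTestResult(label, float(q), p, n=n)


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n: int  # pairs used after zero removal
    n_zeros: int
    exact: bool


@lru_cache(maxsize=64)
def _signed_rank_null(doubled_ranks: tuple) -> np.ndarray:
    """Exact null counts of 2*W+ over all sign assignments (convolution)."""
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (count reported).  For n <= ``exact_max_n``
    the exact null distribution over all 2^n sign assignments is used
    (computed by convolution over mid-ranks, so ties in |d| are handled);
    larger n uses the normal approximation with tie correction and a
    continuity correction.  All differences zero yields p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    nz = d != 0
    n_zeros = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zeros, exact=True)
    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = tuple(int(round(2 * r)) for r in sorted(ranks))
        counts = _signed_rank_null(doubled)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, float(p), n, n_zeros, exact=True)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, n_zeros, exact=False)


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 3, decimals: int = 3) -> float:
    """Bonferroni-adjusted alpha, truncated (not rounded) to ``decimals``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    scale = 10**decimals
    return np.floor(family_alpha / m * scale) / scale


def posthoc_wilcoxon(
    reference,
    tests: dict,
    family_alpha: float = 0.05,
    m: int | None = None,
):
    """Post-hoc Wilcoxon signed-rank tests of each arm against a reference.

    Each comparison is two-sided at the Bonferroni-adjusted alpha
    ``family_alpha / m`` truncated to three decimals (0.05/3 -> 0.016).
    """
    reference = np.asarray(reference, dtype=float)
    m = len(tests) if m is None else m
    alpha = bonferroni_alpha(family_alpha, m)
    results = []
    for label, values in tests.items():
        values = np.asarray(values, dtype=float)
        if values.shape != reference.shape:
            raise ValueError(f"comparison {label!r}: length mismatch with reference")
        w = wilcoxon_signed_rank(values, reference)
        results.append(
            PairedTestResult(
                label=label,
                statistic=w.statistic,
                p_value=w.p_value,
                adjusted_alpha=alpha,
                n=w.n,
                exact=w.exact,
                all_zero=(w.n == 0),
            )
        )
    return results
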