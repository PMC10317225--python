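"""Population statistics: kinetic histograms and workflow comparison.

A cell population's cross-membrane transport is summarized by the
frequency histogram of per-cell rate constants, characterized by its
median (peak position) and skewness (peak asymmetry).  Two workflows (or
two populations) are compared with the two-sample Kolmogorov-Smirnov
test, which is insensitive to unequal sample sizes; significance is
assessed at alpha = 0.001 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import special, stats

__all__ = ["HistogramSummary", "KSResult", "kinetic_histogram", "ks_two_sample", "compare_workflows"]


@dataclass
class HistogramSummary:
    """Kinetic histogram "number of cells vs rate constant" plus summary stats.

    median is the sample median (peak position); skewness the adjusted
    Fisher-Pearson standardized third moment G1 (NaN below n=3).
    """

    edges: np.ndarray  # min^-1, strictly increasing
    counts: np.ndarray
    n: int
    median: float
    skewness: float


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison.

    D is the supremum distance between the two ECDFs; D_alpha the critical
    value c(alpha) * sqrt((n1+n2)/(n1*n2)) with c(alpha) =
    sqrt(-ln(alpha/2)/2); p the (asymptotic, unless method="exact")
    tail probability.  ``significant`` is D > D_alpha.
    """

    D: float
    D_alpha: float
    p_value: float
    alpha: float
    significant: bool
    n1: int
    n2: int


def kinetic_histogram(k_values: np.ndarray, bins="fd") -> HistogramSummary:
    """Histogram + median + skewness of per-cell rate constants.

    ``bins`` is anything `numpy.histogram_bin_edges` accepts: the default
    Freedman-Diaconis rule, a count, or explicit custom edges.
    """
    k = np.asarray(k_values, dtype=float)
    if len(k) == 0:
        raise ValueError("no rate constants to histogram")
    if np.any(~np.isfinite(k)) or np.any(k <= 0):
        raise ValueError("rate constants must be finite and positive")
    edges = np.histogram_bin_edges(k, bins=bins)
    counts, edges = np.histogram(k, bins=edges)
    skew = float(stats.skew(k, bias=False)) if len(k) >= 3 else float("nan")
    return HistogramSummary(edges=edges, counts=counts, n=len(k), median=float(np.median(k)), skewness=skew)


def _ecdf_sup_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Exact sup |ECDF_a - ECDF_b| over the pooled breakpoints."""
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_two_sample(k_a: np.ndarray, k_b: np.ndarray, alpha: float = 0.001, method: str = "asymp") -> KSResult:
    """Two-sample KS test on rate-constant samples.

    D is computed exactly; the p-value comes from the asymptotic
    Kolmogorov distribution evaluated at sqrt(n_eff) * D with effective
    sample size n_eff = n1*n2/(n1+n2) (``method="exact"`` switches to the
    exact small-sample distribution, available for n1*n2 <= 1e4).  The
    significance call is made against the critical value D_alpha, which is
    the same asymptotic criterion solved for D.
    """
    a = np.asarray(k_a, dtype=float)
    b = np.asarray(k_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d = _ecdf_sup_distance(a, b)
    n1, n2 = len(a), len(b)
    n_eff = n1 * n2 / (n1 + n2)
    if method == "exact":
        if n1 * n2 > 10_000:
            raise ValueError("exact p-value limited to n1*n2 <= 10000")
        p = float(stats.ks_2samp(a, b, method="exact").pvalue)
    elif method == "asymp":
        p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    else:
        raise ValueError(f"unknown method {method!r}")
    c_alpha = np.sqrt(-np.log(alpha / 2.0) / 2.0)
    d_alpha = float(c_alpha * np.sqrt((n1 + n2) / (n1 * n2)))
    return KSResult(
        D=d, D_alpha=d_alpha, p_value=p, alpha=alpha, significant=bool(d > d_alpha), n1=n1, n2=n2
    )


@dataclass
class WorkflowComparison:
    histogram_original: HistogramSummary
    histogram_new: HistogramSummary
    ks: KSResult
    median_ratio: float  # original / new

    def to_dict(self) -> dict:
        def hist_dict(h: HistogramSummary) -> dict:
            d = asdict(h)
            d["edges"] = list(map(float, d["edges"]))
            d["counts"] = list(map(int, d["counts"]))
            return d

        return {
            "histogram_original": hist_dict(self.histogram_original),
            "histogram_new": hist_dict(self.histogram_new),
            "ks": asdict(self.ks),
            "median_ratio": self.median_ratio,
        }


def compare_workflows(
    k_original: np.ndarray, k_new: np.ndarray, alpha: float = 0.001, bins="fd"
) -> WorkflowComparison:
    """Full population-level comparison of the two workflows' accepted k sets."""
    h_orig = kinetic_histogram(k_original, bins=bins)
    h_new = kinetic_histogram(k_new, bins=bins)
    ks = ks_two_sample(k_original, k_new, alpha=alpha)
    return WorkflowComparison(h_orig, h_new, ks, median_ratio=h_orig.median / h_new.median)


def plot_histograms(comparison: WorkflowComparison, path=None):
    """Side-by-side kinetic histograms of the two workflows (optional PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, hist, name in (
        (axes[0], comparison.histogram_original, "original"),
        (axes[1], comparison.histogram_new, "new"),
    ):
        widths = np.diff(hist.edges)
        ax.bar(hist.edges[:-1], hist.counts, width=widths, align="edge", edgecolor="k")
        ax.axvline(hist.median, color="r", ls="--", label=f"median {hist.median:.3g}")
        ax.set_xlabel("k_efflux (min$^{-1}$)")
        ax.set_title(f"{name} workflow (n={hist.n}, skew {hist.skewness:.2f})")
        ax.legend()
    axes[0].set_ylabel("number of cells")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
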