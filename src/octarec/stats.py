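"""Summary statistics over inferred recombination events.

Crossover interference is quantified by maximum-likelihood fitting of a
gamma distribution to inter-CO distances: the shape parameter is 1 for a
memoryless (non-interfering) process and rises above 1 with positive
interference.  The MLE solves the shape score equation

    log(k) - psi(k) = log(mean(x)) - mean(log(x))

by safeguarded Newton iteration; the scale follows as mean(x)/k.

Tract-length and inter-CO-distance distributions are compared with the
Wilcoxon rank-sum and two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "GammaFit", "inter_co_distances", "fit_gamma_mle",
    "compare_interference", "compare_tract_lengths", "summarize",
    "TractLengthSummary", "fit_gamma_by_genotype",
]


@dataclass(frozen=True)
class GammaFit:
    shape: float          # gamma (unitless); interference strength
    scale: float          # bp
    loglik: float         # nats, maximized
    n_gaps: int
    converged: bool

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def inter_co_distances(events: pd.DataFrame,
                       by: Sequence[str] = ("meiosis", "chrom")) -> np.ndarray:
    """Successive CO midpoint differences, pooled over chromosomes/meioses.

    ``events`` needs columns ``type`` and ``co_pos`` plus the grouping
    columns; chromosomes with fewer than two COs contribute nothing.
    """
    cos = events[(events["type"] == "CO") & (events["co_pos"] >= 0)]
    gaps: list[np.ndarray] = []
    if len(cos) == 0:
        return np.empty(0)
    group_cols = [c for c in by if c in cos.columns]
    for _, sub in cos.groupby(group_cols, sort=False):
        pos = np.sort(sub["co_pos"].to_numpy(dtype=float))
        if len(pos) >= 2:
            gaps.append(np.diff(pos))
    return np.concatenate(gaps) if gaps else np.empty(0)


def _gamma_loglik(gaps: np.ndarray, shape: float, scale: float) -> float:
    return float(np.sum(sps.gamma.logpdf(gaps, a=shape, scale=scale)))


def fit_gamma_mle(gaps: Sequence[float], tol: float = 1e-12,
                  max_iter: int = 200) -> GammaFit:
    """Gamma MLE of inter-CO gaps by safeguarded Newton on the shape score.

    Requires at least two positive, non-identical gaps.  The returned
    log-likelihood is the global maximum of the two-parameter gamma
    likelihood (the profile in the shape is unimodal).
    """
    x = np.asarray(gaps, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two gaps to fit a gamma distribution")
    if (x <= 0).any():
        raise ValueError("gaps must be positive")
    mean = float(x.mean())
    s = float(np.log(mean) - np.mean(np.log(x)))
    if s <= 0:
        raise ValueError("zero-variance gaps: gamma shape is unbounded")

    # Minka-style initialisation, then Newton with bisection safeguard on
    # f(k) = log(k) - psi(k) - s, which is strictly decreasing in k
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    lo, hi = 1e-12, None
    converged = False
    for _ in range(max_iter):
        f = np.log(k) - special.digamma(k) - s
        if f > 0:
            lo = max(lo, k)
        else:
            hi = k if hi is None else min(hi, k)
        fprime = 1.0 / k - special.polygamma(1, k)
        step = f / fprime
        k_new = k - step
        if not (lo < k_new and (hi is None or k_new < hi)) or not np.isfinite(k_new):
            k_new = 2.0 * lo if hi is None else 0.5 * (lo + hi)
        if abs(k_new - k) <= tol * max(1.0, k):
            k = k_new
            converged = True
            break
        k = k_new
    scale = mean / k
    return GammaFit(shape=float(k), scale=float(scale),
                    loglik=_gamma_loglik(x, k, scale),
                    n_gaps=int(x.size), converged=converged)


def compare_interference(gaps_a: Sequence[float], gaps_b: Sequence[float],
                         method: str = "auto"):
    """Two-sample Kolmogorov-Smirnov comparison of inter-CO distance
    distributions.  Returns the scipy result (statistic D, p-value);
    small samples use the exact null distribution, large ones the
    asymptotic approximation."""
    a = np.asarray(gaps_a, dtype=float)
    b = np.asarray(gaps_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return sps.ks_2samp(a, b, method=method)


def compare_tract_lengths(lengths_a: Sequence[float], lengths_b: Sequence[float],
                          alternative: str = "two-sided", method: str = "auto"):
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of tract lengths.

    Mid-ranks for ties; exact enumeration for small untied samples, else the
    tie-corrected normal approximation.  Returns the scipy result (U for the
    first sample, p-value)."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return sps.mannwhitneyu(a, b, alternative=alternative, method=method,
                            use_continuity=False)


@dataclass
class TractLengthSummary:
    """Per genotype x event type medians/means and per-meiosis counts."""

    tract_table: pd.DataFrame      # genotype, type, n, median_bp, mean_bp
    count_table: pd.DataFrame      # genotype, type, mean_per_meiosis, se, n_meioses
    symmetric_table: pd.DataFrame  # genotype, n_events, n_meioses, mean_bp
    convention: str


def summarize(events: pd.DataFrame, convention: str = "mid") -> TractLengthSummary:
    """Headline statistics over labeled events.

    ``events`` needs columns genotype, meiosis, type, category and the
    length columns len_min/len_mid/len_max.  Tract statistics use events
    with at least one affected marker; the symmetric-hDNA tally (count and
    mean length) is reported separately.
    """
    col = f"len_{convention}"
    if col not in events.columns:
        raise ValueError(f"unknown length convention {convention!r}")
    with_len = events[events["n_markers"] > 0] if "n_markers" in events.columns \
        else events.dropna(subset=[col])

    tract_rows = []
    for (gt, kind), sub in with_len.groupby(["genotype", "type"], sort=False):
        vals = sub[col].dropna().to_numpy()
        tract_rows.append({
            "genotype": gt, "type": kind, "n": len(vals),
            "median_bp": float(np.median(vals)) if len(vals) else float("nan"),
            "mean_bp": float(np.mean(vals)) if len(vals) else float("nan"),
        })
    tract_table = pd.DataFrame(
        tract_rows, columns=["genotype", "type", "n", "median_bp", "mean_bp"])

    count_rows = []
    for gt, sub in events.groupby("genotype", sort=False):
        per = sub.groupby(["meiosis", "type"]).size().unstack(fill_value=0)
        for kind in ("CO", "NCO"):
            counts = per[kind].to_numpy() if kind in per else np.zeros(len(per))
            n = len(counts)
            se = float(np.std(counts, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            count_rows.append({
                "genotype": gt, "type": kind,
                "mean_per_meiosis": float(np.mean(counts)) if n else 0.0,
                "se": se, "n_meioses": n,
            })
    count_table = pd.DataFrame(
        count_rows,
        columns=["genotype", "type", "mean_per_meiosis", "se", "n_meioses"])

    sym_rows = []
    for gt, sub in events.groupby("genotype", sort=False):
        sym = sub[sub["category"] == "symmetric_hDNA"]
        vals = sym[col].dropna().to_numpy()
        sym_rows.append({
            "genotype": gt, "n_events": len(sym),
            "n_meioses": sub["meiosis"].nunique(),
            "mean_bp": float(np.mean(vals)) if len(vals) else float("nan"),
        })
    symmetric_table = pd.DataFrame(
        sym_rows, columns=["genotype", "n_events", "n_meioses", "mean_bp"])

    return TractLengthSummary(tract_table=tract_table, count_table=count_table,
                              symmetric_table=symmetric_table,
                              convention=convention)


def fit_gamma_by_genotype(events: pd.DataFrame) -> dict[str, GammaFit]:
    """One pooled gamma fit of inter-CO distances per genotype."""
    out: dict[str, GammaFit] = {}
    for gt, sub in events.groupby("genotype", sort=False):
        gaps = inter_co_distances(sub)
        if gaps.size >= 2:
            try:
                out[gt] = fit_gamma_mle(gaps)
            except ValueError:
                continue
    return out
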