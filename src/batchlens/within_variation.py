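"""Within-batch variation: permutation case/control scans and
coefficient-of-variation (CV) expression profiles.

The scan randomly splits every sufficiently large batch into case and
control halves, fits a batch-blocked linear model with a single global
case/control factor, and records the DEG count of the class contrast;
the maximum count over many permutations is an indirect measure of the
heterogeneity among individuals of a batch.  The CV profile computes,
per probe and per batch, the sample standard deviation over the mean of
the log2 intensities, then averages over batches (unweighted), which is
the substrate of all pathway-level and cross-species comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BatchDesign, ExpressionMatrix
from .linear_models import build_design, count_degs, estimate_ebayes, fit_genewise, moderated_t

__all__ = [
    "WithinScanResult",
    "CVProfile",
    "within_batch_scan",
    "count_split_configurations",
    "cv_profile",
    "cv_distribution",
    "top_variable_genes",
    "TABLE5_CV_EDGES",
]

# CV histogram bin edges: <0.01, 0.01-0.049, 0.05-0.059, ..., 0.1-0.199, >=0.2
TABLE5_CV_EDGES = (0.01, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.20)


@dataclass
class WithinScanResult:
    """Outcome of the permutation case/control scan under one factor."""

    factor_name: str
    n_perm: int
    counts: np.ndarray                 # DEG count per permutation
    eligible_batches: list
    case_assignments: list             # per permutation: frozenset of case samples
    n_probes: int
    alpha: float
    seed: int

    @property
    def max_count(self) -> int:
        return int(np.max(self.counts))

    @property
    def min_count(self) -> int:
        return int(np.min(self.counts))

    @property
    def max_pct(self) -> float:
        """Maximum DEG count as a percentage of the transcriptome."""
        return 100.0 * self.max_count / self.n_probes

    @property
    def argmax_cases(self) -> frozenset:
        return self.case_assignments[int(np.argmax(self.counts))]


_SCAN_STREAM = 0x5CA7


def within_batch_scan(matrix: ExpressionMatrix, batch_design: BatchDesign,
                      n_perm: int = 250, min_batch_size: int = 12,
                      alpha: float = 0.05, seed: int = 0,
                      adjust_method: str = "BH") -> WithinScanResult:
    """Random case/control splits within each eligible batch, batch-blocked.

    Only batches with at least ``min_batch_size`` samples take part (the
    floor keeps the number of distinct splits large enough that the
    permutations are essentially unique).  Odd batches give the case
    class floor(n/2) samples.  One global case/control factor is shared
    across batches within a permutation, so a single blocked model tests
    the class contrast over all eligible samples at once.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    batch_design = batch_design.restrict(matrix.sample_ids)
    sizes = batch_design.batch_sizes
    eligible = [b for b in batch_design.batches if sizes[b] >= min_batch_size]
    if not eligible:
        raise ValueError(
            f"no batch under factor {batch_design.factor_name!r} reaches the "
            f"size floor of {min_batch_size}"
        )
    samples = [s for b in eligible for s in sorted(batch_design.samples_in(b))]
    sub = matrix.subset_samples(samples)
    sub_design = batch_design.restrict(samples)
    counts = np.empty(n_perm, dtype=int)
    case_sets = []
    for r in range(n_perm):
        rng = np.random.default_rng([seed, _SCAN_STREAM, r])
        labels = {}
        for b in eligible:
            members = sorted(batch_design.samples_in(b))
            order = rng.permutation(len(members))
            n_case = len(members) // 2
            for rank, i in enumerate(order):
                labels[members[i]] = "case" if rank < n_case else "control"
        design = build_design(samples,
                              sub_design if len(eligible) > 1 else None,
                              class_labels=labels)
        fit = fit_genewise(sub, design)
        res = moderated_t(fit, estimate_ebayes(fit), "class[case]", adjust_method)
        counts[r] = count_degs(res, alpha)
        case_sets.append(frozenset(s for s, v in labels.items() if v == "case"))
    return WithinScanResult(batch_design.factor_name, n_perm, counts, eligible,
                            case_sets, matrix.n_probes, alpha, seed)


def count_split_configurations(n: int, min_size: int, max_size: int) -> int:
    """Number of labeled (case, control) splits with case size in [min, max]."""
    if not (0 < min_size <= max_size < n):
        raise ValueError(f"need 0 < min_size <= max_size < n, got ({n}, {min_size}, {max_size})")
    return sum(math.comb(n, k) for k in range(min_size, max_size + 1))


@dataclass
class CVProfile:
    """Per-probe within-batch mean intensity and CV, averaged over batches."""

    table: pd.DataFrame          # index probe_id; columns intensity, cv, n_batches
    per_batch_mean: pd.DataFrame  # probes x qualifying batches
    per_batch_cv: pd.DataFrame
    factor_name: str
    min_reps: int

    @property
    def probe_ids(self) -> list:
        return list(self.table.index)

    @property
    def grand_mean_cv(self) -> float:
        return float(self.table["cv"].mean())

    @property
    def grand_mean_intensity(self) -> float:
        return float(self.table["intensity"].mean())


def cv_profile(matrix: ExpressionMatrix, batch_design: BatchDesign,
               min_reps: int = 2) -> CVProfile:
    """Per-probe CV = s/m of log2 intensities within each qualifying batch.

    Batches with fewer than ``min_reps`` replicates are excluded from the
    average (not zero-filled).  The standard deviation uses the n-1
    (sample) convention; a non-positive within-batch mean intensity is an
    error because the CV is only meaningful on positive log2 values.
    """
    if min_reps < 2:
        raise ValueError("min_reps must be at least 2 (a standard deviation needs 2 values)")
    batch_design = batch_design.restrict(matrix.sample_ids)
    sizes = batch_design.batch_sizes
    qualifying = [b for b in batch_design.batches if sizes[b] >= min_reps]
    if not qualifying:
        raise ValueError(f"no batch under {batch_design.factor_name!r} has >= {min_reps} replicates")
    frame = matrix.to_frame()
    means, cvs = {}, {}
    for b in qualifying:
        block = frame[batch_design.samples_in(b)]
        m = block.mean(axis=1)
        if (m <= 0).any():
            probe = m.index[int(np.argmax((m <= 0).to_numpy()))]
            raise ValueError(
                f"non-positive within-batch mean for probe {probe!r} in batch {b!r}; "
                "CV profiling expects log2-scale intensities"
            )
        s = block.std(axis=1, ddof=1)
        means[b] = m
        cvs[b] = s / m
    per_batch_mean = pd.DataFrame(means)
    per_batch_cv = pd.DataFrame(cvs)
    table = pd.DataFrame({
        "intensity": per_batch_mean.mean(axis=1),
        "cv": per_batch_cv.mean(axis=1),
        "n_batches": len(qualifying),
    })
    table.index.name = "probe_id"
    return CVProfile(table, per_batch_mean, per_batch_cv, batch_design.factor_name, min_reps)


def cv_distribution(profile: CVProfile, bin_edges=TABLE5_CV_EDGES) -> pd.DataFrame:
    """Histogram of per-probe CVs with open-ended first and last bins."""
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    cv = profile.table["cv"].to_numpy()
    full = [-np.inf] + edges + [np.inf]
    labels = [f"<{edges[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels += [f">={edges[-1]:g}"]
    counts = np.histogram(cv, bins=full)[0]
    out = pd.DataFrame({"cv_range": labels, "count": counts})
    out["pct"] = 100.0 * out["count"] / max(len(cv), 1)
    return out


def top_variable_genes(profile: CVProfile, k: int) -> pd.DataFrame:
    """Top-k probes by CV (descending), ties broken by probe id; each row
    carries the probe's intensity for comparison against the global mean."""
    if k > len(profile.table):
        raise ValueError(f"k={k} exceeds {len(profile.table)} probes")
    ordered = profile.table.iloc[
        sorted(range(len(profile.table)),
               key=lambda i: (-profile.table["cv"].iloc[i], profile.table.index[i]))
    ]
    out = ordered.head(k)[["cv", "intensity"]].copy()
    out["below_global_mean"] = out["intensity"] < profile.grand_mean_intensity
    return out
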