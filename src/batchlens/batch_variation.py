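"""Between-batch variation measured by DEG counts.

Two reference schemes quantify how much untreated batches differ:

* simulated reference -- each batch's replicates are tested against a
  pseudo-sample group holding, for every gene, the mean of each batch
  (k pseudo-samples for k batches).  Because those k means carry the
  between-batch spread, the pooled variance is inflated and the test is
  the more conservative of the two.
* designated reference -- one batch is the common reference and every
  remaining batch is contrasted against it inside a single batch-blocked
  linear model (N-1 contrasts).

A permutation null of the designated scheme (labels shuffled, batch
sizes preserved, reference batch rotated cyclically across permutations)
yields empirical critical values for the mean DEG count per batch pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BatchDesign, ExpressionMatrix
from .linear_models import (
    EBayesParams,
    build_design,
    estimate_ebayes,
    fit_genewise,
    moderated_t,
)

__all__ = [
    "BetweenBatchResult",
    "PermutationNull",
    "simulated_reference",
    "between_batch_simulated",
    "between_batch_designated",
    "pool_degs",
    "permutation_null",
    "default_reference_batch",
]


@dataclass
class BetweenBatchResult:
    """Per-batch DEG counts under one factor and one reference scheme."""

    factor_name: str
    scheme: str                       # "simulated" | "designated"
    counts: dict                      # batch (or contrast batch) -> DEG count
    deg_sets: dict                    # batch -> set of probe ids
    n_probes: int
    alpha: float
    reference_batch: str = None       # designated scheme only

    @property
    def mean_count(self) -> float:
        return float(np.mean(list(self.counts.values())))

    @property
    def sd_count(self) -> float:
        vals = list(self.counts.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    @property
    def pooled_degs(self) -> set:
        return pool_degs(self.deg_sets.values())

    @property
    def pooled_fraction(self) -> float:
        return len(self.pooled_degs) / self.n_probes


def default_reference_batch(batch_design: BatchDesign) -> str:
    """Largest batch; ties broken lexicographically."""
    sizes = batch_design.batch_sizes
    return min(sizes, key=lambda b: (-sizes[b], b))


def simulated_reference(matrix: ExpressionMatrix, batch_design: BatchDesign) -> ExpressionMatrix:
    """One pseudo-sample per batch holding the per-gene batch mean."""
    batches = batch_design.batches
    if len(batches) < 2:
        raise ValueError(f"factor {batch_design.factor_name!r} has a single batch; nothing to compare")
    frame = matrix.to_frame()
    cols = [frame[batch_design.samples_in(b)].mean(axis=1) for b in batches]
    values = np.column_stack([c.to_numpy() for c in cols])
    return ExpressionMatrix(matrix.probe_ids, [f"ref::{b}" for b in batches], values, matrix.species)


def _is_constant(matrix: ExpressionMatrix) -> bool:
    # a matrix with no variation anywhere carries no evidence of DEGs
    return bool(np.ptp(matrix.values, axis=1).max() == 0.0)


def between_batch_simulated(matrix: ExpressionMatrix, batch_design: BatchDesign,
                            alpha: float = 0.05, adjust_method: str = "BH") -> BetweenBatchResult:
    """Each batch vs the k-pseudo-sample simulated reference (two-group moderated t)."""
    batch_design = batch_design.restrict(matrix.sample_ids)
    if _is_constant(matrix):
        zero = {b: set() for b in batch_design.batches}
        return BetweenBatchResult(batch_design.factor_name, "simulated",
                                  {b: 0 for b in zero}, zero, matrix.n_probes, alpha)
    reference = simulated_reference(matrix, batch_design)
    counts, deg_sets = {}, {}
    for batch in batch_design.batches:
        batch_samples = batch_design.samples_in(batch)
        sub = matrix.subset_samples(batch_samples)
        combined = ExpressionMatrix(
            matrix.probe_ids,
            batch_samples + reference.sample_ids,
            np.hstack([sub.values, reference.values]),
            matrix.species,
        )
        group = {s: "case" for s in batch_samples}
        group.update({s: "control" for s in reference.sample_ids})
        design = build_design(combined.sample_ids, class_labels=group)
        fit = fit_genewise(combined, design)
        res = moderated_t(fit, estimate_ebayes(fit), "class[case]", adjust_method)
        deg_sets[batch] = res.deg_set(alpha)
        counts[batch] = len(deg_sets[batch])
    return BetweenBatchResult(batch_design.factor_name, "simulated", counts, deg_sets,
                              matrix.n_probes, alpha)


def between_batch_designated(matrix: ExpressionMatrix, batch_design: BatchDesign,
                             reference_batch: str = None, alpha: float = 0.05,
                             adjust_method: str = "BH",
                             ebayes: EBayesParams = None) -> BetweenBatchResult:
    """N-1 contrasts of each batch vs a designated reference in one blocked GLM."""
    batch_design = batch_design.restrict(matrix.sample_ids)
    batches = batch_design.batches
    if len(batches) < 2:
        raise ValueError(f"factor {batch_design.factor_name!r} has a single batch; nothing to compare")
    if reference_batch is None:
        reference_batch = default_reference_batch(batch_design)
    if batch_design.batch_sizes.get(reference_batch, 0) < 2:
        raise ValueError(f"designated reference batch {reference_batch!r} has fewer than 2 samples")
    if _is_constant(matrix):
        zero = {b: set() for b in batches if b != reference_batch}
        return BetweenBatchResult(batch_design.factor_name, "designated",
                                  {b: 0 for b in zero}, zero, matrix.n_probes, alpha,
                                  reference_batch)
    design = build_design(matrix.sample_ids, batch_design, reference_batch=reference_batch)
    fit = fit_genewise(matrix, design)
    if ebayes is None:
        ebayes = estimate_ebayes(fit)
    counts, deg_sets = {}, {}
    for batch in batches:
        if batch == reference_batch:
            continue
        term = f"{batch_design.factor_name}[{batch}]"
        res = moderated_t(fit, ebayes, term, adjust_method)
        deg_sets[batch] = res.deg_set(alpha)
        counts[batch] = len(deg_sets[batch])
    return BetweenBatchResult(batch_design.factor_name, "designated", counts, deg_sets,
                              matrix.n_probes, alpha, reference_batch)


def pool_degs(deg_sets) -> set:
    """Non-redundant union of per-batch DEG sets for one factor."""
    pooled: set = set()
    for s in deg_sets:
        pooled |= set(s)
    return pooled


@dataclass
class PermutationNull:
    """Empirical null distribution of the mean DEG count per batch pair."""

    factor_name: str
    n_perm: int
    mean_counts: np.ndarray          # one mean-per-pair count per permutation
    critical_values: dict            # significance level -> empirical cutoff
    seed: int
    alpha: float
    alpha_levels: tuple = (0.05, 0.01, 0.001)

    def exceeds(self, observed: float, level: float = 0.05) -> bool:
        return observed > self.critical_values[level]


_PERM_STREAM = 0xBA7C  # namespaces permutation RNG streams within one seed


def permutation_null(matrix: ExpressionMatrix, batch_design: BatchDesign,
                     n_perm: int = 1000, alpha: float = 0.05,
                     alpha_levels=(0.05, 0.01, 0.001), seed: int = 0,
                     adjust_method: str = "BH") -> PermutationNull:
    """Permutation null of between-batch DEG counts (designated scheme).

    Per permutation: sample labels are globally shuffled while batch
    sizes are preserved, the reference batch advances cyclically
    (permutation r uses the r-mod-k-th batch), and the mean DEG count
    over the N-1 pairs is recorded.  Critical values are the empirical
    (1 - level) quantiles of those means.  Each permutation draws from
    an independent counter-derived stream, so results do not depend on
    execution order, probe order or sample order.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations for stable tail quantiles")
    batch_design = batch_design.restrict(matrix.sample_ids)
    batches = batch_design.batches
    sizes = batch_design.batch_sizes
    samples_sorted = sorted(matrix.sample_ids)
    means = np.empty(n_perm)
    for r in range(n_perm):
        rng = np.random.default_rng([seed, _PERM_STREAM, r])
        shuffled = list(rng.permutation(samples_sorted))
        assignment, start = {}, 0
        for b in batches:
            for s in shuffled[start:start + sizes[b]]:
                assignment[s] = b
            start += sizes[b]
        perm_design = BatchDesign(batch_design.factor_name, assignment)
        reference = batches[r % len(batches)]
        if sizes[reference] < 2:
            reference = default_reference_batch(perm_design)
        res = between_batch_designated(matrix, perm_design, reference, alpha, adjust_method)
        means[r] = res.mean_count
    critical = {lv: float(np.quantile(means, 1.0 - lv)) for lv in alpha_levels}
    return PermutationNull(batch_design.factor_name, n_perm, means, critical, seed,
                           alpha, tuple(alpha_levels))
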