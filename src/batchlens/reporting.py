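"""Visualization-ready summaries: PCA on pooled DEGs, bootstrap
hierarchical clustering with support values, and report assembly.

PCA uses singular value decomposition of the gene-centered DEG
submatrix, no scaling (expression is already on a common log2 scale
after quantile normalization); units are either individual samples or
per-batch means.  The dendrogram uses correlation distance (1 - Pearson)
with average linkage, and ordinary bootstrap proportions over
gene-resampled matrices ("BP" support) at each internal node.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import BatchDesign, ExpressionMatrix

__all__ = [
    "PcaResult",
    "BootstrapTree",
    "pca_on_degs",
    "bootstrap_dendrogram",
    "build_report",
]


@dataclass
class PcaResult:
    """Scores of units (samples or batch means) on principal components."""

    scores: pd.DataFrame               # units x components
    explained: np.ndarray              # explained-variance fractions, non-increasing
    unit_kind: str                     # "sample" | "batch-mean"
    components: np.ndarray             # genes x components (for projections)
    center: np.ndarray                 # per-gene mean removed before the SVD

    def project(self, values: np.ndarray) -> np.ndarray:
        """Project new unit columns (genes x units) onto the fitted axes."""
        return (values - self.center[:, None]).T @ self.components


def pca_on_degs(matrix: ExpressionMatrix, deg_set, by: str = "sample",
                batch_design: BatchDesign = None) -> PcaResult:
    """Mean-centered PCA restricted to the pooled-DEG rows."""
    degs = sorted(set(deg_set) & set(matrix.probe_ids))
    if not degs:
        raise ValueError("empty DEG set")
    sub = matrix.subset_probes(degs)
    if by == "sample":
        units = sub.sample_ids
        x = sub.values
    elif by == "batch-mean":
        if batch_design is None:
            raise ValueError("batch-mean mode needs a batch design")
        batch_design = batch_design.restrict(sub.sample_ids)
        units = batch_design.batches
        frame = sub.to_frame()
        x = np.column_stack([frame[batch_design.samples_in(b)].mean(axis=1) for b in units])
    else:
        raise ValueError(f"unknown unit kind {by!r}")
    center = x.mean(axis=1)
    xc = x - center[:, None]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    explained = (s**2 / total) if total > 0 else np.zeros_like(s)
    scores = vt.T * s                     # units x components
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(pd.DataFrame(scores, index=units, columns=cols),
                     explained, by, u, center)


@dataclass
class BootstrapTree:
    """Average-linkage dendrogram with bootstrap-proportion node supports."""

    linkage: np.ndarray
    leaf_ids: list
    supports: dict                      # frozenset of leaves -> support in [0, 100]
    n_boot: int
    distance: str = "correlation"
    linkage_method: str = "average"

    def clades(self) -> list:
        return _clades_from_linkage(self.linkage, self.leaf_ids)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.leaf_ids[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            leaves = frozenset(self.leaf_ids[i] for i in node.pre_order())
            support = self.supports.get(leaves)
            label = "" if support is None else f"{support:g}"
            return f"({left},{right}){label}:{node.dist:.6g}"

        return walk(tree) + ";"


def _clades_from_linkage(z: np.ndarray, leaf_ids) -> list:
    n = len(leaf_ids)
    members = {i: frozenset([leaf_ids[i]]) for i in range(n)}
    out = []
    for k, (i, j, _, _) in enumerate(z):
        merged = members[int(i)] | members[int(j)]
        members[n + k] = merged
        out.append(merged)
    return out


def _linkage_of(values: np.ndarray, distance: str, method: str) -> np.ndarray:
    d = pdist(values.T, metric=distance)
    d = np.nan_to_num(d, nan=1.0)  # constant units give undefined correlation
    return hierarchy.linkage(d, method=method)


def bootstrap_dendrogram(matrix: ExpressionMatrix, deg_set, n_boot: int = 100,
                         linkage: str = "average", distance: str = "correlation",
                         seed: int = 0) -> BootstrapTree:
    """Cluster samples on DEG rows; support = % of gene-bootstrap trees
    in which an internal node's exact leaf set recurs."""
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 units to cluster")
    if n_boot < 10:
        raise ValueError("need at least 10 bootstrap resamples")
    degs = sorted(set(deg_set) & set(matrix.probe_ids))
    if not degs:
        raise ValueError("empty DEG set")
    sub = matrix.subset_probes(degs)
    base = _linkage_of(sub.values, distance, linkage)
    base_clades = _clades_from_linkage(base, sub.sample_ids)
    hits = {c: 0 for c in base_clades}
    rng = np.random.default_rng([seed, 0xB001])
    n_genes = sub.n_probes
    for _ in range(n_boot):
        rows = rng.integers(0, n_genes, size=n_genes)
        z = _linkage_of(sub.values[rows], distance, linkage)
        for c in _clades_from_linkage(z, sub.sample_ids):
            if c in hits:
                hits[c] += 1
    supports = {c: 100.0 * h / n_boot for c, h in hits.items()}
    return BootstrapTree(base, sub.sample_ids, supports, n_boot, distance, linkage)


_REQUIRED_ARTIFACTS = {
    "between_simulated": "between-batch DEG counts (simulated reference)",
    "between_designated": "between-batch DEG counts (designated reference)",
    "within_scan": "within-batch permutation scan",
    "cv_profile": "per-probe CV/intensity profile",
}


def build_report(run_artifacts: dict, out_dir, seed: int = None,
                 config_digest: str = None) -> dict:
    """Assemble the standard output bundle from upstream results.

    ``run_artifacts`` must hold ``between_simulated`` and
    ``between_designated`` (factor -> BetweenBatchResult),
    ``within_scan`` (factor -> WithinScanResult) and ``cv_profile``
    (species -> CVProfile); optional keys ``permutation_null``,
    ``gene_correlation``, ``pathway_correlation`` and ``pca`` add the
    corresponding files.  Writes four table-shaped TSVs plus plot-data
    TSVs and a JSON manifest; returns path names by artifact.
    """
    missing = [k for k in _REQUIRED_ARTIFACTS if k not in run_artifacts]
    if missing:
        raise ValueError("missing artifact(s): "
                         + ", ".join(f"{k} ({_REQUIRED_ARTIFACTS[k]})" for k in missing))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    for key in ("between_simulated", "between_designated"):
        rows = []
        for factor, res in run_artifacts[key].items():
            rows.append({"factor": factor, "mean_degs": res.mean_count,
                         "sd_degs": res.sd_count, "n_batches": len(res.counts) + (res.scheme == "designated"),
                         "pooled_degs": len(res.pooled_degs),
                         "pooled_fraction": res.pooled_fraction,
                         "reference": res.reference_batch or ""})
        path = out_dir / f"table_{key}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written[key] = str(path)

    rows = []
    for factor, scan in run_artifacts["within_scan"].items():
        rows.append({"factor": factor, "max_degs": scan.max_count,
                     "max_pct": scan.max_pct, "min_degs": scan.min_count,
                     "n_perm": scan.n_perm})
    path = out_dir / "table_within_scan.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written["within_scan"] = str(path)

    from .within_variation import cv_distribution
    for species, profile in run_artifacts["cv_profile"].items():
        dist = cv_distribution(profile)
        path = out_dir / f"table_cv_distribution_{species}.tsv"
        dist.to_csv(path, sep="\t", index=False)
        written[f"cv_distribution_{species}"] = str(path)
        path = out_dir / f"plotdata_cv_vs_intensity_{species}.tsv"
        profile.table[["intensity", "cv"]].to_csv(path, sep="\t")
        written[f"cv_vs_intensity_{species}"] = str(path)

    if "permutation_null" in run_artifacts:
        null = run_artifacts["permutation_null"]
        path = out_dir / "plotdata_permutation_null.tsv"
        pd.DataFrame({"mean_degs_per_pair": null.mean_counts}).to_csv(path, sep="\t", index=False)
        written["permutation_null"] = str(path)
        written["critical_values"] = {str(k): v for k, v in null.critical_values.items()}

    for key in ("gene_correlation", "pathway_correlation"):
        if key in run_artifacts:
            path = out_dir / f"plotdata_{key}.tsv"
            frame = run_artifacts[key]
            (frame if isinstance(frame, pd.DataFrame) else pd.DataFrame(frame)).to_csv(path, sep="\t")
            written[key] = str(path)

    manifest = {"seed": seed, "config_digest": config_digest, "artifacts": written}
    manifest["manifest_digest"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    written["manifest"] = str(out_dir / "manifest.json")
    return written
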