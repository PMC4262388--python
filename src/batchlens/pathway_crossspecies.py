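"""Gene- and pathway-level conservation of expression variability.

Duplicate probes are first consolidated to genes (unweighted probe
means) through the ortholog map, giving per-gene (intensity, CV)
profiles in each species.  Pathway summaries average member genes and
carry cross-species Pearson correlations of the member values; the
conservation analyses then correlate the two species at gene level
(all shared orthologs) and at pathway level (pathways passing the
minimum-ortholog and member-correlation-p filters).  A hypergeometric
gene-set enrichment test stands in for an external annotation service
when asking whether a DEG set concentrates in particular pathways.

Correlations are Pearson throughout (Spearman available by flag), with
simple ordinary-least-squares regressions, Shapiro-Wilk residual
normality checks, and a reproducible outlier rule: externally
studentized residuals |r| > 3 from a first-pass fit, applied once.
Undefined correlations (zero variance among members) are flagged and
excluded from correlation-based lists, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OrthologMap, PathwaySet
from .linear_models import adjust_pvalues
from .within_variation import CVProfile

__all__ = [
    "GeneProfile",
    "CorrelationResult",
    "consolidate_probes",
    "pathway_summaries",
    "intra_species_regression",
    "interspecies_gene_correlation",
    "interspecies_pathway_correlation",
    "enrichment_test",
]


@dataclass
class GeneProfile:
    """Per-gene mean intensity and CV consolidated from member probes."""

    table: pd.DataFrame      # index gene_id; columns intensity, cv, n_probes
    species: str = ""

    @property
    def gene_ids(self) -> set:
        return set(self.table.index)


def consolidate_probes(profile: CVProfile, ortholog_map: OrthologMap,
                       side: str = "a", strict: bool = True,
                       species: str = "") -> GeneProfile:
    """Collapse duplicate probes to genes by unweighted probe means."""
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    index = ortholog_map.probe_to_gene_a if side == "a" else ortholog_map.probe_to_gene_b
    genes = []
    for p in profile.probe_ids:
        if p not in index:
            if strict:
                raise KeyError(f"probe {p!r} has no gene in the ortholog map (side {side!r})")
            genes.append(None)
        else:
            genes.append(index[p])
    work = profile.table.copy()
    work["gene_id"] = genes
    work = work.dropna(subset=["gene_id"])
    grouped = work.groupby("gene_id").agg(
        intensity=("intensity", "mean"), cv=("cv", "mean"), n_probes=("cv", "size"))
    return GeneProfile(grouped, species)


def pathway_summaries(profile_a: GeneProfile, profile_b: GeneProfile,
                      pathways: PathwaySet, min_genes: int = 5) -> pd.DataFrame:
    """Per-pathway averages and member-gene cross-species correlations.

    One row per pathway: ortholog count (genes present in both species'
    profiles), plain-mean averages of CV and intensity per species, the
    Pearson correlation of member-gene values between species for each
    metric with its two-sided p, and inclusion flags.  Pathways with
    fewer than ``min_genes`` shared orthologs are flagged excluded;
    zero-variance member sets leave the correlation undefined (NaN).
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway set")
    shared = profile_a.gene_ids & profile_b.gene_ids
    rows = []
    for pw, members in sorted(pathways.items()):
        genes = sorted(members & shared)
        row = {"pathway_id": pw, "n_orthologs": len(genes),
               "included": len(genes) >= min_genes}
        for metric in ("cv", "intensity"):
            if genes:
                va = profile_a.table.loc[genes, metric].to_numpy()
                vb = profile_b.table.loc[genes, metric].to_numpy()
                row[f"{metric}_a"] = float(np.mean(va))
                row[f"{metric}_b"] = float(np.mean(vb))
                if len(genes) >= 3 and np.ptp(va) > 0 and np.ptp(vb) > 0:
                    cc, p = stats.pearsonr(va, vb)
                    row[f"member_cc_{metric}"] = float(cc)
                    row[f"member_p_{metric}"] = float(p)
                else:
                    row[f"member_cc_{metric}"] = np.nan
                    row[f"member_p_{metric}"] = np.nan
            else:
                for key in (f"{metric}_a", f"{metric}_b",
                            f"member_cc_{metric}", f"member_p_{metric}"):
                    row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway_id")


@dataclass
class CorrelationResult:
    """Correlation + simple linear regression with residual diagnostics."""

    cc: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    normality_p: float
    n: int
    excluded: list = field(default_factory=list)
    method: str = "pearson"


def _studentized_outliers(x: np.ndarray, y: np.ndarray, ids, threshold: float = 3.0):
    """Externally studentized residuals from a first-pass OLS fit."""
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = OLSInfluence(model).resid_studentized_external
    return [i for i, r in zip(ids, resid) if abs(r) > threshold]


def _correlate(x, y, ids, method: str = "pearson",
               outlier_rule: str = "studentized3") -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = list(ids)
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    excluded: list = []
    if outlier_rule == "studentized3" and x.size > 3:
        excluded = _studentized_outliers(x, y, ids)
        if excluded and x.size - len(excluded) >= 3:
            keep = [i for i, g in enumerate(ids) if g not in set(excluded)]
            x, y, ids = x[keep], y[keep], [ids[i] for i in keep]
        else:
            excluded = []
    elif outlier_rule not in ("studentized3", "none"):
        raise ValueError(f"unknown outlier rule {outlier_rule!r}")
    if method == "pearson":
        cc, p = stats.pearsonr(x, y)
    elif method == "spearman":
        cc, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    if x.size >= 3 and np.ptp(resid) > 0:
        normality_p = float(stats.shapiro(resid).pvalue)
    else:
        normality_p = np.nan
    pearson_cc = stats.pearsonr(x, y)[0]
    return CorrelationResult(float(cc), float(p), float(slope), float(intercept),
                             float(pearson_cc**2), normality_p, int(x.size),
                             excluded, method)


def intra_species_regression(summaries: pd.DataFrame, species: str,
                             response: str = "cv", predictor: str = "intensity",
                             outlier_rule: str = "studentized3",
                             method: str = "pearson") -> CorrelationResult:
    """Regress per-pathway average response on predictor within one species."""
    if species not in ("a", "b"):
        raise ValueError("species must be 'a' or 'b'")
    sub = summaries[summaries["included"]]
    x = sub[f"{predictor}_{species}"]
    y = sub[f"{response}_{species}"]
    ok = x.notna() & y.notna()
    return _correlate(x[ok], y[ok], list(sub.index[ok]), method, outlier_rule)


def interspecies_gene_correlation(profile_a: GeneProfile, profile_b: GeneProfile,
                                  metric: str = "cv",
                                  method: str = "pearson") -> CorrelationResult:
    """Correlate the two species over all shared orthologs for one metric."""
    shared = sorted(profile_a.gene_ids & profile_b.gene_ids)
    if not shared:
        raise ValueError("no shared genes between the two profiles")
    x = profile_a.table.loc[shared, metric]
    y = profile_b.table.loc[shared, metric]
    return _correlate(x, y, shared, method, outlier_rule="none")


def interspecies_pathway_correlation(summaries: pd.DataFrame, metric: str = "cv",
                                     include_p: float = 0.1,
                                     outlier_rule: str = "studentized3",
                                     method: str = "pearson") -> CorrelationResult:
    """Correlate per-pathway species averages over conserved pathways.

    Only pathways that pass the minimum-ortholog filter and whose
    member-gene correlation for ``metric`` is defined with p <=
    ``include_p`` take part.
    """
    if not (0.0 < include_p <= 1.0):
        raise ValueError(f"include_p must lie in (0, 1], got {include_p}")
    mask = (summaries["included"]
            & summaries[f"member_p_{metric}"].notna()
            & (summaries[f"member_p_{metric}"] <= include_p))
    sub = summaries[mask]
    if len(sub) == 0:
        raise ValueError("no pathway passes the inclusion filters")
    return _correlate(sub[f"{metric}_a"], sub[f"{metric}_b"], list(sub.index),
                      method, outlier_rule)


def enrichment_test(deg_set, pathways: PathwaySet, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a DEG set per pathway, BH-adjusted."""
    deg_set = set(deg_set)
    universe = set(universe)
    if not deg_set:
        raise ValueError("empty DEG set")
    if not deg_set <= universe:
        raise ValueError("DEG set must be a subset of the universe")
    rows = []
    for pw, members in sorted(pathways.items()):
        in_universe = members & universe
        overlap = in_universe & deg_set
        p = stats.hypergeom.sf(len(overlap) - 1, len(universe), len(in_universe), len(deg_set))
        rows.append({"pathway_id": pw, "n_pathway": len(in_universe),
                     "n_overlap": len(overlap), "p": float(p)})
    out = pd.DataFrame(rows).set_index("pathway_id")
    out["adj_p"] = adjust_pvalues(out["p"].to_numpy(), "BH")
    return out
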