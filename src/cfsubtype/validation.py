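"""Marker validation: fragment fold-change reproducibility, array-based
differential testing, and promoter-level expression association.

Three independent checks of a marker catalog: (1) direction-consistent
fold change of normalized qualifying-read counts in an independent
fragment cohort; (2) per-region two-sample t tests on probe-averaged beta
values with Benjamini-Hochberg correction; (3) genes whose promoters
overlap markers, scored by the fraction differentially expressed against
500 random same-size gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import normalized_count_table
from .types import BetaMatrix, Marker, Region, SampleFragments, TpmMatrix, ValidationError

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_OVERLAP = 0.5
DEFAULT_ALPHA = 0.05


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# 1. fold-change reproducibility in an independent fragment cohort
# ---------------------------------------------------------------------------

def fold_change_reproducibility(
    markers: list[Marker],
    cohort: list[SampleFragments],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_cpgs: int = 1,
) -> tuple[pd.DataFrame, float]:
    """Per-marker fold change of mean normalized qualifying counts.

    A marker reproduces when (target mean + pseudocount) / (other mean +
    pseudocount) exceeds ``fc_threshold`` — qualifying reads are enriched
    in the marker's target class for hypo and hyper markers alike.
    Returns the per-marker table and the reproduced fraction.
    """
    labels = np.array([s.label for s in cohort])
    for cls in ("LUAD", "LUSC"):
        if not (labels == cls).any():
            raise ValidationError(f"independent cohort lacks {cls} samples")
    norm = normalized_count_table(cohort, markers, min_cpgs=min_cpgs)
    rows = []
    for m in markers:
        col = norm[m.marker_id].to_numpy()
        target_mean = col[labels == m.target_class].mean()
        other = "LUSC" if m.target_class == "LUAD" else "LUAD"
        other_mean = col[labels == other].mean()
        fc = (target_mean + pseudocount) / (other_mean + pseudocount)
        rows.append((m.marker_id, target_mean, other_mean, fc, fc > fc_threshold))
    table = pd.DataFrame(
        rows, columns=["marker_id", "target_mean", "other_mean",
                       "fold_change", "consistent"]
    ).set_index("marker_id")
    fraction = float(table["consistent"].mean()) if len(table) else float("nan")
    return table, fraction


# ---------------------------------------------------------------------------
# 2. 450K-style probe-to-region differential testing
# ---------------------------------------------------------------------------

def map_probes_to_regions(
    probes: pd.DataFrame, regions: list[Region]
) -> pd.Series:
    """Assign probes (chrom, pos) to the half-open region containing them.

    Probes outside every region are omitted from the returned mapping.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    pieces = []
    for chrom, group in probes.groupby("chrom", sort=False):
        rs = sorted(by_chrom.get(chrom, []), key=lambda r: r.start)
        if not rs:
            continue
        starts = np.array([r.start for r in rs])
        ends = np.array([r.end for r in rs])
        ids = np.array([r.region_id for r in rs], dtype=object)
        pos = group["pos"].to_numpy(np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        pieces.append(
            pd.Series(ids[idx[inside]], index=group.index[inside], dtype=object)
        )
    if not pieces:
        return pd.Series(dtype=object, name="region_id")
    out = pd.concat(pieces)
    out.name = "region_id"
    return out


def region_beta(beta: BetaMatrix, assignment: pd.Series) -> pd.DataFrame:
    """Region x sample matrix: unweighted mean beta of assigned probes.

    Regions with no assigned probe are omitted, never zero-filled.
    """
    probes = assignment.index.intersection(beta.values.index)
    if not len(probes):
        return pd.DataFrame(columns=beta.values.columns)
    sub = beta.values.loc[probes]
    return sub.groupby(assignment.loc[probes]).mean()


def differential_test_450k(
    region_beta_matrix: pd.DataFrame,
    labels: pd.Series,
    markers: list[Marker],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Equal-variance t tests per marker region with BH correction.

    A marker is *consistent* when its adjusted p is below ``alpha`` and
    the mean beta difference matches the marker's direction (target class
    lower for hypo, higher for hyper).  Zero variance in both groups gives
    p = 1 by convention.
    """
    lab = labels.loc[region_beta_matrix.columns].to_numpy()
    rows = []
    for m in markers:
        if m.region_id not in region_beta_matrix.index:
            continue
        vals = region_beta_matrix.loc[m.region_id].to_numpy(float)
        target = vals[lab == m.target_class]
        other = vals[lab != m.target_class]
        if len(target) < 2 or len(other) < 2:
            raise ValidationError("differential test needs >= 2 samples per class")
        t, p = stats.ttest_ind(target, other, equal_var=True)
        if not np.isfinite(p):
            t, p = 0.0, 1.0
        delta = float(target.mean() - other.mean())
        rows.append((m.marker_id, m.region_id, m.direction, t, p, delta))
    table = pd.DataFrame(
        rows, columns=["marker_id", "region_id", "direction", "t", "p", "delta"]
    ).set_index("marker_id")
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        direction_ok = np.where(
            table["direction"] == "hypo", table["delta"] < 0, table["delta"] > 0
        )
        table["consistent"] = (table["p_adj"] < alpha) & direction_ok
    else:
        table["p_adj"] = []
        table["consistent"] = []
    return table


# ---------------------------------------------------------------------------
# 3. promoter association and differential-expression empirical p
# ---------------------------------------------------------------------------

def associate_genes(
    markers: list[Marker],
    marker_regions: dict[str, Region],
    promoters: pd.DataFrame,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Marker-gene pairs whose promoter covers > ``min_overlap`` of the
    marker interval (strict).  Many-to-many associations are allowed.

    The overlap denominator is the marker length: promoters are typically
    far longer than the ~117 bp regions, so fraction-of-marker is the
    generically satisfiable reading.
    """
    rows = []
    for m in markers:
        region = marker_regions.get(m.region_id)
        if region is None:
            continue
        for gene_id, prom in promoters.iterrows():
            if prom["chrom"] != region.chrom:
                continue
            overlap = min(region.end, prom["end"]) - max(region.start, prom["start"])
            if overlap <= 0:
                continue
            frac = overlap / region.length
            if frac > min_overlap:
                rows.append((m.marker_id, gene_id, frac))
    return pd.DataFrame(rows, columns=["marker_id", "gene_id", "overlap_fraction"])


def de_empirical_p(
    tpm: TpmMatrix,
    labels: pd.Series,
    gene_set: list[str],
    n_random: int = 500,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    plus_one: bool = False,
) -> tuple[float, float]:
    """Fraction of DE genes in ``gene_set`` and its empirical p value.

    DE per gene: two-sided equal-variance t test on ln(TPM + 1) with BH
    correction across all genes, significant below ``alpha``.  The
    empirical p is the share of ``n_random`` uniformly drawn same-size
    gene sets whose DE fraction is at least the observed one (``plus_one``
    switches to the conservative (r+1)/(n+1) estimator).
    """
    if not gene_set:
        raise ValidationError("empty gene set")
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    missing = set(gene_set) - set(tpm.values.index)
    if missing:
        raise ValidationError(f"gene set not in matrix: {sorted(missing)[:3]}")
    lab = labels.loc[tpm.values.columns].to_numpy()
    classes = sorted(pd.unique(lab))
    if len(classes) != 2:
        raise ValidationError("need exactly two classes for DE testing")
    X = np.log1p(tpm.values.to_numpy(float))
    a, b = X[:, lab == classes[0]], X[:, lab == classes[1]]
    _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.nan_to_num(p, nan=1.0)
    de = bh_adjust(p) < alpha
    de_by_gene = pd.Series(de, index=tpm.values.index)

    fraction_de = float(de_by_gene.loc[gene_set].mean())
    rng = np.random.default_rng(seed)
    all_genes = tpm.values.index.to_numpy()
    n_at_least = 0
    for _ in range(n_random):
        pick = rng.choice(all_genes, size=len(gene_set), replace=False)
        if de_by_gene.loc[pick].mean() >= fraction_de:
            n_at_least += 1
    if plus_one:
        empirical_p = (n_at_least + 1) / (n_random + 1)
    else:
        empirical_p = n_at_least / n_random
    return fraction_de, float(empirical_p)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    fraction_reproduced_fragment: float = float("nan")
    fraction_significant_450k: float = float("nan")
    associated_genes: list[str] = field(default_factory=list)
    fraction_de: float = float("nan")
    empirical_p: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "fraction_reproduced_fragment": self.fraction_reproduced_fragment,
            "fraction_significant_450k": self.fraction_significant_450k,
            "associated_genes": self.associated_genes,
            "fraction_de": self.fraction_de,
            "empirical_p": self.empirical_p,
        }


def validate_markers(
    markers: list[Marker],
    independent_cohort: list[SampleFragments] | None = None,
    beta: BetaMatrix | None = None,
    beta_labels: pd.Series | None = None,
    regions: list[Region] | None = None,
    tpm: TpmMatrix | None = None,
    tpm_labels: pd.Series | None = None,
    promoters: pd.DataFrame | None = None,
    n_random: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Run whichever validation stages the supplied inputs allow."""
    report = ValidationReport()
    if independent_cohort:
        _, report.fraction_reproduced_fragment = fold_change_reproducibility(
            markers, independent_cohort
        )
    if beta is not None and regions is not None:
        labels = beta_labels if beta_labels is not None else beta.labels
        assignment = map_probes_to_regions(beta.probes, regions)
        rb = region_beta(beta, assignment)
        table = differential_test_450k(rb, labels, markers)
        report.fraction_significant_450k = (
            float(table["consistent"].mean()) if len(table) else float("nan")
        )
    if tpm is not None and promoters is not None and regions is not None:
        region_map = {r.region_id: r for r in regions}
        assoc = associate_genes(markers, region_map, promoters)
        genes = sorted(set(assoc["gene_id"]))
        report.associated_genes = genes
        if genes:
            labels = tpm_labels if tpm_labels is not None else tpm.labels
            report.fraction_de, report.empirical_p = de_empirical_p(
                tpm, labels, genes, n_random=n_random, seed=seed
            )
    return report
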