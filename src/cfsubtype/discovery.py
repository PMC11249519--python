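"""Fragment-based discovery of subtype-specific methylation markers.

For each region and each of the four (target class, direction) cells the
scan chooses an alpha-value threshold over the *observed* fragment alphas:
a sample qualifies when it contains at least ``min_fragments`` fragments
with alpha <= threshold (hypo) or >= threshold (hyper, both inclusive).
A region is a candidate when some threshold leaves fewer than two
qualifying samples of the other subtype; among admissible thresholds the
scan maximises the number of qualifying target-class samples and breaks
ties toward the more extreme threshold.  Candidates seen in more than 20%
of noncancer plasma samples are removed, and each cell keeps the top-k
candidates by target support, ties included.

The exhaustive search over observed alphas collapses to order statistics:
a sample's qualification at any threshold depends only on its
``min_fragments``-th most extreme alpha in the region, so the optimal
threshold is the largest target order statistic lying strictly below the
second-smallest other-class statistic (mirrored for hypermethylation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Fragment, Marker, SampleFragments, ValidationError

DEFAULT_MIN_CPGS = 3
DEFAULT_TOP_K = 2500
DEFAULT_MAX_BG_FRACTION = 0.2
MAX_N_OTHER = 2  # candidate constraint: n_other < 2

CELLS = tuple(
    (cls, direction) for cls in ("LUAD", "LUSC") for direction in ("hypo", "hyper")
)


def alpha_value(fragment: Fragment) -> float:
    """Fraction of methylated CpGs on one fragment."""
    if fragment.n_cpgs == 0:
        raise ValidationError("fragment has zero CpGs")
    return fragment.n_methylated / fragment.n_cpgs


def sample_qualifies(
    sample: SampleFragments,
    region_id: str,
    threshold: float,
    direction: str,
    min_fragments: int = 1,
    min_cpgs: int = 1,
) -> bool:
    """Does the sample contain qualifying fragments at this threshold?"""
    alphas = sample.region_alphas(region_id, min_cpgs=min_cpgs)
    if direction == "hypo":
        n = int((alphas <= threshold).sum())
    elif direction == "hyper":
        n = int((alphas >= threshold).sum())
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return n >= min_fragments


@dataclass(frozen=True)
class ScanResult:
    alpha_threshold: float
    n_target: int
    n_other: int


def _order_stat(alphas: np.ndarray, direction: str, min_fragments: int) -> float:
    """Per-sample qualification statistic; NaN when not enough fragments."""
    if len(alphas) < min_fragments:
        return np.nan
    s = np.sort(alphas)
    if direction == "hypo":
        return float(s[min_fragments - 1])
    return float(s[len(s) - min_fragments])


def _scan_stats(
    t_stats: np.ndarray, o_stats: np.ndarray, direction: str
) -> ScanResult | None:
    """Optimal threshold from per-sample order statistics (see module doc)."""
    if direction == "hyper":
        res = _scan_stats(-t_stats, -o_stats, "hypo")
        if res is None:
            return None
        return ScanResult(-res.alpha_threshold, res.n_target, res.n_other)
    t = np.sort(t_stats[np.isfinite(t_stats)])
    if t.size == 0:
        return None
    o = np.sort(o_stats[np.isfinite(o_stats)])
    m2 = o[1] if o.size >= 2 else np.inf
    idx = int(np.searchsorted(t, m2, side="left")) - 1
    if idx < 0:
        return None
    alpha_star = float(t[idx])
    n_other = int(np.searchsorted(o, alpha_star, side="right"))
    return ScanResult(alpha_star, idx + 1, n_other)


def scan_thresholds(
    region_id: str,
    target_samples: list[SampleFragments],
    other_samples: list[SampleFragments],
    direction: str,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_fragments: int = 1,
) -> ScanResult | None:
    """Best admissible threshold for one region, or None.

    Evaluates every distinct observed fragment alpha as a candidate
    threshold, keeps those with fewer than two qualifying other-class
    samples, maximises the number of qualifying target samples, and breaks
    ties toward the more extreme threshold.
    """
    if not target_samples or not other_samples:
        raise ValidationError("scan requires non-empty target and other cohorts")
    t_stats = np.array(
        [
            _order_stat(s.region_alphas(region_id, min_cpgs), direction, min_fragments)
            for s in target_samples
        ]
    )
    o_stats = np.array(
        [
            _order_stat(s.region_alphas(region_id, min_cpgs), direction, min_fragments)
            for s in other_samples
        ]
    )
    return _scan_stats(t_stats, o_stats, direction)


# ---------------------------------------------------------------------------
# vectorised cohort machinery
# ---------------------------------------------------------------------------

def _cohort_stat_matrices(
    cohort: list[SampleFragments],
    region_index: pd.Index,
    min_cpgs: int,
    min_fragments: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(lo, hi) matrices of per-(region, sample) order statistics.

    ``lo[r, s]`` is sample s's ``min_fragments``-th smallest alpha in
    region r (+inf when absent); ``hi`` the mirrored statistic (-inf).
    """
    n_regions, n_samples = len(region_index), len(cohort)
    lo = np.full((n_regions, n_samples), np.inf)
    hi = np.full((n_regions, n_samples), -np.inf)
    for si, sample in enumerate(cohort):
        f = sample.frame
        keep = f["n_cpgs"].to_numpy() >= min_cpgs
        col = f["region_id"]
        if isinstance(col.dtype, pd.CategoricalDtype):
            # translate small category table instead of materialising strings
            cat_codes = region_index.get_indexer(col.cat.categories)
            codes = cat_codes[col.cat.codes.to_numpy()][keep]
        else:
            codes = region_index.get_indexer(col.to_numpy()[keep])
        alphas = (
            f["n_methylated"].to_numpy(float)[keep]
            / f["n_cpgs"].to_numpy(float)[keep]
        )
        valid = codes >= 0
        codes, alphas = codes[valid], alphas[valid]
        if codes.size == 0:
            continue
        order = np.lexsort((alphas, codes))
        codes, alphas = codes[order], alphas[order]
        starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        sizes = np.diff(np.r_[starts, codes.size])
        ok = sizes >= min_fragments
        grp_codes = codes[starts[ok]]
        lo[grp_codes, si] = alphas[starts[ok] + (min_fragments - 1)]
        hi[grp_codes, si] = alphas[starts[ok] + sizes[ok] - min_fragments]
    return lo, hi


def _scan_cell(
    target_stats: np.ndarray, other_stats: np.ndarray, direction: str
) -> pd.DataFrame:
    """Vectorised `_scan_stats` over all regions of one cell."""
    if direction == "hyper":
        t = np.sort(np.where(np.isfinite(target_stats), -target_stats, np.inf), axis=1)
        o = np.sort(np.where(np.isfinite(other_stats), -other_stats, np.inf), axis=1)
    else:
        t, o = np.sort(target_stats, axis=1), np.sort(other_stats, axis=1)
    m2 = o[:, 1] if o.shape[1] >= 2 else np.full(len(o), np.inf)
    n_target = (t < m2[:, None]).sum(axis=1)
    hit = n_target >= 1
    rows = np.flatnonzero(hit)
    alpha_star = t[rows, n_target[rows] - 1]
    n_other = (o[rows] <= alpha_star[:, None]).sum(axis=1)
    if direction == "hyper":
        alpha_star = -alpha_star
    return pd.DataFrame(
        {
            "row": rows,
            "alpha_threshold": alpha_star,
            "n_target": n_target[rows],
            "n_other": n_other,
        }
    )


def apply_background_filter(
    candidates: list[Marker],
    noncancer_plasma: list[SampleFragments],
    max_fraction: float = DEFAULT_MAX_BG_FRACTION,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_fragments: int = 1,
) -> list[Marker]:
    """Drop candidates qualifying in too many noncancer plasma samples.

    ``bg_fraction`` is set on every candidate; a candidate is removed iff
    the fraction strictly exceeds ``max_fraction``.
    """
    if not noncancer_plasma:
        raise ValidationError("noncancer plasma cohort is empty")
    kept = []
    n = len(noncancer_plasma)
    for m in candidates:
        hits = sum(
            sample_qualifies(
                s, m.region_id, m.alpha_threshold, m.direction,
                min_fragments=min_fragments, min_cpgs=min_cpgs,
            )
            for s in noncancer_plasma
        )
        m.bg_fraction = hits / n
        if m.bg_fraction <= max_fraction:
            kept.append(m)
    return kept


def rank_and_select(
    candidates: list[Marker], k: int = DEFAULT_TOP_K, strict: bool = False
) -> list[Marker]:
    """Top-k candidates of one cell by target support, ties included.

    Sorting is by descending ``n_target`` with ``region_id`` as the
    deterministic secondary key.  All candidates tied with the k-th
    ``n_target`` value are included unless ``strict`` is set, in which
    case exactly ``min(k, len(candidates))`` are returned.
    """
    ordered = sorted(candidates, key=lambda m: (-m.n_target, m.region_id))
    if k < len(ordered) and not strict:
        cutoff = ordered[k - 1].n_target
        selected = [m for m in ordered if m.n_target >= cutoff]
    else:
        selected = ordered[:k]
    for rank, m in enumerate(selected, start=1):
        m.rank = rank
    return selected


@dataclass
class DiscoveryResult:
    cells: dict[tuple[str, str], list[Marker]] = field(default_factory=dict)

    @property
    def combined(self) -> list[Marker]:
        out: list[Marker] = []
        for cell in CELLS:
            out.extend(self.cells.get(cell, []))
        return out

    def __len__(self) -> int:
        return len(self.combined)


def discover_markers(
    luad_tissue: list[SampleFragments],
    lusc_tissue: list[SampleFragments],
    noncancer_plasma: list[SampleFragments],
    k: int = DEFAULT_TOP_K,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_fragments: int = 1,
    max_bg_fraction: float = DEFAULT_MAX_BG_FRACTION,
    strict_k: bool = False,
) -> DiscoveryResult:
    """Run the four marker-discovery cells and assemble the catalog."""
    for name, cohort in (
        ("LUAD tissue", luad_tissue),
        ("LUSC tissue", lusc_tissue),
        ("noncancer plasma", noncancer_plasma),
    ):
        if not cohort:
            raise ValidationError(f"{name} cohort is empty")

    all_ids: list[np.ndarray] = []
    for cohort in (luad_tissue, lusc_tissue, noncancer_plasma):
        for s in cohort:
            all_ids.append(np.asarray(s.frame["region_id"].unique(), dtype=object))
    region_index = pd.Index(np.unique(np.concatenate(all_ids)))

    mats = {
        "LUAD": _cohort_stat_matrices(luad_tissue, region_index, min_cpgs, min_fragments),
        "LUSC": _cohort_stat_matrices(lusc_tissue, region_index, min_cpgs, min_fragments),
    }
    nc_lo, nc_hi = _cohort_stat_matrices(
        noncancer_plasma, region_index, min_cpgs, min_fragments
    )
    nc_lo_sorted = np.sort(nc_lo, axis=1)
    nc_hi_sorted = np.sort(nc_hi, axis=1)
    n_nc = len(noncancer_plasma)

    result = DiscoveryResult()
    for cls, direction in CELLS:
        other = "LUSC" if cls == "LUAD" else "LUAD"
        axis = 0 if direction == "hypo" else 1
        cand = _scan_cell(mats[cls][axis], mats[other][axis], direction)
        cand = cand[cand["n_other"] < MAX_N_OTHER]
        if direction == "hypo":
            bg = (
                nc_lo_sorted[cand["row"].to_numpy()]
                <= cand["alpha_threshold"].to_numpy()[:, None]
            ).sum(axis=1)
        else:
            bg = (
                nc_hi_sorted[cand["row"].to_numpy()]
                >= cand["alpha_threshold"].to_numpy()[:, None]
            ).sum(axis=1)
        bg_fraction = bg / n_nc
        keep = bg_fraction <= max_bg_fraction
        markers = [
            Marker(
                region_id=str(region_index[row.row]),
                target_class=cls,
                direction=direction,
                alpha_threshold=float(row.alpha_threshold),
                n_target=int(row.n_target),
                n_other=int(row.n_other),
                bg_fraction=float(frac),
            )
            for row, frac in zip(
                cand[keep].itertuples(index=False), bg_fraction[keep]
            )
        ]
        selected = rank_and_select(markers, k=k, strict=strict_k)
        for m in selected:
            m.check_invariants(max_bg_fraction=max_bg_fraction,
                               max_n_other=MAX_N_OTHER)
        result.cells[(cls, direction)] = selected
    return result
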