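"""Synthetic fragment-level methylomes with planted subtype markers.

The generator produces the statistical structure the analysis assumes
without any real data: a region catalog whose background methylation is
bimodal (most of the genome is stably hypo- or hypermethylated), planted
subtype-specific regions carrying an alternative methylation component,
tissue cohorts diluted by tumor purity and subclonal carrier fraction, and
plasma cohorts that are tumor-fraction mixtures over a noncancer
background.  Per-fragment methylation is beta-binomial: the CpGs of one
molecule are correlated, which is exactly what makes fragment-level alpha
values separate mixture components that per-CpG averages blur.

None of the generator parameters come from the study being emulated; they
are module defaults chosen so the planted signal is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Region, SampleFragments, ValidationError

PROFILE_COLUMNS = (
    "region_id", "chrom", "start", "end", "n_cpgs",
    "m_bg", "kappa", "planted", "m_alt", "phi", "direction", "target_class",
)

#: Exponential scale such that 20 + Exp(scale) truncated below 350 has mean
#: close to 117 bp (matches the real enriched-region length scale).
_LENGTH_SCALE = 119.0
_MIN_LENGTH = 20
_MAX_LENGTH = 349

# background methylation mixture: mostly stably methylated, a smaller
# stably unmethylated mode, and a thin intermediate slab
_BG_WEIGHTS = (0.55, 0.35, 0.10)
_BG_COMPONENTS = ((25.5, 4.5), (4.5, 25.5), (10.0, 10.0))

_CELLS = tuple(
    (cls, direction) for cls in ("LUAD", "LUSC") for direction in ("hypo", "hyper")
)


@dataclass
class CohortConfig:
    """Shared knobs of one simulated cohort."""

    n_per_class: int
    seed: int
    depth: float = 50.0  # mean fragments per region per sample
    cpg_range: tuple[int, int] = (4, 12)
    purity: float = 1.0  # tumor-cell fraction in tissue
    tumor_fraction: float = 0.0  # tumor-derived cfDNA fraction in plasma

    def __post_init__(self) -> None:
        for name in ("purity", "tumor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        lo, hi = self.cpg_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid cpg_range {self.cpg_range}")


def generate_region_catalog(
    n_regions: int,
    seed: int,
    kappa: float = 30.0,
) -> pd.DataFrame:
    """Region catalog plus per-region methylation profiles.

    Returns a profile table (one row per region) holding both the genomic
    interval and the beta-binomial background parameters.  Lengths are
    drawn from a truncated exponential with mean close to 117 bp and all
    strictly below 350 bp; the whole draw is deterministic given ``seed``.
    """
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)

    # rejection-free truncated exponential via inverse CDF
    span = _MAX_LENGTH - _MIN_LENGTH
    u = rng.random(n_regions)
    tail = np.exp(-span / _LENGTH_SCALE)
    lengths = _MIN_LENGTH + np.floor(
        -_LENGTH_SCALE * np.log(1.0 - u * (1.0 - tail))
    ).astype(int)
    lengths = np.clip(lengths, _MIN_LENGTH, _MAX_LENGTH)

    gaps = rng.integers(50, 500, size=n_regions)
    starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lengths[:-1])))
    ends = starts + lengths

    comp = rng.choice(len(_BG_WEIGHTS), size=n_regions, p=_BG_WEIGHTS)
    a = np.array([c[0] for c in _BG_COMPONENTS])[comp]
    b = np.array([c[1] for c in _BG_COMPONENTS])[comp]
    m_bg = rng.beta(a, b)

    n_cpgs = np.maximum(2, np.round(lengths * 0.09).astype(int))

    return pd.DataFrame(
        {
            "region_id": [f"simr{i:06d}" for i in range(n_regions)],
            "chrom": "chrSim1",
            "start": starts,
            "end": ends,
            "n_cpgs": n_cpgs,
            "m_bg": m_bg,
            "kappa": kappa,
            "planted": False,
            "m_alt": np.nan,
            "phi": 0.0,
            "direction": "",
            "target_class": "",
        }
    )


def profiles_to_regions(profiles: pd.DataFrame) -> list[Region]:
    return [
        Region(row.chrom, int(row.start), int(row.end), row.region_id,
               int(row.n_cpgs))
        for row in profiles.itertuples(index=False)
    ]


def plant_markers(
    profiles: pd.DataFrame,
    n_per_class_per_direction: int,
    m_alt: float = 0.1,
    phi: float = 0.3,
    seed: int = 0,
    hypo_min_bg: float = 0.8,
    hyper_max_bg: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant subtype-specific regions; returns (profiles, truth ledger).

    For each of the four (class, direction) cells, ``n`` regions are marked
    with an alternative fragment component.  Hypomethylation markers are
    planted on stably methylated background (``m_bg >= hypo_min_bg``) with
    alternative mean ``m_alt``; hypermethylation markers mirror this on
    unmethylated background with alternative mean ``1 - m_alt``.  ``phi``
    is the carrier fraction of the alternative component within tumor.
    """
    if phi <= 0.0 or phi > 1.0:
        raise ValidationError(f"carrier fraction phi must be in (0, 1], got {phi}")
    if not 0.0 < m_alt < 1.0:
        raise ValidationError("m_alt must be inside (0, 1)")
    rng = np.random.default_rng(seed)
    out = profiles.copy()
    truth_rows = []
    for cls, direction in _CELLS:
        if direction == "hypo":
            eligible = out.index[(~out["planted"]) & (out["m_bg"] >= hypo_min_bg)]
            alt = m_alt
        else:
            eligible = out.index[(~out["planted"]) & (out["m_bg"] <= hyper_max_bg)]
            alt = 1.0 - m_alt
        if len(eligible) < n_per_class_per_direction:
            raise ValidationError(
                f"only {len(eligible)} regions eligible for {cls}-{direction}, "
                f"need {n_per_class_per_direction}"
            )
        chosen = rng.choice(eligible, size=n_per_class_per_direction, replace=False)
        out.loc[chosen, ["planted", "m_alt", "phi"]] = True, alt, phi
        out.loc[chosen, ["direction", "target_class"]] = direction, cls
        for idx in chosen:
            truth_rows.append((out.at[idx, "region_id"], cls, direction))
    truth = pd.DataFrame(truth_rows, columns=["region_id", "target_class", "direction"])
    return out, truth


def simulate_sample(
    profiles: pd.DataFrame,
    config: CohortConfig,
    label: str,
    material: str,
    seed: int,
    sample_id: str = "S0",
    region_indices: np.ndarray | None = None,
) -> SampleFragments:
    """Draw one sample's fragments from the per-region mixture model.

    Per region the fragment count is Poisson(depth).  Each fragment is
    tumor-derived with probability ``purity`` (tissue) or
    ``tumor_fraction`` (plasma); tumor fragments on a region planted for
    the sample's own class come from the alternative component with
    probability ``phi``.  ``region_indices`` restricts simulation to a
    subset of the catalog (the genome-wide ``total_fragments`` still
    accounts for the full catalog).
    """
    if label == "noncancer" and material == "tissue":
        raise ValidationError("noncancer cohorts are plasma-only in this model")
    rng = np.random.default_rng(seed)
    n_total_regions = len(profiles)
    if region_indices is None:
        sub = profiles
    else:
        sub = profiles.iloc[np.asarray(region_indices)]

    counts = rng.poisson(config.depth, size=len(sub))
    ridx = np.repeat(np.arange(len(sub)), counts)
    n = len(ridx)

    lo, hi = config.cpg_range
    n_cpgs = rng.integers(lo, hi + 1, size=n)

    m_bg = sub["m_bg"].to_numpy()[ridx]
    kappa = sub["kappa"].to_numpy()[ridx]
    m = m_bg.copy()
    if label in ("LUAD", "LUSC"):
        p_tumor = config.purity if material == "tissue" else config.tumor_fraction
        if p_tumor > 0:
            is_tumor = rng.random(n) < p_tumor
            planted = sub["planted"].to_numpy()[ridx]
            target = sub["target_class"].to_numpy()[ridx]
            phi = sub["phi"].to_numpy()[ridx]
            m_alt = sub["m_alt"].to_numpy()[ridx]
            is_alt = is_tumor & planted & (target == label) & (rng.random(n) < phi)
            m = np.where(is_alt, m_alt, m_bg)

    m = np.clip(m, 1e-4, 1.0 - 1e-4)
    p = rng.beta(m * kappa, (1.0 - m) * kappa)
    n_meth = rng.binomial(n_cpgs, p)

    total = n
    if region_indices is not None and n_total_regions > len(sub):
        total += int(rng.poisson(config.depth * (n_total_regions - len(sub))))
    total = max(total, 1)

    # categorical region ids + narrow ints keep large cohorts compact
    frame = pd.DataFrame(
        {
            "region_id": pd.Categorical.from_codes(
                ridx, categories=sub["region_id"].tolist()
            ),
            "n_cpgs": n_cpgs.astype(np.int16),
            "n_methylated": n_meth.astype(np.int16),
        }
    )
    return SampleFragments(sample_id, label, material, total, frame)


def simulate_cohort(
    profiles: pd.DataFrame,
    config: CohortConfig,
    label: str,
    material: str,
    n: int,
    seed: int,
    prefix: str | None = None,
    region_indices: np.ndarray | None = None,
) -> list[SampleFragments]:
    """Simulate ``n`` independent samples with reproducible child seeds."""
    prefix = prefix or f"{label}_{material}"
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    return [
        simulate_sample(
            profiles, config, label, material,
            seed=int(child_seeds[i]),
            sample_id=f"{prefix}_{i:03d}",
            region_indices=region_indices,
        )
        for i in range(n)
    ]


def generate_validation_matrices(
    profiles: pd.DataFrame,
    truth: pd.DataFrame,
    seed: int,
    n_per_class: int = 50,
    purity: float = 0.6,
    phi: float = 0.3,
    beta_sd: float = 0.05,
    n_extra_probe_regions: int = 200,
    tpm_effect: float = 1.0,
    n_null_genes: int = 200,
):
    """Matched 450K-style beta and TPM matrices for the validation stages.

    Probes are placed inside every planted region plus a random subset of
    unplanted ones; per-sample beta is the mixture mean of the region for
    that sample's class plus Gaussian noise, clipped to [0, 1].  One gene
    is created per planted marker with its promoter equal to the marker
    interval, and its expression is anti-correlated with promoter
    methylation (hypomethylated in a class => higher TPM in that class);
    null genes get promoters on unplanted regions and no class effect.

    Returns ``(BetaMatrix, TpmMatrix, promoters, labels)``.
    """
    from .types import BetaMatrix, TpmMatrix

    rng = np.random.default_rng(seed)
    samples = [f"T_LUAD_{i:03d}" for i in range(n_per_class)] + [
        f"T_LUSC_{i:03d}" for i in range(n_per_class)
    ]
    labels = pd.Series(
        ["LUAD"] * n_per_class + ["LUSC"] * n_per_class, index=samples
    )

    planted_idx = profiles.index[profiles["planted"]].to_numpy()
    unplanted_idx = profiles.index[~profiles["planted"]].to_numpy()
    extra = rng.choice(
        unplanted_idx,
        size=min(n_extra_probe_regions, len(unplanted_idx)),
        replace=False,
    )
    probe_regions = np.concatenate([planted_idx, np.sort(extra)])

    probe_rows = []
    beta_rows = []
    for idx in probe_regions:
        row = profiles.loc[idx]
        pos = int(rng.integers(row.start, row.end))
        probe_id = f"cg_{row.region_id}"
        probe_rows.append((probe_id, row.chrom, pos))
        mu = np.full(len(samples), row.m_bg)
        if row.planted:
            shifted = labels.to_numpy() == row.target_class
            mu_alt = (1.0 - purity * phi) * row.m_bg + purity * phi * row.m_alt
            mu = np.where(shifted, mu_alt, mu)
        beta_rows.append(np.clip(mu + rng.normal(0.0, beta_sd, len(samples)), 0, 1))

    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos"]
    ).set_index("probe_id")
    beta = BetaMatrix(
        values=pd.DataFrame(beta_rows, index=probes.index, columns=samples),
        probes=probes,
        labels=labels,
    )

    prom_rows = []
    ln_rows = []
    gene_ids = []
    by_region = profiles.set_index("region_id")
    for rec in truth.itertuples(index=False):
        row = by_region.loc[rec.region_id]
        gene = f"gene_{rec.region_id}"
        gene_ids.append(gene)
        prom_rows.append((gene, row.chrom, int(row.start), int(row.end)))
        base = rng.normal(3.0, 0.5)
        sign = 1.0 if rec.direction == "hypo" else -1.0
        effect = np.where(labels.to_numpy() == rec.target_class, sign * tpm_effect, 0.0)
        ln_rows.append(base + effect + rng.normal(0.0, 0.4, len(samples)))
    null_regions = rng.choice(
        unplanted_idx, size=min(n_null_genes, len(unplanted_idx)), replace=False
    )
    for idx in null_regions:
        row = profiles.loc[idx]
        gene = f"gene_{row.region_id}"
        gene_ids.append(gene)
        prom_rows.append((gene, row.chrom, int(row.start), int(row.end)))
        ln_rows.append(rng.normal(3.0, 0.5) + rng.normal(0.0, 0.4, len(samples)))

    promoters = pd.DataFrame(
        prom_rows, columns=["gene_id", "chrom", "start", "end"]
    ).set_index("gene_id")
    tpm = TpmMatrix(
        values=pd.DataFrame(np.exp(ln_rows), index=gene_ids, columns=samples),
        promoters=promoters,
        labels=labels,
    )
    return beta, tpm, promoters, labels


@dataclass
class DiscoveryBenchmark:
    """A self-contained planted-truth benchmark for marker discovery."""

    profiles: pd.DataFrame
    truth: pd.DataFrame
    luad: list[SampleFragments]
    lusc: list[SampleFragments]
    noncancer: list[SampleFragments]


def make_discovery_benchmark(
    seed: int,
    n_regions: int = 10_000,
    n_planted_per_cell: int = 50,
    n_per_class: int = 30,
    n_noncancer: int = 30,
    depth: float = 50.0,
    purity: float = 0.6,
    phi: float = 0.3,
    m_alt: float = 0.1,
) -> DiscoveryBenchmark:
    """Tissue cohorts + noncancer plasma with a planted-marker ledger.

    The defaults reproduce the parameter-recovery setting used by the
    acceptance suite: 30 tissue samples per subtype at depth 50, 200
    planted regions among 10,000 (50 per class and direction), purity 0.6,
    carrier fraction 0.3, stably methylated background around 0.85 for the
    hypomethylation cells (mirrored for the hypermethylation cells).
    """
    ss = np.random.SeedSequence(seed).generate_state(5)
    profiles = generate_region_catalog(n_regions, seed=int(ss[0]))
    profiles, truth = plant_markers(
        profiles, n_planted_per_cell, m_alt=m_alt, phi=phi, seed=int(ss[1])
    )
    tissue_cfg = CohortConfig(
        n_per_class=n_per_class, seed=seed, depth=depth, purity=purity
    )
    plasma_cfg = CohortConfig(
        n_per_class=n_noncancer, seed=seed, depth=depth, tumor_fraction=0.0
    )
    luad = simulate_cohort(profiles, tissue_cfg, "LUAD", "tissue",
                           n_per_class, seed=int(ss[2]))
    lusc = simulate_cohort(profiles, tissue_cfg, "LUSC", "tissue",
                           n_per_class, seed=int(ss[3]))
    noncancer = simulate_cohort(profiles, plasma_cfg, "noncancer", "plasma",
                                n_noncancer, seed=int(ss[4]))
    return DiscoveryBenchmark(profiles, truth, luad, lusc, noncancer)
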