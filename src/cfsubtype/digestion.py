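"""In-silico MspI digestion of a genome into the enriched-region catalog.

MspI cuts C^CGG.  Every CCGG occurrence therefore yields one cut point,
placed between the first C and the CGG (offset ``match_start + 1``).  A
candidate region spans two adjacent cut points on the same chromosome and
is retained when strictly shorter than ``max_len`` (350 bp by default).
CCGG is its own reverse complement, so a single-strand scan is complete.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .types import Region, ValidationError

MSPI_SITE = "CCGG"
DEFAULT_MAX_LEN = 350

_SITE_RE = re.compile(r"(?=CCGG)")  # lookahead: overlapping hits all reported


@dataclass(frozen=True)
class CutSite:
    chrom: str
    pos: int  # 0-based cut point: between C and CGG of the CCGG occurrence


@dataclass
class DigestionSummary:
    n_regions: int
    mean_length: float
    n_with_n_bases: int = 0


def find_cut_sites(sequence: str, chrom: str) -> list[CutSite]:
    """All MspI cut points in ``sequence``, sorted by position.

    Matching is case-insensitive so that soft-masked genome FASTAs behave
    identically to upper-case ones.
    """
    seq = sequence.upper()
    return [CutSite(chrom, m.start() + 1) for m in _SITE_RE.finditer(seq)]


def build_regions(
    cut_sites: list[CutSite],
    max_len: int = DEFAULT_MAX_LEN,
    sequence: str | None = None,
) -> list[Region]:
    """Regions between adjacent cut points, keeping lengths ``< max_len``.

    ``sequence`` (the chromosome the cut sites came from) is optional; when
    given, each region is annotated with its CpG count and an N-content flag.
    """
    regions: list[Region] = []
    seq = sequence.upper() if sequence is not None else None
    for a, b in zip(cut_sites, cut_sites[1:]):
        if a.chrom != b.chrom:
            raise ValidationError("cut sites from different chromosomes")
        if b.pos <= a.pos:
            raise ValidationError("cut sites must be sorted by position")
        if b.pos - a.pos >= max_len:
            continue
        n_cpgs = None
        contains_n = False
        if seq is not None:
            sub = seq[a.pos:b.pos + 3]  # include trailing CGG context
            n_cpgs = sub.count("CG")
            contains_n = "N" in seq[a.pos:b.pos]
        regions.append(
            Region(
                chrom=a.chrom,
                start=a.pos,
                end=b.pos,
                region_id=f"{a.chrom}:{a.pos}-{b.pos}",
                n_cpgs=n_cpgs,
                contains_n=contains_n,
            )
        )
    return regions


def digest_sequences(
    sequences: dict[str, str],
    max_len: int = DEFAULT_MAX_LEN,
    drop_n: bool = False,
) -> tuple[list[Region], DigestionSummary]:
    """Digest a mapping of chromosome name -> sequence."""
    regions: list[Region] = []
    for chrom, seq in sequences.items():
        cuts = find_cut_sites(seq, chrom)
        regions.extend(build_regions(cuts, max_len=max_len, sequence=seq))
    if drop_n:
        regions = [r for r in regions if not r.contains_n]
    lengths = np.array([r.length for r in regions], dtype=float)
    summary = DigestionSummary(
        n_regions=len(regions),
        mean_length=float(lengths.mean()) if len(regions) else float("nan"),
        n_with_n_bases=sum(r.contains_n for r in regions),
    )
    return regions, summary


def digest_genome(
    fasta_path: str,
    max_len: int = DEFAULT_MAX_LEN,
    drop_n: bool = False,
) -> tuple[list[Region], DigestionSummary]:
    """Digest a genome FASTA file (streamed chromosome by chromosome)."""
    from pyfaidx import Fasta

    try:
        fa = Fasta(fasta_path, rebuild=True)
    except Exception as exc:  # pragma: no cover - error path
        raise ValidationError(f"cannot read FASTA {fasta_path!r}: {exc}") from exc

    regions: list[Region] = []
    n_with_n = 0
    total_len = 0.0
    for name in fa.keys():
        seq = str(fa[name][:])
        cuts = find_cut_sites(seq, name)
        chrom_regions = build_regions(cuts, max_len=max_len, sequence=seq)
        if drop_n:
            chrom_regions = [r for r in chrom_regions if not r.contains_n]
        n_with_n += sum(r.contains_n for r in chrom_regions)
        total_len += sum(r.length for r in chrom_regions)
        regions.extend(chrom_regions)
    summary = DigestionSummary(
        n_regions=len(regions),
        mean_length=total_len / len(regions) if regions else float("nan"),
        n_with_n_bases=n_with_n,
    )
    return regions, summary
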