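"""Readers and writers for on-disk artifacts.

Formats are all plain text: BED for region catalogs, TSV for fragment
tables and marker catalogs, CSV for beta/TPM matrices and features, JSON
for merged-marker catalogs and reports.  Coordinates are BED-style on disk
and 0-based half-open in memory (they are the same thing).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BetaMatrix,
    Marker,
    MergedMarker,
    Region,
    SampleFragments,
    TpmMatrix,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# region catalogs (BED 3-5)
# ---------------------------------------------------------------------------

def read_region_catalog(path: str | Path) -> list[Region]:
    """Read a BED-like region catalog (chrom, start, end[, id[, n_cpgs]])."""
    regions: list[Region] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            region_id = fields[3] if len(fields) > 3 and fields[3] else (
                f"{chrom}:{start}-{end}"
            )
            n_cpgs = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    n_cpgs = int(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer n_cpgs") from exc
            try:
                region = Region(chrom, start, end, region_id, n_cpgs)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if region_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate region_id {region_id!r}")
            seen.add(region_id)
            regions.append(region)
    return regions


def write_region_catalog(regions: list[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            n_cpgs = "." if r.n_cpgs is None else str(r.n_cpgs)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{n_cpgs}\n")


# ---------------------------------------------------------------------------
# fragment tables
# ---------------------------------------------------------------------------
#
# One row = one fragment (optional multiplicity column).  Per-sample
# metadata (total mapped fragments, label, material) travels in sidecar
# header lines of the form:
#   #sample<TAB>sample_id<TAB>total_fragments<TAB>label<TAB>material

_SAMPLE_META_PREFIX = "#sample\t"
_FRAGMENT_HEADER = ("sample_id", "region_id", "n_cpgs", "n_methylated")


def write_fragment_table(samples: list[SampleFragments], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(
                f"#sample\t{s.sample_id}\t{s.total_fragments}\t{s.label}\t{s.material}\n"
            )
        fh.write("\t".join(_FRAGMENT_HEADER) + "\n")
        for s in samples:
            f = s.frame
            ids = f["region_id"].astype(str).to_numpy()
            n_cpgs = f["n_cpgs"].to_numpy()
            n_meth = f["n_methylated"].to_numpy()
            for rid, nc, nm in zip(ids, n_cpgs, n_meth):
                fh.write(f"{s.sample_id}\t{rid}\t{nc}\t{nm}\n")


def read_fragment_table(path: str | Path) -> list[SampleFragments]:
    """Read a per-molecule fragment TSV with #sample sidecar metadata."""
    meta: dict[str, tuple[int, str, str]] = {}
    rows_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    lineno = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(_SAMPLE_META_PREFIX):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: malformed #sample line")
            _, sid, total, label, material = parts
            try:
                meta[sid] = (int(total), label, material)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer total") from exc
        elif line.startswith("#"):
            continue
        else:
            rows_start = lineno
            break
    header = lines[rows_start - 1].rstrip("\n").split("\t") if lines else []
    if tuple(header[:4]) != _FRAGMENT_HEADER:
        raise ParseError(f"{path}: missing fragment table header")
    has_count = len(header) > 4 and header[4] == "count"

    records: dict[str, list[tuple[str, int, int]]] = {sid: [] for sid in meta}
    for lineno, line in enumerate(lines[rows_start:], start=rows_start + 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        sid, rid = parts[0], parts[1]
        try:
            n_cpgs, n_meth = int(parts[2]), int(parts[3])
            count = int(parts[4]) if has_count and len(parts) > 4 else 1
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed fragment row") from exc
        if not 0 <= n_meth <= n_cpgs or n_cpgs < 1:
            raise ParseError(
                f"{path}:{lineno}: n_methylated={n_meth} invalid for n_cpgs={n_cpgs}"
            )
        if sid not in records:
            raise ParseError(f"{path}:{lineno}: sample {sid!r} has no #sample metadata")
        records[sid].extend([(rid, n_cpgs, n_meth)] * count)

    samples = []
    for sid, (total, label, material) in meta.items():
        frame = pd.DataFrame(
            records[sid], columns=["region_id", "n_cpgs", "n_methylated"]
        )
        samples.append(SampleFragments(sid, label, material, total, frame))
    return samples


# ---------------------------------------------------------------------------
# beta / TPM matrices
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    kind: str,
    meta_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> BetaMatrix | TpmMatrix:
    """Read a feature x sample CSV matrix as a beta or TPM matrix.

    ``meta_path`` optionally supplies probe coordinates (probe_id, chrom,
    pos) for beta matrices or promoter intervals (gene_id, chrom, start,
    end) for TPM matrices; ``labels_path`` a (sample_id, label) CSV.
    """
    if kind not in ("beta", "tpm"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    values = pd.read_csv(path, index_col=0)
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, index_col=0)
        labels = lab.iloc[:, 0]
    if kind == "beta":
        probes = None
        if meta_path is not None:
            probes = pd.read_csv(meta_path, index_col=0)
        return BetaMatrix(values=values, probes=probes, labels=labels)
    promoters = None
    if meta_path is not None:
        promoters = pd.read_csv(meta_path, index_col=0)
    return TpmMatrix(values=values, promoters=promoters, labels=labels)


def write_matrix(matrix: BetaMatrix | TpmMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path)


# ---------------------------------------------------------------------------
# markers / merged markers / features
# ---------------------------------------------------------------------------

MARKER_COLUMNS = (
    "region_id",
    "class",
    "direction",
    "alpha_threshold",
    "n_target",
    "n_other",
    "bg_fraction",
    "rank",
)


def write_markers(markers: list[Marker], path: str | Path) -> None:
    rows = [
        (
            m.region_id,
            m.target_class,
            m.direction,
            m.alpha_threshold,
            m.n_target,
            m.n_other,
            m.bg_fraction,
            -1 if m.rank is None else m.rank,
        )
        for m in markers
    ]
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t")
    markers = []
    for row in df.itertuples(index=False):
        rank = None if row.rank < 0 else int(row.rank)
        markers.append(
            Marker(
                region_id=str(row.region_id),
                target_class=row[1],
                direction=row.direction,
                alpha_threshold=float(row.alpha_threshold),
                n_target=int(row.n_target),
                n_other=int(row.n_other),
                bg_fraction=float(row.bg_fraction),
                rank=rank,
            )
        )
    return markers


def write_merged_markers(merged: list[MergedMarker], path: str | Path) -> None:
    payload = [
        {
            "merged_id": m.merged_id,
            "class": m.target_class,
            "direction": m.direction,
            "members": list(m.members),
        }
        for m in merged
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_merged_markers(path: str | Path) -> list[MergedMarker]:
    payload = json.loads(Path(path).read_text())
    return [
        MergedMarker(
            merged_id=item["merged_id"],
            target_class=item["class"],
            direction=item["direction"],
            members=tuple(item["members"]),
        )
        for item in payload
    ]


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_hm450_manifest(path: str | Path) -> pd.DataFrame:
    """Probe coordinates from a HumanMethylation450 manifest CSV.

    Accepts either the Illumina manifest (header section skipped, columns
    ``IlmnID``/``CHR``/``MAPINFO`` with 1-based coordinates and a trailing
    [Controls] section) or a plain CSV with columns probe_id, chrom, pos
    (0-based).  Returns a frame indexed by probe_id with chrom and 0-based
    pos columns.
    """
    with open(path) as fh:
        head = [fh.readline() for _ in range(10)]
    simple_header = head[0].strip().split(",")[:3]
    if simple_header == ["probe_id", "chrom", "pos"]:
        return pd.read_csv(path, index_col=0)
    skip = next(
        (i for i, line in enumerate(head) if line.startswith("IlmnID")), 0
    )
    df = pd.read_csv(
        path,
        skiprows=skip,
        usecols=["IlmnID", "CHR", "MAPINFO"],
        dtype={"CHR": str},
        low_memory=False,
    )
    df = df.dropna(subset=["CHR", "MAPINFO"])
    chrom = df["CHR"].astype(str)
    chrom = np.where(chrom.str.startswith("chr"), chrom, "chr" + chrom)
    out = pd.DataFrame(
        {
            "probe_id": df["IlmnID"],
            "chrom": chrom,
            "pos": df["MAPINFO"].astype(np.int64) - 1,  # manifest is 1-based
        }
    )
    return out.set_index("probe_id")


# ---------------------------------------------------------------------------
# promoters / CNA inputs
# ---------------------------------------------------------------------------

def read_promoters(path: str | Path) -> pd.DataFrame:
    """BED-like promoter file: chrom, start, end, gene_id."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            rows.append((fields[3], fields[0], start, end))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return df.set_index("gene_id")


def read_cna_bins(path: str | Path) -> pd.DataFrame:
    """Per-bin copy-number table: chrom, start, end, log2_ratio (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "log2_ratio"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
    if (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: bin with end <= start")
    return df
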