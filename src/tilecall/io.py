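"""Readers, writers and spot-level quality control for two-color arrays.

The pipeline's on-disk dialects are deliberately plain text:

* **Spot tables** — tab-separated with header columns
  ``probe_id, chrom, start, end, ch1_fg, ch1_bg, ch2_fg, ch2_bg, flag``;
  the parsed equivalent of one GenePix-quantified spot per row.  An
  optional first line ``#coordinates=1-based-inclusive`` marks files in
  1-based inclusive convention; their ``start`` is shifted by −1 on read.
  Internally everything is 0-based half-open.
* **Gene annotation** — BED6+ (``thickStart`` column, when present, is the
  TSS) or GFF-lite (9 columns, ``ID=`` attribute names the gene).
* **Regions** — BED6, score column = max enrichment × 1000, capped at 1000.
* **Gene sets** — GMT.

Quality control follows the standard reliability rule for scanned spots:
keep a spot only if, in both channels, the foreground is at least twice
the local background, below the scanner saturation level, and the spot is
not flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SPOT_COLUMNS = [
    "probe_id", "chrom", "start", "end",
    "ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg", "flag",
]

_INTENSITY_COLS = ["ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg"]

#: scanner convention: 16-bit intensity ceiling
DEFAULT_SATURATION = 65535


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


def read_spot_table(path, channel_roles=None) -> pd.DataFrame:
    """Read a spot-intensity TSV into a spot table.

    Parameters
    ----------
    path : str or file-like
        Tab-separated file with the documented 9-column header.
    channel_roles : dict, optional
        Mapping like ``{"ch1": "IP", "ch2": "input"}`` recorded in
        ``DataFrame.attrs["channel_roles"]``.

    Raises
    ------
    FormatError
        On a missing column, an unparseable or negative intensity, or a
        non-positive interval; messages carry 1-based data row numbers.
    """
    one_based = False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "1-based" in first:
                one_based = True
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")

    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spot table missing required column(s): {missing}")

    for col in _INTENSITY_COLS + ["start", "end"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise FormatError(
                f"non-numeric value in column '{col}' at data row(s) "
                f"{[int(i) + 1 for i in bad[:5]]}"
            )
        df[col] = vals
    neg = df[_INTENSITY_COLS].lt(0).any(axis=1)
    if neg.any():
        rows = [int(i) + 1 for i in np.flatnonzero(neg.to_numpy())[:5]]
        raise FormatError(f"negative intensity at data row(s) {rows}")

    df = df[SPOT_COLUMNS].copy()
    if one_based:
        df["start"] = df["start"] - 1
    if (df["end"] <= df["start"]).any():
        rows = [int(i) + 1 for i in
                np.flatnonzero((df["end"] <= df["start"]).to_numpy())[:5]]
        raise FormatError(f"end must exceed start at data row(s) {rows}")
    df["flag"] = df["flag"].astype(int).astype(bool)
    df.attrs["channel_roles"] = dict(channel_roles or {"ch1": "sample", "ch2": "reference"})
    return df


def write_spot_table(spots: pd.DataFrame, path) -> None:
    out = spots[SPOT_COLUMNS].copy()
    out["flag"] = out["flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def qc_filter_spots(spots: pd.DataFrame,
                    saturation_level: int = DEFAULT_SATURATION) -> pd.DataFrame:
    """Keep spots that are reliable in *both* channels.

    A spot survives iff, per channel, foreground ≥ 2 × local background
    (inclusive at exactly 2×) and foreground < ``saturation_level``, and
    the spot is unflagged.  Row order is preserved; idempotent.
    """
    ok = (
        (spots["ch1_fg"] >= 2 * spots["ch1_bg"])
        & (spots["ch2_fg"] >= 2 * spots["ch2_bg"])
        & (spots["ch1_fg"] < saturation_level)
        & (spots["ch2_fg"] < saturation_level)
        & ~spots["flag"].astype(bool)
    )
    out = spots.loc[ok].copy()
    out.attrs = dict(spots.attrs)
    return out


def background_subtract(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract local background per channel, flooring at 1 count.

    Adds ``ch1_net`` and ``ch2_net`` columns; the floor keeps log ratios
    finite for spots whose signal barely clears background.
    """
    out = spots.copy()
    out["ch1_net"] = np.maximum(spots["ch1_fg"] - spots["ch1_bg"], 1.0)
    out["ch2_net"] = np.maximum(spots["ch2_fg"] - spots["ch2_bg"], 1.0)
    out.attrs = dict(spots.attrs)
    return out


def load_qc_spots(path, channel_roles=None,
                  saturation_level: int = DEFAULT_SATURATION) -> pd.DataFrame:
    """Read, QC-filter and background-subtract a spot table in one step."""
    spots = read_spot_table(path, channel_roles=channel_roles)
    return background_subtract(qc_filter_spots(spots, saturation_level))


# ---------------------------------------------------------------------------
# gene annotation

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss", "orf_start", "orf_end"]


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene annotation from BED6+ or GFF-lite.

    BED is taken as 0-based half-open; a 7th column (thickStart) overrides
    the TSS, otherwise the TSS is ``start`` on + and ``end`` on −.  GFF
    coordinates (1-based inclusive) are converted on read.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 9 and not fields[1].isdigit():
                rows.append(_parse_gff_row(fields, lineno))
            elif len(fields) >= 6:
                rows.append(_parse_bed_row(fields, lineno))
            else:
                raise FormatError(
                    f"line {lineno}: expected BED6+ or 9-column GFF, "
                    f"got {len(fields)} fields"
                )
    if not rows:
        raise FormatError(f"no annotation records in {path}")
    ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if (ann["orf_start"] >= ann["orf_end"]).any():
        raise FormatError("annotation with orf_start >= orf_end")
    return ann


def _check_strand(strand, lineno):
    if strand not in ("+", "-"):
        raise FormatError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")


def _parse_bed_row(fields, lineno):
    chrom, start, end, name, _score, strand = fields[:6]
    _check_strand(strand, lineno)
    start, end = int(start), int(end)
    tss = int(fields[6]) if len(fields) > 6 else (start if strand == "+" else end)
    return dict(gene_id=name, chrom=chrom, strand=strand,
                tss=tss, orf_start=start, orf_end=end)


def _parse_gff_row(fields, lineno):
    seqid, _src, _type, start, end, _score, strand, _frame, attrs = fields
    _check_strand(strand, lineno)
    gene_id = None
    for item in attrs.rstrip(";").split(";"):
        key, _, val = item.strip().partition("=")
        if key in ("ID", "gene_id", "Name"):
            gene_id = val.strip('"')
            break
    if gene_id is None:
        raise FormatError(f"line {lineno}: GFF attributes carry no ID/gene_id")
    start0, end0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
    tss = start0 if strand == "+" else end0
    return dict(gene_id=gene_id, chrom=seqid, strand=strand,
                tss=tss, orf_start=start0, orf_end=end0)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """Write annotation as BED6+1 with thickStart = TSS."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.orf_start}\t{row.orf_end}\t{row.gene_id}"
                f"\t0\t{row.strand}\t{row.tss}\n"
            )


# ---------------------------------------------------------------------------
# regions

def write_bed(regions: pd.DataFrame, path) -> None:
    """Write bound regions as BED6; score = max_enrichment×1000, capped 1000."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            score = min(1000, int(round(1000 * getattr(row, "max_enrichment", 0.0))))
            name = getattr(row, "gene_id", None) or "region"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t+\n")


def read_bed_regions(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            rec = dict(chrom=fields[0], start=int(fields[1]), end=int(fields[2]))
            if len(fields) > 3:
                rec["gene_id"] = fields[3]
            if len(fields) > 4:
                rec["score"] = float(fields[4])
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene sets

def read_gmt(path) -> dict:
    """Read a GMT file into ``{set_id: [members...]}`` (duplicates dropped)."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: GMT needs set_id, description, >=1 member")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            sets[fields[0]] = members
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id, members in sets.items():
            fh.write("\t".join([set_id, description, *members]) + "\n")
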