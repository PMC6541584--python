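"""Reading and writing of expression matrices, annotation, design and result tables.

All on-disk formats are plain tab-delimited text: an expression matrix with a
transcript-id first column and sample-id header, a two-column design file
(sample, group), a BED-like 4-column annotation of gene start sites
(0-based, half-open), a UCSC-style chrom.sizes file, and TSV result tables.
Malformed input is a hard error naming the offending location — values are
never silently coerced or dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("telodiff")

GROUP_LABELS = ("case", "control")


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates the format contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcripts x samples grid of non-negative expression values (RPKM-like).

    Parameters
    ----------
    values
        DataFrame indexed by transcript id with one column per sample id.
    group_of
        Mapping from sample id to group label, either ``"case"`` or
        ``"control"``. Both groups must be present with at least two samples.
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate transcript id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number)):
            raise ValidationError("expression values must be numeric")
        if arr.size:
            bad = ~np.isfinite(arr)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-finite value at transcript {idx[i]!r}, sample {cols[j]!r}"
                )
            neg = arr < 0
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise ValidationError(
                    f"negative value {arr[i, j]} at transcript {idx[i]!r}, "
                    f"sample {cols[j]!r}"
                )
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise ValidationError(
                f"samples missing from design: {', '.join(map(repr, missing))}"
            )
        bad_labels = {g for g in self.group_of.values()} - set(GROUP_LABELS)
        if bad_labels:
            raise ValidationError(
                f"unknown group labels {sorted(bad_labels)}; expected {GROUP_LABELS}"
            )
        for label in GROUP_LABELS:
            n = sum(1 for s in cols if self.group_of[s] == label)
            if n < 2:
                raise ValidationError(
                    f"group {label!r} has {n} samples; at least 2 required"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == label]

    def subset_transcripts(self, ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], dict(self.group_of))


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus a transcript -> (chromosome, gene start) map.

    Coordinates are 0-based; every start must satisfy
    ``0 <= start < chrom_lengths[chrom]``.
    """

    chrom_lengths: dict[str, int]
    gene_start_of: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if not (isinstance(length, (int, np.integer)) and length > 0):
                raise ValidationError(f"chromosome {chrom!r} has invalid length {length!r}")
        for tid, (chrom, pos) in self.gene_start_of.items():
            if chrom not in self.chrom_lengths:
                raise ValidationError(
                    f"transcript {tid!r} references unknown chromosome {chrom!r}"
                )
            if not 0 <= pos < self.chrom_lengths[chrom]:
                raise ValidationError(
                    f"transcript {tid!r} start {pos} outside [0, "
                    f"{self.chrom_lengths[chrom]}) on {chrom!r}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def restrict(self, ids: Iterable[str]) -> "GenomeAnnotation":
        """Annotation restricted to the given transcript ids (missing ids dropped)."""
        sub = {t: self.gene_start_of[t] for t in ids if t in self.gene_start_of}
        return GenomeAnnotation(dict(self.chrom_lengths), sub)

    def positions_on(self, chrom: str) -> np.ndarray:
        """Sorted-by-insertion array of gene start positions on one chromosome."""
        return np.array(
            [p for c, p in self.gene_start_of.values() if c == chrom], dtype=float
        )

    def ids_on(self, chrom: str) -> list[str]:
        return [t for t, (c, _) in self.gene_start_of.items() if c == chrom]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV into a sample -> group map."""
    path = Path(path)
    design: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        sample, group = parts
        if sample in design:
            raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
        design[sample] = group
    return design


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV plus design file into a validated matrix.

    The first column holds transcript ids, the header row sample ids. Samples
    present in the matrix but absent from the design are an error (never a
    silent drop); design entries for samples not in the matrix are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"{path}: non-numeric value in sample column {col!r}, transcript {row!r}"
            )
    design = read_design(design_path)
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValidationError(
            f"{design_path}: no group for sample(s) {', '.join(map(repr, missing))}"
        )
    group_of = {s: design[s] for s in df.columns}
    return ExpressionMatrix(df.astype(float), group_of)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    path = Path(path)
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        chrom, length = parts
        try:
            sizes[chrom] = int(length)
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: bad length {length!r}") from exc
    return sizes


def read_annotation(bed_path: str | Path, sizes_path: str | Path) -> GenomeAnnotation:
    """Read a 4-column BED of gene start sites plus a chrom.sizes file.

    BED starts are 0-based; an empty BED yields a valid, empty annotation.
    Starts at or beyond the chromosome length are an error with a line number.
    """
    bed_path = Path(bed_path)
    sizes = read_chrom_sizes(sizes_path)
    gene_start_of: dict[str, tuple[str, int]] = {}
    for lineno, line in enumerate(bed_path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise ValidationError(
                f"{bed_path}:{lineno}: expected >= 4 columns, got {len(parts)}"
            )
        chrom, start_s, _end, tid = parts[:4]
        try:
            start = int(start_s)
        except ValueError as exc:
            raise ValidationError(f"{bed_path}:{lineno}: bad start {start_s!r}") from exc
        if chrom not in sizes:
            raise ValidationError(
                f"{bed_path}:{lineno}: chromosome {chrom!r} missing from sizes file"
            )
        if not 0 <= start < sizes[chrom]:
            raise ValidationError(
                f"{bed_path}:{lineno}: start {start} outside [0, {sizes[chrom]}) "
                f"on {chrom!r}"
            )
        if tid in gene_start_of:
            raise ValidationError(f"{bed_path}:{lineno}: duplicate transcript {tid!r}")
        gene_start_of[tid] = (chrom, start)
    return GenomeAnnotation(sizes, gene_start_of)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_design(group_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in group_of.items():
            fh.write(f"{sample}\t{group}\n")


def write_annotation(ann: GenomeAnnotation, bed_path: str | Path, sizes_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for tid, (chrom, start) in ann.gene_start_of.items():
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{tid}\n")
    with open(sizes_path, "w") as fh:
        for chrom, length in ann.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def write_results(
    de_table: pd.DataFrame,
    telomere_stats,
    path_prefix: str | Path,
    metadata: Mapping | None = None,
) -> list[Path]:
    """Write the DE table, telomere statistics and run metadata.

    Produces ``<prefix>.de.tsv`` (id, log2 ratio, p, q, direction, significant),
    ``<prefix>.telomere.tsv`` and ``<prefix>.meta.json``. An empty DE table
    yields a header-only file. Returns the written paths.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    de_path = prefix.with_suffix(prefix.suffix + ".de.tsv") if prefix.suffix else Path(
        str(prefix) + ".de.tsv"
    )
    cols = ["transcript_id", "log2_ratio", "t_stat", "p_raw", "q_value", "direction", "significant"]
    out = de_table.reset_index() if de_table.index.name == "transcript_id" else de_table.copy()
    if "transcript_id" not in out.columns and out.index.name is None and len(out):
        out = out.rename_axis("transcript_id").reset_index()
    for c in cols:
        if c not in out.columns:
            out[c] = pd.Series(dtype=float)
    out[cols].to_csv(de_path, sep="\t", index=False, float_format="%.17g")
    written.append(de_path)

    tel_path = Path(str(prefix) + ".telomere.tsv")
    rows = []
    if telomere_stats is not None:
        for chrom, frac in telomere_stats.per_chrom_fraction.items():
            rows.append(
                {
                    "chrom": chrom,
                    "fraction_telomeric": frac,
                    "flagged": chrom in telomere_stats.flagged_chroms,
                }
            )
        rows.append(
            {
                "chrom": "genome",
                "fraction_telomeric": telomere_stats.overall_fraction_telomeric,
                "flagged": False,
            }
        )
    pd.DataFrame(rows, columns=["chrom", "fraction_telomeric", "flagged"]).to_csv(
        tel_path, sep="\t", index=False, float_format="%.17g"
    )
    written.append(tel_path)

    meta_path = Path(str(prefix) + ".meta.json")
    with open(meta_path, "w") as fh:
        json.dump(dict(metadata or {}), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(meta_path)
    return written
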