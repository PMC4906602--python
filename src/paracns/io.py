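"""Readers and writers for the pipeline's tab-delimited tables and BED tracks.

Coordinates are 0-based half-open in memory.  BED files are read and
written natively in that convention; annotation tables are declared
1-based inclusive on disk (the convention of the source genome tables)
and converted on read/write.  All tables are plain TSV with header rows,
so every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from paracns.cns_props import gc_content
from paracns.regions import CNSRecord, GeneModel

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_bed",
    "write_bed",
]


def _format_introns(introns: Sequence[tuple[int, int]]) -> str:
    if not introns:
        return "."
    # stored 1-based inclusive on disk
    return ";".join(f"{s + 1}-{e}" for s, e in introns)


def _parse_introns(text: str) -> tuple[tuple[int, int], ...]:
    if text in (".", "", None) or pd.isna(text):
        return ()
    out = []
    for part in str(text).split(";"):
        s, e = part.split("-")
        out.append((int(s) - 1, int(e)))
    return tuple(out)


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene": g.gene,
            "chrom": g.chrom,
            "strand": g.strand,
            "cds_start": g.cds_start + 1,  # 1-based inclusive on disk
            "cds_end": g.cds_end,
            "introns": _format_introns(g.introns),
            "protein_length": g.protein_length,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "introns": str},
                     float_precision="round_trip")
    return [
        GeneModel(
            gene=row.gene,
            chrom=row.chrom,
            strand=row.strand,
            cds_start=int(row.cds_start) - 1,
            cds_end=int(row.cds_end),
            introns=_parse_introns(row.introns),
            protein_length=int(row.protein_length),
        )
        for row in df.itertuples()
    ]


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "gene") -> None:
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path: str | Path, index_name: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = index_name
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, string_columns: Sequence[str] = ()) -> pd.DataFrame:
    dtype = {c: str for c in string_columns}
    df = pd.read_csv(path, sep="\t", dtype=dtype, float_precision="round_trip")
    for c in string_columns:
        if c in df.columns:
            df[c] = df[c].where(pd.notna(df[c]), None)
    return df


def write_bed(records: Iterable[CNSRecord], path: str | Path) -> None:
    """Write CNS records as BED6(+sequence); empty input yields an empty file."""
    lines = []
    for r in records:
        fields = [r.chrom, str(r.start), str(r.end), r.name or ".", "0", "."]
        if r.sequence is not None:
            fields.append(r.sequence)
        lines.append("\t".join(fields))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_bed(
    path: str | Path, dataset: int = 1, exclude_name: str | None = None
) -> list[CNSRecord]:
    """Read a BED3+ track into CNS records (0-based half-open, as written).

    An optional 7th column carries the CNS nucleotide sequence, from which
    GC content is derived.  ``exclude_name`` drops records whose name
    contains the given substring (e.g. to filter a labelled CNS subclass
    such as ``sncCNS`` from a published track).
    """
    records: list[CNSRecord] = []
    text = Path(path).read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed BED line {line!r}")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
        if exclude_name and exclude_name in name:
            continue
        sequence = fields[6] if len(fields) > 6 else None
        gc = gc_content(sequence) if sequence else None
        records.append(
            CNSRecord(
                chrom=chrom,
                start=start,
                end=end,
                dataset=dataset,
                name=name,
                sequence=sequence,
                gc=gc,
            )
        )
    return records
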