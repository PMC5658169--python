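"""Readers and writers for the tabular and sequence formats used throughout.

Record tables are delimited text (comma or tab) with a schema-version
comment header.  Coordinates are stored 0-based half-open; 1-based
inclusive input is converted via an explicit ``coords`` argument — never
guessed.  Column-name aliases let supplementary-style tables with
different headers map onto the canonical schema.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SCHEMA_VERSION = "1.0"
SCHEMA_HEADER = f"#casprop-records v{SCHEMA_VERSION}"

#: identity columns every record table must provide
REQUIRED_COLUMNS = ("guide_id", "chrom", "start", "end", "strand")

#: canonical optional columns (anything else passes through untouched)
KNOWN_COLUMNS = REQUIRED_COLUMNS + (
    "study", "guide_seq", "site_seq", "pam", "raw_reads", "label",
    "log_reads", "harmonized", "target_value",
    "cctop_score", "optcd_score", "cfd_score", "predicted",
)

DEFAULT_ALIASES: dict[str, str] = {
    "chromosome": "chrom", "seq_id": "chrom", "contig": "chrom",
    "guide": "guide_id", "sgrna": "guide_id",
    "sgrna_seq": "guide_seq", "spacer": "guide_seq",
    "reads": "raw_reads", "read_count": "raw_reads",
    "sequence": "site_seq", "target_seq": "site_seq",
    "cfd": "cfd_score", "cctop": "cctop_score", "optcd": "optcd_score",
}


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if line.count("\t") >= line.count(",") else ","
    return ","


def read_records(
    path,
    coords: str = "bed",
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load a record table; normalize names, coordinates, and types.

    ``coords`` is ``"bed"`` (0-based half-open, the native convention) or
    ``"one-based"`` (1-based inclusive; starts are decremented).  Malformed
    rows (unparsable coordinates, bad strand) are quarantined with a
    warning; the count is available as ``df.attrs["n_quarantined"]``.
    """
    path = Path(path)
    if coords not in ("bed", "one-based"):
        raise ValueError(f"coords must be 'bed' or 'one-based', got {coords!r}")
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#casprop-records"):
        major = first.split("v")[-1].split(".")[0]
        if major != SCHEMA_VERSION.split(".")[0]:
            raise ValueError(f"unsupported record-schema major version in {first!r}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#")
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(aliases)
    df = df.rename(columns={c: alias_map.get(c.lower(), c.lower().strip())
                            for c in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table {path} missing required column(s): {missing}")

    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    ok = start.notna() & end.notna() & df["strand"].isin(["+", "-"])
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{path}: quarantined {n_bad} malformed row(s)", stacklevel=2)
    df = df[ok].copy()
    df["start"] = start[ok].astype(int)
    df["end"] = end[ok].astype(int)
    if coords == "one-based":
        df["start"] = df["start"] - 1
    if "raw_reads" in df.columns:
        df["raw_reads"] = pd.to_numeric(df["raw_reads"], errors="coerce").fillna(0)
    df = df.reset_index(drop=True)
    df.attrs["n_quarantined"] = n_bad
    return df


def write_records(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a record table with the schema-version header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df.to_csv(fh, sep=sep, index=False)


def verify_sequences(records: pd.DataFrame, genome: Mapping[str, str]) -> int:
    """Count rows whose stored site_seq disagrees with the genome; warn."""
    from ._seq import reverse_complement

    bad = 0
    for row in records.itertuples():
        contig = genome.get(row.chrom)
        if contig is None or not isinstance(getattr(row, "site_seq", None), str):
            continue
        s = contig[row.start : row.end]
        if row.strand == "-":
            s = reverse_complement(s)
        if s.upper() != row.site_seq.upper():
            bad += 1
    if bad:
        warnings.warn(f"{bad} record(s) disagree with the genome sequence", stacklevel=2)
    return bad


# ---------------------------------------------------------------------------
# sequence formats


def read_genome(path) -> dict[str, str]:
    """FASTA -> {contig: sequence} (desk-scale genomes, held in memory)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_guides(path) -> list[tuple[str, str]]:
    """Guides from FASTA ((id, spacer) pairs) or a two-column CSV/TSV."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    out = []
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    for i, row in enumerate(csv.reader(text.splitlines(), delimiter=delim)):
        if not row or row[0].startswith("#"):
            continue
        if len(row) == 1:
            out.append((f"guide{i + 1:02d}", row[0].strip().upper()))
        else:
            out.append((row[0].strip(), row[1].strip().upper()))
    return out


def write_bed(sites: Sequence, path, scores: Sequence[float] | None = None) -> None:
    """TargetSites as BED6 (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for i, site in enumerate(sites):
            score = 0.0 if scores is None else float(scores[i])
            name = f"site{i + 1}"
            fh.write(f"{site.seq_id}\t{site.start}\t{site.end}\t{name}\t{score:g}\t{site.strand}\n")
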