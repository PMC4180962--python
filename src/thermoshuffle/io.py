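"""Readers and writers for the external formats the pipeline consumes.

GenBank and FASTA go through Biopython; Newick trees through dendropy;
12-column tabular hit files through pandas after a line-level validation
pass so malformed rows are reported with their line number.
"""
from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genome import Gene, Genome, ProteinSet

PathLike = Union[str, Path]

HIT_COLUMNS = [
    "query",
    "subject",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def parse_genbank(path: PathLike) -> tuple[Genome, ProteinSet]:
    """Read one GenBank record into a Genome plus its protein set.

    GenBank 1-based inclusive coordinates become 0-based half-open.
    A CDS declared as ``join(a..L,1..b)`` on a circular replicon is kept
    as one gene with two segments. Translations come from the
    ``/translation`` qualifier when present, otherwise from the sequence
    with the bacterial code (table 11).
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc

    length = len(record.seq)
    if length == 0:
        raise ValueError(f"{path}: LOCUS declares a zero-length sequence")
    topology = (record.annotations.get("topology") or "").lower()
    circular = topology == "circular"

    seq = str(record.seq).upper()
    has_real_seq = bool(seq) and set(seq) <= set("ACGTN")

    genes: list[Gene] = []
    proteins = ProteinSet()
    counter = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        counter += 1
        quals = feat.qualifiers
        gid = (
            quals.get("locus_tag", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"CDS_{counter:05d}"
        )
        segments = []
        for part in feat.location.parts:
            s, e = int(part.start), int(part.end)
            if s < 0 or e > length:
                raise ValueError(
                    f"{path}: CDS {gid} segment ({s}, {e}) outside replicon "
                    f"bounds [0, {length})"
                )
            segments.append((s, e))
        strand = "-" if feat.location.strand == -1 else "+"
        product = quals.get("product", [None])[0]
        genes.append(
            Gene(
                gene_id=gid,
                segments=tuple(segments),
                strand=strand,
                coding=True,
                product=product,
            )
        )
        if "translation" in quals:
            proteins[gid] = quals["translation"][0]
        elif has_real_seq:
            cds_seq = feat.extract(record.seq)
            proteins[gid] = str(Seq(cds_seq).translate(table=11)).rstrip("*")

    genome = Genome(
        replicon_id=record.id or record.name,
        length_bp=length,
        circular=circular,
        sequence=seq if has_real_seq else None,
        genes=genes,
    )
    proteins.validate()
    return genome, proteins


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_newick(text_or_path: Union[str, Path]) -> dendropy.Tree:
    """Parse a Newick string (or file path) into a dendropy tree."""
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str)
        and "(" not in text_or_path
        and Path(text_or_path).exists()
    ):
        data = Path(text_or_path).read_text()
    else:
        data = str(text_or_path)
    try:
        return dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def read_hit_table(path: PathLike) -> pd.DataFrame:
    """Read a 12-column tab-separated similarity-search hit table.

    Duplicate (query, subject) rows are collapsed to the best bitscore.
    A row with the wrong column count raises, naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    if not rows:
        return pd.DataFrame(columns=HIT_COLUMNS)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df = df.astype(
        {
            "pct_identity": float,
            "aln_length": int,
            "mismatches": int,
            "gap_opens": int,
            "qstart": int,
            "qend": int,
            "sstart": int,
            "send": int,
            "evalue": float,
            "bitscore": float,
        }
    )
    if (df["bitscore"] < 0).any():
        raise ValueError(f"{path}: negative bitscore")
    # keep best bitscore per (query, subject)
    df = (
        df.sort_values("bitscore", ascending=False)
        .drop_duplicates(["query", "subject"], keep="first")
        .reset_index(drop=True)
    )
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def hit_table_from_string(text: str) -> pd.DataFrame:
    """Convenience for tests: parse hit-table rows from an in-memory string."""
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_hit_table(name)
    finally:
        os.unlink(name)
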