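"""FASTA / GFF3 / BED readers and writers shared by the pipeline.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive GFF3 convention happens only in the writers.
"""

from __future__ import annotations

import urllib.parse
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Wrapped lines are tolerated, sequences are uppercased, duplicate record
    ids and ambiguity codes other than N are rejected.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains unsupported characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted"
            )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _gff_escape(value) -> str:
    return urllib.parse.quote(str(value), safe="")


def write_gff3(features: Iterable[dict], path) -> None:
    """Write features as GFF3.

    Each feature dict needs seqid, start, end (0-based half-open), type;
    optional score, strand and an `attributes` mapping.  Coordinates are
    converted to 1-based inclusive on output.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in features:
            attrs = ";".join(
                f"{_gff_escape(k)}={_gff_escape(v)}"
                for k, v in ft.get("attributes", {}).items()
            )
            score = ft.get("score")
            fh.write(
                "\t".join(
                    [
                        str(ft["seqid"]),
                        ft.get("source", "satellitome"),
                        ft.get("type", "satellite_DNA"),
                        str(int(ft["start"]) + 1),
                        str(int(ft["end"])),
                        "." if score is None else f"{score:.3f}",
                        ft.get("strand", "+"),
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[dict]:
    """Parse a GFF3 file back into 0-based half-open feature dicts."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    k, _, v = item.partition("=")
                    attrs[urllib.parse.unquote(k)] = urllib.parse.unquote(v)
            feats.append(
                {
                    "seqid": cols[0],
                    "source": cols[1],
                    "type": cols[2],
                    "start": int(cols[3]) - 1,
                    "end": int(cols[4]),
                    "score": None if cols[5] == "." else float(cols[5]),
                    "strand": cols[6],
                    "attributes": attrs,
                }
            )
    return feats


def write_bed6(intervals: Iterable[dict], path) -> None:
    """BED6 writer; interval dicts carry seqid/start/end/name/score/strand."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(
                    [
                        str(iv["seqid"]),
                        str(int(iv["start"])),
                        str(int(iv["end"])),
                        str(iv.get("name", ".")),
                        str(int(iv.get("score", 0))),
                        iv.get("strand", "+"),
                    ]
                )
                + "\n"
            )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
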