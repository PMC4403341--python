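"""Readers and writers for the pipeline's text formats.

BED3/BED6 interval tracks, FASTA region sequences (via Biopython), TSV count
matrices and design tables, MEME minimal motif collections, link/network
tables and JSON manifests. Coordinates are 0-based half-open internally;
GFF-style 1-based conversion happens only at the GFF boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import sort_intervals
from .enrichment import PWM


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "id", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in ["chrom", "start", "end", "id", "score", "strand"]
                       if c in df.columns]
    sort_intervals(df)[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tss_gff3(path) -> pd.DataFrame:
    """Gene TSS table from a GFF3 of gene features (1-based inclusive input)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id")
            start, end, strand = int(f[3]) - 1, int(f[4]), f[6]
            tss = start if strand != "-" else end - 1
            rows.append((gid, f[0], tss, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def write_tss_bed(annotation: pd.DataFrame, path) -> None:
    df = annotation.assign(start=annotation["tss"], end=annotation["tss"] + 1,
                           score=0)
    write_bed(df.rename(columns={"gene_id": "id"}),
              path, columns=["chrom", "start", "end", "id", "score", "strand"])


def read_tss_bed(path) -> pd.DataFrame:
    df = read_bed(path)
    return pd.DataFrame({"gene_id": df["id"], "chrom": df["chrom"],
                         "tss": df["start"],
                         "strand": df.get("strand", "+")})


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_meme(path) -> list[PWM]:
    """PWMs from MEME minimal motif format (Biopython parser)."""
    with open(path) as fh:
        parsed = motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        arr = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        arr = arr / arr.sum(axis=1, keepdims=True)
        out.append(PWM(m.name, arr))
    return out


def write_meme(pwms: list[PWM], path, background=None) -> None:
    bg = background if background is not None else [0.25] * 4
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(bg))
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.length} nsites= 10000 E= 0\n")
            for row in p.matrix:
                fh.write(" %8.6f %8.6f %8.6f %8.6f\n" % tuple(row))
            fh.write("\n")


def read_pwm_tsv(path, name=None) -> PWM:
    """PWM from a 4-column (A, C, G, T) probability TSV, one row per position."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in ["A", "C", "G", "T"] if c in df.columns]
    arr = (df[cols] if len(cols) == 4 else df.iloc[:, :4]).to_numpy(dtype=float)
    return PWM(name or Path(path).stem, arr / arr.sum(axis=1, keepdims=True))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, inputs: dict, params: dict, seed: int | None = None) -> None:
    """JSON manifest pairing an output with its input checksums and parameters."""
    payload = {"inputs": {str(k): sha256_file(v) for k, v in inputs.items()},
               "params": params, "seed": seed}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)


def check_manifest(path) -> None:
    """Re-hash every input recorded in a manifest; raise on any mismatch."""
    with open(path) as fh:
        payload = json.load(fh)
    for name, digest in payload.get("inputs", {}).items():
        if sha256_file(name) != digest:
            raise ValueError(f"checksum mismatch for {name}")
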