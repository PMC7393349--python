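"""Readers and writers for every interchange format the pipeline uses.

All intermediates are plain text (TSV, FASTA, BED, JASPAR flat format,
JSON) so every stage is inspectable; write(read(x)) is content-
identical for well-formed inputs. Coordinates in BED files are 0-based
half-open.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountMatrix
from .motifs import PFM


def write_counts(cm: CountMatrix, counts_path: Path, samples_path: Path) -> None:
    cm.values.to_csv(counts_path, sep="\t", index_label="gene")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_counts(counts_path: Path, samples_path: Path) -> CountMatrix:
    values = read_matrix(counts_path).astype(int)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return CountMatrix(values, samples)


def write_matrix(m: pd.DataFrame, path: Path, index_label: str = "id") -> None:
    m.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing cell(s) in row(s) {rows[:5]}")
    return df


def write_fasta(seqs: dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(rows: pd.DataFrame, path: Path) -> None:
    """Write BED (0-based half-open); expects chrom/start/end plus extras."""
    rows.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: Path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    base = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = (names or base)[: df.shape[1]]
    for i, row in df.iterrows():
        if not (int(row["start"]) >= 0 and int(row["end"]) > int(row["start"])):
            raise ValueError(f"{path}:{i + 1}: bad interval {row['start']}-{row['end']}")
    return df


def write_jaspar(pfms: dict[str, PFM], path: Path) -> None:
    """Write PFMs in JASPAR flat format (">ID NAME" + 4 bracketed rows)."""
    with open(path, "w") as fh:
        for i, (name, pfm) in enumerate(pfms.items()):
            mid = pfm.matrix_id or f"MA{i:04d}.1"
            fh.write(f">{mid} {name}\n")
            for row, base in zip(pfm.counts, "ACGT"):
                cells = " ".join(_fmt_count(c) for c in row)
                fh.write(f"{base} [ {cells} ]\n")


def _fmt_count(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(float(c))


def read_jaspar(path: Path) -> dict[str, PFM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out: dict[str, PFM] = {}
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        name = m.name or m.matrix_id
        out[name] = PFM(name=name, counts=counts, matrix_id=m.matrix_id or "")
    return out


def write_edge_list(m: pd.DataFrame, path: Path,
                    cols: tuple[str, str, str] = ("tf_a", "tf_b", "weight")) -> None:
    rows = []
    names = list(m.index)
    for i, a in enumerate(names):
        for j, b in enumerate(m.columns):
            rows.append((a, b, m.iat[i, j]))
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, sep="\t", index=False)


def read_edge_list(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, found {df.shape[1]}")
    a, b, w = df.columns
    return df.pivot(index=a, columns=b, values=w)


def write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def fasta_string(seqs: dict[str, str]) -> str:
    buf = _io.StringIO()
    SeqIO.write([SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()],
                buf, "fasta")
    return buf.getvalue()
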