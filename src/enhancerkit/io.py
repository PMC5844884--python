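"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open, tab-separated, no header; bedGraph shares the
coordinate convention (zero bins are omitted, runs of equal values are
collapsed); all files use LF line endings. Writers are deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .intervals import Interval, RegionSet
from .tracks import TagTrack


def write_bed(path: str | Path, regions: RegionSet | list[Interval]) -> None:
    ivs = list(regions)
    with open(path, "w", newline="\n") as fh:
        for iv in ivs:
            fields = [iv.chromosome, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(float(iv.score)))
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path, label: str = "") -> RegionSet:
    ivs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        name = parts[3] if len(parts) > 3 and parts[3] != "." else None
        score = float(parts[4]) if len(parts) > 4 else None
        ivs.append(Interval(parts[0], int(parts[1]), int(parts[2]), name, score))
    return RegionSet(label, ivs)


def write_bedgraph(path: str | Path, track: TagTrack, layout: GenomeLayout) -> None:
    bw = track.bin_width
    with open(path, "w", newline="\n") as fh:
        for chrom in layout.chromosomes:
            arr = track.counts[chrom]
            length = layout.lengths[chrom]
            # collapse runs of equal values; skip zero runs
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * bw}\t{min(e * bw, length)}\t{v}\n")


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> TagTrack:
    counts = {
        c: np.zeros(layout.n_bins(c), dtype=np.int64) for c in layout.chromosomes
    }
    bw = layout.bin_width
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("track"):
            continue
        chrom, s, e, v = line.split("\t")
        lo = int(s) // bw
        hi = -(-int(e) // bw)
        counts[chrom][lo:hi] = int(v)
    return TagTrack.from_counts(counts, bw)


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = []
        elif name is not None and line:
            out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}


def write_gmt(path: str | Path, gene_sets: dict[str, list[str]]) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        out[parts[0]] = parts[2:]
    return out


def _sanitize(obj):
    """Strict-JSON form: non-finite floats become strings."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return repr(float(obj))
    return obj


def write_json(path: str | Path, obj) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(_sanitize(obj), fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
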