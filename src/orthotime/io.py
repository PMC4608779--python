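"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: tab-separated tables for expression, probe maps,
ortholog pairs and presence calls; FASTA for promoters (via Biopython); the
MEME-minimal text format for motif libraries (written here, parsed with
``Bio.motifs``); JSON for the simulation ground truth.

Expression / presence TSV layout: first column ``probe_id``, remaining
columns ``d{day}_r{replicate}`` (e.g. ``d3_r2``).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import BASES, GroundTruth, MotifLibrary, PWM, TimeCourseMatrix

_SAMPLE_RE = re.compile(r"^d(?P<day>[0-9.]+)_r(?P<rep>\d+)$")


def _sample_name(day: float, rep: int) -> str:
    return f"d{day:g}_r{rep}"


def _parse_sample_columns(columns) -> pd.MultiIndex:
    pairs = []
    for c in columns:
        m = _SAMPLE_RE.match(c)
        if m is None:
            raise ValueError(f"unrecognized sample column {c!r}")
        pairs.append((float(m.group("day")), int(m.group("rep"))))
    return pd.MultiIndex.from_tuples(pairs, names=["day", "replicate"])


# ---------------------------------------------------------------------------
# expression & presence matrices
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: TimeCourseMatrix, path) -> None:
    df = matrix.values.copy()
    df.columns = [_sample_name(d, r) for d, r in matrix.values.columns]
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_expression_tsv(path, species: str) -> TimeCourseMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    cols = _parse_sample_columns(df.columns)
    df.columns = cols
    days = tuple(sorted(set(cols.get_level_values("day"))))
    n_rep = int(cols.get_level_values("replicate").max())
    return TimeCourseMatrix(species, days, n_rep, df)


def write_presence_tsv(calls: pd.DataFrame, path) -> None:
    """``calls``: probes x (day, replicate) MultiIndex columns of P/M/A."""
    df = calls.copy()
    df.columns = [_sample_name(d, r) for d, r in calls.columns]
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def read_presence_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    df.columns = _parse_sample_columns(df.columns)
    bad = set(np.unique(df.values)) - {"P", "M", "A"}
    if bad:
        raise ValueError(f"presence calls must be P/M/A, found {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------

def write_probe_map(mapping: pd.Series, path) -> None:
    mapping.rename("gene_id").rename_axis("probe_id").to_csv(path, sep="\t")


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return df["gene_id"]


def write_ortholog_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[["human_gene", "mouse_gene"]].to_csv(path, sep="\t", index=False)


def read_ortholog_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"human_gene", "mouse_gene"} <= set(df.columns):
        raise ValueError("ortholog table needs human_gene and mouse_gene columns")
    return df[["human_gene", "mouse_gene"]]


def write_annotation(table: pd.DataFrame, path) -> None:
    table[["gene_id", "term"]].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[["gene_id", "term"]]


# ---------------------------------------------------------------------------
# promoters (FASTA)
# ---------------------------------------------------------------------------

def write_promoters(promoters: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


# ---------------------------------------------------------------------------
# motif libraries (MEME-minimal text)
# ---------------------------------------------------------------------------

def write_meme(library: MotifLibrary, path) -> None:
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
    ]
    for pwm in library:
        lines.append(f"MOTIF {pwm.motif_id}")
        # large nsites keeps readers that convert probabilities to integer
        # counts (e.g. Bio.motifs) from rounding the matrix
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 1000000 E= 0"
        )
        for col in pwm.probs.T:
            lines.append(" " + " ".join(f"{x:.6f}" for x in col))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path) -> MotifLibrary:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        probs = np.array([list(m.pwm[b]) for b in BASES], dtype=float)
        probs = probs / probs.sum(axis=0, keepdims=True)
        out.append(PWM(m.name, probs))
    return MotifLibrary(out)


# ---------------------------------------------------------------------------
# ground truth sidecar
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
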