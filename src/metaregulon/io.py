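"""File-format plumbing: FASTA, TSV tables, BED6, provenance headers.

All tabular outputs are TSV with ``#`` comment headers carrying a
provenance block (tool version, timestamp, parameter echo). Sequence I/O
goes through Biopython.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inference import PosteriorRecord
from .motifs import BindingSiteCollection, ScoreVector
from .operons import PromoterRecord


def provenance_header(command: str, params: Mapping | None = None) -> list:
    """Comment lines recording tool version, timestamp and parameters."""
    from . import __version__

    lines = [
        f"# metaregulon {__version__}",
        f"# command: {command}",
        f"# timestamp: {datetime.datetime.now().isoformat(timespec='seconds')}",
    ]
    for key, value in (params or {}).items():
        lines.append(f"# param {key} = {value}")
    return lines


def _write_tsv(path, frame: pd.DataFrame, header_lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path) -> dict:
    """FASTA file -> ordered {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Mapping[str, str] | Iterable) -> None:
    if isinstance(records, Mapping):
        records = records.items()
    seq_records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_site_collection(path, source_label: str | None = None) -> BindingSiteCollection:
    """Binding sites from FASTA or one-sequence-per-line plain text."""
    path = Path(path)
    text = path.read_text()
    first = text.lstrip()[:1]
    if first == ">":
        sites = tuple(read_fasta(path).values())
    else:
        sites = tuple(line.strip().upper() for line in text.splitlines()
                      if line.strip())
    return BindingSiteCollection(sites, source_label=source_label or path.name)


# ---------------------------------------------------------------------------
# scores

def write_score_table(path, vectors: Sequence[ScoreVector],
                      header_lines: Sequence[str] = (),
                      strand_scores: Mapping[str, tuple] | None = None) -> None:
    """Score TSV: promoter_id, position, combined_score [, forward, reverse]."""
    rows = []
    for sv in vectors:
        for j in range(sv.n_windows):
            row = {"promoter_id": sv.promoter_id,
                   "position": int(sv.positions[j]),
                   "combined_score": float(sv.scores[j])}
            if strand_scores is not None:
                fwd, rev = strand_scores[sv.promoter_id]
                row["forward_score"] = float(fwd[j])
                row["reverse_score"] = float(rev[j])
            rows.append(row)
    _write_tsv(path, pd.DataFrame(rows), header_lines)


def read_score_table(path) -> list:
    """Inverse of :func:`write_score_table` (ScoreVectors, order preserved)."""
    frame = read_tsv(path)
    vectors = []
    for pid, group in frame.groupby("promoter_id", sort=False):
        vectors.append(ScoreVector(
            promoter_id=str(pid),
            scores=group["combined_score"].to_numpy(dtype=np.float64),
            positions=group["position"].to_numpy(dtype=np.int64),
        ))
    return vectors


# ---------------------------------------------------------------------------
# cluster maps and posterior tables

def read_cluster_map(path) -> pd.DataFrame:
    """TSV mapping promoter_id -> cluster_id (many-to-many)."""
    frame = read_tsv(path)
    missing = {"promoter_id", "cluster_id"} - set(frame.columns)
    if missing:
        raise ValueError(f"cluster map missing columns: {sorted(missing)}")
    return frame[["promoter_id", "cluster_id"]].astype(str)


def write_cluster_map(path, mapping: Iterable,
                      header_lines: Sequence[str] = ()) -> None:
    frame = pd.DataFrame(mapping, columns=["promoter_id", "cluster_id"])
    _write_tsv(path, frame, header_lines)


def posterior_frame(records: Sequence[PosteriorRecord],
                    selected: Sequence[PosteriorRecord] = ()) -> pd.DataFrame:
    chosen = {r.cluster_id for r in selected}
    return pd.DataFrame([
        {
            "cluster_id": r.cluster_id,
            "n_promoters_total": r.n_promoters_total,
            "n_promoters_analyzed": r.n_promoters_analyzed,
            "posterior": r.posterior,
            "log_ratio": r.log_likelihood_ratio_sum,
            "adjusted_P_R": r.priors_used.p_r,
            "selected": int(r.cluster_id in chosen),
        }
        for r in records
    ])


def write_posterior_table(path, records, selected=(),
                          header_lines: Sequence[str] = ()) -> None:
    _write_tsv(path, posterior_frame(records, selected), header_lines)


# ---------------------------------------------------------------------------
# promoters

def promoter_fasta_records(promoters: Sequence[PromoterRecord]):
    """(header, sequence) pairs carrying operon provenance in the header."""
    for prom in promoters:
        op = prom.operon
        clusters = ",".join(op.cluster_ids) or "."
        name = (f"{op.operon_id}|contig={op.contig_id}|strand={op.strand}"
                f"|tls={op.tls}|clusters={clusters}")
        yield name, prom.sequence


def write_promoter_bed(path, promoters: Sequence[PromoterRecord]) -> None:
    """BED6 of promoter intervals (0-based half-open, as BED requires)."""
    rows = [
        {
            "chrom": p.operon.contig_id,
            "chromStart": p.start - 1,
            "chromEnd": p.end,
            "name": p.operon.operon_id,
            "score": 0,
            "strand": p.operon.strand,
        }
        for p in promoters
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
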