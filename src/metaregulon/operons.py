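"""Operon reconstruction and promoter extraction from gene annotations.

Genes on the same strand of a contig whose intergenic gap is below 50 bp
are grouped into one operon. Only operons whose lead gene (first in
transcription direction) has a predicted translational start codon and at
least 60 bp of contig sequence upstream of it qualify; the available
upstream region, up to 300 bp, is extracted 5'->3' relative to
transcription (reverse-complemented for minus-strand operons). Promoters
may run over upstream genes -- only the 300 bp cap and the contig edge
truncate them.

Coordinates are 1-based and inclusive throughout this module; BED output
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._sequences import reverse_complement

#: operons require an intergenic gap strictly below this many bases
MAX_INTERGENIC_GAP = 50
#: minimum available upstream sequence for a promoter
MIN_PROMOTER_LENGTH = 60
#: promoters are capped at this length
MAX_PROMOTER_LENGTH = 300


@dataclass(frozen=True)
class GeneRecord:
    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    complete_start: bool = True
    cluster_ids: tuple = ()

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        object.__setattr__(self, "cluster_ids", tuple(self.cluster_ids))


@dataclass(frozen=True)
class Operon:
    contig_id: str
    strand: str
    genes: tuple

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValueError("operon needs at least one gene")
        for g in self.genes:
            if g.contig_id != self.contig_id or g.strand != self.strand:
                raise ValueError("operon genes must share contig and strand")

    @property
    def lead_gene(self) -> GeneRecord:
        """First gene in transcription direction."""
        return self.genes[0] if self.strand == "+" else self.genes[-1]

    @property
    def operon_id(self) -> str:
        return f"{self.contig_id}:{self.lead_gene.gene_id}"

    @property
    def cluster_ids(self) -> tuple:
        """Every cluster id carried by any member gene, deduplicated."""
        seen: dict = {}
        for g in self.genes:
            for cid in g.cluster_ids:
                seen.setdefault(cid, None)
        return tuple(seen)

    @property
    def tls(self) -> int:
        """Translational start coordinate of the lead gene."""
        lead = self.lead_gene
        return lead.start if self.strand == "+" else lead.end


@dataclass(frozen=True)
class PromoterRecord:
    operon: Operon
    sequence: str
    start: int  # 1-based inclusive contig coordinates of the interval
    end: int

    def __post_init__(self):
        if not MIN_PROMOTER_LENGTH <= len(self.sequence) <= MAX_PROMOTER_LENGTH:
            raise ValueError(
                f"promoter length {len(self.sequence)} outside "
                f"[{MIN_PROMOTER_LENGTH}, {MAX_PROMOTER_LENGTH}]"
            )

    @property
    def promoter_id(self) -> str:
        return self.operon.operon_id

    @property
    def length(self) -> int:
        return len(self.sequence)


def call_operons(genes: Sequence[GeneRecord],
                 contig_length: int | None = None) -> list:
    """Group genes into operons by strand and intergenic distance.

    Genes must belong to one contig and be sorted by start. The gap
    between genome-adjacent genes is ``next.start - prev.end - 1``;
    same-strand neighbours with gap < 50 (overlaps included) merge, a
    strand switch always breaks the run. The output partitions the input.
    """
    genes = list(genes)
    if not genes:
        return []
    contig = genes[0].contig_id
    for g in genes:
        if g.contig_id != contig:
            raise ValueError("call_operons expects genes from a single contig")
        if contig_length is not None and g.end > contig_length:
            raise ValueError(f"gene {g.gene_id} extends beyond the contig")
    if any(genes[i].start > genes[i + 1].start for i in range(len(genes) - 1)):
        raise ValueError("genes must be sorted by start coordinate")

    operons = []
    run = [genes[0]]
    for prev, nxt in zip(genes, genes[1:]):
        gap = nxt.start - prev.end - 1
        if nxt.strand == prev.strand and gap < MAX_INTERGENIC_GAP:
            run.append(nxt)
        else:
            operons.append(Operon(contig, run[0].strand, tuple(run)))
            run = [nxt]
    operons.append(Operon(contig, run[0].strand, tuple(run)))
    return operons


def _upstream_available(operon: Operon, contig_length: int) -> int:
    lead = operon.lead_gene
    if operon.strand == "+":
        return lead.start - 1
    return contig_length - lead.end


def filter_operons(operons: Iterable[Operon],
                   contig_lengths: Mapping[str, int],
                   require_cluster: bool = False) -> list:
    """Keep operons eligible for promoter extraction.

    Requires a complete lead ORF (predicted start codon) and at least
    60 bp of contig sequence upstream of its translational start;
    ``require_cluster`` additionally drops operons with no gene carrying
    any ortholog-cluster id.
    """
    kept = []
    for op in operons:
        if not op.lead_gene.complete_start:
            continue
        if _upstream_available(op, contig_lengths[op.contig_id]) < MIN_PROMOTER_LENGTH:
            continue
        if require_cluster and not op.cluster_ids:
            continue
        kept.append(op)
    return kept


def extract_promoter(operon: Operon, contig_sequence: str) -> PromoterRecord:
    """Extract up to 300 bp immediately upstream of the lead gene's TLS.

    Oriented 5'->3' relative to transcription (reverse-complemented for
    minus-strand operons); truncated only at the contig edge.
    """
    contig_length = len(contig_sequence)
    lead = operon.lead_gene
    if lead.end > contig_length:
        raise ValueError(
            f"operon {operon.operon_id}: coordinates exceed contig length"
        )
    if operon.strand == "+":
        start = max(1, lead.start - MAX_PROMOTER_LENGTH)
        end = lead.start - 1
        seq = contig_sequence[start - 1:end]
    else:
        start = lead.end + 1
        end = min(contig_length, lead.end + MAX_PROMOTER_LENGTH)
        seq = reverse_complement(contig_sequence[start - 1:end])
    return PromoterRecord(operon=operon, sequence=seq, start=start, end=end)


def extract_promoters(genes_by_contig: Mapping[str, Sequence[GeneRecord]],
                      contigs: Mapping[str, str],
                      require_cluster: bool = False) -> list:
    """End-to-end: call, filter, and extract promoters for many contigs."""
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    promoters = []
    for cid, genes in genes_by_contig.items():
        ordered = sorted(genes, key=lambda g: (g.start, g.end))
        ops = call_operons(ordered, lengths[cid])
        for op in filter_operons(ops, lengths, require_cluster):
            promoters.append(extract_promoter(op, contigs[cid]))
    return promoters


# ---------------------------------------------------------------------------
# tabular / GFF input

def genes_from_table(table: pd.DataFrame) -> dict:
    """GeneRecords grouped by contig from a flat table.

    Expected columns: contig_id, start, end, strand, gene_id; optional
    complete_start (bool) and cluster_ids (comma-separated string).
    """
    out: dict = {}
    for row in table.itertuples(index=False):
        cluster_ids = ()
        raw = getattr(row, "cluster_ids", "")
        if isinstance(raw, str) and raw:
            cluster_ids = tuple(x for x in raw.split(",") if x)
        gene = GeneRecord(
            contig_id=str(row.contig_id), start=int(row.start),
            end=int(row.end), strand=str(row.strand),
            gene_id=str(row.gene_id),
            complete_start=bool(getattr(row, "complete_start", True)),
            cluster_ids=cluster_ids,
        )
        out.setdefault(gene.contig_id, []).append(gene)
    return out


def genes_from_gff(path) -> dict:
    """GeneRecords grouped by contig from a GFF3 file.

    Reads features of type ``gene`` or ``CDS``. Recognised attributes:
    ``ID`` (gene id), ``complete_start`` ("true"/"false", default true)
    and ``cluster_ids`` (comma-separated ortholog-cluster identifiers).
    """
    import gffutils

    out: dict = {}
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or [f"{feat.seqid}:{feat.start}"])[0]
        complete = (attrs.get("complete_start") or ["true"])[0].lower() == "true"
        raw = (attrs.get("cluster_ids") or [""])[0]
        cluster_ids = tuple(x for x in raw.split(",") if x)
        gene = GeneRecord(contig_id=feat.seqid, start=feat.start, end=feat.end,
                          strand=feat.strand, gene_id=gene_id,
                          complete_start=complete, cluster_ids=cluster_ids)
        out.setdefault(feat.seqid, []).append(gene)
    return out
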