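"""Operon calling, filtering and promoter extraction."""

import numpy as np
import pytest

from metaregulon._sequences import reverse_complement
from metaregulon.operons import (
    GeneRecord,
    call_operons,
    extract_promoter,
    extract_promoters,
    filter_operons,
    genes_from_table,
)


def _gene(start, end, strand="+", gene_id=None, contig="ctg", **kw):
    return GeneRecord(contig, start, end, strand,
                      gene_id or f"g{start}", **kw)


class TestCallOperons:
    def test_close_same_strand_genes_merge(self):
        # 30 bp gap < 50 -> one operon
        ops = call_operons([_gene(100, 200), _gene(231, 300)])
        assert len(ops) == 1 and len(ops[0].genes) == 2

    def test_distant_same_strand_genes_split(self):
        # 60 bp gap -> two single-gene operons
        ops = call_operons([_gene(100, 200), _gene(261, 300)])
        assert [len(o.genes) for o in ops] == [1, 1]

    @pytest.mark.parametrize("gap,merged", [(48, True), (49, True),
                                            (50, False)])
    def test_gap_boundary(self, gap, merged):
        ops = call_operons([_gene(100, 200), _gene(200 + gap + 1, 400)])
        assert (len(ops) == 1) == merged

    def test_overlapping_genes_merge(self):
        ops = call_operons([_gene(100, 200), _gene(150, 300)])
        assert len(ops) == 1

    def test_strand_switch_always_breaks(self):
        genes = [_gene(100, 200, "+"), _gene(210, 300, "-"),
                 _gene(310, 400, "+")]
        ops = call_operons(genes)
        assert [len(o.genes) for o in ops] == [1, 1, 1]

    def test_output_partitions_input(self):
        rng = np.random.default_rng(0)
        pos = 1
        genes = []
        for i in range(30):
            length = int(rng.integers(90, 400))
            genes.append(_gene(pos, pos + length,
                               strand="+" if rng.random() < 0.5 else "-",
                               gene_id=f"g{i}"))
            pos += length + int(rng.integers(1, 120))
        ops = call_operons(genes)
        flattened = [g.gene_id for o in ops for g in o.genes]
        assert flattened == [g.gene_id for g in genes]

    def test_empty_input(self):
        assert call_operons([]) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            call_operons([_gene(500, 600), _gene(100, 200)])


class TestFilterOperons:
    def test_lead_gene_too_close_to_edge_dropped(self):
        # + strand gene starting at 40: only 39 bp upstream
        ops = call_operons([_gene(40, 400)])
        assert filter_operons(ops, {"ctg": 1000}) == []

    def test_exactly_sixty_bp_upstream_kept(self):
        ops = call_operons([_gene(61, 400)])
        assert len(filter_operons(ops, {"ctg": 1000})) == 1

    def test_incomplete_lead_orf_dropped(self):
        ops = call_operons([_gene(500, 900, complete_start=False)])
        assert filter_operons(ops, {"ctg": 1000}) == []

    def test_minus_strand_upstream_measured_to_contig_end(self):
        ops = call_operons([_gene(100, 941, "-")])
        assert len(filter_operons(ops, {"ctg": 1001})) == 1
        assert filter_operons(ops, {"ctg": 1000}) == []

    def test_cluster_requirement_flag(self):
        ops = call_operons([_gene(100, 400)])
        assert filter_operons(ops, {"ctg": 1000}, require_cluster=True) == []
        ops2 = call_operons([_gene(100, 400, cluster_ids=("COG1",))])
        assert len(filter_operons(ops2, {"ctg": 1000},
                                  require_cluster=True)) == 1


class TestExtractPromoter:
    def test_plus_strand_full_length(self):
        contig = "A" * 1000
        op = call_operons([_gene(500, 900)])[0]
        prom = extract_promoter(op, contig)
        assert (prom.start, prom.end) == (200, 499)
        assert prom.length == 300

    def test_plus_strand_truncated_at_contig_edge(self):
        contig = "A" * 1000
        op = call_operons([_gene(100, 400)])[0]
        prom = extract_promoter(op, contig)
        assert (prom.start, prom.end) == (1, 99)
        assert prom.length == 99

    def test_minus_strand_reverse_complemented(self):
        rng = np.random.default_rng(1)
        contig = "".join(rng.choice(list("ACGT"), size=500))
        op = call_operons([_gene(20, 100, "-")])[0]
        prom = extract_promoter(op, contig)
        # hand construction: upstream of a minus-strand gene ending at 100
        # is contig[101..400], read back 5'->3' as its reverse complement
        assert prom.sequence == reverse_complement(contig[100:400])
        assert (prom.start, prom.end) == (101, 400)

    def test_coordinates_beyond_contig_error(self):
        op = call_operons([_gene(500, 900)])[0]
        with pytest.raises(ValueError, match="exceed"):
            extract_promoter(op, "A" * 700)

    def test_promoter_length_bounds_enforced(self):
        op = call_operons([_gene(30, 400)])[0]
        with pytest.raises(ValueError, match="length"):
            extract_promoter(op, "A" * 1000)


class TestPlantedMotifRoundTrip:
    def test_motif_recoverable_at_known_offset(self):
        """Plant a motif k bp upstream of the TLS and read it back."""
        rng = np.random.default_rng(7)
        motif = "ACGTACGTACGTACGT"
        k = 40  # gap between motif end and the TLS
        contig = "".join(rng.choice(list("ACGT"), size=1000))
        tls = 600
        start = tls - k - len(motif)  # 0-based insert position
        contig = contig[:start] + motif + contig[start + len(motif):]
        op = call_operons([_gene(tls + 1, 950)])[0]  # 1-based TLS
        prom = extract_promoter(op, contig)
        # promoter ends immediately before the TLS: motif occupies
        # positions L-k-w+1 .. L-k (1-based)
        L, w = prom.length, len(motif)
        assert prom.sequence[L - k - w:L - k] == motif

    def test_minus_strand_round_trip(self):
        rng = np.random.default_rng(8)
        motif = "AACCGGTTAACCGGTT"
        contig = "".join(rng.choice(list("ACGT"), size=1000))
        # minus-strand gene ends at 400; upstream is 401..700 on the
        # plus strand; plant the reverse complement with its 3' end k bp
        # from the TLS
        k = 25
        insert = 400 + k  # 0-based start of rc(motif)
        contig = (contig[:insert] + reverse_complement(motif)
                  + contig[insert + len(motif):])
        op = call_operons([_gene(100, 400, "-")])[0]
        prom = extract_promoter(op, contig)
        L, w = prom.length, len(motif)
        assert prom.sequence[L - k - w:L - k] == motif


class TestEndToEnd:
    def test_extract_promoters_multi_contig(self):
        rng = np.random.default_rng(9)
        contigs = {f"c{i}": "".join(rng.choice(list("ACGT"), size=800))
                   for i in range(2)}
        genes = {
            "c0": [_gene(100, 300, contig="c0"),
                   _gene(320, 500, contig="c0")],
            "c1": [_gene(30, 200, contig="c1"),       # too close to edge
                   _gene(400, 700, "-", contig="c1")],
        }
        promoters = extract_promoters(genes, contigs)
        ids = [p.operon.operon_id for p in promoters]
        assert ids == ["c0:g100", "c1:g400"]
        for p in promoters:
            assert 60 <= p.length <= 300

    def test_genes_from_table(self):
        import pandas as pd

        frame = pd.DataFrame([
            {"contig_id": "c", "start": 100, "end": 300, "strand": "+",
             "gene_id": "g1", "complete_start": True,
             "cluster_ids": "COG1,COG2"},
        ])
        genes = genes_from_table(frame)
        assert genes["c"][0].cluster_ids == ("COG1", "COG2")


class TestOperonProperties:
    def test_lead_gene_and_tls_by_strand(self):
        plus = call_operons([_gene(100, 200), _gene(220, 300)])[0]
        assert plus.lead_gene.gene_id == "g100" and plus.tls == 100
        minus = call_operons([_gene(100, 200, "-"),
                              _gene(220, 300, "-")])[0]
        assert minus.lead_gene.gene_id == "g220" and minus.tls == 300

    def test_operon_maps_to_union_of_gene_clusters(self):
        genes = [_gene(100, 200, cluster_ids=("A",)),
                 _gene(220, 300, cluster_ids=("B", "A"))]
        op = call_operons(genes)[0]
        assert set(op.cluster_ids) == {"A", "B"}
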