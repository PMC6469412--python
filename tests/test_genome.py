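"""Interval algebra, GTF round-trips, class codes and locus clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovilnc.genome import (
    CLASS_I,
    CLASS_OVERLAP,
    CLASS_U,
    GTFParseError,
    GenomeInterval,
    KNOWN_LNCRNA,
    PROTEIN_CODING,
    assign_class_code,
    cluster_loci,
    gene_distance,
    read_gtf,
    write_gtf,
)

from conftest import make_annotation, make_tx


class TestGTF:
    def test_coordinate_convention(self, tmp_path):
        """A GTF exon printed as 101-200 is the internal interval [100, 200)."""
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            '1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
            'gene_biotype "protein_coding";\n'
            '1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
            'gene_biotype "protein_coding";\n'
        )
        ann = read_gtf(gtf)
        t = ann.transcripts["t1"]
        assert t.exon_count == 2
        assert (t.exons[0].start, t.exons[0].end) == (100, 200)
        assert t.exons[0].length == 100
        assert t.biotype == PROTEIN_CODING

    def test_lncRNA_biotype_maps_to_known(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            '1\tx\texon\t11\t50\t.\t-\t.\tgene_id "g"; transcript_id "t"; '
            'gene_biotype "lncRNA";\n'
        )
        assert read_gtf(gtf).transcripts["t"].biotype == KNOWN_LNCRNA

    def test_round_trip_preserves_annotation(self, tmp_path, world):
        """reference GTF -> internal -> GTF -> internal is the identity."""
        first = read_gtf(world.paths["reference.gtf"])
        out = tmp_path / "rt.gtf"
        write_gtf(first, out)
        second = read_gtf(out)
        assert set(first.transcripts) == set(second.transcripts)
        for tid, t in first.transcripts.items():
            u = second.transcripts[tid]
            assert [(e.start, e.end) for e in t.exons] == [(e.start, e.end) for e in u.exons]
            assert (t.gene_id, t.biotype, t.strand) == (u.gene_id, u.biotype, u.strand)

    def test_parse_error_names_line(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("1\tx\texon\t10\t20\n")
        with pytest.raises(GTFParseError, match="line 1"):
            read_gtf(gtf)

    def test_zero_exon_transcript_dropped(self, tmp_path, caplog):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            '1\tx\ttranscript\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "empty";\n'
            '1\tx\texon\t11\t50\t.\t+\t.\tgene_id "g2"; transcript_id "ok";\n'
        )
        ann = read_gtf(gtf)
        assert set(ann.transcripts) == {"ok"}


class TestGeneDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (200, 300), 0),  # touching
            ((100, 200), (1199, 1300), 999),
            ((100, 200), (150, 300), None),  # overlapping
        ],
    )
    def test_examples(self, a, b, expected):
        ia = GenomeInterval("1", *a)
        ib = GenomeInterval("1", *b)
        assert gene_distance(ia, ib) == expected

    def test_different_chromosomes_are_infinitely_far(self):
        assert gene_distance(GenomeInterval("1", 0, 10), GenomeInterval("2", 0, 10)) == math.inf

    @given(
        st.tuples(st.integers(0, 500), st.integers(1, 100)),
        st.tuples(st.integers(0, 500), st.integers(1, 100)),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_positionwise_scan(self, a, b):
        """Gap equals the count of bases strictly between the two intervals."""
        ia = GenomeInterval("1", a[0], a[0] + a[1])
        ib = GenomeInterval("1", b[0], b[0] + b[1])
        occupied_a = set(range(ia.start, ia.end))
        occupied_b = set(range(ib.start, ib.end))
        if occupied_a & occupied_b:
            assert gene_distance(ia, ib) is None
        else:
            lo = min(ia.end, ib.end)
            hi = max(ia.start, ib.start)
            assert gene_distance(ia, ib) == len(
                [x for x in range(lo, hi) if x not in occupied_a | occupied_b]
            )


def _brute_force_class(query, ann):
    """Independent pairwise-overlap oracle for the class code."""
    gene_exonic = any(
        e.overlaps(GenomeInterval(s.chrom, s.start, s.end))
        for g, s in ann.gene_spans.items()
        if ann.gene_biotypes[g] in (PROTEIN_CODING, KNOWN_LNCRNA)
        for e in query.exons
    )
    if not gene_exonic:
        return CLASS_U
    span = query.span
    for t in ann.transcripts.values():
        if t.biotype != PROTEIN_CODING:
            continue
        for intron in t.introns:
            if intron.contains(span):
                return CLASS_I
    return CLASS_OVERLAP


class TestClassCode:
    def setup_method(self):
        self.ann = make_annotation(
            make_tx("pc1", "1", [(1000, 1200), (3000, 3500)], gene_id="G1",
                    biotype=PROTEIN_CODING),
            make_tx("pc2", "1", [(9000, 9500), (11000, 12000)], gene_id="G2",
                    biotype=PROTEIN_CODING),
        )

    def test_intergenic(self):
        q = make_tx("q", "1", [(5000, 5600)])
        assert assign_class_code(q, self.ann) == CLASS_U

    def test_intronic(self):
        q = make_tx("q", "1", [(1500, 1700), (2000, 2400)])
        assert assign_class_code(q, self.ann) == CLASS_I

    def test_exonic_overlap(self):
        q = make_tx("q", "1", [(1100, 1400)])
        assert assign_class_code(q, self.ann) == CLASS_OVERLAP

    def test_absent_chromosome_is_intergenic(self):
        q = make_tx("q", "99", [(0, 100)])
        assert assign_class_code(q, self.ann) == CLASS_U

    def test_random_queries_match_bruteforce(self):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(8):
            start = int(rng.integers(0, 50_000))
            n_ex = int(rng.integers(2, 5))
            blocks, pos = [], start
            for _ in range(n_ex):
                ln = int(rng.integers(100, 400))
                blocks.append((pos, pos + ln))
                pos += ln + int(rng.integers(300, 2000))
            genes.append(
                make_tx(f"pc{i}", "1", blocks, gene_id=f"G{i}", biotype=PROTEIN_CODING)
            )
        ann = make_annotation(*genes)
        codes = set()
        for k in range(50):
            start = int(rng.integers(0, 60_000))
            ln = int(rng.integers(50, 3000))
            q = make_tx(f"q{k}", "1", [(start, start + ln)])
            code = assign_class_code(q, ann)
            assert code == _brute_force_class(q, ann)
            codes.add(code)
        assert codes == {CLASS_U, CLASS_I, CLASS_OVERLAP}  # all classes exercised


class TestClusterLoci:
    def test_overlap_shares_locus(self):
        a = make_tx("a", "1", [(100, 300)])
        b = make_tx("b", "1", [(250, 500)])
        loci = cluster_loci([a, b])
        assert loci["a"] == loci["b"] == "a"

    def test_disjoint_transcripts_two_loci(self):
        a = make_tx("a", "1", [(100, 300)])
        b = make_tx("b", "1", [(400, 500)])
        assert len(set(cluster_loci([a, b]).values())) == 2

    def test_opposite_strands_never_cluster(self):
        a = make_tx("a", "1", [(100, 300)], strand="+")
        b = make_tx("b", "1", [(100, 300)], strand="-")
        assert len(set(cluster_loci([a, b]).values())) == 2

    def test_matches_graph_components_and_is_order_invariant(self):
        import networkx as nx

        rng = np.random.default_rng(17)
        ts = []
        for i in range(30):
            start = int(rng.integers(0, 5000))
            ln = int(rng.integers(50, 600))
            strand = "+" if rng.random() < 0.5 else "-"
            ts.append(make_tx(f"t{i:02d}", "1", [(start, start + ln)], strand=strand))
        loci = cluster_loci(ts)
        g = nx.Graph()
        g.add_nodes_from(t.transcript_id for t in ts)
        for i, a in enumerate(ts):
            for b in ts[i + 1 :]:
                if a.strand == b.strand and any(
                    ea.overlaps(eb) for ea in a.exons for eb in b.exons
                ):
                    g.add_edge(a.transcript_id, b.transcript_id)
        comps = {frozenset(c) for c in nx.connected_components(g)}
        ours = {}
        for tid, locus in loci.items():
            ours.setdefault(locus, set()).add(tid)
        assert {frozenset(v) for v in ours.values()} == comps
        # locus ids are the smallest member; input order does not matter
        assert all(locus == min(members) for locus, members in ours.items())
        shuffled = list(ts)
        rng.shuffle(shuffled)
        assert cluster_loci(shuffled) == loci
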