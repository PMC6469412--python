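"""The filtering funnel: individual rules, the ORF finder and planted recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from ovilnc.expression import ExpressionMatrix
from ovilnc.funnel import (
    CodingScores,
    EvidenceRecord,
    FilterParams,
    coding_vote,
    domain_filter,
    expression_filter,
    find_longest_orf,
    homology_filter,
    proximity_filter,
    run_funnel,
    structural_filter,
)
from ovilnc.genome import PROTEIN_CODING, read_gtf

from conftest import make_annotation, make_tx

P = FilterParams()


def _expr(values, feature="t"):
    samples = [f"s{i}" for i in range(len(values))]
    groups = {s: ("A" if i < len(values) // 2 else "B") for i, s in enumerate(samples)}
    return ExpressionMatrix(pd.DataFrame([values], index=[feature], columns=samples), groups)


class TestStructural:
    @pytest.mark.parametrize(
        "blocks,expected_reason",
        [
            ([(0, 150)], "min_length"),          # single exon, 150 nt
            ([(0, 200)], "min_length"),          # boundary: 200 nt is not "longer than 200"
            ([(0, 201)], None),                   # 201 nt survives
            ([(0, 10_001)], "monoexon_too_long"),
            ([(0, 10_000)], None),                # boundary: exactly 10 kb kept
            ([(0, 6000), (7000, 13_000)], None),  # 12 kb but two exons
        ],
    )
    def test_length_rules(self, blocks, expected_reason):
        d = structural_filter(make_tx("t", "1", blocks), None, P)
        assert d.reason == expected_reason

    def test_monoexon_on_repeat_rejected(self):
        repeats = {"1": IntervalTree()}
        repeats["1"].addi(100, 160)
        mono = make_tx("t", "1", [(150, 600)])
        assert structural_filter(mono, repeats, P).reason == "monoexon_repeat"
        multi = make_tx("t2", "1", [(150, 600), (900, 1200)])
        assert structural_filter(multi, repeats, P).keep  # repeat rule is mono-exon only

    def test_random_transcripts_match_rule_oracle(self):
        rng = np.random.default_rng(3)
        repeats = {"1": IntervalTree()}
        repeats["1"].addi(5000, 5400)
        for _ in range(100):
            n_ex = int(rng.integers(1, 4))
            start = int(rng.integers(0, 8000))
            blocks, pos = [], start
            for _ in range(n_ex):
                ln = int(rng.integers(50, 6000))
                blocks.append((pos, pos + ln))
                pos += ln + 200
            t = make_tx("t", "1", blocks)
            expect_keep = (
                t.spliced_length > 200
                and not (n_ex == 1 and t.spliced_length > 10_000)
                and not (n_ex == 1 and any(s < 5400 and e > 5000 for s, e in blocks))
            )
            assert structural_filter(t, repeats, P).keep == expect_keep


class TestExpression:
    def test_one_qualifying_sample_rejected(self):
        assert not expression_filter("t", _expr([1.2, 0.5, 0, 0, 0, 0]), P).keep

    def test_boundary_fpkm_one_inclusive(self):
        assert expression_filter("t", _expr([1.0, 1.0, 0, 0, 0, 0]), P).keep

    def test_missing_feature_rejected_with_reason(self):
        d = expression_filter("absent", _expr([5, 5, 5, 5]), P)
        assert not d.keep and d.reason == "missing_expression"

    def test_random_matrices_match_count_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            vals = rng.uniform(0, 3, size=6).round(3)
            keep = expression_filter("t", _expr(list(vals)), P).keep
            assert keep == (int((vals >= 1.0).sum()) >= 2)


class TestHomologyAndDomains:
    def test_sub_threshold_hit_rejects(self):
        ev = EvidenceRecord("t", hits=[("Rfam", 1e-6)])
        assert not homology_filter(ev, P).keep

    def test_boundary_evalue_kept(self):
        """E-value exactly 1e-5 survives: the cut-off is strict '<'."""
        ev = EvidenceRecord("t", hits=[("UniProtKB", 1e-5)])
        assert homology_filter(ev, P).keep

    @pytest.mark.parametrize("pattern", list(itertools.product([None, 1e-6, 1e-4], repeat=3)))
    def test_all_database_patterns(self, pattern):
        """Rejection iff any of the three databases carries a sub-threshold hit."""
        dbs = ("UniProtKB", "miRBase", "Rfam")
        hits = [(db, e) for db, e in zip(dbs, pattern) if e is not None]
        ev = EvidenceRecord("t", hits=hits)
        assert homology_filter(ev, P).keep == all(e is None or e >= 1e-5 for e in pattern)

    def test_any_domain_hit_rejects(self):
        assert not domain_filter(EvidenceRecord("t", domain_hits=[("PF00001", 0.2)])).keep
        assert domain_filter(EvidenceRecord("t")).keep

    def test_optional_domain_evalue_cutoff(self):
        p = FilterParams(domain_evalue_max=1e-5)
        ev = EvidenceRecord("t", domain_hits=[("PF00001", 1e-3)])
        assert domain_filter(ev, p).keep
        assert not domain_filter(EvidenceRecord("t", domain_hits=[("PF1", 1e-6)]), p).keep


class TestCodingVote:
    def test_three_votes_is_coding(self):
        votes, verdict = coding_vote(CodingScores(0.6, 1.2, 0.40, -0.1, "noncoding"))
        assert (votes, verdict) == (3, "coding")

    def test_thresholds_are_strict(self):
        """Scores exactly at every threshold yield zero votes."""
        votes, verdict = coding_vote(CodingScores(0.5, 0.0, 0.36, 0.0, "noncoding"))
        assert (votes, verdict) == (0, "noncoding")

    @pytest.mark.parametrize("pattern", list(itertools.product([False, True], repeat=5)))
    def test_exhaustive_32_patterns(self, pattern):
        """verdict == (votes >= 3) for every one of the 2^5 vote patterns."""
        cpc2 = 0.9 if pattern[0] else 0.1
        cnci = 1.0 if pattern[1] else -1.0
        cpat = 0.5 if pattern[2] else 0.1
        plek = 0.5 if pattern[3] else -0.5
        feelnc = "coding" if pattern[4] else "noncoding"
        votes, verdict = coding_vote(CodingScores(cpc2, cnci, cpat, plek, feelnc))
        assert votes == sum(pattern)
        assert (verdict == "coding") == (votes >= 3)

    def test_missing_feelnc_counts_noncoding(self):
        votes, _ = coding_vote(CodingScores(0.9, 1.0, 0.5, 0.5, "missing"))
        assert votes == 4

    def test_non_numeric_score_errors(self):
        with pytest.raises(TypeError):
            CodingScores("high", 0, 0, 0, "noncoding")


def _orf_oracle(seq):
    """Position-by-position brute-force ORF scanner (independent of the package)."""
    seq = seq.upper()
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        aa = 0
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if j > i and codon in ("TAA", "TAG", "TGA"):
                break
            aa += 1
            j += 3
        else:
            pass
        # aa counted codons from ATG up to (not including) stop or sequence end
        best = max(best, aa)
    return best


class TestORF:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGTAA", 1),
            ("CCCCCC", 0),
            ("", 0),
            ("ATGAAA", 2),        # 3'-partial ORF, no stop
            ("ATGAAATAG", 2),
            ("AATGAAATAA", 2),    # frame 1
            ("ATGTAAATGGCCGCCTAA", 3),  # second ORF after a stop
        ],
    )
    def test_examples(self, seq, expected):
        assert find_longest_orf(seq) == expected

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            n = int(rng.integers(0, 120))
            seq = "".join(rng.choice(list("ACGTN"), size=n))
            assert find_longest_orf(seq) == _orf_oracle(seq)

    def test_never_exceeds_length_over_three(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=900))
            assert find_longest_orf(seq) <= 300


class TestProximity:
    def _ann(self, gene_blocks):
        return make_annotation(
            make_tx("pc", "1", gene_blocks, gene_id="G", biotype=PROTEIN_CODING)
        )

    def test_distance_boundary_strict(self):
        lnc = make_tx("t", "1", [(2000, 2500)])
        # gene ends 999 bp before the lncRNA -> rejected; 1000 bp -> kept
        assert not proximity_filter(lnc, self._ann([(0, 1001)]), P).keep
        assert proximity_filter(lnc, self._ann([(0, 1000)]), P).keep

    def test_gene_on_other_chromosome_ignored(self):
        lnc = make_tx("t", "2", [(0, 500)])
        assert proximity_filter(lnc, self._ann([(0, 100_000)]), P).keep


class TestFunnelEndToEnd:
    def test_planted_recovery(self, world):
        """All planted lncRNAs survive; every decoy dies at its designated step."""
        from Bio import SeqIO

        from ovilnc.genome import read_bed
        from ovilnc.pipeline import load_evidence

        ref = read_gtf(world.paths["reference.gtf"])
        assembled = read_gtf(world.paths["assembled.gtf"])
        repeats = read_bed(world.paths["repeats.bed"])
        expr = ExpressionMatrix.from_tsv(world.paths["expression.tsv"], world.paths["groups.tsv"])
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(world.paths["transcripts.fa"]), "fasta")}
        evidence = load_evidence(world.outdir)
        candidates, report = run_funnel(assembled, ref, repeats, expr, evidence,
                                        sequences=seqs)
        got = {c.transcript_id for c in candidates}
        planted = set(world.truth.planted_lincrnas) | set(world.truth.planted_ilncrnas)
        assert got == planted
        by_cat = {c.transcript_id: c.category for c in candidates}
        assert all(by_cat[t] == "lincRNA" for t in world.truth.planted_lincrnas)
        assert all(by_cat[t] == "ilncRNA" for t in world.truth.planted_ilncrnas)
        # decoys: removed with exactly the planted reason
        for tid, (step, reason) in world.truth.decoys.items():
            assert report.rejections[tid] == reason, tid
        # monotone counts, nested survivors
        rows = report.to_rows()
        for prev, cur in zip(rows, rows[1:]):
            assert cur["input"] == prev["surviving"]
            assert cur["surviving"] <= cur["input"]
        for prev, cur in zip(report.steps, report.steps[1:]):
            assert set(cur.surviving_ids) <= set(prev.surviving_ids)

    def test_empty_assembly(self, world):
        ref = read_gtf(world.paths["reference.gtf"])
        expr = ExpressionMatrix.from_tsv(world.paths["expression.tsv"], world.paths["groups.tsv"])
        candidates, report = run_funnel(make_annotation(), ref, None, expr, {})
        assert candidates == []
        assert all(r["input"] == 0 for r in report.to_rows())
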