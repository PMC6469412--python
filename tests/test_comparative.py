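"""Conservation summaries and flanking-ortholog synteny."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ovilnc.comparative import (
    SHEEP_AS_QUERY,
    SHEEP_AS_SUBJECT,
    SyntenyRecord,
    conservation_summary,
    conserved_ids,
    foreign_flank_pairs,
    read_blast6,
    synteny_conserved,
    synteny_venn,
)
from ovilnc.genome import PROTEIN_CODING, read_gtf

from conftest import make_annotation, make_tx


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["query_id", "subject_id", "species", "e_value",
                       "alignment_length", "direction"]
    )


class TestConservation:
    def test_significant_hit_is_conserved(self):
        h = _hits([("t1", "x", "bovine", 1e-6, 100, SHEEP_AS_QUERY)])
        out = conservation_summary(h)
        assert out.loc[0, "conserved_transcripts"] == 1

    def test_insignificant_hit_is_not(self):
        h = _hits([("t1", "x", "bovine", 1e-4, 100, SHEEP_AS_QUERY)])
        assert conservation_summary(h).empty

    def test_boundary_emax_inclusive(self):
        h = _hits([("t1", "x", "bovine", 1e-5, 100, SHEEP_AS_QUERY)])
        assert len(conservation_summary(h)) == 1

    def test_union_of_directions(self):
        h = _hits([
            ("t1", "x", "bovine", 1e-6, 100, SHEEP_AS_QUERY),
            ("t2", "y", "bovine", 1e-8, 200, SHEEP_AS_SUBJECT),
        ])
        assert conserved_ids(h, "bovine") == {"t1", "t2"}

    def test_best_hit_mean_length(self):
        h = _hits([
            ("t1", "a", "bovine", 1e-6, 100, SHEEP_AS_QUERY),
            ("t1", "b", "bovine", 1e-9, 300, SHEEP_AS_QUERY),  # best: lower e
            ("t2", "c", "bovine", 1e-7, 200, SHEEP_AS_QUERY),
        ])
        out = conservation_summary(h)
        assert out.loc[0, "mean_alignment_length"] == pytest.approx(250.0)

    def test_emax_monotonicity(self):
        rng = np.random.default_rng(6)
        rows = [
            (f"t{i}", "x", "bovine", float(10.0 ** -rng.uniform(2, 10)), 100, SHEEP_AS_QUERY)
            for i in range(40)
        ]
        h = _hits(rows)
        counts = []
        for emax in (1e-8, 1e-6, 1e-4, 1e-2):
            out = conservation_summary(h, emax=emax)
            counts.append(0 if out.empty else int(out.loc[0, "conserved_transcripts"]))
        assert counts == sorted(counts)

    def test_world_counts_and_planted_means(self, world):
        frames = []
        for sp in ("bovine", "human", "chicken"):
            for tag, direction in (("query", SHEEP_AS_QUERY), ("subject", SHEEP_AS_SUBJECT)):
                path = world.paths[f"cons_{sp}_{tag}.tsv"]
                if path.stat().st_size:
                    frames.append(read_blast6(path, sp, direction))
        hits = pd.concat(frames, ignore_index=True)
        out = conservation_summary(hits).set_index("species")
        for sp, planted in world.truth.conserved.items():
            if not planted:
                assert sp not in out.index
                continue
            assert out.loc[sp, "conserved_transcripts"] == len(planted)
            assert out.loc[sp, "mean_alignment_length"] == pytest.approx(
                np.mean(list(planted.values()))
            )
            assert conserved_ids(hits, sp) == set(planted)


def _foreign_world(pairs):
    """Build foreign gene/linc tables realizing the given flank pairs."""
    genes, lincs = [], []
    cursor = 1
    for k, (left, right) in enumerate(pairs):
        genes.append((left, "c1", cursor, cursor + 999))
        lincs.append((f"fl{k}", "c1", cursor + 3000, cursor + 3499))
        genes.append((right, "c1", cursor + 6000, cursor + 6999))
        cursor += 20_000
    return (
        pd.DataFrame(lincs, columns=["id", "chrom", "start", "end"]),
        pd.DataFrame(genes, columns=["id", "chrom", "start", "end"]),
    )


class TestSynteny:
    def setup_method(self):
        self.ann = make_annotation(
            make_tx("ACACA.t", "11", [(0, 2000)], gene_id="ACACA", biotype=PROTEIN_CODING),
            make_tx("C17orf78.t", "11", [(30_000, 32_000)], gene_id="C17orf78",
                    biotype=PROTEIN_CODING),
        )
        self.lnc = make_tx("lincRNA.3473", "11", [(10_000, 11_000)])
        self.orth = {"ACACA": "ACACA_h", "C17orf78": "C17orf78_h"}

    def test_matching_flank_pair_is_conserved(self):
        lincs, genes = _foreign_world([("ACACA_h", "C17orf78_h")])
        pairs = foreign_flank_pairs(lincs, genes)
        rec = synteny_conserved(self.lnc, self.ann, "human", pairs, self.orth)
        assert rec.conserved_synteny and rec.matched_foreign_linc == "fl0"
        assert rec.sheep_neighbors == ("ACACA", "C17orf78")

    def test_flank_order_is_ignored_by_default(self):
        lincs, genes = _foreign_world([("C17orf78_h", "ACACA_h")])
        pairs = foreign_flank_pairs(lincs, genes)
        assert synteny_conserved(self.lnc, self.ann, "human", pairs, self.orth).conserved_synteny
        pairs_o = foreign_flank_pairs(lincs, genes, ordered=True)
        rec = synteny_conserved(self.lnc, self.ann, "human", pairs_o, self.orth, ordered=True)
        assert not rec.conserved_synteny

    def test_single_matching_flank_is_not_conserved(self):
        lincs, genes = _foreign_world([("ACACA_h", "OTHER_h")])
        pairs = foreign_flank_pairs(lincs, genes)
        assert not synteny_conserved(self.lnc, self.ann, "human", pairs, self.orth).conserved_synteny

    def test_missing_ortholog_flagged(self):
        lincs, genes = _foreign_world([("ACACA_h", "C17orf78_h")])
        pairs = foreign_flank_pairs(lincs, genes)
        rec = synteny_conserved(self.lnc, self.ann, "human", pairs, {"ACACA": "ACACA_h"})
        assert not rec.conserved_synteny and rec.flag == "missing_ortholog"

    def test_incomplete_flank_flagged(self):
        ann = make_annotation(
            make_tx("g.t", "11", [(0, 2000)], gene_id="g", biotype=PROTEIN_CODING)
        )
        rec = synteny_conserved(self.lnc, ann, "human", {}, {"g": "g_h"})
        assert not rec.conserved_synteny and rec.flag == "incomplete_flank"

    def test_world_planted_recovery(self, world):
        """Per-species synteny sets equal the planted truth; 9 loci in all species."""
        from ovilnc.comparative import read_orthologs_tsv, read_positions_tsv

        ref = read_gtf(world.paths["reference.gtf"])
        assembled = read_gtf(world.paths["assembled.gtf"])
        records = []
        for sp in world.config.species:
            pairs = foreign_flank_pairs(
                read_positions_tsv(world.paths[f"foreign_lincs_{sp}.tsv"]),
                read_positions_tsv(world.paths[f"foreign_genes_{sp}.tsv"]),
            )
            orth = read_orthologs_tsv(world.paths[f"orthologs_{sp}.tsv"])
            for tid in world.truth.planted_lincrnas:
                records.append(
                    synteny_conserved(assembled.transcripts[tid], ref, sp, pairs, orth)
                )
        venn = synteny_venn(records)
        truth_sets = {sp: set() for sp in world.config.species}
        for tid, sps in world.truth.syntenic.items():
            for sp in sps:
                truth_sets[sp].add(tid)
        assert venn["sets"] == truth_sets
        all_sp = tuple(sorted(world.config.species))
        expect_all = {t for t, sps in world.truth.syntenic.items()
                      if set(sps) == set(world.config.species)}
        assert venn["partition"][all_sp] == len(expect_all) == world.config.n_syntenic_all


class TestVenn:
    def test_disjoint_sets_have_empty_intersections(self):
        recs = [
            SyntenyRecord("a", "s1", (None, None), "x", True),
            SyntenyRecord("b", "s2", (None, None), "y", True),
        ]
        venn = synteny_venn(recs)
        assert venn["partition"][("s1",)] == 1
        assert venn["partition"][("s1", "s2")] == 0

    def test_triple_membership_counted_once(self):
        recs = [
            SyntenyRecord("a", sp, (None, None), "x", True) for sp in ("s1", "s2", "s3")
        ]
        venn = synteny_venn(recs)
        assert venn["partition"][("s1", "s2", "s3")] == 1
        assert venn["partition"][("s1",)] == 0

    def test_random_sets_match_membership_enumeration(self):
        rng = np.random.default_rng(13)
        species = ["s1", "s2", "s3"]
        recs = []
        membership = {}
        for i in range(40):
            lnc = f"l{i}"
            sps = [sp for sp in species if rng.random() < 0.5]
            membership[lnc] = tuple(sps)
            for sp in species:
                recs.append(SyntenyRecord(lnc, sp, (None, None),
                                          "m" if sp in sps else None, sp in sps))
        venn = synteny_venn(recs)
        for k in range(1, 4):
            for combo in itertools.combinations(species, k):
                expect = sum(1 for m in membership.values() if m == combo)
                assert venn["partition"][combo] == expect
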