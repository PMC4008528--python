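"""Census filters, locus assembly, overlap typing, unusual-locus search."""
import numpy as np
import pytest

from comcensus.census import (Candidate, ComLocus, LengthRanges, assemble_loci,
                              classify_overlap, count_tm_helices, filter_hits,
                              find_hypothetical_comX, scan_genomes)
from comcensus.genome_io import AnnotatedGenome, GeneRecord
from comcensus.phmm import HitScore
from comcensus.synth import SynthConfig, ancestors, make_decoys, plant_locus, random_dna


def _hit(gene, role, e=1e-6):
    return Candidate(gene=gene,
                     role=role,
                     hit=HitScore(query_id=gene.gene_id, model_name=role,
                                  bit_score=100.0, e_value=e, database_size=100),
                     coverage=1.0)


def _gene(gid="g", protein="M" * 60, start=1, end=None, strand="+", contig="c"):
    end = end or start + 3 * len(protein) + 2
    return GeneRecord(gene_id=gid, contig_id=contig, start=start, end=end,
                      strand=strand, protein=protein)


class TestFilterHits:
    def test_comx_with_cterm_trp_accepted(self):
        prot = "M" * 55 + "W" + "A" * 4  # 60 aa, Trp at position len-4
        accepted, audit = filter_hits([_hit(_gene(protein=prot), "ComX")])
        assert len(accepted) == 1 and "trp_ok" in accepted[0].flags

    def test_comx_without_trp_rejected(self):
        prot = "M" + "A" * 59
        accepted, audit = filter_hits([_hit(_gene(protein=prot), "ComX")])
        assert not accepted
        assert audit[0]["failed"] == "cterm_trp"

    def test_comq_length_boundary(self):
        accepted, audit = filter_hits([_hit(_gene(protein="A" * 285), "ComQ")])
        assert not accepted and audit[0]["failed"] == "length"
        accepted, _ = filter_hits([_hit(_gene(protein="A" * 286), "ComQ")])
        assert len(accepted) == 1

    def test_evalue_gate(self):
        accepted, audit = filter_hits([_hit(_gene(protein="A" * 290), "ComQ", e=0.1)])
        assert not accepted and audit[0]["failed"] == "e_value"

    def test_comp_requires_both_subdomains(self):
        gene = _gene(protein="I" * 750)
        cand = _hit(gene, "ComP")
        cand.sub_hits = {"ComP_HK": HitScore("g", "ComP_HK", 50, 1e-9, 100)}
        accepted, audit = filter_hits([cand])
        assert not accepted and audit[0]["failed"] == "atp_domain"

    def test_unknown_role_is_error(self):
        with pytest.raises(ValueError):
            filter_hits([_hit(_gene(), "ComZ")])

    def test_low_coverage_rejected(self):
        cand = _hit(_gene(protein="A" * 290), "ComQ")
        cand.coverage = 0.3
        accepted, audit = filter_hits([cand])
        assert not accepted and audit[0]["failed"] == "coverage"


class TestTmHelices:
    def test_poly_ala_thirty_residues_is_one_helix(self):
        # KD(A)=1.8 > 1.6 for every window of a 30-mer
        assert count_tm_helices("A" * 30) == 1

    def test_poly_arg_is_zero(self):
        assert count_tm_helices("R" * 40) == 0

    def test_two_separated_hydrophobic_stretches(self):
        assert count_tm_helices("I" * 25 + "R" * 30 + "I" * 25) == 2

    def test_shorter_than_window_is_zero(self):
        assert count_tm_helices("I" * 10) == 0

    def test_comp_ancestor_has_ten_membrane_helices(self):
        assert count_tm_helices(ancestors()["ComP"]) == 10


class TestClassifyOverlap:
    @staticmethod
    def _locus(coords):
        genes = {}
        for role, (s, e) in coords.items():
            genes[role] = _gene(gid=role, protein="M" * ((e - s + 1 - 3) // 3),
                                start=s, end=e)
        return ComLocus(genome_id="g", contig_id="c", genes=genes,
                        completeness="full", overlap_type="", unusual="none",
                        strand="+")

    def test_no_overlap_is_type_a(self):
        loc = self._locus({"ComQ": (1, 900), "ComX": (950, 1150),
                           "ComP": (1200, 3500), "ComA": (3550, 4200)})
        assert classify_overlap(loc) == "A"

    def test_qx_45bp_is_type_b_with_15aa(self):
        loc = self._locus({"ComQ": (1, 994), "ComX": (950, 1150),
                           "ComP": (1200, 3500), "ComA": (3550, 4200)})
        assert classify_overlap(loc) == "B"
        assert loc.overlaps_bp["QX"] == 45 and loc.overlaps_bp["QX"] // 3 == 15

    def test_xp_and_pa_is_type_e(self):
        loc = self._locus({"ComQ": (1, 900), "ComX": (950, 1150),
                           "ComP": (1142, 3500), "ComA": (3435, 4200)})
        assert loc.genes["ComX"].end - loc.genes["ComP"].start + 1 == 9
        assert classify_overlap(loc) == "E"
        assert loc.overlaps_bp["XP"] == 9 and loc.overlaps_bp["PA"] == 66

    def test_strand_flip_invariance(self):
        coords = {"ComQ": (1, 994), "ComX": (950, 1150),
                  "ComP": (1200, 3500), "ComA": (3480, 4200)}
        loc = self._locus(coords)
        t = classify_overlap(loc)
        total = 5000
        mirrored = {r: (total - e + 1, total - s + 1) for r, (s, e) in coords.items()}
        loc2 = self._locus(mirrored)
        loc2.strand = "-"
        assert classify_overlap(loc2) == t

    def test_incomplete_locus_is_error(self):
        loc = self._locus({"ComQ": (1, 900), "ComX": (950, 1150),
                           "ComP": (1200, 3500), "ComA": (3550, 4200)})
        loc.completeness = "incomplete"
        with pytest.raises(ValueError):
            classify_overlap(loc)


class TestAssembly:
    def _genome_with_genes(self, genes, contig_len=20000):
        g = AnnotatedGenome("g", {"c": "A" * contig_len}, genes=list(genes))
        g.sort_and_index()
        return g

    def test_serial_order_on_plus_strand_gives_full_locus(self):
        coords = [("ComQ", 1, 900), ("ComX", 950, 1150), ("ComP", 1200, 3500),
                  ("ComA", 3550, 4200)]
        genes = [_gene(gid=r, start=s, end=e, protein="M" * ((e - s - 2) // 3))
                 for r, s, e in coords]
        genome = self._genome_with_genes(genes)
        hits = [Candidate(gene=x, role=x.gene_id,
                          hit=HitScore(x.gene_id, x.gene_id, 99, 1e-9, 10)).gene
                for x in genes]
        from comcensus.census import ComHit
        com_hits = [ComHit(gene=x, role=x.gene_id,
                           hit=HitScore(x.gene_id, x.gene_id, 99, 1e-9, 10))
                    for x in genes]
        loci = assemble_loci(genome, com_hits)
        assert len(loci) == 1 and loci[0].completeness == "full"
        assert loci[0].overlap_type == "A"

    def test_wrong_strand_member_breaks_locus(self):
        coords = [("ComQ", 1, 900, "+"), ("ComX", 950, 1150, "+"),
                  ("ComP", 1200, 3500, "-"), ("ComA", 3550, 4200, "+")]
        genes = [_gene(gid=r, start=s, end=e, strand=st,
                       protein="M" * ((e - s - 2) // 3))
                 for r, s, e, st in coords]
        genome = self._genome_with_genes(genes)
        from comcensus.census import ComHit
        com_hits = [ComHit(gene=x, role=x.gene_id,
                           hit=HitScore(x.gene_id, x.gene_id, 99, 1e-9, 10))
                    for x in genes]
        loci = assemble_loci(genome, com_hits)
        assert not any(l.completeness == "full" for l in loci)

    def test_gap_beyond_limit_splits_chain(self):
        coords = [("ComQ", 1, 900), ("ComX", 1600, 1800), ("ComP", 1850, 4000),
                  ("ComA", 4050, 4700)]  # Q-X gap 699 > 600
        genes = [_gene(gid=r, start=s, end=e, protein="M" * ((e - s - 2) // 3))
                 for r, s, e in coords]
        genome = self._genome_with_genes(genes)
        from comcensus.census import ComHit
        com_hits = [ComHit(gene=x, role=x.gene_id,
                           hit=HitScore(x.gene_id, x.gene_id, 99, 1e-9, 10))
                    for x in genes]
        loci = assemble_loci(genome, com_hits)
        assert not any(l.completeness == "full" for l in loci)
        assert any(l.completeness == "incomplete" for l in loci)

    def test_every_hit_in_at_most_one_locus(self, small_dataset, recognizers):
        loci, _, _ = scan_genomes(small_dataset.genomes, recognizers)
        seen = set()
        for loc in loci:
            for role, h in loc.hits.items():
                key = (loc.genome_id, h.gene.gene_id)
                assert key not in seen
                seen.add(key)


class TestHypotheticalComX:
    def _frame(self, unusual, seed=57):
        rng = np.random.default_rng(seed)
        g = AnnotatedGenome("g", {"c": random_dna(300, rng)})
        g, truth = plant_locus(g, ancestors(), "A", unusual, position=150, rng=rng)
        q = next(x for x in g.genes if x.gene_id.endswith("ComQ"))
        p = next(x for x in g.genes if x.gene_id.endswith("ComP"))
        return g, truth, q, p

    def test_same_strand_orf_found_as_hypothetical(self):
        g, truth, q, p = self._frame("hypothetical_comX")
        rec, kind = find_hypothetical_comX(q, p, g)
        assert kind == "hypothetical_comX"
        assert (rec.start, rec.end) == truth.coords["ComX"][:2]

    def test_opposite_strand_orf_found_as_antisense(self):
        g, truth, q, p = self._frame("antisense_comX")
        rec, kind = find_hypothetical_comX(q, p, g)
        assert kind == "antisense_comX"
        assert rec.strand == "-"

    def test_span_without_orf_gives_none(self):
        rng = np.random.default_rng(61)
        # A/C-only spacer: no start codon anywhere
        g = AnnotatedGenome("g", {"c": "AC" * 400})
        q = _gene(gid="q", start=1, end=93, protein="M" * 30)
        p = _gene(gid="p", start=700, end=793, protein="M" * 30)
        g.genes = [q, p]
        g.sort_and_index()
        assert find_hypothetical_comX(q, p, g) is None


class TestEndToEnd:
    def test_planted_loci_recovered_with_types(self, small_dataset, recognizers):
        loci, audit, n = scan_genomes(small_dataset.genomes, recognizers)
        truth = {t.genome_id: t for t in small_dataset.truth}
        full = [l for l in loci if l.completeness == "full"]
        assert len(full) == len(truth)
        for l in full:
            t = truth[l.genome_id]
            assert l.overlap_type == t.overlap_type
            assert l.unusual == t.unusual
            assert l.strand == t.strand

    def test_decoy_only_genome_yields_no_loci_but_hits_exist(self, recognizers):
        rng = np.random.default_rng(67)
        g = AnnotatedGenome("d", {"d_c1": random_dna(300, rng)})
        g = make_decoys(g, 6, rng)
        loci, audit, n = scan_genomes([g], recognizers)
        assert loci == []
        # the full-length kinase decoy still registers an accepted ComP hit:
        # isolated hits are suppressed below the two-role floor, so this is
        # visible only through the absence of any locus plus audit silence
        # for at least one ComP candidate
        audited = {a["gene_id"] for a in audit}
        decoy_p = [x.gene_id for x in g.genes if x.gene_id.endswith("hk")]
        assert decoy_p and any(gid not in audited for gid in decoy_p)
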