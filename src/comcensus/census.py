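"""Locus census: hit filtering, comQXPA assembly, overlap typing.

Applies the survey's acceptance rules to profile-HMM hits (E-value < 0.1,
role-specific length ranges, the ComX C-terminal tryptophan, ComP
histidine-kinase + ATP-binding sub-domain evidence, Viterbi match-state
coverage) and assembles accepted hits into candidate loci: maximal
same-contig, same-strand groups in the serial order comQ-comX-comP-comA,
with bounded intergenic gaps. A full candidate missing only comX is
re-examined for an unannotated or antisense open reading frame of the right
length carrying the C-terminal tryptophan - the "hypothetical comX"
arrangements. Full loci are typed A-E by their reading-frame overlap
pattern (A none, B comQ-comX, C comQ-comX-comP, D comP-comA,
E comX-comP-comA).

Transmembrane helices in ComP are annotated (not filtered) with a
Kyte-Doolittle hydropathy heuristic standing in for a dedicated topology
predictor; the survey keeps ComP candidates without the membrane domain.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (ROLES, AnnotatedGenome, GeneRecord, reverse_complement,
                        translate_cds)
from .phmm import HitScore, ProfileHMM, evalue, score_forward, viterbi_match_coverage

DEFAULT_E_MAX = 0.1
DEFAULT_MAX_GAP_BP = 600
DEFAULT_MAX_INTERVENING = 1
DEFAULT_COVERAGE_MIN = 0.6
#: permissive bound of the "tryptophan within 5-10 residues of the C
#: terminus" rule
TRP_WINDOW = 10

#: Kyte-Doolittle hydropathy values
KD = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
      "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
      "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
      "Y": -1.3, "V": 4.2}
TM_WINDOW = 19
TM_THRESHOLD = 1.6
TM_MERGE_GAP = 5


@dataclass
class LengthRanges:
    """Accepted protein length range (aa) per role, from the seed sets."""

    ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "ComQ": (286, 309), "ComX": (52, 73), "ComP": (700, 800),
        "ComA": (196, 245)})

    def __post_init__(self) -> None:
        for role, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"min > max for {role}")

    def ok(self, role: str, length: int) -> bool:
        lo, hi = self.ranges[role]
        return lo <= length <= hi

    @classmethod
    def from_seeds(cls, seed_msas: dict, slack: float = 0.1) -> "LengthRanges":
        ranges = {}
        for role in ROLES:
            lens = [len(r.replace("-", "")) for r in seed_msas[role].rows]
            ranges[role] = (int(min(lens) * (1 - slack)), int(max(lens) * (1 + slack)) + 1)
        return cls(ranges=ranges)


@dataclass
class ComHit:
    """One accepted protein-vs-recognizer match with its filter evidence."""

    gene: GeneRecord
    role: str
    hit: HitScore
    flags: set[str] = field(default_factory=set)
    tm_helix_count: int | None = None  # ComP only; annotation, not a filter


@dataclass
class ComLocus:
    genome_id: str
    contig_id: str
    genes: dict[str, GeneRecord]  # role -> gene, serial order comQ..comA
    completeness: str             # full | incomplete
    overlap_type: str             # A..E | other | "" (incomplete)
    unusual: str                  # none | antisense_comX | hypothetical_comX
    strand: str
    hits: dict[str, ComHit] = field(default_factory=dict)
    overlaps_bp: dict[str, int] = field(default_factory=dict)


def count_tm_helices(protein: str) -> int:
    """Count transmembrane helices by Kyte-Doolittle windowing.

    19-residue window means > 1.6 mark membrane-spanning stretches; maximal
    runs of qualifying windows count one helix each, runs closer than 5
    positions are merged. Sequences shorter than one window give 0.
    """
    if not protein:
        raise ValueError("empty sequence")
    vals = np.array([KD.get(a, 0.0) for a in protein.upper()])
    if len(vals) < TM_WINDOW:
        return 0
    kernel = np.ones(TM_WINDOW) / TM_WINDOW
    means = np.convolve(vals, kernel, mode="valid")
    above = means > TM_THRESHOLD
    runs: list[list[int]] = []
    for i, flag in enumerate(above):
        if flag and runs and runs[-1][1] == i - 1:
            runs[-1][1] = i
        elif flag:
            runs.append([i, i])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < TM_MERGE_GAP:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return len(merged)


def has_cterm_trp(protein: str, window: int = TRP_WINDOW) -> bool:
    return "W" in protein[-window:]


@dataclass
class Candidate:
    """A scored (gene, role) pair prior to acceptance filtering."""

    gene: GeneRecord
    role: str
    hit: HitScore
    sub_hits: dict[str, HitScore] = field(default_factory=dict)  # ComP only
    coverage: float | None = None


def filter_hits(candidates: list[Candidate], ranges: LengthRanges | None = None,
                e_max: float = DEFAULT_E_MAX,
                coverage_min: float = DEFAULT_COVERAGE_MIN,
                ) -> tuple[list[ComHit], list[dict]]:
    """Apply the acceptance rules; return (accepted hits, audit records).

    Acceptance: E < e_max, length in the role's range, Viterbi match-state
    coverage >= coverage_min; ComX additionally needs a Trp in the
    C-terminal 10 residues; ComP needs both sub-domain recognizers
    (histidine-kinase and ATP-binding) below e_max. Rejected hits are
    returned as audit records naming the failed criterion.
    """
    ranges = ranges or LengthRanges()
    accepted: list[ComHit] = []
    audit: list[dict] = []

    def reject(c: Candidate, reason: str) -> None:
        audit.append({"gene_id": c.gene.gene_id, "role": c.role,
                      "e_value": c.hit.e_value, "bit_score": c.hit.bit_score,
                      "length": len(c.gene.protein), "failed": reason})

    for c in candidates:
        if c.role not in ROLES:
            raise ValueError(f"unknown role {c.role!r}")
        if not (c.hit.e_value < e_max):
            reject(c, "e_value")
            continue
        if not ranges.ok(c.role, len(c.gene.protein)):
            reject(c, "length")
            continue
        flags = {"length_ok"}
        if c.role == "ComX":
            if not has_cterm_trp(c.gene.protein):
                reject(c, "cterm_trp")
                continue
            flags.add("trp_ok")
        if c.role == "ComP":
            hk = c.sub_hits.get("ComP_HK")
            atp = c.sub_hits.get("ComP_ATP")
            if hk is None or not hk.e_value < e_max:
                reject(c, "hk_domain")
                continue
            if atp is None or not atp.e_value < e_max:
                reject(c, "atp_domain")
                continue
            flags.update({"hk_domain", "atp_domain"})
        if c.coverage is not None and c.coverage < coverage_min:
            reject(c, "coverage")
            continue
        tm = count_tm_helices(c.gene.protein) if c.role == "ComP" else None
        accepted.append(ComHit(gene=c.gene, role=c.role, hit=c.hit,
                               flags=flags, tm_helix_count=tm))
    return accepted, audit


# ---------------------------------------------------------------------------
# ORF search for hypothetical / antisense comX
# ---------------------------------------------------------------------------

_STARTS = ("ATG", "GTG", "TTG")
_STOPS = ("TAA", "TAG", "TGA")


def _orfs_in(seq: str) -> list[tuple[int, int, str]]:
    """All (0-based start, end-exclusive incl. stop, protein) ORFs fully
    inside ``seq``, forward frame."""
    out = []
    L = len(seq)
    for s in range(L - 5):
        if seq[s:s + 3] not in _STARTS:
            continue
        for e in range(s + 3, L - 2, 3):
            codon = seq[e:e + 3]
            if codon in _STOPS:
                out.append((s, e + 3, translate_cds(seq[s:e + 3])))
                break
    return out


def find_hypothetical_comX(q_gene: GeneRecord, p_gene: GeneRecord,
                           genome: AnnotatedGenome,
                           x_range: tuple[int, int] = (52, 73),
                           locus_strand: str = "+") -> tuple[GeneRecord, str] | None:
    """Search the comQ-comP intergenic span for a comX-sized ORF with the
    C-terminal tryptophan.

    Both strands are scanned; the longest qualifying ORF wins, ties broken
    by leftmost genome start. Returns (gene record, kind) where kind is
    ``hypothetical_comX`` for a locus-strand ORF or ``antisense_comX`` for
    an opposite-strand one; None if the span holds no qualifying ORF.
    """
    if q_gene.contig_id != p_gene.contig_id:
        raise ValueError("comQ and comP on different contigs")
    contig = genome.contigs[q_gene.contig_id]
    left = min(q_gene.end, p_gene.end) + 1
    right = max(q_gene.start, p_gene.start) - 1
    if right - left + 1 < 3 * x_range[0]:
        return None
    region = contig[left - 1:right]
    candidates: list[tuple[int, int, GeneRecord, str]] = []
    for strand, seq in (("+", region), ("-", reverse_complement(region))):
        for s, e, prot in _orfs_in(seq):
            if not (x_range[0] <= len(prot) <= x_range[1]):
                continue
            if not has_cterm_trp(prot):
                continue
            if strand == "+":
                g_start, g_end = left + s, left + e - 1
            else:
                g_start = left + len(region) - e
                g_end = left + len(region) - 1 - s
            kind = "hypothetical_comX" if strand == locus_strand else "antisense_comX"
            rec = GeneRecord(gene_id=f"{q_gene.gene_id}_hypX", contig_id=q_gene.contig_id,
                             start=g_start, end=g_end, strand=strand, protein=prot)
            candidates.append((len(prot), g_start, rec, kind))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, _, rec, kind = candidates[0]
    # reuse an annotated gene record if one matches exactly
    for g in genome.genes:
        if (g.contig_id, g.start, g.end, g.strand) == (rec.contig_id, rec.start,
                                                       rec.end, rec.strand):
            return g, kind
    return rec, kind


# ---------------------------------------------------------------------------
# Locus assembly and overlap typing
# ---------------------------------------------------------------------------

def _pairwise_overlap(a: GeneRecord, b: GeneRecord) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def classify_overlap(locus: ComLocus) -> str:
    """Map the consecutive-pair overlap pattern to types A-E.

    Pattern {} -> A, {QX} -> B, {QX, XP} -> C, {PA} -> D, {XP, PA} -> E;
    anything else -> "other". Overlap lengths (bp) are stored on the locus;
    aa lengths follow as bp // 3. Pure coordinate arithmetic, invariant
    under a strand flip of the whole locus.
    """
    if locus.completeness != "full":
        raise ValueError("overlap classification needs a full locus")
    q, x, p, a = (locus.genes[r] for r in ROLES)
    ov = {"QX": _pairwise_overlap(q, x), "XP": _pairwise_overlap(x, p),
          "PA": _pairwise_overlap(p, a)}
    locus.overlaps_bp = ov
    present = frozenset(k for k, v in ov.items() if v > 0)
    mapping = {frozenset(): "A", frozenset({"QX"}): "B",
               frozenset({"QX", "XP"}): "C", frozenset({"PA"}): "D",
               frozenset({"XP", "PA"}): "E"}
    return mapping.get(present, "other")


def assemble_loci(genome: AnnotatedGenome, hits: list[ComHit],
                  max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                  max_intervening: int = DEFAULT_MAX_INTERVENING,
                  x_range: tuple[int, int] = (52, 73)) -> list[ComLocus]:
    """Group accepted hits into candidate loci.

    A chain is a maximal run of same-contig, same-strand accepted hits in
    which consecutive hits are separated by at most ``max_gap_bp`` and at
    most ``max_intervening`` annotated genes. A chain whose roles follow
    the serial order comQ-comX-comP-comA along the strand is a full locus;
    chains with >= 2 roles in serial order are kept as incomplete; full
    chains missing only comX are re-examined for a hypothetical or
    antisense comX before being finalized. Ambiguity is resolved by
    leftmost-start greedy assembly; every accepted hit lands in at most one
    locus.
    """
    loci: list[ComLocus] = []
    by_key: dict[tuple[str, str], list[ComHit]] = {}
    for h in hits:
        by_key.setdefault((h.gene.contig_id, h.gene.strand), []).append(h)

    for (contig_id, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.gene.start)
        chains: list[list[ComHit]] = []
        current: list[ComHit] = []
        for h in group:
            if not current:
                current = [h]
                continue
            prev = current[-1]
            gap = h.gene.start - prev.gene.end - 1
            intervening = h.gene.index_on_contig - prev.gene.index_on_contig - 1
            if gap <= max_gap_bp and intervening <= max_intervening:
                current.append(h)
            else:
                chains.append(current)
                current = [h]
        if current:
            chains.append(current)

        serial = list(ROLES) if strand == "+" else list(reversed(ROLES))
        for chain in chains:
            # greedy subsequence match of the serial role order
            picked: dict[str, ComHit] = {}
            si = 0
            for h in chain:
                while si < len(serial) and serial[si] != h.role:
                    si += 1
                if si < len(serial) and h.role not in picked:
                    picked[h.role] = h
                    si += 1
            if len(picked) < 2:
                continue
            genes = {r: picked[r].gene for r in ROLES if r in picked}
            unusual = "none"
            completeness = "full" if len(picked) == 4 else "incomplete"
            if set(picked) == {"ComQ", "ComP", "ComA"}:
                found = find_hypothetical_comX(genes["ComQ"], genes["ComP"],
                                               genome, x_range, strand)
                if found is not None:
                    x_rec, unusual = found
                    genes["ComX"] = x_rec
                    completeness = "full"
            locus = ComLocus(genome_id=genome.genome_id, contig_id=contig_id,
                             genes=genes, completeness=completeness,
                             overlap_type="", unusual=unusual, strand=strand,
                             hits={r: h for r, h in picked.items()})
            if completeness == "full":
                locus.overlap_type = classify_overlap(locus)
            loci.append(locus)
    loci.sort(key=lambda l: (l.genome_id, l.contig_id,
                             min(g.start for g in l.genes.values())))
    return loci


# ---------------------------------------------------------------------------
# End-to-end scan
# ---------------------------------------------------------------------------

MODEL_NAMES = ("ComQ", "ComX", "ComP", "ComA", "ComP_HK", "ComP_ATP")


def build_recognizers(seed_msas: dict, seed: int = 0, n_null: int = 500,
                      ) -> dict[str, ProfileHMM]:
    """Build and calibrate the four role recognizers plus the two ComP
    sub-domain recognizers from their seed alignments."""
    from .phmm import build_profile, calibrate
    models: dict[str, ProfileHMM] = {}
    for i, name in enumerate(MODEL_NAMES):
        model = build_profile(seed_msas[name], name)
        calibrate(model, n_null=n_null, seed=seed + i)
        models[name] = model
    return models

#: pre-filter factors: only score a protein against a role model when its
#: length is loosely compatible (cannot pass the hard range filter otherwise)
PREFILTER_LO, PREFILTER_HI = 0.5, 2.0


def scan_genomes(genomes: list[AnnotatedGenome], models: dict[str, ProfileHMM],
                 ranges: LengthRanges | None = None,
                 e_max: float = DEFAULT_E_MAX,
                 coverage_min: float = DEFAULT_COVERAGE_MIN,
                 max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                 max_intervening: int = DEFAULT_MAX_INTERVENING,
                 ) -> tuple[list[ComLocus], list[dict], int]:
    """Run the whole census: score, filter, assemble.

    The E-value database size N is the total number of annotated proteins
    scanned across all genomes. Returns (loci, audit records, N).
    """
    ranges = ranges or LengthRanges()
    n_proteins = sum(len(g.genes) for g in genomes)
    all_loci: list[ComLocus] = []
    all_audit: list[dict] = []
    for genome in genomes:
        candidates: list[Candidate] = []
        for gene in genome.genes:
            L = len(gene.protein)
            if L == 0:
                continue
            for role in ROLES:
                lo, hi = ranges.ranges[role]
                if not (PREFILTER_LO * lo <= L <= PREFILTER_HI * hi):
                    continue
                model = models[role]
                s = score_forward(model, gene.protein)
                e = evalue(model, s, n_proteins)
                hit = HitScore(query_id=gene.gene_id, model_name=role,
                               bit_score=s, e_value=e, database_size=n_proteins)
                cand = Candidate(gene=gene, role=role, hit=hit)
                if e < e_max:
                    cand.coverage = viterbi_match_coverage(model, gene.protein)
                    if role == "ComP":
                        for sub in ("ComP_HK", "ComP_ATP"):
                            ss = score_forward(models[sub], gene.protein)
                            cand.sub_hits[sub] = HitScore(
                                query_id=gene.gene_id, model_name=sub,
                                bit_score=ss,
                                e_value=evalue(models[sub], ss, n_proteins),
                                database_size=n_proteins)
                candidates.append(cand)
        accepted, audit = filter_hits(candidates, ranges, e_max, coverage_min)
        all_audit.extend(audit)
        all_loci.extend(assemble_loci(genome, accepted, max_gap_bp,
                                      max_intervening,
                                      x_range=ranges.ranges["ComX"]))
    return all_loci, all_audit, n_proteins


def write_audit_log(audit: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in audit:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
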