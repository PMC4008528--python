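"""Synthetic annotated genomes with planted comQXPA loci.

Generates two clades of genomes ("bsub-like" / "non-bsub-like") carrying
quorum-sensing cassettes with controlled protein divergence, the five
reading-frame overlap configurations (A: none, B: comQ-comX, C:
comQ-comX-comP, D: comP-comA, E: comX-comP-comA), unusual locus variants
(antisense or non-homologous hypothetical comX), and decoy genes (lone
histidine kinases, response regulators, isoprenyl transferases, random
proteins) - so the whole census pipeline is testable without downloads,
with exact ground truth.

Protein evolution is a site-independent Poisson substitution process with
uniform replacement among the 19 alternatives (a 20-state Jukes-Cantor
analogue), which has the closed-form expected p-distance
``(19/20) * (1 - exp(-(20/19) * d))`` for a path of ``d`` expected
substitutions/site. Indels, rearrangements and codon bias are deliberately
out of scope: families remain length-matched and hence trivially aligned.

Overlap geometry: a k-amino-acid extension of one reading frame into its
neighbour is realized as a ``3k + 1`` bp coordinate overlap, which shifts
the second frame by +1 so that both CDSs stay well-formed (stop codons
cannot coexist in overlapping identical frames); the census reports the
extension back as ``bp // 3 == k`` aa. Overlap nucleotides are constructed
codon-first: synonymous choices in the carrier gene satisfy the second
frame's start/stop constraints wherever possible, and where no synonymous
assignment exists single residues are relaxed - the ground truth always
records the realized proteins.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome_io import (AA_ALPHABET, AnnotatedGenome, GeneRecord, Msa,
                        reverse_complement, translate_cds, write_genome)
from .phmm import ROBINSON_FREQS

ROLES = ("ComQ", "ComX", "ComP", "ComA")
CLADES = ("bsub-like", "non-bsub-like")
STOPS = ("TAA", "TAG", "TGA")

# Bacterial (table 11) coding codons per amino acid.
_CODON_TABLE: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODON_TABLE:
        from Bio.Data import CodonTable
        fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
        for codon, aa in fwd.items():
            _CODON_TABLE.setdefault(aa, []).append(codon)
        for aa in _CODON_TABLE:
            _CODON_TABLE[aa].sort()
    return _CODON_TABLE


def _syn(aa: str) -> list[str]:
    return _codon_table()[aa]


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(codon).translate(table=11))


def backtranslate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous back-translation (no stop appended)."""
    table = _codon_table()
    return "".join(table[aa][rng.integers(len(table[aa]))] for aa in protein)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_protein(n: int, rng: np.random.Generator,
                   freqs: np.ndarray | None = None) -> str:
    idx = rng.choice(20, size=n, p=ROBINSON_FREQS if freqs is None else freqs)
    return "".join(AA_ALPHABET[i] for i in idx)


def _cytoplasmic_freqs() -> np.ndarray:
    """Residue composition for soluble/cytoplasmic segments: background
    with strongly hydrophobic residues (I, L, V, F) down-weighted."""
    f = ROBINSON_FREQS.copy()
    for aa in "ILVF":
        f[AA_ALPHABET.index(aa)] *= 0.55
    return f / f.sum()


# ---------------------------------------------------------------------------
# Packaged ancestors
# ---------------------------------------------------------------------------

ANCESTOR_LENGTHS = {"ComQ": 290, "ComX": 60, "ComP": 750, "ComA": 214}
#: 0-based position of the conserved signal tryptophan of ComX (6 residues
#: from the C terminus, inside the reported 5-10 residue window).
COMX_TRP_POS = 54
#: slices of the ComP ancestor used as kinase / ATP-binding sub-domain seeds
COMP_HK_SPAN = (430, 505)
COMP_ATP_SPAN = (560, 670)
#: length of planted non-homologous hypothetical comX proteins (top of the
#: 52-73 aa range, so no spurious intergenic ORF can out-rank them)
HYPX_LENGTH = 73

_ANCESTORS: dict[str, str] = {}


def ancestors() -> dict[str, str]:
    """Fixed packaged ancestor proteins for the four Com families.

    Generated deterministically (independent of any user seed). The ComP
    ancestor carries ten strongly hydrophobic N-terminal stretches so the
    transmembrane-helix annotation mirrors real receptors; ComX carries the
    conserved C-terminal tryptophan.
    """
    if _ANCESTORS:
        return _ANCESTORS
    rng = np.random.default_rng(96122)
    q = "M" + random_protein(ANCESTOR_LENGTHS["ComQ"] - 1, rng)
    x = list("M" + random_protein(ANCESTOR_LENGTHS["ComX"] - 1, rng))
    x[COMX_TRP_POS] = "W"
    x = "".join(x)
    # ComP: 10 x (22 hydrophobic + 8 loop) = 300 aa membrane region, then
    # cytoplasmic remainder containing the HK and ATP sub-domain spans.
    parts = []
    hydro = "ILVF"
    loop = "DEKRNQSTG"
    for _ in range(10):
        parts.append("".join(hydro[i] for i in rng.integers(0, len(hydro), 22)))
        parts.append("".join(loop[i] for i in rng.integers(0, len(loop), 8)))
    membrane = "".join(parts)
    p = "M" + membrane + random_protein(ANCESTOR_LENGTHS["ComP"] - len(membrane) - 1,
                                        rng, _cytoplasmic_freqs())
    a = "M" + random_protein(ANCESTOR_LENGTHS["ComA"] - 1, rng)
    _ANCESTORS.update({"ComQ": q, "ComX": x, "ComP": p, "ComA": a})
    return _ANCESTORS


def comx_site_rates() -> np.ndarray:
    """Relative substitution rates along ComX: hypervariable C-terminal quarter."""
    L = ANCESTOR_LENGTHS["ComX"]
    rates = np.full(L, 0.6)
    rates[3 * L // 4:] = 2.5
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# Protein-family evolution
# ---------------------------------------------------------------------------

def expected_p_distance(d: float) -> float:
    """Closed-form expected p-distance of the substitution process for a
    path of ``d`` expected substitutions/site."""
    return (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * d))


def mutate(seq: str, d: float, rng: np.random.Generator,
           mask: tuple[int, ...] = (), site_rates: np.ndarray | None = None) -> str:
    """Apply the Poisson/uniform-replacement process along one branch.

    ``d`` is the expected number of substitutions per (unit-rate) site;
    masked positions never mutate regardless of rates.
    """
    L = len(seq)
    if mask and max(mask) >= L:
        raise ValueError("conservation mask extends beyond the sequence")
    rates = np.ones(L) if site_rates is None else np.asarray(site_rates, dtype=float)
    if len(rates) != L:
        raise ValueError("site_rates length must equal sequence length")
    hits = rng.poisson(d * rates)
    out = list(seq)
    for pos in np.nonzero(hits)[0]:
        if pos in mask:
            continue
        for _ in range(hits[pos]):
            alternatives = [a for a in AA_ALPHABET if a != out[pos]]
            out[pos] = alternatives[rng.integers(19)]
    return "".join(out)


def evolve_family(ancestor: str, clade_sizes: dict[str, int],
                  divergence_within: float, divergence_between: float,
                  seed: int, mask: tuple[int, ...] = (),
                  site_rates: np.ndarray | None = None,
                  clade_scale: dict[str, float] | None = None,
                  ) -> tuple[dict[str, str], dict[str, str]]:
    """Evolve a family over a two-clade star-within-clades topology.

    The root ancestor sits ``divergence_between / 2`` from each clade
    ancestor; each leaf sits ``divergence_within`` (optionally scaled per
    clade) from its clade ancestor, so the expected within-clade pairwise
    path is ``2 * divergence_within``. Returns (name -> protein,
    name -> clade).
    """
    if len(ancestor) < 10:
        raise ValueError("ancestor too short")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    for clade, n in clade_sizes.items():
        scale = 1.0 if clade_scale is None else clade_scale.get(clade, 1.0)
        clade_anc = mutate(ancestor, divergence_between / 2.0, rng, mask, site_rates)
        for i in range(n):
            name = f"{clade}_{i:03d}"
            seqs[name] = mutate(clade_anc, divergence_within * scale, rng, mask, site_rates)
            clade_of[name] = clade
    return seqs, clade_of


def make_seed_msa(role: str, n: int = 8, divergence: float = 0.05,
                  seed: int = 12061) -> Msa:
    """Seed alignment for one Com family: the packaged ancestor plus ``n``
    shallow descendants (length-preserving evolution => already aligned)."""
    anc = ancestors()[role]
    rng = np.random.default_rng(seed + 101 * ROLES.index(role))
    mask = (COMX_TRP_POS,) if role == "ComX" else ()
    rows = [anc] + [mutate(anc, divergence, rng, mask) for _ in range(n)]
    return Msa(names=[f"{role}_seed{i}" for i in range(len(rows))], rows=rows)


def seed_msas(seed: int = 12061) -> dict[str, Msa]:
    """Seed alignments for the four recognizers and the two ComP sub-domains."""
    out = {role: make_seed_msa(role, seed=seed) for role in ROLES}
    p = out["ComP"]
    for name, (lo, hi) in (("ComP_HK", COMP_HK_SPAN), ("ComP_ATP", COMP_ATP_SPAN)):
        out[name] = Msa(names=list(p.names), rows=[r[lo:hi] for r in p.rows])
    return out


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

def _default_overlap_dist() -> dict[str, dict[str, float]]:
    return {"bsub-like": {"A": 0.5, "B": 0.35, "C": 0.15},
            "non-bsub-like": {"A": 0.5, "D": 0.35, "E": 0.15}}


@dataclass
class SynthConfig:
    """Study conditions of the synthetic census.

    Divergences are expected substitutions/site; ``divergence_within`` is
    the leaf branch length inside a clade and ``divergence_between`` the
    separation of the two clade ancestors. ``family_divergence_scale`` and
    ``clade_divergence_scale`` multiply the within-clade branch per family
    and per clade, inducing the observed diversity orderings
    (ComX > ComQ > ComP > ComA; non-bsub > bsub)."""

    n_genomes_per_clade: int = 50
    clades: tuple[str, str] = CLADES
    divergence_within: float = 0.1
    divergence_between: float = 0.5
    clade_divergence_scale: dict[str, float] = field(
        default_factory=lambda: {"bsub-like": 1.0, "non-bsub-like": 1.6})
    family_divergence_scale: dict[str, float] = field(
        default_factory=lambda: {"ComQ": 1.8, "ComX": 2.5, "ComP": 1.0, "ComA": 0.5})
    overlap_type_by_clade: dict[str, dict[str, float]] = field(
        default_factory=_default_overlap_dist)
    p_unusual: float = 0.1
    n_decoys: int = 4
    intergenic_gap: tuple[int, int] = (5, 120)
    ext_qx: tuple[int, int] = (13, 18)   # comQ C-terminal extension (aa), types B/C
    ext_xp_c: int = 14                    # comP N-terminal extension, type C
    ext_xp_e: int = 3                     # comP N-terminal extension, type E
    ext_pa: int = 21                      # comP C-terminal extension, types D/E
    seed: int = 0

    def validate(self) -> None:
        if self.divergence_between < self.divergence_within:
            raise ValueError("divergence_between must be >= divergence_within")
        if not 0.0 <= self.p_unusual <= 1.0:
            raise ValueError("p_unusual must be in [0, 1]")
        for clade, dist in self.overlap_type_by_clade.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"overlap distribution for {clade!r} must sum to 1")
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValueError("overlap probabilities must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["clades"] = list(self.clades)
        data["intergenic_gap"] = list(self.intergenic_gap)
        data["ext_qx"] = list(self.ext_qx)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("clades", "intergenic_gap", "ext_qx"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruthEntry:
    genome_id: str
    contig_id: str
    clade: str
    strand: str
    overlap_type: str
    unusual: str  # none | antisense_comX | hypothetical_comX
    coords: dict[str, tuple[int, int, str]]       # role -> (start, end, strand)
    proteins: dict[str, str]                       # role -> realized protein


# ---------------------------------------------------------------------------
# Overlap-aware nucleotide construction
# ---------------------------------------------------------------------------

def _pick(options: list[str], rng: np.random.Generator) -> str:
    return options[rng.integers(len(options))]


def _choose_codons_cext(down_protein: str, k: int, rng: np.random.Generator,
                        ) -> tuple[list[str], str, str]:
    """Codons of the downstream gene accommodating a k-aa C-terminal
    extension of its upstream neighbour (frame +1 overlap of 3k+1 bp).

    Constraints on downstream codons 0..k: the shifted-frame codons
    ``codons[j][1:] + codons[j+1][0]`` must be non-stop for j < k-1 and a
    stop exactly at j = k-1. Returns (codons, extension residues of the
    upstream gene, realized downstream protein).
    """
    if k + 1 >= len(down_protein):
        raise ValueError("extension too long for the downstream gene")
    prot = list(down_protein)
    codons: list[str] = []

    def _no_stop(prev: str, c: str) -> bool:
        return not prev or (prev[1:] + c[0]) not in STOPS

    for j, aa in enumerate(prot):
        prev = codons[-1] if codons else ""
        if j == k - 1:
            # codon whose last two nts spell the start of a stop (TA or TG),
            # without completing a stop with its predecessor
            opts = [c for c in _syn(aa)
                    if c[1:] in ("TA", "TG") and _no_stop(prev, c)]
            if not opts:
                prot[j] = "L"  # CTA/TTA/CTG/TTG start with C/T: always safe
                opts = [c for c in _syn("L") if c[1:] in ("TA", "TG")]
                opts = [c for c in opts if _no_stop(prev, c)]
            codons.append(_pick(opts, rng))
        elif j == k:
            want = {"TA": "AG", "TG": "A"}[prev[1:]]  # first nts completing a stop
            opts = [c for c in _syn(aa) if c[0] in want]
            if not opts:
                prot[j] = "E" if "G" in want else "K"
                opts = [c for c in _syn(prot[j]) if c[0] in want]
            codons.append(_pick(opts, rng))
        elif j < k - 1:
            opts = [c for c in _syn(aa) if _no_stop(prev, c)]
            if not opts:
                prot[j] = "P"  # CCN starts with C: never completes a stop
                opts = _syn("P")
            codons.append(_pick(opts, rng))
        else:
            codons.append(_pick(_syn(aa), rng))
    # extension residues read in the +1 frame: 'GC?' (Ala) then the patterns
    ext = "A" + "".join(_translate_codon(codons[j][1:] + codons[j + 1][0])
                        for j in range(0, k - 1))
    return codons, ext, "".join(prot)


def _choose_codons_next(codons: list[str], prot: list[str], m: int,
                        rng: np.random.Generator) -> str:
    """Adjust the tail codons of an upstream gene so its downstream
    neighbour can start inside it with an m-aa N-terminal extension
    (frame overlap of 3m+1 bp).

    ``codons``/``prot`` are modified in place from index ``t = len - m``
    onward: the downstream ATG start is spelled by codons ``t``/``t+1`` and
    shifted-frame codons through the rest of the gene (and across its TAA
    stop) are kept non-stop. Returns the downstream extension residues
    (length m, leading M)."""
    L = len(prot)
    t = L - m
    if t <= 1:
        raise ValueError("extension too long for the upstream gene")
    for j in range(t, L):
        aa = prot[j]
        if j == t:
            opts = [c for c in _syn(aa) if c[2] == "A"]
            if not opts:
                prot[j] = "K"
                opts = [c for c in _syn("K") if c[2] == "A"]
        elif j == t + 1:
            opts = [c for c in _syn(aa) if c[:2] == "TG"]
            if not opts:
                prot[j] = "W"
                opts = ["TGG"]
        else:
            opts = _syn(aa)
            if codons[j - 1][2] == "T":
                safe = [c for c in opts if c[:2] not in ("AA", "AG", "GA")]
                if not safe:
                    prot[j] = "P"  # CCN starts with C: never completes a stop
                    safe = _syn("P")
                opts = safe
        codons[j] = _pick(opts, rng)
    ext_codons = ["ATG"] + [codons[j][2] + codons[j + 1][:2] for j in range(t + 1, L - 1)]
    if m > 1:
        ext_codons.append(codons[L - 1][2] + "TA")  # reads into TAA; '?TA' is never a stop
    ext = "".join(_translate_codon(c) for c in ext_codons)
    assert ext[0] == "M" and len(ext) == m
    return ext


@dataclass
class _Gene:
    role: str
    start: int  # 1-based within the locus block
    end: int
    strand: str
    protein: str


def build_locus_block(proteins: dict[str, str], overlap_type: str,
                      unusual: str, rng: np.random.Generator,
                      config: SynthConfig | None = None,
                      ) -> tuple[str, list[_Gene]]:
    """Construct the nucleotide block of one locus on the '+' strand.

    Returns the DNA and the four gene records with block-relative 1-based
    coordinates and realized proteins. ``unusual`` loci use the no-overlap
    geometry with a planted non-homologous comX ORF (same or opposite
    strand)."""
    cfg = config or SynthConfig()
    if overlap_type not in "ABCDE":
        raise ValueError(f"unknown overlap type {overlap_type!r}")
    if unusual not in ("none", "antisense_comX", "hypothetical_comX"):
        raise ValueError(f"unknown unusual kind {unusual!r}")
    if unusual != "none" and overlap_type != "A":
        raise ValueError("unusual loci use the type-A geometry")

    gap = lambda: int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
    q, x, p, a = (proteins[r] for r in ROLES)
    qx = overlap_type in ("B", "C")
    xp = overlap_type in ("C", "E")
    pa = overlap_type in ("D", "E")
    k_qx = int(rng.integers(cfg.ext_qx[0], cfg.ext_qx[1] + 1)) if qx else 0
    m_xp = (cfg.ext_xp_c if overlap_type == "C" else cfg.ext_xp_e) if xp else 0
    k_pa = cfg.ext_pa if pa else 0

    genes: list[_Gene] = []
    buf: list[str] = []
    pos = 1  # next free 1-based position

    def emit(s: str) -> None:
        nonlocal pos
        buf.append(s)
        pos += len(s)

    # --- comQ ---
    q_start = pos
    if qx:
        x_codons, q_ext, x_real = _choose_codons_cext(x, k_qx, rng)
        emit(backtranslate(q, rng) + "GC")
        x_start = pos
        q_end = x_start + 3 * k_qx  # overlap 3k+1 bp, +1 frame shift
        q_real = q + q_ext
    else:
        emit(backtranslate(q, rng) + _pick(list(STOPS), rng))
        q_end = pos - 1
        q_real = q
        emit(random_dna(gap(), rng))
        x_start = pos
    genes.append(_Gene("ComQ", q_start, q_end, "+", q_real))

    # --- comX (or the planted unusual variant) ---
    if unusual != "none":
        hypx = list(random_protein(HYPX_LENGTH, rng))
        hypx[0] = "M"
        hypx[HYPX_LENGTH - 6] = "W"
        hypx = "".join(hypx)
        x_dna = backtranslate(hypx, rng) + "TAA"
        x_strand = "-" if unusual == "antisense_comX" else "+"
        if x_strand == "-":
            x_dna = reverse_complement(x_dna)
        emit(x_dna)
        x_end = pos - 1
        genes.append(_Gene("ComX", x_start, x_end, x_strand, hypx))
        emit(random_dna(gap(), rng))
        p_start = pos
        p_head = ""
    else:
        if not qx:
            x_codons = [_pick(_syn(aa), rng) for aa in x]
            x_real = x
        x_prot = list(x_real)
        if xp:
            assert k_qx + 1 < len(x) - m_xp, "QX and XP regions must not collide"
            p_head = _choose_codons_next(x_codons, x_prot, m_xp, rng)
            x_stop = "TAA"
        else:
            p_head = ""
            x_stop = _pick(list(STOPS), rng)
        x_real = "".join(x_prot)
        emit("".join(x_codons) + x_stop)
        x_end = pos - 1
        genes.append(_Gene("ComX", x_start, x_end, "+", x_real))
        if xp:
            p_start = x_end - 3 * m_xp  # overlap 3m+1 bp
        else:
            emit(random_dna(gap(), rng))
            p_start = pos

    # --- comP ---
    if xp and unusual == "none":
        # 'A' (last nt of comX's TAA) + 'TG' completes the boundary codon
        # as ATG: the residue after the extension is forced to Met.
        p_mid = "TG" + backtranslate(p[1:], rng)
        p_real_base = p_head + "M" + p[1:]
    else:
        p_mid = backtranslate(p, rng)
        p_real_base = p
    if pa:
        a_codons, p_ext, a_real = _choose_codons_cext(a, k_pa, rng)
        emit(p_mid + "GC")
        a_start = pos
        p_end = a_start + 3 * k_pa
        p_real = p_real_base + p_ext
    else:
        emit(p_mid + _pick(list(STOPS), rng))
        p_end = pos - 1
        p_real = p_real_base
        emit(random_dna(gap(), rng))
        a_start = pos
        a_codons, a_real = [_pick(_syn(aa), rng) for aa in a], a
    genes.append(_Gene("ComP", p_start, p_end, "+", p_real))

    # --- comA ---
    emit("".join(a_codons) + _pick(list(STOPS), rng))
    a_end = pos - 1
    genes.append(_Gene("ComA", a_start, a_end, "+", a_real))

    dna = "".join(buf)
    for g in genes:
        got = translate_cds(dna[g.start - 1:g.end], g.strand)
        if got != g.protein:
            raise AssertionError(
                f"locus construction self-check failed for {g.role} "
                f"(type {overlap_type}, unusual {unusual})")
    return dna, genes


def plant_locus(genome: AnnotatedGenome, proteins: dict[str, str],
                overlap_type: str, unusual: str, position: int,
                rng: np.random.Generator | int = 0, strand: str = "+",
                clade: str = "", config: SynthConfig | None = None,
                gene_prefix: str | None = None,
                ) -> tuple[AnnotatedGenome, GroundTruthEntry]:
    """Insert one comQXPA locus into a genome's (single) contig.

    The locus block is built on the '+' strand and reverse-complemented as a
    whole for ``strand='-'``; existing genes downstream of ``position`` are
    shifted. Returns the genome and the matching ground-truth entry."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    contig_id = next(iter(genome.contigs))
    contig = genome.contigs[contig_id]
    if not 1 <= position <= len(contig) + 1:
        raise ValueError("position outside the contig")
    dna, genes = build_locus_block(proteins, overlap_type, unusual, rng, config)
    if strand == "-":
        L = len(dna)
        dna = reverse_complement(dna)
        for g in genes:
            g.start, g.end = L - g.end + 1, L - g.start + 1
            g.strand = "-" if g.strand == "+" else "+"
    shift = len(dna)
    genome.contigs[contig_id] = contig[:position - 1] + dna + contig[position - 1:]
    for g in genome.genes:
        if g.start >= position:
            g.start += shift
            g.end += shift
    prefix = gene_prefix or f"{genome.genome_id}_L{position}"
    coords: dict[str, tuple[int, int, str]] = {}
    prots: dict[str, str] = {}
    for g in genes:
        start, end = g.start + position - 1, g.end + position - 1
        rec = GeneRecord(gene_id=f"{prefix}_{g.role}", contig_id=contig_id,
                         start=start, end=end, strand=g.strand, protein=g.protein)
        genome.genes.append(rec)
        coords[g.role] = (start, end, g.strand)
        prots[g.role] = g.protein
    genome.sort_and_index()
    truth = GroundTruthEntry(
        genome_id=genome.genome_id, contig_id=contig_id, clade=clade,
        strand=strand, overlap_type=overlap_type, unusual=unusual,
        coords=coords, proteins=prots)
    return genome, truth


DECOY_KINDS = ("hk", "rr", "ipt", "random")
_DECOY_ROLE = {"hk": "ComP", "rr": "ComA", "ipt": "ComQ"}
#: decoys are appended with at least this much clearance so they can never
#: satisfy the census's adjacency rule with any other gene
DECOY_CLEARANCE = 701


def make_decoys(genome: AnnotatedGenome, n: int,
                seed: int | np.random.Generator = 0,
                divergence: float = 0.35) -> AnnotatedGenome:
    """Append ``n`` isolated decoy genes: full-length histidine-kinase
    (ComP-family), response-regulator (ComA-family) and isoprenyl-transferase
    (ComQ-family) homologs plus random-composition proteins, each separated
    by > 600 bp from every other gene and never in comQXPA serial order."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contig_id = next(iter(genome.contigs))
    anc = ancestors()
    for i in range(n):
        kind = DECOY_KINDS[i % len(DECOY_KINDS)]
        if kind == "random":
            prot = random_protein(int(rng.integers(150, 400)), rng)
        else:
            prot = mutate(anc[_DECOY_ROLE[kind]], divergence, rng)
        dna = backtranslate(prot, rng) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            dna = reverse_complement(dna)
        pad = random_dna(DECOY_CLEARANCE + int(rng.integers(0, 300)), rng)
        contig = genome.contigs[contig_id]
        start = len(contig) + len(pad) + 1
        genome.contigs[contig_id] = contig + pad + dna
        genome.genes.append(GeneRecord(
            gene_id=f"{genome.genome_id}_decoy{i}_{kind}", contig_id=contig_id,
            start=start, end=start + len(dna) - 1, strand=strand, protein=prot))
    genome.sort_and_index()
    return genome


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SynthDataset:
    config: SynthConfig
    genomes: list[AnnotatedGenome]
    truth: list[GroundTruthEntry]
    families: dict[str, dict[str, str]]      # role -> {leaf name -> protein}
    clade_of: dict[str, str]                  # leaf name -> clade
    seed_alignments: dict[str, Msa]

    def family_msa(self, role: str, clade: str | None = None) -> Msa:
        items = [(n, s) for n, s in self.families[role].items()
                 if clade is None or self.clade_of[n] == clade]
        return Msa(names=[n for n, _ in items], rows=[s for _, s in items])

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out_dir / "config.yaml")
        for g in self.genomes:
            write_genome(g, out_dir / "genomes")
        import pandas as pd
        rows = []
        for t in self.truth:
            row = {"genome_id": t.genome_id, "contig_id": t.contig_id,
                   "clade": t.clade, "strand": t.strand,
                   "overlap_type": t.overlap_type, "unusual": t.unusual}
            for role, (s, e, st) in t.coords.items():
                row[f"{role}_start"], row[f"{role}_end"], row[f"{role}_strand"] = s, e, st
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
        from .genome_io import write_msa
        aln_dir = out_dir / "seed_alignments"
        aln_dir.mkdir(exist_ok=True)
        for name, msa in self.seed_alignments.items():
            write_msa(msa, aln_dir / f"{name}.afa")


def simulate(config: SynthConfig | None = None) -> SynthDataset:
    """Generate the full synthetic dataset under one configuration.

    Deterministic for a fixed config (seed included): identical GFF3/FASTA
    bytes on repeated calls."""
    cfg = config or SynthConfig()
    cfg.validate()
    anc = ancestors()
    master = np.random.SeedSequence(cfg.seed)
    fam_seed, genome_seed, msa_seed = master.spawn(3)
    fam_rngs = fam_seed.spawn(len(ROLES))

    families: dict[str, dict[str, str]] = {}
    clade_of: dict[str, str] = {}
    sizes = {c: cfg.n_genomes_per_clade for c in cfg.clades}
    for role, ss in zip(ROLES, fam_rngs):
        mask = (COMX_TRP_POS,) if role == "ComX" else ()
        rates = comx_site_rates() if role == "ComX" else None
        scale = cfg.family_divergence_scale.get(role, 1.0)
        seqs, cl = evolve_family(
            anc[role], sizes, cfg.divergence_within * scale, cfg.divergence_between,
            seed=ss.generate_state(1)[0] % (2**31), mask=mask, site_rates=rates,
            clade_scale=cfg.clade_divergence_scale)
        families[role] = seqs
        clade_of = cl  # identical naming across roles

    genomes: list[AnnotatedGenome] = []
    truth: list[GroundTruthEntry] = []
    g_rngs = genome_seed.spawn(2 * cfg.n_genomes_per_clade)
    idx = 0
    for clade in cfg.clades:
        dist = cfg.overlap_type_by_clade[clade]
        type_names = sorted(dist)
        type_probs = np.array([dist[t] for t in type_names])
        for i in range(cfg.n_genomes_per_clade):
            rng = np.random.default_rng(g_rngs[idx])
            idx += 1
            leaf = f"{clade}_{i:03d}"
            gid = f"{clade.split('-')[0]}{i:03d}" if clade == "bsub-like" else f"nonbsub{i:03d}"
            genome = AnnotatedGenome(genome_id=gid,
                                     contigs={f"{gid}_c1": random_dna(200, rng)})
            unusual = "none"
            if clade == "non-bsub-like" and rng.random() < cfg.p_unusual:
                unusual = "antisense_comX" if rng.random() < 0.5 else "hypothetical_comX"
            ov = "A" if unusual != "none" else type_names[
                rng.choice(len(type_names), p=type_probs)]
            strand = "+" if rng.random() < 0.5 else "-"
            prots = {role: families[role][leaf] for role in ROLES}
            genome, t = plant_locus(genome, prots, ov, unusual,
                                    position=101, rng=rng, strand=strand,
                                    clade=clade, config=cfg,
                                    gene_prefix=f"{gid}_com")
            genome = make_decoys(genome, cfg.n_decoys, rng)
            genomes.append(genome)
            truth.append(t)
    msas = seed_msas(seed=int(msa_seed.generate_state(1)[0] % (2**31)))
    return SynthDataset(config=cfg, genomes=genomes, truth=truth,
                        families=families, clade_of=clade_of,
                        seed_alignments=msas)
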