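"""Profile hidden Markov models for remote-homology search.

A profile is built from a seed alignment (match columns = columns with gap
fraction < 0.5, maximum-likelihood emission/transition estimates with +1
Laplace pseudocounts) and scored against protein sequences in glocal mode:
global in the model, local in the sequence, so a short signal-peptide model
can hit anywhere inside a longer (possibly mispredicted) ORF.

Architecture (per model node ``k`` = 0..M; node 0 is Begin):

* match states ``M_1..M_M`` (emit), insert states ``I_0..I_M`` (emit),
  delete states ``D_1..D_M`` (silent);
* from each of ``{M_k, I_k, D_k}`` transitions go to
  ``{M_{k+1}, I_k, D_{k+1}}``; at ``k = M`` the successors are
  ``{End, I_M}``;
* entry: a free N-flank emits any sequence prefix at background odds, then
  Begin; exit from node M to a free C-flank.

The reported score is ``log2 P(seq | model) / P(seq | background)`` where
flank residues contribute odds of exactly 1. The forward score sums over all
(entry point, state path, exit point) triples; Viterbi takes the maximum.
Statistical calibration fits a Gumbel to forward bit-scores of random
background-composition sequences; E-values use the fitted tail
``E = N * exp(-lambda * (s - mu))`` for a search over ``N`` proteins,
mirroring the census's E < 0.1 acceptance gate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gumbel_r

from .genome_io import AA_ALPHABET, AA_INDEX, Msa

LN2 = float(np.log(2.0))
_NEG = -1e30  # effective log-zero

# Source/successor index order used throughout: 0=M, 1=I, 2=D.
SRC_M, SRC_I, SRC_D = 0, 1, 2

#: Robinson & Robinson amino-acid frequencies (order = AA_ALPHABET); used as
#: the default null composition for calibration sequences.
ROBINSON_FREQS = np.array([
    0.0780, 0.0152, 0.0535, 0.0668, 0.0405, 0.0722, 0.0220, 0.0573, 0.0646,
    0.0934, 0.0219, 0.0429, 0.0520, 0.0426, 0.0516, 0.0715, 0.0581, 0.0652,
    0.0128, 0.0321])
ROBINSON_FREQS = ROBINSON_FREQS / ROBINSON_FREQS.sum()


@dataclass
class HitScore:
    query_id: str
    model_name: str
    bit_score: float
    e_value: float
    database_size: int


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with emission/transition parameters.

    ``transitions[k]`` is a 3x3 row-stochastic matrix: rows are the source
    state at node ``k`` (M/I/D; row M of node 0 is Begin), columns the
    successor (M_{k+1} or End, I_k, D_{k+1}). The D column at node M is
    structurally zero.
    """

    name: str
    M: int
    match_emissions: np.ndarray    # (M, 20)
    insert_emissions: np.ndarray   # (M+1, 20)
    transitions: np.ndarray        # (M+1, 3, 3)
    background: np.ndarray         # (20,)
    calibration: tuple[float, float] | None = None  # (mu, lambda)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("profile needs at least one match state")
        self._log_cache: dict[str, np.ndarray] = {}

    # -- cached log-space parameters -------------------------------------
    def _logs(self) -> dict[str, np.ndarray]:
        if not self._log_cache:
            with np.errstate(divide="ignore"):
                lm = np.log(self.match_emissions) - np.log(self.background)
                li = np.log(self.insert_emissions) - np.log(self.background)
                lt = np.log(self.transitions)
            lt[np.isneginf(lt)] = _NEG
            self._log_cache = {"m": lm, "i": li, "t": lt}
        return self._log_cache

    def validate(self) -> None:
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.allclose(self.insert_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("insert emission rows must sum to 1")
        sums = self.transitions.sum(axis=2)
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")


def _encode(seq: str) -> np.ndarray:
    """Map residues to alphabet indices; non-standard residues get -1."""
    return np.array([AA_INDEX.get(a, -1) for a in seq.upper()], dtype=np.int64)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_profile(msa: Msa, name: str) -> ProfileHMM:
    """Estimate a profile from a seed alignment.

    Match columns are those with gap fraction strictly below 0.5. Emissions
    and transitions are ML counts with +1 Laplace pseudocounts; the
    background is the alignment's residue frequency mixed 1:1 with the
    uniform distribution.
    """
    n, L = msa.n_rows, msa.n_cols
    cols = np.array([[AA_INDEX.get(c, -2) if c != "-" else -1 for c in row]
                     for row in msa.rows], dtype=np.int64)  # (n, L)
    gap_frac = (cols == -1).mean(axis=0)
    is_match = gap_frac < 0.5
    M = int(is_match.sum())
    if M == 0:
        raise ValueError("alignment has zero match columns (all gap fractions >= 0.5)")

    node_of_col = np.cumsum(is_match)  # match col -> its node (1-based)

    match_counts = np.zeros((M, 20))
    insert_counts = np.zeros((M + 1, 20))
    # transition counts: (node, src{M,I,D}, dst{M/E, I, D})
    trans_counts = np.zeros((M + 1, 3, 3))

    for r in range(n):
        state, node = SRC_M, 0  # Begin behaves as the M row of node 0
        for c in range(L):
            sym = cols[r, c]
            if is_match[c]:
                k = int(node_of_col[c])
                if sym >= 0:
                    match_counts[k - 1, sym] += 1
                    trans_counts[node, state, 0] += 1
                    state, node = SRC_M, k
                else:  # gap in a match column -> delete state
                    trans_counts[node, state, 2] += 1
                    state, node = SRC_D, k
            else:
                if sym >= 0:
                    insert_counts[node, sym] += 1
                    trans_counts[node, state, 1] += 1
                    state = SRC_I
                # gap in insert column: nothing happens
        trans_counts[node, state, 0] += 1  # exit to End

    match_emissions = (match_counts + 1.0) / (match_counts.sum(axis=1, keepdims=True) + 20.0)
    insert_emissions = (insert_counts + 1.0) / (insert_counts.sum(axis=1, keepdims=True) + 20.0)

    trans = np.zeros_like(trans_counts)
    for k in range(M + 1):
        for s in range(3):
            if k == 0 and s == SRC_D:
                continue  # no D_0 state
            row = trans_counts[k, s].copy()
            if k == M:
                row[2] = 0.0  # no D_{M+1}
                trans[k, s, :2] = (row[:2] + 1.0) / (row[:2].sum() + 2.0)
            else:
                trans[k, s] = (row + 1.0) / (row.sum() + 3.0)

    aa_counts = np.bincount(cols[cols >= 0].ravel(), minlength=20).astype(float)
    if aa_counts.sum() == 0:
        raise ValueError("alignment contains no residues")
    background = 0.5 * (aa_counts / aa_counts.sum()) + 0.5 / 20.0

    model = ProfileHMM(name=name, M=M, match_emissions=match_emissions,
                       insert_emissions=insert_emissions, transitions=trans,
                       background=background)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _emission_rows(model: ProfileHMM, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position log-odds emission vectors; unknown residues score 0."""
    logs = model._logs()
    L = len(enc)
    em = np.zeros((L, model.M))
    ei = np.zeros((L, model.M + 1))
    known = enc >= 0
    em[known] = logs["m"][:, enc[known]].T
    ei[known] = logs["i"][:, enc[known]].T
    return em, ei


def _chain_deletes(a: np.ndarray, tdd: np.ndarray, mode: str) -> np.ndarray:
    """Resolve the silent-delete chain D_k = op(a_k, D_{k-1} + tdd_k).

    ``a`` are the per-node entry values into D (from M/I of node k-1), ``tdd``
    the D->D log transition entering node k. Vectorized via the cumulative
    transform D_k - C_k = accumulate(a_k - C_k) with C = cumsum(tdd).
    """
    c = np.cumsum(tdd)
    shifted = a - c
    if mode == "sum":
        acc = np.logaddexp.accumulate(shifted)
    else:
        acc = np.maximum.accumulate(shifted)
    return acc + c


def _dp(model: ProfileHMM, seq: str, mode: str, keep: bool = False):
    """Shared forward/Viterbi dynamic program in log-odds space.

    Returns the total log2 score; with ``keep=True`` also the full DP
    matrices for traceback.
    """
    if not seq:
        raise ValueError("cannot score an empty sequence")
    enc = _encode(seq)
    L, M = len(enc), model.M
    logs = model._logs()
    lt = logs["t"]  # (M+1, 3, 3)
    em, ei = _emission_rows(model, enc)

    combine = np.logaddexp if mode == "sum" else np.maximum

    tMM = lt[:-1, SRC_M, 0]  # node k -> M_{k+1}, k=0..M-1
    tIM = lt[:-1, SRC_I, 0]
    tDM = lt[:-1, SRC_D, 0]
    tMI = lt[:, SRC_M, 1]
    tII = lt[:, SRC_I, 1]
    tDI = lt[:, SRC_D, 1]
    tMD = lt[:-1, SRC_M, 2]
    tID = lt[:-1, SRC_I, 2]
    tDD = lt[:-1, SRC_D, 2]
    tME, tIE, tDE = lt[M, SRC_M, 0], lt[M, SRC_I, 0], lt[M, SRC_D, 0]

    neg = np.full(M, _NEG)
    # state value arrays indexed by node 1..M (match/delete) and 0..M (insert)
    Mv = neg.copy()
    Iv = np.full(M + 1, _NEG)
    Dv = neg.copy()
    # i = 0: only delete chain reachable (Begin value 0)
    a0 = np.full(M, _NEG)
    a0[0] = lt[0, SRC_M, 2]  # Begin -> D_1
    Dv = _chain_deletes(a0, np.concatenate(([0.0], tDD[1:])), mode)

    if keep:
        Mk = np.full((L + 1, M), _NEG)
        Ik = np.full((L + 1, M + 1), _NEG)
        Dk = np.full((L + 1, M), _NEG)
        Dk[0] = Dv

    exit_total = combine(Dv[M - 1] + tDE, _NEG)  # all-delete, zero-emission path

    for i in range(1, L + 1):
        prevM, prevI, prevD = Mv, Iv, Dv
        # Match: from node k-1 states at i-1; Begin contributes value 0 at k=1.
        fromM = np.concatenate(([0.0], prevM[:-1])) + tMM
        fromI = prevI[:-1] + tIM
        fromD = np.concatenate(([_NEG], prevD[:-1])) + tDM
        Mv = em[i - 1] + combine(combine(fromM, fromI), fromD)
        # Insert: node k from same-node states at i-1 (Begin feeds I_0).
        srcM = np.concatenate(([0.0], prevM)) + tMI
        srcI = prevI + tII
        srcD = np.concatenate(([_NEG], prevD)) + tDI
        Iv = ei[i - 1] + combine(combine(srcM, srcI), srcD)
        # Delete chain at position i: entries from M/I of node k-1.
        aM = np.concatenate(([0.0], Mv[:-1])) + tMD
        aI = Iv[:-1] + tID
        a = combine(aM, aI)
        Dv = _chain_deletes(a, np.concatenate(([0.0], tDD[1:])), mode)

        exit_here = combine(combine(Mv[M - 1] + tME, Iv[M] + tIE), Dv[M - 1] + tDE)
        exit_total = combine(exit_total, exit_here)
        if keep:
            Mk[i], Ik[i], Dk[i] = Mv, Iv, Dv

    score_bits = float(exit_total) / LN2
    if keep:
        return score_bits, (Mk, Ik, Dk)
    return score_bits


def score_forward(model: ProfileHMM, seq: str) -> float:
    """Forward bit-score: log2 of the summed odds over all glocal paths."""
    if not seq:
        raise ValueError("cannot score an empty sequence")
    return float(_forward_batch(model, _encode(seq)[None, :])[0])


def _dchain_prob(a: np.ndarray, tdd_in: np.ndarray, block: int = 64) -> np.ndarray:
    """Silent-delete chain ``D_k = a_k + D_{k-1} * t_k`` in probability
    space, vectorized blockwise via cumulative products (block size keeps
    the running product within float64 range)."""
    B, M = a.shape
    out = np.empty_like(a)
    carry = None
    for s in range(0, M, block):
        e = min(s + block, M)
        a_blk = a[:, s:e].copy()
        t_blk = tdd_in[s:e]
        if carry is not None:
            a_blk[:, 0] = a_blk[:, 0] + carry * t_blk[0]
        Q = np.cumprod(np.concatenate(([1.0], t_blk[1:])))
        blk = np.cumsum(a_blk / Q, axis=1) * Q
        out[:, s:e] = blk
        carry = blk[:, -1]
    return out


def _forward_batch(model: ProfileHMM, encs: np.ndarray) -> np.ndarray:
    """Forward bit-scores for a batch of equal-length encoded sequences.

    Runs the forward recurrences in probability space with per-position
    rescaling (the classical scaling trick), which is much faster than
    log-space arithmetic; exit mass is accumulated in log space so glocal
    entry/exit at every position stays exact.
    """
    B, L = encs.shape
    M = model.M
    t = model.transitions
    with np.errstate(divide="ignore"):
        em_ratio = model.match_emissions / model.background        # (M, 20)
        ei_ratio = model.insert_emissions / model.background       # (M+1, 20)
    em_pad = np.column_stack([em_ratio, np.ones(M)])               # unknown -> odds 1
    ei_pad = np.column_stack([ei_ratio, np.ones(M + 1)])
    idx = np.where(encs >= 0, encs, 20)

    tMM, tIM, tDM = t[:-1, SRC_M, 0], t[:-1, SRC_I, 0], t[:-1, SRC_D, 0]
    tMI, tII, tDI = t[:, SRC_M, 1], t[:, SRC_I, 1], t[:, SRC_D, 1]
    tMD, tID, tDD = t[:-1, SRC_M, 2], t[:-1, SRC_I, 2], t[:-1, SRC_D, 2]
    tME, tIE, tDE = t[M, SRC_M, 0], t[M, SRC_I, 0], t[M, SRC_D, 0]
    tdd_in = np.concatenate(([1.0], tDD[1:]))

    scale = np.zeros(B)            # log of accumulated rescale factors
    begin = np.ones(B)             # Begin value on the current scale
    Mv = np.zeros((B, M))
    Iv = np.zeros((B, M + 1))
    a0 = np.zeros((B, M))
    a0[:, 0] = begin * t[0, SRC_M, 2]
    Dv = _dchain_prob(a0, tdd_in)
    exit_log = np.log(np.maximum(Dv[:, M - 1] * tDE, 1e-300)) + scale

    zero_col = np.zeros((B, 1))
    for i in range(1, L + 1):
        prevM, prevI, prevD = Mv, Iv, Dv
        em_i = em_pad[:, idx[:, i - 1]].T          # (B, M)
        ei_i = ei_pad[:, idx[:, i - 1]].T          # (B, M+1)
        fromM = np.concatenate([begin[:, None], prevM[:, :-1]], axis=1) * tMM
        fromI = prevI[:, :-1] * tIM
        fromD = np.concatenate([zero_col, prevD[:, :-1]], axis=1) * tDM
        Mv = em_i * (fromM + fromI + fromD)
        srcM = np.concatenate([begin[:, None], prevM], axis=1) * tMI
        srcI = prevI * tII
        srcD = np.concatenate([zero_col, prevD], axis=1) * tDI
        Iv = ei_i * (srcM + srcI + srcD)
        aM = np.concatenate([begin[:, None], Mv[:, :-1]], axis=1) * tMD
        aI = Iv[:, :-1] * tID
        Dv = _dchain_prob(aM + aI, tdd_in)

        # floor keeps the score finite when the live mass underflows
        exit_here = np.maximum(Mv[:, M - 1] * tME + Iv[:, M] * tIE
                               + Dv[:, M - 1] * tDE, 1e-300)
        exit_log = np.logaddexp(exit_log, np.log(exit_here) + scale)

        # rescale so the largest live value (incl. Begin) is 1
        c = np.maximum(np.maximum(Mv.max(axis=1), Iv.max(axis=1)),
                       np.maximum(Dv.max(axis=1), begin))
        c = np.where(c > 0, c, 1.0)
        Mv /= c[:, None]
        Iv /= c[:, None]
        Dv /= c[:, None]
        begin = begin / c
        scale += np.log(c)

    return exit_log / LN2


def score_viterbi(model: ProfileHMM, seq: str) -> float:
    """Viterbi bit-score: log2 odds of the single best glocal path."""
    return _dp(model, seq, "max")


def viterbi_match_coverage(model: ProfileHMM, seq: str) -> float:
    """Fraction of model match states used (vs deleted) on the Viterbi path.

    Operationalizes the census's manual check for alignment coverage.
    """
    score, (Mk, Ik, Dk) = _dp(model, seq, "max", keep=True)
    lt = model._logs()["t"]
    M = model.M
    tol = 1e-6
    target = score * LN2
    # locate exit
    best_i, best_state = None, None
    for i in range(len(seq), -1, -1):
        for state, val in (("M", Mk[i, M - 1] + lt[M, SRC_M, 0]),
                           ("I", Ik[i, M] + lt[M, SRC_I, 0]),
                           ("D", Dk[i, M - 1] + lt[M, SRC_D, 0])):
            if abs(val - target) < tol and val > _NEG / 2:
                best_i, best_state = i, state
                break
        if best_i is not None:
            break
    if best_i is None:  # numerically degenerate; report zero coverage
        return 0.0

    n_match = 0
    i, k, state = best_i, M, best_state  # k = node of current state (I uses node index directly)
    while True:
        if state == "M":
            n_match += 1
            cur = Mk[i, k - 1] - (model._logs()["m"][k - 1, AA_INDEX.get(seq[i - 1].upper(), -1)]
                                  if AA_INDEX.get(seq[i - 1].upper(), -1) >= 0 else 0.0)
            # predecessors at node k-1, position i-1
            preds = []
            if k == 1:
                preds.append(("B", 0, 0.0 + lt[0, SRC_M, 0]))
            else:
                preds.append(("M", k - 1, Mk[i - 1, k - 2] + lt[k - 1, SRC_M, 0]))
                preds.append(("D", k - 1, Dk[i - 1, k - 2] + lt[k - 1, SRC_D, 0]))
            preds.append(("I", k - 1, Ik[i - 1, k - 1] + lt[k - 1, SRC_I, 0]))
            i -= 1
        elif state == "I":
            sym = AA_INDEX.get(seq[i - 1].upper(), -1)
            cur = Ik[i, k] - (model._logs()["i"][k, sym] if sym >= 0 else 0.0)
            preds = [("I", k, Ik[i - 1, k] + lt[k, SRC_I, 1])]
            if k == 0:
                preds.append(("B", 0, 0.0 + lt[0, SRC_M, 1]))
            else:
                preds.append(("M", k, Mk[i - 1, k - 1] + lt[k, SRC_M, 1]))
                preds.append(("D", k, Dk[i - 1, k - 1] + lt[k, SRC_D, 1]))
            i -= 1
        else:  # D
            cur = Dk[i, k - 1]
            preds = []
            if k == 1:
                preds.append(("B", 0, 0.0 + lt[0, SRC_M, 2]))
            else:
                preds.append(("M", k - 1, Mk[i, k - 2] + lt[k - 1, SRC_M, 2]))
                preds.append(("I", k - 1, Ik[i, k - 1] + lt[k - 1, SRC_I, 2]))
                preds.append(("D", k - 1, Dk[i, k - 2] + lt[k - 1, SRC_D, 2]))
        chosen = None
        for pstate, pk, val in preds:
            if abs(val - cur) < tol:
                chosen = (pstate, pk)
                break
        if chosen is None:  # fall back to best available
            chosen = max(preds, key=lambda p: p[2])[:2]
        state, k = chosen
        if state == "B":
            break
    return n_match / M


# ---------------------------------------------------------------------------
# Calibration and E-values
# ---------------------------------------------------------------------------

def calibrate(model: ProfileHMM, n_null: int = 500,
              null_len: int | None = None, seed: int = 0) -> ProfileHMM:
    """Fit a Gumbel (mu, lambda) to forward scores of random null sequences.

    Null sequences are i.i.d. draws from a fixed background composition
    (Robinson frequencies); their length defaults to the model length.
    The fit is maximum likelihood; the parameters are stored on the model.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100 for a stable fit")
    if null_len is None:
        null_len = model.M
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n_null, null_len), p=ROBINSON_FREQS)
    scores = _forward_batch(model, draws)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate null score variance; cannot calibrate")
    mu, beta = gumbel_r.fit(scores)
    model.calibration = (float(mu), float(1.0 / beta))
    return model


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """MLE Gumbel fit returning (mu, lambda); exposed for parameter-recovery tests."""
    mu, beta = gumbel_r.fit(np.asarray(scores, dtype=float))
    return float(mu), float(1.0 / beta)


def evalue(model: ProfileHMM, bit_score: float, database_size: int) -> float:
    """Expected false hits at this score: ``N * exp(-lambda * (s - mu))``."""
    if model.calibration is None:
        raise ValueError(f"model {model.name!r} is not calibrated")
    mu, lam = model.calibration
    return max(0.0, database_size * float(np.exp(-lam * (bit_score - mu))))


def score_hit(model: ProfileHMM, query_id: str, seq: str,
              database_size: int) -> HitScore:
    s = score_forward(model, seq)
    return HitScore(query_id=query_id, model_name=model.name, bit_score=s,
                    e_value=evalue(model, s, database_size),
                    database_size=database_size)


# ---------------------------------------------------------------------------
# Serialization (documented key/value text format)
# ---------------------------------------------------------------------------

def save_model(model: ProfileHMM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format comcensus-phmm 1\n")
        fh.write(f"name {model.name}\n")
        fh.write(f"M {model.M}\n")
        fh.write(f"alphabet {AA_ALPHABET}\n")
        if model.calibration is not None:
            fh.write(f"calibration {float(model.calibration[0])!r} {float(model.calibration[1])!r}\n")
        fh.write("background " + " ".join(repr(float(x)) for x in model.background) + "\n")
        for k in range(model.M):
            fh.write(f"match {k + 1} " + " ".join(repr(float(x)) for x in model.match_emissions[k]) + "\n")
        for k in range(model.M + 1):
            fh.write(f"insert {k} " + " ".join(repr(float(x)) for x in model.insert_emissions[k]) + "\n")
        for k in range(model.M + 1):
            fh.write(f"trans {k} " + " ".join(repr(float(x)) for x in model.transitions[k].ravel()) + "\n")


def load_model(path: str | Path) -> ProfileHMM:
    name, M, calibration, background = "", 0, None, None
    match_rows: dict[int, np.ndarray] = {}
    insert_rows: dict[int, np.ndarray] = {}
    trans_rows: dict[int, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0]
            if key == "name":
                name = parts[1] if len(parts) > 1 else ""
            elif key == "M":
                M = int(parts[1])
            elif key == "calibration":
                calibration = (float(parts[1]), float(parts[2]))
            elif key == "background":
                background = np.array([float(x) for x in parts[1:]])
            elif key == "match":
                match_rows[int(parts[1])] = np.array([float(x) for x in parts[2:]])
            elif key == "insert":
                insert_rows[int(parts[1])] = np.array([float(x) for x in parts[2:]])
            elif key == "trans":
                trans_rows[int(parts[1])] = np.array([float(x) for x in parts[2:]]).reshape(3, 3)
    model = ProfileHMM(
        name=name, M=M,
        match_emissions=np.vstack([match_rows[k] for k in range(1, M + 1)]),
        insert_emissions=np.vstack([insert_rows[k] for k in range(M + 1)]),
        transitions=np.stack([trans_rows[k] for k in range(M + 1)]),
        background=background, calibration=calibration)
    return model
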