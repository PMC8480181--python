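"""Structure-constrained profile scanning.

Aligns a :class:`~trscout.profile_model.TRProfile` to genomic windows with a
dynamic programme guided by the profile's nested consensus structure: the
recursion follows the guide-structure tree (pair nodes close both strands of
a helix together, Nussinov/CYK style on paired spans), so each consensus
pair contributes a bonus when the two aligned target residues close
canonically (Watson-Crick or G.U) and a penalty when they do not.
Pseudoknot-layer pairs are scored additively on the optimal nested-layer
trace, which keeps the scanner polynomial.

Scoring model (bits):

* match of profile column ``c`` to residue ``x``: ``log2(p_c(x)/bg(x))``;
  ambiguity codes score 0 but can never close a pair;
* each deleted profile column costs ``gap_open``;
* each run of inserted target residues at one profile boundary costs
  ``gap_open + gap_extend*(run-1)``, capped at ``max_insert_per_gap_region``;
* each consensus pair adds its bonus if both partners are matched to a
  canonical pair, else ``pair_penalty_broken``.

Significance is calibrated empirically against dinucleotide-preserving
shuffles of the target (Altschul-Erickson shuffling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .msa_io import revcomp_dna
from .profile_model import TRProfile

NEG = -np.inf

#: residue encoding used throughout the DP (4 = ambiguous/unscorable)
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_CANON = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}


def encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(ch, 4) for ch in seq.upper()], dtype=np.int64)


@dataclass(frozen=True)
class ScanConfig:
    """Scanner parameters (all score terms in bits)."""

    gap_open: float = -3.0
    gap_extend: float = -1.0
    pair_bonus_canonical: float = 1.0
    pair_bonus_covarying: float = 2.0
    pair_penalty_broken: float = -1.0
    score_threshold: float = 20.0
    max_insert_per_gap_region: int = 5
    window_stride: int = 1
    null_shuffles: int = 0
    seed: int = 0
    #: extra flanking sequence around stage-1 anchors for the full DP
    window_pad: Optional[int] = None
    #: candidate anchors refined per strand and record
    max_candidates: int = 4
    #: net indel band for the DP (None = unbanded, exact)
    dp_band: Optional[int] = None
    #: windows shorter than this cannot be scored (None = profile//2)
    min_window: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.score_threshold):
            raise ValueError("score_threshold must be finite")
        if self.null_shuffles < 0:
            raise ValueError("null_shuffles must be >= 0")


@dataclass
class Hit:
    """A scored genomic interval (0-based half-open, forward coordinates)."""

    target_id: str
    start: int
    end: int
    strand: str
    score: float
    trace: list[tuple[str, Optional[int], Optional[int]]]
    region_seq: str = ""
    evalue_emp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must precede end")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# guide tree
# ---------------------------------------------------------------------------

class GuideTree:
    """Precomputed structure of the DP recursion for one profile."""

    def __init__(self, profile: TRProfile, config: ScanConfig):
        self.profile = profile
        self.L = profile.length
        self.lo = profile.log_odds()
        self.partner = profile.pairs.partner_array(self.L)
        self.seg_end = [self.L] * self.L
        self._assign_seg_ends(0, self.L)
        self.pair_bonus = {}
        for i, j in profile.pairs.nested:
            self.pair_bonus[(i, j)] = profile.pair_bonus.get(
                (i, j), config.pair_bonus_canonical)
        self.pk_pairs = [(i, j, profile.pair_bonus.get((i, j),
                                                       config.pair_bonus_canonical))
                         for i, j in profile.pairs.pseudoknot]
        self.broken = config.pair_penalty_broken
        # 5x5 pair-score matrix per nested pair
        self.pairmat = {}
        for (i, j), bonus in self.pair_bonus.items():
            m = np.full((5, 5), self.broken)
            for a, b in _CANON:
                m[a, b] = bonus
            self.pairmat[(i, j)] = m

    def _assign_seg_ends(self, i: int, j: int) -> None:
        while i < j:
            self.seg_end[i] = j
            p = self.partner[i]
            if p == -1:
                i += 1
            else:
                self._assign_seg_ends(i + 1, p)
                self.seg_end[p] = p  # close columns own no table
                i = p + 1

    def owned_indices(self) -> list[int]:
        """Columns owning a DP table (unpaired or pair-opening), descending."""
        return [i for i in range(self.L - 1, -1, -1)
                if self.partner[i] == -1 or self.partner[i] > i]


# ---------------------------------------------------------------------------
# the DP
# ---------------------------------------------------------------------------

class _DP:
    def __init__(self, tree: GuideTree, S: np.ndarray, config: ScanConfig):
        self.tree = tree
        self.S = S
        self.cfg = config
        self.W = len(S)
        self.max_ins = config.max_insert_per_gap_region
        go, ge = config.gap_open, config.gap_extend
        self.ic = np.array(
            [0.0] + [go + ge * (m - 1) for m in range(1, self.W + 1)])
        self.ic[self.max_ins + 1:] = NEG
        self.del_cost = go
        self.tables: dict[int, np.ndarray] = {}
        self.pair_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.empty = self._empty_table()
        self.band = config.dp_band

    def _empty_table(self) -> np.ndarray:
        W = self.W
        E = np.full((W + 1, W + 1), NEG)
        for k in range(W + 1):
            hi = min(W, k + self.max_ins)
            E[k, k:hi + 1] = self.ic[:hi + 1 - k]
        return E

    def _tab(self, idx: int, end: int) -> np.ndarray:
        return self.empty if idx == end else self.tables[idx]

    def _preinsert(self, base: np.ndarray) -> np.ndarray:
        """max over m pre-inserted residues: ic[m] + base[k+m, l]."""
        out = base.copy()
        for m in range(1, min(self.max_ins, self.W) + 1):
            out[:-m, :] = np.maximum(out[:-m, :], self.ic[m] + base[m:, :])
        return out

    def run(self) -> None:
        tree, S, W = self.tree, self.S, self.W
        lo = tree.lo
        for i in tree.owned_indices():
            end = tree.seg_end[i]
            p = tree.partner[i]
            if p == -1:
                nxt = self._tab(i + 1, end)
                M = np.full((W + 1, W + 1), NEG)
                M[:W, :] = lo[i, S][:, None] + nxt[1:, :]
                base = np.maximum(M, self.del_cost + nxt)
                T = self._preinsert(base)
            else:
                inner = self._tab(i + 1, p)
                rest = self._tab(p + 1, end)
                G = self._pair_table(i, p, inner)
                Gp = self._preinsert(G)
                self.pair_cache[i] = (G, Gp)
                T = self._maxplus(Gp, rest, span_left=p + 1 - i)
            if self.band is not None:
                self._band_mask(T, end - i)
            self.tables[i] = T

    def _band_mask(self, T: np.ndarray, span: int) -> None:
        W = self.W
        diff = np.arange(W + 1)[None, :] - np.arange(W + 1)[:, None] - span
        T[np.abs(diff) > self.band] = NEG

    def _pair_table(self, i: int, p: int, inner: np.ndarray) -> np.ndarray:
        S, W = self.S, self.W
        lo = self.tree.lo
        pm = self.tree.pairmat[(i, p)]
        A = lo[i, S]                      # score of matching col i at k
        B = lo[p, S]                      # score of matching col p at m-1
        dc, br = self.del_cost, self.tree.broken
        G = np.full((W + 1, W + 1), NEG)
        # delete both strands
        np.maximum(G, 2 * dc + br + inner, out=G)
        # delete i, match p at m-1
        G[:, 1:] = np.maximum(G[:, 1:], dc + br + B[None, :] + inner[:, :-1])
        # match i at k, delete p
        G[:W, :] = np.maximum(G[:W, :], dc + br + A[:, None] + inner[1:, :])
        # match both: pair term on the aligned residues
        P2 = pm[S[:, None], S[None, :]]   # (W, W): residue k vs residue m-1
        G[:W, 1:] = np.maximum(G[:W, 1:],
                               A[:, None] + B[None, :] + P2 + inner[1:, :-1])
        return G

    def _maxplus(self, A: np.ndarray, Bt: np.ndarray,
                 span_left: int) -> np.ndarray:
        """C[k,l] = max_m A[k,m] + Bt[m,l], restricted to A's finite band."""
        W = self.W
        C = np.full((W + 1, W + 1), NEG)
        if self.band is None:
            for k in range(W + 1):
                row = A[k]
                finite = np.isfinite(row)
                if not finite.any():
                    continue
                idx = np.nonzero(finite)[0]
                C[k] = np.max(row[idx][:, None] + Bt[idx, :], axis=0)
        else:
            # m = k + s for diagonal offsets s inside the band: the split
            # point slides with k, so each offset is one diagonal of A
            # against a row-shifted view of Bt
            for d in range(-self.band, self.band + 1):
                s = span_left + d
                if s < 0:
                    continue
                if s > W:
                    break
                diag = np.diagonal(A, offset=s)       # A[k, k+s]
                n = diag.shape[0]
                np.maximum(C[:n], diag[:, None] + Bt[s:s + n, :], out=C[:n])
        return C

    # -- traceback ---------------------------------------------------------

    def traceback(self, k: int, l: int) -> list[tuple[str, Optional[int], Optional[int]]]:
        ops: list[tuple[str, Optional[int], Optional[int]]] = []
        self._tb_segment(0, self.tree.L, k, l, ops)
        return ops

    @staticmethod
    def _close(a: float, b: float) -> bool:
        return (a == b) or (math.isfinite(a) and math.isfinite(b)
                            and abs(a - b) < 1e-6)

    def _tb_segment(self, i: int, end: int, k: int, l: int, ops: list) -> None:
        while True:
            if i == end:
                for w in range(k, l):
                    ops.append(("I", None, w))
                return
            p = self.tree.partner[i]
            target = self.tables[i][k, l]
            if not math.isfinite(target):
                raise RuntimeError("traceback entered an unreachable cell")
            lo = self.tree.lo
            S = self.S
            if p == -1:
                nxt = self._tab(i + 1, end)
                done = False
                for m in range(0, min(self.max_ins, l - k) + 1):
                    v = self.ic[m]
                    if k + m < l and self._close(
                            target, v + lo[i, S[k + m]] + nxt[k + m + 1, l]):
                        for w in range(k, k + m):
                            ops.append(("I", None, w))
                        ops.append(("M", i, k + m))
                        i, k = i + 1, k + m + 1
                        done = True
                        break
                    if self._close(target, v + self.del_cost + nxt[k + m, l]):
                        for w in range(k, k + m):
                            ops.append(("I", None, w))
                        ops.append(("D", i, None))
                        i, k = i + 1, k + m
                        done = True
                        break
                if not done:
                    raise RuntimeError("traceback failed at unpaired column")
            else:
                inner = self._tab(i + 1, p)
                rest = self._tab(p + 1, end)
                G, Gp = self.pair_cache[i]
                split = None
                for m in range(k, l + 1):
                    if self._close(target, Gp[k, m] + rest[m, l]):
                        split = m
                        break
                if split is None:
                    raise RuntimeError("traceback failed at bifurcation")
                self._tb_pair(i, p, k, split, G, Gp, inner, ops)
                i, k = p + 1, split

    def _tb_pair(self, i: int, p: int, k: int, m: int,
                 G: np.ndarray, Gp: np.ndarray, inner: np.ndarray,
                 ops: list) -> None:
        lo, S = self.tree.lo, self.S
        target = Gp[k, m]
        for r in range(0, min(self.max_ins, m - k) + 1):
            if self._close(target, self.ic[r] + G[k + r, m]):
                for w in range(k, k + r):
                    ops.append(("I", None, w))
                k = k + r
                break
        else:
            raise RuntimeError("traceback failed at pair pre-insert")
        g = G[k, m]
        dc, br = self.del_cost, self.tree.broken
        pm = self.tree.pairmat[(i, p)]
        if (m - k >= 2 and self._close(
                g, lo[i, S[k]] + lo[p, S[m - 1]] + pm[S[k], S[m - 1]]
                + inner[k + 1, m - 1])):
            ops.append(("M", i, k))
            self._tb_segment(i + 1, p, k + 1, m - 1, ops)
            ops.append(("M", p, m - 1))
        elif m - k >= 1 and self._close(g, dc + br + lo[p, S[m - 1]] + inner[k, m - 1]):
            ops.append(("D", i, None))
            self._tb_segment(i + 1, p, k, m - 1, ops)
            ops.append(("M", p, m - 1))
        elif m - k >= 1 and self._close(g, dc + br + lo[i, S[k]] + inner[k + 1, m]):
            ops.append(("M", i, k))
            self._tb_segment(i + 1, p, k + 1, m, ops)
            ops.append(("D", p, None))
        elif self._close(g, 2 * dc + br + inner[k, m]):
            ops.append(("D", i, None))
            self._tb_segment(i + 1, p, k, m, ops)
            ops.append(("D", p, None))
        else:
            raise RuntimeError("traceback failed inside pair node")


# ---------------------------------------------------------------------------
# public scoring API
# ---------------------------------------------------------------------------

def _pk_adjustment(tree: GuideTree, S: np.ndarray,
                   trace: Sequence[tuple[str, Optional[int], Optional[int]]],
                   ) -> float:
    """Additive pseudoknot-layer pair score on an optimal nested trace."""
    matched = {c: w for op, c, w in trace if op == "M"}
    adj = 0.0
    for i, j, bonus in tree.pk_pairs:
        wi, wj = matched.get(i), matched.get(j)
        if wi is None or wj is None:
            adj += tree.broken
        elif (int(S[wi]), int(S[wj])) in _CANON:
            adj += bonus
        else:
            adj += tree.broken
    return adj


def score_trace(profile: TRProfile,
                window_seq: str,
                trace: Sequence[tuple[str, Optional[int], Optional[int]]],
                config: ScanConfig) -> float:
    """Re-score a trace under the declared model (self-consistency check)."""
    S = encode(window_seq)
    lo = profile.log_odds()
    tree = GuideTree(profile, config)
    score = 0.0
    run = 0
    for op, c, w in trace:
        if op == "I":
            run += 1
        else:
            if run:
                score += config.gap_open + config.gap_extend * (run - 1)
                run = 0
            if op == "M":
                score += lo[c, S[w]]
            elif op == "D":
                score += config.gap_open
    if run:
        score += config.gap_open + config.gap_extend * (run - 1)
    matched = {c: w for op, c, w in trace if op == "M"}
    for (i, j), bonus in tree.pair_bonus.items():
        wi, wj = matched.get(i), matched.get(j)
        if wi is not None and wj is not None and (int(S[wi]), int(S[wj])) in _CANON:
            score += bonus
        else:
            score += tree.broken
    score += _pk_adjustment(tree, S, trace)
    return score


def score_window(profile: TRProfile, window_seq: str, config: ScanConfig,
                 ) -> Optional[tuple[float, list]]:
    """Best global profile-window alignment score (bits) and its trace.

    Returns None (no-score sentinel) for windows below the minimum
    alignable length.  The returned score includes the post-hoc
    pseudoknot-layer adjustment.
    """
    min_w = config.min_window
    if min_w is None:
        min_w = max(1, profile.length // 2)
    if len(window_seq) < min_w:
        return None
    tree = GuideTree(profile, config)
    S = encode(window_seq)
    dp = _DP(tree, S, config)
    dp.run()
    W = len(S)
    score = dp.tables[0][0, W] if profile.length else dp.empty[0, W]
    if not math.isfinite(score):
        return None
    trace = dp.traceback(0, W)
    score += _pk_adjustment(tree, S, trace)
    return float(score), trace


# ---------------------------------------------------------------------------
# genome scanning
# ---------------------------------------------------------------------------

def _ungapped_scores(tree: GuideTree, S: np.ndarray) -> np.ndarray:
    """Stage-1 screen: ungapped full-profile score at every offset."""
    L, N = tree.L, len(S)
    if N < L:
        return np.full(0, NEG)
    from numpy.lib.stride_tricks import sliding_window_view
    Wd = sliding_window_view(S, L)
    sc = tree.lo[np.arange(L)[None, :], Wd].sum(axis=1)
    for (i, j), pm in tree.pairmat.items():
        sc = sc + pm[Wd[:, i], Wd[:, j]]
    for i, j, bonus in tree.pk_pairs:
        pm = np.full((5, 5), tree.broken)
        for a, b in _CANON:
            pm[a, b] = bonus
        sc = sc + pm[Wd[:, i], Wd[:, j]]
    return sc


def _stage1_anchors(scores: np.ndarray, L: int, max_candidates: int,
                    stride: int) -> list[int]:
    if len(scores) == 0:
        return []
    order = np.argsort(scores[::stride], kind="stable")[::-1] * stride
    chosen: list[int] = []
    for o in order:
        o = int(o)
        if all(abs(o - c) >= L for c in chosen):
            chosen.append(o)
            if len(chosen) >= max_candidates:
                break
    return chosen


def _scan_strand(tree: GuideTree, seq: str, config: ScanConfig,
                 ) -> list[tuple[int, int, float, list, str]]:
    """Hits on one strand-oriented sequence: (start, end, score, trace, region)."""
    L = tree.L
    S = encode(seq)
    anchors = _stage1_anchors(_ungapped_scores(tree, S), L,
                              config.max_candidates, max(1, config.window_stride))
    pad = config.window_pad
    if pad is None:
        pad = config.max_insert_per_gap_region + 4
    band = config.dp_band
    if band is None:
        band = 2 * config.max_insert_per_gap_region + 6
    cfg = replace(config, dp_band=band)
    # a hit can never reach the reporting threshold if even the most
    # favourable pseudoknot adjustment leaves it short
    pk_max = sum(max(b, tree.broken) for _i, _j, b in tree.pk_pairs)
    out = []
    for o in anchors:
        w_lo = max(0, o - pad)
        w_hi = min(len(seq), o + L + pad)
        Sw = S[w_lo:w_hi]
        dp = _DP(tree, Sw, cfg)
        dp.run()
        T0 = dp.tables[0] if L else dp.empty
        if not np.isfinite(T0).any():
            continue
        k, l = np.unravel_index(int(np.argmax(T0)), T0.shape)
        score = float(T0[k, l])
        if not math.isfinite(score) or l <= k:
            continue
        if score + pk_max < config.score_threshold:
            continue
        trace = dp.traceback(int(k), int(l))
        # shift window positions so the trace is relative to the hit region
        trace = [(op, c, (w - int(k)) if w is not None else None)
                 for op, c, w in trace]
        region = seq[w_lo + int(k):w_lo + int(l)]
        score += _pk_adjustment(tree, encode(region), trace)
        out.append((w_lo + int(k), w_lo + int(l), score, trace, region))
    return out


def _resolve_overlaps(hits: list[Hit]) -> list[Hit]:
    """Keep the higher-scoring of overlapping same-strand hits (ties: leftmost)."""
    kept: list[Hit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.end)):
        if any(k.target_id == h.target_id and k.strand == h.strand
               and h.start < k.end and k.start < h.end for k in kept):
            continue
        kept.append(h)
    return kept


def scan(profile: TRProfile, targets: Sequence[tuple[str, str]],
         config: ScanConfig) -> list[Hit]:
    """Scan FASTA records on both strands; hits sorted by score descending.

    Reverse-strand hits are reported in forward coordinates; their trace and
    ``region_seq`` stay strand-oriented (the reverse complement).  With
    ``null_shuffles > 0`` an empirical E-value from dinucleotide-preserving
    shuffles of each record is attached.
    """
    tree = GuideTree(profile, config)
    hits: list[Hit] = []
    for rid, seq in targets:
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp_dna(seq)
            for start, end, score, trace, region in _scan_strand(tree, s, config):
                if score < config.score_threshold:
                    continue
                f_start, f_end = ((start, end) if strand == "+"
                                  else (n - end, n - start))
                hits.append(Hit(target_id=rid, start=f_start, end=f_end,
                                strand=strand, score=score, trace=trace,
                                region_seq=region))
    hits = _resolve_overlaps(hits)
    hits.sort(key=lambda h: (-h.score, h.target_id, h.start))
    if config.null_shuffles > 0 and hits:
        null_scores = calibrate_null(profile, targets, config)
        for h in hits:
            h.evalue_emp = empirical_evalue(h.score, null_scores)
    return hits


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Uniform dinucleotide-preserving shuffle (Altschul-Erickson)."""
    n = len(seq)
    if n < 3:
        return seq
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(succ.keys())
    for _ in range(10000):
        # choose a candidate last-edge for every vertex except the terminal
        last_edge: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = succ[v][rng.integers(len(succ[v]))]
        # the chosen last-edges must form a tree rooted at the terminal vertex
        for v in list(last_edge):
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("dinucleotide shuffle failed to converge")
    shuffled: dict[str, list[str]] = {}
    for v, edges in succ.items():
        edges = list(edges)
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = rng.permutation(len(edges))
        edges = [edges[i] for i in perm]
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled[v] = edges
    out = [first]
    ptr = {v: 0 for v in shuffled}
    cur = first
    for _ in range(n - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def calibrate_null(profile: TRProfile, targets: Sequence[tuple[str, str]],
                   config: ScanConfig) -> list[float]:
    """Best-hit score per dinucleotide-preserving shuffle of the targets."""
    if config.null_shuffles < 1:
        raise ValueError("null_shuffles must be >= 1 for calibration")
    rng = np.random.default_rng(config.seed)
    tree = GuideTree(profile, config)
    scores: list[float] = []
    quiet = replace(config, null_shuffles=0, score_threshold=-1e300)
    for _ in range(config.null_shuffles):
        best = -math.inf
        for _rid, seq in targets:
            shuf = dinucleotide_shuffle(seq, rng)
            for strand_seq in (shuf, revcomp_dna(shuf)):
                for _s, _e, score, _t, _r in _scan_strand(tree, strand_seq, quiet):
                    best = max(best, score)
        scores.append(best)
    return sorted(scores)


def empirical_evalue(score: float, null_scores: Sequence[float]) -> float:
    """Mean count of null best-hits with score >= s (monotone in s)."""
    if not null_scores:
        return math.nan
    return sum(1 for s in null_scores if s >= score) / len(null_scores)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def hits_to_table(hits: Sequence[Hit]) -> str:
    """Tab-delimited hit table (1-based inclusive coordinates)."""
    lines = ["\t".join(["target", "start", "end", "strand", "score_bits",
                        "evalue_emp"])]
    for h in hits:
        lines.append("\t".join([
            h.target_id, str(h.start + 1), str(h.end), h.strand,
            f"{h.score:.3f}",
            "NA" if h.evalue_emp is None else f"{h.evalue_emp:.4g}"]))
    return "\n".join(lines) + "\n"


def hits_to_bed(hits: Sequence[Hit]) -> str:
    """BED6 (0-based half-open, score scaled into 0-1000)."""
    lines = []
    for i, h in enumerate(hits):
        bed_score = int(max(0, min(1000, round(h.score * 10))))
        lines.append("\t".join([
            h.target_id, str(h.start), str(h.end), f"hit{i + 1}",
            str(bed_score), h.strand]))
    return "\n".join(lines) + ("\n" if lines else "")
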