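"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's DP/recursion code paths: alignment
scores are computed by exhaustive enumeration of monotone alignments,
parsimony scores by enumeration of all internal labelings, and template
search by trying every substring against every repeat rotation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

CANON = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}
ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def brute_force_best_alignment(col_freqs, gap_freq, background, pairs,
                               window, gap_open, gap_extend, max_ins,
                               pair_bonus, pair_broken):
    """Max score over all monotone global alignments, by enumeration.

    ``pairs`` are nested consensus pairs (i, j).  Cost model: match =
    log2(p/bg) (renormalised over non-gap mass), each deleted column costs
    ``gap_open``, each insertion run costs ``gap_open + gap_extend*(n-1)``
    and is capped at ``max_ins``; every pair adds ``pair_bonus`` when both
    partners match canonical residues, else ``pair_broken``.
    """
    L = len(col_freqs)
    W = len(window)
    S = [ENC.get(ch, 4) for ch in window.upper()]
    lo = np.zeros((L, 5))
    for c in range(L):
        nong = 1.0 - gap_freq[c]
        for x in range(4):
            p = col_freqs[c][x] / nong if nong > 0 else 0.25
            lo[c, x] = math.log2(max(p, 1e-12) / background[x])
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    best = [-math.inf]

    def rec(c, w, run, score, matched):
        if c == L and w == W:
            total = score
            for i, j in pairs:
                wi, wj = matched.get(i), matched.get(j)
                if wi is not None and wj is not None and (S[wi], S[wj]) in CANON:
                    total += pair_bonus
                else:
                    total += pair_broken
            best[0] = max(best[0], total)
            return
        if c < L and w < W:  # match
            matched[c] = w
            rec(c + 1, w + 1, 0, score + lo[c, S[w]], matched)
            del matched[c]
        if c < L:  # delete profile column
            rec(c + 1, w, 0, score + gap_open, matched)
        if w < W and run < max_ins:  # insert window residue
            cost = gap_open if run == 0 else gap_extend
            rec(c, w + 1, run + 1, score + cost, matched)

    rec(0, 0, 0, 0.0, {})
    return best[0]


def brute_force_parsimony(children, leaf_states, dollo):
    """Minimal state-change count by enumerating internal labelings.

    ``children``: dict internal-node -> list of child node ids; leaves are
    keys of ``leaf_states``.  Root is node 0.  Under ``dollo`` the character
    may be gained (0->1 along an edge) at most once in the whole tree and
    the root must be absent unless the gain is placed above the root.
    """
    internal = sorted(children)
    best = math.inf
    for labels in product([0, 1], repeat=len(internal)):
        state = dict(zip(internal, labels))
        state.update(leaf_states)
        changes = 0
        gains = 0
        for node, kids in children.items():
            for k in kids:
                if state[node] != state[k]:
                    changes += 1
                    if state[k] == 1:
                        gains += 1
        root_gain = state[0] == 1  # element present at root = gained above it
        if dollo:
            if gains + (1 if root_gain else 0) > 1:
                continue
            # the single origin is an event wherever it falls, including
            # on the lineage above the root
            if root_gain:
                changes += 1
        best = min(best, changes)
    return best


def brute_force_template(seq, repeat_unit, min_copies=1.5, max_copies=2.0):
    """Leftmost longest substring matching any rotation window of the
    reverse-complemented tandem repeat."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(repeat_unit.upper()))
    rc_rna = rc.replace("T", "U")
    u = len(repeat_unit)
    lo = math.ceil(min_copies * u - 1e-9)
    hi = math.floor(max_copies * u + 1e-9)
    periodic = rc_rna * (hi // u + 3)
    seq = seq.upper().replace("T", "U")
    for L in range(min(hi, len(seq)), lo - 1, -1):
        for i in range(len(seq) - L + 1):
            frag = seq[i:i + L]
            if any(periodic[k:k + L] == frag for k in range(u)):
                return (i, i + L)
    return None


def best_register_enumeration(template, primer, min_suffix=3):
    """All-register enumeration for the annealing oracle."""
    pair = {"A": "U", "C": "G", "G": "C", "T": "A"}
    template = template.upper().replace("T", "U")
    best = None
    for k in range(min_suffix, min(len(primer), len(template)) + 1):
        suffix = primer.upper()[-k:]
        for i in range(len(template) - k + 1):
            region = template[i:i + k]
            if all(pair[suffix[k - 1 - d]] == region[d] for d in range(k)):
                cand = (k, i)
                if best is None or k > best[0] or (k == best[0] and i > best[1]):
                    best = cand
    return best
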