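"""RNA secondary-structure prediction by base-pair maximization.

The folder is a Nussinov dynamic program over Watson–Crick plus G:U wobble
pairs with a minimum hairpin loop of 3 unpaired nucleotides.  It is fully
deterministic: ties in the recursion are broken by preferring to leave the
3'-most base unpaired, then by the smallest pairing partner index.  The score
is the number of paired bases-pairs in the optimal structure, which serves as
the structure component of hairpin candidate scoring and as the free-energy
proxy for the conserved-lncRNA structure screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import encode_rna

MIN_LOOP = 3

# pairing matrix over the A=0,C=1,G=2,U=3 encoding: WC + G:U wobble
_PAIRS = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRS[_a, _b] = True


def can_pair(a: str, b: str) -> bool:
    """Whether two bases form a Watson–Crick or G:U pair."""
    ea, eb = encode_rna(a)[0], encode_rna(b)[0]
    return bool(_PAIRS[ea, eb])


@njit(cache=False)
def _nussinov_table(enc, pairs, min_loop):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i, j - 1]
            for k in range(i, j - min_loop):
                if pairs[enc[k], enc[j]]:
                    left = N[i, k - 1] if k > i else 0
                    cand = left + N[k + 1, j - 1] + 1
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


def _traceback(enc: np.ndarray, N: np.ndarray) -> list[tuple[int, int]]:
    n = len(enc)
    pairs_out: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        if N[i, j] == N[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_LOOP):
            if _PAIRS[enc[k], enc[j]]:
                left = N[i, k - 1] if k > i else 0
                if left + N[k + 1, j - 1] + 1 == N[i, j]:
                    pairs_out.append((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return pairs_out


@dataclass(frozen=True)
class FoldResult:
    """A nested (pseudoknot-free) structure for one RNA sequence."""

    sequence: str
    structure: str  # dot-bracket, same length as sequence
    n_pairs: int

    def pair_table(self) -> dict[int, int]:
        """0-based partner map (both directions) from the dot-bracket."""
        stack: list[int] = []
        table: dict[int, int] = {}
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                table[i] = j
                table[j] = i
        return table


def nussinov(sequence: str) -> FoldResult:
    """Maximum base-pair nested structure of an RNA (or DNA) string.

    Deterministic; allows WC and G:U pairs, minimum loop 3 nt.
    """
    if len(sequence) == 0:
        return FoldResult("", "", 0)
    enc = encode_rna(sequence)
    n = len(enc)
    if n <= MIN_LOOP + 1:
        return FoldResult(sequence, "." * n, 0)
    N = _nussinov_table(enc, _PAIRS, MIN_LOOP)
    pairs = _traceback(enc, N)
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return FoldResult(sequence, "".join(db), int(N[0, n - 1]))


def fold_hairpin(sequence: str) -> FoldResult:
    """Fold a candidate precursor; refuses sequences too short to be one."""
    if len(sequence) < 40:
        raise ValueError(
            f"sequence of {len(sequence)} nt is too short for a miRNA precursor (<40 nt)"
        )
    return nussinov(sequence)


def paired_fraction(fold: FoldResult, start: int, end: int) -> float:
    """Fraction of bases in [start, end) (0-based) that are paired."""
    if end <= start:
        return 0.0
    region = fold.structure[start:end]
    return sum(1 for c in region if c != ".") / (end - start)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving dinucleotide composition.

    Altschul–Erikson style: build the multigraph of dinucleotide transitions,
    draw a random Eulerian arrangement by shuffling each vertex's out-edge
    list and keeping the last edge to form a spanning arborescence to the
    final vertex, then walk the edges.
    """
    if len(sequence) < 3:
        return sequence
    seq = list(sequence)
    first, last = seq[0], seq[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        edges.setdefault(a, []).append(b)
    # repeat until the sampled edge ordering admits an Eulerian walk
    for _ in range(200):
        trial = {v: list(out) for v, out in edges.items()}
        for v in trial:
            perm = rng.permutation(len(trial[v]))
            trial[v] = [trial[v][k] for k in perm]
        walk = [first]
        pos = {v: 0 for v in trial}
        v = first
        ok = True
        for _step in range(len(sequence) - 1):
            out = trial.get(v)
            if out is None or pos[v] >= len(out):
                ok = False
                break
            nxt = out[pos[v]]
            pos[v] += 1
            walk.append(nxt)
            v = nxt
        if ok and walk[-1] == last:
            return "".join(walk)
    return sequence  # degenerate composition; give up and return as-is
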