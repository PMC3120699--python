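"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming code paths they check:
alignment posteriors come from exhaustive enumeration of every legal state
path through the pair-HMM lattice, weighted and normalised directly.
"""

import numpy as np

from turbofold.energy_model import NT_INDEX


def enumerate_alignment_paths(a: str, b: str, params):
    """All complete pair-HMM paths with their probabilities.

    Returns a list of ``(path, weight)`` where path is a list of
    ``(state, i, k)`` tuples (states 0=ALN, 1=INS1, 2=INS2; i, k are the
    1-based indices of the residues emitted so far).
    """
    A = [NT_INDEX[c] for c in a]
    B = [NT_INDEX[c] for c in b]
    n, m = len(A), len(B)
    T, M, e, pi = (
        params.transition,
        params.match_emission,
        params.insert_emission,
        params.start,
    )
    out = []

    def rec(i, k, prev, w, path):
        if i == n and k == m:
            out.append((list(path), w))
            return
        for s in (0, 1, 2):
            t = pi[s] if prev is None else T[prev, s]
            if s == 0 and i < n and k < m:
                path.append((s, i + 1, k + 1))
                rec(i + 1, k + 1, s, w * t * M[A[i], B[k]], path)
                path.pop()
            elif s == 1 and i < n:
                path.append((s, i + 1, k))
                rec(i + 1, k, s, w * t * e[A[i]], path)
                path.pop()
            elif s == 2 and k < m:
                path.append((s, i, k + 1))
                rec(i, k + 1, s, w * t * e[B[k]], path)
                path.pop()

    rec(0, 0, None, 1.0, [])
    return out


def alignment_posteriors_by_enumeration(a: str, b: str, params):
    """(posterior[s, i, k], total probability) by full path enumeration."""
    paths = enumerate_alignment_paths(a, b, params)
    z = sum(w for _, w in paths)
    post = np.zeros((3, len(a) + 1, len(b) + 1))
    for path, w in paths:
        for s, i, k in path:
            post[s, i, k] += w
    return post / z, z


def best_path_weight(a: str, b: str, params) -> float:
    """Maximum single-path probability, by enumeration."""
    return max(w for _, w in enumerate_alignment_paths(a, b, params))
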