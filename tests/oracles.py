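"""Independent oracles shared by the test modules (no package internals)."""

import numpy as np

from molhetero.latent import AlignmentParams


def exhaustive_alignment_score(s1, s2, params=AlignmentParams()):
    """Enumerate every global alignment recursively and return the best score.

    A gap run of length k costs gap_open + (k-1) * gap_extend; end gaps are
    scored like internal ones. No dynamic programming — this is the slow,
    obviously-correct enumeration, usable only for short strings.
    """

    def rec(i, j, prev):
        # prev in {None, "gap1", "gap2"}: which sequence the previous
        # alignment column gapped, for open-vs-extend accounting
        if i == len(s1) and j == len(s2):
            return 0.0
        best = -np.inf
        if i < len(s1) and j < len(s2):
            sub = params.match if s1[i] == s2[j] else params.mismatch
            best = max(best, sub + rec(i + 1, j + 1, None))
        if i < len(s1):  # gap in s2
            cost = params.gap_extend if prev == "gap2" else params.gap_open
            best = max(best, cost + rec(i + 1, j, "gap2"))
        if j < len(s2):  # gap in s1
            cost = params.gap_extend if prev == "gap1" else params.gap_open
            best = max(best, cost + rec(i, j + 1, "gap1"))
        return best

    return rec(0, 0, None)
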