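"""Independent brute-force oracles used by the test suite.

These re-derive the quantities under test by naive enumeration, staying
deliberately independent of the library's implementation paths.
"""

import itertools

import numpy as np
import pandas as pd

from crc_deconv import cnv


def brute_force_max_arc(x, min_width=3):
    """Naive all-pairs search for the maximal circular arc statistic."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sigma = x.std()
    xc = x - x.mean()
    c = np.concatenate(([0.0], np.cumsum(xc)))
    best, arc = -np.inf, None
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            z = abs(c[j] - c[i]) / (sigma * np.sqrt(k * (n - k) / n))
            if z > best:
                best, arc = z, (i, j)
    return best, arc


def brute_force_clonality(breakpoint_sets, tol, min_shared=2):
    """All-pairs linkage with optimal matching + transitive closure (networkx)."""
    import networkx as nx
    from scipy.optimize import linear_sum_assignment

    def optimal_shared(a, b):
        if not a or not b:
            return 0
        ok = np.array([[abs(x - y) <= tol for y in b] for x in a])
        cost = np.where(ok, 0.0, 1.0)
        ri, ci = linear_sum_assignment(cost)
        return int(ok[ri, ci].sum())

    g = nx.Graph()
    g.add_nodes_from(breakpoint_sets)
    for a, b in itertools.combinations(breakpoint_sets, 2):
        aa, bb = breakpoint_sets[a], breakpoint_sets[b]
        if not aa or not bb:
            continue
        required = max(1, min(min_shared, len(aa), len(bb)))
        if optimal_shared(aa, bb) >= required:
            g.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]


def interior_cuts(arc, n):
    """Interior split points induced by an arc (an arc and its complement
    describe the same partition of the segment)."""
    return {c for c in arc if 0 < c < n}


def make_segset(cell_id, boundaries, states, n_bins, chrom="chr1"):
    """Hand-built SegmentSet with called states for clonality tests."""
    rows = []
    for (a, b), st in zip(zip(boundaries[:-1], boundaries[1:]), states):
        mean = {"gain": 1.5, "loss": 0.5, "neutral": 1.0}[st]
        rows.append((chrom, a, b, mean, np.log2(mean), st))
    seg = pd.DataFrame(
        rows, columns=["chrom", "start_bin", "end_bin", "mean_ratio", "mean_log2", "state"]
    )
    return cnv.SegmentSet(cell_id=cell_id, segments=seg, n_bins=n_bins)
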