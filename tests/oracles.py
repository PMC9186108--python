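"""Independent oracles used by the property and acceptance suites.

Each oracle is a deliberately naive re-derivation (explicit loops,
brute-force closure) kept independent of the library code paths it
checks.
"""

import numpy as np
import pandas as pd

from rnalof.splicing import JUNCTION_COLUMNS


def naive_psi(tpm):
    """Explicit-loop re-derivation of the PAS usage metric."""
    n = len(tpm)
    total = sum(tpm)
    return sum(t * (m - 1) / (n - 1) for m, t in enumerate(tpm, start=1)) / total


def bh_stepup_oracle(p):
    """Brute-force BH: sort, step-up from the largest rank, undo the sort."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def clustering_oracle(junctions: pd.DataFrame, minclureads: int):
    """Brute-force transitive closure: O(n^2) adjacency + BFS."""
    pooled = junctions.groupby(["chrom", "strand", "start", "end"], as_index=False)["count"].sum()
    keys = list(pooled.itertuples(index=False))
    n = len(keys)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            same = keys[i].chrom == keys[j].chrom and keys[i].strand == keys[j].strand
            if same and (keys[i].start == keys[j].start or keys[i].end == keys[j].end):
                adj[i][j] = True
    seen, components = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        total = sum(keys[k].count for k in comp)
        if total >= minclureads:
            components.append(frozenset((keys[k].chrom, keys[k].strand, keys[k].start, keys[k].end) for k in comp))
    return set(components)


def random_junctions(rng, n):
    """Random junction configurations with heavy splice-site sharing."""
    starts = rng.integers(0, 8, size=n) * 100
    ends = starts + rng.integers(1, 8, size=n) * 50
    return pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=n),
            "start": starts,
            "end": ends,
            "strand": rng.choice(["+", "-", "."], size=n),
            "sample_id": rng.choice(["s1", "s2"], size=n),
            "count": rng.integers(0, 15, size=n),
            "min_anchor": np.full(n, 8),
        },
        columns=JUNCTION_COLUMNS,
    )
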