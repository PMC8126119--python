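"""Independent brute-force oracles used to pin expected values in tests.

Each oracle restates a definition in the most literal way possible and is
kept free of any code path it checks.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_uorfs(seq: str, min_codons: int) -> list[tuple[int, int]]:
    """All (start, end) pairs with ATG at start and the first in-frame stop
    ending at end, enumerated by trying every (i, i+3k) pair."""
    seq = seq.upper()
    out = []
    for i in range(len(seq)):
        if seq[i : i + 3] != "ATG":
            continue
        for k in range(1, (len(seq) - i) // 3 + 1):
            codon = seq[i + 3 * (k - 1) : i + 3 * k]
            if codon in STOPS:
                if k >= min_codons:
                    out.append((i, i + 3 * k))
                break
    return out


def per_base_assignment(
    blocks: list[tuple[int, int]],
    features: dict[str, list[tuple[int, int]]],
    mode: str,
) -> str:
    """Literal per-base set algebra over gene sets covering each base."""
    base_sets = []
    for b0, b1 in blocks:
        for pos in range(b0, b1):
            covering = {
                g
                for g, ivs in features.items()
                if any(s <= pos < e for s, e in ivs)
            }
            base_sets.append(covering)
    if mode == "union":
        genes = set().union(*base_sets) if base_sets else set()
    else:
        genes = base_sets[0].copy() if base_sets else set()
        for s in base_sets[1:]:
            genes &= s
    if not genes:
        return "no_feature"
    if len(genes) > 1:
        return "ambiguous"
    return next(iter(genes))


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Step-up BH: adj_i = min over j>=i (ranked) of m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        adj[idx] = running_min
    return adj


def spearman_rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of average ranks."""
    import scipy.stats as st

    rx = st.rankdata(x)
    ry = st.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
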