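"""Brute-force reference implementation of the frame-linking rules.

Deliberately written as plain nested loops over explicit label pairs,
independent of the production code paths, so it can serve as an oracle.
"""

from __future__ import annotations

import numpy as np


def brute_force_links(
    a: np.ndarray,
    b: np.ndarray,
    f_min: float = 0.1,
    f_merge: float = 0.3,
    merge_volume_min: float = 0.7,
) -> set[tuple[int, int]]:
    parents = sorted(int(l) for l in np.unique(a) if l > 0)
    children = sorted(int(l) for l in np.unique(b) if l > 0)
    pvol = {p: int((a == p).sum()) for p in parents}
    cvol = {c: int((b == c).sum()) for c in children}
    overlap = {}
    for p in parents:
        for c in children:
            o = int(((a == p) & (b == c)).sum())
            if o > 0:
                overlap[(p, c)] = o

    chosen: set[tuple[int, int]] = set()
    for c in children:
        cands = [(p, overlap[(p, c)]) for p in parents if (p, c) in overlap]
        if not cands:
            continue
        cands.sort(key=lambda po: (-po[1], po[0]))
        p1, o1 = cands[0]
        if o1 < f_min * cvol[c]:
            continue
        chosen.add((p1, c))
        if len(cands) > 1:
            p2, o2 = cands[1]
            if (
                o2 >= f_merge * pvol[p2]
                and o1 >= f_merge * pvol[p1]
                and cvol[c] >= merge_volume_min * (pvol[p1] + pvol[p2])
            ):
                chosen.add((p2, c))

    for p in parents:
        kids = sorted(
            [(c, overlap[(p, c)]) for (q, c) in chosen if q == p],
            key=lambda co: (-co[1], co[0]),
        )
        for c, _ in kids[2:]:
            chosen.discard((p, c))
    return chosen
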