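"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written as naive linear scans and full
enumerations, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations


def scan_runs(states) -> list[tuple[int, int, int]]:
    """Linear scan into maximal runs: list of (start, end, value), 1-based closed."""
    states = list(int(s) for s in states)
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((start + 1, i, states[start]))
            start = i
    return runs


def scan_has_long(states, min_len: int) -> bool:
    """Count consecutive disordered residues one by one."""
    count = 0
    for s in states:
        count = count + 1 if int(s) == 1 else 0
        if count >= min_len:
            return True
    return False


def scan_completely_disordered(states, long_len: int = 30, short_run: int = 5) -> bool:
    """Literal three-step rule: reclassify short disorder, then re-scan."""
    filtered = list(int(s) for s in states)
    for start, end, value in scan_runs(states):
        if value == 1 and (end - start + 1) < short_run:
            for i in range(start - 1, end):
                filtered[i] = 0
    if scan_has_long([1 - s for s in filtered], long_len):  # ordered run >= long_len
        return False
    return scan_has_long(filtered, long_len)


def mwu_statistic(x, y) -> float:
    """U statistic for x: pairs where x beats y (ties count half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def exact_mwu_pvalue(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group assignments.

    Assumes no ties between or within groups.  The p-value is the
    probability, over all C(n+m, n) equally likely assignments of the
    pooled values to the two groups, of a U statistic at least as extreme
    (in either tail) as observed.
    """
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires distinct values"
    n = len(x)
    nm = len(x) * len(y)
    u_obs = mwu_statistic(x, y)
    lo, hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    count = 0
    total = 0
    for chosen in combinations(range(len(pooled)), n):
        cx = [pooled[i] for i in chosen]
        cy = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = mwu_statistic(cx, cy)
        if u <= lo or u >= hi:
            count += 1
        total += 1
    return min(1.0, count / total)


def recount_related(pairs, track_ids_a, track_ids_b, long_ids_a, long_ids_b):
    """Naive recount of the relatedness table from a pair list.

    ``pairs`` is an iterable of (protein_a_or_b, protein_b_or_a) tuples;
    membership is resolved against the id collections.  Returns
    (n_related_a, n_related_disordered_a, n_related_b, n_related_disordered_b).
    """
    related_a, related_b = set(), set()
    for p, q in pairs:
        for protein in (p, q):
            if protein in track_ids_a:
                related_a.add(protein)
            elif protein in track_ids_b:
                related_b.add(protein)
    return (
        len(related_a),
        len([p for p in related_a if p in long_ids_a]),
        len(related_b),
        len([p for p in related_b if p in long_ids_b]),
    )
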