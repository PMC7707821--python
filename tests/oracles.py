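"""Independent reference implementations used to cross-check the pipeline.

These deliberately avoid the libraries and code paths of the package: the
Levenshtein oracle is a plain dynamic-programming table, the consensus
oracle a per-position Counter tally, the grouping oracle a sort-based scan.
"""

from __future__ import annotations

from collections import Counter


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(nm) edit-distance table."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def tally_consensus(seq_counts: dict[str, int]) -> str:
    """Per-position weighted tally; ties give N; modal-length sequences only."""
    lengths = Counter()
    for s, c in seq_counts.items():
        lengths[len(s)] += c
    modal_len = min(lengths, key=lambda n: (-lengths[n], n))
    out = []
    for i in range(modal_len):
        tally: Counter = Counter()
        for s, c in seq_counts.items():
            if len(s) == modal_len:
                tally[s[i]] += c
        best = max(tally.values())
        winners = [b for b, c in tally.items() if c == best]
        out.append(winners[0] if len(winners) == 1 else "N")
    return "".join(out)


def sorted_grouping(reads: list[str], barcode_len: int) -> dict[str, dict[str, int]]:
    """Group reads by barcode via sorting, no hashing of the pipeline's kind."""
    pairs = sorted((r[:barcode_len], r[barcode_len:]) for r in reads
                   if len(r) > barcode_len)
    groups: dict[str, dict[str, int]] = {}
    for bc, insert in pairs:
        groups.setdefault(bc, {})
        groups[bc][insert] = groups[bc].get(insert, 0) + 1
    return groups


def collision_verdict(seq_counts: dict[str, int], d_min: int = 4) -> bool:
    """Re-evaluate the collision rule with the DP distance."""
    modal = min(seq_counts, key=lambda s: (-seq_counts[s], s))
    return any(c > 1 and s != modal and dp_levenshtein(s, modal) >= d_min
               for s, c in seq_counts.items())


def entropy_bits(p) -> float:
    import math

    return -sum(x * math.log2(x) for x in p if x > 0)


def jsd_bits(p, q) -> float:
    m = [(a + b) / 2 for a, b in zip(p, q)]
    return entropy_bits(m) - 0.5 * (entropy_bits(p) + entropy_bits(q))
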