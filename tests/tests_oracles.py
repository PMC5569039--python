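"""Shared brute-force oracles, independent of the library implementations."""

CANONICAL = "WRKYGQK"


def oracle_heptapeptides(seq, max_mm):
    """Exhaustive window check: anchors exact, Hamming distance elsewhere."""
    hits = []
    for i in range(len(seq) - 6):
        w = seq[i : i + 7]
        if w[0] == "W" and w[2] == "K" and w[3] == "Y":
            mm = sum(a != b for a, b in zip(w, CANONICAL))
            if mm <= max_mm:
                hits.append((i, w, mm))
    return hits


def oracle_zinc_finger(seq, from_index, r1, r2):
    """Enumerate all (start, a, b) triples; first in (s, a, b) order wins."""
    candidates = []
    for s in range(from_index, len(seq)):
        for a in range(r1[0], r1[1] + 1):
            for b in range(r2[0], r2[1] + 1):
                t = s + a + b + 4
                if t >= len(seq):
                    continue
                if (
                    seq[s] == "C"
                    and seq[s + 1 + a] == "C"
                    and seq[s + a + b + 2] == "H"
                    and seq[t] in "HCY"
                ):
                    candidates.append((s, a, b, seq[t]))
    return min(candidates) if candidates else None


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_oracle(seq, pattern):
    """Naive per-window IUPAC check, forward orientation only."""
    m = len(pattern)
    return [
        i
        for i in range(len(seq) - m + 1)
        if all(seq[i + k] in IUPAC[p] for k, p in enumerate(pattern))
    ]
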