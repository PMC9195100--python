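"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: the Fisher oracle
enumerates every 2x2 table with the observed margins and sums exact rational
probabilities from reciprocal factorial products; the binomial oracle sums
the tail term by term; the context oracle walks the sequence string; the
territory oracle enumerates every (gene, label) candidate with explicit
per-strand arithmetic.
"""

import math
from fractions import Fraction

_FACT = [math.factorial(i) for i in range(200)]


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by full enumeration over fixed margins."""
    n1, n2 = a + b, c + d
    K = a + c
    N = n1 + n2
    if min(n1, n2, K, N - K) == 0:
        return 1.0
    kmin, kmax = max(0, K - n2), min(K, n1)
    # P(table with k) proportional to 1 / (k! (n1-k)! (K-k)! (n2-K+k)!)
    weights = [
        Fraction(1, _FACT[k] * _FACT[n1 - k] * _FACT[K - k] * _FACT[n2 - K + k])
        for k in range(kmin, kmax + 1)
    ]
    w_obs = weights[a - kmin]
    total = sum(weights)
    num = sum(w for w in weights if w <= w_obs)
    return float(num / total)


def binom_upper_tail_oracle(m, n, r):
    """P(X >= m | n, r) by exhaustive summation."""
    return math.fsum(
        math.comb(n, k) * r**k * (1.0 - r) ** (n - k) for k in range(m, n + 1)
    )


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def context_oracle(seq, pos, strand):
    """CG/CHG/CHH classification by direct string inspection; None if the
    triplet runs off the end, ValueError if not a cytosine."""
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError("not a cytosine")
        trip = seq[pos : pos + 3]
    else:
        if seq[pos] != "G":
            raise ValueError("not a cytosine")
        trip = "".join(_COMP[x] for x in reversed(seq[max(0, pos - 2) : pos + 1]))
        if pos - 2 < 0:
            trip = trip  # shorter than 3; handled below
    if len(trip) < 2:
        return None
    if trip[1] == "G":
        return "CG"
    if len(trip) < 3:
        return None
    if trip[2] == "G":
        return "CHG"
    if "N" in trip[1:3]:
        return None
    return "CHH"


def scan_contexts_oracle(genome):
    """Set of (chrom, pos, strand, context) for every classifiable cytosine."""
    out = set()
    for chrom, seq in genome.items():
        for i, base in enumerate(seq):
            if base == "C":
                ctx = context_oracle(seq, i, "+")
                if ctx:
                    out.add((chrom, i, "+", ctx))
            elif base == "G":
                ctx = context_oracle(seq, i, "-")
                if ctx:
                    out.add((chrom, i, "-", ctx))
    return out


_ORACLE_PRECEDENCE = [
    "utr5",
    "utr3",
    "exon_first",
    "exon_other",
    "intron_first",
    "intron_other",
    "promoter_0_1kb",
    "promoter_1_2kb",
    "promoter_2_3kb",
    "downstream",
]


def territory_oracle(pos, genes):
    """(gene_id, label) for a point by exhaustive candidate enumeration.

    Works in 'transcript coordinates': d = signed distance from the TSS in
    the direction of transcription (negative = upstream).
    """
    candidates = []
    for g in genes:
        sign = 1 if g.strand == "+" else -1
        d = (pos - g.tss) * sign
        labels = []
        if -1000 <= d < 0:
            labels.append("promoter_0_1kb")
        if -2000 <= d < -1000:
            labels.append("promoter_1_2kb")
        if -3000 <= d < -2000:
            labels.append("promoter_2_3kb")
        # downstream: within 1 kb past the transcription end
        if g.strand == "+" and g.end <= pos < g.end + 1000:
            labels.append("downstream")
        if g.strand == "-" and g.start - 1000 <= pos < g.start:
            labels.append("downstream")
        exons = g.exons  # transcription order
        for i, (s, e) in enumerate(exons):
            if s <= pos < e:
                labels.append("exon_first" if i == 0 else "exon_other")
        for i, (s, e) in enumerate(g.introns):
            if s <= pos < e:
                labels.append("intron_first" if i == 0 else "intron_other")
        for s, e in g.utr5:
            if s <= pos < e:
                labels.append("utr5")
        for s, e in g.utr3:
            if s <= pos < e:
                labels.append("utr3")
        for lbl in labels:
            candidates.append((_ORACLE_PRECEDENCE.index(lbl), abs(d), g.gene_id, lbl))
    if not candidates:
        return None, "distal_intergenic"
    rank, _, gid, lbl = min(candidates)
    return gid, lbl
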