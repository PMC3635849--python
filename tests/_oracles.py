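"""Independent brute-force reference implementations.

Each function here recomputes a statistic directly from its definition
with plain Python loops, sharing no code with the package, so that the
optimized implementations can be checked against them on small inputs.
"""

import math

from Bio.Seq import Seq

VALID = set("ACGT")


def identity_pairs(seqs):
    """Percent identity per pair, pairwise deletion, plain loops."""
    out = []
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            match = comp = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in VALID and b in VALID:
                    comp += 1
                    match += a == b
            out.append(100.0 * match / comp)
    return out


def p_distance(s1, s2):
    match = comp = 0
    for a, b in zip(s1, s2):
        if a in VALID and b in VALID:
            comp += 1
            match += a == b
    return 1.0 - match / comp


def jc69(s1, s2):
    p = p_distance(s1, s2)
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def site_counts(seqs):
    """(S, eta) by direct column enumeration."""
    S = eta = 0
    for col in zip(*seqs):
        states = {c for c in col if c in VALID}
        if len(states) >= 2:
            S += 1
            eta += len(states) - 1
    return S, eta


def mean_pairwise_diffs(seqs):
    n = len(seqs)
    total = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(
                1
                for a, b in zip(seqs[i], seqs[j])
                if a in VALID and b in VALID and a != b
            )
            pairs += 1
    return total / pairs


def tajimas_d(seqs, basis="eta"):
    """Tajima (1989) D, term by term, with the basis count substituted."""
    n = len(seqs)
    S, eta = site_counts(seqs)
    k = eta if basis == "eta" else S
    if k == 0:
        raise ZeroDivisionError("monomorphic")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = mean_pairwise_diffs(seqs)
    return (pi - k / a1) / math.sqrt(e1 * k + e2 * k * (k - 1))


def watterson_theta(seqs, basis="eta"):
    n = len(seqs)
    S, eta = site_counts(seqs)
    k = eta if basis == "eta" else S
    a1 = sum(1.0 / i for i in range(1, n))
    return k / (a1 * len(seqs[0]))


# ---------------------------------------------------------------------------
# Li / Pamilo-Bianchi-Li Ka, Ks

def _degeneracy(codon, pos):
    """0/2/4-fold class of a codon position by literal translation."""
    aa = str(Seq(codon).translate(table=11))
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if str(Seq(alt).translate(table=11)) == aa:
            syn += 1
    return 4 if syn == 3 else (0 if syn == 0 else 2)


def _is_stop(codon):
    return str(Seq(codon).translate(table=11)) == "*"


def pbl_kaks(s1, s2):
    """PBL (Ka, Ks): half-site convention, K2P per degeneracy class."""
    assert len(s1) == len(s2) and len(s1) % 3 == 0
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    ts = {0: 0.0, 2: 0.0, 4: 0.0}
    tv = {0: 0.0, 2: 0.0, 4: 0.0}
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for ci in range(len(s1) // 3):
        c1 = s1[3 * ci : 3 * ci + 3]
        c2 = s2[3 * ci : 3 * ci + 3]
        if set(c1) - VALID or set(c2) - VALID or _is_stop(c1) or _is_stop(c2):
            continue
        for pos in range(3):
            d1 = _degeneracy(c1, pos)
            d2 = _degeneracy(c2, pos)
            L[d1] += 0.5
            L[d2] += 0.5
            if c1[pos] != c2[pos]:
                kind = ts if (c1[pos], c2[pos]) in transitions else tv
                kind[d1] += 0.5
                kind[d2] += 0.5

    def AB(cls):
        if L[cls] == 0:
            return 0.0, 0.0
        P, Q = ts[cls] / L[cls], tv[cls] / L[cls]
        A = -0.5 * math.log(1 - 2 * P - Q) + 0.25 * math.log(1 - 2 * Q)
        B = -0.5 * math.log(1 - 2 * Q)
        return A, B

    A0, B0 = AB(0)
    A2, B2 = AB(2)
    A4, B4 = AB(4)
    Ks = (L[2] * A2 + L[4] * A4) / (L[2] + L[4]) + B4
    Ka = A0 + (L[0] * B0 + L[2] * B2) / (L[0] + L[2])
    return Ka, Ks


# ---------------------------------------------------------------------------
# Hudson F_ST

def hudson_fst(seqs_a, seqs_b):
    """(pi_b - pi_w) / pi_b with per-site pairwise differences, loops only."""

    def per_site(s1, s2):
        comp = diff = 0
        for a, b in zip(s1, s2):
            if a in VALID and b in VALID:
                comp += 1
                diff += a != b
        return diff / comp

    def mean_within(seqs):
        vals = [
            per_site(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ]
        return sum(vals) / len(vals)

    between = [per_site(a, b) for a in seqs_a for b in seqs_b]
    pi_b = sum(between) / len(between)
    pi_w = 0.5 * (mean_within(seqs_a) + mean_within(seqs_b))
    return (pi_b - pi_w) / pi_b


def haversine_km(lat1, lon1, lat2, lon2, radius=6371.0088):
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))
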