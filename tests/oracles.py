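"""Naive, loop-based reference implementations of the descriptor formulas.

Deliberately independent of the package's vectorized code paths: everything
here is written directly from the published definitions using plain Python
loops.  Only the raw physicochemical constant tables are shared with the
package (they are published data, not algorithm).
"""

import math

from bactipred.descriptors import (
    CTD_PROPERTIES,
    COIL_PROPENSITY,
    HELIX_PROPENSITY,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    SHEET_PROPENSITY,
    SIDE_CHAIN_MASS,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _std_scale(raw):
    vals = [raw[a] for a in AA]
    mean = sum(vals) / 20.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20.0)
    return {a: (raw[a] - mean) / sd for a in AA}


def naive_aac(seq):
    return [sum(1 for c in seq if c == a) / len(seq) for a in AA]


def naive_dpc(seq):
    out = []
    for a in AA:
        for b in AA:
            n = sum(1 for i in range(len(seq) - 1) if seq[i] == a and seq[i + 1] == b)
            out.append(n / (len(seq) - 1))
    return out


def naive_pseaac(seq, lam=10, w=0.05):
    h1, h2, m = _std_scale(HYDROPHOBICITY), _std_scale(HYDROPHILICITY), _std_scale(SIDE_CHAIN_MASS)
    L = len(seq)
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            a, b = seq[i], seq[i + j]
            total += ((h1[a] - h1[b]) ** 2 + (h2[a] - h2[b]) ** 2 + (m[a] - m[b]) ** 2) / 3.0
        thetas.append(total / (L - j))
    f = naive_aac(seq)
    denom = sum(f) + w * sum(thetas)
    return [x / denom for x in f] + [w * t / denom for t in thetas]


def naive_apaac(seq, lam=10, w=0.05):
    h1, h2 = _std_scale(HYDROPHOBICITY), _std_scale(HYDROPHILICITY)
    L = len(seq)
    taus = []
    for j in range(1, lam + 1):
        t1 = sum(h1[seq[i]] * h1[seq[i + j]] for i in range(L - j)) / (L - j)
        t2 = sum(h2[seq[i]] * h2[seq[i + j]] for i in range(L - j)) / (L - j)
        taus.extend([t1, t2])
    f = naive_aac(seq)
    denom = sum(f) + w * sum(taus)
    return [x / denom for x in f] + [w * t / denom for t in taus]


def _group_of(residue, prop):
    for g, members in enumerate(CTD_PROPERTIES[prop], start=1):
        if residue in members:
            return g
    raise KeyError(residue)


def naive_ctd_composition(seq, prop):
    groups = [_group_of(c, prop) for c in seq]
    return [groups.count(g) / len(seq) for g in (1, 2, 3)]


def naive_ctd_transition(seq, prop):
    groups = [_group_of(c, prop) for c in seq]
    out = []
    for g, h in ((1, 2), (1, 3), (2, 3)):
        n = sum(
            1
            for i in range(len(seq) - 1)
            if {groups[i], groups[i + 1]} == {g, h}
        )
        out.append(n / (len(seq) - 1))
    return out


def naive_ctd_distribution(seq, prop):
    groups = [_group_of(c, prop) for c in seq]
    L = len(seq)
    out = []
    for g in (1, 2, 3):
        positions = [i + 1 for i, x in enumerate(groups) if x == g]
        n = len(positions)
        if n == 0:
            out.extend([0.0] * 5)
            continue
        ks = [1] + [max(1, math.floor(q * n)) for q in (0.25, 0.5, 0.75, 1.0)]
        out.extend(100.0 * positions[k - 1] / L for k in ks)
    return out


def naive_secondary_structure(seq, window=5):
    raw = []
    for a in seq:
        scores = [("C", COIL_PROPENSITY[a]), ("H", HELIX_PROPENSITY[a]), ("E", SHEET_PROPENSITY[a])]
        raw.append(max(scores, key=lambda sv: sv[1])[0])
    half = window // 2
    out = []
    for i in range(len(raw)):
        win = raw[max(0, i - half) : i + half + 1]
        counts = [("C", win.count("C")), ("H", win.count("H")), ("E", win.count("E"))]
        out.append(max(counts, key=lambda sv: sv[1])[0])
    return "".join(out)


def naive_ss_features(states):
    L = len(states)
    out = []
    for s in "HEC":
        out.append(states.count(s) / L)
        longest = run = 0
        for c in states:
            run = run + 1 if c == s else 0
            longest = max(longest, run)
        out.append(longest / L)
    return out


def naive_metrics(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(prod) if prod else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, mcc, rec, prec, f1


def naive_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def naive_percent_identity_best(seq_a, seq_b_list, align_fn):
    """Brute-force all-pairs helper used by the redundancy oracle."""
    return max(align_fn(seq_a, b) for b in seq_b_list)
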