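"""Independent brute-force oracles for descriptor and metric tests.

Every function here is a deliberately naive re-derivation (explicit Python
loops, no shared code paths with the package implementation beyond the raw
per-residue data tables, which are the definition of each descriptor's
inputs rather than part of its algorithm).
"""

from collections import Counter

import math

from plantloc.scales import (
    CHOU_TRIPLET,
    CTD_GROUPS,
    DISTANCE_MATRICES,
    GEARY_PROPERTIES,
    residue_charge,
)
from plantloc.seqio import AA_ALPHABET


def aac_oracle(seq):
    c = Counter(seq)
    return [c.get(aa, 0) / len(seq) for aa in AA_ALPHABET]


def _props(seq):
    """Per-position values of the standardized property triplet."""
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    return [[CHOU_TRIPLET[j][idx[aa]] for aa in seq] for j in range(3)]


def pseaac_type1_oracle(seq, lam, w):
    p = _props(seq)
    L = len(seq)
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            total += sum((p[j][i + k] - p[j][i]) ** 2 for j in range(3)) / 3.0
        thetas.append(total / (L - k))
    f = aac_oracle(seq)
    denom = 1.0 + w * sum(thetas)
    return [x / denom for x in f] + [w * t / denom for t in thetas]


def pseaac_type2_oracle(seq, lam, w):
    p = _props(seq)
    L = len(seq)
    taus = []
    for k in range(1, lam + 1):
        for j in range(3):
            total = sum((p[j][i + k] - p[j][i]) ** 2 for i in range(L - k))
            taus.append(total / (L - k))
    f = aac_oracle(seq)
    denom = 1.0 + w * sum(taus)
    return [x / denom for x in f] + [w * t / denom for t in taus]


def apaac_oracle(seq, lam, w):
    p = _props(seq)
    L = len(seq)
    taus = []
    for k in range(1, lam + 1):
        for j in (0, 1):
            total = sum(p[j][i] * p[j][i + k] for i in range(L - k))
            taus.append(total / (L - k))
    f = aac_oracle(seq)
    denom = 1.0 + w * sum(taus)
    return [x / denom for x in f] + [w * t / denom for t in taus]


def ctd_oracle(seq):
    L = len(seq)
    C, T, D = [], [], []
    for prop, groups in CTD_GROUPS.items():
        codes = []
        for aa in seq:
            for g, members in enumerate(groups):
                if aa in members:
                    codes.append(g)
        for g in range(3):
            C.append(codes.count(g) / L)
        pairs = [(codes[i], codes[i + 1]) for i in range(L - 1)]
        hetero = [p for p in pairs if p[0] != p[1]]
        for g1, g2 in ((0, 1), (0, 2), (1, 2)):
            n = sum(1 for p in hetero if set(p) == {g1, g2})
            T.append(n / len(hetero) if hetero else 0.0)
        for g in range(3):
            pos = [i + 1 for i, c in enumerate(codes) if c == g]
            if not pos:
                D.extend([0.0] * 5)
                continue
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                k = max(1, math.ceil(q * len(pos)))
                D.append(100.0 * pos[k - 1] / L)
    return C, T, D


def geary_oracle(seq, nlag=10):
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    out = []
    L = len(seq)
    for table in GEARY_PROPERTIES.values():
        vals = [table[aa] for aa in AA_ALPHABET]
        mean20 = sum(vals) / 20.0
        sd20 = math.sqrt(sum((v - mean20) ** 2 for v in vals) / 20.0)
        x = [(table[aa] - mean20) / sd20 for aa in seq]
        xbar = sum(x) / L
        denom = sum((xi - xbar) ** 2 for xi in x)
        if denom < 1e-12 * L:  # degenerate-case convention shared with the spec
            denom = 0
        for k in range(1, nlag + 1):
            if denom == 0:
                out.append(1.0)
                continue
            num = (L - 1) * sum((x[i] - x[i + k]) ** 2 for i in range(L - k))
            out.append(num / (2.0 * (L - k) * denom))
    return out


def qso_socn_oracle(seq, nlag=10, w=0.1):
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    qso, socn = [], []
    counts = [seq.count(aa) for aa in AA_ALPHABET]
    L = len(seq)
    for D in DISTANCE_MATRICES.values():
        taus = []
        for d in range(1, nlag + 1):
            taus.append(sum(D[idx[seq[i]], idx[seq[i + d]]] ** 2 for i in range(L - d)))
        socn.extend(taus)
        denom = sum(counts) + w * sum(taus)
        qso.extend([c / denom for c in counts])
        qso.extend([w * t / denom for t in taus])
    return qso, socn


def instability_oracle(seq):
    from Bio.SeqUtils.ProtParamData import DIWV

    total = sum(DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 / len(seq) * total


def pi_gridscan_oracle(seq, step=0.001):
    """Finest-|charge| pH on a fine grid — independent of the bisection root."""
    counts = Counter(seq)
    best, best_ph = float("inf"), 0.0
    ph = 0.0
    while ph <= 14.0:
        q = abs(residue_charge(counts, ph))
        if q < best:
            best, best_ph = q, ph
        ph += step
    return best_ph


def binary_metrics_oracle(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return acc, sn, sp, mcc


def auc_pair_counting_oracle(truth, scores):
    """AUC by direct positive/negative pair counting with half-credit ties."""
    pos = [s for t, s in zip(truth, scores) if t]
    neg = [s for t, s in zip(truth, scores) if not t]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
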