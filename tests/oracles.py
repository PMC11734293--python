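"""Independent naive reference implementations used only by tests.

Everything here is written as directly as possible (explicit loops,
brute-force enumeration) and stays independent of the package code paths
it checks.
"""

from __future__ import annotations

import math

import numpy as np

GRID = [round(0.01 * k, 2) for k in range(101)]


def naive_contact_map(coords, threshold):
    n = len(coords)
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.dist(coords[i], coords[j])
            if d < threshold:
                adj[i, j] = 1
    return adj


def naive_gcn_layer(H, A, W):
    n = len(A)
    A_tilde = np.asarray(A, dtype=float) + np.eye(n)
    deg = A_tilde.sum(axis=1)
    D_inv_sqrt = np.diag(1.0 / np.sqrt(deg))
    return np.maximum(D_inv_sqrt @ A_tilde @ D_inv_sqrt @ H @ W, 0.0)


def naive_softmax(x, axis=-1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def bfs_closure(terms, parent_map):
    """Transitive closure of a term set under a child->parents map."""
    out = set(terms)
    frontier = list(terms)
    while frontier:
        term = frontier.pop()
        for parent in parent_map.get(term, ()):  # may be absent for roots
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def naive_term_aupr(scores, truth):
    """PR step integration over the descending 101-point grid."""
    n_pos = sum(truth)
    area = 0.0
    prev_rc = 0.0
    for t in reversed(GRID):
        pred = [s >= t for s in scores]
        n_pred = sum(pred)
        if n_pred == 0:
            continue
        tp = sum(1 for p, y in zip(pred, truth) if p and y)
        pr = tp / n_pred
        rc = tp / n_pos
        area += (rc - prev_rc) * pr
        prev_rc = rc
    return area


def naive_macro_aupr(P, Y):
    vals = []
    for c in range(Y.shape[1]):
        if Y[:, c].sum() == 0:
            continue
        vals.append(naive_term_aupr(list(P[:, c]), list(Y[:, c])))
    return sum(vals) / len(vals)


def naive_fmax(P, Y):
    n, C = P.shape
    best, best_t = 0.0, 0.0
    for t in GRID:
        prs, rcs = [], []
        for i in range(n):
            pred = [P[i, c] >= t for c in range(C)]
            tp = sum(1 for c in range(C) if pred[c] and Y[i, c])
            n_pred = sum(pred)
            n_true = sum(Y[i, :])
            if n_pred > 0:
                prs.append(tp / n_pred)
            rcs.append(tp / n_true)
        if not prs:
            continue
        avg_pr = sum(prs) / len(prs)
        avg_rc = sum(rcs) / n
        if avg_pr + avg_rc == 0:
            continue
        f = 2 * avg_pr * avg_rc / (avg_pr + avg_rc)
        if f > best:
            best, best_t = f, t
    return best, best_t


def naive_mcc(P, Y, t):
    tp = fp = tn = fn = 0
    n, C = P.shape
    for i in range(n):
        for c in range(C):
            pred = P[i, c] >= t
            true = Y[i, c] > 0
            if pred and true:
                tp += 1
            elif pred and not true:
                fp += 1
            elif not pred and true:
                fn += 1
            else:
                tn += 1
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def naive_smin(P, Y, term_ids, cond_ic, parent_map=None):
    """Exhaustive grid search; optional hierarchy closure of predictions."""
    n, C = P.shape
    pos = {t: c for c, t in enumerate(term_ids)}
    best, best_t = float("inf"), 0.0
    for t in GRID:
        ru_total = mi_total = 0.0
        for i in range(n):
            true_set = {term_ids[c] for c in range(C) if Y[i, c] > 0}
            pred_set = {term_ids[c] for c in range(C) if P[i, c] >= t}
            if parent_map is not None:
                pred_set = bfs_closure(pred_set, parent_map) & set(term_ids)
            for c in true_set - pred_set:
                ru_total += cond_ic[c]
            for c in pred_set - true_set:
                mi_total += cond_ic[c]
        ru = ru_total / n
        mi = mi_total / n
        s = math.sqrt(ru * ru + mi * mi)
        if s < best:
            best, best_t = s, t
    return best, best_t


def naive_pairwise_auc(scores, site_indices):
    """Mann-Whitney all-pairs comparison with ties counted 0.5."""
    sites = set(site_indices)
    pos = [scores[i] for i in range(len(scores)) if i in sites]
    neg = [scores[i] for i in range(len(scores)) if i not in sites]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def motif_occurrence_probability(motif, length, letter_probs):
    """Exact P(motif occurs in an iid sequence) via a KMP automaton DP."""
    m = len(motif)
    # failure function
    fail = [0] * m
    k = 0
    for i in range(1, m):
        while k > 0 and motif[i] != motif[k]:
            k = fail[k - 1]
        if motif[i] == motif[k]:
            k += 1
        fail[i] = k

    def advance(state, ch):
        while state > 0 and ch != motif[state]:
            state = fail[state - 1]
        if ch == motif[state]:
            state += 1
        return state

    # transition[state][letter] -> next state, absorbing at m
    letters = list(letter_probs)
    trans = {s: {ch: advance(s, ch) for ch in letters} for s in range(m)}
    prob = {0: 1.0}
    hit = 0.0
    for _ in range(length):
        nxt: dict[int, float] = {}
        for state, p in prob.items():
            for ch, q in letter_probs.items():
                ns = trans[state][ch]
                if ns == m:
                    hit += p * q
                else:
                    nxt[ns] = nxt.get(ns, 0.0) + p * q
        prob = nxt
    return hit


def finite_difference_grads(f, params, step=1e-5):
    """Central finite differences of scalar f() w.r.t. a dict of Tensors."""
    grads = {}
    for name, p in params.items():
        g = np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + step
            fp = f()
            flat[i] = orig - step
            fm = f()
            flat[i] = orig
            gflat[i] = (fp - fm) / (2 * step)
        grads[name] = g
    return grads
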