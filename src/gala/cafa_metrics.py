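"""CAFA-style evaluation: function-centric AUPR, protein-centric Fmax,
MCC at the Fmax threshold, and the information-theoretic Smin.

All metrics share the threshold grid t in {0.00, 0.01, ..., 1.00} and the
convention that "predicted at t" means score >= t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

THRESHOLDS = np.round(np.arange(0, 101) * 0.01, 2)


@dataclass
class EvalResult:
    aupr_macro: float
    per_term_aupr: dict[str, float]
    fmax: float
    fmax_threshold: float
    mcc: float
    smin: float | None = None
    smin_threshold: float | None = None
    per_bucket_aupr: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "aupr": self.aupr_macro,
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "mcc": self.mcc,
        }
        if self.smin is not None:
            out["smin"] = self.smin
            out["smin_threshold"] = self.smin_threshold
        if self.per_bucket_aupr:
            out["aupr_by_ic_bucket"] = self.per_bucket_aupr
        return out


class NoPositivesError(ValueError):
    """Raised when a term has no positive proteins and cannot be scored."""


def term_aupr(scores: np.ndarray, truth: np.ndarray) -> float:
    """Step-wise PR integration over the 101-threshold grid.

    Thresholds are visited in descending order so recall increments are
    non-negative; thresholds with zero predicted positives are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if scores.shape != truth.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {truth.shape}")
    n_pos = truth.sum()
    if n_pos == 0:
        raise NoPositivesError("term has no positive proteins")
    area = 0.0
    prev_recall = 0.0
    for t in THRESHOLDS[::-1]:
        predicted = scores >= t
        n_pred = predicted.sum()
        if n_pred == 0:
            continue
        tp = (predicted * truth).sum()
        precision = tp / n_pred
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return float(area)


def macro_aupr(P: np.ndarray, Y: np.ndarray,
               term_ids: list[str] | None = None
               ) -> tuple[float, dict[str, float]]:
    """Unweighted mean of term AUPRs over terms with >= 1 positive."""
    P, Y = np.asarray(P, dtype=float), np.asarray(Y, dtype=float)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Y.shape}")
    ids = term_ids if term_ids is not None else [str(c) for c in range(Y.shape[1])]
    per_term: dict[str, float] = {}
    for c in range(Y.shape[1]):
        if Y[:, c].sum() == 0:
            continue
        per_term[ids[c]] = term_aupr(P[:, c], Y[:, c])
    if not per_term:
        raise NoPositivesError("no terms with positive test proteins")
    return float(np.mean(list(per_term.values()))), per_term


def fmax(P: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """Protein-centric Fmax and its argmax threshold.

    Precision is averaged over proteins with at least one score >= t;
    recall is averaged over all proteins. Ties resolve to the smaller t.
    """
    P, Y = np.asarray(P, dtype=float), np.asarray(Y, dtype=float)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Y.shape}")
    empty = np.where(Y.sum(axis=1) == 0)[0]
    if empty.size:
        raise ValueError(f"proteins with empty truth at rows {empty.tolist()}")
    n = P.shape[0]
    n_true = Y.sum(axis=1)
    best_f, best_t = 0.0, 0.0
    for t in THRESHOLDS:
        predicted = P >= t
        n_pred = predicted.sum(axis=1)
        covered = n_pred > 0
        m_t = covered.sum()
        if m_t == 0:
            continue
        tp = (predicted * Y).sum(axis=1)
        avg_pr = (tp[covered] / n_pred[covered]).mean()
        avg_rc = (tp / n_true).sum() / n
        if avg_pr + avg_rc == 0:
            continue
        f = 2 * avg_pr * avg_rc / (avg_pr + avg_rc)
        if f > best_f:
            best_f, best_t = float(f), float(t)
    return best_f, best_t


def mcc_at_threshold(P: np.ndarray, Y: np.ndarray, threshold: float) -> float:
    """Micro MCC over all protein-term pairs binarized at score >= t.

    Any zero factor in the denominator yields MCC = 0.
    """
    P, Y = np.asarray(P, dtype=float), np.asarray(Y, dtype=float)
    predicted = P >= threshold
    truth = Y > 0
    tp = float(np.sum(predicted & truth))
    tn = float(np.sum(~predicted & ~truth))
    fp = float(np.sum(predicted & ~truth))
    fn = float(np.sum(~predicted & truth))
    return mcc_from_counts(tp, tn, fp, fn)


def mcc_from_counts(tp: float, tn: float, fp: float, fn: float) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def smin(P: np.ndarray, Y: np.ndarray, term_ids: list[str],
         conditional_ic: dict[str, float],
         dag=None) -> tuple[float, float]:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the grid.

    ru(t) averages the conditional IC of missed true terms, mi(t) that of
    falsely predicted terms. Predicted sets are hierarchy-closed before
    the set differences when a DAG is supplied.
    """
    P, Y = np.asarray(P, dtype=float), np.asarray(Y, dtype=float)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Y.shape}")
    missing = [t for c, t in enumerate(term_ids)
               if (Y[:, c].any() or P[:, c].any()) and t not in conditional_ic]
    if missing:
        raise ValueError(f"terms missing conditional IC: {missing}")
    ic = np.array([conditional_ic.get(t, 0.0) for t in term_ids])
    n = P.shape[0]

    closure = None
    if dag is not None:
        pos = {t: i for i, t in enumerate(term_ids)}
        closure = np.eye(len(term_ids), dtype=bool)
        for c, t in enumerate(term_ids):
            if t in dag.terms:
                for anc in dag.ancestors(t):
                    if anc in pos:
                        closure[c, pos[anc]] = True

    truth = Y > 0
    best = (np.inf, 0.0)
    for t in THRESHOLDS:
        predicted = P >= t
        if closure is not None:
            predicted = (predicted @ closure) > 0
        ru = (ic * (truth & ~predicted)).sum() / n
        mi = (ic * (predicted & ~truth)).sum() / n
        s = float(np.sqrt(ru * ru + mi * mi))
        if s < best[0]:
            best = (s, float(t))
    return best


def evaluate(P: np.ndarray, Y: np.ndarray, term_ids: list[str],
             conditional_ic: dict[str, float] | None = None,
             marginal_ic: dict[str, float] | None = None,
             dag=None) -> EvalResult:
    """All metrics on one prediction/truth pair; Smin needs an IC table."""
    aupr, per_term = macro_aupr(P, Y, term_ids)
    f, t_star = fmax(P, Y)
    mcc = mcc_at_threshold(P, Y, t_star)
    result = EvalResult(aupr_macro=aupr, per_term_aupr=per_term,
                        fmax=f, fmax_threshold=t_star, mcc=float(mcc))
    if conditional_ic is not None:
        result.smin, result.smin_threshold = smin(
            P, Y, term_ids, conditional_ic, dag=dag)
    if marginal_ic is not None:
        from .ontology import ic_category
        buckets: dict[str, list[float]] = {}
        for term, value in per_term.items():
            if term in marginal_ic:
                buckets.setdefault(ic_category(marginal_ic[term]), []).append(value)
        result.per_bucket_aupr = {k: float(np.mean(v))
                                  for k, v in sorted(buckets.items())}
    return result


# ---------------------------------------------------------------------------
# CAFA-style prediction TSV I/O
# ---------------------------------------------------------------------------

def write_predictions(P: np.ndarray, protein_ids: list[str],
                      term_ids: list[str], path) -> None:
    """`protein_id<TAB>GO_term<TAB>score`, scores rounded to 3 decimals."""
    with open(path, "w") as fh:
        for i, pid in enumerate(protein_ids):
            for c, term in enumerate(term_ids):
                fh.write(f"{pid}\t{term}\t{P[i, c]:.3f}\n")


def read_predictions(path, term_ids: list[str] | None = None
                     ) -> tuple[np.ndarray, list[str], list[str]]:
    rows: dict[str, dict[str, float]] = {}
    terms_seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, term, score = line.split("\t")
            rows.setdefault(pid, {})[term] = float(score)
            terms_seen.add(term)
    protein_ids = sorted(rows)
    if term_ids is None:
        term_ids = sorted(terms_seen)
    P = np.zeros((len(protein_ids), len(term_ids)))
    for i, pid in enumerate(protein_ids):
        for c, term in enumerate(term_ids):
            P[i, c] = rows[pid].get(term, 0.0)
    return P, protein_ids, list(term_ids)
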