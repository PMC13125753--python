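"""Survival-analysis applications: baseline tree encodings, Kaplan-Meier
and log-rank cluster analysis, and concordance evaluation.

Kaplan-Meier, the log-rank test and the censored concordance index are
implemented directly (and cross-checked against lifelines / scikit-survival
in the test suite); the IPCW concordance index and the survival SVM are
consumed from scikit-survival by contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .clustering import Clustering
from .trees import AlterationVocabulary, PhyloTree, clone

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "alteration_encoding",
    "clone_count_encoding",
    "concat_encoding",
    "cluster_onehot_encoding",
    "kaplan_meier",
    "logrank_test",
    "concordance_index_censored",
    "concordance_index_ipcw",
    "fit_survival_svm",
    "parse_survival_tsv",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """(time, event) pair: event=1 observed, event=0 censored."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


def _to_arrays(records: Sequence[SurvivalRecord]) -> Tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return times, events


def parse_survival_tsv(text: str) -> Dict[str, SurvivalRecord]:
    """Parse a TSV with columns patient_id, time, event."""
    out: Dict[str, SurvivalRecord] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("patient_id"):
            continue
        pid, t, e = line.split("\t")
        out[pid] = SurvivalRecord(time=float(t), event=int(e))
    return out


# ---------------------------------------------------------------------------
# Baseline tree encodings
# ---------------------------------------------------------------------------


def alteration_encoding(tree: PhyloTree, vocab: AlterationVocabulary) -> np.ndarray:
    """Binary presence vector of length m+2 (root flag, alterations, unknown)."""
    s = np.zeros(vocab.m + 2, dtype=np.int64)
    s[0] = 1
    for node in tree.nodes.values():
        for alt in node.label:
            idx = vocab.index_of.get(alt)
            if idx is None:
                s[vocab.m + 1] = 1
            else:
                s[idx] = 1
    return s


def clone_count_encoding(tree: PhyloTree, vocab: AlterationVocabulary) -> np.ndarray:
    """Per-alteration clone-membership counts, length m+2.

    Component 0 is the number of clones (= nodes, all contain the germline
    state); component m+1 counts clones containing any unknown alteration.
    """
    t = np.zeros(vocab.m + 2, dtype=np.int64)
    t[0] = len(tree.nodes)
    for v in tree.nodes:
        cl = clone(tree, v)
        has_unknown = False
        for alt in cl:
            idx = vocab.index_of.get(alt)
            if idx is None:
                has_unknown = True
            else:
                t[idx] += 1
        if has_unknown:
            t[vocab.m + 1] += 1
    return t


def concat_encoding(tree: PhyloTree, vocab: AlterationVocabulary) -> np.ndarray:
    """Alteration encoding followed by the clone-count encoding, length 2(m+2)."""
    return np.concatenate(
        [alteration_encoding(tree, vocab), clone_count_encoding(tree, vocab)]
    )


def cluster_onehot_encoding(item_id: str, clustering: Clustering) -> np.ndarray:
    if item_id not in clustering.assignment:
        raise KeyError(f"unknown item {item_id!r}")
    vec = np.zeros(clustering.K, dtype=np.int64)
    vec[clustering.assignment[item_id]] = 1
    return vec


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, sorted
    survival: np.ndarray  # product-limit estimate at those times
    at_risk: np.ndarray  # number at risk just before each time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")

    def probability_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator over the distinct observed event times."""
    if not records:
        raise ValueError("no survival records")
    times, events = _to_arrays(records)
    event_times = np.unique(times[events])
    surv = []
    at_risk = []
    s = 1.0
    for t in event_times:
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & events).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
    return KMCurve(
        times=event_times,
        survival=np.array(surv, dtype=float),
        at_risk=np.array(at_risk, dtype=int),
    )


def logrank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> Tuple[float, float]:
    """Multi-group log-rank test; chi-square with len(groups)-1 dof."""
    G = len(groups)
    if G < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    times_g, events_g = zip(*(_to_arrays(g) for g in groups))
    all_times = np.concatenate(times_g)
    all_events = np.concatenate(events_g)
    event_times = np.unique(all_times[all_events])

    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for t in event_times:
        n_t = int((all_times >= t).sum())
        d_t = int(((all_times == t) & all_events).sum())
        n_gt = np.array([(tg >= t).sum() for tg in times_g], dtype=float)
        d_gt = np.array(
            [((tg == t) & eg).sum() for tg, eg in zip(times_g, events_g)], dtype=float
        )
        O += d_gt
        E += d_t * n_gt / n_t
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1)
            p_gt = n_gt / n_t
            V += factor * (np.diag(p_gt) - np.outer(p_gt, p_gt))
    x = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(x @ np.linalg.pinv(Vsub) @ x)
    p = float(chi2_dist.sf(stat, G - 1))
    return stat, p


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def concordance_index_censored(
    scores: Sequence[float], records: Sequence[SurvivalRecord]
) -> float:
    """Harrell's C over comparable pairs (t_i < t_j with event_i = 1).

    Higher score must mean higher risk; score ties count 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    times, events = _to_arrays(records)
    if len(scores) != len(times):
        raise ValueError("scores and records are not aligned")
    concordant = 0.0
    comparable = 0
    for i in range(len(scores)):
        if not events[i]:
            continue
        later = times > times[i]
        comparable += int(later.sum())
        concordant += float((scores[i] > scores[later]).sum())
        concordant += 0.5 * float((scores[i] == scores[later]).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable


def concordance_index_ipcw(
    scores: Sequence[float],
    train_records: Sequence[SurvivalRecord],
    test_records: Sequence[SurvivalRecord],
) -> float:
    """IPCW concordance (Uno's C), censoring weights from the train records.

    Thin contract wrapper around scikit-survival.
    """
    from sksurv.metrics import concordance_index_ipcw as _sksurv_ipcw
    from sksurv.util import Surv

    tr_t, tr_e = _to_arrays(train_records)
    te_t, te_e = _to_arrays(test_records)
    y_train = Surv.from_arrays(event=tr_e, time=tr_t)
    y_test = Surv.from_arrays(event=te_e, time=te_t)
    cindex, *_ = _sksurv_ipcw(y_train, y_test, np.asarray(scores, dtype=float))
    return float(cindex)


def fit_survival_svm(
    features: np.ndarray, records: Sequence[SurvivalRecord], seed: int = 0
):
    """Fit a ranking survival SVM on feature vectors; consumed by contract.

    Returns a callable mapping a feature matrix to risk scores with the
    package-wide orientation (higher = shorter predicted survival).
    """
    from sksurv.svm import FastSurvivalSVM
    from sksurv.util import Surv

    times, events = _to_arrays(records)
    y = Surv.from_arrays(event=events, time=times)
    model = FastSurvivalSVM(rank_ratio=1.0, max_iter=200, random_state=seed)
    model.fit(np.asarray(features, dtype=float), y)

    def predict_risk(X: np.ndarray) -> np.ndarray:
        # with rank_ratio=1 predictions are already risk-oriented
        # (higher value = shorter predicted survival)
        return model.predict(np.asarray(X, dtype=float))

    return predict_risk
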